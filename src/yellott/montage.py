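"""Pointwise spacing/density maps over montages.

A montage is covered by an overlapping grid of n x n ROIs stepped by p
pixels (defaults n=128, p=32).  Each ROI is analyzed with the modal-spacing
estimator; its ICD and density values are spread over its whole footprint,
weighted by the estimate's confidence, and the overlapping contributions
are combined by weighted average per pixel.  ROIs with low mean intensity
(unimaged canvas, vessels) or bottom-percentile confidence are excluded,
and a foveal-artifact mask removes the physiologically impossible central
density dip produced by unresolved foveal cones.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .spacing import SpacingEstimate, estimate_modal_spacing
from .spectral import VERTICAL, RoiImage

__all__ = [
    "RoiGrid",
    "RoiEstimate",
    "DensityMap",
    "enumerate_rois",
    "analyze_rois",
    "apply_exclusions",
    "accumulate_maps",
    "build_pointwise_maps",
    "foveal_artifact_mask",
    "REASON_NONE",
    "REASON_LOW_INTENSITY",
    "REASON_LOW_CONFIDENCE",
    "REASON_FOVEAL",
    "REASON_UNCOVERED",
]

# Exclusion reason codes, per ROI (string) and per pixel (uint8 raster).
REASON_NONE = ""
REASON_LOW_INTENSITY = "low-intensity"
REASON_LOW_CONFIDENCE = "low-confidence"
REASON_FOVEAL = "foveal"
REASON_UNCOVERED = "uncovered"
REASON_CODES = {
    REASON_NONE: 0,
    REASON_UNCOVERED: 1,
    REASON_LOW_INTENSITY: 2,
    REASON_LOW_CONFIDENCE: 3,
    REASON_FOVEAL: 4,
}


@dataclass(frozen=True)
class RoiGrid:
    """Overlapping grid of square ROIs fully inside a montage."""

    n_px: int
    p_px: int
    origins: np.ndarray  # (k, 2) of 0-based (row, col) top-left offsets

    def __len__(self) -> int:
        return self.origins.shape[0]


@dataclass
class RoiEstimate:
    """Per-ROI spacing estimate plus bookkeeping for exclusions."""

    origin_row: int
    origin_col: int
    estimate: SpacingEstimate
    mean_intensity: float
    excluded_reason: str = REASON_NONE

    @property
    def excluded(self) -> bool:
        return self.excluded_reason != REASON_NONE


@dataclass
class DensityMap:
    """Per-pixel weighted maps over a montage with an exclusion mask.

    ``icd_map`` (um), ``density_map`` (cells/mm^2) and ``confidence_map``
    are confidence-weighted averages of the contributing ROIs; excluded
    pixels hold NaN.  ``reason_map`` carries per-pixel reason codes (see
    ``REASON_CODES``).
    """

    icd_map: np.ndarray
    density_map: np.ndarray
    confidence_map: np.ndarray
    weight_map: np.ndarray
    exclusion_mask: np.ndarray
    reason_map: np.ndarray
    roi_estimates: list = field(default_factory=list)
    n_px: int = 128
    p_px: int = 32
    scale_um_per_px: float = 1.0
    confidence_percentile: float = 5.0
    intensity_threshold: float = 10.0

    @property
    def shape(self) -> tuple[int, int]:
        return self.icd_map.shape


def enumerate_rois(montage_shape: tuple[int, int], n: int = 128, p: int = 32) -> RoiGrid:
    """Row-major origins {0, p, 2p, ...} per axis with every ROI inside."""
    h, w = int(montage_shape[0]), int(montage_shape[1])
    if not (n > p > 0):
        raise ValueError(f"require n > p > 0, got n={n}, p={p}")
    if h < n or w < n:
        raise ValueError(f"montage {h}x{w} smaller than ROI side n={n}")
    rows = np.arange(0, h - n + 1, p)
    cols = np.arange(0, w - n + 1, p)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    return RoiGrid(n_px=n, p_px=p, origins=np.column_stack([rr.ravel(), cc.ravel()]))


def analyze_rois(
    montage: np.ndarray,
    scale_um_per_px: float,
    grid: RoiGrid,
    orientation: str = VERTICAL,
) -> list[RoiEstimate]:
    """Run the modal-spacing estimator on every ROI of the grid."""
    montage = np.asarray(montage, dtype=float)
    out = []
    for r0, c0 in grid.origins:
        window = montage[r0 : r0 + grid.n_px, c0 : c0 + grid.n_px]
        roi = RoiImage(window, scale_um_per_px)
        est = estimate_modal_spacing(roi, orientation=orientation)
        out.append(
            RoiEstimate(
                origin_row=int(r0),
                origin_col=int(c0),
                estimate=est,
                mean_intensity=float(window.mean()),
            )
        )
    return out


def _assign_exclusions(
    estimates: list[RoiEstimate],
    confidence_percentile: float,
    intensity_threshold: float,
) -> None:
    """Set per-ROI exclusion reasons (in place, idempotent).

    Low mean intensity is applied first; the confidence percentile is then
    computed over the intensity-passing ROIs, and ROIs at or below it are
    dropped.  Foveal reasons assigned later by the artifact mask survive.
    """
    for e in estimates:
        if e.excluded_reason != REASON_FOVEAL:
            e.excluded_reason = REASON_NONE
        if e.mean_intensity < intensity_threshold:
            e.excluded_reason = REASON_LOW_INTENSITY
    bright = [e for e in estimates if e.excluded_reason in (REASON_NONE, REASON_FOVEAL)]
    if bright and confidence_percentile > 0:
        confs = np.array([e.estimate.confidence for e in bright])
        cutoff = np.percentile(confs, confidence_percentile)
        # Strictly below the percentile: K distinct confidences lose exactly
        # ceil(K * percentile / 100) ROIs, and ties at the cutoff (e.g. all
        # confidences equal) are kept rather than wiping the whole map.
        for e in bright:
            if e.estimate.confidence < cutoff and e.excluded_reason == REASON_NONE:
                e.excluded_reason = REASON_LOW_CONFIDENCE


def accumulate_maps(
    montage_shape: tuple[int, int],
    estimates: list[RoiEstimate],
    n: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Confidence-weighted accumulation of ROI values over their footprints.

    Every non-excluded ROI contributes its ICD/density/confidence, weighted
    by its confidence, to every pixel of its n x n footprint; the per-pixel
    value is sum(w*v)/sum(w).  Pixels with zero accumulated weight are NaN.
    Also returns the per-pixel exclusion reason raster, where a pixel
    covered only by excluded ROIs inherits the reason code of its covering
    ROIs (ties resolved toward the higher code).
    """
    h, w = montage_shape
    wsum = np.zeros((h, w))
    icd_acc = np.zeros((h, w))
    den_acc = np.zeros((h, w))
    conf_acc = np.zeros((h, w))
    reason = np.zeros((h, w), dtype=np.uint8)
    covered = np.zeros((h, w), dtype=bool)
    for e in estimates:
        sl = (slice(e.origin_row, e.origin_row + n), slice(e.origin_col, e.origin_col + n))
        covered[sl] = True
        if e.excluded:
            code = REASON_CODES[e.excluded_reason]
            reason[sl] = np.maximum(reason[sl], code)
            continue
        w_i = e.estimate.confidence
        if w_i <= 0:
            continue
        wsum[sl] += w_i
        icd_acc[sl] += w_i * e.estimate.icd_m_um
        den_acc[sl] += w_i * e.estimate.density_mm2
        conf_acc[sl] += w_i * e.estimate.confidence
    valid = wsum > 0
    icd_map = np.full((h, w), np.nan)
    den_map = np.full((h, w), np.nan)
    conf_map = np.full((h, w), np.nan)
    icd_map[valid] = icd_acc[valid] / wsum[valid]
    den_map[valid] = den_acc[valid] / wsum[valid]
    conf_map[valid] = conf_acc[valid] / wsum[valid]
    reason[valid] = 0
    reason[~covered] = REASON_CODES[REASON_UNCOVERED]
    return icd_map, den_map, conf_map, wsum, ~valid, reason


def apply_exclusions(
    dmap: DensityMap,
    roi_estimates: list[RoiEstimate] | None = None,
    confidence_percentile: float | None = None,
    intensity_threshold: float | None = None,
) -> DensityMap:
    """(Re)apply the intensity and confidence-percentile exclusion rules.

    The percentile is always recomputed over the full intensity-passing ROI
    set, so re-running on an already-masked map changes nothing.
    Returns a new :class:`DensityMap` with rebuilt maps and masks.
    """
    estimates = roi_estimates if roi_estimates is not None else dmap.roi_estimates
    cp = dmap.confidence_percentile if confidence_percentile is None else confidence_percentile
    it = dmap.intensity_threshold if intensity_threshold is None else intensity_threshold
    _assign_exclusions(estimates, cp, it)
    icd, den, conf, wsum, excl, reason = accumulate_maps(dmap.shape, estimates, dmap.n_px)
    return replace(
        dmap,
        icd_map=icd,
        density_map=den,
        confidence_map=conf,
        weight_map=wsum,
        exclusion_mask=excl,
        reason_map=reason,
        roi_estimates=estimates,
        confidence_percentile=cp,
        intensity_threshold=it,
    )


def build_pointwise_maps(
    montage: np.ndarray,
    scale_um_per_px: float,
    n: int = 128,
    p: int = 32,
    orientation: str = VERTICAL,
    confidence_percentile: float = 5.0,
    intensity_threshold: float = 10.0,
    mask_foveal_artifact: bool = False,
) -> DensityMap:
    """Build confidence-weighted ICD/density/confidence maps over a montage.

    Defaults follow standard practice for ~0.5 um/px confocal AOSLO
    montages: 128-px ROIs stepped by 32 px, bottom-5th-percentile
    confidence and mean intensity < 10 (0-255 scale) excluded.
    """
    montage = np.asarray(montage, dtype=float)
    grid = enumerate_rois(montage.shape, n, p)
    estimates = analyze_rois(montage, scale_um_per_px, grid, orientation=orientation)
    dmap = DensityMap(
        icd_map=np.full(montage.shape, np.nan),
        density_map=np.full(montage.shape, np.nan),
        confidence_map=np.full(montage.shape, np.nan),
        weight_map=np.zeros(montage.shape),
        exclusion_mask=np.ones(montage.shape, dtype=bool),
        reason_map=np.zeros(montage.shape, dtype=np.uint8),
        roi_estimates=estimates,
        n_px=n,
        p_px=p,
        scale_um_per_px=scale_um_per_px,
        confidence_percentile=confidence_percentile,
        intensity_threshold=intensity_threshold,
    )
    dmap = apply_exclusions(dmap)
    if mask_foveal_artifact:
        mask = foveal_artifact_mask(dmap)
        if mask.any():
            dmap.reason_map[mask] = REASON_CODES[REASON_FOVEAL]
            dmap.exclusion_mask |= mask
            for m in (dmap.icd_map, dmap.density_map, dmap.confidence_map):
                m[mask] = np.nan
    return dmap


def _ring_profile(
    density: np.ndarray, center: tuple[int, int], ring_px: int
) -> np.ndarray:
    """Mean density in concentric rings of width ring_px around center."""
    h, w = density.shape
    yy, xx = np.mgrid[0:h, 0:w]
    r = np.hypot(yy - center[0], xx - center[1])
    ring = (r // ring_px).astype(int)
    valid = np.isfinite(density)
    n_rings = int(ring[valid].max()) + 1 if valid.any() else 0
    out = np.full(n_rings, np.nan)
    for k in range(n_rings):
        sel = valid & (ring == k)
        if sel.any():
            out[k] = density[sel].mean()
    return out


def foveal_artifact_mask(
    dmap: DensityMap,
    ring_px: int | None = None,
    min_rise_frac: float = 0.02,
) -> np.ndarray:
    """Mask the spurious central density dip caused by unresolved foveal cones.

    Physiologically, density decreases monotonically with eccentricity; a
    central region where density instead *increases* outward is an imaging
    artifact.  The mask grows outward from the central density minimum
    ring by ring until the radial density gradient changes sign (density
    begins its normal decrease with eccentricity).  Returns an empty mask
    when no inverted gradient is present.
    """
    density = dmap.density_map
    h, w = density.shape
    ring_px = ring_px or max(4, dmap.p_px // 2)
    smoothed = density.copy()
    finite = np.isfinite(smoothed)
    if not finite.any():
        return np.zeros((h, w), dtype=bool)
    fill = np.nanmedian(smoothed)
    smoothed[~finite] = fill
    smoothed = gaussian_filter(smoothed, sigma=max(2.0, dmap.p_px / 2.0))

    # Candidate dip: a genuine local minimum of the smoothed density inside
    # the central half of the montage (a monotone map has its minimum at
    # the periphery and therefore no interior local minimum).
    from scipy.ndimage import minimum_filter

    local_min = smoothed <= minimum_filter(smoothed, size=5)
    window = np.zeros((h, w), dtype=bool)
    window[h // 4 : 3 * h // 4, w // 4 : 3 * w // 4] = True
    candidates = np.argwhere(local_min & window)
    if candidates.size == 0:
        return np.zeros((h, w), dtype=bool)
    vals = smoothed[candidates[:, 0], candidates[:, 1]]
    cy, cx = (int(v) for v in candidates[int(np.argmin(vals))])

    profile = _ring_profile(np.where(finite, density, np.nan), (cy, cx), ring_px)
    profile = profile[np.isfinite(profile)]
    if profile.size < 3:
        return np.zeros((h, w), dtype=bool)
    # Require a genuine rise away from the dip before the normal decrease.
    k_peak = int(np.argmax(profile))
    if k_peak == 0 or profile[k_peak] - profile[0] < min_rise_frac * abs(profile[0]):
        return np.zeros((h, w), dtype=bool)
    # First ring where density starts decreasing with eccentricity.
    k_stop = k_peak
    for k in range(1, profile.size):
        if profile[k] < profile[k - 1]:
            k_stop = k - 1
            break
    radius = (k_stop + 1) * ring_px
    yy, xx = np.mgrid[0:h, 0:w]
    return np.hypot(yy - cy, xx - cx) <= radius
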