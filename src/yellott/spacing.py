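"""Modal spacing extraction: multiscale exponential fits, peak crawling,
confidence scoring, and hexagonal-packing conversions.

Pipeline for a single ROI:

1. radially averaged log power spectrum (``yellott.spectral``);
2. single-term exponential fit ``A*exp(B*r)`` to the profile, subtracted;
3. residuals smoothed with a cubic smoothing spline; the residual maximum
   gives a rough modal-spacing estimate;
4. a piecewise single-term exponential, linked (and continuous) at the
   rough estimate, is refit to the profile and subtracted;
5. starting from the rough estimate, a peak crawl toward lower frequency
   finds the first peak of the re-smoothed residuals: the modal spacing;
6. confidence = peak prominence (larger one-sided drop to a flanking base)
   normalized by the maximum residual amplitude, clamped to [0, 1].

The modal peak radius ``f`` (cycles per ROI side) converts to a row spacing
``s_r = N / f`` pixels.  For a hexagonally packed mosaic the intercell
distance is ``ICD = (2/sqrt(3)) * s_r`` and the areal density is
``D = 1e6 * sqrt(3) / (2 * s_r_um**2)`` cells/mm^2.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.interpolate import make_smoothing_spline
from scipy.optimize import OptimizeWarning, curve_fit

from .spectral import (
    HORIZONTAL,
    VERTICAL,
    RadialProfile,
    RoiImage,
    _normalize_orientation,
    log_power_spectrum,
    radial_wedge_average,
)

__all__ = [
    "ExponentialFit",
    "SpacingEstimate",
    "fit_exp1",
    "smooth_residuals",
    "initial_spacing_estimate",
    "fit_piecewise_exp",
    "peak_crawl",
    "spacing_confidence",
    "estimate_modal_spacing",
    "icd_from_row_spacing",
    "density_from_row_spacing",
    "R_MIN",
]

#: Low-frequency guard (radius bins): the residual search and peak crawl
#: never descend below this radius, excluding residual DC leakage.
R_MIN = 3

SQRT3 = math.sqrt(3.0)


@dataclass(frozen=True)
class ExponentialFit:
    """Single or piecewise single-term exponential fit to a radial profile."""

    kind: str  # "single" | "piecewise"
    coefficients: tuple
    fitted_values: np.ndarray
    residuals: np.ndarray
    link_radius: int | None = None
    fallback: bool = False
    degenerate_segment: bool = False

    @property
    def sse(self) -> float:
        return float(np.sum(self.residuals**2))


@dataclass(frozen=True)
class SpacingEstimate:
    """Modal row spacing of one ROI with derived metrics.

    Attributes
    ----------
    s_r_px, s_r_um
        Modal row spacing in pixels and micrometers.
    icd_m_um
        Modal intercell distance; ``(2/sqrt(3)) * s_r_um`` for the vertical
        wedge, ``s_r_um`` itself for the horizontal (split-detection) wedge.
    density_mm2
        Hexagonal-packing areal density in cells/mm^2.
    confidence
        Normalized modal-peak prominence in [0, 1].
    peak_radius
        Sub-bin frequency of the modal peak (cycles per ROI side).
    """

    s_r_px: float
    s_r_um: float
    icd_m_um: float
    density_mm2: float
    confidence: float
    peak_radius: float
    orientation: str = VERTICAL
    low_confidence_flag: bool = False

    def to_dict(self) -> dict:
        return {
            "s_r_px": self.s_r_px,
            "s_r_um": self.s_r_um,
            "icd_m_um": self.icd_m_um,
            "density_mm2": self.density_mm2,
            "confidence": self.confidence,
            "peak_radius": self.peak_radius,
            "orientation": self.orientation,
            "low_confidence_flag": self.low_confidence_flag,
        }


# ---------------------------------------------------------------------------
# conversions (hexagonal packing)
# ---------------------------------------------------------------------------

def icd_from_row_spacing(s_r: float) -> float:
    """Intercell distance of a hexagonally packed mosaic with row spacing s_r."""
    if not s_r > 0:
        raise ValueError("row spacing must be positive")
    return (2.0 / SQRT3) * s_r


def density_from_row_spacing(s_r_um: float) -> float:
    """Areal density (cells/mm^2) of a hexagonal mosaic with row spacing in um."""
    if not s_r_um > 0:
        raise ValueError("row spacing must be positive")
    return 1000.0**2 * SQRT3 / (2.0 * s_r_um**2)


# ---------------------------------------------------------------------------
# exponential fits
# ---------------------------------------------------------------------------

def _loglinear_seed(r: np.ndarray, v: np.ndarray) -> tuple[float, float]:
    """(A, B) from a log-linear regression on the positively shifted profile."""
    shifted = v - v.min() + 1.0
    slope, intercept = np.polyfit(r, np.log(shifted), 1)
    return float(np.exp(intercept)), float(slope)


def fit_exp1(profile: RadialProfile) -> ExponentialFit:
    """Least-squares fit of ``v(r) = A * exp(B * r)`` over the full profile.

    Initial parameters come from a log-linear regression; if the nonlinear
    solver does not converge the closed-form log-linear solution is
    returned with ``fallback=True``.
    """
    r = profile.radius_bins.astype(float)
    v = profile.values
    if r.size < 8:
        raise ValueError("profile needs at least 8 bins for an exponential fit")
    a0, b0 = _loglinear_seed(r, v)

    def model(x, a, b):
        return a * np.exp(np.clip(b * x, -700, 700))

    fallback = False
    try:
        with warnings.catch_warnings():
            # Degenerate covariance is expected on e.g. constant profiles.
            warnings.simplefilter("ignore", OptimizeWarning)
            (a, b), _ = curve_fit(model, r, v, p0=(a0, b0), maxfev=10000)
        if not (np.isfinite(a) and np.isfinite(b)):
            raise RuntimeError("non-finite fit")
    except (RuntimeError, ValueError):
        a, b = a0, b0
        fallback = True
    fitted = model(r, a, b)
    return ExponentialFit(
        kind="single",
        coefficients=(float(a), float(b)),
        fitted_values=fitted,
        residuals=v - fitted,
        fallback=fallback,
    )


def _piecewise_model(r: np.ndarray, link: float, v_link: float, b1: float, b2: float) -> np.ndarray:
    """Two single-term exponentials sharing the value v_link at the link radius.

    Each half is ``v_link * exp(b * (r - link))``, so continuity at the link
    is enforced by construction.
    """
    out = np.where(
        r <= link,
        v_link * np.exp(np.clip(b1 * (r - link), -700, 700)),
        v_link * np.exp(np.clip(b2 * (r - link), -700, 700)),
    )
    return out


def fit_piecewise_exp(profile: RadialProfile, link_radius: int) -> ExponentialFit:
    """Continuous piecewise single-term exponential fit linked at ``link_radius``.

    The two halves are fit jointly by least squares over the full profile
    support.  Initialization tries both per-segment log-linear seeds and the
    global single-exponential solution (which the piecewise family nests),
    keeping whichever converged solution has the lower SSE; the piecewise
    SSE therefore never exceeds the single-exponential SSE beyond solver
    tolerance.  A segment with fewer than 3 bins degenerates to a constant.
    """
    r = profile.radius_bins.astype(float)
    v = profile.values
    link = int(link_radius)
    if link <= r[0] or link >= r[-1]:
        raise ValueError(
            f"link radius {link} outside the open range ({int(r[0])}, {int(r[-1])})"
        )
    left = r <= link
    right = r >= link
    degenerate = left.sum() < 3 or right.sum() < 3

    single = fit_exp1(profile)
    a_s, b_s = single.coefficients
    v_link0 = float(np.interp(link, r, v))

    seeds = [(v_link0, 0.0, 0.0), (a_s * math.exp(min(b_s * link, 700)), b_s, b_s)]
    if left.sum() >= 3 and right.sum() >= 3:
        try:
            _, bl = _loglinear_seed(r[left], v[left])
            _, br = _loglinear_seed(r[right], v[right])
            seeds.insert(0, (v_link0, bl, br))
        except (ValueError, np.linalg.LinAlgError):
            pass

    def model(x, v_link, b1, b2):
        if degenerate:
            b1 = b1 if left.sum() >= 3 else 0.0
            b2 = b2 if right.sum() >= 3 else 0.0
        return _piecewise_model(x, link, v_link, b1, b2)

    best = None
    for p0 in seeds:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", OptimizeWarning)
                popt, _ = curve_fit(model, r, v, p0=p0, maxfev=10000)
        except (RuntimeError, ValueError):
            continue
        if not np.all(np.isfinite(popt)):
            continue
        sse = float(np.sum((v - model(r, *popt)) ** 2))
        if best is None or sse < best[0]:
            best = (sse, popt)
    if best is None:  # fall back to the nested single-exponential solution
        popt = np.array(seeds[-1])
    else:
        popt = best[1]
    # Never report a fit worse than the nested single-exponential one.
    nested = np.array(seeds[1])
    if float(np.sum((v - model(r, *popt)) ** 2)) > float(
        np.sum((v - model(r, *nested)) ** 2)
    ):
        popt = nested
    fitted = model(r, *popt)
    return ExponentialFit(
        kind="piecewise",
        coefficients=tuple(float(c) for c in popt),
        fitted_values=fitted,
        residuals=v - fitted,
        link_radius=link,
        degenerate_segment=bool(degenerate),
    )


# ---------------------------------------------------------------------------
# spline smoothing with a fixed effective-df rule
# ---------------------------------------------------------------------------

def _smoother_trace(x: np.ndarray, lam: float) -> float:
    """Trace of the cubic smoothing-spline hat matrix at penalty lam."""
    m = x.size
    trace = 0.0
    e = np.zeros(m)
    for i in range(m):
        e[i] = 1.0
        trace += float(make_smoothing_spline(x, e, lam=lam)(x[i]))
        e[i] = 0.0
    return trace


@lru_cache(maxsize=64)
def _lam_for_radii(radii: tuple) -> float:
    """Penalty giving effective df ~ one third of the bin count (floor 3)."""
    x = np.asarray(radii, dtype=float)
    target = max(3.0, x.size / 3.0)
    lo, hi = 1e-9, 1e9
    # df(lam) decreases monotonically from m toward 2 as lam grows.
    for _ in range(60):
        mid = math.sqrt(lo * hi)
        if _smoother_trace(x, mid) > target:
            lo = mid
        else:
            hi = mid
    return math.sqrt(lo * hi)


def smooth_residuals(residuals: np.ndarray, radii: np.ndarray | None = None) -> np.ndarray:
    """Cubic smoothing-spline estimate of the residuals at the same radii.

    The smoothing penalty is fixed by a deterministic, size-relative rule:
    effective residual degrees of freedom of roughly one third of the bin
    count (enough to suppress bin-to-bin noise without flattening a modal
    peak a few bins wide).  The penalty depends only on the radius grid and
    is cached.
    """
    v = np.asarray(residuals, dtype=float)
    if v.size < 8:
        raise ValueError("need at least 8 values to smooth")
    x = np.arange(1, v.size + 1, dtype=float) if radii is None else np.asarray(radii, dtype=float)
    if np.allclose(v, v[0]):
        return np.full_like(v, v[0])
    lam = _lam_for_radii(tuple(x))
    return make_smoothing_spline(x, v, lam=lam)(x)


# ---------------------------------------------------------------------------
# residual peak machinery
# ---------------------------------------------------------------------------

def initial_spacing_estimate(profile: RadialProfile, r_min: int = R_MIN) -> int:
    """Rough modal-spacing frequency: argmax of the smoothed first-pass residuals.

    The search is restricted to radii >= ``r_min`` so residual DC energy
    cannot capture the estimate.
    """
    fit = fit_exp1(profile)
    smoothed = smooth_residuals(fit.residuals, profile.radius_bins)
    mask = profile.radius_bins >= r_min
    if not mask.any():
        raise ValueError(f"no radii >= r_min={r_min} to search")
    idx = np.argmax(smoothed[mask])
    return int(profile.radius_bins[mask][idx])


def _quadratic_refine(values: np.ndarray, i: int) -> float:
    """Sub-bin offset of a peak at index i from a 3-point parabola, in [-0.5, 0.5]."""
    if i <= 0 or i >= values.size - 1:
        return 0.0
    denom = values[i - 1] - 2.0 * values[i] + values[i + 1]
    if denom >= 0:
        return 0.0
    offset = 0.5 * (values[i - 1] - values[i + 1]) / denom
    return float(np.clip(offset, -0.5, 0.5))


def peak_crawl(
    smoothed_residuals: np.ndarray,
    start: int,
    radii: np.ndarray | None = None,
    r_min: int = R_MIN,
) -> tuple[int, float, bool]:
    """Walk from ``start`` toward lower radii to the first peak encountered.

    The crawl moves while the value is non-decreasing toward lower radii,
    so a plateau resolves to its lowest-radius bin.  If the value at the
    start is already a local maximum the start is returned.  Reaching
    ``r_min`` without a maximum returns ``r_min`` flagged low-confidence.

    Returns ``(peak_bin, refined_radius, flagged)`` where ``refined_radius``
    adds a 3-point quadratic sub-bin offset.
    """
    v = np.asarray(smoothed_residuals, dtype=float)
    r = np.arange(1, v.size + 1) if radii is None else np.asarray(radii, dtype=int)
    pos_candidates = np.flatnonzero(r == int(start))
    if pos_candidates.size == 0:
        raise ValueError(f"start radius {start} not in profile range")
    i = int(pos_candidates[0])
    i_min = int(np.flatnonzero(r >= r_min)[0]) if (r >= r_min).any() else 0
    while i > i_min and v[i - 1] >= v[i]:
        i -= 1
    if i > i_min:
        flagged = False  # stopped at a genuine local maximum
    elif i > 0:
        flagged = bool(v[i - 1] >= v[i])  # floor reached while still climbing
    else:
        flagged = not (v.size > 1 and v[0] > v[1])
    refined = float(r[i]) + _quadratic_refine(v, i)
    return int(r[i]), refined, bool(flagged)


def _flanking_base(values: np.ndarray, peak: int, step: int) -> float:
    """Minimum value between the peak and the next higher point (or boundary)."""
    base = values[peak]
    i = peak + step
    while 0 <= i < values.size and values[i] <= values[peak]:
        base = min(base, values[i])
        i += step
    return float(base)


def spacing_confidence(
    smoothed_residuals: np.ndarray, peak: int, radii: np.ndarray | None = None
) -> float:
    """Normalized prominence of the modal peak, in [0, 1].

    Prominence is the larger of the two one-sided drops from the peak to
    its flanking bases (the minimum on each side before the curve exceeds
    the peak again, or the boundary).  The result is normalized by the
    maximum absolute residual amplitude and clamped to [0, 1].
    """
    v = np.asarray(smoothed_residuals, dtype=float)
    r = np.arange(1, v.size + 1) if radii is None else np.asarray(radii, dtype=int)
    amp = float(np.max(np.abs(v))) if v.size else 0.0
    if amp == 0.0:
        return 0.0
    idx = np.flatnonzero(r == int(peak))
    if idx.size == 0:
        raise ValueError(f"peak radius {peak} not in profile range")
    i = int(idx[0])
    drop_left = v[i] - _flanking_base(v, i, -1)
    drop_right = v[i] - _flanking_base(v, i, +1)
    prominence = max(drop_left, drop_right)
    return float(np.clip(prominence / amp, 0.0, 1.0))


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def estimate_modal_spacing(
    roi: RoiImage,
    orientation: str = VERTICAL,
    r_min: int = R_MIN,
    profile: RadialProfile | None = None,
) -> SpacingEstimate:
    """Run the full modal-spacing pipeline on one ROI.

    Parameters
    ----------
    roi
        Square ROI with a physical scale.
    orientation
        ``"vertical-wedge"`` (default, confocal cone imagery: the peak
        measures row spacing, converted to ICD via the hexagonal factor
        2/sqrt(3)) or ``"horizontal-wedge"`` (split detection: the modal
        spacing is taken as the ICD directly).
    profile
        Precomputed radial profile, if the caller already has one.

    A structureless (flat) spectrum yields an estimate with confidence 0
    rather than an error.
    """
    orientation = _normalize_orientation(orientation)
    if profile is None:
        spectrum = log_power_spectrum(roi)
        profile = radial_wedge_average(spectrum, orientation)
    n = roi.side_px

    if np.allclose(profile.values, profile.values[0]):
        # Flat spectrum: no modal structure.
        s_r_px = float(n) / max(r_min, 1)
        s_r_um = s_r_px * roi.scale_um_per_px
        icd = s_r_um if orientation == HORIZONTAL else icd_from_row_spacing(s_r_um)
        return SpacingEstimate(
            s_r_px=s_r_px,
            s_r_um=s_r_um,
            icd_m_um=icd,
            density_mm2=1000.0**2 * 2.0 / (SQRT3 * icd**2),
            confidence=0.0,
            peak_radius=float(r_min),
            orientation=orientation,
            low_confidence_flag=True,
        )

    rough = initial_spacing_estimate(profile, r_min=r_min)
    r_last = int(profile.radius_bins[-1])
    link = int(np.clip(rough, r_min + 1, r_last - 1))
    piecewise = fit_piecewise_exp(profile, link)
    smoothed = smooth_residuals(piecewise.residuals, profile.radius_bins)
    peak_bin, peak_radius, flagged = peak_crawl(
        smoothed, start=rough, radii=profile.radius_bins, r_min=r_min
    )
    confidence = 0.0 if flagged else spacing_confidence(
        smoothed, peak_bin, radii=profile.radius_bins
    )

    s_r_px = float(n) / peak_radius
    s_r_um = s_r_px * roi.scale_um_per_px
    if orientation == HORIZONTAL:
        icd = s_r_um
    else:
        icd = icd_from_row_spacing(s_r_um)
    density = 1000.0**2 * 2.0 / (SQRT3 * icd**2)
    return SpacingEstimate(
        s_r_px=s_r_px,
        s_r_um=s_r_um,
        icd_m_um=icd,
        density_mm2=density,
        confidence=confidence,
        peak_radius=peak_radius,
        orientation=orientation,
        low_confidence_flag=flagged,
    )
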