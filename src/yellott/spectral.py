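"""Fourier-domain primitives: log power spectra and wedge-restricted radial averages.

A quasi-regular photoreceptor mosaic concentrates spectral energy in an
annulus whose radius equals the dominant spatial frequency of the cell
packing (the "Yellott's ring" phenomenon).  The radial average of the log
power spectrum over a 90-degree double wedge turns that annulus into a
one-dimensional profile with a single modal peak, which downstream fitting
converts into a row-spacing estimate.

Only the two fixed orientations used for cone imaging are supported: the
vertical double wedge (polar angles within 45 degrees of straight up/down,
sensitive to the row spacing of a hexagonal mosaic) and the horizontal
double wedge (within 45 degrees of left/right, used for split-detection
imagery whose contrast is horizontally dominant).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RoiImage",
    "RadialProfile",
    "log_power_spectrum",
    "radial_wedge_average",
    "POWER_FLOOR_FRAC",
    "MIN_ROI_SIDE",
]

#: Relative floor added to the power spectrum before taking the log, as a
#: fraction of the maximum power.  Makes log power defined on zero bins.
POWER_FLOOR_FRAC = 1e-12

#: Smallest ROI side length (pixels) the estimator accepts.
MIN_ROI_SIDE = 16

VERTICAL = "vertical-wedge"
HORIZONTAL = "horizontal-wedge"
_ORIENTATIONS = (VERTICAL, HORIZONTAL)


def _normalize_orientation(orientation: str) -> str:
    key = str(orientation).lower().replace("_", "-")
    if key in ("vertical", VERTICAL, "v"):
        return VERTICAL
    if key in ("horizontal", HORIZONTAL, "h"):
        return HORIZONTAL
    raise ValueError(
        f"orientation must be one of {_ORIENTATIONS}, got {orientation!r}"
    )


@dataclass(frozen=True)
class RoiImage:
    """A square, single-channel region of interest with a physical scale.

    Parameters
    ----------
    pixels
        2-D array of non-negative, finite intensities in native units
        (8-bit images stay on the 0-255 scale).
    scale_um_per_px
        Micrometers on the retina per image pixel (> 0).
    """

    pixels: np.ndarray
    scale_um_per_px: float

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise ValueError("ROI must be a 2-D array")
        if px.shape[0] != px.shape[1]:
            raise ValueError(
                f"ROI must be square, got shape {px.shape}; "
                "montage grids always yield square ROIs"
            )
        if px.shape[0] < MIN_ROI_SIDE:
            raise ValueError(f"ROI must be at least {MIN_ROI_SIDE}x{MIN_ROI_SIDE}")
        if not np.all(np.isfinite(px)):
            raise ValueError("ROI contains non-finite pixels")
        if not (np.isfinite(self.scale_um_per_px) and self.scale_um_per_px > 0):
            raise ValueError("scale_um_per_px must be positive and finite")
        object.__setattr__(self, "pixels", px)
        object.__setattr__(self, "scale_um_per_px", float(self.scale_um_per_px))

    @property
    def side_px(self) -> int:
        return self.pixels.shape[0]


@dataclass(frozen=True)
class RadialProfile:
    """Radially averaged log power within one double wedge.

    ``values[i]`` is the mean log power over all spectrum elements whose
    rounded Euclidean radius from the zero-frequency center equals
    ``radius_bins[i]`` (cycles per ROI side) and whose polar angle falls in
    the wedge.  The DC term (radius 0) is excluded; bins run 1..floor(N/2).
    """

    radius_bins: np.ndarray
    values: np.ndarray
    orientation: str
    roi_side_px: int
    interpolated: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        r = np.asarray(self.radius_bins, dtype=int)
        v = np.asarray(self.values, dtype=float)
        if r.shape != v.shape or r.ndim != 1:
            raise ValueError("radius_bins and values must be matching 1-D arrays")
        if r.size and (r[0] < 1 or np.any(np.diff(r) <= 0)):
            raise ValueError("radius bins must be strictly increasing and start >= 1")
        if not np.all(np.isfinite(v)):
            raise ValueError("profile values must be finite")
        interp = self.interpolated
        if interp is None:
            interp = np.zeros(r.shape, dtype=bool)
        object.__setattr__(self, "radius_bins", r)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "orientation", _normalize_orientation(self.orientation))
        object.__setattr__(self, "interpolated", np.asarray(interp, dtype=bool))

    def __len__(self) -> int:
        return self.values.size


def log_power_spectrum(roi: RoiImage) -> np.ndarray:
    """Centered log power spectrum of an ROI.

    The ROI mean is subtracted before the DFT to suppress DC leakage into
    the low-frequency bins; no apodization window is applied.  Output has
    the same shape as the input with the zero-frequency term at element
    ``(N//2, N//2)`` and values ``log(|F|^2 + eps)`` where ``eps`` is
    :data:`POWER_FLOOR_FRAC` times the maximum power.
    """
    if not isinstance(roi, RoiImage):
        roi = RoiImage(np.asarray(roi, dtype=float), 1.0)
    px = roi.pixels - roi.pixels.mean()
    spectrum = np.fft.fftshift(np.fft.fft2(px))
    power = np.abs(spectrum) ** 2
    peak = power.max()
    eps = POWER_FLOOR_FRAC * (peak if peak > 0 else 1.0)
    return np.log(power + eps)


def _wedge_masks(n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rounded radius and wedge membership for an n x n centered spectrum."""
    center = n // 2
    rows = np.arange(n) - center
    cols = np.arange(n) - center
    dr = rows[:, None]
    dc = cols[None, :]
    radius = np.rint(np.hypot(dr, dc)).astype(int)
    # Boundary angles (exactly 45 degrees) belong to the vertical wedge.
    vertical = np.abs(dc) <= np.abs(dr)
    return radius, vertical, ~vertical


def radial_wedge_average(spectrum: np.ndarray, orientation: str) -> RadialProfile:
    """Average a centered log-power grid over integer radii within a wedge.

    Both opposing 90-degree sectors are pooled.  A radius bin with no
    members inside the wedge is filled by linear interpolation from its
    neighbors and flagged in ``profile.interpolated``.
    """
    spectrum = np.asarray(spectrum, dtype=float)
    if spectrum.ndim != 2 or spectrum.shape[0] != spectrum.shape[1]:
        raise ValueError("spectrum must be a square 2-D array")
    orientation = _normalize_orientation(orientation)
    n = spectrum.shape[0]
    r_max = n // 2
    radius, vertical, horizontal = _wedge_masks(n)
    in_wedge = vertical if orientation == VERTICAL else horizontal
    select = in_wedge & (radius >= 1) & (radius <= r_max)

    r_sel = radius[select]
    v_sel = spectrum[select]
    counts = np.bincount(r_sel, minlength=r_max + 1)[1:]
    sums = np.bincount(r_sel, weights=v_sel, minlength=r_max + 1)[1:]

    values = np.full(r_max, np.nan)
    nonzero = counts > 0
    values[nonzero] = sums[nonzero] / counts[nonzero]
    interpolated = ~nonzero
    if interpolated.any():
        bins = np.arange(1, r_max + 1, dtype=float)
        values[interpolated] = np.interp(
            bins[interpolated], bins[nonzero], values[nonzero]
        )
    return RadialProfile(
        radius_bins=np.arange(1, r_max + 1),
        values=values,
        orientation=orientation,
        roi_side_px=n,
        interpolated=interpolated,
    )
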