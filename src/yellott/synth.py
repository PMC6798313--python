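"""Synthetic cone mosaics with known geometry, and coordinate-based metrics.

The generators emulate confocal AOSLO imagery of the photoreceptor mosaic:
cones appear as bright, roughly Gaussian spots arranged on a jittered
triangular (hexagonal-packing) lattice, over a dim background with additive
sensor noise, optionally with an unresolved (blurred) foveal center.  The
coordinate-based metrics (mean Delaunay-neighbor distance, bounded-area
count density) serve as the direct oracle against which the Fourier-domain
estimates are validated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial import ConvexHull, Delaunay, QhullError

from .spacing import SQRT3
from .spectral import RoiImage

__all__ = [
    "MosaicTruth",
    "SynthConfig",
    "generate_hex_mosaic",
    "render_mosaic_image",
    "render_field",
    "direct_icd",
    "direct_density",
    "generate_gradient_montage",
]


@dataclass(frozen=True)
class MosaicTruth:
    """Ground-truth cone coordinates for a synthetic mosaic.

    Coordinates are (x_um, y_um) cone centers inside the half-open square
    ``[0, field_um)``; ``icd_true_um`` is the lattice nearest-neighbor
    distance before jitter.
    """

    coords: np.ndarray
    icd_true_um: float
    jitter_frac: float
    field_um: float
    seed: int

    def __post_init__(self) -> None:
        c = np.asarray(self.coords, dtype=float)
        if c.ndim != 2 or c.shape[1] != 2:
            raise ValueError("coords must be an (n, 2) array")
        if not (self.icd_true_um > 0):
            raise ValueError("icd_true_um must be positive")
        if not (0.0 <= self.jitter_frac < 0.5):
            raise ValueError("jitter_frac must lie in [0, 0.5)")
        if c.size and (c.min() < 0 or c.max() >= self.field_um):
            raise ValueError("coordinates must lie inside [0, field_um)")
        object.__setattr__(self, "coords", c)

    @property
    def n_cells(self) -> int:
        return self.coords.shape[0]


@dataclass(frozen=True)
class SynthConfig:
    """Rendering parameters for synthetic mosaic images.

    ``spot_sigma_frac`` is the Gaussian spot sigma as a fraction of the true
    ICD; ``noise_sd`` is the additive Gaussian noise SD in intensity units.
    ``amplitude`` scales the unit spots (use ~150 with ``background`` ~20 to
    mimic 8-bit AOSLO exports on the 0-255 scale).  ``foveal_blur_um`` > 0
    blurs a central disk of that radius, emulating unresolved foveal cones.
    """

    scale_um_per_px: float = 1.0
    spot_sigma_frac: float = 0.2
    noise_sd: float = 0.0
    background: float = 0.0
    amplitude: float = 1.0
    foveal_blur_um: float = 0.0

    def __post_init__(self) -> None:
        if self.scale_um_per_px <= 0:
            raise ValueError("scale_um_per_px must be positive")
        if self.spot_sigma_frac <= 0:
            raise ValueError("spot_sigma_frac must be positive")
        if self.noise_sd < 0 or self.background < 0 or self.foveal_blur_um < 0:
            raise ValueError("noise_sd, background and foveal_blur_um must be >= 0")


#: Default lattice orientation relative to the image raster, degrees.
#: Real mosaics are never aligned with the scanner axes; a raster-aligned
#: synthetic lattice is a degenerate case whose row-truncation leakage
#: produces coherent spectral stripes that no real image exhibits.
DEFAULT_ROTATION_DEG = 18.0


def _hex_lattice(icd: float, half_extent: float) -> np.ndarray:
    """Centered triangular lattice covering [-half_extent, half_extent]^2."""
    dy = SQRT3 / 2.0 * icd
    n_rows = int(math.ceil(half_extent / dy))
    rows = []
    for i in range(-n_rows, n_rows + 1):
        offset = (i % 2) * icd / 2.0
        n_cols = int(math.ceil((half_extent + abs(offset)) / icd))
        x = np.arange(-n_cols, n_cols + 1) * icd + offset
        rows.append(np.column_stack([x, np.full(x.size, i * dy)]))
    return np.concatenate(rows, axis=0)


def generate_hex_mosaic(
    icd_true_um: float,
    jitter_frac: float,
    field_um: float,
    seed: int,
    rotation_deg: float = DEFAULT_ROTATION_DEG,
) -> MosaicTruth:
    """Jittered triangular lattice inside the half-open square [0, field_um).

    The lattice has row spacing ``(sqrt(3)/2) * icd_true_um`` with alternate
    rows offset by half the ICD, and is oriented ``rotation_deg`` away from
    the image axes (default 18 degrees; mosaics are never raster-aligned).
    Each site is displaced by isotropic Gaussian jitter with sigma
    ``jitter_frac * icd_true_um`` and clipped back into the field.
    Deterministic for a fixed seed.
    """
    if field_um < 5 * icd_true_um:
        raise ValueError("field_um must be at least 5 * icd_true_um")
    if not (0.0 <= jitter_frac < 0.5):
        raise ValueError("jitter_frac must lie in [0, 0.5)")
    half = field_um / 2.0 * math.sqrt(2.0) + 2.0 * icd_true_um
    lattice = _hex_lattice(icd_true_um, half)
    th = math.radians(rotation_deg)
    rot = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
    coords = lattice @ rot.T + field_um / 2.0
    inside = np.all((coords >= 0.0) & (coords < field_um), axis=1)
    coords = coords[inside]
    rng = np.random.default_rng(seed)
    if jitter_frac > 0:
        coords = coords + rng.normal(0.0, jitter_frac * icd_true_um, coords.shape)
        upper = np.nextafter(field_um, 0.0)
        coords = np.clip(coords, 0.0, upper)
    return MosaicTruth(
        coords=coords,
        icd_true_um=icd_true_um,
        jitter_frac=jitter_frac,
        field_um=field_um,
        seed=seed,
    )


def render_field(
    coords: np.ndarray,
    field_um: float,
    cfg: SynthConfig,
    spot_sigma_um: float,
    noise_seed: int,
) -> np.ndarray:
    """Render Gaussian spots at ``coords`` into a square intensity image."""
    n_px = int(round(field_um / cfg.scale_um_per_px))
    img = np.zeros((n_px, n_px), dtype=float)
    sigma_px = spot_sigma_um / cfg.scale_um_per_px
    half = max(1, int(math.ceil(4.0 * sigma_px)))
    for x_um, y_um in np.asarray(coords, dtype=float):
        cx = x_um / cfg.scale_um_per_px
        cy = y_um / cfg.scale_um_per_px
        r0 = max(0, int(math.floor(cy)) - half)
        r1 = min(n_px, int(math.ceil(cy)) + half + 1)
        c0 = max(0, int(math.floor(cx)) - half)
        c1 = min(n_px, int(math.ceil(cx)) + half + 1)
        if r0 >= r1 or c0 >= c1:
            continue
        yy = np.arange(r0, r1)[:, None] - cy
        xx = np.arange(c0, c1)[None, :] - cx
        img[r0:r1, c0:c1] += np.exp(-(xx**2 + yy**2) / (2.0 * sigma_px**2))
    img = cfg.background + cfg.amplitude * img
    if cfg.foveal_blur_um > 0:
        center = n_px / 2.0
        yy, xx = np.mgrid[0:n_px, 0:n_px]
        mask = np.hypot(yy - center, xx - center) <= cfg.foveal_blur_um / cfg.scale_um_per_px
        blurred = gaussian_filter(img, sigma=2.0 * sigma_px)
        img = np.where(mask, blurred, img)
    if cfg.noise_sd > 0:
        rng = np.random.default_rng(noise_seed)
        img = img + rng.normal(0.0, cfg.noise_sd, img.shape)
    return np.clip(img, 0.0, None)


def render_mosaic_image(
    truth: MosaicTruth,
    cfg: SynthConfig,
    noise_seed: int | None = None,
) -> RoiImage:
    """Render a mosaic as a square ROI image.

    Intensity = background + amplitude * sum of Gaussian spots (sigma =
    ``spot_sigma_frac * icd_true``) + additive Gaussian noise, clipped at
    zero.  ``noise_seed`` defaults to a value derived from the truth seed;
    pass distinct seeds to obtain paired noise realizations of the same
    mosaic (a synthetic test-retest pair).
    """
    if noise_seed is None:
        noise_seed = (truth.seed + 101) % 2**31
    img = render_field(
        truth.coords,
        truth.field_um,
        cfg,
        spot_sigma_um=cfg.spot_sigma_frac * truth.icd_true_um,
        noise_seed=noise_seed,
    )
    return RoiImage(img, cfg.scale_um_per_px)


def direct_icd(coords: np.ndarray) -> float:
    """Direct intercell distance from coordinates (micrometers).

    Mean, over every cell with a complete neighborhood, of the mean distance
    to its Delaunay-adjacent neighbors.  Boundary cells are excluded: cells
    on the convex hull, cells adjacent to one, and cells within two median
    nearest-neighbor distances of the point-set bounding box, whose
    truncated or notched neighborhoods pick up sliver-triangle edges that
    bias the spacing upward.
    """
    pts = np.asarray(coords, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 7:
        raise ValueError("need at least 7 non-collinear (x, y) points")
    try:
        tri = Delaunay(pts)
        hull = ConvexHull(pts)
    except QhullError as exc:
        raise ValueError("degenerate point geometry") from exc
    neighbors: list[set[int]] = [set() for _ in range(pts.shape[0])]
    for simplex in tri.simplices:
        for a in simplex:
            for b in simplex:
                if a != b:
                    neighbors[a].add(b)
    on_hull = np.zeros(pts.shape[0], dtype=bool)
    on_hull[hull.vertices] = True
    nn = np.array(
        [min(np.hypot(*(pts[list(neighbors[i])] - pts[i]).T)) for i in range(pts.shape[0])]
    )
    margin = 2.0 * float(np.median(nn))
    lo = pts.min(axis=0) + margin
    hi = pts.max(axis=0) - margin
    complete = [
        i
        for i in range(pts.shape[0])
        if not on_hull[i]
        and not any(on_hull[j] for j in neighbors[i])
        and np.all(pts[i] >= lo)
        and np.all(pts[i] <= hi)
    ]
    interior = np.asarray(complete, dtype=int)
    if interior.size == 0:
        raise ValueError("no interior cells with complete neighborhoods")
    per_cell = [
        np.mean(np.hypot(*(pts[list(neighbors[i])] - pts[i]).T))
        for i in interior
    ]
    return float(np.mean(per_cell))


def direct_density(coords: np.ndarray, area_um2: float) -> float:
    """Bounded-area count density in cells/mm^2."""
    if not area_um2 > 0:
        raise ValueError("area must be positive")
    n = np.asarray(coords).shape[0] if np.asarray(coords).size else 0
    return 1e6 * n / area_um2


@dataclass(frozen=True)
class GradientMontage:
    """A rendered montage with an eccentricity gradient and its truth maps."""

    image: np.ndarray
    icd_truth_map_um: np.ndarray
    coords: np.ndarray
    scale_um_per_px: float
    field_um: float
    profile: tuple  # (a, b, c) of icd(x_dist) = a * (x_dist - b)**c
    center_um: float = field(default=0.0)


def generate_gradient_montage(
    a: float,
    b: float,
    c: float,
    field_um: float,
    seed: int,
    cfg: SynthConfig | None = None,
    jitter_frac: float = 0.0,
    rotation_deg: float = DEFAULT_ROTATION_DEG,
) -> GradientMontage:
    """Locally hexagonal montage whose ICD follows a power law of eccentricity.

    The local intercell distance is ``icd(x_dist) = a * (x_dist - b)**c``
    with eccentricity ``x_dist`` measured along a single axis through the
    montage center (emulating a strip along a retinal meridian), oriented
    ``rotation_deg`` from the image vertical.  Lattice rows run
    perpendicular to that axis; consecutive row positions integrate
    ``(sqrt(3)/2) * icd``, so the local row spacing -- the quantity the
    spectral estimator measures -- tracks the profile exactly, and the
    within-row spacing equals the local ICD.  A per-pixel true ICD map is
    returned for map-accuracy tests.

    With ``c == 0`` the profile is constant and the generator reduces to
    :func:`generate_hex_mosaic`.
    """
    cfg = cfg or SynthConfig()
    center = field_um / 2.0

    def icd_of_dist(x_dist: np.ndarray) -> np.ndarray:
        val = a * np.power(np.abs(np.asarray(x_dist, dtype=float)) - b, c)
        if np.any(~np.isfinite(val)) or np.any(val <= 0):
            raise ValueError("ICD profile must be positive and finite over the field")
        return val

    th = math.radians(rotation_deg)
    e_u = np.array([math.sin(th), math.cos(th)])  # eccentricity axis
    e_v = np.array([math.cos(th), -math.sin(th)])  # row direction
    half = field_um / 2.0 * math.sqrt(2.0) + 2.0 * float(icd_of_dist(0.0))

    if c == 0:
        truth = generate_hex_mosaic(float(a), jitter_frac, field_um, seed,
                                    rotation_deg=rotation_deg)
        coords = truth.coords
    else:
        # March row positions outward from the center along the axis.
        us = [0.0]
        u = 0.0
        while u < half:
            u = u + SQRT3 / 2.0 * float(icd_of_dist(u))
            us.append(u)
        u = 0.0
        neg = []
        while u > -half:
            u = u - SQRT3 / 2.0 * float(icd_of_dist(u))
            neg.append(u)
        rows = []
        for i, ru in enumerate(sorted(neg) + us):
            spacing = float(icd_of_dist(ru))
            offset = (i % 2) * spacing / 2.0
            n_cols = int(math.ceil((half + abs(offset)) / spacing))
            v = np.arange(-n_cols, n_cols + 1) * spacing + offset
            rows.append(
                np.column_stack([np.full(v.size, ru), v])  # (u, v) pairs
            )
        uv = np.concatenate(rows, axis=0)
        coords = center + uv[:, :1] * e_u + uv[:, 1:] * e_v
        inside = np.all((coords >= 0.0) & (coords < field_um), axis=1)
        coords = coords[inside]
        if jitter_frac > 0:
            rng = np.random.default_rng(seed)
            u_dist = (coords - center) @ e_u
            sigma = jitter_frac * icd_of_dist(u_dist)
            coords = coords + rng.normal(size=coords.shape) * sigma[:, None]
            coords = np.clip(coords, 0.0, np.nextafter(field_um, 0.0))

    u_all = (coords - center) @ e_u
    median_icd = float(np.median(icd_of_dist(u_all))) if c != 0 else float(a)
    image = render_field(
        coords,
        field_um,
        cfg,
        spot_sigma_um=cfg.spot_sigma_frac * median_icd,
        noise_seed=(seed + 7) % 2**31,
    )
    n_px = image.shape[0]
    px_um = (np.arange(n_px) + 0.5) * cfg.scale_um_per_px
    xx, yy = np.meshgrid(px_um, px_um)  # xx: column coord, yy: row coord
    u_map = (xx - center) * e_u[0] + (yy - center) * e_u[1]
    if c == 0:
        icd_map = np.full((n_px, n_px), float(a))
    else:
        icd_map = icd_of_dist(u_map)
    return GradientMontage(
        image=image,
        icd_truth_map_um=icd_map,
        coords=coords,
        scale_um_per_px=cfg.scale_um_per_px,
        field_um=field_um,
        profile=(float(a), float(b), float(c)),
        center_um=center,
    )
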