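# Methods

## Model and assumptions

The estimator treats a photoreceptor mosaic as a quasi-regular planar
point process close to hexagonal packing. Under that model the dominant
spatial frequency of the image — the radius of the spectral ring — equals
the reciprocal of the lattice *row* spacing `s_r`, and the intercell
distance and areal density follow from the packing geometry alone:
`ICD = (2/√3)·s_r` and `D = 10⁶·√3/(2·s_r²)` (s_r in µm, D in
cells/mm²). Two identities worth keeping in mind: `D·ICD² = 2×10⁶/√3`
for every spacing, so density and ICD are a single degree of freedom; and
the conversion is exact only for a perfect hexagonal packing — real
mosaics are locally hexagonal at best, which is why the method reports a
*modal* (dominant-periodicity) estimate rather than a per-cell one.

The orientation-selective radial average uses the two 90° sectors within
±45° of the vertical frequency axis. This measures row spacing while
suppressing the slight row/column asymmetry of cone packing. For
split-detection imagery, whose contrast is horizontally dominant, the
horizontal double wedge is used instead and the modal spacing is taken as
the ICD directly (no 2/√3 factor); density still follows from the same
hexagonal identity, so both orientations satisfy `D·ICD² = 2×10⁶/√3`.

The average is taken of the *log* power (log first, then average,
following the processing order of the pipeline). A fixed floor of
10⁻¹² × max power keeps the log defined on empty bins. The ROI mean is
subtracted before the DFT to stop DC leakage from contaminating the
lowest radii; no apodization window is applied.

## The multiscale fit and peak crawl

A single-term exponential `A·exp(B·f)` models the gross decay of the
radially averaged log power. It is deliberately too stiff to follow a
localized spectral ring, so the ring survives in the residuals. The
residuals are smoothed with a cubic smoothing spline and their maximum
(over radii ≥ r_min = 3, a guard against residual DC energy) seeds a
second, piecewise single-term exponential whose two halves join
continuously at that seed — this absorbs the change of decay rate near
the ring without a constant offset term. The final peak is found by
crawling from the seed toward lower frequency across the re-smoothed
residuals, stopping at the first local maximum (plateaus resolve to their
lowest-radius bin; a crawl that reaches r_min without a maximum returns
flagged with confidence 0). Sub-bin position comes from a 3-point
quadratic interpolation, so the spacing estimate is continuous rather
than quantized to `N/f` at integer f.

Numerical choices:

- **Spline stiffness.** The smoothing penalty is set so the effective
  degrees of freedom of the smoother equal one third of the bin count
  (floored at 3). A stiffer rule (a quarter of the bin count) measurably
  flattened and displaced modal peaks only a few bins wide on
  low-disorder mosaics, producing >1-bin localization errors; one third
  preserves such peaks while still suppressing bin-to-bin noise. The
  penalty is found by bisection on the trace of the smoother matrix and
  cached per radius grid, so behavior is deterministic.
- **Fit domains.** Both exponentials are fit over the full profile
  support; r_min guards only the search and crawl.
- **Piecewise initialization.** The piecewise fit starts from per-segment
  log-linear seeds *and* from the nested single-exponential solution,
  keeping the best; its SSE therefore never exceeds the single fit's.
- **Confidence.** Peak prominence is the larger of the two one-sided
  drops from the peak to its flanking bases (the minimum on each side
  before the curve re-exceeds the peak, or the boundary), normalized by
  the maximum absolute smoothed residual and clamped to [0, 1].
- **Scaling behavior.** Multiplying the ROI by k > 0 shifts the log-power
  profile by the constant 2·ln k. Because `A·exp(B·f)` has no offset
  term, the fitted baseline is not exactly shift-equivariant and the
  sub-bin peak can drift by ~0.1%; the integer peak bin and the
  confidence are invariant. Adding an offset term would restore exact
  invariance but changes the model family; the offset-free form is kept.

## Montage maps

Defaults n = 128 px and p = 32 px balance spectral resolution (the ROI
must span ≥ 8–10 lattice rows for a usable ring) against map smoothness;
at a typical confocal AOSLO scale of ~0.46 µm/px they correspond to
58.8 µm and 14.7 µm. Every ROI spreads its ICD/density over its whole
footprint weighted by its confidence, so overlapping footprints blend
smoothly. Exclusions: mean ROI intensity < 10 on the 0–255 scale
(unimaged canvas, vessels) is applied first; the confidence cutoff is the
5th percentile of the remaining ROIs' confidences, removing those
*strictly below* it — K distinct confidences lose exactly ⌈0.05·K⌉ ROIs,
and ties at the cutoff (e.g. all confidences equal) are kept. Because the
percentile is recomputed over the same base set each time, re-applying
the exclusions is idempotent. Pixels covered only by excluded ROIs carry
a reason code (low-intensity | low-confidence | foveal | uncovered).

The foveal-artifact mask handles the physiologically impossible signature
of unresolved foveal cones: density *increasing* with eccentricity near
the center. A candidate dip is a local minimum of the smoothed density
map inside the central half of the montage (a well-resolved fovea has its
density maximum there and no interior minimum, yielding an empty mask).
From the dip, ring-averaged density is scanned outward and the mask grows
until the radial gradient changes sign — the onset of the normal decrease
of density with eccentricity. This is an iterative region-growth
surrogate for an active contour, with the same stopping rule.

Note that averaging ICD and density as separate weighted maps preserves
the hexagonal identity only up to the spread of the contributing ROIs
(exactly per ROI, to ~1% per pixel in practice).

## Synthetic mosaics: what they emulate and what they do not

The generator produces a triangular lattice with row spacing (√3/2)·ICD,
alternate rows offset by half the ICD, oriented 18° away from the image
raster, with isotropic Gaussian positional jitter (σ = jitter_frac·ICD)
and rendered as Gaussian spots (σ = 0.2·ICD, about the width of a cone
inner segment) over a uniform background with additive Gaussian noise,
clipped at zero. The non-zero default orientation matters: a lattice
exactly aligned with the raster axes is a degenerate configuration whose
row-truncation leakage forms coherent horizontal stripes in the spectrum
— including a strong half-frequency stripe — that real retinal images
never exhibit and that specifically sabotage log-domain radial averaging.
Rotation leaves jitter-free hexagonality, the ring radius, and the
direct ICD untouched.

The gradient-montage generator marches lattice rows along a single
eccentricity axis (also 18° from vertical), integrating (√3/2)·icd(x)
between rows so the local row spacing — the quantity the spectral
estimator measures — follows the prescribed power law exactly, with the
within-row spacing equal to the local ICD. It emulates a strip along a
retinal meridian; it is locally hexagonal but *not* isotropic at strong
gradients, and a constant profile reduces it to the uniform generator.

Not emulated: optical point-spread functions and speckle, rod intrusion,
vessel shadows, per-cone reflectance variability, and montage seams.
Passing tests therefore demonstrate correctness of the spectral analysis
and its bookkeeping under controlled geometry and noise — not robustness
to every AOSLO artifact. The paper-scale human results (multi-eye
test–retest and inter-method statistics) are not reproducible without the
original images; the tests use desk-scale synthetic analogues (20 mosaics
per comparison, 128-px ROIs, a 1024-px gradient montage).

## Direct (coordinate-based) metrics

ICD_D is the mean, over cells with complete neighborhoods, of the mean
distance to Delaunay-adjacent neighbors. Cells on the convex hull, cells
adjacent to one, and cells within two median nearest-neighbor distances
of the point-set bounding box are excluded: truncated or notched boundary
neighborhoods acquire sliver-triangle edges that bias spacing upward.
On a perfect lattice ICD_D equals the lattice constant to 1e-9. Direct
density is the bounded-area count 10⁶·count/area.

## Agreement statistics

Percent differences use the symmetric convention 100·|x−y|/mean(x,y).
Bland–Altman limits are `D̄ ± 1.96·S` with the sample SD (n−1); when
differences violate normality the analysis is run on log₁₀ values and the
linear-scale ratio interpretation (10^D̄ and its limits) is reported
alongside. Shapiro–Wilk normality of the differences is reported, not
enforced. The eccentricity fit `ICD = a·(x−b)^c` is plain nonlinear least
squares with b bounded below min(x) to keep the power real, initialized
at (first ICD, 0, 0.3); CIs are asymptotic with a Student-t critical
value.

## Problem sizes and determinism

All generators and analyses are deterministic given a seed. The test
suite and the acceptance script use: 128-px ROIs for recovery and
agreement runs (5 lattice spacings; 20 mosaics per statistical
comparison), a 1024-px gradient montage (841 overlapping ROIs) for the
map-accuracy check, and ≤16-px / ≤50-point instances for the brute-force
oracle comparisons. A full acceptance run completes in well under a
minute on one CPU.

## Known limitations

- A Fourier-domain estimate carries no local regularity or tessellation
  information; highly localized loss (smaller than the ROI) is invisible
  unless it perturbs the dominant periodicity.
- Additional periodic structure (rods, reflectance banding) adds spectral
  peaks that can capture the crawl or inflate confidence.
- The hexagonal conversion biases ICD/density wherever the mosaic departs
  from hexagonal packing (pathology, fovea under-sampling).
- The confidence percentile is montage-wide; a montage that is uniformly
  poor still keeps 95% of its ROIs.
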