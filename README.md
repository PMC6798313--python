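# yellott

Fully automated, Fourier-domain estimation of photoreceptor intercell
distance (ICD) and cone density for adaptive-optics retinal images —
single regions of interest or whole montages — with no cell marking and no
grader in the loop.

## The method

A healthy cone mosaic is locally close to a hexagonal packing. Its power
spectrum therefore concentrates energy in an annulus ("Yellott's ring")
whose radius equals the modal spatial frequency of the packing. For an
N×N region of interest (ROI) the pipeline is:

1. log power spectrum of the DFT (mean-subtracted, no window);
2. radial average of the upper/lower 90° double wedge — the two sectors
   within ±45° of the vertical frequency axis — giving one mean log-power
   value per integer radius `f = 1 .. N/2` (cycles per ROI side);
3. a single-term exponential `A·exp(B·f)` is fit and subtracted; the
   residuals are smoothed with a cubic smoothing spline and their maximum
   gives a rough estimate of the modal frequency;
4. a continuous piecewise single-term exponential, linked at the rough
   estimate, is refit to the profile and subtracted; from the rough
   estimate, a peak crawl toward lower frequency finds the first peak of
   the re-smoothed residuals — the modal frequency `f*` (sub-bin, via
   3-point quadratic interpolation);
5. the modal row spacing is `s_r = N / f*` pixels. For a hexagonal mosaic

       ICD_M = (2/√3) · s_r            [µm, using the image scale]
       D_M   = 10⁶·√3 / (2·s_r²)       [cells/mm², s_r in µm]

6. confidence = prominence of the modal peak (the larger one-sided drop
   to a flanking base) normalized by the maximum residual amplitude,
   clamped to [0, 1].

For montages, the image is covered by an overlapping grid of n×n ROIs
stepped by p pixels (defaults n=128, p=32). Each ROI spreads its ICD and
density over its footprint weighted by its confidence; per-pixel values
are the weighted averages. ROIs with mean intensity < 10 (0–255 scale) or
confidence below the montage-wide 5th percentile are excluded, and an
optional mask removes the spurious central density dip that unresolved
foveal cones produce.

The package also ships a synthetic-mosaic generator (jittered hexagonal
lattices of Gaussian spots with optional eccentricity-dependent spacing),
a coordinate-based direct-ICD oracle (mean Delaunay-neighbor distance),
and the validation statistics used to compare the two routes: symmetric
percent differences, log₁₀ Bland–Altman limits of agreement
`LOA = D̄ ± 1.96·S`, and the eccentricity power law
`ICD_fit = a·(x_dist − b)^c`.

## Worked example

```python
import yellott as y

truth = y.generate_hex_mosaic(icd_true_um=8.0, jitter_frac=0.05,
                              field_um=128.0, seed=1)
cfg = y.SynthConfig(scale_um_per_px=1.0, noise_sd=2.0,
                    background=20.0, amplitude=150.0)
roi = y.render_mosaic_image(truth, cfg)
est = y.estimate_modal_spacing(roi)
print(est.icd_m_um, y.direct_icd(truth.coords), est.confidence)
```

prints (see `examples/01_single_roi_spacing.py`):

```
true ICD              : 8.000 um (295 cones)
modal row spacing s_r : 7.10 px = 7.10 um
modal ICD_M           : 8.203 um
direct ICD_D          : 8.020 um
density D_M           : 17,161 cells/mm^2
confidence            : 1.00
```

The spectral estimate (8.20 µm) agrees with the coordinate-based one
(8.02 µm) to ~2%, and the confidence of 1.0 reflects a clean modal peak.
The other scripts in `examples/` map a gradient montage against its truth
map, run the log₁₀ Bland–Altman comparison over 20 mosaics, and invert
the eccentricity power law.

A thin CLI wraps the same functions:

```sh
yellott roi mosaic.tif --scale 0.46
yellott map montage.tif --scale 0.46 --n 128 --p 32 --out maps/
yellott simulate --icd 8 --jitter 0.05 --out fixtures/run1
yellott validate fixtures/ --scale 1.0
```

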