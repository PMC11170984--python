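# Methods

This note documents the models, conventions and numerical choices behind
`memloc`, and what its validation does and does not demonstrate.

## Coordinate and sampling conventions

Pixel coordinates are 0-based, x rightward (column), y downward (row); a
coordinate denotes a pixel *center*, and polygons live in the same
continuous frame. Intensity lookup is bilinear by default
(`scipy.ndimage.map_coordinates`, order 1); nearest-neighbor lookup is
available and used by some oracle tests. ImageJ's line-profile sampling
differs in sub-pixel details; exact ImageJ emulation is a non-goal.

## Radial profiling

Each cell's ROI must be a simple polygon that is star-shaped about its
area centroid: every ray from the centroid crosses the boundary exactly
once, which is what makes a radial coordinate well-defined. Violations
are rejected at construction (vertex-visibility check) and again at ray
time (multiple-crossing detection) rather than silently mis-sampled.

The fan consists of `n_lines` diameters at angles kπ/n_lines. Lines of
different physical length are reconciled on a shared normalized diameter
grid: `n_samples` (odd, so r = 0 is a grid point) positions equally
spaced in r ∈ [−1, 1], where the physical position along a ray is
r · R(θ) with R(θ) the centroid-to-boundary distance of that half-ray.
For cells symmetric about their centroid this coincides with equal
spacing along the physical segment; for asymmetric cells it keeps the
centroid pinned at r = 0, which pointwise averaging across lines and
cells requires. Averaging weights every grid point equally (not by
physical arc length), matching the convention of averaging "measured
points" rather than integrating intensity over area.

Per-cell profiles are *not* intensity-normalized before population
averaging (raw means are averaged); a `profile.normalize` switch exists
and defaults off. Cells whose polygon touches the image border are
excluded with a logged count.

Defaults: `n_lines = 180` (1° spacing), `n_samples = 101`. Fan
convergence is monotone on phantoms (45→180 lines changes a profile less
than 12→45), so 180 lines is comfortably converged for cells of radius
20–30 px.

## Band scoring and background

The membrane score is the mean of the profile over |r| ≥ 1 − f_mem
(both tails), the cytoplasm score over |r| ≤ r_cyto; defaults
f_mem = 0.15, r_cyto = 0.6. The band definition is the single most
consequential free parameter of the pipeline and is deliberately
prominent in the configuration: the outer-15% band tolerates ~1 px of
PSF blur at cell radius ~25 px, while r_cyto = 0.6 keeps the cytoplasm
band clear of both the membrane and any central (nuclear) region.

Background is estimated per channel by policy: `none` (0), a configured
`global_offset`, or `image_median_outside_cells` — the median over
pixels outside every ROI's padded bounding box, which is robust to the
cells and their blur halos and recovers a constant background exactly on
clean scenes. Scores are background-subtracted and floored at 0; a cell
whose cytoplasm mean floors to 0 yields a flagged record with undefined
ratio, not an exception.

The group contrast reports fold change as the ratio of group means of
the chosen field (selecting the per-cell `ratio` field gives the
mean-of-ratios variant), dispersion as the sample sd of group-b values
relative to the group-a mean, and significance from a one-way ANOVA
treating cells as independent observations. No multiple-testing
correction is applied (single planned contrast); replicate-aware nesting
is out of scope.

## Binned correlation

Cells are merged k at a time (default 10) into scatter points of
within-bin means before the Pearson correlation. Bin membership is
`consecutive` in input order by default (reproducible without a seed) or
`random` with a stated seed; the trailing remainder of fewer than k
cells is dropped and logged. Under a linear latent model, random
k-binning shrinks signal and noise by the same factor, so the expected
binned r equals the unbinned population R (verified by Monte Carlo);
binning does reduce the *effective* number of points, which dominates
the estimator's variance (see Validation).

## Synthetic scenes

Cells are ellipses with semi-major axis `radius` ~ U(20, 30) px,
eccentricity ~ U(0, 0.6), free orientation; the membrane is the shell
between the outer ellipse and an inner ellipse with both semi-axes
reduced by `shell_thickness` (default 3 px) — exactly a constant-
thickness shell for circles and uniformly close to one at these bounded
eccentricities, while keeping band membership analytic for oracles. The
nucleus is a concentric disk rendered only in the nuclear channel; the
FR1 channel is cytoplasm amplitude inside, membrane amplitude in the
shell; GPI-T is uniform over the footprint.

Imaging model: constant background (default 100 a.u.), isotropic
Gaussian PSF (default σ = 1 px), Poisson shot noise on the blurred
signal, additive Gaussian read noise (default sd 5 a.u.), then clipping
and quantization to 16 bits. Defaults are strong enough to defeat naive
scorers while leaving planted parameters recoverable. Pixel size and
camera settings are metadata only.

Placement is rejection sampling of strictly disjoint bounding circles;
large populations are split across as many 1024² fields of view as
needed (default ≤ 60 cells per tile, like separate micrographs), with
globally unique cell ids. Real tissue has touching cells; disjoint
synthesis mirrors an analysis restricted to manually selected single
cells. A single master seed drives deterministically spawned per-tile
streams, so identical spec + seed reproduces bit-identical images.

Per-group amplitudes are Normal(mean, sd) floored at 0 (default spread
cv = 0.2). When the latent correlation model is enabled
(mem = a + b(z + ε), gpit = c + d·z, z ~ N(0,1), ε ~ N(0, σ²)), it
overrides the per-group membrane/GPI-T draws and plants a population
Pearson correlation of exactly 1/√(1 + σ²); σ = 0.747 gives R = 0.801.

What the generator does **not** emulate: touching/overlapping cells,
irregular (non-elliptical) cell shapes, uneven illumination,
autofluorescence, multiple focal planes, or texture inside compartments.
Passing validation therefore shows the measurement chain is correct and
well-calibrated under these idealized conditions; it does not certify
performance on crowded or poorly illuminated real tissue, where ROI
quality and background structure will dominate.

## Known biases and edge effects

Two systematic effects are characterized by the validation suite rather
than hidden:

* **Boundary bleed.** Profile samples within ~1.4 px of the ROI
  boundary mix, via bilinear interpolation, with pixels outside the
  cell. A membrane band that touches r = ±1 therefore loses roughly half
  an edge-pixel of membrane signal to background. Because background
  contributes zero after correction to *both* groups, this cancels in
  fold changes only partially (see next point), and not at all in
  absolute per-cell amplitudes.
* **Band–shell mismatch under blur.** With a 3 px shell at radius
  ~25 px, the outer-15% band (~3.75 px) necessarily admits some
  cytoplasm, and 1 px PSF blur mixes the compartments further. For the
  study-scale contrast (planted fold 1.31, cytoplasm 80 a.u.) a 1-D
  convolution model predicts a recovered fold of ≈ 1.24–1.27; the
  pipeline measures ≈ 1.245, stable across seeds. The attenuation is a
  property of band scoring under blur, not an estimator bug; narrowing
  the band or deconvolving would trade it against noise.

Unit tests that check *unbiased* per-cell recovery use phantoms whose
ROI is drawn on the membrane ridge (inside a thick shell), so the band
is interior to a uniform region — a realistic way to outline a cell and
the regime where band means are exact.

## Validation figures of merit

`scripts/acceptance.py` recomputes two study-scale quantities from
scratch (sizes chosen to mirror the study: 300 + 600 cells for the
fold change, 500 cells / 50 scatter points for the correlation; both
run in well under a minute on one CPU):

* Recovered membrane fold change ≈ 1.245 for a planted 1.31 (the
  characterized attenuation above), with per-seed variation < 0.3%.
* Recovered 10-cell-binned Pearson r for planted R = 0.801: unbiased in
  expectation, but with only 50 binned points its sampling sd is
  ≈ (1 − R²)/√50 ≈ 0.05, so individual seeds scatter accordingly. This
  is the intrinsic precision of a 50-point correlation estimate, not a
  pipeline defect.

## Numerical details

* Ray casting solves ray–edge intersections in closed form, vectorized
  over angles and edges, with a half-open edge rule plus tolerance
  dedup so rays through vertices count once; zero or multiple crossings
  raise a geometry error naming the angle.
* ANOVA delegates to `scipy.stats.f_oneway`; zero within-group variance
  with unequal means reports p = 0 (logged), with equal means p = 1.
  Pearson r delegates to `scipy.stats.pearsonr` after explicit
  zero-variance checks.
* Measurement CSVs are written with 6 significant digits and a stable
  column order, making fixed-seed reruns byte-identical; report plots
  and the markdown summary contain no timestamps for the same reason.
* Degenerate inputs (polygons with < 3 distinct vertices, self-
  intersections, centroid outside, bands covering < 2 grid points,
  empty groups, reference mean 0) fail fast with named errors; the CLI
  maps configuration errors to exit code 2 and data/geometry errors
  to 3.
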