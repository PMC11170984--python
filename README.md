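# memloc

Single-cell radial fluorescence profiling and membrane-localization
scoring for two-channel immunofluorescence microscopy, with a synthetic
scene generator for end-to-end validation.

## The problem

Folate receptor 1 (FR1, *FOLR1*) is a GPI-anchored surface protein whose
*localization* — membrane versus cytoplasm — changes in prostate cancer
cells, driven by the GPI transamidase (GPI-T) that attaches the GPI
anchor. Total FR1 intensity per cell often fails to separate tumor from
healthy tissue; the diagnostic signal is the *shift* of FR1 fluorescence
toward the plasma membrane, and its coupling to GPI-T expression.
`memloc` is for microscopists and image analysts who want that readout
as a reproducible, scriptable pipeline instead of a manual ImageJ
workflow.

## The method

For each cell, outlined by a polygon ROI:

1. **Radial line fan.** A fan of `n_lines` (default 180) equally angled
   diameters is cast through the polygon's area centroid; each line ends
   on the polygon boundary in both directions.
2. **Normalized profile.** Intensities are sampled (bilinear) at
   `n_samples` (default 101, odd) points per line on the normalized
   diameter coordinate r ∈ [−1, 1] (0 = centroid, ±1 = boundary) and
   averaged pointwise over lines, giving the cell profile I(r).
   Population profiles are the pointwise mean ± sd over cells.
3. **Band scores.** The membrane score is the background-corrected mean
   of I(r) over the outer band |r| ≥ 1 − f_mem (default f_mem = 0.15),
   the cytoplasm score over |r| ≤ 0.6; GPI-T intensity is the
   background-corrected mean over the whole polygon.
4. **Group statistics.** The tumor/healthy contrast is the fold change
   of group means with a one-way ANOVA p-value starred as
   `***` (p ≤ 0.001), `**` (≤ 0.01), `*` (≤ 0.05), `n.s.` otherwise.
5. **Binned correlation.** Cells are merged k at a time (default k = 10,
   seeded random assignment) into scatter points
   (mean GPI-T, mean FR1-membrane) and summarized by Pearson r.

The synthetic generator renders elliptical cells (bright membrane shell,
dimmer cytoplasm, uniform GPI-T, nuclear disk) on a constant background,
degraded by Gaussian PSF blur, Poisson shot noise and Gaussian read
noise, and emits ground-truth tables and ROI CSVs — so every stage can
be validated against planted parameters. Membrane and GPI-T amplitudes
can share a latent Gaussian z (mem = a + b(z + ε), gpit = c + dz,
ε ~ N(0, σ²)), which plants a population correlation of exactly
1/√(1 + σ²).

## Worked example

```python
import memloc

cfg = {
    "seed": 1,
    "simulate": {"n_per_group": {"healthy": 40, "tumor": 40},
                 "cells_per_tile": 40},
    "stats": {"bin_k": 10},
}
manifest = memloc.run_full(cfg, "demo_out")
```

This simulates 80 cells on two 1024² three-channel fields (the default
generator plants a 1.31-fold tumor membrane enrichment with 20%
cell-to-cell spread), profiles and scores every cell, and writes CSVs,
plots and `demo_out/report/summary.md`, which for this seed reads:

```
- contrast: healthy vs tumor on `mem_mean`
- fold change: 1.166 (rel. sd 0.204)
- ANOVA: F = 19.24, df = (1, 78), p = 3.57e-05 (***)
- binned correlation: Pearson R = 0.2716 over 8 points (k = 10, random binning)
```

So at n = 40 per group the planted membrane shift is detected highly
significantly, though the fold estimate (1.166) is attenuated by PSF
blur and still noisy at this sample size; 8 scatter points are far too
few for a stable correlation. At study scale (hundreds of cells, below)
both readouts stabilize.

The same run from the shell:

```sh
memloc run --config demo.yaml --out demo_out --seed 1
```

Stages are also available individually (`memloc simulate|profile|score|
compare|correlate|report`), all driven by one YAML config whose keys
mirror `memloc.pipeline.DEFAULT_CONFIG`; real data enter by disabling
the simulate stage and pointing `inputs.fields` at TIFF channels and a
`cell_id,vertex_index,x,y` ROI CSV per field of view.

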