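"""Validation benchmarks: full-pipeline recovery of planted parameters.

Two standard study-scale configurations exercise the whole chain
(simulate -> profile -> score -> compare/correlate) and report how well
the pipeline recovers what was planted:

* membrane-shift benchmark — 300 "healthy" cells with membrane amplitude
  100 a.u. vs 600 "tumor" cells at 131 a.u. (planted fold 1.31), equal
  cytoplasm amplitude 80 a.u., default imaging model; the recovered
  fold change of the background-corrected membrane-band intensity is
  the figure of merit.
* correlation benchmark — 500 cells whose membrane and GPI-T amplitudes
  share a standard-normal latent z (mem = 150 + 40*(z + eps),
  gpit = 600 + 120*z, eps ~ N(0, 0.747^2), population Pearson
  R = 1/sqrt(1 + 0.747^2) ~= 0.801); the 10-cell random-binned Pearson
  correlation recovered by the pipeline is the figure of merit.

Both run in a throwaway directory unless one is supplied and are fully
deterministic for a fixed seed.
"""

from __future__ import annotations

import tempfile
from pathlib import Path

import pandas as pd

from . import pipeline

MEMBRANE_SHIFT_CONFIG = {
    "simulate": {
        "n_per_group": {"healthy": 300, "tumor": 600},
        "cyto_amp": {"healthy": [80.0, 0.0], "tumor": [80.0, 0.0]},
        "mem_amp": {"healthy": [100.0, 0.0], "tumor": [131.0, 0.0]},
        "gpit_amp": {"healthy": [400.0, 0.0], "tumor": [600.0, 0.0]},
    },
    "stats": {"contrast": ["healthy", "tumor"], "field": "mem_mean"},
}

CORRELATION_CONFIG = {
    "simulate": {
        "n_per_group": {"tumor": 500},
        "cyto_amp": {"tumor": [80.0, 0.0]},
        "mem_amp": {"tumor": [150.0, 0.0]},     # overridden by the latent model
        "gpit_amp": {"tumor": [600.0, 0.0]},    # overridden by the latent model
        "correlation": {"a": 150.0, "b": 40.0, "c": 600.0, "d": 120.0,
                        "sigma_eps": 0.747},
    },
    "stats": {"bin_k": 10, "bin_policy": "random"},
}


def membrane_shift_benchmark(seed: int, outdir=None) -> dict:
    """Recover the planted 1.31-fold membrane-intensity shift."""
    with tempfile.TemporaryDirectory() as tmp:
        out = Path(outdir) if outdir is not None else Path(tmp)
        cfg = pipeline.resolve_config(MEMBRANE_SHIFT_CONFIG)
        cfg["seed"] = int(seed)
        pipeline.stage_simulate(cfg, out)
        pipeline.stage_profile(cfg, out)
        pipeline.stage_score(cfg, out)
        comp = pipeline.stage_compare(cfg, out)
        return {
            "fold_change": comp.fold_change,
            "rel_sd": comp.rel_sd,
            "p_value": comp.p_value,
            "stars": comp.stars,
            "n_healthy": comp.n_a,
            "n_tumor": comp.n_b,
        }


def correlation_benchmark(seed: int, outdir=None) -> dict:
    """Recover the planted latent-model Pearson correlation (~0.801)."""
    with tempfile.TemporaryDirectory() as tmp:
        out = Path(outdir) if outdir is not None else Path(tmp)
        cfg = pipeline.resolve_config(CORRELATION_CONFIG)
        cfg["seed"] = int(seed)
        pipeline.stage_simulate(cfg, out)
        pipeline.stage_profile(cfg, out)
        pipeline.stage_score(cfg, out)
        corr = pipeline.stage_correlate(cfg, out)
        n_cells = len(pd.read_csv(out / "scores.csv"))
        return {
            "pearson_r": corr.pearson_r,
            "n_points": corr.n_points,
            "k": corr.k,
            "n_cells": n_cells,
        }
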