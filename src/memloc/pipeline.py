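"""Pipeline orchestration: simulate -> profile -> score -> compare ->
correlate -> report.

Every stage reads its inputs from, and writes its outputs to, a single
output directory, so stages can be run one at a time (CLI subcommands) or
end to end (``run_full``).  All numeric defaults live in the
configuration, every stage is deterministic for a fixed config + seed,
and the run manifest reconciles cell counts across stages.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import imgio, locscore, radialprof, statcmp, synthgen
from .errors import ConfigError, DataError

logger = logging.getLogger("memloc")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "simulate": {
        "enabled": True,
        "n_per_group": {"healthy": 20, "tumor": 20},
        "radius": [20.0, 30.0],
        "eccentricity": [0.0, 0.6],
        "shell_thickness": 3.0,
        "nucleus_radius_frac": 0.45,
        "cyto_amp": {"healthy": [80.0, 16.0], "tumor": [80.0, 16.0]},
        "mem_amp": {"healthy": [100.0, 20.0], "tumor": [131.0, 26.2]},
        "gpit_amp": {"healthy": [400.0, 80.0], "tumor": [600.0, 120.0]},
        "correlation": None,   # or {a, b, c, d, sigma_eps}
        "cells_per_tile": 60,
        "tile_size": [1024, 1024],
        "nuclear_amp": 1000.0,
        "roi_vertices": 64,
        "imaging": {
            "psf_sigma": 1.0,
            "background": 100.0,
            "read_noise_sd": 5.0,
            "shot_noise": True,
            "bit_depth": 16,
            "pixel_size": 0.227,
        },
    },
    "inputs": {"fields": []},
    "profile": {
        "n_lines": 180,
        "n_samples": 101,
        "interpolation": "bilinear",
        "normalize": False,
    },
    "score": {
        "f_mem": 0.15,
        "r_cyto": 0.6,
        "background_policy": "image_median_outside_cells",
        "background_offset": 0.0,
    },
    "stats": {
        "bin_k": 10,
        "bin_policy": "random",
        "contrast": ["healthy", "tumor"],
        "field": "mem_mean",
    },
}


# keys whose values are replaced wholesale rather than deep-merged
# (group maps and lists, where merging defaults in would be surprising)
_ATOMIC_KEYS = {
    ("simulate", "n_per_group"), ("simulate", "cyto_amp"),
    ("simulate", "mem_amp"), ("simulate", "gpit_amp"),
    ("simulate", "correlation"), ("stats", "contrast"),
    ("inputs", "fields"),
}


def _merge(base: dict, override: dict, _path: tuple = ()) -> dict:
    out = copy.deepcopy(base)
    for k, v in (override or {}).items():
        path = _path + (k,)
        if (isinstance(v, dict) and isinstance(out.get(k), dict)
                and path not in _ATOMIC_KEYS):
            out[k] = _merge(out[k], v, path)
        else:
            out[k] = copy.deepcopy(v)
    return out


def resolve_config(config: dict | str | Path | None) -> dict:
    """Merge a user config (mapping or YAML path) over the defaults."""
    if config is None:
        user = {}
    elif isinstance(config, (str, Path)):
        user = imgio.load_config(config)
    elif isinstance(config, dict):
        user = config
    else:
        raise ConfigError(f"unsupported config type {type(config).__name__}")
    return _merge(DEFAULT_CONFIG, user)


def config_hash(cfg: dict) -> str:
    canon = yaml.safe_dump(cfg, sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    """Provenance and count reconciliation for one pipeline run."""

    config_hash: str = ""
    seed: int = 0
    inputs: list[str] = field(default_factory=list)
    outputs: list[str] = field(default_factory=list)
    counts: dict = field(default_factory=dict)

    def save(self, outdir: Path) -> None:
        path = Path(outdir) / "manifest.json"
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def load(cls, outdir: Path) -> "RunManifest":
        path = Path(outdir) / "manifest.json"
        if not path.exists():
            return cls()
        with open(path) as fh:
            return cls(**json.load(fh))


def _validate(cfg: dict) -> None:
    sim = cfg["simulate"]
    if not sim["enabled"]:
        fields = cfg["inputs"]["fields"]
        if not fields:
            raise ConfigError(
                "simulation disabled and no inputs.fields configured")
        for i, f in enumerate(fields):
            for key in ("fr1", "gpit", "rois"):
                if key not in f:
                    raise ConfigError(
                        f"inputs.fields[{i}] missing required key {key!r}")
    # constructing BandConfig validates the band geometry up front
    locscore.BandConfig(
        f_mem=cfg["score"]["f_mem"], r_cyto=cfg["score"]["r_cyto"],
        background_policy=cfg["score"]["background_policy"],
        background_offset=cfg["score"]["background_offset"])
    if cfg["profile"]["n_lines"] < 1:
        raise ConfigError("profile.n_lines must be >= 1")
    ns = cfg["profile"]["n_samples"]
    if ns < 3 or ns % 2 == 0:
        raise ConfigError("profile.n_samples must be odd and >= 3")
    if cfg["stats"]["bin_k"] < 1:
        raise ConfigError("stats.bin_k must be >= 1")


def _population_spec(cfg: dict, seed: int) -> synthgen.PopulationSpec:
    sim = cfg["simulate"]
    corr = sim.get("correlation")
    amp = {g: tuple(v) for g, v in sim["cyto_amp"].items()}
    return synthgen.PopulationSpec(
        n_per_group=dict(sim["n_per_group"]),
        radius=tuple(sim["radius"]),
        eccentricity=tuple(sim["eccentricity"]),
        shell_thickness=sim["shell_thickness"],
        nucleus_radius_frac=sim["nucleus_radius_frac"],
        cyto_amp=amp,
        mem_amp={g: tuple(v) for g, v in sim["mem_amp"].items()},
        gpit_amp={g: tuple(v) for g, v in sim["gpit_amp"].items()},
        correlation=synthgen.CorrelationModel(**corr) if corr else None,
        seed=seed)


def stage_simulate(cfg: dict, outdir: Path) -> list[dict]:
    """Render synthetic fields of view and write images/ROIs/ground truth."""
    outdir = Path(outdir)
    sim = cfg["simulate"]
    seed = int(cfg["seed"])
    model = synthgen.ImagingModel(**sim["imaging"])
    spec = _population_spec(cfg, seed)
    scenes = synthgen.simulate_tiles(
        spec, model, tile_size=tuple(sim["tile_size"]),
        cells_per_tile=sim["cells_per_tile"], nuclear_amp=sim["nuclear_amp"])
    for sub in ("images", "rois", "truth"):
        (outdir / sub).mkdir(parents=True, exist_ok=True)
    fields = []
    for i, scene in enumerate(scenes):
        entry = {}
        for ch, arr in scene.channels.items():
            path = outdir / "images" / f"tile{i:03d}_{ch}.tif"
            imgio.write_image(arr, path)
            entry[ch] = str(path)
        rois = imgio.RoiSet(
            polygons={c.cell_id: c.boundary_polygon(sim["roi_vertices"])
                      for c in scene.cells},
            source="ground_truth")
        roi_path = outdir / "rois" / f"tile{i:03d}_rois.csv"
        imgio.write_rois(rois, roi_path)
        entry["rois"] = str(roi_path)
        truth_path = outdir / "truth" / f"tile{i:03d}_truth.csv"
        synthgen.write_ground_truth(scene.cells, truth_path)
        entry["truth"] = str(truth_path)
        fields.append(entry)
    with open(outdir / "fields.json", "w") as fh:
        json.dump(fields, fh, indent=2)
    n_cells = sum(len(s.cells) for s in scenes)
    logger.info("simulate: %d cells across %d tile(s)", n_cells, len(scenes))
    return fields


def _load_fields(cfg: dict, outdir: Path) -> list[dict]:
    path = Path(outdir) / "fields.json"
    if path.exists():
        with open(path) as fh:
            return json.load(fh)
    if cfg["inputs"]["fields"]:
        return cfg["inputs"]["fields"]
    raise DataError(
        f"no fields.json under {outdir} and no inputs.fields configured; "
        "run the simulate stage or point the config at real images")


def _cell_groups(entry: dict) -> dict[int, str]:
    if "truth" in entry and entry["truth"]:
        cells = synthgen.read_ground_truth(entry["truth"])
        return {c.cell_id: c.group for c in cells}
    if "groups" in entry and entry["groups"]:
        df = pd.read_csv(entry["groups"])
        return {int(r.cell_id): str(r.group) for r in df.itertuples()}
    return {}


def stage_profile(cfg: dict, outdir: Path) -> pd.DataFrame:
    """Compute per-cell FR1 radial profiles and population averages."""
    outdir = Path(outdir)
    fields = _load_fields(cfg, outdir)
    pcfg = cfg["profile"]
    rows = []
    n_loaded = n_border = 0
    profiles_by_group: dict[str, list] = {}
    for entry in fields:
        fr1 = imgio.read_image(entry["fr1"], "fr1",
                               page=entry.get("fr1_page", 0))
        rois = imgio.read_rois(entry["rois"])
        groups = _cell_groups(entry)
        h, w = fr1.shape
        for cell_id, poly in sorted(rois.items()):
            n_loaded += 1
            minx, miny, maxx, maxy = poly.bounds()
            if minx < 0 or miny < 0 or maxx > w - 1 or maxy > h - 1:
                n_border += 1
                continue
            prof = radialprof.cell_profile(
                fr1, poly, cell_id=cell_id, channel_name="fr1",
                n_lines=pcfg["n_lines"], n_samples=pcfg["n_samples"],
                interpolation=pcfg["interpolation"])
            group = groups.get(cell_id, "all")
            pop_prof = prof
            if pcfg["normalize"]:
                m = prof.mean_intensity.mean()
                pop_prof = radialprof.CellProfile(
                    cell_id=cell_id, channel_name="fr1", grid=prof.grid,
                    mean_intensity=prof.mean_intensity / m if m > 0
                    else prof.mean_intensity,
                    n_lines=prof.n_lines, n_samples=prof.n_samples)
            profiles_by_group.setdefault(group, []).append(pop_prof)
            for j, (r, v) in enumerate(zip(prof.grid, prof.mean_intensity)):
                rows.append((cell_id, group, j, r, v))
    if n_border:
        logger.warning("profile: excluded %d border cell(s)", n_border)
    if not rows:
        raise DataError("no cells could be profiled")
    df = pd.DataFrame(
        rows, columns=["cell_id", "group", "grid_index", "r", "mean_intensity"])
    df.to_csv(outdir / "profiles.csv", index=False, float_format="%.6g")
    pop_rows = []
    for group, profs in sorted(profiles_by_group.items()):
        pop = radialprof.population_profile(profs, group)
        for r, m, s in zip(pop.grid, pop.mean, pop.sd):
            pop_rows.append((group, r, m, s, pop.n_cells))
    pd.DataFrame(pop_rows, columns=["group", "r", "mean", "sd", "n_cells"]) \
        .to_csv(outdir / "population_profiles.csv", index=False,
                float_format="%.6g")
    manifest = RunManifest.load(outdir)
    manifest.counts.update(loaded=n_loaded, excluded_border=n_border,
                           profiled=n_loaded - n_border)
    manifest.save(outdir)
    logger.info("profile: %d cells profiled (%d loaded)",
                n_loaded - n_border, n_loaded)
    return df


def stage_score(cfg: dict, outdir: Path) -> pd.DataFrame:
    """Score every profiled cell (membrane/cytoplasm bands + GPI-T mean)."""
    outdir = Path(outdir)
    fields = _load_fields(cfg, outdir)
    scfg = cfg["score"]
    bands = locscore.BandConfig(
        f_mem=scfg["f_mem"], r_cyto=scfg["r_cyto"],
        background_policy=scfg["background_policy"],
        background_offset=scfg["background_offset"])
    prof_df = imgio.read_measurements(outdir / "profiles.csv")
    grouped = {cid: sub for cid, sub in prof_df.groupby("cell_id")}
    records = []
    for entry in fields:
        fr1 = imgio.read_image(entry["fr1"], "fr1",
                               page=entry.get("fr1_page", 0))
        gpit = imgio.read_image(entry["gpit"], "gpit",
                                page=entry.get("gpit_page", 0))
        rois = imgio.read_rois(entry["rois"])
        groups = _cell_groups(entry)
        background = {
            "fr1": locscore.estimate_background(
                fr1, rois, bands.background_policy, bands.background_offset),
            "gpit": locscore.estimate_background(
                gpit, rois, bands.background_policy, bands.background_offset),
        }
        for cell_id, poly in sorted(rois.items()):
            sub = grouped.get(cell_id)
            if sub is None:   # excluded at the profile stage
                continue
            sub = sub.sort_values("grid_index")
            prof = radialprof.CellProfile(
                cell_id=cell_id, channel_name="fr1",
                grid=sub["r"].to_numpy(),
                mean_intensity=sub["mean_intensity"].to_numpy(),
                n_lines=cfg["profile"]["n_lines"],
                n_samples=len(sub))
            score = locscore.score_cell(prof, gpit, poly, bands, background)
            records.append({
                "cell_id": cell_id, "group": groups.get(cell_id, "all"),
                "mem_mean": score.mem_mean, "cyto_mean": score.cyto_mean,
                "ratio": score.ratio, "gpit_mean": score.gpit_mean,
                "valid": score.valid})
    if not records:
        raise DataError("no cells to score; run the profile stage first")
    df = pd.DataFrame(records)
    df.to_csv(outdir / "scores.csv", index=False, float_format="%.6g")
    manifest = RunManifest.load(outdir)
    manifest.counts.update(scored=len(df))
    manifest.save(outdir)
    logger.info("score: %d cells scored", len(df))
    return df


def _scores_from_csv(outdir: Path
                     ) -> tuple[list[locscore.MembraneScore], pd.DataFrame]:
    path = Path(outdir) / "scores.csv"
    if not path.exists():
        raise DataError(f"scores.csv not found under {outdir}; "
                        "run the score stage first")
    df = imgio.read_measurements(path)
    return [locscore.MembraneScore(
        cell_id=int(r.cell_id), channel_name="fr1",
        mem_mean=float(r.mem_mean), cyto_mean=float(r.cyto_mean),
        ratio=float(r.ratio), gpit_mean=float(r.gpit_mean),
        valid=bool(r.valid)) for r in df.itertuples()], df


def stage_compare(cfg: dict, outdir: Path) -> locscore.GroupComparison:
    """Two-group contrast (fold change, rel. sd, ANOVA stars) on a field."""
    outdir = Path(outdir)
    scores, df = _scores_from_csv(outdir)
    field_name = cfg["stats"]["field"]
    ga, gb = cfg["stats"]["contrast"]
    by_id = {s.cell_id: s for s in scores}
    ids_a = df.loc[df["group"] == ga, "cell_id"]
    ids_b = df.loc[df["group"] == gb, "cell_id"]
    if len(ids_a) < 2 or len(ids_b) < 2:
        raise DataError(
            f"contrast ({ga!r}, {gb!r}) needs >= 2 cells per group; "
            f"got {len(ids_a)} and {len(ids_b)}")
    cmp_res = locscore.compare_groups(
        [by_id[i] for i in ids_a], [by_id[i] for i in ids_b],
        field=field_name, labels=(ga, gb))
    pd.DataFrame([asdict(cmp_res)]).to_csv(
        outdir / "group_comparison.csv", index=False, float_format="%.6g")
    logger.info("compare: %s vs %s fold_change=%.4f p=%.3g %s",
                ga, gb, cmp_res.fold_change, cmp_res.p_value, cmp_res.stars)
    return cmp_res


def stage_correlate(cfg: dict, outdir: Path) -> statcmp.CorrelationResult:
    """k-cell binned Pearson correlation of gpit_mean vs mem_mean."""
    outdir = Path(outdir)
    scores, _df = _scores_from_csv(outdir)
    k = cfg["stats"]["bin_k"]
    policy = cfg["stats"]["bin_policy"]
    seed = int(cfg["seed"])
    points = statcmp.bin_cells(scores, k, policy=policy, seed=seed)
    result = statcmp.CorrelationResult(
        pearson_r=statcmp.pearson([p.x for p in points],
                                  [p.y for p in points]),
        n_points=len(points), k=k, binning_policy=policy, seed=seed)
    pd.DataFrame([(p.bin_id, p.x, p.y, p.k) for p in points],
                 columns=["bin_id", "x", "y", "k"]).to_csv(
        outdir / "binned_scatter.csv", index=False, float_format="%.6g")
    pd.DataFrame([asdict(result)]).to_csv(
        outdir / "correlation.csv", index=False, float_format="%.6g")
    manifest = RunManifest.load(outdir)
    manifest.counts.update(binned_points=len(points),
                           dropped_at_binning=len(scores) - len(points) * k)
    manifest.save(outdir)
    logger.info("correlate: R=%.4f over %d points (k=%d, %s)",
                result.pearson_r, result.n_points, k, policy)
    return result


def render_report(cfg: dict, outdir: Path) -> list[Path]:
    """Figure-style outputs: population profiles, group bars, binned scatter,
    and a markdown summary (no timestamps, so reruns are identical)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    rep = outdir / "report"
    rep.mkdir(parents=True, exist_ok=True)
    for name in ("population_profiles.csv", "group_comparison.csv",
                 "binned_scatter.csv", "correlation.csv"):
        if not (outdir / name).exists():
            raise DataError(f"missing upstream output {name}; "
                            "run the earlier stages first")
    outputs = []

    pop = pd.read_csv(outdir / "population_profiles.csv")
    fig, ax = plt.subplots(figsize=(6, 4))
    for group, sub in pop.groupby("group"):
        ax.plot(sub["r"], sub["mean"], label=f"{group} (n={sub['n_cells'].iat[0]})")
        ax.fill_between(sub["r"], sub["mean"] - sub["sd"],
                        sub["mean"] + sub["sd"], alpha=0.2)
    ax.set_xlabel("normalized diameter r")
    ax.set_ylabel("FR1 intensity (a.u.)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(rep / "population_profiles.png", dpi=120)
    plt.close(fig)
    outputs.append(rep / "population_profiles.png")

    comp = pd.read_csv(outdir / "group_comparison.csv").iloc[0]
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.bar([comp["group_a"], comp["group_b"]], [1.0, comp["fold_change"]],
           yerr=[0.0, comp["rel_sd"]], capsize=6,
           color=["#888888", "#c0392b"])
    ax.set_ylabel(f"relative {comp['field_name']} (fold of {comp['group_a']})")
    ax.text(1, comp["fold_change"] + comp["rel_sd"] + 0.02, comp["stars"],
            ha="center")
    fig.tight_layout()
    fig.savefig(rep / "group_bars.png", dpi=120)
    plt.close(fig)
    outputs.append(rep / "group_bars.png")

    scat = pd.read_csv(outdir / "binned_scatter.csv")
    corr = pd.read_csv(outdir / "correlation.csv").iloc[0]
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(scat["x"], scat["y"], s=18)
    slope, intercept = np.polyfit(scat["x"], scat["y"], 1)
    xs = np.linspace(scat["x"].min(), scat["x"].max(), 50)
    ax.plot(xs, slope * xs + intercept, "r-")
    ax.set_xlabel(f"GPI-T intensity (a.u., {int(corr['k'])}-cell bins)")
    ax.set_ylabel("FR1 membrane intensity (a.u.)")
    ax.set_title(f"Pearson R = {corr['pearson_r']:.3f}")
    fig.tight_layout()
    fig.savefig(rep / "binned_scatter.png", dpi=120)
    plt.close(fig)
    outputs.append(rep / "binned_scatter.png")

    lines = [
        "# Run summary", "",
        f"- contrast: {comp['group_a']} vs {comp['group_b']} "
        f"on `{comp['field_name']}`",
        f"- fold change: {comp['fold_change']:.4g} "
        f"(rel. sd {comp['rel_sd']:.3g})",
        f"- ANOVA: F = {comp['f_stat']:.4g}, "
        f"df = ({int(comp['df_between'])}, {int(comp['df_within'])}), "
        f"p = {comp['p_value']:.3g} ({comp['stars']})",
        f"- binned correlation: Pearson R = {corr['pearson_r']:.4g} over "
        f"{int(corr['n_points'])} points (k = {int(corr['k'])}, "
        f"{corr['binning_policy']} binning)",
        "", "## Group comparison table", "",
        pd.read_csv(outdir / "group_comparison.csv").to_markdown(index=False),
        "",
    ]
    summary = rep / "summary.md"
    summary.write_text("\n".join(lines))
    outputs.append(summary)
    manifest = RunManifest.load(outdir)
    manifest.outputs = sorted(set(manifest.outputs) | {str(p) for p in outputs})
    manifest.save(outdir)
    return outputs


def run_full(config: dict | str | Path | None, outdir,
             seed: int | None = None) -> RunManifest:
    """Execute all stages in order and return the reconciled manifest."""
    cfg = resolve_config(config)
    if seed is not None:
        cfg["seed"] = int(seed)
    _validate(cfg)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=config_hash(cfg), seed=int(cfg["seed"]))
    manifest.save(outdir)
    if cfg["simulate"]["enabled"]:
        fields = stage_simulate(cfg, outdir)
    else:
        fields = cfg["inputs"]["fields"]
    manifest = RunManifest.load(outdir)
    manifest.config_hash = config_hash(cfg)
    manifest.seed = int(cfg["seed"])
    manifest.inputs = sorted({str(v) for f in fields for v in f.values()})
    manifest.save(outdir)
    stage_profile(cfg, outdir)
    stage_score(cfg, outdir)
    stage_compare(cfg, outdir)
    stage_correlate(cfg, outdir)
    render_report(cfg, outdir)
    manifest = RunManifest.load(outdir)
    manifest.config_hash = config_hash(cfg)
    manifest.seed = int(cfg["seed"])
    manifest.inputs = sorted({str(v) for f in fields for v in f.values()})
    manifest.outputs = sorted(set(manifest.outputs) | {
        str(outdir / n) for n in
        ("profiles.csv", "population_profiles.csv", "scores.csv",
         "group_comparison.csv", "binned_scatter.csv", "correlation.csv")})
    manifest.save(outdir)
    return manifest
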