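"""Synthetic two-group, three-channel fluorescence scene generator.

Emulates the immunofluorescence data the downstream pipeline analyses:
elliptical cells with a bright membrane shell and dimmer cytoplasm in the
FR1 channel, a per-cell uniform GPI-T channel, and a nuclear channel for
cell picking — on a constant background, blurred by a Gaussian PSF and
degraded by Poisson shot noise and Gaussian read noise.

Geometry.  A cell is an ellipse with semi-major axis ``radius``,
semi-minor ``radius * sqrt(1 - eccentricity^2)`` and free orientation.
The membrane is the shell between the outer ellipse and an inner ellipse
with both semi-axes reduced by ``shell_thickness`` (exactly constant
thickness for circles, uniformly close for the bounded eccentricities
used here).  The nucleus is a concentric disk.  Footprints are strictly
disjoint (rejection sampling), matching an analysis of manually selected
single cells.

Amplitudes.  Per-group cytoplasm/membrane/GPI-T amplitudes are drawn from
Normal(mean, sd) floored at 0, or — when a correlation model is set —
membrane and GPI-T amplitudes share a standard-normal latent z:

    mem_amp  = a + b * (z + eps),   eps ~ Normal(0, sigma_eps^2)
    gpit_amp = c + d * z

so the population correlation is 1 / sqrt(1 + sigma_eps^2).

All randomness flows from a single master seed through deterministically
spawned child streams (placement, amplitudes, noise), so an identical
spec + seed reproduces bit-identical scenes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .errors import ConfigError, DataError, PlacementError
from .radialprof import Polygon

GROUPS = ("healthy", "tumor")


@dataclass
class CellGroundTruth:
    """Planted parameters of one synthetic cell."""

    cell_id: int
    group: str
    center: tuple[float, float]     # (x, y) pixels
    radius: float                   # semi-major axis, pixels
    eccentricity: float             # in [0, 0.6]
    orientation: float              # radians
    shell_thickness: float          # pixels
    cyto_amp: float
    mem_amp: float
    gpit_amp: float
    nucleus_radius: float
    latent_z: float = 0.0

    def __post_init__(self) -> None:
        if not self.radius > self.shell_thickness > 0:
            raise ConfigError("need radius > shell_thickness > 0")
        if not 0 <= self.eccentricity <= 0.6:
            raise ConfigError("eccentricity must lie in [0, 0.6]")
        if self.nucleus_radius >= self.semi_minor - self.shell_thickness:
            raise ConfigError("nucleus must fit inside the cytoplasm")
        for a in (self.cyto_amp, self.mem_amp, self.gpit_amp):
            if not math.isfinite(a) or a < 0:
                raise ConfigError(f"amplitudes must be finite and >= 0, got {a}")

    @property
    def semi_minor(self) -> float:
        return self.radius * math.sqrt(1.0 - self.eccentricity ** 2)

    def boundary_polygon(self, n_vertices: int = 64) -> Polygon:
        """The shell's outer boundary discretized as an inscribed polygon."""
        tau = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
        a, b = self.radius, self.semi_minor
        co, so = math.cos(self.orientation), math.sin(self.orientation)
        ex, ey = a * np.cos(tau), b * np.sin(tau)
        xs = self.center[0] + ex * co - ey * so
        ys = self.center[1] + ex * so + ey * co
        return Polygon(np.column_stack([xs, ys]))


@dataclass
class ImagingModel:
    """Camera/optics model applied to the noiseless scene."""

    psf_sigma: float = 1.0          # Gaussian PSF sd, pixels
    background: float = 100.0       # a.u., all channels
    read_noise_sd: float = 5.0      # a.u., additive Gaussian
    shot_noise: bool = True         # Poisson on the pre-noise signal
    bit_depth: int = 16
    pixel_size: float = 0.227       # µm/pixel, metadata only

    def __post_init__(self) -> None:
        if self.psf_sigma < 0 or self.background < 0 or self.read_noise_sd < 0:
            raise ConfigError("psf_sigma, background, read_noise_sd must be >= 0")


@dataclass
class CorrelationModel:
    """Latent linear coupling of membrane and GPI-T amplitudes."""

    a: float = 150.0
    b: float = 40.0
    c: float = 600.0
    d: float = 120.0
    sigma_eps: float = 0.747

    def __post_init__(self) -> None:
        if self.b <= 0 or self.d <= 0:
            raise ConfigError("correlation slopes b, d must be > 0")
        if self.sigma_eps < 0:
            raise ConfigError("sigma_eps must be >= 0")

    @property
    def population_r(self) -> float:
        """Closed-form Pearson correlation of (mem_amp, gpit_amp)."""
        return 1.0 / math.sqrt(1.0 + self.sigma_eps ** 2)


@dataclass
class PopulationSpec:
    """Distributions defining a synthetic cell population.

    Amplitude entries map group -> (mean, sd); geometric ranges are
    uniform (low, high).  When ``correlation`` is set it overrides the
    per-group membrane and GPI-T amplitude draws for every cell.
    """

    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"healthy": 50, "tumor": 50})
    radius: tuple[float, float] = (20.0, 30.0)
    eccentricity: tuple[float, float] = (0.0, 0.6)
    shell_thickness: float = 3.0
    nucleus_radius_frac: float = 0.45   # of (semi-minor - shell)
    cyto_amp: dict = field(
        default_factory=lambda: {"healthy": (80.0, 16.0), "tumor": (80.0, 16.0)})
    mem_amp: dict = field(
        default_factory=lambda: {"healthy": (100.0, 20.0), "tumor": (131.0, 26.2)})
    gpit_amp: dict = field(
        default_factory=lambda: {"healthy": (400.0, 80.0), "tumor": (600.0, 120.0)})
    correlation: CorrelationModel | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for g, n in self.n_per_group.items():
            if n < 1:
                raise ConfigError(f"group {g!r} count must be >= 1, got {n}")
        if self.radius[0] <= self.shell_thickness:
            raise ConfigError("minimum radius must exceed shell thickness")


@dataclass
class SyntheticScene:
    """Rendered three-channel field of view plus its ground truth."""

    channels: dict[str, np.ndarray]   # nuclear | gpit | fr1
    cells: list[CellGroundTruth]
    model: ImagingModel
    canvas: tuple[int, int]           # (width, height)

    def __post_init__(self) -> None:
        if not self.cells:
            raise DataError("a scene must contain at least one cell")
        shapes = {ch.shape for ch in self.channels.values()}
        if shapes != {(self.canvas[1], self.canvas[0])}:
            raise DataError("channel rasters do not match the canvas size")


def _draw_amplitude(rng: np.random.Generator, mean_sd) -> float:
    mean, sd = mean_sd
    return float(max(rng.normal(mean, sd) if sd > 0 else mean, 0.0))


def sample_population(spec: PopulationSpec, canvas: tuple[int, int],
                      rng: np.random.Generator | None = None,
                      margin: float = 4.0, max_attempts: int = 2000,
                      start_id: int = 0) -> list[CellGroundTruth]:
    """Draw cell parameters and place footprints disjointly on the canvas.

    Placement is rejection sampling on bounding circles (semi-major axis
    plus ``margin``); after ``max_attempts`` failed draws for a cell a
    PlacementError reports the density achieved so far.  Deterministic for
    a fixed spec seed (or an explicitly passed generator).
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    w, h = canvas
    placed: list[CellGroundTruth] = []
    cell_id = start_id
    for group in sorted(spec.n_per_group):
        for _ in range(spec.n_per_group[group]):
            radius = float(rng.uniform(*spec.radius))
            ecc = float(rng.uniform(*spec.eccentricity))
            orient = float(rng.uniform(0.0, np.pi))
            if radius + margin > min(w, h) / 2:
                raise PlacementError(
                    f"canvas {w}x{h} too small for cell radius {radius:.1f}")
            for attempt in range(max_attempts):
                cx = float(rng.uniform(radius + margin, w - 1 - radius - margin))
                cy = float(rng.uniform(radius + margin, h - 1 - radius - margin))
                ok = all((cx - c.center[0]) ** 2 + (cy - c.center[1]) ** 2
                         > (radius + c.radius + margin) ** 2 for c in placed)
                if ok:
                    break
            else:
                density = sum(np.pi * c.radius * c.semi_minor
                              for c in placed) / (w * h)
                raise PlacementError(
                    f"could not place cell {cell_id} after {max_attempts} "
                    f"attempts (achieved footprint density {density:.2f})")
            z = float(rng.standard_normal())
            if spec.correlation is not None:
                cm = spec.correlation
                eps = float(rng.normal(0.0, cm.sigma_eps))
                mem = max(cm.a + cm.b * (z + eps), 0.0)
                gpit = max(cm.c + cm.d * z, 0.0)
            else:
                mem = _draw_amplitude(rng, spec.mem_amp[group])
                gpit = _draw_amplitude(rng, spec.gpit_amp[group])
            cyto = _draw_amplitude(rng, spec.cyto_amp[group])
            semi_minor = radius * math.sqrt(1.0 - ecc ** 2)
            placed.append(CellGroundTruth(
                cell_id=cell_id, group=group, center=(cx, cy), radius=radius,
                eccentricity=ecc, orientation=orient,
                shell_thickness=spec.shell_thickness,
                cyto_amp=cyto, mem_amp=mem, gpit_amp=gpit,
                nucleus_radius=spec.nucleus_radius_frac
                * (semi_minor - spec.shell_thickness),
                latent_z=z))
            cell_id += 1
    return placed


def _ellipse_rho2(xs, ys, center, a, b, orientation):
    """Squared normalized elliptical radius of pixel grids."""
    dx = xs - center[0]
    dy = ys - center[1]
    co, so = math.cos(orientation), math.sin(orientation)
    xp = dx * co + dy * so
    yp = -dx * so + dy * co
    return (xp / a) ** 2 + (yp / b) ** 2


def render_scene(cells: list[CellGroundTruth], model: ImagingModel,
                 canvas: tuple[int, int],
                 rng: np.random.Generator | None = None,
                 nuclear_amp: float = 1000.0) -> SyntheticScene:
    """Render the three channels for one field of view.

    Channel composition before degradation (per pixel, a.u.):
      fr1     = background + cyto_amp in the body, mem_amp replacing it in
                the shell
      gpit    = background + gpit_amp over the whole footprint
      nuclear = background + nuclear_amp inside the nucleus disk
    then Gaussian PSF blur, optional Poisson shot noise, additive Gaussian
    read noise, and clipping/quantization to the camera bit depth.
    """
    w, h = canvas
    raster = {name: np.zeros((h, w)) for name in ("nuclear", "gpit", "fr1")}
    for cell in cells:
        if not all(math.isfinite(v) for v in
                   (cell.cyto_amp, cell.mem_amp, cell.gpit_amp)):
            raise DataError(f"cell {cell.cell_id}: non-finite amplitude")
        a, b = cell.radius, cell.semi_minor
        t = cell.shell_thickness
        x0 = max(int(math.floor(cell.center[0] - a)) - 1, 0)
        x1 = min(int(math.ceil(cell.center[0] + a)) + 1, w - 1)
        y0 = max(int(math.floor(cell.center[1] - a)) - 1, 0)
        y1 = min(int(math.ceil(cell.center[1] + a)) + 1, h - 1)
        xs, ys = np.meshgrid(np.arange(x0, x1 + 1), np.arange(y0, y1 + 1))
        body = _ellipse_rho2(xs, ys, cell.center, a, b,
                             cell.orientation) <= 1.0
        inner = _ellipse_rho2(xs, ys, cell.center, a - t, b - t,
                              cell.orientation) <= 1.0
        shell = body & ~inner
        sl = np.s_[y0:y1 + 1, x0:x1 + 1]
        fr1 = raster["fr1"][sl]
        fr1[inner] = cell.cyto_amp
        fr1[shell] = cell.mem_amp
        raster["gpit"][sl][body] = cell.gpit_amp
        nuc = (xs - cell.center[0]) ** 2 + (ys - cell.center[1]) ** 2 \
            <= cell.nucleus_radius ** 2
        raster["nuclear"][sl][nuc] = nuclear_amp
    needs_rng = model.shot_noise or model.read_noise_sd > 0
    if rng is None and needs_rng:
        rng = np.random.default_rng(0)
    vmax = 2.0 ** model.bit_depth - 1
    channels = {}
    for name, img in raster.items():
        img = img + model.background
        if model.psf_sigma > 0:
            img = gaussian_filter(img, model.psf_sigma, mode="nearest")
        if model.shot_noise:
            img = rng.poisson(np.clip(img, 0, None)).astype(float)
        if model.read_noise_sd > 0:
            img = img + rng.normal(0.0, model.read_noise_sd, size=img.shape)
        channels[name] = np.clip(np.round(img), 0, vmax)
    return SyntheticScene(channels=channels, cells=list(cells), model=model,
                          canvas=canvas)


GROUND_TRUTH_COLUMNS = [
    "cell_id", "group", "center_x", "center_y", "radius", "eccentricity",
    "orientation", "shell_thickness", "cyto_amp", "mem_amp", "gpit_amp",
    "nucleus_radius", "latent_z",
]


def write_ground_truth(cells: list[CellGroundTruth], path) -> None:
    """One CSV row per cell with exactly the ground-truth fields."""
    if not cells:
        raise DataError("refusing to write an empty ground-truth table")
    rows = [{
        "cell_id": c.cell_id, "group": c.group,
        "center_x": c.center[0], "center_y": c.center[1],
        "radius": c.radius, "eccentricity": c.eccentricity,
        "orientation": c.orientation, "shell_thickness": c.shell_thickness,
        "cyto_amp": c.cyto_amp, "mem_amp": c.mem_amp, "gpit_amp": c.gpit_amp,
        "nucleus_radius": c.nucleus_radius, "latent_z": c.latent_z,
    } for c in cells]
    pd.DataFrame(rows, columns=GROUND_TRUTH_COLUMNS).to_csv(path, index=False)


def read_ground_truth(path) -> list[CellGroundTruth]:
    df = pd.read_csv(path)
    missing = set(GROUND_TRUTH_COLUMNS) - set(df.columns)
    if missing:
        raise DataError(f"ground-truth table missing columns {sorted(missing)}")
    return [CellGroundTruth(
        cell_id=int(r.cell_id), group=str(r.group),
        center=(float(r.center_x), float(r.center_y)),
        radius=float(r.radius), eccentricity=float(r.eccentricity),
        orientation=float(r.orientation),
        shell_thickness=float(r.shell_thickness),
        cyto_amp=float(r.cyto_amp), mem_amp=float(r.mem_amp),
        gpit_amp=float(r.gpit_amp), nucleus_radius=float(r.nucleus_radius),
        latent_z=float(r.latent_z)) for r in df.itertuples()]


def simulate_tiles(spec: PopulationSpec, model: ImagingModel,
                   tile_size: tuple[int, int] = (1024, 1024),
                   cells_per_tile: int = 60,
                   nuclear_amp: float = 1000.0) -> list[SyntheticScene]:
    """Render a whole population as a series of fields of view.

    Cells are split across as many ``tile_size`` canvases as needed to
    keep the rejection-sampling density low; cell ids are global and group
    proportions are preserved per tile as closely as integer splits allow.
    """
    total = sum(spec.n_per_group.values())
    n_tiles = max(1, math.ceil(total / cells_per_tile))
    ss = np.random.SeedSequence(spec.seed)
    tile_seeds = ss.spawn(n_tiles)
    remaining = dict(spec.n_per_group)
    scenes = []
    next_id = 0
    for i in range(n_tiles):
        tiles_left = n_tiles - i
        counts = {}
        for g in sorted(remaining):
            take = math.ceil(remaining[g] / tiles_left)
            take = min(take, remaining[g])
            if take:
                counts[g] = take
            remaining[g] -= take
        if not counts:
            break
        tile_spec = replace(spec, n_per_group=counts)
        rng = np.random.default_rng(tile_seeds[i])
        cells = sample_population(tile_spec, tile_size, rng=rng,
                                  start_id=next_id)
        next_id += len(cells)
        scenes.append(render_scene(cells, model, tile_size, rng=rng,
                                   nuclear_amp=nuclear_amp))
    return scenes
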