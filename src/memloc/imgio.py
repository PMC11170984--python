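"""Readers and writers for every on-disk artifact.

Conventions
-----------
* Pixel coordinates are 0-based, x rightward (column), y downward (row);
  a coordinate refers to a pixel *center*.  Polygons live in the same
  continuous frame.
* Images are grayscale 8- or 16-bit TIFF, single- or multi-page; loading
  is lossless (no rescaling).
* ROIs travel as CSV with columns ``cell_id,vertex_index,x,y``.
* Measurement tables are CSV with a stable column order and floats at
  6 significant digits.
"""

from __future__ import annotations

import dataclasses
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import ConfigError, DataError
from .radialprof import Polygon

logger = logging.getLogger("memloc")
if not logger.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)

CHANNEL_NAMES = ("nuclear", "gpit", "fr1", "other")


@dataclass
class ChannelImage:
    """A single fluorescence channel as a 2-D raster of intensities."""

    pixels: np.ndarray
    channel_name: str = "other"
    pixel_size: float | None = None  # µm per pixel, metadata only

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise DataError(f"channel image must be 2-D, got shape {px.shape}")
        if not np.all(np.isfinite(px)):
            raise DataError("channel image contains non-finite values")
        if px.min() < 0:
            raise DataError("channel image contains negative intensities")
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # (rows, cols) = (height, width)


@dataclass
class RoiSet:
    """Per-cell polygon ROIs keyed by unique cell id."""

    polygons: dict[int, Polygon]
    source: str = "manual"  # manual | ground_truth

    def __len__(self) -> int:
        return len(self.polygons)

    def items(self):
        return self.polygons.items()


def read_image(path, channel_name: str = "other", page: int = 0,
               allow_float: bool = False) -> ChannelImage:
    """Load one grayscale TIFF page losslessly.

    Multi-page files are addressed by ``page``.  RGB input, or float input
    without ``allow_float``, is rejected rather than silently converted.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"image file not found: {path}")
    with tifffile.TiffFile(path) as tif:
        n_pages = len(tif.pages)
        if not 0 <= page < n_pages:
            raise DataError(
                f"page {page} out of range for {path} ({n_pages} pages)")
        arr = tif.pages[page].asarray()
    if arr.ndim == 3:
        raise DataError(
            f"{path} page {page} is not grayscale (shape {arr.shape}); "
            "RGB input is not supported")
    if np.issubdtype(arr.dtype, np.floating) and not allow_float:
        raise DataError(
            f"{path} has float pixels; pass allow_float=True to accept")
    return ChannelImage(pixels=arr, channel_name=channel_name)


def write_image(image: ChannelImage | np.ndarray, path) -> None:
    """Write a 2-D raster as 16-bit grayscale TIFF (values clipped)."""
    px = image.pixels if isinstance(image, ChannelImage) else np.asarray(image)
    arr = np.clip(np.round(px), 0, 2 ** 16 - 1).astype(np.uint16)
    tifffile.imwrite(Path(path), arr)


def read_rois(path) -> RoiSet:
    """Parse a ROI CSV (``cell_id,vertex_index,x,y``) into polygons.

    Vertices are ordered by ``vertex_index`` within each cell, so row order
    in the file is irrelevant; duplicate consecutive vertices are collapsed.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"ROI file not found: {path}")
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # malformed CSV
        raise DataError(f"cannot parse ROI file {path}: {exc}") from exc
    required = {"cell_id", "vertex_index", "x", "y"}
    if not required.issubset(df.columns):
        raise DataError(
            f"ROI file {path} missing columns {sorted(required - set(df.columns))}")
    for col in ("x", "y"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 zero-based
            raise DataError(
                f"non-numeric coordinate in {path} column {col!r} near line {line}")
        df[col] = pd.to_numeric(df[col])
    polygons: dict[int, Polygon] = {}
    for cell_id, grp in df.groupby("cell_id"):
        grp = grp.sort_values("vertex_index")
        verts = grp[["x", "y"]].to_numpy(dtype=float)
        # collapse duplicate consecutive vertices
        keep = np.ones(len(verts), dtype=bool)
        keep[1:] = np.any(np.diff(verts, axis=0) != 0, axis=1)
        verts = verts[keep]
        if len(verts) > 1 and np.all(verts[0] == verts[-1]):
            verts = verts[:-1]
        if len(np.unique(verts, axis=0)) < 3:
            raise DataError(
                f"cell {cell_id}: polygon has fewer than 3 distinct vertices")
        try:
            polygons[int(cell_id)] = Polygon(verts)
        except Exception as exc:
            raise DataError(f"cell {cell_id}: invalid polygon: {exc}") from exc
    return RoiSet(polygons=polygons)


def write_rois(rois: RoiSet, path) -> None:
    rows = []
    for cell_id, poly in rois.items():
        for i, (x, y) in enumerate(poly.vertices):
            rows.append((cell_id, i, x, y))
    pd.DataFrame(rows, columns=["cell_id", "vertex_index", "x", "y"]).to_csv(
        Path(path), index=False, float_format="%.6g")


def write_measurements(records: Sequence, path) -> None:
    """Write homogeneous records (dataclasses or mappings) as CSV.

    Column order follows the first record; floats use 6 significant digits.
    An empty list yields a header-only file only if records carry no schema,
    so an explicit empty DataFrame with columns may be passed instead.
    """
    path = Path(path)
    if isinstance(records, pd.DataFrame):
        records.to_csv(path, index=False, float_format="%.6g")
        return
    dicts = []
    schema = None
    for rec in records:
        if dataclasses.is_dataclass(rec):
            d = dataclasses.asdict(rec)
        elif isinstance(rec, Mapping):
            d = dict(rec)
        else:
            raise DataError(f"unsupported record type {type(rec).__name__}")
        d = {k: v for k, v in d.items()
             if np.isscalar(v) or v is None or isinstance(v, str)}
        if schema is None:
            schema = tuple(d.keys())
        elif set(d.keys()) != set(schema):
            raise DataError("mixed record schemas in one measurement table")
        dicts.append({k: d[k] for k in schema})  # first record fixes order
    df = pd.DataFrame(dicts, columns=list(schema) if schema else None)
    df.to_csv(path, index=False, float_format="%.6g")


def read_measurements(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise DataError(f"measurement file not found: {path}")
    return pd.read_csv(path)


def load_config(path) -> dict:
    """Load the YAML pipeline configuration."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path) as fh:
        try:
            cfg = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse config {path}: {exc}") from exc
    if not isinstance(cfg, dict):
        raise ConfigError(f"config {path} must be a YAML mapping")
    return cfg
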