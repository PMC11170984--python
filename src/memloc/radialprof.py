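"""Radial intensity profiling of single cells.

The geometric core of the pipeline: a polygon drawn around one cell, a fan
of equally angled lines (diameters) through its area centroid, intensities
sampled along every line, and a per-cell profile obtained by averaging the
lines on a shared normalized diameter grid.

The normalized coordinate r runs over [-1, 1]: 0 is the centroid, +/-1 the
polygon boundary along each ray.  Because a ray and its opposite may have
different physical lengths, sampling is equally spaced *in r* on each
half-line separately; the centroid is always the middle grid point (odd
number of samples).  For cells symmetric about their centroid this
coincides with equal spacing along the physical segment.

Coordinates are 0-based pixel indices, x rightward, y downward, referring
to pixel centers; intensity lookup is bilinear by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
import shapely.geometry as sgeom
from scipy.ndimage import map_coordinates

from .errors import GeometryError

_T_TOL = 1e-9


class Polygon:
    """A simple, star-shaped (about its centroid) polygon ROI.

    Parameters
    ----------
    vertices : (n, 2) array-like
        Ordered (x, y) vertices, not closed (first != last required).

    Raises
    ------
    GeometryError
        For polygons with fewer than 3 distinct vertices, self-intersection,
        zero area, a centroid outside the polygon, or a shape that is not
        star-shaped about the centroid (a ray from the centroid would cross
        the boundary more than once, making radial sampling ill-defined).
    """

    def __init__(self, vertices) -> None:
        verts = np.asarray(vertices, dtype=float)
        if verts.ndim != 2 or verts.shape[1] != 2:
            raise GeometryError(f"vertices must be (n, 2), got {verts.shape}")
        if not np.all(np.isfinite(verts)):
            raise GeometryError("polygon has non-finite vertices")
        if len(verts) > 1 and np.all(verts[0] == verts[-1]):
            verts = verts[:-1]
        if len(np.unique(verts, axis=0)) < 3:
            raise GeometryError("polygon needs at least 3 distinct vertices")
        shp = sgeom.Polygon(verts)
        if not shp.is_valid:
            raise GeometryError("polygon is self-intersecting or degenerate")
        if shp.area <= 0:
            raise GeometryError("polygon has non-positive area")
        self.vertices = verts
        self._shapely = shp
        c = shp.centroid
        self._centroid = (c.x, c.y)
        if not shp.contains(c):
            raise GeometryError(
                "polygon centroid lies outside the polygon "
                "(not star-shaped about its centroid)")
        # star-shapedness: every vertex must be visible from the centroid
        for vx, vy in verts:
            seg = sgeom.LineString([self._centroid, (vx, vy)])
            if not shp.covers(seg):
                raise GeometryError(
                    "polygon is not star-shaped about its centroid: "
                    f"vertex ({vx:g}, {vy:g}) is not visible from it")

    @property
    def shapely(self) -> sgeom.Polygon:
        return self._shapely

    @property
    def centroid(self) -> tuple[float, float]:
        """Area (shoelace-weighted) centroid."""
        return self._centroid

    @property
    def area(self) -> float:
        return self._shapely.area

    def bounds(self) -> tuple[float, float, float, float]:
        return self._shapely.bounds

    def contains_point(self, x: float, y: float) -> bool:
        return self._shapely.contains(sgeom.Point(x, y))

    def __repr__(self) -> str:
        return f"Polygon(n_vertices={len(self.vertices)}, area={self.area:.1f})"


def polygon_centroid(poly: Polygon) -> tuple[float, float]:
    """Area centroid of a polygon (guaranteed inside by construction)."""
    return poly.centroid


def ray_boundary_distances(poly: Polygon, center, angles) -> np.ndarray:
    """Distance from ``center`` to the polygon boundary along each angle.

    Vectorized over angles; raises if the center is not strictly inside or
    if any ray crosses the boundary more than once (star-shape violation).
    """
    cx, cy = center
    if not poly.contains_point(cx, cy):
        raise GeometryError(
            f"ray center ({cx:g}, {cy:g}) is not strictly inside the polygon")
    angles = np.atleast_1d(np.asarray(angles, dtype=float))
    p = poly.vertices
    q = np.roll(p, -1, axis=0)
    d = q - p                       # (E, 2) edge vectors
    w = p - np.array([cx, cy])      # (E, 2)
    u = np.stack([np.cos(angles), np.sin(angles)], axis=1)  # (A, 2)
    # 2-D cross products
    uxd = u[:, 0, None] * d[None, :, 1] - u[:, 1, None] * d[None, :, 0]
    wxd = w[:, 0] * d[:, 1] - w[:, 1] * d[:, 0]             # (E,)
    wxu = w[None, :, 0] * u[:, 1, None] - w[None, :, 1] * u[:, 0, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = wxd[None, :] / uxd
        s = wxu / uxd
    ok = np.isfinite(t) & (t > _T_TOL) & (s >= 0.0) & (s < 1.0)
    t = np.where(ok, t, np.inf)
    tmin = t.min(axis=1)
    if not np.all(np.isfinite(tmin)):
        bad = angles[~np.isfinite(tmin)][0]
        raise GeometryError(f"no boundary crossing along angle {bad:g} rad")
    # more than one distinct crossing on some ray -> not star-shaped there
    extra = ok & (t > tmin[:, None] * (1 + 1e-9) + _T_TOL)
    if extra.any():
        bad = angles[extra.any(axis=1)][0]
        raise GeometryError(
            f"ray at angle {bad:g} rad crosses the boundary more than once "
            "(polygon not star-shaped about this center)")
    return tmin


def ray_boundary_distance(poly: Polygon, center, angle: float) -> float:
    """Distance to the nearest boundary crossing along one direction."""
    return float(ray_boundary_distances(poly, center, [angle])[0])


@dataclass
class LineFan:
    """``n_lines`` equally angled diameters through a cell center.

    ``r_pos[k]`` / ``r_neg[k]`` are the boundary distances in the
    ``angles[k]`` and ``angles[k] + pi`` directions.
    """

    center: tuple[float, float]
    angles: np.ndarray
    r_pos: np.ndarray
    r_neg: np.ndarray

    @property
    def n_lines(self) -> int:
        return len(self.angles)

    @property
    def endpoints(self) -> np.ndarray:
        """(n_lines, 2, 2) array of [negative, positive] (x, y) endpoints."""
        u = np.stack([np.cos(self.angles), np.sin(self.angles)], axis=1)
        c = np.asarray(self.center)
        pos = c + u * self.r_pos[:, None]
        neg = c - u * self.r_neg[:, None]
        return np.stack([neg, pos], axis=1)


def make_line_fan(poly: Polygon, center=None, n_lines: int = 180) -> LineFan:
    """Build the fan of ``n_lines`` diameters at angles k*pi/n_lines."""
    if n_lines < 1:
        raise GeometryError(f"n_lines must be >= 1, got {n_lines}")
    if center is None:
        center = poly.centroid
    angles = np.arange(n_lines) * np.pi / n_lines
    dists = ray_boundary_distances(poly, center,
                                   np.concatenate([angles, angles + np.pi]))
    return LineFan(center=tuple(center), angles=angles,
                   r_pos=dists[:n_lines], r_neg=dists[n_lines:])


def _check_inside_image(xs: np.ndarray, ys: np.ndarray, shape) -> None:
    h, w = shape
    if xs.min() < 0 or xs.max() > w - 1 or ys.min() < 0 or ys.max() > h - 1:
        raise GeometryError(
            "sampling point outside image bounds "
            f"(x in [{xs.min():.2f}, {xs.max():.2f}], "
            f"y in [{ys.min():.2f}, {ys.max():.2f}], image {w}x{h}); "
            "cells touching the border must be excluded upstream")


_INTERP_ORDER = {"bilinear": 1, "nearest": 0}


def sample_line(image, start, end, n_samples: int,
                interpolation: str = "bilinear") -> np.ndarray:
    """Intensities at ``n_samples`` points equally spaced from start to end."""
    if n_samples < 3 or n_samples % 2 == 0:
        raise GeometryError(
            f"n_samples must be odd and >= 3, got {n_samples}")
    if interpolation not in _INTERP_ORDER:
        raise GeometryError(f"unknown interpolation {interpolation!r}")
    px = image.pixels if hasattr(image, "pixels") else np.asarray(image, float)
    frac = np.linspace(0.0, 1.0, n_samples)
    xs = start[0] + frac * (end[0] - start[0])
    ys = start[1] + frac * (end[1] - start[1])
    _check_inside_image(xs, ys, px.shape)
    return map_coordinates(px, np.stack([ys, xs]),
                           order=_INTERP_ORDER[interpolation], mode="nearest")


@dataclass
class CellProfile:
    """Radial intensity profile of one cell in one channel."""

    cell_id: int
    channel_name: str
    grid: np.ndarray            # n_samples points on [-1, 1]
    mean_intensity: np.ndarray  # average over fan lines, per grid point
    n_lines: int
    n_samples: int
    per_line: np.ndarray | None = None  # (n_lines, n_samples), optional


def cell_profile(image, poly: Polygon, cell_id: int = -1,
                 channel_name: str = "other", n_lines: int = 180,
                 n_samples: int = 101, interpolation: str = "bilinear",
                 keep_per_line: bool = False, center=None) -> CellProfile:
    """Average radial profile over a fan of diameters through the centroid.

    Each line is sampled on the shared normalized grid r in [-1, 1]
    (boundary to boundary through the centroid at r = 0) and the per-line
    vectors are averaged pointwise.
    """
    if n_samples < 3 or n_samples % 2 == 0:
        raise GeometryError(f"n_samples must be odd and >= 3, got {n_samples}")
    if interpolation not in _INTERP_ORDER:
        raise GeometryError(f"unknown interpolation {interpolation!r}")
    px = image.pixels if hasattr(image, "pixels") else np.asarray(image, float)
    fan = make_line_fan(poly, center=center, n_lines=n_lines)
    grid = np.linspace(-1.0, 1.0, n_samples)
    u = np.stack([np.cos(fan.angles), np.sin(fan.angles)], axis=1)
    # physical distance from the centroid: r * r_pos for r >= 0, |r| * r_neg
    # for r < 0 (sign carried by r itself)
    scale = np.where(grid[None, :] >= 0,
                     fan.r_pos[:, None], fan.r_neg[:, None])  # (L, S)
    dist = grid[None, :] * scale
    xs = fan.center[0] + dist * u[:, 0:1]
    ys = fan.center[1] + dist * u[:, 1:2]
    _check_inside_image(xs, ys, px.shape)
    vals = map_coordinates(px, np.stack([ys.ravel(), xs.ravel()]),
                           order=_INTERP_ORDER[interpolation],
                           mode="nearest").reshape(n_lines, n_samples)
    return CellProfile(
        cell_id=cell_id, channel_name=channel_name, grid=grid,
        mean_intensity=vals.mean(axis=0), n_lines=n_lines,
        n_samples=n_samples, per_line=vals if keep_per_line else None)


@dataclass
class PopulationProfile:
    """Pointwise mean +/- sd of per-cell profiles within one group."""

    group: str
    grid: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n_cells: int


def population_profile(profiles, group: str) -> PopulationProfile:
    """Average per-cell profiles pointwise (sample sd; 0 for a single cell)."""
    if len(profiles) == 0:
        raise GeometryError("cannot average an empty list of profiles")
    grid = profiles[0].grid
    for p in profiles[1:]:
        if len(p.grid) != len(grid) or not np.allclose(p.grid, grid):
            raise GeometryError("profiles have mismatched grids")
    stack = np.stack([p.mean_intensity for p in profiles])
    sd = (np.zeros(len(grid)) if len(profiles) == 1
          else stack.std(axis=0, ddof=1))
    return PopulationProfile(group=group, grid=grid, mean=stack.mean(axis=0),
                             sd=sd, n_cells=len(profiles))


def region_mean_intensity(image, poly: Polygon) -> tuple[float, float]:
    """Mean intensity over pixels whose centers fall inside the polygon.

    Returns ``(mean, area)`` where area is the polygon's geometric area in
    pixel^2 (not the pixel count).
    """
    px = image.pixels if hasattr(image, "pixels") else np.asarray(image, float)
    h, w = px.shape
    minx, miny, maxx, maxy = poly.bounds()
    x0 = max(int(np.ceil(minx)), 0)
    x1 = min(int(np.floor(maxx)), w - 1)
    y0 = max(int(np.ceil(miny)), 0)
    y1 = min(int(np.floor(maxy)), h - 1)
    if x1 < x0 or y1 < y0:
        raise GeometryError("polygon encloses no pixel centers")
    xs, ys = np.meshgrid(np.arange(x0, x1 + 1), np.arange(y0, y1 + 1))
    inside = shapely.contains_xy(poly.shapely, xs.ravel(), ys.ravel())
    if not inside.any():
        raise GeometryError("polygon encloses no pixel centers")
    vals = px[y0:y1 + 1, x0:x1 + 1].ravel()[inside]
    return float(vals.mean()), float(poly.area)
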