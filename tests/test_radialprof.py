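"""Geometric core: polygon validity, ray casting, the line fan, profile
sampling and their invariants (flatness, equivariance, fan convergence)."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from memloc.errors import GeometryError
from memloc.radialprof import (CellProfile, Polygon, cell_profile,
                               make_line_fan, polygon_centroid,
                               population_profile, ray_boundary_distance,
                               region_mean_intensity, sample_line)

from conftest import clean_scene, make_cell

UNIT_SQUARE = [(0.0, 0.0), (1.0, 0.0), (1.0, 1.0), (0.0, 1.0)]


def circle_polygon(center, r, n=128):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return Polygon(np.column_stack([center[0] + r * np.cos(t),
                                    center[1] + r * np.sin(t)]))


class TestPolygon:
    def test_centroid_of_square_and_triangle(self):
        assert polygon_centroid(Polygon(UNIT_SQUARE)) == pytest.approx((0.5, 0.5))
        tri = Polygon([(0.0, 0.0), (3.0, 0.0), (0.0, 3.0)])
        assert polygon_centroid(tri) == pytest.approx((1.0, 1.0))

    def test_crescent_with_outside_centroid_rejected(self):
        # thin crescent: centroid falls in the concave void
        t = np.linspace(-0.75 * np.pi, 0.75 * np.pi, 40)
        outer = np.column_stack([10 * np.cos(t), 10 * np.sin(t)])
        inner = np.column_stack([9 * np.cos(t[::-1]), 9 * np.sin(t[::-1])])
        with pytest.raises(GeometryError):
            Polygon(np.vstack([outer, inner]))

    def test_self_intersection_rejected(self):
        with pytest.raises(GeometryError, match="self-intersect"):
            Polygon([(0, 0), (1, 1), (1, 0), (0, 1)])

    def test_too_few_distinct_vertices(self):
        with pytest.raises(GeometryError, match="3 distinct"):
            Polygon([(0, 0), (1, 0), (1, 0), (0, 0)])

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.integers(5, 40), st.integers(0, 10 ** 6))
    def test_random_star_polygons_validate_and_contain_centroid(self, n, seed):
        rng = np.random.default_rng(seed)
        # jittered regular angles keep the shape star-shaped about a
        # neighborhood of the generating center, not just the center itself
        t = 2 * np.pi * np.arange(n) / n + rng.uniform(0, np.pi / n, n)
        r = rng.uniform(10, 14, n)
        poly = Polygon(np.column_stack([50 + r * np.cos(t),
                                        50 + r * np.sin(t)]))
        cx, cy = poly.centroid
        assert poly.contains_point(cx, cy)


class TestRayCasting:
    def test_square_axis_and_diagonal(self):
        sq = Polygon([(-1, -1), (1, -1), (1, 1), (-1, 1)])
        assert ray_boundary_distance(sq, (0, 0), 0.0) == pytest.approx(1.0)
        assert ray_boundary_distance(sq, (0, 0), np.pi / 4) == pytest.approx(np.sqrt(2))

    def test_matches_dense_boundary_sampling_oracle(self, rng):
        poly = circle_polygon((0, 0), 10, n=24)  # coarse 24-gon
        # oracle: densely sample every edge and pick the boundary point
        # closest in direction to the ray
        v = poly.vertices
        frac = np.linspace(0, 1, 2000, endpoint=False)[:, None]
        pts = np.concatenate([v[i] + frac * (np.roll(v, -1, axis=0)[i] - v[i])
                              for i in range(len(v))])
        center = np.array([0.5, -0.3])
        vec = pts - center
        ang = np.arctan2(vec[:, 1], vec[:, 0])
        dist = np.linalg.norm(vec, axis=1)
        for angle in rng.uniform(0, 2 * np.pi, 20):
            d = ray_boundary_distance(poly, tuple(center), angle)
            dang = np.abs((ang - angle + np.pi) % (2 * np.pi) - np.pi)
            near = dist[dang < 2e-3]
            assert d == pytest.approx(near.min(), abs=0.02)

    def test_center_on_boundary_rejected(self):
        sq = Polygon(UNIT_SQUARE)
        with pytest.raises(GeometryError, match="inside"):
            ray_boundary_distance(sq, (0.0, 0.5), 0.0)


class TestLineFan:
    def test_equal_angular_spacing(self):
        sq = Polygon([(-1, -1), (1, -1), (1, 1), (-1, 1)])
        fan = make_line_fan(sq, n_lines=4)
        np.testing.assert_allclose(fan.angles,
                                   np.deg2rad([0, 45, 90, 135]))
        fan180 = make_line_fan(sq, n_lines=180)
        np.testing.assert_allclose(np.diff(fan180.angles), np.deg2rad(1.0))

    def test_circle_gives_equal_endpoint_distances(self):
        poly = circle_polygon((0, 0), 20, n=256)
        fan = make_line_fan(poly, n_lines=90)
        dists = np.concatenate([fan.r_pos, fan.r_neg])
        np.testing.assert_allclose(dists, 20.0, rtol=5e-3)

    def test_invalid_n_lines(self):
        with pytest.raises(GeometryError):
            make_line_fan(Polygon(UNIT_SQUARE), n_lines=0)


class TestSampleLine:
    def test_constant_image(self):
        img = np.full((20, 20), 7.0)
        vals = sample_line(img, (2, 3), (15, 12), 5)
        np.testing.assert_array_equal(vals, 7.0)

    def test_bilinear_exact_on_linear_field(self):
        # I(x, y) = x; bilinear interpolation is exact for linear fields
        img = np.tile(np.arange(16, dtype=float), (16, 1))
        vals = sample_line(img, (2.0, 5.0), (10.0, 5.0), 5)
        np.testing.assert_allclose(vals, [2, 4, 6, 8, 10])

    def test_even_n_samples_rejected(self):
        img = np.zeros((10, 10))
        with pytest.raises(GeometryError, match="odd"):
            sample_line(img, (1, 1), (8, 8), 4)

    def test_endpoint_outside_image_rejected(self):
        img = np.zeros((10, 10))
        with pytest.raises(GeometryError, match="outside"):
            sample_line(img, (1, 1), (12, 5), 5)


class TestCellProfile:
    def test_uniform_disk_phantom_is_flat(self):
        cell = make_cell(mem=80.0, cyto=80.0)  # uniform interior
        scene = clean_scene([cell])
        poly = cell.boundary_polygon()
        prof = cell_profile(scene.channels["fr1"], poly, n_lines=45)
        # outermost grid points touch the boundary where bilinear lookup
        # mixes with background pixels; interior points are exact
        np.testing.assert_allclose(prof.mean_intensity[3:-3], 130.0,
                                   rtol=1e-9)
        np.testing.assert_allclose(prof.mean_intensity, 130.0, rtol=0.35)

    def test_ring_phantom_band_structure(self):
        # shell = outer 10% of a radius-30 disk
        cell = make_cell(center=(64.0, 64.0), radius=30.0, shell=3.0,
                         cyto=80.0, mem=200.0)
        scene = clean_scene([cell], canvas=(128, 128))
        prof = cell_profile(scene.channels["fr1"], cell.boundary_polygon(),
                            n_lines=90, n_samples=101)
        r = prof.grid
        step = r[1] - r[0]
        # keep two grid steps clear of the cyto/shell transition and of the
        # outer boundary, where bilinear lookup straddles the edge
        mem_zone = (np.abs(r) >= 0.9 + 2 * step) & (np.abs(r) <= 1 - 2 * step)
        cyto_zone = np.abs(r) <= 0.9 - 2 * step
        np.testing.assert_allclose(prof.mean_intensity[mem_zone], 250.0,
                                   rtol=1.5e-2)
        np.testing.assert_allclose(prof.mean_intensity[cyto_zone], 130.0,
                                   rtol=1.5e-2)

    def test_profile_mean_equals_per_line_mean(self):
        cell = make_cell()
        scene = clean_scene([cell])
        prof = cell_profile(scene.channels["fr1"], cell.boundary_polygon(),
                            n_lines=30, keep_per_line=True)
        np.testing.assert_allclose(prof.mean_intensity,
                                   prof.per_line.mean(axis=0))

    def test_translation_equivariance_bit_identical(self):
        cell = make_cell(center=(40.0, 44.0))
        scene = clean_scene([cell], canvas=(128, 128))
        img = scene.channels["fr1"]
        poly = cell.boundary_polygon()
        shifted = np.roll(img, (7, 11), axis=(0, 1))  # dy=7, dx=11
        poly2 = Polygon(poly.vertices + np.array([11.0, 7.0]))
        a = cell_profile(img, poly, n_lines=45)
        b = cell_profile(shifted, poly2, n_lines=45)
        # equal to the last ulp modulo float associativity in the shifted
        # centroid/ray computation
        np.testing.assert_allclose(a.mean_intensity, b.mean_intensity,
                                   rtol=0, atol=1e-9)

    def test_rotation_by_90_degrees_equivariant(self):
        cell = make_cell(center=(48.0, 40.0), eccentricity=0.5,
                         orientation=0.4)
        scene = clean_scene([cell], canvas=(112, 96), psf_sigma=1.0)
        img = scene.channels["fr1"]
        h, w = img.shape
        rot = np.rot90(img, 1)  # (x, y) -> (y, w-1-x)
        verts = cell.boundary_polygon().vertices
        poly2 = Polygon(np.column_stack([verts[:, 1], w - 1 - verts[:, 0]]))
        a = cell_profile(img, cell.boundary_polygon(), n_lines=180)
        b = cell_profile(rot, poly2, n_lines=180)
        dyn = img.max() - img.min()
        assert np.max(np.abs(a.mean_intensity - b.mean_intensity)) < 0.01 * dyn

    def test_fan_convergence_is_monotone(self):
        cell = make_cell(eccentricity=0.4, orientation=0.7)
        scene = clean_scene([cell], psf_sigma=1.0)
        img = scene.channels["fr1"]
        poly = cell.boundary_polygon()
        p12, p45, p180 = (cell_profile(img, poly, n_lines=n).mean_intensity
                          for n in (12, 45, 180))
        assert np.max(np.abs(p45 - p180)) < np.max(np.abs(p12 - p45))

    def test_flatness_matches_region_mean_on_constant_image(self):
        img = np.full((96, 96), 41.0)
        poly = make_cell().boundary_polygon()
        prof = cell_profile(img, poly, n_lines=20)
        mean, _area = region_mean_intensity(img, poly)
        assert np.all(prof.mean_intensity == 41.0)
        assert mean == 41.0


class TestPopulationProfile:
    def make_profile(self, values, cell_id=0):
        values = np.asarray(values, dtype=float)
        return CellProfile(cell_id=cell_id, channel_name="fr1",
                           grid=np.linspace(-1, 1, len(values)),
                           mean_intensity=values, n_lines=1,
                           n_samples=len(values))

    def test_identical_profiles_have_zero_sd(self):
        p = self.make_profile([1.0, 2.0, 3.0])
        pop = population_profile([p, p], "g")
        np.testing.assert_array_equal(pop.mean, p.mean_intensity)
        np.testing.assert_array_equal(pop.sd, 0.0)

    def test_linearity_of_mean(self):
        f = np.array([1.0, 5.0, 2.0])
        c = 4.0
        pop = population_profile([self.make_profile(f),
                                  self.make_profile(-f + 2 * c)], "g")
        np.testing.assert_allclose(pop.mean, c)

    def test_single_profile_convention(self):
        p = self.make_profile([3.0, 1.0, 2.0])
        pop = population_profile([p], "g")
        np.testing.assert_array_equal(pop.mean, p.mean_intensity)
        np.testing.assert_array_equal(pop.sd, 0.0)
        assert pop.n_cells == 1

    def test_mismatched_grids_rejected(self):
        with pytest.raises(GeometryError, match="grid"):
            population_profile([self.make_profile([1, 2, 3]),
                                self.make_profile([1, 2, 3, 4, 5])], "g")


class TestRegionMean:
    def test_constant_image(self):
        img = np.full((32, 32), 7.0)
        mean, area = region_mean_intensity(img, Polygon(
            [(3.2, 4.1), (20.0, 5.0), (18.0, 25.0), (4.0, 22.0)]))
        assert mean == 7.0

    def test_axis_aligned_square(self):
        img = np.full((32, 32), 5.0)
        # square covering pixel centers 5..14 in both axes
        sq = Polygon([(4.5, 4.5), (14.5, 4.5), (14.5, 14.5), (4.5, 14.5)])
        mean, area = region_mean_intensity(img, sq)
        assert mean == 5.0
        assert area == pytest.approx(100.0)

    def test_half_bright_square_matches_pixel_counting(self):
        img = np.zeros((32, 32))
        img[:, 16:] = 10.0  # bright for x >= 16
        sq = Polygon([(10.5, 9.5), (21.5, 9.5), (21.5, 19.5), (10.5, 19.5)])
        mean, _ = region_mean_intensity(img, sq)
        # oracle: centers x in 11..21 -> 5 dark columns (11..15) and
        # 6 bright (16..21): mean = 6/11 * 10
        assert mean == pytest.approx(60.0 / 11.0)

    def test_zero_enclosed_centers_rejected(self):
        img = np.zeros((16, 16))
        tiny = Polygon([(3.1, 3.1), (3.4, 3.1), (3.4, 3.4), (3.1, 3.4)])
        with pytest.raises(GeometryError, match="pixel centers"):
            region_mean_intensity(img, tiny)
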