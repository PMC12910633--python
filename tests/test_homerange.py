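"""Kernel UDs, isopleths, minimum stable bandwidth, Bhattacharyya affinity."""

import numpy as np
import pytest

from sympatry import homerange as hr
from sympatry.raster import Raster


def _unit_variance_cloud(n=64, seed=0):
    pts = np.random.default_rng(seed).standard_normal((n, 2))
    return (pts - pts.mean(0)) / pts.std(0, ddof=1)


class TestReferenceBandwidth:
    def test_closed_form_unit_variance_n64(self):
        assert hr.reference_bandwidth(_unit_variance_cloud()) == pytest.approx(0.5)

    def test_scale_equivariance(self):
        pts = np.random.default_rng(1).normal(0, 3, (50, 2))
        assert hr.reference_bandwidth(pts * 10) == pytest.approx(
            10 * hr.reference_bandwidth(pts)
        )

    def test_monotone_decreasing_in_n(self):
        rng = np.random.default_rng(2)
        hs = []
        for n in (32, 128, 512):
            pts = rng.standard_normal((n, 2))
            pts = (pts - pts.mean(0)) / pts.std(0, ddof=1)
            hs.append(hr.reference_bandwidth(pts))
        assert hs[0] > hs[1] > hs[2]

    def test_zero_variance_rejected(self):
        with pytest.raises(hr.DegenerateDataError):
            hr.reference_bandwidth(np.zeros((10, 2)))


class TestEstimateUd:
    def test_single_point_peaks_at_its_cell(self):
        grid = Raster(np.zeros((21, 21)), x0=-105.0, y0=105.0, cell=10.0)
        ud = hr.estimate_ud(np.array([[0.0, 0.0]]), h=15.0, grid=grid)
        r, c = np.unravel_index(np.argmax(ud.mass), ud.mass.shape)
        assert (r, c) == (10, 10)
        assert ud.mass.sum() == pytest.approx(1.0, abs=1e-6)

    def test_bimodal_mass_split_tracks_cloud_sizes(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 30, (300, 2))
        b = rng.normal(0, 30, (100, 2)) + [5000, 0]
        pts = np.vstack([a, b])
        grid = hr.make_grid(pts, 100.0, cell=50.0)
        ud = hr.estimate_ud(pts, h=60.0, grid=grid)
        X, _ = ud.grid.cell_centres()
        left = ud.mass[X < 2500].sum()
        assert left == pytest.approx(0.75, abs=0.02)

    def test_normalisation_random_inputs(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            pts = rng.normal(0, 200, (rng.integers(10, 80), 2))
            grid = hr.make_grid(pts, hr.reference_bandwidth(pts))
            ud = hr.estimate_ud(pts, hr.reference_bandwidth(pts), grid)
            assert ud.mass.sum() == pytest.approx(1.0, abs=1e-6)

    def test_uncovered_grid_rejected(self):
        grid = Raster(np.zeros((5, 5)), x0=0.0, y0=50.0, cell=10.0)
        with pytest.raises(ValueError):
            hr.estimate_ud(np.array([[500.0, 0.0]]), h=5.0, grid=grid)

    def test_binned_matches_exact_shape(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(0, 100, (200, 2))
        grid = hr.make_grid(pts, 40.0, cell=10.0)
        exact = hr.estimate_ud(pts, 40.0, grid, method="exact")
        binned = hr.estimate_ud(pts, 40.0, grid, method="binned")
        assert np.abs(exact.mass - binned.mass).sum() < 0.05  # total variation


class TestIsopleth:
    def test_containment_50_in_95(self):
        rng = np.random.default_rng(6)
        pts = rng.normal(0, 100, (120, 2))
        grid = hr.make_grid(pts, 50.0)
        ud = hr.estimate_ud(pts, 50.0, grid)
        i50 = hr.isopleth(ud, 0.50)
        i95 = hr.isopleth(ud, 0.95)
        assert (i50.cells <= i95.cells).all()
        assert i50.mass >= 0.50 and i95.mass >= 0.95

    def test_unimodal_single_polygon(self):
        pts = np.random.default_rng(7).normal(0, 50, (200, 2))
        grid = hr.make_grid(pts, 60.0)
        ud = hr.estimate_ud(pts, 60.0, grid)
        assert hr.isopleth(ud, 0.50).n_polygons == 1
        assert hr.isopleth(ud, 0.95).n_polygons == 1

    def test_two_separated_modes_two_polygons(self):
        rng = np.random.default_rng(8)
        pts = np.vstack([rng.normal(0, 40, (150, 2)),
                         rng.normal(0, 40, (150, 2)) + [4000, 0]])
        grid = hr.make_grid(pts, 60.0, cell=40.0)
        ud = hr.estimate_ud(pts, 60.0, grid)
        assert hr.isopleth(ud, 0.95).n_polygons == 2

    def test_level_bounds(self):
        pts = np.random.default_rng(9).normal(0, 50, (30, 2))
        grid = hr.make_grid(pts, 30.0)
        ud = hr.estimate_ud(pts, 30.0, grid)
        for bad in (0.0, 1.0, -0.2, 1.3):
            with pytest.raises(ValueError):
                hr.isopleth(ud, bad)

    def test_polygon_count_matches_geometry(self):
        rng = np.random.default_rng(10)
        pts = np.vstack([rng.normal(0, 40, (100, 2)),
                         rng.normal(0, 40, (100, 2)) + [4000, 0]])
        grid = hr.make_grid(pts, 60.0, cell=40.0)
        iso = hr.isopleth(hr.estimate_ud(pts, 60.0, grid), 0.95)
        assert len(iso.polygons()) == iso.n_polygons


class TestMinStableBandwidth:
    def test_hmin_below_href_random_sets(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            pts = rng.normal(0, 100, (rng.integers(15, 60), 2))
            res = hr.min_stable_bandwidth(pts)
            assert res["h_min"] <= res["h_ref"] + 1e-12

    def test_definition_checks_out_on_two_clouds(self):
        rng = np.random.default_rng(12)
        pts = np.vstack([rng.normal(0, 60, (80, 2)),
                         rng.normal(0, 60, (80, 2)) + [2500, 0]])
        res = hr.min_stable_bandwidth(pts)
        grid = hr.make_grid(pts, res["h_ref"])
        n_ref = hr.isopleth(hr.estimate_ud(pts, res["h_ref"], grid), 0.95).n_polygons
        n_at = hr.isopleth(hr.estimate_ud(pts, res["h_min"], grid), 0.95).n_polygons
        assert n_at <= n_ref
        if not res["broken_at_href"] and any(b for _, b in res["trace"]):
            n_below = hr.isopleth(
                hr.estimate_ud(pts, res["h_min"] / 1.01, grid), 0.95
            ).n_polygons
            assert n_below > n_ref

    def test_deterministic(self):
        pts = np.random.default_rng(13).normal(0, 80, (40, 2))
        assert hr.min_stable_bandwidth(pts)["h_min"] == hr.min_stable_bandwidth(pts)["h_min"]


class TestBhattacharyya:
    @staticmethod
    def _ud(mass, x0=0.0):
        mass = np.atleast_2d(np.asarray(mass, float))
        grid = Raster(mass, x0=x0, y0=mass.shape[0] * 10.0, cell=10.0)
        return hr.UtilisationDistribution(grid=grid, h=10.0, n=1)

    def test_identity(self):
        rng = np.random.default_rng(14)
        m = rng.random((6, 6))
        m /= m.sum()
        assert hr.bhattacharyya_affinity(self._ud(m), self._ud(m)) == pytest.approx(1.0, abs=1e-6)

    def test_disjoint_supports(self):
        a = self._ud([[1.0, 0.0, 0.0]])
        b = self._ud([[0.0, 0.0, 1.0]])
        assert hr.bhattacharyya_affinity(a, b) == 0.0

    def test_half_overlap_hand_value(self):
        a = self._ud([[0.5, 0.5, 0.0]])
        b = self._ud([[0.0, 0.5, 0.5]])
        assert hr.bhattacharyya_affinity(a, b) == pytest.approx(0.5, abs=1e-12)

    def test_symmetry_and_range(self):
        rng = np.random.default_rng(15)
        for _ in range(10):
            a = rng.random((5, 5)); a /= a.sum()
            b = rng.random((5, 5)); b /= b.sum()
            ba1 = hr.bhattacharyya_affinity(self._ud(a), self._ud(b))
            ba2 = hr.bhattacharyya_affinity(self._ud(b), self._ud(a))
            assert ba1 == pytest.approx(ba2, abs=1e-12)
            assert 0.0 <= ba1 <= 1.0 + 1e-12

    def test_regrid_conserves_mass(self):
        rng = np.random.default_rng(16)
        m = rng.random((8, 8)); m /= m.sum()
        ud1 = self._ud(m)
        # same field on an offset, coarser grid fully covering the source
        grid2 = Raster(np.zeros((5, 5)), x0=-4.0, y0=82.0, cell=18.0)
        regridded = hr._regrid(ud1, grid2)
        assert regridded.sum() == pytest.approx(1.0, abs=1e-3)
        ud2 = hr.UtilisationDistribution(
            grid=Raster(regridded, grid2.x0, grid2.y0, grid2.cell), h=10.0, n=1
        )
        ba = hr.bhattacharyya_affinity(ud1, ud2)
        assert 0.9 < ba <= 1.0 + 1e-9
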