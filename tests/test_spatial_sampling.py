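import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Point, Polygon, box

import tiptempo as tt
from tiptempo.spatial_sampling import (KM_PER_DEG, Landscape,
                                       exclusivity_filter, grid_centroids,
                                       unproject)


@pytest.fixture
def landscape_3x3():
    return tt.synthetic_landscape(3, 3, ecoregion_size_km=150.0,
                                  habitat_rule="checkerboard", seed=0)


class TestProjection:
    def test_center_maps_to_origin(self):
        x, y = tt.project(-56.0, -15.0)
        assert x == pytest.approx(0.0, abs=1e-9)
        assert y == pytest.approx(0.0, abs=1e-9)

    def test_round_trip(self):
        rng = np.random.default_rng(1)
        lon = rng.uniform(-86, -34, 50)
        lat = rng.uniform(-56, 12, 50)
        lon2, lat2 = unproject(*tt.project(lon, lat))
        assert np.allclose(lon2, lon, atol=1e-6)
        assert np.allclose(lat2, lat, atol=1e-6)

    def test_equal_area_against_spherical_excess(self):
        # small spherical quadrilateral: projected area vs spherical area
        lon0, lat0, d = -60.0, -20.0, 0.5
        xs, ys = tt.project(np.array([lon0, lon0 + d, lon0 + d, lon0]),
                            np.array([lat0, lat0, lat0 + d, lat0 + d]))
        planar = Polygon(zip(xs, ys)).area
        R = 6371.0088
        spherical = (R**2 * np.radians(d)
                     * (np.sin(np.radians(lat0 + d)) - np.sin(np.radians(lat0))))
        assert planar == pytest.approx(spherical, rel=0.005)

    def test_invalid_latitude_rejected(self):
        with pytest.raises(ValueError):
            tt.project(0.0, 95.0)


class TestGridCentroids:
    def test_square_counting(self):
        poly = box(0, 0, 100, 100)
        pts = grid_centroids(poly, cell_width_km=25.0)
        assert len(pts) == 16

    def test_all_inside(self):
        poly = Point(30, 40).buffer(57.3)
        pts = grid_centroids(poly, cell_width_km=10.0)
        assert pts and all(poly.contains(p) for p in pts)

    def test_matches_brute_force_scan(self):
        poly = Polygon([(0, 0), (90, 10), (110, 80), (40, 100), (-10, 50)])
        h = 12.0
        pts = grid_centroids(poly, cell_width_km=h)
        minx, miny, _, _ = poly.bounds
        count = 0
        for i in range(30):
            for j in range(30):
                p = Point(minx + (i + 0.5) * h, miny + (j + 0.5) * h)
                if poly.contains(p):
                    count += 1
        assert len(pts) == count

    def test_bad_cell_width(self):
        with pytest.raises(ValueError):
            grid_centroids(box(0, 0, 1, 1), cell_width_km=0)


class TestSelectCoreEcotone:
    def test_counts_and_disjointness(self, landscape_3x3):
        pts = tt.select_core_ecotone(landscape_3x3, cell_width_km=20.0, k=10)
        assert len(pts) == 9 * 20
        for eid, grp in pts.groupby("ecoregion"):
            eco = set(grp[grp.position == "ecotone"].point_id)
            core = set(grp[grp.position == "core"].point_id)
            assert len(eco) == len(core) == 10
            assert not eco & core

    def test_core_points_are_innermost(self, landscape_3x3):
        pts = tt.select_core_ecotone(landscape_3x3, cell_width_km=20.0, k=4)
        grp = pts[pts.ecoregion == "E01_01"]
        poly = landscape_3x3.polygons["E01_01"]
        core_d = grp[grp.position == "core"]["boundary_dist_km"]
        eco_d = grp[grp.position == "ecotone"]["boundary_dist_km"]
        assert core_d.min() > eco_d.max()
        c = poly.centroid
        for r in grp[grp.position == "core"].itertuples():
            assert Point(r.x, r.y).distance(c) < 40

    def test_small_ecoregion_downscales_with_warning(self):
        land = tt.synthetic_landscape(2, 2, ecoregion_size_km=60.0, seed=1)
        with pytest.warns(UserWarning, match="candidates"):
            pts = tt.select_core_ecotone(land, cell_width_km=20.0, k=10)
        # 9 candidates per ecoregion -> floor(9/2) = 4 per class
        assert all(len(g) == 8 for _, g in pts.groupby("ecoregion"))

    def test_distance_is_true_boundary_distance(self, landscape_3x3):
        pts = tt.select_core_ecotone(landscape_3x3, cell_width_km=30.0, k=5)
        for r in pts.sample(10, random_state=0).itertuples():
            poly = landscape_3x3.polygons[r.ecoregion]
            assert r.boundary_dist_km == pytest.approx(
                poly.boundary.distance(Point(r.x, r.y)), abs=1e-9)


class TestBufferComposition:
    def test_brute_force_equivalence(self, landscape_3x3):
        pts = tt.select_core_ecotone(landscape_3x3, cell_width_km=30.0, k=3)
        species = [f"s{i}" for i in range(12)]
        ranges = tt.synthetic_ranges(species, landscape_3x3, seed=4)
        occ = tt.buffer_composition(pts, ranges, radius_km=10.0,
                                    exclusive=False)
        for r in pts.itertuples():
            disc = Point(r.x, r.y).buffer(10.0, quad_segs=32)
            for sp in occ.columns:
                assert bool(occ.loc[r.point_id, sp]) == disc.intersects(ranges[sp])

    def test_global_range_dropped_by_exclusivity(self, landscape_3x3):
        pts = tt.select_core_ecotone(landscape_3x3, cell_width_km=30.0, k=3)
        whole = box(-50, -50, 500, 500)
        occ = tt.buffer_composition(pts, {"wide": whole}, radius_km=10.0)
        assert "wide" not in occ.columns or not occ["wide"].any()
        occ_raw = tt.buffer_composition(pts, {"wide": whole}, radius_km=10.0,
                                        exclusive=False)
        assert occ_raw["wide"].all()

    def test_disjoint_range_absent(self, landscape_3x3):
        pts = tt.select_core_ecotone(landscape_3x3, cell_width_km=30.0, k=3)
        far = Point(5000, 5000).buffer(10)
        occ = tt.buffer_composition(pts, {"far": far}, radius_km=10.0,
                                    exclusive=False)
        assert not occ["far"].any()

    def test_exclusivity_idempotent(self, landscape_3x3):
        pts = tt.select_core_ecotone(landscape_3x3, cell_width_km=20.0, k=10)
        species = [f"s{i}" for i in range(20)]
        ranges = tt.synthetic_ranges(species, landscape_3x3, seed=8,
                                     placement_bias=0.7)
        occ = tt.buffer_composition(pts, ranges, radius_km=10.0,
                                    exclusive=False)
        once = exclusivity_filter(occ, pts)
        twice = exclusivity_filter(once, pts)
        pd.testing.assert_frame_equal(once, twice)

    def test_invalid_range_rejected(self, landscape_3x3):
        pts = tt.select_core_ecotone(landscape_3x3, cell_width_km=30.0, k=3)
        with pytest.raises(ValueError, match="invalid range"):
            tt.buffer_composition(pts, {"bad": Polygon()}, radius_km=10.0)


class TestSmallRangeFilter:
    def test_strict_threshold(self):
        areas = pd.Series({"a": 0.02, "b": 4.16, "c": 18.30})
        assert tt.small_range_filter(areas, 4.16) == ["a"]
        assert tt.small_range_filter(areas, 0.0) == []

    def test_missing_area_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            tt.small_range_filter(pd.Series({"a": 1.0, "b": np.nan}))

    def test_quartile_profile_retains_about_a_quarter(self):
        # right-skewed sizes with 1st quartile at the threshold
        rng = np.random.default_rng(0)
        areas = pd.Series(rng.lognormal(np.log(18.3), 1.6, 2000))
        q1 = np.quantile(areas, 0.25)
        kept = tt.small_range_filter(areas, q1)
        assert len(kept) / len(areas) == pytest.approx(0.25, abs=0.01)


class TestCovariateTable:
    def test_standardization_and_flags(self, landscape_3x3):
        pts = tt.select_core_ecotone(landscape_3x3, cell_width_km=20.0, k=5)
        cov = tt.covariate_table(pts, landscape_3x3)
        for col in ("neighbor_area_sum", "n_overlap_forest_neighbors",
                    "n_overlap_open_neighbors"):
            assert cov[col].mean() == pytest.approx(0.0, abs=1e-12)
            assert cov[col].std(ddof=1) == pytest.approx(1.0, abs=1e-12)
        assert cov["position"].cat.categories[0] == "core"
        assert cov["habitat"].cat.categories[0] == "open"
        assert set(cov.loc[cov["andes"] == 1].index) == set(
            pts[pts.ecoregion.str.endswith("_00")].point_id)

    def test_neighbor_area_sums_match_hand_computation(self):
        land = tt.synthetic_landscape(2, 2, ecoregion_size_km=100.0, seed=0)
        pts = tt.select_core_ecotone(land, cell_width_km=30.0, k=2)
        cov = tt.covariate_table(pts, land, standardize=False)
        cell_area = 100.0**2 / KM_PER_DEG**2
        # every corner ecoregion in a 2x2 grid has exactly 2 rook neighbors
        assert np.allclose(cov["neighbor_area_sum"], 2 * cell_area)

    def test_unknown_ecoregion_rejected(self, landscape_3x3):
        pts = tt.select_core_ecotone(landscape_3x3, cell_width_km=30.0, k=3)
        pts.loc[0, "ecoregion"] = "nope"
        with pytest.raises(KeyError):
            tt.covariate_table(pts, landscape_3x3)


class TestMoransI:
    def test_gradient_on_transect_has_strong_positive_i(self):
        n = 40
        xy = np.column_stack([np.arange(n, dtype=float), np.zeros(n)])
        i_obs, p = tt.morans_i(xy[:, 0], xy, n_perm=199, seed=1)
        assert i_obs > 0.5
        assert p <= 0.01
        i_knn, _ = tt.morans_i(xy[:, 0], xy, n_perm=9, seed=1,
                               weighting="knn", k_neighbors=2)
        assert i_knn > 0.95

    def test_random_values_near_null_expectation(self):
        rng = np.random.default_rng(5)
        xy = rng.uniform(0, 100, size=(200, 2))
        vals = rng.normal(size=200)
        i_obs, p = tt.morans_i(vals, xy, n_perm=99, seed=2)
        assert abs(i_obs - (-1 / 199)) < 0.05
        assert p > 0.01

    def test_matches_double_sum_oracle(self):
        rng = np.random.default_rng(9)
        xy = rng.uniform(0, 50, size=(20, 2))
        vals = rng.normal(size=20)
        i_obs, _ = tt.morans_i(vals, xy, n_perm=9, seed=0)
        # brute-force double sum with row-standardized inverse distance
        z = vals - vals.mean()
        num = den = s0 = 0.0
        W = np.zeros((20, 20))
        for i in range(20):
            for j in range(20):
                if i != j:
                    W[i, j] = 1.0 / np.hypot(*(xy[i] - xy[j]))
        W = W / W.sum(axis=1, keepdims=True)
        for i in range(20):
            den += z[i] ** 2
            for j in range(20):
                num += W[i, j] * z[i] * z[j]
                s0 += W[i, j]
        expected = len(vals) / s0 * num / den
        assert i_obs == pytest.approx(expected, abs=1e-12)

    def test_constant_values_rejected(self):
        xy = np.random.default_rng(0).uniform(0, 1, (12, 2))
        with pytest.raises(ValueError, match="constant"):
            tt.morans_i(np.ones(12), xy)


class TestLandscapeGeoJSON:
    def test_roundtrip(self, tmp_path, landscape_3x3):
        p = tmp_path / "land.geojson"
        landscape_3x3.to_geojson(str(p))
        back = Landscape.from_geojson(str(p))
        assert back.ids == landscape_3x3.ids
        assert back.habitat == landscape_3x3.habitat
        assert back.andes == landscape_3x3.andes
        for eid in back.ids:
            assert back.polygons[eid].equals(landscape_3x3.polygons[eid])

    def test_adjacency_matches_brute_force(self, landscape_3x3):
        adj = landscape_3x3.adjacency
        ids = landscape_3x3.ids
        for a in ids:
            for b in ids:
                if a == b:
                    continue
                shared = landscape_3x3.polygons[a].intersection(
                    landscape_3x3.polygons[b])
                assert (b in adj[a]) == (shared.length > 0)
        # corner ecoregion of a 3x3 grid has exactly 2 rook neighbors
        assert len(adj["E00_00"]) == 2


def test_boundary_grid_distance_mode_close_to_exact():
    land = tt.synthetic_landscape(2, 2, ecoregion_size_km=120.0, seed=0)
    exact = tt.select_core_ecotone(land, cell_width_km=20.0, k=5)
    grid = tt.select_core_ecotone(land, cell_width_km=20.0, k=5,
                                  dist_mode="boundary_grid")
    merged = exact.merge(grid, on="point_id", suffixes=("_e", "_g"))
    # sampled-vertex distances can only exceed the exact distance,
    # and by at most half the sampling step
    assert (merged.boundary_dist_km_g >= merged.boundary_dist_km_e - 1e-9).all()
    assert (merged.boundary_dist_km_g - merged.boundary_dist_km_e <= 10.0).all()
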