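import numpy as np
import pandas as pd
import pytest

import oracles
from conftest import make_raster, random_raster

from birdscape.landscape import (BufferError, MSPA_CORE, MSPA_EDGE,
                                 MSPA_ISLET, MSPA_PERFORATION,
                                 area_weighted_patch_size, composition,
                                 count_patches, extract_buffer, label_patches,
                                 metrics_timeseries, mspa_classify,
                                 proximity_index, summarize_metrics)
from birdscape.raster import FOREST, OTHER


def grid_of(n, fill=OTHER):
    return np.full((n, n), fill, dtype=np.int8)


# ---------------------------------------------------------------------------
# buffers


class TestExtractBuffer:
    def test_half_cell_radius_selects_single_cell(self):
        r = make_raster(grid_of(11))
        x, y = r.cell_center(5, 5)
        buf = extract_buffer(r, (x, y), r.cell_size / 2)
        assert buf.n_cells == 1

    def test_largest_admissible_radius_matches_oracle(self):
        # the radius cannot exceed the distance to the nearest raster
        # edge (clipped buffers are an error), so the largest admissible
        # circle from the centre is checked against the per-cell oracle
        r = make_raster(grid_of(9), cell_size=10.0)
        center = (45.0, 45.0)
        buf = extract_buffer(r, center, 45.0)
        assert buf.n_cells == oracles_count(r, center, 45.0)

    def test_count_matches_brute_force_at_400m(self):
        r = make_raster(grid_of(40))  # 1200 m across
        center = (600.0, 600.0)
        buf = extract_buffer(r, center, 400.0)
        assert buf.n_cells == oracles_count(r, center, 400.0)
        # area within one cell-ring of the continuous circle area
        expected = np.pi * 400.0**2 / 30.0**2
        ring = 2 * np.pi * 400.0 / 30.0
        assert abs(buf.n_cells - expected) <= ring

    def test_clipped_buffer_raises_with_stop_name(self):
        r = make_raster(grid_of(10))
        with pytest.raises(BufferError, match="stop S9"):
            extract_buffer(r, (20.0, 20.0), 100.0, stop_id="S9")


def oracles_count(r, center, radius):
    return len(oracles.buffer_cells(r, center, radius))


# ---------------------------------------------------------------------------
# patches & composition


class TestPatches:
    def test_single_cell_patch_area(self):
        g = grid_of(5)
        g[2, 2] = FOREST
        ps = label_patches(g == FOREST, 30.0)
        assert ps.n_patches == 1
        assert ps.areas_ha[0] == pytest.approx(0.09)

    def test_diagonal_cells_connectivity(self):
        g = grid_of(4)
        g[1, 1] = g[2, 2] = FOREST
        assert label_patches(g == FOREST, 30.0, connectivity=8).n_patches == 1
        assert label_patches(g == FOREST, 30.0, connectivity=4).n_patches == 2

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_labeling_matches_flood_fill_oracle(self, connectivity):
        rng = np.random.default_rng(3)
        g = (rng.random((50, 50)) < 0.5)
        ps = label_patches(g, 30.0, connectivity=connectivity)
        ours = {frozenset(map(tuple, np.argwhere(ps.labels == i + 1)))
                for i in range(ps.n_patches)}
        assert ours == set(oracles.flood_fill_label(g, connectivity))

    def test_empty_class_empty_patchset(self):
        ps = label_patches(grid_of(5) == FOREST, 30.0)
        assert ps.n_patches == 0
        assert area_weighted_patch_size(ps) == 0.0


class TestComposition:
    def test_all_forest(self):
        r = make_raster(grid_of(9, FOREST))
        buf = extract_buffer(r, (135.0, 135.0), 100.0)
        f, e = composition(buf)
        assert f == 100.0 and e == 0.0

    def test_checkerboard_half_forest(self):
        g = np.indices((20, 20)).sum(axis=0) % 2
        r = make_raster(g * FOREST)
        buf = extract_buffer(r, (300.0, 300.0), 290.0)
        f, _ = composition(buf)
        direct = 100.0 * sum(
            g[c] == 1 for c in oracles.buffer_cells(r, (300.0, 300.0), 290.0)
        ) / oracles_count(r, (300.0, 300.0), 290.0)
        assert f == pytest.approx(direct)
        assert f == pytest.approx(50.0, abs=2.0)


class TestAwpsAndCounts:
    def test_single_patch_awps_is_its_area(self):
        ps = _patchset([10.0])
        assert area_weighted_patch_size(ps) == pytest.approx(10.0)

    def test_awps_formula(self):
        assert area_weighted_patch_size(_patchset([1.0, 3.0])) == pytest.approx(2.5)

    def test_equal_patches_awps_invariant_to_count(self):
        for k in (1, 3, 7):
            assert area_weighted_patch_size(_patchset([2.5] * k)) == pytest.approx(2.5)

    def test_count_strict_inequality_at_045(self):
        # 5 cells at 30 m = exactly 0.45 ha -> not counted
        assert count_patches(_patchset([0.45])) == 0
        assert count_patches(_patchset([0.36, 0.54, 2.0])) == 2
        assert count_patches(_patchset([])) == 0


def _patchset(areas):
    from birdscape.landscape import PatchSet

    return PatchSet(labels=np.zeros((1, 1), dtype=int),
                    areas_ha=np.array(areas), cell_size=30.0)


# ---------------------------------------------------------------------------
# proximity


def _prox_setup(grid, stop_rc, cell=30.0):
    r = make_raster(grid, cell_size=cell)
    full = label_patches(r.grid == FOREST, cell)
    x, y = r.cell_center(*stop_rc)
    buf = extract_buffer(r, (x, y), cell * 3)
    return r, full, buf, (x, y)


class TestProximity:
    def test_isolated_patch_scores_zero(self):
        g = grid_of(40)
        g[18:22, 18:22] = FOREST
        r, full, buf, xy = _prox_setup(g, (20, 20))
        assert proximity_index(r, full, buf, xy) == 0.0

    def test_known_neighbor_distance_and_area(self):
        # focal cell at one corner; one ~100 ha neighbour square whose
        # nearest edge is h metres away -> index == area_m2 / h^2
        n = 80
        g = grid_of(n)
        g[40, 5] = FOREST  # focal single cell
        g[35:69, 39:72] = FOREST  # 34x33 = 1122 cells = 100.98 ha
        r, full, buf, xy = _prox_setup(g, (40, 5))
        got = proximity_index(r, full, buf, xy)
        h = (39 - 5) * 30.0
        expect = 1122 * 900.0 / h**2
        assert got == pytest.approx(expect, rel=1e-9)

    def test_doubling_area_doubles_index_when_distance_fixed(self):
        n = 90
        g1 = grid_of(n)
        g1[45, 5] = FOREST
        g1[10:44, 40:74] = FOREST  # 34x34
        g2 = g1.copy()
        g2[44:78, 40:74] = FOREST  # second identical block, same min distance
        r1, f1, b1, xy1 = _prox_setup(g1, (45, 5))
        r2, f2, b2, xy2 = _prox_setup(g2, (45, 5))
        p1 = proximity_index(r1, f1, b1, xy1)
        p2 = proximity_index(r2, f2, b2, xy2)
        assert p1 > 0
        assert p2 == pytest.approx(2 * p1, rel=0.35)

    def test_non_qualifying_patch_leaves_index_unchanged(self):
        n = 90
        g = grid_of(n)
        g[45, 5] = FOREST
        g[10:44, 40:74] = FOREST
        base = _prox_setup(g, (45, 5))
        p_base = proximity_index(*base[:3], base[3])
        g2 = g.copy()
        g2[80:83, 2:5] = FOREST  # tiny patch, far below 100 ha
        mod = _prox_setup(g2, (45, 5))
        assert proximity_index(*mod[:3], mod[3]) == pytest.approx(p_base)

    def test_no_forest_returns_zero(self):
        r, full, buf, xy = _prox_setup(grid_of(40), (20, 20))
        assert proximity_index(r, full, buf, xy) == 0.0

    def test_matches_brute_force_on_random_rasters(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            r = random_raster(rng, n=40, p_forest=0.55, smooth=1)
            full = label_patches(r.grid == FOREST, 30.0)
            stop_rc = (20 + rng.integers(-5, 5), 20 + rng.integers(-5, 5))
            xy = r.cell_center(*stop_rc)
            buf = extract_buffer(r, xy, 150.0)
            got = proximity_index(r, full, buf, xy,
                                  neighbor_min_area_ha=2.0,
                                  search_radius_m=600.0)
            want = oracles.proximity(r, xy, oracles.buffer_cells(r, xy, 150.0),
                                     neighbor_min_area_ha=2.0,
                                     search_radius_m=600.0)
            assert got == pytest.approx(want, rel=1e-9)


# ---------------------------------------------------------------------------
# morphological classes


class TestMspa:
    def test_5x5_block_core_and_edge(self):
        g = grid_of(9)
        g[2:7, 2:7] = FOREST
        cls = mspa_classify(g)
        assert (cls == MSPA_CORE).sum() == 9
        assert (cls == MSPA_EDGE).sum() == 16
        assert (cls == MSPA_PERFORATION).sum() == 0
        assert (cls == MSPA_ISLET).sum() == 0

    def test_2x2_patch_is_islet(self):
        g = grid_of(6)
        g[2:4, 2:4] = FOREST
        cls = mspa_classify(g)
        assert (cls == MSPA_ISLET).sum() == 4
        assert (cls > 0).sum() == 4

    def test_9x9_block_with_center_hole_has_perforation_ring(self):
        g = grid_of(13)
        g[2:11, 2:11] = FOREST
        g[6, 6] = OTHER
        cls = mspa_classify(g)
        want = oracles.mspa(g)
        assert np.array_equal(cls, want)
        # ring of 8 cells around the hole is perforation
        assert (cls == MSPA_PERFORATION).sum() == 8
        assert cls[5, 5] == MSPA_PERFORATION
        assert cls[2, 2] == MSPA_EDGE

    def test_partition_is_exact_on_random_rasters(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            r = random_raster(rng, n=40, p_forest=rng.uniform(0.3, 0.7),
                              smooth=rng.integers(0, 2))
            cls = mspa_classify(r)
            assert ((cls > 0) == (r.grid == FOREST)).all()

    def test_matches_oracle_on_random_rasters(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            r = random_raster(rng, n=30, p_forest=rng.uniform(0.3, 0.7),
                              smooth=1)
            assert np.array_equal(mspa_classify(r), oracles.mspa(r.grid))


# ---------------------------------------------------------------------------
# time series


class TestMetricsTimeseries:
    def _stops(self, r):
        return pd.DataFrame([
            {"stop": "A", "x": r.extent[2] / 2 - 100, "y": r.extent[3] / 2},
            {"stop": "B", "x": r.extent[2] / 2 + 100, "y": r.extent[3] / 2},
        ])

    def test_cardinality(self):
        rng = np.random.default_rng(8)
        rasters = [random_raster(rng, n=40, smooth=1) for _ in range(4)]
        for i, r in enumerate(rasters):
            r.date = 2000 + i
        table = metrics_timeseries(rasters, self._stops(rasters[0]),
                                   radii=(120.0, 240.0))
        assert len(table) == 2 * 2 * 4

    def test_constant_series_constant_metrics(self):
        rng = np.random.default_rng(9)
        base = random_raster(rng, n=40, smooth=1)
        rasters = []
        for i in range(3):
            r = make_raster(base.grid.copy())
            r.date = 2000 + i
            rasters.append(r)
        table = metrics_timeseries(rasters, self._stops(base), radii=(150.0,))
        for _, grp in table.groupby("stop"):
            assert grp.drop(columns="date").round(9).nunique().max() == 1

    def test_records_match_single_op_recomputation(self):
        rng = np.random.default_rng(10)
        r = random_raster(rng, n=40, p_forest=0.55, smooth=1)
        stops = self._stops(r)
        table = metrics_timeseries([r], stops, radii=(150.0,))
        full = label_patches(r.grid == FOREST, r.cell_size)
        cls = mspa_classify(r)
        for _, row in table.iterrows():
            s = stops[stops["stop"] == row["stop"]].iloc[0]
            buf = extract_buffer(r, (s["x"], s["y"]), row["radius_m"])
            f, e = composition(buf)
            assert row["forest_pct"] == pytest.approx(f)
            assert row["exurban_pct"] == pytest.approx(e)
            clipped = label_patches(buf.masked_class(FOREST), r.cell_size)
            assert row["awps_ha"] == pytest.approx(
                area_weighted_patch_size(clipped))
            assert row["n_patches_gt_045ha"] == count_patches(clipped)
            assert row["proximity_index"] == pytest.approx(
                proximity_index(r, full, buf, (s["x"], s["y"])))

    def test_mspa_partition_invariant_per_record(self):
        rng = np.random.default_rng(12)
        r = random_raster(rng, n=40, p_forest=0.5, smooth=1)
        table = metrics_timeseries([r], self._stops(r), radii=(150.0,))
        for _, row in table.iterrows():
            total = (row["core_pct"] + row["islet_pct"] + row["edge_pct"]
                     + row["residual_pct"])
            assert total == pytest.approx(row["forest_pct"], abs=1e-9)

    def test_summary_mean_sd(self):
        df = pd.DataFrame({
            "stop": ["A", "B"], "radius_m": [150.0] * 2, "date": [2000] * 2,
            **{c: [1.0, 3.0] for c in
               ["forest_pct", "exurban_pct", "core_pct", "islet_pct",
                "edge_pct", "residual_pct", "awps_ha", "n_patches_gt_045ha",
                "proximity_index"]},
        })
        s = summarize_metrics(df)
        assert s["forest_pct_mean"].iloc[0] == pytest.approx(2.0)
        assert s["forest_pct_std"].iloc[0] == pytest.approx(np.sqrt(2.0))


def test_awps_between_min_and_max_patch_area():
    rng = np.random.default_rng(13)
    for _ in range(20):
        areas = rng.uniform(0.1, 20.0, rng.integers(1, 10))
        v = area_weighted_patch_size(_patchset(list(areas)))
        assert areas.min() - 1e-12 <= v <= areas.max() + 1e-12


def test_class_grid_written_in_ascii_grid_format(tmp_path):
    from birdscape.landscape import write_class_grid
    from birdscape.raster import read_ascii_grid

    g = grid_of(9)
    g[2:7, 2:7] = FOREST
    cls = mspa_classify(g)
    path = tmp_path / "mspa.asc"
    write_class_grid(cls, path)
    header = path.read_text().splitlines()[:6]
    assert header[0].startswith("ncols") and header[4].startswith("cellsize")
    body = np.loadtxt(path, skiprows=6)
    assert np.array_equal(body, cls)
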