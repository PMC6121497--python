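import math

import numpy as np
import pytest

from hrulci.grids import CategoricalGrid
from hrulci.metrics import (
    adjacency_table,
    ai,
    AdjacencyTable,
    awmsi,
    enn_mn,
    iji,
    label_patches,
    lsi,
    metric_report,
    np_pd_lpi,
    patch_geometry,
    _max_like_adjacencies,
)

from _oracles import (
    bf_enn_mn,
    bf_label_patches,
    bf_like_adjacencies,
    bf_pair_edges,
    bf_patch_perimeter,
)


def cat(codes, cell=30.0, mask=None):
    codes = np.asarray(codes)
    if mask is None:
        mask = np.zeros(codes.shape, bool)
    return CategoricalGrid(codes, mask, cell)


def landscape_area(grid):
    return int((~grid.nodata_mask).sum()) * grid.cell_size ** 2


class TestPatches:
    def test_hand_traced_three_patches(self, worked_grid):
        ps = label_patches(worked_grid, connectivity=4)
        assert sorted(p.n_cells for p in ps.patches) == [3, 3, 3]

    def test_uniform_grid_single_patch(self):
        ps = label_patches(cat(np.ones((5, 5), int)))
        assert len(ps) == 1 and ps.patches[0].n_cells == 25

    def test_diagonal_connectivity_definition(self):
        codes = np.array([[1, 2], [2, 1]])
        assert len([p for p in label_patches(cat(codes), 4).patches if p.class_code == 1]) == 2
        assert len([p for p in label_patches(cat(codes), 8).patches if p.class_code == 1]) == 1

    def test_nodata_cells_belong_to_no_patch(self):
        mask = np.array([[False, True], [False, False]])
        ps = label_patches(cat([[1, 1], [1, 1]], mask=mask))
        assert sum(p.n_cells for p in ps.patches) == 3

    @pytest.mark.parametrize("connectivity", [4, 8])
    @pytest.mark.parametrize("seed", range(5))
    def test_partition_matches_flood_fill(self, random_categorical, seed, connectivity):
        g = random_categorical(seed, shape=(12, 12), nodata_frac=0.1)
        ps = label_patches(g, connectivity)
        ref = bf_label_patches(g.codes, ~g.nodata_mask, connectivity)
        assert len(ps) == ref.max()
        # identical partitions up to relabelling
        for p in ps.patches:
            ref_ids = {ref[r, c] for r, c in p.cells}
            assert len(ref_ids) == 1


class TestGeometry:
    def test_single_cell(self):
        ps = label_patches(cat([[1]]))
        geom = patch_geometry(ps)
        assert geom.loc[0, "area_m2"] == 900.0
        assert geom.loc[0, "perimeter_m"] == 120.0

    def test_square_patch(self):
        codes = np.full((4, 4), 2)
        codes[1:3, 1:3] = 1
        ps = label_patches(cat(codes))
        geom = patch_geometry(ps).set_index("class_code")
        assert geom.loc[1, "area_m2"] == 3600.0
        assert geom.loc[1, "perimeter_m"] == 240.0

    @pytest.mark.parametrize("seed", range(5))
    def test_perimeters_match_edge_enumeration(self, random_categorical, seed):
        g = random_categorical(seed, shape=(10, 10), nodata_frac=0.1)
        ps = label_patches(g)
        geom = patch_geometry(ps).set_index("patch_id")
        for p in ps.patches:
            expect = bf_patch_perimeter(ps.label_grid, p.patch_id) * g.cell_size
            assert geom.loc[p.patch_id, "perimeter_m"] == expect


class TestComposition:
    def test_uniform(self):
        ps = label_patches(cat(np.ones((5, 5), int)))
        n, _, lpi = np_pd_lpi(ps, 25 * 900.0)
        assert n == 1 and lpi == 100.0

    def test_worked_grid_lpi(self, worked_grid):
        ps = label_patches(worked_grid, connectivity=4)
        n, _, lpi = np_pd_lpi(ps, landscape_area(worked_grid))
        assert n == 3
        assert lpi == pytest.approx(100 * 3 / 9)

    def test_pd_unit_definition(self):
        # one patch on exactly 100 ha -> PD = 1.0 per 100 ha
        ps = label_patches(cat(np.ones((10, 10), int), cell=100.0))  # 10000 m2/cell * 100
        n, pd_val, _ = np_pd_lpi(ps, 100 * 100.0 ** 2)
        assert n == 1 and pd_val == pytest.approx(1.0)

    def test_zero_area_rejected(self):
        ps = label_patches(cat([[1]]))
        with pytest.raises(ValueError):
            np_pd_lpi(ps, 0.0)


class TestShape:
    def test_one_class_landscape_has_no_edge(self):
        g = cat(np.ones((6, 6), int))
        assert lsi(label_patches(g), landscape_area(g)) == 0.0

    def test_interior_square_patch_edge(self):
        codes = np.full((10, 10), 2)
        codes[4:6, 4:6] = 1
        g = cat(codes)
        val = lsi(label_patches(g), landscape_area(g))
        # both the island and the background hole contribute 4*s*cell each
        e = 2 * 4 * 2 * 30.0
        assert val == pytest.approx(e / (2 * math.sqrt(math.pi * landscape_area(g))))

    @pytest.mark.parametrize("seed", range(5))
    def test_formula_from_oracle_perimeters(self, random_categorical, seed):
        g = random_categorical(seed, shape=(12, 12), n_classes=3)
        ps = label_patches(g)
        total = sum(bf_patch_perimeter(ps.label_grid, p.patch_id) for p in ps.patches)
        border = 4 * 12  # all border cells valid here
        e = (total - border) * g.cell_size
        assert lsi(ps, landscape_area(g)) == pytest.approx(
            e / (2 * math.sqrt(math.pi * landscape_area(g))))

    def test_square_patch_shape_index_is_one(self):
        assert awmsi(label_patches(cat(np.ones((4, 4), int)))) == pytest.approx(1.0)

    def test_rectangle_shape_index(self):
        assert awmsi(label_patches(cat([[1, 1, 1, 1]]))) == pytest.approx(1.25)

    def test_area_weighting(self):
        # 1x4 rectangle (class 1) over a 4x4 square (class 2), disjoint rows
        codes = np.vstack([np.full((1, 4), 1), np.full((4, 4), 2)])
        ps = label_patches(cat(codes))
        shapes = {1: 1.25, 2: 1.0}
        weights = {1: 4 / 20, 2: 16 / 20}
        expect = sum(shapes[c] * weights[c] for c in shapes)
        assert awmsi(ps) == pytest.approx(expect)

    def test_empty_patchset_rejected(self):
        g = cat([[1]], mask=np.array([[True]]))
        with pytest.raises(ValueError):
            awmsi(label_patches(g))


class TestEnn:
    def test_single_pair(self):
        # class-1 patches at columns 0 and 3 (3 cells apart); the class-2
        # run between them is a single patch, so it is excluded
        codes = np.array([[1, 2, 2, 1]])
        assert enn_mn(label_patches(cat(codes), 4)) == pytest.approx(90.0)

    def test_not_available_without_repeats(self):
        g = cat([[1, 2], [3, 4]])
        assert math.isnan(enn_mn(label_patches(g)))

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_all_pairs_brute_force(self, random_categorical, seed):
        g = random_categorical(seed, shape=(8, 8), n_classes=3)
        ps = label_patches(g)
        ref = bf_enn_mn(ps.label_grid, ps.class_of_patch, g.cell_size)
        got = enn_mn(ps)
        if math.isnan(ref):
            assert math.isnan(got)
        else:
            assert got == pytest.approx(ref)


class TestIji:
    @staticmethod
    def table(codes, matrix):
        m = np.asarray(matrix, dtype=float)
        full = np.zeros((len(codes) + 1, len(codes) + 1))
        full[1:, 1:] = m
        return AdjacencyTable(list(codes), full)

    def test_equal_pairs_maximum_entropy(self):
        m = [[0, 5, 5], [5, 0, 5], [5, 5, 0]]
        assert iji(self.table([1, 2, 3], m)) == pytest.approx(100.0)

    def test_single_adjacent_pair(self):
        m = [[0, 7, 0], [7, 0, 0], [0, 0, 0]]
        assert iji(self.table([1, 2, 3], m)) == pytest.approx(0.0)

    def test_two_classes_not_available(self):
        assert math.isnan(iji(self.table([1, 2], [[0, 3], [3, 0]])))

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_oracle_adjacency(self, random_categorical, seed):
        g = random_categorical(seed, shape=(10, 10), n_classes=4)
        codes_present = sorted(np.unique(g.codes))
        pair_e = {}
        for i, a in enumerate(codes_present):
            for b in codes_present[i + 1:]:
                pair_e[(a, b)] = bf_pair_edges(g.codes, ~g.nodata_mask, a, b) * g.cell_size
        e_total = sum(pair_e.values())
        terms = [e / e_total for e in pair_e.values() if e > 0]
        t = len(codes_present)
        expect = -sum(f * math.log(f) for f in terms) / math.log(t * (t - 1) / 2) * 100
        assert iji(adjacency_table(g)) == pytest.approx(expect)


class TestAi:
    def test_solid_rectangle_is_100(self):
        per_class, landscape = ai(cat(np.ones((5, 8), int)))
        assert per_class[1] == pytest.approx(100.0)
        assert landscape == pytest.approx(100.0)

    def test_checkerboard_is_0(self):
        codes = np.indices((8, 8)).sum(axis=0) % 2 + 1
        per_class, landscape = ai(cat(codes))
        assert per_class[1] == 0.0 and per_class[2] == 0.0 and landscape == 0.0

    def test_single_cell_class_fully_aggregated(self):
        codes = np.ones((4, 4), int)
        codes[0, 0] = 2
        per_class, _ = ai(cat(codes))
        assert per_class[2] == 100.0

    @pytest.mark.parametrize("seed", range(5))
    def test_like_adjacencies_match_brute_force(self, random_categorical, seed):
        g = random_categorical(seed, shape=(10, 10), nodata_frac=0.1)
        per_class, _ = ai(g)
        for code in np.unique(g.codes[~g.nodata_mask]):
            gii = bf_like_adjacencies(g.codes, ~g.nodata_mask, code)
            n = int(((g.codes == code) & ~g.nodata_mask).sum())
            gmax = _max_like_adjacencies(n)
            expect = 100.0 if gmax == 0 else 100.0 * gii / gmax
            assert per_class[int(code)] == pytest.approx(expect)


class TestReport:
    def test_uniform_grid_report(self):
        rep = metric_report(cat(np.ones((5, 5), int))).set_index("metric")
        land = rep[rep["level"] == "landscape"]["value"]
        assert land["NP"] == 1 and land["LPI"] == 100.0
        assert land["LSI"] == 0.0 and land["AI"] == 100.0
        assert math.isnan(land["ENN_MN"]) and math.isnan(land["IJI"])

    def test_report_consistent_with_operations(self, worked_grid):
        rep = metric_report(worked_grid, connectivity=4)
        land = rep[rep["level"] == "landscape"].set_index("metric")["value"]
        ps = label_patches(worked_grid, connectivity=4)
        area = landscape_area(worked_grid)
        n, pd_val, lpi_val = np_pd_lpi(ps, area)
        assert land["NP"] == n and land["PD"] == pytest.approx(pd_val)
        assert land["LPI"] == pytest.approx(lpi_val)
        assert land["LSI"] == pytest.approx(lsi(ps, area))
        assert land["AWMSI"] == pytest.approx(awmsi(ps))

    def test_csv_round_trip(self, tmp_path, worked_grid):
        import pandas as pd

        rep = metric_report(worked_grid)
        path = tmp_path / "metrics.csv"
        rep.to_csv(path, index=False)
        back = pd.read_csv(path)
        assert np.allclose(back["value"].to_numpy(), rep["value"].to_numpy(), equal_nan=True)


class TestInvariants:
    @pytest.mark.parametrize("seed", range(8))
    def test_patch_areas_partition_landscape(self, random_categorical, seed):
        g = random_categorical(seed, shape=(14, 14), nodata_frac=0.15)
        ps = label_patches(g)
        assert sum(p.n_cells for p in ps.patches) == int((~g.nodata_mask).sum())

    @pytest.mark.parametrize("seed", range(8))
    def test_metric_ranges(self, random_categorical, seed):
        g = random_categorical(seed, shape=(12, 12))
        ps = label_patches(g)
        area = landscape_area(g)
        _, _, lpi_val = np_pd_lpi(ps, area)
        per_class, land_ai = ai(g)
        assert 0 <= lpi_val <= 100
        assert all(0 <= v <= 100 for v in per_class.values()) and 0 <= land_ai <= 100
        assert awmsi(ps) >= 1.0 - 1e-12
        assert lsi(ps, area) >= 0
        v = iji(adjacency_table(g))
        assert math.isnan(v) or 0 <= v <= 100 + 1e-9

    def test_filling_gap_never_increases_np_or_decreases_ai(self):
        codes = np.full((6, 6), 2)
        codes[1, 1] = codes[1, 3] = 1  # two class-1 patches with a gap at (1,2)
        before_np = len([p for p in label_patches(cat(codes)).patches if p.class_code == 1])
        before_ai = ai(cat(codes))[0][1]
        codes2 = codes.copy()
        codes2[1, 2] = 1
        after_np = len([p for p in label_patches(cat(codes2)).patches if p.class_code == 1])
        after_ai = ai(cat(codes2))[0][1]
        assert after_np <= before_np
        assert after_ai >= before_ai
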