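"""Reference grid, presence assembly and the twelve cell scores."""

import numpy as np
import pandas as pd
import pytest

from expdiv.phylo import Phylogeny
from expdiv.spatial import (
    assemble_presence,
    build_reference_grid,
    gexp_pd,
    hotspots,
    lexp_pd,
    pd_cell_scores,
    phylogenetic_endemism,
    proportion_map,
    range_sizes,
    species_cell_scores,
    top_set_richness,
    write_presence_csv,
    read_presence_csv,
    EqualAreaGrid,
)
from expdiv.species_scores import expected_pd, hedge_scores, ledge_scores

from conftest import random_phylogeny


def small_grid(n_rows=2, n_cols=2) -> EqualAreaGrid:
    """A tiny grid for worked examples; projection params are irrelevant."""
    return EqualAreaGrid(
        cell_size_km=100.0, standard_parallel=30.0, lat_max=10.0, lat_min=-10.0,
        n_rows=n_rows, n_cols=n_cols,
    )


@pytest.fixture
def t3():
    return Phylogeny.from_newick("((A:1,B:1):1,C:2);")


def risk_table(rows):
    return pd.DataFrame(rows, columns=["species", "category", "range_size"])


class TestReferenceGrid:
    def test_study_grid_dimensions(self):
        grid = build_reference_grid(96.5, 30.0, 90.0, -60.0)
        assert (grid.n_cols, grid.n_rows) == (360, 142)
        assert grid.n_cells == 51120

    def test_single_row_when_cell_spans_band(self):
        ref = build_reference_grid(96.5, 30.0, 90.0, -60.0)
        band_height = ref.y_of_lat(90.0) - ref.y_of_lat(-60.0)
        grid = build_reference_grid(band_height, 30.0, 90.0, -60.0)
        assert grid.n_rows == 1

    def test_equal_cell_areas(self):
        grid = build_reference_grid(96.5, 30.0, 90.0, -60.0)
        for cid in (0, 51119, 12345):
            x0, y0, x1, y1 = grid.cell_bounds(cid)
            assert (x1 - x0) * (y1 - y0) == pytest.approx(grid.cell_area_km2)

    def test_degenerate_extent_rejected(self):
        with pytest.raises(ValueError):
            build_reference_grid(96.5, 30.0, -60.0, 90.0)
        with pytest.raises(ValueError):
            build_reference_grid(-1.0, 30.0, 90.0, -60.0)

    def test_rowcol_roundtrip(self):
        grid = build_reference_grid(96.5, 30.0, 90.0, -60.0)
        assert grid.cell_id(*grid.rowcol(12345)) == 12345


class TestPresence:
    def test_basic_assembly(self):
        grid = small_grid()
        pm = assemble_presence(grid, [("A", 0), ("A", 1)])
        assert pm.matrix.nnz == 2

    def test_duplicates_collapsed(self):
        grid = small_grid()
        pm = assemble_presence(grid, [("A", 0), ("A", 0), ("A", 0)])
        assert pm.matrix.nnz == 1
        assert pm.matrix[0, 0] == 1.0

    def test_out_of_grid_rejected(self):
        with pytest.raises(ValueError):
            assemble_presence(small_grid(), [("A", 99)])

    def test_triplet_table_row_major(self):
        grid = small_grid(2, 3)
        df = pd.DataFrame({"species": ["A"], "row": [1], "col": [2]})
        pm = assemble_presence(grid, df)
        assert pm.matrix[5, 0] == 1.0

    def test_triplet_out_of_bounds(self):
        df = pd.DataFrame({"species": ["A"], "row": [5], "col": [0]})
        with pytest.raises(ValueError):
            assemble_presence(small_grid(), df)

    def test_zero_range_species_retained(self):
        pm = assemble_presence(small_grid(), [("A", 0)], species=["A", "B"])
        rs = range_sizes(pm)
        assert rs["B"] == 0 and rs["A"] == 1

    def test_csv_roundtrip(self, tmp_path):
        grid = small_grid(3, 3)
        pm = assemble_presence(grid, [("A", 0), ("A", 4), ("B", 8)])
        path = tmp_path / "presence.csv"
        write_presence_csv(pm, path)
        back = read_presence_csv(path, grid, species=list(pm.species))
        assert (back.matrix != pm.matrix).nnz == 0

    def test_range_sizes_median(self):
        grid = small_grid(2, 2)
        pm = assemble_presence(
            grid, [("A", 0), ("B", 0), ("B", 1), ("C", 0), ("C", 1), ("C", 2)]
        )
        rs = range_sizes(pm)
        assert rs.tolist() == [1, 2, 3]
        assert rs.median() == 2


class TestSpeciesCellScores:
    def test_worked_swr(self):
        # 2-cell grid: A in cell0, B in both, C in cell1
        grid = small_grid(1, 2)
        pm = assemble_presence(grid, [("A", 0), ("B", 0), ("B", 1), ("C", 1)])
        risk = risk_table([("A", "CR", 1), ("B", "LC", 2), ("C", "LC", 1)])
        out = species_cell_scores(pm, risk)
        assert out.loc[0, "SWR"] == pytest.approx(1.0 + 0.5)
        assert out.loc[0, "SR"] == 2
        assert out.loc[0, "TSR"] == 1  # only A threatened

    def test_empty_cell_all_zero(self, t3):
        grid = small_grid(2, 2)
        pm = assemble_presence(grid, [("A", 0)], species=["A", "B", "C"])
        risk = risk_table([("A", "LC", 1), ("B", "LC", 0), ("C", "LC", 0)])
        out = species_cell_scores(pm, risk)
        assert (out.loc[3] == 0).all()

    def test_single_endemic_swr_one(self):
        grid = small_grid()
        pm = assemble_presence(grid, [("A", 2)])
        risk = risk_table([("A", "LC", 1)])
        assert species_cell_scores(pm, risk).loc[2, "SWR"] == pytest.approx(1.0)

    def test_rarity_strictly_below_median(self):
        grid = small_grid(1, 4)
        pm = assemble_presence(
            grid,
            [("A", 0), ("B", 0), ("B", 1), ("C", 0), ("C", 1), ("C", 2)],
        )
        # ranges 1,2,3 -> median 2; only A (range 1) is rare
        risk = risk_table([("A", "LC", 1), ("B", "LC", 2), ("C", "LC", 3)])
        out = species_cell_scores(pm, risk)
        assert out.loc[0, "RSR"] == 1

    def test_missing_species_keyerror(self):
        pm = assemble_presence(small_grid(), [("A", 0)])
        with pytest.raises(KeyError):
            species_cell_scores(pm, risk_table([("B", "LC", 1)]))

    def test_dd_rejected(self):
        pm = assemble_presence(small_grid(), [("A", 0)])
        with pytest.raises(ValueError, match="DD"):
            species_cell_scores(pm, risk_table([("A", "DD", 1)]))

    def test_swr_sums_to_occurring_species_count(self):
        rng = np.random.default_rng(8)
        grid = small_grid(6, 6)
        pairs = [
            (f"s{j}", int(c))
            for j in range(30)
            for c in rng.choice(36, size=rng.integers(1, 8), replace=False)
        ]
        pm = assemble_presence(grid, pairs)
        risk = risk_table([(sp, "LC", 1) for sp in pm.species])
        out = species_cell_scores(pm, risk)
        assert out["SWR"].sum() == pytest.approx(pm.n_species, abs=1e-9)


class TestPDCellScores:
    def test_full_cell_pd_is_tree_length(self, t3):
        grid = small_grid(1, 2)
        pm = assemble_presence(grid, [("A", 0), ("B", 0), ("C", 0)])
        risk = risk_table([("A", "LC", 1), ("B", "LC", 1), ("C", "LC", 1)])
        out = pd_cell_scores(pm, t3, risk)
        assert out.loc[0, "PD"] == pytest.approx(5.0)

    def test_single_species_cell_root_path(self, t3):
        grid = small_grid(1, 2)
        pm = assemble_presence(grid, [("A", 0)], species=["A", "B", "C"])
        risk = risk_table([("A", "LC", 1), ("B", "LC", 0), ("C", "LC", 0)])
        out = pd_cell_scores(pm, t3, risk)
        assert out.loc[0, "PD"] == pytest.approx(2.0)

    def test_no_threatened_means_zero_tpd(self, t3):
        grid = small_grid(1, 2)
        pm = assemble_presence(grid, [("A", 0), ("B", 0), ("C", 1)])
        risk = risk_table([("A", "LC", 1), ("B", "NT", 1), ("C", "LC", 1)])
        out = pd_cell_scores(pm, t3, risk)
        assert (out["TPD"] == 0).all()

    def test_subscores_bounded_by_pd(self, t3):
        grid = small_grid(2, 2)
        pm = assemble_presence(grid, [("A", 0), ("B", 1), ("C", 1), ("A", 3)])
        risk = risk_table([("A", "CR", 2), ("B", "LC", 1), ("C", "EN", 1)])
        out = pd_cell_scores(pm, t3, risk)
        sp_out = species_cell_scores(pm, risk)
        assert (out["TPD"] <= out["PD"] + 1e-12).all()
        assert (out["RPD"] <= out["PD"] + 1e-12).all()
        assert (sp_out["TSR"] <= sp_out["SR"]).all()
        assert (sp_out["RSR"] <= sp_out["SR"]).all()

    def test_species_off_tree_keyerror(self, t3):
        pm = assemble_presence(small_grid(), [("Z", 0)])
        risk = risk_table([("Z", "LC", 1)])
        with pytest.raises(KeyError):
            pd_cell_scores(pm, t3, risk)


class TestPhylogeneticEndemism:
    def test_all_in_one_cell_gets_total_pd(self, t3):
        grid = small_grid(1, 2)
        pm = assemble_presence(grid, [("A", 0), ("B", 0), ("C", 0)])
        out = phylogenetic_endemism(pm, t3)
        assert out.loc[0, "PWR"] == pytest.approx(5.0)

    def test_worked_two_cell_example(self, t3):
        # A in cell0, B in both, C in cell1
        grid = small_grid(1, 2)
        pm = assemble_presence(grid, [("A", 0), ("B", 0), ("B", 1), ("C", 1)])
        out = phylogenetic_endemism(pm, t3)
        # cell0: brA 1/1 + brB 1/2 + brAB 1/2 = 2.0
        # cell1: brB 1/2 + brAB 1/2 + brC 2/1 = 3.0
        assert out.loc[0, "PWR"] == pytest.approx(2.0)
        assert out.loc[1, "PWR"] == pytest.approx(3.0)
        assert out["PWR"].sum() == pytest.approx(5.0)

    def test_sum_identity_random(self):
        rng = np.random.default_rng(12)
        tree = random_phylogeny(20, seed=4)
        grid = small_grid(5, 5)
        pairs = [
            (lab, int(c))
            for lab in tree.labels
            for c in rng.choice(25, size=rng.integers(1, 6), replace=False)
        ]
        pm = assemble_presence(grid, pairs, species=list(tree.labels))
        out = phylogenetic_endemism(pm, tree)
        assert out["PWR"].sum() == pytest.approx(tree.total_length, rel=1e-9)


class TestTopSetRichness:
    def test_all_species_equals_sr(self, t3):
        grid = small_grid(1, 2)
        pm = assemble_presence(grid, [("A", 0), ("B", 0), ("C", 1)])
        risk = risk_table([("A", "LC", 1), ("B", "LC", 1), ("C", "LC", 1)])
        top = top_set_richness(pm, set(pm.species))["TOP"]
        assert (top == species_cell_scores(pm, risk)["SR"]).all()

    def test_empty_set_zero(self):
        pm = assemble_presence(small_grid(), [("A", 0)])
        assert (top_set_richness(pm, set())["TOP"] == 0).all()

    def test_intersection_count(self):
        grid = small_grid(1, 2)
        pm = assemble_presence(grid, [("A", 0), ("B", 0), ("C", 1)])
        assert top_set_richness(pm, {"A", "C"})["TOP"].loc[0] == 1

    def test_unknown_species_keyerror(self):
        pm = assemble_presence(small_grid(), [("A", 0)])
        with pytest.raises(KeyError):
            top_set_richness(pm, {"Z"})


class TestCellExpectedPD:
    def test_empty_cell_zero(self, t3):
        grid = small_grid(1, 2)
        pm = assemble_presence(grid, [("A", 0), ("B", 0), ("C", 0)])
        p = {"A": 0.5, "B": 0.5, "C": 0.5}
        assert gexp_pd(pm, t3, p).loc[1, "GexpPD"] == 0.0
        assert lexp_pd(pm, t3, p).loc[1, "LexpPD"] == 0.0

    def test_singleton_cell_reduces_to_species_scores(self, t3):
        grid = small_grid(1, 2)
        pm = assemble_presence(grid, [("A", 0)], species=["A", "B", "C"])
        p = {"A": 0.5, "B": 0.5, "C": 0.5}
        assert gexp_pd(pm, t3, p).loc[0, "GexpPD"] == pytest.approx(
            hedge_scores(t3, p)["A"], abs=1e-12
        )
        assert lexp_pd(pm, t3, p).loc[0, "LexpPD"] == pytest.approx(
            ledge_scores(t3, p)["A"], abs=1e-12
        )

    def test_worked_pair_cell(self, t3):
        grid = small_grid(1, 2)
        pm = assemble_presence(grid, [("A", 0), ("B", 0)], species=["A", "B", "C"])
        p = {"A": 0.5, "B": 0.5, "C": 0.5}
        # expPD(0,0,.5)=4.0 minus expPD(.5,.5,.5)=2.75
        assert gexp_pd(pm, t3, p).loc[0, "GexpPD"] == pytest.approx(1.25, abs=1e-12)

    def test_all_species_cell_loses_everything(self, t3):
        grid = small_grid(1, 2)
        pm = assemble_presence(grid, [("A", 0), ("B", 0), ("C", 0)])
        p = {"A": 0.5, "B": 0.5, "C": 0.5}
        assert lexp_pd(pm, t3, p).loc[0, "LexpPD"] == pytest.approx(2.75, abs=1e-12)

    def test_matches_two_evaluation_oracles_random(self):
        rng = np.random.default_rng(77)
        for rep in range(20):
            tree = random_phylogeny(int(rng.integers(2, 13)), seed=500 + rep)
            grid = small_grid(3, 3)
            pairs = [
                (lab, int(c))
                for lab in tree.labels
                for c in rng.choice(9, size=rng.integers(0, 4), replace=False)
            ]
            pm = assemble_presence(grid, pairs, species=list(tree.labels))
            p = rng.uniform(size=tree.n_leaves)
            pser = pd.Series(p, index=list(tree.labels))
            g = gexp_pd(pm, tree, pser)["GexpPD"]
            l = lexp_pd(pm, tree, pser)["LexpPD"]
            base = expected_pd(tree, pser)
            csr = pm.matrix.tocsr()
            for c in range(9):
                present = [pm.species[j]
                           for j in csr.indices[csr.indptr[c]:csr.indptr[c + 1]]]
                secured = pser.copy()
                secured[present] = 0.0
                lost = pser.copy()
                lost[present] = 1.0
                assert g[c] == pytest.approx(expected_pd(tree, secured) - base,
                                             abs=1e-10)
                assert l[c] == pytest.approx(base - expected_pd(tree, lost),
                                             abs=1e-10)

    def test_hedge_ledge_bounds_random(self):
        rng = np.random.default_rng(13)
        for rep in range(10):
            tree = random_phylogeny(10, seed=900 + rep)
            grid = small_grid(3, 3)
            pairs = [
                (lab, int(c))
                for lab in tree.labels
                for c in rng.choice(9, size=rng.integers(1, 4), replace=False)
            ]
            pm = assemble_presence(grid, pairs, species=list(tree.labels))
            p = pd.Series(rng.uniform(size=10), index=list(tree.labels))
            g = gexp_pd(pm, tree, p)["GexpPD"]
            l = lexp_pd(pm, tree, p)["LexpPD"]
            h = hedge_scores(tree, p)
            led = ledge_scores(tree, p)
            base = expected_pd(tree, p)
            csr = pm.matrix.tocsr()
            for c in range(9):
                present = [pm.species[j]
                           for j in csr.indices[csr.indptr[c]:csr.indptr[c + 1]]]
                if not present:
                    continue
                assert h[present].max() - 1e-10 <= g[c] <= h[present].sum() + 1e-10
                assert led[present].sum() - 1e-10 <= l[c] <= base + 1e-10


class TestProportionsAndHotspots:
    def test_all_threatened_ratio_one(self):
        num = pd.Series([2.0, 0.0], name="TSR")
        den = pd.Series([2.0, 0.0], name="SR")
        out = proportion_map(num, den)
        assert out[0] == pytest.approx(1.0)
        assert np.isnan(out[1])  # empty cell masked, not 0

    def test_quarter_ratio(self):
        out = proportion_map(pd.Series([1.0]), pd.Series([4.0]))
        assert out[0] == pytest.approx(0.25)

    def test_grid_mismatch(self):
        with pytest.raises(ValueError):
            proportion_map(pd.Series([1.0], index=[0]), pd.Series([1.0], index=[1]))

    def test_hotspot_count_floor(self):
        scores = pd.Series(np.arange(1000, dtype=float))
        assert len(hotspots(scores, 0.025)) == 25

    def test_study_scale_hotspot_count(self):
        rng = np.random.default_rng(0)
        scores = pd.Series(rng.permutation(51120).astype(float))
        assert len(hotspots(scores, 0.025)) == 1278

    def test_all_equal_ties_warn_lowest_ids(self):
        scores = pd.Series(np.ones(200))
        with pytest.warns(UserWarning, match="tie"):
            cells = hotspots(scores, 0.025)
        assert cells == set(range(5))

    def test_masked_cells_excluded(self):
        scores = pd.Series([np.nan] * 60 + list(np.arange(40.0)))
        cells = hotspots(scores, 0.1)  # floor(0.1 * 40 defined) = 4
        assert cells == {96, 97, 98, 99}

    def test_all_undefined_rejected(self):
        with pytest.raises(ValueError):
            hotspots(pd.Series([np.nan, np.nan]), 0.025)
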