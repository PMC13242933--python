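"""LR smoothing, coexpression screen, scoring, differential test, attribution."""

import numpy as np
import pandas as pd
import pytest

from decidua_niche import lr, synthetic
from decidua_niche.coloc import ColocMatrix
from decidua_niche.core_io import GeneMatrix, SingleCellReference


def _catalog(rows):
    return lr.LRCatalog(pairs=pd.DataFrame.from_dict(rows, orient="index")
                        .rename_axis("pair_id"))


def _grid(rows=10, cols=10, section="sec", condition="healthy"):
    cfg = synthetic.SyntheticConfig(grid_rows=rows, grid_cols=cols)
    grid, domain = synthetic._section_grid(cfg, section, condition, 8.0)
    return grid, domain


def _gm(values, grid, genes=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{j}" for j in range(values.shape[1])]
    return GeneMatrix(values=values, genes=genes, spot_ids=list(grid.spots.index))


class TestNeighborSmooth:
    def test_constant_gene_unchanged(self, rng):
        grid, _ = _grid()
        gm = _gm(np.full((100, 1), 2.5), grid)
        out = lr.neighbor_smooth(gm, grid)
        assert np.allclose(out.values, 2.5, atol=1e-12)

    def test_interior_hex_mean(self):
        """Interior spot with neighbours 1..6 and centre 7 smooths to 28/7."""
        grid, _ = _grid(rows=4, cols=4)
        from decidua_niche.core_io import hex_adjacency
        adj = hex_adjacency(grid)
        deg = np.asarray(adj.sum(axis=1)).ravel()
        center = int(np.flatnonzero(deg == 6)[0])
        neigh = adj[center].nonzero()[1]
        vals = np.zeros((grid.n_spots, 1))
        vals[center, 0] = 7.0
        vals[neigh, 0] = np.arange(1.0, 7.0)
        out = lr.neighbor_smooth(_gm(vals, grid), grid)
        assert out.values[center, 0] == pytest.approx(4.0, abs=1e-12)

    def test_isolated_spot_identity(self):
        grid, _ = _grid(rows=1, cols=1)
        gm = _gm([[3.3]], grid)
        assert lr.neighbor_smooth(gm, grid).values[0, 0] == pytest.approx(3.3)

    def test_linearity(self, rng):
        grid, _ = _grid()
        a = rng.random((100, 1))
        b = rng.random((100, 1))
        sm = lambda v: lr.neighbor_smooth(_gm(v, grid), grid).values
        assert np.allclose(sm(a + b), sm(a) + sm(b), atol=1e-12)


class TestCoexpressionScreen:
    def test_self_pair_fully_coexpressed(self, rng):
        grid, _ = _grid()
        gm = _gm(rng.random((100, 1)), grid, genes=["L"])
        cat = _catalog({"p": {"ligand": ("L",), "receptor": ("L",), "pathway": ""}})
        res = lr.coexpression_screen(gm, cat, grid=grid)
        assert res.iloc[0]["rho"] == pytest.approx(1.0)
        assert bool(res.iloc[0]["coexpressed"])

    def test_symmetric_in_ligand_receptor_exchange(self, rng):
        grid, _ = _grid()
        gm = _gm(rng.random((100, 2)), grid, genes=["L", "R"])
        cat1 = _catalog({"p": {"ligand": ("L",), "receptor": ("R",), "pathway": ""}})
        cat2 = _catalog({"p": {"ligand": ("R",), "receptor": ("L",), "pathway": ""}})
        r1 = lr.coexpression_screen(gm, cat1, grid=grid).iloc[0]
        r2 = lr.coexpression_screen(gm, cat2, grid=grid).iloc[0]
        assert r1["rho"] == pytest.approx(r2["rho"], abs=1e-12)

    def test_null_calibration(self, rng):
        """Independent pairs flag at most ~the one-sided 0.025 region."""
        grid, _ = _grid(rows=20, cols=10)  # 200 spots
        n_pairs = 400
        gm = _gm(np.abs(rng.normal(size=(200, 2 * n_pairs))), grid)
        cat = _catalog({f"p{i}": {"ligand": (f"g{2 * i}",), "receptor": (f"g{2 * i + 1}",),
                                  "pathway": ""} for i in range(n_pairs)})
        res = lr.coexpression_screen(gm, cat, grid=grid)
        assert res["coexpressed"].mean() <= 0.05

    def test_missing_gene_skipped_with_warning(self, rng):
        grid, _ = _grid()
        gm = _gm(rng.random((100, 1)), grid, genes=["L"])
        cat = _catalog({"p": {"ligand": ("L",), "receptor": ("ABSENT",), "pathway": ""}})
        with pytest.warns(UserWarning, match="ABSENT"):
            res = lr.coexpression_screen(gm, cat, grid=grid)
        assert res.empty

    def test_zero_variance_not_flagged(self):
        grid, _ = _grid()
        vals = np.column_stack([np.ones(100), np.ones(100)])
        cat = _catalog({"p": {"ligand": ("g0",), "receptor": ("g1",), "pathway": ""}})
        res = lr.coexpression_screen(_gm(vals, grid), cat, grid=grid)
        assert not bool(res.iloc[0]["coexpressed"]) and res.iloc[0]["p"] == 1.0

    def test_complex_reduced_to_limiting_subunit(self, rng):
        grid, _ = _grid()
        a = rng.random(100)
        vals = np.column_stack([a, a + 1.0, rng.random(100)])
        gm = _gm(vals, grid, genes=["s1", "s2", "R"])
        cat = _catalog({"p": {"ligand": ("s1", "s2"), "receptor": ("R",), "pathway": ""}})
        res = lr.coexpression_screen(gm, cat, grid=grid)
        expected = np.corrcoef(np.minimum(a, a + 1.0), vals[:, 2])[0, 1]
        assert res.iloc[0]["rho"] == pytest.approx(expected, abs=1e-12)


class TestSpotScore:
    def test_product_rule_and_bilinearity(self, rng):
        grid, _ = _grid(rows=4, cols=4)
        vals = np.column_stack([np.full(16, 2.0), np.full(16, 3.0)])
        vals[0, 0] = 0.0
        gm = _gm(vals, grid, genes=["L", "R"])
        cat = _catalog({"p": {"ligand": ("L",), "receptor": ("R",), "pathway": ""}})
        sc = lr.spot_score(gm, cat)["p"]
        assert sc.iloc[0] == 0.0
        assert sc.iloc[1] == pytest.approx(6.0)
        gm3 = _gm(np.column_stack([3 * vals[:, 0], vals[:, 1]]), grid, genes=["L", "R"])
        assert np.allclose(lr.spot_score(gm3, cat)["p"], 3 * sc, atol=1e-12)


class TestDifferentialLR:
    def test_identical_distributions_not_retained(self, rng):
        scores = pd.DataFrame({"p1": np.tile(rng.random(50), 2)})
        mask = np.r_[np.ones(50, bool), np.zeros(50, bool)]
        res = lr.differential_lr(scores, mask)
        assert not res["up"].any() and not res["down"].any()

    def test_doubled_scores_retained(self, rng):
        base = rng.random(500) + 1.0
        scores = pd.DataFrame({"p1": np.r_[2 * base, base]})
        mask = np.r_[np.ones(500, bool), np.zeros(500, bool)]
        res = lr.differential_lr(scores, mask)
        assert res.loc["p1", "log2fc"] == pytest.approx(1.0, abs=0.01)
        assert bool(res.loc["p1", "up"]) and not bool(res.loc["p1", "down"])

    def test_null_fdr_control(self, rng):
        """100 null pairs: BH-adjusted discoveries at q=0.05 are rare."""
        hits = 0
        for _ in range(10):
            scores = pd.DataFrame(rng.random((200, 100)),
                                  columns=[f"p{i}" for i in range(100)])
            mask = np.r_[np.ones(100, bool), np.zeros(100, bool)]
            res = lr.differential_lr(scores, mask)
            hits += int((res["p_adj"] < 0.05).sum() > 0)
        assert hits <= 2

    def test_empty_group_rejected(self, rng):
        scores = pd.DataFrame({"p1": rng.random(10)})
        with pytest.raises(ValueError):
            lr.differential_lr(scores, np.ones(10, bool))


class TestAttribution:
    def _reference(self, expr_rows):
        df = pd.DataFrame(expr_rows).T
        props = pd.Series(1 / len(df), index=df.index)
        return SingleCellReference(subset_proportions=props, subset_mean_expression=df)

    def _coloc(self, values, types):
        return ColocMatrix(values=pd.DataFrame(values, index=types, columns=types))

    def test_exclusive_expression_forces_pair(self):
        ref = self._reference({"X": {"L": 5.0, "R": 0.0}, "Y": {"L": 0.0, "R": 4.0},
                               "Z": {"L": 0.1, "R": 0.1}})
        cmat = self._coloc([[0, 0.3, 0.0], [0.3, 0, 0.0], [0.0, 0.0, 0]], ["X", "Y", "Z"])
        cat = _catalog({"p": {"ligand": ("L",), "receptor": ("R",), "pathway": ""}})
        assert lr.attribute_pair("p", cat, ref, cmat) == ("X", "Y")

    def test_brute_force_over_ordered_pairs(self, rng):
        types = ["A", "B", "C"]
        expr = {t: {"L": float(rng.random()), "R": float(rng.random())} for t in types}
        ref = self._reference(expr)
        raw = rng.uniform(-0.2, 0.8, size=(3, 3))
        cvals = (raw + raw.T) / 2
        np.fill_diagonal(cvals, 0.0)
        cmat = self._coloc(cvals, types)
        cat = _catalog({"p": {"ligand": ("L",), "receptor": ("R",), "pathway": ""}})
        got = lr.attribute_pair("p", cat, ref, cmat, corr_min=0.1)
        best, best_score = None, -np.inf
        for a in types:
            for b in types:
                cc = 1.0 if a == b else cvals[types.index(a), types.index(b)]
                if cc < 0.1:
                    continue
                s = expr[a]["L"] * expr[b]["R"]
                if s > best_score:
                    best, best_score = (a, b), s
        assert got == best

    def test_no_colocalized_pair_unassigned(self):
        ref = self._reference({"X": {"L": 1.0, "R": 1.0}, "Y": {"L": 1.0, "R": 1.0}})
        cmat = self._coloc([[0, -0.5], [-0.5, 0]], ["X", "Y"])
        cat = _catalog({"p": {"ligand": ("L",), "receptor": ("R",), "pathway": ""}})
        # self-pairs count as colocalized, so exclude them via corr_min > 1
        assert lr.attribute_pair("p", cat, ref, cmat, corr_min=1.5) == "unassigned"


class TestEndToEndPlanted:
    def test_planted_pair_detected_and_down_in_rpl(self, small_dataset):
        ds = small_dataset
        pair = ds.config.planted_lr_pairs[0]
        screens = []
        scores_iz, is_rpl = [], []
        for s in ds.sections:
            sm = lr.neighbor_smooth(s.expression, s.grid)
            screens.append(lr.coexpression_screen(sm, ds.catalog, grid=s.grid))
            sc = lr.spot_score(sm, ds.catalog)
            m = (s.truth.domain == "IZ").to_numpy()
            scores_iz.append(sc.loc[m])
            is_rpl.append(np.full(int(m.sum()), s.truth.condition == "RPL"))
        screen = pd.concat(screens)
        flagged = screen[(screen["pair_id"] == pair.pair_id) & screen["coexpressed"]]
        assert len(flagged) >= 1  # planted pair called coexpressed
        res = lr.differential_lr(pd.concat(scores_iz), np.concatenate(is_rpl))
        assert bool(res.loc[pair.pair_id, "down"])
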