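"""Probability normalisation, domain markers, Jaccard, ANCOVA contrast."""

import numpy as np
import pandas as pd
import pytest

from decidua_niche import domains
from decidua_niche.core_io import (CellTypeProbabilities, GeneMatrix,
                                   SingleCellReference)


def _reference(props: dict, genes=("g1", "g2")):
    expr = pd.DataFrame(1.0, index=list(props), columns=list(genes))
    return SingleCellReference(subset_proportions=pd.Series(props),
                               subset_mean_expression=expr)


def _probs(rows, types):
    return CellTypeProbabilities(values=np.asarray(rows, dtype=float),
                                 cell_types=list(types),
                                 spot_ids=[f"s{i}" for i in range(len(rows))])


class TestNormalizeProbabilities:
    def test_equal_proportions_cancel(self):
        ref = _reference({"A": 0.25, "B": 0.25, "C": 0.5})
        ref.subset_proportions[:] = 1 / 3
        out = domains.normalize_probabilities(_probs([[0.2, 0.2, 0.6]], "ABC"), ref)
        assert out.values[0] == pytest.approx([0.2, 0.2, 0.6])
        assert out.normalized

    def test_hand_computed_ratio_rule(self):
        # (0.5/0.5, 0.5/0.25) = (1, 2) -> renormalised (1/3, 2/3)
        ref = _reference({"A": 0.5, "B": 0.25, "C": 0.25})
        out = domains.normalize_probabilities(_probs([[0.5, 0.5]], "AB"), ref)
        assert out.values[0] == pytest.approx([1 / 3, 2 / 3], abs=1e-12)

    def test_column_permutation_commutes(self, rng):
        ref = _reference({"A": 0.5, "B": 0.3, "C": 0.2}, genes=("g1",))
        vals = rng.random((6, 3))
        out = domains.normalize_probabilities(_probs(vals, "ABC"), ref)
        perm = [2, 0, 1]
        permuted_in = CellTypeProbabilities(values=vals[:, perm],
                                            cell_types=["C", "A", "B"],
                                            spot_ids=out.spot_ids)
        out_perm = domains.normalize_probabilities(permuted_in, ref)
        assert np.allclose(out_perm.values, out.values[:, perm], atol=1e-12)

    def test_idempotent_under_uniform_reference(self, rng):
        ref = _reference({"A": 0.5, "B": 0.3, "C": 0.2})
        ref.subset_proportions[:] = 1 / 3
        first = domains.normalize_probabilities(_probs(rng.random((4, 3)), "ABC"), ref)
        again = domains.normalize_probabilities(
            CellTypeProbabilities(values=first.values, cell_types=first.cell_types,
                                  spot_ids=first.spot_ids, normalized=False), ref)
        assert np.allclose(again.values, first.values, atol=1e-12)

    def test_zero_reference_proportion_named(self):
        ref = _reference({"A": 1.0, "B": 0.0})
        with pytest.raises(ValueError, match="B"):
            domains.normalize_probabilities(_probs([[0.5, 0.5]], "AB"), ref)

    def test_all_zero_row_uniform_with_warning(self):
        ref = _reference({"A": 0.5, "B": 0.5})
        with pytest.warns(UserWarning, match="uniform"):
            out = domains.normalize_probabilities(_probs([[0.0, 0.0], [0.4, 0.6]], "AB"), ref)
        assert out.values[0] == pytest.approx([0.5, 0.5])


class TestDomainMarkers:
    def _expr(self, values):
        values = np.asarray(values, dtype=float)
        return GeneMatrix(values=values, genes=[f"g{j}" for j in range(values.shape[1])],
                          spot_ids=[f"s{i}" for i in range(values.shape[0])])

    def test_constant_gene_not_retained(self, rng):
        vals = np.column_stack([np.ones(40), rng.random(40)])
        labels = ["IZ"] * 20 + ["GZ"] * 20
        sig = domains.domain_markers(self._expr(vals), labels, lfc_min=0.0, p_max=1.0)
        assert "g0" not in sig["IZ"].genes or "g0" not in sig["GZ"].genes
        assert sig["IZ"].stats.loc["g0", "log2fc"] == pytest.approx(0.0, abs=1e-9)

    def test_planted_marker_recovered(self, rng):
        """A 4x shifted gene at n=800/domain clears both thresholds."""
        n = 800
        base = rng.lognormal(0.0, 0.3, size=(2 * n, 3))
        base[:n, 0] *= 4.0
        expr = self._expr(np.log1p(base))
        labels = ["IZ"] * n + ["GZ"] * n
        sig = domains.domain_markers(expr, labels)
        assert "g0" in sig["IZ"].genes
        assert sig["IZ"].stats.loc["g0", "p"] < 1e-10
        assert not (sig["GZ"].genes & {"g0"})

    def test_permissive_thresholds_partition_genes(self, rng):
        vals = rng.random((30, 6)) + 0.1
        labels = ["IZ"] * 15 + ["GZ"] * 15
        sig = domains.domain_markers(self._expr(vals), labels, lfc_min=0.0, p_max=1.0)
        counts = [int(g in sig["IZ"].genes) + int(g in sig["GZ"].genes)
                  for g in sig["IZ"].stats.index]
        assert all(c == 1 for c in counts)

    def test_spot_order_invariance(self, rng):
        vals = rng.lognormal(size=(40, 5))
        labels = np.array(["IZ"] * 18 + ["GZ"] * 22, dtype=object)
        sig = domains.domain_markers(self._expr(vals), labels, lfc_min=0.1, p_max=0.5)
        perm = rng.permutation(40)
        sig_p = domains.domain_markers(self._expr(vals[perm]), labels[perm],
                                       lfc_min=0.1, p_max=0.5)
        assert sig["IZ"].genes == sig_p["IZ"].genes
        assert sig["GZ"].genes == sig_p["GZ"].genes

    def test_tiny_domain_rejected(self, rng):
        with pytest.raises(ValueError, match="at least 2"):
            domains.domain_markers(self._expr(rng.random((5, 2))),
                                   ["IZ", "GZ", "GZ", "GZ", "GZ"])


class TestJaccard:
    @pytest.mark.parametrize("a, b, expected", [
        ({"x", "y"}, {"x", "y"}, 1.0),
        ({"x"}, {"y"}, 0.0),
        ({"a", "b", "c"}, {"b", "c", "d"}, 0.5),  # 2 shared / 4 total
    ])
    def test_values(self, a, b, expected):
        assert domains.jaccard(a, b) == pytest.approx(expected, abs=1e-12)

    def test_symmetric_bounded(self, rng):
        for _ in range(20):
            a = set(rng.integers(0, 20, size=rng.integers(0, 10)).tolist())
            b = set(rng.integers(0, 20, size=rng.integers(1, 10)).tolist())
            j = domains.jaccard(a, b)
            assert j == domains.jaccard(b, a)
            assert 0.0 <= j <= 1.0

    def test_both_empty_flagged(self):
        with pytest.warns(UserWarning):
            assert domains.jaccard(set(), set()) == 0.0


class TestConditionEffect:
    def test_identical_groups_null(self):
        values = np.ones(40)
        cond = np.array(["healthy"] * 20 + ["RPL"] * 20, dtype=object)
        age = np.r_[np.linspace(6, 12, 20), np.linspace(6, 12, 20)]
        res = domains.condition_effect(values, cond, age)
        assert res.effect == pytest.approx(0.0, abs=1e-9)
        assert res.p_value == pytest.approx(1.0, abs=1e-6)

    def test_confounded_effect_recovered(self, rng):
        """Planted effect recovered despite an age-shifted disease group."""
        n = 1000
        cond = np.array(["healthy"] * n + ["RPL"] * n, dtype=object)
        age = np.r_[rng.uniform(6, 12, n), rng.uniform(7, 13, n)]  # +1 week shift
        values = 0.3 * age + 1.0 * (cond == "RPL") + rng.normal(0, 1, 2 * n)
        res = domains.condition_effect(values, cond, age)
        assert res.effect == pytest.approx(1.0, abs=0.1)
        # matches the closed-form normal-equations solution
        x = np.column_stack([np.ones(2 * n), (cond == "RPL").astype(float), age])
        beta = np.linalg.solve(x.T @ x, x.T @ values)
        assert res.effect == pytest.approx(beta[1], abs=1e-8)

    def test_constant_covariate_falls_back(self, rng):
        cond = np.array(["healthy"] * 10 + ["RPL"] * 10, dtype=object)
        with pytest.warns(UserWarning, match="t-test"):
            res = domains.condition_effect(rng.normal(size=20), cond, np.full(20, 8.0))
        assert res.method == "t-test"

    def test_single_condition_rejected(self, rng):
        cond = np.array(["healthy"] * 10, dtype=object)
        with pytest.raises(ValueError, match="both conditions"):
            domains.condition_effect(rng.normal(size=10), cond, rng.uniform(6, 12, 10))

    def test_null_type_i_rate_calibrated(self, rng):
        """Under the null the ANCOVA P is uniform enough at alpha=0.05."""
        hits = 0
        n_rep = 400
        cond = np.array(["healthy"] * 50 + ["RPL"] * 50, dtype=object)
        for _ in range(n_rep):
            age = rng.uniform(6, 12, 100)
            values = 0.2 * age + rng.normal(size=100)
            if domains.condition_effect(values, cond, age).p_value < 0.05:
                hits += 1
        assert 0.02 <= hits / n_rep <= 0.08
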