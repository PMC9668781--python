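"""Correlation matrix, correlogram ordering and the partial-correlation net."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from biofortqg.network import (
    CorrelationMatrix,
    order_correlogram,
    partial_correlation_network,
    pearson_matrix,
)


class TestPearsonMatrix:
    def test_hand_example(self):
        # x=(1..5), y=(2,1,4,3,5): r = 0.8, t = 2.309, p ~ 0.104
        df = pd.DataFrame({"x": [1, 2, 3, 4, 5], "y": [2, 1, 4, 3, 5]})
        cm = pearson_matrix(df)
        assert cm.r.at["x", "y"] == pytest.approx(0.8)
        t = 0.8 * np.sqrt(3 / (1 - 0.64))
        assert t == pytest.approx(2.3094, abs=1e-4)
        assert cm.p.at["x", "y"] == pytest.approx(2 * stats.t.sf(t, 3), rel=1e-9)
        assert cm.p.at["x", "y"] == pytest.approx(0.1041, abs=1e-3)

    def test_unit_diagonal_and_symmetry(self, blup_like_table):
        cm = pearson_matrix(blup_like_table)
        np.testing.assert_allclose(np.diag(cm.r), 1.0)
        np.testing.assert_allclose(cm.r, cm.r.T)
        np.testing.assert_allclose(cm.p, cm.p.T)

    def test_exact_linearity(self):
        df = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [2.0, 4, 6, 8]})
        cm = pearson_matrix(df)
        assert cm.r.at["a", "b"] == pytest.approx(1.0)
        assert cm.p.at["a", "b"] < 0.05

    def test_matches_two_pass_covariance(self, blup_like_table):
        cm = pearson_matrix(blup_like_table)
        brute = np.corrcoef(blup_like_table.to_numpy(), rowvar=False)
        np.testing.assert_allclose(cm.r.to_numpy(), brute, atol=1e-12)

    def test_pairwise_complete_counts(self, blup_like_table):
        df = blup_like_table.copy()
        df.iloc[:5, 0] = np.nan
        cm = pearson_matrix(df)
        assert cm.n_pairs.at["TCC", "FRY"] == 20
        assert cm.n_pairs.at["FRY", "HCN"] == 25
        # cross-check against scipy on the complete pairs
        m = df["TCC"].notna()
        r_ref, p_ref = stats.pearsonr(df.loc[m, "TCC"], df.loc[m, "FRY"])
        assert cm.r.at["TCC", "FRY"] == pytest.approx(r_ref, rel=1e-9)
        assert cm.p.at["TCC", "FRY"] == pytest.approx(p_ref, rel=1e-6)

    def test_constant_trait_warns_and_reports_missing(self):
        df = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [5.0, 5, 5, 5]})
        with pytest.warns(UserWarning, match="constant"):
            cm = pearson_matrix(df)
        assert np.isnan(cm.r.at["a", "b"])


class TestCorrelogramOrdering:
    @staticmethod
    def block_matrix(names_a, names_b, within=0.8, between=0.05):
        names = names_a + names_b
        k = len(names)
        r = np.full((k, k), between)
        for grp in (range(len(names_a)), range(len(names_a), k)):
            for i in grp:
                for j in grp:
                    r[i, j] = within
        np.fill_diagonal(r, 1.0)
        rdf = pd.DataFrame(r, index=names, columns=names)
        ones = pd.DataFrame(np.ones_like(r), index=names, columns=names)
        return CorrelationMatrix(names, rdf, ones * 0.01, ones * 100)

    def test_two_traits_unchanged(self):
        cm = self.block_matrix(["a"], ["b"])
        assert order_correlogram(cm) == ["a", "b"]

    def test_block_groups_stay_contiguous(self):
        cm = self.block_matrix(["a1", "a2", "a3"], ["b1", "b2"])
        order = order_correlogram(cm)
        pos = {t: i for i, t in enumerate(order)}
        a_pos = sorted(pos[t] for t in ["a1", "a2", "a3"])
        assert a_pos[-1] - a_pos[0] == 2  # consecutive

    def test_permutation_invariance_of_grouping(self):
        cm = self.block_matrix(["a1", "a2"], ["b1", "b2"])
        perm = ["b1", "a2", "b2", "a1"]
        cm2 = CorrelationMatrix(perm, cm.r.loc[perm, perm], cm.p.loc[perm, perm],
                                cm.n_pairs.loc[perm, perm])
        order2 = order_correlogram(cm2)
        pos = {t: i for i, t in enumerate(order2)}
        assert abs(pos["a1"] - pos["a2"]) == 1
        assert abs(pos["b1"] - pos["b2"]) == 1


class TestPartialCorrelationNetwork:
    def test_independent_traits_give_sparse_network(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.standard_normal((400, 5)),
                          columns=list("abcde"))
        net = partial_correlation_network(df)
        assert len(net.edges()) <= 1

    def test_chain_drops_the_indirect_edge(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(500)
        y = 0.8 * x + 0.6 * rng.standard_normal(500)
        z = 0.8 * y + 0.6 * rng.standard_normal(500)
        net = partial_correlation_network(pd.DataFrame({"X": x, "Y": y, "Z": z}))
        w = net.weights
        assert w.at["X", "Z"] == 0.0
        assert w.at["X", "Y"] > 0.3
        assert w.at["Y", "Z"] > 0.3

    def test_infinite_penalty_empties_the_network(self, blup_like_table):
        net = partial_correlation_network(blup_like_table,
                                          penalty_range=(10.0, 100.0),
                                          n_penalties=3)
        assert net.edges().empty

    def test_weights_are_symmetric_partial_correlations(self):
        rng = np.random.default_rng(1)
        base = rng.standard_normal(300)
        df = pd.DataFrame({
            "a": base + 0.3 * rng.standard_normal(300),
            "b": base + 0.3 * rng.standard_normal(300),
            "c": rng.standard_normal(300),
        })
        net = partial_correlation_network(df)
        w = net.weights
        np.testing.assert_allclose(w, w.T)
        np.testing.assert_allclose(np.diag(w), 0.0)
        assert (w.abs() <= 1).all().all()
        assert w.at["a", "b"] > 0.5


def test_pearson_holm_adjustment_flag(blup_like_table):
    from biofortqg.clustering import holm_adjust

    raw = pearson_matrix(blup_like_table)
    adj = pearson_matrix(blup_like_table, p_adjust="holm")
    iu = np.triu_indices(len(raw.traits), 1)
    expected = holm_adjust(raw.p.to_numpy()[iu])
    np.testing.assert_allclose(adj.p.to_numpy()[iu], expected)
    assert (adj.p.to_numpy()[iu] >= raw.p.to_numpy()[iu] - 1e-15).all()
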