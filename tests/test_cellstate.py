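"""Signature scoring, cell-cycle phases, quiescence gating and rank-sum DE."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from escreg import cellstate, io
from escreg.cellstate import QuiescenceGate


def _lognorm(values, genes=None, cells=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"G{i}" for i in range(values.shape[0])]
    cells = cells or [f"C{j}" for j in range(values.shape[1])]
    return io.ExpressionMatrix(values, genes, cells, "lognorm")


class TestScoreSignature:
    def test_singleton_signature_equals_gene_value(self):
        m = _lognorm([[0.5, 1.5, 0.0], [2.0, 0.1, 3.0]])
        score = cellstate.score_signature(m, ["G1"])
        np.testing.assert_allclose(score.to_numpy(), [2.0, 0.1, 3.0])

    def test_two_gene_mean_by_hand(self):
        m = _lognorm([[1.0, 0.0, 2.0], [3.0, 1.0, 0.0]])
        score = cellstate.score_signature(m, ["G0", "G1"])
        np.testing.assert_allclose(score.to_numpy(), [2.0, 0.5, 1.0])

    def test_all_zero_cell_scores_zero(self):
        m = _lognorm([[0.0, 1.0], [0.0, 2.0]])
        assert cellstate.score_signature(m, ["G0", "G1"])["C0"] == 0.0

    def test_gene_order_invariant(self):
        m = _lognorm(np.random.default_rng(1).random((4, 6)))
        a = cellstate.score_signature(m, ["G0", "G2", "G3"])
        b = cellstate.score_signature(m, ["G3", "G0", "G2"])
        pd.testing.assert_series_equal(a, b)

    def test_no_gene_present_rejected(self):
        m = _lognorm([[1.0, 2.0, 0.5]])
        with pytest.raises(ValueError, match="no signature gene"):
            cellstate.score_signature(m, ["MISSING"])


class TestClusterHighCall:
    def test_two_cluster_median_rule(self):
        scores = pd.Series([0.1, 0.1, 0.9, 0.9, 0.9], index=list("abcde"))
        clusters = pd.Series(["k1", "k1", "k2", "k2", "k2"], index=list("abcde"))
        table, fraction = cellstate.cluster_high_call(scores, clusters)
        assert table.loc["k2", "high"] and not table.loc["k1", "high"]
        assert fraction == pytest.approx(3 / 5)

    def test_equal_means_flag_nothing(self):
        scores = pd.Series([0.5, 0.5], index=["a", "b"])
        clusters = pd.Series(["k1", "k2"], index=["a", "b"])
        table, fraction = cellstate.cluster_high_call(scores, clusters)
        assert not table["high"].any() and fraction == 0.0

    def test_planted_high_module_cluster(self, default_lognorm):
        """The cycling cluster carries the module signature; its share is exact."""
        lognorm, truth, labels = default_lognorm
        score = cellstate.score_signature(lognorm, sorted(truth.module_genes))
        clusters = labels["cluster"].reindex(score.index)
        table, fraction = cellstate.cluster_high_call(score, clusters)
        assert table.loc["cycling", "high"] and not table.loc["quiescent", "high"]
        assert fraction == pytest.approx((clusters == "cycling").mean())

    def test_missing_labels_rejected(self):
        scores = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(ValueError):
            cellstate.cluster_high_call(scores, pd.Series(["k"], index=["a"]))


class TestAssignCellCycle:
    def _constructed(self):
        """20 genes x 4 cells; S genes elevated in cell 0, G2M in cell 1,
        cell 2 cycling-quiet with MKI67 on, cell 3 quiet with MKI67 off."""
        rng = np.random.default_rng(0)
        base = rng.uniform(0.5, 1.5, size=(20, 4))
        genes = [f"S{i}" for i in range(5)] + [f"M{i}" for i in range(5)] + [
            f"N{i}" for i in range(9)
        ] + ["MKI67"]
        base[0:5, 0] += 5.0
        base[5:10, 1] += 5.0
        base[0:10, 2:] = 0.05
        base[19, :] = [1.0, 1.0, 1.0, 0.0]
        return _lognorm(base, genes), [f"S{i}" for i in range(5)], [f"M{i}" for i in range(5)]

    def test_constructed_dominance(self):
        m, s_genes, g2m_genes = self._constructed()
        out = cellstate.assign_cell_cycle(m, s_genes, g2m_genes, n_bins=4, n_ctrl=5, seed=0)
        assert out.loc["C0", "phase"] == "S" and out.loc["C0", "s_score"] > 0
        assert out.loc["C1", "phase"] == "G2M"
        assert out.loc["C2", "phase"] == "G1"
        assert out.loc["C3", "phase"] == "G0"

    def test_missing_mki67_rejected(self):
        m = _lognorm(np.ones((4, 4)) + np.eye(4))
        with pytest.raises(ValueError, match="MKI67"):
            cellstate.assign_cell_cycle(m, ["G0"], ["G1"])

    def test_agrees_with_independent_control_matched_scorer(self, default_lognorm):
        """Scores track an independent control-matched implementation (r > 0.99)."""
        anndata = pytest.importorskip("anndata")
        sc = pytest.importorskip("scanpy")
        lognorm, truth, _ = default_lognorm
        adata = anndata.AnnData(
            lognorm.values.T,
            obs=pd.DataFrame(index=lognorm.cell_ids),
            var=pd.DataFrame(index=lognorm.gene_ids),
        )
        sc.tl.score_genes(adata, truth.s_genes, score_name="s",
                          ctrl_size=50, n_bins=25, random_state=0)
        mine = cellstate.assign_cell_cycle(lognorm, truth.s_genes, truth.g2m_genes, seed=11)
        r = np.corrcoef(mine["s_score"], adata.obs["s"])[0, 1]
        assert r > 0.99

    def test_planted_phase_recovery(self, default_lognorm):
        """>=90% agreement with the planted cycle phases."""
        lognorm, truth, _ = default_lognorm
        out = cellstate.assign_cell_cycle(
            lognorm, truth.s_genes, truth.g2m_genes, seed=11
        )
        planted = pd.Series(truth.phase_of_cell).reindex(out.index)
        assert (out["phase"] == planted).mean() >= 0.90

    def test_phase_labels_partition_and_g0_lacks_mki67(self, default_lognorm):
        lognorm, truth, _ = default_lognorm
        out = cellstate.assign_cell_cycle(lognorm, truth.s_genes, truth.g2m_genes, seed=11)
        assert set(out["phase"]) <= {"G0", "G1", "S", "G2M"}
        mki67 = lognorm.values[lognorm.gene_index(["MKI67"])[0]]
        assert (mki67[(out["phase"] == "G0").to_numpy()] == 0).all()


class TestSelectExemplars:
    def _table(self, n_s=20, n_g0=3):
        rows = []
        for i in range(n_s):
            rows.append((f"s{i:03d}", 1.0 + i, -1.0, "S"))
        for i in range(n_g0):
            rows.append((f"q{i:03d}", -2.0 - i, -3.0, "G0"))
        return pd.DataFrame(
            rows, columns=["cell_id", "s_score", "g2m_score", "phase"]
        ).set_index("cell_id")

    def test_top_n_by_phase_score(self):
        table = self._table(n_s=20)
        out = cellstate.select_exemplars(table, n_per_phase=5)
        assert len(out["S"]) == 5
        chosen = table.loc[out["S"], "s_score"]
        excluded = table.loc[table.index.difference(out["S"])]
        excluded_s = excluded[excluded["phase"] == "S"]["s_score"]
        assert chosen.min() >= excluded_s.max()

    def test_shortfall_returns_all_with_warning(self):
        table = self._table(n_g0=3)
        with pytest.warns(UserWarning, match="only 3"):
            out = cellstate.select_exemplars(table, n_per_phase=500)
        assert len(out["G0"]) == 3

    def test_tie_breaks_lexicographically_and_rerun_stable(self):
        table = pd.DataFrame(
            {
                "cell_id": ["zz", "aa", "mm"],
                "s_score": [1.0, 1.0, 1.0],
                "g2m_score": [-1.0, -1.0, -1.0],
                "phase": ["S", "S", "S"],
            }
        ).set_index("cell_id")
        first = cellstate.select_exemplars(table, n_per_phase=2)
        second = cellstate.select_exemplars(table, n_per_phase=2)
        assert first["S"] == ["aa", "mm"] == second["S"]


class TestClassifyQuiescent:
    def _matrix(self):
        """40 cells: first 20 quiescent-like (low module, zero markers)."""
        rng = np.random.default_rng(7)
        n = 40
        module = np.vstack([np.r_[rng.uniform(0, 0.2, 20), rng.uniform(1, 2, 20)]
                            for _ in range(5)])
        markers = np.vstack([np.r_[np.zeros(20), rng.uniform(0.5, 2.0, 20)]
                             for _ in range(3)])
        values = np.vstack([module, markers])
        genes = [f"R{i}" for i in range(5)] + ["MKI67", "CD38", "TP53"]
        return io.ExpressionMatrix(values, genes, [f"C{i:02d}" for i in range(n)], "lognorm")

    def test_extremal_cell_is_quiescent(self):
        m = self._matrix()
        flags, report = cellstate.classify_quiescent(m, [f"R{i}" for i in range(5)])
        assert flags["C00"]
        assert set(report["marker_thresholds"]) == {"MKI67", "CD38", "TP53"}

    def test_cell_above_marker_quantile_never_quiescent(self):
        """Even a module-low cell fails when MKI67 sits above its 95th quantile."""
        m = self._matrix()
        values = m.values.copy()
        mki67_row = m.gene_index(["MKI67"])[0]
        values[mki67_row, 0] = values[mki67_row].max() + 1.0  # top expresser
        m2 = io.ExpressionMatrix(values, m.gene_ids, m.cell_ids, "lognorm")
        flags, _ = cellstate.classify_quiescent(m2, [f"R{i}" for i in range(5)])
        assert not flags["C00"]

    def test_gate_monotone_in_quantiles(self):
        m = self._matrix()
        tight = QuiescenceGate(escreg_quantile=0.3,
                               marker_gates=[("MKI67", 0.5, True)])
        loose = QuiescenceGate(escreg_quantile=0.6,
                               marker_gates=[("MKI67", 0.95, True)])
        f_tight, _ = cellstate.classify_quiescent(m, [f"R{i}" for i in range(5)], tight)
        f_loose, _ = cellstate.classify_quiescent(m, [f"R{i}" for i in range(5)], loose)
        assert set(f_tight.index[f_tight]) <= set(f_loose.index[f_loose])

    def test_no_expressing_cells_rejected(self):
        values = np.vstack([np.random.default_rng(0).random((2, 6)), np.zeros((1, 6))])
        m = io.ExpressionMatrix(values, ["R0", "R1", "MKI67"], list("abcdef"), "lognorm")
        gate = QuiescenceGate(marker_gates=[("MKI67", 0.95, True)])
        with pytest.raises(ValueError, match="MKI67"):
            cellstate.classify_quiescent(m, ["R0", "R1"], gate)

    def test_planted_quiescent_recovery(self, default_lognorm):
        """Default gate recovers the planted quiescent cells at P/R >= 0.90."""
        lognorm, truth, _ = default_lognorm
        flags, _ = cellstate.classify_quiescent(lognorm, sorted(truth.module_genes))
        called = set(flags.index[flags])
        planted = truth.quiescent_cells
        tp = len(called & planted)
        assert tp / len(called) >= 0.90
        assert tp / len(planted) >= 0.90


def exact_ranksum_oracle(x, y):
    """Two-sided p by full enumeration of C(n, len(x)) labelings."""
    import scipy.stats

    pooled = np.concatenate([x, y])
    ranks = scipy.stats.rankdata(pooled)
    mu = len(x) * (len(pooled) + 1) / 2.0
    d_obs = abs(ranks[: len(x)].sum() - mu)
    hits = total = 0
    for combo in itertools.combinations(range(len(pooled)), len(x)):
        total += 1
        if abs(ranks[list(combo)].sum() - mu) >= d_obs - 1e-12:
            hits += 1
    return hits / total


class TestRankSumDE:
    def test_boundary_lfc_excluded(self):
        """A gene at |log2FC| = 0.49 never enters the 0.5-cutoff set."""
        rng = np.random.default_rng(2)
        n = 30
        target_lfc = 0.49
        # pick group-b values so the de-logged-mean fold change is exactly 0.49
        a_vals = rng.uniform(1.0, 2.0, n)
        scale = (2 ** -target_lfc * (np.expm1(a_vals).mean() + 1) - 1) / np.expm1(a_vals).mean()
        b_vals = np.log1p(np.expm1(a_vals) * scale)
        m = _lognorm(np.r_[a_vals, b_vals].reshape(1, -1), ["GENE"],
                     [f"a{i}" for i in range(n)] + [f"b{i}" for i in range(n)])
        de = cellstate.rank_sum_de(m, [f"a{i}" for i in range(n)],
                                   [f"b{i}" for i in range(n)], lfc_cut=0.5)
        assert de.loc[0, "log2fc"] == pytest.approx(target_lfc, abs=1e-9)
        assert de.loc[0, "p"] < 0.05
        assert not de.loc[0, "significant"]

    def test_identical_distribution_yields_nothing(self):
        rng = np.random.default_rng(3)
        vals = np.tile(rng.random(10), (4, 2))  # group b duplicates group a
        m = _lognorm(vals, cells=[f"a{i}" for i in range(10)] + [f"b{i}" for i in range(10)])
        de = cellstate.rank_sum_de(m, [f"a{i}" for i in range(10)],
                                   [f"b{i}" for i in range(10)])
        assert not de["significant"].any()
        assert (de["p"] == 1.0).all()

    def test_exact_p_matches_enumeration_on_3v3(self):
        """Small-sample p equals brute-force label enumeration, ties included."""
        cases = [
            ([0.1, 0.9, 0.5], [1.2, 1.4, 1.3]),
            ([1.0, 1.0, 2.0], [1.0, 3.0, 2.0]),  # ties across groups
            ([0.2, 0.4, 0.6], [0.3, 0.5, 0.7]),
        ]
        for x, y in cases:
            m = _lognorm(np.array([x + y]), ["G"], list("abcdef"))
            de = cellstate.rank_sum_de(m, list("abc"), list("def"), lfc_cut=0.0)
            assert de.loc[0, "p"] == pytest.approx(exact_ranksum_oracle(x, y), abs=1e-12)

    def test_group_swap_symmetry(self):
        rng = np.random.default_rng(4)
        m = _lognorm(rng.random((5, 12)),
                     cells=[f"a{i}" for i in range(6)] + [f"b{i}" for i in range(6)])
        ga, gb = [f"a{i}" for i in range(6)], [f"b{i}" for i in range(6)]
        fwd = cellstate.rank_sum_de(m, ga, gb, lfc_cut=0.0)
        rev = cellstate.rank_sum_de(m, gb, ga, lfc_cut=0.0)
        np.testing.assert_allclose(fwd["p"], rev["p"], atol=1e-12)
        np.testing.assert_allclose(fwd["log2fc"], -rev["log2fc"], atol=1e-12)

    def test_asymptotic_matches_reference_implementation(self):
        """Tie-corrected normal approximation agrees with the scipy test."""
        import scipy.stats

        rng = np.random.default_rng(5)
        x = np.round(rng.random(15), 1)
        y = np.round(rng.random(20) + 0.2, 1)
        m = _lognorm(np.array([np.r_[x, y]]), ["G"],
                     [f"a{i}" for i in range(15)] + [f"b{i}" for i in range(20)])
        de = cellstate.rank_sum_de(m, [f"a{i}" for i in range(15)],
                                   [f"b{i}" for i in range(20)], lfc_cut=0.0)
        ref = scipy.stats.mannwhitneyu(x, y, alternative="two-sided",
                                       method="asymptotic", use_continuity=False)
        assert de.loc[0, "p"] == pytest.approx(ref.pvalue, abs=1e-10)

    def test_overlapping_groups_rejected(self):
        m = _lognorm(np.random.default_rng(6).random((2, 6)), cells=list("abcdef"))
        with pytest.raises(ValueError, match="disjoint"):
            cellstate.rank_sum_de(m, list("abc"), list("cde"))


@settings(deadline=None, max_examples=25)
@given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=30))
def test_bh_adjustment_matches_stepup_oracle(pvals):
    """BH output equals the definitional step-up (cumulative min from largest)."""
    from escreg.stats import bh_adjust

    p = np.asarray(pvals)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    np.testing.assert_allclose(bh_adjust(p), adj, atol=1e-12)
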