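import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pairsplice import (StudyDesign, TranscriptCountMatrix, adapt_external_results,
                        fit_moderated_expression, fit_precision_weights, fit_splicing,
                        logcpm, run_differential, simulate_counts)
from pairsplice.differential import PrecisionWeights, _wls_condition_fit


def _uniform_weights(shape):
    return PrecisionWeights(weights=np.ones(shape), trend_x=np.array([0.0]),
                            trend_y=np.array([1.0]))


class TestLogcpm:
    def test_zero_count_unit_library(self):
        got = logcpm(np.array([[0], [10**6]]))  # library size 1e6
        val = np.log2((0 + 0.5) / (10**6 + 1) * 1e6)
        assert got[0, 0] == pytest.approx(val, abs=1e-9)
        assert val == pytest.approx(-1.0000014, abs=1e-6)

    def test_count_100_in_unit_library(self):
        got = logcpm(np.array([[100], [10**6 - 100]]))
        assert got[0, 0] == pytest.approx(np.log2(100.5 / (10**6 + 1) * 1e6), abs=1e-9)
        assert got[0, 0] == pytest.approx(6.651, abs=1e-3)

    def test_doubling_counts_and_library_near_invariant(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(1000, size=(500, 4))
        a = logcpm(counts)
        b = logcpm(2 * counts)
        assert np.max(np.abs(a - b)) < 1e-3

    def test_all_zero_sample_rejected(self):
        counts = np.array([[1, 0], [2, 0]])
        with pytest.raises(ValueError, match="all-zero"):
            logcpm(counts)


class TestPrecisionWeights:
    def test_homoscedastic_data_gives_near_uniform_weights(self, design_6v6):
        rng = np.random.default_rng(1)
        Y = rng.normal(8.0, 1.0, size=(300, 12)) + rng.normal(0, 2, size=(300, 1))
        w = fit_precision_weights(Y, design_6v6)
        cv = w.weights.std() / w.weights.mean()
        assert cv < 0.2

    def test_planted_variance_trend_recovered(self, design_6v6):
        rng = np.random.default_rng(2)
        means = np.linspace(2, 12, 400)
        sd = 2.0 / np.sqrt(2.0**means / 8)  # decreasing variance with mean
        Y = means[:, None] + rng.normal(size=(400, 12)) * sd[:, None]
        w = fit_precision_weights(Y, design_6v6)
        med_w = np.median(w.weights, axis=1)
        rho = stats.spearmanr(means, med_w).statistic
        assert rho > 0.8

    def test_permutation_equivariance(self, design_6v6):
        rng = np.random.default_rng(3)
        Y = rng.normal(6, 1, size=(100, 12)) + rng.normal(0, 2, size=(100, 1))
        w = fit_precision_weights(Y, design_6v6)
        perm = rng.permutation(100)
        w_p = fit_precision_weights(Y[perm], design_6v6)
        np.testing.assert_allclose(w_p.weights, w.weights[perm], rtol=1e-10)

    def test_degenerate_trend_warns_uniform(self, design_6v6):
        Y = np.full((20, 12), 5.0)
        with pytest.warns(UserWarning, match="degenerate"):
            w = fit_precision_weights(Y, design_6v6)
        assert np.all(w.weights == 1.0)

    def test_too_few_transcripts_rejected(self, design_6v6):
        with pytest.raises(ValueError, match=">= 10 transcripts"):
            fit_precision_weights(np.ones((5, 12)), design_6v6)


class TestModeratedExpression:
    def test_prior_df_zero_equals_ordinary_wls(self, design_6v6):
        """With no shrinkage the moderated t must equal per-transcript OLS."""
        rng = np.random.default_rng(4)
        Y = rng.normal(5, 1, size=(200, 12))
        res = fit_moderated_expression(Y, _uniform_weights(Y.shape), design_6v6,
                                       prior_df=0)
        X = design_6v6.design_matrix().to_numpy()
        cond = X[:, 1]
        for i in rng.choice(200, size=20, replace=False):
            slope, _, _, p, _ = stats.linregress(cond, Y[i])
            assert res.loc[i, "lfc"] == pytest.approx(slope, rel=1e-8)
            assert res.loc[i, "p_value"] == pytest.approx(p, rel=1e-8)

    def test_prior_df_infinite_pools_variance(self, design_6v6):
        rng = np.random.default_rng(5)
        Y = rng.normal(5, 1, size=(100, 12))
        res = fit_moderated_expression(Y, _uniform_weights(Y.shape), design_6v6,
                                       prior_df=np.inf)
        beta, u2, s2, df = _wls_condition_fit(Y, np.ones_like(Y),
                                              design_6v6.design_matrix().to_numpy(), 1)
        ratio = res["se"].to_numpy() ** 2 / u2
        np.testing.assert_allclose(ratio, ratio[0], rtol=1e-9)

    def test_null_type_one_error_calibrated(self, design_6v6):
        rng = np.random.default_rng(6)
        Y = rng.normal(5, 1, size=(5000, 12))
        res = fit_moderated_expression(Y, _uniform_weights(Y.shape), design_6v6)
        frac = (res["p_value"] < 0.05).mean()
        assert 0.03 <= frac <= 0.07

    def test_too_few_replicates_rejected(self):
        design = StudyDesign(("a", "b", "c", "d"), ("x", "x", "y", "y"), "x", "y",
                             known_covariates=pd.DataFrame(
                                 {"c1": [0.1, 0.9, 0.4, 0.7],
                                  "c2": [0.5, 0.2, 0.8, 0.3]},
                                 index=["a", "b", "c", "d"]))
        Y = np.random.default_rng(0).normal(size=(10, 4))
        with pytest.raises(ValueError, match="replicates"):
            fit_moderated_expression(Y, _uniform_weights(Y.shape), design)


class TestSplicing:
    def _gene_of(self, n_genes, tx_per_gene):
        gene_of = {}
        ids = []
        for g in range(n_genes):
            for t in range(tx_per_gene):
                tid = f"g{g}t{t}"
                ids.append(tid)
                gene_of[tid] = f"g{g}"
        return ids, gene_of

    def test_shared_shift_produces_no_relative_change(self, design_6v6):
        rng = np.random.default_rng(7)
        ids, gene_of = self._gene_of(150, 2)
        Y = rng.normal(5, 0.3, size=(300, 12))
        cond = design_6v6.condition_indicator
        Y += cond[None, :] * 1.0  # both transcripts shift by +1
        res = fit_splicing(Y, _uniform_weights(Y.shape), design_6v6, gene_of,
                           transcript_ids=ids)
        assert np.abs(res["lfc"]).mean() < 0.3
        frac = (res["p_value"] < 0.05).mean()
        assert 0.01 <= frac <= 0.10

    def test_opposite_shifts_detected(self, design_6v6):
        rng = np.random.default_rng(8)
        ids, gene_of = self._gene_of(50, 2)
        Y = rng.normal(5, 0.3, size=(100, 12))
        cond = design_6v6.condition_indicator
        Y[::2] += cond[None, :] * 1.0
        Y[1::2] -= cond[None, :] * 1.0
        res = fit_splicing(Y, _uniform_weights(Y.shape), design_6v6, gene_of,
                           transcript_ids=ids)
        assert (res["p_value"] < 0.05).mean() > 0.9

    def test_single_isoform_gene_absent_from_splicing(self, design_6v6):
        rng = np.random.default_rng(9)
        ids = ["gA_t1", "gA_t2", "gB_t1"]
        gene_of = {"gA_t1": "gA", "gA_t2": "gA", "gB_t1": "gB"}
        Y = rng.normal(5, 1, size=(3, 12))
        res = fit_splicing(Y, _uniform_weights(Y.shape), design_6v6, gene_of,
                           transcript_ids=ids)
        assert set(res["gene_id"]) == {"gA"}
        expr = fit_moderated_expression(Y, _uniform_weights(Y.shape), design_6v6,
                                        transcript_ids=ids, gene_of=gene_of)
        assert "gB" in set(expr["gene_id"])

    def test_missing_gene_map_entry_rejected(self, design_6v6):
        Y = np.random.default_rng(0).normal(size=(2, 12))
        with pytest.raises(ValueError, match="gene map"):
            fit_splicing(Y, _uniform_weights(Y.shape), design_6v6, {"t0": "g"},
                         transcript_ids=["t0", "t1"])

    def test_centering_identity_with_effective_weights(self, design_6v6):
        """The leave-one-out contrast satisfies sum_t w_t(W-w_t)/W * rel_t = 0
        per gene (the algebraic centering identity of the contrast)."""
        rng = np.random.default_rng(10)
        ids, gene_of = self._gene_of(40, 3)
        Y = rng.normal(5, 1, size=(120, 12)) + rng.normal(0, 1, (120, 1))
        w = fit_precision_weights(Y, design_6v6)
        res = fit_splicing(Y, w, design_6v6, gene_of, transcript_ids=ids)
        X = design_6v6.design_matrix().to_numpy()
        beta, u2, s2, df = _wls_condition_fit(Y, w.weights, X, 1)
        prec = pd.Series(1.0 / u2, index=ids)
        for gene, grp in res.groupby("gene_id"):
            wts = prec[grp["transcript_id"]].to_numpy()
            W = wts.sum()
            eff = wts * (W - wts) / W
            assert abs(np.sum(eff * grp["lfc"].to_numpy())) < 1e-8 * np.abs(
                grp["lfc"]).max() * W


class TestRunDifferential:
    def test_shared_design_and_backgrounds(self):
        tcm, design, _ = simulate_counts(n_genes=150, seed=0)
        tcm_f = __import__("pairsplice").filter_low_expression(tcm)
        res = run_differential(tcm_f, design)
        expr = res[res["analysis"] == "expression"]
        splice = res[res["analysis"] == "splicing"]
        assert set(expr["transcript_id"]) == set(tcm_f.transcript_ids)
        multi = tcm_f.multi_isoform_genes()
        assert set(splice["gene_id"]) == multi & set(expr["gene_id"])
        # both analyses share base means per transcript
        merged = expr.merge(splice, on="transcript_id", suffixes=("_e", "_s"))
        np.testing.assert_allclose(merged["base_mean_e"], merged["base_mean_s"])


class TestAdapter:
    def test_external_table_validated_and_standardized(self):
        tbl = pd.DataFrame({
            "transcript_id": ["t1"], "gene_id": ["g1"], "base_mean": [10.0],
            "lfc": [1.0], "p_value": [0.01], "extra": ["x"]})
        out = adapt_external_results(tbl, "expression")
        assert list(out.columns) == ["transcript_id", "gene_id", "base_mean",
                                     "lfc", "se", "t_stat", "p_value", "analysis"]
        assert out.loc[0, "analysis"] == "expression"

    def test_rejects_bad_p_and_missing_columns(self):
        with pytest.raises(ValueError, match="missing column"):
            adapt_external_results(pd.DataFrame({"transcript_id": []}), "splicing")
        tbl = pd.DataFrame({"transcript_id": ["t"], "gene_id": ["g"],
                            "base_mean": [1.0], "lfc": [0.0], "p_value": [1.5]})
        with pytest.raises(ValueError, match="p_value"):
            adapt_external_results(tbl, "expression")
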