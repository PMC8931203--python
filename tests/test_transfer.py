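"""Sparse pseudotime transfer: ranking, signature, lasso oracle, prediction."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

import bulktime as bt
from bulktime.transfer import lasso_fit, rank_trajectory_genes, select_signature
from bulktime.trajectory import GeneSignificance

from conftest import SEED_B, align_sign, recovery_config


def flags(gene_ids, flagged):
    n = len(gene_ids)
    return GeneSignificance(
        gene_ids=list(gene_ids),
        nonzero_lambda=np.asarray(flagged, bool),
        nonzero_beta=np.zeros(n, bool),
        lam_lo=np.zeros(n), lam_hi=np.zeros(n),
        beta_lo=np.zeros(n), beta_hi=np.zeros(n), k=2.0,
    )


def orthonormal_design(n, p, seed=0):
    """Columns zero-mean with X'X = n*I, so the lasso is soft-thresholding."""
    rng = np.random.default_rng(seed)
    A = rng.normal(size=(n, p + 1))
    A[:, 0] = 1.0
    Q, _ = np.linalg.qr(A)
    return Q[:, 1 : p + 1] * np.sqrt(n)


def prox_gradient_lasso(X, y, penalty, n_steps=200000, tol=1e-14):
    """Independent proximal-gradient solver for the same lasso objective."""
    n, p = X.shape
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    L = np.linalg.norm(Xc, 2) ** 2 / n
    w = np.zeros(p)
    for _ in range(n_steps):
        grad = Xc.T @ (Xc @ w - yc) / n
        w_new = w - grad / L
        w_new = np.sign(w_new) * np.maximum(np.abs(w_new) - penalty / L, 0.0)
        if np.max(np.abs(w_new - w)) < tol:
            w = w_new
            break
        w = w_new
    b = y.mean() - X.mean(axis=0) @ w
    return w, b


def lasso_objective(X, y, w, b, penalty):
    n = len(y)
    return 0.5 * np.mean((y - X @ w - b) ** 2) + penalty * np.abs(w).sum()


class TestRanking:
    def test_gene_equal_to_z_tops_positive(self):
        rng = np.random.default_rng(0)
        z = rng.normal(size=40)
        vals = np.vstack([z, -z + 0.01 * rng.normal(size=40), rng.normal(size=40)])
        expr = bt.ExpressionMatrix(["gz", "gneg", "gnoise"], [f"s{i}" for i in range(40)], vals)
        ranked = rank_trajectory_genes(expr, z, flags(expr.gene_ids, [True] * 3))
        pos = ranked[ranked["group"] == "positive"]
        neg = ranked[ranked["group"] == "negative"]
        assert pos.iloc[0]["gene_id"] == "gz"
        assert pos.iloc[0]["r"] == pytest.approx(1.0)
        assert neg.iloc[0]["gene_id"] == "gneg"

    def test_zero_variance_gene_excluded(self):
        z = np.linspace(-1, 1, 10)
        vals = np.vstack([z, np.full(10, 5.0)])
        expr = bt.ExpressionMatrix(["g1", "gflat"], [f"s{i}" for i in range(10)], vals)
        ranked = rank_trajectory_genes(expr, z, flags(expr.gene_ids, [True, True]))
        assert "gflat" not in set(ranked["gene_id"])

    def test_top_ranked_enriched_for_true_informative(self, cohort_a, fit_a):
        expr, _, truth = cohort_a
        fit, _ = fit_a
        sig = bt.significant_genes(fit)
        ranked = rank_trajectory_genes(expr, fit.z_mean, sig)
        top = ranked.groupby("group").head(50)["gene_id"]
        idx = {g: i for i, g in enumerate(truth.gene_ids)}
        frac = np.mean([truth.lam[idx[g]] != 0 for g in top])
        assert frac >= 0.8


class TestSignatureSelection:
    def _ranked(self, n_pos, n_neg):
        rows = [(f"p{i}", 0.9 - i * 1e-3, "positive") for i in range(n_pos)]
        rows += [(f"n{i}", -(0.9 - i * 1e-3), "negative") for i in range(n_neg)]
        return pd.DataFrame(rows, columns=["gene_id", "r", "group"])

    def test_deficit_truncation(self):
        assert len(select_signature(self._ranked(150, 60), n_each=100)) == 160

    def test_full_groups_give_200(self):
        assert len(select_signature(self._ranked(120, 130), n_each=100)) == 200

    def test_ties_broken_lexicographically(self):
        rows = [(g, 0.5, "positive") for g in ["gb", "ga", "gc"]]
        ranked = pd.DataFrame(rows, columns=["gene_id", "r", "group"])
        # re-sort through rank_trajectory_genes' convention: equal |r| -> id order
        ranked = ranked.sort_values(["gene_id"]).reset_index(drop=True)
        assert select_signature(ranked, n_each=2) == ["ga", "gb"]


class TestLassoSolver:
    def test_zero_penalty_is_ols(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(50, 1))
        y = 2.0 * x[:, 0] + 1.0 + 0.01 * rng.normal(size=50)
        w, b = lasso_fit(x, y, 0.0)
        slope = np.polyfit(x[:, 0], y, 1)[0]
        assert w[0] == pytest.approx(slope, abs=1e-6)

    @pytest.mark.parametrize("penalty", [0.05, 0.2, 0.8])
    def test_orthonormal_soft_threshold(self, penalty):
        n, p = 80, 10
        X = orthonormal_design(n, p, seed=2)
        rng = np.random.default_rng(3)
        y = X @ rng.normal(size=p) + 0.5 + 0.1 * rng.normal(size=n)
        w, _ = lasso_fit(X, y, penalty)
        ols = X.T @ (y - y.mean()) / n
        soft = np.sign(ols) * np.maximum(np.abs(ols) - penalty, 0.0)
        np.testing.assert_allclose(w, soft, atol=1e-6)

    def test_objective_matches_proximal_gradient(self):
        rng = np.random.default_rng(4)
        n, p = 60, 15
        X = rng.normal(size=(n, p))
        y = X[:, 0] - 2 * X[:, 3] + 0.3 * rng.normal(size=n)
        for penalty in (0.02, 0.1):
            w1, b1 = lasso_fit(X, y, penalty)
            w2, b2 = prox_gradient_lasso(X, y, penalty)
            f1 = lasso_objective(X, y, w1, b1, penalty)
            f2 = lasso_objective(X, y, w2, b2, penalty)
            assert abs(f1 - f2) <= 1e-6

    def test_support_shrinks_along_path(self):
        rng = np.random.default_rng(5)
        n, p = 70, 12
        X = rng.normal(size=(n, p))
        y = X @ rng.normal(size=p) + 0.2 * rng.normal(size=n)
        grid = np.geomspace(1e-3, 2.0, 25)
        sizes = [int(np.sum(lasso_fit(X, y, pen)[0] != 0)) for pen in grid]
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))


@pytest.fixture(scope="module")
def model_and_data(cohort_a, fit_a):
    expr, _, _ = cohort_a
    fit, _ = fit_a
    sig = bt.significant_genes(fit)
    ranked = rank_trajectory_genes(expr, fit.z_mean, sig)
    genes = select_signature(ranked)
    expr_sig = expr.subset_genes(genes)
    model = bt.fit_transfer(expr_sig, fit.z_mean, seed=2)
    return model, expr_sig, fit


class TestTransferModel:
    def test_chosen_penalty_on_curve(self, model_and_data):
        model, _, _ = model_and_data
        assert any(np.isclose(model.chosen_penalty, p) for p, _ in model.cv_curve)

    def test_prediction_on_training_data(self, model_and_data):
        model, expr_sig, fit = model_and_data
        pred = bt.predict_pseudotime(model, expr_sig)
        manual = expr_sig.values.T @ model.coefficients + model.intercept
        np.testing.assert_allclose(pred.to_numpy(), manual, rtol=1e-9)

    def test_all_zero_expression_predicts_intercept(self, model_and_data):
        model, expr_sig, _ = model_and_data
        zeros = bt.ExpressionMatrix(
            expr_sig.gene_ids, ["a", "b"], np.zeros((expr_sig.n_genes, 2))
        )
        pred = bt.predict_pseudotime(model, zeros)
        np.testing.assert_allclose(pred.to_numpy(), model.intercept, rtol=1e-12)

    def test_row_permutation_invariance(self, model_and_data):
        model, expr_sig, _ = model_and_data
        rng = np.random.default_rng(6)
        perm = rng.permutation(expr_sig.n_genes)
        permuted = bt.ExpressionMatrix(
            [expr_sig.gene_ids[i] for i in perm],
            expr_sig.sample_ids,
            expr_sig.values[perm],
        )
        p1 = bt.predict_pseudotime(model, expr_sig)
        p2 = bt.predict_pseudotime(model, permuted)
        np.testing.assert_allclose(p1.to_numpy(), p2.to_numpy(), rtol=1e-12)

    def test_low_coverage_is_error(self, model_and_data):
        model, expr_sig, _ = model_and_data
        few = expr_sig.subset_genes(expr_sig.gene_ids[: expr_sig.n_genes // 4])
        with pytest.raises(ValueError, match="50%"):
            bt.predict_pseudotime(model, few)

    def test_transfer_recovery_on_independent_cohort(self, model_and_data, cohort_b):
        model, _, _ = model_and_data
        expr_b, _, truth_b = cohort_b
        pred = bt.predict_pseudotime(model, expr_b)
        assert abs(spearmanr(pred.to_numpy(), truth_b.z_true)[0]) >= 0.8

    def test_stage_ordering_preserved(self, model_and_data, cohort_b):
        model, _, _ = model_and_data
        expr_b, clin_b, truth_b = cohort_b
        pred = align_sign(
            bt.predict_pseudotime(model, expr_b).to_numpy(), truth_b.z_true
        )
        stages = clin_b.table["overall_stage"].to_numpy()
        means = [pred[stages == s].mean() for s in ["I", "II", "III", "IV"]]
        assert all(a < b for a, b in zip(means, means[1:]))

    def test_too_few_samples_error(self, cohort_a):
        expr, _, _ = cohort_a
        small = expr.subset_samples(expr.sample_ids[:20])
        with pytest.raises(ValueError, match="30 samples"):
            bt.fit_transfer(small, np.zeros(20))
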