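"""Project pseudotime onto a new cohort via a sparse linear signature.

Genes with significant pseudotime dependency are ranked by their Pearson
correlation with the fitted pseudotime, the top ``n_each`` of the
positive and negative correlation groups (default 100 + 100 = 200 genes)
form the signature, and an L1-penalized (lasso) linear model — solved by
cyclic coordinate descent over a logarithmic penalty path, with the
penalty chosen by k-fold cross-validation inside a 2:1 train/validation
split — predicts pseudotime from signature-gene expression in any cohort
sharing enough of the signature.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import Lasso, LassoCV
from sklearn.model_selection import KFold, train_test_split

from .datatypes import ExpressionMatrix
from .trajectory import GeneSignificance

logger = logging.getLogger("bulktime")

__all__ = [
    "TransferModel",
    "rank_trajectory_genes",
    "select_signature",
    "lasso_fit",
    "fit_transfer",
    "predict_pseudotime",
]


@dataclass
class TransferModel:
    """Sparse linear pseudotime predictor for new cohorts."""

    signature_genes: list
    intercept: float
    coefficients: np.ndarray
    gene_means: np.ndarray          # training means, used to impute missing genes
    chosen_penalty: float
    cv_curve: list                  # (penalty, mean CV MSE) pairs
    validation_mse: float
    train_ids: list
    validation_ids: list

    def __post_init__(self) -> None:
        if len(self.signature_genes) > 200:
            raise ValueError("signature exceeds 200 genes")
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.coefficients) != len(self.signature_genes):
            raise ValueError("coefficient length does not match signature")
        penalties = [p for p, _ in self.cv_curve]
        if not any(np.isclose(self.chosen_penalty, p) for p in penalties):
            raise ValueError("chosen penalty not on the CV curve")

    def to_json(self, path) -> None:
        obj = {
            "signature_genes": self.signature_genes,
            "intercept": self.intercept,
            "coefficients": self.coefficients.tolist(),
            "gene_means": np.asarray(self.gene_means).tolist(),
            "chosen_penalty": self.chosen_penalty,
            "cv_curve": [[float(a), float(b)] for a, b in self.cv_curve],
            "validation_mse": self.validation_mse,
            "train_ids": self.train_ids,
            "validation_ids": self.validation_ids,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "TransferModel":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(
            signature_genes=obj["signature_genes"],
            intercept=float(obj["intercept"]),
            coefficients=np.asarray(obj["coefficients"]),
            gene_means=np.asarray(obj["gene_means"]),
            chosen_penalty=float(obj["chosen_penalty"]),
            cv_curve=[tuple(p) for p in obj["cv_curve"]],
            validation_mse=float(obj["validation_mse"]),
            train_ids=obj["train_ids"],
            validation_ids=obj["validation_ids"],
        )


def rank_trajectory_genes(
    expr: ExpressionMatrix, z, sig: GeneSignificance
) -> pd.DataFrame:
    """Pearson correlation with pseudotime for each significant gene.

    Returns a table (gene_id, r, group) with group in {positive, negative},
    each group sorted by |r| descending. Zero-variance genes are excluded
    with a warning.
    """
    z = np.asarray(z, dtype=float)
    if len(z) != expr.n_samples:
        raise ValueError("z length does not match sample count")
    flagged = [g for g, f in zip(sig.gene_ids, sig.nonzero_lambda) if f]
    rows = []
    idx = {g: i for i, g in enumerate(expr.gene_ids)}
    for g in flagged:
        if g not in idx:
            continue
        v = expr.values[idx[g]]
        if np.std(v) == 0 or np.std(z) == 0:
            logger.warning("gene %s has zero variance; excluded from ranking", g)
            continue
        r = float(stats.pearsonr(v, z)[0])
        rows.append((g, r, "positive" if r >= 0 else "negative"))
    tab = pd.DataFrame(rows, columns=["gene_id", "r", "group"])
    # |r| descending within group; gene id breaks ties deterministically
    tab["abs_r"] = tab["r"].abs()
    tab = tab.sort_values(["group", "abs_r", "gene_id"], ascending=[True, False, True])
    return tab.drop(columns="abs_r").reset_index(drop=True)


def select_signature(ranked: pd.DataFrame, n_each: int = 100) -> list:
    """Top ``n_each`` genes of each correlation group (positive + negative)."""
    genes = []
    for group in ("positive", "negative"):
        grp = ranked[ranked["group"] == group]
        take = list(grp["gene_id"].head(n_each))
        if len(take) < n_each:
            logger.warning(
                "%s correlation group has only %d genes (wanted %d)",
                group, len(take), n_each,
            )
        genes.extend(take)
    return genes


def lasso_fit(X: np.ndarray, y: np.ndarray, penalty: float) -> tuple:
    """Solve min_w 1/(2n)||y - Xw - b||^2 + penalty*||w||_1 by coordinate descent.

    Thin wrapper around the cyclic coordinate-descent solver; returns
    (coefficients, intercept).
    """
    if penalty <= 0:
        # unpenalized least squares with intercept
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        w = np.linalg.lstsq(Xc, yc, rcond=None)[0]
        return w, float(y.mean() - X.mean(axis=0) @ w)
    model = Lasso(alpha=penalty, fit_intercept=True, max_iter=100000, tol=1e-10)
    model.fit(X, y)
    return model.coef_.copy(), float(model.intercept_)


def _penalty_grid(Xs: np.ndarray, y: np.ndarray, n_grid: int = 100) -> np.ndarray:
    n = Xs.shape[0]
    lam_max = np.max(np.abs(Xs.T @ (y - y.mean()))) / n
    if not np.isfinite(lam_max) or lam_max <= 0:
        raise ValueError("degenerate penalty path: lambda_max is zero")
    return np.geomspace(lam_max, 1e-4 * lam_max, n_grid)


def fit_transfer(
    expr_sig: ExpressionMatrix,
    z,
    split_ratio: float = 2.0 / 3.0,
    n_folds: int = 10,
    seed: int = 0,
    n_grid: int = 100,
) -> TransferModel:
    """Train the sparse pseudotime predictor on signature-gene expression.

    Samples are split 2:1 into training/validation (seeded, stratified on
    pseudotime tertiles so both splits span the trajectory). Predictors
    are standardized on the training split; the penalty minimizing mean
    squared error over ``n_folds`` CV folds within training is chosen;
    coefficients are returned on the original expression scale.
    """
    z = np.asarray(z, dtype=float)
    n = expr_sig.n_samples
    if n < 30:
        raise ValueError("need >= 30 samples to fit the transfer model")
    if len(z) != n:
        raise ValueError("z length does not match sample count")

    tertile = pd.qcut(z, 3, labels=False, duplicates="drop")
    idx_train, idx_val = train_test_split(
        np.arange(n),
        test_size=1.0 - split_ratio,
        random_state=int(seed) % (2**32),
        stratify=tertile,
    )
    idx_train, idx_val = np.sort(idx_train), np.sort(idx_val)

    X = expr_sig.values.T  # samples x genes
    Xtr, ytr = X[idx_train], z[idx_train]
    mu = Xtr.mean(axis=0)
    sd = Xtr.std(axis=0, ddof=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    Xs = (Xtr - mu) / sd_safe

    grid = _penalty_grid(Xs, ytr, n_grid)
    cv = KFold(n_splits=n_folds, shuffle=True, random_state=int(seed) % (2**32))
    model = LassoCV(alphas=grid, cv=cv, fit_intercept=True, max_iter=100000, tol=1e-8)
    model.fit(Xs, ytr)
    if np.all(model.coef_ == 0):
        logger.warning("all transfer coefficients are zero at the chosen penalty")

    mse_curve = model.mse_path_.mean(axis=1)
    # LassoCV sorts alphas descending internally
    order = np.argsort(model.alphas_)[::-1]
    cv_curve = [(float(a), float(m)) for a, m in zip(model.alphas_[order], mse_curve[order])]

    coef = model.coef_ / sd_safe
    intercept = float(model.intercept_ - np.sum(model.coef_ * mu / sd_safe))

    Xval = X[idx_val]
    pred_val = Xval @ coef + intercept
    val_mse = float(np.mean((pred_val - z[idx_val]) ** 2))

    return TransferModel(
        signature_genes=list(expr_sig.gene_ids),
        intercept=intercept,
        coefficients=coef,
        gene_means=mu,
        chosen_penalty=float(model.alpha_),
        cv_curve=cv_curve,
        validation_mse=val_mse,
        train_ids=[expr_sig.sample_ids[i] for i in idx_train],
        validation_ids=[expr_sig.sample_ids[i] for i in idx_val],
    )


def predict_pseudotime(model: TransferModel, expr_new: ExpressionMatrix):
    """Predicted pseudotime per sample of a new cohort.

    Signature genes absent from the new cohort are imputed at their
    training-set mean (contributing the average effect); fails if fewer
    than half the signature genes are present.
    """
    idx = {g: i for i, g in enumerate(expr_new.gene_ids)}
    present = [g in idx for g in model.signature_genes]
    frac = float(np.mean(present))
    if frac < 0.5:
        raise ValueError(
            f"only {frac:.0%} of signature genes present in new cohort (need >= 50%)"
        )
    if frac < 1.0:
        logger.warning(
            "imputing %d missing signature genes at training means",
            int(np.sum(~np.asarray(present))),
        )
    n = expr_new.n_samples
    Xg = np.empty((len(model.signature_genes), n))
    means = np.asarray(model.gene_means, dtype=float)
    for j, g in enumerate(model.signature_genes):
        Xg[j] = expr_new.values[idx[g]] if g in idx else means[j]
    pred = Xg.T @ model.coefficients + model.intercept
    return pd.Series(pred, index=expr_new.sample_ids, name="pseudotime")
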