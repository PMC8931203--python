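"""Highly variable gene selection via a CV^2-vs-mean reference curve.

Per gene the squared coefficient of variation CV^2 = var/mean^2 is
computed and a gamma-family GLM with identity link fits the reference
curve ``cv2 ~ a1/mean + a0`` (the classical Brennecke-style mean-variance
reference). Deviation from the curve is tested with the variance-ratio
chi-squared approximation ``T = (n-1) * cv2 / expected_cv2`` on n-1
degrees of freedom; genes with p below the cut (default 0.001) are
selected as highly variable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .datatypes import ExpressionMatrix

logger = logging.getLogger("bulktime")

__all__ = ["GeneVariability", "gene_stats", "fit_variability_reference", "hvg_test", "select_hvgs"]

#: floor for the predicted reference CV^2
EPS_EXPECTED = 1e-8


@dataclass
class GeneVariability:
    """Per-gene variability table; columns filled in as the stages run.

    ``table`` columns: gene_id, mean, variance, cv2, excluded,
    then expected_cv2, statistic, p_value, selected once the reference
    curve is fitted and the test applied.
    """

    table: pd.DataFrame
    n_samples: int
    curve: tuple | None = None

    @property
    def selected_genes(self) -> list:
        if "selected" not in self.table.columns:
            raise ValueError("run hvg_test before asking for selected genes")
        return list(self.table.loc[self.table["selected"], "gene_id"])


def gene_stats(expr: ExpressionMatrix, metric: str = "cv2") -> GeneVariability:
    """Per-gene mean, unbiased variance and CV^2 (or CV).

    Genes with non-positive mean are flagged ``excluded``: their CV is
    undefined on the log2(x+1) scale.
    """
    if expr.n_samples < 2:
        raise ValueError("variability needs at least 2 samples")
    if metric not in ("cv2", "cv"):
        raise ValueError(f"unknown variability metric {metric!r}")
    m = expr.values.mean(axis=1)
    v = expr.values.var(axis=1, ddof=1)
    excluded = m <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        cv2 = np.where(excluded, np.nan, v / np.square(m))
    if metric == "cv":
        cv2 = np.sqrt(cv2)
    table = pd.DataFrame(
        {
            "gene_id": expr.gene_ids,
            "mean": m,
            "variance": v,
            "cv2": cv2,
            "excluded": excluded,
        }
    )
    if excluded.any():
        logger.warning("%d genes with non-positive mean excluded from HVG", excluded.sum())
    return GeneVariability(table, n_samples=expr.n_samples)


def fit_variability_reference(gv: GeneVariability) -> tuple:
    """Fit the reference curve ``cv2 = a1/mean + a0`` by gamma GLM.

    Identity-link gamma regression of CV^2 on 1/mean, matching the
    standard mean-variability reference for bulk log expression. Returns
    (a0, a1) and stores predicted values (floored at a small positive
    epsilon) in the table.
    """
    tab = gv.table
    usable = (~tab["excluded"]) & (tab["cv2"] > 0) & np.isfinite(tab["cv2"])
    if usable.sum() < 10:
        raise ValueError(f"need >= 10 usable genes to fit the reference, have {usable.sum()}")
    y = tab.loc[usable, "cv2"].to_numpy()
    inv_m = 1.0 / tab.loc[usable, "mean"].to_numpy()
    exog = np.column_stack([np.ones_like(inv_m), inv_m])
    import warnings

    with warnings.catch_warnings():
        # identity link is the canonical choice here despite the domain caveat,
        # and a perfect (noiseless) fit trips a separation warning
        warnings.simplefilter("ignore")
        model = sm.GLM(y, exog, family=sm.families.Gamma(link=sm.families.links.Identity()))
        start = np.array([0.5 * np.median(y), 0.5 * np.median(y) / np.median(inv_m)])
        try:
            res = model.fit(start_params=start, maxiter=200)
        except Exception:
            # identity-link gamma can step outside the positive-mean region;
            # retry from an OLS start
            ols = np.linalg.lstsq(exog, y, rcond=None)[0]
            res = model.fit(start_params=np.clip(ols, 1e-8, None), maxiter=200)
    if not res.converged and abs(res.deviance) > 1e-10:
        raise RuntimeError(
            f"gamma GLM did not converge after {res.fit_history['iteration']} "
            f"iterations (deviance {res.deviance:.4g})"
        )
    a0, a1 = (float(p) for p in res.params)
    gv.curve = (a0, a1)
    with np.errstate(divide="ignore"):
        expected = a1 / tab["mean"].to_numpy() + a0
    expected = np.where(tab["excluded"], np.nan, np.maximum(expected, EPS_EXPECTED))
    gv.table = tab.assign(expected_cv2=expected)
    return a0, a1


def hvg_test(gv: GeneVariability, p_cut: float = 0.001) -> GeneVariability:
    """Chi-squared deviation test from the fitted reference curve.

    ``T = (n-1) * cv2 / expected_cv2`` is referred to the upper tail of a
    chi-squared distribution with n-1 degrees of freedom; genes with
    p < ``p_cut`` are selected.
    """
    if gv.curve is None or "expected_cv2" not in gv.table.columns:
        raise ValueError("fit_variability_reference must run before hvg_test")
    n = gv.n_samples
    if n < 2:
        raise ValueError("need >= 2 samples")
    tab = gv.table
    expected = tab["expected_cv2"].to_numpy()
    bad = (~tab["excluded"].to_numpy()) & ~(expected > 0)
    if bad.any():
        logger.warning("%d genes excluded: non-positive expected CV^2", bad.sum())
    usable = (~tab["excluded"].to_numpy()) & (expected > 0)
    stat = np.full(len(tab), np.nan)
    p = np.full(len(tab), np.nan)
    stat[usable] = (n - 1) * tab["cv2"].to_numpy()[usable] / expected[usable]
    p[usable] = stats.chi2.sf(stat[usable], df=n - 1)
    selected = np.where(usable, p < p_cut, False)
    gv.table = tab.assign(statistic=stat, p_value=p, selected=selected)
    return gv


def select_hvgs(
    expr: ExpressionMatrix, p_cut: float = 0.001, metric: str = "cv2"
) -> GeneVariability:
    """Convenience: stats -> reference fit -> test in one call."""
    gv = gene_stats(expr, metric=metric)
    fit_variability_reference(gv)
    return hvg_test(gv, p_cut=p_cut)
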