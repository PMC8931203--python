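"""Pseudotime-versus-phenotype statistics.

Correlations (Pearson via the t distribution, Spearman) with Bonferroni
multiplicity control; stage-group comparisons (t-test / ANOVA /
Wilcoxon rank-sum / Kruskal-Wallis); Kaplan-Meier survival with a
cutoff on pseudotime explored over the 10th-90th percentile candidates
by minimizing the two-group log-rank p. The minimized p is reported with
an explicit anti-conservative annotation — optimizing the cutoff inflates
significance, exactly as in explored-cutoff survival analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

logger = logging.getLogger("bulktime")

__all__ = [
    "AssociationResult",
    "SurvivalSplit",
    "correlate",
    "adjust_bonferroni",
    "correlate_table",
    "compare_groups",
    "survival_split_at",
    "km_split",
]


@dataclass
class AssociationResult:
    variable: str
    method: str
    r: float
    p: float
    p_adjusted: float
    n: int

    def __post_init__(self) -> None:
        if not -1.0 <= self.r <= 1.0 + 1e-12:
            raise ValueError(f"correlation {self.r} outside [-1,1]")
        if self.p_adjusted < self.p - 1e-12:
            raise ValueError("adjusted p below raw p")


@dataclass
class SurvivalSplit:
    """Cutoff-optimized two-group survival comparison."""

    cutoff: float
    group_sizes: tuple
    statistic: float
    p_value: float
    curves: dict           # group -> DataFrame(time, survival, at_risk)
    annotation: str = "cutoff-optimized, anti-conservative"

    def __post_init__(self) -> None:
        if min(self.group_sizes) < 1:
            raise ValueError("empty survival group")
        for name, cur in self.curves.items():
            s = cur["survival"].to_numpy()
            if (np.diff(s) > 1e-12).any() or s.min() < -1e-12 or s.max() > 1 + 1e-12:
                raise ValueError(f"invalid KM curve for group {name}")


def correlate(values, z, method: str = "pearson", name: str = "") -> AssociationResult:
    """Correlation between a phenotype and pseudotime, missing pairs dropped."""
    v = np.asarray(values, dtype=float)
    z = np.asarray(z, dtype=float)
    if v.shape != z.shape:
        raise ValueError("value/pseudotime length mismatch")
    keep = np.isfinite(v) & np.isfinite(z)
    v, z = v[keep], z[keep]
    if len(v) < 3:
        raise ValueError(f"need >= 3 paired observations, have {len(v)}")
    if np.std(v) == 0 or np.std(z) == 0:
        raise ValueError("zero variance input to correlation")
    if method == "pearson":
        r, p = stats.pearsonr(v, z)
    elif method == "spearman":
        r, p = stats.spearmanr(v, z)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return AssociationResult(name or "value", method, float(r), float(p), float(p), len(v))


def adjust_bonferroni(p_values) -> np.ndarray:
    """Bonferroni family-wise adjustment: min(1, m*p) elementwise."""
    p = np.asarray(p_values, dtype=float)
    return np.minimum(1.0, len(p) * p)


def correlate_table(table: pd.DataFrame, z, method: str = "pearson") -> pd.DataFrame:
    """Correlate every row of a variables x samples table with pseudotime,
    Bonferroni-adjusting across rows."""
    results = [
        correlate(table.loc[name].to_numpy(), z, method=method, name=str(name))
        for name in table.index
    ]
    adj = adjust_bonferroni([r.p for r in results])
    return pd.DataFrame(
        {
            "variable": [r.variable for r in results],
            "method": [r.method for r in results],
            "r": [r.r for r in results],
            "p_value": [r.p for r in results],
            "p_bonferroni": adj,
            "n": [r.n for r in results],
        }
    )


def compare_groups(z, labels, test: str = "ttest"):
    """Compare pseudotime across groups.

    ``ttest`` (Welch) and ``wilcoxon`` (rank-sum) require exactly 2 groups;
    ``anova`` and ``kruskal`` accept 2 or more. Missing labels are dropped.
    Returns (statistic, p, per-group summary table).
    """
    z = np.asarray(z, dtype=float)
    labels = pd.Series(labels).astype("object")
    keep = np.isfinite(z) & labels.notna().to_numpy()
    z, labels = z[keep], labels[keep]
    groups = [z[labels.to_numpy() == g] for g in pd.unique(labels)]
    names = list(pd.unique(labels))
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 members each")
    if test in ("ttest", "wilcoxon") and len(groups) != 2:
        raise ValueError(f"{test} requires exactly 2 groups, got {len(groups)}")
    if test == "ttest":
        if all(np.array_equal(groups[0], g) for g in groups[1:]):
            stat, p = 0.0, 1.0  # identical groups: no evidence, degenerate variance
        else:
            stat, p = stats.ttest_ind(groups[0], groups[1], equal_var=False)
    elif test == "anova":
        stat, p = stats.f_oneway(*groups)
    elif test == "wilcoxon":
        stat, p = stats.mannwhitneyu(groups[0], groups[1], alternative="two-sided")
    elif test == "kruskal":
        stat, p = stats.kruskal(*groups)
    else:
        raise ValueError(f"unknown test {test!r}")
    summary = pd.DataFrame(
        {
            "group": names,
            "n": [len(g) for g in groups],
            "mean": [float(np.mean(g)) for g in groups],
            "median": [float(np.median(g)) for g in groups],
        }
    )
    return float(stat), float(p), summary


def _km_curve(time, event) -> pd.DataFrame:
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    sf = kmf.survival_function_
    at_risk = kmf.event_table["at_risk"].reindex(sf.index).ffill()
    return pd.DataFrame(
        {
            "time": sf.index.to_numpy(dtype=float),
            "survival": sf.iloc[:, 0].to_numpy(dtype=float),
            "at_risk": at_risk.to_numpy(dtype=float),
        }
    )


def survival_split_at(z, surv_time, surv_event, cutoff: float) -> SurvivalSplit:
    """Two-group KM comparison at a fixed pseudotime cutoff (low: z <= cutoff)."""
    z = np.asarray(z, dtype=float)
    t = np.asarray(surv_time, dtype=float)
    e = np.asarray(surv_event, dtype=float)
    low = z <= cutoff
    if low.all() or (~low).all():
        raise ValueError(f"cutoff {cutoff} puts all samples on one side")
    res = logrank_test(t[low], t[~low], event_observed_A=e[low], event_observed_B=e[~low])
    curves = {"early": _km_curve(t[low], e[low]), "late": _km_curve(t[~low], e[~low])}
    return SurvivalSplit(
        cutoff=float(cutoff),
        group_sizes=(int(low.sum()), int((~low).sum())),
        statistic=float(res.test_statistic),
        p_value=float(res.p_value),
        curves=curves,
        annotation="fixed cutoff",
    )


def km_split(z, surv_time, surv_event, scan_range=(0.1, 0.9)) -> SurvivalSplit:
    """Two-group Kaplan-Meier split at the log-rank-optimal pseudotime cutoff.

    Candidate cutoffs are the observed pseudotime values between the
    ``scan_range`` quantiles; the cutoff minimizing the two-group log-rank
    p is returned, with the caveat that the minimized p is
    anti-conservative (recorded in ``annotation``).
    """
    z = np.asarray(z, dtype=float)
    t = np.asarray(surv_time, dtype=float)
    e = np.asarray(surv_event, dtype=float)
    keep = np.isfinite(z) & np.isfinite(t) & np.isfinite(e)
    z, t, e = z[keep], t[keep], e[keep]
    if len(z) < 20:
        raise ValueError("need >= 20 samples for a survival split")
    if e.sum() == 0:
        raise ValueError("no events in the cohort")
    lo, hi = np.quantile(z, scan_range)
    candidates = np.unique(z[(z >= lo) & (z <= hi)])
    best = None
    for c in candidates:
        low = z <= c
        if low.all() or (~low).all():
            continue
        res = logrank_test(t[low], t[~low], event_observed_A=e[low], event_observed_B=e[~low])
        if best is None or res.p_value < best[1]:
            best = (float(c), float(res.p_value), float(res.test_statistic), low)
    if best is None:
        raise ValueError("every candidate cutoff put all samples on one side")
    cutoff, p, statistic, low = best
    curves = {
        "early": _km_curve(t[low], e[low]),
        "late": _km_curve(t[~low], e[~low]),
    }
    return SurvivalSplit(
        cutoff=cutoff,
        group_sizes=(int(low.sum()), int((~low).sum())),
        statistic=statistic,
        p_value=p,
        curves=curves,
    )
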