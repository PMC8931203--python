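"""Single-sample signature enrichment and over-representation analysis.

``score_signatures`` produces a per-sample, per-cell-type score: genes
are ranked within each sample (average ranks on ties) and the score is
the standardized mean rank of the signature's member genes,

    score(S, j) = (mean_rank(S, j) - (G+1)/2) / sqrt((G+1)(G-|S|) / (12 |S|)),

which has exact mean 0 and sd 1 under random draws of S without
replacement, is positive when member genes are highly expressed, and is
invariant to any monotone transform of a sample's expression. It is a
deliberately generic stand-in for cell-type scoring suites (e.g. xCell's
64 immune/stromal types): the downstream analyses consume scores only
through correlations with pseudotime, for which sign and monotonicity —
preserved here by construction — are what matters.

``ora_test`` is a classical hypergeometric over-representation test with
Benjamini-Hochberg q-values.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import ExpressionMatrix, SignatureSet

logger = logging.getLogger("bulktime")

__all__ = ["score_signatures", "ora_test"]


def score_signatures(
    expr: ExpressionMatrix, sigs: SignatureSet, min_overlap: int = 3
) -> pd.DataFrame:
    """Standardized mean-rank enrichment score, cell types x samples.

    Signatures sharing fewer than ``min_overlap`` genes with the matrix,
    or leaving no non-member genes (degenerate denominator), are skipped
    with a warning.
    """
    G = expr.n_genes
    ranks = stats.rankdata(expr.values, axis=0)  # per-sample ranks, ties averaged
    rows = {}
    gene_index = {g: i for i, g in enumerate(expr.gene_ids)}
    for name, members in sigs:
        present = [gene_index[g] for g in members if g in gene_index]
        s = len(present)
        if s < min_overlap:
            logger.warning("signature %r overlaps %d genes (< %d); skipped", name, s, min_overlap)
            continue
        if G - s <= 0:
            logger.warning("signature %r covers every gene; score undefined; skipped", name)
            continue
        mean_rank = ranks[present].mean(axis=0)
        denom = np.sqrt((G + 1) * (G - s) / (12.0 * s))
        rows[name] = (mean_rank - (G + 1) / 2.0) / denom
    if not rows:
        raise ValueError("no signature had sufficient overlap with the expression matrix")
    return pd.DataFrame(rows, index=expr.sample_ids).T


def ora_test(
    query,
    sigs: SignatureSet,
    universe,
    p_cut: float = 0.05,
    q_cut: float = 0.1,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each gene set.

    p = P(X >= k) with population N = |universe|, K = |set ∩ universe|,
    draws n = |query|; q = Benjamini-Hochberg across sets; a set is
    significant when p < ``p_cut`` and q < ``q_cut``.
    """
    universe = set(map(str, universe))
    if not universe:
        raise ValueError("empty universe")
    query = set(map(str, query))
    if not query:
        raise ValueError("empty query")
    outside = query - universe
    if outside:
        logger.warning("%d query genes outside the universe dropped", len(outside))
        query &= universe
        if not query:
            raise ValueError("no query genes inside the universe")
    N, n = len(universe), len(query)
    names, ks, Ks, ps = [], [], [], []
    for name, members in sigs:
        K = len(set(members) & universe)
        k = len(set(members) & query)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K > 0 else 1.0
        names.append(name)
        ks.append(k)
        Ks.append(K)
        ps.append(min(p, 1.0))
    q = multipletests(ps, method="fdr_bh")[1] if names else np.array([])
    out = pd.DataFrame(
        {
            "set": names,
            "overlap": ks,
            "set_size": Ks,
            "query_size": n,
            "universe_size": N,
            "p_value": ps,
            "q_value": q,
        }
    )
    out["significant"] = (out["p_value"] < p_cut) & (out["q_value"] < q_cut)
    return out
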