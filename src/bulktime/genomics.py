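"""Tumor mutation burden (TMB) from somatic mutation tables.

TMB is the per-sample count of non-synonymous somatic mutations,
following the de-facto MAF convention for which variant classes count;
an optional capture size converts counts to a per-megabase rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import MAF_CLASSES, MutationTable

logger = logging.getLogger("bulktime")

__all__ = ["NONSYNONYMOUS_CLASSES", "TMBResult", "compute_tmb"]

#: variant classes counted as non-synonymous (MAF convention; configurable)
NONSYNONYMOUS_CLASSES = frozenset(
    {
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Nonstop_Mutation",
        "Frame_Shift_Del",
        "Frame_Shift_Ins",
        "In_Frame_Del",
        "In_Frame_Ins",
        "Splice_Site",
        "Translation_Start_Site",
    }
)


@dataclass
class TMBResult:
    """Per-sample non-synonymous mutation counts (and optional per-Mb rate)."""

    table: pd.DataFrame      # columns: sample_id, tmb_count [, tmb_per_mb]
    capture_mb: float | None = None

    def __post_init__(self) -> None:
        if (self.table["tmb_count"] < 0).any():
            raise ValueError("negative TMB count")

    def counts(self, sample_ids=None) -> pd.Series:
        s = self.table.set_index("sample_id")["tmb_count"]
        return s if sample_ids is None else s.loc[list(sample_ids)]


def compute_tmb(
    muts: MutationTable,
    roster=None,
    capture_mb: float | None = None,
    nonsynonymous=NONSYNONYMOUS_CLASSES,
) -> TMBResult:
    """Count non-synonymous mutations per sample.

    ``roster`` lists the cohort's sample ids; rostered samples absent from
    the table get count 0. Records with classifications outside the
    controlled vocabulary are excluded (warned once per class). Duplicate
    records are not deduplicated.
    """
    rec = muts.records
    unknown = sorted(set(rec["variant_classification"]) - set(MAF_CLASSES))
    for cls in unknown:
        logger.warning("unknown variant classification %r excluded from TMB", cls)
    nonsyn = rec[rec["variant_classification"].isin(nonsynonymous)]
    counts = nonsyn.groupby("sample_id").size()
    if roster is None:
        roster = sorted(set(rec["sample_id"]))
    counts = counts.reindex([str(s) for s in roster], fill_value=0).astype(int)
    table = pd.DataFrame({"sample_id": counts.index, "tmb_count": counts.to_numpy()})
    if capture_mb is not None:
        if capture_mb <= 0:
            raise ValueError("capture_mb must be positive")
        table["tmb_per_mb"] = table["tmb_count"] / capture_mb
    return TMBResult(table.reset_index(drop=True), capture_mb=capture_mb)
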