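"""Core in-memory containers shared by every pipeline stage.

The substrate of the pipeline is a dense genes x samples matrix of
log2-scale expression; everything downstream (clinical tables, gene-set
signatures, mutation records, PET volumes) is keyed to its sample ids.
All containers validate their invariants on construction so that format
errors surface at the I/O boundary, not deep inside a fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "ClinicalTable",
    "SignatureSet",
    "MutationTable",
    "PETVolume",
]


def _find_duplicates(ids) -> list:
    seen: set = set()
    dups: list = []
    for i in ids:
        if i in seen and i not in dups:
            dups.append(i)
        seen.add(i)
    return dups


@dataclass
class ExpressionMatrix:
    """Dense genes x samples expression on the log2 scale.

    Rows are genes, columns are samples; this orientation is fixed for the
    whole package. Values must be finite.
    """

    gene_ids: list
    sample_ids: list
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        dup_g = _find_duplicates(self.gene_ids)
        if dup_g:
            raise ValueError(f"duplicate gene ids: {dup_g}")
        dup_s = _find_duplicates(self.sample_ids)
        if dup_s:
            raise ValueError(f"duplicate sample ids: {dup_s}")
        if self.values.ndim != 2 or self.values.shape != (
            len(self.gene_ids),
            len(self.sample_ids),
        ):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"({len(self.gene_ids)} genes, {len(self.sample_ids)} samples)"
            )
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite expression value at gene {self.gene_ids[bad[0]]}, "
                f"sample {self.sample_ids[bad[1]]}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float))

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        """Restrict to the given genes, in the given order."""
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in idx]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:10]}")
        rows = [idx[g] for g in gene_ids]
        return ExpressionMatrix(list(gene_ids), list(self.sample_ids), self.values[rows])

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in idx]
        if missing:
            raise KeyError(f"samples not in matrix: {missing[:10]}")
        cols = [idx[s] for s in sample_ids]
        return ExpressionMatrix(list(self.gene_ids), list(sample_ids), self.values[:, cols])


#: canonical clinical columns; stages are ordered categoricals or missing
CLINICAL_COLUMNS = (
    "sample_id",
    "t_stage",
    "n_stage",
    "m_stage",
    "overall_stage",
    "surv_time",
    "surv_event",
    "covariate",
)


@dataclass
class ClinicalTable:
    """Per-sample clinical annotation: TNM stage, survival, binary covariate.

    The covariate is coded {-1, +1} (e.g. histology contrast) so that the
    trajectory model's main effect and interaction are orthogonal contrasts.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table.copy()
        for col in CLINICAL_COLUMNS:
            if col not in df.columns:
                df[col] = np.nan
        df = df[list(CLINICAL_COLUMNS)]
        df["sample_id"] = df["sample_id"].astype(str)
        if df["sample_id"].duplicated().any():
            dup = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValueError(f"duplicate sample ids in clinical table: {dup}")
        st = pd.to_numeric(df["surv_time"], errors="coerce")
        if (st.dropna() < 0).any():
            raise ValueError("negative survival times")
        df["surv_time"] = st
        df["surv_event"] = pd.to_numeric(df["surv_event"], errors="coerce")
        cov = pd.to_numeric(df["covariate"], errors="coerce")
        bad = cov.dropna()[~cov.dropna().isin([-1, 1])]
        if len(bad):
            raise ValueError(f"covariate values outside {{-1,+1}}: {sorted(bad.unique())}")
        df["covariate"] = cov
        self.table = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list:
        return list(self.table["sample_id"])

    def covariate_vector(self, sample_ids) -> np.ndarray:
        """Covariate values aligned to the given sample order."""
        s = self.table.set_index("sample_id")["covariate"]
        missing = [i for i in sample_ids if i not in s.index]
        if missing:
            raise KeyError(f"samples missing from clinical table: {missing[:10]}")
        v = s.loc[list(sample_ids)].to_numpy(dtype=float)
        if np.isnan(v).any():
            raise ValueError("missing covariate for requested samples")
        return v


@dataclass
class SignatureSet:
    """Named gene sets with GMT semantics (name, description, members)."""

    sets: dict
    descriptions: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        cleaned = {}
        for name, genes in self.sets.items():
            genes = [str(g) for g in genes]
            if not genes:
                raise ValueError(f"signature {name!r} is empty")
            dups = _find_duplicates(genes)
            if dups:
                raise ValueError(f"signature {name!r} has duplicate members: {dups}")
            cleaned[str(name)] = genes
        self.sets = cleaned
        self.descriptions = {str(k): str(v) for k, v in self.descriptions.items()}

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def __getitem__(self, name: str) -> list:
        return self.sets[name]


#: MAF Variant_Classification controlled vocabulary (de-facto convention)
MAF_CLASSES = frozenset(
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
        "Silent",
        "Intron",
        "3'UTR",
        "5'UTR",
        "3'Flank",
        "5'Flank",
        "IGR",
        "RNA",
        "Targeted_Region",
    }
)


@dataclass
class MutationTable:
    """Somatic mutation records: (sample_id, gene_id, variant_classification).

    Classifications outside the controlled vocabulary are preserved but
    listed in ``unknown_classes`` so downstream counting can warn.
    """

    records: pd.DataFrame
    unknown_classes: list = field(default_factory=list)

    def __post_init__(self) -> None:
        df = self.records.copy()
        required = ["sample_id", "gene_id", "variant_classification"]
        for col in required:
            if col not in df.columns:
                raise ValueError(f"mutation records missing column {col!r}")
        df = df[required].astype(str)
        self.records = df.reset_index(drop=True)
        unknown = sorted(set(df["variant_classification"]) - MAF_CLASSES)
        self.unknown_classes = unknown

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class PETVolume:
    """A 3-D standardized-uptake-value image with voxel spacing in mm."""

    voxels: np.ndarray
    spacing: tuple

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise ValueError(f"PET volume must be 3-D, got shape {self.voxels.shape}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("non-finite SUV voxel")
        if (self.voxels < 0).any():
            raise ValueError("negative SUV voxel")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive mm values, got {self.spacing}")

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in mL (mm^3 / 1000)."""
        dx, dy, dz = self.spacing
        return dx * dy * dz / 1000.0
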