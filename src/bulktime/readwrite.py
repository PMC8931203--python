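"""Readers and writers for the on-disk formats the pipeline consumes.

Expression matrices come as TSV (first column gene id, header row sample
ids) or MatrixMarket triplets with side files of gene and sample ids;
gene sets as GMT; somatic mutations as MAF-style tab-delimited tables;
PET volumes as NIfTI. Every reader/writer pair round-trips losslessly at
the declared precision.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .datatypes import (
    CLINICAL_COLUMNS,
    ClinicalTable,
    ExpressionMatrix,
    MutationTable,
    PETVolume,
    SignatureSet,
)

logger = logging.getLogger("bulktime")

__all__ = [
    "read_expression",
    "write_expression",
    "read_gmt",
    "write_gmt",
    "read_maf",
    "write_maf",
    "read_clinical",
    "write_clinical",
    "read_volume",
    "write_volume",
    "write_table",
    "align_samples",
]

_FLOAT_FMT = "%.10g"


def read_expression(path, format: str = "tsv", log2_input: bool = True) -> ExpressionMatrix:
    """Read a genes x samples expression matrix.

    Parameters
    ----------
    path
        TSV file, or for ``format="mtx"`` a directory containing
        ``matrix.mtx``, ``genes.tsv`` and ``samples.tsv``.
    format
        ``"tsv"`` or ``"mtx"``.
    log2_input
        If True (default) values are taken as already log2-scale. If
        False they are treated as raw and transformed as ``log2(x + 1)``.
    """
    path = Path(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
        values = np.empty(df.shape, dtype=float)
        for j, col in enumerate(df.columns):
            parsed = pd.to_numeric(df[col], errors="coerce")
            raw = df[col]
            bad = parsed.isna() & raw.notna()
            if bad.any():
                g = df.index[bad.argmax()]
                raise ValueError(
                    f"non-numeric expression value {raw[bad].iloc[0]!r} "
                    f"at gene {g!r}, sample {col!r}"
                )
            if parsed.isna().any():
                g = df.index[parsed.isna().argmax()]
                raise ValueError(f"missing expression value at gene {g!r}, sample {col!r}")
            values[:, j] = parsed.to_numpy()
        gene_ids = [str(g) for g in df.index]
        sample_ids = [str(s) for s in df.columns]
    elif format == "mtx":
        mat = scipy.io.mmread(path / "matrix.mtx")
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        gene_ids = (path / "genes.tsv").read_text().split()
        sample_ids = (path / "samples.tsv").read_text().split()
        values = np.asarray(mat, dtype=float)
    else:
        raise ValueError(f"unknown expression format {format!r}")
    if not log2_input:
        if (values < 0).any():
            raise ValueError("raw expression contains negative values; cannot log2(x+1)")
        values = np.log2(values + 1.0)
    return ExpressionMatrix(gene_ids, sample_ids, values)


def write_expression(expr: ExpressionMatrix, path) -> None:
    expr.to_frame().to_csv(path, sep="\t", index_label="gene_id", float_format=_FLOAT_FMT)


def read_gmt(path) -> SignatureSet:
    """Read a GMT file: one set per line, ``name<TAB>description<TAB>genes...``."""
    sets: dict = {}
    descriptions: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"GMT line {lineno} has {len(fields)} fields (< 3)")
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            sets[name] = genes
            descriptions[name] = desc
    return SignatureSet(sets, descriptions)


def write_gmt(sigs: SignatureSet, path) -> None:
    with open(path, "w") as fh:
        for name, genes in sigs:
            desc = sigs.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")


_MAF_REQUIRED = ("Tumor_Sample_Barcode", "Hugo_Symbol", "Variant_Classification")


def read_maf(path) -> MutationTable:
    """Read a MAF-style tab-delimited mutation table (comment lines ``#``)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in _MAF_REQUIRED:
        if col not in df.columns:
            raise ValueError(f"MAF file missing required column {col!r}")
    records = pd.DataFrame(
        {
            "sample_id": df["Tumor_Sample_Barcode"],
            "gene_id": df["Hugo_Symbol"],
            "variant_classification": df["Variant_Classification"],
        }
    )
    table = MutationTable(records)
    if table.unknown_classes:
        logger.warning("MAF contains unknown variant classes: %s", table.unknown_classes)
    return table


def write_maf(muts: MutationTable, path) -> None:
    out = pd.DataFrame(
        {
            "Hugo_Symbol": muts.records["gene_id"],
            "Tumor_Sample_Barcode": muts.records["sample_id"],
            "Variant_Classification": muts.records["variant_classification"],
        }
    )
    out.to_csv(path, sep="\t", index=False)


def read_clinical(path) -> ClinicalTable:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    return ClinicalTable(df)


def write_clinical(clin: ClinicalTable, path) -> None:
    clin.table.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_volume(path) -> PETVolume:
    img = nib.load(str(path))
    voxels = np.asarray(img.get_fdata(), dtype=float)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return PETVolume(voxels, spacing)


def write_volume(vol: PETVolume, path) -> None:
    affine = np.diag([*vol.spacing, 1.0])
    nib.save(nib.Nifti1Image(vol.voxels.astype(np.float32), affine), str(path))


def write_table(obj, path) -> None:
    """Write a DataFrame (or dict of scalars/arrays) as TSV or JSON by suffix."""
    path = Path(path)
    if path.suffix == ".json":
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=2, default=_jsonable)
            fh.write("\n")
        return
    if isinstance(obj, dict):
        obj = pd.DataFrame(obj)
    obj.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")


def align_samples(expr: ExpressionMatrix, clin: ClinicalTable):
    """Intersect expression and clinical tables on sample id.

    Mismatch is not an error: dropped samples are logged and both objects
    are returned restricted to the common ids, in expression order.
    """
    common = [s for s in expr.sample_ids if s in set(clin.sample_ids)]
    dropped_expr = [s for s in expr.sample_ids if s not in set(common)]
    dropped_clin = [s for s in clin.sample_ids if s not in set(common)]
    if dropped_expr or dropped_clin:
        logger.warning(
            "sample alignment dropped %d expression / %d clinical samples",
            len(dropped_expr),
            len(dropped_clin),
        )
    if not common:
        raise ValueError("no samples shared between expression and clinical tables")
    expr2 = expr.subset_samples(common)
    clin2 = ClinicalTable(
        clin.table.set_index("sample_id").loc[common].reset_index()[list(CLINICAL_COLUMNS)]
    )
    return expr2, clin2
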