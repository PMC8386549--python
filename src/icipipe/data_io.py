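"""Tabular I/O and unit handling for expression, clinical, gene-set and mutation data.

The pipeline's in-memory containers are thin wrappers around pandas objects:

* :class:`ExpressionMatrix` — genes x samples with an explicit unit tag
  (``FPKM``, ``TPM`` or ``LOG2``), so unit-sensitive steps (TPM conversion,
  log transform, DEG statistics) can refuse inputs on the wrong scale.
* Clinical tables are plain DataFrames with ``sample_id``, ``os_time`` (days)
  and ``os_event`` (0/1) columns, plus optional covariates.
* Mutation tables are long-format MAF-like DataFrames with
  ``Tumor_Sample_Barcode``, ``Hugo_Symbol`` and ``Variant_Classification``.

All text formats are TSV (first column = row id, header = column ids) and
GMT for gene sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "ParseError",
    "fpkm_to_tpm",
    "log2_transform",
    "merge_cohorts",
    "read_expression",
    "write_expression",
    "read_clinical",
    "write_clinical",
    "read_gmt",
    "write_gmt",
    "read_maf",
    "write_maf",
]

VALID_UNITS = ("FPKM", "TPM", "LOG2")

CLINICAL_REQUIRED = ("sample_id", "os_time", "os_event")

MAF_REQUIRED = ("Tumor_Sample_Barcode", "Hugo_Symbol", "Variant_Classification")


class ParseError(ValueError):
    """Malformed input file (bad header, ragged row, non-numeric cell)."""


@dataclass
class ExpressionMatrix:
    """Genes x samples abundance matrix with a unit tag.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with sample ids as columns.
    unit
        One of ``FPKM``, ``TPM``, ``LOG2``.
    sample_cohort
        Optional per-sample cohort-of-origin labels (kept through merges so
        users can stratify; no batch correction is applied).
    """

    values: pd.DataFrame
    unit: str
    sample_cohort: pd.Series | None = field(default=None)

    def __post_init__(self) -> None:
        if self.unit not in VALID_UNITS:
            raise ValueError(f"unit must be one of {VALID_UNITS}, got {self.unit!r}")
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dupes[:5]}")
        if self.values.columns.has_duplicates:
            dupes = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dupes[:5]}")
        if self.unit in ("FPKM", "TPM") and (self.values.to_numpy() < 0).any():
            raise ValueError(f"negative values are not allowed in a {self.unit} matrix")
        if self.sample_cohort is not None:
            self.sample_cohort = self.sample_cohort.reindex(self.values.columns)

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def fpkm_to_tpm(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Convert FPKM to TPM by per-sample total normalization.

    TPM_gj = FPKM_gj / sum_g FPKM_gj * 1e6, so every column sums to 1e6.
    """
    if expr.unit != "FPKM":
        raise ValueError(f"expected FPKM input, got {expr.unit}")
    colsum = expr.values.sum(axis=0)
    zero = colsum[colsum <= 0]
    if len(zero):
        raise ValueError(f"sample(s) with all-zero FPKM: {zero.index.tolist()}")
    tpm = expr.values.div(colsum, axis=1) * 1e6
    return ExpressionMatrix(tpm, "TPM", sample_cohort=expr.sample_cohort)


def log2_transform(expr: ExpressionMatrix) -> ExpressionMatrix:
    """log2(x + 1) transform of a TPM matrix (pseudocount keeps zeros at zero)."""
    if expr.unit == "LOG2":
        raise ValueError("matrix is already log2-transformed")
    if expr.unit != "TPM":
        raise ValueError(f"log2_transform expects TPM input, got {expr.unit}")
    return ExpressionMatrix(np.log2(expr.values + 1.0), "LOG2", sample_cohort=expr.sample_cohort)


def merge_cohorts(
    a: ExpressionMatrix,
    b: ExpressionMatrix,
    labels: tuple[str, str] = ("cohort_a", "cohort_b"),
) -> ExpressionMatrix:
    """Merge two cohorts on the intersection of their gene sets.

    Both inputs must be on the same scale (TPM or LOG2). Sample ids must be
    disjoint; a cohort-of-origin label is retained per sample.
    """
    if a.unit != b.unit:
        raise ValueError(f"unit mismatch: {a.unit} vs {b.unit}")
    if a.unit == "FPKM":
        raise ValueError("merge on TPM or LOG2 matrices (convert FPKM first)")
    shared = a.gene_ids.intersection(b.gene_ids)
    if len(shared) == 0:
        raise ValueError("empty gene intersection between cohorts")
    overlap = a.sample_ids.intersection(b.sample_ids)
    if len(overlap):
        raise ValueError(f"duplicate sample ids across cohorts: {overlap.tolist()[:5]}")
    # keep a's gene order for the shared genes
    shared = a.gene_ids[a.gene_ids.isin(shared)]
    merged = pd.concat([a.values.loc[shared], b.values.loc[shared]], axis=1)
    cohort = pd.concat(
        [
            a.sample_cohort
            if a.sample_cohort is not None
            else pd.Series(labels[0], index=a.sample_ids),
            b.sample_cohort
            if b.sample_cohort is not None
            else pd.Series(labels[1], index=b.sample_ids),
        ]
    )
    cohort.name = "cohort"
    return ExpressionMatrix(merged, a.unit, sample_cohort=cohort)


# ---------------------------------------------------------------------------
# file formats
# ---------------------------------------------------------------------------


def read_expression(path, unit: str = "TPM") -> ExpressionMatrix:
    """Read a genes-x-samples TSV (first column gene id, header sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.columns.size == 0:
        raise ParseError(f"{path}: no sample columns found")
    for j, col in enumerate(df.columns):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna()
        if bad.any():
            row = df.index[bad.to_numpy().argmax()]
            raise ParseError(
                f"{path}: non-numeric expression cell at gene {row!r}, sample {col!r}"
            )
        df[col] = numeric.astype(float)
    return ExpressionMatrix(df.astype(float), unit)


def write_expression(expr: ExpressionMatrix, path) -> None:
    out = expr.values.copy()
    out.index.name = out.index.name or "gene_id"
    out.to_csv(path, sep="\t")


def read_clinical(path) -> pd.DataFrame:
    """Read a clinical TSV with sample_id, os_time (days), os_event (0/1)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in CLINICAL_REQUIRED if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing clinical columns {missing}")
    if df["sample_id"].duplicated().any():
        raise ParseError(f"{path}: duplicate sample_id values")
    if not df["os_event"].isin([0, 1]).all():
        raise ParseError(f"{path}: os_event must be 0/1")
    if (df["os_time"] < 0).any():
        raise ParseError(f"{path}: negative os_time")
    return df


def write_clinical(clinical: pd.DataFrame, path) -> None:
    clinical.to_csv(path, sep="\t", index=False)


def read_gmt(path) -> dict[str, set[str]]:
    """Read GMT gene sets: name <tab> description <tab> member genes..."""
    sets: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line needs name, description, >=1 gene")
            name = parts[0]
            if name in sets:
                raise ParseError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            sets[name] = {g for g in parts[2:] if g}
    return sets


def write_gmt(sets: dict[str, set[str]], path, description: str = "na") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *sorted(members)]) + "\n")


def read_maf(path) -> pd.DataFrame:
    """Read a MAF-like TSV (requires sample barcode, gene symbol, variant class)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in MAF_REQUIRED if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing MAF columns {missing}")
    empties = df[list(MAF_REQUIRED)].isna().any(axis=1)
    if empties.any():
        raise ParseError(f"{path}: empty field in record {int(empties.to_numpy().argmax()) + 2}")
    return df


def write_maf(muts: pd.DataFrame, path) -> None:
    muts.to_csv(path, sep="\t", index=False)
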