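"""Tabular I/O and unit handling for the TIME stratification pipeline.

Every downstream module consumes the canonical containers defined here:
an :class:`ExpressionMatrix` (genes x samples with a declared unit), a
clinical table, a MAF-style mutation table, a 22-column leukocyte
fraction table and named gene-set configurations.  Expression matrices
are dense pandas DataFrames; the pipeline targets cohorts up to roughly
10^4 samples x 2x10^4 genes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

VALID_UNITS = ("counts", "FPKM", "TPM", "log2TPM")

#: Minimal MAF vocabulary recognised by the genomics module.
MAF_CLASSIFICATIONS = frozenset(
    {
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Nonstop_Mutation",
        "Translation_Start_Site",
        "Splice_Site",
        "Frame_Shift_Ins",
        "Frame_Shift_Del",
        "In_Frame_Ins",
        "In_Frame_Del",
        "Silent",
        "3'UTR",
        "5'UTR",
        "3'Flank",
        "5'Flank",
        "Intron",
        "IGR",
        "RNA",
        "Targeted_Region",
    }
)


class ExpressionUnitError(ValueError):
    """Raised when an operation receives a matrix in the wrong unit."""


@dataclass
class ExpressionMatrix:
    """Dense genes x samples expression matrix with a declared unit.

    Parameters
    ----------
    values
        DataFrame indexed by gene symbol with sample-id columns.
    unit
        One of ``counts``, ``FPKM``, ``TPM`` or ``log2TPM``.
    """

    values: pd.DataFrame
    unit: str

    def __post_init__(self) -> None:
        if self.unit not in VALID_UNITS:
            raise ExpressionUnitError(
                f"unknown expression unit {self.unit!r}; expected one of {VALID_UNITS}"
            )
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene ids in expression matrix")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids in expression matrix")
        if self.unit in ("counts", "FPKM", "TPM") and (self.values.values < 0).any():
            raise ValueError(f"negative values are invalid for unit {self.unit}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def require_unit(self, unit: str) -> None:
        if self.unit != unit:
            raise ExpressionUnitError(
                f"operation requires unit {unit!r} but matrix is in {self.unit!r}"
            )


def _detect_sep(path: str | Path) -> str:
    with open(path) as fh:
        first = fh.readline()
    if not first:
        raise ValueError(f"empty expression file: {path}")
    return "\t" if first.count("\t") >= first.count(",") else ","


def read_expression(path: str | Path, unit: str) -> ExpressionMatrix:
    """Read a gene x sample TSV/CSV into an :class:`ExpressionMatrix`.

    First column holds gene symbols, header row holds sample ids, the
    body must be numeric.  Duplicate gene rows are collapsed by their
    arithmetic mean (the standard multi-probe rule).  Non-numeric body
    cells raise with the offending row and column named.
    """
    sep = _detect_sep(path)
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"expression file has no data body: {path}")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if df[col].isna().any():
            bad |= df[col].isna()
        if bad.any():
            gene = df.index[np.flatnonzero(bad.values)[0]]
            raise ValueError(
                f"non-numeric cell at gene {gene!r}, sample {col!r} in {path}"
            )
        df[col] = coerced
    if df.index.has_duplicates:
        df = df.groupby(level=0, sort=False).mean()
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(values=df.astype(float), unit=unit)


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write tab-delimited genes x samples; gene symbols in column one."""
    matrix.values.to_csv(path, sep="\t", index_label="gene")


def fpkm_to_tpm(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Rescale each sample column of an FPKM matrix so it sums to 1e6.

    TPM is the within-sample normalisation of FPKM:
    ``tpm_gs = fpkm_gs / sum_g fpkm_gs * 1e6``.
    """
    matrix.require_unit("FPKM")
    colsums = matrix.values.sum(axis=0)
    zero = colsums[colsums == 0]
    if len(zero):
        raise ValueError(
            f"all-zero expression column(s) {list(zero.index)}: TPM undefined"
        )
    values = matrix.values / colsums * 1e6
    return ExpressionMatrix(values=values, unit="TPM")


def log2_tpm(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Elementwise ``log2(TPM + 1)`` transform."""
    matrix.require_unit("TPM")
    if (matrix.values.values < 0).any():
        raise ValueError("negative TPM values; cannot log-transform")
    return ExpressionMatrix(values=np.log2(matrix.values + 1.0), unit="log2TPM")


# ---------------------------------------------------------------------------
# Clinical table
# ---------------------------------------------------------------------------

CLINICAL_COLUMNS = ["sample_id", "os_months", "event", "age", "sex", "stage"]


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Read a clinical TSV with columns sample_id, os_months, event, age, sex, stage.

    Missing categorical fields become "unknown"; samples lacking
    follow-up (os_months or event missing) are kept with NaN so that
    survival operations can exclude them while classification retains
    them.
    """
    sep = _detect_sep(path)
    df = pd.read_csv(path, sep=sep, dtype={"sample_id": str})
    missing = [c for c in ("sample_id",) if c not in df.columns]
    if missing:
        raise ValueError(f"clinical table missing required column(s) {missing}")
    for col in ("os_months", "event", "age"):
        if col not in df.columns:
            df[col] = np.nan
        df[col] = pd.to_numeric(df[col], errors="coerce")
    if (df["os_months"].dropna() < 0).any():
        raise ValueError("negative os_months in clinical table")
    bad_event = df["event"].dropna()
    if not bad_event.isin([0, 1]).all():
        raise ValueError("event flag must be 0 or 1")
    for col, allowed in (("sex", {"male", "female"}), ("stage", {"I", "II", "III", "IV"})):
        if col not in df.columns:
            df[col] = "unknown"
        df[col] = df[col].astype(str).where(df[col].astype(str).isin(allowed), "unknown")
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in clinical table")
    return df[CLINICAL_COLUMNS + [c for c in df.columns if c not in CLINICAL_COLUMNS]]


def write_clinical(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# MAF
# ---------------------------------------------------------------------------

MAF_REQUIRED = ["Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification"]


def read_maf(path: str | Path) -> pd.DataFrame:
    """Read a tab-delimited MAF keeping the three columns the pipeline uses."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in MAF_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"MAF missing required column(s) {missing}")
    return df[MAF_REQUIRED].copy()


def write_maf(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Leukocyte fraction table
# ---------------------------------------------------------------------------


def read_fractions(path: str | Path, renormalize: bool = True) -> pd.DataFrame:
    """Read a sample x 22-fraction table indexed by sample_id.

    Fractions must lie in [0, 1]; rows are renormalised to sum to 1 and
    rejected if the renormalised sum leaves [0.99, 1.01] before
    correction by more than 20%.
    """
    sep = _detect_sep(path)
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.shape[1] != 22:
        raise ValueError(f"fraction table must have 22 columns, found {df.shape[1]}")
    vals = df.values.astype(float)
    if (vals < 0).any() or (vals > 1).any():
        raise ValueError("fractions must lie in [0, 1]")
    sums = vals.sum(axis=1)
    if (sums <= 0).any():
        raise ValueError("all-zero fraction row")
    if renormalize:
        vals = vals / sums[:, None]
    out = pd.DataFrame(vals, index=df.index.astype(str), columns=df.columns)
    if not np.allclose(out.sum(axis=1), 1.0, atol=0.01):
        raise ValueError("fraction rows do not sum to 1 within tolerance")
    return out


# ---------------------------------------------------------------------------
# Gene-set configuration (GMT and JSON dialect)
# ---------------------------------------------------------------------------


@dataclass
class GeneSet:
    """A named gene set with an optional class tag and +/-1 weight."""

    name: str
    genes: list[str]
    set_class: str | None = None
    weight: int = 1

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} has no members")
        if self.weight not in (-1, 1):
            raise ValueError(f"gene set {self.name!r} weight must be +1 or -1")


def read_gmt(path: str | Path) -> dict[str, GeneSet]:
    """Parse a GMT file (name, description, members...) into gene sets."""
    sets: dict[str, GeneSet] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line {lineno} in {path}")
            name, _desc, *genes = parts
            genes = [g for g in genes if g]
            if name in sets:
                raise ValueError(f"duplicate gene-set name {name!r} in {path}")
            sets[name] = GeneSet(name=name, genes=genes)
    return sets


def read_gene_set_json(path: str | Path) -> list[GeneSet]:
    """Parse the JSON gene-set dialect: a list of {name, class, weight, genes}."""
    with open(path) as fh:
        raw = json.load(fh)
    sets = []
    seen: set[str] = set()
    for entry in raw:
        name = entry["name"]
        if name in seen:
            raise ValueError(f"duplicate gene-set name {name!r} in {path}")
        seen.add(name)
        sets.append(
            GeneSet(
                name=name,
                genes=list(entry["genes"]),
                set_class=entry.get("class"),
                weight=int(entry.get("weight", 1)),
            )
        )
    return sets
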