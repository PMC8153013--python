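"""Composite TIL Z score and gene-signature scoring.

The tumor-infiltrating-lymphocyte (TIL) state of a sample is summarised
by averaging cohort z-scores of 26 immune determinant gene sets: 20
single factors (MHC molecules, immunoinhibitors, immunostimulators) and
6 immune cell types, each carrying a +/-1 weight.  A positive score
indicates an infiltrated ("hot") microenvironment.  The same machinery
provides mean-z signature scores (T-cell exhaustion, MDSC) and raw-TPM
cytokine/cytolysis composites.
"""

from __future__ import annotations

import warnings
from importlib import resources

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GeneSet, read_gene_set_json, read_gmt

DETERMINANT_CLASSES = ("MHC", "immunoinhibitor", "immunostimulator", "cell_type")


def default_determinants() -> list[GeneSet]:
    """The packaged 26-determinant configuration (editable data file).

    20 single-factor sets (10 MHC, 5 immunoinhibitors, 5
    immunostimulators) plus 6 immune-cell-type sets.  Membership is
    configuration, not code: pass any conforming JSON to override.
    """
    path = resources.files("timequad.data").joinpath("determinants_default.json")
    with resources.as_file(path) as p:
        return read_gene_set_json(p)


def default_signatures() -> dict[str, GeneSet]:
    """Packaged signature sets (exhaustion, MDSC, cytokine composites)."""
    path = resources.files("timequad.data").joinpath("signatures.gmt")
    with resources.as_file(path) as p:
        return read_gmt(p)


def validate_determinants(sets: list[GeneSet]) -> None:
    """Check the 26-set class structure: 20 single factors + 6 cell types."""
    if len(sets) != 26:
        raise ValueError(f"expected 26 determinant sets, got {len(sets)}")
    names = [s.name for s in sets]
    if len(set(names)) != 26:
        raise ValueError("determinant set names must be unique")
    classes = [s.set_class for s in sets]
    bad = [c for c in classes if c not in DETERMINANT_CLASSES]
    if bad:
        raise ValueError(f"unknown determinant class(es): {sorted(set(bad))}")
    n_cell = sum(c == "cell_type" for c in classes)
    if n_cell != 6:
        raise ValueError(f"expected 6 cell-type determinants, got {n_cell}")


def zscore_by_gene(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Standardise each gene row to mean 0, sample SD 1 across the cohort.

    Constant rows are mapped to all-zero rather than dropped so that
    determinant-set means stay defined regardless of membership.
    """
    matrix.require_unit("log2TPM")
    if matrix.n_samples < 2:
        raise ValueError("z-scoring requires at least 2 samples")
    vals = matrix.values
    mu = vals.mean(axis=1)
    sd = vals.std(axis=1, ddof=1)
    z = vals.sub(mu, axis=0).div(sd.where(sd > 0, np.inf), axis=0)
    return z


def _set_mean_z(z: pd.DataFrame, gene_set: GeneSet, min_coverage: float = 0.5):
    present = [g for g in gene_set.genes if g in z.index]
    if not present:
        raise ValueError(f"determinant set {gene_set.name!r} has no genes in the matrix")
    if len(present) < min_coverage * len(gene_set.genes):
        warnings.warn(
            f"set {gene_set.name!r}: only {len(present)}/{len(gene_set.genes)} "
            "genes present in the matrix",
            stacklevel=3,
        )
    return z.loc[present].mean(axis=0)


def til_z_score(
    matrix: ExpressionMatrix, determinants: list[GeneSet] | None = None
) -> pd.Series:
    """Per-sample TIL Z score: weighted average of determinant-set z means.

    For determinant d with weight w_d, ``score(d, s)`` is the mean of
    the member genes' cohort z-scores in sample s, and

        til_z(s) = sum_d w_d * score(d, s) / n_sets

    with n_sets = 26 in the default configuration.
    """
    if determinants is None:
        determinants = default_determinants()
        validate_determinants(determinants)
    z = zscore_by_gene(matrix)
    total = pd.Series(0.0, index=z.columns)
    for det in determinants:
        total = total + det.weight * _set_mean_z(z, det)
    out = total / len(determinants)
    out.name = "til_z"
    return out


def signature_score(
    matrix: ExpressionMatrix, gene_set: GeneSet, mode: str = "mean_z"
) -> pd.Series:
    """Score a signature per sample.

    mode "mean_z": mean of per-gene cohort z-scores (requires log2TPM);
    used for the exhaustion and MDSC signatures.
    mode "mean_tpm": mean of raw TPM values (requires TPM); used for the
    cytokine and cytolytic-activity composites, which are reported on
    the expression scale.
    Missing member genes are dropped with a warning; an empty
    intersection is an error.
    """
    present = [g for g in gene_set.genes if g in matrix.values.index]
    if not present:
        raise ValueError(f"signature {gene_set.name!r} has no genes in the matrix")
    if len(present) < len(gene_set.genes):
        missing = sorted(set(gene_set.genes) - set(present))
        warnings.warn(f"signature {gene_set.name!r}: dropping missing genes {missing}")
    if mode == "mean_z":
        z = zscore_by_gene(matrix)
        out = z.loc[present].mean(axis=0)
    elif mode == "mean_tpm":
        matrix.require_unit("TPM")
        out = matrix.values.loc[present].mean(axis=0)
    else:
        raise ValueError(f"unknown signature mode {mode!r}")
    out.name = gene_set.name
    return out
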