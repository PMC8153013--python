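"""One-vs-rest differential expression and the gene-score / pathway-score
normalisation used to rank pathway dysregulation across the four TIME
subtypes.

The DE contract: per gene, log2FC = log2((mean CPM_subtype + 0.5) /
(mean CPM_rest + 0.5)), a two-sided rank-sum p on log-CPM, BH FDR, and
a DEG flag at |log2FC| >= 2 and FDR < 0.05.  Externally computed
per-subtype log2FC/FDR tables can be supplied in place of this engine.

Scoring: with log2FC_k = 0 for subtypes where the gene is not a DEG,

    mean_log2fc(g)      = sum_k log2FC_k / 4
    gene_score(g, k)    = |log2FC_k| / |mean_log2fc(g)|
    pathway_score(P, k) = sum_{g in P} gene_score(g, k)
                          / sum_j sum_{g in P} gene_score(g, j)

so each retained pathway's four subtype scores sum to 1.  Genes whose
mean log2FC is exactly 0 (fold changes cancelling across subtypes) are
excluded from scoring with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix

SUBTYPES = ("I", "II", "III", "IV")
LOG2FC_THRESHOLD = 2.0
FDR_THRESHOLD = 0.05
ENRICH_P = 0.01
ENRICH_MIN_OVERLAP = 3
CPM_PSEUDOCOUNT = 0.5


def cpm(counts: ExpressionMatrix) -> pd.DataFrame:
    """Counts per million per sample column."""
    counts.require_unit("counts")
    colsums = counts.values.sum(axis=0)
    if (colsums == 0).any():
        raise ValueError("all-zero count column; CPM undefined")
    return counts.values / colsums * 1e6


def differential_expression(
    counts: ExpressionMatrix, subtypes: pd.Series, k: str
) -> pd.DataFrame:
    """One-vs-rest DE for subtype ``k``: columns log2FC, p, fdr, deg.

    Experimental group = samples labeled k; control = the pooled other
    subtypes.  Both groups need >= 3 samples.
    """
    if k not in SUBTYPES:
        raise ValueError(f"unknown subtype {k!r}")
    labels = subtypes.reindex(counts.sample_ids)
    in_k = (labels == k).values
    if in_k.sum() < 3 or (~in_k).sum() < 3:
        raise ValueError(
            f"subtype {k}: need >= 3 samples per group "
            f"(got {int(in_k.sum())} vs {int((~in_k).sum())})"
        )
    x = cpm(counts)
    log_x = np.log2(x + 1.0)
    mean_k = x.values[:, in_k].mean(axis=1)
    mean_rest = x.values[:, ~in_k].mean(axis=1)
    log2fc = np.log2((mean_k + CPM_PSEUDOCOUNT) / (mean_rest + CPM_PSEUDOCOUNT))
    a = log_x.values[:, in_k]
    b = log_x.values[:, ~in_k]
    # vectorised two-sided Mann-Whitney over gene rows
    res = stats.mannwhitneyu(a, b, axis=1, alternative="two-sided")
    pvals = np.asarray(res.pvalue, dtype=float)
    fdr = multipletests(pvals, method="fdr_bh")[1]
    deg = (np.abs(log2fc) >= LOG2FC_THRESHOLD) & (fdr < FDR_THRESHOLD)
    return pd.DataFrame(
        {"log2FC": log2fc, "p": pvals, "fdr": fdr, "deg": deg},
        index=counts.values.index,
    )


def de_all_subtypes(
    counts: ExpressionMatrix, subtypes: pd.Series
) -> dict[str, pd.DataFrame]:
    return {k: differential_expression(counts, subtypes, k) for k in SUBTYPES}


def _effective_lfc(de_results: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Genes x subtype log2FC with 0 where the gene is not a DEG."""
    genes = de_results[SUBTYPES[0]].index
    out = pd.DataFrame(0.0, index=genes, columns=list(SUBTYPES))
    for k in SUBTYPES:
        d = de_results[k]
        out[k] = np.where(d["deg"], d["log2FC"], 0.0)
    return out


def mean_log2fc(de_results: dict[str, pd.DataFrame]) -> pd.Series:
    """Per-gene mean of the four effective log2FC values (divisor 4)."""
    return _effective_lfc(de_results).sum(axis=1) / 4.0


def gene_scores(de_results: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Genes x subtype gene scores: |log2FC_k| / |mean log2FC|.

    Only genes that are a DEG in at least one subtype are scored; genes
    whose effective fold changes cancel to a zero mean are excluded
    with a warning naming them.
    """
    lfc = _effective_lfc(de_results)
    any_deg = (lfc != 0).any(axis=1)
    lfc = lfc.loc[any_deg]
    mean = lfc.sum(axis=1) / 4.0
    degenerate = mean.index[mean == 0]
    if len(degenerate):
        warnings.warn(
            f"excluding {len(degenerate)} gene(s) with zero mean log2FC "
            f"(sign-cancelling fold changes): {list(degenerate)[:5]}"
        )
        lfc = lfc.drop(index=degenerate)
        mean = mean.drop(index=degenerate)
    return lfc.abs().div(mean.abs(), axis=0)


def pathway_scores(
    pathways: dict[str, list[str]], scores: pd.DataFrame
) -> pd.DataFrame:
    """Pathway x subtype table of normalised summed gene scores.

    Each row sums to 1; pathways with no scored gene are dropped with a
    warning.
    """
    rows = {}
    for name, genes in pathways.items():
        present = scores.index.intersection(genes)
        if len(present) == 0:
            warnings.warn(f"pathway {name!r} has no scored genes; dropped")
            continue
        sums = scores.loc[present].sum(axis=0)
        total = sums.sum()
        if total == 0:
            warnings.warn(f"pathway {name!r} has zero total gene score; dropped")
            continue
        rows[name] = sums / total
    if not rows:
        return pd.DataFrame(columns=list(SUBTYPES))
    return pd.DataFrame(rows).T[list(SUBTYPES)]


def enrich(
    deg_list: list[str],
    pathway_db: dict[str, list[str]],
    universe: list[str],
    p_threshold: float = ENRICH_P,
    min_overlap: int = ENRICH_MIN_OVERLAP,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of DEGs per pathway.

    Keeps pathways with p < 0.01 and overlap >= 3.  Returns all tested
    pathways with a ``kept`` flag so callers can inspect the filter.
    """
    uni = set(universe)
    degs = set(deg_list)
    if not degs <= uni:
        raise ValueError("DEG list must be a subset of the universe")
    M = len(uni)
    n = len(degs)
    rows = []
    for name, genes in pathway_db.items():
        members = set(genes) & uni
        K = len(members)
        k = len(members & degs)
        # P(X >= k) for X ~ Hypergeom(M, K, n)
        p = float(stats.hypergeom.sf(k - 1, M, K, n)) if K else 1.0
        rows.append(
            {
                "pathway": name,
                "overlap": k,
                "pathway_size": K,
                "p_value": p,
                "kept": (p < p_threshold) and (k >= min_overlap),
            }
        )
    return pd.DataFrame(rows).sort_values("p_value", ignore_index=True)


def read_de_override(path) -> dict[str, pd.DataFrame]:
    """Load externally computed DE tables: TSV of gene, subtype, log2FC, FDR.

    Genes absent for a subtype are treated as non-DEGs there; the DEG
    flag is recomputed at the standard thresholds.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "subtype", "log2FC", "FDR"}
    if not required <= set(df.columns):
        raise ValueError(f"DE override needs columns {sorted(required)}")
    genes = sorted(df["gene"].unique())
    out = {}
    for k in SUBTYPES:
        sub = df[df["subtype"] == k].set_index("gene")
        lfc = sub["log2FC"].reindex(genes).fillna(0.0)
        fdr = sub["FDR"].reindex(genes).fillna(1.0)
        deg = (lfc.abs() >= LOG2FC_THRESHOLD) & (fdr < FDR_THRESHOLD)
        out[k] = pd.DataFrame({"log2FC": lfc, "p": fdr, "fdr": fdr, "deg": deg})
    return out
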