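"""Somatic mutation summaries: TMB, per-subtype mutation spectra,
pairwise co-occurrence / mutual-exclusivity and group-association tests.

Tumor mutation burden counts nonsynonymous, insertion-deletion and
silent somatic variants per sample and divides by a fixed exome size
(default 38 Mb).  Pairwise somatic interaction uses the two-sided
Fisher exact test on the 2x2 mutated/wild-type table with a
Haldane-corrected odds ratio and Benjamini-Hochberg adjustment across
pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import MAF_CLASSIFICATIONS

EXOME_MB = 38.0

#: Variant classes counted toward TMB: nonsynonymous + indel + silent.
TMB_COUNTED_CLASSES = frozenset(
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
    }
)


def fisher_two_sided(table) -> float:
    """Two-sided Fisher exact p (minimum-likelihood definition) for a 2x2 table."""
    _, p = stats.fisher_exact(np.asarray(table, dtype=float), alternative="two-sided")
    return float(p)


def compute_tmb(
    maf: pd.DataFrame,
    samples: list[str],
    exome_mb: float = EXOME_MB,
    counted_classes: frozenset[str] = TMB_COUNTED_CLASSES,
) -> pd.DataFrame:
    """Mutations per megabase for every sample in ``samples``.

    Samples absent from the MAF get TMB 0.  Variant classes outside the
    recognised MAF vocabulary are excluded with a warning listing them.
    Returns columns counted_mutations and tmb.
    """
    if exome_mb <= 0:
        raise ValueError("exome_mb must be positive")
    cls = maf["Variant_Classification"]
    unknown = sorted(set(cls) - MAF_CLASSIFICATIONS)
    if unknown:
        warnings.warn(f"excluding unrecognised variant classification(s): {unknown}")
    counted = maf[cls.isin(counted_classes)]
    per_sample = counted.groupby("Tumor_Sample_Barcode").size()
    counts = per_sample.reindex(samples, fill_value=0).astype(int)
    return pd.DataFrame(
        {"counted_mutations": counts, "tmb": counts / exome_mb},
        index=pd.Index(samples, name="sample_id"),
    )


def mutation_matrix(
    maf: pd.DataFrame,
    samples: list[str],
    counted_classes: frozenset[str] = TMB_COUNTED_CLASSES,
) -> pd.DataFrame:
    """Binary sample x gene indicator of any counted variant."""
    counted = maf[maf["Variant_Classification"].isin(counted_classes)]
    mm = (
        counted.assign(hit=1)
        .pivot_table(
            index="Tumor_Sample_Barcode",
            columns="Hugo_Symbol",
            values="hit",
            aggfunc="max",
            fill_value=0,
        )
        .reindex(samples, fill_value=0)
    )
    mm.index.name = "sample_id"
    return mm.astype(int)


def mutation_frequency(
    mm: pd.DataFrame, subtypes: pd.Series, top_k: int = 10
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-subtype mutation frequency of the top_k pooled genes.

    Returns (gene x subtype frequency table, per-subtype overall altered
    rate), where the altered rate is the fraction of samples carrying a
    mutation in at least one of the top_k genes.  Empty subtypes get
    NaN.
    """
    unlabeled = mm.index.difference(subtypes.index)
    if len(unlabeled):
        raise ValueError(f"unlabeled samples in mutation matrix: {list(unlabeled)[:5]}")
    labels = subtypes.reindex(mm.index)
    pooled = mm.mean(axis=0).sort_values(ascending=False)
    top_genes = list(pooled.index[:top_k])
    freq = pd.DataFrame(index=top_genes, columns=["I", "II", "III", "IV"], dtype=float)
    altered = pd.Series(index=["I", "II", "III", "IV"], dtype=float, name="altered_rate")
    for label in ["I", "II", "III", "IV"]:
        sub = mm.loc[labels == label, top_genes]
        if len(sub) == 0:
            continue
        freq[label] = sub.mean(axis=0)
        altered[label] = (sub.sum(axis=1) > 0).mean()
    return freq, altered


@dataclass
class InteractionResult:
    gene_a: str
    gene_b: str
    both: int
    a_only: int
    b_only: int
    neither: int
    odds_ratio: float
    p_value: float
    q_value: float
    direction: str  # co-occurrence iff OR > 1


def somatic_interaction(mm: pd.DataFrame, gene_list: list[str]) -> list[InteractionResult]:
    """Pairwise co-occurrence / exclusivity over unordered gene pairs.

    Two-sided Fisher exact p per pair (minimum-likelihood definition),
    odds ratio with Haldane 0.5 correction when any cell is zero, and a
    BH-adjusted q across all pairs.
    """
    if len(gene_list) < 2:
        raise ValueError("need at least 2 genes for interaction testing")
    if len(set(gene_list)) < len(gene_list):
        raise ValueError("gene paired with itself (duplicate in gene_list)")
    missing = [g for g in gene_list if g not in mm.columns]
    if missing:
        raise ValueError(f"gene(s) absent from mutation matrix: {missing}")
    if len(mm) < 10:
        raise ValueError("interaction testing requires cohort n >= 10")
    results = []
    for a, b in combinations(gene_list, 2):
        va, vb = mm[a].values.astype(bool), mm[b].values.astype(bool)
        both = int((va & vb).sum())
        a_only = int((va & ~vb).sum())
        b_only = int((~va & vb).sum())
        neither = int((~va & ~vb).sum())
        table = np.array([[both, a_only], [b_only, neither]], dtype=float)
        p = fisher_two_sided(table)
        if (table == 0).any():
            table = table + 0.5
        odds = (table[0, 0] * table[1, 1]) / (table[0, 1] * table[1, 0])
        results.append(
            InteractionResult(
                gene_a=a,
                gene_b=b,
                both=both,
                a_only=a_only,
                b_only=b_only,
                neither=neither,
                odds_ratio=float(odds),
                p_value=float(p),
                q_value=np.nan,
                direction="co-occurrence" if odds > 1 else "exclusivity",
            )
        )
    qvals = multipletests([r.p_value for r in results], method="fdr_bh")[1]
    for r, q in zip(results, qvals):
        r.q_value = float(q)
    return results


def interaction_table(results: list[InteractionResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])


def mutation_group_association(
    mm: pd.DataFrame, gene: str, group_flags: pd.Series
) -> dict:
    """2x2 association of a gene's mutation status with a binary grouping.

    Pearson chi-square, falling back to the Fisher exact test when any
    expected cell is below 5.  Returns test name, p and the mutated
    proportion per group.
    """
    if gene not in mm.columns:
        raise ValueError(f"gene {gene!r} absent from mutation matrix")
    flags = group_flags.reindex(mm.index)
    if flags.isna().any():
        raise ValueError("group flags missing for some samples")
    levels = pd.unique(flags)
    if len(levels) != 2 or any((flags == g).sum() == 0 for g in levels):
        raise ValueError("association test requires two non-empty groups")
    mut = mm[gene].astype(bool)
    table = np.array(
        [
            [int((mut & (flags == g)).sum()), int((~mut & (flags == g)).sum())]
            for g in levels
        ],
        dtype=float,
    )
    expected = stats.contingency.expected_freq(table)
    if (expected < 5).any():
        p = fisher_two_sided(table)
        test = "fisher"
    else:
        _, p, _, _ = stats.chi2_contingency(table, correction=False)
        test = "chi2"
    props = {str(g): float(mut[flags == g].mean()) for g in levels}
    return {"test": test, "p_value": float(p), "proportions": props}
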