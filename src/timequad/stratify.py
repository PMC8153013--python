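"""Percentile positivity calls, survival-optimised cutpoint selection and
the four-quadrant TIME classification.

Positivity is a rank rule: for cut percentile q, the top floor(n*q/100)
samples by score are "positive".  For tie-free continuous scores this is
identical to thresholding at the (100-q)th percentile value, but it
makes positive fractions exact and deterministic.  The cut percentile
itself is selected from a grid (top 10/20/30/40/50%) by minimising the
two-group log-rank p-value of positive vs negative overall survival.

Quadrants: type I = PD-L1+/TIL+, type II = PD-L1-/TIL-,
type III = PD-L1+/TIL-, type IV = PD-L1-/TIL+.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .survival import km_logrank

DEFAULT_GRID = (10, 20, 30, 40, 50)
SUBTYPE_OF_FLAGS = {
    (True, True): "I",
    (False, False): "II",
    (True, False): "III",
    (False, True): "IV",
}


def call_positivity(scores: pd.Series, percentile_q: float) -> pd.Series:
    """Flag the top floor(n*q/100) samples by score as positive.

    Boundary ties resolve by descending score then stable input order.
    Returns a boolean Series aligned to the input index.
    """
    n = len(scores)
    if n < 10:
        raise ValueError(f"positivity call requires n >= 10, got {n}")
    if not 0 < percentile_q < 100:
        raise ValueError(f"percentile must lie in (0, 100), got {percentile_q}")
    vals = np.asarray(scores, dtype=float)
    if np.all(vals == vals[0]):
        raise ValueError("all scores identical: positivity undefined")
    n_pos = int(np.floor(n * percentile_q / 100.0))
    order = np.argsort(-vals, kind="stable")
    flags = np.zeros(n, dtype=bool)
    flags[order[:n_pos]] = True
    return pd.Series(flags, index=scores.index, name="positive")


@dataclass
class CutpointSelection:
    """Chosen percentile with the per-percentile log-rank p-values."""

    chosen_percentile: int
    p_values: pd.Series  # indexed by grid percentile


def select_positive_cutpoint(
    scores: pd.Series,
    clinical: pd.DataFrame,
    grid: tuple[int, ...] = DEFAULT_GRID,
) -> CutpointSelection:
    """Pick the grid percentile whose positive/negative survival split is
    most significant (minimum log-rank p); ties go to the smaller
    percentile (the more stringent positivity definition).

    Samples lacking follow-up are excluded from the survival test but
    not from the positivity call.  A split with an event-free arm gets
    p = 1 with a warning rather than an error.
    """
    grid = tuple(grid)
    if any(not 0 < q < 100 for q in grid) or list(grid) != sorted(set(grid)):
        raise ValueError(f"grid must be strictly increasing within (0,100): {grid}")
    clin = clinical.set_index("sample_id") if "sample_id" in clinical.columns else clinical
    clin = clin.loc[clin.index.intersection(scores.index)]
    clin = clin.dropna(subset=["os_months", "event"])
    if clin["event"].sum() < 1:
        raise ValueError("cohort has no observed events; cutpoint undefined")
    pvals = {}
    for q in grid:
        flags = call_positivity(scores, q).loc[clin.index]
        groups = np.where(flags, "positive", "negative")
        events = clin["event"].values
        if events[flags.values].sum() == 0 or events[~flags.values].sum() == 0:
            warnings.warn(f"percentile {q}: one arm is event-free; recording p = 1")
            pvals[q] = 1.0
            continue
        _, lr = km_logrank(pd.Series(groups, index=clin.index), clin)
        pvals[q] = lr.p_value
    p_series = pd.Series(pvals, name="logrank_p")
    chosen = min(grid, key=lambda q: (p_series[q], q))
    return CutpointSelection(chosen_percentile=int(chosen), p_values=p_series)


def classify_subtypes(pdl1_pos: pd.Series, til_pos: pd.Series) -> pd.Series:
    """Map the two positivity flags onto the four TIME quadrants."""
    if set(pdl1_pos.index) != set(til_pos.index):
        only = set(pdl1_pos.index) ^ set(til_pos.index)
        raise ValueError(f"positivity calls cover different samples: {sorted(only)[:5]}")
    til_pos = til_pos.loc[pdl1_pos.index]
    labels = [
        SUBTYPE_OF_FLAGS[(bool(p), bool(t))]
        for p, t in zip(pdl1_pos.values, til_pos.values)
    ]
    return pd.Series(pd.Categorical(labels, categories=["I", "II", "III", "IV"]),
                     index=pdl1_pos.index, name="subtype")


def subtype_proportions(subtypes: pd.Series) -> pd.Series:
    """Fraction of the cohort in each quadrant (sums to 1)."""
    return subtypes.value_counts(normalize=True, sort=False).reindex(
        ["I", "II", "III", "IV"], fill_value=0.0
    )
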