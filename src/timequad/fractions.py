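"""Regrouping of 22 deconvolved leukocyte fractions into 8 broad categories.

The 22 columns follow the standard LM22 naming of bulk deconvolution
output.  They are summed into eight lineages — T cells, B cells,
macrophages (incl. monocytes), dendritic cells, NK cells, mast cells,
eosinophils and neutrophils — so per-sample category fractions still
sum to 1.
"""

from __future__ import annotations

import pandas as pd

#: LM22 column -> broad category. 22 entries mapping onto 8 categories.
LM22_REGROUP: dict[str, str] = {
    "B cells naive": "B cells",
    "B cells memory": "B cells",
    "Plasma cells": "B cells",
    "T cells CD8": "T cells",
    "T cells CD4 naive": "T cells",
    "T cells CD4 memory resting": "T cells",
    "T cells CD4 memory activated": "T cells",
    "T cells follicular helper": "T cells",
    "T cells regulatory (Tregs)": "T cells",
    "T cells gamma delta": "T cells",
    "NK cells resting": "NK cells",
    "NK cells activated": "NK cells",
    "Monocytes": "Macrophages",
    "Macrophages M0": "Macrophages",
    "Macrophages M1": "Macrophages",
    "Macrophages M2": "Macrophages",
    "Dendritic cells resting": "DC cells",
    "Dendritic cells activated": "DC cells",
    "Mast cells resting": "Mast cells",
    "Mast cells activated": "Mast cells",
    "Eosinophils": "Eosinophils",
    "Neutrophils": "Neutrophils",
}

CATEGORIES = (
    "T cells",
    "B cells",
    "Macrophages",
    "DC cells",
    "NK cells",
    "Mast cells",
    "Eosinophils",
    "Neutrophils",
)


def regroup_fractions(fractions: pd.DataFrame) -> pd.DataFrame:
    """Sum a sample x 22 fraction table into the 8 broad categories.

    Columns must match the LM22 names exactly; rows keep their sum.
    """
    missing = [c for c in LM22_REGROUP if c not in fractions.columns]
    if missing:
        raise ValueError(f"fraction table missing LM22 column(s) {missing}")
    out = pd.DataFrame(index=fractions.index)
    for cat in CATEGORIES:
        cols = [c for c, g in LM22_REGROUP.items() if g == cat]
        out[cat] = fractions[cols].sum(axis=1)
    return out
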