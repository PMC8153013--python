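# timequad

Stratification of cancer cohorts into the four **tumor immune
microenvironment (TIME) quadrants** from bulk expression data, with the
downstream survival, genomics and transcriptomics comparisons that the
classification supports.

## Who this is for

Computational immuno-oncology analysts working with pan-cancer or
single-disease bulk RNA-seq cohorts (expression + clinical follow-up +
somatic mutation calls) who want a reproducible, testable implementation
of PD-L1/TIL quadrant typing — including on fully synthetic cohorts when
real data cannot be shared.

## The method

Two per-sample axes define the classification:

* **PD-L1 axis** — expression of *CD274* (TPM).
* **TIL axis** — a composite *TIL Z score*: genes are z-scored across the
  cohort on the `log2(TPM+1)` scale, averaged within each of 26 immune
  determinant gene sets (10 MHC-class molecules, 5 immunoinhibitors,
  5 immunostimulators and 6 immune-cell types), and combined as

  `TIL_Z(s) = Σ_d w_d · mean_{g∈d} z_gs / 26`, with weights `w_d = ±1`
  (suppressive determinants enter negatively).

Positivity on each axis is a **rank rule**: at cut percentile *q*, the
top `⌊n·q/100⌋` samples are positive. The percentile is chosen from the
grid {10, 20, 30, 40, 50} by minimising the two-group log-rank p-value
of the positive-vs-negative overall-survival split (canonical cuts: top
10 % for PD-L1, median for TIL). The two flags map to quadrants:

| | TIL+ | TIL− |
|---|---|---|
| **PD-L1+** | type I | type III |
| **PD-L1−** | type IV | type II |

Around the classification the package implements: Mann–Whitney ROC/AUC
for checkpoint-inhibitor response predictors and a ridge-logistic
PD-L1 + TIL combination; tumor mutation burden (counted somatic variants
per 38 Mb of exome); per-quadrant mutation spectra with Fisher-exact
co-occurrence/exclusivity; one-vs-rest differential expression
(|log2FC| ≥ 2, FDR < 0.05) feeding normalised gene/pathway dysregulation
scores (each pathway's four subtype scores sum to 1); hypergeometric
enrichment (p < 0.01, overlap ≥ 3); Kaplan–Meier/log-rank/Cox survival
models; and regrouping of 22 deconvolved leukocyte fractions into 8
lineages. A seeded synthetic-cohort generator reproduces the statistical
structure all of this assumes (see `docs/methods.md`).

## Worked example

Simulate a cohort, score and classify it:

```bash
python analysis/01_simulate_cohort.py --seed 1 --n 3000
python analysis/02_til_score_and_stratify.py
```

which prints (seed 1):

```
classifying at top 10% (PD-L1) / top 50% (TIL)
quadrant proportions (%): {'I': 3.93, 'II': 43.93, 'III': 6.07, 'IV': 46.07}
Spearman(PD-L1, TIL Z) = -0.147 (p = 4.77e-16)
4-group log-rank: chi2 = 8.91, df = 3, p = 3.05e-02
```

Read: with a weak negative PD-L1–TIL rank correlation (here −0.147),
the double-positive quadrant (type I, 3.93 %) is depleted below the
5 % expected under independence of a 10 % × 50 % cut, and the four
quadrants separate in overall survival. Continue with
`analysis/03…06` for response AUCs, mutation spectra, pathway scores
and the Cox forest table; e.g. `analysis/06_survival_analysis.py`
reports `multivariate TIL+ hazard ratio = 0.892 (planted 0.85)`.

The same steps are available as a CLI (`time-quad simulate|til-score|
stratify|roc|genomics|run`); `time-quad run --config run.yaml` executes
the whole pipeline and writes a run manifest.

## Repository layout

- `src/timequad/` — the library (io, til, stratify, roc, genomics,
  pathways, survival, fractions, simulate, cli).
- `analysis/` — numbered narrative drivers over the library.
- `tests/` — unit, property and end-to-end acceptance tests.
- `docs/methods.md` — model, parameter and design documentation.
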