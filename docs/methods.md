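# Methods

## TIL Z score

The tumor-infiltrating-lymphocyte state of a sample is summarised by an
average-z composite over 26 immune determinant gene sets. Expression is
taken to `log2(TPM+1)`, each gene is standardised across the cohort
(mean 0, sample SD with ddof = 1), set scores are means of member-gene
z values, and the TIL Z score is the weighted mean of the 26 set scores
with weights ±1 (MHC molecules, immunostimulators and effector /
memory T-cell sets enter with +1; immunoinhibitors, Tregs and MDSCs
with −1). Constant genes get z = 0 rather than being dropped, so set
means stay defined independently of cohort composition. The score is
invariant to any per-gene affine rescaling of the input.

Determinant membership is configuration, not code: the packaged default
(`data/determinants_default.json`, editable JSON) provides the required
class structure — 20 single-factor sets (10 MHC, 5 inhibitors,
5 stimulators) and 6 cell-type sets — with membership drawn from
standard marker genes. Any conforming 26-set configuration can be
substituted. The upstream immunophenogram-style scorers additionally
discretise to a 0–10 score; only the average Z is implemented here
because only it feeds the classification.

Signature scores (T-cell exhaustion, PMN-/M-MDSC) use the same mean-z
machinery. This is a deliberate, simpler stand-in for kernel-based
set-variation scoring (GSVA): downstream comparisons are rank-based
across samples, which mean-z preserves. Cytokine composites
(immuno-activating: IFNG/TNF/IL12A/IL12B; immuno-suppressive:
VEGFA/TGFB1/IL6/IL10; cytolytic: GZMB/PRF1) are means of **raw TPM**,
because those composites are conventionally reported on the expression
scale.

## Positivity, cutpoints and quadrants

Positivity at cut percentile *q* is a rank rule: the top
`⌊n·q/100⌋` scores are positive, boundary ties resolved by descending
score then stable input order. For tie-free continuous scores this is
exactly a percentile-value threshold, but it makes positive fractions
deterministic (the type I + III share equals the PD-L1 positive
fraction exactly, and I + IV the TIL fraction).

The cut percentile is selected over the grid {10, 20, 30, 40, 50} (top-
X% definitions) by minimising the positive-vs-negative two-group
log-rank p-value; ties break toward the smaller percentile (more
stringent positivity). No multiple-testing correction is applied across
the five candidate splits — this is an exploratory selector and is
documented as such; with a mild underlying effect its argmin is noisy,
which is why the analysis drivers classify at the canonical top-10 %
(PD-L1) / median (TIL) cuts while reporting the grid. A split with an
event-free arm records p = 1 with a warning instead of failing.
Percentiles are computed pan-cohort, not within disease subsets.

Quadrants: I = PD-L1+/TIL+, II = −/−, III = +/−, IV = −/+. The PD-L1
score is CD274 TPM (gene symbol configurable).

## Response ROC

AUC is the Mann–Whitney rank estimator (ties counted ½), which equals
the trapezoidal area under the empirical ROC; both identities are
cross-checked in the tests against brute-force pair counting. The
combined PD-L1 + TIL predictor is a bivariate logistic model on
z-standardised features fit by penalised maximum likelihood with ridge
λ = 1e-4 — enough to keep perfect separation and collinearity finite
while negligible at realistic n. A rank-sum alternative (mean of the
two percentile ranks) is provided. The published combination rule
behind this predictor is not specified anywhere we could verify, so
in-sample bivariate logistic scoring is our declared default; this is
the largest open methodological choice in the package.

## Genomics

TMB counts Missense, Nonsense, Nonstop, Translation_Start_Site,
Splice_Site, Frame_Shift_Ins/Del, In_Frame_Ins/Del and Silent variants
per sample and divides by a 38 Mb exome (both the class list and the
denominator are configurable). Unrecognised classification strings are
excluded with a warning. Somatic interaction tests every unordered gene
pair with the two-sided Fisher exact test (minimum-likelihood
definition, validated against full hypergeometric enumeration for all
2×2 tables with n ≤ 40), reports odds ratios with a Haldane 0.5
correction when a cell is zero, and adds Benjamini–Hochberg q-values
across pairs while keeping raw p (interaction calls are conventionally
made at raw p < 0.01). Mutation-vs-group association uses Pearson
chi-square with an automatic Fisher fallback when any expected cell is
below 5. The per-subtype "altered rate" denominator is the top-k gene
panel (k exposed, default 10), since the panel definition is ambiguous
in the source analyses. Neoantigen counts, when present, are consumed
as an input column, never computed.

## Differential expression and pathway scores

The DE contract is deliberately simple and fully specified: per gene,
`log2FC = log2((mean CPM_k + 0.5) / (mean CPM_rest + 0.5))` under a
one-vs-rest design, two-sided rank-sum p on log-CPM, BH FDR, and a DEG
flag at |log2FC| ≥ 2 and FDR < 0.05. This replaces a negative-binomial
exact test; externally computed per-subtype log2FC/FDR tables can be
supplied instead (`read_de_override`), so any DE engine can be plugged
in.

Scoring, with `log2FC_k = 0` wherever the gene is not a DEG in
subtype k:

1. mean score = `Σ_k log2FC_k / 4` (divisor always 4);
2. gene score in k = `|log2FC_k| / |mean score|`;
3. pathway score in k = pathway's summed gene scores in k divided by
   the same sum totalled over all four subtypes, so every retained
   pathway's four scores sum to 1.

The literal mean in step 1 is signed; when fold changes cancel to an
exactly zero mean the ratio in step 2 is undefined and the gene is
excluded with a warning (taking |mean| in the denominator otherwise
preserves the intended magnitude ratio when the mean is negative).
Scores are invariant to scaling all fold changes by a positive
constant. Enrichment is a one-sided hypergeometric test per pathway
with the universe defaulting to all genes in the matrix, filtered at
p < 0.01 and overlap ≥ 3.

## Survival statistics

Kaplan–Meier estimation, the k-group log-rank test and Cox
proportional-hazards fits are delegated to lifelines; with survival in
months, tied event times are common, and lifelines' Efron tie handling
is the appropriate default. The multivariate workflow mirrors a
forest-table analysis: every covariate is first fit alone, and only
univariately significant covariates (p < 0.05) enter the joint model —
no stepwise refinement. Constant covariates are dropped with a warning;
of a perfectly collinear pair the later column is dropped. Continuous
covariates flagged "high vs low" are dichotomised at the cohort median.
Samples without follow-up are excluded from survival operations only,
never from classification. Significance is 0.05 throughout.

## Synthetic cohort generator

The generator emulates the joint structure the analysis assumes; its
defaults are the study conditions and are not tuned per test:

* **Latent infiltration** L ~ N(0,1). Determinant genes load on L with
  strength 0.9 and sign matching their determinant's weight, plus
  N(0, 0.8²) gene noise on the log2 scale; baselines are U(3, 7)
  log2-TPM. With ~50 determinant genes the cohort-z TIL score tracks L
  at Spearman > 0.8 by n = 1000.
* **PD-L1**: `log2 CD274 = 4 − b·L + N(0,1)`, with b calibrated by
  monotone bisection (20 iterations, tolerance 0.01, 10⁴-sample probe)
  so that Spearman(PD-L1, TIL Z) hits the target, default −0.159.
* **Survival**: exponential times with baseline hazard 0.02/month and
  log-hazard offsets log(0.85) for TIL+ and log(1.0/1.33/1.87/3.41)
  for stages I–IV (stage probabilities 0.33/0.32/0.24/0.11); censoring
  independent U(0, 140) months, yielding ≈ 25–30 % censored.
* **Mutations**: per-gene, per-subtype Bernoulli rates; TP53 defaults
  to 24/41/51/29 % across quadrants I–IV, with TTN, MUC16, LRP1B,
  CSMD3, BRAF, GTF2I and PIK3CA at plausible companion rates.
* **Counts**: negative binomial with dispersion 0.1 (typical bulk
  RNA-seq) around TPM-proportional means at a 3×10⁶ library size, with
  planted one-vs-rest log2 fold changes of ±3 on 20 designated genes
  (5 per subtype).
* **Fractions**: 22 LM22-style columns drawn per sample from a
  Dirichlet whose 8-category means depend on the subtype (T-cell
  aggregate 0.47/0.28/0.36/0.36), concentration 7 (matching an SD of
  roughly 0.17 at mean 0.47).
* **Response**: Bernoulli with logit −0.7 + 1.0·z(TIL) + 0.5·z(log
  PD-L1), giving ≈ 35 % responders overall.

All randomness flows from one seed through independent spawned streams
per table; identical configs are byte-identical on disk. An exponential
(rather than Weibull) baseline keeps the planted hazard ratios exactly
interpretable.

What the generator does **not** emulate: cancer-type mixtures and batch
effects, realistic gene–gene correlation beyond the single latent
factor, mutational signatures or CNV segmentation, and any
cohort-specific response biology. Tests passing on these cohorts
demonstrate the pipeline's bookkeeping, calibration and recovery
properties — not clinical validity on real data.

## Problem sizes and numerics

The test suite and the acceptance script use cohorts of 600–5,000
samples and ~200 genes, with 4,000 samples for hazard-ratio recovery,
5,000 for correlation/depletion checks, 100 replicates of n = 1,000
for cutpoint recovery, and 800 per subtype for mutation-rate recovery
— sizes at which the planted effects are comfortably identifiable while
a full run stays in the minutes range on one core. Oracle-equivalence
assertions (brute-force pathway scores, hypergeometric Fisher
enumeration, AUC pair counting) use 1e-12..1e-9 tolerances; stochastic
recovery assertions use the generator's own planted values with bands
stated in the tests. Degenerate inputs fail loudly: all-tied scores,
single-sample z-scoring, event-free cohorts, zero-expression columns
and empty gene-set intersections all raise with a named cause rather
than propagating NaN.

## Known limitations

* The TIL determinant membership shipped is a reasonable default, not a
  canonical list; results depend on it only through the configured
  JSON.
* The cutpoint selector's minimum-p criterion is exploratory and
  inherits the usual optimism of maximally selected statistics.
* The DE engine is rank-based; heavy-tailed count noise at very small
  group sizes (< 10) will be underpowered relative to NB-likelihood
  methods.
* In-sample AUC for the combined predictor is optimistic by
  construction; no cross-validation is provided.
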