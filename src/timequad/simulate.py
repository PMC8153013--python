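"""Synthetic pan-cancer cohort generator.

Emulates the statistical structure the TIME quadrant analysis assumes,
so that every pipeline stage is testable without external downloads:

* a latent infiltration factor L ~ N(0, 1) on which the immune
  determinant genes load (sign-matched to each determinant's weight);
* PD-L1 (CD274) expression weakly negatively rank-correlated with the
  resulting TIL Z score (default Spearman target -0.159, calibrated by
  bisection on the PD-L1 loading);
* exponential overall-survival times whose log-hazard carries a planted
  TIL+ effect (default HR 0.85) and tumor-stage effects
  (1.0 / 1.33 / 1.87 / 3.41 for stages I-IV), with independent uniform
  censoring targeting ~30%;
* a MAF with per-gene, per-subtype Bernoulli mutation rates (default
  TP53 at 24/41/51/29% across quadrants I-IV);
* negative-binomial counts (dispersion 0.1) with planted per-subtype
  fold changes on designated genes;
* Dirichlet 22-column leukocyte fractions with per-subtype means
  (T-cell aggregate 0.47 / 0.28 / 0.36 / 0.36);
* Bernoulli ICI-response labels from a logistic model on the
  standardised TIL Z and log PD-L1.

All randomness flows from a single seed through independent spawned
streams per table, so identical configs reproduce byte-identical
cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .fractions import CATEGORIES, LM22_REGROUP
from .io import ExpressionMatrix, GeneSet
from .stratify import call_positivity, classify_subtypes
from .til import default_determinants, til_z_score

SUBTYPES = ("I", "II", "III", "IV")

DEFAULT_MUTATION_RATES: dict[str, tuple[float, float, float, float]] = {
    "TP53": (0.24, 0.41, 0.51, 0.29),
    "TTN": (0.29, 0.29, 0.46, 0.26),
    "MUC16": (0.16, 0.18, 0.28, 0.16),
    "LRP1B": (0.10, 0.11, 0.23, 0.09),
    "CSMD3": (0.11, 0.13, 0.25, 0.09),
    "BRAF": (0.125, 0.04, 0.05, 0.07),
    "GTF2I": (0.10, 0.01, 0.01, 0.02),
    "PIK3CA": (0.12, 0.10, 0.12, 0.11),
}

#: broad-category Dirichlet means per subtype (T cells, B, Macro, DC, NK,
#: Mast, Eos, Neut); renormalised at generation time.
DEFAULT_FRACTION_MEANS: dict[str, tuple[float, ...]] = {
    "I": (0.47, 0.08, 0.31, 0.06, 0.04, 0.04, 0.002, 0.004),
    "II": (0.28, 0.09, 0.46, 0.04, 0.04, 0.08, 0.002, 0.01),
    "III": (0.36, 0.10, 0.41, 0.05, 0.04, 0.05, 0.002, 0.01),
    "IV": (0.36, 0.09, 0.37, 0.05, 0.05, 0.07, 0.002, 0.01),
}

#: planted one-vs-rest DE effects: gene -> (subtype, log2 fold change)
DEFAULT_DE_EFFECTS: dict[str, tuple[str, float]] = {
    **{f"DEG_I_{i}": ("I", 3.0) for i in range(1, 6)},
    **{f"DEG_II_{i}": ("II", 3.0) for i in range(1, 6)},
    **{f"DEG_III_{i}": ("III", 3.0) for i in range(1, 6)},
    **{f"DEG_IV_{i}": ("IV", -3.0) for i in range(1, 6)},
}


@dataclass
class CohortConfig:
    """Study conditions for a synthetic cohort."""

    n_samples: int = 1000
    seed: int = 0
    target_spearman_pdl1_til: float = -0.159
    planted_hr_til_pos: float = 0.85
    stage_hrs: tuple[float, float, float, float] = (1.0, 1.33, 1.87, 3.41)
    stage_probs: tuple[float, float, float, float] = (0.33, 0.32, 0.24, 0.11)
    pdl1_percentile: int = 10
    til_percentile: int = 50
    mutation_rates: dict = field(default_factory=lambda: dict(DEFAULT_MUTATION_RATES))
    de_effects: dict = field(default_factory=lambda: dict(DEFAULT_DE_EFFECTS))
    fraction_means: dict = field(default_factory=lambda: dict(DEFAULT_FRACTION_MEANS))
    fraction_concentration: float = 7.0
    response_beta: tuple[float, float] = (1.0, 0.5)  # (til_z, pdl1) on z scale
    response_intercept: float = -0.7
    n_noise_genes: int = 120
    determinant_loading: float = 0.9
    gene_noise_sd: float = 0.8
    baseline_hazard: float = 0.02  # events per month
    censor_horizon_months: float = 140.0
    nb_dispersion: float = 0.1
    library_size: float = 3e6


@dataclass
class SyntheticCohort:
    """All tables of one simulated cohort plus the ground-truth latents."""

    tpm: ExpressionMatrix
    counts: ExpressionMatrix
    clinical: pd.DataFrame
    maf: pd.DataFrame
    fractions: pd.DataFrame
    response: pd.Series
    truth: dict


def _probe_til_spearman(b: float, loadings: np.ndarray, weights: np.ndarray,
                        set_sizes: np.ndarray, cfg: CohortConfig,
                        rng: np.random.Generator, n: int = 10_000) -> float:
    """Spearman between the PD-L1 driver and the score a cohort-z TIL
    aggregation would produce, on a fresh probe cohort of size n."""
    L = rng.standard_normal(n)
    # per-set mean of z-scored member genes ~ load*L + noise/sqrt(size)
    score = np.zeros(n)
    for w, load, size in zip(weights, loadings, set_sizes):
        gene_z = load * L[None, :] + rng.standard_normal((size, n)) * cfg.gene_noise_sd
        score += w * gene_z.mean(axis=0)
    pdl1 = -b * L + rng.standard_normal(n)
    return float(spearmanr(pdl1, score).statistic)


def calibrate_pdl1_loading(cfg: CohortConfig, rng: np.random.Generator) -> float:
    """Bisection on the PD-L1 loading b so that Spearman(PD-L1, TIL Z)
    hits the configured target (tolerance 0.01, 20 iterations, 1e4-sample
    probe).  Monotone: larger b -> more negative correlation."""
    target = cfg.target_spearman_pdl1_til
    if abs(target) > 0.95:
        raise ValueError(f"unsatisfiable Spearman target {target}")
    if target == 0:
        return 0.0
    dets = default_determinants()
    weights = np.array([d.weight for d in dets], dtype=float)
    set_sizes = np.array([len(d.genes) for d in dets])
    loadings = np.array([d.weight * cfg.determinant_loading for d in dets])
    probe_rng = np.random.default_rng(rng.integers(2**31))
    lo, hi = 0.0, 5.0
    b = 1.0
    for _ in range(20):
        b = 0.5 * (lo + hi)
        rho = _probe_til_spearman(
            b, loadings, weights, set_sizes, cfg,
            np.random.default_rng(probe_rng.integers(2**31)),
        )
        if abs(rho - target) < 0.01:
            break
        if rho > target:  # not negative enough yet
            lo = b
        else:
            hi = b
    return b


def _gene_catalog(cfg: CohortConfig) -> tuple[list[str], dict[str, float]]:
    """Assemble the simulated gene list with per-gene L-loadings."""
    dets = default_determinants()
    loadings: dict[str, float] = {}
    for d in dets:
        for g in d.genes:
            loadings.setdefault(g, d.weight * cfg.determinant_loading)
    extra = [
        "TOX", "ENTPD1", "CXCR2", "CSF3R", "CSF1R", "CCR2",
        "IL12A", "IL12B", "VEGFA", "TGFB1", "IL6", "IL10",
    ]
    for g in extra:
        loadings.setdefault(g, 0.0)
    for g in cfg.de_effects:
        loadings.setdefault(g, 0.0)
    for i in range(cfg.n_noise_genes):
        loadings.setdefault(f"NOISE_{i:04d}", 0.0)
    genes = list(loadings)
    return genes, loadings


def sample_maf(
    subtype_labels: pd.Series,
    mutation_rates: dict[str, tuple[float, float, float, float]],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Draw a MAF by per-gene, per-subtype Bernoulli mutation rates."""
    samples = list(subtype_labels.index)
    sub_idx = subtype_labels.map({"I": 0, "II": 1, "III": 2, "IV": 3}).values.astype(int)
    rows = []
    for gene, rates in mutation_rates.items():
        p = np.asarray(rates)[sub_idx]
        hit = rng.random(len(samples)) < p
        for s in np.flatnonzero(hit):
            rows.append((gene, samples[s], "Missense_Mutation"))
    return pd.DataFrame(
        rows, columns=["Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification"]
    )


def generate(cfg: CohortConfig) -> SyntheticCohort:
    """Simulate a full cohort under ``cfg``; see the module docstring."""
    master = np.random.SeedSequence(cfg.seed)
    streams = master.spawn(8)
    rng_cal, rng_expr, rng_surv, rng_maf, rng_counts, rng_frac, rng_resp, rng_misc = (
        np.random.default_rng(s) for s in streams
    )
    n = cfg.n_samples
    samples = [f"S{i:05d}" for i in range(n)]

    # --- latent infiltration factor and expression ---------------------
    L = rng_expr.standard_normal(n)
    b = calibrate_pdl1_loading(cfg, rng_cal)
    genes, loadings = _gene_catalog(cfg)
    base = rng_expr.uniform(3.0, 7.0, size=len(genes))
    log2tpm = (
        base[:, None]
        + np.array([loadings[g] for g in genes])[:, None] * L[None, :]
        + rng_expr.standard_normal((len(genes), n)) * cfg.gene_noise_sd
    )
    pdl1_log = 4.0 - b * L + rng_expr.standard_normal(n)
    gene_list = genes + ["CD274"]
    log2tpm = np.vstack([log2tpm, pdl1_log[None, :]])
    tpm_vals = np.power(2.0, log2tpm)
    tpm = ExpressionMatrix(
        pd.DataFrame(tpm_vals, index=gene_list, columns=samples), unit="TPM"
    )

    # --- truth TIL Z / PD-L1 flags and subtypes ------------------------
    log_mat = ExpressionMatrix(np.log2(tpm.values + 1.0), unit="log2TPM")
    til_z = til_z_score(log_mat)
    pdl1 = tpm.values.loc["CD274"]
    pdl1_pos = call_positivity(pdl1, cfg.pdl1_percentile)
    til_pos = call_positivity(til_z, cfg.til_percentile)
    subtype = classify_subtypes(pdl1_pos, til_pos)

    # --- clinical: stages and exponential survival ---------------------
    stage_idx = rng_surv.choice(4, size=n, p=np.asarray(cfg.stage_probs) / sum(cfg.stage_probs))
    stage = np.array(["I", "II", "III", "IV"])[stage_idx]
    log_hazard = (
        np.log(cfg.baseline_hazard)
        + np.log(cfg.planted_hr_til_pos) * til_pos.values
        + np.log(np.asarray(cfg.stage_hrs))[stage_idx]
    )
    t_event = rng_surv.exponential(scale=1.0 / np.exp(log_hazard))
    t_censor = rng_surv.uniform(0.0, cfg.censor_horizon_months, size=n)
    os_months = np.minimum(t_event, t_censor)
    event = (t_event <= t_censor).astype(int)
    age = np.clip(rng_surv.normal(58.0, 14.0, size=n), 20, 90).round(1)
    sex = np.where(rng_surv.random(n) < 0.5, "male", "female")
    clinical = pd.DataFrame(
        {
            "sample_id": samples,
            "os_months": np.round(os_months, 3),
            "event": event,
            "age": age,
            "sex": sex,
            "stage": stage,
        }
    )

    # --- MAF ------------------------------------------------------------
    maf = sample_maf(subtype, cfg.mutation_rates, rng_maf)

    # --- negative-binomial counts with planted DE -----------------------
    frac = tpm.values.values / tpm.values.values.sum(axis=0, keepdims=True)
    mu = frac * cfg.library_size
    for gene, (k, lfc) in cfg.de_effects.items():
        gi = gene_list.index(gene)
        mu[gi, subtype.values == k] *= 2.0**lfc
    r = 1.0 / cfg.nb_dispersion
    counts_vals = rng_counts.negative_binomial(r, r / (r + np.maximum(mu, 1e-8)))
    counts = ExpressionMatrix(
        pd.DataFrame(counts_vals.astype(float), index=gene_list, columns=samples),
        unit="counts",
    )

    # --- 22-column Dirichlet fractions ----------------------------------
    lm22_cols = list(LM22_REGROUP)
    frac_rows = np.empty((n, 22))
    cat_of = [LM22_REGROUP[c] for c in lm22_cols]
    within = rng_frac.uniform(0.5, 1.5, size=22)  # fixed within-category split
    alpha22 = {}
    for lab in SUBTYPES:
        means8 = np.asarray(cfg.fraction_means[lab], dtype=float)
        means8 = means8 / means8.sum()
        alpha = np.empty(22)
        # split each category mean over its member columns
        for cat, mean_c in zip(CATEGORIES, means8):
            idx = [j for j, c in enumerate(cat_of) if c == cat]
            w = within[idx] / within[idx].sum()
            alpha[idx] = mean_c * w
        alpha22[lab] = alpha * cfg.fraction_concentration
    for s_i, lab in enumerate(subtype.values):
        frac_rows[s_i] = rng_frac.dirichlet(alpha22[lab])
    fractions = pd.DataFrame(frac_rows, index=samples, columns=lm22_cols)
    fractions.index.name = "sample_id"

    # --- ICI response ----------------------------------------------------
    tz = (til_z - til_z.mean()) / til_z.std(ddof=0)
    pz = (np.log2(pdl1 + 1) - np.log2(pdl1 + 1).mean()) / np.log2(pdl1 + 1).std(ddof=0)
    eta = cfg.response_intercept + cfg.response_beta[0] * tz + cfg.response_beta[1] * pz
    prob = 1.0 / (1.0 + np.exp(-eta))
    response = pd.Series(
        (rng_resp.random(n) < prob).astype(int), index=samples, name="response"
    )

    truth = {
        "L": pd.Series(L, index=samples, name="L"),
        "til_z": til_z,
        "pdl1_tpm": pdl1,
        "pdl1_positive": pdl1_pos,
        "til_positive": til_pos,
        "subtype": subtype,
        "pdl1_loading_b": b,
        "response_prob": pd.Series(prob, index=samples),
    }
    return SyntheticCohort(
        tpm=tpm,
        counts=counts,
        clinical=clinical,
        maf=maf,
        fractions=fractions,
        response=response,
        truth=truth,
    )


def simulate_score_survival(
    n: int,
    seed: int,
    hazard_ratio_top_decile: float = 0.5,
    baseline_hazard: float = 0.02,
    censor_horizon: float = 140.0,
) -> tuple[pd.Series, pd.DataFrame]:
    """Light-weight score + survival simulation: the hazard changes only
    for the top decile of a continuous score.  Used for cutpoint-recovery
    experiments without generating expression."""
    rng = np.random.default_rng(seed)
    samples = [f"S{i:05d}" for i in range(n)]
    score = pd.Series(rng.standard_normal(n), index=samples, name="score")
    top = call_positivity(score, 10)
    hazard = baseline_hazard * np.where(top.values, hazard_ratio_top_decile, 1.0)
    t_event = rng.exponential(1.0 / hazard)
    t_censor = rng.uniform(0, censor_horizon, size=n)
    clinical = pd.DataFrame(
        {
            "sample_id": samples,
            "os_months": np.minimum(t_event, t_censor),
            "event": (t_event <= t_censor).astype(int),
            "age": 60.0,
            "sex": "unknown",
            "stage": "unknown",
        }
    )
    return score, clinical


def generate_toy_fixtures() -> dict:
    """Deterministic printed-size fixtures for unit tests.

    km4   : 4-sample survival worked case (times 1-4, all events, AABB).
    fisher10 : perfect 5/5 co-occurrence 2x2 table.
    eq123 : single pathway, single gene, DEG only in subtype I.
    """
    km4 = pd.DataFrame(
        {
            "sample_id": ["a", "b", "c", "d"],
            "os_months": [1.0, 2.0, 3.0, 4.0],
            "event": [1, 1, 1, 1],
            "age": [60] * 4,
            "sex": ["unknown"] * 4,
            "stage": ["unknown"] * 4,
        }
    )
    km4_groups = pd.Series(["A", "A", "B", "B"], index=km4["sample_id"])
    fisher10 = np.array([[5, 0], [0, 5]])
    de = {}
    for k in SUBTYPES:
        de[k] = pd.DataFrame(
            {
                "log2FC": [8.0 if k == "I" else 0.0],
                "p": [1e-6 if k == "I" else 1.0],
                "fdr": [1e-5 if k == "I" else 1.0],
                "deg": [k == "I"],
            },
            index=["G1"],
        )
    return {
        "km4": (km4, km4_groups),
        "fisher10": fisher10,
        "eq123": {"de_results": de, "pathways": {"P1": ["G1"]}},
    }
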