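"""Kaplan-Meier / log-rank / Cox proportional-hazards utilities and the
generic group-comparison tests used throughout the pipeline.

Thin, opinionated wrappers over lifelines and scipy: Efron handling of
tied event times (survival is recorded in months, so ties are common),
a univariate-screen-then-multivariate Cox workflow (covariates enter
the multivariate model only if univariately significant at p < 0.05),
and median dichotomisation for "high vs low" continuous covariates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

ALPHA = 0.05  # significance threshold used for the multivariate screen


@dataclass
class LogRankResult:
    statistic: float
    df: int
    p_value: float


def _align_clinical(groups: pd.Series, clinical: pd.DataFrame) -> pd.DataFrame:
    clin = clinical.set_index("sample_id") if "sample_id" in clinical.columns else clinical
    df = pd.DataFrame(
        {
            "group": groups,
            "os_months": clin["os_months"].reindex(groups.index),
            "event": clin["event"].reindex(groups.index),
        }
    )
    # samples without follow-up are excluded from survival analyses only
    return df.dropna(subset=["os_months", "event"])


def km_logrank(
    groups: pd.Series, clinical: pd.DataFrame
) -> tuple[dict[str, pd.DataFrame], LogRankResult]:
    """Product-limit estimate per group plus the k-group log-rank test.

    Returns a mapping group -> DataFrame(time, survival, at_risk) and a
    :class:`LogRankResult` with df = k - 1.
    """
    df = _align_clinical(groups, clinical)
    levels = [g for g in pd.unique(df["group"])]
    if len(levels) < 2:
        raise ValueError("log-rank test requires at least 2 non-empty groups")
    if df["event"].sum() < 1:
        raise ValueError("no observed events")
    curves: dict[str, pd.DataFrame] = {}
    for g in levels:
        sub = df[df["group"] == g]
        if len(sub) == 0:
            raise ValueError(f"group {g!r} has no samples")
        kmf = KaplanMeierFitter()
        kmf.fit(sub["os_months"], sub["event"])
        tbl = kmf.event_table
        curves[g] = pd.DataFrame(
            {
                "time": kmf.survival_function_.index,
                "survival": kmf.survival_function_["KM_estimate"].values,
                "at_risk": tbl["at_risk"].reindex(kmf.survival_function_.index).values,
            }
        ).reset_index(drop=True)
    res = multivariate_logrank_test(df["os_months"], df["group"], df["event"])
    return curves, LogRankResult(
        statistic=float(res.test_statistic),
        df=len(levels) - 1,
        p_value=float(res.p_value),
    )


def dichotomize_at_median(values: pd.Series) -> pd.Series:
    """1 where the value exceeds the cohort median, else 0 (high vs low)."""
    return (values > values.median()).astype(int)


def cox_fit(
    covariates: pd.DataFrame,
    clinical: pd.DataFrame,
    multivariate: bool = False,
    alpha_enter: float = ALPHA,
) -> pd.DataFrame:
    """Cox proportional-hazards fit, mirroring a forest-table workflow.

    Univariate mode fits each covariate alone.  Multivariate mode first
    runs the univariate screen and enters only covariates with
    univariate p < ``alpha_enter``.  Constant covariates are dropped
    with a warning; among perfectly collinear pairs the later column is
    dropped.  Returns a tidy table: covariate, HR, CI_low, CI_high, p,
    model.
    """
    clin = clinical.set_index("sample_id") if "sample_id" in clinical.columns else clinical
    data = covariates.copy()
    data["os_months"] = clin["os_months"].reindex(data.index)
    data["event"] = clin["event"].reindex(data.index)
    data = data.dropna(subset=["os_months", "event"])
    cov_cols = [c for c in covariates.columns]

    keep: list[str] = []
    for c in cov_cols:
        col = data[c].dropna()
        if col.nunique() <= 1:
            warnings.warn(f"covariate {c!r} is constant; dropped")
            continue
        dup = next(
            (k for k in keep if np.allclose(np.corrcoef(data[k], data[c])[0, 1], 1.0)),
            None,
        )
        if dup is not None:
            warnings.warn(f"covariate {c!r} is collinear with {dup!r}; dropped")
            continue
        keep.append(c)

    def _fit(cols: list[str]) -> pd.DataFrame:
        cph = CoxPHFitter()
        cph.fit(
            data[cols + ["os_months", "event"]],
            duration_col="os_months",
            event_col="event",
        )
        s = cph.summary
        return pd.DataFrame(
            {
                "covariate": s.index,
                "HR": s["exp(coef)"].values,
                "CI_low": s["exp(coef) lower 95%"].values,
                "CI_high": s["exp(coef) upper 95%"].values,
                "p": s["p"].values,
            }
        )

    uni = pd.concat([_fit([c]) for c in keep], ignore_index=True)
    uni["model"] = "uni"
    if not multivariate:
        return uni
    entered = [c for c in keep if float(uni.loc[uni["covariate"] == c, "p"].iloc[0]) < alpha_enter]
    if not entered:
        raise ValueError("no covariate passed the univariate screen")
    multi = _fit(entered)
    multi["model"] = "multi"
    return pd.concat([uni, multi], ignore_index=True)


@dataclass
class GroupTestResult:
    test: str
    statistic: float
    p_value: float
    effect: float | None = None


def compare_groups(values, group_flags=None, kind: str = "wilcoxon") -> GroupTestResult:
    """Dispatch the generic two-sample / k-sample / association tests.

    kind "wilcoxon": two-sided rank-sum for a continuous variable in two
    groups; "kruskal": k groups; "chi2"/"fisher": 2x2 counts, with an
    automatic Fisher fallback from chi2 when any expected cell < 5;
    "spearman": rank correlation of two continuous vectors (values and
    group_flags are then the two vectors).
    """
    if kind == "spearman":
        rho, p = stats.spearmanr(values, group_flags)
        return GroupTestResult("spearman", float(rho), float(p), effect=float(rho))
    if kind in ("chi2", "fisher"):
        table = np.asarray(values, dtype=float)
        if table.shape != (2, 2):
            raise ValueError("chi2/fisher expects a 2x2 contingency table")
        expected = stats.contingency.expected_freq(table)
        if kind == "fisher" or (expected < 5).any():
            odds, p = stats.fisher_exact(table, alternative="two-sided")
            return GroupTestResult("fisher", float(odds), float(p), effect=float(odds))
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        return GroupTestResult("chi2", float(chi2), float(p))
    vals = np.asarray(values, dtype=float)
    flags = np.asarray(group_flags)
    groups = [vals[flags == g] for g in pd.unique(flags)]
    if any(len(g) == 0 for g in groups):
        raise ValueError("empty group in comparison")
    if np.all(vals == vals[0]):
        warnings.warn("all values tied; rank test degenerate, returning p = 1")
        return GroupTestResult(kind, 0.0, 1.0)
    if kind == "wilcoxon":
        if len(groups) != 2:
            raise ValueError("wilcoxon requires exactly 2 groups")
        stat, p = stats.mannwhitneyu(groups[0], groups[1], alternative="two-sided")
        return GroupTestResult("wilcoxon", float(stat), float(p))
    if kind == "kruskal":
        stat, p = stats.kruskal(*groups)
        return GroupTestResult("kruskal", float(stat), float(p))
    raise ValueError(f"unknown test kind {kind!r}")
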