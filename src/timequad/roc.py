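"""ROC/AUC evaluation of checkpoint-blockade response predictors.

Candidate predictors (CD8A, CD8B, the TIL Z score, PD-L1, and a
combined PD-L1 + TIL model) are compared by the area under the ROC
curve for discriminating responders from non-responders.  The AUC is
computed by the Mann-Whitney rank estimator — the fraction of
(responder, non-responder) pairs ranked concordantly, ties counted
half — which equals the trapezoidal area under the empirical ROC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve

RIDGE_LAMBDA = 1e-4  # l2 penalty on standardized features


def auc(scores, labels) -> float:
    """Mann-Whitney AUC: P(score_pos > score_neg) + 0.5 P(tie)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires at least one sample of each class")
    ranks = rankdata(scores)  # midranks handle ties
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def roc_points(scores, labels) -> pd.DataFrame:
    """Stepwise ROC curve as (threshold, fpr, tpr) rows, (0,0) to (1,1)."""
    labels = np.asarray(labels).astype(int)
    fpr, tpr, thr = roc_curve(labels, np.asarray(scores, dtype=float))
    return pd.DataFrame({"threshold": thr, "fpr": fpr, "tpr": tpr})


@dataclass
class CombinedModel:
    """Standardised two-feature logistic model combining PD-L1 and TIL."""

    feature_names: list[str]
    intercept: float
    coef: np.ndarray
    means: np.ndarray
    scales: np.ndarray
    auc_in_sample: float

    def decision(self, features: pd.DataFrame) -> pd.Series:
        x = (features[self.feature_names].values - self.means) / self.scales
        return pd.Series(
            self.intercept + x @ self.coef, index=features.index, name="combined"
        )


def fit_combined(
    features: pd.DataFrame, labels: pd.Series, feature_names: list[str] | None = None
) -> CombinedModel:
    """Fit the bivariate ridge-logistic combination of PD-L1 and TIL.

    Features are z-standardised and fit by penalised maximum likelihood
    with a small ridge term (lambda = 1e-4) so perfect separation and
    collinearity stay finite; a warning is emitted when either is
    detected.  The combined score is the linear predictor.
    """
    if feature_names is None:
        feature_names = list(features.columns)
    x = features[feature_names].values.astype(float)
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("both response classes required to fit the combined model")
    means = x.mean(axis=0)
    scales = x.std(axis=0, ddof=0)
    if (scales == 0).any():
        bad = [feature_names[i] for i in np.flatnonzero(scales == 0)]
        raise ValueError(f"zero-variance feature(s): {bad}")
    xz = (x - means) / scales
    if np.linalg.matrix_rank(xz) < xz.shape[1]:
        warnings.warn("collinear features; ridge penalty keeps the fit defined")
    model = LogisticRegression(C=1.0 / RIDGE_LAMBDA, solver="lbfgs", max_iter=10_000)
    model.fit(xz, y)
    coef = model.coef_[0]
    linear = model.intercept_[0] + xz @ coef
    if auc(linear, y) == 1.0:
        warnings.warn("perfect separation; coefficients stabilised by the ridge penalty")
    return CombinedModel(
        feature_names=feature_names,
        intercept=float(model.intercept_[0]),
        coef=coef,
        means=means,
        scales=scales,
        auc_in_sample=auc(linear, y),
    )


def combine_ranksum(features: pd.DataFrame) -> pd.Series:
    """Rank-sum alternative: mean of the two features' percentile ranks."""
    ranks = features.rank(pct=True)
    out = ranks.mean(axis=1)
    out.name = "combined_ranksum"
    return out


def evaluate_predictors(
    cohort: pd.DataFrame,
    predictors: list[str],
    response_col: str = "response",
    combined: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """AUC per predictor column, optionally adding the combined model.

    ``response_col`` holds 1/0 (or "responder"/"non-responder") labels.
    """
    resp = cohort[response_col]
    if resp.dtype == object:
        resp = (resp == "responder").astype(int)
    rows = []
    for name in predictors:
        rows.append({"predictor": name, "auc": auc(cohort[name], resp)})
    if combined is not None:
        model = fit_combined(cohort[list(combined)], resp)
        rows.append({"predictor": "combined", "auc": model.auc_in_sample})
    return pd.DataFrame(rows)


def response_rate_by_subtype(
    subtypes: pd.Series, response: pd.Series
) -> pd.DataFrame:
    """Responders / total per TIME quadrant, with counts.

    Empty quadrants report an undefined (NaN) rate rather than 0.
    """
    resp = response.reindex(subtypes.index)
    if resp.isna().any():
        raise ValueError("every labeled sample needs a response value")
    if resp.dtype == object:
        resp = (resp == "responder").astype(int)
    rows = []
    for label in ["I", "II", "III", "IV"]:
        mask = subtypes == label
        total = int(mask.sum())
        responders = int(resp[mask].sum())
        rows.append(
            {
                "subtype": label,
                "responders": responders,
                "total": total,
                "rate": responders / total if total else np.nan,
            }
        )
    return pd.DataFrame(rows)
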