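"""Predictive layer: univariate feature ranking, exhaustive AICc subset
selection, penalized logistic fits, and paired ROC comparison by the DeLong
placement-value test.

Feature importances are -ln(p) of a univariate test (chi-square independence
on a discretized feature for classification, the slope F test of a simple
linear fit for regression), so ``exp(-score)`` recovers the p-value exactly.
Model selection fits every predictor subset on an identical complete-case set
and ranks by the small-sample corrected Akaike criterion
``AICc = AIC + 2k(k+1)/(n-k-1)``. AUCs are in-sample via the Mann-Whitney
identity ``AUC = U/(n1*n2)`` (ties counted half).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold


# ---------------------------------------------------------------------------
# ROC / AUC / DeLong
# ---------------------------------------------------------------------------


def auc_mann_whitney(scores, labels) -> float:
    """AUC via the rank (Mann-Whitney) identity, ties counted half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos, n_neg = labels.sum(), (~labels).sum()
    if n_pos == 0 or n_neg == 0:
        raise ValueError("labels must contain both classes")
    ranks = sps.rankdata(scores)
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


@dataclass
class ROCCurve:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    delong_variance: float


def _placement_values(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """DeLong structural components: V10 (per positive) and V01 (per negative)."""
    pos = scores[labels]
    neg = scores[~labels]
    # psi(x, y) = 1 if x > y, 1/2 if tie, 0 otherwise
    gt = (pos[:, None] > neg[None, :]).astype(float)
    eq = (pos[:, None] == neg[None, :]).astype(float)
    psi = gt + 0.5 * eq
    auc = float(psi.mean())
    v10 = psi.mean(axis=1)
    v01 = psi.mean(axis=0)
    return v10, v01, auc


def roc_curve_points(scores, labels) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Empirical ROC by threshold sweep over the unique scores."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    thresholds = np.concatenate([[np.inf], np.unique(scores)[::-1]])
    sens = np.array([(scores[labels] >= t).mean() for t in thresholds])
    spec = np.array([(scores[~labels] < t).mean() for t in thresholds])
    return thresholds, sens, spec


def roc_with_delong(
    scores_a, scores_b, labels
) -> tuple[ROCCurve, ROCCurve, float, float]:
    """Compare two correlated ROC curves built from paired scores.

    Returns (roc_a, roc_b, Z, p) where Z tests the AUC difference using the
    DeLong placement-value covariance and p is two-tailed. Identical score
    vectors give Z = 0, p = 1.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if len(scores_a) != len(scores_b) or len(scores_a) != len(labels):
        raise ValueError("scores and labels must be paired (equal length)")
    if labels.all() or not labels.any():
        raise ValueError("labels must contain both classes")

    v10a, v01a, auc_a = _placement_values(scores_a, labels)
    v10b, v01b, auc_b = _placement_values(scores_b, labels)
    m, n = len(v10a), len(v01a)
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
    var_a = s10[0, 0] / m + s01[0, 0] / n
    var_b = s10[1, 1] / m + s01[1, 1] / n
    var_diff = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    if var_diff <= 0:
        z, p = 0.0, 1.0
    else:
        z = (auc_a - auc_b) / math.sqrt(var_diff)
        p = float(2.0 * sps.norm.sf(abs(z)))

    def curve(scores, auc, var):
        t, se, sp = roc_curve_points(scores, labels)
        return ROCCurve(t, se, sp, auc, var)

    return curve(scores_a, auc_a, var_a), curve(scores_b, auc_b, var_b), float(z), p


# ---------------------------------------------------------------------------
# univariate feature ranking
# ---------------------------------------------------------------------------


@dataclass
class FeatureRank:
    feature: str
    score: float  # -ln p
    p: float
    rank: int


def _chi2_pvalue_binned(x: np.ndarray, y: np.ndarray, n_bins: int = 10) -> float:
    """Chi-square independence p-value of a decile-binned feature vs the label.

    Bins are deciles of the pooled feature (duplicate edges merged); adjacent
    bins are merged until every expected cell count is at least one.
    """
    edges = np.unique(np.quantile(x, np.linspace(0, 1, n_bins + 1)))
    if len(edges) < 3:  # (near-)constant feature
        return 1.0
    bins = np.clip(np.searchsorted(edges[1:-1], x, side="right"), 0, len(edges) - 2)
    table = pd.crosstab(bins, y).to_numpy(dtype=float)
    while table.shape[0] > 2:
        expected = sps.contingency.expected_freq(table)
        if expected.min() >= 1.0:
            break
        i = int(np.argmin(table.sum(axis=1)))
        j = i + 1 if i == 0 else i - 1
        table[j] += table[i]
        table = np.delete(table, i, axis=0)
    stat, p, _, _ = sps.chi2_contingency(table, correction=False)
    return float(p)


def rank_features_classification(features: pd.DataFrame, labels) -> list[FeatureRank]:
    """Rank features for a binary classification target by chi-square tests on
    the discretized feature; importance = -ln p, so exp(-score) inverts it."""
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) != 2:
        raise ValueError("labels must be binary")
    if min(np.bincount(y)) < 10:
        raise ValueError("need at least 10 observations per class")
    ranks = []
    for name in features.columns:
        x = features[name].to_numpy(dtype=float)
        if np.ptp(x[~np.isnan(x)]) == 0:
            warnings.warn(f"feature '{name}' is constant; importance set to 0")
            ranks.append(FeatureRank(name, 0.0, 1.0, -1))
            continue
        ok = ~np.isnan(x)
        p = _chi2_pvalue_binned(x[ok], y[ok])
        ranks.append(FeatureRank(name, -math.log(max(p, 1e-300)), p, -1))
    ranks.sort(key=lambda r: r.score, reverse=True)
    for i, r in enumerate(ranks):
        r.rank = i + 1
    return ranks


def rank_features_regression(features: pd.DataFrame, target) -> list[FeatureRank]:
    """Rank features for a continuous target by the F test of the slope of a
    simple linear fit (F = t^2 of the slope); importance = -ln p."""
    y = np.asarray(target, dtype=float)
    ranks = []
    for name in features.columns:
        x = features[name].to_numpy(dtype=float)
        ok = ~(np.isnan(x) | np.isnan(y))
        if np.ptp(x[ok]) == 0:
            warnings.warn(f"feature '{name}' is constant; importance set to 0")
            ranks.append(FeatureRank(name, 0.0, 1.0, -1))
            continue
        res = sps.linregress(x[ok], y[ok])
        p = float(res.pvalue)
        ranks.append(FeatureRank(name, -math.log(max(p, 1e-300)), p, -1))
    ranks.sort(key=lambda r: r.score, reverse=True)
    for i, r in enumerate(ranks):
        r.rank = i + 1
    return ranks


# ---------------------------------------------------------------------------
# model fitting and exhaustive selection
# ---------------------------------------------------------------------------


def adjusted_r2(r2: float, n: int, k: int) -> float:
    """1 - (1 - R^2)(n - 1)/(n - k - 1); intercept-only (k = 0, R^2 = 0) gives 0."""
    if n - k - 1 <= 0:
        raise ValueError("n must exceed k + 1")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1)


def _aicc(loglik: float, k: int, n: int) -> float:
    aic = 2 * k - 2 * loglik
    return aic + 2 * k * (k + 1) / (n - k - 1)


@dataclass
class PenalizedLogisticFit:
    coefficients: np.ndarray
    intercept: float
    scores: np.ndarray  # in-sample linear predictor
    C: float
    loglik: float


def fit_penalized_logistic(
    features: pd.DataFrame,
    labels,
    C: Optional[float] = None,
    cv: int = 5,
    seed: int = 0,
) -> PenalizedLogisticFit:
    """L1-penalized logistic regression; the penalty keeps coefficients finite
    on separable data, where the unpenalized likelihood diverges.

    Penalty strength is chosen by stratified cross-validation unless ``C`` is
    given. Returns the in-sample linear predictor for ROC construction.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels).astype(int)
    if C is None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)
            warnings.simplefilter("ignore", UserWarning)
            model = LogisticRegressionCV(
                Cs=np.logspace(-2, 4, 10),
                penalty="l1",
                solver="liblinear",
                cv=StratifiedKFold(cv, shuffle=True, random_state=seed),
                scoring="neg_log_loss",
                max_iter=5000,
            ).fit(X, y)
            chosen_c = float(model.C_[0])
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)
            warnings.simplefilter("ignore", UserWarning)
            model = LogisticRegression(
                C=C, penalty="l1", solver="liblinear", max_iter=5000, tol=1e-10
            ).fit(X, y)
        chosen_c = float(C)
    scores = model.decision_function(X)
    prob = np.clip(model.predict_proba(X)[:, 1], 1e-12, 1 - 1e-12)
    ll = float(np.sum(y * np.log(prob) + (1 - y) * np.log(1 - prob)))
    return PenalizedLogisticFit(
        coefficients=model.coef_.ravel(),
        intercept=float(model.intercept_[0]),
        scores=scores,
        C=chosen_c,
        loglik=ll,
    )


@dataclass
class ModelComparison:
    table: pd.DataFrame  # one row per candidate subset, sorted by AICc
    winner: tuple[str, ...]
    family: str
    skipped: list[tuple[tuple[str, ...], str]] = field(default_factory=list)


def _fit_logistic_subset(X: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray, bool]:
    """Log-likelihood and in-sample scores for one subset; falls back to a
    fixed-strength L1 fit (flagged) under (quasi-)separation."""
    design = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, design).fit(disp=0, maxiter=200)
            if np.all(np.isfinite(fit.params)) and np.abs(fit.params).max() < 50:
                return float(fit.llf), np.asarray(design @ fit.params), False
        except Exception:
            pass
    pen = fit_penalized_logistic(pd.DataFrame(X), y, C=1.0)
    return pen.loglik, pen.scores, True


def exhaustive_model_selection(
    candidates: pd.DataFrame,
    response,
    family: Literal["logistic", "linear"] = "logistic",
    max_candidates: int = 12,
) -> ModelComparison:
    """Fit every predictor subset (including intercept-only) on the identical
    complete-case set and rank by AICc.

    Logistic models report in-sample AUC, linear models adjusted R^2. Subsets
    with too few cases for their parameter count are skipped with a log entry;
    separable logistic subsets fall back to a penalized fit and are flagged.
    """
    names = list(candidates.columns)
    if len(names) > max_candidates:
        raise ValueError(f"at most {max_candidates} candidate predictors supported")
    y = np.asarray(response, dtype=float)
    X_all = candidates.to_numpy(dtype=float)
    ok = ~(np.isnan(X_all).any(axis=1) | np.isnan(y))
    X_all, y = X_all[ok], y[ok]
    n = len(y)
    if family == "logistic":
        y = y.astype(int)

    rows = []
    skipped: list[tuple[tuple[str, ...], str]] = []
    for r in range(len(names) + 1):
        for subset in itertools.combinations(range(len(names)), r):
            sub_names = tuple(names[i] for i in subset)
            k = len(subset) + 1 + (1 if family == "linear" else 0)  # + sigma for linear
            if n - k - 1 <= 1:
                skipped.append((sub_names, f"n={n} too small for k={k}"))
                continue
            X = X_all[:, list(subset)]
            if family == "logistic":
                ll, scores, penalized = _fit_logistic_subset(X, y)
                perf = auc_mann_whitney(scores, y) if r > 0 else 0.5
                rows.append(
                    {
                        "predictors": " + ".join(sub_names) if sub_names else "(intercept)",
                        "k": k,
                        "loglik": ll,
                        "aicc": _aicc(ll, k, n),
                        "auc": perf,
                        "penalized": penalized,
                        "_subset": sub_names,
                    }
                )
            else:
                design = sm.add_constant(X, has_constant="add")
                fit = sm.OLS(y, design).fit()
                rows.append(
                    {
                        "predictors": " + ".join(sub_names) if sub_names else "(intercept)",
                        "k": k,
                        "loglik": float(fit.llf),
                        "aicc": _aicc(float(fit.llf), k, n),
                        "adj_r2": adjusted_r2(float(fit.rsquared), n, len(subset)),
                        "penalized": False,
                        "_subset": sub_names,
                    }
                )
    table = pd.DataFrame(rows).sort_values("aicc", kind="stable").reset_index(drop=True)
    winner = tuple(table.loc[0, "_subset"])
    table = table.drop(columns="_subset")
    return ModelComparison(table=table, winner=winner, family=family, skipped=skipped)
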