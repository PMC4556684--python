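"""Cohort-level statistics: group comparisons, discrimination, survival.

Implements the statistics layer of the stroke-risk analysis: CHA2DS2-VASc
scoring from its clinical components, two-group comparisons (Student's t,
chi-square / Fisher), Spearman correlation matrices, multiple regression of
an entropy feature on clinical covariates, C-statistics with DeLong
confidence intervals and paired comparison, Cox proportional-hazards fits
reported as hazard ratio per 1-SD increment, Nelson–Aalen cumulative-hazard
curves with log-rank tests, and stratified k-fold cross-validated
sensitivity/specificity with a Youden-index threshold chosen on the training
folds only.

All tests are two-sided with alpha = 0.05.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from lifelines import CoxPHFitter, NelsonAalenFitter
from lifelines.statistics import multivariate_logrank_test
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "cha2ds2_vasc",
    "compare_groups",
    "correlation_matrix",
    "covariate_regression",
    "c_statistic",
    "compare_c",
    "cox_fit",
    "cumulative_incidence",
    "cross_validate",
    "GroupComparison",
    "CStatResult",
    "CoxResult",
    "CumulativeIncidence",
    "CrossValidationResult",
]

ALPHA = 0.05


# ---------------------------------------------------------------------------
# CHA2DS2-VASc

def cha2ds2_vasc(
    *,
    age: float,
    female: bool,
    chf: bool,
    hypertension: bool,
    diabetes: bool,
    stroke_tia: bool,
    vascular: bool,
) -> int:
    """CHA2DS2-VASc stroke-risk score (0–9) from its clinical components.

    One point each for congestive heart failure, hypertension, diabetes,
    vascular disease, age 65–74 and female sex; two points each for age >= 75
    and prior stroke/TIA.
    """
    comps = dict(age=age, female=female, chf=chf, hypertension=hypertension,
                 diabetes=diabetes, stroke_tia=stroke_tia, vascular=vascular)
    for name, v in comps.items():
        if v is None or (isinstance(v, float) and math.isnan(v)):
            raise ValueError(f"missing CHA2DS2-VASc component: {name}")
    score = int(chf) + int(hypertension) + int(diabetes) + int(vascular) + int(female)
    score += 2 * int(stroke_tia)
    if age >= 75:
        score += 2
    elif age >= 65:
        score += 1
    return score


# ---------------------------------------------------------------------------
# group comparison

@dataclass
class GroupComparison:
    feature: str
    kind: str  # "continuous" or "categorical"
    group_names: tuple
    means: tuple | None
    sds: tuple | None
    counts: tuple
    p_value: float
    test: str


def compare_groups(
    cohort: pd.DataFrame,
    feature: str,
    group_col: str = "event",
    kind: str | None = None,
) -> GroupComparison:
    """Two-group comparison of one feature between outcome groups.

    Continuous features use Student's t-test (equal variances, the classical
    form); categorical features use the chi-square test, or Fisher's exact
    test when any expected cell count is below 5 (2x2 tables).
    """
    sub = cohort[[feature, group_col]].dropna()
    levels = sorted(sub[group_col].unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups, found {len(levels)}")
    g0 = sub.loc[sub[group_col] == levels[0], feature]
    g1 = sub.loc[sub[group_col] == levels[1], feature]
    if len(g0) == 0 or len(g1) == 0:
        raise ValueError("empty group")
    if kind is None:
        vals = sub[feature].dropna().unique()
        kind = "categorical" if len(vals) <= 2 else "continuous"

    if kind == "continuous":
        t, p = stats.ttest_ind(g0, g1, equal_var=True)
        return GroupComparison(
            feature, kind, tuple(levels),
            (float(g0.mean()), float(g1.mean())),
            (float(g0.std(ddof=1)), float(g1.std(ddof=1))),
            (len(g0), len(g1)), float(p), "student_t",
        )
    table = pd.crosstab(sub[group_col], sub[feature]).to_numpy()
    expected = stats.contingency.expected_freq(table)
    if table.shape == (2, 2) and (expected < 5).any():
        _, p = stats.fisher_exact(table)
        test = "fisher_exact"
    else:
        _, p, _, _ = stats.chi2_contingency(table)
        test = "chi2"
    return GroupComparison(feature, kind, tuple(levels), None, None,
                           (len(g0), len(g1)), float(p), test)


# ---------------------------------------------------------------------------
# Spearman correlation matrix

def correlation_matrix(
    cohort: pd.DataFrame, features: list[str]
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pairwise Spearman rank correlations with p-values and stars.

    Returns ``(rho, p, stars)`` DataFrames; stars mark p < 0.05 / 0.01 /
    0.001 with '*', '**', '***'.  Constant features yield NaN (flagged by the
    empty star cell).
    """
    if len(cohort) < 3:
        raise ValueError("need at least 3 records")
    k = len(features)
    rho = np.full((k, k), np.nan)
    pval = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(k):
            xi = cohort[features[i]]
            xj = cohort[features[j]]
            ok = xi.notna() & xj.notna()
            if xi[ok].nunique() < 2 or xj[ok].nunique() < 2:
                continue  # constant feature: undefined, left NaN
            r, p = stats.spearmanr(xi[ok], xj[ok])
            rho[i, j], pval[i, j] = r, p
    stars = np.where(pval < 0.001, "***",
                     np.where(pval < 0.01, "**", np.where(pval < 0.05, "*", "")))
    stars = np.where(np.isnan(pval), "", stars)
    return (pd.DataFrame(rho, index=features, columns=features),
            pd.DataFrame(pval, index=features, columns=features),
            pd.DataFrame(stars, index=features, columns=features))


# ---------------------------------------------------------------------------
# multiple regression

def covariate_regression(
    cohort: pd.DataFrame, target: str, covariates: list[str]
):
    """OLS of ``target`` on clinical covariates; statsmodels results object.

    Raises on a rank-deficient design, naming the collinear columns.
    """
    import statsmodels.api as sm

    sub = cohort[[target] + covariates].dropna()
    X = sm.add_constant(sub[covariates].astype(float))
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # identify columns not contributing rank, scanning left to right
        bad, cols = [], []
        for c in X.columns:
            trial = cols + [c]
            if np.linalg.matrix_rank(X[trial].to_numpy()) == len(cols):
                bad.append(c)
            else:
                cols = trial
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    return sm.OLS(sub[target].astype(float), X).fit()


# ---------------------------------------------------------------------------
# C-statistic (DeLong)

@dataclass
class CStatResult:
    auc: float
    ci_low: float
    ci_high: float
    se: float
    n_pos: int
    n_neg: int


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_cov(scores: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong AUC estimates and covariance for one or more scores.

    ``scores`` has shape (k, n); returns (aucs shape (k,), cov shape (k, k)).
    Structural components follow the fast midrank formulation.
    """
    y = np.asarray(y).astype(int)
    pos = scores[:, y == 1]
    neg = scores[:, y == 0]
    m, n = pos.shape[1], neg.shape[1]
    if m == 0 or n == 0:
        raise ValueError("both outcome classes must be present")
    k = scores.shape[0]
    v01 = np.empty((k, m))
    v10 = np.empty((k, n))
    aucs = np.empty(k)
    for r in range(k):
        all_r = np.concatenate([pos[r], neg[r]])
        tx = _midrank(pos[r])
        ty = _midrank(neg[r])
        tz = _midrank(all_r)
        auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
        aucs[r] = auc
        v01[r] = (tz[:m] - tx) / n
        v10[r] = 1.0 - (tz[m:] - ty) / m
    s01 = np.cov(v01) if k > 1 else np.atleast_2d(np.var(v01, ddof=1))
    s10 = np.cov(v10) if k > 1 else np.atleast_2d(np.var(v10, ddof=1))
    cov = s01 / m + s10 / n
    return aucs, np.atleast_2d(cov)


def c_statistic(
    cohort: pd.DataFrame, score: str, outcome: str = "event"
) -> CStatResult:
    """AUC of a score for event-ever-during-follow-up, with DeLong 95% CI."""
    sub = cohort[[score, outcome]].dropna()
    y = sub[outcome].to_numpy(dtype=int)
    s = sub[score].to_numpy(dtype=float)[None, :]
    aucs, cov = _delong_cov(s, y)
    se = math.sqrt(max(cov[0, 0], 0.0))
    zcrit = stats.norm.ppf(1 - ALPHA / 2)
    return CStatResult(
        auc=float(aucs[0]),
        ci_low=max(0.0, float(aucs[0] - zcrit * se)),
        ci_high=min(1.0, float(aucs[0] + zcrit * se)),
        se=se, n_pos=int(y.sum()), n_neg=int(len(y) - y.sum()),
    )


def compare_c(
    cohort: pd.DataFrame, score1: str, score2: str, outcome: str = "event"
) -> float:
    """Two-sided DeLong p-value for the paired AUC difference of two scores."""
    sub = cohort[[score1, score2, outcome]].dropna()
    y = sub[outcome].to_numpy(dtype=int)
    s = sub[[score1, score2]].to_numpy(dtype=float).T
    aucs, cov = _delong_cov(s, y)
    var = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if var <= 0:
        return 1.0
    z = (aucs[0] - aucs[1]) / math.sqrt(var)
    return float(2 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# Cox models

@dataclass
class CoxResult:
    feature: str
    hr_per_sd: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int
    n_events: int
    adjusters: list[str] = field(default_factory=list)


def cox_fit(
    cohort: pd.DataFrame,
    feature: str,
    adjusters: list[str] | None = None,
    duration_col: str = "follow_up_months",
    event_col: str = "event",
) -> CoxResult:
    """Cox proportional-hazards fit; hazard ratio per 1-SD increment.

    The feature is standardized to zero mean and unit SD *within the
    analyzed subset*, so the reported HR is per 1-SD of that subset and is
    invariant to any positive rescaling of the raw feature.
    """
    adjusters = list(adjusters or [])
    cols = [feature, duration_col, event_col] + adjusters
    sub = cohort[cols].dropna().copy()
    if sub[event_col].sum() < 2:
        raise ValueError("need at least 2 events for a Cox fit")
    sd = sub[feature].std(ddof=1)
    if not sd > 0:
        raise ValueError(f"feature {feature!r} has zero variance in the subset")
    sub["_z"] = (sub[feature] - sub[feature].mean()) / sd

    cph = CoxPHFitter()
    cph.fit(sub[["_z", duration_col, event_col] + adjusters],
            duration_col=duration_col, event_col=event_col)
    coef = float(cph.params_["_z"])
    se = float(cph.standard_errors_["_z"])
    zcrit = stats.norm.ppf(1 - ALPHA / 2)
    return CoxResult(
        feature=feature,
        hr_per_sd=math.exp(coef),
        ci_low=math.exp(coef - zcrit * se),
        ci_high=math.exp(coef + zcrit * se),
        p_value=float(cph.summary.loc["_z", "p"]),
        n=len(sub),
        n_events=int(sub[event_col].sum()),
        adjusters=adjusters,
    )


# ---------------------------------------------------------------------------
# Nelson–Aalen cumulative incidence

@dataclass
class CumulativeIncidence:
    curves: dict  # group -> DataFrame(timeline, cumulative_hazard)
    logrank_p: float
    group_sizes: dict


def cumulative_incidence(
    cohort: pd.DataFrame,
    group_by: str | pd.Series | None = None,
    feature: str = "mean_en_vlf2",
    duration_col: str = "follow_up_months",
    event_col: str = "event",
) -> CumulativeIncidence:
    """Nelson–Aalen cumulative-hazard curves per group with a log-rank test.

    By default patients are dichotomized at the cohort mean of
    ``feature`` (groups "high" / "low"); pass ``group_by`` as a column name
    or a Series for any other grouping.
    """
    if group_by is None:
        thr = cohort[feature].mean()
        groups = pd.Series(np.where(cohort[feature] > thr, "high", "low"),
                           index=cohort.index)
    elif isinstance(group_by, str):
        groups = cohort[group_by]
    else:
        groups = group_by

    curves, sizes = {}, {}
    for g in sorted(pd.unique(groups)):
        sel = groups == g
        if sel.sum() == 0:
            raise ValueError(f"group {g!r} has no subjects")
        naf = NelsonAalenFitter()
        naf.fit(cohort.loc[sel, duration_col], cohort.loc[sel, event_col],
                label=str(g))
        curves[g] = naf.cumulative_hazard_
        sizes[g] = int(sel.sum())
    res = multivariate_logrank_test(cohort[duration_col], groups, cohort[event_col])
    return CumulativeIncidence(curves=curves, logrank_p=float(res.p_value),
                               group_sizes=sizes)


# ---------------------------------------------------------------------------
# cross-validated sensitivity/specificity

@dataclass
class CrossValidationResult:
    sensitivity: float
    specificity: float
    thresholds: list[float]
    k: int


def _youden_threshold(scores: np.ndarray, y: np.ndarray) -> float:
    """Threshold maximizing sensitivity + specificity - 1 on (scores, y)."""
    from sklearn.metrics import roc_curve

    fpr, tpr, thr = roc_curve(y, scores)
    j = tpr - fpr
    best = int(np.argmax(j))
    t = thr[best]
    if np.isinf(t):  # sklearn's sentinel above the max score
        t = scores.max() + 1.0
    return float(t)


def cross_validate(
    cohort: pd.DataFrame,
    score: str,
    outcome: str = "event",
    k: int = 4,
    threshold_rule: str = "youden",
    seed: int = 0,
) -> CrossValidationResult:
    """Stratified k-fold cross-validated sensitivity and specificity.

    In each fold the classification threshold is chosen on the training data
    only (Youden index on the training ROC) and applied to the held-out fold
    (score >= threshold predicts an event); predictions are pooled across
    folds before computing sensitivity and specificity.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if threshold_rule != "youden":
        raise ValueError("only the 'youden' threshold rule is implemented")
    sub = cohort[[score, outcome]].dropna()
    y = sub[outcome].to_numpy(dtype=int)
    s = sub[score].to_numpy(dtype=float)
    if y.sum() < k or (1 - y).sum() < k:
        raise ValueError("too few subjects in a class for stratified folds")

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    tp = fp = tn = fn = 0
    thresholds = []
    for train, test in skf.split(s.reshape(-1, 1), y):
        t = _youden_threshold(s[train], y[train])
        thresholds.append(t)
        pred = s[test] >= t
        truth = y[test] == 1
        tp += int(np.sum(pred & truth))
        fn += int(np.sum(~pred & truth))
        fp += int(np.sum(pred & ~truth))
        tn += int(np.sum(~pred & ~truth))
    return CrossValidationResult(
        sensitivity=tp / (tp + fn) if tp + fn else float("nan"),
        specificity=tn / (tn + fp) if tn + fp else float("nan"),
        thresholds=thresholds, k=k,
    )
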