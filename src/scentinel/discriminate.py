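"""Prognostic classification of smell group from subtest features.

Pipeline: one-hot feature encoding, two-class linear discriminant analysis
(closed form via the pooled within-class covariance), ROC/AUC with the
concordance (Mann-Whitney) construction, DeLong's variance and paired test
for correlated AUCs, repeated stratified cross-validation with a stratified
holdout, and greedy backward feature selection.

The second identification attempt is excluded from classification features:
it is structurally missing whenever the first attempt succeeded, and
imputation under that missingness pattern is not defensible.

All routines are deterministic given a seed and use only numpy/scipy;
scikit-learn serves as an independent cross-check in the test suite, never
as the implementation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

SUBTEST_FEATURES = ["detection", "intensity", "id_first"]
DEMOGRAPHIC_FEATURES = ["age", "sex_female", "sex_male", "eth_white", "eth_nonwhite"]


@dataclass(frozen=True)
class FeatureMatrix:
    """Design matrix for a pairwise group contrast."""

    X: pd.DataFrame
    y: np.ndarray  # 1 = positive class
    positive_label: str
    negative_label: str

    @property
    def feature_names(self) -> list[str]:
        return list(self.X.columns)


def one_hot(
    cohort: pd.DataFrame,
    contrast: tuple[str, str],
    include_demographics: bool = True,
) -> FeatureMatrix:
    """Encode a cohort into numeric features for a two-group contrast.

    ``contrast`` is (negative, positive) group labels.  Subtest features are
    the detection and first-identification indicators and the raw 0-100
    intensity; demographics add age and one-hot sex/ethnicity indicators.
    Column order is fixed and documented in ``SUBTEST_FEATURES`` /
    ``DEMOGRAPHIC_FEATURES``.
    """
    neg, pos = contrast
    known = {"anosmic", "other", "normosmic"}
    if neg not in known or pos not in known:
        raise ValueError(f"unknown group in contrast {contrast}")
    sub = cohort[cohort["group"].isin([neg, pos])].reset_index(drop=True)
    bad_sex = set(sub["sex"].unique()) - {"F", "M", "unreported"}
    if bad_sex:
        raise ValueError(f"unknown sex categories {bad_sex}")
    X = pd.DataFrame(
        {
            "detection": sub["detect_correct"].astype(float),
            "intensity": sub["intensity"].astype(float),
            "id_first": sub["id1_correct"].astype(float),
        }
    )
    if include_demographics:
        X["age"] = sub["age"].astype(float)
        X["sex_female"] = (sub["sex"] == "F").astype(float)
        X["sex_male"] = (sub["sex"] == "M").astype(float)
        X["eth_white"] = sub["ethnicity_white"].astype(float)
        X["eth_nonwhite"] = 1.0 - X["eth_white"]
    y = (sub["group"] == pos).to_numpy(dtype=int)
    return FeatureMatrix(X=X, y=y, positive_label=pos, negative_label=neg)


@dataclass(frozen=True)
class LdaModel:
    """Closed-form two-class linear discriminant.

    ``score(x) = x @ weights + intercept`` is the log-posterior-odds of the
    positive class under shared-covariance Gaussians with empirical priors.
    """

    weights: np.ndarray
    intercept: float
    priors: tuple[float, float]  # (negative, positive)
    ridge_applied: bool = False

    def decision_scores(self, X: np.ndarray | pd.DataFrame) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.weights + self.intercept


def fit_lda(
    X: np.ndarray | pd.DataFrame,
    y: Sequence[int],
    ridge_fallback: bool = True,
) -> LdaModel:
    """Fit two-class LDA: weights proportional to S_pooled^-1 (mu1 - mu0).

    The pooled covariance is the Gaussian maximum-likelihood estimate
    (within-class scatter divided by n), the plug-in convention under which
    the score is the exact log-posterior-odds of the fitted model.

    A singular pooled covariance triggers a ridge fallback
    (lambda = 1e-6 * trace(S)/d added to the diagonal) when enabled.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    classes = np.unique(y)
    if set(classes) != {0, 1}:
        raise ValueError("labels must contain both classes {0, 1}")
    X0, X1 = X[y == 0], X[y == 1]
    if min(len(X0), len(X1)) < 2:
        raise ValueError("need >= 2 respondents per class")
    n0, n1 = len(X0), len(X1)
    mu0, mu1 = X0.mean(axis=0), X1.mean(axis=0)
    S = ((n0 - 1) * np.cov(X0, rowvar=False, ddof=1)
         + (n1 - 1) * np.cov(X1, rowvar=False, ddof=1)) / (n0 + n1)
    S = np.atleast_2d(S)
    ridge = False
    try:
        w = np.linalg.solve(S, mu1 - mu0)
    except np.linalg.LinAlgError:
        if not ridge_fallback:
            raise
        lam = 1e-6 * np.trace(S) / S.shape[0]
        if lam <= 0:
            lam = 1e-6
        w = np.linalg.solve(S + lam * np.eye(S.shape[0]), mu1 - mu0)
        ridge = True
    pi0, pi1 = n0 / (n0 + n1), n1 / (n0 + n1)
    intercept = float(-0.5 * (mu0 + mu1) @ w + np.log(pi1 / pi0))
    return LdaModel(
        weights=w, intercept=intercept, priors=(pi0, pi1), ridge_applied=ridge
    )


@dataclass(frozen=True)
class RocCurve:
    """ROC curve with AUC, DeLong variance, and the scores that built it."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    auc_variance: float
    scores: np.ndarray = field(repr=False, default=None)
    labels: np.ndarray = field(repr=False, default=None)


def _placement_values(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong placement values: per-positive and per-negative concordance."""
    pos, neg = scores[labels == 1], scores[labels == 0]
    # midranks via average ranking of the pooled sample
    diff = pos[:, None] - neg[None, :]
    wins = (diff > 0).astype(float) + 0.5 * (diff == 0)
    return wins.mean(axis=1), 1.0 - wins.mean(axis=0)


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> RocCurve:
    """ROC curve over all thresholds; AUC by trapezoid = tied-pair concordance.

    Tied scores are grouped into single curve steps.  The variance attached
    to the AUC is DeLong's placement-value estimate.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if set(np.unique(labels)) != {0, 1}:
        raise ValueError("labels must contain both classes")
    order = np.argsort(-scores, kind="stable")
    s, l = scores[order], labels[order]
    # collapse ties: cumulative counts at the last index of each distinct score
    distinct = np.r_[np.diff(s) != 0, True]
    tps = np.cumsum(l)[distinct]
    fps = np.cumsum(1 - l)[distinct]
    P, N = l.sum(), (1 - l).sum()
    tpr = np.r_[0.0, tps / P]
    fpr = np.r_[0.0, fps / N]
    thresholds = np.r_[np.inf, s[distinct]]
    auc = float(np.trapezoid(tpr, fpr))
    v10, v01 = _placement_values(scores, labels)
    m, n = len(v10), len(v01)
    var = 0.0
    if m > 1:
        var += np.var(v10, ddof=1) / m
    if n > 1:
        var += np.var(v01, ddof=1) / n
    return RocCurve(
        fpr=fpr, tpr=tpr, thresholds=thresholds, auc=auc,
        auc_variance=float(var), scores=scores, labels=labels,
    )


def delong_compare(curve_a: RocCurve, curve_b: RocCurve) -> tuple[float, float]:
    """DeLong's paired test for two correlated ROC curves.

    Both curves must be built on the same respondents (identical labels, in
    the same order).  Returns (z statistic, two-sided p-value).
    """
    if curve_a.labels is None or curve_b.labels is None:
        raise ValueError("curves must retain scores and labels")
    if len(curve_a.labels) != len(curve_b.labels) or not np.array_equal(
        curve_a.labels, curve_b.labels
    ):
        raise ValueError("curves are not paired on the same respondents")
    va10, va01 = _placement_values(curve_a.scores, curve_a.labels)
    vb10, vb01 = _placement_values(curve_b.scores, curve_b.labels)
    m, n = len(va10), len(va01)
    var = 0.0
    if m > 1:
        cov10 = np.cov(np.vstack([va10, vb10]), ddof=1)
        var += (cov10[0, 0] + cov10[1, 1] - 2 * cov10[0, 1]) / m
    if n > 1:
        cov01 = np.cov(np.vstack([va01, vb01]), ddof=1)
        var += (cov01[0, 0] + cov01[1, 1] - 2 * cov01[0, 1]) / n
    diff = curve_a.auc - curve_b.auc
    if var <= 0:
        return (0.0, 1.0) if diff == 0 else (np.inf * np.sign(diff), 0.0)
    z = diff / np.sqrt(var)
    p = 2 * stats.norm.sf(abs(z))
    return float(z), float(p)


def _stratified_assignments(
    y: np.ndarray, k: int, rng: np.random.Generator
) -> np.ndarray:
    """Fold index per row, class-stratified with a seeded shuffle."""
    folds = np.empty(len(y), dtype=int)
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        folds[idx] = np.arange(len(idx)) % k
    return folds


def stratified_holdout_split(
    y: np.ndarray, holdout: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Indices (train, holdout) with per-class proportional allocation."""
    train, test = [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        n_hold = max(1, int(round(holdout * len(idx))))
        test.append(idx[:n_hold])
        train.append(idx[n_hold:])
    return np.sort(np.concatenate(train)), np.sort(np.concatenate(test))


@dataclass(frozen=True)
class ClassifierReport:
    auc: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    threshold: float
    cv_auc_mean: float
    cv_auc_sd: float
    cv_scheme: str
    holdout_fraction: float
    n_train: int
    n_holdout: int
    degenerate_margin: bool = False  # PPV/NPV margin was zero


def confusion_metrics(
    scores: np.ndarray, labels: np.ndarray, threshold: float
) -> dict:
    pred = scores >= threshold
    labels = labels.astype(bool)
    tp = int((pred & labels).sum())
    fp = int((pred & ~labels).sum())
    fn = int((~pred & labels).sum())
    tn = int((~pred & ~labels).sum())
    degenerate = (tp + fp == 0) or (tn + fn == 0)
    return {
        "sensitivity": tp / (tp + fn) if tp + fn else np.nan,
        "specificity": tn / (tn + fp) if tn + fp else np.nan,
        "ppv": tp / (tp + fp) if tp + fp else np.nan,
        "npv": tn / (tn + fn) if tn + fn else np.nan,
        "degenerate_margin": degenerate,
    }


def _cv_aucs(
    X: np.ndarray,
    y: np.ndarray,
    folds: int,
    repeats: int,
    rng: np.random.Generator,
) -> tuple[list[float], np.ndarray, np.ndarray]:
    """Per-fold out-of-fold AUCs plus pooled out-of-fold scores/labels."""
    aucs: list[float] = []
    oof_scores, oof_labels = [], []
    for _ in range(repeats):
        assign = _stratified_assignments(y, folds, rng)
        for fold in range(folds):
            test_mask = assign == fold
            if len(np.unique(y[test_mask])) < 2 or len(np.unique(y[~test_mask])) < 2:
                raise RuntimeError(
                    "a CV fold lost a class; use fewer folds or more data"
                )
            model = fit_lda(X[~test_mask], y[~test_mask])
            s = model.decision_scores(X[test_mask])
            aucs.append(roc_auc(s, y[test_mask]).auc)
            oof_scores.append(s)
            oof_labels.append(y[test_mask])
    return aucs, np.concatenate(oof_scores), np.concatenate(oof_labels)


def youden_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    """Threshold maximizing sensitivity + specificity - 1."""
    curve = roc_auc(scores, labels)
    j = curve.tpr - curve.fpr
    best = int(np.argmax(j))
    t = curve.thresholds[best]
    return float(t) if np.isfinite(t) else float(np.max(scores) + 1)


def cv_evaluate(
    features: FeatureMatrix,
    folds: int = 10,
    repeats: int = 5,
    holdout: float = 0.2,
    seed: int = 0,
) -> ClassifierReport:
    """Stratified 80/20 evaluation with repeated stratified k-fold CV.

    The holdout fraction is split off first and never touched during CV; the
    decision threshold is chosen on pooled out-of-fold training scores
    (Youden's J), then a final model fit on all training rows is evaluated
    once on the holdout.  Fully reproducible given ``seed``.
    """
    rng = np.random.default_rng(seed)
    X = features.X.to_numpy(dtype=float)
    y = features.y
    train_idx, hold_idx = stratified_holdout_split(y, holdout, rng)
    assert not np.intersect1d(train_idx, hold_idx).size
    Xtr, ytr = X[train_idx], y[train_idx]
    Xho, yho = X[hold_idx], y[hold_idx]
    aucs, oof_s, oof_y = _cv_aucs(Xtr, ytr, folds, repeats, rng)
    threshold = youden_threshold(oof_s, oof_y)
    final = fit_lda(Xtr, ytr)
    hold_scores = final.decision_scores(Xho)
    curve = roc_auc(hold_scores, yho)
    metrics = confusion_metrics(hold_scores, yho, threshold)
    return ClassifierReport(
        auc=curve.auc,
        sensitivity=metrics["sensitivity"],
        specificity=metrics["specificity"],
        ppv=metrics["ppv"],
        npv=metrics["npv"],
        threshold=threshold,
        cv_auc_mean=float(np.mean(aucs)),
        cv_auc_sd=float(np.std(aucs, ddof=1)),
        cv_scheme=f"stratified {folds}-fold x {repeats} repeats",
        holdout_fraction=holdout,
        n_train=len(train_idx),
        n_holdout=len(hold_idx),
        degenerate_margin=metrics["degenerate_margin"],
    )


def backward_feature_selection(
    features: FeatureMatrix,
    folds: int = 5,
    repeats: int = 2,
    seed: int = 0,
) -> list[dict]:
    """Greedy backward elimination ranked by repeated-CV AUC.

    At each step the feature whose removal least degrades CV AUC is dropped.
    Returns one record per model size (largest first) with the retained
    features, the CV AUC, and the feature eliminated next.
    """
    X_full = features.X
    y = features.y
    if X_full.shape[1] < 2:
        raise ValueError("need >= 2 features")

    def cv_auc(cols: list[str], seed_offset: int) -> float:
        rng = np.random.default_rng(seed + seed_offset)
        aucs, _, _ = _cv_aucs(X_full[cols].to_numpy(float), y, folds, repeats, rng)
        return float(np.mean(aucs))

    remaining = list(X_full.columns)
    history: list[dict] = []
    step = 0
    while len(remaining) >= 1:
        score = cv_auc(remaining, step)
        record = {"features": list(remaining), "cv_auc": score, "eliminated_next": None}
        if len(remaining) == 1:
            history.append(record)
            break
        # drop the feature whose removal leaves the best AUC
        candidates = [
            (cv_auc([c for c in remaining if c != drop], step), drop)
            for drop in remaining
        ]
        best_auc, drop = max(candidates, key=lambda t: t[0])
        record["eliminated_next"] = drop
        history.append(record)
        remaining.remove(drop)
        step += 1
    return history
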