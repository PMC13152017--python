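"""Threshold-free evaluation machinery, written from first principles.

ROC and PR curves are built by an explicit sweep over unique score
thresholds with the decision rule ``score >= t  =>  positive``. ROC-AUC
uses the trapezoid rule, which makes tied scores earn half credit so the
area equals the Mann-Whitney concordance probability exactly. PR-AUC uses
the step rule (average precision) — no linear interpolation, which is
known to flatter PR curves. The Youden operating point maximizes
TPR - FPR, breaking ties toward the larger threshold (fewer subjects
flagged).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class MetricsError(ValueError):
    pass


@dataclass
class ScoreSet:
    """Continuous risk scores aligned with binary ground truth (1 = positive)."""

    subject_ids: list
    scores: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if not (len(self.subject_ids) == self.scores.size == self.labels.size):
            raise MetricsError("subject_ids, scores, labels must align")
        if np.any(~np.isfinite(self.scores)):
            raise MetricsError("scores must be finite")
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise MetricsError("labels must be binary 0/1")

    @property
    def n_pos(self) -> int:
        return int(self.labels.sum())

    @property
    def n_neg(self) -> int:
        return int(self.labels.size - self.labels.sum())


@dataclass
class RocCurve:
    thresholds: np.ndarray  # descending; leading +inf anchor
    tpr: np.ndarray
    fpr: np.ndarray
    n_pos: int
    n_neg: int


@dataclass
class OperatingPoint:
    threshold: float
    tpr: float
    fpr: float
    j: float
    tp: int
    fp: int
    tn: int
    fn: int


@dataclass
class ImportanceReport:
    per_feature: pd.DataFrame  # feature, delta_auc_mean, delta_auc_sd, joint
    grouped: pd.DataFrame  # joint, n_features, total, mean, sd, pct_of_total
    baseline_auc: float


@dataclass
class ScalingResult:
    n_grid: np.ndarray
    auc_mean: np.ndarray
    auc_per_repeat: list
    slope: float
    intercept: float
    residuals: np.ndarray


def _curve_points(scores: ScoreSet):
    """Cumulative TP/FP counts at each unique threshold, descending."""
    order = np.argsort(-scores.scores, kind="stable")
    s = scores.scores[order]
    y = scores.labels[order]
    # collapse ties: only the last index of each tied block is a curve point
    distinct = np.r_[np.diff(s) != 0, True]
    tp = np.cumsum(y)[distinct]
    fp = np.cumsum(1 - y)[distinct]
    thresholds = s[distinct]
    return thresholds, tp, fp


def roc_auc(scores: ScoreSet):
    """ROC curve and area. Area == Mann-Whitney concordance (ties half credit)."""
    if scores.n_pos == 0 or scores.n_neg == 0:
        raise MetricsError("roc_auc needs both classes present")
    thresholds, tp, fp = _curve_points(scores)
    tpr = np.r_[0.0, tp / scores.n_pos]
    fpr = np.r_[0.0, fp / scores.n_neg]
    curve = RocCurve(
        thresholds=np.r_[np.inf, thresholds],
        tpr=tpr,
        fpr=fpr,
        n_pos=scores.n_pos,
        n_neg=scores.n_neg,
    )
    auc = float(np.trapezoid(tpr, fpr))
    return curve, auc


def pr_auc(scores: ScoreSet):
    """Precision-recall curve and step-rule area (average precision)."""
    if scores.n_pos == 0:
        raise MetricsError("pr_auc needs at least one positive")
    thresholds, tp, fp = _curve_points(scores)
    recall = tp / scores.n_pos
    precision = tp / (tp + fp)
    ap = float(np.sum(np.diff(np.r_[0.0, recall]) * precision))
    curve = pd.DataFrame(
        {"threshold": thresholds, "recall": recall, "precision": precision}
    )
    return curve, ap


def youden_threshold(curve: RocCurve) -> OperatingPoint:
    """Operating point maximizing J = TPR - FPR; ties -> larger threshold."""
    j = curve.tpr - curve.fpr
    # skip the +inf anchor; thresholds are descending so the FIRST argmax is
    # the largest threshold attaining max J
    best = 1 + int(np.argmax(j[1:]))
    t = float(curve.thresholds[best])
    tpr, fpr = float(curve.tpr[best]), float(curve.fpr[best])
    tp = int(round(tpr * curve.n_pos))
    fp = int(round(fpr * curve.n_neg))
    return OperatingPoint(
        threshold=t, tpr=tpr, fpr=fpr, j=tpr - fpr,
        tp=tp, fp=fp, tn=curve.n_neg - fp, fn=curve.n_pos - tp,
    )


def confusion_at_threshold(scores: ScoreSet, t: float) -> OperatingPoint:
    """Confusion counts and rates with the rule score >= t => positive."""
    pred = scores.scores >= t
    y = scores.labels.astype(bool)
    tp = int(np.sum(pred & y))
    fp = int(np.sum(pred & ~y))
    fn = int(np.sum(~pred & y))
    tn = int(np.sum(~pred & ~y))
    tpr = tp / (tp + fn) if (tp + fn) else 0.0
    fpr = fp / (fp + tn) if (fp + tn) else 0.0
    return OperatingPoint(
        threshold=float(t), tpr=tpr, fpr=fpr, j=tpr - fpr,
        tp=tp, fp=fp, tn=tn, fn=fn,
    )


def permutation_importance(model, features: pd.DataFrame, labels,
                           n_repeats: int = 10, seed: int = 0,
                           groups: dict | None = None) -> ImportanceReport:
    """Per-feature drop in ROC-AUC when that column is shuffled, plus the
    by-joint aggregation.

    ``model`` is anything with a ``score(features) -> array`` method (a
    :class:`kinescreen.classify.TrainedModel`). ``groups`` maps feature name
    to joint group; defaults to the canonical 38-feature grouping.
    """
    from .features import FEATURE_GROUPS

    groups = groups or FEATURE_GROUPS
    labels = np.asarray(labels, dtype=int)
    ids = list(features.index.astype(str))
    base_scores = model.score(features)
    _, baseline = roc_auc(ScoreSet(ids, base_scores, labels))
    rng = np.random.default_rng(seed)

    rows = []
    for col in features.columns:
        deltas = []
        for _ in range(n_repeats):
            shuffled = features.copy()
            shuffled[col] = rng.permutation(shuffled[col].to_numpy())
            _, auc = roc_auc(ScoreSet(ids, model.score(shuffled), labels))
            deltas.append(baseline - auc)
        deltas = np.asarray(deltas)
        rows.append({
            "feature": col,
            "delta_auc_mean": float(deltas.mean()),
            "delta_auc_sd": float(deltas.std(ddof=1)) if n_repeats > 1 else 0.0,
            "joint": groups.get(col, "other"),
        })
    per_feature = pd.DataFrame(rows)

    grouped_rows = []
    totals = per_feature.groupby("joint")["delta_auc_mean"].sum()
    grand_total = float(totals.sum())
    for joint, sub in per_feature.groupby("joint"):
        total = float(sub["delta_auc_mean"].sum())
        grouped_rows.append({
            "joint": joint,
            "n_features": len(sub),
            "total": total,
            "mean": float(sub["delta_auc_mean"].mean()),
            "sd": float(sub["delta_auc_mean"].std(ddof=1)) if len(sub) > 1 else 0.0,
            "pct_of_total": 100.0 * total / grand_total if grand_total != 0 else float("nan"),
        })
    grouped = pd.DataFrame(grouped_rows).sort_values("total", ascending=False)
    grouped = grouped.reset_index(drop=True)
    return ImportanceReport(per_feature=per_feature, grouped=grouped,
                            baseline_auc=float(baseline))


def fit_power_law(n_grid, auc) -> tuple:
    """OLS fit of log(1 - AUC) on log(n); returns (slope, intercept, residuals)."""
    n_grid = np.asarray(n_grid, dtype=float)
    auc = np.asarray(auc, dtype=float)
    if np.any(np.diff(n_grid) <= 0):
        raise MetricsError("n_grid must be strictly increasing")
    if np.any((auc <= 0) | (auc >= 1)):
        raise MetricsError("AUC values must lie in (0, 1) for the log-log fit")
    x = np.log(n_grid)
    y = np.log(1.0 - auc)
    slope, intercept = np.polyfit(x, y, 1)
    residuals = y - (slope * x + intercept)
    return float(slope), float(intercept), residuals


def scaling_curve(features: pd.DataFrame, labels, subject_ids=None,
                  n_grid=(50, 100, 200, 400, 800), test_size: int = 100,
                  cv_folds: int = 6, seed: int = 0,
                  train_config=None) -> ScalingResult:
    """Learning curve: AUC on a fixed held-out test set vs training-set size.

    For each n in ``n_grid``, ``cv_folds`` stratified subsamples of n
    training subjects are drawn (seeded), a model is trained on each, and
    test-set ROC-AUC is averaged. The curve is then fit as a power law in
    log-log space.
    """
    from .classify import TrainConfig, train as train_model

    labels = np.asarray(labels, dtype=int)
    n_total = len(features)
    if subject_ids is None:
        subject_ids = [str(i) for i in range(n_total)]
    n_grid = sorted(n_grid)
    if max(n_grid) + test_size > n_total:
        raise MetricsError(
            f"cohort of {n_total} too small for max train {max(n_grid)} "
            f"+ test {test_size}"
        )
    rng = np.random.default_rng(seed)
    # stratified fixed test set
    test_idx = _stratified_subsample(labels, test_size, rng)
    train_pool = np.setdiff1d(np.arange(n_total), test_idx)
    x_test = features.iloc[test_idx]
    y_test = labels[test_idx]
    test_ids = [subject_ids[i] for i in test_idx]

    train_config = train_config or TrainConfig(seed=seed)
    auc_mean, auc_per_repeat = [], []
    for n in n_grid:
        aucs = []
        for rep in range(cv_folds):
            sub = train_pool[
                _stratified_subsample(labels[train_pool], n,
                                      np.random.default_rng(rng.integers(2**32)))
            ]
            model = train_model(features.iloc[sub], labels[sub], train_config)
            _, auc = roc_auc(ScoreSet(test_ids, model.score(x_test), y_test))
            aucs.append(auc)
        auc_per_repeat.append(aucs)
        auc_mean.append(float(np.mean(aucs)))
    auc_mean = np.asarray(auc_mean)
    eps = 1e-12
    slope, intercept, residuals = fit_power_law(
        n_grid, np.clip(auc_mean, eps, 1 - eps)
    )
    return ScalingResult(
        n_grid=np.asarray(n_grid), auc_mean=auc_mean,
        auc_per_repeat=auc_per_repeat, slope=slope, intercept=intercept,
        residuals=residuals,
    )


def _stratified_subsample(labels: np.ndarray, size: int, rng) -> np.ndarray:
    """Indices of a label-stratified subsample of ``size`` items."""
    labels = np.asarray(labels)
    n = labels.size
    if size > n:
        raise MetricsError(f"cannot subsample {size} from {n}")
    out = []
    classes = np.unique(labels)
    quotas = {}
    for c in classes:
        quotas[c] = int(np.floor(size * np.mean(labels == c)))
    short = size - sum(quotas.values())
    for c in list(classes)[:short]:
        quotas[c] += 1
    for c in classes:
        idx = np.flatnonzero(labels == c)
        take = min(max(quotas[c], 1), idx.size)
        out.append(rng.choice(idx, size=take, replace=False))
    out = np.concatenate(out)
    # trim or top up to the exact size deterministically
    if out.size > size:
        out = out[:size]
    elif out.size < size:
        rest = np.setdiff1d(np.arange(n), out)
        out = np.concatenate([out, rng.choice(rest, size=size - out.size, replace=False)])
    return np.sort(out)
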