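"""Imbalance-aware binary classification of the 38-feature table.

The builtin backend stands in for a heavyweight AutoML engine while keeping
its contract: balanced-accuracy objective, internal stratified CV on the
training data only, class-imbalance handling via inverse-prevalence
weights, and a single refit final model (no ensembling). Standardization
and median imputation are fit inside each training fold — never globally —
so no evaluation-fold statistics leak into training.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import HistGradientBoostingClassifier
from sklearn.impute import SimpleImputer
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import balanced_accuracy_score
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .metrics import ScoreSet, roc_auc


class ClassifyError(ValueError):
    pass


@dataclass(frozen=True)
class TrainConfig:
    seed: int = 0
    objective: str = "balanced_accuracy"
    internal_cv_folds: int = 3
    imbalance_strategy: str = "class_weight"  # or "oversample"
    backend: str = "builtin"  # "automl" delegates to an external engine
    time_budget_s: float | None = None
    candidate_family: str = "full"  # "full", "linear", "trees"


@dataclass
class TrainedModel:
    """A fitted scorer with its provenance. ``score`` maps features to [0, 1]."""

    pipeline: Pipeline
    feature_names: tuple
    backend: str
    chosen_candidate: str
    candidate_grid: list
    internal_cv_balanced_accuracy: float
    seed: int

    def score(self, features: pd.DataFrame) -> np.ndarray:
        self._check_signature(features)
        x = features[list(self.feature_names)].to_numpy(dtype=float)
        return self.pipeline.predict_proba(x)[:, 1]

    def _check_signature(self, features: pd.DataFrame) -> None:
        missing = [c for c in self.feature_names if c not in features.columns]
        if missing:
            raise ClassifyError(
                f"feature signature mismatch: missing {missing[:5]}"
            )

    def save(self, path) -> Path:
        path = Path(path)
        with open(path, "wb") as fh:
            pickle.dump(self, fh)
        return path

    @staticmethod
    def load(path) -> "TrainedModel":
        with open(path, "rb") as fh:
            model = pickle.load(fh)
        if not isinstance(model, TrainedModel):
            raise ClassifyError(f"{path} does not contain a TrainedModel")
        return model


def _candidates(config: TrainConfig, class_weight: dict):
    """The fixed candidate family the builtin backend searches."""
    cands = []
    if config.candidate_family in ("full", "linear"):
        for c in (0.01, 0.1, 1.0, 10.0):
            cands.append((
                f"logistic(C={c})",
                Pipeline([
                    ("impute", SimpleImputer(strategy="median")),
                    ("scale", StandardScaler()),
                    ("clf", LogisticRegression(
                        C=c, class_weight=class_weight, max_iter=2000,
                        random_state=config.seed,
                    )),
                ]),
            ))
    if config.candidate_family in ("full", "trees"):
        for depth, lr in ((3, 0.1), (None, 0.05)):
            cands.append((
                f"hgb(depth={depth},lr={lr})",
                Pipeline([
                    ("impute", SimpleImputer(strategy="median")),
                    ("clf", HistGradientBoostingClassifier(
                        max_depth=depth, learning_rate=lr, max_iter=150,
                        class_weight=class_weight, random_state=config.seed,
                    )),
                ]),
            ))
    if not cands:
        raise ClassifyError(f"unknown candidate_family {config.candidate_family!r}")
    return cands


def train(features: pd.DataFrame, labels, config: TrainConfig | None = None) -> TrainedModel:
    """Fit the single best candidate by internal CV balanced accuracy.

    ``features`` holds one row per subject with numeric feature columns
    (non-feature columns subject_id/label are ignored if present);
    ``labels`` is binary with 1 = positive (FM-) class.
    """
    config = config or TrainConfig()
    if config.backend != "builtin":
        raise ClassifyError(
            f"backend {config.backend!r} is a plug-in point; only 'builtin' ships"
        )
    feature_cols = [c for c in features.columns if c not in ("subject_id", "label")]
    x = features[feature_cols].to_numpy(dtype=float)
    y = np.asarray(labels, dtype=int)
    if x.shape[0] != y.size:
        raise ClassifyError("features and labels misaligned")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ClassifyError("training requires both classes present")

    if config.imbalance_strategy == "class_weight":
        # inverse-prevalence weights
        class_weight = {int(c): float(y.size / (2.0 * n)) for c, n in zip(classes, counts)}
    elif config.imbalance_strategy == "oversample":
        class_weight = None
    else:
        raise ClassifyError(f"unknown imbalance strategy {config.imbalance_strategy!r}")

    candidates = _candidates(config, class_weight)
    k = min(config.internal_cv_folds, int(counts.min()))
    if k < 2:
        raise ClassifyError("too few minority-class subjects for internal CV")
    cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=config.seed)

    def _fold_xy(idx):
        xf, yf = x[idx], y[idx]
        if config.imbalance_strategy == "oversample":
            rng = np.random.default_rng(config.seed)
            minority = classes[np.argmin(np.bincount(yf, minlength=2))]
            n_extra = int(np.sum(yf != minority) - np.sum(yf == minority))
            if n_extra > 0:
                pool = np.flatnonzero(yf == minority)
                extra = rng.choice(pool, size=n_extra, replace=True)
                xf = np.vstack([xf, xf[extra]])
                yf = np.concatenate([yf, yf[extra]])
        return xf, yf

    best_name, best_score, best_pipe = None, -np.inf, None
    grid_log = []
    for name, pipe in candidates:
        fold_scores = []
        for tr, te in cv.split(x, y):
            xf, yf = _fold_xy(tr)
            pipe.fit(xf, yf)
            fold_scores.append(balanced_accuracy_score(y[te], pipe.predict(x[te])))
        mean_score = float(np.mean(fold_scores))
        grid_log.append({"candidate": name, "cv_balanced_accuracy": mean_score})
        if mean_score > best_score:
            best_name, best_score, best_pipe = name, mean_score, pipe

    xf, yf = _fold_xy(np.arange(x.shape[0]))
    best_pipe.fit(xf, yf)
    return TrainedModel(
        pipeline=best_pipe,
        feature_names=tuple(feature_cols),
        backend="builtin",
        chosen_candidate=best_name,
        candidate_grid=grid_log,
        internal_cv_balanced_accuracy=best_score,
        seed=config.seed,
    )


def predict_scores(model: TrainedModel, features: pd.DataFrame,
                   labels=None, subject_ids=None) -> ScoreSet:
    """Score rows with a trained model; returns an aligned ScoreSet."""
    scores = model.score(features)
    if subject_ids is None:
        if "subject_id" in features.columns:
            subject_ids = list(features["subject_id"].astype(str))
        else:
            subject_ids = [str(i) for i in range(len(features))]
    if labels is None:
        labels = np.zeros(len(features), dtype=int)
    return ScoreSet(subject_ids=subject_ids, scores=np.clip(scores, 0.0, 1.0),
                    labels=labels)


def cross_validate(features: pd.DataFrame, labels, k: int = 5,
                   seeds=(0, 1, 2, 3, 4, 5),
                   config: TrainConfig | None = None) -> dict:
    """Subject-wise stratified k-fold ROC-AUC, repeated over seeds.

    Returns per-fold AUCs plus mean and sd. The caller is responsible for
    keeping lock-box subjects out of ``features``.
    """
    y = np.asarray(labels, dtype=int)
    feature_cols = [c for c in features.columns if c not in ("subject_id", "label")]
    if k < 2:
        raise ClassifyError("k must be >= 2")
    if np.bincount(y, minlength=2).min() < k:
        raise ClassifyError(
            f"only {int(np.bincount(y, minlength=2).min())} minority subjects: "
            f"use fewer than {k} folds"
        )
    aucs = []
    for seed in seeds:
        cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        fold_config = TrainConfig(
            seed=seed,
            internal_cv_folds=(config or TrainConfig()).internal_cv_folds,
            imbalance_strategy=(config or TrainConfig()).imbalance_strategy,
            candidate_family=(config or TrainConfig()).candidate_family,
        )
        for tr, te in cv.split(features[feature_cols], y):
            model = train(features.iloc[tr], y[tr], fold_config)
            ids = [str(i) for i in te]
            _, auc = roc_auc(ScoreSet(ids, model.score(features.iloc[te]), y[te]))
            aucs.append(auc)
    aucs = np.asarray(aucs)
    return {
        "fold_aucs": aucs,
        "mean_auc": float(aucs.mean()),
        "sd_auc": float(aucs.std(ddof=1)),
        "k": k,
        "n_seeds": len(tuple(seeds)),
    }
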