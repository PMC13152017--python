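"""End-to-end orchestration with run logging and lock-box discipline.

The Test split is guarded in software: any attempt to score it without an
explicit unlock raises :class:`LockBoxError`, and every unlock is recorded
in the append-only run log. This makes the preregistration discipline
structural rather than procedural.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify, cohort as cohort_mod, metrics
from .features import FEATURE_NAMES, feature_table, feature_vector
from .keypoint_io import (
    POSITIVE_LABEL,
    read_cohort,
    read_feature_table,
    read_keypoints,
    write_feature_table,
)
from .posenorm import head_up_normalize
from .preprocess import PreprocessConfig, preprocess_pipeline


class LockBoxError(RuntimeError):
    """Raised when the Test split is read without an explicit unlock."""


@dataclass
class RunConfig:
    output_dir: str
    keypoints_dir: str | None = None
    cohort_csv: str | None = None
    seed: int = 0
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    split_fractions: tuple = (0.70, 0.10, 0.20)
    train: classify.TrainConfig | None = None
    evaluate_test: bool = False  # requires unlock=True at run time


@dataclass
class RunLog:
    entries: list = field(default_factory=list)
    unlock_events: list = field(default_factory=list)

    def record(self, stage: str, **info) -> None:
        self.entries.append({
            "stage": stage,
            "time": datetime.now(timezone.utc).isoformat(),
            **info,
        })

    def record_unlock(self, split: str) -> None:
        event = {"split": split, "time": datetime.now(timezone.utc).isoformat()}
        self.unlock_events.append(event)
        self.record("lockbox_unlock", **event)

    def save(self, path) -> Path:
        Path(path).write_text(json.dumps(
            {"entries": self.entries, "unlock_events": self.unlock_events}, indent=1
        ))
        return Path(path)


def file_sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def extract_features_for_sequences(raws, records, config: PreprocessConfig | None = None) -> pd.DataFrame:
    """Preprocess + normalize + featurize a batch of RawDetections."""
    label_map = {r.subject_id: r.label for r in records}
    vectors = []
    for raw in raws:
        clean = preprocess_pipeline(raw, config)
        norm = head_up_normalize(clean)
        vectors.append(
            feature_vector(norm, label=label_map.get(raw.subject_id, "unknown"))
        )
    return feature_table(vectors)


def evaluate_split(model: classify.TrainedModel, features: pd.DataFrame,
                   manifest: cohort_mod.SplitManifest, split: str,
                   unlock: bool = False, log: RunLog | None = None) -> dict:
    """Score one split and report ROC/PR/Youden. Test requires ``unlock``."""
    if split == "test" and not unlock:
        raise LockBoxError(
            "the Test split is a preregistered lock box; pass unlock=True "
            "(CLI: --unlock) to evaluate it — the unlock will be logged"
        )
    if split == "test" and log is not None:
        log.record_unlock(split)
    ids = set(manifest.splits[split])
    rows = features[features["subject_id"].astype(str).isin(ids)]
    if len(rows) == 0:
        raise ValueError(f"no feature rows for split {split!r}")
    y = (rows["label"] == POSITIVE_LABEL).astype(int).to_numpy()
    scores = metrics.ScoreSet(
        list(rows["subject_id"].astype(str)), model.score(rows), y
    )
    curve, auc = metrics.roc_auc(scores)
    _, ap = metrics.pr_auc(scores)
    op = metrics.youden_threshold(curve)
    return {
        "split": split,
        "n": len(rows),
        "n_positive": int(y.sum()),
        "roc_auc": auc,
        "pr_auc": ap,
        "youden": asdict(op),
        "roc_curve": {
            "thresholds": [float(t) for t in curve.thresholds],
            "tpr": curve.tpr.tolist(),
            "fpr": curve.fpr.tolist(),
        },
    }


def run(config: RunConfig, unlock: bool = False,
        synth_cohort=None) -> dict:
    """Execute extract -> split -> train -> evaluate(Val) [-> evaluate(Test)].

    ``synth_cohort`` (a :class:`kinescreen.synthetic.SynthCohort`) substitutes
    for on-disk keypoints; otherwise keypoint files are read from
    ``config.keypoints_dir`` (one JSON per subject) with labels from
    ``config.cohort_csv``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = RunLog()
    log.record("start", config=json.loads(json.dumps(
        {"seed": config.seed, "split_fractions": list(config.split_fractions)})))

    if synth_cohort is not None:
        raws = [raw for raw, _ in synth_cohort.subjects]
        records = [rec for _, rec in synth_cohort.subjects]
    else:
        if not config.keypoints_dir or not config.cohort_csv:
            raise ValueError("need keypoints_dir and cohort_csv (or synth_cohort)")
        records = read_cohort(config.cohort_csv)
        raws = [
            read_keypoints(p, format="json")
            for p in sorted(Path(config.keypoints_dir).glob("*.keypoints.json"))
        ]

    features = extract_features_for_sequences(raws, records, config.preprocess)
    feat_path = write_feature_table(features, out / "features.csv")
    log.record("extract", n_subjects=len(features), output=str(feat_path),
               sha256=file_sha256(feat_path))

    trainable = features[features["label"].isin(("FM_plus", "FM_minus"))]
    labels = {
        str(r["subject_id"]): r["label"] for _, r in trainable.iterrows()
    }
    strata = {r.subject_id: r.strata for r in records}
    manifest = cohort_mod.stratified_split(
        list(labels), labels, strata, config.split_fractions, config.seed
    )
    manifest_path = out / "split_manifest.json"
    cohort_mod.freeze_manifest(manifest, manifest_path)
    log.record("split", manifest=str(manifest_path), sha256=manifest.sha256)

    train_ids = set(manifest.splits["train"])
    train_rows = trainable[trainable["subject_id"].astype(str).isin(train_ids)]
    y_train = (train_rows["label"] == POSITIVE_LABEL).astype(int).to_numpy()
    model = classify.train(
        train_rows, y_train, config.train or classify.TrainConfig(seed=config.seed)
    )
    model_path = model.save(out / "model.pkl")
    log.record("train", chosen=model.chosen_candidate,
               internal_cv_balanced_accuracy=model.internal_cv_balanced_accuracy,
               output=str(model_path))

    reports = {}
    val_report = evaluate_split(model, trainable, manifest, "val", log=log)
    (out / "report_val.json").write_text(json.dumps(val_report, indent=1))
    log.record("evaluate", split="val", roc_auc=val_report["roc_auc"],
               sha256=file_sha256(out / "report_val.json"))
    reports["val"] = val_report

    if config.evaluate_test:
        test_report = evaluate_split(
            model, trainable, manifest, "test", unlock=unlock, log=log
        )
        (out / "report_test.json").write_text(json.dumps(test_report, indent=1))
        log.record("evaluate", split="test", roc_auc=test_report["roc_auc"],
                   sha256=file_sha256(out / "report_test.json"))
        reports["test"] = test_report

    log.save(out / "run_log.json")
    return {
        "features": features,
        "manifest": manifest,
        "model": model,
        "reports": reports,
        "log": log,
        "output_dir": out,
    }
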