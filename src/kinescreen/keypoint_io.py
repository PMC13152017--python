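"""Readers and writers for keypoint detections, feature tables, and cohort tables.

All on-disk formats are plain text (JSON / CSV), carry a ``schema_version``
field, and round-trip bit-exactly. Multiple candidate detections per frame
are preserved at read time; picking one is a preprocessing decision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .skeleton import SkeletonConvention, COCO17

SCHEMA_VERSION = "1.0"

#: accepted label spellings -> canonical token
_LABEL_ALIASES = {
    "fm_plus": "FM_plus",
    "fm+": "FM_plus",
    "fm_minus": "FM_minus",
    "fm-": "FM_minus",
    "atypical": "atypical",
    "unknown": "unknown",
}

#: labels usable for binary model training (atypical/unknown are excluded)
TRAINABLE_LABELS = frozenset({"FM_plus", "FM_minus"})

#: the positive (higher-risk) class
POSITIVE_LABEL = "FM_minus"


class KeypointIOError(ValueError):
    """Raised on malformed keypoint, feature, or cohort files."""


@dataclass
class Detection:
    """One candidate pose instance: 17 x (x, y, confidence) plus optional score."""

    keypoints: np.ndarray  # (17, 3)
    score: float | None = None

    def effective_score(self) -> float:
        """Instance score; falls back to mean keypoint confidence."""
        if self.score is not None:
            return float(self.score)
        return float(np.mean(self.keypoints[:, 2]))


@dataclass
class RawDetections:
    """Per-frame candidate detections for one subject's video."""

    frames: list  # list over frames of list[Detection]; empty list = missing frame
    fps: float
    resolution: tuple  # (width, height)
    subject_id: str

    def __post_init__(self) -> None:
        if len(self.frames) < 1:
            raise KeypointIOError("RawDetections needs at least one frame")
        if not self.fps > 0:
            raise KeypointIOError(f"fps must be > 0, got {self.fps}")
        for t, dets in enumerate(self.frames):
            for d in dets:
                kp = np.asarray(d.keypoints, dtype=float)
                if kp.shape != (17, 3):
                    raise KeypointIOError(
                        f"frame {t}: expected 17 keypoint triplets, got shape {kp.shape}"
                    )
                c = kp[:, 2]
                if np.any(c < 0) or np.any(c > 1):
                    raise KeypointIOError(f"frame {t}: confidence outside [0, 1]")

    @property
    def n_frames(self) -> int:
        return len(self.frames)


@dataclass
class KeypointSequence:
    """Exactly one detection per frame: (n_frames, 17, 3) of x, y, confidence.

    Missing frames are all-NaN rows with confidence 0.
    """

    data: np.ndarray  # (n, 17, 3)
    fps: float
    resolution: tuple
    subject_id: str
    provenance: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[1:] != (17, 3):
            raise KeypointIOError(f"expected (n, 17, 3), got {self.data.shape}")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def xy(self) -> np.ndarray:
        return self.data[:, :, :2]

    @property
    def confidence(self) -> np.ndarray:
        return self.data[:, :, 2]


@dataclass
class SubjectRecord:
    """One row of the cohort table: id, GMA label, optional strata."""

    subject_id: str
    label: str
    strata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        canonical = _LABEL_ALIASES.get(str(self.label).strip().lower())
        if canonical is None:
            raise KeypointIOError(
                f"subject {self.subject_id}: unknown label {self.label!r}; "
                f"expected one of FM+, FM-, atypical, unknown"
            )
        self.label = canonical

    @property
    def trainable(self) -> bool:
        return self.label in TRAINABLE_LABELS

    @property
    def is_positive(self) -> bool:
        return self.label == POSITIVE_LABEL


# ---------------------------------------------------------------------------
# keypoint files
# ---------------------------------------------------------------------------


def read_keypoints(path, format: str | None = None,
                   skeleton: SkeletonConvention = COCO17) -> RawDetections:
    """Read per-frame keypoint detections from JSON or flat CSV.

    ``format`` defaults to the file suffix. Frames come back in ascending
    frame order; frames absent from the file appear as empty candidate lists.
    """
    path = Path(path)
    if not path.exists():
        raise KeypointIOError(f"no such file: {path}")
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt == "json":
        return _read_keypoints_json(path)
    if fmt == "csv":
        return _read_keypoints_csv(path)
    raise KeypointIOError(f"unsupported keypoint format: {fmt!r}")


def _read_keypoints_json(path: Path) -> RawDetections:
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise KeypointIOError(f"{path}: invalid JSON ({exc})") from exc
    for key in ("fps", "frames"):
        if key not in doc:
            raise KeypointIOError(f"{path}: missing required metadata field {key!r}")
    frame_map: dict[int, list[Detection]] = {}
    for entry in doc["frames"]:
        idx = int(entry["frame"])
        dets = []
        for j, inst in enumerate(entry.get("detections", [])):
            kp = np.asarray(inst["keypoints"], dtype=float)
            if kp.shape != (17, 3):
                raise KeypointIOError(
                    f"{path}: frame {idx}, detection {j}: "
                    f"expected 17 keypoint triplets, got shape {kp.shape}"
                )
            dets.append(Detection(keypoints=kp, score=inst.get("score")))
        frame_map[idx] = dets
    n = max(frame_map) + 1 if frame_map else 0
    if n == 0:
        raise KeypointIOError(f"{path}: no frames")
    frames = [frame_map.get(t, []) for t in range(n)]
    return RawDetections(
        frames=frames,
        fps=float(doc["fps"]),
        resolution=tuple(doc.get("resolution", (0, 0))),
        subject_id=str(doc.get("subject_id", path.stem)),
    )


_CSV_META_KEYS = ("schema_version", "subject_id", "fps", "width", "height")


def _read_keypoints_csv(path: Path) -> RawDetections:
    meta: dict[str, str] = {}
    n_meta = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_meta += 1
            key, _, value = line.lstrip("# ").rstrip("\n").partition("=")
            meta[key.strip()] = value.strip()
    if "fps" not in meta:
        raise KeypointIOError(f"{path}: missing '# fps=' metadata header")
    df = pd.read_csv(path, skiprows=n_meta, float_precision="round_trip")
    kp_cols = [f"{axis}{k}" for k in range(17) for axis in ("x", "y", "c")]
    missing = [c for c in ("frame",) + tuple(kp_cols) if c not in df.columns]
    if missing:
        raise KeypointIOError(f"{path}: missing columns {missing[:3]}...")
    n = int(df["frame"].max()) + 1 if len(df) else 0
    frames: list[list[Detection]] = [[] for _ in range(n)]
    coords = df[kp_cols].to_numpy(dtype=float).reshape(len(df), 17, 3)
    scores = df["score"].to_numpy(dtype=float) if "score" in df.columns else [None] * len(df)
    for row, (t, kp) in enumerate(zip(df["frame"].astype(int), coords)):
        score = scores[row]
        frames[t].append(Detection(keypoints=kp, score=None if score is None or np.isnan(score) else float(score)))
    return RawDetections(
        frames=frames,
        fps=float(meta["fps"]),
        resolution=(int(float(meta.get("width", 0))), int(float(meta.get("height", 0)))),
        subject_id=meta.get("subject_id", path.stem),
    )


def write_keypoints(raw: RawDetections, path, format: str | None = None) -> Path:
    """Write RawDetections to JSON (default) or flat CSV; inverse of read_keypoints."""
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt == "json":
        doc = {
            "schema_version": SCHEMA_VERSION,
            "subject_id": raw.subject_id,
            "fps": raw.fps,
            "resolution": list(raw.resolution),
            "frames": [
                {
                    "frame": t,
                    "detections": [
                        {
                            "keypoints": np.asarray(d.keypoints, dtype=float).tolist(),
                            **({"score": float(d.score)} if d.score is not None else {}),
                        }
                        for d in dets
                    ],
                }
                for t, dets in enumerate(raw.frames)
            ],
        }
        path.write_text(json.dumps(doc))
    elif fmt == "csv":
        lines = [
            f"# schema_version={SCHEMA_VERSION}",
            f"# subject_id={raw.subject_id}",
            f"# fps={raw.fps!r}",
            f"# width={raw.resolution[0]}",
            f"# height={raw.resolution[1]}",
        ]
        header = ["frame", "detection", "score"] + [
            f"{axis}{k}" for k in range(17) for axis in ("x", "y", "c")
        ]
        lines.append(",".join(header))
        for t, dets in enumerate(raw.frames):
            for j, d in enumerate(dets):
                vals = np.asarray(d.keypoints, dtype=float).ravel()
                score = "" if d.score is None else repr(float(d.score))
                lines.append(
                    ",".join([str(t), str(j), score] + [repr(float(v)) for v in vals])
                )
        path.write_text("\n".join(lines) + "\n")
    else:
        raise KeypointIOError(f"unsupported keypoint format: {fmt!r}")
    return path


# ---------------------------------------------------------------------------
# feature tables
# ---------------------------------------------------------------------------


def write_feature_table(table: pd.DataFrame, path) -> Path:
    """Write a per-subject feature table as CSV with canonical column order.

    Columns: subject_id, label, then the 38 canonical feature names. NaNs
    are a validation error — imputation (if any) happens downstream and must
    be explicit.
    """
    from .features import FEATURE_NAMES  # local import avoids a cycle

    if len(table) == 0:
        raise KeypointIOError("refusing to write an empty feature table")
    missing = [c for c in FEATURE_NAMES if c not in table.columns]
    if missing:
        raise KeypointIOError(f"feature table is missing columns: {missing[:5]}")
    cols = ["subject_id", "label"] + list(FEATURE_NAMES)
    if "label" not in table.columns:
        table = table.assign(label="unknown")
    out = table[cols]
    feat = out[list(FEATURE_NAMES)].to_numpy(dtype=float)
    if np.any(~np.isfinite(feat)):
        bad = np.array(FEATURE_NAMES)[np.any(~np.isfinite(feat), axis=0)]
        raise KeypointIOError(f"non-finite feature values in columns {list(bad[:5])}")
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# schema_version={SCHEMA_VERSION}\n")
        fh.write(",".join(cols) + "\n")
        for _, row in out.iterrows():
            fh.write(
                ",".join(
                    [str(row["subject_id"]), str(row["label"])]
                    + [repr(float(row[c])) for c in FEATURE_NAMES]
                )
                + "\n"
            )
    return path


def read_feature_table(path) -> pd.DataFrame:
    """Read a feature-table CSV written by :func:`write_feature_table`."""
    from .features import FEATURE_NAMES

    path = Path(path)
    if not path.exists():
        raise KeypointIOError(f"no such file: {path}")
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    missing = [c for c in ("subject_id", "label") + tuple(FEATURE_NAMES) if c not in df.columns]
    if missing:
        raise KeypointIOError(f"{path}: missing columns {missing[:5]}")
    df["subject_id"] = df["subject_id"].astype(str)
    return df


# ---------------------------------------------------------------------------
# cohort tables
# ---------------------------------------------------------------------------

_STRATA_COLS = ("sex", "age_weeks", "race_ethnicity")


def read_cohort(path) -> list:
    """Read the subject table (id, label, optional strata) from CSV."""
    path = Path(path)
    if not path.exists():
        raise KeypointIOError(f"no such file: {path}")
    df = pd.read_csv(path, comment="#")
    for col in ("subject_id", "label"):
        if col not in df.columns:
            raise KeypointIOError(f"{path}: missing required column {col!r}")
    ids = df["subject_id"].astype(str)
    dupes = sorted(ids[ids.duplicated()].unique())
    if dupes:
        raise KeypointIOError(f"{path}: duplicate subject_id values: {dupes}")
    records = []
    for _, row in df.iterrows():
        strata = {
            k: row[k] for k in _STRATA_COLS if k in df.columns and pd.notna(row[k])
        }
        records.append(SubjectRecord(str(row["subject_id"]), str(row["label"]), strata))
    return records


def write_cohort(records: list, path) -> Path:
    """Write SubjectRecords as a cohort CSV."""
    rows = []
    for r in records:
        row = {"subject_id": r.subject_id, "label": r.label}
        row.update(r.strata)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
    return Path(path)
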