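"""Canonical body frame and dataset-level QC.

Each pose is translated so the mid-hip sits at the origin and rotated so
the mid-hip -> mid-shoulder axis points "up" (along -y in image
convention); coordinates are then divided by the per-video median torso
length so the median torso measures exactly one unit. Rigid motion plus a
single uniform scale — within-video amplitude dynamics are preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import CleanSequence
from .skeleton import SkeletonConvention, COCO17


class PoseNormError(ValueError):
    pass


#: default QC band for the wingspan ratio: cohort mean +/- 2 SD
WINGSPAN_FLAG_BAND = (0.53, 1.01)


@dataclass
class NormalizedSequence:
    """(n, 17, 2) coordinates in torso units, head-up orientation."""

    xy: np.ndarray
    fps: float
    subject_id: str
    torso_length_px: np.ndarray = field(default_factory=lambda: np.array([]))
    median_torso_px: float = float("nan")
    rotation_deg: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        self.xy = np.asarray(self.xy, dtype=float)
        if self.xy.ndim != 3 or self.xy.shape[1:] != (17, 2):
            raise PoseNormError(f"expected (n, 17, 2), got {self.xy.shape}")

    @property
    def n_frames(self) -> int:
        return self.xy.shape[0]


def _midpoints(xy: np.ndarray, skeleton: SkeletonConvention):
    ls, rs, lh, rh = skeleton.torso_anchors
    mid_shoulder = 0.5 * (xy[:, ls] + xy[:, rs])
    mid_hip = 0.5 * (xy[:, lh] + xy[:, rh])
    return mid_shoulder, mid_hip


def head_up_normalize(seq: CleanSequence,
                      skeleton: SkeletonConvention = COCO17) -> NormalizedSequence:
    """Rotate each pose head-up and scale the video so median torso length = 1.

    Per frame: translate mid-hip to the origin and rotate so the torso axis
    (mid-hip to mid-shoulder) points along -y. A single uniform scale — the
    per-video median torso length — is then applied to all frames.
    """
    xy = seq.xy
    mid_shoulder, mid_hip = _midpoints(xy, skeleton)
    torso = mid_shoulder - mid_hip  # (n, 2)
    torso_len = np.linalg.norm(torso, axis=1)
    degenerate = torso_len < 1e-6
    if degenerate.mean() > 0.5:
        raise PoseNormError(
            f"degenerate torso (length < 1e-6 px) in "
            f"{degenerate.mean():.0%} of frames"
        )
    median_len = float(np.median(torso_len[~degenerate]))
    if median_len < 1e-6:
        raise PoseNormError("median torso length is degenerate")

    centered = xy - mid_hip[:, None, :]
    # rotation taking the torso direction onto (0, -1), per frame
    angle = np.arctan2(torso[:, 0], -torso[:, 1])  # 0 when already head-up
    cos, sin = np.cos(-angle), np.sin(-angle)
    rot = np.empty_like(centered)
    rot[:, :, 0] = cos[:, None] * centered[:, :, 0] - sin[:, None] * centered[:, :, 1]
    rot[:, :, 1] = sin[:, None] * centered[:, :, 0] + cos[:, None] * centered[:, :, 1]
    out = rot / median_len
    return NormalizedSequence(
        xy=out,
        fps=seq.fps,
        subject_id=seq.subject_id,
        torso_length_px=torso_len,
        median_torso_px=median_len,
        rotation_deg=np.degrees(-angle),
    )


def wingspan_ratio(seq: NormalizedSequence,
                   skeleton: SkeletonConvention = COCO17) -> float:
    """Per-frame x-extent over y-extent of the 12 body joints, averaged.

    Head keypoints are excluded. A proxy for camera viewing angle: values
    far from the supine-anatomy band indicate a non-top-down view.
    """
    body = seq.xy[:, skeleton.body_indices, :]
    x_range = body[:, :, 0].max(axis=1) - body[:, :, 0].min(axis=1)
    y_range = body[:, :, 1].max(axis=1) - body[:, :, 1].min(axis=1)
    if np.any(y_range <= 0):
        raise PoseNormError("zero y-range in at least one frame")
    return float(np.mean(x_range / y_range))


def ks_two_sample(a, b):
    """Two-sample Kolmogorov-Smirnov test: (D, p) by the asymptotic series."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise PoseNormError("ks_two_sample requires nonempty samples")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def retention_report(sequences, flag_below: float = 0.9) -> pd.DataFrame:
    """Per-video retention table; rows below ``flag_below`` are flagged."""
    if not sequences:
        raise PoseNormError("retention_report requires at least one sequence")
    rows = [
        {
            "subject_id": s.subject_id,
            "retention": s.retention,
            "flagged": s.retention < flag_below,
        }
        for s in sequences
    ]
    df = pd.DataFrame(rows)
    df.attrs["cohort_retention"] = float(df["retention"].mean())
    df.attrs["n_flagged"] = int(df["flagged"].sum())
    return df
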