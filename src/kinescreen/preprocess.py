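"""Raw detections -> clean, gap-free, smoothed keypoint time series.

Stage order is fixed: best-detection selection, confidence masking (< 0.8
by default), linear gap interpolation, 1-s rolling-median despike, 1-s
rolling-mean smoothing. All windows are specified in seconds and converted
with each video's own frame rate, so mixed-FPS cohorts are handled
uniformly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .keypoint_io import RawDetections, KeypointSequence


class PreprocessError(ValueError):
    pass


@dataclass(frozen=True)
class PreprocessConfig:
    confidence_threshold: float = 0.8
    median_window_s: float = 1.0
    mean_window_s: float = 1.0
    #: "cell" masks single (frame, keypoint) cells; "frame" drops whole frames
    mask_mode: str = "cell"

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence_threshold <= 1.0:
            raise PreprocessError("confidence_threshold must be in [0, 1]")
        if self.median_window_s <= 0 or self.mean_window_s <= 0:
            raise PreprocessError("filter windows must be positive")
        if self.mask_mode not in ("cell", "frame"):
            raise PreprocessError("mask_mode must be 'cell' or 'frame'")


@dataclass
class CleanSequence:
    """Gap-free (n, 17, 2) coordinates plus retention accounting."""

    xy: np.ndarray  # (n, 17, 2), no NaNs
    fps: float
    subject_id: str
    mask_log: np.ndarray = field(default_factory=lambda: np.zeros(17, dtype=int))
    retention: float = 1.0
    per_keypoint_retention: np.ndarray = field(default_factory=lambda: np.ones(17))
    config: PreprocessConfig = field(default_factory=PreprocessConfig)

    def __post_init__(self) -> None:
        self.xy = np.asarray(self.xy, dtype=float)
        if self.xy.ndim != 3 or self.xy.shape[1:] != (17, 2):
            raise PreprocessError(f"expected (n, 17, 2), got {self.xy.shape}")
        if not 0.0 <= self.retention <= 1.0:
            raise PreprocessError("retention must be in [0, 1]")

    @property
    def n_frames(self) -> int:
        return self.xy.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps


def select_best_detection(raw: RawDetections) -> KeypointSequence:
    """Keep the single highest-scoring candidate in each frame.

    The detection score is the instance score if present, else the mean
    keypoint confidence. Frames with no candidates become all-NaN rows with
    zero confidence (handled by masking/interpolation downstream).
    """
    n = raw.n_frames
    data = np.full((n, 17, 3), np.nan)
    data[:, :, 2] = 0.0
    for t, dets in enumerate(raw.frames):
        if not dets:
            continue
        best = max(dets, key=lambda d: d.effective_score())
        data[t] = np.asarray(best.keypoints, dtype=float)
    return KeypointSequence(
        data=data,
        fps=raw.fps,
        resolution=raw.resolution,
        subject_id=raw.subject_id,
        provenance="argmax detection score (fallback: mean keypoint confidence)",
    )


def mask_low_confidence(seq: KeypointSequence, threshold: float = 0.8,
                        mask_mode: str = "cell"):
    """NaN-out coordinates whose confidence falls below ``threshold``.

    Returns ``(masked_xy, mask_log, retention, per_keypoint_retention)``
    where retention counts (frame, keypoint) cells that survive.
    """
    if not 0.0 <= threshold <= 1.0:
        raise PreprocessError("threshold must be in [0, 1]")
    conf = seq.confidence
    low = conf < threshold
    if mask_mode == "frame":
        low = np.broadcast_to(low.any(axis=1)[:, None], low.shape).copy()
    xy = seq.xy.copy()
    xy[low] = np.nan
    # cells already missing (empty frames) count as not retained too
    missing = low | np.isnan(seq.xy).any(axis=2)
    mask_log = missing.sum(axis=0)
    per_kp = 1.0 - missing.mean(axis=0)
    retention = float(1.0 - missing.mean())
    return xy, mask_log.astype(int), retention, per_kp


def interpolate_gaps(xy: np.ndarray, copy: bool = True) -> np.ndarray:
    """Fill NaN gaps per keypoint per coordinate by linear interpolation.

    Interior gaps are straight lines in frame time; leading/trailing gaps
    take the nearest observed value (no invented motion at the edges).
    """
    xy = np.array(xy, dtype=float, copy=copy)
    n = xy.shape[0]
    t = np.arange(n)
    for k in range(xy.shape[1]):
        for a in range(xy.shape[2]):
            col = xy[:, k, a]
            obs = ~np.isnan(col)
            if obs.sum() < 2:
                raise PreprocessError(
                    f"keypoint {k} axis {a}: observed in {int(obs.sum())} frames; "
                    "need at least 2 to interpolate (unrecoverable track)"
                )
            if obs.all():
                continue
            # np.interp extends flat beyond the first/last observation
            xy[:, k, a] = np.interp(t, t[obs], col[obs])
    return xy


def _window_frames(window_s: float, fps: float, n_frames: int) -> int:
    w = int(round(window_s * fps))
    if w % 2 == 0:
        w += 1
    w = max(w, 1)
    if w >= n_frames:
        raise PreprocessError(
            f"filter window of {w} frames >= sequence length {n_frames}"
        )
    return w


def _rolling(xy: np.ndarray, w: int, how: str) -> np.ndarray:
    n = xy.shape[0]
    flat = pd.DataFrame(xy.reshape(n, -1))
    roll = flat.rolling(window=w, center=True, min_periods=1)
    out = roll.median() if how == "median" else roll.mean()
    return out.to_numpy().reshape(xy.shape)


def rolling_median_despike(xy: np.ndarray, fps: float, window_s: float = 1.0) -> np.ndarray:
    """Centered rolling median over round(window_s * fps) frames (forced odd).

    The window shrinks to the available frames at the boundaries. Removes
    isolated single-frame spikes completely for any window >= 3.
    """
    if window_s <= 0:
        raise PreprocessError("window_s must be positive")
    return _rolling(xy, _window_frames(window_s, fps, xy.shape[0]), "median")


def rolling_mean_smooth(xy: np.ndarray, fps: float, window_s: float = 1.0) -> np.ndarray:
    """Centered rolling mean, same windowing conventions as the despike."""
    if window_s <= 0:
        raise PreprocessError("window_s must be positive")
    return _rolling(xy, _window_frames(window_s, fps, xy.shape[0]), "mean")


def preprocess_pipeline(raw: RawDetections,
                        config: PreprocessConfig | None = None) -> CleanSequence:
    """select_best -> mask -> interpolate -> rolling median -> rolling mean."""
    config = config or PreprocessConfig()
    seq = select_best_detection(raw)
    xy, mask_log, retention, per_kp = mask_low_confidence(
        seq, config.confidence_threshold, config.mask_mode
    )
    xy = interpolate_gaps(xy, copy=False)
    xy = rolling_median_despike(xy, seq.fps, config.median_window_s)
    xy = rolling_mean_smooth(xy, seq.fps, config.mean_window_s)
    return CleanSequence(
        xy=xy,
        fps=seq.fps,
        subject_id=seq.subject_id,
        mask_log=mask_log,
        retention=retention,
        per_keypoint_retention=per_kp,
        config=config,
    )
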