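"""The preregistered 38-feature kinematic vector.

Feature layout (38 = 12 wrist + 12 ankle + 7 elbow + 7 knee):

* POSITION block, per extremity pair (wrist, ankle): five statistics per
  axis — median position, IQR position, median absolute velocity, IQR
  velocity, IQR acceleration — each computed per side then averaged
  left/right (5 stats x 2 axes = 10), plus two pair-level statistics:
  Shannon entropy of 2D endpoint speed (side-averaged), and the maximum
  lagged cross-correlation between left and right speed.
* ANGULAR block, per joint pair (elbow, knee): mean angle, stdev angle,
  median absolute angular velocity, IQR angular velocity, IQR angular
  acceleration, entropy of angle (all side-averaged), and the left/right
  angle cross-correlation.

Units: positions in torso units, velocities per second, accelerations per
second squared, angles in degrees, entropy in bits, cross-correlation
dimensionless in [0, 1]. Within each joint the canonical column order is
alphabetical by statistic name; joints are ordered wrist, ankle, elbow,
knee.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .posenorm import NormalizedSequence
from .skeleton import SkeletonConvention, COCO17


class FeatureError(ValueError):
    pass


@dataclass(frozen=True)
class FeatureConfig:
    entropy_bins: int = 50
    entropy_range_quantiles: tuple = (0.01, 0.99)
    xcorr_max_lag_s: float = 0.5


_POSITION_STATS = sorted(
    [f"{stat}_{axis}" for stat in (
        "median_position", "iqr_position", "median_abs_velocity",
        "iqr_velocity", "iqr_acceleration",
    ) for axis in ("x", "y")]
    + ["entropy_speed", "xcorr_speed"]
)
_ANGULAR_STATS = sorted([
    "mean_angle", "stdev_angle", "median_abs_angular_velocity",
    "iqr_angular_velocity", "iqr_angular_acceleration",
    "entropy_angle", "xcorr_angle",
])

_POSITION_JOINTS = ("wrist", "ankle")
_ANGULAR_JOINTS = ("elbow", "knee")

#: the 38 canonical feature names, in documented column order
FEATURE_NAMES = tuple(
    [f"{joint}_{stat}" for joint in _POSITION_JOINTS for stat in _POSITION_STATS]
    + [f"{joint}_{stat}" for joint in _ANGULAR_JOINTS for stat in _ANGULAR_STATS]
)

#: feature name -> joint group (wrist/ankle: 12 each; elbow/knee: 7 each)
FEATURE_GROUPS = {name: name.split("_", 1)[0] for name in FEATURE_NAMES}

#: the skeleton vertex triples for interior joint angles
_ANGLE_TRIPLES = {
    ("elbow", "left"): ("left_shoulder", "left_elbow", "left_wrist"),
    ("elbow", "right"): ("right_shoulder", "right_elbow", "right_wrist"),
    ("knee", "left"): ("left_hip", "left_knee", "left_ankle"),
    ("knee", "right"): ("right_hip", "right_knee", "right_ankle"),
}


@dataclass
class FeatureVector:
    subject_id: str
    values: dict  # name -> float, all 38, finite
    label: str | None = None

    def __post_init__(self) -> None:
        missing = [n for n in FEATURE_NAMES if n not in self.values]
        if missing:
            raise FeatureError(f"missing features: {missing[:5]}")
        for name in FEATURE_NAMES:
            if not np.isfinite(self.values[name]):
                raise FeatureError(f"non-finite feature: {name}")

    def as_array(self) -> np.ndarray:
        return np.array([self.values[n] for n in FEATURE_NAMES], dtype=float)


# ---------------------------------------------------------------------------
# primitive statistics
# ---------------------------------------------------------------------------


def finite_difference(signal: np.ndarray, fps: float, order: int = 1) -> np.ndarray:
    """Central-difference derivative scaled to per-second units.

    Endpoints use one-sided differences. ``order=2`` differentiates twice.
    """
    signal = np.asarray(signal, dtype=float)
    if order not in (1, 2):
        raise FeatureError("order must be 1 or 2")
    if signal.shape[0] < order + 1:
        raise FeatureError(
            f"need at least {order + 1} frames for order-{order} derivative"
        )
    out = np.gradient(signal, axis=0) * fps
    if order == 2:
        out = np.gradient(out, axis=0) * fps
    return out


def joint_angle(seq: NormalizedSequence, joint: str, side: str,
                skeleton: SkeletonConvention = COCO17) -> np.ndarray:
    """Interior angle (degrees) at the joint vertex, in [0, 180].

    Elbow: angle between elbow->shoulder and elbow->wrist; knee: hip/ankle.
    Frames with a zero-length segment get the angle linearly interpolated
    from neighboring frames.
    """
    try:
        prox_name, vertex_name, dist_name = _ANGLE_TRIPLES[(joint, side)]
    except KeyError:
        raise FeatureError(f"no angle defined for joint={joint!r} side={side!r}")
    prox = seq.xy[:, skeleton.index_of(prox_name)]
    vertex = seq.xy[:, skeleton.index_of(vertex_name)]
    dist = seq.xy[:, skeleton.index_of(dist_name)]
    u = prox - vertex
    v = dist - vertex
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    ok = (nu > 1e-12) & (nv > 1e-12)
    if ok.sum() < 2:
        raise FeatureError(f"{side} {joint}: angle undefined in nearly all frames")
    cosang = np.full(len(u), np.nan)
    cosang[ok] = np.einsum("ij,ij->i", u[ok], v[ok]) / (nu[ok] * nv[ok])
    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    if not ok.all():
        t = np.arange(len(ang))
        ang = np.interp(t, t[ok], ang[ok])
    return ang


def robust_stats(x: np.ndarray):
    """(median, IQR, mean, stdev). IQR uses linear-interpolation quantiles;
    stdev uses the n-1 denominator."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise FeatureError("robust_stats on empty series")
    if x.size == 1:
        raise FeatureError("stdev undefined for a single observation")
    q1, q3 = np.quantile(x, [0.25, 0.75])
    return float(np.median(x)), float(q3 - q1), float(np.mean(x)), float(np.std(x, ddof=1))


def shannon_entropy(x: np.ndarray, n_bins: int = 50,
                    range_quantiles: tuple = (0.01, 0.99)) -> float:
    """Binned Shannon entropy in bits over the robust [q01, q99] range.

    Values outside the range are clipped into the end bins. A constant
    series has zero entropy by definition.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise FeatureError("shannon_entropy on empty series")
    if n_bins < 2:
        raise FeatureError("n_bins must be >= 2")
    lo, hi = np.quantile(x, range_quantiles)
    # ranges below float resolution are numerically constant series
    if hi - lo <= n_bins * np.spacing(max(abs(lo), abs(hi))):
        return 0.0
    counts, _ = np.histogram(np.clip(x, lo, hi), bins=n_bins, range=(lo, hi))
    p = counts[counts > 0] / x.size
    return float(-np.sum(p * np.log2(p)))


def max_xcorr(left: np.ndarray, right: np.ndarray, fps: float,
              max_lag_s: float = 0.5):
    """Max absolute Pearson correlation between left(t) and right(t+lag).

    Lags scan integers up to round(max_lag_s * fps) in both directions;
    correlation is computed on the overlapping samples. Returns
    ``(max_correlation, best_lag_frames)``; zero-variance input gives 0.
    """
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    if left.shape != right.shape:
        raise FeatureError("left/right series must have equal length")
    max_lag = int(round(max_lag_s * fps))
    if left.size < max(2 * max_lag, 2):
        raise FeatureError(
            f"series of {left.size} frames too short for +/-{max_lag} frame lags"
        )
    def _degenerate(v):  # variance at float-noise level counts as zero
        return np.std(v) <= 1e-10 * max(1.0, float(np.max(np.abs(v))))

    best, best_lag = 0.0, 0
    for lag in range(-max_lag, max_lag + 1):
        if lag >= 0:
            a, b = left[: left.size - lag or None], right[lag:]
        else:
            a, b = left[-lag:], right[:lag]
        if a.size < 2 or _degenerate(a) or _degenerate(b):
            continue
        r = abs(float(np.corrcoef(a, b)[0, 1]))
        if r > best:
            best, best_lag = r, lag
    return best, best_lag


# ---------------------------------------------------------------------------
# the 38-feature vector
# ---------------------------------------------------------------------------


def _series_stats(pos: np.ndarray, fps: float) -> dict:
    """Per-axis stats for one endpoint track ``pos`` of shape (n, 2)."""
    vel = finite_difference(pos, fps, order=1)
    acc = finite_difference(pos, fps, order=2)
    out = {}
    for a, axis in enumerate(("x", "y")):
        out[f"median_position_{axis}"] = float(np.median(pos[:, a]))
        out[f"iqr_position_{axis}"] = _iqr(pos[:, a])
        out[f"median_abs_velocity_{axis}"] = float(np.median(np.abs(vel[:, a])))
        out[f"iqr_velocity_{axis}"] = _iqr(vel[:, a])
        out[f"iqr_acceleration_{axis}"] = _iqr(acc[:, a])
    return out


def _iqr(x: np.ndarray) -> float:
    q1, q3 = np.quantile(x, [0.25, 0.75])
    return float(q3 - q1)


def feature_vector(seq: NormalizedSequence,
                   skeleton: SkeletonConvention = COCO17,
                   config: FeatureConfig | None = None,
                   label: str | None = None) -> FeatureVector:
    """Compute the 38 canonical kinematic features from a normalized sequence."""
    config = config or FeatureConfig()
    values: dict[str, float] = {}

    for joint in _POSITION_JOINTS:
        li, ri = skeleton.joint_groups[joint]
        left_pos = seq.xy[:, li]
        right_pos = seq.xy[:, ri]
        left_stats = _series_stats(left_pos, seq.fps)
        right_stats = _series_stats(right_pos, seq.fps)
        for stat in left_stats:
            values[f"{joint}_{stat}"] = 0.5 * (left_stats[stat] + right_stats[stat])
        left_speed = np.linalg.norm(finite_difference(left_pos, seq.fps), axis=1)
        right_speed = np.linalg.norm(finite_difference(right_pos, seq.fps), axis=1)
        values[f"{joint}_entropy_speed"] = 0.5 * (
            shannon_entropy(left_speed, config.entropy_bins,
                            config.entropy_range_quantiles)
            + shannon_entropy(right_speed, config.entropy_bins,
                              config.entropy_range_quantiles)
        )
        values[f"{joint}_xcorr_speed"] = max_xcorr(
            left_speed, right_speed, seq.fps, config.xcorr_max_lag_s
        )[0]

    for joint in _ANGULAR_JOINTS:
        sides = {}
        for side in ("left", "right"):
            ang = joint_angle(seq, joint, side, skeleton)
            angvel = finite_difference(ang, seq.fps, order=1)
            angacc = finite_difference(ang, seq.fps, order=2)
            sides[side] = {
                "mean_angle": float(np.mean(ang)),
                "stdev_angle": float(np.std(ang, ddof=1)),
                "median_abs_angular_velocity": float(np.median(np.abs(angvel))),
                "iqr_angular_velocity": _iqr(angvel),
                "iqr_angular_acceleration": _iqr(angacc),
                "_angle": ang,
            }
        for stat in ("mean_angle", "stdev_angle", "median_abs_angular_velocity",
                     "iqr_angular_velocity", "iqr_angular_acceleration"):
            values[f"{joint}_{stat}"] = 0.5 * (
                sides["left"][stat] + sides["right"][stat]
            )
        values[f"{joint}_entropy_angle"] = 0.5 * (
            shannon_entropy(sides["left"]["_angle"], config.entropy_bins,
                            config.entropy_range_quantiles)
            + shannon_entropy(sides["right"]["_angle"], config.entropy_bins,
                              config.entropy_range_quantiles)
        )
        values[f"{joint}_xcorr_angle"] = max_xcorr(
            sides["left"]["_angle"], sides["right"]["_angle"],
            seq.fps, config.xcorr_max_lag_s,
        )[0]

    return FeatureVector(subject_id=seq.subject_id, values=values, label=label)


def windowed_features(seq: NormalizedSequence, window_s: float = 2.0,
                      overlap_frac: float = 0.5,
                      skeleton: SkeletonConvention = COCO17,
                      config: FeatureConfig | None = None) -> pd.DataFrame:
    """The 38 features per overlapping sliding window (rest periods included).

    Window starts are spaced ``window_s * (1 - overlap_frac)`` seconds
    apart; a trailing partial window is dropped. Rows carry window start
    and end times in seconds.
    """
    if not 0.0 <= overlap_frac < 1.0:
        raise FeatureError("overlap_frac must be in [0, 1)")
    w = int(round(window_s * seq.fps))
    if w > seq.n_frames:
        raise FeatureError(
            f"video of {seq.n_frames} frames shorter than one "
            f"{window_s}-s window ({w} frames)"
        )
    step = max(int(round(w * (1.0 - overlap_frac))), 1)
    rows = []
    for start in range(0, seq.n_frames - w + 1, step):
        sub = NormalizedSequence(
            xy=seq.xy[start:start + w], fps=seq.fps, subject_id=seq.subject_id
        )
        fv = feature_vector(sub, skeleton, config)
        row = {
            "subject_id": seq.subject_id,
            "window_start_s": start / seq.fps,
            "window_end_s": (start + w) / seq.fps,
        }
        row.update(fv.values)
        rows.append(row)
    return pd.DataFrame(rows)


def feature_table(vectors) -> pd.DataFrame:
    """Stack FeatureVectors into the canonical per-subject table."""
    rows = []
    for fv in vectors:
        row = {"subject_id": fv.subject_id, "label": fv.label or "unknown"}
        row.update({n: fv.values[n] for n in FEATURE_NAMES})
        rows.append(row)
    return pd.DataFrame(rows, columns=["subject_id", "label"] + list(FEATURE_NAMES))


def feature_dictionary() -> list:
    """Machine-readable description of every canonical feature."""
    units = {
        "median_position": "torso units", "iqr_position": "torso units",
        "median_abs_velocity": "torso units/s", "iqr_velocity": "torso units/s",
        "iqr_acceleration": "torso units/s^2", "entropy_speed": "bits",
        "xcorr_speed": "dimensionless", "mean_angle": "deg", "stdev_angle": "deg",
        "median_abs_angular_velocity": "deg/s", "iqr_angular_velocity": "deg/s",
        "iqr_angular_acceleration": "deg/s^2", "entropy_angle": "bits",
        "xcorr_angle": "dimensionless",
    }
    out = []
    for name in FEATURE_NAMES:
        joint, stat = name.split("_", 1)
        base = stat[:-2] if stat.endswith(("_x", "_y")) else stat
        out.append({
            "name": name,
            "joint_group": joint,
            "statistic": stat,
            "units": units[base],
        })
    return out
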