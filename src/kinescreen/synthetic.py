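"""Labeled synthetic keypoint cohorts with the statistical structure the
pipeline assumes.

Each subject is a supine infant skeleton whose wrist/ankle endpoints move
as band-limited sums of sinusoids (0.5-4 Hz) gated by rest bouts, with
class differences encoded along exactly the axes the kinematic features
measure: movement amplitude, oscillatory complexity (component count), and
left-right coupling. Confidence dropouts, single-frame spikes, and
occasional spurious second detections exercise the preprocessing stages.
No claim of clinical realism is made — the generator exists so every
pipeline stage is testable without patient data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.ndimage import uniform_filter1d

from .keypoint_io import Detection, RawDetections, SubjectRecord
from .skeleton import COCO17


class SynthError(ValueError):
    pass


@dataclass(frozen=True)
class ClassParams:
    """Movement regime for one class."""

    amplitude_scale: float = 1.0  # multiplies base endpoint amplitudes
    amplitude_jitter: float = 0.25  # per-subject lognormal sd of the scale
    n_components: int = 5  # oscillatory components per axis (complexity)
    freq_range: tuple = (0.5, 4.0)  # Hz
    coupling: float = 0.3  # left-right coupling in [0, 1]
    rest_fraction: float = 0.2  # fraction of time in rest bouts

    def __post_init__(self) -> None:
        if self.amplitude_scale < 0:
            raise SynthError("amplitude_scale must be >= 0")
        if not 0.0 <= self.coupling <= 1.0:
            raise SynthError("coupling must be in [0, 1]")
        if not 0.0 <= self.rest_fraction <= 1.0:
            raise SynthError("rest_fraction must be in [0, 1]")
        if self.n_components < 1:
            raise SynthError("n_components must be >= 1")


#: typical-movement (FM+) regime
TYPICAL_PARAMS = ClassParams()
#: reduced-complexity / reduced-variance regime for the positive (FM-) class
RISK_PARAMS = ClassParams(
    amplitude_scale=0.45, n_components=2, coupling=0.7, rest_fraction=0.5
)


def blend_params(effect_size: float,
                 typical: ClassParams = TYPICAL_PARAMS,
                 risk: ClassParams = RISK_PARAMS) -> ClassParams:
    """Interpolate the risk regime toward the typical one.

    ``effect_size=0`` makes the classes indistinguishable (null cohort);
    ``effect_size=1`` gives the full default separation.
    """
    t = float(effect_size)
    return ClassParams(
        amplitude_scale=(1 - t) * typical.amplitude_scale + t * risk.amplitude_scale,
        amplitude_jitter=typical.amplitude_jitter,
        n_components=int(round((1 - t) * typical.n_components + t * risk.n_components)),
        freq_range=typical.freq_range,
        coupling=(1 - t) * typical.coupling + t * risk.coupling,
        rest_fraction=(1 - t) * typical.rest_fraction + t * risk.rest_fraction,
    )


@dataclass(frozen=True)
class NoiseParams:
    jitter_sd_px: float = 1.0
    confidence_base: float = 0.95
    confidence_sd: float = 0.02
    dropout_prob: float = 0.03  # per (frame, keypoint): c drawn from U(0.2, 0.7)
    spike_prob: float = 0.002  # per (frame, keypoint) single-frame excursion
    spike_magnitude_px: float = 120.0
    spurious_detection_prob: float = 0.05  # per frame, low-score second instance


@dataclass(frozen=True)
class SynthConfig:
    n_subjects: int = 100
    prevalence: float = 0.11
    fps_choices: tuple = (15.0, 30.0, 120.0)
    fps_weights: tuple = (0.003, 0.990, 0.007)
    duration_range_s: tuple = (60.0, 120.0)
    resolution: tuple = (1280, 720)
    effect_size: float = 1.0
    typical_params: ClassParams = TYPICAL_PARAMS
    noise: NoiseParams = field(default_factory=NoiseParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.prevalence <= 1.0:
            raise SynthError("prevalence must be in [0, 1]")
        if self.duration_range_s[0] > self.duration_range_s[1]:
            raise SynthError("duration_range_s must be (lo, hi)")
        if abs(sum(self.fps_weights) - 1.0) > 1e-9:
            raise SynthError("fps_weights must sum to 1")

    def risk_params(self) -> ClassParams:
        return blend_params(self.effect_size, self.typical_params)


@dataclass
class SynthCohort:
    subjects: list  # list of (RawDetections, SubjectRecord)
    ground_truth: dict  # subject_id -> true generator parameter draws
    config: SynthConfig


# supine base skeleton, pixels, head toward small y (image "up")
_BASE_POSE = np.array([
    [0, -200],            # nose
    [-10, -208], [10, -208],   # eyes
    [-22, -205], [22, -205],   # ears
    [-55, -150], [55, -150],   # shoulders
    [-95, -110], [95, -110],   # elbows (rest)
    [-120, -65], [120, -65],   # wrists (rest)
    [-40, 0], [40, 0],         # hips
    [-60, 80], [60, 80],       # knees (rest)
    [-70, 160], [70, 160],     # ankles (rest)
], dtype=float)

_BASE_AMPLITUDE_PX = {"wrist": 32.0, "ankle": 26.0}
_SEGMENT_BEND_FRAC = {"elbow": 0.30, "knee": 0.28}
_LIMB_CHAIN = {
    # endpoint group -> (proximal anchor L, R), (mid joint L, R)
    "wrist": ((5, 6), (7, 8)),
    "ankle": ((11, 12), (13, 14)),
}


def _band_limited_offsets(n: int, fps: float, params: ClassParams,
                          amp_px: float, rng) -> np.ndarray:
    """(n, 2) endpoint displacement: sum of K sinusoids + low-pass noise."""
    t = np.arange(n) / fps
    out = np.zeros((n, 2))
    for axis in range(2):
        freqs = rng.uniform(*params.freq_range, size=params.n_components)
        phases = rng.uniform(0, 2 * np.pi, size=params.n_components)
        amps = rng.uniform(0.4, 1.0, size=params.n_components)
        amps *= amp_px / np.sqrt(np.sum(amps**2))
        for f, p, a in zip(freqs, phases, amps):
            out[:, axis] += a * np.sin(2 * np.pi * f * t + p)
        noise = rng.normal(0, 0.15 * amp_px, size=n)
        out[:, axis] += uniform_filter1d(noise, size=max(int(fps / 4), 1))
    return out


def _rest_envelope(n: int, fps: float, rest_fraction: float, rng) -> np.ndarray:
    """Smooth 0..1 gating signal spending ~rest_fraction of time near 0."""
    if rest_fraction <= 0:
        return np.ones(n)
    gate = (rng.random(n) > rest_fraction).astype(float)
    # hold bouts for ~2 s, then smooth the edges
    hold = max(int(2 * fps), 1)
    idx = (np.arange(n) // hold) * hold
    gate = gate[np.minimum(idx, n - 1)]
    return uniform_filter1d(gate, size=max(int(fps / 2), 1))


def generate_subject(params: ClassParams, fps: float, duration_s: float,
                     seed: int, resolution: tuple = (1280, 720),
                     noise: NoiseParams = NoiseParams(),
                     subject_id: str = "synth") -> tuple:
    """One subject's RawDetections plus the ground-truth parameter draws."""
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fps))
    if n < 2:
        raise SynthError("duration too short")
    width, height = resolution

    amp_factor = float(np.exp(rng.normal(0, params.amplitude_jitter)))
    true_amplitude = params.amplitude_scale * amp_factor

    center = np.array([width / 2.0, height / 2.0])
    xy = np.broadcast_to(_BASE_POSE + center, (n, 17, 2)).copy()

    envelope = _rest_envelope(n, fps, params.rest_fraction, rng)
    for group, ((anchor_l, anchor_r), (mid_l, mid_r)) in _LIMB_CHAIN.items():
        amp = _BASE_AMPLITUDE_PX[group] * true_amplitude
        off_l = _band_limited_offsets(n, fps, params, amp, rng)
        off_ind = _band_limited_offsets(n, fps, params, amp, rng)
        # mirrored copy of the left signal, blended with an independent one
        mirror = off_l * np.array([-1.0, 1.0])
        c = params.coupling
        off_r = c * mirror + np.sqrt(max(1.0 - c**2, 0.0)) * off_ind
        end_l, end_r = COCO17.joint_groups[group]
        xy[:, end_l] += off_l * envelope[:, None]
        xy[:, end_r] += off_r * envelope[:, None]
        # mid joint: midpoint of anchor->endpoint plus an outward bend
        bend = _SEGMENT_BEND_FRAC["elbow" if group == "wrist" else "knee"]
        for anchor, mid, end, sign in ((anchor_l, mid_l, end_l, -1.0),
                                       (anchor_r, mid_r, end_r, 1.0)):
            seg = xy[:, end] - xy[:, anchor]
            perp = np.stack([-seg[:, 1], seg[:, 0]], axis=1) * sign
            xy[:, mid] = xy[:, anchor] + 0.5 * seg + bend * perp

    xy += rng.normal(0, noise.jitter_sd_px, size=xy.shape)

    conf = np.clip(
        rng.normal(noise.confidence_base, noise.confidence_sd, size=(n, 17)), 0, 1
    )
    dropouts = rng.random((n, 17)) < noise.dropout_prob
    conf[dropouts] = rng.uniform(0.2, 0.7, size=int(dropouts.sum()))
    spikes = rng.random((n, 17)) < noise.spike_prob
    angles = rng.uniform(0, 2 * np.pi, size=int(spikes.sum()))
    xy[spikes] += noise.spike_magnitude_px * np.stack(
        [np.cos(angles), np.sin(angles)], axis=1
    )

    frames = []
    spurious = rng.random(n) < noise.spurious_detection_prob
    for tdx in range(n):
        kp = np.concatenate([xy[tdx], conf[tdx, :, None]], axis=1)
        dets = [Detection(keypoints=kp, score=float(np.mean(conf[tdx])))]
        if spurious[tdx]:
            ghost = kp.copy()
            ghost[:, :2] += rng.normal(0, 60, size=(17, 2))
            ghost[:, 2] = rng.uniform(0.1, 0.4, size=17)
            dets.append(Detection(keypoints=ghost, score=float(np.mean(ghost[:, 2]))))
        frames.append(dets)

    raw = RawDetections(frames=frames, fps=fps, resolution=tuple(resolution),
                        subject_id=subject_id)
    truth = {
        "amplitude_scale": true_amplitude,
        "n_components": params.n_components,
        "coupling": params.coupling,
        "rest_fraction": params.rest_fraction,
        "fps": fps,
        "duration_s": duration_s,
        "seed": seed,
        "n_dropout_cells": int(dropouts.sum()),
        "n_spike_cells": int(spikes.sum()),
    }
    return raw, truth


def generate_cohort(config: SynthConfig) -> SynthCohort:
    """A labeled cohort: Bernoulli(prevalence) class draws, seeded fan-out."""
    master = np.random.default_rng(config.seed)
    risk = config.risk_params()
    subjects = []
    truth = {}
    for i in range(config.n_subjects):
        child_seed = int(master.integers(2**63))
        rng = np.random.default_rng(child_seed)
        positive = rng.random() < config.prevalence
        params = risk if positive else config.typical_params
        fps = float(rng.choice(config.fps_choices, p=config.fps_weights))
        duration = float(rng.uniform(*config.duration_range_s))
        sid = f"synth{i:05d}"
        raw, t = generate_subject(
            params, fps, duration, seed=int(rng.integers(2**63)),
            resolution=config.resolution, noise=config.noise, subject_id=sid,
        )
        label = "FM_minus" if positive else "FM_plus"
        sex = "F" if rng.random() < 0.55 else "M"
        subjects.append((raw, SubjectRecord(sid, label, {"sex": sex})))
        t["label"] = label
        t["params"] = asdict(params)
        truth[sid] = t
    return SynthCohort(subjects=subjects, ground_truth=truth, config=config)
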