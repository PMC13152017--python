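import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from kinescreen import features as ft
from kinescreen.posenorm import NormalizedSequence, head_up_normalize
from kinescreen.preprocess import CleanSequence
from kinescreen.skeleton import COCO17


def norm_seq(xy, fps=30.0):
    return NormalizedSequence(xy=xy, fps=fps, subject_id="s")


# --- independent oracles -------------------------------------------------

def diff_oracle(x, fps):
    """Hand-coded central difference with one-sided endpoints."""
    n = len(x)
    out = np.empty(n)
    out[0] = (x[1] - x[0]) * fps
    out[-1] = (x[-1] - x[-2]) * fps
    for i in range(1, n - 1):
        out[i] = (x[i + 1] - x[i - 1]) / 2.0 * fps
    return out


def angle_oracle(p, v, d):
    """Interior angle at v via atan2 of the two segment directions."""
    a1 = np.arctan2(p[1] - v[1], p[0] - v[0])
    a2 = np.arctan2(d[1] - v[1], d[0] - v[0])
    ang = np.degrees(abs(a1 - a2)) % 360.0
    return 360.0 - ang if ang > 180.0 else ang


def entropy_oracle(x, n_bins=50):
    lo, hi = np.quantile(x, [0.01, 0.99])
    if hi <= lo:
        return 0.0
    edges = np.linspace(lo, hi, n_bins + 1)
    counts = np.zeros(n_bins)
    for xi in np.clip(x, lo, hi):
        b = min(int((xi - lo) / (hi - lo) * n_bins), n_bins - 1)
        counts[b] += 1
    p = counts[counts > 0] / len(x)
    return -np.sum(p * np.log2(p))


class TestFiniteDifference:
    def test_constant_zero(self):
        assert np.allclose(ft.finite_difference(np.full(50, 3.0), 30.0), 0.0)

    def test_linear_slope(self):
        fps = 30.0
        x = 2.0 * np.arange(100) / fps
        np.testing.assert_allclose(ft.finite_difference(x, fps), 2.0)

    def test_matches_oracle(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=77)
        np.testing.assert_allclose(ft.finite_difference(x, 25.0), diff_oracle(x, 25.0))

    def test_second_order_of_quadratic(self):
        fps = 30.0
        t = np.arange(200) / fps
        np.testing.assert_allclose(
            ft.finite_difference(3.0 * t**2, fps, order=2)[2:-2], 6.0, rtol=1e-9
        )

    def test_too_short_errors(self):
        with pytest.raises(ft.FeatureError):
            ft.finite_difference(np.array([1.0]), 30.0)


class TestJointAngle:
    def _seq_with_triple(self, joint, side, p, v, d, n=5):
        xy = np.zeros((n, 17, 2))
        names = {("elbow", "left"): ("left_shoulder", "left_elbow", "left_wrist"),
                 ("elbow", "right"): ("right_shoulder", "right_elbow", "right_wrist"),
                 ("knee", "left"): ("left_hip", "left_knee", "left_ankle"),
                 ("knee", "right"): ("right_hip", "right_knee", "right_ankle")}[(joint, side)]
        for name, pt in zip(names, (p, v, d)):
            xy[:, COCO17.index_of(name)] = pt
        return norm_seq(xy)

    def test_collinear_180(self):
        seq = self._seq_with_triple("elbow", "left", (0, 0), (1, 0), (2, 0))
        np.testing.assert_allclose(ft.joint_angle(seq, "elbow", "left"), 180.0)

    def test_perpendicular_90(self):
        seq = self._seq_with_triple("knee", "right", (0, 1), (0, 0), (1, 0))
        np.testing.assert_allclose(ft.joint_angle(seq, "knee", "right"), 90.0)

    def test_random_triples_match_atan2_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            p, v, d = rng.normal(size=(3, 2))
            seq = self._seq_with_triple("elbow", "right", p, v, d)
            got = ft.joint_angle(seq, "elbow", "right")[0]
            assert got == pytest.approx(angle_oracle(p, v, d), abs=1e-9)

    def test_zero_length_segment_interpolated(self):
        xy = np.zeros((3, 17, 2))
        xy[:, COCO17.index_of("left_shoulder")] = (0, 1)
        xy[:, COCO17.index_of("left_wrist")] = (1, 0)
        # frame 1: wrist collapses onto the elbow -> undefined, interpolated
        xy[1, COCO17.index_of("left_wrist")] = (0, 0)
        ang = ft.joint_angle(norm_seq(xy), "elbow", "left")
        assert ang[1] == pytest.approx(0.5 * (ang[0] + ang[2]))


class TestRobustStats:
    def test_closed_form(self):
        m, iqr, mean, sd = ft.robust_stats(np.array([1.0, 2, 3, 4, 5]))
        assert (m, iqr, mean) == (3.0, 2.0, 3.0)

    def test_constant(self):
        m, iqr, mean, sd = ft.robust_stats(np.full(10, 7.0))
        assert iqr == 0.0 and sd == 0.0

    def test_matches_sort_based_oracle(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=101)
        m, iqr, mean, sd = ft.robust_stats(x)
        s = np.sort(x)
        # linear-interpolation quantile oracle on the sorted sample
        def q(p):
            h = p * (len(s) - 1)
            lo = int(np.floor(h))
            return s[lo] + (h - lo) * (s[min(lo + 1, len(s) - 1)] - s[lo])
        assert m == pytest.approx(q(0.5), rel=1e-12)
        assert iqr == pytest.approx(q(0.75) - q(0.25), rel=1e-12)
        assert sd == pytest.approx(np.sqrt(np.sum((x - x.mean())**2) / (len(x) - 1)))

    def test_single_value_errors(self):
        with pytest.raises(ft.FeatureError):
            ft.robust_stats(np.array([1.0]))


class TestShannonEntropy:
    def test_constant_zero(self):
        assert ft.shannon_entropy(np.full(100, 2.5)) == 0.0

    def test_uniform_bins_max_entropy(self):
        # exactly 20 samples per bin across 50 bins, quantile range == full range
        x = np.repeat(np.arange(50) + 0.5, 20)
        got = ft.shannon_entropy(x, n_bins=50, range_quantiles=(0.0, 1.0))
        assert got == pytest.approx(np.log2(50), rel=1e-9)

    def test_matches_oracle(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=500)
        assert ft.shannon_entropy(x) == pytest.approx(entropy_oracle(x), rel=1e-9)

    @given(st.integers(0, 10_000))
    @settings(max_examples=20, deadline=None)
    def test_nonnegative(self, seed):
        x = np.random.default_rng(seed).normal(size=64)
        assert ft.shannon_entropy(x) >= 0.0


class TestMaxXcorr:
    def test_identical_signals(self):
        x = np.sin(np.linspace(0, 20, 300))
        r, lag = ft.max_xcorr(x, x, fps=30.0)
        assert r == pytest.approx(1.0)
        assert lag == 0

    def test_sign_flip_absolute(self):
        x = np.sin(np.linspace(0, 20, 300))
        r, _ = ft.max_xcorr(x, -x, fps=30.0)
        assert r == pytest.approx(1.0)

    def test_shifted_sinusoid_recovers_lag(self):
        fps = 30.0
        t = np.arange(600) / fps
        x = np.sin(2 * np.pi * 1.0 * t)
        shift = int(0.2 * fps)
        y = np.roll(x, -shift)
        r, lag = ft.max_xcorr(x, y, fps, max_lag_s=0.5)
        assert r >= 0.999
        assert abs(lag) == shift

    def test_zero_variance_gives_zero(self):
        r, _ = ft.max_xcorr(np.zeros(100), np.ones(100), fps=30.0)
        assert r == 0.0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=(2, 120))
        fps = 30.0
        r, lag = ft.max_xcorr(x, y, fps, max_lag_s=0.5)
        best = 0.0
        for l in range(-15, 16):
            if l >= 0:
                a, b = x[: len(x) - l], y[l:]
            else:
                a, b = x[-l:], y[: l]
            best = max(best, abs(np.corrcoef(a, b)[0, 1]))
        assert r == pytest.approx(best, rel=1e-12)


class TestFeatureVector:
    def test_exact_38_with_group_counts(self, small_norm_seq):
        fv = ft.feature_vector(small_norm_seq)
        assert len(fv.values) == 38
        counts = {}
        for name in fv.values:
            counts[ft.FEATURE_GROUPS[name]] = counts.get(ft.FEATURE_GROUPS[name], 0) + 1
        assert counts == {"wrist": 12, "ankle": 12, "elbow": 7, "knee": 7}

    def test_static_pose_zeros(self):
        rng = np.random.default_rng(5)
        pose = rng.normal(size=(17, 2))
        pose[5:] *= 3  # keep segments non-degenerate
        xy = np.broadcast_to(pose, (200, 17, 2)).copy()
        fv = ft.feature_vector(norm_seq(xy))
        for name, v in fv.values.items():
            if "iqr_velocity" in name or "iqr_acceleration" in name or "entropy" in name:
                assert v == 0.0, name
            if "xcorr" in name:
                assert v == 0.0, name

    def test_amplitude_monotonicity(self):
        from kinescreen import preprocess, synthetic
        from kinescreen.posenorm import head_up_normalize

        vals = {}
        for amp in (0.5, 1.0):
            params = synthetic.ClassParams(amplitude_scale=amp, amplitude_jitter=0.0,
                                           rest_fraction=0.0)
            raw, _ = synthetic.generate_subject(params, 30.0, 20.0, seed=9)
            norm = head_up_normalize(preprocess.preprocess_pipeline(raw))
            vals[amp] = ft.feature_vector(norm).values
        for name in ft.FEATURE_NAMES:
            if "iqr_velocity" in name:
                assert vals[1.0][name] > vals[0.5][name], name

    def test_left_right_swap_invariance(self, small_norm_seq):
        fv = ft.feature_vector(small_norm_seq)
        perm = COCO17.swap_left_right_indices()
        swapped = NormalizedSequence(xy=small_norm_seq.xy[:, perm, :],
                                     fps=small_norm_seq.fps, subject_id="s")
        fv_sw = ft.feature_vector(swapped)
        for name in ft.FEATURE_NAMES:
            assert fv_sw.values[name] == pytest.approx(fv.values[name], rel=1e-9), name

    def test_similarity_invariance_through_normalization(self):
        from kinescreen.posenorm import head_up_normalize
        from kinescreen import preprocess, synthetic

        raw, _ = synthetic.generate_subject(
            synthetic.TYPICAL_PARAMS, 30.0, 15.0, seed=17,
            noise=synthetic.NoiseParams(jitter_sd_px=0.0, dropout_prob=0.0,
                                        spike_prob=0.0, spurious_detection_prob=0.0),
        )
        clean = preprocess.preprocess_pipeline(raw)
        ref = ft.feature_vector(head_up_normalize(clean)).values
        angle, scale, shift = 1.1, 2.7, np.array([300.0, -40.0])
        c, s = np.cos(angle), np.sin(angle)
        rot = np.array([[c, -s], [s, c]])
        xy_t = scale * clean.xy @ rot.T + shift
        clean_t = preprocess.CleanSequence(xy=xy_t, fps=clean.fps, subject_id="s")
        got = ft.feature_vector(head_up_normalize(clean_t)).values
        for name in ft.FEATURE_NAMES:
            assert got[name] == pytest.approx(ref[name], rel=1e-6, abs=1e-9), name

    def test_fps_resampling_robustness(self):
        # band-limited analytic trajectory sampled at 30 and 120 FPS
        def build(fps, duration=40.0):
            n = int(duration * fps)
            t = np.arange(n) / fps
            xy = np.zeros((n, 17, 2))
            base = np.array([
                [0, -200], [-10, -208], [10, -208], [-22, -205], [22, -205],
                [-55, -150], [55, -150], [-95, -110], [95, -110],
                [-120, -65], [120, -65], [-40, 0], [40, 0],
                [-60, 80], [60, 80], [-70, 160], [70, 160],
            ], dtype=float)
            xy += base
            # mirrored left/right drive keeps the bilateral features stable
            for kl, kr, (fx, fy) in ((9, 10, (0.7, 1.1)), (15, 16, (0.5, 1.2))):
                ox = 30 * np.sin(2 * np.pi * fx * t)
                oy = 25 * np.sin(2 * np.pi * fy * t + 1.0)
                xy[:, kl, 0] += ox
                xy[:, kl, 1] += oy
                xy[:, kr, 0] -= ox
                xy[:, kr, 1] += oy
            for anchor, mid, end, sign in ((5, 7, 9, -1), (6, 8, 10, 1),
                                           (11, 13, 15, -1), (12, 14, 16, 1)):
                seg = xy[:, end] - xy[:, anchor]
                perp = np.stack([-seg[:, 1], seg[:, 0]], axis=1) * sign
                xy[:, mid] = xy[:, anchor] + 0.5 * seg + 0.3 * perp
            return ft.feature_vector(norm_seq(xy, fps=fps)).values

        f30 = build(30.0)
        f120 = build(120.0)
        for name in ft.FEATURE_NAMES:
            if abs(f30[name]) < 1e-9 and abs(f120[name]) < 1e-9:
                continue
            rel = abs(f120[name] - f30[name]) / max(abs(f30[name]), abs(f120[name]))
            assert rel <= 0.05, (name, f30[name], f120[name])

    def test_non_finite_feature_named(self):
        with pytest.raises(ft.FeatureError, match="wrist"):
            ft.FeatureVector("s", {n: (np.nan if n == "wrist_xcorr_speed" else 1.0)
                                   for n in ft.FEATURE_NAMES})


class TestWindowedFeatures:
    def test_window_count_10s(self):
        xy = np.random.default_rng(0).normal(size=(300, 17, 2)) * 0.1
        xy += _spread_pose()
        table = ft.windowed_features(norm_seq(xy), window_s=2.0, overlap_frac=0.5)
        assert len(table) == 9  # floor((10 - 2) / 1) + 1

    def test_window_count_formula_random_durations(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            dur = rng.uniform(4.0, 12.0)
            n = int(round(dur * 30))
            xy = rng.normal(size=(n, 17, 2)) * 0.1 + _spread_pose()
            table = ft.windowed_features(norm_seq(xy), 2.0, 0.5)
            w, step = 60, 30
            expected = (n - w) // step + 1
            assert len(table) == expected

    def test_stationary_windows_approximate_whole_video(self):
        rng = np.random.default_rng(2)
        n = 1800
        t = np.arange(n) / 30.0
        xy = np.zeros((n, 17, 2)) + _spread_pose()
        xy[:, 9, 0] += np.sin(2 * np.pi * 2.0 * t)
        whole = ft.feature_vector(norm_seq(xy)).values
        table = ft.windowed_features(norm_seq(xy), 2.0, 0.5)
        med = table["wrist_median_abs_velocity_x"].mean()
        assert med == pytest.approx(whole["wrist_median_abs_velocity_x"], rel=0.15)

    def test_too_short_video_errors(self):
        xy = np.zeros((30, 17, 2)) + _spread_pose()
        with pytest.raises(ft.FeatureError, match="shorter"):
            ft.windowed_features(norm_seq(xy), window_s=2.0)


def _spread_pose():
    rng = np.random.default_rng(99)
    pose = rng.normal(size=(17, 2)) * 2
    return pose


class TestFeatureDictionary:
    def test_covers_all_38(self):
        d = ft.feature_dictionary()
        assert [e["name"] for e in d] == list(ft.FEATURE_NAMES)
        assert all(e["units"] for e in d)
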