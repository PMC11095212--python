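"""Gaussian-kernel smoothing and finite-difference velocity estimation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oncomotion import (
    AcquisitionMeta,
    KernelSpec,
    compute_kinematics,
    estimate_velocity,
    gaussian_kernel,
    segment_trajectory,
    smooth_trajectory,
    speed_summary,
)

from conftest import make_track


def brute_force_smooth(x, sigma, stencil):
    """Independent O(n·m) double-loop oracle: renormalized truncated kernel."""
    h = (stencil - 1) // 2
    out = np.empty_like(x, dtype=float)
    for i in range(len(x)):
        num = den = 0.0
        for k in range(-h, h + 1):
            j = i + k
            if 0 <= j < len(x):
                w = math.exp(-(k**2) / (2 * sigma**2))
                num += w * x[j]
                den += w
        out[i] = num / den
    return out


class TestSmoothing:
    def test_constant_track_unchanged(self):
        t = make_track(0, np.full(20, 5.0), np.full(20, -3.0))
        s = smooth_trajectory(t, KernelSpec(2, 9))
        np.testing.assert_allclose(s.x_um, t.x_um, atol=1e-12)
        np.testing.assert_allclose(s.y_um, t.y_um, atol=1e-12)

    def test_affine_track_unchanged_in_interior(self):
        n = 30
        t = make_track(0, 2.0 + 0.7 * np.arange(n), 1.0 - 0.3 * np.arange(n))
        s = smooth_trajectory(t, KernelSpec(2, 9))
        np.testing.assert_allclose(s.x_um[4:-4], t.x_um[4:-4], atol=1e-9)
        np.testing.assert_allclose(s.y_um[4:-4], t.y_um[4:-4], atol=1e-9)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 10, 15)
        y = rng.normal(0, 10, 15)
        s = smooth_trajectory(make_track(0, x, y), KernelSpec(2, 9))
        np.testing.assert_allclose(s.x_um, brute_force_smooth(x, 2, 9), atol=1e-12)
        np.testing.assert_allclose(s.y_um, brute_force_smooth(y, 2, 9), atol=1e-12)

    def test_kernel_weights_sum_to_one(self):
        for sigma, m in ((0.5, 3), (2, 9), (4, 21)):
            assert gaussian_kernel(KernelSpec(sigma, m)).sum() == pytest.approx(1.0, abs=1e-12)

    @given(st.integers(min_value=5, max_value=40), st.integers(min_value=0, max_value=10**6))
    @settings(max_examples=30, deadline=None)
    def test_smoothing_stays_in_stencil_hull(self, n, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 50, n)
        s = smooth_trajectory(make_track(0, x, np.zeros(n)), KernelSpec(2, 9))
        h = 4
        for i in range(n):
            win = x[max(0, i - h): i + h + 1]
            assert win.min() - 1e-9 <= s.x_um[i] <= win.max() + 1e-9

    def test_invalid_kernel_rejected(self):
        with pytest.raises(ValueError):
            KernelSpec(0.0, 9)
        with pytest.raises(ValueError):
            KernelSpec(2.0, 8)


class TestVelocity:
    def test_straight_line_closed_form(self, meta):
        # 10 µm per 30-min frame step -> 20 µm/h along +x
        m = AcquisitionMeta(frame_interval_min=30.0)
        t = make_track(0, 10.0 * np.arange(10), np.zeros(10), interval=30.0)
        df = estimate_velocity(t, m)
        np.testing.assert_allclose(df.speed_um_per_h, 20.0, atol=1e-9)
        np.testing.assert_allclose(df.theta_rad, 0.0, atol=1e-12)

    def test_circular_track_tangent_speed(self):
        # radius r at angular rate w rad/min: speed ~ r*w within O(dt^2)
        r, w, dt = 50.0, 0.01, 10.0
        m = AcquisitionMeta(frame_interval_min=dt)
        frames = np.arange(40)
        ang = w * dt * frames
        t = make_track(0, r * np.cos(ang), r * np.sin(ang), interval=dt)
        df = estimate_velocity(t, m)
        expected = r * w * 60.0
        interior = df.speed_um_per_h.iloc[1:-1]
        assert np.allclose(interior, expected, rtol=(w * dt) ** 2)

    def test_stationary_track_flagged(self, meta):
        df = estimate_velocity(make_track(0, np.zeros(10), np.zeros(10)), meta)
        assert (df.speed_um_per_h == 0).all()
        assert df.theta_rad.isna().all()

    def test_rotation_equivariance(self, meta):
        rng = np.random.default_rng(11)
        x, y = rng.normal(0, 20, (2, 25))
        phi = 0.77
        c, s = math.cos(phi), math.sin(phi)
        a = estimate_velocity(make_track(0, x, y), meta)
        b = estimate_velocity(make_track(0, c * x - s * y, s * x + c * y), meta)
        np.testing.assert_allclose(b.vx, c * a.vx - s * a.vy, atol=1e-9)
        np.testing.assert_allclose(b.vy, s * a.vx + c * a.vy, atol=1e-9)
        dtheta = np.mod(b.theta_rad - a.theta_rad - phi + np.pi, 2 * np.pi) - np.pi
        np.testing.assert_allclose(dtheta, 0.0, atol=1e-9)

    def test_bridged_gap_uses_actual_time(self, meta):
        # one missed frame: central difference spans 3 frame intervals
        t = make_track(0, [0.0, 10.0, 30.0], [0, 0, 0], frames=[0, 1, 3])
        df = estimate_velocity(t, meta)
        assert df.vx.iloc[1] == pytest.approx((30.0 - 0.0) / 30.0 * 60.0)


class TestSegmentation:
    def test_bridge1_keeps_single_frame_gap(self):
        t = make_track(0, np.arange(12.0), np.zeros(12),
                       frames=[0, 1, 2, 3, 4, 6, 7, 8, 9, 10, 11, 12])
        assert len(segment_trajectory(t, "bridge1")) == 1

    def test_long_gap_splits(self):
        t = make_track(0, np.arange(12.0), np.zeros(12),
                       frames=[0, 1, 2, 3, 4, 9, 10, 11, 12, 13, 14, 15])
        segs = segment_trajectory(t, "bridge1")
        assert [len(s) for s in segs] == [5, 7]

    def test_split_policy_splits_any_gap(self):
        t = make_track(0, np.arange(6.0), np.zeros(6), frames=[0, 1, 2, 4, 5, 6])
        segs = segment_trajectory(t, "split", min_points=2)
        assert [len(s) for s in segs] == [3, 3]


class TestSpeedSummary:
    def test_constant_speeds(self):
        s = speed_summary([7.5] * 8)
        assert s["mean"] == pytest.approx(7.5) and s["sd"] == 0.0

    def test_two_point_mean(self):
        assert speed_summary([5.0, 15.0])["mean"] == pytest.approx(10.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            speed_summary([])

    def test_pooled_mean_batch_invariant(self):
        rng = np.random.default_rng(5)
        v = rng.lognormal(2, 0.5, 1000)
        whole = speed_summary(v)["mean"]
        parts = np.concatenate([v[:300], v[300:]])
        assert speed_summary(parts)["mean"] == pytest.approx(whole, rel=1e-12)

    def test_lognormal_mean_recovery(self):
        # generator-style lognormal with mean 12: sample mean within 3 SE
        rng = np.random.default_rng(99)
        cv = 0.3
        s2 = math.log1p(cv**2)
        v = rng.lognormal(math.log(12) - s2 / 2, math.sqrt(s2), 10_000)
        s = speed_summary(v)
        se = s["sd"] / math.sqrt(s["n"])
        assert abs(s["mean"] - 12.0) < 3 * se


class TestComputeKinematics:
    def test_pipeline_stage_counts(self, meta):
        rng = np.random.default_rng(2)
        tracks = [
            make_track(i, rng.normal(0, 5, 15).cumsum(), rng.normal(0, 5, 15).cumsum())
            for i in range(4)
        ]
        df = compute_kinematics(tracks, meta, min_points=10)
        assert len(df) == 4 * 15
        assert set(df.track_id) == {0, 1, 2, 3}
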