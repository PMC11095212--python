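"""Focal-frame pair construction and binned spatial statistics."""

import math

import numpy as np
import pandas as pd
import pytest

from oncomotion import (
    build_pairs,
    mean_cell_radius,
    nematic_correlation_map,
    polar_correlation_map,
    relative_position_map,
    velocity_heatmap,
)


def frame_df(rows):
    """rows: (track_id, frame, x, y, theta)"""
    df = pd.DataFrame(rows, columns=["track_id", "frame", "x_um", "y_um", "theta_rad"])
    df["vx"] = 10 * np.cos(df.theta_rad)
    df["vy"] = 10 * np.sin(df.theta_rad)
    df["speed_um_per_h"] = 10.0
    return df


class TestBuildPairs:
    def test_neighbor_directly_ahead(self):
        df = frame_df([(0, 0, 0.0, 0.0, 0.0), (1, 0, 10.0, 0.0, 0.0)])
        pairs = build_pairs(df, 50)
        row = pairs[pairs.focal_id == 0].iloc[0]
        assert row.rel_front_um == pytest.approx(10.0, abs=1e-12)
        assert row.rel_left_um == pytest.approx(0.0, abs=1e-12)

    def test_rotation_equivariance_of_frame(self):
        # focal heading +y, neighbor displaced +y: still directly ahead
        df = frame_df([(0, 0, 0.0, 0.0, math.pi / 2), (1, 0, 0.0, 10.0, math.pi / 2)])
        row = build_pairs(df, 50).iloc[0]
        assert row.rel_front_um == pytest.approx(10.0, abs=1e-12)
        assert row.rel_left_um == pytest.approx(0.0, abs=1e-12)

    def test_left_is_heading_rotated_plus_90(self):
        # focal heading +x; neighbor at +y = mathematical left
        df = frame_df([(0, 0, 0.0, 0.0, 0.0), (1, 0, 0.0, 7.0, 0.0)])
        row = build_pairs(df, 50)[lambda d: d.focal_id == 0].iloc[0]
        assert row.rel_left_um == pytest.approx(7.0, abs=1e-12)

    def test_ordered_pair_count(self):
        df = frame_df([(i, 0, 10.0 * i, 0.0, 0.0) for i in range(3)])
        assert len(build_pairs(df, 1000)) == 6

    def test_rmax_cut_and_no_self_pairs(self):
        df = frame_df([(0, 0, 0.0, 0.0, 0.0), (1, 0, 100.0, 0.0, 0.0)])
        assert len(build_pairs(df, 50)) == 0
        assert len(build_pairs(df, 150)) == 2

    def test_pair_antisymmetry(self):
        rng = np.random.default_rng(4)
        rows = [(i, 0, *rng.uniform(0, 100, 2), rng.uniform(-math.pi, math.pi)) for i in range(6)]
        pairs = build_pairs(frame_df(rows), 1000)
        assert len(pairs) % 2 == 0
        ab = pairs.set_index(["focal_id", "neighbor_id"])
        for (i, j), row in ab.iterrows():
            rev = ab.loc[(j, i)]
            assert rev.dtheta_rad == pytest.approx(-row.dtheta_rad, abs=1e-12)
            # separation length is frame-independent
            assert math.hypot(rev.rel_front_um, rev.rel_left_um) == pytest.approx(
                math.hypot(row.rel_front_um, row.rel_left_um), abs=1e-9
            )

    def test_undefined_headings_excluded(self):
        df = frame_df([(0, 0, 0.0, 0.0, 0.0), (1, 0, 5.0, 0.0, np.nan)])
        assert len(build_pairs(df, 50)) == 0

    def test_separate_frames_do_not_pair(self):
        df = frame_df([(0, 0, 0.0, 0.0, 0.0), (1, 1, 5.0, 0.0, 0.0)])
        assert len(build_pairs(df, 50)) == 0


def synthetic_pairs(dthetas, fronts, lefts):
    return pd.DataFrame(
        {
            "focal_id": range(len(dthetas)),
            "neighbor_id": range(len(dthetas)),
            "frame": 0,
            "rel_front_um": fronts,
            "rel_left_um": lefts,
            "dtheta_rad": dthetas,
        }
    )


class TestCorrelationMaps:
    def test_parallel_pairs_polar_plus_one(self):
        p = synthetic_pairs(np.zeros(40), np.linspace(-90, 90, 40), np.zeros(40))
        fld = polar_correlation_map(p, 100, 5, min_count=1)
        assert np.nanmin(fld.stat) == pytest.approx(1.0, abs=1e-12)

    def test_antiparallel_pairs_polar_minus_one_nematic_plus_one(self):
        p = synthetic_pairs(np.full(40, math.pi), np.linspace(-90, 90, 40), np.zeros(40))
        pol = polar_correlation_map(p, 100, 5, min_count=1)
        nem = nematic_correlation_map(p, 100, 5, min_count=1)
        assert np.nanmax(pol.stat) == pytest.approx(-1.0, abs=1e-12)
        assert np.nanmin(nem.stat) == pytest.approx(1.0, abs=1e-12)

    def test_perpendicular_pairs_nematic_minus_one(self):
        p = synthetic_pairs(np.full(20, math.pi / 2), np.linspace(-40, 40, 20), np.zeros(20))
        nem = nematic_correlation_map(p, 100, 5, min_count=1)
        assert np.nanmax(nem.stat) == pytest.approx(-1.0, abs=1e-12)

    def test_hand_computed_bin_means(self):
        # 20-pair fixture: two bins, hand-computable means
        dt = np.array([0.0] * 5 + [math.pi] * 5 + [math.pi / 3] * 10)
        fronts = np.array([2.0] * 10 + [12.0] * 10)  # bins [0,5) and [10,15)
        p = synthetic_pairs(dt, fronts, np.zeros(20))
        fld = polar_correlation_map(p, 20, 5, min_count=1)
        centers = fld.centers
        b1 = np.argmin(np.abs(centers - 2.5))
        b2 = np.argmin(np.abs(centers - 12.5))
        # left coordinate 0 falls in bin [0,5)
        j = np.argmax(fld.counts[b1])
        assert fld.stat[b1, j] == pytest.approx((5 * 1.0 + 5 * (-1.0)) / 10, abs=1e-12)
        j2 = np.argmax(fld.counts[b2])
        assert fld.stat[b2, j2] == pytest.approx(math.cos(math.pi / 3), abs=1e-12)

    def test_polar_and_nematic_share_pair_sets(self):
        rng = np.random.default_rng(8)
        p = synthetic_pairs(
            rng.uniform(-math.pi, math.pi, 300),
            rng.uniform(-80, 80, 300),
            rng.uniform(-80, 80, 300),
        )
        pol = polar_correlation_map(p, 100, 5, min_count=1)
        nem = nematic_correlation_map(p, 100, 5, min_count=1)
        assert np.array_equal(pol.counts, nem.counts)
        # exact per-pair identity cos(2d) = 2cos^2(d) - 1
        d = p.dtheta_rad.to_numpy()
        np.testing.assert_allclose(np.cos(2 * d), 2 * np.cos(d) ** 2 - 1, atol=1e-12)

    def test_min_count_masks_sparse_bins(self):
        p = synthetic_pairs([0.0], [2.0], [2.0])
        fld = polar_correlation_map(p, 100, 5, min_count=10)
        assert np.all(np.isnan(fld.stat))
        assert fld.counts.sum() == 1


class TestRelativePosition:
    def test_single_pair_concentrates_probability(self):
        p = synthetic_pairs([0.0], [10.0], [0.0])
        fld = relative_position_map(p, 100, 5)
        assert fld.stat.max() == pytest.approx(1.0, abs=1e-12)
        assert fld.stat.sum() == pytest.approx(1.0, abs=1e-12)

    def test_grid_sums_to_one(self):
        rng = np.random.default_rng(9)
        p = synthetic_pairs(
            rng.uniform(-math.pi, math.pi, 500),
            rng.uniform(-99, 99, 500),
            rng.uniform(-99, 99, 500),
        )
        assert relative_position_map(p, 100, 5).stat.sum() == pytest.approx(1.0, abs=1e-12)

    def test_per_area_normalization(self):
        p = synthetic_pairs([0.0, 0.0], [10.0, -10.0], [0.0, 0.0])
        per_pair = relative_position_map(p, 100, 5)
        per_area = relative_position_map(p, 100, 5, per_area=True)
        np.testing.assert_allclose(per_area.stat, per_pair.stat / 25.0, atol=1e-15)

    def test_uniform_isotropic_positions_flat_map(self):
        # uniform neighbors: bin probabilities nearly equal (cv < 0.2)
        rng = np.random.default_rng(10)
        n = 200_000
        p = synthetic_pairs(
            rng.uniform(-math.pi, math.pi, n),
            rng.uniform(-100, 100, n),
            rng.uniform(-100, 100, n),
        )
        fld = relative_position_map(p, 100, 10)
        probs = fld.stat.ravel()
        assert probs.std() / probs.mean() < 0.2

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            relative_position_map(synthetic_pairs([], [], []), 100, 5)


class TestVelocityHeatmap:
    def test_point_mass(self):
        df = frame_df([(i, 0, 0.0, 0.0, 0.0) for i in range(5)])
        fld = velocity_heatmap(df, v_extent=50, v_bin=2)
        assert fld.stat.max() == pytest.approx(1.0, abs=1e-12)
        assert fld.stat.sum() == pytest.approx(1.0, abs=1e-12)

    def test_stream_two_antipodal_modes(self):
        rng = np.random.default_rng(30)
        th = np.where(rng.random(4000) < 0.5, 0.0, math.pi) + rng.normal(0, 0.15, 4000)
        v = 15 + rng.normal(0, 1.5, 4000)
        df = pd.DataFrame(
            {"vx": v * np.cos(th), "vy": v * np.sin(th)}
        )
        fld = velocity_heatmap(df, v_extent=30, v_bin=3)
        # two strong modes on opposite sides of the origin
        half = fld.stat.shape[0] // 2
        assert fld.stat[half:].max() > 0.01 and fld.stat[:half].max() > 0.01


class TestMeanCellRadius:
    def test_mean_and_default(self):
        assert mean_cell_radius([8.0, 12.0]) == pytest.approx(10.0)
        assert mean_cell_radius() == 10.0
        assert mean_cell_radius([7.0, 7.0, 7.0]) == pytest.approx(7.0)


class TestRigidRotationInvariance:
    def test_fields_invariant_under_global_rotation(self):
        rng = np.random.default_rng(31)
        n = 40
        x, y = rng.uniform(0, 200, (2, n))
        th = rng.uniform(-math.pi, math.pi, n)
        df = frame_df(list(zip(range(n), [0] * n, x, y, th)))
        phi = 0.6
        c, s = math.cos(phi), math.sin(phi)
        df_rot = frame_df(
            list(zip(range(n), [0] * n, c * x - s * y, s * x + c * y,
                     np.mod(th + phi + math.pi, 2 * math.pi) - math.pi))
        )
        for maker in (
            lambda p: polar_correlation_map(p, 100, 10, 1),
            lambda p: nematic_correlation_map(p, 100, 10, 1),
            lambda p: relative_position_map(p, 100, 10),
        ):
            a = maker(build_pairs(df, 250))
            b = maker(build_pairs(df_rot, 250))
            np.testing.assert_allclose(
                np.nan_to_num(a.stat, nan=-99), np.nan_to_num(b.stat, nan=-99), atol=1e-9
            )
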