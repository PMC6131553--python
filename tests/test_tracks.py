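"""Track statistics: MSD, persistency index, order statistics, nuclear position."""

import numpy as np
import pandas as pd
import pytest

from sheetflock.synth import TrackSpec, gen_premitotic_track, gen_tracks
from sheetflock.tracks import (
    DirectionSample,
    TrackSet,
    direction_order_stats,
    fixed_lag_msd,
    mpi_series,
    relative_nuclear_position,
    rose_histogram,
    track_motility_summary,
)


def make_tracks(arrays, frame_interval=10.0):
    """Build a TrackSet from a list of (T, 2) coordinate arrays."""
    parts = []
    for tid, xy in enumerate(arrays):
        f = np.arange(len(xy))
        parts.append(
            pd.DataFrame(
                {"track_id": tid, "frame": f, "t_min": f * frame_interval,
                 "x_um": xy[:, 0], "y_um": xy[:, 1]}
            )
        )
    return TrackSet(pd.concat(parts, ignore_index=True), frame_interval)


class TestFixedLagMSD:
    def test_ballistic_closed_form(self):
        # 10 µm/h for 5 h -> 50 µm -> MSD 2500 µm² at every time point
        ts = gen_tracks(TrackSpec(kind="ballistic", n_tracks=4, n_frames=40,
                                  frame_interval=10.0, speed=10.0, seed=3))
        msd = fixed_lag_msd(ts, lag=300.0)
        assert np.allclose(msd["msd_um2"].dropna(), 2500.0)

    def test_stationary_tracks_zero(self):
        ts = gen_tracks(TrackSpec(kind="stationary", n_tracks=3, n_frames=30,
                                  frame_interval=10.0, seed=1))
        msd = fixed_lag_msd(ts, lag=100.0)
        assert np.allclose(msd["msd_um2"].dropna(), 0.0)

    def test_brownian_matches_known_diffusivity(self):
        # fixed step length l each frame in a random direction:
        # MSD(lag) = (lag/dt) * l^2 = 4 D lag with D = l^2/(4 dt)
        spec = TrackSpec(kind="brownian", n_tracks=800, n_frames=25,
                         frame_interval=10.0, speed=30.0, seed=7)
        ts = gen_tracks(spec)
        step = spec.speed * spec.frame_interval / 60.0
        lag_frames = 12
        msd = fixed_lag_msd(ts, lag=120.0, min_spots=19)
        expected = lag_frames * step**2
        got = msd["msd_um2"].dropna().mean()
        assert got == pytest.approx(expected, rel=0.1)

    def test_equals_naive_double_loop(self, rng):
        arrays = [rng.normal(size=(30, 2)).cumsum(axis=0) for _ in range(6)]
        ts = make_tracks(arrays)
        lagf = 5
        msd = fixed_lag_msd(ts, lag=50.0, min_spots=10)
        for t in range(30 - lagf):
            vals = [((a[t + lagf] - a[t]) ** 2).sum() for a in arrays]
            assert msd["msd_um2"].iloc[t] == pytest.approx(np.mean(vals))

    def test_short_tracks_discarded(self):
        long = np.zeros((25, 2))
        short = np.ones((10, 2))
        ts = make_tracks([long, short])
        msd = fixed_lag_msd(ts, lag=50.0, min_spots=19)
        assert np.all(msd["n_tracks"].to_numpy() <= 1)

    def test_noninteger_lag_rejected(self):
        ts = make_tracks([np.zeros((25, 2))])
        with pytest.raises(ValueError):
            fixed_lag_msd(ts, lag=25.0)


class TestMPI:
    def test_straight_track_is_one(self):
        xy = np.stack([np.arange(30.0), 2 * np.arange(30.0)], axis=1)
        assert np.allclose(mpi_series(xy, 10), 1.0)

    def test_alternating_track_cancels(self):
        # 9 alternating unit displacements leave a resultant of 1/9
        xy = np.zeros((30, 2))
        xy[1::2, 0] = 1.0
        assert np.allclose(mpi_series(xy, 10), 1.0 / 9.0)

    def test_random_headings_monte_carlo_level(self, rng):
        # mean resultant length of 9 iid unit vectors ~ sqrt(pi/36)
        vals = []
        for _ in range(400):
            ang = rng.uniform(0, 2 * np.pi, 9)
            steps = np.stack([np.cos(ang), np.sin(ang)], axis=1)
            xy = np.concatenate([np.zeros((1, 2)), steps.cumsum(axis=0)])
            vals.append(mpi_series(xy, 10)[0])
        assert np.mean(vals) == pytest.approx(np.sqrt(np.pi / 36.0), rel=0.1)

    def test_upper_bound_and_attainment(self, rng):
        xy = rng.normal(size=(40, 2)).cumsum(axis=0)
        m = mpi_series(xy, 10)
        assert np.all(m[np.isfinite(m)] <= 1.0 + 1e-12)

    def test_zero_steps_skipped_and_undefined_window(self):
        xy = np.zeros((12, 2))  # no displacement anywhere
        assert np.all(np.isnan(mpi_series(xy, 10)))

    def test_monotone_in_persistence(self):
        meds = []
        for pers in (0.2, 0.5, 0.8, 1.0):
            vals = []
            for rep in range(20):
                ts = gen_tracks(TrackSpec(kind="persistent", n_tracks=1,
                                          n_frames=40, persistence=pers,
                                          seed=500 + rep))
                xy = ts.data[["x_um", "y_um"]].to_numpy()
                vals.append(np.nanmean(mpi_series(xy, 10)))
            meds.append(np.median(vals))
        assert all(b >= a for a, b in zip(meds, meds[1:]))
        assert meds[-1] == pytest.approx(1.0)


class TestMotilitySummary:
    def test_ballistic_velocity_and_distance(self):
        spec = TrackSpec(kind="ballistic", n_tracks=2, n_frames=13,
                         frame_interval=10.0, speed=24.0, seed=2)
        out = track_motility_summary(gen_tracks(spec))
        assert np.allclose(out["mean_velocity_um_h"], 24.0)
        assert np.allclose(out["euclidean_um"], 24.0 * 2.0)  # 2 h elapsed

    def test_alternating_low_euclidean(self):
        spec = TrackSpec(kind="alternating", n_tracks=1, n_frames=13,
                         frame_interval=10.0, speed=24.0, seed=2)
        out = track_motility_summary(gen_tracks(spec))
        assert out["euclidean_um"].iloc[0] == pytest.approx(0.0)
        assert out["mean_velocity_um_h"].iloc[0] == pytest.approx(24.0)

    def test_stationary_zero(self):
        spec = TrackSpec(kind="stationary", n_tracks=1, n_frames=5, seed=0)
        out = track_motility_summary(gen_tracks(spec))
        assert out["mean_velocity_um_h"].iloc[0] == 0.0
        assert out["euclidean_um"].iloc[0] == 0.0


class TestDirectionOrderStats:
    def test_identical_angles_unit_magnitude(self):
        s = direction_order_stats(DirectionSample(np.full(7, 90.0)))
        assert s.magnitude == pytest.approx(1.0)
        assert s.mean_angle_deg == pytest.approx(90.0)

    def test_antipodal_pair_cancels(self):
        s = direction_order_stats(DirectionSample(np.array([0.0, 180.0])))
        assert s.magnitude == pytest.approx(0.0, abs=1e-12)
        assert np.isnan(s.mean_angle_deg)

    def test_right_angle_pair(self):
        s = direction_order_stats(DirectionSample(np.array([0.0, 90.0])))
        assert s.magnitude == pytest.approx(np.sqrt(2) / 2)
        assert s.mean_angle_deg == pytest.approx(45.0)

    def test_magnitude_identity(self):
        s = direction_order_stats(DirectionSample(np.array([10.0, 40.0, 250.0])))
        assert s.magnitude**2 == pytest.approx(s.mean_x**2 + s.mean_y**2)

    def test_rotation_equivariance(self, rng):
        ang = rng.uniform(0, 360, 25)
        s0 = direction_order_stats(DirectionSample(ang))
        s1 = direction_order_stats(DirectionSample(ang + 77.0))
        assert s1.magnitude == pytest.approx(s0.magnitude)
        assert np.mod(s1.mean_angle_deg - s0.mean_angle_deg, 360.0) == pytest.approx(
            77.0, abs=1e-8
        )

    def test_axial_mode_identifies_antipodes(self, rng):
        ang = rng.uniform(0, 360, 30)
        flipped = np.where(rng.random(30) < 0.5, ang, ang + 180.0)
        s0 = direction_order_stats(DirectionSample(ang, axial=True))
        s1 = direction_order_stats(DirectionSample(flipped, axial=True))
        assert s1.magnitude == pytest.approx(s0.magnitude)
        assert s1.mean_angle_deg == pytest.approx(s0.mean_angle_deg, abs=1e-8)

    def test_uniform_large_sample_scale(self, rng):
        mags = [
            direction_order_stats(
                DirectionSample(rng.uniform(0, 360, 1000))
            ).magnitude
            for _ in range(30)
        ]
        assert np.mean(mags) == pytest.approx(np.sqrt(np.pi / 4000.0), rel=0.25)


class TestRoseHistogram:
    def test_single_occupied_bin(self):
        edges, h = rose_histogram(DirectionSample(np.full(5, 10.0)), 8)
        assert h[0] == 1.0 and np.allclose(h[1:], 0.0)

    def test_min_max_scaling(self):
        ang = np.concatenate([np.full(10, 10.0), np.full(30, 100.0)])
        _, h = rose_histogram(DirectionSample(ang), 4)
        assert h.min() == 0.0 and h.max() == 1.0

    def test_flat_histogram_convention(self):
        ang = np.array([45.0, 135.0, 225.0, 315.0])
        _, h = rose_histogram(DirectionSample(ang), 4)
        assert np.allclose(h, 0.0)


class TestNuclearPosition:
    @pytest.mark.parametrize(
        "c,expect", [((0.0, 0.0), 0.0), ((15.0, 0.0), 0.5), ((30.0, 0.0), 1.0)]
    )
    def test_canonical_geometries(self, c, expect):
        df = pd.DataFrame(
            {"frame": [0], "cx": [c[0]], "cy": [c[1]],
             "xx": [0.0], "xy": [0.0], "yx": [30.0], "yy": [0.0]}
        )
        out = relative_nuclear_position(df)
        assert out["p"].iloc[0] == pytest.approx(expect)

    def test_time_axis_ends_at_mitosis_entry(self):
        series = gen_premitotic_track(n_frames=61, frame_interval=2.0, seed=0)
        out = relative_nuclear_position(series)
        assert out["t_min"].iloc[-1] == 0.0
        assert out["t_min"].iloc[0] == -120.0

    def test_degenerate_membrane_points_invalid(self):
        df = pd.DataFrame(
            {"frame": [0], "cx": [1.0], "cy": [0.0],
             "xx": [0.0], "xy": [0.0], "yx": [0.0], "yy": [0.0]}
        )
        assert np.isnan(relative_nuclear_position(df)["p"].iloc[0])


class TestTrackSetContract:
    def test_gapped_track_rejected(self):
        df = pd.DataFrame(
            {"track_id": 0, "frame": [0, 2, 3], "t_min": [0.0, 20.0, 30.0],
             "x_um": 0.0, "y_um": 0.0}
        )
        with pytest.raises(ValueError, match="contiguous"):
            TrackSet(df, 10.0)

    def test_nonfinite_coordinates_rejected(self):
        df = pd.DataFrame(
            {"track_id": 0, "frame": [0, 1], "t_min": [0.0, 10.0],
             "x_um": [0.0, np.nan], "y_um": 0.0}
        )
        with pytest.raises(ValueError, match="finite"):
            TrackSet(df, 10.0)
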