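"""Microchannel statistics: entries, speeds, fluctuation, density profile."""
import numpy as np
import pandas as pd
import pytest

from conftest import make_track
from migrochip.channel_metrics import (
    assign_to_channels,
    count_entries,
    density_profile,
    fraction_within,
    instantaneous_speeds,
    speed_fluctuation,
    summarize_channel_cells,
    time_resolved_speed,
)
from migrochip.geometry import ChannelGeometry, GeometryError
from migrochip.synthetic_data import SimulationConfig, simulate_channel_1d
from migrochip.tracks import Track


def axial_track(axials, dt=3.0, track_id=0, geom=None):
    geom = geom or ChannelGeometry()
    xy = geom.to_xy(np.asarray(axials, dtype=float))
    return Track(track_id=track_id, t=np.arange(len(axials)) * dt, xy=xy)


class TestSpeeds:
    def test_unit_speed_track(self):
        tr = axial_track([0.0, 3.0, 6.0])
        np.testing.assert_allclose(
            instantaneous_speeds(tr, ChannelGeometry()), [1.0, 1.0]
        )

    def test_stationary_cell_zero_speed(self):
        tr = axial_track([5.0, 5.0, 5.0])
        np.testing.assert_allclose(instantaneous_speeds(tr, ChannelGeometry()), 0.0)

    def test_matches_finite_difference_oracle(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 100, size=(20, 2))
        tr = make_track(pts, dt=2.0)
        v = instantaneous_speeds(tr)
        oracle = [
            np.hypot(*(pts[i + 1] - pts[i])) / 2.0 for i in range(len(pts) - 1)
        ]
        np.testing.assert_allclose(v, oracle, rtol=1e-12)

    def test_duplicate_timestamps_rejected(self):
        tr = make_track([(0, 0), (1, 0)])
        tr.t = np.array([0.0, 0.0])
        with pytest.raises(ValueError):
            instantaneous_speeds(tr)


class TestSpeedFluctuation:
    def test_constant_speed_zero(self):
        tr = axial_track([0.0, 3.0, 6.0, 9.0])
        assert speed_fluctuation(tr, ChannelGeometry()) == 0.0

    def test_hand_computed_sample_sd(self):
        # speeds 1 and 3 µm/min -> sample SD sqrt(2)
        tr = axial_track([0.0, 3.0, 12.0], dt=3.0)
        assert speed_fluctuation(tr, ChannelGeometry()) == pytest.approx(
            np.sqrt(2.0), rel=1e-12
        )

    def test_time_reversal_invariance(self):
        rng = np.random.default_rng(2)
        axials = np.cumsum(rng.normal(2.0, 1.5, size=15))
        fwd = axial_track(axials)
        rev = axial_track(axials[::-1])
        assert speed_fluctuation(fwd, ChannelGeometry()) == pytest.approx(
            speed_fluctuation(rev, ChannelGeometry()), rel=1e-12
        )

    def test_too_short_track_is_missing(self):
        assert np.isnan(speed_fluctuation(axial_track([0.0, 1.0])))

    def test_zero_speed_sd_cohort_all_zero(self):
        cfg = SimulationConfig(mean_speed=3.0, speed_sd=0.0, duration=60.0,
                               n_cells=10, seed=8)
        geom = ChannelGeometry()
        tracks = simulate_channel_1d(cfg, geom, entry_probability=1.0)
        for tr in tracks:
            assert speed_fluctuation(tr, geom) == pytest.approx(0.0, abs=1e-12)

    def test_cv_variant(self):
        tr = axial_track([0.0, 3.0, 12.0], dt=3.0)  # speeds 1, 3
        cv = speed_fluctuation(tr, ChannelGeometry(), statistic="cv")
        assert cv == pytest.approx(np.sqrt(2.0) / 2.0, rel=1e-12)


class TestEntries:
    def test_deep_crossing_counts_once(self):
        tr = axial_track([-20.0, 10.0, 50.0, 30.0, 60.0])
        assert count_entries([tr], ChannelGeometry()) == 1

    def test_entrance_grazing_not_counted(self):
        tr = axial_track([-5.0, 2.0, -3.0, 4.0, -1.0])
        assert count_entries([tr], ChannelGeometry()) == 0

    def test_simulated_cohort_matches_ground_truth(self):
        geom = ChannelGeometry()
        cfg = SimulationConfig(mean_speed=2.0, speed_sd=1.0, duration=60.0,
                               n_cells=100, seed=13)
        tracks = simulate_channel_1d(cfg, geom, entry_probability=0.05)
        truth = sum(tr.meta["entered"] for tr in tracks)
        assert 0 < truth < 100  # informative mix
        assert count_entries(tracks, geom) == truth


class TestAssignment:
    def test_inside_single_band(self):
        geoms = [ChannelGeometry(channel_id=0, lateral_center=0.0),
                 ChannelGeometry(channel_id=1, lateral_center=20.0)]
        tr = axial_track([10.0, 20.0, 30.0], geom=geoms[0])
        assert assign_to_channels([tr], geoms)[tr.track_id] == 0

    def test_outside_all_bands_unassigned(self):
        geoms = [ChannelGeometry(channel_id=0)]
        tr = make_track([(10.0, 50.0), (20.0, 50.0)])
        assert assign_to_channels([tr], geoms)[0] is None

    def test_majority_vote(self):
        g0 = ChannelGeometry(channel_id=0, lateral_center=0.0)
        g1 = ChannelGeometry(channel_id=1, lateral_center=10.0)
        pts = [(float(i), 0.0) for i in range(6)] + [(float(i), 10.0) for i in range(4)]
        tr = make_track(pts)
        assert assign_to_channels([tr], [g0, g1])[0] == 0

    def test_overlapping_bands_rejected(self):
        g0 = ChannelGeometry(channel_id=0, lateral_center=0.0)
        g1 = ChannelGeometry(channel_id=1, lateral_center=2.0)
        with pytest.raises(GeometryError):
            assign_to_channels([], [g0, g1])


class TestDensityProfile:
    def summaries(self, distances):
        return pd.DataFrame(
            {
                "entered": [True] * len(distances),
                "furthest_distance": distances,
            }
        )

    def test_counts_sum_to_entered_cells(self):
        rng = np.random.default_rng(3)
        s = self.summaries(rng.uniform(0, 900, size=137))
        prof = density_profile(s, bin_width=50.0, length=900.0)
        assert prof["count"].sum() == 137

    def test_all_at_150_fraction_within_200_is_one(self):
        s = self.summaries([150.0] * 10)
        assert fraction_within(s, 200.0) == 1.0

    def test_single_cell_at_end(self):
        s = self.summaries([900.0])
        prof = density_profile(s, bin_width=50.0, length=900.0)
        assert prof["count"].iloc[-1] == 1
        assert fraction_within(s, 200.0) == 0.0

    def test_uniform_law(self):
        rng = np.random.default_rng(4)
        n = 10_000
        s = self.summaries(rng.uniform(0, 900, size=n))
        p = 200.0 / 900.0
        se = np.sqrt(p * (1 - p) / n)
        assert abs(fraction_within(s, 200.0) - p) < 3 * se

    def test_no_entered_cells_fraction_missing(self):
        s = pd.DataFrame({"entered": [False], "furthest_distance": [0.0]})
        assert np.isnan(fraction_within(s))


class TestSummaries:
    def test_furthest_distance_monotone_under_extension(self):
        geom = ChannelGeometry()
        axials = [-5.0, 20.0, 80.0, 40.0, 120.0]
        prev = 0.0
        for k in range(2, len(axials) + 1):
            s = summarize_channel_cells([axial_track(axials[:k])], geom)
            d = s["furthest_distance"].iloc[0]
            assert d >= prev
            prev = d

    def test_mean_speed_recovery_from_simulation(self):
        geom = ChannelGeometry(length=5000.0)
        cfg = SimulationConfig(mean_speed=2.5, speed_sd=0.0, duration=300.0,
                               n_cells=200, seed=21)
        tracks = simulate_channel_1d(cfg, geom, entry_probability=1.0)
        s = summarize_channel_cells(tracks, geom)
        est = s["mean_speed"].mean()
        assert est == pytest.approx(2.5, rel=0.05)


class TestTimeResolvedSpeed:
    def test_constant_speed_flat_profile(self):
        geom = ChannelGeometry(length=5000.0)
        cfg = SimulationConfig(mean_speed=3.0, speed_sd=0.0, duration=60.0,
                               n_cells=5, seed=6)
        tracks = simulate_channel_1d(cfg, geom, entry_probability=1.0)
        prof = time_resolved_speed(tracks, window=15.0, duration=60.0, geometry=geom)
        np.testing.assert_allclose(prof["mean_speed"], 3.0, rtol=1e-12)

    def test_two_regime_cohort_decreases(self):
        geom = ChannelGeometry(length=50000.0)
        cfg = SimulationConfig(mean_speed=4.0, speed_sd=0.0, duration=240.0,
                               n_cells=20, seed=7)
        profile_fn = lambda t: 4.0 if t < 120.0 else 1.5
        tracks = simulate_channel_1d(cfg, geom, entry_probability=1.0,
                                     speed_profile=profile_fn)
        prof = time_resolved_speed(tracks, window=60.0, duration=240.0,
                                   geometry=geom)
        means = prof["mean_speed"].to_numpy()
        assert means[0] > means[-1]
        assert (np.diff(means) <= 1e-9).all()

    def test_single_step_lands_in_midpoint_window(self):
        tr = axial_track([0.0, 3.0])  # one step, midpoint t = 1.5 min
        prof = time_resolved_speed([tr], window=3.0, duration=6.0,
                                   geometry=ChannelGeometry())
        assert prof["n_steps"].tolist() == [1, 0]
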