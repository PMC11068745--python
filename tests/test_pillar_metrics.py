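"""Turning angles, confinement classification and trajectory statistics."""
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import make_track
from migrochip.geometry import PillarGeometry
from migrochip.pillar_metrics import (
    percent_time_confined,
    step_metrics,
    summarize_pillar_tracks,
    top_n_tracks,
    track_length,
    turning_angles,
)
from migrochip.synthetic_data import SimulationConfig, simulate_prw_2d


def law_of_cosines_angle(p0, p1, p2):
    """Independent oracle: angle between the two displacement vectors
    from side lengths, via the law of cosines."""
    a = np.linalg.norm(np.subtract(p1, p0))
    b = np.linalg.norm(np.subtract(p2, p1))
    c = np.linalg.norm(np.subtract(p2, p0))
    # turning angle is the supplement of the triangle's interior angle at p1
    cosang = (c * c - a * a - b * b) / (2 * a * b)
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


class TestTurningAngles:
    @pytest.mark.parametrize(
        "points,expected",
        [
            ([(0, 0), (1, 0), (2, 0)], 0.0),  # collinear forward
            ([(0, 0), (1, 0), (1, 1)], 90.0),  # right angle
            ([(0, 0), (1, 0), (0, 0)], 180.0),  # reversal
        ],
    )
    def test_canonical_cases_exact(self, points, expected):
        (alpha,) = turning_angles(make_track(points))
        assert alpha == expected

    def test_matches_law_of_cosines_oracle(self):
        rng = np.random.default_rng(11)
        triples = rng.uniform(-50, 50, size=(10_000, 3, 2))
        for tri in triples[:500]:  # deeper loop lives in the acceptance suite
            (alpha,) = turning_angles(make_track(tri))
            assert alpha == pytest.approx(law_of_cosines_angle(*tri), abs=1e-9)

    def test_pause_gives_missing_angle(self):
        alpha = turning_angles(make_track([(0, 0), (0, 0), (1, 0)]))
        assert np.isnan(alpha[0])

    def test_short_track_empty(self):
        assert turning_angles(make_track([(0, 0), (1, 0)])).size == 0

    @given(
        angle=st.floats(-np.pi, np.pi),
        shift_x=st.floats(-100, 100),
        shift_y=st.floats(-100, 100),
    )
    def test_rotation_translation_invariance(self, angle, shift_x, shift_y):
        pts = np.array([(0.0, 0.0), (3.0, 1.0), (5.0, -2.0), (4.0, 4.0)])
        R = np.array(
            [[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]]
        )
        moved = pts @ R.T + [shift_x, shift_y]
        a0 = turning_angles(make_track(pts))
        a1 = turning_angles(make_track(moved))
        np.testing.assert_allclose(a0, a1, atol=1e-6)

    def test_range_is_0_180(self):
        rng = np.random.default_rng(12)
        tr = make_track(np.cumsum(rng.normal(0, 3, size=(200, 2)), axis=0))
        alpha = turning_angles(tr)
        ok = np.isfinite(alpha)
        assert (alpha[ok] >= 0).all() and (alpha[ok] <= 180).all()


class TestClassification:
    def step_track(self, alpha_deg):
        """3-point track whose single turning angle is alpha_deg, unit steps."""
        return make_track(
            [(0, 0), (1, 0), (1 + np.cos(np.radians(alpha_deg)),
                              np.sin(np.radians(alpha_deg)))]
        )

    @pytest.mark.parametrize(
        "alpha,expected",
        [(29.999, "persistent"), (30.001, "confined")],
    )
    def test_threshold_boundary(self, alpha, expected):
        steps = step_metrics(self.step_track(alpha), motile_min_disp=0.5)
        assert steps["label"].iloc[1] == expected
        assert steps["alpha_deg"].iloc[1] == pytest.approx(alpha, abs=1e-9)

    def test_exact_threshold_assigned_to_confined(self):
        """alpha of exactly 30° goes to confined (the defining
        inequalities are strict on both sides; the boundary is a
        convention, chosen conservative toward confinement)."""
        import pandas as pd

        from migrochip.pillar_metrics import classify_steps

        table = pd.DataFrame(
            {
                "track_id": 0,
                "step": [0, 1],
                "displacement_um": [3.0, 3.0],
                "speed_um_min": [1.0, 1.0],
                "alpha_deg": [np.nan, 30.0],
            }
        )
        out = classify_steps(table, alpha_threshold=30.0, motile_min_disp=0.5)
        assert out["label"].iloc[1] == "confined"

    def test_zero_displacement_is_non_motile(self):
        tr = make_track([(0, 0), (1, 0), (1, 0)])
        steps = step_metrics(tr, motile_min_disp=0.5)
        assert steps["label"].iloc[1] == "non-motile"
        assert not steps["motile"].iloc[1]

    def test_conservation_persistent_plus_confined_equals_motile_interior(self):
        geom = PillarGeometry()
        cfg = SimulationConfig(mean_speed=3.0, speed_sd=1.0, angular_noise_sd=0.8,
                               duration=150.0, n_cells=30, seed=17)
        for tr in simulate_prw_2d(cfg, geom):
            steps = step_metrics(tr)
            n_p = (steps["label"] == "persistent").sum()
            n_c = (steps["label"] == "confined").sum()
            motile_interior = (
                steps["motile"] & np.isfinite(steps["alpha_deg"])
            ).sum()
            assert n_p + n_c == motile_interior


class TestPercentConfined:
    def test_straight_track_zero_percent(self):
        tr = make_track([(float(i), 0.0) for i in range(10)])
        assert percent_time_confined(tr) == 0.0

    def test_alternating_fifty_percent(self):
        # zig-zag with 90° turns: every interior step confined
        zigzag = [(i, i % 2) for i in range(10)]
        tr = make_track(np.asarray(zigzag, dtype=float) * 3.0)
        assert percent_time_confined(tr) == 100.0
        # mix: straight run then zig-zag, half the interior steps confined
        pts = [(float(i), 0.0) for i in range(5)]
        last = pts[-1]
        for i in range(1, 5):
            pts.append((last[0] + i, (i % 2) * 1.0 * 3))
        tr2 = make_track(np.asarray(pts) * 1.0)
        p = percent_time_confined(tr2)
        assert 0.0 < p < 100.0

    def test_no_motile_steps_missing(self):
        tr = make_track([(0, 0), (0, 0), (0, 0)])
        assert np.isnan(percent_time_confined(tr))

    def test_range_0_100_and_brute_force_recount(self):
        geom = PillarGeometry()
        cfg = SimulationConfig(mean_speed=3.0, angular_noise_sd=0.6,
                               duration=150.0, n_cells=20, seed=19)
        for tr in simulate_prw_2d(cfg, geom):
            steps = step_metrics(tr)
            p = percent_time_confined(steps)
            if np.isnan(p):
                continue
            assert 0.0 <= p <= 100.0
            # independent per-step recount
            confined = persistent = 0
            for _, row in steps.iterrows():
                if row["label"] == "confined":
                    confined += 1
                elif row["label"] == "persistent":
                    persistent += 1
            assert p == pytest.approx(100.0 * confined / (confined + persistent))

    def test_monotone_in_angular_noise(self):
        geom = PillarGeometry(pillar_diameter=0.0, arena_size=(2000.0, 2000.0))
        means = []
        for sigma in (0.05, 0.15, 0.3, 0.6, 1.2):
            cfg = SimulationConfig(mean_speed=3.0, angular_noise_sd=sigma,
                                   duration=300.0, n_cells=50, seed=23)
            summary = summarize_pillar_tracks(simulate_prw_2d(cfg, geom))
            means.append(summary["percent_time_confined"].mean())
        assert all(b >= a for a, b in zip(means, means[1:]))

    def test_zero_noise_zero_confined(self, open_arena):
        cfg = SimulationConfig(mean_speed=3.0, angular_noise_sd=0.0,
                               duration=150.0, n_cells=10, seed=29)
        for tr in simulate_prw_2d(cfg, open_arena):
            assert percent_time_confined(tr) == 0.0


class TestTrackLength:
    def test_straight_steps(self):
        tr = make_track([(float(i), 0.0) for i in range(11)])
        assert track_length(tr) == pytest.approx(10.0)

    def test_closed_square_path_length_vs_net(self):
        square = [(0, 0), (5, 0), (5, 5), (0, 5), (0, 0)]
        tr = make_track(square)
        assert track_length(tr) == pytest.approx(20.0)
        assert np.linalg.norm(tr.xy[-1] - tr.xy[0]) == 0.0

    def test_matches_euclidean_sum_oracle(self):
        rng = np.random.default_rng(31)
        pts = rng.uniform(0, 50, size=(30, 2))
        tr = make_track(pts)
        oracle = sum(
            float(np.hypot(*(pts[i + 1] - pts[i]))) for i in range(len(pts) - 1)
        )
        assert track_length(tr) == pytest.approx(oracle, rel=1e-12)


class TestTopN:
    def test_fewer_than_n_returns_all(self):
        tracks = [make_track([(0, 0), (i + 1.0, 0)], track_id=i) for i in range(3)]
        assert len(top_n_tracks(tracks, 16)) == 3

    def test_selects_longest(self):
        lengths = [5.0, 9.0, 7.0]
        tracks = [make_track([(0, 0), (l, 0)], track_id=i)
                  for i, l in enumerate(lengths)]
        top = top_n_tracks(tracks, 2)
        assert [tr.track_id for tr in top] == [1, 2]

    def test_agrees_with_full_sort_oracle(self):
        rng = np.random.default_rng(37)
        tracks = [
            make_track(np.cumsum(rng.normal(0, 2, size=(20, 2)), axis=0), track_id=i)
            for i in range(100)
        ]
        top = top_n_tracks(tracks, 16)
        oracle = sorted(tracks, key=lambda tr: (-track_length(tr), tr.track_id))[:16]
        assert [t.track_id for t in top] == [t.track_id for t in oracle]
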