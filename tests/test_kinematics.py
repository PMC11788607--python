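import numpy as np
import pandas as pd
import pytest

from conftest import make_trajectory
from reachbias import kinematics
from reachbias.geometry import DEFAULT_LAYOUT, Point
from reachbias.kinematics import (
    classify_change_of_mind,
    initial_velocity,
    movement_time,
    reaction_time,
    rt_summary,
    trial_kinematics,
)

DT = 1000.0 / 60.0


def _random_walk_fixture(rng, n=40):
    """A jittery path from the start center out to the left-closer left button."""
    start = np.array([0.0, 7.5])
    target = np.array([-12.5, 16.5])
    frac = np.linspace(0.0, 1.0, n)[:, None]
    pts = start + frac * (target - start) + rng.normal(0, 0.15, size=(n, 2)) * (frac < 0.9)
    pts[0] = start
    pts[-1] = target
    return make_trajectory(pts)


class TestReactionTime:
    def test_exit_sample_timestamp(self):
        pts = [(0, 7.5)] * 30 + [(0.5, 8.0), (2.0, 9.0), (4.0, 11.0), (-12.5, 16.5)]
        traj = make_trajectory(pts)
        # sample 32 is the first with distance > 2.5 from (0, 7.5)
        assert reaction_time(traj) == pytest.approx(32 * DT)

    def test_never_exits_flagged(self):
        traj = make_trajectory([(0, 7.5), (0.3, 7.6), (0.1, 7.4)])
        assert reaction_time(traj) is None

    def test_matches_linear_scan_oracle(self, rng):
        for _ in range(100):
            traj = _random_walk_fixture(rng)
            expected = None
            for i in range(len(traj)):
                d = np.hypot(traj.x_cm[i] - 0.0, traj.y_cm[i] - 7.5)
                if d > 2.5:
                    expected = traj.t_ms[i]
                    break
            assert reaction_time(traj) == expected


class TestMovementTime:
    def test_single_sample_teleport(self):
        traj = make_trajectory([(0, 7.5), (-12.5, 16.5)])
        assert movement_time(traj, DEFAULT_LAYOUT, "left_closer") == pytest.approx(0.0)
        # exit and registration on the same sample: rt + movement = registration time
        assert reaction_time(traj) == pytest.approx(DT)

    def test_oracle_agreement_and_additivity(self, rng):
        for _ in range(50):
            traj = _random_walk_fixture(rng)
            rt = reaction_time(traj)
            mt = movement_time(traj, DEFAULT_LAYOUT, "left_closer")
            d_btn = np.hypot(traj.x_cm + 12.5, traj.y_cm - 16.5)
            reg = np.flatnonzero(d_btn < 1.7)[0]
            assert rt + mt == pytest.approx(traj.t_ms[reg])

    def test_no_button_reached_flagged(self):
        traj = make_trajectory([(0, 7.5), (0, 12.0), (0, 14.0)])
        assert movement_time(traj, DEFAULT_LAYOUT, "left_closer") is None


class TestInitialVelocity:
    def test_half_cm_step_at_60hz(self):
        # consecutive samples 0.5 cm apart crossing the boundary
        pts = [(0, 7.5), (0, 9.75), (0, 10.25), (0, 16.0)]
        traj = make_trajectory(pts)
        assert initial_velocity(traj) == pytest.approx(0.5 * 60.0)

    def test_scales_with_coordinates(self):
        from reachbias.geometry import Layout

        pts = [(0, 7.5), (0.8, 8.1), (1.6, 8.9), (3.2, 10.4), (6.0, 13.0)]
        traj = make_trajectory(pts)
        v1 = initial_velocity(traj)
        doubled = traj.copy()
        doubled[["x_cm", "y_cm"]] *= 2.0
        scaled_layout = Layout(start_center=Point(0.0, 15.0), start_radius=5.0)
        assert initial_velocity(doubled, scaled_layout) == pytest.approx(2.0 * v1)

    def test_exit_at_first_sample_flagged(self):
        traj = make_trajectory([(6.0, 7.5), (8.0, 7.5)])
        assert initial_velocity(traj) is None


class TestChangeOfMind:
    def test_exit_right_land_left_is_com(self):
        pts = [(0, 7.5), (2.0, 9.5), (3.0, 10.5), (-12.5, 16.5)]
        traj = make_trajectory(pts)
        assert classify_change_of_mind(traj, "left")

    def test_exit_left_land_left_is_not_com(self):
        pts = [(0, 7.5), (-2.0, 9.5), (-3.0, 10.5), (-12.5, 16.5)]
        traj = make_trajectory(pts)
        assert not classify_change_of_mind(traj, "left")

    def test_midline_exit_defers_to_next_sample(self):
        pts = [(0, 7.5), (0.0, 10.5), (4.0, 12.0), (12.5, 16.5)]
        traj = make_trajectory(pts)
        assert not classify_change_of_mind(traj, "right")
        assert classify_change_of_mind(traj, "left")

    def test_midline_only_counts_as_no_com(self):
        pts = [(0, 7.5), (0.0, 10.5), (0.0, 14.0)]
        traj = make_trajectory(pts)
        assert not classify_change_of_mind(traj, "left")

    def test_invariant_to_y_coordinates(self, rng):
        pts = [(0, 7.5), (2.0, 9.5), (3.0, 10.5), (-12.5, 16.5)]
        traj = make_trajectory(pts)
        shifted = traj.copy()
        shifted["y_cm"] = [7.5, 7.5, 7.5, 16.5]  # same x signs, different y
        assert classify_change_of_mind(traj, "left") == classify_change_of_mind(
            shifted, "left"
        )


class TestTrialKinematics:
    def test_appending_samples_after_registration_changes_nothing(self, rng):
        traj = _random_walk_fixture(rng)
        base = trial_kinematics(traj, DEFAULT_LAYOUT, "left_closer")
        extra = pd.concat(
            [traj, make_trajectory([(-12.5, 16.5)] * 5).assign(
                t_ms=lambda d: d.t_ms + traj.t_ms.iloc[-1] + DT)],
            ignore_index=True,
        )
        more = trial_kinematics(extra, DEFAULT_LAYOUT, "left_closer")
        assert base.rt_ms == more.rt_ms
        assert base.movement_ms == more.movement_ms
        assert base.initial_velocity_cm_s == more.initial_velocity_cm_s
        assert base.change_of_mind == more.change_of_mind

    def test_miss_trial_yields_empty_fields(self):
        traj = make_trajectory([(0, 7.5)] * 10)
        meas = trial_kinematics(traj, DEFAULT_LAYOUT, "left_closer")
        assert meas.rt_ms is None and meas.movement_ms is None
        assert meas.registered_choice is None


class TestRtSummary:
    def _log(self, rows):
        return pd.DataFrame(
            rows,
            columns=["participant_id", "task", "block", "condition",
                     "stimulus_level", "response", "rt_ms", "movement_ms",
                     "initial_velocity_cm_s", "change_of_mind"],
        )

    def test_single_participant_mean_equals_median(self):
        rows = [
            [0, "motion", "main", "left_closer", -5.0, "left", rt, 200.0, 80.0, 0]
            for rt in (900.0, 1000.0, 5000.0)
        ]
        per_level, overall = rt_summary(self._log(rows))
        assert per_level.mean_median_rt_ms.iloc[0] == 1000.0
        assert overall.mean_median_rt_ms.iloc[0] == 1000.0

    def test_median_robust_to_outlier(self):
        base = [
            [0, "motion", "main", "left_closer", -5.0, "left", 1000.0 + i, 200.0, 80.0, 0]
            for i in range(99)
        ]
        clean = rt_summary(self._log(base))[1].mean_median_rt_ms.iloc[0]
        spiked = base + [[0, "motion", "main", "left_closer", -5.0, "left", 1e6, 200.0, 80.0, 0]]
        dirty = rt_summary(self._log(spiked))[1].mean_median_rt_ms.iloc[0]
        assert abs(dirty - clean) <= 1.0  # at most one order-statistic step

    def test_matches_naive_groupby_oracle(self, rng):
        rows = []
        for pid in range(3):
            for level in (-10.0, 0.0, 10.0):
                for _ in range(7):
                    rows.append(
                        [pid, "motion", "main", "left_closer", level, "left",
                         float(rng.uniform(500, 2000)), 200.0, 80.0, 0]
                    )
        log = self._log(rows)
        per_level, _ = rt_summary(log)
        oracle = (
            log.groupby(["stimulus_level", "participant_id"]).rt_ms.median()
            .groupby("stimulus_level").mean()
        )
        for _, r in per_level.iterrows():
            assert r.mean_median_rt_ms == pytest.approx(oracle[r.stimulus_level])

    def test_misses_excluded(self):
        rows = [
            [0, "motion", "main", "left_closer", -5.0, "left", 1000.0, 200.0, 80.0, 0],
            [0, "motion", "main", "left_closer", -5.0, "miss", np.nan, np.nan, np.nan, np.nan],
        ]
        _, overall = rt_summary(self._log(rows))
        assert overall.mean_median_rt_ms.iloc[0] == 1000.0
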