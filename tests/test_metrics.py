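import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fuccitrack.metrics import (
    JumpCriterion,
    PairFilter,
    daughter_pair_differences,
    detect_terminal_speed_jump,
    division_synchrony,
    doubling_times,
    instantaneous_speeds,
    per_phase_dynamics,
    phase_durations,
    summarize_durations,
    trajectory_measures,
)
from fuccitrack.synthetic import SimulationParams, simulate_lineage
from fuccitrack.tracking import Track, build_lineage
from tests.conftest import random_walk_track, straight_track


class TestTrajectoryMeasures:
    def test_straight_path(self):
        tr = straight_track(10, 5.0)
        m = trajectory_measures(tr, pixel_size_um=1.0, frame_interval_min=10)
        assert m.total_distance_um == pytest.approx(50.0)
        assert m.displacement_um == pytest.approx(50.0)
        assert m.directionality == pytest.approx(1.0)
        assert m.trajectory_time_h == pytest.approx(10 / 6)
        assert m.avg_speed_um_h == pytest.approx(30.0)

    def test_closed_loop_directionality_zero(self):
        tr = Track(id="C1", birth_frame=0,
                   positions=[(0, 0), (5, 0), (5, 5), (0, 5), (0, 0)])
        m = trajectory_measures(tr, 1.0, 10)
        assert m.directionality == pytest.approx(0.0)

    def test_triangle_path(self):
        tr = Track(id="C1", birth_frame=0, positions=[(0, 0), (3, 4), (6, 0)])
        m = trajectory_measures(tr, 1.0, 10)
        assert m.total_distance_um == pytest.approx(10.0)
        assert m.displacement_um == pytest.approx(6.0)
        assert m.directionality == pytest.approx(0.6)

    def test_stationary_cell_nan_directionality(self):
        tr = Track(id="C1", birth_frame=0, positions=[(1, 1), (1, 1)])
        assert math.isnan(trajectory_measures(tr, 1.0, 10).directionality)

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            trajectory_measures(Track(id="C1", birth_frame=0, positions=[(0, 0)]), 1, 10)


class TestInstantaneousSpeeds:
    def test_unit_steps(self):
        v = instantaneous_speeds(straight_track(6, 1.0), 1.0, 10)
        np.testing.assert_allclose(v, 6.0)

    def test_stationary(self):
        tr = Track(id="C1", birth_frame=0, positions=[(2, 2)] * 5)
        np.testing.assert_allclose(instantaneous_speeds(tr, 1.0, 10), 0.0)

    def test_calibrated_single_step(self):
        tr = Track(id="C1", birth_frame=0, positions=[(0, 0), (3, 4)])
        v = instantaneous_speeds(tr, pixel_size_um=0.65, frame_interval_min=10)
        np.testing.assert_allclose(v, [19.5])

    def test_mean_speed_times_time_equals_distance(self, rng):
        for _ in range(50):
            tr = random_walk_track(rng, n_steps=int(rng.integers(2, 100)))
            v = instantaneous_speeds(tr, 0.65, 10.0)
            m = trajectory_measures(tr, 0.65, 10.0)
            assert v.mean() * m.trajectory_time_h == pytest.approx(
                m.total_distance_um, rel=1e-9)


class TestDirectionalityProperties:
    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_bounds_and_ordering(self, seed):
        rng = np.random.default_rng(seed)
        tr = random_walk_track(rng, n_steps=int(rng.integers(2, 60)))
        m = trajectory_measures(tr, 1.0, 10.0)
        assert m.displacement_um <= m.total_distance_um + 1e-9
        if not math.isnan(m.directionality):
            assert 0.0 <= m.directionality <= 1.0 + 1e-12

    def test_equals_one_only_for_monotone_collinear(self):
        back_and_forth = Track(id="C1", birth_frame=0,
                               positions=[(0, 0), (5, 0), (3, 0)])
        assert trajectory_measures(back_and_forth, 1, 10).directionality < 1.0


def _dividing_daughter(cid, parent, birth, div):
    t = Track(id=cid, parent_id=parent, birth_frame=birth,
              positions=[(0.0, 0.0)] * (div - birth + 1))
    t.division_frame = div
    t.end_reason = "divided"
    return t


class TestDoublingTimes:
    def test_arithmetic(self):
        root = _dividing_daughter("C1", None, 0, 29)
        root.daughter_ids = ["C1.1", "C1.2"]
        d1 = _dividing_daughter("C1.1", "C1", 30, 216)
        d1.daughter_ids = []
        d2 = Track(id="C1.2", parent_id="C1", birth_frame=30, positions=[(0, 0)] * 10)
        lin = build_lineage([root, d1, d2])
        dts = dict(doubling_times(lin, frame_interval_min=10))
        assert dts == {"C1.1": pytest.approx(31.0)}

    def test_empty_without_dividing_daughters(self):
        lin = build_lineage([Track(id="C1", birth_frame=0, positions=[(0, 0)] * 5)])
        assert doubling_times(lin, 10) == []

    def test_recovers_simulated_cycle_mean(self):
        params = SimulationParams(
            n_cells=50, n_frames=360, cycle_mean_h=24.0, cycle_sd_h=3.0)
        truth = simulate_lineage(params, seed=11)
        lin = build_lineage(truth.tracks)
        hours = [h for _, h in doubling_times(lin, params.frame_interval_min)]
        assert len(hours) >= 50
        assert abs(np.mean(hours) - 24.0) < 2.0

    def test_summary_mode_uses_frame_width_bins(self):
        s = summarize_durations([10.0, 10.05, 10.1, 30.0], frame_interval_min=10)
        assert abs(s["mode"] - 10.05) < 0.2
        assert s["n"] == 4


class TestDaughterPairs:
    def _pair(self, t1, t2, speeds=(10.0, 12.0)):
        root = _dividing_daughter("C1", None, 0, 0)
        root.daughter_ids = ["C1.1", "C1.2"]
        made = [root]
        for k, (hours, v) in enumerate(zip((t1, t2), speeds), start=1):
            n = int(hours * 6)  # 10-min frames
            step = v / 6.0  # px at 1 µm/px
            t = Track(id=f"C1.{k}", parent_id="C1", birth_frame=1,
                      positions=[(i * step, 0.0) for i in range(n + 1)])
            made.append(t)
        lin = build_lineage(made)
        measures = {
            t.id: trajectory_measures(t, 1.0, 10.0) for t in made if t.n_frames > 1
        }
        return lin, measures

    def test_speed_difference(self):
        lin, measures = self._pair(12, 12)
        df = daughter_pair_differences(lin, measures, PairFilter(10, 3))
        assert len(df) == 1
        assert df["d_avg_speed_um_h"].iloc[0] == pytest.approx(2.0)

    def test_filter_excludes_short_pair(self):
        lin, measures = self._pair(12, 4)
        assert len(daughter_pair_differences(lin, measures, PairFilter(10, 3))) == 0

    def test_identical_twins_zero_differences(self):
        lin, measures = self._pair(12, 12, speeds=(10.0, 10.0))
        df = daughter_pair_differences(lin, measures, PairFilter(10, 3))
        row = df.iloc[0]
        assert row["d_total_distance_um"] == 0 and row["d_avg_speed_um_h"] == 0


class TestDivisionSynchrony:
    def _lineage(self, div1, div2=None):
        root = _dividing_daughter("C1", None, 0, 0)
        root.daughter_ids = ["C1.1", "C1.2"]
        d1 = _dividing_daughter("C1.1", "C1", 1, div1)
        d1.daughter_ids = []
        if div2 is None:
            d2 = Track(id="C1.2", parent_id="C1", birth_frame=1, positions=[(0, 0)] * 50)
        else:
            d2 = _dividing_daughter("C1.2", "C1", 1, div2)
            d2.daughter_ids = []
        return build_lineage([root, d1, d2])

    def test_time_difference(self):
        assert division_synchrony(self._lineage(100, 112), 10) == [pytest.approx(2.0)]

    def test_one_daughter_excluded(self):
        assert division_synchrony(self._lineage(100), 10) == []

    def test_synchronous(self):
        assert division_synchrony(self._lineage(100, 100), 10) == [0.0]


class TestPhaseDurations:
    def test_fraction_counting(self):
        labels = ["G1"] * 22 + ["S"] * 59 + ["G2M"] * 19
        d = phase_durations(labels, 10)
        assert d["G1"]["fraction"] == pytest.approx(0.22)
        assert d["S"]["fraction"] == pytest.approx(0.59)
        assert d["G2M"]["fraction"] == pytest.approx(0.19)

    def test_single_phase(self):
        d = phase_durations(["S"] * 10, 10)
        assert d["S"]["fraction"] == 1.0

    def test_duration_arithmetic(self):
        d = phase_durations(["S"] * 30 + ["G1"], 20)
        assert d["S"]["duration_h"] == pytest.approx(10.0)

    def test_all_unknown_raises(self):
        with pytest.raises(ValueError):
            phase_durations(["Unknown"] * 5, 10)

    def test_durations_sum_to_trajectory_time(self, rng):
        labels = list(rng.choice(["G1", "S", "G2M", "Unknown"], size=60))
        labels[0] = "G1"
        d = phase_durations(labels, 10)
        total = sum(d[p]["duration_h"] for p in d)
        assert total == pytest.approx((len(labels)) * 10 / 60)


class TestPerPhaseDynamics:
    def test_constant_speed_all_phases(self):
        tr = straight_track(30, 1.0)
        labels = ["G1"] * 10 + ["S"] * 11 + ["G2M"] * 10
        dyn = per_phase_dynamics(tr, labels, 1.0, 10)
        for p in ("G1", "S", "G2M"):
            assert dyn[p]["mean_speed_um_h"] == pytest.approx(6.0)

    def test_straight_g2m_directionality(self):
        tr = straight_track(20, 2.0)
        labels = ["G1"] * 10 + ["G2M"] * 11
        dyn = per_phase_dynamics(tr, labels, 1.0, 10)
        assert dyn["G2M"]["directionality"] == pytest.approx(1.0)
        assert math.isnan(dyn["S"]["mean_speed_um_h"])

    def test_phase_specific_speeds(self):
        pos = [(0.0, 0.0)]
        for _ in range(10):
            pos.append((pos[-1][0] + 5 / 6, 0.0))  # 5 µm/h at 1 µm/px, 10 min
        for _ in range(10):
            pos.append((pos[-1][0] + 15 / 6, 0.0))  # 15 µm/h
        tr = Track(id="C1", birth_frame=0, positions=pos)
        labels = ["S"] * 10 + ["G2M"] * 11
        dyn = per_phase_dynamics(tr, labels, 1.0, 10)
        assert dyn["S"]["mean_speed_um_h"] == pytest.approx(5.0)
        assert dyn["G2M"]["mean_speed_um_h"] == pytest.approx(15.0)


def _divider_with_speeds(speeds_um_h, frame_interval_min=10.0, pixel_size_um=1.0):
    """Dividing track with prescribed step speeds, all G2M labels."""
    step_h = frame_interval_min / 60.0
    pos = [(0.0, 0.0)]
    for v in speeds_um_h:
        pos.append((pos[-1][0] + v * step_h / pixel_size_um, 0.0))
    t = Track(id="C1.1", parent_id=None, birth_frame=0, positions=pos)
    t.parent_id = None
    t.division_frame = t.last_frame
    t.end_reason = "divided"
    return t, ["G2M"] * len(pos)


class TestTerminalSpeedJump:
    def test_detects_qualifying_spike(self):
        # last 2 h: eleven steps at 8 µm/h, one at 30 inside the last hour
        speeds = [8.0] * 20
        speeds[-3] = 30.0
        tr, labels = _divider_with_speeds(speeds)
        flag, idx = detect_terminal_speed_jump(tr, labels, 1.0, 10.0)
        assert flag and idx == [len(speeds) - 3]

    def test_constant_speed_no_jump(self):
        tr, labels = _divider_with_speeds([8.0] * 20)
        flag, idx = detect_terminal_speed_jump(tr, labels, 1.0, 10.0)
        assert not flag and idx == []

    def test_subthreshold_spike_rejected(self):
        speeds = [8.0] * 20
        speeds[-3] = 20.0  # 2.5 × mean(9.83) = 24.6 > 20
        tr, labels = _divider_with_speeds(speeds)
        flag, _ = detect_terminal_speed_jump(tr, labels, 1.0, 10.0)
        assert not flag

    def test_neighbor_rule_rejects_broad_peak(self):
        speeds = [8.0] * 20
        speeds[-3] = 40.0
        speeds[-4] = 35.0  # adjacent step inside window too fast: 40 < 3×35
        tr, labels = _divider_with_speeds(speeds)
        flag, idx = detect_terminal_speed_jump(tr, labels, 1.0, 10.0)
        assert len(idx) <= 1 and (len(speeds) - 3) not in idx

    def test_spike_outside_g2m_ignored(self):
        speeds = [8.0] * 20
        speeds[-3] = 40.0
        tr, labels = _divider_with_speeds(speeds)
        labels = ["S"] * len(labels)
        flag, _ = detect_terminal_speed_jump(tr, labels, 1.0, 10.0)
        assert not flag

    def test_non_dividing_raises(self):
        tr = straight_track(20, 1.0)
        with pytest.raises(ValueError):
            detect_terminal_speed_jump(tr, ["G2M"] * 21, 1.0, 10.0)

    def test_short_track_raises(self):
        tr, labels = _divider_with_speeds([8.0] * 5)
        with pytest.raises(ValueError):
            detect_terminal_speed_jump(tr, labels, 1.0, 10.0)

    def test_no_false_positive_any_constant_baseline(self):
        for v in (1.0, 8.0, 25.0):
            tr, labels = _divider_with_speeds([v] * 30)
            flag, _ = detect_terminal_speed_jump(tr, labels, 1.0, 10.0)
            assert not flag

    def test_criterion_validation(self):
        with pytest.raises(ValueError):
            JumpCriterion(jump_window_h=3.0, baseline_window_h=2.0)
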