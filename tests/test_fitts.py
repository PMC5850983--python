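"""Target-acquisition task: difficulty indices, trial engine, metrics."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emg2kin import (
    TargetSpec,
    count_overshoots,
    generate_target_set,
    index_of_difficulty,
    log_from_trajectory,
    path_efficiency,
    path_length,
    run_trial,
    summarize,
    target_amplitude,
    throughput,
    trial_speed,
    truncate_id,
)
from emg2kin.fitts import rm_anova


class TestAmplitudeAndDifficulty:
    @pytest.mark.parametrize(
        "g1,g2,a",
        [(1.0, 1.0, 1.0), (0.0, 0.0, 0.0), (2.0, 0.0, 1.0)],
    )
    def test_amplitude_formula(self, g1, g2, a):
        assert target_amplitude(g1, g2) == pytest.approx(a)

    def test_unit_ratio_gives_one_bit(self):
        assert index_of_difficulty(0.08, 0.08) == pytest.approx(1.0)

    def test_nonpositive_width_is_an_error(self):
        with pytest.raises(ValueError, match="width"):
            index_of_difficulty(1.0, 0.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        a=st.floats(0.01, 10.0),
        da=st.floats(0.01, 5.0),
        w=st.floats(0.01, 1.0),
        dw=st.floats(0.01, 1.0),
    )
    def test_id_monotone_increasing_in_a_decreasing_in_w(self, a, da, w, dw):
        assert index_of_difficulty(a + da, w) > index_of_difficulty(a, w)
        assert index_of_difficulty(a, w + dw) < index_of_difficulty(a, w)

    def test_truncation_toward_zero(self):
        assert truncate_id(3.459) == 3.4
        assert truncate_id(4.0) == 4.0


class TestTargetSet:
    def test_amplitudes_realize_the_three_levels(self, targets):
        for t in targets:
            assert min(abs(t.amplitude - a) for a in (0.8, 1.2, 1.4)) < 1e-9

    def test_difficulties_at_one_decimal(self, targets):
        assert {t.id_truncated for t in targets} == {3.4, 4.0, 4.2}

    def test_fixed_seed_is_deterministic(self):
        a = generate_target_set(seed=123)
        b = generate_target_set(seed=123)
        assert [t.center for t in a] == [t.center for t in b]

    def test_twenty_targets_cover_all_quadrants_and_axes(self, targets):
        assert len(targets) == 20
        xs = np.array([t.center[0] for t in targets])
        ys = np.array([t.center[1] for t in targets])
        assert (xs > 0).any() and (xs < 0).any()
        assert (ys > 0).any() and (ys < 0).any()
        # single-DoF targets lie on each axis in both directions
        on_axis = [t for t in targets if t.gamma1 == 0 or t.gamma2 == 0]
        assert len(on_axis) > 0
        assert all(abs(t.amplitude - 1.2) < 1e-9 for t in on_axis)

    def test_centers_inside_workspace(self, targets):
        for t in targets:
            assert abs(t.center[0]) <= 1 and abs(t.center[1]) <= 1


def _target(cx=0.5, cy=0.0, w=0.08):
    return TargetSpec(center=(cx, cy), width=w, gamma1=1.0, gamma2=1.0)


def _traj(points):
    return log_from_trajectory(np.asarray(points, dtype=float), _target())


class TestTrialEngine:
    def test_cursor_held_on_target_succeeds_at_dwell(self):
        log = _traj([(0.5, 0.0)] * 10)
        assert log.success
        assert log.success_time == pytest.approx(0.3)
        assert count_overshoots(log) == 0

    def test_cursor_never_entering_fails_at_stream_end(self):
        log = _traj([(0.0, 0.0)] * 10)
        assert not log.success
        assert count_overshoots(log) == 0

    def test_timeout_flag_set_at_twenty_seconds(self):
        log = _traj([(0.0, 0.0)] * 205)
        assert not log.success and log.timed_out

    def test_enter_exit_enter_hold_counts_one_overshoot(self):
        # hand event trace: enter at t=0.1, exit at t=0.3, re-enter at t=0.4,
        # hold -> success at t=0.7; the first visit lasted 0.1 s < dwell
        points = [(0, 0), (0.5, 0), (0.5, 0), (0, 0)] + [(0.5, 0)] * 6
        log = _traj(points)
        assert log.success
        assert log.entries == [pytest.approx(0.1), pytest.approx(0.4)]
        assert log.exits == [pytest.approx(0.3)]
        assert count_overshoots(log) == 1

    def test_three_passes_then_timeout_count_three(self):
        visit = [(0.5, 0.0), (0.0, 0.0)]
        points = [(0.0, 0.0)] + visit * 3 + [(0.0, 0.0)] * 10
        log = _traj(points)
        assert not log.success
        assert count_overshoots(log) == 3

    def test_empty_stream_is_an_error(self, model):
        from emg2kin import AENPositionController

        ctl = AENPositionController(model)
        with pytest.raises(ValueError, match="empty"):
            run_trial(ctl, iter([]), _target())


class TestPathMetrics:
    def test_straight_line_gives_full_efficiency(self):
        points = [(x, 0.0) for x in np.linspace(0, 0.5, 6)] + [(0.5, 0.0)] * 4
        log = _traj(points)
        assert path_efficiency(log) == pytest.approx(100.0)

    def test_double_length_gives_half_efficiency(self):
        # detour: 0 -> -0.25 -> 0.5 travels 1.0 for a straight distance 0.5
        path = (
            list(np.linspace(0, -0.25, 3))
            + list(np.linspace(-0.25, 0.5, 7))[1:]
        )
        points = [(x, 0.0) for x in path] + [(0.5, 0.0)] * 4
        log = _traj(points)
        assert path_efficiency(log) == pytest.approx(50.0, rel=1e-9)

    def test_zigzag_length_matches_segment_sum_oracle(self, rng):
        pts = rng.uniform(-1, 1, size=(40, 2))
        pts[-5:] = [0.5, 0.0]
        log = _traj(pts)
        oracle = sum(
            math.hypot(*(pts[i + 1] - pts[i])) for i in range(len(pts) - 1)
        )
        if log.success:
            mask = log.times <= log.success_time
            oracle = sum(
                math.hypot(*(pts[i + 1] - pts[i]))
                for i in range(mask.sum() - 1)
            )
        assert path_length(log) == pytest.approx(oracle, rel=1e-9)

    def test_efficiency_capped_at_hundred(self):
        # stopping just inside the near rim travels less than the center distance
        points = [(x, 0.0) for x in np.linspace(0, 0.43, 5)] + [(0.43, 0.0)] * 5
        log = _traj(points)
        assert path_efficiency(log) == 100.0

    def test_speed_is_length_over_completion_time(self):
        points = [(x, 0.0) for x in np.linspace(0, 0.5, 11)] + [(0.5, 0.0)] * 3
        log = _traj(points)
        assert trial_speed(log) == pytest.approx(
            path_length(log) / log.completion_time
        )

    def test_failed_trial_has_no_speed_or_efficiency(self):
        log = _traj([(0.0, 0.0)] * 10)
        with pytest.raises(ValueError):
            trial_speed(log)
        with pytest.raises(ValueError):
            path_efficiency(log)


class TestThroughput:
    def test_ratio_examples(self):
        assert throughput(4.0, 2.0) == pytest.approx(2.0)
        assert throughput(4.2, 4.2) == pytest.approx(1.0)

    def test_zero_completion_time_is_an_error(self):
        with pytest.raises(ValueError):
            throughput(4.0, 0.0)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(id_bits=st.floats(0.1, 10.0), ct=st.floats(0.1, 20.0))
    def test_throughput_times_ct_recovers_id(self, id_bits, ct):
        assert throughput(id_bits, ct) * ct == pytest.approx(id_bits)


class TestSummarize:
    def test_identical_trials_report_single_trial_values(self):
        points = [(x, 0.0) for x in np.linspace(0, 0.5, 6)] + [(0.5, 0.0)] * 4
        logs = [_traj(points) for _ in range(5)]
        rep = summarize(logs)
        assert rep.completion_rate == 100.0
        assert rep.completion_time == pytest.approx(logs[0].completion_time)
        assert rep.path_efficiency == pytest.approx(path_efficiency(logs[0]))
        assert rep.throughput == pytest.approx(
            logs[0].target.id_bits / logs[0].completion_time
        )

    def test_nineteen_of_twenty_is_95_percent(self):
        good = [(x, 0.0) for x in np.linspace(0, 0.5, 6)] + [(0.5, 0.0)] * 4
        bad = [(0.0, 0.0)] * 10
        logs = [_traj(good) for _ in range(19)] + [_traj(bad)]
        assert summarize(logs).completion_rate == pytest.approx(95.0)

    def test_mixed_set_matches_per_trial_oracle(self, rng):
        logs = []
        for _ in range(12):
            pts = rng.uniform(-0.9, 0.9, size=(30, 2))
            if rng.uniform() < 0.7:
                pts[-6:] = [0.5, 0.0]
            logs.append(_traj(pts))
        rep = summarize(logs)
        succ = [lg for lg in logs if lg.success]
        assert rep.n_successful == len(succ)
        if succ:
            assert rep.completion_time == pytest.approx(
                np.mean([lg.completion_time for lg in succ])
            )
            assert rep.overshoots_total == sum(
                count_overshoots(lg) for lg in logs
            )


def test_rm_anova_wrapper_runs_on_toy_table(rng):
    rows = []
    for subj in range(4):
        for method in ("aen", "soa"):
            for idx in (3.4, 4.0, 4.2):
                rows.append(
                    {
                        "subject": subj,
                        "method": method,
                        "id": idx,
                        "ct": rng.uniform(1, 5),
                    }
                )
    res = rm_anova(pd.DataFrame(rows), dv="ct")
    table = res.anova_table
    assert {"method", "id", "method:id"} <= set(table.index)
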