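import numpy as np
import pandas as pd
import pytest

from _oracles import decile_times_bruteforce, knee_index_bruteforce
from rewardpace.operant import (
    OperantEvent,
    OperantLogError,
    OperantSession,
    average_repeated_tests,
    detect_press_bouts,
    find_interval_threshold,
    fr1_metrics,
    generate_pr_schedule,
    pr_metrics,
    read_operant_log,
    scree_knee_index,
    write_operant_log,
)


def session(schedule, events, duration=None, subject="r1"):
    evs = tuple(OperantEvent(t=float(t), kind=k) for t, k in sorted(events))
    return OperantSession(
        subject=subject, schedule=schedule, events=evs, session_duration=duration
    )


class TestPRSchedule:
    def test_printed_prefix(self):
        assert generate_pr_schedule(9).requirements == (1, 2, 4, 6, 9, 12, 15, 20, 25)

    def test_first_element(self):
        assert generate_pr_schedule(1).requirements == (1,)

    def test_tenth_element_from_progression(self):
        assert generate_pr_schedule(10)[9] == 32

    def test_strictly_increasing(self):
        r = generate_pr_schedule(30).requirements
        assert all(b > a for a, b in zip(r, r[1:]))

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            generate_pr_schedule(0)


class TestFR1Metrics:
    def test_mean_reward_interval_formula(self):
        s = session(
            "FR1",
            [(10, "active_press"), (10, "reward"), (100, "active_press"), (100, "reward")],
        )
        assert fr1_metrics(s).mean_reward_interval == 90.0

    def test_no_rewards(self):
        s = session("FR1", [(5, "inactive_press")])
        m = fr1_metrics(s)
        assert m.n_rewards == 0
        assert m.mean_reward_interval is None
        assert np.all(m.cumulative_curve == 0)
        assert m.reward_decile_times is None

    def test_decile_times_equally_spaced(self):
        times = [90.0 * k for k in range(1, 11)]
        s = session("FR1", [(t, "reward") for t in times])
        np.testing.assert_allclose(
            fr1_metrics(s).reward_decile_times, times
        )

    def test_decile_times_match_accumulation_oracle(self, rng):
        for _ in range(20):
            times = np.sort(rng.uniform(0, 1800, int(rng.integers(1, 40))))
            s = session("FR1", [(t, "reward") for t in times])
            np.testing.assert_allclose(
                fr1_metrics(s).reward_decile_times,
                decile_times_bruteforce(times),
            )

    def test_cumulative_curve_nondecreasing_ends_at_total(self, rng):
        times = np.sort(rng.uniform(0, 1800, 25))
        m = fr1_metrics(session("FR1", [(t, "reward") for t in times]))
        assert np.all(np.diff(m.cumulative_curve) >= 0)
        assert m.cumulative_curve[-1] == 25

    def test_wrong_schedule_rejected(self):
        with pytest.raises(OperantLogError):
            fr1_metrics(session("PR", []))


class TestIntervalThreshold:
    def test_default_fixed_mode_is_10s(self):
        assert find_interval_threshold([1.0, 2.0, 50.0]) == 10.0

    def test_bimodal_threshold_between_modes(self, rng):
        within = rng.lognormal(0.0, 0.3, 50)  # ~1 s
        between = rng.lognormal(np.log(60.0), 0.3, 50)  # ~60 s
        intervals = np.concatenate([within, between])
        th = find_interval_threshold(intervals, mode="auto")
        assert within.max() < th < between.min()

    def test_knee_index_matches_bruteforce(self, rng):
        for _ in range(20):
            y = np.sort(
                np.concatenate(
                    [rng.lognormal(0, 0.3, 40), rng.lognormal(4, 0.3, 15)]
                )
            )[::-1]
            assert scree_knee_index(y) == knee_index_bruteforce(y)

    def test_constant_intervals_fall_back_with_warning(self):
        with pytest.warns(UserWarning, match="no knee"):
            th = find_interval_threshold([5.0] * 10, mode="auto")
        assert th == 10.0

    def test_too_few_intervals_rejected(self):
        with pytest.raises(ValueError):
            find_interval_threshold([1.0, 2.0], mode="auto")


class TestPressBouts:
    def test_gap_scan_example(self):
        bouts = detect_press_bouts([0, 1, 2, 100, 101], threshold=10)
        assert [len(b) for b in bouts.bouts] == [3, 2]
        assert bouts.mean_presses_per_bout == 2.5

    def test_single_press(self):
        assert detect_press_bouts([5.0], 10).n_bouts == 1

    def test_all_gaps_below_threshold(self):
        assert detect_press_bouts([0, 1, 2, 3], 10).n_bouts == 1

    def test_gap_exactly_at_threshold_starts_new_bout(self):
        assert detect_press_bouts([0.0, 10.0], 10.0).n_bouts == 2

    def test_empty_input(self):
        assert detect_press_bouts([], 10).n_bouts == 0

    def test_extreme_thresholds(self, rng):
        times = np.sort(rng.uniform(0, 1800, 40))
        assert detect_press_bouts(times, np.inf).n_bouts == 1
        tiny = np.diff(times).min() / 2
        assert detect_press_bouts(times, tiny).n_bouts == 40

    def test_bouts_partition_the_presses(self, rng):
        times = np.sort(rng.uniform(0, 1800, 60))
        bouts = detect_press_bouts(times, 10.0)
        flat = [t for b in bouts.bouts for t in b]
        np.testing.assert_allclose(flat, times)


class TestPRMetrics:
    def test_mean_press_interval_formula(self):
        events = [(10.0 * k, "active_press") for k in range(1, 61)]
        events.append((600.0, "reward"))
        s = session("PR", events, duration=600.0)
        m = pr_metrics(s, generate_pr_schedule(5))
        assert m.mean_press_interval == pytest.approx(600.0 / 60)

    def test_breakpoint_is_last_completed_requirement(self):
        # rewards through requirement 9 (five rewards), none after
        events, t = [], 0.0
        for req in (1, 2, 4, 6, 9):
            for _ in range(req):
                t += 2.0
                events.append((t, "active_press"))
            events.append((t, "reward"))
        s = session("PR", events, duration=t + 1800.0)
        m = pr_metrics(s, generate_pr_schedule(12))
        assert m.n_rewards == 5
        assert m.breakpoint == 9

    def test_stop_rule_duration_matches_event_replay(self, rng):
        from rewardpace.simulate import OperantSimParams, simulate_operant

        for seed in range(10):
            sess, truth = simulate_operant(
                OperantSimParams(schedule="PR"), seed
            )
            m = pr_metrics(sess, generate_pr_schedule(12))
            # replay oracle: last reward + 30-min window, capped at the log end
            rewards = sess.times_of("reward")
            expected = min(sess.duration, rewards[-1] + 1800.0)
            assert m.test_duration == pytest.approx(expected)
            assert m.breakpoint == truth.breakpoint

    def test_zero_presses_interval_absent(self):
        s = session("PR", [], duration=100.0)
        assert pr_metrics(s, generate_pr_schedule(3)).mean_press_interval is None


class TestAverageRepeatedTests:
    def frame(self, rows):
        return pd.DataFrame(rows, columns=["subject", "treatment", "value"])

    def test_mean_of_two_tests(self):
        out = average_repeated_tests(
            self.frame([("r1", "VEH", 20.0), ("r1", "VEH", 30.0)]), "value"
        )
        assert out.loc[0, "value"] == 25.0
        assert out.loc[0, "n_tests"] == 2

    def test_single_test_flagged_not_imputed(self):
        out = average_repeated_tests(
            self.frame([("r1", "CNO", 12.0)]), "value"
        )
        assert out.loc[0, "value"] == 12.0
        assert out.loc[0, "n_tests"] == 1

    def test_three_tests_violate_design(self):
        with pytest.raises(OperantLogError, match="more than two"):
            average_repeated_tests(
                self.frame(
                    [("r1", "VEH", 1.0), ("r1", "VEH", 2.0), ("r1", "VEH", 3.0)]
                ),
                "value",
            )


def test_log_round_trip(tmp_path):
    s = session(
        "FR1",
        [(1.0, "active_press"), (1.0, "reward"), (2.5, "nosepoke"), (9.0, "inactive_press")],
    )
    f = tmp_path / "op.csv"
    write_operant_log(s, f)
    back = read_operant_log(f, subject="r1", schedule="FR1")
    assert back.events == s.events
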