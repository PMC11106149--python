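import numpy as np
import pytest

from _oracles import bruteforce_bouts, random_small_log
from rewardpace.copulation import (
    compute_measures,
    partition_series,
    segment_mount_bouts,
)
from rewardpace.ethogram import BehaviorEvent, CopulationTestLog
from rewardpace.simulate import CopulationSimParams, simulate_copulation

# the worked example: two bouts split by other_grooming, one 7-s time-out
WORKED_LOG = (
    ("mount", 10.0, 12.0),
    ("head_towards_female", 12.0, 20.0),
    ("intromission", 20.0, 23.0),
    ("other_grooming", 23.0, 30.0),
    ("mount", 30.0, 32.0),
    ("chasing", 32.0, 40.0),
    ("ejaculation", 40.0, 42.0),
)


class TestPartitionSeries:
    def test_single_series_with_pei(self, make_log):
        log = make_log(
            ("mount", 5.0, 5.0),
            ("intromission", 9.0, 9.0),
            ("ejaculation", 20.0, 20.0),
            ("mount", 60.0, 60.0),
        )
        series = partition_series(log)
        assert len(series) == 2
        s1 = series[0]
        assert (s1.start, s1.ejaculation_time) == (5.0, 20.0)
        assert s1.pei == 40.0
        assert series[1].start == 60.0 and not series[1].complete

    def test_no_ejaculation_yields_one_incomplete_series(self, make_log):
        log = make_log(("mount", 5.0, 6.0), ("intromission", 9.0, 10.0))
        series = partition_series(log)
        assert len(series) == 1
        assert series[0].ejaculation_time is None
        assert series[0].pei is None

    def test_no_copulatory_events_yields_zero_series(self, make_log):
        log = make_log(("chasing", 5.0, 6.0), ("other_grooming", 9.0, 10.0))
        assert partition_series(log) == []

    def test_two_complete_series_are_contiguous(self, make_log):
        log = make_log(
            ("mount", 5.0, 6.0),
            ("ejaculation", 20.0, 22.0),
            ("intromission", 100.0, 102.0),
            ("mount", 110.0, 112.0),
            ("ejaculation", 130.0, 133.0),
        )
        series = partition_series(log)
        assert [s.index for s in series] == [1, 2]
        assert all(s.complete for s in series)
        assert series[0].pei == 100.0 - 22.0
        # non-overlap: series 2 starts after series 1's ejaculation
        assert series[1].start > series[0].ejaculation_time


class TestSegmentMountBouts:
    def test_no_copulatory_events(self, make_log):
        log = make_log(("chasing", 5.0, 6.0))
        assert partition_series(log) == []

    def test_worked_example_two_bouts_one_timeout(self, make_log):
        log = make_log(*WORKED_LOG)
        (s1,) = partition_series(log)
        bouts, touts = segment_mount_bouts(log, s1)
        assert [(b.start, b.end) for b in bouts] == [(10.0, 23.0), (30.0, 42.0)]
        assert len(touts) == 1
        assert (touts[0].start, touts[0].end, touts[0].duration) == (23.0, 30.0, 7.0)

    def test_genital_grooming_does_not_split(self, make_log):
        log = make_log(
            ("mount", 10.0, 12.0),
            ("genital_grooming", 12.0, 18.0),
            ("mount", 18.0, 20.0),
        )
        (s1,) = partition_series(log)
        bouts, touts = segment_mount_bouts(log, s1)
        assert len(bouts) == 1 and touts == []
        assert (bouts[0].start, bouts[0].end) == (10.0, 20.0)

    def test_breaking_event_overlapping_a_copulatory_event_does_not_split(
        self, make_log
    ):
        # grooming wholly inside the mount interval never touches the gap
        log = make_log(
            ("mount", 10.0, 16.0),
            ("other_grooming", 12.0, 15.0),
            ("intromission", 18.0, 20.0),
        )
        (s1,) = partition_series(log)
        bouts, _ = segment_mount_bouts(log, s1)
        assert len(bouts) == 1

    def test_partition_property_on_synthetic_logs(self):
        # bout spans + time-out durations tile the copulatory extent
        for seed in range(20):
            log, _ = simulate_copulation(CopulationSimParams(), seed)
            for s in partition_series(log):
                bouts, touts = segment_mount_bouts(log, s)
                cop = [e for b in bouts for e in b.events]
                total = cop[-1].end - cop[0].start
                tiled = sum(b.span for b in bouts) + sum(
                    t.duration for t in touts
                )
                assert tiled == pytest.approx(total, abs=1e-9)

    def test_matches_bruteforce_oracle_on_random_logs(self, rng):
        for _ in range(500):
            log = random_small_log(rng)
            for s in partition_series(log):
                bouts, touts = segment_mount_bouts(log, s)
                cop = [e for b in bouts for e in b.events]
                ref_bouts, ref_touts = bruteforce_bouts(
                    cop, log.events_of(*log.vocabulary.bout_breaking)
                )
                assert [list(b.events) for b in bouts] == ref_bouts
                assert [(t.start, t.end) for t in touts] == ref_touts


class TestComputeMeasures:
    def test_intromission_ratio_formula(self, make_log):
        triples = [("mount", 10.0 * k, 10.0 * k + 1.0) for k in range(1, 11)]
        triples += [("intromission", 200.0 + 10 * k, 201.0 + 10 * k) for k in range(5)]
        triples += [("ejaculation", 300.0, 302.0)]
        m = compute_measures(make_log(*triples))
        assert m.n_mounts == 10 and m.n_intromissions == 5
        assert m.intromission_ratio == pytest.approx(5 / 15)

    def test_censoring_no_ejaculation(self, make_log):
        m = compute_measures(
            make_log(("mount", 100.0, 102.0), ("intromission", 150.0, 152.0))
        )
        assert m.latency_to_ejaculation == 1800.0
        assert m.latency_to_first_copulatory_behavior == 100.0

    def test_censoring_no_copulatory_behavior(self, make_log):
        m = compute_measures(make_log(("chasing", 5.0, 50.0)))
        assert m.latency_to_first_copulatory_behavior == 1800.0
        assert m.latency_to_ejaculation == 1800.0
        assert m.intromission_ratio is None  # undefined, not 0

    def test_worked_log_microstructure(self, make_log):
        m = compute_measures(make_log(*WORKED_LOG))
        assert m.n_mount_bouts == 2
        assert m.mean_timeout_duration == pytest.approx(7.0)
        assert m.n_ejaculations == 1
        assert m.latency_to_ejaculation == pytest.approx(30.0)  # 40 - 10

    def test_percent_time_until_first_ejaculation(self, make_log):
        # horizon = ejaculation onset at 40 s; other_grooming covers 7 s
        m = compute_measures(make_log(*WORKED_LOG))
        assert m.percent_time["other_grooming"] == pytest.approx(100 * 7 / 40)
        assert m.percent_non_copulation_oriented == pytest.approx(100 * 7 / 40)

    def test_monotone_censoring(self, make_log, rng):
        # appending an ejaculation can only decrease the latency
        for _ in range(50):
            log = random_small_log(rng)
            if not any(e.behavior in ("mount", "intromission") for e in log.events):
                continue
            before = compute_measures(log).latency_to_ejaculation
            t = max(e.end for e in log.events) + 1.0
            with_e = log.with_events(
                log.events + (BehaviorEvent(start=t, end=t, behavior="ejaculation"),)
            )
            after = compute_measures(with_e).latency_to_ejaculation
            assert after <= before
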