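import math

import numpy as np
import pytest

from rewardpace.copulation import (
    compute_measures,
    partition_series,
    segment_mount_bouts,
)
from rewardpace.ethogram import validate_log
from rewardpace.motivation import zone_occupancy
from rewardpace.operant import detect_press_bouts, find_interval_threshold
from rewardpace.simulate import (
    ArenaSimParams,
    CopulationSimParams,
    ImageSimParams,
    OperantSimParams,
    simulate_copulation,
    simulate_design_outcomes,
    simulate_operant,
    simulate_section_image,
    simulate_trace,
)


class TestCopulationGenerator:
    def test_deterministic_given_seed(self):
        a, _ = simulate_copulation(CopulationSimParams(), 123)
        b, _ = simulate_copulation(CopulationSimParams(), 123)
        assert a.events == b.events

    def test_generated_logs_are_valid(self):
        for seed in range(20):
            log, _ = simulate_copulation(CopulationSimParams(), seed)
            assert validate_log(log) == []

    def test_infinite_threshold_censors_latency(self):
        params = CopulationSimParams(intromission_threshold=math.inf)
        log, truth = simulate_copulation(params, 0)
        assert not any(e.behavior == "ejaculation" for e in log.events)
        assert compute_measures(log).latency_to_ejaculation == 1800.0

    def test_segmenter_recovers_ground_truth(self):
        # full recovery sweep lives in the acceptance suite
        for seed in range(100):
            log, truth = simulate_copulation(CopulationSimParams(), seed)
            series = partition_series(log)
            assert len(series) == len(truth.series)
            for s, gs in zip(series, truth.series):
                bouts, touts = segment_mount_bouts(log, s)
                gb = truth.bouts_of_series(gs.index)
                gt = truth.timeouts_of_series(gs.index)
                assert len(bouts) == len(gb)
                for b, g in zip(bouts, gb):
                    assert b.start == pytest.approx(g.start, abs=1e-9)
                    assert b.end == pytest.approx(g.end, abs=1e-9)
                assert len(touts) == len(gt)
                for t, g in zip(touts, gt):
                    assert t.duration == pytest.approx(
                        g.end - g.start, abs=1e-9
                    )

    def test_timeout_scale_lengthens_timeouts(self):
        base, scaled = [], []
        for seed in range(60):
            _, t0 = simulate_copulation(CopulationSimParams(), seed)
            _, t2 = simulate_copulation(
                CopulationSimParams().with_effects(timeout_scale=2.0), seed
            )
            base += [t.end - t.start for t in t0.timeouts]
            scaled += [t.end - t.start for t in t2.timeouts]
        ratio = np.mean(scaled) / np.mean(base)
        assert 1.6 < ratio < 2.5

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            CopulationSimParams(p_continue_bout=1.5)
        with pytest.raises(ValueError):
            CopulationSimParams(timeout_scale=0.0)


class TestOperantGenerator:
    def test_deterministic_given_seed(self):
        a, _ = simulate_operant(OperantSimParams(), 5)
        b, _ = simulate_operant(OperantSimParams(), 5)
        assert a.events == b.events

    def test_endless_bouts_yield_single_bout(self):
        _, truth = simulate_operant(
            OperantSimParams(bout_size_mean=math.inf), 0
        )
        assert truth.n_bouts == 1

    def test_fr1_trial_structure(self):
        sess, _ = simulate_operant(OperantSimParams(), 1)
        rewards = sess.times_of("reward")
        presses = sess.times_of("active_press")
        np.testing.assert_allclose(rewards, presses)  # FR1: 1 press = 1 reward

    def test_auto_threshold_recovers_partitions(self):
        # full 200-seed sweep lives in the acceptance suite
        ok = 0
        for seed in range(40):
            sess, truth = simulate_operant(OperantSimParams(), seed)
            presses = sess.times_of("active_press")
            th = find_interval_threshold(np.diff(presses), mode="auto")
            sizes = [len(b) for b in detect_press_bouts(presses, th).bouts]
            _, counts = np.unique(truth.bout_labels, return_counts=True)
            ok += sizes == list(counts)
        assert ok >= 38

    def test_overlapping_interval_modes_rejected(self):
        with pytest.raises(ValueError, match="stochastically larger"):
            OperantSimParams(within_mu=np.log(60.0), between_mu=np.log(30.0))


class TestArenaGenerator:
    def test_ledger_matches_analyzer_exactly(self):
        params = ArenaSimParams()
        for seed in range(5):
            trace, truth = simulate_trace(params, seed)
            occ = zone_occupancy(trace, params.zones)
            for zone in params.zones.zones:
                assert occ[zone].time_s == pytest.approx(
                    truth.time_in_zone[zone], abs=1e-9
                )
                assert occ[zone].entries == truth.entries[zone]

    def test_exclusive_female_dwell_gives_full_preference(self):
        params = ArenaSimParams(dwell_probs=(1.0, 0.0))
        _, truth = simulate_trace(params, 0)
        assert truth.preference_score == 1.0

    def test_symmetric_dwell_approaches_chance(self):
        params = ArenaSimParams(dwell_probs=(0.4, 0.4), duration=3600.0)
        scores = [
            simulate_trace(params, seed)[1].preference_score
            for seed in range(8)
        ]
        assert np.mean(scores) == pytest.approx(0.5, abs=0.05)

    def test_probabilities_validated(self):
        with pytest.raises(ValueError):
            ArenaSimParams(dwell_probs=(0.7, 0.6))


class TestImageGenerator:
    def test_deterministic_given_seed(self):
        a, ta = simulate_section_image(ImageSimParams(), 9)
        b, tb = simulate_section_image(ImageSimParams(), 9)
        np.testing.assert_array_equal(a, b)
        assert ta.equals(tb)

    def test_disks_never_overlap(self):
        _, table = simulate_section_image(ImageSimParams(n_disks=30), 4)
        pts = table[["row", "col"]].to_numpy()
        radii = table["radius"].to_numpy()
        for i in range(len(pts)):
            for j in range(i + 1, len(pts)):
                d = np.hypot(*(pts[i] - pts[j]))
                assert d > radii[i] + radii[j]

    def test_planted_area_matches_rendered_foreground(self):
        params = ImageSimParams(noise_sigma=0.0, background=0.0)
        img, table = simulate_section_image(params, 7)
        assert (img == 200).sum() == table["area_px"].sum()


class TestDesignOutcomes:
    def test_injected_effect_shifts_cno_minus_veh(self):
        df = simulate_design_outcomes(
            n_per_group=2000, effect_d={"Gi": 1.0}, sigma_diff=1.0, seed=0
        )
        wide = df.pivot_table(
            index=["virus", "subject"], columns="treatment", values="value"
        )
        diff = (wide["CNO"] - wide["VEH"]).groupby("virus").mean()
        # SE of a group mean difference is sigma_diff/sqrt(2000) ~ 0.022
        assert diff["Gi"] == pytest.approx(1.0, abs=0.1)
        assert abs(diff["Sham"]) < 0.1 and abs(diff["Gq"]) < 0.1

    def test_balanced_design(self):
        df = simulate_design_outcomes(n_per_group=12, seed=1)
        assert len(df) == 12 * 3 * 2
        assert set(df["treatment"]) == {"VEH", "CNO"}
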