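#!/usr/bin/env python
"""Post-hoc contrast families over the cohort's outcome measures.

For each key outcome (mean time-out duration, first PEI, FR1 rewards, PR
press interval, SIM preference score) runs the Bonferroni-corrected family:
paired CNO-vs-VEH within each virus group plus Gi-vs-Sham and Gq-vs-Sham on
the CNO cells.  Writes the tidy results/posthoc_contrasts.csv and reports
which contrasts the injected Gi x CNO effects reach.
"""

from __future__ import annotations

import argparse
import importlib
from pathlib import Path

import pandas as pd

from _cohort import RESULTS
from rewardpace.stats import posthoc_family, results_to_frame

OUTCOMES = {
    "copulation_measures.csv": ["mean_timeout_duration", "pei_1",
                                "latency_to_first_copulatory_behavior"],
    "sim_measures.csv": ["preference_score", "time_female_zone_s"],
    "operant_fr1.csv": ["n_rewards", "mean_reward_interval_s"],
    "operant_pr.csv": ["mean_press_interval_s", "breakpoint"],
}


def _table(name: str, seed: int) -> pd.DataFrame:
    path = RESULTS / name
    if not path.exists():
        driver = {
            "copulation_measures.csv": "02_copulation_microstructure",
            "sim_measures.csv": "03_incentive_motivation",
            "operant_fr1.csv": "04_operant_performance",
            "operant_pr.csv": "04_operant_performance",
        }[name]
        importlib.import_module(driver).main(seed)
    return pd.read_csv(path)


def main(seed: int = 0) -> pd.DataFrame:
    frames = []
    for name, outcomes in OUTCOMES.items():
        df = _table(name, seed)
        for outcome in outcomes:
            data = df.dropna(subset=[outcome])
            results = posthoc_family(data, outcome)
            frame = results_to_frame(results)
            frame.insert(0, "outcome", outcome)
            frames.append(frame)
    table = pd.concat(frames, ignore_index=True)
    RESULTS.mkdir(parents=True, exist_ok=True)
    table.to_csv(RESULTS / "posthoc_contrasts.csv", index=False)

    hits = table[table["p_adj"] < 0.05]
    print("contrasts significant after Bonferroni correction:")
    for _, row in hits.iterrows():
        print(
            f"  {row['outcome']:<38} {row['contrast']:<22} "
            f"p_adj = {row['p_adj']:.4f}"
        )
    print(f"\nwrote {RESULTS / 'posthoc_contrasts.csv'} ({len(table)} contrasts)")
    return table


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    main(ap.parse_args().seed)
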