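#!/usr/bin/env python
"""Copulation microstructure per subject x treatment.

Reads the cohort ethograms, computes every copulation outcome measure
(series-1 counts, intromission ratio, mount-bout composition, time-out and
PEI durations, censored latencies, percent-time budgets) and writes the
tidy table results/copulation_measures.csv with a group-level summary of
the pause measures on stdout.
"""

from __future__ import annotations

import argparse
import importlib

import pandas as pd

from _cohort import RESULTS, SCRATCH, TREATMENTS, subjects
from rewardpace.copulation import compute_measures
from rewardpace.ethogram import read_ethogram


def main(seed: int = 0) -> pd.DataFrame:
    if not SCRATCH.exists():
        importlib.import_module("01_simulate_cohort").main(seed)
    rows = []
    for subject, virus in subjects():
        for treatment in TREATMENTS:
            log = read_ethogram(SCRATCH / f"{subject}_{treatment}_ethogram.csv")
            row = compute_measures(log).to_row()
            row.update(virus=virus, treatment=treatment)
            rows.append(row)
    df = pd.DataFrame(rows)
    RESULTS.mkdir(parents=True, exist_ok=True)
    df.to_csv(RESULTS / "copulation_measures.csv", index=False)
    summary = (
        df.groupby(["virus", "treatment"])[
            ["n_ejaculations", "latency_to_ejaculation",
             "mean_timeout_duration", "pei_1"]
        ]
        .mean()
        .round(1)
    )
    print("group means (pause structure):")
    print(summary)
    print(f"\nwrote {RESULTS / 'copulation_measures.csv'} ({len(df)} tests)")
    return df


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    main(ap.parse_args().seed)
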