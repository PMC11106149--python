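#!/usr/bin/env python
"""Operant sucrose self-administration per subject x treatment.

Reads the cohort FR1 and PR logs, computes reward counts, the two pacing
interval formulas, press-bout structure at the fixed 10-s threshold, PR
breakpoints and stop-rule test durations; averages the two FR1 tests per
treatment; writes results/operant_fr1.csv and results/operant_pr.csv and a
group-mean FR1 cumulative-reward figure.
"""

from __future__ import annotations

import argparse
import importlib

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from _cohort import RESULTS, SCRATCH, TREATMENTS, subjects
from rewardpace.operant import (
    average_repeated_tests,
    detect_press_bouts,
    fr1_metrics,
    generate_pr_schedule,
    pr_metrics,
    read_operant_log,
)

BOUT_THRESHOLD = 10.0  # s, the published fixed inter-bout threshold


def main(seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    if not SCRATCH.exists():
        importlib.import_module("01_simulate_cohort").main(seed)
    schedule = generate_pr_schedule(12)
    fr1_rows, pr_rows, curves = [], [], {}
    for subject, virus in subjects():
        for treatment in TREATMENTS:
            tag = f"{subject}_{treatment}"
            for rep in (1, 2):
                sess = read_operant_log(
                    SCRATCH / f"{tag}_fr1_{rep}.csv", subject, "FR1"
                )
                m = fr1_metrics(sess)
                bouts = detect_press_bouts(
                    sess.times_of("active_press"), BOUT_THRESHOLD
                )
                fr1_rows.append(
                    {
                        "subject": subject, "virus": virus,
                        "treatment": treatment, "rep": rep,
                        "n_rewards": m.n_rewards,
                        "n_inactive": m.n_inactive,
                        "mean_reward_interval_s": m.mean_reward_interval,
                        "n_bouts": bouts.n_bouts,
                        "mean_presses_per_bout": bouts.mean_presses_per_bout,
                    }
                )
                curves.setdefault((virus, treatment), []).append(
                    m.cumulative_curve
                )
            sess = read_operant_log(SCRATCH / f"{tag}_pr.csv", subject, "PR")
            m = pr_metrics(sess, schedule)
            pr_rows.append(
                {
                    "subject": subject, "virus": virus, "treatment": treatment,
                    "n_rewards": m.n_rewards, "breakpoint": m.breakpoint,
                    "mean_press_interval_s": m.mean_press_interval,
                    "test_duration_s": m.test_duration,
                }
            )
    fr1 = pd.DataFrame(fr1_rows)
    pr = pd.DataFrame(pr_rows)
    RESULTS.mkdir(parents=True, exist_ok=True)
    fr1.to_csv(RESULTS / "operant_fr1.csv", index=False)
    pr.to_csv(RESULTS / "operant_pr.csv", index=False)

    averaged = average_repeated_tests(fr1, "n_rewards")
    print("FR1 rewards (mean of the two tests per treatment):")
    print(
        fr1.groupby(["virus", "treatment"])["n_rewards"].mean().round(1)
    )
    print("\nPR pacing:")
    print(
        pr.groupby(["virus", "treatment"])[
            ["breakpoint", "mean_press_interval_s"]
        ].mean().round(2)
    )

    fig, ax = plt.subplots(figsize=(6, 4))
    for (virus, treatment), cc in sorted(curves.items()):
        n = min(len(c) for c in cc)
        mean_curve = np.mean([c[:n] for c in cc], axis=0)
        ax.plot(mean_curve, label=f"{virus} {treatment}")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("cumulative rewards (group mean)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(RESULTS / "fr1_cumulative.png", dpi=120)
    print(f"\nwrote {RESULTS}/operant_fr1.csv, operant_pr.csv, fr1_cumulative.png")
    return averaged, pr


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    main(ap.parse_args().seed)
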