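#!/usr/bin/env python
"""c-Fos+ particle counts in the cohort's section images.

Applies one global threshold to every image, counts filtered particles
(5-2000 px, circularity 0.5-1.0) in a left and a right ROI box, averages
across hemispheres, writes results/cfos_counts.csv, and compares Gq vs
Sham densities with the one-tailed two-sample procedure (t, or
Mann-Whitney U when an F-test rejects equal variances).
"""

from __future__ import annotations

import argparse
import importlib

import pandas as pd
import tifffile

from _cohort import RESULTS, SCRATCH
from rewardpace.cfos import RoiBox, binarize, count_particles, hemisphere_average
from rewardpace.stats import one_tailed_comparison

GLOBAL_THRESHOLD = 120  # one threshold shared by every image of the batch
ROIS = [
    RoiBox("BNST", "left", x0=12, y0=24, width=170, height=336),
    RoiBox("BNST", "right", x0=202, y0=24, width=170, height=336),
]


def main(seed: int = 0) -> pd.DataFrame:
    if not SCRATCH.exists():
        importlib.import_module("01_simulate_cohort").main(seed)
    rows = []
    for path in sorted(SCRATCH.glob("section_*.tiff")):
        virus = "Gq" if "Gq" in path.stem else "Sham"
        binary = binarize(tifffile.imread(path), GLOBAL_THRESHOLD)
        triples = []
        for roi in ROIS:
            count, _ = count_particles(binary, roi=roi)
            triples.append((roi.region, roi.hemisphere, count))
        (rc,) = hemisphere_average(triples)
        rows.append(
            {
                "section": path.stem, "virus": virus,
                "left": rc.left, "right": rc.right, "mean_count": rc.mean,
            }
        )
    df = pd.DataFrame(rows)
    RESULTS.mkdir(parents=True, exist_ok=True)
    df.to_csv(RESULTS / "cfos_counts.csv", index=False)

    gq = df.loc[df["virus"] == "Gq", "mean_count"]
    sham = df.loc[df["virus"] == "Sham", "mean_count"]
    r = one_tailed_comparison(gq, sham, direction="greater")
    print(df.groupby("virus")["mean_count"].agg(["mean", "std"]).round(1))
    print(
        f"\nGq > Sham ({r.method}): statistic = {r.statistic:.2f}, "
        f"one-tailed p = {r.p_raw:.4f}"
    )
    print(f"wrote {RESULTS / 'cfos_counts.csv'} ({len(df)} sections)")
    return df


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    main(ap.parse_args().seed)
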