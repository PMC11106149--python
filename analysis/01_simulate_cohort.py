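#!/usr/bin/env python
"""Generate the synthetic study cohort: all four input streams per subject.

Writes, under scratch/cohort/: one copulation ethogram and one SIM tracking
trace per subject x treatment, two FR1 and one PR operant log per
subject x treatment, and a handful of stained-section images; plus the
design table results/design.csv that every later driver joins against.
"""

from __future__ import annotations

import argparse

import pandas as pd
import tifffile

from _cohort import (
    RESULTS,
    SCRATCH,
    TREATMENTS,
    arena_params,
    copulation_params,
    operant_params,
    subjects,
    test_seed,
)
from rewardpace.ethogram import write_ethogram
from rewardpace.operant import write_operant_log
from rewardpace.simulate import (
    ImageSimParams,
    simulate_copulation,
    simulate_operant,
    simulate_section_image,
    simulate_trace,
)


def main(seed: int = 0) -> pd.DataFrame:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)
    rows = []
    for subject, virus in subjects():
        for treatment in TREATMENTS:
            tag = f"{subject}_{treatment}"
            log, _ = simulate_copulation(
                copulation_params(virus, treatment),
                test_seed(seed, subject, treatment, "cop"),
                subject=subject,
            )
            write_ethogram(log, SCRATCH / f"{tag}_ethogram.csv")
            trace, _ = simulate_trace(
                arena_params(virus, treatment),
                test_seed(seed, subject, treatment, "sim"),
            )
            trace.to_csv(SCRATCH / f"{tag}_trace.csv")
            for rep in (1, 2):
                session, _ = simulate_operant(
                    operant_params(virus, treatment, "FR1"),
                    test_seed(seed, subject, treatment, "fr1", rep),
                    subject=subject,
                )
                write_operant_log(session, SCRATCH / f"{tag}_fr1_{rep}.csv")
            session, _ = simulate_operant(
                operant_params(virus, treatment, "PR", subject),
                test_seed(seed, subject, treatment, "pr"),
                subject=subject,
            )
            write_operant_log(session, SCRATCH / f"{tag}_pr.csv")
            rows.append(
                {"subject": subject, "virus": virus, "treatment": treatment}
            )
    # a small imaging arm: 6 Gq + 6 Sham sections (CNO homecage condition)
    for i in range(12):
        virus = "Gq" if i < 6 else "Sham"
        n_disks = 40 if virus == "Gq" else 18  # activation raises density
        img, table = simulate_section_image(
            ImageSimParams(n_disks=n_disks), (seed * 977 + i) % (2**31)
        )
        tifffile.imwrite(SCRATCH / f"section_{virus}{i:02d}.tiff", img)
        table.to_csv(SCRATCH / f"section_{virus}{i:02d}_truth.csv", index=False)
    design = pd.DataFrame(rows)
    design.to_csv(RESULTS / "design.csv", index=False)
    print(
        f"cohort: {design['subject'].nunique()} subjects x {len(TREATMENTS)} "
        f"treatments; streams under {SCRATCH}"
    )
    return design


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    main(ap.parse_args().seed)
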