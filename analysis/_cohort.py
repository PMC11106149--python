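"""Shared definition of the synthetic study cohort used by the drivers.

Three virus groups (Sham, Gi, Gq) of 12 subjects, each tested under VEH and
CNO.  Injected effects mirror the qualitative pattern the pipeline is meant
to resolve: under Gi x CNO the copulatory pauses lengthen (time-outs, PEI),
copulation starts later, operant pressing slows, and female-zone dwell
drops.  Sham and Gq cells stay at the null.
"""

from __future__ import annotations

from pathlib import Path

from rewardpace.simulate import (
    ArenaSimParams,
    CopulationSimParams,
    OperantSimParams,
)

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "cohort"
RESULTS = ROOT / "results"

VIRUS_GROUPS = ("Sham", "Gi", "Gq")
TREATMENTS = ("VEH", "CNO")
N_PER_GROUP = 12


def subjects():
    for virus in VIRUS_GROUPS:
        for k in range(N_PER_GROUP):
            yield f"{virus}{k:02d}", virus


def copulation_params(virus: str, treatment: str) -> CopulationSimParams:
    base = CopulationSimParams()
    if virus == "Gi" and treatment == "CNO":
        return base.with_effects(
            timeout_scale=1.6, pei_scale=1.5, initial_latency_mean=120.0
        )
    return base


def operant_params(
    virus: str, treatment: str, schedule: str, subject: str = ""
) -> OperantSimParams:
    base = OperantSimParams(schedule=schedule)
    if schedule == "PR":
        # stable per-subject quit point (6-10 rewards): breakpoints vary
        # across rats but not with treatment, as observed empirically
        base = OperantSimParams(
            schedule="PR", pr_max_rewards=6 + _fnv(subject) % 5
        )
    if virus == "Gi" and treatment == "CNO":
        return base.with_effects(interval_scale=1.4)
    return base


def arena_params(virus: str, treatment: str) -> ArenaSimParams:
    if virus == "Gi" and treatment == "CNO":
        return ArenaSimParams(dwell_probs=(0.32, 0.20))
    return ArenaSimParams()


def _fnv(key: str) -> int:
    h = 2166136261
    for ch in key.encode():
        h = ((h ^ ch) * 16777619) & 0xFFFFFFFF
    return h


def test_seed(base_seed: int, subject: str, treatment: str, stream: str, rep: int = 0) -> int:
    """Stable per-test seed below 2**31."""
    h = _fnv(f"{subject}|{treatment}|{stream}|{rep}")
    return (base_seed * 1_000_003 + h) % (2**31)
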