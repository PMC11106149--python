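# rewardpace

Microstructure analysis of natural-reward seeking in male rats: from
annotated behavior logs, arena tracking traces, operant timestamp logs and
brain-section images to the pacing and motivation measures used in
chemogenetic (DREADD) studies of reward behavior.

## What it computes

Behavioral studies of sexual behavior and sucrose self-administration
increasingly rest on *temporal patterning* rather than raw counts: how
copulation is organized into **mount bouts** separated by **time-outs**,
how long the **post-ejaculatory interval** (PEI) lasts, how operant
responding clusters into **press bouts**, and how fast rewards are
collected. This package implements that analysis layer end to end:

* **Copulation** — segmentation of scored ethograms into ejaculation
  series, mount bouts (runs of mounts/intromissions uninterrupted by any
  non-female-oriented behavior, genital grooming exempt) and time-outs;
  intromission ratio I/(M+I), per-bout composition, PEI, latencies censored
  at the 1800-s test end, percent-time budgets.
* **Incentive motivation (SIM)** — zone occupancy, entries, preference
  score t_female/(t_female + t_male), and locomotion from tracking traces.
* **Operant sessions** — FR1/PR metrics: mean reward interval
  (t_last − t_first)/(n − 1), mean press interval T/n_presses, cumulative
  curves, reward deciles, press bouts via a fixed 10-s or automatic
  scree-knee inter-bout threshold, and progressive-ratio breakpoints on the
  r_j = round(5·e^(0.2j)) − 5 schedule (1, 2, 4, 6, 9, 12, 15, 20, 25, …).
* **c-Fos counting** — global thresholding, 8-connected particle filtering
  (area 5–2000 px, circularity 0.5–1.0), hemisphere-averaged ROI counts.
* **Statistics** — the post-hoc contrast layer: one-sample and paired
  t-tests, Bonferroni-corrected within/between families, one-tailed
  comparisons with a Mann-Whitney fallback under unequal variances.
* **Synthetic data** — semi-Markov generators for all four input streams
  with exact ground truth, so every stage is verifiable without raw data.

See `docs/methods.md` for the definitions, conventions and generator
models in full.

## Worked example

Segment a small scored log: a mount at 10–12 s, an intromission at
20–23 s (the head-towards-female gap between them does not break the
bout), non-genital grooming at 23–30 s (which does), then a second bout
ending in ejaculation at 40–42 s.

```python
from rewardpace.ethogram import BehaviorEvent, CopulationTestLog
from rewardpace.copulation import compute_measures, partition_series, segment_mount_bouts

events = tuple(sorted(
    BehaviorEvent(start=s, end=e, behavior=b) for b, s, e in [
        ("mount", 10, 12), ("head_towards_female", 12, 20),
        ("intromission", 20, 23), ("other_grooming", 23, 30),
        ("mount", 30, 32), ("chasing", 32, 40), ("ejaculation", 40, 42),
    ]))
log = CopulationTestLog(subject="demo", events=events)

(s1,) = partition_series(log)
bouts, touts = segment_mount_bouts(log, s1)
print("bouts:", [(b.start, b.end) for b in bouts])
print("time-outs:", [(t.start, t.end, t.duration) for t in touts])

m = compute_measures(log)
print("n_mount_bouts:", m.n_mount_bouts)
print("mean_timeout_duration:", m.mean_timeout_duration)
print("intromission_ratio:", round(m.intromission_ratio, 3))
print("latency_to_ejaculation:", m.latency_to_ejaculation)
```

prints

```
bouts: [(10, 23), (30, 42)]
time-outs: [(23, 30, 7)]
n_mount_bouts: 2
mean_timeout_duration: 7.0
intromission_ratio: 0.333
latency_to_ejaculation: 30
```

Two bouts `[10, 23]` and `[30, 42]` split by the grooming gap, one 7-s
time-out, one intromission against two mounts (ratio 1/3), and a 30-s
latency from the first mount to the ejaculation onset.

The same operations are available from the shell:

```bash
rewardpace simulate copulation --seed 3 --out demo/
rewardpace ethogram validate demo/ethogram.csv
rewardpace copulation analyze demo/ethogram.csv
rewardpace operant analyze session.csv --schedule FR1 --bout-threshold 10
```

## Analysis drivers

`analysis/` holds the numbered drivers of the full synthetic study (three
virus groups × 12 subjects × two treatments, with effects injected only in
the Gi × CNO cell):

```bash
cd analysis
python 01_simulate_cohort.py --seed 0   # all four input streams -> scratch/
python 02_copulation_microstructure.py  # -> results/copulation_measures.csv
python 03_incentive_motivation.py       # -> results/sim_measures.csv
python 04_operant_performance.py        # -> results/operant_fr1.csv, operant_pr.csv
python 05_cfos_quantification.py        # -> results/cfos_counts.csv
python 06_posthoc_contrasts.py          # -> results/posthoc_contrasts.csv
```

Each driver prints what it found; the post-hoc table localizes the
injected effects to the pause/pacing measures (time-outs, PEI, reward
intervals) while counts-per-bout and breakpoints stay flat.

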