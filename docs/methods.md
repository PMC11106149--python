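# Methods

This note documents the models, conventions, and numerical choices behind
`rewardpace`, and what the synthetic-data validation does and does not show
about real data.

## Copulation microstructure

Male rat copulation is organized in **ejaculation series**: mounts and
intromissions in rapid succession culminating in an ejaculation, then a
post-ejaculatory interval (PEI) of inactivity before the next series.
Within a series, copulatory events cluster in **mount bouts** — sequences of
one or more copulatory behaviors uninterrupted by any behavior that is not
oriented towards the female, with genital autogrooming exempt. The gaps
between consecutive bouts are **time-outs**.

The segmenter operates on a closed behavior vocabulary partitioned into
three classes (copulatory / bout-breaking / bout-neutral); the class table
is configuration, because segmentation semantics depend entirely on class
membership. For each consecutive pair of copulatory events, the open gap
between the end of the earlier and the start of the later is scanned: the
bout is split iff a bout-breaking event intersects that open interval (a
point event must fall strictly inside it). Events wholly overlapping a
copulatory event cannot split, since copulatory annotation is exclusive. A
bout therefore ends at the end of its last copulatory member, the next bout
starts at the onset of the next copulatory event, and the gap is recorded as
a time-out. The ejaculation belongs to (and terminates) the final bout of
its series; it is excluded from mount/intromission counts and ratios. The
interval before the first copulatory behavior and the PEI are never
time-outs.

Conventions where interval annotation leaves slack:

* latency to ejaculation runs from the **onset** of the first
  mount/intromission to the **onset** of the ejaculation;
* the PEI runs from the **offset** of the ejaculation to the onset of the
  next mount or intromission (for point-annotated events the conventions
  coincide);
* the PEI is taken strictly as ejaculation-to-next-copulatory-event;
  non-copulatory behavior during the PEI does not enter its definition;
* series-1 measures use events from the series start through its
  ejaculation, inclusive.

Censoring: a 30-min (1800 s) test with no ejaculation scores latency to
ejaculation as 1800 s; a test with no copulatory behavior at all scores
latency to first copulatory behavior as 1800 s. Undefined ratios (zero
mounts and intromissions) are reported as absent, never as 0. Percent-time
budgets divide by the time from test start to the first ejaculation (the
full 1800 s when none is reached); "non-copulation-oriented" time is the
sum of the bout-breaking budgets (non-genital grooming + head not towards
female). Tests invalidated externally (e.g. a non-receptive stimulus
female) are flagged in the design table, never inferred from the log.

## Incentive motivation (SIM)

The arena is 100 x 50 cm with two 30 x 21 cm stimulus zones; the subject is
in a zone whenever its tracked center of gravity is. Zones are half-open
rectangles `[x0, x1) x [y0, y1)` so boundary points belong to at most one
zone. Occupancy time attributes each inter-sample interval to the zone
containing the earlier sample (left-constant interpolation, matching
sample-based tracker exports; no sub-sample interpolation of crossings).
Entries count outside-to-inside transitions, the first in-zone sample
included; no minimum-visit filter is applied. Preference score =
t_female / (t_female + t_male), absent when both are zero; chance level is
0.5. Locomotion is the Euclidean step sum and its time average.

## Operant sessions

Under FR1 every active press earns a reward and sessions last 1800 s; under
PR the j-th reward requires `r_j = round(5 * exp(0.2 * j)) - 5` presses
(1, 2, 4, 6, 9, 12, 15, 20, 25, 32, ...; rounding half away from zero, as
the progression is conventionally tabulated), and a session ends when the
rat fails to earn the next reward within 30 min of the last. The recorded
PR test duration is the last reward time + 1800 s, unless the log ends
earlier, in which case the recorded end is used.

Pacing measures follow the fixed conventions: FR1 mean reward interval =
(last reward − first reward)/(n − 1), absent below 2 rewards; PR mean
lever-press interval = test duration / number of active presses; cumulative
reward curves in 1-s bins; decile times are the timestamps of the
`ceil(0.1·k·n)`-th reward. The PR breakpoint is the requirement of the last
obtained reward.

**Press bouts.** Active presses are split into bouts at inter-press
intervals at or above a threshold; a gap exactly at the threshold starts a
new bout (deterministic tie-break). The default threshold is the fixed
10 s used for the published analyses. The automatic alternative sorts all
intervals descending (a scree plot), normalizes both axes to [0, 1], and
finds the knee as the point of maximum perpendicular distance to the chord
joining the extremes. That point sits where the scree slope matches the
chord slope — for a flat within-bout tail this is a few ranks past the
corner, inside the small-interval mode — so the returned threshold is the
midpoint of the steepest adjacent drop within a ±3-rank window of the knee,
which for bimodal interval data is the gap between the between-bout and
within-bout modes. For unimodal interval data the local drops are small and
the returned value is close to the knee value itself. All-equal intervals
have no knee; the fixed threshold is returned with a warning. When deriving
thresholds from real data they should be pooled per animal under vehicle
conditions only.

FR1 outcome measures are variable across sessions, so subjects are tested
twice per treatment and per-subject values are the mean of the two tests;
a missing second test is flagged, never imputed, and a third test is a
design violation.

## c-Fos quantification

Section images are reduced to 8-bit, binarized at one global threshold per
experiment (a configuration input — the appropriate value depends on the
staining batch), and connected components are extracted with 8-connectivity
(the reference tool's default). Particles are filtered by area (5–2000 px,
inclusive) and circularity 4πA/P², kept within [0.5, 1.0]. The perimeter
estimator is the weighted boundary-crack length of scikit-image; it differs
from other tools' estimators by small per-shape amounts, so circularity of
discretized shapes carries tolerance and values above 1 (small round
objects) are capped at 1. Particles touching the ROI edge are kept by
default (configurable). Counts from fixed, same-shape ROI boxes are
averaged across hemispheres per region; a region with one usable hemisphere
is reported with that value and flagged.

## Statistics

The omnibus model (linear mixed model on virus x treatment(× condition)
cell means with a random subject intercept) is deliberately pluggable: it
is an off-the-shelf fit, and the package implements the contrast layer that
annotates figures. The post-hoc family for an outcome is: paired CNO vs VEH
within each virus group (3 tests) plus independent-samples Gi vs Sham and
Gq vs Sham on the CNO cells (2 tests), Bonferroni-corrected with family
size m = the number of tests emitted (5 by default, configurable — the
appropriate family size is a design choice).

Two-sample contrasts use pooled variance by default (Welch optional).
One-tailed c-Fos comparisons use an independent-samples t-test, replaced by
a one-tailed Mann-Whitney U when a two-sided variance-ratio F-test rejects
equal variances at α = 0.05. A paired test on identical samples returns
t = 0, p = 1 (no effect); a constant non-zero difference raises, since the
t statistic is undefined there. Preference scores are tested against the
0.5 chance level with a one-sample t-test per design cell.

## Synthetic data

The generators exist so that every stage can be validated against exact
ground truth; they emulate structure, not physiology.

**Copulation** is an explicit semi-Markov chain over {mount bout, time-out,
PEI} macro-states — the simplest structure whose ground truth is exact for
the segmenter. Within a bout, copulatory events (intromission probability
0.5, durations 1–3 s) are separated by log-normal within-bout intervals
(median 12 s), optionally filled with bout-neutral behavior strictly inside
the gap. With probability 0.4 after each event the bout ends in a time-out
(log-normal, median 45 s) that always contains a bout-breaking event
strictly inside the gap — otherwise it would not be a time-out by
definition. An ejaculation fires once 8 intromissions accumulate, followed
by a log-normal PEI (median 300 s) before the next series; the test
truncates at 1800 s. Defaults are chosen so medians resemble figure-scale
magnitudes for sexually experienced male rats (a handful of
mounts/intromissions per bout, ~2 ejaculations per test, time-outs of tens
of seconds, PEI of minutes); no claim of distributional fidelity is made.
Per-design-cell multipliers (`timeout_scale`, `pei_scale`, …) inject
effects for end-to-end recovery experiments.

**Operant** sessions emit press bouts (geometric size, mean 5) with
log-normal within-bout intervals (median 1.5 s) and between-bout intervals
(median 60 s); the constraint that within-bout intervals are stochastically
smaller than between-bout intervals is validated at construction. FR1
replays the trial structure (press → reward → nosepoke before the next
press); PR replays the requirement ladder with a per-rat quit point and the
30-min stop rule. `interval_scale` slows all pressing for effect injection.

**Arena traces** use a semi-Markov dwell model over {female zone, male
zone, elsewhere} (default dwell probabilities 0.45/0.20/0.35, exponential
dwell, mean 15 s, 10 Hz sampling, 600 s). Positions random-walk strictly
inside the current region (zones shrunk by a 2 cm margin), so the
analyzer's half-open membership agrees with the generator's state sequence
sample for sample and the occupancy ledger is exact, not merely
approximate.

**Section images** plant non-overlapping disks (radii 5–15 px, intensity
200) on Gaussian background noise (mean 40, σ 8), so any threshold between
the noise ceiling and the disk intensity separates all disks; the planted
table carries exact positions and pixel areas.

All generators are deterministic given a seed, and ground truth is emitted
in the same vocabulary/format the analysis stages consume.

**What passing recovery tests shows — and does not.** Exact recovery on
synthetic logs shows the segmenter implements the stated definitions
without boundary or tie errors. It does not show robustness to annotation
noise (mislabeled or shifted events), overlapping state behaviors,
tracker jitter across zone boundaries, uneven staining, or touching cells:
none of these are emulated. The generators produce cleanly separated
within/between interval modes; on real press data with overlapping modes
the automatic knee threshold degrades gracefully toward an arbitrary split,
which is why the fixed 10-s threshold remains the default.

## Numerical choices and problem sizes

* Times are float seconds from test start; recovery comparisons use an
  absolute tolerance of 1e-9 s.
* Ethogram CSVs are written with `%.17g` and read with round-trip float
  parsing, so write∘read is the identity.
* Validation suite scales: segmentation vs. brute-force oracle on 10,000
  randomized small logs (≤ 12 events); copulation ground-truth recovery
  over 1,000 seeds; operant partition recovery over 200 seeds (≥ 95%
  required; 199/200 observed); type-I calibration at 10,000 null
  replicates (0.05 ± 0.01); within-subject effect detection over 500
  replicate experiments at n = 12 per group, d = 1 on the paired
  difference (power ≥ 0.8 at α = 0.05, uncorrected — the within-subject
  contrast is the designated test for an injected within-subject effect).
* The analysis drivers use a cohort of 3 × 12 subjects × 2 treatments with
  effects injected only in the Gi × CNO cell (time-outs × 1.6, PEI × 1.5,
  first-copulation latency × 2, operant intervals × 1.4, female dwell
  0.45 → 0.32), chosen to mirror the qualitative pattern the pipeline is
  meant to resolve.

## Known limitations

* No inference about annotation quality: the pipeline consumes scored
  event logs and trusts them (video scoring and inter-rater reliability
  are out of scope).
* The c-Fos stage does not promise pixel-for-pixel parity with ImageJ's
  particle analyzer; perimeter estimators differ, so counts of borderline
  particles (circularity near 0.5, area near 5 px) can disagree.
* The omnibus mixed model is not fitted here; families are corrected with
  Bonferroni only, and the family size on real analyses is a reporting
  decision.
* Generator realism is structural, not physiological; absolute magnitudes
  in the drivers' outputs are illustrative.
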