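"""Independent reference implementations used only to check the package.

Each oracle is deliberately written as direct enumeration / brute force over
the definitions, staying independent of the code paths it validates.
"""

from __future__ import annotations

import numpy as np

from rewardpace.ethogram import BehaviorEvent, CopulationTestLog, DEFAULT_VOCABULARY


def bruteforce_bouts(cop_events, breaking_events):
    """Gap-scan oracle for mount-bout segmentation.

    For every consecutive copulatory pair, a boundary is declared iff any
    bout-breaking event intersects the open gap between them.  Returns
    (list of bouts as event lists, list of (start, end) time-outs).
    """
    cop = sorted(cop_events, key=lambda e: (e.start, e.end))
    if not cop:
        return [], []
    boundaries = []
    for i in range(len(cop) - 1):
        lo, hi = cop[i].end, cop[i + 1].start
        hit = False
        for b in breaking_events:
            if b.start == b.end:
                if lo < b.start < hi:
                    hit = True
            else:
                overlap = min(hi, b.end) - max(lo, b.start)
                if overlap > 0:
                    hit = True
        boundaries.append(hit)
    bouts, current = [], [cop[0]]
    timeouts = []
    for i, hit in enumerate(boundaries):
        if hit:
            bouts.append(current)
            timeouts.append((cop[i].end, cop[i + 1].start))
            current = [cop[i + 1]]
        else:
            current.append(cop[i + 1])
    bouts.append(current)
    return bouts, timeouts


def random_small_log(rng, max_events=12, horizon=120.0):
    """A randomized small copulation log (copulatory events never overlap)."""
    voc = DEFAULT_VOCABULARY
    labels = sorted(voc.labels)
    n = int(rng.integers(1, max_events + 1))
    events = []
    t_cop = 0.0  # running lower bound keeping copulatory events disjoint
    for _ in range(n):
        label = labels[int(rng.integers(len(labels)))]
        dur = 0.0 if rng.random() < 0.3 else float(rng.uniform(0.2, 6.0))
        if label in voc.copulatory:
            start = t_cop + float(rng.uniform(0.1, 10.0))
            t_cop = start + dur
        else:
            start = float(rng.uniform(0.0, horizon))
        end = start + dur
        if end > 1800.0:
            continue
        events.append(BehaviorEvent(start=start, end=end, behavior=label))
    return CopulationTestLog(subject="rand", events=tuple(sorted(events)))


def knee_index_bruteforce(y_desc):
    """Max perpendicular distance to the chord, computed point by point."""
    y = np.asarray(y_desc, dtype=float)
    n = len(y)
    xs = np.arange(n) / (n - 1)
    ys = (y - y[-1]) / (y[0] - y[-1])
    x1, y1, x2, y2 = 0.0, 1.0, 1.0, 0.0
    best, best_i = -1.0, 0
    for i in range(n):
        d = abs(
            (y2 - y1) * xs[i] - (x2 - x1) * ys[i] + x2 * y1 - y2 * x1
        ) / np.hypot(y2 - y1, x2 - x1)
        if d > best:
            best, best_i = d, i
    return best_i


def decile_times_bruteforce(reward_times):
    """Direct accumulation: earliest time reaching each 10% of total rewards."""
    rt = np.sort(np.asarray(reward_times, dtype=float))
    n = len(rt)
    out = []
    for k in range(1, 11):
        needed = k * n / 10.0
        count = 0
        for t in rt:
            count += 1
            if count >= needed:
                out.append(t)
                break
    return np.array(out)


def mannwhitney_u_bruteforce(a, b):
    """U statistic of sample a: count of pairs a_i > b_j (+0.5 per tie)."""
    u = 0.0
    for x in a:
        for y in b:
            if x > y:
                u += 1.0
            elif x == y:
                u += 0.5
    return u
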