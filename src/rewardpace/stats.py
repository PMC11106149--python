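"""Post-hoc contrast layer for the chemogenetic design.

The experimental design crosses a between-subject virus factor (Sham, Gi,
Gq) with a within-subject treatment factor (VEH, CNO), optionally under a
deprivation condition.  The omnibus model (a linear mixed model on the
virus x treatment cell means with a random intercept per subject) is an
off-the-shelf fit and stays pluggable; this module implements the contrast
layer that annotates the figures:

* one-sample t-tests (preference score against chance, 0.5);
* paired t-tests (within-subject CNO vs VEH; female vs male zone);
* the Bonferroni-corrected post-hoc family: paired CNO-vs-VEH within each
  virus group plus independent-samples Gi-vs-Sham and Gq-vs-Sham contrasts
  on the CNO cells (family size m = number of tests emitted, 5 by default,
  configurable);
* one-tailed independent-samples comparisons for c-Fos densities, with a
  one-tailed Mann-Whitney U fallback when an F-test rejects equal variances.

All tests run through scipy.stats; results carry the raw and adjusted p so
the family correction is explicit and auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ContrastResult",
    "one_sample_t",
    "paired_t",
    "independent_t",
    "one_tailed_comparison",
    "bonferroni",
    "posthoc_family",
    "results_to_frame",
]

VIRUS_GROUPS = ("Sham", "Gi", "Gq")


@dataclass(frozen=True)
class ContrastResult:
    """One test in a contrast family, before/after Bonferroni adjustment."""

    label: str
    estimate: float
    statistic: float
    df: Optional[float]
    p_raw: float
    p_adj: Optional[float] = None
    m: Optional[int] = None
    method: str = "t"

    def adjusted(self, m: int) -> "ContrastResult":
        return replace(self, p_adj=min(1.0, m * self.p_raw), m=m)


def _as_clean_array(values: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if np.any(np.isnan(arr)):
        arr = arr[~np.isnan(arr)]
    return arr


def one_sample_t(
    values: Sequence[float], mu: float, label: str = "one-sample"
) -> ContrastResult:
    """One-sample t-test of the mean against *mu* (two-sided)."""
    arr = _as_clean_array(values, "values")
    n = len(arr)
    if n < 2:
        raise ValueError("one-sample t-test requires n >= 2")
    if np.all(arr == arr[0]):
        raise ValueError("zero variance: t statistic undefined")
    res = sps.ttest_1samp(arr, popmean=mu)
    return ContrastResult(
        label=label,
        estimate=float(arr.mean() - mu),
        statistic=float(res.statistic),
        df=float(n - 1),
        p_raw=float(res.pvalue),
    )


def paired_t(
    a: Sequence[float], b: Sequence[float], label: str = "paired"
) -> ContrastResult:
    """Paired t-test: one-sample t on the differences a - b against 0."""
    a_arr = np.asarray(a, dtype=float)
    b_arr = np.asarray(b, dtype=float)
    if a_arr.shape != b_arr.shape:
        raise ValueError("paired samples must have equal length")
    keep = ~(np.isnan(a_arr) | np.isnan(b_arr))
    a_arr, b_arr = a_arr[keep], b_arr[keep]
    if len(a_arr) < 2:
        raise ValueError("paired t-test requires n >= 2 complete pairs")
    diffs = a_arr - b_arr
    if np.all(diffs == diffs[0]):
        if diffs[0] == 0:  # identical samples: no effect, not an error
            return ContrastResult(
                label=label,
                estimate=0.0,
                statistic=0.0,
                df=float(len(diffs) - 1),
                p_raw=1.0,
            )
        raise ValueError("zero variance of differences: t statistic undefined")
    res = sps.ttest_rel(a_arr, b_arr)
    return ContrastResult(
        label=label,
        estimate=float(diffs.mean()),
        statistic=float(res.statistic),
        df=float(len(diffs) - 1),
        p_raw=float(res.pvalue),
    )


def independent_t(
    a: Sequence[float],
    b: Sequence[float],
    label: str = "independent",
    welch: bool = False,
    alternative: Literal["two-sided", "greater", "less"] = "two-sided",
) -> ContrastResult:
    """Independent-samples t-test (pooled variance by default)."""
    a_arr = _as_clean_array(a, "a")
    b_arr = _as_clean_array(b, "b")
    if len(a_arr) < 2 or len(b_arr) < 2:
        raise ValueError("independent t-test requires n >= 2 per group")
    res = sps.ttest_ind(
        a_arr, b_arr, equal_var=not welch, alternative=alternative
    )
    df = res.df if hasattr(res, "df") else len(a_arr) + len(b_arr) - 2
    return ContrastResult(
        label=label,
        estimate=float(a_arr.mean() - b_arr.mean()),
        statistic=float(res.statistic),
        df=float(df),
        p_raw=float(res.pvalue),
    )


def equal_variance_f_test(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided p of the variance-ratio F-test for equal variances."""
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    if va == 0 and vb == 0:
        return 1.0
    if vb == 0 or (va >= vb and vb > 0):
        f, dfn, dfd = va / vb if vb > 0 else np.inf, len(a) - 1, len(b) - 1
    else:
        f, dfn, dfd = vb / va, len(b) - 1, len(a) - 1
    if not np.isfinite(f):
        return 0.0
    return float(min(1.0, 2.0 * sps.f.sf(f, dfn, dfd)))


def one_tailed_comparison(
    a: Sequence[float],
    b: Sequence[float],
    direction: Literal["greater", "less"] = "greater",
    label: str = "one-tailed",
    variance_alpha: float = 0.05,
) -> ContrastResult:
    """One-tailed two-group comparison with a rank-based fallback.

    An independent-samples t-test with one-tailed p in the stated direction
    (of group *a* relative to *b*); when a variance-ratio F-test rejects
    equal variances at *variance_alpha*, a one-tailed Mann-Whitney U test is
    used instead.
    """
    a_arr = _as_clean_array(a, "a")
    b_arr = _as_clean_array(b, "b")
    if len(a_arr) < 2 or len(b_arr) < 2:
        raise ValueError("comparison requires n >= 2 per group")
    if np.var(a_arr, ddof=1) == 0 and np.var(b_arr, ddof=1) == 0:
        raise ValueError("both groups degenerate (zero variance)")
    if equal_variance_f_test(a_arr, b_arr) < variance_alpha:
        res = sps.mannwhitneyu(a_arr, b_arr, alternative=direction)
        return ContrastResult(
            label=label,
            estimate=float(np.median(a_arr) - np.median(b_arr)),
            statistic=float(res.statistic),
            df=None,
            p_raw=float(res.pvalue),
            method="mann-whitney",
        )
    return independent_t(a_arr, b_arr, label=label, alternative=direction)


def bonferroni(
    results: Sequence[ContrastResult], m: Optional[int] = None
) -> list[ContrastResult]:
    """Bonferroni-adjust a family: p_adj = min(1, m * p_raw)."""
    family_size = m if m is not None else len(results)
    return [r.adjusted(family_size) for r in results]


def posthoc_family(
    design: pd.DataFrame,
    outcome: str,
    subject: str = "subject",
    virus: str = "virus",
    treatment: str = "treatment",
    m: Optional[int] = None,
) -> list[ContrastResult]:
    """The post-hoc family for one outcome measure.

    Emits the paired CNO-vs-VEH contrast within each virus group and the
    independent Gi-vs-Sham and Gq-vs-Sham contrasts on the CNO cells, then
    Bonferroni-adjusts over the family (m = number of tests emitted unless
    given).  Raises on an empty design cell.
    """
    for col in (subject, virus, treatment, outcome):
        if col not in design.columns:
            raise KeyError(f"missing column {col!r}")
    results: list[ContrastResult] = []
    for group in VIRUS_GROUPS:
        cell = design[design[virus] == group]
        if cell.empty:
            raise ValueError(f"empty design cell: virus {group!r}")
        wide = cell.pivot_table(
            index=subject, columns=treatment, values=outcome, aggfunc="mean"
        )
        for level in ("CNO", "VEH"):
            if level not in wide.columns:
                raise ValueError(
                    f"empty design cell: virus {group!r}, treatment {level!r}"
                )
        paired = wide.dropna(subset=["CNO", "VEH"])
        results.append(
            paired_t(
                paired["CNO"], paired["VEH"], label=f"{group}: CNO vs VEH"
            )
        )
    cno = design[design[treatment] == "CNO"]

    def _cno_values(group: str) -> pd.Series:
        return cno[cno[virus] == group].groupby(subject)[outcome].mean()

    sham_cno = _cno_values("Sham")
    for group in ("Gi", "Gq"):
        results.append(
            independent_t(
                _cno_values(group), sham_cno, label=f"{group} vs Sham (CNO)"
            )
        )
    return bonferroni(results, m=m)


def results_to_frame(results: Sequence[ContrastResult]) -> pd.DataFrame:
    """Tidy results table (one row per contrast)."""
    return pd.DataFrame(
        {
            "contrast": [r.label for r in results],
            "estimate": [r.estimate for r in results],
            "statistic": [r.statistic for r in results],
            "df": [r.df for r in results],
            "p_raw": [r.p_raw for r in results],
            "p_adj": [r.p_adj for r in results],
            "m": [r.m for r in results],
            "method": [r.method for r in results],
        }
    )
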