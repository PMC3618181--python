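"""Test-retest reliability and agreement statistics for V_T tables.

Retest variability is the absolute test/retest difference divided by the
pair mean (in percent).  The intraclass correlation coefficient follows the
one-way random-effects mean-square form

    ICC = (BSMSS - WSMSS) / (BSMSS + WSMSS)

with BSMSS the between-subject and WSMSS the within-subject mean of summed
squares over the k = 2 replicates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .io_core import SubjectMeta, log


@dataclass(frozen=True)
class VTTable:
    """Subject x region matrix of distribution volumes (mL/cm^3)."""

    subjects: Sequence[SubjectMeta]
    regions: Sequence[str]
    values: np.ndarray
    method: str = "logan_full"  # 2tcm_full | logan_full | logan_pbif

    def __post_init__(self):
        v = np.asarray(self.values, float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "subjects", list(self.subjects))
        object.__setattr__(self, "regions", list(self.regions))
        if v.shape != (len(self.subjects), len(self.regions)):
            raise ValueError(
                f"values shape {v.shape} does not match {len(self.subjects)} "
                f"subjects x {len(self.regions)} regions")
        if not np.all(np.isfinite(v)):
            raise ValueError("V_T values must be finite")
        if np.any(v <= 0):
            raise ValueError("V_T values must be positive")

    @property
    def subject_ids(self) -> list[str]:
        return [s.subject_id for s in self.subjects]

    def subject_means(self) -> np.ndarray:
        return self.values.mean(axis=1)

    def reordered_like(self, other: "VTTable") -> "VTTable":
        """Reorder rows to match another table's subject ids."""
        idx = {sid: i for i, sid in enumerate(self.subject_ids)}
        order = [idx[sid] for sid in other.subject_ids]
        return VTTable(subjects=[self.subjects[i] for i in order],
                       regions=self.regions, values=self.values[order],
                       method=self.method)


@dataclass(frozen=True)
class RetestStats:
    """Per-region (variability %, ICC) plus their unweighted region means."""

    per_region: dict
    overall_variability_pct: float
    overall_icc: float


def retest_variability(v1: float, v2: float) -> float:
    """Percent test-retest variability: 100 |v1 - v2| / mean(v1, v2)."""
    if v1 <= 0 or v2 <= 0:
        raise ValueError("retest variability needs positive measurements")
    return 100.0 * abs(v1 - v2) / (0.5 * (v1 + v2))


def icc(test, retest) -> float:
    """One-way random-effects ICC for paired measurements.

    BSMSS = k * sum_j (ybar_j - ybar)^2 / (n - 1) with k = 2 replicates;
    WSMSS = sum_jk (y_jk - ybar_j)^2 / n.  Returns 0 (with a warning) when
    there is no variance at all.
    """
    a = np.asarray(test, float)
    b = np.asarray(retest, float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("icc needs two equal-length vectors of >= 2 subjects")
    n = a.size
    pair_mean = 0.5 * (a + b)
    grand = pair_mean.mean()
    bsmss = 2.0 * np.sum((pair_mean - grand) ** 2) / (n - 1)
    wsmss = (np.sum((a - pair_mean) ** 2) + np.sum((b - pair_mean) ** 2)) / n
    denom = bsmss + wsmss
    if denom == 0:
        warnings.warn("zero total variance; ICC defined as 0")
        return 0.0
    return float((bsmss - wsmss) / denom)


def cohort_retest_stats(test: VTTable, retest: VTTable) -> RetestStats:
    """Per-region retest variability (mean over subjects) and ICC, plus
    unweighted region means as the overall summary."""
    if test.regions != retest.regions:
        raise ValueError("region sets differ between test and retest tables")
    if set(test.subject_ids) != set(retest.subject_ids):
        raise ValueError("subject sets differ between test and retest tables")
    retest = retest.reordered_like(test)
    per_region = {}
    for j, region in enumerate(test.regions):
        a, b = test.values[:, j], retest.values[:, j]
        var_pct = float(np.mean([retest_variability(x, y) for x, y in zip(a, b)]))
        per_region[region] = (var_pct, icc(a, b))
    overall_var = float(np.mean([v for v, _ in per_region.values()]))
    overall_icc = float(np.mean([i for _, i in per_region.values()]))
    log.debug("cohort_retest_stats overall var=%.1f%% icc=%.3f",
              overall_var, overall_icc)
    return RetestStats(per_region=per_region,
                       overall_variability_pct=overall_var,
                       overall_icc=overall_icc)


def concordance(x: VTTable, y: VTTable, pool: str = "all"):
    """Agreement between two V_T tables for the same subjects.

    Returns (r_squared, mean_ratio, sd_ratio): least-squares R^2 over all
    subject-region pairs (``pool='all'``) or over subject means
    (``pool='subject_means'``), and the mean +/- SD of the per-subject ratio
    of region-mean V_T (y relative to x).
    """
    if x.values.shape != y.values.shape or x.regions != y.regions:
        raise ValueError("tables must have matching subjects and regions")
    y = y.reordered_like(x)
    if pool == "all":
        a, b = x.values.ravel(), y.values.ravel()
    elif pool == "subject_means":
        a, b = x.subject_means(), y.subject_means()
    else:
        raise ValueError(f"unknown pool {pool!r}")
    r = stats.pearsonr(a, b).statistic
    ratios = y.subject_means() / x.subject_means()
    return float(r ** 2), float(ratios.mean()), float(ratios.std(ddof=1))
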