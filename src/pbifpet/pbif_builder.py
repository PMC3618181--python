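"""Population-based input function (PBIF) construction and individual scaling.

A PBIF is the pointwise mean (with SD) of a cohort of peak-aligned, fitted,
SUV-normalised input functions evaluated on the standard grid.  Applying it to
a new subject requires no arterial line: the population shape is rescaled by a
single factor estimated from two late venous/arterial samples, by default at
15 and 60 min.  The sample-time pair itself is chosen as the one whose summed
parent activity best correlates (Pearson) with total input-function AUC across
a calibration cohort.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .io_core import SubjectMeta, log_stage
from .input_function import FittedInputFunction, StandardGrid, align_peak, resample


@dataclass(frozen=True)
class PBIF:
    """Population mean input function on a standard grid.

    ``excluded_subject`` records a leave-one-out build (the left-out subject
    must never contribute to the mean that is later scaled to them).
    """

    grid: StandardGrid
    mean: np.ndarray
    sd: np.ndarray
    n: int
    excluded_subject: Optional[str] = None

    def __post_init__(self):
        m = np.asarray(self.mean, float)
        s = np.asarray(self.sd, float)
        object.__setattr__(self, "mean", m)
        object.__setattr__(self, "sd", s)
        if m.shape != self.grid.times.shape or s.shape != m.shape:
            raise ValueError("mean/sd length must match the grid")
        if np.any(m < -1e-12):
            raise ValueError("PBIF mean must be non-negative")
        if np.any(s < -1e-12):
            raise ValueError("PBIF sd must be non-negative")
        if self.n < 1:
            raise ValueError("PBIF needs n >= 1")

    def value_at(self, t) -> np.ndarray:
        """Linear interpolation of the mean curve at arbitrary times."""
        return np.interp(np.asarray(t, float), self.grid.times, self.mean)


@dataclass(frozen=True)
class ScaledInputFunction:
    """A PBIF rescaled to one subject from a pair of blood samples (SUV)."""

    pbif: PBIF
    scale: float
    sample_times: tuple
    sample_values: tuple
    subject: SubjectMeta

    def __post_init__(self):
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    @property
    def times(self) -> np.ndarray:
        return self.pbif.grid.times

    @property
    def values(self) -> np.ndarray:
        return self.scale * self.pbif.mean


def build_pbif(curves: Sequence[FittedInputFunction], grid: StandardGrid,
               leave_out: Optional[str] = None) -> PBIF:
    """Average a cohort of fitted input functions into a PBIF.

    Curves are peak-aligned to their common mean peak time, evaluated on the
    grid, then averaged pointwise; SD uses the n-1 denominator.  With
    ``leave_out``, that subject's curve is dropped before averaging.
    """
    curves = list(curves)
    ids = [c.subject_id for c in curves]
    if len(set(ids)) != len(ids):
        raise ValueError("subject ids must be unique in the PBIF cohort")
    if leave_out is not None:
        if leave_out not in ids:
            raise ValueError(f"leave_out subject {leave_out!r} not in cohort")
        curves = [c for c in curves if c.subject_id != leave_out]
    if len(curves) < 2:
        raise ValueError("need >= 2 curves to build a PBIF")
    aligned = align_peak(curves)
    samples = np.vstack([resample(c, grid) for c in aligned])
    mean = samples.mean(axis=0)
    sd = samples.std(axis=0, ddof=1)
    log_stage("build_pbif", n=len(curves), leave_out=leave_out)
    return PBIF(grid=grid, mean=mean, sd=sd, n=len(curves),
                excluded_subject=leave_out)


DEFAULT_SAMPLE_TIMES = (15.0, 60.0)


def scale_pbif(pbif: PBIF, samples: Sequence[tuple],
               subject: SubjectMeta | None = None,
               method: str = "least_squares") -> ScaledInputFunction:
    """Rescale a PBIF to an individual from measured blood samples.

    ``samples`` is a sequence of (time_min, SUV) pairs, by default taken at 15
    and 60 min.  The scale is the one-parameter least-squares fit

        s = sum(m_i p_i) / sum(p_i^2)

    of the measurements ``m_i`` against the PBIF values ``p_i`` at the sample
    times.  ``method='mean_ratio'`` instead averages the per-sample ratios
    m_i/p_i; both are exact when the subject's curve is a scalar multiple of
    the PBIF.
    """
    ts = np.array([t for t, _ in samples], float)
    ms = np.array([m for _, m in samples], float)
    if np.any(ms <= 0):
        raise ValueError("blood sample values must be positive")
    ps = pbif.value_at(ts)
    if np.any(ps <= 0):
        raise ValueError("PBIF is zero at a sample time; cannot scale")
    if method == "least_squares":
        s = float(np.dot(ms, ps) / np.dot(ps, ps))
    elif method == "mean_ratio":
        s = float(np.mean(ms / ps))
    else:
        raise ValueError(f"unknown scale method {method!r}")
    return ScaledInputFunction(
        pbif=pbif, scale=s, sample_times=tuple(ts), sample_values=tuple(ms),
        subject=subject or SubjectMeta("anon"))


def select_sample_pair(curves: Sequence[FittedInputFunction],
                       candidate_times: Sequence[float] = (
                           10, 15, 20, 30, 40, 50, 60, 75, 90),
                       predictor: str = "sum"):
    """Choose the two sample times whose combined parent activity best
    predicts total input-function AUC across the cohort.

    For every unordered pair (t_a, t_b) the per-subject predictor is
    m(t_a) + m(t_b) (normalised SUV read off each subject's fitted curve) and
    the response is the subject's fitted AUC(0-120).  Returns the pair with
    the highest Pearson r (ties broken by lexicographically earliest pair)
    and the full correlation table as a dict {(t_a, t_b): r}.

    ``predictor='auc_of_scaled_pbif'`` instead correlates the total AUC of a
    leave-one-out PBIF scaled by that pair of samples with the true AUC.
    """
    curves = list(curves)
    if len(curves) < 3:
        raise ValueError("need >= 3 subjects to correlate")
    cands = sorted(float(t) for t in candidate_times)
    if len(cands) < 2:
        raise ValueError("need >= 2 candidate times")
    y = np.array([c.auc(0, 120) for c in curves])
    table: dict = {}
    if predictor == "sum":
        vals = {t: np.array([c.value(t) for c in curves]) for t in cands}
        for ta, tb in combinations(cands, 2):
            x = vals[ta] + vals[tb]
            table[(ta, tb)] = _pearson(x, y)
    elif predictor == "auc_of_scaled_pbif":
        from .input_function import default_grid
        grid = default_grid()
        for ta, tb in combinations(cands, 2):
            x = np.empty(len(curves))
            for j, c in enumerate(curves):
                loo = build_pbif(curves, grid, leave_out=c.subject_id)
                sif = scale_pbif(loo, [(ta, c.value(ta)), (tb, c.value(tb))])
                x[j] = np.trapezoid(sif.values, sif.times)
            table[(ta, tb)] = _pearson(x, y)
    else:
        raise ValueError(f"unknown predictor {predictor!r}")
    # round so exact ties (e.g. perfectly proportional cohorts) resolve to the
    # lexicographically earliest pair rather than float noise
    best = max(sorted(table), key=lambda k: round(table[k], 12))
    return best, table


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if np.std(x) == 0:
        raise ValueError("degenerate (zero-variance) predictor")
    if np.std(y) == 0:
        return 0.0
    return float(stats.pearsonr(x, y).statistic)
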