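"""End-to-end drivers tying the stages together for whole cohorts.

The two quantification routes share everything up to the input function:

* full-input: each subject's own plasma curve is SUV-normalised, fitted, and
  used as the Logan input;
* PBIF: a population curve (built from healthy subjects, leave-one-out where
  the subject contributed to it) is rescaled from the subject's measured 15-
  and 60-min samples and used instead.

In both routes the input is converted back to the subject's kBq/mL scale
before the Logan fit, matching the units of the measured tissue curves.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .input_function import (FittedInputFunction, StandardGrid, default_grid,
                             fit_input_function, normalize_to_suv, suv_factor)
from .io_core import log_stage
from .kinetics import logan_vt
from .pbif_builder import PBIF, build_pbif, scale_pbif
from .reliability_stats import VTTable
from .synthetic_data import SyntheticCohort

DEFAULT_T_STAR = 30.0


def fit_cohort_ifs(cohort: SyntheticCohort) -> list[FittedInputFunction]:
    """SUV-normalise and fit every subject's measured plasma curve."""
    fitted = []
    for rec in cohort.subjects:
        curve = rec.plasma
        if curve is None:
            raise ValueError(f"{rec.meta.subject_id}: cohort was generated "
                             "without plasma curves")
        if curve.parent_fraction is not None:
            from .input_function import apply_parent_fraction
            curve = apply_parent_fraction(curve)
        if curve.units != "SUV":
            curve = normalize_to_suv(curve)
        fitted.append(fit_input_function(curve))
    return fitted


def logan_full_table(cohort: SyntheticCohort,
                     fitted: Optional[Sequence[FittedInputFunction]] = None,
                     t_star: float = DEFAULT_T_STAR) -> VTTable:
    """Logan V_T for every subject and region using each subject's own
    fitted arterial input."""
    if fitted is None:
        fitted = fit_cohort_ifs(cohort)
    rows = []
    for rec, fif in zip(cohort.subjects, fitted):
        f = suv_factor(rec.meta)
        fif_kbq = fif.scaled(f)
        rows.append([
            logan_vt(rec.tacs.column(r), rec.tacs.frame_starts,
                     rec.tacs.frame_ends, fif_kbq, t_star=t_star).vt
            for r in cohort.regions])
    log_stage("logan_full_table", n=len(rows), t_star=t_star)
    return VTTable(subjects=[rec.meta for rec in cohort.subjects],
                   regions=list(cohort.regions), values=np.array(rows),
                   method="logan_full")


def measured_suv_samples(rec, times: Sequence[float]) -> list[tuple]:
    """Read the subject's measured plasma (SUV) at the scaling sample times."""
    curve = rec.plasma
    if curve.units != "SUV":
        curve = normalize_to_suv(curve)
    vals = np.interp(np.asarray(times, float), curve.times,
                     curve.concentrations)
    return list(zip([float(t) for t in times], [float(v) for v in vals]))


def logan_pbif_table(cohort: SyntheticCohort, pbif: PBIF,
                     sample_times: Sequence[float] = (15.0, 60.0),
                     t_star: float = DEFAULT_T_STAR) -> VTTable:
    """Logan V_T with the PBIF rescaled per subject from two blood samples."""
    rows = []
    for rec in cohort.subjects:
        sif = scale_pbif(pbif, measured_suv_samples(rec, sample_times),
                         subject=rec.meta)
        f = suv_factor(rec.meta)
        input_kbq = (sif.times, sif.values * f)
        rows.append([
            logan_vt(rec.tacs.column(r), rec.tacs.frame_starts,
                     rec.tacs.frame_ends, input_kbq, t_star=t_star).vt
            for r in cohort.regions])
    log_stage("logan_pbif_table", n=len(rows), t_star=t_star)
    return VTTable(subjects=[rec.meta for rec in cohort.subjects],
                   regions=list(cohort.regions), values=np.array(rows),
                   method="logan_pbif")


def healthy_pbif(cohort: SyntheticCohort,
                 grid: Optional[StandardGrid] = None,
                 fitted: Optional[Sequence[FittedInputFunction]] = None,
                 leave_out: Optional[str] = None) -> PBIF:
    """Build the population input function from a (healthy) cohort's fitted
    curves on the standard grid."""
    if fitted is None:
        fitted = fit_cohort_ifs(cohort)
    return build_pbif(fitted, grid or default_grid(), leave_out=leave_out)
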