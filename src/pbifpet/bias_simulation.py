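"""Bias-injection simulation: how much systematic V_T bias can a study absorb
before its statistical conclusions change?

Starting from a patient V_T table carrying some known multiplicative bias, the
scan rescales the whole table to each bias level on a grid (global
multiplicative rescaling is the unique rank-preserving transform that sets the
target mean while keeping the coefficient of variation constant), reruns the
group statistics against the reference (control) table at every level, and
flags levels whose per-region significance pattern -- or headline ANOVA
effects -- deviate from a stated reference pattern.  The tolerable range is
the contiguous non-deviating run of grid points around the table's own bias.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .group_inference import (AnovaResult, RegionTestTable, combine_tables,
                              mixed_anova, per_region_tests)
from .reliability_stats import VTTable

HEADLINE_EFFECTS = ("group", "group_x_region")


def default_bias_grid() -> np.ndarray:
    """-8% to +9% in 1-percent-unit steps."""
    return np.round(np.arange(-0.08, 0.09 + 1e-9, 0.01), 10)


def bias_rescale(vt: VTTable, current_bias: float, target_bias: float) -> VTTable:
    """Multiply every value by (1 + target) / (1 + current).

    Biases are fractions relative to an (implicit) unbiased reference; the
    rescaling sets the mean ratio to 1 + target_bias while preserving the CV
    and value ranks exactly.
    """
    if 1.0 + current_bias <= 0 or 1.0 + target_bias <= 0:
        raise ValueError("bias must be > -100%")
    factor = (1.0 + target_bias) / (1.0 + current_bias)
    return VTTable(subjects=vt.subjects, regions=vt.regions,
                   values=vt.values * factor, method=vt.method)


@dataclass(frozen=True)
class BiasScanResult:
    """Per-bias statistics and the contiguous tolerable bias window."""

    grid: np.ndarray
    per_bias: dict  # bias -> (AnovaResult, RegionTestTable, deviates: bool)
    tolerable_range: Optional[tuple]

    def deviation_flags(self) -> dict:
        return {b: dev for b, (_, _, dev) in self.per_bias.items()}


def bias_scan(reference_vt: VTTable, biased_vt: VTTable,
              grid: Optional[Sequence[float]] = None,
              reference_pattern: Optional[RegionTestTable] = None,
              alpha: float = 0.05, current_bias: float = 0.0,
              covariate: Optional[Sequence[float]] = None,
              reference_effects: Optional[dict] = None) -> BiasScanResult:
    """Sweep injected bias and locate where conclusions deviate.

    ``biased_vt`` is the patient table at its actual bias ``current_bias``
    (fraction); ``reference_vt`` is the control-group table each level is
    tested against.  ``reference_pattern`` gives the expected per-region
    significance flags (e.g. from the full-input analysis); a level deviates
    when any region's significance flips relative to it, or -- when
    ``reference_effects`` maps headline ANOVA effect names to expected
    significance -- when a headline effect flips.
    """
    if reference_pattern is None:
        raise ValueError("bias_scan needs an explicit reference pattern")
    if list(reference_pattern.per_region) != list(reference_vt.regions):
        raise ValueError("reference pattern regions do not match the tables")
    grid_arr = (default_bias_grid() if grid is None
                else np.asarray(list(grid), float))
    expected = reference_pattern.significance_pattern()

    per_bias: dict = {}
    for b in grid_arr:
        scaled = bias_rescale(biased_vt, current_bias, float(b))
        regions = per_region_tests(reference_vt, scaled, paired=False,
                                   alpha=alpha)
        anova = mixed_anova(combine_tables(reference_vt, scaled),
                            covariate=covariate, alpha=alpha)
        deviates = regions.significance_pattern() != expected
        if reference_effects is not None:
            for eff, sig in reference_effects.items():
                if anova.significant(eff, alpha) != bool(sig):
                    deviates = True
        per_bias[float(b)] = (anova, regions, bool(deviates))

    flags = [per_bias[float(b)][2] for b in grid_arr]
    anchor = int(np.argmin(np.abs(grid_arr - current_bias)))
    tolerable = None
    if not flags[anchor]:
        lo = anchor
        while lo > 0 and not flags[lo - 1]:
            lo -= 1
        hi = anchor
        while hi < len(flags) - 1 and not flags[hi + 1]:
            hi += 1
        tolerable = (float(grid_arr[lo]), float(grid_arr[hi]))
    return BiasScanResult(grid=grid_arr, per_bias=per_bias,
                          tolerable_range=tolerable)
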