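"""Group-level inference on V_T tables.

The primary design is a split-plot ("mixed model") two-way ANOVA: group is a
between-subject factor, brain region a within-subject factor, subjects are
random and nested in group.  The group main effect is tested against the
subject-within-group mean square, the group x region interaction against the
region x subject-within-group mean square.  A subject-level covariate (BMI)
can adjust the between-subject stratum (classical split-plot ANCOVA).  The
abstinence comparisons use a fully within-subject two-way ANOVA (time point x
region).

All sums of squares are the classical means-based forms; with every subject
measured in every region the region terms are orthogonal to group, so these
coincide with Type II sums of squares even for unbalanced group sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .reliability_stats import VTTable


@dataclass(frozen=True)
class AnovaResult:
    """F tests per effect: name -> (F, df1, df2, p)."""

    effects: dict
    design: str  # mixed_group_by_region | within_time_by_region
    covariate_used: bool = False
    ss: dict = field(default_factory=dict)  # sums of squares, for auditing

    def significant(self, effect: str, alpha: float = 0.05) -> bool:
        return self.effects[effect][3] < alpha


@dataclass(frozen=True)
class RegionTestTable:
    """Per-region effect size and significance: region -> (effect_pct, p,
    significant at alpha)."""

    per_region: dict
    alpha: float = 0.05

    def significance_pattern(self) -> dict:
        return {r: sig for r, (_, _, sig) in self.per_region.items()}


def _f_test(ss_eff: float, df_eff: int, ss_err: float, df_err: int,
            ss_total: float = 0.0):
    # rounding dust: a component smaller than ~1e-12 of the total variation
    # is an exact zero (e.g. identical sessions), not a real effect
    tiny = 1e-12 * max(ss_total, 1e-300)
    ss_eff = 0.0 if ss_eff < tiny else ss_eff
    ss_err = 0.0 if ss_err < tiny else ss_err
    ms_eff = ss_eff / df_eff
    ms_err = ss_err / df_err
    if ms_err == 0:
        f = 0.0 if ms_eff == 0 else float("inf")
    else:
        f = ms_eff / ms_err
    p = float(stats.f.sf(f, df_eff, df_err)) if np.isfinite(f) else 0.0
    return float(f), int(df_eff), int(df_err), p


def mixed_anova(vt: VTTable, covariate: Optional[Sequence[float]] = None,
                alpha: float = 0.05) -> AnovaResult:
    """Split-plot ANOVA of a V_T table whose subjects carry group labels.

    ``covariate`` is one value per subject (row order); when given, the
    between-subject stratum becomes a one-way ANCOVA of subject means on the
    covariate plus group, losing one error df.
    """
    y = vt.values
    n_subj, r = y.shape
    labels = [s.group for s in vt.subjects]
    group_names = list(dict.fromkeys(labels))
    g = len(group_names)
    if g < 2:
        raise ValueError("mixed_anova needs at least two groups")
    gidx = np.array([group_names.index(l) for l in labels])
    n_g = np.array([(gidx == i).sum() for i in range(g)])

    grand = y.mean()
    subj_means = y.mean(axis=1)
    group_means = np.array([y[gidx == i].mean() for i in range(g)])
    region_means = y.mean(axis=0)
    cell_means = np.array([y[gidx == i].mean(axis=0) for i in range(g)])

    ss_group = r * float(np.sum(n_g * (group_means - grand) ** 2))
    ss_between = r * float(np.sum((subj_means - grand) ** 2))
    ss_subj = ss_between - ss_group
    ss_region = n_subj * float(np.sum((region_means - grand) ** 2))
    ss_int = float(np.sum(
        n_g[:, None] * (cell_means - group_means[:, None]
                        - region_means[None, :] + grand) ** 2))
    resid = y - subj_means[:, None] - cell_means[gidx] + group_means[gidx][:, None]
    ss_resid = float(np.sum(resid ** 2))

    df_subj = n_subj - g
    df_within_err = (n_subj - g) * (r - 1)
    effects = {}
    covariate_used = covariate is not None
    if covariate_used:
        x = np.asarray(covariate, float)
        if x.shape != (n_subj,):
            raise ValueError("covariate must have one value per subject")
        if np.std(x) == 0:
            raise ValueError("singular covariate (zero variance)")
        # ANCOVA on subject means (x r to stay on the observation scale)
        eff = _ancova_between(subj_means, x, gidx, g)
        ss_grp_adj, ss_err_adj, df_err_adj = (r * eff[0], r * eff[1], eff[2])
        effects["group"] = _f_test(ss_grp_adj, g - 1, ss_err_adj, df_err_adj,
                                   ss_total=r * float(np.sum((subj_means - subj_means.mean()) ** 2)))
        ss_group, ss_subj, df_subj = ss_grp_adj, ss_err_adj, df_err_adj
    else:
        effects["group"] = _f_test(ss_group, g - 1, ss_subj, df_subj,
                                   ss_total=ss_between)
    ss_total = float(np.sum((y - grand) ** 2))
    effects["region"] = _f_test(ss_region, r - 1, ss_resid, df_within_err,
                                ss_total=ss_total)
    effects["group_x_region"] = _f_test(ss_int, (g - 1) * (r - 1),
                                        ss_resid, df_within_err,
                                        ss_total=ss_total)
    ss = {"group": ss_group, "subjects_within_group": ss_subj,
          "region": ss_region, "group_x_region": ss_int,
          "region_x_subjects_within_group": ss_resid,
          "total": float(np.sum((y - grand) ** 2))}
    return AnovaResult(effects=effects, design="mixed_group_by_region",
                       covariate_used=covariate_used, ss=ss)


def _ancova_between(u: np.ndarray, x: np.ndarray, gidx: np.ndarray, g: int):
    """One-way ANCOVA on subject means: Type II SS for group given the
    covariate.  Returns (ss_group_adj, ss_error_adj, df_error)."""
    n = u.size

    def sse(design: np.ndarray) -> float:
        beta, *_ = np.linalg.lstsq(design, u, rcond=None)
        return float(np.sum((u - design @ beta) ** 2))

    ones = np.ones((n, 1))
    xcol = x[:, None]
    gdum = np.zeros((n, g - 1))
    for i in range(1, g):
        gdum[gidx == i, i - 1] = 1.0
    sse_cov = sse(np.hstack([ones, xcol]))
    sse_full = sse(np.hstack([ones, xcol, gdum]))
    return sse_cov - sse_full, sse_full, n - g - 1


def within_anova(baseline: VTTable, followup: VTTable) -> AnovaResult:
    """Two-way fully within-subject ANOVA: time point x region, both crossed
    with subjects.  Each effect is tested against its interaction with
    subjects."""
    if baseline.regions != followup.regions:
        raise ValueError("region sets differ")
    if set(baseline.subject_ids) != set(followup.subject_ids):
        raise ValueError("subject sets differ between sessions")
    followup = followup.reordered_like(baseline)
    y = np.stack([baseline.values, followup.values], axis=1)  # (n, t=2, r)
    n, t, r = y.shape

    grand = y.mean()
    m_s = y.mean(axis=(1, 2))
    m_t = y.mean(axis=(0, 2))
    m_k = y.mean(axis=(0, 1))
    m_st = y.mean(axis=2)
    m_tk = y.mean(axis=0)
    m_sk = y.mean(axis=1)

    ss_subj = t * r * float(np.sum((m_s - grand) ** 2))
    ss_rep = n * r * float(np.sum((m_t - grand) ** 2))
    ss_region = n * t * float(np.sum((m_k - grand) ** 2))
    ss_rep_subj = r * float(np.sum(
        (m_st - m_s[:, None] - m_t[None, :] + grand) ** 2))
    ss_region_subj = t * float(np.sum(
        (m_sk - m_s[:, None] - m_k[None, :] + grand) ** 2))
    ss_rep_region = n * float(np.sum(
        (m_tk - m_t[:, None] - m_k[None, :] + grand) ** 2))
    ss_total = float(np.sum((y - grand) ** 2))
    resid = (y - m_st[:, :, None] - m_sk[:, None, :] - m_tk[None, :, :]
             + m_s[:, None, None] + m_t[None, :, None] + m_k[None, None, :]
             - grand)
    ss_resid = float(np.sum(resid ** 2))

    effects = {
        "repetition": _f_test(ss_rep, t - 1, ss_rep_subj, (n - 1) * (t - 1),
                              ss_total=ss_total),
        "region": _f_test(ss_region, r - 1, ss_region_subj,
                          (n - 1) * (r - 1), ss_total=ss_total),
        "repetition_x_region": _f_test(
            ss_rep_region, (t - 1) * (r - 1), ss_resid,
            (n - 1) * (t - 1) * (r - 1), ss_total=ss_total),
    }
    ss = {"subjects": ss_subj, "repetition": ss_rep, "region": ss_region,
          "repetition_x_subjects": ss_rep_subj,
          "region_x_subjects": ss_region_subj,
          "repetition_x_region": ss_rep_region,
          "repetition_x_region_x_subjects": ss_resid, "total": ss_total}
    return AnovaResult(effects=effects, design="within_time_by_region", ss=ss)


def per_region_tests(a: VTTable, b: VTTable, paired: bool = False,
                     alpha: float = 0.05) -> RegionTestTable:
    """Region-by-region comparison of two V_T tables.

    Unpaired uses Welch's t-test (no equal-variance assumption); paired uses
    the paired t-test on matched subjects.  effect_pct is the percent change
    of b's mean relative to a's.  No multiplicity correction is applied.
    """
    if a.regions != b.regions:
        raise ValueError("region sets differ")
    if paired:
        if set(a.subject_ids) != set(b.subject_ids):
            raise ValueError("paired tests need matching subjects")
        b = b.reordered_like(a)
    per_region = {}
    for j, region in enumerate(a.regions):
        va, vb = a.values[:, j], b.values[:, j]
        if va.size < 2 or vb.size < 2:
            raise ValueError(f"region {region}: need >= 2 subjects per cell")
        if paired:
            res = stats.ttest_rel(vb, va)
        else:
            res = stats.ttest_ind(vb, va, equal_var=False)
        effect_pct = 100.0 * (vb.mean() - va.mean()) / va.mean()
        p = float(res.pvalue)
        per_region[region] = (float(effect_pct), p, bool(p < alpha))
    return RegionTestTable(per_region=per_region, alpha=alpha)


def combine_tables(a: VTTable, b: VTTable) -> VTTable:
    """Stack two single-group tables into one two-group table for
    :func:`mixed_anova`."""
    if a.regions != b.regions:
        raise ValueError("region sets differ")
    return VTTable(subjects=list(a.subjects) + list(b.subjects),
                   regions=a.regions,
                   values=np.vstack([a.values, b.values]),
                   method=a.method)
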