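"""Synthetic cohorts with the statistical structure the pipeline assumes.

Each group (healthy controls, alcohol-dependent, chronic cannabis smokers)
is summarised by a :class:`GroupProfile`: target input-function AUCs over
0-5 min (the bolus peak) and 5-120 min (the metabolite-corrected tail),
between-subject CVs for each segment, and per-region distribution-volume
means with fractional group effects relative to healthy.  The input-function
template is a linear rise to a 1-min peak followed by a fixed-rate
tri-exponential tail whose amplitudes are solved so the two AUC components
hit their targets exactly -- so the cannabis template has a blunted peak but
a healthy-sized tail, the structure that makes a healthy-shaped population
input function overestimate total AUC in that group.

Subject curves multiply the template's fast (peak) and slow (tail) components
by correlated lognormal factors; regional V_T values share a subject-level
lognormal factor (CV 28%, matching a 13.3 +/- 3.8 mL/cm^3 healthy spread)
with small independent regional jitter.  Tissue curves come from the 2TCM
forward model driven by each subject's own input function, with proportional
Gaussian noise on TAC frames (5%) and plasma samples (3%).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .input_function import FittedInputFunction, suv_factor
from .io_core import PlasmaCurve, SubjectMeta, TACSet
from .kinetics import TwoTCMParams, default_frames, simulate_2tcm

REGIONS = ("prefrontal", "occipital", "hippocampus", "putamen", "thalamus",
           "cerebellum", "pons", "white_matter")
#: regions showing the cannabis-selective downregulation
CORTICAL_REGIONS = ("prefrontal", "occipital", "hippocampus")

#: healthy regional V_T means (mL/cm^3); unweighted mean is 13.3
_HEALTHY_VT = {"prefrontal": 16.0, "occipital": 15.0, "hippocampus": 15.0,
               "putamen": 14.0, "thalamus": 13.0, "cerebellum": 14.0,
               "pons": 10.0, "white_matter": 9.4}

#: plasma sampling schedule (min): 15-s sampling to 2 min, then sparser
PLASMA_SCHEDULE = np.array(
    [0.0, 0.25, 0.5, 0.75, 1.0, 1.25, 1.5, 1.75, 2.0,
     2.5, 3.0, 4.0, 5.0, 8.0, 10.0, 15.0, 20.0, 30.0, 40.0, 50.0, 60.0,
     75.0, 90.0, 105.0, 120.0])

TAIL_RATES = (3.0, 0.3, 0.02)  # 1/min: bolus clearance, fast and slow tail
T_PEAK = 1.0                   # min; injection over ~1 min
#: share of tail AUC (5-120) carried by the intermediate rate; fixing the
#: tail's internal mix keeps late-time tail values proportional to tail AUC
#: across groups, so groups with equal tails have equal 15/60-min samples
TAIL_MIX = 0.15

# kinetic nuisance constants when back-solving 2TCM params from V_T
K2_FIXED = 0.15   # 1/min
K4_FIXED = 0.025  # 1/min
K3K4_RATIO = 2.0


@dataclass(frozen=True)
class GroupProfile:
    """Study-condition summary for one subject group."""

    name: str
    target_auc_0_5: float     # SUV*min
    target_auc_5_120: float   # SUV*min
    between_subject_cv_peak: float
    between_subject_cv_tail: float
    region_vt_means: dict
    region_effect: dict
    between_subject_cv_vt: float = 0.28
    region_jitter_cv: float = 0.05

    def __post_init__(self):
        if self.target_auc_0_5 <= 0 or self.target_auc_5_120 <= 0:
            raise ValueError("AUC targets must be positive")
        for cv in (self.between_subject_cv_peak, self.between_subject_cv_tail):
            if not 0 < cv < 1:
                raise ValueError("between-subject CVs must be in (0, 1)")


_PROFILES = {
    # AUC targets and CVs follow the observed group decompositions:
    # healthy 38.1+/-9.6 / 32.7+/-9.9, alcohol 40.5+/-9.0 / 32.2+/-7.5,
    # cannabis 33.4+/-12.4 / 32.6+/-6.9 SUV*min.
    "healthy": dict(target_auc_0_5=38.1, target_auc_5_120=32.7,
                    between_subject_cv_peak=9.6 / 38.1,
                    between_subject_cv_tail=9.9 / 32.7,
                    region_effect={r: 0.0 for r in REGIONS}),
    "alcohol": dict(target_auc_0_5=40.5, target_auc_5_120=32.2,
                    between_subject_cv_peak=9.0 / 40.5,
                    between_subject_cv_tail=7.5 / 32.2,
                    region_effect={r: -0.20 for r in REGIONS}),
    "cannabis": dict(target_auc_0_5=33.4, target_auc_5_120=32.6,
                     between_subject_cv_peak=12.4 / 33.4,
                     between_subject_cv_tail=6.9 / 32.6,
                     region_effect={r: (-0.19 if r in CORTICAL_REGIONS else 0.0)
                                    for r in REGIONS}),
}


def group_profile(name: str) -> GroupProfile:
    """Default profile for 'healthy', 'alcohol' or 'cannabis'."""
    if name not in _PROFILES:
        raise ValueError(f"unknown group {name!r}")
    return GroupProfile(name=name, region_vt_means=dict(_HEALTHY_VT),
                        **_PROFILES[name])


def make_template_if(profile: GroupProfile) -> FittedInputFunction:
    """Deterministic group template: linear rise from (0, 0) to the peak at
    1 min, tri-exponential tail at fixed rates.

    Peak height and the two slow amplitudes are solved from a linear 3x3
    system so that AUC(0-5) and AUC(5-120) equal the profile targets exactly,
    with the tail's internal AUC split pinned to ``TAIL_MIX`` (the fast
    amplitude then follows from continuity at the peak).  Pinning the tail
    mix rather than the peak split makes late-time tail values scale with
    tail AUC alone, so two groups with matching tails present matching 15-
    and 60-min scaling samples regardless of how blunted their peaks are.
    """
    lam = np.asarray(TAIL_RATES, float)
    c = (1.0 - np.exp(-lam * (5.0 - T_PEAK))) / lam
    d = (np.exp(-lam * (5.0 - T_PEAK)) - np.exp(-lam * (120.0 - T_PEAK))) / lam
    # unknowns: (peak, A2, A3); A1 = peak - A2 - A3 by continuity
    M = np.array([
        [T_PEAK / 2.0 + c[0], c[1] - c[0], c[2] - c[0]],
        [d[0], d[1] - d[0], d[2] - d[0]],
        [0.0, (1.0 - TAIL_MIX) * d[1], -TAIL_MIX * d[2]],
    ])
    rhs = np.array([profile.target_auc_0_5, profile.target_auc_5_120, 0.0])
    peak, a2, a3 = np.linalg.solve(M, rhs)
    a1 = peak - a2 - a3
    if peak <= 0 or a1 < 0 or a2 < 0 or a3 < 0:
        raise ValueError(
            f"infeasible AUC targets for profile {profile.name!r}: "
            f"peak={peak:.3g}, A1={a1:.3g}, A2={a2:.3g}, A3={a3:.3g}")
    return FittedInputFunction(
        t_peak=T_PEAK, peak_value=float(peak),
        rise_times=np.array([0.0, T_PEAK]),
        rise_values=np.array([0.0, float(peak)]),
        tail_amplitudes=np.array([float(a1), float(a2), float(a3)]),
        tail_rates=lam, subject_id=f"template_{profile.name}")


def _lognormal_factor(rng, cv: float, z: Optional[float] = None) -> float:
    """Unit-mean lognormal multiplier with the given CV."""
    sigma = np.sqrt(np.log1p(cv * cv))
    if z is None:
        z = rng.standard_normal()
    return float(np.exp(-0.5 * sigma * sigma + sigma * z))


def _subject_if(template: FittedInputFunction, s_peak: float, s_tail: float,
                subject_id: str) -> FittedInputFunction:
    """Blunt or boost the peak independently of the tail: scale the fast
    amplitude by s_peak and the two slow amplitudes by s_tail, then rebuild
    the rise so the curve stays continuous at the peak."""
    a = template.tail_amplitudes * np.array([s_peak, s_tail, s_tail])
    peak = float(a.sum())
    return FittedInputFunction(
        t_peak=template.t_peak, peak_value=peak,
        rise_times=template.rise_times,
        rise_values=template.rise_values * (peak / template.peak_value),
        tail_amplitudes=a, tail_rates=template.tail_rates,
        subject_id=subject_id)


@dataclass(frozen=True)
class SubjectRecord:
    """One synthetic subject: ground truth plus measured (noisy) data."""

    meta: SubjectMeta
    true_if: FittedInputFunction          # SUV
    plasma: PlasmaCurve                   # kBq/mL, noisy samples
    tacs: Optional[TACSet]                # kBq/mL, noisy frames
    true_params: dict                     # region -> TwoTCMParams
    true_vt: dict                         # region -> mL/cm^3


@dataclass(frozen=True)
class SyntheticCohort:
    subjects: list
    profile: GroupProfile
    seed: int
    regions: tuple = REGIONS

    def __len__(self):
        return len(self.subjects)


def sample_cohort(profile: GroupProfile, n: int, seed: int,
                  session: str = "test", tacs: bool = True,
                  tac_noise_cv: float = 0.05,
                  plasma_noise_cv: float = 0.03) -> SyntheticCohort:
    """Draw ``n`` subjects from a group profile, reproducibly from the seed.

    Peak and tail lognormal factors are correlated 0.5 on the log scale;
    body weight ~ N(83, 18) kg truncated above 40, injected activity
    ~ N(181, 9) MBq, BMI ~ N(24, 4) for cannabis smokers else N(27, 5).
    Set ``tacs=False`` to skip TAC/plasma simulation when only true V_T
    tables are needed (e.g. for statistics-only studies).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    template = make_template_if(profile)
    frame_starts, frame_ends = default_frames()
    subjects = []
    for i in range(n):
        sid = f"{profile.name}_{session}_{i + 1:03d}"
        z1, z2 = rng.standard_normal(2)
        z_tail = 0.5 * z1 + np.sqrt(1 - 0.25) * z2
        s_peak = _lognormal_factor(rng, profile.between_subject_cv_peak, z=z1)
        s_tail = _lognormal_factor(rng, profile.between_subject_cv_tail, z=z_tail)
        fif = _subject_if(template, s_peak, s_tail, sid)

        weight = 0.0
        while weight <= 40.0:
            weight = rng.normal(83.0, 18.0)
        activity = max(rng.normal(181.0, 9.0), 1.0)
        bmi_mu, bmi_sd = (24.0, 4.0) if profile.name == "cannabis" else (27.0, 5.0)
        bmi = max(rng.normal(bmi_mu, bmi_sd), 15.0)
        meta = SubjectMeta(subject_id=sid, group=profile.name, session=session,
                           weight=float(weight), injected_activity=float(activity),
                           bmi=float(bmi))

        subj_factor = _lognormal_factor(rng, profile.between_subject_cv_vt)
        true_vt, true_params = {}, {}
        for region in REGIONS:
            jitter = _lognormal_factor(rng, profile.region_jitter_cv)
            vt = (profile.region_vt_means[region]
                  * (1.0 + profile.region_effect[region]) * subj_factor * jitter)
            true_vt[region] = vt
            k1 = vt * K2_FIXED / (1.0 + K3K4_RATIO)
            true_params[region] = TwoTCMParams(
                K1=k1, k2=K2_FIXED, k3=K3K4_RATIO * K4_FIXED, k4=K4_FIXED)

        plasma, tacset = None, None
        if tacs:
            plasma, tacset = _measure_subject(
                rng, fif, meta, true_params, frame_starts, frame_ends,
                tac_noise_cv, plasma_noise_cv)
        subjects.append(SubjectRecord(meta=meta, true_if=fif, plasma=plasma,
                                      tacs=tacset, true_params=true_params,
                                      true_vt=true_vt))
    return SyntheticCohort(subjects=subjects, profile=profile, seed=seed)


def _measure_subject(rng, fif, meta, true_params, frame_starts, frame_ends,
                     tac_noise_cv, plasma_noise_cv):
    f = suv_factor(meta)
    suv_samples = fif.value(PLASMA_SCHEDULE)
    noisy = suv_samples * (1.0 + plasma_noise_cv * rng.standard_normal(
        PLASMA_SCHEDULE.size))
    noisy = np.maximum(noisy, 0.0)
    plasma = PlasmaCurve(times=PLASMA_SCHEDULE.copy(), concentrations=noisy * f,
                         units="kBq_per_mL", meta=meta)
    fif_kbq = fif.scaled(f)
    cols = []
    for region in REGIONS:
        tac = simulate_2tcm(true_params[region], fif_kbq,
                            frame_starts, frame_ends)
        tac = tac * (1.0 + tac_noise_cv * rng.standard_normal(tac.size))
        cols.append(np.maximum(tac, 1e-9))
    tacset = TACSet(frame_starts=frame_starts, frame_ends=frame_ends,
                    regions=REGIONS, values=np.column_stack(cols), meta=meta)
    return plasma, tacset


def make_retest(cohort: SyntheticCohort, within_cv: float = 0.15,
                seed: int = 0) -> SyntheticCohort:
    """Retest session: each subject's regional V_T and input-function scale
    are multiplied by independent unit-mean lognormal factors of CV
    ``within_cv``, then plasma and TAC measurements are regenerated with
    fresh noise."""
    if not 0 < within_cv < 0.5:
        raise ValueError("within_cv must be in (0, 0.5)")
    rng = np.random.default_rng(seed)
    frame_starts, frame_ends = default_frames()
    out = []
    for rec in cohort.subjects:
        m_vt = _lognormal_factor(rng, within_cv)
        m_if = _lognormal_factor(rng, within_cv)
        meta = replace(rec.meta, session="retest")
        fif = replace(rec.true_if.scaled(m_if), subject_id=rec.meta.subject_id)
        true_vt = {r: v * m_vt for r, v in rec.true_vt.items()}
        true_params = {
            r: TwoTCMParams(K1=vt * K2_FIXED / (1.0 + K3K4_RATIO),
                            k2=K2_FIXED, k3=K3K4_RATIO * K4_FIXED, k4=K4_FIXED)
            for r, vt in true_vt.items()}
        plasma, tacset = (None, None)
        if rec.tacs is not None:
            plasma, tacset = _measure_subject(
                rng, fif, meta, true_params, frame_starts, frame_ends,
                tac_noise_cv=0.05, plasma_noise_cv=0.03)
        out.append(SubjectRecord(meta=meta, true_if=fif, plasma=plasma,
                                 tacs=tacset, true_params=true_params,
                                 true_vt=true_vt))
    return SyntheticCohort(subjects=out, profile=cohort.profile, seed=seed)


def true_vt_table(cohort: SyntheticCohort, method: str = "logan_full"):
    """Ground-truth V_T table for a cohort (no measurement noise)."""
    from .reliability_stats import VTTable

    values = np.array([[rec.true_vt[r] for r in REGIONS]
                       for rec in cohort.subjects])
    return VTTable(subjects=[rec.meta for rec in cohort.subjects],
                   regions=list(REGIONS), values=values, method=method)
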