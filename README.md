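# pbifpet

Population-based arterial input functions (PBIF) for quantitative brain PET,
with Logan graphical V_T quantification, test–retest and group statistics,
and a bias-injection simulation framework — plus a synthetic-cohort generator
so every stage can be exercised end to end without patient data.

## The problem

Kinetic quantification of a reversible radioligand needs the *arterial input
function* C_p(t): the plasma concentration of unmetabolized tracer over the
scan. Serial arterial sampling is invasive, so a common shortcut is the PBIF:
average the SUV-normalized input functions of a healthy calibration cohort
into one standard-shape curve, then rescale that shape to each new subject
from just two late blood samples (here 15 and 60 min). The regional outcome
measure is the total distribution volume

    V_T = (K1/k2) (1 + k3/k4)   [mL/cm^3]

estimated either by fitting the two-tissue compartment model (2TCM) or, more
robustly for population-shaped inputs, as the asymptotic slope of the Logan
plot

    ∫₀ᵀ C_T dt / C_T(T)  =  V_T · ∫₀ᵀ C_p dt / C_T(T)  +  b,   T ≥ t*.

The catch this package exists to study: because the Logan slope depends on
the *running integral* of the input, a PBIF whose peak shape differs from the
target population's — e.g. a patient group whose bolus peak is blunted while
the metabolite-corrected tail is unchanged — picks up a systematic group-level
V_T bias that two-sample rescaling cannot remove. A bias of a few percent is
enough to flip per-region significance patterns in a downregulation study,
manufacturing "effects" in spared regions (negative bias) or erasing true
cortical effects (positive bias). The package is aimed at PET methodologists
who want to quantify that failure mode before trusting a PBIF in a clinical
protocol.

## What is implemented

- `io_core` — delimited-text formats (plasma curves, PMOD-style TAC tables,
  PBIF files, V_T tables), subject metadata, config and logging.
- `input_function` — SUV normalization, parent-fraction (metabolite)
  correction, piecewise fit (linear rise to the peak + tri-exponential tail,
  continuous at the peak), peak-time alignment, standard-grid resampling, and
  analytic AUCs.
- `pbif_builder` — cohort averaging (with leave-one-out), one-parameter
  least-squares rescaling from two blood samples, and Pearson-based selection
  of the best sample-time pair.
- `kinetics` — analytic 2TCM impulse response and forward simulation, Logan
  graphical V_T with a linearity check, and multistart weighted 2TCM fitting.
- `reliability_stats` — retest variability `100·|v1−v2|/mean`, one-way
  mean-square ICC `(BSMSS−WSMSS)/(BSMSS+WSMSS)`, and concordance summaries.
- `group_inference` — split-plot (group × region) ANOVA with optional
  subject-level BMI covariate, fully within-subject (time × region) ANOVA,
  and per-region Welch/paired tests.
- `bias_simulation` — CV-preserving multiplicative bias injection and a grid
  scan locating the bias window inside which a study's conclusions survive.
- `synthetic_data` — group profiles (healthy / alcohol / cannabis) calibrated
  to input-function AUC decompositions (peak 0–5 min vs tail 5–120 min) and
  regional V_T structure; cohorts with realistic between- and within-subject
  dispersion; reproducible from a seed.

A thin CLI (`pbifpet --help`) exposes the pipeline stages:
`simulate-cohort`, `build-pbif`, `scale-if`, `logan`, `fit-2tcm`,
`retest-stats`, `group-anova`, `bias-scan`.

## Worked example

Build a PBIF from healthy cohorts and apply it to peak-blunted
cannabis-profile cohorts (three replicate studies at the clinical sample
sizes):

```python
import numpy as np
import pbifpet as p

ratios, below = [], []
for k in (1, 2, 3):
    healthy = p.sample_cohort(p.group_profile("healthy"), n=42, seed=100 + k)
    cannabis = p.sample_cohort(p.group_profile("cannabis"), n=29, seed=200 + k)
    pbif = p.healthy_pbif(healthy)
    full = p.logan_full_table(cannabis)      # subject's own arterial input
    pb = p.logan_pbif_table(cannabis, pbif)  # PBIF rescaled from 15/60-min samples
    _, mean_ratio, sd_ratio = p.concordance(full, pb)
    ratios.append(mean_ratio)
    below.extend(pb.subject_means() < full.subject_means())
    print(f"replicate {k}: V_T ratio (PBIF/full) = {mean_ratio:.3f} +/- {sd_ratio:.3f}")
print(f"ensemble mean ratio: {np.mean(ratios):.3f}; "
      f"subjects underestimated: {100 * np.mean(below):.0f}%")
```

Output:

```
replicate 1: V_T ratio (PBIF/full) = 0.906 +/- 0.072
replicate 2: V_T ratio (PBIF/full) = 0.929 +/- 0.057
replicate 3: V_T ratio (PBIF/full) = 0.930 +/- 0.086
ensemble mean ratio: 0.922; subjects underestimated: 85%
```

Read: the cannabis-profile input functions have ~12% less AUC in the first
5 minutes than healthy ones but identical tails, so the healthy-shaped PBIF —
rescaled to match each subject's *tail* samples — overestimates the input
integral and deflates Logan V_T by a systematic ~7% for the whole group. The
same construction applied to healthy or alcohol-profile cohorts (taller peak,
same tail) yields ratios near 1.00–1.05: the shortcut validates cleanly where
the shape matches and fails silently where it does not.

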