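# Methods

This note records the models, parameter choices and numerical conventions
behind `pbifpet`, and what the synthetic cohorts do and do not emulate.

## Input-function model

An individual arterial input function is represented piecewise: linear
interpolation of the measured samples up to the peak (the maximum sample;
ties broken by the earliest time), then a tri-exponential decay

    C(t) = Σᵢ Aᵢ exp(−λᵢ (t − t_peak)),   Aᵢ ≥ 0,  λᵢ > 0,

with the continuity constraint Σ Aᵢ = C(t_peak) imposed exactly. The
constraint is a modelling choice: without it the fitted tail can jump at the
peak, which corrupts the early AUC that the Logan plot integrates. Before the
first sample the curve extends leftward at the first sample value, which
keeps time-shifted curves defined and non-negative on the whole grid and is
AUC-conservative for the sub-minute shifts peak alignment produces.

Fitting is weighted least squares with weights 1/max(y, ε), ε = 10⁻³ ×
peak — relative weighting, because plasma tails span two orders of
magnitude and unweighted fits ignore the late tail entirely. The amplitude
simplex is parameterised through a softmax so non-negativity and the
continuity sum hold by construction; decay rates are searched in log-space
within (10⁻⁴, 20) min⁻¹ from five log-spaced starting triplets
(geometric scalings of (3, 0.3, 0.02) min⁻¹), and the lowest-cost solution
wins. A fit whose relative RMSE exceeds 25% raises rather than returning
silently.

**Standard grid.** Curves are compared and averaged on a fixed grid spanning
0–120 min: 0.05-min steps through 3 min, 0.25 to 10 min, then 0.5/1/2.5/5-min
steps out to 120. The spacing is graded so that trapezoid integration of a
resampled curve reproduces the analytic AUC within ~0.05% for decay rates up
to 3 min⁻¹; a uniform 0.25-min early grid — adequate for the rise — leaves
~1% error from the fast post-peak decay, which would propagate directly into
population-curve AUCs.

## PBIF construction and scaling

Cohort curves are SUV-normalised (concentration divided by injected activity
per body weight), metabolite-corrected if a parent fraction is present,
time-shifted so every peak sits at the cohort-mean peak time, evaluated on
the standard grid and averaged pointwise (SD with the n−1 denominator).
Leave-one-out builds drop the target subject before averaging so the
population mean never contains the curve it is being tested against.

Rescaling to an individual uses two blood samples, by default at 15 and
60 min. The "combination" of the two samples is resolved as the
one-parameter least-squares fit

    s = Σ mᵢ pᵢ / Σ pᵢ²,

where mᵢ are the measured SUV values and pᵢ the PBIF values at the sample
times. Alternatives (mean of ratios, ratio of sums) differ only in how the
two samples are weighted; least squares is optimal under additive noise and
the choice is isolated behind `scale_method`. Sample-pair selection
correlates, across a calibration cohort, the summed parent activity at each
candidate time pair with the subject's total fitted AUC(0–120) (Pearson);
a config switch instead correlates the AUC of the pair-scaled
leave-one-out PBIF.

## Kinetics

The 2TCM impulse response is used in closed form (with the repeated-
eigenvalue limit handled analytically); tissue curves are the impulse
response convolved with the input by trapezoid rule on a 0.05-min grid and
averaged within acquisition frames. At these rate scales the quadrature
error is ≪ 0.1%. The integral of the impulse response equals
V_T = (K1/k2)(1 + k3/k4), which the test suite verifies numerically over
random rate draws around the operating point (the draw is restricted so the
slow kinetic eigenvalue exceeds 0.015 min⁻¹; slower eigenvalues simply do
not converge on a 600-min numeric horizon and say nothing about the
implementation).

Logan V_T is the OLS slope of the normalised tissue integral against the
normalised plasma integral over frames with mid-time ≥ t*. Tissue integrals
are cumulative frame sums, the plasma integral a fine-grid trapezoid.
Defaults: t* = 30 min, with a linearity diagnostic (maximum relative
deviation of included points from the fitted line; `is_linear(tol=0.10)`)
that operationalises "the plot did not linearize" as an exclusion rule.
The 2TCM fit is unconstrained in the sense of no coupling between rate
constants, but searched within (10⁻⁴, 2) in log-space with 8 seeded
log-uniform multistarts and frame-duration weights; V_T is derived from the
fitted constants. The default synthetic frame schedule is 6×0.5, 3×1, 2×2,
4×5, 9×10 min = 120 min.

For input functions of different shape but matched tails, the Logan slope
responds to the input's *running* integral: an early-AUC surplus enters the
Logan abscissa as an offset divided by the decaying tissue curve, so part of
it is absorbed by the intercept and the V_T deficit is somewhat smaller than
the raw total-AUC ratio. This matters when predicting group-level PBIF bias
from AUC decompositions alone.

## Reliability and group statistics

Retest variability is 100·|v1−v2|/mean(v1, v2); ICC uses the one-way
random-effects mean squares with k = 2 replicates,
(BSMSS − WSMSS)/(BSMSS + WSMSS), with zero total variance defined as ICC 0
with a warning. Cohort summaries are unweighted region means (a pooled
variant is available through `concordance(..., pool=...)`).

The group comparison is a split-plot ANOVA: group between subjects, region
within, subjects random and nested in group. F_group tests against
MS_subjects(group); F_group×region against MS_region×subjects(group). Because
every subject contributes every region, the region terms are orthogonal to
group and the classical weighted-means sums of squares coincide with Type II
even for unbalanced groups. A subject-level covariate (BMI) adjusts only the
between-subject stratum — it is constant within subject, so it has nothing
to say about within-subject contrasts — via classical ANCOVA on subject
means (error df N − g − 1). No sphericity correction is applied by default.
Per-region tests are Welch (unpaired) or paired t; no multiplicity
correction, with α = 0.05, so that the per-region significance pattern is
the raw object the bias scan perturbs.

## Bias injection

Rescaling a V_T table to a target mean bias multiplies every value by
(1 + target)/(1 + current): the unique rank-preserving transform that sets
the group mean while keeping the coefficient of variation constant. The scan
applies it globally (not per region), consistent with modelling a single
group-level input-function bias. "Deviation" at a bias level is
operationalised as any flip of the per-region significance pattern relative
to an explicit reference pattern, optionally extended to flips of the
headline ANOVA effects; the tolerable range is the contiguous non-deviating
run of grid points around the table's own bias. Default grid: −8% to +9% in
1-point steps.

## Synthetic cohorts

Each group profile fixes the input-function AUC decomposition (0–5 min peak
segment vs 5–120 min tail, in SUV·min: healthy 38.1/32.7, alcohol 40.5/32.2,
cannabis 33.4/32.6), segment-wise between-subject CVs taken from the same
decomposition (e.g. 12.4/33.4 for the cannabis peak), regional V_T means
averaging 13.3 mL/cm³ over eight regions (prefrontal, occipital,
hippocampus, putamen, thalamus, cerebellum, pons, white matter), and
fractional group effects: −20% everywhere for the alcohol profile, −19% in
the three cortical/limbic regions (and zero elsewhere) for cannabis.

The group template is deterministic: rise from (0, 0) to the peak at 1 min,
tail rates fixed at (3, 0.3, 0.02) min⁻¹, peak height and slow amplitudes
solved from a linear system so both AUC components hit their targets
exactly. The remaining amplitude degree of freedom is closed by pinning the
tail's internal AUC split (15% of tail AUC on the intermediate rate). This
convention — rather than pinning the fast amplitude to a fraction of the
peak — keeps the late-time tail values proportional to tail AUC alone, so
two groups with equal tails present equal 15/60-min scaling samples no matter
how blunted their peaks are; that is precisely the structure that makes the
peak-blunting bias invisible to two-sample rescaling. With it, the healthy
template's 60-min value is ≈0.21 SUV.

Subjects multiply the template's fast component by a lognormal peak factor
and the two slow components by a lognormal tail factor (unit means,
segment CVs as above, correlation 0.5 on the log scale); the peak follows by
continuity. Because the slow components also contribute to the first five
minutes, the realised AUC(0–5) spread is somewhat narrower than the peak
factor's CV — peak blunting is modelled strictly as a fast-component
phenomenon with the tail preserved. Body weight is N(83, 18) kg truncated
above 40, injected activity N(181, 9) MBq, BMI N(24, 4) kg/m² for the
cannabis profile and N(27, 5) otherwise. Regional V_T values share a
subject-level lognormal factor (CV 28%, reproducing a 13.3 ± 3.8 mL/cm³
population spread) with 5% independent regional jitter; 2TCM parameters are
back-solved from V_T with k2 = 0.15 min⁻¹ and k3/k4 = 2 (k4 =
0.025 min⁻¹) fixed — V_T is the analysis currency and the micro-parameters
are nuisance here. Plasma is sampled at 15-s intervals to 2 min and then
progressively sparser to 120 min with 3% proportional noise; TAC frames
carry 5% proportional noise. Retest sessions multiply each subject's V_T and
input-function scale by independent lognormal factors (default CV 15%) and
re-measure with fresh noise. All randomness flows from one seeded generator
per call.

**What the generator does not emulate.** Real plasma data have dispersion
and delay between sampling site and brain, time-varying metabolite
fractions, whole-blood-to-plasma ratios, occasional outlier samples, and —
crucially — tail-shape differences that can make two groups with equal tail
AUCs present *different* late-time sample values. The cohorts here impose
tails of identical shape, so the group-level PBIF bias they generate
(~−6% for the cannabis profile) is the floor implied by the AUC
decomposition alone; shape effects on the scaling samples can push the real
bias further (to around −9%) and make the underestimation more uniform
across subjects than the segment-CV/correlation-0.5 dispersion model
predicts. Passing the mechanism tests therefore demonstrates the direction
and systematic nature of the bias, not its exact clinical magnitude or
per-subject consistency.

Study-level quantities (group V_T ratios, fractions of subjects
underestimated, tolerable bias windows) fluctuate noticeably at clinical
sample sizes because the cohort means of the lognormal factors carry 4–7%
standard error; the test suite and the acceptance script therefore aggregate
small ensembles of replicate studies rather than trusting a single draw.

## Degenerate inputs and tie-breaks

Readers reject non-monotone times, negative concentrations and overlapping
frames with messages naming the offending row; nothing is silently reordered
or dropped. Writers emit full-precision floats and reads use round-trip
float parsing, so reader/writer pairs are lossless. Sample-pair selection
rounds Pearson r to 12 decimals before the argmax so exact ties resolve to
the lexicographically earliest pair. ANOVA components smaller than 10⁻¹²
of the total variation are treated as exact zeros before forming F ratios,
so identical sessions give F = 0 rather than a ratio of rounding dust.
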