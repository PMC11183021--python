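# Methods

This note records the models implemented in `hepadce`, the assumptions behind
them, the defaults that matter, and the numerical and design choices made
where more than one reasonable option existed.

## Kinetic model

Liver tissue is modelled as a single well-mixed compartment fed by two
vascular inputs (hepatic artery, portal vein) and drained at a single efflux
rate:

    dCt/dt = fa · Ca(t − τa) + fp · Cp(t − τp) − k2 · Ct(t),   Ct(0) = 0

with concentrations in mM, rates in 1/s. The six reported parameters follow
algebraically: Ft = Fa + Fp, ART = 100·Fa/Ft, DV = 100·(fa + fp)/k2,
MTT = 1/k2 = 60·DV/Ft. Tissue density is fixed at 1 g/mL so "per 100 g"
equals "per 100 mL"; no haematocrit correction is applied, and the input
curves are treated as the concentrations the tissue actually sees (whether
blood or plasma concentration is a calibration convention the fit is agnostic
to). These identities are enforced at derivation time — every fitted voxel
satisfies them exactly, which is a per-fit property; region-median summaries
of heterogeneous tissue need not satisfy them.

Assumptions worth keeping in mind: a single tissue compartment (no separate
interstitial/vascular terms), linearity between tracer concentration and
relaxation-rate change, flip-angle and B1 accuracy, and no water-exchange
effects.

## Signal model and T1 mapping

SPGR magnitude follows S = M0 sin α (1 − E1)/(1 − E1 cos α), E1 = exp(−TR/T1).
Baseline T1/M0 come from variable-flip-angle acquisitions via the linearised
fit (S/sin α against S/tan α); voxels whose slope falls outside (0, 1) or
with non-positive intercept are flagged invalid rather than clamped.
Dynamic signal is converted to concentration by full SPGR inversion — not a
linear relative-enhancement approximation — with M0 re-anchored per voxel on
the mean of the pre-contrast frames (default 3), then
C(t) = (R1(t) − R1(0))/r1 with r1 = 4.5 s⁻¹mM⁻¹ by default (a mid-range
gadolinium relaxivity at 3 T). Full inversion makes the noise-free
concentration→signal→concentration round trip exact to numerical precision.
Invalid voxels and unphysical frames propagate as missing (NaN), never as
zero.

## Voxel fitting

The forward model is evaluated by exact convolution of the exponential kernel
against piecewise-linear inputs (closed-form per-interval updates), so there
is no quadrature error on the coarse 3-s dynamic grid; it agrees with a
fine-step ODE integration to < 1e-4 mM. Fitting is bounded trust-region
least squares over (fa, fp, k2): flows in [0, 600] mL/min/100 g, k2 in
[1e-4, 5] s⁻¹, three multi-starts at log-spaced total flows (30/100/300),
with an early exit when a start already reaches a near-zero relative
residual. Ties between starts break to the lowest residual, then the lowest
total flow. All-zero or all-missing curves are skipped (missing parameters);
a fit that never converges returns its best candidate flagged.

Bolus-arrival delays τa, τp are fixed at 0 by default and can be fitted over
[0, 10] s via `FitOptions(fit_delays=True)`. The default is off because the
phantom generator introduces no voxel-level delays and joint delay estimation
on 3-s sampling is poorly identified; enabling it is one flag.

## Regions and agreement

The peritumoral shell is every liver voxel within 10 mm (default) Euclidean
distance of the tumor, excluding the tumor, computed on physical distances so
anisotropic voxels are handled correctly; the dilation is 3-D (an in-plane
2-D variant would be a trivial restriction but is not the default).
Clipping to the liver mask automates the manual correction a reader would
apply at the organ boundary. Regional features are plain means over valid
voxels; two readers are averaged element-wise, with a single-reader fallback
when one value is missing (logged).

Continuous agreement uses ICC(2,1) — two-way random effects, absolute
agreement, single measures — the common choice for two-reader continuous
measurements; the CI is the F-based interval with Satterthwaite degrees of
freedom. Categorical agreement uses Cohen's kappa with the large-sample Wald
CI; kappa is undefined (flagged) when both readers are constant and equal.

## Risk modelling

`C_DCE = −10.052 + 0.026·Ft_T + 0.170·ART_P` is the published combined DCE
score. The published point nomogram (baseline 208; AFP 20–400: +14,
AFP > 400: +33; corona: +19; TTPVI: +18; 11 points per C_DCE unit; high risk
strictly above 232.3) ships as a fixed preset. AFP bands close at the upper
boundary: 20 ng/mL falls in the lowest band, 400 in the middle band, and the
lowest band contributes 0 points.

The preset points→probability map is logit-linear, p = expit(a + b·RS), with
(a, b) solved exactly from the two published worked examples
(258.948 → 0.989 and 208.228 → 0.009, giving b ≈ 0.1814 logit/point); it is
labelled `preset-derived` in every output to distinguish it from a refitted
model. A nomogram can instead be rebuilt from any fitted combined model by
the standard 0–100 scaling (largest |coefficient|·range spans 100 points);
its probability map then follows exactly from the model, so nomogram
probabilities and model probabilities agree to machine precision.

Model families (clinical-radiological, intra-tumoral, peritumoral, pooled
DCE, combined) each pass a univariate screen at p < 0.05 — Mann-Whitney for
the perfusion features (they are reported as medians/IQR and are skewed),
chi-square with a 2×2 Fisher fallback for categoricals — before a
multivariable logistic fit (IRLS, tolerance 1e-10, 100 iterations).
Separation is detected (saturated fitted probabilities or diverging
coefficients) and flagged, never silently returned: with 12 candidate
perfusion features and ~30 events the pooled DCE family does separate at the
default cohort size, in which case the combined model falls back to the
published C_DCE coefficients. The train/validation split is 7:3, stratified
by MVI so both splits keep near-equal prevalence, with a configurable seed.

## Evaluation

Empirical ROC over observed score values; trapezoid AUC (identical to the
normalised Mann-Whitney U with half-credit for ties); DeLong placement-value
variance for AUC CIs and paired model comparisons; Youden's J for operating
cutoffs (ties break to the smallest cutoff). Decision curves use
NB(pt) = TP/N − (FP/N)·pt/(1 − pt) on a 0.01–0.99 grid.

The Hosmer-Lemeshow statistic uses deciles of risk (quantile bins, merged
when tied, logged) and a χ²(g − 2) reference. That reference distribution is
derived for probabilities estimated on the same data; the test is therefore
calibrated (type-I error ≈ α) when applied to fitted models, which is how
the calibration simulations exercise it. Feeding externally fixed "true"
probabilities shifts the null towards χ²(g) and inflates rejection — a
property of the test, not of this implementation.

## Survival

Kaplan-Meier product-limit curves with events ordered before censorings at
tied times; log-rank across risk groups and, within a risk group, between
anatomical and non-anatomical resection (crude, unstratified). A median the
follow-up never reaches is reported as "not reached (> last follow-up)"
rather than a number.

## Synthetic data: what it emulates and what it does not

The phantom is a box liver containing a spherical tumor and its surrounding
band, each perfectly homogeneous, with region ground truth defaulting to the
emulated cohort's group medians (tumor: Ft 197.3, ART 53.85, DV 23.17;
band: Ft 156.0, ART 30.41; background: Ft 158.6, ART 24.45; T1 810/1100 ms
liver/tumor at M0 = 1000). The dynamic protocol is 42 frames at 3 s (the
frame count is as acquired; the spacing is a plausible placeholder, the true
temporal resolution being unpublished), flip angle 12°, TR 4 ms, VFA at
3/6/9/12°. The arterial input is a peak-normalised gamma-variate
(5 mM peak at 15 s) plus a dispersed recirculation bump; the portal input is
the same bolus delayed 4 s and dispersed through an 8-s exponential kernel.
Noise defaults to Rician at SNR 20 on the magnitude signal (the MR magnitude
noise model), seeded.

The cohort generator draws MVI at 33.3% prevalence, all twelve perfusion
features from log-normals matched to the emulated group medians and
IQR-derived sigmas, AFP/corona/TTPVI from their group-conditional
frequencies, and recurrence times from exponentials whose risk-group hazards
are solved from 2-year RFS rates of 31.6% (high risk) and 64.1% (low risk),
with an AR-vs-NAR hazard ratio of 0.5 inside the high-risk group only and
uniform censoring over 4–35 months. A second mode draws labels from a
logistic model with known coefficients (default: those implied by the preset
nomogram's point scale), which turns the generator into a parameter-recovery
benchmark.

What passing tests on these data do **not** show: robustness to anatomy
(real livers are not boxes, tumors not spheres), motion, B1/flip-angle
error, arterial-phase artifacts, input-function measurement error,
between-feature correlation (cohort features are drawn independently per
patient, so e.g. Ft = Fa + Fp holds voxel-wise in the phantom but not across
a patient table), or model misspecification of the kinetic model itself.

## Problem sizes used in the shipped checks

Phantom round-trip: 20×20×5 grid (972 liver voxels), noise-free, all six
parameters recovered within 0.1% (observed: ~1e-13). Noise robustness: 100
Monte-Carlo fits of the reference voxel (Fa 30, Fp 70, DV 25) at Rician SNR
20 through the full signal→concentration→fit chain; median |relative error|
of Ft observed ≈ 6%. Oracle equivalences (trapezoid AUC vs U-statistic,
distance-transform dilation vs brute force, IRLS vs Newton, KM vs ECDF): 100
random small instances each. Type-I error of Hosmer-Lemeshow and log-rank:
500 replicates at n = 2000. Coefficient recovery: combined logistic refits
on two n = 5000 cohorts.

## Known limitations

* The kinetic equations are the standard dual-input one-compartment model;
  the original in-house implementation this emulates is unpublished, so
  absolute parameter scales may differ even where the structure matches.
  Published per-group medians do not satisfy MTT = 60·DV/Ft (e.g.
  60·23.17/197.3 ≈ 7.0 s against a reported 12.12 s); this package does not
  force agreement and reports the identity-consistent value.
* Whether MTT should include bolus-arrival delay is convention-dependent;
  here MTT = 1/k2 excludes it.
* No motion correction, B1 correction, or vessel detection: input functions
  arrive as curves.
* The exact published combined-model coefficients are unavailable; the
  preset nomogram is treated as the reference and the refit path as a
  methodological reconstruction.
* No bootstrap/optimism correction beyond the single split; no Cox models or
  competing risks.
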