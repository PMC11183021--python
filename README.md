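# hepadce

Bi-regional dynamic contrast-enhanced MRI (DCE-MRI) analysis for predicting
microvascular invasion (MVI) in early-stage hepatocellular carcinoma, and for
stratifying recurrence risk after hepatectomy.

MVI — tumor invasion of small vessels visible only on postoperative
pathology — is a major driver of recurrence after resection of solitary
BCLC stage A HCC, and knowing its likelihood *preoperatively* changes
surgical strategy (anatomical vs non-anatomical resection). `hepadce`
implements the full quantitative chain from raw dynamic MR signal to a
patient-level risk score, exercised end-to-end on digital liver phantoms and
synthetic cohorts so that every stage is testable without patient data. It
is aimed at quantitative-imaging researchers and biostatisticians who need a
reproducible, fully seeded reference implementation of this analysis.

## What it computes

**Perfusion quantification.** Baseline T1 from variable-flip-angle SPGR
(3°–12°), full SPGR inversion of a 42-phase dynamic series to tracer
concentration, and voxel-wise fitting of the dual-input one-compartment
liver model

    dCt/dt = fa·Ca(t − τa) + fp·Cp(t − τp) − k2·Ct(t)

yielding six parameter maps: arterial fraction ART (%), arterial flow Fa,
portal-venous flow Fp, total flow Ft (mL/min/100 g), distribution volume
DV (%) and mean transit time MTT (s).

**Bi-regional features.** Mean parameters in the intra-tumoral region (`_T`)
and in the 10-mm peritumoral shell (`_P`, physical-distance dilation clipped
to the liver), plus ICC(2,1)/kappa inter-observer agreement.

**Risk modelling.** The combined DCE score

    C_DCE = −10.052 + 0.026·Ft_T + 0.170·ART_P

univariate screening and multivariable logistic models (clinical-
radiological, intra-tumoral, peritumoral, DCE, combined), and the point
nomogram

    RS = 208 + {0, 14, 33}_AFP + 19·corona + 18·TTPVI + 11·C_DCE

with high MVI risk defined by RS > 232.3.

**Evaluation and survival.** ROC/AUC with DeLong CIs and paired DeLong
tests, Youden cutoffs, confusion metrics, Hosmer-Lemeshow calibration,
decision-curve net benefit, Kaplan-Meier recurrence-free survival and
log-rank tests by risk group and surgical approach.

**Synthetic data.** Digital liver phantoms with known ground-truth perfusion
(gamma-variate arterial input, delayed/dispersed portal input, SPGR signal
synthesis, seeded Rician noise) and patient cohorts matching the emulated
study's prevalence, predictor frequencies, perfusion-feature distributions
and recurrence hazards.

## Worked example

```python
from hepadce import modeling as mdl

nomo = mdl.preset_nomogram()
# 53-year-old, AFP 12 ng/mL, corona enhancement and TTPVI present,
# C_DCE = 1.268 from the patient's perfusion maps
rs = mdl.nomogram_points(nomo, mdl.afp_band(12.0), corona=True, ttpvi=True, c_dce=1.268)
print(round(rs), mdl.stratify_risk(rs), round(mdl.points_to_probability(nomo, rs), 3))
```

prints `259 HMVI 0.989`: the patient scores 259 points, lands in the
high-MVI-risk group (RS > 232.3), with a predicted MVI probability of 0.989.
The same call with AFP 95 ng/mL, no corona/TTPVI and C_DCE = −1.252 prints
`208 LMVI 0.009`.

A full phantom-plus-cohort run:

```bash
hepadce run-all --out run --seed 0
```

writes volumes, parameter maps, features, cohort, models, evaluation and
survival JSONs plus a `manifest.json` with artifact hashes. With the default
seed the phantom's tumor-region mean total flow comes back at
`Ft_T = 210.9` mL/min/100 g against a ground truth of 197.3 under Rician
noise at SNR 20 (noise-free fits recover truth to ~1e-13 relative), the
combined model reaches a training AUC of 0.985, and the high-risk group
shows a median RFS of 15.6 months against "not reached" in the low-risk
group (log-rank p = 0.0009). Individual stages are available as `simulate`,
`fit-perfusion`, `extract-rois`, `build-model`, `evaluate` and `survive`.

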