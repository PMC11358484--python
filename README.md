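# renalmri

Multiparametric renal MRI analysis for small-animal kidney-injury studies:
DCE-MRI pharmacokinetic modeling with parsimonious (AIC-based) voxel-wise
model selection, IVIM/ADC diffusion fitting, FAIR-ASL T1 and renal blood
flow quantification, volumetry-based single-kidney GFR, and the cohort
statistics layer (two-way ANOVA, ROC, PCA, Bland–Altman) used to classify
injured versus healthy kidneys. A seeded synthetic-data module generates
every input the pipeline consumes — phantoms, inversion-recovery and DWI
series, and a 9-animal × 3-timepoint × 2-kidney cohort — together with the
ground truth needed to measure recovery error at every stage.

## The models

**DCE-MRI.** Tissue gadolinium concentration C(t) is explained per voxel by
one of three nested-complexity tracer-kinetic models driven by the plasma
input Cp(t):

- Patlak (2 parameters): `C = Vp·Cp + F_T·∫Cp`
- Two-compartment filtration, 2CFM (3): `C = Vp·Cp + F_T·(e^{−t/T_T} * Cp)`
- 2CFM with outflow, 2CFM-O (3): `dC1/dt = k1(C0 − C1)`,
  `dC2/dt = F_T·C1 − k2·C3`, with `C = C1 + C2` and C3 a measured
  inner-medullary-papilla curve.

Each masked voxel is fitted with all three by bounded multi-start nonlinear
least squares; the model with the lowest small-sample-corrected Akaike
criterion `AICc = n·ln(RSS/n) + 2k + 2k(k+1)/(n−k−1)` wins — the
*parsimonious* model. The winning voxel-wise filtration coefficient F_T
(1/min), averaged over the kidney and multiplied by the T2-derived kidney
volume (mm³), gives the single-kidney GFR in µl/min with no hidden unit
factor.

**DWI.** `S(b) = S0[f·e^{−b·D*} + (1−f)·e^{−b·D}]` (IVIM), fitted by the
segmented strategy (high-b log-linear for D, then the fast component, then a
joint polish); the mono-exponential ADC is fitted log-linearly over all 13
b-values.

**ASL.** Magnitude inversion recovery `S(TI) = |S0(1 − b·e^{−TI/T1})|` with
polarity restoration; renal blood flow from the FAIR pair:
`RBF = 6000·λ·(1/T1_sel − 1/T1_glob)` ml/min/100 g (T1 in s, λ in ml/g).

## Worked example

```sh
python examples/dce_model_selection.py
```

```
voxels fitted:                 144
generating model selected:     91.7% of voxels
F_T relative RMSE:             1.6%
voxels with R2 > 0.70 (pars.): 100.0%
```

On the standard three-region phantom at SNR 20, AICc picks the generating
model in ~92% of voxels and the recovered F_T map is within a couple of
percent of truth — the quantity that propagates into GFR. The other
examples (`ivim_adc.py`, `asl_t1_rbf.py`, `gfr_from_ft.py`,
`cohort_classification.py`) each run one capability end to end and print
the recovered values next to their ground truth.

A thin CLI exposes the same stages
(`renalmri simulate|fit-dce|fit-dwi|fit-asl|volume|gfr|stats|run-all`),
writing NIfTI maps, CSV tables, JSON statistics and a manifest that makes
any run exactly reproducible.

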