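# Methods

## Scope and model chain

The package quantifies kidney function in a unilateral ischemia–reperfusion
(IRI) imaging study design: per-kidney filtration (DCE-MRI), perfusion
(FAIR-ASL), water diffusion (DWI), volume (T2 volumetry), their combination
into a single-kidney GFR, and a statistics layer that classifies injured
versus healthy kidneys. All internal time units are minutes (rate constants
are reported in 1/min), concentrations mM, diffusion in mm²/s, T1 in ms,
volume in mm³, GFR in µl/min.

## DCE-MRI pharmacokinetics

Three candidate models explain the voxel concentration C(t) given the
plasma input Cp(t) (aorta ROI, corrected to plasma by 1/(1−Hct)):

| model  | k | parameters | form |
|--------|---|------------|------|
| Patlak | 2 | Vp, F_T | C = Vp·Cp + F_T·∫₀ᵗCp |
| 2CFM   | 3 | Vp, F_T, T_T | C = Vp·Cp + F_T·(e^{−t/T_T} * Cp) |
| 2CFM-O | 3 | k1, F_T, k2 | dC1/dt = k1(C0−C1); dC2/dt = F_T·C1 − k2·C3 |

Design choices where the chain was genuinely open:

- **2CFM-O observable.** Only the ODE system is specified by the model
  family; we take the voxel signal to be C = C1 + C2 (no extra
  volume-fraction weights), with C3 supplied as one ROI-averaged
  inner-medullary-papilla curve shared by all voxels. This is the minimal
  parameterization consistent with three free rates.
- **Convolution quadrature.** Exponential-kernel convolutions use a causal
  recursive scheme exact for piecewise-linear inputs (no FFT wrap-around);
  the x→0 limit is series-expanded below x = rate·dt = 10⁻³ to avoid
  catastrophic cancellation, so the Patlak limit of the 2CFM kernel is
  numerically clean. The 2CFM-O integral of C1 is obtained exactly from its
  own ODE (∫C1 = ∫C0 − ΔC1/k1), keeping the whole forward chain exact for
  piecewise-linear C0 and C3.
- **Signal → concentration.** Spoiled-gradient-echo inversion with defaults
  TR 15.43 ms, flip 25°, r1 = 3.3 s⁻¹mM⁻¹, T10 = 1900 ms tissue / 2200 ms
  blood, Hct = 0.45 — representative 9.4 T values, all configurable, never
  hard-coded inside operations. Signal ratios outside the invertible range
  are marked missing (never clamped high); negative concentrations are
  clamped to zero with an observable clamp count. A dual-echo TE→0
  extrapolation (R2* from the echo pair) is available upstream.
- **Fitting.** Bounded trust-region least squares, three starts (literature
  values ×1, ×0.3, ×3), cost tolerances 10⁻¹⁰, iteration cap 500. The 2CFM
  is optimized over the washout rate 1/T_T so its nested Patlak limit is a
  finite bound rather than a runaway direction. Model selection uses AICc
  with RSS floored at 10⁻¹² (noiseless fits must not yield −∞); exact ties
  go to fewer parameters, then fixed model order.

## Diffusion

ADC comes from a log-linear fit over all 13 b-values (20–1460 s/mm²); it
deliberately absorbs the perfusion component, so ADC > D on IVIM-generated
data. IVIM uses the standard segmented strategy: D and the slow-pool
intercept from b > 200 s/mm² (between 140 and 230 in the acquisition grid),
the fast amplitude and D* with those fixed, then a joint polish under
f ∈ [0,1], D ∈ [10⁻⁵,10⁻²], D* ∈ [D,1] mm²/s. Fits with f at a bound or
D* ≈ D carry a warning flag: the perfusion fraction is unidentifiable when
the two decay rates merge.

## ASL relaxometry

T1 is fitted from 14-TI magnitude data with the three-parameter model
S0(1 − b·e^{−TI/T1}); the inversion efficiency b is fitted, not assumed
perfect. Magnitude data lose the sign of early-TI points, so polarity is
restored by exhaustive flip-index search — deterministic and robust without
prior knowledge of the null point. RBF uses the classic FAIR T1-difference
formula RBF = 6000·λ(1/T1_sel − 1/T1_glob) with λ = 0.9 ml/g by default;
negative RBF (selective T1 above global) is returned flagged, not clipped.
Because RBF rides on a small 1/T1 difference, percent-level T1 noise maps
to tens of ml/min/100 g; quantitative RBF therefore presumes ROI-averaged
series.

## GFR

GFR = mean F_T over converged ROI voxels × kidney volume; median
aggregation is available by option. The volume term uses the full mask.
1 min⁻¹ × 1 mm³ = 1 µl/min exactly — tests assert the identity against 100
random parameter draws.

## Statistics

- Two-way ANOVA (side × timepoint, with interaction, ordinary not
  repeated-measures) via OLS; left-vs-right pooled-variance t-tests within
  each timepoint, Bonferroni-corrected across the three timepoints. Cells
  with zero variance everywhere return F = 0, p = 1 by convention.
- ROC via the rank (Mann–Whitney) estimator with tie correction. Scores are
  never auto-flipped; the classifier applies one fixed global orientation —
  parameters are negated because every marker studied here declines with
  injury — so non-discriminating parameters land at AUC ≈ 0.5 or below.
- PCA on z-scored parameters by eigendecomposition of the correlation
  matrix (variance fractions sum to one exactly). A principal axis has no
  intrinsic sign; each component is oriented toward the positive (injured)
  class before its score is fed to ROC. Components are retained up to 80%
  cumulative variance by default. Class definition: healthy = both kidneys
  at baseline; injured = right (clamped) kidney at days 1 and 15;
  contralateral post-surgery kidneys are excluded.
- Bland–Altman: bias = mean(a−b), limits of agreement ±1.96·SD (sample SD).
- Pearson correlation reported as R² with the two-sided t-test p-value.

## Synthetic data: what it emulates, and what it does not

Generators are pure functions of spec + seed (bit-identical reruns) and
always emit ground truth alongside the data.

- **AIF**: gamma-variate A·((t−t0)/kτ)^k·e^{k−(t−t0)/τ} peaking at t0 + kτ,
  plus a small slow washout tail; defaults (A = 5 mM, k = 3, τ = 0.05 min,
  onset after a 2-min baseline) describe a compact small-animal bolus first
  pass.
- **DCE phantom**: three stripes generated by the three models with truth
  near healthy-kidney values (F_T = 0.6 min⁻¹; Vp = 0.15; T_T = 0.8 min;
  k1 = 2.5, k2 = 0.15 min⁻¹ — deliberately not the fitting start values),
  pushed through the SPGR signal equation at a common baseline of 1000 and
  Rician noise at SNR 20 (baseline/σ). C3 is a delayed (0.3 min), smoothed
  copy of the mean tissue curve, mimicking an IMP ROI average. The standard
  grid is 12×12 voxels over 6 min at 0.987 s frames — sized so that the
  full three-model voxel-wise fit runs in seconds while leaving ~50 voxels
  per region for selection statistics.
- **DWI**: the fit consumes ROI-averaged trace series, so the generator
  models that chain: `snr` is the per-image SNR and the averaged series
  carries noise reduced by √(n_directions·roi_voxels), Gaussian by default
  for the averaged series (defaults: 3 orthogonal directions, a 30-voxel
  cortex ROI). A full per-voxel Rician chain, including its noise floor,
  is available via `noise='rician'`; no Rician-bias correction is applied
  anywhere, so heavy noise floors bias D low by design.
- **IR series**: forward model on the 14-TI grid plus Gaussian magnitude
  noise at S0/snr.
- **Cohort**: per (animal, timepoint, side), parameters are drawn from
  zero-truncated normals with the published group means and SD = SEM·√9;
  GFR is not drawn but computed per animal as F_T × volume, so the unit
  identity holds by construction. Between-parameter correlation within an
  animal defaults to zero — a known simplification: real injured kidneys
  co-vary across parameters, which tends to make multivariate classifiers
  look *better* on real data than here. Transcutaneous GFR readings are
  paired per kidney as MRI-GFR + 40.08 µl/min bias + N(0, 33.05²) µl/min
  disagreement.

Passing tests on these phantoms demonstrates correctness of the estimators
and the selection machinery under the stated noise models; they do not
demonstrate robustness to respiratory motion, partial volume, B1
inhomogeneity, water-exchange effects, or anatomically realistic geometry,
none of which are simulated.

## Problem sizes and determinism

The test suite and the acceptance script use the 12×12 phantom,
200-replicate recovery suites per fitting stage, a 9-animal cohort for the
headline statistics and a 200-animal cohort for ordering properties — sizes
chosen so the estimators' medians are stable while the whole suite runs in
about a minute. All randomness flows from explicit seeds; replicate r of a
suite uses seed0 + r so suites are reproducible and non-overlapping.

## Known limitations

- Absolute RBF values depend on the unstated λ and quantification constants
  of any given acquisition; only relative behavior and recovery are
  validated.
- The 2CFM-O composition rule (C = C1 + C2) is an assumption; alternative
  weightings would rescale k1 and Vp-like effects but leave F_T's role.
- Voxel-wise IVIM at realistic single-voxel SNR is strongly biased by the
  Rician floor (D low, f high); the package fits ROI-averaged series by
  default and provides no floor correction.
- The ANOVA treats animals as independent across timepoints
  (no repeated-measures structure); with n = 9 per cell this is
  conservative for the contrasts reported.
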