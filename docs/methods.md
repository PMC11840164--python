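# Methods

## Signal model and tensor estimation

Diffusion-weighted signals follow the monoexponential tensor model
S(b, g) = S0·exp(−b·gᵀDg), with b in s/mm², g a unit gradient direction and
D the symmetric 3×3 diffusion tensor in mm²/s. The default acquisition
mirrors the emulated study: one b = 0 volume plus 128 directions at
b = 1000 s/mm² on 2 mm isotropic voxels; directions are a deterministic
Fibonacci-sphere set so schemes are reproducible without a seed. Most tests
and the shipped pipeline use a 32-direction subset — the estimation problem
is identical and the runtime a quarter.

Fitting is unweighted ordinary least squares on log-signals over the six
unique tensor elements plus log S0. Weighted least squares (reliability
weighting by signal magnitude) would reduce noise-floor bias at low SNR but
adds an estimator choice with no benefit at the SNR ≈ 30 regime simulated
here; OLS is deterministic and exactly inverts noise-free data, which the
suite asserts to 1e-10 relative. Non-positive signals are dropped from a
voxel's fit with a warning; a voxel with fewer than 7 usable measurements
(or no b0) is excluded from the output mask. Negative fitted diagonal
elements are retained unclamped but the voxel is flagged and excluded from
ROI means — clamping would bias ROI means upward asymmetrically.

Coordinate convention, fixed package-wide: x = left–right (perivascular
axis), y = anterior–posterior (association fibers), z = inferior–superior
(projection fibers). NIfTI outputs carry an identity-scaled affine at the
stated voxel size; no reorientation logic exists because phantoms are
generated directly in this canonical frame.

## ALPS index and ICC

ALPS = mean(Dxx_proj, Dxx_assoc) / mean(Dyy_proj, Dzz_assoc), computed per
hemisphere; the subject-level "mean" index is the arithmetic mean of the
left and right indices (not the index of averaged diffusivities — the two
differ only at second order for the effect sizes simulated). ROI means use
only voxels passing the fit mask, and the voxel count used is always
reported. ROIs are specified either as a labeled NIfTI (codes 1–4) or as
axis-aligned boxes (center + half-width); the phantom generator places
3×3×3 boxes at the centers of its four fiber compartments.

Test–retest reliability uses the two-way mixed-effects, absolute-agreement,
single-measure intraclass correlation, ICC(A,1) =
(MSR − MSE) / (MSR + (k−1)MSE + k(MSC − MSE)/n) from the standard two-way
ANOVA mean squares; the model label is stored in the result so the choice
is auditable. The p-value tests zero subject variance via F = MSR/MSE.

## Phantom generator

A rectangular grid holds four fiber compartments in an isotropic background
(0.7e-3 mm²/s): projection compartments with diag(g + radial, radial,
axial) and association compartments with diag(g + radial, axial, radial),
using axial = 1.4e-3 and radial = 0.4e-3 mm²/s — typical coherent
white-matter values. The perivascular parameter g ≥ 0 adds x-axis
diffusivity to both compartments, which moves the ALPS numerator while the
denominator stays fixed; this is the minimal mechanism isolating exactly
what the index measures, and it gives the closed-form ground truth
ALPS = (g + radial)/radial per hemisphere (g can differ between
hemispheres). Noise is Rician by default — magnitude of a complex Gaussian
with σ = S0/SNR, SNR 30 at b0 — with a Gaussian option for analytic
checks.

What the phantom does not emulate: anatomy, partial-volume mixing at
compartment borders (ROIs sit strictly inside compartments), fiber
dispersion and crossing, eddy/motion artifacts, and spatial normalization.
Passing tests therefore validate the estimator chain and index
construction, not robustness to real-data confounds.

## Cohort generator

Per-hemisphere ALPS values are bivariate normal per group with the emulated
study's printed means/SDs (patients 1.46 ± 0.19 left, 1.44 ± 0.18 right;
controls 1.62 ± 0.17 and 1.66 ± 0.20). The inter-hemisphere correlation
0.688 is not free: it is the unique value making SD[(L+R)/2] equal the
printed 0.17 of the mean index in both groups simultaneously. Covariates:
age and education normal with the printed group parameters, sex Bernoulli
with the printed group frequencies (encoded 0/1, 1 = male), total
intracranial volume normal (1450 ± 120 cm³, a typical adult scale).
Covariate loadings on GMV default to zero so adjustment code paths can be
exercised both inert and active.

Regional grey-matter volumes and cognition follow a linear structural
model, centered at a reference ALPS of 1.45 (the patient mean):

- GMV_region = mean_region + a_region·(ALPS − 1.45) + loadings·covariates + ε,
  ε ~ N(0, σ_region);
- MMSE = 23.9 + c′·(ALPS − 1.45) + Σ b_region·(GMV − mean_region) + ε,
  ε ~ N(0, 3.2), then rounded and clamped to [0, 30].

Defaults are calibrated from the printed statistics alone: the total
ALPS→MMSE effect c = 14 points per unit ALPS reproduces the printed
partial correlation (r ≈ c·σ_ALPS/σ_MMSE = 14·0.17/4.38 ≈ 0.54); a-paths
come from the six printed ALPS–GMV partial correlations at unit region SD
(a = r/0.17, residual SD √(1−r²)); b-paths are nonzero only for the two
mediating regions and are set so the true proportions mediated are 17.49%
(anterior cingulate) and 32.24% (orbital inferior frontal), i.e. indirect
effects 2.4486 and 4.5136 and direct effect c′ = 7.0378. Region mean
volumes (3.5–9 cm³) are plausible bilateral scales, configurable — the
source study reports GMV only graphically. True paths and proportions are
emitted as a ground-truth sidecar with every generated cohort; reported
coefficients are pre-rounding.

The MMSE rounding/clamp produces a realistic ceiling in controls (~24% at
30 at the default settings) and mildly attenuates regression paths. Because
the emitted truth is the pre-rounding coefficient, calibration-style checks
of the bootstrap (CI coverage of the true indirect effect) use
`mmse_discretize=False`, which skips rounding and clamping; all recovery
checks of study-scale quantities run on the discretized default. A clamp
rate above 20% raises a warning.

## Statistical battery

Continuous group comparisons are gated per outcome by Shapiro–Wilk at
α = 0.05: normal → ANCOVA (OLS y ~ group + covariates; the group F is the
squared t of the group coefficient, identical to the Type-III F for a
single two-level factor — the suite cross-checks against statsmodels'
`anova_lm(typ=3)`), non-normal → Quade's rank analysis of covariance
(rank-transform outcome and covariates with midranks, regress outcome
ranks on covariate ranks, one-way ANOVA on the residuals by group). The
route taken is recorded per variable in the run report. A constant outcome
is non-normal by convention.

χ² of independence is Pearson without continuity correction by default
(Yates available by flag). Partial correlation residualizes both variables
on the covariates with intercepts and correlates the residuals, with
p from t on df = n − 2 − k; with no covariates it is exactly Pearson. ROC
AUC uses the Mann–Whitney construction (ties ½) with the higher-ALPS
control group coded positive. Benjamini–Hochberg adjustment is applied
within two families — the six ALPS–GMV correlations and the six GMV–MMSE
correlations — a boundary choice the source analysis leaves open. All
p-values are two-sided.

## Mediation

Simple (single-mediator) Preacher–Hayes mediation per region: a from
m ~ x + Z, b and c′ from y ~ x + m + Z, c from y ~ x + Z, all OLS with
intercepts; covariates Z fixed to age, sex, education and total
intracranial volume. On every sample c = c′ + a·b exactly (asserted to
1e-10). The CI for a·b is a case-resampling percentile bootstrap
(default 5000 resamples, seed mandatory in the pipeline config) — the
simplest member of the family; bias-corrected variants are deliberately
not implemented since the reference analysis does not specify one.
Resamples with zero predictor variance are redrawn, capped at 1% of draws.
Proportion mediated is 100·a·b/c (equal to a·b/(a·b + c′) on OLS
estimates), flagged as unstable under inconsistent mediation (opposite
signs or |a·b| > |c|). One degenerate-input rule: on an exactly
rank-deficient y ~ x + m design (mediator perfectly collinear with
predictor, direct effect unidentifiable) the shared variance is attributed
to the mediator — b is fit from y ~ m + Z and c′ = c − a·b — matching the
causal-chain reading; near-collinearity below exact rank deficiency only
warns with the condition number. Regions are modeled one at a time;
parallel multiple-mediator decompositions are out of scope.

## Pipeline and reproducibility

Stage seeds derive from the master seed by SHA-256 of "seed:stage-name"
(truncated below 2³¹), so adding a stage never perturbs earlier stages'
randomness. The config is echoed verbatim into the output directory, CSV
floats are written at 10 significant digits, and two runs from the same
config are byte-identical — asserted in the suite. Problem sizes in the
shipped tests and acceptance script (12³ phantom grids, 32-direction
schemes, 10⁴-subject cohorts for AUC/means, 100–200 replicate batches for
calibration checks) were chosen so the full chain demonstrates convergence
at comfortable desk scale; all are configurable upward.

## Known limitations

- The phantom's compartments are noise-free rectangles; no partial volume,
  dispersion, or misregistration, so real-data ALPS variance components are
  not represented.
- GMV is generated at region level; no segmentation noise model.
- The ICC operation implements one fixed model (A,1); the reliability of
  manual ROI placement on real anatomy cannot be simulated here.
- The cohort's linear structural model is the identification assumption of
  the mediation analysis, so mediation "recovery" demonstrates estimator
  correctness, not causal validity on observational data.
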