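# alpsflow

Diffusion-tensor "analysis along the perivascular space" (DTI-ALPS) is a
non-invasive MRI surrogate of glymphatic function: at the level of the
lateral ventricle body, the deep medullary veins (and their perivascular
spaces) run left–right (x), projection fibers run inferior–superior (z) and
association fibers run anterior–posterior (y). Water diffusivity along x,
measured where it is orthogonal to both fiber populations, therefore
reflects perivascular fluid mobility. The index is

```
ALPS = mean(Dxx_proj, Dxx_assoc) / mean(Dyy_proj, Dzz_assoc)
```

with Dxx, Dyy, Dzz the diagonal diffusion-tensor elements (mm²/s) averaged
over projection-fiber and association-fiber ROIs; it equals 1 for isotropic
diffusion and rises as perivascular diffusion increases. Reduced ALPS in
Parkinson's disease, its association with cognition (MMSE) and with
regional grey-matter volume (GMV), and the mediation chain
ALPS → regional GMV → MMSE are the analyses this package reproduces —
end-to-end on synthetic data, since the original MRI cohort is not public.

`alpsflow` is for researchers who want a tested, fully reproducible
implementation of that analytical chain: a diffusion-phantom generator with
closed-form ALPS ground truth `(g + radial)/radial` (where `g` is the
perivascular x-diffusivity increment), log-linear least-squares tensor
fitting, ROI extraction and the ALPS ratio, a cohort generator with the
study's group distributions and a known mediation structure, the
statistical battery (Shapiro–Wilk-gated ANCOVA/Quade, χ², partial
correlation, ROC/AUC, Benjamini–Hochberg), and Preacher–Hayes percentile
bootstrap mediation.

## Worked example

```bash
alpsflow run --config examples/run_demo.yaml --out demo_run
```

simulates 4 noisy phantoms (Rician noise, SNR 30, b = 1000 s/mm²) and an
81-subject cohort (51 patients, 30 controls), fits tensors, computes ALPS,
and runs the full statistics and mediation chain. It prints:

```
stage phantom: ok
stage cohort: ok
stage statistics: ok
stage mediation: ok

phantoms = 4
phantom_failed_fits = 0
subjects = 81
subjects_pd = 51
subjects_nc = 30

route alps_l: ancova
route alps_r: ancova
route alps_m: quade

phantom_alps_mean_error = 0.007401212884
auc_alps_l = 0.7281045752
auc_alps_r = 0.7980392157
auc_alps_m = 0.7823529412
group_F_alps_m = 12.12248592
group_p_alps_m = 0.0008146823788
partial_r_alps_m_mmse = 0.50240263
proportion_mediated_anterior_cingulate_gyrus = 6.097028155
proportion_mediated_orbital_inferior_frontal_gyrus = 33.68399221
```

Reading the output: the imaging chain recovers the phantoms' known ALPS to
~0.007; the three ALPS indices separate patients from controls with AUC
0.73–0.80; the mean index differs between groups (F = 12.1, p = 8×10⁻⁴,
age/sex-adjusted — note the normality gate routed `alps_m` to the Quade
rank test for this seed); ALPS correlates with cognition (partial r = 0.50
given age, sex, education); and grey-matter volume partially mediates the
ALPS–MMSE association (34% through the orbital inferior frontal gyrus for
this 51-patient draw; per-draw proportions are noisy at this sample size).
Full tables land in `demo_run/` (`statistics.csv`, `mediation.csv`,
`cohort.csv`, `alps_phantoms.csv`, `report.json`).

The same steps are available piecewise (`alpsflow simulate-phantom`,
`fit-tensor`, `alps`, `simulate-cohort`, `analyze`, `mediate`) and as a
Python API (`alpsflow.generate_phantom`, `fit_volume`,
`compute_subject_alps`, `generate_cohort`, `mediate`, ...).

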