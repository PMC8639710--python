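# aslscov

Spatial heterogeneity of arterial-spin-labelling (ASL) perfusion maps as a
surrogate marker of arterial transit time, with the statistical machinery to
compare it across ordered cognitive-decline groups.

## The problem

ASL MRI measures cerebral blood flow (CBF, ml/100g/min) by magnetically
labelling arterial blood. The arterial transit time (ATT) — how long labelled
blood takes to reach a voxel's microvasculature — is a marker of vascular
health, but measuring it directly costs scan time. When a single
post-labelling delay (PLD) acquisition images before the label has fully
arrived (PLD < ATT), the CBF map becomes spatially heterogeneous: bright
proximal vessels, under-supplied distal tissue. The **spatial coefficient of
variation**

```
sCoV = σ(CBF in ROI) / μ(CBF in ROI) × 100 %
```

computed on *uncorrected* (non partial-volume-corrected) CBF maps therefore
acts as an ATT surrogate that can be read off any existing CBF map. In
cohorts spanning subjective cognitive decline (SCD), mild cognitive
impairment (MCI) and probable Alzheimer's dementia (AD), sCoV is expected to
rise with disease severity.

`aslscov` provides, as a library:

- **synthetic phantoms** (`aslscov.phantom`) — stylised three-shell digital
  brains with group-dependent ATT prolongation, regional hypoperfusion, and
  age/sex/site covariate structure, for a five-level severity design
  (control/SCD/aMCI/mMCI/AD, sizes 20/44/23+22/13 by default);
- **kinetic forward model** (`aslscov.kinetic`) — single-compartment pCASL
  general kinetic model (α = 0.60, T1 of blood 1.65 s, τ = PLD = 1.8 s,
  8 repeats) plus a gated macrovascular term for label stalled in arteries;
- **quantification** (`aslscov.quantify`) — M0 calibration, single-PLD CBF
  quantification (an exact inverse of the forward model when ATT ≤ PLD), and
  local linear-regression partial-volume correction;
- **ROI metrics** (`aslscov.roi`) — GM mask at a 25% partial-volume
  threshold, four lobes and four AD-sensitive parcels (PCC, precuneus,
  hippocampus, angular gyrus), per-subject sCoV and mean CBF;
- **order-restricted Bayesian ANCOVA** (`aslscov.ordered_bayes`) — Bayes
  factors for hypotheses such as `[control=scd] < mci < ad` against a
  covariates-only null, via a g-prior marginal likelihood (deterministic
  quadrature) combined with the encompassing-prior ratio of posterior to
  prior constraint probabilities (Gibbs sampler, analytic 1/B! prior);
- **classical cohort statistics** (`aslscov.cohort_stats`) — one-way ANOVA
  and pairwise post-hoc t tests from summary statistics, chi-square tests,
  vascular-risk scoring, Pearson and partial correlations.

A thin CLI (`aslscov run / simulate / validate`) orchestrates the full
simulate → acquire → quantify → metrics → statistics pipeline with a
reproducibility manifest.

## Worked example

Order-restricted model comparison on a staged cohort
(`examples/04_ordered_bayes.py`):

```
simulated n = 300 subjects, metric pattern 50/50/53/56 (sd 6)
M1: control < scd < mci < ad  BF vs null =   1.07e+11  (posterior constraint prob 0.134, prior 0.0417, Rhat 1.000)
M2: [control=scd] < mci < ad  BF vs null =   6.94e+11  (posterior constraint prob 0.999, prior 0.1667, Rhat 1.000)
M3: control < scd < [mci=ad]  BF vs null =   1.81e+07  (posterior constraint prob 0.150, prior 0.1667, Rhat 1.000)
M4: [control=scd] < [mci=ad]  BF vs null =   1.34e+08  (posterior constraint prob 1.000, prior 0.5000, Rhat 1.000)

preferred model: [control=scd] < mci < ad
```

The Bayes factor of each restriction is the unrestricted group-model BF
times the posterior/prior probability ratio of the ordering; the generating
pattern (M2) wins, and M1 is penalised because only ~13% of posterior draws
order the (truly equal) control and SCD effects. The transit-delay mechanism
itself is shown in `examples/03_scov_mechanism.py`: sweeping a group ATT
offset from 0 to 1 s at fixed true CBF raises GM sCoV (25.7 → 27.9 %) while
measured GM CBF falls (50.7 → 31.7 ml/100g/min).

Each script in `examples/` is a runnable narrative for one capability:
phantom cohorts, kinetic round-trip, the sCoV mechanism, ordered Bayes
factors, and summary-statistics re-analysis of a published 122-participant
cohort table.

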