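# Methods

This note documents the models, defaults and design choices behind
`aslscov`, and what the synthetic experiments do and do not establish.

## Kinetic model and quantification

The control–label difference signal follows the single-compartment general
kinetic model for pseudo-continuous labelling with label duration τ and
post-labelling delay w. Labelled water relaxes with the T1 of blood both in
transit and after arrival; no outflow or exchange into a tissue-T1 pool is
modelled. Writing Δ = ATT (s), f = CBF (ml/100g/min), the voxel signal is

- f/6000 · 2α·m0b·T1b · e^(−w/T1b)(1 − e^(−τ/T1b))   for Δ ≤ w,
- f/6000 · 2α·m0b·T1b · e^(−Δ/T1b)(1 − e^(−(τ+w−Δ)/T1b)) for w < Δ < τ+w,
- 0 for Δ ≥ τ+w,

continuous at both boundaries. Keeping T1-of-blood decay after arrival (no
tissue-T1 exchange) makes the standard single-PLD quantification formula

f = 6000·ΔM·e^(w/T1b) / (2α·T1b·m0b·(1 − e^(−τ/T1b)))

an *exact algebraic inverse* of the forward model whenever Δ ≤ w — the
basis of the machine-precision round-trip test. For Δ > w the quantified
CBF under-reads true CBF, monotonically in Δ: the under-delivery bias that
the sCoV metric exploits.

Defaults: α = 0.60, T1b = 1.65 s, τ = w = 1.8 s, λ = 0.9 ml/g, M0 scan
TR = 4 s with tissue T1 = 1.3 s for the saturation correction
(m0b = M0 / (1 − e^(−TR/T1t)) / λ; the order of the λ division and the
saturation correction is algebraically irrelevant and fixed as written),
8 control–label repeats. The macrovascular term contributes
2α·m0b·aBV·e^(−Δa/T1b) only while the tissue compartment is unreached
(Δ > w) and label remains in the vessel (Δa < τ+w): a non-dispersed, gated
bolus. Noise is additive white Gaussian per repeat (SD 1.0 signal units
against a tissue difference signal of ≈ 4–6 units, i.e. a realistic
post-averaging SNR of ~10–15); no temporal autocorrelation or motion is
modelled, since motion correction is outside the package's scope.

## Phantom and cohort generator

The phantom is a three-shell ellipsoid (WM core, GM ribbon, CSF rim) on a
32×32×24 grid of 3×3×4 mm voxels; boundary voxels get mixed partial
volumes through a one-voxel linear ramp, which is what exercises the
partial-volume correction. Statistical structure, not anatomy, is the
design goal. ROI labels are fixed geometric parcels: four lobes partition
the GM by anterior–posterior and superior–inferior position, and four small
parcels (PCC, precuneus, hippocampus, angular gyrus) override lobe codes in
plausible locations.

Ground-truth effects are additive and therefore exactly recoverable from
the maps:

- tissue ATT = 1.2 s base + group offset (0 / 0.10 / 0.25 / 0.35 / 0.50 s
  for control/SCD/aMCI/mMCI/AD) + site offset (0, ±0.05 s) + 5 ms/year ×
  (age − 70), with a +0.2 s increment in the posterior third of the brain
  so that transit delays bite there first;
- pure-tissue CBF: GM 60, WM 20 ml/100g/min, with group-wise reductions of
  2–10 ml/100g/min in the four AD-sensitive parcels and small site offsets
  (±3);
- covariates emulate the reference cohort: per-group age means 67.4–74.9
  years (SDs 6.2–8.3), female proportions 0.80/0.59/0.51/0.51/0.23, site
  sampling 91:16:15. The aMCI/mMCI split of the 45 MCI participants is not
  published; the default 23/22 is a documented guess.

The voxelwise "true" CBF is pv_gm·f_gm + pv_wm·f_wm, i.e. the
partial-volume-diluted value a correct non-PVC quantification should
return. Vessel tracks carry aBV = 0.5 and are placed where pv_gm < 0.2, so
macrovascular signal brightens the map without entering GM-masked
statistics; the diffuse arterial fraction defaults to zero because a
diffuse term switches on discontinuously as ATT crosses the PLD and raises
measured GM CBF, confounding the clean monotone transit-delay mechanism the
generator exists to produce (both parameters are configurable). All
randomness flows from a single master seed through per-subject spawned
streams; identical configuration gives bit-identical cohorts.

What the generator does *not* emulate: realistic anatomy and registration,
motion and susceptibility artefacts, dispersion of the labelled bolus,
background-suppression physics, atrophy. Passing tests therefore show the
pipeline's algorithms are correct and the transit-delay mechanism behaves
as theory predicts on clean geometry — not that effect sizes on real
scanners will match.

## ROI metrics

sCoV uses the sample (n−1) standard deviation; at ROI sizes of hundreds of
voxels the population/sample distinction is negligible, but the choice is
fixed for determinism. The GM mask threshold is inclusive (pv ≥ 0.25).
Lobe ROIs are intersected with the GM mask by default (configurable), and
sCoV is computed only from non-PVC maps — enforced through the map's
`pvc_flag`, since partial-volume correction smooths away precisely the
heterogeneity of interest. Mean CBF is reported from both map types.

## Partial-volume correction

A local linear-regression PVC: within a kernel (radius 2 in-plane, 1
through-plane by default) the measured CBF is regressed on (pv_gm, pv_wm),
giving pure-tissue perfusion estimates. Voxels whose local 2×2 Gram matrix
is rank deficient (condition number above 1e6, or fewer than two usable
neighbours) are masked out rather than extrapolated. Spatial-prior
variational PVC methods exist in scanner toolchains; the regression method
was chosen here for determinism and testability — it recovers a noiseless
two-tissue scene exactly, which gives a sharp correctness oracle.

## Order-restricted Bayesian ANCOVA

Model: y = Wδ + Zθ + ε with W the intercept plus covariates (age
standardised; sex and site as sum-to-zero contrasts — the coding keeps the
group effects exchangeable, which the analytic prior constraint probability
requires), Z the one-hot group factor, ε ~ N(0, σ²I). Common parameters δ
take flat priors in both models and σ² the Jeffreys prior, so their
contributions cancel exactly in the Bayes factor; the group effects take
θ_j | g, σ² ~ N(0, g σ²) with g ~ InverseGamma(1/2, r²/2), r = 0.5 —
equivalently a zero-centred Cauchy(0.5) prior on each standardised effect,
matching common "default prior" conventions for fixed effects. Covariates
sit in *both* the null and alternative models: they are controls, not
hypotheses.

The unrestricted BF is computed by projecting out W (the group/intercept
confound then appears harmlessly as a zero eigenvalue of the projected
group Gram matrix), reducing the marginal-likelihood ratio at fixed g to an
eigenvalue expression, and integrating over log g with adaptive quadrature
(deterministic; cross-checked in tests against an explicit two-dimensional
grid integration over effect scale and error variance).

Equality blocks (e.g. `[control=scd]`) are implemented by merging factor
levels before fitting, which keeps the encompassing formula exact. The
order-restricted BF is then BF_full × P(ordering | data) / P(ordering),
with the prior probability 1/B! for B blocks (exchangeability) and the
posterior probability estimated from a Gibbs sampler with conditionally
conjugate updates for (δ, θ), σ² and g (4 chains × 10,000 draws by
default; convergence monitored with the split-chain statistic and
effective sample size via ArviZ). Posterior draws with ties (θ_i = θ_j, a
probability-zero event) count as violations, fixed for determinism. A
posterior proportion of exactly zero is reported as BF = 0 with a warning
rather than an exception. The Monte-Carlo standard error of the BF is
BF_full × se(p̂)/p_prior with se(p̂) adjusted by the indicator's effective
sample size.

Open modelling choices, decided and fixed: site enters as fixed
sum-to-zero contrasts (no random effects), and covariates are common to
both models rather than carrying their own test priors. Both choices are
conventional for covariate *controls* and keep the null/alternative
comparison about the group factor only.

## Classical statistics

ANOVA and pairwise t tests are reconstructed from group (mean, SD, n)
summaries — algebraically identical to raw-data tests when the summaries
come from the raw data (tested to 1e-10). The post-hoc default is the
pooled-variance t with Bonferroni correction over all pairs (Welch
available via a flag); published tables do not always state which family
was corrected, and reconstructed post-hoc p-values near the significance
boundary can differ from printed ones for that reason. Chi-square tests are
Pearson, no continuity correction. Percentages are converted to counts by
nearest-integer rounding of percent×n. Partial correlation residualises
both variables on the covariates and adjusts the t degrees of freedom to
n − 2 − q.

## Problem sizes and numerical choices

Default test and acceptance runs use the 32×32×24 phantom grid (16³ for the
fastest unit tests), cohorts of 100–122 subjects for imaging experiments,
and records-level simulation (no imaging) with n = 300 and 20 replicates
for the model-selection study — sizes chosen so the full suite completes in
minutes on one core while leaving the Monte-Carlo margins (3 SE) far from
the tested thresholds. Quantification masks voxels whose m0b falls below 5%
of the robust (99th percentile) maximum. Quadrature for the BF runs on
log-scale with the integrand peak normalised out; the Gibbs sampler
discards max(200, n/10) burn-in draws per chain.
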