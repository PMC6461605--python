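# Methods

## The data-generating model

The package targets longitudinal morphometry in a small, unbalanced
two-group design: a patient group followed at roughly annual visits for up
to seven sessions and a control group seen one to three times. Because the
motivating cohort's raw images are restricted, a synthetic generator defines
the conditions under which every method is validated.

**Cohort.** Group sizes are exact (defaults 29 patients / 52 controls).
Visit counts are drawn from per-group probability vectors; the defaults were
calibrated so the expected follow-up among multi-visit participants equals
the published cohort means — 3.6 yr for patients (SD 1.70 at ~annual
spacing) and 2.0 yr for controls — with single-visit probabilities 4/29 and
12/52. Inter-visit intervals are Normal(1.0, 0.15²) yr, truncated at 0.2 yr.
Baseline ages are uniform on the per-group observed ranges (5.9–25.8 and
6.0–26.2 yr). All patients carry a diabetes flag; 24/52 controls do. eTIV is
log-normal with *mean* 1.5×10⁶ mm³ (log-SD 0.08); parameterising the mean
rather than the median keeps proportional head-size correction free of a
systematic scale bias. Each participant owns a deterministic RNG substream
spawned from the named seed, so any fixed seed reproduces every table
bitwise.

**Regional volumes.** For region r and participant i,

    V_ij = a_i + s_i t_ij + e_ij,  a_i ~ N(μ_a, σ_a²),
    s_i ~ N(μ_s(group), τ²),       e_ij ~ N(0, σ²),

on the head-size-corrected scale; the recorded raw volume is
`V_ij (eTIV_i / eTIV_ref)^c` with coupling exponent c = 1 by default, so the
proportional correction (`raw × ref / eTIV`) exactly inverts the coupling.
Group mean slopes μ_s are the published per-region annual rates (e.g.
thalamus −84.68 mm³/yr patients, +11.26 controls; brainstem −123.61 /
+182.39). Slope SDs take τ = SEM·√n from the published per-group SEMs (the
SEM of a mean of per-subject slopes), e.g. thalamus patients 5.86·√29 ≈
31.56 mm³/yr. Baseline means/SDs and residual SDs are not published;
defaults are plausible FreeSurfer-scale values stored in
`data/params.yaml`. The thalamus residual SD (177 mm³) is the one
deliberate calibration: it is the value at which the closed-form trial
power for the published design reproduces the published minimum arm sizes
of 48 and 34 for 50% and 60% slowing — the only printed information that
constrains this otherwise unpublished variance.

**Symptom scores.** WURS Physical scores exist for patients only and are
rank-coupled to a severity measure (by default the latent thalamic annual
percent change). The coupling is a latent bivariate-normal construction:
severity is Gaussianised and the score latent is
`z = ρ·z_sev + √(1−ρ²)·ε`, then mapped through a strictly increasing
log-normal transform to a nonnegative score scale (median ≈ 8), which
leaves rank correlations untouched. Three Gaussianisation routes are
available: (i) normal scores through an auxiliary severity pool's empirical
CDF — a Gaussian-copula coupling, exact for any continuous severity and the
route used in the validation experiments; (ii) linear standardisation with
population moments (exact for normal severity); (iii) sample moments (a
small-sample convenience that conditions the marginal and strengthens the
realised coupling slightly, ≈ +0.02 in |ρ_s| at n = 17). The latent ρ is
derived from the target rank correlation either asymptotically
(ρ = 2 sin(π ρ_s / 6)) or, by default, by inverting Moran's exact
finite-sample expectation of the sample Spearman coefficient at a stated
calibration size. The packaged target is a *sample* statistic observed at
n = 17, so the default calibrates at n = 17 (latent ρ ≈ −0.718 for a target
of −0.669, versus −0.687 from the asymptotic map).

**Jacobian maps.** TBM stacks are generated directly on a small grid (no
registration is simulated). Log-Jacobians are `slope_g·t_mid + noise` for
the within-subject-midpoint variant and
`group offset + subject offset + slope_g·(age − mean age) + noise` in
template space; effects are confined to a stated voxel cluster, all other
voxels have slope 0, and values are exponentiated so maps are positive.
A single-visit participant is its own midpoint, so its midpoint-variant map
is exactly 1 inside the mask. Noise is a Gaussian random field: white noise
convolved with a Gaussian kernel (default FWHM 3 voxels) and rescaled to a
per-voxel SD (default 0.02). Spatial smoothness matters: deformation-derived
Jacobians are smooth in practice, and with white noise the null
distribution of cluster sizes degenerates to ties at 1–2 voxels, making
cluster-extent FWE inference unusably conservative at desk scale.

## ROI mixed models

Fits use REML with β and σ² profiled out of the likelihood, leaving a
Nelder-Mead search over the Cholesky factor of Ψ/σ² (one to three
parameters). Each subject enters through its cross-products only, and the
Woodbury identity reduces every likelihood evaluation to batched q×q
operations (q ≤ 2), which keeps a fit in the low milliseconds — the property
that makes the Monte-Carlo validation suites (thousands of refits)
tractable. A perfect-fit branch returns the exact generalised-least-squares
solution with zero variance components when the residual sum of squares
vanishes (noise-free data). On datasets where statsmodels' MixedLM
converges, the two engines agree in coefficients, variance parameters and
REML log-likelihood (asserted in the tests); where MixedLM's optimizer
fails, this engine reaches an equal or higher restricted likelihood.

Binary covariates (group, sex, diabetes) are effect-coded ±½ and age
(fixed at first session) is centred, so single-df Wald tests of each term
are marginal, Type-III-style, in the presence of interactions, and the
per-group mean annual rates read off as β_time ± β_group:time/2.
Denominator degrees of freedom are Satterthwaite approximations:
df = 2g²/Var(g) with g = c'(X'V⁻¹X)⁻¹c, the gradient of g and the REML
curvature in the variance parameters both obtained by central differences
at the estimate; a residual-df fallback applies when the curvature is
singular (boundary fits are flagged). Backward selection removes the most
non-significant term with p > α one step at a time, working down from the
three-way interaction tier through two-way interactions to main effects; a
term is ineligible while any retained higher-order interaction contains it,
so the final model always respects the hierarchy.

Per-subject slopes are the group rate plus the BLUP deviation
`Ψ Z_i' V_i⁻¹ (y_i − X_i β̂)`; annual percent change scales each slope by
the mean of that participant's own corrected volumes. Slope-versus-zero
tests are one-sample t; the one-tailed option (default for the
percent-change display) directs the alternative at the sign of the group
mean, while model term tests are always two-tailed. The Spearman
correlation between severity and change uses midrank ties and a Bonferroni
criterion α/n_tests (0.05/5 = 0.01 for the five planned regional tests);
constant inputs yield a flagged, undefined correlation rather than a
number.

Participants with one visit are retained in ROI fits (they inform the
intercept distribution) but excluded from midpoint-variant voxel-wise
designs, where their change maps are uninformative constants.

## Voxel-wise marginal model

At each voxel the map series is fitted by OLS across all retained maps; the
coefficient covariance is the subject-level sandwich
`(X'X)⁻¹ [Σ_i X_i' ẽ_i ẽ_i' X_i] (X'X)⁻¹` with HC2-type block adjustment
`ẽ_i = (I − H_ii)^(−1/2) e_i` (switchable to none). Residuals never cross
subjects, so each group's covariance is estimated from that group's own
subjects. Wald statistics `(c'β)²/(c'Vc)` are referred to χ²; the
cluster-forming threshold is applied on the p scale (default p < 0.001) and
connected components are labelled at 18-connectivity by default (6 and 26
selectable), ordered deterministically by size then lexicographic peak.

Cluster-extent FWE uses a subject-level wild bootstrap: the contrast is
removed by restricted least squares, each replicate multiplies every
subject's whole residual block by an independent Rademacher sign, the full
model is refitted, and the maximum suprathreshold cluster size is recorded;
`fwe_p = (1 + #{max ≥ observed}) / (B + 1)`, so the attainable floor is
1/(B+1) and fwe_p is monotone in observed size by construction. With one
map per subject the sandwich reduces exactly to the HC2
heteroscedasticity-robust OLS covariance (asserted against a dense
reference implementation in the tests). The χ² reference is asymptotic and
anticonservative voxel-wise at these subject counts; cluster-level
inference does not rely on it, since the bootstrap recomputes the same
statistic under the null.

## Trial power

Trials simulate the random-slope model without a random intercept (arms
share the baseline mean by design): per-subject slope
N(arm mean, τ²), homoscedastic residuals, visits at 0, 0.5, …, 3.0 yr, with
the treatment arm mean slope (1 − reduction)·placebo slope. Each trial is
analysed by the same REML engine (slope-only random structure) with a
two-sided Satterthwaite Wald t test of the arm-by-time coefficient at
α = 0.05; non-convergent trials would be excluded from the power
denominator with a reported count (none occur at the default settings).
The closed-form oracle treats each subject's OLS slope as
N(arm mean, σ²/Sxx + τ²) — Sxx = 7.0 for the default grid — and gives
two-sample z power; it brackets the integer search for the minimum arm
size, which then bisects on seeded empirical power (fixed per-n seeds make
the search reproducible). At the packaged thalamus preset the oracle yields
minimum arm sizes of 48 (50% slowing) and 34 (60% slowing).

## Problem sizes used in validation

The validation suites run at the scale of the original study where that is
stated, and at reduced grid sizes chosen for desk-scale experiments
elsewhere: slope recovery uses 200 replicate cohorts per region (all five
regions, both groups, each within 2 Monte-Carlo SEs of the generating
rate); the severity-coupling experiment uses 200 replicates of 17 patients;
voxel-wise type-I calibration uses 200 null simulations of a 10+10-subject,
three-visit cohort on a 16³ grid with 99 bootstrap replicates; the power
grid crosses arm sizes (24, 36, 48) with reductions (0.4, 0.5, 0.6) at
1000 trials per cell; null-trial calibration uses 1000 trials at 40 per
arm. What passing shows — and does not show. The generator draws exactly
the model the ROI analysis fits, so recovery there demonstrates estimator
correctness, not robustness to model misspecification; real data add
skewed residuals, informative dropout, registration artefacts and spatial
nonstationarity that these synthetic conditions do not emulate. The
voxel-wise and bootstrap calibration checks are the exception: they hold
under group-specific covariance the fitted marginal model does not assume.

## Known limitations

- Multi-df voxel-wise contrasts are supported in the engine but all shipped
  contrasts are single-df; term tests in the ROI models are single-df by
  construction of the binary codings.
- Satterthwaite df are numerical (finite differences); step sizes induce
  ~percent-level df variation, immaterial at these sample sizes.
- The wild bootstrap assumes symmetric residual blocks under the null;
  heavy asymmetry at very small subject counts is not covered by the
  shipped calibration experiment.
- Voxel-wise analyses fit the raw Jacobian by default (log as an option);
  at the simulated effect and noise scales the two are nearly linear maps
  of each other.
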