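# Default study-condition parameters for the synthetic Wolfram-syndrome
# longitudinal morphometry cohort and downstream analyses.
#
# Published quantities (group sizes, age ranges, mean follow-up, per-region
# mean annual slopes and their SEMs) are taken from the study's demographic
# and mixed-model tables. Quantities the study did not print (visit-count
# probabilities, baseline volume means/SDs, residual SDs, slope SDs, eTIV
# distribution) are package choices documented in docs/methods.md; edit here,
# not in code.

cohort:
  n_wolfram: 29
  n_control: 52
  diabetic_control_fraction: 0.4615384615384615   # 24 / 52
  sex_balance_male: 0.52                          # 15/29 and 27/52 male
  baseline_age_range:
    wolfram: [5.9, 25.8]
    control: [6.0, 26.2]
  # P(number of visits). Wolfram: mass 4/29 on a single visit (study footnote),
  # remainder spread over 2..7 so that the mean follow-up among multi-visit
  # participants is 3.6 yr with SD 1.70 at ~annual spacing.
  visit_count_probs:
    wolfram: [0.13793103448275862,   # 1 visit (4/29)
              0.1264367816091954,    # 2 visits = (25/29)*(1/6 - 0.02)
              0.14367816091954022,   # 3
              0.14367816091954022,   # 4
              0.14367816091954022,   # 5
              0.14367816091954022,   # 6
              0.16091954022988508]   # 7 visits = (25/29)*(1/6 + 0.02)
    # Controls: 12/52 single visit, all multi-visit controls seen 3 times
    # (follow-up 2.0 yr, matching the published 2.0 +- 0.3).
    control: [0.23076923076923078, 0.0, 0.7692307692307693]
  inter_visit_interval:
    mean: 1.0          # years
    jitter_sd: 0.15    # years; truncated so intervals stay positive
  etiv:
    mean: 1.5e6        # mm^3; log-normal parameterized so the MEAN is this
    log_sd: 0.08
  seed: 20200417

# Per-region trajectory presets. mean_slope (mm^3/yr) are the published
# group means; slope_sd = published SEM * sqrt(group n) (SEM of a mean of
# per-subject slopes); baseline and residual values are package choices at
# roughly FreeSurfer-scale volumes (hemisphere-averaged where applicable).
regions:
  brainstem:
    mean_slope: {wolfram: -123.61, control: 182.39}
    slope_sd:   {wolfram: 140.44,  control: 127.72}    # 26.08*sqrt(29), 17.71*sqrt(52)
    baseline_mean: 21000.0
    baseline_sd: 2200.0
    residual_sd: 260.0
    etiv_coupling: 1.0
  ventral_pons:
    mean_slope: {wolfram: -48.44, control: 93.23}
    slope_sd:   {wolfram: 98.71,  control: 88.99}      # 18.33*sqrt(29), 12.34*sqrt(52)
    baseline_mean: 2400.0
    baseline_sd: 320.0
    residual_sd: 60.0
    etiv_coupling: 1.0
  cerebellar_white:
    mean_slope: {wolfram: 24.32,  control: 248.91}
    slope_sd:   {wolfram: 141.30, control: 129.95}     # 26.24*sqrt(29), 18.02*sqrt(52)
    baseline_mean: 13000.0
    baseline_sd: 1600.0
    residual_sd: 220.0
    etiv_coupling: 1.0
  cerebellar_gray:
    mean_slope: {wolfram: -420.95, control: -49.26}
    slope_sd:   {wolfram: 444.20,  control: 435.79}    # 82.49*sqrt(29), 60.43*sqrt(52)
    baseline_mean: 47000.0
    baseline_sd: 4800.0
    residual_sd: 600.0
    etiv_coupling: 1.0
  thalamus:
    mean_slope: {wolfram: -84.68, control: 11.26}
    slope_sd:   {wolfram: 31.56,  control: 34.69}      # 5.86*sqrt(29), 4.81*sqrt(52)
    baseline_mean: 7500.0
    baseline_sd: 750.0
    # Chosen so the closed-form power of the published trial design
    # (biannual visits over 3 yr, alpha 0.05, 80% power) reproduces the
    # published 48 / 34 patients per arm at 50% / 60% slowing.
    residual_sd: 177.0
    etiv_coupling: 1.0

wurs:
  # Target sample Spearman correlation between WURS Physical score and
  # per-participant thalamic annual percent change, and the subsample size
  # at which that sample statistic was observed. The generator converts the
  # target to a latent Pearson coupling with a finite-sample (Moran)
  # calibration at calibration_n; set calibration_n to null to use the
  # asymptotic 2*sin(pi*rho_s/6) map instead.
  target_rank_corr: -0.669
  calibration_n: 17
  # strictly increasing map latent-normal -> nonnegative score scale
  score_log_mean: 2.08   # median ~ 8 points
  score_log_sd: 0.6

trial:
  region: thalamus
  visit_times: [0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0]
  alpha: 0.05
  n_trials: 1000
  target_power: 0.8
  reductions: [0.5, 0.6]

voxelwise:
  cluster_forming_p: 0.001
  n_bootstrap: 999
  fwe_alpha: 0.05
  connectivity: 18
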