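"""Reusable Monte-Carlo experiments: parameter recovery, rank-correlation
coupling, voxel-wise type-I calibration, and power-versus-oracle grids.

These drive both the test suite and the reproduction script, so problem
sizes are parameters with the study-scale values as defaults.
"""
from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import (
    CohortDesign,
    default_design,
    default_region_params,
    generate_cohort,
    simulate_roi_volumes,
    simulate_wurs,
)
from .mixed import MixedModelSpec, correct_for_etiv, fit_random_slope
from .params import REGION_NAMES, load_params
from .power import analytic_oracle, default_trial_design, empirical_power
from .tbm import simulate_tbm_stack
from .voxelwise import build_design, wild_bootstrap_fwe

__all__ = [
    "slope_recovery",
    "true_percent_change",
    "wurs_coupling",
    "fwe_null_calibration",
    "power_grid_vs_oracle",
    "null_trial_rejection_rate",
]


def slope_recovery(
    n_cohorts: int = 200,
    regions: tuple = REGION_NAMES,
    seed: int = 0,
) -> pd.DataFrame:
    """Fit the group-slope model to repeated synthetic cohorts.

    Returns one row per (region, group) with the preset truth, the Monte-
    Carlo mean of the fitted mean annual rate, and its MC standard error.
    """
    params = default_region_params()
    spec = MixedModelSpec(fixed_terms=("group", "time", "group:time"))
    est: dict = {(r, g): [] for r in regions for g in ("wolfram", "control")}
    for i in range(n_cohorts):
        cohort = generate_cohort(seed=seed + 10_000 + i)
        vols = simulate_roi_volumes(cohort, seed=seed + 20_000 + i, regions=regions)
        corrected = correct_for_etiv(vols.data)
        merged = corrected.merge(cohort.participants, on="participant_id")
        for region in regions:
            fit = fit_random_slope(
                merged[merged.region == region], spec, satterthwaite=False
            )
            for g in ("wolfram", "control"):
                est[(region, g)].append(fit.group_slopes[g])
    rows = []
    for (region, g), vals in est.items():
        vals = np.asarray(vals)
        rows.append(
            (region, g, params[region].mean_slope[g], vals.mean(),
             vals.std(ddof=1) / np.sqrt(len(vals)))
        )
    return pd.DataFrame(
        rows, columns=["region", "group", "truth", "mean_estimate", "mc_se"]
    )


def true_percent_change(cohort, vols, region: str = "thalamus") -> pd.Series:
    """Latent annual percent change per participant: 100 * slope over the
    participant's expected mean volume across their own visits."""
    lat = vols.latents[vols.latents.region == region].set_index("participant_id")
    tbar = cohort.visits.groupby("participant_id").time_from_baseline.mean()
    return 100.0 * lat.slope / (lat.intercept + lat.slope * tbar.reindex(lat.index))


def wurs_coupling(
    n_reps: int = 200,
    n_wolfram: int = 17,
    seed: int = 0,
    target: float | None = None,
    calibration_n: int | None = None,
) -> dict:
    """Sample Spearman correlation between WURS score and thalamic percent
    change over replicate patient samples.

    With ``target=None`` the packaged default coupling (finite-sample
    calibrated) is used.
    """
    base = default_design()
    design = replace(
        base,
        n_wolfram=n_wolfram,
        n_control=2,
        visit_count_probs=base.visit_count_probs,
    )

    def patient_pct(seed_gen, seed_vol):
        cohort = generate_cohort(design, seed=seed_gen)
        vols = simulate_roi_volumes(cohort, seed=seed_vol, regions=("thalamus",))
        pct = true_percent_change(cohort, vols)
        wolf = cohort.participants.loc[
            cohort.participants.group == "wolfram", "participant_id"
        ]
        return cohort, pct.loc[wolf]

    # auxiliary severity pool: the coupling is applied through the severity
    # population's own CDF (Gaussian copula), which the finite-sample
    # Spearman calibration assumes
    pool = np.concatenate(
        [patient_pct(seed + 90_000 + j, seed + 95_000 + j)[1].to_numpy()
         for j in range(max(2000 // n_wolfram, 30))]
    )

    rhos = []
    for i in range(n_reps):
        cohort, pct = patient_pct(seed + 30_000 + i, seed + 40_000 + i)
        wurs = simulate_wurs(
            cohort, pct, target_rank_corr=target, seed=seed + 50_000 + i,
            calibration_n=calibration_n, severity_reference=pool,
        )
        rho, _ = stats.spearmanr(pct.loc[wurs.index], wurs)
        rhos.append(rho)
    rhos = np.asarray(rhos)
    cfg = load_params()["wurs"]
    return dict(
        mean_rho=float(rhos.mean()),
        mc_se=float(rhos.std(ddof=1) / np.sqrt(len(rhos))),
        n_reps=n_reps,
        n_wolfram=n_wolfram,
        target=float(target if target is not None else cfg["target_rank_corr"]),
    )


def _calibration_design(n_per_group: int = 10) -> CohortDesign:
    return CohortDesign(
        n_wolfram=n_per_group,
        n_control=n_per_group,
        visit_count_probs={
            "wolfram": [0, 0, 1.0, 0, 0, 0, 0],
            "control": [0, 0, 1.0],
        },
        seed=0,
    )


def fwe_null_calibration(
    n_sims: int = 200,
    n_bootstrap: int = 99,
    shape: tuple = (16, 16, 16),
    n_per_group: int = 10,
    noise_sd: float = 0.02,
    cluster_forming_p: float = 0.001,
    fwe_alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Fraction of pure-null analyses declaring any FWE-significant cluster.

    Each simulation draws a fresh balanced two-group cohort, generates
    effect-free smooth Jacobian stacks, runs the group-by-time wild
    bootstrap, and checks for any cluster with fwe_p < fwe_alpha.
    """
    design = _calibration_design(n_per_group)
    hits = 0
    for s in range(n_sims):
        cohort = generate_cohort(design, seed=seed + 60_000 + s)
        stack = simulate_tbm_stack(
            cohort, shape=shape, effect=None, noise_sd=noise_sd,
            seed=seed + 70_000 + s,
        )
        vd = build_design(
            stack, covariates=("group", "time"), interactions=("group:time",),
            participants=cohort.participants, variant="to_midpoint",
        )
        ct = wild_bootstrap_fwe(
            stack, vd, "group:time", n_bootstrap=n_bootstrap,
            cluster_forming_p=cluster_forming_p, seed=seed + 80_000 + s,
        )
        if len(ct) and (ct.table.fwe_p < fwe_alpha).any():
            hits += 1
    rate = hits / n_sims
    half = 1.96 * np.sqrt(fwe_alpha * (1 - fwe_alpha) / n_sims)
    return dict(
        rate=rate, n_sims=n_sims, nominal=fwe_alpha,
        band=(fwe_alpha - half, fwe_alpha + half),
    )


def power_grid_vs_oracle(
    n_values: tuple = (24, 36, 48),
    reductions: tuple = (0.4, 0.5, 0.6),
    n_trials: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Empirical power against the closed-form oracle over an (n, reduction)
    grid; one row per cell with mc_se."""
    base = default_trial_design()
    rows = []
    for n in n_values:
        for r in reductions:
            d = replace(base, n_per_arm=n, reduction=r, n_trials=n_trials)
            res = empirical_power(d, seed=seed + 1000 * n + int(100 * r))
            res["analytic_power"] = analytic_oracle(d)
            rows.append(res)
    return pd.DataFrame(rows)


def null_trial_rejection_rate(
    n_trials: int = 1000, n_per_arm: int = 40, seed: int = 0
) -> dict:
    """Type-I rate of the trial analysis with identical arms."""
    d = replace(
        default_trial_design(), reduction=0.0, n_per_arm=n_per_arm,
        n_trials=n_trials,
    )
    return empirical_power(d, seed=seed)
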