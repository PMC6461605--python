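"""Monte-Carlo power and sample-size estimation for a two-arm trial that
slows the annual rate of regional volume loss.

Subjects follow y_ij = baseline + slope_i * t_j + e_ij with a random slope
(no random intercept: baseline volumes are equal by design) and
homoscedastic noise; the treatment arm's mean slope is
(1 - reduction) * placebo_slope.  Each simulated trial is analysed with the
random-slope mixed model and a two-sided Wald t test of the arm-by-time
coefficient.  A closed-form normal-approximation oracle

    v = residual_sd^2 / Sxx + slope_sd^2,   Sxx = sum (t - tbar)^2,
    power = Phi( |d slope| / sqrt(2 v / n) - z_{1-alpha/2} )

serves as an independent check and as the bracket for the sample-size
search.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .mixed import MixedModelSpec, fit_random_slope
from .params import load_params

__all__ = [
    "TrialDesign",
    "PowerCurve",
    "default_trial_design",
    "simulate_trial",
    "trial_test",
    "empirical_power",
    "analytic_oracle",
    "min_sample_size",
]


@dataclass(frozen=True)
class TrialDesign:
    """Two-arm longitudinal trial design."""

    n_per_arm: int = 48
    visit_times: tuple = (0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0)
    placebo_slope: float = -84.68
    reduction: float = 0.5
    slope_sd: float = 31.56
    residual_sd: float = 177.0
    baseline_mean: float = 7500.0
    alpha: float = 0.05
    n_trials: int = 1000
    seed: int = 0

    def __post_init__(self):
        t = np.asarray(self.visit_times)
        if len(t) < 2 or (np.diff(t) <= 0).any():
            raise ValueError("visit_times must be strictly increasing with >= 2 points")
        if not 0 <= self.reduction <= 1:
            raise ValueError("reduction must be in [0, 1]")

    @property
    def treatment_slope(self) -> float:
        return (1.0 - self.reduction) * self.placebo_slope

    @property
    def sxx(self) -> float:
        t = np.asarray(self.visit_times)
        return float(((t - t.mean()) ** 2).sum())


@dataclass
class PowerCurve:
    """Empirical power by arm size and slope-reduction fraction."""

    rows: pd.DataFrame  # n_per_arm, reduction, empirical_power, mc_se, n_trials, n_nonconverged
    min_n: dict = field(default_factory=dict)  # reduction -> n at target power


def default_trial_design(region: str | None = None, **overrides) -> TrialDesign:
    """Trial design preset from the packaged parameter file.

    The placebo slope and slope SD come from the chosen region's patient
    preset; the residual SD from the same region entry.
    """
    params = load_params()
    tcfg = params["trial"]
    region = region or tcfg["region"]
    r = params["regions"][region]
    base = dict(
        visit_times=tuple(tcfg["visit_times"]),
        placebo_slope=float(r["mean_slope"]["wolfram"]),
        slope_sd=float(r["slope_sd"]["wolfram"]),
        residual_sd=float(r["residual_sd"]),
        baseline_mean=float(r["baseline_mean"]),
        alpha=float(tcfg["alpha"]),
        n_trials=int(tcfg["n_trials"]),
    )
    base.update(overrides)
    return TrialDesign(**base)


def simulate_trial(design: TrialDesign, rng=None) -> pd.DataFrame:
    """One simulated trial: long table (participant_id, arm, time, volume)."""
    rng = np.random.default_rng(design.seed) if rng is None else rng
    t = np.asarray(design.visit_times)
    k = len(t)
    n = design.n_per_arm
    rows = []
    for arm, mean_slope in (
        ("placebo", design.placebo_slope),
        ("treatment", design.treatment_slope),
    ):
        slopes = mean_slope + (
            rng.normal(0.0, design.slope_sd, size=n) if design.slope_sd > 0 else np.zeros(n)
        )
        noise = (
            rng.normal(0.0, design.residual_sd, size=(n, k))
            if design.residual_sd > 0
            else np.zeros((n, k))
        )
        vols = design.baseline_mean + slopes[:, None] * t[None, :] + noise
        for i in range(n):
            pid = f"{arm[0].upper()}{i + 1:04d}"
            for j in range(k):
                rows.append((pid, arm, t[j], vols[i, j]))
    return pd.DataFrame(rows, columns=["participant_id", "arm", "time_from_baseline", "volume"])


def trial_test(dataset: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Two-sided mixed-model Wald t test of the arm-by-time effect.

    Delegates to the random-slope REML fit (random slope only, matching the
    generating model); returns reject flag, p, estimate and convergence.
    """
    if dataset["arm"].nunique() != 2:
        raise ValueError("both arms must be present")
    fit = fit_random_slope(
        dataset,
        MixedModelSpec(fixed_terms=("group", "time", "group:time"), random_terms=("slope",)),
        group_col="arm",
    )
    row = fit.fixed_effects.set_index("term").loc["group:time"]
    return dict(
        reject=bool(row.p < alpha),
        p=float(row.p),
        estimate=float(row.estimate),
        se=float(row.se),
        df=float(row.df),
        converged=bool(fit.converged),
    )


def empirical_power(design: TrialDesign, seed: int | None = None) -> dict:
    """Fraction of simulated trials rejecting at the design alpha."""
    if design.n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    seed = design.seed if seed is None else seed
    ss = np.random.SeedSequence([seed, 505])
    rejects = 0
    used = 0
    nonconv = 0
    for child in ss.spawn(design.n_trials):
        rng = np.random.default_rng(child)
        data = simulate_trial(design, rng=rng)
        try:
            res = trial_test(data, design.alpha)
        except np.linalg.LinAlgError:
            nonconv += 1
            continue
        if not res["converged"]:
            nonconv += 1
            continue
        used += 1
        rejects += res["reject"]
    if used == 0:
        raise RuntimeError("all trials failed to converge")
    p = rejects / used
    return dict(
        n_per_arm=design.n_per_arm,
        reduction=design.reduction,
        empirical_power=p,
        mc_se=float(np.sqrt(p * (1 - p) / used)),
        n_trials=used,
        n_nonconverged=nonconv,
    )


def analytic_oracle(design: TrialDesign) -> float:
    """Closed-form two-sample z approximation to the trial power."""
    v = design.residual_sd**2 / design.sxx + design.slope_sd**2
    delta = abs(design.placebo_slope - design.treatment_slope)
    if v == 0:
        return float(design.alpha if delta == 0 else 1.0)
    z = delta / np.sqrt(2 * v / design.n_per_arm) - stats.norm.ppf(1 - design.alpha / 2)
    return float(stats.norm.cdf(z)) if delta > 0 else float(design.alpha)


def analytic_min_n(design: TrialDesign, target_power: float) -> int:
    """Smallest n per arm with closed-form power >= target."""
    v = design.residual_sd**2 / design.sxx + design.slope_sd**2
    delta = abs(design.placebo_slope - design.treatment_slope)
    if delta == 0:
        raise ValueError("no effect: sample size undefined")
    za = stats.norm.ppf(1 - design.alpha / 2)
    zb = stats.norm.ppf(target_power)
    n = 2 * v * (za + zb) ** 2 / delta**2
    n = int(np.ceil(n))
    while analytic_oracle(replace(design, n_per_arm=n)) < target_power:
        n += 1
    return max(n, 2)


def min_sample_size(
    target_power: float,
    reduction: float,
    design: TrialDesign | None = None,
    n_cap: int = 500,
    seed: int | None = None,
) -> tuple[int, PowerCurve]:
    """Smallest integer n per arm whose empirical power reaches the target.

    Brackets the search with the analytic oracle, verifies the bracket
    empirically, then bisects; power is evaluated with a fixed per-n seed so
    the search is reproducible and monotone in expectation.
    """
    if not 0 < target_power < 1:
        raise ValueError("target power must be in (0, 1)")
    design = design or default_trial_design()
    design = replace(design, reduction=reduction)
    seed = design.seed if seed is None else seed

    n_anal = analytic_min_n(design, target_power)
    lo = max(2, int(np.floor(0.6 * n_anal)))
    hi = min(n_cap, max(lo + 1, int(np.ceil(1.6 * n_anal))))

    evaluated = {}

    def power_at(n):
        if n not in evaluated:
            evaluated[n] = empirical_power(
                replace(design, n_per_arm=n), seed=seed + 7 * n
            )
        return evaluated[n]["empirical_power"]

    while power_at(hi) < target_power:
        if hi >= n_cap:
            raise RuntimeError(f"target power unreachable within n_per_arm <= {n_cap}")
        lo = hi
        hi = min(n_cap, hi * 2)
    if power_at(lo) >= target_power:
        lo = 2
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if power_at(mid) >= target_power:
            hi = mid
        else:
            lo = mid
    rows = pd.DataFrame(
        [evaluated[n] for n in sorted(evaluated)],
    )
    return hi, PowerCurve(rows=rows, min_n={reduction: hi})


def power_grid(
    designs: list[TrialDesign] | None = None,
    n_values: tuple = (24, 36, 48),
    reductions: tuple = (0.4, 0.5, 0.6),
    base: TrialDesign | None = None,
    seed: int = 0,
) -> PowerCurve:
    """Empirical power over an (n, reduction) grid with the analytic oracle."""
    base = base or default_trial_design()
    rows = []
    if designs is None:
        designs = [
            replace(base, n_per_arm=n, reduction=r)
            for n in n_values
            for r in reductions
        ]
    for i, d in enumerate(designs):
        res = empirical_power(d, seed=seed + 11 * (i + 1))
        res["analytic_power"] = analytic_oracle(d)
        rows.append(res)
    return PowerCurve(rows=pd.DataFrame(rows))
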