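"""Synthetic longitudinal cohorts: participants, visit schedules, regional
volume trajectories and symptom-severity scores.

The generator emulates the structure of an unbalanced two-group pediatric
neuroimaging study: a patient group (``wolfram``) followed annually for up
to seven visits and a control group seen up to three times, with
group-specific mean annual volume change per brain region, per-participant
random intercepts and slopes, homoscedastic measurement noise, and head-size
(eTIV) coupling of raw volumes.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .params import REGION_NAMES, load_params

__all__ = [
    "CohortDesign",
    "Cohort",
    "ROIParams",
    "ROIVolumes",
    "default_design",
    "default_region_params",
    "generate_cohort",
    "simulate_roi_volumes",
    "simulate_wurs",
    "spearman_to_pearson",
    "expected_sample_spearman",
    "calibrate_latent_pearson",
]

GROUPS = ("wolfram", "control")


class ConfigurationError(ValueError):
    """Raised for invalid design or parameter configurations."""


@dataclass(frozen=True)
class CohortDesign:
    """Sampling plan for a two-group longitudinal cohort."""

    n_wolfram: int = 29
    n_control: int = 52
    diabetic_control_fraction: float = 24 / 52
    sex_balance_male: float = 0.52
    baseline_age_range: dict = field(
        default_factory=lambda: {"wolfram": (5.9, 25.8), "control": (6.0, 26.2)}
    )
    # probability over 1..7 visits (wolfram) and 1..3 (control)
    visit_count_probs: dict = field(default_factory=dict)
    interval_mean: float = 1.0
    interval_jitter_sd: float = 0.15
    etiv_mean: float = 1.5e6
    etiv_log_sd: float = 0.08
    seed: int = 20200417

    def validate(self) -> None:
        if self.n_wolfram < 1 or self.n_control < 1:
            raise ConfigurationError("group sizes must be >= 1")
        if self.interval_mean <= 0:
            raise ConfigurationError("inter-visit interval mean must be > 0")
        for g in GROUPS:
            p = np.asarray(self.visit_count_probs[g], dtype=float)
            if p.ndim != 1 or (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"visit-count probabilities for {g!r} must be a "
                    "nonnegative vector summing to 1"
                )


@dataclass(frozen=True)
class Cohort:
    """Participants plus visit schedule.

    ``participants``: one row per participant (id, group, diabetes, sex,
    baseline_age, etiv).  ``visits``: one row per scan (participant_id,
    session, age_at_scan, time_from_baseline, time_to_midpoint).
    """

    participants: pd.DataFrame
    visits: pd.DataFrame

    def n_by_group(self) -> dict:
        return self.participants.groupby("group").size().to_dict()


@dataclass(frozen=True)
class ROIParams:
    """Trajectory-generating parameters for one region.

    ``mean_slope``/``slope_sd`` are per-group (mm^3/yr); volumes are on the
    head-size-corrected scale, and raw volumes are obtained by scaling with
    ``(etiv / etiv_reference) ** etiv_coupling``.
    """

    region: str
    mean_slope: dict
    slope_sd: dict
    baseline_mean: float
    baseline_sd: float
    residual_sd: float
    etiv_coupling: float = 1.0

    def validate(self) -> None:
        if min(self.slope_sd.values()) < 0 or self.baseline_sd < 0 or self.residual_sd < 0:
            raise ConfigurationError(f"{self.region}: SDs must be >= 0")


@dataclass(frozen=True)
class ROIVolumes:
    """Long-format per-visit regional volumes plus the latent truth.

    ``data`` columns: participant_id, session, region, time_from_baseline,
    volume (raw, eTIV-coupled), etiv.  ``latents`` columns: participant_id,
    region, intercept, slope (corrected scale).
    """

    data: pd.DataFrame
    latents: pd.DataFrame
    etiv_reference: float


def default_design(params: dict | None = None) -> CohortDesign:
    p = (params or load_params())["cohort"]
    return CohortDesign(
        n_wolfram=p["n_wolfram"],
        n_control=p["n_control"],
        diabetic_control_fraction=p["diabetic_control_fraction"],
        sex_balance_male=p["sex_balance_male"],
        baseline_age_range={g: tuple(p["baseline_age_range"][g]) for g in GROUPS},
        visit_count_probs={g: list(p["visit_count_probs"][g]) for g in GROUPS},
        interval_mean=p["inter_visit_interval"]["mean"],
        interval_jitter_sd=p["inter_visit_interval"]["jitter_sd"],
        etiv_mean=float(p["etiv"]["mean"]),
        etiv_log_sd=p["etiv"]["log_sd"],
        seed=p["seed"],
    )


def default_region_params(params: dict | None = None) -> dict[str, ROIParams]:
    cfg = (params or load_params())["regions"]
    out = {}
    for name in REGION_NAMES:
        r = cfg[name]
        out[name] = ROIParams(
            region=name,
            mean_slope=dict(r["mean_slope"]),
            slope_sd=dict(r["slope_sd"]),
            baseline_mean=float(r["baseline_mean"]),
            baseline_sd=float(r["baseline_sd"]),
            residual_sd=float(r["residual_sd"]),
            etiv_coupling=float(r.get("etiv_coupling", 1.0)),
        )
    return out


def generate_cohort(design: CohortDesign | None = None, seed: int | None = None) -> Cohort:
    """Draw a cohort: group sizes are exact, visit counts and schedules random.

    ``time_to_midpoint`` is the signed time (years) from each scan to the
    participant's mean scan time, so it sums to zero within participant.
    """
    design = design or default_design()
    if seed is not None:
        design = replace(design, seed=seed)
    design.validate()

    root = np.random.SeedSequence(design.seed)

    rows, vrows = [], []
    for group, n in (("wolfram", design.n_wolfram), ("control", design.n_control)):
        probs = np.asarray(design.visit_count_probs[group], dtype=float)
        lo, hi = design.baseline_age_range[group]
        n_diab = (
            n if group == "wolfram" else int(round(design.diabetic_control_fraction * n))
        )
        for i in range(n):
            pid = f"{'W' if group == 'wolfram' else 'C'}{i + 1:03d}"
            sub = np.random.default_rng(root.spawn(1)[0])
            n_visits = int(sub.choice(np.arange(1, len(probs) + 1), p=probs))
            baseline_age = sub.uniform(lo, hi)
            sex = "M" if sub.random() < design.sex_balance_male else "F"
            diabetes = 1 if i < n_diab else 0
            etiv = design.etiv_mean * np.exp(
                sub.normal(-0.5 * design.etiv_log_sd**2, design.etiv_log_sd)
            )
            intervals = sub.normal(
                design.interval_mean, design.interval_jitter_sd, size=n_visits - 1
            )
            intervals = np.clip(intervals, 0.2 * design.interval_mean, None)
            times = np.concatenate([[0.0], np.cumsum(intervals)])
            tmid = times - times.mean()
            rows.append((pid, group, diabetes, sex, baseline_age, etiv))
            for s in range(n_visits):
                vrows.append((pid, s + 1, baseline_age + times[s], times[s], tmid[s]))

    participants = pd.DataFrame(
        rows,
        columns=["participant_id", "group", "diabetes", "sex", "baseline_age", "etiv"],
    )
    visits = pd.DataFrame(
        vrows,
        columns=[
            "participant_id",
            "session",
            "age_at_scan",
            "time_from_baseline",
            "time_to_midpoint",
        ],
    )
    return Cohort(participants=participants, visits=visits)


def simulate_roi_volumes(
    cohort: Cohort,
    region_params: dict[str, ROIParams] | None = None,
    seed: int = 0,
    regions: tuple[str, ...] | None = None,
) -> ROIVolumes:
    """Simulate per-visit regional volumes under the random-slope model.

    volume_corrected = intercept_i + slope_i * t + e,  e ~ N(0, residual_sd^2)
    with intercept_i ~ N(baseline_mean, baseline_sd^2) and slope_i drawn from
    the participant's group Normal.  The recorded raw volume is the corrected
    value scaled by (etiv_i / etiv_reference)**etiv_coupling.
    """
    if region_params is None:
        region_params = default_region_params()
    regions = regions or tuple(region_params)
    missing = [r for r in regions if r not in region_params]
    if missing:
        raise ConfigurationError(f"missing region parameters: {missing}")
    etiv_ref = float(load_params()["cohort"]["etiv"]["mean"])

    root = np.random.SeedSequence([seed, 101])
    parts = cohort.participants.set_index("participant_id")
    visits = cohort.visits

    lat_rows, data_rows = [], []
    for pid, prow in parts.iterrows():
        sub = np.random.default_rng(root.spawn(1)[0])
        v = visits[visits.participant_id == pid]
        t = v.time_from_baseline.to_numpy()
        for name in regions:
            p = region_params[name]
            p.validate()
            icpt = sub.normal(p.baseline_mean, p.baseline_sd)
            slope = sub.normal(p.mean_slope[prow.group], p.slope_sd[prow.group])
            noise = (
                sub.normal(0.0, p.residual_sd, size=len(t))
                if p.residual_sd > 0
                else np.zeros(len(t))
            )
            corrected = icpt + slope * t + noise
            raw = corrected * (prow.etiv / etiv_ref) ** p.etiv_coupling
            lat_rows.append((pid, name, icpt, slope))
            for sess, ti, volume in zip(v.session, t, raw):
                data_rows.append((pid, sess, name, ti, volume, prow.etiv))

    data = pd.DataFrame(
        data_rows,
        columns=["participant_id", "session", "region", "time_from_baseline", "volume", "etiv"],
    )
    latents = pd.DataFrame(
        lat_rows, columns=["participant_id", "region", "intercept", "slope"]
    )
    return ROIVolumes(data=data, latents=latents, etiv_reference=etiv_ref)


# --- rank-correlation coupling -------------------------------------------

def spearman_to_pearson(rho_s: float) -> float:
    """Latent Pearson correlation giving population Spearman ``rho_s`` for
    bivariate normal data: rho = 2 sin(pi * rho_s / 6)."""
    return 2.0 * np.sin(np.pi * rho_s / 6.0)


def expected_sample_spearman(rho: float, n: int) -> float:
    """Exact expectation of the sample Spearman coefficient for an i.i.d.
    bivariate-normal sample of size n with Pearson correlation rho (Moran)."""
    return 6.0 / (np.pi * (n + 1)) * (np.arcsin(rho) + (n - 2) * np.arcsin(rho / 2.0))


def calibrate_latent_pearson(target_rank_corr: float, n: int | None = None) -> float:
    """Latent Pearson coupling for a target Spearman correlation.

    With ``n`` given, solves Moran's finite-sample expectation so that the
    *expected sample* Spearman at that n equals the target; otherwise uses
    the asymptotic (population) map.
    """
    if not -1.0 <= target_rank_corr <= 1.0:
        raise ConfigurationError("target rank correlation must be in [-1, 1]")
    if n is None:
        return spearman_to_pearson(target_rank_corr)
    if abs(target_rank_corr) == 1.0:
        return float(np.sign(target_rank_corr))
    f = lambda r: expected_sample_spearman(r, n) - target_rank_corr
    return float(optimize.brentq(f, -1 + 1e-12, 1 - 1e-12))


def simulate_wurs(
    cohort: Cohort,
    severity: pd.Series,
    target_rank_corr: float | None = None,
    seed: int = 0,
    calibration_n: int | None = None,
    severity_loc: float | None = None,
    severity_scale: float | None = None,
    severity_reference: np.ndarray | None = None,
) -> pd.Series:
    """Simulate WURS Physical scores for the patient group.

    ``severity`` is a per-participant measure of progression (typically the
    latent thalamic annual percent change, negative = worse) indexed by
    participant id.  Scores are nonnegative and coupled to severity through
    a latent bivariate normal whose Pearson correlation is derived from
    ``target_rank_corr``; any strictly increasing transform of the latent
    leaves the rank correlation intact, so the score scale is a log-normal
    map chosen to resemble a symptom-count scale.

    The latent Gaussianised severity can be formed three ways, in order of
    fidelity of the resulting rank coupling:

    * ``severity_reference``: an auxiliary draw from the severity
      *population*; severities are mapped to normal scores through the
      reference's empirical CDF (Gaussian-copula coupling, exact for any
      continuous severity distribution);
    * ``severity_loc``/``severity_scale``: linear population
      standardisation (exact for normal severity);
    * neither: sample moments — this conditions the marginal and slightly
      strengthens the realised rank coupling in small samples.
    """
    wurs_cfg = load_params()["wurs"]
    if target_rank_corr is None:
        target_rank_corr = float(wurs_cfg["target_rank_corr"])
        if calibration_n is None:
            calibration_n = wurs_cfg.get("calibration_n")
    rho = calibrate_latent_pearson(target_rank_corr, calibration_n)

    wolf = cohort.participants.loc[
        cohort.participants.group == "wolfram", "participant_id"
    ]
    wolf = [p for p in wolf if p in set(severity.index)]
    if not wolf:
        return pd.Series(dtype=float, name="wurs_physical")
    x = severity.loc[wolf].to_numpy(dtype=float)
    if severity_reference is not None:
        pool = np.sort(np.asarray(severity_reference, dtype=float))
        u = (np.searchsorted(pool, x) + 0.5) / (len(pool) + 1)
        z_sev = stats.norm.ppf(np.clip(u, 1e-9, 1 - 1e-9))
    else:
        loc = x.mean() if severity_loc is None else float(severity_loc)
        sd = x.std(ddof=0) if severity_scale is None else float(severity_scale)
        z_sev = (x - loc) / sd if sd > 0 else np.zeros_like(x)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 202]))
    eps = rng.standard_normal(len(x))
    z = rho * z_sev + np.sqrt(max(0.0, 1.0 - rho**2)) * eps
    scores = np.exp(wurs_cfg["score_log_mean"] + wurs_cfg["score_log_sd"] * z)
    return pd.Series(scores, index=pd.Index(wolf, name="participant_id"), name="wurs_physical")
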