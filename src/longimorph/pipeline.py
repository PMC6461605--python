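"""End-to-end pipeline: generate -> ROI fits -> voxel-wise -> power.

Every run writes a JSON echo of the fully resolved configuration and a log
with versions, seeds and stage durations, sufficient to reproduce the run
bit-for-bit.
"""
from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import generate_cohort, simulate_roi_volumes, simulate_wurs
from .mixed import (
    annual_percent_change,
    backward_select,
    correct_for_etiv,
    wurs_slope_correlation,
)
from .params import REGION_NAMES
from .power import analytic_oracle, default_trial_design, empirical_power
from .tbm import TBMEffect, simulate_tbm_stack
from .voxelwise import build_design, wild_bootstrap_fwe
from . import io as lio

logger = logging.getLogger("longimorph")

__all__ = ["RunConfig", "run_pipeline", "StageError"]


class StageError(RuntimeError):
    """A pipeline stage failed; the message is tagged with the stage name."""


_KNOWN_KEYS = {
    "seed", "out_dir", "grid_shape", "noise_sd", "cluster_slope",
    "n_bootstrap", "cluster_forming_p", "connectivity", "regions",
    "power_reductions", "power_n_trials", "power_n_per_arm", "run_voxelwise",
    "run_power", "one_tailed", "mask_path",
}


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run (unknown keys rejected)."""

    seed: int = 0
    out_dir: str = "longimorph_run"
    grid_shape: tuple = (16, 16, 16)
    noise_sd: float = 0.02
    cluster_slope: float = -0.03   # patient-group log-Jacobian change per year
    n_bootstrap: int = 99
    cluster_forming_p: float = 0.001
    connectivity: int = 18
    regions: tuple = REGION_NAMES
    power_reductions: tuple = (0.5, 0.6)
    power_n_trials: int = 200
    power_n_per_arm: int = 48
    run_voxelwise: bool = True
    run_power: bool = True
    one_tailed: bool = True
    mask_path: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise StageError(f"[config] unknown configuration keys: {sorted(unknown)}")
        for k in ("grid_shape", "regions", "power_reductions"):
            if k in raw:
                raw[k] = tuple(raw[k])
        return cls(**raw)


def _stage(name):
    def deco(fn):
        def wrapped(*a, **kw):
            t0 = time.time()
            logger.info("stage %s: start", name)
            try:
                out = fn(*a, **kw)
            except Exception as exc:  # tag and re-raise
                raise StageError(f"[{name}] {exc}") from exc
            logger.info("stage %s: done in %.1fs", name, time.time() - t0)
            return out
        return wrapped
    return deco


@_stage("generate")
def _generate(cfg: RunConfig, out: Path):
    cohort = generate_cohort(seed=cfg.seed)
    vols = simulate_roi_volumes(cohort, seed=cfg.seed, regions=cfg.regions)
    lio.write_cohort(cohort, out)
    lio.write_table(vols.data, out / "volumes.csv")
    lio.write_table(vols.latents, out / "latent_truth.csv")
    return cohort, vols


@_stage("fit-roi")
def _fit_roi(cfg: RunConfig, out: Path, cohort, vols):
    corrected = correct_for_etiv(vols.data)
    merged = corrected.merge(cohort.participants, on="participant_id")
    summaries, traces = [], []
    fits = {}
    for region in cfg.regions:
        sub = merged[merged.region == region]
        spec, fit, trace = backward_select(sub)
        fits[region] = fit
        change = annual_percent_change(fit, corrected, region=region,
                                       one_tailed=cfg.one_tailed)
        tab = change.table.copy()
        tab.insert(0, "region", region)
        gt = fit.term_tests.set_index("term")
        if "group:time" in gt.index:
            tab["group_by_time_F"] = float(gt.loc["group:time", "F"])
            tab["group_by_time_p"] = float(gt.loc["group:time", "p"])
        summaries.append(tab)
        trace = trace.copy()
        trace.insert(0, "region", region)
        traces.append(trace)
    summary = pd.concat(summaries, ignore_index=True)
    lio.write_table(summary, out / "roi_change_summary.csv")
    pd.concat(traces, ignore_index=True).to_csv(out / "selection_trace.csv", index=False)

    # WURS coupling against thalamic percent change (patients only)
    lat = vols.latents[vols.latents.region == "thalamus"].set_index("participant_id")
    tbar = cohort.visits.groupby("participant_id").time_from_baseline.mean()
    pct = 100.0 * lat.slope / (lat.intercept + lat.slope * tbar.reindex(lat.index))
    wurs = simulate_wurs(cohort, pct, seed=cfg.seed)
    corr = wurs_slope_correlation(pct.loc[wurs.index], wurs)
    with open(out / "wurs_correlation.json", "w") as fh:
        json.dump(
            dict(rho=corr.rho, p=corr.p, n=corr.n, criterion=corr.criterion,
                 significant=corr.significant), fh, indent=2)
    lio.write_table(wurs.reset_index(), out / "wurs_scores.csv")
    return fits, summary


@_stage("fit-voxelwise")
def _fit_voxelwise(cfg: RunConfig, out: Path, cohort):
    shape = tuple(cfg.grid_shape)
    from .tbm import ellipsoid_mask

    if cfg.mask_path:
        mask = lio.read_mask(cfg.mask_path)
    else:
        mask = ellipsoid_mask(shape)
    cx = tuple(s // 2 for s in shape)
    cluster = np.zeros(shape, dtype=bool)
    cluster[cx[0] - 1 : cx[0] + 2, cx[1] - 1 : cx[1] + 2, cx[2] - 1 : cx[2] + 2] = True
    cluster &= mask
    effect = TBMEffect(cluster=cluster,
                       slope={"wolfram": cfg.cluster_slope, "control": 0.0})
    stack = simulate_tbm_stack(cohort, shape=shape, effect=effect,
                               noise_sd=cfg.noise_sd, seed=cfg.seed, mask=mask)

    results = {}
    contrast_specs = {
        "group": ("to_group_template", ("group", "etiv", "age", "sex", "diabetes"), (), "group"),
        "group_by_time": ("to_midpoint", ("group", "time", "age", "sex", "diabetes"),
                          ("group:time",), "group:time"),
        "group_by_time_by_age": (
            "to_midpoint", ("group", "time", "age", "sex", "diabetes"),
            ("group:time", "group:age", "time:age", "group:time:age"), "group:time:age"),
    }
    for name, (variant, covs, inters, cvec) in contrast_specs.items():
        design = build_design(stack, covariates=covs, interactions=inters,
                              participants=cohort.participants, variant=variant)
        ct = wild_bootstrap_fwe(stack, design, cvec, n_bootstrap=cfg.n_bootstrap,
                                cluster_forming_p=cfg.cluster_forming_p,
                                connectivity=cfg.connectivity, seed=cfg.seed)
        results[name] = ct
    # time within each group
    design = build_design(stack, covariates=("group", "time", "age", "sex", "diabetes"),
                          interactions=("group:time",),
                          participants=cohort.participants, variant="to_midpoint")
    for gname, code in (("wolfram", 0.5), ("control", -0.5)):
        c = np.zeros(design.X.shape[1])
        c[design.columns.index("time")] = 1.0
        c[design.columns.index("group:time")] = code
        ct = wild_bootstrap_fwe(stack, design, c, n_bootstrap=cfg.n_bootstrap,
                                cluster_forming_p=cfg.cluster_forming_p,
                                connectivity=cfg.connectivity, seed=cfg.seed)
        results[f"time_within_{gname}"] = ct

    rows = []
    for name, ct in results.items():
        t = ct.table.copy()
        t.insert(0, "contrast", name)
        if len(t):
            rows.append(t)
    if rows:
        tab = pd.concat(rows, ignore_index=True)
    else:
        tab = pd.DataFrame(
            columns=["contrast", "cluster_id", "size", "peak_x", "peak_y",
                     "peak_z", "peak_stat", "fwe_p"]
        )
    lio.write_table(tab, out / "cluster_table.csv")
    lio.write_nifti(mask.astype(float), out / "mask.nii.gz")
    return results


@_stage("power")
def _power(cfg: RunConfig, out: Path):
    rows = []
    for red in cfg.power_reductions:
        d = default_trial_design(
            n_per_arm=cfg.power_n_per_arm, reduction=red,
            n_trials=cfg.power_n_trials, seed=cfg.seed,
        )
        res = empirical_power(d)
        res["analytic_power"] = analytic_oracle(d)
        rows.append(res)
    tab = pd.DataFrame(rows)
    lio.write_table(tab, out / "power.csv")
    return tab


def run_pipeline(cfg: RunConfig) -> Path:
    """Run all stages; returns the output directory."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out / "run.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(fh)
    logger.setLevel(logging.INFO)
    t0 = time.time()
    try:
        logger.info("longimorph %s  seed=%d  numpy=%s", __version__, cfg.seed,
                    np.__version__)
        resolved = asdict(cfg)
        with open(out / "config.json", "w") as f:
            json.dump(resolved, f, indent=2, default=list)
        cohort, vols = _generate(cfg, out)
        _fit_roi(cfg, out, cohort, vols)
        if cfg.run_voxelwise:
            _fit_voxelwise(cfg, out, cohort)
        if cfg.run_power:
            _power(cfg, out)
        logger.info("pipeline complete in %.1fs", time.time() - t0)
    finally:
        logger.removeHandler(fh)
        fh.close()
    return out
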