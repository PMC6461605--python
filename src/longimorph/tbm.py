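"""Synthetic tensor-based-morphometry (Jacobian determinant) map stacks.

Maps are generated directly on a small 3-D grid — no image registration is
simulated.  A Jacobian value above 1 marks local expansion, below 1 local
contraction.  Two variants mirror a longitudinal TBM pipeline:

``to_midpoint``
    change of each timepoint relative to the participant's within-subject
    midpoint template; log-Jacobian = slope * time_to_midpoint + noise.
    A single-visit participant is its own midpoint, so its map is the
    identity (exactly 1 in the mask).
``to_group_template``
    each timepoint relative to a common template; log-Jacobian =
    subject offset + slope * (age - cohort mean age) + noise.

Effects are confined to a voxel cluster; all other voxels have slope 0.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .cohort import Cohort, ConfigurationError

__all__ = ["TBMStack", "TBMEffect", "simulate_tbm_stack", "ellipsoid_mask"]


@dataclass(frozen=True)
class TBMEffect:
    """Localized group-by-time effect on the log-Jacobian scale.

    ``cluster``: boolean 3-D array (or index array) of affected voxels.
    ``slope``: per-group log-Jacobian change per year inside the cluster.
    ``group_offset``: optional static per-group log-Jacobian offset inside
    the cluster (drives a group main effect in template space).
    """

    cluster: np.ndarray
    slope: dict = field(default_factory=lambda: {"wolfram": 0.0, "control": 0.0})
    group_offset: dict = field(default_factory=dict)


@dataclass
class TBMStack:
    """4-D stack of Jacobian maps plus manifest.

    ``maps``: (n_maps, X, Y, Z); ``meta`` has one row per map with columns
    (index, participant_id, session, variant, time); ``time`` is the
    variant's time covariate in years.
    """

    maps: np.ndarray
    mask: np.ndarray
    meta: pd.DataFrame
    grid_spacing: float = 2.0

    def variant(self, name: str) -> pd.DataFrame:
        return self.meta[self.meta.variant == name]


def ellipsoid_mask(shape: tuple) -> np.ndarray:
    """Brain-ish analysis mask: inscribed ellipsoid at 90% of the half-axes."""
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    c = [(s - 1) / 2 for s in shape]
    r = [max(0.9 * s / 2, 1.0) for s in shape]
    d = sum(((g - ci) / ri) ** 2 for g, ci, ri in zip(grids, c, r))
    return d <= 1.0


def simulate_tbm_stack(
    cohort: Cohort,
    shape: tuple = (16, 16, 16),
    effect: TBMEffect | None = None,
    noise_sd: float = 0.02,
    seed: int = 0,
    mask: np.ndarray | None = None,
    subject_offset_sd: float = 0.05,
    noise_fwhm: float = 3.0,
    variants: tuple = ("to_midpoint", "to_group_template"),
    grid_spacing: float = 2.0,
) -> TBMStack:
    """Generate Jacobian-determinant maps for every visit of every participant.

    ``noise_sd`` is the per-voxel log-Jacobian noise SD; ``subject_offset_sd``
    the SD of the per-subject anatomical offset in template space.
    ``noise_fwhm`` (voxels) sets the spatial correlation of the noise field:
    deformation-derived Jacobians are smooth, so the noise is a Gaussian
    random field (white noise convolved with a Gaussian kernel and rescaled
    to per-voxel SD ``noise_sd``); 0 gives white noise.
    """
    if noise_sd < 0:
        raise ConfigurationError("noise_sd must be >= 0")
    mask = ellipsoid_mask(shape) if mask is None else mask.astype(bool)
    if mask.shape != tuple(shape):
        raise ConfigurationError("mask shape must match grid shape")

    if effect is None:
        cluster = np.zeros(shape, dtype=bool)
        slopes = {g: 0.0 for g in cohort.participants.group.unique()}
        offsets = {}
    else:
        cluster = np.asarray(effect.cluster)
        if cluster.dtype != bool:
            idx = np.asarray(effect.cluster)
            cluster = np.zeros(shape, dtype=bool)
            cluster[tuple(idx.T)] = True
        if cluster.shape != tuple(shape):
            raise ConfigurationError("effect cluster shape must match grid")
        if (cluster & ~mask).any():
            raise ConfigurationError("effect cluster must lie inside the mask")
        if not cluster.any():
            raise ConfigurationError("effect cluster is empty (grid too small?)")
        slopes = dict(effect.slope)
        offsets = dict(effect.group_offset)

    sigma = noise_fwhm / 2.3548200450309493  # FWHM -> Gaussian sigma
    if sigma > 0:
        # rescaling so the smoothed field keeps per-voxel SD = noise_sd
        impulse = np.zeros(shape)
        impulse[tuple(s // 2 for s in shape)] = 1.0
        kernel = ndimage.gaussian_filter(impulse, sigma, mode="constant")
        smooth_gain = float(np.sqrt((kernel**2).sum()))

    def draw_noise(rng):
        w = rng.standard_normal(shape)
        if sigma > 0:
            w = ndimage.gaussian_filter(w, sigma, mode="constant") / smooth_gain
        return noise_sd * w

    parts = cohort.participants.set_index("participant_id")
    mean_age = float(parts.baseline_age.mean())
    root = np.random.SeedSequence([seed, 303])

    maps, meta = [], []
    for pid, prow in parts.iterrows():
        sub = np.random.default_rng(root.spawn(1)[0])
        v = cohort.visits[cohort.visits.participant_id == pid]
        slope_field = np.where(cluster, slopes.get(prow.group, 0.0), 0.0)
        offset_field = np.where(cluster, offsets.get(prow.group, 0.0), 0.0)
        subject_offset = sub.normal(0.0, subject_offset_sd) if subject_offset_sd > 0 else 0.0
        single = len(v) == 1
        for _, vr in v.iterrows():
            for variant in variants:
                if variant == "to_midpoint":
                    t = float(vr.time_to_midpoint)
                    if single:
                        logj = np.zeros(shape)
                    else:
                        logj = slope_field * t
                        if noise_sd > 0:
                            logj = logj + draw_noise(sub)
                else:
                    t = float(vr.age_at_scan - mean_age)
                    logj = offset_field + subject_offset + slope_field * t
                    if noise_sd > 0:
                        logj = logj + draw_noise(sub)
                m = np.where(mask, np.exp(logj), 1.0)
                meta.append((len(maps), pid, int(vr.session), variant, t))
                maps.append(m)

    meta_df = pd.DataFrame(
        meta, columns=["index", "participant_id", "session", "variant", "time"]
    )
    return TBMStack(
        maps=np.stack(maps), mask=mask, meta=meta_df, grid_spacing=grid_spacing
    )
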