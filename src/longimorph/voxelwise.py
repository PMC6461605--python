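"""Voxel-wise marginal-model inference on tensor-based-morphometry stacks.

Each voxel's Jacobian-determinant series is modelled with ordinary least
squares across maps; the coefficient covariance is estimated with a
subject-level sandwich (heteroscedasticity-robust) estimator, so repeated
maps from one participant are treated as a correlated block and each
group's residuals enter only through that group's own subjects.  Wald
statistics are converted to p-values on the chi-square scale, suprathreshold
voxels are grouped into connected clusters, and cluster-extent family-wise
error is controlled with a subject-level wild (Rademacher) bootstrap of the
null-restricted model.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

__all__ = [
    "VoxelDesign",
    "StatMap",
    "ClusterTable",
    "build_design",
    "fit_marginal",
    "form_clusters",
    "wild_bootstrap_fwe",
]


class DesignError(ValueError):
    """Raised for invalid or rank-deficient voxel-wise designs."""


CONNECTIVITY_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass(frozen=True)
class VoxelDesign:
    """Design for one voxel-wise analysis."""

    X: np.ndarray                 # n_maps x p
    columns: tuple                # column names
    subject_index: np.ndarray     # n_maps ints, contiguous per subject
    subject_ids: tuple            # id per unique index
    map_rows: pd.DataFrame        # the manifest rows used (in order)
    outcome_variant: str = "to_midpoint"


@dataclass
class StatMap:
    """Per-contrast voxel-wise statistics on the analysis mask."""

    beta: np.ndarray              # p x V (in-mask columns)
    wald: np.ndarray              # V
    p: np.ndarray                 # V (uncorrected)
    mask: np.ndarray              # 3-D bool
    contrast: np.ndarray
    df: int
    n_zero_variance: int = 0

    def volume(self, values: np.ndarray, fill=np.nan) -> np.ndarray:
        """Scatter an in-mask vector back into a 3-D volume."""
        out = np.full(self.mask.shape, fill, dtype=float)
        out[self.mask] = values
        return out


@dataclass
class ClusterTable:
    """Clusters of suprathreshold voxels, optionally with FWE p-values."""

    table: pd.DataFrame  # cluster_id, size, peak_x, peak_y, peak_z, peak_stat[, fwe_p]
    cluster_forming_p: float
    connectivity: int
    n_bootstrap: int | None = None
    max_null_sizes: np.ndarray | None = None

    def __len__(self):
        return len(self.table)


# --------------------------------------------------------------------------

def build_design(
    stack,
    covariates: tuple = ("group", "time"),
    interactions: tuple = ("group:time",),
    participants: pd.DataFrame | None = None,
    variant: str = "to_midpoint",
    drop_single_visit: bool | None = None,
) -> VoxelDesign:
    """Build the marginal-model design matrix from a TBM stack manifest.

    One row per map of the requested variant.  ``time`` is the map's time
    covariate (signed years to the within-subject midpoint for the
    ``to_midpoint`` variant).  Binary covariates are effect-coded (+-1/2);
    ``age`` (baseline age) and ``etiv`` are centred.  Single-visit
    participants are dropped from ``to_midpoint`` designs by default: their
    change maps are uninformative constants.
    """
    meta = stack.meta[stack.meta.variant == variant].copy()
    if drop_single_visit is None:
        drop_single_visit = variant == "to_midpoint"
    if drop_single_visit:
        counts = meta.groupby("participant_id")["session"].transform("size")
        meta = meta[counts >= 2]
    if participants is not None:
        meta = meta.merge(participants, on="participant_id", how="left")
    meta = meta.sort_values(["participant_id", "session"]).reset_index(drop=False)

    base = {}
    if "group" in str(covariates) + str(interactions):
        levels = sorted(meta["group"].unique())
        base["group"] = np.where(meta["group"] == levels[-1], 0.5, -0.5)
    base["time"] = meta["time"].to_numpy(dtype=float)
    if "age" in str(covariates) + str(interactions):
        a = meta["baseline_age"].to_numpy(dtype=float)
        base["age"] = a - a.mean()
    if "sex" in covariates:
        base["sex"] = np.where(meta["sex"] == "M", 0.5, -0.5)
    if "diabetes" in covariates:
        base["diabetes"] = meta["diabetes"].to_numpy(dtype=float) - 0.5
    if "etiv" in covariates:
        e = meta["etiv"].to_numpy(dtype=float)
        base["etiv"] = (e - e.mean()) / e.std(ddof=0)

    cols = [np.ones(len(meta))]
    names = ["intercept"]
    for c in covariates:
        cols.append(base[c])
        names.append(c)
    for term in interactions:
        v = np.ones(len(meta))
        for part in term.split(":"):
            v = v * base[part]
        cols.append(v)
        names.append(term)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        corr = np.corrcoef(X[:, 1:].T)
        bad = [
            (names[i + 1], names[j + 1])
            for i in range(corr.shape[0])
            for j in range(i)
            if abs(corr[i, j]) > 0.999
        ]
        raise DesignError(f"rank-deficient design; collinear columns: {bad}")

    uid, sidx = np.unique(meta["participant_id"], return_inverse=True)
    return VoxelDesign(
        X=X,
        columns=tuple(names),
        subject_index=sidx,
        subject_ids=tuple(uid),
        map_rows=meta,
        outcome_variant=variant,
    )


def contrast_vector(design: VoxelDesign, name_or_vec) -> np.ndarray:
    if isinstance(name_or_vec, str):
        if name_or_vec not in design.columns:
            raise DesignError(f"no design column {name_or_vec!r}")
        c = np.zeros(design.X.shape[1])
        c[design.columns.index(name_or_vec)] = 1.0
        return c
    c = np.asarray(name_or_vec, dtype=float)
    if c.shape != (design.X.shape[1],):
        raise DesignError("contrast length must equal number of design columns")
    return c


# --------------------------------------------------------------------------

def _subject_slices(subject_index):
    """(start, stop) per subject; rows must be contiguous per subject."""
    boundaries = np.flatnonzero(np.diff(subject_index)) + 1
    starts = np.concatenate([[0], boundaries])
    stops = np.concatenate([boundaries, [len(subject_index)]])
    return list(zip(starts, stops))


class _SandwichEngine:
    """Precomputed quantities for repeated sandwich fits on a fixed design."""

    def __init__(self, X, subject_index, adjust="hc2"):
        self.X = X
        self.n, self.p = X.shape
        self.slices = _subject_slices(subject_index)
        self.XtX = X.T @ X
        self.XtXinv = np.linalg.inv(self.XtX)
        self.pinv = self.XtXinv @ X.T          # p x n
        # per-subject residual adjustment (I - H_ii)^(-1/2)
        self.adj = []
        for a, b in self.slices:
            Xi = X[a:b]
            Hii = Xi @ self.XtXinv @ Xi.T
            if adjust == "hc2":
                w, U = np.linalg.eigh(np.eye(b - a) - Hii)
                w = np.maximum(w, 1e-12)
                self.adj.append(U @ np.diag(w**-0.5) @ U.T)
            else:
                self.adj.append(np.eye(b - a))

    def fit(self, Y, contrast):
        """OLS beta and sandwich Wald statistic for each column of Y.

        Y: n_maps x V.  Returns (beta p x V, wald V, denom V).
        """
        beta = self.pinv @ Y
        E = Y - self.X @ beta
        c = contrast
        ct_pinv = c @ self.pinv                # n-vector: row weights
        # u_i = c' (X'X)^-1 X_i' adj_i E_i  per subject, summed squares
        denom = np.zeros(Y.shape[1])
        for (a, b), A in zip(self.slices, self.adj):
            w = ct_pinv[a:b] @ A               # (k_i,)
            u = w @ E[a:b]                     # (V,)
            denom += u * u
        num = (c @ beta) ** 2
        return beta, num, denom

    def sandwich_cov(self, Y):
        """Full p x p sandwich covariance of beta per voxel (V x p x p)."""
        beta = self.pinv @ Y
        E = Y - self.X @ beta
        V = Y.shape[1]
        S = np.zeros((V, self.p, self.p))
        for (a, b), A in zip(self.slices, self.adj):
            G = self.pinv[:, a:b] @ A @ E[a:b]   # p x V
            S += np.einsum("pv,qv->vpq", G, G)
        return beta, S


def fit_marginal(
    stack,
    design: VoxelDesign,
    contrast,
    adjust: str = "hc2",
    log_jacobian: bool = False,
) -> StatMap:
    """Voxel-wise OLS with subject-level sandwich covariance and Wald test.

    The covariance of beta is sum over subjects of
    (X'X)^-1 X_i' e~_i e~_i' X_i (X'X)^-1 with HC2-adjusted residual blocks
    e~_i = (I - H_ii)^(-1/2) e_i; residuals never cross subjects, so each
    group contributes only its own covariance.  The Wald statistic
    (c beta)^2 / c' V c is referred to chi-square with 1 df.
    """
    Y = _stack_matrix(stack, design, log_jacobian)
    c = contrast_vector(design, contrast)
    groups = design.map_rows.get("group")
    if groups is not None:
        per_group = design.map_rows.groupby("group")["participant_id"].nunique()
        if (per_group < 2).any():
            raise DesignError("need >= 2 subjects per group")
    eng = _SandwichEngine(design.X, design.subject_index, adjust=adjust)
    beta, num, denom = eng.fit(Y, c)
    wald = np.zeros_like(num)
    ok = denom > 0
    wald[ok] = num[ok] / denom[ok]
    p = np.ones_like(wald)
    p[ok] = stats.chi2.sf(wald[ok], 1)
    return StatMap(
        beta=beta, wald=wald, p=p, mask=stack.mask, contrast=c, df=1,
        n_zero_variance=int((~ok).sum()),
    )


def _stack_matrix(stack, design: VoxelDesign, log_jacobian=False) -> np.ndarray:
    rows = design.map_rows["index"].to_numpy()
    Y = stack.maps[rows][:, stack.mask]
    return np.log(Y) if log_jacobian else Y.astype(float)


# --------------------------------------------------------------------------

def form_clusters(
    p_map: np.ndarray,
    mask: np.ndarray,
    cluster_forming_p: float = 0.001,
    connectivity: int = 18,
    stat_map: np.ndarray | None = None,
) -> ClusterTable:
    """Connected components of {p < threshold} inside the mask.

    ``p_map`` may be a 3-D volume or an in-mask vector.  Labeling is
    deterministic: clusters are ordered by size (desc), then by the
    lexicographically smallest voxel index.
    """
    if connectivity not in CONNECTIVITY_STRUCTS:
        raise ValueError("connectivity must be one of 6, 18, 26")
    vol = np.ones(mask.shape)
    if p_map.ndim == 1:
        vol[mask] = p_map
    else:
        vol = np.where(mask, p_map, 1.0)
    supra = vol < cluster_forming_p
    labels, n = ndimage.label(supra, structure=CONNECTIVITY_STRUCTS[connectivity])
    svol = None
    if stat_map is not None:
        svol = np.zeros(mask.shape)
        if stat_map.ndim == 1:
            svol[mask] = stat_map
        else:
            svol = np.where(mask, stat_map, 0.0)
    rows = []
    for lab in range(1, n + 1):
        vox = np.argwhere(labels == lab)
        size = len(vox)
        if svol is not None:
            stats_here = svol[tuple(vox.T)]
            peak = vox[int(np.argmax(stats_here))]
            peak_stat = float(stats_here.max())
        else:
            peak = vox[0]
            peak_stat = np.nan
        rows.append((size, *map(int, peak), peak_stat, tuple(map(tuple, vox))))
    rows.sort(key=lambda r: (-r[0], r[-1]))
    table = pd.DataFrame(
        [(i + 1, r[0], r[1], r[2], r[3], r[4]) for i, r in enumerate(rows)],
        columns=["cluster_id", "size", "peak_x", "peak_y", "peak_z", "peak_stat"],
    )
    return ClusterTable(
        table=table, cluster_forming_p=cluster_forming_p, connectivity=connectivity
    )


def wild_bootstrap_fwe(
    stack,
    design: VoxelDesign,
    contrast,
    n_bootstrap: int = 999,
    cluster_forming_p: float = 0.001,
    connectivity: int = 18,
    seed: int = 0,
    adjust: str = "hc2",
    log_jacobian: bool = False,
) -> ClusterTable:
    """Cluster-extent FWE correction by a subject-level wild bootstrap.

    The null model (contrast effect removed by restricted least squares)
    provides fitted values and residuals; each replicate flips the sign of
    every subject's whole residual block with an independent Rademacher
    multiplier, refits the full model, and records the maximum suprathreshold
    cluster size.  fwe_p = (1 + #{max >= observed size}) / (B + 1).
    """
    if n_bootstrap < 1:
        raise ValueError("need at least one bootstrap replicate")
    Y = _stack_matrix(stack, design, log_jacobian)
    c = contrast_vector(design, contrast)
    eng = _SandwichEngine(design.X, design.subject_index, adjust=adjust)

    def wald_p(Ym):
        beta, num, denom = eng.fit(Ym, c)
        wald = np.where(denom > 0, num / np.maximum(denom, 1e-300), 0.0)
        p = np.where(denom > 0, stats.chi2.sf(wald, 1), 1.0)
        return wald, p

    wald_obs, p_obs = wald_p(Y)
    observed = form_clusters(
        p_obs, stack.mask, cluster_forming_p, connectivity, stat_map=wald_obs
    )

    # restricted (null-imposed) fit: Cbeta = 0
    beta = eng.pinv @ Y
    A = eng.XtXinv
    lam = (c @ beta) / float(c @ A @ c)
    beta0 = beta - np.outer(A @ c, lam)
    fitted0 = design.X @ beta0
    R = Y - fitted0

    rng = np.random.default_rng(np.random.SeedSequence([seed, 404]))
    n_subj = len(eng.slices)
    max_sizes = np.zeros(n_bootstrap, dtype=int)
    signs_row = np.empty(Y.shape[0])
    for b in range(n_bootstrap):
        f = rng.integers(0, 2, size=n_subj) * 2 - 1
        for (a, bb), fi in zip(eng.slices, f):
            signs_row[a:bb] = fi
        Yb = fitted0 + signs_row[:, None] * R
        _, p_b = wald_p(Yb)
        labels, nlab = ndimage.label(
            _to_vol(p_b, stack.mask) < cluster_forming_p,
            structure=CONNECTIVITY_STRUCTS[connectivity],
        )
        if nlab:
            max_sizes[b] = np.bincount(labels.ravel())[1:].max()

    tab = observed.table.copy()
    if len(tab):
        sizes = tab["size"].to_numpy()
        counts = (max_sizes[None, :] >= sizes[:, None]).sum(axis=1)
        tab["fwe_p"] = (1 + counts) / (n_bootstrap + 1)
    else:
        tab["fwe_p"] = pd.Series(dtype=float)
    return ClusterTable(
        table=tab,
        cluster_forming_p=cluster_forming_p,
        connectivity=connectivity,
        n_bootstrap=n_bootstrap,
        max_null_sizes=max_sizes,
    )


def _to_vol(vec, mask):
    out = np.ones(mask.shape)
    out[mask] = vec
    return out
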