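"""Random-slope linear mixed models for regional volume trajectories.

The model for participant i with visit times t_ij is

    y_ij = x_ij' beta + b0_i + b1_i * t_ij + e_ij,
    (b0_i, b1_i) ~ N(0, Psi),  e_ij ~ N(0, sigma^2),

fitted by REML with the fixed-effect coefficients and the residual variance
profiled out, leaving a low-dimensional optimisation over the Cholesky
factor of Psi / sigma^2.  Subjects with equal visit counts are processed as
batched small matrices, which keeps a fit in the low milliseconds even for
Monte-Carlo loops of thousands of cohorts.

Wald tests of single fixed-effect terms use Satterthwaite-approximate
denominator degrees of freedom obtained from the curvature of the REML
criterion in the variance parameters.  Binary covariates are effect-coded
(+-1/2) and age is centred, so with interactions present each main-effect
test is marginal (Type-III-style) and group-specific slopes read off as
beta_time +- beta_group:time / 2.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "MixedModelSpec",
    "MixedFitResult",
    "ChangeSummary",
    "correct_for_etiv",
    "fit_random_slope",
    "backward_select",
    "annual_percent_change",
    "wurs_slope_correlation",
]

TERM_ORDER = (
    "group",
    "time",
    "age",
    "sex",
    "diabetes",
    "group:time",
    "group:age",
    "time:age",
    "group:time:age",
)


class DataError(ValueError):
    """Raised for unusable input data (e.g. nonpositive eTIV)."""


@dataclass(frozen=True)
class MixedModelSpec:
    """Fixed- and random-effect structure for one region's model."""

    outcome: str = "volume"
    fixed_terms: tuple = ("group", "time", "group:time")
    random_terms: tuple = ("intercept", "slope")
    alpha: float = 0.05

    def __post_init__(self):
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        for t in self.fixed_terms:
            if t not in TERM_ORDER:
                raise ValueError(f"unknown term {t!r}")
            for sub in _constituents(t):
                if sub not in self.fixed_terms:
                    raise ValueError(
                        f"term {t!r} requires its constituent {sub!r} in the model"
                    )
        if not set(self.random_terms) <= {"intercept", "slope"}:
            raise ValueError("random_terms must be within {intercept, slope}")


def _constituents(term: str) -> list[str]:
    parts = term.split(":")
    out = []
    for r in range(1, len(parts)):
        out += [":".join(c) for c in itertools.combinations(parts, r)]
    return [t for t in out if t in TERM_ORDER]


@dataclass
class MixedFitResult:
    """REML fit: coefficients, variance components, tests, BLUP slopes."""

    spec: MixedModelSpec
    fixed_effects: pd.DataFrame      # term, estimate, se, t, df, p
    variance_components: dict        # intercept_var, slope_var, cov, residual_var
    term_tests: pd.DataFrame         # term, F, df_num, df_den, p
    per_subject_slopes: pd.DataFrame  # participant_id, group, slope
    loglik: float
    converged: bool
    boundary: bool
    n_obs: int
    n_subjects: int
    group_slopes: dict = field(default_factory=dict)  # group -> mean annual rate
    diagnostics: dict = field(default_factory=dict)


@dataclass
class ChangeSummary:
    """Per-group annual rates and percent change with slope-vs-0 tests."""

    region: str
    table: pd.DataFrame  # group, n, mean_rate, sem_rate, mean_pct, sem_pct, t, df, p
    one_tailed: bool


# --------------------------------------------------------------------------
# eTIV correction

def correct_for_etiv(
    volumes: pd.DataFrame,
    reference_etiv: float | None = None,
    method: str = "proportional",
) -> pd.DataFrame:
    """Head-size correction of raw volumes.

    ``proportional`` (atlas-scaling style): corrected = raw * ref / etiv.
    ``residual``: removes the fitted linear dependence of volume on
    (etiv - ref) within the table.
    """
    if (volumes["etiv"] <= 0).any():
        raise DataError("etiv must be positive for all rows")
    ref = (
        float(reference_etiv)
        if reference_etiv is not None
        else float(volumes.groupby("participant_id")["etiv"].first().mean())
    )
    out = volumes.copy()
    if method == "proportional":
        out["volume"] = out["volume"] * ref / out["etiv"]
    elif method == "residual":
        for region, idx in out.groupby("region").groups.items():
            sub = out.loc[idx]
            x = sub["etiv"].to_numpy() - ref
            b = np.polyfit(x, sub["volume"].to_numpy(), 1)[0]
            out.loc[idx, "volume"] = sub["volume"] - b * x
    else:
        raise ValueError(f"unknown correction method {method!r}")
    return out


# --------------------------------------------------------------------------
# design construction

def _build_design(df: pd.DataFrame, terms: tuple, group_col: str, time_col: str):
    """Effect-coded design matrix; returns (X, colnames, codes) where codes
    maps each binary factor to its +1/2 level."""
    levels = sorted(df[group_col].unique())
    if len(levels) != 2:
        raise DataError(f"{group_col} must have exactly two levels, got {levels}")
    codes = {"group_pos": levels[1]}
    base = {}
    base["group"] = np.where(df[group_col] == levels[1], 0.5, -0.5)
    base["time"] = df[time_col].to_numpy(dtype=float)
    if "age" in terms or any("age" in t for t in terms):
        age = df["baseline_age"].to_numpy(dtype=float)
        codes["age_center"] = float(age.mean())
        base["age"] = age - codes["age_center"]
    if "sex" in terms:
        base["sex"] = np.where(df["sex"] == "M", 0.5, -0.5)
    if "diabetes" in terms:
        base["diabetes"] = df["diabetes"].to_numpy(dtype=float) - 0.5
    cols = [np.ones(len(df))]
    names = ["intercept"]
    for t in TERM_ORDER:
        if t not in terms:
            continue
        parts = t.split(":")
        col = np.ones(len(df))
        for p in parts:
            col = col * base[p]
        cols.append(col)
        names.append(t)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DataError("design matrix is rank deficient")
    return X, names, codes


# --------------------------------------------------------------------------
# batched REML core

class _Blocks:
    """Per-subject sufficient statistics for the mixed-model likelihood.

    All likelihood quantities depend on the data only through the
    cross-products X_i'X_i, X_i'Z_i, Z_i'Z_i, X_i'y_i, Z_i'y_i, y_i'y_i, so
    every subject is reduced to a handful of small arrays and each
    likelihood evaluation is a single batched Woodbury step:

        W_i^-1 = I - Z_i D (I_q + Z_i'Z_i D)^-1 Z_i',
        log|W_i| = log|I_q + Z_i'Z_i D|.
    """

    def __init__(self, X, Z, y, subject_ids):
        uid, inv = np.unique(subject_ids, return_inverse=True)
        n, p = X.shape
        q = Z.shape[1]
        ns = len(uid)
        self.XtX = np.zeros((ns, p, p))
        self.XtZ = np.zeros((ns, p, q))
        self.ZtZ = np.zeros((ns, q, q))
        self.Xty = np.zeros((ns, p))
        self.Zty = np.zeros((ns, q))
        self.yty = np.zeros(ns)
        np.add.at(self.XtX, inv, X[:, :, None] * X[:, None, :])
        np.add.at(self.XtZ, inv, X[:, :, None] * Z[:, None, :])
        np.add.at(self.ZtZ, inv, Z[:, :, None] * Z[:, None, :])
        np.add.at(self.Xty, inv, X * y[:, None])
        np.add.at(self.Zty, inv, Z * y[:, None])
        np.add.at(self.yty, inv, y * y)
        self.subject_ids = list(uid)
        self.n_obs = n
        self.p = p
        self.q = q
        self.n_subjects = ns
        self._tril = np.tril_indices(q)

    def subject_order(self):
        return self.subject_ids

    def whitened_crossprods(self, D):
        """Sums of X'W^-1X, X'W^-1y, y'W^-1y and sum of log|W_i| at
        D = Psi / sigma^2 (batched over subjects)."""
        q = self.q
        M = np.eye(q)[None] + self.ZtZ @ D          # (ns, q, q)
        sign, logdet = np.linalg.slogdet(M)
        if (sign <= 0).any():
            raise np.linalg.LinAlgError("indefinite within-subject covariance")
        DMinv = D @ np.linalg.inv(M)                 # (ns, q, q) broadcasting D
        XtWX = self.XtX - np.einsum("npq,nqr,nsr->nps", self.XtZ, DMinv, self.XtZ)
        XtWy = self.Xty - np.einsum("npq,nqr,nr->np", self.XtZ, DMinv, self.Zty)
        ytWy = self.yty - np.einsum("nq,nqr,nr->n", self.Zty, DMinv, self.Zty)
        return XtWX.sum(0), XtWy.sum(0), ytWy.sum(), logdet.sum(), DMinv


def _theta_to_D(theta, q):
    L = np.zeros((q, q))
    L[np.tril_indices(q)] = theta
    return L @ L.T


def _profiled_criterion(theta, blocks: _Blocks):
    """-2 REML log-likelihood (up to constants) with beta and sigma^2
    profiled out; theta parameterises the Cholesky of D = Psi / sigma^2."""
    D = _theta_to_D(theta, blocks.q)
    XtWX, XtWy, ytWy, logdetW, _ = blocks.whitened_crossprods(D)
    sign, logdetXtWX = np.linalg.slogdet(XtWX)
    beta = np.linalg.solve(XtWX, XtWy)
    ssr = max(ytWy - beta @ XtWy, 1e-300)
    crit = (blocks.n_obs - blocks.p) * np.log(ssr) + logdetW + logdetXtWX
    return crit, beta, ssr, XtWX


def _gamma_to_Psi(gamma, q):
    m = q * (q + 1) // 2
    Psi = np.zeros((q, q))
    Psi[np.tril_indices(q)] = gamma[:m]
    Psi = Psi + np.tril(Psi, -1).T
    return Psi, float(gamma[m])


def _reml_loglik_gamma(gamma, blocks: _Blocks):
    """-2 REML log-likelihood (up to the 2*pi constant) at the unprofiled
    variance parameters gamma = (unique Psi elements..., sigma^2)."""
    Psi, s2 = _gamma_to_Psi(gamma, blocks.q)
    XtWX, XtWy, ytWy, logdetW, _ = blocks.whitened_crossprods(Psi / s2)
    XtVX = XtWX / s2
    beta = np.linalg.solve(XtVX, XtWy / s2)
    quad = (ytWy - beta @ XtWy) / s2
    sign, logdetXtVX = np.linalg.slogdet(XtVX)
    return blocks.n_obs * np.log(s2) + logdetW + logdetXtVX + quad


def _cov_beta_gamma(gamma, blocks: _Blocks):
    """(X' V^-1 X)^-1 at variance parameters gamma."""
    Psi, s2 = _gamma_to_Psi(gamma, blocks.q)
    XtWX, *_ = blocks.whitened_crossprods(Psi / s2)
    return np.linalg.inv(XtWX / s2)


def _satterthwaite_many(contrasts: dict, gamma, blocks: _Blocks) -> dict:
    """Satterthwaite denominator df for several single-df contrasts.

    df(c) = 2 g^2 / (grad_g' Cov(gamma) grad_g) with g = c' A(gamma) c,
    A = (X'V^-1 X)^-1, and Cov(gamma) from the inverse curvature of the
    REML criterion.  The curvature is computed once by central differences
    and shared across contrasts.
    """
    m = len(gamma)
    fallback = float(blocks.n_obs - blocks.p)
    steps = np.maximum(np.abs(gamma) * 1e-4, 1e-8 * max(gamma[-1], 1e-12))
    try:
        return _satterthwaite_inner(contrasts, gamma, blocks, steps)
    except np.linalg.LinAlgError:
        return {name: fallback for name in contrasts}


def _satterthwaite_inner(contrasts, gamma, blocks, steps):
    m = len(gamma)
    A_plus, A_minus = [], []
    for j in range(m):
        e = np.zeros(m)
        e[j] = steps[j]
        A_plus.append(_cov_beta_gamma(gamma + e, blocks))
        A_minus.append(_cov_beta_gamma(gamma - e, blocks))
    A0 = _cov_beta_gamma(gamma, blocks)

    f0 = _reml_loglik_gamma(gamma, blocks)
    f_p = np.array([_reml_loglik_gamma(gamma + _unit(m, j, steps), blocks) for j in range(m)])
    f_m = np.array([_reml_loglik_gamma(gamma - _unit(m, j, steps), blocks) for j in range(m)])
    H = np.zeros((m, m))
    for j in range(m):
        H[j, j] = (f_p[j] - 2 * f0 + f_m[j]) / steps[j] ** 2
        for l in range(j):
            fpl = _reml_loglik_gamma(gamma + _unit(m, j, steps) + _unit(m, l, steps), blocks)
            fml = _reml_loglik_gamma(gamma - _unit(m, j, steps) - _unit(m, l, steps), blocks)
            H[j, l] = H[l, j] = (
                fpl - f_p[j] - f_p[l] + 2 * f0 - f_m[j] - f_m[l] + fml
            ) / (2 * steps[j] * steps[l])
    cov_gamma = np.linalg.pinv(0.5 * H)

    out = {}
    fallback = float(blocks.n_obs - blocks.p)
    for name, c in contrasts.items():
        c = np.asarray(c, float)
        g0 = float(c @ A0 @ c)
        grad = np.array(
            [float(c @ (A_plus[j] - A_minus[j]) @ c) / (2 * steps[j]) for j in range(m)]
        )
        var_g = float(grad @ cov_gamma @ grad)
        if not np.isfinite(var_g) or var_g <= 0 or g0 <= 0:
            out[name] = fallback
        else:
            out[name] = float(np.clip(2.0 * g0**2 / var_g, 1.0, 1e7))
    return out


def _unit(m, j, steps):
    e = np.zeros(m)
    e[j] = steps[j]
    return e


def _fit_reml(blocks: _Blocks, satterthwaite=True, contrasts=None):
    """Optimise the profiled REML criterion; return estimates and tests."""
    q = blocks.q
    ntheta = q * (q + 1) // 2

    # perfect-fit degenerate branch: GLS at D=0 explains everything
    crit0, beta0, ssr0, XtWX0 = _profiled_criterion(np.zeros(ntheta), blocks)
    yscale = max(float(blocks.yty.sum() / blocks.n_obs), 1e-300)
    if ssr0 / blocks.n_obs < 1e-16 * yscale:
        covb = np.zeros((blocks.p, blocks.p))
        return dict(
            beta=beta0, cov_beta=covb, Psi=np.zeros((q, q)), sigma2=0.0,
            loglik=np.inf, converged=True, boundary=True,
            gamma=np.concatenate([np.zeros(ntheta), [0.0]]),
            df=np.full(blocks.p, blocks.n_obs - blocks.p),
        )

    # moment-based start: per-subject OLS coefficient dispersion over the
    # OLS residual variance gives the scale of D = Psi / sigma^2
    s2_ols = ssr0 / (blocks.n_obs - blocks.p)
    diag_idx = np.cumsum([0] + list(range(2, q + 1)))[:q]
    D0 = np.full(q, 0.25)
    ztz_scale = max(float(np.trace(blocks.ZtZ.sum(0))) / max(blocks.n_subjects, 1), 1e-300)
    if s2_ols > 0:
        full = np.abs(np.linalg.det(blocks.ZtZ)) > (1e-8 * ztz_scale) ** q
        if full.sum() >= 3:
            u = blocks.Zty[full] - np.einsum("npq,p->nq", blocks.XtZ[full], beta0)
            dev = np.linalg.solve(blocks.ZtZ[full], u[..., None])[..., 0]
            D0 = np.maximum(dev.var(axis=0) / s2_ols, 1e-3)
    theta0 = np.zeros(ntheta)
    theta0[diag_idx] = np.sqrt(D0)

    def crit_fn(th):
        try:
            return _profiled_criterion(th, blocks)[0]
        except np.linalg.LinAlgError:
            return np.inf

    best = optimize.minimize(
        crit_fn, theta0, method="Nelder-Mead",
        options=dict(xatol=1e-6, fatol=1e-8, maxfev=3000),
    )
    if not best.success or best.fun > crit0 + 1e-8:
        alt = optimize.minimize(
            crit_fn, np.zeros(ntheta), method="Nelder-Mead",
            options=dict(xatol=1e-6, fatol=1e-8, maxfev=3000),
        )
        if alt.fun < best.fun:
            best = alt
    theta = best.x
    crit, beta, ssr, XtWX = _profiled_criterion(theta, blocks)
    sigma2 = ssr / (blocks.n_obs - blocks.p)
    L = np.zeros((q, q))
    L[np.tril_indices(q)] = theta
    D = L @ L.T
    Psi = sigma2 * D
    gamma = np.concatenate([Psi[np.tril_indices(q)], [sigma2]])
    cov_beta = sigma2 * np.linalg.inv(XtWX)
    loglik = -0.5 * (
        _reml_loglik_gamma(gamma, blocks)
        + (blocks.n_obs - blocks.p) * np.log(2 * np.pi)
    )
    boundary = bool(np.any(np.abs(np.diag(D)) < 1e-10))
    dfs = {}
    if satterthwaite and contrasts:
        dfs = _satterthwaite_many(contrasts, gamma, blocks)
    return dict(
        beta=beta, cov_beta=cov_beta, Psi=Psi, sigma2=sigma2, loglik=loglik,
        converged=bool(best.success), boundary=boundary, gamma=gamma, df=dfs,
    )


def _blups(blocks: _Blocks, Psi, sigma2, beta):
    """Per-subject random-effect predictors b_i = Psi Z_i' V_i^-1 r_i.

    Via Woodbury, b_i = D (u_i - Z_i'Z_i D M_i^-1 u_i) with
    u_i = Z_i'(y_i - X_i beta) and D = Psi / sigma^2.
    """
    if sigma2 <= 0:
        return {sid: np.zeros(blocks.q) for sid in blocks.subject_ids}
    D = Psi / sigma2
    q = blocks.q
    M = np.eye(q)[None] + blocks.ZtZ @ D
    DMinv = D @ np.linalg.inv(M)
    u = blocks.Zty - np.einsum("npq,p->nq", blocks.XtZ, beta)
    zwr = u - np.einsum("nqr,nrs,ns->nq", blocks.ZtZ, DMinv, u)
    b = np.einsum("qr,nr->nq", D, zwr)
    return dict(zip(blocks.subject_ids, b))


# --------------------------------------------------------------------------
# public fitting API

def fit_random_slope(
    data: pd.DataFrame,
    spec: MixedModelSpec | None = None,
    *,
    subject_col: str = "participant_id",
    group_col: str = "group",
    time_col: str = "time_from_baseline",
    volume_col: str = "volume",
    satterthwaite: bool = True,
) -> MixedFitResult:
    """Fit the random-slope mixed model by REML.

    ``data`` is a long table with one row per visit.  Participants with a
    single visit are retained (they inform the intercept distribution).
    """
    spec = spec or MixedModelSpec()
    df = data.reset_index(drop=True)
    groups = df.groupby(group_col)[subject_col].nunique()
    multi = df.groupby(subject_col).size()
    n_multi = df[df[subject_col].isin(multi[multi >= 2].index)].groupby(group_col)[
        subject_col
    ].nunique()
    if len(groups) == 2 and (n_multi.reindex(groups.index).fillna(0) < 2).any():
        raise DataError("need >= 2 participants with >= 2 visits in each group")

    X, names, codes = _build_design(df, spec.fixed_terms, group_col, time_col)
    zcols = []
    if "intercept" in spec.random_terms:
        zcols.append(np.ones(len(df)))
    if "slope" in spec.random_terms:
        zcols.append(df[time_col].to_numpy(dtype=float))
    Z = np.column_stack(zcols)
    y = df[volume_col].to_numpy(dtype=float)
    blocks = _Blocks(X, Z, y, df[subject_col].to_numpy())

    contrasts = {}
    for j, nm in enumerate(names):
        c = np.zeros(len(names))
        c[j] = 1.0
        contrasts[nm] = c
    fit = _fit_reml(blocks, satterthwaite=satterthwaite, contrasts=contrasts)

    beta, covb = fit["beta"], fit["cov_beta"]
    se = np.sqrt(np.maximum(np.diag(covb), 0.0))
    rows = []
    for j, nm in enumerate(names):
        if isinstance(fit["df"], dict):
            dfj = fit["df"].get(nm, blocks.n_obs - blocks.p)
        else:
            dfj = float(np.asarray(fit["df"]).flat[0])
        tval = beta[j] / se[j] if se[j] > 0 else np.inf * np.sign(beta[j] or 1)
        pval = 2 * stats.t.sf(abs(tval), dfj) if np.isfinite(tval) else 0.0
        rows.append((nm, beta[j], se[j], tval, dfj, pval))
    fixed = pd.DataFrame(rows, columns=["term", "estimate", "se", "t", "df", "p"])

    tests = fixed[fixed.term != "intercept"].copy()
    tests["F"] = tests["t"] ** 2
    tests["df_num"] = 1
    term_tests = tests[["term", "F", "df_num", "df", "p"]].rename(
        columns={"df": "df_den"}
    )

    Psi = fit["Psi"]
    if Z.shape[1] == 2:
        vc = dict(
            intercept_var=float(Psi[0, 0]),
            slope_var=float(Psi[1, 1]),
            intercept_slope_cov=float(Psi[0, 1]),
            residual_var=float(fit["sigma2"]),
        )
    elif "slope" in spec.random_terms:
        vc = dict(intercept_var=0.0, slope_var=float(Psi[0, 0]),
                  intercept_slope_cov=0.0, residual_var=float(fit["sigma2"]))
    else:
        vc = dict(intercept_var=float(Psi[0, 0]), slope_var=0.0,
                  intercept_slope_cov=0.0, residual_var=float(fit["sigma2"]))

    # group mean annual rates at the age centre
    bmap = dict(zip(names, beta))
    levels = sorted(df[group_col].unique())
    gslopes = {}
    for lev, code in ((levels[1], 0.5), (levels[0], -0.5)):
        s = bmap.get("time", 0.0) + code * bmap.get("group:time", 0.0)
        gslopes[lev] = float(s)

    blup = _blups(blocks, Psi, fit["sigma2"], beta)
    slope_idx = 1 if Z.shape[1] == 2 else (0 if "slope" in spec.random_terms else None)
    grp_of = df.drop_duplicates(subject_col).set_index(subject_col)[group_col]
    srows = []
    for sid in blocks.subject_order():
        dev = blup[sid][slope_idx] if slope_idx is not None else 0.0
        srows.append((sid, grp_of[sid], gslopes[grp_of[sid]] + dev))
    slopes = pd.DataFrame(srows, columns=["participant_id", "group", "slope"])

    return MixedFitResult(
        spec=spec,
        fixed_effects=fixed,
        variance_components=vc,
        term_tests=term_tests,
        per_subject_slopes=slopes,
        loglik=float(fit["loglik"]),
        converged=fit["converged"],
        boundary=fit["boundary"],
        n_obs=blocks.n_obs,
        n_subjects=blocks.n_subjects,
        group_slopes=gslopes,
        diagnostics=dict(codes=codes, design_columns=names),
    )


# --------------------------------------------------------------------------
# backward selection

FULL_MODEL_TERMS = (
    "group", "time", "age", "sex", "diabetes",
    "group:time", "group:age", "time:age", "group:time:age",
)


def backward_select(
    data: pd.DataFrame,
    full_spec: MixedModelSpec | None = None,
    **fit_kwargs,
) -> tuple[MixedModelSpec, MixedFitResult, pd.DataFrame]:
    """Backward elimination respecting term hierarchy.

    Starting from the full model, the most non-significant term with
    p > alpha is removed one step at a time, working down from the
    three-way interaction through two-way interactions to main effects; a
    term is never removed while a retained higher-order interaction
    contains it.  Returns (final spec, final fit, trace).
    """
    full_spec = full_spec or MixedModelSpec(fixed_terms=FULL_MODEL_TERMS)
    terms = list(full_spec.fixed_terms)
    alpha = full_spec.alpha
    trace = []
    fit = fit_random_slope(data, full_spec, **fit_kwargs)
    for tier in (3, 2, 1):
        while True:
            eligible = [
                t for t in terms
                if len(t.split(":")) == tier
                and not any(t in _constituents(u) for u in terms)
            ]
            if not eligible:
                break
            pvals = fit.term_tests.set_index("term")["p"]
            cand = max(eligible, key=lambda t: pvals.get(t, 0.0))
            pmax = float(pvals.get(cand, 0.0))
            if pmax <= alpha:
                break
            terms.remove(cand)
            trace.append((cand, pmax, tuple(terms)))
            spec = MixedModelSpec(
                outcome=full_spec.outcome,
                fixed_terms=tuple(t for t in TERM_ORDER if t in terms),
                random_terms=full_spec.random_terms,
                alpha=alpha,
            )
            fit = fit_random_slope(data, spec, **fit_kwargs)
    trace_df = pd.DataFrame(trace, columns=["removed", "p", "remaining"])
    return fit.spec, fit, trace_df


# --------------------------------------------------------------------------
# annual percent change and severity correlation

def annual_percent_change(
    fit: MixedFitResult,
    volumes: pd.DataFrame,
    region: str | None = None,
    one_tailed: bool = True,
) -> ChangeSummary:
    """Per-group mean annual rate and percent change with slope-vs-zero tests.

    Each participant's model slope is scaled by the mean of that
    participant's own (corrected) volumes: pct_i = 100 * slope_i / mean_i.
    The one-tailed test directs the alternative at the sign of the group
    mean, matching a display of directional change; set ``one_tailed=False``
    for two-sided tests.
    """
    vols = volumes if region is None else volumes[volumes.region == region]
    mean_vol = vols.groupby("participant_id")["volume"].mean()
    if (mean_vol == 0).any():
        raise DataError("zero mean volume for some participant")
    sl = fit.per_subject_slopes.set_index("participant_id")
    common = [p for p in sl.index if p in mean_vol.index]
    sl = sl.loc[common]
    pct = 100.0 * sl["slope"] / mean_vol.loc[common]
    rows = []
    for g, idx in sl.groupby("group").groups.items():
        s = sl.loc[idx, "slope"]
        pc = pct.loc[idx]
        n = len(pc)
        mean_pc = float(pc.mean())
        if n > 1 and pc.std(ddof=1) > 0:
            tval = mean_pc / (pc.std(ddof=1) / np.sqrt(n))
        else:
            tval = 0.0 if mean_pc == 0 else np.inf * np.sign(mean_pc)
        dfree = max(n - 1, 1)
        if one_tailed:
            pv = stats.t.sf(abs(tval), dfree)
        else:
            pv = 2 * stats.t.sf(abs(tval), dfree)
        rows.append(
            (g, n, float(s.mean()), float(s.sem()) if n > 1 else np.nan,
             mean_pc, float(pc.sem()) if n > 1 else np.nan,
             float(tval), dfree, float(pv))
        )
    table = pd.DataFrame(
        rows,
        columns=["group", "n", "mean_rate", "sem_rate", "mean_pct", "sem_pct",
                 "t", "df", "p"],
    )
    return ChangeSummary(region=region or fit.spec.outcome, table=table,
                         one_tailed=one_tailed)


@dataclass
class CorrelationResult:
    rho: float
    p: float
    n: int
    criterion: float
    significant: bool
    valid: bool


def wurs_slope_correlation(
    change: pd.Series,
    wurs: pd.Series,
    n_tests: int = 5,
    alpha: float = 0.05,
) -> CorrelationResult:
    """Spearman correlation between per-participant change and WURS score
    with a Bonferroni criterion of alpha / n_tests.

    Ranks use midrank tie handling.  Constant input yields an undefined
    correlation flagged via ``valid=False``.
    """
    pair = pd.concat([change.rename("x"), wurs.rename("y")], axis=1).dropna()
    n = len(pair)
    if n < 4:
        raise DataError("need at least 4 paired observations")
    criterion = alpha / n_tests
    if pair["x"].nunique() == 1 or pair["y"].nunique() == 1:
        return CorrelationResult(np.nan, np.nan, n, criterion, False, False)
    rho, p = stats.spearmanr(pair["x"], pair["y"])
    return CorrelationResult(float(rho), float(p), n, criterion,
                             bool(p < criterion), True)
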