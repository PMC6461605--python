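"""Voxel-wise sandwich estimator, clustering and wild-bootstrap FWE."""
import numpy as np
import pandas as pd
import pytest

import longimorph as lm
from longimorph.cohort import CohortDesign
from longimorph.tbm import TBMEffect
from longimorph.voxelwise import (
    DesignError,
    _SandwichEngine,
    build_design,
    contrast_vector,
    fit_marginal,
    form_clusters,
    wild_bootstrap_fwe,
)


def _toy_stack(seed=0, shape=(3, 3, 3), n_per_group=3, n_visits=2, noise=0.05):
    design = CohortDesign(
        n_wolfram=n_per_group, n_control=n_per_group,
        visit_count_probs={
            "wolfram": [0] * (n_visits - 1) + [1.0] + [0] * (7 - n_visits),
            "control": [0] * (n_visits - 1) + [1.0] + [0] * (3 - n_visits),
        },
        seed=seed,
    )
    coh = lm.generate_cohort(design)
    mask = np.ones(shape, dtype=bool)
    stack = lm.simulate_tbm_stack(
        coh, shape=shape, noise_sd=noise, noise_fwhm=0.0, seed=seed, mask=mask,
    )
    return coh, stack


def _dense_sandwich_reference(X, Y, subject_index, adjust=True):
    """Brute-force marginal model: per-voxel OLS beta and subject-level
    sandwich covariance via explicit dense matrices."""
    n, p = X.shape
    XtXinv = np.linalg.inv(X.T @ X)
    betas, covs = [], []
    for v in range(Y.shape[1]):
        y = Y[:, v]
        b = XtXinv @ X.T @ y
        e = y - X @ b
        meat = np.zeros((p, p))
        for sid in np.unique(subject_index):
            rows = np.where(subject_index == sid)[0]
            Xi, ei = X[rows], e[rows]
            if adjust:
                Hii = Xi @ XtXinv @ Xi.T
                w, U = np.linalg.eigh(np.eye(len(rows)) - Hii)
                ei = U @ np.diag(np.maximum(w, 1e-12) ** -0.5) @ U.T @ ei
            meat += Xi.T @ np.outer(ei, ei) @ Xi
        betas.append(b)
        covs.append(XtXinv @ meat @ XtXinv)
    return np.array(betas), np.array(covs)


# --------------------------------------------------------------------------
# design

def test_build_design_shapes_and_interaction_column():
    coh, stack = _toy_stack(seed=1, n_per_group=4, n_visits=2)
    d = build_design(
        stack, covariates=("group", "time"), interactions=("group:time",),
        participants=coh.participants, variant="to_midpoint",
    )
    assert d.X.shape == (16, 4)
    assert np.linalg.matrix_rank(d.X) == 4
    ig, it, igt = (d.columns.index(c) for c in ("group", "time", "group:time"))
    np.testing.assert_allclose(d.X[:, igt], d.X[:, ig] * d.X[:, it])


def test_single_visit_participants_excluded_from_midpoint_design():
    design = CohortDesign(
        n_wolfram=4, n_control=4,
        visit_count_probs={"wolfram": [0.5, 0, 0.5, 0, 0, 0, 0],
                           "control": [0, 0, 1.0]},
        seed=3,
    )
    coh = lm.generate_cohort(design)
    stack = lm.simulate_tbm_stack(coh, shape=(4, 4, 4), noise_sd=0.01, seed=0)
    d = build_design(stack, covariates=("group", "time"), interactions=("group:time",),
                    participants=coh.participants, variant="to_midpoint")
    counts = coh.visits.groupby("participant_id").size()
    singles = set(counts[counts == 1].index)
    assert singles  # the design above produces some single-visit participants
    assert not singles & set(d.map_rows.participant_id)
    # but they are retained in template space
    d2 = build_design(stack, covariates=("group",), interactions=(),
                     participants=coh.participants, variant="to_group_template")
    assert singles <= set(d2.map_rows.participant_id)


def test_rank_deficient_design_reports_collinearity():
    # no diabetic controls: the diabetes column duplicates the group column
    design = CohortDesign(
        n_wolfram=3, n_control=3, diabetic_control_fraction=0.0,
        visit_count_probs={"wolfram": [0, 1.0, 0, 0, 0, 0, 0], "control": [0, 1.0, 0]},
        seed=1,
    )
    coh = lm.generate_cohort(design)
    stack = lm.simulate_tbm_stack(coh, shape=(3, 3, 3), noise_sd=0.05,
                                  mask=np.ones((3, 3, 3), bool), seed=1)
    with pytest.raises(DesignError):
        build_design(stack, covariates=("group", "diabetes"), interactions=(),
                     participants=coh.participants, variant="to_midpoint")


def test_bad_contrast_rejected():
    coh, stack = _toy_stack(seed=1)
    d = build_design(stack, covariates=("group", "time"), interactions=(),
                    participants=coh.participants)
    with pytest.raises(DesignError):
        contrast_vector(d, "group:time")
    with pytest.raises(DesignError):
        contrast_vector(d, [1.0, 0.0])


# --------------------------------------------------------------------------
# sandwich oracle equivalence

def test_sandwich_matches_dense_reference():
    """<=8 maps, 27 voxels: engine vs explicit dense computation to 1e-8."""
    coh, stack = _toy_stack(seed=5, shape=(3, 3, 3), n_per_group=2, n_visits=2)
    d = build_design(stack, covariates=("group", "time"), interactions=("group:time",),
                    participants=coh.participants, variant="to_midpoint")
    Y = stack.maps[d.map_rows["index"].to_numpy()][:, stack.mask]
    assert Y.shape[0] == 8 and Y.shape[1] == 27
    eng = _SandwichEngine(d.X, d.subject_index)
    beta, S = eng.sandwich_cov(Y)
    ref_beta, ref_cov = _dense_sandwich_reference(Y=Y, X=d.X, subject_index=d.subject_index)
    np.testing.assert_allclose(beta.T, ref_beta, atol=1e-8)
    np.testing.assert_allclose(S, ref_cov, atol=1e-8)
    # Wald statistic path agrees with the dense formula
    c = contrast_vector(d, "group:time")
    _, num, denom = eng.fit(Y, c)
    wald_ref = np.array(
        [(c @ b) ** 2 / (c @ V @ c) for b, V in zip(ref_beta, ref_cov)]
    )
    np.testing.assert_allclose(num / denom, wald_ref, atol=1e-8)


def test_sandwich_psd_at_every_voxel():
    coh, stack = _toy_stack(seed=6, shape=(3, 3, 3), n_per_group=3, n_visits=3)
    d = build_design(stack, covariates=("group", "time"), interactions=("group:time",),
                    participants=coh.participants, variant="to_midpoint")
    Y = stack.maps[d.map_rows["index"].to_numpy()][:, stack.mask]
    _, S = _SandwichEngine(d.X, d.subject_index).sandwich_cov(Y)
    eig = np.linalg.eigvalsh(S)
    assert (eig > -1e-12).all()
    assert np.allclose(S, np.swapaxes(S, 1, 2))


def test_one_map_per_subject_equals_hc2_robust_ols():
    """Cross-sectional case: subject blocks of size 1 reduce the sandwich to
    the HC2 heteroscedasticity-robust OLS covariance."""
    rng = np.random.default_rng(8)
    n, p, V = 6, 2, 5
    X = np.column_stack([np.ones(n), rng.standard_normal(n)])
    Y = rng.standard_normal((n, V))
    eng = _SandwichEngine(X, np.arange(n))
    beta, S = eng.sandwich_cov(Y)
    XtXinv = np.linalg.inv(X.T @ X)
    H = X @ XtXinv @ X.T
    for v in range(V):
        e = Y[:, v] - X @ beta[:, v]
        meat = (X * (e**2 / (1 - np.diag(H)))[:, None]).T @ X
        hc2 = XtXinv @ meat @ XtXinv
        np.testing.assert_allclose(S[v], hc2, atol=1e-10)


def test_zero_effect_zero_noise_below_threshold():
    coh, stack = _toy_stack(seed=7, noise=0.0)
    d = build_design(stack, covariates=("group", "time"), interactions=("group:time",),
                    participants=coh.participants, variant="to_midpoint")
    sm = fit_marginal(stack, d, "group:time")
    assert sm.n_zero_variance == sm.p.size  # perfectly constant maps
    assert (sm.p >= 0.001).all()


def test_injected_cluster_detected():
    """In-cluster slope far above noise: the suprathreshold set covers the
    injected cluster in >= 95% of replicates."""
    shape = (8, 8, 8)
    mask = np.ones(shape, dtype=bool)
    cl = np.zeros(shape, bool)
    cl[2:5, 2:5, 2:5] = True
    hits = 0
    n_rep = 20
    for s in range(n_rep):
        design = CohortDesign(
            n_wolfram=8, n_control=8,
            visit_count_probs={"wolfram": [0, 0, 1.0, 0, 0, 0, 0],
                               "control": [0, 0, 1.0]},
            seed=s,
        )
        coh = lm.generate_cohort(design, seed=900 + s)
        stack = lm.simulate_tbm_stack(
            coh, shape=shape, mask=mask,
            effect=TBMEffect(cluster=cl, slope={"wolfram": -0.2, "control": 0.0}),
            noise_sd=0.01, noise_fwhm=0.0, seed=s,
        )
        d = build_design(stack, covariates=("group", "time"),
                        interactions=("group:time",),
                        participants=coh.participants, variant="to_midpoint")
        sm = fit_marginal(stack, d, "group:time")
        supra = sm.volume(sm.p, fill=1.0) < 0.001
        hits += bool((supra & cl).sum() == cl.sum())
    assert hits >= int(0.95 * n_rep)


def test_log_jacobian_recovers_injected_slope():
    """Per-voxel OLS of log J on time recovers the generating slope."""
    shape = (6, 6, 6)
    mask = np.ones(shape, dtype=bool)
    cl = np.zeros(shape, bool)
    cl[2:4, 2:4, 2:4] = True
    slopes = []
    for s in range(20):
        design = CohortDesign(
            n_wolfram=6, n_control=1,
            visit_count_probs={"wolfram": [0, 0, 0, 1.0, 0, 0, 0],
                               "control": [1.0, 0, 0]},
            seed=s,
        )
        coh = lm.generate_cohort(design, seed=700 + s)
        stack = lm.simulate_tbm_stack(
            coh, shape=shape, mask=mask,
            effect=TBMEffect(cluster=cl, slope={"wolfram": -0.08, "control": 0.0}),
            noise_sd=0.02, noise_fwhm=0.0, seed=s, variants=("to_midpoint",),
        )
        meta = stack.meta.merge(coh.participants, on="participant_id")
        sel = meta[meta.group == "wolfram"]
        Y = np.log(stack.maps[sel["index"].to_numpy()][:, cl])
        t = sel.time.to_numpy()
        b = np.polyfit(t, Y, 1)[0]
        slopes.append(b.mean())
    slopes = np.asarray(slopes)
    assert abs(slopes.mean() - (-0.08)) < 3 * slopes.std(ddof=1) / np.sqrt(len(slopes)) + 1e-3


# --------------------------------------------------------------------------
# clustering

def test_form_clusters_empty():
    mask = np.ones((4, 4, 4), bool)
    ct = form_clusters(np.ones(mask.sum()), mask, 0.001)
    assert len(ct) == 0


def test_corner_voxels_connectivity():
    mask = np.ones((4, 4, 4), bool)
    p = np.ones((4, 4, 4))
    p[0, 0, 0] = 0.0
    p[1, 1, 1] = 0.0  # shares only a corner
    c26 = form_clusters(p, mask, 0.001, connectivity=26)
    c6 = form_clusters(p, mask, 0.001, connectivity=6)
    assert len(c26) == 1 and c26.table.loc[0, "size"] == 2
    assert len(c6) == 2


def test_l_shape_single_cluster_default_connectivity():
    mask = np.ones((4, 4, 4), bool)
    p = np.ones((4, 4, 4))
    p[1, 1, 1] = p[1, 2, 1] = p[2, 2, 1] = 0.0
    ct = form_clusters(p, mask, 0.001)
    assert len(ct) == 1
    assert ct.table.loc[0, "size"] == 3


# --------------------------------------------------------------------------
# wild bootstrap

def test_identity_multipliers_reproduce_null_reconstruction():
    """With all Rademacher signs +1 the replicate equals the null-model
    reconstruction, whose refit equals a direct fit of that dataset."""
    coh, stack = _toy_stack(seed=9, shape=(3, 3, 3), n_per_group=3, n_visits=2)
    d = build_design(stack, covariates=("group", "time"), interactions=("group:time",),
                    participants=coh.participants, variant="to_midpoint")
    Y = stack.maps[d.map_rows["index"].to_numpy()][:, stack.mask]
    eng = _SandwichEngine(d.X, d.subject_index)
    c = contrast_vector(d, "group:time")
    beta = eng.pinv @ Y
    lam = (c @ beta) / float(c @ eng.XtXinv @ c)
    beta0 = beta - np.outer(eng.XtXinv @ c, lam)
    Y0 = d.X @ beta0 + (Y - d.X @ beta0)  # signs all +1
    np.testing.assert_allclose(Y0, Y, atol=1e-12)
    # restricted fit satisfies the null constraint
    assert np.abs(c @ beta0).max() < 1e-10


def test_fwe_p_monotone_in_cluster_size_and_reproducible():
    shape = (8, 8, 8)
    cl = np.zeros(shape, bool)
    cl[2:5, 2:5, 2:5] = True
    mask = np.ones(shape, bool)
    design = CohortDesign(
        n_wolfram=8, n_control=8,
        visit_count_probs={"wolfram": [0, 0, 1.0, 0, 0, 0, 0], "control": [0, 0, 1.0]},
        seed=12,
    )
    coh = lm.generate_cohort(design)
    stack = lm.simulate_tbm_stack(
        coh, shape=shape, mask=mask,
        effect=TBMEffect(cluster=cl, slope={"wolfram": -0.08, "control": 0.0}),
        noise_sd=0.03, seed=2,
    )
    d = build_design(stack, covariates=("group", "time"), interactions=("group:time",),
                    participants=coh.participants, variant="to_midpoint")
    ct1 = wild_bootstrap_fwe(stack, d, "group:time", n_bootstrap=49, seed=21)
    ct2 = wild_bootstrap_fwe(stack, d, "group:time", n_bootstrap=49, seed=21)
    np.testing.assert_array_equal(ct1.max_null_sizes, ct2.max_null_sizes)
    pd.testing.assert_frame_equal(ct1.table, ct2.table)
    t = ct1.table.sort_values("size", ascending=False)
    assert t.fwe_p.is_monotonic_increasing
    assert t.fwe_p.between(1 / 50, 1).all()


def test_fwe_floor_when_observed_exceeds_all_null():
    """An overwhelming effect yields the minimum attainable fwe_p 1/(B+1)."""
    shape = (8, 8, 8)
    cl = np.zeros(shape, bool)
    cl[2:6, 2:6, 2:6] = True
    design = CohortDesign(
        n_wolfram=8, n_control=8,
        visit_count_probs={"wolfram": [0, 0, 1.0, 0, 0, 0, 0], "control": [0, 0, 1.0]},
        seed=13,
    )
    coh = lm.generate_cohort(design)
    stack = lm.simulate_tbm_stack(
        coh, shape=shape, mask=np.ones(shape, bool),
        effect=TBMEffect(cluster=cl, slope={"wolfram": -0.5, "control": 0.0}),
        noise_sd=0.005, seed=3,
    )
    d = build_design(stack, covariates=("group", "time"), interactions=("group:time",),
                    participants=coh.participants, variant="to_midpoint")
    ct = wild_bootstrap_fwe(stack, d, "group:time", n_bootstrap=99, seed=5)
    assert ct.table.fwe_p.min() == pytest.approx(1 / 100)
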