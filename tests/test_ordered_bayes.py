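"""Order-restricted Bayesian ANCOVA and the encompassing-prior identity."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.linalg import null_space
from scipy.stats import invgamma, multivariate_normal

from aslscov import (
    bf_order_restricted,
    compare_restrictions,
    merge_equality_blocks,
    parse_restriction,
    prior_constraint_probability,
    sample_posterior,
    simulate_metric_records,
)
from aslscov.ordered_bayes import (
    STANDARD_RESTRICTIONS,
    bf_full_vs_null,
    bf_groups_vs_null,
    build_design,
)

M1 = STANDARD_RESTRICTIONS["M1"]
M2 = STANDARD_RESTRICTIONS["M2"]
M3 = STANDARD_RESTRICTIONS["M3"]
M4 = STANDARD_RESTRICTIONS["M4"]


def _cohort_frame(counts, values=None, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for g, n in counts.items():
        for i in range(n):
            rows.append(
                {
                    "group": g,
                    "value": (values[g] if values else 0.0) + rng.normal(),
                    "age": rng.normal(70, 7),
                    "sex": "f" if i % 2 else "m",
                    "site": ("site_a", "site_b", "site_c")[i % 3],
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# restrictions and block merging
# ---------------------------------------------------------------------------

def test_parse_and_format_roundtrip():
    r = parse_restriction("[control=scd]<mci<ad")
    assert r.blocks == (("control", "scd"), ("mci",), ("ad",))
    assert str(r) == "[control=scd] < mci < ad"


def test_merge_m1_leaves_factor_unchanged():
    df = _cohort_frame({"control": 5, "scd": 5, "mci": 5, "ad": 5})
    merged = merge_equality_blocks(df, M1)
    assert sorted(merged.group.unique()) == sorted(df.group.unique())
    assert len(merged) == len(df)


def test_merge_m4_collapses_to_two_levels_with_cohort_sizes():
    df = _cohort_frame({"control": 20, "scd": 44, "mci": 45, "ad": 13})
    merged = merge_equality_blocks(df, M4)
    sizes = merged.group.value_counts()
    assert sizes["control=scd"] == 64
    assert sizes["mci=ad"] == 58


def test_merge_missing_level_raises_and_single_block_warns():
    df = _cohort_frame({"control": 5, "scd": 5, "mci": 5, "ad": 5})
    with pytest.raises(ValueError):
        merge_equality_blocks(df, parse_restriction("control<scd<mci"))
    with pytest.warns(UserWarning):
        merge_equality_blocks(df, parse_restriction("[control=scd=mci=ad]"))


# ---------------------------------------------------------------------------
# prior constraint probability
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "restriction,expected",
    [(M1, 1 / 24), (M2, 1 / 6), (M3, 1 / 6), (M4, 1 / 2)],
)
def test_prior_probability_analytic(restriction, expected):
    assert prior_constraint_probability(restriction) == pytest.approx(expected)


def test_prior_probability_monte_carlo_agrees():
    analytic, mc, se = prior_constraint_probability(M4, n_mc=1_000_000, seed=1)
    assert abs(mc - analytic) < 3 * se


# ---------------------------------------------------------------------------
# unrestricted Bayes factor: brute-force integration oracle
# ---------------------------------------------------------------------------

TINY_Y = np.array([1.2, 0.8, 1.5, 0.9, 1.1, 0.7, 2.1, 2.4, 1.9, 2.6, 2.2, 2.0])
TINY_G = ["a"] * 6 + ["b"] * 6


def _oracle_bf_2d(y, W, Z, r):
    """BF by explicit 2-D grid integration over (effect scale, error variance).

    Works in the covariate-projected space: with K an orthonormal null-space
    basis of W', u = K'y has a proper density under both models, and the
    common-parameter flat priors cancel.  Densities evaluated point-wise
    with scipy.stats; trapezoid-free Riemann sums on wide log grids.
    """
    K = null_space(W.T)
    u = K.T @ y
    m = len(u)
    lgs = np.linspace(-18, 12, 400)
    ls2s = np.linspace(-12, 8, 400)
    log_num = np.empty((len(lgs), len(ls2s)))
    for i, lg in enumerate(lgs):
        g = np.exp(lg)
        C = K.T @ (np.eye(len(y)) + g * Z @ Z.T) @ K
        lp_g = invgamma.logpdf(g, 0.5, scale=r**2 / 2) + lg
        for j, ls2 in enumerate(ls2s):
            s2 = np.exp(ls2)
            log_num[i, j] = (
                multivariate_normal.logpdf(u, mean=np.zeros(m), cov=s2 * C) + lp_g
            )
    mx = log_num.max()
    num = np.exp(log_num - mx).sum() * (lgs[1] - lgs[0]) * (ls2s[1] - ls2s[0])
    log_den = np.array(
        [
            multivariate_normal.logpdf(u, mean=np.zeros(m), cov=np.exp(s) * np.eye(m))
            for s in ls2s
        ]
    )
    md = log_den.max()
    den = np.exp(log_den - md).sum() * (ls2s[1] - ls2s[0])
    return num / den * np.exp(mx - md)


def test_bf_full_matches_brute_force_integration():
    df = pd.DataFrame({"value": TINY_Y, "group": TINY_G})
    y, W, Z, _ = build_design(df, covariates=())
    impl = bf_full_vs_null(y, W, Z, prior_scale=0.5)
    oracle = _oracle_bf_2d(y, W, Z, r=0.5)
    assert impl == pytest.approx(oracle, rel=1e-3)  # 3 significant figures


def test_duplicated_covariate_rejected():
    df = _cohort_frame({"control": 10, "ad": 10})
    df["age2"] = df["age"]
    with pytest.raises(ValueError):
        bf_groups_vs_null(df, covariates=("age", "age2"))


def test_null_data_usually_favours_null():
    wins = 0
    reps = 20
    for rep in range(reps):
        df = simulate_metric_records(
            {"control": 100, "scd": 100, "mci": 100, "ad": 100},
            {g: 50.0 for g in ("control", "scd", "mci", "ad")},
            sd=6.0,
            seed=100 + rep,
        )
        if bf_groups_vs_null(df) < 1.0:
            wins += 1
    assert wins >= int(0.85 * reps)


# ---------------------------------------------------------------------------
# Gibbs sampler
# ---------------------------------------------------------------------------

def _design_no_covariates(seed=3, shift=1.0, n=40):
    rng = np.random.default_rng(seed)
    y = np.r_[rng.normal(0, 1, n), rng.normal(shift, 1, n)]
    df = pd.DataFrame({"value": y, "group": ["a"] * n + ["b"] * n})
    return build_design(df, covariates=())


def test_gibbs_matches_conjugate_posterior_mean():
    """With fixed g and error variance the posterior is exactly Gaussian."""
    y, W, Z, _ = _design_no_covariates()
    g_fix, s2_fix = 0.25, 1.0
    post = sample_posterior(
        y, W, Z, n_samples=4000, seed=8, n_chains=2, g_fixed=g_fix,
        sigma2_fixed=s2_fix,
    )
    X = np.column_stack([W, Z])
    Q = X.T @ X + np.diag([0.0, 1 / g_fix, 1 / g_fix])
    mean = np.linalg.solve(Q, X.T @ y)[1:]
    for j in range(2):
        draws = post["theta"][:, :, j].ravel()
        se = draws.std(ddof=1) / math.sqrt(max(post["ess"][j], 1.0))
        assert abs(draws.mean() - mean[j]) < 3 * se


def test_gibbs_same_seed_identical_draws():
    y, W, Z, _ = _design_no_covariates()
    p1 = sample_posterior(y, W, Z, n_samples=200, seed=4, n_chains=2)
    p2 = sample_posterior(y, W, Z, n_samples=200, seed=4, n_chains=2)
    assert np.array_equal(p1["theta"], p2["theta"])


def test_gibbs_converges_on_well_posed_data():
    df = simulate_metric_records(
        {"control": 60, "scd": 60, "mci": 60, "ad": 60},
        {"control": 50.0, "scd": 51.0, "mci": 53.0, "ad": 55.0},
        sd=5.0,
        seed=6,
    )
    y, W, Z, _ = build_design(df)
    post = sample_posterior(y, W, Z, n_samples=4000, seed=2, n_chains=4)
    assert post["rhat"].max() <= 1.01
    assert post["ess"].min() > 400


# ---------------------------------------------------------------------------
# encompassing-prior Bayes factors
# ---------------------------------------------------------------------------

def test_bf_identity_holds_exactly():
    df = simulate_metric_records(
        {"control": 40, "scd": 40, "mci": 40, "ad": 40},
        {"control": 50.0, "scd": 50.0, "mci": 53.0, "ad": 56.0},
        sd=6.0,
        seed=21,
    )
    for r in (M1, M2, M3, M4):
        res = bf_order_restricted(df, r, n_samples=500, n_chains=2, seed=3)
        assert res.bf_vs_null == pytest.approx(
            res.bf_full_vs_null
            * res.posterior_constraint_prob
            / res.prior_constraint_prob,
            rel=1e-12,
        )


def test_posterior_ordering_probability_matches_counting_oracle():
    """Gibbs ordering proportion vs iid draws from the exact fixed-(g, s2)
    Gaussian posterior."""
    y, W, Z, _ = _design_no_covariates(seed=5, shift=0.5)
    g_fix, s2_fix = 0.25, 1.0
    post = sample_posterior(
        y, W, Z, n_samples=6000, seed=9, n_chains=2,
        g_fixed=g_fix, sigma2_fixed=s2_fix,
    )
    ind = np.all(np.diff(post["theta"], axis=-1) > 0, axis=-1).ravel()
    p_gibbs = ind.mean()

    X = np.column_stack([W, Z])
    Q = X.T @ X + np.diag([0.0, 1 / g_fix, 1 / g_fix])
    mean = np.linalg.solve(Q, X.T @ y)
    cov = s2_fix * np.linalg.inv(Q)
    rng = np.random.default_rng(77)
    iid = rng.multivariate_normal(mean, cov, size=200_000)[:, 1:]
    p_iid = np.all(np.diff(iid, axis=-1) > 0, axis=-1).mean()

    se = math.sqrt(
        p_gibbs * (1 - p_gibbs) / 2000 + p_iid * (1 - p_iid) / 200_000
    )
    assert abs(p_gibbs - p_iid) < 3 * se


def test_overwhelming_ordering_reaches_encompassing_limit():
    """When the posterior fully satisfies the order, BF/BF_full -> B!."""
    df = simulate_metric_records(
        {"control": 50, "scd": 50, "mci": 50, "ad": 50},
        {"control": 10.0, "scd": 20.0, "mci": 30.0, "ad": 40.0},
        sd=1.0,
        seed=13,
    )
    res = bf_order_restricted(df, M1, n_samples=500, n_chains=2, seed=1)
    assert res.posterior_constraint_prob == 1.0
    assert res.bf_vs_null / res.bf_full_vs_null == pytest.approx(
        math.factorial(4), rel=1e-12
    )


def test_five_level_restrictions_supported():
    df = simulate_metric_records(
        {"control": 30, "scd": 30, "amci": 30, "mmci": 30, "ad": 30},
        {"control": 50.0, "scd": 50.0, "amci": 53.0, "mmci": 55.0, "ad": 58.0},
        sd=5.0,
        seed=31,
    )
    r5 = parse_restriction("[control=scd]<amci<mmci<ad")
    res = bf_order_restricted(df, r5, n_samples=500, n_chains=2, seed=2)
    assert res.prior_constraint_prob == pytest.approx(1 / 24)
    assert res.bf_vs_null == pytest.approx(
        res.bf_full_vs_null * res.posterior_constraint_prob * 24, rel=1e-12
    )


def test_compare_restrictions_identities():
    df = simulate_metric_records(
        {"control": 40, "scd": 40, "mci": 40, "ad": 40},
        {"control": 50.0, "scd": 50.0, "mci": 53.0, "ad": 56.0},
        sd=6.0,
        seed=22,
    )
    results = [
        bf_order_restricted(df, r, n_samples=400, n_chains=2, seed=5)
        for r in (M1, M2, M3)
    ]
    mat = compare_restrictions(results)
    assert np.allclose(np.diag(mat.to_numpy()), 1.0)
    m = mat.to_numpy()
    assert m[0, 1] * m[1, 2] == pytest.approx(m[0, 2], rel=1e-9)
    assert m[1, 0] == pytest.approx(
        results[1].bf_vs_null / results[0].bf_vs_null, rel=1e-12
    )


def test_compare_restrictions_rejects_mixed_datasets():
    df1 = simulate_metric_records(
        {"control": 20, "scd": 20, "mci": 20, "ad": 20},
        {g: 50.0 for g in ("control", "scd", "mci", "ad")}, sd=5.0, seed=1,
    )
    df2 = simulate_metric_records(
        {"control": 20, "scd": 20, "mci": 20, "ad": 20},
        {g: 50.0 for g in ("control", "scd", "mci", "ad")}, sd=5.0, seed=2,
    )
    r1 = bf_order_restricted(df1, M1, n_samples=200, n_chains=2, seed=1)
    r2 = bf_order_restricted(df2, M2, n_samples=200, n_chains=2, seed=1)
    with pytest.raises(ValueError):
        compare_restrictions([r1, r2])
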