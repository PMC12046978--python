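import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from penumbra.stats import (
    auto_lambda,
    bh_fdr,
    cohens_d_one_sample,
    d_confidence_interval,
    effective_df,
    one_sample_test,
    partial_r2,
    pearson_test,
    ridge_fit,
    standardize,
    two_sided_p_from_t,
    voxelwise_group_glm,
    welch_two_sample_test,
)


# ---------------------------------------------------------------------------
# t distribution p-values


def test_p_at_t_zero_is_one():
    assert two_sided_p_from_t(0.0, 5) == pytest.approx(1.0)
    assert two_sided_p_from_t(0.0, 3.7) == pytest.approx(1.0)


@pytest.mark.parametrize(
    "t, df, expected, places",
    [
        (-2.63, 59, 0.011, 3),      # integer df
        (-2.76, 36.46, 0.009, 3),   # fractional (Welch) df
        (-1.93, 78, 0.057, 3),
    ],
)
def test_p_reproduces_reported_values(t, df, expected, places):
    assert round(two_sided_p_from_t(t, df), places) == expected


def test_p_rejects_nonpositive_df():
    with pytest.raises(ValueError):
        two_sided_p_from_t(1.0, 0.0)


# ---------------------------------------------------------------------------
# one-sample test and Cohen's d


def test_one_sample_closed_form():
    res = one_sample_test([1.0, 2.0, 3.0], mu=0.0)
    assert res.t == pytest.approx(2 * np.sqrt(3))
    assert res.df == 2
    assert res.d == pytest.approx(2.0)


def test_one_sample_at_mu_is_null():
    res = one_sample_test([4.0, 5.0, 6.0], mu=5.0)
    assert res.t == 0.0
    assert res.p == pytest.approx(1.0)
    assert res.d == 0.0


def test_one_sample_d_identity_machine_precision(rng):
    x = rng.normal(size=17)
    res = one_sample_test(x)
    assert res.d == res.t / np.sqrt(17)


def test_one_sample_zero_variance_fails():
    with pytest.raises(ValueError):
        one_sample_test([2.0, 2.0, 2.0])


@pytest.mark.parametrize(
    "t, n, expected",
    [(-20.54, 60, -2.65), (-9.06, 60, -1.17), (0.0, 60, 0.0)],
)
def test_cohens_d_from_t(t, n, expected):
    assert round(cohens_d_one_sample(t, n), 2) == expected


def test_d_ci_symmetric_at_zero():
    lo, hi = d_confidence_interval(0.0, 60)
    assert lo == pytest.approx(-1.959964 / np.sqrt(60), abs=1e-6)
    assert hi == -lo
    assert round(hi, 3) == 0.253


def test_d_ci_closed_form_frozen():
    d = cohens_d_one_sample(-9.06, 60)  # -1.1696...
    lo, hi = d_confidence_interval(d, 60)
    assert (round(lo, 3), round(hi, 3)) == (-1.498, -0.841)
    assert (round(lo, 2), round(hi, 2)) == (-1.50, -0.84)


def test_d_ci_width_grows_with_magnitude():
    widths = [np.diff(d_confidence_interval(d, 60))[0] for d in (0.0, 0.5, 1.0, 2.0)]
    assert all(b > a for a, b in zip(widths, widths[1:]))


# ---------------------------------------------------------------------------
# two-sample test


def test_welch_identical_samples_null(rng):
    x = rng.normal(size=10)
    res = welch_two_sample_test(x, x.copy())
    assert res.t == pytest.approx(0.0, abs=1e-12)
    assert res.p == pytest.approx(1.0)


def test_welch_separated_samples():
    res = welch_two_sample_test([0.0, 0.001, -0.001], [1.0, 1.001, 0.999])
    assert abs(res.t) > 100
    assert res.p < 1e-6


def test_welch_matches_scipy_oracle(rng):
    a, b = rng.normal(size=12), rng.normal(0.5, 2.0, size=9)
    res = welch_two_sample_test(a, b)
    t_ref, p_ref = sps.ttest_ind(b, a, equal_var=False)
    assert res.t == pytest.approx(t_ref)
    assert res.p == pytest.approx(p_ref)
    res_p = welch_two_sample_test(a, b, equal_var=True)
    t_ref, p_ref = sps.ttest_ind(b, a, equal_var=True)
    assert res_p.t == pytest.approx(t_ref)
    assert res_p.df == len(a) + len(b) - 2


def test_welch_double_zero_variance_fails():
    with pytest.raises(ValueError):
        welch_two_sample_test([1.0, 1.0], [2.0, 2.0])


# ---------------------------------------------------------------------------
# Pearson


def test_pearson_exact_linear():
    x = np.arange(10.0)
    r, t, df, p = pearson_test(x, 2 * x + 1)
    assert r == pytest.approx(1.0)
    assert p == pytest.approx(0.0, abs=1e-12)


def test_pearson_reported_value_r049_df18():
    # build data with r ~= -0.49 at n=20, then verify the p derived from r
    r = -0.49
    df = 18
    t = r * np.sqrt(df / (1 - r * r))
    assert round(two_sided_p_from_t(t, df), 2) == 0.03


def test_pearson_matches_scipy(rng):
    x, y = rng.normal(size=25), rng.normal(size=25)
    r, t, df, p = pearson_test(x, y)
    ref = sps.pearsonr(x, y)
    assert r == pytest.approx(ref.statistic)
    assert p == pytest.approx(ref.pvalue)
    assert df == 23


def test_pearson_constant_input_fails():
    with pytest.raises(ValueError):
        pearson_test([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


# ---------------------------------------------------------------------------
# ridge regression


def _design(rng, n=20, p=4):
    X = standardize(rng.normal(size=(n, p)))
    beta = rng.normal(size=p)
    y = X @ beta + rng.normal(size=n)
    return X, y - y.mean()


def test_ridge_lambda_zero_equals_ols(rng):
    X, y = _design(rng)
    fit = ridge_fit(X, y, lam=0.0)
    beta_ols = np.linalg.solve(X.T @ X, X.T @ y)
    np.testing.assert_allclose(fit.coef, beta_ols, rtol=1e-8)
    assert fit.edf == pytest.approx(len(y) - X.shape[1], abs=1e-8)
    # OLS standard errors as the oracle
    resid = y - X @ beta_ols
    sigma2 = resid @ resid / (len(y) - X.shape[1])
    se_ols = np.sqrt(np.diag(sigma2 * np.linalg.inv(X.T @ X)))
    np.testing.assert_allclose(fit.se, se_ols, rtol=1e-8)


def test_ridge_huge_lambda_shrinks_to_zero(rng):
    X, y = _design(rng)
    fit = ridge_fit(X, y, lam=1e12)
    np.testing.assert_allclose(fit.coef, 0.0, atol=1e-9)
    assert fit.edf == pytest.approx(len(y), abs=1e-6)


def test_ridge_small_fixture_dense_oracle():
    # n=6, p=2, lambda=1: everything from an explicit 2x2 matrix inversion
    X = standardize(np.array([[1.0, 2.0], [2.0, 1.0], [3.0, 5.0], [4.0, 2.0], [5.0, 7.0], [6.0, 3.0]]))
    y = np.array([1.0, -2.0, 3.0, -1.0, 2.0, 0.5])
    y = y - y.mean()
    lam = 1.0
    fit = ridge_fit(X, y, lam=lam)

    G = X.T @ X + lam * np.eye(2)
    a, b, c, d = G[0, 0], G[0, 1], G[1, 0], G[1, 1]
    det = a * d - b * c
    G_inv = np.array([[d, -b], [-c, a]]) / det  # analytic 2x2 inverse
    coef = G_inv @ X.T @ y
    np.testing.assert_allclose(fit.coef, coef, rtol=1e-12)

    H = X @ G_inv @ X.T
    edf = 6 - np.trace(2 * H - H @ H.T)
    assert fit.edf == pytest.approx(edf, abs=1e-12)
    resid = y - X @ coef
    sigma2 = resid @ resid / edf
    se = np.sqrt(np.diag(sigma2 * G_inv @ (X.T @ X) @ G_inv))
    np.testing.assert_allclose(fit.se, se, rtol=1e-12)
    np.testing.assert_allclose(fit.t, coef / se, rtol=1e-12)
    for ti, pi in zip(fit.t, fit.p):
        assert pi == pytest.approx(2 * sps.t.sf(abs(ti), edf))
    assert fit.r2 == pytest.approx(1 - (resid @ resid) / (y @ y))


def test_ridge_requires_standardized_x(rng):
    X = rng.normal(size=(15, 3)) + 5.0
    y = rng.normal(size=15)
    with pytest.raises(ValueError, match="standardized"):
        ridge_fit(X, y - y.mean(), lam=1.0)


def test_ridge_negative_lambda_fails(rng):
    X, y = _design(rng)
    with pytest.raises(ValueError):
        ridge_fit(X, y, lam=-0.5)


def test_ridge_partial_r2_in_range(rng):
    X, y = _design(rng, n=30, p=5)
    fit = ridge_fit(X, y, lam=2.0)
    assert ((fit.partial_r2 >= 0) & (fit.partial_r2 < 1)).all()
    np.testing.assert_allclose(fit.partial_r2, fit.t**2 / (fit.t**2 + fit.edf))


# ---------------------------------------------------------------------------
# effective df


def test_edf_lambda_zero_full_rank(rng):
    X = rng.normal(size=(12, 4))
    assert effective_df(X, 0.0) == pytest.approx(8.0, abs=1e-9)


def test_edf_huge_lambda_tends_to_n(rng):
    X = rng.normal(size=(12, 4))
    assert effective_df(X, 1e14) == pytest.approx(12.0, abs=1e-6)


def test_edf_svd_identity_oracle(rng):
    X = rng.normal(size=(8, 3))
    lam = 0.7
    s = np.linalg.svd(X, compute_uv=False)
    d2 = s * s
    oracle = 8 - np.sum(d2 * (d2 + 2 * lam) / (d2 + lam) ** 2)
    assert effective_df(X, lam) == pytest.approx(oracle, abs=1e-10)


@settings(max_examples=20, deadline=None)
@given(seed=st.integers(0, 10_000))
def test_edf_strictly_increasing_in_lambda(seed):
    r = np.random.default_rng(seed)
    X = r.normal(size=(10, 3))
    lams = [0.0, 0.1, 1.0, 10.0, 100.0]
    vals = [effective_df(X, l) for l in lams]
    assert all(b > a for a, b in zip(vals, vals[1:]))
    assert vals[-1] <= 10.0 + 1e-9


# ---------------------------------------------------------------------------
# automatic penalty


def test_auto_lambda_noiseless_linear_is_tiny(rng):
    X = standardize(rng.normal(size=(30, 3)))
    y = X @ np.array([1.0, -2.0, 0.5])
    assert auto_lambda(X, y) < 1e-5


def test_auto_lambda_pure_noise_positive():
    r = np.random.default_rng(42)
    X = standardize(r.normal(size=(14, 10)))
    y = r.normal(size=14)
    y = y - y.mean()
    lam = auto_lambda(X, y)
    assert lam > 0

    # GCV grid oracle: the returned lambda must beat every coarse grid point
    def gcv(l):
        H = X @ np.linalg.solve(X.T @ X + l * np.eye(10), X.T)
        resid = y - H @ y
        return (resid @ resid) / (14 - np.trace(H)) ** 2

    coarse = np.concatenate([[0.0], np.logspace(-6, 6, 121)])
    assert gcv(lam) <= min(gcv(l) for l in coarse) + 1e-12


def test_auto_lambda_degenerate_outcome_fails(rng):
    X = standardize(rng.normal(size=(10, 2)))
    with pytest.raises(ValueError):
        auto_lambda(X, np.zeros(10))


# ---------------------------------------------------------------------------
# partial R^2


@pytest.mark.parametrize(
    "t, df, expected",
    [(2.65, 54.6, 0.11), (2.91, 53.4, 0.14), (0.0, 10, 0.0)],
)
def test_partial_r2_values(t, df, expected):
    assert round(partial_r2(t, df), 2) == expected


def test_partial_r2_rejects_bad_df():
    with pytest.raises(ValueError):
        partial_r2(1.0, 0.0)


# ---------------------------------------------------------------------------
# BH-FDR


def test_bh_all_ones_no_rejections():
    assert not bh_fdr(np.ones(10)).any()


def test_bh_single_small_p_rejected():
    assert bh_fdr([0.01], alpha=0.05).all()


def test_bh_stepup_hand_computation():
    p = np.array([0.001, 0.008, 0.039, 0.041, 0.042, 0.06, 0.9])
    rej = bh_fdr(p, alpha=0.05)
    # step-up by hand: thresholds 0.05*k/7 are (0.0071, 0.0143, 0.0214, 0.0286,
    # 0.0357, 0.0429, 0.05); the largest k with p_(k) <= 0.05*k/7 is k=2
    # (p_(3)=0.039 > 0.0214 and every later rank also fails its bound)
    np.testing.assert_array_equal(rej, [True, True, False, False, False, False, False])


def test_bh_empty_input():
    assert bh_fdr([]).size == 0


@settings(max_examples=40, deadline=None)
@given(seed=st.integers(0, 100_000), n=st.integers(1, 60))
def test_bh_matches_statsmodels(seed, n):
    from statsmodels.stats.multitest import multipletests

    p = np.random.default_rng(seed).uniform(size=n)
    mine = bh_fdr(p, alpha=0.05)
    ref = multipletests(p, alpha=0.05, method="fdr_bh")[0]
    np.testing.assert_array_equal(mine, ref)


# ---------------------------------------------------------------------------
# voxelwise GLM


def test_voxelwise_identical_groups_zero_noise_no_clusters():
    base = np.zeros((10, 8, 8, 8))
    base[:, 2:6, 2:6, 2:6] = 1.0  # identical for everyone, zero variance
    mask = np.ones((8, 8, 8), bool)
    group = np.array([0, 0, 0, 0, 0, 1, 1, 1, 1, 1])
    res = voxelwise_group_glm(base, group, mask, extent_k=1)
    assert res.n_tested == 0
    assert res.clusters.empty
    assert not res.sig_mask.any()


def test_voxelwise_planted_block_recovered():
    r = np.random.default_rng(5)
    n = 30
    shape = (12, 12, 12)
    data = r.normal(0, 0.1, size=(n,) + shape)
    group = np.array([0] * 15 + [1] * 15)
    block = np.zeros(shape, bool)
    block[4:9, 4:9, 4:9] = True
    for i in np.nonzero(group == 1)[0]:
        data[i][block] += 2.0  # SNR = 20
    mask = np.ones(shape, bool)
    res = voxelwise_group_glm(data, group, mask, alpha=0.05, extent_k=10)
    assert len(res.clusters) >= 1
    inside = (res.sig_mask & block).sum()
    assert inside >= 0.9 * block.sum()
    from scipy import ndimage

    halo = ndimage.binary_dilation(block, structure=ndimage.generate_binary_structure(3, 3))
    assert not (res.sig_mask & ~halo).any()


def test_voxelwise_extent_rule_drops_small_components():
    r = np.random.default_rng(11)
    n = 24
    shape = (10, 10, 10)
    data = r.normal(0, 0.05, size=(n,) + shape)
    group = np.array([0] * 12 + [1] * 12)
    comp = np.zeros(shape, bool)
    comp[1:4, 1:4, 2] = True  # 9-voxel component
    for i in np.nonzero(group == 1)[0]:
        data[i][comp] += 3.0
    res = voxelwise_group_glm(data, group, np.ones(shape, bool), extent_k=10)
    assert res.clusters.empty
    res2 = voxelwise_group_glm(data, group, np.ones(shape, bool), extent_k=9)
    assert len(res2.clusters) == 1
    assert res2.clusters.iloc[0]["size_voxels"] == 9


def test_voxelwise_matches_per_voxel_ols_oracle():
    r = np.random.default_rng(3)
    n = 16
    shape = (4, 4, 4)
    data = r.normal(size=(n,) + shape)
    group = (r.uniform(size=n) > 0.5).astype(float)
    group[:2] = [0, 1]  # ensure both groups present
    cov = r.normal(size=(n, 1))
    mask = np.ones(shape, bool)
    res = voxelwise_group_glm(data, group, mask, covariates=cov, extent_k=1)
    import statsmodels.api as sm

    X = sm.add_constant(np.column_stack([group, cov]))
    for idx in [(0, 0, 0), (1, 2, 3), (3, 3, 3)]:
        fit = sm.OLS(data[(slice(None), *idx)], X).fit()
        assert res.t_map[idx] == pytest.approx(fit.tvalues[1], rel=1e-8)
        assert res.p_map[idx] == pytest.approx(fit.pvalues[1], rel=1e-8)
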