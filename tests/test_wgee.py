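"""Weighted-GEE estimator and tests against independent oracles.

Oracles: statsmodels GLM (ordinary logistic MLE and Rao score test) for the
unit-weight reductions, and a dense grid search over the weighted
log-likelihood for small weighted problems.
"""

import numpy as np
import pytest
import statsmodels.api as sm
from scipy.special import expit
from scipy.stats import chi2

from wip.wgee import (
    CohortData,
    ConvergenceError,
    SeparationError,
    fit_wgee,
    score_test,
    wald_test,
)


def _simulate(n, seed, beta=(-0.3, 0.5, 0.2)):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    g = rng.binomial(2, 0.3, size=n).astype(float)
    eta = beta[0] + beta[1] * x + beta[2] * g
    y = rng.binomial(1, expit(eta)).astype(float)
    Z = np.column_stack([np.ones(n), x])
    return CohortData(y=y, Z=Z, G=g), np.column_stack([Z, g])


@pytest.mark.parametrize("seed", range(5))
def test_unit_weights_match_logistic_mle(seed):
    data, X = _simulate(500, seed)
    fit = fit_wgee(data)
    ref = sm.GLM(data.y, X, family=sm.families.Binomial()).fit()
    assert fit.converged
    assert np.allclose(fit.params, ref.params, atol=1e-8)


def test_weighted_fit_matches_grid_search_oracle():
    # 8 hand-listed rows, intercept + one regressor, fractional weights
    y = np.array([1, 0, 1, 1, 0, 1, 0, 0], dtype=float)
    x = np.array([0.5, -1.2, 1.0, -0.3, 0.4, 2.0, -1.5, 0.1])
    w = np.array([1, 1, 1, 1, 0.9, 0.8, 0.7, 0.6])
    data = CohortData(y=y, Z=np.ones((8, 1)), G=x, w=w)
    fit = fit_wgee(data)

    def ll_surface(b0s, b1s):
        eta = b0s[:, None, None] + b1s[None, :, None] * x
        mu = np.clip(expit(eta), 1e-12, 1 - 1e-12)
        return (w * (y * np.log(mu) + (1 - y) * np.log(1 - mu))).sum(axis=-1)

    coarse = np.arange(-3, 3, 0.05)
    ll = ll_surface(coarse, coarse)
    i, j = np.unravel_index(np.argmax(ll), ll.shape)
    fine0 = coarse[i] + np.arange(-0.06, 0.06, 1e-3)
    fine1 = coarse[j] + np.arange(-0.06, 0.06, 1e-3)
    ll = ll_surface(fine0, fine1)
    i, j = np.unravel_index(np.argmax(ll), ll.shape)
    assert fit.params == pytest.approx((fine0[i], fine1[j]), abs=2e-3)


def test_duplicated_row_equals_doubled_weight():
    data, _ = _simulate(60, 3)
    r = 7
    dup = CohortData(
        y=np.append(data.y, data.y[r]),
        Z=np.vstack([data.Z, data.Z[r]]),
        G=np.append(data.G.ravel(), data.G[r]),
    )
    w2 = np.ones(60)
    w2[r] = 2.0
    reweighted = CohortData(y=data.y, Z=data.Z, G=data.G.ravel(), w=w2)
    assert np.allclose(fit_wgee(dup).params, fit_wgee(reweighted).params, atol=1e-10)


def test_weight_scaling_invariance():
    data, _ = _simulate(200, 9)
    rng = np.random.default_rng(1)
    w = rng.uniform(0.5, 1.0, 200)
    base = fit_wgee(CohortData(y=data.y, Z=data.Z, G=data.G.ravel(), w=w))
    scaled = fit_wgee(CohortData(y=data.y, Z=data.Z, G=data.G.ravel(), w=3.0 * w))
    assert np.allclose(base.params, scaled.params, atol=1e-9)
    # model-based information scales with c, so the covariance scales with 1/c
    assert np.allclose(scaled.cov_model * 3.0, base.cov_model, rtol=1e-6)


def test_score_at_optimum_below_tolerance():
    data, _ = _simulate(300, 11)
    fit = fit_wgee(data, tol=1e-10)
    assert fit.converged and fit.score_norm <= 1e-10


def test_wald_single_beta_equals_z_squared():
    data, X = _simulate(400, 2)
    fit = fit_wgee(data)
    ref = sm.GLM(data.y, X, family=sm.families.Binomial()).fit()
    res = wald_test(fit, cov="model")
    assert res.statistic == pytest.approx(float(ref.tvalues[-1] ** 2), rel=1e-6)
    assert res.df == 1


def test_wald_zero_beta_gives_unit_pvalue():
    fit_stub = fit_wgee(_simulate(100, 4)[0])
    fit_stub.params[fit_stub.geno_idx] = 0.0
    res = wald_test(fit_stub)
    assert res.statistic == 0.0 and res.pvalue == 1.0


def test_wald_refuses_nonconverged_fit():
    data, _ = _simulate(500, 5)
    fit = fit_wgee(data, max_iter=1, tol=1e-12)
    assert not fit.converged
    with pytest.raises(ConvergenceError):
        wald_test(fit)


def test_null_rejection_rate_calibrated():
    """Under beta_G = 0, the Wald test rejects ~5% at alpha = 0.05."""
    rng = np.random.default_rng(123)
    reject = 0
    reps = 400
    for _ in range(reps):
        n = 1000
        x = rng.normal(size=n)
        g = rng.binomial(2, 0.3, n).astype(float)
        y = rng.binomial(1, expit(0.2 * x)).astype(float)
        fit = fit_wgee(CohortData(y=y, Z=np.column_stack([np.ones(n), x]), G=g))
        reject += wald_test(fit).pvalue < 0.05
    rate = reject / reps
    assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / reps)


@pytest.mark.parametrize("seed", range(3))
def test_unit_weight_score_matches_rao(seed):
    data, X = _simulate(600, seed + 40)
    null = sm.GLM(data.y, data.Z, family=sm.families.Binomial()).fit()
    stat_ref, p_ref, df_ref = null.score_test(exog_extra=data.G)
    res = score_test(data, cov="model")
    assert res.statistic == pytest.approx(np.squeeze(stat_ref).item(), abs=1e-6)
    assert res.pvalue == pytest.approx(np.squeeze(p_ref).item(), abs=1e-8)
    assert res.df == int(np.squeeze(df_ref))


def test_constant_genotype_gives_null_score():
    data, _ = _simulate(100, 7)
    const = CohortData(y=data.y, Z=data.Z, G=np.full(100, 1.0))
    res = score_test(const)
    assert res.statistic == 0.0 and res.pvalue == 1.0


def test_score_and_wald_agree_asymptotically():
    rng = np.random.default_rng(314)
    n = 10_000
    x = rng.normal(size=n)
    g = rng.binomial(2, 0.3, n).astype(float)
    y = rng.binomial(1, expit(-0.2 + 0.3 * x + 0.2 * g)).astype(float)
    data = CohortData(y=y, Z=np.column_stack([np.ones(n), x]), G=g)
    p_score = score_test(data).pvalue
    p_wald = wald_test(fit_wgee(data), cov="model").pvalue
    lw, ls = -np.log10(p_wald), -np.log10(p_score)
    assert abs(lw - ls) / ls < 0.10


def test_robust_score_close_to_model_score_at_unit_weights():
    data, _ = _simulate(2000, 77)
    t_model = score_test(data, cov="model").statistic
    t_robust = score_test(data, cov="robust").statistic
    assert t_robust == pytest.approx(t_model, rel=0.15)


def test_perfect_separation_raises_named_column():
    n = 40
    y = np.array([0.0] * 20 + [1.0] * 20)
    sep = np.array([-1.0] * 20 + [1.0] * 20)
    data = CohortData(y=y, Z=np.ones((n, 1)), G=sep)
    with pytest.raises(SeparationError, match="column 1"):
        fit_wgee(data)


def test_method_taxonomy_single_code_path():
    """LR/IP/WIP differ only in (subset, weight); hard probabilities collapse IP=WIP."""
    rng = np.random.default_rng(10)
    n = 300
    y = rng.binomial(1, 0.5, n).astype(float)
    Z = np.column_stack([np.ones(n), rng.normal(size=n)])
    G = rng.binomial(2, 0.2, n).astype(float)
    labeled = rng.random(n) < 0.7
    p = y.astype(float)  # oracle probabilities: exactly 0/1 and correct
    ip = CohortData.for_method("ip", y, p, Z, G, labeled)
    wip = CohortData.for_method("wip", y, p, Z, G, labeled)
    assert np.allclose(fit_wgee(ip).params, fit_wgee(wip).params, atol=1e-12)
    # with nothing masked, IP and WIP reduce to LR exactly
    all_lab = np.ones(n, dtype=bool)
    lr = CohortData.for_method("lr", y, p, Z, G, all_lab)
    ip0 = CohortData.for_method("ip", y, p, Z, G, all_lab)
    assert np.allclose(fit_wgee(lr).params, fit_wgee(ip0).params, atol=1e-12)


def test_cohort_data_validation():
    with pytest.raises(ValueError, match="intercept"):
        CohortData(y=np.array([0.0, 1.0]), Z=np.array([[2.0], [2.0]]), G=np.zeros(2))
    with pytest.raises(ValueError, match="positive"):
        CohortData(y=np.array([0.0, 1.0]), Z=np.ones((2, 1)), G=np.zeros(2),
                   w=np.array([1.0, 0.0]))
    with pytest.raises(ValueError, match="row mismatch"):
        CohortData(y=np.array([0.0, 1.0]), Z=np.ones((3, 1)), G=np.zeros(2))
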