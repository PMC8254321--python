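"""Model-layer tests: group statistics, likelihoods, full and null fits."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps
from scipy.optimize import minimize

from xciskew import (
    DegenerateGroupError,
    QuantSample,
    XCISkewModel,
    fit_full,
    fit_null,
    group_stats,
    loglik_full,
    lr_stat,
)
from xciskew.model import _loglik_null

from conftest import make_sample


# ---------------------------------------------------------------------------
# QuantSample and group statistics


def test_sample_rejects_bad_codes():
    with pytest.raises(ValueError, match="0/1/2"):
        QuantSample([1.0, 2.0], [0, 3])
    with pytest.raises(ValueError, match="finite"):
        QuantSample([1.0, np.inf], [0, 1])
    with pytest.raises(ValueError, match="empty"):
        QuantSample([], [])


@pytest.mark.parametrize(
    "traits, genos, counts, means, variances",
    [
        # constant within group
        ((0, 0, 1, 1, 2, 2), (0, 0, 1, 1, 2, 2), (2, 2, 2), (0, 1, 2), (0, 0, 0)),
        # hand arithmetic with the MLE divisor n_i
        ((0, 2, 1, 3, 2, 4), (0, 0, 1, 1, 2, 2), (2, 2, 2), (1, 2, 3), (1, 1, 1)),
    ],
)
def test_group_stats_examples(traits, genos, counts, means, variances):
    st_ = group_stats(QuantSample(traits, genos))
    np.testing.assert_array_equal(st_.counts, counts)
    np.testing.assert_allclose(st_.means, means)
    np.testing.assert_allclose(st_.variances, variances)


def test_group_stats_flags_empty_groups():
    st_ = group_stats(QuantSample([1.0, 2.0, 3.0], [1, 1, 1]))
    np.testing.assert_array_equal(st_.counts, [0, 3, 0])
    np.testing.assert_array_equal(st_.empty_groups, [0, 2])


# ---------------------------------------------------------------------------
# unconstrained log-likelihood


def test_loglik_full_zero_residual_single_point():
    s = QuantSample([0.7], [0])
    ll = loglik_full(s, beta0=0.7, beta1=0, beta2=0, sigma0=1, sigma1=1, sigma2=1)
    assert ll == pytest.approx(-np.log(np.sqrt(2 * np.pi)))


def test_loglik_full_matches_normal_logpdf(sim_sample):
    params = dict(beta0=0.1, beta1=0.4, beta2=0.2, sigma0=1.0, sigma1=1.2, sigma2=0.9)
    means = np.array([0.1, 0.5, 0.7])[sim_sample.genotype]
    sds = np.array([1.0, 1.2, 0.9])[sim_sample.genotype]
    expected = sps.norm.logpdf(sim_sample.trait, means, sds).sum()
    assert loglik_full(sim_sample, **params) == pytest.approx(expected, rel=1e-12)


def test_loglik_full_scale_identity():
    # at zero residuals, scaling every sigma by k lowers l1 by n log k
    s = QuantSample([0.0, 0.0, 1.0, 1.0, 2.0, 2.0], [0, 0, 1, 1, 2, 2])
    base = dict(beta0=0.0, beta1=1.0, beta2=1.0)
    l1 = loglik_full(s, **base, sigma0=1, sigma1=1, sigma2=1)
    lk = loglik_full(s, **base, sigma0=3, sigma1=3, sigma2=3)
    assert l1 - lk == pytest.approx(s.n * np.log(3.0))


def test_loglik_full_rejects_nonpositive_sigma(toy_sample):
    with pytest.raises(ValueError, match="positive"):
        loglik_full(toy_sample, 0, 0, 0, sigma0=0.0, sigma1=1, sigma2=1)


# ---------------------------------------------------------------------------
# full fit


def test_fit_full_closed_form(toy_sample):
    f = fit_full(toy_sample, variance_structure="free")
    assert (f.beta0, f.beta1, f.beta2) == (1.0, 1.0, 1.0)
    np.testing.assert_allclose(f.sigma**2, [1, 1, 1])
    np.testing.assert_allclose(f.cov_b1_b2, [[1.0, -0.5], [-0.5, 1.0]])
    # shared structure pools the (equal) homozygote variances -> same result
    fs = fit_full(toy_sample)
    np.testing.assert_allclose(fs.sigma**2, [1, 1, 1])
    assert fs.loglik == pytest.approx(f.loglik)


@pytest.mark.parametrize("structure", ["free", "shared"])
def test_fit_full_matches_numerical_maximizer(rng, structure):
    """The closed-form fit agrees with a generic optimizer of l1."""
    s = make_sample(rng, n=250)
    fit = fit_full(s, variance_structure=structure)

    def neg(theta):
        b0, b1, b2, l0_, l1_, l2_ = theta
        if structure == "shared":
            l2_ = l0_
        return -loglik_full(
            s, b0, b1, b2, np.exp(l0_), np.exp(l1_), np.exp(l2_)
        )

    res = minimize(
        neg,
        [0.0, 0.3, 0.3, 0.0, 0.0, 0.0],
        method="Nelder-Mead",
        options=dict(maxiter=40000, xatol=1e-10, fatol=1e-12),
    )
    assert fit.loglik >= -res.fun - 1e-6
    assert fit.loglik == pytest.approx(-res.fun, abs=1e-6)


def test_fit_full_covariates_matches_optimizer(rng):
    scen_free = make_sample(rng, n=300)
    z = rng.normal(size=(scen_free.n, 1))
    y = scen_free.trait + 0.5 * z[:, 0]
    s = QuantSample(y, scen_free.genotype, covariates=z)
    fit = fit_full(s)
    assert fit.converged

    def neg(theta):
        b0, b1, b2, bz, l02, l1_ = theta
        return -loglik_full(
            s, b0, b1, b2, np.exp(l02), np.exp(l1_), np.exp(l02), b=[bz]
        )

    x0 = [fit.beta0 + 0.05, fit.beta1, fit.beta2, 0.4, 0.05, 0.0]
    res = minimize(neg, x0, method="Nelder-Mead",
                   options=dict(maxiter=40000, xatol=1e-10, fatol=1e-12))
    assert fit.loglik == pytest.approx(-res.fun, abs=1e-6)


def test_fit_full_is_maximum(sim_sample):
    fit = fit_full(sim_sample, variance_structure="free")
    base = loglik_full(
        sim_sample, fit.beta0, fit.beta1, fit.beta2, fit.sigma0, fit.sigma1,
        fit.sigma2,
    )
    assert base == pytest.approx(fit.loglik, rel=1e-12)
    rng = np.random.default_rng(1)
    for _ in range(20):
        eps = rng.normal(scale=0.05, size=6)
        perturbed = loglik_full(
            sim_sample,
            fit.beta0 + eps[0], fit.beta1 + eps[1], fit.beta2 + eps[2],
            fit.sigma0 * np.exp(eps[3]), fit.sigma1 * np.exp(eps[4]),
            fit.sigma2 * np.exp(eps[5]),
        )
        assert perturbed <= base + 1e-10


def test_fit_refuses_degenerate_groups():
    with pytest.raises(DegenerateGroupError, match="at least"):
        fit_full(QuantSample([1.0, 2.0, 3.0, 4.0], [0, 0, 1, 1]))
    constant_group = QuantSample([1.0, 1.0, 0.0, 2.0, 0.0, 2.0], [0, 0, 1, 1, 2, 2])
    with pytest.raises(DegenerateGroupError, match="variance"):
        fit_full(constant_group)


# ---------------------------------------------------------------------------
# null fit and LR statistic


def test_fit_null_nonbinding_constraint():
    # group means exactly (m0, m0 + gamma0*b, m0 + 2b): constraint inactive
    gamma0, m0, b = 0.8, 0.5, 0.7
    means = [m0, m0 + gamma0 * b, m0 + 2 * b]
    y, g = [], []
    for i, m in enumerate(means):
        y += [m - 0.3, m + 0.3, m - 0.1, m + 0.1]
        g += [i] * 4
    s = QuantSample(y, g)
    full = fit_full(s)
    null = fit_null(s, gamma0)
    assert null.loglik == pytest.approx(full.loglik, abs=1e-9)
    np.testing.assert_allclose(
        [null.beta0, null.beta], [m0, b], atol=1e-7
    )
    assert lr_stat(s, gamma0) == pytest.approx(0.0, abs=1e-8)


def test_fit_null_gamma0_one_is_weighted_regression(rng):
    """At gamma0=1 the null model is WLS on additive codes (0, 1, 2)."""
    s = make_sample(rng, n=400)
    null = fit_null(s, 1.0, variance_structure="free")
    # independent oracle: iterate statsmodels WLS + variance update
    import statsmodels.api as sm

    X = sm.add_constant(s.genotype.astype(float))
    sigma2 = np.array([s.trait[s.genotype == i].var() for i in range(3)])
    for _ in range(400):
        w = 1.0 / sigma2[s.genotype]
        res = sm.WLS(s.trait, X, weights=w).fit()
        resid = s.trait - res.fittedvalues
        new = np.array(
            [np.mean(resid[s.genotype == i] ** 2) for i in range(3)]
        )
        if np.max(np.abs(new - sigma2)) < 1e-14:
            break
        sigma2 = new
    np.testing.assert_allclose(
        [null.beta0, null.beta], res.params, atol=1e-6
    )
    np.testing.assert_allclose(null.sigma**2, sigma2, rtol=1e-6)


@pytest.mark.parametrize("structure", ["free", "shared"])
def test_fit_null_matches_optimizer(rng, structure):
    s = make_sample(rng, n=250)
    for gamma0 in (0.0, 0.6, 1.7):
        null = fit_null(s, gamma0, variance_structure=structure)

        def neg(theta):
            b0, b, l0_, l1_, l2_ = theta
            if structure == "shared":
                l2_ = l0_
            return -_loglik_null(s, gamma0, b0, b, np.exp([l0_, l1_, l2_]))

        res = minimize(neg, [0.1, 0.3, 0.0, 0.0, 0.0], method="Nelder-Mead",
                       options=dict(maxiter=40000, xatol=1e-10, fatol=1e-12))
        assert null.loglik == pytest.approx(-res.fun, abs=1e-6)


def test_lr_stat_zero_at_raw_gamma(sim_sample):
    from xciskew import estimate_gamma

    full = fit_full(sim_sample)
    est = estimate_gamma(full)
    if 0.0 <= est.gamma_raw <= 2.0:
        assert lr_stat(sim_sample, est.gamma_raw) == pytest.approx(0.0, abs=1e-8)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000), gamma0=st.floats(0.0, 2.0))
def test_nesting_l0_le_l1(seed, gamma0):
    """The constrained maximum never exceeds the unconstrained one."""
    rng = np.random.default_rng(seed)
    s = make_sample(rng, n=90, gamma=rng.uniform(0, 2))
    for structure in ("shared", "free"):
        full = fit_full(s, variance_structure=structure)
        null = fit_null(s, gamma0, variance_structure=structure)
        assert null.loglik <= full.loglik + 1e-8


def test_lr_chi2_calibration(rng):
    """Empirical 95th percentile of lambda under H0 near chi2_{0.95,1}."""
    from xciskew import _kernels
    from xciskew.simulate import SimScenario, simulate_group_stats

    scen = SimScenario(p=0.3, gamma=1.0, a=0.3, n=2000)
    counts, means, ss, _ = simulate_group_stats(scen, 5000, 77)
    lam, _ = _kernels.lr_stat(counts, means, ss, 1.0)
    q95 = np.quantile(lam, 0.95)
    assert abs(q95 - sps.chi2.ppf(0.95, 1)) < 0.3


def test_parameter_recovery():
    """Mean of the estimates over replicates within 3 MC SEs of truth."""
    from xciskew import _kernels
    from xciskew.simulate import SimScenario, simulate_group_stats, sigma1_sq

    scen = SimScenario(p=0.3, gamma=1.0, a=0.3, n=2000)
    counts, means, ss, _ = simulate_group_stats(scen, 1000, 13)
    k = _kernels.full_fit(counts, means, ss, shared=False)
    truth = {
        "beta0": scen.beta0,
        "beta1": scen.gamma * scen.beta,
        "beta2": (2 - scen.gamma) * scen.beta,
    }
    for name, true_val in truth.items():
        est = k[name]
        se = est.std(ddof=1) / np.sqrt(len(est))
        assert abs(est.mean() - true_val) < 3 * se + 1e-12
    for i, true_var in enumerate([1.0, sigma1_sq(1.0, 0.3), 1.0]):
        est = k["sigma2"][:, i]
        se = est.std(ddof=1) / np.sqrt(len(est))
        # the MLE variance has exact expectation sigma^2 (n_i - 1)/n_i
        expected = true_var * (counts[:, i] - 1) / counts[:, i]
        assert abs(est.mean() - expected.mean()) < 3 * se


def test_model_results_surface(toy_sample):
    res = XCISkewModel(toy_sample.trait, toy_sample.genotype).fit()
    assert res.gamma == pytest.approx(1.0)
    assert res.theta == pytest.approx(0.5)
    assert res.llf == pytest.approx(res.fullfit.loglik)
    text = res.summary()
    assert "gamma_hat" in text and "confidence regions" in text
    t = res.test_gamma(1.0, method="lr")
    assert t.pvalue == pytest.approx(1.0)
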