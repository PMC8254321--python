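"""Confidence-region constructions: cases, oracles and duality."""

import numpy as np
import pytest
from scipy import stats as sps

from xciskew import QuantSample, fit_full, estimate_gamma
from xciskew.estimate import GammaEstimate
from xciskew.hypotheses import fieller_test, lr_test
from xciskew.intervals import (
    ConfidenceRegion,
    delta_ci,
    fieller_ci,
    lr_ci,
)
from xciskew.model import FullFit

from conftest import make_sample


def _est(gamma_hat, var, gamma_raw=None):
    fit = FullFit(0, 1, 1, None, 1, 1, 1, 0.0, np.eye(2))
    return GammaEstimate(
        gamma_raw=gamma_raw if gamma_raw is not None else gamma_hat,
        gamma_hat=gamma_hat,
        theta_hat=gamma_hat / 2,
        beta_hat=1.0,
        var_delta=var,
        source_fit=fit,
    )


def _fit(beta1, beta2, cov):
    return FullFit(0.0, beta1, beta2, None, 1, 1, 1, 0.0,
                   np.asarray(cov, dtype=float))


# ---------------------------------------------------------------------------
# region container


def test_region_status_vocabulary():
    full = ConfidenceRegion("LR", 0.95, [(0.0, 2.0, False, False)])
    assert full.status == "full" and full.contains(0.0) and full.contains(2.0)
    empty = ConfidenceRegion("Fieller", 0.95, [])
    assert empty.status == "empty" and not empty.contains(1.0)
    point = ConfidenceRegion("Fieller", 0.95, [(1.0, 1.0, False, False)])
    assert point.status == "point" and point.contains(1.0)
    two = ConfidenceRegion(
        "LR", 0.95, [(0.0, 0.4, False, True), (1.6, 2.0, True, False)]
    )
    assert two.status == "discontinuous"
    assert two.contains(0.2) and not two.contains(1.0)
    assert not two.contains(0.4) and not two.contains(1.6)  # open endpoints
    assert str(two) == "[0.0000, 0.4000) U (1.6000, 2.0000]"


# ---------------------------------------------------------------------------
# delta method


def test_delta_ci_hand_example():
    region = delta_ci(_est(0.5, 0.04), alpha=0.05)
    lo, hi, lo_open, hi_open = region.segments[0]
    z = 1.959963984540054
    assert lo == pytest.approx(0.5 - z * 0.2)
    assert hi == pytest.approx(0.5 + z * 0.2)
    assert lo_open and hi_open and region.status == "continuous"


def test_delta_ci_point_and_clipping():
    assert delta_ci(_est(1.0, 0.0)).status == "point"
    clipped = delta_ci(_est(2.0, 4.0))
    assert clipped.segments == [(0.0, 2.0, False, False)]
    assert clipped.status == "full"
    upper = delta_ci(_est(1.8, 0.04))
    lo, hi, _, hi_open = upper.segments[0]
    assert hi == 2.0 and not hi_open and upper.status == "continuous"


# ---------------------------------------------------------------------------
# Fieller cases


def test_fieller_full_when_no_association():
    # tiny coefficients, huge variance: Delta < 0 and A < 0 -> [0, 2]
    region = fieller_ci(_fit(0.01, 0.01, np.eye(2)), alpha=0.05)
    assert region.status == "full"
    assert not region.diagnostics["association_significant"]


def test_fieller_zero_variance_limit_collapses_to_point():
    region = fieller_ci(_fit(0.6, 1.4, 1e-18 * np.eye(2)), alpha=0.05)
    lo, hi, *_ = region.segments[0]
    assert lo == pytest.approx(0.6, abs=1e-6)
    assert hi == pytest.approx(0.6, abs=1e-6)


def test_fieller_discontinuous_case():
    # association absent (beta = 0) but the mid-range of gamma0 strongly
    # rejected: A < 0 with both roots inside [0, 2]
    cov = np.array([[0.09, 0.08], [0.08, 0.09]])
    region = fieller_ci(_fit(0.5, -0.5, cov), alpha=0.05)
    assert region.diagnostics["A"] < 0 < region.diagnostics["discriminant"]
    assert region.status == "discontinuous"
    # truncation endpoints closed, analytic roots open
    (l0, h0, l0o, h0o), (l1, h1, l1o, h1o) = region.segments
    assert l0 == 0.0 and not l0o and h0o
    assert h1 == 2.0 and l1o and not h1o


def test_fieller_matches_grid_inversion(rng):
    """Quadratic endpoints equal dense-grid inversion of the Wald pivot."""
    for _ in range(100):
        s = make_sample(rng, n=150, gamma=rng.uniform(0, 2), p=0.25)
        fit = fit_full(s)
        region = fieller_ci(fit, alpha=0.05)
        # oracle: |Z(gamma0)| < z on a dense grid, straight from the pivot
        grid = np.linspace(0.0, 2.0, 4001)
        c = fit.cov_b1_b2
        beta = 0.5 * (fit.beta1 + fit.beta2)
        var_b = 0.25 * (c[0, 0] + c[1, 1] + 2 * c[0, 1])
        cov_1b = 0.5 * (c[0, 0] + c[0, 1])
        var = c[0, 0] + grid**2 * var_b - 2 * grid * cov_1b
        zval = (fit.beta1 - grid * beta) / np.sqrt(var)
        accepted = np.abs(zval) < sps.norm.ppf(0.975)
        for lo, hi, *_ in region.segments:
            inside = (grid > lo + 5e-4) & (grid < hi - 5e-4)
            assert accepted[inside].all()
        outside = np.ones_like(accepted)
        for lo, hi, *_ in region.segments:
            outside &= ~((grid > lo - 5e-4) & (grid < hi + 5e-4))
        assert not accepted[outside.astype(bool)].any()


# ---------------------------------------------------------------------------
# LR region


def test_lr_ci_full_when_flat(toy_sample):
    # tiny sample: lambda never reaches the chi-square cutoff
    region = lr_ci(toy_sample, alpha=0.05)
    assert region.status == "full"
    assert region.diagnostics["f_at_0"] < 0


def test_lr_one_root_cases(rng):
    """Estimates pinned at a boundary give one-sided regions (gLR, 2] / [0, gLR)."""
    seen = set()
    for _ in range(40):
        s = make_sample(rng, n=400, gamma=rng.choice([0.0, 2.0]), p=0.3)
        region = lr_ci(s, alpha=0.05)
        if len(region.diagnostics["roots"]) != 1:
            continue
        (lo, hi, lo_open, hi_open) = region.segments[0]
        f0, f2 = region.diagnostics["f_at_0"], region.diagnostics["f_at_2"]
        if f0 > 0 > f2:
            assert hi == 2.0 and not hi_open and lo_open
            seen.add("upper")
        elif f0 < 0 < f2:
            assert lo == 0.0 and not lo_open and hi_open
            seen.add("lower")
    assert {"upper", "lower"} <= seen


def test_lr_ci_matches_dense_grid(rng):
    """Region endpoints agree with a 4001-point inversion of the LR test."""
    for _ in range(3):
        s = make_sample(rng, n=300, gamma=1.3, p=0.3)
        full = fit_full(s)
        region = lr_ci(s, alpha=0.05)
        grid = np.linspace(0.0, 2.0, 4001)
        crit = sps.chi2.ppf(0.95, 1)
        from xciskew import lr_stat

        accepted = np.array([lr_stat(s, g0, full=full) < crit for g0 in grid])
        member = np.array([region.contains(g0) for g0 in grid])
        disagreements = grid[accepted != member]
        # disagreement only within grid resolution of an endpoint
        roots = np.array(region.diagnostics["roots"])
        for g0 in disagreements:
            assert roots.size and np.min(np.abs(roots - g0)) < 6e-4


# ---------------------------------------------------------------------------
# cross-method properties


def test_test_ci_duality(rng):
    """gamma0 in the region  <=>  test p-value above alpha (LR and Fieller)."""
    gammas = np.linspace(0.01, 1.99, 23)
    for _ in range(8):
        s = make_sample(rng, n=200, gamma=rng.uniform(0, 2), p=0.3)
        fit = fit_full(s)
        lr_region = lr_ci(s, alpha=0.05, full=fit)
        f_region = fieller_ci(fit, alpha=0.05)
        lr_roots = np.array(lr_region.diagnostics["roots"])
        for g0 in gammas:
            root_dist = np.min(np.abs(lr_roots - g0)) if lr_roots.size else np.inf
            if root_dist > 1e-4:
                assert lr_region.contains(g0) == (
                    lr_test(s, g0, full=fit).pvalue > 0.05
                )
            fl = [abs(g0 - e) for seg in f_region.segments for e in seg[:2]]
            if not fl or min(fl) > 1e-9:
                assert f_region.contains(g0) == (
                    fieller_test(fit, g0).pvalue > 0.05
                )


def test_nested_levels(rng):
    """The 99% region contains the 95% region, for every method."""
    for _ in range(5):
        s = make_sample(rng, n=200, gamma=rng.uniform(0, 2), p=0.3)
        fit = fit_full(s)
        est = estimate_gamma(fit)
        probe = np.linspace(0, 2, 201)
        for narrow, wide in [
            (lr_ci(s, 0.05, full=fit), lr_ci(s, 0.01, full=fit)),
            (fieller_ci(fit, 0.05), fieller_ci(fit, 0.01)),
            (delta_ci(est, 0.05), delta_ci(est, 0.01)),
        ]:
            for g0 in probe:
                if narrow.contains(g0):
                    assert wide.contains(g0)
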