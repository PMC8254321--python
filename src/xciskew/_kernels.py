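"""Vectorized fitting kernels on per-genotype sufficient statistics.

For the no-covariate heteroscedastic three-group normal model the
likelihood depends on the data only through the per-genotype counts
``n_i``, sample means ``ybar_i`` and within-group sums of squares
``ss_i = sum_j (y_ij - ybar_i)^2``.  Every function here operates on
stacked arrays of those statistics with genotype as the trailing axis
of length 3, so a whole batch of Monte-Carlo replicates (and, for the
likelihood-ratio interval, a whole grid of hypothesized gamma values)
is fitted in one shot.

These kernels are private plumbing; the public surface lives in
:mod:`xciskew.model`, :mod:`xciskew.intervals` and
:mod:`xciskew.evaluate`.
"""

from __future__ import annotations

import numpy as np

LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)

#: relative log-likelihood change below which the constrained ascent stops
NULL_FIT_TOL = 1e-10
#: iteration cap for the constrained block-coordinate ascent
NULL_FIT_MAX_ITER = 500


def _mle_sigma2(counts, ss, shared):
    """Per-group MLE variances; ``shared`` pools the two homozygote groups.

    Under the shared structure the dd and DD groups have one common
    variance (XCI inflates only the heterozygote variance), estimated as
    (ss_0 + ss_2) / (n_0 + n_2) and repeated in slots 0 and 2.
    """
    sigma2 = ss / counts
    if shared:
        pooled = (ss[..., 0] + ss[..., 2]) / (counts[..., 0] + counts[..., 2])
        sigma2 = np.stack([pooled, sigma2[..., 1], pooled], axis=-1)
    return sigma2


def full_loglik(counts, means, ss, shared=True):
    """Maximized unconstrained log-likelihood l1, closed form.

    At the MLE the fitted group means are the sample means, so the
    exponential term contributes exactly n/2 whatever the variance
    structure.
    """
    counts = np.asarray(counts, dtype=float)
    n = counts.sum(axis=-1)
    sigma2 = _mle_sigma2(counts, np.asarray(ss, dtype=float), shared)
    return (
        -0.5 * (counts * np.log(sigma2)).sum(axis=-1)
        - 0.5 * n
        - n * LOG_SQRT_2PI
    )


def full_fit(counts, means, ss, shared=True):
    """Closed-form unconstrained MLE for a batch of samples.

    Returns a dict of arrays: regression coefficients ``beta0``,
    ``beta1``, ``beta2``, MLE variances ``sigma2`` (trailing axis 3,
    slots 0 and 2 equal under the shared structure), log-likelihood
    ``loglik`` and the model-information covariance entries ``var_b1``,
    ``var_b2``, ``cov_b1b2`` of (beta1_hat, beta2_hat).
    """
    counts = np.asarray(counts, dtype=float)
    means = np.asarray(means, dtype=float)
    ss = np.asarray(ss, dtype=float)
    sigma2 = _mle_sigma2(counts, ss, shared)
    v = sigma2 / counts  # Var(ybar_i)
    return {
        "beta0": means[..., 0],
        "beta1": means[..., 1] - means[..., 0],
        "beta2": means[..., 2] - means[..., 1],
        "sigma2": sigma2,
        "loglik": full_loglik(counts, means, ss, shared),
        "var_b1": v[..., 0] + v[..., 1],
        "var_b2": v[..., 1] + v[..., 2],
        "cov_b1b2": -v[..., 1],
    }


def null_loglik(counts, means, ss, beta0, beta, gamma0, sigma2):
    """Constrained log-likelihood l0 at arbitrary parameter values."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum(axis=-1)
    code = _genotype_code(gamma0, np.shape(beta0))
    m = beta0[..., None] + code * beta[..., None]
    resid = ss + counts * (means - m) ** 2
    return (
        -0.5 * (counts * np.log(sigma2)).sum(axis=-1)
        - (resid / (2.0 * sigma2)).sum(axis=-1)
        - n * LOG_SQRT_2PI
    )


def _genotype_code(gamma0, shape):
    """Genotypic values (0, gamma0, 2) broadcast to ``shape + (3,)``."""
    g = np.broadcast_to(np.asarray(gamma0, dtype=float), shape)
    code = np.empty(shape + (3,), dtype=float)
    code[..., 0] = 0.0
    code[..., 1] = g
    code[..., 2] = 2.0
    return code


def null_fit(counts, means, ss, gamma0, shared=True, tol=NULL_FIT_TOL,
             max_iter=NULL_FIT_MAX_ITER):
    """Constrained MLE under gamma = gamma0 by block coordinate ascent.

    Alternates a weighted least-squares update of (beta0, beta) at the
    current variances (weights n_i / sigma_i^2) with the closed-form
    variance update — per group ``sigma_i^2 = ss_i/n_i + (ybar_i - m_i)^2``,
    with the homozygote slots pooled when ``shared`` — at the current
    means.  Both steps are exact blockwise maximizations, so the
    log-likelihood ascends monotonically.

    ``gamma0`` broadcasts against the batch shape of the statistics.
    Returns a dict of arrays ``beta0, beta, sigma2, loglik, converged,
    iterations``.
    """
    counts = np.asarray(counts, dtype=float)
    means = np.asarray(means, dtype=float)
    ss = np.asarray(ss, dtype=float)
    shape = np.broadcast_shapes(counts.shape[:-1], np.shape(gamma0))
    counts = np.broadcast_to(counts, shape + (3,))
    means = np.broadcast_to(means, shape + (3,))
    ss = np.broadcast_to(ss, shape + (3,))
    code = _genotype_code(gamma0, shape)

    n = counts.sum(axis=-1)
    base = ss / counts
    sigma2 = _mle_sigma2(counts, ss, shared)
    loglik = np.full(shape, -np.inf)
    converged = np.zeros(shape, dtype=bool)
    iterations = 0
    beta0 = np.zeros(shape)
    beta = np.zeros(shape)
    const = -0.5 * n - n * LOG_SQRT_2PI
    for iterations in range(1, max_iter + 1):
        w = counts / sigma2
        sw = w.sum(axis=-1)
        swc = (w * code).sum(axis=-1)
        swcc = (w * code * code).sum(axis=-1)
        swy = (w * means).sum(axis=-1)
        swcy = (w * code * means).sum(axis=-1)
        det = sw * swcc - swc * swc
        beta = (sw * swcy - swc * swy) / det
        beta0 = (swy - swc * beta) / sw
        m = beta0[..., None] + code * beta[..., None]
        resid = ss + counts * (means - m) ** 2
        if shared:
            pooled = (resid[..., 0] + resid[..., 2]) / (
                counts[..., 0] + counts[..., 2]
            )
            sigma2 = np.stack(
                [pooled, resid[..., 1] / counts[..., 1], pooled], axis=-1
            )
        else:
            sigma2 = base + (means - m) ** 2
        # after the exact variance update the exponent contributes n/2
        new_ll = -0.5 * (counts * np.log(sigma2)).sum(axis=-1) + const
        converged = np.abs(new_ll - loglik) <= tol * (np.abs(new_ll) + 1.0)
        loglik = new_ll
        if converged.all():
            break
    return {
        "beta0": beta0,
        "beta": beta,
        "sigma2": sigma2,
        "loglik": loglik,
        "converged": converged,
        "iterations": iterations,
    }


def lr_stat(counts, means, ss, gamma0, full_ll=None, shared=True, **kwargs):
    """Likelihood-ratio statistic lambda(gamma0) = 2 (l1 - l0), clipped at 0."""
    if full_ll is None:
        full_ll = full_loglik(counts, means, ss, shared)
    nf = null_fit(counts, means, ss, gamma0, shared=shared, **kwargs)
    lam = 2.0 * (np.asarray(full_ll) - nf["loglik"])
    return np.maximum(lam, 0.0), nf


def fieller_coefficients(beta1, beta2, var_b1, var_b2, cov_b1b2, z):
    """Quadratic coefficients A, B, C of Fieller's equation in gamma0.

    Uses beta = (beta1+beta2)/2 with Var(beta) and Cov(beta1, beta) derived
    from the covariance of (beta1_hat, beta2_hat).
    """
    beta = 0.5 * (beta1 + beta2)
    var_b = 0.25 * (var_b1 + var_b2 + 2.0 * cov_b1b2)
    cov_1b = 0.5 * (var_b1 + cov_b1b2)
    z2 = z * z
    a = beta * beta - z2 * var_b
    b = 2.0 * z2 * cov_1b - 2.0 * beta1 * beta
    c = beta1 * beta1 - z2 * var_b1
    return a, b, c


def delta_variance(beta1, beta2, var_b1, var_b2, cov_b1b2):
    """Plug-in first-order error-propagation variance of gamma_hat."""
    beta = 0.5 * (beta1 + beta2)
    var_b = 0.25 * (var_b1 + var_b2 + 2.0 * cov_b1b2)
    cov_1b = 0.5 * (var_b1 + cov_b1b2)
    b2 = beta * beta
    return (
        var_b1 / b2
        + beta1 * beta1 * var_b / (b2 * b2)
        - 2.0 * beta1 * cov_1b / (b2 * beta)
    )
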