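"""Heteroscedastic three-genotype normal model for X-linked quantitative traits.

In a sample of unrelated females at a diallelic X-linked locus, the trait
is modelled as normal within each genotype group with its own variance:

    Y | dd ~ N(beta0 + b'z,                   sigma0^2)
    Y | Dd ~ N(beta0 + beta1 + b'z,           sigma1^2)
    Y | DD ~ N(beta0 + beta1 + beta2 + b'z,   sigma2^2)

where D is the caller-declared focal (mutant) allele and the genotype code
counts copies of D.  X-inactivation skewing shows up both in where the
heterozygote mean sits between the homozygote means and in an inflated
heterozygote variance.  Two variance structures are supported:
``"shared"`` (default) estimates one common variance for the two
homozygote groups — inactivation noise inflates only the heterozygote
variance, and pooling keeps inference calibrated when the rarer
homozygote group is small — while ``"free"`` gives every genotype its
own variance.

The primary surface is :class:`XCISkewModel` (construct from arrays or a
DataFrame) whose :meth:`XCISkewModel.fit` returns :class:`XCISkewResults`
carrying the estimates, their covariance, the skewness measure gamma and
its confidence regions.  The module-level functions ``group_stats``,
``loglik_full``, ``fit_full``, ``fit_null`` and ``lr_stat`` expose the same
computations functionally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import _kernels

logger = logging.getLogger(__name__)

__all__ = [
    "QuantSample",
    "GroupStats",
    "FullFit",
    "NullFit",
    "XCISkewModel",
    "XCISkewResults",
    "DegenerateGroupError",
    "ConvergenceError",
    "group_stats",
    "loglik_full",
    "fit_full",
    "fit_null",
    "lr_stat",
]


class DegenerateGroupError(ValueError):
    """A genotype group is empty/too small or has zero within-group variance.

    The heteroscedastic likelihood is unbounded (sigma_i -> 0) or gamma is
    undefined in these cases; the fit refuses rather than regularizing.
    """


class ConvergenceError(RuntimeError):
    """An iterative fit did not converge within its iteration cap."""


@dataclass(frozen=True)
class QuantSample:
    """Per-female trait values, genotype codes and optional covariates.

    Parameters
    ----------
    trait : array of float, shape (n,)
        Quantitative trait values; must all be finite.
    genotype : array of int, shape (n,)
        Count of the focal allele D: 0 (dd), 1 (Dd), 2 (DD).
    covariates : array of float, shape (n, c), optional
        Adjustment covariates (the z vector per subject).
    focal_allele : str
        Label of the counted allele; gamma's direction (towards/against D)
        depends on this orientation, which is the caller's responsibility.
    """

    trait: np.ndarray
    genotype: np.ndarray
    covariates: Optional[np.ndarray] = None
    focal_allele: str = "D"

    def __post_init__(self):
        y = np.asarray(self.trait, dtype=float)
        g = np.asarray(self.genotype)
        if y.ndim != 1 or g.shape != y.shape:
            raise ValueError("trait and genotype must be 1-d arrays of equal length")
        if y.size == 0:
            raise ValueError("empty sample")
        if not np.all(np.isfinite(y)):
            raise ValueError("trait values must be finite")
        if not np.isin(g, (0, 1, 2)).all():
            bad = np.unique(g[~np.isin(g, (0, 1, 2))])
            raise ValueError(f"genotype codes must be 0/1/2, found {bad.tolist()}")
        g = g.astype(np.int64)
        z = self.covariates
        if z is not None:
            z = np.asarray(z, dtype=float)
            if z.ndim == 1:
                z = z[:, None]
            if z.shape[0] != y.size:
                raise ValueError("covariates must have one row per subject")
            if not np.all(np.isfinite(z)):
                raise ValueError("covariate values must be finite")
        object.__setattr__(self, "trait", y)
        object.__setattr__(self, "genotype", g)
        object.__setattr__(self, "covariates", z)
        logger.debug(
            "QuantSample: n=%d, counted allele %r", y.size, self.focal_allele
        )

    @property
    def n(self) -> int:
        return self.trait.size

    @property
    def n_covariates(self) -> int:
        return 0 if self.covariates is None else self.covariates.shape[1]

    def group_counts(self) -> np.ndarray:
        return np.bincount(self.genotype, minlength=3)[:3]


@dataclass(frozen=True)
class GroupStats:
    """Per-genotype counts, means and MLE variances (divisor n_i)."""

    counts: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    ss: np.ndarray  # within-group sums of squared deviations

    @property
    def empty_groups(self) -> np.ndarray:
        """Indices of genotype groups with no observations."""
        return np.flatnonzero(self.counts == 0)


@dataclass(frozen=True)
class FullFit:
    """Unconstrained maximum-likelihood fit of the three-group model.

    ``sigma0 == sigma2`` when fitted with the shared homozygote-variance
    structure.
    """

    beta0: float
    beta1: float
    beta2: float
    b: Optional[np.ndarray]
    sigma0: float
    sigma1: float
    sigma2: float
    loglik: float
    cov_b1_b2: np.ndarray  # 2x2 covariance of (beta1_hat, beta2_hat)
    converged: bool = True
    iterations: int = 0
    cov_type: str = "mle"
    variance_structure: str = "shared"

    @property
    def sigma(self) -> np.ndarray:
        return np.array([self.sigma0, self.sigma1, self.sigma2])

    @property
    def group_means(self) -> np.ndarray:
        """Fitted genotype means at covariates = 0."""
        return np.array(
            [self.beta0, self.beta0 + self.beta1, self.beta0 + self.beta1 + self.beta2]
        )


@dataclass(frozen=True)
class NullFit:
    """Constrained MLE under H0: gamma = gamma0 (means beta0 + (0, gamma0, 2) beta)."""

    gamma0: float
    beta0: float
    beta: float
    b: Optional[np.ndarray]
    sigma0: float
    sigma1: float
    sigma2: float
    loglik: float
    converged: bool = True
    iterations: int = 0
    variance_structure: str = "shared"

    @property
    def sigma(self) -> np.ndarray:
        return np.array([self.sigma0, self.sigma1, self.sigma2])


def group_stats(sample: QuantSample) -> GroupStats:
    """Per-genotype counts, sample means and MLE variances (divisor n_i).

    Groups with ``n_i = 0`` get NaN mean/variance and are flagged via
    :attr:`GroupStats.empty_groups`.
    """
    g = sample.genotype
    y = sample.trait
    counts = np.bincount(g, minlength=3)[:3]
    sums = np.bincount(g, weights=y, minlength=3)[:3]
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        dev = y - means[g]
        ss = np.bincount(g, weights=dev * dev, minlength=3)[:3]
        variances = np.where(counts > 0, ss / np.maximum(counts, 1), np.nan)
    if counts.sum() == 0:
        raise ValueError("empty sample")
    return GroupStats(counts=counts, means=means, variances=variances, ss=ss)


def loglik_full(
    sample: QuantSample,
    beta0: float,
    beta1: float,
    beta2: float,
    sigma0: float,
    sigma1: float,
    sigma2: float,
    b: Optional[Sequence[float]] = None,
) -> float:
    """Unconstrained log-likelihood l1 at arbitrary parameter values.

    Includes the -n log(sqrt(2 pi)) constant, so it is the exact sum of
    normal log-densities.
    """
    sigma = np.array([sigma0, sigma1, sigma2], dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("sigma_i must be positive")
    mean_by_group = np.array([beta0, beta0 + beta1, beta0 + beta1 + beta2])
    mu = mean_by_group[sample.genotype]
    if sample.covariates is not None:
        if b is None:
            raise ValueError("sample has covariates: b is required")
        mu = mu + sample.covariates @ np.asarray(b, dtype=float)
    elif b is not None and len(np.atleast_1d(b)) > 0:
        raise ValueError("b given but sample has no covariates")
    s = sigma[sample.genotype]
    resid = sample.trait - mu
    return float(
        -np.log(s).sum()
        - 0.5 * np.sum(resid * resid / (s * s))
        - sample.n * _kernels.LOG_SQRT_2PI
    )


def _loglik_null(sample, gamma0, beta0, beta, sigma, b=None):
    code = np.array([0.0, gamma0, 2.0])
    mu = beta0 + code[sample.genotype] * beta
    if sample.covariates is not None:
        mu = mu + sample.covariates @ np.asarray(b, dtype=float)
    s = np.asarray(sigma, dtype=float)[sample.genotype]
    resid = sample.trait - mu
    return float(
        -np.log(s).sum()
        - 0.5 * np.sum(resid * resid / (s * s))
        - sample.n * _kernels.LOG_SQRT_2PI
    )


def _check_groups(sample: QuantSample, stats: GroupStats) -> None:
    min_n = 2 + sample.n_covariates
    if np.any(stats.counts < min_n):
        raise DegenerateGroupError(
            f"each genotype group needs at least {min_n} females, got "
            f"counts {stats.counts.tolist()}"
        )
    if np.any(stats.ss <= 0):
        raise DegenerateGroupError(
            "a genotype group has zero within-group variance; the "
            "heteroscedastic likelihood is unbounded"
        )


def _wls_solve(design, y, weights):
    xtw = design.T * weights
    xtwx = xtw @ design
    coef = np.linalg.solve(xtwx, xtw @ y)
    return coef, xtwx


def _pool_sigma2(resid_ss, counts, shared):
    sigma2 = resid_ss / counts
    if shared:
        pooled = (resid_ss[0] + resid_ss[2]) / (counts[0] + counts[2])
        sigma2 = np.array([pooled, sigma2[1], pooled])
    return sigma2


def _iterative_fit(sample, design, group_of_row, shared, tol, max_iter):
    """Block coordinate ascent for an arbitrary mean design.

    WLS update of the mean coefficients at current variances, closed-form
    per-group variance update at current means (homozygote groups pooled
    when ``shared``).  Returns (coef, sigma2, loglik, converged,
    iterations, xtwx).
    """
    y = sample.trait
    counts = np.bincount(group_of_row, minlength=3)[:3].astype(float)
    # initialize at the homoscedastic fit with per-group residual variances
    coef = np.linalg.lstsq(design, y, rcond=None)[0]
    resid = y - design @ coef
    rss = np.bincount(group_of_row, weights=resid * resid, minlength=3)[:3]
    sigma2 = _pool_sigma2(rss, counts, shared)
    if np.any(sigma2 <= 0):
        raise DegenerateGroupError("zero residual variance in a genotype group")
    prev = -np.inf
    converged = False
    iterations = 0
    xtwx = None
    for iterations in range(1, max_iter + 1):
        weights = 1.0 / sigma2[group_of_row]
        coef, xtwx = _wls_solve(design, y, weights)
        resid = y - design @ coef
        rss = np.bincount(group_of_row, weights=resid * resid, minlength=3)[:3]
        sigma2 = _pool_sigma2(rss, counts, shared)
        ll = float(
            -0.5 * (counts * np.log(sigma2)).sum()
            - (rss / (2.0 * sigma2)).sum()
            - sample.n * _kernels.LOG_SQRT_2PI
        )
        if abs(ll - prev) <= tol * (abs(ll) + 1.0):
            converged = True
            prev = ll
            break
        prev = ll
    return coef, sigma2, prev, converged, iterations, xtwx


def _ols_cov_b1_b2(sample: QuantSample) -> np.ndarray:
    """Homoscedastic OLS covariance of (beta1_hat, beta2_hat).

    Reproduces the covariance a Gaussian GLM reports (dispersion
    RSS/(n-p)), for fidelity checks against analyses that ignored the
    variance heterogeneity.
    """
    import statsmodels.api as sm

    x1 = (sample.genotype >= 1).astype(float)
    x2 = (sample.genotype == 2).astype(float)
    cols = [np.ones(sample.n), x1, x2]
    if sample.covariates is not None:
        cols.extend(sample.covariates.T)
    design = np.column_stack(cols)
    res = sm.OLS(sample.trait, design).fit()
    return np.asarray(res.cov_params())[1:3, 1:3]


def _check_structure(variance_structure: str) -> bool:
    if variance_structure not in ("shared", "free"):
        raise ValueError("variance_structure must be 'shared' or 'free'")
    return variance_structure == "shared"


def fit_full(
    sample: QuantSample,
    cov: str = "mle",
    variance_structure: str = "shared",
    tol: float = _kernels.NULL_FIT_TOL,
    max_iter: int = _kernels.NULL_FIT_MAX_ITER,
) -> FullFit:
    """Unconstrained MLE of the heteroscedastic three-group model.

    Without covariates the MLE is closed form (group means; MLE group
    variances, the homozygote pair pooled under the default ``"shared"``
    structure); with covariates the likelihood is maximized by block
    coordinate ascent.  ``cov`` selects the covariance of
    (beta1_hat, beta2_hat): ``"mle"`` (default) uses the model's
    information, ``"ols"`` the homoscedastic OLS formula.
    """
    shared = _check_structure(variance_structure)
    stats = group_stats(sample)
    _check_groups(sample, stats)
    if sample.covariates is None:
        k = _kernels.full_fit(
            stats.counts[None, :], stats.means[None, :], stats.ss[None, :],
            shared=shared,
        )
        v = k["sigma2"][0] / stats.counts
        cov_mle = np.array(
            [[v[0] + v[1], -v[1]], [-v[1], v[1] + v[2]]]
        )
        fit = FullFit(
            beta0=float(k["beta0"][0]),
            beta1=float(k["beta1"][0]),
            beta2=float(k["beta2"][0]),
            b=None,
            sigma0=float(np.sqrt(k["sigma2"][0, 0])),
            sigma1=float(np.sqrt(k["sigma2"][0, 1])),
            sigma2=float(np.sqrt(k["sigma2"][0, 2])),
            loglik=float(k["loglik"][0]),
            cov_b1_b2=cov_mle if cov == "mle" else _ols_cov_b1_b2(sample),
            converged=True,
            iterations=0,
            cov_type=cov,
            variance_structure=variance_structure,
        )
        return fit
    x1 = (sample.genotype >= 1).astype(float)
    x2 = (sample.genotype == 2).astype(float)
    design = np.column_stack(
        [np.ones(sample.n), x1, x2] + list(sample.covariates.T)
    )
    coef, sigma2, ll, converged, iters, xtwx = _iterative_fit(
        sample, design, sample.genotype, shared, tol, max_iter
    )
    if not converged:
        raise ConvergenceError(f"full fit did not converge in {max_iter} iterations")
    cov_full = np.linalg.inv(xtwx)
    cov_b = cov_full[1:3, 1:3] if cov == "mle" else _ols_cov_b1_b2(sample)
    return FullFit(
        beta0=float(coef[0]),
        beta1=float(coef[1]),
        beta2=float(coef[2]),
        b=coef[3:].copy(),
        sigma0=float(np.sqrt(sigma2[0])),
        sigma1=float(np.sqrt(sigma2[1])),
        sigma2=float(np.sqrt(sigma2[2])),
        loglik=ll,
        cov_b1_b2=cov_b,
        converged=converged,
        iterations=iters,
        cov_type=cov,
        variance_structure=variance_structure,
    )


def fit_null(
    sample: QuantSample,
    gamma0: float,
    variance_structure: str = "shared",
    tol: float = _kernels.NULL_FIT_TOL,
    max_iter: int = _kernels.NULL_FIT_MAX_ITER,
) -> NullFit:
    """Constrained MLE under H0: gamma = gamma0 by block coordinate ascent.

    The genotype means are restricted to beta0 + (0, gamma0, 2) beta; the
    weighted least-squares step uses weights 1/sigma_i^2 and the variance
    step is the closed-form per-group update.  Non-convergence within the
    iteration cap raises :class:`ConvergenceError`.
    """
    if not 0.0 <= gamma0 <= 2.0:
        raise ValueError("gamma0 must lie in [0, 2]")
    shared = _check_structure(variance_structure)
    stats = group_stats(sample)
    _check_groups(sample, stats)
    if sample.covariates is None:
        k = _kernels.null_fit(
            stats.counts[None, :],
            stats.means[None, :],
            stats.ss[None, :],
            np.array([gamma0]),
            shared=shared,
            tol=tol,
            max_iter=max_iter,
        )
        if not bool(k["converged"][0]):
            raise ConvergenceError(
                f"null fit at gamma0={gamma0} did not converge in {max_iter} iterations"
            )
        s2 = k["sigma2"][0]
        return NullFit(
            gamma0=gamma0,
            beta0=float(k["beta0"][0]),
            beta=float(k["beta"][0]),
            b=None,
            sigma0=float(np.sqrt(s2[0])),
            sigma1=float(np.sqrt(s2[1])),
            sigma2=float(np.sqrt(s2[2])),
            loglik=float(k["loglik"][0]),
            converged=True,
            iterations=int(k["iterations"]),
            variance_structure=variance_structure,
        )
    code = np.array([0.0, gamma0, 2.0])
    design = np.column_stack(
        [np.ones(sample.n), code[sample.genotype]] + list(sample.covariates.T)
    )
    coef, sigma2, ll, converged, iters, _ = _iterative_fit(
        sample, design, sample.genotype, shared, tol, max_iter
    )
    if not converged:
        raise ConvergenceError(
            f"null fit at gamma0={gamma0} did not converge in {max_iter} iterations"
        )
    return NullFit(
        gamma0=gamma0,
        beta0=float(coef[0]),
        beta=float(coef[1]),
        b=coef[2:].copy(),
        sigma0=float(np.sqrt(sigma2[0])),
        sigma1=float(np.sqrt(sigma2[1])),
        sigma2=float(np.sqrt(sigma2[2])),
        loglik=ll,
        converged=converged,
        iterations=iters,
        variance_structure=variance_structure,
    )


def lr_stat(
    sample: QuantSample,
    gamma0: float,
    full: Optional[FullFit] = None,
    null: Optional[NullFit] = None,
    variance_structure: str = "shared",
) -> float:
    """Likelihood-ratio statistic lambda(gamma0) = 2 (l1 - l0) >= 0.

    Asymptotically chi-square with one degree of freedom under H0.
    Tiny negative values from finite-precision fits are clipped to zero;
    anything below -1e-8 raises.
    """
    if full is None:
        full = fit_full(sample, variance_structure=variance_structure)
    else:
        variance_structure = full.variance_structure
    if null is None:
        null = fit_null(sample, gamma0, variance_structure=variance_structure)
    elif null.variance_structure != full.variance_structure:
        raise ValueError("full and null fits use different variance structures")
    lam = 2.0 * (full.loglik - null.loglik)
    if lam < -1e-8:
        raise RuntimeError(f"negative LR statistic {lam}; fits inconsistent")
    return max(lam, 0.0)


class XCISkewModel:
    """Model of skewed X-chromosome inactivation for a quantitative trait.

    Wraps a :class:`QuantSample`; :meth:`fit` performs the heteroscedastic
    maximum-likelihood fit and returns :class:`XCISkewResults` with the
    skewness measure gamma, its variance and confidence-region methods.

    Examples
    --------
    >>> import numpy as np
    >>> from xciskew import XCISkewModel
    >>> rng = np.random.default_rng(0)
    >>> g = rng.integers(0, 3, 500)
    >>> y = [0.0, 0.45, 0.6][0] + np.take([0.0, 0.45, 0.6], g) + rng.normal(size=500)
    >>> res = XCISkewModel(y, g).fit()
    >>> 0 <= res.gamma <= 2
    True
    """

    def __init__(self, trait, genotype, covariates=None, focal_allele="D"):
        self.sample = QuantSample(trait, genotype, covariates, focal_allele)

    @classmethod
    def from_dataframe(cls, df, trait, genotype="genotype", covariates=None,
                       focal_allele="D"):
        """Build the model from DataFrame columns."""
        z = None if not covariates else df[list(covariates)].to_numpy(float)
        return cls(
            df[trait].to_numpy(float),
            df[genotype].to_numpy(),
            covariates=z,
            focal_allele=focal_allele,
        )

    def loglike(self, beta0, beta1, beta2, sigma0, sigma1, sigma2, b=None):
        return loglik_full(self.sample, beta0, beta1, beta2, sigma0, sigma1,
                           sigma2, b=b)

    def fit(self, cov: str = "mle",
            variance_structure: str = "shared") -> "XCISkewResults":
        return XCISkewResults(
            self,
            fit_full(self.sample, cov=cov, variance_structure=variance_structure),
        )

    def fit_null(self, gamma0: float,
                 variance_structure: str = "shared") -> NullFit:
        return fit_null(self.sample, gamma0,
                        variance_structure=variance_structure)


@dataclass
class XCISkewResults:
    """Results of the heteroscedastic fit: estimates, gamma and inference.

    Attributes of note: ``gamma`` (truncated point estimate in [0, 2]),
    ``gamma_raw`` (untruncated ratio), ``theta`` (= gamma/2, average
    proportion of heterozygote cells keeping the focal allele active),
    ``var_gamma`` (first-order error-propagation variance).
    """

    model: XCISkewModel
    fullfit: FullFit
    _estimate: object = field(default=None, repr=False)

    @property
    def params(self) -> dict:
        f = self.fullfit
        out = {"beta0": f.beta0, "beta1": f.beta1, "beta2": f.beta2}
        if f.b is not None:
            out["b"] = f.b
        return out

    @property
    def llf(self) -> float:
        return self.fullfit.loglik

    @property
    def estimate(self):
        if self._estimate is None:
            from .estimate import estimate_gamma

            self._estimate = estimate_gamma(self.fullfit)
        return self._estimate

    @property
    def gamma(self) -> float:
        return self.estimate.gamma_hat

    @property
    def gamma_raw(self) -> float:
        return self.estimate.gamma_raw

    @property
    def theta(self) -> float:
        return self.estimate.theta_hat

    @property
    def var_gamma(self) -> float:
        return self.estimate.var_delta

    def conf_int(self, alpha: float = 0.05, method: str = "fieller"):
        """Confidence region for gamma by one of the three constructions."""
        from . import intervals

        if method == "lr":
            return intervals.lr_ci(self.model.sample, alpha)
        if method == "fieller":
            return intervals.fieller_ci(self.fullfit, alpha)
        if method == "delta":
            return intervals.delta_ci(self.estimate, alpha)
        raise ValueError(f"unknown method {method!r}")

    def conf_int_all(self, alpha: float = 0.05) -> dict:
        return {m: self.conf_int(alpha, m) for m in ("lr", "fieller", "delta")}

    def test_gamma(self, gamma0: float, method: str = "lr"):
        """Test H0: gamma = gamma0 (LR, Fieller-Wald or delta-Wald)."""
        from . import hypotheses

        if method == "lr":
            return hypotheses.lr_test(self.model.sample, gamma0, full=self.fullfit)
        if method == "fieller":
            return hypotheses.fieller_test(self.fullfit, gamma0)
        if method == "delta":
            return hypotheses.delta_test(self.estimate, gamma0)
        raise ValueError(f"unknown method {method!r}")

    def summary(self, alpha: float = 0.05) -> str:
        """Plain-text summary of the fit and the three confidence regions."""
        f = self.fullfit
        e = self.estimate
        lines = [
            "Skewed X-inactivation model (heteroscedastic 3-genotype normal)",
            f"  n = {self.model.sample.n}   counted allele = "
            f"{self.model.sample.focal_allele!r}   cov = {f.cov_type}",
            f"  beta0 = {f.beta0: .4f}  beta1 = {f.beta1: .4f}  "
            f"beta2 = {f.beta2: .4f}",
            f"  sigma = ({f.sigma0:.4f}, {f.sigma1:.4f}, {f.sigma2:.4f})"
            f"   loglik = {f.loglik:.3f}",
            f"  gamma_hat = {e.gamma_hat:.4f} (raw {e.gamma_raw:.4f}), "
            f"theta_hat = {e.theta_hat:.4f}, Var_delta = {e.var_delta:.5f}",
            f"  {100 * (1 - alpha):.0f}% confidence regions:",
        ]
        for m, region in self.conf_int_all(alpha).items():
            lines.append(f"    {m:>7}: {region} [{region.status}]")
        return "\n".join(lines)
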