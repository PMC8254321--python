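"""Hypothesis tests: H0 gamma = gamma0, plus the scan prescreen statistics.

The three tests of H0: gamma = gamma0 mirror the three interval
constructions: the likelihood-ratio statistic (chi-square, 1 df), the
Fieller-Wald pivot for beta1 - gamma0 * beta (standard normal), and the
delta-Wald statistic for the truncated estimate (standard normal; known to
be mis-calibrated — inflated or conservative depending on gamma0).

The prescreen statistics used by the per-SNP scan are also here: Levene's
association/variance-heterogeneity test, the exact Hardy-Weinberg
equilibrium test and the minor-allele frequency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats as sps

from .estimate import GammaEstimate
from .model import FullFit, NullFit, QuantSample, fit_full, fit_null, lr_stat

__all__ = [
    "TestResult",
    "lr_test",
    "fieller_test",
    "delta_test",
    "levene_test",
    "hwe_test",
    "maf",
]


@dataclass(frozen=True)
class TestResult:
    """Statistic, p-value and reference distribution of one test."""

    statistic: float
    pvalue: float
    null_distribution: str  # "chi2_df1", "std_normal" or "f"
    method: str
    gamma0: Optional[float] = None

    def __str__(self):
        g = "" if self.gamma0 is None else f" (gamma0={self.gamma0})"
        return f"{self.method}{g}: stat={self.statistic:.4f}, p={self.pvalue:.4g}"


def lr_test(
    sample: QuantSample,
    gamma0: float,
    full: Optional[FullFit] = None,
    null: Optional[NullFit] = None,
) -> TestResult:
    """Likelihood-ratio test of H0: gamma = gamma0 (chi-square, 1 df)."""
    lam = lr_stat(sample, gamma0, full=full, null=null)
    return TestResult(
        statistic=lam,
        pvalue=float(sps.chi2.sf(lam, 1)),
        null_distribution="chi2_df1",
        method="LR",
        gamma0=gamma0,
    )


def _fieller_pieces(fit: FullFit):
    cov = fit.cov_b1_b2
    var_b1 = float(cov[0, 0])
    var_b = float(0.25 * (cov[0, 0] + cov[1, 1] + 2.0 * cov[0, 1]))
    cov_1b = float(0.5 * (cov[0, 0] + cov[0, 1]))
    beta = 0.5 * (fit.beta1 + fit.beta2)
    return beta, var_b1, var_b, cov_1b


def fieller_test(fit: FullFit, gamma0: float) -> TestResult:
    """Wald test of H0: beta1 = gamma0 * beta (standard normal)."""
    beta, var_b1, var_b, cov_1b = _fieller_pieces(fit)
    var = var_b1 + gamma0 * gamma0 * var_b - 2.0 * gamma0 * cov_1b
    if var <= 0:
        raise ValueError(f"nonpositive variance term {var} in Fieller test")
    z = (fit.beta1 - gamma0 * beta) / math.sqrt(var)
    return TestResult(
        statistic=float(z),
        pvalue=float(2.0 * sps.norm.sf(abs(z))),
        null_distribution="std_normal",
        method="Fieller",
        gamma0=gamma0,
    )


def delta_test(
    est: GammaEstimate, gamma0: float, truncated: bool = True
) -> TestResult:
    """Wald test of H0: gamma = gamma0 from the delta-method variance.

    Uses the [0, 2]-truncated estimate by default (``truncated=False``
    switches to the raw ratio).  The truncation breaks the normal
    approximation, so this test is anti-conservative or conservative
    depending on gamma0; it is provided for completeness.
    """
    if est.var_delta <= 0:
        raise ValueError("delta variance must be positive")
    g = est.gamma_hat if truncated else est.gamma_raw
    z = (g - gamma0) / math.sqrt(est.var_delta)
    return TestResult(
        statistic=float(z),
        pvalue=float(2.0 * sps.norm.sf(abs(z))),
        null_distribution="std_normal",
        method="delta",
        gamma0=gamma0,
    )


def levene_test(values, groups, center: str = "mean") -> TestResult:
    """Levene's one-way test on absolute deviations from the group center.

    ``center="mean"`` is the classical Levene statistic (robust for
    non-normal but symmetric data); ``center="median"`` gives the
    Brown-Forsythe variant.  Used as the association prescreen in the
    per-SNP scan, following its use as a variance-heterogeneity detector
    for X-linked loci.
    """
    if center not in ("mean", "median"):
        raise ValueError("center must be 'mean' or 'median'")
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    arrays = [values[groups == g] for g in np.unique(groups)]
    arrays = [a for a in arrays if a.size >= 2]
    if len(arrays) < 2:
        raise ValueError("Levene's test needs >= 2 groups with >= 2 members")
    stat, p = sps.levene(*arrays, center=center)
    return TestResult(
        statistic=float(stat),
        pvalue=float(p),
        null_distribution="f",
        method=f"levene_{center}",
    )


def hwe_test(n_dd: int, n_Dd: int, n_DD: int) -> float:
    """Exact Hardy-Weinberg equilibrium test for one diallelic locus.

    Conditions on the observed allele counts and enumerates every
    heterozygote count of the same parity; the p-value is the sum of the
    conditional probabilities not exceeding that of the observed count
    (plain exact p, no mid-p correction), as in standard GWAS toolkits.
    """
    counts = (int(n_dd), int(n_Dd), int(n_DD))
    if any(c < 0 for c in counts):
        raise ValueError("genotype counts must be nonnegative")
    n = sum(counts)
    if n < 1:
        raise ValueError("total genotype count must be >= 1")
    n_het = counts[1]
    rare = 2 * min(counts[0], counts[2]) + n_het  # minor-allele copies
    # log-probabilities over feasible heterozygote counts (same parity as rare)
    hets = range(rare % 2, rare + 1, 2)
    logprobs = {}
    for h in hets:
        hom_rare = (rare - h) // 2
        hom_common = n - h - hom_rare
        if hom_common < 0:
            continue
        logprobs[h] = (
            math.lgamma(n + 1)
            - math.lgamma(hom_rare + 1)
            - math.lgamma(h + 1)
            - math.lgamma(hom_common + 1)
            + h * math.log(2.0)
            + math.lgamma(rare + 1)
            + math.lgamma(2 * n - rare + 1)
            - math.lgamma(2 * n + 1)
        )
    if not logprobs:  # monomorphic locus
        return 1.0
    obs = logprobs[n_het]
    total = sum(
        math.exp(lp) for lp in logprobs.values() if lp <= obs + 1e-12
    )
    return float(min(total, 1.0))


def maf(genotypes) -> float:
    """Minor allele frequency over nonmissing 0/1/2 genotype codes."""
    g = np.asarray(genotypes, dtype=float)
    g = g[~np.isnan(g)]
    if g.size == 0:
        raise ValueError("all genotypes missing")
    p = g.sum() / (2.0 * g.size)
    return float(min(p, 1.0 - p))
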