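"""Generative model for the Monte-Carlo evaluation of the gamma methods.

Female genotypes at a diallelic X-linked locus are drawn with frequencies

    g0 = q^2 + rho p q,   g1 = 2 (1 - rho) p q,   g2 = p^2 + rho p q,

where p is the focal-allele frequency and rho the inbreeding coefficient
(rho = 0 is Hardy-Weinberg equilibrium).  Conditional on genotype the
trait is normal with means (beta0, beta0 + gamma*beta, beta0 + 2*beta)
and variances (sigma0^2, sigma1^2, sigma2^2), where the heterozygote
variance is inflated by inactivation noise:

    sigma1^2 = theta (1 - theta) a^2 + base_var,   theta = gamma / 2,

with additive effect a and residual variance base_var.  Defaults are the
study conditions of the evaluation grid: beta0 = 0.1, beta = 0.3,
sigma0^2 = sigma2^2 = 1, base_var = 1.1, K = 10,000 replicates at the 5%
level.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .model import QuantSample

__all__ = [
    "SimScenario",
    "genotype_freqs",
    "sigma1_sq",
    "simulate_sample",
    "simulate_group_stats",
    "scenario_grid",
]

#: residual variance of the heterozygote group not attributable to the QTL
BASE_VAR = 1.1


def genotype_freqs(p: float, rho: float = 0.0):
    """Female genotype frequencies (g0, g1, g2) under inbreeding.

    Requires all three frequencies to be nonnegative, which constrains
    rho >= -min(p/q, q/p); the three always sum to one.
    """
    if not 0.0 < p < 1.0:
        raise ValueError("allele frequency p must lie in (0, 1)")
    q = 1.0 - p
    g0 = q * q + rho * p * q
    g1 = 2.0 * (1.0 - rho) * p * q
    g2 = p * p + rho * p * q
    if min(g0, g1, g2) < 0.0:
        raise ValueError(
            f"negative genotype frequency for p={p}, rho={rho}: "
            f"({g0:.4g}, {g1:.4g}, {g2:.4g})"
        )
    return g0, g1, g2


def sigma1_sq(gamma: float, a: float, base_var: float = BASE_VAR) -> float:
    """Heterozygote trait variance theta(1-theta) a^2 + base_var, theta = gamma/2."""
    if not 0.0 <= gamma <= 2.0:
        raise ValueError("gamma must lie in [0, 2]")
    theta = gamma / 2.0
    return theta * (1.0 - theta) * a * a + base_var


@dataclass(frozen=True)
class SimScenario:
    """One cell of the evaluation grid.

    ``a`` is the additive effect entering only the heterozygote variance;
    the genotype means come from ``beta0`` and ``beta`` via beta1 =
    gamma*beta, beta2 = (2-gamma)*beta.
    """

    p: float
    gamma: float
    a: float
    n: int
    rho: float = 0.0
    beta0: float = 0.1
    beta: float = 0.3
    base_var: float = BASE_VAR
    sigma0_sq: float = 1.0
    sigma2_sq: float = 1.0
    K: int = 10_000
    alpha: float = 0.05
    seed: Optional[int] = None

    def __post_init__(self):
        genotype_freqs(self.p, self.rho)  # validates
        if sigma1_sq(self.gamma, self.a, self.base_var) <= 0:
            raise ValueError("heterozygote variance must be positive")
        if self.n < 3:
            raise ValueError("sample size too small")

    @property
    def freqs(self):
        return genotype_freqs(self.p, self.rho)

    @property
    def group_means(self) -> np.ndarray:
        return np.array(
            [self.beta0, self.beta0 + self.gamma * self.beta, self.beta0 + 2.0 * self.beta]
        )

    @property
    def group_sds(self) -> np.ndarray:
        return np.sqrt(
            np.array(
                [
                    self.sigma0_sq,
                    sigma1_sq(self.gamma, self.a, self.base_var),
                    self.sigma2_sq,
                ]
            )
        )

    def replace(self, **kwargs) -> "SimScenario":
        return dataclasses.replace(self, **kwargs)


def simulate_sample(scenario: SimScenario, rng: np.random.Generator) -> QuantSample:
    """Draw one sample of n females: genotypes, then traits given genotype.

    Genotypes are drawn per subject from (g0, g1, g2); traits from the
    group-conditional normals.  Stream order is fixed (one uniform block
    for genotypes, one normal block for traits), so a given generator
    state reproduces the sample bit-exactly.
    """
    cum = np.cumsum(scenario.freqs)
    g = np.searchsorted(cum, rng.random(scenario.n), side="right").astype(np.int64)
    np.clip(g, 0, 2, out=g)
    y = scenario.group_means[g] + scenario.group_sds[g] * rng.standard_normal(
        scenario.n
    )
    return QuantSample(trait=y, genotype=g)


def _stats_of(y, g):
    counts = np.bincount(g, minlength=3)[:3]
    sums = np.bincount(g, weights=y, minlength=3)[:3]
    means = sums / counts
    dev = y - means[g]
    ss = np.bincount(g, weights=dev * dev, minlength=3)[:3]
    return counts, means, ss

def simulate_group_stats(scenario: SimScenario, K: int, seed):
    """Sufficient statistics for K replicates, one RNG substream each.

    Every replicate gets an independent child stream spawned from ``seed``
    (so the set of replicates is reproducible and order-independent of any
    chunking).  Replicates in which any genotype group has fewer than two
    members — for which the heteroscedastic likelihood is singular — are
    resampled from the same substream and counted.

    Returns ``(counts, means, ss, n_resampled)`` with arrays of shape
    (K, 3).
    """
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = root.spawn(K)
    counts = np.empty((K, 3), dtype=np.int64)
    means = np.empty((K, 3))
    ss = np.empty((K, 3))
    n_resampled = 0
    for k, child in enumerate(children):
        rng = np.random.Generator(np.random.PCG64(child))
        while True:
            sample = simulate_sample(scenario, rng)
            c = sample.group_counts()
            if c.min() >= 2:
                break
            n_resampled += 1
        counts[k], means[k], ss[k] = _stats_of(sample.trait, sample.genotype)
    return counts, means, ss, n_resampled


def scenario_grid(
    p_values=(0.1, 0.3),
    rho_values=(0.0, 0.05),
    gamma_values=(0.0, 0.5, 1.0, 1.5, 2.0),
    a_values=(0.1, 0.3),
    n_values=(1_000, 2_000),
    **overrides,
):
    """Full factorial evaluation grid (2 x 2 x 5 x 2 x 2 = 80 scenarios).

    Ordered a-major then p, gamma, n, rho innermost kept stable for
    reproducible per-cell seeds.
    """
    return [
        SimScenario(p=p, rho=rho, gamma=g, a=a, n=n, **overrides)
        for a in a_values
        for p in p_values
        for g in gamma_values
        for n in n_values
        for rho in rho_values
    ]
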