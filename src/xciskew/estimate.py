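"""Point estimation of the XCI skewness measure gamma and its variance.

gamma = 2 beta1 / (beta1 + beta2) lies in [0, 2] when inactivation is at
work: gamma = 1 is random inactivation, gamma > 1 skewing towards the
focal allele D, gamma < 1 skewing against it.  theta = gamma / 2 is the
average proportion of cells in a heterozygote that keep D active (e.g.
gamma = 1.5 means 75% of cells express D).  The reported estimate is the
raw ratio truncated to [0, 2]; its variance comes from first-order error
propagation through the covariance of (beta1_hat, beta2_hat).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .model import FullFit

__all__ = ["GammaEstimate", "NoAssociationError", "estimate_gamma", "delta_variance"]


class NoAssociationError(ValueError):
    """gamma is undefined without association (beta1_hat + beta2_hat = 0)."""


@dataclass(frozen=True)
class GammaEstimate:
    """Raw and truncated gamma with its error-propagation variance."""

    gamma_raw: float
    gamma_hat: float
    theta_hat: float
    beta_hat: float
    var_delta: float
    source_fit: FullFit

    def __str__(self):
        return (
            f"gamma_hat={self.gamma_hat:.4f} (raw {self.gamma_raw:.4f}, "
            f"SE_delta {np.sqrt(self.var_delta):.4f})"
        )


def delta_variance(fit: FullFit) -> float:
    """First-order (delta-method) variance of gamma_hat.

    Var(gamma_hat) = Var(b1)/beta^2 + b1^2 Var(beta)/beta^4
                     - 2 b1 Cov(b1, beta)/beta^3,
    with beta = (b1 + b2)/2, Var(beta) = [Var(b1) + Var(b2) + 2 Cov]/4 and
    Cov(b1, beta) = [Var(b1) + Cov]/2, all evaluated at the estimates.
    """
    beta = 0.5 * (fit.beta1 + fit.beta2)
    if beta == 0.0:
        raise NoAssociationError("beta_hat = 0: delta variance undefined")
    c = fit.cov_b1_b2
    return float(
        _kernels.delta_variance(fit.beta1, fit.beta2, c[0, 0], c[1, 1], c[0, 1])
    )


def estimate_gamma(fit: FullFit) -> GammaEstimate:
    """Point estimate of gamma from an unconstrained fit.

    Raises :class:`NoAssociationError` when beta1_hat + beta2_hat vanishes
    (to machine precision relative to the coefficient scale): the ratio is
    then undefined.  Significance screening for association is a separate
    pipeline stage.
    """
    denom = fit.beta1 + fit.beta2
    scale = max(abs(fit.beta1), abs(fit.beta2), 1e-300)
    if denom == 0.0 or abs(denom) < 1e-12 * scale:
        raise NoAssociationError(
            "gamma undefined without association: beta1_hat + beta2_hat = 0"
        )
    gamma_raw = 2.0 * fit.beta1 / denom
    gamma_hat = min(2.0, max(0.0, gamma_raw))
    return GammaEstimate(
        gamma_raw=float(gamma_raw),
        gamma_hat=float(gamma_hat),
        theta_hat=float(gamma_hat / 2.0),
        beta_hat=float(denom / 2.0),
        var_delta=delta_variance(fit),
        source_fit=fit,
    )
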