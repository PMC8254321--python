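"""Confidence regions for the XCI skewness measure gamma.

Three constructions, all restricted to the parameter space [0, 2]:

* **LR** — inversion of the likelihood-ratio test: the region is
  ``{gamma0 : lambda(gamma0) < chi2_{1-alpha,1}}``, found by a sign-change
  scan of ``f(gamma0) = lambda(gamma0) - chi2`` over a grid followed by
  bisection refinement of each bracketed root.
* **Fieller** — roots of the quadratic ``A g^2 + B g + C = 0`` arising from
  the Wald pivot for ``beta1 - gamma0 * beta``; depending on the signs of
  the leading coefficient and the discriminant the region may be a bounded
  interval, the complement of one (possibly discontinuous after
  truncation), or all of [0, 2].
* **delta** — the symmetric Wald interval around the truncated estimate
  using the error-propagation variance; always a single bounded interval.

Because of the truncation, LR and Fieller regions can be empty, a single
point, or a union of two disjoint intervals; :class:`ConfidenceRegion`
records segments with endpoint openness (truncation endpoints closed,
analytic roots open) and a status tag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from . import _kernels
from .estimate import GammaEstimate
from .model import FullFit, QuantSample, fit_full, fit_null, group_stats, lr_stat

__all__ = [
    "ConfidenceRegion",
    "lr_ci",
    "fieller_ci",
    "delta_ci",
    "lr_ci_from_stats",
    "fieller_ci_from_params",
]

#: a segment narrower than this counts as a point (numeric roots never collide exactly)
POINT_TOL = 1e-9
#: bisection stops when the bracketing interval is narrower than this
ROOT_TOL = 1e-6
#: default number of scan points on [0, 2] used to bracket LR roots
LR_GRID_POINTS = 401


@dataclass
class ConfidenceRegion:
    """Level-(1-alpha) region for gamma inside [0, 2].

    ``segments`` is a list of up to two disjoint ``(lower, upper,
    lower_open, upper_open)`` tuples sorted by position.  ``status`` is one
    of ``continuous``, ``discontinuous``, ``empty``, ``point``, ``full``.
    """

    method: str
    level: float
    segments: list
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        self.segments = sorted(self.segments, key=lambda s: s[0])

    @property
    def status(self) -> str:
        if not self.segments:
            return "empty"
        if len(self.segments) == 2:
            return "discontinuous"
        lo, hi, *_ = self.segments[0]
        if hi - lo < POINT_TOL:
            return "point"
        if lo == 0.0 and hi == 2.0:
            return "full"
        return "continuous"

    def contains(self, x: float) -> bool:
        for lo, hi, lo_open, hi_open in self.segments:
            above = x > lo if lo_open else x >= lo
            below = x < hi if hi_open else x <= hi
            if above and below:
                return True
        return False

    __contains__ = contains

    @property
    def bounds(self):
        """(lower, upper) of the hull of the region; None when empty."""
        if not self.segments:
            return None
        return (self.segments[0][0], self.segments[-1][1])

    def __str__(self):
        if not self.segments:
            return "{}"
        parts = []
        for lo, hi, lo_open, hi_open in self.segments:
            lb = "(" if lo_open else "["
            rb = ")" if hi_open else "]"
            parts.append(f"{lb}{lo:.4f}, {hi:.4f}{rb}")
        return " U ".join(parts)


def _clip_segment(lo, hi, lo_open, hi_open):
    """Intersect an interval with [0, 2]; clipped endpoints become closed."""
    if hi < 0.0 or lo > 2.0:
        return None
    if lo < 0.0:
        lo, lo_open = 0.0, False
    if hi > 2.0:
        hi, hi_open = 2.0, False
    if lo > hi:
        return None
    if lo == hi and (lo_open or hi_open):
        return None
    return (lo, hi, lo_open, hi_open)


def _segments_from_roots(roots, negative_at_zero):
    """Sub-level set {f < 0} on [0, 2] given the interior roots of f.

    The sign alternates across consecutive simple roots; truncation
    endpoints 0 and 2 are closed, analytic roots open.
    """
    bounds = [0.0] + list(roots) + [2.0]
    segments = []
    neg = negative_at_zero
    for i in range(len(bounds) - 1):
        if neg:
            lo, hi = bounds[i], bounds[i + 1]
            seg = _clip_segment(lo, hi, lo_open=i > 0, hi_open=i + 2 < len(bounds))
            if seg is not None:
                segments.append(seg)
        neg = not neg
    return segments


# ---------------------------------------------------------------------------
# likelihood-ratio interval


def lr_ci(
    sample: QuantSample,
    alpha: float = 0.05,
    grid_points: int = LR_GRID_POINTS,
    full: FullFit | None = None,
    variance_structure: str = "shared",
) -> ConfidenceRegion:
    """Likelihood-ratio confidence region by test inversion.

    ``f(gamma0) = lambda(gamma0) - chi2_{1-alpha,1}`` is evaluated on an
    equally spaced scan grid over [0, 2]; each sign change is refined by
    bisection to an interval narrower than 1e-6, and the region is the set
    where f is negative.
    """
    if full is not None:
        variance_structure = full.variance_structure
    if sample.covariates is None:
        st = group_stats(sample)
        return lr_ci_from_stats(
            st.counts[None, :],
            st.means[None, :],
            st.ss[None, :],
            alpha=alpha,
            grid_points=grid_points,
            variance_structure=variance_structure,
        )[0]
    # covariate path: scalar scan using the general constrained fit
    if full is None:
        full = fit_full(sample, variance_structure=variance_structure)
    crit = sps.chi2.ppf(1.0 - alpha, 1)
    grid = np.linspace(0.0, 2.0, grid_points)
    f = np.array(
        [lr_stat(sample, g0, full=full) - crit for g0 in grid]
    )
    neg = f < 0
    flips = np.flatnonzero(neg[1:] != neg[:-1])
    if flips.size > 2:
        raise RuntimeError(
            f"LR scan found {flips.size} sign changes; f values: {f[flips]}"
        )
    roots = []
    for j in flips:
        lo, hi = grid[j], grid[j + 1]
        lo_neg = neg[j]
        while hi - lo > ROOT_TOL:
            mid = 0.5 * (lo + hi)
            if (lr_stat(sample, mid, full=full) - crit < 0) == lo_neg:
                lo = mid
            else:
                hi = mid
        roots.append(0.5 * (lo + hi))
    segments = _segments_from_roots(roots, bool(neg[0]))
    return ConfidenceRegion(
        method="LR",
        level=1.0 - alpha,
        segments=segments,
        diagnostics={"roots": roots, "f_at_0": float(f[0]), "f_at_2": float(f[-1])},
    )


def lr_ci_from_stats(
    counts,
    means,
    ss,
    alpha: float = 0.05,
    grid_points: int = LR_GRID_POINTS,
    variance_structure: str = "shared",
) -> list:
    """Batched LR regions from per-genotype sufficient statistics.

    ``counts``, ``means``, ``ss`` have shape (B, 3); returns a list of B
    :class:`ConfidenceRegion`.  The scan and every bisection step are
    vectorized across replicates, which is what makes Monte-Carlo coverage
    studies of the LR interval affordable.
    """
    counts = np.asarray(counts, dtype=float)
    means = np.asarray(means, dtype=float)
    ss = np.asarray(ss, dtype=float)
    shared = variance_structure == "shared"
    nrep = counts.shape[0]
    crit = sps.chi2.ppf(1.0 - alpha, 1)
    grid = np.linspace(0.0, 2.0, grid_points)
    ll1 = _kernels.full_loglik(counts, means, ss, shared)
    nf = _kernels.null_fit(
        counts[:, None, :], means[:, None, :], ss[:, None, :], grid[None, :],
        shared=shared,
    )
    f = 2.0 * (ll1[:, None] - nf["loglik"]) - crit
    neg = f < 0
    flips = neg[:, 1:] != neg[:, :-1]
    nchanges = flips.sum(axis=1)
    if np.any(nchanges > 2):
        bad = int(np.argmax(nchanges))
        raise RuntimeError(
            f"LR scan found {int(nchanges[bad])} sign changes for replicate "
            f"{bad}; f on grid: {f[bad]}"
        )
    rows, cols = np.nonzero(flips)
    lo = grid[cols]
    hi = grid[cols + 1]
    lo_neg = neg[rows, cols]
    if rows.size:
        sub_c = counts[rows]
        sub_m = means[rows]
        sub_s = ss[rows]
        sub_ll1 = ll1[rows]
        for _ in range(60):
            if np.max(hi - lo) <= ROOT_TOL:
                break
            mid = 0.5 * (lo + hi)
            nfm = _kernels.null_fit(sub_c, sub_m, sub_s, mid, shared=shared)
            mid_neg = (2.0 * (sub_ll1 - nfm["loglik"]) - crit) < 0
            go_right = mid_neg == lo_neg
            lo = np.where(go_right, mid, lo)
            hi = np.where(go_right, hi, mid)
    roots = 0.5 * (lo + hi)
    regions = []
    for i in range(nrep):
        mask = rows == i
        r = sorted(roots[mask].tolist())
        segments = _segments_from_roots(r, bool(neg[i, 0]))
        regions.append(
            ConfidenceRegion(
                method="LR",
                level=1.0 - alpha,
                segments=segments,
                diagnostics={
                    "roots": r,
                    "f_at_0": float(f[i, 0]),
                    "f_at_2": float(f[i, -1]),
                },
            )
        )
    return regions


# ---------------------------------------------------------------------------
# Fieller interval


def _fieller_region(a, b, c, level, diagnostics):
    """Assemble the Fieller region on [0, 2] from quadratic coefficients.

    The acceptance set of the Wald pivot is {gamma0 : a g^2 + b g + c < 0}.
    A > 0 is equivalent to the association being significant at the level;
    Fieller's theorem then guarantees a positive discriminant.
    """
    disc = b * b - 4.0 * a * c
    diagnostics = dict(diagnostics, A=a, B=b, C=c, discriminant=disc)
    diagnostics["association_significant"] = a > 0
    if a == 0.0:
        if b == 0.0:
            segments = [(0.0, 2.0, False, False)] if c < 0 else []
        else:
            # linear case: f(g) = b g + c changes sign once, at -c/b
            root = -c / b
            segments = _segments_from_roots(
                [root] if 0.0 < root < 2.0 else [], negative_at_zero=c < 0
            )
        return ConfidenceRegion("Fieller", level, segments, diagnostics)
    if disc > 0.0:
        r1 = (-b - np.sqrt(disc)) / (2.0 * a)
        r2 = (-b + np.sqrt(disc)) / (2.0 * a)
        lo, hi = (r1, r2) if r1 <= r2 else (r2, r1)
        if a > 0:
            seg = _clip_segment(lo, hi, True, True)
            segments = [seg] if seg is not None else []
        else:
            segments = []
            seg = _clip_segment(0.0, lo, False, True)
            if seg is not None:
                segments.append(seg)
            seg = _clip_segment(hi, 2.0, True, False)
            if seg is not None:
                segments.append(seg)
            # the two pieces may merge into [0, 2] when both roots are outside
            if len(segments) == 2 and segments[0][1] >= segments[1][0]:
                segments = [(0.0, 2.0, False, False)]
        return ConfidenceRegion("Fieller", level, segments, diagnostics)
    if disc == 0.0:
        seg = _clip_segment(-b / (2.0 * a), -b / (2.0 * a), False, False)
        segments = [seg] if (seg is not None and a > 0) else (
            [(0.0, 2.0, False, False)] if a < 0 else []
        )
        return ConfidenceRegion("Fieller", level, segments, diagnostics)
    # disc < 0
    if a < 0:
        return ConfidenceRegion(
            "Fieller", level, [(0.0, 2.0, False, False)], diagnostics
        )
    # A > 0 with a negative discriminant contradicts Fieller's theorem and can
    # only arise from rounding; fall back to the full interval with a warning.
    warnings.warn(
        "Fieller quadratic has A > 0 but negative discriminant; reporting "
        "[0, 2] (rounding artefact)",
        RuntimeWarning,
    )
    diagnostics["degenerate"] = "A>0 with disc<0"
    return ConfidenceRegion("Fieller", level, [(0.0, 2.0, False, False)], diagnostics)


def fieller_ci(fit: FullFit, alpha: float = 0.05) -> ConfidenceRegion:
    """Fieller confidence region for gamma from a full fit."""
    z = sps.norm.ppf(1.0 - alpha / 2.0)
    cov = fit.cov_b1_b2
    a, b, c = _kernels.fieller_coefficients(
        fit.beta1, fit.beta2, cov[0, 0], cov[1, 1], cov[0, 1], z
    )
    return _fieller_region(float(a), float(b), float(c), 1.0 - alpha, {"z": z})


def fieller_ci_from_params(beta1, beta2, var_b1, var_b2, cov_b1b2,
                           alpha: float = 0.05) -> list:
    """Batched Fieller regions from arrays of coefficient estimates."""
    z = sps.norm.ppf(1.0 - alpha / 2.0)
    a, b, c = _kernels.fieller_coefficients(
        np.asarray(beta1), np.asarray(beta2), np.asarray(var_b1),
        np.asarray(var_b2), np.asarray(cov_b1b2), z
    )
    return [
        _fieller_region(float(ai), float(bi), float(ci), 1.0 - alpha, {"z": z})
        for ai, bi, ci in zip(np.ravel(a), np.ravel(b), np.ravel(c))
    ]


# ---------------------------------------------------------------------------
# delta interval


def delta_ci(est: GammaEstimate, alpha: float = 0.05) -> ConfidenceRegion:
    """Wald interval around the truncated estimate, clipped to [0, 2].

    Always a single continuous (possibly point) interval — never empty and
    never discontinuous.
    """
    if not np.isfinite(est.var_delta):
        raise ValueError("delta variance is not finite")
    z = sps.norm.ppf(1.0 - alpha / 2.0)
    hw = z * np.sqrt(max(est.var_delta, 0.0))
    if hw == 0.0:
        seg = (est.gamma_hat, est.gamma_hat, False, False)
    else:
        seg = _clip_segment(est.gamma_hat - hw, est.gamma_hat + hw, True, True)
    return ConfidenceRegion(
        method="delta",
        level=1.0 - alpha,
        segments=[seg],
        diagnostics={"z": z, "half_width": float(hw)},
    )
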