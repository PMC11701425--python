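"""Maximal point-polyserial correlation machinery.

The central object is the comonotonic coupling of a continuous random
variable X and a discrete variable supported on k ordered values: the
largest Pearson correlation attainable between them is reached exactly
when the pair is comonotonic, and the mixed moment then decomposes into a
sum of partial moments of X between consecutive quantile thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.stats import norm

from .distributions import (
    ContinuousModel,
    LogNormal,
    partial_moment,
)

__all__ = [
    "Discretization",
    "MaxCorrResult",
    "comonotonic_mixed_moment",
    "max_point_polyserial",
    "optimal_scores",
    "corr_with_optimal_scores",
    "biserial_ratio_normal",
    "normal_ratio",
    "attainable_bounds",
    "empirical_max_corr",
]

_PROB_ATOL = 1e-12


@dataclass(frozen=True)
class Discretization:
    """A k-point discrete law: strictly increasing support values + probabilities.

    Consecutive-integer scores (CIS) correspond to ``values = 1..k``.
    """

    values: np.ndarray
    probs: np.ndarray

    def __post_init__(self):
        values = np.atleast_1d(np.asarray(self.values, dtype=float))
        probs = np.atleast_1d(np.asarray(self.probs, dtype=float))
        if values.shape != probs.shape or values.ndim != 1:
            raise ValueError("values and probs must be 1-D arrays of equal length")
        if values.size < 1:
            raise ValueError("need at least one support point")
        if np.any(np.diff(values) <= 0):
            raise ValueError("support values must be strictly increasing")
        if np.any(probs < -_PROB_ATOL):
            raise ValueError("probabilities must be nonnegative")
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError(f"probabilities sum to {probs.sum()}, not 1")
        probs = np.clip(probs, 0.0, None)
        probs = probs / probs.sum()
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "probs", probs)

    # -- constructors ----------------------------------------------------
    @classmethod
    def cis(cls, probs) -> "Discretization":
        """Consecutive integer scores 1..k with the given probabilities."""
        probs = np.atleast_1d(np.asarray(probs, dtype=float))
        return cls(np.arange(1, probs.size + 1, dtype=float), probs)

    @classmethod
    def equal_prob_cis(cls, k: int) -> "Discretization":
        """Discrete uniform on scores 1..k."""
        if k < 2:
            raise ValueError("k must be >= 2")
        return cls.cis(np.full(k, 1.0 / k))

    # -- summaries -------------------------------------------------------
    @property
    def k(self) -> int:
        return self.values.size

    @property
    def cumprobs(self) -> np.ndarray:
        c = np.cumsum(self.probs)
        c[-1] = 1.0
        return c

    @property
    def mean(self) -> float:
        return float(self.values @ self.probs)

    @property
    def var(self) -> float:
        m = self.mean
        return float(self.values**2 @ self.probs - m * m)

    def moment(self, n: int) -> float:
        return float(self.values**n @ self.probs)


@dataclass(frozen=True)
class MaxCorrResult:
    """A maximal point-polyserial correlation with its optimizing discretization.

    ``thresholds`` are the k-1 cut values induced on the continuous scale,
    ``mixed_moment`` is the comonotonic E(X * Xd), and ``covariance``
    equals ``mixed_moment - mu * E(Xd) = rho * sigma * sqrt(V)``.
    """

    rho: float
    disc: Discretization
    thresholds: np.ndarray
    mixed_moment: float
    covariance: float
    diagnostics: dict = field(default_factory=dict)


def comonotonic_mixed_moment(model: ContinuousModel, disc: Discretization) -> float:
    """E(X * Xd) under comonotonicity: sum of value-weighted cell partial moments.

    Cells with probability below 1e-12 are skipped (their partial moment is
    zero in the limit).
    """
    cum = np.concatenate(([0.0], disc.cumprobs))
    total = 0.0
    for i in range(disc.k):
        if disc.probs[i] <= _PROB_ATOL:
            continue
        lo = model.ppf(cum[i]) if cum[i] > 0.0 else model.support[0]
        hi = model.ppf(cum[i + 1]) if cum[i + 1] < 1.0 else model.support[1]
        total += disc.values[i] * partial_moment(model, lo, hi)
    return float(total)


def max_point_polyserial(model: ContinuousModel, disc: Discretization) -> MaxCorrResult:
    """Maximal point-polyserial correlation between ``model`` and ``disc``.

    ``rho = (E_c(X Xd) - mu E(Xd)) / (sigma sqrt(Var(Xd)))``.
    """
    v = disc.var
    if v <= 0:
        raise ValueError("discrete variance must be positive (>= 2 cells with mass)")
    mu, sigma = model.mean, model.std
    mixed = comonotonic_mixed_moment(model, disc)
    cov = mixed - mu * disc.mean
    rho = cov / (sigma * np.sqrt(v))
    inner = disc.cumprobs[:-1]
    with np.errstate(divide="ignore"):
        thresholds = np.asarray(model.ppf(np.clip(inner, 1e-300, 1.0)), dtype=float)
    return MaxCorrResult(
        rho=float(rho),
        disc=disc,
        thresholds=thresholds,
        mixed_moment=mixed,
        covariance=float(cov),
    )


def optimal_scores(model: ContinuousModel, probs) -> np.ndarray:
    """Cell-conditional means of X for the given probability vector.

    These are the support values maximizing the correlation for fixed
    probabilities; the resulting discrete law has mean ``mu`` and variance
    strictly below ``sigma^2``.
    """
    probs = np.atleast_1d(np.asarray(probs, dtype=float))
    if np.any(probs <= 0):
        raise ValueError("all probabilities must be positive (empty cells have no conditional mean)")
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("probabilities must sum to 1")
    cum = np.concatenate(([0.0], np.cumsum(probs)))
    cum[-1] = 1.0
    out = np.empty(probs.size)
    for i in range(probs.size):
        lo = model.ppf(cum[i]) if cum[i] > 0.0 else model.support[0]
        hi = model.ppf(cum[i + 1]) if cum[i + 1] < 1.0 else model.support[1]
        out[i] = partial_moment(model, lo, hi) / probs[i]
    return out


def corr_with_optimal_scores(model: ContinuousModel, probs) -> float:
    """Correlation achieved by the optimal scores: ``sqrt(Var(Xd)) / sigma``."""
    disc = Discretization(optimal_scores(model, probs), np.asarray(probs, dtype=float))
    return float(np.sqrt(disc.var) / model.std)


def biserial_ratio_normal(omega: float) -> float:
    """Pearson's ratio ``phi(omega)/sqrt(p q)`` for a normal dichotomized at omega."""
    p = norm.sf(omega)
    q = norm.cdf(omega)  # not 1 - p: avoids cancellation in the tails
    if p <= 0.0 or q <= 0.0:
        return 0.0
    return float(norm.pdf(omega) / np.sqrt(p * q))


def normal_ratio(probs) -> float:
    """Normal-theory point-polyserial/polyserial ratio for CIS probabilities.

    ``sum_i phi(Phi^-1(F_i)) / sqrt(Var(Xd))`` — equals the maximal
    point-polyserial correlation for a standard normal X.
    """
    probs = np.atleast_1d(np.asarray(probs, dtype=float))
    k = probs.size
    i = np.arange(1, k + 1)
    e = float(i @ probs)
    v = float(i**2 @ probs - e * e)
    if v <= 0:
        raise ValueError("probability vector is degenerate (zero discrete variance)")
    cum = np.cumsum(probs)[:-1]
    cum = cum[(cum > 0.0) & (cum < 1.0)]
    num = norm.pdf(norm.ppf(cum)).sum()
    return float(num / np.sqrt(v))


# ---------------------------------------------------------------------------
# attainable correlation bounds
# ---------------------------------------------------------------------------

_GL_NODES = 2048


def _gl_cache(n=_GL_NODES):
    z, w = leggauss(n)
    return z, w


_Z, _W = _gl_cache()


def _quantile_quadrature(m1: ContinuousModel, m2: ContinuousModel, anti: bool) -> float:
    """Pearson correlation of (F1^-1(U), F2^-1(U)) (or 1-U) by Gauss-Legendre.

    Bounded-support pairs integrate directly over u in (0,1); otherwise the
    substitution u = Phi(z) maps the integral onto a smooth weight so tail
    quantile growth is tamed.
    """
    bounded = all(np.isfinite(m.support).all() for m in (m1, m2))
    if bounded:
        u = (_Z + 1.0) / 2.0
        w = _W / 2.0
    else:
        zlim = 8.0  # norm.cdf stays strictly below 1 in double precision
        z = _Z * zlim
        u = norm.cdf(z)
        w = _W * zlim * norm.pdf(z)
    u = np.clip(u, 1e-300, 1.0 - 1e-16)
    q1 = np.asarray(m1.ppf(u), dtype=float)
    q2 = np.asarray(m2.ppf(1.0 - u if anti else u), dtype=float)
    mixed = float((q1 * q2) @ w)
    return (mixed - m1.mean * m2.mean) / (m1.std * m2.std)


def _lognormal_bounds(m1: LogNormal, m2: LogNormal) -> tuple[float, float]:
    # closed form for the comonotonic / countermonotonic correlation of
    # exp(mu1 + s1 Z) and exp(mu2 +- s2 Z); location parameters cancel.
    s1, s2 = m1.sigma, m2.sigma
    den = np.sqrt(np.expm1(s1 * s1) * np.expm1(s2 * s2))
    rho_max = np.expm1(s1 * s2) / den
    rho_min = np.expm1(-s1 * s2) / den
    return float(rho_min), float(rho_max)


def attainable_bounds(
    model1: ContinuousModel, model2: ContinuousModel, *, method: str = "auto"
) -> tuple[float, float]:
    """Frechet-Hoeffding attainable Pearson correlation interval (rho_min, rho_max).

    Lognormal-lognormal pairs use the closed form; other pairs (and
    ``method="quadrature"``) use 2048-node Gauss-Legendre quadrature of the
    quantile representation ``cor(F1^-1(U), F2^-1(U))``.
    """
    for m in (model1, model2):
        m.var  # raises MomentExistenceError if the variance does not exist
    if (
        method in ("auto", "closed_form")
        and isinstance(model1, LogNormal)
        and isinstance(model2, LogNormal)
    ):
        return _lognormal_bounds(model1, model2)
    if method == "closed_form":
        raise ValueError("closed-form bounds only available for lognormal pairs")
    rho_max = _quantile_quadrature(model1, model2, anti=False)
    rho_min = _quantile_quadrature(model1, model2, anti=True)
    return float(rho_min), float(min(rho_max, 1.0))


def empirical_max_corr(sample_x, sample_y) -> float:
    """Pearson correlation of two samples after ascending sorting.

    Sorting makes the paired samples comonotonic, so this is the sample
    analogue of the maximal correlation for the two empirical margins.
    """
    x = np.asarray(sample_x, dtype=float).ravel()
    y = np.asarray(sample_y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("samples must have equal length")
    if x.size < 2:
        raise ValueError("need at least two observations")
    xs = np.sort(x, kind="stable")
    ys = np.sort(y, kind="stable")
    if xs[0] == xs[-1] or ys[0] == ys[-1]:
        raise ValueError("correlation undefined for a constant sample")
    return float(np.corrcoef(xs, ys)[0, 1])
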