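"""Copula-linked point-polyserial correlation.

Four parametric copulas (Gauss, Frank, Clayton, Gumbel) with uniform
margins: density and CDF evaluation, Spearman's rho calibration, and the
point-polyserial correlation when the second uniform margin is cut into k
equal-probability CIS categories.

The band mixed moment reduces, after integrating the copula density by
parts, to one-dimensional integrals of the copula CDF:

    E(U1 U2d) = 1/2 + sum_{i=1}^{k-1} int_0^1 C(u, i/k) du,

which is far better conditioned than 2-D cubature of the density (the
Gumbel density has corner singularities; the CDF does not).  The density
is still exposed and cross-checked against the CDF by finite differences
in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy import integrate
from scipy import optimize as sopt
from scipy.stats import multivariate_normal, norm

__all__ = [
    "CopulaModel",
    "RatioCurve",
    "copula_density",
    "copula_cdf",
    "spearman_rho",
    "calibrate_theta",
    "point_polyserial_under_copula",
    "ratio_curve",
    "COPULA_FAMILIES",
]

COPULA_FAMILIES = ("gauss", "frank", "clayton", "gumbel")


@dataclass(frozen=True)
class CopulaModel:
    """A parametric copula: family name + dependence parameter theta.

    Domains: gauss theta in (-1, 1); frank theta != 0; clayton theta > 0;
    gumbel theta >= 1 (Clayton and Gumbel model positive dependence only).
    """

    family: str
    theta: float

    def __post_init__(self):
        fam = self.family.lower()
        object.__setattr__(self, "family", fam)
        th = float(self.theta)
        if fam == "gauss":
            if not -1.0 < th < 1.0:
                raise ValueError(f"gauss copula needs theta in (-1,1), got {th}")
        elif fam == "frank":
            if th == 0.0:
                raise ValueError("frank copula needs theta != 0")
        elif fam == "clayton":
            if not th > 0.0:
                raise ValueError(f"clayton copula needs theta > 0, got {th}")
        elif fam == "gumbel":
            if not th >= 1.0:
                raise ValueError(f"gumbel copula needs theta >= 1, got {th}")
        else:
            raise ValueError(f"unknown copula family {fam!r}; choose from {COPULA_FAMILIES}")


def _log_abs_expm1(d):
    """log|e^d - 1|, overflow-safe for large positive d."""
    d = np.asarray(d, dtype=float)
    pos_big = d > 30.0
    with np.errstate(divide="ignore"):
        small = np.log(np.abs(np.expm1(np.where(pos_big, 0.0, d))))
    big = d + np.log1p(-np.exp(-np.abs(d)))
    return np.where(pos_big, big, small)


def copula_cdf(cop: CopulaModel, u, v):
    """C(u, v; theta), vectorized; evaluated in log space where the naive
    closed forms cancel catastrophically at strong dependence."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    th = cop.theta
    if cop.family == "gauss":
        x = norm.ppf(u)
        y = norm.ppf(v)
        mvn = multivariate_normal(mean=[0.0, 0.0], cov=[[1.0, th], [th, 1.0]])
        pts = np.stack(np.broadcast_arrays(x, y), axis=-1)
        return np.asarray(mvn.cdf(pts))
    if cop.family == "frank":
        if abs(th) <= 25.0:
            # naive closed form is exact here; the log-space variant below
            # would cancel catastrophically for small |theta|
            return -np.log1p(np.expm1(-th * u) * np.expm1(-th * v) / np.expm1(-th)) / th
        # C = -(1/th) log[(e^a + e^b - e^{a+b} - e^d)/(1 - e^d)],
        # a = -th u, b = -th v, d = -th; factor out the dominant exponential
        a, b, d = -th * u, -th * v, -th
        c = a + b
        m = np.maximum(np.maximum(a, b), np.maximum(c, np.full_like(c, d)))
        s = np.exp(a - m) + np.exp(b - m) - np.exp(c - m) - np.exp(d - m)
        with np.errstate(divide="ignore"):
            log_num = m + np.log(np.abs(s))
        log_den = _log_abs_expm1(np.asarray(d, dtype=float))
        return np.maximum(-(log_num - log_den) / th, 0.0)
    if cop.family == "clayton":
        # (u^-th + v^-th - 1)^(-1/th) via logsumexp of the two power terms
        a = -th * np.log(u)
        b = -th * np.log(v)
        m = np.maximum(a, b)
        s = np.exp(a - m) + np.exp(b - m) - np.exp(-m)
        return np.exp(-(m + np.log(s)) / th)
    # gumbel: exp(-((-log u)^th + (-log v)^th)^(1/th)), powers in log space
    with np.errstate(divide="ignore"):
        la = th * np.log(-np.log(u))
        lb = th * np.log(-np.log(v))
    m = np.maximum(la, lb)
    out = np.exp(-np.exp((m + np.log(np.exp(la - m) + np.exp(lb - m))) / th))
    return np.where((u >= 1.0) | (v >= 1.0), np.minimum(u, v), out)


def copula_density(cop: CopulaModel, u, v):
    """Copula density c(u, v; theta) for strictly interior (u, v)."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if np.any((u <= 0) | (u >= 1) | (v <= 0) | (v >= 1)):
        raise ValueError("density requires u, v strictly inside (0, 1)")
    th = cop.theta
    if cop.family == "gauss":
        x = norm.ppf(u)
        y = norm.ppf(v)
        r2 = 1.0 - th * th
        expo = -(th * th * (x * x + y * y) - 2.0 * th * x * y) / (2.0 * r2)
        return np.exp(expo) / math.sqrt(r2)
    if cop.family == "frank":
        # expm1(-th*u)*expm1(-th*v) == (1 - e^{-th u})(1 - e^{-th v})
        num = th * -np.expm1(-th) * np.exp(-th * (u + v))
        den = (-np.expm1(-th) - np.expm1(-th * u) * np.expm1(-th * v)) ** 2
        return num / den
    if cop.family == "clayton":
        s = u**-th + v**-th - 1.0
        return (1.0 + th) * (u * v) ** (-th - 1.0) * s ** (-2.0 - 1.0 / th)
    # gumbel, evaluated in log space to dodge corner overflow
    lu = -np.log(u)
    lv = -np.log(v)
    a = lu**th + lv**th
    log_c = (
        -(a ** (1.0 / th))
        + lu
        + lv  # the 1/(u v) factor: -log u - log v = lu + lv ... in log space
        + (th - 1.0) * (np.log(lu) + np.log(lv))
        + (2.0 / th - 2.0) * np.log(a)
    )
    return np.exp(log_c) * (1.0 + (th - 1.0) * a ** (-1.0 / th))


# ---------------------------------------------------------------------------
# Spearman's rho
# ---------------------------------------------------------------------------

_GL_N = 256
_gl_z, _gl_w = leggauss(_GL_N)
_gl_u = (_gl_z + 1.0) / 2.0
_gl_wu = _gl_w / 2.0


def _debye(n: int, x: float) -> float:
    """Debye function D_n(x) = (n/x^n) * int_0^x t^n/(e^t - 1) dt."""

    def f(t):
        return t**n / np.expm1(t) if t != 0 else (1.0 if n == 1 else 0.0)

    val, _ = integrate.quad(f, 0.0, x, limit=200)
    return n / x**n * val


def spearman_rho(cop: CopulaModel) -> float:
    """Spearman's rank correlation of the copula (= Pearson's rho of its margins)."""
    th = cop.theta
    if cop.family == "gauss":
        return 6.0 / math.pi * math.asin(th / 2.0)
    if cop.family == "frank":
        return 1.0 - 12.0 / th * (_debye(1, th) - _debye(2, th))
    # clayton / gumbel: 12 * int int C(u,v) du dv - 3 on a Gauss-Legendre grid
    uu, vv = np.meshgrid(_gl_u, _gl_u)
    ww = np.outer(_gl_wu, _gl_wu)
    c = copula_cdf(cop, uu, vv)
    return float(12.0 * (c * ww).sum() - 3.0)


def calibrate_theta(cop_family: str, spearman: float) -> float:
    """Find theta such that the copula's Spearman rho equals ``spearman``.

    Gauss uses the closed form ``theta = 2 sin(pi rho / 6)``; the other
    families root-find on the rho(theta) map with geometric bracket
    expansion.  Values outside the family's attainable range raise.
    """
    fam = cop_family.lower()
    if fam not in COPULA_FAMILIES:
        raise ValueError(f"unknown copula family {fam!r}")
    s = float(spearman)
    if not -1.0 < s < 1.0:
        raise ValueError("spearman must lie strictly inside (-1, 1)")
    if fam == "gauss":
        return 2.0 * math.sin(math.pi * s / 6.0)
    if fam in ("clayton", "gumbel") and s <= 0.0:
        raise ValueError(f"{fam} copula models positive dependence only (got {s})")
    if s == 0.0:
        raise ValueError("frank copula attains independence only in the limit theta -> 0")

    def f(th):
        return spearman_rho(CopulaModel(fam, th)) - s

    # rho(theta) is increasing in theta for all four families
    if fam == "frank" and s < 0:
        lo, hi = -1.0, -1e-8
        for _ in range(60):
            if f(lo) <= 0.0:
                break
            lo *= 2.0
        else:
            raise ValueError(f"spearman={s} unattainable for {fam}")
    else:
        lo = {"frank": 1e-8, "clayton": 1e-8, "gumbel": 1.0 + 1e-10}[fam]
        hi = 2.0 if fam != "gumbel" else 2.0
        for _ in range(60):
            if f(hi) >= 0.0:
                break
            lo, hi = hi, hi * 2.0
        else:
            raise ValueError(f"spearman={s} unattainable for {fam}")
    return float(sopt.brentq(f, lo, hi, xtol=1e-12, rtol=8.9e-16, maxiter=200))


# ---------------------------------------------------------------------------
# point-polyserial correlation under a copula
# ---------------------------------------------------------------------------


def _band_cdf_integral(cop: CopulaModel, v: float) -> float:
    """int_0^1 C(u, v) du."""
    if cop.family == "gauss":
        # int_0^1 Phi2(Phi^-1(u), y; th) du = P(X <= X', Y <= y) with X' an
        # independent standard normal = Phi2(0, y; th/sqrt(2))
        th = cop.theta
        y = norm.ppf(v)
        mvn = multivariate_normal(
            mean=[0.0, 0.0], cov=[[1.0, th / math.sqrt(2)], [th / math.sqrt(2), 1.0]]
        )
        return float(mvn.cdf([0.0, y]))
    c = copula_cdf(cop, _gl_u, v)
    return float(c @ _gl_wu)


def point_polyserial_under_copula(cop: CopulaModel, k: int) -> float:
    """Point-polyserial correlation of (U1, U2d) with U2 cut into k equal bands.

    U2d takes CIS values 1..k; the uniform margin has mean 1/2 and variance
    1/12, the discrete-uniform margin mean (k+1)/2 and variance (k^2-1)/12.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    g = sum(_band_cdf_integral(cop, i / k) for i in range(1, k))
    mixed = 0.5 + g
    e2 = (k + 1) / 2.0
    v2 = (k * k - 1) / 12.0
    return float((mixed - 0.5 * e2) / math.sqrt(v2 / 12.0))


@dataclass(frozen=True)
class RatioCurve:
    """Point-polyserial correlations and ratios along a grid of target rhos."""

    family: str
    k: int
    rho_target: np.ndarray
    theta: np.ndarray
    rho_pp: np.ndarray
    ratio: np.ndarray

    def to_records(self) -> list[dict]:
        return [
            {
                "family": self.family,
                "k": self.k,
                "rho_target": float(r),
                "theta": float(t),
                "rho_pp": float(p),
                "ratio": float(q),
            }
            for r, t, p, q in zip(self.rho_target, self.theta, self.rho_pp, self.ratio)
        ]


def ratio_curve(cop_family: str, rho_grid=None, k: int = 2) -> RatioCurve:
    """Ratio of point-polyserial to polyserial correlation along a rho grid.

    Default grid: .05 to .95 in steps of .05.  Each grid point calibrates
    theta to the target Spearman/Pearson correlation of the uniform pair,
    then computes the point-polyserial correlation of the discretized pair.
    """
    if rho_grid is None:
        rho_grid = np.round(np.arange(0.05, 0.951, 0.05), 10)
    rho_grid = np.atleast_1d(np.asarray(rho_grid, dtype=float))
    if np.any(rho_grid == 0.0):
        raise ValueError("rho grid entries must be nonzero (ratio undefined at 0)")
    thetas = np.empty_like(rho_grid)
    rho_pp = np.empty_like(rho_grid)
    for j, r in enumerate(rho_grid):
        th = calibrate_theta(cop_family, r)
        thetas[j] = th
        rho_pp[j] = point_polyserial_under_copula(CopulaModel(cop_family, th), k)
    return RatioCurve(
        family=cop_family.lower(),
        k=k,
        rho_target=rho_grid,
        theta=thetas,
        rho_pp=rho_pp,
        ratio=rho_pp / rho_grid,
    )
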