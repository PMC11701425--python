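"""Maximization of the point-polyserial correlation.

Two problems are solved:

* **CIS** — scores fixed at 1..k, maximize over the probability vector on
  the simplex.  The primary search runs sequential quadratic programming
  (SLSQP) from several starting points; one of them is the optimum of the
  exact two-variable shift/scale reformulation (see
  :func:`maximize_cis_ab`), which makes the solver immune to the spurious
  boundary optima that plain equal-probability starts can fall into for
  heavily skewed families.
* **OPT** — scores free: Lloyd's fixed-point iteration, whose solution is
  the set of k principal points (optimal quantizer) of the law.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize as sopt

from .distributions import ContinuousModel, partial_moment, second_partial_moment
from .maxcorr import Discretization, MaxCorrResult, max_point_polyserial

__all__ = [
    "OptimizationSettings",
    "CISReformulation",
    "ConvergenceError",
    "maximize_cis",
    "maximize_cis_ab",
    "maximize_opt",
    "threshold_spacing",
    "mse",
]


class ConvergenceError(RuntimeError):
    """The optimizer failed to converge within the iteration budget."""


@dataclass(frozen=True)
class OptimizationSettings:
    tol: float = 1e-10
    max_iter: int = 10000
    init: str = "equal_probs"
    multistart: int = 1
    seed: int | None = None

    def __post_init__(self):
        if not self.tol > 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.multistart < 1:
            raise ValueError("multistart must be >= 1")


@dataclass(frozen=True)
class CISReformulation:
    """Shift/scale parametrization of the CIS optimum (two free variables).

    Support points are ``a + b*i``; the implied cut points are their
    midpoints ``a + b*(i + 1/2)``, i = 1..k-1.
    """

    a: float
    b: float
    k: int

    def __post_init__(self):
        if not self.b > 0:
            raise ValueError("scale b must be positive")

    @property
    def cut_points(self) -> np.ndarray:
        return self.a + self.b * (np.arange(1, self.k) + 0.5)

    def probs(self, model: ContinuousModel) -> np.ndarray:
        cdf_c = np.asarray(model.cdf(self.cut_points), dtype=float)
        cdf_c = np.maximum.accumulate(np.clip(cdf_c, 0.0, 1.0))
        return np.diff(np.concatenate(([0.0], cdf_c, [1.0])))


# ---------------------------------------------------------------------------
# vectorized CIS objective
# ---------------------------------------------------------------------------


def _cis_rho(model: ContinuousModel, probs: np.ndarray) -> float:
    """rho_PP,max on scores 1..k, vectorized via the partial-moment antiderivative."""
    k = probs.size
    p = np.clip(np.asarray(probs, dtype=float), 0.0, 1.0)
    s = p.sum()
    if s <= 0:
        return 0.0
    p = p / s
    i = np.arange(1, k + 1)
    e = float(i @ p)
    v = float(i**2 @ p - e * e)
    if v <= 1e-300:
        return 0.0
    cum = np.cumsum(p)
    cum[-1] = 1.0
    lo, hi = model.support
    q = np.empty(k + 1)
    q[0] = lo
    q[-1] = hi
    inner = np.clip(cum[:-1], 0.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        q[1:-1] = np.where(
            inner <= 0.0, lo, np.where(inner >= 1.0, hi, model.ppf(np.clip(inner, 1e-300, 1 - 1e-16)))
        )
    anti = np.asarray(model._pm1(q), dtype=float)
    mixed = float(i @ np.diff(anti))
    return (mixed - model.mean * e) / (model.std * np.sqrt(v))


def _result_from_probs(model: ContinuousModel, probs: np.ndarray, diagnostics: dict) -> MaxCorrResult:
    probs = np.clip(probs, 0.0, None)
    probs = probs / probs.sum()
    res = max_point_polyserial(model, Discretization.cis(probs))
    return MaxCorrResult(
        rho=res.rho,
        disc=res.disc,
        thresholds=res.thresholds,
        mixed_moment=res.mixed_moment,
        covariance=res.covariance,
        diagnostics=diagnostics,
    )


def maximize_cis_ab(
    model: ContinuousModel,
    k: int,
    settings: OptimizationSettings | None = None,
) -> MaxCorrResult:
    """Solve the CIS problem through its two-variable shift/scale restatement.

    The optimum over probability vectors induces equally spaced thresholds
    on the continuous scale, so the search reduces to a shift ``a`` and a
    scale ``b > 0``; ``b`` is optimized on the log scale to keep it
    positive.
    """
    settings = settings or OptimizationSettings()
    if k < 2:
        raise ValueError("k must be >= 2")
    model.var  # moment existence check

    def objective(t):
        a, logb = t
        ref = CISReformulation(a=float(a), b=float(np.exp(np.clip(logb, -700, 700))), k=k)
        return -_cis_rho(model, ref.probs(model))

    # initialize by least-squares fitting scores to equal-probability quantiles
    scores = np.arange(1, k + 1, dtype=float)
    q = np.asarray(model.ppf((scores - 0.5) / k), dtype=float)
    b0 = max(np.polyfit(scores, q, 1)[0], 1e-8)
    a0 = q.mean() - b0 * (k + 1) / 2.0
    res = sopt.minimize(
        objective,
        np.array([a0, np.log(b0)]),
        method="Nelder-Mead",
        options={
            "xatol": 1e-12,
            "fatol": settings.tol * 1e-3,
            "maxiter": settings.max_iter,
            "maxfev": 4 * settings.max_iter,
        },
    )
    a, b = float(res.x[0]), float(np.exp(res.x[1]))
    ref = CISReformulation(a=a, b=b, k=k)
    diagnostics = {
        "method": "nelder-mead(a,b)",
        "iterations": int(res.nit),
        "converged": bool(res.success),
        "a": a,
        "b": b,
    }
    return _result_from_probs(model, ref.probs(model), diagnostics)


def maximize_cis(
    model: ContinuousModel,
    k: int,
    settings: OptimizationSettings | None = None,
) -> MaxCorrResult:
    """Maximize the maximal point-polyserial correlation over CIS probabilities.

    SLSQP on the probability simplex, run from (i) equal probabilities,
    (ii) the shift/scale optimum, and (iii) ``multistart - 1`` seeded
    Dirichlet(1) jitters; the best objective wins.
    """
    settings = settings or OptimizationSettings()
    if k < 2:
        raise ValueError("k must be >= 2")
    model.var

    def neg(p):
        return -_cis_rho(model, np.asarray(p))

    starts = [np.full(k, 1.0 / k)]
    ab_result = maximize_cis_ab(model, k, settings)
    starts.append(ab_result.disc.probs)
    if settings.multistart > 1:
        rng = np.random.default_rng(settings.seed)
        for _ in range(settings.multistart - 1):
            starts.append(rng.dirichlet(np.ones(k)))

    best = None
    n_ok = 0
    total_iter = 0
    for x0 in starts:
        res = sopt.minimize(
            neg,
            x0,
            method="SLSQP",
            bounds=[(0.0, 1.0)] * k,
            constraints=[{"type": "eq", "fun": lambda p: p.sum() - 1.0}],
            options={"maxiter": settings.max_iter, "ftol": settings.tol * 1e-2},
        )
        total_iter += int(res.nit)
        if res.success:
            n_ok += 1
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None or (n_ok == 0 and not best.success):
        raise ConvergenceError(
            f"CIS optimization failed for {model!r}, k={k}: no start converged"
        )
    diagnostics = {
        "method": "slsqp-simplex",
        "starts": len(starts),
        "converged_starts": n_ok,
        "iterations": total_iter,
        "converged": True,
        "ab_rho": ab_result.rho,
    }
    return _result_from_probs(model, np.asarray(best.x), diagnostics)


def threshold_spacing(model: ContinuousModel, disc: Discretization) -> np.ndarray:
    """Differences of consecutive induced thresholds ``F^-1(F_i)``.

    At a CIS optimum with k >= 4 all entries coincide (equal-threshold
    spacing property); the common value is C/V.
    """
    if disc.k < 3:
        raise ValueError("threshold spacing needs k >= 3")
    inner = disc.cumprobs[:-1]
    t = np.asarray(model.ppf(inner), dtype=float)
    return np.diff(t)


# ---------------------------------------------------------------------------
# OPT problem: Lloyd's algorithm / principal points
# ---------------------------------------------------------------------------


def _cells_from_values(model: ContinuousModel, values: np.ndarray):
    cuts = (values[:-1] + values[1:]) / 2.0
    lo = np.concatenate(([model.support[0]], cuts))
    hi = np.concatenate((cuts, [model.support[1]]))
    return lo, hi, cuts


def maximize_opt(
    model: ContinuousModel,
    k: int,
    settings: OptimizationSettings | None = None,
) -> MaxCorrResult:
    """Free-support maximization: Lloyd fixed point = k principal points.

    Iterates (i) cut points at midpoints of consecutive support values,
    (ii) support values at cell-conditional means, until the largest
    support-value change drops below 1e-10.  The achieved correlation is
    ``sqrt(Var(Xd))/sigma = sqrt(1 - MSE/sigma^2)``.
    """
    settings = settings or OptimizationSettings()
    if k < 2:
        raise ValueError("k must be >= 2")
    sigma = model.std

    values = np.asarray(model.ppf((np.arange(1, k + 1) - 0.5) / k), dtype=float)
    converged = False
    it = 0
    probs = None
    for it in range(1, settings.max_iter + 1):
        lo, hi, _ = _cells_from_values(model, values)
        cdf_hi = np.asarray(model.cdf(hi[:-1]), dtype=float)
        cdf_lo = np.asarray(model.cdf(lo), dtype=float)
        probs = np.diff(np.concatenate(([0.0], cdf_hi, [1.0])))
        anti = np.asarray(model._pm1(np.concatenate((lo[:1], hi))), dtype=float)
        pm = np.diff(anti)
        with np.errstate(invalid="ignore", divide="ignore"):
            new_values = pm / probs
        if not np.all(np.isfinite(new_values)):
            raise ConvergenceError(
                f"Lloyd iteration produced an empty cell for {model!r}, k={k}; "
                "k may exceed the numerical resolution of the tails"
            )
        delta = float(np.max(np.abs(new_values - values)))
        values = new_values
        if delta < 1e-10:
            converged = True
            break
    if not converged:
        raise ConvergenceError(
            f"Lloyd's algorithm did not converge in {settings.max_iter} iterations for "
            f"{model!r}, k={k}"
        )
    lo, hi, cuts = _cells_from_values(model, values)
    probs = np.diff(
        np.concatenate(([0.0], np.asarray(model.cdf(cuts), dtype=float), [1.0]))
    )
    disc = Discretization(values, probs)
    rho = float(np.sqrt(disc.var) / sigma)
    mixed = float(disc.values**2 @ disc.probs)  # E(X Xd) = E(Xd^2) at a Lloyd point
    diagnostics = {"method": "lloyd", "iterations": it, "converged": True}
    return MaxCorrResult(
        rho=rho,
        disc=disc,
        thresholds=cuts,
        mixed_moment=mixed,
        covariance=float(rho * sigma * np.sqrt(disc.var)),
        diagnostics=diagnostics,
    )


def mse(model: ContinuousModel, disc: Discretization) -> float:
    """Expected squared distance from X to the nearest support value.

    Cells are bounded by midpoints of consecutive support values; within a
    cell the squared distance integrates to
    ``int x^2 f - 2 x_i int x f + x_i^2 P(cell)``.  At a Lloyd fixed point
    ``sigma^2 = Var(Xd) + MSE``.
    """
    values = disc.values
    if disc.k == 1:
        lo_all = [model.support[0]]
        hi_all = [model.support[1]]
    else:
        lo_all, hi_all, _ = _cells_from_values(model, values)
    total = 0.0
    for xi, lo, hi in zip(values, lo_all, hi_all):
        p = float(model.cdf(hi) - model.cdf(lo))
        m1 = partial_moment(model, lo, hi)
        m2 = second_partial_moment(model, lo, hi)
        total += m2 - 2.0 * xi * m1 + xi * xi * p
    return float(total)
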