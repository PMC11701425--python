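"""k-point discrete approximations of a continuous law, three ways.

* ``maxcorr_cis`` — the CIS correlation-maximizing probabilities, with the
  scores affinely rescaled to match the first two moments of the parent
  law (the correlation is unchanged by the affine map);
* ``maxcorr_opt`` — the principal points / optimal quantizer (Lloyd);
* ``moment_match`` — the Gaussian-quadrature rule with the density as
  weight, which reproduces the first 2k-1 raw moments exactly
  (Golub-Welsch).

Recurrence coefficients for moment matching are built from exact raw
moments with the Chebyshev algorithm in extended precision (mpmath), then
the Jacobi matrix is diagonalized in double precision.  Raw Hankel
inversion is notoriously ill-conditioned; the extended-precision detour
keeps k <= 12 accurate.
"""

from __future__ import annotations

from dataclasses import dataclass

import mpmath
import numpy as np
from scipy.linalg import eigh_tridiagonal

from .distributions import ContinuousModel, MomentExistenceError
from .maxcorr import Discretization
from .optimize import OptimizationSettings, maximize_cis, maximize_opt, mse

__all__ = [
    "MAX_MOMENT_MATCH_K",
    "ApproximationTable",
    "moment_match",
    "standardized_cis_approx",
    "compare_approximations",
    "step_cdf",
]

MAX_MOMENT_MATCH_K = 12


def _recurrence_from_moments(moments: list[mpmath.mpf], k: int):
    """Chebyshev algorithm: raw moments m_0..m_{2k-1} -> (a_j, b_j) recurrence."""
    a = [mpmath.mpf(0)] * k
    b = [mpmath.mpf(0)] * k
    n = 2 * k
    sigma_prev = [mpmath.mpf(0)] * n
    sigma = list(moments)
    a[0] = moments[1] / moments[0]
    b[0] = moments[0]
    for j in range(1, k):
        sigma_new = [mpmath.mpf(0)] * n
        for ell in range(j, n - j):
            sigma_new[ell] = (
                sigma[ell + 1]
                - a[j - 1] * sigma[ell]
                - b[j - 1] * sigma_prev[ell]
            )
        if sigma_new[j] == 0:
            raise MomentExistenceError("degenerate moment sequence (Hankel ill-conditioning)")
        a[j] = sigma_new[j + 1] / sigma_new[j] - sigma[j] / sigma[j - 1]
        b[j] = sigma_new[j] / sigma[j - 1]
        sigma_prev, sigma = sigma, sigma_new
    return a, b


def moment_match(model: ContinuousModel, k: int) -> Discretization:
    """k-point law matching the first 2k-1 raw moments of ``model``.

    This is the k-node Gaussian quadrature rule for the model's density as
    weight function: nodes are the eigenvalues of the Jacobi matrix built
    from the three-term recurrence, weights the squared first components of
    its eigenvectors.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > MAX_MOMENT_MATCH_K:
        raise ValueError(
            f"moment matching is capped at k={MAX_MOMENT_MATCH_K} "
            "(double precision degrades beyond that); use a smaller k"
        )
    # moment existence check up front (Pareto needs alpha > 2k-1 for the
    # matched moments and > 2k for the weight integrals to behave)
    raw = [model.moment(n) for n in range(2 * k)]
    with mpmath.workdps(80):
        moments = [mpmath.mpf(m) for m in raw]
        a, b = _recurrence_from_moments(moments, k)
        diag = np.array([float(x) for x in a])
        off = np.array([float(mpmath.sqrt(x)) for x in b[1:]])
    vals, vecs = eigh_tridiagonal(diag, off)
    weights = vecs[0, :] ** 2
    order = np.argsort(vals)
    nodes = vals[order]
    weights = np.clip(weights[order], 0.0, None)
    weights = weights / weights.sum()
    return Discretization(nodes, weights)


def standardized_cis_approx(
    model: ContinuousModel,
    k: int,
    settings: OptimizationSettings | None = None,
) -> Discretization:
    """CIS correlation-maximizing law, rescaled to the parent's mean and variance.

    The affine map ``i -> a + b*i`` with ``b = sigma/sqrt(V)`` and
    ``a = mu - b*E`` matches the first two moments and leaves the
    correlation with X untouched.
    """
    res = maximize_cis(model, k, settings)
    disc = res.disc
    b = model.std / np.sqrt(disc.var)
    a = model.mean - b * disc.mean
    return Discretization(a + b * disc.values, disc.probs)


@dataclass(frozen=True)
class ApproximationTable:
    """Side-by-side k-point approximations with their summary statistics."""

    model: ContinuousModel
    k: int
    methods: dict[str, Discretization]
    summaries: dict[str, dict[str, float]]

    def method_names(self) -> list[str]:
        return list(self.methods)


def _summary(model: ContinuousModel, disc: Discretization, matched: int) -> dict[str, float]:
    return {
        "mean": disc.mean,
        "var": disc.var,
        "mse": mse(model, disc),
        "range": float(disc.values[-1] - disc.values[0]),
        "matched_moments": matched,
    }


def compare_approximations(
    model: ContinuousModel,
    k: int,
    settings: OptimizationSettings | None = None,
) -> ApproximationTable:
    """Assemble the three k-point approximations and their summaries."""
    cis = standardized_cis_approx(model, k, settings)
    opt = maximize_opt(model, k, settings).disc
    methods = {"maxcorr_cis": cis, "maxcorr_opt": opt}
    summaries = {
        "maxcorr_cis": _summary(model, cis, 2),
        "maxcorr_opt": _summary(model, opt, 1),
    }
    try:
        mm = moment_match(model, k)
    except (MomentExistenceError, ValueError):
        mm = None
    if mm is not None:
        methods["moment_match"] = mm
        summaries["moment_match"] = _summary(model, mm, 2 * k - 1)
    return ApproximationTable(model=model, k=k, methods=methods, summaries=summaries)


def step_cdf(disc: Discretization) -> tuple[np.ndarray, np.ndarray]:
    """(x, F) evaluation points of the step CDF, for plotting/CSV export."""
    x = np.repeat(disc.values, 2)
    f = np.concatenate(([0.0], np.repeat(disc.cumprobs, 2)[:-1]))
    return x, f
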