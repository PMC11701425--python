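"""Seeded generators of bivariate continuous/ordinal samples.

Monte-Carlo cross-validation of the analytic results: draw a continuous
column by inverse-CDF sampling and an ordinal column as the cell index of
a coupled uniform — the same driver for comonotone pairs, ``1 - U`` for
countermonotone pairs, or a copula-conditional draw.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .copulas import CopulaModel, copula_cdf
from .distributions import ContinuousModel
from .maxcorr import Discretization

__all__ = ["FixtureSpec", "generate_pair"]

DEPENDENCE_KINDS = ("comonotone", "countermonotone", "copula")


@dataclass(frozen=True)
class FixtureSpec:
    model: ContinuousModel
    disc: Discretization
    n: int
    seed: int
    dependence: str = "comonotone"
    copula: CopulaModel | None = field(default=None)

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if self.dependence not in DEPENDENCE_KINDS:
            raise ValueError(f"dependence must be one of {DEPENDENCE_KINDS}")
        if self.dependence == "copula" and self.copula is None:
            raise ValueError("copula dependence requires a CopulaModel")


def _conditional_uniform(cop: CopulaModel, u: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Sample V | U = u by inverting the conditional copula at quantile w."""
    th = cop.theta
    if cop.family == "gauss":
        x = norm.ppf(u)
        return norm.cdf(th * x + np.sqrt(1.0 - th * th) * norm.ppf(w))
    if cop.family == "clayton":
        return (u ** (-th) * (w ** (-th / (1.0 + th)) - 1.0) + 1.0) ** (-1.0 / th)
    if cop.family == "frank":
        num = w * np.expm1(-th)
        den = np.exp(-th * u) - w * np.expm1(-th * u)
        return -np.log1p(num / den) / th
    # gumbel: no closed-form conditional inverse; vectorized bisection on
    # dC/du(u, v) = w, which is monotone increasing in v
    lo = np.full_like(u, 1e-12)
    hi = np.full_like(u, 1.0 - 1e-12)

    def h(v):
        lu = -np.log(u)
        lv = -np.log(v)
        a = lu**th + lv**th
        c = np.exp(-(a ** (1.0 / th)))
        return c * a ** (1.0 / th - 1.0) * lu ** (th - 1.0) / u

    for _ in range(60):
        mid = (lo + hi) / 2.0
        mask = h(mid) < w
        lo = np.where(mask, mid, lo)
        hi = np.where(mask, hi, mid)
    return (lo + hi) / 2.0


def generate_pair(spec: FixtureSpec) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``(continuous sample, ordinal sample)`` of size n, reproducibly.

    The ordinal column holds the 1-based cell index of the coupled uniform
    in the discretization's cumulative probabilities.
    """
    rng = np.random.default_rng(spec.seed)
    u = rng.random(spec.n)
    x = np.asarray(spec.model.ppf(np.clip(u, 1e-16, 1.0 - 1e-16)), dtype=float)
    if spec.dependence == "comonotone":
        v = u
    elif spec.dependence == "countermonotone":
        v = 1.0 - u
    else:
        w = rng.random(spec.n)
        v = _conditional_uniform(spec.copula, np.clip(u, 1e-12, 1 - 1e-12), w)
    cells = np.searchsorted(spec.disc.cumprobs, v, side="left") + 1
    cells = np.clip(cells, 1, spec.disc.k)
    return x, cells.astype(np.int64)
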