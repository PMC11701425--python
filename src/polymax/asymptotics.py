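"""Equal-probability closed forms and their large-k limits.

Each supported family has a printed closed-form expression for the maximal
point-polyserial correlation with a k-category equal-probability CIS
variable, plus an analytic limit as k tends to infinity.  The finite-k
formulas here are written directly from the family-specific sums (not the
generic partial-moment path), which makes them an independent oracle for
the machinery in :mod:`polymax.maxcorr`.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.stats import norm

from .distributions import (
    ContinuousModel,
    Exponential,
    Logistic,
    LogNormal,
    Normal,
    Pareto,
    Power,
    Uniform,
)

__all__ = ["equalprob_maxcorr", "limit_equalprob"]


def _disc_uniform_sd(k: int) -> float:
    return math.sqrt((k * k - 1.0) / 12.0)


def equalprob_maxcorr(model: ContinuousModel, k: int) -> float:
    """Maximal point-polyserial correlation with equal probabilities p_i = 1/k.

    Evaluates the family's closed form; the sums are accumulated with
    compensated (pairwise numpy) summation and are exact matches of the
    generic comonotonic computation.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    sd = _disc_uniform_sd(k)
    if isinstance(model, Uniform):
        return math.sqrt(1.0 - 1.0 / k**2)
    if isinstance(model, Normal):
        i = np.arange(1, k)
        return float(norm.pdf(norm.ppf(i / k)).sum() / sd)
    if isinstance(model, Exponential):
        # rate cancels: correlation is scale invariant
        i = np.arange(2, k + 1)
        mixed = (k * (k + 1) * (1.0 + math.log(k)) / 2.0 - float(i @ np.log(i))) / k
        return float((mixed - (k + 1) / 2.0) / sd)
    if isinstance(model, Pareto):
        a = model.alpha
        model.var  # alpha > 2 required
        i = np.arange(1, k)
        mixed = a / (a - 1.0) * (1.0 + float(((1.0 - i / k) ** ((a - 1.0) / a)).sum()))
        mu = a / (a - 1.0)
        return float((mixed - mu * (k + 1) / 2.0) / (model.std * sd))
    if isinstance(model, Logistic):
        i = np.arange(1, k)
        f = i / k
        mixed = -float((f * np.log(f / (1.0 - f)) + np.log1p(-f)).sum())
        return float(mixed / (model.std * sd))
    if isinstance(model, Power):
        a = model.alpha
        i = np.arange(1, k)
        s = float(((i / k) ** ((a + 1.0) / a)).sum())
        return float((k / 2.0 - 0.5 - s) * math.sqrt(a * (a + 2.0)) / sd)
    raise NotImplementedError(
        f"no equal-probability closed form for family {model.family!r}"
    )


def limit_equalprob(model: ContinuousModel) -> float:
    """Limit as k -> infinity of the equal-probability maximal correlation.

    The limit equals 1 exactly for the uniform law (equivalently the power
    law with shape 1) and is strictly below 1 otherwise.
    """
    if isinstance(model, Uniform):
        return 1.0
    if isinstance(model, Normal):
        return math.sqrt(3.0 / math.pi)
    if isinstance(model, Exponential):
        return math.sqrt(3.0) / 2.0
    if isinstance(model, Pareto):
        a = model.alpha
        model.var
        return math.sqrt(3.0 * a * (a - 2.0)) / (2.0 * a - 1.0)
    if isinstance(model, Logistic):
        return 3.0 / math.pi
    if isinstance(model, Power):
        a = model.alpha
        return math.sqrt(3.0 * a * (a + 2.0)) / (2.0 * a + 1.0)
    if isinstance(model, LogNormal):
        raise NotImplementedError("no closed-form limit for the lognormal family")
    raise NotImplementedError(f"unknown family {model.family!r}")
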