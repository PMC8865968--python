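"""Lifetime performance index and its link to the conforming rate.

The index is ``C_L = (mean - L_X) / sd`` for a lower specification limit
``L_X``.  For the power-hazard model this is

    ``C_L = (gamma1 - (alpha/(beta+1))**(1/(beta+1)) * L_X) / gamma2``,

always below ``gamma1/gamma2`` for ``L_X > 0``.  The conforming rate
``P(X >= L_X)`` depends on the parameters only through ``C_L``:
``P_r = exp(-(gamma1 - gamma2*C_L)**(beta+1))`` — strictly increasing in the
index, so capability demands translate directly into index levels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .distribution import PHFDParams, gamma_constants

__all__ = [
    "TestSpec",
    "c_index",
    "conforming_rate",
    "c_from_rate",
    "l_x_from_c",
    "rate_table",
]


@dataclass(frozen=True)
class TestSpec:
    """A capability demand: lower specification limit ``l_x``, required index
    level ``c``, and significance level ``delta``."""

    __test__ = False  # not a pytest class, despite the name

    l_x: float
    c: float
    delta: float

    def __post_init__(self) -> None:
        if self.l_x <= 0:
            raise ValueError(f"l_x must be positive, got {self.l_x!r}")
        if not 0 < self.delta < 1:
            raise ValueError(f"delta must lie in (0, 1), got {self.delta!r}")


def c_index(params: PHFDParams, l_x: float) -> float:
    """Lifetime performance index of the model at specification limit ``l_x``.

    Equals ``(mean(params) - l_x) / sd(params)`` exactly.
    """
    if l_x < 0:
        raise ValueError(f"l_x must be nonnegative, got {l_x!r}")
    mc = gamma_constants(params.beta)
    scale = params.rate ** (1.0 / (params.beta + 1.0))
    return (mc.gamma1 - scale * l_x) / mc.gamma2


def conforming_rate(c_l, beta: float, alpha: float | None = None):
    """Probability that a lifetime meets the specification, as a function of
    the index ``c_l``.

    The rate is scale-free: ``exp(-(gamma1 - gamma2*c_l)**(beta+1))``.  When
    ``alpha`` is supplied, the unsimplified parameter-dependent expression
    (survival function at the ``l_x`` implied by ``c_l``) is evaluated as a
    cross-check and must agree to 1e-12 — the scale cancels algebraically.

    ``c_l`` above ``gamma1/gamma2`` is a domain error (the implied ``l_x``
    would be negative); ``-inf`` is allowed and maps to 0.
    """
    mc = gamma_constants(beta)
    c_arr = np.asarray(c_l, dtype=float)
    if np.any(c_arr > mc.ratio):
        raise ValueError(
            f"c_l must not exceed gamma1/gamma2 = {mc.ratio!r} at beta={beta!r}"
        )
    base = mc.gamma1 - mc.gamma2 * c_arr
    out = np.exp(-np.power(base, beta + 1.0))
    if alpha is not None:
        # unsimplified route: P_r = S(l_x) with l_x implied by c_l
        params = PHFDParams(alpha=alpha, beta=beta)
        l_x = params.rate ** (-1.0 / (beta + 1.0)) * base
        direct = np.exp(-params.rate * np.power(l_x, beta + 1.0))
        if not np.allclose(direct, out, rtol=0, atol=1e-12, equal_nan=True):
            raise AssertionError("scale-dependent and scale-free rate forms disagree")
    return out if out.ndim else float(out)


def c_from_rate(p_r, beta: float):
    """Index level achieving conforming rate ``p_r``; inverse of
    :func:`conforming_rate`.  Requires ``0 < p_r <= 1``."""
    mc = gamma_constants(beta)
    p_arr = np.asarray(p_r, dtype=float)
    if np.any(p_arr <= 0) or np.any(p_arr > 1):
        raise ValueError("p_r must lie in (0, 1]")
    out = (mc.gamma1 - np.power(-np.log(p_arr), 1.0 / (beta + 1.0))) / mc.gamma2
    return out if out.ndim else float(out)


def l_x_from_c(params: PHFDParams, c_l: float) -> float:
    """Specification limit at which the model attains index ``c_l``; inverse
    of :func:`c_index`.  Requires ``c_l < gamma1/gamma2``."""
    mc = gamma_constants(params.beta)
    if c_l >= mc.ratio:
        raise ValueError(
            f"c_l must be below gamma1/gamma2 = {mc.ratio!r}, got {c_l!r}"
        )
    scale = params.rate ** (-1.0 / (params.beta + 1.0))
    return (mc.gamma1 - mc.gamma2 * c_l) * scale


def rate_table(beta: float, grid) -> pd.DataFrame:
    """Tabulate ``(c_l, p_r)`` over a grid of index values.

    Values are kept at full precision; presentation layers round to 6
    decimals.  An empty grid yields an empty (header-only) table.
    """
    grid = np.asarray(list(grid), dtype=float)
    if grid.size == 0:
        return pd.DataFrame({"c_l": [], "p_r": []})
    return pd.DataFrame({"c_l": grid, "p_r": conforming_rate(grid, beta)})
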