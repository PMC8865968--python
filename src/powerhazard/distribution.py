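"""Power-hazard lifetime distribution.

A positive lifetime ``X`` has a power hazard rate ``h(x) = alpha * x**beta``
with scale ``alpha > 0`` and shape ``beta > -1``.  The survival function is
``S(x) = exp(-alpha * x**(beta+1) / (beta+1))``.  Special cases:

* ``beta = 0``  — exponential with rate ``alpha`` (mean ``1/alpha``);
* ``beta = 1``, ``alpha = 1/lam**2`` — Rayleigh with scale ``lam``;
* general ``beta`` — a Weibull reparameterisation.

The moment constants ``gamma1 = Gamma((beta+2)/(beta+1))`` and
``gamma2 = sqrt(Gamma((beta+3)/(beta+1)) - gamma1**2)`` are the standardised
mean and standard deviation; every capability-index formula in
:mod:`powerhazard.lpi` and :mod:`powerhazard.inference` is expressed through
them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special

__all__ = [
    "PHFDParams",
    "MomentConstants",
    "gamma_constants",
    "hazard",
    "cdf",
    "sf",
    "pdf",
    "quantile",
    "mean",
    "second_moment",
    "sd",
    "sample_iid",
]

#: guard band below which ``beta`` is rejected (the distribution degenerates
#: as ``beta -> -1``).
_BETA_FLOOR = -1.0 + 1e-9


@dataclass(frozen=True)
class PHFDParams:
    """Scale ``alpha`` (units time**-(beta+1)) and shape ``beta`` of the model.

    Construction rejects ``alpha <= 0`` and ``beta <= -1`` (with a small
    guard band); all module functions may then assume valid parameters.
    """

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.alpha) or self.alpha <= 0:
            raise ValueError(f"alpha must be a positive finite real, got {self.alpha!r}")
        if not np.isfinite(self.beta) or self.beta <= _BETA_FLOOR:
            raise ValueError(f"beta must exceed -1, got {self.beta!r}")

    @property
    def rate(self) -> float:
        """``alpha / (beta + 1)`` — the exponent scale of the survival function."""
        return self.alpha / (self.beta + 1.0)


@dataclass(frozen=True)
class MomentConstants:
    """Standardised mean ``gamma1`` and standard deviation ``gamma2``.

    Satisfy ``gamma1 = Gamma((beta+2)/(beta+1))`` and
    ``gamma1**2 + gamma2**2 = Gamma((beta+3)/(beta+1))``.
    """

    beta: float
    gamma1: float
    gamma2: float

    @property
    def ratio(self) -> float:
        """``gamma1 / gamma2`` — the supremum of the performance index."""
        return self.gamma1 / self.gamma2


def gamma_constants(beta: float) -> MomentConstants:
    """Moment constants of the standardised power-hazard distribution.

    Parameters
    ----------
    beta
        Shape parameter, must exceed -1.

    Returns
    -------
    MomentConstants
        ``gamma1 = Gamma((beta+2)/(beta+1))`` and
        ``gamma2 = sqrt(Gamma((beta+3)/(beta+1)) - gamma1**2)``.
    """
    if not np.isfinite(beta) or beta <= _BETA_FLOOR:
        raise ValueError(f"beta must exceed -1, got {beta!r}")
    bp1 = beta + 1.0
    gamma1 = float(np.exp(special.gammaln((beta + 2.0) / bp1)))
    second = float(np.exp(special.gammaln((beta + 3.0) / bp1)))
    radicand = second - gamma1 * gamma1
    if radicand < 0:
        if radicand < -1e-12 * second:
            raise ArithmeticError(
                f"negative variance radicand {radicand!r} at beta={beta!r}"
            )
        radicand = 0.0
    return MomentConstants(beta=beta, gamma1=gamma1, gamma2=float(np.sqrt(radicand)))


def hazard(x, params: PHFDParams):
    """Hazard rate ``alpha * x**beta``.

    ``x = 0`` yields 0 for ``beta > 0`` and ``alpha`` for ``beta = 0``;
    for ``beta < 0`` the hazard diverges at the origin, so ``x = 0`` is a
    domain error.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("hazard requires x >= 0")
    if params.beta < 0 and np.any(x == 0):
        raise ValueError("hazard at x=0 is infinite for beta < 0")
    out = params.alpha * np.power(x, params.beta)
    return out if out.ndim else float(out)


def _cumulative_hazard(x: np.ndarray, params: PHFDParams) -> np.ndarray:
    return params.rate * np.power(x, params.beta + 1.0)


def cdf(x, params: PHFDParams):
    """Distribution function ``1 - exp(-alpha * x**(beta+1) / (beta+1))``."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("cdf requires x >= 0")
    out = -np.expm1(-_cumulative_hazard(x, params))
    return out if out.ndim else float(out)


def sf(x, params: PHFDParams):
    """Survival function, evaluated in log space to avoid underflow."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("sf requires x >= 0")
    out = np.exp(-_cumulative_hazard(x, params))
    return out if out.ndim else float(out)


def pdf(x, params: PHFDParams):
    """Density ``hazard(x) * sf(x)``.

    At ``x = 0``: 0 for ``beta > 0``, ``alpha`` for ``beta = 0``, and ``+inf``
    for ``beta < 0`` (integrable singularity — signalled, not raised).
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("pdf requires x >= 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        log_haz = np.log(params.alpha) + params.beta * np.log(
            x, out=np.full(x.shape, -np.inf), where=x > 0
        )
        out = np.exp(log_haz - _cumulative_hazard(x, params))
    if params.beta < 0:
        out = np.where(x == 0, np.inf, out)
    elif params.beta == 0:
        out = np.where(x == 0, params.alpha, out)
    return out if out.ndim else float(out)


def quantile(u, params: PHFDParams):
    """Inverse cdf: ``x = ((beta+1) * (-log(1-u)) / alpha)**(1/(beta+1))``.

    ``u`` must lie in ``[0, 1]``; ``u = 1`` returns ``+inf``.  Uses
    ``log1p(-u)`` for accuracy near ``u -> 1``.
    """
    u = np.asarray(u, dtype=float)
    if np.any((u < 0) | (u > 1)) or np.any(np.isnan(u)):
        raise ValueError("quantile requires u in [0, 1]")
    with np.errstate(divide="ignore"):
        out = np.power(-np.log1p(-u) / params.rate, 1.0 / (params.beta + 1.0))
    return out if out.ndim else float(out)


def mean(params: PHFDParams) -> float:
    """Expected lifetime ``(alpha/(beta+1))**(-1/(beta+1)) * gamma1``."""
    mc = gamma_constants(params.beta)
    return params.rate ** (-1.0 / (params.beta + 1.0)) * mc.gamma1


def second_moment(params: PHFDParams) -> float:
    """``E[X**2] = (alpha/(beta+1))**(-2/(beta+1)) * Gamma((beta+3)/(beta+1))``."""
    bp1 = params.beta + 1.0
    g = float(np.exp(special.gammaln((params.beta + 3.0) / bp1)))
    return params.rate ** (-2.0 / bp1) * g


def sd(params: PHFDParams) -> float:
    """Lifetime standard deviation ``(alpha/(beta+1))**(-1/(beta+1)) * gamma2``."""
    mc = gamma_constants(params.beta)
    return params.rate ** (-1.0 / (params.beta + 1.0)) * mc.gamma2


def sample_iid(
    params: PHFDParams, n: int, seed: int | np.random.Generator | None = None
) -> np.ndarray:
    """``n`` independent draws by inverse-transform sampling.

    ``seed`` may be an integer (reproducible) or a ``numpy`` Generator.
    """
    if n < 1:
        raise ValueError(f"n must be a positive integer, got {n!r}")
    rng = np.random.default_rng(seed)
    return quantile(rng.random(int(n)), params)
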