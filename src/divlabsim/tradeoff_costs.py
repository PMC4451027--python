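"""Cost trade-off between the two subtasks and single-individual cost optimisation.

An individual that performs subtask A at additional cost ``c_A`` must perform
subtask B at the complementary cost ``c_B`` lying on the power-law constraint
surface ``c_A**alpha + c_B**alpha == k**alpha``.  For a fixed probability ``q``
of choosing subtask A, the average cost ``q*c_A + (1-q)*c_B`` has an interior
minimum for ``alpha < 1``, a corner minimum for ``alpha > 1``, and is linear in
``c_A`` (cost-neutral at ``q == 1/2``) for ``alpha == 1``.

The module also provides ``cost_gradient_term`` -- the contribution of the
cost side to the selection gradient in ``q`` along the optimal-cost curve --
which together with the benefit-side term (``adaptive_dynamics``) determines
the singular points of trait evolution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "TradeOff",
    "CostRegime",
    "OptimalCost",
    "regime_of",
    "complementary_cost",
    "mean_cost",
    "optimal_cost",
    "cost_gradient_term",
    "cost_gradient_limit",
]

#: alpha values within this distance of 1 are treated as the linear regime.
ALPHA_LINEAR_TOL = 1e-12

INTERIOR_OPTIMUM = "interior_optimum"
CORNER_OPTIMUM = "corner_optimum"
NEUTRAL_LINE = "neutral_line"


@dataclass(frozen=True)
class TradeOff:
    """Power-law cost constraint ``c_A**alpha + c_B**alpha == k**alpha``.

    Parameters
    ----------
    k : float
        Maximal additional cost of full specialisation to the wrong task
        (dimensionless payoff units), ``k > 0``.
    alpha : float
        Shape exponent; ``alpha < 1`` penalises generalists (convex constraint),
        ``alpha > 1`` penalises specialists relative to the linear case.
    """

    k: float
    alpha: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.k) and self.k > 0):
            raise ValueError(f"k must be a finite positive real, got {self.k!r}")
        if not (math.isfinite(self.alpha) and self.alpha > 0):
            raise ValueError(f"alpha must be a finite positive real, got {self.alpha!r}")

    @property
    def is_linear(self) -> bool:
        """True when alpha is (numerically) exactly 1."""
        return abs(self.alpha - 1.0) <= ALPHA_LINEAR_TOL

    def to_dict(self) -> dict:
        return {"k": self.k, "alpha": self.alpha}

    @classmethod
    def from_dict(cls, d: dict) -> "TradeOff":
        return cls(k=float(d["k"]), alpha=float(d["alpha"]))


@dataclass(frozen=True)
class CostRegime:
    """Qualitative regime of the cost-minimisation problem.

    ``theta`` encodes the sign of the endpoint limits of the cost gradient
    term: -1 for ``alpha > 1``, 0 for ``alpha == 1``, +1 for ``alpha < 1``.
    """

    label: str
    theta: int

    def __post_init__(self) -> None:
        if self.label not in (INTERIOR_OPTIMUM, CORNER_OPTIMUM, NEUTRAL_LINE):
            raise ValueError(f"unknown regime label {self.label!r}")


def regime_of(t: TradeOff) -> CostRegime:
    """Classify a trade-off into its cost-optimisation regime."""
    if t.is_linear:
        return CostRegime(NEUTRAL_LINE, 0)
    if t.alpha < 1:
        return CostRegime(INTERIOR_OPTIMUM, 1)
    return CostRegime(CORNER_OPTIMUM, -1)


def _check_cost(c_A: float, t: TradeOff) -> float:
    c_A = float(c_A)
    if not math.isfinite(c_A) or c_A < 0 or c_A > t.k:
        raise ValueError(f"c_A must lie in [0, k={t.k}], got {c_A!r}")
    return c_A


def _check_prob(q: float, name: str = "q") -> float:
    q = float(q)
    if not math.isfinite(q) or q < 0 or q > 1:
        raise ValueError(f"{name} must lie in [0, 1], got {q!r}")
    return q


def complementary_cost(c_A: float, t: TradeOff) -> float:
    """Cost of subtask B complementary to ``c_A`` on the constraint surface.

    Returns ``(k**alpha - c_A**alpha)**(1/alpha)``, clipped into ``[0, k]``
    against floating-point round-off.
    """
    c_A = _check_cost(c_A, t)
    if c_A == 0.0:
        return t.k
    if c_A == t.k:
        return 0.0
    a = t.alpha
    # c_B = k * (1 - (c_A/k)**alpha)**(1/alpha), in log space: accurate at
    # both corners, where the plain power form loses all precision.
    u = math.exp(a * (math.log(c_A) - math.log(t.k)))
    if u >= 1.0:
        return 0.0
    return float(t.k * math.exp(math.log1p(-u) / a))


def mean_cost(q: float, c_A: float, t: TradeOff) -> float:
    """Average per-game cost ``q*c_A + (1-q)*c_B`` of an individual."""
    q = _check_prob(q)
    c_A = _check_cost(c_A, t)
    return q * c_A + (1.0 - q) * complementary_cost(c_A, t)


@dataclass(frozen=True)
class OptimalCost:
    """Result of the cost minimisation for a fixed ``q``.

    ``degenerate`` is set when both endpoints are equally optimal
    (``alpha > 1``, ``q == 1/2``) or when the cost is neutral in ``c_A``
    (``alpha == 1``, ``q == 1/2``); the returned ``c_A`` is then the
    deterministic conventional choice ``k``.
    """

    c_A: float
    regime: CostRegime
    degenerate: bool = False


def _interior_optimum(q: float, t: TradeOff) -> float:
    # c = k * (1 + r**(alpha/(1-alpha)))**(-1/alpha) with r = q/(1-q),
    # evaluated in log space so extreme alpha cannot overflow.
    a = t.alpha
    if q == 0.0:
        return t.k
    if q == 1.0:
        return 0.0
    log_r = math.log(q) - math.log1p(-q)
    a2 = a / (1.0 - a) * log_r
    log_c = math.log(t.k) - np.logaddexp(0.0, a2) / a
    return float(math.exp(log_c))


def optimal_cost(q: float, t: TradeOff) -> OptimalCost:
    """Cost strategy minimising :func:`mean_cost` over ``c_A`` in ``[0, k]``.

    For ``alpha < 1`` the minimiser is interior; for ``alpha > 1`` it sits at
    a corner (``k`` for ``q < 1/2``, ``0`` for ``q > 1/2``); for ``alpha == 1``
    the corner rule applies for ``q != 1/2`` and ``c_A`` is cost-neutral at
    ``q == 1/2``.
    """
    q = _check_prob(q)
    regime = regime_of(t)
    if regime.label == INTERIOR_OPTIMUM:
        return OptimalCost(_interior_optimum(q, t), regime)
    # corner / neutral regimes share the endpoint rule
    if q < 0.5:
        return OptimalCost(t.k, regime)
    if q > 0.5:
        return OptimalCost(0.0, regime)
    return OptimalCost(t.k, regime, degenerate=True)


def cost_gradient_term(q: float, t: TradeOff) -> float:
    """Cost-side contribution H(q) to the selection gradient in ``q``.

    Equals minus the derivative, with respect to ``q``, of the minimal average
    cost along the optimal-cost curve:

    ``H(q) = k*(r**(1/(1-alpha)) - 1) * (r**(alpha/(1-alpha)) + 1)**(-1/alpha)``

    with ``r = q/(1-q)``; identically zero for ``alpha == 1``.  Antisymmetric
    about ``q = 1/2`` with finite endpoint limits ``-theta*k`` (q -> 0) and
    ``+theta*k`` (q -> 1); use :func:`cost_gradient_limit` for those.
    """
    q = _check_prob(q)
    if q == 0.0 or q == 1.0:
        raise ValueError("cost_gradient_term is defined on the open interval (0, 1); "
                         "use cost_gradient_limit for the endpoints")
    if t.is_linear:
        return 0.0
    a = t.alpha
    log_r = math.log(q) - math.log1p(-q)
    a1 = log_r / (1.0 - a)
    a2 = a * a1
    log_b = -np.logaddexp(0.0, a2) / a  # log of the shared bracket factor
    # H = k * (exp(a1) - 1) * exp(log_b), with the product expanded so both
    # exponents stay bounded even when a1 alone would overflow.
    return float(t.k * (math.exp(a1 + log_b) - math.exp(log_b)))


def cost_gradient_limit(t: TradeOff, endpoint: int) -> float:
    """Finite limit of :func:`cost_gradient_term` at ``q -> 0`` or ``q -> 1``.

    ``endpoint`` must be 0 or 1; the limits are ``-theta*k`` and ``+theta*k``.
    """
    if endpoint not in (0, 1):
        raise ValueError("endpoint must be 0 or 1")
    theta = regime_of(t).theta
    return theta * t.k if endpoint == 1 else -theta * t.k
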