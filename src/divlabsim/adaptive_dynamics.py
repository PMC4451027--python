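"""Selection gradients, singular points and convergence/branching classification.

Trait evolution by small mutational steps is governed by the selection
gradient of the invasion fitness.  Along the optimal-cost curve the gradient
in ``q`` splits into a benefit-side term ``G(q)`` (expected benefit advantage
of playing A) and a cost-side term ``H(q)`` (``tradeoff_costs``).  Interior
singular points are the roots of ``G(q) + H(q) = 0``; with a symmetric
benefit the central point is ``{q=1/2, c_A=k/2**(1/alpha)}`` and, for
``alpha < 1``, an unstable pair of additional roots can bracket it.

Classification of the central point follows the Jacobian/Hessian criteria of
directional evolution: the Jacobian ``[[dw, -2], [-2, (alpha-1)/c*]]`` decides
convergence stability, and the mutant Hessian ``[[0, -2], [-2, (alpha-1)/c*]]``
is always indefinite, so a convergence-stable central point is always a
branching point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Optional

import numpy as np
from scipy.optimize import brentq
from scipy.special import comb

from .group_game import (
    GameSpec,
    Strategy,
    _advantage_table,
    expected_role_payoffs,
    group_composition_pmf,
)
from .tradeoff_costs import (
    _check_prob,
    cost_gradient_limit,
    cost_gradient_term,
    optimal_cost,
)

__all__ = [
    "SingularPoint",
    "StabilityReport",
    "InvasionVerdict",
    "SelectionGradient",
    "benefit_gradient_term",
    "selection_gradient",
    "find_singular_points",
    "delta_w",
    "delta_w_general",
    "stability_report",
    "critical_k",
    "pure_state_invasibility",
]

CENTRAL = "central"
UNSTABLE_PAIR_MEMBER = "unstable_pair_member"
BOUNDARY_PURE = "boundary_pure"
NEUTRAL_LINE = "neutral_line"

ALL_A = "all_A"
ALL_B = "all_B"


@dataclass(frozen=True)
class InvasionVerdict:
    """Invasibility of a pure resident state by nearby mixed mutants.

    ``margin`` is the first-order fitness barrier: ``G(1) + k`` for the all-A
    state and ``-(G(0) - k)`` for the all-B state.  A negative margin means a
    slightly mixed mutant invades.
    """

    state: str
    margin: float
    invasible: bool


@dataclass(frozen=True)
class SingularPoint:
    """A located equilibrium of trait evolution.

    ``residual`` is ``|G + H|`` at the root for interior points (NaN for
    boundary and neutral-line descriptors); boundary points carry their
    :class:`InvasionVerdict`.
    """

    strategy: Strategy
    kind: str
    residual: float = math.nan
    invasion: Optional[InvasionVerdict] = None


@dataclass(frozen=True)
class StabilityReport:
    """Jacobian/Hessian classification of a singular point.

    For the central point with ``alpha != 1`` the closed forms are used; the
    convergence criterion reads ``delta_w(1/2) * 2**(1/alpha) * (alpha-1)/4 > k``
    and can hold only for ``alpha < 1``.  For ``alpha >= 1`` both matrices are
    indefinite and convergence depends on the mutational covariance, which is
    out of scope here; ``note`` says so explicitly.
    """

    jacobian: Optional[np.ndarray]
    hessian: Optional[np.ndarray]
    delta_w: float
    convergence_stable: bool
    branching_point: bool
    criterion_lhs: float
    note: str = ""
    numeric_fallback: bool = False


class SelectionGradient(NamedTuple):
    dW_dq: float
    dW_dc: float


def benefit_gradient_term(q: float, g: GameSpec) -> float:
    """Expected benefit advantage ``G(q)`` of the focal individual playing A:
    the composition-pmf average of the per-composition advantage.

    Antisymmetric about ``q = 1/2`` (so ``G(1/2) = 0``) for symmetric benefits,
    in both sharing models.
    """
    q = _check_prob(q)
    pmf = group_composition_pmf(q, g)
    return float(pmf @ _advantage_table(g))


def selection_gradient(x: Strategy, g: GameSpec) -> SelectionGradient:
    """Gradient of the invasion fitness in the mutant traits at ``x' = x``.

    ``dW_dq = w_A - w_B``; ``dW_dc = -d(mean cost)/d(c_A)``.  At the corners
    ``c_A in {0, k}`` the one-sided derivative is returned (it may be
    ``+/-inf`` for ``alpha < 1``, reflecting the vertical/flat approach of the
    trade-off curve in the local natural coordinate).
    """
    t = g.trade_off
    if x.c_A > t.k:
        raise ValueError(f"c_A={x.c_A} exceeds k={t.k}")
    w_a, w_b = expected_role_payoffs(x.q, x.c_A, g)
    dW_dq = w_a - w_b

    a = t.alpha
    q, c = x.q, x.c_A
    if t.is_linear:
        dW_dc = 1.0 - 2.0 * q
    elif 0.0 < c < t.k:
        dcbar = q - (1.0 - q) * c ** (a - 1.0) * (t.k**a - c**a) ** ((1.0 - a) / a)
        dW_dc = -dcbar
    elif c == 0.0:
        # one-sided from above, in the natural coordinate c_A
        if q == 1.0:
            dW_dc = -1.0
        elif a < 1:
            dW_dc = math.inf  # c_A**(alpha-1) diverges: increasing c_A pays
        else:
            dW_dc = -q
    else:  # c == k
        if q == 0.0:
            dW_dc = 1.0
        elif a < 1:
            dW_dc = -q
        else:
            dW_dc = -math.inf
    return SelectionGradient(float(dW_dq), float(dW_dc))


def _grad_q_total(q: float, g: GameSpec) -> float:
    """G(q) + H(q) with the finite endpoint limits of H."""
    if q <= 0.0:
        return benefit_gradient_term(0.0, g) + cost_gradient_limit(g.trade_off, 0)
    if q >= 1.0:
        return benefit_gradient_term(1.0, g) + cost_gradient_limit(g.trade_off, 1)
    return benefit_gradient_term(q, g) + cost_gradient_term(q, g.trade_off)


def _require_symmetric(g: GameSpec, what: str) -> None:
    if not g.is_symmetric():
        raise ValueError(
            f"{what} requires a symmetric benefit (beta(i) == beta(N-i)); the supplied "
            "benefit is asymmetric, so the symmetry-based formulas do not apply. "
            "Use the individual-based simulator for asymmetric benefits.")


def find_singular_points(g: GameSpec, grid_points: int = 10_000,
                         xtol: float = 1e-12) -> list[SingularPoint]:
    """All singular points of the two-trait dynamics for a symmetric benefit.

    Interior roots of ``G + H`` are located by a uniform sign-change scan
    (``grid_points`` cells) refined by Brent's method; each root is paired
    with its optimal cost.  The central root ``q = 1/2`` (exact by symmetry)
    is always included.  The two pure boundary states ``{0, k}`` and
    ``{1, 0}`` are appended with their invasion verdicts.  For ``alpha == 1``
    the interior is a neutral line and a single descriptor is returned.
    """
    _require_symmetric(g, "find_singular_points")
    t = g.trade_off
    out: list[SingularPoint] = []

    if t.is_linear:
        out.append(SingularPoint(Strategy(0.5, t.k), NEUTRAL_LINE, residual=0.0))
    else:
        gh = lambda q: _grad_q_total(q, g)
        qs = np.linspace(0.0, 1.0, grid_points + 1)
        vals = np.array([gh(q) for q in qs])
        roots = [0.5]  # exact by symmetry
        for j in range(grid_points):
            lo, hi = qs[j], qs[j + 1]
            if vals[j] == 0.0 and 0.0 < lo < 1.0:
                roots.append(float(lo))
            elif vals[j] * vals[j + 1] < 0.0:
                r = brentq(gh, lo, hi, xtol=xtol)
                roots.append(float(min(max(r, lo), hi)))
        roots = sorted(roots)
        dedup: list[float] = []
        for r in roots:
            if not dedup or abs(r - dedup[-1]) > 1e-9:
                dedup.append(r)
        for r in dedup:
            kind = CENTRAL if abs(r - 0.5) <= 1e-9 else UNSTABLE_PAIR_MEMBER
            c = optimal_cost(r, t).c_A
            res = abs(gh(0.5 if kind == CENTRAL else r))
            out.append(SingularPoint(Strategy(r, c), kind, residual=res))

    out.append(SingularPoint(Strategy(0.0, t.k), BOUNDARY_PURE,
                             invasion=pure_state_invasibility(ALL_B, g)))
    out.append(SingularPoint(Strategy(1.0, 0.0), BOUNDARY_PURE,
                             invasion=pure_state_invasibility(ALL_A, g)))
    return out


def delta_w_general(q: float, g: GameSpec) -> float:
    """Derivative of ``w_A - w_B`` with respect to the resident mixing
    probability, by direct summation of the composition expansion:

    ``sum_i C(N-1,i) q**(i-1) (1-q)**(N-2-i) [i - (N-1)q] Delta_b(i)``.
    """
    q = _check_prob(q)
    N = g.N
    db = _advantage_table(g)
    i = np.arange(N, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = (comb(N - 1, i) * np.power(q, i - 1.0) * np.power(1.0 - q, N - 2.0 - i)
                 * (i - (N - 1) * q) * db)
    return float(np.sum(np.nan_to_num(terms, nan=0.0, posinf=0.0, neginf=0.0)))


def delta_w(g: GameSpec) -> float:
    """``delta_w(1/2)`` via the symmetric closed form
    ``2**(3-N) * sum_i C(N-1,i) * i * Delta_b(i)``; negative for symmetric
    single-peaked benefits in both sharing models."""
    _require_symmetric(g, "delta_w")
    N = g.N
    db = _advantage_table(g)
    i = np.arange(N, dtype=float)
    return float(2.0 ** (3 - N) * np.sum(comb(N - 1, i) * i * db))


def _central_matrices(g: GameSpec) -> tuple[np.ndarray, np.ndarray, float]:
    t = g.trade_off
    dw = delta_w(g)
    c_star = optimal_cost(0.5, t).c_A
    h22 = (t.alpha - 1.0) / c_star
    J = np.array([[dw, -2.0], [-2.0, h22]])
    H = np.array([[0.0, -2.0], [-2.0, h22]])
    return J, H, dw


def _is_indefinite(m: np.ndarray) -> bool:
    ev = np.linalg.eigvalsh(m)
    return bool(ev[0] < 0 < ev[-1])


def stability_report(p: SingularPoint, g: GameSpec) -> StabilityReport:
    """Convergence/branching classification of a singular point.

    Closed forms apply to the central point with ``alpha != 1``; any other
    interior point gets a numeric-Jacobian fallback flagged as such.
    """
    t = g.trade_off
    if p.kind == NEUTRAL_LINE or t.is_linear:
        return StabilityReport(
            jacobian=None, hessian=None, delta_w=math.nan,
            convergence_stable=False, branching_point=False, criterion_lhs=math.nan,
            note="alpha == 1: the cost trait is neutral at q = 1/2, the singular point "
                 "is replaced by a neutral line and the Jacobian classification does "
                 "not apply.")
    if p.kind == CENTRAL:
        _require_symmetric(g, "stability_report")
        J, H, dw = _central_matrices(g)
        a = t.alpha
        lhs = dw * 2.0 ** (1.0 / a) * (a - 1.0) / 4.0
        if a < 1:
            conv = lhs > t.k
            note = ""
        else:
            conv = False
            note = ("alpha >= 1: Jacobian and Hessian are both indefinite; convergence "
                    "then depends on the covariance matrix of mutational steps, which "
                    "is not modelled here.")
        return StabilityReport(jacobian=J, hessian=H, delta_w=dw,
                               convergence_stable=conv,
                               branching_point=_is_indefinite(H),
                               criterion_lhs=lhs, note=note)
    # non-central interior point: numeric Jacobian of the selection gradient
    q0, c0 = p.strategy.q, p.strategy.c_A
    h = 1e-6

    def grad(q: float, c: float) -> np.ndarray:
        sg = selection_gradient(Strategy(min(max(q, 0.0), 1.0),
                                         min(max(c, 0.0), t.k)), g)
        return np.array(sg)

    J = np.empty((2, 2))
    J[:, 0] = (grad(q0 + h, c0) - grad(q0 - h, c0)) / (2 * h)
    J[:, 1] = (grad(q0, c0 + h) - grad(q0, c0 - h)) / (2 * h)
    ev = np.linalg.eigvals(J)
    conv = bool(np.all(ev.real < 0))
    return StabilityReport(jacobian=J, hessian=None, delta_w=math.nan,
                           convergence_stable=conv, branching_point=False,
                           criterion_lhs=math.nan, numeric_fallback=True,
                           note="numeric Jacobian fallback for a non-central point; "
                                "branching classification is only derived for the "
                                "central point.")


def critical_k(alpha: float, g: GameSpec) -> float:
    """Largest ``k`` at which the central point is convergence stable (and
    hence a branching attractor) for the given ``alpha < 1``:
    ``delta_w(1/2) * 2**(1/alpha) * (alpha - 1) / 4``.  Independent of the
    trade-off ``k`` carried by ``g``."""
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"critical_k requires 0 < alpha < 1, got {alpha!r}")
    _require_symmetric(g, "critical_k")
    return delta_w(g) * 2.0 ** (1.0 / alpha) * (alpha - 1.0) / 4.0


def pure_state_invasibility(state: str, g: GameSpec) -> InvasionVerdict:
    """First-order invasibility of the pure resident states.

    The all-A state ``{1, 0}`` is invasible by slightly mixed mutants iff
    ``G(1) + k < 0``; the all-B state ``{0, k}`` iff ``G(0) - k > 0``.  The
    verdict's ``margin`` is sign-normalised so ``invasible == (margin < 0)``
    for both states.
    """
    k = g.trade_off.k
    if state == ALL_A:
        margin = benefit_gradient_term(1.0, g) + k
    elif state == ALL_B:
        margin = -(benefit_gradient_term(0.0, g) - k)
    else:
        raise ValueError(f"state must be {ALL_A!r} or {ALL_B!r}, got {state!r}")
    return InvasionVerdict(state=state, margin=float(margin), invasible=bool(margin < 0))
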