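"""Group benefit, benefit sharing, composition distribution and expected payoffs.

A group of ``N`` individuals produces a total benefit ``beta(i)`` that depends
only on the number ``i`` of members performing subtask A.  Two sharing rules
are supported: model I divides ``beta(i)`` equally among all ``N`` members;
model II divides it between the two task subgroups and then equally within
each, so the scarcer task is better rewarded.

Index conventions (documented on every operation):

* ``i`` in ``benefit_total`` and ``individual_share`` counts A-players in the
  *full* group of ``N``;
* ``i`` in ``benefit_advantage`` and ``group_composition_pmf`` counts
  A-players among the *other* ``N - 1`` group members.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np
from scipy import special

from .tradeoff_costs import TradeOff, _check_prob, complementary_cost

__all__ = [
    "MODEL_I",
    "MODEL_II",
    "BenefitSpec",
    "GameSpec",
    "Strategy",
    "RolePayoffs",
    "benefit_total",
    "individual_share",
    "benefit_advantage",
    "group_composition_pmf",
    "expected_role_payoffs",
    "mean_payoff",
    "invasion_fitness",
]

MODEL_I = "I"
MODEL_II = "II"

_SYMMETRY_TOL = 1e-12


@dataclass(frozen=True)
class BenefitSpec:
    """Total group benefit as a function of the A-player count.

    ``kind='gaussian'`` uses
    ``beta(i) = amplitude/(sigma*sqrt(2*pi)) * exp(-(i-mu)**2/(2*sigma)**2)``.
    Note the ``(2*sigma)**2`` denominator, which is the form used throughout;
    set ``conventional_variance=True`` for the usual ``2*sigma**2``.

    ``kind='table'`` takes an explicit table of ``N + 1`` nonnegative values.
    """

    kind: str = "gaussian"
    amplitude: float = 30.0
    sigma: float = 5.0
    mu: float = 3.5
    table: Optional[tuple] = None
    conventional_variance: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian", "table"):
            raise ValueError(f"benefit kind must be 'gaussian' or 'table', got {self.kind!r}")
        if self.kind == "gaussian":
            if not (self.amplitude > 0 and self.sigma > 0):
                raise ValueError("gaussian benefit requires amplitude > 0 and sigma > 0")
        else:
            if self.table is None:
                raise ValueError("table benefit requires an explicit table")
            tab = tuple(float(v) for v in self.table)
            if len(tab) < 2 or any(v < 0 or not math.isfinite(v) for v in tab):
                raise ValueError("benefit table must hold >= 2 finite nonnegative values")
            object.__setattr__(self, "table", tab)

    @classmethod
    def gaussian(cls, amplitude: float = 30.0, sigma: float = 5.0, mu: float = 3.5,
                 conventional_variance: bool = False) -> "BenefitSpec":
        return cls(kind="gaussian", amplitude=amplitude, sigma=sigma, mu=mu,
                   conventional_variance=conventional_variance)

    @classmethod
    def from_table(cls, table: Sequence[float]) -> "BenefitSpec":
        return cls(kind="table", table=tuple(float(v) for v in table))

    def values(self, N: int) -> np.ndarray:
        """Benefit table ``beta(0..N)`` for a group of size ``N``."""
        if self.kind == "table":
            if len(self.table) != N + 1:
                raise ValueError(
                    f"benefit table has {len(self.table)} entries, expected N+1={N + 1}")
            return np.asarray(self.table, dtype=float)
        i = np.arange(N + 1, dtype=float)
        denom = 2.0 * self.sigma**2 if self.conventional_variance else (2.0 * self.sigma) ** 2
        return (self.amplitude / (self.sigma * math.sqrt(2.0 * math.pi))
                * np.exp(-((i - self.mu) ** 2) / denom))

    def is_symmetric(self, N: int, tol: float = _SYMMETRY_TOL) -> bool:
        """True iff ``beta(i) == beta(N - i)`` for all ``i`` within ``tol``."""
        b = self.values(N)
        scale = max(float(np.max(np.abs(b))), 1.0)
        return bool(np.all(np.abs(b - b[::-1]) <= tol * scale))

    def to_dict(self) -> dict:
        d = {"kind": self.kind}
        if self.kind == "gaussian":
            d.update(amplitude=self.amplitude, sigma=self.sigma, mu=self.mu,
                     conventional_variance=self.conventional_variance)
        else:
            d["table"] = list(self.table)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "BenefitSpec":
        return cls(**d)


@dataclass(frozen=True)
class Strategy:
    """Two-trait phenotype: probability ``q`` of choosing subtask A and the
    cost ``c_A`` assigned to it."""

    q: float
    c_A: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.q) and 0.0 <= self.q <= 1.0):
            raise ValueError(f"q must lie in [0, 1], got {self.q!r}")
        if not (math.isfinite(self.c_A) and self.c_A >= 0.0):
            raise ValueError(f"c_A must be a finite nonnegative real, got {self.c_A!r}")


@dataclass(frozen=True)
class GameSpec:
    """One instance of the group game: size, benefit, sharing rule, trade-off.

    ``half_factor`` keeps the optional factor 1/2 in the model II shares; the
    default drops it, matching the analytical treatment, so that analysis and
    simulation stay directly comparable.
    """

    N: int
    benefit: BenefitSpec
    sharing: str
    trade_off: TradeOff
    half_factor: bool = False

    def __post_init__(self) -> None:
        if int(self.N) != self.N or self.N < 2:
            raise ValueError(f"group size N must be an integer >= 2, got {self.N!r}")
        object.__setattr__(self, "N", int(self.N))
        if self.sharing not in (MODEL_I, MODEL_II):
            raise ValueError(f"sharing must be {MODEL_I!r} or {MODEL_II!r}, got {self.sharing!r}")
        self.benefit.values(self.N)  # validates table length early

    def beta_values(self) -> np.ndarray:
        """``beta(0..N)`` as an array."""
        return self.benefit.values(self.N)

    def share_tables(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-member shares ``(share_A[i], share_B[i])`` indexed by the
        A-count ``i`` of the full group.

        ``share_A[0]`` and ``share_B[N]`` are never paid out (no member of
        that role exists) and are set to 0.
        """
        N = self.N
        beta = self.beta_values()
        if self.sharing == MODEL_I:
            share_a = beta / N
            share_b = beta / N
            share_a = share_a.copy()
            share_b = share_b.copy()
        else:
            i = np.arange(N + 1, dtype=float)
            with np.errstate(divide="ignore", invalid="ignore"):
                share_a = np.where(i > 0, beta / np.maximum(i, 1), 0.0)
                share_b = np.where(i < N, beta / np.maximum(N - i, 1), 0.0)
            if self.half_factor:
                share_a = share_a / 2.0
                share_b = share_b / 2.0
        share_a[0] = 0.0
        share_b[N] = 0.0
        return share_a, share_b

    def is_symmetric(self) -> bool:
        return self.benefit.is_symmetric(self.N)

    def to_dict(self) -> dict:
        return {"N": self.N, "benefit": self.benefit.to_dict(), "sharing": self.sharing,
                "trade_off": self.trade_off.to_dict(), "half_factor": self.half_factor}

    @classmethod
    def from_dict(cls, d: dict) -> "GameSpec":
        return cls(N=int(d["N"]), benefit=BenefitSpec.from_dict(d["benefit"]),
                   sharing=d["sharing"], trade_off=TradeOff.from_dict(d["trade_off"]),
                   half_factor=bool(d.get("half_factor", False)))


def _check_full_count(i: int, g: GameSpec) -> int:
    if int(i) != i or i < 0 or i > g.N:
        raise ValueError(f"i must be an integer in [0, N={g.N}], got {i!r}")
    return int(i)


def benefit_total(i: int, g: GameSpec) -> float:
    """Total group benefit ``beta(i)``; ``i`` counts A-players in the full group."""
    i = _check_full_count(i, g)
    return float(g.beta_values()[i])


def individual_share(i: int, role: str, g: GameSpec) -> float:
    """Benefit share of one member of the given role in a group with ``i``
    A-players (full-group count).

    Role ``'A'`` requires ``i >= 1`` and role ``'B'`` requires ``i <= N - 1``:
    a share is only defined for roles that are actually present.
    """
    i = _check_full_count(i, g)
    if role not in ("A", "B"):
        raise ValueError(f"role must be 'A' or 'B', got {role!r}")
    if role == "A" and i < 1:
        raise ValueError("an A-share requires at least one A-player (i >= 1)")
    if role == "B" and i > g.N - 1:
        raise ValueError("a B-share requires at least one B-player (i <= N-1)")
    share_a, share_b = g.share_tables()
    return float(share_a[i] if role == "A" else share_b[i])


def benefit_advantage(i: int, g: GameSpec) -> float:
    """Benefit advantage ``Delta_b(i) = b_A(i+1) - b_B(i)`` of a focal
    individual playing A instead of B, given ``i`` A-players among the other
    ``N - 1`` group members.

    Antisymmetric -- ``Delta_b(i) == -Delta_b(N-1-i)`` -- whenever the benefit
    is symmetric.
    """
    if int(i) != i or i < 0 or i > g.N - 1:
        raise ValueError(f"i must be an integer in [0, N-1={g.N - 1}], got {i!r}")
    i = int(i)
    share_a, share_b = g.share_tables()
    return float(share_a[i + 1] - share_b[i])


def _advantage_table(g: GameSpec) -> np.ndarray:
    share_a, share_b = g.share_tables()
    return share_a[1:] - share_b[:-1]


def group_composition_pmf(q_bar: float, g: GameSpec) -> np.ndarray:
    """Binomial pmf over the number of A-players among the other ``N - 1``
    members, each independently playing A with probability ``q_bar``.

    Computed term by term (N is small); unlike ``scipy.stats.binom.pmf`` this
    stays well defined for subnormal ``q_bar``.
    """
    q_bar = _check_prob(q_bar, "q_bar")
    i = np.arange(g.N, dtype=float)
    with np.errstate(under="ignore"):
        return (special.comb(g.N - 1, i) * np.power(q_bar, i)
                * np.power(1.0 - q_bar, g.N - 1 - i))


class RolePayoffs(NamedTuple):
    w_A: float
    w_B: float


def expected_role_payoffs(q_bar: float, c_A: float, g: GameSpec) -> RolePayoffs:
    """Expected payoffs of a focal individual playing pure A or pure B against
    a population mixing at ``q_bar``, given its cost allocation ``c_A``."""
    q_bar = _check_prob(q_bar, "q_bar")
    pmf = group_composition_pmf(q_bar, g)
    share_a, share_b = g.share_tables()
    w_a = float(pmf @ share_a[1:]) - c_A
    w_b = float(pmf @ share_b[:-1]) - complementary_cost(c_A, g.trade_off)
    return RolePayoffs(w_a, w_b)


def mean_payoff(s: Strategy, q_bar: float, g: GameSpec) -> float:
    """Expected payoff ``q*w_A + (1-q)*w_B`` of strategy ``s`` in a resident
    population mixing at ``q_bar``."""
    w_a, w_b = expected_role_payoffs(q_bar, s.c_A, g)
    return s.q * w_a + (1.0 - s.q) * w_b


def invasion_fitness(mutant: Strategy, resident: Strategy, g: GameSpec) -> float:
    """Relative fitness of a rare mutant in a monomorphic resident population:
    ``W(x', x) = w(x'; q_res) - w(x; q_res)``; exactly zero for ``x' == x``."""
    return mean_payoff(mutant, resident.q, g) - mean_payoff(resident, resident.q, g)
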