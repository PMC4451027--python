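"""Stochastic individual-based model of the group game.

Each generation, ``groups_per_generation`` groups of ``N`` distinct
individuals are drawn from the well-mixed population; every member commits to
a subtask by an independent Bernoulli draw on its own ``q``, the realised
group benefit is shared out, and each member banks its share minus the cost
of the task it chose.  Realised fitness is the per-game average; individuals
that played no game keep fitness zero.  Reproduction is by ``bouts`` serial
tournaments: of two randomly chosen individuals the fitter one's offspring
replaces the other, mutating both traits with probability ``mutation_prob``
(uniform steps; the cost trait mutates uniformly in the transformed
coordinate ``u = c_A**alpha``).

The inner loops are numba-compiled; a pure-Python twin of the group stage
(``play_generation(..., record_groups=...)``) consumes the generator
identically and is used to audit per-group payout conservation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numba import njit

from .group_game import GameSpec, Strategy, mean_payoff

__all__ = [
    "IBMConfig",
    "PopulationState",
    "Trajectory",
    "BranchingVerdict",
    "initialize_population",
    "play_generation",
    "reproduce_and_mutate",
    "run_simulation",
    "detect_branching",
    "classify_population",
]

BRANCHED = "branched"
NEAR_PURE = "near_pure"
UNDECIDED = "undecided"

#: columns of Trajectory.records
RECORD_COLUMNS = ("generation", "mean_q", "var_q", "mean_c", "var_c",
                  "frac_low", "mean_q_low", "mean_q_high", "mean_c_low", "mean_c_high")


@dataclass(frozen=True)
class IBMConfig:
    """Run parameters of the individual-based model.

    Defaults are the reference parameterisation (population 1000, 1000 groups
    per generation so each individual plays 7 games on average at N=7, 100
    tournament bouts, mutation probability 0.1 with half-width 0.005).
    ``init_c=None`` means the central singular cost ``k/2**(1/alpha)``.
    """

    pop_size: int = 1000
    groups_per_generation: int = 1000
    bouts: int = 100
    mutation_prob: float = 0.1
    epsilon: float = 0.005
    generations: int = 150_000
    seed: int = 0
    init_q: float = 0.5
    init_c: Optional[float] = None
    record_every: int = 100
    store_snapshots: bool = False

    def __post_init__(self) -> None:
        if self.pop_size < 2:
            raise ValueError("pop_size must be >= 2")
        if self.groups_per_generation < 1:
            raise ValueError("groups_per_generation must be >= 1")
        if self.bouts < 0:
            raise ValueError("bouts must be >= 0")
        if not 0.0 <= self.mutation_prob <= 1.0:
            raise ValueError("mutation_prob must lie in [0, 1]")
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if self.generations < 0:
            raise ValueError("generations must be >= 0")
        if not 0.0 <= self.init_q <= 1.0:
            raise ValueError("init_q must lie in [0, 1]")
        if self.record_every < 1:
            raise ValueError("record_every must be >= 1")

    @classmethod
    def desk_scale(cls, **overrides) -> "IBMConfig":
        """Scaled-down defaults that keep the reference dynamics reachable on
        one CPU in seconds: population 300 (groups scaled to keep ~7 games per
        individual per generation), 2e4 generations, and a mutation half-width
        of 0.02 compensating the ~7x shorter run of the mutation-limited
        dynamics."""
        base = dict(pop_size=300, groups_per_generation=300, bouts=100,
                    epsilon=0.02, generations=20_000, record_every=100)
        base.update(overrides)
        return cls(**base)

    def resolve_init_c(self, g: GameSpec) -> float:
        t = g.trade_off
        if self.init_c is None:
            return float(t.k * 2.0 ** (-1.0 / t.alpha))
        if not 0.0 <= self.init_c <= t.k:
            raise ValueError(f"init_c={self.init_c} outside [0, k={t.k}]")
        return float(self.init_c)

    def to_dict(self) -> dict:
        return {
            "pop_size": self.pop_size,
            "groups_per_generation": self.groups_per_generation,
            "bouts": self.bouts,
            "mutation_prob": self.mutation_prob,
            "epsilon": self.epsilon,
            "generations": self.generations,
            "seed": self.seed,
            "init_q": self.init_q,
            "init_c": self.init_c,
            "record_every": self.record_every,
            "store_snapshots": self.store_snapshots,
        }


@dataclass
class PopulationState:
    """Per-individual arrays plus the generator driving the run."""

    q: np.ndarray
    c_A: np.ndarray
    fitness: np.ndarray
    games_played: np.ndarray
    generation: int
    rng: np.random.Generator

    @property
    def size(self) -> int:
        return self.q.shape[0]


@dataclass
class BranchingVerdict:
    """Operational classification of a population (or run endpoint).

    A population counts as branched when the split at ``q = 1/2`` leaves at
    least ``mass_min`` of the individuals on each side with side means below
    ``lo_max`` and above ``hi_min``; near-pure when >= 80% sit on one side
    beyond the same centroid threshold.  Trajectory verdicts additionally
    require the branched state to persist over the last ``persistence``
    recorded snapshots.  Thresholds are reported with every verdict.
    """

    outcome: str
    frac_low: float
    mean_q_low: float
    mean_q_high: float
    mean_c_low: float = math.nan
    mean_c_high: float = math.nan
    onset_generation: Optional[int] = None
    thresholds: dict = field(default_factory=dict)


@dataclass
class Trajectory:
    """Recorded summaries of one simulation run."""

    records: np.ndarray  # shape (n_records, len(RECORD_COLUMNS))
    final: PopulationState
    verdict: BranchingVerdict
    config: IBMConfig
    snapshots: Optional[list] = None  # list of (generation, q copy, c copy)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.records, columns=list(RECORD_COLUMNS))


# --------------------------------------------------------------------------
# kernels


@njit(cache=False)
def _play_groups_kernel(q, c, acc, games, share_a, share_b, n_group, n_groups,
                        alpha, k_alpha, rng):  # pragma: no cover - compiled
    pop = q.shape[0]
    idx = np.empty(n_group, dtype=np.int64)
    tasks = np.empty(n_group, dtype=np.uint8)
    for _ in range(n_groups):
        m = 0
        while m < n_group:
            cand = int(rng.integers(0, pop))
            dup = False
            for j in range(m):
                if idx[j] == cand:
                    dup = True
                    break
            if not dup:
                idx[m] = cand
                m += 1
        i_a = 0
        for j in range(n_group):
            if rng.random() < q[idx[j]]:
                tasks[j] = 1
                i_a += 1
            else:
                tasks[j] = 0
        for j in range(n_group):
            w = idx[j]
            if tasks[j] == 1:
                acc[w] += share_a[i_a] - c[w]
            else:
                acc[w] += share_b[i_a] - (k_alpha - c[w] ** alpha) ** (1.0 / alpha)
            games[w] += 1


@njit(cache=False)
def _tournament_kernel(q, c, fitness, n_bouts, mutation_prob, eps, alpha,
                       k_alpha, rng):  # pragma: no cover - compiled
    pop = q.shape[0]
    for _ in range(n_bouts):
        a = int(rng.integers(0, pop))
        b = int(rng.integers(0, pop - 1))
        if b >= a:
            b += 1
        if fitness[a] > fitness[b]:
            win, lose = a, b
        elif fitness[b] > fitness[a]:
            win, lose = b, a
        elif rng.random() < 0.5:
            win, lose = a, b
        else:
            win, lose = b, a
        q[lose] = q[win]
        c[lose] = c[win]
        fitness[lose] = 0.0
        if mutation_prob > 0.0 and rng.random() < mutation_prob:
            qn = q[win] + (2.0 * rng.random() - 1.0) * eps
            if qn < 0.0:
                qn = 0.0
            elif qn > 1.0:
                qn = 1.0
            q[lose] = qn
            u = c[win] ** alpha + (2.0 * rng.random() - 1.0) * eps
            if u < 0.0:
                u = 0.0
            elif u > k_alpha:
                u = k_alpha
            c[lose] = u ** (1.0 / alpha)


# --------------------------------------------------------------------------
# operations


def initialize_population(cfg: IBMConfig, g: GameSpec) -> PopulationState:
    """Monomorphic population at ``(init_q, init_c)`` with a freshly seeded
    generator; fitness and game counters zeroed."""
    c0 = cfg.resolve_init_c(g)
    pop = cfg.pop_size
    if g.N > pop:
        raise ValueError(f"group size N={g.N} exceeds population size {pop}")
    return PopulationState(
        q=np.full(pop, float(cfg.init_q)),
        c_A=np.full(pop, c0),
        fitness=np.zeros(pop),
        games_played=np.zeros(pop, dtype=np.int64),
        generation=0,
        rng=np.random.default_rng(cfg.seed),
    )


def _play_groups_python(state, g, cfg, rng, acc, games, record_groups):
    """Pure-Python twin of the compiled group stage.

    Consumes the generator in exactly the same order as the kernel, so a run
    with ``record_groups`` is bit-identical to the compiled path while logging
    every realised group for auditing.
    """
    share_a, share_b = g.share_tables()
    t = g.trade_off
    k_alpha = t.k**t.alpha
    pop = state.size
    for _ in range(cfg.groups_per_generation):
        idx: list[int] = []
        while len(idx) < g.N:
            cand = int(rng.integers(0, pop))
            if cand not in idx:
                idx.append(cand)
        tasks = []
        i_a = 0
        for j in idx:
            task = 1 if rng.random() < state.q[j] else 0
            tasks.append(task)
            i_a += task
        payouts = []
        for j, task in zip(idx, tasks):
            if task == 1:
                pay = share_a[i_a] - state.c_A[j]
            else:
                pay = share_b[i_a] - (k_alpha - state.c_A[j] ** t.alpha) ** (1.0 / t.alpha)
            acc[j] += pay
            games[j] += 1
            payouts.append(pay)
        record_groups.append(
            {"members": list(idx), "tasks": list(tasks), "i_A": i_a,
             "payouts": payouts, "beta": float(g.beta_values()[i_a])})


def play_generation(state: PopulationState, g: GameSpec, cfg: IBMConfig,
                    rng: Optional[np.random.Generator] = None,
                    record_groups: Optional[list] = None) -> PopulationState:
    """Play one generation of group games, in place.

    Fitness accumulators and game counters are reset at the start; afterwards
    ``fitness`` holds the per-game average payoff (zero for individuals that
    played no game).  Passing ``record_groups`` (a list) switches to the
    audited pure-Python path, which draws from the generator in the same
    order and appends one dict per realised group.
    """
    if g.N > state.size:
        raise ValueError(f"group size N={g.N} exceeds population size {state.size}")
    rng = state.rng if rng is None else rng
    t = g.trade_off
    acc = np.zeros(state.size)
    games = np.zeros(state.size, dtype=np.int64)
    if record_groups is not None:
        _play_groups_python(state, g, cfg, rng, acc, games, record_groups)
    else:
        share_a, share_b = g.share_tables()
        _play_groups_kernel(state.q, state.c_A, acc, games, share_a, share_b,
                            g.N, cfg.groups_per_generation, t.alpha,
                            t.k**t.alpha, rng)
    played = games > 0
    state.fitness = np.where(played, acc / np.maximum(games, 1), 0.0)
    state.games_played = games
    return state


def reproduce_and_mutate(state: PopulationState, g: GameSpec, cfg: IBMConfig,
                         rng: Optional[np.random.Generator] = None) -> PopulationState:
    """Run the tournament bouts, in place.

    Each bout picks two distinct individuals uniformly; the lower-fitness one
    (ties by fair coin) is replaced immediately by the winner's offspring, so
    later bouts see earlier replacements.  With probability ``mutation_prob``
    the offspring mutates both traits; its fitness is reset to zero.
    """
    rng = state.rng if rng is None else rng
    t = g.trade_off
    _tournament_kernel(state.q, state.c_A, state.fitness, cfg.bouts,
                       cfg.mutation_prob, cfg.epsilon, t.alpha, t.k**t.alpha, rng)
    state.generation += 1
    return state


def _record_row(state: PopulationState, generation: int) -> np.ndarray:
    q, c = state.q, state.c_A
    low = q < 0.5
    n_low = int(low.sum())
    n_high = q.shape[0] - n_low
    return np.array([
        generation,
        q.mean(), q.var(), c.mean(), c.var(),
        n_low / q.shape[0],
        q[low].mean() if n_low else math.nan,
        q[~low].mean() if n_high else math.nan,
        c[low].mean() if n_low else math.nan,
        c[~low].mean() if n_high else math.nan,
    ])


def run_simulation(cfg: IBMConfig, g: GameSpec) -> Trajectory:
    """Full run: generations of {reset -> group games -> tournaments} with
    summary rows every ``record_every`` generations (always including the
    initial state), ending in a branching verdict."""
    state = initialize_population(cfg, g)
    rows = [_record_row(state, 0)]
    snaps = [(0, state.q.copy(), state.c_A.copy())] if cfg.store_snapshots else None
    for gen in range(1, cfg.generations + 1):
        play_generation(state, g, cfg)
        reproduce_and_mutate(state, g, cfg)
        if gen % cfg.record_every == 0 or gen == cfg.generations:
            rows.append(_record_row(state, gen))
            if snaps is not None:
                snaps.append((gen, state.q.copy(), state.c_A.copy()))
    records = np.vstack(rows)
    traj = Trajectory(records=records, final=state, verdict=None, config=cfg,
                      snapshots=snaps)
    traj.verdict = detect_branching(traj)
    return traj


# --------------------------------------------------------------------------
# branching detection


def classify_population(q: np.ndarray, c: Optional[np.ndarray] = None,
                        mass_min: float = 0.2, lo_max: float = 0.25,
                        hi_min: float = 0.75) -> BranchingVerdict:
    """Classify a single population snapshot into branched / near-pure /
    undecided (thresholds are conventions, echoed in the verdict)."""
    q = np.asarray(q, dtype=float)
    if q.size == 0:
        raise ValueError("cannot classify an empty population")
    low = q < 0.5
    frac_low = float(low.mean())
    mean_lo = float(q[low].mean()) if low.any() else math.nan
    mean_hi = float(q[~low].mean()) if (~low).any() else math.nan
    if c is not None:
        c = np.asarray(c, dtype=float)
        mc_lo = float(c[low].mean()) if low.any() else math.nan
        mc_hi = float(c[~low].mean()) if (~low).any() else math.nan
    else:
        mc_lo = mc_hi = math.nan

    thresholds = {"mass_min": mass_min, "lo_max": lo_max, "hi_min": hi_min}
    branched = (mass_min <= frac_low <= 1.0 - mass_min
                and mean_lo < lo_max and mean_hi > hi_min)
    if branched:
        outcome = BRANCHED
    elif (frac_low >= 0.8 and mean_lo < lo_max) or (1.0 - frac_low >= 0.8 and mean_hi > hi_min):
        outcome = NEAR_PURE
    else:
        outcome = UNDECIDED
    return BranchingVerdict(outcome=outcome, frac_low=frac_low,
                            mean_q_low=mean_lo, mean_q_high=mean_hi,
                            mean_c_low=mc_lo, mean_c_high=mc_hi,
                            thresholds=thresholds)


def _row_branched(row: np.ndarray, mass_min: float, lo_max: float, hi_min: float) -> bool:
    frac_low = row[5]
    return (mass_min <= frac_low <= 1.0 - mass_min
            and row[6] < lo_max and row[7] > hi_min)


def detect_branching(obj, mass_min: float = 0.2, lo_max: float = 0.25,
                     hi_min: float = 0.75, persistence: int = 10) -> BranchingVerdict:
    """Branching verdict for a :class:`PopulationState`, a bare ``q`` array,
    or a :class:`Trajectory` (where the branched state must persist over the
    last ``persistence`` recorded snapshots)."""
    if isinstance(obj, Trajectory):
        final = classify_population(obj.final.q, obj.final.c_A,
                                    mass_min, lo_max, hi_min)
        recs = obj.records
        tail = recs[-persistence:]
        sustained = len(recs) >= 1 and all(
            _row_branched(r, mass_min, lo_max, hi_min) for r in tail)
        if sustained and final.outcome == BRANCHED:
            onset = None
            for j in range(len(recs)):
                if all(_row_branched(r, mass_min, lo_max, hi_min) for r in recs[j:]):
                    onset = int(recs[j, 0])
                    break
            final.onset_generation = onset
            return final
        if final.outcome == BRANCHED:  # not yet sustained
            final.outcome = UNDECIDED
        return final
    if isinstance(obj, PopulationState):
        return classify_population(obj.q, obj.c_A, mass_min, lo_max, hi_min)
    return classify_population(np.asarray(obj, dtype=float), None,
                               mass_min, lo_max, hi_min)


def analytic_mean_payoff(q: float, c_A: float, g: GameSpec) -> float:
    """Expected per-game payoff of a monomorphic population -- the analytic
    benchmark the simulator's realised fitness must reproduce."""
    return mean_payoff(Strategy(q, c_A), q, g)
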