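"""Henry-gas-solubility optimization engine.

A population of "gas" agents moves through a box-bounded continuous search
space.  Each agent belongs to a gas cluster sharing one Henry coefficient;
per-iteration the coefficient decays with an exponential temperature schedule,
solubility is the product of the Henry coefficient and the agent's partial
pressure, and positions are attracted to the cluster best and to the
solubility-scaled global best.  A random 10-20% of the worst agents is
re-randomized every iteration to escape local optima.

The engine minimizes.  Wrap ``lambda x: -f(x)`` for maximization.

Randomness contract (one iteration, in order): direction flags (N draws),
step sizes r (N draws), worst-count uniform (1 draw), worst re-init uniforms
(Nw x D draws).  Tests transcribe the update equations independently against
this pinned stream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .exceptions import EvaluationError, ParameterError

__all__ = [
    "SearchSpace",
    "HGSOParams",
    "GasPopulation",
    "OptimizationTrace",
    "assign_clusters",
    "initialize_population",
    "temperature",
    "update_henry",
    "update_solubility",
    "interaction_gamma",
    "update_positions",
    "count_worst",
    "reinitialize_worst",
    "hgso_iteration",
    "run_hgso",
    "diversity",
    "exploration_exploitation",
]

Objective = Callable[[np.ndarray], float]


@dataclass(frozen=True)
class SearchSpace:
    """Box-bounded continuous search space."""

    dim: int
    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        lower = np.broadcast_to(np.asarray(self.lower, dtype=float), (self.dim,)).copy()
        upper = np.broadcast_to(np.asarray(self.upper, dtype=float), (self.dim,)).copy()
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)
        if self.dim < 1:
            raise ParameterError("dim must be >= 1")
        if not np.all(lower < upper):
            raise ParameterError("lower must be < upper elementwise")

    def clamp(self, positions: np.ndarray) -> np.ndarray:
        return np.clip(positions, self.lower, self.upper)


@dataclass(frozen=True)
class HGSOParams:
    """Engine constants.

    ``l1, l2, l3`` scale the initial Henry coefficients, partial pressures and
    temperature-sensitivity constants; ``k``/``alpha``/``beta``/``epsilon``
    are unit-scale defaults (the source formulation leaves them unspecified);
    ``c1 < c2`` bound the worst-agent fraction.
    """

    n_agents: int = 30
    n_clusters: int = 2
    l1: float = 5e-2
    l2: float = 100.0
    l3: float = 1e-2
    k: float = 1.0
    alpha: float = 1.0
    beta: float = 1.0
    epsilon: float = 0.05
    c1: float = 0.1
    c2: float = 0.2
    t_theta: float = 298.15
    max_iter: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_agents < self.n_clusters or self.n_clusters < 1:
            raise ParameterError("need n_agents >= n_clusters >= 1")
        if self.max_iter < 1:
            raise ParameterError("max_iter must be >= 1")
        if not (0.0 <= self.c1 < self.c2 <= 1.0):
            raise ParameterError("need 0 <= c1 < c2 <= 1")
        for name in ("l1", "l2", "l3", "k", "alpha", "beta", "epsilon", "t_theta"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")


@dataclass
class GasPopulation:
    """Mutable optimizer state: positions, per-agent/cluster coefficients, bests."""

    positions: np.ndarray  # (N, D)
    fitness: np.ndarray  # (N,)
    cluster_id: np.ndarray  # (N,) agent -> cluster
    henry: np.ndarray  # (n_clusters,)
    pressure: np.ndarray  # (N,) constant after initialization
    cvals: np.ndarray  # (n_clusters,)
    solubility: np.ndarray  # (N,)
    cluster_best_pos: np.ndarray | None = None  # (n_clusters, D)
    cluster_best_fit: np.ndarray | None = None  # (n_clusters,)
    best_pos: np.ndarray | None = None
    best_fit: float = math.inf

    @property
    def n_agents(self) -> int:
        return self.positions.shape[0]


@dataclass
class OptimizationTrace:
    """Per-iteration diagnostics of one optimizer run."""

    best_fitness: np.ndarray
    div: np.ndarray
    temperature: np.ndarray
    exploration_pct: np.ndarray
    exploitation_pct: np.ndarray
    initial_fitness: float = math.inf

    def __len__(self) -> int:
        return len(self.best_fitness)

    def to_rows(self) -> list[dict]:
        return [
            {
                "iteration": t + 1,
                "best_fitness": float(self.best_fitness[t]),
                "div": float(self.div[t]),
                "exploration_pct": float(self.exploration_pct[t]),
                "exploitation_pct": float(self.exploitation_pct[t]),
                "temperature": float(self.temperature[t]),
            }
            for t in range(len(self))
        ]


def assign_clusters(n_agents: int, n_clusters: int) -> np.ndarray:
    """Contiguous near-equal partition; any remainder goes to the first clusters."""
    if n_clusters > n_agents:
        raise ParameterError(f"n_clusters {n_clusters} > n_agents {n_agents}")
    base, rem = divmod(n_agents, n_clusters)
    sizes = [base + (1 if j < rem else 0) for j in range(n_clusters)]
    return np.repeat(np.arange(n_clusters), sizes)


def initialize_population(
    space: SearchSpace, params: HGSOParams, rng: np.random.Generator
) -> GasPopulation:
    """Uniform positions in the box; H, P, C scaled uniforms; S = K*H*P."""
    n, d = params.n_agents, space.dim
    positions = space.lower + rng.random((n, d)) * (space.upper - space.lower)
    henry = params.l1 * rng.random(params.n_clusters)
    pressure = params.l2 * rng.random(n)
    cvals = params.l3 * rng.random(params.n_clusters)
    cluster_id = assign_clusters(n, params.n_clusters)
    solubility = params.k * henry[cluster_id] * pressure
    return GasPopulation(
        positions=positions,
        fitness=np.full(n, math.inf),
        cluster_id=cluster_id,
        henry=henry,
        pressure=pressure,
        cvals=cvals,
        solubility=solubility,
    )


def temperature(t: int, max_iter: int) -> float:
    """Exponentially decaying schedule ``exp(-t / max_iter)``."""
    if not 1 <= t <= max_iter:
        raise ParameterError(f"iteration {t} outside [1, {max_iter}]")
    return math.exp(-t / max_iter)


def update_henry(henry_j: float, c_j: float, temp: float, t_theta: float) -> float:
    """Van't Hoff-style decay of the Henry coefficient at temperature ``temp``."""
    if temp <= 0:
        raise ParameterError(f"temperature must be > 0, got {temp}")
    return henry_j * math.exp(-c_j * (1.0 / temp - 1.0 / t_theta))


def update_solubility(k: float, henry_j, pressure_ij):
    """Solubility is proportional to Henry coefficient times partial pressure."""
    return k * henry_j * pressure_ij


def interaction_gamma(f_best: float, f_ij: float, beta: float, epsilon: float):
    """Interaction ability ``beta * exp(-(F_best + eps) / (F_agent + eps))``."""
    denom = f_ij + epsilon
    if np.any(np.asarray(denom) <= 0):
        raise ParameterError("agent fitness + epsilon must be > 0")
    return beta * np.exp(-(f_best + epsilon) / denom)


def update_positions(
    pop: GasPopulation,
    space: SearchSpace,
    params: HGSOParams,
    rng: np.random.Generator,
) -> None:
    """One attraction step toward cluster bests and the solubility-scaled global best.

    Per agent: a direction flag F = +-1 and a step size r ~ U(0,1), then
    ``x += F*r*gamma*(x_cluster_best - x) + F*r*alpha*(S*x_best - x)``,
    clamped to the box.  Draw order: all N flags, then all N step sizes.
    """
    flags = np.where(rng.random(pop.n_agents) < 0.5, 1.0, -1.0)
    steps = rng.random(pop.n_agents)
    gamma = interaction_gamma(pop.best_fit, pop.fitness, params.beta, params.epsilon)
    cb = pop.cluster_best_pos[pop.cluster_id]  # (N, D)
    fr = (flags * steps)[:, None]
    pop.positions = space.clamp(
        pop.positions
        + fr * gamma[:, None] * (cb - pop.positions)
        + fr * params.alpha * (pop.solubility[:, None] * pop.best_pos - pop.positions)
    )


def count_worst(
    n_agents: int, rng: np.random.Generator, c1: float = 0.1, c2: float = 0.2
) -> int:
    """Random worst-agent count in ``[floor(c1*N), floor(c2*N)]`` (floor rule).

    At least one agent is replaced when the population has >= 10 agents.
    """
    nw = int(math.floor(n_agents * (rng.random() * (c2 - c1) + c1)))
    if n_agents >= 10:
        nw = max(nw, 1)
    return nw


def reinitialize_worst(
    pop: GasPopulation,
    n_worst: int,
    space: SearchSpace,
    rng: np.random.Generator,
) -> np.ndarray:
    """Re-draw the ``n_worst`` highest-fitness agents uniformly in the box.

    Ties are broken by agent index (lowest index replaced first).  Returns the
    replaced agent indices; their fitness is marked stale (+inf) for
    re-evaluation.
    """
    if not 0 <= n_worst <= pop.n_agents:
        raise ParameterError(f"n_worst {n_worst} outside [0, {pop.n_agents}]")
    if n_worst == 0:
        return np.empty(0, dtype=int)
    order = np.argsort(-pop.fitness, kind="stable")
    worst = order[:n_worst]
    pop.positions[worst] = space.lower + rng.random((n_worst, space.dim)) * (
        space.upper - space.lower
    )
    pop.fitness[worst] = math.inf
    return worst


def diversity(positions: np.ndarray) -> float:
    """Mean absolute deviation from the per-dimension median, averaged over dimensions."""
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    med = np.median(positions, axis=0)
    return float(np.mean(np.abs(med[None, :] - positions)))


def exploration_exploitation(div_series: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    """Percent exploration ``Div/Div_max*100`` and its complement, per iteration."""
    div = np.asarray(div_series, dtype=float)
    div_max = float(np.max(div)) if div.size else 0.0
    if div_max <= 0:
        raise ParameterError("diversity series is all zero; percentages undefined")
    exploration = div / div_max * 100.0
    exploitation = np.abs(div - div_max) / div_max * 100.0
    return exploration, exploitation


def _evaluate(objective: Objective, pop: GasPopulation, idx: np.ndarray) -> None:
    for i in idx:
        value = float(objective(pop.positions[i]))
        if not math.isfinite(value):
            raise EvaluationError(f"objective returned non-finite value for agent {i}")
        pop.fitness[i] = value


def _refresh_bests(pop: GasPopulation, n_clusters: int) -> None:
    if pop.cluster_best_pos is None:
        pop.cluster_best_pos = np.empty((n_clusters, pop.positions.shape[1]))
        pop.cluster_best_fit = np.full(n_clusters, math.inf)
    for j in range(n_clusters):
        members = np.flatnonzero(pop.cluster_id == j)
        i = members[np.argmin(pop.fitness[members])]
        if pop.fitness[i] <= pop.cluster_best_fit[j]:
            pop.cluster_best_fit[j] = pop.fitness[i]
            pop.cluster_best_pos[j] = pop.positions[i].copy()
    j_best = int(np.argmin(pop.cluster_best_fit))
    if pop.cluster_best_fit[j_best] <= pop.best_fit:
        pop.best_fit = float(pop.cluster_best_fit[j_best])
        pop.best_pos = pop.cluster_best_pos[j_best].copy()


def hgso_iteration(
    pop: GasPopulation,
    space: SearchSpace,
    params: HGSOParams,
    objective: Objective,
    rng: np.random.Generator,
    t: int,
) -> float:
    """One full loop iteration; returns the temperature used.

    Order: move positions toward bests, evaluate, decay Henry coefficients,
    refresh solubility, replace and re-evaluate the worst agents, refresh
    cluster/global bests.
    """
    update_positions(pop, space, params, rng)
    _evaluate(objective, pop, np.arange(pop.n_agents))
    temp = temperature(t, params.max_iter)
    for j in range(params.n_clusters):
        pop.henry[j] = update_henry(pop.henry[j], pop.cvals[j], temp, params.t_theta)
    pop.solubility = update_solubility(
        params.k, pop.henry[pop.cluster_id], pop.pressure
    )
    nw = count_worst(pop.n_agents, rng, params.c1, params.c2)
    replaced = reinitialize_worst(pop, nw, space, rng)
    if replaced.size:
        _evaluate(objective, pop, replaced)
    _refresh_bests(pop, params.n_clusters)
    return temp


def run_hgso(
    objective: Objective,
    space: SearchSpace,
    params: HGSOParams,
    *,
    initial_positions: np.ndarray | None = None,
) -> tuple[np.ndarray, float, OptimizationTrace]:
    """Run the full engine for ``params.max_iter`` iterations.

    Returns the best-so-far position, its fitness, and the per-iteration
    trace.  Deterministic given ``params.seed``.  ``initial_positions``
    optionally overwrites the leading rows of the random initial population
    (used by the hybrid hand-off).
    """
    rng = np.random.default_rng(params.seed)
    pop = initialize_population(space, params, rng)
    if initial_positions is not None:
        seeded = space.clamp(np.atleast_2d(np.asarray(initial_positions, dtype=float)))
        pop.positions[: len(seeded)] = seeded
    _evaluate(objective, pop, np.arange(pop.n_agents))
    _refresh_bests(pop, params.n_clusters)
    initial_best = pop.best_fit

    best_hist, div_hist, temp_hist = [], [], []
    for t in range(1, params.max_iter + 1):
        temp = hgso_iteration(pop, space, params, objective, rng, t)
        best_hist.append(pop.best_fit)
        div_hist.append(diversity(pop.positions))
        temp_hist.append(temp)

    div_arr = np.asarray(div_hist)
    if np.max(div_arr) > 0:
        expl, expt = exploration_exploitation(div_arr)
    else:  # fully collapsed population; percentages are undefined
        expl = np.full(len(div_arr), math.nan)
        expt = np.full(len(div_arr), math.nan)
    trace = OptimizationTrace(
        best_fitness=np.asarray(best_hist),
        div=div_arr,
        temperature=np.asarray(temp_hist),
        exploration_pct=expl,
        exploitation_pct=expt,
        initial_fitness=initial_best,
    )
    return pop.best_pos.copy(), float(pop.best_fit), trace
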