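"""Aquila-style population optimizer and the hybrid hand-off to the gas engine.

The optimizer switches from exploration to exploitation once two thirds of the
iteration budget has elapsed.  Within each phase one of two canonical update
rules is chosen at random per agent: expanded/narrowed exploration (global
best with population mean / Levy-flight spiral around a random peer) and
expanded/narrowed exploitation (best-mean blend / quality-function dive).
The rule internals are not fixed by the framework here, so all coefficients
are configurable on :class:`AQOParams`.

Minimization convention, greedy replacement: a candidate position replaces an
agent only when it improves the agent's fitness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .exceptions import EvaluationError, ParameterError
from .hgso_core import (
    HGSOParams,
    Objective,
    OptimizationTrace,
    SearchSpace,
    diversity,
    exploration_exploitation,
    run_hgso,
)

__all__ = ["AQOParams", "initialize_aqo", "phase", "run_aqo", "run_hybrid"]


@dataclass(frozen=True)
class AQOParams:
    """Aquila optimizer settings; rule coefficients follow the canonical source."""

    n_agents: int = 20
    max_iter: int = 100
    seed: int = 0
    alpha: float = 0.1  # expanded-exploitation shrink
    delta: float = 0.1  # expanded-exploitation shrink
    levy_beta: float = 1.5
    spiral_r1: float = 10.0
    spiral_u: float = 0.00565
    spiral_omega: float = 0.005

    def __post_init__(self) -> None:
        if self.n_agents < 2:
            raise ParameterError("n_agents must be >= 2")
        if self.max_iter < 1:
            raise ParameterError("max_iter must be >= 1")


def initialize_aqo(
    space: SearchSpace, params: AQOParams, rng: np.random.Generator
) -> np.ndarray:
    """Uniform initial population ``LB + rand(1,D) * (UB - LB)``."""
    return space.lower + rng.random((params.n_agents, space.dim)) * (
        space.upper - space.lower
    )


def phase(t: int, max_iter: int) -> str:
    """``"exploration"`` iff ``t <= (2/3) * max_iter`` (inclusive), else ``"exploitation"``."""
    if not 1 <= t <= max_iter:
        raise ParameterError(f"iteration {t} outside [1, {max_iter}]")
    return "exploration" if t <= (2.0 / 3.0) * max_iter else "exploitation"


def _levy(dim: int, beta: float, rng: np.random.Generator) -> np.ndarray:
    num = math.gamma(1 + beta) * math.sin(math.pi * beta / 2)
    den = math.gamma((1 + beta) / 2) * beta * 2 ** ((beta - 1) / 2)
    sigma = (num / den) ** (1 / beta)
    u = rng.standard_normal(dim) * sigma
    v = rng.standard_normal(dim)
    return 0.01 * u / np.abs(v) ** (1 / beta)


def _spiral(dim: int, params: AQOParams) -> tuple[np.ndarray, np.ndarray]:
    d1 = np.arange(1, dim + 1, dtype=float)
    r = params.spiral_r1 + params.spiral_u * d1
    theta = -params.spiral_omega * d1 + 3 * math.pi / 2
    return r * np.sin(theta), r * np.cos(theta)  # x, y


def run_aqo(
    objective: Objective, space: SearchSpace, params: AQOParams
) -> tuple[np.ndarray, float, OptimizationTrace]:
    """Run the Aquila loop for ``params.max_iter`` iterations (deterministic per seed)."""
    rng = np.random.default_rng(params.seed)
    pos = initialize_aqo(space, params, rng)
    fit = np.empty(params.n_agents)
    for i in range(params.n_agents):
        fit[i] = _checked(objective, pos[i], i)
    i_best = int(np.argmin(fit))
    best_pos, best_fit = pos[i_best].copy(), float(fit[i_best])
    initial_best = best_fit

    x_spiral, y_spiral = _spiral(space.dim, params)
    best_hist, div_hist = [], []
    for t in range(1, params.max_iter + 1):
        mean_pos = pos.mean(axis=0)
        exploring = phase(t, params.max_iter) == "exploration"
        for i in range(params.n_agents):
            if exploring:
                if rng.random() < 0.5:
                    cand = best_pos * (1 - t / params.max_iter) + (
                        mean_pos - best_pos * rng.random()
                    )
                else:
                    peer = pos[rng.integers(params.n_agents)]
                    cand = (
                        best_pos * _levy(space.dim, params.levy_beta, rng)
                        + peer
                        + (y_spiral - x_spiral) * rng.random()
                    )
            else:
                if rng.random() < 0.5:
                    cand = (best_pos - mean_pos) * params.alpha - rng.random() + (
                        (space.upper - space.lower) * rng.random() + space.lower
                    ) * params.delta
                else:
                    qf = t ** ((2 * rng.random() - 1) / (1 - params.max_iter) ** 2)
                    g1 = 2 * rng.random() - 1
                    g2 = 2 * (1 - t / params.max_iter)
                    cand = (
                        qf * best_pos
                        - pos[i] * g1 * rng.random()
                        - g2 * _levy(space.dim, params.levy_beta, rng)
                        + rng.random() * g1
                    )
            cand = space.clamp(cand)
            cand_fit = _checked(objective, cand, i)
            if cand_fit < fit[i]:
                pos[i], fit[i] = cand, cand_fit
                if cand_fit < best_fit:
                    best_fit, best_pos = cand_fit, cand.copy()
        best_hist.append(best_fit)
        div_hist.append(diversity(pos))

    div_arr = np.asarray(div_hist)
    if np.max(div_arr) > 0:
        expl, expt = exploration_exploitation(div_arr)
    else:
        expl = np.full(len(div_arr), math.nan)
        expt = np.full(len(div_arr), math.nan)
    trace = OptimizationTrace(
        best_fitness=np.asarray(best_hist),
        div=div_arr,
        temperature=np.full(len(div_arr), math.nan),
        exploration_pct=expl,
        exploitation_pct=expt,
        initial_fitness=initial_best,
    )
    return best_pos, best_fit, trace


def _checked(objective: Objective, x: np.ndarray, i: int) -> float:
    value = float(objective(x))
    if not math.isfinite(value):
        raise EvaluationError(f"objective returned non-finite value for agent {i}")
    return value


def run_hybrid(
    objective: Objective,
    space: SearchSpace,
    aqo_params: AQOParams,
    hgso_params: HGSOParams,
) -> tuple[np.ndarray, float, OptimizationTrace]:
    """Sequential hand-off: Aquila for the first half of the combined budget,
    then its best position seeds the gas-solubility population for the rest.

    ``max_iter`` on each params object is reinterpreted as the total budget;
    each stage receives half (Aquila gets the ceiling).
    """
    total = max(aqo_params.max_iter, hgso_params.max_iter)
    t_aqo = max(1, math.ceil(total / 2))
    t_hgso = max(1, total - t_aqo)
    aqo = AQOParams(**{**aqo_params.__dict__, "max_iter": t_aqo})
    best_a, _, trace_a = run_aqo(objective, space, aqo)
    hgso = HGSOParams(**{**hgso_params.__dict__, "max_iter": t_hgso})
    best, best_fit, trace_h = run_hgso(
        objective, space, hgso, initial_positions=best_a[None, :]
    )
    best_fitness = np.minimum.accumulate(
        np.concatenate([trace_a.best_fitness, trace_h.best_fitness])
    )
    div = np.concatenate([trace_a.div, trace_h.div])
    if np.max(div) > 0:
        expl, expt = exploration_exploitation(div)
    else:
        expl = np.full(len(div), math.nan)
        expt = np.full(len(div), math.nan)
    trace = OptimizationTrace(
        best_fitness=best_fitness,
        div=div,
        temperature=np.concatenate([trace_a.temperature, trace_h.temperature]),
        exploration_pct=expl,
        exploitation_pct=expt,
        initial_fitness=trace_a.initial_fitness,
    )
    return best, float(best_fitness[-1]), trace
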