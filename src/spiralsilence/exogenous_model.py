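"""Model 1: probabilistic belief expression versus local-majority conformity.

When an agent is selected it voices its private belief with probability σ
(the strength of the belief); otherwise it conforms to the sign of the sum
of its neighbors' currently expressed opinions.  A zero sum is resolved by
a fair coin *if* at least one neighbor has ever expressed a non-null
opinion; if no neighbor has ever spoken the agent emits the null opinion
ω = 0.  Silence is therefore only an initial-stage state here, not a
choice — the distinction with the goal-function model, where staying
silent is a deliberate best response.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from . import _kernels
from ._dynamics import (
    DEFAULT_HORIZON,
    DEFAULT_TOLERANCE,
    DEFAULT_WINDOW,
    Trajectory,
    draw_step_randoms,
    run_dynamics,
)
from .netgen import Graph, Population

__all__ = [
    "ElementaryStepRecord",
    "exogenous_expression",
    "time_unit_exogenous",
    "run_exogenous",
]


@dataclass(frozen=True)
class ElementaryStepRecord:
    """Bookkeeping for one elementary step of the conformity dynamics."""

    agent: int
    branch: Literal["belief", "conformity"]
    omega_out: int


def _expression_step(
    i: int, pop: Population, graph: Graph, u_branch: float, u_coin: float
) -> ElementaryStepRecord:
    """Pure step given explicit uniform draws (shared by API and oracle tests)."""
    if graph.degree[i] == 0:
        raise RuntimeError("isolated node encountered; generator guarantees degree >= 2")
    if u_branch < pop.sigma[i]:
        pop.omega[i] = pop.b[i]
        pop.has_expressed[i] = True
        return ElementaryStepRecord(agent=i, branch="belief", omega_out=int(pop.b[i]))
    nbrs = graph.neighbors(i)
    s = int(pop.omega[nbrs].sum())
    if s > 0:
        out = 1
    elif s < 0:
        out = -1
    elif bool(pop.has_expressed[nbrs].any()):
        out = 1 if u_coin < 0.5 else -1
    else:
        out = 0
    pop.omega[i] = out
    if out != 0:
        pop.has_expressed[i] = True
    return ElementaryStepRecord(agent=i, branch="conformity", omega_out=out)


def exogenous_expression(
    i: int, pop: Population, graph: Graph, rng: np.random.Generator
) -> ElementaryStepRecord:
    """Apply one elementary step to agent ``i`` (mutates ``pop``).

    With probability σ_i the agent expresses its belief; otherwise it
    adopts the sign of the summed neighbor opinions, coin-flipping exact
    ties among neighbors that have expressed, and staying null when no
    neighbor ever has.
    """
    if not (0 <= i < pop.n):
        raise IndexError(f"agent index {i} out of range")
    return _expression_step(i, pop, graph, float(rng.random()), float(rng.random()))


def time_unit_exogenous(pop: Population, graph: Graph, rng: np.random.Generator) -> Population:
    """Perform N elementary steps on uniformly chosen agents (in place)."""
    agents, u_branch, u_coin = draw_step_randoms(pop.n, rng)
    _kernels.exogenous_steps(
        graph.indptr,
        graph.indices,
        pop.b,
        pop.sigma,
        pop.omega,
        pop.has_expressed,
        agents,
        u_branch,
        u_coin,
    )
    return pop


def run_exogenous(
    graph: Graph,
    pop: Population,
    rng: np.random.Generator,
    horizon: int = DEFAULT_HORIZON,
    stationarity: tuple[int, float] = (DEFAULT_WINDOW, DEFAULT_TOLERANCE),
) -> Trajectory:
    """Run the conformity dynamics to stationarity or the horizon."""
    return run_dynamics(graph, pop, time_unit_exogenous, rng, horizon, stationarity)
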