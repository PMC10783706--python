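"""Model 2: goal-function best response with a first-class silence option.

Each selected agent chooses the expressed opinion ω ∈ {−1, 0, +1} that
maximizes

    G(ω) = −| σ·b + (Σ_{j∈Γ} A_ij ω_j)/(m + 1)  −  ω |

where A_ij = deg(j)/deg(i) weights a neighbor's voice by its relative
connectivity ("charisma") and m = Σ_j |ω_j| counts the currently
non-silent neighbors.  Maximizing G is equivalent to picking the candidate
nearest to the anchor v = σ·b + social term, so an agent whose private
pull and social pull nearly cancel (|v| < 1/2) prefers silence — the
mechanism behind the silencing cascade.

The typeset goal function is ambiguous about what the (m + 1) denominator
divides.  Two readings are implemented: ``"full"`` (the default) divides
the whole anchor, private term included, v = (σ·b + Σ A_ij ω_j)/(m + 1);
``"social"`` attaches the denominator to the social sum only,
v = σ·b + (Σ A_ij ω_j)/(m + 1).  The full parse is the default because it
is the only one of the two under which a macroscopic spiral of silence
develops — under the social parse the belief drive σ·b is never damped,
expression cascades, and silence all but disappears.

Hard-core agents bypass the maximization entirely: they always voice
their private opinion −1, regardless of the opinion climate around them.
"""

from __future__ import annotations

from dataclasses import dataclass

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
    "GoalEvaluation",
    "PARSE_VARIANTS",
    "influence_weight",
    "expressing_count",
    "goal",
    "best_response",
    "time_unit_endogenous",
    "run_endogenous",
]

PARSE_VARIANTS = {"social": _kernels.PARSE_SOCIAL, "full": _kernels.PARSE_FULL}
CANDIDATES = (-1, 0, 1)


@dataclass(frozen=True)
class GoalEvaluation:
    """Payoff of one candidate expressed opinion under the goal function."""

    candidate: int
    payoff: float
    anchor: float


def _parse_code(parse: str) -> int:
    try:
        return PARSE_VARIANTS[parse]
    except KeyError:
        raise ValueError(f"unknown parse variant {parse!r}; use 'social' or 'full'") from None


def influence_weight(graph: Graph, i: int, j: int) -> float:
    """Influence of neighbor j on agent i: deg(j)/deg(i)."""
    if j not in graph.neighbors(i):
        raise ValueError(f"node {j} is not a neighbor of {i}")
    return float(graph.degree[j]) / float(graph.degree[i])


def expressing_count(pop: Population, graph: Graph, i: int) -> int:
    """m = Σ_{j∈Γ_i} |ω_j|, the number of non-silent neighbors of i."""
    return int(np.abs(pop.omega[graph.neighbors(i)]).sum())


def anchor(pop: Population, graph: Graph, i: int, parse: str = "full") -> float:
    """The anchor value v such that G(ω) = −|v − ω|."""
    return float(
        _kernels.goal_anchor(
            graph.indptr, graph.indices, graph.degree, pop.b, pop.sigma, pop.omega, i, _parse_code(parse)
        )
    )


def goal(
    pop: Population, graph: Graph, i: int, candidate: int, parse: str = "full"
) -> GoalEvaluation:
    """Evaluate G for one candidate expressed opinion of agent i."""
    if candidate not in CANDIDATES:
        raise ValueError(f"candidate must be in {CANDIDATES}, got {candidate}")
    v = anchor(pop, graph, i, parse)
    return GoalEvaluation(candidate=candidate, payoff=-abs(v - candidate), anchor=v)


def best_response(
    pop: Population, graph: Graph, i: int, parse: str = "full", rng: np.random.Generator | None = None
) -> int:
    """The expressed opinion maximizing G for agent i.

    Hard-core agents return −1 without maximizing.  Exact payoff ties
    (anchor at ±1/2) are broken uniformly at random.
    """
    if pop.is_hc[i]:
        return -1
    u = float(rng.random()) if rng is not None else 0.5
    v = anchor(pop, graph, i, parse)
    return int(_kernels.nearest_candidate(v, u))


def time_unit_endogenous(
    pop: Population, graph: Graph, rng: np.random.Generator, parse: str = "full"
) -> Population:
    """N best-response elementary steps on uniformly chosen agents (in place)."""
    agents, _, u_coin = draw_step_randoms(pop.n, rng)
    _kernels.endogenous_steps(
        graph.indptr,
        graph.indices,
        graph.degree,
        pop.b,
        pop.sigma,
        pop.omega,
        pop.is_hc,
        pop.has_expressed,
        agents,
        u_coin,
        _parse_code(parse),
    )
    return pop


def run_endogenous(
    graph: Graph,
    pop: Population,
    rng: np.random.Generator,
    horizon: int = DEFAULT_HORIZON,
    stationarity: tuple[int, float] = (DEFAULT_WINDOW, DEFAULT_TOLERANCE),
    parse: str = "full",
) -> Trajectory:
    """Run the goal-function dynamics to stationarity or the horizon."""
    _parse_code(parse)  # validate early

    def step(p, g, r):
        time_unit_endogenous(p, g, r, parse=parse)

    return run_dynamics(graph, pop, step, rng, horizon, stationarity)
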