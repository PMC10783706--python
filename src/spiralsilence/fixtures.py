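"""Miniature deterministic systems and an exact one-step oracle.

The fixtures are tiny graphs with hand-set (b, σ, ω) states on which every
expected number can be checked by hand; ``enumerate_one_step`` computes the
*exact* distribution over post-step states by summing over agent choice ×
branch × tie-coin outcomes, and serves as an independent oracle for the
Monte-Carlo simulators.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .netgen import Graph, Population

__all__ = ["Fixture", "make_fixture", "enumerate_one_step", "FIXTURE_NAMES"]

FIXTURE_NAMES = ("triangle", "star5", "path4", "two_hubs")


@dataclass
class Fixture:
    name: str
    graph: Graph
    population: Population
    notes: str = ""

    def copy_population(self) -> Population:
        return self.population.copy()


def _pop(b, sigma, omega, is_hc=None, has_expressed=None) -> Population:
    b = np.asarray(b, dtype=np.int8)
    n = b.shape[0]
    omega = np.asarray(omega, dtype=np.int8)
    if has_expressed is None:
        has_expressed = omega != 0
    return Population(
        b=b,
        sigma=np.asarray(sigma, dtype=np.float64),
        omega=omega,
        is_hc=np.zeros(n, dtype=bool) if is_hc is None else np.asarray(is_hc, dtype=bool),
        has_expressed=np.asarray(has_expressed, dtype=bool),
    )


def make_fixture(name: str) -> Fixture:
    """Named miniature systems with fully specified, hand-checkable states.

    * ``triangle``  — 3 mutually connected agents, mixed strengths.
    * ``star5``     — hub with 4 leaves (K_{1,4}); hub expresses +1, leaves silent.
    * ``path4``     — 4 nodes in a line; endpoints have degree 1, below the
      generator's minimum, so this fixture exists for tests only.
    * ``two_hubs``  — two degree-4 hubs sharing 3 leaves; one hub is a
      hard-core agent expressing −1.
    """
    if name == "triangle":
        graph = Graph.from_edges(3, [(0, 1), (1, 2), (0, 2)])
        pop = _pop(b=[1, 1, -1], sigma=[1.0, 0.5, 0.25], omega=[1, 0, -1])
        return Fixture(name, graph, pop, "deg-2 everywhere; one +1 and one -1 expressed")
    if name == "star5":
        graph = Graph.from_edges(5, [(0, 1), (0, 2), (0, 3), (0, 4)])
        pop = _pop(b=[1, 1, 1, -1, 1], sigma=[0.5, 0.5, 0.75, 0.25, 0.5], omega=[1, 0, 0, 0, 0])
        return Fixture(name, graph, pop, "center node 0 expresses +1, leaves silent")
    if name == "path4":
        graph = Graph.from_edges(4, [(0, 1), (1, 2), (2, 3)])
        pop = _pop(b=[1, -1, 1, 1], sigma=[0.5, 1.0, 0.25, 0.75], omega=[0, -1, 0, 1],
                   is_hc=[False, True, False, False])
        return Fixture(name, graph, pop, "degree-1 endpoints; test-only topology")
    if name == "two_hubs":
        # hubs 0 and 1 adjacent, sharing leaves 2, 3, 4 -> both hubs deg 4, leaves deg 2
        edges = [(0, 1), (0, 2), (0, 3), (0, 4), (1, 2), (1, 3), (1, 4)]
        graph = Graph.from_edges(5, edges)
        pop = _pop(
            b=[-1, 1, 1, 1, 1],
            sigma=[1.0, 0.75, 0.5, 0.25, 0.5],
            omega=[-1, 1, 0, 0, 0],
            is_hc=[True, False, False, False, False],
        )
        return Fixture(name, graph, pop, "HC hub 0 at -1, majority hub 1 at +1")
    raise ValueError(f"unknown fixture {name!r}; known: {FIXTURE_NAMES}")


def _exo_outcomes(fx: Fixture, i: int):
    """(probability, omega_out, expressed) outcomes for one model-1 step on i."""
    pop, graph = fx.population, fx.graph
    sigma = float(pop.sigma[i])
    out = []
    if sigma > 0:
        out.append((sigma, int(pop.b[i]), True))
    if sigma < 1:
        nbrs = graph.neighbors(i)
        s = int(pop.omega[nbrs].sum())
        if s > 0:
            out.append((1 - sigma, 1, True))
        elif s < 0:
            out.append((1 - sigma, -1, True))
        elif bool(pop.has_expressed[nbrs].any()):
            out.append(((1 - sigma) / 2, 1, True))
            out.append(((1 - sigma) / 2, -1, True))
        else:
            out.append((1 - sigma, 0, False))
    return out


def _plain_anchor(fx: Fixture, i: int, parse: str) -> float:
    """Anchor of the goal function, computed from first principles (no shared
    code with the simulator, so the oracle stays independent)."""
    pop, graph = fx.population, fx.graph
    social = 0.0
    m = 0
    for j in graph.neighbors(i):
        j = int(j)
        social += (graph.degree[j] / graph.degree[i]) * pop.omega[j]
        m += abs(int(pop.omega[j]))
    private = float(pop.sigma[i]) * int(pop.b[i])
    if parse == "social":
        return private + social / (m + 1)
    if parse == "full":
        return (private + social) / (m + 1)
    raise ValueError(f"unknown parse {parse!r}")


def _endo_outcomes(fx: Fixture, i: int, parse: str):
    pop = fx.population
    if pop.is_hc[i]:
        return [(1.0, -1, True)]
    v = _plain_anchor(fx, i, parse)
    dists = {w: abs(v - w) for w in (-1, 0, 1)}
    dmin = min(dists.values())
    tied = [w for w in (-1, 0, 1) if dists[w] == dmin]
    return [(1.0 / len(tied), w, w != 0) for w in tied]


def enumerate_one_step(fx: Fixture, model: str, parse: str = "full") -> dict:
    """Exact distribution over states after ONE elementary step.

    States are keyed as (omega tuple, has_expressed tuple); probabilities
    sum over agent choice (uniform 1/n) and branch/coin outcomes.
    """
    n = fx.graph.n
    if n > 5:
        raise ValueError("oracle enumeration restricted to fixtures with <= 5 nodes")
    dist: dict[tuple, float] = {}
    for i in range(n):
        outcomes = (
            _exo_outcomes(fx, i) if model == "exogenous" else _endo_outcomes(fx, i, parse)
        )
        for prob, omega_out, expressed in outcomes:
            omega = fx.population.omega.copy()
            he = fx.population.has_expressed.copy()
            omega[i] = omega_out
            if expressed:
                he[i] = True
            key = (tuple(int(x) for x in omega), tuple(bool(x) for x in he))
            dist[key] = dist.get(key, 0.0) + prob / n
    return dist
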