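"""Scale-free network generation and hard-core minority placement.

Networks are built in two stages: a truncated power-law degree sequence
(``P(k) ∝ k^-λ`` on ``k_min ≤ k ≤ k_max``) is sampled i.i.d., then a simple
graph realizing it exactly is assembled by Molloy–Reed stub matching with
rejection of self-loops and parallel edges.  The default degree bounds are
``k_min = 2`` (so no leaves or isolated nodes exist) and the structural
cutoff ``k_max = ⌊√N⌋``, above which an uncorrelated simple scale-free
graph cannot realize the target distribution.

The population layer places a "hard-core" minority — agents with belief
``b = -1`` and maximal strength ``σ = 1`` — on every node of degree exactly
``K_c``; all remaining agents hold ``b = +1`` with strength drawn uniformly
on (0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DegreeSequence",
    "Graph",
    "Population",
    "EmptyHardCoreError",
    "GraphConstructionError",
    "sample_degree_sequence",
    "build_graph",
    "assign_population",
    "hc_prevalence",
    "truncated_power_law_pmf",
    "write_edge_list",
    "read_edge_list",
    "write_population_csv",
]

logger = logging.getLogger(__name__)


class EmptyHardCoreError(ValueError):
    """Raised when no node of the requested hard-core degree exists."""


class GraphConstructionError(RuntimeError):
    """Raised when stub matching cannot realize a degree sequence."""


@dataclass(frozen=True)
class DegreeSequence:
    """A sampled degree sequence with even sum.

    Attributes
    ----------
    degrees : numpy.ndarray of int
        One degree per node, each within ``[k_min, k_max]``.
    k_min, k_max : int
        The truncation bounds of the sampling distribution.
    """

    degrees: np.ndarray
    k_min: int
    k_max: int

    def __post_init__(self) -> None:
        deg = np.asarray(self.degrees, dtype=np.int64)
        object.__setattr__(self, "degrees", deg)
        if int(deg.sum()) % 2 != 0:
            raise ValueError("degree sequence must have even sum")

    @property
    def n(self) -> int:
        return int(self.degrees.shape[0])


@dataclass(frozen=True)
class Graph:
    """Undirected simple graph in CSR form.

    ``indices[indptr[i]:indptr[i+1]]`` are the neighbors of node ``i``;
    ``degree[i]`` equals the slice length.  Both directions of every edge
    are stored, so ``j ∈ Γ_i ⇔ i ∈ Γ_j``.
    """

    n: int
    indptr: np.ndarray
    indices: np.ndarray
    degree: np.ndarray

    def neighbors(self, i: int) -> np.ndarray:
        return self.indices[self.indptr[i] : self.indptr[i + 1]]

    @property
    def adjacency(self) -> list[set[int]]:
        """Per-node neighbor sets (convenience view; O(E) to build)."""
        return [set(map(int, self.neighbors(i))) for i in range(self.n)]

    def edges(self) -> np.ndarray:
        """Array of (u, v) with u < v, one row per undirected edge."""
        out = []
        for i in range(self.n):
            for j in self.neighbors(i):
                if i < j:
                    out.append((i, int(j)))
        return np.asarray(out, dtype=np.int64).reshape(-1, 2)

    @classmethod
    def from_edges(cls, n: int, edges) -> "Graph":
        edges = np.asarray(list(edges), dtype=np.int64).reshape(-1, 2)
        if edges.size and (edges.min() < 0 or edges.max() >= n):
            raise ValueError("edge endpoint out of range")
        if np.any(edges[:, 0] == edges[:, 1]):
            raise ValueError("self-loop in edge list")
        key = {tuple(sorted(e)) for e in map(tuple, edges)}
        if len(key) != len(edges):
            raise ValueError("parallel edge in edge list")
        deg = np.zeros(n, dtype=np.int64)
        both = np.concatenate([edges, edges[:, ::-1]]) if edges.size else edges
        np.add.at(deg, both[:, 0] if both.size else [], 1)
        order = np.lexsort((both[:, 1], both[:, 0])) if both.size else []
        both = both[order] if len(both) else both
        indptr = np.zeros(n + 1, dtype=np.int64)
        np.cumsum(deg, out=indptr[1:])
        indices = (both[:, 1] if both.size else np.empty(0)).astype(np.int32)
        return cls(n=n, indptr=indptr, indices=indices, degree=deg)


@dataclass
class Population:
    """Per-agent state: belief b ∈ {−1,+1}, strength σ ∈ (0,1], expressed
    opinion ω ∈ {−1,0,+1}, hard-core flag, and a has-expressed flag that
    records whether the agent has ever emitted a non-null opinion."""

    b: np.ndarray
    sigma: np.ndarray
    omega: np.ndarray
    is_hc: np.ndarray
    has_expressed: np.ndarray

    @property
    def n(self) -> int:
        return int(self.b.shape[0])

    def copy(self) -> "Population":
        return Population(
            b=self.b.copy(),
            sigma=self.sigma.copy(),
            omega=self.omega.copy(),
            is_hc=self.is_hc.copy(),
            has_expressed=self.has_expressed.copy(),
        )


def truncated_power_law_pmf(lambda_exp: float, k_min: int, k_max: int) -> tuple[np.ndarray, np.ndarray]:
    """Support and probabilities of P(k) = k^-λ / Σ_{m=k_min}^{k_max} m^-λ."""
    ks = np.arange(k_min, k_max + 1, dtype=np.int64)
    w = ks.astype(np.float64) ** (-lambda_exp)
    return ks, w / w.sum()


def sample_degree_sequence(
    n: int,
    lambda_exp: float,
    rng: np.random.Generator,
    k_min: int = 2,
    k_max: int | None = None,
) -> DegreeSequence:
    """Draw n degrees i.i.d. from the truncated power law and repair parity.

    ``k_max`` defaults to the structural cutoff ``⌊√n⌋``.  If the sampled
    sum is odd, one uniformly chosen entry is redrawn until the total
    becomes even, so the sequence is always graphical input for stub
    matching.
    """
    if not isinstance(n, (int, np.integer)) or n < 4:
        raise ValueError(f"n must be an integer >= 4, got {n!r}")
    if not lambda_exp > 1:
        raise ValueError(f"lambda_exp must be > 1, got {lambda_exp!r}")
    if k_max is None:
        k_max = int(np.floor(np.sqrt(n)))
    if not (1 <= k_min <= k_max):
        raise ValueError(f"need 1 <= k_min <= k_max, got ({k_min}, {k_max})")
    ks, p = truncated_power_law_pmf(lambda_exp, k_min, k_max)
    degrees = rng.choice(ks, size=n, p=p)
    if int(degrees.sum()) % 2 != 0:
        idx = int(rng.integers(n))
        while int(degrees.sum()) % 2 != 0:
            degrees[idx] = rng.choice(ks, p=p)
    return DegreeSequence(degrees=degrees, k_min=k_min, k_max=k_max)


def _try_stub_matching(
    degrees: np.ndarray, rng: np.random.Generator, max_repair_rounds: int = 200
) -> set[tuple[int, int]] | None:
    """One Molloy–Reed attempt: pair stubs uniformly; illegal pairs
    (self-loops / duplicates) are pooled and re-paired among themselves.
    Returns the edge set, or None if re-pairing stalls."""
    stubs = np.repeat(np.arange(degrees.shape[0], dtype=np.int64), degrees)
    rng.shuffle(stubs)
    edges: set[tuple[int, int]] = set()
    pending = stubs
    for _ in range(max_repair_rounds):
        bad: list[int] = []
        for a, b in zip(pending[0::2], pending[1::2]):
            a, b = int(a), int(b)
            e = (a, b) if a < b else (b, a)
            if a == b or e in edges:
                bad.append(a)
                bad.append(b)
            else:
                edges.add(e)
        if not bad:
            return edges
        pending = np.asarray(bad, dtype=np.int64)
        rng.shuffle(pending)
        # a 2-stub remainder that is a self-pair or an existing edge can
        # never resolve by reshuffling alone
        if len(bad) == 2:
            a, b = sorted(bad)
            if a == b or (a, b) in edges:
                return None
    return None


def build_graph(
    seq: DegreeSequence,
    rng: np.random.Generator,
    max_retries: int = 50,
) -> Graph:
    """Build a simple graph whose degrees equal ``seq`` exactly.

    Stub matching is restarted from scratch when local re-pairing cannot
    resolve the remaining illegal pairs; after ``max_retries`` restarts the
    degree sequence is resampled from the same truncated law (logged), so
    the returned graph may then realize a fresh sequence with the same
    (n, λ-implied) statistics.
    """
    degrees = seq.degrees
    n = degrees.shape[0]
    if np.any(degrees > n - 1):
        raise GraphConstructionError("a degree exceeds n-1; sequence not simple-graphical")
    for attempt in range(max_retries):
        edges = _try_stub_matching(degrees, rng)
        if edges is not None:
            return Graph.from_edges(n, edges)
    raise GraphConstructionError(
        f"stub matching failed after {max_retries} restarts for n={n}"
    )


def assign_population(graph: Graph, k_c: int, rng: np.random.Generator) -> Population:
    """Place the hard-core minority on all degree-``k_c`` nodes.

    Hard-core agents get (b, σ) = (−1, 1); everyone else b = +1 with
    σ ~ U(0, 1] (exact zeros rejected).  All expressed opinions start null.
    """
    is_hc = graph.degree == k_c
    if not is_hc.any():
        raise EmptyHardCoreError(f"no node of degree {k_c} in this graph")
    n = graph.n
    b = np.where(is_hc, -1, 1).astype(np.int8)
    sigma = rng.uniform(0.0, 1.0, size=n)
    while np.any(sigma == 0.0):  # σ ∈ (0, 1]: reject the measure-zero endpoint
        redo = sigma == 0.0
        sigma[redo] = rng.uniform(0.0, 1.0, size=int(redo.sum()))
    sigma = np.where(is_hc, 1.0, sigma)
    return Population(
        b=b,
        sigma=sigma,
        omega=np.zeros(n, dtype=np.int8),
        is_hc=is_hc,
        has_expressed=np.zeros(n, dtype=bool),
    )


def hc_prevalence(pop: Population) -> float:
    """Fraction of agents flagged as hard-core."""
    if pop.n == 0:
        raise ValueError("empty population")
    return float(pop.is_hc.sum()) / pop.n


def write_edge_list(graph: Graph, path) -> None:
    """Whitespace-separated edge list, 0-based ids, one undirected edge per line."""
    np.savetxt(path, graph.edges(), fmt="%d")


def read_edge_list(path, n: int | None = None) -> Graph:
    """Read an undirected simple graph from a whitespace-separated edge list."""
    raw = np.loadtxt(path, dtype=np.int64, ndmin=2)
    if n is None:
        n = int(raw.max()) + 1 if raw.size else 0
    return Graph.from_edges(n, raw)


def write_population_csv(pop: Population, graph: Graph, path) -> None:
    """CSV export with header ``node,degree,b,sigma,is_hc``."""
    import pandas as pd

    pd.DataFrame(
        {
            "node": np.arange(pop.n),
            "degree": graph.degree,
            "b": pop.b,
            "sigma": pop.sigma,
            "is_hc": pop.is_hc.astype(int),
        }
    ).to_csv(path, index=False)
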