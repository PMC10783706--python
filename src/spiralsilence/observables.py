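"""State variables of the opinion dynamics and the misperception decomposition.

The observables all live in [−1, 1]:

* ``⟨ω⟩`` — mean expressed opinion over all agents (silent agents count 0);
* ``⟨b⟩`` — mean private belief, constant in time by construction;
* ``r``  — the local opinion climate: each agent averages the expressed
  opinions over its neighborhood (Δ_i = Σ_{j∈Γ_i} ω_j / deg(i)) and r is the
  population mean of Δ_i.  In heterogeneous networks r over-weights hubs
  (the friendship paradox), which is exactly the distortion under study.

Misperception is decomposed as ⟨b⟩ − r = (⟨b⟩ − ⟨ω⟩) − (r − ⟨ω⟩): the gap
between what agents privately believe and the climate they observe splits
into a behavioral part (expressing differently from believing) and a purely
topological part (the neighborhood average differing from the global one).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .netgen import Graph, Population

__all__ = [
    "Snapshot",
    "MisperceptionDecomposition",
    "snapshot",
    "misperception",
    "silenced_per_hc",
    "fit_power_law_exponent",
]


@dataclass(frozen=True)
class Snapshot:
    """Instantaneous observables of one system state."""

    mean_omega: float
    mean_belief: float
    r: float
    frac_plus: float
    frac_minus: float
    frac_silent: float


@dataclass(frozen=True)
class MisperceptionDecomposition:
    private_public_mismatch: float  # ⟨b⟩ − ⟨ω⟩
    misperception: float  # ⟨b⟩ − r
    topo_contribution: float  # r − ⟨ω⟩


def snapshot(pop: Population, graph: Graph) -> Snapshot:
    """Compute all state variables for the current population state."""
    n = pop.n
    omega = pop.omega
    return Snapshot(
        mean_omega=float(omega.sum()) / n,
        mean_belief=float(pop.b.sum()) / n,
        r=float(_kernels.local_climate(graph.indptr, graph.indices, omega)),
        frac_plus=float(np.count_nonzero(omega == 1)) / n,
        frac_minus=float(np.count_nonzero(omega == -1)) / n,
        frac_silent=float(np.count_nonzero(omega == 0)) / n,
    )


def misperception(snap: Snapshot, mean_belief: float | None = None) -> MisperceptionDecomposition:
    """The three gap statistics; identity (⟨b⟩−r) = (⟨b⟩−⟨ω⟩) − (r−⟨ω⟩) holds
    exactly by construction."""
    b = snap.mean_belief if mean_belief is None else float(mean_belief)
    return MisperceptionDecomposition(
        private_public_mismatch=b - snap.mean_omega,
        misperception=b - snap.r,
        topo_contribution=snap.r - snap.mean_omega,
    )


def silenced_per_hc(pop: Population) -> float:
    """Number of silent agents (ω = 0) per hard-core agent, on a final state."""
    n_hc = int(pop.is_hc.sum())
    if n_hc == 0:
        raise ValueError("population has no hard-core agents")
    return float(np.count_nonzero(pop.omega == 0)) / n_hc


def fit_power_law_exponent(points) -> tuple[float, dict]:
    """OLS fit of log(y) on log(k_c) for (k_c, y) pairs; returns (exponent, meta).

    ``meta`` carries the intercept (log-prefactor), per-point residuals and
    the fitted values, so the quality of the scaling law can be inspected.
    """
    pts = np.asarray(list(points), dtype=np.float64).reshape(-1, 2)
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 points for a power-law fit")
    if np.any(pts <= 0):
        raise ValueError("all k_c and y values must be positive")
    logx, logy = np.log(pts[:, 0]), np.log(pts[:, 1])
    slope, intercept = np.polyfit(logx, logy, 1)
    fitted = slope * logx + intercept
    meta = {
        "intercept": float(intercept),
        "fitted_log": fitted.tolist(),
        "residuals": (logy - fitted).tolist(),
        "method": "unweighted OLS on log-log",
    }
    return float(slope), meta
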