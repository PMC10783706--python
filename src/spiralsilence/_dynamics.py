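"""Shared machinery for asynchronous random-sequential simulation runs.

A *time unit* is N elementary steps, each applied to an agent drawn
uniformly with replacement; a run records one Snapshot per time unit
(plus the t=0 initial state) and stops at the horizon or once the mean
expressed opinion has moved less than a tolerance over a trailing window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .netgen import Graph, Population
from .observables import Snapshot, snapshot

DEFAULT_HORIZON = 200
DEFAULT_WINDOW = 20
DEFAULT_TOLERANCE = 1e-4

__all__ = ["Trajectory", "run_dynamics", "draw_step_randoms"]


@dataclass
class Trajectory:
    """Per-time-unit series of observables for one realization."""

    t: np.ndarray
    mean_omega: np.ndarray
    r: np.ndarray
    frac_plus: np.ndarray
    frac_minus: np.ndarray
    frac_silent: np.ndarray
    mean_belief: float
    final_population: Population
    converged: bool

    @property
    def final(self) -> Snapshot:
        return Snapshot(
            mean_omega=float(self.mean_omega[-1]),
            mean_belief=self.mean_belief,
            r=float(self.r[-1]),
            frac_plus=float(self.frac_plus[-1]),
            frac_minus=float(self.frac_minus[-1]),
            frac_silent=float(self.frac_silent[-1]),
        )

    def to_csv(self, path) -> None:
        """CSV with header ``t,mean_omega,r,frac_plus,frac_minus,frac_silent``."""
        import pandas as pd

        pd.DataFrame(
            {
                "t": self.t,
                "mean_omega": self.mean_omega,
                "r": self.r,
                "frac_plus": self.frac_plus,
                "frac_minus": self.frac_minus,
                "frac_silent": self.frac_silent,
            }
        ).to_csv(path, index=False)


def draw_step_randoms(n: int, rng: np.random.Generator):
    """Random inputs for one time unit: agent picks and two uniforms per step."""
    agents = rng.integers(0, n, size=n)
    u1 = rng.random(n)
    u2 = rng.random(n)
    return agents, u1, u2


def run_dynamics(
    graph: Graph,
    pop: Population,
    step_fn,
    rng: np.random.Generator,
    horizon: int = DEFAULT_HORIZON,
    stationarity: tuple[int, float] = (DEFAULT_WINDOW, DEFAULT_TOLERANCE),
) -> Trajectory:
    """Drive ``step_fn`` (one time unit, mutating pop in place) to the horizon.

    ``pop`` is copied first; the caller's population is left untouched.
    Early stop when |⟨ω⟩(t) − ⟨ω⟩(t − window)| < tolerance.
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    window, tolerance = stationarity
    pop = pop.copy()
    snaps = [snapshot(pop, graph)]
    converged = False
    for t in range(1, horizon + 1):
        step_fn(pop, graph, rng)
        snaps.append(snapshot(pop, graph))
        if window and t >= window:
            if abs(snaps[-1].mean_omega - snaps[-1 - window].mean_omega) < tolerance:
                converged = True
                break
    return Trajectory(
        t=np.arange(len(snaps)),
        mean_omega=np.array([s.mean_omega for s in snaps]),
        r=np.array([s.r for s in snaps]),
        frac_plus=np.array([s.frac_plus for s in snaps]),
        frac_minus=np.array([s.frac_minus for s in snaps]),
        frac_silent=np.array([s.frac_silent for s in snaps]),
        mean_belief=snaps[0].mean_belief,
        final_population=pop,
        converged=converged,
    )
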