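"""Ensemble orchestration: K_c sweeps, aggregation, and reproducible I/O.

Every realization is fully independent: a fresh degree sequence, a fresh
Molloy–Reed graph (regenerated with a new child seed until at least one
node of degree K_c exists), a fresh population, and an independent random
stream spawned from the master seed.  Ensemble rows report means and
standard errors of the final-state observables across realizations.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .endogenous_model import run_endogenous
from .exogenous_model import run_exogenous
from .netgen import (
    EmptyHardCoreError,
    assign_population,
    build_graph,
    hc_prevalence,
    sample_degree_sequence,
    write_edge_list,
)
from .observables import fit_power_law_exponent, silenced_per_hc

logger = logging.getLogger(__name__)

ENSEMBLE_COLUMNS = [
    "kc",
    "n_real",
    "mean_b",
    "mean_omega_f",
    "se_omega",
    "r_f",
    "se_r",
    "frac_plus",
    "frac_minus",
    "frac_silent",
    "silenced_per_hc",
    "hc_fraction",
]

__all__ = ["ModelConfig", "realize_system", "run_ensemble", "sweep_kc", "fit_silencing_scaling"]


@dataclass
class ModelConfig:
    """Full configuration of an ensemble experiment."""

    model: str = "endogenous"  # "exogenous" or "endogenous"
    n: int = 5000
    lambda_exp: float = 2.2
    kc_list: tuple[int, ...] = (2, 3, 5, 10, 20)
    horizon: int = 200
    window: int = 20
    tolerance: float = 1e-4
    realizations: int = 100
    seed: int = 0
    parse: str = "full"
    outputs: str | None = None
    save_trajectories: bool = False
    save_networks: bool = False

    def __post_init__(self) -> None:
        if self.model not in ("exogenous", "endogenous"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.realizations < 1:
            raise ValueError("realizations must be >= 1")
        kmax = int(np.floor(np.sqrt(self.n)))
        for kc in self.kc_list:
            if not (2 <= kc <= kmax):
                raise ValueError(f"K_c={kc} outside [2, {kmax}] for n={self.n}")


def _child_rng(master_seed: int, *key: int) -> np.random.Generator:
    """Independent, reproducible stream for (master seed, key...)."""
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=key))


def realize_system(config: ModelConfig, k_c: int, rng: np.random.Generator):
    """Sample a graph with >=1 degree-K_c node, assign agents; count regenerations."""
    regenerations = 0
    while True:
        seq = sample_degree_sequence(config.n, config.lambda_exp, rng)
        graph = build_graph(seq, rng)
        try:
            pop = assign_population(graph, k_c, rng)
            return graph, pop, regenerations
        except EmptyHardCoreError:
            regenerations += 1
            if regenerations % 50 == 0:
                logger.warning(
                    "K_c=%d: %d regenerations without a degree-%d node", k_c, regenerations, k_c
                )


def _run_one(config: ModelConfig, k_c: int, realization: int):
    rng = _child_rng(config.seed, k_c, realization)
    graph, pop, regens = realize_system(config, k_c, rng)
    runner = run_exogenous if config.model == "exogenous" else run_endogenous
    kwargs = {} if config.model == "exogenous" else {"parse": config.parse}
    traj = runner(
        graph,
        pop,
        rng,
        horizon=config.horizon,
        stationarity=(config.window, config.tolerance),
        **kwargs,
    )
    return graph, traj, regens


def run_ensemble(config: ModelConfig, k_c: int) -> dict:
    """One ensemble row: means ± standard errors of final observables at K_c."""
    finals = {k: [] for k in ("mean_b", "omega", "r", "fp", "fm", "fs", "sphc", "hcfrac")}
    regen_total = 0
    out_dir = Path(config.outputs) if config.outputs else None
    for real in range(config.realizations):
        graph, traj, regens = _run_one(config, k_c, real)
        regen_total += regens
        snap = traj.final
        pop = traj.final_population
        finals["mean_b"].append(traj.mean_belief)
        finals["omega"].append(snap.mean_omega)
        finals["r"].append(snap.r)
        finals["fp"].append(snap.frac_plus)
        finals["fm"].append(snap.frac_minus)
        finals["fs"].append(snap.frac_silent)
        finals["sphc"].append(silenced_per_hc(pop))
        finals["hcfrac"].append(hc_prevalence(pop))
        if out_dir is not None and config.save_trajectories:
            traj.to_csv(out_dir / f"trajectory_kc{k_c}_r{real}.csv")
        if out_dir is not None and config.save_networks:
            write_edge_list(graph, out_dir / f"network_kc{k_c}_r{real}.edges")
        logger.info("kc=%d realization=%d final frac_silent=%.4f", k_c, real, snap.frac_silent)

    def mean(k):
        return float(np.mean(finals[k]))

    def se(k):
        v = np.asarray(finals[k])
        return float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else 0.0

    row = {
        "kc": k_c,
        "n_real": config.realizations,
        "mean_b": mean("mean_b"),
        "mean_omega_f": mean("omega"),
        "se_omega": se("omega"),
        "r_f": mean("r"),
        "se_r": se("r"),
        "frac_plus": mean("fp"),
        "frac_minus": mean("fm"),
        "frac_silent": mean("fs"),
        "silenced_per_hc": mean("sphc"),
        "hc_fraction": mean("hcfrac"),
    }
    row["_regenerations"] = regen_total
    return row


def sweep_kc(config: ModelConfig) -> pd.DataFrame:
    """Run run_ensemble for every K_c in the config; optionally write outputs.

    Returns the ensemble table; when ``config.outputs`` is set, writes
    ``ensemble.csv`` plus a JSON manifest with the full configuration,
    regeneration counts and wall time.
    """
    out_dir = Path(config.outputs) if config.outputs else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    rows = [run_ensemble(config, kc) for kc in config.kc_list]
    regenerations = {int(r["kc"]): int(r.pop("_regenerations")) for r in rows}
    table = pd.DataFrame(rows, columns=ENSEMBLE_COLUMNS)
    if out_dir is not None:
        table.to_csv(out_dir / "ensemble.csv", index=False)
        manifest = {
            "config": asdict(config),
            "parse_variant": config.parse,
            "regenerations": regenerations,
            "code_version": __version__,
            "wall_time_s": time.time() - t0,
        }
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return table


def fit_silencing_scaling(summary: pd.DataFrame) -> tuple[float, dict]:
    """Power-law exponent of silenced-per-HC versus K_c from an ensemble table."""
    pts = list(zip(summary["kc"].to_numpy(float), summary["silenced_per_hc"].to_numpy(float)))
    nu, meta = fit_power_law_exponent(pts)
    meta["points"] = [{"kc": kc, "silenced_per_hc": y} for kc, y in pts]
    return nu, meta
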