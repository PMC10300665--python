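"""Replicated experiment grids over model x priors x threshold.

Each condition gets its own RNG stream derived by hashing
(base_seed, model, priors, theta, replicate) through ``SeedSequence``, so
adding conditions or replicates never perturbs existing ones.  Output is the
tidy long format defined in :mod:`rolesim.metrics`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .config import ConfigurationError, WorldConfig
from .cognition import PRESET_NAMES
from .metrics import tidy_frame
from .simulation import SimulationResult, run_simulation

#: canonical condition names for the priors axis (plus the baseline condition)
PRIORS_AXIS_NAMES = tuple(PRESET_NAMES) + ("perfect",)

#: printed perfect-knowledge baselines: optimal final segregation by reality
BASELINE_MODELS = (1, 2, 3)


def _priors_code(priors) -> tuple[str, int, bool]:
    """Normalise a priors axis value to (name, preset id, perfect flag)."""
    if priors == "perfect":
        return "perfect", 0, True
    if isinstance(priors, str):
        if priors not in PRESET_NAMES:
            raise ConfigurationError(f"unknown priors condition {priors!r}")
        return priors, PRESET_NAMES[priors], False
    if priors in range(5):
        name = {v: k for k, v in PRESET_NAMES.items()}[priors]
        return name, int(priors), False
    raise ConfigurationError(f"unknown priors condition {priors!r}")


def condition_seed(base_seed: int, model: int, priors_code: int,
                   perfect: bool, theta: float, replicate: int) -> int:
    """Deterministic per-replicate seed, independent across conditions."""
    ss = np.random.SeedSequence(
        (int(base_seed), int(model), int(priors_code), int(perfect),
         int(round(theta * 1000)), int(replicate)))
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


@dataclass(frozen=True)
class ExperimentGrid:
    """Axes of a replicated experiment."""

    models: tuple = (1, 2, 3, 4, 5, 6)
    priors: tuple = PRIORS_AXIS_NAMES
    thetas: tuple = (1.0, 0.9, 0.75)
    replicates: int = 10
    base_seed: int = 0

    def __post_init__(self) -> None:
        if not (self.models and self.priors and self.thetas):
            raise ConfigurationError("grid axes must be non-empty")
        if self.replicates < 1:
            raise ConfigurationError("replicates must be >= 1")
        for m in self.models:
            if m not in range(1, 7):
                raise ConfigurationError(f"unknown model {m!r}")
        for th in self.thetas:
            if not 0.0 < th <= 1.0:
                raise ConfigurationError(f"theta {th!r} outside (0, 1]")
        for p in self.priors:
            _priors_code(p)


def run_condition(model: int, priors, theta: float, replicates: int,
                  base_seed: int = 0, progress=None,
                  **overrides) -> list[SimulationResult]:
    """Run seeded replicates of one (model, priors, theta) condition."""
    name, code, perfect = _priors_code(priors)
    results = []
    for rep in range(replicates):
        seed = condition_seed(base_seed, model, code, perfect, theta, rep)
        cfg = WorldConfig(model_id=model, priors_preset=code,
                          perfect_knowledge=perfect, theta=theta,
                          seed=seed, **overrides)
        results.append(run_simulation(cfg))
        if progress is not None:
            progress()
    return results


def run_grid(grid: ExperimentGrid, progress=None,
             provenance_path=None, **overrides) -> pd.DataFrame:
    """Run the whole grid; one tidy row per (condition, replicate, timestep)."""
    frames = []
    prov = []
    for model in grid.models:
        for priors in grid.priors:
            name, _, _ = _priors_code(priors)
            for theta in grid.thetas:
                results = run_condition(model, priors, theta, grid.replicates,
                                        grid.base_seed, progress=progress,
                                        **overrides)
                frames.append(tidy_frame(results, model, name, theta))
                prov.extend(r.provenance() for r in results)
    if provenance_path is not None:
        with open(provenance_path, "w") as fh:
            for record in prov:
                fh.write(json.dumps(record) + "\n")
    return pd.concat(frames, ignore_index=True)


def baseline_suite(replicates: int = 10, base_seed: int = 0,
                   theta: float = 1.0, **overrides) -> dict[int, dict]:
    """Optimal-segregation baselines: perfect-knowledge agents, models 1-3.

    Perfect-knowledge agents self-select on true ability, so their mean
    final-timestep segregation is the 'optimal' level for each state of
    reality.  Returns per model the replicate final values and their mean.
    """
    if replicates < 5:
        raise ConfigurationError("baselines need >= 5 replicates")
    out = {}
    for model in BASELINE_MODELS:
        results = run_condition(model, "perfect", theta, replicates,
                                base_seed, **overrides)
        finals = np.array([r.segregation[-1] for r in results])
        out[model] = {"finals": finals, "mean": float(finals.mean()),
                      "sd": float(finals.std(ddof=1))}
    return out
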