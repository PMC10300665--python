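"""Miniature deterministic worlds for fast tests.

A mini world is a fully valid :class:`~rolesim.simulation.World` at toy scale
(tens of agents, a handful of roles).  Abilities and social counts may be set
explicitly — such worlds are synthetic constructions for decision-level
tests, bypassing the Normal ability generator — and are otherwise drawn
through the ordinary initialiser so that all simulation invariants hold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import ConfigurationError, WorldConfig
from .simulation import World, init_world


@dataclass(frozen=True)
class MiniWorldSpec:
    """Small-world recipe: explicit abilities/counts override random draws."""

    n_agents: int = 4
    n_roles: int = 2
    n_steps: int = 10
    model_id: int = 3
    priors_preset: int = 0
    perfect_knowledge: bool = False
    theta: float = 1.0
    death_rate: float = 0.0
    abilities: np.ndarray | None = None      # (n_agents, n_roles)
    continuing: np.ndarray | None = None     # (2, n_roles), synthetic
    abandoned: np.ndarray | None = None      # (2, n_roles), synthetic
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_agents > 50 or self.n_roles > 8:
            raise ConfigurationError("mini worlds are capped at 50 x 8")
        if self.abilities is not None:
            ab = np.asarray(self.abilities)
            if ab.shape != (self.n_agents, self.n_roles):
                raise ConfigurationError("ability matrix shape mismatch")
            if np.any(ab <= 0):
                raise ConfigurationError("abilities must be positive")


def make_mini_world(spec: MiniWorldSpec) -> World:
    """Build a small, fully initialised world honouring all invariants."""
    cfg = WorldConfig(
        n_agents=spec.n_agents, n_roles=spec.n_roles, n_steps=spec.n_steps,
        model_id=spec.model_id, priors_preset=spec.priors_preset,
        perfect_knowledge=spec.perfect_knowledge, theta=spec.theta,
        death_rate=spec.death_rate, seed=spec.seed)
    world = init_world(cfg)
    if spec.abilities is not None:
        world.abilities[:] = np.asarray(spec.abilities, dtype=np.float64)
    if spec.continuing is not None or spec.abandoned is not None:
        world.set_social_counts(
            spec.continuing if spec.continuing is not None
            else np.zeros((2, spec.n_roles), dtype=np.int64),
            spec.abandoned if spec.abandoned is not None
            else np.zeros((2, spec.n_roles), dtype=np.int64))
    return world
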