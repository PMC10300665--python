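"""World orchestration: lifecycle, random acting order, and recording.

Time passes in discrete steps.  Each step draws a fresh random order over the
population; every agent either dies (5% by default, replaced in place by a
naive agent of the same type that starts acting the following step) or
performs one of the roles and earns ability x price.  Social counts and
prices update live as agents act.  The end-of-step occupancy (every agent's
role performed that step, explorers included) yields one segregation value
per step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _engine
from .config import WorldConfig
from .metrics import segregation_index
from .reality import RoleEffectTable, ability_matrix, make_role_effects


@dataclass
class SimulationResult:
    """One replicate: per-step segregation series plus final occupancy."""

    segregation: np.ndarray        # (n_steps,)
    final_occupancy: np.ndarray    # (n_roles, 2) counts by type
    config: WorldConfig
    seed: int
    role_effects: RoleEffectTable

    @property
    def final_segregation(self) -> float | None:
        return segregation_index(self.final_occupancy)

    def provenance(self) -> dict:
        return {"config": self.config.to_dict(), "seed": self.seed,
                "role_effects": self.role_effects.to_dict()}


class World:
    """Mutable state of one replicate; see :mod:`rolesim._engine` for layout."""

    def __init__(self, cfg: WorldConfig, rng: np.random.Generator,
                 effects: RoleEffectTable, abilities: np.ndarray,
                 agent_type: np.ndarray):
        n, r = cfg.n_agents, cfg.n_roles
        if abilities.shape != (n, r) or agent_type.shape != (n,):
            raise ValueError("inconsistent world dimensions")
        self.cfg = cfg
        self.rng = rng
        self.effects = effects
        self.agent_type = np.ascontiguousarray(agent_type, dtype=np.int8)
        self.created_at = np.zeros(n, dtype=np.int64)
        self.abilities = np.ascontiguousarray(abilities, dtype=np.float64)
        self.tried = np.zeros((n, r), dtype=np.bool_)
        self.n_tried = np.zeros(n, dtype=np.int64)
        self.occupation = np.full(n, -1, dtype=np.int64)
        self.performing = np.full(n, -1, dtype=np.int64)
        self.continuing = np.zeros((2, r), dtype=np.int64)
        self.abandoned = np.zeros((2, r), dtype=np.int64)
        self.role_supply = np.zeros(r, dtype=np.float64)
        self.belief_mean = np.full((2, r), cfg.ability_mean)
        self.ver = np.zeros(2, dtype=np.int64)
        self.t = 0
        self._priors = None

    @property
    def priors(self):
        if self._priors is None:
            from .cognition import Priors
            self._priors = Priors.from_preset(self.cfg.priors_preset)
        return self._priors

    def refresh_beliefs(self) -> None:
        """Bring the cached posterior-expected abilities up to date."""
        p = self.priors
        if self.cfg.perfect_knowledge or p.q <= 0.0:
            return
        if self.ver[0] != self.ver[1]:
            _engine.refresh_beliefs(self.continuing, self.abandoned,
                                    self.belief_mean, p.q, p.s, p.delta,
                                    self.cfg.ability_mean, self.cfg.ability_sd)
            self.ver[1] = self.ver[0]

    def occ_count(self) -> np.ndarray:
        """Headcount of current performers per role."""
        return np.bincount(self.performing[self.performing >= 0],
                           minlength=self.cfg.n_roles)

    def occupancy_by_type(self) -> np.ndarray:
        """(n_roles, 2) counts of performers this step, by agent type."""
        occ = np.zeros((self.cfg.n_roles, 2), dtype=np.int64)
        mask = self.performing >= 0
        np.add.at(occ, (self.performing[mask], self.agent_type[mask]), 1)
        return occ

    def prices(self) -> np.ndarray:
        return (self.cfg.price_unit
                / (self.role_supply / self.cfg.ability_mean + 1.0))

    def set_social_counts(self, continuing, abandoned) -> None:
        """Overwrite social counts (synthetic; for belief-level tests only)."""
        self.continuing[:] = np.asarray(continuing, dtype=np.int64)
        self.abandoned[:] = np.asarray(abandoned, dtype=np.int64)
        self.ver[0] += 1


def init_world(config: WorldConfig, rng: np.random.Generator | None = None,
               effects: RoleEffectTable | None = None) -> World:
    """Build a fresh world: balanced types, all agents naive, empty counts."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if effects is None:
        effects = make_role_effects(config.model_id, config.n_roles, rng)
    half = config.n_agents // 2
    agent_type = np.repeat(np.array([0, 1], dtype=np.int8), half)
    abilities = ability_matrix(agent_type, 0, effects, config, rng)
    return World(config, rng, effects, abilities, agent_type)


def step_world(world: World, rng: np.random.Generator | None = None,
               compiled: bool = True) -> float | None:
    """Advance one timestep; returns the end-of-step segregation index.

    ``compiled=False`` runs the same kernel as interpreted Python (slow;
    used to validate compilation on miniature worlds).
    """
    cfg = world.cfg
    p = world.priors
    rng = world.rng if rng is None else rng
    kern = _engine.step_world_kernel if compiled \
        else _engine.step_world_kernel.py_func
    kern(world.t, rng, world.agent_type, world.created_at, world.abilities,
         world.tried, world.n_tried, world.occupation, world.performing,
         world.continuing, world.abandoned, world.role_supply,
         world.belief_mean, world.ver, world.effects.favoured_type,
         world.effects.offset, cfg.death_rate, p.q, p.s, p.delta,
         cfg.perfect_knowledge, cfg.theta, cfg.forced_min_roles,
         cfg.price_unit, cfg.ability_mean, cfg.ability_sd, cfg.vanish_step)
    world.t += 1
    return segregation_index(world.occupancy_by_type())


def run_simulation(config: WorldConfig, compiled: bool = True
                   ) -> SimulationResult:
    """Run one seeded replicate for ``config.n_steps`` steps."""
    world = init_world(config)
    series = np.empty(config.n_steps)
    for t in range(config.n_steps):
        s = step_world(world, compiled=compiled)
        series[t] = np.nan if s is None else s
    return SimulationResult(segregation=series,
                            final_occupancy=world.occupancy_by_type(),
                            config=config, seed=config.seed,
                            role_effects=world.effects)


def audit_world(world: World) -> None:
    """Recompute all counts from scratch and check every invariant.

    Raises AssertionError on any inconsistency: occupancy vs performing,
    social counts attributable to living agents only, occupation in tried,
    conserved type split, forced-exploration quota.
    """
    cfg, n, r = world.cfg, world.cfg.n_agents, world.cfg.n_roles
    assert world.agent_type.shape == (n,)
    counts = np.bincount(world.agent_type, minlength=2)
    assert counts[0] == counts[1] == n // 2, "type split not conserved"
    supply = np.zeros(r)
    for i in np.flatnonzero(world.performing >= 0):
        supply[world.performing[i]] += world.abilities[i, world.performing[i]]
    assert np.allclose(supply, world.role_supply), "supply out of sync"
    cont = np.zeros((2, r), dtype=np.int64)
    aban = np.zeros((2, r), dtype=np.int64)
    for i in range(n):
        o = world.occupation[i]
        ty = world.agent_type[i]
        assert world.n_tried[i] == world.tried[i].sum()
        if o >= 0:
            assert world.tried[i, o], "occupation not in tried set"
            assert world.n_tried[i] >= cfg.forced_min_roles, \
                "occupation adopted inside forced-exploration quota"
            cont[ty, o] += 1
        for role in np.flatnonzero(world.tried[i]):
            if role != o:
                aban[ty, role] += 1
    assert np.array_equal(cont, world.continuing), "continuing counts drifted"
    assert np.array_equal(aban, world.abandoned), "abandoned counts drifted"
    assert (world.continuing.sum(axis=1)
            <= np.array([n // 2, n // 2])).all()
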