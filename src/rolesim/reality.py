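"""The true state of the world: which roles favour which type, and abilities.

Six states of reality are modelled.  In models with real differences,
|_0.2 R_| roles favour type 0 and as many favour type 1; an agent of the
favoured type gets ``+offset`` on its N(100, 20) base ability for that role,
the other type ``-offset``.  The offset is 15 for the large-difference models
(between-type gap 30, Cohen's d = 30/20 = 1.5) and 4 for the small one
(d = 8/20 = 0.4).  In the vanishing-difference models agents created after
the vanish step receive no offsets at all.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import (ConfigurationError, LARGE_OFFSET_MODELS,
                     SMALL_OFFSET_MODEL, VANISHING_MODELS, WorldConfig)

LARGE_OFFSET = 15.0
SMALL_OFFSET = 4.0
FAVOURED_FRACTION = 0.2


def model_offset(model_id: int) -> float:
    """Ability offset magnitude implied by a state-of-reality model id."""
    if model_id in LARGE_OFFSET_MODELS:
        return LARGE_OFFSET
    if model_id == SMALL_OFFSET_MODEL:
        return SMALL_OFFSET
    if model_id == 3:
        return 0.0
    raise ConfigurationError(f"unknown model_id {model_id!r}")


@dataclass(frozen=True)
class RoleEffectTable:
    """Per role: favoured type (-1 none, 0, 1) and non-negative offset."""

    favoured_type: np.ndarray  # (R,) int8
    offset: np.ndarray         # (R,) float64

    @property
    def n_roles(self) -> int:
        return self.favoured_type.shape[0]

    def to_dict(self) -> dict:
        return {"favoured_type": self.favoured_type.tolist(),
                "offset": self.offset.tolist()}


def make_role_effects(model_id: int, n_roles: int,
                      rng: np.random.Generator) -> RoleEffectTable:
    """Draw the static favoured-role structure for one replicate.

    Model 3 returns all-neutral roles.  Otherwise |_0.2 R_| roles per type are
    drawn uniformly without replacement and given the model's offset.
    """
    off = model_offset(model_id)
    favoured = np.full(n_roles, -1, dtype=np.int8)
    offsets = np.zeros(n_roles)
    if off > 0.0:
        if n_roles < 5:
            raise ConfigurationError(
                "models with real differences need n_roles >= 5")
        k = int(FAVOURED_FRACTION * n_roles)
        chosen = rng.choice(n_roles, size=2 * k, replace=False)
        favoured[chosen[:k]] = 0
        favoured[chosen[k:]] = 1
        offsets[chosen] = off
    return RoleEffectTable(favoured, offsets)


def ability_matrix(owner_types: np.ndarray, created_at: int,
                   effects: RoleEffectTable, config: WorldConfig,
                   rng: np.random.Generator) -> np.ndarray:
    """True abilities, one row per agent, for agents created at one timestep.

    Base draws are iid N(ability_mean, ability_sd); the signed offset is
    applied per (agent type, role), except for agents created after the
    vanish step in vanishing-difference models.
    """
    owner_types = np.asarray(owner_types)
    base = rng.normal(config.ability_mean, config.ability_sd,
                      size=(owner_types.size, effects.n_roles))
    if config.vanish_step >= 0 and created_at > config.vanish_step:
        return base
    fav = effects.favoured_type
    sign = np.where(fav[None, :] < 0, 0.0,
                    np.where(owner_types[:, None] == fav[None, :], 1.0, -1.0))
    return base + sign * effects.offset[None, :]


def draw_abilities(owner_type: int, created_at: int, effects: RoleEffectTable,
                   config: WorldConfig, rng: np.random.Generator) -> np.ndarray:
    """True ability in every role for one agent of the given type."""
    return ability_matrix(np.array([owner_type]), created_at, effects,
                          config, rng)[0]


@dataclass(frozen=True)
class CohensDAudit:
    """Empirical effect sizes of the ability generator, by role class."""

    d_favoured: float  # favoured type minus other, pooled sd; nan if no class
    d_neutral: float   # type 0 minus type 1 on neutral roles


def _pooled_d(x: np.ndarray, y: np.ndarray) -> float:
    sp = np.sqrt((x.var(ddof=1) + y.var(ddof=1)) / 2.0)
    return float((x.mean() - y.mean()) / sp)


def cohens_d_audit(model_id: int, n_samples: int, rng: np.random.Generator,
                   n_roles: int = 60) -> CohensDAudit:
    """Measure the generator's realised Cohen's d between the two types.

    Draws ``n_samples`` agents per type through the ordinary ability
    generator and pools favoured roles (oriented so the favoured type is
    first) and neutral roles separately.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    cfg = WorldConfig(model_id=model_id, n_roles=n_roles)
    effects = make_role_effects(model_id, n_roles, rng)
    # n_samples agents per type, each with a full ability row
    a0 = ability_matrix(np.zeros(n_samples, dtype=int), 0, effects, cfg, rng)
    a1 = ability_matrix(np.ones(n_samples, dtype=int), 0, effects, cfg, rng)
    fav0 = effects.favoured_type == 0
    fav1 = effects.favoured_type == 1
    neutral = effects.favoured_type < 0
    if fav0.any():
        x = np.concatenate([a0[:, fav0].ravel(), a1[:, fav1].ravel()])
        y = np.concatenate([a1[:, fav0].ravel(), a0[:, fav1].ravel()])
        d_fav = _pooled_d(x, y)
    else:
        d_fav = float("nan")
    d_neu = _pooled_d(a0[:, neutral].ravel(), a1[:, neutral].ravel())
    return CohensDAudit(d_favoured=d_fav, d_neutral=d_neu)
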