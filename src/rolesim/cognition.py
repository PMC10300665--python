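"""Agent beliefs and decisions.

Agents estimate how well an unexplored role would pay them from three
ingredients: globally shared priors about group differences, social counts of
living agents of each type who tried the role and stayed or left, and the
role's current scarcity price.  Roles an agent has performed are valued by the
perfectly known own ability instead.  This module exposes the belief and
decision operations on top of the compiled kernels in :mod:`rolesim._engine`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _engine
from .config import ConfigurationError

#: maximum Bernoulli shift, keeps continue-probabilities inside (0, 1)
DELTA_CAP = 0.45

#: preset id -> (q, s): expected proportion of roles favouring each type and
#: expected favour size in ability-sd units (relative to neutral)
PRIOR_PRESETS = {
    0: (0.0, 0.0),    # egalitarian: certain no role favours either type
    1: (0.1, 0.2),    # few small differences
    2: (0.1, 0.5),    # few large differences
    3: (0.4, 0.2),    # many small differences
    4: (0.4, 0.5),    # many large differences
}

PRESET_NAMES = {
    "none": 0, "few-small": 1, "few-large": 2,
    "many-small": 3, "many-large": 4,
}


@dataclass(frozen=True)
class Priors:
    """Shared beliefs: q roles per type expected to differ, by s sd units."""

    q: float
    s: float
    preset: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= 2.0 * self.q <= 1.0:
            raise ConfigurationError("priors require 0 <= 2q <= 1")
        if self.s < 0.0:
            raise ConfigurationError("priors require s >= 0")

    @classmethod
    def from_preset(cls, preset: int | str) -> "Priors":
        if isinstance(preset, str):
            try:
                preset = PRESET_NAMES[preset]
            except KeyError:
                raise ConfigurationError(f"unknown priors preset {preset!r}")
        if preset not in PRIOR_PRESETS:
            raise ConfigurationError(f"unknown priors preset {preset!r}")
        q, s = PRIOR_PRESETS[preset]
        return cls(q=q, s=s, preset=preset)

    @property
    def delta(self) -> float:
        """Bernoulli continue-probability shift under a favouring hypothesis."""
        return min(self.s / 2.0, DELTA_CAP)


@dataclass(frozen=True)
class PosteriorTriple:
    """Probabilities that a role favours type 0, type 1, or neither."""

    a0: float
    a1: float
    an: float

    def as_array(self) -> np.ndarray:
        return np.array([self.a0, self.a1, self.an])


def posterior_role_favour(counts, priors: Priors) -> PosteriorTriple:
    """Infer whether one role favours type 0, type 1 or neither.

    ``counts`` is ``(continuing_0, abandoned_0, continuing_1, abandoned_1)``
    over living agents.  Prior mass q goes on each favouring hypothesis and
    1-2q on neutrality; each observed try-outcome is a Bernoulli
    continue-vs-abandon trial with continue-probability 0.5 under neutrality
    and 0.5 +/- delta (delta = s/2) under a favouring hypothesis.  With q = 0
    (egalitarian priors) social information is ignored: (0, 0, 1).
    """
    c0, a0, c1, a1 = (float(x) for x in counts)
    if min(c0, a0, c1, a1) < 0:
        raise ValueError("social counts must be non-negative")
    p0, p1, pn = _engine.posterior_kernel(c0, a0, c1, a1, priors.q,
                                          priors.delta)
    return PosteriorTriple(p0, p1, pn)


def expected_payoff(agent_type: int, posterior: PosteriorTriple,
                    priors: Priors, price: float,
                    mu: float = 100.0, sd: float = 20.0) -> float:
    """Expected payoff of an untried role for an agent of the given type.

    The prior effect size s enters twice, exactly as in inference: a role
    believed to favour the agent's own type is expected to pay
    ``mu + s*sd`` in ability units, the other type's roles ``mu - s*sd``.
    """
    if price <= 0:
        raise ValueError("price must be positive")
    own = posterior.a0 if agent_type == 0 else posterior.a1
    other = posterior.a1 if agent_type == 0 else posterior.a0
    ability = (own * (mu + priors.s * sd)
               + other * (mu - priors.s * sd)
               + posterior.an * mu)
    return price * ability


def _world_args(world):
    world.refresh_beliefs()
    return (world.agent_type, world.abilities, world.tried, world.n_tried,
            world.role_supply, world.belief_mean, world.cfg.perfect_knowledge,
            world.cfg.price_unit, world.cfg.ability_mean)


def search_value(world, agent_id: int, exclude: int | None = None) -> float:
    """Estimated payoff of further search for one agent, at current state.

    The maximum expected payoff over roles the agent has not yet tried; once
    every role is tried, the best known payoff over roles other than
    ``exclude`` (by default the agent's current occupation).
    """
    if exclude is None:
        exclude = int(world.occupation[agent_id])
    return float(_engine.search_value_kernel(
        agent_id, exclude, *_world_args(world)))


def choose_role(world, agent_id: int, rng: np.random.Generator) -> int:
    """Role with the highest expected payoff; exact ties break uniformly.

    Tried roles are valued at known ability x price, untried roles at the
    posterior-expected ability x price.  Inside the forced-exploration quota
    only untried roles are candidates.
    """
    (atype, abil, tried, ntried, supply, bmean, perfect, price_k,
     mu) = _world_args(world)
    vals = np.empty(world.cfg.n_roles)
    return int(_engine.choose_role_kernel(
        agent_id, rng, atype, abil, tried, ntried, supply, bmean, perfect,
        world.cfg.forced_min_roles, price_k, mu, vals))


def should_abandon(world, agent_id: int, theta: float | None = None) -> bool:
    """True iff the occupation pays < theta x the current value of search.

    The agent's threshold equals its estimated payoff of further search; the
    occupation is held until its payoff drops below the fraction theta of it
    (e.g. because the price of the good falls).  Payoff exactly at the
    reservation level is kept.
    """
    o = int(world.occupation[agent_id])
    if o < 0:
        raise ValueError("agent has no occupation to abandon")
    if theta is None:
        theta = world.cfg.theta
    price = world.cfg.price_unit / (
        world.role_supply[o] / world.cfg.ability_mean + 1.0)
    payoff = float(world.abilities[agent_id, o]) * price
    sv = search_value(world, agent_id, exclude=o)
    return payoff < theta * sv * (1.0 - _engine.TIE_RTOL)
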