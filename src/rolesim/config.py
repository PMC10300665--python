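"""World configuration: all parameters of one simulated labour market."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

#: models whose favoured roles carry the large (+/-15) ability offset
LARGE_OFFSET_MODELS = frozenset({1, 4, 5, 6})
#: model with the small offset calibrated to d = 0.4 (Delta = 4 at sd 20)
SMALL_OFFSET_MODEL = 2
#: models in which agents created after ``vanish_step`` get no offsets
VANISHING_MODELS = frozenset({4, 5, 6})
#: forced-exploration minima implied by the model id
FORCED_MIN_BY_MODEL = {5: 4, 6: 10}


class ConfigurationError(ValueError):
    """Raised for invalid simulation configurations."""


@dataclass
class WorldConfig:
    """Parameters of one replicate.

    Defaults are the headline study conditions: 1000 agents (500 per type),
    60 roles, 400 timesteps, 5% death per agent-step, abilities ~ N(100, 20).
    ``model_id`` selects the state of reality (1 large real differences,
    2 small, 3 none, 4 vanishing after step 40, 5/6 vanishing plus forced
    exploration of >= 4 / >= 10 roles).  ``priors_preset`` selects the shared
    beliefs (0 egalitarian .. 4 many-large); ``perfect_knowledge`` replaces
    belief-based valuation with each agent's true abilities.  ``theta`` is the
    switching threshold: an occupation is abandoned when its payoff drops
    below ``theta`` x the estimated payoff of further search.
    """

    n_agents: int = 1000
    n_roles: int = 60
    n_steps: int = 400
    death_rate: float = 0.05
    ability_mean: float = 100.0
    ability_sd: float = 20.0
    model_id: int = 3
    priors_preset: int = 0
    perfect_knowledge: bool = False
    theta: float = 1.0
    forced_min_roles: int | None = None
    vanish_step: int | None = None
    price_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model_id not in range(1, 7):
            raise ConfigurationError(f"unknown model_id {self.model_id!r}")
        if self.priors_preset not in range(5):
            raise ConfigurationError(
                f"unknown priors preset {self.priors_preset!r}")
        if self.n_agents <= 0 or self.n_agents % 2:
            raise ConfigurationError("n_agents must be positive and even "
                                     "(the two types are balanced)")
        if self.n_roles < 2:
            raise ConfigurationError("need at least 2 roles")
        if self.n_steps < 0:
            raise ConfigurationError("n_steps must be >= 0")
        if not 0.0 <= self.death_rate < 1.0:
            raise ConfigurationError("death_rate must be in [0, 1)")
        if not 0.0 < self.theta <= 1.0:
            raise ConfigurationError("theta must be in (0, 1]")
        if self.ability_sd <= 0 or self.price_scale <= 0:
            raise ConfigurationError("ability_sd and price_scale must be > 0")
        if self.forced_min_roles is None:
            self.forced_min_roles = FORCED_MIN_BY_MODEL.get(self.model_id, 0)
        if not 0 <= self.forced_min_roles < self.n_roles:
            raise ConfigurationError(
                "forced_min_roles must satisfy 0 <= E < n_roles")
        if self.vanish_step is None:
            self.vanish_step = 40 if self.model_id in VANISHING_MODELS else -1

    @property
    def price_unit(self) -> float:
        """Numerator of the scarcity price, N/R (price ~ 1 at uniform load)."""
        return self.price_scale * self.n_agents / self.n_roles

    def to_dict(self) -> dict:
        return asdict(self)
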