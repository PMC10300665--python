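"""Scarcity pricing and payoffs.

Each role yields goods priced by scarcity, so agents are better off producing
rare goods; this negative feedback forces a division of labour.  Goods output
is proportional to the producers' ability, so the supply of role r is the
summed ability of its current performers, measured in mean-agent units
``s_r = S_r / mu``.  The price is ``(N/R) / (s_r + 1)``: strictly positive
(empty roles stay finite and attractive), strictly decreasing in supply, and
~1 at uniform load of average producers.  An agent's payoff is its true
ability in the role times the price in force when it acts.
"""

from __future__ import annotations

import numpy as np

from .config import WorldConfig


def compute_price(supply, config: WorldConfig):
    """Scarcity price of a role given the summed ability of its producers.

    ``supply`` is the total ability currently producing the role (0 for an
    empty role); for ``n`` producers of exactly average ability it equals
    ``n * ability_mean`` and the price reduces to ``(N/R) / (n + 1)``.
    """
    s = np.asarray(supply, dtype=float)
    if np.any(s < 0):
        raise ValueError("supply must be >= 0")
    return config.price_unit / (s / config.ability_mean + 1.0)


def realized_payoff(ability, price):
    """Payoff actually earned: ability x price."""
    if np.any(np.asarray(price) <= 0):
        raise ValueError("price must be positive")
    return ability * price
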