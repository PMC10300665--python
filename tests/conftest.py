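"""Shared fixtures: session-scoped caches of full-scale replicate runs.

Full-scale conditions (1000 agents x 60 roles x 400 steps) are expensive, and
several tests interrogate the same conditions; ``condition_runs`` memoises
them for the whole session under a fixed base seed.
"""

import numpy as np
import pytest

from rolesim import run_condition

BASE_SEED = 7
REPLICATES = 10


def finals(results):
    """Final-timestep segregation of each replicate."""
    return np.array([r.segregation[-1] for r in results])


@pytest.fixture(scope="session")
def condition_runs():
    """Memoised accessor: (model, priors, theta) -> list of results."""
    cache = {}

    def get(model, priors, theta, reps=REPLICATES):
        key = (model, priors, theta, reps)
        if key not in cache:
            cache[key] = run_condition(model, priors, theta, reps,
                                       base_seed=BASE_SEED)
        return cache[key]

    return get


def bayes_posterior_oracle(c0, a0, c1, a1, q, delta):
    """Brute-force three-hypothesis Bayes rule, explicit sum, linear space."""
    weights = []
    for hyp in ("favours0", "favours1", "neither"):
        prior = q if hyp != "neither" else 1.0 - 2.0 * q
        if hyp == "favours0":
            p0, p1 = 0.5 + delta, 0.5 - delta
        elif hyp == "favours1":
            p0, p1 = 0.5 - delta, 0.5 + delta
        else:
            p0, p1 = 0.5, 0.5
        like = (p0 ** c0 * (1 - p0) ** a0) * (p1 ** c1 * (1 - p1) ** a1)
        weights.append(prior * like)
    z = sum(weights)
    return tuple(w / z for w in weights)
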