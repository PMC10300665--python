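"""Compiled kernels for the agent-based labour-market simulation.

All hot-path logic lives here as numba ``@njit`` functions operating on plain
arrays; the public modules (:mod:`rolesim.cognition`, :mod:`rolesim.economy`,
:mod:`rolesim.simulation`) are thin wrappers over these kernels, so the maths
has a single source of truth.  Every kernel is also runnable un-compiled via
its ``.py_func`` attribute, which the test-suite uses to check compilation
fidelity against an identical RNG stream.

State layout (one world = one replicate):

* ``agent_type``   (N,)   int8   -- 0 or 1, fixed at creation
* ``created_at``   (N,)   int64  -- timestep the agent was created
* ``abilities``    (N,R)  f8     -- true ability per role (offsets applied)
* ``tried``        (N,R)  bool   -- roles with perfectly known own ability
* ``n_tried``      (N,)   int64
* ``occupation``   (N,)   int64  -- settled role, -1 if searching
* ``performing``   (N,)   int64  -- role produced this step, -1 before acting
* ``continuing``   (2,R)  int64  -- living agents of each type settled in role
* ``abandoned``    (2,R)  int64  -- living agents who tried the role and left
* ``role_supply``  (R,)   f8     -- summed ability of current producers
* ``belief_mean``  (2,R)  f8     -- cached posterior-expected ability per type
* ``ver``          (2,)   int64  -- [social-count version, cached version]

Price convention: the price of role r is ``k / (S_r / mu + 1)`` where S_r is
the summed ability of its current producers and mu the population mean
ability, i.e. supply measured in mean-agent units.  When an agent acts it
first vacates its production slot, so the prices it sees reflect the other
N-1 agents; the +1 keeps empty roles finite and accounts for one mean agent
joining.

Satisficing convention: an agent's reservation payoff is ``theta`` times its
estimated payoff of further search.  A tried role is adopted as occupation
when its realized payoff exceeds the reservation, and an occupation is
abandoned when its payoff drops below it; theta < 1 therefore models inertia,
settling agents early (often on heavily social information) and holding them
in place against moderate price declines.
"""

import numpy as np
from numba import njit

#: relative tolerance below which two payoffs count as an exact tie
TIE_RTOL = 1e-9


@njit(cache=True)
def posterior_kernel(c0, a0, c1, a1, q, delta):
    """Posterior (A0, A1, An) that a role favours type 0, type 1 or neither.

    Prior mass: q on each "favours type t" hypothesis, 1-2q on "neither".
    Each observed try is a Bernoulli continue-vs-abandon trial: p = 0.5 under
    the neutral hypothesis, 0.5 +/- delta under a favouring hypothesis.
    Computed in log space; binomial coefficients cancel in normalisation.
    """
    if q <= 0.0:
        return 0.0, 0.0, 1.0
    lph = np.log(0.5 + delta)
    lpl = np.log(0.5 - delta)
    lh = np.log(0.5)
    l0 = np.log(q) + c0 * lph + a0 * lpl + c1 * lpl + a1 * lph
    l1 = np.log(q) + c0 * lpl + a0 * lph + c1 * lph + a1 * lpl
    pn = 1.0 - 2.0 * q
    if pn > 0.0:
        ln = np.log(pn) + (c0 + a0 + c1 + a1) * lh
    else:
        ln = -np.inf
    m = l0
    if l1 > m:
        m = l1
    if ln > m:
        m = ln
    e0 = np.exp(l0 - m)
    e1 = np.exp(l1 - m)
    en = np.exp(ln - m)
    z = e0 + e1 + en
    return e0 / z, e1 / z, en / z


@njit(cache=True)
def refresh_beliefs(continuing, abandoned, belief_mean, q, s, delta, mu, sd):
    """Recompute the posterior-expected ability of each role for both types.

    A role believed to favour a type is expected to pay that type mu + s*sd
    in ability and the other type mu - s*sd, so the expected ability of role
    r for type 0 is ``A0*(mu+s*sd) + A1*(mu-s*sd) + An*mu`` (symmetrically
    for type 1).
    """
    n_roles = belief_mean.shape[1]
    hi = mu + s * sd
    lo = mu - s * sd
    for r in range(n_roles):
        a0, a1, an = posterior_kernel(
            continuing[0, r], abandoned[0, r],
            continuing[1, r], abandoned[1, r], q, delta,
        )
        belief_mean[0, r] = a0 * hi + a1 * lo + an * mu
        belief_mean[1, r] = a1 * hi + a0 * lo + an * mu


@njit(cache=True)
def search_value_kernel(i, exclude, agent_type, abilities, tried, n_tried,
                        role_supply, belief_mean, perfect, price_k, mu):
    """Estimated payoff of further search for agent i.

    Maximum expected payoff over roles the agent has not yet tried; if every
    role is tried, the best known payoff over roles other than ``exclude``
    (the current occupation, or the role whose adoption is being decided).
    """
    ty = agent_type[i]
    n_roles = role_supply.shape[0]
    best = -np.inf
    if n_tried[i] < n_roles:
        for r in range(n_roles):
            if tried[i, r]:
                continue
            price = price_k / (role_supply[r] / mu + 1.0)
            if perfect:
                e = abilities[i, r] * price
            else:
                e = belief_mean[ty, r] * price
            if e > best:
                best = e
    else:
        for r in range(n_roles):
            if r == exclude:
                continue
            e = abilities[i, r] * price_k / (role_supply[r] / mu + 1.0)
            if e > best:
                best = e
    return best


@njit(cache=True)
def choose_role_kernel(i, rng, agent_type, abilities, tried, n_tried,
                       role_supply, belief_mean, perfect, forced_min, price_k,
                       mu, vals):
    """Pick the role with the highest expected payoff; ties break uniformly.

    Tried roles are valued at known ability x price, untried ones at the
    posterior-expected ability x price (or known ability under perfect
    knowledge).  While an agent is still inside its forced-exploration quota
    only untried roles are candidates.  ``vals`` is a scratch buffer (R,).
    """
    ty = agent_type[i]
    n_roles = role_supply.shape[0]
    forced = n_tried[i] < forced_min
    best = -np.inf
    for r in range(n_roles):
        if forced and tried[i, r]:
            vals[r] = -np.inf
            continue
        price = price_k / (role_supply[r] / mu + 1.0)
        if perfect or tried[i, r]:
            v = abilities[i, r] * price
        else:
            v = belief_mean[ty, r] * price
        vals[r] = v
        if v > best:
            best = v
    cut = best - abs(best) * TIE_RTOL
    n_tie = 0
    for r in range(n_roles):
        if vals[r] >= cut:
            n_tie += 1
    if n_tie == 1:
        for r in range(n_roles):
            if vals[r] >= cut:
                return r
    pick = rng.integers(0, n_tie)
    seen = 0
    for r in range(n_roles):
        if vals[r] >= cut:
            if seen == pick:
                return r
            seen += 1
    return -1  # unreachable


@njit(cache=True)
def spawn_agent(i, t, rng, agent_type, created_at, abilities, tried, n_tried,
                occupation, fav_type, offsets, mu, sd, vanish_step):
    """Re-initialise slot i as a naive agent of the same type, born at t."""
    created_at[i] = t
    occupation[i] = -1
    n_tried[i] = 0
    n_roles = abilities.shape[1]
    no_offset = vanish_step >= 0 and t > vanish_step
    for r in range(n_roles):
        tried[i, r] = False
        a = rng.normal(mu, sd)
        if fav_type[r] >= 0 and not no_offset:
            if agent_type[i] == fav_type[r]:
                a += offsets[r]
            else:
                a -= offsets[r]
        abilities[i, r] = a


@njit(cache=True)
def remove_agent(i, agent_type, abilities, tried, n_tried, occupation,
                 performing, continuing, abandoned, role_supply, ver):
    """Erase a dying agent's contributions to supply and social counts."""
    ty = agent_type[i]
    p = performing[i]
    if p >= 0:
        role_supply[p] -= abilities[i, p]
        performing[i] = -1
    o = occupation[i]
    changed = False
    for r in range(tried.shape[1]):
        if tried[i, r]:
            if r == o:
                continuing[ty, r] -= 1
            else:
                abandoned[ty, r] -= 1
            changed = True
    if changed:
        ver[0] += 1


@njit(cache=True)
def act_agent(i, rng, agent_type, created_at, abilities, tried, n_tried,
              occupation, performing, continuing, abandoned, role_supply,
              belief_mean, ver, q, s, delta, perfect, theta, forced_min,
              price_k, mu, sd, vals):
    """One agent's turn: keep, abandon, or explore a role; live count updates."""
    ty = agent_type[i]
    p = performing[i]
    if p >= 0:
        role_supply[p] -= abilities[i, p]
        performing[i] = -1
    if (not perfect) and q > 0.0 and ver[0] != ver[1]:
        refresh_beliefs(continuing, abandoned, belief_mean, q, s, delta, mu,
                        sd)
        ver[1] = ver[0]
    o = occupation[i]
    if o >= 0:
        price_o = price_k / (role_supply[o] / mu + 1.0)
        payoff = abilities[i, o] * price_o
        sv = search_value_kernel(i, o, agent_type, abilities, tried, n_tried,
                                 role_supply, belief_mean, perfect, price_k,
                                 mu)
        if payoff < theta * sv * (1.0 - TIE_RTOL):
            continuing[ty, o] -= 1
            abandoned[ty, o] += 1
            occupation[i] = -1
            ver[0] += 1
        else:
            performing[i] = o
            role_supply[o] += abilities[i, o]
            return
    r = choose_role_kernel(i, rng, agent_type, abilities, tried, n_tried,
                           role_supply, belief_mean, perfect, forced_min,
                           price_k, mu, vals)
    first = not tried[i, r]
    if first:
        tried[i, r] = True
        n_tried[i] += 1
    price_r = price_k / (role_supply[r] / mu + 1.0)
    payoff = abilities[i, r] * price_r
    sv = search_value_kernel(i, r, agent_type, abilities, tried, n_tried,
                             role_supply, belief_mean, perfect, price_k, mu)
    if n_tried[i] >= forced_min and payoff > theta * sv * (1.0 + TIE_RTOL):
        occupation[i] = r
        if not first:
            abandoned[ty, r] -= 1
        continuing[ty, r] += 1
        ver[0] += 1
    elif first:
        abandoned[ty, r] += 1
        ver[0] += 1
    performing[i] = r
    role_supply[r] += abilities[i, r]


@njit(cache=True)
def step_world_kernel(t, rng, agent_type, created_at, abilities, tried,
                      n_tried, occupation, performing, continuing, abandoned,
                      role_supply, belief_mean, ver, fav_type, offsets,
                      death_rate, q, s, delta, perfect, theta, forced_min,
                      price_k, mu, sd, vanish_step):
    """Advance the world one timestep.

    Draws a fresh random order over agents; each either dies (probability
    ``death_rate``, replaced in place by a naive same-type agent that starts
    acting next step) or acts.  Counts and prices update live within the step.
    """
    n_agents = agent_type.shape[0]
    n_roles = role_supply.shape[0]
    vals = np.empty(n_roles, dtype=np.float64)
    perm = np.arange(n_agents)
    for i in range(n_agents - 1, 0, -1):
        j = rng.integers(0, i + 1)
        tmp = perm[i]
        perm[i] = perm[j]
        perm[j] = tmp
    for k in range(n_agents):
        i = perm[k]
        if t > 0 and created_at[i] == t:
            continue  # replacement spawned earlier this step
        if rng.random() < death_rate:
            remove_agent(i, agent_type, abilities, tried, n_tried, occupation,
                         performing, continuing, abandoned, role_supply, ver)
            spawn_agent(i, t, rng, agent_type, created_at, abilities, tried,
                        n_tried, occupation, fav_type, offsets, mu, sd,
                        vanish_step)
            continue
        act_agent(i, rng, agent_type, created_at, abilities, tried, n_tried,
                  occupation, performing, continuing, abandoned, role_supply,
                  belief_mean, ver, q, s, delta, perfect, theta, forced_min,
                  price_k, mu, sd, vals)
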