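"""Beliefs and decisions: posteriors, expected payoffs, choice, abandonment."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rolesim import (Priors, WorldConfig, choose_role, expected_payoff,
                     posterior_role_favour, search_value, should_abandon,
                     init_world)
from rolesim.cognition import PRIOR_PRESETS
from rolesim.fixtures import MiniWorldSpec, make_mini_world
from conftest import bayes_posterior_oracle

counts_st = st.tuples(*[st.integers(0, 100)] * 4)


def test_preset_table():
    assert PRIOR_PRESETS == {0: (0.0, 0.0), 1: (0.1, 0.2), 2: (0.1, 0.5),
                             3: (0.4, 0.2), 4: (0.4, 0.5)}
    assert Priors.from_preset("many-large") == Priors(0.4, 0.5, 4)
    assert Priors.from_preset(2).delta == 0.25


def test_egalitarian_prior_ignores_social_information():
    p = Priors.from_preset(0)
    for counts in [(0, 0, 0, 0), (50, 0, 0, 50), (3, 9, 1, 2)]:
        post = posterior_role_favour(counts, p)
        assert (post.a0, post.a1, post.an) == (0.0, 0.0, 1.0)


def test_symmetric_counts_give_symmetric_posterior():
    p = Priors.from_preset(4)
    post = posterior_role_favour((7, 3, 7, 3), p)
    assert post.a0 == pytest.approx(post.a1)


def test_worked_example_one_sided_counts():
    """Counts 8/2 continuing vs 2/8 point firmly at a type-0 favour."""
    p = Priors.from_preset(4)
    post = posterior_role_favour((8, 2, 2, 8), p)
    o0, o1, on = bayes_posterior_oracle(8, 2, 2, 8, p.q, p.delta)
    assert post.a0 == pytest.approx(o0, abs=1e-12)
    assert post.an == pytest.approx(on, abs=1e-12)
    assert post.a0 > post.an > post.a1


@pytest.mark.parametrize("preset", [1, 2, 3, 4])
def test_posterior_matches_bruteforce_bayes(preset):
    """Log-space kernel agrees with the explicit linear-space Bayes sum."""
    p = Priors.from_preset(preset)
    rng = np.random.default_rng(17)
    for _ in range(250):
        c0, a0, c1, a1 = rng.integers(0, 120, size=4)
        post = posterior_role_favour((c0, a0, c1, a1), p)
        oracle = bayes_posterior_oracle(int(c0), int(a0), int(c1), int(a1),
                                        p.q, p.delta)
        assert np.allclose(post.as_array(), oracle, atol=1e-10)


@settings(max_examples=300, derandomize=True)
@given(counts=counts_st, preset=st.integers(0, 4))
def test_posterior_normalised_and_bounded(counts, preset):
    post = posterior_role_favour(counts, Priors.from_preset(preset))
    arr = post.as_array()
    assert np.all(arr >= 0) and np.all(arr <= 1)
    assert abs(arr.sum() - 1.0) < 1e-12


@settings(max_examples=300, derandomize=True)
@given(counts=counts_st, preset=st.integers(1, 4))
def test_label_swap_equivariance(counts, preset):
    c0, a0, c1, a1 = counts
    p = Priors.from_preset(preset)
    post = posterior_role_favour((c0, a0, c1, a1), p)
    swapped = posterior_role_favour((c1, a1, c0, a0), p)
    assert post.a0 == pytest.approx(swapped.a1, abs=1e-12)
    assert post.a1 == pytest.approx(swapped.a0, abs=1e-12)
    assert post.an == pytest.approx(swapped.an, abs=1e-12)


@settings(max_examples=200, derandomize=True)
@given(counts=st.tuples(st.integers(0, 60), st.integers(0, 60),
                        st.integers(0, 60), st.integers(0, 60)),
       preset=st.integers(1, 4))
def test_more_onesided_evidence_raises_own_favour(counts, preset):
    c0, a0, c1, a1 = counts
    p = Priors.from_preset(preset)
    lo = posterior_role_favour((c0, a0, c1, a1), p).a0
    hi = posterior_role_favour((c0 + 1, a0, c1, a1), p).a0
    assert hi >= lo - 1e-12


def test_expected_payoff_examples():
    p = Priors.from_preset(2)  # s = 0.5
    neutral = posterior_role_favour((0, 0, 0, 0), Priors.from_preset(0))
    assert expected_payoff(0, neutral, p, price=1.0) == pytest.approx(100.0)
    sure0 = type(neutral)(1.0, 0.0, 0.0)
    assert expected_payoff(0, sure0, p, price=1.0) == pytest.approx(110.0)
    assert expected_payoff(1, sure0, p, price=1.0) == pytest.approx(90.0)
    assert expected_payoff(0, sure0, p, price=2.0) == pytest.approx(220.0)


def test_stronger_priors_amplify_type_gap():
    """|E0 - E1| weakly increases in both q and s for fixed one-sided counts."""
    counts = (6, 2, 2, 6)
    price = 1.0

    def gap(q, s):
        p = Priors(q=q, s=s)
        post = posterior_role_favour(counts, p)
        return abs(expected_payoff(0, post, p, price)
                   - expected_payoff(1, post, p, price))

    for s in (0.2, 0.5):
        gaps = [gap(q, s) for q in (0.0, 0.05, 0.1, 0.2, 0.3, 0.4)]
        assert np.all(np.diff(gaps) >= -1e-12)
    for q in (0.1, 0.4):
        gaps = [gap(q, s) for s in (0.1, 0.2, 0.3, 0.4, 0.5)]
        assert np.all(np.diff(gaps) >= -1e-12)


def _occupied_world(ability_occ, ability_alt, theta=1.0):
    """Two-agent perfect-knowledge world with agent 0 settled in role 0."""
    spec = MiniWorldSpec(n_agents=2, n_roles=2, perfect_knowledge=True,
                         abilities=np.array([[ability_occ, ability_alt],
                                             [100.0, 100.0]]),
                         theta=theta)
    w = make_mini_world(spec)
    w.tried[0, 0] = True
    w.n_tried[0] = 1
    w.occupation[0] = 0
    w.continuing[0, 0] = 1
    return w


def test_abandonment_boundary_and_thresholds():
    # payoff equal to the reservation is kept
    w = _occupied_world(100.0, 100.0)
    assert not should_abandon(w, 0, theta=1.0)
    # payoff 80 vs search value 100: leaves at 90% but not at 75%
    w = _occupied_world(80.0, 100.0)
    assert should_abandon(w, 0, theta=1.0)
    assert should_abandon(w, 0, theta=0.9)
    assert not should_abandon(w, 0, theta=0.75)


def test_abandonment_nested_in_theta():
    rng = np.random.default_rng(4)
    for _ in range(25):
        w = _occupied_world(rng.uniform(60, 130), rng.uniform(60, 130))
        flags = [should_abandon(w, 0, theta=t) for t in (0.75, 0.9, 1.0)]
        assert flags == sorted(flags)  # 0.75 abandons => 0.9 => 1.0


def test_search_value_max_over_untried():
    spec = MiniWorldSpec(n_agents=4, n_roles=4, perfect_knowledge=True,
                         abilities=np.array([[50., 80., 120., 90.]] * 4))
    w = make_mini_world(spec)
    price = w.cfg.price_unit
    assert search_value(w, 0) == pytest.approx(120.0 * price)
    w.tried[0, 2] = True
    w.n_tried[0] = 1
    assert search_value(w, 0) == pytest.approx(90.0 * price)  # max shrinks
    w.tried[0] = True
    w.n_tried[0] = 4
    w.occupation[0] = 2
    w.continuing[0, 2] = 1
    # all tried: best known alternative excluding the current occupation
    assert search_value(w, 0) == pytest.approx(90.0 * price)


def test_choose_role_argmax_and_uniform_tiebreak():
    cfg = WorldConfig(n_agents=60, n_roles=60, model_id=3, priors_preset=0,
                      seed=2)
    w = init_world(cfg)
    rng = np.random.default_rng(8)
    picks = np.array([choose_role(w, 0, rng) for _ in range(10_000)])
    hist = np.bincount(picks, minlength=60)
    assert hist.min() > 100 and hist.max() < 235  # ~167 +/- 5 sd
    # break the tie: a unique best role wins always
    w.abilities[0, 7] = 1000.0
    w.tried[0, 7] = True
    w.n_tried[0] = 1
    assert all(choose_role(w, 0, rng) == 7 for _ in range(20))


def test_choose_role_follows_own_type_majority():
    """Under difference priors, agents prefer roles their type dominates."""
    spec = MiniWorldSpec(n_agents=4, n_roles=2, priors_preset=4,
                         abilities=np.full((4, 2), 100.0),
                         continuing=np.array([[10, 0], [0, 10]]))
    w = make_mini_world(spec)
    rng = np.random.default_rng(9)
    assert w.agent_type[0] == 0 and w.agent_type[-1] == 1
    assert all(choose_role(w, 0, rng) == 0 for _ in range(20))
    assert all(choose_role(w, 3, rng) == 1 for _ in range(20))


def test_forced_exploration_restricts_to_untried():
    cfg = WorldConfig(n_agents=10, n_roles=6, model_id=5, seed=3)
    w = init_world(cfg)
    assert cfg.forced_min_roles == 4
    w.tried[0, [0, 1]] = True
    w.n_tried[0] = 2
    rng = np.random.default_rng(10)
    picks = {choose_role(w, 0, rng) for _ in range(100)}
    assert picks <= {2, 3, 4, 5}
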