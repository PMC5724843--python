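"""Post-war fusion: enumeration engine, analytic rank maps, payoffs."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from warskew import (
    GroupConfig,
    Individual,
    analytic_coefficients,
    analytic_new_rank,
    build_population,
    enumerate_merge,
    payoff_shares,
    post_war_payoff,
)


def _pops(cfg1, cfg2):
    return build_population(cfg1, 1), build_population(cfg2, 2)


def test_hand_enumerated_three_survivors():
    """Strengths g1=[2,1], g2=[3,0.5], kill 1: survivor order is 2, 1, 0.5."""
    cfg1 = GroupConfig(2, 50.0, 3.0, 0.5, 0.5)  # shares 2, 1 of S=3
    cfg2 = GroupConfig(2, 50.0, 3.5, 0.5, 5 / 6)  # shares 3, 0.5 of S=3.5
    pop1, pop2 = _pops(cfg1, cfg2)
    np.testing.assert_allclose(pop1.strengths, [2.0, 1.0])
    np.testing.assert_allclose(pop2.strengths, [3.0, 0.5])
    out = enumerate_merge(pop1, pop2, 1)
    assert out.killed == [(2, 1)]
    assert list(out.new_rank_g1) == [1, 2]
    assert list(out.new_rank_g2) == [0, 3]
    # payoffs follow payoff_shares(X1+X2, beta1, 3) at the new ranks
    expected = payoff_shares(100.0, 0.5, 3)
    np.testing.assert_allclose(out.payoff_g1, expected[:2], rtol=1e-12)
    assert out.payoff_g2[0] == 0.0
    assert out.payoff_g2[1] == pytest.approx(expected[2], rel=1e-12)
    # post_war_payoff agrees on the Individual interface
    assert post_war_payoff(Individual(2, 1, 3.0, 37.5), out) == 0.0
    assert post_war_payoff(Individual(1, 1, 2.0, 33.0), out) == pytest.approx(expected[0])


def test_total_elimination_reduces_to_winner_profile(equal_cfg):
    pop1, pop2 = _pops(equal_cfg, equal_cfg)
    out = enumerate_merge(pop1, pop2, equal_cfg.n_males)
    assert out.n_merged == equal_cfg.n_males
    assert list(out.new_rank_g1) == list(range(1, equal_cfg.n_males + 1))
    np.testing.assert_allclose(
        out.payoff_g1,
        payoff_shares(200.0, equal_cfg.beta, equal_cfg.n_males),
        rtol=1e-12,
    )
    assert np.all(out.payoff_g2 == 0.0)


def test_identical_groups_interleave_with_group1_above(equal_cfg):
    """Equal-strength ties: group-1 rank i lands at 2i-1, his group-2 twin at 2i."""
    pop1, pop2 = _pops(equal_cfg, equal_cfg)
    out = enumerate_merge(pop1, pop2, 0)
    n = equal_cfg.n_males
    assert list(out.new_rank_g1) == [2 * i - 1 for i in range(1, n + 1)]
    assert list(out.new_rank_g2) == [2 * i for i in range(1, n + 1)]


def test_nk_domain_error(equal_cfg):
    pop1, pop2 = _pops(equal_cfg, equal_cfg)
    with pytest.raises(ValueError):
        enumerate_merge(pop1, pop2, equal_cfg.n_males + 1)
    with pytest.raises(ValueError):
        enumerate_merge(pop1, pop2, -1)


@given(
    n1=st.integers(1, 60),
    n2=st.integers(1, 60),
    beta1=st.floats(0.0, 0.9),
    beta2=st.floats(0.0, 0.9),
    sigma1=st.floats(0.0, 0.9),
    sigma2=st.floats(0.0, 0.9),
    kill_frac=st.floats(0.0, 1.0),
)
@settings(max_examples=120, deadline=None)
def test_merge_bijection_and_conservation(n1, n2, beta1, beta2, sigma1, sigma2, kill_frac):
    cfg1 = GroupConfig(n1, 80.0, 50.0, beta1, sigma1)
    cfg2 = GroupConfig(n2, 120.0, 90.0, beta2, sigma2)
    pop1, pop2 = _pops(cfg1, cfg2)
    n_kill = int(round(kill_frac * n2))
    out = enumerate_merge(pop1, pop2, n_kill)
    survivors = np.concatenate([out.new_rank_g1, out.new_rank_g2[n_kill:]])
    assert sorted(survivors) == list(range(1, n1 + n2 - n_kill + 1))
    # source-group order preserved among survivors
    assert np.all(np.diff(out.new_rank_g1) > 0)
    assert np.all(np.diff(out.new_rank_g2[n_kill:]) > 0)
    total = out.payoff_g1.sum() + out.payoff_g2.sum()
    assert total == pytest.approx(200.0, rel=1e-9)
    assert np.all(out.payoff_g2[:n_kill] == 0.0)


def test_more_killing_never_hurts_survivors(equal_cfg):
    """Raising n_kill removes sharers and competitors: payoffs weakly rise."""
    pop1, pop2 = _pops(equal_cfg, equal_cfg)
    prev = enumerate_merge(pop1, pop2, 0)
    for nk in range(1, equal_cfg.n_males + 1):
        cur = enumerate_merge(pop1, pop2, nk)
        assert np.all(cur.payoff_g1 >= prev.payoff_g1 - 1e-12)
        alive = slice(nk, None)
        assert np.all(cur.payoff_g2[alive] >= prev.payoff_g2[alive] - 1e-12)
        prev = cur


@pytest.mark.parametrize("s1,s2", list(itertools.product([0.05, 0.1, 0.2], repeat=2)))
@pytest.mark.parametrize("n", [10, 50])
@pytest.mark.parametrize("nk", [0, 5])
def test_analytic_ranks_match_enumeration(s1, s2, n, nk):
    """Floor/ceiling-rounded analytic ranks track the exact sort within +/-1."""
    cfg1 = GroupConfig(n, 100.0, 120.0, s1, s1)
    cfg2 = GroupConfig(n, 100.0, 100.0, s2, s2)
    pop1, pop2 = _pops(cfg1, cfg2)
    out = enumerate_merge(pop1, pop2, nk)
    coeffs = analytic_coefficients(cfg1, cfg2, nk)
    for ind in pop1.members:
        r = math.floor(analytic_new_rank(ind, coeffs, cfg1, cfg2, nk) + 1e-9)
        assert abs(r - out.new_rank_g1[ind.rank - 1]) <= 1
    for ind in pop2.members:
        if ind.rank <= nk:
            continue
        r = math.ceil(analytic_new_rank(ind, coeffs, cfg1, cfg2, nk) - 1e-9)
        assert abs(r - out.new_rank_g2[ind.rank - 1]) <= 1


def test_analytic_exact_for_identical_groups(equal_cfg):
    cfg = equal_cfg
    coeffs = analytic_coefficients(cfg, cfg, 0)
    assert (coeffs.M, coeffs.mu, coeffs.B) == (1.0, 1.0, 1.0)
    pop1, pop2 = _pops(cfg, cfg)
    for ind in pop1.members:
        assert analytic_new_rank(ind, coeffs, cfg, cfg, 0) == pytest.approx(2 * ind.rank - 1)
    for ind in pop2.members:
        assert analytic_new_rank(ind, coeffs, cfg, cfg, 0) == pytest.approx(2 * ind.rank)


def test_analytic_coefficients_strength_ratio():
    cfg1 = GroupConfig(100, 100.0, 200.0, 0.1, 0.1)
    cfg2 = GroupConfig(200, 100.0, 100.0, 0.1, 0.1)
    coeffs = analytic_coefficients(cfg1, cfg2, 0)
    assert coeffs.M == 2.0
    assert coeffs.mu == 1.0
    expected_b = (1 - 0.9 ** 100) / (1 - 0.9 ** 200)
    assert coeffs.B == pytest.approx(expected_b, rel=1e-12)


def test_analytic_requires_positive_sigma(equal_cfg):
    flat = GroupConfig(10, 100.0, 100.0, 0.1, 0.0)
    with pytest.raises(ValueError):
        analytic_coefficients(flat, equal_cfg, 0)


def test_killed_individual_has_no_analytic_rank(equal_cfg):
    coeffs = analytic_coefficients(equal_cfg, equal_cfg, 3)
    victim = Individual(2, 1, 1.0, 1.0)
    with pytest.raises(ValueError):
        analytic_new_rank(victim, coeffs, equal_cfg, equal_cfg, 3)
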