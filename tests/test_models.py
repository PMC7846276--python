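"""Choice-probability models: closed forms, oracles, limits, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

from lapsekit import models as M

PHI_1 = 0.8413447460685429  # standard normal CDF at 1, frozen oracle value


# ---------------------------------------------------------------------------
# psychometric curve
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("x, params, expected", [
    (12.5, (12.5, 1.0, 0.1, 0.2), 0.45),           # midpoint: gamma + (1-g-l)/2
    (1e9, (12.5, 1.0, 0.1, 0.2), 0.8),             # upper asymptote 1 - lam
    (-1e9, (12.5, 1.0, 0.1, 0.2), 0.1),            # lower asymptote gamma
    (13.5, (12.5, 1.0, 0.0, 0.0), PHI_1),          # normal-CDF oracle
])
def test_psychometric_prob_values(x, params, expected):
    p = M.psychometric_prob(x, M.PsychometricParams(*params))
    assert p == pytest.approx(expected, abs=1e-9)


def test_psychometric_prob_rejects_bad_inputs():
    with pytest.raises(ValueError, match="sigma"):
        M.PsychometricParams(12.5, 0.0)
    with pytest.raises(ValueError, match="gamma"):
        M.PsychometricParams(12.5, 1.0, gamma=1.2)
    with pytest.raises(ValueError):
        M.PsychometricParams(12.5, 1.0, gamma=0.7, lam=0.6)  # sum > 1
    with pytest.raises(ValueError, match="finite"):
        M.psychometric_prob(np.nan, M.PsychometricParams(12.5, 1.0))


# ---------------------------------------------------------------------------
# cue combination and belief state
# ---------------------------------------------------------------------------

def test_combined_sigma_closed_form():
    assert M.combined_sigma(3.0, 4.0) == pytest.approx(2.4, abs=1e-12)
    assert M.combined_sigma(2.0, 2.0) == pytest.approx(2.0 / np.sqrt(2), abs=1e-12)
    assert M.combined_sigma(1.0, 1e9) == pytest.approx(1.0, rel=1e-9)
    with pytest.raises(ValueError):
        M.combined_sigma(-1.0, 2.0)


@given(st.floats(0.1, 10), st.floats(0.1, 10))
@settings(derandomize=True, max_examples=50)
def test_combined_sigma_never_exceeds_best_cue(sa, sv):
    assert M.combined_sigma(sa, sv) <= min(sa, sv) + 1e-12


def test_sensory_params_reliability_weights():
    sp = M.SensoryParams(sigma_a=3.0, sigma_v=4.0)
    assert sp.sigma_m == pytest.approx(2.4, abs=1e-12)  # optimal combination
    assert sp.w_a + sp.w_v == pytest.approx(1.0, abs=1e-12)
    assert sp.w_a == pytest.approx(sp.sigma_m**2 / 9.0, abs=1e-12)
    with pytest.raises(ValueError):
        M.SensoryParams(sigma_a=-1.0, sigma_v=2.0)


def test_belief_state_record_validation():
    b = M.BeliefState(x_combined=13.1, rho=M.belief_state(13.1, 12.5, 1.3),
                      s_true=13.0, category="High")
    assert 0.5 < b.rho < 1.0
    with pytest.raises(ValueError):
        M.BeliefState(x_combined=13.1, rho=1.2)


def test_belief_state_values():
    assert M.belief_state(12.5, 12.5, 1.3) == pytest.approx(0.5)
    assert M.belief_state(1e9, 12.5, 1.3) == pytest.approx(1.0)
    assert M.belief_state(12.5 + 1.3, 12.5, 1.3) == pytest.approx(PHI_1, abs=1e-9)
    with pytest.raises(ValueError):
        M.belief_state(12.0, 12.5, 0.0)


def test_belief_state_strictly_increasing():
    x = np.linspace(5, 20, 200)
    rho = M.belief_state(x, 12.5, 2.0)
    assert np.all(np.diff(rho) > 0)


def test_action_values():
    assert M.action_values(1.0, 2.0, 1.0) == (2.0, 0.0)
    assert M.action_values(0.0, 2.0, 1.0) == (0.0, 1.0)
    assert M.action_values(0.5, 1.0, 1.0) == (0.5, 0.5)
    # reversed contingency swaps the category -> action map
    assert M.action_values(1.0, 2.0, 1.0, contingency="reversed") == (0.0, 1.0)
    with pytest.raises(ValueError):
        M.action_values(1.5, 1.0, 1.0)


# ---------------------------------------------------------------------------
# ideal observer
# ---------------------------------------------------------------------------

def test_ideal_observer_symmetry_and_oracle():
    assert M.ideal_observer_prob(12.5, 2.0, 12.5) == pytest.approx(0.5)
    assert M.ideal_observer_prob(12.5 + 2.0, 2.0, 12.5) == pytest.approx(PHI_1, abs=1e-9)


def test_ideal_observer_reward_bias():
    # rR = 2 rL: criterion at posterior 1/3, so p(R) at the boundary is 2/3
    p = M.ideal_observer_prob(12.5, 2.0, 12.5, r_right=2.0, r_left=1.0)
    assert p == pytest.approx(1.0 - norm.cdf(norm.ppf(1.0 / 3.0)), abs=1e-12)
    assert p == pytest.approx(2.0 / 3.0, abs=1e-12)


def test_ideal_observer_asymptotes_exact():
    assert M.ideal_observer_prob(1e9, 2.0, 12.5) == 1.0
    assert M.ideal_observer_prob(-1e9, 2.0, 12.5) == 0.0
    with pytest.raises(ValueError):
        M.ideal_observer_prob(12.0, -1.0, 12.5)


# ---------------------------------------------------------------------------
# inattention and epsilon-greedy
# ---------------------------------------------------------------------------

def test_inattention_reduces_exactly_to_ideal():
    s = np.linspace(9, 16, 30)
    np.testing.assert_array_equal(
        M.inattention_prob(s, 2.0, 12.5, p_attend=1.0, p_bias=0.3),
        M.ideal_observer_prob(s, 2.0, 12.5))


def test_epsilon_greedy_reduces_exactly_to_ideal():
    s = np.linspace(9, 16, 30)
    np.testing.assert_array_equal(
        M.epsilon_greedy_prob(s, 2.0, 12.5, eps=0.0, p_bias=0.3),
        M.ideal_observer_prob(s, 2.0, 12.5))


def test_inattention_limit_value():
    # p_attend = 0.9, p_bias = 0.5: upper asymptote 0.95 (lam = 0.05)
    assert M.inattention_prob(1e9, 2.0, 12.5, 0.9, 0.5) == pytest.approx(0.95)


def test_epsilon_greedy_asymptote_values():
    # eps = 0.2, p_bias = 0.5: asymptotes 0.1 and 0.9
    assert M.epsilon_greedy_prob(-1e9, 2.0, 12.5, 0.2, 0.5) == pytest.approx(0.1)
    assert M.epsilon_greedy_prob(1e9, 2.0, 12.5, 0.2, 0.5) == pytest.approx(0.9)


# ---------------------------------------------------------------------------
# exploration model
# ---------------------------------------------------------------------------

def test_exploration_symmetry():
    assert M.exploration_prob(12.5, 1.3, 12.5, beta=1.7) == pytest.approx(0.5, abs=1e-12)


def test_exploration_matches_monte_carlo_oracle():
    """Quadrature agrees with a 10^6-sample forward simulation of the
    belief-state softmax within 3 Monte-Carlo standard errors."""
    s, sigma, mu0, beta = 12.5 + 1.3, 1.3, 12.5, 1.0
    rng = np.random.default_rng(42)
    x = rng.normal(s, sigma, 1_000_000)
    rho = M.belief_state(x, mu0, sigma)
    samples = 1.0 / (1.0 + np.exp(-beta * (2.0 * rho - 1.0)))
    mc, se = samples.mean(), samples.std(ddof=1) / 1000.0
    assert abs(M.exploration_prob(s, sigma, mu0, beta) - mc) < 3 * se


@pytest.mark.parametrize("beta", [0.3, 2.0, 8.0, 40.0])
@pytest.mark.parametrize("s", [9.0, 12.5, 14.5])
def test_exploration_matches_rho_space_integral(beta, s):
    """The observation-space quadrature equals the belief-space
    density-ratio integral (they differ only by a change of variables)."""
    q = M.exploration_prob(s, 1.6, 12.5, beta, 1.4, 1.0)
    r = M._exploration_prob_rho_space(s, 1.6, 12.5, beta, 1.4, 1.0)
    assert q == pytest.approx(r, abs=1e-6)


def test_exploration_asymptote_closed_forms():
    g, l = M.exploration_asymptotes(1.0, 1.0, 1.0)
    assert g == pytest.approx(1.0 / (1.0 + np.e), abs=1e-12)
    assert l == pytest.approx(1.0 / (1.0 + np.e), abs=1e-12)
    assert M.exploration_asymptotes(1e4, 1.0, 1.0) == pytest.approx((0.0, 0.0), abs=1e-12)
    assert M.exploration_asymptotes(0.0, 1.0, 1.0) == (0.5, 0.5)


def test_exploration_curve_reaches_asymptotes():
    g, l = M.exploration_asymptotes(2.0, 1.5, 1.0)
    assert M.exploration_prob(-1e3, 1.3, 12.5, 2.0, 1.5, 1.0) == pytest.approx(g, abs=1e-4)
    assert M.exploration_prob(1e3, 1.3, 12.5, 2.0, 1.5, 1.0) == pytest.approx(1 - l, abs=1e-4)


def test_exploration_large_beta_is_ideal_observer():
    s = np.linspace(9, 16, 29)
    err = np.abs(M.exploration_prob(s, 1.3, 12.5, 1e4)
                 - M.ideal_observer_prob(s, 1.3, 12.5))
    assert err.max() < 1e-3


@given(st.floats(0.2, 8.0), st.floats(0.5, 3.0), st.floats(0.2, 3.0),
       st.floats(0.2, 3.0))
@settings(derandomize=True, max_examples=40, deadline=None)
def test_exploration_monotone_and_bounded(beta, sigma, rr, rl):
    s = np.linspace(7, 18, 45)
    p = M.exploration_prob(s, sigma, 12.5, beta, rr, rl)
    assert np.all(p >= 0) and np.all(p <= 1)
    assert np.all(np.diff(p) >= -1e-12)


@given(st.floats(0.1, 10.0), st.floats(0.1, 5.0), st.floats(0.1, 5.0),
       st.floats(0.05, 2.0))
@settings(derandomize=True, max_examples=100)
def test_lapse_dissociation_is_exact(beta, rr, rl, bump):
    """Perturbing rR moves only lam; perturbing rL moves only gamma."""
    g0, l0 = M.exploration_asymptotes(beta, rr, rl)
    g1, l1 = M.exploration_asymptotes(beta, rr + bump, rl)
    g2, l2 = M.exploration_asymptotes(beta, rr, rl + bump)
    assert g1 == g0 and l1 < l0
    assert l2 == l0 and g2 < g0


@given(st.floats(0.0, 1.0), st.floats(0.0, 1.0), st.floats(0.1, 5.0),
       st.floats(9.0, 16.0))
@settings(derandomize=True, max_examples=60)
def test_all_model_probabilities_in_unit_interval(pa, pb, sigma, s):
    for p in (M.inattention_prob(s, sigma, 12.5, pa, pb),
              M.epsilon_greedy_prob(s, sigma, 12.5, pa, pb),
              M.ideal_observer_prob(s, sigma, 12.5),
              M.exploration_prob(s, sigma, 12.5, 4.0 * pa, 1 + pb, 1.0)):
        assert 0.0 <= p <= 1.0


# ---------------------------------------------------------------------------
# matching rule (no-lapse contrast)
# ---------------------------------------------------------------------------

def test_matching_rule_values():
    assert M.matching_rule_prob(1.0, 1.0, 3.0) == pytest.approx(0.5)
    assert M.matching_rule_prob(2.0, 1.0, 1.0) == pytest.approx(2.0 / 3.0)
    with pytest.raises(ValueError):
        M.matching_rule_prob(0.0, 1.0, 1.0)


def test_matching_rule_produces_no_lapses():
    """As Q_L -> 0 the matching rule saturates at 1 for any beta > 0,
    unlike the value-softmax whose asymptote stays below 1."""
    for beta in (0.5, 1.0, 4.0):
        assert M.matching_rule_prob(1.0, 1e-12, beta) > 1.0 - 1e-3
    _, lam = M.exploration_asymptotes(1.0, 1.0, 1.0)
    assert lam > 0.2  # the softmax observer lapses; the matcher does not


def test_asymptote_identities_from_value_params():
    vals = M.trained_values(r_right=1.4, r_left=0.8, beta=2.0)
    g, l = M.exploration_asymptotes_values(vals)
    g2, l2 = M.exploration_asymptotes(2.0, 1.4, 0.8)
    assert g == pytest.approx(g2, abs=1e-15)
    assert l == pytest.approx(l2, abs=1e-15)
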