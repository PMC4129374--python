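"""Model components and the trial-level likelihood, checked against
independent hand-rolled recursions of the same equations."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import igtmodel as ig
from igtmodel.models import ModelKind


# --- independent oracle: a literal, scalar re-derivation of the models ---

def oracle_loglik(model, p, choices, outcomes):
    """Straight transcription of utility/learning/softmax recursions."""
    E = [0.0, 0.0, 0.0, 0.0]
    Ps = [0.0, 0.0, 0.0, 0.0]
    theta = 3.0 ** p.c - 1.0
    total = 0.0
    per = []
    for ch, x in zip(choices, outcomes):
        j = ch - 1
        if model == "vpp":
            V = [p.w * E[i] + (1 - p.w) * Ps[i] for i in range(4)]
        else:
            V = E[:]
        denom = sum(math.exp(theta * (V[i] - max(V))) for i in range(4))
        lp = theta * (V[j] - max(V)) - math.log(denom)
        per.append(lp)
        total += lp
        u = x ** p.alpha if x >= 0 else -p.lam * (-x) ** p.alpha
        if model == "pvl-decay":
            E = [p.A * e for e in E]
            E[j] += u
        else:
            E[j] += p.A * (u - E[j])
        if model == "vpp":
            Ps = [p.k * q for q in Ps]
            Ps[j] += p.eps_p if x >= 0 else p.eps_n
    return total, per


@pytest.mark.parametrize("x,alpha,lam,expected", [
    (0.0, 0.7, 2.0, 0.0),
    (4.0, 0.5, 3.0, 2.0),
    (-4.0, 0.5, 1.5, -3.0),
])
def test_prospect_utility_values(x, alpha, lam, expected):
    assert ig.prospect_utility(x, alpha, lam) == pytest.approx(expected)


def test_prospect_utility_bounds_enforced():
    with pytest.raises(ValueError, match="alpha"):
        ig.prospect_utility(1.0, 2.5, 1.0)
    with pytest.raises(ValueError, match="lam"):
        ig.prospect_utility(1.0, 0.5, 11.0)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(x=st.floats(0.01, 20), alpha=st.floats(0.05, 1.95),
       lam=st.floats(1.01, 9.9))
def test_loss_aversion_asymmetry(x, alpha, lam):
    """lam > 1 makes a loss loom larger than the equal-sized gain."""
    assert abs(ig.prospect_utility(-x, alpha, lam)) > ig.prospect_utility(x, alpha, lam)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(xs=st.lists(st.floats(-30, 30), min_size=2, max_size=6),
       alpha=st.floats(0.05, 1.95), lam=st.floats(0.05, 9.9))
def test_prospect_utility_monotone(xs, alpha, lam):
    xs = sorted(xs)
    us = [ig.prospect_utility(x, alpha, lam) for x in xs]
    assert all(a <= b + 1e-12 for a, b in zip(us, us[1:]))


def test_learning_rule_examples():
    np.testing.assert_allclose(
        ig.decay_update([1, 1, 1, 1], 2, 2.0, 0.5), [0.5, 2.5, 0.5, 0.5])
    np.testing.assert_allclose(
        ig.decay_update([1, 2, 3, 4], 1, 5.0, 0.0), [5, 0, 0, 0])
    np.testing.assert_allclose(ig.decay_update([1, 2, 3, 4], 3, 0.0, 1.0),
                               [1, 2, 3, 4])
    np.testing.assert_allclose(
        ig.delta_update([0, 0, 0, 0], 1, 1.0, 0.1), [0.1, 0, 0, 0])
    np.testing.assert_allclose(
        ig.delta_update([1, 2, 3, 4], 2, 9.0, 1.0), [1, 9, 3, 4])
    np.testing.assert_allclose(
        ig.delta_update([1, 2, 3, 4], 2, 9.0, 0.0), [1, 2, 3, 4])


def test_perseverance_update_examples():
    np.testing.assert_allclose(
        ig.perseverance_update([0, 0, 0, 0], 3, +1, 0.5, 1.0, -1.0),
        [0, 0, 1, 0])
    np.testing.assert_allclose(
        ig.perseverance_update([1, 2, 3, 4], 1, +1, 1.0, 0.0, 0.0),
        [1, 2, 3, 4])
    np.testing.assert_allclose(
        ig.perseverance_update([2, 0, 0, 0], 1, -1, 0.5, 1.0, -1.0),
        [0, 0, 0, 0])


def test_combine_value():
    np.testing.assert_allclose(ig.combine_value([1, 0, 0, 0], [0, 1, 0, 0], 1.0),
                               [1, 0, 0, 0])
    np.testing.assert_allclose(ig.combine_value([1, 0, 0, 0], [0, 1, 0, 0], 0.0),
                               [0, 1, 0, 0])
    np.testing.assert_allclose(ig.combine_value([1, 0, 0, 0], [0, 1, 0, 0], 0.5),
                               [0.5, 0.5, 0, 0])


@pytest.mark.parametrize("c,theta", [(0, 0.0), (1, 2.0), (5, 242.0)])
def test_sensitivity_from_consistency(c, theta):
    assert ig.sensitivity_from_consistency(c) == pytest.approx(theta)


def test_sensitivity_rejects_out_of_range():
    with pytest.raises(ValueError):
        ig.sensitivity_from_consistency(5.5)


def test_choice_probabilities_uniform_and_peaked():
    np.testing.assert_allclose(ig.choice_probabilities([3, -1, 9, 0], 0.0),
                               [0.25] * 4)
    np.testing.assert_allclose(ig.choice_probabilities([2, 2, 2, 2], 50.0),
                               [0.25] * 4)
    p = ig.choice_probabilities([1, 0, 0, 0], 242.0)
    assert p[0] > 1 - 1e-10


@settings(max_examples=80, deadline=None, derandomize=True)
@given(values=st.lists(st.floats(-3, 3), min_size=4, max_size=4),
       theta=st.floats(0, 230))
def test_choice_probabilities_conserved(values, theta):
    p = ig.choice_probabilities(values, theta)
    assert p.sum() == pytest.approx(1.0, abs=1e-12)
    assert np.all(p >= 0)


def test_choice_probabilities_rejects_nonfinite():
    with pytest.raises(ValueError):
        ig.choice_probabilities([np.inf, 0, 0, 0], 1.0)


@pytest.mark.parametrize("model", ["pvl-delta", "pvl-decay", "vpp"])
def test_likelihood_matches_independent_recursion(model, scaled_schedule):
    """Kernel likelihood equals the literal scalar recursion to 1e-10."""
    p = ig.SubjectParameters(A=0.37, alpha=0.81, c=1.9, lam=2.4,
                             eps_p=0.3, eps_n=-0.5, k=0.6, w=0.55)
    seq = ig.simulate_subject(model, p, scaled_schedule, T=60, rng_seed=7)
    total, per = ig.subject_log_likelihood(model, p, seq)
    o_total, o_per = oracle_loglik(model, p, seq.choices, seq.net_outcomes)
    assert total == pytest.approx(o_total, abs=1e-10)
    np.testing.assert_allclose(per, o_per, atol=1e-10)


def test_likelihood_two_deck_enumeration(scaled_schedule):
    """All 2^3 choice paths over decks {1,2}: probabilities from the
    per-trial log densities agree with exhaustive enumeration and the
    restricted path probabilities sum to the softmax normalisation."""
    import itertools
    p = ig.SubjectParameters(A=0.5, alpha=0.9, c=1.0, lam=1.2)
    outcomes = {1: [-2.0, 1.0, -0.5], 2: [0.5, 0.5, 0.5]}
    for path in itertools.product([1, 2], repeat=3):
        xs = [outcomes[d][t] for t, d in enumerate(path)]
        seq = ig.ChoiceSequence(choices=np.array(path),
                                net_outcomes=np.array(xs))
        total, per = ig.subject_log_likelihood("pvl-delta", p, seq)
        o_total, o_per = oracle_loglik("pvl-delta", p, path, xs)
        assert total == pytest.approx(o_total, abs=1e-10)
        assert np.all(np.exp(per) <= 1.0 + 1e-12)


def test_likelihood_closed_forms(scaled_schedule, pvl_params):
    """theta = 0 gives T * ln(1/4); a single trial is always ln(1/4)."""
    seq = ig.simulate_subject("pvl-delta", pvl_params, scaled_schedule,
                              T=100, rng_seed=9)
    p0 = ig.SubjectParameters(A=0.2, alpha=0.4, c=0.0, lam=2.0)
    total, per = ig.subject_log_likelihood("pvl-delta", p0, seq)
    assert total == pytest.approx(100 * np.log(0.25), abs=1e-9)
    one = ig.ChoiceSequence(choices=[3], net_outcomes=[1.0])
    t1, _ = ig.subject_log_likelihood("pvl-delta", pvl_params, one)
    assert t1 == pytest.approx(np.log(0.25), abs=1e-12)


def test_empty_sequence_rejected():
    with pytest.raises(ValueError, match="empty"):
        ig.ChoiceSequence(choices=[], net_outcomes=[])


def test_parameter_counts():
    assert ModelKind.VPP.n_params == 8
    assert ModelKind.PVL_DELTA.n_params == 4
    assert ModelKind.PVL_DECAY.n_params == 4


def test_simulation_deterministic(scaled_schedule, vpp_params):
    a = ig.simulate_subject("vpp", vpp_params, scaled_schedule, T=100, rng_seed=5)
    b = ig.simulate_subject("vpp", vpp_params, scaled_schedule, T=100, rng_seed=5)
    np.testing.assert_array_equal(a.choices, b.choices)
    np.testing.assert_array_equal(a.net_outcomes, b.net_outcomes)


def test_vpp_with_full_rl_weight_reduces_to_pvl_delta(scaled_schedule):
    shared = dict(A=0.25, alpha=0.6, c=1.4, lam=1.1)
    pvl = ig.SubjectParameters(**shared)
    vpp = ig.SubjectParameters(**shared, eps_p=0.9, eps_n=-0.9, k=0.3, w=1.0)
    a = ig.simulate_subject("pvl-delta", pvl, scaled_schedule, T=100, rng_seed=11)
    b = ig.simulate_subject("vpp", vpp, scaled_schedule, T=100, rng_seed=11)
    np.testing.assert_array_equal(a.choices, b.choices)


def test_random_agent_uniform_deck_frequencies(scaled_schedule):
    """theta = 0 agents choose each deck with probability ~1/4."""
    p = ig.SubjectParameters(A=0.3, alpha=0.5, c=0.0, lam=1.0)
    counts = np.zeros(4)
    for r in range(100):
        seq = ig.simulate_subject("pvl-delta", p, scaled_schedule, T=100,
                                  rng_seed=r)
        counts += np.bincount(seq.choices - 1, minlength=4)
    freq = counts / counts.sum()
    np.testing.assert_allclose(freq, 0.25, atol=0.02)


def test_simulated_outcomes_come_from_schedule(scaled_schedule, pvl_params):
    """Each trial's outcome equals the card served at that deck's draw count."""
    seq = ig.simulate_subject("pvl-delta", pvl_params, scaled_schedule,
                              T=100, rng_seed=13)
    counters = {d: 0 for d in "ABCD"}
    for t in range(seq.T):
        deck = "ABCD"[seq.choices[t] - 1]
        counters[deck] += 1
        assert seq.net_outcomes[t] == pytest.approx(
            scaled_schedule.draw_card(deck, counters[deck]))


def test_high_alpha_low_lambda_agents_prefer_deck_b(scaled_schedule):
    """Gain-driven, loss-insensitive agents gravitate to the big-win deck B."""
    p = ig.SubjectParameters(A=0.2, alpha=1.2, c=1.5, lam=0.1)
    counts = np.zeros(4)
    for r in range(30):
        seq = ig.simulate_subject("pvl-decay", p, scaled_schedule, T=100,
                                  rng_seed=200 + r)
        counts += np.bincount(seq.choices - 1, minlength=4)
    assert counts.argmax() == 1  # deck B
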