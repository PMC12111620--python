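"""Fixture machines, simulators, and cohort generation."""

import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from causalstates import (
    CohortConfig,
    fixture_machine_3state,
    fixture_transducer_2state,
    fixture_transducer_balanced,
    generate_cohort,
    simulate_input_process,
    simulate_machine,
    simulate_transducer,
    stationary_distribution,
    validate_machine,
    validate_transducer,
)
from causalstates.io import machine_to_json
from causalstates.synth import _jitter_prob


def test_two_state_fixture_probabilities(m2):
    assert m2.transitions[("troll", 1)][0] == pytest.approx(0.67)
    assert m2.transitions[("non-troll", 0)][0] == pytest.approx(0.69)
    for state in m2.states:
        assert m2.next_symbol_dist(state).sum() == pytest.approx(1.0)


def test_two_state_stationary_values(m2):
    pi = stationary_distribution(m2)
    assert pi["troll"] == pytest.approx(0.31 / (0.31 + 0.33), abs=1e-12)
    assert pi["non-troll"] == pytest.approx(0.516, abs=1e-3)


def test_three_state_fixture_structure(m3):
    assert m3.transitions[("non-troll", 0)][0] == pytest.approx(0.68)
    assert m3.transitions[("transition", 1)][0] == pytest.approx(0.39)
    assert m3.transitions[("troll", 1)][0] == pytest.approx(0.76)
    # troll unreachable directly from non-troll; transition unreachable from troll
    assert m3.transitions[("non-troll", 1)][1] == "transition"
    assert m3.transitions[("troll", 0)][1] == "non-troll"
    assert validate_machine(m3) == []
    assert set(m3.recurrent_states) == {"non-troll", "transition", "troll"}


def test_transducer_fixture_conditionals(t2):
    assert t2.emissions[("non-troll", 1)][1] == pytest.approx(0.48)
    assert t2.emissions[("troll", 1)][1] == pytest.approx(0.72)
    assert t2.emissions[("troll", 0)][0] == pytest.approx(0.71)
    assert t2.emissions[("troll", 0)][1] == pytest.approx(0.29)  # complement
    for dist in t2.emissions.values():
        assert dist.sum() == pytest.approx(1.0)
    assert validate_transducer(t2) == []


def test_balanced_transducer_marginal_is_memoryless():
    tb = fixture_transducer_balanced()
    for state in tb.states:
        marginal = 0.5 * tb.emissions[(state, 0)][1] + 0.5 * tb.emissions[(state, 1)][1]
        assert marginal == pytest.approx(0.4)


def test_simulate_coin_law_of_large_numbers(m_coin):
    seq = simulate_machine(m_coin, 100_000, 1)
    assert seq.symbols.mean() == pytest.approx(0.5, abs=0.01)


def test_simulate_period2_exact(period2_machine):
    seq = simulate_machine(period2_machine, 1000, 3)
    diffs = np.abs(np.diff(seq.symbols.astype(int)))
    assert (diffs == 1).all()


def test_simulate_three_state_conditional_frequencies(seq3_long):
    s = seq3_long.symbols
    after_11 = s[2:][(s[:-2] == 1) & (s[1:-1] == 1)]
    assert after_11.mean() == pytest.approx(0.76, abs=0.01)
    after_01 = s[2:][(s[:-2] == 0) & (s[1:-1] == 1)]
    assert after_01.mean() == pytest.approx(0.39, abs=0.01)


def test_simulate_transducer_conditional_frequencies(pair2_long):
    y, x = pair2_long.inputs, pair2_long.outputs.symbols
    stay_troll = x[1:][(x[:-1] == 1) & (y[1:] == 1)]
    assert stay_troll.mean() == pytest.approx(0.72, abs=0.01)
    switch = x[1:][(x[:-1] == 0) & (y[1:] == 1)]
    assert switch.mean() == pytest.approx(0.48, abs=0.01)


def test_transducer_all_zero_inputs_marginal_chain(t2):
    pair = simulate_transducer(t2, np.zeros(200_000, dtype=np.int8), 9)
    x = pair.outputs.symbols
    p1_given_1 = x[1:][x[:-1] == 1].mean()
    p1_given_0 = x[1:][x[:-1] == 0].mean()
    assert p1_given_1 == pytest.approx(0.29, abs=0.01)
    assert p1_given_0 == pytest.approx(0.28, abs=0.01)


@pytest.mark.parametrize("p_one, expected", [(0.0, 0.0), (1.0, 1.0)])
def test_input_process_degenerate(p_one, expected):
    arr = simulate_input_process(1000, p_one, 4)
    assert arr.mean() == expected


def test_input_process_mean():
    arr = simulate_input_process(100_000, 0.5, 5)
    assert arr.mean() == pytest.approx(0.5, abs=0.01)


def test_cohort_reproducible_byte_identical():
    cfg = CohortConfig(n_users=5, length_range=(200, 400), seed=42)
    a = generate_cohort(cfg)
    b = generate_cohort(cfg)
    for ua, ub in zip(a, b):
        assert ua.archetype == ub.archetype
        assert np.array_equal(ua.pair.inputs, ub.pair.inputs)
        assert np.array_equal(ua.pair.outputs.symbols, ub.pair.outputs.symbols)
        if hasattr(ua.truth, "transitions") and hasattr(ua.truth, "states"):
            if hasattr(ua.truth, "emissions"):
                for k in ua.truth.emissions:
                    assert np.array_equal(ua.truth.emissions[k], ub.truth.emissions[k])
            else:
                assert json.loads(machine_to_json(ua.truth)) == json.loads(
                    machine_to_json(ub.truth)
                )


def test_cohort_pure_coin_mix():
    cfg = CohortConfig(
        n_users=8,
        length_range=(200, 200),
        mix={"coin": 1.0, "two_state": 0.0, "three_state": 0.0, "transducer_coupled": 0.0},
        seed=1,
    )
    for user in generate_cohort(cfg):
        assert user.archetype == "coin"
        assert len(user.truth.recurrent_states) == 1


def test_cohort_zero_jitter_equals_fixture():
    cfg = CohortConfig(
        n_users=4,
        length_range=(200, 200),
        mix={"coin": 0.0, "two_state": 0.0, "three_state": 1.0, "transducer_coupled": 0.0},
        jitter=0.0,
        seed=2,
    )
    ref = machine_to_json(fixture_machine_3state())
    for user in generate_cohort(cfg):
        assert machine_to_json(user.truth) == ref


def test_cohort_jittered_machines_valid():
    cfg = CohortConfig(n_users=20, length_range=(200, 300), jitter=0.05, seed=3)
    for user in generate_cohort(cfg):
        if hasattr(user.truth, "emissions"):
            assert validate_transducer(user.truth) == []
        else:
            assert validate_machine(user.truth) == []


def test_cohort_config_validation():
    with pytest.raises(ValueError, match="sum to 1"):
        CohortConfig(mix={"coin": 0.5, "two_state": 0.1, "three_state": 0.1,
                          "transducer_coupled": 0.1})
    with pytest.raises(ValueError, match="jitter"):
        CohortConfig(jitter=0.5)
    with pytest.raises(ValueError, match="lengths"):
        CohortConfig(length_range=(10, 20))


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    p=st.floats(min_value=0.02, max_value=0.98),
    sd=st.floats(min_value=0.0, max_value=0.1),
    seed=st.integers(min_value=0, max_value=2**31 - 1),
)
def test_jitter_keeps_probabilities_in_bounds(p, sd, seed):
    rng = np.random.default_rng(seed)
    out = _jitter_prob(p, sd, rng)
    assert 0.01 <= out <= 0.99


def test_convergence_rate_of_conditional_frequencies(m3):
    """Empirical conditional frequencies approach generator probabilities
    roughly like n^(-1/2)."""
    errs = {}
    for n in (1_000, 10_000, 100_000):
        seq = simulate_machine(m3, n, 77)
        s = seq.symbols
        after_11 = s[2:][(s[:-2] == 1) & (s[1:-1] == 1)]
        errs[n] = abs(after_11.mean() - 0.76)
    # allow generous slack on a single realization: 10x the binomial scale
    for n, err in errs.items():
        assert err < 10 / np.sqrt(0.28 * n)
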