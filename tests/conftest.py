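import numpy as np
import pytest

from causalstates import (
    fixture_machine_2state,
    fixture_machine_3state,
    fixture_machine_coin,
    fixture_transducer_2state,
    simulate_input_process,
    simulate_machine,
    simulate_transducer,
)


@pytest.fixture(scope="session")
def m_coin():
    return fixture_machine_coin()


@pytest.fixture(scope="session")
def m2():
    return fixture_machine_2state()


@pytest.fixture(scope="session")
def m3():
    return fixture_machine_3state()


@pytest.fixture(scope="session")
def t2():
    return fixture_transducer_2state()


@pytest.fixture(scope="session")
def seq3_long(m3):
    """One long realization of the three-state machine, shared across tests."""
    return simulate_machine(m3, 200_000, 12345)


@pytest.fixture(scope="session")
def pair2_long(t2):
    """Long (input, output) realization of the two-state transducer with
    fair-coin inputs."""
    inputs = simulate_input_process(200_000, 0.5, 54321)
    return simulate_transducer(t2, inputs, 98765)


@pytest.fixture
def period2_machine():
    from causalstates import EpsilonMachine

    return EpsilonMachine(
        states=("A", "B"),
        transitions={("A", 1): (1.0, "B"), ("B", 0): (1.0, "A")},
    )


@pytest.fixture
def alternating_seq():
    from causalstates import BinarySequence

    return BinarySequence(np.tile([0, 1], 5000))
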