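"""Parameter-recovery experiments on the printed average models.

Each experiment simulates a long realization from a fixture, runs the
matching reconstruction, and reads the estimated probabilities off the
states identified by their defining contexts (e.g. the state reached
after two consecutive trolling symbols).  These are the package's
end-to-end checks that reconstruction recovers the generators it is
pointed at.
"""

from __future__ import annotations

from .cssr import estimate_machine
from .models import CSSRConfig, state_after_context
from .synth import (
    fixture_machine_2state,
    fixture_machine_3state,
    fixture_transducer_2state,
    simulate_input_process,
    simulate_machine,
    simulate_transducer,
)
from .transducer import estimate_transducer

__all__ = [
    "three_state_recovery",
    "two_state_recovery",
    "transducer_recovery",
    "memoryless_baseline",
]


def three_state_recovery(seed: int, n: int = 200_000, lmax: int = 3, alpha: float = 0.001) -> dict:
    """Simulate the three-state average machine and re-estimate it.

    Returns the recovered state count, the troll self-stay probability
    (P(1) from the state reached after '11') and the transition-to-troll
    probability (P(1) from the state reached after '01')."""
    seq = simulate_machine(fixture_machine_3state(), n, seed)
    est = estimate_machine(seq, CSSRConfig(alpha=alpha, lmax=lmax))
    out = {"n_states": est.n_states, "troll_stay": None, "transition_to_troll": None}
    troll = state_after_context(est, seq, [1, 1])
    transition = state_after_context(est, seq, [0, 1])
    if troll is not None:
        out["troll_stay"] = float(est.next_symbol_dist(troll)[1])
    if transition is not None:
        out["transition_to_troll"] = float(est.next_symbol_dist(transition)[1])
    return out


def two_state_recovery(seed: int, n: int = 200_000, lmax: int = 2, alpha: float = 0.001) -> dict:
    """Simulate the two-state average machine and re-estimate the troll
    self-stay probability (P(1) from the state reached after a '1')."""
    seq = simulate_machine(fixture_machine_2state(), n, seed)
    est = estimate_machine(seq, CSSRConfig(alpha=alpha, lmax=lmax))
    out = {"n_states": est.n_states, "troll_stay": None}
    troll = state_after_context(est, seq, [1])
    if troll is not None:
        out["troll_stay"] = float(est.next_symbol_dist(troll)[1])
    return out


def transducer_recovery(seed: int, n: int = 200_000, lmax: int = 2, alpha: float = 0.001) -> dict:
    """Simulate the two-state average transducer under fair-coin inputs
    and re-estimate its input-conditional responses.

    Recovered quantities: P(1 | non-troll state, troll parent) — the
    contagious switch; P(1 | troll state, troll parent) — the reinforced
    stay; P(0 | non-troll state, benign parent) — the benign stay."""
    inputs = simulate_input_process(n, 0.5, seed)
    pair = simulate_transducer(fixture_transducer_2state(), inputs, seed + 1)
    est = estimate_transducer(pair, CSSRConfig(alpha=alpha, lmax=lmax))
    out = {
        "n_states": est.n_states,
        "switch_on_troll_input": None,
        "stay_troll_on_troll_input": None,
        "stay_nontroll_on_benign_input": None,
    }
    hm = est.history_map or {}
    # joint pair codes 2*input + output: states identified by last output
    non_troll = hm.get((0,), hm.get((2,)))
    troll = hm.get((1,), hm.get((3,)))
    if non_troll is not None and (non_troll, 1) in est.emissions:
        out["switch_on_troll_input"] = float(est.emissions[(non_troll, 1)][1])
    if troll is not None and (troll, 1) in est.emissions:
        out["stay_troll_on_troll_input"] = float(est.emissions[(troll, 1)][1])
    if non_troll is not None and (non_troll, 0) in est.emissions:
        out["stay_nontroll_on_benign_input"] = float(est.emissions[(non_troll, 0)][0])
    return out


def memoryless_baseline(seed: int, n: int = 50_000, lmax: int = 3, alpha: float = 0.001) -> int:
    """State count recovered from i.i.d. fair-coin data (should be 1)."""
    from .synth import fixture_machine_coin

    seq = simulate_machine(fixture_machine_coin(), n, seed)
    est = estimate_machine(seq, CSSRConfig(alpha=alpha, lmax=lmax))
    return est.n_states
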