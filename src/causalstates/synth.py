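"""Synthetic cohorts of behavior sequences with known ground truth.

The fixtures are the population-average hidden-state models of trolling
dynamics whose transition probabilities are reported for Reddit users:
a two-state machine (troll / non-troll with sticky self-transitions), a
three-state machine (with an intermediate "transition" gateway state into
trolling), and a two-state transducer whose trolling probability shifts
with the parent comment's label.  Cohorts mix memoryless (coin) users
with users driven by these machines, so every downstream stage — CSSR
reconstruction, information measures, model averaging, population tests —
can be exercised and validated against known generators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .models import (
    BinarySequence,
    EpsilonMachine,
    EpsilonTransducer,
    IOSequencePair,
    stationary_distribution,
    validate_machine,
)

__all__ = [
    "CohortConfig",
    "CohortUser",
    "fixture_machine_coin",
    "fixture_machine_2state",
    "fixture_machine_3state",
    "fixture_transducer_2state",
    "simulate_machine",
    "simulate_transducer",
    "simulate_input_process",
    "generate_cohort",
]

DEFAULT_MIX = {
    "coin": 0.6,
    "two_state": 0.2,
    "three_state": 0.1,
    "transducer_coupled": 0.1,
    "balanced_coupled": 0.0,
}


def fixture_machine_coin(p_one: float = 0.5) -> EpsilonMachine:
    """Single-state machine: behavior is an i.i.d. coin flip."""
    return EpsilonMachine(
        states=("S0",),
        transitions={
            ("S0", 0): (1.0 - p_one, "S0"),
            ("S0", 1): (p_one, "S0"),
        },
    )


def fixture_machine_2state() -> EpsilonMachine:
    """Average two-state self-driven machine: once trolling, a user stays
    trolling with probability 0.67; once not, stays non-trolling with 0.69."""
    return EpsilonMachine(
        states=("non-troll", "troll"),
        transitions={
            ("non-troll", 0): (0.69, "non-troll"),
            ("non-troll", 1): (0.31, "troll"),
            ("troll", 1): (0.67, "troll"),
            ("troll", 0): (0.33, "non-troll"),
        },
    )


def fixture_machine_3state() -> EpsilonMachine:
    """Average three-state self-driven machine.

    Trolling is reached only through an intermediate "transition" state
    (entered from non-troll with probability 0.32); from there the user
    advances to the troll state with probability 0.39 or falls back.  The
    troll state is sticky (self-stay 0.76) and exits only to non-troll.
    """
    return EpsilonMachine(
        states=("non-troll", "transition", "troll"),
        transitions={
            ("non-troll", 0): (0.68, "non-troll"),
            ("non-troll", 1): (0.32, "transition"),
            ("transition", 1): (0.39, "troll"),
            ("transition", 0): (0.61, "non-troll"),
            ("troll", 1): (0.76, "troll"),
            ("troll", 0): (0.24, "non-troll"),
        },
    )


def fixture_transducer_2state() -> EpsilonTransducer:
    """Average two-state social-induced transducer.

    The hidden state is the label of the user's own last comment.  A troll
    parent raises the trolling probability in both states: switching into
    trolling happens with probability 0.48 after a troll parent versus
    0.28 after a benign one, and trolling persists with 0.72 after a troll
    parent while a benign parent keeps a non-trolling run going with 0.71.
    """
    emissions = {
        ("non-troll", 1): np.array([0.52, 0.48]),
        ("non-troll", 0): np.array([0.72, 0.28]),
        ("troll", 1): np.array([0.28, 0.72]),
        ("troll", 0): np.array([0.71, 0.29]),
    }
    transitions = {
        (state, inp, out): ("troll" if out == 1 else "non-troll")
        for state in ("non-troll", "troll")
        for inp in (0, 1)
        for out in (0, 1)
    }
    return EpsilonTransducer(
        states=("non-troll", "troll"),
        emissions=emissions,
        transitions=transitions,
    )


def fixture_transducer_balanced() -> EpsilonTransducer:
    """Two-state transducer whose coupling is invisible to the self-driven
    view: trolling probability is 0.6 or 0.2 depending on whether the
    parent's label disagrees with the user's own last label, so the
    input-marginalized output process is i.i.d. Bernoulli(0.4) (one causal
    state) while the input-conditional model has two.  Used for cohorts
    that emulate populations where most users look memoryless self-driven
    yet show hidden multi-state patterns once social input is considered.
    """
    emissions = {
        ("non-troll", 0): np.array([0.8, 0.2]),
        ("non-troll", 1): np.array([0.4, 0.6]),
        ("troll", 0): np.array([0.4, 0.6]),
        ("troll", 1): np.array([0.8, 0.2]),
    }
    transitions = {
        (state, inp, out): ("troll" if out == 1 else "non-troll")
        for state in ("non-troll", "troll")
        for inp in (0, 1)
        for out in (0, 1)
    }
    return EpsilonTransducer(
        states=("non-troll", "troll"),
        emissions=emissions,
        transitions=transitions,
    )


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_machine(m: EpsilonMachine, n: int, seed) -> BinarySequence:
    """Draw a length-``n`` realization, starting from the stationary
    distribution over recurrent states."""
    if n < 1:
        raise ValueError("n must be >= 1")
    violations = validate_machine(m)
    if violations:
        raise ValueError(f"machine invalid: {violations}")
    rng = _rng(seed)
    rec = list(m.recurrent_states)
    pi = stationary_distribution(m)
    start = rng.choice(len(rec), p=[pi[s] for s in rec])

    idx = {s: i for i, s in enumerate(rec)}
    p_one = np.zeros(len(rec))
    nxt = np.full((len(rec), 2), -1, dtype=np.int64)
    for (state, sym), (prob, dest) in m.transitions.items():
        if state in idx:
            if sym == 1:
                p_one[idx[state]] = prob
            nxt[idx[state], sym] = idx[dest]

    u = rng.random(n)
    out = np.empty(n, dtype=np.int8)
    s = int(start)
    for t in range(n):
        x = 1 if u[t] < p_one[s] else 0
        out[t] = x
        s = nxt[s, x]
    return BinarySequence(out)


def simulate_input_process(n: int, p_one: float, seed) -> np.ndarray:
    """i.i.d. Bernoulli(p_one) input labels (the parent-comment stream)."""
    if not 0.0 <= p_one <= 1.0:
        raise ValueError("p_one must lie in [0, 1]")
    rng = _rng(seed)
    return (rng.random(n) < p_one).astype(np.int8)


def simulate_transducer(t: EpsilonTransducer, inputs, seed) -> IOSequencePair:
    """Drive the transducer with the given input labels: outputs[i] is
    drawn from the emission distribution of (state_i, inputs[i]), and the
    state follows the unifilar transition on (input, output)."""
    inputs = np.asarray(inputs, dtype=np.int8)
    if inputs.size == 0:
        raise ValueError("inputs must be nonempty")
    if not np.isin(inputs, (0, 1)).all():
        raise ValueError("input symbol outside the {0,1} alphabet")
    rng = _rng(seed)
    rec = list(t.recurrent_states)
    idx = {s: i for i, s in enumerate(rec)}
    p_one = np.full((len(rec), 2), np.nan)
    for (state, inp), dist in t.emissions.items():
        if state in idx:
            p_one[idx[state], inp] = dist[1]
    nxt = np.full((len(rec), 2, 2), -1, dtype=np.int64)
    for (state, inp, out), dest in t.transitions.items():
        if state in idx:
            nxt[idx[state], inp, out] = idx[dest]

    u = rng.random(inputs.size)
    out = np.empty(inputs.size, dtype=np.int8)
    s = int(rng.integers(len(rec)))
    for i, y in enumerate(inputs):
        p = p_one[s, y]
        if np.isnan(p):
            raise ValueError(f"no emission defined for state {rec[s]!r}, input {int(y)}")
        x = 1 if u[i] < p else 0
        out[i] = x
        s = nxt[s, y, x]
        if s < 0:
            raise ValueError("transducer transition undefined during simulation")
    return IOSequencePair(inputs=inputs, outputs=BinarySequence(out))


@dataclass(frozen=True)
class CohortConfig:
    """Study-condition knobs for a synthetic cohort.

    Defaults emulate the observed Reddit cohort: per-user sequence lengths
    spanning the reported range (9,642 to 89,763 comments per user), a
    majority of memoryless users, and minorities with two-/three-state
    hidden patterns or genuine input coupling.  ``jitter`` is the standard
    deviation of per-user probability perturbation around the fixture
    values (applied on the logit scale, clipped to [0.01, 0.99]).
    """

    n_users: int = 50
    length_range: tuple = (9_642, 89_763)
    mix: dict = field(default_factory=lambda: dict(DEFAULT_MIX))
    jitter: float = 0.02
    seed: int = 0
    input_p_one: float = 0.5

    def __post_init__(self) -> None:
        if self.n_users < 1:
            raise ValueError("n_users must be >= 1")
        lo, hi = self.length_range
        if lo < 100 or hi < lo:
            raise ValueError("lengths must be >= 100 with min <= max")
        if abs(sum(self.mix.values()) - 1.0) > 1e-9:
            raise ValueError("mix proportions must sum to 1")
        if unknown := set(self.mix) - set(DEFAULT_MIX):
            raise ValueError(f"unknown archetypes: {sorted(unknown)}")
        if not 0.0 <= self.jitter <= 0.1:
            raise ValueError("jitter must lie in [0, 0.1]")


@dataclass(frozen=True)
class CohortUser:
    user_id: str
    archetype: str
    pair: IOSequencePair
    truth: object  # ground-truth EpsilonMachine or EpsilonTransducer


def _jitter_prob(p: float, sd: float, rng: np.random.Generator) -> float:
    """Perturb a probability by ~N(0, sd) via the logit scale (keeps it
    inside (0,1) without boundary pileup), then clip to [0.01, 0.99]."""
    if sd == 0.0 or p <= 0.01 or p >= 0.99:
        return p
    logit = np.log(p / (1.0 - p))
    # logit-scale s.d. chosen so the induced probability s.d. is ~sd
    logit += rng.normal(0.0, sd / (p * (1.0 - p)))
    return float(np.clip(1.0 / (1.0 + np.exp(-logit)), 0.01, 0.99))


def _jittered_machine(base: EpsilonMachine, sd: float, rng) -> EpsilonMachine:
    transitions = {}
    for state in base.states:
        p1_edge = base.transitions.get((state, 1))
        p0_edge = base.transitions.get((state, 0))
        p1 = _jitter_prob(p1_edge[0], sd, rng) if p1_edge else 0.0
        if p1_edge:
            transitions[(state, 1)] = (p1, p1_edge[1])
        if p0_edge:
            # keep the printed value exact when the jitter left p1 unchanged
            p0 = p0_edge[0] if (not p1_edge or p1 == p1_edge[0]) else 1.0 - p1
            transitions[(state, 0)] = (p0, p0_edge[1])
    return EpsilonMachine(states=base.states, transitions=transitions)


def _jittered_transducer(base: EpsilonTransducer, sd: float, rng) -> EpsilonTransducer:
    emissions = {}
    for key in sorted(base.emissions, key=str):
        p1 = _jitter_prob(float(base.emissions[key][1]), sd, rng)
        emissions[key] = np.array([1.0 - p1, p1])
    return EpsilonTransducer(
        states=base.states, emissions=emissions, transitions=dict(base.transitions)
    )


def _jittered_balanced_transducer(sd: float, rng) -> EpsilonTransducer:
    """Per-user perturbation of the balanced fixture that preserves the
    marginal balance: the (low, high) trolling probabilities are jittered
    but both states keep the same swapped pair, so the input-marginalized
    output process stays memoryless."""
    base = fixture_transducer_balanced()
    low = _jitter_prob(float(base.emissions[("non-troll", 0)][1]), sd, rng)
    high = _jitter_prob(float(base.emissions[("non-troll", 1)][1]), sd, rng)
    emissions = {
        ("non-troll", 0): np.array([1.0 - low, low]),
        ("non-troll", 1): np.array([1.0 - high, high]),
        ("troll", 0): np.array([1.0 - high, high]),
        ("troll", 1): np.array([1.0 - low, low]),
    }
    return EpsilonTransducer(
        states=base.states, emissions=emissions, transitions=dict(base.transitions)
    )


def generate_cohort(cfg: CohortConfig) -> list:
    """Generate a reproducible cohort: per user an archetype drawn from
    the mix, a jittered copy of the matching fixture, and a simulated
    (input, output) pair; the ground-truth generator is returned for
    recovery testing."""
    master = np.random.SeedSequence(cfg.seed)
    top_rng = np.random.default_rng(master.spawn(1)[0])
    names = sorted(cfg.mix)
    probs = [cfg.mix[k] for k in names]
    archetypes = top_rng.choice(names, size=cfg.n_users, p=probs)
    lengths = top_rng.integers(cfg.length_range[0], cfg.length_range[1] + 1, cfg.n_users)

    users = []
    for i, (arche, length) in enumerate(zip(archetypes, lengths)):
        rng = np.random.default_rng(master.spawn(1)[0])
        inputs = simulate_input_process(int(length), cfg.input_p_one, rng)
        if arche == "transducer_coupled":
            truth = _jittered_transducer(fixture_transducer_2state(), cfg.jitter, rng)
            pair = simulate_transducer(truth, inputs, rng)
        elif arche == "balanced_coupled":
            truth = _jittered_balanced_transducer(cfg.jitter, rng)
            pair = simulate_transducer(truth, inputs, rng)
        else:
            base = {
                "coin": fixture_machine_coin(),
                "two_state": fixture_machine_2state(),
                "three_state": fixture_machine_3state(),
            }[arche]
            truth = _jittered_machine(base, cfg.jitter, rng)
            outputs = simulate_machine(truth, int(length), rng)
            pair = IOSequencePair(inputs=inputs, outputs=outputs)
        users.append(
            CohortUser(user_id=f"u{i:04d}", archetype=str(arche), pair=pair, truth=truth)
        )
    return users
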