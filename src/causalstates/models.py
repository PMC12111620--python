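"""Domain types for binary behavior sequences and their hidden-state models.

A user's behavior stream is a binary sequence (1 = trolling comment,
0 = not).  The self-driven model of such a stream is a unifilar,
edge-emitting hidden Markov model (an epsilon-machine): each state carries
a next-symbol distribution, and state + emitted symbol determine the next
state.  The social-induced model is an epsilon-transducer whose emission
distribution additionally conditions on the aligned parent-comment label.

This module holds the containers plus the machinery every later stage
shares: invariant validation, stationary analysis, state filtering along a
sequence, and predictive log-loss scoring.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "BinarySequence",
    "IOSequencePair",
    "EpsilonMachine",
    "EpsilonTransducer",
    "CSSRConfig",
    "FilterResult",
    "LogLossResult",
    "validate_machine",
    "validate_transducer",
    "stationary_distribution",
    "filter_states",
    "sequence_log_loss",
    "state_after_context",
]

_ROW_TOL = 1e-9


def _as_binary_array(values: Iterable[int], what: str) -> np.ndarray:
    arr = np.asarray(list(values) if not isinstance(values, np.ndarray) else values)
    if arr.ndim != 1 or arr.size < 1:
        raise ValueError(f"{what} must be a non-empty 1-d sequence")
    if not np.isin(arr, (0, 1)).all():
        bad = np.flatnonzero(~np.isin(arr, (0, 1)))[0]
        raise ValueError(f"{what} contains a symbol outside {{0,1}} at position {bad}")
    return arr.astype(np.int8)


@dataclass(frozen=True)
class BinarySequence:
    """An ordered stream of binary behavior labels for one user."""

    symbols: np.ndarray
    user_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "symbols", _as_binary_array(self.symbols, "symbols"))

    def __len__(self) -> int:
        return int(self.symbols.size)

    def __iter__(self):
        return iter(self.symbols)

    def __getitem__(self, idx):
        return self.symbols[idx]


@dataclass(frozen=True)
class IOSequencePair:
    """Aligned (input, output) series: inputs[t] is the parent label known
    before outputs[t] is emitted."""

    inputs: np.ndarray
    outputs: BinarySequence

    def __post_init__(self) -> None:
        object.__setattr__(self, "inputs", _as_binary_array(self.inputs, "inputs"))
        if not isinstance(self.outputs, BinarySequence):
            object.__setattr__(self, "outputs", BinarySequence(self.outputs))
        if len(self.inputs) != len(self.outputs):
            raise ValueError(
                f"inputs (len {len(self.inputs)}) and outputs (len {len(self.outputs)}) "
                "must have equal length"
            )

    def __len__(self) -> int:
        return int(self.inputs.size)


@dataclass(frozen=True)
class CSSRConfig:
    """Knobs of causal-state splitting reconstruction.

    alpha
        significance level of the split test: two history classes are
        distinguished when their next-symbol distributions differ with
        p < alpha.
    lmax
        maximum history (sliding-window) length.
    min_count
        minimum observations before a history extension is tested;
        untestable extensions inherit their parent state.
    smoothing_floor
        probability floor applied when scoring held-out data, so unseen
        events incur a finite penalty.
    """

    alpha: float = 0.001
    lmax: int = 1
    min_count: int = 5
    smoothing_floor: float = 1e-6

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie strictly between 0 and 1")
        if self.lmax < 1:
            raise ValueError("lmax must be >= 1")
        if self.min_count < 1:
            raise ValueError("min_count must be >= 1")
        if not 0.0 < self.smoothing_floor < 1.0:
            raise ValueError("smoothing_floor must lie in (0, 1)")


@dataclass
class EpsilonMachine:
    """Unifilar edge-emitting hidden Markov model over the alphabet {0, 1}.

    ``transitions[(state, symbol)] = (probability, next_state)``; at most
    one entry per (state, symbol), and each state's outgoing probabilities
    sum to one.  ``recurrent`` flags the states of the terminal strongly
    connected component.  ``history_map`` (optional) records which history
    suffixes an estimation run grouped into each state.
    """

    states: tuple
    transitions: dict
    recurrent: dict = field(default_factory=dict)
    history_map: dict | None = None

    def __post_init__(self) -> None:
        self.states = tuple(self.states)
        if not self.recurrent:
            self.recurrent = {s: True for s in self.states}

    @property
    def recurrent_states(self) -> tuple:
        return tuple(s for s in self.states if self.recurrent.get(s, False))

    @property
    def n_states(self) -> int:
        return len(self.recurrent_states)

    def next_symbol_dist(self, state) -> np.ndarray:
        """[P(0 | state), P(1 | state)], zero where no edge exists."""
        dist = np.zeros(2)
        for sym in (0, 1):
            if (state, sym) in self.transitions:
                dist[sym] = self.transitions[(state, sym)][0]
        return dist

    def edge(self, state, symbol):
        return self.transitions.get((state, symbol))


@dataclass
class EpsilonTransducer:
    """Input-conditional hidden-state model.

    ``emissions[(state, input)]`` is the output distribution as a length-2
    array; ``transitions[(state, input, output)]`` the unique next state.
    A missing emission entry marks a (state, input) cell never observed
    during estimation.
    """

    states: tuple
    emissions: dict
    transitions: dict
    recurrent: dict = field(default_factory=dict)
    history_map: dict | None = None

    def __post_init__(self) -> None:
        self.states = tuple(self.states)
        self.emissions = {
            key: np.asarray(val, dtype=float) for key, val in self.emissions.items()
        }
        if not self.recurrent:
            self.recurrent = {s: True for s in self.states}

    @property
    def recurrent_states(self) -> tuple:
        return tuple(s for s in self.states if self.recurrent.get(s, False))

    @property
    def n_states(self) -> int:
        return len(self.recurrent_states)


def validate_machine(m: EpsilonMachine) -> list:
    """Return human-readable invariant violations (empty list = valid)."""
    violations: list[str] = []
    seen_keys = set()
    for key, value in m.transitions.items():
        state, symbol = key
        prob, dest = value
        if state not in m.states:
            violations.append(f"transition from unknown state {state!r}")
        if dest not in m.states:
            violations.append(f"transition ({state!r}, {symbol}) points to unknown state {dest!r}")
        if symbol not in (0, 1):
            violations.append(f"state {state!r}: symbol {symbol!r} outside alphabet")
        if not 0.0 <= prob <= 1.0:
            violations.append(f"state {state!r}, symbol {symbol}: probability {prob} outside [0,1]")
        if key in seen_keys:
            violations.append(f"unifilarity: duplicate entry for state {state!r}, symbol {symbol}")
        seen_keys.add(key)

    for state in m.states:
        row = sum(
            m.transitions[(state, sym)][0] for sym in (0, 1) if (state, sym) in m.transitions
        )
        has_edges = any((state, sym) in m.transitions for sym in (0, 1))
        if has_edges and abs(row - 1.0) > _ROW_TOL:
            violations.append(f"state {state!r}: row sum {row:.12g} != 1")
        if not has_edges:
            violations.append(f"state {state!r}: no outgoing edges")

    rec = [s for s in m.states if m.recurrent.get(s, False)]
    if len(rec) > 1:
        g = nx.DiGraph()
        g.add_nodes_from(rec)
        for (state, _sym), (prob, dest) in m.transitions.items():
            if prob > 0 and state in g and dest in g:
                g.add_edge(state, dest)
        if not nx.is_strongly_connected(g):
            comps = sorted(
                tuple(sorted(map(str, c))) for c in nx.strongly_connected_components(g)
            )
            violations.append(f"recurrent part not strongly connected: components {comps}")
    return violations


def validate_transducer(t: EpsilonTransducer) -> list:
    """Invariant violations for an epsilon-transducer (empty list = valid)."""
    violations: list[str] = []
    for (state, inp), dist in t.emissions.items():
        if state not in t.states:
            violations.append(f"emission from unknown state {state!r}")
        if inp not in (0, 1):
            violations.append(f"state {state!r}: input symbol {inp!r} outside alphabet")
        if dist.shape != (2,) or (dist < -_ROW_TOL).any():
            violations.append(f"state {state!r}, input {inp}: malformed distribution")
        elif abs(float(dist.sum()) - 1.0) > _ROW_TOL:
            violations.append(
                f"state {state!r}, input {inp}: emission sum {float(dist.sum()):.12g} != 1"
            )
    seen = set()
    for key, dest in t.transitions.items():
        state, inp, out = key
        if dest not in t.states:
            violations.append(f"transition {key!r} points to unknown state {dest!r}")
        if key in seen:
            violations.append(f"unifilarity: duplicate transition for {key!r}")
        seen.add(key)
        if (state, inp) not in t.emissions:
            violations.append(f"transition {key!r} has no matching emission entry")
    return violations


def stationary_distribution(m: EpsilonMachine) -> dict:
    """Stationary law over states: the fixed point pi P = pi of the
    state-to-state chain, with transient states carrying probability 0.

    Raises if the recurrent part is reducible, naming the disconnected
    components.
    """
    rec = list(m.recurrent_states)
    if not rec:
        raise ValueError("machine has no recurrent states")
    if len(rec) == 1:
        out = {s: 0.0 for s in m.states}
        out[rec[0]] = 1.0
        return out

    g = nx.DiGraph()
    g.add_nodes_from(rec)
    for (state, _sym), (prob, dest) in m.transitions.items():
        if state in g and prob > 0:
            g.add_edge(state, dest)
    if not nx.is_strongly_connected(g):
        comps = [sorted(map(str, c)) for c in nx.strongly_connected_components(g)]
        raise ValueError(f"recurrent part is reducible: components {comps}")

    idx = {s: i for i, s in enumerate(rec)}
    P = np.zeros((len(rec), len(rec)))
    for (state, _sym), (prob, dest) in m.transitions.items():
        if state in idx:
            P[idx[state], idx[dest]] += prob

    # pi (P - I) = 0 with sum(pi) = 1, as a direct linear solve
    A = P.T - np.eye(len(rec))
    A[-1, :] = 1.0
    b = np.zeros(len(rec))
    b[-1] = 1.0
    pi = np.linalg.solve(A, b)
    pi = np.clip(pi, 0.0, None)
    pi /= pi.sum()
    out = {s: 0.0 for s in m.states}
    for s, i in idx.items():
        out[s] = float(pi[i])
    return out


@dataclass(frozen=True)
class FilterResult:
    """Per-position state labels from filtering a sequence through a machine.

    ``states[t]`` is the unique state occupied before emitting symbol t, or
    None where the state is still ambiguous or the position was flagged
    desynchronized.  ``sync_index`` is the first position with a unique
    state (None if the sequence never synchronizes).
    """

    states: list
    sync_index: int | None
    desync_positions: list


def filter_states(m: EpsilonMachine, seq: BinarySequence | Sequence[int]) -> FilterResult:
    """Walk the sequence keeping the set of states consistent with the
    observed suffix.  An observation with no outgoing edge from any
    candidate state flags the position desynchronized and restarts
    filtering from the full recurrent state set."""
    symbols = seq.symbols if isinstance(seq, BinarySequence) else _as_binary_array(seq, "seq")
    rec = m.recurrent_states
    if not rec:
        raise ValueError("machine has no recurrent states to filter with")
    full = frozenset(rec)
    cand = full
    labels: list = [None] * len(symbols)
    desync: list[int] = []
    sync_index: int | None = None

    for t, x in enumerate(symbols):
        if len(cand) == 1:
            (state,) = cand
            labels[t] = state
            if sync_index is None:
                sync_index = t
        successors = {
            m.transitions[(s, x)][1] for s in cand if (s, int(x)) in m.transitions
        }
        if not successors:
            labels[t] = None
            desync.append(t)
            cand = full
        else:
            cand = frozenset(successors)
    return FilterResult(states=labels, sync_index=sync_index, desync_positions=desync)


@dataclass(frozen=True)
class LogLossResult:
    bits_per_symbol: float
    n_scored: int


def sequence_log_loss(
    m: EpsilonMachine,
    seq: BinarySequence | Sequence[int],
    floor: float = 1e-6,
) -> LogLossResult:
    """Mean -log2 P(next symbol | filtered state) over positions where the
    state is unambiguous.  Probabilities below ``floor`` are floored so
    unseen events cost a finite penalty."""
    symbols = seq.symbols if isinstance(seq, BinarySequence) else _as_binary_array(seq, "seq")
    result = filter_states(m, symbols)
    total = 0.0
    n = 0
    for t, state in enumerate(result.states):
        if state is None:
            continue
        edge = m.transitions.get((state, int(symbols[t])))
        if edge is None:
            continue  # flagged desynchronized by the filter
        total += -math.log2(max(edge[0], floor))
        n += 1
    if n == 0:
        raise ValueError(
            "sequence never synchronizes with the machine; "
            "use more data or a smaller model"
        )
    return LogLossResult(bits_per_symbol=total / n, n_scored=n)


def state_after_context(
    m: EpsilonMachine,
    seq: BinarySequence | Sequence[int],
    context: Sequence[int],
):
    """The state the machine occupies immediately after the given symbol
    context, read off by filtering the sequence: the modal filtered state
    at positions preceded by ``context``.  Returns None if the context
    never occurs at a synchronized position."""
    symbols = seq.symbols if isinstance(seq, BinarySequence) else _as_binary_array(seq, "seq")
    ctx = np.asarray(list(context), dtype=np.int8)
    k = ctx.size
    labels = filter_states(m, symbols).states
    votes: dict = {}
    for t in range(k, len(symbols)):
        if labels[t] is not None and np.array_equal(symbols[t - k : t], ctx):
            votes[labels[t]] = votes.get(labels[t], 0) + 1
    if not votes:
        return None
    return max(sorted(votes, key=str), key=lambda s: votes[s])
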