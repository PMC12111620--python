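"""Information-theoretic summaries of sequences and their hidden-state models.

Three complementary quantities, all in bits:

* predictive complexity ``C`` — entropy of the stationary distribution
  over causal states: the stored information an optimal predictor needs;
* predictable information ``E`` — mutual information between past and
  future, estimated from block entropies as ``E = 2 H(L) - H(2L)``;
* remaining uncertainty ``h`` — per-symbol conditional entropy of the
  future given the past, ``h = (H(2L) - H(L)) / L``, the irreducible
  unpredictability.

``L`` is taken to be the model's maximum history length.  Block entropies
are plug-in (maximum-likelihood) estimates over overlapping windows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .models import (
    BinarySequence,
    EpsilonMachine,
    EpsilonTransducer,
    IOSequencePair,
    stationary_distribution,
)

__all__ = [
    "InfoSummary",
    "statistical_complexity",
    "machine_entropy_rate",
    "block_entropy",
    "empirical_E_h",
    "empirical_E_h_joint",
    "summarize",
]

_NEG_TOL = 1e-6


@dataclass(frozen=True)
class InfoSummary:
    """Per-model scorecard: number of recurrent states, maximum history
    length, predictive complexity C, predictable information E, and
    remaining uncertainty h (bits per symbol)."""

    n_states: int
    lmax: int
    C: float
    E: float
    h: float

    def __post_init__(self) -> None:
        if self.C < 0 or self.E < 0 or not 0.0 <= self.h <= 1.0 + _NEG_TOL:
            raise ValueError("information measures outside their valid ranges")


def _entropy(probs: np.ndarray) -> float:
    probs = np.asarray(probs, dtype=float)
    probs = probs[probs > 0]
    return float(-(probs * np.log2(probs)).sum())


def statistical_complexity(m: EpsilonMachine) -> float:
    """Shannon entropy (bits) of the stationary distribution over
    recurrent causal states."""
    pi = stationary_distribution(m)
    return _entropy(np.array([pi[s] for s in m.recurrent_states]))


def machine_entropy_rate(m: EpsilonMachine) -> float:
    """Entropy rate (bits/symbol): stationary-weighted next-symbol
    uncertainty, sum_s pi(s) H(X | s)."""
    pi = stationary_distribution(m)
    rate = 0.0
    for s in m.recurrent_states:
        rate += pi[s] * _entropy(m.next_symbol_dist(s))
    return float(rate)


def block_entropy(seq: BinarySequence, L: int) -> float:
    """Plug-in Shannon entropy (bits) of the empirical distribution of
    overlapping length-L blocks."""
    symbols = seq.symbols if isinstance(seq, BinarySequence) else np.asarray(seq, dtype=np.int8)
    n = symbols.size
    if L < 1:
        raise ValueError("L must be >= 1")
    if L > n:
        raise ValueError(f"block length {L} exceeds sequence length {n}")
    codes = np.zeros(n, dtype=np.int64)
    for k in range(1, L + 1):
        codes = (codes[: n - k + 1] << 1) | symbols[k - 1 :]
    counts = np.bincount(codes, minlength=2**L).astype(float)
    return _entropy(counts / counts.sum())


def empirical_E_h(seq: BinarySequence, L: int) -> tuple:
    """Block-entropy estimates of predictable information and entropy
    rate at window length L: E = 2 H(L) - H(2L), h = (H(2L) - H(L)) / L.

    Tiny negative plug-in artifacts are clipped to zero.  Emits a warning
    (without failing) when the sequence is short relative to 4**L.
    """
    symbols = seq.symbols if isinstance(seq, BinarySequence) else np.asarray(seq, dtype=np.int8)
    n = symbols.size
    if n < 10 * 4**L:
        warnings.warn(
            f"sequence length {n} is small for window {L} "
            f"(recommend >= {10 * 4 ** L}); estimates may be biased",
            stacklevel=2,
        )
    h_L = block_entropy(symbols, L)
    h_2L = block_entropy(symbols, 2 * L)
    E = 2.0 * h_L - h_2L
    h = (h_2L - h_L) / L
    return max(E, 0.0), min(max(h, 0.0), 1.0)


def _stream_block_entropy(stream: np.ndarray, L: int, bits_per_symbol: int) -> float:
    """Plug-in block entropy of an integer-coded stream with alphabet
    size 2**bits_per_symbol."""
    n = stream.size
    if L > n:
        raise ValueError(f"block length {L} exceeds stream length {n}")
    codes = np.zeros(n, dtype=np.int64)
    for k in range(1, L + 1):
        codes = (codes[: n - k + 1] << bits_per_symbol) | stream[k - 1 :]
    counts = np.bincount(codes, minlength=2 ** (bits_per_symbol * L)).astype(float)
    return _entropy(counts / counts.sum())


def empirical_E_h_joint(pair: IOSequencePair, L: int) -> tuple:
    """Block-entropy E and h for the social-induced view of a pair.

    E is the predictable information of the joint (input, output) process,
    ``2 H4(L) - H4(2L)`` over 4-letter joint blocks.  h is the remaining
    *output* uncertainty given the joint past and the current input:
    the joint block entropy rate minus the input block entropy rate
    (exactly ``H(X_t | joint past, Y_t)`` when the input stream carries no
    extra information about the output), clipped to [0, 1].
    """
    stream = (2 * pair.inputs.astype(np.int64)) + pair.outputs.symbols
    h4_L = _stream_block_entropy(stream, L, 2)
    h4_2L = _stream_block_entropy(stream, 2 * L, 2)
    inp = pair.inputs.astype(np.int64)
    hin_L = _stream_block_entropy(inp, L, 1)
    hin_2L = _stream_block_entropy(inp, 2 * L, 1)
    E = max(2.0 * h4_L - h4_2L, 0.0)
    h_joint = (h4_2L - h4_L) / L
    h_in = (hin_2L - hin_L) / L
    return E, min(max(h_joint - h_in, 0.0), 1.0)


def summarize(model, data, lmax: int) -> InfoSummary:
    """Assemble the InfoSummary of a fitted model and the sequence it was
    fit to.

    For a machine, C comes from the stationary law of the model and E/h
    from output block entropies.  For a transducer, whose stationary law
    depends on the unmodelled input process, C is the entropy of the
    empirical post-synchronization state-visit distribution, and E/h come
    from joint (input, output) block entropies so the information carried
    by the social input is counted.  Window L = lmax throughout.
    """
    if isinstance(model, EpsilonMachine):
        seq = data.outputs if isinstance(data, IOSequencePair) else data
        C = statistical_complexity(model)
        E, h = empirical_E_h(seq, lmax)
    elif isinstance(model, EpsilonTransducer):
        if not isinstance(data, IOSequencePair):
            raise TypeError("transducer summaries need an IOSequencePair")
        C = _empirical_state_complexity(model, data)
        E, h = empirical_E_h_joint(data, lmax)
    else:
        raise TypeError(f"cannot summarize {type(model).__name__}")
    n_states = model.n_states
    if n_states == 1:
        C = 0.0
    return InfoSummary(n_states=n_states, lmax=lmax, C=C, E=E, h=h)


def _empirical_state_complexity(t: EpsilonTransducer, pair: IOSequencePair) -> float:
    from .transducer import filter_transducer_states

    labels, _sync, _desync = filter_transducer_states(t, pair)
    visits: dict = {}
    for s in labels:
        if s is not None:
            visits[s] = visits.get(s, 0) + 1
    total = sum(visits.values())
    if total == 0:
        return 0.0
    return _entropy(np.array([c / total for c in visits.values()]))
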