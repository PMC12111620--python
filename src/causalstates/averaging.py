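"""Population-average machines and transducers via optimal state alignment.

Hidden states are unlabeled and permutation-invariant, so models cannot be
averaged element-wise as fitted.  One model is chosen as the reference;
every other model's states are matched to the reference's by minimizing
the total Euclidean distance between next-symbol (or input-conditional
emission) probability vectors with the Hungarian algorithm; the aligned
transition/emission matrices are then averaged element-wise.

Averaged destination structure is reported with a per-edge agreement
fraction: when the aligned models do not all route an edge to the same
state, the average is a structural summary rather than a generative
model.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .models import EpsilonMachine, EpsilonTransducer

__all__ = [
    "AlignmentResult",
    "AveragedModel",
    "state_feature_vector",
    "align_states",
    "average_models",
]

_LEX_ENUM_LIMIT = 7  # enumerate permutations for lexicographic tie-breaks


@dataclass(frozen=True)
class AlignmentResult:
    """``permutation[i] = j`` maps the model's i-th state onto the
    reference's j-th state; ``cost`` is the total feature distance."""

    permutation: tuple
    cost: float

    def __post_init__(self) -> None:
        if sorted(self.permutation) != list(range(len(self.permutation))):
            raise ValueError("permutation must be a bijection")
        if self.cost < -1e-12:
            raise ValueError("cost must be nonnegative")


def state_feature_vector(model, state) -> np.ndarray:
    """The probability vector used to compare states across models.

    Machines: [P(0|s), P(1|s)].  Transducers:
    [P(0|s,in=0), P(1|s,in=0), P(0|s,in=1), P(1|s,in=1)]; an unobserved
    (state, input) cell is filled with the uninformative 0.5/0.5 row (and
    flagged with a warning).
    """
    if isinstance(model, EpsilonMachine):
        return model.next_symbol_dist(state)
    if isinstance(model, EpsilonTransducer):
        parts = []
        for inp in (0, 1):
            if (state, inp) in model.emissions:
                parts.append(model.emissions[(state, inp)])
            else:
                warnings.warn(
                    f"unobserved emission cell ({state!r}, input {inp}); using 0.5/0.5",
                    stacklevel=2,
                )
                parts.append(np.array([0.5, 0.5]))
        return np.concatenate(parts)
    raise TypeError(f"no feature vector for {type(model).__name__}")


def _cost_matrix(model, reference) -> np.ndarray:
    m_states = model.recurrent_states
    r_states = reference.recurrent_states
    cost = np.zeros((len(m_states), len(r_states)))
    for i, s in enumerate(m_states):
        f_i = state_feature_vector(model, s)
        for j, r in enumerate(r_states):
            cost[i, j] = float(np.linalg.norm(f_i - state_feature_vector(reference, r)))
    return cost


def align_states(model, reference) -> AlignmentResult:
    """Optimal assignment of the model's states onto the reference's,
    minimizing total Euclidean feature distance (Hungarian algorithm).
    Ties among optimal permutations break to the lexicographically
    smallest (resolved by enumeration for small machines)."""
    k_m = len(model.recurrent_states)
    k_r = len(reference.recurrent_states)
    if k_m != k_r:
        raise ValueError(f"state counts differ: {k_m} vs {k_r}")
    cost = _cost_matrix(model, reference)
    rows, cols = linear_sum_assignment(cost)
    best_cost = float(cost[rows, cols].sum())
    perm = tuple(int(cols[np.flatnonzero(rows == i)[0]]) for i in range(k_m))

    if k_m <= _LEX_ENUM_LIMIT:
        for candidate in itertools.permutations(range(k_m)):
            c = float(sum(cost[i, candidate[i]] for i in range(k_m)))
            if c <= best_cost + 1e-12:
                perm = candidate
                break
    return AlignmentResult(permutation=tuple(perm), cost=best_cost)


@dataclass(frozen=True)
class AveragedModel:
    """An element-wise average of aligned models.

    ``destination_agreement`` maps each averaged edge to the fraction of
    input models routing it to the modal destination;
    ``is_structural_summary`` is True when any edge's agreement falls
    below 1, i.e. the average summarizes structure but is not the
    machine of any single topology.
    """

    model: object
    destination_agreement: dict
    is_structural_summary: bool


def average_models(models: list, reference_index: int = 0) -> AveragedModel:
    """Align all models to ``models[reference_index]`` and average the
    symbol-labeled transition (and emission) probabilities element-wise.
    State names come from the reference."""
    if not models:
        raise ValueError("need at least one model to average")
    reference = models[reference_index]
    if isinstance(reference, EpsilonMachine):
        return _average_machines(models, reference)
    if isinstance(reference, EpsilonTransducer):
        return _average_transducers(models, reference)
    raise TypeError(f"cannot average {type(reference).__name__}")


def _state_maps(models, reference):
    """Per model: dict reference-state -> that model's matched state."""
    ref_states = reference.recurrent_states
    maps = []
    for m in models:
        perm = align_states(m, reference).permutation
        m_states = m.recurrent_states
        maps.append({ref_states[perm[i]]: m_states[i] for i in range(len(m_states))})
    return maps


def _modal(values: list):
    tally: dict = {}
    for v in values:
        tally[v] = tally.get(v, 0) + 1
    top = max(tally.values())
    winners = sorted([v for v, c in tally.items() if c == top], key=str)
    return winners[0], top / len(values)


def _average_machines(models, reference) -> AveragedModel:
    ref_states = reference.recurrent_states
    maps = _state_maps(models, reference)
    inverse = [{v: k for k, v in mp.items()} for mp in maps]

    transitions: dict = {}
    agreement: dict = {}
    for rs in ref_states:
        probs = np.zeros(2)
        dests = {0: [], 1: []}
        for m, mp, inv in zip(models, maps, inverse):
            probs += m.next_symbol_dist(mp[rs])
            for sym in (0, 1):
                edge = m.edge(mp[rs], sym)
                if edge is not None:
                    dests[sym].append(inv[edge[1]])
        probs /= len(models)
        if abs(probs.sum() - 1.0) > 1e-9:
            probs = probs / probs.sum()
        for sym in (0, 1):
            if probs[sym] > 0 and dests[sym]:
                dest, agree = _modal(dests[sym])
                transitions[(rs, sym)] = (float(probs[sym]), dest)
                agreement[(rs, sym)] = agree
    avg = EpsilonMachine(states=ref_states, transitions=transitions)
    structural = any(a < 1.0 for a in agreement.values())
    return AveragedModel(model=avg, destination_agreement=agreement, is_structural_summary=structural)


def _average_transducers(models, reference) -> AveragedModel:
    ref_states = reference.recurrent_states
    maps = _state_maps(models, reference)
    inverse = [{v: k for k, v in mp.items()} for mp in maps]

    emissions: dict = {}
    transitions: dict = {}
    agreement: dict = {}
    for rs in ref_states:
        for inp in (0, 1):
            rows = []
            for m, mp in zip(models, maps):
                if (mp[rs], inp) in m.emissions:
                    rows.append(m.emissions[(mp[rs], inp)])
            if not rows:
                continue
            dist = np.mean(rows, axis=0)
            if abs(float(dist.sum()) - 1.0) > 1e-9:
                dist = dist / dist.sum()
            emissions[(rs, inp)] = dist
            for out in (0, 1):
                dests = [
                    inv[m.transitions[(mp[rs], inp, out)]]
                    for m, mp, inv in zip(models, maps, inverse)
                    if (mp[rs], inp, out) in m.transitions
                ]
                if dist[out] > 0 and dests:
                    dest, agree = _modal(dests)
                    transitions[(rs, inp, out)] = dest
                    agreement[(rs, inp, out)] = agree
    avg = EpsilonTransducer(states=ref_states, emissions=emissions, transitions=transitions)
    structural = any(a < 1.0 for a in agreement.values())
    return AveragedModel(model=avg, destination_agreement=agreement, is_structural_summary=structural)
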