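"""Epsilon-transducer reconstruction from aligned input-output pairs.

The social-induced model predicts the next output (the user's own label)
from the joint past of (parent label, own label) pairs together with the
*current* parent label.  Reconstruction generalizes CSSR to joint
histories: two joint pasts belong to the same causal state only when
their conditional next-output distributions agree, at significance level
``alpha`` (Bonferroni-corrected across the two input values), for every
input value with sufficient support.

Joint histories are tuples of pair codes ``2*input + output`` with the
most recent pair last; extension prepends the older pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math

import networkx as nx
import numpy as np

from .models import (
    BinarySequence,
    CSSRConfig,
    EpsilonTransducer,
    IOSequencePair,
    LogLossResult,
    validate_transducer,
)
from .cssr import _chi2_pvalue, DEFAULT_LMAX_GRID

__all__ = [
    "JointHistoryCounts",
    "count_joint_histories",
    "estimate_transducer",
    "transducer_log_loss",
    "select_transducer_lmax",
]

_MAX_REFINE_PASSES = 200


class JointHistoryCounts:
    """Overlapping counts of joint (input, output) words up to length
    ``lmax + 1``, encoded base-4 with the oldest pair first.

    ``next_counts(h)[y, x]`` is the number of occurrences of joint history
    ``h`` followed by input ``y`` and output ``x``; marginalizing over
    ``x`` recovers the (history, next-input) count.
    """

    def __init__(self, lmax: int, tables: dict, n: int):
        self.lmax = lmax
        self.n = n
        self._tables = tables

    @staticmethod
    def encode(word: tuple) -> int:
        code = 0
        for pair in word:
            code = (code << 2) | int(pair)
        return code

    def count(self, word: tuple) -> int:
        return int(self._tables[len(word)][self.encode(word)])

    def next_counts(self, history: tuple) -> np.ndarray:
        if len(history) > self.lmax:
            raise ValueError("history longer than lmax")
        base = self.encode(history) << 2
        table = self._tables[len(history) + 1]
        return np.array(
            [[table[base + 0], table[base + 1]], [table[base + 2], table[base + 3]]],
            dtype=float,
        )


def count_joint_histories(pair: IOSequencePair, lmax: int) -> JointHistoryCounts:
    """Exact overlapping-window counts over the paired stream."""
    if lmax < 1:
        raise ValueError("lmax must be >= 1")
    n = len(pair)
    if n < lmax + 2:
        raise ValueError(f"pair of length {n} too short for lmax={lmax}")
    stream = (2 * pair.inputs.astype(np.int64)) + pair.outputs.symbols
    tables: dict = {0: np.array([n], dtype=np.int64)}
    codes = np.zeros(n, dtype=np.int64)
    for k in range(1, lmax + 2):
        codes = (codes[: n - k + 1] << 2) | stream[k - 1 :]
        tables[k] = np.bincount(codes, minlength=4**k)
    return JointHistoryCounts(lmax=lmax, tables=tables, n=n)


@dataclass
class _JointState:
    histories: set = field(default_factory=set)
    counts: np.ndarray = field(default_factory=lambda: np.zeros((2, 2)))

    def add(self, history, next_counts):
        self.histories.add(history)
        self.counts = self.counts + next_counts

    def remove(self, history, next_counts):
        self.histories.discard(history)
        self.counts = self.counts - next_counts


def _joint_state_pvalue(state, child, child_counts, min_count):
    """Smallest per-input chi-square p-value of the child against the
    state's pooled counts (child's own contribution excluded); inputs
    with support below ``min_count`` on the child side, or unseen on the
    state side, are not testable.  Returns (min p, number tested)."""
    pooled = state.counts.copy()
    if child in state.histories:
        pooled = pooled - child_counts
    min_p, tested = 1.0, 0
    for y in (0, 1):
        if child_counts[y].sum() < min_count or pooled[y].sum() <= 0:
            continue
        p = _chi2_pvalue(child_counts[y], pooled[y])
        tested += 1
        min_p = min(min_p, p)
    return min_p, tested


def _desired_joint_state(child, child_counts, parent_state, states, cfg):
    if child_counts.sum() < cfg.min_count:
        return parent_state
    threshold = cfg.alpha / 2  # Bonferroni across the two input values
    p_parent, tested = _joint_state_pvalue(parent_state, child, child_counts, cfg.min_count)
    if tested == 0 or p_parent >= threshold:
        return parent_state
    best, best_p = None, -1.0
    for state in states:
        if state is parent_state or not state.histories:
            continue
        p, tested = _joint_state_pvalue(state, child, child_counts, cfg.min_count)
        if tested == 0:
            continue
        if p >= threshold and p > best_p:
            best, best_p = state, p
    return best


def _joint_phase1(counts: JointHistoryCounts, cfg: CSSRConfig) -> list:
    root = _JointState()
    root.add((), counts.next_counts(()))
    states = [root]
    assignment: dict = {(): root}

    for level in range(cfg.lmax):
        parents = sorted(h for h in assignment if len(h) == level)
        children = []
        for h in parents:
            for a in range(4):
                child = (a,) + h
                if counts.count(child) > 0:
                    children.append(child)
        children.sort()
        for _sweep in range(_MAX_REFINE_PASSES):
            changed = False
            for child in children:
                child_counts = counts.next_counts(child)
                parent_state = assignment[child[1:]]
                target = _desired_joint_state(child, child_counts, parent_state, states, cfg)
                current = assignment.get(child)
                if current is None or target is not current:
                    if current is not None:
                        current.remove(child, child_counts)
                    if target is None:
                        target = _JointState()
                        states.append(target)
                    target.add(child, child_counts)
                    assignment[child] = target
                    changed = True
            if not changed:
                break
        states = [s for s in states if s.histories]
    return states


def _joint_successor(history, pair_code, counts, assignment, lmax):
    if counts.count(history + (pair_code,)) == 0:
        return None
    suffix = (history + (pair_code,))[-lmax:]
    while suffix not in assignment:
        suffix = suffix[1:]
    return assignment[suffix]


def _joint_leaves(part: set) -> list:
    members = sorted(part, key=lambda h: (len(h), h))
    return [
        h
        for h in members
        if not any(g is not h and len(g) > len(h) and g[len(g) - len(h) :] == h for g in members)
    ]


def _joint_phase2(states, counts: JointHistoryCounts, cfg: CSSRConfig) -> EpsilonTransducer:
    partition = [set(s.histories) for s in states if s.histories]

    while True:
        assignment = {h: i for i, part in enumerate(partition) for h in part}
        split_done = False
        for i, part in enumerate(partition):
            for a in range(4):
                groups: dict = {}
                unobserved = []
                for h in sorted(part):
                    succ = _joint_successor(h, a, counts, assignment, cfg.lmax)
                    if succ is None:
                        unobserved.append(h)
                    else:
                        groups.setdefault(succ, []).append(h)
                if len(groups) > 1:
                    def mass(item):
                        return sum(counts.count(h) for h in item[1])

                    ordered = sorted(groups.items(), key=lambda it: (-mass(it), it[0]))
                    partition[i] = set(ordered[0][1]) | set(unobserved)
                    for _, movers in ordered[1:]:
                        partition.append(set(movers))
                    split_done = True
                    break
            if split_done:
                break
        if not split_done:
            break

    def canon(part):
        h = min(part, key=lambda x: (len(x), x))
        return (len(h), h)

    partition.sort(key=canon)
    assignment = {h: i for i, part in enumerate(partition) for h in part}

    pooled, successors = [], []
    for part in partition:
        leaf_counts = np.zeros((2, 2))
        for h in _joint_leaves(part):
            leaf_counts += counts.next_counts(h)
        succ: dict = {}
        for a in range(4):
            for h in sorted(part):
                s = _joint_successor(h, a, counts, assignment, cfg.lmax)
                if s is not None:
                    succ[a] = s
                    break
        pooled.append(leaf_counts)
        successors.append(succ)

    graph = nx.DiGraph()
    graph.add_nodes_from(range(len(partition)))
    for i, (leaf_counts, succ) in enumerate(zip(pooled, successors)):
        for a, dest in succ.items():
            y, x = a >> 1, a & 1
            if leaf_counts[y, x] > 0:
                graph.add_edge(i, dest)

    terminal = [
        comp
        for comp in nx.strongly_connected_components(graph)
        if all(dest in comp for node in comp for dest in graph.successors(node))
    ]
    if not terminal:
        raise ValueError("no recurrent component found")
    terminal.sort(key=lambda comp: (-sum(pooled[i].sum() for i in comp), min(comp)))
    recurrent = sorted(terminal[0])

    names = {i: f"S{rank}" for rank, i in enumerate(recurrent)}
    emissions, transitions = {}, {}
    for i in recurrent:
        for y in (0, 1):
            support = pooled[i][y].sum()
            if support == 0:
                continue  # (state, input) cell never observed
            emissions[(names[i], y)] = pooled[i][y] / support
            for x in (0, 1):
                a = 2 * y + x
                if pooled[i][y, x] > 0 and a in successors[i]:
                    transitions[(names[i], y, x)] = names[successors[i][a]]
    history_map = {h: names[i] for h, i in assignment.items() if i in names}
    t = EpsilonTransducer(
        states=tuple(names[i] for i in recurrent),
        emissions=emissions,
        transitions=transitions,
        history_map=history_map,
    )
    violations = validate_transducer(t)
    if violations:
        raise RuntimeError(f"estimated transducer failed validation: {violations}")
    return t


def estimate_transducer(
    pair: IOSequencePair,
    cfg: CSSRConfig,
    input_shift: int = 0,
) -> EpsilonTransducer:
    """Reconstruct the epsilon-transducer from an aligned pair.

    ``input_shift=0`` (default) conditions the output at step t on the
    input at step t — the parent comment being replied to;
    ``input_shift=1`` conditions on the strictly previous input instead.
    """
    if input_shift not in (0, 1):
        raise ValueError("input_shift must be 0 or 1")
    if input_shift == 1:
        pair = IOSequencePair(
            inputs=pair.inputs[:-1], outputs=BinarySequence(pair.outputs.symbols[1:])
        )
    counts = count_joint_histories(pair, cfg.lmax)
    states = _joint_phase1(counts, cfg)
    return _joint_phase2(states, counts, cfg)


def filter_transducer_states(t: EpsilonTransducer, pair: IOSequencePair):
    """Per-position candidate tracking, analogous to machine filtering:
    labels[t] is the unique state before step t, or None."""
    rec = t.recurrent_states
    full = frozenset(rec)
    cand = full
    labels: list = [None] * len(pair)
    desync: list[int] = []
    sync_index = None
    for i, (y, x) in enumerate(zip(pair.inputs, pair.outputs.symbols)):
        y, x = int(y), int(x)
        if len(cand) == 1:
            (state,) = cand
            labels[i] = state
            if sync_index is None:
                sync_index = i
        successors = {t.transitions[(s, y, x)] for s in cand if (s, y, x) in t.transitions}
        if not successors:
            labels[i] = None
            desync.append(i)
            cand = full
        else:
            cand = frozenset(successors)
    return labels, sync_index, desync


def transducer_log_loss(
    t: EpsilonTransducer, pair: IOSequencePair, floor: float = 1e-6
) -> LogLossResult:
    """Mean -log2 P(output | state, input) over synchronized positions.
    Positions in unobserved (state, input) cells are excluded."""
    labels, _sync, _desync = filter_transducer_states(t, pair)
    total, n = 0.0, 0
    for i, state in enumerate(labels):
        if state is None:
            continue
        key = (state, int(pair.inputs[i]))
        if key not in t.emissions:
            continue
        p = float(t.emissions[key][int(pair.outputs.symbols[i])])
        total += -math.log2(max(p, floor))
        n += 1
    if n == 0:
        raise ValueError("pair never synchronizes with the transducer")
    return LogLossResult(bits_per_symbol=total / n, n_scored=n)


def select_transducer_lmax(
    pair: IOSequencePair,
    candidates=DEFAULT_LMAX_GRID,
    cfg: CSSRConfig | None = None,
    input_shift: int = 0,
    tie_tol: float = 1e-4,
):
    """Train/test choice of the joint history length, mirroring the
    machine-side selection: fit on the first half, score held-out
    per-output log loss, argmin with near-ties (within ``tie_tol`` bits)
    broken toward the smallest candidate."""
    candidates = tuple(sorted(candidates))
    if not candidates:
        raise ValueError("candidate list must be nonempty")
    base = cfg or CSSRConfig()
    half = len(pair) // 2
    train = IOSequencePair(
        inputs=pair.inputs[:half], outputs=BinarySequence(pair.outputs.symbols[:half])
    )
    test = IOSequencePair(
        inputs=pair.inputs[half:], outputs=BinarySequence(pair.outputs.symbols[half:])
    )
    table: dict = {}
    for lmax in candidates:
        try:
            t = estimate_transducer(
                train,
                CSSRConfig(
                    alpha=base.alpha,
                    lmax=lmax,
                    min_count=base.min_count,
                    smoothing_floor=base.smoothing_floor,
                ),
                input_shift=input_shift,
            )
            table[lmax] = transducer_log_loss(t, test, base.smoothing_floor).bits_per_symbol
        except (ValueError, RuntimeError):
            table[lmax] = float("inf")
    lo = min(table.values())
    best = min(L for L in candidates if table[L] <= lo + tie_tol)
    return best, table
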