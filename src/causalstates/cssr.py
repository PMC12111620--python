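"""Causal-state splitting reconstruction (CSSR) for a single binary sequence.

The self-driven model of a behavior stream is its epsilon-machine: the
minimal unifilar hidden Markov model whose states are equivalence classes
of history suffixes with statistically indistinguishable next-symbol
distributions.  Reconstruction runs in two phases:

1. *Splitting.*  Starting from one state holding the empty history, each
   history in each state is extended one symbol further into the past;
   extensions whose empirical next-symbol distribution differs
   significantly (two-sample chi-square, level ``alpha``) from their
   state's pooled distribution are reassigned to the best-matching
   existing state or spawn a new one.
2. *Determinization and transient removal.*  States are refined until,
   for every state and emitted symbol, all member histories lead to the
   same successor state; transition probabilities are pooled maximum
   likelihood estimates; the machine is restricted to the terminal
   strongly connected component.

The maximum history length ``lmax`` is chosen by a train/test split:
candidate machines are fit on the first half of the sequence and scored
by predictive log loss on the second half.

Histories are stored as tuples of past symbols with the *most recent
symbol last*; extending a history prepends the older symbol.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats

from .models import (
    BinarySequence,
    CSSRConfig,
    EpsilonMachine,
    sequence_log_loss,
    validate_machine,
)

__all__ = [
    "HistoryCounts",
    "ProvisionalState",
    "count_histories",
    "next_distribution",
    "split_test",
    "cssr_phase1",
    "cssr_phase2",
    "estimate_machine",
    "select_lmax",
]

DEFAULT_LMAX_GRID = (1, 2, 3, 4, 5, 6)

_MAX_REFINE_PASSES = 200


class HistoryCounts:
    """Overlapping sliding-window counts of all subsequences up to length
    ``lmax + 1``.

    Words are tuples with the oldest symbol first, encoded as big-endian
    binary integers into one count array per length.
    """

    def __init__(self, lmax: int, tables: dict, n: int):
        self.lmax = lmax
        self.n = n
        self._tables = tables  # length -> np.ndarray of size 2**length

    @staticmethod
    def encode(word: tuple) -> int:
        code = 0
        for sym in word:
            code = (code << 1) | int(sym)
        return code

    def count(self, word: tuple) -> int:
        k = len(word)
        if k not in self._tables:
            raise ValueError(f"no counts recorded for words of length {k}")
        return int(self._tables[k][self.encode(word)])

    def next_counts(self, history: tuple) -> np.ndarray:
        """Counts of (history followed by 0, history followed by 1)."""
        if len(history) > self.lmax:
            raise ValueError("history longer than lmax")
        base = self.encode(history) << 1
        table = self._tables[len(history) + 1]
        return np.array([table[base], table[base + 1]], dtype=float)

    def observed_histories(self, length: int) -> list:
        table = self._tables[length]
        return [self.decode(code, length) for code in np.flatnonzero(table)]

    @staticmethod
    def decode(code: int, length: int) -> tuple:
        return tuple((code >> (length - 1 - i)) & 1 for i in range(length))


def count_histories(seq: BinarySequence, lmax: int) -> HistoryCounts:
    """Exact overlapping-window counts for all subsequences up to length
    ``lmax + 1``."""
    symbols = seq.symbols if isinstance(seq, BinarySequence) else np.asarray(seq, dtype=np.int8)
    n = symbols.size
    if lmax < 1:
        raise ValueError("lmax must be >= 1")
    if n < lmax + 2:
        raise ValueError(
            f"sequence of length {n} too short for lmax={lmax}; "
            "use a smaller lmax or more data"
        )
    tables: dict = {0: np.array([n], dtype=np.int64)}
    codes = np.zeros(n, dtype=np.int64)
    for k in range(1, lmax + 2):
        # codes of length-k windows ending at positions k-1 .. n-1
        codes = (codes[: n - k + 1] << 1) | symbols[k - 1 :]
        tables[k] = np.bincount(codes, minlength=2**k)
    return HistoryCounts(lmax=lmax, tables=tables, n=n)


def next_distribution(counts: HistoryCounts, history: tuple):
    """Maximum-likelihood next-symbol distribution after ``history`` with
    its support count; (None, 0) for an unobserved history."""
    nc = counts.next_counts(tuple(history))
    support = int(nc.sum())
    if support == 0:
        return None, 0
    return nc / support, support


def _chi2_pvalue(counts_a: np.ndarray, counts_b: np.ndarray) -> float:
    """Two-sample Pearson chi-square p-value on the 2x2 next-symbol table.
    Degenerate tables (a symbol unseen in both samples) cannot be split."""
    table = np.array([counts_a, counts_b], dtype=float)
    keep = table.sum(axis=0) > 0
    table = table[:, keep]
    if table.shape[1] < 2 or (table.sum(axis=1) == 0).any():
        return 1.0
    _, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(p)


def split_test(dist_a, n_a: int, dist_b, n_b: int, alpha: float) -> str:
    """Decide whether two next-symbol distributions come from the same
    predictive state: ``"different"`` iff the two-sample chi-square
    p-value falls below ``alpha``."""
    if n_a < 1 or n_b < 1:
        raise ValueError("both samples need at least one observation")
    counts_a = np.asarray(dist_a, dtype=float) * n_a
    counts_b = np.asarray(dist_b, dtype=float) * n_b
    p = _chi2_pvalue(counts_a, counts_b)
    return "different" if p < alpha else "same"


@dataclass
class ProvisionalState:
    """A weakly prescient state: member histories plus pooled next-symbol
    counts, whose normalization is the state's predictive distribution."""

    histories: set = field(default_factory=set)
    counts: np.ndarray = field(default_factory=lambda: np.zeros(2))

    @property
    def dist(self) -> np.ndarray:
        total = self.counts.sum()
        return self.counts / total if total > 0 else np.full(2, 0.5)

    def add(self, history: tuple, next_counts: np.ndarray) -> None:
        self.histories.add(history)
        self.counts = self.counts + next_counts

    def remove(self, history: tuple, next_counts: np.ndarray) -> None:
        self.histories.discard(history)
        self.counts = self.counts - next_counts


def _state_pvalue(state: ProvisionalState, child: tuple, child_counts: np.ndarray) -> float:
    """p-value of the child's next counts against the state's pooled
    counts, excluding the child's own contribution if already a member."""
    pooled = state.counts.copy()
    if child in state.histories:
        pooled = pooled - child_counts
    if pooled.sum() <= 0:
        return 1.0
    return _chi2_pvalue(child_counts, pooled)


def cssr_phase1(counts: HistoryCounts, cfg: CSSRConfig) -> list:
    """Build weakly prescient states by sufficiency splitting.

    For L = 0 .. lmax-1 every history of length L is extended one symbol
    into the past.  Extensions with support >= ``cfg.min_count`` are
    tested against their parent state's distribution; on rejection they
    are assigned to the non-rejecting existing state with the highest
    p-value, or to a fresh state if all reject.  The sweep over a level
    repeats whenever any assignment (hence a pooled distribution)
    changes.
    """
    root = ProvisionalState()
    root.add((), counts.next_counts(()))
    states: list[ProvisionalState] = [root]
    assignment: dict = {(): root}

    for level in range(cfg.lmax):
        parents = sorted(h for h in assignment if len(h) == level)
        children = []
        for h in parents:
            for a in (0, 1):
                child = (a,) + h
                if counts.count(child) > 0:
                    children.append(child)
        children.sort()

        for _sweep in range(_MAX_REFINE_PASSES):
            changed = False
            for child in children:
                child_counts = counts.next_counts(child)
                parent_state = assignment[child[1:]]
                target = _desired_state(
                    child, child_counts, parent_state, states, assignment, cfg
                )
                current = assignment.get(child)
                if current is None or target is not current:
                    if current is not None:
                        current.remove(child, child_counts)
                    if target is None:
                        target = ProvisionalState()
                        states.append(target)
                    target.add(child, child_counts)
                    assignment[child] = target
                    changed = True
            if not changed:
                break
        states = [s for s in states if s.histories]
    return states


def _desired_state(child, child_counts, parent_state, states, assignment, cfg):
    """Where the child history belongs under the current pooled
    distributions; None requests a new state."""
    if child_counts.sum() < cfg.min_count:
        return parent_state  # untestable: inherit
    if _state_pvalue(parent_state, child, child_counts) >= cfg.alpha:
        return parent_state
    best, best_p = None, -1.0
    for state in states:
        if state is parent_state or not state.histories:
            continue
        p = _state_pvalue(state, child, child_counts)
        if p >= cfg.alpha and p > best_p:
            best, best_p = state, p
    return best  # None -> create a new state


def _leaf_members(part: set) -> list:
    """Members not subsumed by a longer member of the same state: pooling
    their counts partitions sequence positions without double counting."""
    members = sorted(part, key=lambda h: (len(h), h))
    leaves = []
    for h in members:
        subsumed = any(
            g is not h and len(g) > len(h) and g[len(g) - len(h) :] == h for g in members
        )
        if not subsumed:
            leaves.append(h)
    return leaves


def _successor_index(history, symbol, counts, assignment, lmax):
    """Index of the state reached from ``history`` on ``symbol``: the state
    of the length-truncated suffix, falling back to shorter suffixes for
    contexts never split off.  None when the extension was never observed."""
    if counts.count(history + (symbol,)) == 0:
        return None
    suffix = (history + (symbol,))[-lmax:]
    while suffix not in assignment:
        suffix = suffix[1:]
    return assignment[suffix]


def cssr_phase2(states: list, counts: HistoryCounts, cfg: CSSRConfig) -> EpsilonMachine:
    """Determinize the provisional partition, estimate transition
    probabilities, and remove transient states.

    A state violates unifilarity when two member histories lead, on the
    same emitted symbol, to different successor states; such states are
    split by successor until a fixed point.  The final machine is the
    terminal strongly connected component (states a long realization
    cannot leave), which must be unique up to count mass.
    """
    partition = [set(s.histories) for s in states if s.histories]

    while True:
        assignment = {h: i for i, part in enumerate(partition) for h in part}
        split_done = False
        for i, part in enumerate(partition):
            for symbol in (0, 1):
                groups: dict = {}
                unobserved = []
                for h in sorted(part):
                    succ = _successor_index(h, symbol, counts, assignment, cfg.lmax)
                    if succ is None:
                        unobserved.append(h)
                    else:
                        groups.setdefault(succ, []).append(h)
                if len(groups) > 1:
                    # keep the heaviest successor group in place, split the rest
                    def mass(item):
                        return sum(counts.count(h) for h in item[1])

                    ordered = sorted(groups.items(), key=lambda it: (-mass(it), it[0]))
                    keep = set(ordered[0][1]) | set(unobserved)
                    partition[i] = keep
                    for _, movers in ordered[1:]:
                        partition.append(set(movers))
                    split_done = True
                    break
            if split_done:
                break
        if not split_done:
            break

    # canonical ordering by shortest member history
    def canon(part):
        h = min(part, key=lambda x: (len(x), x))
        return (len(h), h)

    partition.sort(key=canon)
    assignment = {h: i for i, part in enumerate(partition) for h in part}

    # pooled MLE transition probabilities from leaf members
    pooled = []
    successors = []
    for part in partition:
        leaf_counts = np.zeros(2)
        succ = {0: None, 1: None}
        for h in _leaf_members(part):
            leaf_counts += counts.next_counts(h)
        for symbol in (0, 1):
            for h in sorted(part):
                s = _successor_index(h, symbol, counts, assignment, cfg.lmax)
                if s is not None:
                    succ[symbol] = s
                    break
        pooled.append(leaf_counts)
        successors.append(succ)

    graph = nx.DiGraph()
    graph.add_nodes_from(range(len(partition)))
    for i, (leaf_counts, succ) in enumerate(zip(pooled, successors)):
        for symbol in (0, 1):
            if leaf_counts[symbol] > 0 and succ[symbol] is not None:
                graph.add_edge(i, succ[symbol])

    terminal = [
        comp
        for comp in nx.strongly_connected_components(graph)
        if all(dest in comp for node in comp for dest in graph.successors(node))
    ]
    if not terminal:
        raise ValueError("no recurrent component found")
    terminal.sort(
        key=lambda comp: (-sum(pooled[i].sum() for i in comp), min(comp))
    )
    recurrent = sorted(terminal[0])

    names = {i: f"S{rank}" for rank, i in enumerate(recurrent)}
    transitions = {}
    for i in recurrent:
        total = pooled[i].sum()
        if total <= 0:
            raise ValueError("recurrent state with no observations")
        for symbol in (0, 1):
            if pooled[i][symbol] > 0:
                transitions[(names[i], symbol)] = (
                    float(pooled[i][symbol] / total),
                    names[successors[i][symbol]],
                )
    history_map = {h: names[i] for h, i in assignment.items() if i in names}
    machine = EpsilonMachine(
        states=tuple(names[i] for i in recurrent),
        transitions=transitions,
        history_map=history_map,
    )
    violations = validate_machine(machine)
    if violations:
        raise RuntimeError(f"estimated machine failed validation: {violations}")
    return machine


def estimate_machine(seq: BinarySequence, cfg: CSSRConfig) -> EpsilonMachine:
    """Full CSSR reconstruction: count, split, determinize."""
    counts = count_histories(seq, cfg.lmax)
    states = cssr_phase1(counts, cfg)
    return cssr_phase2(states, counts, cfg)


def select_lmax(
    seq: BinarySequence,
    candidates=DEFAULT_LMAX_GRID,
    cfg: CSSRConfig | None = None,
    tie_tol: float = 1e-4,
):
    """Choose the maximum history length by train/test predictive loss.

    The machine is fit on the first half of the sequence and scored by
    per-symbol log loss on the second half, for every candidate; the
    winner is the argmin with ties broken toward the smallest candidate.
    Losses within ``tie_tol`` bits of the minimum count as ties, so
    differences below estimation noise never buy extra model size.
    Unfittable candidates score +inf.
    """
    candidates = tuple(sorted(candidates))
    if not candidates:
        raise ValueError("candidate list must be nonempty")
    base = cfg or CSSRConfig()
    symbols = seq.symbols if isinstance(seq, BinarySequence) else np.asarray(seq)
    half = len(symbols) // 2
    train = BinarySequence(symbols[:half])
    test = symbols[half:]

    table: dict = {}
    for lmax in candidates:
        try:
            machine = estimate_machine(
                train,
                CSSRConfig(
                    alpha=base.alpha,
                    lmax=lmax,
                    min_count=base.min_count,
                    smoothing_floor=base.smoothing_floor,
                ),
            )
            table[lmax] = sequence_log_loss(machine, test, base.smoothing_floor).bits_per_symbol
        except (ValueError, RuntimeError):
            table[lmax] = float("inf")
    lo = min(table.values())
    best = min(L for L in candidates if table[L] <= lo + tie_tol)
    return best, table
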