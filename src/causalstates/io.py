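"""Readers and writers: sequence text files, pair CSVs, model JSON, DOT.

Sequences travel as plain text (one character per symbol, optionally
newline-separated) or CSV; machines and transducers as a small JSON
schema that round-trips probabilities bit-exactly; DOT exports label each
edge "symbol: probability" (transducers "output|input: probability").
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .models import (
    BinarySequence,
    EpsilonMachine,
    EpsilonTransducer,
    IOSequencePair,
)

__all__ = [
    "read_sequence",
    "write_sequence",
    "read_pair_csv",
    "write_pair_csv",
    "machine_to_json",
    "machine_from_json",
    "transducer_to_json",
    "transducer_from_json",
    "dot_export",
]


def read_sequence(path) -> BinarySequence:
    """Read a binary sequence from text (one char per symbol, single line
    or newline-separated) or a CSV with a single symbol column.  Rejects
    anything outside {0,1}, citing the offending line."""
    path = Path(path)
    text = path.read_text()
    symbols: list[int] = []
    if path.suffix.lower() == ".csv" or "," in text.splitlines()[0]:
        df = pd.read_csv(path)
        col = df.columns[-1]
        for i, v in enumerate(df[col]):
            if v not in (0, 1):
                raise ValueError(f"{path}: symbol {v!r} outside {{0,1}} at line {i + 2}")
            symbols.append(int(v))
    else:
        for lineno, line in enumerate(text.splitlines(), start=1):
            for ch in line.strip():
                if ch not in "01":
                    raise ValueError(f"{path}: symbol {ch!r} outside {{0,1}} at line {lineno}")
                symbols.append(int(ch))
    if not symbols:
        raise ValueError(f"{path}: empty sequence")
    return BinarySequence(np.array(symbols, dtype=np.int8), user_id=path.stem)


def write_sequence(seq: BinarySequence, path) -> None:
    Path(path).write_text("".join(str(int(s)) for s in seq.symbols) + "\n")


def read_pair_csv(path) -> IOSequencePair:
    """Read an aligned pair CSV with columns t, input, output; t must be
    strictly increasing."""
    df = pd.read_csv(path)
    missing = {"t", "input", "output"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    t = df["t"].to_numpy()
    if len(t) and not (np.diff(t) > 0).all():
        raise ValueError(f"{path}: column t must be strictly increasing")
    return IOSequencePair(
        inputs=df["input"].to_numpy(), outputs=BinarySequence(df["output"].to_numpy())
    )


def write_pair_csv(pair: IOSequencePair, path) -> None:
    pd.DataFrame(
        {
            "t": np.arange(len(pair)),
            "input": pair.inputs.astype(int),
            "output": pair.outputs.symbols.astype(int),
        }
    ).to_csv(path, index=False)


def machine_to_json(m: EpsilonMachine, path=None) -> str:
    """Serialize a machine; probabilities keep full precision (repr), so
    read(write(m)) is bit-exact."""
    doc = {
        "states": [str(s) for s in m.states],
        "alphabet": [0, 1],
        "transitions": [
            {"from": str(state), "symbol": int(sym), "prob": float(prob), "to": str(dest)}
            for (state, sym), (prob, dest) in sorted(m.transitions.items(), key=str)
        ],
    }
    text = json.dumps(doc, indent=1)
    if path is not None:
        Path(path).write_text(text)
    return text


def _load_doc(source) -> dict:
    if isinstance(source, Path):
        return json.loads(source.read_text())
    if isinstance(source, str) and not source.lstrip().startswith("{"):
        return json.loads(Path(source).read_text())
    return json.loads(source)


def machine_from_json(source) -> EpsilonMachine:
    doc = _load_doc(source)
    for key in ("states", "alphabet", "transitions"):
        if key not in doc:
            raise ValueError(f"machine JSON missing field {key!r}")
    transitions = {}
    for entry in doc["transitions"]:
        for key in ("from", "symbol", "prob", "to"):
            if key not in entry:
                raise ValueError(f"transition entry missing field {key!r}: {entry}")
        transitions[(entry["from"], int(entry["symbol"]))] = (
            float(entry["prob"]),
            entry["to"],
        )
    return EpsilonMachine(states=tuple(doc["states"]), transitions=transitions)


def transducer_to_json(t: EpsilonTransducer, path=None) -> str:
    """Transducer JSON adds an "input" field per transition; prob is the
    emission probability of the output symbol in that (state, input) cell."""
    entries = []
    for (state, inp, out), dest in sorted(t.transitions.items(), key=str):
        entries.append(
            {
                "from": str(state),
                "input": int(inp),
                "symbol": int(out),
                "prob": float(t.emissions[(state, inp)][out]),
                "to": str(dest),
            }
        )
    doc = {"states": [str(s) for s in t.states], "alphabet": [0, 1], "transitions": entries}
    text = json.dumps(doc, indent=1)
    if path is not None:
        Path(path).write_text(text)
    return text


def transducer_from_json(source) -> EpsilonTransducer:
    doc = _load_doc(source)
    for key in ("states", "alphabet", "transitions"):
        if key not in doc:
            raise ValueError(f"transducer JSON missing field {key!r}")
    emissions: dict = {}
    transitions: dict = {}
    for entry in doc["transitions"]:
        for key in ("from", "input", "symbol", "prob", "to"):
            if key not in entry:
                raise ValueError(f"transition entry missing field {key!r}: {entry}")
        state, inp, out = entry["from"], int(entry["input"]), int(entry["symbol"])
        emissions.setdefault((state, inp), np.zeros(2))[out] = float(entry["prob"])
        transitions[(state, inp, out)] = entry["to"]
    return EpsilonTransducer(
        states=tuple(doc["states"]), emissions=emissions, transitions=transitions
    )


def dot_export(model, path=None) -> str:
    """Graphviz DOT text with one edge per transition, labeled
    "symbol: prob" for machines and "output|input: prob" for transducers."""
    lines = ["digraph model {", "  rankdir=LR;", "  node [shape=circle];"]
    if isinstance(model, EpsilonMachine):
        for (state, sym), (prob, dest) in sorted(model.transitions.items(), key=str):
            lines.append(f'  "{state}" -> "{dest}" [label="{sym}: {prob:.2f}"];')
    elif isinstance(model, EpsilonTransducer):
        for (state, inp, out), dest in sorted(model.transitions.items(), key=str):
            prob = float(model.emissions[(state, inp)][out])
            lines.append(f'  "{state}" -> "{dest}" [label="{out}|{inp}: {prob:.2f}"];')
    else:
        raise TypeError(f"cannot export {type(model).__name__}")
    lines.append("}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text
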