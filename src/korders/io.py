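"""Readers, writers and graph export.

Dataset files are CSV/TSV with one row per respondent and one column per
canonical unordered pair, named ``"a|b"`` where ``a`` precedes ``b`` in
the option ordering; a cell is 1 if ``a`` was chosen over ``b`` and 0
otherwise.  Rows with missing or non-binary cells are rejected (the
clustering algorithms require complete response patterns) and counted.
Preference structures serialize to JSON as sets of ordered-pair lists,
optionally with state probabilities.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import networkx as nx
import numpy as np
import pandas as pd

from .clustering import Dataset
from .relations import PairUniverse, PreferenceStructure, Relation

__all__ = [
    "read_dataset",
    "write_dataset",
    "read_structure",
    "write_structure",
    "structure_graph",
    "graph_to_dot",
    "write_graph",
    "RunConfig",
]


def _universe_from_columns(columns: Sequence[str]) -> PairUniverse:
    options: list[str] = []
    seen = set()
    for col in columns:
        if col.count("|") != 1:
            raise ValueError(f"malformed pair column {col!r} (expected 'a|b')")
        for opt in col.split("|"):
            if opt not in seen:
                seen.add(opt)
                options.append(opt)
    universe = PairUniverse(tuple(options))
    expected = {universe.pair_label(j) for j in range(universe.n_pairs)}
    got = set()
    for col in columns:
        a, b = col.split("|")
        ia, ib = universe.option_index(a), universe.option_index(b)
        got.add(universe.pair_label(universe.pair_index(ia, ib)))
    if got != expected or len(columns) != universe.n_pairs:
        raise ValueError("columns do not form the complete pair set of the options")
    return universe


def read_dataset(path: Union[str, Path]) -> tuple[Dataset, int]:
    """Read a respondent-level CSV/TSV into an aggregated Dataset.

    Columns may appear in any order and are canonicalized.  Returns the
    dataset together with the number of rejected (incomplete or
    non-binary) rows.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    frame = pd.read_csv(path, sep=sep, dtype="object")
    universe = _universe_from_columns(list(frame.columns))
    patterns: list[Relation] = []
    rejected = 0
    for _, row in frame.iterrows():
        pairs = []
        ok = True
        for col, cell in row.items():
            a, b = str(col).split("|")
            if pd.isna(cell) or str(cell).strip() not in ("0", "1"):
                ok = False
                break
            chosen = str(cell).strip() == "1"
            pairs.append((a, b) if chosen else (b, a))
        if not ok:
            rejected += 1
            continue
        patterns.append(Relation.from_pairs(universe, pairs))
    if not patterns:
        raise ValueError("no complete rows in dataset")
    return Dataset.from_patterns(universe, patterns), rejected


def write_dataset(
    data: Dataset, path: Union[str, Path], respondents: Optional[Sequence[Relation]] = None
) -> None:
    """Write respondent rows in canonical column order.

    With ``respondents`` given, rows follow that (pre-aggregation) order;
    otherwise each pattern is repeated by its (integer) frequency.
    """
    universe = data.universe
    cols = [universe.pair_label(j) for j in range(universe.n_pairs)]
    if respondents is None:
        rows_src: list[Relation] = []
        for pat, f in zip(data.patterns, data.freqs):
            if abs(f - round(f)) > 1e-9:
                raise ValueError("non-integer frequencies need explicit respondents")
            rows_src.extend([pat] * int(round(f)))
    else:
        rows_src = list(respondents)
    rows = [1 - r.bit_array() for r in rows_src]  # cell 1 = reference chosen
    pd.DataFrame(np.stack(rows), columns=cols).to_csv(path, index=False)


def write_structure(
    structure: PreferenceStructure, path: Union[str, Path]
) -> None:
    payload = {
        "options": list(structure.universe.options),
        "states": [
            sorted([a, b] for a, b in s.to_pairs()) for s in structure.states
        ],
    }
    if structure.probs is not None:
        payload["probs"] = list(structure.probs)
    Path(path).write_text(json.dumps(payload, indent=1))


def read_structure(path: Union[str, Path]) -> PreferenceStructure:
    payload = json.loads(Path(path).read_text())
    universe = PairUniverse(tuple(payload["options"]))
    states = tuple(
        Relation.from_pairs(universe, [tuple(p) for p in state])
        for state in payload["states"]
    )
    probs = tuple(payload["probs"]) if "probs" in payload else None
    return PreferenceStructure(states, probs)


def structure_graph(
    structure: PreferenceStructure,
    probs: Optional[Sequence[float]] = None,
    counts: Optional[Sequence[int]] = None,
) -> nx.Graph:
    """The neighbor graph of a structure: vertices are states, undirected
    edges join states at canonical distance exactly 2.

    Optional vertex attributes: state probability ``pi`` and the
    health-count ``n_health`` from the two-component partition.
    """
    g = nx.Graph()
    states = structure.states
    for i, s in enumerate(states):
        label = ">".join(structure.universe.options[r] for r in s.ranking()) \
            if s.is_transitive() else "".join(str(b) for b in s.bits())
        attrs = {"label": label}
        if probs is not None:
            attrs["pi"] = float(probs[i])
        elif structure.probs is not None:
            attrs["pi"] = float(structure.probs[i])
        if counts is not None:
            attrs["n_health"] = int(counts[i])
        g.add_node(i, **attrs)
    for i in range(len(states)):
        for k in range(i + 1, len(states)):
            if states[i].distance(states[k]) == 2:
                g.add_edge(i, k)
    return g


def graph_to_dot(g: nx.Graph) -> str:
    lines = ["graph preference_structure {"]
    for node, attrs in g.nodes(data=True):
        parts = [f'label="{attrs.get("label", node)}"']
        if "pi" in attrs:
            parts.append(f'pi="{attrs["pi"]:.6g}"')
        if "n_health" in attrs:
            parts.append(f'n_health="{attrs["n_health"]}"')
        lines.append(f'  {node} [{", ".join(parts)}];')
    for a, b in g.edges():
        lines.append(f"  {a} -- {b};")
    lines.append("}")
    return "\n".join(lines)


def write_graph(g: nx.Graph, path: Union[str, Path], fmt: str = "dot") -> None:
    path = Path(path)
    if fmt == "dot":
        path.write_text(graph_to_dot(g) + "\n")
    elif fmt == "graphml":
        path.write_text("\n".join(nx.generate_graphml(g)) + "\n")
    else:
        raise ValueError(f"unknown graph format {fmt!r}")


@dataclass(frozen=True)
class RunConfig:
    """A validated, serializable record of one pipeline run's parameters."""

    command: str
    method: str = "tca"
    k: int = 1
    seed: int = 0
    tol: float = 0.0
    max_iter: int = 100
    restarts: int = 1
    ma_design: Optional[tuple[int, int]] = None
    extra: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        payload = json.loads(text)
        if payload.get("ma_design") is not None:
            payload["ma_design"] = tuple(payload["ma_design"])
        return cls(**payload)
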