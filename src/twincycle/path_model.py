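"""Manifest-variable path models: representation, parsing, validation, paths.

A path model here is a directed graph over observed (manifest) variables.
Each edge carries a label and stands for a regression coefficient from a
parent node to an outcome node; edges into the same outcome co-vary, exactly
as in a simultaneous linear system.  Directed cycles are permitted — the
twin-cycle model is non-recursive (e.g. IS -> FI -> LF -> IS) — so validity
of a candidate coefficient matrix B is a question of invertibility of
(I - B), not acyclicity.

The two built-in models:

``TC``
    the twin-cycle system over 8 endogenous metabolic nodes (13 edges);
``TC-PA``
    the twin-cycle system plus an exogenous physical-activity node with an
    edge into every metabolic node (9 nodes, 21 edges).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import yaml


class ModelSpecError(ValueError):
    """Raised when a model specification is malformed or inconsistent."""


@dataclass(frozen=True)
class Edge:
    """A labelled directed edge: a regression of ``target`` on ``source``."""

    label: str
    source: str
    target: str


@dataclass(frozen=True)
class DirectedPath:
    """A simple directed path through a model, with the edge labels traversed."""

    nodes: tuple[str, ...]
    edge_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.nodes) != len(self.edge_labels) + 1:
            raise ValueError("node list must be one longer than edge list")
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError(f"path {self.nodes} revisits a node")

    def __str__(self) -> str:
        return "→".join(self.nodes)


@dataclass
class PathModel:
    """A validated directed path model over manifest nodes.

    Parameters
    ----------
    nodes
        Ordered node names; the order fixes the row/column order of every
        matrix built from the model.
    edges
        Labelled directed edges.
    exogenous
        Names of exogenous nodes (no inbound edges).  By default their
        variances are fixed to the sample value when fitting ("fixed-x");
        set ``free_exogenous_variance`` to estimate them instead.
    """

    nodes: list[str]
    edges: list[Edge]
    exogenous: set[str] = field(default_factory=set)
    free_exogenous_variance: bool = False
    name: str = "model"

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        if len(set(self.nodes)) != len(self.nodes):
            raise ModelSpecError("duplicate node names")
        known = set(self.nodes)
        seen_pairs: set[tuple[str, str]] = set()
        seen_labels: set[str] = set()
        for e in self.edges:
            for end in (e.source, e.target):
                if end not in known:
                    raise ModelSpecError(f"edge {e.label!r} references unknown node {end!r}")
            if (e.source, e.target) in seen_pairs:
                raise ModelSpecError(f"duplicate edge {e.source!r} -> {e.target!r}")
            if e.label in seen_labels:
                raise ModelSpecError(f"duplicate edge label {e.label!r}")
            seen_pairs.add((e.source, e.target))
            seen_labels.add(e.label)
        targets = {e.target for e in self.edges}
        for x in self.exogenous:
            if x not in known:
                raise ModelSpecError(f"exogenous node {x!r} not declared")
            if x in targets:
                raise ModelSpecError(f"exogenous node {x!r} is the target of an edge")
        for node in self.endogenous:
            if node not in targets:
                raise ModelSpecError(f"endogenous node {node!r} has no inbound edge")

    # -- basic queries ------------------------------------------------------

    @property
    def endogenous(self) -> list[str]:
        return [n for n in self.nodes if n not in self.exogenous]

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def node_index(self, node: str) -> int:
        return self.nodes.index(node)

    def edge(self, label: str) -> Edge:
        for e in self.edges:
            if e.label == label:
                return e
        raise KeyError(f"no edge labelled {label!r}")

    def edge_between(self, source: str, target: str) -> Edge:
        for e in self.edges:
            if e.source == source and e.target == target:
                return e
        raise KeyError(f"no edge {source!r} -> {target!r}")

    def successors(self, node: str) -> list[str]:
        return sorted(e.target for e in self.edges if e.source == node)

    def predecessors(self, node: str) -> list[str]:
        return sorted(e.source for e in self.edges if e.target == node)

    def is_recursive(self) -> bool:
        """True if the edge set is acyclic (a recursive system)."""
        import networkx as nx

        g = nx.DiGraph([(e.source, e.target) for e in self.edges])
        return nx.is_directed_acyclic_graph(g)

    # -- parameter accounting -----------------------------------------------

    @property
    def n_free_parameters(self) -> int:
        """Free parameters: edges + endogenous disturbances (+ exogenous if free)."""
        q = len(self.edges) + len(self.endogenous)
        if self.free_exogenous_variance:
            q += len(self.exogenous)
        return q

    @property
    def degrees_of_freedom(self) -> int:
        """Model df: distinct sample moments minus free parameters.

        Under the fixed-x convention each fixed exogenous variance reproduces
        its sample moment exactly, so that moment carries no testable
        restriction and is subtracted alongside the free-parameter count.
        """
        p = self.n_nodes
        moments = p * (p + 1) // 2
        df = moments - self.n_free_parameters
        if not self.free_exogenous_variance:
            df -= len(self.exogenous)
        return df

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "nodes": list(self.nodes),
            "exogenous": sorted(self.exogenous),
            "free_exogenous_variance": self.free_exogenous_variance,
            "edges": [
                {"label": e.label, "source": e.source, "target": e.target}
                for e in self.edges
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PathModel":
        return cls(
            nodes=list(d["nodes"]),
            edges=[Edge(e["label"], e["source"], e["target"]) for e in d["edges"]],
            exogenous=set(d.get("exogenous", [])),
            free_exogenous_variance=bool(d.get("free_exogenous_variance", False)),
            name=d.get("name", "model"),
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def to_dot(self) -> str:
        """GraphViz DOT rendering of the model diagram."""
        lines = [f'digraph "{self.name}" {{', "  node [shape=box];"]
        for n in self.nodes:
            lines.append(f'  "{n}";')
        for e in self.edges:
            lines.append(f'  "{e.source}" -> "{e.target}" [label="{e.label}"];')
        lines.append("}")
        return "\n".join(lines)


_EDGE_LINE = re.compile(
    r"^\s*(?P<target>\w+)\s*<-\s*(?P<source>\w+)\s*\[(?P<label>[\w-]+)\]\s*$"
)


def parse_model_spec(text: str) -> PathModel:
    """Parse a model from structured text (YAML/JSON mapping or edge lines).

    Two forms are accepted.  A mapping document with ``nodes``, ``edges`` and
    optional ``exogenous`` keys (the :meth:`PathModel.to_dict` layout), or a
    plain edge-list document of lines ``target <- source [label]`` with
    optional ``exogenous: A B`` and ``name: ...`` directives; nodes are then
    collected from the edges in first-appearance order.
    """
    stripped = text.strip()
    if not stripped:
        raise ModelSpecError("empty model specification")
    doc = None
    try:
        doc = yaml.safe_load(stripped)
    except yaml.YAMLError:
        doc = None
    if isinstance(doc, dict) and "edges" in doc:
        return PathModel.from_dict(doc)

    edges: list[Edge] = []
    nodes: list[str] = []
    exogenous: set[str] = set()
    name = "model"
    for raw in stripped.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.lower().startswith("exogenous:"):
            exogenous.update(line.split(":", 1)[1].split())
            continue
        if line.lower().startswith("name:"):
            name = line.split(":", 1)[1].strip()
            continue
        m = _EDGE_LINE.match(line)
        if m is None:
            raise ModelSpecError(f"unparseable edge line: {raw!r}")
        target, source, label = m.group("target"), m.group("source"), m.group("label")
        for n in (source, target):
            if n not in nodes:
                nodes.append(n)
        edges.append(Edge(label, source, target))
    return PathModel(nodes=nodes, edges=edges, exogenous=exogenous, name=name)


# Built-in edge sets.  Entries are (target, source, label): "target <- source".
_TC_EDGES: list[tuple[str, str, str]] = [
    ("IS", "LF", "is1"),
    ("LF", "FI", "lf1"),
    ("FI", "FG", "fi1"),
    ("FI", "IS", "fi2"),
    ("FG", "IS", "fg1"),
    ("FG", "GS", "fg2"),
    ("TG", "IS", "tg1"),
    ("TG", "LF", "tg2"),
    ("PF", "TG", "pf1"),
    ("GS", "PF", "gs1"),
    ("GS", "IS", "gs2"),
    ("PG", "IS", "pg1"),
    ("PG", "GS", "pg2"),
]

_TC_PA_EXTRA: list[tuple[str, str, str]] = [
    ("IS", "PA", "is2"),
    ("LF", "PA", "lf2"),
    ("FI", "PA", "fi3"),
    ("FG", "PA", "fg3"),
    ("TG", "PA", "tg3"),
    ("PF", "PA", "pf2"),
    ("GS", "PA", "gs3"),
    ("PG", "PA", "pg3"),
]

_TC_NODES = ["IS", "LF", "FI", "FG", "TG", "PF", "GS", "PG"]

BUILTIN_MODELS = ("TC", "TC-PA")


def builtin_model(name: str) -> PathModel:
    """Return a built-in model: ``"TC"`` or ``"TC-PA"``."""
    key = name.upper().replace("_", "-")
    if key == "TC":
        edges = [Edge(lab, src, tgt) for tgt, src, lab in _TC_EDGES]
        return PathModel(nodes=list(_TC_NODES), edges=edges, name="TC")
    if key == "TC-PA":
        edges = [Edge(lab, src, tgt) for tgt, src, lab in _TC_EDGES + _TC_PA_EXTRA]
        return PathModel(
            nodes=["PA"] + list(_TC_NODES),
            edges=edges,
            exogenous={"PA"},
            name="TC-PA",
        )
    raise ModelSpecError(
        f"unknown model {name!r}; available built-ins: {', '.join(BUILTIN_MODELS)}"
    )


def enumerate_directed_paths(
    model: PathModel,
    source: str,
    sink: str,
    max_length: int | None = None,
) -> list[DirectedPath]:
    """All simple directed paths from ``source`` to ``sink``.

    ``max_length`` bounds the number of *nodes* on a path (2 = direct edge
    only); ``None`` leaves the length unbounded.  Paths are returned in
    deterministic lexicographic order of their node sequences.
    """
    for end in (source, sink):
        if end not in model.nodes:
            raise KeyError(f"node {end!r} not in model {model.name!r}")
    if source == sink:
        raise ValueError("source and sink must differ")
    if max_length is not None and max_length < 2:
        raise ValueError("max_length must allow at least one edge (>= 2 nodes)")

    adjacency: dict[str, list[str]] = {n: [] for n in model.nodes}
    for e in model.edges:
        adjacency[e.source].append(e.target)
    for succs in adjacency.values():
        succs.sort()

    results: list[DirectedPath] = []
    stack: list[str] = [source]
    on_path = {source}

    def visit(node: str) -> None:
        if node == sink:
            labels = tuple(
                model.edge_between(a, b).label for a, b in zip(stack, stack[1:])
            )
            results.append(DirectedPath(tuple(stack), labels))
            return
        if max_length is not None and len(stack) >= max_length:
            return
        for nxt in adjacency[node]:
            if nxt in on_path:
                continue
            stack.append(nxt)
            on_path.add(nxt)
            visit(nxt)
            stack.pop()
            on_path.remove(nxt)

    visit(source)
    results.sort(key=lambda p: p.nodes)
    return results
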