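"""Metapopulation graphs: patches with finite space, joined by dispersal routes.

A metapopulation is a weighted directed graph.  Each node is a patch
(subpopulation) with a fixed number of spaces; each directed edge is a
dispersal route whose weight sets the relative probability that a migrant
leaving the source patch travels along it.

Two builders cover the canonical topologies used throughout the package:

``build_well_mixed``
    the complete digraph, every patch exchanging migrants with every other
    at equal weight — the null topology against which amplification is
    measured.

``build_star``
    one central hub connected to ``n_leaves`` peripheral patches, with
    independently settable leaf->hub and hub->leaf weights.  Unequal weights
    encode dispersal asymmetry (inward- or outward-biased stars); a zero
    hub-bound weight gives the rooted star, where the hub only exports.

Node labels follow the ``P1..Pn`` convention with ``P2`` as the hub and
``P3`` as the customary patch of introduction of the mutant, so that
per-patch output lines up across star and well-mixed runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .errors import GraphValidationError, InvalidGraphError, InvalidParameterError

__all__ = [
    "NodeSpec",
    "EdgeSpec",
    "MetapopGraph",
    "build_well_mixed",
    "build_star",
    "HUB_LABEL",
    "INTRO_LABEL",
]

#: conventional labels used by the builders and the scenario presets
HUB_LABEL = "P2"
INTRO_LABEL = "P3"


@dataclass(frozen=True)
class NodeSpec:
    """A patch: a label, a space capacity, and a topological role."""

    id: str
    capacity: int
    role: str = "plain"  # one of {"hub", "leaf", "plain"}

    def __post_init__(self):
        if self.capacity < 1:
            raise InvalidGraphError(f"node {self.id!r}: capacity must be >= 1")
        if self.role not in ("hub", "leaf", "plain"):
            raise InvalidGraphError(f"node {self.id!r}: unknown role {self.role!r}")


@dataclass(frozen=True)
class EdgeSpec:
    """A directed dispersal route with non-negative weight."""

    src: str
    dst: str
    weight: float = 1.0

    def __post_init__(self):
        if self.src == self.dst:
            raise InvalidGraphError(f"self-edge on {self.src!r} is not allowed")
        if self.weight < 0:
            raise InvalidParameterError(
                f"edge {self.src}->{self.dst}: weight must be >= 0"
            )


@dataclass(frozen=True)
class MetapopGraph:
    """An immutable, validated metapopulation graph."""

    nodes: tuple[NodeSpec, ...]
    edges: tuple[EdgeSpec, ...]
    _out: dict = field(init=False, repr=False, compare=False)

    def __init__(self, nodes, edges):
        object.__setattr__(self, "nodes", tuple(nodes))
        object.__setattr__(self, "edges", tuple(edges))
        self._validate()
        out: dict[str, dict[str, float]] = {n.id: {} for n in self.nodes}
        for e in self.edges:
            out[e.src][e.dst] = e.weight
        object.__setattr__(self, "_out", out)

    def _validate(self):
        problems = []
        ids = [n.id for n in self.nodes]
        seen = set()
        for i in ids:
            if i in seen:
                problems.append(f"duplicate node id {i!r}")
            seen.add(i)
        pairs = set()
        for e in self.edges:
            if e.src not in seen:
                problems.append(f"edge {e.src}->{e.dst}: unknown src {e.src!r}")
            if e.dst not in seen:
                problems.append(f"edge {e.src}->{e.dst}: unknown dst {e.dst!r}")
            if (e.src, e.dst) in pairs:
                problems.append(f"duplicate edge {e.src}->{e.dst}")
            pairs.add((e.src, e.dst))
        if problems:
            raise GraphValidationError(problems)

    # -- accessors ---------------------------------------------------------

    @property
    def node_ids(self) -> tuple[str, ...]:
        return tuple(n.id for n in self.nodes)

    @property
    def capacities(self) -> tuple[int, ...]:
        return tuple(n.capacity for n in self.nodes)

    @property
    def total_capacity(self) -> int:
        return sum(n.capacity for n in self.nodes)

    def node(self, node_id: str) -> NodeSpec:
        for n in self.nodes:
            if n.id == node_id:
                return n
        raise InvalidGraphError(f"no node {node_id!r} in graph")

    def index(self, node_id: str) -> int:
        for i, n in enumerate(self.nodes):
            if n.id == node_id:
                return i
        raise InvalidGraphError(f"no node {node_id!r} in graph")

    @property
    def hub_id(self) -> str | None:
        """Label of the hub node, or None if no node carries the hub role."""
        for n in self.nodes:
            if n.role == "hub":
                return n.id
        return None

    def outgoing_weight(self, node_id: str) -> float:
        """Total weight of the node's outgoing edges (its dispersal propensity)."""
        if node_id not in self._out:
            raise InvalidGraphError(f"no node {node_id!r} in graph")
        return sum(self._out[node_id].values())

    def outgoing_distribution(self, node_id: str) -> dict[str, float]:
        """Destination probabilities for a migrant leaving ``node_id``.

        Probabilities are edge weights normalised over the node's outgoing
        edges.  Returns an empty mapping when the node has no outgoing edge
        of positive weight: migrants from such a node never move.
        """
        out = self._out[node_id] if node_id in self._out else None
        if out is None:
            raise InvalidGraphError(f"no node {node_id!r} in graph")
        total = sum(out.values())
        if total <= 0:
            return {}
        return {dst: w / total for dst, w in out.items() if w > 0}

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "nodes": [
                {"id": n.id, "capacity": n.capacity, "role": n.role}
                for n in self.nodes
            ],
            "edges": [
                {"src": e.src, "dst": e.dst, "weight": e.weight} for e in self.edges
            ],
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "MetapopGraph":
        problems = []
        nodes, edges = [], []
        for rec in doc.get("nodes", []):
            try:
                nodes.append(
                    NodeSpec(
                        str(rec["id"]), int(rec["capacity"]), rec.get("role", "plain")
                    )
                )
            except (KeyError, ValueError, TypeError) as exc:
                problems.append(f"bad node record {rec!r}: {exc}")
        for rec in doc.get("edges", []):
            try:
                edges.append(
                    EdgeSpec(str(rec["src"]), str(rec["dst"]), float(rec["weight"]))
                )
            except (KeyError, ValueError, TypeError) as exc:
                problems.append(f"bad edge record {rec!r}: {exc}")
        if problems:
            raise GraphValidationError(problems)
        return cls(nodes, edges)


def save_graph(graph: MetapopGraph, path) -> None:
    """Write a graph as a canonical JSON document (UTF-8)."""
    Path(path).write_text(
        json.dumps(graph.to_dict(), indent=2) + "\n", encoding="utf-8"
    )


def load_graph(path) -> MetapopGraph:
    """Load and validate a graph JSON document."""
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    return MetapopGraph.from_dict(doc)


def build_well_mixed(n_nodes: int, capacity: int) -> MetapopGraph:
    """Complete digraph on ``n_nodes`` patches, all edge weights 1.

    All roles are ``plain``: in a well-mixed system no patch is
    topologically special, although the ``P2``/``P3`` labels keep
    bookkeeping aligned with star runs.
    """
    if n_nodes < 2:
        raise InvalidGraphError("well-mixed graph needs at least 2 nodes")
    ids = [f"P{i + 1}" for i in range(n_nodes)]
    nodes = [NodeSpec(i, capacity) for i in ids]
    edges = [EdgeSpec(a, b, 1.0) for a in ids for b in ids if a != b]
    return MetapopGraph(nodes, edges)


def build_star(
    n_leaves: int,
    capacity: int,
    w_leaf_to_hub: float = 1.0,
    w_hub_to_leaf: float = 1.0,
) -> MetapopGraph:
    """Star graph: one hub, ``n_leaves`` leaves, no leaf-leaf edges.

    ``w_leaf_to_hub == w_hub_to_leaf`` gives the balanced (IN=OUT) star;
    a larger hub-bound weight gives the inward-biased (IN>OUT) star, the
    reverse the outward-biased one.  ``w_leaf_to_hub == 0`` is the rooted
    star in which the hub only supplies migrants.
    """
    if n_leaves < 1:
        raise InvalidGraphError("star graph needs at least 1 leaf")
    if w_leaf_to_hub < 0 or w_hub_to_leaf < 0:
        raise InvalidParameterError("star edge weights must be >= 0")
    if w_leaf_to_hub == 0 and w_hub_to_leaf == 0:
        raise InvalidParameterError("star edge weights cannot both be zero")
    ids = [f"P{i + 1}" for i in range(n_leaves + 1)]
    hub = HUB_LABEL if HUB_LABEL in ids else ids[0]
    nodes = [NodeSpec(i, capacity, "hub" if i == hub else "leaf") for i in ids]
    edges = []
    for i in ids:
        if i == hub:
            continue
        if w_leaf_to_hub > 0:
            edges.append(EdgeSpec(i, hub, w_leaf_to_hub))
        if w_hub_to_leaf > 0:
            edges.append(EdgeSpec(hub, i, w_hub_to_leaf))
    return MetapopGraph(nodes, edges)
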