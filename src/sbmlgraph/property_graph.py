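"""In-memory labeled property graph with merge-by-key semantics.

This is the database-free core: nodes are keyed by (primary label,
local id, import tag) — the same composite key the emitted Cypher
``MERGE``s on — so upserting is idempotent and two models imported under
different tags can never collide or cross-link.  Property merges follow
the ``MERGE … SET`` overwrite convention: incoming values win, and each
overwrite of a differing value is logged.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional

from .errors import GraphError

__all__ = [
    "NodeKey",
    "GraphNode",
    "GraphRelationship",
    "PropertyGraph",
    "GraphStats",
    "upsert_node",
    "upsert_relationship",
    "graph_stats",
    "degree",
]


@dataclass(frozen=True)
class NodeKey:
    """Identity of a graph node: primary label + local id + import tag.

    ``local_id`` is the SBML component's id, or a path-derived surrogate
    for id-less components.  The tag keeps separately imported models
    disjoint inside one store.
    """

    primary_label: str
    local_id: str
    tag: str

    def __post_init__(self) -> None:
        for name in ("primary_label", "local_id", "tag"):
            if not getattr(self, name):
                raise GraphError(f"NodeKey.{name} must be non-empty")


@dataclass
class GraphNode:
    """A node: key, ordered labels, and scalar properties.

    ``properties`` always carries ``id`` and ``tag`` mirroring the key,
    so serialized forms are self-contained.
    """

    key: NodeKey
    labels: tuple[str, ...] = ()
    properties: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.labels:
            self.labels = (self.key.primary_label,)
        if self.labels[0] != self.key.primary_label:
            raise GraphError(
                f"labels[0]={self.labels[0]!r} != key.primary_label={self.key.primary_label!r}"
            )
        self.properties.setdefault("id", self.key.local_id)
        self.properties["tag"] = self.key.tag

    def copy(self) -> "GraphNode":
        return GraphNode(self.key, tuple(self.labels), dict(self.properties))


@dataclass
class GraphRelationship:
    """A typed, directed edge between two node keys."""

    type: str
    source: NodeKey
    target: NodeKey
    properties: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.type:
            raise GraphError("relationship type must be non-empty")

    @property
    def dedup_key(self) -> tuple:
        return (self.type, self.source, self.target)

    def copy(self) -> "GraphRelationship":
        return GraphRelationship(self.type, self.source, self.target, dict(self.properties))


@dataclass(frozen=True)
class GraphStats:
    """Per-label node counts and per-type relationship counts."""

    node_counts: dict[str, int]
    relationship_counts: dict[str, int]

    @property
    def total_nodes(self) -> int:
        return sum(self.node_counts.values())

    @property
    def total_relationships(self) -> int:
        return sum(self.relationship_counts.values())


class PropertyGraph:
    """A mutable labeled property graph.

    Nodes are unique per :class:`NodeKey`; relationships are de-duplicated
    on (type, source, target).  Endpoints must exist before an edge can
    be added, so the graph never dangles.
    """

    def __init__(self) -> None:
        self._nodes: dict[NodeKey, GraphNode] = {}
        self._rels: dict[tuple, GraphRelationship] = {}
        self.log: list[str] = []

    # -- querying -----------------------------------------------------
    def __len__(self) -> int:
        return len(self._nodes)

    def __contains__(self, key: NodeKey) -> bool:
        return key in self._nodes

    def __eq__(self, other) -> bool:
        if not isinstance(other, PropertyGraph):
            return NotImplemented
        return (
            {k: (n.labels, n.properties) for k, n in self._nodes.items()}
            == {k: (n.labels, n.properties) for k, n in other._nodes.items()}
            and {k: r.properties for k, r in self._rels.items()}
            == {k: r.properties for k, r in other._rels.items()}
        )

    def nodes(self) -> list[GraphNode]:
        return list(self._nodes.values())

    def relationships(self) -> list[GraphRelationship]:
        return list(self._rels.values())

    def node(self, key: NodeKey) -> GraphNode:
        try:
            return self._nodes[key]
        except KeyError:
            raise GraphError(f"unknown node key {key}") from None

    def nodes_with_label(self, label: str) -> list[GraphNode]:
        return [n for n in self._nodes.values() if label in n.labels]

    def incident(self, key: NodeKey, rel_type: Optional[str] = None,
                 direction: Optional[str] = None) -> list[GraphRelationship]:
        """Edges touching ``key``, filtered by type and direction
        (``"out"``: key is source; ``"in"``: key is target; ``None``: both)."""
        if key not in self._nodes:
            raise GraphError(f"unknown node key {key}")
        out = []
        for rel in self._rels.values():
            if rel_type is not None and rel.type != rel_type:
                continue
            if direction == "out":
                hit = rel.source == key
            elif direction == "in":
                hit = rel.target == key
            elif direction is None:
                hit = rel.source == key or rel.target == key
            else:
                raise ValueError(f"direction must be 'in', 'out' or None, got {direction!r}")
            if hit:
                out.append(rel)
        return out

    def neighbors(self, key: NodeKey) -> list[NodeKey]:
        seen: list[NodeKey] = []
        for rel in self.incident(key):
            other = rel.target if rel.source == key else rel.source
            if other not in seen:
                seen.append(other)
        return seen

    # -- mutation -----------------------------------------------------
    def upsert_node(self, node: GraphNode) -> GraphNode:
        """Insert, or merge properties into an existing node (incoming wins)."""
        existing = self._nodes.get(node.key)
        if existing is None:
            self._nodes[node.key] = node.copy()
            return self._nodes[node.key]
        if existing.labels[0] != node.labels[0]:
            raise GraphError(
                f"primary-label conflict for {node.key}: "
                f"{existing.labels[0]!r} vs {node.labels[0]!r}"
            )
        for lab in node.labels:
            if lab not in existing.labels:
                existing.labels = existing.labels + (lab,)
        for k, v in node.properties.items():
            if k in existing.properties and existing.properties[k] != v:
                self.log.append(
                    f"node {node.key}: property {k!r} overwritten "
                    f"({existing.properties[k]!r} -> {v!r})"
                )
            existing.properties[k] = v
        return existing

    def upsert_relationship(self, rel: GraphRelationship) -> GraphRelationship:
        """Insert, or merge properties into the existing (type, src, tgt) edge."""
        if rel.source not in self._nodes:
            raise GraphError(f"relationship source {rel.source} not in graph")
        if rel.target not in self._nodes:
            raise GraphError(f"relationship target {rel.target} not in graph")
        existing = self._rels.get(rel.dedup_key)
        if existing is None:
            self._rels[rel.dedup_key] = rel.copy()
            return self._rels[rel.dedup_key]
        for k, v in rel.properties.items():
            if k in existing.properties and existing.properties[k] != v:
                self.log.append(
                    f"edge {rel.dedup_key}: property {k!r} overwritten "
                    f"({existing.properties[k]!r} -> {v!r})"
                )
            existing.properties[k] = v
        return existing

    def remove_node(self, key: NodeKey) -> None:
        """Delete a node and every incident edge."""
        if key not in self._nodes:
            raise GraphError(f"unknown node key {key}")
        del self._nodes[key]
        self._rels = {
            k: r for k, r in self._rels.items() if r.source != key and r.target != key
        }

    def remove_relationship(self, rel: GraphRelationship) -> None:
        self._rels.pop(rel.dedup_key, None)

    def merge(self, other: "PropertyGraph") -> "PropertyGraph":
        """Upsert every node then every edge of ``other`` into this graph."""
        for node in other.nodes():
            self.upsert_node(node)
        for rel in other.relationships():
            self.upsert_relationship(rel)
        return self

    def copy(self) -> "PropertyGraph":
        g = PropertyGraph()
        g.merge(self)
        return g


# -- module-level operation surface ----------------------------------

def upsert_node(graph: PropertyGraph, node: GraphNode) -> PropertyGraph:
    graph.upsert_node(node)
    return graph


def upsert_relationship(graph: PropertyGraph, rel: GraphRelationship) -> PropertyGraph:
    graph.upsert_relationship(rel)
    return graph


def graph_stats(graph: PropertyGraph) -> GraphStats:
    """Table-style counts: nodes per primary label, edges per type."""
    nodes = Counter(n.key.primary_label for n in graph.nodes())
    rels = Counter(r.type for r in graph.relationships())
    return GraphStats(node_counts=dict(nodes), relationship_counts=dict(rels))


def degree(graph: PropertyGraph, key: NodeKey, rel_type: Optional[str] = None,
           direction: Optional[str] = None) -> int:
    """Number of incident edges, optionally filtered by type/direction."""
    return len(graph.incident(key, rel_type=rel_type, direction=direction))
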