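"""Analysis and refactoring operations on an imported metabolic graph.

These mirror the queries a modeller runs once a genome-scale model sits
in the graph store: inspecting a metabolite's reaction neighborhood,
flagging hub ("currency") metabolites, enumerating fixed-length
producer pathways, and the two refactoring steps that precede pathway
enumeration — contracting SpeciesReference stubs onto their Species and
pruning low-degree species.

All operations are non-mutating: each returns a new graph (or result
list) and leaves its input untouched.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .property_graph import NodeKey, PropertyGraph
from .schema_model import normalize_name

__all__ = [
    "PathResult",
    "species_neighborhood",
    "flag_dense_nodes",
    "producers_at_distance",
    "contract_species_references",
    "prune_species_by_degree",
]


@dataclass(frozen=True)
class PathResult:
    """A producer pathway: species and reactions visited, in order.

    ``nodes`` alternates Species / Reaction / Species / ... keys;
    ``rel_types`` holds the relationship type between each consecutive
    pair, so ``elements`` interleaves them into the familiar
    node-edge-node chain.
    """

    nodes: tuple[NodeKey, ...]
    rel_types: tuple[str, ...]

    @property
    def elements(self) -> tuple:
        out: list = [self.nodes[0]]
        for rel, node in zip(self.rel_types, self.nodes[1:]):
            out.extend((rel, node))
        return tuple(out)

    @property
    def n_reactions(self) -> int:
        return sum(1 for k in self.nodes if _is_label(k, "reaction"))


def _is_label(key: NodeKey, normalized: str) -> bool:
    return normalize_name(key.primary_label) == normalized


def _label_nodes(graph: PropertyGraph, normalized: str):
    return [n for n in graph.nodes() if _is_label(n.key, normalized)]


def _induced(graph: PropertyGraph, keep: set[NodeKey]) -> PropertyGraph:
    out = PropertyGraph()
    for node in graph.nodes():
        if node.key in keep:
            out.upsert_node(node.copy())
    for rel in graph.relationships():
        if rel.source in keep and rel.target in keep:
            out.upsert_relationship(rel.copy())
    return out


def species_neighborhood(graph: PropertyGraph, species_name: str, radius: int) -> PropertyGraph:
    """Subgraph within ``radius`` hops of every Species named ``species_name``.

    Name matching is exact on the ``name`` property.  Hops ignore edge
    direction; the result is the induced subgraph (all edges between
    retained nodes).  No matching species yields an empty graph.
    """
    if radius < 1:
        raise ValueError(f"radius must be >= 1, got {radius}")
    seeds = [
        n.key
        for n in _label_nodes(graph, "species")
        if n.properties.get("name") == species_name
    ]
    keep: set[NodeKey] = set(seeds)
    frontier = set(seeds)
    for _ in range(radius):
        nxt: set[NodeKey] = set()
        for key in frontier:
            for other in graph.neighbors(key):
                if other not in keep:
                    nxt.add(other)
        keep |= nxt
        frontier = nxt
        if not frontier:
            break
    return _induced(graph, keep)


def flag_dense_nodes(graph: PropertyGraph, label: str, threshold: int) -> PropertyGraph:
    """Mark nodes of ``label`` with degree >= ``threshold`` as ``dense=true``."""
    if threshold < 0:
        raise ValueError(f"threshold must be >= 0, got {threshold}")
    out = graph.copy()
    for node in out.nodes():
        if label in node.labels and len(out.incident(node.key)) >= threshold:
            node.properties["dense"] = True
    return out


def _species_compartment_matches(graph: PropertyGraph, key: NodeKey, compartment: str) -> bool:
    node = graph.node(key)
    if node.properties.get("compartment") == compartment:
        return True
    for other in graph.neighbors(key):
        if _is_label(other, "compartment"):
            cnode = graph.node(other)
            if other.local_id == compartment or cnode.properties.get("name") == compartment:
                return True
    return False


def producers_at_distance(
    graph: PropertyGraph,
    target_species_name: str,
    source_compartment: str,
    n_reactions: int,
    respect_direction: bool = True,
) -> list[PathResult]:
    """All simple producer paths into a target species.

    A path starts at a Species in ``source_compartment``, traverses
    exactly ``n_reactions`` Reaction nodes following reactant→reaction
    and reaction→product edge orientations (set
    ``respect_direction=False`` for schemas drawn the other way round),
    ends at every Species whose ``name`` equals ``target_species_name``,
    and never repeats a node.  Unknown compartments simply match no
    sources, giving an empty list.
    """
    if n_reactions < 1:
        raise ValueError(f"n_reactions must be >= 1, got {n_reactions}")

    species = _label_nodes(graph, "species")
    reactions = _label_nodes(graph, "reaction")
    bipartite = {n.key for n in species} | {n.key for n in reactions}

    dg = nx.DiGraph()
    dg.add_nodes_from(bipartite)
    edge_types: dict[tuple[NodeKey, NodeKey], str] = {}
    for rel in graph.relationships():
        if rel.source not in bipartite or rel.target not in bipartite:
            continue
        if _is_label(rel.source, "species") == _is_label(rel.target, "species"):
            continue  # only species<->reaction edges participate
        dg.add_edge(rel.source, rel.target)
        edge_types.setdefault((rel.source, rel.target), rel.type)
        if not respect_direction:
            dg.add_edge(rel.target, rel.source)
            edge_types.setdefault((rel.target, rel.source), rel.type)

    targets = [
        n.key for n in species if n.properties.get("name") == target_species_name
    ]
    sources = [
        n.key
        for n in species
        if _species_compartment_matches(graph, n.key, source_compartment)
        and n.key not in targets
    ]

    results: list[PathResult] = []
    cutoff = 2 * n_reactions
    for src in sources:
        for tgt in targets:
            if not (dg.has_node(src) and dg.has_node(tgt)):
                continue
            for path in nx.all_simple_paths(dg, src, tgt, cutoff=cutoff):
                if len(path) != 2 * n_reactions + 1:
                    continue
                if sum(1 for k in path if _is_label(k, "reaction")) != n_reactions:
                    continue
                rel_types = tuple(
                    edge_types[(a, b)] for a, b in zip(path, path[1:])
                )
                results.append(PathResult(nodes=tuple(path), rel_types=rel_types))
    results.sort(key=lambda p: tuple((k.primary_label, k.local_id, k.tag) for k in p.nodes))
    return results


def contract_species_references(graph: PropertyGraph) -> PropertyGraph:
    """Remove SpeciesReference stubs, re-wiring their edges onto the Species.

    Each SpeciesReference node names its Species through its
    ``species`` property; every incident edge is re-attached to that
    Species (type and direction preserved), duplicates collapse, and
    edges that would join the reference to its own Species disappear.
    References with no resolvable Species are dropped with a warning.
    """
    out = graph.copy()
    species_by_id = {
        (n.key.local_id, n.key.tag): n.key for n in _label_nodes(out, "species")
    }
    for refnode in _label_nodes(out, "speciesreference"):
        refkey = refnode.key
        sid = refnode.properties.get("species")
        target = species_by_id.get((sid, refkey.tag)) if isinstance(sid, str) else None
        incident = out.incident(refkey)
        if target is None:
            out.log.append(
                f"speciesReference {refkey.local_id!r}: species {sid!r} not in "
                f"graph; node dropped"
            )
            out.remove_node(refkey)
            continue
        for rel in incident:
            src = target if rel.source == refkey else rel.source
            tgt = target if rel.target == refkey else rel.target
            if src == tgt:
                continue  # the reference's own link to its species vanishes
            moved = rel.copy()
            moved.source, moved.target = src, tgt
            out.remove_relationship(rel)
            out.upsert_relationship(moved)
        out.remove_node(refkey)
    return out


def prune_species_by_degree(graph: PropertyGraph, min_reactions: int) -> PropertyGraph:
    """Delete Species linked to fewer than ``min_reactions`` distinct Reactions.

    Counts distinct Reaction neighbors (not edge multiplicity), decides
    on the input graph, and applies the deletions in a single pass — no
    cascading re-evaluation.
    """
    if min_reactions < 0:
        raise ValueError(f"min_reactions must be >= 0, got {min_reactions}")
    doomed = [
        n.key
        for n in _label_nodes(graph, "species")
        if sum(1 for k in graph.neighbors(n.key) if _is_label(k, "reaction")) < min_reactions
    ]
    out = graph.copy()
    for key in doomed:
        out.remove_node(key)
    return out
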