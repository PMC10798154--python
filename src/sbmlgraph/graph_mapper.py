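"""Schema-driven extraction: SBML component records → property graph.

This is the heart of the package.  Node extraction is name matching:
every document record whose kind matches a schema node's first label
becomes one graph node carrying the schema-listed properties that exist
on the record.  Relationship resolution is introspective — the mapper
inspects the records themselves to discover how two selected kinds are
linked, trying three strategies in a fixed, most-specific-first order
for each source instance:

1. **target-name** — the source record has an attribute named after the
   target label whose value is a target id (``species.compartment`` →
   ``Compartment``).
2. **relationship-name** — the drawn relationship type itself (minus a
   leading HAS/IS/IN verb) names an attribute (``HAS_UNITS`` →
   ``units``) or a ``listOf*`` child container (``HAS_PRODUCT`` →
   ``listOfProducts``) on the source; container members either are the
   targets (when they are of the target kind) or reference them through
   an attribute named after the target label.
3. **containment** — targets are nested somewhere beneath the source
   (``Reaction`` → ``LocalParameter`` inside a ``kineticLaw``), or are
   referenced by an attribute of some nested element (``Reaction`` →
   ``GeneProduct`` through ``geneProductRef``).

If the drawn direction yields nothing for a relationship, the same
ladder is tried from the target side (a reactant species stores no
pointer to its reaction — the reaction's ``listOfReactants`` stores the
pointer); edges are still emitted in the drawn direction.  The outcome
per relationship is recorded in a :class:`ResolutionTrace`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .errors import ConfigurationError
from .property_graph import (
    GraphNode,
    GraphRelationship,
    NodeKey,
    PropertyGraph,
)
from .sbml_document import (
    ComponentRecord,
    DocumentModel,
    attribute_value,
    descendant_records,
)
from .schema_model import (
    SchemaGraph,
    SchemaRelationship,
    names_match,
    normalize_name,
)

__all__ = [
    "ResolutionTrace",
    "MappingResult",
    "surrogate_key",
    "extract_nodes",
    "resolve_by_target_name",
    "resolve_by_relationship_name",
    "resolve_by_containment",
    "resolve_relationship",
    "map_document",
    "map_document_detailed",
]

#: Strategy names, in precedence order.
STRATEGIES = ("target-name", "relationship-name", "containment")


@dataclass
class ResolutionTrace:
    """How one schema relationship was resolved.

    ``strategy`` is the strategy that produced the edges (``"none"`` if
    no edges were produced); ``reversed`` marks resolution from the
    target side; ``counts`` maps strategy → number of source instances
    it resolved (plus ``"none"`` for unresolved instances).
    """

    rel_type: str
    strategy: str = "none"
    reversed: bool = False
    counts: dict[str, int] = field(default_factory=dict)
    n_edges: int = 0


@dataclass
class MappingResult:
    """Full mapping output: graph, per-relationship traces, warnings."""

    graph: PropertyGraph
    traces: list[ResolutionTrace]
    warnings: list[str]


def surrogate_key(record: ComponentRecord) -> str:
    """Deterministic id for an id-less component.

    Built from the document path, skipping the ``sbml``/``model`` roots
    and ``listOf*`` wrappers: the first eventAssignment of the first
    event is ``event[0]/eventAssignment[0]``.  Unique per document and
    stable across parses of identical bytes.
    """
    source = record.component_path or record.path
    parts = [f"{name}[{i}]" for name, i in source]
    return "/".join(parts) if parts else record.path_string()


def record_local_id(record: ComponentRecord) -> str:
    return record.id if record.id is not None else surrogate_key(record)


def extract_nodes(doc: DocumentModel, schema: SchemaGraph, tag: str) -> list[GraphNode]:
    """One graph node per document record of each schema-selected kind.

    Properties are the schema-listed ones present on the record (absent
    ones are simply omitted); ``id`` and ``tag`` are always set.  Kinds
    not selected by the schema produce nothing.
    """
    if not tag:
        raise ConfigurationError("import tag must be non-empty")
    nodes: list[GraphNode] = []
    for snode in schema.nodes:
        kind = normalize_name(snode.primary_label)
        for rec in doc.kind_index.get(kind, []):
            props: dict = {}
            for pname in snode.properties:
                value = attribute_value(rec, pname)
                if value is not None:
                    props[pname] = value
            key = NodeKey(
                primary_label=snode.primary_label,
                local_id=record_local_id(rec),
                tag=tag,
            )
            nodes.append(GraphNode(key=key, labels=tuple(snode.labels), properties=props))
    return nodes


def _id_of_kind(doc: DocumentModel, kind_norm: str, value) -> Optional[ComponentRecord]:
    if not isinstance(value, str):
        return None
    return doc.id_index.get((kind_norm, value))


def resolve_by_target_name(
    source: ComponentRecord,
    target_label: str,
    doc: DocumentModel,
    warnings: Optional[list[str]] = None,
) -> list[str]:
    """Strategy 1: an attribute named after the target label holds a target id."""
    want = normalize_name(target_label)
    value = attribute_value(source, target_label)
    if value is None:
        return []
    if _id_of_kind(doc, want, value) is not None:
        return [value]
    if warnings is not None:
        warnings.append(
            f"{source.kind} {record_local_id(source)!r}: attribute matching "
            f"{target_label!r} = {value!r} references no {target_label} record"
        )
    return []


def resolve_by_relationship_name(
    source: ComponentRecord,
    rel_type: str,
    target_label: str,
    doc: DocumentModel,
    warnings: Optional[list[str]] = None,
) -> list[str]:
    """Strategy 2: the relationship type names an attribute or listOf* child.

    The type is normalized with verb-prefix stripping (``HAS_UNITS`` →
    ``units``); singular/plural differences (one trailing ``s``) are
    ignored when matching container names.
    """
    if not rel_type:
        raise ValueError("rel_type must be non-empty")
    want = normalize_name(rel_type, strip_verb_prefix=True)
    target_norm = normalize_name(target_label)

    # (i) scalar attribute on the source
    for aname, avalue in source.attributes.items():
        local = aname.split(":")[-1]
        if names_match(normalize_name(local), want, loose_plural=True):
            if _id_of_kind(doc, target_norm, avalue) is not None:
                return [avalue]
            if warnings is not None:
                warnings.append(
                    f"{source.kind} {record_local_id(source)!r}: attribute "
                    f"{local!r} = {avalue!r} references no {target_label} record"
                )
            return []

    # (ii) listOf* child container named after the relationship
    out: list[str] = []
    for child in source.children:
        if not child.kind.startswith("listOf"):
            continue
        container = normalize_name(child.kind[len("listOf"):])
        if not names_match(container, want, loose_plural=True):
            continue
        for member in child.children:
            if normalize_name(member.kind) == target_norm:
                # members are themselves the targets (Reaction→SpeciesReference)
                out.append(record_local_id(member))
                continue
            value = attribute_value(member, target_label)
            if value is None:
                continue
            if _id_of_kind(doc, target_norm, value) is not None:
                if value not in out:
                    out.append(value)
            elif warnings is not None:
                warnings.append(
                    f"{member.kind} in {child.kind} of {source.kind} "
                    f"{record_local_id(source)!r}: {value!r} references no "
                    f"{target_label} record"
                )
    return out


def resolve_by_containment(
    source: ComponentRecord,
    target_label: str,
    doc: DocumentModel,
    warnings: Optional[list[str]] = None,
) -> list[ComponentRecord]:
    """Strategy 3: targets nested beneath the source, or referenced by a
    nested element's attribute.

    Phase 1 (direct): descendant records of the target kind (``listOf*``
    wrappers only when explicitly named).  Phase 2 (referential, only if
    phase 1 is empty): target-kind records whose id equals any attribute
    value of any descendant.  De-duplicated, document order.
    """
    target_norm = normalize_name(target_label)
    descendants = descendant_records(source)

    direct = [
        rec
        for rec in descendants
        if normalize_name(rec.kind) == target_norm
        and (not rec.kind.startswith("listOf") or target_norm.startswith("listof"))
    ]
    if direct:
        return direct

    out: list[ComponentRecord] = []
    seen: set[int] = set()
    for rec in descendants:
        for avalue in rec.attributes.values():
            hit = _id_of_kind(doc, target_norm, avalue)
            if hit is not None and id(hit) not in seen:
                seen.add(id(hit))
                out.append(hit)
    return out


def _resolve_from(
    record: ComponentRecord,
    rel_type: str,
    other_label: str,
    doc: DocumentModel,
    warnings: Optional[list[str]],
) -> tuple[str, list[str]]:
    """Run the strategy ladder from one record toward ``other_label``.

    Returns (strategy, list of other-side local ids); strategy is
    ``"none"`` when every rung comes up empty.
    """
    ids = resolve_by_target_name(record, other_label, doc, warnings)
    if ids:
        return "target-name", ids
    ids = resolve_by_relationship_name(record, rel_type, other_label, doc, warnings)
    if ids:
        return "relationship-name", ids
    records = resolve_by_containment(record, other_label, doc, warnings)
    if records:
        return "containment", [record_local_id(r) for r in records]
    return "none", []


def resolve_relationship(
    schema_rel: SchemaRelationship,
    doc: DocumentModel,
    nodes: list[GraphNode],
    tag: str,
    warnings: Optional[list[str]] = None,
) -> tuple[list[GraphRelationship], ResolutionTrace]:
    """Resolve one drawn relationship into concrete edges.

    Strategies run in the fixed order target-name → relationship-name →
    containment per source instance; if the whole forward pass yields no
    edges, the ladder is retried from the target side.  Edges are always
    emitted source→target as drawn, de-duplicated on (type, source,
    target), and restricted to extracted endpoint nodes (an edge toward
    a non-extracted node is dropped with a warning).
    """
    if warnings is None:
        warnings = []
    if not schema_rel.source_label or not schema_rel.target_label:
        raise ConfigurationError(
            f"relationship {schema_rel.type!r} has unresolved endpoint labels; "
            f"build it through a SchemaGraph"
        )
    src_label = schema_rel.source_label
    tgt_label = schema_rel.target_label

    keyed = {n.key: n for n in nodes}
    labels_present = {n.key.primary_label for n in nodes}
    for lab in (src_label, tgt_label):
        # zero instances is fine; a label entirely unknown to the node set
        # (not even extractable) is a configuration error
        if lab not in labels_present and doc.kind_index.get(normalize_name(lab)):
            raise ConfigurationError(
                f"relationship {schema_rel.type!r}: endpoint label {lab!r} has "
                f"document instances but no extracted nodes; extract both "
                f"endpoint labels before resolving"
            )

    src_records = doc.kind_index.get(normalize_name(src_label), [])
    tgt_records = doc.kind_index.get(normalize_name(tgt_label), [])
    by_local_id = {
        lab: {record_local_id(r): r for r in recs}
        for lab, recs in ((src_label, src_records), (tgt_label, tgt_records))
    }

    trace = ResolutionTrace(rel_type=schema_rel.type)
    edges: dict[tuple, GraphRelationship] = {}

    def emit(src_rec: ComponentRecord, tgt_local_id: str) -> None:
        src_key = NodeKey(src_label, record_local_id(src_rec), tag)
        tgt_key = NodeKey(tgt_label, tgt_local_id, tag)
        for key in (src_key, tgt_key):
            if key not in keyed:
                warnings.append(
                    f"{schema_rel.type}: edge endpoint {key.primary_label} "
                    f"{key.local_id!r} is not an extracted node; edge dropped"
                )
                return
        props: dict = {}
        src_record = by_local_id[src_label].get(src_key.local_id)
        if src_record is not None:
            for pname in schema_rel.properties:
                value = attribute_value(src_record, pname)
                if value is not None:
                    props[pname] = value
        rel = GraphRelationship(schema_rel.type, src_key, tgt_key, props)
        edges.setdefault(rel.dedup_key, rel)

    # forward pass: drawn direction
    for rec in src_records:
        strategy, ids = _resolve_from(rec, schema_rel.type, tgt_label, doc, warnings)
        trace.counts[strategy] = trace.counts.get(strategy, 0) + 1
        if strategy != "none" and trace.strategy == "none":
            trace.strategy = strategy
        for tid in ids:
            emit(rec, tid)

    if not edges:
        # reverse pass: resolve source ids from target records, emit as drawn
        trace.counts = {}
        trace.strategy = "none"
        for rec in tgt_records:
            strategy, ids = _resolve_from(rec, schema_rel.type, src_label, doc, warnings)
            trace.counts[strategy] = trace.counts.get(strategy, 0) + 1
            if strategy != "none" and trace.strategy == "none":
                trace.strategy = strategy
                trace.reversed = True
            for sid in ids:
                src_rec = by_local_id[src_label].get(sid)
                if src_rec is not None:
                    emit(src_rec, record_local_id(rec))

    if not edges:
        trace.strategy = "none"
        trace.reversed = False
    trace.n_edges = len(edges)
    return list(edges.values()), trace


def map_document_detailed(doc: DocumentModel, schema: SchemaGraph, tag: str) -> MappingResult:
    """Extract nodes and resolve every drawn relationship into one graph."""
    warnings: list[str] = []
    nodes = extract_nodes(doc, schema, tag)
    graph = PropertyGraph()
    for node in nodes:
        graph.upsert_node(node)
    traces: list[ResolutionTrace] = []
    for schema_rel in schema.relationships:
        rels, trace = resolve_relationship(schema_rel, doc, nodes, tag, warnings)
        traces.append(trace)
        for rel in rels:
            graph.upsert_relationship(rel)
    return MappingResult(graph=graph, traces=traces, warnings=warnings)


def map_document(doc: DocumentModel, schema: SchemaGraph, tag: str) -> PropertyGraph:
    """The full import: deterministic given (document bytes, schema, tag)."""
    return map_document_detailed(doc, schema, tag).graph
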