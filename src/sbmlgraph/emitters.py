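"""Materialize a property graph: Cypher scripts, database loads, files.

The Cypher emitted here is plain ``MERGE``-based bulk loading — batched,
parameterized ``UNWIND`` statements, nodes before relationships, no
server plugins required.  Nodes merge on ``{id, tag}`` under the primary
label (the minimal key that keeps separately imported models apart);
relationships match both endpoints on the same key and merge the typed
edge.  Replaying a script is therefore idempotent, which
:class:`InMemoryStore` — a minimal interpreter for exactly the statement
shapes this module emits — lets tests verify without a live database.

JSON and GraphML exports provide the lossless offline surface:
``import(export(g)) == g`` field-wise.
"""

from __future__ import annotations

import json
import os
import re
from dataclasses import dataclass, field
from typing import Optional

from lxml import etree

from .errors import DatabaseError, DatabaseUnavailableError, EmitError
from .property_graph import (
    GraphNode,
    GraphRelationship,
    GraphStats,
    NodeKey,
    PropertyGraph,
)

__all__ = [
    "CypherStatement",
    "CypherScript",
    "LoadReport",
    "ImportConfig",
    "InMemoryStore",
    "to_cypher",
    "load_graph",
    "export_graph",
    "import_graph",
    "write_script",
]

DEFAULT_BATCH_SIZE = 1000


@dataclass(frozen=True)
class CypherStatement:
    text: str
    params: dict


@dataclass
class CypherScript:
    """Ordered, parameterized statements; node statements precede edges."""

    statements: list[CypherStatement]
    batch_size: int

    def __len__(self) -> int:
        return len(self.statements)


@dataclass
class LoadReport:
    nodes_created: int = 0
    nodes_merged: int = 0
    relationships_created: int = 0
    relationships_merged: int = 0
    warnings: list[str] = field(default_factory=list)


@dataclass
class ImportConfig:
    """Run settings for an import.

    ``dry_run_path`` and connection settings are mutually exclusive
    requirements: a dry run needs no server, a live load needs one.
    Passwords are only ever referenced through an environment variable
    name (``password_env``), never stored.
    """

    tag: str = "import"
    dry_run_path: Optional[str] = None
    uri: Optional[str] = None
    database: str = "neo4j"
    user: Optional[str] = None
    password_env: Optional[str] = None
    batch_size: int = DEFAULT_BATCH_SIZE
    strict: bool = False
    verbosity: int = 0

    def __post_init__(self) -> None:
        if self.dry_run_path is None and self.uri is None:
            raise EmitError("either dry_run_path or a connection URI is required")


def _chunks(rows: list, size: int):
    for i in range(0, len(rows), size):
        yield rows[i : i + size]


def to_cypher(graph: PropertyGraph, batch_size: int = DEFAULT_BATCH_SIZE,
              constraints: bool = False) -> CypherScript:
    """Emit a bit-stable, idempotent Cypher script for ``graph``.

    Nodes are grouped per label set and batched into ``UNWIND`` payloads
    merging on ``{id, tag}``; relationship statements then match both
    endpoints and merge the typed edge.  All data travels as parameters
    — statement text never interpolates values.  With ``constraints``,
    composite uniqueness constraints on (id, tag) per label are emitted
    as a preamble.
    """
    if batch_size < 1:
        raise EmitError(f"batch_size must be >= 1, got {batch_size}")

    statements: list[CypherStatement] = []

    if constraints:
        for label in sorted({n.key.primary_label for n in graph.nodes()}):
            statements.append(
                CypherStatement(
                    f"CREATE CONSTRAINT IF NOT EXISTS FOR (n:`{label}`) "
                    f"REQUIRE (n.id, n.tag) IS UNIQUE",
                    {},
                )
            )

    # nodes, grouped by full label tuple for stable SET clauses
    groups: dict[tuple[str, ...], list[GraphNode]] = {}
    for node in graph.nodes():
        groups.setdefault(tuple(node.labels), []).append(node)
    for labels in sorted(groups):
        rows = [
            {
                "id": n.key.local_id,
                "tag": n.key.tag,
                "props": {k: v for k, v in n.properties.items() if k not in ("id", "tag")},
            }
            for n in sorted(groups[labels], key=lambda n: (n.key.local_id, n.key.tag))
        ]
        extra = "".join(f" SET n:`{lab}`" for lab in labels[1:])
        text = (
            f"UNWIND $rows AS row MERGE (n:`{labels[0]}` {{id: row.id, tag: row.tag}}) "
            f"SET n += row.props{extra}"
        )
        for chunk in _chunks(rows, batch_size):
            statements.append(CypherStatement(text, {"rows": chunk}))

    # relationships, grouped by (type, endpoint labels)
    rgroups: dict[tuple[str, str, str], list[GraphRelationship]] = {}
    for rel in graph.relationships():
        rgroups.setdefault(
            (rel.type, rel.source.primary_label, rel.target.primary_label), []
        ).append(rel)
    for rtype, slabel, tlabel in sorted(rgroups):
        rows = [
            {
                "sid": r.source.local_id,
                "stag": r.source.tag,
                "tid": r.target.local_id,
                "ttag": r.target.tag,
                "props": dict(r.properties),
            }
            for r in sorted(
                rgroups[(rtype, slabel, tlabel)],
                key=lambda r: (r.source.local_id, r.target.local_id, r.source.tag),
            )
        ]
        text = (
            f"UNWIND $rows AS row "
            f"MATCH (a:`{slabel}` {{id: row.sid, tag: row.stag}}) "
            f"MATCH (b:`{tlabel}` {{id: row.tid, tag: row.ttag}}) "
            f"MERGE (a)-[r:`{rtype}`]->(b) SET r += row.props"
        )
        for chunk in _chunks(rows, batch_size):
            statements.append(CypherStatement(text, {"rows": chunk}))

    return CypherScript(statements=statements, batch_size=batch_size)


# -- in-memory MERGE interpreter -------------------------------------

_NODE_RE = re.compile(
    r"^UNWIND \$rows AS row MERGE \(n:`(?P<label>[^`]+)` \{id: row\.id, tag: row\.tag\}\) "
    r"SET n \+= row\.props(?P<extra>( SET n:`[^`]+`)*)$"
)
_REL_RE = re.compile(
    r"^UNWIND \$rows AS row "
    r"MATCH \(a:`(?P<slabel>[^`]+)` \{id: row\.sid, tag: row\.stag\}\) "
    r"MATCH \(b:`(?P<tlabel>[^`]+)` \{id: row\.tid, tag: row\.ttag\}\) "
    r"MERGE \(a\)-\[r:`(?P<rtype>[^`]+)`\]->\(b\) SET r \+= row\.props$"
)
_CONSTRAINT_RE = re.compile(r"^CREATE CONSTRAINT\b")


class InMemoryStore:
    """A tiny stand-in store executing the Cypher shapes ``to_cypher`` emits.

    It understands exactly three statement forms — the node MERGE, the
    relationship MERGE and the uniqueness-constraint preamble — and
    applies Neo4j MERGE semantics (match on key, create if absent, SET
    overwrites).  Sufficient to verify idempotence and count-equivalence
    offline; anything else raises.
    """

    def __init__(self) -> None:
        self.nodes: dict[tuple[str, str, str], dict] = {}
        self.node_labels: dict[tuple[str, str, str], tuple[str, ...]] = {}
        self.rels: dict[tuple, dict] = {}

    def execute(self, script: CypherScript) -> LoadReport:
        report = LoadReport()
        for i, stmt in enumerate(script.statements):
            if _CONSTRAINT_RE.match(stmt.text):
                continue
            m = _NODE_RE.match(stmt.text)
            if m:
                label = m.group("label")
                extra = tuple(re.findall(r"SET n:`([^`]+)`", m.group("extra") or ""))
                for row in stmt.params["rows"]:
                    key = (label, row["id"], row["tag"])
                    if key not in self.nodes:
                        self.nodes[key] = {"id": row["id"], "tag": row["tag"]}
                        self.node_labels[key] = (label,) + extra
                        report.nodes_created += 1
                    else:
                        report.nodes_merged += 1
                    self.nodes[key].update(row["props"])
                continue
            m = _REL_RE.match(stmt.text)
            if m:
                slabel, tlabel, rtype = m.group("slabel"), m.group("tlabel"), m.group("rtype")
                for row in stmt.params["rows"]:
                    skey = (slabel, row["sid"], row["stag"])
                    tkey = (tlabel, row["tid"], row["ttag"])
                    if skey not in self.nodes or tkey not in self.nodes:
                        report.warnings.append(
                            f"statement {i}: MATCH failed for {skey} -> {tkey}; row skipped"
                        )
                        continue
                    rkey = (rtype, skey, tkey)
                    if rkey not in self.rels:
                        self.rels[rkey] = {}
                        report.relationships_created += 1
                    else:
                        report.relationships_merged += 1
                    self.rels[rkey].update(row["props"])
                continue
            raise DatabaseError(f"statement {i}: unrecognized statement shape: {stmt.text!r}")
        return report

    def stats(self) -> GraphStats:
        from collections import Counter

        return GraphStats(
            node_counts=dict(Counter(k[0] for k in self.nodes)),
            relationship_counts=dict(Counter(k[0] for k in self.rels)),
        )


# -- script files and database loads ---------------------------------

def write_script(script: CypherScript, path: str) -> None:
    """Write statements one per line, parameters as a JSON-lines sidecar."""
    with open(path, "w", encoding="utf-8") as fh:
        for stmt in script.statements:
            fh.write(stmt.text + "\n")
    with open(path + ".params.jsonl", "w", encoding="utf-8") as fh:
        for stmt in script.statements:
            fh.write(json.dumps(stmt.params, sort_keys=True) + "\n")


def load_graph(graph: PropertyGraph, config: ImportConfig) -> LoadReport:
    """Load a graph: write a script (dry run) or execute it over Bolt.

    Dry runs never attempt a connection; the returned report comes from
    replaying the script through :class:`InMemoryStore`.  Live loads run
    one transaction per batch, fail fast (no retries), and name the
    failed batch index on error.
    """
    script = to_cypher(graph, batch_size=config.batch_size)
    if config.dry_run_path is not None:
        write_script(script, config.dry_run_path)
        return InMemoryStore().execute(script)

    try:
        import neo4j  # noqa: PLC0415 - optional dependency
    except ImportError as exc:
        raise DatabaseUnavailableError(
            "the neo4j Bolt driver is not installed; install the 'neo4j' extra "
            "or use a dry run"
        ) from exc

    password = os.environ.get(config.password_env or "", "")
    auth = (config.user, password) if config.user else None
    try:
        driver = neo4j.GraphDatabase.driver(config.uri, auth=auth)
        driver.verify_connectivity()
    except Exception as exc:  # driver raises its own hierarchy
        raise DatabaseUnavailableError(f"cannot connect to {config.uri}: {exc}") from exc

    report = LoadReport()
    try:
        with driver.session(database=config.database) as session:
            for i, stmt in enumerate(script.statements):
                try:
                    summary = session.execute_write(
                        lambda tx, s=stmt: tx.run(s.text, **s.params).consume()
                    )
                except Exception as exc:
                    raise DatabaseError(f"batch {i} failed: {exc}") from exc
                counters = summary.counters
                report.nodes_created += counters.nodes_created
                report.relationships_created += counters.relationships_created
    finally:
        driver.close()
    report.nodes_merged = len(graph.nodes()) - report.nodes_created
    report.relationships_merged = len(graph.relationships()) - report.relationships_created
    return report


# -- offline serialization -------------------------------------------

_GRAPHML_NS = "http://graphml.graphdrawing.org/xmlns"


def export_graph(graph: PropertyGraph, format: str) -> str:
    """Serialize losslessly to ``json`` or ``graphml`` text."""
    if format == "json":
        return _to_json(graph)
    if format == "graphml":
        return _to_graphml(graph)
    raise EmitError(f"unknown export format {format!r} (expected 'json' or 'graphml')")


def import_graph(text: str, format: str) -> PropertyGraph:
    """Inverse of :func:`export_graph`: ``import(export(g)) == g``."""
    if format == "json":
        return _from_json(text)
    if format == "graphml":
        return _from_graphml(text)
    raise EmitError(f"unknown import format {format!r} (expected 'json' or 'graphml')")


def _key_dict(key: NodeKey) -> dict:
    return {"label": key.primary_label, "id": key.local_id, "tag": key.tag}


def _key_from(d: dict) -> NodeKey:
    return NodeKey(d["label"], d["id"], d["tag"])


def _to_json(graph: PropertyGraph) -> str:
    doc = {
        "format": "sbmlgraph-json",
        "version": 1,
        "nodes": [
            {
                "key": _key_dict(n.key),
                "labels": list(n.labels),
                "properties": n.properties,
            }
            for n in graph.nodes()
        ],
        "relationships": [
            {
                "type": r.type,
                "source": _key_dict(r.source),
                "target": _key_dict(r.target),
                "properties": r.properties,
            }
            for r in graph.relationships()
        ],
    }
    return json.dumps(doc, indent=2, sort_keys=False)


def _from_json(text: str) -> PropertyGraph:
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise EmitError(f"not a valid JSON graph document: {exc}") from exc
    graph = PropertyGraph()
    for n in doc.get("nodes", []):
        graph.upsert_node(
            GraphNode(
                key=_key_from(n["key"]),
                labels=tuple(n["labels"]),
                properties=dict(n["properties"]),
            )
        )
    for r in doc.get("relationships", []):
        graph.upsert_relationship(
            GraphRelationship(
                type=r["type"],
                source=_key_from(r["source"]),
                target=_key_from(r["target"]),
                properties=dict(r["properties"]),
            )
        )
    return graph


def _to_graphml(graph: PropertyGraph) -> str:
    nsmap = {None: _GRAPHML_NS}
    root = etree.Element(f"{{{_GRAPHML_NS}}}graphml", nsmap=nsmap)
    keys = [
        ("d_labels", "node", "labels"),
        ("d_nid", "node", "local_id"),
        ("d_ntag", "node", "tag"),
        ("d_nprops", "node", "properties"),
        ("d_etype", "edge", "type"),
        ("d_eprops", "edge", "properties"),
    ]
    for kid, domain, name in keys:
        el = etree.SubElement(root, f"{{{_GRAPHML_NS}}}key")
        el.set("id", kid)
        el.set("for", domain)
        el.set("attr.name", name)
        el.set("attr.type", "string")
    gel = etree.SubElement(root, f"{{{_GRAPHML_NS}}}graph")
    gel.set("id", "G")
    gel.set("edgedefault", "directed")

    ids: dict[NodeKey, str] = {}
    for i, node in enumerate(graph.nodes()):
        nid = f"n{i}"
        ids[node.key] = nid
        nel = etree.SubElement(gel, f"{{{_GRAPHML_NS}}}node", id=nid)
        for kid, value in (
            ("d_labels", json.dumps(list(node.labels))),
            ("d_nid", node.key.local_id),
            ("d_ntag", node.key.tag),
            ("d_nprops", json.dumps(node.properties)),
        ):
            d = etree.SubElement(nel, f"{{{_GRAPHML_NS}}}data")
            d.set("key", kid)
            d.text = value
    for i, rel in enumerate(graph.relationships()):
        eel = etree.SubElement(gel, f"{{{_GRAPHML_NS}}}edge", id=f"e{i}")
        eel.set("source", ids[rel.source])
        eel.set("target", ids[rel.target])
        for kid, value in (
            ("d_etype", rel.type),
            ("d_eprops", json.dumps(rel.properties)),
        ):
            d = etree.SubElement(eel, f"{{{_GRAPHML_NS}}}data")
            d.set("key", kid)
            d.text = value
    return etree.tostring(
        root, pretty_print=True, xml_declaration=True, encoding="UTF-8"
    ).decode("utf-8")


def _from_graphml(text: str) -> PropertyGraph:
    try:
        root = etree.fromstring(text.encode("utf-8"))
    except etree.XMLSyntaxError as exc:
        raise EmitError(f"not a valid GraphML document: {exc}") from exc
    ns = {"g": _GRAPHML_NS}
    graph = PropertyGraph()
    key_by_xmlid: dict[str, NodeKey] = {}
    for nel in root.findall(".//g:node", ns):
        data = {d.get("key"): d.text or "" for d in nel.findall("g:data", ns)}
        labels = tuple(json.loads(data["d_labels"]))
        key = NodeKey(labels[0], data["d_nid"], data["d_ntag"])
        key_by_xmlid[nel.get("id")] = key
        graph.upsert_node(
            GraphNode(key=key, labels=labels, properties=json.loads(data["d_nprops"]))
        )
    for eel in root.findall(".//g:edge", ns):
        data = {d.get("key"): d.text or "" for d in eel.findall("g:data", ns)}
        graph.upsert_relationship(
            GraphRelationship(
                type=data["d_etype"],
                source=key_by_xmlid[eel.get("source")],
                target=key_by_xmlid[eel.get("target")],
                properties=json.loads(data["d_eprops"]),
            )
        )
    return graph
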