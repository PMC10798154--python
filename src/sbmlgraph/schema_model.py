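"""Graph schemas in the Arrows drawing-app export format.

The schema is the user's declaration of *what to extract* from an SBML
document: each drawn node selects one SBML component kind (its first
label) plus the attributes to carry over as graph properties, and each
drawn arrow declares a typed, directed relationship between two selected
kinds.  Coordinates, colours and other visual fields in the export are
ignored.

Name matching between schema and document is deliberately forgiving:
``normalize_name`` lower-cases and strips punctuation, so the label
``UnitDefinition`` matches the element ``unitDefinition``.  Relationship
types additionally drop leading verb tokens (``HAS``, ``IS``, ``IN``),
so ``IN_COMPARTMENT`` is compared as ``compartment`` and ``HAS_UNITS``
as ``units``.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Mapping, Optional

from .errors import SchemaParseError, SchemaValidationError

__all__ = [
    "SchemaNode",
    "SchemaRelationship",
    "SchemaGraph",
    "Diagnostic",
    "load_schema",
    "dump_schema",
    "validate_schema",
    "normalize_name",
    "names_match",
]

#: Leading relationship-type tokens treated as verbs, not names.
VERB_PREFIXES = frozenset({"has", "is", "in"})

# Split on non-alphanumeric runs and on lowerCamel→Upper boundaries.
_TOKEN_SPLIT = re.compile(r"[^0-9A-Za-z]+|(?<=[a-z0-9])(?=[A-Z])")
_NON_ALNUM = re.compile(r"[^0-9a-z]+")


def normalize_name(name: str, *, strip_verb_prefix: bool = False) -> str:
    """Canonical comparison form of a schema or SBML name.

    Lower-cases and removes every non-alphanumeric character, so
    ``unitDefinition``/``UnitDefinition`` and ``HAS_LOWERFLUXBOUND``/
    ``hasLowerFluxBound`` collapse to the same string.  With
    ``strip_verb_prefix=True`` (used for relationship types) leading
    ``HAS``/``IS``/``IN`` tokens are dropped first, so
    ``IN_COMPARTMENT`` normalizes to ``compartment``.

    Idempotent: ``normalize_name(normalize_name(x)) == normalize_name(x)``.
    """
    if not isinstance(name, str) or not name.strip():
        raise ValueError("name must be a non-empty string")
    if strip_verb_prefix:
        tokens = [t for t in _TOKEN_SPLIT.split(name) if t]
        while len(tokens) > 1 and tokens[0].lower() in VERB_PREFIXES:
            tokens = tokens[1:]
        name = "".join(tokens)
    out = _NON_ALNUM.sub("", name.lower())
    if not out:
        raise ValueError(f"name {name!r} normalizes to the empty string")
    return out


def names_match(a: str, b: str, *, loose_plural: bool = False) -> bool:
    """Whether two already-normalized names refer to the same thing.

    With ``loose_plural`` a single trailing ``s`` is ignored on either
    side, so ``listOfProducts`` (→ ``products``) matches ``HAS_PRODUCT``
    (→ ``product``).
    """
    if a == b:
        return True
    if loose_plural:
        return _singular(a) == _singular(b)
    return False


def _singular(name: str) -> str:
    return name[:-1] if name.endswith("s") else name


@dataclass(frozen=True)
class SchemaNode:
    """One drawn node: a selected SBML component kind plus its properties.

    ``labels[0]`` names the SBML component; any further labels are
    carried verbatim onto the extracted graph nodes.  Property values in
    the Arrows export hold optional type hints which are documentation
    only and never enforced.
    """

    key: str
    labels: tuple[str, ...]
    properties: Mapping[str, Optional[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.key:
            raise SchemaValidationError("schema node key must be non-empty")
        if not self.labels:
            raise SchemaValidationError(f"schema node {self.key!r} has no labels")
        for lab in self.labels:
            if not lab or any(ch.isspace() for ch in lab):
                raise SchemaValidationError(
                    f"schema node {self.key!r} has invalid label {lab!r}"
                )

    @property
    def primary_label(self) -> str:
        return self.labels[0]


@dataclass(frozen=True)
class SchemaRelationship:
    """One drawn arrow: a typed, directed relationship between two nodes.

    Direction is meaningful — edges are emitted source→target exactly as
    drawn.  ``source_label``/``target_label`` are filled in by the owning
    :class:`SchemaGraph` for convenience.
    """

    type: str
    source_key: str
    target_key: str
    properties: Mapping[str, Optional[str]] = field(default_factory=dict)
    source_label: str = ""
    target_label: str = ""

    def __post_init__(self) -> None:
        if not self.type:
            raise SchemaValidationError("relationship type must be non-empty")


@dataclass(frozen=True)
class SchemaGraph:
    """A validated schema: the complete extraction request."""

    nodes: tuple[SchemaNode, ...]
    relationships: tuple[SchemaRelationship, ...]

    def __post_init__(self) -> None:
        keys = [n.key for n in self.nodes]
        if len(set(keys)) != len(keys):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise SchemaValidationError(f"duplicate schema node keys: {dupes}")
        by_key = {n.key: n for n in self.nodes}
        dangling = sorted(
            {
                k
                for r in self.relationships
                for k in (r.source_key, r.target_key)
                if k not in by_key
            }
        )
        if dangling:
            raise SchemaValidationError(
                f"relationships reference missing node keys: {dangling}"
            )
        # Resolve endpoint labels once, so downstream code never needs the map.
        resolved = tuple(
            SchemaRelationship(
                type=r.type,
                source_key=r.source_key,
                target_key=r.target_key,
                properties=r.properties,
                source_label=by_key[r.source_key].primary_label,
                target_label=by_key[r.target_key].primary_label,
            )
            for r in self.relationships
        )
        object.__setattr__(self, "relationships", resolved)

    def node_by_key(self, key: str) -> SchemaNode:
        for n in self.nodes:
            if n.key == key:
                return n
        raise KeyError(key)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(n.primary_label for n in self.nodes)


@dataclass(frozen=True)
class Diagnostic:
    """A non-fatal schema/document mismatch report."""

    severity: str  # "warning"
    code: str  # "unknown-label" | "unknown-property"
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.severity}: [{self.code}] {self.message}"


def _require(obj: Mapping, key: str, where: str):
    if key not in obj:
        raise SchemaParseError(f"{where} is missing required field {key!r}")
    return obj[key]


def load_schema(schema_text: str) -> SchemaGraph:
    """Parse an Arrows-export document into a :class:`SchemaGraph`.

    The export is a JSON object with ``nodes`` (id, labels, properties,
    plus visual fields) and ``relationships`` (id, type, fromId, toId,
    properties).  Visual fields are discarded; label order and property
    names are preserved.  Malformed documents raise
    :class:`SchemaParseError` naming the offending element; dangling
    relationship endpoints raise :class:`SchemaValidationError`.
    """
    try:
        doc = json.loads(schema_text)
    except json.JSONDecodeError as exc:
        raise SchemaParseError(f"schema is not valid JSON: {exc}") from exc
    if not isinstance(doc, dict):
        raise SchemaParseError("schema document must be a JSON object")

    raw_nodes = doc.get("nodes", [])
    raw_rels = doc.get("relationships", [])
    if not isinstance(raw_nodes, list) or not isinstance(raw_rels, list):
        raise SchemaParseError("'nodes' and 'relationships' must be arrays")

    nodes = []
    for i, rn in enumerate(raw_nodes):
        where = f"node #{i}"
        if not isinstance(rn, dict):
            raise SchemaParseError(f"{where} is not an object")
        key = str(_require(rn, "id", where))
        labels = _require(rn, "labels", where)
        if not isinstance(labels, list) or not all(isinstance(l, str) for l in labels):
            raise SchemaParseError(f"{where} ({key!r}): 'labels' must be a string array")
        props = rn.get("properties", {})
        if not isinstance(props, dict):
            raise SchemaParseError(f"{where} ({key!r}): 'properties' must be an object")
        nodes.append(
            SchemaNode(key=key, labels=tuple(labels), properties=dict(props))
        )

    rels = []
    for i, rr in enumerate(raw_rels):
        where = f"relationship #{i}"
        if not isinstance(rr, dict):
            raise SchemaParseError(f"{where} is not an object")
        rels.append(
            SchemaRelationship(
                type=str(_require(rr, "type", where)),
                source_key=str(_require(rr, "fromId", where)),
                target_key=str(_require(rr, "toId", where)),
                properties=dict(rr.get("properties", {}) or {}),
            )
        )
    return SchemaGraph(nodes=tuple(nodes), relationships=tuple(rels))


def dump_schema(schema: SchemaGraph) -> str:
    """Write a :class:`SchemaGraph` back out in the Arrows export layout.

    Round-trips losslessly through :func:`load_schema` for labels,
    properties and relationship types (visual fields, having been
    discarded on load, are emitted as defaults).
    """
    doc = {
        "nodes": [
            {
                "id": n.key,
                "position": {"x": 0, "y": 0},
                "caption": "",
                "labels": list(n.labels),
                "properties": dict(n.properties),
                "style": {},
            }
            for n in schema.nodes
        ],
        "relationships": [
            {
                "id": f"r{i}",
                "type": r.type,
                "fromId": r.source_key,
                "toId": r.target_key,
                "properties": dict(r.properties),
                "style": {},
            }
            for i, r in enumerate(schema.relationships)
        ],
    }
    return json.dumps(doc, indent=2)


def validate_schema(schema: SchemaGraph, catalog) -> list[Diagnostic]:
    """Check a schema against a parsed document's component catalog.

    Returns one warning per schema label with no matching component kind
    and one per schema property never observed as an attribute on any
    instance of its kind.  Diagnostics never abort an import: an
    unmatched label simply extracts zero nodes.
    """
    diags: list[Diagnostic] = []
    for node in schema.nodes:
        kind = normalize_name(node.primary_label)
        if kind not in catalog.counts:
            diags.append(
                Diagnostic(
                    "warning",
                    "unknown-label",
                    f"schema label {node.primary_label!r} matches no component "
                    f"kind in the document",
                )
            )
            continue
        known_attrs = catalog.attributes.get(kind, frozenset())
        for prop in node.properties:
            if normalize_name(prop) not in known_attrs:
                diags.append(
                    Diagnostic(
                        "warning",
                        "unknown-property",
                        f"property {prop!r} on label {node.primary_label!r} "
                        f"matches no attribute on any instance",
                    )
                )
    return diags
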