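"""SBML parsing into a uniform component-record tree.

An SBML model is a deep XML tree of typed components (species,
reactions, compartments, ...) extended by Level 3 packages (fbc,
groups, layout, qual).  Everything downstream — schema validation,
introspective mapping, the ground-truth oracle — works on one uniform
substrate: a tree of :class:`ComponentRecord` objects, each exposing its
kind (the element name), package, attributes, optional math/annotation/
notes payloads, and a stable document path.

Supported inputs are Level 2 Version 5 and Level 3 Version 2 core plus
the fbc/groups/layout/qual package namespaces; other Level 2/3 core
releases and unknown package namespaces are still parsed (the package
tag is then derived from the namespace prefix, with a warning).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import cached_property
from typing import Optional, Union

from lxml import etree

from ._mathml import mathml_to_infix
from .errors import SbmlFormatError, SbmlParseError
from .schema_model import normalize_name

__all__ = [
    "ComponentRecord",
    "DocumentModel",
    "ComponentCatalog",
    "parse_document",
    "component_catalog",
    "attribute_value",
    "descendant_records",
]

Scalar = Union[str, int, float, bool]

#: Known package namespace URIs are recognized by their path fragment.
_PACKAGE_FRAGMENTS = {"/fbc/": "fbc", "/groups/": "groups", "/layout/": "layout", "/qual/": "qual"}
_CORE_RE = re.compile(r"^http://www\.sbml\.org/sbml/level\d+(/version\d+)?(/core)?$")
_MATHML_NS = "http://www.w3.org/1998/Math/MathML"

# Attributes the SBML specifications declare boolean / numeric; values are
# coerced so graph properties come out typed.  Unparseable values stay
# strings (with a warning) rather than failing the import.
_BOOL_ATTRS = frozenset(
    {
        "constant", "reversible", "fast", "hasOnlySubstanceUnits",
        "boundaryCondition", "useValuesFromTriggerTime", "persistent",
        "initialValue", "required", "strict",
    }
)
_FLOAT_ATTRS = frozenset(
    {
        "stoichiometry", "size", "value", "initialAmount",
        "initialConcentration", "multiplier", "width", "height", "depth",
        "x", "y", "z",
    }
)
_INT_ATTRS = frozenset(
    {"charge", "scale", "exponent", "spatialDimensions", "maxLevel", "thresholdLevel"}
)


@dataclass
class ComponentRecord:
    """One SBML element as a uniform record.

    ``kind`` is the element's local name exactly as written in the
    document (``species``, ``unitDefinition``, ``geneProduct``);
    ``path`` is the ordered list of (element-name, ordinal) pairs from
    the document root, unique per record and stable across parses.
    """

    kind: str
    package: str
    id: Optional[str]
    attributes: dict[str, Scalar]
    path: tuple[tuple[str, int], ...]
    #: path with sbml/model/listOf* wrappers folded out; ordinals count
    #: same-kind components under the nearest retained ancestor, so two
    #: speciesReference siblings in different listOf wrappers stay distinct
    component_path: tuple[tuple[str, int], ...] = ()
    math: Optional[str] = None
    annotation: Optional[str] = None
    notes: Optional[str] = None
    children: list["ComponentRecord"] = field(default_factory=list)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<ComponentRecord {self.kind} id={self.id!r} path={self.path_string()!r}>"

    def path_string(self) -> str:
        return "/".join(f"{name}[{i}]" for name, i in self.path)


@dataclass(frozen=True)
class ComponentCatalog:
    """What a document contains: per-kind package, instance count, and the
    set of attribute names observed on any instance (all names normalized)."""

    counts: dict[str, tuple[str, int]]
    attributes: dict[str, frozenset[str]]


@dataclass
class DocumentModel:
    """A parsed SBML document: the model record tree plus flat views."""

    level: int
    version: int
    model: ComponentRecord
    all_records: list[ComponentRecord]
    warnings: list[str] = field(default_factory=list)

    @cached_property
    def kind_index(self) -> dict[str, list[ComponentRecord]]:
        """Records grouped by normalized kind, in document order."""
        out: dict[str, list[ComponentRecord]] = {}
        for rec in self.all_records:
            out.setdefault(normalize_name(rec.kind), []).append(rec)
        return out

    @cached_property
    def id_index(self) -> dict[tuple[str, str], ComponentRecord]:
        """(normalized kind, id) → record; first wins on duplicates."""
        out: dict[tuple[str, str], ComponentRecord] = {}
        for rec in self.all_records:
            if rec.id is not None:
                out.setdefault((normalize_name(rec.kind), rec.id), rec)
        return out


def _package_of(tag: str, nsmap_prefix: dict[str, str], warnings: list[str]) -> str:
    qname = etree.QName(tag)
    ns = qname.namespace
    if ns is None or _CORE_RE.match(ns):
        return "core"
    for frag, pkg in _PACKAGE_FRAGMENTS.items():
        if frag in ns:
            return pkg
    prefix = nsmap_prefix.get(ns)
    label = prefix or ns.rstrip("/").rsplit("/", 1)[-1]
    msg = f"unsupported package namespace {ns!r}; recording elements with package {label!r}"
    if msg not in warnings:
        warnings.append(msg)
    return label


def _coerce(name: str, value: str, warnings: list[str]) -> Scalar:
    if name in _BOOL_ATTRS:
        if value in ("true", "1"):
            return True
        if value in ("false", "0"):
            return False
        warnings.append(f"attribute {name}={value!r}: expected boolean, kept as string")
        return value
    if name in _INT_ATTRS:
        try:
            return int(value)
        except ValueError:
            pass  # fall through to float (spatialDimensions may be fractional in L3)
    if name in _FLOAT_ATTRS or name in _INT_ATTRS:
        try:
            return float(value)
        except ValueError:
            warnings.append(f"attribute {name}={value!r}: expected number, kept as string")
            return value
    return value


def parse_document(xml_text: Union[str, bytes]) -> DocumentModel:
    """Parse SBML text into a :class:`DocumentModel`.

    Every element beneath ``<sbml>`` becomes a :class:`ComponentRecord`
    (``listOf*`` containers included — a schema may target them), except
    ``math``, ``annotation`` and ``notes`` subtrees, which are captured
    on their parent record as an infix formula string and raw XML text
    respectively.  Malformed XML raises :class:`SbmlParseError` with
    line/column; a non-SBML root raises :class:`SbmlFormatError`.
    """
    data = xml_text.encode("utf-8") if isinstance(xml_text, str) else xml_text
    try:
        root = etree.fromstring(data)
    except etree.XMLSyntaxError as exc:
        raise SbmlParseError(f"malformed XML: {exc}") from exc

    if etree.QName(root).localname != "sbml":
        raise SbmlFormatError(
            f"root element is <{etree.QName(root).localname}>, expected <sbml>"
        )

    warnings: list[str] = []
    try:
        level = int(root.get("level", "3"))
        version = int(root.get("version", "2"))
    except ValueError as exc:
        raise SbmlFormatError(f"non-integer level/version on <sbml>: {exc}") from exc

    ns_to_prefix = {uri: p for p, uri in (root.nsmap or {}).items() if p}

    model_elems = [
        c
        for c in root
        if isinstance(c.tag, str) and etree.QName(c).localname == "model"
    ]
    if not model_elems:
        raise SbmlFormatError("document has no <model> element")

    all_records: list[ComponentRecord] = []

    def build(elem, path_prefix: tuple[tuple[str, int], ...], sibling_counts,
              comp_prefix: tuple[tuple[str, int], ...], scope_counts: dict) -> ComponentRecord:
        qname = etree.QName(elem)
        name = qname.localname
        ordinal = sibling_counts.get(name, 0)
        sibling_counts[name] = ordinal + 1
        path = path_prefix + ((name, ordinal),)

        # component path: wrappers (model, listOf*) are transparent — their
        # children number within the enclosing retained component's scope
        wrapper = name == "model" or name.startswith("listOf")
        if wrapper:
            comp_path = comp_prefix + ((name, ordinal),)
            child_comp_prefix, child_scope = comp_prefix, scope_counts
        else:
            comp_ordinal = scope_counts.get(name, 0)
            scope_counts[name] = comp_ordinal + 1
            comp_path = comp_prefix + ((name, comp_ordinal),)
            child_comp_prefix, child_scope = comp_path, {}

        prefixes = dict(ns_to_prefix)
        prefixes.update({uri: p for p, uri in (elem.nsmap or {}).items() if p})

        attrs: dict[str, Scalar] = {}
        for aname, avalue in elem.attrib.items():
            local = etree.QName(aname).localname if aname.startswith("{") else aname
            if local in attrs:
                # core attribute wins the plain slot; keep qualified copy
                attrs[f"{_package_of(aname, prefixes, warnings)}:{local}"] = avalue
                continue
            attrs[local] = _coerce(local, avalue, warnings)

        rec = ComponentRecord(
            kind=name,
            package=_package_of(elem.tag, prefixes, warnings),
            id=attrs.get("id") if isinstance(attrs.get("id"), str) else None,
            attributes=attrs,
            path=path,
            component_path=comp_path,
        )
        all_records.append(rec)

        child_counts: dict[str, int] = {}
        for child in elem:
            if not isinstance(child.tag, str):
                continue  # comments / PIs
            cname = etree.QName(child).localname
            cns = etree.QName(child).namespace
            if cname == "math" or cns == _MATHML_NS:
                rec.math = mathml_to_infix(child)
                continue
            if cname == "annotation":
                rec.annotation = etree.tostring(child, encoding="unicode")
                continue
            if cname == "notes":
                rec.notes = etree.tostring(child, encoding="unicode")
                continue
            rec.children.append(
                build(child, path, child_counts, child_comp_prefix, child_scope)
            )
        return rec

    sbml_path: tuple[tuple[str, int], ...] = (("sbml", 0),)
    model_rec = build(model_elems[0], sbml_path, {}, (), {})

    doc = DocumentModel(level=level, version=version, model=model_rec, all_records=all_records, warnings=warnings)

    # SId uniqueness within each kind: a validation warning, never a failure.
    seen: dict[tuple[str, str], int] = {}
    for rec in all_records:
        if rec.id is not None:
            key = (normalize_name(rec.kind), rec.id)
            seen[key] = seen.get(key, 0) + 1
    for (kind, sid), n in seen.items():
        if n > 1:
            warnings.append(f"duplicate id {sid!r} on {n} {kind} records")
    return doc


def component_catalog(doc: DocumentModel) -> ComponentCatalog:
    """Per-kind (package, count) plus observed attribute names.

    Attribute names are normalized; the pseudo-attributes ``math``,
    ``annotation`` and ``notes`` are included for records that carry
    those payloads, mirroring :func:`attribute_value`.
    """
    counts: dict[str, tuple[str, int]] = {}
    attrs: dict[str, set[str]] = {}
    for rec in doc.all_records:
        kind = normalize_name(rec.kind)
        pkg, n = counts.get(kind, (rec.package, 0))
        counts[kind] = (pkg, n + 1)
        bucket = attrs.setdefault(kind, set())
        for aname in rec.attributes:
            bucket.add(normalize_name(aname.split(":")[-1]))
        if rec.math is not None:
            bucket.add("math")
        if rec.annotation is not None:
            bucket.add("annotation")
        if rec.notes is not None:
            bucket.add("notes")
    return ComponentCatalog(
        counts=counts, attributes={k: frozenset(v) for k, v in attrs.items()}
    )


def attribute_value(record: ComponentRecord, property_name: str) -> Optional[Scalar]:
    """Look up an attribute by schema property name.

    Matching is by :func:`normalize_name` over the attribute's local
    name, core attributes first, then package-qualified ones.  The
    pseudo-names ``math``, ``annotation`` and ``notes`` return the
    formula string and raw XML payloads.  Absence is ``None``, never an
    error.
    """
    if not property_name:
        raise ValueError("property_name must be non-empty")
    want = normalize_name(property_name)
    core_hits = [
        v for k, v in record.attributes.items() if ":" not in k and normalize_name(k) == want
    ]
    if core_hits:
        return core_hits[0]
    qual_hits = [
        v
        for k, v in record.attributes.items()
        if ":" in k and normalize_name(k.split(":")[-1]) == want
    ]
    if qual_hits:
        return qual_hits[0]
    if want == "math":
        return record.math
    if want == "annotation":
        return record.annotation
    if want == "notes":
        return record.notes
    return None


def descendant_records(record: ComponentRecord) -> list[ComponentRecord]:
    """All records strictly beneath ``record``, pre-order."""
    out: list[ComponentRecord] = []
    stack = list(reversed(record.children))
    while stack:
        rec = stack.pop()
        out.append(rec)
        stack.extend(reversed(rec.children))
    return out
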