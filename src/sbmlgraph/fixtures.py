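"""Synthetic SBML fixtures with computable ground truth.

Real genome-scale models are megabyte downloads; tests need small,
deterministic documents whose correct graph is knowable by construction.
:func:`generate_model` emits a valid SBML Level 3 Version 2 document —
compartments, species assigned round-robin, reactions with seeded
pseudo-random participants, optionally decorated with the fbc, groups,
layout and qual packages, kinetic laws, and id-less components — as a
pure function of a :class:`FixtureSpec` (identical specs give identical
bytes).

:func:`ground_truth` is the independent oracle: a deliberately naive
second implementation of the extraction rules as a plain XML scan over
``xml.etree.ElementTree``, sharing no code with the mapper.  Its
normalization, strategy ladder and tie-breaks are re-stated here from
scratch so that agreement between mapper and oracle is evidence, not
tautology.

The module also bundles the canonical schema drawings used throughout
the tests (metabolic-network, genome-scale, pathway/SpeciesReference,
and one per supported package), as Arrows-export JSON text.
"""

from __future__ import annotations

import json
import random
import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass
from typing import Optional, Union

from lxml import etree

from .schema_model import SchemaGraph, load_schema

__all__ = [
    "FixtureSpec",
    "GroundTruth",
    "generate_model",
    "toy1_xml",
    "ground_truth",
    "schema_metabolic",
    "schema_gem",
    "schema_pathway",
    "schema_groups",
    "schema_layout",
    "schema_qual",
]

_SBML_L3V2 = "http://www.sbml.org/sbml/level3/version2/core"
_FBC = "http://www.sbml.org/sbml/level3/version1/fbc/version2"
_GROUPS = "http://www.sbml.org/sbml/level3/version1/groups/version1"
_LAYOUT = "http://www.sbml.org/sbml/level3/version1/layout/version1"
_QUAL = "http://www.sbml.org/sbml/level3/version1/qual/version1"
_MATHML = "http://www.w3.org/1998/Math/MathML"


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic model; generation is a pure function of this."""

    n_compartments: int = 1
    n_species: int = 2
    n_reactions: int = 1
    n_reactants: int = 1
    n_products: int = 1
    packages: frozenset[str] = frozenset()
    include_idless: bool = False
    include_kinetics: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_compartments", "n_species", "n_reactions", "n_reactants", "n_products"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        unknown = set(self.packages) - {"fbc", "groups", "layout", "qual"}
        if unknown:
            raise ValueError(f"unknown packages: {sorted(unknown)}")


@dataclass(frozen=True)
class GroundTruth:
    """Expected per-label node counts and per-type edge counts."""

    node_counts: dict[str, int]
    relationship_counts: dict[str, int]


def generate_model(spec: FixtureSpec) -> str:
    """Emit deterministic SBML L3V2 text realizing ``spec``."""
    rng = random.Random(spec.seed)
    nsmap = {None: _SBML_L3V2}
    root_attrs = {"level": "3", "version": "2"}
    for pkg, uri in (("fbc", _FBC), ("groups", _GROUPS), ("layout", _LAYOUT), ("qual", _QUAL)):
        if pkg in spec.packages:
            nsmap[pkg] = uri
            root_attrs[f"{{{uri}}}required"] = "false"

    E = lambda tag, parent=None, **attrs: (  # noqa: E731 - local element factory
        etree.SubElement(parent, f"{{{_SBML_L3V2}}}{tag}", **attrs)
        if parent is not None
        else None
    )

    root = etree.Element(f"{{{_SBML_L3V2}}}sbml", nsmap=nsmap, **root_attrs)
    model = E("model", root, id=f"toy_{spec.seed}", name=f"synthetic model seed {spec.seed}")
    if "fbc" in spec.packages:
        model.set(f"{{{_FBC}}}strict", "false")

    lud = E("listOfUnitDefinitions", model)
    ud = E("unitDefinition", lud, id="u_flux", name="flux unit")
    lu = E("listOfUnits", ud)
    E("unit", lu, kind="mole", exponent="1", scale="-3", multiplier="1")

    compartments = [f"c{i}" for i in range(spec.n_compartments)]
    if compartments:
        lc = E("listOfCompartments", model)
        for cid in compartments:
            E("compartment", lc, id=cid, name=f"{cid}_name", size="1",
              spatialDimensions="3", constant="true")

    species = [f"S{i}" for i in range(spec.n_species)]
    if species:
        ls = E("listOfSpecies", model)
        for i, sid in enumerate(species):
            attrs = {"id": sid, "name": f"{sid}_name",
                     "hasOnlySubstanceUnits": "false", "boundaryCondition": "false",
                     "constant": "false"}
            if compartments:
                attrs["compartment"] = compartments[i % len(compartments)]
            E("species", ls, **attrs)

    if "fbc" in spec.packages:
        lp = E("listOfParameters", model)
        E("parameter", lp, id="fb_lower", value="-1000", constant="true", units="u_flux")
        E("parameter", lp, id="fb_upper", value="1000", constant="true", units="u_flux")
        genes = [f"g{i}" for i in range(max(1, spec.n_reactions))]
        lgp = etree.SubElement(model, f"{{{_FBC}}}listOfGeneProducts")
        for gid in genes:
            etree.SubElement(
                lgp, f"{{{_FBC}}}geneProduct",
                {f"{{{_FBC}}}id": gid, f"{{{_FBC}}}label": f"{gid}_label"},
            )
    else:
        genes = []

    reactions = [f"R{i}" for i in range(spec.n_reactions)]
    if reactions:
        lr = E("listOfReactions", model)
        for rid in reactions:
            rattrs = {"id": rid, "name": f"{rid}_name", "reversible": "false"}
            if "fbc" in spec.packages:
                rattrs[f"{{{_FBC}}}lowerFluxBound"] = "fb_lower"
                rattrs[f"{{{_FBC}}}upperFluxBound"] = "fb_upper"
            rxn = E("reaction", lr, **rattrs)
            n_re = min(spec.n_reactants, len(species))
            reactants = rng.sample(species, n_re) if n_re else []
            rest = [s for s in species if s not in reactants] or species
            n_pr = min(spec.n_products, len(rest))
            products = rng.sample(rest, n_pr) if n_pr else []
            sr_no = 0
            if reactants:
                lre = E("listOfReactants", rxn)
                for sid in reactants:
                    attrs = {"species": sid, "stoichiometry": "1", "constant": "true"}
                    if not spec.include_idless:
                        attrs = {"id": f"sr_{rid}_{sr_no}", **attrs}
                    sr_no += 1
                    E("speciesReference", lre, **attrs)
            if products:
                lpr = E("listOfProducts", rxn)
                for sid in products:
                    attrs = {"species": sid, "stoichiometry": "1", "constant": "true"}
                    if not spec.include_idless:
                        attrs = {"id": f"sr_{rid}_{sr_no}", **attrs}
                    sr_no += 1
                    E("speciesReference", lpr, **attrs)
            if spec.include_kinetics:
                kl = E("kineticLaw", rxn)
                math = etree.SubElement(kl, f"{{{_MATHML}}}math")
                apply_ = etree.SubElement(math, f"{{{_MATHML}}}apply")
                etree.SubElement(apply_, f"{{{_MATHML}}}times")
                for name in (f"k_{rid}", reactants[0] if reactants else "1"):
                    ci = etree.SubElement(apply_, f"{{{_MATHML}}}ci")
                    ci.text = f" {name} "
                llp = E("listOfLocalParameters", kl)
                E("localParameter", llp, id=f"k_{rid}", value="0.1", units="u_flux")
            if "fbc" in spec.packages and genes:
                gpa = etree.SubElement(rxn, f"{{{_FBC}}}geneProductAssociation")
                etree.SubElement(
                    gpa, f"{{{_FBC}}}geneProductRef",
                    {f"{{{_FBC}}}geneProduct": rng.choice(genes)},
                )

    if "groups" in spec.packages and species:
        lg = etree.SubElement(model, f"{{{_GROUPS}}}listOfGroups")
        grp = etree.SubElement(
            lg, f"{{{_GROUPS}}}group",
            {f"{{{_GROUPS}}}id": "grp0", f"{{{_GROUPS}}}kind": "classification"},
        )
        lm = etree.SubElement(grp, f"{{{_GROUPS}}}listOfMembers")
        for sid in species[: min(2, len(species))]:
            etree.SubElement(lm, f"{{{_GROUPS}}}member", {f"{{{_GROUPS}}}idRef": sid})

    if "layout" in spec.packages:
        ll = etree.SubElement(model, f"{{{_LAYOUT}}}listOfLayouts")
        lay = etree.SubElement(ll, f"{{{_LAYOUT}}}layout", {f"{{{_LAYOUT}}}id": "lay0"})
        etree.SubElement(
            lay, f"{{{_LAYOUT}}}dimensions",
            {f"{{{_LAYOUT}}}id": "dim0", f"{{{_LAYOUT}}}width": "400",
             f"{{{_LAYOUT}}}height": "300"},
        )

    if "qual" in spec.packages:
        n_q = max(1, min(2, spec.n_species))
        lqs = etree.SubElement(model, f"{{{_QUAL}}}listOfQualitativeSpecies")
        qids = [f"q{i}" for i in range(n_q)]
        for qid in qids:
            attrs = {f"{{{_QUAL}}}id": qid, f"{{{_QUAL}}}constant": "false",
                     f"{{{_QUAL}}}maxLevel": "1"}
            if compartments:
                attrs[f"{{{_QUAL}}}compartment"] = compartments[0]
            etree.SubElement(lqs, f"{{{_QUAL}}}qualitativeSpecies", attrs)
        lt = etree.SubElement(model, f"{{{_QUAL}}}listOfTransitions")
        tr = etree.SubElement(lt, f"{{{_QUAL}}}transition", {f"{{{_QUAL}}}id": "tr0"})
        li = etree.SubElement(tr, f"{{{_QUAL}}}listOfInputs")
        etree.SubElement(
            li, f"{{{_QUAL}}}input",
            {f"{{{_QUAL}}}qualitativeSpecies": qids[0],
             f"{{{_QUAL}}}transitionEffect": "none"},
        )
        lo = etree.SubElement(tr, f"{{{_QUAL}}}listOfOutputs")
        etree.SubElement(
            lo, f"{{{_QUAL}}}output",
            {f"{{{_QUAL}}}qualitativeSpecies": qids[-1],
             f"{{{_QUAL}}}transitionEffect": "assignmentLevel"},
        )
        lft = etree.SubElement(tr, f"{{{_QUAL}}}listOfFunctionTerms")
        etree.SubElement(lft, f"{{{_QUAL}}}defaultTerm", {f"{{{_QUAL}}}resultLevel": "0"})

    if spec.include_idless:
        le = E("listOfEvents", model)
        ev = E("event", le, id="e0", useValuesFromTriggerTime="true")
        trg = E("trigger", ev, initialValue="false", persistent="true")
        tmath = etree.SubElement(trg, f"{{{_MATHML}}}math")
        etree.SubElement(tmath, f"{{{_MATHML}}}true")
        lea = E("listOfEventAssignments", ev)
        for sid in species[: min(2, len(species))]:
            ea = E("eventAssignment", lea, variable=sid)
            amath = etree.SubElement(ea, f"{{{_MATHML}}}math")
            cn = etree.SubElement(amath, f"{{{_MATHML}}}cn")
            cn.text = " 0 "

    return etree.tostring(
        root, pretty_print=True, xml_declaration=True, encoding="UTF-8"
    ).decode("utf-8")


def toy1_xml() -> str:
    """The canonical micro-model: 1 compartment, 2 species, 1 reaction."""
    return generate_model(FixtureSpec())


# -- canonical schemas -----------------------------------------------

def _arrows(nodes, rels) -> str:
    return json.dumps(
        {
            "nodes": [
                {
                    "id": key,
                    "position": {"x": 0, "y": 0},
                    "caption": "",
                    "labels": [label] if isinstance(label, str) else list(label),
                    "properties": {p: "" for p in props},
                    "style": {},
                }
                for key, label, props in nodes
            ],
            "relationships": [
                {
                    "id": f"r{i}",
                    "type": rtype,
                    "fromId": src,
                    "toId": tgt,
                    "properties": {},
                    "style": {},
                }
                for i, (src, rtype, tgt) in enumerate(rels)
            ],
        },
        indent=2,
    )


def schema_metabolic() -> str:
    """Metabolic-network drawing: Species, Reaction, Compartment."""
    return _arrows(
        [
            ("n_species", "Species", ["id", "name"]),
            ("n_reaction", "Reaction", ["id", "name", "reversible"]),
            ("n_compartment", "Compartment", ["id", "name"]),
        ],
        [
            ("n_species", "IN_COMPARTMENT", "n_compartment"),
            ("n_species", "IS_REACTANT", "n_reaction"),
            ("n_reaction", "HAS_PRODUCT", "n_species"),
        ],
    )


def schema_gem() -> str:
    """Genome-scale drawing: adds Model, Parameter, UnitDefinition, GeneProduct."""
    return _arrows(
        [
            ("n_model", "Model", ["id", "name"]),
            ("n_species", "Species", ["id", "name"]),
            ("n_reaction", "Reaction", ["id", "name", "reversible"]),
            ("n_compartment", "Compartment", ["id", "name"]),
            ("n_parameter", "Parameter", ["id", "value", "constant"]),
            ("n_unitdef", "UnitDefinition", ["id", "name"]),
            ("n_gene", "GeneProduct", ["id", "label"]),
        ],
        [
            ("n_species", "IN_COMPARTMENT", "n_compartment"),
            ("n_species", "IS_REACTANT", "n_reaction"),
            ("n_reaction", "HAS_PRODUCT", "n_species"),
            ("n_reaction", "HAS_LOWERFLUXBOUND", "n_parameter"),
            ("n_reaction", "HAS_UPPERFLUXBOUND", "n_parameter"),
            ("n_model", "HAS_PARAMETER", "n_parameter"),
            ("n_parameter", "HAS_UNIT", "n_unitdef"),
            ("n_gene", "IS_IMPLIED", "n_reaction"),
        ],
    )


def schema_pathway() -> str:
    """Pathway-enumeration drawing: Species, SpeciesReference, Reaction."""
    return _arrows(
        [
            ("n_species", "Species", ["id", "name", "compartment"]),
            ("n_sref", "SpeciesReference", ["id", "species", "stoichiometry"]),
            ("n_reaction", "Reaction", ["id", "name"]),
        ],
        [
            ("n_reaction", "HAS_REACTANT", "n_sref"),
            ("n_reaction", "HAS_PRODUCT", "n_sref"),
            ("n_sref", "HAS_SPECIES", "n_species"),
        ],
    )


def schema_groups() -> str:
    return _arrows(
        [
            ("n_group", "Group", ["id", "kind"]),
            ("n_species", "Species", ["id", "name"]),
        ],
        [("n_group", "HAS_MEMBER", "n_species")],
    )


def schema_layout() -> str:
    return _arrows(
        [
            ("n_layout", "Layout", ["id"]),
            ("n_dim", "Dimensions", ["id", "width", "height"]),
        ],
        [("n_layout", "HAS_DIMENSIONS", "n_dim")],
    )


def schema_qual() -> str:
    return _arrows(
        [
            ("n_qs", "QualitativeSpecies", ["id", "maxLevel"]),
            ("n_tr", "Transition", ["id"]),
            ("n_compartment", "Compartment", ["id", "name"]),
        ],
        [
            ("n_qs", "IN_COMPARTMENT", "n_compartment"),
            ("n_tr", "HAS_INPUT", "n_qs"),
            ("n_tr", "HAS_OUTPUT", "n_qs"),
        ],
    )


# -- the independent oracle ------------------------------------------
#
# Everything below re-implements the extraction rules as a flat scan
# over xml.etree.ElementTree, with its own normalization helpers.  It
# intentionally shares no code with schema_model/sbml_document/
# graph_mapper.

_O_SPLIT = re.compile(r"[^0-9A-Za-z]+|(?<=[a-z0-9])(?=[A-Z])")


def _o_norm(name: str) -> str:
    return re.sub(r"[^0-9a-z]", "", name.lower())


def _o_verbstrip(name: str) -> str:
    toks = [t for t in _O_SPLIT.split(name) if t]
    while len(toks) > 1 and toks[0].lower() in ("has", "is", "in"):
        toks = toks[1:]
    return "".join(toks)


def _o_sing(name: str) -> str:
    return name[:-1] if name.endswith("s") else name


def _o_local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _o_attrs(elem) -> list[tuple[str, str]]:
    return [(_o_local(k), v) for k, v in elem.attrib.items()]


def _o_id(elem) -> Optional[str]:
    for k, v in _o_attrs(elem):
        if k == "id":
            return v
    return None


def ground_truth(xml_text: str, schema: Union[SchemaGraph, str]) -> GroundTruth:
    """Expected (label → nodes, type → edges) for a (document, schema) pair.

    Computed by direct XML scanning: kind counts by element local name,
    relationship counts by replaying the attribute/container/descendant
    reference rules — including the most-specific-first tie-break and
    the reverse pass — over raw elements.
    """
    if isinstance(schema, str):
        schema = load_schema(schema)
    root = ET.fromstring(xml_text)
    model = next(c for c in root if _o_local(c.tag) == "model")

    # collect "record" elements: everything under model except math/
    # annotation/notes subtrees
    records: list = []
    children_of: dict[int, list] = {}

    def collect(elem):
        records.append(elem)
        kids = []
        for child in elem:
            lname = _o_local(child.tag)
            ns = child.tag[1:].split("}")[0] if child.tag.startswith("{") else ""
            if lname in ("annotation", "notes") or lname == "math" or ns == _MATHML:
                continue
            kids.append(child)
            collect(child)
        children_of[id(elem)] = kids

    collect(model)

    def rec_descendants(elem):
        out = []
        stack = list(reversed(children_of[id(elem)]))
        while stack:
            e = stack.pop()
            out.append(e)
            stack.extend(reversed(children_of[id(e)]))
        return out

    by_kind: dict[str, list] = {}
    for e in records:
        by_kind.setdefault(_o_norm(_o_local(e.tag)), []).append(e)
    id_map: dict[tuple[str, str], object] = {}
    for e in records:
        eid = _o_id(e)
        if eid is not None:
            id_map.setdefault((_o_norm(_o_local(e.tag)), eid), e)

    # zero-count labels are omitted, matching stats over an actual graph
    node_counts = {
        n.primary_label: len(by_kind[_o_norm(n.primary_label)])
        for n in schema.nodes
        if by_kind.get(_o_norm(n.primary_label))
    }

    def ladder(elem, rel_type: str, other_label: str) -> list:
        """Resolve targets of kind other_label from elem; returns elements."""
        want_other = _o_norm(other_label)
        # 1. target-name (a dangling hit yields nothing; the ladder goes on)
        for k, v in _o_attrs(elem):
            if _o_norm(k) == want_other:
                hit = id_map.get((want_other, v))
                if hit is not None:
                    return [hit]
                break
        # 2. relationship-name
        want_rel = _o_norm(_o_verbstrip(rel_type))
        for k, v in _o_attrs(elem):
            if _o_sing(_o_norm(k)) == _o_sing(want_rel):
                hit = id_map.get((want_other, v))
                if hit is not None:
                    return [hit]
                break  # dangling scalar: strategy 2 yields nothing
        else:
            found = []
            for child in children_of[id(elem)]:
                cname = _o_local(child.tag)
                if not cname.startswith("listOf"):
                    continue
                if _o_sing(_o_norm(cname[len("listOf"):])) != _o_sing(want_rel):
                    continue
                for member in children_of[id(child)]:
                    if _o_norm(_o_local(member.tag)) == want_other:
                        found.append(member)
                        continue
                    for k, v in _o_attrs(member):
                        if _o_norm(k) == want_other:
                            hit = id_map.get((want_other, v))
                            if hit is not None and hit not in found:
                                found.append(hit)
                            break
            if found:
                return found
        # 3. containment
        desc = rec_descendants(elem)
        direct = [
            e
            for e in desc
            if _o_norm(_o_local(e.tag)) == want_other
            and (not _o_local(e.tag).startswith("listOf") or want_other.startswith("listof"))
        ]
        if direct:
            return direct
        seen, out = set(), []
        for e in desc:
            for _, v in _o_attrs(e):
                hit = id_map.get((want_other, v))
                if hit is not None and id(hit) not in seen:
                    seen.add(id(hit))
                    out.append(hit)
        return out

    rel_counts: dict[str, int] = {}
    for srel in schema.relationships:
        src_kind = _o_norm(srel.source_label)
        tgt_kind = _o_norm(srel.target_label)
        pairs: set[tuple[int, int]] = set()
        for s in by_kind.get(src_kind, []):
            for t in ladder(s, srel.type, srel.target_label):
                pairs.add((id(s), id(t)))
        if not pairs:
            for t in by_kind.get(tgt_kind, []):
                for s in ladder(t, srel.type, srel.source_label):
                    pairs.add((id(s), id(t)))
        if pairs:
            rel_counts[srel.type] = rel_counts.get(srel.type, 0) + len(pairs)
    return GroundTruth(node_counts=node_counts, relationship_counts=rel_counts)
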