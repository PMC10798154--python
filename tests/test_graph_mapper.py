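"""Introspective mapping: node extraction, the three resolution strategies,
direction, tags, determinism."""

import pytest

from sbmlgraph.errors import ConfigurationError
from sbmlgraph.fixtures import (
    FixtureSpec,
    generate_model,
    ground_truth,
    schema_metabolic,
    toy1_xml,
)
from sbmlgraph.graph_mapper import (
    extract_nodes,
    map_document,
    map_document_detailed,
    resolve_by_containment,
    resolve_by_relationship_name,
    resolve_by_target_name,
    resolve_relationship,
    surrogate_key,
)
from sbmlgraph.property_graph import graph_stats
from sbmlgraph.schema_model import SchemaGraph, SchemaNode, SchemaRelationship, load_schema
from sbmlgraph.sbml_document import component_catalog, parse_document


def _schema(nodes, rels):
    return SchemaGraph(
        nodes=tuple(
            SchemaNode(key=k, labels=(lab,) if isinstance(lab, str) else tuple(lab),
                       properties={p: None for p in props})
            for k, lab, props in nodes
        ),
        relationships=tuple(
            SchemaRelationship(type=t, source_key=s, target_key=d) for s, t, d in rels
        ),
    )


class TestSurrogateKey:
    def test_event_assignment_dialect(self):
        doc = parse_document(generate_model(FixtureSpec(include_idless=True)))
        ea = doc.kind_index["eventassignment"][0]
        assert surrogate_key(ea) == "event[0]/eventAssignment[0]"

    def test_sibling_species_references_distinct(self):
        doc = parse_document(generate_model(FixtureSpec(include_idless=True)))
        keys = [surrogate_key(r) for r in doc.kind_index["speciesreference"]]
        assert len(set(keys)) == len(keys)

    def test_stable_across_reparses(self):
        xml = generate_model(FixtureSpec(include_idless=True, n_reactions=2, n_species=3))
        first = [surrogate_key(r) for r in parse_document(xml).all_records if r.id is None]
        second = [surrogate_key(r) for r in parse_document(xml).all_records if r.id is None]
        assert first == second


class TestExtractNodes:
    def test_toy_counts(self, toy1_doc, metabolic_schema):
        nodes = extract_nodes(toy1_doc, metabolic_schema, "t")
        by_label = {}
        for n in nodes:
            by_label[n.key.primary_label] = by_label.get(n.key.primary_label, 0) + 1
        assert by_label == {"Species": 2, "Reaction": 1, "Compartment": 1}

    def test_empty_schema_extracts_nothing(self, toy1_doc):
        assert extract_nodes(toy1_doc, _schema([], []), "t") == []

    def test_node_count_equals_catalog_count(self, fbc_doc, gem_schema):
        nodes = extract_nodes(fbc_doc, gem_schema, "t")
        catalog = component_catalog(fbc_doc)
        from sbmlgraph.schema_model import normalize_name

        for snode in gem_schema.nodes:
            kind = normalize_name(snode.primary_label)
            expected = catalog.counts.get(kind, (None, 0))[1]
            got = sum(1 for n in nodes if n.key.primary_label == snode.primary_label)
            assert got == expected

    def test_schema_properties_copied_absent_omitted(self, toy1_doc, metabolic_schema):
        species = [
            n for n in extract_nodes(toy1_doc, metabolic_schema, "t")
            if n.key.primary_label == "Species"
        ]
        for node in species:
            assert node.properties["name"].endswith("_name")
            assert node.properties["tag"] == "t"

    def test_extra_labels_carried(self, toy1_doc):
        schema = _schema([("a", ("Species", "Metabolite"), ["id"])], [])
        nodes = extract_nodes(toy1_doc, schema, "t")
        assert all(n.labels == ("Species", "Metabolite") for n in nodes)

    def test_empty_tag_rejected(self, toy1_doc, metabolic_schema):
        with pytest.raises(ConfigurationError):
            extract_nodes(toy1_doc, metabolic_schema, "")


class TestStrategies:
    def test_target_name_species_to_compartment(self, toy1_doc):
        species = toy1_doc.kind_index["species"][0]
        assert resolve_by_target_name(species, "Compartment", toy1_doc) == ["c0"]

    def test_target_name_absent_attribute(self, toy1_doc):
        rxn = toy1_doc.kind_index["reaction"][0]
        assert resolve_by_target_name(rxn, "Compartment", toy1_doc) == []

    def test_target_name_dangling_warns(self):
        xml = toy1_xml().replace('compartment="c0"', 'compartment="zz"')
        doc = parse_document(xml)
        warnings = []
        out = resolve_by_target_name(doc.kind_index["species"][0], "Compartment", doc, warnings)
        assert out == [] and any("zz" in w for w in warnings)

    def test_relationship_name_scalar_units(self):
        doc = parse_document(generate_model(FixtureSpec(include_kinetics=True)))
        lp = doc.kind_index["localparameter"][0]
        out = resolve_by_relationship_name(lp, "HAS_UNITS", "UnitDefinition", doc)
        assert out == ["u_flux"]

    def test_relationship_name_collection_products(self, toy1_doc):
        rxn = toy1_doc.kind_index["reaction"][0]
        out = resolve_by_relationship_name(rxn, "HAS_PRODUCT", "Species", toy1_doc)
        # oracle: scan listOfProducts/@species directly
        import xml.etree.ElementTree as ET

        root = ET.fromstring(toy1_xml())
        expected = [
            sr.get("species")
            for lp in root.iter()
            if lp.tag.endswith("listOfProducts")
            for sr in lp
        ]
        assert out == expected and len(out) == 1

    def test_relationship_name_no_match(self, toy1_doc):
        rxn = toy1_doc.kind_index["reaction"][0]
        assert resolve_by_relationship_name(rxn, "HAS_NOTHING", "Species", toy1_doc) == []

    def test_containment_direct_local_parameter(self):
        doc = parse_document(generate_model(FixtureSpec(include_kinetics=True)))
        rxn = doc.kind_index["reaction"][0]
        hits = resolve_by_containment(rxn, "LocalParameter", doc)
        assert [r.kind for r in hits] == ["localParameter"]

    def test_containment_empty_for_leaf(self, toy1_doc):
        sref = toy1_doc.kind_index["speciesreference"][0]
        assert resolve_by_containment(sref, "Species", toy1_doc) == []

    def test_containment_referential_gene_products(self, fbc_doc):
        rxn = fbc_doc.kind_index["reaction"][0]
        hits = resolve_by_containment(rxn, "GeneProduct", fbc_doc)
        assert len(hits) == 1 and hits[0].kind == "geneProduct"


class TestResolveRelationship:
    def test_toy_edge_counts(self, toy1_doc, metabolic_schema):
        result = map_document_detailed(toy1_doc, metabolic_schema, "t")
        stats = graph_stats(result.graph)
        assert stats.relationship_counts == {
            "IN_COMPARTMENT": 2,
            "IS_REACTANT": 1,
            "HAS_PRODUCT": 1,
        }

    def test_zero_instance_labels_give_strategy_none(self, toy1_doc):
        schema = _schema(
            [("a", "Event", ["id"]), ("b", "Delay", ["id"])],
            [("a", "HAS_DELAY", "b")],
        )
        result = map_document_detailed(toy1_doc, schema, "t")
        trace = result.traces[0]
        assert trace.strategy == "none" and trace.n_edges == 0

    def test_reverse_resolution_flagged(self, toy1_doc, metabolic_schema):
        result = map_document_detailed(toy1_doc, metabolic_schema, "t")
        by_type = {t.rel_type: t for t in result.traces}
        assert by_type["IS_REACTANT"].reversed is True
        assert by_type["IS_REACTANT"].strategy == "relationship-name"
        assert by_type["IN_COMPARTMENT"].reversed is False

    def test_direction_matches_drawing(self, fbc_doc, gem_schema):
        result = map_document_detailed(fbc_doc, gem_schema, "t")
        drawn = {
            r.type: (r.source_label, r.target_label) for r in gem_schema.relationships
        }
        for rel in result.graph.relationships():
            assert (rel.source.primary_label, rel.target.primary_label) == drawn[rel.type]

    def test_repeated_reference_collapses_to_one_edge(self):
        xml = toy1_xml().replace(
            '<speciesReference id="sr_R0_1" species="S0" stoichiometry="1" constant="true"/>',
            '<speciesReference id="sr_R0_1" species="S0" stoichiometry="1" constant="true"/>'
            '<speciesReference id="sr_R0_2" species="S0" stoichiometry="1" constant="true"/>',
        )
        doc = parse_document(xml)
        graph = map_document(doc, load_schema(schema_metabolic()), "t")
        assert graph_stats(graph).relationship_counts["HAS_PRODUCT"] == 1

    def test_unextracted_endpoint_is_config_error(self, toy1_doc, metabolic_schema):
        rel = next(r for r in metabolic_schema.relationships if r.type == "IN_COMPARTMENT")
        species_only = [
            n for n in extract_nodes(toy1_doc, metabolic_schema, "t")
            if n.key.primary_label == "Species"
        ]
        with pytest.raises(ConfigurationError):
            resolve_relationship(rel, toy1_doc, species_only, "t")


class TestMapDocument:
    def test_toy_totals(self, toy1_graph):
        stats = graph_stats(toy1_graph)
        assert stats.total_nodes == 4 and stats.total_relationships == 4

    def test_empty_schema_gives_empty_graph(self, toy1_doc):
        graph = map_document(toy1_doc, _schema([], []), "t")
        assert len(graph) == 0 and graph.relationships() == []

    def test_matches_ground_truth(self, fbc_doc, gem_schema):
        from sbmlgraph.fixtures import schema_gem

        xml = generate_model(
            FixtureSpec(n_compartments=2, n_species=5, n_reactions=3, n_reactants=2,
                        n_products=2, packages=frozenset({"fbc"}),
                        include_kinetics=True, seed=7)
        )
        stats = graph_stats(map_document(fbc_doc, gem_schema, "t"))
        truth = ground_truth(xml, schema_gem())
        assert stats.node_counts == truth.node_counts
        assert stats.relationship_counts == truth.relationship_counts

    def test_tag_isolation(self, toy1_doc, metabolic_schema):
        ga = map_document(toy1_doc, metabolic_schema, "A")
        gb = map_document(toy1_doc, metabolic_schema, "B")
        keys_a = {n.key for n in ga.nodes()}
        keys_b = {n.key for n in gb.nodes()}
        assert keys_a & keys_b == set()
        merged = ga.copy().merge(gb)
        for rel in merged.relationships():
            assert rel.source.tag == rel.target.tag

    def test_determinism(self, toy1, metabolic_schema):
        ra = map_document_detailed(parse_document(toy1), metabolic_schema, "t")
        rb = map_document_detailed(parse_document(toy1), metabolic_schema, "t")
        assert ra.graph == rb.graph
        assert [
            (t.rel_type, t.strategy, t.reversed, t.counts, t.n_edges) for t in ra.traces
        ] == [(t.rel_type, t.strategy, t.reversed, t.counts, t.n_edges) for t in rb.traces]
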