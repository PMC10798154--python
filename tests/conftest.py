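import pytest

from sbmlgraph import load_schema, map_document, parse_document
from sbmlgraph.fixtures import (
    FixtureSpec,
    generate_model,
    schema_gem,
    schema_metabolic,
    schema_pathway,
    toy1_xml,
)


@pytest.fixture(scope="session")
def toy1():
    return toy1_xml()


@pytest.fixture(scope="session")
def toy1_doc(toy1):
    return parse_document(toy1)


@pytest.fixture(scope="session")
def metabolic_schema():
    return load_schema(schema_metabolic())


@pytest.fixture(scope="session")
def gem_schema():
    return load_schema(schema_gem())


@pytest.fixture(scope="session")
def pathway_schema():
    return load_schema(schema_pathway())


@pytest.fixture()
def toy1_graph(toy1_doc, metabolic_schema):
    return map_document(toy1_doc, metabolic_schema, "toy")


@pytest.fixture(scope="session")
def fbc_doc():
    xml = generate_model(
        FixtureSpec(
            n_compartments=2,
            n_species=5,
            n_reactions=3,
            n_reactants=2,
            n_products=2,
            packages=frozenset({"fbc"}),
            include_kinetics=True,
            seed=7,
        )
    )
    return parse_document(xml)
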