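# sbmlgraph

Schema-driven import of SBML models into a labeled property graph, with
idempotent Cypher emission for Neo4j.

Systems-biology models — in particular genome-scale metabolic models
(GEMs) such as the *E. coli* reconstructions iAF1260, iML1515 and
e_coli_core — are exchanged as SBML: a deep XML tree of typed components
(species, reactions, compartments, parameters, gene products, ...) whose
interactions are exactly the kind of richly connected data a graph
database handles well. `sbmlgraph` bridges the two worlds for modellers
who want to explore their own models with Cypher: the user *draws* the
part of the model they care about as a small labeled graph (in the
[Arrows](https://arrows.app) web app, exported as JSON), and the
importer extracts precisely those components and relationships into a
property graph that can be loaded into Neo4j, exported to JSON/GraphML,
or analyzed in memory.

## How it works

The drawn schema follows one convention: a node's first label names an
SBML component kind (`Species`, `Reaction`, `UnitDefinition`,
`GeneProduct`, ...) and its properties name attributes of that
component; matching is case- and punctuation-insensitive. Every
document instance of a selected kind becomes one graph node. Each drawn
arrow (e.g. `Species -IN_COMPARTMENT-> Compartment`) is resolved by
introspection of the parsed components, trying three strategies in
most-specific-first order for each instance:

1. **target-name** — the source carries an attribute named after the
   target label holding a target id (`species.compartment` → the
   `Compartment` with that id);
2. **relationship-name** — the arrow's type, minus a leading
   `HAS`/`IS`/`IN` verb, names an attribute (`HAS_UNITS` → `units`) or a
   `listOf*` child container (`HAS_PRODUCT` → `listOfProducts`) on the
   source;
3. **containment** — targets are nested beneath the source
   (`Reaction` → `LocalParameter` inside its `kineticLaw`), or are
   referenced by a nested element's attribute (`Reaction` →
   `GeneProduct` through `geneProductRef`).

If the drawn direction resolves nothing, the same ladder runs from the
target side (a reactant species stores no pointer to its reaction — the
reaction's `listOfReactants` does); edges are always emitted in the
drawn direction. Every imported node carries an import *tag*, so
several models coexist in one database without cross-linking, and the
emitted Cypher `MERGE`s on `{id, tag}` — replaying a load script is a
no-op.

Core SBML Level 2 Version 5 and Level 3 Version 2 are supported, plus
the fbc, groups, layout and qual Level 3 packages. Mathematical
expressions are flattened to infix strings; annotations and notes are
carried as raw XML text.

## Worked example

```python
from sbmlgraph import (
    graph_stats, load_schema, map_document, parse_document, to_cypher,
)
from sbmlgraph.fixtures import schema_metabolic, toy1_xml

doc = parse_document(toy1_xml())          # 1 compartment, 2 species, 1 reaction
schema = load_schema(schema_metabolic())  # Species / Reaction / Compartment drawing
graph = map_document(doc, schema, tag="toy")

stats = graph_stats(graph)
print(stats.node_counts)
print(stats.relationship_counts)
print(len(to_cypher(graph).statements), "Cypher statements")
```

prints

```
{'Species': 2, 'Reaction': 1, 'Compartment': 1}
{'IN_COMPARTMENT': 2, 'IS_REACTANT': 1, 'HAS_PRODUCT': 1}
6 Cypher statements
```

Both species link to their compartment by the target-name strategy; the
reaction's product edge comes from its `listOfProducts`; the reactant
edge is resolved from the reaction side but emitted
`Species -IS_REACTANT-> Reaction` as drawn. The six statements are one
batched `MERGE` per node label and per relationship type.

The same pipeline from the shell:

```sh
sbmlgraph stats  --input model.xml --schema schema.json
sbmlgraph import --input model.xml --schema schema.json --dry-run out.cypher
sbmlgraph import --input model.xml --schema schema.json \
    --uri bolt://localhost:7687 --user neo4j --password-env NEO4J_PASSWORD
sbmlgraph export --input model.xml --schema schema.json --output graph.json
sbmlgraph ops producers --graph graph.json --target PEP --compartment e --n-reactions 2
```

`ops` also offers `neighborhood` (metabolite surroundings), `flag-dense`
(mark hub metabolites), `contract` (merge SpeciesReference stubs onto
their Species) and `prune` (drop species below a reaction-degree
threshold) — the usual refactoring steps before pathway analysis.

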