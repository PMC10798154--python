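# Methods

This note records how `sbmlgraph` maps SBML onto a labeled property
graph: the procedure, the conventions and tie-breaks it fixes where the
problem is genuinely open, what the synthetic fixtures do and do not
emulate, and known limitations.

## The extraction model

An SBML document is parsed (with `lxml`) into a uniform tree of
*component records*: every element beneath `<sbml>` — `listOf*`
containers included, since a schema may target them — becomes a record
exposing its kind (the element's local name), its package (`core`,
`fbc`, `groups`, `layout`, `qual`, or a prefix-derived label for
unrecognized namespaces), its attributes, and a document path that is
unique and stable across parses. `math`, `annotation` and `notes`
subtrees do not become records; they are captured on the parent record
as an infix formula string and raw XML text, retrievable through the
pseudo-attribute names `math`, `annotation` and `notes`.

Extraction is driven by a drawn schema (Arrows export). Node selection
is pure name matching; relationship resolution is introspective, per
source instance, in a fixed most-specific-first order:
**target-name** (an attribute named after the target label holding a
target id), then **relationship-name** (the arrow type, verb-stripped,
naming an attribute or a direct `listOf*` child), then **containment**
(targets nested beneath the source; failing that, targets referenced by
any attribute of any nested element). The first strategy returning a
non-empty result wins. The precedence runs from precise attribute
references down to structural proximity so that containment can never
shadow an explicit reference; it also keeps diagram-layout components
from over-linking (a `Layout` connects only to the `Dimensions` nested
inside it, never to every `Dimensions` in the document).

Two refinements proved necessary for real schema idioms:

- **Reverse resolution.** SBML stores most references on the container
  side: a reactant species holds no pointer to its reaction — the
  reaction's `listOfReactants` holds the pointer. When a drawn
  relationship (e.g. `Species -IS_REACTANT-> Reaction`) yields no edges
  in the drawn direction, the same strategy ladder is retried from the
  target side, and edges are still emitted as drawn. The
  `ResolutionTrace` records the firing strategy and a `reversed` flag.
- **Container members as targets.** In the relationship-name strategy,
  if the members of the matching `listOf*` container are themselves of
  the target kind (`Reaction -HAS_REACTANT-> SpeciesReference` via
  `listOfReactants`), they are the targets directly; otherwise the
  member's attribute named after the target label supplies the
  reference (`Reaction -HAS_PRODUCT-> Species` via
  `listOfProducts/speciesReference/@species`). Without the first case,
  containment would take over and collect reactant *and* product
  references indiscriminately.

### Naming conventions

All label↔kind, property↔attribute and relationship↔accessor
comparisons go through one canonical form: lower-case, non-alphanumeric
characters removed. Relationship types additionally drop leading
`HAS`/`IS`/`IN` verb tokens (`IN_COMPARTMENT` → `compartment`,
`HAS_UNITS` → `units`), and container matching ignores one trailing
`s` (`HAS_PRODUCT` ↔ `listOfProducts`). This is deliberately more
permissive than exact matching: it reproduces every conventional
pairing (upper-snake relationship types against lowerCamel SBML
accessors) without a hard-coded correspondence table. The cost is that
a schema cannot distinguish two names differing only in case or
punctuation — which SBML's own naming rules make a non-issue.

### Identity, tags and merge semantics

A graph node's identity is the triple (primary label, local id, import
tag). The local id is the component's SBML id; components without one
(SpeciesReference in many models, EventAssignment always) get a
deterministic path-derived surrogate such as
`event[0]/eventAssignment[0]`, in which structural wrappers are
transparent and ordinals count same-kind components under the nearest
real ancestor — so the first reactant and the first product of a
reaction stay distinct. The tag (defaulting to the model id, else the
input filename stem) keeps sequentially imported models disjoint: node
key sets under different tags never intersect and no resolution step
can produce a cross-tag edge.

Merging follows Cypher `MERGE … SET` semantics both in memory and in
the emitted script: insert on a missing key, otherwise union properties
with incoming values winning (each overwrite of a differing value is
logged). Edges are de-duplicated on (type, source key, target key); a
species appearing twice among a reaction's products yields one edge.
Dangling references — attributes pointing at ids that do not exist —
are dropped with warnings, never errors, because published GEMs contain
them and an importer's job is faithful extraction.

## Cypher emission

`to_cypher` produces batched, parameterized `UNWIND … MERGE` statements
(default batch size 1000, a conventional bulk-load size): node
statements grouped per label set, then relationship statements grouped
per (type, endpoint labels), all rows sorted so the script is
bit-stable for a given graph. Data travels only in parameters, never
interpolated into statement text. Nodes merge on `{id, tag}` under the
primary label — the minimal key realizing multi-model disambiguation —
so replaying a script is idempotent. Uniqueness constraints on
(id, tag) per label are available as an optional preamble.

Idempotence is verified without a database by `InMemoryStore`, a
minimal interpreter for exactly the three statement shapes the emitter
produces. It checks the *script text*, not shared in-memory objects, so
a regression in the emitted Cypher would be caught. Bit-compatibility
with any other tool's Cypher text is explicitly not a goal; idempotence
and count-equivalence are the contract. JSON and GraphML exports are
lossless round-trips (`import(export(g)) == g` field-wise); GraphML
encodes labels and property maps as JSON-valued data fields to keep
typed scalars intact.

## Graph operations

The analysis operations assume the bipartite Species/Reaction shape the
metabolic schema produces and are all non-mutating:

- `species_neighborhood(graph, name, radius)` — induced subgraph within
  `radius` undirected hops of every species with that exact `name`
  property; monotone in `radius`.
- `flag_dense_nodes(graph, label, threshold)` — sets `dense=true` on
  labeled nodes with degree ≥ threshold (the usual prelude to excluding
  currency metabolites from path queries).
- `producers_at_distance(graph, target, compartment, n)` — all simple
  (node-disjoint, hence acyclic) paths from a species in the named
  compartment to the target species traversing exactly `n` reactions,
  following reactant→reaction→product orientation;
  `respect_direction=False` accommodates schemas drawn the other way.
  Path enumeration delegates to `networkx.all_simple_paths`; tests
  check it against an independent hand-written DFS enumeration.
- `contract_species_references(graph)` — removes SpeciesReference
  stubs, re-attaching their edges to the Species named by their
  `species` property; conserves Species and Reaction counts and never
  increases the edge count.
- `prune_species_by_degree(graph, min_reactions)` — deletes species
  adjacent to fewer than `min_reactions` *distinct* reactions (distinct
  neighbors, not edge multiplicity), decided on the input graph in a
  single pass with no cascade; a cascade would couple the result to
  deletion order.

## Synthetic fixtures and the ground-truth oracle

Tests run entirely on generated SBML. `FixtureSpec` defaults describe
the canonical micro-model used throughout (1 compartment, 2 species, 1
reaction with one reactant and one product); sweeps vary compartments
(1–3), species (2–6), reactions (1–4), participants (1–2 each side),
toggle the fbc package, kinetic laws and id-less components, and are
pure functions of a seed. Generated documents are accepted without
error by a reference SBML validator for core and all four packages.
These sizes keep the whole suite under a few seconds while exercising
every resolution strategy, both resolution directions, surrogate keys
and package-qualified attributes; what they deliberately do not emulate
is the *scale* of real GEMs (thousands of species) or their messiness —
RDF annotation bodies, dangling references, non-standard id schemes —
beyond targeted negative fixtures. Passing tests therefore demonstrate
correctness of the extraction rules, not performance at genome scale,
although nothing in the pipeline is worse than linear in document size
plus quadratic in the rare containment fallback.

The central test property is oracle equivalence: for every (fixture,
schema) pair, `graph_stats(map_document(...))` must equal
`ground_truth(...)` exactly — node counts per label and edge counts per
type. The oracle is a deliberately naive second implementation of the
extraction rules: a flat scan over `xml.etree.ElementTree` with its own
normalization and ladder code, sharing nothing with the mapper but the
schema data class. Agreement is evidence against implementation slips,
not against a misreading of the rules themselves — which is why the
strategy micro-cases are additionally asserted one by one on their
traces.

## Numerical and degenerate-input choices

- Attribute values are strings except those the SBML specifications
  declare numeric or boolean (`stoichiometry`, `size`, `value`,
  `constant`, `reversible`, ...), which are coerced; unparseable
  declared-numeric values stay strings with a warning rather than
  failing an import.
- Math serialization uses a fixed infix dialect — single spaces around
  binary operators, minimal parentheses by precedence, `power` printed
  as `^`, functions as calls — so outputs are reproducible byte for
  byte.
- Empty schemas, empty models, zero-instance labels, unknown species
  names and unknown compartments are all empty-result cases, never
  errors; schema/document mismatches surface as diagnostics (warnings)
  unless `--strict` is set.
- Id uniqueness violations within a kind are warnings; the first record
  wins reference resolution.

## Known limitations

- Live database loading requires the optional Bolt driver and is
  exercised only through its dry-run path and the in-memory
  interpreter; the driver code path follows the same script and
  transaction-per-batch contract but is not covered by the test suite.
- Annotations are carried as raw XML text; RDF/CV terms are not parsed
  into structured properties.
- Relationship properties are taken from the source component's
  attributes; properties living on the target side would need the
  relationship drawn in the other direction.
- One edge is created per (source, target) pair and type; occurrence
  multiplicity (a species consumed twice by one reaction) survives only
  in `stoichiometry`-style properties, not as parallel edges.
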