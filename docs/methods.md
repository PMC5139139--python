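# Methods

## Data model

`sbgraph` works on two representations. An `SbgnMap` is a lossless
in-memory form of an SBGN-ML document: the language tag (`PD` or `AF`),
the glyph tree (nested to arbitrary depth, auxiliary units and ports
included) and the arc list. A `PropertyGraph` mirrors the labelled
property graph model of graph databases: nodes with one label and
string-valued properties, directed typed relationships with properties,
multi-edges allowed. Property values are strings or lists of strings
throughout — no numeric coercion — because every matching rule in the
linking procedures is string equality, and that is also how such values
behave in a graph database.

Reserved node properties: `Name` (the glyph label, whitespace-trimmed),
`NodeType` (the node's type as a matchable property), `StateVariable`
(sorted list of `value@variable` strings), `UnitOfInformation`,
`Compartment`, `Clone`, `Language` (`PD`/`AF`), and the provenance pair
`File` / `SbgnId`. Relationships carry `File`, `SbgnId` and optionally
`Cardinality`.

## Reading and writing SBGN-ML

The reader targets the LibSBGN milestone-2 dialect and tolerates
unknown extension elements rather than failing, so any milestone-2
valid document is in scope. Parsing preserves everything the
translator needs and nothing it does not: bounding boxes are kept but
never used in graph logic (the graph model carries no geometry), and
auxiliary units stay subglyphs at parse time — their reinterpretation
as properties happens in the translator, which keeps the reader
lossless and the write∘parse round trip an identity on structural
content. Arc-attached cardinality glyphs collapse to an integer field
on the arc, since they annotate the arc rather than denote a network
entity. Maps declaring the Entity Relationship language are rejected.
`validate_map` reports (never throws) on duplicate identifiers,
classes outside the language's inventory, and dangling arc or
compartment references.

## Translation rules

The rule table is total over the PD and AF class inventories: every
entity-pool, process and logic-operator class maps to a node label (the
SBGN class with spaces removed, e.g. `macromolecule multimer` →
`macromoleculemultimer`), and every arc class to a relationship type
formed the same way. The table is a reconstruction built from the
class inventories and the model's worked examples; the original
framework's class-by-class tables are not published in citable form, so
the mapping here is the package's own, chosen to be conservative
(unhandled constructs raise rather than silently drop).

Deliberate deviations from a 1:1 glyph→node mapping:

* **Complexes.** Each direct member of a complex yields one
  `belongs_to_complex` relationship, member → complex; nested complexes
  recurse (member → inner complex → outer complex). The direction
  (member as source) reads the membership as "is part of".
* **Auxiliary units.** State variables populate the parent node's
  `StateVariable` property as a lexicographically sorted list, so set
  equality is order-insensitive during matching; an empty state renders
  as `@`. Units of information populate `UnitOfInformation` (a single
  string when there is one unit, a sorted list otherwise).
* **AF `NodeType` promotion.** An AF biological activity is labelled
  `biologicalactivity`, but when its unit of information declares the
  underlying entity type (macromolecule, simple chemical, ...), that
  class — space-stripped — overrides the node's `NodeType` property.
  Without this promotion a PD macromolecule and its AF activity could
  never agree on `NodeType` and granularity linking would be
  unsatisfiable; the label field itself stays untouched.
* **Compartments.** Compartment glyphs produce no node; each node whose
  glyph referenced a compartment gets `Compartment` = that
  compartment's label. The linking rules match on a compartment
  *property*, and a compartment node would add hub edges that distort
  neighbourhood extraction.
* **Clone markers** become `Clone="true"`; cloned pools remain distinct
  nodes, as SBGN clones are visual duplicates and no fusion rule is
  defined for them.
* **Submaps and tags** translate to nodes of label `submap`/`tag` with
  their arcs kept as-is; no expansion is attempted.

Arc direction follows the SBGN-ML source→target orientation exactly
(consumption: entity→process; production: process→entity), with
endpoints resolved through ports to the owning glyph. An arc endpoint
resolving to an auxiliary unit or a compartment is a translation error.

Node ids are namespaced by the source map name (`<file>::<glyph id>`),
which makes multi-map merging a disjoint union: counts add, provenance
unions, and no deduplication ever happens — cross-map identity is
expressed only by explicit link relationships.

## Analyses

**Neighbourhood extraction** matches nodes by exact `Name` equality and
runs a breadth-first search treating relationships as undirected,
returning the induced subgraph of everything within the requested
depth. Depth 0 returns only the matched nodes; a missing name returns
an empty graph, not an error.

**Granularity linking** considers every cross-file PD×AF node pair and
creates one `equivalent_to` relationship when `Name`, `NodeType`,
`Compartment` and `UnitOfInformation` all agree, where a property
absent on one node matches only its absence on the other. Both nodes
must carry a `Name`: process and logic nodes are unnamed, and linking
two anonymous logic operators on type alone would be meaningless.
`StateVariable` deliberately does not participate, so a detailed map's
phosphorylated and unphosphorylated pools both link to the single
activity that abstracts them. All qualifying pairs are linked — no
greedy 1:1 assignment.

**Identical-process linking** compares process nodes from different PD
files by their one-hop environment, encoded as a multiset of
`(relationship type, direction, neighbour signature)` triples with the
neighbour signature being the tuple (`NodeType`, `Name`,
`UnitOfInformation`, `StateVariable`, `Compartment`). Two processes
link iff the multisets are equal. Three readings were genuinely open
and were fixed as follows: the environment is compared as a *multiset*
(stoichiometric duplicates count — the strictest reading, preventing
false merges), relationship *direction* is part of the element (a
consumption into a process differs from a production out of it), and
`belongs_to_complex` edges participate like any other relationship.
Link relationships themselves are excluded from signatures, which makes
both linking procedures idempotent; names are compared exactly
(case-sensitive) after trimming leading/trailing whitespace, removing
serialization artifacts without imposing a normalization the matching
rules never state. Fuzzy or ontology-assisted matching is out of
scope.

## Exporters

All exporters emit elements sorted by node/relationship id, so output
is deterministic and diffable. The Cypher script creates nodes with a
temporary per-export key property, wires relationships by matching on
it, and removes it at the end; executing the script in an empty
database reproduces the graph. CSV follows the common bulk-import
header dialect; list values join with `;`. JSON is lossless and has an
import counterpart used by the round-trip tests. A live database
connection is intentionally not part of the package — file exports
keep the toolchain testable offline.

## Synthetic data

The generators define the study conditions for every test:

* **Bricks** implement five minimal patterns (phosphorylation, complex
  association, dissociation, transcription, influence) with the state
  conventions of the field (substrate `@` → product `P@`;
  transcription driven by a `ct:gene` nucleic-acid feature through a
  necessary stimulation, with a source-and-sink input).
* **Random maps** are seed-deterministic, respect each language's
  grammar (consumption/production arcs alternate entity–process in PD;
  influences connect activities in AF; arcs never target complex
  members directly), and report their own ground-truth counts
  (entities including complex members, processes, arcs, membership
  pairs) from generation-time bookkeeping — the oracle for the central
  cross-module property: translated node count = entity + process +
  logic glyphs, relationship count = arcs + membership pairs.
* **The signalling scenario** reconstructs an interferon-gamma cascade
  (IFNG binds its receptor complex of IFNGR1/IFNGR2 dimers and
  JAK1/JAK2; the bound complex is phosphorylated; STAT1alpha is
  phosphorylated, dimerises, and drives IRF1 transcription) as a PD
  map, its AF abstraction, and a PD variant that differs only at the
  transcription step (gene regulatory region GAS vs gene IRF1). It is
  a synthetic reconstruction from the pathway's published description,
  not a copy of any distributed file, sized so the three analyses show
  their qualitative behaviour: equivalence links on IFNG, STAT1alpha
  and IRF1; process links on exactly the four shared upstream steps.

What the generators do not emulate: curated-map scale (hundreds of
glyphs with layout), annotation/ontology identifiers, submap
hierarchies, and the full breadth of rarely-used PD classes in random
maps (perturbing agents appear, tags and submaps only in hand-built
fixtures). Passing tests therefore demonstrate correctness of the
translation and matching *rules*, not robustness to every real-world
curation idiosyncrasy.

## Problem sizes and numerical choices

The test suite checks count conservation on 200 seeded random maps (up
to ~200 glyphs each) and oracle equivalence (breadth-first-search and
exhaustive-pair brute force) on instances up to a few hundred nodes;
these sizes give full code-path coverage with seconds-scale runtimes.
There is no floating-point numerics anywhere in the pipeline — bounding
boxes are parsed and re-emitted via exact `repr` round-tripping, and
all matching is string equality — so no tolerances apply.

## Known limitations

* The Entity Relationship language is not supported.
* XSD schema validation is not performed; validation is structural.
* Granularity linking requires a `Name` on both nodes, so unnamed
  activities can never link.
* Process matching is exact: a single differing state variable or
  compartment on any neighbour blocks a link, and semantically
  compatible but differently-labelled maps (generic vs specific protein
  names) will not link — judging such links is an open research
  question, left to the user.
* The rule table is a reconstruction (see above); where an authoritative
  class-by-class mapping differs, property names here may deviate.
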