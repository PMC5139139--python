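# sbgraph

SBGN pathway maps as labelled property graphs.

Biological pathway maps drawn in the Systems Biology Graphical Notation
(SBGN) are stored as SBGN-ML — an XML format that is easy to render but
hard to *query*: finding the neighbourhood of a gene, comparing a
detailed Process Description (PD) map with its Activity Flow (AF)
abstraction, or spotting processes shared by two maps all require graph
structure, not XML trees. `sbgraph` translates SBGN-ML PD and AF maps
into the labelled property graph model used by graph databases such as
Neo4j (nodes with labels and key–value properties, typed relationships)
and implements three analyses directly on that model:

1. **Named-entity subnetwork extraction** — breadth-first neighbourhood
   of every node with a given name, at a chosen depth.
2. **Granularity linking (PD ↔ AF)** — an `equivalent_to` relationship
   joins each cross-file PD/AF node pair that agrees on `Name`,
   `NodeType`, `Compartment` and `UnitOfInformation`.
3. **Identical-process linking (PD ↔ PD)** — an `identical_process`
   relationship joins process nodes from different maps whose one-hop
   environments coincide: same relationship effects and directions, and
   neighbours identical in `NodeType`, `Name`, `UnitOfInformation`,
   `StateVariable` and `Compartment` (compared as multisets).

The translation maps every entity pool, process and logic-operator
glyph to a node and every arc to a relationship, with two deliberate
exceptions: complex members attach to their complex via
`belongs_to_complex` relationships (member → complex, recursing through
nested complexes), and auxiliary units fold into node properties — a
state variable becomes an entry of the `StateVariable` list
(`value@variable`, e.g. `P@Ser15`), a unit of information becomes the
`UnitOfInformation` property, and on AF activities the unit's entity
type is promoted into `NodeType` so PD and AF nodes are comparable.
Compartments become a `Compartment` property rather than nodes.

Exporters serialize the resulting graph to a Cypher `CREATE` script,
bulk-import CSV tables (`:ID`/`:LABEL`/`:START_ID`/`:END_ID`/`:TYPE`
header dialect), GraphML and lossless JSON. A synthetic-map module
generates SBGN-brick-style fixtures (phosphorylation, complex
association, dissociation, transcription, influence patterns), seeded
random maps with ground-truth counts, and a reconstructed
interferon-gamma / iNOS-style signalling scenario used throughout the
tests. The Entity Relationship (ER) SBGN language is out of scope.

## Worked example

A receptor complex with four subunits — the dimerised receptor chains
IFNGR1 and IFNGR2 (macromolecule multimers carrying the `N:2` unit of
information) plus the kinases JAK1 and JAK2 — translates to five nodes
and four `belongs_to_complex` relationships:

```python
>>> import sbgraph as sg
>>> graph = sg.translate(sg.make_receptor_complex_map())
>>> graph.node_count(), graph.relationship_count()
(5, 4)
>>> node = graph.find_nodes(Name="IFNGR1")[0]
>>> node.label, node.properties["UnitOfInformation"]
('macromoleculemultimer', 'N:2')
```

Linking the PD signalling cascade against its AF abstraction, and
against a PD variant that regulates transcription through the gene
IRF1 instead of the regulatory region GAS:

```python
>>> pd_map, af_map, pd_variant = sg.make_inos_like_pair()
>>> merged = sg.merge_graphs([sg.translate(pd_map), sg.translate(af_map)])
>>> len(sg.link_granularity(merged))
4
>>> pair = sg.merge_graphs([sg.translate(pd_map), sg.translate(pd_variant)])
>>> links = sg.link_identical_processes(pair)
>>> sorted({pair.nodes[l.start].properties["SbgnId"] for l in links.links})
['p_bind', 'p_dim', 'p_phos', 'p_stat']
```

The four granularity links connect IFNG, IRF1 and STAT1alpha (twice:
unphosphorylated and phosphorylated pools) across the two levels of
detail; the four process links are exactly the shared upstream steps —
receptor binding, complex phosphorylation, STAT1alpha phosphorylation
and dimerisation — while the divergent transcription processes stay
unlinked.

The same pipeline is available from a shell:

```sh
sbgraph make-fixtures --out-dir fixtures --seed 1
sbgraph convert fixtures/receptor_complex.sbgn --format cypher --out graph.cypher
# -> 5 nodes, 4 relationships
sbgraph query fixtures/inos_pd.sbgn --name IFNG --depth 2
sbgraph link fixtures/inos_pd.sbgn fixtures/inos_af.sbgn --mode granularity
```

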