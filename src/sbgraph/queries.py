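"""Graph analyses: neighborhood extraction and cross-map linking.

Three operations, all working on merged property graphs produced by
:mod:`sbgraph.translate`:

* :func:`neighborhood` — extract the subnetwork around every node with a
  given name, out to a chosen depth (relationships traversed as
  undirected edges).
* :func:`link_granularity` — connect a detailed Process Description map
  to its Activity Flow abstraction: one ``equivalent_to`` relationship
  per cross-file PD/AF node pair agreeing on name, node type,
  compartment and unit of information.
* :func:`link_identical_processes` — connect identical process nodes
  between two Process Description maps: processes whose complete
  one-hop environments (relationship effect, direction, and the
  neighbor's name/type/state/compartment/unit signature) coincide get an
  ``identical_process`` relationship.

Both linking procedures are idempotent (re-running adds no duplicate
links) and link all qualifying pairs — a node may carry several links.
"""

from __future__ import annotations

from collections import Counter, deque
from dataclasses import dataclass, field

from .errors import ContractError
from .graph import GraphNode, GraphRelationship, PropertyGraph, subgraph
from .translate import PD_PROCESS_LABELS

EQUIVALENT_TO = "equivalent_to"
IDENTICAL_PROCESS = "identical_process"

#: Relationship types produced by linking; excluded from signatures so
#: linking is idempotent.
LINK_TYPES = frozenset({EQUIVALENT_TO, IDENTICAL_PROCESS})

#: Node properties compared by :func:`link_granularity`.
GRANULARITY_PROPERTIES = (
    "Name", "NodeType", "Compartment", "UnitOfInformation",
)

#: Neighbor-node properties entering a process signature in
#: :func:`link_identical_processes`.
PROCESS_PROPERTIES = (
    "NodeType", "Name", "UnitOfInformation", "StateVariable", "Compartment",
)


@dataclass
class LinkSet:
    """Cross-map relationships produced by a linking procedure, with the
    match evidence per link (matched property names, or matched neighbor
    signatures for process links)."""

    links: list[GraphRelationship] = field(default_factory=list)
    evidence: list[dict] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.links)

    def pairs(self) -> set[frozenset]:
        return {frozenset((l.start, l.end)) for l in self.links}


# ---------------------------------------------------------------------------
# neighborhood extraction
# ---------------------------------------------------------------------------

def neighborhood(graph: PropertyGraph, name: str,
                 depth: int = 2) -> PropertyGraph:
    """Induced subgraph around every node whose ``Name`` equals ``name``.

    Traversal is breadth-first over relationships treated as undirected,
    out to ``depth`` hops from any matched node.  ``depth=0`` returns
    only the matched nodes themselves.  An absent name yields an empty
    graph, not an error.
    """
    if depth < 0:
        raise ValueError("depth must be non-negative")
    seeds = [n.node_id for n in graph.nodes.values()
             if n.properties.get("Name") == name]
    adj = graph.adjacency()
    reached: set[str] = set(seeds)
    frontier = deque((s, 0) for s in seeds)
    while frontier:
        nid, d = frontier.popleft()
        if d == depth:
            continue
        for nb in adj[nid]:
            if nb not in reached:
                reached.add(nb)
                frontier.append((nb, d + 1))
    return subgraph(graph, reached)


# ---------------------------------------------------------------------------
# PD <-> AF granularity linking
# ---------------------------------------------------------------------------

def _value(node: GraphNode, prop: str):
    v = node.properties.get(prop)
    if isinstance(v, list):
        return tuple(v)
    return v


def _existing_pairs(graph: PropertyGraph, rel_type: str) -> set[frozenset]:
    return {frozenset((r.start, r.end)) for r in graph.relationships
            if r.rel_type == rel_type}


def link_granularity(graph: PropertyGraph,
                     properties: tuple = GRANULARITY_PROPERTIES,
                     add_to_graph: bool = True) -> LinkSet:
    """Link equivalent nodes between Process Description and Activity
    Flow maps.

    For every node pair with one node from a PD map and one from an AF
    map, different ``File`` values, a ``Name`` present on both, and
    equal values for every property in ``properties`` (a property absent
    on one node matches only its absence on the other), one
    ``equivalent_to`` relationship is created.  All qualifying pairs are
    linked; no one-to-one restriction applies.
    """
    for node in graph.nodes.values():
        if "Language" not in node.properties:
            raise ContractError(
                f"node {node.node_id!r} lacks the Language property; "
                "was the graph produced by the translator?"
            )
    pd_nodes = [n for n in graph.nodes_sorted()
                if n.properties["Language"] == "PD"]
    af_nodes = [n for n in graph.nodes_sorted()
                if n.properties["Language"] == "AF"]
    existing = _existing_pairs(graph, EQUIVALENT_TO)

    out = LinkSet()
    counter = 0
    for p in pd_nodes:
        for a in af_nodes:
            if p.properties["File"] == a.properties["File"]:
                continue
            if "Name" not in p.properties or "Name" not in a.properties:
                continue
            if any(_value(p, k) != _value(a, k) for k in properties):
                continue
            if frozenset((p.node_id, a.node_id)) in existing:
                continue
            counter += 1
            rel = GraphRelationship(
                rel_id=f"link::eq{counter}::{p.node_id}|{a.node_id}",
                rel_type=EQUIVALENT_TO,
                start=p.node_id,
                end=a.node_id,
                properties={"File": "link"},
            )
            out.links.append(rel)
            out.evidence.append({
                "matched_properties": [k for k in properties
                                       if p.properties.get(k) is not None],
            })
            if add_to_graph:
                graph.add_relationship(rel)
    return out


# ---------------------------------------------------------------------------
# identical-process linking between PD maps
# ---------------------------------------------------------------------------

def _node_signature(node: GraphNode,
                    properties: tuple = PROCESS_PROPERTIES) -> tuple:
    return tuple(_value(node, k) for k in properties)


def process_signature(graph: PropertyGraph, process_id: str,
                      properties: tuple = PROCESS_PROPERTIES) -> Counter:
    """Multiset describing a process node's one-hop environment.

    Each incident relationship contributes one element
    ``(rel_type, direction, neighbor signature)`` where direction is
    ``"out"`` when the relationship starts at the process and ``"in"``
    otherwise, and the neighbor signature is the tuple of the neighbor's
    values for ``properties``.  Stoichiometric duplicates count:
    signatures are compared as multisets.  Link relationships
    (``equivalent_to``, ``identical_process``) are excluded.
    """
    sig: Counter = Counter()
    for rel in graph.relationships:
        if rel.rel_type in LINK_TYPES:
            continue
        if rel.start == process_id:
            other, direction = rel.end, "out"
        elif rel.end == process_id:
            other, direction = rel.start, "in"
        else:
            continue
        sig[(rel.rel_type, direction,
             _node_signature(graph.nodes[other], properties))] += 1
    return sig


def link_identical_processes(graph: PropertyGraph,
                             properties: tuple = PROCESS_PROPERTIES,
                             add_to_graph: bool = True) -> LinkSet:
    """Link identical process nodes across Process Description maps.

    Two processes from different files are linked with one
    ``identical_process`` relationship iff every relationship incident
    to one has a counterpart at the other with the same effect
    (relationship type), the same direction, and a neighbor identical in
    name, node type, unit of information, state variables and
    compartment — with matching multiplicities.
    """
    processes = [n for n in graph.nodes_sorted()
                 if n.label in PD_PROCESS_LABELS
                 and n.properties.get("Language") == "PD"]
    signatures = {n.node_id: process_signature(graph, n.node_id, properties)
                  for n in processes}
    existing = _existing_pairs(graph, IDENTICAL_PROCESS)

    out = LinkSet()
    counter = 0
    for i, q in enumerate(processes):
        for r in processes[i + 1:]:
            if q.properties["File"] == r.properties["File"]:
                continue
            if signatures[q.node_id] != signatures[r.node_id]:
                continue
            if frozenset((q.node_id, r.node_id)) in existing:
                continue
            counter += 1
            rel = GraphRelationship(
                rel_id=f"link::ip{counter}::{q.node_id}|{r.node_id}",
                rel_type=IDENTICAL_PROCESS,
                start=q.node_id,
                end=r.node_id,
                properties={"File": "link"},
            )
            out.links.append(rel)
            out.evidence.append({
                "matched_neighbors": sorted(
                    (t, d, repr(s), c)
                    for (t, d, s), c in signatures[q.node_id].items()
                ),
            })
            if add_to_graph:
                graph.add_relationship(rel)
    return out
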