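"""Labelled-property-graph data model.

Mirrors the node/relationship/property model of graph databases such as
Neo4j: nodes carry a single label (the node type, e.g. ``macromolecule``
or ``process``) plus string-valued properties; relationships are
directed, typed, and also carry properties.  Multi-edges are allowed —
two SBGN arcs between the same pair of glyphs remain two relationships.

All property values are strings or lists of strings.  Equality of
biological entities across maps is never assumed by this layer; the
linking procedures in :mod:`sbgraph.queries` express it with explicit
``equivalent_to`` / ``identical_process`` relationships instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Union

from .errors import GraphLookupError, MergeError

PropertyValue = Union[str, list]


@dataclass
class GraphNode:
    node_id: str
    label: str
    properties: dict[str, PropertyValue] = field(default_factory=dict)


@dataclass
class GraphRelationship:
    rel_id: str
    rel_type: str
    start: str
    end: str
    properties: dict[str, PropertyValue] = field(default_factory=dict)


class PropertyGraph:
    """A multigraph of :class:`GraphNode` and :class:`GraphRelationship`.

    Keeps file provenance (the set of source map names that contributed
    nodes) so that cross-map linking can distinguish origins.
    """

    def __init__(self) -> None:
        self.nodes: dict[str, GraphNode] = {}
        self.relationships: list[GraphRelationship] = []
        self.provenance: set[str] = set()

    # -- construction -----------------------------------------------------

    def add_node(self, node: GraphNode) -> GraphNode:
        if node.node_id in self.nodes:
            raise MergeError(f"node id {node.node_id!r} already present")
        self.nodes[node.node_id] = node
        return node

    def add_relationship(self, rel: GraphRelationship) -> GraphRelationship:
        for endpoint in (rel.start, rel.end):
            if endpoint not in self.nodes:
                raise GraphLookupError(
                    f"relationship {rel.rel_id!r} references unknown node "
                    f"{endpoint!r}"
                )
        self.relationships.append(rel)
        return rel

    # -- queries ----------------------------------------------------------

    def node_count(self) -> int:
        return len(self.nodes)

    def relationship_count(self) -> int:
        return len(self.relationships)

    def nodes_sorted(self) -> list[GraphNode]:
        return [self.nodes[k] for k in sorted(self.nodes)]

    def relationships_sorted(self) -> list[GraphRelationship]:
        return sorted(self.relationships, key=lambda r: r.rel_id)

    def find_nodes(self, **props: str) -> list[GraphNode]:
        """Nodes whose properties equal every given keyword value."""
        out = []
        for node in self.nodes_sorted():
            if all(node.properties.get(k) == v for k, v in props.items()):
                out.append(node)
        return out

    def adjacency(self) -> dict[str, set[str]]:
        """Undirected adjacency over node ids."""
        adj: dict[str, set[str]] = {nid: set() for nid in self.nodes}
        for rel in self.relationships:
            adj[rel.start].add(rel.end)
            adj[rel.end].add(rel.start)
        return adj

    def check_integrity(self) -> None:
        """Raise if any relationship endpoint is missing (invariant check)."""
        for rel in self.relationships:
            for endpoint in (rel.start, rel.end):
                if endpoint not in self.nodes:
                    raise GraphLookupError(
                        f"relationship {rel.rel_id!r} endpoint {endpoint!r} "
                        "not in node set"
                    )


def merge_graphs(graphs: Iterable[PropertyGraph]) -> PropertyGraph:
    """Disjoint union of property graphs; no deduplication.

    Node and relationship counts of the result are the sums of the
    inputs'; provenance is the union.  Node ids must be disjoint across
    the inputs (guaranteed when each graph's ids are namespaced by its
    source map name); a collision raises :class:`MergeError` naming the
    id.
    """
    merged = PropertyGraph()
    for g in graphs:
        for node in g.nodes.values():
            merged.add_node(node)
        merged.provenance |= g.provenance
    for g in graphs:
        for rel in g.relationships:
            merged.add_relationship(rel)
    return merged


def subgraph(graph: PropertyGraph, node_ids: Iterable[str]) -> PropertyGraph:
    """Induced subgraph on ``node_ids``: those nodes plus every
    relationship with both endpoints in the set.  Provenance is carried
    over unchanged."""
    wanted = set(node_ids)
    unknown = wanted - graph.nodes.keys()
    if unknown:
        raise GraphLookupError(
            f"unknown node id(s): {sorted(unknown)}"
        )
    sub = PropertyGraph()
    sub.provenance = set(graph.provenance)
    for nid in wanted:
        sub.add_node(graph.nodes[nid])
    for rel in graph.relationships:
        if rel.start in wanted and rel.end in wanted:
            sub.add_relationship(rel)
    return sub
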