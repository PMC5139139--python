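"""Serialize property graphs to database-loadable and standard formats.

Four output formats:

* **Cypher** — a ``CREATE`` script that rebuilds the graph in an empty
  Neo4j (or any openCypher) database.  Relationships are wired up via a
  temporary per-export key property that the script removes at the end.
* **CSV** — a node table and a relationship table in the bulk-import
  header dialect (``:ID``, ``:LABEL``, ``:START_ID``, ``:END_ID``,
  ``:TYPE``); list-valued properties are joined with ``;``.
* **GraphML** — via networkx, for generic graph tooling.
* **JSON** — a lossless structural dump with an import counterpart
  (:func:`import_json`) used for round-trip testing and as the on-disk
  result format of the CLI.

All exporters order elements by node/relationship id, so output is
deterministic and diffable.
"""

from __future__ import annotations

import json

import networkx as nx
import pandas as pd

from .errors import ExportError
from .graph import GraphNode, GraphRelationship, PropertyGraph

RESERVED_HEADERS = frozenset({":ID", ":LABEL", ":START_ID", ":END_ID",
                              ":TYPE"})
_EXPORT_KEY = "_export_key"


# ---------------------------------------------------------------------------
# Cypher
# ---------------------------------------------------------------------------

def _cypher_string(value: str) -> str:
    return "'" + value.replace("\\", "\\\\").replace("'", "\\'") + "'"


def _cypher_value(value) -> str:
    if isinstance(value, list):
        return "[" + ", ".join(_cypher_string(v) for v in value) + "]"
    return _cypher_string(value)


def _cypher_props(props: dict) -> str:
    items = [f"`{k}`: {_cypher_value(v)}" for k, v in sorted(props.items())]
    return "{" + ", ".join(items) + "}"


def export_cypher(graph: PropertyGraph) -> str:
    """Cypher CREATE script reproducing the graph in an empty database."""
    lines = [
        f"// property graph export: {graph.node_count()} nodes, "
        f"{graph.relationship_count()} relationships",
    ]
    keys = {}
    for i, node in enumerate(graph.nodes_sorted()):
        keys[node.node_id] = f"n{i}"
        props = dict(node.properties)
        props[_EXPORT_KEY] = keys[node.node_id]
        lines.append(f"CREATE (:`{node.label}` {_cypher_props(props)});")
    for rel in graph.relationships_sorted():
        props = _cypher_props(rel.properties)
        lines.append(
            f"MATCH (a {{`{_EXPORT_KEY}`: "
            f"{_cypher_string(keys[rel.start])}}}), "
            f"(b {{`{_EXPORT_KEY}`: {_cypher_string(keys[rel.end])}}}) "
            f"CREATE (a)-[:`{rel.rel_type}` {props}]->(b);"
        )
    if graph.nodes:
        lines.append(f"MATCH (n) REMOVE n.`{_EXPORT_KEY}`;")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# CSV (bulk-import dialect)
# ---------------------------------------------------------------------------

def _flat(value) -> str:
    if isinstance(value, list):
        return ";".join(value)
    return value


def export_csv(graph: PropertyGraph) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(nodes table, relationships table) in bulk-import convention.

    Node columns: ``:ID``, ``:LABEL`` then every property name in sorted
    order; relationship columns: ``:START_ID``, ``:END_ID``, ``:TYPE``
    then properties.  A property whose name collides with a reserved
    header is refused.
    """
    node_props = sorted({k for n in graph.nodes.values()
                         for k in n.properties})
    rel_props = sorted({k for r in graph.relationships
                        for k in r.properties})
    clash = (set(node_props) | set(rel_props)) & RESERVED_HEADERS
    if clash:
        raise ExportError(
            f"property name(s) {sorted(clash)} clash with reserved "
            "bulk-import headers"
        )

    node_rows = [
        {":ID": n.node_id, ":LABEL": n.label,
         **{k: _flat(n.properties[k]) for k in node_props
            if k in n.properties}}
        for n in graph.nodes_sorted()
    ]
    rel_rows = [
        {":START_ID": r.start, ":END_ID": r.end, ":TYPE": r.rel_type,
         **{k: _flat(r.properties[k]) for k in rel_props
            if k in r.properties}}
        for r in graph.relationships_sorted()
    ]
    nodes = pd.DataFrame(node_rows, columns=[":ID", ":LABEL", *node_props])
    rels = pd.DataFrame(rel_rows,
                        columns=[":START_ID", ":END_ID", ":TYPE", *rel_props])
    return nodes, rels


# ---------------------------------------------------------------------------
# GraphML
# ---------------------------------------------------------------------------

def export_graphml(graph: PropertyGraph) -> str:
    """GraphML text (multigraph, directed); list properties joined with ';'."""
    g = nx.MultiDiGraph()
    for node in graph.nodes_sorted():
        attrs = {k: _flat(v) for k, v in sorted(node.properties.items())}
        g.add_node(node.node_id, label=node.label, **attrs)
    for rel in graph.relationships_sorted():
        attrs = {k: _flat(v) for k, v in sorted(rel.properties.items())}
        g.add_edge(rel.start, rel.end, key=rel.rel_id,
                   rel_type=rel.rel_type, **attrs)
    return "\n".join(nx.generate_graphml(g)) + "\n"


# ---------------------------------------------------------------------------
# JSON (lossless, with import counterpart)
# ---------------------------------------------------------------------------

def export_json(graph: PropertyGraph) -> str:
    payload = {
        "provenance": sorted(graph.provenance),
        "nodes": [
            {"id": n.node_id, "label": n.label, "properties": n.properties}
            for n in graph.nodes_sorted()
        ],
        "relationships": [
            {"id": r.rel_id, "type": r.rel_type, "start": r.start,
             "end": r.end, "properties": r.properties}
            for r in graph.relationships_sorted()
        ],
    }
    return json.dumps(payload, indent=2, sort_keys=True)


def import_json(text: str) -> PropertyGraph:
    """Inverse of :func:`export_json` (structural identity round trip)."""
    payload = json.loads(text)
    graph = PropertyGraph()
    graph.provenance = set(payload.get("provenance", []))
    for n in payload["nodes"]:
        graph.add_node(GraphNode(n["id"], n["label"],
                                 dict(n["properties"])))
    for r in payload["relationships"]:
        graph.add_relationship(GraphRelationship(
            r["id"], r["type"], r["start"], r["end"],
            dict(r["properties"]),
        ))
    return graph


def graphs_structurally_equal(a: PropertyGraph, b: PropertyGraph) -> bool:
    """Same provenance, node set (ids, labels, properties) and
    relationship multiset."""
    if a.provenance != b.provenance:
        return False
    na = {k: (v.label, json.dumps(v.properties, sort_keys=True))
          for k, v in a.nodes.items()}
    nb = {k: (v.label, json.dumps(v.properties, sort_keys=True))
          for k, v in b.nodes.items()}
    if na != nb:
        return False
    key = lambda r: (r.rel_id, r.rel_type, r.start, r.end,
                     json.dumps(r.properties, sort_keys=True))
    return sorted(map(key, a.relationships)) == \
        sorted(map(key, b.relationships))
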