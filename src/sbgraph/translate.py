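"""SBGN-to-property-graph translation rules for PD and AF maps.

The translation follows the natural correspondence between the two
models: SBGN glyphs that denote biochemical entities, processes or logic
operators become graph nodes; SBGN arcs become relationships.  Two
constructs deliberately deviate from a one-to-one mapping:

* **Complexes (PD).**  A complex and each of its member entities all
  become nodes, and every direct member is connected to its complex by a
  ``belongs_to_complex`` relationship (member → complex); nested
  complexes recurse.
* **Auxiliary units.**  State variables and units of information do not
  become nodes: they are folded into the ``StateVariable`` /
  ``UnitOfInformation`` properties of their parent's node.  On AF
  biological activities, the unit of information also states the
  activity's underlying entity type (macromolecule, simple chemical,
  ...); that class is promoted into the node's ``NodeType`` property so
  that PD and AF nodes describing the same entity are comparable.

Compartments become a ``Compartment`` property (the compartment's label)
on every node whose glyph referenced them, not nodes of their own.
Every node and relationship carries ``File`` (the source map name) and
``SbgnId`` provenance properties, and every node a ``Language`` property
("PD"/"AF").

The concrete class-by-class rule table lives in :data:`RULES`; it is a
reconstruction assembled from the PD/AF class inventories, since the
original tool's rule tables are not published in citable form.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import TranslationError, UnsupportedLanguageError
from .graph import GraphNode, GraphRelationship, PropertyGraph
from .sbgnml import (
    AF_ACTIVITY_CLASSES,
    AF_ARC_CLASSES,
    AF_AUXILIARY_CLASSES,
    AF_LOGIC_CLASSES,
    AF_STRUCTURAL_CLASSES,
    Glyph,
    PD_ARC_CLASSES,
    PD_AUXILIARY_CLASSES,
    PD_ENTITY_CLASSES,
    PD_LOGIC_CLASSES,
    PD_PROCESS_CLASSES,
    PD_STRUCTURAL_CLASSES,
    SbgnMap,
    validate_map,
)

#: Relationship type used to attach complex members to their complex.
BELONGS_TO_COMPLEX = "belongs_to_complex"

#: PD complex classes whose subglyphs are members.
COMPLEX_CLASSES = frozenset({"complex", "complex multimer"})

#: Node labels of PD process nodes (used by the process-linking query).
PD_PROCESS_LABELS = frozenset(
    c.replace(" ", "") for c in PD_PROCESS_CLASSES
)


def _strip(cls: str) -> str:
    """SBGN class name → graph label ("macromolecule multimer" →
    "macromoleculemultimer")."""
    return cls.replace(" ", "")


@dataclass(frozen=True)
class TranslationRuleTable:
    """Total mapping from SBGN classes to graph labels / relationship types.

    ``node_label`` covers every node-producing glyph class of each
    language; ``rel_type`` every arc class.  The flag sets record each
    class's role (entity, process, logic operator, compartment,
    auxiliary unit).
    """

    node_label: dict = field(default_factory=dict)
    rel_type: dict = field(default_factory=dict)
    is_entity: frozenset = frozenset()
    is_process: frozenset = frozenset()
    is_compartment: frozenset = frozenset()
    is_logic: frozenset = frozenset()
    is_auxiliary: frozenset = frozenset()


def _build_rules() -> TranslationRuleTable:
    node_label = {}
    rel_type = {}
    pd_node_classes = (PD_ENTITY_CLASSES | PD_PROCESS_CLASSES
                       | PD_LOGIC_CLASSES | PD_STRUCTURAL_CLASSES)
    af_node_classes = (AF_ACTIVITY_CLASSES | AF_LOGIC_CLASSES
                       | AF_STRUCTURAL_CLASSES)
    for cls in pd_node_classes:
        node_label[("PD", cls)] = _strip(cls)
    for cls in af_node_classes:
        node_label[("AF", cls)] = _strip(cls)
    for cls in PD_ARC_CLASSES:
        rel_type[("PD", cls)] = _strip(cls)
    for cls in AF_ARC_CLASSES:
        rel_type[("AF", cls)] = _strip(cls)
    return TranslationRuleTable(
        node_label=node_label,
        rel_type=rel_type,
        is_entity=frozenset(
            {("PD", c) for c in PD_ENTITY_CLASSES}
            | {("AF", c) for c in AF_ACTIVITY_CLASSES}
        ),
        is_process=frozenset({("PD", c) for c in PD_PROCESS_CLASSES}),
        is_compartment=frozenset({("PD", "compartment"),
                                  ("AF", "compartment")}),
        is_logic=frozenset(
            {("PD", c) for c in PD_LOGIC_CLASSES}
            | {("AF", c) for c in AF_LOGIC_CLASSES}
        ),
        is_auxiliary=frozenset(
            {("PD", c) for c in PD_AUXILIARY_CLASSES}
            | {("AF", c) for c in AF_AUXILIARY_CLASSES}
        ),
    )


RULES = _build_rules()


def node_id_for(smap: SbgnMap, glyph_id: str) -> str:
    """Graph node id for a glyph: namespaced by the source map name so
    that merged graphs never collide."""
    return f"{smap.source_name}::{glyph_id}"


def state_string(g: Glyph) -> str:
    """State variable subglyph → its ``value@variable`` string."""
    return g.state_text


# ---------------------------------------------------------------------------
# translation
# ---------------------------------------------------------------------------

def translate(smap: SbgnMap) -> PropertyGraph:
    """Translate a parsed map; dispatches on the map's language."""
    if smap.language == "PD":
        return translate_pd(smap)
    if smap.language == "AF":
        return translate_af(smap)
    raise UnsupportedLanguageError(
        f"cannot translate language {smap.language!r}"
    )


def _require_valid(smap: SbgnMap) -> None:
    issues = [i for i in validate_map(smap) if i.severity == "error"]
    if issues:
        raise TranslationError(f"map is not valid: {issues[0]}")


def _compartment_labels(smap: SbgnMap) -> dict[str, str]:
    return {g.id: g.label for g in smap.iter_glyphs()
            if g.cls == "compartment"}


def _base_properties(smap: SbgnMap, g: Glyph, label: str,
                     compartments: dict[str, str]) -> dict:
    props: dict = {
        "File": smap.source_name,
        "SbgnId": g.id,
        "NodeType": label,
        "Language": smap.language,
    }
    name = g.label.strip()
    if name:
        props["Name"] = name
    if g.compartment_ref is not None:
        props["Compartment"] = compartments.get(g.compartment_ref, "")
    if g.clone:
        props["Clone"] = "true"
    return props


def _fold_pd_auxiliaries(g: Glyph, props: dict) -> None:
    states = sorted(
        state_string(s) for s in g.subglyphs if s.cls == "state variable"
    )
    if states:
        props["StateVariable"] = states
    units = sorted(
        s.label for s in g.subglyphs
        if s.cls == "unit of information" and s.label
    )
    if len(units) == 1:
        props["UnitOfInformation"] = units[0]
    elif units:
        props["UnitOfInformation"] = units


def translate_pd(smap: SbgnMap) -> PropertyGraph:
    """Translate a Process Description map.

    Every entity pool, process and logic-operator glyph — at any nesting
    depth inside complexes — becomes one node; every arc one
    relationship (endpoints resolved through ports); every direct
    complex membership one ``belongs_to_complex`` relationship.
    """
    if smap.language != "PD":
        raise UnsupportedLanguageError("translate_pd requires a PD map")
    _require_valid(smap)

    graph = PropertyGraph()
    graph.provenance.add(smap.source_name)
    compartments = _compartment_labels(smap)
    rel_counter = 0

    def walk(g: Glyph, parent_complex: Glyph | None) -> None:
        nonlocal rel_counter
        if g.cls == "compartment" or g.cls in PD_AUXILIARY_CLASSES:
            return
        key = ("PD", g.cls)
        label = RULES.node_label.get(key)
        if label is None:
            raise TranslationError(
                f"no PD translation rule for glyph class {g.cls!r}"
            )
        props = _base_properties(smap, g, label, compartments)
        _fold_pd_auxiliaries(g, props)
        graph.add_node(GraphNode(node_id_for(smap, g.id), label, props))

        if parent_complex is not None:
            rel_counter += 1
            graph.add_relationship(GraphRelationship(
                rel_id=f"{smap.source_name}::btc{rel_counter}",
                rel_type=BELONGS_TO_COMPLEX,
                start=node_id_for(smap, g.id),
                end=node_id_for(smap, parent_complex.id),
                properties={"File": smap.source_name,
                            "SbgnId": parent_complex.id},
            ))

        next_parent = g if g.cls in COMPLEX_CLASSES else None
        for sub in g.subglyphs:
            if sub.cls in PD_AUXILIARY_CLASSES:
                continue
            walk(sub, next_parent)

    for g in smap.glyphs:
        walk(g, None)

    _translate_arcs(smap, graph)
    return graph


def translate_af(smap: SbgnMap) -> PropertyGraph:
    """Translate an Activity Flow map.

    Activities, phenotypes and logic operators become nodes; influence
    arcs become relationships.  A unit of information decorating a
    biological activity is folded into the node: its entity class
    overrides ``NodeType`` and its text (if any) becomes the
    ``UnitOfInformation`` property.
    """
    if smap.language != "AF":
        raise UnsupportedLanguageError("translate_af requires an AF map")
    _require_valid(smap)

    graph = PropertyGraph()
    graph.provenance.add(smap.source_name)
    compartments = _compartment_labels(smap)

    for g in smap.iter_glyphs():
        if g.cls == "compartment" or g.cls in AF_AUXILIARY_CLASSES:
            continue
        label = RULES.node_label.get(("AF", g.cls))
        if label is None:
            raise TranslationError(
                f"no AF translation rule for glyph class {g.cls!r}"
            )
        props = _base_properties(smap, g, label, compartments)
        for unit in g.subglyphs:
            if unit.cls != "unit of information":
                continue
            if unit.entity:
                props["NodeType"] = _strip(unit.entity)
            if unit.label:
                props["UnitOfInformation"] = unit.label
        graph.add_node(GraphNode(node_id_for(smap, g.id), label, props))

    _translate_arcs(smap, graph)
    return graph


def _translate_arcs(smap: SbgnMap, graph: PropertyGraph) -> None:
    aux = (PD_AUXILIARY_CLASSES if smap.language == "PD"
           else AF_AUXILIARY_CLASSES)
    for arc in smap.arcs:
        rel_type = RULES.rel_type.get((smap.language, arc.cls))
        if rel_type is None:
            raise TranslationError(
                f"no {smap.language} translation rule for arc class "
                f"{arc.cls!r}"
            )
        endpoints = []
        for ref in (arc.source_ref, arc.target_ref):
            owner = smap.resolve(ref)
            if owner.cls in aux or owner.cls == "compartment":
                raise TranslationError(
                    f"arc {arc.id!r} endpoint {ref!r} resolves to a "
                    f"{owner.cls!r} glyph, which has no node"
                )
            endpoints.append(node_id_for(smap, owner.id))
        props: dict = {"File": smap.source_name, "SbgnId": arc.id}
        if arc.cardinality is not None:
            props["Cardinality"] = str(arc.cardinality)
        graph.add_relationship(GraphRelationship(
            rel_id=f"{smap.source_name}::{arc.id}",
            rel_type=rel_type,
            start=endpoints[0],
            end=endpoints[1],
            properties=props,
        ))


def translate_all(maps: list[SbgnMap]) -> PropertyGraph:
    """Translate several maps and merge them into one graph."""
    from .graph import merge_graphs

    return merge_graphs([translate(m) for m in maps])
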