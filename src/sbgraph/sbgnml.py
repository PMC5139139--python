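"""Reading, writing and validation of SBGN-ML maps (PD and AF languages).

SBGN-ML is the XML serialization of the Systems Biology Graphical
Notation.  A map is a flat list of ``glyph`` elements (entity pools,
processes, compartments, auxiliary units — possibly nested to arbitrary
depth) plus a list of ``arc`` elements connecting glyphs or their ports.
This module targets the LibSBGN milestone-2 dialect; unknown extension
elements are tolerated and ignored, so any milestone-2-valid document is
readable.  Auxiliary units (state variables, units of information) are
kept as subglyphs here — their reinterpretation as graph properties is
the translator's job, which keeps this reader lossless.

Only the Process Description (PD) and Activity Flow (AF) languages are
supported; Entity Relationship maps are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

from lxml import etree

from .errors import (
    DanglingReferenceError,
    DuplicateIdError,
    SbgnParseError,
    SerializationError,
    UnsupportedLanguageError,
)

SBGN_NS = "http://sbgn.org/libsbgn/0.2"

#: SBGN-ML ``language`` attribute values accepted by the parser.
LANGUAGE_TAGS = {
    "process description": "PD",
    "activity flow": "AF",
}

# ---------------------------------------------------------------------------
# class inventories (milestone-2 PD and AF glyph/arc classes)
# ---------------------------------------------------------------------------

PD_ENTITY_CLASSES = frozenset({
    "unspecified entity", "simple chemical", "macromolecule",
    "nucleic acid feature", "perturbing agent", "source and sink",
    "complex", "simple chemical multimer", "macromolecule multimer",
    "nucleic acid feature multimer", "complex multimer", "phenotype",
})
PD_PROCESS_CLASSES = frozenset({
    "process", "omitted process", "uncertain process",
    "association", "dissociation",
})
PD_LOGIC_CLASSES = frozenset({"and", "or", "not"})
PD_STRUCTURAL_CLASSES = frozenset({"submap", "tag", "terminal"})
PD_AUXILIARY_CLASSES = frozenset({
    "state variable", "unit of information", "cardinality",
})
PD_GLYPH_CLASSES = (
    PD_ENTITY_CLASSES | PD_PROCESS_CLASSES | PD_LOGIC_CLASSES
    | PD_STRUCTURAL_CLASSES | PD_AUXILIARY_CLASSES | {"compartment"}
)
PD_ARC_CLASSES = frozenset({
    "consumption", "production", "modulation", "stimulation", "catalysis",
    "inhibition", "necessary stimulation", "logic arc", "equivalence arc",
})

AF_ACTIVITY_CLASSES = frozenset({"biological activity", "phenotype"})
AF_LOGIC_CLASSES = frozenset({"and", "or", "not", "delay"})
AF_STRUCTURAL_CLASSES = frozenset({"submap", "tag", "terminal"})
AF_AUXILIARY_CLASSES = frozenset({"unit of information"})
AF_GLYPH_CLASSES = (
    AF_ACTIVITY_CLASSES | AF_LOGIC_CLASSES | AF_STRUCTURAL_CLASSES
    | AF_AUXILIARY_CLASSES | {"compartment"}
)
AF_ARC_CLASSES = frozenset({
    "positive influence", "negative influence", "unknown influence",
    "necessary stimulation", "logic arc", "equivalence arc",
})

GLYPH_CLASSES = {"PD": PD_GLYPH_CLASSES, "AF": AF_GLYPH_CLASSES}
ARC_CLASSES = {"PD": PD_ARC_CLASSES, "AF": AF_ARC_CLASSES}
AUXILIARY_CLASSES = {"PD": PD_AUXILIARY_CLASSES, "AF": AF_AUXILIARY_CLASSES}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Glyph:
    """One SBGN glyph: an entity pool, process, compartment or auxiliary unit.

    ``state_value``/``state_variable`` hold the two halves of a state
    variable (rendered in SBGN as ``value@variable``, e.g. ``P@Ser15``);
    ``entity`` holds the entity-type name carried by an AF unit of
    information (e.g. ``macromolecule``).
    """

    id: str
    cls: str
    label: str = ""
    compartment_ref: Optional[str] = None
    subglyphs: list["Glyph"] = field(default_factory=list)
    ports: list[str] = field(default_factory=list)
    bbox: Optional[tuple[float, float, float, float]] = None
    state_value: str = ""
    state_variable: str = ""
    entity: Optional[str] = None
    clone: bool = False

    @property
    def state_text(self) -> str:
        """State variable as its conventional ``value@variable`` string."""
        return f"{self.state_value}@{self.state_variable}"

    def iter_glyphs(self) -> Iterator["Glyph"]:
        """This glyph and every descendant, depth-first."""
        yield self
        for sub in self.subglyphs:
            yield from sub.iter_glyphs()


@dataclass
class Arc:
    """One SBGN arc between two glyphs (or glyph ports)."""

    id: str
    cls: str
    source_ref: str
    target_ref: str
    cardinality: Optional[int] = None


@dataclass
class SbgnMap:
    """A parsed SBGN-ML document (one map, PD or AF)."""

    language: str  # "PD" or "AF"
    glyphs: list[Glyph] = field(default_factory=list)
    arcs: list[Arc] = field(default_factory=list)
    source_name: str = "map"

    def iter_glyphs(self) -> Iterator[Glyph]:
        """All glyphs, top-level and nested, in document order."""
        for g in self.glyphs:
            yield from g.iter_glyphs()

    def glyph_index(self) -> dict[str, Glyph]:
        """Glyph id → glyph, over every nesting level."""
        return {g.id: g for g in self.iter_glyphs()}

    def port_owner(self) -> dict[str, str]:
        """Port id → id of the glyph carrying the port."""
        return {p: g.id for g in self.iter_glyphs() for p in g.ports}

    def resolve(self, ref: str) -> Glyph:
        """Resolve an arc endpoint (glyph or port id) to the owning glyph."""
        index = self.glyph_index()
        if ref in index:
            return index[ref]
        owner = self.port_owner().get(ref)
        if owner is not None:
            return index[owner]
        raise DanglingReferenceError(
            f"reference {ref!r} matches no glyph or port in map "
            f"{self.source_name!r}"
        )


@dataclass(frozen=True)
class ValidationIssue:
    """One structural problem found by :func:`validate_map`."""

    severity: str  # "error" or "warning"
    element_id: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - convenience
        return f"[{self.severity}] {self.element_id}: {self.message}"


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def _local(tag) -> str:
    return etree.QName(tag).localname if isinstance(tag, str) else ""


def _parse_glyph(el) -> Glyph:
    g = Glyph(
        id=el.get("id", ""),
        cls=el.get("class", ""),
        compartment_ref=el.get("compartmentRef"),
    )
    for child in el:
        name = _local(child.tag)
        if name == "label":
            g.label = child.get("text", "")
        elif name == "state":
            g.state_value = child.get("value", "")
            g.state_variable = child.get("variable", "")
        elif name == "entity":
            g.entity = child.get("name")
        elif name == "clone":
            g.clone = True
        elif name == "bbox":
            g.bbox = tuple(
                float(child.get(k, "0")) for k in ("x", "y", "w", "h")
            )
        elif name == "port":
            g.ports.append(child.get("id", ""))
        elif name == "glyph":
            g.subglyphs.append(_parse_glyph(child))
        # anything else (extensions, notes) is tolerated and dropped
    return g


def _parse_arc(el) -> Arc:
    arc = Arc(
        id=el.get("id", ""),
        cls=el.get("class", ""),
        source_ref=el.get("source", ""),
        target_ref=el.get("target", ""),
    )
    for child in el:
        # an arc-attached cardinality glyph collapses to an integer field
        if _local(child.tag) == "glyph" and child.get("class") == "cardinality":
            for sub in child:
                if _local(sub.tag) == "label":
                    try:
                        arc.cardinality = int(sub.get("text", ""))
                    except ValueError:
                        pass
    return arc


def parse_sbgnml(document: bytes | str, source_name: str = "map") -> SbgnMap:
    """Parse an SBGN-ML document into an :class:`SbgnMap`.

    Parameters
    ----------
    document:
        The XML content (bytes or text).
    source_name:
        Identifier recorded on the map, normally the file name; it becomes
        the ``File`` provenance property after translation.

    Raises
    ------
    SbgnParseError
        Malformed XML (the message names the offending line) or no
        ``map`` element.
    UnsupportedLanguageError
        Missing language attribute, or a language other than
        "process description" / "activity flow".
    DanglingReferenceError
        An arc endpoint that resolves to no glyph or port.
    DuplicateIdError
        Two glyphs or ports sharing an id.
    """
    if isinstance(document, str):
        document = document.encode("utf-8")
    try:
        root = etree.fromstring(document)
    except etree.XMLSyntaxError as exc:
        raise SbgnParseError(f"malformed XML: {exc}") from exc

    if _local(root.tag) == "map":
        map_el = root
    else:
        map_el = next(
            (c for c in root if _local(c.tag) == "map"), None
        )
        if map_el is None:
            raise SbgnParseError("document contains no <map> element")

    lang_attr = map_el.get("language")
    if lang_attr is None:
        raise UnsupportedLanguageError("map has no language attribute")
    if lang_attr not in LANGUAGE_TAGS:
        raise UnsupportedLanguageError(
            f"unsupported SBGN language {lang_attr!r}; only "
            "'process description' and 'activity flow' are handled"
        )

    smap = SbgnMap(language=LANGUAGE_TAGS[lang_attr], source_name=source_name)
    for child in map_el:
        name = _local(child.tag)
        if name == "glyph":
            smap.glyphs.append(_parse_glyph(child))
        elif name == "arc":
            smap.arcs.append(_parse_arc(child))

    _check_unique_ids(smap)
    index = smap.glyph_index()
    ports = smap.port_owner()
    for arc in smap.arcs:
        for ref in (arc.source_ref, arc.target_ref):
            if ref not in index and ref not in ports:
                raise DanglingReferenceError(
                    f"arc {arc.id!r}: endpoint {ref!r} resolves to no "
                    "glyph or port"
                )
    return smap


def _check_unique_ids(smap: SbgnMap) -> None:
    seen: set[str] = set()
    for g in smap.iter_glyphs():
        for ident in (g.id, *g.ports):
            if ident in seen:
                raise DuplicateIdError(f"duplicate identifier {ident!r}")
            seen.add(ident)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_map(smap: SbgnMap) -> list[ValidationIssue]:
    """Check the structural invariants of a map; never raises.

    Returns an empty list iff the map is valid: unique identifiers,
    classes drawn from the language's inventory, arc endpoints and
    compartment references resolving.
    """
    issues: list[ValidationIssue] = []
    err = lambda eid, msg: issues.append(ValidationIssue("error", eid, msg))

    if smap.language not in ("PD", "AF"):
        err("map", f"unsupported language {smap.language!r}")
        return issues

    glyph_classes = GLYPH_CLASSES[smap.language]
    arc_classes = ARC_CLASSES[smap.language]

    seen: set[str] = set()
    index: dict[str, Glyph] = {}
    ports: set[str] = set()
    for g in smap.iter_glyphs():
        if g.id in seen:
            err(g.id, f"duplicate glyph id {g.id!r}")
        seen.add(g.id)
        index[g.id] = g
        for p in g.ports:
            if p in seen:
                err(p, f"duplicate port id {p!r}")
            seen.add(p)
            ports.add(p)
        if g.cls not in glyph_classes:
            err(g.id, f"class {g.cls!r} is not in the {smap.language} "
                      "glyph inventory")

    for g in smap.iter_glyphs():
        if g.compartment_ref is not None:
            target = index.get(g.compartment_ref)
            if target is None:
                err(g.id, f"compartmentRef {g.compartment_ref!r} resolves "
                          "to no glyph")
            elif target.cls != "compartment":
                err(g.id, f"compartmentRef {g.compartment_ref!r} points to "
                          f"a {target.cls!r}, not a compartment")

    for arc in smap.arcs:
        if arc.cls not in arc_classes:
            err(arc.id, f"arc class {arc.cls!r} is not in the "
                        f"{smap.language} arc inventory")
        for ref in (arc.source_ref, arc.target_ref):
            if ref not in index and ref not in ports:
                err(arc.id, f"endpoint {ref!r} resolves to no glyph or port")

    return issues


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def _num(x: float) -> str:
    return repr(x)


def _write_glyph(parent, g: Glyph) -> None:
    el = etree.SubElement(parent, f"{{{SBGN_NS}}}glyph",
                          id=g.id)
    el.set("class", g.cls)
    if g.compartment_ref is not None:
        el.set("compartmentRef", g.compartment_ref)
    if g.label:
        etree.SubElement(el, f"{{{SBGN_NS}}}label", text=g.label)
    if g.cls == "state variable" or g.state_value or g.state_variable:
        etree.SubElement(el, f"{{{SBGN_NS}}}state",
                         value=g.state_value, variable=g.state_variable)
    if g.entity is not None:
        etree.SubElement(el, f"{{{SBGN_NS}}}entity", name=g.entity)
    if g.clone:
        etree.SubElement(el, f"{{{SBGN_NS}}}clone")
    if g.bbox is not None:
        x, y, w, h = g.bbox
        etree.SubElement(el, f"{{{SBGN_NS}}}bbox",
                         x=_num(x), y=_num(y), w=_num(w), h=_num(h))
    for sub in g.subglyphs:
        _write_glyph(el, sub)
    for p in g.ports:
        etree.SubElement(el, f"{{{SBGN_NS}}}port", id=p, x="0", y="0")


def write_sbgnml(smap: SbgnMap) -> bytes:
    """Serialize a map back to SBGN-ML; inverse of :func:`parse_sbgnml`.

    Refuses (``SerializationError``) if the map violates its structural
    invariants, naming the first violated one.
    """
    issues = validate_map(smap)
    if issues:
        raise SerializationError(f"map is not serializable: {issues[0]}")

    lang = {v: k for k, v in LANGUAGE_TAGS.items()}[smap.language]
    root = etree.Element(f"{{{SBGN_NS}}}sbgn", nsmap={None: SBGN_NS})
    map_el = etree.SubElement(root, f"{{{SBGN_NS}}}map", language=lang)
    for g in smap.glyphs:
        _write_glyph(map_el, g)
    for arc in smap.arcs:
        arc_el = etree.SubElement(map_el, f"{{{SBGN_NS}}}arc", id=arc.id,
                                  source=arc.source_ref,
                                  target=arc.target_ref)
        arc_el.set("class", arc.cls)
        if arc.cardinality is not None:
            card = etree.SubElement(arc_el, f"{{{SBGN_NS}}}glyph",
                                    id=f"{arc.id}.cardinality")
            card.set("class", "cardinality")
            etree.SubElement(card, f"{{{SBGN_NS}}}label",
                             text=str(arc.cardinality))
        etree.SubElement(arc_el, f"{{{SBGN_NS}}}start", x="0", y="0")
        etree.SubElement(arc_el, f"{{{SBGN_NS}}}end", x="0", y="0")
    return etree.tostring(root, xml_declaration=True, encoding="UTF-8",
                          pretty_print=True)


# ---------------------------------------------------------------------------
# structural equality (round-trip checks)
# ---------------------------------------------------------------------------

def _glyph_key(g: Glyph):
    return (
        g.id, g.cls, g.label, g.compartment_ref, tuple(g.ports), g.bbox,
        g.state_value, g.state_variable, g.entity, g.clone,
        tuple(_glyph_key(s) for s in g.subglyphs),
    )


def maps_structurally_equal(a: SbgnMap, b: SbgnMap) -> bool:
    """True iff two maps carry the same structural content.

    Compares language, the full glyph tree (ids, classes, labels, state
    values, entity annotations, nesting, bboxes) and the arc list;
    ignores ``source_name``.
    """
    if a.language != b.language or len(a.glyphs) != len(b.glyphs):
        return False
    if [_glyph_key(g) for g in a.glyphs] != [_glyph_key(g) for g in b.glyphs]:
        return False
    key = lambda arc: (arc.id, arc.cls, arc.source_ref, arc.target_ref,
                       arc.cardinality)
    return [key(x) for x in a.arcs] == [key(x) for x in b.arcs]
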