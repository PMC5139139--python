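"""Synthetic SBGN-ML maps: brick patterns, random maps, and a
reconstructed iNOS-style signalling scenario.

The brick patterns follow the SBGN-bricks idea — minimal reusable
pathway motifs (phosphorylation, complex association, dissociation,
transcription, influence) that compose into larger maps.  The
iNOS-style trio is a reconstruction of the interferon-gamma signalling
cascade from its published description (IFNG binds its receptor
complex, the bound complex is phosphorylated, STAT1alpha is
phosphorylated and dimerises, the dimer drives IRF1 transcription),
built here from bricks; it is synthetic — not a copy of any distributed
map file — but structured so the cross-map analyses reproduce the
expected behaviours: PD/AF equivalence links on the named species and
identical-process links on the shared upstream processes only.

Random maps respect each language's grammar (consumption/production
arcs alternate entity–process in PD; influences connect activities in
AF) and report their own ground-truth counts so translator output can
be checked against independent bookkeeping.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .errors import GenerationError
from .sbgnml import Arc, Glyph, SbgnMap

BRICK_KINDS = ("phosphorylation", "complex_association", "dissociation",
               "transcription", "influence")

_PD_ENTITY_POOL = ("macromolecule", "simple chemical",
                   "nucleic acid feature", "unspecified entity")
_PD_MODULATIONS = ("catalysis", "stimulation", "inhibition", "modulation")


def _bbox(i: int) -> tuple[float, float, float, float]:
    # trivial grid layout; geometry is never used in graph logic
    return (float(40 * (i % 10)), float(40 * (i // 10)), 30.0, 20.0)


def _mm(gid: str, name: str, i: int, state: str | None = None,
        compartment: str | None = None) -> Glyph:
    g = Glyph(id=gid, cls="macromolecule", label=name,
              compartment_ref=compartment, bbox=_bbox(i))
    if state is not None:
        value, _, variable = state.partition("@")
        g.subglyphs.append(Glyph(id=f"{gid}.sv", cls="state variable",
                                 state_value=value, state_variable=variable,
                                 bbox=_bbox(i)))
    return g


# ---------------------------------------------------------------------------
# bricks
# ---------------------------------------------------------------------------

def make_brick(kind: str, names: list[str], language: str = "PD",
               source_name: str | None = None) -> SbgnMap:
    """Build one brick-pattern map.

    ``names`` fills the pattern's slots:

    * ``phosphorylation`` (PD): [substrate, catalyst?] — substrate with
      empty state variable, phosphorylated product, process, optional
      catalyst with a catalysis arc.
    * ``complex_association`` (PD): members (≥2) — one complex glyph
      containing the named member macromolecules.
    * ``dissociation`` (PD): [complex_name, member1, member2, ...] —
      complex consumed by a dissociation process producing each member.
    * ``transcription`` (PD): [gene, product] — nucleic acid feature
      with a necessary stimulation into a process producing the product
      from an empty set.
    * ``influence`` (AF): [source, target] — two biological activities
      with a positive influence.
    """
    if kind not in BRICK_KINDS:
        raise GenerationError(f"unknown brick kind {kind!r}")
    name = source_name or f"brick_{kind}"

    if kind == "influence":
        if language != "AF":
            raise GenerationError("the influence brick is an AF pattern")
        if len(names) != 2:
            raise GenerationError("influence brick needs [source, target]")
        smap = SbgnMap(language="AF", source_name=name)
        for i, n in enumerate(names):
            act = Glyph(id=f"a{i}", cls="biological activity", label=n,
                        bbox=_bbox(i))
            act.subglyphs.append(Glyph(id=f"a{i}.uoi",
                                       cls="unit of information",
                                       entity="macromolecule",
                                       bbox=_bbox(i)))
            smap.glyphs.append(act)
        smap.arcs.append(Arc(id="arc0", cls="positive influence",
                             source_ref="a0", target_ref="a1"))
        return smap

    if language != "PD":
        raise GenerationError(f"the {kind} brick is a PD pattern")
    smap = SbgnMap(language="PD", source_name=name)

    if kind == "phosphorylation":
        if not 1 <= len(names) <= 2:
            raise GenerationError(
                "phosphorylation brick needs [substrate] or "
                "[substrate, catalyst]")
        substrate = names[0]
        smap.glyphs.append(_mm("sub", substrate, 0, state="@"))
        smap.glyphs.append(_mm("prod", substrate, 1, state="P@"))
        smap.glyphs.append(Glyph(id="proc", cls="process", bbox=_bbox(2)))
        smap.arcs.append(Arc(id="arc_c", cls="consumption",
                             source_ref="sub", target_ref="proc"))
        smap.arcs.append(Arc(id="arc_p", cls="production",
                             source_ref="proc", target_ref="prod"))
        if len(names) == 2:
            smap.glyphs.append(_mm("cat", names[1], 3))
            smap.arcs.append(Arc(id="arc_cat", cls="catalysis",
                                 source_ref="cat", target_ref="proc"))
        return smap

    if kind == "complex_association":
        if len(names) < 2:
            raise GenerationError(
                "complex_association brick needs at least two members")
        cx = Glyph(id="cx", cls="complex",
                   label=":".join(names), bbox=_bbox(0))
        for i, n in enumerate(names):
            cx.subglyphs.append(_mm(f"m{i}", n, i + 1))
        smap.glyphs.append(cx)
        return smap

    if kind == "dissociation":
        if len(names) < 3:
            raise GenerationError(
                "dissociation brick needs [complex, member1, member2, ...]")
        cx = Glyph(id="cx", cls="complex", label=names[0], bbox=_bbox(0))
        for i, n in enumerate(names[1:]):
            cx.subglyphs.append(_mm(f"cm{i}", n, i + 1))
        smap.glyphs.append(cx)
        smap.glyphs.append(Glyph(id="proc", cls="dissociation",
                                 bbox=_bbox(8)))
        smap.arcs.append(Arc(id="arc_c", cls="consumption",
                             source_ref="cx", target_ref="proc"))
        for i, n in enumerate(names[1:]):
            smap.glyphs.append(_mm(f"f{i}", n, i + 9))
            smap.arcs.append(Arc(id=f"arc_p{i}", cls="production",
                                 source_ref="proc", target_ref=f"f{i}"))
        return smap

    # transcription
    if len(names) != 2:
        raise GenerationError("transcription brick needs [gene, product]")
    gene, product = names
    g = Glyph(id="gene", cls="nucleic acid feature", label=gene,
              bbox=_bbox(0))
    g.subglyphs.append(Glyph(id="gene.uoi", cls="unit of information",
                             label="ct:gene", bbox=_bbox(0)))
    smap.glyphs.append(g)
    smap.glyphs.append(Glyph(id="src", cls="source and sink", bbox=_bbox(1)))
    smap.glyphs.append(Glyph(id="proc", cls="process", bbox=_bbox(2)))
    smap.glyphs.append(_mm("prod", product, 3))
    smap.arcs.append(Arc(id="arc_ns", cls="necessary stimulation",
                         source_ref="gene", target_ref="proc"))
    smap.arcs.append(Arc(id="arc_c", cls="consumption",
                         source_ref="src", target_ref="proc"))
    smap.arcs.append(Arc(id="arc_p", cls="production",
                         source_ref="proc", target_ref="prod"))
    return smap


def make_receptor_complex_map(
        multimer_names: tuple[str, str] = ("IFNGR1", "IFNGR2"),
        monomer_names: tuple[str, str] = ("JAK1", "JAK2"),
        source_name: str = "receptor_complex") -> SbgnMap:
    """Interferon-gamma receptor complex: one complex glyph whose four
    subunits are two dimerised macromolecule multimers (unit of
    information ``N:2``) and two plain macromolecules."""
    smap = SbgnMap(language="PD", source_name=source_name)
    cx = Glyph(id="cx", cls="complex", label="IFNG receptor", bbox=_bbox(0))
    i = 1
    for n in multimer_names:
        g = Glyph(id=f"mm_{n}", cls="macromolecule multimer", label=n,
                  bbox=_bbox(i))
        g.subglyphs.append(Glyph(id=f"mm_{n}.uoi",
                                 cls="unit of information",
                                 label="N:2", bbox=_bbox(i)))
        cx.subglyphs.append(g)
        i += 1
    for n in monomer_names:
        cx.subglyphs.append(_mm(f"m_{n}", n, i))
        i += 1
    smap.glyphs.append(cx)
    return smap


# ---------------------------------------------------------------------------
# random maps
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroundTruth:
    """Generator bookkeeping for oracle checks against the translator."""

    n_entity_glyphs: int      # entity pools incl. complex members & complexes
    n_process_glyphs: int
    n_arcs: int
    n_membership_pairs: int

    @property
    def expected_nodes(self) -> int:
        return self.n_entity_glyphs + self.n_process_glyphs

    @property
    def expected_relationships(self) -> int:
        return self.n_arcs + self.n_membership_pairs


def make_random_map(language: str = "PD", n_entities: int = 10,
                    n_processes: int = 3, n_arcs: int = 8,
                    complex_fraction: float = 0.2,
                    seed: int = 0) -> tuple[SbgnMap, GroundTruth]:
    """Seed-deterministic random map plus its ground-truth counts.

    PD maps: ``n_entities`` entity pools (a ``complex_fraction`` of them
    packed as members into complex glyphs, which are additional
    entities), ``n_processes`` process nodes, and ``n_arcs`` arcs
    respecting the PD grammar (consumption entity→process, production
    process→entity, modulations entity→process).  AF maps: activities
    with influence arcs.  Some entities receive state variables, units
    of information, or a compartment.
    """
    if min(n_entities, n_processes, n_arcs) < 0:
        raise GenerationError("counts must be non-negative")
    rng = random.Random(seed)

    if language == "AF":
        if n_arcs > 0 and n_entities < 1:
            raise GenerationError("arcs need at least one activity")
        smap = SbgnMap(language="AF",
                       source_name=f"random_af_{seed}")
        has_compartment = n_entities > 0 and rng.random() < 0.5
        if has_compartment:
            smap.glyphs.append(Glyph(id="comp0", cls="compartment",
                                     label="cytosol", bbox=_bbox(99)))
        for i in range(n_entities):
            act = Glyph(
                id=f"a{i}", cls="biological activity", label=f"act{i}",
                compartment_ref=("comp0" if has_compartment
                                 and rng.random() < 0.5 else None),
                bbox=_bbox(i))
            if rng.random() < 0.6:
                act.subglyphs.append(Glyph(
                    id=f"a{i}.uoi", cls="unit of information",
                    entity=rng.choice(("macromolecule", "simple chemical")),
                    bbox=_bbox(i)))
            smap.glyphs.append(act)
        for j in range(n_arcs):
            smap.arcs.append(Arc(
                id=f"arc{j}",
                cls=rng.choice(("positive influence", "negative influence",
                                "unknown influence")),
                source_ref=f"a{rng.randrange(n_entities)}",
                target_ref=f"a{rng.randrange(n_entities)}"))
        return smap, GroundTruth(n_entities, 0, n_arcs, 0)

    if language != "PD":
        raise GenerationError(f"unknown language {language!r}")
    if n_arcs > 0 and (n_processes < 1 or n_entities < 1):
        raise GenerationError(
            "PD arcs need at least one entity and one process")

    smap = SbgnMap(language="PD", source_name=f"random_pd_{seed}")
    has_compartment = n_entities > 0 and rng.random() < 0.5
    if has_compartment:
        smap.glyphs.append(Glyph(id="comp0", cls="compartment",
                                 label="cytosol", bbox=_bbox(99)))

    n_members = int(n_entities * complex_fraction)
    entities: list[Glyph] = []
    for i in range(n_entities):
        g = Glyph(
            id=f"e{i}", cls=rng.choice(_PD_ENTITY_POOL), label=f"ent{i}",
            compartment_ref=("comp0" if has_compartment
                             and rng.random() < 0.5 else None),
            bbox=_bbox(i))
        if rng.random() < 0.3:
            g.subglyphs.append(Glyph(id=f"e{i}.sv", cls="state variable",
                                     state_value=rng.choice(("", "P")),
                                     state_variable=rng.choice(
                                         ("", "Ser15", "Thr100")),
                                     bbox=_bbox(i)))
        if rng.random() < 0.2:
            g.subglyphs.append(Glyph(id=f"e{i}.uoi",
                                     cls="unit of information",
                                     label=f"N:{rng.randrange(2, 5)}",
                                     bbox=_bbox(i)))
        entities.append(g)

    members, free = entities[:n_members], entities[n_members:]
    n_complexes = 0
    membership_pairs = 0
    arc_targets: list[str] = [g.id for g in free]
    while members:
        size = min(len(members), rng.randrange(1, 4))
        cx = Glyph(id=f"cx{n_complexes}", cls="complex",
                   label=f"complex{n_complexes}", bbox=_bbox(50))
        for m in members[:size]:
            m.compartment_ref = None  # members live inside the complex
            cx.subglyphs.append(m)
        membership_pairs += size
        members = members[size:]
        smap.glyphs.append(cx)
        arc_targets.append(cx.id)
        n_complexes += 1
    smap.glyphs.extend(free)

    processes = [Glyph(id=f"p{i}",
                       cls=rng.choice(("process", "process", "process",
                                       "omitted process",
                                       "uncertain process")),
                       bbox=_bbox(60 + i))
                 for i in range(n_processes)]
    smap.glyphs.extend(processes)

    for j in range(n_arcs):
        proc = rng.choice(processes).id
        ent = rng.choice(arc_targets)
        cls = rng.choice(("consumption", "production", "catalysis",
                          "stimulation", "inhibition"))
        if cls == "production":
            src, tgt = proc, ent
        else:
            src, tgt = ent, proc
        smap.arcs.append(Arc(id=f"arc{j}", cls=cls, source_ref=src,
                             target_ref=tgt,
                             cardinality=(rng.randrange(2, 4)
                                          if cls in ("consumption",
                                                     "production")
                                          and rng.random() < 0.1
                                          else None)))

    truth = GroundTruth(
        n_entity_glyphs=n_entities + n_complexes,
        n_process_glyphs=n_processes,
        n_arcs=n_arcs,
        n_membership_pairs=membership_pairs,
    )
    return smap, truth


# ---------------------------------------------------------------------------
# the iNOS-style demonstration scenario
# ---------------------------------------------------------------------------

def _pd_cascade(source_name: str, transcription_target: str) -> SbgnMap:
    """Interferon-gamma PD cascade up to IRF1 transcription.

    ``transcription_target`` selects the divergent step: ``"grr"`` uses
    the gene regulatory region GAS, ``"gene"`` the gene IRF1.
    """
    smap = SbgnMap(language="PD", source_name=source_name)
    smap.glyphs.append(Glyph(id="c_ext", cls="compartment",
                             label="extracellular", bbox=_bbox(90)))
    smap.glyphs.append(Glyph(id="c_cyt", cls="compartment",
                             label="cytosol", bbox=_bbox(91)))

    def receptor_complex(gid: str, phosphorylated: bool,
                         with_ifng: bool) -> Glyph:
        cx = Glyph(id=gid, cls="complex",
                   label="IFNG:IFNG receptor" if with_ifng
                   else "IFNG receptor",
                   compartment_ref="c_cyt", bbox=_bbox(10))
        units = [("IFNGR1", True), ("IFNGR2", True),
                 ("JAK1", False), ("JAK2", False)]
        for i, (n, dimer) in enumerate(units):
            cls = "macromolecule multimer" if dimer else "macromolecule"
            sub = Glyph(id=f"{gid}.{n}", cls=cls, label=n, bbox=_bbox(11 + i))
            if dimer:
                sub.subglyphs.append(Glyph(id=f"{gid}.{n}.uoi",
                                           cls="unit of information",
                                           label="N:2", bbox=_bbox(11 + i)))
            if phosphorylated and not dimer:
                sub.subglyphs.append(Glyph(id=f"{gid}.{n}.sv",
                                           cls="state variable",
                                           state_value="P",
                                           bbox=_bbox(11 + i)))
            cx.subglyphs.append(sub)
        if with_ifng:
            cx.subglyphs.append(Glyph(id=f"{gid}.IFNG", cls="macromolecule",
                                      label="IFNG", bbox=_bbox(15)))
        return cx

    smap.glyphs.append(Glyph(id="ifng", cls="macromolecule", label="IFNG",
                             compartment_ref="c_ext", bbox=_bbox(0)))
    smap.glyphs.append(receptor_complex("rec", False, False))
    smap.glyphs.append(receptor_complex("bound", False, True))
    smap.glyphs.append(receptor_complex("bound_p", True, True))

    smap.glyphs.append(Glyph(id="p_bind", cls="association", bbox=_bbox(20)))
    smap.arcs += [
        Arc(id="a1", cls="consumption", source_ref="ifng",
            target_ref="p_bind"),
        Arc(id="a2", cls="consumption", source_ref="rec",
            target_ref="p_bind"),
        Arc(id="a3", cls="production", source_ref="p_bind",
            target_ref="bound"),
    ]
    smap.glyphs.append(Glyph(id="p_phos", cls="process", bbox=_bbox(21)))
    smap.arcs += [
        Arc(id="a4", cls="consumption", source_ref="bound",
            target_ref="p_phos"),
        Arc(id="a5", cls="production", source_ref="p_phos",
            target_ref="bound_p"),
    ]

    smap.glyphs.append(_mm("stat1", "STAT1alpha", 30, state="@",
                           compartment="c_cyt"))
    smap.glyphs.append(_mm("stat1_p", "STAT1alpha", 31, state="P@",
                           compartment="c_cyt"))
    smap.glyphs.append(Glyph(id="p_stat", cls="process", bbox=_bbox(32)))
    smap.arcs += [
        Arc(id="a6", cls="consumption", source_ref="stat1",
            target_ref="p_stat"),
        Arc(id="a7", cls="production", source_ref="p_stat",
            target_ref="stat1_p"),
        Arc(id="a8", cls="stimulation", source_ref="bound_p",
            target_ref="p_stat"),
    ]

    dimer = Glyph(id="dimer", cls="complex", label="STAT1alpha dimer",
                  compartment_ref="c_cyt", bbox=_bbox(40))
    for i in (1, 2):
        dimer.subglyphs.append(_mm(f"dimer.s{i}", "STAT1alpha", 41 + i,
                                   state="P@"))
    smap.glyphs.append(dimer)
    smap.glyphs.append(Glyph(id="p_dim", cls="association", bbox=_bbox(43)))
    smap.arcs += [
        Arc(id="a9", cls="consumption", source_ref="stat1_p",
            target_ref="p_dim", cardinality=2),
        Arc(id="a10", cls="production", source_ref="p_dim",
            target_ref="dimer"),
    ]

    if transcription_target == "grr":
        gene = Glyph(id="gene", cls="nucleic acid feature", label="GAS",
                     bbox=_bbox(50))
        gene.subglyphs.append(Glyph(id="gene.uoi",
                                    cls="unit of information",
                                    label="ct:grr", bbox=_bbox(50)))
    else:
        gene = Glyph(id="gene", cls="nucleic acid feature", label="IRF1",
                     bbox=_bbox(50))
        gene.subglyphs.append(Glyph(id="gene.uoi",
                                    cls="unit of information",
                                    label="ct:gene", bbox=_bbox(50)))
    smap.glyphs.append(gene)
    smap.glyphs.append(Glyph(id="src", cls="source and sink", bbox=_bbox(51)))
    smap.glyphs.append(Glyph(id="p_tx", cls="process", bbox=_bbox(52)))
    smap.glyphs.append(_mm("irf1", "IRF1", 53, compartment="c_cyt"))
    smap.arcs += [
        Arc(id="a11", cls="necessary stimulation", source_ref="gene",
            target_ref="p_tx"),
        Arc(id="a12", cls="consumption", source_ref="src",
            target_ref="p_tx"),
        Arc(id="a13", cls="production", source_ref="p_tx",
            target_ref="irf1"),
        Arc(id="a14", cls="stimulation", source_ref="dimer",
            target_ref="p_tx"),
    ]
    return smap


def _af_abstraction(source_name: str) -> SbgnMap:
    """AF view of the cascade: IFNG and the receptor components activate
    STAT1alpha, which activates IRF1, which activates NOS2."""
    smap = SbgnMap(language="AF", source_name=source_name)
    smap.glyphs.append(Glyph(id="c_ext", cls="compartment",
                             label="extracellular", bbox=_bbox(90)))
    smap.glyphs.append(Glyph(id="c_cyt", cls="compartment",
                             label="cytosol", bbox=_bbox(91)))
    species = [
        ("ifng", "IFNG", "c_ext"),
        ("jak1", "JAK1", "c_cyt"),
        ("jak2", "JAK2", "c_cyt"),
        ("stat1", "STAT1alpha", "c_cyt"),
        ("irf1", "IRF1", "c_cyt"),
        ("nos2", "NOS2", "c_cyt"),
    ]
    for i, (gid, n, comp) in enumerate(species):
        act = Glyph(id=gid, cls="biological activity", label=n,
                    compartment_ref=comp, bbox=_bbox(i))
        act.subglyphs.append(Glyph(id=f"{gid}.uoi",
                                   cls="unit of information",
                                   entity="macromolecule", bbox=_bbox(i)))
        smap.glyphs.append(act)
    influences = [("ifng", "stat1"), ("jak1", "stat1"), ("jak2", "stat1"),
                  ("stat1", "irf1"), ("irf1", "nos2")]
    for j, (s, t) in enumerate(influences):
        smap.arcs.append(Arc(id=f"arc{j}", cls="positive influence",
                             source_ref=s, target_ref=t))
    return smap


def make_inos_like_pair() -> tuple[SbgnMap, SbgnMap, SbgnMap]:
    """(PD cascade, AF abstraction, PD variant) for the demonstration
    scenario.

    The PD cascade and the variant share the four upstream processes
    (receptor binding, complex phosphorylation, STAT1alpha
    phosphorylation, dimerisation) and diverge at the transcription
    step: the cascade regulates via the gene regulatory region GAS, the
    variant via the gene IRF1.
    """
    pd_map = _pd_cascade("inos_pd", "grr")
    af_map = _af_abstraction("inos_af")
    pd_variant = _pd_cascade("irf1_pd", "gene")
    return pd_map, af_map, pd_variant
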