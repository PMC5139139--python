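import random

import pytest

from sbgraph import (
    PropertyGraph,
    GraphNode,
    GraphRelationship,
    make_inos_like_pair,
    make_random_map,
    make_receptor_complex_map,
    merge_graphs,
    translate,
)


@pytest.fixture
def fig1_map():
    """Receptor-complex map: one complex, four subunits (two dimerised
    multimers with unit of information N:2, two macromolecules)."""
    return make_receptor_complex_map()


@pytest.fixture
def inos_trio():
    """(PD cascade, AF abstraction, PD variant) demonstration maps."""
    return make_inos_like_pair()


@pytest.fixture
def merged_pd_af(inos_trio):
    pd_map, af_map, _ = inos_trio
    return merge_graphs([translate(pd_map), translate(af_map)])


def random_translated_graph(seed: int) -> PropertyGraph:
    """One random PD map and one random AF map, translated and merged."""
    rng = random.Random(seed)
    pd_map, _ = make_random_map(
        "PD", n_entities=rng.randrange(3, 20),
        n_processes=rng.randrange(1, 6), n_arcs=rng.randrange(0, 25),
        complex_fraction=rng.choice((0.0, 0.2, 0.5)), seed=seed)
    af_map, _ = make_random_map(
        "AF", n_entities=rng.randrange(1, 12),
        n_arcs=rng.randrange(0, 15), seed=seed + 1)
    return merge_graphs([translate(pd_map), translate(af_map)])


def random_property_graph(seed: int) -> PropertyGraph:
    """Random labelled property graph with PD and AF nodes drawn from
    small property pools, so that cross-language matches and
    near-misses are both frequent.  Built directly (not via the
    translator) to exercise the linking predicates independently."""
    rng = random.Random(seed)
    g = PropertyGraph()
    names = ["IFNG", "STAT1", "JAK1", "IRF1"]
    types = ["macromolecule", "simplechemical"]
    compartments = [None, "cytosol", "nucleus"]
    uois = [None, "N:2"]
    for lang, fname, count in (("PD", "mapA", rng.randrange(2, 8)),
                               ("AF", "mapB", rng.randrange(2, 8)),
                               ("PD", "mapC", rng.randrange(0, 4))):
        for i in range(count):
            props = {
                "File": fname, "SbgnId": f"g{i}", "Language": lang,
                "Name": rng.choice(names),
                "NodeType": rng.choice(types),
            }
            comp = rng.choice(compartments)
            if comp:
                props["Compartment"] = comp
            uoi = rng.choice(uois)
            if uoi:
                props["UnitOfInformation"] = uoi
            g.add_node(GraphNode(f"{fname}::n{i}", props["NodeType"], props))
        g.provenance.add(fname)
    ids = sorted(g.nodes)
    for j in range(rng.randrange(0, 2 * len(ids))):
        g.add_relationship(GraphRelationship(
            f"r{j}", rng.choice(("stimulation", "consumption")),
            rng.choice(ids), rng.choice(ids), {"File": "x", "SbgnId": f"r{j}"}))
    return g
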