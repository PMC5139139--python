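"""Neighborhood extraction and the two cross-map linking procedures,
each checked against an independent brute-force oracle."""

import copy
from collections import Counter

import networkx as nx
import pytest

from sbgraph import (
    link_granularity,
    link_identical_processes,
    make_inos_like_pair,
    make_random_map,
    merge_graphs,
    neighborhood,
    translate,
)
from sbgraph.errors import ContractError
from sbgraph.queries import (
    EQUIVALENT_TO,
    GRANULARITY_PROPERTIES,
    IDENTICAL_PROCESS,
    PROCESS_PROPERTIES,
)

from conftest import random_property_graph, random_translated_graph


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def bfs_oracle(graph, name, depth):
    """Expected neighborhood node set via networkx shortest paths."""
    nxg = nx.Graph()
    nxg.add_nodes_from(graph.nodes)
    for r in graph.relationships:
        nxg.add_edge(r.start, r.end)
    seeds = [nid for nid, n in graph.nodes.items()
             if n.properties.get("Name") == name]
    reached = set(seeds)
    for s in seeds:
        reached |= set(
            nx.single_source_shortest_path_length(nxg, s,
                                                  cutoff=depth))
    return reached


def tup(v):
    return tuple(v) if isinstance(v, list) else v


def granularity_oracle(graph, properties=GRANULARITY_PROPERTIES):
    """Exhaustive double loop over all cross-language node pairs."""
    expected = set()
    for p in graph.nodes.values():
        for a in graph.nodes.values():
            if p.properties.get("Language") != "PD":
                continue
            if a.properties.get("Language") != "AF":
                continue
            if p.properties["File"] == a.properties["File"]:
                continue
            if "Name" not in p.properties or "Name" not in a.properties:
                continue
            if all(tup(p.properties.get(k)) == tup(a.properties.get(k))
                   for k in properties):
                expected.add(frozenset((p.node_id, a.node_id)))
    return expected


def signature_oracle(graph, nid):
    """Independent recomputation of a process environment multiset."""
    sig = Counter()
    for r in graph.relationships:
        if r.rel_type in (EQUIVALENT_TO, IDENTICAL_PROCESS):
            continue
        for me, other, direction in ((r.start, r.end, "out"),
                                     (r.end, r.start, "in")):
            if me == nid:
                nb = graph.nodes[other].properties
                sig[(r.rel_type, direction,
                     tuple(tup(nb.get(k))
                           for k in PROCESS_PROPERTIES))] += 1
    return sig


def process_oracle(graph):
    procs = [n for n in graph.nodes.values()
             if n.label in ("process", "omittedprocess", "uncertainprocess",
                            "association", "dissociation")
             and n.properties.get("Language") == "PD"]
    expected = set()
    for q in procs:
        for r in procs:
            if q.node_id >= r.node_id:
                continue
            if q.properties["File"] == r.properties["File"]:
                continue
            if signature_oracle(graph, q.node_id) == \
                    signature_oracle(graph, r.node_id):
                expected.add(frozenset((q.node_id, r.node_id)))
    return expected


def duplicate_pd_graph(seed, rename="copyB", perturb=None):
    """Two translations of one random PD map under different file names;
    ``perturb`` optionally renames one entity label in the copy."""
    smap, _ = make_random_map("PD", n_entities=8, n_processes=3,
                              n_arcs=10, complex_fraction=0.25, seed=seed)
    copy_map = copy.deepcopy(smap)
    copy_map.source_name = rename
    if perturb is not None:
        target = copy_map.glyph_index()[perturb]
        target.label = target.label + "_mut"
    return merge_graphs([translate(smap), translate(copy_map)])


# ---------------------------------------------------------------------------
# neighborhood
# ---------------------------------------------------------------------------

class TestNeighborhood:
    def test_depth_zero_returns_matches_only(self, merged_pd_af):
        sub = neighborhood(merged_pd_af, "IFNG", 0)
        assert all(n.properties.get("Name") == "IFNG"
                   for n in sub.nodes.values())
        assert sub.node_count() == len(merged_pd_af.find_nodes(Name="IFNG"))
        assert sub.node_count() > 0
        assert sub.relationship_count() == 0

    def test_absent_name_gives_empty_graph(self, merged_pd_af):
        sub = neighborhood(merged_pd_af, "NOT_A_GENE", 3)
        assert sub.node_count() == 0

    def test_negative_depth_rejected(self, merged_pd_af):
        with pytest.raises(ValueError):
            neighborhood(merged_pd_af, "IFNG", -1)

    def test_receptor_binding_subnetwork(self, inos_trio):
        """IFNG's depth-2 neighborhood reaches the binding process and
        the receptor complex it consumes."""
        pd_map, _, _ = inos_trio
        sub = neighborhood(translate(pd_map), "IFNG", 2)
        names = {n.properties.get("Name") for n in sub.nodes.values()}
        assert "IFNG receptor" in names
        assert "IFNG:IFNG receptor" in names

    @pytest.mark.parametrize("seed", range(8))
    @pytest.mark.parametrize("depth", [0, 1, 2, 3])
    def test_matches_bfs_oracle(self, seed, depth):
        graph = random_translated_graph(seed)
        name = f"ent{seed % 5}"
        sub = neighborhood(graph, name, depth)
        assert set(sub.nodes) == bfs_oracle(graph, name, depth)

    @pytest.mark.parametrize("seed", range(5))
    def test_monotone_in_depth(self, seed):
        graph = random_translated_graph(seed)
        previous = set()
        for depth in range(4):
            current = set(neighborhood(graph, "ent1", depth).nodes)
            assert previous <= current
            previous = current


# ---------------------------------------------------------------------------
# granularity linking
# ---------------------------------------------------------------------------

class TestLinkGranularity:
    def test_ifng_linked_across_pd_and_af(self, merged_pd_af):
        links = link_granularity(merged_pd_af)
        named = {
            frozenset((merged_pd_af.nodes[l.start].properties["Name"],
                       merged_pd_af.nodes[l.end].properties["Name"]))
            for l in links.links
        }
        assert frozenset(("IFNG",)) in named
        assert all(l.rel_type == EQUIVALENT_TO for l in links.links)

    def test_links_join_different_files(self, merged_pd_af):
        links = link_granularity(merged_pd_af)
        for l in links.links:
            a = merged_pd_af.nodes[l.start].properties
            b = merged_pd_af.nodes[l.end].properties
            assert a["File"] != b["File"]
            assert {a["Language"], b["Language"]} == {"PD", "AF"}

    def test_compartment_presence_mismatch_blocks_link(self):
        from sbgraph import GraphNode, PropertyGraph
        g = PropertyGraph()
        g.add_node(GraphNode("p", "macromolecule", {
            "File": "a.sbgn", "SbgnId": "p", "Language": "PD",
            "Name": "IFNG", "NodeType": "macromolecule"}))
        g.add_node(GraphNode("a", "biologicalactivity", {
            "File": "b.sbgn", "SbgnId": "a", "Language": "AF",
            "Name": "IFNG", "NodeType": "macromolecule",
            "Compartment": "nucleus"}))
        assert len(link_granularity(g)) == 0

    def test_contract_error_without_language(self):
        from sbgraph import GraphNode, PropertyGraph
        g = PropertyGraph()
        g.add_node(GraphNode("n", "macromolecule",
                             {"File": "f", "SbgnId": "n"}))
        with pytest.raises(ContractError):
            link_granularity(g)

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_exhaustive_pair_oracle(self, seed):
        g = random_property_graph(seed)
        links = link_granularity(g, add_to_graph=False)
        assert links.pairs() == granularity_oracle(g)

    def test_idempotent(self, merged_pd_af):
        first = link_granularity(merged_pd_af)
        assert len(first) > 0
        again = link_granularity(merged_pd_af)
        assert len(again) == 0

    def test_symmetric_under_map_swap(self, inos_trio):
        pd_map, af_map, _ = inos_trio
        g1 = merge_graphs([translate(pd_map), translate(af_map)])
        g2 = merge_graphs([translate(af_map), translate(pd_map)])
        assert link_granularity(g1, add_to_graph=False).pairs() == \
            link_granularity(g2, add_to_graph=False).pairs()


# ---------------------------------------------------------------------------
# identical-process linking
# ---------------------------------------------------------------------------

class TestLinkIdenticalProcesses:
    def test_duplicate_map_links_every_process(self):
        graph = duplicate_pd_graph(seed=11)
        n_processes = sum(
            1 for n in graph.nodes.values()
            if n.label in ("process", "omittedprocess", "uncertainprocess")
            and n.properties["File"] != "copyB")
        links = link_identical_processes(graph)
        # every process matches at least its own copy; identical twins
        # within one map can add cross-copy links beyond the diagonal
        assert len(links) >= n_processes
        diagonal = {frozenset((l.start, l.end)) for l in links.links
                    if l.start.split("::")[1] == l.end.split("::")[1]}
        assert len(diagonal) == n_processes

    def test_perturbed_neighbor_breaks_adjacent_links_only(self):
        intact = duplicate_pd_graph(seed=5)
        base = link_identical_processes(intact, add_to_graph=False).pairs()
        perturbed = duplicate_pd_graph(seed=5, perturb="e7")
        after = link_identical_processes(perturbed,
                                         add_to_graph=False).pairs()
        assert after <= base
        # exactly the processes adjacent to the renamed entity lose links
        adjacent = set()
        for r in perturbed.relationships:
            for a, b in ((r.start, r.end), (r.end, r.start)):
                if a.endswith("::e7") and b.split("::")[1].startswith("p"):
                    adjacent.add(b.split("::")[1])
        lost = base - after
        assert lost == {pair for pair in base
                        if any(nid.split("::")[1] in adjacent
                               for nid in pair)}
        assert lost or not adjacent

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_pair_oracle(self, seed):
        graph = duplicate_pd_graph(seed=seed,
                                   perturb="e3" if seed % 2 else None)
        links = link_identical_processes(graph, add_to_graph=False)
        assert links.pairs() == process_oracle(graph)

    def test_idempotent(self):
        graph = duplicate_pd_graph(seed=2)
        first = link_identical_processes(graph)
        assert len(first) > 0
        assert len(link_identical_processes(graph)) == 0

    def test_shared_upstream_linked_divergent_transcription_not(self):
        """The two PD variants share the receptor-binding,
        phosphorylation and dimerisation machinery but regulate
        transcription through different elements (regulatory region GAS
        vs gene IRF1): the four upstream processes link, the
        transcription processes do not."""
        pd_map, _, pd_variant = make_inos_like_pair()
        graph = merge_graphs([translate(pd_map), translate(pd_variant)])
        links = link_identical_processes(graph, add_to_graph=False)
        linked_sbgn_ids = {
            frozenset((l.start.split("::")[1], l.end.split("::")[1]))
            for l in links.links
        }
        assert linked_sbgn_ids == {
            frozenset(("p_bind",)), frozenset(("p_phos",)),
            frozenset(("p_stat",)), frozenset(("p_dim",)),
        }
        assert frozenset(("p_tx",)) not in linked_sbgn_ids
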