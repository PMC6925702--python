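"""Aromatic graph construction, Dijkstra pathway, symmetric-unit extraction."""

import itertools

import networkx as nx
import numpy as np
import pytest

from pilitransport.pathway import (
    AromaticGraph,
    PathwayWarning,
    bottleneck_distance,
    build_graph,
    extract_symmetric_unit,
    interaromatic_distance,
    proximal_cc_distance,
    shortest_path,
)
from pilitransport.structure import StructureError, ring_from_coords
from pilitransport.synthetic import SyntheticSpec, make_pathway_pilus, make_ring
from conftest import GS1_DISTANCES, GS2_DISTANCES


def hexagon_ring(center, normal=(0, 0, 1.0), rotation=0.0, seq=1, subunit=0, rtype="F"):
    res = make_ring(np.asarray(center, float), np.asarray(normal, float), rtype, rotation,
                    residue_seq=seq)
    coords = np.stack([a.position for a in res.atoms])
    return ring_from_coords(coords, "A", seq, rtype, subunit)


class TestDistances:
    def test_identical_rings_are_zero_apart(self):
        r = hexagon_ring((1.0, 2.0, 3.0))
        assert interaromatic_distance(r, r) == 0.0

    def test_planted_centroid_separation(self):
        a = hexagon_ring((0, 0, 0))
        b = hexagon_ring((0, 0, 3.9))
        assert interaromatic_distance(a, b) == pytest.approx(3.9)

    def test_matches_direct_centroid_norm(self, rng):
        for _ in range(20):
            ca, cb = rng.normal(scale=10, size=(2, 3))
            na, nb = rng.normal(size=(2, 3))
            a = hexagon_ring(ca, na / np.linalg.norm(na))
            b = hexagon_ring(cb, nb / np.linalg.norm(nb))
            assert interaromatic_distance(a, b) == pytest.approx(
                np.linalg.norm(a.centroid - b.centroid), abs=1e-12
            )

    def test_eclipsed_coaxial_stack_separation(self):
        a = hexagon_ring((0, 0, 0))
        b = hexagon_ring((0, 0, 3.5))
        assert proximal_cc_distance(a, b) == pytest.approx(3.5)

    def test_staggered_stack_matches_exhaustive_pair_scan(self):
        a = hexagon_ring((0, 0, 0))
        b = hexagon_ring((0, 0, 3.5), rotation=30.0)
        expected = min(
            np.linalg.norm(pa - pb)
            for pa, pb in itertools.product(a.ring_coords, b.ring_coords)
        )
        assert proximal_cc_distance(a, b) == pytest.approx(expected, abs=1e-12)
        assert expected < 3.6  # staggering brings carbons closer than the planes

    def test_rings_sharing_an_atom_have_zero_proximal_distance(self):
        a = hexagon_ring((0, 0, 0))
        shared = a.ring_coords[0]
        b_coords = a.ring_coords + (np.array([3.0, 0.0, 0.0]))
        b_coords[0] = shared
        b = ring_from_coords(b_coords)
        assert proximal_cc_distance(a, b) == 0.0

    def test_proximal_bounded_by_centroid_distance_and_circumradius(self, rng):
        for _ in range(20):
            ca, cb = rng.normal(scale=6, size=(2, 3))
            na, nb = rng.normal(size=(2, 3))
            a = hexagon_ring(ca, na / np.linalg.norm(na))
            b = hexagon_ring(cb, nb / np.linalg.norm(nb))
            centroid_d = interaromatic_distance(a, b)
            cc = proximal_cc_distance(a, b)
            assert centroid_d - 2 * 1.39 - 1e-9 <= cc <= centroid_d + 2 * 1.39 + 1e-9


class TestGraph:
    def test_two_rings_one_edge(self):
        a = hexagon_ring((0, 0, 0), seq=1, subunit=0)
        b = hexagon_ring((0, 0, 5.0), seq=1, subunit=1)
        g = nx.Graph()
        g.add_nodes_from([a.key, b.key])
        g.add_edge(a.key, b.key, weight=interaromatic_distance(a, b))
        graph = AromaticGraph(g, {a.key: a, b.key: b})
        path, length = shortest_path(graph, a, b)
        assert [r.key for r in path] == [a.key, b.key]
        assert length == pytest.approx(5.0)

    def test_edge_set_matches_exhaustive_pair_scan(self, gs1_assembly):
        cutoff = 7.0
        graph = build_graph(gs1_assembly, cutoff)
        rings = list(graph.rings.values())
        expected = {
            frozenset((ra.key, rb.key))
            for ra, rb in itertools.combinations(rings, 2)
            if interaromatic_distance(ra, rb) <= cutoff
        }
        got = {frozenset(e) for e in graph.graph.edges}
        assert got == expected

    def test_zero_cutoff_gives_edgeless_graph(self, gs1_assembly):
        graph = build_graph(gs1_assembly, cutoff=1e-9)
        assert graph.graph.number_of_edges() == 0

    def test_assembly_without_aromatics_rejected(self):
        from pilitransport.assembly import HelicalParams, apply_helical_symmetry
        from pilitransport.structure import AtomRecord, PilinStructure, Residue

        atom = AtomRecord(1, "CA", "ALA", "A", 1, np.zeros(3), "C")
        sub = PilinStructure("A", [Residue("ALA", 1, [atom])])
        asm = apply_helical_symmetry(sub, HelicalParams(10.0, 90.0, n_subunits=3))
        with pytest.raises(StructureError):
            build_graph(asm)


def random_ring_graph(rng, n=8, p=0.4):
    rings = {}
    g = nx.Graph()
    for i in range(n):
        r = hexagon_ring(rng.normal(scale=20, size=3), seq=1, subunit=i)
        rings[r.key] = r
        g.add_node(r.key)
    keys = list(rings)
    for a, b in itertools.combinations(keys, 2):
        if rng.random() < p:
            g.add_edge(a, b, weight=float(rng.uniform(0.5, 10)))
    return AromaticGraph(g, rings)


def brute_force_shortest(graph: AromaticGraph, src, dst):
    best = np.inf
    for path in nx.all_simple_paths(graph.graph, src, dst):
        length = sum(
            graph.graph.edges[a, b]["weight"] for a, b in zip(path, path[1:])
        )
        best = min(best, length)
    return best


class TestShortestPath:
    def test_two_hop_route_beats_heavy_direct_edge(self):
        rings = {(i, 1): hexagon_ring((i * 5.0, 0, 0), seq=1, subunit=i) for i in range(3)}
        g = nx.Graph()
        g.add_edge((0, 1), (1, 1), weight=1.0)
        g.add_edge((1, 1), (2, 1), weight=1.0)
        g.add_edge((0, 1), (2, 1), weight=3.0)
        graph = AromaticGraph(g, rings)
        path, length = shortest_path(graph, rings[(0, 1)], rings[(2, 1)])
        assert length == pytest.approx(2.0)
        assert [r.key for r in path] == [(0, 1), (1, 1), (2, 1)]

    def test_source_equals_target(self, gs1_assembly):
        graph = build_graph(gs1_assembly)
        ring = graph.find(0, 1)
        path, length = shortest_path(graph, ring, ring)
        assert [r.key for r in path] == [(0, 1)]
        assert length == 0.0

    def test_disconnected_returns_no_path(self):
        a = hexagon_ring((0, 0, 0), subunit=0)
        b = hexagon_ring((100, 0, 0), subunit=1)
        g = nx.Graph()
        g.add_nodes_from([a.key, b.key])
        graph = AromaticGraph(g, {a.key: a, b.key: b})
        path, length = shortest_path(graph, a, b)
        assert path is None and length == np.inf

    def test_random_graphs_match_brute_force_and_networkx(self, rng):
        for _ in range(15):
            graph = random_ring_graph(rng)
            keys = list(graph.rings)
            src, dst = keys[0], keys[-1]
            path, length = shortest_path(graph, graph.ring(src), graph.ring(dst))
            if path is None:
                assert not nx.has_path(graph.graph, src, dst)
                continue
            assert length == pytest.approx(brute_force_shortest(graph, src, dst), rel=1e-12)
            assert length == pytest.approx(
                nx.dijkstra_path_length(graph.graph, src, dst), rel=1e-12
            )

    def test_removing_off_path_edge_changes_nothing(self, rng):
        graph = random_ring_graph(rng, n=7, p=0.6)
        keys = sorted(graph.rings)
        src, dst = keys[0], keys[-1]
        path, length = shortest_path(graph, graph.ring(src), graph.ring(dst))
        if path is None:
            pytest.skip("random draw disconnected")
        on_path = {frozenset(p) for p in zip([r.key for r in path], [r.key for r in path][1:])}
        off = [e for e in graph.graph.edges if frozenset(e) not in on_path]
        if off:
            graph.graph.remove_edge(*off[0])
            _, length2 = shortest_path(graph, graph.ring(src), graph.ring(dst))
            assert length2 == pytest.approx(length, rel=1e-12)


class TestSymmetricUnit:
    @pytest.mark.parametrize(
        "planted,bottleneck",
        [(GS1_DISTANCES, 6.1), (GS2_DISTANCES, 5.9), ((5.0, 5.0, 5.0), 5.0)],
    )
    def test_planted_distances_recovered(self, planted, bottleneck):
        asm = make_pathway_pilus(SyntheticSpec(distances=planted))
        graph = build_graph(asm, 7.0)
        path, _ = shortest_path(graph, graph.find(0, 1), graph.find(asm.n_subunits - 1, 1))
        unit = extract_symmetric_unit(path, subunit_p=7)
        assert unit.is_canonical
        assert unit.distances == pytest.approx(planted, abs=1e-9)
        assert bottleneck_distance(unit) == pytest.approx(bottleneck, abs=1e-9)
        # unit membership: F1(P-1) -> F24 -> Y27 -> F1(P)
        assert [(r.residue_type, r.residue_seq) for r in unit.rings] == [
            ("F", 1), ("F", 24), ("Y", 27), ("F", 1),
        ]

    def test_distances_repeat_with_helical_period(self, gs1_assembly):
        graph = build_graph(gs1_assembly, 7.0)
        path, _ = shortest_path(
            graph, graph.find(0, 1), graph.find(gs1_assembly.n_subunits - 1, 1)
        )
        units = [extract_symmetric_unit(path, subunit_p=p) for p in range(2, 15)]
        for unit in units[1:]:
            assert unit.distances == pytest.approx(units[0].distances, abs=1e-6)

    def test_missing_middle_ring_warns_with_membership(self, gs1_assembly):
        graph = build_graph(gs1_assembly, 7.0)
        path, _ = shortest_path(
            graph, graph.find(0, 1), graph.find(gs1_assembly.n_subunits - 1, 1)
        )
        truncated = [r for r in path if not (r.residue_seq == 24 and r.subunit_index == 6)]
        with pytest.warns(PathwayWarning, match="3 rings"):
            unit = extract_symmetric_unit(truncated, subunit_p=7)
        assert not unit.is_canonical
        assert len(unit.rings) == 3

    def test_bottleneck_of_equal_distances(self):
        asm = make_pathway_pilus(SyntheticSpec(distances=(5.0, 5.0, 5.0)))
        graph = build_graph(asm, 7.0)
        path, _ = shortest_path(graph, graph.find(0, 1), graph.find(asm.n_subunits - 1, 1))
        unit = extract_symmetric_unit(path)
        assert bottleneck_distance(unit) == pytest.approx(5.0, abs=1e-9)
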