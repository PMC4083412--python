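import networkx as nx
import numpy as np
import pytest

from oracles import brute_centralities

from rinstab.rin import (
    RIN,
    build_rin,
    centralities_by_subnetwork,
    neighbor_composition,
    node_centralities,
    subnetworks,
)
from rinstab.structure_io import Atom, Residue, Structure


def _res(seq_id, aa, atoms, chain="A"):
    return Residue(chain, str(seq_id), aa, atoms)


def _ala(seq_id, origin):
    """Minimal alanine: CA + CB at a given origin."""
    o = np.asarray(origin, dtype=float)
    return _res(seq_id, "ALA", [Atom("CA", "C", o), Atom("CB", "C", o + [1.5, 0, 0])])


def _spacer_structure(gap):
    """Residues 1 and 3 with closest atoms exactly `gap` apart (residue 2 far away)."""
    r1 = _ala(1, [0, 0, 0])  # CB at (1.5, 0, 0)
    r2 = _ala(2, [0, 50, 0])
    r3 = _ala(3, [1.5 + gap, 0, 0])  # CA at closest approach to r1's CB
    return Structure("toy", "A", [r1, r2, r3])


class TestBuildRin:
    def test_iac_distance_threshold(self):
        near = build_rin(_spacer_structure(4.9))
        far = build_rin(_spacer_structure(5.1))
        key = (("A", "1"), ("A", "3"))
        assert any((e.u, e.v) == key and e.etype == "IAC" for e in near.edges)
        assert not any((e.u, e.v) == key for e in far.edges)

    def test_iac_edge_stores_brute_force_minimum(self):
        s = _spacer_structure(4.9)
        net = build_rin(s)
        edge = next(e for e in net.edges if e.etype == "IAC")
        all_d = [np.linalg.norm(a.coord - b.coord)
                 for a in s.residues[0].atoms for b in s.residues[2].atoms]
        assert edge.distance == pytest.approx(min(all_d))

    def test_sequence_separation_excludes_adjacent(self):
        r1 = _ala(1, [0, 0, 0])
        r2 = _ala(2, [3.0, 0, 0])
        r3 = _ala(3, [50, 0, 0])
        net = build_rin(Structure("t", "A", [r1, r2, r3]))
        assert not any({e.u, e.v} == {("A", "1"), ("A", "2")} for e in net.edges)

    def test_ionic_edge(self):
        lys = _res(1, "LYS", [Atom("CA", "C", [0, 0, 0]), Atom("NZ", "N", [0, 0, 5])])
        spacer = _ala(2, [0, 50, 0])
        asp = _res(3, "ASP", [Atom("CA", "C", [10, 0, 0]),
                              Atom("OD1", "O", [0, 3.8, 5])])
        net = build_rin(Structure("t", "A", [lys, spacer, asp]))
        etypes = {e.etype for e in net.edges if {e.u, e.v} == {("A", "1"), ("A", "3")}}
        assert "IONIC" in etypes
        assert "IAC" in etypes  # 3.8 < 5.0 also fires the generic contact

    def test_pipistack_threshold(self):
        def phe(seq_id, z):
            ring = [Atom(n, "C", [np.cos(k), np.sin(k), z])
                    for n, k in zip(("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
                                    np.linspace(0, 2 * np.pi, 6, endpoint=False))]
            return _res(seq_id, "PHE", [Atom("CA", "C", [3, 0, z])] + ring)

        near = build_rin(Structure("t", "A", [phe(1, 0), _ala(2, [0, 50, 0]), phe(3, 6.0)]))
        far = build_rin(Structure("t", "A", [phe(1, 0), _ala(2, [0, 50, 0]), phe(3, 7.0)]))
        assert any(e.etype == "PIPISTACK" for e in near.edges)
        assert not any(e.etype == "PIPISTACK" for e in far.edges)

    def test_symmetric_under_residue_reversal(self):
        s, _ = __import__("rinstab.datasets", fromlist=["make_fixture_structure"]) \
            .make_fixture_structure("helix", 12, sequence="ACDEFGHIKLMN")
        net_fwd = build_rin(s)
        rev = Structure(s.pdb_id, "A", list(reversed(s.residues)))
        net_rev = build_rin(rev)
        as_set = lambda net: {(frozenset((e.u, e.v)), e.etype) for e in net.edges}
        assert as_set(net_fwd) == as_set(net_rev)

    def test_cutoff_monotonicity(self):
        s, _ = __import__("rinstab.datasets", fromlist=["make_fixture_structure"]) \
            .make_fixture_structure("hairpin", 14)
        small = {(frozenset((e.u, e.v))) for e in build_rin(s, contact_cutoff=4.0).edges
                 if e.etype == "IAC"}
        large = {(frozenset((e.u, e.v))) for e in build_rin(s, contact_cutoff=5.5).edges
                 if e.etype == "IAC"}
        assert small <= large

    def test_too_small_structure_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            build_rin(Structure("t", "A", [_ala(1, [0, 0, 0])]))
        with pytest.raises(ValueError, match="positive"):
            build_rin(_spacer_structure(4.0), contact_cutoff=-1.0)


class TestSubnetworks:
    def test_six_subnetworks_full_node_set(self):
        net = build_rin(_spacer_structure(4.9))
        subs = subnetworks(net)
        assert set(subs) == {"HBOND", "IAC", "PIPISTACK", "PICATION", "IONIC", "ALL"}
        assert all(sub.size == net.size for sub in subs.values())
        assert len(subs["HBOND"].edges) == 0  # only IAC fires here
        assert len(subs["ALL"].edges) == len(net.edges)

    def test_typed_edge_counts_bound_distinct_pairs(self):
        lys = _res(1, "LYS", [Atom("CA", "C", [0, 0, 0]), Atom("NZ", "N", [0, 0, 5])])
        spacer = _ala(2, [0, 50, 0])
        asp = _res(3, "ASP", [Atom("CA", "C", [10, 0, 0]), Atom("OD1", "O", [0, 3.8, 5])])
        net = build_rin(Structure("t", "A", [lys, spacer, asp]))
        subs = subnetworks(net)
        typed_total = sum(len(subs[t].edges) for t in
                          ("HBOND", "IAC", "PIPISTACK", "PICATION", "IONIC"))
        distinct_pairs = len({frozenset((e.u, e.v)) for e in net.edges})
        assert typed_total >= distinct_pairs


def _rin_from_graph(g: nx.Graph) -> RIN:
    nodes = {("A", str(v)): "ALA" for v in g.nodes}
    from rinstab.rin import RINEdge

    edges = [RINEdge(("A", str(u)), ("A", str(v)), "IAC", 1.0, ("CA", "CA"))
             for u, v in g.edges]
    return RIN(nodes, edges)


class TestCentralities:
    def test_triangle(self):
        g = nx.complete_graph(3)
        r = _rin_from_graph(g)
        c = node_centralities(r, ("A", "0"))
        assert c == {"degree": 2.0, "clustering": 1.0, "closeness": 1.0, "betweenness": 0.0}

    def test_path_center(self):
        r = _rin_from_graph(nx.path_graph(3))
        c = node_centralities(r, ("A", "1"))
        assert c["betweenness"] == pytest.approx(1.0)
        assert c["closeness"] == pytest.approx(1.0)

    def test_isolated_node_conventions(self):
        g = nx.Graph()
        g.add_nodes_from([0, 1, 2])
        g.add_edge(1, 2)
        c = node_centralities(_rin_from_graph(g), ("A", "0"))
        assert c == {"degree": 0.0, "clustering": 0.0, "closeness": 0.0, "betweenness": 0.0}

    def test_unknown_node(self):
        with pytest.raises(KeyError):
            node_centralities(_rin_from_graph(nx.path_graph(3)), ("A", "99"))

    def test_matches_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(42)
        for trial in range(100):
            n = int(rng.integers(2, 31))
            p = float(rng.uniform(0.05, 0.5))
            g = nx.gnp_random_graph(n, p, seed=int(rng.integers(0, 2**31)))
            r = _rin_from_graph(g)
            expected = brute_centralities(n, list(g.edges))
            got = centralities_by_subnetwork(r)["IAC"]
            for v in g.nodes:
                for measure in ("degree", "clustering", "closeness", "betweenness"):
                    assert got[("A", str(v))][measure] == pytest.approx(
                        expected[measure][v], abs=1e-9), (trial, v, measure)


class TestNeighborComposition:
    def test_counts_by_type(self):
        # residue 1 contacts ALA(3), ALA(4), GLY(5); residue 2 is far away
        center = _ala(1, [0, 0, 0])
        far = _ala(2, [50, 0, 0])
        a1 = _ala(3, [0, 3, 0])
        a2 = _ala(4, [0, -3, 0])
        g = _res(5, "GLY", [Atom("CA", "C", [0, 0, 3])])
        net = build_rin(Structure("t", "A", [center, far, a1, a2, g]))
        counts, size = neighbor_composition(net, ("A", "1"))
        from rinstab._aa import AA_INDEX

        assert counts[AA_INDEX["ALA"]] == 2
        assert counts[AA_INDEX["GLY"]] == 1
        assert counts.sum() == 3
        assert size == 5

    def test_isolated_node_zero_vector(self):
        net = build_rin(_spacer_structure(4.9))
        counts, _ = neighbor_composition(net, ("A", "2"))
        assert counts.sum() == 0

    def test_multi_edge_neighbor_counted_once(self):
        lys = _res(1, "LYS", [Atom("CA", "C", [0, 0, 0]), Atom("NZ", "N", [0, 0, 5])])
        spacer = _ala(2, [0, 50, 0])
        asp = _res(3, "ASP", [Atom("CA", "C", [10, 0, 0]), Atom("OD1", "O", [0, 3.8, 5])])
        net = build_rin(Structure("t", "A", [lys, spacer, asp]))
        counts, _ = neighbor_composition(net, ("A", "1"))
        assert counts.sum() == 1
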