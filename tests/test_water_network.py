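import itertools

import numpy as np
import pytest

from etsface.errors import EtsfaceError
from etsface.structure_io import superpose
from etsface.synthetic_structures import (
    build_water_network_complex,
    perturb_structure,
)
from etsface.water_network import (
    AssignmentSolution,
    HBondGraph,
    Node,
    build_hbond_graph,
    conserved_waters,
    enumerate_h_assignments,
    find_bridging_waters,
    selectivity_report,
)
from etsface.contacts import AtomRef
from conftest import random_rotation


class TestBridgingWaters:
    def test_planted_network_gives_four_bridges(self, water_complex):
        st, truth = water_complex
        bridges = find_bridging_waters(st)
        assert len(bridges) == truth["n_waters"]
        for b in bridges:
            assert b.protein_partners and b.dna_partners

    def test_bridge_partners_match_planted_edges(self, water_complex):
        st, truth = water_complex
        bridges = {b.water.seq_id: b for b in find_bridging_waters(st)}
        for (chain, wi), expected in truth["water_edges"].items():
            got = {(r.chain_id, r.seq_id, r.atom_name)
                   for r, _ in bridges[wi].protein_partners + bridges[wi].dna_partners}
            got |= {(r.chain_id, r.seq_id, r.atom_name)
                    for r, _ in bridges[wi].water_partners}
            want = {(c, s, a if len(t) > 2 else "O")
                    for t in expected for c, s, a in [t if len(t) == 3 else (*t, "O")]}
            assert got == want

    def test_no_waters_warns_empty(self, consensus_duplex):
        with pytest.warns(UserWarning):
            assert find_bridging_waters(consensus_duplex) == []

    def test_equals_all_pairs_oracle(self, water_complex):
        st, _ = water_complex
        got = {b.water.seq_id: ({r.seq_id for r, _ in b.protein_partners},
                                {r.seq_id for r, _ in b.dna_partners})
               for b in find_bridging_waters(st)}
        from etsface.water_network import _polar_class
        records = list(st.atom_records())
        expected = {}
        for chw, rw, aw in records:
            if rw.kind != "water":
                continue
            prot, dna = set(), set()
            for ch, r, a in records:
                if r.kind in ("water",):
                    continue
                if _polar_class(r.kind, r.name, a.name) is None:
                    continue
                if np.linalg.norm(aw.xyz - a.xyz) <= 3.5:
                    (prot if r.kind == "protein" else dna).add(r.seq_id)
            if prot and dna:
                expected[rw.seq_id] = (prot, dna)
        assert got == expected


class TestConservation:
    def test_same_structure_twice_all_conserved(self, water_complex):
        st, _ = water_complex
        clusters = conserved_waters([st, st.copy()])
        assert sum(c.conserved for c in clusters) == 4
        assert all(c.max_pair_distance < 1e-9 for c in clusters if c.conserved)

    def test_conserved_across_transform_and_noise(self, water_complex, rng):
        st, _ = water_complex
        # noise kept small: planted bonds sit at up to 3.3 A, only 0.2 A
        # inside the 3.5 A bridge criterion
        other = perturb_structure(
            st.transformed(random_rotation(rng), rng.uniform(-20, 20, 3)),
            0.05, seed=8)
        clusters = conserved_waters([st, other])
        assert sum(c.conserved for c in clusters) == 4

    def test_decoy_water_not_conserved(self, water_complex):
        st, _ = water_complex
        with_decoy, _ = build_water_network_complex(include_extra_water=True)
        clusters = conserved_waters([st, with_decoy])
        assert sum(c.conserved for c in clusters) == 4
        assert sum(not c.conserved for c in clusters) == 1

    def test_symmetric_in_structure_order(self, water_complex, rng):
        st, _ = water_complex
        other = perturb_structure(st, 0.1, seed=3)
        a = conserved_waters([st, other])
        b = conserved_waters([other, st])
        assert sum(c.conserved for c in a) == sum(c.conserved for c in b)

    def test_needs_two_structures(self, water_complex):
        with pytest.raises(EtsfaceError):
            conserved_waters([water_complex[0]])


def _graph(nodes, edges):
    return HBondGraph(nodes=nodes, edges=[(i, j, 3.0) for i, j in edges])


def _node(name, chem, don=None, acc=None):
    defaults = {"water": (2, 2), "donor_only": (2, 0),
                "acceptor_only": (0, 2), "ambivalent": (1, 2)}
    d, a = defaults[chem]
    return Node(ref=AtomRef("Z", "XXX", hash(name) % 1000, name),
                chem=chem, max_don=d if don is None else don,
                max_acc=a if acc is None else acc)


class TestEnumerate:
    def test_water_between_two_phosphates_forced(self):
        """A single water flanked by two pure acceptors donates both."""
        g = _graph([_node("W", "water"), _node("OP1", "acceptor_only"),
                    _node("OP2", "acceptor_only")], [(0, 1), (0, 2)])
        sols = enumerate_h_assignments(g)
        assert len(sols) == 1
        assert sols[0].directions == (True, True)

    def test_capacity_forced_four_edges(self):
        """Water with two donor-only and two acceptor-only partners has
        exactly one arrangement: accept two, donate two."""
        g = _graph([_node("W", "water"),
                    _node("NH1", "donor_only"), _node("NZ", "donor_only"),
                    _node("O1", "acceptor_only"), _node("O2", "acceptor_only")],
                   [(0, 1), (0, 2), (0, 3), (0, 4)])
        sols = enumerate_h_assignments(g)
        assert len(sols) == 1

    def test_oversize_graph_refused(self):
        nodes = [_node(f"W{i}", "water") for i in range(27)]
        edges = [(i, i + 1) for i in range(26)]
        with pytest.raises(EtsfaceError):
            enumerate_h_assignments(_graph(nodes, edges))

    def test_planted_network_unique_solution(self, water_complex):
        """The recognition-site network admits exactly one hydrogen
        arrangement, in which the base-facing water accepts from N4."""
        st, truth = water_complex
        bridges = find_bridging_waters(st)
        g = build_hbond_graph(st, bridges)
        assert g.n_edges == 12
        sols = enumerate_h_assignments(g)
        assert len(sols) == 1
        rep = selectivity_report(g, sols)
        assert rep.unique
        assert rep.water_role == "acceptor"
        assert rep.base_water.chain_id == truth["base_facing_water"][0]
        assert rep.base_water.seq_id == truth["base_facing_water"][1]
        assert [b for b, _ in rep.allowed_bases] == ["C", "A"]

    @pytest.mark.parametrize("seed", range(100))
    def test_equals_bruteforce_oracle_on_random_graphs(self, seed):
        """Pruned enumeration equals the naive filter over all 2^E direction
        assignments on random graphs up to 12 edges."""
        rng = np.random.default_rng(seed)
        n_nodes = int(rng.integers(3, 8))
        chems = list(np.array(["water", "donor_only", "acceptor_only",
                               "ambivalent"])[rng.integers(0, 4, n_nodes)])
        nodes = [_node(f"n{i}", c) for i, c in enumerate(chems)]
        possible = list(itertools.combinations(range(n_nodes), 2))
        rng.shuffle(possible)
        edges = possible[:int(rng.integers(2, min(13, len(possible) + 1)))]
        g = _graph(nodes, edges)
        got = {s.directions for s in enumerate_h_assignments(g)}

        expected = set()
        for dirs in itertools.product([True, False], repeat=len(edges)):
            don = [0] * n_nodes
            acc = [0] * n_nodes
            ok = True
            for (i, j), fwd in zip(edges, dirs):
                a, b = (i, j) if fwd else (j, i)
                don[a] += 1
                acc[b] += 1
            for k, node in enumerate(nodes):
                if don[k] > node.max_don or acc[k] > node.max_acc:
                    ok = False
            if ok:
                expected.add(tuple(dirs))
        assert got == expected

    def test_solution_count_invariant_under_relabeling(self, water_complex, rng):
        st, _ = water_complex
        bridges = find_bridging_waters(st)
        g = build_hbond_graph(st, bridges)
        n = len(g.nodes)
        perm = list(rng.permutation(n))
        remap = {old: new for new, old in enumerate(perm)}
        nodes2 = [g.nodes[old] for old in perm]
        edges2 = []
        for i, j, d in g.edges:
            a, b = remap[i], remap[j]
            edges2.append((min(a, b), max(a, b), d))
        g2 = HBondGraph(nodes=nodes2, edges=edges2)
        assert len(enumerate_h_assignments(g2)) == \
            len(enumerate_h_assignments(g))


class TestSelectivity:
    def test_forced_donor_variant_allows_g_and_t(self):
        """If the base-edge water is forced to donate, the allowed bases
        flip to those with exocyclic acceptors (G via O6, T via O4)."""
        # water's other partners: two donor_only sites saturate acceptance,
        # one acceptor_only site plus the base edge consume its donations
        nodes = [_node("W", "water"), _node("NH1", "donor_only"),
                 _node("NZ", "donor_only"), _node("OP1", "acceptor_only"),
                 Node(ref=AtomRef("X", "DG", 4, "O6"), chem="acceptor_only",
                      max_don=0, max_acc=2)]
        g = _graph(nodes, [(0, 1), (0, 2), (0, 3), (0, 4)])
        sols = enumerate_h_assignments(g)
        assert len(sols) == 1
        rep = selectivity_report(g, sols)
        assert rep.water_role == "donor"
        assert [b for b, _ in rep.allowed_bases] == ["G", "T"]

    def test_ambiguous_network_reported_not_asserted(self):
        g = _graph([_node("W1", "water"), _node("W2", "water")], [(0, 1)])
        sols = enumerate_h_assignments(g)
        assert len(sols) == 2
        rep = selectivity_report(g, sols)
        assert not rep.unique
        assert rep.allowed_bases == []
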