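import numpy as np
import pytest

from etsface.errors import EtsfaceError
from etsface.modifications import (
    add_5_methyl,
    add_phosphoserine,
    clash_scan,
    phosphoserine_rotamer_scan,
)
from etsface.structure_io import Atom, Chain, Residue, Structure
from etsface.synthetic_structures import (
    PlantedComplexSpec,
    PlantedContact,
    build_bdna,
    build_planted_complex,
)
from conftest import random_rotation


def _methyl_zmatrix_oracle(c4, c5, c6):
    """Independent internal-coordinate construction of the 5-methyl carbon:
    1.50 A from C5, equal angles to C4 and C6, in the ring plane."""
    u = (c4 - c5) / np.linalg.norm(c4 - c5)
    v = (c6 - c5) / np.linalg.norm(c6 - c5)
    normal = np.cross(u, v)
    normal /= np.linalg.norm(normal)
    # solve for the in-plane unit vector w with w.u = w.v = cos(theta),
    # theta the half-angle of the exterior sector
    interior = np.arccos(np.clip(np.dot(u, v), -1, 1))
    theta = np.pi - interior / 2
    e1 = u
    e2 = np.cross(normal, u)
    # w = cos(a) e1 + sin(a) e2 with w.u = cos a = cos theta, pick the sign
    # placing w opposite the ring interior
    for sign in (1.0, -1.0):
        w = np.cos(theta) * e1 + sign * np.sin(theta) * e2
        if abs(np.dot(w, v) - np.cos(theta)) < 1e-9:
            return c5 + 1.50 * w
    raise AssertionError("oracle failed to close the construction")


class TestMethylation:
    def test_methyl_geometry(self, consensus_duplex):
        """C7 sits 1.50 A from C5, in the base plane, off the ring."""
        st = add_5_methyl(consensus_duplex, "X", 3)
        res = st.chain("X").residue(3)
        assert res.name == "5CM"
        c7 = res.atom("C7").xyz
        c5 = res.atom("C5").xyz
        assert np.linalg.norm(c7 - c5) == pytest.approx(1.50, abs=0.01)
        # planarity: C7 lies in the C4/C5/C6 plane
        c4, c6 = res.atom("C4").xyz, res.atom("C6").xyz
        n = np.cross(c4 - c5, c6 - c5)
        n /= np.linalg.norm(n)
        assert abs(np.dot(c7 - c5, n)) < 0.05
        for ring_atom in ("C4", "C6", "N3"):
            assert np.linalg.norm(c7 - res.atom(ring_atom).xyz) > 2.0

    def test_matches_zmatrix_oracle(self, consensus_duplex):
        st = add_5_methyl(consensus_duplex, "X", 3)
        res = st.chain("X").residue(3)
        expected = _methyl_zmatrix_oracle(res.atom("C4").xyz, res.atom("C5").xyz,
                                          res.atom("C6").xyz)
        assert np.linalg.norm(res.atom("C7").xyz - expected) < 1e-3

    def test_non_cytosine_rejected(self, consensus_duplex):
        with pytest.raises(EtsfaceError):
            add_5_methyl(consensus_duplex, "X", 4)  # a guanine

    def test_builder_is_local(self, consensus_duplex):
        """All pre-existing atoms are untouched (RMSD exactly 0)."""
        st = add_5_methyl(consensus_duplex, "X", 3)
        before = consensus_duplex.coords()
        names_before = [(c.id, r.seq_id, a.name)
                        for c, r, a in consensus_duplex.atom_records()]
        after = {key: a.xyz for key, a in
                 zip([(c.id, r.seq_id, a.name) for c, r, a in st.atom_records()],
                     [a for _, _, a in st.atom_records()])}
        for key, xyz in zip(names_before, before):
            assert np.array_equal(after[key], xyz)


class TestPhosphoserine:
    @pytest.fixture()
    def ser_complex(self):
        return build_planted_complex(PlantedComplexSpec(planted_hbonds=[
            PlantedContact("SER", 334, "OG", ("X", 5, "OP1"), 3.5)]))

    def test_bond_lengths(self, ser_complex):
        st = add_phosphoserine(ser_complex, "A", 334)
        res = st.chain("A").residue(334)
        assert res.name == "SEP"
        og, p = res.atom("OG").xyz, res.atom("P").xyz
        assert np.linalg.norm(p - og) == pytest.approx(1.61, abs=0.01)
        terminal = [res.atom(f"O{k}P").xyz for k in (1, 2, 3)]
        for o in terminal:
            assert np.linalg.norm(o - p) == pytest.approx(1.48, abs=0.01)
        # tetrahedral terminal oxygens: O-O = 2*1.48*sin(109.5/2)
        expected_oo = 2 * 1.48 * np.sin(np.deg2rad(109.5 / 2))
        for a, b in ((0, 1), (0, 2), (1, 2)):
            assert np.linalg.norm(terminal[a] - terminal[b]) == \
                pytest.approx(expected_oo, abs=0.05)

    def test_torsion_rotates_only_phosphate(self, ser_complex):
        a = add_phosphoserine(ser_complex, "A", 334, torsion=0.0)
        b = add_phosphoserine(ser_complex, "A", 334, torsion=120.0)
        pa = a.chain("A").residue(334).atom("P").xyz
        pb = b.chain("A").residue(334).atom("P").xyz
        assert np.linalg.norm(pa - pb) > 0.5
        og_a = a.chain("A").residue(334).atom("OG").xyz
        og_b = b.chain("A").residue(334).atom("OG").xyz
        assert np.array_equal(og_a, og_b)

    def test_rotamer_scan_reports_proximity(self, ser_complex):
        rows = phosphoserine_rotamer_scan(ser_complex, "A", 334, step=30.0)
        assert len(rows) == 12
        dists = [r["min_phosphate_dna_distance"] for r in rows]
        assert all(d is not None and d > 0 for d in dists)
        # facing-the-backbone rotamers must come closer than averted ones
        assert min(dists) < max(dists)

    def test_non_serine_rejected(self, consensus_duplex):
        with pytest.raises(EtsfaceError):
            add_phosphoserine(consensus_duplex, "X", 3)


class TestClashScan:
    def test_unmodified_structure_empty(self, consensus_duplex):
        assert clash_scan(consensus_duplex) == []

    def test_isolated_methylated_cytosine_no_partners(self):
        st = build_bdna("ACGT")
        only = Structure(id="frag", chains=[Chain(id="X", residues=[
            st.chain("X").residue(2)])])
        mod = add_5_methyl(only, "X", 2)
        assert clash_scan(mod) == []

    def test_overlap_arithmetic(self):
        """A planted atom 2.0 A from a methyl carbon (both C, r=1.70)
        overlaps by 1.40 A: severity clash."""
        st = build_bdna("ACCGGAAGTG")
        mod = add_5_methyl(st, "X", 3)
        c7 = mod.chain("X").residue(3).atom("C7")
        probe = Residue(name="ALA", seq_id=999, chain_id="Z")
        probe.atoms.append(Atom(name="CB", element="C",
                                xyz=c7.xyz + np.array([0, 0, 2.0])))
        mod.chains.append(Chain(id="Z", residues=[probe]))
        recs = [r for r in clash_scan(mod)
                if r.b.seq_id == 999 or r.a.seq_id == 999]
        assert len(recs) == 1
        assert recs[0].distance == pytest.approx(2.0, abs=1e-9)
        assert recs[0].overlap == pytest.approx(1.40, abs=1e-9)
        assert recs[0].severity == "clash"

    def test_equals_bruteforce_oracle(self, consensus_duplex):
        from etsface.chemistry import vdw_radius
        mod = add_5_methyl(add_5_methyl(consensus_duplex, "X", 3), "Y", 7)
        got = {(r.a.residue_key, r.a.atom_name, r.b.residue_key, r.b.atom_name):
               round(r.overlap, 9) for r in clash_scan(mod)}
        mod_keys = set(mod.meta["modified_atoms"])
        expected = {}
        records = list(mod.atom_records())
        for ch1, r1, a1 in records:
            if (ch1.id, r1.seq_id, a1.name) not in mod_keys:
                continue
            for ch2, r2, a2 in records:
                if (ch2.id, r2.seq_id) == (ch1.id, r1.seq_id):
                    continue
                if (ch2.id, r2.seq_id, a2.name) in mod_keys:
                    continue
                d = float(np.linalg.norm(a1.xyz - a2.xyz))
                ov = vdw_radius(a1.element) + vdw_radius(a2.element) - d
                if ov > 0:
                    expected[((ch1.id, r1.seq_id), a1.name,
                              (ch2.id, r2.seq_id), a2.name)] = round(ov, 9)
        assert got == expected

    def test_clash_list_invariant_under_rigid_transform(self, consensus_duplex, rng):
        mod = add_5_methyl(consensus_duplex, "X", 3)
        moved = mod.transformed(random_rotation(rng), rng.uniform(-15, 15, 3))
        moved.meta = dict(mod.meta)
        a = [(r.a.atom_name, r.b.atom_name, round(r.overlap, 6))
             for r in clash_scan(mod)]
        b = [(r.a.atom_name, r.b.atom_name, round(r.overlap, 6))
             for r in clash_scan(moved)]
        assert a == b
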