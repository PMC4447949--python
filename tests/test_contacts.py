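import numpy as np
import pytest

from etsface.chemistry import (
    BASE_MAJOR_ATOMS,
    BASE_MINOR_ATOMS,
    DNA_BACKBONE_ATOMS,
    DNA_SUGAR_ATOMS,
    STANDARD_BASE_COORDS,
)
from etsface.contacts import (
    build_contact_map,
    classify_dna_contact,
    contacted_bp_span,
    find_hbonds,
    find_salt_bridges,
    find_vdw_contacts,
)
from etsface.dna_geometry import find_base_pairs
from etsface.synthetic_structures import (
    PlantedComplexSpec,
    PlantedContact,
    build_planted_complex,
)
from conftest import random_rotation


class TestPlantedRecovery:
    def test_planted_ser_og_hbond(self):
        st = build_planted_complex(PlantedComplexSpec(planted_hbonds=[
            PlantedContact("SER", 10, "OG", ("X", 5, "OP1"), 2.9)]))
        hb = find_hbonds(st)
        assert len(hb) == 1
        assert hb[0].distance == pytest.approx(2.9, abs=0.05)
        assert (hb[0].donor.res_name, hb[0].donor.atom_name) == ("SER", "OG")

    def test_planted_lys_salt_bridge_not_reported_as_hbond(self):
        st = build_planted_complex(PlantedComplexSpec(planted_salt_bridges=[
            PlantedContact("LYS", 20, "NZ", ("X", 6, "OP2"), 3.2)]))
        sb = find_salt_bridges(st)
        assert len(sb) == 1
        assert sb[0].distance == pytest.approx(3.2, abs=0.05)
        assert find_hbonds(st) == []  # exclusive classification

    def test_footprint_residue_sets(self, ets_complex):
        """The planted interface anatomy is recovered exactly: the five
        phosphate-bonded side chains, the four lysine salt bridges, and the
        arginine base contact at +1."""
        st, truth = ets_complex
        pairs = find_base_pairs(st, reference_chain="X")
        cm = build_contact_map(st, pairs)
        assert cm.residues_of_kind("hbond", "phosphate_backbone") == \
            truth["phosphate_hbond_residues"]
        assert cm.residues_of_kind("salt_bridge") == truth["salt_bridge_residues"]
        arg_contacts = [c for c in cm.contacts
                        if c.kind == "hbond" and c.dna_part == "base_major"]
        assert {c.donor.seq_id for c in arg_contacts} == {391}
        assert {c.position_label for c in arg_contacts} <= {1, 2}

    def test_span_of_planted_footprint(self, ets_complex):
        st, truth = ets_complex
        pairs = find_base_pairs(st, reference_chain="X")
        assert contacted_bp_span(st, pairs) == truth["span_bp"]


def _random_two_part_structure(seed, n=25):
    """Small random system: DNA fragment atoms vs protein probe atoms."""
    from etsface.structure_io import Atom, Chain, Residue, Structure

    rng = np.random.default_rng(seed)
    st = Structure(id=f"toy{seed}")
    prot = Chain(id="A")
    names = [("SER", "OG"), ("LYS", "NZ"), ("TYR", "OH"), ("ASP", "OD1"),
             ("GLN", "NE2"), ("ARG", "NH1"), ("THR", "OG1"), ("ALA", "CB")]
    for i in range(n):
        rn, an = names[int(rng.integers(len(names)))]
        res = Residue(name=rn, seq_id=i + 1, chain_id="A")
        res.atoms.append(Atom(name=an, element=an[0], xyz=rng.uniform(0, 14, 3)))
        prot.residues.append(res)
    st.chains.append(prot)
    dna = Chain(id="X")
    dnames = ["OP1", "OP2", "O5'", "N7", "O6", "N4", "C5'"]
    for i in range(n):
        res = Residue(name="DG" if i % 2 else "DC", seq_id=i + 1, chain_id="X")
        an = dnames[int(rng.integers(len(dnames)))]
        if res.name == "DC" and an in ("N7", "O6"):
            an = "N4"
        if res.name == "DG" and an == "N4":
            an = "N7"
        res.atoms.append(Atom(name=an, element=an[0], xyz=rng.uniform(0, 14, 3)))
        dna.residues.append(res)
    st.chains.append(dna)
    return st


class TestBruteForceOracle:
    @pytest.mark.parametrize("seed", range(8))
    def test_hbonds_equal_all_pairs_filter(self, seed):
        """Detection equals an exhaustive all-pairs filter applying the same
        chemistry dictionaries and cutoffs."""
        from etsface.chemistry import (
            BASE_ACCEPTORS,
            BASE_CODE,
            BASE_DONORS,
            DNA_BACKBONE_ACCEPTORS,
            PROTEIN_SC_ACCEPTORS,
            PROTEIN_SC_DONORS,
        )
        st = _random_two_part_structure(seed)
        got = {frozenset([(c.donor.chain_id, c.donor.seq_id, c.donor.atom_name),
                          (c.acceptor.chain_id, c.acceptor.seq_id,
                           c.acceptor.atom_name)])
               for c in find_hbonds(st, exclude_salt_bridges=False)}

        expected = set()
        records = list(st.atom_records())
        for ch1, r1, a1 in records:
            for ch2, r2, a2 in records:
                if (ch1.id, r1.seq_id) == (ch2.id, r2.seq_id):
                    continue
                if {r1.kind, r2.kind} != {"protein", "dna"}:
                    continue
                d, a = (r1, r2) if r1.kind == "protein" else (r2, r1)
                datom, aatom = (a1, a2) if r1.kind == "protein" else (a2, a1)
                donor_ok = datom.name in PROTEIN_SC_DONORS.get(d.name, set()) | {"N"}
                code = BASE_CODE.get(a.name, "")
                acc_ok = aatom.name in DNA_BACKBONE_ACCEPTORS | \
                    (BASE_ACCEPTORS[code] if code else set())
                # also DNA-donor to protein-acceptor orientation
                donor_ok2 = code and aatom.name in BASE_DONORS[code]
                acc_ok2 = datom.name in PROTEIN_SC_ACCEPTORS.get(d.name, set()) | {"O"}
                dist = np.linalg.norm(datom.xyz - aatom.xyz)
                if dist <= 3.5 and ((donor_ok and acc_ok) or (donor_ok2 and acc_ok2)):
                    expected.add(frozenset([(ch1.id, r1.seq_id, a1.name),
                                            (ch2.id, r2.seq_id, a2.name)]))
        assert got == expected

    @pytest.mark.parametrize("seed", range(8))
    def test_salt_bridges_equal_all_pairs_filter(self, seed):
        from etsface.chemistry import DNA_PHOSPHATE_OXYGENS, PROTEIN_CATION_ATOMS
        st = _random_two_part_structure(seed)
        got = {(c.a.residue_key, c.b.residue_key, round(c.distance, 6))
               for c in find_salt_bridges(st)}
        best = {}
        for ch1, r1, a1 in st.atom_records():
            if a1.name not in PROTEIN_CATION_ATOMS.get(r1.name, set()):
                continue
            for ch2, r2, a2 in st.atom_records():
                if r2.kind != "dna" or a2.name not in DNA_PHOSPHATE_OXYGENS:
                    continue
                d = float(np.linalg.norm(a1.xyz - a2.xyz))
                key = ((ch1.id, r1.seq_id), (ch2.id, r2.seq_id))
                if key not in best or d < best[key]:
                    best[key] = d
        expected = {(k[0], k[1], round(d, 6)) for k, d in best.items() if d <= 4.0}
        assert got == expected


class TestInvariants:
    def test_contacts_invariant_under_rigid_transform(self, ets_complex, rng):
        st, _ = ets_complex
        R = random_rotation(rng)
        t = rng.uniform(-30, 30, 3)
        moved = st.transformed(R, t)

        def key_set(contacts):
            return {(frozenset([(c.partners[0].chain_id, c.partners[0].seq_id,
                                 c.partners[0].atom_name),
                                (c.partners[1].chain_id, c.partners[1].seq_id,
                                 c.partners[1].atom_name)]), c.kind)
                    for c in contacts}

        assert key_set(find_hbonds(st)) == key_set(find_hbonds(moved))
        assert key_set(find_salt_bridges(st)) == key_set(find_salt_bridges(moved))

    def test_kind_classes_mutually_exclusive(self, ets_complex):
        st, _ = ets_complex
        pairs = find_base_pairs(st, reference_chain="X")
        cm = build_contact_map(st, pairs)
        seen = {}
        for c in cm.contacts:
            r1, r2 = c.partners
            key = frozenset([(r1.chain_id, r1.seq_id, r1.atom_name),
                             (r2.chain_id, r2.seq_id, r2.atom_name)])
            assert key not in seen, f"pair {key} reported as {seen[key]} and {c.kind}"
            seen[key] = c.kind


class TestSpanAndClassification:
    def test_span_is_inclusive_index_distance(self):
        """A protein touching pairs 2 and 8 of a 10-mer spans 7 bp."""
        spec = PlantedComplexSpec(planted_hbonds=[
            PlantedContact("SER", 1, "OG", ("X", 2, "OP1"), 2.9),
            PlantedContact("THR", 5, "OG1", ("X", 8, "OP1"), 2.9)])
        st = build_planted_complex(spec)
        pairs = find_base_pairs(st, reference_chain="X")
        assert contacted_bp_span(st, pairs) == 7

    def test_span_matches_enumeration_oracle(self, ets_complex):
        st, truth = ets_complex
        pairs = find_base_pairs(st, reference_chain="X")
        vdw = find_vdw_contacts(st, "protein", "dna", 3.9)
        res_to_pair = {}
        for p in pairs:
            res_to_pair[(p.res_i.chain_id, p.res_i.seq_id)] = p.pair_index
            res_to_pair[(p.res_j.chain_id, p.res_j.seq_id)] = p.pair_index
        touched = sorted({res_to_pair[ref.residue_key] for c in vdw
                          for ref in c.partners if ref.residue_key in res_to_pair})
        assert contacted_bp_span(st, pairs) == touched[-1] - touched[0] + 1
        assert set(touched) == truth["contacted_pairs"]

    def test_no_contacts_span_zero(self, consensus_duplex):
        pairs = find_base_pairs(consensus_duplex)
        assert contacted_bp_span(consensus_duplex, pairs) == 0

    @pytest.mark.parametrize("code,resname", [("G", "DG"), ("A", "DA"),
                                              ("C", "DC"), ("T", "DT")])
    def test_every_base_atom_classified_exactly_once(self, code, resname):
        """Backbone/sugar/major/minor atom dictionaries partition every
        template nucleotide atom (exhaustive check)."""
        from etsface.synthetic_structures import _nucleotide_template
        atoms = set(_nucleotide_template(code))
        for name in atoms:
            groups = [name in DNA_BACKBONE_ATOMS, name in DNA_SUGAR_ATOMS,
                      name in BASE_MAJOR_ATOMS[code], name in BASE_MINOR_ATOMS[code]]
            assert sum(groups) == 1, f"{resname} atom {name} in {sum(groups)} groups"

    def test_phosphate_contact_classified_backbone(self, ets_complex):
        st, _ = ets_complex
        pairs = find_base_pairs(st, reference_chain="X")
        hb = find_hbonds(st)
        op_contacts = [classify_dna_contact(c, pairs) for c in hb
                       if c.acceptor.atom_name in ("OP1", "OP2")]
        assert op_contacts
        assert all(c.dna_part == "phosphate_backbone" for c in op_contacts)
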