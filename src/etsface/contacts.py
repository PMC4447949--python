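"""Hydrogen-bond, salt-bridge and van der Waals contact detection.

Heavy-atom criteria (the crystal structures carry no hydrogens):

* hydrogen bond - donor and acceptor chemistry from the per-residue atom
  dictionaries, donor-acceptor distance <= 3.5 A, and, where the donor has
  a covalent antecedent, an antecedent-donor-acceptor angle of at least
  90 degrees;
* salt bridge - charged-group nitrogen (Lys NZ, Arg NE/NH1/NH2) to
  carboxylate or phosphate oxygen within 4.0 A, reported once per residue
  pair at the minimum N-O distance;
* the two classes are mutually exclusive: a pair satisfying the
  salt-bridge chemistry is never also reported as a hydrogen bond.

Histidine ring nitrogens are treated as neutral and ambivalent.  DNA-side
atoms are classified backbone / sugar / base (major or minor groove face),
and base-pair contacts are mapped onto EBS coordinates -3..+6.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .chemistry import (
    BASE_ACCEPTORS,
    BASE_CODE,
    BASE_DONORS,
    BASE_MAJOR_ATOMS,
    BASE_MINOR_ATOMS,
    DNA_BACKBONE_ACCEPTORS,
    DNA_BACKBONE_ATOMS,
    DNA_PHOSPHATE_OXYGENS,
    DNA_SUGAR_ATOMS,
    DONOR_ANTECEDENT,
    PROTEIN_ANION_ATOMS,
    PROTEIN_CATION_ATOMS,
    PROTEIN_SC_ACCEPTORS,
    PROTEIN_SC_DONORS,
)
from .structure_io import Atom, Chain, Residue, Structure, select
from .dna_geometry import BasePair

__all__ = [
    "Contact", "ContactMap", "AtomRef",
    "find_hbonds", "find_salt_bridges", "find_vdw_contacts",
    "contacted_bp_span", "classify_dna_contact", "build_contact_map",
]

DEFAULT_MAX_DA = 3.5
DEFAULT_MAX_NO = 4.0
DEFAULT_ANY_ATOM_CUT = 3.9
MIN_ANTECEDENT_ANGLE = 90.0


@dataclass(frozen=True)
class AtomRef:
    chain_id: str
    res_name: str
    seq_id: int
    atom_name: str

    @property
    def residue_key(self) -> tuple[str, int]:
        return (self.chain_id, self.seq_id)

    def __str__(self):
        return f"{self.res_name}-{self.chain_id}{self.seq_id}:{self.atom_name}"


@dataclass
class Contact:
    kind: str                     # hbond | salt_bridge | vdw
    donor: AtomRef | None         # None for vdw/salt bridges (use a/b)
    acceptor: AtomRef | None
    a: AtomRef | None = None      # unordered partners (salt bridge, vdw)
    b: AtomRef | None = None
    distance: float = 0.0
    dna_part: str = "none"        # phosphate_backbone | sugar | base_major | base_minor | none
    position_label: int | None = None

    @property
    def partners(self) -> tuple[AtomRef, AtomRef]:
        if self.donor is not None:
            return (self.donor, self.acceptor)
        return (self.a, self.b)


def _ref(ch: Chain, res: Residue, atom: Atom) -> AtomRef:
    return AtomRef(ch.id, res.name, res.seq_id, atom.name)


def _donor_sites(ch: Chain, res: Residue) -> list[tuple[AtomRef, Atom, Atom | None]]:
    out = []
    if res.kind == "protein":
        names = set(PROTEIN_SC_DONORS.get(res.name, ()))
        if res.name != "PRO":
            names.add("N")
        for n in names:
            a = res.atom(n)
            if a is not None:
                out.append((_ref(ch, res, a), a, res.atom(DONOR_ANTECEDENT.get(n, ""))))
    elif res.kind == "dna":
        code = BASE_CODE.get(res.name)
        if code:
            for n in BASE_DONORS[code]:
                a = res.atom(n)
                if a is not None:
                    out.append((_ref(ch, res, a), a, res.atom(DONOR_ANTECEDENT.get(n, ""))))
    elif res.kind == "water":
        a = res.atom("O")
        if a is not None:
            out.append((_ref(ch, res, a), a, None))
    return out


def _acceptor_sites(ch: Chain, res: Residue) -> list[tuple[AtomRef, Atom]]:
    out = []
    if res.kind == "protein":
        names = set(PROTEIN_SC_ACCEPTORS.get(res.name, ())) | {"O"}
        for n in names:
            a = res.atom(n)
            if a is not None:
                out.append((_ref(ch, res, a), a))
    elif res.kind == "dna":
        code = BASE_CODE.get(res.name)
        names = set(DNA_BACKBONE_ACCEPTORS)
        if code:
            names |= BASE_ACCEPTORS[code]
        for n in names:
            a = res.atom(n)
            if a is not None:
                out.append((_ref(ch, res, a), a))
    elif res.kind == "water":
        a = res.atom("O")
        if a is not None:
            out.append((_ref(ch, res, a), a))
    return out


def _charged_sites(ch: Chain, res: Residue, polarity: str) -> list[tuple[AtomRef, Atom]]:
    names: set = set()
    if polarity == "cation" and res.kind == "protein":
        names = PROTEIN_CATION_ATOMS.get(res.name, set())
    elif polarity == "anion":
        if res.kind == "protein":
            names = PROTEIN_ANION_ATOMS.get(res.name, set())
        elif res.kind == "dna":
            names = DNA_PHOSPHATE_OXYGENS
    return [(_ref(ch, res, res.atom(n)), res.atom(n)) for n in names
            if res.atom(n) is not None]


def _salt_bridge_pairs(structure: Structure, partA: str, partB: str):
    """Residue-pair keys that qualify as salt bridges (for exclusivity)."""
    sub_a = select(structure, partA)
    sub_b = select(structure, partB)
    out = {}
    for side1, side2 in ((sub_a, sub_b), (sub_b, sub_a)):
        cats = [s for ch in side1.chains for r in ch.residues
                for s in _charged_sites(ch, r, "cation")]
        anis = [s for ch in side2.chains for r in ch.residues
                for s in _charged_sites(ch, r, "anion")]
        for ref_c, atom_c in cats:
            for ref_a, atom_a in anis:
                d = float(np.linalg.norm(atom_c.xyz - atom_a.xyz))
                key = (ref_c.residue_key, ref_a.residue_key)
                if key not in out or d < out[key][0]:
                    out[key] = (d, ref_c, ref_a)
    return out


def find_salt_bridges(structure: Structure, partA: str = "protein",
                      partB: str = "dna", max_no: float = DEFAULT_MAX_NO
                      ) -> list[Contact]:
    """Charged-group N-O pairs within ``max_no``; one record per residue pair."""
    out = []
    for (k1, k2), (d, ref_c, ref_a) in sorted(_salt_bridge_pairs(
            structure, partA, partB).items()):
        if d <= max_no:
            out.append(Contact(kind="salt_bridge", donor=None, acceptor=None,
                               a=ref_c, b=ref_a, distance=d))
    return out


def _antecedent_ok(donor_atom: Atom, antecedent: Atom | None, acceptor_atom: Atom) -> bool:
    if antecedent is None:
        return True
    v1 = antecedent.xyz - donor_atom.xyz
    v2 = acceptor_atom.xyz - donor_atom.xyz
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))) >= MIN_ANTECEDENT_ANGLE


def find_hbonds(structure: Structure, partA: str = "protein",
                partB: str = "dna", max_da: float = DEFAULT_MAX_DA,
                exclude_salt_bridges: bool = True) -> list[Contact]:
    """Hydrogen bonds between two selections (canonicalized, deduplicated).

    Pairs whose atoms carry formal charge (salt-bridge chemistry) are left
    to find_salt_bridges when ``exclude_salt_bridges`` (the default).
    """
    sub_a = select(structure, partA)
    sub_b = select(structure, partB)
    if sub_a.n_atoms == 0 or sub_b.n_atoms == 0:
        warnings.warn("empty selection: no hydrogen bonds", stacklevel=2)
        return []

    charged = set()
    if exclude_salt_bridges:
        for (d, ref_c, ref_a) in _salt_bridge_pairs(structure, partA, partB).values():
            charged.add(frozenset(((ref_c.chain_id, ref_c.seq_id, ref_c.atom_name),
                                   (ref_a.chain_id, ref_a.seq_id, ref_a.atom_name))))

    seen = set()
    out = []
    for side1, side2 in ((sub_a, sub_b), (sub_b, sub_a)):
        donors = [s for ch in side1.chains for r in ch.residues
                  for s in _donor_sites(ch, r)]
        acceptors = [s for ch in side2.chains for r in ch.residues
                     for s in _acceptor_sites(ch, r)]
        if not donors or not acceptors:
            continue
        acc_xyz = np.array([a.xyz for _, a in acceptors])
        tree = cKDTree(acc_xyz)
        for ref_d, atom_d, antecedent in donors:
            for j in tree.query_ball_point(atom_d.xyz, max_da):
                ref_a, atom_a = acceptors[j]
                if ref_d.residue_key == ref_a.residue_key:
                    continue
                pair_key = frozenset((
                    (ref_d.chain_id, ref_d.seq_id, ref_d.atom_name),
                    (ref_a.chain_id, ref_a.seq_id, ref_a.atom_name)))
                if pair_key in seen or pair_key in charged:
                    continue
                if not _antecedent_ok(atom_d, antecedent, atom_a):
                    continue
                seen.add(pair_key)
                out.append(Contact(kind="hbond", donor=ref_d, acceptor=ref_a,
                                   distance=float(np.linalg.norm(
                                       atom_d.xyz - atom_a.xyz))))
    out.sort(key=lambda c: (c.donor.chain_id, c.donor.seq_id, c.donor.atom_name,
                            c.acceptor.chain_id, c.acceptor.seq_id))
    return out


def find_vdw_contacts(structure: Structure, partA: str = "protein",
                      partB: str = "dna",
                      cutoff: float = DEFAULT_ANY_ATOM_CUT,
                      exclude: set | None = None) -> list[Contact]:
    """Any-atom proximity contacts not already classified as polar."""
    sub_a = select(structure, partA)
    sub_b = select(structure, partB)
    rec_a = list(sub_a.atom_records())
    rec_b = list(sub_b.atom_records())
    if not rec_a or not rec_b:
        return []
    xyz_b = np.array([a.xyz for _, _, a in rec_b])
    tree = cKDTree(xyz_b)
    out = []
    seen = set()
    for ch, res, atom in rec_a:
        ref1 = _ref(ch, res, atom)
        for j in tree.query_ball_point(atom.xyz, cutoff):
            chb, resb, atomb = rec_b[j]
            ref2 = _ref(chb, resb, atomb)
            key = frozenset(((ref1.chain_id, ref1.seq_id, ref1.atom_name),
                             (ref2.chain_id, ref2.seq_id, ref2.atom_name)))
            if key in seen or (exclude and key in exclude):
                continue
            seen.add(key)
            out.append(Contact(kind="vdw", donor=None, acceptor=None,
                               a=ref1, b=ref2,
                               distance=float(np.linalg.norm(atom.xyz - atomb.xyz))))
    return out


def classify_dna_contact(contact: Contact, pairs: list[BasePair]) -> Contact:
    """Assign dna_part and the EBS position label to a contact in place."""
    res_index = {}
    for p in pairs:
        for r in (p.res_i, p.res_j):
            res_index[(r.chain_id, r.seq_id)] = p
    dna_ref = None
    for ref in contact.partners:
        if ref is not None and ref.residue_key in res_index:
            dna_ref = ref
            break
    if dna_ref is None:
        # partner may be a nucleotide outside the pairing; fall back on name
        contact.dna_part = "none"
        return contact
    pair = res_index[dna_ref.residue_key]
    name = dna_ref.atom_name
    code = BASE_CODE.get(dna_ref.res_name, "")
    if name in DNA_BACKBONE_ATOMS:
        contact.dna_part = "phosphate_backbone"
    elif name in DNA_SUGAR_ATOMS:
        contact.dna_part = "sugar"
    elif code and name in BASE_MAJOR_ATOMS[code]:
        contact.dna_part = "base_major"
    elif code and name in BASE_MINOR_ATOMS[code]:
        contact.dna_part = "base_minor"
    else:
        contact.dna_part = "none"
    contact.position_label = pair.ebs_position
    return contact


def contacted_bp_span(structure: Structure, pairs: list[BasePair],
                      contacts: list[Contact] | None = None,
                      partA: str = "protein", partB: str = "dna",
                      cutoff: float = DEFAULT_ANY_ATOM_CUT) -> int:
    """Inclusive base-pair span covered by protein-DNA contacts.

    With no explicit contact list, any-atom contacts at ``cutoff`` are used,
    matching the convention of a 9-bp footprint on the consensus duplex.
    """
    if contacts is None:
        contacts = find_vdw_contacts(structure, partA, partB, cutoff)
    res_index = {}
    for p in pairs:
        for r in (p.res_i, p.res_j):
            res_index[(r.chain_id, r.seq_id)] = p.pair_index
    touched = set()
    for c in contacts:
        for ref in c.partners:
            if ref is not None and ref.residue_key in res_index:
                touched.add(res_index[ref.residue_key])
    if not touched:
        return 0
    return max(touched) - min(touched) + 1


@dataclass
class ContactMap:
    contacts: list[Contact] = field(default_factory=list)

    @property
    def by_residue(self) -> dict:
        out: dict = {}
        for c in self.contacts:
            for ref in c.partners:
                if ref is None:
                    continue
                out.setdefault((ref.chain_id, ref.res_name, ref.seq_id), []).append(c)
        return out

    def residues_of_kind(self, kind: str, dna_part: str | None = None) -> set:
        """Protein residues making contacts of a kind (optionally to a DNA part)."""
        out = set()
        for c in self.contacts:
            if c.kind != kind:
                continue
            if dna_part is not None and c.dna_part != dna_part:
                continue
            for ref in c.partners:
                if ref is not None and BASE_CODE.get(ref.res_name) is None \
                        and ref.res_name not in ("HOH", "WAT"):
                    out.add((ref.res_name, ref.seq_id))
        return out

    @property
    def summary(self) -> dict:
        counts: dict = {}
        for c in self.contacts:
            counts[c.kind] = counts.get(c.kind, 0) + 1
            counts[(c.kind, c.dna_part)] = counts.get((c.kind, c.dna_part), 0) + 1
        return counts


def build_contact_map(structure: Structure, pairs: list[BasePair],
                      partA: str = "protein", partB: str = "dna",
                      max_da: float = DEFAULT_MAX_DA,
                      max_no: float = DEFAULT_MAX_NO,
                      vdw_cut: float = DEFAULT_ANY_ATOM_CUT) -> ContactMap:
    """Full classified contact map between a protein and DNA selection."""
    hb = find_hbonds(structure, partA, partB, max_da)
    sb = find_salt_bridges(structure, partA, partB, max_no)
    polar_keys = set()
    for c in hb + sb:
        r1, r2 = c.partners
        polar_keys.add(frozenset(((r1.chain_id, r1.seq_id, r1.atom_name),
                                  (r2.chain_id, r2.seq_id, r2.atom_name))))
    vdw = find_vdw_contacts(structure, partA, partB, vdw_cut, exclude=polar_keys)
    contacts = hb + sb + vdw
    for c in contacts:
        classify_dna_contact(c, pairs)
    return ContactMap(contacts=contacts)
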