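"""In-silico base and side-chain modifications with steric-clash scanning.

Two rigid modifications are modelled, mirroring static modelling on the
crystal coordinates (no geometry relaxation):

* 5-methylcytosine - a methyl carbon (C7) placed in the base plane at
  1.50 A from C5, bisecting the exterior C4-C5-C6 angle; the residue is
  renamed 5CM;
* phosphoserine - a PO3 group esterified on the Ser OG (P-OG 1.61 A,
  P=O 1.48 A, tetrahedral geometry), with the CB-OG-P torsion exposed for
  rotamer scanning.

clash_scan reports every non-bonded atom pair involving the newly built
atoms with positive van der Waals overlap; overlaps of at least 0.4 A are
severity "clash", smaller ones "contact".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chemistry import vdw_radius
from .errors import EtsfaceError
from .structure_io import Atom, Structure
from .contacts import AtomRef

__all__ = ["ClashRecord", "add_5_methyl", "add_phosphoserine", "clash_scan",
           "phosphoserine_rotamer_scan"]

CLASH_OVERLAP = 0.4
MODIFIED_FLAG = "modified_atoms"   # structure.meta key -> list of atom keys


@dataclass
class ClashRecord:
    a: AtomRef
    b: AtomRef
    distance: float
    overlap: float

    @property
    def severity(self) -> str:
        return "clash" if self.overlap >= CLASH_OVERLAP else "contact"


def _get_residue(structure: Structure, chain_id: str, seq_id: int):
    ch = structure.chain(chain_id)
    res = ch.residue(seq_id) if ch else None
    if res is None:
        raise EtsfaceError(f"no residue {chain_id}/{seq_id}")
    return res


def add_5_methyl(structure: Structure, chain_id: str, seq_id: int) -> Structure:
    """Return a copy with the cytosine at (chain, seq_id) 5-methylated."""
    out = structure.copy()
    res = _get_residue(out, chain_id, seq_id)
    if res.name not in ("DC", "C"):
        raise EtsfaceError(f"{res.label} is not a cytosine")
    c5, c4, c6 = res.atom("C5"), res.atom("C4"), res.atom("C6")
    if c5 is None or c4 is None or c6 is None:
        raise EtsfaceError(f"{res.label}: ring atoms C4/C5/C6 required")
    u = (c5.xyz - c4.xyz) / np.linalg.norm(c5.xyz - c4.xyz)
    v = (c5.xyz - c6.xyz) / np.linalg.norm(c5.xyz - c6.xyz)
    bisector = u + v
    bisector /= np.linalg.norm(bisector)
    new_xyz = c5.xyz + 1.50 * bisector
    res.name = "5CM"
    res.atoms.append(Atom(name="C7", element="C", xyz=new_xyz,
                          bfactor=c5.bfactor, occupancy=c5.occupancy))
    out.meta.setdefault(MODIFIED_FLAG, []).append((chain_id, seq_id, "C7"))
    return out


def add_phosphoserine(structure: Structure, chain_id: str, seq_id: int,
                      torsion: float = 180.0) -> Structure:
    """Return a copy with the serine at (chain, seq_id) phosphorylated.

    ``torsion`` is the CB-OG-P dihedral reference in degrees (default
    staggered); the three phosphate oxygens are placed tetrahedrally
    around P.
    """
    out = structure.copy()
    res = _get_residue(out, chain_id, seq_id)
    if res.name != "SER":
        raise EtsfaceError(f"{res.label} is not a serine")
    og, cb = res.atom("OG"), res.atom("CB")
    if og is None or cb is None:
        raise EtsfaceError(f"{res.label}: OG and CB required")
    ca = res.atom("CA")
    axis = (og.xyz - cb.xyz) / np.linalg.norm(og.xyz - cb.xyz)
    # reference perpendicular for the torsion origin
    seed = (ca.xyz - cb.xyz) if ca is not None else np.array([0.0, 0.0, 1.0])
    perp = seed - np.dot(seed, axis) * axis
    if np.linalg.norm(perp) < 1e-6:
        perp = np.cross(axis, [1.0, 0.0, 0.0])
    perp /= np.linalg.norm(perp)
    perp2 = np.cross(axis, perp)

    tors = np.deg2rad(torsion)
    direction = np.cos(np.deg2rad(180 - 119)) * axis + \
        np.sin(np.deg2rad(180 - 119)) * (np.cos(tors) * perp + np.sin(tors) * perp2)
    # P placed at 1.61 A from OG with a ~119 degree CB-OG-P angle
    p_xyz = og.xyz + 1.61 * direction / np.linalg.norm(direction)

    # three terminal oxygens tetrahedral about P, staggered against OG
    po = (p_xyz - og.xyz) / np.linalg.norm(p_xyz - og.xyz)
    ref = perp - np.dot(perp, po) * po
    ref /= np.linalg.norm(ref)
    ref2 = np.cross(po, ref)
    new_atoms = [("P", p_xyz)]
    for k in range(3):
        ang = np.deg2rad(120.0 * k + 60.0)
        d = np.cos(np.deg2rad(180 - 109.5)) * po + \
            np.sin(np.deg2rad(180 - 109.5)) * (np.cos(ang) * ref + np.sin(ang) * ref2)
        new_atoms.append((f"O{k + 1}P", p_xyz + 1.48 * d / np.linalg.norm(d)))
    res.name = "SEP"
    for name, xyz in new_atoms:
        res.atoms.append(Atom(name=name, element=name[0] if name[0] != "O" else "O",
                              xyz=xyz, bfactor=og.bfactor, occupancy=og.occupancy))
        out.meta.setdefault(MODIFIED_FLAG, []).append((chain_id, seq_id, name))
    return out


_EXCLUDE_BOND = 2.0  # same-residue pairs are covalent context, never clashes


def clash_scan(structure: Structure,
               modified: list[tuple[str, int, str]] | None = None
               ) -> list[ClashRecord]:
    """van der Waals overlaps between modification atoms and the rest.

    ``modified`` defaults to the builder-flagged atoms in
    ``structure.meta['modified_atoms']``.  Pairs within the modified residue
    are skipped (covalent context).  Records are sorted by decreasing
    overlap.
    """
    if modified is None:
        modified = structure.meta.get(MODIFIED_FLAG, [])
    mod_keys = set(modified)
    records = []
    mod_atoms = []
    others = []
    for ch, res, a in structure.atom_records():
        entry = (AtomRef(ch.id, res.name, res.seq_id, a.name), a,
                 (ch.id, res.seq_id))
        if (ch.id, res.seq_id, a.name) in mod_keys:
            mod_atoms.append(entry)
        else:
            others.append(entry)
    for ref_m, atom_m, res_m in mod_atoms:
        r_m = vdw_radius(atom_m.element)
        for ref_o, atom_o, res_o in others:
            if res_o == res_m:
                continue
            d = float(np.linalg.norm(atom_m.xyz - atom_o.xyz))
            overlap = r_m + vdw_radius(atom_o.element) - d
            if overlap > 0:
                records.append(ClashRecord(a=ref_m, b=ref_o, distance=d,
                                           overlap=float(overlap)))
    records.sort(key=lambda r: -r.overlap)
    return records


def phosphoserine_rotamer_scan(structure: Structure, chain_id: str, seq_id: int,
                               step: float = 30.0) -> list[dict]:
    """Scan the CB-OG-P torsion and report phosphate-to-DNA proximity.

    For each rotamer, the minimum distance from any built phosphate atom to
    any DNA phosphate-group atom (P, OP1, OP2) is reported together with
    the clash list - the repulsive-proximity picture of a phosphoserine
    facing the DNA backbone.
    """
    out = []
    for torsion in np.arange(0.0, 360.0, step):
        mod = add_phosphoserine(structure, chain_id, seq_id, torsion=float(torsion))
        new_keys = set(mod.meta.get(MODIFIED_FLAG, []))
        mod_xyz = [a.xyz for ch, res, a in mod.atom_records()
                   if (ch.id, res.seq_id, a.name) in new_keys]
        dna_p = [a.xyz for ch, res, a in mod.atom_records()
                 if res.kind == "dna" and a.name in ("P", "OP1", "OP2")]
        min_d = None
        if mod_xyz and dna_p:
            M = np.array(mod_xyz)
            D = np.array(dna_p)
            min_d = float(np.linalg.norm(M[:, None, :] - D[None, :, :],
                                         axis=2).min())
        clashes = clash_scan(mod)
        out.append({"torsion": float(torsion),
                    "min_phosphate_dna_distance": min_d,
                    "n_clashes": sum(1 for c in clashes if c.severity == "clash"),
                    "clashes": clashes})
    return out
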