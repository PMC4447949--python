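"""Synthetic coordinate fixtures: fiber-model B-DNA, planted complexes, noise.

This module is first-class functionality, not test scaffolding: it provides
the canonical straight B-form reference duplex that measured DNA geometry is
compared against, and builds minimal protein-DNA complexes with *planted*
interactions (hydrogen bonds, salt bridges, bridging-water networks) whose
ground truth is known by construction, so that every detection stage of the
pipeline can be validated without any external coordinates.

The duplex generator is an idealized fiber model: each base pair is a rigid
template (standard base-pair reference frame + sugar-phosphate backbone)
stacked with fixed twist (36 deg/step) and rise (3.38 A/step); strand II is
generated from the complementary base template by the Watson-Crick dyad
(180 deg about x).  There is no sequence-dependent shape.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chemistry import (
    BDNA_BACKBONE_TEMPLATE,
    COMPLEMENT,
    STANDARD_BASE_COORDS,
    element_of,
)
from .errors import ConflictError, EtsfaceError
from .structure_io import Atom, Chain, Residue, Structure

__all__ = [
    "BDnaSpec", "PlantedContact", "PlantedWater", "PlantedComplexSpec",
    "build_bdna", "build_kinked_duplex", "perturb_structure",
    "build_planted_complex", "build_ets_like_complex",
    "build_water_network_complex", "build_toy_dimer", "build_ca_domain",
]

DEFAULT_TWIST = 36.0
DEFAULT_RISE = 3.38
_FLIP = np.diag([1.0, -1.0, -1.0])  # Watson-Crick dyad about x
_DNA_RESNAME = {"A": "DA", "C": "DC", "G": "DG", "T": "DT"}


@dataclass
class BDnaSpec:
    """Parameters of an idealized straight B-form duplex."""

    sequence: str
    twist: float = DEFAULT_TWIST   # degrees per base-pair step
    rise: float = DEFAULT_RISE     # Angstrom per step

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - set("ACGT")
        if bad:
            raise EtsfaceError(f"invalid base letter(s) {sorted(bad)} in sequence")
        if len(self.sequence) < 2:
            raise EtsfaceError("duplex needs at least 2 base pairs")
        if not (0.0 < self.twist < 360.0):
            raise EtsfaceError("twist must be in (0, 360) degrees")
        if self.rise <= 0:
            raise EtsfaceError("rise must be positive")


def _rz(deg: float) -> np.ndarray:
    a = np.deg2rad(deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _nucleotide_template(base: str) -> dict[str, np.ndarray]:
    coords = {k: np.array(v) for k, v in STANDARD_BASE_COORDS[base].items()}
    for k, v in BDNA_BACKBONE_TEMPLATE.items():
        coords[k] = np.array(v)
    return coords


def build_bdna(spec: BDnaSpec | str, chain_ids: tuple[str, str] = ("X", "Y"),
               bfactor: float = 20.0) -> Structure:
    """Build an idealized straight B-form duplex for a 5'->3' sequence.

    Strand I (first chain id) carries the given sequence numbered 1..n
    5'->3'; strand II carries the reverse complement, also numbered 1..n in
    its own 5'->3' direction, so strand-II residue j pairs with strand-I
    residue n+1-j.  5'-terminal phosphates (P, OP1, OP2) are omitted on both
    strands, as in the deposited oligonucleotide structures.
    """
    if isinstance(spec, str):
        spec = BDnaSpec(sequence=spec)
    seq = spec.sequence
    n = len(seq)

    def place(level: int, local: dict[str, np.ndarray], flip: bool) -> dict[str, np.ndarray]:
        R = _rz(level * spec.twist)
        shift = np.array([0.0, 0.0, level * spec.rise])
        out = {}
        for name, xyz in local.items():
            p = _FLIP @ xyz if flip else xyz
            out[name] = R @ p + shift
        return out

    st = Structure(id=f"bdna-{seq}", meta={"generator": "fiber", "twist": spec.twist,
                                           "rise": spec.rise, "sequence": seq})
    strand1 = Chain(id=chain_ids[0])
    for i, base in enumerate(seq):
        coords = place(i, _nucleotide_template(base), flip=False)
        if i == 0:
            for name in ("P", "OP1", "OP2"):
                coords.pop(name)
        res = Residue(name=_DNA_RESNAME[base], seq_id=i + 1, chain_id=chain_ids[0])
        res.atoms = [Atom(name=k, element=element_of(k), xyz=v, bfactor=bfactor)
                     for k, v in coords.items()]
        strand1.residues.append(res)
    st.chains.append(strand1)

    strand2 = Chain(id=chain_ids[1])
    comp = "".join(COMPLEMENT[b] for b in reversed(seq))  # strand II 5'->3'
    for j, base in enumerate(comp):
        level = n - 1 - j  # pairs with strand-I residue level
        coords = place(level, _nucleotide_template(base), flip=True)
        if j == 0:
            for name in ("P", "OP1", "OP2"):
                coords.pop(name)
        res = Residue(name=_DNA_RESNAME[base], seq_id=j + 1, chain_id=chain_ids[1])
        res.atoms = [Atom(name=k, element=element_of(k), xyz=v, bfactor=bfactor)
                     for k, v in coords.items()]
        strand2.residues.append(res)
    st.chains.append(strand2)
    return st


def build_kinked_duplex(sequence: str, kink_deg: float,
                        at: int | None = None) -> Structure:
    """Straight duplex with a planted rigid kink of ``kink_deg`` degrees.

    All atoms above the junction plane (between pair ``at`` and ``at+1``,
    default the midpoint) are rotated about an in-plane axis through the
    junction, so the duplex consists of two straight fiber segments whose
    helical axes meet at exactly the planted angle.
    """
    st = build_bdna(sequence)
    n = len(sequence)
    k = at if at is not None else n // 2
    z_cut = (k - 0.5) * DEFAULT_RISE
    a = np.deg2rad(kink_deg)
    c, s = np.cos(a), np.sin(a)
    R = np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])  # about x
    pivot = np.array([0.0, 0.0, z_cut])
    for atom in st.atoms():
        if atom.xyz[2] > z_cut:
            atom.xyz = R @ (atom.xyz - pivot) + pivot
    st.meta["kink_deg"] = kink_deg
    return st


def perturb_structure(structure: Structure, noise_sd: float, seed: int) -> Structure:
    """Copy with i.i.d. Gaussian displacement of every atom; seed-reproducible."""
    if noise_sd < 0:
        raise EtsfaceError("noise_sd must be >= 0")
    out = structure.copy()
    if noise_sd == 0:
        return out
    rng = np.random.default_rng(seed)
    xyz = out.coords()
    out.set_coords(xyz + rng.normal(0.0, noise_sd, xyz.shape))
    out.meta = dict(out.meta, noise_sd=noise_sd, noise_seed=seed)
    return out


# ---------------------------------------------------------------------------
# Planted complexes
#
# Protein probe residues are placed as rigid side-chain templates whose
# interacting atom sits exactly at the requested distance from its target
# DNA atom, with the rest of the residue extending away from the helix.

# Local templates: interacting (anchor) atom at the origin, body extending
# along +x.  Geometry is idealized but keeps realistic bond lengths.
def _backbone(ca: tuple[float, float, float]) -> list[tuple[str, tuple[float, float, float]]]:
    cax, cay, caz = ca
    return [
        ("CA", (cax, cay, caz)),
        ("N", (cax + 0.7, cay + 1.2, caz + 0.5)),
        ("C", (cax + 0.7, cay - 1.2, caz - 0.5)),
        ("O", (cax + 1.7, cay - 1.6, caz - 0.7)),
    ]


_SIDE_CHAIN_TEMPLATES: dict[str, list[tuple[str, tuple[float, float, float]]]] = {
    "SER": [("OG", (0, 0, 0)), ("CB", (1.30, 0.35, 0))] + _backbone((2.55, -0.35, 0)),
    "THR": [("OG1", (0, 0, 0)), ("CB", (1.35, 0.35, 0)), ("CG2", (1.85, 1.55, 0.60))]
           + _backbone((2.60, -0.35, 0)),
    "CYS": [("SG", (0, 0, 0)), ("CB", (1.70, 0.40, 0))] + _backbone((2.95, -0.30, 0)),
    "ALA": [("CB", (0, 0, 0))] + _backbone((1.35, 0.55, 0)),
    "LYS": [("NZ", (0, 0, 0)), ("CE", (1.30, 0.35, 0)), ("CD", (2.60, -0.35, 0)),
            ("CG", (3.90, 0.35, 0)), ("CB", (5.20, -0.35, 0))]
           + _backbone((6.50, 0.35, 0)),
    "ARG": [("NH1", (0, 0, 0)), ("CZ", (1.23, 0.35, 0)), ("NH2", (1.58, 1.62, 0)),
            ("NE", (2.42, -0.45, 0)), ("CD", (3.72, 0.15, 0)), ("CG", (5.00, -0.45, 0)),
            ("CB", (6.30, 0.15, 0))] + _backbone((7.55, -0.45, 0)),
    "TYR": [("OH", (0, 0, 0)), ("CZ", (1.36, 0, 0)),
            ("CE1", (2.06, 1.20, 0)), ("CE2", (2.06, -1.20, 0)),
            ("CD1", (3.45, 1.20, 0)), ("CD2", (3.45, -1.20, 0)),
            ("CG", (4.14, 0, 0)), ("CB", (5.65, 0, 0.20))]
           + _backbone((6.40, 1.10, 0.60)),
    "TRP": [("NE1", (0, 0, 0)), ("CD1", (1.10, 0.85, 0)), ("CE2", (1.25, -0.90, 0)),
            ("CG", (2.45, 0.55, 0.20)), ("CB", (3.80, 1.05, 0.30))]
           + _backbone((4.95, 0.15, 0.40)),
    "GLN": [("NE2", (0, 0, 0)), ("CD", (1.33, 0.35, 0)), ("OE1", (1.70, 1.53, 0)),
            ("CG", (2.55, -0.50, 0)), ("CB", (3.85, 0.10, 0))]
           + _backbone((5.10, -0.50, 0)),
    "ASN": [("ND2", (0, 0, 0)), ("CG", (1.33, 0.35, 0)), ("OD1", (1.70, 1.53, 0)),
            ("CB", (2.55, -0.50, 0))] + _backbone((3.85, 0.10, 0)),
    "ASP": [("OD1", (0, 0, 0)), ("OD2", (0.0, 2.20, 0)), ("CG", (0.62, 1.10, 0)),
            ("CB", (2.10, 1.10, 0))] + _backbone((2.85, 2.30, 0.40)),
    "GLU": [("OE1", (0, 0, 0)), ("OE2", (0.0, 2.20, 0)), ("CD", (0.62, 1.10, 0)),
            ("CG", (2.10, 1.10, 0)), ("CB", (2.85, 2.30, 0.40))]
           + _backbone((4.20, 1.80, 0.60)),
    "HIS": [("ND1", (0, 0, 0)), ("CE1", (0.60, -1.20, 0)), ("CG", (1.35, 0.45, 0)),
            ("NE2", (1.95, -1.25, 0)), ("CD2", (2.40, 0.0, 0)),
            ("CB", (2.20, 1.85, 0.30))] + _backbone((3.45, 2.50, 0.50)),
}


@dataclass
class PlantedContact:
    """One planted protein-to-DNA interaction.

    ``target`` is (chain_id, seq_id, atom_name) of the existing DNA atom;
    the probe residue ``res_name``/``seq_id`` is created with ``atom_name``
    placed exactly ``distance`` Angstrom from the target, by default along
    the outward normal from the helix axis (override with ``direction``).
    """

    res_name: str
    seq_id: int
    atom_name: str
    target: tuple[str, int, str]
    distance: float
    direction: tuple[float, float, float] | None = None


@dataclass
class PlantedWater:
    seq_id: int
    xyz: tuple[float, float, float]


@dataclass
class PlantedComplexSpec:
    dna_sequence: str = "ACCGGAAGTG"
    planted_hbonds: list[PlantedContact] = field(default_factory=list)
    planted_salt_bridges: list[PlantedContact] = field(default_factory=list)
    planted_waters: list[PlantedWater] = field(default_factory=list)
    protein_chain: str = "A"
    water_chain: str = "W"


def _find_atom(st: Structure, ref: tuple[str, int, str]) -> np.ndarray:
    chain_id, seq_id, atom_name = ref
    ch = st.chain(chain_id)
    if ch is None:
        raise EtsfaceError(f"no chain {chain_id!r} in structure")
    res = ch.residue(seq_id)
    if res is None:
        raise EtsfaceError(f"no residue {seq_id} in chain {chain_id}")
    atom = res.atom(atom_name)
    if atom is None:
        raise EtsfaceError(f"no atom {atom_name!r} in {res.label}")
    return atom.xyz


def _orient_frame(x_dir: np.ndarray) -> np.ndarray:
    """Rotation whose first column is x_dir (unit), other axes arbitrary."""
    x = x_dir / np.linalg.norm(x_dir)
    helper = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(helper, x)) > 0.95:
        helper = np.array([0.0, 1.0, 0.0])
    y = np.cross(helper, x)
    y /= np.linalg.norm(y)
    z = np.cross(x, y)
    return np.column_stack([x, y, z])


def _place_probe_residue(contact: PlantedContact, dna: Structure,
                         bfactor: float = 25.0) -> Residue:
    if contact.res_name not in _SIDE_CHAIN_TEMPLATES:
        raise EtsfaceError(f"no probe template for residue {contact.res_name!r}")
    if not (2.2 <= contact.distance <= 4.5):
        raise EtsfaceError(
            f"planted distance {contact.distance} outside detection-feasible 2.2-4.5 A")
    target = _find_atom(dna, contact.target)
    if contact.direction is not None:
        u = np.asarray(contact.direction, float)
        u = u / np.linalg.norm(u)
    else:
        axis_point = np.array([0.0, 0.0, target[2]])
        u = target - axis_point
        u = u / np.linalg.norm(u)
    anchor = target + contact.distance * u
    R = _orient_frame(u)
    template = _SIDE_CHAIN_TEMPLATES[contact.res_name]
    if template[0][0] != contact.atom_name:
        # allow planting on any template atom by shifting the local origin
        local = {n: np.array(p) for n, p in template}
        if contact.atom_name not in local:
            raise EtsfaceError(
                f"{contact.res_name} template has no atom {contact.atom_name!r}")
        origin = local[contact.atom_name]
        template = [(n, tuple(p - origin)) for n, p in local.items()]
    res = Residue(name=contact.res_name, seq_id=contact.seq_id, chain_id="A")
    for name, local_xyz in template:
        xyz = anchor + R @ np.asarray(local_xyz, float)
        res.atoms.append(Atom(name=name, element=element_of(name), xyz=xyz,
                              bfactor=bfactor))
    return res


_BONDED_CUTOFF = 1.5  # below this, non-bonded atoms are a geometry conflict


def _check_conflicts(st: Structure) -> None:
    records = [(res, a) for _, res, a in st.atom_records()]
    xyz = np.array([a.xyz for _, a in records])
    if len(xyz) < 2:
        return
    from scipy.spatial import cKDTree
    tree = cKDTree(xyz)
    for i, j in tree.query_pairs(_BONDED_CUTOFF):
        ri, ai = records[i]
        rj, aj = records[j]
        if ri is rj:
            continue  # intra-residue: covalent
        # consecutive DNA residues share the phosphodiester linkage
        if (ri.kind == rj.kind == "dna" and ri.chain_id == rj.chain_id
                and abs(ri.seq_id - rj.seq_id) == 1):
            continue
        d = float(np.linalg.norm(ai.xyz - aj.xyz))
        raise ConflictError(
            f"planted geometry conflict: {ri.label}:{ai.name} vs "
            f"{rj.label}:{aj.name} at {d:.2f} A")


def build_planted_complex(spec: PlantedComplexSpec) -> Structure:
    """Minimal complex containing exactly the planted interactions.

    Raises ConflictError when the requested placements put non-bonded atoms
    closer than 1.5 A.
    """
    st = build_bdna(spec.dna_sequence)
    st.id = "planted-complex"
    protein = Chain(id=spec.protein_chain)
    for contact in list(spec.planted_hbonds) + list(spec.planted_salt_bridges):
        protein.residues.append(_place_probe_residue(contact, st))
    if protein.residues:
        protein.residues.sort(key=lambda r: r.seq_id)
        st.chains.append(protein)
    if spec.planted_waters:
        wchain = Chain(id=spec.water_chain)
        for w in spec.planted_waters:
            res = Residue(name="HOH", seq_id=w.seq_id, chain_id=spec.water_chain)
            res.atoms.append(Atom(name="O", element="O", xyz=np.array(w.xyz),
                                  bfactor=30.0))
            wchain.residues.append(res)
        st.chains.append(wchain)
    _check_conflicts(st)
    return st


# ---------------------------------------------------------------------------
# Higher-level emulations

def build_ets_like_complex() -> tuple[Structure, dict]:
    """Emulation of an Ets-domain footprint on its 10-bp recognition duplex.

    Plants, on the ACCGGAAGTG consensus duplex, the interaction anatomy the
    Ets interface exhibits: five side-chain hydrogen bonds to phosphate
    oxygens (Gln-336, Trp-375, Tyr-386, Ser-392, Tyr-396), four lysine salt
    bridges (Lys-379, Lys-388, Lys-399, Lys-404), and the invariant-arginine
    major-groove contact to the +1 guanine (Arg-391), spanning 9 base pairs.
    Returns the structure and the planted ground truth.
    """
    # strand X residue i is pair i; strand Y residue j is pair 11-j
    hbonds = [
        PlantedContact("TRP", 375, "NE1", ("Y", 10, "OP1"), 2.9),   # pair 1
        PlantedContact("GLN", 336, "NE2", ("Y", 9, "OP2"), 2.9),    # pair 2
        PlantedContact("TYR", 386, "OH", ("X", 5, "OP1"), 2.7),     # pair 5
        PlantedContact("SER", 392, "OG", ("X", 7, "OP1"), 2.7),     # pair 7
        PlantedContact("TYR", 396, "OH", ("X", 8, "OP1"), 2.7),     # pair 8
    ]
    salt_bridges = [
        PlantedContact("LYS", 379, "NZ", ("Y", 8, "OP2"), 3.0),     # pair 3
        PlantedContact("LYS", 388, "NZ", ("X", 6, "OP2"), 3.0),     # pair 6
        PlantedContact("LYS", 399, "NZ", ("X", 9, "OP2"), 3.0),     # pair 9
        PlantedContact("LYS", 404, "NZ", ("X", 4, "OP2"), 3.0),     # pair 4
    ]
    spec = PlantedComplexSpec(planted_hbonds=hbonds,
                              planted_salt_bridges=salt_bridges)
    st = build_planted_complex(spec)

    # invariant arginine over the +1 guanine O6 (base, major groove);
    # approach from above the base plane on the major-groove side
    dna_only = st
    o6 = _find_atom(dna_only, ("X", 4, "O6"))
    n7 = _find_atom(dna_only, ("X", 4, "N7"))
    outward = (o6 + n7) / 2 - np.array([0.0, 0.0, o6[2]])
    outward = outward / np.linalg.norm(outward)
    direction = outward + np.array([0.0, 0.0, 0.9])
    arg = _place_probe_residue(
        PlantedContact("ARG", 391, "NH1", ("X", 4, "O6"), 2.9,
                       direction=tuple(direction)), st)
    st.chain("A").residues.append(arg)
    st.chain("A").residues.sort(key=lambda r: r.seq_id)
    _check_conflicts(st)
    st.id = "ets-like-complex"

    truth = {
        "hbond_residues": {("GLN", 336), ("TRP", 375), ("TYR", 386),
                           ("SER", 392), ("TYR", 396), ("ARG", 391)},
        "phosphate_hbond_residues": {("GLN", 336), ("TRP", 375), ("TYR", 386),
                                     ("SER", 392), ("TYR", 396)},
        "salt_bridge_residues": {("LYS", 379), ("LYS", 388), ("LYS", 399),
                                 ("LYS", 404)},
        "contacted_pairs": set(range(1, 10)),
        "span_bp": 9,
    }
    return st, truth


def build_water_network_complex(include_extra_water: bool = False
                                ) -> tuple[Structure, dict]:
    """Complex with a planted four-water recognition network upstream of GGA.

    Emulates the water-mediated base readout at the -1/-2 positions of the
    Ets-binding site: four waters chained at hydrogen-bond distance linking
    the exocyclic N4 of the -1 cytosine to the phosphodiester oxygens of
    the -1 and -2 cytosine nucleotides, coordinated by an aspartate carboxylate,
    a serine and a tyrosine hydroxyl, and an arginine guanidinium (author
    numbering 387/390/394/412).  The intended
    donor/acceptor graph admits exactly one hydrogen assignment, in which
    the base-facing water accepts from N4.

    Returns the structure and a dict with the intended (water, partner)
    edges and node chemistry for validation.
    """
    st = build_bdna("ACCGGAAGTG")
    st.id = "water-network-complex"
    n4 = _find_atom(st, ("X", 3, "N4"))       # -1 cytosine, base edge
    op1_m1 = _find_atom(st, ("X", 3, "OP1"))  # -1 phosphate
    op1_m2 = _find_atom(st, ("X", 2, "OP1"))  # -2 phosphate

    up = np.array([0.0, 0.0, 1.0])

    def outward(p):
        v = p - np.array([0.0, 0.0, p[2]])
        return v / np.linalg.norm(v)

    # Deterministic staged placement.  For each water, enumerate candidate
    # points at hydrogen-bond distance from its DNA partner that keep every
    # *other* donor/acceptor site outside the detection cutoff; then pick
    # the chain w1..w4 with consecutive waters at hydrogen-bond distance by
    # dynamic programming over the candidate sets; finally place protein
    # anchor atoms the same way around their waters.
    o3_m2 = _find_atom(st, ("X", 2, "O3'"))  # -2/-1 phosphodiester oxygen
    partners = [n4, o3_m2, op1_m1, op1_m2]
    from .chemistry import (BASE_ACCEPTORS, BASE_CODE, BASE_DONORS,
                            DNA_BACKBONE_ACCEPTORS)
    dna_records = [(res, a) for _, res, a in st.atom_records()]
    dna_xyz = np.array([a.xyz for _, a in dna_records])
    # only real donor/acceptor sites can create stray graph edges
    dna_polar = np.array([
        a.name in DNA_BACKBONE_ACCEPTORS
        or a.name in BASE_DONORS[BASE_CODE[res.name]]
        or a.name in BASE_ACCEPTORS[BASE_CODE[res.name]]
        for res, a in dna_records])
    # planted hydrogen-bond lengths; slightly longer at the phosphates so
    # the chain can turn out of the groove without stray contacts
    HB_PARTNER = [3.10, 3.20, 3.30, 3.30]
    HB = 3.10
    STRAY = 3.60      # minimum distance to any unintended donor/acceptor
    STERIC = 2.90     # minimum distance to any other atom

    def fib_sphere(n: int) -> np.ndarray:
        k = np.arange(n) + 0.5
        phi = np.arccos(1 - 2 * k / n)
        theta = np.pi * (1 + 5 ** 0.5) * k
        return np.column_stack([np.sin(phi) * np.cos(theta),
                                np.sin(phi) * np.sin(theta), np.cos(phi)])

    dirs = fib_sphere(1200)

    def candidates(center: np.ndarray, exclude: np.ndarray,
                   avoid_extra: list[np.ndarray], hb: float = HB) -> np.ndarray:
        pts = center + hb * dirs
        d_all = np.linalg.norm(pts[:, None, :] - dna_xyz[None, :, :], axis=2)
        own = np.linalg.norm(dna_xyz - exclude, axis=1) < 1e-9
        ok = (d_all[:, dna_polar & ~own] >= STRAY).all(axis=1)
        ok &= (d_all[:, ~dna_polar] >= STERIC).all(axis=1)
        for p in avoid_extra:
            ok &= np.linalg.norm(pts - p, axis=1) >= STRAY
        return pts[ok]

    cand = [candidates(p, p, [], hb) for p, hb in zip(partners, HB_PARTNER)]
    for i, c in enumerate(cand):
        if len(c) == 0:
            raise ConflictError(f"no feasible placement for network water {i + 1}")

    # DP over the chain: consecutive waters within [2.6, 3.4] A, and
    # non-consecutive ones separated by >= STRAY; maximize clearance.
    LO, HI = 2.60, 3.45
    best: list[dict[int, tuple[float, list[int]]]] = [
        {k: (0.0, [k]) for k in range(len(cand[0]))}]
    for step in range(1, 4):
        layer: dict[int, tuple[float, list[int]]] = {}
        prev = best[step - 1]
        for k, pt in enumerate(cand[step]):
            entries = []
            for kp, (score, path) in prev.items():
                d = float(np.linalg.norm(pt - cand[step - 1][kp]))
                if not (LO <= d <= HI):
                    continue
                ok = True
                for s, idx in enumerate(path[:-1]):
                    if np.linalg.norm(pt - cand[s][idx]) < STRAY:
                        ok = False
                        break
                if ok:
                    entries.append((score - abs(d - HB), path))
            if entries:
                sc, path = max(entries, key=lambda e: e[0])
                layer[k] = (sc, path + [k])
        if not layer:
            raise ConflictError(
                f"no feasible water chain at step {step + 1} of the network")
        best.append(layer)
    _, path = max(best[3].values(), key=lambda e: e[0])
    waters = np.array([cand[i][path[i]] for i in range(4)])

    # protein anchors: OD1/OD2 (water 1), OG (water 2), NH1 (water 3), OH (water 4)
    placed: list[np.ndarray] = []

    def anchor_candidates(w_idx: int) -> np.ndarray:
        w = waters[w_idx]
        pts = w + HB * dirs
        d_all = np.linalg.norm(pts[:, None, :] - dna_xyz[None, :, :], axis=2)
        ok = (d_all[:, dna_polar] >= STRAY).all(axis=1)
        ok &= (d_all[:, ~dna_polar] >= STERIC).all(axis=1)
        for j in range(4):
            if j != w_idx:
                ok &= np.linalg.norm(pts - waters[j], axis=1) >= STRAY
        for p in placed:
            ok &= np.linalg.norm(pts - p, axis=1) >= 3.3
        pts = pts[ok]
        if len(pts) == 0:
            raise ConflictError(f"no feasible protein anchor around water {w_idx + 1}")
        return pts

    # Asp carboxylate: pick the outward-most candidate pair at the O-O
    # separation of a carboxylate group (2.19 A)
    pts0 = anchor_candidates(0)
    pair_d = np.linalg.norm(pts0[:, None, :] - pts0[None, :, :], axis=2)
    ii, jj = np.nonzero(np.abs(pair_d - 2.19) < 0.3)
    if len(ii) == 0:
        raise ConflictError("no carboxylate-geometry anchor pair")
    score = (np.linalg.norm(pts0[ii, :2], axis=1)
             + np.linalg.norm(pts0[jj, :2], axis=1))
    k = int(np.argmax(score))
    od1, od2 = pts0[ii[k]], pts0[jj[k]]
    placed.extend([od1, od2])

    def anchor_for(w_idx: int) -> np.ndarray:
        pts = anchor_candidates(w_idx)
        choice = pts[int(np.argmax(np.linalg.norm(pts[:, :2], axis=1)))]
        placed.append(choice)
        return choice

    og = anchor_for(1)
    nh1 = anchor_for(2)
    oh = anchor_for(3)
    anchors = np.array([od1, od2, og, nh1, oh])

    wchain = Chain(id="W")
    for i, xyz in enumerate(waters):
        res = Residue(name="HOH", seq_id=i + 1, chain_id="W")
        res.atoms.append(Atom(name="O", element="O", xyz=xyz, bfactor=25.0))
        wchain.residues.append(res)

    protein = Chain(id="A")

    # Residue bodies are oriented by searching rolls/tilts of the template
    # frame for the placement with the largest clearance from everything
    # already built (and keeping polar body atoms off the water network).
    existing = [a.xyz for a in st.atoms()] + [w for w in waters]

    def _frames(u: np.ndarray):
        u = u / np.linalg.norm(u)
        tilts = [u]
        for mix in (0.45, 0.9):
            for ref in (up, -up, np.cross(up, u), -np.cross(up, u)):
                nref = np.linalg.norm(ref)
                if nref < 1e-8:
                    continue
                v = u + mix * ref / nref
                tilts.append(v / np.linalg.norm(v))
        for t in tilts:
            base = _orient_frame(t)
            for roll in range(0, 360, 30):
                a = np.deg2rad(roll)
                c, sn = np.cos(a), np.sin(a)
                Rx = np.array([[1, 0, 0], [0, c, -sn], [0, sn, c]], float)
                yield base @ Rx

    def _place_body(res: Residue, anchor_names: list[str],
                    body: list[tuple[str, np.ndarray]],
                    origin: np.ndarray, u: np.ndarray,
                    n_own: int = 0) -> None:
        # the residue's own anchor atoms (last n_own in ``existing``) are
        # covalently bonded to the body and excluded from clearance scoring
        ex = np.array(existing[:len(existing) - n_own])
        wat = np.array(waters)
        best_R, best_score = None, -1.0
        for R in _frames(u):
            pts = np.array([origin + R @ p for _, p in body])
            d_ex = np.linalg.norm(pts[:, None, :] - ex[None, :, :], axis=2).min()
            d_w = np.linalg.norm(pts[:, None, :] - wat[None, :, :], axis=2).min()
            if d_ex < 2.2 or d_w < 3.6:
                continue
            score = min(d_ex, d_w)
            if score > best_score:
                best_score, best_R = score, R
        if best_R is None:
            raise ConflictError(f"cannot orient body of {res.label} without clashes")
        for name, p in body:
            xyz = origin + best_R @ p
            res.atoms.append(Atom(name=name, element=element_of(name), xyz=xyz,
                                  bfactor=25.0))
            existing.append(xyz)

    # Asp-387: carboxylate, both oxygens accept from the base-facing water
    od1, od2 = anchors[0], anchors[1]
    mid = (od1 + od2) / 2
    u = mid - waters[0]
    u /= np.linalg.norm(u)
    asp = Residue(name="ASP", seq_id=387, chain_id="A")
    cg = mid + 0.62 * u
    for name, xyz in [("OD1", od1), ("OD2", od2), ("CG", cg)]:
        asp.atoms.append(Atom(name=name, element=element_of(name), xyz=xyz, bfactor=25.0))
        existing.append(xyz)
    body = [("CB", np.array([1.5, 0, 0])),
            ("CA", np.array([2.7, 0.9, 0.3])),
            ("N", np.array([3.4, 1.8, 1.0])),
            ("C", np.array([3.4, 0.3, -0.9])),
            ("O", np.array([4.5, 0.1, -1.2]))]
    _place_body(asp, ["OD1", "OD2", "CG"], body, cg, u, n_own=3)
    protein.residues.append(asp)

    probes = [
        ("SER", 390, "OG", anchors[2], waters[1]),
        ("ARG", 394, "NH1", anchors[3], waters[2]),
        ("TYR", 412, "OH", anchors[4], waters[3]),
    ]
    for res_name, seq_id, atom_name, anchor, w_xyz in probes:
        u = anchor - w_xyz
        u /= np.linalg.norm(u)
        res = Residue(name=res_name, seq_id=seq_id, chain_id="A")
        res.atoms.append(Atom(name=atom_name, element=element_of(atom_name),
                              xyz=anchor, bfactor=25.0))
        existing.append(anchor)
        body = [(n, np.asarray(p, float)) for n, p in _SIDE_CHAIN_TEMPLATES[res_name]
                if n != atom_name]
        _place_body(res, [atom_name], body, anchor, u, n_own=1)
        protein.residues.append(res)

    st.chains.append(protein)
    st.chains.append(wchain)
    if include_extra_water:
        # a non-conserved decoy bridging water far from the network,
        # hydrogen bonded to a phosphate oxygen and a serine hydroxyl
        op = _find_atom(st, ("Y", 3, "OP1"))
        extra_xyz = op + 2.9 * outward(op)
        extra = Residue(name="HOH", seq_id=99, chain_id="W")
        extra.atoms.append(Atom(name="O", element="O", xyz=extra_xyz, bfactor=30.0))
        wchain.residues.append(extra)
        u = outward(extra_xyz)
        anchor = extra_xyz + 2.9 * u
        R = _orient_frame(u)
        ser = Residue(name="SER", seq_id=500, chain_id="A")
        for name, local in _SIDE_CHAIN_TEMPLATES["SER"]:
            ser.atoms.append(Atom(name=name, element=element_of(name),
                                  xyz=anchor + R @ np.asarray(local, float),
                                  bfactor=25.0))
        protein.residues.append(ser)
    _check_conflicts(st)

    truth = {
        "n_waters": 4,
        "water_edges": {
            ("W", 1): {("X", 3, "N4"), ("A", 387, "OD1"), ("A", 387, "OD2"),
                       ("W", 2, "O")},
            ("W", 2): {("X", 2, "O3'"), ("A", 390, "OG"), ("W", 1, "O"),
                       ("W", 3, "O")},
            ("W", 3): {("X", 3, "OP1"), ("A", 394, "NH1"), ("W", 2, "O"),
                       ("W", 4, "O")},
            ("W", 4): {("X", 2, "OP1"), ("A", 412, "OH"), ("W", 3, "O")},
        },
        "base_facing_water": ("W", 1),
    }
    return st, truth


def build_ca_domain(n_residues: int = 93, seed: int = 11,
                    chain_id: str = "A", start: int = 334) -> Structure:
    """Compact alpha-carbon-only pseudo-domain (seeded self-avoiding walk).

    A stand-in for a folded ~90-residue domain used to exercise
    superposition and profile machinery at realistic size; it has no
    secondary structure or side chains.
    """
    rng = np.random.default_rng(seed)
    coords = [np.zeros(3)]
    while len(coords) < n_residues:
        step = rng.normal(size=3)
        step *= 3.8 / np.linalg.norm(step)
        cand = coords[-1] + step
        # soft compactness + self-avoidance
        if np.linalg.norm(cand) > 3.8 * n_residues ** 0.45:
            continue
        if len(coords) > 2 and min(np.linalg.norm(cand - c)
                                   for c in coords[:-1]) < 3.0:
            continue
        coords.append(cand)
    st = Structure(id=f"ca-domain-{seed}", meta={"generator": "ca-walk"})
    ch = Chain(id=chain_id)
    for i, xyz in enumerate(coords):
        res = Residue(name="ALA", seq_id=start + i, chain_id=chain_id)
        res.atoms.append(Atom(name="CA", element="C", xyz=xyz,
                              bfactor=20.0 + 10.0 * rng.random()))
        ch.residues.append(res)
    st.chains.append(ch)
    return st


def build_toy_dimer(separation: float = 0.0, seed: int = 5) -> Structure:
    """Two identical compact poly-Ala blobs related by a 2-fold axis.

    At ``separation`` 0 the blobs are in van der Waals contact across a flat
    interface; positive separation moves them apart along the dyad, which
    must never increase the buried area.
    """
    rng = np.random.default_rng(seed)
    st = Structure(id="toy-dimer", meta={"generator": "toy-dimer",
                                         "separation": separation})
    half_gap = 2.0 + separation / 2.0
    for chain_id, sign in (("A", -1.0), ("B", 1.0)):
        ch = Chain(id=chain_id)
        num = 1
        for ix in range(4):
            for iy in range(4):
                jitter = rng.normal(0, 0.25, 3)
                ca = np.array([ix * 5.0 + jitter[0], iy * 5.0 + jitter[1],
                               sign * (half_gap + 1.0) + jitter[2]])
                res = Residue(name="ALA", seq_id=num, chain_id=chain_id)
                for name, off in (("N", [-1.2, 0.5, 0.4]), ("CA", [0, 0, 0]),
                                  ("C", [1.2, 0.6, -0.4]), ("O", [2.2, 0.2, -0.8]),
                                  ("CB", [0.2, -1.0, sign * 1.2])):
                    res.atoms.append(Atom(name=name, element=element_of(name),
                                          xyz=ca + np.array(off, float),
                                          bfactor=20.0))
                ch.residues.append(res)
                num += 1
        st.chains.append(ch)
    return st
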