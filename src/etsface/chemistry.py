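"""Chemical dictionaries shared across the analysis modules.

Everything here is a literal table: van der Waals radii, residue-kind sets,
heavy-atom hydrogen-bond donor/acceptor assignments (normal protonation
states at physiological pH), charged-group atoms for salt bridges, the
backbone/sugar/base partition of nucleotide atoms with their groove faces,
and idealized base coordinates in the standard base-pair reference frame
(x toward the major groove, y along the long pair axis, z along the helix).

The crystal structures this package analyses contain no hydrogens, so all
donor/acceptor logic is heavy-atom based; a donor is an N/O/S that carries
at least one proton in the dominant tautomer.
"""

from __future__ import annotations

# ---------------------------------------------------------------------------
# van der Waals radii (Angstrom), element-keyed.  Used by SASA and clash
# scanning.  Unknown elements fall back to DEFAULT_VDW_RADIUS with a warning.
VDW_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "H": 1.20,
    "SE": 1.90,
}
DEFAULT_VDW_RADIUS = 1.70

# ---------------------------------------------------------------------------
# Residue kinds
AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "MSE", "SEP", "TPO", "PTR",
}
# Deoxyribonucleotides; 5CM is 5-methyl-deoxycytidine.
DNA_RESIDUES = {"DA", "DC", "DG", "DT", "DI", "5CM", "A", "C", "G", "T"}
WATER_RESIDUES = {"HOH", "WAT", "H2O", "DOD"}

#: one-letter base code for a nucleotide residue name
BASE_CODE = {"DA": "A", "DC": "C", "DG": "G", "DT": "T",
             "A": "A", "C": "C", "G": "G", "T": "T", "5CM": "C"}
COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}
PURINES = {"A", "G"}

def residue_kind(name: str) -> str:
    """Classify a residue name as protein, dna, water or other."""
    name = name.strip().upper()
    if name in AMINO_ACIDS:
        return "protein"
    if name in DNA_RESIDUES:
        return "dna"
    if name in WATER_RESIDUES:
        return "water"
    return "other"

# ---------------------------------------------------------------------------
# Hydrogen-bond chemistry (heavy atoms).
# Protein side-chain donors / acceptors by residue name.
PROTEIN_SC_DONORS: dict[str, set[str]] = {
    "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"}, "CYS": {"SG"},
    "ASN": {"ND2"}, "GLN": {"NE2"}, "LYS": {"NZ"},
    "ARG": {"NE", "NH1", "NH2"}, "HIS": {"ND1", "NE2"}, "TRP": {"NE1"},
}
PROTEIN_SC_ACCEPTORS: dict[str, set[str]] = {
    "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"},
    "ASN": {"OD1"}, "GLN": {"OE1"},
    "ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"},
    "HIS": {"ND1", "NE2"}, "MET": {"SD"},
}
# Backbone amide N donates (except proline); carbonyl O accepts.
BACKBONE_DONOR = "N"
BACKBONE_ACCEPTOR = "O"

# DNA acceptors common to every nucleotide (phosphate + sugar oxygens).
DNA_BACKBONE_ACCEPTORS = {"OP1", "OP2", "O5'", "O3'", "O4'"}
# Base-specific donors/acceptors, keyed by one-letter base code.
BASE_DONORS: dict[str, set[str]] = {
    "A": {"N6"}, "C": {"N4"}, "G": {"N1", "N2"}, "T": {"N3"},
}
BASE_ACCEPTORS: dict[str, set[str]] = {
    "A": {"N1", "N3", "N7"},
    "C": {"O2", "N3"},
    "G": {"O6", "N3", "N7"},
    "T": {"O2", "O4"},
}

# Salt-bridge (charged-group) atoms.
PROTEIN_CATION_ATOMS: dict[str, set[str]] = {
    "LYS": {"NZ"},
    "ARG": {"NE", "NH1", "NH2"},
}
PROTEIN_ANION_ATOMS: dict[str, set[str]] = {
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
}
DNA_PHOSPHATE_OXYGENS = {"OP1", "OP2"}

# Donor antecedent atoms (for the heavy-atom angle proxy: the
# antecedent-donor-acceptor angle must open at least 90 degrees).
DONOR_ANTECEDENT: dict[str, str] = {
    "OG": "CB", "OG1": "CB", "OH": "CZ", "SG": "CB",
    "ND2": "CG", "NE2": "CD", "NZ": "CE",
    "NE": "CD", "NH1": "CZ", "NH2": "CZ",
    "ND1": "CG", "NE1": "CE2", "N": "CA",
    # nucleobases
    "N6": "C6", "N4": "C4", "N2": "C2", "N1": "C6", "N3": "C2",
}

# ---------------------------------------------------------------------------
# Nucleotide atom partition (backbone / sugar / base) and groove faces.
DNA_BACKBONE_ATOMS = {"P", "OP1", "OP2", "OP3", "O5'", "O3'"}
DNA_SUGAR_ATOMS = {"C1'", "C2'", "C3'", "C4'", "C5'", "O4'"}

# Major / minor groove faces of the base edges.  Every base atom that is not
# backbone or sugar belongs to exactly one of the two faces or to the ring
# core (classified major by convention only if listed here).
BASE_MAJOR_ATOMS: dict[str, set[str]] = {
    "A": {"N6", "N7", "C5", "C6", "C8"},
    "G": {"O6", "N7", "C5", "C6", "C8"},
    "C": {"N4", "C4", "C5", "C6", "C7M", "C7"},   # C7 present on 5-methyl-C
    "T": {"O4", "C4", "C5", "C6", "C7"},
}
BASE_MINOR_ATOMS: dict[str, set[str]] = {
    "A": {"N1", "N3", "C2", "C4", "N9"},
    "G": {"N1", "N2", "N3", "C2", "C4", "N9"},
    "C": {"O2", "N3", "C2", "N1"},
    "T": {"O2", "N3", "C2", "N1"},
}

# ---------------------------------------------------------------------------
# Standard base-pair reference frame coordinates (Angstrom).  The base lies
# in the xy plane; the Watson-Crick partner is generated by a 180 degree
# rotation about x (y -> -y, z -> -z).  C1' is included so glycosidic
# geometry is defined.  Values are the idealized planar base geometries used
# for frame fitting and for the fiber-model duplex builder.
STANDARD_BASE_COORDS: dict[str, dict[str, tuple[float, float, float]]] = {
    "A": {
        "C1'": (-2.479, 5.346, 0.000),
        "N9": (-1.291, 4.498, 0.000),
        "C8": (0.024, 4.897, 0.000),
        "N7": (0.877, 3.902, 0.000),
        "C5": (0.071, 2.771, 0.000),
        "C6": (0.369, 1.398, 0.000),
        "N6": (1.611, 0.909, 0.000),
        "N1": (-0.668, 0.532, 0.000),
        "C2": (-1.912, 1.023, 0.000),
        "N3": (-2.320, 2.290, 0.000),
        "C4": (-1.267, 3.124, 0.000),
    },
    "G": {
        "C1'": (-2.477, 5.399, 0.000),
        "N9": (-1.289, 4.551, 0.000),
        "C8": (0.023, 4.962, 0.000),
        "N7": (0.870, 3.969, 0.000),
        "C5": (0.071, 2.833, 0.000),
        "C6": (0.424, 1.460, 0.000),
        "O6": (1.554, 0.955, 0.000),
        "N1": (-0.700, 0.641, 0.000),
        "C2": (-1.999, 1.087, 0.000),
        "N2": (-2.949, 0.139, 0.000),
        "N3": (-2.342, 2.364, 0.000),
        "C4": (-1.265, 3.177, 0.000),
    },
    "C": {
        "C1'": (-2.477, 5.402, 0.000),
        "N1": (-1.285, 4.542, 0.000),
        "C2": (-1.472, 3.158, 0.000),
        "O2": (-2.628, 2.709, 0.000),
        "N3": (-0.391, 2.344, 0.000),
        "C4": (0.837, 2.868, 0.000),
        "N4": (1.875, 2.027, 0.000),
        "C5": (1.056, 4.275, 0.000),
        "C6": (-0.023, 5.068, 0.000),
    },
    "T": {
        "C1'": (-2.481, 5.354, 0.000),
        "N1": (-1.284, 4.500, 0.000),
        "C2": (-1.462, 3.135, 0.000),
        "O2": (-2.562, 2.608, 0.000),
        "N3": (-0.298, 2.407, 0.000),
        "C4": (0.994, 2.897, 0.000),
        "O4": (1.944, 2.119, 0.000),
        "C5": (1.106, 4.338, 0.000),
        "C7": (2.466, 4.961, 0.000),
        "C6": (-0.024, 5.057, 0.000),
    },
}

# Sugar-phosphate backbone template in the same base-pair frame, one
# nucleotide of strand I.  Derived once by least-squares fitting ideal bond
# lengths (P-O 1.59/1.48, C-C 1.52-1.53, C-O 1.42-1.45, ring diagonals of a
# C2'-endo-like pucker) under the fiber operation (36 deg twist, 3.38 A
# rise), with the phosphate placed to reproduce canonical raw cross-strand
# P-P groove widths (minor ~12.0 A, major ~17.8 A).  The O3' of level i
# bonds the P of level i+1.
BDNA_BACKBONE_TEMPLATE: dict[str, tuple[float, float, float]] = {
    "P": (-0.524, 10.131, -1.365),
    "OP1": (-0.089, 11.093, -0.350),
    "OP2": (-0.814, 10.540, -2.744),
    "O5'": (-1.851, 9.449, -0.807),
    "C5'": (-1.769, 8.097, -0.321),
    "C4'": (-3.116, 7.617, 0.166),
    "O4'": (-2.468, 6.629, -0.670),
    "C3'": (-4.239, 6.836, 0.876),
    "O3'": (-4.821, 7.511, 1.981),
    "C2'": (-3.725, 5.386, 0.904),
}

#: ring atoms used for base-plane fitting and frame superposition
BASE_RING_ATOMS: dict[str, tuple[str, ...]] = {
    "A": ("N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4"),
    "G": ("N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4"),
    "C": ("N1", "C2", "N3", "C4", "C5", "C6"),
    "T": ("N1", "C2", "N3", "C4", "C5", "C6"),
}

#: glycosidic nitrogen per base code
GLYCOSIDIC_N = {"A": "N9", "G": "N9", "C": "N1", "T": "N1"}


def element_of(atom_name: str) -> str:
    """Infer the element from a PDB-style atom name (heavy atoms only)."""
    name = atom_name.strip()
    if not name:
        return ""
    if name[0].isdigit():
        name = name.lstrip("0123456789")
    return name[0].upper()


def vdw_radius(element: str) -> float:
    return VDW_RADII.get(element.upper(), DEFAULT_VDW_RADIUS)
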