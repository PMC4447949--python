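"""Bridging-water detection, conservation across complexes, and hydrogen
assignment by constraint satisfaction.

A *bridging water* is a crystallographic water hydrogen-bonded (heavy-atom
distance criterion) to at least one protein polar atom and at least one DNA
polar atom.  Around a set of bridging waters, a donor/acceptor graph is
built whose nodes are polar sites with fixed chemistry classes (normal
protonation states at physiological pH):

* ``donor_only``    - Arg guanidinium NH/NE, Lys NZ, base exocyclic amino
                      nitrogens (one proton available outside the
                      Watson-Crick edge), amide NH2 groups;
* ``acceptor_only`` - carbonyl, carboxylate, phosphate/ester oxygens, base
                      ring N7/N3, O6/O4/O2;
* ``ambivalent``    - hydroxyls (Ser/Thr/Tyr), His ring nitrogens;
* ``water``         - donates up to two and accepts up to two.

Every edge of the graph must be assigned a unique direction
(donor -> acceptor); bifurcated hydrogens are disallowed.  The solver
enumerates directions exhaustively (depth-first with capacity pruning,
equivalent to filtering all 2^E assignments) and reports every consistent
arrangement.  A unique solution over the recognition-site network is what
turns the geometry into a base-selectivity statement: if the water facing
the -1 base must *accept*, only bases presenting an exocyclic donor
(cytosine N4-H; adenine N6-H, at a longer reach) are compatible.
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
    DNA_BACKBONE_ACCEPTORS,
    PROTEIN_ANION_ATOMS,
    PROTEIN_SC_ACCEPTORS,
    PROTEIN_SC_DONORS,
)
from .errors import EtsfaceError
from .structure_io import Structure, SuperpositionResult, superpose
from .contacts import AtomRef

__all__ = [
    "WaterBridge", "HBondGraph", "Node", "AssignmentSolution",
    "find_bridging_waters", "conserved_waters", "build_hbond_graph",
    "enumerate_h_assignments", "selectivity_report",
]

DEFAULT_CUTOFF = 3.5
MAX_EDGES = 25
MIN_OCCUPANCY = 0.5


@dataclass
class WaterBridge:
    water: AtomRef
    xyz: np.ndarray
    protein_partners: list      # (AtomRef, distance)
    dna_partners: list
    water_partners: list = field(default_factory=list)


def _polar_class(res_kind: str, res_name: str, atom_name: str) -> str | None:
    """Chemistry class of a polar site, or None if not a donor/acceptor."""
    if res_kind == "water":
        return "water" if atom_name == "O" else None
    if res_kind == "protein":
        if atom_name == "N":
            return "donor_only" if res_name != "PRO" else None
        if atom_name == "O":
            return "acceptor_only"
        if res_name in ("SER", "THR", "TYR") and \
                atom_name in PROTEIN_SC_DONORS.get(res_name, ()):
            return "ambivalent"
        if res_name == "HIS" and atom_name in ("ND1", "NE2"):
            return "ambivalent"
        if atom_name in PROTEIN_ANION_ATOMS.get(res_name, ()):
            return "acceptor_only"
        if atom_name in PROTEIN_SC_DONORS.get(res_name, ()):
            return "donor_only"
        if atom_name in PROTEIN_SC_ACCEPTORS.get(res_name, ()):
            return "acceptor_only"
        return None
    if res_kind == "dna":
        code = BASE_CODE.get(res_name)
        if atom_name in DNA_BACKBONE_ACCEPTORS:
            return "acceptor_only"
        if code and atom_name in BASE_DONORS[code]:
            return "donor_only"
        if code and atom_name in BASE_ACCEPTORS[code]:
            return "acceptor_only"
    return None


#: per-class capacities (max donations, max acceptances)
CLASS_CAPACITY = {
    "water": (2, 2),
    "donor_only": (2, 0),
    "acceptor_only": (0, 2),
    "ambivalent": (1, 2),
}
# base exocyclic amino groups have one proton left after Watson-Crick pairing
_BASE_AMINO = {"N4", "N6", "N2"}


def _capacity(cls: str, res_kind: str, atom_name: str) -> tuple[int, int]:
    don, acc = CLASS_CAPACITY[cls]
    if res_kind == "dna" and atom_name in _BASE_AMINO:
        don = 1
    return don, acc


def find_bridging_waters(structure: Structure, cutoff: float = DEFAULT_CUTOFF,
                         min_occupancy: float = MIN_OCCUPANCY
                         ) -> list[WaterBridge]:
    """Waters with >=1 protein and >=1 DNA polar partner within ``cutoff``.

    Water-water links are recorded for network building but do not count
    toward the bridge criterion.  Reliable only for structures whose
    resolution supports ordered-water placement (< ~2.0 A).
    """
    waters = []
    polar = []
    for ch in structure.chains:
        for res in ch.residues:
            for a in res.atoms:
                if res.kind == "water":
                    if a.name == "O" and a.occupancy >= min_occupancy:
                        waters.append((AtomRef(ch.id, res.name, res.seq_id, a.name),
                                       a.xyz))
                    continue
                cls = _polar_class(res.kind, res.name, a.name)
                if cls is not None:
                    polar.append((AtomRef(ch.id, res.name, res.seq_id, a.name),
                                  a.xyz, res.kind))
    if not waters:
        warnings.warn("no waters in structure (resolution too low, or waters "
                      "stripped)", stacklevel=2)
        return []
    out = []
    if polar:
        tree = cKDTree(np.array([x for _, x, _ in polar]))
    water_xyz = np.array([x for _, x in waters])
    wtree = cKDTree(water_xyz)
    for idx, (wref, wxyz) in enumerate(waters):
        prot, dna = [], []
        if polar:
            for j in tree.query_ball_point(wxyz, cutoff):
                ref, x, kind = polar[j]
                d = float(np.linalg.norm(wxyz - x))
                (prot if kind == "protein" else dna).append((ref, d))
        wps = []
        for j in wtree.query_ball_point(wxyz, cutoff):
            if j != idx:
                wps.append((waters[j][0], float(np.linalg.norm(wxyz - water_xyz[j]))))
        if prot and dna:
            out.append(WaterBridge(water=wref, xyz=wxyz,
                                   protein_partners=sorted(prot, key=lambda t: t[1]),
                                   dna_partners=sorted(dna, key=lambda t: t[1]),
                                   water_partners=sorted(wps, key=lambda t: t[1])))
    return out


@dataclass
class WaterCluster:
    members: list               # (structure index, WaterBridge)
    conserved: bool
    max_pair_distance: float


def conserved_waters(structures: list[Structure],
                     superpositions: list[SuperpositionResult] | None = None,
                     match_radius: float = 1.0,
                     cutoff: float = DEFAULT_CUTOFF) -> list[WaterCluster]:
    """Cluster bridging waters across superposed structures.

    All structures are mapped onto the first (via the provided
    superpositions, or default shared-CA superposition).  Clusters are
    greedy mutual-nearest groups; a cluster is conserved when it contains a
    water from every input within ``match_radius``.
    """
    if len(structures) < 2:
        raise EtsfaceError("conservation needs >= 2 structures")
    if superpositions is None:
        superpositions = [None] + [superpose(s, structures[0])
                                   for s in structures[1:]]
    bridges = []
    for k, st in enumerate(structures):
        sup = superpositions[k]
        for b in find_bridging_waters(st, cutoff):
            xyz = b.xyz if sup is None else sup.apply_points(b.xyz)
            bridges.append((k, b, xyz))

    # greedy: repeatedly grow the tightest available cross-structure cluster
    unused = set(range(len(bridges)))
    clusters = []
    while unused:
        i = min(unused)
        members = {bridges[i][0]: (i, 0.0)}
        for j in unused:
            k = bridges[j][0]
            if j == i or k == bridges[i][0]:
                continue
            d = float(np.linalg.norm(bridges[i][2] - bridges[j][2]))
            if d <= match_radius and (k not in members or d < members[k][1]):
                members[k] = (j, d)
        idxs = [v[0] for v in members.values()]
        dmax = max((v[1] for v in members.values()), default=0.0)
        clusters.append(WaterCluster(
            members=[(bridges[j][0], bridges[j][1]) for j in idxs],
            conserved=len(members) == len(structures),
            max_pair_distance=dmax))
        unused -= set(idxs)
    return clusters


# ---------------------------------------------------------------------------
# Hydrogen-assignment constraint satisfaction

@dataclass(frozen=True)
class Node:
    ref: AtomRef
    chem: str                   # water | donor_only | acceptor_only | ambivalent
    max_don: int
    max_acc: int


@dataclass
class HBondGraph:
    nodes: list
    edges: list                 # (i, j, distance) with i < j

    @property
    def n_edges(self) -> int:
        return len(self.edges)


@dataclass
class AssignmentSolution:
    directions: tuple           # per edge: True if nodes[i] donates to nodes[j]
    feasible: bool = True

    def describe(self, graph: HBondGraph) -> list[str]:
        out = []
        for (i, j, d), forward in zip(graph.edges, self.directions):
            a, b = (i, j) if forward else (j, i)
            out.append(f"{graph.nodes[a].ref} -> {graph.nodes[b].ref} ({d:.2f} A)")
        return out


def build_hbond_graph(structure: Structure, bridges: list[WaterBridge],
                      cutoff: float = DEFAULT_CUTOFF) -> HBondGraph:
    """Graph over the bridging waters and their polar partners.

    Edges connect any two node sites within ``cutoff`` for which at least
    one donor->acceptor orientation is chemically possible.
    """
    site_xyz: dict = {}
    site_class: dict = {}
    for b in bridges:
        site_xyz[b.water] = b.xyz
        site_class[b.water] = ("water", "water", "O")
    index = {(ch.id, r.seq_id, a.name): (r.kind, r.name, a.xyz)
             for ch, r, a in structure.atom_records()}
    for b in bridges:
        for ref, _ in b.protein_partners + b.dna_partners:
            kind, name, xyz = index[(ref.chain_id, ref.seq_id, ref.atom_name)]
            cls = _polar_class(kind, name, ref.atom_name)
            if cls:
                site_xyz[ref] = xyz
                site_class[ref] = (cls, kind, ref.atom_name)
        for ref, _ in b.water_partners:
            if ref in site_xyz:
                continue
            rec = index.get((ref.chain_id, ref.seq_id, ref.atom_name))
            if rec is not None:
                site_xyz[ref] = rec[2]
                site_class[ref] = ("water", "water", "O")

    refs = sorted(site_xyz, key=str)
    nodes = []
    for ref in refs:
        cls, kind, aname = site_class[ref]
        don, acc = _capacity(cls, kind, aname)
        nodes.append(Node(ref=ref, chem=cls, max_don=don, max_acc=acc))
    edges = []
    for i in range(len(refs)):
        for j in range(i + 1, len(refs)):
            d = float(np.linalg.norm(site_xyz[refs[i]] - site_xyz[refs[j]]))
            if d > cutoff:
                continue
            ci, cj = nodes[i].chem, nodes[j].chem
            fwd_ok = nodes[i].max_don > 0 and nodes[j].max_acc > 0
            rev_ok = nodes[j].max_don > 0 and nodes[i].max_acc > 0
            if ci == "acceptor_only" and cj == "acceptor_only":
                continue  # no possible hydrogen between two pure acceptors
            if ci == "donor_only" and cj == "donor_only":
                continue
            if fwd_ok or rev_ok:
                edges.append((i, j, d))
    return HBondGraph(nodes=nodes, edges=edges)


def enumerate_h_assignments(graph: HBondGraph,
                            max_edges: int = MAX_EDGES) -> list[AssignmentSolution]:
    """All consistent edge orientations (exhaustive; refuses oversize graphs)."""
    E = graph.n_edges
    if E > max_edges:
        raise EtsfaceError(f"graph has {E} edges > {max_edges}: exhaustive "
                           "enumeration refused")
    nodes = graph.nodes
    don = [0] * len(nodes)
    acc = [0] * len(nodes)
    solutions = []
    directions = [False] * E

    def feasible_dir(i: int, j: int) -> bool:
        return (don[i] < nodes[i].max_don and acc[j] < nodes[j].max_acc)

    def recurse(e: int):
        if e == E:
            solutions.append(AssignmentSolution(directions=tuple(directions)))
            return
        i, j, _ = graph.edges[e]
        if feasible_dir(i, j):
            don[i] += 1
            acc[j] += 1
            directions[e] = True
            recurse(e + 1)
            don[i] -= 1
            acc[j] -= 1
        if feasible_dir(j, i):
            don[j] += 1
            acc[i] += 1
            directions[e] = False
            recurse(e + 1)
            don[j] -= 1
            acc[i] -= 1

    recurse(0)
    return solutions


@dataclass
class SelectivityReport:
    unique: bool
    n_solutions: int
    base_water: AtomRef | None
    water_role: str | None          # "acceptor" | "donor" | None
    allowed_bases: list
    notes: list


#: exocyclic donor/acceptor inventory of the four bases at a major-groove edge
_BASE_EDGE_DONORS = {"C": "N4", "A": "N6"}     # amino N-H available
_BASE_EDGE_ACCEPTORS = {"G": "O6", "T": "O4"}  # carbonyl lone pairs


def selectivity_report(graph: HBondGraph,
                       solutions: list[AssignmentSolution],
                       ebs_position: int = -1) -> SelectivityReport:
    """Base preferences implied by the hydrogen arrangement at a base edge.

    With a unique solution, the direction of the water-to-base edge decides
    the compatible bases: a water that *accepts* requires an exocyclic
    donor (C via N4-H; A via N6-H, flagged as an elongated ~4.0 A reach),
    whereas a water that donates requires an exocyclic acceptor (G O6,
    T O4).
    """
    if len(solutions) != 1:
        return SelectivityReport(unique=False, n_solutions=len(solutions),
                                 base_water=None, water_role=None,
                                 allowed_bases=[],
                                 notes=[f"{len(solutions)} consistent hydrogen "
                                        "arrangements: selectivity ambiguous"])
    sol = solutions[0]
    base_edge = None
    for k, (i, j, d) in enumerate(graph.edges):
        ni, nj = graph.nodes[i], graph.nodes[j]
        for a, b in ((ni, nj), (nj, ni)):
            if a.chem == "water" and b.ref.atom_name in _BASE_AMINO | {"O6", "O4"}:
                base_edge = (k, i, j)
    if base_edge is None:
        return SelectivityReport(unique=True, n_solutions=1, base_water=None,
                                 water_role=None, allowed_bases=[],
                                 notes=["no water-to-base-edge contact in graph"])
    k, i, j = base_edge
    water_node, base_node = (graph.nodes[i], graph.nodes[j]) \
        if graph.nodes[i].chem == "water" else (graph.nodes[j], graph.nodes[i])
    forward = sol.directions[k]
    donates_to_base = (forward and graph.nodes[i] is water_node) or \
                      (not forward and graph.nodes[j] is water_node)
    if donates_to_base:
        allowed = [("G", "O6"), ("T", "O4")]
        role = "donor"
        notes = ["water donates into the base edge: requires an exocyclic "
                 "acceptor"]
    else:
        allowed = [("C", "N4"), ("A", "N6")]
        role = "acceptor"
        notes = ["water accepts from the base edge: requires an exocyclic "
                 "donor; adenine N6 reaches only at an elongated ~4.0 A "
                 "distance"]
    return SelectivityReport(unique=True, n_solutions=1,
                             base_water=water_node.ref, water_role=role,
                             allowed_bases=allowed, notes=notes)
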