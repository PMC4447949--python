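"""Coordinate data model, PDB/mmCIF reading, selection, writing, superposition.

The in-memory model is a small hierarchical Structure -> Chain -> Residue ->
Atom tree carrying author residue numbering, B-factors, occupancies and
altlocs.  Reading goes through gemmi (PDB and mmCIF dialects); writing emits
a minimal PDB subset at the format's native 3-decimal coordinate precision.

Only model 1 of multi-model files is read.  By default the first alternate
location ('A' or blank) is kept; ``keep_altlocs=True`` retains all.
"""

from __future__ import annotations

import copy as _copy
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterator, Sequence

import gemmi
import numpy as np

from .chemistry import element_of, residue_kind
from .errors import EmptyStructureError, GeometryError, ParseError, SelectionError

__all__ = [
    "Atom", "Residue", "Chain", "Structure", "SuperpositionResult",
    "parse_structure", "select", "write_pdb", "superpose", "ca_pairing",
]


@dataclass
class Atom:
    """One heavy (or hydrogen) atom with coordinates in Angstrom."""

    name: str
    element: str
    xyz: np.ndarray
    bfactor: float = 0.0
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self):
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.shape != (3,) or not np.all(np.isfinite(self.xyz)):
            raise ValueError(f"atom {self.name}: coordinates must be a finite 3-vector")
        if not self.element:
            self.element = element_of(self.name)
        if not (0.0 <= self.occupancy <= 1.0):
            raise ValueError(f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]")


@dataclass
class Residue:
    """A residue identified by author numbering within its chain."""

    name: str
    seq_id: int
    chain_id: str
    kind: str = ""
    atoms: list[Atom] = field(default_factory=list)

    def __post_init__(self):
        if not self.kind:
            self.kind = residue_kind(self.name)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def label(self) -> str:
        return f"{self.name}-{self.chain_id}{self.seq_id}"


@dataclass
class Chain:
    id: str
    residues: list[Residue] = field(default_factory=list)

    def residue(self, seq_id: int) -> Residue | None:
        for r in self.residues:
            if r.seq_id == seq_id:
                return r
        return None


@dataclass
class Structure:
    """Hierarchical atom model; ``meta`` records provenance."""

    id: str
    chains: list[Chain] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    # -- iteration helpers --------------------------------------------------
    def residues(self) -> Iterator[Residue]:
        for ch in self.chains:
            yield from ch.residues

    def atoms(self) -> Iterator[Atom]:
        for r in self.residues():
            yield from r.atoms

    def atom_records(self) -> Iterator[tuple[Chain, Residue, Atom]]:
        for ch in self.chains:
            for r in ch.residues:
                for a in r.atoms:
                    yield ch, r, a

    def chain(self, chain_id: str) -> Chain | None:
        for ch in self.chains:
            if ch.id == chain_id:
                return ch
        return None

    @property
    def n_atoms(self) -> int:
        return sum(1 for _ in self.atoms())

    def coords(self) -> np.ndarray:
        n = self.n_atoms
        out = np.empty((n, 3))
        for i, a in enumerate(self.atoms()):
            out[i] = a.xyz
        return out

    def set_coords(self, xyz: np.ndarray) -> None:
        xyz = np.asarray(xyz, dtype=float)
        for i, a in enumerate(self.atoms()):
            a.xyz = xyz[i].copy()

    def copy(self) -> "Structure":
        return _copy.deepcopy(self)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Return a rigidly transformed copy (x -> R x + t)."""
        out = self.copy()
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        for a in out.atoms():
            a.xyz = R @ a.xyz + t
        return out


# ---------------------------------------------------------------------------
# Parsing

def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in {".cif", ".mmcif"}:
        return "mmcif"
    if suffix in {".pdb", ".ent"}:
        return "pdb"
    # content sniff: mmCIF files start with 'data_'
    try:
        head = path.read_text(errors="replace")[:64]
    except OSError as exc:
        raise ParseError(f"cannot read {path}: {exc}") from exc
    return "mmcif" if head.lstrip().startswith("data_") else "pdb"


def parse_structure(path: str | Path, fmt: str = "auto",
                    keep_altlocs: bool = False) -> Structure:
    """Read a PDB or mmCIF file into a Structure.

    Model 1 only.  Waters get ``kind='water'``.  Unless ``keep_altlocs``,
    only the blank or first-sorting altloc of each atom name is retained.
    Author residue numbering is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    if fmt == "auto":
        fmt = _infer_format(path)
    try:
        if fmt == "pdb":
            gst = gemmi.read_pdb(str(path))
        elif fmt == "mmcif":
            gst = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            raise ParseError(f"unknown format {fmt!r} (use pdb, mmcif or auto)")
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"{path}: {exc}") from exc

    if len(gst) == 0:
        raise EmptyStructureError(f"{path}: no models")
    model = gst[0]

    st = Structure(id=gst.name or path.stem,
                   meta={"source": str(path), "format": fmt, "model": 1})
    for gchain in model:
        chain = Chain(id=gchain.name)
        for gres in gchain:
            res = Residue(name=gres.name.strip(),
                          seq_id=gres.seqid.num,
                          chain_id=gchain.name)
            seen: dict[str, str] = {}
            for gatom in gres:
                alt = gatom.altloc if gatom.altloc != "\x00" else ""
                if not keep_altlocs:
                    prev = seen.get(gatom.name)
                    if prev is not None and alt >= prev and alt != "":
                        continue
                    if alt not in ("", "A") and gatom.name in seen:
                        continue
                    seen[gatom.name] = alt
                    if prev is not None:
                        # replace earlier non-preferred altloc
                        res.atoms = [a for a in res.atoms if a.name != gatom.name]
                occ = min(max(float(gatom.occ), 0.0), 1.0)
                res.atoms.append(Atom(name=gatom.name,
                                      element=gatom.element.name.upper(),
                                      xyz=np.array([gatom.pos.x, gatom.pos.y, gatom.pos.z]),
                                      bfactor=float(gatom.b_iso),
                                      occupancy=occ,
                                      altloc=alt))
            if res.atoms:
                chain.residues.append(res)
        if chain.residues:
            st.chains.append(chain)
    if st.n_atoms == 0:
        raise EmptyStructureError(f"{path}: zero atoms in model 1")
    return st


# ---------------------------------------------------------------------------
# Writing (PDB subset, 3-decimal coordinates)

def write_pdb(structure: Structure, path: str | Path) -> None:
    lines = []
    serial = 0
    for ch in structure.chains:
        for res in ch.residues:
            het = res.kind in ("water", "other")
            rec = "HETATM" if het else "ATOM  "
            for a in res.atoms:
                serial += 1
                name = a.name
                # PDB column rule: 1-char element names start in column 14
                if len(name) < 4 and len(a.element) == 1:
                    name = " " + name
                lines.append(
                    f"{rec}{serial:5d} {name:<4s}{a.altloc or ' '}{res.name:>3s} "
                    f"{ch.id[:1]:1s}{res.seq_id:4d}    "
                    f"{a.xyz[0]:8.3f}{a.xyz[1]:8.3f}{a.xyz[2]:8.3f}"
                    f"{a.occupancy:6.2f}{a.bfactor:6.2f}          "
                    f"{a.element:>2s}"
                )
        lines.append(f"TER   {serial + 1:5d}")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Selection expressions
#
# Grammar (whitespace-tokenized, case-insensitive keywords):
#   expr      := or_expr
#   or_expr   := and_expr ('or' and_expr)*
#   and_expr  := unary (('and')? unary)*
#   unary     := 'not' unary | '(' expr ')' | primitive
#   primitive := 'all' | 'water' | 'protein' | 'dna'
#              | 'chain' ID | 'kind' KIND | 'element' EL
#              | 'res' RANGES          (e.g. res 334-426 or res 3,7,9)
#              | 'name' NAMES          (comma-separated atom names)

Predicate = Callable[[Chain, Residue, Atom], bool]


def _parse_ranges(token: str, pos: int) -> list[tuple[int, int]]:
    out = []
    for part in token.split(","):
        if "-" in part[1:]:  # allow negative single numbers
            lo, _, hi = part.rpartition("-")
            try:
                out.append((int(lo), int(hi)))
            except ValueError:
                raise SelectionError(f"bad residue range {part!r}", pos)
        else:
            try:
                v = int(part)
            except ValueError:
                raise SelectionError(f"bad residue number {part!r}", pos)
            out.append((v, v))
    return out


class _SelParser:
    def __init__(self, expr: str):
        self.tokens = expr.replace("(", " ( ").replace(")", " ) ").split()
        self.pos = 0

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self) -> str:
        tok = self.peek()
        if tok is None:
            raise SelectionError("unexpected end of expression", self.pos)
        self.pos += 1
        return tok

    def parse(self) -> Predicate:
        pred = self.or_expr()
        if self.peek() is not None:
            raise SelectionError(f"trailing token {self.peek()!r}", self.pos)
        return pred

    def or_expr(self) -> Predicate:
        left = self.and_expr()
        while self.peek() and self.peek().lower() == "or":
            self.take()
            right = self.and_expr()
            l, r = left, right
            left = lambda c, res, a, l=l, r=r: l(c, res, a) or r(c, res, a)
        return left

    def and_expr(self) -> Predicate:
        preds = [self.unary()]
        while True:
            tok = self.peek()
            if tok is None or tok.lower() in {"or", ")"}:
                break
            if tok.lower() == "and":
                self.take()
                tok = self.peek()
                if tok is None:
                    raise SelectionError("dangling 'and'", self.pos)
            preds.append(self.unary())
        if len(preds) == 1:
            return preds[0]
        return lambda c, r, a, ps=tuple(preds): all(p(c, r, a) for p in ps)

    def unary(self) -> Predicate:
        tok = self.peek()
        if tok is None:
            raise SelectionError("unexpected end of expression", self.pos)
        low = tok.lower()
        if low == "not":
            self.take()
            inner = self.unary()
            return lambda c, r, a, p=inner: not p(c, r, a)
        if tok == "(":
            self.take()
            inner = self.or_expr()
            if self.peek() != ")":
                raise SelectionError("missing ')'", self.pos)
            self.take()
            return inner
        return self.primitive()

    def primitive(self) -> Predicate:
        pos = self.pos
        tok = self.take().lower()
        if tok == "all":
            return lambda c, r, a: True
        if tok in {"water", "protein", "dna"}:
            return lambda c, r, a, k=tok: r.kind == k
        if tok == "chain":
            arg = self.take()
            ids = set(arg.split(","))
            return lambda c, r, a, ids=ids: c.id in ids
        if tok == "kind":
            arg = self.take().lower()
            if arg not in {"protein", "dna", "water", "other"}:
                raise SelectionError(f"unknown kind {arg!r}", pos + 1)
            return lambda c, r, a, k=arg: r.kind == k
        if tok == "element":
            els = {e.upper() for e in self.take().split(",")}
            return lambda c, r, a, els=els: a.element.upper() in els
        if tok in {"res", "resi", "residue"}:
            ranges = _parse_ranges(self.take(), pos + 1)
            return lambda c, r, a, rg=tuple(ranges): any(lo <= r.seq_id <= hi for lo, hi in rg)
        if tok == "name":
            names = set(self.take().split(","))
            return lambda c, r, a, ns=names: a.name in ns
        raise SelectionError(f"unknown selection token {tok!r}", pos)


def compile_selection(expr: str) -> Predicate:
    return _SelParser(expr).parse()


def select(structure: Structure, expr: str | Predicate) -> Structure:
    """Return a new Structure holding exactly the atoms matching ``expr``.

    An empty match is returned as a zero-atom Structure flagged in
    ``meta['empty']`` (with a warning) rather than raising.
    """
    pred = compile_selection(expr) if isinstance(expr, str) else expr
    out = Structure(id=structure.id, meta=dict(structure.meta))
    out.meta["selection"] = expr if isinstance(expr, str) else "<predicate>"
    for ch in structure.chains:
        new_ch = Chain(id=ch.id)
        for res in ch.residues:
            hits = [a for a in res.atoms if pred(ch, res, a)]
            if hits:
                new_ch.residues.append(
                    Residue(name=res.name, seq_id=res.seq_id, chain_id=ch.id,
                            kind=res.kind, atoms=[_copy.deepcopy(a) for a in hits]))
        if new_ch.residues:
            out.chains.append(new_ch)
    if out.n_atoms == 0:
        out.meta["empty"] = True
        warnings.warn(f"selection {out.meta['selection']!r} matched no atoms",
                      stacklevel=2)
    return out


# ---------------------------------------------------------------------------
# Superposition (Kabsch)

@dataclass
class SuperpositionResult:
    """Least-squares rigid transform mapping mobile onto reference."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_atoms: int

    def apply(self, structure: Structure) -> Structure:
        return structure.transformed(self.rotation, self.translation)

    def apply_points(self, xyz: np.ndarray) -> np.ndarray:
        return np.asarray(xyz, float) @ self.rotation.T + self.translation


def ca_pairing(mobile: Structure, reference: Structure,
               chain_map: dict[str, str] | None = None) -> list[tuple[Atom, Atom]]:
    """Pair alpha-carbon atoms by chain id and author residue number."""
    ref_index: dict[tuple[str, int], Atom] = {}
    for ch, res, a in reference.atom_records():
        if res.kind == "protein" and a.name == "CA":
            ref_index[(ch.id, res.seq_id)] = a
    pairs = []
    for ch, res, a in mobile.atom_records():
        if res.kind == "protein" and a.name == "CA":
            key = ((chain_map or {}).get(ch.id, ch.id), res.seq_id)
            partner = ref_index.get(key)
            if partner is not None:
                pairs.append((a, partner))
    return pairs


def kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rotation/translation mapping point set P onto Q; returns (R, t, rmsd)."""
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - cp, Q - cq
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    diff = P0 @ R.T - Q0
    rmsd = float(np.sqrt((diff ** 2).sum() / len(P)))
    return R, t, rmsd


def superpose(mobile: Structure, reference: Structure,
              pairing: Sequence[tuple[Atom, Atom]] | None = None) -> SuperpositionResult:
    """Kabsch superposition over an atom pairing (default: shared CA atoms).

    Raises GeometryError for fewer than 3 pairs or collinear pairings.  The
    mobile structure is not modified; apply the result to obtain transformed
    coordinates.
    """
    if pairing is None:
        pairing = ca_pairing(mobile, reference)
    if len(pairing) < 3:
        raise GeometryError(f"superposition needs >= 3 atom pairs, got {len(pairing)}")
    P = np.array([a.xyz for a, _ in pairing])
    Q = np.array([b.xyz for _, b in pairing])
    # collinearity check on either cloud
    for X in (P, Q):
        s = np.linalg.svd(X - X.mean(axis=0), compute_uv=False)
        if s[1] < 1e-8 * max(s[0], 1.0):
            raise GeometryError("degenerate (collinear) atom pairing")
    R, t, rmsd = kabsch(P, Q)
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd, n_atoms=len(pairing))
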