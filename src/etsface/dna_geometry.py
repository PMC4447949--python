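"""Base-pair detection, pair frames, helical bend, groove widths.

Pairs are detected from Watson-Crick geometry (complementary bases, purine
N1 to pyrimidine N3 within hydrogen-bond range, near-parallel base planes,
canonical C1'-C1' separation) and ordered 5'->3' along a reference strand.
Pair reference frames are obtained by least-squares fitting the idealized
standard-frame base templates to the observed base atoms.  The bend angle
is the angle between local helix axes fitted to the terminal pairs at each
end; groove widths are raw cross-strand phosphorus-phosphorus minima (no
probe-radius correction), reported per helical level.

Ets-binding-site (EBS) registration: the 9-bp site is numbered -3..+6 with
the first guanine of the invariant 5'-GGA-3' core at +1 (there is no
position 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chemistry import (
    BASE_CODE,
    BASE_RING_ATOMS,
    COMPLEMENT,
    PURINES,
    STANDARD_BASE_COORDS,
)
from .errors import EtsfaceError, GeometryError
from .structure_io import Residue, Structure, kabsch
from .synthetic_structures import build_bdna

__all__ = [
    "BasePair", "BpFrame", "BendResult", "GrooveProfile",
    "find_base_pairs", "base_pair_frames", "bend_angle", "groove_widths",
    "compare_to_bform", "register_ebs",
]

MAX_N1N3 = 3.5          # Angstrom
MAX_PLANE_ANGLE = 65.0  # degrees
C1C1_RANGE = (9.5, 11.0)
# cross-strand P-P offset windows (partner level minus own level)
MINOR_WINDOW = range(-5, -1)
MAJOR_WINDOW = range(3, 8)


@dataclass
class BasePair:
    res_i: Residue             # reference strand
    res_j: Residue             # partner strand
    wc_class: str              # "WC" or "non-WC"
    pair_index: int            # 1-based, 5'->3' on the reference strand
    ebs_position: int | None = None

    @property
    def code(self) -> str:
        return BASE_CODE[self.res_i.name]


@dataclass
class BpFrame:
    origin: np.ndarray
    axes: np.ndarray           # columns x, y, z; right-handed orthonormal


@dataclass
class BendResult:
    bend_angle: float          # degrees
    end_axes: tuple
    end_len: int


@dataclass
class GrooveProfile:
    levels: list
    major: list                # Angstrom or None where undefined
    minor: list

    @property
    def major_max(self) -> float:
        vals = [v for v in self.major if v is not None]
        if not vals:
            raise GeometryError("no defined major-groove levels")
        return max(vals)

    @property
    def minor_min(self) -> float:
        vals = [v for v in self.minor if v is not None]
        if not vals:
            raise GeometryError("no defined minor-groove levels")
        return min(vals)


def _base_normal(res: Residue) -> np.ndarray | None:
    code = BASE_CODE.get(res.name)
    if code is None:
        return None
    pts = [res.atom(n).xyz for n in BASE_RING_ATOMS[code] if res.atom(n)]
    if len(pts) < 4:
        return None
    X = np.array(pts)
    X = X - X.mean(axis=0)
    _, _, Vt = np.linalg.svd(X)
    return Vt[2]


def _wc_atom(res: Residue):
    code = BASE_CODE.get(res.name)
    if code is None:
        return None
    return res.atom("N1") if code in PURINES else res.atom("N3")


def find_base_pairs(structure: Structure, reference_chain: str | None = None
                    ) -> list[BasePair]:
    """Detect Watson-Crick base pairs and order them along the duplex.

    Uses a maximal non-conflicting pairing (greedy by N1-N3 distance).  The
    reference strand is ``reference_chain`` or, by default, the DNA chain
    contributing the most pairs; EBS positions are registered by locating
    the GGA core on either strand.
    """
    nts = [r for r in structure.residues() if r.kind == "dna"]
    candidates = []
    for i, ri in enumerate(nts):
        ci = BASE_CODE.get(ri.name)
        if ci not in PURINES:
            continue
        for rj in nts:
            cj = BASE_CODE.get(rj.name)
            if rj is ri or cj is None or COMPLEMENT[ci] != cj:
                continue
            ai, aj = _wc_atom(ri), _wc_atom(rj)
            c1i, c1j = ri.atom("C1'"), rj.atom("C1'")
            if ai is None or aj is None or c1i is None or c1j is None:
                continue
            d = float(np.linalg.norm(ai.xyz - aj.xyz))
            if d > MAX_N1N3:
                continue
            dc1 = float(np.linalg.norm(c1i.xyz - c1j.xyz))
            if not (C1C1_RANGE[0] <= dc1 <= C1C1_RANGE[1]):
                continue
            ni, nj = _base_normal(ri), _base_normal(rj)
            if ni is None or nj is None:
                continue
            ang = np.degrees(np.arccos(np.clip(abs(np.dot(ni, nj)), 0, 1)))
            if ang > MAX_PLANE_ANGLE:
                continue
            candidates.append((d, ri, rj))
    candidates.sort(key=lambda t: t[0])
    used = set()
    chosen = []
    for d, ri, rj in candidates:
        ki = (ri.chain_id, ri.seq_id)
        kj = (rj.chain_id, rj.seq_id)
        if ki in used or kj in used:
            continue
        used.update((ki, kj))
        chosen.append((ri, rj))
    if not chosen:
        import warnings
        warnings.warn("no base pairs detected", stacklevel=2)
        return []

    # reference strand: requested chain, or the one with the most pairs
    counts: dict = {}
    for ri, rj in chosen:
        counts[ri.chain_id] = counts.get(ri.chain_id, 0) + 1
        counts[rj.chain_id] = counts.get(rj.chain_id, 0) + 1
    ref = reference_chain or max(sorted(counts), key=counts.get)
    pairs = []
    for ri, rj in chosen:
        if rj.chain_id == ref and ri.chain_id != ref:
            ri, rj = rj, ri
        elif ri.chain_id != ref and rj.chain_id != ref:
            pass  # keep purine first
        pairs.append((ri, rj))
    pairs.sort(key=lambda t: t[0].seq_id if t[0].chain_id == ref else 10 ** 6)

    out = [BasePair(res_i=ri, res_j=rj, wc_class="WC", pair_index=k + 1)
           for k, (ri, rj) in enumerate(pairs)]
    register_ebs(out)
    return out


def register_ebs(pairs: list[BasePair]) -> None:
    """Locate the GGA core and assign EBS positions -3..+6 (no zero)."""
    if not pairs:
        return
    seq_ref = "".join(p.code for p in pairs)
    seq_partner = "".join(COMPLEMENT[p.code] for p in reversed(pairs))

    def assign(start_idx: int, forward: bool):
        for k, p in enumerate(pairs):
            if forward:
                off = k - start_idx
            else:
                off = (len(pairs) - 1 - k) - start_idx
            pos = off + 1 if off >= 0 else off
            p.ebs_position = pos if -3 <= pos <= 6 else None

    idx = seq_ref.find("GGA")
    if idx >= 0:
        assign(idx, forward=True)
        return
    idx = seq_partner.find("GGA")
    if idx >= 0:
        assign(idx, forward=False)
        return
    import warnings
    warnings.warn("GGA core not found: EBS positions left unassigned",
                  stacklevel=2)


def _fit_base_frame(res: Residue) -> tuple[np.ndarray, np.ndarray] | None:
    """Fit the standard-frame template to the observed base; returns (R, t)
    mapping template coordinates into the structure frame."""
    code = BASE_CODE.get(res.name)
    if code is None:
        return None
    names = [n for n in STANDARD_BASE_COORDS[code]
             if res.atom(n) is not None and n != "C1'"]
    if len(names) < 4:
        return None
    P = np.array([STANDARD_BASE_COORDS[code][n] for n in names])
    Q = np.array([res.atom(n).xyz for n in names])
    R, t, _ = kabsch(P, Q)
    return R, t


_FLIP = np.diag([1.0, -1.0, -1.0])


def base_pair_frames(pairs: list[BasePair]) -> list[BpFrame]:
    """Pair frames averaged from the two fitted base frames (partner flipped)."""
    frames = []
    for p in pairs:
        fits = []
        fit_i = _fit_base_frame(p.res_i)
        if fit_i is not None:
            fits.append(fit_i[0])
            t_i = fit_i[1]
        fit_j = _fit_base_frame(p.res_j)
        if fit_j is not None:
            fits.append(fit_j[0] @ _FLIP)
            t_j = fit_j[1]
        if not fits:
            raise GeometryError(f"cannot fit a frame for pair {p.pair_index}")
        M = sum(fits) / len(fits)
        U, _, Vt = np.linalg.svd(M)
        D = np.diag([1.0, 1.0, np.sign(np.linalg.det(U @ Vt))])
        axes = U @ D @ Vt
        origin = t_i if fit_j is None else (t_j if fit_i is None else (t_i + t_j) / 2)
        frames.append(BpFrame(origin=origin, axes=axes))
    # orient z consistently along increasing pair index
    if len(frames) > 1:
        step = frames[-1].origin - frames[0].origin
        for f in frames:
            if np.dot(f.axes[:, 2], step) < 0:
                f.axes = f.axes @ np.diag([1.0, -1.0, -1.0])
    return frames


def _segment_axis(frames: list[BpFrame]) -> np.ndarray:
    origins = np.array([f.origin for f in frames])
    mean_z = np.mean([f.axes[:, 2] for f in frames], axis=0)
    spread = origins - origins.mean(axis=0)
    s = np.linalg.svd(spread, compute_uv=False)
    if s[0] < 1.0:  # origins nearly coincident: fall back to frame z
        axis = mean_z
    else:
        _, _, Vt = np.linalg.svd(spread)
        axis = Vt[0]
        if np.dot(axis, mean_z) < 0:
            axis = -axis
    return axis / np.linalg.norm(axis)


def bend_angle(pairs: list[BasePair], frames: list[BpFrame] | None = None,
               end_len: int = 4) -> BendResult:
    """Angle between local helix axes of the two duplex ends (degrees)."""
    if frames is None:
        frames = base_pair_frames(pairs)
    if len(frames) < 2 * end_len:
        raise GeometryError(
            f"bend angle needs >= {2 * end_len} pairs, got {len(frames)}")
    a1 = _segment_axis(frames[:end_len])
    a2 = _segment_axis(frames[-end_len:])
    ang = float(np.degrees(np.arccos(np.clip(np.dot(a1, a2), -1.0, 1.0))))
    return BendResult(bend_angle=ang, end_axes=(a1, a2), end_len=end_len)


def groove_widths(structure: Structure, pairs: list[BasePair]) -> GrooveProfile:
    """Raw cross-strand P-P groove widths per helical level.

    At level i, the minor width is the minimum distance from the reference
    strand phosphorus P1(i) to partner-strand phosphorus P2(j) over the
    minor-groove offset window (j-i in -5..-2), and the major width over the
    major-groove window (j-i in +3..+7).  Levels lacking a phosphorus are
    reported as None, never zero-filled.
    """
    n = len(pairs)
    if n == 0:
        raise GeometryError("no pairs for groove widths")
    p1 = [pairs[i].res_i.atom("P") for i in range(n)]
    p2 = [pairs[i].res_j.atom("P") for i in range(n)]

    def width(i: int, window) -> float | None:
        if p1[i] is None:
            return None
        ds = []
        for off in window:
            j = i + off
            if 0 <= j < n and p2[j] is not None:
                ds.append(float(np.linalg.norm(p1[i].xyz - p2[j].xyz)))
        # a truncated window near the termini cannot bracket the true
        # minimum; flag the level undefined rather than report an inflated
        # value
        if len(ds) < 2:
            return None
        return min(ds)

    major = [width(i, MAJOR_WINDOW) for i in range(n)]
    minor = [width(i, MINOR_WINDOW) for i in range(n)]
    return GrooveProfile(levels=list(range(1, n + 1)), major=major, minor=minor)


@dataclass
class BFormComparison:
    bend_delta: float
    major_delta: list
    minor_delta: list
    origin_displacement: list
    observed: GrooveProfile
    reference: GrooveProfile
    observed_bend: float
    reference_bend: float


def compare_to_bform(structure: Structure, pairs: list[BasePair] | None = None
                     ) -> BFormComparison:
    """Deviation report against a straight fiber duplex of the same sequence.

    The idealized reference is built with the synthetic generator, superposed
    onto the observed duplex over the C1' atoms of the central 4 pairs.
    """
    if pairs is None:
        pairs = find_base_pairs(structure)
    if len(pairs) < 8:
        raise GeometryError("comparison needs at least 8 base pairs")
    seq = "".join(p.code for p in pairs)
    ref = build_bdna(seq)
    ref_pairs = find_base_pairs(ref, reference_chain="X")
    if "".join(p.code for p in ref_pairs) != seq:
        raise EtsfaceError("reference sequence mismatch")

    mid = len(pairs) // 2
    sel = range(mid - 2, mid + 2)
    P = []
    Q = []
    for k in sel:
        for rr, ro in ((ref_pairs[k].res_i, pairs[k].res_i),
                       (ref_pairs[k].res_j, pairs[k].res_j)):
            if rr.atom("C1'") and ro.atom("C1'"):
                P.append(rr.atom("C1'").xyz)
                Q.append(ro.atom("C1'").xyz)
    R, t, _ = kabsch(np.array(P), np.array(Q))
    ref_sup = ref.transformed(R, t)
    ref_pairs_sup = find_base_pairs(ref_sup, reference_chain="X")

    obs_g = groove_widths(structure, pairs)
    ref_g = groove_widths(ref_sup, ref_pairs_sup)
    obs_b = bend_angle(pairs)
    ref_b = bend_angle(ref_pairs_sup)
    obs_f = base_pair_frames(pairs)
    ref_f = base_pair_frames(ref_pairs_sup)

    def delta(a, b):
        return [None if x is None or y is None else x - y for x, y in zip(a, b)]

    disp = [float(np.linalg.norm(fo.origin - fr.origin))
            for fo, fr in zip(obs_f, ref_f)]
    return BFormComparison(
        bend_delta=obs_b.bend_angle - ref_b.bend_angle,
        major_delta=delta(obs_g.major, ref_g.major),
        minor_delta=delta(obs_g.minor, ref_g.minor),
        origin_displacement=disp,
        observed=obs_g, reference=ref_g,
        observed_bend=obs_b.bend_angle, reference_bend=ref_b.bend_angle)
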