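"""Shrake-Rupley solvent-accessible surface area and buried-interface summaries.

The accessible surface of each atom is sampled on a deterministic Fibonacci
sphere of ``n_points`` at radius r_vdw + r_probe; a point is accessible when
it lies outside every neighbouring atom's expanded sphere.  Buried interface
area between two disjoint selections A and B is reported as

    buried = (SASA(A) + SASA(B) - SASA(A u B)) / 2

(the one-face, PISA-style convention), alongside the unhalved per-side loss
used for percent-of-monomer figures.  Waters are excluded by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .chemistry import DEFAULT_VDW_RADIUS, VDW_RADII
from .errors import EtsfaceError
from .structure_io import Structure, select

__all__ = ["SasaResult", "InterfaceSummary", "sasa", "interface_area",
           "fibonacci_sphere"]

DEFAULT_PROBE = 1.4
DEFAULT_N_POINTS = 960


def fibonacci_sphere(n: int) -> np.ndarray:
    """n near-uniform unit vectors (golden-angle lattice); deterministic."""
    k = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * k
    return np.column_stack([np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta),
                            np.cos(phi)])


@dataclass
class SasaResult:
    per_atom: np.ndarray           # Angstrom^2, ordered as structure.atoms()
    per_residue: dict              # (chain_id, seq_id) -> Angstrom^2
    total: float
    probe_radius: float
    n_points: int
    atom_keys: list = field(default_factory=list)

    def residue_area(self, chain_id: str, seq_id: int) -> float:
        return self.per_residue.get((chain_id, seq_id), 0.0)


def _radii(structure: Structure, default_radius: float) -> np.ndarray:
    rads = []
    unknown = set()
    for a in structure.atoms():
        el = a.element.upper()
        if el not in VDW_RADII:
            unknown.add(el)
        rads.append(VDW_RADII.get(el, default_radius))
    if unknown:
        warnings.warn(f"unknown element(s) {sorted(unknown)}: using default "
                      f"radius {default_radius} A", stacklevel=3)
    return np.array(rads)


def sasa(structure: Structure, probe: float = DEFAULT_PROBE,
         n_points: int = DEFAULT_N_POINTS, include_waters: bool = False,
         default_radius: float = DEFAULT_VDW_RADIUS) -> SasaResult:
    """Shrake-Rupley SASA; deterministic for fixed n_points."""
    if not include_waters:
        structure = select(structure, "not water")
    records = list(structure.atom_records())
    if not records:
        raise EtsfaceError("no atoms for SASA (all waters?)")
    xyz = np.array([a.xyz for _, _, a in records])
    rad = _radii(structure, default_radius) + probe
    sphere = fibonacci_sphere(n_points)

    tree = cKDTree(xyz)
    max_r = rad.max()
    # exact duplicates (same centre and radius) contribute once: later
    # copies get zero area and are dropped from the occlusion set
    duplicate_of = np.full(len(records), -1)
    for i, j in sorted(tree.query_pairs(1e-6)):
        if np.isclose(rad[i], rad[j]) and duplicate_of[max(i, j)] < 0:
            duplicate_of[max(i, j)] = min(i, j)
    per_atom = np.empty(len(records))
    for i in range(len(records)):
        if duplicate_of[i] >= 0:
            per_atom[i] = 0.0
            continue
        pts = xyz[i] + rad[i] * sphere
        neighbors = [j for j in tree.query_ball_point(xyz[i], rad[i] + max_r)
                     if j != i and duplicate_of[j] < 0]
        if neighbors:
            nb_xyz = xyz[neighbors]
            nb_rad = rad[neighbors]
            d2 = ((pts[:, None, :] - nb_xyz[None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (nb_rad ** 2)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        per_atom[i] = frac * 4.0 * np.pi * rad[i] ** 2

    per_res: dict = {}
    keys = []
    for (ch, res, _), area in zip(records, per_atom):
        key = (ch.id, res.seq_id)
        per_res[key] = per_res.get(key, 0.0) + area
        keys.append(key)
    return SasaResult(per_atom=per_atom, per_residue=per_res,
                      total=float(per_atom.sum()), probe_radius=probe,
                      n_points=n_points, atom_keys=keys)


@dataclass
class InterfaceSummary:
    buried_area: float                  # one face, Angstrom^2
    interface_residues: dict            # side label -> list of (chain, seq_id)
    percent_of_monomer: dict            # side label -> %
    delta_per_side: dict                # side label -> unhalved dSASA
    parts: tuple
    probe_radius: float
    n_points: int
    area_convention: str = "half"


def interface_area(structure: Structure, partA: str, partB: str,
                   probe: float = DEFAULT_PROBE,
                   n_points: int = DEFAULT_N_POINTS,
                   area_convention: str = "half",
                   residue_cut: float = 0.1) -> InterfaceSummary:
    """Buried area between two disjoint selections of one structure.

    ``area_convention`` 'half' reports dSASA/2 (one face); 'sum' reports the
    full two-sided dSASA.  A residue is an interface residue when it loses
    more than ``residue_cut`` Angstrom^2 on complexation.
    """
    sub_a = select(structure, partA)
    sub_b = select(structure, partB)
    keys_a = {(ch.id, r.seq_id, a.name) for ch, r, a in sub_a.atom_records()}
    keys_b = {(ch.id, r.seq_id, a.name) for ch, r, a in sub_b.atom_records()}
    overlap = keys_a & keys_b
    if overlap:
        raise EtsfaceError(f"selections overlap on {len(overlap)} atoms, "
                           f"e.g. {sorted(overlap)[0]}")
    if not keys_a or not keys_b:
        raise EtsfaceError("empty selection for interface computation")

    res_a = sasa(sub_a, probe, n_points)
    res_b = sasa(sub_b, probe, n_points)
    both = _merge(sub_a, sub_b)
    res_ab = sasa(both, probe, n_points)

    delta_total = res_a.total + res_b.total - res_ab.total
    buried = delta_total / 2.0 if area_convention == "half" else delta_total

    iface: dict = {"A": [], "B": []}
    delta_side = {"A": 0.0, "B": 0.0}
    pct = {}
    for label, solo in (("A", res_a), ("B", res_b)):
        d_side = 0.0
        for key, area_alone in solo.per_residue.items():
            area_complex = res_ab.per_residue.get(key, 0.0)
            loss = area_alone - area_complex
            d_side += loss
            if loss > residue_cut:
                iface[label].append(key)
        delta_side[label] = d_side
        pct[label] = 100.0 * d_side / solo.total if solo.total > 0 else 0.0
        iface[label].sort()
    return InterfaceSummary(buried_area=float(buried),
                            interface_residues=iface,
                            percent_of_monomer=pct,
                            delta_per_side=delta_side,
                            parts=(partA, partB), probe_radius=probe,
                            n_points=n_points, area_convention=area_convention)


def _merge(a: Structure, b: Structure) -> Structure:
    out = a.copy()
    for ch in b.chains:
        dest = out.chain(ch.id)
        if dest is None:
            out.chains.append(ch)
        else:
            dest.residues.extend(ch.residues)
    return out
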