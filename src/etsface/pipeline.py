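"""Pipeline orchestration: run every analysis stage over a set of inputs and
emit a consolidated, deterministic report bundle.

Inputs are coordinate files (PDB/mmCIF) and/or the named synthetic fixtures
("ets_complex", "water_network", "bdna:<SEQUENCE>").  Individual stage
failures are recorded in the report and do not abort the remaining stages.
All numeric thresholds live in PipelineConfig with the package defaults;
the config round-trips through a flat key=value text file.  Logs go to
stderr; report payloads contain no timestamps, so identical configs give
byte-identical output.
"""

from __future__ import annotations

import json
import sys
import time
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import binding_fit, contacts, dna_geometry, interface_sasa, profiles, water_network
from .structure_io import Structure, parse_structure
from .synthetic_structures import (
    build_bdna,
    build_ets_like_complex,
    build_water_network_complex,
)

__all__ = ["PipelineConfig", "run_pipeline", "load_config", "save_config"]


@dataclass
class PipelineConfig:
    inputs: list = field(default_factory=lambda: ["ets_complex", "water_network"])
    out_dir: str = "etsface-report"
    # analysis toggles
    do_contacts: bool = True
    do_interface: bool = True
    do_dna_shape: bool = True
    do_waters: bool = True
    do_bprofile: bool = True
    do_binding_demo: bool = True
    # thresholds (package defaults; every report row carries these)
    hbond_max_da: float = contacts.DEFAULT_MAX_DA
    salt_bridge_max_no: float = contacts.DEFAULT_MAX_NO
    any_atom_cut: float = contacts.DEFAULT_ANY_ATOM_CUT
    probe_radius: float = interface_sasa.DEFAULT_PROBE
    sasa_n_points: int = interface_sasa.DEFAULT_N_POINTS
    water_cutoff: float = water_network.DEFAULT_CUTOFF
    match_radius: float = 1.0
    binding_noise_sd: float = 0.02
    seed: int = 1


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    lines = []
    for f in fields(cfg):
        v = getattr(cfg, f.name)
        if f.name == "inputs":
            v = ",".join(v)
        lines.append(f"{f.name} = {v}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_config(path: str | Path) -> PipelineConfig:
    cfg = PipelineConfig()
    types = {f.name: f.type for f in fields(cfg)}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, _, raw = line.partition("=")
        key, raw = key.strip(), raw.strip()
        if key not in types:
            raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
        current = getattr(cfg, key)
        if key == "inputs":
            value = [s for s in raw.split(",") if s]
        elif isinstance(current, bool):
            value = raw.lower() in ("1", "true", "yes")
        elif isinstance(current, int):
            value = int(raw)
        elif isinstance(current, float):
            value = float(raw)
        else:
            value = raw
        setattr(cfg, key, value)
    return cfg


def _load_input(name: str) -> Structure:
    if name == "ets_complex":
        return build_ets_like_complex()[0]
    if name == "water_network":
        return build_water_network_complex()[0]
    if name.startswith("bdna:"):
        return build_bdna(name.split(":", 1)[1])
    return parse_structure(name)


def _log(msg: str) -> None:
    print(msg, file=sys.stderr)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all enabled stages; returns (and writes) the report dict."""
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": {**asdict(cfg)}, "structures": {}, "errors": {}}

    for name in cfg.inputs:
        t0 = time.time()
        entry: dict = {}
        report["structures"][name] = entry
        try:
            st = _load_input(name)
        except Exception as exc:  # noqa: BLE001 - stage isolation by design
            report["errors"][name] = f"load: {exc}"
            continue
        entry["n_atoms"] = st.n_atoms
        entry["chains"] = [c.id for c in st.chains]

        pairs = []
        try:
            pairs = dna_geometry.find_base_pairs(st)
            entry["n_base_pairs"] = len(pairs)
        except Exception as exc:
            report["errors"][f"{name}/pairs"] = str(exc)

        if cfg.do_contacts and pairs:
            try:
                cm = contacts.build_contact_map(
                    st, pairs, max_da=cfg.hbond_max_da,
                    max_no=cfg.salt_bridge_max_no, vdw_cut=cfg.any_atom_cut)
                rows = []
                for c in cm.contacts:
                    r1, r2 = c.partners
                    rows.append({"kind": c.kind, "res1": str(r1), "res2": str(r2),
                                 "distance": round(c.distance, 3),
                                 "dna_part": c.dna_part,
                                 "ebs_position": c.position_label})
                pd.DataFrame(rows).to_csv(out_dir / f"{_safe(name)}_contacts.tsv",
                                          sep="\t", index=False)
                entry["contacts"] = {
                    "n_hbonds": sum(1 for c in cm.contacts if c.kind == "hbond"),
                    "n_salt_bridges": sum(1 for c in cm.contacts
                                          if c.kind == "salt_bridge"),
                    "hbond_phosphate_residues": sorted(map(list, cm.residues_of_kind(
                        "hbond", "phosphate_backbone"))),
                    "salt_bridge_residues": sorted(map(list, cm.residues_of_kind(
                        "salt_bridge"))),
                    "span_bp": contacts.contacted_bp_span(
                        st, pairs, cutoff=cfg.any_atom_cut),
                    "thresholds": {"max_da": cfg.hbond_max_da,
                                   "max_no": cfg.salt_bridge_max_no,
                                   "any_atom": cfg.any_atom_cut},
                }
            except Exception as exc:
                report["errors"][f"{name}/contacts"] = str(exc)

        if cfg.do_interface:
            try:
                has_protein = any(r.kind == "protein" for r in st.residues())
                has_dna = any(r.kind == "dna" for r in st.residues())
                if has_protein and has_dna:
                    summ = interface_sasa.interface_area(
                        st, "protein", "dna", probe=cfg.probe_radius,
                        n_points=cfg.sasa_n_points)
                    entry["interface"] = {
                        "buried_area": round(summ.buried_area, 1),
                        "percent_of_monomer": {k: round(v, 2) for k, v in
                                               summ.percent_of_monomer.items()},
                        "n_interface_residues": {
                            k: len(v) for k, v in summ.interface_residues.items()},
                        "convention": summ.area_convention,
                        "n_points": summ.n_points,
                    }
            except Exception as exc:
                report["errors"][f"{name}/interface"] = str(exc)

        if cfg.do_dna_shape and pairs:
            try:
                bend = dna_geometry.bend_angle(pairs)
                groove = dna_geometry.groove_widths(st, pairs)
                prof = pd.DataFrame({"level": groove.levels,
                                     "major": groove.major,
                                     "minor": groove.minor})
                prof.to_csv(out_dir / f"{_safe(name)}_grooves.tsv", sep="\t",
                            index=False)
                entry["dna_shape"] = {
                    "bend_deg": round(bend.bend_angle, 2),
                    "major_max": round(groove.major_max, 2),
                    "minor_min": round(groove.minor_min, 2),
                }
            except Exception as exc:
                report["errors"][f"{name}/dna_shape"] = str(exc)

        if cfg.do_waters:
            try:
                bridges = water_network.find_bridging_waters(
                    st, cutoff=cfg.water_cutoff)
                entry["waters"] = {"n_bridging": len(bridges)}
                if bridges:
                    graph = water_network.build_hbond_graph(
                        st, bridges, cutoff=cfg.water_cutoff)
                    if graph.n_edges <= water_network.MAX_EDGES:
                        sols = water_network.enumerate_h_assignments(graph)
                        entry["waters"]["n_edges"] = graph.n_edges
                        entry["waters"]["n_assignments"] = len(sols)
                        rep = water_network.selectivity_report(graph, sols)
                        entry["waters"]["selectivity"] = {
                            "unique": rep.unique,
                            "water_role": rep.water_role,
                            "allowed_bases": rep.allowed_bases,
                        }
            except Exception as exc:
                report["errors"][f"{name}/waters"] = str(exc)

        if cfg.do_bprofile:
            try:
                prof_rows = []
                for ch in st.chains:
                    if any(r.kind == "protein" for r in ch.residues):
                        bp = profiles.bfactor_profile(st, ch.id)
                        prof_rows += [{"chain": ch.id, "residue": n,
                                       "raw_b": round(float(r), 3),
                                       "normalized_b": round(float(z), 3)}
                                      for n, r, z in zip(bp.residue_numbers,
                                                         bp.raw_mean_b,
                                                         bp.normalized_b)]
                if prof_rows:
                    pd.DataFrame(prof_rows).to_csv(
                        out_dir / f"{_safe(name)}_bprofile.tsv", sep="\t",
                        index=False)
                    entry["bprofile"] = {"n_rows": len(prof_rows)}
            except Exception as exc:
                report["errors"][f"{name}/bprofile"] = str(exc)

        _log(f"[etsface] {name}: {time.time() - t0:.2f}s")

    if cfg.do_binding_demo:
        t0 = time.time()
        try:
            iso = binding_fit.simulate_isotherm(
                kd=2.7e-10, hill=1.0, bmax=1.0,
                noise_sd=cfg.binding_noise_sd, seed=cfg.seed)
            fit = binding_fit.fit_isotherm(iso)
            report["binding_demo"] = {
                "true_kd": 2.7e-10, "fitted_kd": fit.kd,
                "hill": round(fit.hill, 3), "bmax": round(fit.bmax, 3),
                "noise_sd": cfg.binding_noise_sd, "seed": cfg.seed,
            }
        except Exception as exc:
            report["errors"]["binding_demo"] = str(exc)
        _log(f"[etsface] binding demo: {time.time() - t0:.2f}s")

    (out_dir / "report.json").write_text(json.dumps(report, indent=2,
                                                    sort_keys=True) + "\n")
    return report


def _safe(name: str) -> str:
    return "".join(c if c.isalnum() or c in "-_" else "_" for c in name)
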