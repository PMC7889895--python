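"""End-to-end analysis of a two-protein redox co-complex.

Given a complex structure, a chain map naming the two binding partners, and
optional free-reference structures and cofactor selectors, the pipeline runs
the four analysis stages in order — interface (buried area, hydrogen bonds,
closest contact, interface residues, B-factor comparison), conformational
change (anchored deviation profiles, macrocycle distortion), tunneling
pathways (per-step best paths, donor-atom ranking, bridging residues) and
energetics (the empirical rate ruler along the redox chain) — and collects
everything into one deterministic, JSON-serializable report.

Configuration is explicit: chain identities and cofactor selectors are never
guessed from the file.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field
from typing import Any

import pandas as pd

from . import __version__
from .atoms import CofactorGroup, Structure, select_atoms
from .contacts import closest_contact, detect_hbonds, hbond_table, interface_bfactor_summary
from .geometry import deviation_profile, macrocycle_distortion
from .io import read_structure
from .pathways import (
    CouplingParams,
    best_path,
    bridging_residues,
    build_molecular_graph,
    donor_atom_ranking,
)
from .ruler import RedoxCenter, chain_report
from .surface import SasaParams, buried_area, interface_residues

__all__ = ["AnalysisConfig", "CofactorSpec", "run_analysis", "write_report"]


@dataclass
class CofactorSpec:
    """Selector for one prosthetic group plus its role-tagged atom names."""

    label: str
    selector: dict  # select_atoms query, e.g. {"chain": "C", "res_name": "HEM", "res_seq": 1}
    center_names: list[str] = field(default_factory=list)
    edge_names: list[str] = field(default_factory=list)  # empty = all atoms
    potential_mv: float | None = None  # midpoint potential, millivolts

    def resolve(self, structure: Structure) -> CofactorGroup:
        atoms = select_atoms(structure, **self.selector)
        if not atoms:
            raise ValueError(f"cofactor {self.label!r}: selector matched no atoms")
        by_name = {a.name: a for a in atoms}
        missing = [n for n in self.center_names + self.edge_names if n not in by_name]
        if missing:
            raise ValueError(f"cofactor {self.label!r}: atoms not found: {missing}")
        center = [by_name[n] for n in self.center_names] or list(atoms)
        edge = [by_name[n] for n in self.edge_names] or list(atoms)
        return CofactorGroup(self.label, list(atoms), center_atoms=center, edge_atoms=edge)


@dataclass
class AnalysisConfig:
    """Fully explicit inputs of one analysis run."""

    complex_path: str
    side_a: dict  # selection query for binding partner A (e.g. the soluble carrier)
    side_b: dict  # selection query for partner B
    reference_paths: dict = field(default_factory=dict)  # label -> path
    deviation_profiles: list[dict] = field(default_factory=list)
    # each: {"reference": label, "align_on": query, "report_on": query}
    cofactors: list[CofactorSpec] = field(default_factory=list)  # chain order = ET order
    sasa: SasaParams = field(default_factory=SasaParams)
    coupling: CouplingParams = field(default_factory=CouplingParams)
    lambda_reorg: float = 0.7
    rho_packing: float = 0.77
    hbond_max: float = 3.5
    hbond_min: float = 2.2
    min_delta_asa: float = 1.0

    @classmethod
    def from_json(cls, path: str) -> "AnalysisConfig":
        with open(path) as fh:
            raw = json.load(fh)
        cofs = [CofactorSpec(**c) for c in raw.pop("cofactors", [])]
        sasa = SasaParams(**raw.pop("sasa", {}))
        coupling = CouplingParams(**raw.pop("coupling", {}))
        return cls(cofactors=cofs, sasa=sasa, coupling=coupling, **raw)


def run_analysis(config: AnalysisConfig) -> dict:
    """Run all stages and return the report as a plain nested dict.

    Fails fast: every selector is resolved before any stage computes.
    """
    structure = read_structure(config.complex_path)
    atoms_a = select_atoms(structure, **config.side_a)
    atoms_b = select_atoms(structure, **config.side_b)
    if not atoms_a or not atoms_b:
        raise ValueError("side_a / side_b selections must both match atoms")
    groups = [spec.resolve(structure) for spec in config.cofactors]
    references = {
        label: read_structure(path) for label, path in config.reference_paths.items()
    }
    for prof in config.deviation_profiles:
        if prof["reference"] not in references:
            raise ValueError(f"deviation profile references unknown structure {prof['reference']!r}")

    report: dict[str, Any] = {"provenance": _provenance(config)}

    # --- interface stage ---
    buried, contact = buried_area(atoms_a, atoms_b, config.sasa)
    hbonds = detect_hbonds(atoms_a, atoms_b, config.hbond_max, config.hbond_min)
    cc_dist, (cc_a, cc_b) = closest_contact(atoms_a, atoms_b)
    iface = interface_residues(atoms_a, atoms_b, config.sasa, config.min_delta_asa)
    iface_keys_a = [
        (r.chain, int(r.res_seq), r.insertion_code)
        for r in iface.itertuples()
        if r.side == "a"
    ]
    bsummary = None
    if iface_keys_a:
        try:
            bsummary = interface_bfactor_summary(structure, config.side_a, iface_keys_a)
        except ValueError:
            bsummary = None
    report["interface"] = {
        "buried_area": buried,
        "contact_area": contact,
        "n_hbonds": len(hbonds),
        "hbonds": hbond_table(hbonds).to_dict(orient="records"),
        "closest_contact": {
            "distance": cc_dist,
            "atom_a": f"{cc_a.residue_label}/{cc_a.name}",
            "atom_b": f"{cc_b.residue_label}/{cc_b.name}",
        },
        "interface_residues": iface.to_dict(orient="records"),
        "bfactor_summary": bsummary,
    }

    # --- conformational stage ---
    conf: dict[str, Any] | None = None
    if config.deviation_profiles:
        conf = {"profiles": []}
        for prof in config.deviation_profiles:
            table = deviation_profile(
                references[prof["reference"]],
                structure,
                align_on=prof["align_on"],
                report_on=prof["report_on"],
            )
            worst = table.loc[table["max_deviation"].idxmax()]
            conf["profiles"].append(
                {
                    "reference": prof["reference"],
                    "n_residues": int(len(table)),
                    "max_deviation": float(worst["max_deviation"]),
                    "max_deviation_residue": f"{worst['res_name']}{worst['res_seq']}:{worst['chain']}",
                    "per_residue": table.to_dict(orient="records"),
                }
            )
    report["conformational"] = conf

    # --- pathway + energetics stages ---
    pathway_block: dict[str, Any] | None = None
    energetics: dict[str, Any] | None = None
    if len(groups) >= 2:
        graph = build_molecular_graph(structure, config.coupling)
        steps = []
        for donor, acceptor in zip(groups, groups[1:]):
            res = best_path(graph, donor.edge_atoms, acceptor.edge_atoms)
            entry: dict[str, Any] = {
                "donor": donor.label,
                "acceptor": acceptor.label,
                "connected": res.connected,
            }
            if res.connected:
                entry.update(
                    {
                        "total_coupling": res.total_coupling,
                        "log10_coupling": res.log10_coupling,
                        "n_covalent": res.n_covalent,
                        "n_hbond": res.n_hbond,
                        "n_space": res.n_space,
                        "steps": res.steps_table().to_dict(orient="records"),
                        "bridging_residues": bridging_residues(res).to_dict(orient="records"),
                    }
                )
            steps.append(entry)
        ranking = donor_atom_ranking(graph, groups[0], groups[1]).to_dict(orient="records")
        pathway_block = {"steps": steps, "donor_atom_ranking": ranking}

        centers = [
            RedoxCenter(
                label=spec.label,
                cofactor=group,
                midpoint_potential=None if spec.potential_mv is None else spec.potential_mv / 1000.0,
            )
            for spec, group in zip(config.cofactors, groups)
        ]
        table = chain_report(centers, config.lambda_reorg, config.rho_packing)
        energetics = {
            "steps": table.to_dict(orient="records"),
            "span_sum_of_steps": table.attrs["span_sum_of_steps"],
            "span_direct": table.attrs["span_direct"],
        }
    report["pathway"] = pathway_block
    report["energetics"] = energetics
    return report


def _provenance(config: AnalysisConfig) -> dict:
    checksums = {}
    paths = {"complex": config.complex_path, **config.reference_paths}
    for label, path in paths.items():
        h = hashlib.sha256()
        with open(path, "rb") as fh:
            h.update(fh.read())
        checksums[label] = h.hexdigest()
    cfg = {
        "complex_path": config.complex_path,
        "side_a": config.side_a,
        "side_b": config.side_b,
        "reference_paths": config.reference_paths,
        "lambda_reorg": config.lambda_reorg,
        "rho_packing": config.rho_packing,
        "hbond_window": [config.hbond_min, config.hbond_max],
        "min_delta_asa": config.min_delta_asa,
        "sasa": {"probe_radius": config.sasa.probe_radius, "n_points": config.sasa.n_points},
        "coupling": {
            "eps_covalent": config.coupling.eps_covalent,
            "beta_space": config.coupling.beta_space,
            "through_space_cutoff": config.coupling.through_space_cutoff,
        },
        "cofactors": [
            {"label": c.label, "selector": c.selector, "potential_mv": c.potential_mv}
            for c in config.cofactors
        ],
    }
    blob = json.dumps(cfg, sort_keys=True).encode()
    return {
        "package_version": __version__,
        "config": cfg,
        "config_hash": hashlib.sha256(blob).hexdigest(),
        "input_checksums": checksums,
    }


def write_report(report: dict, out_dir: str, formats: tuple[str, ...] = ("json", "tsv", "text")) -> list[str]:
    """Write the report as canonical JSON plus TSV tables and a text summary."""
    os.makedirs(out_dir, exist_ok=True)
    written: list[str] = []
    if "json" in formats:
        path = os.path.join(out_dir, "report.json")
        with open(path, "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True, default=_jsonable)
            fh.write("\n")
        written.append(path)
    if "tsv" in formats:
        tables = {
            "hbonds.tsv": report["interface"]["hbonds"],
            "interface_residues.tsv": report["interface"]["interface_residues"],
        }
        if report.get("pathway"):
            tables["donor_atom_ranking.tsv"] = report["pathway"]["donor_atom_ranking"]
        if report.get("energetics"):
            tables["energetics.tsv"] = report["energetics"]["steps"]
        for name, records in tables.items():
            path = os.path.join(out_dir, name)
            pd.DataFrame(records).to_csv(path, sep="\t", index=False)
            written.append(path)
    if "text" in formats:
        path = os.path.join(out_dir, "report.txt")
        with open(path, "w") as fh:
            fh.write(_text_summary(report))
        written.append(path)
    return written


def _jsonable(obj):
    try:
        import numpy as np

        if isinstance(obj, np.generic):
            return obj.item()
        if isinstance(obj, np.ndarray):
            return obj.tolist()
    except ImportError:  # pragma: no cover
        pass
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _text_summary(report: dict) -> str:
    lines = ["Redox co-complex analysis", "=" * 26, ""]
    iface = report["interface"]
    lines += [
        f"Buried area: {iface['buried_area']:.0f} A^2 (contact area {iface['contact_area']:.0f} A^2)",
        f"Hydrogen bonds across the interface: {iface['n_hbonds']}",
        f"Closest contact: {iface['closest_contact']['distance']:.1f} A "
        f"({iface['closest_contact']['atom_a']} ... {iface['closest_contact']['atom_b']})",
        "",
    ]
    if report.get("conformational"):
        for prof in report["conformational"]["profiles"]:
            lines.append(
                f"Deviation vs {prof['reference']}: max {prof['max_deviation']:.1f} A "
                f"at {prof['max_deviation_residue']}"
            )
        lines.append("")
    if report.get("pathway"):
        for step in report["pathway"]["steps"]:
            if step["connected"]:
                lines.append(
                    f"Pathway {step['donor']} -> {step['acceptor']}: "
                    f"log10 coupling {step['log10_coupling']:.2f} "
                    f"({step['n_covalent']} covalent, {step['n_hbond']} H-bond, "
                    f"{step['n_space']} space steps)"
                )
            else:
                lines.append(f"Pathway {step['donor']} -> {step['acceptor']}: disconnected")
        lines.append("")
    if report.get("energetics"):
        for row in report["energetics"]["steps"]:
            rate = row.get("log10_rate")
            rate_txt = f", log10 k = {rate:.2f}" if rate is not None else ""
            lines.append(
                f"Step {row['donor']} -> {row['acceptor']}: "
                f"center-to-center {row['center_to_center']:.1f} A, "
                f"edge-to-edge {row['edge_to_edge']:.1f} A{rate_txt}"
            )
        lines.append("")
    return "\n".join(lines) + "\n"
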