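"""Whole-complex analysis reports.

``analyze`` runs the docking-geometry, interface-contact and surface modules
on one annotated complex and returns a JSON-serializable report whose body is
byte-identical for identical inputs and parameters.  ``compare`` appends
superposition sections (fit/measure RMSDs and per-residue displacement
profiles) for pairs of structures.
"""

from __future__ import annotations

import json
from typing import Dict, Optional, Sequence

import pandas as pd

from . import __version__
from .contacts import (
    LOOP_COLUMNS,
    FRAMEWORK_COLUMNS,
    TARGETS,
    build_contact_table,
    chain_share,
    contact_percentages,
)
from .frames import docking_geometry, rank_percentile
from .sasa import SasaParams, buried_peptide_fraction
from .sc import ScParams, shape_complementarity
from .structure import AnnotatedComplex
from .superpose import Selection, displacement_profile, fit_measure_rmsd


def _round(x: float, nd: int = 4) -> float:
    return float(round(float(x), nd))


def analyze(
    complex: AnnotatedComplex,
    cutoff: float = 4.0,
    sasa_params: Optional[SasaParams] = None,
    sc_params: Optional[ScParams] = None,
    reference_table: Optional[pd.DataFrame] = None,
    incident_strategy: str = "elevation",
    include_surfaces: bool = True,
) -> Dict:
    """Full single-complex analysis: geometry, contacts, surfaces."""
    ann = complex.annotation
    report: Dict = {
        "complex": complex.structure.identifier,
        "provenance": {
            "tool": "tcrpmhc",
            "version": __version__,
            "parameters": {
                "contact_cutoff": cutoff,
                "incident_strategy": incident_strategy,
                "probe_radius": (sasa_params or SasaParams()).probe_radius,
            },
            "roles": dict(sorted(ann.role_map.items())),
        },
    }

    has_tcr = ann.has_roles("tcr_alpha", "tcr_beta")
    has_pmhc = ann.has_roles("mhc_heavy", "peptide")

    if has_tcr and has_pmhc:
        geom = docking_geometry(complex, incident_strategy=incident_strategy)
        report["docking_geometry"] = {
            "crossing_angle_deg": _round(geom.crossing_angle),
            "incident_angle_deg": _round(geom.incident_angle),
            "x_pos": _round(geom.x_pos),
            "y_pos": _round(geom.y_pos),
            "canonical_polarity": geom.canonical_polarity,
            "anchor_ca_fallback": geom.anchor_fallback,
        }
        if reference_table is not None:
            ranks = {}
            for descriptor, column in (
                ("incident_angle_deg", "incident_angle"),
                ("crossing_angle_deg", "crossing_angle"),
                ("x_pos", "x_pos"),
            ):
                rank, pct = rank_percentile(
                    report["docking_geometry"][descriptor],
                    reference_table[column].to_numpy(),
                )
                ranks[column] = {"rank": rank, "percentile": pct,
                                 "n_total": len(reference_table) + 1}
            report["reference_ranks"] = ranks

        table = build_contact_table(complex, cutoff=cutoff)
        pct = contact_percentages(table)
        contacts_section: Dict = {"cutoff": cutoff}
        for target in TARGETS:
            contacts_section[target] = {
                "counts": {loop: table.count(loop, target)
                           for loop in LOOP_COLUMNS + FRAMEWORK_COLUMNS},
                "loop_total": table.loop_total(target),
                "grand_total": table.grand_total(target),
                "percentages": {loop: pct.percent(loop, target)
                                for loop in LOOP_COLUMNS + FRAMEWORK_COLUMNS},
                "hbonds": sum(
                    1 for r in table.records.get(target, []) if r.category == "hbond"
                ),
            }
            for chain in ("alpha", "beta"):
                count, share = chain_share(table, chain, target)
                contacts_section[target][f"v{chain}_share"] = {
                    "count": count, "percent": share,
                }
        contacts_section["b2m_contacts"] = table.b2m_contacts
        contacts_section["water_contacts"] = table.water_contacts
        report["contacts"] = contacts_section

        if include_surfaces:
            buried_area, buried_frac = buried_peptide_fraction(
                complex, sasa_params or SasaParams()
            )
            report["buried_peptide_surface"] = {
                "buried_area_A2": _round(buried_area, 1),
                "buried_fraction": _round(buried_frac),
            }
            tcr_side = (complex.atoms_of_role("tcr_alpha")
                        + complex.atoms_of_role("tcr_beta"))
            pmhc_side = (complex.atoms_of_role("peptide")
                         + complex.atoms_of_role("mhc_heavy"))
            sc = shape_complementarity(tcr_side, pmhc_side,
                                       sc_params or ScParams(),
                                       sasa_params or SasaParams())
            report["shape_complementarity"] = {
                "sc": _round(sc.sc),
                "median_a_to_b": _round(sc.median_a_to_b),
                "median_b_to_a": _round(sc.median_b_to_a),
                "n_dots_a": sc.n_dots_a,
                "n_dots_b": sc.n_dots_b,
            }
    return report


def compare(
    ref: AnnotatedComplex,
    mov: AnnotatedComplex,
    fit_selection: Sequence[Selection],
    measure_selection: Optional[Sequence[Selection]] = None,
    strict: bool = True,
) -> Dict:
    """Superposition section: fit/measure RMSD plus displacement profile."""
    result = fit_measure_rmsd(ref, mov, fit_selection, measure_selection,
                              strict=strict)
    profile = displacement_profile(
        ref, mov, measure_selection or fit_selection,
        superposition=result.superposition,
    )
    section = {
        "ref": ref.structure.identifier,
        "mov": mov.structure.identifier,
        "fit_selection": [_selection_dict(s) for s in fit_selection],
        "measure_selection": [
            _selection_dict(s) for s in (measure_selection or fit_selection)
        ],
        "rmsd_A": _round(result.rmsd),
        "n_atoms_fit": result.n_atoms_fit,
        "n_atoms_measured": result.n_atoms_measured,
        "displacements": {
            f"{role}:{seq}{icode}": _round(d)
            for (role, seq, icode), d in sorted(profile.per_residue.items())
        },
    }
    if profile.max_residue is not None:
        role, seq, icode = profile.max_residue
        section["max_displacement"] = {
            "residue": f"{role}:{seq}{icode}",
            "displacement_A": _round(profile.max_displacement),
        }
    return section


def _selection_dict(sel: Selection) -> Dict:
    return {
        "role": sel.role,
        "residues": [list(r) for r in sel.residues] if sel.residues else None,
        "atoms": sel.atoms,
    }


def to_json(report: Dict) -> str:
    """Deterministic serialization (sorted keys, fixed separators)."""
    return json.dumps(report, sort_keys=True, indent=2)
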