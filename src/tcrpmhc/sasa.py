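"""Solvent-accessible surface area (Shrake-Rupley) and buried peptide surface.

Each atom's sphere of radius (vdW radius + probe) is sampled with a fixed
deterministic spiral lattice; the accessible fraction of sample points gives
the per-atom area.  Buried peptide surface is the SASA the peptide loses on
TCR engagement: SASA(peptide in pMHC alone) - SASA(peptide in the full
TCR-pMHC complex).

Radii sets are data.  The default ("chothia") is the united-atom-flavoured
set used by classic SASA programs; "bondi" element radii are provided for
cross-checks against other implementations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import AnnotationError, RadiiError
from .structure import AnnotatedComplex, AtomRecord

RADII_SETS: Dict[str, Dict[str, float]] = {
    # Chothia (1976)-style radii as used by naccess-lineage programs
    "chothia": {"C": 1.87, "N": 1.65, "O": 1.40, "S": 1.85, "P": 1.90, "H": 1.00},
    # Bondi element vdW radii (matches biotite's "Single" set for protein atoms)
    "bondi": {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80, "H": 1.20},
}
DEFAULT_RADIUS_FALLBACK = 1.80


@dataclass
class SasaParams:
    probe_radius: float = 1.4
    n_sphere_points: int = 960
    radii_set: Mapping[str, float] = field(
        default_factory=lambda: dict(RADII_SETS["chothia"])
    )
    fallback_radius: float = DEFAULT_RADIUS_FALLBACK

    def __post_init__(self) -> None:
        if self.probe_radius <= 0:
            raise ValueError("probe_radius must be positive")
        if self.n_sphere_points < 92:
            raise ValueError("n_sphere_points must be >= 92")

    def radius_of(self, atom: AtomRecord) -> float:
        r = self.radii_set.get(atom.element.upper())
        if r is None:
            r = self.fallback_radius
            if r is None or r <= 0:
                raise RadiiError(
                    f"no radius for element {atom.element!r} and no fallback"
                )
        return float(r)


@dataclass
class SasaResult:
    per_atom: List[float]
    atoms: List[AtomRecord]

    @property
    def total(self) -> float:
        return float(np.sum(self.per_atom))

    def per_residue(self) -> Dict[Tuple[str, int, str], float]:
        out: Dict[Tuple[str, int, str], float] = {}
        for atom, area in zip(self.atoms, self.per_atom):
            key = (atom.chain_id, atom.residue_seq, atom.insertion_code)
            out[key] = out.get(key, 0.0) + area
        return out

    def per_chain(self) -> Dict[str, float]:
        out: Dict[str, float] = {}
        for atom, area in zip(self.atoms, self.per_atom):
            out[atom.chain_id] = out.get(atom.chain_id, 0.0) + area
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "chain": c, "residue": s, "insertion_code": i,
                "sasa": round(a, 3),
            }
            for (c, s, i), a in sorted(self.per_residue().items())
        ]
        return pd.DataFrame(rows)


def sphere_points(n: int) -> np.ndarray:
    """Deterministic near-uniform unit-sphere lattice (golden-spiral)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0**0.5) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def compute_sasa(
    atoms: Sequence[AtomRecord],
    params: SasaParams | None = None,
    context: Sequence[AtomRecord] | None = None,
) -> SasaResult:
    """Shrake-Rupley SASA of ``atoms``.

    ``context`` adds occluding atoms whose own areas are not computed (used
    for component-within-complex areas).  Hydrogens are ignored on both
    sides.
    """
    params = params or SasaParams()
    atoms = [a for a in atoms if not a.is_hydrogen]
    occluders = list(atoms) + [
        a for a in (context or []) if not a.is_hydrogen
    ]
    if not atoms:
        return SasaResult(per_atom=[], atoms=[])

    unit = sphere_points(params.n_sphere_points)
    coords = np.array([a.coords for a in occluders])
    radii = np.array([params.radius_of(a) for a in occluders])
    expanded = radii + params.probe_radius
    tree = cKDTree(coords)
    max_expanded = float(expanded.max())

    per_atom: List[float] = []
    for i in range(len(atoms)):
        r_i = expanded[i]
        points = coords[i] + r_i * unit
        # any occluder whose expanded sphere could reach this atom's surface
        neighbor_idx = [
            j for j in tree.query_ball_point(coords[i], r_i + max_expanded)
            if j != i
        ]
        if neighbor_idx:
            diff = points[:, None, :] - coords[neighbor_idx][None, :, :]
            d2 = np.einsum("ijk,ijk->ij", diff, diff)
            buried = (d2 < (expanded[neighbor_idx] ** 2)[None, :] - 1e-12).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        per_atom.append(float(frac * 4.0 * np.pi * r_i**2))
    return SasaResult(per_atom=per_atom, atoms=list(atoms))


def buried_peptide_fraction(
    complex: AnnotatedComplex, params: SasaParams | None = None
) -> Tuple[float, float]:
    """Peptide surface buried by TCR engagement.

    Returns (buried_area in A^2, buried_fraction), where the reference is the
    peptide's SASA within the pMHC alone (heavy chain + beta-2-microglobulin
    when present) and the buried area is the loss of that SASA once the TCR
    chains are added.
    """
    params = params or SasaParams()
    ann = complex.annotation
    if not ann.has_roles("peptide", "mhc_heavy", "tcr_alpha", "tcr_beta"):
        raise AnnotationError(
            "buried peptide fraction requires peptide, mhc_heavy and both TCR roles"
        )
    peptide = complex.atoms_of_role("peptide")
    pmhc_context = list(complex.atoms_of_role("mhc_heavy"))
    if ann.chain_for_role("b2m") is not None:
        pmhc_context += complex.atoms_of_role("b2m")
    tcr = complex.atoms_of_role("tcr_alpha") + complex.atoms_of_role("tcr_beta")

    free = compute_sasa(peptide, params, context=pmhc_context).total
    bound = compute_sasa(peptide, params, context=pmhc_context + tcr).total
    buried = free - bound
    if free <= 0:
        raise AnnotationError("peptide has zero accessible surface within pMHC")
    return buried, buried / free
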