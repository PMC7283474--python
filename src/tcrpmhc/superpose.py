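"""Rigid-body superposition and conformational-change metrics.

Implements the Kabsch least-squares superposition (proper rotations only),
fit-on-one-selection / measure-on-another RMSDs, and per-residue displacement
profiles.  Residue correspondence is by chain role plus author residue
number; no sequence alignment is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import PairingError
from .structure import AnnotatedComplex

logger = logging.getLogger(__name__)

MAIN_CHAIN_ATOMS = ("N", "CA", "C", "O")

AtomKey = Tuple[str, int, str, str]  # (role, residue_seq, insertion_code, atom_name)


@dataclass
class SuperpositionResult:
    rotation: np.ndarray   # 3x3, proper
    translation: np.ndarray
    rmsd: float
    n_atoms_fit: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, float) @ self.rotation.T + self.translation


def kabsch_superpose(coords_a, coords_b) -> SuperpositionResult:
    """Least-squares rigid transform taking ``coords_b`` onto ``coords_a``.

    Returns the proper rotation R and translation t minimizing
    ||R b + t - a||; reflections are rejected.  Collinear inputs produce a
    warning (the in-line rotation component is arbitrary) but still return
    the least-squares solution.
    """
    a = np.asarray(coords_a, dtype=float).reshape(-1, 3)
    b = np.asarray(coords_b, dtype=float).reshape(-1, 3)
    if a.shape != b.shape:
        raise PairingError(f"coordinate count mismatch: {a.shape[0]} vs {b.shape[0]}")
    if a.shape[0] < 3:
        raise PairingError("need at least 3 paired atoms")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    a0, b0 = a - ca, b - cb
    h = b0.T @ a0
    u, s, vt = np.linalg.svd(h)
    if s[1] < 1e-10:
        logger.warning("superposition input nearly collinear; rotation about the "
                       "common axis is arbitrary")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = ca - rot @ cb
    moved = b @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((moved - a) ** 2, axis=1))))
    return SuperpositionResult(rotation=rot, translation=trans, rmsd=rmsd,
                               n_atoms_fit=a.shape[0])


# ---------------------------------------------------------------------------
# Selections


@dataclass
class Selection:
    """A set of atoms addressed by role, residue ranges and atom subset.

    atoms: ``ca`` | ``main_chain`` | ``all_non_h`` | ``custom`` (with
    ``atom_names``).  ``exclude_residue_sidechains`` drops all non-main-chain
    atoms of the listed residue numbers (e.g. to exclude a mutated side
    chain from an all-atom comparison).
    """

    role: str
    residues: Optional[Sequence[Tuple[int, int]]] = None  # inclusive ranges
    atoms: str = "ca"
    atom_names: Optional[Sequence[str]] = None
    exclude_residues: Sequence[Tuple[int, int]] = field(default_factory=tuple)
    exclude_residue_sidechains: Sequence[int] = field(default_factory=tuple)

    def _in_ranges(self, seq: int, ranges) -> bool:
        return any(lo <= seq <= hi for lo, hi in ranges)

    def _wants_atom(self, atom_name: str) -> bool:
        if self.atoms == "ca":
            return atom_name == "CA"
        if self.atoms == "main_chain":
            return atom_name in MAIN_CHAIN_ATOMS
        if self.atoms == "all_non_h":
            return True
        if self.atoms == "custom":
            return atom_name in set(self.atom_names or ())
        raise ValueError(f"unknown atom subset {self.atoms!r}")

    def resolve(self, complex: AnnotatedComplex) -> Dict[AtomKey, np.ndarray]:
        chain = complex.chain_for_role(self.role)
        out: Dict[AtomKey, np.ndarray] = {}
        for res in chain.polymer_residues():
            if self.residues is not None and not self._in_ranges(res.seq, self.residues):
                continue
            if self.exclude_residues and self._in_ranges(res.seq, self.exclude_residues):
                continue
            drop_side = res.seq in set(self.exclude_residue_sidechains)
            for atom in res.atoms:
                if atom.is_hydrogen or atom.is_hetero:
                    continue
                if not self._wants_atom(atom.name):
                    continue
                if drop_side and atom.name not in MAIN_CHAIN_ATOMS:
                    continue
                out[(self.role, res.seq, res.insertion_code, atom.name)] = atom.coords
        return out


def _resolve_many(
    complex: AnnotatedComplex, selections: Sequence[Selection]
) -> Dict[AtomKey, np.ndarray]:
    out: Dict[AtomKey, np.ndarray] = {}
    for sel in selections:
        out.update(sel.resolve(complex))
    return out


def _paired_coords(
    ref: AnnotatedComplex, mov: AnnotatedComplex, selections: Sequence[Selection],
    strict: bool = True,
) -> Tuple[np.ndarray, np.ndarray, List[AtomKey]]:
    ref_map = _resolve_many(ref, selections)
    mov_map = _resolve_many(mov, selections)
    common = sorted(set(ref_map) & set(mov_map))
    if strict:
        unmatched = sorted(set(ref_map) ^ set(mov_map))
        if unmatched:
            raise PairingError(
                f"{len(unmatched)} atoms unmatched between structures, e.g. "
                f"{unmatched[:5]}"
            )
    if not common:
        raise PairingError("selections share no atoms between the two structures")
    ref_xyz = np.array([ref_map[k] for k in common])
    mov_xyz = np.array([mov_map[k] for k in common])
    return ref_xyz, mov_xyz, common


@dataclass
class FitMeasureResult:
    rmsd: float
    n_atoms_fit: int
    n_atoms_measured: int
    superposition: SuperpositionResult
    fit_keys: List[AtomKey]
    measure_keys: List[AtomKey]


def fit_measure_rmsd(
    ref: AnnotatedComplex,
    mov: AnnotatedComplex,
    fit_selection: Sequence[Selection],
    measure_selection: Optional[Sequence[Selection]] = None,
    strict: bool = True,
) -> FitMeasureResult:
    """Superpose on ``fit_selection`` and report RMSD over ``measure_selection``.

    The transform is computed once on the fit atoms; the measured RMSD is
    evaluated without refitting.  ``measure_selection`` defaults to the fit
    selection.
    """
    fit_ref, fit_mov, fit_keys = _paired_coords(ref, mov, fit_selection, strict)
    sup = kabsch_superpose(fit_ref, fit_mov)
    if measure_selection is None:
        measure_selection = fit_selection
    meas_ref, meas_mov, meas_keys = _paired_coords(ref, mov, measure_selection, strict)
    moved = sup.apply(meas_mov)
    rmsd = float(np.sqrt(np.mean(np.sum((moved - meas_ref) ** 2, axis=1))))
    return FitMeasureResult(
        rmsd=rmsd,
        n_atoms_fit=len(fit_keys),
        n_atoms_measured=len(meas_keys),
        superposition=sup,
        fit_keys=fit_keys,
        measure_keys=meas_keys,
    )


# ---------------------------------------------------------------------------
# Displacement profiles


@dataclass
class DisplacementProfile:
    per_residue: Dict[Tuple[str, int, str], float]
    max_residue: Optional[Tuple[str, int, str]]

    @property
    def max_displacement(self) -> float:
        return self.per_residue[self.max_residue] if self.max_residue else 0.0

    def rmsd(self) -> float:
        """Root mean square of the per-residue displacements."""
        vals = np.array(list(self.per_residue.values()))
        return float(np.sqrt(np.mean(vals**2))) if vals.size else 0.0


def displacement_profile(
    ref: AnnotatedComplex,
    mov: AnnotatedComplex,
    selection: Sequence[Selection],
    superposition: Optional[SuperpositionResult] = None,
) -> DisplacementProfile:
    """Per-residue C-alpha displacements between superposed structures.

    ``mov`` is assumed already in the common frame unless a ``superposition``
    is given, in which case it is applied to the moving coordinates.  The
    maximum is identified with ties broken by lower residue number.  Residues
    lacking a C-alpha in either structure are skipped with a warning.
    """
    ca_selection = [
        Selection(role=s.role, residues=s.residues, atoms="ca",
                  exclude_residues=s.exclude_residues)
        for s in selection
    ]
    ref_map = _resolve_many(ref, ca_selection)
    mov_map = _resolve_many(mov, ca_selection)
    skipped = sorted(set(ref_map) ^ set(mov_map))
    if skipped:
        logger.warning("displacement profile: %d residues missing a C-alpha in one "
                       "structure were skipped", len(skipped))
    per_residue: Dict[Tuple[str, int, str], float] = {}
    for key in sorted(set(ref_map) & set(mov_map)):
        role, seq, icode, _ = key
        mov_xyz = mov_map[key]
        if superposition is not None:
            mov_xyz = superposition.apply(mov_xyz)
        per_residue[(role, seq, icode)] = float(np.linalg.norm(ref_map[key] - mov_xyz))
    if per_residue:
        max_residue = max(
            per_residue,
            key=lambda k: (per_residue[k], -k[1]),
        )
    else:
        max_residue = None
    return DisplacementProfile(per_residue=per_residue, max_residue=max_residue)
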