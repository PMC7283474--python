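"""Interface contacts and per-CDR contact tables.

A contact is any pair of non-hydrogen atoms from opposite sides of the
interface at 4.0 A or less (inclusive cutoff).  Contacts are aggregated per
CDR loop (CDR1/CDR2/HV4/CDR3 of each TCR chain, framework kept in a visible
separate bucket) against two targets: the bound peptide and the MHC heavy
chain.  beta-2-microglobulin and waters are excluded from the tables and
reported separately.

Hydrogen bonds are flagged with a distance-only default criterion
(donor-typed N/O/S to acceptor-typed N/O heavy atoms at <= 3.5 A), since
crystal structures at typical resolution carry no hydrogens.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import AnnotationError
from .structure import AnnotatedComplex, AtomRecord

logger = logging.getLogger(__name__)

DEFAULT_CUTOFF = 4.0  # Angstrom, inclusive
HBOND_MAX_DIST = 3.5  # Angstrom, donor/acceptor heavy atoms

#: Table row order: four loops of the alpha chain, then of the beta chain.
LOOP_COLUMNS = (
    "CDR1a", "CDR2a", "HV4a", "CDR3a",
    "CDR1b", "CDR2b", "HV4b", "CDR3b",
)
FRAMEWORK_COLUMNS = ("FWa", "FWb")
TARGETS = ("peptide", "mhc")


# Donor/acceptor typing.  Keyed (residue_name, atom_name); element-level
# fallbacks cover non-standard residues and synthetic structures.
_DONORS = {
    ("*", "N"),  # backbone amide
    ("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2"),
    ("ASN", "ND2"), ("GLN", "NE2"),
    ("HIS", "ND1"), ("HIS", "NE2"),
    ("LYS", "NZ"), ("TRP", "NE1"),
    ("SER", "OG"), ("THR", "OG1"), ("TYR", "OH"),
    ("CYS", "SG"),
}
_ACCEPTORS = {
    ("*", "O"), ("*", "OXT"),  # backbone carbonyl / terminus
    ("ASP", "OD1"), ("ASP", "OD2"),
    ("GLU", "OE1"), ("GLU", "OE2"),
    ("ASN", "OD1"), ("GLN", "OE1"),
    ("HIS", "ND1"), ("HIS", "NE2"),
    ("SER", "OG"), ("THR", "OG1"), ("TYR", "OH"),
    ("MET", "SD"),
}
_STANDARD_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


def _is_donor(atom: AtomRecord) -> bool:
    if ("*", atom.name) in _DONORS or (atom.residue_name, atom.name) in _DONORS:
        return True
    if atom.residue_name not in _STANDARD_RESIDUES:
        # element-level fallback for non-standard residues
        return atom.element.upper() in ("N", "O", "S")
    return False


def _is_acceptor(atom: AtomRecord) -> bool:
    if ("*", atom.name) in _ACCEPTORS or (atom.residue_name, atom.name) in _ACCEPTORS:
        return True
    if atom.residue_name not in _STANDARD_RESIDUES:
        return atom.element.upper() in ("N", "O")
    return False


@dataclass(frozen=True)
class ContactRecord:
    atom_a: AtomRecord
    atom_b: AtomRecord
    distance: float
    category: str = "vdw"  # or "hbond"

    def as_row(self) -> Dict[str, object]:
        a, b = self.atom_a, self.atom_b
        return {
            "chain_a": a.chain_id, "residue_a": a.residue_seq,
            "resname_a": a.residue_name, "atom_a": a.name,
            "chain_b": b.chain_id, "residue_b": b.residue_seq,
            "resname_b": b.residue_name, "atom_b": b.name,
            "distance": round(self.distance, 3), "category": self.category,
        }


def atomic_contacts(
    group_a: Sequence[AtomRecord],
    group_b: Sequence[AtomRecord],
    cutoff: float = DEFAULT_CUTOFF,
) -> List[ContactRecord]:
    """All non-hydrogen atom pairs across the two groups at <= cutoff.

    Symmetric in group order; empty groups give an empty result.
    """
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    a = [at for at in group_a if not at.is_hydrogen]
    b = [at for at in group_b if not at.is_hydrogen]
    if not a or not b:
        return []
    coords_a = np.array([at.coords for at in a])
    coords_b = np.array([at.coords for at in b])
    tree = cKDTree(coords_b)
    out: List[ContactRecord] = []
    # tiny epsilon keeps the boundary inclusive under float rounding
    for i, neighbors in enumerate(tree.query_ball_point(coords_a, cutoff * (1 + 1e-12))):
        for j in sorted(neighbors):
            d = float(np.linalg.norm(coords_a[i] - coords_b[j]))
            if d <= cutoff:
                out.append(ContactRecord(atom_a=a[i], atom_b=b[j], distance=d))
    return out


def detect_hbonds(
    contacts: Sequence[ContactRecord], max_dist: float = HBOND_MAX_DIST
) -> List[ContactRecord]:
    """Re-categorize contacts, flagging hydrogen bonds.

    A contact becomes ``hbond`` when either atom is donor-typed (N/O/S) and
    the other acceptor-typed (N/O) with the pair at <= ``max_dist``.
    Atoms whose typing is unknown keep the ``vdw`` category (warned once).
    """
    out = []
    for c in contacts:
        is_hb = False
        if c.distance <= max_dist:
            ab = _is_donor(c.atom_a) and _is_acceptor(c.atom_b)
            ba = _is_donor(c.atom_b) and _is_acceptor(c.atom_a)
            is_hb = ab or ba
        out.append(
            ContactRecord(c.atom_a, c.atom_b, c.distance, "hbond" if is_hb else "vdw")
        )
    return out


@dataclass
class ContactTable:
    """Per-loop x per-target contact counts (Tables 2-style layout)."""

    counts: Dict[Tuple[str, str], int] = field(default_factory=dict)
    records: Dict[str, List[ContactRecord]] = field(default_factory=dict)
    b2m_contacts: int = 0
    water_contacts: int = 0
    cutoff: float = DEFAULT_CUTOFF

    def count(self, loop: str, target: str) -> int:
        return self.counts.get((loop, target), 0)

    def loop_total(self, target: str) -> int:
        """Sum over the eight CDR loops only."""
        return sum(self.count(loop, target) for loop in LOOP_COLUMNS)

    def grand_total(self, target: str) -> int:
        """Loops plus framework buckets."""
        return self.loop_total(target) + sum(
            self.count(fw, target) for fw in FRAMEWORK_COLUMNS
        )

    def to_frame(self) -> pd.DataFrame:
        rows = {}
        for target in TARGETS:
            row = {loop: self.count(loop, target) for loop in LOOP_COLUMNS}
            for fw in FRAMEWORK_COLUMNS:
                row[fw] = self.count(fw, target)
            row["total"] = self.grand_total(target)
            rows[target] = row
        return pd.DataFrame.from_dict(rows, orient="index")


@dataclass
class PercentageTable:
    """Integer percentages of per-target totals, same shape as ContactTable."""

    percentages: Dict[Tuple[str, str], Optional[int]] = field(default_factory=dict)

    def percent(self, loop: str, target: str) -> Optional[int]:
        return self.percentages.get((loop, target))

    def to_frame(self) -> pd.DataFrame:
        rows = {}
        for target in TARGETS:
            rows[target] = {
                loop: self.percent(loop, target)
                for loop in LOOP_COLUMNS + FRAMEWORK_COLUMNS
            }
        return pd.DataFrame.from_dict(rows, orient="index")


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def _loop_bucket(annotation, atom: AtomRecord, alpha_id: str) -> str:
    loop = annotation.loop_of(atom.chain_id, atom.residue_seq)
    suffix = "a" if atom.chain_id == alpha_id else "b"
    if loop is None:
        return "FW" + suffix
    return loop + suffix


def build_contact_table(
    complex: AnnotatedComplex, cutoff: float = DEFAULT_CUTOFF
) -> ContactTable:
    """Aggregate TCR-side contacts per loop against peptide and MHC heavy chain.

    Waters and beta-2-microglobulin contacts are counted separately, never in
    the table.  TCR atoms outside all loop ranges land in a visible framework
    bucket rather than being dropped.
    """
    ann = complex.annotation
    if not ann.has_roles("tcr_alpha", "tcr_beta"):
        raise AnnotationError("contact table requires tcr_alpha and tcr_beta roles")
    alpha_id = ann.chain_for_role("tcr_alpha")

    tcr_atoms = complex.atoms_of_role("tcr_alpha") + complex.atoms_of_role("tcr_beta")

    table = ContactTable(cutoff=cutoff)
    for target, role in (("peptide", "peptide"), ("mhc", "mhc_heavy")):
        if ann.chain_for_role(role) is None:
            continue
        target_atoms = complex.atoms_of_role(role)
        recs = detect_hbonds(atomic_contacts(tcr_atoms, target_atoms, cutoff=cutoff))
        table.records[target] = recs
        for rec in recs:
            bucket = _loop_bucket(ann, rec.atom_a, alpha_id)
            table.counts[(bucket, target)] = table.counts.get((bucket, target), 0) + 1

    if ann.chain_for_role("b2m") is not None:
        table.b2m_contacts = len(
            atomic_contacts(tcr_atoms, complex.atoms_of_role("b2m"), cutoff=cutoff)
        )
    # water contacts against the whole TCR, reported separately
    waters = [
        atom
        for chain in complex.structure.chains
        for res in chain.residues
        if res.is_water
        for atom in res.atoms
    ]
    if waters:
        table.water_contacts = len(atomic_contacts(tcr_atoms, waters, cutoff=cutoff))
    return table


def contact_percentages(table: ContactTable, include_framework: bool = True) -> PercentageTable:
    """Each cell as a rounded integer percentage of its per-target total."""
    out = PercentageTable()
    columns = LOOP_COLUMNS + (FRAMEWORK_COLUMNS if include_framework else ())
    for target in TARGETS:
        total = table.grand_total(target) if include_framework else table.loop_total(target)
        for loop in columns:
            if total == 0:
                out.percentages[(loop, target)] = None
            else:
                out.percentages[(loop, target)] = _round_half_up(
                    100.0 * table.count(loop, target) / total
                )
    return out


def chain_share(table: ContactTable, chain: str, target: str) -> Tuple[int, Optional[int]]:
    """Contacts of one TCR chain (its four loops plus framework) with a target,
    as a count and a rounded percent of the target total."""
    if chain not in ("alpha", "beta"):
        raise ValueError(f"chain must be 'alpha' or 'beta', got {chain!r}")
    suffix = "a" if chain == "alpha" else "b"
    count = sum(
        table.count(loop, target)
        for loop in LOOP_COLUMNS + FRAMEWORK_COLUMNS
        if loop.endswith(suffix)
    )
    total = table.grand_total(target)
    if total == 0:
        return count, None
    return count, _round_half_up(100.0 * count / total)


def contacts_to_frame(records: Sequence[ContactRecord]) -> pd.DataFrame:
    """Contact list as a tidy table (one row per atomic contact)."""
    return pd.DataFrame([r.as_row() for r in records])
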