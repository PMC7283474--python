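"""Structure I/O and complex annotation.

Reads PDB/mmCIF coordinate files (via gemmi) into a light-weight atom/residue/
chain model keyed by author numbering, and attaches the chain-role and
loop-range annotation (TCR alpha/beta, MHC heavy chain, beta-2-microglobulin,
peptide; CDR1/CDR2/HV4/CDR3 ranges; MHC alpha1/alpha2 helix ranges; conserved
V-domain disulfide positions) that every downstream analysis consumes.

Conventions
-----------
* Author residue numbering as deposited is the canonical key; nothing is
  renumbered.
* For alternate-location groups only the highest-occupancy conformer is kept
  (ties broken by altloc letter order); the choice is logged.
* Hydrogens are parsed but excluded from contact and surface computations.
* Waters are retained and flagged hetero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterator, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .errors import (
    AnnotationError,
    CysDetectionError,
    FormatError,
    GeometryError,
    ParseError,
)

logger = logging.getLogger(__name__)

ROLES = ("mhc_heavy", "b2m", "peptide", "tcr_alpha", "tcr_beta")
LOOPS = ("CDR1", "CDR2", "HV4", "CDR3")

#: IMGT-like default loop boundaries (residue numbers, inclusive). These are
#: data, not code: real structures keep author numbering, so per-structure
#: overrides in the annotation config are expected whenever deposited
#: numbering differs from IMGT.
DEFAULT_CDR_RANGES: Dict[str, Tuple[int, int]] = {
    "CDR1": (27, 38),
    "CDR2": (56, 65),
    "HV4": (81, 86),
    "CDR3": (105, 117),
}

#: Default MHC class I helix ranges on the heavy chain (inclusive).
DEFAULT_HELIX_RANGES: Dict[str, Tuple[int, int]] = {
    "alpha1": (50, 86),
    "alpha2": (138, 176),
}

WATER_NAMES = {"HOH", "WAT", "DOD"}

ResidueKey = Tuple[int, str]  # (author residue number, insertion code)


@dataclass
class AtomRecord:
    """A single atom with author-numbered residue identity."""

    name: str
    element: str
    coords: np.ndarray
    residue_name: str
    residue_seq: int
    insertion_code: str = ""
    chain_id: str = ""
    altloc: str = ""
    occupancy: float = 1.0
    is_hetero: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: coords must be a finite 3-vector")
        if not self.element:
            raise ValueError(f"atom {self.name}: element must be non-empty")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")


@dataclass
class Residue:
    name: str
    seq: int
    insertion_code: str = ""
    atoms: List[AtomRecord] = field(default_factory=list)

    @property
    def key(self) -> ResidueKey:
        return (self.seq, self.insertion_code)

    @property
    def is_water(self) -> bool:
        return self.name in WATER_NAMES

    def find_atom(self, name: str) -> Optional[AtomRecord]:
        for atom in self.atoms:
            if atom.name == name:
                return atom
        return None


@dataclass
class Chain:
    chain_id: str
    residues: List[Residue] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._index: Dict[ResidueKey, Residue] = {}
        for res in self.residues:
            if res.key in self._index:
                raise ValueError(
                    f"chain {self.chain_id}: duplicate residue key {res.key}"
                )
            self._index[res.key] = res

    def add_residue(self, res: Residue) -> None:
        if res.key in self._index:
            raise ValueError(f"chain {self.chain_id}: duplicate residue key {res.key}")
        self.residues.append(res)
        self._index[res.key] = res

    def get(self, seq: int, insertion_code: str = "") -> Optional[Residue]:
        return self._index.get((seq, insertion_code))

    def polymer_residues(self) -> List[Residue]:
        return [r for r in self.residues if not r.is_water]

    def atoms(self) -> Iterator[AtomRecord]:
        for res in self.residues:
            yield from res.atoms


@dataclass
class StructureModel:
    """Ordered chains of ordered residues of atoms."""

    identifier: str
    chains: List[Chain] = field(default_factory=list)
    resolution: Optional[float] = None

    def __post_init__(self) -> None:
        ids = [c.chain_id for c in self.chains]
        if len(set(ids)) != len(ids):
            raise ValueError(f"{self.identifier}: chain ids not unique: {ids}")

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"{self.identifier}: no chain {chain_id!r}")

    @property
    def chain_ids(self) -> List[str]:
        return [c.chain_id for c in self.chains]

    def atoms(self) -> Iterator[AtomRecord]:
        for c in self.chains:
            yield from c.atoms()

    def n_atoms(self) -> int:
        return sum(1 for _ in self.atoms())

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """Return a rigidly transformed copy (x -> R x + t)."""
        rotation = np.asarray(rotation, dtype=float)
        translation = np.asarray(translation, dtype=float)
        new_chains = []
        for c in self.chains:
            new_res = []
            for r in c.residues:
                new_atoms = [
                    replace(a, coords=rotation @ a.coords + translation)
                    for a in r.atoms
                ]
                new_res.append(Residue(r.name, r.seq, r.insertion_code, new_atoms))
            new_chains.append(Chain(c.chain_id, new_res))
        return StructureModel(self.identifier, new_chains, self.resolution)


# ---------------------------------------------------------------------------
# Reading and writing


def _select_altloc(atoms: Sequence) -> object:
    """Pick the conformer to keep from an altloc group.

    Highest occupancy wins; ties broken by altloc letter order.
    """
    return min(atoms, key=lambda a: (-a.occ, a.altloc))


def read_structure(path, format: str = "auto") -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    Only the first model of multi-model files is used.  For altloc groups the
    highest-occupancy conformer is retained (logged).  Waters are kept and
    flagged hetero.
    """
    import gemmi

    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    fmt_map = {
        "pdb": gemmi.CoorFormat.Pdb,
        "mmcif": gemmi.CoorFormat.Mmcif,
        "auto": gemmi.CoorFormat.Detect,
    }
    if format not in fmt_map:
        raise FormatError(f"unknown format {format!r}; expected pdb, mmcif or auto")
    try:
        st = gemmi.read_structure(str(path), format=fmt_map[format])
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"failed to parse {path}: {exc}") from exc
    if len(st) == 0:
        raise ParseError(f"{path}: no models found")
    st.setup_entities()

    model = st[0]
    chains: List[Chain] = []
    for gchain in model:
        chain = Chain(gchain.name)
        for gres in gchain:
            is_het = gres.het_flag == "H"
            residue = Residue(gres.name, gres.seqid.num, (gres.seqid.icode or "").strip())
            # group altlocs by atom name
            by_name: Dict[str, list] = {}
            for gatom in gres:
                by_name.setdefault(gatom.name, []).append(gatom)
            for name, group in by_name.items():
                chosen = _select_altloc(group) if len(group) > 1 else group[0]
                if len(group) > 1:
                    logger.info(
                        "altloc %s/%d%s %s: kept conformer %r (occ %.2f) of %d",
                        gchain.name, gres.seqid.num, residue.insertion_code,
                        name, chosen.altloc, chosen.occ, len(group),
                    )
                residue.atoms.append(
                    AtomRecord(
                        name=name,
                        element=chosen.element.name,
                        coords=np.array([chosen.pos.x, chosen.pos.y, chosen.pos.z]),
                        residue_name=gres.name,
                        residue_seq=gres.seqid.num,
                        insertion_code=residue.insertion_code,
                        chain_id=gchain.name,
                        altloc=(chosen.altloc or "").strip(),
                        occupancy=min(max(chosen.occ, 0.0), 1.0),
                        is_hetero=is_het,
                    )
                )
            chain.add_residue(residue)
        chains.append(chain)

    resolution = st.resolution if st.resolution and st.resolution > 0 else None
    identifier = st.name if st.name and st.name != "XXXX" else path.stem
    return StructureModel(identifier=identifier, chains=chains, resolution=resolution)


def _pdb_atom_name(atom: AtomRecord) -> str:
    """PDB columns 13-16: element right-justified in 13-14."""
    name = atom.name
    if len(name) >= 4:
        return name[:4]
    if len(atom.element) == 1 and len(name) < 4:
        return f" {name:<3s}"
    return f"{name:<4s}"


def write_pdb(model: StructureModel, path) -> None:
    """Serialize to PDB format (coordinates at standard 3-decimal precision)."""
    lines = []
    serial = 0
    for chain in model.chains:
        for res in chain.residues:
            for atom in res.atoms:
                serial += 1
                record = "HETATM" if atom.is_hetero else "ATOM  "
                x, y, z = atom.coords
                lines.append(
                    f"{record}{serial:5d} {_pdb_atom_name(atom)}{atom.altloc or ' ':.1s}"
                    f"{atom.residue_name:>3s} {chain.chain_id[:1]:1s}{atom.residue_seq:4d}"
                    f"{atom.insertion_code or ' ':.1s}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{0.0:6.2f}"
                    f"          {atom.element.upper():>2s}"
                )
        lines.append(f"TER   {serial + 1:5d}      {chain.chain_id[:1]:1s}")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Annotation


@dataclass
class ComplexAnnotation:
    """Chain roles plus loop/helix ranges and disulfide anchor positions."""

    role_map: Dict[str, str]
    cdr_ranges: Dict[str, Dict[str, Tuple[int, int]]] = field(default_factory=dict)
    helix_ranges: Dict[str, Tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_HELIX_RANGES)
    )
    cys_pairs: Dict[str, Tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chain_id, role in self.role_map.items():
            if role not in ROLES:
                raise AnnotationError(
                    f"chain {chain_id}: unknown role {role!r}; expected one of {ROLES}"
                )
        seen: Dict[str, str] = {}
        for chain_id, role in self.role_map.items():
            if role in seen:
                raise AnnotationError(
                    f"role {role!r} assigned to both chains {seen[role]} and {chain_id}"
                )
            seen[role] = chain_id
        for chain_id, ranges in self.cdr_ranges.items():
            spans = sorted(ranges.values())
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                if s2 <= e1:
                    raise AnnotationError(
                        f"chain {chain_id}: overlapping loop ranges {(s1, e1)} and {(s2, e2)}"
                    )
        for chain_id, pair in self.cys_pairs.items():
            if len(pair) != 2 or pair[0] == pair[1]:
                raise AnnotationError(
                    f"chain {chain_id}: cys pair must be 2 distinct positions, got {pair}"
                )

    def chain_for_role(self, role: str) -> Optional[str]:
        for chain_id, r in self.role_map.items():
            if r == role:
                return chain_id
        return None

    def has_roles(self, *roles: str) -> bool:
        present = set(self.role_map.values())
        return all(r in present for r in roles)

    def loop_of(self, chain_id: str, residue_seq: int) -> Optional[str]:
        """Loop name for a TCR residue, or None for framework."""
        ranges = self.cdr_ranges.get(chain_id, {})
        for loop, (start, end) in ranges.items():
            if start <= residue_seq <= end:
                return loop
        return None


@dataclass
class AnnotatedComplex:
    structure: StructureModel
    annotation: ComplexAnnotation

    def __post_init__(self) -> None:
        missing = [
            cid for cid in self.annotation.role_map if cid not in self.structure.chain_ids
        ]
        if missing:
            raise AnnotationError(
                f"annotated chains absent from structure: {missing} "
                f"(structure has {self.structure.chain_ids})"
            )

    def chain_for_role(self, role: str) -> Chain:
        chain_id = self.annotation.chain_for_role(role)
        if chain_id is None:
            raise AnnotationError(f"no chain annotated with role {role!r}")
        return self.structure.chain(chain_id)

    def atoms_of_role(
        self,
        role: str,
        include_hetero: bool = False,
        include_hydrogens: bool = False,
    ) -> List[AtomRecord]:
        chain = self.chain_for_role(role)
        out = []
        for res in chain.residues:
            if res.is_water and not include_hetero:
                continue
            for atom in res.atoms:
                if atom.is_hetero and not include_hetero:
                    continue
                if atom.is_hydrogen and not include_hydrogens:
                    continue
                out.append(atom)
        return out

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "AnnotatedComplex":
        return AnnotatedComplex(
            self.structure.transformed(rotation, translation), self.annotation
        )


def _as_range(value) -> Tuple[int, int]:
    start, end = value
    return (int(start), int(end))


def annotate_complex(structure: StructureModel, config: Mapping) -> AnnotatedComplex:
    """Attach chain roles and loop/helix ranges to a structure.

    ``config`` keys:

    roles
        mapping chain id -> role; a role value of ``"auto"`` under key
        ``peptide`` (or ``peptide: auto`` at top level) requests peptide
        auto-detection: the unique unassigned protein chain of length 8-13.
    cdr_ranges
        optional; either one mapping applied to both TCR chains or a
        per-chain-id mapping loop -> [start, end].  Defaults to IMGT-like
        boundaries.
    helix_ranges
        optional mapping {alpha1: [start, end], alpha2: [start, end]}.
    cys_pairs
        optional mapping chain id -> [pos1, pos2].
    """
    roles: Dict[str, str] = {
        str(k): str(v) for k, v in dict(config.get("roles", {})).items()
    }
    peptide_auto = config.get("peptide") == "auto" or "auto" in roles.values()
    roles = {k: v for k, v in roles.items() if v != "auto"}

    if peptide_auto and "peptide" not in roles.values():
        assigned = set(roles)
        candidates = []
        for chain in structure.chains:
            if chain.chain_id in assigned:
                continue
            n = len(chain.polymer_residues())
            if 8 <= n <= 13:
                candidates.append(chain.chain_id)
        if len(candidates) != 1:
            raise AnnotationError(
                "peptide auto-detection requires exactly one unassigned protein "
                f"chain of length 8-13; found {candidates or 'none'}"
            )
        roles[candidates[0]] = "peptide"

    unknown = [cid for cid in roles if cid not in structure.chain_ids]
    if unknown:
        raise AnnotationError(f"role config names unknown chains: {unknown}")

    # CDR ranges: default for TCR chains; accept either per-loop (shared) or
    # per-chain-id mapping.
    tcr_chains = [cid for cid, role in roles.items() if role in ("tcr_alpha", "tcr_beta")]
    cfg_cdr = config.get("cdr_ranges") or {}
    cdr_ranges: Dict[str, Dict[str, Tuple[int, int]]] = {}
    if cfg_cdr and set(cfg_cdr) <= set(LOOPS):
        shared = {loop: _as_range(v) for loop, v in cfg_cdr.items()}
        for cid in tcr_chains:
            cdr_ranges[cid] = dict(shared)
    else:
        for cid in tcr_chains:
            per_chain = cfg_cdr.get(cid, DEFAULT_CDR_RANGES)
            cdr_ranges[cid] = {loop: _as_range(v) for loop, v in per_chain.items()}

    cfg_helix = config.get("helix_ranges") or {}
    helix_ranges = {
        name: _as_range(cfg_helix.get(name, DEFAULT_HELIX_RANGES[name]))
        for name in ("alpha1", "alpha2")
    }

    cys_pairs = {
        str(cid): (int(pair[0]), int(pair[1]))
        for cid, pair in (config.get("cys_pairs") or {}).items()
    }

    annotation = ComplexAnnotation(
        role_map=roles,
        cdr_ranges=cdr_ranges,
        helix_ranges=helix_ranges,
        cys_pairs=cys_pairs,
    )
    return AnnotatedComplex(structure=structure, annotation=annotation)


# ---------------------------------------------------------------------------
# Conserved disulfide detection


@dataclass(frozen=True)
class CysPair:
    """Anchor positions for a V-domain center.

    ``used_ca`` flags positions where no Cys Sgamma was present and the
    C-alpha atom substitutes.
    """

    positions: Tuple[ResidueKey, ResidueKey]
    used_ca: Tuple[bool, bool] = (False, False)

    @property
    def any_fallback(self) -> bool:
        return any(self.used_ca)


DISULFIDE_MAX_SG_DIST = 2.5  # Angstrom


def _anchor_atom(residue: Residue) -> Tuple[AtomRecord, bool]:
    """Sgamma of a Cys, else C-alpha fallback (flagged)."""
    sg = residue.find_atom("SG")
    if sg is not None:
        return sg, False
    ca = residue.find_atom("CA")
    if ca is None:
        raise GeometryError(
            f"residue {residue.name} {residue.key}: neither SG nor CA present"
        )
    return ca, True


def detect_conserved_cys(
    chain: Chain, override: Optional[Tuple[int, int]] = None
) -> CysPair:
    """Find the conserved intrachain disulfide of an immunoglobulin V domain.

    Returns the unique Cys pair whose Sgamma atoms are within 2.5 A.  With an
    explicit ``override`` of residue positions, missing Sgamma atoms fall back
    to C-alpha and the fallback is flagged.  If several pairs qualify (e.g. a
    full-length chain containing both V and C domain disulfides), the
    lowest-numbered pair (the V domain) is chosen and a warning logged.
    """
    if override is not None:
        res = []
        flags = []
        for pos in override:
            residue = chain.get(int(pos))
            if residue is None:
                raise CysDetectionError(
                    f"chain {chain.chain_id}: override position {pos} not found"
                )
            _, fallback = _anchor_atom(residue)
            res.append(residue.key)
            flags.append(fallback)
        if res[0] == res[1]:
            raise CysDetectionError("override positions must be distinct")
        return CysPair(positions=(res[0], res[1]), used_ca=(flags[0], flags[1]))

    if len(chain.polymer_residues()) < 2:
        raise CysDetectionError(f"chain {chain.chain_id}: fewer than 2 residues")

    cys = [
        (r, r.find_atom("SG"))
        for r in chain.polymer_residues()
        if r.name == "CYS" and r.find_atom("SG") is not None
    ]
    pairs = []
    for i in range(len(cys)):
        for j in range(i + 1, len(cys)):
            d = np.linalg.norm(cys[i][1].coords - cys[j][1].coords)
            if d <= DISULFIDE_MAX_SG_DIST:
                pairs.append((cys[i][0].key, cys[j][0].key))
    if not pairs:
        raise CysDetectionError(
            f"chain {chain.chain_id}: no Cys pair with Sgamma-Sgamma <= "
            f"{DISULFIDE_MAX_SG_DIST} A and no config override"
        )
    pairs.sort()
    if len(pairs) > 1:
        logger.warning(
            "chain %s: %d disulfide pairs found; using lowest-numbered %s",
            chain.chain_id, len(pairs), pairs[0],
        )
    return CysPair(positions=pairs[0], used_ca=(False, False))
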