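"""Synthetic annotated TCR-pMHC complexes and geometric fixtures.

The generator builds toy complexes directly in the canonical pMHC frame:
two MHC "helices" whose C-alpha atoms lie exactly in the z = 0 plane, an
extended peptide along +x ordered N -> C between them, a beta-2-microglobulin
stub below the plane, and two pseudo-V domains above it whose conserved-Cys
Sgamma anchor pairs realize a prescribed crossing angle, incident angle and
TCR-center projection exactly.  Optional contact layouts are realized by
planting side-chain atoms 3.5 A from designated peptide/MHC atoms (strictly
inside the 4.0 A contact cutoff) and are verified by brute force before the
complex is returned.

Toy domains are geometric scaffolds, not folded immunoglobulin domains: the
docking descriptors depend only on anchor atoms and frames, which is what
these fixtures exercise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .errors import GenerationError
from .frames import build_mhc_frame
from .sc import DotSurface
from .structure import (
    AnnotatedComplex,
    AtomRecord,
    Chain,
    ComplexAnnotation,
    DEFAULT_CDR_RANGES,
    Residue,
    StructureModel,
)

CHAIN_IDS = {"mhc_heavy": "M", "b2m": "B", "peptide": "C",
             "tcr_alpha": "D", "tcr_beta": "E"}

#: loop bucket -> (chain role, default residue range)
LOOP_RANGES: Dict[str, Tuple[str, Tuple[int, int]]] = {
    "CDR1a": ("tcr_alpha", DEFAULT_CDR_RANGES["CDR1"]),
    "CDR2a": ("tcr_alpha", DEFAULT_CDR_RANGES["CDR2"]),
    "HV4a": ("tcr_alpha", DEFAULT_CDR_RANGES["HV4"]),
    "CDR3a": ("tcr_alpha", DEFAULT_CDR_RANGES["CDR3"]),
    "CDR1b": ("tcr_beta", DEFAULT_CDR_RANGES["CDR1"]),
    "CDR2b": ("tcr_beta", DEFAULT_CDR_RANGES["CDR2"]),
    "HV4b": ("tcr_beta", DEFAULT_CDR_RANGES["HV4"]),
    "CDR3b": ("tcr_beta", DEFAULT_CDR_RANGES["CDR3"]),
    "FWa": ("tcr_alpha", (1, 20)),
    "FWb": ("tcr_beta", (1, 20)),
}

PEPTIDE_SPACING = 3.5   # A between consecutive peptide C-alphas
PLANT_DISTANCE = 3.5    # A, planted contact distance (inside the 4.0 cutoff)
CONTACT_CUTOFF = 4.0


@dataclass
class ToyComplexSpec:
    """Prescription for a synthetic TCR-pMHC complex.

    Angles in degrees, positions in A.  ``contact_layout`` maps a loop bucket
    (e.g. ``CDR3b``) to ``{"peptide": n, "mhc": m}`` planted contact counts.
    """

    crossing_angle: float = 51.0
    incident_angle: float = 20.0
    x_pos: float = 0.0
    y_pos: float = 0.0
    peptide_length: int = 9
    helix_length: int = 37
    tcr_height: float = 25.0
    domain_separation: float = 28.0
    contact_layout: Mapping[str, Mapping[str, int]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.crossing_angle <= 180.0:
            raise GenerationError("crossing_angle must be in [0, 180] deg")
        if not 0.0 <= self.incident_angle <= 90.0:
            raise GenerationError("incident_angle must be in [0, 90] deg")
        if self.incident_angle >= 90.0:
            raise GenerationError(
                "incident_angle of 90 deg leaves the crossing angle undefined"
            )
        if self.peptide_length < 3:
            raise GenerationError("peptide_length must be >= 3")
        if self.helix_length < 10:
            raise GenerationError("helix_length must be >= 10 residues")


def make_ideal_helix(
    n_residues: int,
    rise: float = 1.5,
    twist: float = 100.0,
    radius: float = 2.3,
    axis: Sequence[float] = (1.0, 0.0, 0.0),
    origin: Sequence[float] = (0.0, 0.0, 0.0),
    phase: float = 0.0,
) -> np.ndarray:
    """C-alpha positions of a regular helix along ``axis`` (returns (n, 3))."""
    if n_residues < 2:
        raise GenerationError("a helix needs >= 2 residues")
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    # complete an orthonormal basis around the axis
    seed_vec = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(seed_vec, axis)) > 0.9:
        seed_vec = np.array([0.0, 1.0, 0.0])
    u = seed_vec - np.dot(seed_vec, axis) * axis
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    i = np.arange(n_residues, dtype=float)
    theta = np.radians(twist) * i + phase
    return (
        np.asarray(origin, float)
        + np.outer(rise * i, axis)
        + radius * (np.outer(np.cos(theta), u) + np.outer(np.sin(theta), v))
    )


def _ca_residue(name: str, seq: int, chain_id: str, coords, element: str = "C",
                atom_name: str = "CA", is_hetero: bool = False) -> Residue:
    res = Residue(name=name, seq=seq)
    res.atoms.append(
        AtomRecord(
            name=atom_name, element=element, coords=np.asarray(coords, float),
            residue_name=name, residue_seq=seq, chain_id=chain_id,
            is_hetero=is_hetero,
        )
    )
    return res


def _flat_helix_chain_residues(
    chain_id: str, start_seq: int, n: int, y_center: float, mirror: bool
) -> List[Residue]:
    """A helix-like C-alpha trace flattened into the z = 0 plane.

    The radial wobble is folded into y only (mirrored between the two
    helices so the combined centroid sits exactly on y = 0), keeping the
    helix-plane fit exact for frame round-trips.
    """
    rise, twist, radius = 1.5, 100.0, 2.3
    xs = (np.arange(n) - (n - 1) / 2.0) * rise
    wob = radius * np.cos(np.radians(twist) * np.arange(n))
    ys = y_center + (-wob if mirror else wob)
    return [
        _ca_residue("GLY", start_seq + i, chain_id, (xs[i], ys[i], 0.0))
        for i in range(n)
    ]


def make_toy_pmhc(spec: Optional[ToyComplexSpec] = None) -> AnnotatedComplex:
    """Toy pMHC in the canonical frame: helix C-alpha plane exactly z = 0,
    peptide C-alphas on the +x axis ordered N -> C."""
    spec = spec or ToyComplexSpec()
    n_helix = spec.helix_length
    groove_half = 12.0

    heavy = Chain(CHAIN_IDS["mhc_heavy"])
    for res in _flat_helix_chain_residues(heavy.chain_id, 50, n_helix,
                                          +groove_half, mirror=False):
        heavy.add_residue(res)   # alpha1 helix
    for res in _flat_helix_chain_residues(heavy.chain_id, 138, n_helix,
                                          -groove_half, mirror=True):
        heavy.add_residue(res)   # alpha2 helix

    peptide = Chain(CHAIN_IDS["peptide"])
    n_pep = spec.peptide_length
    for j in range(n_pep):
        x = (j - (n_pep - 1) / 2.0) * PEPTIDE_SPACING
        peptide.add_residue(_ca_residue("GLY", j + 1, peptide.chain_id, (x, 0.0, 0.0)))

    b2m = Chain(CHAIN_IDS["b2m"])
    for j in range(3):
        b2m.add_residue(_ca_residue("GLY", j + 1, b2m.chain_id,
                                    (j * 3.8 - 3.8, 0.0, -20.0)))

    structure = StructureModel("toy_pmhc", [heavy, b2m, peptide])
    annotation = ComplexAnnotation(
        role_map={heavy.chain_id: "mhc_heavy", b2m.chain_id: "b2m",
                  peptide.chain_id: "peptide"},
        helix_ranges={"alpha1": (50, 50 + n_helix - 1),
                      "alpha2": (138, 138 + n_helix - 1)},
    )
    return AnnotatedComplex(structure=structure, annotation=annotation)


N_PLANT_SLOTS = 13


def _plant_slots(target: np.ndarray) -> List[np.ndarray]:
    """Candidate positions 3.5 A from a target atom: one apical, eight on a
    1.0 A ring and four on a 0.7 A ring (all > 4 A from neighbour targets
    spaced >= 3.5 A apart)."""
    slots = [target + np.array([0.0, 0.0, PLANT_DISTANCE])]
    for radius, n_ring, offset in ((1.0, 8, 0.0), (0.7, 4, 22.5)):
        ring_dz = np.sqrt(PLANT_DISTANCE**2 - radius**2)
        for k in range(n_ring):
            ang = np.radians(offset + 360.0 * k / n_ring)
            slots.append(target + np.array([radius * np.cos(ang),
                                            radius * np.sin(ang), ring_dz]))
    return slots


def make_toy_tcr_pmhc(spec: Optional[ToyComplexSpec] = None) -> AnnotatedComplex:
    """Toy TCR-pMHC complex realizing the spec's docking descriptors exactly.

    The pseudo-V domains are anchored by synthetic Cys Sgamma pairs placed so
    that the measured crossing angle, incident angle, x_pos and y_pos equal
    the prescription to machine precision; an optional contact layout is
    planted and verified by brute-force pair enumeration.
    """
    spec = spec or ToyComplexSpec()
    base = make_toy_pmhc(spec)
    frame = build_mhc_frame(base)

    theta_c = np.radians(spec.crossing_angle)
    theta_i = np.radians(spec.incident_angle)
    v_frame = np.array([
        np.cos(theta_i) * np.cos(theta_c),
        np.cos(theta_i) * np.sin(theta_c),
        np.sin(theta_i),
    ])
    axes = np.stack([frame.x_axis, frame.y_axis, frame.z_axis])
    v_world = v_frame @ axes
    center = (frame.origin + spec.x_pos * frame.x_axis
              + spec.y_pos * frame.y_axis + spec.tcr_height * frame.z_axis)
    half = spec.domain_separation / 2.0
    anchors = {"tcr_alpha": center - half * v_world,
               "tcr_beta": center + half * v_world}

    # a unit vector perpendicular to the inter-domain axis, for the Sg pair
    perp = np.cross(v_world, frame.z_axis)
    if np.linalg.norm(perp) < 1e-6:
        perp = np.cross(v_world, frame.x_axis)
    perp /= np.linalg.norm(perp)

    chains: Dict[str, Chain] = {}
    cdr_ranges: Dict[str, Dict[str, Tuple[int, int]]] = {}
    for role in ("tcr_alpha", "tcr_beta"):
        cid = CHAIN_IDS[role]
        chain = Chain(cid)
        for seq in (23, 104):
            res = Residue(name="CYS", seq=seq)
            sign = -1.0 if seq == 23 else 1.0
            sg = anchors[role] + sign * perp  # pair 2.0 A apart, mean = anchor
            res.atoms.append(AtomRecord(
                name="SG", element="S", coords=sg, residue_name="CYS",
                residue_seq=seq, chain_id=cid))
            res.atoms.append(AtomRecord(
                name="CA", element="C", coords=sg + 0.8 * v_world,
                residue_name="CYS", residue_seq=seq, chain_id=cid))
            chain.add_residue(res)
        chains[role] = chain
        cdr_ranges[cid] = dict(DEFAULT_CDR_RANGES)

    # ---- plant the requested contact layout --------------------------------
    heavy = base.chain_for_role("mhc_heavy")
    peptide = base.chain_for_role("peptide")

    platform: List[Residue] = []
    if any("mhc" in targets for targets in spec.contact_layout.values()):
        # contact platform on the heavy chain, clear of helices and peptide
        seq = 200
        for y in (+4.5, -4.5):
            for k in range(12):
                x = (k - 5.5) * PEPTIDE_SPACING
                platform.append(_ca_residue("UNK", seq, heavy.chain_id,
                                            (x, y, 0.0), atom_name="CB"))
                seq += 1
        for res in platform:
            heavy.add_residue(res)

    target_atoms = {
        "peptide": [r.atoms[0] for r in peptide.residues],
        "mhc": [r.atoms[0] for r in platform],
    }
    slot_cursor = {"peptide": 0, "mhc": 0}

    for loop, targets in spec.contact_layout.items():
        if loop not in LOOP_RANGES:
            raise GenerationError(f"unknown loop bucket {loop!r}")
        role, (lo, hi) = LOOP_RANGES[loop]
        cid = CHAIN_IDS[role]
        for target, count in targets.items():
            if target not in ("peptide", "mhc"):
                raise GenerationError(f"unknown contact target {target!r}")
            atoms = target_atoms[target]
            if not atoms:
                raise GenerationError(f"no {target} target atoms available")
            capacity = len(atoms) * N_PLANT_SLOTS
            if slot_cursor[target] + count > capacity:
                raise GenerationError(
                    f"contact layout infeasible: {target} capacity {capacity} "
                    f"exceeded"
                )
            res = Residue(name="UNK", seq=lo)
            existing = chains[role].get(lo)
            if existing is not None:
                res = existing
            for n in range(count):
                cursor = slot_cursor[target]
                slot_cursor[target] += 1
                t_idx, s_idx = cursor % len(atoms), cursor // len(atoms)
                pos = _plant_slots(atoms[t_idx].coords)[s_idx]
                res.atoms.append(AtomRecord(
                    name=f"X{len(res.atoms) + 1}", element="C", coords=pos,
                    residue_name="UNK", residue_seq=lo, chain_id=cid))
            if existing is None:
                chains[role].add_residue(res)

    structure = StructureModel(
        "toy_tcr_pmhc",
        base.structure.chains + [chains["tcr_alpha"], chains["tcr_beta"]],
    )
    role_map = dict(base.annotation.role_map)
    role_map[CHAIN_IDS["tcr_alpha"]] = "tcr_alpha"
    role_map[CHAIN_IDS["tcr_beta"]] = "tcr_beta"
    annotation = ComplexAnnotation(
        role_map=role_map,
        cdr_ranges=cdr_ranges,
        helix_ranges=base.annotation.helix_ranges,
    )
    out = AnnotatedComplex(structure=structure, annotation=annotation)

    if spec.contact_layout:
        _verify_layout(out, spec)
    return out


def _verify_layout(complex: AnnotatedComplex, spec: ToyComplexSpec) -> None:
    """Brute-force check that planted counts match the prescription."""
    ann = complex.annotation
    tcr_atoms = (complex.atoms_of_role("tcr_alpha")
                 + complex.atoms_of_role("tcr_beta"))
    alpha_id = ann.chain_for_role("tcr_alpha")
    for target, role in (("peptide", "peptide"), ("mhc", "mhc_heavy")):
        counts: Dict[str, int] = {}
        for ta in complex.atoms_of_role(role):
            for at in tcr_atoms:
                if np.linalg.norm(ta.coords - at.coords) <= CONTACT_CUTOFF:
                    loop = ann.loop_of(at.chain_id, at.residue_seq)
                    suffix = "a" if at.chain_id == alpha_id else "b"
                    bucket = (loop + suffix) if loop else ("FW" + suffix)
                    counts[bucket] = counts.get(bucket, 0) + 1
        expected = {
            loop: t.get(target, 0) for loop, t in spec.contact_layout.items()
        }
        expected = {k: v for k, v in expected.items() if v}
        if counts != expected:
            raise GenerationError(
                f"planted {target} layout verification failed: requested "
                f"{expected}, realized {counts} (overlapping atoms?)"
            )


def make_dot_surface_pair(
    shape: str = "plane",
    separation: float = 1.0,
    density: float = 4.0,
    extent: float = 10.0,
    normals: str = "antiparallel",
) -> Tuple[DotSurface, DotSurface]:
    """Two congruent dot surfaces at a given separation, for Sc fixtures.

    ``plane``: two aligned square dot grids separated along z.
    ``hemisphere``: two concentric domes with a constant radial gap.
    Facing (anti-parallel) normals by default; ``normals="parallel"`` flips
    the second surface's normals to probe the sign convention.
    """
    if separation < 0:
        raise ValueError("separation must be >= 0")
    if normals not in ("antiparallel", "parallel"):
        raise ValueError("normals must be 'antiparallel' or 'parallel'")

    if shape == "plane":
        spacing = 1.0 / np.sqrt(density)
        n = max(2, int(round(extent / spacing)))
        g = (np.arange(n) - (n - 1) / 2.0) * spacing
        xx, yy = np.meshgrid(g, g)
        pts_a = np.column_stack([xx.ravel(), yy.ravel(), np.zeros(xx.size)])
        pts_b = pts_a + np.array([0.0, 0.0, separation])
        nrm_a = np.tile([0.0, 0.0, 1.0], (len(pts_a), 1))
        nrm_b = np.tile([0.0, 0.0, -1.0], (len(pts_b), 1))
    elif shape == "hemisphere":
        radius = extent / 2.0
        n_dots = max(24, int(round(density * 4.0 * np.pi * radius**2)))
        from .sasa import sphere_points

        unit = sphere_points(n_dots)
        unit = unit[unit[:, 2] > 0.05]
        pts_a = radius * unit
        nrm_a = unit.copy()
        pts_b = (radius + separation) * unit
        nrm_b = -unit.copy()
    else:
        raise ValueError(f"unknown shape {shape!r}")

    if normals == "parallel":
        nrm_b = -nrm_b
    return DotSurface(pts_a, nrm_a), DotSurface(pts_b, nrm_b)
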