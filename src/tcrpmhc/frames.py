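"""pMHC reference frame and docking-geometry descriptors.

The frame follows the convention used for surveys of TCR docking modes:
origin at the mean C-alpha position of the MHC alpha1/alpha2 helices, the
x-y plane parallel to the helices (total-least-squares plane), the x-axis
along the peptide groove with greater x toward the peptide C-terminus, and
the z-axis pointing toward the TCR.

Descriptors:

crossing angle
    angle in [0, 180] deg between the x-y-plane projection of the
    Valpha -> Vbeta disulfide-center vector and the +x (peptide) axis.
incident angle
    elevation in [0, 90] deg of the Valpha -> Vbeta vector out of the
    x-y plane -- the tilt of the TCR over the pMHC surface.  The exact
    construction differs between published surveys, so the definition is a
    pluggable strategy; this elevation form is the default.
x_pos / y_pos
    in-plane coordinates of the TCR center (midpoint of the Valpha and
    Vbeta disulfide centers).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .errors import FrameError, GeometryError, RankingError
from .structure import AnnotatedComplex, CysPair, detect_conserved_cys


@dataclass(frozen=True)
class ReferenceFrame:
    origin: np.ndarray
    x_axis: np.ndarray
    y_axis: np.ndarray
    z_axis: np.ndarray

    def __post_init__(self) -> None:
        axes = np.stack([self.x_axis, self.y_axis, self.z_axis])
        if not np.allclose(axes @ axes.T, np.eye(3), atol=1e-9):
            raise FrameError("frame axes are not orthonormal")
        if np.dot(np.cross(self.x_axis, self.y_axis), self.z_axis) < 0:
            raise FrameError("frame is not right-handed")

    def to_frame(self, point: np.ndarray) -> np.ndarray:
        """Coordinates of a world-space point in this frame."""
        rel = np.asarray(point, dtype=float) - self.origin
        return np.array(
            [np.dot(rel, self.x_axis), np.dot(rel, self.y_axis), np.dot(rel, self.z_axis)]
        )


@dataclass
class DockingGeometry:
    crossing_angle: float
    incident_angle: float
    valpha_center: np.ndarray
    vbeta_center: np.ndarray
    tcr_center: np.ndarray
    x_pos: float
    y_pos: float
    canonical_polarity: Optional[bool] = None
    anchor_fallback: bool = False

    def as_dict(self) -> Dict[str, float]:
        return {
            "crossing_angle": self.crossing_angle,
            "incident_angle": self.incident_angle,
            "x_pos": self.x_pos,
            "y_pos": self.y_pos,
        }


def _unit(v: np.ndarray, what: str = "vector") -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise GeometryError(f"zero-length {what}")
    return v / n


def _ca_coords(chain, lo: int, hi: int) -> np.ndarray:
    coords = [
        res.find_atom("CA").coords
        for res in chain.polymer_residues()
        if lo <= res.seq <= hi and res.find_atom("CA") is not None
    ]
    return np.asarray(coords, dtype=float).reshape(-1, 3)


def build_mhc_frame(complex: AnnotatedComplex) -> ReferenceFrame:
    """Construct the pMHC reference frame from helix and peptide C-alphas.

    z = total-least-squares plane normal of the helix C-alphas, signed toward
    the TCR (toward +z of the input coordinates when no TCR is present);
    x = first principal axis of the peptide C-alphas projected into the
    plane, oriented so the C-terminal C-alpha has the greater x; y = z cross x.
    """
    ann = complex.annotation
    heavy = complex.chain_for_role("mhc_heavy")
    helix_ca = np.vstack(
        [_ca_coords(heavy, *ann.helix_ranges[name]) for name in ("alpha1", "alpha2")]
    )
    if any(
        _ca_coords(heavy, *ann.helix_ranges[name]).shape[0] < 10
        for name in ("alpha1", "alpha2")
    ):
        raise FrameError("each helix range must resolve to >= 10 C-alpha atoms")

    origin = helix_ca.mean(axis=0)
    centered = helix_ca - origin
    # total least squares plane: smallest principal component is the normal
    _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    if svals[1] < 1e-8:
        raise FrameError("helix C-alpha atoms are collinear; plane undefined")
    z_axis = vt[2]

    # sign the normal toward the TCR side
    tcr_cas = []
    for role in ("tcr_alpha", "tcr_beta"):
        if ann.chain_for_role(role) is not None:
            chain = complex.chain_for_role(role)
            tcr_cas.extend(
                res.find_atom("CA").coords
                for res in chain.polymer_residues()
                if res.find_atom("CA") is not None
            )
    if tcr_cas:
        toward = np.mean(np.asarray(tcr_cas), axis=0) - origin
        if np.dot(z_axis, toward) < 0:
            z_axis = -z_axis
    elif z_axis[2] < 0:
        z_axis = -z_axis

    peptide = complex.chain_for_role("peptide")
    pep_ca = [
        res.find_atom("CA").coords
        for res in peptide.polymer_residues()
        if res.find_atom("CA") is not None
    ]
    if len(pep_ca) < 3:
        raise FrameError("peptide must have >= 3 C-alpha atoms")
    pep_ca = np.asarray(pep_ca)
    pep_centered = pep_ca - pep_ca.mean(axis=0)
    _, psv, pvt = np.linalg.svd(pep_centered, full_matrices=False)
    if psv[0] < 1e-8:
        raise FrameError("peptide C-alpha atoms are coincident; axis undefined")
    axis = pvt[0]
    # orientation: greater x toward the peptide C-terminus
    if np.dot(axis, pep_ca[-1] - pep_ca[0]) < 0:
        axis = -axis
    x_axis = axis - np.dot(axis, z_axis) * z_axis
    x_axis = _unit(x_axis, "in-plane peptide axis")
    y_axis = np.cross(z_axis, x_axis)

    return ReferenceFrame(origin=origin, x_axis=x_axis, y_axis=y_axis, z_axis=z_axis)


def domain_center(chain, cys_pair: CysPair) -> Tuple[np.ndarray, bool]:
    """Mean position of the two disulfide anchor atoms of a V domain.

    Returns the center and a flag marking C-alpha fallback at either anchor.
    """
    coords = []
    fallback = False
    for (seq, icode), use_ca in zip(cys_pair.positions, cys_pair.used_ca):
        residue = chain.get(seq, icode)
        if residue is None:
            raise GeometryError(f"chain {chain.chain_id}: anchor residue {seq}{icode} missing")
        atom = residue.find_atom("CA") if use_ca else residue.find_atom("SG")
        if atom is None:
            atom = residue.find_atom("CA")
            use_ca = atom is not None
        if atom is None:
            raise GeometryError(
                f"chain {chain.chain_id}: residue {seq}{icode} has neither SG nor CA"
            )
        coords.append(atom.coords)
        fallback = fallback or use_ca
    if np.linalg.norm(coords[0] - coords[1]) < 1e-9:
        raise GeometryError("anchor positions resolve to the same atom")
    return (coords[0] + coords[1]) / 2.0, fallback


def tcr_center_projection(
    valpha_center: np.ndarray, vbeta_center: np.ndarray, frame: ReferenceFrame
) -> Tuple[np.ndarray, float, float]:
    """TCR center (midpoint of domain centers) and its x/y frame coordinates."""
    tcr_center = (np.asarray(valpha_center, float) + np.asarray(vbeta_center, float)) / 2.0
    fx, fy, _ = frame.to_frame(tcr_center)
    return tcr_center, float(fx), float(fy)


def crossing_angle(
    valpha_center: np.ndarray, vbeta_center: np.ndarray, frame: ReferenceFrame
) -> float:
    """Angle (deg, in [0, 180]) between the in-plane projection of the
    Valpha -> Vbeta vector and the peptide (+x) axis."""
    v = np.asarray(vbeta_center, float) - np.asarray(valpha_center, float)
    vx, vy = np.dot(v, frame.x_axis), np.dot(v, frame.y_axis)
    norm = np.hypot(vx, vy)
    if norm < 1e-12:
        raise GeometryError("Valpha->Vbeta vector is perpendicular to the MHC plane")
    return float(np.degrees(np.arccos(np.clip(vx / norm, -1.0, 1.0))))


def incident_angle_elevation(
    valpha_center: np.ndarray, vbeta_center: np.ndarray, frame: ReferenceFrame
) -> float:
    """Default incident-angle strategy: elevation (deg, [0, 90]) of the
    Valpha -> Vbeta vector out of the MHC plane."""
    v = np.asarray(vbeta_center, float) - np.asarray(valpha_center, float)
    u = _unit(v, "Valpha->Vbeta vector")
    return float(np.degrees(np.arcsin(abs(np.dot(u, frame.z_axis)))))


#: Pluggable incident-angle strategies.
INCIDENT_STRATEGIES: Dict[str, Callable] = {
    "elevation": incident_angle_elevation,
}


def incident_angle(
    valpha_center: np.ndarray,
    vbeta_center: np.ndarray,
    frame: ReferenceFrame,
    strategy: str = "elevation",
) -> float:
    try:
        fn = INCIDENT_STRATEGIES[strategy]
    except KeyError:
        raise GeometryError(
            f"unknown incident-angle strategy {strategy!r}; "
            f"available: {sorted(INCIDENT_STRATEGIES)}"
        )
    return fn(valpha_center, vbeta_center, frame)


def docking_geometry(
    complex: AnnotatedComplex,
    incident_strategy: str = "elevation",
) -> DockingGeometry:
    """All docking descriptors of an annotated TCR-pMHC complex."""
    frame = build_mhc_frame(complex)
    ann = complex.annotation
    centers = {}
    fallback = False
    for role in ("tcr_alpha", "tcr_beta"):
        chain = complex.chain_for_role(role)
        override = ann.cys_pairs.get(chain.chain_id)
        pair = detect_conserved_cys(chain, override=override)
        center, fb = domain_center(chain, pair)
        centers[role] = center
        fallback = fallback or fb or pair.any_fallback

    va, vb = centers["tcr_alpha"], centers["tcr_beta"]
    tcr_center, x_pos, y_pos = tcr_center_projection(va, vb, frame)

    # canonical polarity diagnostic: Valpha over the alpha2 helix (y > 0 side
    # in this frame when the peptide runs N->C along +x), Vbeta over alpha1
    heavy = complex.chain_for_role("mhc_heavy")
    a1 = _ca_coords(heavy, *ann.helix_ranges["alpha1"]).mean(axis=0)
    a2 = _ca_coords(heavy, *ann.helix_ranges["alpha2"]).mean(axis=0)
    polarity = bool(
        np.linalg.norm(va - a2) < np.linalg.norm(va - a1)
        and np.linalg.norm(vb - a1) < np.linalg.norm(vb - a2)
    )

    return DockingGeometry(
        crossing_angle=crossing_angle(va, vb, frame),
        incident_angle=incident_angle(va, vb, frame, strategy=incident_strategy),
        valpha_center=va,
        vbeta_center=vb,
        tcr_center=tcr_center,
        x_pos=x_pos,
        y_pos=y_pos,
        canonical_polarity=polarity,
        anchor_fallback=fallback,
    )


# ---------------------------------------------------------------------------
# Reference-table ranking

TABLE_COLUMNS = ("complex_id", "crossing_angle", "incident_angle", "x_pos", "y_pos")


def read_reference_table(path) -> pd.DataFrame:
    """Read a docking-descriptor reference table (TSV with header)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise RankingError(f"reference table missing columns: {missing}")
    if df["complex_id"].duplicated().any():
        raise RankingError("reference table has duplicate complex ids")
    values = df[list(TABLE_COLUMNS[1:])].to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise RankingError("reference table contains non-finite values")
    return df


def write_reference_table(df: pd.DataFrame, path) -> None:
    df.to_csv(Path(path), sep="\t", index=False)


def rank_percentile(
    value: float, table_values, direction: str = "highest_is_1"
) -> Tuple[int, int]:
    """Rank of ``value`` among reference values, plus its percentile.

    rank = 1 + number of reference values strictly greater (for
    ``highest_is_1``); percentile = round(100 * (1 - rank / N)) where N
    counts the reference rows plus the query itself.
    """
    values = np.asarray(table_values, dtype=float)
    if values.size == 0:
        raise RankingError("empty reference table")
    if not np.isfinite(value):
        raise RankingError("query value must be finite")
    if direction == "highest_is_1":
        rank = 1 + int(np.sum(values > value))
    elif direction == "lowest_is_1":
        rank = 1 + int(np.sum(values < value))
    else:
        raise RankingError(f"unknown direction {direction!r}")
    n_total = values.size + 1
    percentile = int(np.floor(100.0 * (1.0 - rank / n_total) + 0.5))
    return rank, percentile
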