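"""Lawrence-Colman shape complementarity (Sc) of an interface.

For every dot x_a (with outward normal n_a) on one side's surface, find the
nearest dot x_b (normal n_b) on the partner surface and score

    s(a->b) = -(n_a . n_b) * exp(-w * d(x_a, x_b)^2)

so perfectly apposed, anti-parallel surface patches score +1.  Sc is the mean
of the two median scores over interface dots, after discarding a peripheral
band of width ``border_trim`` along the interface rim.

Surfaces here are contact (van der Waals) dot surfaces: a deterministic
spiral lattice on each atom's sphere, dots inside any other atom's sphere
removed.  The original statistic is defined on the molecular (Connolly)
surface, which coincides with the contact surface exactly where the two
sides touch -- the region Sc scores -- and differs only in reentrant
crevices.  A solvent-accessible variant is available but unsuitable for
scoring tight interfaces: probe-expanded surfaces of the two sides
interpenetrate there, scrambling nearest-dot normals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .errors import ScUndefinedError
from .sasa import SasaParams, sphere_points
from .structure import AtomRecord


@dataclass
class ScParams:
    dot_density: float = 4.0          # dots per A^2 of sphere surface
    probe_radius: float = 1.4         # A
    weight_w: float = 0.5             # A^-2, distance weighting
    border_trim: float = 1.5          # A, rim band excluded from scoring
    interface_distance: float = 1.5   # A, max dot-to-partner-surface distance

    def __post_init__(self) -> None:
        for name in ("dot_density", "probe_radius", "weight_w", "border_trim",
                     "interface_distance"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class ScResult:
    sc: float
    median_a_to_b: float
    median_b_to_a: float
    n_dots_a: int
    n_dots_b: int


@dataclass
class DotSurface:
    points: np.ndarray   # (n, 3)
    normals: np.ndarray  # (n, 3), unit, outward

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        self.normals = np.asarray(self.normals, dtype=float).reshape(-1, 3)
        if self.points.shape != self.normals.shape:
            raise ValueError("points and normals must have matching shapes")


def dot_surface(
    atoms: Sequence[AtomRecord],
    params: ScParams,
    radii: SasaParams | None = None,
    kind: str = "contact",
) -> DotSurface:
    """Dot surface of an atom set with outward unit normals.

    ``kind="contact"`` places dots on the van der Waals spheres (the default
    for Sc); ``kind="accessible"`` on probe-expanded spheres.
    """
    if kind not in ("contact", "accessible"):
        raise ValueError(f"unknown surface kind {kind!r}")
    radii = radii or SasaParams()
    atoms = [a for a in atoms if not a.is_hydrogen]
    if not atoms:
        return DotSurface(np.empty((0, 3)), np.empty((0, 3)))
    coords = np.array([a.coords for a in atoms])
    expanded = np.array([radii.radius_of(a) for a in atoms])
    if kind == "accessible":
        expanded = expanded + params.probe_radius
    tree = cKDTree(coords)
    max_expanded = float(expanded.max())

    all_points = []
    all_normals = []
    for i in range(len(atoms)):
        r = expanded[i]
        n_dots = max(12, int(round(params.dot_density * 4.0 * np.pi * r * r)))
        unit = sphere_points(n_dots)
        pts = coords[i] + r * unit
        neighbor_idx = [
            j for j in tree.query_ball_point(coords[i], r + max_expanded) if j != i
        ]
        if neighbor_idx:
            diff = pts[:, None, :] - coords[neighbor_idx][None, :, :]
            d2 = np.einsum("ijk,ijk->ij", diff, diff)
            keep = ~(d2 < (expanded[neighbor_idx] ** 2)[None, :] - 1e-12).any(axis=1)
        else:
            keep = np.ones(len(pts), dtype=bool)
        all_points.append(pts[keep])
        all_normals.append(unit[keep])
    return DotSurface(np.vstack(all_points), np.vstack(all_normals))


def _directed_scores(
    src: DotSurface, dst: DotSurface, params: ScParams
) -> Tuple[np.ndarray, np.ndarray]:
    """Per-dot scores from src toward dst, plus the interface mask on src."""
    tree = cKDTree(dst.points)
    dist, idx = tree.query(src.points)
    interface = dist <= params.interface_distance
    if interface.any() and not interface.all():
        # trim the band of interface dots within border_trim of the rim,
        # the rim being the nearest non-interface dot of the same surface
        rim_tree = cKDTree(src.points[~interface])
        rim_dist, _ = rim_tree.query(src.points[interface])
        kept = np.where(interface)[0][rim_dist > params.border_trim]
        mask = np.zeros(len(src.points), dtype=bool)
        mask[kept] = True
    else:
        mask = interface
    scores = -np.einsum("ij,ij->i", src.normals, dst.normals[idx]) * np.exp(
        -params.weight_w * dist**2
    )
    return scores[mask], mask


def sc_from_dots(
    surface_a: DotSurface, surface_b: DotSurface, params: ScParams | None = None
) -> ScResult:
    """Sc statistic from two precomputed dot surfaces."""
    params = params or ScParams()
    if len(surface_a.points) == 0 or len(surface_b.points) == 0:
        raise ScUndefinedError("empty dot surface")
    s_ab, mask_a = _directed_scores(surface_a, surface_b, params)
    s_ba, mask_b = _directed_scores(surface_b, surface_a, params)
    if len(s_ab) == 0 or len(s_ba) == 0:
        raise ScUndefinedError(
            "no interface dots within "
            f"{params.interface_distance} A of the partner surface"
        )
    med_ab = float(np.median(s_ab))
    med_ba = float(np.median(s_ba))
    return ScResult(
        sc=(med_ab + med_ba) / 2.0,
        median_a_to_b=med_ab,
        median_b_to_a=med_ba,
        n_dots_a=int(mask_a.sum()),
        n_dots_b=int(mask_b.sum()),
    )


def shape_complementarity(
    side_a: Sequence[AtomRecord],
    side_b: Sequence[AtomRecord],
    params: ScParams | None = None,
    radii: SasaParams | None = None,
    surface: str = "contact",
) -> ScResult:
    """Sc of the interface between two atom sets (e.g. TCR vs peptide+MHC)."""
    params = params or ScParams()
    surf_a = dot_surface(side_a, params, radii, kind=surface)
    surf_b = dot_surface(side_b, params, radii, kind=surface)
    return sc_from_dots(surf_a, surf_b, params)
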