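"""Shrake–Rupley solvent-accessible surface area with retained surface points.

A probe sphere (default radius 1.4 Angstrom) is rolled over the atomic
spheres by sampling each atom's expanded sphere with a deterministic
golden-spiral point set and discarding points occluded by neighboring
expanded spheres.  Unlike packaged SASA codes, the accessible surface
points themselves are kept: downstream membrane-slab analysis partitions
each residue's accessible area by the z coordinate of its surface points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .structure import StructureModel

__all__ = ["SasaResult", "compute_sasa", "sphere_points"]


def sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere points (golden spiral)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0**0.5) * i
    return np.column_stack(
        (np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi))
    )


@dataclass
class SasaResult:
    """Per-atom accessible areas plus the accessible surface points."""

    atom_areas: np.ndarray              # Angstrom^2, one per atom
    surface_points: list[np.ndarray]    # (m_i, 3) accessible points per atom
    point_areas: np.ndarray             # area carried by one point, per atom
    probe_radius: float
    n_points: int

    @property
    def total_area(self) -> float:
        return float(self.atom_areas.sum())

    def residue_areas(self, structure: StructureModel) -> dict[tuple[str, int], float]:
        return {
            key: float(self.atom_areas[idx].sum())
            for key, idx in structure.residues().items()
        }


def compute_sasa(
    structure: StructureModel,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> SasaResult:
    """Per-atom SASA of the structure with surface-point bookkeeping.

    Each of the ``n_points`` test points on atom i's expanded sphere
    (radius r_i + probe) carries area 4*pi*(r_i+probe)^2 / n_points; a
    point is accessible when it lies outside every neighbor's expanded
    sphere.
    """
    if probe_radius <= 0:
        raise ValueError("probe_radius must be positive")
    if n_points < 8:
        raise ValueError("n_points too small for a meaningful estimate")
    coords = structure.coords
    radii = structure.radii
    n_atoms = coords.shape[0]
    if n_atoms == 0:
        raise ValueError("structure has no atoms")
    if n_atoms > 1:
        tree = cKDTree(coords)
        dup = tree.query_pairs(1e-6)
        if dup:
            warnings.warn(f"{len(dup)} pairs of coincident atoms", stacklevel=2)
    else:
        tree = None

    unit = sphere_points(n_points)
    expanded = radii + probe_radius
    max_reach = 2.0 * expanded.max()
    areas = np.empty(n_atoms)
    points: list[np.ndarray] = []
    point_areas = 4.0 * np.pi * expanded**2 / n_points

    for i in range(n_atoms):
        pts = coords[i] + expanded[i] * unit
        if tree is not None:
            nbrs = [j for j in tree.query_ball_point(coords[i], max_reach) if j != i]
        else:
            nbrs = []
        mask = np.ones(n_points, dtype=bool)
        for j in nbrs:
            center_d2 = float(np.sum((coords[i] - coords[j]) ** 2))
            if center_d2 < 1e-12:
                # coincident atoms: assign the shared surface to the
                # first-indexed atom so the total is counted once
                if j < i:
                    mask[:] = False
                    break
                continue
            d2 = np.einsum("ij,ij->i", pts - coords[j], pts - coords[j])
            mask &= d2 > expanded[j] ** 2
            if not mask.any():
                break
        areas[i] = mask.sum() * point_areas[i]
        points.append(pts[mask])
    return SasaResult(
        atom_areas=areas,
        surface_points=points,
        point_areas=point_areas,
        probe_radius=probe_radius,
        n_points=n_points,
    )
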