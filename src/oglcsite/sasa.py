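"""Shrake–Rupley solvent-accessible surface area.

A probe sphere (default 1.4 A) is rolled over each atom's van der Waals
sphere; accessibility is estimated by quadrature over a deterministic
golden-spiral point layout, so results are reproducible without a seed.
Hydrogens are excluded by default (vdW radius tables for H vary between
sources); ``include_hydrogens=True`` restores the fully protonated setting.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .structure import ProteinStructure

DEFAULT_PROBE_RADIUS = 1.4  # A, water-sized probe
DEFAULT_N_POINTS = 960


def sphere_points(n: int) -> np.ndarray:
    """``n`` quasi-uniform unit vectors from the golden-spiral (Fibonacci) layout."""
    if n < 1:
        raise ValueError("n_sphere_points must be >= 1")
    k = np.arange(n, dtype=float)
    # z descends uniformly; azimuth advances by the golden angle
    z = 1.0 - (2.0 * k + 1.0) / n
    theta = np.pi * (1.0 + np.sqrt(5.0)) * k
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])


def compute_sasa(
    structure: ProteinStructure,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_sphere_points: int = DEFAULT_N_POINTS,
    include_hydrogens: bool = False,
) -> dict[tuple[int, int], float]:
    """Per-atom SASA in A^2, keyed by ``(residue_index, atom position in residue)``.

    Excluded hydrogens get an entry of 0.0 and do not occlude other atoms.
    """
    if probe_radius <= 0:
        raise ValueError("probe_radius must be > 0")
    if len(structure) == 0:
        raise ValueError("empty structure")

    keys: list[tuple[int, int]] = []
    active: list[bool] = []
    coords: list[np.ndarray] = []
    radii: list[float] = []
    for res in structure.residues:
        for j, atom in enumerate(res.atoms):
            keys.append((res.index, j))
            use = include_hydrogens or not atom.is_hydrogen
            active.append(use)
            if use:
                coords.append(atom.coords)
                radii.append(atom.vdw_radius)
    if not coords:
        raise ValueError("no atoms left after hydrogen exclusion")

    xyz = np.asarray(coords)
    rad = np.asarray(radii) + probe_radius
    unit = sphere_points(n_sphere_points)
    tree = cKDTree(xyz)
    max_rad = rad.max()

    area = np.empty(len(xyz))
    for i in range(len(xyz)):
        pts = xyz[i] + rad[i] * unit
        neighbours = [j for j in tree.query_ball_point(xyz[i], rad[i] + max_rad) if j != i]
        if neighbours:
            nb_xyz = xyz[neighbours]
            nb_rad = rad[neighbours]
            d2 = ((pts[:, None, :] - nb_xyz[None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < nb_rad[None, :] ** 2).any(axis=1)
            accessible = int((~buried).sum())
        else:
            accessible = n_sphere_points
        area[i] = 4.0 * np.pi * rad[i] ** 2 * accessible / n_sphere_points

    result: dict[tuple[int, int], float] = {}
    it = iter(area)
    for key, use in zip(keys, active):
        result[key] = float(next(it)) if use else 0.0
    return result


def residue_sasa(
    structure: ProteinStructure,
    atom_sasa: dict[tuple[int, int], float],
) -> dict[int, float]:
    """Sum per-atom SASA into per-residue totals (conserves the overall sum)."""
    result: dict[int, float] = {}
    for res in structure.residues:
        total = 0.0
        for j in range(len(res.atoms)):
            key = (res.index, j)
            if key not in atom_sasa:
                raise KeyError(f"atom_sasa is missing entry for atom {key}")
            total += atom_sasa[key]
        result[res.index] = total
    return result
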