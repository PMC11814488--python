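"""Radial local-environment features around a residue.

For a centre residue and each radial cutoff r the feature vector holds,
per physicochemical class c, the number of neighbouring residues within
r whose amino acid belongs to c and the summed per-residue SASA of those
neighbours.  Radius 0 describes the centre alone: its class memberships
(one-hot) and its own SASA.  Residue–residue distance is the minimum
heavy-atom pair distance by default (captures side-chain reach); a
C-alpha metric is available for backbone-only analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classes import ClassTable, DEFAULT_CLASS_TABLE
from .sasa import compute_sasa, residue_sasa
from .structure import ProteinStructure

DEFAULT_RADII = (0.0, 5.0, 10.0, 15.0, 20.0, 25.0)


@dataclass
class LocalEnvVector:
    """Named local-environment features for one centre residue."""

    center: tuple[str, int]
    radii: tuple[float, ...]
    values: dict[str, float]


def _residue_coords(structure: ProteinStructure, metric: str, include_hydrogens: bool):
    coords = []
    for res in structure.residues:
        if metric == "ca":
            ca = [a for a in res.atoms if a.name == "CA"]
            atoms = ca if ca else res.heavy_atoms()
        else:
            atoms = [
                a for a in res.atoms if include_hydrogens or not a.is_hydrogen
            ]
            if not atoms:
                atoms = res.atoms
        coords.append(np.array([a.coords for a in atoms]))
    return coords


def residues_within(
    structure: ProteinStructure,
    center: int,
    cutoff: float,
    metric: str = "heavy",
    include_hydrogens: bool = False,
) -> set[int]:
    """Residue indices whose minimum atom-pair distance to ``center`` is <= cutoff.

    The centre residue is always included; cutoff 0 returns the centre alone.
    """
    indices = [r.index for r in structure.residues]
    if center not in indices:
        raise IndexError(f"invalid center residue index {center}")
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    if metric not in {"heavy", "ca"}:
        raise ValueError(f"unknown distance metric {metric!r}")
    coords = _residue_coords(structure, metric, include_hydrogens)
    pos = indices.index(center)
    c = coords[pos]
    result = {center}
    for res, xyz in zip(structure.residues, coords):
        if res.index == center:
            continue
        d2 = ((c[:, None, :] - xyz[None, :, :]) ** 2).sum(axis=2)
        if np.sqrt(d2.min()) <= cutoff:
            result.add(res.index)
    return result


def local_environment_vector(
    structure: ProteinStructure,
    center: int,
    radii=DEFAULT_RADII,
    table: ClassTable = DEFAULT_CLASS_TABLE,
    residue_sasa_map: dict[int, float] | None = None,
    metric: str = "heavy",
    include_charges: bool = False,
) -> LocalEnvVector:
    """Class-wise neighbour counts and total SASA at each cutoff radius.

    ``radii`` must be ascending; a leading 0 produces the centre's self
    features.  ``residue_sasa_map`` is computed on demand if not supplied.
    With ``include_charges=True``, class-wise sums of atomic partial
    charges are appended per radius (requires charges on every atom).
    """
    radii = tuple(float(r) for r in radii)
    if list(radii) != sorted(radii):
        raise ValueError("radii must be sorted ascending")
    if residue_sasa_map is None:
        residue_sasa_map = residue_sasa(structure, compute_sasa(structure))

    by_index = {r.index: r for r in structure.residues}
    if center not in by_index:
        raise IndexError(f"invalid center residue index {center}")

    values: dict[str, float] = {}
    center_res = by_index[center]
    center_classes = table.membership(center_res.aa_code)
    for cls in table.class_names:
        values[f"self_{cls}"] = 1.0 if cls in center_classes else 0.0
    values["self_sasa"] = residue_sasa_map[center]

    if include_charges:
        charges = {
            r.index: sum(a.partial_charge for a in r.atoms)
            for r in structure.residues
        }

    for r in radii:
        if r == 0.0:
            continue
        hood = residues_within(structure, center, r, metric=metric)
        for cls in table.class_names:
            members = [
                j for j in hood if table.membership(by_index[j].aa_code) >= {cls}
            ]
            values[f"{cls}_r{r:g}_count"] = float(len(members))
            values[f"{cls}_r{r:g}_total_sasa"] = float(
                sum(residue_sasa_map[j] for j in members)
            )
            if include_charges:
                values[f"{cls}_r{r:g}_total_charge"] = float(
                    sum(charges[j] for j in members)
                )
    return LocalEnvVector(center=(structure.id, center), radii=radii, values=values)


def feature_schema(
    radii=DEFAULT_RADII,
    table: ClassTable = DEFAULT_CLASS_TABLE,
    include_charges: bool = False,
) -> list[str]:
    """The ordered feature-name header shared by all structures."""
    names = [f"self_{cls}" for cls in table.class_names] + ["self_sasa"]
    for r in (float(x) for x in radii):
        if r == 0.0:
            continue
        for cls in table.class_names:
            names.append(f"{cls}_r{r:g}_count")
            names.append(f"{cls}_r{r:g}_total_sasa")
            if include_charges:
                names.append(f"{cls}_r{r:g}_total_charge")
    return names


def featurize_sites(
    structure: ProteinStructure,
    sites: list[int],
    radii=DEFAULT_RADII,
    table: ClassTable = DEFAULT_CLASS_TABLE,
    metric: str = "heavy",
    include_charges: bool = False,
) -> pd.DataFrame:
    """Feature table, one row per site, with a schema-stable column order.

    The index is ``(structure id, 1-based site position)``; internally all
    residue indices stay 0-based.
    """
    valid = {r.index for r in structure.residues}
    for s in sites:
        if s not in valid:
            raise IndexError(f"site {s} out of range for structure {structure.id}")
    columns = feature_schema(radii, table, include_charges)
    sasa_map = (
        residue_sasa(structure, compute_sasa(structure)) if sites else {}
    )
    rows = []
    for s in sites:
        vec = local_environment_vector(
            structure, s, radii, table, sasa_map, metric, include_charges
        )
        rows.append([vec.values[c] for c in columns])
    idx = pd.MultiIndex.from_tuples(
        [(structure.id, s + 1) for s in sites], names=["structure_id", "position"]
    )
    return pd.DataFrame(rows, index=idx, columns=columns, dtype=float)
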