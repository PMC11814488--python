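"""Protein structure containers and PDB/mmCIF input.

Structures are reduced to the minimal geometric substrate needed for
solvent-accessible surface area and radial neighbourhood computations:
atoms with coordinates, element symbols and van der Waals radii, grouped
into residues of a chain (or complex, concatenated in file order).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

try:
    import gemmi
except ImportError:  # pragma: no cover
    gemmi = None

#: Bondi-style van der Waals radii (A), bundled so results are
#: bit-reproducible regardless of any external radius table.
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "CL": 1.75,
    "SE": 1.90,
    "BR": 1.85,
    "I": 1.98,
}

THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


@dataclass
class Atom:
    """A single atom: coordinates in A, element, vdW radius in A.

    ``partial_charge`` (elementary-charge units) is optional input data;
    it is never computed internally.
    """

    serial: int
    element: str
    coords: np.ndarray
    vdw_radius: float
    partial_charge: float | None = None
    is_hydrogen: bool = False
    name: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.serial}: coords must be a finite 3-vector")
        if not self.vdw_radius > 0:
            raise ValueError(f"atom {self.serial}: vdw_radius must be > 0")


@dataclass
class Residue:
    """One residue: 0-based chain position, one-letter code, ordered atoms."""

    index: int
    aa_code: str
    atoms: list[Atom]

    def __post_init__(self) -> None:
        if len(self.aa_code) != 1 or (
            self.aa_code not in THREE_TO_ONE.values() and self.aa_code != "X"
        ):
            raise ValueError(f"residue {self.index}: bad one-letter code {self.aa_code!r}")
        if not self.atoms:
            raise ValueError(f"residue {self.index}: needs at least one atom")

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]


@dataclass
class ProteinStructure:
    """Ordered residues of a structure; indices strictly increasing from 0."""

    id: str
    residues: list[Residue]
    source_format: str = "PDB"

    def __post_init__(self) -> None:
        indices = [r.index for r in self.residues]
        if indices != sorted(set(indices)):
            raise ValueError("residue indices must be strictly increasing")

    @property
    def sequence(self) -> str:
        return "".join(r.aa_code for r in self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def iter_atoms(self, include_hydrogens: bool = True):
        """Yield ``(residue_index, atom)`` in residue then file order."""
        for res in self.residues:
            for atom in res.atoms:
                if atom.is_hydrogen and not include_hydrogens:
                    continue
                yield res.index, atom


class StructureFormatError(ValueError):
    pass


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in {".cif", ".mmcif"}:
        return "mmCIF"
    return "PDB"


def read_structure(
    path: str | Path,
    format: str | None = None,
    on_unknown_element: str = "skip",
) -> ProteinStructure:
    """Parse a PDB or mmCIF file into a :class:`ProteinStructure`.

    Only amino-acid residues are kept; the first model is taken if several
    are present.  vdW radii come from the bundled :data:`VDW_RADII` table.
    Atoms with elements absent from that table are skipped with a warning
    (``on_unknown_element="skip"``) or raise (``"error"``).
    """
    if gemmi is None:  # pragma: no cover
        raise ImportError("gemmi is required for structure parsing")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _infer_format(path)
    try:
        st = gemmi.read_structure(str(path))
    except Exception as exc:
        raise StructureFormatError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise StructureFormatError(f"{path}: no models")
    if len(st) > 1:
        warnings.warn(f"{path}: {len(st)} models; using the first")
    model = st[0]

    residues: list[Residue] = []
    idx = 0
    for chain in model:
        for res in chain:
            info = gemmi.find_tabulated_residue(res.name)
            if info is None or not info.is_amino_acid():
                continue
            aa = THREE_TO_ONE.get(res.name.upper(), "X")
            atoms: list[Atom] = []
            for atom in res:
                elem = atom.element.name.upper()
                radius = VDW_RADII.get(elem)
                if radius is None:
                    if on_unknown_element == "error":
                        raise StructureFormatError(
                            f"{path}: unknown element {elem!r} in residue {res.name}"
                        )
                    warnings.warn(f"{path}: skipping atom with unknown element {elem!r}")
                    continue
                atoms.append(
                    Atom(
                        serial=atom.serial,
                        element=elem,
                        coords=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                        vdw_radius=radius,
                        is_hydrogen=(elem == "H"),
                        name=atom.name,
                    )
                )
            if not atoms:
                raise StructureFormatError(
                    f"{path}: residue {res.name} {res.seqid.num} has no usable atoms"
                )
            residues.append(Residue(index=idx, aa_code=aa, atoms=atoms))
            idx += 1
    return ProteinStructure(id=path.stem, residues=residues, source_format=fmt)


def write_pdb(structure: ProteinStructure, path: str | Path) -> None:
    """Write a minimal single-chain PDB file (re-parses to an equal structure)."""
    path = Path(path)
    lines = []
    serial = 0
    for res in structure.residues:
        res3 = ONE_TO_THREE.get(res.aa_code, "UNK")
        for atom in res.atoms:
            serial += 1
            name = atom.name or atom.element
            # PDB columns: name left-padded for 1-letter elements
            name_fmt = f" {name:<3s}" if len(name) < 4 else name
            lines.append(
                f"ATOM  {serial:5d} {name_fmt}{'':1s}{res3:>3s} A{res.index + 1:4d}    "
                f"{atom.coords[0]:8.3f}{atom.coords[1]:8.3f}{atom.coords[2]:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}          {atom.element:>2s}"
            )
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
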