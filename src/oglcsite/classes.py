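"""Physicochemical classes of the 20 amino acids.

The class table defines the schema of the local-environment features:
for each class and radial cutoff the feature vector holds a neighbour
count and a total SASA.  The default inventory covers hydrophobicity,
polarity, charge and size and is fully overridable, so an alternative
published schema can be swapped in from a YAML/JSON mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_DEFAULT_CLASSES: dict[str, frozenset[str]] = {
    "aliphatic": frozenset("AVLI"),
    "aromatic": frozenset("FWYH"),
    "hydrophobic": frozenset("AVLIMFWC"),
    "nonpolar": frozenset("GAVLIPFMW"),
    "polar_uncharged": frozenset("STNQCY"),
    "positively_charged": frozenset("KRH"),
    "negatively_charged": frozenset("DE"),
    "small": frozenset("GASCTPNDV"),
    "large": frozenset("FWYRKMILHEQ"),
    "hydroxyl": frozenset("STY"),
}


@dataclass(frozen=True)
class ClassTable:
    """Named amino-acid classes plus optional partition-group declarations.

    A partition group is a set of class names that together cover the
    20-letter alphabet exactly once; class counts summed over a partition
    therefore equal the neighbourhood size at every radius, a conservation
    law the test-suite exploits.
    """

    classes: dict[str, frozenset[str]]
    partition_groups: tuple[frozenset[str], ...] = ()

    def __post_init__(self) -> None:
        for name, members in self.classes.items():
            extra = set(members) - set(AMINO_ACIDS)
            if extra:
                raise ValueError(f"class {name!r} has non-amino-acid members {extra}")
        for group in self.partition_groups:
            unknown = set(group) - set(self.classes)
            if unknown:
                raise ValueError(f"partition group names unknown classes {unknown}")
            counts = {aa: 0 for aa in AMINO_ACIDS}
            for cls in group:
                for aa in self.classes[cls]:
                    counts[aa] += 1
            bad = {aa: c for aa, c in counts.items() if c != 1}
            if bad:
                raise ValueError(f"group {set(group)} does not partition the alphabet: {bad}")

    @property
    def class_names(self) -> list[str]:
        """Class names in stable (insertion) order — defines feature order."""
        return list(self.classes)

    def membership(self, aa_code: str) -> set[str]:
        if aa_code == "X":
            return set()
        if aa_code not in AMINO_ACIDS:
            raise KeyError(f"unknown amino-acid code {aa_code!r}")
        return {name for name, members in self.classes.items() if aa_code in members}


DEFAULT_CLASS_TABLE = ClassTable(
    classes=dict(_DEFAULT_CLASSES),
    partition_groups=(frozenset({"small", "large"}),),
)


def classify_residue(aa_code: str, table: ClassTable = DEFAULT_CLASS_TABLE) -> set[str]:
    """Every class of ``table`` containing ``aa_code`` ('X' belongs to none)."""
    return table.membership(aa_code)
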