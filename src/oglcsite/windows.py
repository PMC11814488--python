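"""Sequence windows around candidate Ser/Thr sites and one-hot encoding.

A window covers the target site plus N flanking residues on each side
(2N+1 characters, N defaults to 10); positions beyond the sequence ends
are padded with '-' and encode as all-zero rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
PAD = "-"
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


@dataclass(frozen=True)
class SequenceWindow:
    """A 2N+1-residue window centred on a Ser/Thr site (0-based position)."""

    protein_id: str
    site_position: int
    window: str
    half_width: int

    def __post_init__(self) -> None:
        if len(self.window) != 2 * self.half_width + 1:
            raise ValueError("window length must be 2N+1")
        if self.window[self.half_width] not in "ST":
            raise ValueError(
                f"window centre must be S or T, got {self.window[self.half_width]!r}"
            )

    def pad_mask(self) -> np.ndarray:
        """Boolean array, True at pad positions."""
        return np.array([c == PAD for c in self.window])


def extract_candidate_sites(sequence: str) -> list[int]:
    """0-based positions of every S and T in ``sequence``, ascending."""
    bad = set(sequence) - set(AMINO_ACIDS) - {"X"}
    if bad:
        raise ValueError(f"sequence contains non-amino-acid characters {bad}")
    return [i for i, c in enumerate(sequence) if c in "ST"]


def build_window(
    sequence: str, site: int, half_width: int, protein_id: str = ""
) -> SequenceWindow:
    """Window of ``sequence`` around ``site``; termini are '-'-padded."""
    if half_width < 0:
        raise ValueError("half_width must be >= 0")
    if not 0 <= site < len(sequence) or sequence[site] not in "ST":
        raise ValueError(f"site {site} is not a Ser/Thr position")
    chars = []
    for p in range(site - half_width, site + half_width + 1):
        chars.append(sequence[p] if 0 <= p < len(sequence) else PAD)
    return SequenceWindow(
        protein_id=protein_id,
        site_position=site,
        window="".join(chars),
        half_width=half_width,
    )


def one_hot_encode(window: SequenceWindow | str, alphabet: str = AMINO_ACIDS) -> np.ndarray:
    """(2N+1, 20) binary matrix; pad and unknown ('X') rows stay all-zero."""
    seq = window.window if isinstance(window, SequenceWindow) else window
    index = {aa: i for i, aa in enumerate(alphabet)}
    out = np.zeros((len(seq), len(alphabet)))
    for row, c in enumerate(seq):
        if c in index:
            out[row, index[c]] = 1.0
        elif c not in (PAD, "X"):
            raise ValueError(f"character {c!r} not encodable")
    return out
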