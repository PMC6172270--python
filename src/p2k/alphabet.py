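"""Canonical amino-acid alphabet shared by every matrix in the package.

All 20x20 matrices (contact counts, statistical residuals, re-projected
residual spaces) are indexed in this fixed alphabetical one-letter order so
that artifacts written by different runs are directly comparable.
"""

from __future__ import annotations

ALPHABET: str = "ACDEFGHIKLMNPQRSTVWY"
"""The 20 standard amino acids, alphabetical by one-letter code."""

INDEX: dict[str, int] = {aa: i for i, aa in enumerate(ALPHABET)}

PAD: str = "-"
"""Pad symbol used for sequence-window positions past a terminus and for
unknown letters; contributes zero to every feature."""

THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
}

ONE_TO_THREE: dict[str, str] = {v: k for k, v in THREE_TO_ONE.items()}


def is_standard(letter: str) -> bool:
    """True if ``letter`` is one of the 20 standard one-letter codes."""
    return letter in INDEX
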