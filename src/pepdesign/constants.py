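"""Shared vocabularies and geometric constants.

Amino-acid vocabulary: the 20 canonical one-letter codes in alphabetical
order, indices 1-20; index 0 is reserved for padding. Secondary structure
uses a 3-state alphabet H/E/L with the same pad convention.
"""

from __future__ import annotations

import numpy as np

# 20 canonical amino acids, alphabetical one-letter order; index 0 = pad.
AA_ALPHABET: str = "ACDEFGHIKLMNPQRSTVWY"
AA_TO_INDEX: dict[str, int] = {aa: i + 1 for i, aa in enumerate(AA_ALPHABET)}
INDEX_TO_AA: dict[int, str] = {i + 1: aa for i, aa in enumerate(AA_ALPHABET)}
N_AA: int = 20
PAD_INDEX: int = 0

THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
}
ONE_TO_THREE: dict[str, str] = {v: k for k, v in THREE_TO_ONE.items()}

# 3-state secondary structure; index 0 = pad.
SS_ALPHABET: str = "HEL"
SS_TO_INDEX: dict[str, int] = {"H": 1, "E": 2, "L": 3}
INDEX_TO_SS: dict[int, str] = {1: "H", 2: "E", 3: "L"}

# Peptide fragments are always 6 residues; binding sites span 24-48 residues.
PEPTIDE_LEN: int = 6
SITE_MIN: int = 24
SITE_MAX: int = 48

# Idealized backbone geometry (bond lengths in Angstrom, angles in degrees).
BOND_N_CA: float = 1.46
BOND_CA_C: float = 1.52
BOND_C_N: float = 1.33
BOND_C_O: float = 1.23
ANGLE_N_CA_C: float = 111.0
ANGLE_CA_C_N: float = 116.5
ANGLE_C_N_CA: float = 121.7
ANGLE_CA_C_O: float = 120.5
OMEGA: float = 180.0

# Sanity band for consecutive CA-CA distances in an intact chain (Angstrom).
CA_CA_MIN: float = 3.2
CA_CA_MAX: float = 4.2

# Kyte-Doolittle hydropathy, rescaled to [0, 1] (I=1, R=0); drives the
# surrogate per-residue energy weights.
_KD = {
    "A": 1.8, "C": 2.5, "D": -3.5, "E": -3.5, "F": 2.8, "G": -0.4,
    "H": -3.2, "I": 4.5, "K": -3.9, "L": 3.8, "M": 1.9, "N": -3.5,
    "P": -1.6, "Q": -3.5, "R": -4.5, "S": -0.8, "T": -0.7, "V": 4.2,
    "W": -0.9, "Y": -1.3,
}
HYDROPATHY: dict[str, float] = {aa: (v + 4.5) / 9.0 for aa, v in _KD.items()}

# Non-polar residues (aliphatic/aromatic side chains), for the hot-spot
# composition filter.
NONPOLAR_AAS: frozenset[str] = frozenset("AVLIMFWPG")


def aa_index_array(seq: str) -> np.ndarray:
    """Encode an amino-acid string as integer indices (1-20)."""
    try:
        return np.array([AA_TO_INDEX[a] for a in seq], dtype=np.int64)
    except KeyError as exc:  # pragma: no cover - message formatting
        raise ValueError(f"unknown amino-acid code {exc} in {seq!r}") from exc


def indices_to_seq(idx: np.ndarray) -> str:
    """Decode integer indices (1-20) back to a string."""
    return "".join(INDEX_TO_AA[int(i)] for i in idx)
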