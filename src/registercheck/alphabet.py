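"""The 20-letter standard amino-acid alphabet and conversions.

Probability profiles, reference sequences and model sequences all use the
same fixed column order: the 20 standard one-letter codes sorted
alphabetically (A, C, D, ..., Y).
"""

from __future__ import annotations

import numpy as np

#: Canonical column order for residue-type probability profiles.
AA_ORDER: str = "ACDEFGHIKLMNPQRSTVWY"

N_TYPES: int = len(AA_ORDER)

AA_TO_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AA_ORDER)}

#: Three-letter to one-letter code for the 20 standard amino acids.
THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
}

ONE_TO_THREE: dict[str, str] = {v: k for k, v in THREE_TO_ONE.items()}

STANDARD_RESIDUES: frozenset[str] = frozenset(THREE_TO_ONE)


def seq_to_indices(sequence: str) -> np.ndarray:
    """Convert a one-letter sequence to an integer index array.

    Raises ``ValueError`` on any letter outside the 20 standard codes.
    """
    try:
        return np.array([AA_TO_INDEX[c] for c in sequence], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"non-standard amino-acid letter {exc.args[0]!r}") from None


def indices_to_seq(indices: np.ndarray) -> str:
    """Convert an integer index array back to a one-letter sequence."""
    return "".join(AA_ORDER[i] for i in indices)
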