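"""The 20-letter amino-acid alphabet and substitution-matrix encodings.

Every matrix in the package (network inputs, processing matrices, logo
matrices, the generator PSSM) uses the same fixed residue ordering defined
here, so that flattened vectors are comparable across modules.
"""
from __future__ import annotations

from functools import lru_cache

import numpy as np

#: The 20 standard amino acids, alphabetical by one-letter code. This ordering
#: is the column order of every 20-wide matrix in the package.
RESIDUES: str = "ACDEFGHIKLMNPQRSTVWY"

#: Wildcard letter: encodes to an all-zero vector, excluded from counts.
WILDCARD: str = "X"

#: Default set of residues treated as hydrophobic for the burn-in restriction
#: on the P1 core anchor.
HYDROPHOBIC: str = "AFILMVWY"

RESIDUE_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(RESIDUES)}

#: Integer code of the wildcard in coded-sequence arrays (one past the 20).
WILDCARD_CODE: int = 20


def seq_to_codes(sequence: str) -> np.ndarray:
    """Integer-code a sequence; 'X' maps to :data:`WILDCARD_CODE`.

    Raises ``ValueError`` naming the offending letter and its position for
    anything outside the 20 standard residues plus 'X'.
    """
    codes = np.empty(len(sequence), dtype=np.int64)
    for i, aa in enumerate(sequence):
        if aa == WILDCARD:
            codes[i] = WILDCARD_CODE
        else:
            idx = RESIDUE_INDEX.get(aa)
            if idx is None:
                raise ValueError(
                    f"unknown residue {aa!r} at position {i} in {sequence!r}"
                )
            codes[i] = idx
    return codes


def is_standard(sequence: str) -> bool:
    """True if every letter is one of the 20 standard residues (no wildcard)."""
    return all(aa in RESIDUE_INDEX for aa in sequence)


@lru_cache(maxsize=8)
def substitution_rows(name: str = "BLOSUM50", scale: float = 5.0) -> np.ndarray:
    """A (21, 20) encoding table: row i is the substitution-matrix row of
    residue i (in :data:`RESIDUES` order) divided by ``scale``; the final row
    (the wildcard) is all zeros.
    """
    from Bio.Align import substitution_matrices

    mat = substitution_matrices.load(name)
    table = np.zeros((21, 20), dtype=np.float64)
    for i, a in enumerate(RESIDUES):
        for j, b in enumerate(RESIDUES):
            table[i, j] = mat[a][b] / scale
    return table
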