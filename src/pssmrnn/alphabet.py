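"""Canonical amino-acid alphabet shared by every module.

The column order of all PSSM score matrices in this package is the
PSI-BLAST header order.  Every module that indexes PSSM columns or
assigns residues to feature blocks imports these constants rather than
redefining them.
"""

from __future__ import annotations

#: PSI-BLAST ASCII PSSM column order.
AMINO_ACIDS: str = "ARNDCQEGHILKMFPSTWYV"

#: Residue letter -> column index.
AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: Placeholder for non-canonical residues (B, Z, U, O, J, X, ...).
#: Rows carrying it keep their scores but are excluded from composition
#: counts and from summed-feature row assignment.
UNKNOWN: str = "X"

N_AMINO_ACIDS: int = 20


def canonicalize_residue(letter: str) -> str:
    """Map a residue letter to the canonical alphabet or ``UNKNOWN``."""
    letter = letter.upper()
    return letter if letter in AA_INDEX else UNKNOWN


def is_canonical(letter: str) -> bool:
    return letter in AA_INDEX
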