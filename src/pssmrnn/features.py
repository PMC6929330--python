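"""Order-destroying baseline representations of PSSM profiles.

The classical way to feed PSSM profiles to fixed-input classifiers is to
sum all rows that share the same query residue, collapsing the N x 20
matrix to a 20 x 20 matrix (a 400-dimensional vector) regardless of
sequence length.  The positional arrangement of the rows is discarded in
the process — which is exactly the information the recurrent model in
:mod:`pssmrnn.model` is built to preserve.
"""

from __future__ import annotations

import numpy as np

from .alphabet import AA_INDEX, AMINO_ACIDS, N_AMINO_ACIDS
from .pssm_io import LabeledDataset, PSSMProfile

__all__ = [
    "summed_pssm_matrix",
    "summed_pssm_features",
    "dataset_features",
    "dataset_matrices",
    "aa_composition",
]


def summed_pssm_matrix(profile: PSSMProfile) -> np.ndarray:
    """Collapse a profile to its 20 x 20 summed matrix.

    Entry ``(a, j)`` is the sum of ``scores[i, j]`` over positions ``i``
    whose query residue is amino acid ``a``.  Rows whose residue is
    non-canonical (``X``) contribute to no entry; residues absent from
    the sequence yield all-zero rows.
    """
    matrix = np.zeros((N_AMINO_ACIDS, N_AMINO_ACIDS), dtype=np.float64)
    rows = np.array([AA_INDEX.get(c, -1) for c in profile.residues])
    keep = rows >= 0
    np.add.at(matrix, rows[keep], profile.scores[keep].astype(np.float64))
    return matrix


def summed_pssm_features(profile: PSSMProfile) -> np.ndarray:
    """The 400-dimensional summed-PSSM vector, flattened residue-major
    (20 blocks of 20 PSSM columns, both in canonical alphabet order)."""
    return summed_pssm_matrix(profile).ravel()


def dataset_features(dataset: LabeledDataset) -> np.ndarray:
    """Stack summed features for a whole dataset into ``(n, 400)``."""
    return np.stack([summed_pssm_features(p) for p in dataset.profiles])


def dataset_matrices(dataset: LabeledDataset) -> np.ndarray:
    """Stack 20 x 20 summed matrices into ``(n, 20, 20)`` (2-D CNN input)."""
    return np.stack([summed_pssm_matrix(p) for p in dataset.profiles])


def aa_composition(
    dataset: LabeledDataset,
    classes: tuple[str, ...] = ("positive", "negative"),
) -> dict[str, np.ndarray]:
    """Per-class amino-acid composition in percent.

    Returns a mapping ``{class_name: f}`` for each requested class, where
    ``f`` is a 20-vector of residue frequencies (canonical alphabet
    order) over all positions of all sequences of that class; each vector
    sums to 100.  Non-canonical residues are excluded from the counts.
    A requested class with no residues raises ``ValueError``.
    """
    out: dict[str, np.ndarray] = {}
    wanted = {"positive": 1, "negative": 0}
    for name in classes:
        label = wanted[name]
        counts = np.zeros(N_AMINO_ACIDS, dtype=np.float64)
        for profile, y in zip(dataset.profiles, dataset.labels):
            if y != label:
                continue
            for ch in profile.residues:
                idx = AA_INDEX.get(ch)
                if idx is not None:
                    counts[idx] += 1
        total = counts.sum()
        if total == 0:
            raise ValueError(f"no canonical residues in class {name!r}")
        out[name] = 100.0 * counts / total
    return out
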