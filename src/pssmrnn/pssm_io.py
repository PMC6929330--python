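"""Reading and writing FASTA files, PSI-BLAST ASCII PSSM profiles and
dataset manifests.

A PSSM profile for a query protein of length N is an N x 20 matrix of
integer log-odds scores: row i scores each of the 20 amino acids at
position i, large values marking strongly conserved positions.  The
ASCII dialect parsed here is the one PSI-BLAST emits with
``-out_ascii_pssm``: a couple of header lines, one data row per position
(position index, query residue, 20 log-odds columns, 20 weighted
percentage columns, two trailing statistics), then footer statistics.
Only the first 20 numeric columns — the log-odds scores — are retained;
percentages and footer are discarded.
"""

from __future__ import annotations

import dataclasses
import io
import os
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alphabet import AMINO_ACIDS, N_AMINO_ACIDS, UNKNOWN, canonicalize_residue

__all__ = [
    "PSSMProfile",
    "LabeledDataset",
    "PSSMParseError",
    "parse_pssm",
    "write_pssm",
    "read_pssm_file",
    "write_pssm_file",
    "read_fasta",
    "write_fasta",
    "load_manifest",
    "save_dataset",
]

POSITIVE_LABEL = "positive"
NEGATIVE_LABEL = "negative"

_LABEL_ALIASES = {
    "positive": 1, "1": 1, "pos": 1, "adaptor": 1,
    "negative": 0, "0": 0, "neg": 0, "non-adaptor": 0,
}


class PSSMParseError(ValueError):
    """Raised when PSSM text does not conform to the ASCII dialect."""


@dataclasses.dataclass
class PSSMProfile:
    """An N x 20 position-specific scoring matrix with its query residues.

    Attributes
    ----------
    sequence_id:
        Identifier of the query sequence.
    residues:
        Length-N string; non-canonical letters are normalised to ``X``.
    scores:
        ``(N, 20)`` integer array, columns in :data:`~pssmrnn.alphabet.AMINO_ACIDS`
        order.
    """

    sequence_id: str
    residues: str
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.int64)
        if self.scores.ndim != 2 or self.scores.shape[1] != N_AMINO_ACIDS:
            raise ValueError(
                f"scores must be (N, {N_AMINO_ACIDS}), got {self.scores.shape}"
            )
        if self.scores.shape[0] != len(self.residues):
            raise ValueError(
                f"{self.scores.shape[0]} score rows for "
                f"{len(self.residues)} residues"
            )
        if len(self.residues) < 1:
            raise ValueError("profile must have at least one position")
        self.residues = "".join(canonicalize_residue(c) for c in self.residues)

    @property
    def length(self) -> int:
        return self.scores.shape[0]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PSSMProfile):
            return NotImplemented
        return (
            self.sequence_id == other.sequence_id
            and self.residues == other.residues
            and np.array_equal(self.scores, other.scores)
        )


@dataclasses.dataclass
class LabeledDataset:
    """PSSM profiles with binary labels (1 = adaptor / positive)."""

    profiles: list[PSSMProfile]
    labels: np.ndarray
    metadata: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if len(self.profiles) != self.labels.shape[0]:
            raise ValueError("labels and profiles differ in length")
        if self.labels.size and not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary (0/1)")

    def __len__(self) -> int:
        return len(self.profiles)

    def subset(self, indices: Sequence[int]) -> "LabeledDataset":
        idx = np.asarray(indices, dtype=int)
        return LabeledDataset(
            [self.profiles[i] for i in idx], self.labels[idx], dict(self.metadata)
        )

    @property
    def n_positive(self) -> int:
        return int(self.labels.sum())

    @property
    def n_negative(self) -> int:
        return int((self.labels == 0).sum())


# ---------------------------------------------------------------------------
# PSI-BLAST ASCII PSSM
# ---------------------------------------------------------------------------

def parse_pssm(text: str, sequence_id: str = "") -> PSSMProfile:
    """Parse PSI-BLAST ASCII PSSM content into a :class:`PSSMProfile`.

    Data rows are recognised by a leading integer position index followed
    by a residue letter.  Per row, the first 20 numeric columns (log-odds
    scores) are kept; the 20 weighted-percentage columns and the two
    trailing per-row statistics, when present, are ignored, as are header
    and footer lines.
    """
    residues: list[str] = []
    rows: list[list[int]] = []
    expected_pos = 1
    for lineno, line in enumerate(text.splitlines(), start=1):
        fields = line.split()
        if len(fields) < 3 or not fields[0].isdigit():
            continue  # header, footer or blank
        if not (len(fields[1]) == 1 and fields[1].isalpha()):
            continue
        if int(fields[0]) != expected_pos:
            raise PSSMParseError(
                f"line {lineno}: position index {fields[0]}, "
                f"expected {expected_pos}"
            )
        payload = fields[2:]
        # score-only (20), scores+percentages (40) or full dialect (42)
        if len(payload) not in (20, 40, 42):
            raise PSSMParseError(
                f"line {lineno}: {len(payload)} numeric columns, "
                "expected 20, 40 or 42"
            )
        try:
            rows.append([int(v) for v in payload[:N_AMINO_ACIDS]])
        except ValueError as exc:
            raise PSSMParseError(f"line {lineno}: non-integer score: {exc}") from exc
        residues.append(fields[1])
        expected_pos += 1
    if not rows:
        raise PSSMParseError("no PSSM data rows found")
    return PSSMProfile(sequence_id, "".join(residues), np.array(rows))


def write_pssm(profile: PSSMProfile) -> str:
    """Serialise a profile in the PSI-BLAST ASCII dialect.

    The percentage columns and per-row statistics carry no information in
    this package and are written as zeros; :func:`parse_pssm` discards
    them on the way back in, so ``parse_pssm(write_pssm(p)) == p``.
    """
    buf = io.StringIO()
    buf.write("\n")
    buf.write(
        "Last position-specific scoring matrix computed, weight ratios and "
        "information per position\n"
    )
    header = "            " + "".join(f"{aa:>4}" for aa in AMINO_ACIDS) * 2
    buf.write(header + "\n")
    for i, (res, row) in enumerate(zip(profile.residues, profile.scores), start=1):
        cells = "".join(f"{int(v):>4d}" for v in row)
        pct = "".join(f"{0:>4d}" for _ in range(N_AMINO_ACIDS))
        buf.write(f"{i:>5d} {res}  {cells}{pct}  0.00 0.00\n")
    buf.write("\n                      K         Lambda\n")
    return buf.getvalue()


def read_pssm_file(path: str | os.PathLike, sequence_id: str | None = None) -> PSSMProfile:
    path = Path(path)
    sid = path.stem if sequence_id is None else sequence_id
    return parse_pssm(path.read_text(), sequence_id=sid)


def write_pssm_file(profile: PSSMProfile, path: str | os.PathLike) -> None:
    Path(path).write_text(write_pssm(profile))


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | os.PathLike) -> list[tuple[str, str]]:
    """Read a FASTA file into ``(sequence_id, residues)`` pairs, file order."""
    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | os.PathLike) -> None:
    seq_records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Manifest (TSV: path <tab> label)
# ---------------------------------------------------------------------------

def load_manifest(path: str | os.PathLike) -> LabeledDataset:
    """Load a two-column TSV manifest (``path``, ``label``) of PSSM files.

    Relative paths resolve against the manifest's directory.  Labels may
    be ``positive``/``negative`` or ``1``/``0``.
    """
    path = Path(path)
    base = path.parent
    profiles: list[PSSMProfile] = []
    labels: list[int] = []
    lines = path.read_text().splitlines()
    if not lines:
        raise ValueError(f"empty manifest: {path}")
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if lineno == 1 and fields[0].strip().lower() == "path":
            continue
        if len(fields) != 2:
            raise ValueError(f"{path}:{lineno}: expected 2 tab-separated fields")
        rel, label_text = fields[0].strip(), fields[1].strip().lower()
        if label_text not in _LABEL_ALIASES:
            raise ValueError(f"{path}:{lineno}: unknown label {label_text!r}")
        profile_path = base / rel
        if not profile_path.exists():
            raise FileNotFoundError(
                f"{path}:{lineno}: profile file not found: {profile_path}"
            )
        profiles.append(read_pssm_file(profile_path))
        labels.append(_LABEL_ALIASES[label_text])
    if not profiles:
        raise ValueError(f"manifest has no entries: {path}")
    return LabeledDataset(profiles, np.array(labels), {"manifest": str(path)})


def save_dataset(dataset: LabeledDataset, directory: str | os.PathLike) -> Path:
    """Write each profile as ``<id>.pssm`` plus ``manifest.tsv``; returns
    the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    lines = ["path\tlabel"]
    for i, (profile, label) in enumerate(zip(dataset.profiles, dataset.labels)):
        name = profile.sequence_id or f"profile_{i:05d}"
        filename = f"{name}.pssm"
        write_pssm_file(profile, directory / filename)
        lines.append(
            f"{filename}\t{POSITIVE_LABEL if label == 1 else NEGATIVE_LABEL}"
        )
    manifest = directory / "manifest.tsv"
    manifest.write_text("\n".join(lines) + "\n")
    return manifest
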