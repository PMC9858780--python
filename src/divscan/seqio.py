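"""FASTA input/output, sequence validation and greedy redundancy filtering.

Sequences are protein strings over the 20 canonical amino-acid letters
plus ``X``.  Coordinates are 0-based half-open throughout the package.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

from Bio import SeqIO
from .errors import FastaFormatError, ParameterError

if TYPE_CHECKING:  # pragma: no cover
    from .synth import GroundTruth

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = frozenset(AMINO_ACIDS + "X")


@dataclass
class SequenceRecord:
    """One protein sequence with identifier and optional planted ground truth."""

    id: str
    sequence: str
    description: str = ""
    truth: "GroundTruth | None" = None

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise FastaFormatError(f"invalid record id {self.id!r}")
        if not self.sequence:
            raise FastaFormatError(f"record {self.id!r} has an empty sequence")
        self.sequence = self.sequence.upper()
        for pos, letter in enumerate(self.sequence):
            if letter not in ALPHABET:
                raise FastaFormatError(
                    f"record {self.id!r}: illegal character {letter!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


def _check_unique_ids(records: Iterable[SequenceRecord]) -> None:
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise FastaFormatError(f"duplicate record id {rec.id!r}")
        seen.add(rec.id)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a multi-record FASTA file, validating ids and alphabet.

    Sequence lines are concatenated and uppercased; record order is
    preserved.  Raises :class:`FastaFormatError` for empty sequences,
    illegal characters (with position) or duplicate ids, and the usual
    I/O errors for missing files.
    """
    path = Path(path)
    records = [
        SequenceRecord(id=r.id, sequence=str(r.seq), description=r.description)
        for r in SeqIO.parse(path, "fasta")
    ]
    _check_unique_ids(records)
    return records


def write_fasta(
    records: Sequence[SequenceRecord], path: str | Path, line_width: int = 60
) -> None:
    """Write records as wrapped FASTA; round-trips exactly through read_fasta."""
    if line_width < 1:
        raise ParameterError("line_width must be a positive integer")
    with open(path, "w") as handle:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            handle.write(f">{header}\n")
            for i in range(0, len(rec.sequence), line_width):
                handle.write(rec.sequence[i : i + line_width] + "\n")


def fasta_string(records: Sequence[SequenceRecord], line_width: int = 60) -> str:
    """Render records to a FASTA-formatted string (used for determinism checks)."""
    buf = io.StringIO()
    for rec in records:
        header = rec.id if not rec.description else f"{rec.id} {rec.description}"
        buf.write(f">{header}\n")
        for i in range(0, len(rec.sequence), line_width):
            buf.write(rec.sequence[i : i + line_width] + "\n")
    return buf.getvalue()


def redundancy_filter(
    records: Sequence[SequenceRecord],
    max_identity: float = 0.80,
    min_coverage: float = 0.80,
) -> list[SequenceRecord]:
    """Greedy longest-first redundancy filter (identity/coverage thresholds).

    Candidates are visited longest first (ties broken by input order) and a
    candidate is discarded iff some already-retained sequence aligns to it
    locally with identity > ``max_identity`` over an alignment covering at
    least ``min_coverage`` of the *shorter* of the two sequences.  Identity
    is matches / alignment columns (gap columns included; ``X`` never counts
    as a match); coverage is the aligned span on the shorter sequence
    divided by its length.  The result preserves the input's relative order
    among retained records and is idempotent.
    """
    if not (0 < max_identity <= 1) or not (0 < min_coverage <= 1):
        raise ParameterError("max_identity and min_coverage must be fractions in (0, 1]")
    _check_unique_ids(records)
    from .cluster import identity_and_coverage  # deferred: avoids import cycle

    order = sorted(range(len(records)), key=lambda i: (-len(records[i]), i))
    retained_idx: list[int] = []
    for i in order:
        cand = records[i]
        redundant = False
        for j in retained_idx:
            identity, coverage = identity_and_coverage(
                records[j].sequence, cand.sequence
            )
            if identity > max_identity and coverage >= min_coverage:
                redundant = True
                break
        if not redundant:
            retained_idx.append(i)
    return [records[i] for i in sorted(retained_idx)]
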