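"""PROSITE-style bracket-pattern compilation, motif scanning and consensus.

The survey's two patterns are the core motif ``GY[DN]xx[QE]V[DN]`` and its
coiled-coil extension ``GY[DN]xx[QE]V[DN]xx[ILV]xx[ILV]``, which adds the
first two downstream hydrophobic core positions.  Patterns deliberately
start at the G: the residue preceding each hit (R in the consensus
RGYDxxEVD, but variable across clades) is reported separately.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .errors import ContractError, ParameterError, PatternSyntaxError
from .seqio import AMINO_ACIDS, SequenceRecord

#: Core motif pattern (conserved loop, consensus RGYDxxEVD without the R).
CORE_PATTERN = "GY[DN]xx[QE]V[DN]"
#: Extended pattern adding the first two hydrophobic core positions.
EXTENDED_PATTERN = "GY[DN]xx[QE]V[DN]xx[ILV]xx[ILV]"

#: Offset of the motif V (first hydrophobic core residue) from a core hit start.
V_OFFSET = 6

_VALID = set(AMINO_ACIDS)


@dataclass(frozen=True)
class MotifPattern:
    """A compiled bracket pattern: one allowed-letter set per position.

    ``None`` entries are wildcards ('x'), which are the only positions an
    ``X`` in the sequence is allowed to match.
    """

    pattern_string: str
    positions: tuple[frozenset[str] | None, ...]

    def __len__(self) -> int:
        return len(self.positions)

    def matches_at(self, sequence: str, start: int) -> bool:
        if start < 0 or start + len(self.positions) > len(sequence):
            return False
        for offset, allowed in enumerate(self.positions):
            if allowed is not None and sequence[start + offset] not in allowed:
                return False
        return True


def compile_pattern(pattern_string: str) -> MotifPattern:
    """Compile bracket notation into a position-wise allowed-set pattern.

    A letter matches itself, ``[..]`` matches any listed letter and ``x``
    matches any residue.  Raises :class:`PatternSyntaxError` with the
    offending position for unbalanced/empty brackets or illegal letters.
    """
    positions: list[frozenset[str] | None] = []
    i = 0
    n = len(pattern_string)
    while i < n:
        c = pattern_string[i]
        if c == "[":
            j = pattern_string.find("]", i + 1)
            if j < 0:
                raise PatternSyntaxError("unbalanced bracket", i)
            letters = pattern_string[i + 1 : j]
            if not letters:
                raise PatternSyntaxError("empty bracket", i)
            bad = [k for k, l in enumerate(letters) if l not in _VALID]
            if bad:
                raise PatternSyntaxError(
                    f"illegal letter {letters[bad[0]]!r} in bracket", i + 1 + bad[0]
                )
            positions.append(frozenset(letters))
            i = j + 1
        elif c == "]":
            raise PatternSyntaxError("unbalanced bracket", i)
        elif c == "x":
            positions.append(None)
            i += 1
        elif c in _VALID:
            positions.append(frozenset(c))
            i += 1
        else:
            raise PatternSyntaxError(f"illegal character {c!r}", i)
    if not positions:
        raise PatternSyntaxError("empty pattern", 0)
    return MotifPattern(pattern_string, tuple(positions))


@dataclass(frozen=True)
class MotifHit:
    """A pattern match on one record (0-based half-open coordinates)."""

    record_id: str
    start: int
    end: int
    matched_text: str
    pattern_id: str
    preceding: str  # residue immediately before the hit, "" at position 0

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.matched_text):
            raise ContractError("hit span does not match its text")


def scan_motif(
    record: SequenceRecord, pattern: MotifPattern, overlapping: bool = True
) -> list[MotifHit]:
    """All matches of ``pattern`` on ``record`` in ascending start order.

    Overlapping matches are reported by default; with
    ``overlapping=False`` scanning resumes after each match end.
    Equivalent to a brute-force sliding-window set-membership check.
    """
    seq = record.sequence
    hits: list[MotifHit] = []
    plen = len(pattern)
    start = 0
    while start <= len(seq) - plen:
        if pattern.matches_at(seq, start):
            hits.append(
                MotifHit(
                    record_id=record.id,
                    start=start,
                    end=start + plen,
                    matched_text=seq[start : start + plen],
                    pattern_id=pattern.pattern_string,
                    preceding=seq[start - 1] if start > 0 else "",
                )
            )
            start += 1 if overlapping else plen
        else:
            start += 1
    return hits


def hits_table(hits: Sequence[MotifHit]) -> pd.DataFrame:
    """Hit list as a tidy table (TSV-ready)."""
    return pd.DataFrame(
        [
            {
                "record_id": h.record_id,
                "start": h.start,
                "end": h.end,
                "pattern": h.pattern_id,
                "matched_text": h.matched_text,
                "preceding": h.preceding,
            }
            for h in hits
        ],
        columns=["record_id", "start", "end", "pattern", "matched_text", "preceding"],
    )


@dataclass
class PositionFrequencyMatrix:
    """Per-column residue counts of an alignment plus its consensus string."""

    counts: pd.DataFrame  # rows: 20 letters + '-', columns: alignment positions
    n_sequences: int
    consensus: str

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t")


def consensus_from_alignment(
    aligned: Sequence[str], majority_threshold: float = 0.5
) -> PositionFrequencyMatrix:
    """Column counts and majority consensus of an aligned set of sequences.

    Per column the consensus letter is the most frequent residue (ties
    broken alphabetically) if its frequency among non-gap residues is at
    least ``majority_threshold``, else ``x``; columns that are more than
    50% gaps emit ``.``.
    """
    if len(aligned) < 2:
        raise ContractError("need at least 2 aligned sequences")
    length = len(aligned[0])
    if any(len(s) != length for s in aligned):
        raise ContractError("aligned sequences must have equal length")
    if not (0 < majority_threshold <= 1):
        raise ParameterError("majority_threshold must be a fraction in (0, 1]")
    letters = list(AMINO_ACIDS) + ["X", "-"]
    n = len(aligned)
    columns = []
    consensus_chars = []
    for pos in range(length):
        col = Counter(s[pos].upper() for s in aligned)
        counts = {l: col.get(l, 0) for l in letters}
        columns.append(counts)
        gaps = counts["-"]
        non_gap = n - gaps
        if gaps > n / 2 or non_gap == 0:
            consensus_chars.append(".")
            continue
        best = max(
            (l for l in AMINO_ACIDS), key=lambda l: (counts[l], -ord(l))
        )
        if counts[best] / non_gap >= majority_threshold:
            consensus_chars.append(best)
        else:
            consensus_chars.append("x")
    frame = pd.DataFrame(columns, index=range(length)).T
    frame.index.name = "letter"
    return PositionFrequencyMatrix(frame, n, "".join(consensus_chars))
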