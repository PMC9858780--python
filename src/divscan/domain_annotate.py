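"""DivIVA-like domain calling and architecture classification.

A DivIVA-like domain is the conserved motif in the context of a heptad
coiled coil: a core-pattern hit qualifies when its V — the first residue
of the coil's hydrophobic core — is the start of (or lies just upstream
of) a heptad-classified segment of sufficient length.  Architectures are
classified by domain count and downstream rod composition:

* PolyDIV — 2 to 8 tandem domains;
* FilP/Scy-like — one domain followed by a long hendecad rod;
* DivIVA/GpsB-like — one domain without such a rod;
* unclassified — no domains (or more than 8).
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .errors import ContractError
from .motif_scan import V_OFFSET, MotifHit
from .repeat_scan import RepeatAnnotation
from .seqio import SequenceRecord


@dataclass
class DomainCall:
    """One called DivIVA-like domain: motif hit plus its coiled coil."""

    record_id: str
    motif: MotifHit
    segment: RepeatAnnotation
    start: int  # motif start
    end: int  # coiled-coil end (possibly truncated at the next motif)
    preceding_residue: str

    def __post_init__(self) -> None:
        if self.segment.repeat_class != "heptad":
            raise ContractError("domain coiled coils must be heptad-classified")


def call_domains(
    record: SequenceRecord,
    hits: Sequence[MotifHit],
    annotations: Sequence[RepeatAnnotation],
    max_gap: int = 5,
    min_cc_length: int = 14,
) -> list[DomainCall]:
    """Emit one domain call per motif hit anchored to a heptad coil.

    A hit qualifies when some heptad segment starts no later than
    ``max_gap`` residues after the hit's V position (segments may begin
    earlier — the coil physically starts within the motif) and extends at
    least ``min_cc_length`` residues beyond the V.  Hits with overlapping
    motif intervals are deduplicated keeping the earliest; call intervals
    are truncated at the next call's motif so they never overlap.
    """
    heptads = sorted(
        (a for a in annotations if a.repeat_class == "heptad"),
        key=lambda a: (a.start, a.end),
    )
    calls: list[DomainCall] = []
    for hit in sorted(hits, key=lambda h: h.start):
        if calls and hit.start < calls[-1].motif.end:
            continue  # overlapping motif: keep the earliest
        v_pos = hit.start + V_OFFSET
        for seg in heptads:
            if seg.start <= v_pos + max_gap and seg.end - v_pos >= min_cc_length:
                calls.append(
                    DomainCall(
                        record_id=record.id,
                        motif=hit,
                        segment=seg,
                        start=hit.start,
                        end=seg.end,
                        preceding_residue=hit.preceding,
                    )
                )
                break
    for i in range(len(calls) - 1):
        calls[i].end = min(calls[i].end, calls[i + 1].start)
    return calls


@dataclass
class DomainArchitecture:
    """Ordered domain calls on one record plus linkers and family label."""

    record_id: str
    calls: list[DomainCall]
    linker_lengths: list[int]
    downstream_rod: list[tuple[str, int]]  # (repeat class, residues) after last domain
    family: str = "unclassified"

    @property
    def n_domains(self) -> int:
        return len(self.calls)

    def downstream_residues(self, repeat_class: str) -> int:
        return sum(n for name, n in self.downstream_rod if name == repeat_class)


def build_architecture(
    record: SequenceRecord,
    calls: Sequence[DomainCall],
    annotations: Sequence[RepeatAnnotation],
) -> DomainArchitecture:
    """Assemble calls into an architecture with linkers and rod composition."""
    calls = sorted(calls, key=lambda c: c.start)
    for a, b in zip(calls, calls[1:]):
        if b.start < a.end:
            raise ContractError("overlapping domain calls")
    linkers = [b.start - a.end for a, b in zip(calls, calls[1:])]
    boundary = calls[-1].end if calls else 0
    rod: list[tuple[str, int]] = []
    for ann in sorted(annotations, key=lambda a: (a.start, a.end)):
        if ann.repeat_class == "none":
            continue
        residues = max(0, ann.end - max(ann.start, boundary))
        if residues > 0:
            rod.append((ann.repeat_class, residues))
    return DomainArchitecture(
        record_id=record.id,
        calls=list(calls),
        linker_lengths=linkers,
        downstream_rod=rod,
    )


def classify_family(
    arch: DomainArchitecture, hendecad_rod_min: int = 50
) -> str:
    """Family label from domain count and downstream rod composition."""
    n = arch.n_domains
    if 2 <= n <= 8:
        family = "PolyDIV"
    elif n == 1:
        if arch.downstream_residues("hendecad") >= hendecad_rod_min:
            family = "FilP_Scy_like"
        else:
            family = "DivIVA_GpsB_like"
    else:
        family = "unclassified"
    arch.family = family
    return family


@dataclass(frozen=True)
class LinkerPairing:
    """Median within-pair vs between-pair linker lengths of a PolyDIV chain."""

    within_pair_median: float
    between_pair_median: float
    ratio: float
    paired: bool


def linker_pairing_statistic(arch: DomainArchitecture) -> LinkerPairing | None:
    """Paired-linker statistic: are within-pair connectors the shorter ones?

    Domains are paired (1,2), (3,4), ...; with 1-based linker indices the
    within-pair linkers are the odd ones and the between-pair linkers the
    even ones.  Defined only for even domain counts of at least 4;
    returns None otherwise.
    """
    n = arch.n_domains
    if n < 4 or n % 2 != 0:
        return None
    within = arch.linker_lengths[0::2]
    between = arch.linker_lengths[1::2]
    within_median = statistics.median(within)
    between_median = statistics.median(between)
    if between_median > 0:
        ratio = within_median / between_median
    else:
        ratio = float("inf") if within_median > 0 else float("nan")
    return LinkerPairing(
        within_pair_median=float(within_median),
        between_pair_median=float(between_median),
        ratio=float(ratio),
        paired=bool(ratio < 1),
    )


def calls_table(calls: Sequence[DomainCall]) -> pd.DataFrame:
    """Domain calls as a BED-like table."""
    return pd.DataFrame(
        [
            {
                "record_id": c.record_id,
                "start": c.start,
                "end": c.end,
                "name": "DivIVA_like",
                "score": c.segment.spectral_power,
                "preceding": c.preceding_residue,
            }
            for c in calls
        ],
        columns=["record_id", "start", "end", "name", "score", "preceding"],
    )


def architectures_table(archs: Sequence[DomainArchitecture]) -> pd.DataFrame:
    """Architecture summaries as a tidy table."""
    return pd.DataFrame(
        [
            {
                "record_id": a.record_id,
                "n_domains": a.n_domains,
                "linkers": ",".join(str(l) for l in a.linker_lengths),
                "family": a.family,
                "rod": ",".join(f"{name}:{n}" for name, n in a.downstream_rod),
            }
            for a in archs
        ],
        columns=["record_id", "n_domains", "linkers", "family", "rod"],
    )
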