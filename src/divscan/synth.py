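"""Synthetic protein sequences with planted DivIVA-like features.

The generator emulates the sequence families surveyed by the pipeline:

* DivIVA/GpsB-like — short N-terminal buttressing helix, the conserved
  motif (consensus RGYDxxEVD) and a heptad coiled coil;
* FilP-like — the same domain followed by a long hendecad rod with an
  alanine-enriched core;
* Scy-like — a FilP-like rod but N-terminally truncated: the sequence
  starts right before the RGYD motif (no buttressing helix);
* PolyDIV — 2-8 tandem copies of the domain, with within-pair linkers
  shorter than between-pair linkers;
* background — unrelated sequences at natural amino-acid frequencies.

Every record carries full ground truth (motif, domain and repeat-segment
intervals, register phases, linker lengths), and generation is fully
deterministic in the seed.  Within repeat segments and linkers the only
hydrophobic residues are the planted core positions: non-core and linker
residues are drawn from polar residues excluding alanine, so the binary
hydropathy signal reflects exactly the planted periodicity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ContractError, ParameterError
from .motif_scan import CORE_PATTERN, compile_pattern
from .repeats import HEPTAD, REPEAT_CLASSES, RepeatClass
from .seqio import SequenceRecord, write_fasta

FAMILIES = (
    "DivIVA_like",
    "GpsB_like",
    "FilP_like",
    "Scy_like",
    "PolyDIV",
    "background",
)

#: Hydrophobic residues used at coiled-coil core positions.
CORE_RESIDUES = "LIVM"
#: Polar residues for non-core and linker positions.  Alanine is excluded
#: so that planted core positions are the only hydrophobic signal.
POLAR_RESIDUES = "DEGKNQRST"

#: Approximate natural amino-acid background frequencies (Robinson-Robinson).
NATURAL_FREQUENCIES = {
    "A": 0.078, "R": 0.051, "N": 0.045, "D": 0.054, "C": 0.019,
    "Q": 0.043, "E": 0.063, "G": 0.074, "H": 0.022, "I": 0.051,
    "L": 0.090, "K": 0.057, "M": 0.022, "F": 0.039, "P": 0.052,
    "S": 0.071, "T": 0.058, "W": 0.013, "Y": 0.032, "V": 0.064,
}

_CORE_COMPILED = compile_pattern(CORE_PATTERN)
#: Phase of the coiled-coil helix at the motif's E (register c): the motif
#: V is then the first hydrophobic core residue, on register d, and the
#: extended pattern's [ILV] positions fall on the following a and d cores.
_CC_START_PHASE = 2


@dataclass
class GroundTruth:
    """Planted annotations for one synthetic record (0-based half-open)."""

    family: str
    motif_intervals: list[tuple[int, int]] = field(default_factory=list)
    domain_intervals: list[tuple[int, int]] = field(default_factory=list)
    segments: list[tuple[int, int, str, int]] = field(default_factory=list)
    linker_lengths: list[int] = field(default_factory=list)
    core_ala_fraction: float = 0.0

    @property
    def n_domains(self) -> int:
        return len(self.domain_intervals)

    def validate(self, sequence_length: int) -> None:
        for intervals in (self.motif_intervals, self.domain_intervals):
            prev_end = 0
            for start, end in intervals:
                if not (0 <= start < end <= sequence_length):
                    raise ContractError(f"interval ({start}, {end}) out of bounds")
                if start < prev_end:
                    raise ContractError("intervals must be disjoint and sorted")
                prev_end = end


@dataclass
class ArchitectureSpec:
    """Parameters for one synthetic record."""

    family: str
    n_domains: int = 1
    cc_repeats: int = 4
    rod_length: int = 0
    rod_class: str = "heptad"
    core_ala_fraction: float = 0.0
    within_pair_linker: tuple[int, int] = (5, 15)
    between_pair_linker: tuple[int, int] = (25, 60)
    include_buttressing_helix: bool = True
    length: int = 300  # background records only
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ParameterError(f"unknown family {self.family!r}")
        if self.family == "PolyDIV":
            if not (2 <= self.n_domains <= 8):
                raise ParameterError("PolyDIV requires 2 <= n_domains <= 8")
        elif self.family == "background":
            if self.length < 20:
                raise ParameterError("background length must be >= 20")
        elif self.n_domains != 1:
            raise ParameterError(f"{self.family} requires n_domains = 1")
        if self.family == "Scy_like" and self.include_buttressing_helix:
            raise ParameterError("Scy-like records have no buttressing helix")
        if self.rod_class not in REPEAT_CLASSES:
            raise ParameterError(f"unknown rod class {self.rod_class!r}")
        if not (0 <= self.core_ala_fraction <= 1):
            raise ParameterError("core_ala_fraction must be a fraction")

    @classmethod
    def for_family(cls, family: str, **overrides) -> "ArchitectureSpec":
        """Family presets reflecting the surveyed architectures."""
        presets: dict[str, dict] = {
            "DivIVA_like": dict(rod_length=42, rod_class="heptad"),
            "GpsB_like": dict(rod_length=21, rod_class="heptad"),
            "FilP_like": dict(
                cc_repeats=8, rod_length=121, rod_class="hendecad",
                core_ala_fraction=0.35,
            ),
            "Scy_like": dict(
                cc_repeats=8, rod_length=165, rod_class="hendecad",
                core_ala_fraction=0.35, include_buttressing_helix=False,
            ),
            "PolyDIV": dict(n_domains=4, include_buttressing_helix=False),
            "background": dict(include_buttressing_helix=False),
        }
        kwargs = presets[family] | overrides
        return cls(family=family, **kwargs)


def _choice(rng: np.random.Generator, letters: str) -> str:
    return letters[int(rng.integers(len(letters)))]


def _polar_string(rng: np.random.Generator, n: int) -> str:
    return "".join(_choice(rng, POLAR_RESIDUES) for _ in range(n))


def generate_repeat_segment(
    rc: RepeatClass,
    n_repeats: int,
    core_ala_fraction: float = 0.0,
    rng: np.random.Generator | int | None = None,
    phase: int = 0,
) -> tuple[str, str]:
    """One ideal coiled-coil repeat segment plus its register string.

    Core positions carry residues from {L,I,V,M}, except a fraction
    ``core_ala_fraction`` replaced by alanine (hendecad h positions
    preferentially, mirroring knobs-to-knobs packing); all other positions
    are polar.  ``phase`` rotates the register labels so the segment can
    start mid-repeat.  Deterministic for a fixed seed.
    """
    if n_repeats < 2:
        raise ParameterError("n_repeats must be >= 2")
    if not (0 <= core_ala_fraction <= 1):
        raise ParameterError("core_ala_fraction must be a fraction")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    length = n_repeats * rc.repeat_length
    labels = [rc.position_labels[(phase + i) % rc.repeat_length] for i in range(length)]
    core_idx = [i for i, l in enumerate(labels) if l in rc.core_labels]
    letters = [
        _choice(rng, CORE_RESIDUES) if l in rc.core_labels else _choice(rng, POLAR_RESIDUES)
        for l in labels
    ]
    n_ala = int(round(core_ala_fraction * len(core_idx)))
    if n_ala:
        preferred = [i for i in core_idx if labels[i] == "h"]
        others = [i for i in core_idx if labels[i] != "h"]
        rng.shuffle(preferred)
        rng.shuffle(others)
        for i in (preferred + others)[:n_ala]:
            letters[i] = "A"
    return "".join(letters), "".join(labels)


@dataclass
class DomainUnit:
    """One generated DivIVA-like domain with its internal coordinates."""

    sequence: str
    motif_start: int  # position of the pattern G
    motif_end: int
    cc_start: int  # position of the motif E (register c)
    cc_end: int
    register_phase: int = _CC_START_PHASE

    @property
    def v_position(self) -> int:
        return self.motif_start + 6


def generate_divlike_domain(
    rng: np.random.Generator | int | None = None,
    motif_consensus: str = "RGYDxxEVD",
    cc_repeats: int = 4,
    include_buttress: bool = True,
) -> DomainUnit:
    """A buttressing helix (optional), the conserved motif, and a heptad coil.

    The coiled coil is phased so the motif's V is its first hydrophobic
    core residue (register d); the two following core positions are drawn
    from {I,L,V} so the emitted domain always matches the extended
    pattern at the planted anchor.  Motif x positions are polar,
    rejection-sampled so the core pattern matches exactly once.
    """
    if cc_repeats < 2:
        raise ParameterError("cc_repeats must be >= 2 (domain requires a coiled coil)")
    _validate_consensus(motif_consensus)
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    butt_len = int(rng.integers(8, 13)) if include_buttress else 0
    for _ in range(100):
        buttress = _polar_string(rng, butt_len)
        preceding = motif_consensus[0]
        head = "".join(
            _choice(rng, POLAR_RESIDUES) if c == "x" else c
            for c in motif_consensus[1:6]
        )
        cc_seq, _ = generate_repeat_segment(
            HEPTAD, cc_repeats, 0.0, rng, phase=_CC_START_PHASE
        )
        cc = list(cc_seq)
        cc[0:3] = motif_consensus[6], motif_consensus[7], motif_consensus[8]
        cc[5] = _choice(rng, "ILV")  # register a, extended-pattern position
        cc[8] = _choice(rng, "ILV")  # register d, extended-pattern position
        sequence = buttress + preceding + head + "".join(cc)
        anchors = [
            i for i in range(len(sequence)) if _CORE_COMPILED.matches_at(sequence, i)
        ]
        if anchors == [butt_len + 1]:
            motif_start = butt_len + 1
            return DomainUnit(
                sequence=sequence,
                motif_start=motif_start,
                motif_end=motif_start + 8,
                cc_start=motif_start + 5,
                cc_end=motif_start + 5 + cc_repeats * HEPTAD.repeat_length,
            )
    raise ContractError("could not generate a clean domain in 100 attempts")


def _validate_consensus(consensus: str) -> None:
    if len(consensus) != 9:
        raise ParameterError("motif consensus must have 9 positions (R + core)")
    for offset, allowed in enumerate(_CORE_COMPILED.positions):
        c = consensus[1 + offset]
        if c == "x":
            if allowed is not None:
                raise ParameterError(
                    f"consensus wildcard at fixed pattern position {offset}"
                )
        elif allowed is not None and c not in allowed:
            raise ParameterError(
                f"consensus letter {c!r} incompatible with core pattern at {offset}"
            )


def generate_architecture(
    spec: ArchitectureSpec,
    rng: np.random.Generator | int | None = None,
    record_id: str = "synthetic",
) -> SequenceRecord:
    """One synthetic record assembled per its architecture spec."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    elif not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if spec.family == "background":
        return _generate_background(spec, rng, record_id)
    for _ in range(50):
        record = _assemble(spec, rng, record_id)
        anchors = [
            i
            for i in range(len(record.sequence))
            if _CORE_COMPILED.matches_at(record.sequence, i)
        ]
        if anchors == [s for s, _ in record.truth.motif_intervals]:
            return record
    raise ContractError("could not assemble a clean architecture in 50 attempts")


def _assemble(
    spec: ArchitectureSpec, rng: np.random.Generator, record_id: str
) -> SequenceRecord:
    truth = GroundTruth(family=spec.family, core_ala_fraction=spec.core_ala_fraction)
    parts: list[str] = []
    pos = 0
    if spec.family == "PolyDIV":
        leader = _polar_string(rng, int(rng.integers(3, 9)))
        parts.append(leader)
        pos += len(leader)
    for d in range(spec.n_domains):
        if d > 0:
            lo, hi = (
                spec.within_pair_linker if d % 2 == 1 else spec.between_pair_linker
            )
            linker = _polar_string(rng, int(rng.integers(lo, hi + 1)))
            parts.append(linker)
            truth.linker_lengths.append(len(linker))
            pos += len(linker)
        domain = generate_divlike_domain(
            rng,
            cc_repeats=spec.cc_repeats,
            include_buttress=spec.include_buttressing_helix and d == 0,
        )
        parts.append(domain.sequence)
        truth.motif_intervals.append(
            (pos + domain.motif_start, pos + domain.motif_end)
        )
        truth.domain_intervals.append((pos + domain.motif_start, pos + domain.cc_end))
        truth.segments.append(
            (pos + domain.cc_start, pos + domain.cc_end, "heptad", _CC_START_PHASE)
        )
        pos += len(domain.sequence)
    rc = REPEAT_CLASSES[spec.rod_class]
    n_rep = spec.rod_length // rc.repeat_length
    if n_rep >= 2:
        if spec.rod_class == "heptad":
            # continue the domain helix in phase
            cc_len = spec.cc_repeats * 7
            phase = (_CC_START_PHASE + cc_len) % 7
        else:
            phase = 0
        rod, _ = generate_repeat_segment(
            rc, n_rep, spec.core_ala_fraction, rng, phase=phase
        )
        truth.segments.append((pos, pos + len(rod), spec.rod_class, phase))
        parts.append(rod)
        pos += len(rod)
    parts.append(_polar_string(rng, int(rng.integers(3, 9))))
    sequence = "".join(parts)
    truth.validate(len(sequence))
    return SequenceRecord(
        id=record_id, sequence=sequence, description=spec.family, truth=truth
    )


def _generate_background(
    spec: ArchitectureSpec, rng: np.random.Generator, record_id: str
) -> SequenceRecord:
    letters = np.array(list(NATURAL_FREQUENCIES))
    probs = np.array(list(NATURAL_FREQUENCIES.values()))
    probs = probs / probs.sum()
    for _ in range(200):
        sequence = "".join(rng.choice(letters, size=spec.length, p=probs))
        if not any(
            _CORE_COMPILED.matches_at(sequence, i) for i in range(len(sequence))
        ):
            return SequenceRecord(
                id=record_id,
                sequence=sequence,
                description="background",
                truth=GroundTruth(family="background"),
            )
    raise ContractError("could not generate a motif-free background sequence")


def graft_domains(
    scaffold: SequenceRecord, donor: "DomainUnit | str"
) -> SequenceRecord:
    """Replace every domain of a PolyDIV scaffold with a donor domain.

    Mirrors the construction of artificial multi-domain chimeras: linker
    residues are untouched, the domain count is preserved and the ground
    truth is re-indexed for the donor's length.  The donor sequence must
    begin at its pattern G (a plain string is interpreted that way).
    """
    truth = scaffold.truth
    if truth is None or len(truth.domain_intervals) < 2:
        raise ContractError("scaffold must carry >= 2 annotated domains")
    if isinstance(donor, DomainUnit):
        donor_seq = donor.sequence[donor.motif_start : donor.cc_end]
        cc_offset = donor.cc_start - donor.motif_start
    else:
        donor_seq = str(donor)
        cc_offset = 5
    new_truth = GroundTruth(
        family=truth.family, core_ala_fraction=truth.core_ala_fraction
    )
    new_parts: list[str] = []
    cursor = 0
    offset = 0
    rod_segments = [
        seg
        for seg in truth.segments
        if not any(s <= seg[0] < e for s, e in truth.domain_intervals)
    ]
    for start, end in truth.domain_intervals:
        new_parts.append(scaffold.sequence[cursor:start])
        new_start = start + offset
        new_parts.append(donor_seq)
        new_truth.motif_intervals.append((new_start, new_start + 8))
        new_truth.domain_intervals.append((new_start, new_start + len(donor_seq)))
        new_truth.segments.append(
            (new_start + cc_offset, new_start + len(donor_seq), "heptad", _CC_START_PHASE)
        )
        offset += len(donor_seq) - (end - start)
        cursor = end
    new_parts.append(scaffold.sequence[cursor:])
    for start, end, name, phase in rod_segments:
        new_truth.segments.append((start + offset, end + offset, name, phase))
    new_truth.linker_lengths = list(truth.linker_lengths)
    sequence = "".join(new_parts)
    new_truth.validate(len(sequence))
    return SequenceRecord(
        id=f"{scaffold.id}_graft",
        sequence=sequence,
        description=f"{scaffold.description} grafted",
        truth=new_truth,
    )


def generate_dataset(
    specs: list[ArchitectureSpec], seed: int
) -> list[SequenceRecord]:
    """One record per spec, with per-record RNG streams derived from the seed.

    Record ids are ``<family>_<index>``; identical seeds yield identical
    datasets byte for byte.
    """
    if not specs:
        raise ParameterError("need at least one spec")
    records = []
    for idx, spec in enumerate(specs):
        rng = np.random.default_rng([seed, idx])
        records.append(
            generate_architecture(spec, rng, record_id=f"{spec.family}_{idx:03d}")
        )
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ContractError("duplicate record ids in dataset")
    return records


def truth_table(records: list[SequenceRecord]) -> pd.DataFrame:
    """Planted features as a tidy table: one row per feature."""
    rows = []
    for rec in records:
        truth = rec.truth
        if truth is None:
            continue
        rows.append(
            {
                "record_id": rec.id, "feature": "family", "start": 0,
                "end": len(rec.sequence), "label": truth.family, "phase": "",
            }
        )
        for start, end in truth.motif_intervals:
            rows.append(
                {
                    "record_id": rec.id, "feature": "motif", "start": start,
                    "end": end, "label": CORE_PATTERN, "phase": "",
                }
            )
        for start, end in truth.domain_intervals:
            rows.append(
                {
                    "record_id": rec.id, "feature": "domain", "start": start,
                    "end": end, "label": "DivIVA_like", "phase": "",
                }
            )
        for start, end, name, phase in truth.segments:
            rows.append(
                {
                    "record_id": rec.id, "feature": "segment", "start": start,
                    "end": end, "label": name, "phase": phase,
                }
            )
    return pd.DataFrame(
        rows, columns=["record_id", "feature", "start", "end", "label", "phase"]
    )


def write_dataset(
    records: list[SequenceRecord], fasta_path: str | Path, truth_path: str | Path
) -> None:
    """Write a generated dataset as FASTA plus a tab-separated truth table."""
    write_fasta(records, fasta_path)
    truth_table(records).to_csv(truth_path, sep="\t", index=False)


def generate_sequence_families(
    n_families: int,
    members: int,
    length: int = 300,
    mutation_rate: float = 0.10,
    seed: int = 0,
) -> tuple[list[SequenceRecord], dict[str, str]]:
    """Mutated-copy sequence families for clustering validation.

    Each family is an independent random base sequence at natural
    amino-acid frequencies; members are copies with ``mutation_rate`` of
    positions substituted.  Within-family similarity is therefore far
    above chance while between-family similarity is random.  Returns the
    records and a record-id -> family-label map.
    """
    rng = np.random.default_rng(seed)
    letters = np.array(list(NATURAL_FREQUENCIES))
    probs = np.array(list(NATURAL_FREQUENCIES.values()))
    probs = probs / probs.sum()
    records: list[SequenceRecord] = []
    labels: dict[str, str] = {}
    for f in range(n_families):
        base = rng.choice(letters, size=length, p=probs)
        for m in range(members):
            member = base.copy()
            mutate = rng.random(length) < mutation_rate
            member[mutate] = rng.choice(letters, size=int(mutate.sum()), p=probs)
            rec_id = f"fam{f}_m{m}"
            records.append(SequenceRecord(id=rec_id, sequence="".join(member)))
            labels[rec_id] = f"fam{f}"
    return records, labels
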