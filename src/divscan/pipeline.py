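"""End-to-end survey orchestration.

``run_survey`` wires the full chain — redundancy filter, motif scan with
the core and extended patterns, periodicity annotation, domain calling,
architecture classification, similarity clustering and the >=50%
extended-pattern cluster filter — and writes per-stage TSV tables plus a
single deterministic JSON summary.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from .cluster import (
    all_pairs_scores,
    build_graph,
    filter_divlike_clusters,
    girvan_newman,
)
from .domain_annotate import (
    architectures_table,
    build_architecture,
    call_domains,
    calls_table,
    classify_family,
    linker_pairing_statistic,
)
from .errors import ParameterError
from .motif_scan import (
    CORE_PATTERN,
    EXTENDED_PATTERN,
    compile_pattern,
    hits_table,
    scan_motif,
)
from .repeat_scan import annotate_repeats, segments_table
from .seqio import read_fasta, redundancy_filter, write_fasta
from .synth import ArchitectureSpec, generate_dataset, truth_table

logger = logging.getLogger("divscan")

#: Default number of records per family in the bundled demo simulation.
DEMO_FAMILY_COUNTS = {
    "DivIVA_like": 15,
    "FilP_like": 15,
    "PolyDIV": 15,
    "background": 15,
}


@dataclass
class SurveyConfig:
    """All survey parameters with their documented defaults.

    The redundancy (80%/80%), graph threshold (1e-15) and cluster filter
    (at least half) defaults are the survey's standard operating points.
    """

    input_fasta: str | None = None  # mutually exclusive with simulate
    simulate: dict[str, int] | None = None  # family -> record count
    seed: int = 0
    core_pattern: str = CORE_PATTERN
    extended_pattern: str = EXTENDED_PATTERN
    window: int = 25
    scale: str = "binary_hydrophobic"
    min_power: float = 0.2
    max_gap: int = 5
    min_cc_length: int = 14
    matrix: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    threshold: float = 1e-15
    min_fraction: float = 0.5
    max_identity: float = 0.80
    min_coverage: float = 0.80
    apply_redundancy_filter: bool = True
    hendecad_rod_min: int = 50
    log_level: str = "INFO"

    @classmethod
    def demo(cls, seed: int = 0) -> "SurveyConfig":
        return cls(simulate=dict(DEMO_FAMILY_COUNTS), seed=seed)

    @classmethod
    def from_file(cls, path: str | Path) -> "SurveyConfig":
        """Parse a flat ``key = value`` config file (``#`` comments allowed)."""
        values: dict[str, object] = {}
        fields = {f.name: f for f in dataclasses.fields(cls)}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ParameterError(f"{path}:{lineno}: expected 'key = value'")
            key, _, value = (s.strip() for s in line.partition("="))
            if key.startswith("simulate."):
                values.setdefault("simulate", {})[key.split(".", 1)[1]] = int(value)  # type: ignore[union-attr]
                continue
            if key not in fields:
                raise ParameterError(f"{path}:{lineno}: unknown key {key!r}")
            ftype = fields[key].type
            if ftype in ("int", int):
                values[key] = int(value)
            elif ftype in ("float", float):
                values[key] = float(value)
            elif ftype in ("bool", bool):
                values[key] = value.lower() in ("1", "true", "yes")
            else:
                values[key] = value
        return cls(**values)  # type: ignore[arg-type]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _simulate_records(config: SurveyConfig):
    specs = []
    for family in sorted(config.simulate or {}):
        for _ in range(config.simulate[family]):
            specs.append(ArchitectureSpec.for_family(family))
    return generate_dataset(specs, config.seed)


def run_survey(config: SurveyConfig, outdir: str | Path) -> dict:
    """Run the full survey and write its result bundle to ``outdir``.

    Returns the JSON summary as a dict.  Identical config and seed yield
    a byte-identical ``summary.json``.
    """
    logging.basicConfig(level=config.log_level)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages: list[tuple[str, float]] = []

    def _stage(name: str, t0: float) -> None:
        stages.append((name, time.perf_counter() - t0))
        logger.info("stage %s finished in %.2fs", name, stages[-1][1])

    t0 = time.perf_counter()
    if config.input_fasta is not None and config.simulate:
        raise ParameterError("config must set input_fasta or simulate, not both")
    if config.input_fasta is not None:
        records = read_fasta(config.input_fasta)
    elif config.simulate:
        records = _simulate_records(config)
        truth_table(records).to_csv(outdir / "truth.tsv", sep="\t", index=False)
    else:
        raise ParameterError("config must set input_fasta or simulate")
    _stage("load", t0)

    t0 = time.perf_counter()
    if config.apply_redundancy_filter:
        records = redundancy_filter(records, config.max_identity, config.min_coverage)
    write_fasta(records, outdir / "filtered.fasta")
    _stage("redundancy_filter", t0)

    t0 = time.perf_counter()
    core = compile_pattern(config.core_pattern)
    extended = compile_pattern(config.extended_pattern)
    core_hits = {rec.id: scan_motif(rec, core) for rec in records}
    extended_hits = {rec.id: scan_motif(rec, extended) for rec in records}
    hits_table(
        [h for rec in records for h in core_hits[rec.id] + extended_hits[rec.id]]
    ).to_csv(outdir / "motif_hits.tsv", sep="\t", index=False)
    _stage("motif_scan", t0)

    t0 = time.perf_counter()
    annotations = {
        rec.id: annotate_repeats(
            rec, window=config.window, min_power=config.min_power, scale=config.scale
        )
        for rec in records
    }
    segments_table([a for rec in records for a in annotations[rec.id]]).to_csv(
        outdir / "repeat_segments.tsv", sep="\t", index=False
    )
    _stage("repeat_scan", t0)

    t0 = time.perf_counter()
    all_calls = []
    archs = []
    pairings = {}
    for rec in records:
        calls = call_domains(
            rec,
            core_hits[rec.id],
            annotations[rec.id],
            max_gap=config.max_gap,
            min_cc_length=config.min_cc_length,
        )
        all_calls.extend(calls)
        arch = build_architecture(rec, calls, annotations[rec.id])
        classify_family(arch, hendecad_rod_min=config.hendecad_rod_min)
        archs.append(arch)
        pairing = linker_pairing_statistic(arch)
        if pairing is not None:
            pairings[rec.id] = pairing
    calls_table(all_calls).to_csv(outdir / "domain_calls.tsv", sep="\t", index=False)
    architectures_table(archs).to_csv(
        outdir / "architectures.tsv", sep="\t", index=False
    )
    _stage("domain_annotate", t0)

    t0 = time.perf_counter()
    edges = all_pairs_scores(records, config.matrix, config.gap_open, config.gap_extend)
    graph = build_graph(records, edges, config.threshold)
    partition = girvan_newman(graph)
    hit_status = {rec.id: bool(extended_hits[rec.id]) for rec in records}
    selected, fractions = filter_divlike_clusters(
        partition, hit_status, config.min_fraction
    )
    with open(outdir / "edges.tsv", "w") as handle:
        handle.write("id_a\tid_b\tscore\tbit_score\tp_value\n")
        for edge in edges:
            handle.write(
                f"{edge.pair[0]}\t{edge.pair[1]}\t{edge.score:.1f}"
                f"\t{edge.bit_score:.2f}\t{edge.p_value:.3e}\n"
            )
    with open(outdir / "partition.tsv", "w") as handle:
        handle.write("record_id\tcluster\n")
        for rec in records:
            handle.write(f"{rec.id}\t{partition.assignment[rec.id]}\n")
    with open(outdir / "clusters.tsv", "w") as handle:
        handle.write("cluster\tsize\textended_fraction\tselected\n")
        sizes: dict[int, int] = {}
        for idx in partition.assignment.values():
            sizes[idx] = sizes.get(idx, 0) + 1
        for idx in sorted(fractions):
            handle.write(
                f"{idx}\t{sizes[idx]}\t{fractions[idx]:.3f}\t{idx in selected}\n"
            )
    _stage("cluster", t0)

    from . import __version__

    family_counts: dict[str, int] = {}
    for arch in archs:
        family_counts[arch.family] = family_counts.get(arch.family, 0) + 1
    summary = {
        "n_records": len(records),
        "family_counts": dict(sorted(family_counts.items())),
        "n_core_hits": sum(len(h) for h in core_hits.values()),
        "n_extended_hits": sum(len(h) for h in extended_hits.values()),
        "n_clusters": partition.n_clusters,
        "modularity": round(partition.modularity, 6),
        "selected_clusters": selected,
        "cluster_fractions": {str(k): round(v, 4) for k, v in sorted(fractions.items())},
        "paired_linker_records": {
            rid: {"ratio": round(p.ratio, 4), "paired": p.paired}
            for rid, p in sorted(pairings.items())
        },
        "parameters": config.to_dict(),
        "seed": config.seed,
        "version": __version__,
    }
    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )
    return summary
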