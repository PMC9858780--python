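# Methods

This note documents the models, defaults and design choices behind
`divscan`, in the order the pipeline runs.

## Sequence model and coordinates

Sequences are strings over the 20 canonical amino acids plus `X`.  All
coordinates are 0-based half-open.  `X` is treated conservatively
throughout: it matches only wildcard pattern positions, never counts as an
identity in alignments, and scores 0 on the binary hydropathy scale.

## Synthetic data: what it emulates, and what it does not

The generator produces the five surveyed architectures plus unrelated
background sequences, with complete ground truth (motif, domain and
repeat-segment intervals, register phases, linker lengths).

**Domain construction.**  A DivIVA-like domain is emitted as an optional
8–12-residue polar buttressing helix, the preceding R, the motif
`GYDxx` and a heptad coiled coil that begins with `EVD` — the E on
register *c*, so the motif V is the coil's first hydrophobic core residue
on register *d*.  With the V on *d*, the next two core positions fall 4
and 7 residues downstream, exactly the `[ILV]` positions of the extended
pattern; those two positions are drawn from {I,L,V} so every generated
domain matches the extended pattern at its planted anchor.  (Phasing the V
to register *a* instead would put the pattern's first `[ILV]` on the
non-core *e* position and break that guarantee; the 4–3 spacing encoded in
the pattern itself fixes the register.)

**Alphabet choices.**  Core positions use {L,I,V,M}; a configurable
fraction is replaced by alanine (hendecad *h* positions preferentially,
mirroring knobs-to-knobs packing; FilP/Scy rods default to 0.35 — the
published observation is only qualitative, "alanine-rich").  Non-core and
linker positions are drawn uniformly from the polar set {D,E,G,K,N,Q,R,S,T}.
Alanine is deliberately excluded from this set even though it is common in
real linkers: alanine is hydrophobic on the binary scale, and keeping it
out of non-core positions makes the planted periodicity the *only*
hydrophobic signal.  This is the main idealization of the generator —
real sequences carry hydrophobic noise in linkers and imperfect cores, so
the 100% recovery rates demonstrated on synthetic data bound what the
pipeline can do, not what it achieves on natural proteins.

**Family presets.**  DivIVA-like: 4-heptad domain coil + 42-residue heptad
rod; GpsB-like: the same with a 21-residue rod; FilP-like: 8-heptad domain
coil + 121-residue hendecad rod (FilP's N-terminal heptads preceded the
hendecad expansion, and the longer coil also makes the heptad region
resolvable by a window that must otherwise straddle the hendecad rod);
Scy-like: as FilP with a 165-residue rod and no buttressing helix — the
sequence starts at the R of the motif; PolyDIV: 2–8 tandem domains
(default 4) with within-pair linkers of 5–15 and between-pair linkers of
25–60 residues (the source observation is only the ordering
"within shorter than between"; the disjoint ranges make the paired-linker
statistic deterministic on synthetic data).  Background sequences use
Robinson–Robinson natural frequencies and are rejection-sampled until they
contain no core-pattern match; likewise each assembled architecture is
rejection-sampled until its core-pattern matches are exactly the planted
anchors.

**Randomness.**  One integer seed per dataset; record *i* uses the
deterministic stream `default_rng([seed, i])`, so datasets are
byte-identical across runs and insensitive to record order.

## Motif scanning

Bracket patterns are compiled to per-position allowed sets; scanning is a
sliding-window set-membership test (reported overlapping by default; the
domain caller deduplicates).  The shipped patterns start at the G because
the first motif position is clade-variable (E in actinobacterial DivIVA, a
wide range in PolyDIV); the preceding residue is reported with each hit.
Consensus computation over a provided alignment uses a ≥ 0.5 majority rule
among non-gap residues (`x` otherwise, `.` for columns > 50% gaps); the
threshold is a documented default, not a published value.

## Periodicity estimation

The binary hydropathy profile is analysed in sliding windows (default 49
for the standalone estimator).  Each window is mean-centered, zero-padded
to 4096 points and Fourier-transformed; the dominant period is the
maximum-power bin with period in [3.2, 4.0], refined by quadratic
interpolation around the peak.  Spectral power is the peak-bin share of
the window's total signal power at the window's own resolution, so an
ideal repeat scores ≈ 0.5–0.7 and i.i.d. noise ≈ 0.1 (Monte-Carlo median
< 0.2, which motivates the `min_power = 0.2` calling threshold).

Classification bins are midpoints between the ideal periodicities:
heptad [3.40, 3.58], hendecad (3.58, 3.71], pentadecad (3.71, 3.80].
Supercoil offset is exact arithmetic, period − 3.63; handedness is left
below −0.02, right above +0.02.  Note that 11/3 − 3.63 = 0.0367, which
rounds to 0.04 at two decimals; the conventional quote of "0.03" for
hendecads reflects a coarser rounding of the same quantity.

**Segmentation** (`annotate_repeats`) uses a smaller default window of 25:
the smallest odd window that (a) fits entirely inside the shortest planted
domain coil (28 residues) and (b) still places every phase of an ideal
hendecad inside the hendecad bin.  Window classes are majority-smoothed
(half-width 5) to suppress isolated flickers; runs of a common class
become candidate segments, whose boundaries are trimmed to the first/last
hydrophobic residue and split wherever consecutive hydrophobics are more
than 5 apart (core spacings in genuine repeats are 3 or 4, so longer
hydrophobe-free stretches — e.g. linkers — separate tandem domains even
when their windows blur together).  Segments shorter than 8 residues are
dropped.  Window-edge effects can still produce short, low-confidence
segments with inconsistent class at segment borders; they are harmless to
domain calling, which requires ≥ 14 heptad residues beyond the motif V.

Register assignment maximizes summed hydropathy over the class's core
positions across all phases (ties to the smallest phase), making labels
invariant under whole-repeat shifts of the segment start.

## Domain calling and classification

A core-pattern hit is called as a domain when a heptad segment starts no
later than `max_gap = 5` residues after the hit's V and extends at least
`min_cc_length = 14` residues (two heptads) beyond it.  Segments may begin
*before* the V: the coil helix physically starts at the motif's E, and the
detected segment is trimmed to hydrophobics, typically starting at the
motif's Y or V.  Hits with overlapping motif intervals are deduplicated
keeping the earliest; call intervals are truncated at the next call's
motif start so calls never overlap even when coil segments bleed across
short linkers.

Families: PolyDIV for 2–8 domains; FilP/Scy-like for one domain with
≥ 50 hendecad-classified residues downstream; DivIVA/GpsB-like for one
domain otherwise; unclassified for zero (or > 8) domains.  The
paired-linker statistic pairs domains (1,2), (3,4), … and compares the
median within-pair linker (odd 1-based linker indices) against the median
between-pair linker; it is defined only for even domain counts ≥ 4.

## Similarity clustering

Pairwise similarity is the optimal Smith–Waterman score (Biopython's
PairwiseAligner, BLOSUM62, gap open 11 / extend 1, a gap of length *k*
costing 11 + *k*), converted to a bit score with the gapped
Karlin–Altschul constants λ = 0.267, K = 0.041 and to
P = 1 − exp(−mn·2^(−S′)), computed with `expm1` so values far below the
1e-15 graph threshold remain exact.  Exact local alignment is a stronger,
dependency-free stand-in for a heuristic search engine at the few-hundred
sequence scale this package targets; the test suite validates it against
an independent Gotoh dynamic-programming oracle.

The Girvan–Newman implementation removes the maximum-betweenness edge
(ties broken by lexicographically smallest node-id pair, for
reproducibility), evaluates the component partition after every removal
with Newman–Girvan modularity on the original graph and returns the
maximum-modularity partition (the stopping rule is a documented choice;
ties keep the coarsest partition).  Edgeless graphs score modularity 0 by
convention.  Since the graph shrinks by one edge per iteration, only
desk-scale inputs (hundreds of nodes) are practical.  Cluster selection
follows the "at least half" rule: a cluster passes iff the fraction of
members with an extended-pattern hit is ≥ 0.5, boundary inclusive.

The redundancy filter is a greedy longest-first pass (ties by input
order): a candidate is discarded iff a retained sequence aligns to it with
identity > 0.80 over ≥ 0.80 coverage *of the shorter sequence* (the
published criterion does not say which sequence the coverage refers to;
the shorter-sequence reading is the stricter and is fixed here).

## Problem sizes and tolerances

The test and acceptance workloads are sized for a laptop-class single
core: ideal-repeat targets use 24-repeat segments; oracle equivalence uses
1000 random 200-mers (motif), 20 random pairs (alignment) and all
≤ 8-node battery graphs (exhaustive modularity, Bell(8) = 4140
partitions); ground-truth recovery uses 130 records across all families
and every PolyDIV copy number; clustering recovery uses 3 families × 10
mutated copies of 300-mers at 90% identity.  Period assertions use
± 0.02 on ideal constructions; probabilistic assertions fix all seeds.

## Known limitations

* The generator's clean linkers and perfect cores overstate real-world
  separability; no disorder, compositional bias or taxonomic structure is
  emulated.
* Karlin–Altschul constants are fixed for BLOSUM62/11/1; other matrices
  reuse them as approximations.
* All-vs-all alignment and iterated betweenness are quadratic/cubic; the
  pipeline is not meant for database-scale inputs.
* Knobs-to-knobs packing is reported only as a sequence-level flag on
  hendecad segments; no structural analysis is performed.
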