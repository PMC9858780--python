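import numpy as np
import pytest

from divscan.errors import ContractError, ParameterError
from divscan.motif_scan import scan_motif
from divscan.repeats import HENDECAD, HEPTAD, PENTADECAD
from divscan.seqio import SequenceRecord, fasta_string
from divscan.synth import (
    ArchitectureSpec,
    POLAR_RESIDUES,
    generate_architecture,
    generate_dataset,
    generate_divlike_domain,
    generate_repeat_segment,
    graft_domains,
    truth_table,
)

HYDROPHOBIC = set("LIVMFYWA")


class TestRepeatSegment:
    @pytest.mark.parametrize("rc", [HEPTAD, HENDECAD, PENTADECAD], ids=lambda r: r.name)
    def test_hydrophobics_only_at_core_positions(self, rc):
        seq, register = generate_repeat_segment(rc, 4, 0.0, seed := 3)
        assert len(seq) == 4 * rc.repeat_length
        for letter, label in zip(seq, register):
            if label in rc.core_labels:
                assert letter in HYDROPHOBIC
            else:
                assert letter not in HYDROPHOBIC

    def test_full_alanine_core(self):
        seq, register = generate_repeat_segment(HENDECAD, 3, 1.0, 0)
        cores = [s for s, l in zip(seq, register) if l in HENDECAD.core_labels]
        assert cores == ["A"] * 9

    def test_hendecad_alanine_prefers_h_positions(self):
        seq, register = generate_repeat_segment(HENDECAD, 6, 1 / 3, 5)
        at_h = [s for s, l in zip(seq, register) if l == "h"]
        assert at_h == ["A"] * 6  # exactly one-third of cores, all at h

    def test_deterministic_for_fixed_seed(self):
        assert generate_repeat_segment(HEPTAD, 5, 0.2, 42) == generate_repeat_segment(
            HEPTAD, 5, 0.2, 42
        )

    def test_too_few_repeats_rejected(self):
        with pytest.raises(ParameterError):
            generate_repeat_segment(HEPTAD, 1)


class TestDivlikeDomain:
    def test_matches_core_and_extended_pattern_at_anchor(
        self, core_pattern, extended_pattern
    ):
        for seed in range(20):
            domain = generate_divlike_domain(seed)
            rec = SequenceRecord("d", domain.sequence)
            core_hits = scan_motif(rec, core_pattern)
            ext_hits = scan_motif(rec, extended_pattern)
            assert [h.start for h in core_hits] == [domain.motif_start]
            assert [h.start for h in ext_hits] == [domain.motif_start]
            assert rec.sequence[domain.motif_start - 1] == "R"

    def test_motif_v_sits_on_a_core_register(self):
        from divscan.repeat_scan import assign_register

        domain = generate_divlike_domain(7)
        rec = SequenceRecord("d", domain.sequence)
        register = assign_register(rec, (domain.cc_start, domain.cc_end), "heptad")
        v_label = register[domain.v_position - domain.cc_start]
        assert rec.sequence[domain.v_position] == "V"
        assert v_label in "ad"  # first residue of the hydrophobic core

    def test_tiny_coil_rejected(self):
        with pytest.raises(ParameterError):
            generate_divlike_domain(0, cc_repeats=1)


class TestArchitectures:
    def test_polydiv_alternating_linkers(self):
        spec = ArchitectureSpec.for_family("PolyDIV", n_domains=4)
        rec = generate_architecture(spec, rng=0, record_id="p")
        truth = rec.truth
        assert truth.n_domains == 4
        assert len(truth.motif_intervals) == 4
        short, long_, short2 = truth.linker_lengths
        assert 5 <= short <= 15 and 5 <= short2 <= 15
        assert 25 <= long_ <= 60

    def test_scy_starts_right_before_the_motif(self):
        rec = generate_architecture(
            ArchitectureSpec.for_family("Scy_like"), rng=1, record_id="scy"
        )
        assert rec.sequence.startswith("RGYD")
        assert rec.truth.motif_intervals[0][0] == 1

    def test_background_contains_no_core_matches(self, core_pattern):
        for seed in range(10):
            rec = generate_architecture(
                ArchitectureSpec.for_family("background"), rng=seed, record_id="bg"
            )
            assert scan_motif(rec, core_pattern) == []

    def test_nonbackground_core_match_count_equals_domains(self, core_pattern):
        for family, n in (("DivIVA_like", 1), ("FilP_like", 1), ("PolyDIV", 4)):
            rec = generate_architecture(
                ArchitectureSpec.for_family(family), rng=3, record_id="r"
            )
            hits = scan_motif(rec, core_pattern)
            assert len(hits) == n == rec.truth.n_domains

    def test_linkers_are_motif_and_hydrophobe_free(self):
        rec = generate_architecture(
            ArchitectureSpec.for_family("PolyDIV", n_domains=6), rng=9, record_id="p"
        )
        truth = rec.truth
        for (s1, e1), (s2, e2) in zip(
            truth.domain_intervals, truth.domain_intervals[1:]
        ):
            linker = rec.sequence[e1 : s2 - 1]  # excludes the next motif's R
            assert set(linker) <= set(POLAR_RESIDUES)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(family="PolyDIV", n_domains=1),
            dict(family="DivIVA_like", n_domains=2),
            dict(family="Scy_like", include_buttressing_helix=True),
            dict(family="nonsense"),
        ],
    )
    def test_inconsistent_specs_rejected(self, kwargs):
        with pytest.raises(ParameterError):
            ArchitectureSpec(**kwargs)


class TestGraft:
    def _scaffold(self, seed=1):
        return generate_architecture(
            ArchitectureSpec.for_family("PolyDIV", n_domains=4),
            rng=seed,
            record_id="scaffold",
        )

    def test_domain_count_conserved(self, core_pattern):
        scaffold = self._scaffold()
        donor = generate_divlike_domain(99, include_buttress=False)
        chimera = graft_domains(scaffold, donor)
        assert chimera.truth.n_domains == 4
        assert len(scan_motif(chimera, core_pattern)) == 4

    def test_identity_graft_preserves_the_donor_domain_region(self):
        # grafting a scaffold's own first domain leaves that domain unchanged
        # and stamps the same sequence into every other domain slot
        scaffold = self._scaffold()
        start, end = scaffold.truth.domain_intervals[0]
        donor = scaffold.sequence[start:end]
        chimera = graft_domains(scaffold, donor)
        assert chimera.truth.domain_intervals[0] == (start, end)
        assert chimera.sequence[start:end] == donor
        for s, e in chimera.truth.domain_intervals:
            assert chimera.sequence[s:e] == donor

    def test_linker_content_unchanged(self):
        scaffold = self._scaffold()
        donor = generate_divlike_domain(7, include_buttress=False)
        chimera = graft_domains(scaffold, donor)
        old, new = scaffold.truth, chimera.truth
        for i in range(3):
            old_linker = scaffold.sequence[
                old.domain_intervals[i][1] : old.motif_intervals[i + 1][0]
            ]
            new_linker = chimera.sequence[
                new.domain_intervals[i][1] : new.motif_intervals[i + 1][0]
            ]
            assert old_linker == new_linker

    def test_single_domain_scaffold_rejected(self):
        rec = generate_architecture(
            ArchitectureSpec.for_family("DivIVA_like"), rng=0, record_id="d"
        )
        with pytest.raises(ContractError):
            graft_domains(rec, "G" * 40)


class TestDataset:
    def test_counts_and_determinism(self):
        specs = [
            ArchitectureSpec.for_family(f)
            for f in ("DivIVA_like", "FilP_like", "PolyDIV", "background")
            for _ in range(3)
        ]
        first = generate_dataset(specs, seed=21)
        second = generate_dataset(specs, seed=21)
        assert fasta_string(first) == fasta_string(second)
        assert len(first) == 12
        families = [r.truth.family for r in first]
        assert families.count("PolyDIV") == 3
        table = truth_table(first)
        assert len(table) >= len(first)

    def test_different_seeds_differ(self):
        specs = [ArchitectureSpec.for_family("DivIVA_like")]
        assert (
            generate_dataset(specs, 1)[0].sequence
            != generate_dataset(specs, 2)[0].sequence
        )

    def test_empty_spec_list_rejected(self):
        with pytest.raises(ParameterError):
            generate_dataset([], 0)
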