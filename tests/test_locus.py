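"""Locus model: layout arithmetic, haplotype/track construction, digestion,
allele definitions and nomenclature."""

import numpy as np
import pytest

import starlocus.locus as loc
from starlocus import (
    LocusModel,
    StructuralKind,
    Variant,
    build_custom_track,
    build_haplotype_sequence,
    default_locus_spec,
    digest,
    find_cut_sites,
    inclusive_span,
    load_allele_definitions,
    parse_allele,
    parse_diplotype,
    write_allele_definitions,
)
from starlocus.locus import design_flanking_guides, reverse_complement


class TestLayoutArithmetic:
    def test_cut_to_cut_length_matches_target_region(self, model):
        assert model.spec.total_length == 39_551
        assert inclusive_span(42_122_008, 42_161_558) == 39_551

    def test_analysis_window_is_38_kb(self, model):
        assert model.spec.window_length == 38_254
        assert inclusive_span(42_123_069, 42_161_322) == 38_254

    def test_single_spacer_in_pseudogene_downstream_region(self, model):
        offs = model.spec.offsets()
        d7_down_end = offs["D7_DOWN"][1]
        assert offs["SPACER"] == (d7_down_end, d7_down_end + 1_560)

    def test_same_seed_reproduces_sequence(self):
        a = LocusModel(seed=7).reference_seq()
        b = LocusModel(seed=7).reference_seq()
        assert a == b

    def test_different_seed_changes_sequence(self):
        assert LocusModel(seed=7).reference_seq() != LocusModel(seed=8).reference_seq()

    def test_zero_length_segment_rejected(self):
        with pytest.raises(ValueError):
            loc.Segment("X", loc.Role.INTERGENIC, 0, loc.Origin.NEUTRAL)

    def test_config_round_trip(self, model):
        spec2 = loc.LocusSpec.from_config(model.spec.to_config())
        assert spec2.total_length == model.spec.total_length
        assert [s.name for s in spec2.segments] == [s.name for s in model.spec.segments]


class TestHaplotypes:
    @pytest.mark.parametrize(
        "allele, length, kind",
        [
            ("*1.001", 39_551, StructuralKind.NO_SV),
            ("*5.001", 25_000, StructuralKind.DELETION),
            ("*2.001x2", 52_000, StructuralKind.DUPLICATION),
            ("*36+*10.001", 52_000, StructuralKind.HYBRID_TANDEM),
            ("*68+*4.001", 52_000, StructuralKind.HYBRID_TANDEM),
            ("*13+*2.001", 52_000, StructuralKind.HYBRID_TANDEM),
        ],
    )
    def test_fragment_length_spectrum(self, model, defs, allele, length, kind):
        hap = build_haplotype_sequence(model, allele, defs)
        assert hap.length == length
        assert hap.kind is kind

    def test_reference_allele_is_reference_sequence(self, model, defs):
        hap = build_haplotype_sequence(model, "*1.001", defs)
        assert hap.sequence == model.reference_seq()
        assert hap.variants == []

    def test_deletion_has_no_gene_copies(self, model, defs):
        hap = build_haplotype_sequence(model, "*5.001", defs)
        assert hap.copy_gene_starts == []

    def test_length_conservation_is_exact_segment_arithmetic(self, model, defs):
        no_sv = build_haplotype_sequence(model, "*1.001", defs).length
        dele = build_haplotype_sequence(model, "*5.001", defs).length
        dup = build_haplotype_sequence(model, "*2.001x2", defs).length
        assert no_sv - dele == loc.DELETION_BLOCK_LENGTH
        assert dup - no_sv == loc.TANDEM_UNIT_LENGTH

    def test_variants_planted_at_annotated_offsets(self, model, defs):
        hap = build_haplotype_sequence(model, "*2.033", defs)
        assert len(hap.variants) == 3
        for copy_idx, v in hap.variants:
            frag_off = hap.copy_gene_starts[copy_idx] + v.pos - 1
            assert hap.sequence[frag_off] == v.alt
            assert model.reference_seq()[model.spec.window_to_fragment(v.pos)] == v.ref

    def test_duplication_copies_carry_identical_core_variants(self, model, defs):
        hap = build_haplotype_sequence(model, "*2.001x2", defs)
        by_copy = {0: set(), 1: set()}
        for c, v in hap.variants:
            by_copy[c].add(str(v))
        assert by_copy[0] == by_copy[1] != set()

    def test_tandem_spacer_annotated_only_for_track_a_arrangements(self, model, defs):
        a_type = build_haplotype_sequence(model, "*36+*10.001", defs)
        b_type = build_haplotype_sequence(model, "*13+*2.001", defs)
        # track-A tandems carry the unit spacer plus the pseudogene's own
        assert len(a_type.spacer_intervals) == 2
        assert len(b_type.spacer_intervals) == 1

    def test_unknown_suballele_rejected(self, model, defs):
        with pytest.raises(KeyError):
            build_haplotype_sequence(model, "*7.001", defs)


class TestCustomTracks:
    def test_track_a_spacer_window_length(self, model):
        track = build_custom_track(model, "A")
        assert track.spacer_window is not None
        lo, hi = track.spacer_window
        assert hi - lo == 1_560

    def test_track_b_has_no_spacer_in_duplicated_position(self, model):
        track = build_custom_track(model, "B")
        assert track.spacer_window is None
        assert "DUP_POS_SPACER" not in track.segment_map

    def test_tracks_differ_by_exactly_the_spacer_length(self, model):
        a = build_custom_track(model, "A")
        b = build_custom_track(model, "B")
        # oracle: direct sum of the two tracks' segment lengths
        len_a = sum(e - s for s, e in a.segment_map.values())
        len_b = sum(e - s for s, e in b.segment_map.values())
        assert a.length - b.length == len_a - len_b == 1_560

    def test_ref_track_is_no_sv_layout(self, model):
        ref = build_custom_track(model, "REF")
        assert ref.sequence == model.reference_seq()

    def test_invalid_track_id(self, model):
        with pytest.raises(ValueError):
            build_custom_track(model, "C")


def _brute_force_cut_sites(seq: str, guide: str) -> list[tuple[int, str]]:
    """Oracle: exhaustive scan of every 23-mer on both strands."""
    hits = []
    rc = reverse_complement
    for i in range(len(seq) - 22):
        window = seq[i : i + 23]
        if window[:20] == guide and window[21:23] == "GG":
            hits.append((i + 17, "+"))
        if rc(window)[:20] == guide and rc(window)[21:23] == "GG":
            hits.append((i + 6, "-"))
    return sorted(hits)


class TestCutSites:
    def test_planted_plus_strand_protospacer(self):
        rng = np.random.default_rng(0)
        bases = "ACGT"
        seq = "".join(bases[i] for i in rng.integers(0, 4, 300))
        guide = "".join(bases[i] for i in rng.integers(0, 4, 20))
        planted = seq[:100] + guide + "AGG" + seq[100:]
        hits = find_cut_sites(planted, guide)
        assert (100 + 17, "+") in hits

    def test_absent_guide_yields_empty(self):
        assert find_cut_sites("ACGT" * 100, "A" * 20) == []

    def test_reverse_complement_hit_matches_brute_force(self):
        rng = np.random.default_rng(1)
        bases = "ACGT"
        guide = "".join(bases[i] for i in rng.integers(0, 4, 20))
        seq = "".join(bases[i] for i in rng.integers(0, 4, 400))
        planted = seq[:200] + "CC" + "T" + reverse_complement(guide) + seq[200:]
        hits = find_cut_sites(planted, guide)
        assert hits == _brute_force_cut_sites(planted, guide)
        assert any(strand == "-" for _, strand in hits)

    def test_ambiguous_guide_rejected(self):
        with pytest.raises(ValueError):
            find_cut_sites("ACGT" * 10, "ACGTACGTACGTACGTACGN")

    def test_matches_exhaustive_scan_on_random_planted_sequences(self):
        """Digestion oracle over 100 random 5-kb sequences with planted guides."""
        bases = "ACGT"
        for seed in range(100):
            rng = np.random.default_rng(seed)
            seq = "".join(bases[i] for i in rng.integers(0, 4, 5_000))
            guide = "".join(bases[i] for i in rng.integers(0, 4, 20))
            pos = int(rng.integers(0, 4_800))
            strand = rng.random() < 0.5
            insert = guide + "AGG" if strand else "CCT" + reverse_complement(guide)
            seq = seq[:pos] + insert + seq[pos:]
            assert find_cut_sites(seq, guide) == _brute_force_cut_sites(seq, guide)

    def test_in_silico_digestion_excises_the_reference_fragment(self, model):
        genome, g5, g3 = design_flanking_guides(model, margin=1_000)
        fragments = digest(genome, [g5, g3])
        assert model.reference_seq() in fragments


class TestAlleleDefinitions:
    def test_default_table_satisfies_invariants(self, defs):
        for row in defs.rows:
            assert row.full_set >= row.core_variants
        assert defs.cores()["*1"] == frozenset()

    def test_tsv_round_trip(self, defs, tmp_path):
        path = tmp_path / "defs.tsv"
        write_allele_definitions(defs, path)
        loaded = load_allele_definitions(path)
        assert {r.suballele for r in loaded.rows} == {r.suballele for r in defs.rows}
        assert loaded.find("*2.033").full_set == defs.find("*2.033").full_set

    def test_suballele_missing_core_variant_reported_with_row_number(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "star_allele\tsuballele\tstructural_kind\tcore_variants\tsub_variants\n"
            "*2\t*2.001\tNONE\t100:A>G;200:C>T\t100:A>G\n"
        )
        with pytest.raises(ValueError, match="row 1"):
            load_allele_definitions(path)

    def test_core_only_suballele_with_empty_subset_accepted(self, tmp_path):
        path = tmp_path / "ok.tsv"
        path.write_text(
            "star_allele\tsuballele\tstructural_kind\tcore_variants\tsub_variants\n"
            "*1\t*1.001\tNONE\t.\t.\n"
        )
        table = load_allele_definitions(path)
        assert table.find("*1.001").full_set == frozenset()

    def test_duplicate_suballele_sets_rejected(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text(
            "star_allele\tsuballele\tstructural_kind\tcore_variants\tsub_variants\n"
            "*2\t*2.001\tNONE\t100:A>G\t100:A>G\n"
            "*2\t*2.002\tNONE\t100:A>G\t100:A>G\n"
        )
        with pytest.raises(ValueError, match="differ"):
            load_allele_definitions(path)


class TestNomenclature:
    @pytest.mark.parametrize(
        "text, kind, n_copies",
        [
            ("*1.001", StructuralKind.NO_SV, 1),
            ("*5.001", StructuralKind.DELETION, 0),
            ("*2.001x2", StructuralKind.DUPLICATION, 2),
            ("*68+*4.001", StructuralKind.HYBRID_TANDEM, 2),
        ],
    )
    def test_parse_allele_kinds(self, defs, text, kind, n_copies):
        spec = parse_allele(text, defs)
        assert spec.kind is kind
        assert len(spec.copies) == n_copies

    def test_tandem_lists_five_prime_copy_first(self, defs):
        spec = parse_allele("*68+*4.001", defs)
        assert spec.copies[0].core == "*68"
        assert spec.track_type == "A"

    def test_bare_hybrid_outside_tandem_rejected(self, defs):
        with pytest.raises(ValueError):
            parse_allele("*68", defs)

    def test_diplotype_requires_two_alleles(self, defs):
        with pytest.raises(ValueError):
            parse_diplotype("*1.001", defs)
        a, b = parse_diplotype("*1.001/*5.001", defs)
        assert a.kind is StructuralKind.NO_SV and b.kind is StructuralKind.DELETION

    def test_window_coordinate_mapping_round_trip(self, model):
        v = Variant(1, model.window_ref_base(1), "A")
        assert model.spec.window_to_fragment(v.pos) == model.spec.analysis_window[0]
        with pytest.raises(ValueError):
            model.spec.window_to_fragment(0)
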