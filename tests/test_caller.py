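"""Phasing and star-allele calling: clustering, consensus, assignment,
diplotype formatting and full round-trip recovery."""

from collections import Counter

import pytest

from starlocus import (
    ErrorModel,
    StructuralKind,
    Variant,
    assemble_diplotype,
    assign_star_allele,
    build_haplotype_sequence,
    classify_structure,
    cluster_reads,
    consensus_and_call,
    simulate_diploid_reads,
)
from starlocus.caller import AlleleCall, CallerParams, HaplotypeCall, ReadCluster
from starlocus.fixtures import STUDY_SAMPLES, genotype_reads, simulate_sample
from starlocus.locus import Origin
from starlocus.qc import check_full_span


def _probe_all(prober, reads, full_span_only=True):
    feats = [prober.probe_read(r.read_id, r.sequence) for r in reads]
    return [f for f in feats if not full_span_only or check_full_span(f)]


class TestClustering:
    def test_error_free_partition_is_perfect(self, prober, model, defs):
        reads, _, _ = simulate_sample(
            "*2.033/*29.001", model, defs, depth_per_allele=6,
            error_model=ErrorModel.error_free(), seed=1,
        )
        feats = _probe_all(prober, reads)
        clusters, homo = cluster_reads(feats)
        assert not homo and len(clusters) == 2
        truth = {r.read_id: r.source_allele for r in reads}
        for c in clusters:
            assert len({truth[rid] for rid in c.member_ids}) == 1

    def test_suballele_level_heterozygosity_resolved(self, prober, model, defs):
        """Two *1 alleles differing only at suballele sites split cleanly."""
        reads, _, _ = simulate_sample(
            "*1.058/*1.059", model, defs, depth_per_allele=20, seed=2
        )
        feats = _probe_all(prober, reads)
        clusters, homo = cluster_reads(feats)
        assert not homo and len(clusters) == 2
        truth = {r.read_id: r.source_allele for r in reads}
        for c in clusters:
            majority = Counter(truth[rid] for rid in c.member_ids).most_common(1)[0]
            assert majority[1] / len(c) >= 0.9

    def test_true_homozygote_collapses_to_one_cluster(self, prober, model, defs):
        reads, _, _ = simulate_sample(
            "*1.001/*1.001", model, defs, depth_per_allele=15, seed=3
        )
        clusters, homo = cluster_reads(_probe_all(prober, reads))
        assert homo and len(clusters) == 1

    def test_insufficient_reads_yield_no_clusters(self, prober, model, defs):
        reads, _, _ = simulate_sample("*1.001/*2.001", model, defs, depth_per_allele=2, seed=4)
        clusters, _ = cluster_reads(_probe_all(prober, reads))
        assert clusters == []

    def test_assignment_accuracy_at_default_error_rates(self, prober, model, defs):
        """>=95% of reads land in their truth cluster over 20 seeds."""
        n_ok = n_tot = 0
        for seed in range(20):
            reads, _, _ = simulate_sample(
                "*1.001/*2.033", model, defs, depth_per_allele=40, seed=seed
            )
            feats = _probe_all(prober, reads)
            clusters, homo = cluster_reads(feats)
            if homo or len(clusters) != 2:
                n_tot += len(feats)
                continue
            truth = {r.read_id: r.source_allele for r in reads}
            # map each cluster to its majority truth allele
            for c in clusters:
                votes = Counter(truth[rid] for rid in c.member_ids)
                major, count = votes.most_common(1)[0]
                n_ok += count
                n_tot += len(c)
        assert n_ok / n_tot >= 0.95


class TestConsensus:
    def test_single_planted_snv_called_with_full_support(self, prober, model, defs):
        reads, _, _ = simulate_sample(
            "*4.001/*4.001", model, defs, depth_per_allele=25,
            error_model=ErrorModel.error_free(), seed=5,
        )
        feats = _probe_all(prober, reads)
        cluster = ReadCluster([f.read_id for f in feats], feats)
        structure = classify_structure(feats)
        copy_sets, calls = consensus_and_call(cluster, structure, model, defs)
        assert copy_sets == [defs.find("*4.001").full_set]
        assert len(calls) == 1 and calls[0].supporting_fraction == 1.0

    def test_sites_under_read_gaps_are_missing_not_reference(self, prober, model, defs):
        """Deleting the sequence around a definition site must not produce
        reference support at that site."""
        hap = build_haplotype_sequence(model, "*4.001", defs)
        pos = next(iter(defs.find("*4.001").full_set)).pos
        frag = hap.copy_gene_starts[0] + pos - 1
        gapped = hap.sequence[: frag - 25] + hap.sequence[frag + 25 :]
        feats = prober.probe_read("gapped", gapped)
        obs = feats.copies[0].site_obs
        assert obs[pos] is None

    def test_tandem_copy_variants_called_on_the_right_copy(self, prober, model, defs, tracks):
        """The 3' gene copy of a *36+*10 tandem carries the *10 variant; the
        5' hybrid copy must not."""
        reads, _, _ = simulate_sample(
            "*36+*10.001/*36+*10.001", model, defs, depth_per_allele=10,
            error_model=ErrorModel.error_free(), seed=6,
        )
        feats = _probe_all(prober, reads)
        cluster = ReadCluster([f.read_id for f in feats], feats)
        structure = classify_structure(feats)
        copy_sets, calls = consensus_and_call(cluster, structure, model, defs)
        assert copy_sets[0] == frozenset()
        assert copy_sets[1] == defs.find("*10.001").full_set
        assert {c.copy_index for c in calls} == {1}

    def test_planted_novel_snvs_recovered_without_false_positives(
        self, prober, model, defs
    ):
        """10 planted non-definition SNVs, depth 100, 20 seeds: all
        recovered, zero false calls at the 0.7 majority threshold."""
        import numpy as np

        base_hap = build_haplotype_sequence(model, "*1.001", defs)
        def_pos = set(defs.all_positions())
        transitions = {"A": "G", "G": "A", "C": "T", "T": "C"}
        for seed in range(20):
            rng = np.random.default_rng(1_000 + seed)
            planted: dict[int, str] = {}
            while len(planted) < 10:
                exon = int(rng.integers(1, 10))
                off = int(rng.integers(0, 600))
                if not (0 <= off < 250 or 281 <= off < 600):
                    continue  # keep clear of the marker 31-mer
                pos = 1_500 + (exon - 1) * 600 + off + 1
                if pos in def_pos or pos in planted:
                    continue
                planted[pos] = transitions[model.window_ref_base(pos)]
            seq = list(base_hap.sequence)
            for pos, alt in planted.items():
                seq[base_hap.copy_gene_starts[0] + pos - 1] = alt
            hap = build_haplotype_sequence(model, "*1.001", defs)
            hap.sequence = "".join(seq)
            reads = simulate_diploid_reads(hap, hap, depth_per_allele=50, seed=seed)
            feats = _probe_all(prober, reads)
            cluster = ReadCluster([f.read_id for f in feats], feats)
            structure = classify_structure(feats)
            copy_sets, _ = consensus_and_call(cluster, structure, model, defs)
            called = {v.pos: v.alt for v in copy_sets[0]}
            assert called == planted, f"seed {seed}: {called} != {planted}"


class TestStarAssignment:
    def test_empty_variant_set_is_the_reference_allele(self, defs):
        call = assign_star_allele(frozenset(), defs)
        assert (call.core, call.label) == ("*1", "*1.001")
        assert not call.novel

    def test_core_plus_defined_extra_matches_the_suballele(self, defs):
        call = assign_star_allele(defs.find("*2.033").full_set, defs)
        assert (call.core, call.label) == ("*2", "*2.033")

    def test_core_plus_undefined_extra_flags_novel(self, model, defs):
        extra = Variant(3_000, model.window_ref_base(3_000),
                        {"A": "G", "G": "A", "C": "T", "T": "C"}[model.window_ref_base(3_000)])
        variants = defs.find("*2.001").full_set | {extra}
        call = assign_star_allele(variants, defs)
        assert call.core == "*2" and call.novel
        assert call.label == "*2.new1"
        assert call.extra_variants == frozenset({extra})

    def test_hybrid_patterns_matched_by_exon_origin(self, defs):
        call = assign_star_allele(
            frozenset(), defs,
            exon_origins={k: Origin.D7 if k == 9 else Origin.D6 for k in range(1, 10)},
            spacer_in_copy=True,
        )
        assert call.label == "*36"
        unknown = assign_star_allele(
            frozenset(), defs,
            exon_origins={k: Origin.D7 if k in (4, 5) else Origin.D6 for k in range(1, 10)},
        )
        assert not unknown.is_call and "hybrid" in unknown.no_call_reason

    def test_containment_soundness_of_every_definition(self, defs):
        """Every suballele's full set contains its core's set (re-checked)."""
        for row in defs.rows:
            assert row.full_set >= row.core_variants

    def test_calls_respect_containment_on_a_genotyped_sample(self, model, defs):
        reads, _, _ = simulate_sample("*1.001/*2.033", model, defs, 40, seed=8)
        result = genotype_reads(reads, model, defs)
        for allele in result.diplotype.alleles:
            for copy in allele.copies:
                if copy.core and copy.core in defs.cores() and not copy.novel:
                    assert defs.find(copy.label).full_set >= defs.cores()[copy.core]


def _nosv_call(label, core=None):
    from starlocus.align import StructureCall

    s = StructureCall(StructuralKind.NO_SV, "REF", None, None, [], 39_551, 10)
    return AlleleCall(s, [HaplotypeCall(core or label.split(".")[0], label)])


class TestDiplotypeAssembly:
    def test_duplication_formats_with_x2(self, defs):
        from starlocus.align import StructureCall

        dup_s = StructureCall(StructuralKind.DUPLICATION, "B", None, False, [], 52_000, 10)
        dup = AlleleCall(dup_s, [HaplotypeCall("*2", "*2.001"), HaplotypeCall("*2", "*2.001")])
        other = _nosv_call("*29.001", "*29")
        assert assemble_diplotype([dup, other]).formatted == "*2.001x2/*29.001"

    def test_tandem_lists_five_prime_copy_first_and_sorts_numerically(self, defs):
        from starlocus.align import StructureCall

        tan_s = StructureCall(StructuralKind.HYBRID_TANDEM, "A", Origin.D7, True, [], 52_000, 10)
        tandem = AlleleCall(tan_s, [HaplotypeCall("*68", "*68"), HaplotypeCall("*4", "*4.001")])
        other = _nosv_call("*1.037", "*1")
        assert assemble_diplotype([tandem, other]).formatted == "*1.037/*68+*4.001"

    def test_two_reference_alleles(self):
        a = _nosv_call("*1.001", "*1")
        b = _nosv_call("*1.001", "*1")
        assert assemble_diplotype([a, b]).formatted == "*1.001/*1.001"

    def test_both_no_call_is_sample_level_no_call(self):
        from starlocus.align import StructureCall

        s = StructureCall(None, None, None, None, [], None, 1, reason="too few reads")
        calls = [AlleleCall(s, [], no_call_reason="too few reads")] * 2
        diplo = assemble_diplotype(calls)
        assert not diplo.is_call and "too few reads" in diplo.no_call_reason

    def test_swapping_parental_labels_leaves_the_string_unchanged(self, model, defs):
        a, b = "*2.001", "*36+*10.001"
        r1, _, _ = simulate_sample(f"{a}/{b}", model, defs, 30, seed=11)
        r2, _, _ = simulate_sample(f"{b}/{a}", model, defs, 30, seed=11)
        d1 = genotype_reads(r1, model, defs).diplotype.formatted
        d2 = genotype_reads(r2, model, defs).diplotype.formatted
        assert d1 == d2 == "*2.001/*36+*10.001"


class TestRoundTripRecovery:
    @pytest.mark.parametrize("sample", STUDY_SAMPLES, ids=lambda s: s.sample_id)
    def test_all_study_diplotypes_recovered_across_seeds(self, model, defs, sample):
        """Simulate -> genotype recovers the exact diplotype (core and
        suballele level) for every study sample across 5 seeds."""
        for seed in range(5):
            reads, _, _ = simulate_sample(
                sample.diplotype, model, defs, depth_per_allele=40,
                seed=10_000 + 100 * seed + sample.seed,
            )
            result = genotype_reads(reads, model, defs)
            assert result.diplotype.formatted == sample.diplotype, (
                f"seed {seed}: {result.diplotype.formatted}"
            )
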