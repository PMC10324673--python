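"""Direct read-backed phasing and star-allele / diplotype assignment.

Because every retained read spans the whole excised locus, the two
parental alleles can be separated without statistical phasing: reads
first split by structural signature (fragment-length class, spacer
status, 5'-region origin), and structurally identical alleles are split
by agglomerative clustering on Hamming distance over the profiled
variant sites.  Each cluster then yields a per-gene-copy majority
consensus, variants are the consensus minus the track reference, and the
star allele is the containment-maximal core whose defining variants are
all present; the suballele is the one whose full variant set equals the
call, otherwise the call is flagged as a novel suballele of that core.

Tandem arrangements are called per gene copy on the same physical reads
(both copies ride on one molecule), and formatted 5'-copy-first per the
PharmVar tandem-annotation convention.
"""

from __future__ import annotations

import re
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .align import (
    Prober,
    ReadFeatures,
    StructureCall,
    classify_structure,
    measure_fragment_length,
)
from .locus import (
    EXON_LENGTH,
    HYBRID_PATTERNS,
    N_EXONS,
    UP_LENGTH,
    AlleleDefinitionTable,
    LocusModel,
    Origin,
    StructuralKind,
    Variant,
    core_number,
)
from .qc import QCParams, QCReport, check_full_span, coverage_profile, filter_reads

__all__ = [
    "VariantCall",
    "ReadCluster",
    "HaplotypeCall",
    "AlleleCall",
    "DiplotypeCall",
    "SampleResult",
    "CallerParams",
    "extract_variant_profile",
    "cluster_reads",
    "consensus_and_call",
    "assign_star_allele",
    "assemble_diplotype",
    "genotype_sample",
]

MISSING = None


@dataclass(frozen=True)
class CallerParams:
    min_cluster_reads: int = 3
    min_site_depth: int = 3
    site_majority: float = 0.7
    #: fraction of a cluster's reads that must show the same non-reference
    #: base for a non-definition site to enter the profile
    discovery_fraction: float = 0.3


@dataclass(frozen=True)
class VariantCall:
    pos: int  # 1-based analysis-window coordinate in reports
    ref: str
    alt: str
    allele_index: int
    copy_index: int
    supporting_fraction: float

    def __post_init__(self) -> None:
        if not 0.5 < self.supporting_fraction <= 1.0:
            raise ValueError("emitted calls require supporting_fraction in (0.5, 1.0]")

    @property
    def variant(self) -> Variant:
        return Variant(self.pos, self.ref, self.alt)


@dataclass
class ReadCluster:
    member_ids: list[str]
    features: list[ReadFeatures]
    structure: StructureCall | None = None

    def __len__(self) -> int:
        return len(self.member_ids)


@dataclass
class HaplotypeCall:
    """Star-allele call for a single gene copy."""

    core: str | None
    label: str | None  # printed label, e.g. "*2.033", "*68", "*2.new1"
    novel: bool = False
    ambiguous: bool = False
    extra_variants: frozenset[Variant] = frozenset()
    variants: frozenset[Variant] = frozenset()
    no_call_reason: str | None = None

    @property
    def is_call(self) -> bool:
        return self.label is not None


@dataclass
class AlleleCall:
    """One parental allele: structure plus per-copy star calls."""

    structure: StructureCall
    copies: list[HaplotypeCall]
    variant_calls: list[VariantCall] = field(default_factory=list)
    no_call_reason: str | None = None

    @property
    def label(self) -> str | None:
        if self.no_call_reason is not None:
            return None
        if self.structure.kind is StructuralKind.DELETION:
            return self.copies[0].label
        if self.structure.kind in (StructuralKind.DUPLICATION, StructuralKind.HYBRID_TANDEM):
            labels = [c.label for c in self.copies]
            if any(l is None for l in labels):
                return None
            if self.structure.kind is StructuralKind.DUPLICATION and labels[0] == labels[1]:
                return f"{labels[0]}x2"
            return "+".join(labels)
        return self.copies[0].label if self.copies else None


@dataclass
class DiplotypeCall:
    alleles: tuple[AlleleCall, AlleleCall] | None
    formatted: str | None
    no_call_reason: str | None = None

    @property
    def is_call(self) -> bool:
        return self.formatted is not None


@dataclass
class SampleResult:
    qc: QCReport
    clusters: list[ReadCluster]
    structures: list[StructureCall]
    variant_calls: list[VariantCall]
    diplotype: DiplotypeCall
    homozygous: bool = False


# ---------------------------------------------------------------------------
# profiles and clustering


def extract_variant_profile(features: ReadFeatures) -> dict[tuple[int, int], str | None]:
    """Per-site observations of one read, keyed by (copy index, window pos).

    Sites under read gaps or on pseudogene-derived exons are MISSING
    (None), never counted as reference support.
    """
    profile: dict[tuple[int, int], str | None] = {}
    for obs in features.copies:
        for pos, base in obs.site_obs.items():
            profile[(obs.copy_index, pos)] = base
    return profile


def _structure_signature(f: ReadFeatures):
    return (f.length_class, f.spacer_status, f.five_prime_origin)


def _hamming(p1: dict, p2: dict) -> float:
    shared = [k for k in p1 if k in p2 and p1[k] is not None and p2[k] is not None]
    if not shared:
        return 0.0
    return sum(p1[k] != p2[k] for k in shared) / len(shared)


HET_MINOR_FRACTION = 0.25


def _candidate_het_sites(profiles: list[dict], params: CallerParams) -> list:
    """Sites where the second-most-common base reaches the minor-fraction
    threshold at adequate depth — the signature of a heterozygous site."""
    by_site: dict = defaultdict(Counter)
    for p in profiles:
        for k, base in p.items():
            if base is not None:
                by_site[k][base] += 1
    het = {}
    for k, counts in by_site.items():
        depth = sum(counts.values())
        if depth < 2 * params.min_site_depth:
            continue
        ranked = counts.most_common(2)
        if len(ranked) == 2 and ranked[1][1] / depth >= HET_MINOR_FRACTION:
            het[k] = (ranked[0][0], ranked[1][0])
    return dict(sorted(het.items()))


def _augment_with_discovered(
    profiles: list[dict], features: list[ReadFeatures], params: CallerParams
) -> None:
    """Add recurrent non-definition mismatch sites to every profile, so
    clustering can also separate alleles that differ only at novel sites."""
    counts: Counter = Counter()
    for f in features:
        for obs in f.copies:
            for pos, alt in obs.mismatches.items():
                counts[(obs.copy_index, pos, alt)] += 1
    n = max(len(features), 1)
    candidates = {
        (c, pos): alt
        for (c, pos, alt), cnt in counts.items()
        if cnt / n >= HET_MINOR_FRACTION
    }
    if not candidates:
        return
    for f, p in zip(features, profiles):
        for obs in f.copies:
            for (c, pos), alt in candidates.items():
                if obs.copy_index != c or (c, pos) in p:
                    continue
                rel = pos - 1 - UP_LENGTH
                exon = rel // EXON_LENGTH + 1 if 0 <= rel < N_EXONS * EXON_LENGTH else None
                if exon is None or not obs.exon_found.get(exon, False):
                    p[(c, pos)] = None
                elif pos in obs.mismatches:
                    p[(c, pos)] = obs.mismatches[pos]
                else:
                    p[(c, pos)] = "ref"
    return


def _profile_consensus(
    profiles: list[dict], majority: float, min_depth: int
) -> dict[tuple[int, int], str]:
    """Majority base per site across reads; sites failing depth/majority are dropped."""
    by_site: dict[tuple[int, int], Counter] = defaultdict(Counter)
    for p in profiles:
        for k, base in p.items():
            if base is not None:
                by_site[k][base] += 1
    out: dict[tuple[int, int], str] = {}
    for k, counts in by_site.items():
        depth = sum(counts.values())
        if depth < min_depth:
            continue
        base, n = counts.most_common(1)[0]
        if n / depth >= majority:
            out[k] = base
    return out


def cluster_reads(
    features: list[ReadFeatures],
    params: CallerParams | None = None,
    expected_alleles: int = 2,
) -> tuple[list[ReadCluster], bool]:
    """Partition full-span reads into the two parental alleles.

    Reads with distinct structural signatures separate directly; a
    structurally homogeneous sample is split by average-linkage
    agglomerative clustering on pairwise Hamming distance over shared
    non-missing profiled sites.  If the two candidate clusters agree at
    every profiled site after noise filtering the sample is homozygous and
    a single cluster is returned.

    Returns ``(clusters, homozygous)``.
    """
    params = params or CallerParams()
    if len(features) < expected_alleles * params.min_cluster_reads:
        return [], False

    groups: dict[tuple, list[ReadFeatures]] = defaultdict(list)
    for f in features:
        groups[_structure_signature(f)].append(f)
    # drop signatures too small to be an allele (sporadic misreads)
    major = {sig: fs for sig, fs in groups.items() if len(fs) >= params.min_cluster_reads}

    if len(major) >= 2:
        ranked = sorted(major.values(), key=len, reverse=True)[:2]
        clusters = [ReadCluster([f.read_id for f in fs], fs) for fs in ranked]
        # reassign reads from minor signatures to the nearer cluster by span
        assigned = {rid for c in clusters for rid in c.member_ids}
        meds = [np.median([f.span_length for f in c.features]) for c in clusters]
        for f in features:
            if f.read_id in assigned or f.span_length is None:
                continue
            i = int(np.argmin([abs(f.span_length - m) for m in meds]))
            clusters[i].member_ids.append(f.read_id)
            clusters[i].features.append(f)
        return clusters, False

    # structurally homogeneous: cluster on variant profiles, restricted to
    # candidate heterozygous sites (a site where a substantial minority of
    # reads shows a second base); sequencing noise never reaches the
    # minor-fraction threshold, so distances at these sites are clean
    profiles = [extract_variant_profile(f) for f in features]
    _augment_with_discovered(profiles, features, params)
    het_sites = _candidate_het_sites(profiles, params)
    n = len(features)
    if not het_sites:
        return [ReadCluster([f.read_id for f in features], list(features))], True
    # only the two major bases per site are informative; sequencing-error
    # bases would otherwise create flat dendrogram ties
    het_profiles = [
        {k: p[k] for k, majors in het_sites.items() if p.get(k) in majors}
        for p in profiles
    ]
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = _hamming(het_profiles[i], het_profiles[j])
    labels = fcluster(linkage(squareform(dist, checks=False), method="average"), 2, "maxclust")
    groups2 = [
        [i for i in range(n) if labels[i] == lab] for lab in sorted(set(labels))
    ]
    if len(groups2) == 1:
        idx_a, idx_b = groups2[0], []
    else:
        idx_a, idx_b = groups2

    cons_a = _profile_consensus([profiles[i] for i in idx_a], params.site_majority, params.min_site_depth)
    cons_b = _profile_consensus([profiles[i] for i in idx_b], params.site_majority, params.min_site_depth)
    shared = set(cons_a) & set(cons_b)
    # homozygous iff the candidate clusters differ at zero profiled sites
    # after noise filtering (sites below depth/majority are not differences)
    homozygous = (not idx_b) or all(cons_a[k] == cons_b[k] for k in shared)
    if homozygous:
        return [ReadCluster([features[i].read_id for i in range(n)], list(features))], True
    clusters = [
        ReadCluster([features[i].read_id for i in idx], [features[i] for i in idx])
        for idx in (idx_a, idx_b)
    ]
    return clusters, False


# ---------------------------------------------------------------------------
# consensus and star assignment


def consensus_and_call(
    cluster: ReadCluster,
    structure: StructureCall,
    model: LocusModel,
    defs: AlleleDefinitionTable,
    params: CallerParams | None = None,
    allele_index: int = 0,
) -> tuple[list[frozenset[Variant]], list[VariantCall]]:
    """Per-gene-copy majority consensus and variant calls for one cluster.

    Sites are the definition-table positions plus discovered
    high-frequency mismatch sites; a variant is emitted where the
    consensus base differs from the reference at 0.7 site majority and
    depth >= 3.  Returns ``(per-copy variant sets, VariantCalls)``.
    """
    params = params or CallerParams()
    n_copies = {
        StructuralKind.NO_SV: 1,
        StructuralKind.DELETION: 0,
        StructuralKind.DUPLICATION: 2,
        StructuralKind.HYBRID_TANDEM: 2,
    }[structure.kind]

    copy_sets: list[frozenset[Variant]] = []
    calls: list[VariantCall] = []
    for c in range(n_copies):
        # observations at definition sites
        by_site: dict[int, Counter] = defaultdict(Counter)
        mismatch_count: Counter = Counter()
        exon_observed: Counter = Counter()
        n_reads = 0
        for f in cluster.features:
            for obs in f.copies:
                if obs.copy_index != c:
                    continue
                n_reads += 1
                for pos, base in obs.site_obs.items():
                    if base is not None:
                        by_site[pos][base] += 1
                for pos, alt in obs.mismatches.items():
                    mismatch_count[(pos, alt)] += 1
                for k, found in obs.exon_found.items():
                    if found:
                        exon_observed[k] += 1
        # discovered sites: recurrent identical non-reference observations
        threshold = max(params.min_site_depth, params.discovery_fraction * max(n_reads, 1))
        def_positions = set(defs.all_positions())
        discovered: dict[int, list[tuple[str, int]]] = defaultdict(list)
        for (pos, alt), cnt in mismatch_count.items():
            if pos not in def_positions and cnt >= threshold:
                discovered[pos].append((alt, cnt))
        for pos, alts in discovered.items():
            depth_k = exon_observed.get(model.exon_of_window_pos(pos), 0)
            alt_total = 0
            for alt, cnt in alts:
                by_site[pos][alt] += cnt
                alt_total += cnt
            by_site[pos][model.window_ref_base(pos)] += max(depth_k - alt_total, 0)

        variants: set[Variant] = set()
        for pos in sorted(by_site):
            counts = by_site[pos]
            depth = sum(counts.values())
            if depth < params.min_site_depth:
                continue  # site NO_CALL, propagated by omission
            base, nbest = counts.most_common(1)[0]
            frac = nbest / depth
            if frac < params.site_majority:
                continue
            ref = model.window_ref_base(pos)
            if base != ref:
                v = Variant(pos, ref, base)
                variants.add(v)
                calls.append(
                    VariantCall(pos, ref, base, allele_index, c, round(min(frac, 1.0), 4))
                )
        copy_sets.append(frozenset(variants))
    return copy_sets, calls


def _exon_origin_map(structure: StructureCall, copy_index: int) -> dict[int, Origin]:
    if copy_index < len(structure.copy_exon_origins):
        return structure.copy_exon_origins[copy_index]
    return {}


def assign_star_allele(
    variants: frozenset[Variant],
    defs: AlleleDefinitionTable,
    exon_origins: dict[int, Origin] | None = None,
    spacer_in_copy: bool | None = None,
) -> HaplotypeCall:
    """Assign a core allele and suballele to one gene copy's variant set.

    Hybrid copies (any CYP2D7-origin exon) are matched against the known
    hybrid exon-origin patterns.  Otherwise the core allele is the one
    whose defining variants are all present and maximal in count (ties go
    to the lowest numeric star id, flagged AMBIGUOUS); the suballele is
    the one whose full variant set equals the call, else the copy is a
    NOVEL suballele of that core with the extra variants listed.
    """
    exon_origins = exon_origins or {}
    d7_exons = frozenset(k for k, o in exon_origins.items() if o is Origin.D7)
    if d7_exons:
        for star, pattern in HYBRID_PATTERNS.items():
            if pattern.d7_exons == d7_exons and (
                spacer_in_copy is None or pattern.spacer == spacer_in_copy
            ):
                return HaplotypeCall(core=star, label=star, variants=variants)
        return HaplotypeCall(
            None, None,
            no_call_reason=f"unrecognized hybrid exon pattern {sorted(d7_exons)}",
            variants=variants,
        )

    candidates: list[tuple[str, frozenset[Variant]]] = []
    for star, core in defs.cores().items():
        if defs.structural_kind(star) in (StructuralKind.DELETION, StructuralKind.HYBRID_TANDEM):
            continue
        if core <= variants:
            candidates.append((star, core))
    if not candidates:
        return HaplotypeCall(
            None, None, no_call_reason=f"no core allele contained in {sorted(str(v) for v in variants)}",
            variants=variants,
        )
    best_size = max(len(core) for _, core in candidates)
    top = sorted(
        [star for star, core in candidates if len(core) == best_size], key=core_number
    )
    ambiguous = len(top) > 1
    core_star = top[0]
    row = defs.match_suballele(core_star, variants)
    if row is not None:
        return HaplotypeCall(
            core=core_star, label=row.suballele or row.star_allele,
            ambiguous=ambiguous, variants=variants,
        )
    extras = variants - defs.cores()[core_star]
    return HaplotypeCall(
        core=core_star,
        label=f"{core_star}.new1",
        novel=True,
        ambiguous=ambiguous,
        extra_variants=frozenset(extras),
        variants=variants,
    )


def _deletion_label(defs: AlleleDefinitionTable) -> HaplotypeCall:
    for row in defs.rows:
        if row.structural_kind is StructuralKind.DELETION:
            return HaplotypeCall(core=row.star_allele, label=row.suballele or row.star_allele)
    return HaplotypeCall(core="*5", label="*5")


def call_allele(
    cluster: ReadCluster,
    structure: StructureCall,
    model: LocusModel,
    defs: AlleleDefinitionTable,
    params: CallerParams | None = None,
    allele_index: int = 0,
) -> AlleleCall:
    """Full per-allele calling: consensus, per-copy star assignment."""
    if not structure.is_call:
        return AlleleCall(structure, [], no_call_reason=structure.reason or "structure NO_CALL")
    if structure.kind is StructuralKind.DELETION:
        return AlleleCall(structure, [_deletion_label(defs)])
    copy_sets, vcalls = consensus_and_call(cluster, structure, model, defs, params, allele_index)
    copies = []
    for c, variants in enumerate(copy_sets):
        spacer = structure.spacer_present_in_tandem_copy if c == 0 else False
        if structure.kind is StructuralKind.NO_SV:
            spacer = None
        copies.append(
            assign_star_allele(variants, defs, _exon_origin_map(structure, c), spacer)
        )
    reason = None
    if any(not c.is_call for c in copies):
        reason = "; ".join(c.no_call_reason or "copy NO_CALL" for c in copies if not c.is_call)
    return AlleleCall(structure, copies, variant_calls=vcalls, no_call_reason=reason)


# ---------------------------------------------------------------------------
# diplotype assembly


def _allele_sort_key(call: AlleleCall) -> tuple:
    label = call.label or "~"
    m = re.match(r"\*(\d+)(?:\.(\d+))?", label)
    if not m:
        return (9999, 9999, label)
    return (int(m.group(1)), int(m.group(2) or -1), label)


def assemble_diplotype(calls: list[AlleleCall]) -> DiplotypeCall:
    """Format the two per-allele calls as a PharmVar-style diplotype string.

    Tandems print the 5' (duplicated-position) copy first; duplications
    collapse to "x2"; the two alleles are ordered by numeric core id.
    Both alleles NO_CALL yields a sample-level NO_CALL.
    """
    called = [c for c in calls if c.label is not None]
    if not called:
        reasons = "; ".join(filter(None, (c.no_call_reason for c in calls))) or "no callable alleles"
        return DiplotypeCall(None, None, no_call_reason=reasons)
    if len(calls) == 1:  # homozygous: one cluster represents both alleles
        calls = [calls[0], calls[0]]
    ordered = sorted(calls, key=_allele_sort_key)
    labels = [c.label if c.label is not None else "NO_CALL" for c in ordered]
    return DiplotypeCall(tuple(ordered), "/".join(labels))


# ---------------------------------------------------------------------------
# pipeline driver


def genotype_sample(
    reads: list[tuple[str, str, str]],
    model: LocusModel,
    defs: AlleleDefinitionTable,
    qc_params: QCParams | None = None,
    caller_params: CallerParams | None = None,
    tracks: dict | None = None,
    prober: Prober | None = None,
) -> SampleResult:
    """Run the full genotyping pipeline on one sample's reads.

    Order: length/quality filter -> anchored feature extraction ->
    full-span and alignment-score gates -> sample-level coverage gate ->
    allele clustering -> per-allele structural classification -> consensus
    variant calling -> star/suballele assignment -> diplotype assembly.
    A sample-level NO_CALL is a successful result with a reason attached.
    """
    qc_params = qc_params or QCParams()
    caller_params = caller_params or CallerParams()
    prober = prober or Prober(model, defs)

    passing, report = filter_reads(reads, qc_params)
    feats = [prober.probe_read(rid, seq) for rid, seq, _ in passing]
    span_feats = [f for f in feats if check_full_span(f)]
    report.n_pass_span = len(span_feats)
    scored = [f for f in span_feats if f.score >= qc_params.min_alignment_score]
    report.n_pass_score = len(scored)
    depth, mean_depth, sample_pass = coverage_profile(
        scored, model.spec.window_length, qc_params
    )
    report.depth_profile = depth
    report.mean_depth = mean_depth
    report.min_depth = int(depth.min()) if depth.size else 0
    report.sample_pass = sample_pass
    report.validate()

    if not sample_pass:
        return SampleResult(
            report, [], [], [],
            DiplotypeCall(None, None, no_call_reason="insufficient full-span reads"),
        )

    clusters, homozygous = cluster_reads(scored, caller_params)
    if not clusters:
        return SampleResult(
            report, [], [], [],
            DiplotypeCall(None, None, no_call_reason="too few reads to separate alleles"),
        )
    reads_by_id = {rid: seq for rid, seq, _ in passing}
    allele_calls: list[AlleleCall] = []
    structures: list[StructureCall] = []
    vcalls: list[VariantCall] = []
    for i, cluster in enumerate(clusters):
        structure = classify_structure(
            cluster.features,
            min_reads=caller_params.min_cluster_reads,
            reads_by_id=reads_by_id,
            tracks=tracks,
        )
        cluster.structure = structure
        structures.append(structure)
        call = call_allele(cluster, structure, model, defs, caller_params, allele_index=i)
        vcalls.extend(call.variant_calls)
        allele_calls.append(call)
    diplotype = assemble_diplotype(allele_calls)
    return SampleResult(report, clusters, structures, vcalls, diplotype, homozygous)
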