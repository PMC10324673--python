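"""Alignment of full-span reads to reference tracks and SV classification.

Two complementary engines are provided:

* :func:`align_read_to_track` — a semiglobal (end-to-end) alignment of a
  whole read against a whole track (edlib bit-parallel alignment), from
  which track-side gaps, per-segment match fractions and an alignment score
  are extracted.  This is the canonical contract used for spacer-gap
  detection, breakpoint estimation and SAM/TSV export.

* :class:`Prober` — an anchored seed-and-verify engine that locates the two
  flank anchors by exact 31-mer seeds plus local verification, then probes
  the read at expected offsets for exons, the 5' region and the spacer
  element.  It produces the same decision features (anchors, spacer status,
  exon origins, variant-site observations, score) at a fraction of the
  cost, and is what the genotyping pipeline runs per read.

Classification logic follows the fragment-length spectrum of the assay:
deletion alleles excise to ~25 kb, the reference configuration to ~39.5 kb
and duplication / hybrid-tandem alleles to ~52 kb; tandem-length alleles
are then sub-typed by the 5' region of the duplicated-position copy and the
presence or absence of the 1.56 kb CYP2D7-like spacer (custom reference
track A: CYP2D7-like 5' + spacer; track B: CYP2D6-like, no spacer).
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field

import edlib
import numpy as np

from .locus import (
    DELETION_LENGTH,
    EXON_LENGTH,
    GENE_LENGTH,
    GENE_START,
    HYBRID_PATTERNS,
    N_EXONS,
    NO_SV_LENGTH,
    SPACER_LENGTH,
    TANDEM_UNIT_LENGTH,
    UP_LENGTH,
    AlleleDefinitionTable,
    LocusModel,
    Origin,
    ReferenceTrack,
    StructuralKind,
)

__all__ = [
    "AnchorHit",
    "GapRecord",
    "TrackAlignment",
    "StructureCall",
    "ReadFeatures",
    "CopyObservation",
    "Prober",
    "align_read_to_track",
    "detect_anchors",
    "detect_spacer_gap",
    "select_reference_track",
    "classify_structure",
    "measure_fragment_length",
]

ANCHOR_LENGTH = 500
ANCHOR_SEED_LENGTH = 31
ANCHOR_SEED_STRIDE = 8
ANCHOR_MIN_MATCH_FRACTION = 0.7
GAP_FLOOR = 200  # track-side gaps shorter than this are alignment noise
SPACER_GAP_RANGE = (1_200, 2_000)
SPACER_OVERLAP_MIN = 0.5
#: fragment-length class boundaries (bp), midway between fixture lengths
DELETION_RANGE = (20_000, 30_000)
NO_SV_RANGE = (35_000, 43_000)
TANDEM_MIN = 45_000
EXON_MAX_DIST_FRACTION = 0.35
SPACER_MAX_DIST_FRACTION = 0.25

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


@dataclass(frozen=True)
class AnchorHit:
    anchor_id: str  # FLANK_5P | FLANK_3P
    read_offset: int  # read position where the anchor window starts
    track_offset: int
    match_fraction: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.match_fraction <= 1.0:
            raise ValueError("match_fraction must be in [0, 1]")


@dataclass(frozen=True)
class GapRecord:
    """A track-side alignment gap (read is missing this track interval)."""

    start: int
    end: int
    within_spacer_window: bool

    @property
    def length(self) -> int:
        return self.end - self.start

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("gap end must exceed start")


@dataclass
class TrackAlignment:
    """Result of a semiglobal read-vs-track alignment."""

    track_id: str
    score: int
    matches: int
    mismatches: int
    gaps: list[GapRecord]
    insertions: list[tuple[int, int]]  # (track position, length), read-side
    segment_match_fraction: dict[str, float]
    unalignable: bool
    edit_distance: int
    chain: list[tuple[int, int, int, int]] = field(default_factory=list)
    """Chained anchors as (track_start, track_end, read_start, read_end)."""


@dataclass
class CopyObservation:
    """Per-read observations for one gene copy."""

    copy_index: int
    exon_origins: dict[int, Origin] = field(default_factory=dict)
    exon_found: dict[int, bool] = field(default_factory=dict)
    site_obs: dict[int, str | None] = field(default_factory=dict)
    mismatches: dict[int, str] = field(default_factory=dict)  # window pos -> alt


@dataclass
class ReadFeatures:
    """Decision features extracted from a single read."""

    read_id: str
    anchors: list[AnchorHit]
    full_span: bool
    span_length: int | None
    length_class: StructuralKind | None  # None when unclassifiable
    spacer_status: str | None  # PRESENT | ABSENT (tandem-length reads only)
    five_prime_origin: Origin | None
    copies: list[CopyObservation]
    score: int


def _iter_cigar(cigar: str):
    for m in _CIGAR_RE.finditer(cigar):
        yield int(m.group(1)), m.group(2)


def _seq_to_arr(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype="S1")


CHUNK_LENGTH = 500
CHUNK_SEED_STRIDE = 25
CHUNK_MIN_IDENTITY = 0.65
_SEED_K = ANCHOR_SEED_LENGTH  # 31-mer seeds throughout


def _track_chunks(track: ReferenceTrack) -> list[tuple[int, int]]:
    """Half-open track intervals of ~500 bp, restarting at segment edges.

    Chunk boundaries coincide with segment boundaries, so segment-scale
    structural events (the spacer, the REP-to-REP deletion block) map to
    whole runs of chunks and their gap lengths come out exact.
    """
    chunks: list[tuple[int, int]] = []
    for a, b in sorted(track.segment_map.values()):
        n = max(1, round((b - a) / CHUNK_LENGTH))
        bounds = np.linspace(a, b, n + 1).round().astype(int)
        chunks.extend((int(s), int(e)) for s, e in zip(bounds[:-1], bounds[1:]) if e > s)
    return chunks


@dataclass(frozen=True)
class _Anchor:
    track_start: int
    track_end: int
    read_start: int
    read_end: int
    score: int
    dist: int


def _chunk_candidates(
    chunk_seq: str, t0: int, t1: int, read_seq: str, index: dict[str, list[int]]
) -> list[_Anchor]:
    """Seed-and-verify candidate placements of one track chunk in the read."""
    length = t1 - t0
    starts: list[int] = []
    for off in range(0, length - _SEED_K + 1, CHUNK_SEED_STRIDE):
        for p in index.get(chunk_seq[off : off + _SEED_K], ()):
            starts.append(p - off)
    if not starts:
        return []
    starts.sort()
    clusters: list[int] = []
    for s in starts:
        if not clusters or s - clusters[-1] > 40:
            clusters.append(s)
    out: list[_Anchor] = []
    for s in clusters[:6]:
        lo = max(0, s - 40)
        hi = min(len(read_seq), s + length + 40)
        res = edlib.align(chunk_seq, read_seq[lo:hi], mode="HW", task="locations")
        dist = res["editDistance"]
        if dist < 0 or 1.0 - dist / length < CHUNK_MIN_IDENTITY:
            continue
        loc = res["locations"][0]
        out.append(
            _Anchor(t0, t1, lo + loc[0], lo + loc[1] + 1, length - 2 * dist, dist)
        )
    return out


def _chain_anchors(anchors: list[_Anchor]) -> list[_Anchor]:
    """Global sparse chaining: monotone in track and read, gap-penalized."""
    anchors = sorted(anchors, key=lambda a: (a.track_start, a.read_start))
    n = len(anchors)
    dp = np.array([float(a.score) for a in anchors])
    back = np.full(n, -1, dtype=int)
    for i, ai in enumerate(anchors):
        for j in range(i):
            aj = anchors[j]
            if aj.track_end > ai.track_start + 30 or aj.read_end > ai.read_start + 30:
                continue
            dtrack = max(0, ai.track_start - aj.track_end)
            dread = max(0, ai.read_start - aj.read_end)
            pen = 0.0 if max(dtrack, dread) < 50 else 60.0 + 0.02 * (dtrack + dread)
            cand = dp[j] + ai.score - pen
            if cand > dp[i]:
                dp[i] = cand
                back[i] = j
    if n == 0:
        return []
    i = int(np.argmax(dp))
    chain = []
    while i >= 0:
        chain.append(anchors[i])
        i = back[i]
    return chain[::-1]


def align_read_to_track(read_seq: str, track: ReferenceTrack) -> TrackAlignment:
    """Segment-aware semiglobal alignment of a read against a track.

    The engine is seed chaining with banded verification: exact 31-mer
    seeds place ~500 bp track chunks in the read, each placement is
    verified by banded local alignment, and a global chaining DP picks the
    best monotone placement set (which resolves paralog ambiguity — an
    exact gene copy outscores a 2%-diverged pseudogene copy over the whole
    chain).  Inter-anchor jumps become the structural calls: a track-side
    jump of at least ``GAP_FLOOR`` bp is a :class:`GapRecord` (the read
    lacks that track interval), a read-side jump an insertion (a tandem
    read aligned to a single-copy track carries its second gene copy as
    one such insertion).  The score is matched bases minus twice the edits
    inside verified chunks; structural gaps are not penalized.  A read
    whose verified chunks cover under 30% of it is flagged unalignable.
    """
    index: dict[str, list[int]] = {}
    for p in range(0, len(read_seq) - _SEED_K + 1):
        index.setdefault(read_seq[p : p + _SEED_K], []).append(p)

    anchors: list[_Anchor] = []
    for t0, t1 in _track_chunks(track):
        anchors.extend(
            _chunk_candidates(track.sequence[t0:t1], t0, t1, read_seq, index)
        )
    chain = _chain_anchors(anchors)

    gaps: list[GapRecord] = []
    insertions: list[tuple[int, int]] = []
    matches = mismatches = 0
    track_matched = np.zeros(track.length, dtype=float)
    for a in chain:
        matches += (a.track_end - a.track_start) - a.dist
        mismatches += a.dist
        track_matched[a.track_start : a.track_end] = 1.0 - a.dist / (
            a.track_end - a.track_start
        )

    # Track-side gaps are unmatched track runs: intervals no chain anchor
    # covers.  (Jump-based gap calls can be absorbed when the chain routes
    # around an absent element via a duplicated segment; coverage cannot.)
    uncovered = track_matched == 0
    edges = np.flatnonzero(np.diff(np.concatenate(([0], uncovered.view(np.int8), [0]))))
    for start, end in zip(edges[::2], edges[1::2]):
        if end - start < GAP_FLOOR:
            continue
        win = track.spacer_window
        within = False
        if win is not None:
            ov = min(int(end), win[1]) - max(int(start), win[0])
            within = bool(ov >= SPACER_OVERLAP_MIN * (end - start))
        gaps.append(GapRecord(int(start), int(end), within))

    # read-side insertions from net inter-anchor jumps
    bounds = (
        [_Anchor(0, 0, 0, 0, 0, 0)]
        + chain
        + [_Anchor(track.length, track.length, len(read_seq), len(read_seq), 0, 0)]
    )
    for prev, nxt in zip(bounds[:-1], bounds[1:]):
        dtrack = max(0, nxt.track_start - prev.track_end)
        dread = max(0, nxt.read_start - prev.read_end)
        if dread - dtrack >= GAP_FLOOR:
            insertions.append((prev.track_end, dread - dtrack))

    seg_match = {
        name: float(track_matched[a:b].mean())
        for name, (a, b) in track.segment_map.items()
    }
    score = matches - mismatches
    return TrackAlignment(
        track_id=track.track_id,
        score=score,
        matches=matches,
        mismatches=mismatches,
        gaps=gaps,
        insertions=insertions,
        segment_match_fraction=seg_match,
        unalignable=matches < 0.3 * len(read_seq),
        edit_distance=mismatches,
        chain=[(a.track_start, a.track_end, a.read_start, a.read_end) for a in chain],
    )


def write_sam(
    entries: list[tuple[str, str, "TrackAlignment"]], track: ReferenceTrack, path
) -> None:
    """Export segment-level alignments as SAM against the track.

    CIGARs are coarse — M runs over chained anchors with I/D for the
    inter-anchor jumps and soft clips at unanchored read ends — which is
    what a segment-aware chain alignment can honestly claim.
    """
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        fh.write(f"@SQ\tSN:{track.track_id}\tLN:{track.length}\n")
        fh.write("@PG\tID:starlocus\tPN:starlocus\n")
        for read_id, read_seq, aln in entries:
            if not aln.chain:
                fh.write(f"{read_id}\t4\t*\t0\t0\t*\t*\t0\t0\t{read_seq}\t*\n")
                continue
            ops: list[tuple[int, str]] = []
            first = aln.chain[0]
            if first[2] > 0:
                ops.append((first[2], "S"))
            prev = None
            for t0, t1, r0, r1 in aln.chain:
                if prev is not None:
                    dtrack = max(0, t0 - prev[1])
                    dread = max(0, r0 - prev[3])
                    if dread:
                        ops.append((dread, "I"))
                    if dtrack:
                        ops.append((dtrack, "D"))
                r_span, t_span = r1 - r0, t1 - t0
                m = min(r_span, t_span)
                if m:
                    ops.append((m, "M"))
                if r_span > m:
                    ops.append((r_span - m, "I"))
                elif t_span > m:
                    ops.append((t_span - m, "D"))
                prev = (t0, t1, r0, r1)
            tail = len(read_seq) - aln.chain[-1][3]
            if tail > 0:
                ops.append((tail, "S"))
            merged: list[tuple[int, str]] = []
            for n, op in ops:
                if merged and merged[-1][1] == op:
                    merged[-1] = (merged[-1][0] + n, op)
                else:
                    merged.append((n, op))
            cigar = "".join(f"{n}{op}" for n, op in merged)
            pos = aln.chain[0][0] + 1  # SAM is 1-based
            fh.write(
                f"{read_id}\t0\t{track.track_id}\t{pos}\t60\t{cigar}\t*\t0\t0\t{read_seq}\t*\n"
            )


def detect_spacer_gap(
    gaps: list[GapRecord], track: ReferenceTrack
) -> tuple[str, int | None]:
    """Decide spacer presence from alignment gaps against a spacer track.

    ABSENT means the read lacks the spacer the track carries: a gap of
    1,200-2,000 bp overlapping the spacer window by at least half its
    length.  Unrelated gaps are ignored.
    """
    if track.spacer_window is None:
        raise ValueError(f"track {track.track_id} has no spacer window")
    win = track.spacer_window
    for gap in gaps:
        if not SPACER_GAP_RANGE[0] <= gap.length <= SPACER_GAP_RANGE[1]:
            continue
        ov = min(gap.end, win[1]) - max(gap.start, win[0])
        if ov >= SPACER_OVERLAP_MIN * gap.length:
            return "ABSENT", gap.length
    return "PRESENT", None


# ---------------------------------------------------------------------------
# anchored probing


class Prober:
    """Anchored seed-and-verify feature extraction against the locus model.

    Seeds are exact 31-mers sampled every 8 bp from the 500 bp flank anchor
    windows; a hit is verified by local alignment and accepted at a match
    fraction of at least 0.7.  Exons, the 5' region and the spacer are then
    probed at chained expected offsets with banded local alignments.
    """

    def __init__(self, model: LocusModel, defs: AlleleDefinitionTable | None = None):
        self.model = model
        flank5 = model.flank_seq("FLANK_5P")
        flank3 = model.flank_seq("FLANK_3P")
        self.anchor5 = flank5[:ANCHOR_LENGTH]
        self.anchor3 = flank3[-ANCHOR_LENGTH:]
        rng = range(0, ANCHOR_LENGTH - ANCHOR_SEED_LENGTH + 1, ANCHOR_SEED_STRIDE)
        self.seeds5 = [(i, self.anchor5[i : i + ANCHOR_SEED_LENGTH]) for i in rng]
        self.seeds3 = [(i, self.anchor3[i : i + ANCHOR_SEED_LENGTH]) for i in rng]
        self.exon_refs = {
            (o, k): model.block_seq(o, f"EX{k}")
            for o in (Origin.D6, Origin.D7)
            for k in range(1, N_EXONS + 1)
        }
        self.up_refs = {o: model.block_seq(o, "UP") for o in (Origin.D6, Origin.D7)}
        self.spacer = model.spacer_seq()
        self.gene_ref = "".join(model.block_seq(Origin.D6, b) for b in
                                ["UP"] + [f"EX{k}" for k in range(1, N_EXONS + 1)] + ["DOWN"])
        self.sites_by_exon: dict[int, list[int]] = {k: [] for k in range(1, N_EXONS + 1)}
        self.site_alts: dict[int, str] = {}
        if defs is not None:
            for pos in defs.all_positions():
                k = model.exon_of_window_pos(pos)
                if k is not None:
                    self.sites_by_exon[k].append(pos)
            for row in defs.rows:
                for v in row.full_set:
                    self.site_alts.setdefault(v.pos, v.alt)

    # -- anchors ------------------------------------------------------------

    def _find_anchor(self, read_seq: str, which: str) -> AnchorHit | None:
        seeds = self.seeds5 if which == "FLANK_5P" else self.seeds3
        anchor = self.anchor5 if which == "FLANK_5P" else self.anchor3
        for off, seed in seeds:
            p = read_seq.find(seed) if which == "FLANK_5P" else read_seq.rfind(seed)
            if p < 0:
                continue
            start_est = p - off
            lo = max(0, start_est - 60)
            hi = min(len(read_seq), start_est + ANCHOR_LENGTH + 60)
            res = edlib.align(anchor, read_seq[lo:hi], mode="HW", task="locations")
            if res["editDistance"] < 0:
                continue
            mf = 1.0 - res["editDistance"] / ANCHOR_LENGTH
            if mf < ANCHOR_MIN_MATCH_FRACTION:
                continue
            loc = res["locations"][0]
            track_offset = 0 if which == "FLANK_5P" else -ANCHOR_LENGTH
            return AnchorHit(which, lo + loc[0], track_offset, round(mf, 4))
        return None

    def detect_anchors(self, read_seq: str) -> list[AnchorHit]:
        hits = []
        for which in ("FLANK_5P", "FLANK_3P"):
            hit = self._find_anchor(read_seq, which)
            if hit is not None:
                hits.append(hit)
        return hits

    # -- local probes -------------------------------------------------------

    def _probe(self, query: str, read_seq: str, lo: int, hi: int, task: str = "distance"):
        lo = max(0, lo)
        hi = min(len(read_seq), hi)
        if hi - lo < len(query) // 2:
            return None
        return edlib.align(query, read_seq[lo:hi], mode="HW", task=task), lo

    def _probe_copy(
        self, read_seq: str, copy_index: int, gene_start_est: int
    ) -> tuple[CopyObservation, int, int | None]:
        """Probe all exons of one gene copy; returns (obs, score, last_end)."""
        obs = CopyObservation(copy_index=copy_index)
        score = 0
        est = gene_start_est + UP_LENGTH
        last_end: int | None = None
        for k in range(1, N_EXONS + 1):
            d6_ref = self.exon_refs[(Origin.D6, k)]
            hit = self._probe(d6_ref, read_seq, est - 350, est + EXON_LENGTH + 350, "path")
            d7 = self._probe(self.exon_refs[(Origin.D7, k)], read_seq, est - 350, est + EXON_LENGTH + 350)
            dist6 = hit[0]["editDistance"] if hit else -1
            dist7 = d7[0]["editDistance"] if d7 else -1
            best = min(d for d in (dist6, dist7) if d >= 0) if max(dist6, dist7) >= 0 else -1
            if best < 0 or best > EXON_MAX_DIST_FRACTION * EXON_LENGTH:
                obs.exon_found[k] = False
                for pos in self.sites_by_exon[k]:
                    obs.site_obs[pos] = None
                est += EXON_LENGTH
                continue
            obs.exon_found[k] = True
            origin = Origin.D6 if dist6 <= dist7 else Origin.D7
            obs.exon_origins[k] = origin
            score += EXON_LENGTH - 2 * best
            res, lo = hit
            loc = res["locations"][0]
            if origin is Origin.D6:
                self._extract_sites(obs, read_seq, d6_ref, res["cigar"], lo + loc[0], k)
            else:
                # pseudogene-derived exon: CYP2D6 sites are not callable here
                for pos in self.sites_by_exon[k]:
                    obs.site_obs[pos] = None
            last_end = lo + loc[1] + 1
            est = last_end
        return obs, score, last_end

    def _extract_sites(
        self,
        obs: CopyObservation,
        read_seq: str,
        exon_ref: str,
        cigar: str,
        read_start: int,
        exon_k: int,
    ) -> None:
        """Walk an exon alignment, recording site observations and mismatches.

        A definition site under a read gap is recorded as MISSING (None),
        never as reference support.
        """
        exon_window_start = UP_LENGTH + (exon_k - 1) * EXON_LENGTH + 1  # 1-based
        wanted = {pos: pos - exon_window_start for pos in self.sites_by_exon[exon_k]}
        got: dict[int, str | None] = {pos: None for pos in wanted}
        aligned_at: dict[int, int] = {}
        qpos, tpos = 0, read_start  # query = exon ref, target = read
        for n, op in _iter_cigar(cigar):
            if op in ("M", "=", "X"):
                for pos, off in wanted.items():
                    if qpos <= off < qpos + n:
                        aligned_at[pos] = tpos + (off - qpos)
                a = _seq_to_arr(exon_ref[qpos : qpos + n])
                b = _seq_to_arr(read_seq[tpos : tpos + n])
                diff = np.where(a != b)[0]
                for d in diff:
                    wpos = exon_window_start + qpos + int(d)
                    obs.mismatches[wpos] = read_seq[tpos + int(d)]
                qpos += n
                tpos += n
            elif op == "I":  # exon-reference base absent from the read
                qpos += n
            elif op == "D":
                tpos += n
        for pos, read_pos in aligned_at.items():
            got[pos] = self._site_base(read_seq, pos, read_pos)
        obs.site_obs.update(got)

    SITE_CONTEXT = 20

    def _site_base(self, read_seq: str, pos: int, read_pos: int) -> str | None:
        """Base observation at a definition site by local hypothesis testing.

        Arbitrary co-optimal alignment paths can slide a substitution into a
        neighboring indel when the site borders a homopolymer-like context,
        so the read's local window is scored against the reference context
        and the alternate-base context; the closer hypothesis wins.  Ties
        and poor matches for both fall back to the path base / MISSING.
        """
        alt = self.site_alts.get(pos)
        k = self.SITE_CONTEXT
        g0 = pos - 1  # gene-relative 0-based
        ref_ctx = self.gene_ref[max(0, g0 - k) : g0 + k + 1]
        center = g0 - max(0, g0 - k)
        lo = max(0, read_pos - k - 8)
        hi = min(len(read_seq), read_pos + k + 9)
        window = read_seq[lo:hi]
        if len(window) < len(ref_ctx) // 2:
            return None
        d_ref = edlib.align(ref_ctx, window, mode="HW")["editDistance"]
        best_base, best_d = self.gene_ref[g0], d_ref
        if alt is not None:
            alt_ctx = ref_ctx[:center] + alt + ref_ctx[center + 1 :]
            d_alt = edlib.align(alt_ctx, window, mode="HW")["editDistance"]
            if d_alt < best_d:
                best_base, best_d = alt, d_alt
            elif d_alt == best_d:
                return read_seq[read_pos]  # tie: trust the path base
        if best_d > 0.35 * len(ref_ctx):
            return None
        return best_base

    # -- full read ----------------------------------------------------------

    def length_class(self, span: int) -> StructuralKind | None:
        if DELETION_RANGE[0] <= span <= DELETION_RANGE[1]:
            return StructuralKind.DELETION
        if NO_SV_RANGE[0] <= span <= NO_SV_RANGE[1]:
            return StructuralKind.NO_SV
        if span > TANDEM_MIN:
            return StructuralKind.HYBRID_TANDEM  # tandem-length; sub-typed later
        return None

    def probe_read(self, read_id: str, read_seq: str) -> ReadFeatures:
        anchors = self.detect_anchors(read_seq)
        by_id = {a.anchor_id: a for a in anchors}
        full_span = "FLANK_5P" in by_id and "FLANK_3P" in by_id
        score = sum(
            int(ANCHOR_LENGTH * (2 * a.match_fraction - 1)) for a in anchors
        )
        if not full_span:
            return ReadFeatures(read_id, anchors, False, None, None, None, None, [], score)
        a5 = by_id["FLANK_5P"]
        a3 = by_id["FLANK_3P"]
        span = (a3.read_offset + ANCHOR_LENGTH) - a5.read_offset
        klass = self.length_class(span)
        spacer_status: str | None = None
        origin5: Origin | None = None
        copies: list[CopyObservation] = []
        frag0 = a5.read_offset  # read offset of the cut-site boundary

        if klass is StructuralKind.DELETION:
            # no CYP2D6 copy to probe; verify the CYP2D7 gene region (which
            # the REP-to-REP fusion brings next to the 5' flank) for scoring
            _, s_del, _ = self._probe_copy(read_seq, -1, frag0 + GENE_START)
            score += s_del
        if klass in (StructuralKind.NO_SV, StructuralKind.HYBRID_TANDEM):
            up = self._probe_up_origin(read_seq, frag0 + GENE_START)
            if up is not None:
                origin5, up_score = up
                score += up_score
            obs0, s0, _ = self._probe_copy(read_seq, 0, frag0 + GENE_START)
            copies.append(obs0)
            score += s0
        if klass is StructuralKind.HYBRID_TANDEM:
            spacer_status, sp_score = self._probe_spacer(read_seq, frag0 + GENE_START + GENE_LENGTH)
            score += sp_score
            obs1, s1, _ = self._probe_copy(
                read_seq, 1, frag0 + GENE_START + TANDEM_UNIT_LENGTH
            )
            copies.append(obs1)
            score += s1
        return ReadFeatures(
            read_id=read_id,
            anchors=anchors,
            full_span=True,
            span_length=span,
            length_class=klass,
            spacer_status=spacer_status,
            five_prime_origin=origin5,
            copies=copies,
            score=score,
        )

    def _probe_up_origin(self, read_seq: str, up_start_est: int):
        lo, hi = up_start_est - 350, up_start_est + UP_LENGTH + 350
        d6 = self._probe(self.up_refs[Origin.D6], read_seq, lo, hi)
        d7 = self._probe(self.up_refs[Origin.D7], read_seq, lo, hi)
        if d6 is None or d7 is None:
            return None
        dist6, dist7 = d6[0]["editDistance"], d7[0]["editDistance"]
        best = min(dist6, dist7)
        if best > EXON_MAX_DIST_FRACTION * UP_LENGTH:
            return None
        return (Origin.D6 if dist6 <= dist7 else Origin.D7), UP_LENGTH - 2 * best

    def _probe_spacer(self, read_seq: str, spacer_start_est: int) -> tuple[str, int]:
        lo = spacer_start_est - 700
        hi = spacer_start_est + SPACER_LENGTH + 700
        res = self._probe(self.spacer, read_seq, lo, hi)
        if res is None:
            return "ABSENT", 0
        dist = res[0]["editDistance"]
        if 0 <= dist <= SPACER_MAX_DIST_FRACTION * SPACER_LENGTH:
            return "PRESENT", SPACER_LENGTH - 2 * dist
        return "ABSENT", 0


def detect_anchors(read_seq: str, model_or_prober) -> list[AnchorHit]:
    """Locate the 5' and 3' flank anchors of the targeted region in a read."""
    prober = (
        model_or_prober
        if isinstance(model_or_prober, Prober)
        else Prober(model_or_prober)
    )
    return prober.detect_anchors(read_seq)


# ---------------------------------------------------------------------------
# track selection and classification


def select_reference_track(features: ReadFeatures) -> str:
    """Choose the reference track for a read from its decision features.

    Reference-length and deletion-length reads go to the standard track;
    tandem-length reads with a CYP2D7-like 5' region plus spacer go to
    track A, CYP2D6-like without spacer to track B.  Tandem-length reads
    matching neither pattern are surfaced as UNCLASSIFIED, never defaulted.
    """
    if features.length_class in (StructuralKind.NO_SV, StructuralKind.DELETION):
        return "REF"
    if features.length_class is StructuralKind.HYBRID_TANDEM:
        if features.spacer_status == "PRESENT" and features.five_prime_origin is Origin.D7:
            return "A"
        if features.spacer_status == "ABSENT" and features.five_prime_origin is Origin.D6:
            return "B"
    return "UNCLASSIFIED"


@dataclass
class StructureCall:
    """Per-allele structural classification."""

    kind: StructuralKind | None  # None encodes NO_CALL
    selected_track: str | None
    five_prime_origin: Origin | None
    spacer_present_in_tandem_copy: bool | None
    breakpoints: list[tuple[int, int]]
    fragment_length_bp: int | None
    n_reads: int
    copy_exon_origins: list[dict[int, Origin]] = field(default_factory=list)
    reason: str | None = None

    @property
    def is_call(self) -> bool:
        return self.kind is not None


def _majority(values) -> object | None:
    """Strict majority vote; ties resolve to None (conservative NO_CALL)."""
    counts = Counter(v for v in values if v is not None)
    if not counts:
        return None
    ranked = counts.most_common()
    if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
        return None
    return ranked[0][0]


def measure_fragment_length(group, use_truth: bool = True) -> int:
    """Median cut-to-cut fragment length of a read group, integer bp.

    Accepts simulated reads carrying truth lengths, or
    :class:`ReadFeatures` (anchored span estimates).
    """
    if not group:
        raise ValueError("empty read group")
    if use_truth and hasattr(group[0], "fragment_length"):
        vals = [r.fragment_length for r in group]
    else:
        vals = [f.span_length for f in group if f.span_length is not None]
        if not vals:
            raise ValueError("no spanning reads in group")
    return int(round(float(np.median(vals))))


def classify_structure(
    group: list[ReadFeatures],
    min_reads: int = 3,
    reads_by_id: dict[str, str] | None = None,
    tracks: dict[str, ReferenceTrack] | None = None,
) -> StructureCall:
    """Majority-vote structural classification of one allele's read group.

    Per-read length classes, spacer statuses, 5'-region origins and
    per-exon origin calls are combined by strict majority; ties and
    unclassifiable patterns surface as NO_CALL / UNCLASSIFIED rather than
    defaulting to the no-SV configuration.  When raw reads and tracks are
    supplied, breakpoints are estimated from semiglobal alignments of up to
    three reads.
    """
    n = len(group)
    if n < min_reads:
        return StructureCall(
            None, None, None, None, [], None, n, reason=f"fewer than {min_reads} reads"
        )
    kind = _majority([f.length_class for f in group])
    if kind is None:
        return StructureCall(None, None, None, None, [], None, n, reason="ambiguous fragment length")
    frag_len = measure_fragment_length(group, use_truth=False)

    if kind in (StructuralKind.NO_SV, StructuralKind.DELETION):
        track = "REF"
        origin5 = _majority([f.five_prime_origin for f in group])
        exon_origins = _consensus_exon_origins(group, 0) if kind is StructuralKind.NO_SV else []
        call = StructureCall(
            kind,
            track,
            origin5 if kind is StructuralKind.NO_SV else None,
            None,
            [],
            frag_len,
            n,
            copy_exon_origins=exon_origins,
        )
    else:
        track = _majority([select_reference_track(f) for f in group])
        if track in (None, "UNCLASSIFIED"):
            return StructureCall(
                None, "UNCLASSIFIED", None, None, [], frag_len, n,
                reason="tandem-length reads match neither track pattern",
            )
        spacer = _majority([f.spacer_status for f in group]) == "PRESENT"
        origin5 = _majority([f.five_prime_origin for f in group])
        exon_origins = _consensus_exon_origins(group, 0) + _consensus_exon_origins(group, 1)
        hybrid = any(
            o is Origin.D7 for omap in exon_origins for o in omap.values()
        )
        kind = StructuralKind.HYBRID_TANDEM if hybrid else StructuralKind.DUPLICATION
        call = StructureCall(
            kind, track, origin5, spacer, [], frag_len, n, copy_exon_origins=exon_origins
        )

    if call.kind is StructuralKind.DELETION and call.fragment_length_bp >= NO_SV_LENGTH:
        return StructureCall(None, None, None, None, [], frag_len, n, reason="inconsistent deletion length")
    if reads_by_id and tracks and call.selected_track:
        call.breakpoints = _estimate_breakpoints(call, group, reads_by_id, tracks)
    return call


def _consensus_exon_origins(group: list[ReadFeatures], copy_index: int) -> list[dict[int, Origin]]:
    per_exon: dict[int, list[Origin]] = {}
    seen = False
    for f in group:
        for obs in f.copies:
            if obs.copy_index == copy_index:
                seen = True
                for k, o in obs.exon_origins.items():
                    per_exon.setdefault(k, []).append(o)
    if not seen:
        return []
    return [{k: m for k in sorted(per_exon) if (m := _majority(per_exon[k])) is not None}]


def _estimate_breakpoints(
    call: StructureCall,
    group: list[ReadFeatures],
    reads_by_id: dict[str, str],
    tracks: dict[str, ReferenceTrack],
) -> list[tuple[int, int]]:
    track = tracks[call.selected_track]
    starts: list[int] = []
    ends: list[int] = []
    for f in group[:3]:
        seq = reads_by_id.get(f.read_id)
        if seq is None:
            continue
        aln = align_read_to_track(seq, track)
        if call.kind is StructuralKind.DELETION:
            big = [g for g in aln.gaps if g.length >= 5_000]
            if big:
                starts.append(big[0].start)
                ends.append(big[0].end)
        else:
            big = [iv for iv in aln.insertions if iv[1] >= 5_000]
            if big:
                starts.append(big[0][0])
                ends.append(big[0][0] + big[0][1])
    if not starts:
        return []
    return [(int(np.median(starts)), int(np.median(ends)))]
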