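# Methods

## The synthetic locus

The package operates on a synthetic stand-in for the excised
*CYP2D6–CYP2D7–CYP2D8* fragment rather than GRCh38 sequence. The layout is
an ordered segment table (5′→3′ between the two CRISPR cut sites):

| segment | length (bp) | notes |
|---|---|---|
| FLANK_5P | 649 | carries the 5′ cut site; 500 bp anchor window |
| CYP2D6 gene | 8,000 | 1,500 UP + 9 × 600 exon blocks + 1,100 DOWN |
| REP6 | 551 | |
| intergenic 1 | 6,000 | |
| CYP2D7 gene | 8,000 | 2%-diverged copy of the CYP2D6 blocks |
| SPACER | 1,560 | present only in CYP2D7-derived downstream regions |
| REP7 | 551 | 2%-diverged copy of REP6 |
| intergenic 2 | 4,000 | |
| CYP2D8 gene | 8,000 | 2%-diverged copy |
| intergenic 3 | 1,592 | |
| FLANK_3P | 648 | carries the 3′ cut site |

Totals are chosen as exact integers reproducing the assay's printed
coordinate arithmetic: the cut-to-cut no-SV fragment is 39,551 bp (the
inclusive span of chr22:42,122,008–42,161,558) and the analysis window is
38,254 bp (chr22:42,123,069–42,161,322), opening at the CYP2D6 gene start.
Structural alleles are segment edits: the \*5 deletion removes a
14,551 bp REP-to-REP block (gene + REP6 + intergenic 1), giving 25,000 bp;
duplications and hybrid tandems insert a 12,449 bp duplicated-position
unit 5′ of the CYP2D6 position, giving 52,000 bp. Track-A-type units
(CYP2D7-like 5′ region, downstream spacer) and track-B-type units
(CYP2D6-like, no spacer) both total 12,449 bp, so all tandem classes
present the same 52 kb fragment, as the assay's fragment spectrum does.

Sequence content is seeded-uniform. Two devices substitute for real
paralog structure: pseudogene gene blocks are copies of the CYP2D6 blocks
substituted at a flat 2% (the divergence that makes CYP2D6/2D7
discrimination hard but possible), and each gene block carries
origin-specific marker 31-mers every 500 bp so block origin stays
identifiable at nanopore error rates. Fixture allele definitions put all
SNVs inside CYP2D6 exons, clear of the marker windows; hybrid alleles
(\*36, \*68, \*13) are defined by exon-origin patterns, not SNVs.

One deliberate simplification: the fixture \*13 is modeled with a
CYP2D7-derived exon 1 on an otherwise CYP2D6-like copy (CYP2D6-like 5′
region, no spacer), which is what routes \*13+\*2 tandems to custom track
B. The real \*13 has a CYP2D7-derived upstream region as well; the
simplification preserves the track-selection behavior the pipeline tests.

## Custom reference tracks

Track REF is the no-SV layout. Tracks A and B are single-gene-region
layouts carrying the duplicated-position copy's distinguishing features in
place: track A swaps the gene's UP/DOWN blocks for the CYP2D7 versions and
inserts the 1,560 bp spacer after the gene (41,111 bp total); track B is
the CYP2D6-like, spacer-free equivalent (39,551 bp). The two tracks
therefore differ by exactly the spacer length. Against track A, a read
*without* the spacer (no-SV, duplication, \*13 tandem) shows a single
1,560 bp gap inside the spacer window; a read *with* it (\*36, \*68
tandems) covers the window and carries its second gene copy as a read-side
insertion. This single-copy design is what makes the spacer gap the clean,
binary signal the classifier consumes; per-copy variant calling does not
need a two-copy track because the anchored prober addresses each copy at
its expected offset directly.

## Alignment

Two engines, one contract:

- The **anchored prober** (hot path, ~5 ms/read) finds the two flank
  anchors by exact 31-mer seeds (every 8 bp of a 500 bp anchor window)
  verified by banded local alignment at ≥ 0.7 match fraction, then probes
  exons, the 5′ region and the spacer at chained expected offsets with
  banded edlib alignments. Exon origin is the smaller of the edit
  distances to the CYP2D6 vs CYP2D7 exon reference.
- The **track aligner** (`align_read_to_track`) is seed chaining with
  banded verification: ~500 bp track chunks (boundaries snapped to segment
  edges) are placed in the read by exact 31-mer seeds, verified by banded
  alignment, and a global chaining DP (monotone in track and read,
  jump-penalized) picks the best placement set. Global chaining is what
  resolves paralog ambiguity: an exact gene copy outscores a 2%-diverged
  pseudogene copy over the whole chain. Track-side gaps are reported as
  *uncovered track runs* ≥ 200 bp — not as chain jumps, which can absorb
  an absent element when the chain routes around it via a duplicated
  segment. Unit-cost aligners (edlib has no affine gaps) otherwise prefer
  mismatch-storms over contiguous gaps, which is why a plain end-to-end
  alignment cannot produce the spacer-gap signal.

The "DP alignment score" gate is defined on the prober's verified blocks:
sum of (block length − 2 × edits) over anchors, exons and spacer. An
error-free full-span read scores ~8,000–15,000; the default threshold of
1,000 passes all full-span reads at default error rates and fails reads
with under half their bases matching (anchors alone cap an unverifiable
read below the threshold).

Site observations at definition positions are extracted by local
hypothesis testing rather than read off the alignment path: the read
window around the aligned site is scored against the reference context
and the alternate-base context (±20 bp), and the closer hypothesis wins.
Arbitrary co-optimal paths otherwise slide substitutions into neighboring
indels when a site borders a homopolymer-like context, deflating variant
support by tens of percent.

## Classification and calling

Per-read features vote, per-allele calls are strict majorities, and ties
go to NO_CALL, never to a default structure. Fragment-length classes are
deletion 20–30 kb, no-SV 35–43 kb, tandem > 45 kb (midpoints between the
fixture lengths); tandem-length reads are sub-typed by spacer status and
5′-region origin (A: CYP2D7-like + spacer; B: CYP2D6-like, none; other
combinations surface as UNCLASSIFIED). Duplication vs hybrid tandem is
decided by per-exon origin consensus: any CYP2D7-origin exon in either
copy makes it a hybrid. Breakpoints are medians over seed-chain
alignments of up to three reads per cluster.

Clustering is two-stage. Reads first split by structural signature
(length class, spacer status, 5′ origin) — any sample with one SV allele
separates here. Structurally homogeneous samples are split by
average-linkage agglomerative clustering on Hamming distance over
*candidate heterozygous sites* (second-most-common base ≥ 25% of
observations); restricting to het sites keeps the distances clean when
alleles differ at one or two suballele-level positions, and sites carry
only their two major bases so sporadic error bases cannot create flat
dendrogram ties. No het sites means a homozygous sample (one cluster,
reported twice). Consensus calling uses a 0.7 site majority at minimum
depth 3, with MISSING observations (read gaps, pseudogene-origin exons)
never counted as reference support. Non-definition sites enter the
profile when the same non-reference base recurs in ≥ 30% of a cluster's
reads, which is how novel suballeles are detected.

Star assignment is containment-maximal: the core allele is the one with
the most defining variants all present (ties go to the lowest numeric
star id and are flagged AMBIGUOUS); an exact full-set match names the
suballele; leftovers make a NOVEL call labelled `<core>.new1` (registry
numbers are never auto-assigned). Hybrid copies are matched by exon-origin
pattern + spacer against the known hybrid registry. Diplotypes print the
5′ (duplicated-position) copy first, `x2` for identical duplicated copies,
alleles ordered by numeric core id.

## Simulation defaults

Substitution 0.02, insertion 0.015, deletion 0.02 per base (≈5.5% total,
matching mean read PHRED ≈ 14), quality ~N(14, 3²) clipped to 2–41,
truncation probability 0.15 with retained fraction U(0.3, 0.95) — enough
truncated reads to exercise the full-span gate. Depth is a per-allele read
count (each read is a whole fragment), default 40 per allele, comfortably
above the ≥ 35 full-span sample gate after truncation losses. Error rates
are flat: no homopolymer-aware weighting, no quality/error correlation,
no adapter or chimeric reads. Reads are emitted in shuffled allele order.
All randomness flows from a single seed through spawned generators, so
outputs are byte-reproducible.

What passing tests do and do not show: the simulator reproduces the
fragment-length spectrum, pseudogene-like divergence, suballele-level
heterozygosity and span censoring, so recovery results demonstrate the
pipeline's logic end to end. They do not demonstrate robustness to real
nanopore artifacts (systematic homopolymer error, strand bias, basecaller
miscalls correlated along the read), to real CYP2D6/2D7 gene-conversion
mosaics beyond the fixture hybrid patterns, or to rare structural classes
(multi-copy amplifications, \*68x2 stacks) outside the four modeled
classes.

## Numerical and policy choices

- Coordinates: 0-based half-open internally; 1-based inclusive in every
  human-readable report and the VCF.
- Sample gate: `full-span reads ≥ 35` (35 passes, 34 fails).
- Spacer acceptance: gap length 1,200–2,000 bp with ≥ 50% overlap of the
  spacer window — tolerant of indel noise around a 1,560 bp event.
- Gap reporting floor 200 bp; per-group minimum 3 reads for a structure
  call; homozygosity declared only when candidate clusters differ at zero
  profiled sites after noise filtering.
- Mean read quality is computed in probability space (PHRED → error
  probability → mean → PHRED), so low-quality bases dominate, as they
  should.
- Problem sizes in the test and acceptance runs (depth 40/allele, 20
  replicates per structural class, depth 100 for consensus recovery) keep
  a full run in minutes on one CPU while leaving every statistical
  assertion at ≥ 3 SE or ≥ 95% recovery margins.
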