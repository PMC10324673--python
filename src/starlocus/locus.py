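"""Synthetic segmental model of the CYP2D6-CYP2D7-CYP2D8 excision locus.

The real locus spans ~39.5 kb of chromosome 22 and contains the functional
CYP2D6 gene plus the highly similar CYP2D7 and CYP2D8 pseudogenes, REP
repeats involved in recombination, and a ~1.56 kb spacer element found only
in CYP2D7-derived downstream regions.  Structural alleles (full-gene
deletions, duplications and CYP2D6/2D7 hybrid tandems) rearrange these
segments, producing CRISPR-excised fragments of ~25 kb to ~52 kb.

This module builds a deterministic synthetic stand-in for that locus:

* a reference (no-SV) cut-to-cut fragment of exactly 39,551 bp with an
  analysis window of 38,254 bp (the inclusive spans of the genomic anchor
  coordinates of the assay, chr22:42,122,008-42,161,558 and
  chr22:42,123,069-42,161,322);
* haplotype sequences for the four supported structural classes
  (no-SV 39,551 bp; deletion 25,000 bp; duplication / hybrid tandem
  52,000 bp);
* custom reference tracks A and B used for structural-variant triage
  (track A carries a CYP2D7-like 5' region and the spacer at the
  duplicated-position copy; track B is CYP2D6-like with no spacer);
* in-silico CRISPR digestion (protospacer + NGG PAM scanning with the
  blunt cut 3 bp 5' of the PAM);
* the allele-definition table (star alleles, suballeles, core / suballele
  variant sets, structural kinds) and diplotype nomenclature parsing.

Sequence realism is replaced by two explicit devices: pseudogene segments
are 2%-diverged copies of their CYP2D6 counterparts, and every gene block
carries origin-specific marker 31-mers every 500 bp so segment origin stays
identifiable at nanopore error rates.  Coordinates are 0-based half-open
internally; all human-readable reports use 1-based inclusive positions.
"""

from __future__ import annotations

import enum
import json
import re
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Role",
    "Origin",
    "StructuralKind",
    "Segment",
    "LocusSpec",
    "LocusModel",
    "Haplotype",
    "ReferenceTrack",
    "Variant",
    "AlleleDefRow",
    "AlleleDefinitionTable",
    "HybridPattern",
    "HYBRID_PATTERNS",
    "AlleleSpec",
    "CopySpec",
    "inclusive_span",
    "build_reference_locus",
    "build_haplotype_sequence",
    "build_custom_track",
    "find_cut_sites",
    "digest",
    "default_locus_spec",
    "default_allele_definitions",
    "load_allele_definitions",
    "write_allele_definitions",
    "parse_allele",
    "parse_diplotype",
]

BASES = np.frombuffer(b"ACGT", dtype="S1")

# Genomic anchor coordinates of the assay (GRCh38 chr22, 1-based inclusive).
CUT_REGION_START = 42_122_008
CUT_REGION_END = 42_161_558
ANALYSIS_REGION_START = 42_123_069
ANALYSIS_REGION_END = 42_161_322

#: fixture fragment lengths, cut site to cut site
NO_SV_LENGTH = 39_551
DELETION_LENGTH = 25_000
TANDEM_LENGTH = 52_000
SPACER_LENGTH = 1_560
#: length of the duplicated-position unit inserted 5' of the CYP2D6 position
TANDEM_UNIT_LENGTH = TANDEM_LENGTH - NO_SV_LENGTH  # 12,449
#: length of the REP6-to-REP7 fusion block removed by the *5 deletion
DELETION_BLOCK_LENGTH = NO_SV_LENGTH - DELETION_LENGTH  # 14,551

ANALYSIS_WINDOW_LENGTH = ANALYSIS_REGION_END - ANALYSIS_REGION_START + 1  # 38,254

N_EXONS = 9
EXON_LENGTH = 600
UP_LENGTH = 1_500
DOWN_LENGTH = 1_100
GENE_LENGTH = UP_LENGTH + N_EXONS * EXON_LENGTH + DOWN_LENGTH  # 8,000
REP_LENGTH = 551
MARKER_LENGTH = 31
MARKER_SPACING = 500
PARALOG_DIVERGENCE = 0.02

FLANK_5P_LENGTH = 649
FLANK_3P_LENGTH = 648
I1_LENGTH = 6_000
I2_LENGTH = 4_000
I3_LENGTH = 1_592
LINK_A_LENGTH = TANDEM_UNIT_LENGTH - GENE_LENGTH - SPACER_LENGTH - REP_LENGTH  # 2,338
LINK_B_LENGTH = TANDEM_UNIT_LENGTH - GENE_LENGTH - REP_LENGTH  # 3,898

#: fragment offset at which the gene region (and the analysis window) starts
GENE_START = FLANK_5P_LENGTH  # 649


def inclusive_span(start: int, end: int) -> int:
    """Length in bp of a 1-based inclusive genomic interval ``start..end``."""
    if end < start:
        raise ValueError(f"end {end} < start {start}")
    return end - start + 1


class Role(str, enum.Enum):
    GENE_D6 = "GENE_D6"
    GENE_D7 = "GENE_D7"
    GENE_D8 = "GENE_D8"
    REP6 = "REP6"
    REP7 = "REP7"
    SPACER = "SPACER"
    INTERGENIC = "INTERGENIC"
    FLANK_5P = "FLANK_5P"
    FLANK_3P = "FLANK_3P"


class Origin(str, enum.Enum):
    D6 = "D6"
    D7 = "D7"
    D8 = "D8"
    NEUTRAL = "NEUTRAL"


class StructuralKind(str, enum.Enum):
    NO_SV = "NO_SV"
    DELETION = "DELETION"
    DUPLICATION = "DUPLICATION"
    HYBRID_TANDEM = "HYBRID_TANDEM"
    NONE = "NONE"  # definition-table rows without a structural component


@dataclass(frozen=True)
class Segment:
    name: str
    role: Role
    length: int
    origin: Origin

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"segment {self.name}: length must be > 0, got {self.length}")


def _gene_segments(prefix: str, role: Role, origin: Origin) -> list[Segment]:
    segs = [Segment(f"{prefix}_UP", role, UP_LENGTH, origin)]
    segs += [Segment(f"{prefix}_EX{k}", role, EXON_LENGTH, origin) for k in range(1, N_EXONS + 1)]
    segs.append(Segment(f"{prefix}_DOWN", role, DOWN_LENGTH, origin))
    return segs


def default_locus_spec() -> "LocusSpec":
    """The fixture layout: 39,551 bp cut-to-cut, 38,254 bp analysis window."""
    segments = [
        Segment("FLANK_5P", Role.FLANK_5P, FLANK_5P_LENGTH, Origin.NEUTRAL),
        *_gene_segments("D6", Role.GENE_D6, Origin.D6),
        Segment("REP6", Role.REP6, REP_LENGTH, Origin.NEUTRAL),
        Segment("I1", Role.INTERGENIC, I1_LENGTH, Origin.NEUTRAL),
        *_gene_segments("D7", Role.GENE_D7, Origin.D7),
        Segment("SPACER", Role.SPACER, SPACER_LENGTH, Origin.D7),
        Segment("REP7", Role.REP7, REP_LENGTH, Origin.NEUTRAL),
        Segment("I2", Role.INTERGENIC, I2_LENGTH, Origin.NEUTRAL),
        *_gene_segments("D8", Role.GENE_D8, Origin.D8),
        Segment("I3", Role.INTERGENIC, I3_LENGTH, Origin.NEUTRAL),
        Segment("FLANK_3P", Role.FLANK_3P, FLANK_3P_LENGTH, Origin.NEUTRAL),
    ]
    total = sum(s.length for s in segments)
    window_start = GENE_START
    return LocusSpec(
        segments=segments,
        cut_site_5p=0,
        cut_site_3p=total,
        analysis_window=(window_start, window_start + ANALYSIS_WINDOW_LENGTH),
    )


@dataclass
class LocusSpec:
    """Ordered segment model of the excision fragment.

    ``cut_site_5p``/``cut_site_3p`` are fragment coordinates (0-based) of the
    two CRISPR cuts; ``analysis_window`` is the half-open sub-interval used
    for variant calling.
    """

    segments: list[Segment]
    cut_site_5p: int
    cut_site_3p: int
    analysis_window: tuple[int, int]

    def __post_init__(self) -> None:
        names = [s.name for s in self.segments]
        if len(set(names)) != len(names):
            raise ValueError("segment names must be unique")
        spacers = [s for s in self.segments if s.role is Role.SPACER]
        if len(spacers) != 1:
            raise ValueError(f"expected exactly one SPACER segment, got {len(spacers)}")
        if self.cut_site_3p - self.cut_site_5p != self.total_length:
            raise ValueError("cut-to-cut span must equal the sum of segment lengths")
        for cut in (self.cut_site_5p, self.cut_site_3p):
            seg = self.segment_at(min(cut, self.total_length - 1))
            if cut not in (0, self.total_length) and seg.role not in (Role.FLANK_5P, Role.FLANK_3P):
                raise ValueError("cut sites must lie in FLANK segments")

    @property
    def total_length(self) -> int:
        return sum(s.length for s in self.segments)

    @property
    def window_length(self) -> int:
        return self.analysis_window[1] - self.analysis_window[0]

    def offsets(self) -> dict[str, tuple[int, int]]:
        """Half-open fragment interval of each segment, in layout order."""
        out: dict[str, tuple[int, int]] = {}
        pos = 0
        for s in self.segments:
            out[s.name] = (pos, pos + s.length)
            pos += s.length
        return out

    def segment_at(self, pos: int) -> Segment:
        for s, (a, b) in zip(self.segments, self.offsets().values()):
            if a <= pos < b:
                return s
        raise IndexError(f"position {pos} outside the fragment")

    def window_to_fragment(self, window_pos_1based: int) -> int:
        """Map a 1-based analysis-window position to a 0-based fragment offset."""
        if not 1 <= window_pos_1based <= self.window_length:
            raise ValueError(f"window position {window_pos_1based} outside 1..{self.window_length}")
        return self.analysis_window[0] + window_pos_1based - 1

    def to_config(self) -> dict:
        return {
            "segments": [
                {"name": s.name, "role": s.role.value, "length": s.length, "origin": s.origin.value}
                for s in self.segments
            ],
            "cut_site_5p": self.cut_site_5p,
            "cut_site_3p": self.cut_site_3p,
            "analysis_window": list(self.analysis_window),
        }

    @classmethod
    def from_config(cls, cfg: dict) -> "LocusSpec":
        segments = [
            Segment(d["name"], Role(d["role"]), int(d["length"]), Origin(d["origin"]))
            for d in cfg["segments"]
        ]
        return cls(
            segments=segments,
            cut_site_5p=int(cfg["cut_site_5p"]),
            cut_site_3p=int(cfg["cut_site_3p"]),
            analysis_window=tuple(cfg["analysis_window"]),  # type: ignore[arg-type]
        )


# ---------------------------------------------------------------------------
# sequence construction


def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return BASES[rng.integers(0, 4, n)]


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Return a copy of ``seq`` with each base substituted at ``rate``."""
    out = seq.copy()
    hit = np.where(rng.random(seq.size) < rate)[0]
    if hit.size:
        # substitute with one of the three other bases
        shift = rng.integers(1, 4, hit.size)
        idx = np.searchsorted(BASES, out[hit])
        out[hit] = BASES[(idx + shift) % 4]
    return out


GENE_BLOCKS = ["UP"] + [f"EX{k}" for k in range(1, N_EXONS + 1)] + ["DOWN"]
_BLOCK_LENGTHS = {"UP": UP_LENGTH, "DOWN": DOWN_LENGTH}
_BLOCK_LENGTHS.update({f"EX{k}": EXON_LENGTH for k in range(1, N_EXONS + 1)})


@dataclass(frozen=True)
class Variant:
    """A substitution in 1-based analysis-window coordinates."""

    pos: int
    ref: str
    alt: str

    def __str__(self) -> str:
        return f"{self.pos}:{self.ref}>{self.alt}"

    @classmethod
    def parse(cls, text: str) -> "Variant":
        m = re.fullmatch(r"(\d+):([ACGT])>([ACGT])", text.strip())
        if not m:
            raise ValueError(f"malformed variant {text!r} (expected pos:ref>alt)")
        return cls(int(m.group(1)), m.group(2), m.group(3))


@dataclass(frozen=True)
class HybridPattern:
    """Exon-origin signature of a CYP2D6/CYP2D7 hybrid star allele."""

    star: str
    d7_exons: frozenset[int]
    up_origin: Origin
    down_origin: Origin
    spacer: bool  # spacer element in the copy's downstream region


#: Hybrid star alleles supported by the fixture.  *36 and *68 carry a
#: CYP2D7-like 5' region and downstream spacer (custom track A); the fixture
#: *13 carries a CYP2D7-derived exon 1 on a CYP2D6-like backbone with no
#: spacer (custom track B).
HYBRID_PATTERNS: dict[str, HybridPattern] = {
    "*36": HybridPattern("*36", frozenset({9}), Origin.D7, Origin.D7, True),
    "*68": HybridPattern("*68", frozenset(range(2, N_EXONS + 1)), Origin.D7, Origin.D7, True),
    "*13": HybridPattern("*13", frozenset({1}), Origin.D6, Origin.D6, False),
}


class LocusModel:
    """Concrete sequence realization of a :class:`LocusSpec`.

    Holds the per-origin gene block sequences, neutral segments and the
    reference fragment, and constructs haplotypes, custom tracks and
    structure-resolved calling layouts from them.  Fully deterministic for a
    given seed.
    """

    def __init__(self, spec: LocusSpec | None = None, seed: int = 7):
        self.spec = spec if spec is not None else default_locus_spec()
        self.seed = int(seed)
        rng = np.random.default_rng(self.seed)

        lengths = {s.name: s.length for s in self.spec.segments}
        self.neutral: dict[str, np.ndarray] = {}
        for name in ("FLANK_5P", "REP6", "I1", "I2", "I3", "FLANK_3P", "SPACER"):
            self.neutral[name] = _random_seq(rng, lengths.get(name, _DEFAULT_NEUTRAL.get(name, 0)))
        self.neutral["REP7"] = _mutate(self.neutral["REP6"], PARALOG_DIVERGENCE, rng)

        # D6 gene blocks, then paralogs as 2%-diverged copies, then
        # origin-specific marker 31-mers planted every 500 bp.
        d6_plain = {b: _random_seq(rng, _BLOCK_LENGTHS[b]) for b in GENE_BLOCKS}
        self.blocks: dict[tuple[Origin, str], np.ndarray] = {}
        for origin in (Origin.D6, Origin.D7, Origin.D8):
            for b in GENE_BLOCKS:
                seq = (
                    d6_plain[b].copy()
                    if origin is Origin.D6
                    else _mutate(d6_plain[b], PARALOG_DIVERGENCE, rng)
                )
                self.blocks[(origin, b)] = seq
        for origin in (Origin.D6, Origin.D7, Origin.D8):
            for b in GENE_BLOCKS:
                seq = self.blocks[(origin, b)]
                for off in range(MARKER_SPACING // 2, seq.size - MARKER_LENGTH + 1, MARKER_SPACING):
                    seq[off : off + MARKER_LENGTH] = _random_seq(rng, MARKER_LENGTH)

        self.reference = self._assemble_reference()
        if self.reference.size != self.spec.total_length:
            raise AssertionError("reference length does not match the segment table")

    # -- assembly helpers ---------------------------------------------------

    def gene_array(
        self,
        d7_exons: frozenset[int] = frozenset(),
        up_origin: Origin = Origin.D6,
        down_origin: Origin = Origin.D6,
        variants: tuple[Variant, ...] = (),
        origin: Origin = Origin.D6,
    ) -> np.ndarray:
        """Gene region (UP + 9 exons + DOWN) with per-block origins and SNVs.

        ``variants`` are 1-based window positions, which coincide with
        1-based gene-relative positions because the gene region opens the
        analysis window.
        """
        if origin is not Origin.D6:
            parts = [self.blocks[(origin, b)] for b in GENE_BLOCKS]
            return np.concatenate(parts)
        parts = [self.blocks[(up_origin, "UP")]]
        for k in range(1, N_EXONS + 1):
            src = Origin.D7 if k in d7_exons else Origin.D6
            parts.append(self.blocks[(src, f"EX{k}")])
        parts.append(self.blocks[(down_origin, "DOWN")])
        gene = np.concatenate(parts).copy()
        for v in variants:
            off = v.pos - 1
            if not 0 <= off < gene.size:
                raise ValueError(f"variant {v} outside the gene region")
            if gene[off].tobytes().decode() != v.ref:
                raise ValueError(
                    f"variant {v}: reference base is {gene[off].tobytes().decode()}"
                )
            gene[off] = np.bytes_(v.alt.encode())
        return gene

    def _assemble_reference(self) -> np.ndarray:
        parts = [
            self.neutral["FLANK_5P"],
            self.gene_array(),
            self.neutral["REP6"],
            self.neutral["I1"],
            self.gene_array(origin=Origin.D7),
            self.neutral["SPACER"],
            self.neutral["REP7"],
            self.neutral["I2"],
            self.gene_array(origin=Origin.D8),
            self.neutral["I3"],
            self.neutral["FLANK_3P"],
        ]
        return np.concatenate(parts)

    def reference_seq(self) -> str:
        return self.reference.tobytes().decode()

    def block_seq(self, origin: Origin, block: str) -> str:
        return self.blocks[(origin, block)].tobytes().decode()

    def flank_seq(self, which: str) -> str:
        return self.neutral[which].tobytes().decode()

    def spacer_seq(self) -> str:
        return self.neutral["SPACER"].tobytes().decode()

    def window_ref_base(self, window_pos_1based: int) -> str:
        off = self.spec.window_to_fragment(window_pos_1based)
        return self.reference[off].tobytes().decode()

    def exon_of_window_pos(self, pos: int) -> int | None:
        """Exon number (1..9) containing a 1-based window position, if any."""
        rel = pos - 1 - UP_LENGTH
        if 0 <= rel < N_EXONS * EXON_LENGTH:
            return rel // EXON_LENGTH + 1
        return None


_DEFAULT_NEUTRAL = {
    "FLANK_5P": FLANK_5P_LENGTH,
    "REP6": REP_LENGTH,
    "I1": I1_LENGTH,
    "I2": I2_LENGTH,
    "I3": I3_LENGTH,
    "FLANK_3P": FLANK_3P_LENGTH,
    "SPACER": SPACER_LENGTH,
}


def build_reference_locus(
    spec: LocusSpec | None = None, seed: int = 7
) -> tuple[LocusModel, str]:
    """Build the locus model and its reference cut-to-cut sequence."""
    model = LocusModel(spec, seed=seed)
    return model, model.reference_seq()


# ---------------------------------------------------------------------------
# allele definitions


@dataclass(frozen=True)
class AlleleDefRow:
    star_allele: str
    suballele: str
    structural_kind: StructuralKind
    core_variants: frozenset[Variant]
    sub_variants: frozenset[Variant]  # full variant set of the suballele

    @property
    def full_set(self) -> frozenset[Variant]:
        return self.sub_variants if self.sub_variants else self.core_variants


def core_number(star: str) -> int:
    m = re.match(r"\*(\d+)", star)
    if not m:
        raise ValueError(f"malformed star allele label {star!r}")
    return int(m.group(1))


class AlleleDefinitionTable:
    """Star-allele / suballele definitions over the analysis window.

    Each suballele's variant set must contain its core allele's defining
    variants; suballeles of the same core must be distinct; *1 is the
    reference (empty) core.
    """

    def __init__(self, rows: list[AlleleDefRow], window_length: int = ANALYSIS_WINDOW_LENGTH):
        self.rows = list(rows)
        self.window_length = window_length
        self._validate()

    def _validate(self) -> None:
        seen: dict[str, frozenset[Variant]] = {}
        for i, row in enumerate(self.rows, start=1):
            if not row.sub_variants >= row.core_variants and row.sub_variants:
                raise ValueError(
                    f"row {i}: suballele {row.suballele} variants do not contain the "
                    f"{row.star_allele} core variants"
                )
            for v in row.full_set:
                if not 1 <= v.pos <= self.window_length:
                    raise ValueError(f"row {i}: variant {v} outside the analysis window")
            key = f"{row.star_allele}|{row.suballele}"
            if key in seen:
                raise ValueError(f"row {i}: duplicate suballele {row.suballele}")
            seen[key] = row.full_set
        for star in {r.star_allele for r in self.rows}:
            subs = [r for r in self.rows if r.star_allele == star]
            sets = [r.full_set for r in subs]
            if len(sets) != len(set(sets)):
                raise ValueError(f"suballeles of {star} must differ from each other")
        if "*1" in self.cores() and self.cores()["*1"]:
            raise ValueError("*1 core must be the empty (reference) variant set")

    def cores(self) -> dict[str, frozenset[Variant]]:
        out: dict[str, frozenset[Variant]] = {}
        for row in self.rows:
            out.setdefault(row.star_allele, row.core_variants)
        return out

    def structural_kind(self, star: str) -> StructuralKind:
        for row in self.rows:
            if row.star_allele == star:
                return row.structural_kind
        raise KeyError(star)

    def suballeles_of(self, star: str) -> list[AlleleDefRow]:
        return [r for r in self.rows if r.star_allele == star]

    def find(self, label: str) -> AlleleDefRow:
        for row in self.rows:
            if row.suballele == label or (row.suballele == "" and row.star_allele == label):
                return row
        raise KeyError(f"unknown (sub)allele label {label!r}")

    def match_suballele(self, star: str, variants: frozenset[Variant]) -> AlleleDefRow | None:
        for row in self.suballeles_of(star):
            if row.full_set == variants:
                return row
        return None

    def all_positions(self) -> list[int]:
        return sorted({v.pos for r in self.rows for v in r.full_set})


def _fmt_variants(vs: frozenset[Variant]) -> str:
    return ";".join(str(v) for v in sorted(vs, key=lambda v: v.pos)) or "."


def _parse_variants(text: str) -> frozenset[Variant]:
    text = text.strip()
    if text in ("", "."):
        return frozenset()
    return frozenset(Variant.parse(t) for t in text.split(";"))


DEFINITION_COLUMNS = ["star_allele", "suballele", "structural_kind", "core_variants", "sub_variants"]


def write_allele_definitions(table: AlleleDefinitionTable, path) -> None:
    """Serialize to TSV (variants as semicolon-separated pos:ref>alt, 1-based)."""
    with open(path, "w") as fh:
        fh.write("\t".join(DEFINITION_COLUMNS) + "\n")
        for r in table.rows:
            fh.write(
                "\t".join(
                    [
                        r.star_allele,
                        r.suballele or ".",
                        r.structural_kind.value,
                        _fmt_variants(r.core_variants),
                        _fmt_variants(r.sub_variants),
                    ]
                )
                + "\n"
            )


def load_allele_definitions(path) -> AlleleDefinitionTable:
    """Load and validate an allele-definition TSV.

    Violations are reported with 1-based data row numbers.
    """
    rows: list[AlleleDefRow] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != DEFINITION_COLUMNS:
            raise ValueError(f"unexpected definition columns {header}")
        for i, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(DEFINITION_COLUMNS):
                raise ValueError(f"row {i}: expected {len(DEFINITION_COLUMNS)} columns")
            star, sub, kind, core_txt, sub_txt = fields
            try:
                rows.append(
                    AlleleDefRow(
                        star_allele=star,
                        suballele="" if sub == "." else sub,
                        structural_kind=StructuralKind(kind),
                        core_variants=_parse_variants(core_txt),
                        sub_variants=_parse_variants(sub_txt),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"row {i}: {exc}") from exc
    return AlleleDefinitionTable(rows)


def _tv(model: LocusModel, pos: int) -> Variant:
    """Transition variant at a window position, ref taken from the model."""
    ref = model.window_ref_base(pos)
    alt = {"A": "G", "G": "A", "C": "T", "T": "C"}[ref]
    return Variant(pos, ref, alt)


def default_allele_definitions(model: LocusModel) -> AlleleDefinitionTable:
    """Fixture definitions covering the alleles used by the study diplotypes.

    Variant positions are fixture-invented (all inside CYP2D6 exons, clear of
    the marker 31-mers); reference bases are read from the built locus, so
    the table is consistent with any seed.
    """
    V = lambda pos: _tv(model, pos)  # noqa: E731
    c2 = frozenset({V(1620), V(2250)})
    c4 = frozenset({V(2850)})
    c10 = frozenset({V(1600)})
    c29 = frozenset({V(3450), V(4050)})
    empty: frozenset[Variant] = frozenset()
    rows = [
        AlleleDefRow("*1", "*1.001", StructuralKind.NONE, empty, empty),
        AlleleDefRow("*1", "*1.037", StructuralKind.NONE, empty, frozenset({V(5400)})),
        AlleleDefRow("*1", "*1.045", StructuralKind.NONE, empty, frozenset({V(4700)})),
        AlleleDefRow("*1", "*1.058", StructuralKind.NONE, empty, frozenset({V(3500)})),
        AlleleDefRow("*1", "*1.059", StructuralKind.NONE, empty, frozenset({V(6500)})),
        AlleleDefRow("*2", "*2.001", StructuralKind.NONE, c2, c2),
        AlleleDefRow("*2", "*2.033", StructuralKind.NONE, c2, c2 | {V(4882)}),
        AlleleDefRow("*4", "*4.001", StructuralKind.NONE, c4, c4),
        AlleleDefRow("*5", "*5.001", StructuralKind.DELETION, empty, empty),
        AlleleDefRow("*10", "*10.001", StructuralKind.NONE, c10, c10),
        AlleleDefRow("*13", "", StructuralKind.HYBRID_TANDEM, empty, empty),
        AlleleDefRow("*29", "*29.001", StructuralKind.NONE, c29, c29),
        AlleleDefRow("*36", "", StructuralKind.HYBRID_TANDEM, empty, empty),
        AlleleDefRow("*68", "", StructuralKind.HYBRID_TANDEM, empty, empty),
    ]
    return AlleleDefinitionTable(rows)


# ---------------------------------------------------------------------------
# nomenclature


@dataclass(frozen=True)
class CopySpec:
    """One gene copy of an allele: a core star label plus suballele label."""

    core: str
    label: str  # full printed label, e.g. "*2.001", or bare "*68" for hybrids

    @property
    def core_num(self) -> int:
        return core_number(self.core)


@dataclass(frozen=True)
class AlleleSpec:
    """Structural class plus gene-copy content of one parental allele.

    ``copies`` are listed 5'-first (duplicated position first) per PharmVar
    tandem-annotation convention.  Deletion alleles carry no copies.
    """

    kind: StructuralKind
    copies: tuple[CopySpec, ...]
    label: str

    @property
    def track_type(self) -> str | None:
        """Custom track expected for tandem-length alleles ('A' or 'B')."""
        if self.kind not in (StructuralKind.DUPLICATION, StructuralKind.HYBRID_TANDEM):
            return None
        pattern = HYBRID_PATTERNS.get(self.copies[0].core)
        return "A" if pattern is not None and pattern.spacer else "B"


def _parse_copy(text: str, defs: AlleleDefinitionTable) -> CopySpec:
    text = text.strip()
    m = re.fullmatch(r"(\*\d+)(\.\d+)?", text)
    if not m:
        raise ValueError(f"malformed allele label {text!r}")
    row = defs.find(text)  # raises KeyError for unknown labels
    return CopySpec(core=row.star_allele, label=text)


def parse_allele(text: str, defs: AlleleDefinitionTable) -> AlleleSpec:
    """Parse one parental allele label, e.g. '*2.001x2' or '*68+*4.001'."""
    text = text.strip()
    if "x2" in text:
        base = text.replace("x2", "")
        copy = _parse_copy(base, defs)
        return AlleleSpec(StructuralKind.DUPLICATION, (copy, copy), text)
    if "+" in text:
        parts = text.split("+")
        if len(parts) != 2:
            raise ValueError(f"tandem allele {text!r} must have exactly two copies")
        copies = tuple(_parse_copy(p, defs) for p in parts)
        return AlleleSpec(StructuralKind.HYBRID_TANDEM, copies, text)
    copy = _parse_copy(text, defs)
    if defs.structural_kind(copy.core) is StructuralKind.DELETION:
        return AlleleSpec(StructuralKind.DELETION, (), text)
    if copy.core in HYBRID_PATTERNS:
        raise ValueError(f"hybrid allele {text!r} must appear in a tandem arrangement")
    return AlleleSpec(StructuralKind.NO_SV, (copy,), text)


def parse_diplotype(text: str, defs: AlleleDefinitionTable) -> tuple[AlleleSpec, AlleleSpec]:
    parts = text.strip().split("/")
    if len(parts) != 2:
        raise ValueError(f"diplotype {text!r} must contain exactly two alleles")
    return parse_allele(parts[0], defs), parse_allele(parts[1], defs)


# ---------------------------------------------------------------------------
# haplotype construction


@dataclass
class Haplotype:
    """A concrete parental allele sequence with truth annotations."""

    sequence: str
    kind: StructuralKind
    allele: AlleleSpec
    copy_gene_starts: list[int]  # fragment offset of each copy's UP start
    variants: list[tuple[int, Variant]]  # (copy index, window/gene-relative variant)
    spacer_intervals: list[tuple[int, int]]  # spacer element locations, hap coords
    track_type: str | None

    @property
    def length(self) -> int:
        return len(self.sequence)


def _copy_variants(copy: CopySpec, defs: AlleleDefinitionTable) -> tuple[Variant, ...]:
    row = defs.find(copy.label)
    return tuple(sorted(row.full_set, key=lambda v: v.pos))


def build_haplotype_sequence(
    model: LocusModel, allele: AlleleSpec | str, defs: AlleleDefinitionTable
) -> Haplotype:
    """Realize one parental allele as a cut-to-cut sequence with truth labels.

    Lengths by structural class: no-SV 39,551 bp; deletion 25,000 bp;
    duplication and hybrid tandem 52,000 bp.
    """
    if isinstance(allele, str):
        allele = parse_allele(allele, defs)
    n = model.neutral
    parts: list[np.ndarray] = [n["FLANK_5P"]]
    copy_gene_starts: list[int] = []
    variants: list[tuple[int, Variant]] = []
    spacers: list[tuple[int, int]] = []
    pos = n["FLANK_5P"].size

    def add(arr: np.ndarray) -> None:
        nonlocal pos
        parts.append(arr)
        pos += arr.size

    def add_gene(copy_idx: int, copy: CopySpec) -> None:
        pattern = HYBRID_PATTERNS.get(copy.core)
        vs = _copy_variants(copy, defs)
        copy_gene_starts.append(pos)
        variants.extend((copy_idx, v) for v in vs)
        if pattern is None:
            add(model.gene_array(variants=vs))
        else:
            add(
                model.gene_array(
                    d7_exons=pattern.d7_exons,
                    up_origin=pattern.up_origin,
                    down_origin=pattern.down_origin,
                    variants=vs,
                )
            )

    if allele.kind in (StructuralKind.DUPLICATION, StructuralKind.HYBRID_TANDEM):
        # duplicated-position unit: gene copy (+ spacer for track-A-type
        # arrangements) + REP + a link duplicating the start of the
        # downstream intergenic region
        add_gene(0, allele.copies[0])
        if allele.track_type == "A":
            spacers.append((pos, pos + n["SPACER"].size))
            add(n["SPACER"])
            add(n["REP7"])
            add(model.neutral["I1"][:LINK_A_LENGTH])
        else:
            add(n["REP6"])
            add(model.neutral["I1"][:LINK_B_LENGTH])
        add_gene(1, allele.copies[1])
    elif allele.kind is StructuralKind.NO_SV:
        add_gene(0, allele.copies[0])
    elif allele.kind is StructuralKind.DELETION:
        pass  # REP-to-REP fusion removes the CYP2D6 gene region entirely
    else:  # pragma: no cover - parse_allele only emits the four kinds
        raise ValueError(f"unsupported structural kind {allele.kind}")

    if allele.kind is not StructuralKind.DELETION:
        add(n["REP6"])
        add(n["I1"])
    add(model.gene_array(origin=Origin.D7))
    spacers.append((pos, pos + n["SPACER"].size))
    add(n["SPACER"])
    add(n["REP7"])
    add(n["I2"])
    add(model.gene_array(origin=Origin.D8))
    add(n["I3"])
    add(n["FLANK_3P"])

    seq = np.concatenate(parts)
    expected = {
        StructuralKind.NO_SV: NO_SV_LENGTH,
        StructuralKind.DELETION: DELETION_LENGTH,
        StructuralKind.DUPLICATION: TANDEM_LENGTH,
        StructuralKind.HYBRID_TANDEM: TANDEM_LENGTH,
    }[allele.kind]
    if seq.size != expected:
        raise AssertionError(f"haplotype length {seq.size} != expected {expected}")
    return Haplotype(
        sequence=seq.tobytes().decode(),
        kind=allele.kind,
        allele=allele,
        copy_gene_starts=copy_gene_starts,
        variants=variants,
        spacer_intervals=spacers,
        track_type=allele.track_type,
    )


# ---------------------------------------------------------------------------
# custom reference tracks


@dataclass
class ReferenceTrack:
    """A reference sequence used for SV triage and direct haplotyping.

    ``REF`` is the no-SV layout.  Tracks ``A`` and ``B`` present the
    duplicated-position gene copy's distinguishing features in place:
    track A carries a CYP2D7-like 5' region and downstream spacer
    (+1,560 bp), track B a CYP2D6-like region with no spacer, so tandem
    reads match their copy features in place while the second gene copy
    aligns as a read-side insertion.
    """

    track_id: str  # REF | A | B
    sequence: str
    segment_map: dict[str, tuple[int, int]]
    spacer_window: tuple[int, int] | None

    @property
    def length(self) -> int:
        return len(self.sequence)


def build_custom_track(model: LocusModel, track_id: str) -> ReferenceTrack:
    if track_id not in ("REF", "A", "B"):
        raise ValueError(f"invalid track_id {track_id!r} (expected REF, A or B)")
    n = model.neutral
    if track_id == "REF":
        seq = model.reference
        segmap = {name: iv for name, iv in model.spec.offsets().items()}
        return ReferenceTrack("REF", seq.tobytes().decode(), segmap, None)

    d7_like = track_id == "A"
    gene = model.gene_array(
        up_origin=Origin.D7 if d7_like else Origin.D6,
        down_origin=Origin.D7 if d7_like else Origin.D6,
    )
    parts = [n["FLANK_5P"], gene]
    segmap: dict[str, tuple[int, int]] = {"FLANK_5P": (0, n["FLANK_5P"].size)}
    pos = n["FLANK_5P"].size
    segmap["DUP_POS_COPY"] = (pos, pos + gene.size)
    pos += gene.size
    spacer_window = None
    if d7_like:
        spacer_window = (pos, pos + n["SPACER"].size)
        parts.append(n["SPACER"])
        segmap["DUP_POS_SPACER"] = spacer_window
        pos += n["SPACER"].size
    for name, arr in [
        ("REP6", n["REP6"]),
        ("I1", n["I1"]),
        ("GENE_D7", model.gene_array(origin=Origin.D7)),
        ("SPACER", n["SPACER"]),
        ("REP7", n["REP7"]),
        ("I2", n["I2"]),
        ("GENE_D8", model.gene_array(origin=Origin.D8)),
        ("I3", n["I3"]),
        ("FLANK_3P", n["FLANK_3P"]),
    ]:
        segmap[name] = (pos, pos + arr.size)
        parts.append(arr)
        pos += arr.size
    seq = np.concatenate(parts)
    return ReferenceTrack(track_id, seq.tobytes().decode(), segmap, spacer_window)


# ---------------------------------------------------------------------------
# in-silico CRISPR digestion


_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _pam_matches(seq: str, pos: int, pam: str) -> bool:
    if pos + len(pam) > len(seq):
        return False
    return all(seq[pos + i] in _IUPAC[p] for i, p in enumerate(pam))


def find_cut_sites(
    genome_seq: str, guide: str, pam: str = "NGG"
) -> list[tuple[int, str]]:
    """Report Cas9 blunt-cut coordinates for every protospacer+PAM occurrence.

    The cut falls 3 bp 5' of the PAM; positions are 0-based fragment offsets
    of the base immediately 3' of the cut.  Both strands are scanned and
    overlapping occurrences are all reported.
    """
    guide = guide.upper()
    if len(guide) != 20:
        raise ValueError(f"guide must be 20 nt, got {len(guide)}")
    if set(guide) - set("ACGT"):
        raise ValueError(f"ambiguous bases in guide {guide!r}")
    genome_seq = genome_seq.upper()
    hits: list[tuple[int, str]] = []
    # plus strand: guide at i, PAM at i+20; blunt cut between i+16 and i+17
    start = 0
    while True:
        i = genome_seq.find(guide, start)
        if i < 0:
            break
        if _pam_matches(genome_seq, i + 20, pam):
            hits.append((i + 17, "+"))
        start = i + 1
    # minus strand: reverse-complement protospacer preceded by rc(PAM)
    rc_guide = reverse_complement(guide)
    rc_pam = reverse_complement(pam)
    start = 0
    while True:
        j = genome_seq.find(rc_guide, start)
        if j < 0:
            break
        if j >= len(pam) and _pam_matches(genome_seq, j - len(pam), rc_pam):
            hits.append((j + 3, "-"))
        start = j + 1
    return sorted(hits)


def digest(genome_seq: str, guides: list[str], pam: str = "NGG") -> list[str]:
    """In-silico digestion: cut at every guide hit, return the fragments."""
    cuts = sorted({pos for g in guides for pos, _ in find_cut_sites(genome_seq, g, pam)})
    bounds = [0] + cuts + [len(genome_seq)]
    return [genome_seq[a:b] for a, b in zip(bounds[:-1], bounds[1:]) if b > a]


def design_flanking_guides(model: LocusModel, margin: int = 2_000, seed: int = 11):
    """Embed the fragment in neutral genomic margins with planted protospacers.

    Returns ``(genome_seq, guide_5p, guide_3p)`` such that digestion with the
    two guides excises exactly the cut-to-cut reference fragment.
    """
    rng = np.random.default_rng(seed)
    frag = model.reference_seq()
    for _ in range(50):
        left = _random_seq(rng, margin).tobytes().decode()
        right = _random_seq(rng, margin).tobytes().decode()
        # A protospacer straddles its blunt cut (17 bp / 3 bp around it), so
        # guides are taken from the boundary sequence itself and only the PAM
        # is planted, in the margin, leaving the fragment untouched.
        # 5' cut: minus-strand guide, PAM (CCN on the plus strand) ends 3 bp
        # left of the cut; 3' cut: plus-strand guide, PAM starts 3 bp right.
        left = left[: margin - 6] + "CC" + left[margin - 4 :]
        right = right[:4] + "GG" + right[6:]
        genome = left + frag + right
        cut5, cut3 = margin, margin + len(frag)
        g5 = reverse_complement(genome[cut5 - 3 : cut5 + 17])
        g3 = genome[cut3 - 17 : cut3 + 3]
        hits5 = find_cut_sites(genome, g5)
        hits3 = find_cut_sites(genome, g3)
        if hits5 == [(cut5, "-")] and hits3 == [(cut3, "+")]:
            return genome, g5, g3
    raise RuntimeError("failed to design unique flanking guides")  # pragma: no cover
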