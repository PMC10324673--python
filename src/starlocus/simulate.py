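"""Nanopore-like read simulation from a diploid pair of excised haplotypes.

CRISPR excision yields one cut-to-cut fragment per parental allele, so a
"read" here is a whole fragment observed with nanopore-like errors:
per-base substitution / insertion / deletion rates, PHRED qualities drawn
around a configurable mean, and occasional truncation (molecules that broke
or pores that stopped), which is what the full-span QC gate later removes.
Reads are adapter-free (trimming is upstream of this tool).

Error rates are flat along the read (no homopolymer weighting); the
defaults emulate the observed read-level quality of the assay (mean PHRED
around 14, i.e. a few percent errors per base) with enough truncation to
exercise span filtering.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .locus import BASES, Haplotype

__all__ = [
    "ErrorModel",
    "SimRead",
    "apply_error_model",
    "simulate_diploid_reads",
    "write_fastq",
    "read_fastq",
    "write_truth_table",
    "read_truth_table",
]


@dataclass(frozen=True)
class ErrorModel:
    """Per-base error and quality model for simulated nanopore reads."""

    sub_rate: float = 0.02
    ins_rate: float = 0.015
    del_rate: float = 0.02
    mean_q: float = 14.0
    q_sd: float = 3.0
    truncation_prob: float = 0.15
    truncation_frac_range: tuple[float, float] = (0.3, 0.95)

    def __post_init__(self) -> None:
        for name in ("sub_rate", "ins_rate", "del_rate", "truncation_prob"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0, 1), got {v}")
        if self.sub_rate + self.ins_rate + self.del_rate >= 0.5:
            raise ValueError("total per-base error rate must be < 0.5")
        if self.mean_q <= 0:
            raise ValueError("mean_q must be > 0")
        lo, hi = self.truncation_frac_range
        if not 0.0 < lo <= hi <= 1.0:
            raise ValueError("truncation_frac_range must satisfy 0 < lo <= hi <= 1")

    @classmethod
    def error_free(cls) -> "ErrorModel":
        return cls(sub_rate=0.0, ins_rate=0.0, del_rate=0.0, truncation_prob=0.0)

    def to_config(self) -> dict:
        d = dataclasses.asdict(self)
        d["truncation_frac_range"] = list(self.truncation_frac_range)
        return d

    @classmethod
    def from_config(cls, cfg: dict) -> "ErrorModel":
        cfg = dict(cfg)
        if "truncation_frac_range" in cfg:
            cfg["truncation_frac_range"] = tuple(cfg["truncation_frac_range"])
        return cls(**cfg)


@dataclass
class SimRead:
    """A simulated long read plus its truth labels."""

    read_id: str
    sequence: str
    quality: str  # PHRED+33
    source_allele: int  # 0 or 1
    full_span: bool
    fragment_length: int  # pre-error cut-to-cut length of the source molecule

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise ValueError("sequence and quality must have equal length")


def apply_error_model(
    sequence: str, model: ErrorModel, rng: np.random.Generator | int
) -> tuple[str, str]:
    """Apply substitution / insertion / deletion noise and draw qualities.

    Insertions are single bases emitted after the source base; qualities are
    normal around ``mean_q`` (clipped to PHRED 2..41) and independent of
    whether the base is an error.  Returns ``(sequence, quality)``.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    arr = np.frombuffer(sequence.encode(), dtype="S1").copy()
    n = arr.size
    if n == 0:
        raise ValueError("empty sequence")
    u = rng.random(n)
    sub = u < model.sub_rate
    dele = (u >= model.sub_rate) & (u < model.sub_rate + model.del_rate)
    ins = rng.random(n) < model.ins_rate

    if sub.any():
        idx = np.searchsorted(BASES, arr[sub])
        arr[sub] = BASES[(idx + rng.integers(1, 4, int(sub.sum()))) % 4]

    counts = np.ones(n, dtype=np.int64)
    counts[dele] = 0
    counts[ins & ~dele] += 1
    out = np.repeat(arr, counts)
    # positions of the inserted (second) copies, filled with random bases
    ends = np.cumsum(counts)
    ins_pos = ends[ins & ~dele] - 1
    if ins_pos.size:
        out[ins_pos] = BASES[rng.integers(0, 4, ins_pos.size)]

    q = np.clip(np.rint(rng.normal(model.mean_q, model.q_sd, out.size)), 2, 41)
    qual = (q.astype(np.uint8) + 33).tobytes().decode("ascii")
    return out.tobytes().decode(), qual


def simulate_diploid_reads(
    hap_a: Haplotype,
    hap_b: Haplotype,
    depth_per_allele: int,
    model: ErrorModel | None = None,
    seed: int = 0,
) -> list[SimRead]:
    """Simulate ``depth_per_allele`` reads from each parental haplotype.

    Depth is a per-allele read count (every read is a whole excised
    fragment, so read count equals minimum coverage for full-span reads).
    Reads are emitted in randomized allele order with deterministic ids for
    a given seed.
    """
    if depth_per_allele < 1:
        raise ValueError("depth_per_allele must be >= 1")
    model = model if model is not None else ErrorModel()
    for hap in (hap_a, hap_b):
        if not hap.sequence:
            raise ValueError("empty haplotype sequence")
    ss = np.random.SeedSequence(seed)
    order_rng = np.random.default_rng(ss.spawn(1)[0])
    sources = np.repeat([0, 1], depth_per_allele)
    order_rng.shuffle(sources)
    child_seeds = ss.spawn(sources.size)

    reads: list[SimRead] = []
    haps = (hap_a, hap_b)
    for i, (src, child) in enumerate(zip(sources, child_seeds)):
        rng = np.random.default_rng(child)
        hap = haps[src]
        fragment = hap.sequence
        full_span = True
        if rng.random() < model.truncation_prob:
            lo, hi = model.truncation_frac_range
            frac = rng.uniform(lo, hi)
            keep = max(1, int(round(frac * len(fragment))))
            fragment = fragment[:keep] if rng.random() < 0.5 else fragment[-keep:]
            full_span = False
        seq, qual = apply_error_model(fragment, model, rng)
        reads.append(
            SimRead(
                read_id=f"sim_{i:04d}",
                sequence=seq,
                quality=qual,
                source_allele=int(src),
                full_span=full_span,
                fragment_length=hap.length,
            )
        )
    return reads


# ---------------------------------------------------------------------------
# I/O


def write_fastq(reads: list[SimRead], path) -> None:
    """Write standard 4-line FASTQ records (PHRED+33)."""
    import logging

    if not reads:
        logging.getLogger(__name__).warning("writing empty FASTQ to %s", path)
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{r.quality}\n")


def read_fastq(path) -> list[tuple[str, str, str]]:
    """Parse a FASTQ file into ``(read_id, sequence, quality)`` tuples."""
    out = []
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            if not header.startswith("@"):
                raise ValueError(f"malformed FASTQ record header {header!r}")
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline().rstrip("\n")
            if not plus.startswith("+") or len(seq) != len(qual):
                raise ValueError(f"malformed FASTQ record {header.strip()!r}")
            out.append((header[1:].split()[0], seq, qual))
    return out


TRUTH_COLUMNS = ["read_id", "source_allele", "full_span", "fragment_length"]


def write_truth_table(reads: list[SimRead], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(TRUTH_COLUMNS) + "\n")
        for r in reads:
            fh.write(f"{r.read_id}\t{r.source_allele}\t{int(r.full_span)}\t{r.fragment_length}\n")


def read_truth_table(path) -> dict[str, dict]:
    out: dict[str, dict] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != TRUTH_COLUMNS:
            raise ValueError(f"unexpected truth columns {header}")
        for line in fh:
            rid, src, span, flen = line.rstrip("\n").split("\t")
            out[rid] = {
                "source_allele": int(src),
                "full_span": bool(int(span)),
                "fragment_length": int(flen),
            }
    return out
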