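"""Read-level and sample-level quality gates.

The assay's analysis keeps only reads that (1) are at least 20 kb long,
(2) average PHRED quality >= 7, (3) span the whole targeted region as
defined by the 5' and 3' cut-site flanks, and (4) align with a
dynamic-programming score above a configurable threshold; a sample is
callable when enough full-span reads remain.  Gate order and inclusive
boundaries follow that pipeline (a 20,000 bp read passes the "<20 kb"
removal rule).

Mean read quality is computed in probability space (PHRED to error
probability, arithmetic mean, back to PHRED), the standard convention for
per-read quality summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .align import ReadFeatures

__all__ = ["QCParams", "QCReport", "mean_phred", "filter_reads", "check_full_span", "coverage_profile"]


@dataclass(frozen=True)
class QCParams:
    min_read_length: int = 20_000
    min_mean_q: float = 7.0
    min_alignment_score: int = 1_000
    min_full_span_reads: int = 35

    def __post_init__(self) -> None:
        for name in ("min_read_length", "min_mean_q", "min_alignment_score", "min_full_span_reads"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class QCReport:
    """Per-gate read counts plus sample-level coverage summary.

    Counts are non-increasing along the gate order input -> length ->
    quality -> span -> score.
    """

    n_input: int = 0
    n_pass_length: int = 0
    n_pass_quality: int = 0
    n_pass_span: int = 0
    n_pass_score: int = 0
    mean_depth: float = 0.0
    min_depth: int = 0
    sample_pass: bool = False
    depth_profile: np.ndarray | None = field(default=None, repr=False)

    def validate(self) -> None:
        seq = [self.n_input, self.n_pass_length, self.n_pass_quality, self.n_pass_span, self.n_pass_score]
        if any(b > a for a, b in zip(seq, seq[1:])):
            raise AssertionError(f"gate counts must be non-increasing: {seq}")

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_pass_length": self.n_pass_length,
            "n_pass_quality": self.n_pass_quality,
            "n_pass_span": self.n_pass_span,
            "n_pass_score": self.n_pass_score,
            "mean_depth": round(self.mean_depth, 2),
            "min_depth": self.min_depth,
            "sample_pass": self.sample_pass,
        }


def mean_phred(quality: str) -> float:
    """Probability-space mean PHRED quality of a PHRED+33 quality string."""
    if not quality:
        raise ValueError("empty quality string")
    q = np.frombuffer(quality.encode("ascii"), dtype=np.uint8).astype(float) - 33.0
    p = np.power(10.0, -q / 10.0)
    return float(-10.0 * np.log10(p.mean()))


def filter_reads(
    reads: list[tuple[str, str, str]], params: QCParams
) -> tuple[list[tuple[str, str, str]], QCReport]:
    """Apply the length and mean-quality gates.

    ``reads`` are ``(read_id, sequence, quality)``; a read passes iff
    ``len >= min_read_length`` and probability-space mean PHRED
    ``>= min_mean_q``.  Reads without quality strings are an error: the
    quality gate cannot be evaluated.
    """
    report = QCReport(n_input=len(reads))
    passing = []
    for rid, seq, qual in reads:
        if not qual:
            raise ValueError(f"read {rid}: missing quality string")
        if len(seq) < params.min_read_length:
            continue
        report.n_pass_length += 1
        if mean_phred(qual) < params.min_mean_q:
            continue
        report.n_pass_quality += 1
        passing.append((rid, seq, qual))
    return passing, report


def check_full_span(features: ReadFeatures) -> bool:
    """True iff both cut-site flank anchors were located in the read.

    A read with both anchors but a large internal deletion (a *5 allele)
    still spans the targeted region and passes.
    """
    found = {a.anchor_id for a in features.anchors}
    return "FLANK_5P" in found and "FLANK_3P" in found


def coverage_profile(
    features: list[ReadFeatures], window_length: int, params: QCParams
) -> tuple[np.ndarray, float, bool]:
    """Per-base depth over the analysis window plus the sample-level gate.

    Every retained read spans the whole window (that is what the span gate
    enforces), so the minimum depth equals the full-span read count.
    """
    n_span = sum(1 for f in features if check_full_span(f))
    depth = np.full(window_length, n_span, dtype=np.int32)
    mean_depth = float(depth.mean()) if window_length else 0.0
    sample_pass = n_span >= params.min_full_span_reads
    return depth, mean_depth, sample_pass
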