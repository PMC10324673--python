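"""The nine study samples and helpers to simulate and genotype them.

These diplotypes cover the locus's structural spectrum: three samples
without structural variation (including one resolved only at suballele
level), plus a full-gene deletion, a full-gene duplication and three
hybrid-tandem configurations across both custom reference tracks.
"""

from __future__ import annotations

from dataclasses import dataclass

from .caller import CallerParams, SampleResult, genotype_sample
from .locus import (
    AlleleDefinitionTable,
    Haplotype,
    LocusModel,
    build_custom_track,
    build_haplotype_sequence,
    default_allele_definitions,
    parse_diplotype,
)
from .qc import QCParams
from .simulate import ErrorModel, SimRead, simulate_diploid_reads

__all__ = ["STUDY_SAMPLES", "FixtureSample", "simulate_sample", "genotype_reads", "default_model"]


@dataclass(frozen=True)
class FixtureSample:
    sample_id: str
    source: str
    diplotype: str
    has_sv: bool
    seed: int


#: sample ids, sources and detected diplotypes of the nine study samples;
#: per-sample seeds fixed for reproducible fixture simulation
STUDY_SAMPLES: list[FixtureSample] = [
    FixtureSample("LCL_1", "lymphoblastoid cell line", "*1.058/*1.059", False, 101),
    FixtureSample("WB_1", "whole blood", "*1.001/*2.033", False, 102),
    FixtureSample("LV_1", "liver tissue", "*1.001/*4.001", False, 103),
    FixtureSample("LCL_2", "lymphoblastoid cell line", "*2.001/*36+*10.001", True, 104),
    FixtureSample("LCL_3", "lymphoblastoid cell line", "*4.001/*68+*4.001", True, 105),
    FixtureSample("LCL_4", "lymphoblastoid cell line", "*1.045/*5.001", True, 106),
    FixtureSample("LCL_5", "lymphoblastoid cell line", "*1.001/*13+*2.001", True, 107),
    FixtureSample("LCL_6", "lymphoblastoid cell line", "*2.001x2/*29.001", True, 108),
    FixtureSample("SA_1", "saliva", "*1.037/*68+*4.001", True, 109),
]


def default_model(seed: int = 7) -> tuple[LocusModel, AlleleDefinitionTable]:
    model = LocusModel(seed=seed)
    return model, default_allele_definitions(model)


def simulate_sample(
    diplotype: str,
    model: LocusModel,
    defs: AlleleDefinitionTable,
    depth_per_allele: int = 40,
    error_model: ErrorModel | None = None,
    seed: int = 0,
) -> tuple[list[SimRead], Haplotype, Haplotype]:
    """Simulate one sample's read set from a diplotype string."""
    spec_a, spec_b = parse_diplotype(diplotype, defs)
    hap_a = build_haplotype_sequence(model, spec_a, defs)
    hap_b = build_haplotype_sequence(model, spec_b, defs)
    reads = simulate_diploid_reads(hap_a, hap_b, depth_per_allele, error_model, seed)
    return reads, hap_a, hap_b


def genotype_reads(
    reads: list[SimRead],
    model: LocusModel,
    defs: AlleleDefinitionTable,
    qc_params: QCParams | None = None,
    caller_params: CallerParams | None = None,
    prober=None,
) -> SampleResult:
    """Genotype simulated reads (convenience wrapper over the pipeline)."""
    tracks = {tid: build_custom_track(model, tid) for tid in ("REF", "A", "B")}
    triples = [(r.read_id, r.sequence, r.quality) for r in reads]
    return genotype_sample(
        triples, model, defs, qc_params, caller_params, tracks=tracks, prober=prober
    )
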