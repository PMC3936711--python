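"""End-to-end convenience wrappers over the detection and classification steps."""

from __future__ import annotations

from dataclasses import dataclass, field

from .io_model import CasLocus, Completeness, FamilyHit, GeneRecord
from .locus_classification import (
    SignatureMap,
    SubtypeCall,
    assign_types,
    detect_cooccurrence,
    load_signature_map,
)
from .recruitment import (
    CandidateCollection,
    RecruitmentParams,
    assemble_loci,
    best_weak_annotation,
    collect_novel_candidates,
    find_seeds,
    recruit_iteratively,
)

__all__ = ["DetectionResult", "detect_and_classify"]


@dataclass
class DetectionResult:
    loci: list[CasLocus]
    calls: list[SubtypeCall]
    annotations: dict[str, str] = field(default_factory=dict)
    candidates: CandidateCollection = field(default_factory=CandidateCollection)


def detect_and_classify(
    genes: list[GeneRecord],
    cas_hits: list[FamilyHit],
    full_hits: list[FamilyHit] | None = None,
    completeness: Completeness = Completeness.DRAFT_OR_CONTIG,
    params: RecruitmentParams = RecruitmentParams(),
    sigmap: SignatureMap | None = None,
) -> DetectionResult:
    """Run seed finding, recruitment, locus assembly and subtype calling.

    ``cas_hits`` is the hit table against the known Cas families;
    ``full_hits`` (against the entire family database) partitions the
    intervening unknowns into novel candidates vs assorted known functions
    and contributes annotations for TA/transposase analyses.
    """
    sigmap = sigmap or load_signature_map()
    seeds = find_seeds(cas_hits)
    labels = recruit_iteratively(genes, cas_hits, seeds, params)
    loci = assemble_loci(genes, labels, completeness, params)
    annotations = best_weak_annotation(cas_hits)
    candidates = collect_novel_candidates(loci, full_hits or [])
    annotations.update(candidates.assorted_functions)
    calls = []
    for locus in loci:
        call = assign_types(locus, annotations, sigmap)
        detect_cooccurrence(call, annotations, locus, sigmap)
        calls.append(call)
    return DetectionResult(loci=loci, calls=calls, annotations=annotations,
                           candidates=candidates)
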