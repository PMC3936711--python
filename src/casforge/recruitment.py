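"""Seed identification and iterative genomic-neighborhood recruitment.

Genes whose proteins hit a known Cas family at the gathering (trusted)
threshold are seeds.  Genes with only a weak hit (E <= 0.001) are recruited
when they lie within a three-gene distance of an already-labeled gene on the
same replicon; recruited genes recruit in turn, so the procedure runs to a
fixed point.  Labeled genes are then grouped into loci, pulling in the
unlabeled genes that fall between cas genes (the intervening unknowns that
feed novel-family discovery).

Distance is measured in genes (|gene_index difference|), never base pairs,
and both strands are eligible.  Chains never cross replicon boundaries:
contigs are independent assemblies.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

from .io_model import CasLabel, CasLocus, Completeness, FamilyHit, GeneRecord

__all__ = [
    "RecruitmentParams",
    "find_seeds",
    "recruit_iteratively",
    "assemble_loci",
    "CandidateCollection",
    "collect_novel_candidates",
    "best_weak_annotation",
]


@dataclass(frozen=True)
class RecruitmentParams:
    """window: neighborhood radius in genes; weak_e_max: recruitment E cut."""

    window: int = 3
    weak_e_max: float = 0.001

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError(f"window must be >= 1, got {self.window}")
        if self.weak_e_max <= 0:
            raise ValueError(f"weak_e_max must be > 0, got {self.weak_e_max}")


def find_seeds(hits: list[FamilyHit]) -> set[str]:
    """Proteins with at least one hit meeting the gathering cutoff."""
    return {h.protein_id for h in hits if h.meets_gathering}


def recruit_iteratively(
    genes: list[GeneRecord],
    hits: list[FamilyHit],
    seeds: set[str],
    params: RecruitmentParams = RecruitmentParams(),
) -> dict[str, CasLabel]:
    """Expand the seed set through the gene neighborhood to a fixed point.

    Returns {protein_id: SEED_KNOWN | RECRUITED_KNOWN}.  A gene is recruited
    iff it has a hit with E <= weak_e_max and is reachable from a seed
    through a chain of labeled genes each within ``window`` gene indices on
    the same replicon.  The result is the unique least fixed point of that
    relation, so it is independent of processing order.  Seed labels take
    precedence: a seed inside another seed's window stays SEED_KNOWN.
    """
    by_protein = {g.protein_id: g for g in genes}
    missing = seeds - set(by_protein)
    if missing:
        raise ValueError(f"seed proteins absent from gene table: {sorted(missing)[:5]}")

    eligible = {h.protein_id for h in hits if h.e_value <= params.weak_e_max}
    # genes per replicon ordered by index, for window neighbor lookups
    by_replicon: dict[str, list[GeneRecord]] = {}
    for g in sorted(genes, key=lambda g: (g.replicon_id, g.gene_index)):
        by_replicon.setdefault(g.replicon_id, []).append(g)
    pos_in_replicon = {
        g.protein_id: (g.replicon_id, i)
        for glist in by_replicon.values()
        for i, g in enumerate(glist)
    }

    labels: dict[str, CasLabel] = {p: CasLabel.SEED_KNOWN for p in seeds}
    queue = deque(sorted(seeds))
    while queue:
        pid = queue.popleft()
        rid, i = pos_in_replicon[pid]
        glist = by_replicon[rid]
        here = glist[i].gene_index
        for j in range(max(0, i - params.window), min(len(glist), i + params.window + 1)):
            g = glist[j]
            if abs(g.gene_index - here) > params.window:
                continue
            q = g.protein_id
            if q in labels or q not in eligible:
                continue
            labels[q] = CasLabel.RECRUITED_KNOWN
            queue.append(q)
    return labels


def assemble_loci(
    genes: list[GeneRecord],
    labels: dict[str, CasLabel],
    completeness: Completeness = Completeness.DRAFT_OR_CONTIG,
    params: RecruitmentParams = RecruitmentParams(),
) -> list[CasLocus]:
    """Group labeled genes into maximal loci, filling intervening unknowns.

    Per replicon, labeled genes whose consecutive gene_index gaps are
    <= window form one chain; every unlabeled gene strictly inside the chain
    span becomes INTERVENING_UNKNOWN.  Chains without any SEED_KNOWN member
    are discarded (weak hits alone never make a locus).
    """
    by_replicon: dict[str, list[GeneRecord]] = {}
    for g in sorted(genes, key=lambda g: (g.replicon_id, g.gene_index)):
        by_replicon.setdefault(g.replicon_id, []).append(g)

    loci: list[CasLocus] = []
    for rid in sorted(by_replicon):
        glist = by_replicon[rid]
        labeled = [g for g in glist if g.protein_id in labels]
        if not labeled:
            continue
        chains: list[list[GeneRecord]] = [[labeled[0]]]
        for g in labeled[1:]:
            if g.gene_index - chains[-1][-1].gene_index <= params.window:
                chains[-1].append(g)
            else:
                chains.append([g])
        by_index = {g.gene_index: g for g in glist}
        for chain in chains:
            first, last = chain[0].gene_index, chain[-1].gene_index
            members: list[tuple[str, CasLabel]] = []
            n_seed = 0
            for idx in range(first, last + 1):
                g = by_index[idx]
                lab = labels.get(g.protein_id, CasLabel.INTERVENING_UNKNOWN)
                if lab is CasLabel.SEED_KNOWN:
                    n_seed += 1
                members.append((g.protein_id, lab))
            if n_seed == 0:
                continue
            locus = CasLocus(
                locus_id=f"{rid}:{first}-{last}",
                replicon_id=rid,
                first_index=first,
                last_index=last,
                members=members,
                completeness=completeness,
            )
            locus.validate()
            loci.append(locus)
    return loci


@dataclass
class CandidateCollection:
    """Partition of intervening unknown genes by annotatability.

    ``candidates`` have no hit against the full family database and are the
    putative novel Cas proteins; ``assorted_functions`` maps the rest to
    their best known (non-Cas) family — transposases, toxins, antitoxins and
    other functions found embedded in cas loci.
    """

    candidates: set[str] = field(default_factory=set)
    assorted_functions: dict[str, str] = field(default_factory=dict)


def collect_novel_candidates(
    loci: list[CasLocus],
    all_family_hits: list[FamilyHit],
) -> CandidateCollection:
    """Split intervening unknown locus members into novel candidates vs
    known-function (assorted) genes.

    ``all_family_hits`` is the hit table against the *entire* family database
    (Cas and non-Cas alike); any hit there, however weak, removes a gene from
    the novel-candidate set and records its best family instead.
    """
    best: dict[str, FamilyHit] = {}
    for h in all_family_hits:
        prev = best.get(h.protein_id)
        if prev is None or (h.e_value, -h.bit_score) < (prev.e_value, -prev.bit_score):
            best[h.protein_id] = h
    out = CandidateCollection()
    for locus in loci:
        for pid in locus.member_ids(CasLabel.INTERVENING_UNKNOWN):
            if pid in best:
                out.assorted_functions[pid] = best[pid].family_id
            else:
                out.candidates.add(pid)
    return out


def best_weak_annotation(hits: list[FamilyHit]) -> dict[str, str]:
    """Provisional family annotation per protein from its best hit.

    Lowest E-value wins; ties break toward higher bit score, then
    lexicographic family id.  Used to annotate seed and recruited locus
    members for subtype classification.
    """
    best: dict[str, FamilyHit] = {}
    for h in sorted(hits, key=lambda h: (h.protein_id, h.e_value, -h.bit_score, h.family_id)):
        best.setdefault(h.protein_id, h)
    return {p: h.family_id for p, h in best.items()}
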