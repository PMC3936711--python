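"""Synthetic replicons, proteins, hit tables and cohorts with known ground truth.

Real inputs for this kind of survey are complete/draft genomes and
metagenome assembly contigs annotated against curated Cas protein family
profiles.  This module emulates those inputs at a scale where every pipeline
stage can be verified exactly: replicons with planted cas loci of known
type/subtype, weak-hit recruits, intervening unknown genes, transposase and
toxin/antitoxin insertions, protein families at controlled pairwise
identity, and a multi-habitat cohort of subjects.

All generators are deterministic for a fixed seed.  Sub-streams are derived
by hashing (seed, purpose) into a numpy SeedSequence so that adding one
generator never perturbs another.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .alignment import AlignmentParams, DEFAULT_PARAMS, align_pair
from .io_model import Completeness, FamilyHit, GeneRecord, SampleInventory

__all__ = [
    "SimTruth",
    "PlantedLocus",
    "SUBTYPE_LAYOUTS",
    "simulate_replicon",
    "plant_cas_locus",
    "plant_annotated_insertion",
    "plant_ta_pair",
    "mutate_to_identity",
    "generate_family",
    "emit_hit_table",
    "emit_full_annotation_table",
    "simulate_cohort",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: default gene layout per subtype: (family_id, hit strength) in gene order.
#: "strong" members carry a gathering-threshold hit (seeds); "weak" members
#: carry only an E <= 1e-3 hit and must be recovered by neighborhood
#: recruitment.  Signature genes are strong so classification is exercised
#: on the same inputs.
SUBTYPE_LAYOUTS: dict[str, list[tuple[str, str]]] = {
    "I-C": [("cas3", "strong"), ("cas8c", "strong"), ("cas7", "weak"),
            ("cas5", "weak"), ("cas4", "weak"), ("cas1", "strong"), ("cas2", "weak")],
    "I-E": [("cas3", "strong"), ("cse1", "strong"), ("cas7", "weak"),
            ("cas5", "weak"), ("cas6", "weak"), ("cas1", "strong"), ("cas2", "weak")],
    "I-F": [("cas1", "strong"), ("cas3", "strong"), ("csy1", "strong"),
            ("cas7", "weak"), ("cas6", "weak")],
    "IC-variant": [("cas3", "strong"), ("GSU0054", "strong"), ("cas7", "weak"),
                   ("cas5", "weak"), ("cas1", "strong"), ("cas2", "weak")],
    "II-A": [("cas9", "strong"), ("cas1", "strong"), ("cas2", "weak"),
             ("csn2", "strong")],
    "II-B": [("cas9", "strong"), ("cas1", "strong"), ("cas2", "weak"),
             ("cas4", "strong")],
    "II-C": [("cas9", "strong"), ("cas1", "strong"), ("cas2", "weak")],
    "III-A": [("cas10", "strong"), ("csm", "strong"), ("cas7", "weak"),
              ("cas5", "weak"), ("cas1", "strong"), ("cas2", "weak")],
    "III-B": [("cas10", "strong"), ("cmr", "strong"), ("cas7", "weak"),
              ("cas5", "weak"), ("cas6", "weak")],
}


def derive_rng(seed: int, purpose: str) -> np.random.Generator:
    """Derive an independent RNG stream from a global seed and a purpose tag."""
    tag = zlib.crc32(purpose.encode())
    return np.random.default_rng(np.random.SeedSequence((int(seed) & 0x7FFFFFFF, tag)))


@dataclass
class PlantedLocus:
    replicon_id: str
    first_index: int
    last_index: int
    subtype: str
    roles: dict[str, str]  # protein_id -> seed | recruit | intervening


@dataclass
class SimTruth:
    """Ground truth accumulated while building a synthetic dataset."""

    planted_loci: list[PlantedLocus] = field(default_factory=list)
    decoys: list[str] = field(default_factory=list)
    ta_pairs: list[tuple[str, str]] = field(default_factory=list)  # (antitoxin, toxin)
    family_assignments: dict[str, str] = field(default_factory=dict)  # protein -> cas family
    extra_annotations: dict[str, str] = field(default_factory=dict)  # protein -> non-cas family
    cohort_effects: dict[str, float] = field(default_factory=dict)

    def cas_protein_ids(self) -> set[str]:
        return {p for locus in self.planted_loci for p in locus.roles}


def _random_protein(rng: np.random.Generator, length: int) -> str:
    """Uniform background over the 20 standard residues."""
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def simulate_replicon(
    n_genes: int,
    mean_gene_len: int = 900,
    seed: int = 0,
    replicon_id: str | None = None,
    completeness: Completeness = Completeness.COMPLETE_GENOME,
) -> tuple[list[GeneRecord], dict[str, str], SimTruth]:
    """Simulate one replicon: non-overlapping genes with random strands and
    random protein sequences.

    Gene lengths are normal around ``mean_gene_len`` (bp, SD = 20% of mean,
    floor 150); intergenic gaps are exponential with mean 100 bp.  Returns
    (gene records, {protein_id: sequence}, empty SimTruth).
    """
    if n_genes < 1:
        raise ValueError(f"n_genes must be >= 1, got {n_genes}")
    rng = derive_rng(seed, f"replicon:{replicon_id or ''}")
    rid = replicon_id or f"R{seed}"
    genes: list[GeneRecord] = []
    seqs: dict[str, str] = {}
    pos = 1
    for i in range(n_genes):
        gap = int(rng.exponential(100.0))
        length = max(150, int(rng.normal(mean_gene_len, 0.2 * mean_gene_len)))
        length -= length % 3
        start = pos + gap
        end = start + length - 1
        strand = "+" if rng.random() < 0.5 else "-"
        pid = f"{rid}_g{i:04d}"
        genes.append(GeneRecord(rid, i, start, end, strand, pid))
        seqs[pid] = _random_protein(rng, length // 3)
        pos = end + 1
    return genes, seqs, SimTruth()


def plant_cas_locus(
    genes: list[GeneRecord],
    truth: SimTruth,
    subtype: str,
    start_index: int,
    layout: list[tuple[str, str]] | None = None,
    insert_intervening: bool = False,
    seed: int = 0,
) -> SimTruth:
    """Assign cas family roles to consecutive genes starting at ``start_index``.

    ``layout`` is an ordered list of (family_id, "strong"|"weak"); the default
    is the subtype's layout from SUBTYPE_LAYOUTS, which includes the
    subtype's signature family.  With ``insert_intervening`` an extra unknown
    gene (no hits at all) is left in the middle of the planted span.
    """
    if layout is None:
        if subtype not in SUBTYPE_LAYOUTS:
            raise ValueError(f"unknown subtype {subtype!r} and no layout given")
        layout = SUBTYPE_LAYOUTS[subtype]
    span = len(layout) + (1 if insert_intervening else 0)
    replicon = genes[0].replicon_id if genes else ""
    indexed = {g.gene_index: g for g in genes}
    if start_index < 0 or start_index + span - 1 not in indexed:
        raise ValueError(
            f"layout of {span} genes does not fit at index {start_index} "
            f"on replicon {replicon!r} ({len(genes)} genes)"
        )
    roles: dict[str, str] = {}
    mid = span // 2
    offset = 0
    for k, (family, strength) in enumerate(layout):
        if insert_intervening and k == mid:
            g = indexed[start_index + k + offset]
            roles[g.protein_id] = "intervening"
            offset = 1
        g = indexed[start_index + k + offset]
        roles[g.protein_id] = "seed" if strength == "strong" else "recruit"
        truth.family_assignments[g.protein_id] = family
    first = start_index
    last = start_index + span - 1
    truth.planted_loci.append(PlantedLocus(replicon, first, last, subtype, roles))
    return truth


def plant_annotated_insertion(
    genes: list[GeneRecord],
    truth: SimTruth,
    locus: PlantedLocus,
    family_id: str,
    strand: str | None = None,
) -> str:
    """Convert one intervening member of a planted locus into a gene with a
    known non-cas annotation (e.g. a transposase family).

    Returns the protein id.  If the locus has no intervening member, the
    caller should have planted it with ``insert_intervening=True``.
    """
    inter = [p for p, r in locus.roles.items() if r == "intervening"]
    if not inter:
        raise ValueError(f"locus at {locus.first_index} has no intervening member")
    pid = inter[0]
    truth.extra_annotations[pid] = family_id
    if strand is not None:
        for i, g in enumerate(genes):
            if g.protein_id == pid:
                genes[i] = GeneRecord(g.replicon_id, g.gene_index, g.start, g.end,
                                      strand, g.protein_id, g.product)
    return pid


def plant_ta_pair(
    genes: list[GeneRecord],
    truth: SimTruth,
    locus: PlantedLocus,
    antitoxin_family: str = "PhdYeFM_antitox",
    toxin_family: str = "PIN",
    antitoxin_upstream: bool = True,
    strand: str = "+",
) -> tuple[str, str]:
    """Plant an adjacent antitoxin/toxin gene pair just inside a planted locus.

    The pair occupies the two interior genes just before the locus end
    (so locus boundaries stay cas-labeled and early signature genes are
    untouched); their cas roles are removed — TA genes are intervening genes
    whose family tags appear only in the full-database annotation table via
    ``truth.extra_annotations``.
    """
    if locus.last_index - locus.first_index < 3:
        raise ValueError("locus too short to host an interior TA pair")
    i, j = locus.last_index - 2, locus.last_index - 1
    by_index = {g.gene_index: k for k, g in enumerate(genes)}
    upstream_pid = genes[by_index[i]].protein_id
    downstream_pid = genes[by_index[j]].protein_id
    if antitoxin_upstream:
        pid_a, pid_t = upstream_pid, downstream_pid
    else:
        pid_a, pid_t = downstream_pid, upstream_pid
    fam_of = {pid_a: antitoxin_family, pid_t: toxin_family}
    for idx in (i, j):
        k = by_index[idx]
        g = genes[k]
        locus.roles[g.protein_id] = "intervening"
        truth.family_assignments.pop(g.protein_id, None)
        truth.extra_annotations[g.protein_id] = fam_of[g.protein_id]
        genes[k] = GeneRecord(g.replicon_id, g.gene_index, g.start, g.end,
                              strand, g.protein_id, g.product)
    truth.ta_pairs.append((pid_a, pid_t))
    return pid_a, pid_t


# ---------------------------------------------------------------------------
# controlled-identity sequences

def mutate_to_identity(
    seq: str,
    target_identity: float,
    seed: int = 0,
    params: AlignmentParams = DEFAULT_PARAMS,
    tolerance: float = 0.02,
) -> str:
    """Substitute residues so the result aligns to ``seq`` at ~target identity.

    Substitutions only (no indels); the realized global-alignment identity is
    checked with the module's own aligner and nudged until it is within
    ``tolerance`` of the target.  Sequences shorter than 20 residues are
    rejected: the identity grid is too coarse to hit a target reliably.
    """
    if not 0 < target_identity <= 1:
        raise ValueError(f"target_identity must be in (0, 1], got {target_identity}")
    if len(seq) < 20:
        raise ValueError(f"sequence too short ({len(seq)} aa) for identity targeting")
    if target_identity == 1.0:
        return seq
    rng = derive_rng(seed, "mutate")
    n = len(seq)
    order = rng.permutation(n)
    n_mut = round((1 - target_identity) * n)
    residues = list(seq)

    def substitute(pos: int) -> None:
        choices = [a for a in AMINO_ACIDS if a != seq[pos]]
        residues[pos] = choices[rng.integers(len(choices))]

    for pos in order[:n_mut]:
        substitute(pos)
    # alignment may open gaps and shift realized identity off the naive count
    for _ in range(50):
        realized = align_pair(seq, "".join(residues), params).identity
        if abs(realized - target_identity) <= tolerance:
            break
        if realized > target_identity and n_mut < n:
            substitute(order[n_mut])
            n_mut += 1
        elif realized < target_identity and n_mut > 0:
            n_mut -= 1
            residues[order[n_mut]] = seq[order[n_mut]]
        else:
            break
    return "".join(residues)


def generate_family(
    n_members: int,
    length: int,
    pairwise_identity: float,
    seed: int = 0,
    prefix: str = "fam",
) -> dict[str, str]:
    """Generate a protein family at a controlled approximate pairwise identity.

    Members are derived independently from a common random ancestor; for a
    target member-member identity t the per-member ancestor identity is
    ~sqrt(t) (two independent substitution processes compose).
    """
    rng = derive_rng(seed, f"family:{prefix}")
    ancestor = _random_protein(rng, length)
    d = float(np.sqrt(pairwise_identity))
    out = {}
    for i in range(n_members):
        out[f"{prefix}_{i:02d}"] = mutate_to_identity(
            ancestor, d, seed=int(rng.integers(2**31))
        )
    return out


def generate_divergent_family(
    n_members: int,
    length: int,
    identity_range: tuple[float, float] = (0.65, 0.95),
    seed: int = 0,
    prefix: str = "fam",
) -> dict[str, str]:
    """Generate a family whose members span a range of divergence.

    Member i sits at an ancestor identity spaced evenly across
    ``identity_range`` (first member most divergent).  Real protein families
    mix close and remote homologs; profile-refinement behavior (which
    sequences score above the worst seed) depends on that heterogeneity, so
    uniformly divergent families are a poor emulation for it.
    """
    rng = derive_rng(seed, f"divfamily:{prefix}")
    ancestor = _random_protein(rng, length)
    lo, hi = identity_range
    out = {}
    for i in range(n_members):
        frac = i / max(n_members - 1, 1)
        ident = lo + (hi - lo) * frac
        out[f"{prefix}_{i:02d}"] = mutate_to_identity(
            ancestor, ident, seed=int(rng.integers(2**31))
        )
    return out


def make_refinement_scenario(
    n_seeds: int = 5,
    n_members: int = 3,
    n_decoys: int = 50,
    length: int = 120,
    member_identity: float = 0.97,
    seed: int = 0,
) -> tuple[dict[str, str], dict[str, str], set[str]]:
    """Build (seed set, database, held-out member ids) for profile refinement.

    The seed set is a divergence-range family.  The database holds the
    held-out true members — close variants (``member_identity``) of the
    least divergent seeds, emulating the redundant homologs that a 90%
    identity reduction removes from a seed set but that remain in the
    sequence database — plus unrelated random decoys.
    """
    fam = generate_divergent_family(n_seeds, length, seed=seed, prefix="seed")
    ids = sorted(fam)
    rng = derive_rng(seed, "refine-members")
    database: dict[str, str] = {}
    members: set[str] = set()
    for j in range(n_members):
        donor = ids[-(j + 1)]  # least divergent seeds first
        mid = f"member_{j:02d}"
        database[mid] = mutate_to_identity(
            fam[donor], member_identity, seed=int(rng.integers(2**31))
        )
        members.add(mid)
    for j in range(n_decoys):
        database[f"decoy_{j:02d}"] = _random_protein(rng, length)
    return fam, database, members


# ---------------------------------------------------------------------------
# hit tables

def emit_hit_table(
    truth: SimTruth,
    all_gene_ids: list[str],
    fp_rate: float = 0.0,
    seed: int = 0,
) -> list[FamilyHit]:
    """Emit the cas-family hit table implied by the planted roles.

    Seed-role members get gathering-threshold hits (E in [1e-30, 1e-10]);
    recruit-role members get weak hits (E in [1e-6, 1e-3], below gathering
    but at or under the 0.001 recruitment cut).  Each non-cas gene draws a
    spurious weak hit with probability ``fp_rate``; spurious E-values sit in
    (1e-3, 10] so they never satisfy the recruitment threshold, and spurious
    hits never meet the gathering cutoff.
    """
    if not 0 <= fp_rate < 1:
        raise ValueError(f"fp_rate must be in [0, 1), got {fp_rate}")
    rng = derive_rng(seed, "hits")
    hits: list[FamilyHit] = []
    for locus in truth.planted_loci:
        for pid, role in sorted(locus.roles.items()):
            if role == "intervening":
                continue
            family = truth.family_assignments[pid]
            if role == "seed":
                e = 10 ** rng.uniform(-30, -10)
                bit = rng.uniform(200, 500)
                hits.append(FamilyHit(pid, family, round(bit, 1), e, True))
            else:
                e = 10 ** rng.uniform(-6, -3)
                bit = rng.uniform(25, 60)
                hits.append(FamilyHit(pid, family, round(bit, 1), e, False))
    cas_ids = truth.cas_protein_ids()
    families = sorted(set(truth.family_assignments.values())) or ["cas1"]
    truth.decoys = []
    for pid in all_gene_ids:
        if pid in cas_ids:
            continue
        if rng.random() < fp_rate:
            fam = families[rng.integers(len(families))]
            e = 10 ** rng.uniform(-2.99, 1)
            hits.append(FamilyHit(pid, fam, round(rng.uniform(10, 25), 1), e, False))
            truth.decoys.append(pid)
    return hits


def emit_full_annotation_table(truth: SimTruth, seed: int = 0) -> list[FamilyHit]:
    """Hit table against the full family database (cas plus everything else).

    Contains every cas-family hit source plus the planted non-cas
    annotations (transposases, toxins/antitoxins, ...), which is what routes
    an intervening gene to the assorted-functions report instead of the
    novel-candidate set.
    """
    rng = derive_rng(seed, "fullhits")
    hits: list[FamilyHit] = []
    for pid, fam in sorted(truth.family_assignments.items()):
        hits.append(FamilyHit(pid, fam, round(rng.uniform(50, 300), 1),
                              10 ** rng.uniform(-20, -5), True))
    for pid, fam in sorted(truth.extra_annotations.items()):
        hits.append(FamilyHit(pid, fam, round(rng.uniform(40, 200), 1),
                              10 ** rng.uniform(-15, -5), False))
    return hits


# ---------------------------------------------------------------------------
# cohort

DEFAULT_HABITAT_MEANS = {
    "stool": 0.002,
    "tongue_dorsum": 0.006,
    "supragingival_plaque": 0.005,
    "buccal_mucosa": 0.003,
}


def simulate_cohort(
    n_subjects: int = 65,
    habitat_means: dict[str, float] | None = None,
    dispersion: float = 0.3,
    n_genes_range: tuple[int, int] = (20_000, 60_000),
    seed: int = 0,
) -> list[SampleInventory]:
    """Simulate per-subject, per-habitat gene inventories.

    Each subject x habitat gets an independent mean-corrected lognormal
    fluctuation around the habitat mean: cas-gene abundances at different
    body sites of the same subject are uncorrelated, which is what
    within-subject comparisons of real stool vs oral communities show.
    n_cas_genes is binomial at the subject-habitat fraction over a uniform
    total gene count.
    """
    habitat_means = dict(DEFAULT_HABITAT_MEANS if habitat_means is None else habitat_means)
    for h, f in habitat_means.items():
        if not 0 <= f < 1:
            raise ValueError(f"habitat {h!r}: fraction {f} outside [0, 1)")
    rng = derive_rng(seed, "cohort")
    out: list[SampleInventory] = []
    s_hab = dispersion
    for s in range(n_subjects):
        subj = f"S{s:03d}"
        for habitat in sorted(habitat_means):
            mean = habitat_means[habitat]
            v = float(np.exp(rng.normal(0, s_hab) - s_hab**2 / 2))
            frac = min(mean * v, 0.5)
            n_total = int(rng.integers(n_genes_range[0], n_genes_range[1] + 1))
            n_cas = int(rng.binomial(n_total, frac))
            out.append(SampleInventory(subj, habitat, n_total, n_cas))
    return out
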