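"""Type/subtype assignment and locus-content statistics.

A locus is assigned to a type or subtype when the corresponding signature
gene is present among its known-cas members.  Subtype II-C — the minimal
type II system with only cas9, cas1 and cas2 — has no signature gene and is
defined by exact composition; it is only called on complete genomes, because
a truncated locus of another subtype on a contig would masquerade as II-C.

The module also reports cross-type co-occurrence (e.g. cas9 sitting inside
a type I or III locus), adjacent toxin-antitoxin gene pairs with their
orientation relative to the cas genes, and the fraction of a family's
members (e.g. a transposase family) landing on the strand opposite the cas
genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .io_model import CasLabel, CasLocus, Completeness, GeneRecord

__all__ = [
    "SignatureMap",
    "SubtypeCall",
    "TAPair",
    "TAFamilies",
    "load_signature_map",
    "load_ta_families",
    "assign_types",
    "detect_cooccurrence",
    "detect_toxin_antitoxin",
    "strand_opposition_fraction",
    "majority_cas_strand",
]


@dataclass(frozen=True)
class SignatureRule:
    family_id: str
    type: str | None
    subtype: str | None
    role: str
    requires: str | None = None


@dataclass
class SignatureMap:
    rules: dict[str, SignatureRule]
    ii_c_composition: frozenset[str]
    ii_c_subtype: str = "II-C"
    ii_c_type: str = "II"

    def known_cas_families(self) -> set[str]:
        return set(self.rules)


@dataclass
class SubtypeCall:
    locus_id: str
    types: set[str] = field(default_factory=set)
    subtypes: set[str] = field(default_factory=set)
    evidence: dict[str, set[str]] = field(default_factory=dict)
    cooccurrence_flags: set[str] = field(default_factory=set)


@dataclass(frozen=True)
class TAPair:
    antitoxin_protein_id: str
    toxin_protein_id: str
    antitoxin_upstream: bool
    antitoxin_same_strand_as_cas: bool | None
    toxin_same_strand_as_cas: bool | None


@dataclass(frozen=True)
class TAFamilies:
    toxins: frozenset[str]
    antitoxins: frozenset[str]


def _default_config(name: str) -> Path:
    return Path(str(resources.files("casforge").joinpath("data", name)))


def load_signature_map(path: str | Path | None = None) -> SignatureMap:
    """Load the signature map (default: the YAML shipped with the package)."""
    path = _default_config("signature_map.yaml") if path is None else Path(path)
    raw = yaml.safe_load(path.read_text())
    rules = {}
    for fam, entry in raw["families"].items():
        rules[str(fam)] = SignatureRule(
            family_id=str(fam),
            type=entry.get("type"),
            subtype=entry.get("subtype"),
            role=entry["role"],
            requires=entry.get("requires"),
        )
    iic = raw["ii_c"]
    return SignatureMap(
        rules=rules,
        ii_c_composition=frozenset(iic["composition"]),
        ii_c_subtype=iic["subtype"],
        ii_c_type=iic["type"],
    )


def load_ta_families(path: str | Path | None = None) -> TAFamilies:
    path = _default_config("ta_families.yaml") if path is None else Path(path)
    raw = yaml.safe_load(path.read_text())
    return TAFamilies(frozenset(raw["toxins"]), frozenset(raw["antitoxins"]))


def assign_types(
    locus: CasLocus,
    annotations: dict[str, str],
    sigmap: SignatureMap | None = None,
) -> SubtypeCall:
    """Assign types/subtypes to one locus from its members' family annotations.

    ``annotations`` maps member protein ids to family ids (from the best hit
    of seed/recruited members).  Unknown family ids raise a warning and are
    ignored.  Types are the union of the called subtypes' parents plus any
    type-signature-only evidence (cas3 alone still marks type I).
    """
    sigmap = sigmap or load_signature_map()
    call = SubtypeCall(locus_id=locus.locus_id)
    known_members = [
        pid for pid, lab in locus.members if lab is not CasLabel.INTERVENING_UNKNOWN
    ]
    families: dict[str, set[str]] = {}
    for pid in known_members:
        fam = annotations.get(pid)
        if fam is None:
            continue
        if fam not in sigmap.rules:
            warnings.warn(f"locus {locus.locus_id}: unknown family {fam!r} ignored")
            continue
        families.setdefault(fam, set()).add(pid)

    present = set(families)
    for fam in sorted(present):
        rule = sigmap.rules[fam]
        if rule.role == "type_signature" and rule.type:
            call.types.add(rule.type)
        elif rule.role == "subtype_signature" and rule.subtype:
            if rule.requires and rule.requires not in present:
                continue
            call.subtypes.add(rule.subtype)
            call.types.add(rule.type)
            call.evidence.setdefault(rule.subtype, set()).add(fam)

    # II-C: exact composition on complete genomes only
    if (
        locus.completeness is Completeness.COMPLETE_GENOME
        and present == sigmap.ii_c_composition
    ):
        call.subtypes.add(sigmap.ii_c_subtype)
        call.types.add(sigmap.ii_c_type)
        call.evidence.setdefault(sigmap.ii_c_subtype, set()).update(present)
    return call


def detect_cooccurrence(
    call: SubtypeCall,
    annotations: dict[str, str],
    locus: CasLocus,
    sigmap: SignatureMap | None = None,
) -> SubtypeCall:
    """Flag loci whose signature content spans more than one type.

    Adds "II+<X>" for every non-II type or subtype X co-occurring with cas9
    in the locus, and a sorted "<A>+<B>" flag for every pair of distinct
    types present.  Mutates and returns ``call``.
    """
    sigmap = sigmap or load_signature_map()
    member_fams = {
        annotations[pid]
        for pid, lab in locus.members
        if lab is not CasLabel.INTERVENING_UNKNOWN and pid in annotations
    }
    has_cas9 = "cas9" in member_fams
    if has_cas9:
        for st in sorted(call.subtypes):
            if not st.startswith("II-"):
                call.cooccurrence_flags.add(f"II+{st}")
        for t in sorted(call.types):
            if t != "II" and not any(f.startswith(f"II+{t}-") for f in call.cooccurrence_flags):
                call.cooccurrence_flags.add(f"II+{t}")
    types = sorted(call.types)
    for i, a in enumerate(types):
        for b in types[i + 1:]:
            call.cooccurrence_flags.add(f"{a}+{b}")
    return call


def majority_cas_strand(locus: CasLocus, genes_by_id: dict[str, GeneRecord]) -> str | None:
    """Majority strand of the locus's SEED_KNOWN + RECRUITED_KNOWN members.

    Returns '+', '-' or None on a tie (orientation indeterminate).
    """
    plus = minus = 0
    for pid, lab in locus.members:
        if lab is CasLabel.INTERVENING_UNKNOWN:
            continue
        if genes_by_id[pid].strand == "+":
            plus += 1
        else:
            minus += 1
    if plus == minus:
        return None
    return "+" if plus > minus else "-"


def detect_toxin_antitoxin(
    locus: CasLocus,
    annotations: dict[str, str],
    genes: list[GeneRecord],
    ta: TAFamilies | None = None,
    max_gap: int = 2,
) -> list[TAPair]:
    """Find adjacent (antitoxin, toxin) member pairs inside a locus.

    ``annotations`` here includes the full-database annotations of
    intervening genes (TA families are not Cas families).  Pairs must sit
    within ``max_gap`` gene indices of each other.  Orientation is recorded
    relative to the locus's majority cas strand: ``antitoxin_upstream`` means
    the antitoxin precedes the toxin in cas transcription direction;
    per-member strand agreement is None when the cas strand is indeterminate.
    """
    ta = ta or load_ta_families()
    genes_by_id = {g.protein_id: g for g in genes}
    member_ids = [pid for pid, _ in locus.members]
    antitoxins = [p for p in member_ids if annotations.get(p) in ta.antitoxins]
    toxins = [p for p in member_ids if annotations.get(p) in ta.toxins]
    cas_strand = majority_cas_strand(locus, genes_by_id)
    pairs: list[TAPair] = []
    for a in antitoxins:
        for t in toxins:
            ga, gt = genes_by_id[a], genes_by_id[t]
            if abs(ga.gene_index - gt.gene_index) > max_gap:
                continue
            if cas_strand is None:
                upstream = ga.gene_index < gt.gene_index
                same_a = same_t = None
            else:
                # upstream in transcription direction of the cas genes
                if cas_strand == "+":
                    upstream = ga.gene_index < gt.gene_index
                else:
                    upstream = ga.gene_index > gt.gene_index
                same_a = ga.strand == cas_strand
                same_t = gt.strand == cas_strand
            pairs.append(TAPair(a, t, upstream, same_a, same_t))
    return pairs


def strand_opposition_fraction(
    loci: list[CasLocus],
    genes: list[GeneRecord],
    annotations: dict[str, str],
    family_id: str,
) -> tuple[int, int, float]:
    """Fraction of a family's locus members on the strand opposite the cas genes.

    Members in loci with an indeterminate cas strand are excluded from both
    counts.  Raises when no locus contains the family on a determinate
    strand.
    """
    genes_by_id = {g.protein_id: g for g in genes}
    n_opp = n_tot = 0
    for locus in loci:
        cas_strand = majority_cas_strand(locus, genes_by_id)
        if cas_strand is None:
            continue
        for pid, _ in locus.members:
            if annotations.get(pid) != family_id:
                continue
            n_tot += 1
            if genes_by_id[pid].strand != cas_strand:
                n_opp += 1
    if n_tot == 0:
        raise ValueError(f"no locus member annotated to family {family_id!r}")
    return n_opp, n_tot, n_opp / n_tot
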