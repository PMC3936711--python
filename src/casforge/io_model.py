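"""Domain types and readers/writers for the formats the pipeline touches.

The pipeline works on per-replicon gene annotations (GFF3 or a plain TSV
dialect), protein sequences (FASTA), and protein-vs-family similarity hit
tables (TSV modelled on tabular hmmscan output).  Coordinates are 1-based
inclusive throughout, following GFF3 convention.  Downstream modules never
use base-pair distances: the only distance metric is ``gene_index``, the
0-based rank of a gene in replicon coordinate order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "GeneRecord",
    "FamilyHit",
    "CasLabel",
    "CasLocus",
    "SampleInventory",
    "Completeness",
    "read_gene_table",
    "write_gene_table",
    "read_hit_table",
    "write_hit_table",
    "read_fasta",
    "write_fasta",
    "write_locus_report",
    "read_cohort_table",
    "write_cohort_table",
]


class CasLabel(Enum):
    """Role of a gene inside a cas locus.

    SEED_KNOWN genes hit a known Cas family at the family's trusted
    (gathering) threshold; RECRUITED_KNOWN genes carry only a weak hit
    (E <= 0.001) and were pulled in by neighborhood expansion;
    INTERVENING_UNKNOWN genes have no known-family affinity but sit between
    cas genes inside a locus — these are the source of novel-family
    candidates.
    """

    SEED_KNOWN = "SEED_KNOWN"
    RECRUITED_KNOWN = "RECRUITED_KNOWN"
    INTERVENING_UNKNOWN = "INTERVENING_UNKNOWN"


class Completeness(Enum):
    COMPLETE_GENOME = "COMPLETE_GENOME"
    DRAFT_OR_CONTIG = "DRAFT_OR_CONTIG"


@dataclass(frozen=True)
class GeneRecord:
    """One annotated gene on a replicon (1-based inclusive bp coordinates)."""

    replicon_id: str
    gene_index: int
    start: int
    end: int
    strand: str
    protein_id: str
    product: str | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"gene {self.protein_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.protein_id}: bad strand {self.strand!r}")
        if self.gene_index < 0:
            raise ValueError(f"gene {self.protein_id}: negative gene_index")


@dataclass(frozen=True)
class FamilyHit:
    """One protein-vs-family similarity hit.

    ``meets_gathering`` marks hits at or above the family's curated trusted
    threshold; such hits are confident family assignments and seed the
    neighborhood recruitment.  It is carried in the hit table (precomputed by
    whatever scorer produced it) rather than re-derived here.
    """

    protein_id: str
    family_id: str
    bit_score: float
    e_value: float
    meets_gathering: bool

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise ValueError(
                f"hit {self.protein_id}/{self.family_id}: negative E-value"
            )


@dataclass
class CasLocus:
    """A maximal run of cas-labeled genes plus intervening unknowns.

    ``completeness`` records whether the source replicon is a finished
    genome or a draft/metagenome contig; the II-C subtype rule depends on it.
    """

    locus_id: str
    replicon_id: str
    first_index: int
    last_index: int
    members: list[tuple[str, CasLabel]]
    completeness: Completeness

    def member_ids(self, label: CasLabel | None = None) -> list[str]:
        return [p for p, lab in self.members if label is None or lab is label]

    def label_counts(self) -> dict[CasLabel, int]:
        counts = {lab: 0 for lab in CasLabel}
        for _, lab in self.members:
            counts[lab] += 1
        return counts

    def validate(self) -> None:
        if not any(lab is CasLabel.SEED_KNOWN for _, lab in self.members):
            raise ValueError(f"locus {self.locus_id}: no SEED_KNOWN member")
        if len(self.members) != self.last_index - self.first_index + 1:
            raise ValueError(f"locus {self.locus_id}: members not contiguous")
        for _, lab in (self.members[0], self.members[-1]):
            if lab is CasLabel.INTERVENING_UNKNOWN:
                raise ValueError(
                    f"locus {self.locus_id}: boundary member is INTERVENING_UNKNOWN"
                )


@dataclass(frozen=True)
class SampleInventory:
    """Gene inventory of one subject x body habitat sample."""

    subject_id: str
    habitat: str
    n_total_genes: int
    n_cas_genes: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_cas_genes <= self.n_total_genes:
            raise ValueError(
                f"sample {self.subject_id}/{self.habitat}: "
                f"n_cas_genes {self.n_cas_genes} outside [0, {self.n_total_genes}]"
            )


# ---------------------------------------------------------------------------
# gene tables

_TSV_GENE_COLUMNS = ["replicon_id", "start", "end", "strand", "protein_id", "product"]


def _assign_indices(records: list[GeneRecord]) -> list[GeneRecord]:
    """Sort by (replicon_id, start) and assign gene_index per replicon."""
    records = sorted(records, key=lambda r: (r.replicon_id, r.start, r.protein_id))
    out: list[GeneRecord] = []
    counter: dict[str, int] = {}
    for r in records:
        i = counter.get(r.replicon_id, 0)
        counter[r.replicon_id] = i + 1
        out.append(
            GeneRecord(r.replicon_id, i, r.start, r.end, r.strand, r.protein_id, r.product)
        )
    return out


def _parse_gff3_attributes(attrs: str) -> dict[str, str]:
    out = {}
    for part in attrs.strip().split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gene_table(path: str | Path, dialect: str = "tsv") -> list[GeneRecord]:
    """Read gene annotations from ``path``.

    ``dialect`` is ``"gff3"`` (CDS/gene features; the ID attribute becomes the
    protein id) or ``"tsv"`` (header replicon_id/start/end/strand/protein_id
    with optional product).  Records are returned sorted by
    (replicon_id, start) with gene_index assigned per replicon in that order.
    """
    path = Path(path)
    raw: list[GeneRecord] = []
    if dialect == "gff3":
        for lineno, line in enumerate(path.read_text().splitlines(), 1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9:
                raise ValueError(f"{path}:{lineno}: GFF3 row has {len(cols)} columns")
            seqid, _src, ftype, start_s, end_s, _score, strand, _phase, attrs = cols[:9]
            if ftype not in ("CDS", "gene"):
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate") from None
            if start > end:
                raise ValueError(f"{path}:{lineno}: start {start} > end {end}")
            attrd = _parse_gff3_attributes(attrs)
            if "ID" not in attrd:
                raise ValueError(f"{path}:{lineno}: missing ID attribute")
            raw.append(
                GeneRecord(seqid, 0, start, end, strand, attrd["ID"], attrd.get("product"))
            )
    elif dialect == "tsv":
        lines = path.read_text().splitlines()
        if not lines:
            return []
        header = lines[0].rstrip("\n").split("\t")
        required = {"replicon_id", "start", "end", "strand", "protein_id"}
        if not required <= set(header):
            raise ValueError(f"{path}: missing columns {required - set(header)}")
        idx = {name: header.index(name) for name in header}
        for lineno, line in enumerate(lines[1:], 2):
            if not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            try:
                start = int(cols[idx["start"]])
                end = int(cols[idx["end"]])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate") from None
            if start > end:
                raise ValueError(f"{path}:{lineno}: start {start} > end {end}")
            product = None
            if "product" in idx and len(cols) > idx["product"] and cols[idx["product"]]:
                product = cols[idx["product"]]
            raw.append(
                GeneRecord(
                    cols[idx["replicon_id"]], 0, start, end,
                    cols[idx["strand"]], cols[idx["protein_id"]], product,
                )
            )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    seen: set[str] = set()
    for r in raw:
        if r.protein_id in seen:
            raise ValueError(f"{path}: duplicate protein_id {r.protein_id!r}")
        seen.add(r.protein_id)
    return _assign_indices(raw)


def write_gene_table(records: Iterable[GeneRecord], path: str | Path) -> None:
    """Write records as the plain TSV dialect (round-trips with read_gene_table)."""
    path = Path(path)
    lines = ["\t".join(_TSV_GENE_COLUMNS)]
    for r in sorted(records, key=lambda r: (r.replicon_id, r.start)):
        lines.append(
            "\t".join(
                [r.replicon_id, str(r.start), str(r.end), r.strand, r.protein_id,
                 r.product or ""]
            )
        )
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# hit tables

_HIT_COLUMNS = ["protein_id", "family_id", "bit_score", "e_value", "meets_gathering"]
_BOOL_TOKENS = {"true": True, "false": False, "1": True, "0": False}


def read_hit_table(path: str | Path) -> list[FamilyHit]:
    """Read a protein-vs-family hit table.

    Per (protein, family) only the best row is retained: lowest E-value,
    ties broken by highest bit score.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        return []
    header = lines[0].rstrip("\n").split("\t")
    if header != _HIT_COLUMNS:
        raise ValueError(f"{path}: expected columns {_HIT_COLUMNS}, got {header}")
    best: dict[tuple[str, str], FamilyHit] = {}
    for lineno, line in enumerate(lines[1:], 2):
        if not line.strip():
            continue
        cols = line.rstrip("\n").split("\t")
        if len(cols) != 5:
            raise ValueError(f"{path}:{lineno}: expected 5 columns")
        tok = cols[4].strip().lower()
        if tok not in _BOOL_TOKENS:
            raise ValueError(f"{path}:{lineno}: unknown boolean token {cols[4]!r}")
        hit = FamilyHit(cols[0], cols[1], float(cols[2]), float(cols[3]),
                        _BOOL_TOKENS[tok])
        key = (hit.protein_id, hit.family_id)
        prev = best.get(key)
        if prev is None or (hit.e_value, -hit.bit_score) < (prev.e_value, -prev.bit_score):
            best[key] = hit
    return [best[k] for k in sorted(best)]


def write_hit_table(hits: Iterable[FamilyHit], path: str | Path) -> None:
    path = Path(path)
    lines = ["\t".join(_HIT_COLUMNS)]
    for h in hits:
        lines.append(
            "\t".join(
                [h.protein_id, h.family_id, f"{h.bit_score:.1f}", f"{h.e_value:.6g}",
                 "true" if h.meets_gathering else "false"]
            )
        )
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into {id: sequence}; ids are the first header token.

    Sequences are upper-cased and terminal '*' stop markers stripped.
    Duplicate ids and empty sequences are errors.
    """
    path = Path(path)
    out: dict[str, str] = {}
    name: str | None = None
    chunks: list[str] = []

    def flush() -> None:
        if name is None:
            return
        seq = "".join(chunks).upper().strip("*")
        if not seq:
            raise ValueError(f"{path}: empty sequence for {name!r}")
        if name in out:
            raise ValueError(f"{path}: duplicate id {name!r}")
        out[name] = seq

    for line in path.read_text().splitlines():
        if line.startswith(">"):
            flush()
            name = line[1:].split()[0] if line[1:].split() else ""
            if not name:
                raise ValueError(f"{path}: empty FASTA header")
            chunks = []
        elif line.strip():
            chunks.append(line.strip())
    flush()
    return out


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    path = Path(path)
    lines = []
    for name, seq in seqs.items():
        lines.append(f">{name}")
        for i in range(0, len(seq), width):
            lines.append(seq[i : i + width])
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# locus report

def write_locus_report(loci: list[CasLocus], calls: list, path: str | Path) -> None:
    """Write one TSV row per locus plus a JSON sidecar with full member lists.

    ``calls`` are SubtypeCall objects (duck-typed: locus_id, types, subtypes,
    evidence attributes); every call must reference an existing locus.
    """
    path = Path(path)
    by_locus = {l.locus_id: l for l in loci}
    calls_by_locus: dict[str, object] = {}
    for c in calls:
        if c.locus_id not in by_locus:
            raise ValueError(f"call references unknown locus {c.locus_id!r}")
        calls_by_locus[c.locus_id] = c

    header = [
        "locus_id", "replicon_id", "first_index", "last_index",
        "n_seed", "n_recruited", "n_intervening", "types", "subtypes",
        "evidence_families",
    ]
    lines = ["\t".join(header)]
    sidecar = []
    for locus in loci:
        counts = locus.label_counts()
        call = calls_by_locus.get(locus.locus_id)
        types = ",".join(sorted(call.types)) if call else ""
        subtypes = ",".join(sorted(call.subtypes)) if call else ""
        evidence = ""
        if call:
            evidence = ";".join(
                f"{st}:{','.join(sorted(fams))}" for st, fams in sorted(call.evidence.items())
            )
        lines.append(
            "\t".join(
                [locus.locus_id, locus.replicon_id, str(locus.first_index),
                 str(locus.last_index), str(counts[CasLabel.SEED_KNOWN]),
                 str(counts[CasLabel.RECRUITED_KNOWN]),
                 str(counts[CasLabel.INTERVENING_UNKNOWN]), types, subtypes, evidence]
            )
        )
        sidecar.append(
            {
                "locus_id": locus.locus_id,
                "replicon_id": locus.replicon_id,
                "completeness": locus.completeness.value,
                "members": [[p, lab.value] for p, lab in locus.members],
                "types": sorted(call.types) if call else [],
                "subtypes": sorted(call.subtypes) if call else [],
            }
        )
    path.write_text("\n".join(lines) + "\n")
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


# ---------------------------------------------------------------------------
# cohort tables

_COHORT_COLUMNS = ["subject_id", "habitat", "n_total_genes", "n_cas_genes"]


def read_cohort_table(path: str | Path) -> list[SampleInventory]:
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        return []
    header = lines[0].rstrip("\n").split("\t")
    if header != _COHORT_COLUMNS:
        raise ValueError(f"{path}: expected columns {_COHORT_COLUMNS}")
    out = []
    for line in lines[1:]:
        if not line.strip():
            continue
        s, h, nt, nc = line.rstrip("\n").split("\t")
        out.append(SampleInventory(s, h, int(nt), int(nc)))
    return out


def write_cohort_table(samples: Iterable[SampleInventory], path: str | Path) -> None:
    path = Path(path)
    lines = ["\t".join(_COHORT_COLUMNS)]
    for s in samples:
        lines.append("\t".join([s.subject_id, s.habitat, str(s.n_total_genes),
                                str(s.n_cas_genes)]))
    path.write_text("\n".join(lines) + "\n")
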