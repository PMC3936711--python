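"""Cas9 catalytic-residue screening.

Cas9 cleaves each target DNA strand with a separate nuclease domain: the
RuvC-like domain (catalytic aspartate at position 10 of the Streptococcus
pyogenes protein) cuts the strand non-complementary to the crRNA, and the
HNH domain (catalytic histidine at position 840) cuts the complementary
strand; mutating either to alanine abolishes that cut.  Candidate Cas9
proteins are therefore screened for both residues by mapping reference
positions through a global alignment.
"""

from __future__ import annotations

from dataclasses import dataclass

from .alignment import AlignmentParams, DEFAULT_PARAMS, aligned_strings

__all__ = [
    "ResidueRequirement",
    "DEFAULT_CAS9_REQUIREMENTS",
    "SiteReport",
    "map_positions",
    "has_catalytic_residues",
]


@dataclass(frozen=True)
class ResidueRequirement:
    """A required residue at a 1-based position of the reference protein."""

    reference_position: int
    required_residue: str

    def __post_init__(self) -> None:
        if self.reference_position < 1:
            raise ValueError("reference_position must be >= 1")


DEFAULT_CAS9_REQUIREMENTS = (
    ResidueRequirement(10, "D"),
    ResidueRequirement(840, "H"),
)


@dataclass(frozen=True)
class SiteReport:
    reference_position: int
    required_residue: str
    candidate_position: int | None  # 1-based, None when unaligned
    observed_residue: str | None
    satisfied: bool


def map_positions(
    candidate: str,
    reference: str,
    positions: list[int],
    params: AlignmentParams = DEFAULT_PARAMS,
) -> dict[int, int | None]:
    """Map 1-based reference positions onto the candidate via global alignment.

    Returns {reference_position: candidate_position or None} where None
    marks a reference column that aligns to a gap in the candidate.
    """
    if max(positions, default=1) > len(reference):
        raise ValueError(
            f"reference ({len(reference)} aa) shorter than queried position "
            f"{max(positions)}"
        )
    ref_row, cand_row = aligned_strings(reference, candidate, params)
    wanted = set(positions)
    out: dict[int, int | None] = {}
    ref_pos = cand_pos = 0
    for rc, cc in zip(ref_row, cand_row):
        if cc != "-":
            cand_pos += 1
        if rc != "-":
            ref_pos += 1
            if ref_pos in wanted:
                out[ref_pos] = cand_pos if cc != "-" else None
    return out


def has_catalytic_residues(
    candidate: str,
    reference: str,
    requirements: tuple[ResidueRequirement, ...] = DEFAULT_CAS9_REQUIREMENTS,
    params: AlignmentParams = DEFAULT_PARAMS,
) -> tuple[bool, list[SiteReport]]:
    """Check every required site; True iff all map to the required residue."""
    mapping = map_positions(
        candidate, reference, [r.reference_position for r in requirements], params
    )
    reports: list[SiteReport] = []
    ok = True
    for req in requirements:
        cand_pos = mapping[req.reference_position]
        observed = candidate[cand_pos - 1] if cand_pos is not None else None
        satisfied = observed == req.required_residue
        ok = ok and satisfied
        reports.append(
            SiteReport(req.reference_position, req.required_residue,
                       cand_pos, observed, satisfied)
        )
    return ok, reports
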