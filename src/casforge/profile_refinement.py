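"""Per-family scoring profiles with gathering/trusted/noise cutoffs.

For each novel family: drop length outliers (two population standard
deviations or more from the family mean, both tails), align the remainder
with a center-star multiple alignment, and build a position-specific
scoring model (log-odds in bits, Laplace-style background-weighted
pseudocounts, majority-gap columns dropped).  The model is then refined by
recruiting database sequences that score above the worst seed; each
iteration rebuilds the model with the recruits added and the single
worst-scoring seed removed, until no new sequence is recruited.  The lowest
final seed score becomes the gathering and trusted cutoff; the highest
non-seed database score becomes the noise cutoff.

The scoring model is a gapped PSSM rather than a full profile HMM: the
contribution captured here is the refinement iteration and the cutoff
bookkeeping, which are model-agnostic.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .alignment import AlignmentParams, DEFAULT_PARAMS, align_pair, aligned_strings
from .synthetic_data import AMINO_ACIDS

__all__ = [
    "ProfileModel",
    "drop_length_outliers",
    "star_align",
    "build_profile",
    "score_sequence",
    "refine_profile",
]


@dataclass
class ProfileModel:
    """Position-specific scoring model with per-family score cutoffs.

    columns[k][a] is the log-odds (bits) of residue a at model column k.
    gap penalties are in bits and apply uniformly per column.  Cutoffs are
    unset (None) until refinement terminates; noise_cutoff is None when
    every database sequence ended up in the seed set.
    """

    columns: list[dict[str, float]]
    background: dict[str, float]
    gap_open: float = -4.0
    gap_extend: float = -1.0
    seed_ids: list[str] = field(default_factory=list)
    gathering_cutoff: float | None = None
    trusted_cutoff: float | None = None
    noise_cutoff: float | None = None
    n_iterations: int = 0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "columns": self.columns,
            "background": self.background,
            "gap_open": self.gap_open,
            "gap_extend": self.gap_extend,
            "seed_ids": self.seed_ids,
            "gathering_cutoff": self.gathering_cutoff,
            "trusted_cutoff": self.trusted_cutoff,
            "noise_cutoff": self.noise_cutoff,
            "n_iterations": self.n_iterations,
        }, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ProfileModel":
        d = json.loads(Path(path).read_text())
        return cls(**d)


def drop_length_outliers(seqs: dict[str, str]) -> dict[str, str]:
    """Drop sequences two or more population SDs from the mean length.

    Both tails are removed; the comparison is strict (< 2 SD retained), so a
    zero-SD family keeps exactly the sequences at the mean — all of them.
    Requires at least three sequences for the SD to be a meaningful filter.
    """
    if len(seqs) < 3:
        raise ValueError(f"need >= 3 sequences for length filtering, got {len(seqs)}")
    lengths = np.array([len(s) for s in seqs.values()], dtype=float)
    mean = lengths.mean()
    sd = lengths.std()  # population SD
    return {k: s for k, s in seqs.items() if abs(len(s) - mean) < 2 * sd or sd == 0}


def _merge_gaps(master: str, new_center: str) -> tuple[str, list[int]]:
    """Merge the master gapped center with a newly aligned copy of the center.

    Returns the merged center row and, for bookkeeping, nothing else is
    needed: "once a gap, always a gap" means gaps are unioned positionally.
    """
    # walk both gapped strings over the same underlying residues
    out = []
    i = j = 0
    while i < len(master) or j < len(new_center):
        a = master[i] if i < len(master) else None
        b = new_center[j] if j < len(new_center) else None
        if a is not None and b is not None and a != "-" and b != "-":
            out.append(a)
            i += 1
            j += 1
        elif a == "-":
            out.append("-")
            i += 1
            if b == "-":
                j += 1
        elif b == "-":
            out.append("-")
            j += 1
        else:  # one string exhausted
            out.append("-")
            if a is None:
                j += 1
            else:
                i += 1
    return "".join(out), []


def star_align(
    seqs: dict[str, str],
    params: AlignmentParams = DEFAULT_PARAMS,
) -> dict[str, str]:
    """Center-star multiple alignment.

    The center is the sequence maximizing summed pairwise raw scores; every
    other sequence is merged through its pairwise alignment to the center
    with the "once a gap, always a gap" rule.  Projecting any row (removing
    gaps) reproduces that row's input sequence.
    """
    if len(seqs) < 2:
        raise ValueError("need >= 2 sequences to align")
    ids = sorted(seqs)
    sums = {k: 0.0 for k in ids}
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            s = align_pair(seqs[a], seqs[b], params).raw_score
            sums[a] += s
            sums[b] += s
    center = max(ids, key=lambda k: (sums[k], -len(seqs[k]), k))

    # pairwise alignments of every sequence to the center
    pair_alns: dict[str, tuple[str, str]] = {}
    for k in ids:
        if k == center:
            continue
        pair_alns[k] = aligned_strings(seqs[center], seqs[k], params)

    # union of gap patterns on the center defines master columns
    master = seqs[center]
    for k in sorted(pair_alns):
        master, _ = _merge_gaps(master, pair_alns[k][0])

    def project(center_gapped: str, other_gapped: str) -> str:
        """Re-express 'other' on the master column set."""
        out = []
        i = 0  # position in pairwise alignment
        for col in master:
            if col != "-":
                # master residue column: advance pairwise alignment to next
                # center residue, emitting insertions are impossible (center
                # residues only), then emit the partner
                while i < len(center_gapped) and center_gapped[i] == "-":
                    i += 1  # center gap in pairwise alignment: residue in other dropped? no:
                # handled below
                out.append(other_gapped[i] if i < len(center_gapped) else "-")
                i += 1
            else:
                # master gap column: if the pairwise alignment also has a
                # center gap here (an insertion in 'other'), consume it;
                # otherwise pad
                if i < len(center_gapped) and center_gapped[i] == "-":
                    out.append(other_gapped[i])
                    i += 1
                else:
                    out.append("-")
        return "".join(out)

    aligned = {center: master}
    for k in sorted(pair_alns):
        aligned[k] = project(*pair_alns[k])
    # restore input key order
    return {k: aligned[k] for k in seqs if k in aligned}


def build_profile(
    alignment: dict[str, str],
    background: dict[str, float] | None = None,
    pseudocount: float = 1.0,
    gap_open: float = -4.0,
    gap_extend: float = -1.0,
) -> ProfileModel:
    """Build a PSSM from a multiple alignment.

    Column log-odds: log2((count + pc * bg) / (n + pc) / bg), with n the
    number of residues observed in the column.  Columns with more than 50%
    gaps are dropped from the model.  pseudocount must be positive so
    unobserved residues keep finite scores.
    """
    if not alignment:
        raise ValueError("empty alignment")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    if background is None:
        background = {a: 1.0 / len(AMINO_ACIDS) for a in AMINO_ACIDS}
    rows = list(alignment.values())
    n_rows = len(rows)
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise ValueError("ragged alignment")
    columns: list[dict[str, float]] = []
    for k in range(width):
        col = [r[k] for r in rows]
        gaps = col.count("-")
        if gaps * 2 > n_rows:
            continue
        observed = [c for c in col if c != "-"]
        n = len(observed)
        scores = {}
        for a, bg in background.items():
            count = observed.count(a)
            scores[a] = math.log2((count + pseudocount * bg) / (n + pseudocount) / bg)
        columns.append(scores)
    return ProfileModel(columns=columns, background=dict(background),
                        gap_open=gap_open, gap_extend=gap_extend,
                        seed_ids=sorted(alignment))


def score_sequence(profile: ProfileModel, seq: str) -> float:
    """Best global alignment score of a sequence against the profile (bits).

    Standard affine-gap dynamic programming over profile columns x sequence
    residues; skipping a profile column or inserting a sequence residue both
    use the profile's gap penalties.
    """
    if not profile.columns:
        raise ValueError("profile has no columns")
    if not seq:
        raise ValueError("empty sequence")
    ncol = len(profile.columns)
    nres = len(seq)
    neg = -math.inf
    go, ge = profile.gap_open, profile.gap_extend
    # rolling rows over profile columns; M: column i matched to residue j,
    # Ix: gap in profile (residue inserted), Iy: gap in sequence (column
    # skipped)
    m_prev = [0.0] + [neg] * nres
    ix_prev = [neg] + [go + ge * (j - 1) for j in range(1, nres + 1)]
    iy_prev = [neg] * (nres + 1)
    for i in range(1, ncol + 1):
        col = profile.columns[i - 1]
        bg_floor = min(col.values())
        emits = [col.get(c, bg_floor) for c in seq]
        m_cur = [neg] * (nres + 1)
        ix_cur = [neg] * (nres + 1)
        iy_cur = [neg] * (nres + 1)
        iy_cur[0] = go + ge * (i - 1)
        for j in range(1, nres + 1):
            m_cur[j] = emits[j - 1] + max(m_prev[j - 1], ix_prev[j - 1], iy_prev[j - 1])
            ix_cur[j] = max(m_cur[j - 1] + go, ix_cur[j - 1] + ge)
            iy_cur[j] = max(m_prev[j] + go, iy_prev[j] + ge)
        m_prev, ix_prev, iy_prev = m_cur, ix_cur, iy_cur
    return float(max(m_prev[nres], ix_prev[nres], iy_prev[nres]))


def refine_profile(
    seed_seqs: dict[str, str],
    database_seqs: dict[str, str],
    params: AlignmentParams = DEFAULT_PARAMS,
    pseudocount: float = 1.0,
    rerecruit_removed_seeds: bool = True,
    max_iterations: int = 30,
) -> ProfileModel:
    """Iteratively refine a family profile against a sequence database.

    Each iteration builds the profile from the current seeds, scores every
    database sequence, and recruits those scoring strictly above the worst
    current seed; the recruits are added, the single worst-scoring seed is
    removed, and the loop repeats until no sequence is recruited (or a
    previously seen seed set recurs).  On termination the gathering and
    trusted cutoffs are the minimum final-seed score and the noise cutoff is
    the maximum score among database sequences outside the final seed set
    (None when the database is empty or fully recruited).

    Removed seeds rejoin the database pool and may be re-recruited
    (``rerecruit_removed_seeds=False`` drops them permanently instead).
    """
    seeds = dict(seed_seqs)
    pool = {k: v for k, v in database_seqs.items() if k not in seeds}
    seen_seed_sets = {frozenset(seeds)}
    profile = None
    n_iter = 0
    for _ in range(max_iterations):
        n_iter += 1
        alignment = star_align(seeds, params) if len(seeds) > 1 else {
            k: v for k, v in seeds.items()
        }
        profile = build_profile(alignment, pseudocount=pseudocount)
        seed_scores = {k: score_sequence(profile, s) for k, s in seeds.items()}
        worst_id = min(seed_scores, key=lambda k: (seed_scores[k], k))
        worst = seed_scores[worst_id]
        recruits = {
            k: s for k, s in pool.items() if score_sequence(profile, s) > worst
        }
        if not recruits:
            break
        for k in recruits:
            del pool[k]
        seeds.update(recruits)
        del seeds[worst_id]
        if rerecruit_removed_seeds:
            pool[worst_id] = seed_seqs.get(worst_id, database_seqs.get(worst_id))
        key = frozenset(seeds)
        if key in seen_seed_sets:
            break
        seen_seed_sets.add(key)

    assert profile is not None
    final_scores = {k: score_sequence(profile, s) for k, s in seeds.items()}
    profile.seed_ids = sorted(seeds)
    profile.gathering_cutoff = profile.trusted_cutoff = min(final_scores.values())
    non_seed = {k: v for k, v in database_seqs.items() if k not in seeds}
    non_seed.update({k: v for k, v in pool.items() if k not in seeds})
    if non_seed:
        profile.noise_cutoff = max(
            score_sequence(profile, s) for s in non_seed.values()
        )
    else:
        profile.noise_cutoff = None
    profile.n_iterations = n_iter
    return profile
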