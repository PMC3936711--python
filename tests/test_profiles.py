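"""Length filtering, center-star alignment, PSSM scoring and refinement."""

import math

import pytest

from casforge.profile_refinement import (
    ProfileModel,
    build_profile,
    drop_length_outliers,
    refine_profile,
    score_sequence,
    star_align,
)
from casforge.synthetic_data import (
    _random_protein,
    derive_rng,
    generate_divergent_family,
    make_refinement_scenario,
)


def _seqs(lengths, seed=0):
    rng = derive_rng(seed, "lens")
    return {f"s{i}": _random_protein(rng, L) for i, L in enumerate(lengths)}


def test_zero_sd_family_fully_retained():
    seqs = _seqs([100, 100, 100])
    assert drop_length_outliers(seqs) == seqs


def test_short_outlier_removed_both_tails_checked():
    seqs = _seqs([100, 102, 98, 96, 104, 10])
    kept = drop_length_outliers(seqs)
    lengths = sorted(len(s) for s in kept.values())
    assert lengths == [96, 98, 100, 102, 104]


def test_length_filter_determinism_and_min_input():
    seqs = _seqs([90, 100, 110, 300])
    assert drop_length_outliers(seqs) == drop_length_outliers(seqs)
    with pytest.raises(ValueError):
        drop_length_outliers(_seqs([50, 60]))


def test_star_align_identical_pair_gap_free():
    aln = star_align({"a": "MKVLWQHE" * 3, "b": "MKVLWQHE" * 3})
    assert set(aln.values()) == {"MKVLWQHE" * 3}


def test_star_align_short_indel():
    aln = star_align({"x": "ACDE", "y": "ACE"})
    assert len(aln["x"]) == len(aln["y"]) == 4
    assert aln["y"].count("-") == 1
    assert aln["x"].replace("-", "") == "ACDE"
    assert aln["y"].replace("-", "") == "ACE"


def test_star_align_projection_identity():
    fam = generate_divergent_family(6, 90, seed=13)
    aln = star_align(fam)
    width = len(next(iter(aln.values())))
    assert width >= max(len(s) for s in fam.values())
    for k, row in aln.items():
        assert len(row) == width
        assert row.replace("-", "") == fam[k]


def test_build_profile_column_formula():
    aln = {f"r{i}": "AC" for i in range(4)}
    prof = build_profile(aln, pseudocount=1.0)
    bg = 0.05
    expected_a = math.log2((4 + 1.0 * bg) / (4 + 1.0) / bg)
    assert prof.columns[0]["A"] == pytest.approx(expected_a)
    expected_absent = math.log2((0 + 1.0 * bg) / (4 + 1.0) / bg)
    assert prof.columns[0]["W"] == pytest.approx(expected_absent)


def test_build_profile_requires_positive_pseudocount():
    with pytest.raises(ValueError):
        build_profile({"only": "ACD"}, pseudocount=0.0)


def test_gap_majority_column_dropped():
    aln = {"a": "AC", "b": "A-", "c": "A-", "d": "A-"}
    prof = build_profile(aln)
    assert len(prof.columns) == 1  # second column is 75% gaps


def oracle_best_alignment(profile, seq):
    """Exhaustive enumeration of gapped alignments (same move grammar as the
    scorer: gap runs open with gap_open, extend with gap_extend, and gap
    type cannot switch without an intervening match)."""
    go, ge = profile.gap_open, profile.gap_extend
    ncol, nres = len(profile.columns), len(seq)

    def emit(i, j):
        col = profile.columns[i]
        return col.get(seq[j], min(col.values()))

    best = -math.inf

    def walk(i, j, last, score):
        nonlocal best
        if i == ncol and j == nres:
            best = max(best, score)
            return
        if i < ncol and j < nres:
            walk(i + 1, j + 1, "M", score + emit(i, j))
        if j < nres and last in ("start", "M", "X"):
            walk(i, j + 1, "X", score + (ge if last == "X" else go))
        if i < ncol and last in ("start", "M", "Y"):
            walk(i + 1, j, "Y", score + (ge if last == "Y" else go))

    walk(0, 0, "start", 0.0)
    return best


def test_score_matches_enumeration_oracle():
    rng = derive_rng(3, "oracle")
    for trial in range(5):
        seqs = {f"s{i}": _random_protein(rng, 5) for i in range(3)}
        prof = build_profile(star_align(seqs))
        target = _random_protein(rng, 5)
        assert score_sequence(prof, target) == pytest.approx(
            oracle_best_alignment(prof, target)
        ), f"trial {trial}"


def test_seed_scores_maximal_on_own_single_profile():
    seq = "MKVLWQHEACDEFGHIKLMN"
    prof = build_profile({"seed": seq})
    own = score_sequence(prof, seq)
    max_possible = sum(max(c.values()) for c in prof.columns)
    assert own == pytest.approx(max_possible)


def test_score_rejects_degenerate_inputs():
    prof = build_profile({"seed": "ACDEF"})
    with pytest.raises(ValueError):
        score_sequence(prof, "")
    with pytest.raises(ValueError):
        score_sequence(ProfileModel(columns=[], background={}), "MK")


def test_refine_terminates_immediately_without_recruits():
    fam = generate_divergent_family(5, 100, seed=21)
    rng = derive_rng(22, "db")
    db = {f"d{j}": _random_protein(rng, 100) for j in range(10)}
    prof = refine_profile(fam, db)
    assert prof.n_iterations == 1
    assert sorted(prof.seed_ids) == sorted(fam)
    assert prof.noise_cutoff < prof.gathering_cutoff


def test_refine_recruits_members_not_decoys():
    seeds, db, members = make_refinement_scenario(seed=3)
    prof = refine_profile(seeds, db)
    recruited = set(prof.seed_ids) - set(seeds)
    assert members <= recruited
    assert not any(r.startswith("decoy") for r in recruited)
    assert prof.n_iterations <= 3
    assert prof.noise_cutoff < prof.gathering_cutoff == prof.trusted_cutoff


def test_refine_empty_database_leaves_noise_unset():
    fam = generate_divergent_family(4, 80, seed=30)
    prof = refine_profile(fam, {})
    assert prof.noise_cutoff is None
    assert prof.gathering_cutoff == prof.trusted_cutoff


def test_refine_determinism(tmp_path):
    seeds, db, _ = make_refinement_scenario(n_decoys=10, seed=5)
    p1 = refine_profile(seeds, db)
    p2 = refine_profile(seeds, db)
    assert p1.gathering_cutoff == p2.gathering_cutoff
    assert p1.noise_cutoff == p2.noise_cutoff
    assert p1.seed_ids == p2.seed_ids
    out = tmp_path / "prof.json"
    p1.to_json(out)
    back = ProfileModel.from_json(out)
    assert back.gathering_cutoff == p1.gathering_cutoff
    assert back.columns == p1.columns
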