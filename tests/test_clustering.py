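"""Redundancy reduction, similarity graph, MCL and novelty filters."""

import math
import random

import networkx as nx
import pytest
from Bio.Align import substitution_matrices

from oracles import naive_mcl, partition_key

from casforge.alignment import DEFAULT_PARAMS, align_pair
from casforge.novelty_clustering import (
    MCLParams,
    build_graph,
    exclude_known_like,
    mcl,
    reduce_redundancy,
    select_novel_families,
)
from casforge.synthetic_data import derive_rng, generate_family, _random_protein

BLOSUM62 = substitution_matrices.load("BLOSUM62")


def _random_seq(seed, n=10):
    rng = random.Random(seed)
    return "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY") for _ in range(n))


def oracle_affine_global(a, b, open_gap=-11.0, extend_gap=-1.0):
    """Three-state affine-gap global alignment, written independently.

    The first residue of a gap costs open_gap, each further residue
    extend_gap; terminal gaps are penalized like internal ones.
    """
    neg = -math.inf
    la, lb = len(a), len(b)
    M = [[neg] * (lb + 1) for _ in range(la + 1)]
    X = [[neg] * (lb + 1) for _ in range(la + 1)]  # gap in a (b residue)
    Y = [[neg] * (lb + 1) for _ in range(la + 1)]  # gap in b (a residue)
    M[0][0] = 0.0
    for j in range(1, lb + 1):
        X[0][j] = open_gap + extend_gap * (j - 1)
    for i in range(1, la + 1):
        Y[i][0] = open_gap + extend_gap * (i - 1)
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            s = BLOSUM62[a[i - 1], b[j - 1]]
            M[i][j] = s + max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            X[i][j] = max(M[i][j - 1] + open_gap, X[i][j - 1] + extend_gap,
                          Y[i][j - 1] + open_gap)
            Y[i][j] = max(M[i - 1][j] + open_gap, Y[i - 1][j] + extend_gap,
                          X[i - 1][j] + open_gap)
    return max(M[la][lb], X[la][lb], Y[la][lb])


def test_self_alignment_identity_one():
    s = _random_seq(0, 50)
    score = align_pair(s, s)
    assert score.identity == 1.0
    assert score.bit_score == DEFAULT_PARAMS.bit_score(score.raw_score)


def test_alignment_symmetry():
    for seed in range(5):
        a, b = _random_seq(seed, 30), _random_seq(seed + 100, 30)
        ab, ba = align_pair(a, b), align_pair(b, a)
        assert ab.raw_score == ba.raw_score
        assert ab.identity == ba.identity


def test_alignment_rejects_empty():
    with pytest.raises(ValueError):
        align_pair("", "MK")


def test_raw_score_matches_dp_oracle():
    for seed in range(10):
        a, b = _random_seq(seed, 10), _random_seq(seed + 50, 12)
        assert align_pair(a, b).raw_score == pytest.approx(oracle_affine_global(a, b))


def test_identical_sequences_reduce_to_one():
    s = _random_seq(1, 60)
    reps, memb = reduce_redundancy({"a": s, "b": s})
    assert len(reps) == 1
    assert set(memb.values()) == set(reps)


def test_trio_at_high_identity_keeps_longest():
    rng = derive_rng(3, "trio")
    base = _random_protein(rng, 100)
    from casforge.synthetic_data import mutate_to_identity
    seqs = {
        "long": base + "AC",  # longest wins representative status
        "m1": mutate_to_identity(base, 0.95, seed=1),
        "m2": mutate_to_identity(base, 0.95, seed=2),
    }
    reps, memb = reduce_redundancy(seqs)
    assert set(reps) == {"long"}
    assert memb == {"long": "long", "m1": "long", "m2": "long"}


def test_distant_pair_stays_separate():
    a, b = _random_seq(10, 80), _random_seq(20, 80)
    reps, _ = reduce_redundancy({"a": a, "b": b})
    assert len(reps) == 2


def test_redundancy_invariants_on_mixed_pool():
    seqs = {}
    for f in range(3):
        seqs.update(generate_family(4, 80, 0.9, seed=f, prefix=f"g{f}"))
    seqs.update({f"solo{j}": _random_seq(j + 500, 80) for j in range(4)})
    reps, memb = reduce_redundancy(seqs, threshold=0.90)
    # every removed sequence is >= 90% identical to its representative
    for sid, rid in memb.items():
        if sid != rid:
            assert align_pair(seqs[sid], seqs[rid]).identity >= 0.90
    # no representative pair reaches the threshold
    rep_ids = sorted(reps)
    for i, a in enumerate(rep_ids):
        for b in rep_ids[i + 1:]:
            assert align_pair(reps[a], reps[b]).identity < 0.90
    # determinism
    reps2, memb2 = reduce_redundancy(seqs, threshold=0.90)
    assert reps2 == reps and memb2 == memb


def test_graph_unrelated_sequences_edgeless():
    seqs = {f"s{i}": _random_seq(i + 900, 150) for i in range(6)}
    g = build_graph(seqs)
    assert g.number_of_edges() == 0
    assert g.number_of_nodes() == 6


def test_graph_planted_family_is_clique():
    fam = generate_family(6, 150, 0.6, seed=77)
    g = build_graph(fam)
    assert g.number_of_edges() == 15  # 6 choose 2


def test_graph_single_sequence():
    g = build_graph({"only": _random_seq(4, 100)})
    assert g.number_of_nodes() == 1 and g.number_of_edges() == 0


# ---------------------------------------------------------------------------
# MCL



def test_mcl_disconnected_cliques():
    g = nx.Graph()
    for base in ("a", "b"):
        members = [f"{base}{i}" for i in range(4)]
        for i, u in enumerate(members):
            for v in members[i + 1:]:
                g.add_edge(u, v, weight=10.0)
    clusters = mcl(g)
    assert partition_key(clusters) == [tuple(f"a{i}" for i in range(4)),
                                        tuple(f"b{i}" for i in range(4))]


def test_mcl_weak_bridge_splits_at_default_inflation():
    g = nx.Graph()
    for base in ("x", "y"):
        members = [f"{base}{i}" for i in range(5)]
        for i, u in enumerate(members):
            for v in members[i + 1:]:
                g.add_edge(u, v, weight=100.0)
    g.add_edge("x0", "y0", weight=10.0)  # bridge at 1/10 clique weight
    clusters = mcl(g)
    assert len(clusters) == 2
    assert partition_key(clusters) == partition_key(naive_mcl(g))


def test_mcl_single_node_and_empty():
    g = nx.Graph()
    g.add_node("solo")
    assert mcl(g) == [{"solo"}]
    assert mcl(nx.Graph()) == []


def test_mcl_is_partition_and_label_invariant():
    rng = random.Random(99)
    for _ in range(5):
        n = rng.randint(5, 20)
        g = nx.gnp_random_graph(n, 0.3, seed=rng.randint(0, 10**6))
        for u, v in g.edges:
            g[u][v]["weight"] = rng.uniform(1, 100)
        clusters = mcl(g)
        all_nodes = [v for c in clusters for v in c]
        assert sorted(all_nodes) == sorted(g.nodes)  # partition
        relabeled = nx.relabel_nodes(g, {v: f"n{v:03d}" for v in g.nodes})
        re_clusters = mcl(relabeled)
        expected = partition_key(
            [{f"n{v:03d}" for v in c} for c in clusters]
        )
        assert partition_key(re_clusters) == expected


def test_mcl_agrees_with_reference_on_random_graphs():
    rng = random.Random(5)
    for trial in range(20):
        n = rng.randint(4, 30)
        g = nx.gnp_random_graph(n, 0.2, seed=rng.randint(0, 10**6))
        for u, v in g.edges:
            g[u][v]["weight"] = rng.uniform(1, 100)
        assert partition_key(mcl(g)) == partition_key(naive_mcl(g)), f"trial {trial}"


# ---------------------------------------------------------------------------
# family selection

def test_small_cluster_dropped():
    seqs = generate_family(4, 80, 0.6, seed=1)
    fams, discards = select_novel_families([set(seqs)], seqs)
    assert fams == [] and sorted(discards) == sorted(seqs)


def test_diverse_cluster_kept():
    seqs = generate_family(6, 120, 0.40, seed=2)
    fams, _ = select_novel_families([set(seqs)], seqs)
    assert len(fams) == 1
    assert fams[0].passed_size
    assert fams[0].passed_diversity == (fams[0].max_pairwise_identity <= 0.50)


def test_singletons_all_discarded():
    seqs = {f"s{i}": _random_seq(i, 60) for i in range(10)}
    fams, discards = select_novel_families([{k} for k in seqs], seqs)
    assert fams == [] and len(discards) == 10


def test_exclude_known_like_joint_condition():
    fam_seqs = generate_family(5, 120, 0.45, seed=3)
    # reference nearly identical to one member -> excluded
    from casforge.synthetic_data import mutate_to_identity
    member = sorted(fam_seqs)[0]
    close_ref = mutate_to_identity(fam_seqs[member], 0.8, seed=4)
    fams, _ = select_novel_families([set(fam_seqs)], fam_seqs)
    exclude_known_like(fams, fam_seqs, {"cas2_ref": close_ref})
    assert fams[0].excluded_known_like
    assert (member, "cas2_ref") in fams[0].known_like_evidence

    # unrelated reference -> kept
    fams2, _ = select_novel_families([set(fam_seqs)], fam_seqs)
    exclude_known_like(fams2, fam_seqs, {"far_ref": _random_seq(404, 120)})
    assert not fams2[0].excluded_known_like


def test_exclude_requires_identity_not_just_evalue():
    """A hit below 30% identity keeps the family even at a qualifying E-value."""
    fam_seqs = generate_family(5, 200, 0.45, seed=6)
    from casforge.synthetic_data import mutate_to_identity
    member = sorted(fam_seqs)[0]
    # 25% identity to a member: E-value can be small but identity gate fails
    weak_ref = mutate_to_identity(fam_seqs[member], 0.25, seed=7)
    score = align_pair(fam_seqs[member], weak_ref)
    e = DEFAULT_PARAMS.e_value(score.raw_score, 200, len(weak_ref))
    fams, _ = select_novel_families([set(fam_seqs)], fam_seqs)
    exclude_known_like(fams, fam_seqs, {"weak_ref": weak_ref})
    if score.identity < 0.30:
        assert not fams[0].excluded_known_like
    else:  # realized identity drifted above the gate: exclusion is correct
        assert e > 1e-5 or fams[0].excluded_known_like


def test_exclude_with_empty_reference_warns():
    fam_seqs = generate_family(5, 100, 0.45, seed=8)
    fams, _ = select_novel_families([set(fam_seqs)], fam_seqs)
    with pytest.warns(UserWarning):
        exclude_known_like(fams, fam_seqs, {})
    assert not fams[0].excluded_known_like
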