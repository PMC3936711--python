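"""Novel-family discovery: redundancy reduction, similarity graph, MCL.

Candidate proteins (intervening locus genes with no known-family hit) are
first reduced at 90% identity by greedy incremental clustering (longest
sequence first, CD-HIT style, identity over the shorter sequence).  An
undirected similarity graph connects non-redundant pairs with alignment bit
scores above 60, and Markov clustering (MCL) at inflation 1.4 partitions the
graph.  Clusters with at least five members whose pairwise identities stay
at or below 50% — and that do not resemble known Cas references even under
loose criteria (E <= 1e-5 and identity >= 30%, jointly) — are reported as
novel families.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .alignment import AlignmentParams, DEFAULT_PARAMS, AlignmentScore, align_pair

__all__ = [
    "AlignmentScore",
    "align_pair",
    "reduce_redundancy",
    "build_graph",
    "MCLParams",
    "mcl",
    "NovelFamily",
    "select_novel_families",
    "exclude_known_like",
]


def reduce_redundancy(
    seqs: dict[str, str],
    threshold: float = 0.90,
    params: AlignmentParams = DEFAULT_PARAMS,
) -> tuple[dict[str, str], dict[str, str]]:
    """Greedy incremental redundancy reduction at an identity threshold.

    Sequences are visited longest first (ties by id); each joins the first
    existing representative it matches at identity >= threshold, otherwise
    it founds a new representative.  Returns (representatives, membership)
    where membership maps every input id to its representative's id.
    By construction no two representatives reach the threshold.
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    order = sorted(seqs, key=lambda k: (-len(seqs[k]), k))
    reps: dict[str, str] = {}
    membership: dict[str, str] = {}
    for sid in order:
        seq = seqs[sid]
        for rid, rseq in reps.items():
            if align_pair(seq, rseq, params).identity >= threshold:
                membership[sid] = rid
                break
        else:
            reps[sid] = seq
            membership[sid] = sid
    return reps, membership


def build_graph(
    seqs: dict[str, str],
    bit_threshold: float = 60.0,
    params: AlignmentParams = DEFAULT_PARAMS,
) -> nx.Graph:
    """All-vs-all similarity graph: edge iff bit score strictly above threshold."""
    if not seqs:
        raise ValueError("no sequences")
    g = nx.Graph()
    ids = sorted(seqs)
    g.add_nodes_from(ids)
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            score = align_pair(seqs[a], seqs[b], params)
            if score.bit_score > bit_threshold:
                g.add_edge(a, b, weight=score.bit_score, identity=score.identity)
    return g


@dataclass(frozen=True)
class MCLParams:
    """Markov-clustering controls.

    Self-loops at the node's maximum incident edge weight keep dense regions
    stable; pruning and the convergence tolerance follow common MCL
    practice.  Expansion power is 2 (matrix squaring).
    """

    inflation: float = 1.4
    prune_tol: float = 1e-5
    conv_tol: float = 1e-8
    max_iter: int = 100

    def __post_init__(self) -> None:
        if self.inflation <= 1:
            raise ValueError(f"inflation must be > 1, got {self.inflation}")


def mcl(graph: nx.Graph, params: MCLParams = MCLParams()) -> list[set[str]]:
    """Markov clustering of a weighted undirected graph.

    Builds the column-stochastic transition matrix with self-loops, then
    alternates expansion (matrix square) and inflation (entrywise power with
    column renormalization, pruning entries below prune_tol) until the
    maximum entry change falls below conv_tol.  Clusters are the weakly
    connected components of the limit matrix's nonzero structure.  The
    result is a partition of the nodes and is invariant to node labels.
    """
    nodes = sorted(graph.nodes)
    if not nodes:
        return []
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    m = np.zeros((n, n))
    for a, b, data in graph.edges(data=True):
        w = float(data.get("weight", 1.0))
        m[idx[a], idx[b]] = w
        m[idx[b], idx[a]] = w
    for i in range(n):
        incident = m[:, i]
        m[i, i] = incident.max() if incident.max() > 0 else 1.0
    m /= m.sum(axis=0, keepdims=True)

    for _ in range(params.max_iter):
        expanded = m @ m
        inflated = np.power(expanded, params.inflation)
        inflated[inflated < params.prune_tol] = 0.0
        colsum = inflated.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        inflated /= colsum
        if np.max(np.abs(inflated - m)) < params.conv_tol:
            m = inflated
            break
        m = inflated

    structure = nx.Graph()
    structure.add_nodes_from(range(n))
    rows, cols = np.nonzero(m > params.prune_tol)
    structure.add_edges_from(zip(rows.tolist(), cols.tolist()))
    comps = [sorted(c) for c in nx.connected_components(structure)]
    comps.sort(key=lambda c: (-len(c), c[0]))
    return [{nodes[i] for i in comp} for comp in comps]


@dataclass
class NovelFamily:
    """One MCL cluster with its novelty-filter flags.

    A final novel family has passed_size and passed_diversity and is not
    excluded_known_like.
    """

    family_id: str
    members: list[str]
    passed_size: bool
    passed_diversity: bool
    max_pairwise_identity: float
    excluded_known_like: bool = False
    known_like_evidence: list[tuple[str, str]] = field(default_factory=list)
    subtype_context: str | None = None

    @property
    def accepted(self) -> bool:
        return self.passed_size and self.passed_diversity and not self.excluded_known_like


def select_novel_families(
    clusters: list[set[str]],
    seqs: dict[str, str],
    min_size: int = 5,
    diversity_max_identity: float = 0.50,
    params: AlignmentParams = DEFAULT_PARAMS,
) -> tuple[list[NovelFamily], list[str]]:
    """Filter MCL clusters into candidate novel families.

    Clusters below ``min_size`` go to the discard list (ids).  Surviving
    clusters are checked for diversity: passed_diversity is False when any
    member pair exceeds ``diversity_max_identity`` — the violation flags the
    family rather than deleting members.
    """
    families: list[NovelFamily] = []
    discards: list[str] = []
    k = 0
    for cluster in clusters:
        members = sorted(cluster)
        if len(members) < min_size:
            discards.extend(members)
            continue
        max_id = 0.0
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                ident = align_pair(seqs[a], seqs[b], params).identity
                max_id = max(max_id, ident)
        k += 1
        families.append(
            NovelFamily(
                family_id=f"NF{k:03d}",
                members=members,
                passed_size=True,
                passed_diversity=max_id <= diversity_max_identity,
                max_pairwise_identity=max_id,
            )
        )
    return families, discards


def exclude_known_like(
    families: list[NovelFamily],
    seqs: dict[str, str],
    known_refs: dict[str, str],
    e_max: float = 1e-5,
    id_min: float = 0.30,
    params: AlignmentParams = DEFAULT_PARAMS,
) -> list[NovelFamily]:
    """Flag families resembling known Cas references under loose criteria.

    A family is excluded iff ANY member matches ANY reference with
    E <= e_max AND identity >= id_min — both conditions jointly; a low
    E-value at 25% identity keeps the family.  E-values come from the
    Karlin-Altschul formula under the same constants as the bit scores.
    Mutates and returns ``families``.
    """
    if not known_refs:
        warnings.warn("empty known-Cas reference set: no exclusions possible")
        return families
    for fam in families:
        for member in fam.members:
            for ref_id, ref_seq in sorted(known_refs.items()):
                score = align_pair(seqs[member], ref_seq, params)
                e = params.e_value(score.raw_score, len(seqs[member]), len(ref_seq))
                if e <= e_max and score.identity >= id_min:
                    fam.excluded_known_like = True
                    fam.known_like_evidence.append((member, ref_id))
        fam.known_like_evidence.sort()
    return families
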