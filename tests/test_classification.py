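"""Signature-gene subtype calls, co-occurrence, TA pairs, strand statistics."""

import random

import pytest

from casforge.io_model import CasLabel, CasLocus, Completeness, GeneRecord
from casforge.locus_classification import (
    assign_types,
    detect_cooccurrence,
    detect_toxin_antitoxin,
    load_signature_map,
    load_ta_families,
    majority_cas_strand,
    strand_opposition_fraction,
)

SIGMAP = load_signature_map()


def _locus(families, completeness=Completeness.COMPLETE_GENOME, strands=None,
           labels=None):
    """Build a locus plus gene records and annotations from a family list."""
    genes, members, annotations = [], [], {}
    for i, fam in enumerate(families):
        pid = f"p{i}"
        strand = strands[i] if strands else "+"
        genes.append(GeneRecord("r", i, 1 + 100 * i, 90 + 100 * i, strand, pid))
        label = labels[i] if labels else CasLabel.SEED_KNOWN
        members.append((pid, label))
        if fam is not None:
            annotations[pid] = fam
    locus = CasLocus("r:0-%d" % (len(families) - 1), "r", 0, len(families) - 1,
                     members, completeness)
    return locus, genes, annotations


@pytest.mark.parametrize(
    "families,expected_subtypes,expected_types",
    [
        (["cas9", "cas1", "cas2", "csn2"], {"II-A"}, {"II"}),
        (["cas9", "cas1", "cas2", "cas4"], {"II-B"}, {"II"}),
        (["cas3", "cse1", "cas7", "cas5", "cas6", "cas1", "cas2"], {"I-E"}, {"I"}),
        (["cas3", "cas1", "cas2"], set(), {"I"}),  # type signature only
        (["cas10", "cmr", "cas7"], {"III-B"}, {"III"}),
    ],
)
def test_signature_assignment(families, expected_subtypes, expected_types):
    locus, _, ann = _locus(families)
    call = assign_types(locus, ann, SIGMAP)
    assert call.subtypes == expected_subtypes
    assert call.types == expected_types


def test_ii_c_called_only_on_complete_genomes():
    locus, _, ann = _locus(["cas9", "cas1", "cas2"], Completeness.COMPLETE_GENOME)
    call = assign_types(locus, ann, SIGMAP)
    assert call.subtypes == {"II-C"}
    locus, _, ann = _locus(["cas9", "cas1", "cas2"], Completeness.DRAFT_OR_CONTIG)
    call = assign_types(locus, ann, SIGMAP)
    assert call.subtypes == set()
    assert call.types == {"II"}


def test_ii_c_requires_exact_composition():
    locus, _, ann = _locus(["cas9", "cas1", "cas2", "csn2"])
    call = assign_types(locus, ann, SIGMAP)
    assert "II-C" not in call.subtypes  # extra family breaks exact composition


def test_cas4_alone_is_not_type_ii_evidence():
    locus, _, ann = _locus(["cas3", "cas4", "cas1"])
    call = assign_types(locus, ann, SIGMAP)
    assert "II-B" not in call.subtypes
    assert call.types == {"I"}


def test_subtype_implies_type():
    for families in (["cas9", "csn2"], ["cas3", "csy1"], ["cas10", "csm"]):
        locus, _, ann = _locus(families)
        call = assign_types(locus, ann, SIGMAP)
        for st in call.subtypes:
            parent = {"I": "I", "II": "II", "III": "III"}[st.split("-")[0]]
            assert parent in call.types


def test_unknown_family_warns_and_is_ignored():
    locus, _, ann = _locus(["cas9", "mystery_fam"])
    with pytest.warns(UserWarning, match="mystery_fam"):
        call = assign_types(locus, ann, SIGMAP)
    assert call.types == {"II"}


def test_cooccurrence_cas9_with_iii_b():
    locus, _, ann = _locus(["cas9", "cas10", "cmr"])
    call = assign_types(locus, ann, SIGMAP)
    call = detect_cooccurrence(call, ann, locus, SIGMAP)
    assert "II+III-B" in call.cooccurrence_flags


def test_cooccurrence_cas9_with_i_f():
    locus, _, ann = _locus(["cas9", "cas3", "csy1"])
    call = assign_types(locus, ann, SIGMAP)
    call = detect_cooccurrence(call, ann, locus, SIGMAP)
    assert "II+I-F" in call.cooccurrence_flags


def test_pure_locus_has_no_flags():
    locus, _, ann = _locus(["cas9", "cas1", "cas2", "csn2"])
    call = assign_types(locus, ann, SIGMAP)
    call = detect_cooccurrence(call, ann, locus, SIGMAP)
    assert call.cooccurrence_flags == set()


def test_ta_pair_antitoxin_upstream_same_strand():
    fams = ["cas3", "cse1", "PhdYeFM_antitox", "PIN", "cas1"]
    labels = [CasLabel.SEED_KNOWN, CasLabel.SEED_KNOWN,
              CasLabel.INTERVENING_UNKNOWN, CasLabel.INTERVENING_UNKNOWN,
              CasLabel.SEED_KNOWN]
    locus, genes, ann = _locus(fams, labels=labels)
    pairs = detect_toxin_antitoxin(locus, ann, genes)
    assert len(pairs) == 1
    p = pairs[0]
    assert p.antitoxin_protein_id == "p2" and p.toxin_protein_id == "p3"
    assert p.antitoxin_upstream
    assert p.antitoxin_same_strand_as_cas and p.toxin_same_strand_as_cas


def test_ta_upstream_is_relative_to_cas_transcription():
    # cas genes on minus strand: gene order reverses transcription direction
    fams = ["cas3", "cse1", "PhdYeFM_antitox", "PIN", "cas1"]
    labels = [CasLabel.SEED_KNOWN, CasLabel.SEED_KNOWN,
              CasLabel.INTERVENING_UNKNOWN, CasLabel.INTERVENING_UNKNOWN,
              CasLabel.SEED_KNOWN]
    strands = ["-", "-", "-", "-", "-"]
    locus, genes, ann = _locus(fams, strands=strands, labels=labels)
    pairs = detect_toxin_antitoxin(locus, ann, genes)
    assert len(pairs) == 1
    assert not pairs[0].antitoxin_upstream  # antitoxin at lower index = downstream


def test_toxin_without_antitoxin_yields_nothing():
    fams = ["cas3", "PIN", "cas1"]
    labels = [CasLabel.SEED_KNOWN, CasLabel.INTERVENING_UNKNOWN, CasLabel.SEED_KNOWN]
    locus, genes, ann = _locus(fams, labels=labels)
    assert detect_toxin_antitoxin(locus, ann, genes) == []


def test_ta_adjacency_bound():
    fams = ["cas3", "PhdYeFM_antitox", "cas5", "cas6", "cas7", "PIN", "cas1"]
    labels = [CasLabel.SEED_KNOWN] + [CasLabel.INTERVENING_UNKNOWN] * 5 + [CasLabel.SEED_KNOWN]
    locus, genes, ann = _locus(fams, labels=labels)
    assert detect_toxin_antitoxin(locus, ann, genes) == []  # 4 genes apart


def test_strand_tie_gives_indeterminate_orientation():
    fams = ["cas3", "PhdYeFM_antitox", "PIN", "cas1"]
    labels = [CasLabel.SEED_KNOWN, CasLabel.INTERVENING_UNKNOWN,
              CasLabel.INTERVENING_UNKNOWN, CasLabel.SEED_KNOWN]
    strands = ["+", "+", "+", "-"]
    locus, genes, ann = _locus(fams, strands=strands, labels=labels)
    genes_by_id = {g.protein_id: g for g in genes}
    assert majority_cas_strand(locus, genes_by_id) is None
    pairs = detect_toxin_antitoxin(locus, ann, genes)
    assert pairs[0].antitoxin_same_strand_as_cas is None


def test_strand_opposition_nine_of_thirteen():
    """Thirteen transposase members, nine opposite the cas strand -> 69%."""
    loci, genes, ann = [], [], {}
    for k in range(13):
        tn_strand = "-" if k < 9 else "+"
        fams = ["cas3", "Transposase_20", "cas1"]
        strands = ["+", tn_strand, "+"]
        labels = [CasLabel.SEED_KNOWN, CasLabel.INTERVENING_UNKNOWN, CasLabel.SEED_KNOWN]
        for i, fam in enumerate(fams):
            pid = f"k{k}p{i}"
            genes.append(GeneRecord(f"r{k}", i, 1 + 100 * i, 90 + 100 * i,
                                    strands[i], pid))
            ann[pid] = fam
        loci.append(CasLocus(f"r{k}:0-2", f"r{k}", 0, 2,
                             [(f"k{k}p0", labels[0]), (f"k{k}p1", labels[1]),
                              (f"k{k}p2", labels[2])],
                             Completeness.COMPLETE_GENOME))
    n_opp, n_tot, frac = strand_opposition_fraction(loci, genes, ann, "Transposase_20")
    assert (n_opp, n_tot) == (9, 13)
    assert int(frac * 100 + 0.5) == 69  # round half up to integer percent


def test_strand_opposition_all_same_strand_is_zero():
    fams = ["cas3", "Transposase_20", "cas1"]
    labels = [CasLabel.SEED_KNOWN, CasLabel.INTERVENING_UNKNOWN, CasLabel.SEED_KNOWN]
    locus, genes, ann = _locus(fams, labels=labels)
    n_opp, n_tot, frac = strand_opposition_fraction([locus], genes, ann,
                                                    "Transposase_20")
    assert (n_opp, n_tot, frac) == (0, 1, 0.0)


def test_strand_opposition_errors_when_family_absent():
    locus, genes, ann = _locus(["cas3", "cas1"])
    with pytest.raises(ValueError):
        strand_opposition_fraction([locus], genes, ann, "Transposase_20")


def test_strand_opposition_random_strands_near_half():
    rng = random.Random(7)
    loci, genes, ann = [], [], {}
    for k in range(1000):
        tn_strand = "+" if rng.random() < 0.5 else "-"
        pid_c0, pid_t, pid_c1 = f"k{k}p0", f"k{k}p1", f"k{k}p2"
        genes += [
            GeneRecord(f"r{k}", 0, 1, 90, "+", pid_c0),
            GeneRecord(f"r{k}", 1, 101, 190, tn_strand, pid_t),
            GeneRecord(f"r{k}", 2, 201, 290, "+", pid_c1),
        ]
        ann.update({pid_c0: "cas3", pid_t: "Transposase_20", pid_c1: "cas1"})
        loci.append(CasLocus(f"r{k}:0-2", f"r{k}", 0, 2,
                             [(pid_c0, CasLabel.SEED_KNOWN),
                              (pid_t, CasLabel.INTERVENING_UNKNOWN),
                              (pid_c1, CasLabel.SEED_KNOWN)],
                             Completeness.COMPLETE_GENOME))
    _, n_tot, frac = strand_opposition_fraction(loci, genes, ann, "Transposase_20")
    assert n_tot == 1000
    assert 0.45 <= frac <= 0.55


def test_ta_families_config_loads():
    ta = load_ta_families()
    assert "PIN" in ta.toxins and "PhdYeFM_antitox" in ta.antitoxins
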