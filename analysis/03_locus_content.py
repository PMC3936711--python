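"""Toxin-antitoxin pairs and transposase strand orientation inside cas loci.

Reads the detected loci (via re-detection on results/sim/) and reports:
TA pairs with antitoxin-upstream orientation and cas-strand agreement, and
the fraction of transposase-family members sitting on the strand opposite
the cas genes.  Writes results/ta_pairs.tsv and results/strand_stats.tsv.
"""

import json
from pathlib import Path

from casforge.io_model import Completeness, read_gene_table, read_hit_table
from casforge.locus_classification import detect_toxin_antitoxin, strand_opposition_fraction
from casforge.pipeline import detect_and_classify

SIM = Path("results/sim")
genes = read_gene_table(SIM / "genes.tsv")
hits = read_hit_table(SIM / "hits.tsv")
full_hits = read_hit_table(SIM / "full_hits.tsv")

by_replicon = {}
for g in genes:
    by_replicon.setdefault(g.replicon_id, []).append(g)

all_loci, annotations = [], {}
for rid, rgenes in sorted(by_replicon.items()):
    pids = {g.protein_id for g in rgenes}
    res = detect_and_classify(
        rgenes, [h for h in hits if h.protein_id in pids],
        [h for h in full_hits if h.protein_id in pids],
        Completeness.COMPLETE_GENOME,
    )
    all_loci += res.loci
    annotations.update(res.annotations)

rows = ["locus_id\tantitoxin\ttoxin\tantitoxin_upstream\tsame_strand"]
n_up = n_pairs = 0
for locus in all_loci:
    for p in detect_toxin_antitoxin(locus, annotations, genes):
        n_pairs += 1
        n_up += p.antitoxin_upstream
        rows.append(f"{locus.locus_id}\t{p.antitoxin_protein_id}\t"
                    f"{p.toxin_protein_id}\t{p.antitoxin_upstream}\t"
                    f"{p.antitoxin_same_strand_as_cas}")
Path("results/ta_pairs.tsv").write_text("\n".join(rows) + "\n")

n_opp, n_tot, frac = strand_opposition_fraction(all_loci, genes, annotations,
                                                "Transposase_20")
Path("results/strand_stats.tsv").write_text(
    "family_id\tn_opposite\tn_total\tfraction\n"
    f"Transposase_20\t{n_opp}\t{n_tot}\t{frac:.3f}\n"
)
print(f"{n_pairs} TA pairs, antitoxin upstream in {n_up} "
      f"({100*n_up/max(n_pairs,1):.0f}%); Transposase_20 opposite strand "
      f"{n_opp}/{n_tot} ({100*frac:.0f}%)")
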