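"""Build the synthetic genome panel used by the downstream analyses.

Ten replicons (alternating complete genomes and draft contigs), each with
two planted cas loci of assorted subtypes, 2% spurious weak hits on non-cas
genes, plus dedicated panels carrying transposase insertions and
toxin-antitoxin pairs inside type I loci.  Writes gene tables, hit tables
and the ground truth under results/sim/.
"""

import json
import random
import sys
from pathlib import Path

from casforge.io_model import Completeness, write_fasta, write_gene_table, write_hit_table
from casforge.synthetic_data import (
    SUBTYPE_LAYOUTS,
    emit_full_annotation_table,
    emit_hit_table,
    plant_annotated_insertion,
    plant_cas_locus,
    plant_ta_pair,
    simulate_replicon,
)

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path("results/sim")
OUT.mkdir(parents=True, exist_ok=True)

rng = random.Random(SEED)
subtypes = sorted(SUBTYPE_LAYOUTS)
all_genes, all_seqs, hits, full_hits, truth_dump = [], {}, [], [], []

for r in range(10):
    completeness = Completeness.COMPLETE_GENOME if r % 2 == 0 else Completeness.DRAFT_OR_CONTIG
    choices = subtypes if completeness is Completeness.COMPLETE_GENOME else [
        s for s in subtypes if s != "II-C"]
    genes, seqs, truth = simulate_replicon(50, seed=SEED * 100 + r,
                                           replicon_id=f"R{r}",
                                           completeness=completeness)
    plant_cas_locus(genes, truth, rng.choice(choices), start_index=5, seed=SEED * 100 + r)
    plant_cas_locus(genes, truth, rng.choice(choices), start_index=30, seed=SEED * 100 + r + 50)
    hits += emit_hit_table(truth, [g.protein_id for g in genes], fp_rate=0.02,
                           seed=SEED * 100 + r)
    full_hits += emit_full_annotation_table(truth, seed=SEED * 100 + r)
    all_genes += genes
    all_seqs.update(seqs)
    truth_dump += [
        {"replicon": p.replicon_id, "span": [p.first_index, p.last_index],
         "subtype": p.subtype, "roles": p.roles,
         "completeness": completeness.value}
        for p in truth.planted_loci
    ]

# transposase panel: type I-E loci with a randomly stranded insertion
for k in range(20):
    genes, seqs, truth = simulate_replicon(20, seed=SEED * 1000 + k, replicon_id=f"T{k}")
    plant_cas_locus(genes, truth, "I-E", start_index=5, insert_intervening=True,
                    seed=SEED * 1000 + k)
    for i, g in enumerate(genes):
        if g.protein_id in truth.planted_loci[0].roles:
            genes[i] = type(g)(g.replicon_id, g.gene_index, g.start, g.end, "+",
                               g.protein_id, g.product)
    plant_annotated_insertion(genes, truth, truth.planted_loci[0],
                              "Transposase_20", strand=rng.choice("+-"))
    hits += emit_hit_table(truth, [g.protein_id for g in genes], seed=SEED * 1000 + k)
    full_hits += emit_full_annotation_table(truth, seed=SEED * 1000 + k)
    all_genes += genes
    all_seqs.update(seqs)
    truth_dump += [{"replicon": p.replicon_id, "span": [p.first_index, p.last_index],
                    "subtype": p.subtype, "roles": p.roles,
                    "completeness": "COMPLETE_GENOME"} for p in truth.planted_loci]

# TA panel: type I-C loci with an interior antitoxin-toxin pair
for k in range(12):
    genes, seqs, truth = simulate_replicon(20, seed=SEED * 2000 + k, replicon_id=f"TA{k}")
    plant_cas_locus(genes, truth, "I-C", start_index=5, seed=SEED * 2000 + k)
    for i, g in enumerate(genes):
        if g.protein_id in truth.planted_loci[0].roles:
            genes[i] = type(g)(g.replicon_id, g.gene_index, g.start, g.end, "+",
                               g.protein_id, g.product)
    plant_ta_pair(genes, truth, truth.planted_loci[0], strand="+")
    hits += emit_hit_table(truth, [g.protein_id for g in genes], seed=SEED * 2000 + k)
    full_hits += emit_full_annotation_table(truth, seed=SEED * 2000 + k)
    all_genes += genes
    all_seqs.update(seqs)
    truth_dump += [{"replicon": p.replicon_id, "span": [p.first_index, p.last_index],
                    "subtype": p.subtype, "roles": p.roles,
                    "completeness": "COMPLETE_GENOME"} for p in truth.planted_loci]

write_gene_table(all_genes, OUT / "genes.tsv")
write_fasta(all_seqs, OUT / "proteins.faa")
write_hit_table(hits, OUT / "hits.tsv")
write_hit_table(full_hits, OUT / "full_hits.tsv")
(OUT / "truth.json").write_text(json.dumps({"seed": SEED, "loci": truth_dump}, indent=1))

print(f"wrote {len(all_genes)} genes on {10 + 20 + 12} replicons, "
      f"{len(truth_dump)} planted loci, {len(hits)} cas-family hits -> {OUT}")
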