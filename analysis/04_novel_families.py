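"""Cluster unannotated candidate proteins into putative novel Cas families.

Generates a candidate pool with four planted families (six members each at
~40% pairwise identity, one redundant 95%-identity duplicate per family)
plus nine singletons, then runs the full novelty pipeline: 90% redundancy
reduction, bit-score-60 similarity graph, MCL at inflation 1.4, the
size/diversity filters, and exclusion of families resembling a known Cas
reference.  Writes results/novel_families.json and results/clusters.tsv.
"""

import json
import sys
from pathlib import Path

from casforge.novelty_clustering import (
    build_graph,
    exclude_known_like,
    mcl,
    reduce_redundancy,
    select_novel_families,
)
from casforge.synthetic_data import generate_family, mutate_to_identity

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1

seqs = {}
for f in range(4):
    fam = generate_family(6, 130, 0.40, seed=SEED * 10 + f, prefix=f"fam{f}")
    seqs.update(fam)
    donor = sorted(fam)[0]
    seqs[f"fam{f}_dup"] = mutate_to_identity(fam[donor], 0.95, seed=SEED * 10 + f)
for j in range(9):
    seqs.update(generate_family(1, 130, 1.0, seed=SEED * 10 + 90 + j, prefix=f"s{j}"))

reps, membership = reduce_redundancy(seqs, threshold=0.90)
graph = build_graph(reps, bit_threshold=60.0)
clusters = mcl(graph)
families, discards = select_novel_families(clusters, reps)
ref_donor = sorted(k for k in reps if k.startswith("fam0"))[0]
known = {"cas_ref": mutate_to_identity(reps[ref_donor], 0.6, seed=SEED * 10 + 99)}
exclude_known_like(families, reps, known)

Path("results").mkdir(exist_ok=True)
rows = ["protein_id\tfamily_id\taccepted"]
for fam in families:
    rows += [f"{m}\t{fam.family_id}\t{fam.accepted}" for m in fam.members]
Path("results/clusters.tsv").write_text("\n".join(rows) + "\n")
Path("results/novel_families.json").write_text(json.dumps([{
    "family_id": f.family_id, "members": f.members, "passed_size": f.passed_size,
    "passed_diversity": f.passed_diversity, "max_pairwise_identity": f.max_pairwise_identity,
    "excluded_known_like": f.excluded_known_like, "accepted": f.accepted,
} for f in families], indent=1))

accepted = [f for f in families if f.accepted]
print(f"{len(seqs)} candidates -> {len(reps)} non-redundant -> "
      f"{len(clusters)} MCL clusters -> {len(families)} clusters of >= 5 "
      f"members -> {len(accepted)} novel families after excluding "
      f"{sum(f.excluded_known_like for f in families)} known-like; "
      f"{len(discards)} sequences discarded (small clusters/singletons)")
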