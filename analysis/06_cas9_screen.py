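"""Screen candidate Cas9 proteins for the two catalytic residues.

Uses a synthetic 900-residue reference (stand-in for the S. pyogenes Cas9
coordinate system) with D at position 10 and H at 840, builds a candidate
panel containing intact homologs, D10A and H840A mutants and a truncation,
and writes per-site screening results to results/cas9_screen.tsv.
"""

import sys
from pathlib import Path

from casforge.cas9_screen import has_catalytic_residues
from casforge.synthetic_data import _random_protein, derive_rng, mutate_to_identity

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1

rng = derive_rng(SEED, "cas9ref")
ref = list(_random_protein(rng, 900))
ref[9], ref[839] = "D", "H"
reference = "".join(ref)

candidates = {}
for i in range(3):  # diverged homologs keeping both catalytic residues
    hom = list(mutate_to_identity(reference, 0.85, seed=SEED * 10 + i))
    hom[9], hom[839] = "D", "H"
    candidates[f"homolog_{i}"] = "".join(hom)
d10a = list(reference); d10a[9] = "A"
h840a = list(reference); h840a[839] = "A"
candidates["d10a_mutant"] = "".join(d10a)
candidates["h840a_mutant"] = "".join(h840a)
candidates["truncated"] = reference[:700]

rows = ["protein_id\tpass\tsites"]
n_pass = 0
for pid, seq in sorted(candidates.items()):
    ok, reports = has_catalytic_residues(seq, reference)
    n_pass += ok
    sites = ";".join(f"{r.reference_position}{r.required_residue}->"
                     f"{r.observed_residue or '-'}" for r in reports)
    rows.append(f"{pid}\t{str(ok).lower()}\t{sites}")
Path("results").mkdir(exist_ok=True)
Path("results/cas9_screen.tsv").write_text("\n".join(rows) + "\n")
print(f"{n_pass}/{len(candidates)} candidates carry both catalytic residues "
      f"(mutants and the truncation are rejected)")
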