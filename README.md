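# casforge

Discovery and analysis of CRISPR–Cas (*cas*) gene loci in genomes and
metagenome assemblies, for microbial genomics and microbiome researchers.

CRISPR–Cas systems pair CRISPR repeat-spacer arrays with clusters of *cas*
genes that encode the adaptive-immunity machinery. Because *cas* genes are
operonic, membership in a locus is itself evidence: a gene with only a weak
similarity to a known Cas family becomes credible when it sits next to a
confident one, and a gene with no similarity at all becomes a candidate for
a *novel* Cas family when it sits *between* cas genes. casforge implements
that integrated similarity + genomic-neighborhood logic as a tested library
with a CLI, exercised end-to-end on synthetic data with known ground truth.

## Method

1. **Seed and recruit.** Proteins hitting a known Cas family at the
   family's gathering (trusted) cutoff are seeds. Genes with a weak hit
   (E ≤ 10⁻³) within a three-gene distance of a labeled gene are recruited;
   recruits recruit in turn, so labeling runs to its (unique, order-
   independent) fixed point. Labeled genes plus the unlabeled genes caught
   between them form *cas* loci.
2. **Classify.** A locus gets type/subtype labels from signature genes
   (cas3 → I, cas9 → II, cas10 → III; csn2 → II-A, cas4 + cas9 → II-B,
   cse1 → I-E, …, all configurable in YAML). Subtype II-C — exactly
   {cas9, cas1, cas2} — is called only on complete genomes, since a
   truncated locus on a contig mimics it. Cross-type co-occurrence,
   toxin–antitoxin gene pairs (with orientation relative to the cas
   strand), and transposase strand opposition are reported per locus.
3. **Cluster novel candidates.** Intervening genes with no hit against the
   full family database are reduced at 90% identity (greedy, longest-first,
   CD-HIT convention), joined by edges where the pairwise alignment bit
   score exceeds 60 (bit = (λS − ln K)/ln 2, gapped BLOSUM62 constants),
   and partitioned by Markov clustering at inflation 1.4. Clusters need
   ≥ 5 members at ≤ 50% pairwise identity, and are dropped if any member
   resembles a known Cas reference (E ≤ 10⁻⁵ **and** identity ≥ 30%).
4. **Profile refinement.** Per family: drop length outliers (≥ 2 SD from
   the mean), center-star align, build a log-odds scoring profile, then
   iteratively recruit database sequences scoring above the worst seed
   (removing that seed each round) until nothing new is found. The lowest
   final-seed score is the gathering/trusted cutoff; the highest non-seed
   score is the noise cutoff.
5. **Cas9 screening and abundance.** Candidate Cas9 proteins are screened
   for the two catalytic residues (D10 in the RuvC-like domain, H840 in the
   HNH domain, in reference coordinates) via global alignment. Cohort
   abundance uses the per-sample cas percentage, 100·n_cas/n_total, with
   two-tailed paired t-tests between body habitats.

## Worked example

The numbered scripts under `analysis/` run the whole pipeline on a
synthetic panel (42 replicons, 52 planted loci with decoy hits, transposase
and toxin–antitoxin insertions) and write their tables under `results/`:

```text
$ python analysis/01_simulate_genomes.py 1
wrote 1140 genes on 42 replicons, 52 planted loci, 320 cas-family hits -> results/sim
$ python analysis/02_detect_loci.py
52 loci detected; span recovery 100.0% (52/52); subtype recovery 100.0% (52/52); ...
$ python analysis/03_locus_content.py
12 TA pairs, antitoxin upstream in 12 (100%); Transposase_20 opposite strand 8/20 (40%)
$ python analysis/04_novel_families.py 1
37 candidates -> 33 non-redundant -> 13 MCL clusters -> 4 clusters of >= 5
members -> 3 novel families after excluding 1 known-like; 9 sequences discarded ...
$ python analysis/05_refine_profiles.py 1
2 iterations; recruited 3/3 held-out members and 0 decoys;
gathering=trusted=384.9 bits, noise=188.1 bits
$ python analysis/07_habitat_abundance.py 1
mean cas percentage by habitat: stool=0.198%, buccal_mucosa=0.303%,
supragingival_plaque=0.524%, tongue_dorsum=0.596%
  stool vs tongue_dorsum: t=-16.49, p=1.01e-24 (n=65)
```

Every planted locus span and subtype label is recovered exactly in the
noise-free regime; the transposase strand fraction hovers around 50%
(random insertion); oral habitats carry several-fold more cas genes than
stool, and the paired contrast is decisively significant.

The same steps are available as a CLI
(`casforge simulate | detect | cluster | refine | cas9-screen | abundance`),
e.g. `casforge detect --genes G.tsv --hits H.tsv --out out/`.

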