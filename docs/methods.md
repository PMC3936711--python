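# Methods

This note documents the models, parameters and design choices behind
casforge, and what the synthetic-data experiments do and do not establish.

## Locus detection model

Detection operates on gene-order coordinates only: each gene's
`gene_index` is its 0-based rank by start coordinate within its replicon.
Distance between genes is |gene_index difference| — gene counts, not base
pairs — because cas operon structure is a property of gene adjacency, and
intergenic distances vary too much across taxa to carry a portable
threshold. Strand is ignored during recruitment (cas loci commonly mix
strands); it is used only by the orientation analyses.

Two hit classes drive labeling:

* a **gathering-cutoff hit** (`meets_gathering`) marks a confident family
  assignment and makes the gene a seed;
* a **weak hit** (E ≤ `weak_e_max`, default 10⁻³) makes a gene recruitable
  when it lies within `window` (default 3) genes of an already-labeled
  gene on the same replicon.

Labeling is the least fixed point of that relation, computed by BFS. It is
provably order-independent, which the suite checks by shuffling input rows
and by comparison against a brute-force saturation oracle. Chains never
cross replicon boundaries: contigs are independent assemblies, and
adjacency across a contig break is meaningless.

Locus assembly groups labeled genes into maximal chains with consecutive
gaps ≤ `window`, then pulls every unlabeled gene strictly inside the chain
span in as `INTERVENING_UNKNOWN`. Chains with no seed member are discarded:
weak similarity alone, however clustered, never founds a locus. Intervening
genes that match *any* family in the full database (even a non-Cas family,
e.g. a transposase) are routed to the assorted-functions report; only
fully unannotatable intervening genes become novel-family candidates.

`meets_gathering` is carried in the hit table rather than re-derived from
per-family thresholds, so any scorer (including the package's own profile
scorer, or an external HMM engine) can produce the input.

## Classification

The signature map ships as YAML (`data/signature_map.yaml`) because it is
curation, not code: users with different subtype taxonomies edit data.
Two rules are structural rather than per-family:

* **cas4 → II-B only with cas9 present.** cas4 also occurs in type I
  systems, so alone it is not type II evidence.
* **II-C** has no signature family; it is the minimal system defined by
  known-cas composition exactly {cas9, cas1, cas2}, and is only called on
  complete genomes. On drafts/contigs the absence of csn2/cas4 may be an
  assembly artifact, so the call is suppressed regardless of composition
  (enforced unconditionally; the suite checks it can never be emitted for
  draft inputs).

A locus carrying signatures of several subtypes reports all of them —
precedence would be an invention. The "cas strand" for orientation calls
is the majority strand of seed+recruited members; ties are reported as
indeterminate rather than broken arbitrarily.

## Alignment scale

All pairwise alignment is global Needleman–Wunsch under BLOSUM62 with
affine gaps (open −11, extend −1), via Biopython's PairwiseAligner. Raw
scores map to bits with Karlin–Altschul constants λ = 0.267, K = 0.041
(standard gapped BLOSUM62 values, configurable); E-values for the
known-like exclusion use E = K·m·n·e^(−λS) with the same constants, so
"bit score > 60" and "E ≤ 10⁻⁵" sit on one coherent scale. Identity is
identical aligned positions over the shorter sequence length (the CD-HIT
convention), so the 90% reduction and the 30%/50% gates mean the same
thing everywhere.

## Redundancy reduction and MCL

Reduction is greedy incremental: longest sequence first (ties by id), each
sequence joins the first representative at identity ≥ 0.90 or founds a new
one. By construction no representative pair reaches the threshold and
every removed sequence has a representative at ≥ 0.90; both are asserted
post hoc in tests rather than assumed.

MCL uses expansion power 2, inflation 1.4, self-loops at each node's
maximum incident edge weight, pruning below 10⁻⁵, convergence when the
largest entry change falls below 10⁻⁸, and a 100-iteration cap; clusters
are the connected components of the limit matrix's nonzero structure.
These numerical defaults are ordinary MCL practice and configurable; the
suite cross-checks the partition against an independently written dense
reference implementation on random graphs.

Family filters: ≥ 5 members; pairwise identity ≤ 0.50 evaluated on the
non-redundant members. A diversity violation *flags* the family
(`passed_diversity = False`) instead of silently deleting members, since
the 50% bound describes reportable families, not a pruning rule. Known-like
exclusion requires E ≤ 10⁻⁵ **and** identity ≥ 0.30 jointly — a strong
E-value at 25% identity does not exclude.

## Profiles and refinement

The per-family model is a gapped position-specific scoring matrix, not a
full profile HMM: the scientific content captured here is the refinement
loop and the cutoff bookkeeping, which are model-agnostic, and the scorer
is exchangeable. Columns with > 50% gaps are dropped. Column log-odds are
log2((count + pc·bg)/(n + pc)/bg) with Laplace-style pseudocount pc = 1.0
(pc > 0 required: a zero pseudocount produces infinite log-odds on
single-sequence alignments). Scoring is affine-gap DP against the columns
(gap open −4 bits, extend −1 bit), verified against exhaustive alignment
enumeration on small cases. The multiple alignment is center-star (center
maximizes summed pairwise scores; "once a gap, always a gap"), checked by
the projection identity: every row with gaps removed equals its input.

Refinement: build profile from current seeds → score the database →
recruit everything scoring strictly above the worst current seed → add
recruits, drop that one worst seed, repeat; stop when nothing is recruited
or a seed set recurs (cycle guard). Removed seeds rejoin the database and
may be re-recruited; the alternative (permanent removal) is a flag. The
2-SD length filter uses the population SD with a strict retain condition
|len − mean| < 2·SD, so a zero-SD family is fully retained. Gathering =
trusted = minimum final-seed score; noise = maximum non-seed database
score (absent when the database is empty or fully recruited).

## What the synthetic data emulates

The generator stands in for annotated complete/draft genomes and
metagenome contigs:

* replicons with non-overlapping genes (normal lengths around 900 bp,
  exponential gaps, random strands) and uniform-background protein
  sequences;
* planted loci laid out per subtype, mixing gathering-level members
  (seeds) with weak-hit members (recruits) so recruitment is actually
  exercised; weak-hit E-values in [10⁻⁶, 10⁻³]; spurious decoy hits on
  non-cas genes at a configurable rate, with E in (10⁻³, 10] so decoys
  stress seed finding but not the recruitment threshold;
* transposase/toxin/antitoxin insertions inside loci, annotated only in
  the full-database hit table;
* protein families at controlled pairwise identity, built by substituting
  an ancestor (members at ancestor identity √t give member–member identity
  ≈ t); realized identity is verified with the package's own aligner and
  nudged to ±2 points. Families planted as novel families are generated at
  0.40 pairwise identity — comfortably inside the ≤ 0.50 diversity
  criterion they are meant to satisfy, so filter outcomes test the
  pipeline, not the generator's sampling noise;
* refinement scenarios mirror how real seed sets arise: seeds are
  post-redundancy-reduction representatives spanning a divergence range
  (ancestor identity 0.65–0.95), and the database holds near-duplicate
  variants (0.97) of retained seeds — the redundant homologs a 90%
  reduction removes — plus unrelated decoys. With homogeneous families no
  database sequence can outscore the worst seed (each seed's own counts
  inflate its self-score), so heterogeneity is not a convenience but the
  property that makes recruitment observable at all;
* a 65-subject cohort over four body habitats with mean cas-gene
  fractions stool 0.002, buccal mucosa 0.003, supragingival plaque 0.005,
  tongue dorsum 0.006, independent mean-corrected lognormal dispersion
  (0.3) per subject × habitat, and binomial cas counts over 20–60k genes.
  Site abundances are deliberately uncorrelated within subjects, matching
  the observed lack of stool–oral coupling.

Not emulated: nucleotide sequences, CRISPR repeat-spacer arrays, real
amino-acid composition biases, homology between different planted
families, assembly fragmentation inside a locus, and database-scale search
statistics. Passing tests therefore demonstrate the algorithms' contracts
(exact recovery under clean conditions, robustness bounds under decoys),
not expected sensitivity/specificity on real metagenomes.

All generators derive their streams by hashing (global seed, purpose tag)
into independent RNGs, so adding a generator never shifts another's
output; everything is byte-deterministic for a fixed seed.

## Problem sizes

The shipped analyses and the acceptance script run 10 mixed-completeness
replicons of 50 genes (two planted loci each, 2% decoy rate), 20
transposase and 12 TA panels, a 37-sequence candidate pool over 4 planted
families, one refinement scenario (5 seeds, 53 database sequences), and
one 65-subject cohort. These sizes make every ground-truth comparison
exact and enumerable; the library itself has no scale assumptions beyond
O(n²) pairwise alignment in the clustering stages.

## Known limitations

* The PSSM scorer is not calibrated to HMMER bit scores; gathering/noise
  cutoffs are internally consistent but not portable to hmmsearch.
* Center-star alignment is O(n²) in pairwise alignments; families of many
  hundreds of members would want a proper progressive aligner.
* The greedy reduction depends on input lengths for its visit order;
  equal-length ties fall back to lexicographic ids, which is deterministic
  but arbitrary.
* Subtype calls rest entirely on the signature map; unusual fusion loci
  are reported via co-occurrence flags rather than resolved.
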