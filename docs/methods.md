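# Methods

`tbdtscan` profiles TonB-dependent transporter (TBDT) gene families in
bacterial proteomes and fragmented metagenome samples. This note
records the models, the numerical choices, and what the synthetic test
world does and does not establish.

## The analysis model

### Identification: dual-domain filter with reciprocal verification

A TBDT is defined structurally by an N-terminal plug domain inserted in
a C-terminal 22-strand β-barrel. A protein is accepted as a TBDT
candidate when

1. both domain models hit above their thresholds, with the plug
   envelope starting before the barrel envelope (the order check is on
   by default and toggleable — the architecture implies it, but the
   filter can be relaxed to co-occurrence only), and
2. its best match in a labeled reference database is itself a
   TBDT-labeled sequence at E ≤ 1e-5 (reciprocal verification).

Domain models are position-specific score matrices (PSSMs) rather than
profile HMMs: the contribution being tested is the filter architecture,
not HMM machinery, and anything that emits `DomainHit` records (e.g. a
real `hmmsearch` backend) can be plugged in. Model scores are genuine
log₂-odds of a position-specific target distribution against a uniform
background, so the tail bound P(score ≥ s) ≤ 2⁻ˢ holds under the
background model and the window E-value (n_windows · 2^−bits) is
conservative; the Monte-Carlo calibration test exercises exactly this
bound. Defaults: score threshold 25 bits, E ≤ 1e-5. The ambiguity code
X scores 0 against every residue and every model column.

### Pairwise search

All pairwise protein searches are exact Smith–Waterman affine-gap
alignments (BLOSUM62; gap open 11, extend 1, BLAST convention: a gap of
length k costs open + k·extend). No heuristic seeding is performed —
correctness over speed at desk scale. Significance uses the
Karlin–Altschul formulation with fixed published ungapped constants
(λ = 0.3176, K = 0.134 for BLOSUM62):

    bits = (λ·raw − ln K) / ln 2,    E = m·n·2^(−bits),

with effective sizes m, n defaulting to the actual sequence lengths.
Fixing the constants keeps results deterministic; fitted gapped
statistics and composition adjustment are out of scope. Census and
verification searches use a score-only fast path (no traceback); the
full alignment is computed only when percent identity or alignment
length is needed (e.g. the recruitment length filter).

Thresholds follow the method being reproduced: transporter census at
E ≤ 1e-3, metagenome recruitment at E ≤ 1e-5, cluster graph at
E ≤ 1e-40. The "alignment length > 100" recruitment filter is optional
(`min_alignment_length`); in the synthetic world fragment lengths are
drawn independently of the source gene, so the filter removes the same
expected fraction of numerator and denominator of the frequency
statistic and leaves recovery unbiased either way.

### Clustering: shared-neighbor similarity on the match graph

The all-vs-all matches at E ≤ 1e-40 are reduced to per-sequence
neighborhoods (self-match included; symmetrized — a pair is kept if
either direction passes, with the better bit score). The cited
shared-neighbor ("Lek") similarity has no single published closed form,
so the kernel is a configuration choice, not a hard-coded guess:

* `weighted_jaccard` (default): Σ_shared min(score_a, score_b) /
  Σ_union max(available scores) — 1 for identical weighted
  neighborhoods, 0 for disjoint ones;
* `jaccard`: unweighted |∩|/|∪| of neighbor sets;
* `cosine`: cosine of the score vectors over the neighbor union.

Pairs with similarity ≥ 0.6 (a normalized cutoff in [0, 1]) are linked
and clusters are the connected components — deterministic, order-free,
and monotone: raising the cutoff can only refine the partition, and
restricting to a subset of sequences can never merge surviving
clusters. Average-linkage agglomeration is available as an alternative
linkage. Singletons are kept as size-1 clusters; "more than two
members" style reporting filters are applied downstream
(`ClusterPartition.filter_min_size`).

### Annotation

Clusters inherit the substrate groups of the anchors they contain
(group I: DOM; II: siderophores/vitamins; III: heme; IV: metals).
Multi-label clusters are allowed — real siderophore and thiamin
transporters do co-cluster — so no single label is forced. Anchor-free
clusters are `unknown`, and the unknown member fraction is reported per
origin class (reference vs metagenome). The packaged anchor table
transcribes the characterized marine TBDT anchors with their substrates
and groups; duplicate entries of the same protein name were collapsed
to one row.

Best-hit taxonomy labels an environmental sequence with the phylogroup
of its best reference match at E ≤ 1e-5 (the recruitment cutoff; the
original binning cutoff is unstated, so this default is flagged and
configurable). The phylogroup vocabulary is fixed at the coarse level
used for marine surveys (Gammaproteobacteria, CFB, Sphingomonadales,
other Alphaproteobacteria, Cyanobacteria, other).

Gene-context hints mechanize a manual curation pattern only: neighbors
within 5 kb (strand-agnostic, distance between nearest gene
boundaries) whose product annotation contains a rule keyword yield a
substrate suggestion (phytase → phytic acid, cyanophycinase →
cyanophycin, cobalamin/B12 biosynthesis → vitamin B12, acyltransferase
→ fatty-acyl siderophore, heme → heme). The rules ship as an editable
table; the hints never claim the biology.

### Normalization and the frequency statistic

Raw hit counts Ng are length-biased (longer genes recruit more
fragments), so they are normalized against E. coli K12 recA
(L_recA = 1,062 bp):

    Nn = (L_recA / Lx) · Ng,

where Lx is the arithmetic mean nucleotide length of the category's
genes (cluster members, or all genes of a multi-gene transporter
system; the mean type is a design choice — the source describes only
"average"). Genome equivalents are the mean of the six normalized
single-copy marker counts (recA, atpD, gyrB, dnaK, rpoB, tufA); a site
missing a marker raises rather than imputing, and sites flagged as
contaminated are honored and excluded by the profiling operations.
Frequency = Nn / genome equivalents reads as copies per genome.
The statistic is invariant under uniform scaling of all hit counts.

Per-genome censuses report counts per transporter class and densities
per Mbp rounded half-up to integers — the convention under which every
bracket value of the packaged 39-genome table re-derives exactly.
Spearman correlations use average-rank tie handling (scipy); the
t-approximation p-value is reported descriptively and never used as a
gate. Because the published ρ = −0.677 could have been computed on
rounded or exact densities, both variants are computed and reported
(−0.6772 rounded, −0.6839 exact on the packaged table).

## The synthetic world

The generator emulates the statistical structure the analysis assumes,
not marine biology:

* **Family seeds.** Each TBDT family is plug + 80-residue variable
  region + barrel, with the shared plug/barrel consensus mutated at
  rate 0.4 per family. This keeps every family detectable by the domain
  models (≈1.5 bits/column margin at within-family divergence 0.1)
  while inter-family alignments stay above the E ≤ 1e-40 graph cutoff,
  so the stated clustering cutoffs separate the families — chosen a
  priori as a realistic inter-paralog divergence, not tuned. Decoy
  ABC/PTS/TRAP families and a plug-only fragment family provide true
  negatives for the dual filter.
* **Copy counts** are drawn uniformly from per-family integer ranges
  ([0,1], [1,2], [2,4], [1,3] by default — true means 0.5–3 copies per
  genome); six markers occur exactly once per genome. Marker copies
  diverge 0.05 from fixed ancestral sequences (conserved genes).
  Nucleotide gene length is 3·(protein length + 1) so Lx is defined in
  base pairs; recA is pinned at 353 aa = 1,062 bp.
* **Site samples** pick a source genome by composition weight, a gene
  within it proportionally to nucleotide length (the shotgun model the
  recA normalization corrects), a fragment length from a log-normal
  (median ≈ 180 aa, σ = 0.4, floor 30 aa — the source gives no ORF
  length distribution; this is a free config choice), and a uniform
  start. Fragments are amino acids: the analysis operates on peptides,
  so the nucleotide recovery step of the original workflow is skipped.
* **Truth.** Composition weights are ORF-share weights; true copies
  per genome equivalent therefore weight each genome by weight/length,
  renormalized. Under this model the frequency statistic is an
  unbiased estimator of true copies per genome equivalent.
* **Determinism.** One pseudo-random stream per operation, seeded
  explicitly; the copy-count draws form a documented prefix of the
  stream so tests can re-draw them independently.

What a green test does **not** establish: realistic nucleotide
evolution (no indels, no rate heterogeneity, no sequencing error), real
HMM sensitivity on remote homologs, rRNA or intergenic content, or any
claim about which substrates real clusters transport. The synthetic
sensitivity/specificity numbers characterize the filter on the stated
world only.

## Numerical and degenerate-input choices

* Census ties (equal best E-value) break by higher bit score, then
  lexicographic family id; best-hit searches likewise break ties by
  subject id, so results are independent of database order.
* Shared-neighbor similarity of two empty-overlap neighborhoods is 0;
  an all-zero denominator yields 0.
* `spearman_rho` raises on length mismatch, fewer than 3 points, or a
  constant vector (undefined statistic) rather than returning NaN.
* E-values for strongly negative bit scores saturate at infinity
  instead of overflowing.
* Pipeline configuration is validated before execution (e.g. a
  similarity cutoff of 1.01 is rejected); stage failures raise a
  stage-named error and retain partial outputs; the manifest hash
  covers the full configuration.

## Known limitations

* Exact DP search scales quadratically; the package targets desk-scale
  studies (hundreds of genomes, 10⁴–10⁵ fragments), not millions of
  sequences.
* PSSM models underperform profile HMMs on remote homologs; the
  adapter contract exists precisely so a real HMM backend can replace
  them for production use on real data.
* The plug-before-barrel order check can wrongly reject circularly
  permuted or truncated real proteins; it is toggleable.
* Anchor propagation is purely guilt-by-association at the cluster
  level; a contaminating anchor mislabels its whole cluster.
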