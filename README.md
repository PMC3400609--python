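# tbdtscan

Profiling of TonB-dependent transporter (TBDT) gene families in
bacterial genomes and metagenome samples.

TBDTs are outer-membrane receptors of Gram-negative bacteria that
import scarce resources — iron–siderophore complexes, heme, vitamin
B12, metals, and a growing list of dissolved-organic-matter (DOM)
substrates such as chito-oligosaccharides, maltodextrin and phytate.
Counting and classifying them across genomes and ocean metagenomes
tells you which bacterial groups can eat what. `tbdtscan` is a small,
deterministic, fully tested reimplementation of that comparative
workflow for people who want to study the *method* (thresholds, filter
architecture, normalization behaviour) on data with known ground
truth, or to run the same census logic on their own desk-scale data.

## What it computes

* **Identification** — a protein is a TBDT candidate iff both the
  N-terminal plug and the C-terminal β-barrel domain models hit (plug
  before barrel) *and* its best labeled reference match is a TBDT at
  E ≤ 1e-5 (reciprocal verification). Domain models are pluggable
  PSSMs scored by best window.
* **Pairwise search** — exact Smith–Waterman (BLOSUM62, affine gaps
  11/1) with Karlin–Altschul statistics:
  bits = (λ·raw − ln K)/ln 2, E = m·n·2^(−bits).
* **Clustering** — all-vs-all matches at E ≤ 1e-40 define match
  neighborhoods; pairs with shared-neighbor (Lek-style) similarity
  ≥ 0.6 are linked and connected components are the gene families.
* **Annotation** — clusters inherit substrate groups (I DOM,
  II siderophores/vitamins, III heme, IV metals) from a packaged table
  of characterized anchor TBDTs; best-hit taxonomy and keyword-based
  gene-context substrate hints are included.
* **Abundance** — per-site hit counts are length-normalized,
  Nn = (L_recA/Lx)·Ng with L_recA = 1,062 bp, divided by genome
  equivalents (mean normalized count of six single-copy markers:
  recA, atpD, gyrB, dnaK, rpoB, tufA), giving frequencies in copies
  per genome; per-genome censuses report counts and per-Mbp densities;
  Spearman rank correlations (tie-corrected) compare transporter
  classes.
* **Synthetic community** — a first-class generator of reference
  genomes (TBDT families + ABC/PTS/TRAP decoys + markers) and
  fragmented metagenome sites with full ground truth, used by the test
  suite for parameter recovery.

A packaged 39-genome marine census table (counts, genome sizes and the
published per-Mbp density brackets) ships with the package and is used
to reproduce the published density arithmetic and the TBDT-vs-ABC rank
correlation.

## Worked example

```sh
python examples/06_genome_census.py
```

prints (abridged):

```
39 genomes; first rows:
                          organism  size_mb  tbdt  tbdt_density  abc  abc_density
Citromicrobium bathyomarinum JL354     3.27    27             8   22            7
        Sphingomonas wittichii RW1     5.92   134            23   34            6

density round-trip mismatches: 0 (every bracket value re-derives as round-half-up(count / Mb))
Spearman TBDT vs ABC density (rounded): rho = -0.6772, P = 2.2e-06, N = 39
Spearman TBDT vs ABC density (exact):   rho = -0.6839, P = 1.6e-06, N = 39
```

i.e. every published per-Mbp density re-derives exactly from its count
and genome size, and TBDT-rich genomes are ABC-transporter-poor
(ρ ≈ −0.68): the two uptake strategies trade off across marine
bacteria.

`python examples/05_profile_sites.py` runs the other half of the
workflow — recruiting 2,000 synthetic ORF fragments, normalizing by
gene length and genome equivalents, and printing recovered vs true
copies per genome for each TBDT family:

```
site site1 (open sea), 2000 ORFs, genome equivalents = 100.5
family          Ng       Nn  freq est  freq true
TBDT_dom        30     40.7     0.405      0.517
TBDT_sid       143    194.0     1.930      1.620
TBDT_heme      192    260.4     2.591      2.651
TBDT_metal     140    189.9     1.890      1.790
```

The remaining examples (`examples/01`–`07`) each demonstrate one
capability: community simulation, identification, clustering,
annotation + context hints, site profiling, the census, and the full
pipeline with its provenance manifest.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the entire pipeline from scratch on the default synthetic
community (10 genomes, 3 sites of 2,000 ORFs each, all stages from
simulation through correlation), prints per-stage counts to stderr and
writes the report JSON to `--out`. All randomness derives from
`--seed`.

## Layout

```
src/tbdtscan/        library (records, align, domains, identify,
                     clustering, annotation, profiling, synthetic,
                     pipeline, io) + packaged data tables
examples/            one narrative script per capability
tests/               pytest suite incl. independent oracles
docs/methods.md      models, assumptions, numerical choices
```
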