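"""Synthetic bacterial community and fragmented metagenome generator.

Emulates the statistical structure the downstream analysis assumes:

* reference genomes carrying TonB-dependent transporter (TBDT) gene
  families alongside decoy transporter families (ABC / PTS / TRAP-like)
  and exactly one copy of each of six universal single-copy marker genes
  (recA, atpD, gyrB, dnaK, rpoB, tufA);
* metagenome site samples of contiguous amino-acid ORF fragments drawn
  shotgun-style (source gene chosen proportionally to its nucleotide
  length) from a weighted genome mix, with a ground-truth table mapping
  every fragment to its source family and genome.

Because source genes are sampled length-proportionally, raw fragment
counts are biased by gene length exactly the way real shotgun hit counts
are — which is what the recA length normalization (Nn = L_recA/Lx * Ng)
corrects.  True per-family copies per genome equivalent are recorded in
:class:`SyntheticTruth` for parameter-recovery tests.

Every TBDT family seed is built as plug + variable region + barrel,
with the shared plug/barrel consensus mutated at rate 0.4 per family so
that families remain detectable by the domain models while staying below
the E <= 1e-40 clustering cutoff between families.  Fragments are amino
acids throughout: the analysis operates on peptides, so no nucleotide
sequences are simulated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np

from .domains import domain_consensus
from .records import AMINO_ACIDS, GeneModel, ProteinSeq, protein_nt_length

#: Protein lengths (residues) of the six single-copy marker genes.
#: recA is pinned so its nucleotide length is the E. coli K12 reference
#: 1,062 bp = 3 * (353 + 1); the others are typical bacterial lengths.
MARKER_PROTEIN_LENGTHS: dict[str, int] = {
    "recA": 353,
    "atpD": 460,
    "gyrB": 640,
    "dnaK": 630,
    "rpoB": 1340,
    "tufA": 394,
}

#: Reference nucleotide length of recA (base pairs), the normalization unit.
L_RECA = 1062

MARKER_NAMES = tuple(MARKER_PROTEIN_LENGTHS)

_MARKER_SEED = 20120719  # fixed internal stream label for marker seeds
_FAMILY_SEED = 41204     # fixed internal stream label for family seeds

GROUP_LABELS = ("I_DOM", "II_SiderophoreVitamin", "III_Heme", "IV_Metal", "decoy")


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


@dataclass(frozen=True)
class FamilySpec:
    """Blueprint of one gene family carried by the synthetic genomes.

    ``copies_per_genome_range`` is an inclusive integer interval from
    which each genome's copy count is drawn uniformly.  ``divergence``
    is the per-residue substitution rate applied to each copy relative
    to the family seed.  ``category`` names the transporter class the
    census should recover (TBDT / ABC / PTS / TRAP / other).
    """

    family_id: str
    group_label: str
    seed_sequence: str
    copies_per_genome_range: tuple[int, int]
    divergence: float = 0.1
    category: str = "TBDT"

    def __post_init__(self) -> None:
        if self.group_label not in GROUP_LABELS:
            raise ValueError(f"unknown group label {self.group_label!r}")
        if len(self.seed_sequence) < 50:
            raise ValueError("seed sequence must have at least 50 residues")
        lo, hi = self.copies_per_genome_range
        if lo < 0 or hi < lo:
            raise ValueError("copies_per_genome_range must be a nonnegative interval")
        if not 0 <= self.divergence <= 0.6:
            raise ValueError("divergence must lie in [0, 0.6]")

    @property
    def mean_copies(self) -> float:
        lo, hi = self.copies_per_genome_range
        return (lo + hi) / 2.0

    @property
    def nt_length(self) -> int:
        return protein_nt_length(len(self.seed_sequence))


@dataclass
class SyntheticGenome:
    """One simulated genome: gene models, proteome, marker bookkeeping."""

    genome_id: str
    size_mb: float
    genes: list[GeneModel]
    proteome: list[ProteinSeq]
    single_copy_genes: dict[str, str]          # marker name -> gene_id
    family_copies: dict[str, int]              # family_id -> copies carried
    gene_source: dict[str, str]                # gene_id -> family_id or "marker:<name>"

    def __post_init__(self) -> None:
        if set(self.single_copy_genes) != set(MARKER_NAMES):
            raise ValueError("each genome must carry the six markers exactly once")
        if len(self.genes) != len(self.proteome):
            raise ValueError("every gene must map to exactly one protein")

    @property
    def total_nt_length(self) -> int:
        return sum(g.nt_length for g in self.genes)


@dataclass
class SiteSample:
    """A fragmented metagenome sample from one site."""

    site_id: str
    habitat: str
    orfs: list[ProteinSeq]
    excluded: bool = False  # contaminant-style metadata flag


@dataclass
class SyntheticTruth:
    """Ground truth for one site sample.

    ``site_frequencies`` maps family_id to true copies per genome
    equivalent in the sampled mix (genome-equivalent weights are the
    composition weights divided by genome length, renormalized, because
    composition weights are ORF-share weights).  ``orf_sources`` maps
    every emitted ORF id to (source family or "marker:<name>", source
    genome).  ``expected_genome_equivalents`` is the expectation of the
    marker-based genome-equivalent estimator for this sample.
    """

    site_frequencies: dict[str, float]
    orf_sources: dict[str, tuple[str, str]]
    expected_genome_equivalents: float

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.site_frequencies.values()):
            raise ValueError("truth frequencies must be nonnegative")


def mutate_sequence(seq: str | ProteinSeq,
                    substitution_rate: float,
                    seed: int | np.random.Generator = 0) -> str:
    """Substitute each position independently with the given rate.

    A substituted position always receives a *different* residue, so the
    realized Hamming distance is Binomial(L, rate) and rate 1 changes
    every position.
    """
    residues = seq.residues if isinstance(seq, ProteinSeq) else seq
    if not residues:
        raise ValueError("cannot mutate an empty sequence")
    if not 0 <= substitution_rate <= 1:
        raise ValueError("substitution rate must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = list(residues)
    mask = rng.random(len(out)) < substitution_rate
    for i in np.flatnonzero(mask):
        # Pick uniformly among the 19 residues different from the current one.
        j = int(rng.integers(0, 19))
        current = AMINO_ACIDS.find(out[i])
        if current >= 0 and j >= current:
            j += 1
        out[i] = AMINO_ACIDS[j % 20]
    return "".join(out)


def marker_seed_sequences() -> dict[str, str]:
    """Fixed ancestral sequences of the six marker genes (internal stream)."""
    rng = np.random.default_rng(_MARKER_SEED)
    return {name: _random_protein(rng, length)
            for name, length in MARKER_PROTEIN_LENGTHS.items()}


def default_family_specs() -> list[FamilySpec]:
    """The packaged community blueprint.

    Four TBDT families (one per substrate group, plug + variable region
    + barrel architecture, true 0.5-3 mean copies per genome) plus decoy
    ABC / PTS / TRAP families and a plug-only fragment decoy that tests
    the dual-domain filter's true-negative behaviour.  Deterministic:
    seeds are derived from a fixed internal stream.
    """
    rng = np.random.default_rng(_FAMILY_SEED)
    plug_cons, barrel_cons = domain_consensus()

    def tbdt_seed() -> str:
        plug = mutate_sequence(plug_cons, 0.4, rng)
        variable = _random_protein(rng, 80)
        barrel = mutate_sequence(barrel_cons, 0.4, rng)
        return plug + variable + barrel

    specs = [
        FamilySpec("TBDT_dom", "I_DOM", tbdt_seed(), (0, 1)),
        FamilySpec("TBDT_sid", "II_SiderophoreVitamin", tbdt_seed(), (1, 2)),
        FamilySpec("TBDT_heme", "III_Heme", tbdt_seed(), (2, 4)),
        FamilySpec("TBDT_metal", "IV_Metal", tbdt_seed(), (1, 3)),
        FamilySpec("ABC_1", "decoy", _random_protein(rng, 330), (2, 4),
                   category="ABC"),
        FamilySpec("PTS_1", "decoy", _random_protein(rng, 250), (0, 2),
                   category="PTS"),
        FamilySpec("TRAP_1", "decoy", _random_protein(rng, 300), (0, 1),
                   category="TRAP"),
        # Plug domain without a barrel: must be rejected by the dual filter.
        FamilySpec("FRAG_plug", "decoy",
                   mutate_sequence(plug_cons, 0.15, rng) + _random_protein(rng, 120),
                   (0, 1), category="other"),
    ]
    return specs


_PRODUCTS = {
    "TBDT": "TonB-dependent receptor",
    "ABC": "ABC transporter substrate-binding protein",
    "PTS": "PTS system transporter subunit",
    "TRAP": "TRAP dicarboxylate transporter",
    "other": "hypothetical outer membrane protein",
}

_INTERGENIC_BP = 50
_MARKER_DIVERGENCE = 0.05  # markers are conserved genes


def generate_reference_set(family_specs: Sequence[FamilySpec],
                           n_genomes: int,
                           marker_lengths: Mapping[str, int] | None = None,
                           seed: int = 0) -> list[SyntheticGenome]:
    """Simulate ``n_genomes`` genomes carrying the given families.

    Draw order (single stream seeded by ``seed``): first all per-genome,
    per-family copy counts in genome-major, spec order; then, per genome,
    the mutations of every family copy (spec order, copy order), the six
    marker copies (MARKER_NAMES order), and finally the gene-order
    permutation and per-gene strands.  This layout lets a test re-draw
    the copy-count prefix of the stream independently.
    """
    if not family_specs:
        raise ValueError("family_specs must not be empty")
    if n_genomes < 1:
        raise ValueError("n_genomes must be >= 1")
    lengths = dict(MARKER_PROTEIN_LENGTHS)
    if marker_lengths:
        lengths.update(marker_lengths)
        if set(lengths) != set(MARKER_NAMES):
            raise ValueError(f"marker set must be exactly {MARKER_NAMES}")
        if protein_nt_length(lengths["recA"]) != L_RECA:
            raise ValueError("recA nucleotide length is fixed at 1,062 bp")
        if any(l <= 0 for l in lengths.values()):
            raise ValueError("marker lengths must be positive")

    rng = np.random.default_rng(seed)
    counts = np.array(
        [[int(rng.integers(lo, hi + 1))
          for (lo, hi) in (s.copies_per_genome_range for s in family_specs)]
         for _ in range(n_genomes)]
    )

    marker_seeds = marker_seed_sequences()
    if marker_lengths:
        # Re-derive seeds at the requested lengths from the same stream label.
        mrng = np.random.default_rng(_MARKER_SEED)
        marker_seeds = {name: _random_protein(mrng, lengths[name])
                        for name in MARKER_NAMES}

    genomes: list[SyntheticGenome] = []
    for g in range(n_genomes):
        genome_id = f"G{g:03d}"
        entries: list[tuple[str, str, str, str]] = []  # gene_id, residues, source, product
        for f, spec in enumerate(family_specs):
            for c in range(counts[g, f]):
                residues = mutate_sequence(spec.seed_sequence, spec.divergence, rng)
                entries.append((f"{spec.family_id}_{c + 1}", residues,
                                spec.family_id, _PRODUCTS.get(spec.category, "")))
        for name in MARKER_NAMES:
            residues = mutate_sequence(marker_seeds[name], _MARKER_DIVERGENCE, rng)
            entries.append((name, residues, f"marker:{name}",
                            f"single-copy marker {name}"))
        order = rng.permutation(len(entries))
        strands = rng.choice(["+", "-"], size=len(entries))

        genes: list[GeneModel] = []
        proteome: list[ProteinSeq] = []
        gene_source: dict[str, str] = {}
        pos = 0
        for k, idx in enumerate(order):
            gene_id, residues, source, product = entries[idx]
            nt = protein_nt_length(len(residues))
            genes.append(GeneModel(gene_id, genome_id, pos, pos + nt,
                                   str(strands[k]), product))
            proteome.append(ProteinSeq(f"{genome_id}|{gene_id}", residues,
                                       origin=genome_id))
            gene_source[gene_id] = source
            pos += nt + _INTERGENIC_BP
        genomes.append(SyntheticGenome(
            genome_id=genome_id,
            size_mb=pos / 1e6,
            genes=genes,
            proteome=proteome,
            single_copy_genes={name: name for name in MARKER_NAMES},
            family_copies={spec.family_id: int(counts[g, f])
                           for f, spec in enumerate(family_specs)},
            gene_source=gene_source,
        ))
    return genomes


def default_orf_length_dist(rng: np.random.Generator, size: int) -> np.ndarray:
    """Log-normal fragment lengths, median ~180 aa, floored at 30 aa.

    The source data gives no ORF length distribution; this default is a
    free configuration choice in the regime of environmental shotgun
    peptide predictions.
    """
    lengths = rng.lognormal(mean=np.log(180.0), sigma=0.4, size=size)
    return np.maximum(lengths.astype(int), 30)


def genome_equivalent_weights(genomes: Sequence[SyntheticGenome],
                              composition_weights: Sequence[float]) -> np.ndarray:
    """Convert ORF-share weights into genome-equivalent weights.

    A genome's share of sampled ORFs is proportional to (copies x genome
    length), so copies are proportional to weight / length.
    """
    w = np.asarray(composition_weights, dtype=float)
    lengths = np.array([g.total_nt_length for g in genomes], dtype=float)
    eq = w / lengths
    return eq / eq.sum()


def orfs_for_genome_equivalents(genomes: Sequence[SyntheticGenome],
                                composition_weights: Sequence[float],
                                target_equivalents: float) -> int:
    """Number of ORFs that makes the expected genome-equivalent estimate
    equal ``target_equivalents`` for this genome mix."""
    w = np.asarray(composition_weights, dtype=float)
    lengths = np.array([g.total_nt_length for g in genomes], dtype=float)
    per_orf = L_RECA * float((w / lengths).sum())
    return int(round(target_equivalents / per_orf))


def generate_site_sample(genomes: Sequence[SyntheticGenome],
                         composition_weights: Sequence[float],
                         n_orfs: int,
                         orf_length_dist: Callable[[np.random.Generator, int], np.ndarray] | None = None,
                         seed: int = 0,
                         site_id: str = "site1",
                         habitat: str = "open sea") -> tuple[SiteSample, SyntheticTruth]:
    """Draw a fragmented metagenome sample from a weighted genome mix.

    Each ORF picks a source genome by ``composition_weights``, a source
    gene within it proportionally to nucleotide length, a fragment
    length from ``orf_length_dist`` (capped at the protein length), and
    a uniform start.  Fragments are contiguous amino-acid subsequences.
    """
    if n_orfs < 1:
        raise ValueError("n_orfs must be >= 1")
    w = np.asarray(composition_weights, dtype=float)
    if len(w) != len(genomes):
        raise ValueError("one weight per genome required")
    if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-8:
        raise ValueError("composition weights must be nonnegative and sum to 1")
    if orf_length_dist is None:
        orf_length_dist = default_orf_length_dist

    rng = np.random.default_rng(seed)
    genome_idx = rng.choice(len(genomes), size=n_orfs, p=w)
    lengths = np.asarray(orf_length_dist(rng, n_orfs))
    if np.any(lengths < 1):
        raise ValueError("ORF length distribution produced fragments < 1 residue")

    gene_probs = []
    for g in genomes:
        nt = np.array([gene.nt_length for gene in g.genes], dtype=float)
        gene_probs.append(nt / nt.sum())

    orfs: list[ProteinSeq] = []
    orf_sources: dict[str, tuple[str, str]] = {}
    for i in range(n_orfs):
        g = genomes[genome_idx[i]]
        j = int(rng.choice(len(g.genes), p=gene_probs[genome_idx[i]]))
        protein = g.proteome[j].residues
        frag_len = int(min(lengths[i], len(protein)))
        start = int(rng.integers(0, len(protein) - frag_len + 1))
        orf_id = f"{site_id}_ORF{i:05d}"
        orfs.append(ProteinSeq(orf_id, protein[start:start + frag_len],
                               origin=site_id))
        orf_sources[orf_id] = (g.gene_source[g.genes[j].gene_id], g.genome_id)

    eq_w = genome_equivalent_weights(genomes, w)
    families = {fid for g in genomes for fid in g.family_copies}
    site_frequencies = {
        fid: float(sum(eq_w[k] * genomes[k].family_copies.get(fid, 0)
                       for k in range(len(genomes))))
        for fid in sorted(families)
    }
    glengths = np.array([g.total_nt_length for g in genomes], dtype=float)
    expected_ge = n_orfs * L_RECA * float((w / glengths).sum())

    sample = SiteSample(site_id=site_id, habitat=habitat, orfs=orfs)
    truth = SyntheticTruth(site_frequencies=site_frequencies,
                           orf_sources=orf_sources,
                           expected_genome_equivalents=expected_ge)
    return sample, truth
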