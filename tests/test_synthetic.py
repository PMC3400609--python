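"""Synthetic community generator: determinism, stream contracts, sampling."""

import numpy as np
import pytest

from tbdtscan import (FamilySpec, generate_reference_set, generate_site_sample,
                      mutate_sequence)
from tbdtscan.records import protein_nt_length
from tbdtscan.synthetic import (L_RECA, MARKER_NAMES, MARKER_PROTEIN_LENGTHS,
                                default_family_specs,
                                genome_equivalent_weights,
                                orfs_for_genome_equivalents)

from conftest import random_protein


def _one_family(rng, copies=(2, 2), divergence=0.0):
    return [FamilySpec("FAM", "I_DOM", random_protein(rng, 60), copies,
                       divergence)]


class TestMutateSequence:
    def test_rate_zero_is_identity(self, rng):
        seq = random_protein(rng, 100)
        assert mutate_sequence(seq, 0.0, 1) == seq

    def test_rate_one_changes_every_position(self, rng):
        seq = random_protein(rng, 200)
        mutated = mutate_sequence(seq, 1.0, 1)
        assert sum(a != b for a, b in zip(seq, mutated)) == len(seq)

    def test_mean_hamming_matches_binomial(self, rng):
        """100 replicates at rate 0.2 on length 500: mean Hamming distance
        within 3 s.e. of the binomial expectation 100."""
        seq = random_protein(rng, 500)
        n, rate = 500, 0.2
        dists = [sum(a != b for a, b in zip(seq, mutate_sequence(seq, rate, s)))
                 for s in range(100)]
        se_mean = np.sqrt(n * rate * (1 - rate)) / np.sqrt(100)
        assert abs(np.mean(dists) - n * rate) <= 3 * se_mean

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            mutate_sequence("", 0.1, 0)


class TestGenerateReferenceSet:
    def test_forced_copies_and_markers(self, rng):
        """One genome, one family at exactly 2 copies, divergence 0:
        proteome holds 2 identical family members plus the 6 markers."""
        genomes = generate_reference_set(_one_family(rng), 1, seed=3)
        g = genomes[0]
        assert len(g.proteome) == 2 + 6
        fam = [p.residues for p in g.proteome
               if g.gene_source[p.id.split("|")[1]] == "FAM"]
        assert len(fam) == 2 and fam[0] == fam[1]
        for marker in MARKER_NAMES:
            assert list(g.single_copy_genes).count(marker) == 1

    def test_same_seed_identical_output(self, rng):
        specs = default_family_specs()
        a = generate_reference_set(specs, 3, seed=9)
        b = generate_reference_set(specs, 3, seed=9)
        assert [[p.residues for p in g.proteome] for g in a] == \
               [[p.residues for p in g.proteome] for g in b]
        assert [[(x.start, x.end, x.strand) for x in g.genes] for g in a] == \
               [[(x.start, x.end, x.strand) for x in g.genes] for g in b]

    def test_copy_counts_match_stream_redraw(self, rng):
        """Per-genome copy counts across 20 genomes equal an independent
        re-draw of the documented prefix of the pseudo-random stream."""
        specs = [FamilySpec("FAM", "I_DOM", random_protein(rng, 60), (0, 5))]
        genomes = generate_reference_set(specs, 20, seed=77)
        redraw = np.random.default_rng(77)
        expected = [int(redraw.integers(0, 6)) for _ in range(20)]
        assert [g.family_copies["FAM"] for g in genomes] == expected

    def test_reca_length_pinned(self, rng):
        genomes = generate_reference_set(_one_family(rng), 1, seed=0)
        g = genomes[0]
        reca_gene = next(x for x in g.genes if x.gene_id == "recA")
        assert reca_gene.nt_length == L_RECA
        with pytest.raises(ValueError):
            generate_reference_set(_one_family(rng), 1,
                                   marker_lengths={**MARKER_PROTEIN_LENGTHS,
                                                   "recA": 100}, seed=0)

    def test_empty_specs_rejected(self):
        with pytest.raises(ValueError):
            generate_reference_set([], 1, seed=0)


class TestGenerateSiteSample:
    def test_single_genome_all_truth_entries_name_it(self, rng):
        genomes = generate_reference_set(_one_family(rng), 1, seed=5)
        sample, truth = generate_site_sample(genomes, [1.0], 100, seed=5)
        assert len(sample.orfs) == 100
        assert len(truth.orf_sources) == 100
        assert {gid for _, gid in truth.orf_sources.values()} == {"G000"}

    def test_even_composition_recovered(self, rng):
        """50/50 mix over two genomes at 10,000 ORFs: per-genome share
        within 3 binomial s.e. of 0.5."""
        genomes = generate_reference_set(_one_family(rng), 2, seed=6)
        _, truth = generate_site_sample(genomes, [0.5, 0.5], 10_000, seed=6)
        share = np.mean([gid == "G000" for _, gid in truth.orf_sources.values()])
        se = np.sqrt(0.25 / 10_000)
        assert abs(share - 0.5) <= 3 * se

    def test_full_length_distribution_returns_whole_proteins(self, rng):
        genomes = generate_reference_set(_one_family(rng), 1, seed=7)
        proteins = {p.residues for p in genomes[0].proteome}
        sample, _ = generate_site_sample(
            genomes, [1.0], 50,
            orf_length_dist=lambda r, size: np.full(size, 10_000), seed=7)
        assert all(orf.residues in proteins for orf in sample.orfs)

    def test_determinism_and_orf_conservation(self, rng):
        genomes = generate_reference_set(_one_family(rng), 2, seed=8)
        s1, t1 = generate_site_sample(genomes, [0.3, 0.7], 500, seed=11)
        s2, t2 = generate_site_sample(genomes, [0.3, 0.7], 500, seed=11)
        assert [o.residues for o in s1.orfs] == [o.residues for o in s2.orfs]
        assert t1.orf_sources == t2.orf_sources
        assert len(s1.orfs) == 500 and len(t1.orf_sources) == 500

    def test_bad_weights_rejected(self, rng):
        genomes = generate_reference_set(_one_family(rng), 2, seed=8)
        with pytest.raises(ValueError):
            generate_site_sample(genomes, [0.5, 0.6], 10, seed=0)
        with pytest.raises(ValueError):
            generate_site_sample(genomes, [0.5, 0.5], 10,
                                 orf_length_dist=lambda r, size: np.zeros(size, int),
                                 seed=0)

    def test_truth_frequency_weights_by_genome_equivalents(self, rng):
        """True copies per genome equivalent are composition weights
        converted to genome-copy weights (weight / genome length)."""
        specs = [FamilySpec("FAM", "I_DOM", random_protein(rng, 60), (0, 5))]
        genomes = generate_reference_set(specs, 3, seed=12)
        w = [0.2, 0.3, 0.5]
        _, truth = generate_site_sample(genomes, w, 10, seed=12)
        eq_w = genome_equivalent_weights(genomes, w)
        expected = float(sum(eq_w[i] * genomes[i].family_copies["FAM"]
                             for i in range(3)))
        assert truth.site_frequencies["FAM"] == pytest.approx(expected)


def test_default_specs_are_deterministic_and_complete(family_specs):
    again = default_family_specs()
    assert [s.seed_sequence for s in family_specs] == \
           [s.seed_sequence for s in again]
    categories = {s.category for s in family_specs}
    # Decoys are mandatory so the identification filter has true negatives.
    assert {"TBDT", "ABC", "PTS", "TRAP"} <= categories
    tbdt_groups = {s.group_label for s in family_specs if s.category == "TBDT"}
    assert tbdt_groups == {"I_DOM", "II_SiderophoreVitamin", "III_Heme",
                           "IV_Metal"}


def test_orfs_for_genome_equivalents_inverts_expectation(rng):
    genomes = generate_reference_set(_one_family(rng), 1, seed=13)
    n = orfs_for_genome_equivalents(genomes, [1.0], 200.0)
    _, truth = generate_site_sample(genomes, [1.0], n, seed=13)
    assert truth.expected_genome_equivalents == pytest.approx(200.0, rel=0.01)


def test_protein_nt_length_reca_identity():
    assert protein_nt_length(353) == 1062
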