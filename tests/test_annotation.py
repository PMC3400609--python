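"""Group propagation, taxonomy assignment and gene-context hints."""

import numpy as np
import pytest

from tbdtscan import (assign_taxonomy, context_hints, load_anchor_table,
                      load_context_rules, phylogroup_composition,
                      propagate_groups)
from tbdtscan.clustering import ClusterPartition
from tbdtscan.records import GeneModel, ProteinSeq
from tbdtscan.synthetic import mutate_sequence

from conftest import random_protein


def _partition(*clusters):
    return ClusterPartition([tuple(sorted(c)) for c in clusters],
                            evalue_cutoff=1e-40, similarity_cutoff=0.6)


@pytest.fixture(scope="module")
def anchors():
    return load_anchor_table()


class TestAnchorTable:
    def test_packaged_table_loads_and_validates(self, anchors):
        assert len(anchors) > 80
        by_id = {a.protein_id: a for a in anchors}
        # Characterized examples carry the expected groups and substrates.
        assert by_id["FecA"].group_label == "II_SiderophoreVitamin"
        assert "ferric-citrate" in by_id["FecA"].substrates
        assert by_id["RagA"].group_label == "I_DOM"
        assert by_id["SusC"].group_label == "I_DOM"
        assert by_id["BtuB"].group_label == "II_SiderophoreVitamin"
        assert by_id["HumA"].group_label == "III_Heme"
        assert by_id["NosA"].group_label == "IV_Metal"


class TestPropagateGroups:
    def test_fec_a_cluster_gets_siderophore_group(self, anchors):
        part = _partition({"FecA", "env1", "env2"}, {"env3"})
        result = propagate_groups(part, anchors)
        assert result.annotations[0].group_labels == {"II_SiderophoreVitamin"}
        assert result.annotations[0].status == "annotated"

    def test_raga_susc_cluster_gets_dom_group(self, anchors):
        part = _partition({"RagA", "SusC", "env1"})
        result = propagate_groups(part, anchors)
        assert result.annotations[0].group_labels == {"I_DOM"}

    def test_anchor_free_cluster_unknown(self, anchors):
        part = _partition({"envA", "envB"})
        result = propagate_groups(part, anchors)
        assert result.annotations[0].status == "unknown"
        assert result.annotations[0].group_labels == frozenset()

    def test_multi_label_cluster_allowed(self, anchors):
        part = _partition({"FecA", "HumA"})
        result = propagate_groups(part, anchors)
        assert result.annotations[0].group_labels == {
            "II_SiderophoreVitamin", "III_Heme"}

    def test_unresolved_anchors_reported_not_fatal(self, anchors):
        part = _partition({"env1"})
        result = propagate_groups(part, anchors)
        assert "FecA" in result.unresolved_anchor_ids

    def test_unknown_fractions_by_origin_sum_to_one(self, anchors):
        part = _partition({"FecA", "ref1", "env1"}, {"env2", "env3"})
        origins = {"FecA": "reference", "ref1": "reference",
                   "env1": "metagenome", "env2": "metagenome",
                   "env3": "metagenome"}
        result = propagate_groups(part, anchors, origins)
        # reference members all sit in the annotated cluster.
        assert result.unknown_fraction["reference"] == 0.0
        assert result.unknown_fraction["metagenome"] == pytest.approx(2 / 3)
        # unknown + annotated fractions are complementary by construction.
        for cls in ("reference", "metagenome"):
            assert 0.0 <= result.unknown_fraction[cls] <= 1.0

    def test_invariant_to_anchor_and_cluster_order(self, anchors):
        part1 = _partition({"FecA", "env1"}, {"HumA", "env2"})
        part2 = _partition({"HumA", "env2"}, {"FecA", "env1"})
        r1 = propagate_groups(part1, anchors)
        r2 = propagate_groups(part2, list(reversed(anchors)))
        labels1 = {frozenset(part1.clusters[a.cluster_id]): a.group_labels
                   for a in r1.annotations}
        labels2 = {frozenset(part2.clusters[a.cluster_id]): a.group_labels
                   for a in r2.annotations}
        assert labels1 == labels2

    def test_label_conservation(self, anchors):
        part = _partition({"FecA", "HumA", "NosA", "env"})
        result = propagate_groups(part, anchors)
        all_labels = set().union(*(a.group_labels for a in result.annotations))
        assert all_labels <= {a.group_label for a in anchors}


class TestAssignTaxonomy:
    def test_identical_sequence_assigned_its_phylogroup(self, rng, params):
        ref = ProteinSeq("ref1", random_protein(rng, 120))
        db = [(ref, "Gammaproteobacteria")]
        out = assign_taxonomy([ProteinSeq("e", ref.residues)], db, params)
        assert len(out) == 1 and out[0].phylogroup == "Gammaproteobacteria"

    def test_no_match_left_unassigned(self, rng, params):
        db = [(ProteinSeq("ref1", random_protein(rng, 120)), "CFB")]
        out = assign_taxonomy([ProteinSeq("e", random_protein(rng, 40))],
                              db, params)
        assert out == []

    def test_mixed_composition_recovered(self, rng, params):
        """A 70/30 mix of fragments from two phylogroups at divergence 0.1
        is recovered within 3 binomial s.e."""
        ref_g = random_protein(rng, 300)
        ref_c = random_protein(rng, 300)
        db = [(ProteinSeq("g", ref_g), "Gammaproteobacteria"),
              (ProteinSeq("c", ref_c), "CFB")]
        n = 300
        env = []
        labels = rng.random(n) < 0.7
        for i, from_g in enumerate(labels):
            src = ref_g if from_g else ref_c
            start = int(rng.integers(0, 150))
            frag = mutate_sequence(src[start:start + 150], 0.1, int(rng.integers(1e6)))
            env.append(ProteinSeq(f"e{i}", frag))
        out = assign_taxonomy(env, db, params)
        assert len(out) == n  # everything recruits at this divergence
        comp = phylogroup_composition(out)
        se = np.sqrt(0.7 * 0.3 / n)
        assert abs(comp["Gammaproteobacteria"] - labels.mean()) <= 3 * se


class TestContextHints:
    def _genes(self):
        return [
            GeneModel("tbdt1", "G1", 10_000, 12_400, "+",
                      "TonB-dependent receptor"),
            GeneModel("phy1", "G1", 13_000, 14_200, "-", "phytase"),
            GeneModel("cyn1", "G1", 4_000, 5_500, "+", "cyanophycinase"),
            GeneModel("far1", "G1", 40_000, 41_000, "+", "phytase"),  # too far
            GeneModel("oth1", "G2", 12_500, 13_000, "+", "phytase"),  # other genome
        ]

    def test_adjacent_phytase_yields_phytic_acid_hint(self):
        hints = context_hints(self._genes(), ["tbdt1"])
        assert any(h.predicted_substrate == "phytic acid"
                   and h.neighbor_gene_id == "phy1" for h in hints)

    def test_adjacent_cyanophycinase_yields_cyanophycin_hint(self):
        hints = context_hints(self._genes(), ["tbdt1"])
        assert any(h.predicted_substrate == "cyanophycin"
                   and h.neighbor_gene_id == "cyn1" for h in hints)

    def test_window_and_genome_boundaries_respected(self):
        hints = context_hints(self._genes(), ["tbdt1"])
        neighbors = {h.neighbor_gene_id for h in hints}
        assert "far1" not in neighbors  # beyond the 5 kb window
        assert "oth1" not in neighbors  # different genome

    def test_no_annotated_neighbors_no_hints(self):
        genes = [GeneModel("tbdt1", "G1", 0, 1200, "+", "TonB-dependent receptor"),
                 GeneModel("x", "G1", 2000, 3000, "+", "hypothetical protein")]
        assert context_hints(genes, ["tbdt1"]) == []

    def test_unknown_tbdt_id_rejected(self):
        with pytest.raises(ValueError):
            context_hints(self._genes(), ["nope"])

    def test_packaged_rules_cover_documented_keywords(self):
        rules = load_context_rules()
        assert rules["phytase"] == "phytic acid"
        assert rules["cyanophycinase"] == "cyanophycin"
        assert rules["cobalamin"] == "vitamin B12"
        assert rules["heme"] == "heme"
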