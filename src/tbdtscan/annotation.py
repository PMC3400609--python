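"""Substrate-group propagation, best-hit taxonomy and gene-context hints.

Clusters inherit substrate groups from *anchors* — experimentally
characterized TBDTs whose substrates are known.  Groups follow the
four-way classification used for marine TBDT families:

* I_DOM — dissolved organic matter (carbohydrates, digested proteins,
  organic acids, ...);
* II_SiderophoreVitamin — siderophores, vitamin B1/B12;
* III_Heme — heme, hemophores, iron(heme)-binding proteins;
* IV_Metal — nickel, cobalt, copper.

A cluster containing at least one anchor receives the union of its
anchors' labels (multi-label clusters are legitimate: siderophore and
thiamin transporters co-cluster); anchor-free clusters are reported as
``unknown``, and the unknown member fraction is split by origin
(reference vs metagenome), mirroring the headline statistic that a large
share of environmental TBDTs fall in clusters without characterized
members.

Gene-context hints mechanize a manual curation pattern: a TBDT gene
whose neighbor (within a window, strand-agnostic) is annotated with a
keyword such as "phytase" suggests the corresponding substrate.  The
rules are a plain editable keyword table; the hints are suggestions,
not biological claims.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .align import AlignmentParams, score_evalue
from .clustering import ClusterPartition
from .records import GeneModel, ProteinSeq

FUNCTION_GROUPS = ("I_DOM", "II_SiderophoreVitamin", "III_Heme", "IV_Metal")

#: Coarse taxon vocabulary used for best-hit taxonomy summaries.
PHYLOGROUPS = ("Gammaproteobacteria", "CFB", "Sphingomonadales",
               "other Alphaproteobacteria", "Cyanobacteria", "other")


@dataclass(frozen=True)
class AnchorRecord:
    """An experimentally characterized TBDT with known substrates."""

    protein_id: str
    substrates: tuple[str, ...]
    group_label: str

    def __post_init__(self) -> None:
        if self.group_label not in FUNCTION_GROUPS:
            raise ValueError(f"group label must be one of {FUNCTION_GROUPS}")


@dataclass
class ClusterAnnotation:
    """Substrate-group annotation of one cluster."""

    cluster_id: int
    group_labels: frozenset[str]
    anchor_ids: tuple[str, ...]

    @property
    def status(self) -> str:
        return "annotated" if self.anchor_ids else "unknown"


@dataclass(frozen=True)
class TaxonAssignment:
    """Best-hit taxonomy of one environmental sequence."""

    seq_id: str
    best_hit_id: str
    phylogroup: str
    evalue: float


@dataclass(frozen=True)
class ContextHint:
    """A substrate suggestion from a TBDT gene's genomic neighborhood."""

    tbdt_gene_id: str
    neighbor_gene_id: str
    distance_bp: int
    matched_rule: str
    predicted_substrate: str


def load_anchor_table(path: str | Path | None = None) -> list[AnchorRecord]:
    """Load anchors from TSV (protein_id, substrates, group).

    Without a path, the packaged anchor table of characterized marine
    TBDTs is used.  Substrates are semicolon-separated.
    """
    if path is None:
        ref = resources.files("tbdtscan.data") / "anchors.tsv"
        with ref.open() as fh:
            return _parse_anchors(fh)
    with open(path) as fh:
        return _parse_anchors(fh)


def _parse_anchors(fh) -> list[AnchorRecord]:
    reader = csv.DictReader(fh, delimiter="\t")
    return [AnchorRecord(row["protein_id"],
                         tuple(s.strip() for s in row["substrates"].split(";") if s.strip()),
                         row["group"])
            for row in reader]


@dataclass
class PropagationResult:
    annotations: list[ClusterAnnotation]
    unresolved_anchor_ids: list[str]
    #: origin class -> fraction of member sequences in unknown clusters
    unknown_fraction: dict[str, float]


def propagate_groups(partition: ClusterPartition,
                     anchors: Sequence[AnchorRecord],
                     origins: Mapping[str, str] | None = None) -> PropagationResult:
    """Label every anchor-containing cluster with its anchors' groups.

    Anchors whose protein id is not a cluster member are reported in
    ``unresolved_anchor_ids`` (not fatal).  When ``origins`` maps member
    ids to origin classes (e.g. "reference" / "metagenome"), the unknown
    member fraction is computed per class; otherwise a single "all"
    class is used.  Results are independent of anchor and cluster order.
    """
    member_cluster = partition.cluster_of()
    by_cluster: dict[int, list[AnchorRecord]] = {}
    unresolved = []
    for anchor in sorted(anchors, key=lambda a: a.protein_id):
        idx = member_cluster.get(anchor.protein_id)
        if idx is None:
            unresolved.append(anchor.protein_id)
        else:
            by_cluster.setdefault(idx, []).append(anchor)

    annotations = []
    for idx, members in enumerate(partition.clusters):
        cluster_anchors = by_cluster.get(idx, [])
        annotations.append(ClusterAnnotation(
            cluster_id=idx,
            group_labels=frozenset(l for a in cluster_anchors for l in [a.group_label]),
            anchor_ids=tuple(a.protein_id for a in cluster_anchors),
        ))

    totals: dict[str, int] = {}
    unknown: dict[str, int] = {}
    for idx, members in enumerate(partition.clusters):
        is_unknown = not annotations[idx].anchor_ids
        for m in members:
            cls = origins.get(m, "all") if origins is not None else "all"
            totals[cls] = totals.get(cls, 0) + 1
            if is_unknown:
                unknown[cls] = unknown.get(cls, 0) + 1
    fractions = {cls: unknown.get(cls, 0) / n for cls, n in totals.items()}
    return PropagationResult(annotations, unresolved, fractions)


def assign_taxonomy(env_seqs: Sequence[ProteinSeq],
                    reference_db: Sequence[tuple[ProteinSeq, str]],
                    params: AlignmentParams = AlignmentParams(),
                    evalue_cutoff: float = 1e-5) -> list[TaxonAssignment]:
    """Label each environmental sequence with its best hit's phylogroup.

    Sequences without a match at the cutoff are omitted (reported by
    absence).  ``reference_db`` pairs reference proteins with coarse
    phylogroup labels.
    """
    if not reference_db:
        raise ValueError("reference database must not be empty")
    out = []
    for seq in env_seqs:
        best = None
        for ref, group in reference_db:
            ev, bits = score_evalue(seq, ref, params)
            key = (ev, -bits, ref.id, group)
            if best is None or key < best:
                best = key
        ev, _negbits, ref_id, group = best
        if ev <= evalue_cutoff:
            out.append(TaxonAssignment(seq.id, ref_id, group, ev))
    return out


def phylogroup_composition(assignments: Iterable[TaxonAssignment]) -> dict[str, float]:
    """Fraction of assigned sequences per phylogroup."""
    counts: dict[str, int] = {}
    for a in assignments:
        counts[a.phylogroup] = counts.get(a.phylogroup, 0) + 1
    total = sum(counts.values())
    return {g: c / total for g, c in sorted(counts.items())} if total else {}


def load_context_rules(path: str | Path | None = None) -> dict[str, str]:
    """Keyword -> predicted substrate rules (packaged table by default)."""
    if path is None:
        ref = resources.files("tbdtscan.data") / "context_rules.tsv"
        with ref.open() as fh:
            return _parse_rules(fh)
    with open(path) as fh:
        return _parse_rules(fh)


def _parse_rules(fh) -> dict[str, str]:
    reader = csv.DictReader(fh, delimiter="\t")
    return {row["keyword"].lower(): row["substrate"] for row in reader}


def gene_distance(a: GeneModel, b: GeneModel) -> int:
    """Distance between nearest gene boundaries (0 if overlapping)."""
    return max(a.start, b.start) - min(a.end, b.end) if (
        a.end <= b.start or b.end <= a.start) else 0


def context_hints(genes: Sequence[GeneModel],
                  tbdt_ids: Sequence[str],
                  rules: Mapping[str, str] | None = None,
                  window_bp: int = 5000) -> list[ContextHint]:
    """Substrate hints from annotated neighbors of TBDT genes.

    For each TBDT gene, every other gene on the same genome whose
    nearest boundary lies within ``window_bp`` (strand-agnostic) and
    whose product annotation contains a rule keyword (case-insensitive)
    yields one hint per matching rule.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    if rules is None:
        rules = load_context_rules()
    by_id = {g.gene_id: g for g in genes}
    unknown = [t for t in tbdt_ids if t not in by_id]
    if unknown:
        raise ValueError(f"unknown TBDT gene ids: {unknown}")
    hints = []
    for tid in tbdt_ids:
        tgene = by_id[tid]
        for other in genes:
            if other.gene_id == tid or other.genome_id != tgene.genome_id:
                continue
            dist = gene_distance(tgene, other)
            if dist > window_bp:
                continue
            product = other.product.lower()
            for keyword, substrate in sorted(rules.items()):
                if keyword in product:
                    hints.append(ContextHint(tid, other.gene_id, dist,
                                             keyword, substrate))
    return hints
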