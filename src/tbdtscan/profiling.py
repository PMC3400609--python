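"""Hit normalization, site frequency statistics, genome census, correlations.

The central statistic reads as *copies per genome*.  Raw hit counts Ng
for a gene category are biased by gene length (longer genes recruit more
shotgun fragments), so they are length-normalized against the E. coli
K12 recA gene:

    Nn = (L_recA / Lx) * Ng,        L_recA = 1,062 bp,

where Lx is the mean nucleotide length of the category's genes
(arithmetic mean over cluster members, or over all genes of a multi-gene
transporter system).  The number of genomes sampled at a site — the
*genome equivalents* — is estimated as the mean of the six normalized
single-copy marker counts (recA, atpD, gyrB, dnaK, rpoB, tufA), and

    frequency = Nn / genome_equivalents

is the category's copies per genome equivalent.  The per-genome census
counts transporters per class and reports integer-rounded densities per
Mbp (round-half-up, matching the published bracket convention).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats

MARKER_SET = ("recA", "atpD", "gyrB", "dnaK", "rpoB", "tufA")


@dataclass(frozen=True)
class NormalizationParams:
    """Reference gene and marker set of the length normalization."""

    reference_gene: str = "recA"
    L_recA: float = 1062.0
    marker_set: tuple[str, ...] = MARKER_SET

    def __post_init__(self) -> None:
        if self.L_recA <= 0:
            raise ValueError("L_recA must be positive")
        if len(self.marker_set) != 6:
            raise ValueError("marker set must contain exactly six genes")


class MissingMarkerError(ValueError):
    """A site is missing one of the six single-copy markers."""


def normalize_hits(Ng: float, Lx: float,
                   params: NormalizationParams = NormalizationParams()) -> float:
    """Size-normalized hit count Nn = (L_recA / Lx) * Ng."""
    if Lx <= 0:
        raise ValueError("mean gene length Lx must be positive")
    if Ng < 0:
        raise ValueError("hit count Ng must be nonnegative")
    return params.L_recA / Lx * Ng


def genome_equivalents(marker_hits: Mapping[str, float],
                       marker_lengths: Mapping[str, float],
                       params: NormalizationParams = NormalizationParams()) -> float:
    """Mean normalized hit count of the six single-copy markers."""
    missing = [m for m in params.marker_set if m not in marker_hits
               or m not in marker_lengths]
    if missing:
        raise MissingMarkerError(f"missing markers: {missing}")
    return float(np.mean([normalize_hits(marker_hits[m], marker_lengths[m], params)
                          for m in params.marker_set]))


def site_frequency(Nn_category: float, equivalents: float) -> float:
    """Copies per genome equivalent: normalized hits over genome equivalents."""
    if equivalents <= 0:
        raise ValueError("genome equivalents must be positive")
    return Nn_category / equivalents


@dataclass
class SiteProfile:
    """Per-site normalized hit statistics for every gene category."""

    site_id: str
    habitat: str
    total_orfs: int
    ng: dict[str, int]                 # category -> raw hits
    lx: dict[str, float]               # category -> mean gene length (bp)
    marker_ng: dict[str, int]
    marker_lx: dict[str, float]
    params: NormalizationParams = field(default_factory=NormalizationParams)
    excluded: bool = False

    @property
    def nn(self) -> dict[str, float]:
        return {c: normalize_hits(self.ng[c], self.lx[c], self.params)
                for c in self.ng}

    @property
    def genome_equivalents(self) -> float:
        return genome_equivalents(self.marker_ng, self.marker_lx, self.params)

    @property
    def frequency(self) -> dict[str, float]:
        eq = self.genome_equivalents
        return {c: site_frequency(nn, eq) for c, nn in self.nn.items()}

    @property
    def orf_fraction(self) -> dict[str, float]:
        return {c: ng / self.total_orfs for c, ng in self.ng.items()}


def profile_site(site_id: str,
                 habitat: str,
                 total_orfs: int,
                 assignments: Mapping[str, str],
                 category_lengths: Mapping[str, float],
                 marker_lengths: Mapping[str, float],
                 params: NormalizationParams = NormalizationParams(),
                 excluded: bool = False) -> SiteProfile:
    """Build a site profile from census assignments.

    ``assignments`` maps ORF ids to the category (or marker) they were
    recruited to; ``category_lengths`` / ``marker_lengths`` give the mean
    nucleotide gene length per category and marker.
    """
    ng = {c: 0 for c in category_lengths}
    marker_ng = {m: 0 for m in params.marker_set}
    for label in assignments.values():
        if label in marker_ng:
            marker_ng[label] += 1
        elif label in ng:
            ng[label] += 1
    return SiteProfile(site_id, habitat, total_orfs, ng,
                       dict(category_lengths), marker_ng,
                       dict(marker_lengths), params, excluded)


def frequency_matrix(profiles: Sequence[SiteProfile],
                     include_excluded: bool = False) -> pd.DataFrame:
    """Site x category matrix of frequencies.

    Sites flagged as excluded (contaminant-style metadata) are honored
    and dropped unless ``include_excluded`` is set.
    """
    rows = {}
    for p in profiles:
        if p.excluded and not include_excluded:
            continue
        rows[p.site_id] = p.frequency
    return pd.DataFrame.from_dict(rows, orient="index").sort_index(axis=1)


def relative_to_cluster_max(matrix: pd.DataFrame) -> pd.DataFrame:
    """Scale each category column to its across-site maximum (heat-map view).

    Columns with maximum 0 stay 0.  The per-category maxima themselves
    are ``matrix.max(axis=0)``.
    """
    maxima = matrix.max(axis=0).replace(0.0, np.nan)
    return matrix.div(maxima, axis=1).fillna(0.0)


def aggregate_groups(matrix: pd.DataFrame,
                     group_of: Mapping[str, str]) -> pd.DataFrame:
    """Sum member-category frequencies into functional groups."""
    grouped = matrix.T.groupby([group_of.get(c, "unknown") for c in matrix.columns]).sum()
    return grouped.T


def round_half_up(x: float) -> int:
    """Round to nearest integer, halves away from zero-ward up."""
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class GenomeCensus:
    """Per-genome transporter counts and per-Mbp densities."""

    genome_id: str
    taxon: str
    size_mb: float
    counts: dict[str, int]

    def density(self, category: str) -> float:
        return self.counts[category] / self.size_mb

    def rounded_density(self, category: str) -> int:
        return round_half_up(self.density(category))


def genome_census(entries: Sequence[tuple[str, str, float, Mapping[str, int]]]) -> list[GenomeCensus]:
    """Build census records from (genome_id, taxon, size_mb, counts)."""
    out = []
    for genome_id, taxon, size_mb, counts in entries:
        if size_mb <= 0:
            raise ValueError(f"{genome_id}: genome size must be positive")
        out.append(GenomeCensus(genome_id, taxon, size_mb, dict(counts)))
    return out


def load_marine_census(path: str | Path | None = None) -> pd.DataFrame:
    """The packaged 39-genome marine transporter census table.

    Columns: organism, taxon, size_mb, total_orfs, tbdt, tbdt_density,
    abc, abc_density, pts, trap, trophic_strategy.  The *_density
    columns are the published integer per-Mbp values; they recompute
    exactly as round_half_up(count / size_mb).
    """
    if path is None:
        ref = resources.files("tbdtscan.data") / "marine_census.tsv"
        with ref.open() as fh:
            return pd.read_csv(fh, sep="\t")
    return pd.read_csv(path, sep="\t")


def recompute_densities(census: pd.DataFrame) -> pd.DataFrame:
    """Re-derive integer per-Mbp densities from counts and genome sizes."""
    out = census.copy()
    for cat in ("tbdt", "abc"):
        out[f"{cat}_density_exact"] = out[cat] / out["size_mb"]
        out[f"{cat}_density_recomputed"] = [
            round_half_up(v) for v in out[f"{cat}_density_exact"]
        ]
    return out


class SpearmanResult(tuple):
    """(rho, pvalue) with attribute access."""

    def __new__(cls, rho: float, pvalue: float):
        return super().__new__(cls, (rho, pvalue))

    @property
    def rho(self) -> float:
        return self[0]

    @property
    def pvalue(self) -> float:
        return self[1]


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> SpearmanResult:
    """Spearman rank correlation with average-rank tie handling.

    Equivalent to the Pearson correlation of mid-ranks.  The p-value
    (t approximation) is reported descriptively, never used as a gate.
    Constant input vectors leave the statistic undefined and raise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("input vectors must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman rho is undefined for a constant vector")
    res = scipy.stats.spearmanr(x, y)
    return SpearmanResult(float(res.statistic), float(res.pvalue))
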