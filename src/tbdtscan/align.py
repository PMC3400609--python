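"""Exact Smith-Waterman local alignment with BLAST-style E-values.

All pairwise protein searches in the pipeline (reciprocal verification,
the transporter census, the all-vs-all graph feeding the clustering) go
through :func:`local_align`.  The alignment itself is exact affine-gap
dynamic programming (Biopython's ``PairwiseAligner``); significance uses
the Karlin-Altschul formulation with fixed published ungapped constants,

    bit = (lambda * raw - ln K) / ln 2,     E = m * n * 2**(-bit),

which keeps the scores deterministic at desk scale.  No heuristic seeding
is performed: correctness is preferred over speed for the problem sizes
this package targets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from functools import lru_cache
from typing import Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .records import ProteinSeq, SequenceError, PROTEIN_ALPHABET

# Published ungapped Karlin-Altschul constants per substitution matrix.
_KA_CONSTANTS = {
    "BLOSUM62": (0.3176, 0.134),
    "BLOSUM50": (0.2318, 0.112),
}


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring parameters for local alignment and its E-value statistics.

    ``m`` and ``n`` are effective search-space sizes; when left as None
    the actual query/subject lengths are used.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    K: float | None = None
    lam: float | None = None
    m: int | None = None
    n: int | None = None

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        if self.K is None or self.lam is None:
            try:
                lam, K = _KA_CONSTANTS[self.matrix_name]
            except KeyError:
                raise ValueError(
                    f"no built-in Karlin-Altschul constants for {self.matrix_name!r}; "
                    "pass K and lam explicitly"
                ) from None
            object.__setattr__(self, "K", self.K if self.K is not None else K)
            object.__setattr__(self, "lam", self.lam if self.lam is not None else lam)
        if self.K <= 0 or self.lam <= 0:
            raise ValueError("K and lambda must be positive")


@dataclass(frozen=True)
class PairwiseMatch:
    """One local-alignment result in BLAST outfmt-6 terms."""

    query_id: str
    subject_id: str
    raw_score: float
    bit_score: float
    evalue: float
    pct_identity: float
    alignment_length: int


@lru_cache(maxsize=4)
def load_matrix(matrix_name: str = "BLOSUM62"):
    """Substitution matrix with the ambiguity code X scoring 0 vs everything."""
    mat = substitution_matrices.load(matrix_name)
    arr = np.array(mat)
    alphabet = mat.alphabet
    if "X" in alphabet:
        ix = alphabet.index("X")
        arr[ix, :] = 0.0
        arr[:, ix] = 0.0
        mat = substitution_matrices.Array(alphabet=alphabet, dims=2, data=arr)
    return mat


@lru_cache(maxsize=8)
def _aligner(matrix_name: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = load_matrix(matrix_name)
    # BLAST convention: a gap of length k costs open + k*extend, so the
    # first gap column scores -(open + extend).
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def bit_score(raw_score: float, params: AlignmentParams) -> float:
    """Karlin-Altschul normalized score in bits."""
    return (params.lam * raw_score - math.log(params.K)) / math.log(2.0)


def evalue_from_bits(bits: float, m: int, n: int) -> float:
    """Expected chance hits in an m x n search space: E = m*n*2^-bits."""
    # Guard against overflow for strongly negative bit scores on tiny inputs.
    log10_e = math.log10(m) + math.log10(n) - bits * math.log10(2.0)
    if log10_e > 300:
        return math.inf
    return 10.0 ** log10_e


def _check_seq(seq: ProteinSeq) -> None:
    bad = set(seq.residues) - PROTEIN_ALPHABET
    if bad:
        raise SequenceError(f"illegal residues {sorted(bad)} in {seq.id!r}")


def local_align_score(query: ProteinSeq, subject: ProteinSeq,
                      params: AlignmentParams = AlignmentParams()) -> float:
    """Optimal raw Smith-Waterman score only (fast path for large censuses)."""
    aligner = _aligner(params.matrix_name, params.gap_open, params.gap_extend)
    return float(aligner.score(query.residues, subject.residues))


def score_evalue(query: ProteinSeq, subject: ProteinSeq,
                 params: AlignmentParams = AlignmentParams()) -> tuple[float, float]:
    """(E-value, bit score) without traceback — the search fast path."""
    raw = local_align_score(query, subject, params)
    bits = bit_score(raw, params)
    m = params.m or len(query.residues)
    n = params.n or len(subject.residues)
    return evalue_from_bits(bits, m, n), bits


def local_align(query: ProteinSeq, subject: ProteinSeq,
                params: AlignmentParams = AlignmentParams()) -> PairwiseMatch:
    """Align two proteins and report score, E-value, identity and length.

    The optimal raw score comes from exact affine-gap DP; percent identity
    and alignment length are measured on one optimal traceback (identities
    divided by aligned columns, gap columns included, as BLAST reports).
    """
    _check_seq(query)
    _check_seq(subject)
    aligner = _aligner(params.matrix_name, params.gap_open, params.gap_extend)
    alignments = aligner.align(query.residues, subject.residues)
    raw = float(alignments.score)
    if raw <= 0 or len(query.residues) == 0:
        # No positive-scoring local alignment exists.
        bits = bit_score(0.0, params)
        m = params.m or len(query.residues)
        n = params.n or len(subject.residues)
        return PairwiseMatch(query.id, subject.id, 0.0, bits,
                             evalue_from_bits(bits, m, n), 0.0, 0)
    aln = alignments[0]
    counts = aln.counts()
    ncols = counts.identities + counts.mismatches + counts.gaps
    pct_id = 100.0 * counts.identities / ncols if ncols else 0.0
    bits = bit_score(raw, params)
    m = params.m or len(query.residues)
    n = params.n or len(subject.residues)
    return PairwiseMatch(query.id, subject.id, raw, bits,
                         evalue_from_bits(bits, m, n), pct_id, ncols)


def best_match(query: ProteinSeq, subjects: Sequence[ProteinSeq],
               params: AlignmentParams = AlignmentParams()) -> PairwiseMatch | None:
    """Best-scoring subject for one query.

    Ties on E-value break by higher bit score, then lexicographic subject
    id, so results are independent of database ordering.
    """
    if not subjects:
        return None
    best: PairwiseMatch | None = None
    for subj in subjects:
        match = local_align(query, subj, params)
        if best is None or (match.evalue, -match.bit_score, match.subject_id) < (
            best.evalue, -best.bit_score, best.subject_id
        ):
            best = match
    return best


def all_vs_all(seqs: Sequence[ProteinSeq],
               params: AlignmentParams = AlignmentParams()) -> list[PairwiseMatch]:
    """All ordered pairs including self-matches, as the clustering expects.

    Scores are symmetric for symmetric substitution matrices, so each
    unordered pair is aligned once and emitted in both directions.
    """
    matches: list[PairwiseMatch] = []
    for i, a in enumerate(seqs):
        for b in seqs[i:]:
            match = local_align(a, b, params)
            matches.append(match)
            if b.id != a.id:
                matches.append(replace(match, query_id=b.id, subject_id=a.id))
    return matches
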