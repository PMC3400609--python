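"""Position-specific scoring models for the plug and beta-barrel domains.

A TonB-dependent transporter is defined structurally by an N-terminal
plug domain and a C-terminal membrane-spanning beta-barrel.  Real
analyses detect the two with profile HMMs (Pfam PF00715 / PF00593); here
the same filter architecture runs on pluggable position-specific score
matrices (PSSMs): each model is a length-L table of per-residue log2-odds
scores, scored against every length-L window of a protein, and the best
window is reported as a hit if it passes the model's bit-score and
E-value thresholds.  An adapter to a real HMM backend only needs to emit
:class:`DomainHit` records.

PSSM scores are genuine log2 likelihood ratios of a position-specific
target distribution against the uniform background, so the tail bound
P(window score >= s) <= 2**(-s) holds under the background model and
E-values are conservative.

PSSM file format (tab-separated, documented here and parsed by
:meth:`DomainModel.from_tsv`)::

    # pssm model_id=plug score_threshold=25.0 evalue_threshold=1e-05
    pos A   C   D   ... Y
    0   1.2 -0.8 ...
    ...

The ambiguity code X always scores 0.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .records import AMINO_ACIDS, ProteinSeq

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
# X maps to an extra all-zero column.
_X_INDEX = len(AMINO_ACIDS)


@dataclass(frozen=True)
class DomainHit:
    """Best-window match of one domain model on one sequence."""

    seq_id: str
    model_id: str
    bit_score: float
    evalue: float
    envelope: tuple[int, int]  # 0-based half-open residue interval


@dataclass(frozen=True)
class DomainModel:
    """A PSSM domain model with acceptance thresholds.

    ``matrix`` has one row per model position and one column per amino
    acid (order ``ACDEFGHIKLMNPQRSTVWY``), in bits.
    """

    model_id: str
    matrix: np.ndarray
    score_threshold: float = 25.0
    evalue_threshold: float = 1e-5

    def __post_init__(self) -> None:
        mat = np.asarray(self.matrix, dtype=float)
        if mat.ndim != 2 or mat.shape[1] != len(AMINO_ACIDS):
            raise ValueError("PSSM must be (length x 20)")
        if not (np.isfinite(self.score_threshold) and np.isfinite(self.evalue_threshold)):
            raise ValueError("thresholds must be finite")
        object.__setattr__(self, "matrix", mat)

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        """Highest-scoring residue at each position."""
        return "".join(AMINO_ACIDS[i] for i in self.matrix.argmax(axis=1))

    @property
    def max_score(self) -> float:
        """Sum of per-column maxima (score of the consensus itself)."""
        return float(self.matrix.max(axis=1).sum())

    @classmethod
    def from_consensus(cls, model_id: str, consensus: str, match_prob: float = 0.7,
                       score_threshold: float = 25.0,
                       evalue_threshold: float = 1e-5) -> "DomainModel":
        """Build a log2-odds PSSM around a consensus sequence.

        The position-specific target distribution puts ``match_prob`` on
        the consensus residue and spreads the remainder uniformly over
        the other 19; the background is uniform (1/20).
        """
        if not 0 < match_prob < 1:
            raise ValueError("match_prob must be in (0, 1)")
        L = len(consensus)
        mat = np.full((L, len(AMINO_ACIDS)),
                      math.log2((1 - match_prob) / 19 * 20))
        for i, aa in enumerate(consensus):
            mat[i, _AA_INDEX[aa]] = math.log2(match_prob * 20)
        return cls(model_id, mat, score_threshold, evalue_threshold)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(
                f"# pssm model_id={self.model_id} "
                f"score_threshold={self.score_threshold} "
                f"evalue_threshold={self.evalue_threshold}\n"
            )
            fh.write("pos\t" + "\t".join(AMINO_ACIDS) + "\n")
            for i, row in enumerate(self.matrix):
                fh.write(f"{i}\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DomainModel":
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("# pssm"):
                raise ValueError(f"{path}: not a PSSM file")
            meta = dict(tok.split("=", 1) for tok in header.split()[2:])
            cols = fh.readline().split()
            if cols[0] != "pos" or "".join(cols[1:]) != AMINO_ACIDS:
                raise ValueError(f"{path}: unexpected column order")
            rows = [list(map(float, line.split()[1:])) for line in fh if line.strip()]
        return cls(meta["model_id"], np.array(rows),
                   float(meta["score_threshold"]), float(meta["evalue_threshold"]))


def _encode(residues: str) -> np.ndarray:
    return np.fromiter((_AA_INDEX.get(aa, _X_INDEX) for aa in residues),
                       dtype=np.intp, count=len(residues))


def window_scores(seq: ProteinSeq, model: DomainModel) -> np.ndarray:
    """Bit score of every length-L window of ``seq`` under ``model``."""
    L = len(model)
    n = len(seq.residues)
    if n < L:
        return np.empty(0)
    enc = _encode(seq.residues)
    # Pad the matrix with a zero column for X.
    mat = np.hstack([model.matrix, np.zeros((L, 1))])
    nwin = n - L + 1
    scores = np.zeros(nwin)
    for j in range(L):
        scores += mat[j, enc[j:j + nwin]]
    return scores


def nominal_fpr(model: DomainModel, seq_len: int) -> float:
    """Union bound on the chance of a random hit at the score threshold."""
    nwin = max(seq_len - len(model) + 1, 0)
    return min(1.0, nwin * 2.0 ** (-model.score_threshold))


def profile_score(seq: ProteinSeq, model: DomainModel) -> DomainHit | None:
    """Best-window PSSM hit, or None if no window passes the thresholds.

    The E-value is the expected number of random windows at the observed
    bit score: n_windows * 2^-bits (conservative under the log-odds tail
    bound).  A sequence shorter than the model cannot hit.
    """
    scores = window_scores(seq, model)
    if scores.size == 0:
        return None
    best = int(scores.argmax())
    bits = float(scores[best])
    ev = scores.size * 2.0 ** (-bits)
    if bits < model.score_threshold or ev > model.evalue_threshold:
        return None
    return DomainHit(seq.id, model.model_id, bits, ev, (best, best + len(model)))


# --- default plug / barrel stand-in models -------------------------------
#
# Synthetic consensus sequences (fixed internal seed, regenerated
# identically on every import) standing in for the Pfam plug and barrel
# profiles.  Lengths are in the right regime for the two domains; the
# sequences themselves are synthetic and carry no biological meaning.

_PLUG_LEN = 60
_BARREL_LEN = 120
_CONSENSUS_SEED = 1062  # recA reference length, used as a fixed stream label


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def domain_consensus() -> tuple[str, str]:
    """The (plug, barrel) synthetic consensus strings."""
    rng = np.random.default_rng(_CONSENSUS_SEED)
    return _random_protein(rng, _PLUG_LEN), _random_protein(rng, _BARREL_LEN)


def default_models(score_threshold: float = 25.0,
                   evalue_threshold: float = 1e-5) -> dict[str, DomainModel]:
    """The packaged plug and barrel models keyed by model id."""
    plug_cons, barrel_cons = domain_consensus()
    return {
        "plug": DomainModel.from_consensus("plug", plug_cons,
                                           score_threshold=score_threshold,
                                           evalue_threshold=evalue_threshold),
        "barrel": DomainModel.from_consensus("barrel", barrel_cons,
                                             score_threshold=score_threshold,
                                             evalue_threshold=evalue_threshold),
    }
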