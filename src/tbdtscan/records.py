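"""Shared sequence and gene-model record types.

These light-weight containers are passed between every stage of the
pipeline: simulated or loaded proteomes, gene coordinates used both for
length normalization (``nt_length``) and for gene-context substrate hints.
"""

from __future__ import annotations

from dataclasses import dataclass

#: The 20 standard amino acids.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Residues accepted in protein sequences (standard alphabet plus the
#: ambiguity code X, which scores 0 against everything downstream).
PROTEIN_ALPHABET = frozenset(AMINO_ACIDS + "X")


class SequenceError(ValueError):
    """Raised for empty sequences or illegal residues."""


@dataclass(frozen=True)
class ProteinSeq:
    """A protein sequence with a provenance label.

    Parameters
    ----------
    id : str
        Unique identifier (for simulated data ``genome_id|gene_id`` or
        ``site_id_ORFnnnnn``).
    residues : str
        Amino-acid string over the 20-letter alphabet plus ``X``.
    origin : str, optional
        The genome or metagenome site the sequence came from.
    """

    id: str
    residues: str
    origin: str | None = None

    def __post_init__(self) -> None:
        if not self.residues:
            raise SequenceError(f"empty sequence for {self.id!r}")
        bad = set(self.residues) - PROTEIN_ALPHABET
        if bad:
            raise SequenceError(
                f"illegal residues {sorted(bad)} in sequence {self.id!r}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class GeneModel:
    """A protein-coding gene with 0-based half-open nucleotide coordinates.

    ``nt_length`` (base pairs) is the quantity entering the hit
    normalization Nn = L_recA/Lx * Ng; ``product`` is the free-text
    annotation scanned by the gene-context rules.
    """

    gene_id: str
    genome_id: str
    start: int
    end: int
    strand: str = "+"
    product: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"gene {self.gene_id}: end ({self.end}) must exceed start ({self.start})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")

    @property
    def nt_length(self) -> int:
        """Gene length in base pairs (end − start)."""
        return self.end - self.start


def protein_nt_length(protein_length: int) -> int:
    """Nucleotide length of a gene encoding ``protein_length`` residues.

    Defined as 3 * (protein_length + 1): coding residues plus the stop
    codon, so the normalization formula (in base pairs) is well defined
    for synthetic genes.  E. coli recA (353 aa) gives 1,062 bp, the
    reference length of the normalization.
    """
    return 3 * (protein_length + 1)
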