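"""Readers and writers for the standard formats the pipeline exchanges.

FASTA goes through Bio.SeqIO.  Gene models are serialized as GFF3
(0-based half-open in memory, 1-based inclusive on disk per the GFF3
convention).  Pairwise matches use BLAST outfmt-6-like tab-separated
columns.  Truth tables and cluster memberships are plain TSV.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .align import PairwiseMatch
from .clustering import ClusterPartition
from .records import GeneModel, ProteinSeq


def write_fasta(seqs: Iterable[ProteinSeq], path: str | Path) -> None:
    records = [SeqRecord(Seq(s.residues), id=s.id,
                         description=s.origin or "")
               for s in seqs]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path, origin: str | None = None) -> list[ProteinSeq]:
    return [ProteinSeq(rec.id, str(rec.seq),
                       origin=origin or (rec.description.split(maxsplit=1)[1]
                                         if " " in rec.description else None))
            for rec in SeqIO.parse(str(path), "fasta")]


def write_gff3(genes: Iterable[GeneModel], path: str | Path,
               source: str = "tbdtscan") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id}"
            if g.product:
                attrs += f";product={g.product}"
            fh.write("\t".join([
                g.genome_id, source, "CDS",
                str(g.start + 1), str(g.end),  # 1-based inclusive on disk
                ".", g.strand, "0", attrs,
            ]) + "\n")


def read_gff3(path: str | Path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            seqid, _source, _type, start, end, _score, strand, _phase, attrs = \
                line.rstrip("\n").split("\t")
            fields = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            genes.append(GeneModel(
                gene_id=fields.get("ID", f"{seqid}:{start}-{end}"),
                genome_id=seqid,
                start=int(start) - 1,
                end=int(end),
                strand=strand,
                product=fields.get("product", ""),
            ))
    return genes


_OUTFMT6_COLUMNS = ("query_id", "subject_id", "pct_identity", "alignment_length",
                    "evalue", "bit_score", "raw_score")


def write_matches(matches: Iterable[PairwiseMatch], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(_OUTFMT6_COLUMNS)
        for m in matches:
            writer.writerow([m.query_id, m.subject_id, f"{m.pct_identity:.2f}",
                             m.alignment_length, f"{m.evalue:.3g}",
                             f"{m.bit_score:.2f}", f"{m.raw_score:g}"])


def read_matches(path: str | Path) -> list[PairwiseMatch]:
    out = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            out.append(PairwiseMatch(
                query_id=row["query_id"], subject_id=row["subject_id"],
                raw_score=float(row["raw_score"]),
                bit_score=float(row["bit_score"]),
                evalue=float(row["evalue"]),
                pct_identity=float(row["pct_identity"]),
                alignment_length=int(row["alignment_length"]),
            ))
    return out


def write_clusters(partition: ClusterPartition, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["cluster_id", "seq_id"])
        for i, members in enumerate(partition.clusters):
            for m in members:
                writer.writerow([i, m])


def write_tsv(rows: Sequence[dict], path: str | Path) -> None:
    rows = list(rows)
    if not rows:
        Path(path).write_text("")
        return
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0]), delimiter="\t")
        writer.writeheader()
        writer.writerows(rows)


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
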