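"""Readers and writers for the pipeline's on-disk formats.

FASTQ is Phred+33 with ``/1``/``/2`` mate suffixes; the clustering
input format is interlaced FASTA (mates alternating). Truth tables and
cluster tables are TSV.
"""

from __future__ import annotations

import os
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .simulate import SimulatedGenome
from .types import ReadPair, ReadSet


def _pair_records(pair: ReadPair) -> list[SeqRecord]:
    recs = []
    for rid, seq, qual in pair.reads:
        rec = SeqRecord(Seq(seq), id=rid, description="")
        rec.letter_annotations["phred_quality"] = list(qual)
        recs.append(rec)
    return recs


def write_fastq(reads: ReadSet, path1: str, path2: str | None = None) -> None:
    """Write a read set as FASTQ; one file interleaved, or two split by mate."""
    if path2 is None:
        with open(path1, "w") as fh:
            for pair in reads.pairs:
                SeqIO.write(_pair_records(pair), fh, "fastq")
    else:
        with open(path1, "w") as f1, open(path2, "w") as f2:
            for pair in reads.pairs:
                r1, r2 = _pair_records(pair)
                SeqIO.write([r1], f1, "fastq")
                SeqIO.write([r2], f2, "fastq")


def read_fastq(path1: str, path2: str | None = None, species_tag: str | None = None) -> ReadSet:
    """Read FASTQ back into a :class:`ReadSet` (interleaved or split files)."""
    if path2 is None:
        records = list(SeqIO.parse(path1, "fastq"))
        it = zip(records[0::2], records[1::2])
    else:
        it = zip(SeqIO.parse(path1, "fastq"), SeqIO.parse(path2, "fastq"))
    pairs = []
    read_length = None
    for r1, r2 in it:
        stem = r1.id[:-2] if r1.id.endswith("/1") else r1.id
        pairs.append(
            ReadPair(
                stem,
                str(r1.seq),
                list(r1.letter_annotations["phred_quality"]),
                str(r2.seq),
                list(r2.letter_annotations["phred_quality"]),
            )
        )
        read_length = len(r1.seq)
    tag = species_tag or (pairs[0].id_stem[:4] if pairs else "NONE")
    return ReadSet(species_tag=tag, read_length=read_length or 0, pairs=pairs)


def write_interlaced_fasta(reads: ReadSet, path: str) -> None:
    """Interlaced FASTA: mates alternate, ids keep their /1 /2 suffixes."""
    with open(path, "w") as fh:
        for pair in reads.pairs:
            for rid, seq, _ in pair.reads:
                fh.write(f">{rid}\n{seq}\n")


def write_genome_fasta(genome: SimulatedGenome, path: str, width: int = 80) -> None:
    with open(path, "w") as fh:
        fh.write(f">{genome.species_name}\n")
        for i in range(0, len(genome.sequence), width):
            fh.write(genome.sequence[i : i + width] + "\n")


def read_fasta(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}


def truth_table_frame(genome: SimulatedGenome) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "family": r.family,
                "lineage": r.lineage,
                "copies": r.copies,
                "solo_ltrs": r.solo_ltrs,
                "bases": r.bases,
                "gp": r.genome_proportion,
            }
            for r in genome.truth_table
        ]
    )


def write_tsv(frame: pd.DataFrame, path: str, header_comment: str | None = None) -> None:
    """Write a TSV, optionally prefixed with '#'-comment provenance lines."""
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        frame.to_csv(fh, sep="\t", index=False)


def read_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
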