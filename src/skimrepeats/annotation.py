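"""Cluster annotation against a mini reference, and satellite detection.

Each cluster read is searched against lineage-labeled exemplar
sequences (nucleotide similarity, both strands); the winning lineage is
the one supported by the largest fraction of reads, with clusters below
the minimum support left as "unclassified". Tandem satellites are
detected on the cluster consensus as the smallest self-alignment period
and override mobile-element labels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import edlib

from .types import revcomp

__all__ = [
    "ReferenceEntry",
    "AnnotationResult",
    "classify_cluster",
    "detect_satellite",
    "build_mini_reference",
    "write_reference_fasta",
    "read_reference_fasta",
]

#: closed controlled vocabulary of lineage labels
LINEAGES = (
    "Ty1/copia-Angela",
    "Ty1/copia-Ale",
    "Ty1/copia-TAR",
    "Ty1/copia-Tork",
    "Ty1/copia-Ikeros",
    "Ty3/gypsy-Retand",
    "Ty3/gypsy-Tekay",
    "Ty3/gypsy-Athila",
    "Ty3/gypsy-Tat/Ogre",
    "Ty3/gypsy-CRM",
    "LINE",
    "Pararetrovirus",
    "DNA-transposon-CACTA",
    "DNA-transposon-hAT",
    "DNA-transposon-MuDR",
    "DNA-transposon-Helitron",
    "rDNA",
    "satellite",
)


@dataclass(frozen=True)
class ReferenceEntry:
    name: str
    lineage: str
    sequence: str

    def __post_init__(self) -> None:
        if self.lineage not in LINEAGES:
            raise ValueError(f"lineage {self.lineage!r} outside the controlled vocabulary")


@dataclass(frozen=True)
class AnnotationResult:
    cluster_id: str
    label: str
    support: float
    runner_up: Optional[str] = None
    runner_up_support: float = 0.0


def _read_hits_entry(read: str, entry_seq: str, min_identity: float) -> bool:
    """Infix (read-within-exemplar) match at the identity threshold."""
    max_dist = int((1 - min_identity) * len(read))
    for query in (read, revcomp(read)):
        res = edlib.align(query, entry_seq, mode="HW", task="distance", k=max_dist)
        if res["editDistance"] != -1:
            return True
    return False


def classify_cluster(
    cluster_id: str,
    reads: Sequence[str],
    reference: Sequence[ReferenceEntry],
    min_support: float = 0.10,
    min_identity: float = 0.80,
) -> AnnotationResult:
    """Assign a lineage label to a cluster of read sequences.

    Support of a lineage is the fraction of cluster reads hitting any
    of its exemplars; exact ties break toward the lexicographically
    smaller label (determinism over nuance). Label is "unclassified"
    when the best support is below ``min_support``.
    """
    if not reference:
        raise ValueError("empty annotation reference")
    if not reads:
        raise ValueError(f"cluster {cluster_id} has no reads")
    by_lineage: dict[str, list[str]] = {}
    for entry in reference:
        by_lineage.setdefault(entry.lineage, []).append(entry.sequence)

    support: dict[str, int] = {lin: 0 for lin in by_lineage}
    for read in reads:
        for lineage, seqs in by_lineage.items():
            if any(_read_hits_entry(read, s, min_identity) for s in seqs):
                support[lineage] += 1

    n = len(reads)
    ranked = sorted(support.items(), key=lambda kv: (-kv[1], kv[0]))
    best_label, best_hits = ranked[0]
    runner = ranked[1] if len(ranked) > 1 else (None, 0)
    best_support = best_hits / n
    label = best_label if best_support >= min_support else "unclassified"
    return AnnotationResult(
        cluster_id=cluster_id,
        label=label,
        support=best_support,
        runner_up=runner[0],
        runner_up_support=runner[1] / n,
    )


def detect_satellite(
    consensus: str,
    min_copies: int = 2,
    max_monomer: int = 50,
    min_identity: float = 0.80,
) -> Optional[int]:
    """Smallest tandem period of a consensus, or None.

    A period ``p`` is accepted when the consensus aligned to itself
    shifted by ``p`` reaches ``min_identity`` over at least
    ``min_copies * p`` bases.
    """
    n = len(consensus)
    if n < 2 * max_monomer:
        raise ValueError("consensus shorter than twice the maximum monomer length")
    for p in range(1, max_monomer + 1):
        overlap = n - p
        if overlap < min_copies * p:
            break
        matches = sum(
            1 for a, b in zip(consensus[:-p], consensus[p:]) if a == b and a != "N"
        )
        if matches / overlap >= min_identity:
            return p
    return None


def build_mini_reference(
    templates: dict,
    decoys: Sequence[tuple[str, str]] = (),
) -> list[ReferenceEntry]:
    """Reference exemplars from simulator templates plus decoy lineages.

    ``decoys`` are (lineage, sequence) tuples for lineages absent from
    the simulated genomes, so misclassification is possible in
    principle and the support statistic is meaningful.
    """
    entries = []
    for t in templates.values():
        # satellite exemplars are stored as a short tandem array so that
        # full-length reads can match at the nucleotide level
        seq = t.segments[0].sequence * 10 if t.is_satellite else t.full_sequence
        entries.append(ReferenceEntry(name=t.name, lineage=t.lineage, sequence=seq))
    for i, (lineage, seq) in enumerate(decoys, start=1):
        entries.append(ReferenceEntry(name=f"decoy{i}", lineage=lineage, sequence=seq))
    return entries


def default_decoys(seed: int = 99) -> list[tuple[str, str]]:
    import numpy as np

    from .simulate import random_sequence

    rng = np.random.default_rng(seed)
    return [
        ("Ty1/copia-TAR", random_sequence(250, rng)),
        ("Ty3/gypsy-Tat/Ogre", random_sequence(260, rng)),
        ("LINE", random_sequence(240, rng)),
        ("DNA-transposon-hAT", random_sequence(220, rng)),
    ]


def write_reference_fasta(entries: Sequence[ReferenceEntry], path: str) -> None:
    with open(path, "w") as fh:
        for e in entries:
            fh.write(f">{e.name} lineage={e.lineage}\n{e.sequence}\n")


def read_reference_fasta(path: str) -> list[ReferenceEntry]:
    entries = []
    name, lineage, chunks = None, None, []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if name is not None:
                    entries.append(ReferenceEntry(name, lineage, "".join(chunks)))
                fields = line[1:].split()
                name = fields[0]
                lineage = next(
                    f.split("=", 1)[1] for f in fields[1:] if f.startswith("lineage=")
                )
                chunks = []
            else:
                chunks.append(line)
    if name is not None:
        entries.append(ReferenceEntry(name, lineage, "".join(chunks)))
    return entries
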