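"""Pairwise read similarity and k-mer utilities.

The clustering criterion mirrors the comparative-clustering default:
two reads hit when their best strand-aware local alignment reaches 90%
identity over at least 55% of the shorter read. N bases never match
and the identity denominator is the number of aligned columns.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from Bio import Align

from .types import revcomp

__all__ = ["SimilarityParams", "SimilarityHit", "read_similarity", "canonical_kmers", "local_identity"]


@dataclass(frozen=True)
class SimilarityParams:
    """Thresholds of the read-similarity graph."""

    min_identity: float = 0.90
    min_overlap_fraction: float = 0.55
    kmer_seed_length: int = 13
    min_shared_kmers: int = 2
    cluster_size_threshold: float = 0.0001  # fraction of analyzed reads

    def __post_init__(self) -> None:
        for v in (self.min_identity, self.min_overlap_fraction):
            if not 0 < v <= 1:
                raise ValueError("similarity thresholds must be in (0, 1]")
        if self.kmer_seed_length < 1:
            raise ValueError("kmer_seed_length must be positive")


@dataclass(frozen=True)
class SimilarityHit:
    identity: float
    overlap_fraction: float
    strand: str  # "+" or "-"


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    return aligner

_ALIGNER = _make_aligner()


def local_identity(a: str, b: str) -> tuple[float, int, int]:
    """Best local alignment of two strings (one strand).

    Returns (identity over aligned columns, aligned columns, matches).
    N bases never match. Returns (0.0, 0, 0) when no positive-score
    alignment exists.
    """
    try:
        aln = _ALIGNER.align(a, b)[0]
    except (IndexError, ValueError):
        return 0.0, 0, 0
    matches = 0
    columns = 0
    blocks_a, blocks_b = aln.aligned
    prev_a = prev_b = None
    for (sa, ea), (sb, eb) in zip(blocks_a, blocks_b):
        if prev_a is not None:
            # gap columns between aligned blocks
            columns += max(sa - prev_a, sb - prev_b)
        for ca, cb in zip(a[sa:ea], b[sb:eb]):
            columns += 1
            if ca == cb and ca != "N":
                matches += 1
        prev_a, prev_b = ea, eb
    if columns == 0:
        return 0.0, 0, 0
    return matches / columns, columns, matches


def read_similarity(a: str, b: str, params: SimilarityParams) -> Optional[SimilarityHit]:
    """Strand-aware similarity decision for a read pair (symmetric)."""
    shorter = min(len(a), len(b))
    min_span = params.min_overlap_fraction * shorter
    best: Optional[SimilarityHit] = None
    for strand, bb in (("+", b), ("-", revcomp(b))):
        ident, columns, _ = local_identity(a, bb)
        if columns >= min_span and ident >= params.min_identity:
            hit = SimilarityHit(ident, columns / shorter, strand)
            if best is None or (hit.identity, hit.overlap_fraction) > (
                best.identity,
                best.overlap_fraction,
            ):
                best = hit
    return best


def canonical_kmers(seq: str, k: int) -> set[str]:
    """Set of canonical (lexicographic min of fwd/rc) k-mers, skipping N."""
    out = set()
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if "N" in kmer:
            continue
        rc = revcomp(kmer)
        out.add(min(kmer, rc))
    return out
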