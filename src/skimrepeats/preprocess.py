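"""Read preparation: quality filtering, organelle removal, down-sampling.

The chain mirrors a genome-skimming repeat study: pairs must pass a
full-length Phred-20 filter, reads matching plastid/mitochondrial
references are discarded, and the surviving pool is randomly
down-sampled so the analyzed reads represent a fixed genome proportion
(1.5% for individual clustering, 1.3% for the comparative run).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .align import canonical_kmers, local_identity
from .types import ReadSet, SpeciesProfile, revcomp

__all__ = [
    "PreprocessConfig",
    "quality_filter",
    "OrganelleIndex",
    "filter_organellar",
    "read_budget",
    "downsample_to_gp",
]


@dataclass(frozen=True)
class PreprocessConfig:
    quality_threshold: int = 20
    quality_mode: str = "all_bases"  # or "mean"
    organelle_min_identity: float = 0.90
    organelle_min_overlap: float = 0.80
    organelle_seed_length: int = 13
    target_genome_proportion: float = 0.015  # 0.013 for the comparative run
    seed: int = 0

    def __post_init__(self) -> None:
        if self.quality_threshold < 0:
            raise ValueError("quality threshold must be >= 0")
        for v in (
            self.organelle_min_identity,
            self.organelle_min_overlap,
            self.target_genome_proportion,
        ):
            if not 0 < v <= 1:
                raise ValueError("fractions must be in (0, 1]")
        if self.quality_mode not in ("all_bases", "mean"):
            raise ValueError("quality_mode must be 'all_bases' or 'mean'")


def quality_filter(reads: ReadSet, threshold: int = 20, mode: str = "all_bases") -> ReadSet:
    """Keep pairs whose mates both satisfy the quality criterion.

    ``all_bases`` (default, the strict full-length reading): every base
    of both mates must reach the threshold. ``mean``: mean quality of
    each mate must reach it. Retained pairs are unchanged.
    """
    kept = []
    for pair in reads.pairs:
        if not pair.qual1 or not pair.qual2:
            raise ValueError(f"{pair.id_stem}: missing qualities")
        if mode == "all_bases":
            ok = min(pair.qual1) >= threshold and min(pair.qual2) >= threshold
        elif mode == "mean":
            ok = (
                float(np.mean(pair.qual1)) >= threshold
                and float(np.mean(pair.qual2)) >= threshold
            )
        else:
            raise ValueError(f"unknown quality mode {mode!r}")
        if ok:
            kept.append(pair)
    return reads.subset(kept)


class OrganelleIndex:
    """k-mer-seeded matcher against plastid/mitochondrial references."""

    def __init__(self, references: dict[str, str], seed_length: int = 13):
        if not references:
            raise ValueError("organelle reference database is empty")
        self.references = dict(references)
        self.seed_length = seed_length
        self._index: dict[str, list[tuple[str, int]]] = {}
        for name, seq in self.references.items():
            k = seed_length
            for i in range(len(seq) - k + 1):
                kmer = seq[i : i + k]
                canon = min(kmer, revcomp(kmer))
                self._index.setdefault(canon, []).append((name, i))

    def matches(self, read: str, min_identity: float, min_overlap: float) -> bool:
        """True when the read locally matches any reference.

        Candidate windows come from shared canonical k-mer seeds; each
        is verified by local alignment requiring ``min_identity`` over
        ``min_overlap`` of the read length.
        """
        k = self.seed_length
        L = len(read)
        # quantize candidate window starts so one alignment covers a
        # whole diagonal band of seed hits
        windows: set[tuple[str, int]] = set()
        for i in range(0, L - k + 1):
            kmer = read[i : i + k]
            canon = min(kmer, revcomp(kmer))
            for name, pos in self._index.get(canon, ()):
                start = max(0, (pos - i) - L // 2)
                windows.add((name, (start // L) * L))
        for name, wstart in sorted(windows):
            ref = self.references[name]
            window = ref[wstart : wstart + 3 * L]
            for cand in (read, revcomp(read)):
                ident, columns, _ = local_identity(window, cand)
                if columns >= min_overlap * L and ident >= min_identity:
                    return True
        return False


def filter_organellar(
    reads: ReadSet,
    organelle_db: dict[str, str] | OrganelleIndex,
    min_identity: float = 0.90,
    min_overlap: float = 0.80,
) -> ReadSet:
    """Drop pairs where either mate matches an organelle reference.

    The survivors are considered to be of nuclear origin; retained
    pairs are unchanged.
    """
    index = (
        organelle_db
        if isinstance(organelle_db, OrganelleIndex)
        else OrganelleIndex(organelle_db)
    )
    kept = []
    for pair in reads.pairs:
        if index.matches(pair.seq1, min_identity, min_overlap) or index.matches(
            pair.seq2, min_identity, min_overlap
        ):
            continue
        kept.append(pair)
    return reads.subset(kept)


def read_budget(target_gp: float, c_value_bases: float, read_length: int) -> int:
    """Analyzed-read budget for a target genome proportion of 1C."""
    return round(target_gp * c_value_bases / read_length)


def downsample_to_gp(
    reads: ReadSet,
    profile: SpeciesProfile,
    target_gp: float,
    seed: int = 0,
) -> ReadSet:
    """Down-sample so the analyzed reads represent ``target_gp`` of 1C.

    The read budget is ``round(target_gp * 1C_bases / read_length)``,
    rounded down to an even count so mates stay together; pairs are
    sampled uniformly without replacement.
    """
    if not 0 < target_gp <= 1:
        raise ValueError("target_gp must be in (0, 1]")
    n_reads = read_budget(target_gp, profile.c_value_bases, reads.read_length)
    n_pairs = n_reads // 2
    if n_pairs > reads.n_pairs:
        raise ValueError(
            f"insufficient reads: need {n_pairs} pairs, have {reads.n_pairs}"
        )
    rng = np.random.default_rng(seed)
    chosen = sorted(rng.choice(reads.n_pairs, size=n_pairs, replace=False))
    return reads.subset([reads.pairs[i] for i in chosen])
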