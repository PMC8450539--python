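"""Tag-based solo-LTR quantification (the Rsf statistic).

Solo LTRs are single LTRs left behind when unequal homologous
recombination deletes an element's internal region and one LTR. The
read-level proxy works off two 30-nt junction tags: the last 30 bases
of the LTR (LTR-3' end) and the first 30 bases of the internal region
(5'-UTR), plus their 60-nt concatenation. Reads matching the LTR-3'
tag form the candidate set (Lx); the subset also matching the 5'-UTR
tag and confirmed against the combined tag spans the junction (LU).
Rsf = (Lx - LU) / LU; more solo LTRs mean more LTR-ends without a
junction, so larger Rsf.

Lx here counts *all* LTR-3'-tag hits (LU is a subset), so even a
genome of pure full-length elements has Rsf > 0: the 3' LTR of every
element ends in the tag but is followed by genome background, not the
5'-UTR.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional



from .simulate import SimulatedGenome
from .types import ReadSet, RepeatFamilyTemplate, revcomp

__all__ = [
    "JunctionTags",
    "RsfResult",
    "extract_tags",
    "rsf_count",
    "count_tag_sites",
    "expected_rsf",
    "solo_full_grid",
]

TAG_LENGTH = 30


@dataclass(frozen=True)
class JunctionTags:
    family: str
    ltr3_tag: str
    utr5_tag: str

    def __post_init__(self) -> None:
        if len(self.ltr3_tag) != TAG_LENGTH or len(self.utr5_tag) != TAG_LENGTH:
            raise ValueError("junction tags must be exactly 30 nt")

    @property
    def combined_tag(self) -> str:
        return self.ltr3_tag + self.utr5_tag


@dataclass(frozen=True)
class RsfResult:
    family: str
    species: str
    lx: int
    lu: int

    @property
    def rsf(self) -> Optional[float]:
        """(Lx - LU)/LU; None ("undefined") when LU = 0."""
        if self.lu == 0:
            return None
        return (self.lx - self.lu) / self.lu


def extract_tags(template: RepeatFamilyTemplate) -> JunctionTags:
    """30-nt tags flanking the LTR / internal (5'-UTR) boundary."""
    if not template.is_ltr_element:
        raise ValueError(f"{template.name} is not an LTR element")
    if len(template.ltr) < TAG_LENGTH or len(template.internal) < TAG_LENGTH:
        raise ValueError(
            f"{template.name}: LTR and internal segments must be >= {TAG_LENGTH} nt"
        )
    return JunctionTags(
        family=template.name,
        ltr3_tag=template.ltr[-TAG_LENGTH:],
        utr5_tag=template.internal[:TAG_LENGTH],
    )


def _read_contains_tag(read: str, tag: str, min_identity: float) -> bool:
    """True when the read fully contains the tag span (either strand).

    Matching slides the whole tag along the read and accepts at most
    ``floor((1 - min_identity) * len(tag))`` substitutions; a read must
    contain the complete tag span to count (no partial-tag credit, no
    end trimming), which keeps the read counter exactly consistent with
    the site-count expectation.
    """
    import numpy as np

    max_dist = int((1 - min_identity) * len(tag))
    read_arr = np.frombuffer(read.encode(), dtype=np.uint8)
    t = len(tag)
    if read_arr.size < t:
        return False
    windows = np.lib.stride_tricks.sliding_window_view(read_arr, t)
    for variant in (tag, revcomp(tag)):
        tag_arr = np.frombuffer(variant.encode(), dtype=np.uint8)
        if ((windows != tag_arr).sum(axis=1) <= max_dist).any():
            return True
    return False


def rsf_count(
    reads: ReadSet,
    tags: JunctionTags,
    min_identity: float = 0.93,
    species: str | None = None,
) -> RsfResult:
    """Count Lx and LU over individual reads and form Rsf.

    The cascade follows the five-step tag procedure: reads matching the
    LTR-3' tag are the candidate set (Lx); candidates matching the
    5'-UTR tag and then confirmed against the combined 60-nt tag are
    junction-spanning (LU).
    """
    lx = 0
    lu = 0
    for pair in reads.pairs:
        for _, seq, _ in pair.reads:
            if not _read_contains_tag(seq, tags.ltr3_tag, min_identity):
                continue
            lx += 1
            if _read_contains_tag(seq, tags.utr5_tag, min_identity) and _read_contains_tag(
                seq, tags.combined_tag, min_identity
            ):
                lu += 1
    return RsfResult(
        family=tags.family,
        species=species or reads.species_tag,
        lx=lx,
        lu=lu,
    )


def count_tag_sites(sequence: str, tag: str, max_mismatches: int = 0) -> int:
    """Genome positions matching a tag within a mismatch budget.

    Hamming distance over a sliding window, both strands (the
    simulator's divergence model is substitutions-only, so hamming is
    the right site metric). Exact matching is the default.
    """
    import numpy as np

    seq_arr = np.frombuffer(sequence.encode(), dtype=np.uint8)
    t = len(tag)
    if seq_arr.size < t:
        return 0
    windows = np.lib.stride_tricks.sliding_window_view(seq_arr, t)
    count = 0
    for variant in {tag, revcomp(tag)}:
        tag_arr = np.frombuffer(variant.encode(), dtype=np.uint8)
        mism = (windows != tag_arr).sum(axis=1)
        count += int((mism <= max_mismatches).sum())
    return count


def expected_rsf(
    genome: SimulatedGenome | str,
    tags: JunctionTags,
    read_length: int = 100,
    min_identity: float = 0.93,
) -> Optional[float]:
    """Analytic Rsf expectation from tag-site counts in a truth genome.

    For uniform read starts, the expected number of reads fully
    containing a tag of length t is proportional to (number of genome
    sites matching the tag at the counting tolerance) x
    (read_length - t + 1). The expectation is the ratio of those
    eligible-window totals, independent of coverage. Sites are counted
    at the same identity tolerance the read counter uses, so diverged
    copies enter both sides of the comparison consistently.
    """
    seq = genome.sequence if isinstance(genome, SimulatedGenome) else genome
    k30 = int((1 - min_identity) * TAG_LENGTH)
    k60 = int((1 - min_identity) * 2 * TAG_LENGTH)
    nx = count_tag_sites(seq, tags.ltr3_tag, k30) * (read_length - TAG_LENGTH + 1)
    nu = count_tag_sites(seq, tags.combined_tag, k60) * (
        read_length - 2 * TAG_LENGTH + 1
    )
    if nu == 0:
        return None
    return (nx - nu) / nu


def solo_full_grid(
    ratios: Sequence[float] = (0, 1, 2, 4, 7, 10),
    n_full: int = 1000,
    ltr_length: int = 100,
    internal_length: int = 100,
    base_size: int = 1_000_000,
    coverage: float = 0.1,
    read_length: int = 100,
    seed: int = 42,
    min_identity: float = 0.93,
) -> list[dict]:
    """Paired-design Rsf experiment over a grid of solo:full ratios.

    One base genome holds ``n_full`` full-length copies of a single LTR
    family; a separate solo-LTR block holds enough solo copies for the
    largest ratio. Reads are sampled once over the base genome and once
    over the full solo block, and each grid point reuses the base reads
    plus the block reads whose fragments fall inside its solo-prefix.
    Sharing the reads this way isolates the effect of adding solo
    copies: LU is constant across the grid and Lx can only grow, so the
    estimated Rsf responds to the solo fraction alone rather than to
    resampling noise. Divergence and sequencing error are zero so the
    analytic site-count expectation is exact.

    Returns one record per ratio with the estimated and expected Rsf.
    """
    from .simulate import (
        FamilySpec,
        GenomeSpec,
        QualityModel,
        build_genome,
        simulate_reads,
    )
    from .types import RepeatFamilyTemplate

    import numpy as np

    rng = np.random.default_rng(seed)
    from .simulate import random_sequence

    tpl = RepeatFamilyTemplate.ltr_element(
        "gridfam",
        "Ty1/copia-Angela",
        random_sequence(ltr_length, rng),
        random_sequence(internal_length, rng),
    )
    tags = extract_tags(tpl)
    max_solo = int(max(ratios) * n_full)

    base = build_genome(
        GenomeSpec(
            species_name="grid_base",
            target_size=base_size,
            families=(FamilySpec(tpl, n_full, solo_ltr_count=0, divergence=0.0),),
            seed=seed,
        )
    )
    # solo block: solo LTR copies on their own background, same density
    # of solo copies as of full elements in the base genome
    solo_spacing = max(2 * ltr_length, base_size // max(n_full, 1) // 4)
    block_size = max_solo * solo_spacing + 1000
    block = build_genome(
        GenomeSpec(
            species_name="grid_solo_block",
            target_size=block_size,
            families=(FamilySpec(tpl, 0, solo_ltr_count=max_solo, divergence=0.0),),
            seed=seed + 1,
        )
    )
    quiet = QualityModel(low_read_fraction=0.0)
    insert = 2 * read_length
    base_reads = simulate_reads(
        base, coverage, read_length, insert, error_rate=0.0,
        quality_model=quiet, seed=seed + 2, species_tag="GRID",
    )
    block_reads = simulate_reads(
        block, coverage, read_length, insert, error_rate=0.0,
        quality_model=quiet, seed=seed + 3, species_tag="GRID",
    )
    # fragment start of block pair i (same formula as the simulator)
    starts = np.random.default_rng(seed + 3).integers(
        0, len(block) - insert + 1, size=block_reads.n_pairs
    )
    # prefix length needed to include the first s solo copies
    solo_positions = [e for (_, e, _) in block.intervals]

    records = []
    for ratio in ratios:
        n_solo = int(ratio * n_full)
        prefix_end = solo_positions[n_solo - 1] if n_solo else 0
        keep = [
            p
            for p, s in zip(block_reads.pairs, starts)
            if s + insert <= prefix_end
        ]
        reads = base_reads.subset(base_reads.pairs + keep)
        est = rsf_count(reads, tags, min_identity=min_identity)
        truth_seq = base.sequence + block.sequence[:prefix_end]
        exp = expected_rsf(truth_seq, tags, read_length, min_identity)
        records.append(
            {
                "solo_full_ratio": ratio,
                "n_solo": n_solo,
                "n_reads": reads.n_reads,
                "lx": est.lx,
                "lu": est.lu,
                "rsf_estimate": est.rsf,
                "rsf_expected": exp,
            }
        )
    return records
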