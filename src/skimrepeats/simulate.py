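"""Synthetic genomes and genome-skimming reads.

Two congeneric toy genomes of unequal size share repeat families at
differing copy number; LTR retrotransposons carry distinct LTR/internal
segments plus solo-LTR copies left by unequal recombination; a
high-copy tandem satellite and organellar contamination complete the
statistical structure the downstream analysis assumes.

Repeat copies are placed at uniformly drawn non-overlapping positions
on a random single-copy background: the placement draws uniform cut
points over the background and interleaves the shuffled repeat units
with the resulting gaps, which is the uniform non-overlapping layout by
construction and keeps genome-proportion accounting exact at any repeat
occupancy. Divergence is substitutions-only so that identity thresholds
downstream are analytically predictable.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .types import DNA_ALPHABET, ReadPair, ReadSet, RepeatFamilyTemplate, revcomp

__all__ = [
    "QualityModel",
    "FamilySpec",
    "GenomeSpec",
    "TruthRecord",
    "SimulatedGenome",
    "build_genome",
    "simulate_reads",
    "spike_organelle",
    "random_sequence",
    "mutate_sequence",
    "demo_templates",
    "demo_genome_specs",
    "demo_profiles",
    "random_organelle_reference",
]

_BASES = np.frombuffer(DNA_ALPHABET.encode(), dtype=np.uint8)


def random_sequence(length: int, rng: np.random.Generator) -> str:
    """Uniform random DNA string of the given length."""
    return rng.choice(_BASES, size=length).tobytes().decode()


def mutate_sequence(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Apply substitutions at the given per-base rate (no indels).

    Substituted bases are always changed to a *different* base, so the
    realized divergence equals ``rate`` in expectation.
    """
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = rng.random(arr.size) < rate
    n = int(hit.sum())
    if n:
        # shift within the 4-letter alphabet by 1..3 positions
        idx = np.searchsorted(_BASES, arr[hit])
        arr[hit] = _BASES[(idx + rng.integers(1, 4, size=n)) % 4]
    return arr.tobytes().decode()


@dataclass(frozen=True)
class QualityModel:
    """Two-state per-base quality model.

    Most reads are uniformly high quality (``q_high``); a fraction
    ``low_read_fraction`` of reads carry error-prone stretches where
    each base independently drops to ``q_low`` with probability
    ``low_base_rate``. This is enough structure to exercise a
    full-length Phred-20 filter.
    """

    q_high: int = 38
    q_low: int = 12
    low_read_fraction: float = 0.10
    low_base_rate: float = 0.30

    def sample(self, length: int, rng: np.random.Generator) -> list[int]:
        if rng.random() < self.low_read_fraction:
            mask = rng.random(length) < self.low_base_rate
            return [self.q_low if m else self.q_high for m in mask]
        return [self.q_high] * length


@dataclass(frozen=True)
class FamilySpec:
    """How one repeat family enters a simulated genome.

    ``divergence`` is the per-copy substitution fraction relative to the
    template; ``array_monomers`` sets the tandem-array length (in
    monomers) of each placed satellite copy.
    """

    template: RepeatFamilyTemplate
    copy_number: int
    solo_ltr_count: int = 0
    divergence: float = 0.0
    array_monomers: int = 10

    def __post_init__(self) -> None:
        if self.copy_number < 0 or self.solo_ltr_count < 0:
            raise ValueError(f"{self.template.name}: negative copy counts")
        if self.solo_ltr_count and not self.template.is_ltr_element:
            raise ValueError(
                f"{self.template.name}: solo-LTR count requires an LTR element"
            )
        if not 0 <= self.divergence < 1:
            raise ValueError("divergence must be in [0, 1)")

    @property
    def unit_length(self) -> int:
        if self.template.is_satellite:
            return self.template.monomer_length * self.array_monomers
        return len(self.template)

    @property
    def total_bases(self) -> int:
        solo = self.solo_ltr_count * (
            len(self.template.ltr) if self.template.is_ltr_element else 0
        )
        return self.copy_number * self.unit_length + solo


@dataclass(frozen=True)
class GenomeSpec:
    species_name: str
    target_size: int
    families: tuple[FamilySpec, ...]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target_size <= 0:
            raise ValueError("target_size must be positive")

    @property
    def repeat_bases(self) -> int:
        return sum(f.total_bases for f in self.families)

    @property
    def single_copy_fraction(self) -> float:
        return 1.0 - self.repeat_bases / self.target_size


@dataclass(frozen=True)
class TruthRecord:
    family: str
    lineage: str
    copies: int
    solo_ltrs: int
    bases: int
    genome_proportion: float


@dataclass
class SimulatedGenome:
    """A simulated nuclear genome plus its exact repeat truth table."""

    species_name: str
    sequence: str
    truth_table: list[TruthRecord]
    # non-overlapping, sorted (start, end, family) intervals
    intervals: list[tuple[int, int, str]] = field(default_factory=list)
    seed: int = 0

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def single_copy_bases(self) -> int:
        return len(self.sequence) - sum(r.bases for r in self.truth_table)

    def truth_gp(self, family: str) -> float:
        for rec in self.truth_table:
            if rec.family == family:
                return rec.genome_proportion
        raise KeyError(family)


class CapacityError(ValueError):
    pass


def build_genome(spec: GenomeSpec) -> SimulatedGenome:
    """Realize a :class:`GenomeSpec` into a sequence plus truth table.

    Deterministic for a fixed ``spec.seed``. Raises
    :class:`CapacityError` naming the first family whose cumulative
    repeat bases exceed ``target_size``.
    """
    rng = np.random.default_rng(spec.seed)
    running = 0
    for fam in spec.families:
        running += fam.total_bases
        if running > spec.target_size:
            raise CapacityError(
                f"requested copies of family {fam.template.name!r} exceed "
                f"target_size ({running} > {spec.target_size})"
            )

    units: list[tuple[str, str]] = []  # (family name, realized sequence)
    for fam in spec.families:
        tpl = fam.template
        if tpl.is_satellite:
            base_unit = tpl.segments[0].sequence * fam.array_monomers
        else:
            base_unit = tpl.full_sequence
        for _ in range(fam.copy_number):
            units.append((tpl.name, mutate_sequence(base_unit, fam.divergence, rng)))
        for _ in range(fam.solo_ltr_count):
            units.append((tpl.name, mutate_sequence(tpl.ltr, fam.divergence, rng)))

    background = spec.target_size - sum(len(u[1]) for u in units)
    order = rng.permutation(len(units))
    cuts = np.sort(rng.integers(0, background + 1, size=len(units)))

    parts: list[str] = []
    intervals: list[tuple[int, int, str]] = []
    pos = 0
    prev_cut = 0
    for i, unit_idx in enumerate(order):
        gap = int(cuts[i]) - prev_cut
        prev_cut = int(cuts[i])
        if gap:
            parts.append(random_sequence(gap, rng))
            pos += gap
        name, seq = units[unit_idx]
        parts.append(seq)
        intervals.append((pos, pos + len(seq), name))
        pos += len(seq)
    tail = background - prev_cut
    if tail:
        parts.append(random_sequence(tail, rng))
        pos += tail
    sequence = "".join(parts)
    assert len(sequence) == spec.target_size

    truth = []
    for fam in spec.families:
        bases = fam.total_bases
        truth.append(
            TruthRecord(
                family=fam.template.name,
                lineage=fam.template.lineage,
                copies=fam.copy_number,
                solo_ltrs=fam.solo_ltr_count,
                bases=bases,
                genome_proportion=bases / spec.target_size,
            )
        )
    return SimulatedGenome(
        species_name=spec.species_name,
        sequence=sequence,
        truth_table=truth,
        intervals=intervals,
        seed=spec.seed,
    )


def _fragment_provenance(
    intervals: list[tuple[int, int, str]],
    starts: list[int],
    ends: list[int],
    frag_start: int,
    frag_end: int,
) -> str:
    """Majority-overlap provenance of a fragment; ties -> 'ambiguous'."""
    length = frag_end - frag_start
    lo = bisect.bisect_right(ends, frag_start)
    overlaps: dict[str, int] = {}
    i = lo
    while i < len(intervals) and starts[i] < frag_end:
        s, e, name = intervals[i]
        ov = min(e, frag_end) - max(s, frag_start)
        if ov > 0:
            overlaps[name] = overlaps.get(name, 0) + ov
        i += 1
    repeat_total = sum(overlaps.values())
    overlaps["single-copy"] = length - repeat_total
    best = max(overlaps.values())
    winners = [k for k, v in overlaps.items() if v == best]
    return winners[0] if len(winners) == 1 else "ambiguous"


def simulate_reads(
    genome: SimulatedGenome,
    coverage: float,
    read_length: int = 100,
    insert_size: int = 500,
    error_rate: float = 0.005,
    quality_model: QualityModel | None = None,
    seed: int = 0,
    species_tag: str | None = None,
) -> ReadSet:
    """Sample paired-end reads at the requested 1C coverage.

    The number of pairs is ``round(coverage * genome_length /
    (2 * read_length))``; fragment starts are uniform; the second mate
    is reverse-complemented. Provenance comes from majority overlap of
    the fragment with the truth intervals.
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    if insert_size < 2 * read_length:
        raise ValueError("insert_size must be at least 2 * read_length")
    g = len(genome)
    if g < insert_size:
        raise ValueError("genome shorter than insert size")
    qm = quality_model or QualityModel()
    tag = species_tag or (genome.species_name[:4].upper().ljust(4, "X"))
    rng = np.random.default_rng(seed)
    n_pairs = round(coverage * g / (2 * read_length))
    frag_starts = rng.integers(0, g - insert_size + 1, size=n_pairs)

    ivl_starts = [s for s, _, _ in genome.intervals]
    ivl_ends = [e for _, e, _ in genome.intervals]

    pairs = []
    for i, s in enumerate(frag_starts):
        s = int(s)
        frag = genome.sequence[s : s + insert_size]
        r1 = mutate_sequence(frag[:read_length], error_rate, rng)
        r2 = mutate_sequence(revcomp(frag[-read_length:]), error_rate, rng)
        q1 = qm.sample(read_length, rng)
        q2 = qm.sample(read_length, rng)
        prov = _fragment_provenance(
            genome.intervals, ivl_starts, ivl_ends, s, s + insert_size
        )
        pairs.append(
            ReadPair(f"{tag}_{i:07d}", r1, q1, r2, q2, provenance=prov, frag_start=s)
        )
    return ReadSet(species_tag=tag, read_length=read_length, pairs=pairs)


def spike_organelle(
    reads: ReadSet,
    organelle_reference: dict[str, str],
    fraction: float,
    seed: int = 0,
    insert_size: int = 500,
    error_rate: float = 0.005,
    quality_model: QualityModel | None = None,
) -> ReadSet:
    """Add organelle-derived pairs at ``fraction`` of the current total.

    The returned set is a copy of ``reads`` plus ``round(fraction *
    n_pairs)`` new pairs sampled from the organelle reference
    (plastid/mitochondrial sequences), provenance ``"organelle"``.
    """
    if not 0 <= fraction < 1:
        raise ValueError("fraction must be in [0, 1)")
    out = reads.copy()
    n_add = round(fraction * reads.n_pairs)
    if n_add == 0:
        return out
    qm = quality_model or QualityModel()
    rng = np.random.default_rng(seed)
    names = sorted(organelle_reference)
    lengths = np.array([len(organelle_reference[n]) for n in names], dtype=float)
    L = reads.read_length
    probs = lengths / lengths.sum()
    for i in range(n_add):
        src = names[rng.choice(len(names), p=probs)]
        ref = organelle_reference[src]
        s = int(rng.integers(0, len(ref) - insert_size + 1))
        frag = ref[s : s + insert_size]
        r1 = mutate_sequence(frag[:L], error_rate, rng)
        r2 = mutate_sequence(revcomp(frag[-L:]), error_rate, rng)
        out.pairs.append(
            ReadPair(
                f"{reads.species_tag}_org{i:06d}",
                r1,
                qm.sample(L, rng),
                r2,
                qm.sample(L, rng),
                provenance="organelle",
            )
        )
    return out


# ---------------------------------------------------------------------------
# Study fixture: two congeneric toy genomes with a ~1.9x size difference.
#
# The toy genomes are ~1/1000 the scale of the real ones, and the repeat
# templates are scaled down in proportion (elements of ~200-260 bp, a
# 26-bp satellite monomer in 10-monomer arrays) so that read-overlap
# connectivity in element coordinate space matches the regime of the
# real analysis.
# ---------------------------------------------------------------------------

_TEMPLATE_SEED = 20210703  # fixed: templates are part of the study conditions


def demo_templates(seed: int = _TEMPLATE_SEED) -> dict[str, RepeatFamilyTemplate]:
    """Repeat family templates shared by the two demo species."""
    rng = np.random.default_rng(seed)

    def ltr(name, lineage, ltr_len, int_len):
        return RepeatFamilyTemplate.ltr_element(
            name, lineage, random_sequence(ltr_len, rng), random_sequence(int_len, rng)
        )

    tpls = [
        ltr("Angela", "Ty1/copia-Angela", 60, 140),
        ltr("Ale", "Ty1/copia-Ale", 50, 110),
        ltr("Retand", "Ty3/gypsy-Retand", 60, 130),
        ltr("Tekay", "Ty3/gypsy-Tekay", 55, 120),
        ltr("Athila", "Ty3/gypsy-Athila", 60, 120),
        RepeatFamilyTemplate.simple(
            "CACTA", "DNA-transposon-CACTA", random_sequence(220, rng)
        ),
        RepeatFamilyTemplate.simple("45S", "rDNA", random_sequence(200, rng)),
        RepeatFamilyTemplate.satellite("HeloSAT", random_sequence(26, rng)),
    ]
    return {t.name: t for t in tpls}


def demo_genome_specs(
    templates: dict[str, RepeatFamilyTemplate] | None = None,
    seed: int = 42,
    divergence: float = 0.02,
) -> tuple[GenomeSpec, GenomeSpec]:
    """Two genome specs mirroring the studied species pair.

    The small genome ("HKOR"-like) is 1.0 Mb; the large ("HUMB"-like)
    is 1.9 Mb with roughly doubled copy numbers for the shared LTR and
    DNA-transposon families (equal genome proportion), a lower
    proportion of the Athila-like family, and a HeloSAT-like satellite
    at GP ~10% against ~1% in the small genome. The small genome
    carries a higher solo:full ratio for the two most abundant
    lineages, mimicking stronger unequal recombination.
    """
    t = templates or demo_templates()

    def fam(name, n, solo=0):
        return FamilySpec(t[name], n, solo_ltr_count=solo, divergence=divergence)

    small = GenomeSpec(
        species_name="H_koreana_toy",
        target_size=1_000_000,
        families=(
            fam("Angela", 308, solo=150),
            fam("Ale", 95),
            fam("Retand", 240, solo=100),
            fam("Tekay", 174),
            fam("Athila", 167),
            fam("CACTA", 91),
            fam("45S", 50),
            fam("HeloSAT", 38),
        ),
        seed=seed,
    )
    large = GenomeSpec(
        species_name="H_umbellata_toy",
        target_size=1_900_000,
        families=(
            fam("Angela", 585, solo=150),
            fam("Ale", 181),
            fam("Retand", 456, solo=100),
            fam("Tekay", 331),
            fam("Athila", 200),
            fam("CACTA", 173),
            fam("45S", 95),
            fam("HeloSAT", 731),
        ),
        seed=seed + 1,
    )
    return small, large


def matched_pair_specs(
    templates: dict[str, RepeatFamilyTemplate] | None = None,
    seed: int = 42,
    divergence: float = 0.02,
) -> tuple[GenomeSpec, GenomeSpec]:
    """Two-species fixture with every shared family at ~2x copy number.

    Unlike :func:`demo_genome_specs` (where the Athila-like family
    deviates), every family here scales with the 1.9x genome-size
    difference so its genome proportion is equal in both species —
    except the HeloSAT-like satellite, fixed at GP ~10% in the large
    genome versus ~1% in the small one. This is the proportion-recovery
    benchmark: at equal sampled genome proportion the comparative read
    scatter should have slope ~1.9.
    """
    t = templates or demo_templates()

    def fam(name, n, solo=0):
        return FamilySpec(t[name], n, solo_ltr_count=solo, divergence=divergence)

    small = GenomeSpec(
        species_name="matched_small",
        target_size=1_000_000,
        families=(
            fam("Angela", 308, solo=150),
            fam("Ale", 95),
            fam("Retand", 240, solo=100),
            fam("Tekay", 174),
            fam("Athila", 167),
            fam("CACTA", 91),
            fam("45S", 50),
            fam("HeloSAT", 38),
        ),
        seed=seed,
    )
    large = GenomeSpec(
        species_name="matched_large",
        target_size=1_900_000,
        families=(
            fam("Angela", 585, solo=285),
            fam("Ale", 181),
            fam("Retand", 456, solo=190),
            fam("Tekay", 331),
            fam("Athila", 317),
            fam("CACTA", 173),
            fam("45S", 95),
            fam("HeloSAT", 731),
        ),
        seed=seed + 1,
    )
    return small, large


def demo_profiles():
    from .types import SpeciesProfile

    return (
        SpeciesProfile("H_koreana_toy", "HKOR", 1.0),
        SpeciesProfile("H_umbellata_toy", "HUMB", 1.9),
    )


def random_organelle_reference(seed: int = 1234) -> dict[str, str]:
    """Synthetic plastid + mitochondrial reference sequences."""
    rng = np.random.default_rng(seed)
    return {
        "plastid": random_sequence(20_000, rng),
        "mitochondrion": random_sequence(30_000, rng),
    }
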