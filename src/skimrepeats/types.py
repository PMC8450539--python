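"""Core domain types shared across the pipeline.

The package models a genome-skimming repeat analysis: repeat family
templates are used both to simulate genomes and to annotate read
clusters; reads travel through the pipeline as :class:`ReadSet` objects
carrying per-base Phred qualities and (for synthetic data) provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

DNA_ALPHABET = "ACGT"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Segment:
    """One structural segment of a repeat template.

    role is one of ``LTR``, ``internal``, ``monomer``, ``body``.
    """

    role: str
    sequence: str

    VALID_ROLES = ("LTR", "internal", "monomer", "body")

    def __post_init__(self) -> None:
        if self.role not in self.VALID_ROLES:
            raise ValueError(f"unknown segment role {self.role!r}")
        if not self.sequence:
            raise ValueError("segment sequence must be non-empty")
        if set(self.sequence) - set(DNA_ALPHABET):
            raise ValueError("segment sequence must be over {A,C,G,T}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class RepeatFamilyTemplate:
    """A named repeat sequence model with a lineage label.

    LTR retrotransposons have segments (LTR, internal, LTR) with the two
    LTR strings identical before per-copy mutation; satellites have a
    single ``monomer`` segment; other repeats (DNA transposons, rDNA,
    LINEs) are a single ``body`` segment.
    """

    name: str
    lineage: str
    segments: tuple[Segment, ...]
    monomer_length: Optional[int] = None

    def __post_init__(self) -> None:
        roles = [s.role for s in self.segments]
        if roles == ["LTR", "internal", "LTR"]:
            if self.segments[0].sequence != self.segments[2].sequence:
                raise ValueError(
                    f"{self.name}: the two LTR segments must be identical"
                )
        elif roles == ["monomer"]:
            if self.monomer_length != len(self.segments[0]):
                raise ValueError(
                    f"{self.name}: monomer_length must equal monomer segment length"
                )
        elif roles == ["body"]:
            pass
        else:
            raise ValueError(f"{self.name}: unsupported segment layout {roles}")

    @property
    def is_ltr_element(self) -> bool:
        return [s.role for s in self.segments] == ["LTR", "internal", "LTR"]

    @property
    def is_satellite(self) -> bool:
        return [s.role for s in self.segments] == ["monomer"]

    @property
    def ltr(self) -> str:
        if not self.is_ltr_element:
            raise ValueError(f"{self.name} is not an LTR element")
        return self.segments[0].sequence

    @property
    def internal(self) -> str:
        if not self.is_ltr_element:
            raise ValueError(f"{self.name} is not an LTR element")
        return self.segments[1].sequence

    @property
    def full_sequence(self) -> str:
        return "".join(s.sequence for s in self.segments)

    def __len__(self) -> int:
        return len(self.full_sequence)

    @classmethod
    def ltr_element(cls, name: str, lineage: str, ltr: str, internal: str) -> "RepeatFamilyTemplate":
        return cls(name, lineage, (Segment("LTR", ltr), Segment("internal", internal), Segment("LTR", ltr)))

    @classmethod
    def satellite(cls, name: str, monomer: str, lineage: str = "satellite") -> "RepeatFamilyTemplate":
        return cls(name, lineage, (Segment("monomer", monomer),), monomer_length=len(monomer))

    @classmethod
    def simple(cls, name: str, lineage: str, body: str) -> "RepeatFamilyTemplate":
        return cls(name, lineage, (Segment("body", body),))


@dataclass
class ReadPair:
    """One paired-end fragment: two mates with per-base Phred qualities.

    ``id_stem`` is shared by the mates; on disk they become
    ``<id_stem>/1`` and ``<id_stem>/2``. ``provenance`` records the
    simulated source ("family name", "single-copy", "organelle" or
    "ambiguous") when known.
    """

    id_stem: str
    seq1: str
    qual1: list[int]
    seq2: str
    qual2: list[int]
    provenance: Optional[str] = None
    # fragment start on the source genome, when simulated
    frag_start: Optional[int] = None

    def __post_init__(self) -> None:
        if len(self.seq1) != len(self.qual1) or len(self.seq2) != len(self.qual2):
            raise ValueError(f"{self.id_stem}: sequence/quality length mismatch")

    @property
    def reads(self) -> list[tuple[str, str, list[int]]]:
        return [
            (self.id_stem + "/1", self.seq1, self.qual1),
            (self.id_stem + "/2", self.seq2, self.qual2),
        ]


@dataclass
class ReadSet:
    """Quality-bearing paired reads for one species (or a pooled run).

    ``species_tag`` is the four-letter prefix identity code used in the
    comparative clustering mode; every read id starts with it.
    """

    species_tag: str
    read_length: int
    pairs: list[ReadPair] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.species_tag) != 4:
            raise ValueError("species_tag must be a 4-character code")

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def n_reads(self) -> int:
        return 2 * len(self.pairs)

    def validate(self) -> None:
        for p in self.pairs:
            if len(p.seq1) != self.read_length or len(p.seq2) != self.read_length:
                raise ValueError(f"{p.id_stem}: read length != {self.read_length}")
            if not p.id_stem.startswith(self.species_tag):
                raise ValueError(f"{p.id_stem}: id does not carry tag {self.species_tag}")

    def subset(self, pairs: Iterable[ReadPair]) -> "ReadSet":
        return ReadSet(self.species_tag, self.read_length, list(pairs))

    def copy(self) -> "ReadSet":
        return ReadSet(self.species_tag, self.read_length, [replace(p) for p in self.pairs])


@dataclass(frozen=True)
class SpeciesProfile:
    """Per-species metadata: name, 4-letter code, and 1C value in Mb."""

    species_name: str
    four_letter_code: str
    c_value_1c_mb: float
    read_files: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.four_letter_code) != 4:
            raise ValueError("four_letter_code must have length 4")
        if self.c_value_1c_mb <= 0:
            raise ValueError("c_value_1C must be positive")

    @property
    def c_value_bases(self) -> float:
        return self.c_value_1c_mb * 1e6
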