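import numpy as np
import pytest

from skimrepeats.simulate import (
    FamilySpec,
    GenomeSpec,
    QualityModel,
    build_genome,
    demo_genome_specs,
    demo_profiles,
    demo_templates,
    random_organelle_reference,
    random_sequence,
    simulate_reads,
)
from skimrepeats.types import ReadPair, ReadSet


@pytest.fixture(scope="session")
def templates():
    return demo_templates()


@pytest.fixture(scope="session")
def demo_specs(templates):
    return demo_genome_specs(templates, seed=42)


@pytest.fixture(scope="session")
def small_genome(demo_specs):
    return build_genome(demo_specs[0])


@pytest.fixture(scope="session")
def large_genome(demo_specs):
    return build_genome(demo_specs[1])


@pytest.fixture(scope="session")
def profiles():
    return demo_profiles()


@pytest.fixture(scope="session")
def organelle_reference():
    return random_organelle_reference(seed=1234)


def make_pair(id_stem="TEST_0000001", seq1=None, seq2=None, q=38, length=100, seed=0):
    rng = np.random.default_rng(seed)
    s1 = seq1 if seq1 is not None else random_sequence(length, rng)
    s2 = seq2 if seq2 is not None else random_sequence(length, rng)
    return ReadPair(id_stem, s1, [q] * len(s1), s2, [q] * len(s2))


def make_readset(pairs, tag="TEST", read_length=100):
    return ReadSet(species_tag=tag, read_length=read_length, pairs=list(pairs))
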