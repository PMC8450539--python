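"""Similarity graph, connected-component clusters, mate-pair superclusters."""

import numpy as np
import pytest

from skimrepeats.align import SimilarityParams, canonical_kmers, read_similarity
from skimrepeats.clustering import (
    build_cluster_graph,
    cluster_reads,
    comparative_cluster,
    consensus_sequence,
    link_superclusters,
)
from skimrepeats.simulate import (
    FamilySpec,
    GenomeSpec,
    QualityModel,
    build_genome,
    random_sequence,
    simulate_reads,
)
from skimrepeats.types import ReadPair, RepeatFamilyTemplate, revcomp

from conftest import make_readset

PARAMS = SimilarityParams()


class TestReadSimilarity:
    def test_identical_reads_full_hit(self):
        rng = np.random.default_rng(1)
        r = random_sequence(100, rng)
        hit = read_similarity(r, r, PARAMS)
        assert hit is not None
        assert hit.identity == 1.0
        assert hit.overlap_fraction == 1.0

    def test_reverse_complement_hits(self):
        rng = np.random.default_rng(2)
        r = random_sequence(100, rng)
        hit = read_similarity(r, revcomp(r), PARAMS)
        assert hit is not None
        assert hit.strand == "-"

    @pytest.mark.parametrize("overlap,expect_hit", [(54, False), (56, True)])
    def test_overlap_threshold_at_55_percent(self, overlap, expect_hit):
        """100%-identical overlap below 55 nt of a 100-nt read is no hit."""
        rng = np.random.default_rng(3)
        shared = random_sequence(overlap, rng)
        a = "C" * (100 - overlap) + shared
        b = shared + "G" * (100 - overlap)
        hit = read_similarity(a, b, PARAMS)
        assert (hit is not None) == expect_hit

    def test_symmetric(self):
        rng = np.random.default_rng(4)
        a = random_sequence(100, rng)
        b = a[:70] + random_sequence(30, rng)
        ha = read_similarity(a, b, PARAMS)
        hb = read_similarity(b, a, PARAMS)
        assert (ha is None) == (hb is None)
        if ha:
            assert ha.identity == pytest.approx(hb.identity)


def _family_readset(n_copies=100, coverage=0.6, seed=5, divergence=0.0,
                    tag="TEST", with_background=True, array_monomers=10):
    rng = np.random.default_rng(seed)
    sat = RepeatFamilyTemplate.satellite("SAT", random_sequence(26, rng))
    spec = GenomeSpec(
        "toy",
        120_000,
        (FamilySpec(sat, n_copies, divergence=divergence, array_monomers=array_monomers),),
        seed=seed,
    )
    genome = build_genome(spec)
    return genome, simulate_reads(
        genome, coverage, error_rate=0.0, seed=seed + 1, species_tag=tag,
        quality_model=QualityModel(low_read_fraction=0.0),
    )


class TestClusterGraph:
    def test_min_cluster_size_arithmetic(self):
        # 0.01% of one million analyzed reads
        assert SimilarityParams().cluster_size_threshold * 1_000_000 == 100

    def test_satellite_forms_single_dominant_cluster(self):
        """Reads overlapping the satellite arrays by >= 55 nt end up in
        one above-threshold cluster."""
        genome, reads = _family_readset()
        result = cluster_reads([reads])
        min_overlap = 55
        insert = 500
        L = reads.read_length
        sat_ids = set()
        for p in reads.pairs:
            s = p.frag_start
            for rid, start in ((p.id_stem + "/1", s), (p.id_stem + "/2", s + insert - L)):
                ov = sum(
                    max(0, min(e, start + L) - max(b, start))
                    for b, e, fam in genome.intervals
                    if fam == "SAT"
                )
                if ov >= min_overlap:
                    sat_ids.add(rid)
        assert result.clusters, "no clusters formed"
        top = result.clusters[0]
        assert len(sat_ids & set(top.read_ids)) / len(sat_ids) >= 0.95

    def test_divergent_families_never_merge(self):
        """Reads drawn from two templates at mutual identity << 90%
        never land in the same cluster (windows sampled directly from
        mutated copies, so similarity alone decides)."""
        from skimrepeats.simulate import mutate_sequence

        rng = np.random.default_rng(6)
        records = []
        truth = {}
        for fam, lin in (("FA", "rDNA"), ("FB", "LINE")):
            template = random_sequence(400, rng)
            for c in range(30):
                copy = mutate_sequence(template, 0.03, rng)
                for w in range(3):
                    start = int(rng.integers(0, len(copy) - 100 + 1))
                    rid = f"TEST_{fam}_{c:02d}_{w}"
                    records.append((rid, copy[start : start + 100]))
                    truth[rid] = fam
        graph = build_cluster_graph(records, PARAMS)
        import networkx as nx

        for comp in nx.connected_components(graph):
            fams = {truth[r] for r in comp}
            assert len(fams) == 1, f"merged families {fams}"

    def test_input_order_invariance(self):
        _, reads = _family_readset(n_copies=30, coverage=0.3)
        records = [(rid, seq) for p in reads.pairs for rid, seq, _ in p.reads]
        g1 = build_cluster_graph(records)
        g2 = build_cluster_graph(list(reversed(records)))
        import networkx as nx

        c1 = sorted(tuple(sorted(c)) for c in nx.connected_components(g1))
        c2 = sorted(tuple(sorted(c)) for c in nx.connected_components(g2))
        assert c1 == c2

    def test_read_conservation_per_species(self):
        _, reads = _family_readset(n_copies=50, coverage=0.4)
        result = cluster_reads([reads])
        in_clusters = sum(c.size for c in result.clusters)
        assert in_clusters + len(result.singleton_pool) == reads.n_reads


class TestSuperclusters:
    def _two_region_pairs(self, n=8):
        """Mate1s from one region, mate2s from a distant one: similarity
        cannot join them, mate pairs must."""
        rng = np.random.default_rng(9)
        region1 = random_sequence(100, rng)
        region2 = random_sequence(100, rng)
        return [
            ReadPair(f"TEST_{i:04d}", region1, [38] * 100, region2, [38] * 100)
            for i in range(n)
        ]

    def test_mate_linked_clusters_join(self):
        reads = make_readset(self._two_region_pairs())
        result = cluster_reads([reads], min_spanning_pairs=5)
        assert len(result.clusters) == 2
        assert len(result.superclusters) == 1
        assert set(result.superclusters[0].cluster_ids) == {"CL1", "CL2"}

    def test_threshold_infinity_keeps_clusters_apart(self):
        reads = make_readset(self._two_region_pairs())
        result = cluster_reads([reads], min_spanning_pairs=10**9)
        assert len(result.superclusters) == len(result.clusters)

    def test_no_spanning_pairs_identity(self):
        _, reads = _family_readset(n_copies=40, coverage=0.4)
        result = cluster_reads([reads], min_spanning_pairs=10**9)
        assert all(len(sc.cluster_ids) == 1 for sc in result.superclusters)


class TestComparative:
    def test_duplicate_prefix_rejected(self):
        _, reads = _family_readset(n_copies=20, coverage=0.2, tag="AAAA")
        with pytest.raises(ValueError, match="prefix"):
            comparative_cluster([reads, reads])

    def test_species_specific_cluster_flagged(self):
        _, reads_a = _family_readset(n_copies=60, coverage=0.5, seed=20, tag="AAAA")
        rng = np.random.default_rng(21)
        other = RepeatFamilyTemplate.simple("OTH", "LINE", random_sequence(400, rng))
        spec_b = GenomeSpec("b", 120_000, (FamilySpec(other, 60),), seed=22)
        reads_b = simulate_reads(build_genome(spec_b), 0.5, error_rate=0.0, seed=23,
                                 species_tag="BBBB",
                                 quality_model=QualityModel(low_read_fraction=0.0))
        result = comparative_cluster([reads_a, reads_b])
        for cl in result.clusters:
            tags = set(cl.per_species_count)
            assert tags  # every cluster has at least one species
            # the two genomes share no family: nothing should be shared
            assert len(tags) == 1

    def test_per_species_counts_sum_to_size(self):
        _, reads_a = _family_readset(n_copies=60, coverage=0.4, seed=30, tag="AAAA")
        _, reads_b = _family_readset(n_copies=60, coverage=0.4, seed=30, tag="BBBB")
        result = comparative_cluster([reads_a, reads_b])
        for cl in result.clusters:
            assert sum(cl.per_species_count.values()) == cl.size


class TestBruteForceOracle:
    def test_prefilter_partition_equals_all_pairs(self):
        """k-mer-prefiltered clustering == brute-force all-pairs clustering."""
        import networkx as nx

        genome, reads = _family_readset(n_copies=40, coverage=0.4, seed=40)
        records = [(rid, seq) for p in reads.pairs for rid, seq, _ in p.reads]
        assert len(records) <= 500
        fast = build_cluster_graph(records, PARAMS)

        brute = nx.Graph()
        brute.add_nodes_from(rid for rid, _ in records)
        for i in range(len(records)):
            for j in range(i + 1, len(records)):
                (ra, sa), (rb, sb) = records[i], records[j]
                if read_similarity(sa, sb, PARAMS) is not None:
                    brute.add_edge(ra, rb)
        fast_parts = sorted(tuple(sorted(c)) for c in nx.connected_components(fast))
        brute_parts = sorted(tuple(sorted(c)) for c in nx.connected_components(brute))
        assert fast_parts == brute_parts


def test_consensus_recovers_template():
    rng = np.random.default_rng(50)
    template = random_sequence(100, rng)
    reads = [template]
    for i in range(20):
        mutated = list(template)
        for pos in rng.choice(100, size=3, replace=False):
            mutated[pos] = "ACGT"[(("ACGT".index(mutated[pos])) + 1) % 4]
        seq = "".join(mutated)
        reads.append(seq if i % 2 else revcomp(seq))
    cons = consensus_sequence(reads)
    assert sum(a == b for a, b in zip(cons, template)) >= 98


def test_louvain_refinement_splits_bridged_families():
    """Two dense read families chained by a thin bridge stay one
    connected component by default but split under the community-
    refinement flag."""
    import networkx as nx
    from skimrepeats.clustering import _split_component

    rng = np.random.default_rng(60)
    fam_a = random_sequence(100, rng)
    fam_b = random_sequence(100, rng)
    # two junction reads whose mutual overlap (80 nt) links them, each
    # anchored >= 55 nt in a different family
    bridge_a = fam_a[40:] + fam_b[:40]
    bridge_b = fam_a[60:] + fam_b[:60]
    records = (
        [(f"TEST_A{i}", fam_a) for i in range(10)]
        + [(f"TEST_B{i}", fam_b) for i in range(10)]
        + [("TEST_bridge0", bridge_a), ("TEST_bridge1", bridge_b)]
    )
    graph = build_cluster_graph(records)
    comps = list(nx.connected_components(graph))
    assert len(comps) == 1  # default behavior: one chained component
    parts = _split_component(graph, comps[0])
    assert len(parts) >= 2
    for part in parts:
        fams = {r[5] for r in part if not r.startswith("TEST_bridge")}
        assert len(fams) <= 1  # no split mixes the two families
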