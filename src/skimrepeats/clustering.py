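"""Graph-based clustering of reads into repeat clusters and superclusters.

Reads are vertices; edges are strand-aware similarity hits (90%
identity over 55% of the shorter read by default), pre-filtered by
shared canonical k-mers so the all-vs-all comparison stays tractable.
Clusters are connected components; components below the cluster-size
threshold (0.01% of analyzed reads by default) are pooled into the
low/single-copy fraction. Clusters joined by enough mate pairs form
superclusters, approximating repeat families split across structural
domains.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx

from .align import SimilarityParams, canonical_kmers, local_identity, read_similarity
from .types import ReadSet, revcomp

__all__ = [
    "Cluster",
    "Supercluster",
    "ClusteringResult",
    "build_cluster_graph",
    "cluster_reads",
    "comparative_cluster",
    "link_superclusters",
    "consensus_sequence",
]


@dataclass
class Cluster:
    id: str
    read_ids: list[str]
    per_species_count: dict[str, int] = field(default_factory=dict)
    consensus: Optional[str] = None
    annotation: str = "unclassified"
    supercluster: Optional[str] = None

    @property
    def size(self) -> int:
        return len(self.read_ids)

    def genome_proportion(self, species: str, analyzed_reads: int) -> float:
        """GP (fraction) of this cluster in one species' analyzed reads."""
        return self.per_species_count.get(species, 0) / analyzed_reads


@dataclass
class Supercluster:
    id: str
    cluster_ids: list[str]
    per_species_count: dict[str, int] = field(default_factory=dict)

    @property
    def size(self) -> int:
        return sum(self.per_species_count.values())


@dataclass
class ClusteringResult:
    clusters: list[Cluster]
    superclusters: list[Supercluster]
    singleton_pool: list[str]  # read ids in the low/single-copy fraction
    analyzed_reads: dict[str, int]  # per species-tag totals
    graph: Optional[nx.Graph] = None

    @property
    def total_analyzed(self) -> int:
        return sum(self.analyzed_reads.values())

    def cluster_by_id(self, cid: str) -> Cluster:
        for c in self.clusters:
            if c.id == cid:
                return c
        raise KeyError(cid)


def _candidate_pairs(seqs: dict[str, str], params: SimilarityParams):
    """Read-id pairs sharing >= min_shared_kmers canonical k-mers."""
    buckets: dict[str, list[str]] = defaultdict(list)
    for rid, seq in seqs.items():
        for kmer in canonical_kmers(seq, params.kmer_seed_length):
            buckets[kmer].append(rid)
    shared: Counter = Counter()
    for rids in buckets.values():
        if len(rids) < 2:
            continue
        for i in range(len(rids)):
            for j in range(i + 1, len(rids)):
                a, b = rids[i], rids[j]
                shared[(a, b) if a < b else (b, a)] += 1
    return [pair for pair, n in shared.items() if n >= params.min_shared_kmers]


def build_cluster_graph(
    reads: Sequence[tuple[str, str]],
    params: SimilarityParams | None = None,
) -> nx.Graph:
    """Similarity graph over (read_id, sequence) records.

    Vertices are all reads; edges carry identity/overlap/strand
    attributes of the accepted hit. The result is independent of the
    input order of the reads.
    """
    params = params or SimilarityParams()
    graph = nx.Graph()
    seqs = dict(reads)
    if len(seqs) != len(reads):
        raise ValueError("duplicate read ids in clustering input")
    graph.add_nodes_from(seqs)
    for a, b in sorted(_candidate_pairs(seqs, params)):
        hit = read_similarity(seqs[a], seqs[b], params)
        if hit is not None:
            graph.add_edge(a, b, identity=hit.identity, overlap=hit.overlap_fraction, strand=hit.strand)
    return graph


def _species_of(read_id: str) -> str:
    return read_id[:4]


def cluster_reads(
    readsets: Sequence[ReadSet],
    params: SimilarityParams | None = None,
    min_spanning_pairs: int = 5,
    keep_graph: bool = False,
    compute_consensus: bool = True,
    refine_communities: bool = False,
) -> ClusteringResult:
    """Cluster one or several read sets (pooled) into repeat clusters.

    Components are sorted into clusters by (size desc, smallest read id
    asc) and labeled CL1, CL2, ...; components smaller than
    ``cluster_size_threshold x total analyzed reads`` (and never
    smaller than 2 reads) go to the low/single-copy pool. Mate-linked
    clusters are joined into superclusters.

    ``refine_communities`` (off by default) splits connected components
    by Louvain community detection when the split shows strong
    modularity, which can separate distinct repeat families chained
    together by junction-spanning reads at insertion sites.
    """
    params = params or SimilarityParams()
    records: list[tuple[str, str]] = []
    mate_of: dict[str, str] = {}
    analyzed: dict[str, int] = {}
    for rs in readsets:
        analyzed[rs.species_tag] = analyzed.get(rs.species_tag, 0) + rs.n_reads
        for pair in rs.pairs:
            (id1, s1, _), (id2, s2, _) = pair.reads
            records.append((id1, s1))
            records.append((id2, s2))
            mate_of[id1] = id2
            mate_of[id2] = id1
    total = len(records)
    graph = build_cluster_graph(records, params)

    raw_components = list(nx.connected_components(graph))
    if refine_communities:
        refined = []
        for comp in raw_components:
            refined.extend(_split_component(graph, comp))
        raw_components = refined
    components = sorted(
        (sorted(comp) for comp in raw_components),
        key=lambda comp: (-len(comp), comp[0]),
    )
    min_size = max(2, params.cluster_size_threshold * total)
    clusters: list[Cluster] = []
    pool: list[str] = []
    seqs = dict(records)
    for comp in components:
        if len(comp) < min_size:
            pool.extend(comp)
            continue
        cl = Cluster(id=f"CL{len(clusters) + 1}", read_ids=comp)
        counts: Counter = Counter(_species_of(r) for r in comp)
        cl.per_species_count = dict(counts)
        if compute_consensus:
            cl.consensus = consensus_sequence([seqs[r] for r in comp], graph, comp)
        clusters.append(cl)

    superclusters = link_superclusters(clusters, mate_of, min_spanning_pairs)
    return ClusteringResult(
        clusters=clusters,
        superclusters=superclusters,
        singleton_pool=sorted(pool),
        analyzed_reads=analyzed,
        graph=graph if keep_graph else None,
    )


def _split_component(graph: nx.Graph, comp, min_modularity: float = 0.3):
    """Louvain split of one component, kept only when clearly modular."""
    if len(comp) < 4:
        return [comp]
    sub = graph.subgraph(comp)
    parts = nx.community.louvain_communities(sub, seed=0)
    if len(parts) < 2:
        return [comp]
    if nx.community.modularity(sub, parts) < min_modularity:
        return [comp]
    return [set(p) for p in parts]


def comparative_cluster(
    readsets: Sequence[ReadSet],
    params: SimilarityParams | None = None,
    min_spanning_pairs: int = 5,
) -> ClusteringResult:
    """Pooled multi-species clustering with per-species read counts.

    Every read id carries its species' four-letter prefix; duplicate
    prefixes are a configuration error.
    """
    tags = [rs.species_tag for rs in readsets]
    if len(set(tags)) != len(tags):
        raise ValueError("duplicate four-letter species prefixes")
    return cluster_reads(list(readsets), params, min_spanning_pairs)


def link_superclusters(
    clusters: Sequence[Cluster],
    mate_of: dict[str, str],
    min_spanning_pairs: int = 5,
) -> list[Supercluster]:
    """Join clusters connected by >= min_spanning_pairs mate pairs."""
    cluster_of: dict[str, str] = {}
    for cl in clusters:
        for rid in cl.read_ids:
            cluster_of[rid] = cl.id
    links: Counter = Counter()
    for rid, mid in mate_of.items():
        if rid >= mid:  # count each pair once
            continue
        ca, cb = cluster_of.get(rid), cluster_of.get(mid)
        if ca is None or cb is None or ca == cb:
            continue
        links[(ca, cb) if ca < cb else (cb, ca)] += 1

    sc_graph = nx.Graph()
    sc_graph.add_nodes_from(cl.id for cl in clusters)
    for (ca, cb), n in links.items():
        if n >= min_spanning_pairs:
            sc_graph.add_edge(ca, cb)

    by_id = {cl.id: cl for cl in clusters}
    comps = sorted(
        (sorted(c) for c in nx.connected_components(sc_graph)),
        key=lambda comp: (-sum(by_id[c].size for c in comp), comp[0]),
    )
    supers = []
    for i, comp in enumerate(comps, start=1):
        counts: Counter = Counter()
        for cid in comp:
            counts.update(by_id[cid].per_species_count)
        sc = Supercluster(id=f"SCL{i}", cluster_ids=comp, per_species_count=dict(counts))
        for cid in comp:
            by_id[cid].supercluster = sc.id
        supers.append(sc)
    return supers


def consensus_sequence(
    sequences: Sequence[str],
    graph: nx.Graph | None = None,
    read_ids: Sequence[str] | None = None,
    max_reads: int = 60,
) -> str:
    """Majority-vote consensus of a cluster.

    The seed read is the highest-degree vertex (ties: smallest id) when
    a graph is supplied, else the first read. Other reads are locally
    aligned to the seed on their best strand and vote per seed column.
    """
    if not sequences:
        raise ValueError("empty cluster")
    if graph is not None and read_ids is not None:
        order = sorted(read_ids, key=lambda r: (-graph.degree(r), r))
        id_to_seq = dict(zip(read_ids, sequences))
        seed = id_to_seq[order[0]]
        others = [id_to_seq[r] for r in order[1:max_reads]]
    else:
        seed = sequences[0]
        others = list(sequences[1:max_reads])

    votes = [Counter({base: 1}) for base in seed]
    for seq in others:
        best = None
        for cand in (seq, revcomp(seq)):
            ident, columns, matches = local_identity(seed, cand)
            if best is None or matches > best[2]:
                best = (cand, ident, matches)
        cand = best[0]
        try:
            aln = _seed_alignment(seed, cand)
        except ValueError:
            continue
        for (sa, ea), (sb, eb) in zip(*aln):
            for pos, cb in zip(range(sa, ea), cand[sb:eb]):
                votes[pos][cb] += 1
    return "".join(v.most_common(1)[0][0] for v in votes)


def _seed_alignment(seed: str, other: str):
    from .align import _ALIGNER

    alns = _ALIGNER.align(seed, other)
    try:
        aln = alns[0]
    except IndexError:
        raise ValueError("no alignment")
    return aln.aligned
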