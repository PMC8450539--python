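"""Stage orchestration: simulate -> preprocess -> cluster -> annotate ->
quantify -> rsf, plus the independent ancestral stage.

Each stage reads its inputs from and writes its artifacts to a run
directory, so stages can be re-run individually; every output TSV
carries a header comment with package version, seed and config hash.
Identical config + seed gives identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import __version__
from .align import SimilarityParams
from .annotation import (
    build_mini_reference,
    classify_cluster,
    default_decoys,
    detect_satellite,
    read_reference_fasta,
    write_reference_fasta,
)
from .ancestral import PhyloTree, branch_deltas, ml_ancestral_bm
from .clustering import Cluster, ClusteringResult, cluster_reads, comparative_cluster
from .preprocess import (
    OrganelleIndex,
    downsample_to_gp,
    filter_organellar,
    quality_filter,
)
from .quantify import (
    abundance_table,
    comparative_table,
    regression_table,
    scatter_slope,
)
from .seqio import (
    read_fastq,
    truth_table_frame,
    write_fastq,
    write_genome_fasta,
    write_tsv,
)
from .simulate import (
    QualityModel,
    build_genome,
    demo_genome_specs,
    demo_profiles,
    demo_templates,
    random_organelle_reference,
    simulate_reads,
    spike_organelle,
)
from .solo_ltr import extract_tags, rsf_count
from .types import SpeciesProfile

STAGES = ("simulate", "preprocess", "cluster", "annotate", "quantify", "rsf", "ancestral")

_ALLOWED_KEYS = {
    "seed",
    "outdir",
    "species",
    "simulate",
    "preprocess",
    "clustering",
    "annotation",
    "rsf",
    "ancestral",
}


@dataclass
class RunConfig:
    """Structured configuration for a full run (YAML round-trippable)."""

    seed: int = 42
    outdir: str = "results/run"
    species: list[dict] = field(default_factory=lambda: [
        {"name": "H_koreana_toy", "code": "HKOR", "c_value_mb": 1.0},
        {"name": "H_umbellata_toy", "code": "HUMB", "c_value_mb": 1.9},
    ])
    simulate: dict = field(default_factory=lambda: {
        "coverage": 0.15,
        "read_length": 100,
        "insert_size": 500,
        "error_rate": 0.005,
        "divergence": 0.02,
        "organelle_fraction": 0.05,
    })
    preprocess: dict = field(default_factory=lambda: {
        "quality_threshold": 20,
        "organelle_min_identity": 0.90,
        "organelle_min_overlap": 0.80,
        "individual_gp": 0.015,
        "comparative_gp": 0.013,
    })
    clustering: dict = field(default_factory=lambda: {
        "min_identity": 0.90,
        "min_overlap_fraction": 0.55,
        "kmer_seed_length": 13,
        "cluster_size_threshold": 0.0001,
        "min_spanning_pairs": 5,
    })
    annotation: dict = field(default_factory=lambda: {
        "min_support": 0.10,
        "min_identity": 0.80,
    })
    rsf: dict = field(default_factory=lambda: {
        "families": ["Angela", "Retand"],
        "min_identity": 0.93,
    })
    ancestral: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - _ALLOWED_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @property
    def config_hash(self) -> str:
        return hashlib.sha1(
            yaml.safe_dump(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]

    @property
    def profiles(self) -> list[SpeciesProfile]:
        return [
            SpeciesProfile(s["name"], s["code"], s["c_value_mb"])
            for s in self.species
        ]

    def header(self) -> str:
        return (
            f"skimrepeats {__version__}\nseed={self.seed}\n"
            f"config_hash={self.config_hash}"
        )


class MissingArtifactError(FileNotFoundError):
    pass


def _need(path: str, produced_by: str) -> str:
    if not os.path.exists(path):
        raise MissingArtifactError(
            f"missing artifact {path!r}: run the {produced_by!r} stage first"
        )
    return path


def _similarity_params(cfg: RunConfig) -> SimilarityParams:
    c = cfg.clustering
    return SimilarityParams(
        min_identity=c["min_identity"],
        min_overlap_fraction=c["min_overlap_fraction"],
        kmer_seed_length=c["kmer_seed_length"],
        cluster_size_threshold=c["cluster_size_threshold"],
    )


def stage_simulate(cfg: RunConfig, outdir: str) -> None:
    os.makedirs(outdir, exist_ok=True)
    templates = demo_templates()
    sim = cfg.simulate
    specs = demo_genome_specs(templates, seed=cfg.seed, divergence=sim["divergence"])
    organelle = random_organelle_reference(seed=cfg.seed + 1000)
    with open(os.path.join(outdir, "organelle_reference.fasta"), "w") as fh:
        for name, seq in organelle.items():
            fh.write(f">{name}\n{seq}\n")
    write_reference_fasta(
        build_mini_reference(templates, default_decoys(seed=cfg.seed + 2000)),
        os.path.join(outdir, "mini_reference.fasta"),
    )
    for spec, profile in zip(specs, cfg.profiles):
        genome = build_genome(spec)
        write_genome_fasta(genome, os.path.join(outdir, f"genome_{profile.four_letter_code}.fasta"))
        write_tsv(
            truth_table_frame(genome),
            os.path.join(outdir, f"truth_{profile.four_letter_code}.tsv"),
            cfg.header(),
        )
        reads = simulate_reads(
            genome,
            coverage=sim["coverage"],
            read_length=sim["read_length"],
            insert_size=sim["insert_size"],
            error_rate=sim["error_rate"],
            quality_model=QualityModel(),
            seed=cfg.seed + 10,
            species_tag=profile.four_letter_code,
        )
        reads = spike_organelle(
            reads,
            organelle,
            fraction=sim["organelle_fraction"],
            seed=cfg.seed + 20,
            insert_size=sim["insert_size"],
            error_rate=sim["error_rate"],
        )
        write_fastq(reads, os.path.join(outdir, f"raw_{profile.four_letter_code}.fastq"))


def stage_preprocess(cfg: RunConfig, outdir: str) -> dict:
    pp = cfg.preprocess
    organelle_path = _need(os.path.join(outdir, "organelle_reference.fasta"), "simulate")
    from .seqio import read_fasta

    index = OrganelleIndex(read_fasta(organelle_path))
    log = {}
    for profile in cfg.profiles:
        code = profile.four_letter_code
        raw = read_fastq(_need(os.path.join(outdir, f"raw_{code}.fastq"), "simulate"), species_tag=code)
        qpass = quality_filter(raw, pp["quality_threshold"])
        nuclear = filter_organellar(
            qpass, index, pp["organelle_min_identity"], pp["organelle_min_overlap"]
        )
        write_fastq(nuclear, os.path.join(outdir, f"filtered_{code}.fastq"))
        indiv = downsample_to_gp(nuclear, profile, pp["individual_gp"], seed=cfg.seed + 30)
        write_fastq(indiv, os.path.join(outdir, f"individual_{code}.fastq"))
        comp = downsample_to_gp(nuclear, profile, pp["comparative_gp"], seed=cfg.seed + 40)
        write_fastq(comp, os.path.join(outdir, f"comparative_{code}.fastq"))
        log[code] = {
            "raw_pairs": raw.n_pairs,
            "quality_pass_pairs": qpass.n_pairs,
            "nuclear_pairs": nuclear.n_pairs,
            "individual_reads": indiv.n_reads,
            "comparative_reads": comp.n_reads,
        }
    with open(os.path.join(outdir, "preprocess_log.json"), "w") as fh:
        json.dump(log, fh, indent=2)
    return log


def _result_frames(result: ClusteringResult) -> tuple[pd.DataFrame, pd.DataFrame]:
    rows = []
    for cl in result.clusters:
        row = {
            "cluster": cl.id,
            "size": cl.size,
            "supercluster": cl.supercluster,
            "consensus": cl.consensus,
        }
        for tag, n in sorted(cl.per_species_count.items()):
            row[f"reads_{tag}"] = n
        rows.append(row)
    members = [
        {"read_id": rid, "cluster": cl.id}
        for cl in result.clusters
        for rid in cl.read_ids
    ]
    members += [{"read_id": rid, "cluster": "low/single-copy"} for rid in result.singleton_pool]
    return pd.DataFrame(rows), pd.DataFrame(members)


def _run_cluster(readsets, cfg: RunConfig, outdir: str, label: str) -> ClusteringResult:
    params = _similarity_params(cfg)
    if len(readsets) > 1:
        result = comparative_cluster(
            readsets, params, cfg.clustering["min_spanning_pairs"]
        )
    else:
        result = cluster_reads(readsets, params, cfg.clustering["min_spanning_pairs"])
    table, members = _result_frames(result)
    write_tsv(table, os.path.join(outdir, f"clusters_{label}.tsv"), cfg.header())
    write_tsv(members, os.path.join(outdir, f"members_{label}.tsv"), cfg.header())
    with open(os.path.join(outdir, f"analyzed_{label}.json"), "w") as fh:
        json.dump(result.analyzed_reads, fh)
    return result


def load_clustering(outdir: str, label: str) -> ClusteringResult:
    """Rehydrate a clustering result from stage artifacts."""
    from .seqio import read_tsv

    table = read_tsv(_need(os.path.join(outdir, f"clusters_{label}.tsv"), "cluster"))
    members = read_tsv(_need(os.path.join(outdir, f"members_{label}.tsv"), "cluster"))
    with open(_need(os.path.join(outdir, f"analyzed_{label}.json"), "cluster")) as fh:
        analyzed = json.load(fh)
    by_cluster = members.groupby("cluster")["read_id"].apply(list).to_dict()
    clusters = []
    for _, row in table.iterrows():
        cl = Cluster(
            id=row["cluster"],
            read_ids=sorted(by_cluster.get(row["cluster"], [])),
            consensus=row["consensus"] if isinstance(row["consensus"], str) else None,
            supercluster=row["supercluster"] if isinstance(row["supercluster"], str) else None,
        )
        cl.per_species_count = {
            col[len("reads_"):]: int(row[col])
            for col in table.columns
            if col.startswith("reads_") and pd.notna(row[col])
        }
        clusters.append(cl)
    pool = sorted(by_cluster.get("low/single-copy", []))
    return ClusteringResult(
        clusters=clusters, superclusters=[], singleton_pool=pool, analyzed_reads=analyzed
    )


def stage_cluster(cfg: RunConfig, outdir: str) -> None:
    for profile in cfg.profiles:
        code = profile.four_letter_code
        rs = read_fastq(_need(os.path.join(outdir, f"individual_{code}.fastq"), "preprocess"), species_tag=code)
        _run_cluster([rs], cfg, outdir, f"individual_{code}")
    readsets = [
        read_fastq(
            _need(os.path.join(outdir, f"comparative_{p.four_letter_code}.fastq"), "preprocess"),
            species_tag=p.four_letter_code,
        )
        for p in cfg.profiles
    ]
    _run_cluster(readsets, cfg, outdir, "comparative")


def _annotate_result(result: ClusteringResult, reads_by_id: dict[str, str], reference, cfg: RunConfig):
    ann = cfg.annotation
    rows = []
    labels = {}
    for cl in result.clusters:
        res = classify_cluster(
            cl.id,
            [reads_by_id[r] for r in cl.read_ids],
            reference,
            min_support=ann["min_support"],
            min_identity=ann["min_identity"],
        )
        label = res.label
        monomer = None
        if cl.consensus and len(cl.consensus) >= 100:
            monomer = detect_satellite(cl.consensus)
            if monomer is not None:
                label = "satellite"  # satellite detection overrides
        labels[cl.id] = label
        rows.append(
            {
                "cluster": cl.id,
                "label": label,
                "support": res.support,
                "runner_up": res.runner_up,
                "runner_up_support": res.runner_up_support,
                "monomer_length": monomer,
            }
        )
    return labels, pd.DataFrame(rows)


def stage_annotate(cfg: RunConfig, outdir: str) -> None:
    reference = read_reference_fasta(_need(os.path.join(outdir, "mini_reference.fasta"), "simulate"))
    labels_to_run = [f"individual_{p.four_letter_code}" for p in cfg.profiles] + ["comparative"]
    for label in labels_to_run:
        result = load_clustering(outdir, label)
        reads_by_id = {}
        if label == "comparative":
            files = [os.path.join(outdir, f"comparative_{p.four_letter_code}.fastq") for p in cfg.profiles]
        else:
            code = label.split("_")[1]
            files = [os.path.join(outdir, f"individual_{code}.fastq")]
        for f in files:
            rs = read_fastq(_need(f, "preprocess"))
            for pair in rs.pairs:
                for rid, seq, _ in pair.reads:
                    reads_by_id[rid] = seq
        _, frame = _annotate_result(result, reads_by_id, reference, cfg)
        write_tsv(frame, os.path.join(outdir, f"annotation_{label}.tsv"), cfg.header())


def stage_quantify(cfg: RunConfig, outdir: str) -> None:
    from .seqio import read_tsv

    profiles = cfg.profiles
    for profile in profiles:
        label = f"individual_{profile.four_letter_code}"
        result = load_clustering(outdir, label)
        anno = read_tsv(_need(os.path.join(outdir, f"annotation_{label}.tsv"), "annotate"))
        labels = dict(zip(anno["cluster"], anno["label"]))
        table = abundance_table(result, labels, [profile])
        write_tsv(table, os.path.join(outdir, f"abundance_{profile.four_letter_code}.tsv"), cfg.header())

    result = load_clustering(outdir, "comparative")
    anno = read_tsv(_need(os.path.join(outdir, "annotation_comparative.tsv"), "annotate"))
    labels = dict(zip(anno["cluster"], anno["label"]))
    comp = comparative_table(result, labels, profiles[0], profiles[1])
    write_tsv(comp, os.path.join(outdir, "comparative_table.tsv"), cfg.header())
    slope = scatter_slope(comp)
    reg = regression_table(comp)
    write_tsv(reg, os.path.join(outdir, "regressions.tsv"), cfg.header())
    with open(os.path.join(outdir, "comparative_summary.json"), "w") as fh:
        json.dump(
            {
                "scatter_slope": slope,
                "expected_slope": comp.attrs["expected_slope"],
                "analyzed_reads": dict(result.analyzed_reads),
            },
            fh,
            indent=2,
        )


def stage_rsf(cfg: RunConfig, outdir: str) -> pd.DataFrame:
    templates = demo_templates()
    rows = []
    for profile in cfg.profiles:
        code = profile.four_letter_code
        reads = read_fastq(_need(os.path.join(outdir, f"filtered_{code}.fastq"), "preprocess"), species_tag=code)
        for family in cfg.rsf["families"]:
            tags = extract_tags(templates[family])
            res = rsf_count(reads, tags, min_identity=cfg.rsf["min_identity"], species=code)
            rows.append(
                {
                    "family": family,
                    "species": code,
                    "Lx": res.lx,
                    "LU": res.lu,
                    "Rsf": res.rsf,
                }
            )
    frame = pd.DataFrame(rows)
    write_tsv(frame, os.path.join(outdir, "rsf.tsv"), cfg.header())
    return frame


def default_demo_tree() -> tuple[str, dict[str, float]]:
    """A synthetic six-tip tree for the ancestral stage demo.

    Toy stand-in for the genus phylogeny (the real one is not packaged):
    two focal tips carry the observed 1C values 2,480 and 4,680 Mb.
    """
    newick = (
        "((H_koreana:1.0,H_breviscapa:1.0):1.5,"
        "((H_umbellata:0.8,H_orientalis:0.8):1.0,H_tubiflora:1.8):0.7,"
        "Ypsilandra_out:4.0):0.0;"
    )
    tips = {
        "H_koreana": 2480.0,
        "H_breviscapa": 2700.0,
        "H_umbellata": 4680.0,
        "H_orientalis": 4100.0,
        "H_tubiflora": 3200.0,
        "Ypsilandra_out": 2900.0,
    }
    return newick, tips


def stage_ancestral(cfg: RunConfig, outdir: str) -> pd.DataFrame:
    os.makedirs(outdir, exist_ok=True)
    anc = cfg.ancestral
    if anc.get("tree_file"):
        with open(anc["tree_file"]) as fh:
            newick = fh.read()
        tips_frame = pd.read_csv(anc["tip_values_file"], sep="\t", comment="#")
        tips = dict(zip(tips_frame.iloc[:, 0], tips_frame.iloc[:, 1]))
    else:
        newick, tips = default_demo_tree()
    phylo = PhyloTree.from_newick(newick, tips)
    result = ml_ancestral_bm(phylo)
    deltas = branch_deltas(result, result.root_id)
    rows = [
        {
            "node": nid,
            "anc1c_mb": est,
            "variance": result.node_variances[nid],
            "delta_vs_root_mb": deltas.get(nid),
        }
        for nid, est in result.node_estimates.items()
    ]
    frame = pd.DataFrame(rows)
    write_tsv(frame, os.path.join(outdir, "ancestral_states.tsv"), cfg.header())
    return frame


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "cluster": stage_cluster,
    "annotate": stage_annotate,
    "quantify": stage_quantify,
    "rsf": stage_rsf,
    "ancestral": stage_ancestral,
}


def run_pipeline(cfg: RunConfig, stages: Sequence[str] | None = None, outdir: str | None = None):
    """Execute the requested stages in dependency order."""
    outdir = outdir or cfg.outdir
    os.makedirs(outdir, exist_ok=True)
    wanted = list(stages) if stages else list(STAGES)
    unknown = set(wanted) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    for stage in STAGES:  # canonical order
        if stage in wanted:
            _STAGE_FUNCS[stage](cfg, outdir)
    cfg.to_yaml(os.path.join(outdir, "run_config.yaml"))
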