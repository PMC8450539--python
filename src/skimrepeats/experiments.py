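"""Benchmark experiments built on the pipeline.

These drive whole-pipeline simulations used by the analysis scripts and
the test suite: proportion recovery on a matched two-species pair, and
the solo:full Rsf grid (see :mod:`skimrepeats.solo_ltr`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .annotation import (
    build_mini_reference,
    classify_cluster,
    default_decoys,
    detect_satellite,
)
from .clustering import cluster_reads, comparative_cluster
from .preprocess import downsample_to_gp
from .quantify import comparative_table, scatter_slope
from .simulate import (
    build_genome,
    demo_templates,
    matched_pair_specs,
    simulate_reads,
)
from .types import SpeciesProfile

__all__ = ["RecoveryResult", "proportion_recovery_experiment"]


@dataclass
class RecoveryResult:
    """Truth vs estimated genome proportions and the scatter slope."""

    sample_gp: float
    # species code -> family -> (truth GP %, estimated GP %)
    gp_by_species: dict[str, dict[str, tuple[float, float]]]
    scatter_slope: float
    expected_slope: float
    analyzed_reads: dict[str, int] = field(default_factory=dict)

    @property
    def worst_gp_deviation(self) -> float:
        """Largest |estimate - truth| in percentage points."""
        return max(
            abs(est - truth)
            for fams in self.gp_by_species.values()
            for truth, est in fams.values()
        )

    @property
    def slope_relative_error(self) -> float:
        return abs(self.scatter_slope / self.expected_slope - 1)


def _annotate(result, seq_of, reference, lineage_to_family):
    """Cluster id -> family name (satellite detection overrides)."""
    labels = {}
    families = {}
    for cl in result.clusters:
        res = classify_cluster(cl.id, [seq_of[r] for r in cl.read_ids], reference)
        label = res.label
        if cl.consensus and len(cl.consensus) >= 100:
            if detect_satellite(cl.consensus) is not None:
                label = "satellite"
        labels[cl.id] = label
        families[cl.id] = (
            "HeloSAT" if label == "satellite" else lineage_to_family.get(label)
        )
    return labels, families


def proportion_recovery_experiment(
    sample_gp: float = 0.015,
    coverage: float = 0.15,
    seed: int = 42,
    divergence: float = 0.02,
) -> RecoveryResult:
    """Simulate the matched 1.0/1.9-Mb species pair and measure recovery.

    Reads are simulated at the sequencing coverage, down-sampled to
    ``sample_gp`` of each 1C, clustered per species (GP estimates per
    repeat family via annotation) and pooled for the comparative
    scatter, whose slope is compared with the 1.9x genome-size ratio.
    Satellites are excluded from the slope as usual.
    """
    templates = demo_templates()
    specs = matched_pair_specs(templates, seed=seed, divergence=divergence)
    profiles = [
        SpeciesProfile("matched_small", "SMAL", 1.0),
        SpeciesProfile("matched_large", "LARG", 1.9),
    ]
    reference = build_mini_reference(templates, default_decoys(seed=99))
    lineage_to_family = {t.lineage: t.name for t in templates.values()}

    readsets = []
    gp_by_species: dict[str, dict[str, tuple[float, float]]] = {}
    analyzed = {}
    for spec, profile in zip(specs, profiles):
        genome = build_genome(spec)
        reads = simulate_reads(
            genome, coverage=coverage, seed=seed, species_tag=profile.four_letter_code
        )
        sampled = downsample_to_gp(reads, profile, sample_gp, seed=seed)
        readsets.append(sampled)
        result = cluster_reads([sampled])
        seq_of = {rid: s for p in sampled.pairs for rid, s, _ in p.reads}
        _, families = _annotate(result, seq_of, reference, lineage_to_family)
        est_reads: dict[str, int] = {}
        for cl in result.clusters:
            fam = families[cl.id]
            if fam:
                est_reads[fam] = est_reads.get(fam, 0) + cl.size
        n = result.total_analyzed
        analyzed[profile.four_letter_code] = n
        gp_by_species[profile.four_letter_code] = {
            rec.family: (
                100 * rec.genome_proportion,
                100 * est_reads.get(rec.family, 0) / n,
            )
            for rec in genome.truth_table
        }

    pooled = comparative_cluster(readsets)
    seq_of = {rid: s for rs in readsets for p in rs.pairs for rid, s, _ in p.reads}
    labels, _ = _annotate(pooled, seq_of, reference, lineage_to_family)
    table = comparative_table(pooled, labels, profiles[0], profiles[1])
    slope = scatter_slope(table)
    return RecoveryResult(
        sample_gp=sample_gp,
        gp_by_species=gp_by_species,
        scatter_slope=slope,
        expected_slope=table.attrs["expected_slope"],
        analyzed_reads=analyzed,
    )
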