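"""Summary statistics over cluster tables.

Genome proportion (GP, %) of a cluster is its read share of the
analyzed reads; abundance in Mb/1C is GP x 1C. The comparative mode
emits per-cluster read counts and log2 GP ratios between species
(zero = equal genomic proportion), a read-scatter slope whose
expectation is the genome-size ratio, and ordinary least-squares
regressions of shared-cluster abundances between the species.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .clustering import ClusteringResult
from .types import SpeciesProfile

__all__ = [
    "genome_proportion",
    "gp_to_mb",
    "genome_size_ratio",
    "abundance_table",
    "comparative_table",
    "scatter_slope",
    "ols_regression",
    "RegressionResult",
]


def genome_proportion(cluster_reads: int, analyzed_reads: int) -> float:
    """GP in percent: 100 x cluster reads / analyzed reads."""
    if analyzed_reads <= 0:
        raise ValueError("analyzed_reads must be positive")
    if cluster_reads > analyzed_reads:
        raise ValueError("cluster_reads cannot exceed analyzed_reads")
    return 100.0 * cluster_reads / analyzed_reads


def gp_to_mb(gp_percent: float, c_value_mb: float) -> float:
    """Abundance in Mb/1C from a GP in percent and a 1C value in Mb."""
    if not 0 <= gp_percent <= 100:
        raise ValueError("gp_percent must be in [0, 100]")
    return gp_percent / 100.0 * c_value_mb


def genome_size_ratio(c_large_mb: float, c_small_mb: float) -> float:
    """Ratio of two 1C values (dimensionless)."""
    if c_large_mb <= 0 or c_small_mb <= 0:
        raise ValueError("1C values must be positive")
    return c_large_mb / c_small_mb


def abundance_table(
    result: ClusteringResult,
    annotations: dict[str, str],
    profiles: Sequence[SpeciesProfile],
) -> pd.DataFrame:
    """Per-species lineage summary: GP (%) and abundance (Mb/1C).

    Rows cover every annotated lineage plus "unclassified" and the
    "low/single copy" pool; per species the GP column sums to 100 (up
    to rounding) and the Mb column to the 1C value.
    """
    tags = {p.four_letter_code: p for p in profiles}
    rows = []
    lineage_counts: dict[str, dict[str, int]] = {}
    for cl in result.clusters:
        label = annotations.get(cl.id, cl.annotation)
        for tag, count in cl.per_species_count.items():
            lineage_counts.setdefault(label, {}).setdefault(tag, 0)
            lineage_counts[label][tag] += count

    pool_counts: dict[str, int] = {}
    for rid in result.singleton_pool:
        tag = rid[:4]
        pool_counts[tag] = pool_counts.get(tag, 0) + 1

    labels = sorted(lineage_counts) + ["low/single copy"]
    for label in labels:
        for tag, profile in tags.items():
            analyzed = result.analyzed_reads.get(tag, 0)
            if analyzed == 0:
                continue
            count = (
                pool_counts.get(tag, 0)
                if label == "low/single copy"
                else lineage_counts.get(label, {}).get(tag, 0)
            )
            gp = genome_proportion(count, analyzed)
            rows.append(
                {
                    "species": profile.species_name,
                    "code": tag,
                    "lineage": label,
                    "reads": count,
                    "gp_percent": gp,
                    "abundance_mb": gp_to_mb(gp, profile.c_value_1c_mb),
                    "gp_percent_display": round(gp, 2),
                    "abundance_mb_display": round(gp_to_mb(gp, profile.c_value_1c_mb), 2),
                }
            )
    return pd.DataFrame(rows)


def comparative_table(
    result: ClusteringResult,
    annotations: dict[str, str],
    profile_a: SpeciesProfile,
    profile_b: SpeciesProfile,
    use_superclusters: bool = False,
) -> pd.DataFrame:
    """Per-(super)cluster two-species comparison records.

    Emits reads and GP (%) per species, the log2 GP ratio (B over A;
    defined only when both GPs are positive), and a shared flag. The
    expected slope of the reads_B-vs-reads_A scatter at equal sampled
    genome proportion is the 1C ratio of the species.
    """
    tag_a, tag_b = profile_a.four_letter_code, profile_b.four_letter_code
    n_a = result.analyzed_reads.get(tag_a, 0)
    n_b = result.analyzed_reads.get(tag_b, 0)
    if n_a == 0 or n_b == 0:
        raise ValueError("comparative table needs analyzed reads from both species")
    units = result.superclusters if use_superclusters else result.clusters
    anno = annotations
    rows = []
    for unit in units:
        if use_superclusters:
            labels = {anno.get(cid, "unclassified") for cid in unit.cluster_ids}
            label = sorted(labels - {"unclassified"})[0] if labels - {"unclassified"} else "unclassified"
        else:
            label = anno.get(unit.id, "unclassified")
        ra = unit.per_species_count.get(tag_a, 0)
        rb = unit.per_species_count.get(tag_b, 0)
        gp_a = genome_proportion(ra, n_a)
        gp_b = genome_proportion(rb, n_b)
        rows.append(
            {
                "id": unit.id,
                "lineage": label,
                "reads_a": ra,
                "reads_b": rb,
                "gp_a": gp_a,
                "gp_b": gp_b,
                "log2_gp_ratio": np.log2(gp_b / gp_a) if ra > 0 and rb > 0 else np.nan,
                "shared": ra > 0 and rb > 0,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["expected_slope"] = genome_size_ratio(
        profile_b.c_value_1c_mb, profile_a.c_value_1c_mb
    )
    df.attrs["analyzed_a"] = n_a
    df.attrs["analyzed_b"] = n_b
    # warn-and-adjust when the two species were not sampled at the same GP
    sampled_ratio = (n_b / profile_b.c_value_bases) / (n_a / profile_a.c_value_bases)
    if abs(sampled_ratio - 1) > 0.02:
        import warnings

        warnings.warn(
            "species sampled at unequal genome proportions; "
            f"slope expectation adjusted by {sampled_ratio:.3f}"
        )
        df.attrs["expected_slope"] *= sampled_ratio
    return df


def scatter_slope(comparative: pd.DataFrame, exclude_satellites: bool = True) -> float:
    """Through-origin slope of the shared-cluster read scatter.

    Uses Poisson (1/x) weights, i.e. the ratio estimator
    sum(reads_B)/sum(reads_A) over shared clusters; satellites are
    excluded by default, matching the scatter's presentation.
    """
    df = comparative[comparative["shared"]]
    if exclude_satellites:
        df = df[df["lineage"] != "satellite"]
    x = df["reads_a"].to_numpy(float)
    y = df["reads_b"].to_numpy(float)
    if x.sum() == 0:
        raise ValueError("no shared non-satellite clusters")
    return float(y.sum() / x.sum())


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def ols_regression(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """Closed-form simple OLS with a two-sided slope t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 paired finite observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    n = x.size
    xbar, ybar = x.mean(), y.mean()
    sxx = float(((x - xbar) ** 2).sum())
    if sxx == 0:
        raise ValueError("zero variance in x: regression is degenerate")
    sxy = float(((x - xbar) * (y - ybar)).sum())
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    resid = y - (intercept + slope * x)
    ss_res = float((resid**2).sum())
    ss_tot = float(((y - ybar) ** 2).sum())
    r_squared = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    if n > 2 and ss_res > 0:
        se = np.sqrt(ss_res / (n - 2) / sxx)
        t = slope / se
        p = 2 * stats.t.sf(abs(t), df=n - 2)
    else:
        p = 0.0 if slope != 0 else 1.0
    return RegressionResult(slope, intercept, r_squared, float(p), n)


def regression_table(comparative: pd.DataFrame) -> pd.DataFrame:
    """Lineage-wise OLS of species-B GP on species-A GP (shared clusters).

    Includes per-lineage rows (where >= 3 shared clusters exist), all
    LTR retrotransposons pooled, and "all repeats" with and without
    satellites, mirroring the with/without-satellite contrast.
    """
    shared = comparative[comparative["shared"]]
    rows = []

    def add(name: str, sub: pd.DataFrame):
        if len(sub) < 3 or sub["gp_a"].nunique() < 2:
            return
        res = ols_regression(sub["gp_a"], sub["gp_b"])
        rows.append(
            {
                "repeats": name,
                "slope": res.slope,
                "intercept": res.intercept,
                "r_squared": res.r_squared,
                "p_value": res.p_value,
                "n": res.n,
            }
        )

    for lineage, sub in shared.groupby("lineage"):
        add(lineage, sub)
    ltr = shared[shared["lineage"].str.startswith(("Ty1/copia", "Ty3/gypsy"))]
    add("All LTR-retrotransposons", ltr)
    add("All repeats (including satellites)", shared)
    add("All repeats (excluding satellites)", shared[shared["lineage"] != "satellite"])
    return pd.DataFrame(rows)
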