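"""Genome-proportion arithmetic, abundance conservation, OLS regression."""

import numpy as np
import pandas as pd
import pytest

from skimrepeats.clustering import Cluster, ClusteringResult
from skimrepeats.quantify import (
    RegressionResult,
    comparative_table,
    genome_proportion,
    genome_size_ratio,
    gp_to_mb,
    ols_regression,
    regression_table,
    scatter_slope,
)
from skimrepeats.types import SpeciesProfile


class TestGenomeProportion:
    def test_basic_percent(self):
        assert genome_proportion(100, 1_000_000) == pytest.approx(0.01)
        assert genome_proportion(0, 5) == 0.0

    def test_errors(self):
        with pytest.raises(ValueError):
            genome_proportion(1, 0)
        with pytest.raises(ValueError):
            genome_proportion(10, 5)


class TestGpToMb:
    @pytest.mark.parametrize(
        "gp,c,expected",
        [(10.20, 4680, 477), (0, 123, 0), (50, 2000, 1000)],
    )
    def test_values(self, gp, c, expected):
        assert round(gp_to_mb(gp, c)) == expected

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            gp_to_mb(120, 1000)


class TestGenomeSizeRatio:
    def test_studied_pair(self):
        r = genome_size_ratio(4680, 2480)
        assert round(r, 2) == 1.89
        assert round(r, 1) == 1.9

    def test_identity(self):
        assert genome_size_ratio(7.0, 7.0) == 1.0

    def test_equal_gp_read_counts_reproduce_ratio(self):
        # equal sampled genome proportion => read totals scale with 1C
        assert round(665_294 / 349_706, 2) == 1.90


def _two_species_result():
    """Hand-built comparative result: 4 shared clusters + 1 specific."""
    clusters = []
    sizes = [(40, 76), (20, 38), (10, 19), (5, 12), (0, 15)]
    for i, (a, b) in enumerate(sizes, start=1):
        cl = Cluster(id=f"CL{i}", read_ids=[f"r{i}_{j}" for j in range(a + b)])
        cl.per_species_count = {k: v for k, v in (("AAAA", a), ("BBBB", b)) if v}
        clusters.append(cl)
    return ClusteringResult(
        clusters=clusters,
        superclusters=[],
        singleton_pool=[f"p{j}" for j in range(125 - 75 + 160 - 160)],
        analyzed_reads={"AAAA": 100, "BBBB": 190},
    )


class TestComparativeTable:
    def setup_method(self):
        self.pa = SpeciesProfile("a", "AAAA", 1.0)
        self.pb = SpeciesProfile("b", "BBBB", 1.9)
        self.annotations = {
            "CL1": "Ty1/copia-Angela",
            "CL2": "Ty3/gypsy-Retand",
            "CL3": "Ty3/gypsy-Tekay",
            "CL4": "rDNA",
            "CL5": "satellite",
        }

    def test_log2_ratio_zero_for_equal_gp(self):
        df = comparative_table(_two_species_result(), self.annotations, self.pa, self.pb)
        row = df[df["id"] == "CL3"].iloc[0]
        # 10/100 vs 19/190: identical GP
        assert row["log2_gp_ratio"] == pytest.approx(0.0)

    def test_log2_ratio_one_for_doubled_gp(self):
        res = _two_species_result()
        res.clusters[2].per_species_count = {"AAAA": 10, "BBBB": 38}
        df = comparative_table(res, self.annotations, self.pa, self.pb)
        row = df[df["id"] == "CL3"].iloc[0]
        assert row["log2_gp_ratio"] == pytest.approx(1.0)

    def test_species_specific_not_shared(self):
        df = comparative_table(_two_species_result(), self.annotations, self.pa, self.pb)
        assert not df[df["id"] == "CL5"].iloc[0]["shared"]
        assert np.isnan(df[df["id"] == "CL5"].iloc[0]["log2_gp_ratio"])

    def test_expected_slope_is_size_ratio(self):
        df = comparative_table(_two_species_result(), self.annotations, self.pa, self.pb)
        assert df.attrs["expected_slope"] == pytest.approx(1.9)

    def test_scatter_slope_ratio_estimator(self):
        df = comparative_table(_two_species_result(), self.annotations, self.pa, self.pb)
        # shared non-satellite clusters: (40+20+10+5) vs (76+38+19+12)
        assert scatter_slope(df) == pytest.approx(145 / 75)


class TestOlsRegression:
    def test_exact_line(self):
        x = np.arange(10.0)
        res = ols_regression(x, 2 * x)
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(0.0, abs=1e-12)
        assert res.r_squared == pytest.approx(1.0)

    def test_constant_response(self):
        res = ols_regression([1, 2, 3, 4], [5, 5, 5, 5])
        assert res.r_squared == 0.0
        assert res.slope == 0.0

    def test_matches_statsmodels_oracle(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(17)
        x = rng.normal(size=10)
        y = 1.5 * x + rng.normal(scale=0.3, size=10)
        res = ols_regression(x, y)
        fit = sm.OLS(y, sm.add_constant(x)).fit()
        assert res.slope == pytest.approx(fit.params[1], abs=1e-10)
        assert res.intercept == pytest.approx(fit.params[0], abs=1e-10)
        assert res.r_squared == pytest.approx(fit.rsquared, abs=1e-10)
        assert res.p_value == pytest.approx(fit.pvalues[1], abs=1e-10)

    def test_degenerate_x(self):
        with pytest.raises(ValueError, match="variance"):
            ols_regression([1, 1, 1], [1, 2, 3])

    def test_slope_recovery_type_i(self):
        """True slope within 2 SE in ~95% of noisy replicates."""
        rng = np.random.default_rng(23)
        x = np.linspace(0, 5, 20)
        inside = 0
        n_rep = 200
        for _ in range(n_rep):
            y = 3.0 + 2.0 * x + rng.normal(scale=1.0, size=x.size)
            res = ols_regression(x, y)
            resid = y - (res.intercept + res.slope * x)
            se = np.sqrt(
                (resid**2).sum() / (x.size - 2) / ((x - x.mean()) ** 2).sum()
            )
            if abs(res.slope - 2.0) <= 2 * se:
                inside += 1
        assert inside / n_rep >= 0.90


def test_abundance_table_is_conservative():
    """Sum of Mb over all categories equals 1C before rounding."""
    from skimrepeats.quantify import abundance_table

    res = _two_species_result()
    annotations = {
        "CL1": "Ty1/copia-Angela",
        "CL2": "Ty3/gypsy-Retand",
        "CL3": "unclassified",
        "CL4": "rDNA",
        "CL5": "satellite",
    }
    # pool must make per-species totals consistent
    res.singleton_pool = [f"AAAA_p{j}" for j in range(25)] + [
        f"BBBB_p{j}" for j in range(30)
    ]
    profiles = [SpeciesProfile("a", "AAAA", 1.0), SpeciesProfile("b", "BBBB", 1.9)]
    table = abundance_table(res, annotations, profiles)
    for prof in profiles:
        sub = table[table["code"] == prof.four_letter_code]
        assert sub["abundance_mb"].sum() == pytest.approx(prof.c_value_1c_mb, abs=0.01)
        assert sub["gp_percent"].sum() == pytest.approx(100.0, abs=1e-9)


def test_regression_table_has_satellite_contrast():
    df = comparative_table(
        _two_species_result(),
        {
            "CL1": "Ty1/copia-Angela",
            "CL2": "Ty1/copia-Angela",
            "CL3": "Ty1/copia-Angela",
            "CL4": "Ty3/gypsy-Retand",
            "CL5": "satellite",
        },
        SpeciesProfile("a", "AAAA", 1.0),
        SpeciesProfile("b", "BBBB", 1.9),
    )
    table = regression_table(df)
    names = set(table["repeats"])
    assert "All repeats (including satellites)" in names
    assert "All repeats (excluding satellites)" in names
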