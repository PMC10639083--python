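"""The survey's statistical battery: exact tests against independent oracles,
printed contingency values, bias batteries and MIG comparisons."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from minorintron import stats
from minorintron.errors import InsufficientDataError, ParameterError


class TestConservationPercentage:
    @pytest.mark.parametrize("n_cons,n_var,expected", [
        (115, 1391, 7.6), (20, 135, 12.9), (2052, 14162, 12.7), (7, 120, 5.5),
    ])
    def test_printed_values(self, n_cons, n_var, expected):
        assert round(stats.conservation_percentage(n_cons, n_var), 1) == expected

    def test_degenerate(self):
        assert stats.conservation_percentage(0, 10) == 0.0
        with pytest.raises(ParameterError):
            stats.conservation_percentage(0, 0)


def fisher_oracle_two_sided(table) -> float:
    """Exact-rational enumeration of the hypergeometric support."""
    (a, b), (c, d) = table
    r1, c1, n = a + b, a + c, a + b + c + d
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    nums = {k: math.comb(c1, k) * math.comb(n - c1, r1 - k) for k in range(lo, hi + 1)}
    total = math.comb(n, r1)
    return sum(v for v in nums.values() if v <= nums[a]) / total


class TestFisherExact:
    def test_symmetric_table_is_one(self):
        assert stats.fisher_exact_2x2([[1, 1], [1, 1]]) == pytest.approx(1.0)

    def test_printed_table1(self):
        p = stats.fisher_exact_2x2([[2052, 14162], [7, 120]])
        assert float(f"{p:.2g}") == 0.015

    def test_extreme_table_stays_finite_in_log_space(self):
        p = stats.fisher_exact_2x2([[112, 178], [23, 1265]])
        assert 0 < p < 1e-60

    def test_all_zero_rejected(self):
        with pytest.raises(ParameterError):
            stats.fisher_exact_2x2([[0, 0], [0, 0]])

    @given(st.lists(st.integers(0, 60), min_size=4, max_size=4))
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_matches_rational_oracle_and_scipy(self, cells):
        if sum(cells) == 0:
            return
        table = [cells[:2], cells[2:]]
        mine = stats.fisher_exact_2x2(table)
        assert mine == pytest.approx(fisher_oracle_two_sided(table), rel=1e-9)
        assert mine == pytest.approx(sps.fisher_exact(table).pvalue, rel=1e-8)

    def test_one_sided_alternatives_match_scipy(self):
        table = [[8, 2], [1, 5]]
        for alt in ("greater", "less"):
            assert stats.fisher_exact_2x2(table, alt) == pytest.approx(
                sps.fisher_exact(table, alt).pvalue, rel=1e-9)


def binomial_oracle(k, n, p=0.5):
    pmf = [math.comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(n + 1)]
    return min(1.0, sum(q for q in pmf if q <= pmf[k] * (1 + 1e-12)))


class TestBinomialTwoTailed:
    def test_balanced_counts_give_one(self):
        assert stats.binomial_two_tailed(10, 20) == pytest.approx(1.0)

    def test_fully_biased_counts(self):
        assert stats.binomial_two_tailed(20, 20) == pytest.approx(2 * 0.5**20)

    def test_enumerated_example(self):
        assert stats.binomial_two_tailed(15, 20) == pytest.approx(
            binomial_oracle(15, 20), rel=1e-9)
        assert round(stats.binomial_two_tailed(15, 20), 3) == 0.041

    def test_monotone_toward_the_extreme(self):
        ps = [stats.binomial_two_tailed(k, 30) for k in range(15, 31)]
        assert all(a >= b - 1e-12 for a, b in zip(ps, ps[1:]))


class TestBhAdjust:
    def test_monotone_and_never_below_raw(self):
        raw = np.array([0.001, 0.04, 0.03, 0.9, 0.2])
        q = stats.bh_adjust(raw)
        assert (q >= raw - 1e-15).all()
        order = np.argsort(raw)
        assert (np.diff(q[order]) >= -1e-15).all()


class TestPositionalBias:
    def test_balanced_positions_not_flagged(self):
        res = stats.positional_bias_battery([0.25, 0.75] * 10, [0.5] * 30)
        assert res.p_binomial == pytest.approx(1.0)
        assert not res.flagged_5prime_minor_bias

    def test_planted_five_prime_bias_flagged(self):
        rng = np.random.default_rng(0)
        minor = rng.uniform(0, 0.4, 60)
        major = rng.uniform(0, 1, 400)
        res = stats.positional_bias_battery(minor, major)
        assert res.flagged_5prime_minor_bias

    def test_position_domain_enforced(self):
        with pytest.raises(ParameterError):
            stats.positional_bias_battery([1.2], [0.5])
        with pytest.raises(InsufficientDataError):
            stats.positional_bias_battery([], [0.5])

    def test_batch_reports_corrected_and_uncorrected_flags(self):
        rng = np.random.default_rng(1)
        data = {f"sp{i}": (rng.uniform(0, 1, 40), rng.uniform(0, 1, 200))
                for i in range(5)}
        data["biased"] = (rng.uniform(0, 0.3, 40), rng.uniform(0, 1, 200))
        df = stats.positional_bias_batch(data)
        assert {"flagged_5prime_minor_bias", "flagged_corrected"} <= set(df.columns)
        row = df.set_index("species").loc["biased"]
        assert row["flagged_5prime_minor_bias"] and row["flagged_corrected"]


class TestCladeEnrichment:
    def test_printed_table2_layout(self):
        clades = ["Streptophyta"] * 290 + ["Metazoa"] * 1204 + ["Fungi"] * 63 + \
                 ["Stramenopiles"] * 16 + ["Evosea"] * 4 + ["Discosea"] * 1
        flags = [True] * 112 + [False] * 178 + [True] * 21 + [False] * 1183 + \
                [True] * 2 + [False] * 61 + [False] * 21
        table, p = stats.clade_enrichment(pd.Series(flags), pd.Series(clades),
                                          "Streptophyta")
        assert table.tolist() == [[112, 178], [23, 1265]]
        assert p < 1e-60

    def test_equal_rates_near_one(self):
        flags = pd.Series([True, False] * 20)
        clades = pd.Series((["a"] * 2 + ["b"] * 2) * 10)
        _, p = stats.clade_enrichment(flags, clades, "a")
        assert p > 0.5

    def test_missing_focal_clade(self):
        with pytest.raises(ParameterError):
            stats.clade_enrichment(pd.Series([True]), pd.Series(["x"]), "y")


class TestPhaseDistribution:
    def test_all_phase_zero(self):
        assert stats.phase_distribution([0] * 1000) == (1.0, 0.0, 0.0)

    def test_planted_proportions_recovered_exactly(self):
        phases = [0] * 20 + [1] * 50 + [2] * 30
        assert stats.phase_distribution(phases) == (0.2, 0.5, 0.3)

    def test_empty_rejected(self):
        with pytest.raises(InsufficientDataError):
            stats.phase_distribution([])

    def test_phase0_comparison_methods(self):
        p, method = stats.compare_phase0((50, 50), (20, 80))
        assert 0 < p < 1 and method in {"boschloo", "fisher_fallback"}
        p_same, _ = stats.compare_phase0((50, 50), (50, 50))
        assert p_same > 0.9


class TestMigComparisons:
    def make_table(self, rng, mig_density_factor=2.0, n=300):
        rows = []
        for i in range(n):
            is_mig = i < n // 4
            dens = rng.gamma(4, 1.0) * (mig_density_factor if is_mig else 1.0)
            rows.append({"species": "sp1", "gene_id": f"g{i}", "is_mig": is_mig,
                         "genic_intron_density": dens,
                         "coding_length": rng.gamma(5, 300)})
        return pd.DataFrame(rows)

    def test_species_below_minor_floor_excluded(self):
        df = self.make_table(np.random.default_rng(0))
        out = stats.mig_comparisons(df, {"sp1": 8})
        assert out.empty

    def test_planted_density_effect_detected(self):
        df = self.make_table(np.random.default_rng(1))
        out = stats.mig_comparisons(df, {"sp1": 50})
        row = out.iloc[0]
        assert row["median_mig_genic_intron_density"] > \
            row["median_non_mig_genic_intron_density"]
        assert row["p_genic_intron_density"] < 0.05

    def test_null_shows_no_effect(self):
        df = self.make_table(np.random.default_rng(2), mig_density_factor=1.0)
        out = stats.mig_comparisons(df, {"sp1": 50})
        assert out.iloc[0]["p_genic_intron_density"] > 0.01

    def test_age_stratified_mode_with_bh(self):
        rng = np.random.default_rng(3)
        df = pd.concat([self.make_table(rng).assign(age="old"),
                        self.make_table(rng).assign(age="young")])
        out = stats.mig_comparisons(df, {"sp1": 50}, age_column="age")
        assert len(out) == 2
        assert (out["q_genic_intron_density"] >= out["p_genic_intron_density"] - 1e-15).all()


class TestSpearman:
    def test_equals_rank_pearson_without_ties(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=50)
        y = x + rng.normal(size=50)
        rho, _ = stats.spearman(x, y)
        rx = pd.Series(x).rank().to_numpy()
        ry = pd.Series(y).rank().to_numpy()
        assert rho == pytest.approx(np.corrcoef(rx, ry)[0, 1], rel=1e-12)
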