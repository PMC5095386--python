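"""Rates, windowing, region merging, randomization tests and comparisons."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from coscape import datasets, landscape
from coscape.landscape import (
    bin_positions,
    co_rate,
    compare_groups,
    merge_similar,
    randomization_test,
    region_rates,
    spearman,
    telomere_centromere_filter,
    window_counts,
)


def events_at(midpoints, chrom="c1", sample="s1"):
    return pd.DataFrame({"sample": sample, "chrom": chrom, "midpoint": midpoints})


class TestCoRate:
    @pytest.mark.parametrize("mean_co,length,expected", [
        (11.92, 225.4, 2.64),
        (9.47, 225.4, 2.10),
        (0.0, 100.0, 0.0),
    ])
    def test_known_values(self, mean_co, length, expected):
        assert round(co_rate(mean_co, length), 2) == expected

    def test_linear_in_mean_co(self):
        assert co_rate(4.0, 10.0) == 2 * co_rate(2.0, 10.0)

    def test_invalid_length(self):
        with pytest.raises(ValueError):
            co_rate(1.0, 0.0)

    def test_reference_table_internal_consistency(self):
        """Derived lengths reproduce the printed genome-wide rates of both crosses."""
        genome = datasets.genome_length_mbp()
        assert genome == pytest.approx(225.4, abs=0.05)
        for summary in (datasets.INTRASPECIFIC, datasets.INTERSPECIFIC):
            mean = summary.total_co / summary.n_f2
            assert round(co_rate(mean, genome), 2) == summary.genome_rate


class TestWindows:
    lengths = {"c1": 2_000_000, "c2": 1_200_000}

    def test_zero_events_all_zero(self):
        w = window_counts(events_at([]), self.lengths)
        assert w["count"].sum() == 0
        assert len(w) == 4 + 3  # c2 last window truncated

    def test_boundary_midpoint_goes_right(self):
        w = window_counts(events_at([500_000]), self.lengths)
        assert w.loc[(w["chrom"] == "c1") & (w["idx"] == 1), "count"].item() == 1

    def test_total_conserved(self):
        rng = np.random.default_rng(0)
        mids = rng.integers(0, 2_000_000, size=500)
        w = window_counts(events_at(mids), self.lengths)
        assert w["count"].sum() == 500

    def test_out_of_bounds_midpoint_errors(self):
        with pytest.raises(ValueError, match="outside"):
            window_counts(events_at([2_500_000]), self.lengths)

    def test_uniform_placement_is_multinomial(self):
        rng = np.random.default_rng(5)
        mids = rng.integers(0, 2_000_000, size=4_000)
        w = window_counts(events_at(mids), {"c1": 2_000_000})
        chi2 = ((w["count"] - 1000.0) ** 2 / 1000.0).sum()
        assert stats.chi2.sf(chi2, df=3) > 0.001


class TestMergeSimilar:
    def windows_from(self, counts, chrom="c1"):
        n = len(counts)
        return pd.DataFrame(
            {"chrom": chrom, "idx": range(n), "start": np.arange(n) * 100,
             "end": (np.arange(n) + 1) * 100, "count": counts}
        )

    def test_identical_counts_merge(self):
        r = merge_similar(self.windows_from([3, 3, 3, 0, 0]))
        assert r["observed"].tolist() == [9, 0]
        assert r["n_windows"].tolist() == [3, 2]

    def test_all_distinct_no_merge(self):
        r = merge_similar(self.windows_from([1, 2, 3, 4]))
        assert len(r) == 4

    def test_conservation(self):
        counts = [5, 5, 1, 0, 0, 2, 2, 2]
        r = merge_similar(self.windows_from(counts))
        assert r["observed"].sum() == sum(counts)

    def test_tolerance_merges_within_spread(self):
        r = merge_similar(self.windows_from([3, 4, 5, 9]), tol=2)
        assert r["observed"].tolist() == [12, 9]

    def test_chromosomes_not_merged_across(self):
        w = pd.concat(
            [self.windows_from([2, 2]), self.windows_from([2], chrom="c2")],
            ignore_index=True,
        )
        r = merge_similar(w)
        assert len(r) == 2


class TestRandomization:
    def test_extreme_region_hits_resolution_floor(self):
        lengths = {"c1": 1_000_000}
        w = window_counts(events_at([50_000] * 40), lengths, size=100_000)
        r = merge_similar(w)
        called = randomization_test(r, lengths, n_events=40, n_rand=999, seed=1)
        hot = called[called["observed"] == 40]
        assert hot["p_hot"].item() == pytest.approx(1.0 / 1000.0)
        assert hot["class"].item() == "hotspot"

    def test_empty_long_region_is_coldspot(self):
        lengths = {"c1": 10_000_000}
        mids = np.linspace(5_000_000, 9_999_999, 300).astype(int)
        w = window_counts(events_at(mids), lengths, size=500_000)
        r = merge_similar(w)
        called = randomization_test(r, lengths, n_events=300, n_rand=999, seed=2)
        empty = called[(called["observed"] == 0) & (called["n_windows"] >= 10)]
        assert (empty["class"] == "coldspot").all()

    def test_pvalues_in_unit_interval_and_deterministic(self):
        lengths = {"c1": 3_000_000}
        rng = np.random.default_rng(3)
        w = window_counts(events_at(rng.integers(0, 3_000_000, 60)), lengths)
        r = merge_similar(w)
        c1 = randomization_test(r, lengths, 60, n_rand=500, seed=7)
        c2 = randomization_test(r, lengths, 60, n_rand=500, seed=7)
        assert ((c1["p_hot"] > 0) & (c1["p_hot"] <= 1)).all()
        assert c1.equals(c2)

    def test_masked_genome_excludes_placements(self):
        from coscape.markers import MaskSet

        lengths = {"c1": 1_000_000}
        w = window_counts(events_at([950_000] * 10), lengths, size=100_000)
        r = merge_similar(w)
        mask = MaskSet(intervals={"c1": np.array([[0, 900_000]])})
        called = randomization_test(r, lengths, 10, n_rand=200, seed=1, mask=mask)
        # all random events forced into the last window's region -> observed not extreme
        hot = called[called["observed"] == 10]
        assert hot["p_hot"].item() > 0.5

    def test_fully_masked_genome_errors(self):
        from coscape.markers import MaskSet

        lengths = {"c1": 1_000_000}
        w = window_counts(events_at([1_000] * 3), lengths)
        r = merge_similar(w)
        mask = MaskSet(intervals={"c1": np.array([[0, 1_000_000]])})
        with pytest.raises(ValueError, match="empty"):
            randomization_test(r, lengths, 3, n_rand=10, mask=mask)


class TestRegionRates:
    def _regions(self, rates_hot, rates_cold, n_f2=10):
        rows = []
        for i, rate in enumerate(list(rates_hot) + list(rates_cold)):
            span = 1_000_000
            observed = rate * n_f2 * (span / 1e6) / 50.0
            rows.append(
                {"chrom": "c1", "start": i * span, "end": (i + 1) * span,
                 "first_idx": i, "last_idx": i, "n_windows": 1,
                 "observed": observed,
                 "class": "hotspot" if i < len(rates_hot) else "coldspot"}
            )
        return pd.DataFrame(rows)

    def test_fold_ratio_of_known_rates(self):
        out, summary = region_rates(self._regions([8.04], [0.48]), n_f2=10)
        assert summary["mean_hotspot_rate"] == pytest.approx(8.04)
        assert summary["fold_ratio"] == pytest.approx(16.75, abs=0.01)

    def test_identical_rates_ratio_one_p_one(self):
        out, summary = region_rates(self._regions([2.0, 2.0], [2.0, 2.0]), n_f2=10)
        assert summary["fold_ratio"] == pytest.approx(1.0)
        assert summary["t_pvalue"] == 1.0

    def test_missing_class_noticed(self):
        out, summary = region_rates(self._regions([5.0], []), n_f2=10)
        assert summary["fold_ratio"] is None
        assert "notice" in summary


class TestSpearman:
    def test_perfect_correlation(self):
        r = spearman([1, 2, 3, 4], [10, 20, 30, 40])
        assert r.rho == pytest.approx(1.0)

    def test_constant_vector_flagged(self):
        r = spearman([1, 1, 1, 1], [1, 2, 3, 4])
        assert r.flagged and np.isnan(r.rho)

    def test_exact_p_matches_independent_enumeration(self):
        rng = np.random.default_rng(8)
        for n in (4, 5, 6):
            x = rng.random(n)
            y = rng.random(n)
            res = spearman(x, y)
            # independent oracle: classic 1 - 6*sum(d^2)/(n(n^2-1)) over all orderings
            rx = stats.rankdata(x)
            ry = stats.rankdata(y)
            d2 = ((rx - ry) ** 2).sum()
            rho_oracle = 1 - 6 * d2 / (n * (n**2 - 1))
            assert res.rho == pytest.approx(rho_oracle)
            count = 0
            perms = list(itertools.permutations(ry))
            for p in perms:
                d2p = ((rx - np.asarray(p)) ** 2).sum()
                rp = 1 - 6 * d2p / (n * (n**2 - 1))
                if abs(rp) >= abs(rho_oracle) - 1e-12:
                    count += 1
            assert res.pvalue == pytest.approx(count / len(perms))

    def test_large_n_uses_t_approximation(self):
        rng = np.random.default_rng(2)
        x, y = rng.random(30), rng.random(30)
        res = spearman(x, y)
        ref = stats.spearmanr(x, y)
        assert res.method == "t-approx"
        assert res.rho == pytest.approx(ref.statistic)
        assert res.pvalue == pytest.approx(ref.pvalue)


class TestBrunnerMunzel:
    def test_identical_groups_relative_effect_half(self):
        r = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.relative_effect == pytest.approx(0.5)

    def test_large_shift_small_p(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0, 1, 20)
        b = rng.normal(10, 1, 20)
        r = compare_groups(a, b)
        assert r.pvalue < 1e-6
        assert r.relative_effect > 0.99

    def test_agrees_with_permutation_oracle(self):
        rng = np.random.default_rng(12)
        a = rng.normal(2.6, 0.8, 24)
        b = rng.normal(2.1, 0.8, 30)
        r = compare_groups(a, b)
        # permutation oracle on the Brunner-Munzel statistic
        pooled = np.concatenate([a, b])
        obs = abs(stats.brunnermunzel(a, b).statistic)
        count = 0
        n_perm = 2000
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            s = stats.brunnermunzel(perm[: len(a)], perm[len(a):]).statistic
            if abs(s) >= obs - 1e-12:
                count += 1
        p_perm = (count + 1) / (n_perm + 1)
        assert r.pvalue == pytest.approx(p_perm, abs=0.01)

    def test_degenerate_variance_flagged(self):
        r = compare_groups([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert r.flagged


class TestTelomereCentromereFilter:
    lengths = {"c1": 2_000_000, "c2": 1_500_000}

    def test_two_windows_removed_per_chromosome(self):
        w = window_counts(events_at([]), self.lengths)
        f = telomere_centromere_filter(w)
        for c, sub in f.groupby("chrom"):
            n_total = (w["chrom"] == c).sum()
            assert len(sub) == n_total - 2

    def test_pericentromere_covering_chromosome_removes_all(self):
        w = window_counts(events_at([]), self.lengths)
        bed = pd.DataFrame([{"chrom": "c2", "start": 0, "end": 1_500_000}])
        f = telomere_centromere_filter(w, bed, drop_telomeres=False)
        assert (f["chrom"] == "c2").sum() == 0
        assert (f["chrom"] == "c1").sum() == (w["chrom"] == "c1").sum()

    def test_idempotent(self):
        w = window_counts(events_at([]), self.lengths)
        bed = pd.DataFrame([{"chrom": "c1", "start": 900_000, "end": 1_100_000}])
        f1 = telomere_centromere_filter(w, bed)
        f2 = telomere_centromere_filter(f1, bed, drop_telomeres=False)
        assert f1.equals(f2)
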