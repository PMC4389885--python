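"""Diversity statistics against independent textbook-formula oracles."""
import math

import numpy as np
import pandas as pd
import pytest

from polysweep.diversity import (call_outlier_windows, donor_allele_windows,
                                 fst_per_snp, ld_r2, site_pi, snp_hiding_test,
                                 tajimas_d, window_diversity, window_fst)
from polysweep.panel import ALT
from polysweep.regions import merge_adjacent

from conftest import make_panel


# ---------------------------------------------------------------------------
# independent oracles (deliberately written from the defining formulas,
# not shared with the implementation)
# ---------------------------------------------------------------------------

def oracle_tajimas_d(haps: np.ndarray) -> float:
    """Tajima's D from an explicit 0/1 haplotype matrix (sites x samples):
    mean pairwise difference by direct pair enumeration, textbook constants
    by explicit loops."""
    m, n = haps.shape
    diffs = []
    for a in range(n):
        for b in range(a + 1, n):
            diffs.append(int(np.sum(haps[:, a] != haps[:, b])))
    k_hat = sum(diffs) / len(diffs)
    S = sum(1 for i in range(m) if 0 < haps[i].sum() < n)
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i ** 2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    return (k_hat - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


def oracle_hudson_fst(h1: np.ndarray, h2: np.ndarray) -> float:
    """Hudson F_ST for one SNP as 1 - Hw/Hb by explicit pair enumeration:
    Hw is the unweighted average of the two populations' mean pairwise
    differences, Hb the between-population mean difference."""
    def mean_pairwise(pop):
        diffs = [pop[a] != pop[b] for a in range(len(pop))
                 for b in range(a + 1, len(pop))]
        return np.mean(diffs)
    hw = (mean_pairwise(h1) + mean_pairwise(h2)) / 2.0
    hb = np.mean([x != y for x in h1 for y in h2])
    return 1.0 - hw / hb


class TestSitePi:
    @pytest.mark.parametrize("count, n, expected", [
        (2, 4, 2 / 3),
        (0, 10, 0.0),
        (5, 10, 0.5 * 10 / 9),
    ])
    def test_known_values(self, count, n, expected):
        assert site_pi(count, n) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("count, n", [(0, 7), (3, 9), (5, 5), (1, 2)])
    def test_allele_label_swap_invariance(self, count, n):
        assert site_pi(count, n) == pytest.approx(site_pi(n - count, n))

    def test_undefined_below_two_haplotypes(self):
        with pytest.raises(ValueError):
            site_pi(0, 1)


class TestTajimasD:
    def test_matches_oracle_on_random_fixtures(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = int(rng.integers(6, 16))
            m = int(rng.integers(20, 60))
            haps = (rng.random((m, n))
                    < rng.uniform(0.1, 0.9, m)[:, None]).astype(np.int8)
            if not ((haps.sum(1) > 0) & (haps.sum(1) < n)).any():
                continue
            counts = haps.sum(axis=1)
            seg = (counts > 0) & (counts < n)
            pi_sum = sum(site_pi(int(c), n) for c in counts)
            mine = tajimas_d(pi_sum, int(seg.sum()), n)
            assert mine == pytest.approx(oracle_tajimas_d(haps), abs=1e-9)

    def test_intermediate_frequency_classes_give_positive_d(self):
        # two haplotype groups of 5 lines with 20 fixed differences
        haps = np.zeros((20, 10), dtype=np.int8)
        haps[:, 5:] = 1
        assert oracle_tajimas_d(haps) > 0
        pi_sum = sum(site_pi(int(c), 10) for c in haps.sum(axis=1))
        assert tajimas_d(pi_sum, 20, 10) > 0

    def test_undefined_without_segregating_sites(self):
        assert math.isnan(tajimas_d(0.0, 0, 10))


class TestWindowDiversity:
    def test_empty_window_has_zero_pi_and_undefined_d(self):
        calls = np.zeros((5, 8), dtype=np.int8)
        calls[:, 0] = ALT
        panel = make_panel(calls, pos=[100, 200, 300, 400, 500])
        out = window_diversity(panel, win_bp=1000, step_bp=1000,
                               min_covered_bp=0,
                               chrom_lengths={"1A": 3000})
        w2 = out[(out["start"] == 2000)]
        assert w2[w2["statistic"] == "pi"]["value"].iloc[0] == 0.0
        assert np.isnan(w2[w2["statistic"] == "tajimas_d"]["value"].iloc[0])

    def test_low_coverage_window_undefined(self):
        calls = np.zeros((3, 8), dtype=np.int8)
        calls[:, 0] = ALT
        panel = make_panel(calls, pos=[100, 200, 300])
        out = window_diversity(panel, 1000, 1000, min_covered_bp=500,
                               chrom_lengths={"1A": 1000},
                               covered_bp={("1A", 0): 100})
        assert out["value"].isna().all()


class TestHudsonFst:
    def make_two_group_panel(self, h1, h2):
        calls = np.array([list(h1) + list(h2)], dtype=np.int8)
        groups = ["cultivar"] * len(h1) + ["landrace"] * len(h2)
        return make_panel(calls, metadata_groups=groups)

    def test_fixed_difference_is_one(self):
        panel = self.make_two_group_panel([1] * 5, [0] * 5)
        assert fst_per_snp(panel)[0] == pytest.approx(1.0)

    def test_equal_frequencies_centred_on_zero(self):
        """The unbiased estimator is zero in expectation (not exactly per
        SNP) when the groups share the allele frequency."""
        rng = np.random.default_rng(20)
        m = 4000
        calls = (rng.random((m, 40)) < 0.5).astype(np.int8)
        panel = make_panel(calls, metadata_groups=["cultivar"] * 20
                           + ["landrace"] * 20)
        vals = fst_per_snp(panel)
        vals = vals[~np.isnan(vals)]
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean()) < 3 * se

    def test_closed_form_p08_p02(self):
        h1 = [1] * 8 + [0] * 2
        h2 = [1] * 2 + [0] * 8
        panel = self.make_two_group_panel(h1, h2)
        # independent closed form, computed from the defining quantities
        expected = oracle_hudson_fst(np.array(h1), np.array(h2))
        assert fst_per_snp(panel)[0] == pytest.approx(expected, abs=1e-9)

    def test_matches_oracle_on_random_fixtures(self):
        rng = np.random.default_rng(8)
        checked = 0
        for _ in range(20):
            n1, n2 = int(rng.integers(4, 12)), int(rng.integers(4, 12))
            h1 = (rng.random(n1) < rng.uniform(0.2, 0.8)).astype(np.int8)
            h2 = (rng.random(n2) < rng.uniform(0.2, 0.8)).astype(np.int8)
            if len(set(h1)) < 2 and len(set(h2)) < 2 and h1[0] == h2[0]:
                continue
            panel = self.make_two_group_panel(h1, h2)
            got = fst_per_snp(panel)[0]
            assert got == pytest.approx(oracle_hudson_fst(h1, h2), abs=1e-9)
            checked += 1
        assert checked >= 15

    def test_window_mean_retains_negative_estimates(self):
        rng = np.random.default_rng(9)
        calls = (rng.random((40, 20)) < 0.5).astype(np.int8)
        panel = make_panel(calls, metadata_groups=["cultivar"] * 10
                           + ["landrace"] * 10)
        per_snp = fst_per_snp(panel)
        win = window_fst(panel, win_bp=10 ** 6, step_bp=10 ** 6,
                         chrom_lengths={"1A": 10 ** 6})
        assert win["value"].iloc[0] == pytest.approx(np.nanmean(per_snp))
        assert (per_snp[~np.isnan(per_snp)] < 0).any()

    def test_missing_group_is_error(self):
        panel = self.make_two_group_panel([0, 1], [1, 0])
        with pytest.raises(ValueError):
            fst_per_snp(panel, ("cultivar", "nonexistent"))


class TestOutlierWindows:
    def make_stats(self, values):
        m = len(values)
        return pd.DataFrame({
            "chrom": "1A", "start": np.arange(m) * 1000,
            "end": np.arange(1, m + 1) * 1000, "subgenome": "A",
            "statistic": "pi", "value": values, "n_snps": 1,
            "covered_bp": 1000})

    def test_upper_tail_count_matches_sort_oracle(self):
        stats = self.make_stats(np.arange(1, 1001, dtype=float))
        out = call_outlier_windows(stats, 0.025, "upper")
        thr = np.quantile(np.arange(1, 1001), 0.975)  # type-7 definition
        expected = int((np.arange(1, 1001) >= thr).sum())
        assert out["outlier"].sum() == expected == 25

    def test_both_tails(self):
        stats = self.make_stats(np.arange(1, 1001, dtype=float))
        out = call_outlier_windows(stats, 0.025, "both")
        assert (out[out["tail"] == "lower"]["value"] <= 26).all()
        assert out["outlier"].sum() == 50

    def test_nan_windows_excluded(self):
        vals = np.arange(1, 101, dtype=float)
        vals[:10] = np.nan
        out = call_outlier_windows(self.make_stats(vals), 0.025, "upper")
        assert not out.loc[out["value"].isna(), "outlier"].any()


class TestMergeAdjacent:
    def wdf(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])

    def test_overlapping_windows_merge(self):
        regions = merge_adjacent(self.wdf([("1A", 0, 2_000_000, 1.0),
                                           ("1A", 1_000_000, 3_000_000, 2.0)]))
        assert len(regions) == 1
        assert (regions[0].start, regions[0].end) == (0, 3_000_000)
        assert regions[0].peak_value == 2.0

    def test_distant_windows_stay_separate(self):
        regions = merge_adjacent(self.wdf([("1A", 0, 1_000_000, 1.0),
                                           ("1A", 6_000_000, 7_000_000, 1.0)]),
                                 max_gap_bp=1_000_000)
        assert len(regions) == 2

    def test_idempotent_and_disjoint(self):
        rng = np.random.default_rng(10)
        starts = np.sort(rng.choice(np.arange(0, 100) * 1_000_000, 30,
                                    replace=False))
        df = self.wdf([("1A", s, s + 1_000_000, 1.0) for s in starts])
        once = merge_adjacent(df, 500_000)
        again = merge_adjacent(self.wdf(
            [(r.chrom, r.start, r.end, r.peak_value) for r in once]), 500_000)
        assert [(r.start, r.end) for r in once] == \
            [(r.start, r.end) for r in again]
        for a, b in zip(once, once[1:]):
            assert a.end < b.start


class TestLdR2:
    def test_perfect_coupling(self):
        calls = np.array([[0] * 5 + [1] * 5, [0] * 5 + [1] * 5],
                         dtype=np.int8)
        out = ld_r2(make_panel(calls), min_maf=0.05, max_dist_bp=10_000)
        assert out["r2"].iloc[0] == pytest.approx(1.0)

    def test_direct_arithmetic_example(self):
        # haplotype counts AB=4, Ab=1, aB=1, ab=4 -> r2 = 0.36
        a = [1] * 4 + [1] + [0] + [0] * 4
        b = [1] * 4 + [0] + [1] + [0] * 4
        out = ld_r2(make_panel(np.array([a, b], dtype=np.int8)),
                    min_maf=0.05, max_dist_bp=10_000)
        assert out["r2"].iloc[0] == pytest.approx(0.36, abs=1e-12)

    def test_self_r2_is_one_and_symmetric(self):
        rng = np.random.default_rng(11)
        g = (rng.random(30) < 0.4).astype(np.int8)
        from polysweep.diversity import _hap_r2
        assert _hap_r2(g, g) == pytest.approx(1.0)
        h = (rng.random(30) < 0.5).astype(np.int8)
        assert _hap_r2(g, h) == pytest.approx(_hap_r2(h, g))

    def test_independent_sites_mean_r2_near_inverse_n(self):
        """Sampling oracle: for unlinked loci E[r2] ~ 1/n."""
        rng = np.random.default_rng(12)
        n = 50
        calls = (rng.random((200, n)) < 0.5).astype(np.int8)
        out = ld_r2(make_panel(calls), min_maf=0.1, max_dist_bp=3_000)
        se = out["r2"].std(ddof=1) / np.sqrt(len(out))
        assert abs(out["r2"].mean() - 1 / n) < 3 * se + 0.01

    def test_maf_floor_respected(self):
        calls = np.zeros((2, 20), dtype=np.int8)
        calls[0, 0] = ALT  # MAF 0.05... but below floor 0.2
        calls[1, :10] = ALT
        out = ld_r2(make_panel(calls), min_maf=0.2, max_dist_bp=10_000)
        assert len(out) == 0


class TestSnpHiding:
    def test_duplicated_snps_give_probability_one(self):
        rng = np.random.default_rng(13)
        base = (rng.random((30, 20)) < 0.5).astype(np.int8)
        calls = np.repeat(base, 2, axis=0)
        pos = []
        for k in range(30):
            pos += [k * 10_000 + 1, k * 10_000 + 1001]
        panel = make_panel(calls, pos=pos)
        out = snp_hiding_test(panel, [(0, 2_000)], 0.8, seed=0)
        assert out["probability"].iloc[0] == 1.0

    def test_independent_snps_rarely_hidden(self):
        rng = np.random.default_rng(14)
        calls = (rng.random((120, 40)) < 0.5).astype(np.int8)
        panel = make_panel(calls, pos=np.arange(120) * 500 + 1)
        out = snp_hiding_test(panel, [(0, 2_000)], 0.8, seed=0)
        assert out["probability"].iloc[0] < 0.05

    def test_zero_threshold_is_certain_success(self):
        rng = np.random.default_rng(15)
        calls = (rng.random((50, 40)) < 0.5).astype(np.int8)
        panel = make_panel(calls, pos=np.arange(50) * 500 + 1)
        out = snp_hiding_test(panel, [(0, 2_000)], 0.0, seed=0)
        assert out["probability"].iloc[0] == 1.0


class TestDonorWindows:
    def test_everyone_carries_donor_allele(self):
        calls = np.zeros((10, 6), dtype=np.int8)
        panel = make_panel(calls, chrom="1D")
        donor = panel.variants[["chrom", "pos"]].assign(allele="A")  # = ref
        out = donor_allele_windows(panel, donor, None, win_bp=100_000)
        assert (out["value"].dropna() == 1.0).all()

    def test_uninformative_window_is_nan(self):
        calls = np.zeros((2, 6), dtype=np.int8)
        panel = make_panel(calls, chrom="1D")
        donor = panel.variants[["chrom", "pos"]].assign(allele="T")  # neither
        out = donor_allele_windows(panel, donor, None, win_bp=100_000)
        assert out["value"].isna().all()

    def test_planted_tract_recovers_recipient_fraction(self, small_sim):
        cfg, sim = small_sim
        from polysweep.simulate import IntrogressionSpec, plant_introgression
        tract = ("1D", 10_000_000, 50_000_000)
        panel, rec, donor = plant_introgression(
            sim.panel, IntrogressionSpec([tract], 0.95, 0.5), 4)
        full_donor = donor  # planted part only: informative inside tract
        out = donor_allele_windows(panel, full_donor, None, win_bp=5_000_000,
                                   chrom_lengths={"1D": 75_000_000})
        out = out[out["chrom"] == "1D"]
        inside = out[(out["start"] >= tract[1]) & (out["end"] <= tract[2])]
        vals = inside["value"].dropna()
        assert len(vals) > 0
        assert abs(vals.mean() - 0.5) < 0.15
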