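"""Positional profiles, randomization nulls, permutation tests, and the
score/relative-position comparisons."""

import numpy as np
import pytest
from scipy import stats

from apamir.apa_assignment import ApaCall
from apamir.positional_stats import (
    cluster_vs_all_test,
    profile_sites,
    randomized_apa_null,
    relative_position_compare,
    score_window_compare,
    two_set_partition_test,
)
from apamir.site_mapping import SeedSite
from tests.conftest import make_utr


def call_with(gene, length, apa_pos, distal=None):
    utr = make_utr(gene, "N" * length, start=0)
    return ApaCall(gene, utr, [apa_pos, distal if distal else length - 1])


def sites_for(gene, positions, conserved=True, family="f0", **kw):
    return [SeedSite(gene, p, family, conserved, **kw) for p in positions]


class TestProfileSites:
    def test_site_lands_in_expected_bin(self):
        call = call_with("g", 3000, 1500)
        prof = profile_sites([call], sites_for("g", [1350]))
        # distance -150 -> bin [-200, -100)
        b = np.where((prof.bin_edges[:-1] == -200))[0][0]
        assert prof.counts_conserved[b] == 1
        assert prof.counts_conserved.sum() == 1
        assert prof.counts_nonconserved.sum() == 0

    def test_no_sites_all_zero(self):
        prof = profile_sites([call_with("g", 3000, 1500)], [])
        assert prof.counts_conserved.sum() == 0
        assert prof.n_genes == 1

    def test_site_at_anchor_goes_downstream(self):
        call = call_with("g", 3000, 1500)
        prof = profile_sites([call], sites_for("g", [1500]))
        b = np.where(prof.bin_edges[:-1] == 0)[0][0]
        assert prof.counts_conserved[b] == 1

    def test_count_conserved_across_binning(self):
        rng = np.random.default_rng(0)
        calls = [call_with(f"g{i}", 4000, 2000) for i in range(20)]
        sites = []
        for i in range(20):
            sites += sites_for(f"g{i}", rng.integers(0, 3993, size=30),
                               conserved=bool(i % 2))
        prof = profile_sites(calls, sites)
        in_range = sum(1 for s in sites
                       if -1000 <= s.utr_start - 2000 < 1000)
        assert (prof.counts_conserved.sum()
                + prof.counts_nonconserved.sum()) == in_range

    def test_uniform_sites_within_binomial_bounds(self):
        rng = np.random.default_rng(42)
        n_genes, per_gene = 60, 40
        calls = [call_with(f"g{i}", 4001, 2000) for i in range(n_genes)]
        sites = []
        for i in range(n_genes):
            sites += sites_for(f"g{i}", rng.integers(0, 4001, size=per_gene))
        prof = profile_sites(calls, sites)
        n_total = n_genes * per_gene
        p_bin = 100 / 4001
        mean, sd = n_total * p_bin, np.sqrt(n_total * p_bin * (1 - p_bin))
        assert (np.abs(prof.counts_conserved - mean) < 3 * sd).all()

    def test_flank_not_multiple_of_bin_width(self):
        with pytest.raises(ValueError):
            profile_sites([call_with("g", 3000, 1500)], [], flank=1000,
                          bin_width=300)

    def test_utr_end_anchor_uses_distal_site(self):
        call = call_with("g", 5000, 1500, distal=4500)
        prof = profile_sites([call], sites_for("g", [4450]),
                             anchor="utr_end")
        b = np.where(prof.bin_edges[:-1] == -100)[0][0]
        assert prof.counts_conserved[b] == 1


class TestRandomizedApaNull:
    def test_short_genes_excluded(self):
        with pytest.raises(ValueError):
            randomized_apa_null([call_with("g", 2000, 1000)], [])

    def test_deterministic_given_seed(self):
        calls = [call_with(f"g{i}", 3000, 1400) for i in range(10)]
        rng = np.random.default_rng(1)
        sites = []
        for i in range(10):
            sites += sites_for(f"g{i}", rng.integers(0, 2993, size=8))
        a = randomized_apa_null(calls, sites, n_iter=200, seed=9)
        b = randomized_apa_null(calls, sites, n_iter=200, seed=9)
        assert np.array_equal(a.null_counts, b.null_counts)
        assert np.array_equal(a.p_values, b.p_values)
        assert np.array_equal(a.p_values_randomized, b.p_values_randomized)
        c = randomized_apa_null(calls, sites, n_iter=200, seed=10)
        assert not np.array_equal(a.null_counts, c.null_counts)

    def test_planted_excess_detected(self):
        rng = np.random.default_rng(3)
        calls, sites = [], []
        for i in range(150):
            g = f"g{i}"
            calls.append(call_with(g, 4000, 2000))
            sites += sites_for(g, rng.integers(0, 3993, size=4))
            # 3x density in [-300, 0) of the anchor
            sites += sites_for(g, rng.integers(1700, 1994, size=2))
        ens = randomized_apa_null(calls, sites, n_iter=1000, seed=0)
        window = (ens.bin_edges[:-1] >= -300) & (ens.bin_edges[:-1] < 0)
        assert (ens.p_values[window] < 0.05).all()
        assert ens.p_values[~window].min() > 0.001

    def test_p_never_zero_or_above_one(self):
        calls = [call_with("g", 3000, 1500)]
        ens = randomized_apa_null(calls, sites_for("g", [1450]),
                                  n_iter=50, seed=0)
        assert (ens.p_values > 0).all() and (ens.p_values <= 1).all()


class TestTwoSetPartition:
    def _cohort(self, rng, n_per_set, excess_in_b=0):
        calls, sites = [], []
        for i in range(2 * n_per_set):
            g = f"g{i}"
            calls.append(call_with(g, 4000, 2000))
            sites += sites_for(g, rng.integers(0, 3993, size=4))
            if i >= n_per_set and excess_in_b:
                sites += sites_for(g, rng.integers(1700, 1994,
                                                   size=excess_in_b))
        setA = {f"g{i}" for i in range(n_per_set)}
        setB = {f"g{i}" for i in range(n_per_set, 2 * n_per_set)}
        return setA, setB, calls, sites

    def test_planted_excess_in_b_detected(self):
        rng = np.random.default_rng(5)
        setA, setB, calls, sites = self._cohort(rng, 120, excess_in_b=2)
        res = two_set_partition_test(setA, setB, calls, sites,
                                     n_iter=1000, seed=1)
        window = (res.bin_edges[:-1] >= -300) & (res.bin_edges[:-1] < 0)
        assert (res.p_values[window] < 0.05).all()

    def test_empty_bin_in_both_groups_p_is_one(self):
        calls = [call_with("gA", 4000, 2000), call_with("gB", 4000, 2000)]
        sites = sites_for("gA", [1950]) + sites_for("gB", [1960])
        res = two_set_partition_test({"gA"}, {"gB"}, calls, sites,
                                     n_iter=100, seed=0)
        empty = res.bin_edges[:-1] == -1000
        assert res.p_values[empty] == pytest.approx(1.0)

    def test_input_validation(self):
        calls = [call_with("gA", 4000, 2000)]
        with pytest.raises(ValueError):
            two_set_partition_test(set(), {"gA"}, calls, [])
        with pytest.raises(ValueError):
            two_set_partition_test({"gA"}, {"gA"}, calls, [])

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(6)
        setA, setB, calls, sites = self._cohort(rng, 30)
        a = two_set_partition_test(setA, setB, calls, sites, n_iter=300,
                                   seed=4)
        b = two_set_partition_test(setA, setB, calls, sites, n_iter=300,
                                   seed=4)
        assert np.array_equal(a.p_values, b.p_values)
        assert np.array_equal(a.p_values_randomized, b.p_values_randomized)


class TestClusterVsAll:
    def test_cluster_covering_all_genes_gives_p_one(self):
        # every gene has a conserved site of the (single) cluster family:
        # target set == all genes, every null relabeling reproduces it
        calls = [call_with(f"g{i}", 4000, 2000) for i in range(10)]
        sites = []
        for i in range(10):
            sites += sites_for(f"g{i}", [100 + 40 * i], family="fam0")
        res = cluster_vs_all_test(["fam0"], calls, sites, n_iter=50, seed=0)
        assert np.allclose(res.observed_stat, 0.0)
        assert (res.p_values == 1.0).all()

    def test_degenerate_single_iteration_bounds(self):
        calls = [call_with(f"g{i}", 4000, 2000) for i in range(6)]
        sites = []
        for i in range(6):
            fam = "fam0" if i < 3 else "f9"
            sites += sites_for(f"g{i}", [1500 + i], family=fam)
        res = cluster_vs_all_test(["fam0"], calls, sites, n_iter=1, seed=0)
        assert set(np.unique(res.p_values)) <= {0.5, 1.0}

    def test_planted_cluster_window_preference_detected(self):
        rng = np.random.default_rng(8)
        calls, sites = [], []
        for i in range(200):
            g = f"g{i}"
            calls.append(call_with(g, 4000, 2000))
            # background sites of non-cluster families everywhere
            sites += sites_for(g, rng.integers(0, 3993, size=3), family="f9")
            if i < 60:  # cluster-targeted genes: extra sites 5' of APA
                sites += sites_for(g, rng.integers(1700, 1994, size=2),
                                   family="fam0")
        res = cluster_vs_all_test(["fam0"], calls, sites, n_iter=1000,
                                  seed=2)
        window = (res.bin_edges[:-1] >= -300) & (res.bin_edges[:-1] < 0)
        assert (res.p_values[window] < 0.05).all()

    def test_empty_target_set_errors(self):
        calls = [call_with("g", 4000, 2000)]
        with pytest.raises(ValueError):
            cluster_vs_all_test(["fam0"], calls,
                                sites_for("g", [10], family="f9"))

    def test_subset_null_available(self):
        calls = [call_with(f"g{i}", 4000, 2000) for i in range(8)]
        sites = []
        for i in range(8):
            fam = "fam0" if i < 4 else "f9"
            sites += sites_for(f"g{i}", [1000 + i], family=fam)
        res = cluster_vs_all_test(["fam0"], calls, sites, n_iter=100,
                                  seed=0, null_model="subset")
        assert res.p_values.shape == (20,)


class TestScoreWindowCompare:
    def _calls(self, n=1):
        return [call_with(f"g{i}", 3000, 1500) for i in range(n)]

    def test_identical_score_multisets(self):
        scores = [0.2, 0.4, 0.6]
        sites = []
        for j, v in enumerate(scores):
            sites += sites_for("g0", [1400 + j], pct=v)
            sites += sites_for("g0", [1600 + j], pct=v)
        res = score_window_compare(self._calls(), sites, kind="pct")
        assert res.t_statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_separated_normals_match_closed_form(self):
        rng = np.random.default_rng(11)
        a = rng.normal(0.6, 0.1, 200)
        b = rng.normal(0.4, 0.1, 200)
        sites = [SeedSite("g0", 1200 + j, "f", True, pct=v)
                 for j, v in enumerate(a)]
        sites += [SeedSite("g0", 1500 + j, "f", True, pct=v)
                  for j, v in enumerate(b)]
        res = score_window_compare(self._calls(), sites, kind="pct")
        assert res.t_statistic > 0 and res.p_value < 1e-6
        # pooled-variance closed form, written out independently
        na, nb = len(a), len(b)
        sp2 = (((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1))
               / (na + nb - 2))
        t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
        p = 2 * stats.t.sf(abs(t), na + nb - 2)
        assert res.t_statistic == pytest.approx(t, abs=1e-10)
        assert res.p_value == pytest.approx(p, abs=1e-10)

    def test_sparse_group_errors(self):
        sites = sites_for("g0", [1400], pct=0.5) \
            + sites_for("g0", [1600, 1610], pct=0.5)
        with pytest.raises(ValueError):
            score_window_compare(self._calls(), sites, kind="pct")

    def test_conserved_only_filter(self):
        sites = []
        for j in range(3):
            sites += sites_for("g0", [1400 + 10 * j], conserved=True,
                               pct=0.9)
            sites += sites_for("g0", [1600 + 10 * j], conserved=False,
                               pct=0.1)
        with pytest.raises(ValueError):
            # 3' window has no conserved scored sites
            score_window_compare(self._calls(), sites, kind="pct",
                                 conserved_only=True)


class TestRelativePosition:
    def test_identical_classes(self):
        utrs = [make_utr(f"g{i}", "N" * 2000) for i in range(3)]
        sites = []
        for i in range(3):
            sites += sites_for(f"g{i}", [200, 900, 1500])
        res = relative_position_compare(utrs, utrs, sites)
        assert res.t_statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_distal_class_sign_and_significance(self):
        rng = np.random.default_rng(13)
        utrs_a = [make_utr(f"a{i}", "N" * 2000) for i in range(40)]
        utrs_b = [make_utr(f"b{i}", "N" * 2000) for i in range(40)]
        sites = []
        for i in range(40):
            sites += sites_for(f"a{i}",
                               rng.integers(1700, 1950, size=3))  # ~0.9
            sites += sites_for(f"b{i}", rng.integers(0, 1993, size=3))
        res = relative_position_compare(utrs_a, utrs_b, sites)
        assert res.t_statistic > 0  # class A sits more distally
        assert res.p_value < 1e-10
        assert res.mean_a > res.mean_b

    def test_terminal_site_relative_position_below_one(self):
        utr = make_utr("g", "N" * 1000)
        sites = sites_for("g", [993, 500])
        res = relative_position_compare([utr], [utr], sites, min_len=100)
        assert max(res.decile_density_a.nonzero()[0]) == 9
        assert all(s.utr_start / utr.length < 1 for s in sites)

    def test_short_utrs_excluded(self):
        utrs = [make_utr("g", "N" * 500)]
        with pytest.raises(ValueError):
            relative_position_compare(utrs, utrs, sites_for("g", [1, 2]),
                                      min_len=1000)
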