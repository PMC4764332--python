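"""Cleavage-site calling: run clustering, site selection, internal-priming
flagging — each checked against independent brute-force oracles."""

import itertools
import random

import pytest

from apamir.cs_calling import (
    CleavageSite,
    ReadRun,
    build_runs,
    call_cleavage_sites,
    call_sites,
    flag_internal_priming,
    is_internal_priming_window,
    quantify_per_sample,
)
from apamir.io_formats import ReadEnd3p


def ends_at(positions, chrom="chr1", strand="+", sample="s1"):
    return [ReadEnd3p(chrom, p, strand, sample) for p in positions]


# ---------------------------------------------------------------- oracles

def oracle_cluster(positions, gap_max):
    """Single-linkage clustering of sorted unique positions: split where
    the gap is >= gap_max."""
    uniq = sorted(set(positions))
    clusters, block = [], []
    for p in uniq:
        if block and p - block[-1] >= gap_max:
            clusters.append(block)
            block = []
        block.append(p)
    if block:
        clusters.append(block)
    return clusters


def oracle_select(candidates, min_support, min_spacing, strand="+"):
    """Exhaustive greedy selection: support desc, 5'-most first; keep if
    >= min_spacing from every kept; then support floor."""
    if strand == "+":
        order = sorted(candidates, key=lambda t: (-t[1], t[0]))
    else:
        order = sorted(candidates, key=lambda t: (-t[1], -t[0]))
    kept = []
    for pos, cnt in order:
        if all(abs(pos - k) >= min_spacing for k, _ in kept):
            kept.append((pos, cnt))
    return sorted((p, c) for p, c in kept if c >= min_support)


def oracle_ip_window(seq, k=10, min_A=8):
    """Exhaustive scan of every k-mer's composition."""
    seq = seq.upper()
    for i in range(len(seq) - k + 1):
        sub = seq[i:i + k]
        if sub.count("A") >= min_A and sub.count("A") + sub.count("G") == k:
            return True
    return False


# ---------------------------------------------------------------- runs

class TestBuildRuns:
    def test_single_position_pileup(self):
        runs = build_runs(ends_at([100] * 12))
        assert len(runs) == 1
        assert (runs[0].start, runs[0].end) == (100, 101)
        assert runs[0].total_count == 12

    def test_gap_splits_clusters(self):
        runs = build_runs(ends_at([100, 105, 130]), gap_max=10)
        spans = [(r.start, r.end) for r in runs]
        assert spans == [(100, 106), (130, 131)]

    def test_gap_boundary_below_10(self):
        assert len(build_runs(ends_at([100, 109]))) == 1   # gap 9 < 10
        assert len(build_runs(ends_at([100, 110]))) == 2   # gap 10 not < 10

    def test_runs_never_span_strand_or_chrom(self):
        ends = (ends_at([100], strand="+") + ends_at([101], strand="-")
                + ends_at([102], chrom="chr2"))
        runs = build_runs(ends)
        assert len(runs) == 3

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_single_linkage_oracle(self, seed):
        rng = random.Random(seed)
        positions = [rng.randrange(0, 500) for _ in range(rng.randrange(1, 60))]
        gap = rng.randrange(1, 20)
        runs = build_runs(ends_at(positions), gap_max=gap)
        got = [sorted(r.per_position_counts) for r in runs]
        assert got == oracle_cluster(positions, gap)
        # counts conserved
        assert sum(r.total_count for r in runs) == len(positions)


# ---------------------------------------------------------------- sites

def run_from_counts(counts, chrom="chr1", strand="+"):
    pos = sorted(counts)
    return ReadRun(chrom, strand, pos[0], pos[-1] + 1, dict(counts))


class TestCallSites:
    def test_close_maxima_higher_support_wins(self):
        run = run_from_counts({100: 12, 130: 15})
        sites = call_sites([run])
        assert [(s.pos, s.support) for s in sites] == [(130, 15)]

    def test_below_min_support_dropped(self):
        assert call_sites([run_from_counts({100: 9})]) == []

    def test_spacing_satisfied_keeps_both(self):
        runs = [run_from_counts({100: 20}), run_from_counts({160: 11})]
        sites = call_sites(runs)
        assert [(s.pos, s.support) for s in sites] == [(100, 20), (160, 11)]

    def test_plateau_keeps_5p_most(self):
        sites = call_sites([run_from_counts({100: 15, 101: 15})])
        assert [s.pos for s in sites] == [100]
        sites = call_sites([run_from_counts({100: 15, 101: 15})],
                           min_support=10)
        assert sites[0].support == 15
        minus = ReadRun("chr1", "-", 100, 102, {100: 15, 101: 15})
        assert [s.pos for s in call_sites([minus])] == [101]

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_selection_oracle(self, seed):
        rng = random.Random(1000 + seed)
        positions = sorted(rng.sample(range(0, 400), rng.randrange(2, 40)))
        counts = {p: rng.randrange(1, 40) for p in positions}
        gap = 10
        spacing = rng.choice([20, 50, 80])
        min_support = rng.choice([1, 10, 15])
        ends = list(itertools.chain.from_iterable(
            ends_at([p] * c) for p, c in counts.items()))
        runs = build_runs(ends, gap_max=gap)
        sites = call_sites(runs, min_support=min_support, min_spacing=spacing)
        # oracle: local maxima per oracle-clustered run, then greedy select
        candidates = []
        for block in oracle_cluster(positions, gap):
            block_cands = [p for p in block
                           if counts[p] >= counts.get(p - 1, 0)
                           and counts[p] >= counts.get(p + 1, 0)]
            for j, p in enumerate(block_cands):
                # plateau of adjacent equal-count maxima: 5'-most only
                if (j > 0 and block_cands[j - 1] == p - 1
                        and counts[block_cands[j - 1]] == counts[p]):
                    continue
                candidates.append((p, counts[p]))
        expected = oracle_select(candidates, min_support, spacing)
        assert sorted((s.pos, s.support) for s in sites) == expected
        # invariants on every output
        kept = sorted(s.pos for s in sites)
        assert all(b - a >= spacing for a, b in zip(kept, kept[1:]))
        assert all(s.support >= min_support for s in sites)

    def test_order_invariance(self):
        rng = random.Random(7)
        positions = [rng.randrange(0, 300) for _ in range(200)]
        ends = ends_at(positions)
        ref = [(s.pos, s.support) for s in
               call_sites(build_runs(ends))]
        for _ in range(3):
            rng.shuffle(ends)
            got = [(s.pos, s.support) for s in call_sites(build_runs(ends))]
            assert got == ref


# ------------------------------------------------- internal priming flag

class TestInternalPriming:
    def test_poly_a_stretch(self):
        assert is_internal_priming_window("C" * 20 + "AAAAAAAAAA" + "C" * 20)

    def test_eight_a_two_g(self):
        assert is_internal_priming_window("C" * 20 + "AAAAGAAAGA" + "C" * 20)

    def test_c_in_best_stretch_fails(self):
        assert not is_internal_priming_window("C" * 20 + "AAAAAAAACA" + "C" * 20)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_oracle(self, seed):
        rng = random.Random(seed)
        for _ in range(2000):
            # A-heavy alphabet so positives are common
            seq = "".join(rng.choice("AAAGGCT") for _ in range(50))
            assert is_internal_priming_window(seq) == oracle_ip_window(seq)

    def test_minus_strand_scans_transcript_sense(self):
        # genomic plus strand carries TTTTTTTTTT: only the minus-strand
        # transcript sense (AAAAAAAAAA) should trip the filter
        genome = {"chr1": "C" * 40 + "TTTTTTTTTT" + "C" * 40}
        run = ReadRun("chr1", "-", 45, 46, {45: 20})
        site_minus = CleavageSite("chr1", "-", 45, 20, run)
        site_plus = CleavageSite("chr1", "+", 45, 20, run)
        assert flag_internal_priming(site_minus, genome)
        assert not flag_internal_priming(site_plus, genome)

    def test_truncated_window_at_contig_edge(self, caplog):
        genome = {"chr1": "AAAAAAAAAACCC"}
        run = ReadRun("chr1", "+", 2, 3, {2: 20})
        site = CleavageSite("chr1", "+", 2, 20, run)
        with caplog.at_level("WARNING"):
            assert flag_internal_priming(site, genome)
        assert "truncated" in caplog.text


# ------------------------------------------------------- quantification

class TestQuantifyPerSample:
    def test_counts_within_run(self):
        run = ReadRun("chr1", "+", 100, 106, {100: 2, 105: 1})
        site = CleavageSite("chr1", "+", 100, 2, run)
        ends = (ends_at([100, 101], sample="A") + ends_at([105], sample="B"))
        assert quantify_per_sample(site, ends) == {"A": 2, "B": 1}

    def test_no_ends_zero_over_known_samples(self):
        run = ReadRun("chr1", "+", 100, 101, {100: 1})
        site = CleavageSite("chr1", "+", 100, 1, run)
        assert quantify_per_sample(site, [], samples=["A", "B"]) == \
            {"A": 0, "B": 0}

    def test_pooled_equals_sample_sum(self):
        rng = random.Random(3)
        ends = [ReadEnd3p("chr1", rng.randrange(95, 115), "+",
                          rng.choice("AB")) for _ in range(100)]
        run = ReadRun("chr1", "+", 100, 110,
                      {p: 1 for p in range(100, 110)})
        site = CleavageSite("chr1", "+", 100, 1, run)
        counts = quantify_per_sample(site, ends)
        pooled = sum(1 for e in ends if 100 <= e.pos < 110)
        assert sum(counts.values()) == pooled


class TestEndToEnd:
    def test_full_caller_flags_and_quantifies(self):
        genome = {"chr1": "C" * 300 + "A" * 12 + "C" * 300}
        true_ends = ends_at([100] * 30, sample="s1") \
            + ends_at([100] * 10, sample="s2")
        decoy_ends = ends_at([306] * 15, sample="s1")
        sites = call_cleavage_sites(true_ends + decoy_ends, genome)
        by_pos = {s.pos: s for s in sites}
        assert not by_pos[100].internal_priming
        assert by_pos[306].internal_priming
        assert by_pos[100].per_sample_support == {"s1": 30, "s2": 10}
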