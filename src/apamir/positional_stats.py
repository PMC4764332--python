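"""Positional statistics of seed-match sites around APA anchors.

The central quantity is a binned profile of site counts at signed
distances from each gene's APA anchor (negative = 5'/upstream of the
cleavage site, in transcript sense). Significance comes from three
randomization schemes:

* :func:`randomized_apa_null` — per gene, a pseudo-APA position is drawn
  uniformly from the UTR interior (omitting ``flank`` nt at each end) and
  the profile recomputed; the per-bin p-value asks whether the observed
  count is high relative to that ensemble.
* :func:`two_set_partition_test` — the per-bin difference in per-gene site
  density between two gene sets, against random re-partitions of their
  union at the same sizes.
* :func:`cluster_vs_all_test` — the per-bin density difference between
  genes targeted by a designated miRNA-family cluster and all profiled
  genes, against random gene subsets of the same size.

Permutation p-values use the +1-corrected estimator
``(1 + #{null >= observed}) / (1 + n_iter)`` and are therefore never
exactly zero. No multiple-testing correction is applied across bins; raw
per-bin p-values are reported and correction is left to the caller.
"""

from __future__ import annotations

import os
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from apamir.apa_assignment import ApaCall, filter_flank
from apamir.io_formats import UTRModel
from apamir.site_mapping import SeedSite

DEFAULT_FLANK = 1000
DEFAULT_BIN_WIDTH = 100
DEFAULT_N_ITER = 10_000

# cap on the element count of the (iterations x sites) distance matrix
# built per chunk in the randomized null
_CHUNK_ELEMENTS = 4_000_000


def _anchor_position(call: ApaCall, anchor: str) -> int:
    if anchor == "apa":
        if call.apa_pos is None:
            raise ValueError(f"gene {call.gene_id} is not APA-positive")
        return call.apa_pos
    if anchor == "utr_end":
        return call.distal_pos
    raise ValueError("anchor must be 'apa' or 'utr_end'")


@dataclass
class PositionalProfile:
    """Binned site counts at signed distances from an anchor.

    ``bin_edges`` has ``n_bins + 1`` entries from ``-flank`` to ``+flank``;
    a site at distance d falls in the half-open bin containing d, so a site
    exactly at the anchor belongs to the first downstream bin.
    """

    anchor: str
    bin_edges: np.ndarray
    counts_conserved: np.ndarray
    counts_nonconserved: np.ndarray
    n_genes: int
    genes_per_bin: np.ndarray

    @property
    def n_bins(self) -> int:
        return len(self.bin_edges) - 1

    def density_conserved(self) -> np.ndarray:
        """Conserved sites per contributing gene per bin (NaN where no
        gene covers the bin)."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.genes_per_bin > 0,
                            self.counts_conserved / self.genes_per_bin, np.nan)


@dataclass
class NullEnsemble:
    """A randomization ensemble with per-bin one-sided p-values.

    ``p_values`` is the deterministic +1-corrected estimator (conservative
    under ties, never anti-conservative); ``p_values_randomized`` breaks
    ties uniformly at random and is exactly Uniform(0,1] when the observed
    statistic is exchangeable with the ensemble — use it for calibration
    diagnostics, and ``p_values`` for inference.
    """

    bin_edges: np.ndarray
    observed: np.ndarray
    null_counts: np.ndarray  # (n_iter, n_bins)
    p_values: np.ndarray
    p_values_randomized: np.ndarray
    n_iter: int
    seed: int
    n_genes: int

    def null_mean(self) -> np.ndarray:
        return self.null_counts.mean(axis=0)

    def null_sd(self) -> np.ndarray:
        return self.null_counts.std(axis=0, ddof=1)


@dataclass
class PermutationTestResult:
    """Per-bin one-sided permutation test on a density-difference statistic."""

    bin_edges: np.ndarray
    observed_stat: np.ndarray
    p_values: np.ndarray
    p_values_randomized: np.ndarray
    n_iter: int
    seed: int
    group_sizes: tuple[int, int]
    null_mean: np.ndarray = field(default=None)
    null_sd: np.ndarray = field(default=None)


@dataclass
class ScoreCompareResult:
    """Two-sample comparison of site scores 5' vs 3' of the APA anchor."""

    mean_5p: float
    mean_3p: float
    t_statistic: float
    p_value: float
    n_5p: int
    n_3p: int


@dataclass
class RelPosResult:
    """Comparison of conserved-site relative positions (utr_start / length)
    between two gene classes, plus decile density profiles for plotting."""

    t_statistic: float
    p_value: float
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int
    decile_density_a: np.ndarray
    decile_density_b: np.ndarray


def _check_geometry(flank: int, bin_width: int) -> np.ndarray:
    if flank % bin_width != 0:
        raise ValueError("flank must be a multiple of bin_width")
    return np.arange(-flank, flank + bin_width, bin_width)


def _sites_by_gene(sites: Iterable[SeedSite]) -> dict[str, list[SeedSite]]:
    by_gene: dict[str, list[SeedSite]] = defaultdict(list)
    for s in sites:
        by_gene[s.gene_id].append(s)
    return by_gene


def profile_sites(calls: Sequence[ApaCall], sites: Iterable[SeedSite],
                  anchor: str = "apa", flank: int = DEFAULT_FLANK,
                  bin_width: int = DEFAULT_BIN_WIDTH) -> PositionalProfile:
    """Binned conserved/non-conserved site counts around each gene's anchor.

    Each site contributes to the bin containing ``utr_start - anchor_pos``;
    sites outside ``[-flank, flank)`` are ignored. ``genes_per_bin`` counts
    genes whose UTR fully covers the bin's distance range (all genes, when
    calls were pre-filtered with :func:`~apamir.apa_assignment.filter_flank`).
    """
    edges = _check_geometry(flank, bin_width)
    n_bins = len(edges) - 1
    cons = np.zeros(n_bins, dtype=np.int64)
    noncons = np.zeros(n_bins, dtype=np.int64)
    genes_per_bin = np.zeros(n_bins, dtype=np.int64)
    by_gene = _sites_by_gene(sites)
    for call in calls:
        a = _anchor_position(call, anchor)
        lo_cover = edges[:-1] + a >= 0
        hi_cover = edges[1:] + a <= call.utr.length
        genes_per_bin += lo_cover & hi_cover
        for s in by_gene.get(call.gene_id, ()):
            d = s.utr_start - a
            if -flank <= d < flank:
                b = (d + flank) // bin_width
                if s.conserved:
                    cons[b] += 1
                else:
                    noncons[b] += 1
    return PositionalProfile(anchor, edges, cons, noncons, len(calls),
                             genes_per_bin)


def _per_gene_bin_counts(calls: Sequence[ApaCall],
                         sites: Iterable[SeedSite],
                         anchor: str, flank: int, bin_width: int,
                         conserved_only: bool = True) -> np.ndarray:
    """(n_genes, n_bins) matrix of per-gene site counts around each gene's
    own anchor."""
    edges = _check_geometry(flank, bin_width)
    n_bins = len(edges) - 1
    M = np.zeros((len(calls), n_bins), dtype=np.int64)
    by_gene = _sites_by_gene(sites)
    for i, call in enumerate(calls):
        a = _anchor_position(call, anchor)
        for s in by_gene.get(call.gene_id, ()):
            if conserved_only and not s.conserved:
                continue
            d = s.utr_start - a
            if -flank <= d < flank:
                M[i, (d + flank) // bin_width] += 1
    return M


def _permutation_p(observed: np.ndarray, null: np.ndarray, n_iter: int,
                   rng: np.random.Generator
                   ) -> tuple[np.ndarray, np.ndarray]:
    """One-sided p-values against an ensemble.

    Returns (deterministic, randomized): the deterministic estimator is
    ``(1 + #{null >= obs}) / (1 + n_iter)``; the randomized one places the
    observation uniformly within its tie group, giving an exactly uniform
    null distribution for exchangeable statistics.
    """
    greater = (null > observed[None, :]).sum(axis=0)
    ties = (null == observed[None, :]).sum(axis=0)
    det = (1.0 + greater + ties) / (1.0 + n_iter)
    rand = (greater + rng.random(len(observed)) * (ties + 1.0)) / (1.0 + n_iter)
    return det, rand


def randomized_apa_null(calls: Sequence[ApaCall],
                        sites: Iterable[SeedSite],
                        flank: int = DEFAULT_FLANK,
                        bin_width: int = DEFAULT_BIN_WIDTH,
                        n_iter: int = DEFAULT_N_ITER,
                        seed: int = 0,
                        conserved_only: bool = True) -> NullEnsemble:
    """Randomized-anchor null for positional enrichment around the APA site.

    Only genes with ``utr.length > 2 * flank`` participate (a pseudo-anchor
    drawn from ``[flank, length - flank)`` must exist); others are dropped
    from both the observed profile and the ensemble. Per iteration every
    gene receives an independent uniform pseudo-anchor and the same binned
    count is recomputed. The per-bin p-value is the +1-corrected fraction
    of iterations whose count reaches the observed one.
    """
    edges = _check_geometry(flank, bin_width)
    n_bins = len(edges) - 1
    eligible = [c for c in calls
                if c.is_apa_positive and c.utr.length > 2 * flank]
    if not eligible:
        raise ValueError("no genes with utr.length > 2*flank")
    obs = _per_gene_bin_counts(eligible, sites, "apa", flank, bin_width,
                               conserved_only).sum(axis=0)

    by_gene = _sites_by_gene(sites)
    site_pos_parts: list[np.ndarray] = []
    site_gene_idx_parts: list[np.ndarray] = []
    for i, call in enumerate(eligible):
        pos = [s.utr_start for s in by_gene.get(call.gene_id, ())
               if s.conserved or not conserved_only]
        if pos:
            site_pos_parts.append(np.asarray(pos, dtype=np.int64))
            site_gene_idx_parts.append(np.full(len(pos), i, dtype=np.int64))
    site_pos = (np.concatenate(site_pos_parts) if site_pos_parts
                else np.empty(0, dtype=np.int64))
    site_gene = (np.concatenate(site_gene_idx_parts) if site_gene_idx_parts
                 else np.empty(0, dtype=np.int64))
    lengths = np.asarray([c.utr.length for c in eligible], dtype=np.int64)

    rng = np.random.default_rng(seed)
    null_counts = np.zeros((n_iter, n_bins), dtype=np.int64)
    chunk = max(1, _CHUNK_ELEMENTS // max(1, len(site_pos)))
    for start in range(0, n_iter, chunk):
        m = min(chunk, n_iter - start)
        anchors = rng.integers(flank, lengths - flank,
                               size=(m, len(eligible)))
        if len(site_pos):
            d = site_pos[None, :] - anchors[:, site_gene]
            valid = (d >= -flank) & (d < flank)
            ii, jj = np.nonzero(valid)
            bins = (d[ii, jj] + flank) // bin_width
            np.add.at(null_counts, (start + ii, bins), 1)
    p, p_rand = _permutation_p(obs, null_counts, n_iter, rng)
    return NullEnsemble(edges, obs, null_counts, p, p_rand, n_iter, seed,
                        len(eligible))


def _null_sd(null: np.ndarray) -> np.ndarray:
    if null.shape[0] < 2:
        return np.full(null.shape[1], np.nan)
    return null.std(axis=0, ddof=1)


def _random_subset_indicator(rng: np.random.Generator, n_iter: int,
                             n_total: int, n_pick: int) -> np.ndarray:
    """(n_iter, n_total) boolean matrix; each row marks a uniform random
    subset of size ``n_pick``."""
    r = rng.random((n_iter, n_total))
    order = np.argsort(r, axis=1)
    ind = np.zeros((n_iter, n_total), dtype=bool)
    np.put_along_axis(ind, order[:, :n_pick], True, axis=1)
    return ind


def two_set_partition_test(setA: Iterable[str], setB: Iterable[str],
                           calls: Sequence[ApaCall],
                           sites: Iterable[SeedSite],
                           flank: int = DEFAULT_FLANK,
                           bin_width: int = DEFAULT_BIN_WIDTH,
                           n_iter: int = DEFAULT_N_ITER,
                           seed: int = 0) -> PermutationTestResult:
    """Per-bin test of conserved-site density in setB against setA.

    The statistic is ``density_B - density_A`` per bin, density being
    conserved sites per contributing gene. The null re-partitions the union
    of the two sets into random groups of the original sizes; the one-sided
    p-value asks whether the real partition's excess in setB is as large as
    random partitions produce.
    """
    setA, setB = set(setA), set(setB)
    if not setA or not setB:
        raise ValueError("both gene sets must be non-empty")
    if setA & setB:
        raise ValueError("gene sets must be disjoint")
    union = setA | setB
    covered = [c for c in calls if c.gene_id in union]
    if not covered:
        raise ValueError("no APA-covered genes in either set")
    in_b = np.asarray([c.gene_id in setB for c in covered])
    nB = int(in_b.sum())
    nA = len(covered) - nB
    if nA == 0 or nB == 0:
        raise ValueError("a gene set has no APA-covered genes")
    M = _per_gene_bin_counts(covered, sites, "apa", flank, bin_width, True)
    obs = M[in_b].sum(axis=0) / nB - M[~in_b].sum(axis=0) / nA

    rng = np.random.default_rng(seed)
    ind = _random_subset_indicator(rng, n_iter, len(covered), nB)
    Mf = M.astype(np.float64)
    null = ind @ Mf / nB - (~ind) @ Mf / nA
    p, p_rand = _permutation_p(obs, null, n_iter, rng)
    edges = _check_geometry(flank, bin_width)
    return PermutationTestResult(edges, obs, p, p_rand, n_iter, seed,
                                 (nA, nB),
                                 null.mean(axis=0), _null_sd(null))


def cluster_vs_all_test(cluster_families: Iterable[str],
                        calls: Sequence[ApaCall],
                        sites: Sequence[SeedSite],
                        flank: int = DEFAULT_FLANK,
                        bin_width: int = DEFAULT_BIN_WIDTH,
                        n_iter: int = DEFAULT_N_ITER,
                        seed: int = 0,
                        anchor: str = "apa",
                        null_model: str = "relabel") -> PermutationTestResult:
    """Per-bin test of conserved-site density in cluster-target genes
    against all profiled genes.

    Target genes carry >= 1 conserved site of any cluster family anywhere
    in their UTR. The statistic per bin is
    ``density(targets) - density(all genes)`` over all conserved sites.

    ``null_model='relabel'`` (default) permutes family labels over all
    conserved sites and re-derives the target set each iteration; family
    labels are exchangeable when the cluster has no positional preference,
    so this null is calibrated. ``null_model='subset'`` draws random gene
    subsets of the target-set size instead; because the real target set is
    conditioned on owning sites, that null is biased liberal and is kept
    only for comparison with the subset-randomization scheme.
    """
    fams = set(cluster_families)
    cons = [s for s in sites if s.conserved]
    gene_index = {c.gene_id: i for i, c in enumerate(calls)}
    target_genes = {s.gene_id for s in cons if s.family_id in fams}
    in_t = np.asarray([c.gene_id in target_genes for c in calls])
    nT = int(in_t.sum())
    if nT == 0:
        raise ValueError("no profiled gene carries a conserved cluster-family site")
    M = _per_gene_bin_counts(calls, sites, anchor, flank, bin_width, True)
    Mf = M.astype(np.float64)
    all_density = M.sum(axis=0) / len(calls)
    obs = M[in_t].sum(axis=0) / nT - all_density

    rng = np.random.default_rng(seed)
    edges = _check_geometry(flank, bin_width)
    if null_model == "subset":
        ind = _random_subset_indicator(rng, n_iter, len(calls), nT)
        null = ind @ Mf / nT - all_density[None, :]
    elif null_model == "relabel":
        site_gene = np.asarray([gene_index[s.gene_id] for s in cons
                                if s.gene_id in gene_index])
        n_cluster_sites = sum(1 for s in cons if s.family_id in fams
                              and s.gene_id in gene_index)
        if len(site_gene) == 0 or n_cluster_sites == 0:
            raise ValueError("no conserved sites in profiled genes")
        incidence = np.zeros((len(site_gene), len(calls)))
        incidence[np.arange(len(site_gene)), site_gene] = 1.0
        null = np.empty((n_iter, M.shape[1]))
        chunk = max(1, _CHUNK_ELEMENTS // max(1, len(site_gene)))
        for start in range(0, n_iter, chunk):
            m = min(chunk, n_iter - start)
            sel = _random_subset_indicator(rng, m, len(site_gene),
                                           n_cluster_sites)
            gene_hits = sel.astype(np.float64) @ incidence  # (m, n_genes)
            in_t_null = gene_hits > 0
            sizes = in_t_null.sum(axis=1)
            sizes[sizes == 0] = 1
            null[start:start + m] = (in_t_null @ Mf) / sizes[:, None] \
                - all_density[None, :]
    else:
        raise ValueError("null_model must be 'relabel' or 'subset'")
    p, p_rand = _permutation_p(obs, null, n_iter, rng)
    return PermutationTestResult(edges, obs, p, p_rand, n_iter, seed,
                                 (nT, len(calls)),
                                 null.mean(axis=0), _null_sd(null))


def score_window_compare(calls: Sequence[ApaCall],
                         sites: Iterable[SeedSite],
                         window: int = 300,
                         min_flank: int = 500,
                         kind: str = "pct",
                         conserved_only: bool | None = None,
                         welch: bool = False) -> ScoreCompareResult:
    """Compare site scores immediately 5' vs 3' of the APA site.

    Groups: sites with ``utr_start`` in ``[apa - window, apa)`` (5') vs
    ``[apa, apa + window)`` (3'), over genes with >= ``min_flank`` nt each
    side of the anchor. ``conserved_only=True/False`` restricts to
    conserved / non-conserved sites; ``None`` uses all scored sites.
    Returns a two-sided Student t-test (pooled variance unless ``welch``);
    the t sign is mean(5') - mean(3').
    """
    attr = {"pct": "pct", "context": "context_score"}[kind]
    kept = filter_flank(calls, min_flank)
    by_gene = _sites_by_gene(sites)
    g5, g3 = [], []
    for call in kept:
        a = call.apa_pos
        for s in by_gene.get(call.gene_id, ()):
            val = getattr(s, attr)
            if val is None:
                continue
            if conserved_only is not None and s.conserved != conserved_only:
                continue
            if a - window <= s.utr_start < a:
                g5.append(val)
            elif a <= s.utr_start < a + window:
                g3.append(val)
    if len(g5) < 2 or len(g3) < 2:
        raise ValueError(
            f"need >= 2 scored sites per window, got {len(g5)} / {len(g3)}")
    t, p = stats.ttest_ind(g5, g3, equal_var=not welch)
    return ScoreCompareResult(float(np.mean(g5)), float(np.mean(g3)),
                              float(t), float(p), len(g5), len(g3))


def relative_position_compare(utrs_a: Sequence[UTRModel],
                              utrs_b: Sequence[UTRModel],
                              sites: Iterable[SeedSite],
                              min_len: int = 1000,
                              conserved_only: bool = True,
                              welch: bool = False) -> RelPosResult:
    """Compare where conserved sites sit along the full-length UTR between
    two gene classes (e.g. APA-positive vs APA-negative genes).

    Each site maps to ``utr_start / utr.length`` in [0, 1); the two
    relative-position samples are compared by a two-sided Student t-test
    (sign: mean_a - mean_b; a larger mean = sites lie more distally).
    Decile densities (sites per gene per 10%-bin) are returned for both
    classes.
    """
    by_gene = _sites_by_gene(sites)

    def collect(utrs: Sequence[UTRModel]) -> tuple[np.ndarray, int]:
        rels = []
        n_genes = 0
        for u in utrs:
            if u.length < min_len:
                continue
            n_genes += 1
            for s in by_gene.get(u.gene_id, ()):
                if conserved_only and not s.conserved:
                    continue
                rels.append(s.utr_start / u.length)
        return np.asarray(rels), n_genes

    rel_a, na_genes = collect(utrs_a)
    rel_b, nb_genes = collect(utrs_b)
    if len(rel_a) < 2 or len(rel_b) < 2:
        raise ValueError("need >= 2 sites in each gene class")
    t, p = stats.ttest_ind(rel_a, rel_b, equal_var=not welch)
    dec_a = np.histogram(rel_a, bins=10, range=(0, 1))[0] / max(na_genes, 1)
    dec_b = np.histogram(rel_b, bins=10, range=(0, 1))[0] / max(nb_genes, 1)
    return RelPosResult(float(t), float(p), float(rel_a.mean()),
                        float(rel_b.mean()), len(rel_a), len(rel_b),
                        dec_a, dec_b)


def write_profile_tsv(profile: PositionalProfile,
                      path: str | os.PathLike,
                      ensemble: NullEnsemble | None = None,
                      params: Mapping[str, object] | None = None) -> None:
    """Profile (and optional null summary / p-values) as TSV."""
    with open(path, "w") as fh:
        from apamir import __version__
        fh.write(f"# apamir {__version__}")
        if params:
            fh.write(" " + " ".join(f"{k}={v}" for k, v in sorted(params.items())))
        fh.write("\n")
        cols = ["bin_start", "bin_end", "count_conserved", "count_nonconserved",
                "genes_per_bin"]
        if ensemble is not None:
            cols += ["null_mean", "null_sd", "p_value"]
        fh.write("\t".join(cols) + "\n")
        nm = ensemble.null_mean() if ensemble is not None else None
        ns = ensemble.null_sd() if ensemble is not None else None
        for i in range(profile.n_bins):
            row = [str(profile.bin_edges[i]), str(profile.bin_edges[i + 1]),
                   str(profile.counts_conserved[i]),
                   str(profile.counts_nonconserved[i]),
                   str(profile.genes_per_bin[i])]
            if ensemble is not None:
                row += [f"{nm[i]:.4f}", f"{ns[i]:.4f}",
                        f"{ensemble.p_values[i]:.6g}"]
            fh.write("\t".join(row) + "\n")
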