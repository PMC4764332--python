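# Methods

This note documents the models and procedures `apamir` implements, the
parameters that matter, what the synthetic-data generator does and does
not emulate, and the numerical conventions chosen where the design was
genuinely open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinate conventions

All internal coordinates are 0-based, half-open, BED-style; any external
dialect is converted on read. A 3'UTR model orders its exonic intervals
5'→3' in transcript sense and stores the transcript-sense sequence, so
UTR position 0 is the 5'-most base regardless of strand; the
genomic↔UTR-relative mapping is bijective over UTR bases and returns a
sentinel outside them. When a gene has several transcript accessions,
downstream gene-level analyses use the longest UTR (ties broken by
lexicographically smallest accession, for determinism). N bases are legal
in sequences: they never match a seed and carry no conservation score.
Missing conservation values are NaN throughout — never silently 0.

## Cleavage-site calling

Reads from all samples are pooled. **Read runs** are maximal clusters in
which consecutive occupied positions lie < `gap_max` (default 10) nt
apart; runs never span strands or chromosomes. Candidate sites are local
maxima of the per-position read counts (a position whose count is ≥ both
neighbours'; a plateau of adjacent equal maxima keeps only its 5'-most
position — lowest coordinate on +, highest on −). Candidates are then
filtered greedily by descending support, ties resolved 5'-most first: a
candidate within `min_spacing − 1` nt (default spacing 50) of a kept site
is dropped, so kept sites are pairwise ≥ 50 nt apart; "at least 50"
is implemented as ≥ 50 and is configurable. The support floor
(`min_support`, default 10 reads *at the run maximum*) applies after
spacing resolution. The output table reports both the occupied span
(last − first + 1) and the number of occupied positions of each run.
The module uses no randomness; output is invariant to read order.

**Internal-priming filter.** Oligo-dT primers anneal to genomically
encoded A-rich stretches and produce spurious 3' ends. For each candidate
site the 50 nt of genomic sequence centred on it (realized as
`[pos − 25, pos + 25)`; reverse-complemented for minus-strand sites so
the scan runs on transcript sense, the strand mispriming actually reads)
is scanned for any 10-mer with ≥ 8 A and the remaining bases all G.
Windows running off a contig are truncated with a warning.

## APA assignment

A site is assigned to a gene when it falls inside the 3'UTR coordinates
or within 20 nt past the annotated 3' end (`tail_slack`); slack hits are
clamped to the last UTR base for distance computations. Sites flagged as
internal priming are excluded by default (configurable). A gene is
APA-positive with ≥ 2 assigned sites; the anchor of all positional
analyses is the 5'-most one, and the 3'-most assigned site stands in for
the full-length UTR end where an analysis anchors there (falling back to
the annotated end when no site was assigned). A site falling in two
overlapping genes' UTRs is assigned to both, and both calls are marked
`shared`. Per-sample APA calls (a gene APA-positive "in at least one
sample") use per-sample read support against the same support floor.

## Seed matching

A binding site is the exact 7-mer reverse complement of miRNA seed bases
2–8; overlapping occurrences and multiple families at one position are
all reported, and wobble or 6/8-mer variants are out of scope. A site's
position is the 5' end of its 7-mer (configurable to the midpoint in the
distance computations by shifting anchors; distances here always use the
5' end). Conservation flags and per-site scores come from external
tables keyed by (gene, UTR position, family); before use, each table is
validated by checking that the 7-mer at every listed position matches the
family's site sequence — > 5% mismatches aborts with a
coordinate-system error. The scan channel (all perfect 7-mers) and the
table channel (externally curated conserved/scored sites) are kept
separate and never conflated.

## Positional statistics

Profiles bin each site's signed distance to its gene's anchor into 100-nt
bins over ±1,000 nt (both configurable; the flank must be a multiple of
the bin width, and 300-nt analysis windows align with bin edges). Binning
is half-open: a site exactly at the anchor counts in the first
downstream bin. Only genes with ≥ flank nt of UTR on each side of the
anchor contribute, so every profiled gene covers every bin. Conserved and
non-conserved sites are tallied separately.

**Randomized-anchor null.** Genes with UTR length > 2·flank each draw a
pseudo-anchor uniformly from `[flank, length − flank)` per iteration
(default 10,000 iterations), and the binned count is recomputed. The
per-bin one-sided p-value asks whether the observed count is as high as
the null produces.

**Two-set partition test.** The per-bin statistic is the difference in
conserved sites per contributing gene between two disjoint gene sets
(B − A). The null re-partitions their union into random groups of the
original sizes. Per-gene density normalization makes unequal cohort
sizes comparable; with equal-size randomized cohorts it reduces to a
count comparison.

**Cluster-vs-all test.** Target genes are those carrying ≥ 1 conserved
site of any designated cluster family. The statistic is the per-gene
conserved-site density difference between targets and all profiled
genes. The default null permutes family labels over all conserved sites
and re-derives the target set each iteration. This choice is deliberate:
a null of random same-size *gene subsets* is not exchangeable with the
observed target set — targets are selected for owning sites, so they
out-density random subsets in every bin even without any positional
signal, and the subset null is biased liberal. Label permutation keeps
the site geometry fixed and randomizes exactly what the hypothesis is
about (which family sits where); it is calibrated under the no-signal
condition. The subset scheme remains available as
`null_model="subset"` for comparison.

**P-value estimators.** All permutation/randomization p-values are the
one-sided +1-corrected estimator `(1 + #{null ≥ obs}) / (1 + N)`; they
are never exactly 0 and, because the statistics are counts (or count
differences), they are mildly conservative wherever null ties occur —
a property of any deterministic rank estimator on a discrete statistic.
Each test therefore also returns `p_values_randomized`, which places the
observation uniformly within its tie group; that variant is exactly
Uniform(0,1] when observed and null are exchangeable and is the right
quantity for calibration diagnostics. Inference should use the
deterministic values. No multiple-testing correction is applied across
bins; raw per-bin p-values are reported and correction is left to the
caller. With a fixed seed every ensemble is bit-reproducible.

**Score and position comparisons.** Site scores (P_CT, context++) are
compared between the windows 300 nt 5' and 3' of the anchor (genes with
≥ 500 nt on each side) by a two-sided pooled-variance Student t-test
(Welch available by flag); the t sign is mean(5') − mean(3') and
direction interpretation is left to the caller, since sidedness is a
reporting choice. Relative site positions (site / UTR length ∈ [0,1))
are compared between gene classes the same way, with per-class decile
densities returned for plotting.

## Conservation profiles

Anchors (APA positions, or seed-site starts) map to strand-aware genomic
bases; the profile is the per-offset mean of the track over anchors with
a non-missing score there, with the contributing count per offset.
Site-anchored profiles use offsets `[−12, +19)` so the 7-mer occupies
offsets `[0, 7)` with 12 nt of 5' and 12 nt of 3' context — a 31-offset
window; the placement of the window around the 7-mer is a convention,
fixed here and configurable. Genes can be split by presence of a
conserved site in the 300 nt 5' of the APA anchor to compare profiles
between site-bearing and site-free genes.

## Codon-usage gene sets

A gene's codon-usage vector is the relative frequency of the 61 sense
codons in its CDS (one terminal stop trimmed; internal stops and length
≢ 0 mod 3 are errors). Expansion admits every gene whose Pearson
correlation with the seed set's *centroid* (arithmetic mean of member
vectors) reaches the threshold, on raw frequencies — not amino-acid-
normalized adaptiveness values, which is the simplest reading of "codon
usage correlation"; seed genes are always retained, and expansion is
monotone in the threshold. When two sets are expanded jointly, a gene
qualifying for both goes to the one it correlates with more; an exact tie
excludes it.

## The synthetic-data generator

The generator emits every input the pipeline consumes — genome FASTA,
UTR BED12, CDS FASTA, read-ends BED6 (≥ 2 samples), seed table,
conserved-site and score tables, conservation bedGraph, gene-set TSV —
plus a ground-truth object consistent with the files. All randomness
flows from one seed; a fixed seed reproduces the bundle bit-identically.

What it emulates, per gene: a distal cleavage site at the UTR end and,
with probability `apa_fraction` (default 0.5, comparable to the fraction
of genes with detectable APA in 3'-end data), a proximal site uniform in
[0.2, 0.8] of the UTR; UTR lengths log-normal (median 1,500 nt, log-sd
0.6, truncated to [300, 10,000]), matching the scale of mammalian
3'UTRs; read support per site negative-binomial (mean 60, dispersion 3,
clipped to [20, 200]). Reads fluctuate around the major site: a fraction
(default 0.5) jitter by rounded N(0, 2 nt), the rest sit exactly on it.
This split is deliberate — real 3'-end data concentrates most reads on a
dominant position with satellites nearby; jittering *every* read at
σ = 2 would cap the run maximum near 20% of the support, making the
≥ 10-reads-at-the-maximum rule unable to recover low-support sites at
all.

Conserved seed sites are planted at 1.0 site/kb background (non-conserved
at 4.0/kb), with `enrichment_factor` × background (default 3×) inside the
300 nt 5' of the proximal site for the enriched ("pro-differentiation")
class — 15% of genes, with another 15% forming the contrast class —
and a 2× excess in the last 300 nt of non-APA genes' UTRs (the
distal-end pattern of genes that never shorten). Sites in the enrichment
window draw "cluster" families preferentially (4 of 10 families, 70%
weight), carry higher P_CT-like scores (Beta(8,2) vs Beta(3,3)) and
stronger context-like scores (N(−0.40, 0.10) vs N(−0.15, 0.08)).
Enrichment windows are truncated at the UTR start when a proximal site
sits closer than 300 nt to it; the generator errors only if no
enriched-class gene can host any window sites. A-rich decoy clusters
(8 A + 2 G 10-mers written into the genome, read support 12–30, 0.1 per
gene) exercise the internal-priming filter specifically: they pass the
support floor and must be removed by composition. The conservation track
is 0.2 ± 0.05 background with planted conserved-site bases at 0.9, and
has gaps between genes so missing-value handling is exercised. CDSs
(300–600 codons) draw codons from two antipodal class centres 0.2 apart
(Euclidean) around the flat 1/61 vector. That separation was set by a
design calculation, not tuning: with realistic CDS lengths, multinomial
sampling noise is ~6×10⁻³ per component, so a smaller separation (e.g.
0.08) would cap within-class centroid correlations near 0.6 and make
threshold-0.75 expansion unable to recover the classes in principle.

What it does **not** emulate: real genomic sequence composition beyond
40% GC, multi-exon UTRs (the mapping code supports them and is tested on
constructed models; generated UTRs are single-exon), overlapping genes,
expression-dependent read depth, sequencing error, isoform-specific
annotation ambiguity, or any correlation between codon usage and UTR
geometry beyond the planted class labels. Passing the synthetic battery
therefore demonstrates that the algorithms recover the structure they
target under realistic noise and geometry — not that every property
holds on real data with its unmodelled covariates.

## Validation studies and problem sizes

The studies in `apamir.studies` (run by the test suite and by
`scripts/acceptance.py`):

* **Recovery** runs the full read-level pipeline on one default
  1,000-gene cohort and scores planted-site recovery with 5-nt position
  tolerance.
* **Calibration** uses 50 no-signal cohorts (enrichment factors 1.0) of
  17,500 genes each, 1,000 randomization iterations per test, and pools
  the per-bin randomized p-values across cohorts for a KS test against
  Uniform(0,1); the deterministic estimator's rejection rate at 0.05 is
  checked to be at-or-below nominal. Positional cohorts skip sequence
  realization (the planted positions feed the statistics directly), which
  is exact for these tests and keeps 100 cohorts tractable.
* **Power** uses 50 default-condition cohorts of the same size and asks,
  per cohort, whether every bin in [−300, 0) reaches p < 0.05 — for the
  class-contrast partition test and for the randomized-anchor null on the
  enriched class's genes.
* **Score agreement** compares `score_window_compare` with a hand-written
  pooled-t computation and with a 10,000-draw label permutation.
* **Expansion** scores codon-usage class recovery of competing expansion
  at threshold 0.75 on a 400-gene bundle.

The 17,500-gene cohort size was chosen so the flank-filtered two-class
union (≈ 365 genes) matches the scale of a genome-wide partition
contrast between expanded gene sets, and is consistent with the human
protein-coding gene count; 1,000 iterations is the per-cohort ensemble
size for the 50-cohort batteries, while single-cohort analyses default
to 10,000 iterations.

## Known limitations

* The conservative deterministic p-values and the exactly-uniform
  randomized variant differ most when per-bin counts are small; with few
  profiled genes, per-bin inference is weak regardless of estimator.
* The cluster-vs-all subset null reproduces a published randomization
  scheme but is liberal by construction (see above); it is not the
  default.
* Internal-priming filtering is a composition heuristic; genuine sites in
  A-rich context are discarded with the artifacts.
* Gene-set expansion by centroid correlation has no significance control;
  the threshold is a tuning parameter, and reported set sizes depend on
  it strongly.
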