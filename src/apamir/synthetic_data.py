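"""Synthetic input generator with ground-truth bookkeeping.

Emulates the statistical structure the pipeline's analyses assume: genes
with a distal cleavage site at the 3'UTR end and (for a configurable
fraction) a proximal APA site; 3'-end reads with Gaussian positional
jitter and negative-binomial support; A-rich internal-priming decoy
clusters; planted 7-mer seed-match sites with a configurable density
excess in a window 5' of the proximal APA position (stronger in one
designated gene class and for "cluster" miRNA families); conservation
scores elevated on planted conserved-site bases; per-site P_CT-like and
context-like scores stronger for sites in the 5'-of-APA window; and two
gene classes with distinct codon-usage biases plus an inert background
class.

All randomness flows from ``SimConfig.seed`` through one
``numpy.random.Generator``; a fixed seed reproduces the bundle
bit-identically.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from apamir import cs_calling
from apamir.apa_assignment import ApaCall
from apamir.cs_calling import CleavageSite
from apamir.io_formats import (
    ConservationTrack,
    GenomicInterval,
    ReadEnd3p,
    UTRModel,
    reverse_complement,
    write_read_ends,
    write_utr_models,
)
from apamir.site_mapping import MirnaSeed, SeedSite, write_seed_table

_BASES = np.array(list("ACGT"))
# 40% GC background
_BASE_P = np.array([0.30, 0.20, 0.20, 0.30])

SITE_LEN = 7
CLASS_BACKGROUND = "background"
CLASS_PRODIFF = "prodiff"
CLASS_PROPROLIF = "proprolif"


@dataclass
class SimConfig:
    """Generator parameters; defaults define the study conditions.

    Lengths in nucleotides, densities in sites per kb, supports in reads.
    """

    n_genes: int = 1000
    genes_per_contig: int = 50
    utr_len_median: float = 1500.0
    utr_len_log_sd: float = 0.6
    utr_len_min: int = 300
    utr_len_max: int = 10_000
    apa_fraction: float = 0.5
    # read support per cleavage site: negative binomial, clipped
    read_support_mean: float = 60.0
    read_support_dispersion: float = 3.0
    read_support_min: int = 20
    read_support_max: int = 200
    jitter_sd: float = 2.0
    jitter_fraction: float = 0.5
    n_samples: int = 2
    # seed-match site placement
    n_seed_families: int = 10
    n_cluster_families: int = 4
    site_density_background: float = 1.0
    site_density_nonconserved: float = 4.0
    enrichment_window: int = 300
    enrichment_factor: float = 3.0
    cluster_site_fraction_in_window: float = 0.7
    enriched_class_fraction: float = 0.15
    other_class_fraction: float = 0.15
    distal_window: int = 300
    distal_enrichment_factor: float = 2.0
    # internal-priming decoys
    internal_priming_decoy_rate: float = 0.1
    decoy_support_min: int = 12
    decoy_support_max: int = 30
    # conservation track
    conservation_base: float = 0.2
    conservation_site: float = 0.9
    conservation_noise_sd: float = 0.05
    # per-site scores
    pct_background: tuple[float, float] = (3.0, 3.0)   # Beta(a, b)
    pct_window: tuple[float, float] = (8.0, 2.0)
    context_background: tuple[float, float] = (-0.15, 0.08)  # Normal(mu, sd)
    context_window: tuple[float, float] = (-0.40, 0.10)
    # codon usage: two antipodal Dirichlet-style centres this far apart
    # (Euclidean) around the flat 1/61 vector
    codon_center_distance: float = 0.2
    cds_codons_min: int = 300
    cds_codons_max: int = 600
    seed_set_size: int = 40
    seed: int = 0

    @property
    def cluster_family_ids(self) -> tuple[str, ...]:
        return tuple(f"fam{i:02d}" for i in range(self.n_cluster_families))

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("pct_background", "pct_window",
                    "context_background", "context_window"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | os.PathLike) -> None:
        data = asdict(self)
        for key in ("pct_background", "pct_window",
                    "context_background", "context_window"):
            data[key] = list(data[key])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


@dataclass
class PlantedSite:
    utr_start: int
    family_id: str
    conserved: bool
    in_window: bool  # inside the enrichment window 5' of the proximal CS
    pct: float | None = None
    context_score: float | None = None


@dataclass
class GeneTruth:
    gene_id: str
    chrom: str
    strand: str
    utr_gstart: int  # genomic start of the (single-exon) UTR interval
    utr_gend: int
    length: int
    class_label: str
    distal_cs_utr: int
    proximal_cs_utr: int | None
    sites: list[PlantedSite] = field(default_factory=list)
    decoy_utr_positions: list[int] = field(default_factory=list)
    cs_support: dict[int, int] = field(default_factory=dict)  # utr pos -> reads

    @property
    def is_apa(self) -> bool:
        return self.proximal_cs_utr is not None


@dataclass
class GroundTruth:
    config: SimConfig
    genes: dict[str, GeneTruth]
    cluster_families: tuple[str, ...]
    seed_sets: dict[str, set[str]]

    def class_members(self, label: str) -> set[str]:
        return {g for g, t in self.genes.items() if t.class_label == label}


@dataclass
class SimBundle:
    """Everything the pipeline consumes, in memory, plus the ground truth."""

    config: SimConfig
    genome: dict[str, str]
    utrs: list[UTRModel]
    read_ends: list[ReadEnd3p]
    seeds: list[MirnaSeed]
    conserved_table: pd.DataFrame
    pct_table: pd.DataFrame
    context_table: pd.DataFrame
    track: ConservationTrack
    cds: dict[str, str]
    gene_sets: dict[str, set[str]]
    truth: GroundTruth

    def write(self, out_dir: str | os.PathLike) -> None:
        """Write the bundle as the pipeline's external file formats."""
        out = str(out_dir)
        os.makedirs(out, exist_ok=True)
        with open(os.path.join(out, "genome.fa"), "w") as fh:
            for chrom in sorted(self.genome):
                fh.write(f">{chrom}\n")
                seq = self.genome[chrom]
                for i in range(0, len(seq), 60):
                    fh.write(seq[i:i + 60] + "\n")
        write_utr_models(self.utrs, os.path.join(out, "utrs.bed"))
        write_read_ends(self.read_ends, os.path.join(out, "reads.bed"))
        write_seed_table(self.seeds, os.path.join(out, "seeds.tsv"))
        self.conserved_table.to_csv(os.path.join(out, "conserved_sites.tsv"),
                                    sep="\t", index=False)
        self.pct_table.to_csv(os.path.join(out, "pct.tsv"),
                              sep="\t", index=False)
        self.context_table.to_csv(os.path.join(out, "context.tsv"),
                                  sep="\t", index=False)
        self.track.to_bedgraph(os.path.join(out, "conservation.bedgraph"))
        with open(os.path.join(out, "cds.fa"), "w") as fh:
            for gene in sorted(self.cds):
                fh.write(f">{gene}\n")
                seq = self.cds[gene]
                for i in range(0, len(seq), 60):
                    fh.write(seq[i:i + 60] + "\n")
        with open(os.path.join(out, "genesets.tsv"), "w") as fh:
            for name in sorted(self.gene_sets):
                for g in sorted(self.gene_sets[name]):
                    fh.write(f"{name}\t{g}\n")
        self.config.to_yaml(os.path.join(out, "sim.yaml"))


def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.choice(4, size=n, p=_BASE_P)]


def _draw_seed_families(rng: np.random.Generator,
                        cfg: SimConfig) -> list[MirnaSeed]:
    """Distinct random 7-mers, none containing a homopolymer run >= 5
    (avoids colliding with the A/G internal-priming motif)."""
    site7s: list[str] = []
    while len(site7s) < cfg.n_seed_families:
        s = "".join(_BASES[rng.integers(0, 4, SITE_LEN)])
        if s in site7s:
            continue
        if any(b * 5 in s for b in "ACGT"):
            continue
        site7s.append(s)
    return [MirnaSeed(f"fam{i:02d}", s, True)
            for i, s in enumerate(site7s)]


def _truncated_lognormal(rng: np.random.Generator, cfg: SimConfig,
                         n: int) -> np.ndarray:
    out = np.empty(n, dtype=np.int64)
    need = np.arange(n)
    mu = np.log(cfg.utr_len_median)
    while len(need):
        draw = rng.lognormal(mu, cfg.utr_len_log_sd, size=len(need))
        ok = (draw >= cfg.utr_len_min) & (draw <= cfg.utr_len_max)
        out[need[ok]] = draw[ok].astype(np.int64)
        need = need[~ok]
    return out


def _nb_support(rng: np.random.Generator, cfg: SimConfig) -> int:
    r = cfg.read_support_dispersion
    p = r / (r + cfg.read_support_mean)
    return int(np.clip(rng.negative_binomial(r, p),
                       cfg.read_support_min, cfg.read_support_max))


def _place_nonoverlapping(rng: np.random.Generator, lo: int, hi: int,
                          n: int, occupied: list[tuple[int, int]],
                          width: int = SITE_LEN,
                          max_tries: int = 50) -> list[int]:
    """Uniformly place ``n`` width-nt features with starts in [lo, hi),
    rejecting overlap with ``occupied`` intervals (which is updated)."""
    placed: list[int] = []
    if hi <= lo:
        return placed
    for _ in range(n):
        for _try in range(max_tries):
            start = int(rng.integers(lo, hi))
            if all(start + width <= s or start >= e for s, e in occupied):
                occupied.append((start, start + width))
                placed.append(start)
                break
    return placed


def plan_cohort(cfg: SimConfig,
                rng: np.random.Generator | None = None) -> GroundTruth:
    """Draw the positional plan of a cohort: UTR lengths, class labels,
    cleavage sites, planted seed sites with scores, and decoy positions.

    This is the generative core; :func:`simulate` realizes it as sequences,
    reads, and files. Genomic coordinates are filled in by
    :func:`simulate`; here ``utr_gstart``/``utr_gend`` are placeholders.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n = cfg.n_genes
    lengths = _truncated_lognormal(rng, cfg, n)
    labels = np.full(n, CLASS_BACKGROUND, dtype=object)
    u = rng.random(n)
    labels[u < cfg.enriched_class_fraction] = CLASS_PRODIFF
    both = cfg.enriched_class_fraction + cfg.other_class_fraction
    labels[(u >= cfg.enriched_class_fraction) & (u < both)] = CLASS_PROPROLIF

    seeds = _draw_seed_families(rng, cfg)
    family_ids = [s.family_id for s in seeds]
    cluster = cfg.cluster_family_ids

    genes: dict[str, GeneTruth] = {}
    any_window_planted = False
    for i in range(n):
        gene_id = f"g{i:05d}"
        L = int(lengths[i])
        strand = "+" if rng.random() < 0.5 else "-"
        distal = L - 1
        proximal: int | None = None
        if rng.random() < cfg.apa_fraction:
            lo, hi = int(0.2 * L), int(0.8 * L)
            if hi > lo:
                proximal = int(rng.integers(lo, hi))
        gt = GeneTruth(gene_id, "", strand, 0, 0, L, str(labels[i]),
                       distal, proximal)

        occupied: list[tuple[int, int]] = []
        # background conserved sites, uniform over the UTR
        n_bg = rng.poisson(cfg.site_density_background * L / 1000.0)
        for pos in _place_nonoverlapping(rng, 0, L - SITE_LEN + 1, n_bg,
                                         occupied):
            fam = family_ids[rng.integers(0, len(family_ids))]
            gt.sites.append(PlantedSite(pos, fam, True, False))
        # enrichment window 5' of the proximal APA site, enriched class only
        if (proximal is not None and labels[i] == CLASS_PRODIFF
                and cfg.enrichment_factor > 1.0):
            w_lo = max(0, proximal - cfg.enrichment_window)
            extra = rng.poisson((cfg.enrichment_factor - 1.0)
                                * cfg.site_density_background
                                * cfg.enrichment_window / 1000.0)
            for pos in _place_nonoverlapping(rng, w_lo,
                                             max(w_lo + 1,
                                                 proximal - SITE_LEN + 1),
                                             extra, occupied):
                if rng.random() < cfg.cluster_site_fraction_in_window:
                    fam = cluster[rng.integers(0, len(cluster))]
                else:
                    fam = family_ids[rng.integers(0, len(family_ids))]
                gt.sites.append(PlantedSite(pos, fam, True, True))
                any_window_planted = True
        # distal-end excess of conserved sites in non-APA genes
        if proximal is None and cfg.distal_enrichment_factor > 1.0:
            d_lo = max(0, L - cfg.distal_window)
            extra = rng.poisson((cfg.distal_enrichment_factor - 1.0)
                                * cfg.site_density_background
                                * cfg.distal_window / 1000.0)
            for pos in _place_nonoverlapping(rng, d_lo, L - SITE_LEN + 1,
                                             extra, occupied):
                fam = family_ids[rng.integers(0, len(family_ids))]
                gt.sites.append(PlantedSite(pos, fam, True, False))
        # non-conserved sites, uniform
        n_nc = rng.poisson(cfg.site_density_nonconserved * L / 1000.0)
        for pos in _place_nonoverlapping(rng, 0, L - SITE_LEN + 1, n_nc,
                                         occupied):
            fam = family_ids[rng.integers(0, len(family_ids))]
            gt.sites.append(PlantedSite(pos, fam, False, False))
        # per-site scores: stronger (higher P_CT, lower context) in-window
        for s in gt.sites:
            pa, pb = cfg.pct_window if s.in_window else cfg.pct_background
            cm, cs_ = (cfg.context_window if s.in_window
                       else cfg.context_background)
            if s.conserved:
                s.pct = float(rng.beta(pa, pb))
            s.context_score = float(rng.normal(cm, cs_))
        gt.sites.sort(key=lambda s: (s.utr_start, s.family_id))

        # internal-priming decoy clusters, away from true cleavage sites
        if rng.random() < cfg.internal_priming_decoy_rate and L > 120:
            true_cs = [distal] + ([proximal] if proximal is not None else [])
            for _try in range(50):
                dpos = int(rng.integers(50, L - 50))
                if (all(abs(dpos - c) >= 60 for c in true_cs)
                        and all(dpos + 5 <= s or dpos - 5 >= e
                                for s, e in occupied)):
                    gt.decoy_utr_positions.append(dpos)
                    occupied.append((dpos - 5, dpos + 5))
                    break
        # read support per cleavage site and decoy
        gt.cs_support[distal] = _nb_support(rng, cfg)
        if proximal is not None:
            gt.cs_support[proximal] = _nb_support(rng, cfg)
        for dpos in gt.decoy_utr_positions:
            gt.cs_support[dpos] = int(rng.integers(cfg.decoy_support_min,
                                                   cfg.decoy_support_max + 1))
        genes[gene_id] = gt

    if (cfg.enrichment_factor > 1.0 and cfg.n_genes > 0
            and not any_window_planted
            and not any(t.class_label == CLASS_PRODIFF and t.is_apa
                        and t.proximal_cs_utr >= SITE_LEN
                        for t in genes.values())):
        raise ValueError("infeasible geometry: no enriched-class gene can "
                         "host the enrichment window")

    # seed gene sets: a sample of each biased class
    sets: dict[str, set[str]] = {}
    for name, label in (("mphase_like", CLASS_PROPROLIF),
                        ("pattern_like", CLASS_PRODIFF)):
        members = sorted(g for g, t in genes.items()
                         if t.class_label == label)
        k = min(cfg.seed_set_size, len(members))
        if k:
            pick = rng.choice(len(members), size=k, replace=False)
            sets[name] = {members[j] for j in pick}
        else:
            sets[name] = set()
    return GroundTruth(cfg, genes, cluster, sets)


def positional_view(truth: GroundTruth
                    ) -> tuple[list[ApaCall], list[SeedSite]]:
    """ApaCall/SeedSite views of the planted positions, bypassing sequence
    realization and site scanning (for statistics-level studies).

    The UTR models carry all-N sequences on per-gene pseudo-contigs; only
    lengths and positions are meaningful.
    """
    calls: list[ApaCall] = []
    sites: list[SeedSite] = []
    for gene_id in sorted(truth.genes):
        t = truth.genes[gene_id]
        utr = UTRModel(gene_id, gene_id,
                       [GenomicInterval(f"ctg_{gene_id}", 0, t.length, "+")],
                       "N" * t.length)
        cs = [t.distal_cs_utr]
        if t.proximal_cs_utr is not None:
            cs.insert(0, t.proximal_cs_utr)
        calls.append(ApaCall(gene_id, utr, cs))
        for s in t.sites:
            sites.append(SeedSite(gene_id, s.utr_start, s.family_id,
                                  s.conserved, s.pct, s.context_score))
    return calls, sites


def _codon_centers(distance: float) -> tuple[np.ndarray, np.ndarray]:
    """Two antipodal codon-frequency centres around the flat 1/61 vector,
    the given Euclidean distance apart, with a fixed +/- pattern."""
    pattern = np.ones(61)
    pattern[np.random.default_rng(2016).permutation(61)[:30]] = -1.0
    pattern -= pattern.mean()
    pattern /= np.linalg.norm(pattern)
    delta = pattern * distance / 2.0
    base = np.full(61, 1.0 / 61.0)
    a, b = base + delta, base - delta
    if (a <= 0).any() or (b <= 0).any():
        raise ValueError("codon_center_distance too large for positive "
                         "frequencies")
    return a / a.sum(), b / b.sum()


def _sample_cds(rng: np.random.Generator, cfg: SimConfig,
                center: np.ndarray) -> str:
    from apamir.genesets import SENSE_CODONS, STOP_CODONS

    n = int(rng.integers(cfg.cds_codons_min, cfg.cds_codons_max + 1))
    idx = rng.choice(61, size=n, p=center)
    stop = STOP_CODONS[rng.integers(0, len(STOP_CODONS))]
    return "ATG" + "".join(SENSE_CODONS[j] for j in idx) + stop


def simulate(cfg: SimConfig,
             out_dir: str | os.PathLike | None = None) -> SimBundle:
    """Generate a full input bundle (and optionally write it to disk)."""
    rng = np.random.default_rng(cfg.seed)
    truth = plan_cohort(cfg, rng)
    seeds = _draw_seed_families(np.random.default_rng(cfg.seed), cfg)
    seeds_by_id = {s.family_id: s for s in seeds}

    pad = 100      # conservation/IP context on each side of the UTR
    gap = 200      # spacing between genes on a contig
    genome: dict[str, list[str] | str] = {}
    utrs: list[UTRModel] = []
    read_ends: list[ReadEnd3p] = []
    track = ConservationTrack()
    conserved_rows: list[tuple[str, int, str]] = []
    pct_rows: list[tuple[str, int, str, float]] = []
    ctx_rows: list[tuple[str, int, str, float]] = []
    cds: dict[str, str] = {}
    sample_names = [f"sample{j + 1}" for j in range(cfg.n_samples)]
    centers = _codon_centers(cfg.codon_center_distance)
    flat = np.full(61, 1.0 / 61.0)

    gene_ids = sorted(truth.genes)
    cursor: dict[str, int] = {}
    for gi, gene_id in enumerate(gene_ids):
        t = truth.genes[gene_id]
        L = t.length
        chrom = f"chr{gi // cfg.genes_per_contig + 1}"
        pos0 = cursor.get(chrom, 0)

        # transcript-sense UTR sequence with planted features written in
        useq = _random_seq(rng, L)
        for s in t.sites:
            useq[s.utr_start:s.utr_start + SITE_LEN] = \
                list(seeds_by_id[s.family_id].site7)
        for dpos in t.decoy_utr_positions:
            motif = np.array(list("A" * 8 + "G" * 2))
            rng.shuffle(motif)
            lo = min(max(0, dpos - 5), L - 10)
            useq[lo:lo + 10] = motif
        useq_str = "".join(useq)

        utr_gstart = pos0 + pad
        utr_gend = utr_gstart + L
        t.chrom, t.utr_gstart, t.utr_gend = chrom, utr_gstart, utr_gend
        block = _random_seq(rng, pad + L + pad)
        if t.strand == "+":
            block[pad:pad + L] = list(useq_str)
        else:
            block[pad:pad + L] = list(reverse_complement(useq_str))
        genome.setdefault(chrom, [])
        genome[chrom].append("".join(block))
        genome[chrom].append("".join(_random_seq(rng, gap)))
        cursor[chrom] = pos0 + pad + L + pad + gap

        utr = UTRModel(gene_id, gene_id,
                       [GenomicInterval(chrom, utr_gstart, utr_gend,
                                        t.strand)],
                       useq_str)
        utrs.append(utr)

        # reads: jittered around each cleavage site / decoy
        for upos, support in t.cs_support.items():
            gpos = utr.utr_to_genomic(upos)
            # a major site carries most reads; the rest fluctuate around it
            jit = np.rint(rng.normal(0.0, cfg.jitter_sd,
                                     size=support)).astype(int)
            jit[rng.random(support) >= cfg.jitter_fraction] = 0
            which = rng.integers(0, cfg.n_samples, size=support)
            for j, dj in zip(which, jit):
                p = int(np.clip(gpos + dj, 0, cursor[chrom] - 1))
                read_ends.append(ReadEnd3p(chrom, p, t.strand,
                                           sample_names[j]))

        # conservation: base + noise over the padded span, site bases high
        span = pad + L + pad
        scores = np.clip(rng.normal(cfg.conservation_base,
                                    cfg.conservation_noise_sd, size=span),
                         0.0, 1.0)
        for s in t.sites:
            if not s.conserved:
                continue
            for k in range(SITE_LEN):
                g = utr.utr_to_genomic(s.utr_start + k) - pos0
                scores[g] = cfg.conservation_site
        track.set_scores(chrom, pos0, scores)

        # score/conservation tables for planted conserved sites
        for s in t.sites:
            if s.conserved:
                conserved_rows.append((gene_id, s.utr_start, s.family_id))
                pct_rows.append((gene_id, s.utr_start, s.family_id, s.pct))
            ctx_rows.append((gene_id, s.utr_start, s.family_id,
                             s.context_score))

        # CDS from the class's codon-usage centre
        center = {CLASS_PRODIFF: centers[0],
                  CLASS_PROPROLIF: centers[1]}.get(t.class_label, flat)
        cds[gene_id] = _sample_cds(rng, cfg, center)

    genome_str = {c: "".join(parts) for c, parts in genome.items()}
    conserved_table = pd.DataFrame(
        conserved_rows, columns=["gene_id", "utr_start", "family_id"])
    pct_table = pd.DataFrame(
        pct_rows, columns=["gene_id", "utr_start", "family_id", "score"])
    context_table = pd.DataFrame(
        ctx_rows, columns=["gene_id", "utr_start", "family_id", "score"])
    gene_sets = dict(truth.seed_sets)
    bundle = SimBundle(cfg, genome_str, utrs, read_ends, seeds,
                       conserved_table, pct_table, context_table, track,
                       cds, gene_sets, truth)
    if out_dir is not None:
        bundle.write(out_dir)
    return bundle


def truth_report(truth: GroundTruth,
                 called_sites: Sequence[CleavageSite],
                 apa_calls: Sequence[ApaCall] | None = None,
                 tolerance: int = 5,
                 min_support: int = cs_calling.DEFAULT_MIN_SUPPORT
                 ) -> dict[str, float]:
    """Recovery metrics of a pipeline run against the planted truth.

    Cleavage sites match by position within ``tolerance`` nt on the same
    chrom/strand; only planted sites whose support reaches ``min_support``
    count as recoverable. Called sites flagged as internal priming are
    excluded (they are the decoys' intended fate).
    """
    planted: dict[tuple[str, str], list[int]] = {}
    n_recoverable = 0
    for t in truth.genes.values():
        if not t.chrom:
            raise ValueError("truth lacks genomic coordinates; run simulate()")
        utr = UTRModel(t.gene_id, t.gene_id,
                       [GenomicInterval(t.chrom, t.utr_gstart, t.utr_gend,
                                        t.strand)],
                       "N" * t.length)
        for upos in ([t.distal_cs_utr]
                     + ([t.proximal_cs_utr] if t.is_apa else [])):
            if t.cs_support.get(upos, 0) >= min_support:
                planted.setdefault((t.chrom, t.strand), []).append(
                    utr.utr_to_genomic(upos))
                n_recoverable += 1
    kept = [s for s in called_sites if not s.internal_priming]
    n_matched_called = 0
    matched_planted: set[tuple[str, str, int]] = set()
    for s in kept:
        cands = planted.get((s.chrom, s.strand), ())
        hit = [g for g in cands if abs(g - s.pos) <= tolerance]
        if hit:
            n_matched_called += 1
            for g in hit:
                matched_planted.add((s.chrom, s.strand, g))
    report = {
        "n_planted_recoverable": float(n_recoverable),
        "n_called": float(len(kept)),
        "cs_recall": (len(matched_planted) / n_recoverable
                      if n_recoverable else float("nan")),
        "cs_precision": (n_matched_called / len(kept)
                         if kept else float("nan")),
    }
    if apa_calls is not None:
        true_apa = {g for g, t in truth.genes.items()
                    if t.is_apa
                    and t.cs_support[t.proximal_cs_utr] >= min_support
                    and t.cs_support[t.distal_cs_utr] >= min_support}
        found_apa = {c.gene_id for c in apa_calls if c.is_apa_positive}
        report["n_true_apa_genes"] = float(len(true_apa))
        report["apa_gene_recall"] = (
            len(true_apa & found_apa) / len(true_apa)
            if true_apa else float("nan"))
    return report
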