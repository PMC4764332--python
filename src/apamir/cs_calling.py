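"""Poly(A) cleavage-site (CS) calling from pooled 3'-end read positions.

Reads from all samples are pooled and clustered into "read runs": maximal
genomic intervals in which consecutive occupied positions are less than
``gap_max`` nt apart (default 10). Local maxima of the per-position read
counts within each run are CS candidates; candidates closer than
``min_spacing`` nt (default 50) are resolved greedily in favour of higher
read support, and surviving sites need at least ``min_support`` reads
(default 10) at the run maximum. A composition filter flags sites whose
surrounding genomic sequence contains an A/G-rich stretch diagnostic of
oligo-dT internal priming rather than a real poly(A) tail.

The module is fully deterministic: no RNG is used anywhere.
"""

from __future__ import annotations

import logging
import os
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from pyfaidx import Fasta

from apamir.io_formats import ReadEnd3p, reverse_complement

logger = logging.getLogger(__name__)

DEFAULT_GAP_MAX = 10
DEFAULT_MIN_SUPPORT = 10
DEFAULT_MIN_SPACING = 50
DEFAULT_IP_WINDOW = 50
DEFAULT_IP_K = 10
DEFAULT_IP_MIN_A = 8


@dataclass
class ReadRun:
    """A maximal cluster of 3'-end positions on one chrom/strand in which
    consecutive occupied positions are < ``gap_max`` apart."""

    chrom: str
    strand: str
    start: int
    end: int
    per_position_counts: dict[int, int]

    @property
    def total_count(self) -> int:
        return sum(self.per_position_counts.values())

    @property
    def occupied_span(self) -> int:
        """Distance from first to last occupied position, inclusive."""
        return self.end - self.start

    @property
    def n_occupied(self) -> int:
        return len(self.per_position_counts)


@dataclass
class CleavageSite:
    """A called cleavage position: the read-count maximum of its run."""

    chrom: str
    strand: str
    pos: int
    support: int
    run: ReadRun
    internal_priming: bool = False
    per_sample_support: dict[str, int] = field(default_factory=dict)


def build_runs(ends: Iterable[ReadEnd3p],
               gap_max: int = DEFAULT_GAP_MAX) -> list[ReadRun]:
    """Cluster pooled 3'-end positions into read runs.

    Single-linkage along the chromosome: two occupied positions join the
    same run iff their distance is strictly below ``gap_max``. Runs never
    span chromosomes or strands. Output order is (chrom, strand, start).
    """
    if gap_max < 1:
        raise ValueError("gap_max must be >= 1")
    counts: dict[tuple[str, str], Counter[int]] = defaultdict(Counter)
    for e in ends:
        counts[(e.chrom, e.strand)][e.pos] += 1
    runs: list[ReadRun] = []
    for (chrom, strand) in sorted(counts):
        c = counts[(chrom, strand)]
        positions = sorted(c)
        block: list[int] = [positions[0]]
        for pos in positions[1:]:
            if pos - block[-1] < gap_max:
                block.append(pos)
            else:
                runs.append(ReadRun(chrom, strand, block[0], block[-1] + 1,
                                    {p: c[p] for p in block}))
                block = [pos]
        runs.append(ReadRun(chrom, strand, block[0], block[-1] + 1,
                            {p: c[p] for p in block}))
    return runs


def _local_maxima(run: ReadRun) -> list[tuple[int, int]]:
    """(pos, count) candidates: positions whose count is >= both immediate
    neighbours (absent positions count 0). Of a tied plateau of adjacent
    equal-count maxima, only the 5'-most position is kept."""
    c = run.per_position_counts
    cands: list[tuple[int, int]] = []
    for pos in sorted(c):
        if c[pos] >= c.get(pos - 1, 0) and c[pos] >= c.get(pos + 1, 0):
            cands.append((pos, c[pos]))
    # collapse plateaus (runs of adjacent equal-count maxima) to their
    # 5'-most position: lowest coordinate on +, highest on -
    ordered = cands if run.strand == "+" else cands[::-1]
    step = 1 if run.strand == "+" else -1
    collapsed: list[tuple[int, int]] = []
    prev: tuple[int, int] | None = None
    for pos, cnt in ordered:
        is_plateau = (prev is not None and pos - prev[0] == step
                      and cnt == prev[1])
        prev = (pos, cnt)
        if is_plateau:
            continue
        collapsed.append((pos, cnt))
    return collapsed if run.strand == "+" else collapsed[::-1]


def call_sites(runs: Iterable[ReadRun],
               min_support: int = DEFAULT_MIN_SUPPORT,
               min_spacing: int = DEFAULT_MIN_SPACING) -> list[CleavageSite]:
    """Select cleavage sites from run local maxima.

    Per chrom/strand, candidates are taken greedily by descending support
    (ties: 5'-most first); a candidate within ``min_spacing - 1`` nt of an
    already kept site is dropped, so kept sites are pairwise >= min_spacing
    apart. The ``min_support`` floor is applied after spacing resolution.
    """
    if min_spacing < 1:
        raise ValueError("min_spacing must be >= 1")
    by_key: dict[tuple[str, str], list[tuple[int, int, ReadRun]]] = defaultdict(list)
    for run in runs:
        for pos, cnt in _local_maxima(run):
            by_key[(run.chrom, run.strand)].append((pos, cnt, run))
    sites: list[CleavageSite] = []
    for (chrom, strand) in sorted(by_key):
        cands = by_key[(chrom, strand)]
        # support desc; ties 5'-most first (plus: low coord, minus: high coord)
        if strand == "+":
            cands.sort(key=lambda t: (-t[1], t[0]))
        else:
            cands.sort(key=lambda t: (-t[1], -t[0]))
        kept: list[tuple[int, int, ReadRun]] = []
        for pos, cnt, run in cands:
            if all(abs(pos - kpos) >= min_spacing for kpos, _, _ in kept):
                kept.append((pos, cnt, run))
        for pos, cnt, run in kept:
            if cnt >= min_support:
                sites.append(CleavageSite(chrom, strand, pos, cnt, run))
    sites.sort(key=lambda s: (s.chrom, s.strand, s.pos))
    return sites


def is_internal_priming_window(window_seq: str,
                               k: int = DEFAULT_IP_K,
                               min_A: int = DEFAULT_IP_MIN_A) -> bool:
    """True iff any length-``k`` substring has >= ``min_A`` As and the
    remaining bases all G (transcript-sense sequence)."""
    seq = window_seq.upper()
    n = len(seq)
    if n < k:
        return False
    # rolling composition counts over the k-window
    a = sum(1 for b in seq[:k] if b == "A")
    g = sum(1 for b in seq[:k] if b == "G")
    if a >= min_A and a + g == k:
        return True
    for i in range(1, n - k + 1):
        out_b, in_b = seq[i - 1], seq[i + k - 1]
        a += (in_b == "A") - (out_b == "A")
        g += (in_b == "G") - (out_b == "G")
        if a >= min_A and a + g == k:
            return True
    return False


def flag_internal_priming(site: CleavageSite,
                          genome: Fasta | Mapping[str, str],
                          window: int = DEFAULT_IP_WINDOW,
                          k: int = DEFAULT_IP_K,
                          min_A: int = DEFAULT_IP_MIN_A) -> bool:
    """Flag a site as a suspected oligo-dT internal-priming artifact.

    Scans the ``window`` nt of genomic sequence centred on the site
    (realized as ``[pos - window//2, pos + window - window//2)``) on the
    transcript sense strand for a ``k``-mer of >= ``min_A`` As with the
    rest Gs. Windows running off the contig are truncated with a warning.
    """
    if window < k:
        raise ValueError("window must be >= k")
    half = window // 2
    start = site.pos - half
    end = site.pos + (window - half)
    if isinstance(genome, Fasta):
        contig_len = len(genome[site.chrom])
    else:
        contig_len = len(genome[site.chrom])
    if start < 0 or end > contig_len:
        logger.warning(
            "internal-priming window for %s:%d truncated at contig boundary",
            site.chrom, site.pos)
        start, end = max(start, 0), min(end, contig_len)
    if isinstance(genome, Fasta):
        seq = str(genome[site.chrom][start:end]).upper()
    else:
        seq = genome[site.chrom][start:end].upper()
    if site.strand == "-":
        seq = reverse_complement(seq)
    return is_internal_priming_window(seq, k=k, min_A=min_A)


def quantify_per_sample(site: CleavageSite,
                        ends: Iterable[ReadEnd3p],
                        samples: Sequence[str] | None = None) -> dict[str, int]:
    """Count read ends inside the site's run interval, per sample.

    ``samples`` fixes the key set (zero-filled); otherwise keys are the
    samples observed among ``ends``.
    """
    out: dict[str, int] = dict.fromkeys(samples or (), 0)
    for e in ends:
        if samples is None and e.sample not in out:
            out[e.sample] = 0
        if (e.chrom == site.chrom and e.strand == site.strand
                and site.run.start <= e.pos < site.run.end):
            out[e.sample] = out.get(e.sample, 0) + 1
    return out


def call_cleavage_sites(ends: Sequence[ReadEnd3p],
                        genome: Fasta | Mapping[str, str] | None = None,
                        gap_max: int = DEFAULT_GAP_MAX,
                        min_support: int = DEFAULT_MIN_SUPPORT,
                        min_spacing: int = DEFAULT_MIN_SPACING,
                        ip_window: int = DEFAULT_IP_WINDOW,
                        ip_k: int = DEFAULT_IP_K,
                        ip_min_A: int = DEFAULT_IP_MIN_A) -> list[CleavageSite]:
    """Full CS-calling pass: runs -> sites -> internal-priming flags ->
    per-sample quantification."""
    runs = build_runs(ends, gap_max=gap_max)
    sites = call_sites(runs, min_support=min_support, min_spacing=min_spacing)
    samples = sorted({e.sample for e in ends})
    by_key: dict[tuple[str, str], list[ReadEnd3p]] = defaultdict(list)
    for e in ends:
        by_key[(e.chrom, e.strand)].append(e)
    for site in sites:
        if genome is not None:
            site.internal_priming = flag_internal_priming(
                site, genome, window=ip_window, k=ip_k, min_A=ip_min_A)
        site.per_sample_support = quantify_per_sample(
            site, by_key.get((site.chrom, site.strand), ()), samples)
    return sites


def write_sites_tsv(sites: Sequence[CleavageSite], path: str | os.PathLike,
                    params: Mapping[str, object] | None = None) -> None:
    """Write called sites in the S2-style schema: RUN_S, RUN_E, RUN_MAX,
    SUPPORT, per-sample counts, InternalPrim_FLAG."""
    samples = sorted({s for site in sites for s in site.per_sample_support})
    with open(path, "w") as fh:
        from apamir import __version__
        fh.write(f"# apamir {__version__}")
        if params:
            fh.write(" " + " ".join(f"{k}={v}" for k, v in sorted(params.items())))
        fh.write("\n")
        cols = ["CHROM", "STRAND", "RUN_S", "RUN_E", "RUN_MAX", "SUPPORT",
                "RUN_SPAN", "RUN_N_OCCUPIED"]
        cols += [f"N_{s}" for s in samples] + ["InternalPrim_FLAG"]
        fh.write("\t".join(cols) + "\n")
        for s in sites:
            row = [s.chrom, s.strand, str(s.run.start), str(s.run.end),
                   str(s.pos), str(s.support), str(s.run.occupied_span),
                   str(s.run.n_occupied)]
            row += [str(s.per_sample_support.get(sm, 0)) for sm in samples]
            row.append("1" if s.internal_priming else "0")
            fh.write("\t".join(row) + "\n")


def read_sites_tsv(path: str | os.PathLike) -> list[CleavageSite]:
    """Read sites written by :func:`write_sites_tsv`."""
    sites: list[CleavageSite] = []
    with open(path) as fh:
        header: list[str] | None = None
        for raw in fh:
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if header is None:
                header = line.split("\t")
                continue
            rec = dict(zip(header, line.split("\t")))
            run = ReadRun(rec["CHROM"], rec["STRAND"], int(rec["RUN_S"]),
                          int(rec["RUN_E"]),
                          {int(rec["RUN_MAX"]): int(rec["SUPPORT"])})
            per_sample = {c[2:]: int(rec[c]) for c in header if c.startswith("N_")}
            sites.append(CleavageSite(
                rec["CHROM"], rec["STRAND"], int(rec["RUN_MAX"]),
                int(rec["SUPPORT"]), run,
                internal_priming=rec["InternalPrim_FLAG"] == "1",
                per_sample_support=per_sample))
    return sites
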