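"""Readers/writers for the pipeline's external formats and the shared
coordinate conventions.

All internal coordinates are 0-based half-open, BED-style. A 3'UTR model
(:class:`UTRModel`) owns the genomic<->UTR-relative mapping: UTR position 0
is the 5'-most transcript-sense base of the UTR, so on the minus strand it
corresponds to the highest genomic coordinate.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from pyfaidx import Fasta

#: Sentinel returned by coordinate mappers for positions outside the UTR.
NOT_IN_UTR = -1

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


class FormatError(ValueError):
    """Raised on malformed input files; message names the offending line."""


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ReadEnd3p:
    """Genomic coordinate of a transcript's last templated base before the
    poly(A) tail, as mapped from one 3'-end sequencing read."""

    chrom: str
    pos: int
    strand: str
    sample: str

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError("pos must be >= 0")
        if not self.sample:
            raise ValueError("sample label must be non-empty")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")


@dataclass
class UTRModel:
    """A gene's full-length 3'UTR: ordered exonic intervals plus the
    transcript-sense sequence, with bidirectional coordinate mapping.

    ``intervals`` are ordered 5'->3' in transcript sense: ascending genomic
    start on the plus strand, descending on the minus strand.
    """

    gene_id: str
    accession: str
    intervals: Sequence[GenomicInterval]
    sequence: str

    def __post_init__(self) -> None:
        if not self.intervals:
            raise ValueError("UTRModel requires at least one interval")
        chroms = {iv.chrom for iv in self.intervals}
        strands = {iv.strand for iv in self.intervals}
        if len(chroms) != 1 or len(strands) != 1:
            raise ValueError("UTR intervals must share one chrom and strand")
        total = sum(len(iv) for iv in self.intervals)
        if len(self.sequence) != total:
            raise ValueError(
                f"sequence length {len(self.sequence)} != interval total {total}"
            )
        self.sequence = self.sequence.upper()

    @property
    def chrom(self) -> str:
        return self.intervals[0].chrom

    @property
    def strand(self) -> str:
        return self.intervals[0].strand

    @property
    def length(self) -> int:
        return len(self.sequence)

    def genomic_to_utr(self, g: int) -> int:
        """Map a genomic position to its UTR-relative position.

        Returns :data:`NOT_IN_UTR` for positions outside every interval.
        """
        offset = 0
        for iv in self.intervals:
            if iv.start <= g < iv.end:
                if iv.strand == "+":
                    return offset + (g - iv.start)
                return offset + (iv.end - 1 - g)
            offset += len(iv)
        return NOT_IN_UTR

    def utr_to_genomic(self, u: int) -> int:
        """Inverse of :meth:`genomic_to_utr`; raises ``IndexError`` outside
        ``[0, length)``."""
        if not 0 <= u < self.length:
            raise IndexError(f"UTR position {u} outside [0, {self.length})")
        offset = 0
        for iv in self.intervals:
            if u < offset + len(iv):
                if iv.strand == "+":
                    return iv.start + (u - offset)
                return iv.end - 1 - (u - offset)
            offset += len(iv)
        raise AssertionError("unreachable")

    def three_prime_end_genomic(self) -> int:
        """Genomic coordinate of the UTR's 3'-most transcript-sense base."""
        return self.utr_to_genomic(self.length - 1)


class ConservationTrack:
    """Per-base conservation scores with explicit missing values.

    Backed by one NaN-initialized float array per chromosome; positions
    never covered by the input track query as NaN, not 0.
    """

    def __init__(self) -> None:
        self._arrays: dict[str, np.ndarray] = {}

    @classmethod
    def from_bedgraph(cls, path: str | os.PathLike,
                      chrom_sizes: Mapping[str, int] | None = None
                      ) -> "ConservationTrack":
        """Load a bedGraph file (chrom, start, end, score; 0-based half-open).

        ``chrom_sizes`` pre-sizes the per-chromosome arrays; without it the
        arrays grow to the highest covered coordinate.
        """
        intervals: dict[str, list[tuple[int, int, float]]] = {}
        with open(path) as fh:
            for lineno, raw in enumerate(fh, 1):
                line = raw.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split()
                if len(fields) < 4:
                    raise FormatError(f"{path}:{lineno}: expected 4 bedGraph columns")
                try:
                    start, end, score = int(fields[1]), int(fields[2]), float(fields[3])
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: {exc}") from None
                intervals.setdefault(fields[0], []).append((start, end, score))
        track = cls()
        for chrom, ivs in intervals.items():
            size = max(end for _, end, _ in ivs)
            if chrom_sizes is not None:
                size = max(size, chrom_sizes.get(chrom, 0))
            arr = np.full(size, np.nan)
            for start, end, score in ivs:
                arr[start:end] = score
            track._arrays[chrom] = arr
        return track

    def set_scores(self, chrom: str, start: int, values: np.ndarray) -> None:
        """Write a block of scores (used by the synthetic generator)."""
        arr = self._arrays.get(chrom)
        need = start + len(values)
        if arr is None or len(arr) < need:
            new = np.full(need, np.nan)
            if arr is not None:
                new[: len(arr)] = arr
            self._arrays[chrom] = arr = new
        arr[start : start + len(values)] = values

    def score(self, chrom: str, pos: int) -> float:
        """Score at one genomic base; NaN when missing."""
        arr = self._arrays.get(chrom)
        if arr is None or not 0 <= pos < len(arr):
            return float("nan")
        return float(arr[pos])

    def scores(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Vectorized :meth:`score`; out-of-range queries come back NaN."""
        arr = self._arrays.get(chrom)
        out = np.full(len(positions), np.nan)
        if arr is None:
            return out
        positions = np.asarray(positions)
        ok = (positions >= 0) & (positions < len(arr))
        out[ok] = arr[positions[ok]]
        return out

    def to_bedgraph(self, path: str | os.PathLike) -> None:
        """Write covered runs of equal score as bedGraph records."""
        with open(path, "w") as fh:
            for chrom in sorted(self._arrays):
                arr = self._arrays[chrom]
                covered = ~np.isnan(arr)
                i = 0
                while i < len(arr):
                    if not covered[i]:
                        i += 1
                        continue
                    j = i + 1
                    while j < len(arr) and covered[j] and arr[j] == arr[i]:
                        j += 1
                    fh.write(f"{chrom}\t{i}\t{j}\t{arr[i]:g}\n")
                    i = j


def read_read_ends(path: str | os.PathLike | io.TextIOBase) -> list[ReadEnd3p]:
    """Read 3'-end positions from BED6 (name column = sample label).

    The cleavage coordinate is the interval's last base in transcript sense:
    ``end - 1`` on the plus strand, ``start`` on the minus strand (identical
    for the single-base records this pipeline writes).
    """
    close = False
    if isinstance(path, (str, os.PathLike)):
        fh = open(path)
        close = True
        name = str(path)
    else:
        fh, name = path, "<stream>"
    ends: list[ReadEnd3p] = []
    try:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise FormatError(f"{name}:{lineno}: expected 6 BED columns")
            chrom, start, end, sample, _score, strand = fields[:6]
            if strand not in ("+", "-"):
                raise FormatError(f"{name}:{lineno}: unknown strand {strand!r}")
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise FormatError(f"{name}:{lineno}: non-integer coordinates") from None
            if not 0 <= start_i < end_i:
                raise FormatError(f"{name}:{lineno}: invalid interval")
            pos = end_i - 1 if strand == "+" else start_i
            ends.append(ReadEnd3p(chrom, pos, strand, sample))
    finally:
        if close:
            fh.close()
    return ends


def write_read_ends(ends: Iterable[ReadEnd3p], path: str | os.PathLike) -> None:
    """Write read ends as single-base BED6 records."""
    with open(path, "w") as fh:
        for e in ends:
            fh.write(f"{e.chrom}\t{e.pos}\t{e.pos + 1}\t{e.sample}\t0\t{e.strand}\n")


def _fetch(genome: Fasta, chrom: str, start: int, end: int) -> str:
    if chrom not in genome:
        raise FormatError(f"chromosome {chrom!r} absent from genome FASTA")
    contig_len = len(genome[chrom])
    if end > contig_len:
        raise FormatError(
            f"interval end {end} beyond {chrom} length {contig_len}"
        )
    return str(genome[chrom][start:end]).upper()


def read_utr_models(annotation: str | os.PathLike,
                    genome: str | os.PathLike | Fasta) -> list[UTRModel]:
    """Read 3'UTR models from BED (6 or 12 column) plus a genome FASTA.

    BED12 block structure gives multi-exon UTRs; BED6 rows are single-exon.
    The name column is ``gene_id|accession`` (a bare name serves as both).
    Sequences are extracted strand-aware: minus-strand models carry the
    reverse complement of the genomic slice, exons ordered 5'->3' in
    transcript sense.
    """
    if not isinstance(genome, Fasta):
        genome = Fasta(str(genome))
    models: list[UTRModel] = []
    with open(annotation) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise FormatError(f"{annotation}:{lineno}: expected >=6 BED columns")
            chrom, start, end, name, _score, strand = fields[:6]
            start_i, end_i = int(start), int(end)
            if strand not in ("+", "-"):
                raise FormatError(f"{annotation}:{lineno}: unknown strand {strand!r}")
            if len(fields) >= 12:
                sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
                starts = [int(x) for x in fields[11].rstrip(",").split(",")]
                blocks = [(start_i + off, start_i + off + sz)
                          for off, sz in zip(starts, sizes)]
            else:
                blocks = [(start_i, end_i)]
            gene_id, _, accession = name.partition("|")
            accession = accession or gene_id
            ivs = [GenomicInterval(chrom, s, e, strand) for s, e in blocks]
            seqs = [_fetch(genome, chrom, s, e) for s, e in blocks]
            if strand == "-":
                ivs = ivs[::-1]
                seqs = [reverse_complement(s) for s in seqs[::-1]]
            models.append(UTRModel(gene_id, accession, ivs, "".join(seqs)))
    return models


def write_utr_models(models: Iterable[UTRModel], path: str | os.PathLike) -> None:
    """Write UTR models as BED12 (one row per accession)."""
    with open(path, "w") as fh:
        for m in models:
            ivs = sorted(m.intervals, key=lambda iv: iv.start)
            start, end = ivs[0].start, ivs[-1].end
            sizes = ",".join(str(len(iv)) for iv in ivs)
            offsets = ",".join(str(iv.start - start) for iv in ivs)
            fh.write(
                f"{m.chrom}\t{start}\t{end}\t{m.gene_id}|{m.accession}\t0\t"
                f"{m.strand}\t{start}\t{end}\t0\t{len(ivs)}\t{sizes}\t{offsets}\n"
            )


def longest_utr_per_gene(models: Iterable[UTRModel]) -> list[UTRModel]:
    """Keep one model per gene: the longest UTR (ties: lexicographically
    smallest accession, for determinism)."""
    best: dict[str, UTRModel] = {}
    for m in models:
        cur = best.get(m.gene_id)
        if cur is None or m.length > cur.length or (
            m.length == cur.length and m.accession < cur.accession
        ):
            best[m.gene_id] = m
    return list(best.values())
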