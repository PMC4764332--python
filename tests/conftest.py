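"""Shared fixtures: tiny genomes and UTR models built programmatically."""

from __future__ import annotations

import pytest

from apamir.io_formats import GenomicInterval, UTRModel, reverse_complement


def make_utr(gene_id: str, sequence: str, chrom: str = "chr1",
             start: int = 100, strand: str = "+") -> UTRModel:
    """Single-exon UTR whose transcript-sense sequence is ``sequence``."""
    iv = GenomicInterval(chrom, start, start + len(sequence), strand)
    return UTRModel(gene_id, gene_id, [iv], sequence)


def genome_with(utr: UTRModel, contig_len: int = 0,
                fill: str = "C") -> dict[str, str]:
    """A dict genome embedding the UTR's genomic-sense sequence."""
    iv = utr.intervals[0]
    n = max(contig_len, iv.end + 50)
    seq = list(fill * n)
    gseq = utr.sequence if iv.strand == "+" else reverse_complement(utr.sequence)
    seq[iv.start:iv.end] = list(gseq)
    return {iv.chrom: "".join(seq)}


@pytest.fixture
def mini_utr() -> UTRModel:
    return make_utr("geneA", "ACGTACGTACGTACGTACGT")
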