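"""Assignment of cleavage sites to 3'UTR models and APA-gene calling.

A cleavage site belongs to a gene if it lies inside the gene's 3'UTR
coordinates or up to ``tail_slack`` nt (default 20) past the annotated 3'
end, on the same strand. A gene is APA-positive when at least two cleavage
sites map to its UTR; the analysis anchor is the 5'-most of them.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from apamir.cs_calling import CleavageSite, DEFAULT_MIN_SUPPORT
from apamir.io_formats import NOT_IN_UTR, UTRModel

DEFAULT_TAIL_SLACK = 20


@dataclass
class ApaCall:
    """Cleavage sites assigned to one gene's 3'UTR, in UTR coordinates.

    ``apa_pos`` is the 5'-most assigned site when the gene is APA-positive
    (>= 2 assigned sites), else ``None``. ``distal_pos`` is the 3'-most
    assigned site, used where an analysis anchors at the full-length UTR
    end; when no site reaches the distal region the annotated UTR end
    stands in.
    """

    gene_id: str
    utr: UTRModel
    cs_utr_positions: list[int] = field(default_factory=list)
    shared: bool = False  # any site also assigned to another gene

    @property
    def n_cs(self) -> int:
        return len(self.cs_utr_positions)

    @property
    def is_apa_positive(self) -> bool:
        return self.n_cs >= 2

    @property
    def apa_pos(self) -> int | None:
        return min(self.cs_utr_positions) if self.is_apa_positive else None

    @property
    def distal_pos(self) -> int:
        return max(self.cs_utr_positions) if self.cs_utr_positions \
            else self.utr.length - 1

    @property
    def upstream_len(self) -> int | None:
        return self.apa_pos

    @property
    def downstream_len(self) -> int | None:
        return None if self.apa_pos is None else self.utr.length - self.apa_pos


def _assign_position(site: CleavageSite, utr: UTRModel,
                     tail_slack: int) -> int | None:
    """UTR-relative position of a site, or None if it misses the UTR and
    its 3' slack. Slack positions are clamped to ``utr.length - 1``."""
    if site.chrom != utr.chrom or site.strand != utr.strand:
        return None
    u = utr.genomic_to_utr(site.pos)
    if u != NOT_IN_UTR:
        return u
    end3 = utr.three_prime_end_genomic()
    if utr.strand == "+":
        if end3 < site.pos <= end3 + tail_slack:
            return utr.length - 1
    else:
        if end3 - tail_slack <= site.pos < end3:
            return utr.length - 1
    return None


def assign_cs_to_utrs(sites: Iterable[CleavageSite],
                      utrs: Sequence[UTRModel],
                      tail_slack: int = DEFAULT_TAIL_SLACK,
                      include_internal_priming: bool = False,
                      sample: str | None = None,
                      min_support: int = DEFAULT_MIN_SUPPORT) -> list[ApaCall]:
    """Assign cleavage sites to UTR models; one :class:`ApaCall` per UTR.

    Internal-priming-flagged sites are excluded by default. A site that
    falls in two genes' overlapping UTRs is assigned to both and both calls
    are marked ``shared``. With ``sample`` set, only sites whose support in
    that sample reaches ``min_support`` participate (per-cell-type mode);
    otherwise pooled support is used as-is.
    """
    calls = {id(u): ApaCall(u.gene_id, u) for u in utrs}
    by_chrom_strand: dict[tuple[str, str], list[UTRModel]] = {}
    for u in utrs:
        by_chrom_strand.setdefault((u.chrom, u.strand), []).append(u)
    for site in sites:
        if site.internal_priming and not include_internal_priming:
            continue
        if sample is not None:
            if site.per_sample_support.get(sample, 0) < min_support:
                continue
        hits = []
        for u in by_chrom_strand.get((site.chrom, site.strand), ()):
            upos = _assign_position(site, u, tail_slack)
            if upos is not None:
                hits.append((u, upos))
        for u, upos in hits:
            calls[id(u)].cs_utr_positions.append(upos)
            if len(hits) > 1:
                calls[id(u)].shared = True
    out = list(calls.values())
    for c in out:
        c.cs_utr_positions.sort()
    return out


def filter_flank(calls: Iterable[ApaCall], min_flank: int) -> list[ApaCall]:
    """Keep APA-positive calls with >= ``min_flank`` nt of UTR sequence on
    each side of the APA anchor."""
    if min_flank < 0:
        raise ValueError("min_flank must be >= 0")
    kept = []
    for c in calls:
        if not c.is_apa_positive:
            continue
        if c.upstream_len >= min_flank and c.downstream_len >= min_flank:
            kept.append(c)
    return kept


def write_apa_tsv(calls: Sequence[ApaCall], path: str | os.PathLike,
                  params: Mapping[str, object] | None = None) -> None:
    with open(path, "w") as fh:
        from apamir import __version__
        fh.write(f"# apamir {__version__}")
        if params:
            fh.write(" " + " ".join(f"{k}={v}" for k, v in sorted(params.items())))
        fh.write("\n")
        fh.write("gene_id\taccession\tutr_length\tn_cs\tapa_pos\t"
                 "upstream_len\tdownstream_len\tcs_positions\tshared\n")
        for c in calls:
            apa = "" if c.apa_pos is None else str(c.apa_pos)
            up = "" if c.upstream_len is None else str(c.upstream_len)
            down = "" if c.downstream_len is None else str(c.downstream_len)
            cs = ",".join(map(str, c.cs_utr_positions))
            fh.write(f"{c.gene_id}\t{c.utr.accession}\t{c.utr.length}\t"
                     f"{c.n_cs}\t{apa}\t{up}\t{down}\t{cs}\t"
                     f"{int(c.shared)}\n")
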