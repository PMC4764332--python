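"""Mean per-base conservation profiles around UTR anchors.

Anchors (APA positions or seed-site starts) are aligned at offset 0 and the
per-offset mean of a per-base score track (PhastCons/PhyloP-style) is taken
over anchors with a non-missing score at that strand-aware genomic base.
Missing scores are excluded from the mean, never imputed as 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from apamir.apa_assignment import ApaCall, filter_flank
from apamir.io_formats import ConservationTrack, UTRModel
from apamir.site_mapping import SeedSite

logger = logging.getLogger(__name__)

# Fixed 30-base window around a 7-mer site anchor: offsets [-12, +19)
# place the site at offsets [0, 7) with 12 nt 5' and 11 nt 3' context.
SITE_FLANK_5P = 12
SITE_FLANK_3P = 19


@dataclass
class ConservationProfile:
    """Per-offset mean score and number of contributing anchors.

    ``offsets`` runs [-flank_5p, flank_3p); means are NaN where no anchor
    contributes.
    """

    offsets: np.ndarray
    mean: np.ndarray
    n: np.ndarray


def mean_profile(anchors: Iterable[tuple[UTRModel, int]],
                 track: ConservationTrack,
                 flank_5p: int, flank_3p: int) -> ConservationProfile:
    """Mean conservation at transcript-sense offsets around anchors.

    For each anchor (UTR model, UTR-relative position) and each offset in
    ``[-flank_5p, flank_3p)``, the UTR position ``pos + offset`` is mapped
    to its strand-aware genomic base and the track queried; offsets
    falling outside the UTR, or with a missing score, do not contribute.
    """
    if flank_5p < 0 or flank_3p < 0:
        raise ValueError("flanks must be >= 0")
    width = flank_5p + flank_3p
    offsets = np.arange(-flank_5p, flank_3p)
    total = np.zeros(width)
    n = np.zeros(width, dtype=np.int64)
    for utr, pos in anchors:
        upos = pos + offsets
        inside = (upos >= 0) & (upos < utr.length)
        gpos = np.fromiter((utr.utr_to_genomic(int(u)) for u in upos[inside]),
                           dtype=np.int64, count=int(inside.sum()))
        scores = track.scores(utr.chrom, gpos)
        ok = ~np.isnan(scores)
        idx = np.nonzero(inside)[0][ok]
        total[idx] += scores[ok]
        n[idx] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(n > 0, total / np.maximum(n, 1), np.nan)
    return ConservationProfile(offsets, mean, n)


def apa_profile(calls: Sequence[ApaCall], track: ConservationTrack,
                flank: int = 1000) -> ConservationProfile:
    """Mean conservation around the APA anchor of flank-filtered genes."""
    kept = filter_flank(calls, flank)
    return mean_profile(((c.utr, c.apa_pos) for c in kept), track,
                        flank, flank)


def site_profile(sites: Sequence[SeedSite], utrs: Sequence[UTRModel],
                 track: ConservationTrack,
                 flank_5p: int = SITE_FLANK_5P,
                 flank_3p: int = SITE_FLANK_3P) -> ConservationProfile:
    """Mean conservation around seed-site starts (default 30-base window
    with the 7-mer at offsets [0, 7))."""
    by_gene = {u.gene_id: u for u in utrs}
    anchors = [(by_gene[s.gene_id], s.utr_start) for s in sites
               if s.gene_id in by_gene]
    return mean_profile(anchors, track, flank_5p, flank_3p)


def profile_by_group(calls: Sequence[ApaCall], sites: Iterable[SeedSite],
                     track: ConservationTrack,
                     flank: int = 1000, window_5p: int = 300
                     ) -> tuple[ConservationProfile | None,
                                ConservationProfile | None]:
    """APA-anchored profiles split by presence of a conserved site in the
    ``window_5p`` nt 5' of the anchor.

    Returns (with-site profile, without-site profile); an empty group
    yields None for its profile (logged).
    """
    kept = filter_flank(calls, flank)
    if not kept:
        raise ValueError("no genes pass the flank filter")
    cons_pos: dict[str, list[int]] = {}
    for s in sites:
        if s.conserved:
            cons_pos.setdefault(s.gene_id, []).append(s.utr_start)

    def has_site(c: ApaCall) -> bool:
        return any(c.apa_pos - window_5p <= u < c.apa_pos
                   for u in cons_pos.get(c.gene_id, ()))
    group_with = [c for c in kept if has_site(c)]
    group_without = [c for c in kept if not has_site(c)]
    prof_with = prof_without = None
    if group_with:
        prof_with = mean_profile(((c.utr, c.apa_pos) for c in group_with),
                                 track, flank, flank)
    else:
        logger.info("no genes with a conserved site in the 5' window")
    if group_without:
        prof_without = mean_profile(
            ((c.utr, c.apa_pos) for c in group_without), track, flank, flank)
    else:
        logger.info("all genes have a conserved site in the 5' window")
    return prof_with, prof_without


def write_profile_tsv(profile: ConservationProfile, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("offset\tmean\tn\n")
        for off, m, n in zip(profile.offsets, profile.mean, profile.n):
            ms = "" if np.isnan(m) else f"{m:.6g}"
            fh.write(f"{off}\t{ms}\t{n}\n")
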