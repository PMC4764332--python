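"""Exact 7-mer miRNA seed-match scanning in 3'UTR sequences.

A binding site is the perfect 7-nt reverse complement (DNA alphabet) of the
miRNA seed, bases 2-8 of the mature sequence. Conservation status and
per-site scores (P_CT, context++) come from external tables keyed by
(gene_id, utr_start, family_id); table coordinates are validated by
checking the 7-mer actually present at each listed position.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from apamir.io_formats import FormatError, UTRModel, reverse_complement

SITE_LEN = 7
#: fraction of table rows whose 7-mer may mismatch the UTR sequence before
#: a coordinate-system mismatch is declared
MAX_TABLE_MISMATCH = 0.05


@dataclass(frozen=True)
class MirnaSeed:
    """One miRNA seed family: a 7-nt site sequence shared by its members."""

    family_id: str
    site7: str
    conserved_family: bool = True
    mirna_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.site7) != SITE_LEN:
            raise ValueError(f"site7 must be {SITE_LEN} nt, got {self.site7!r}")
        if set(self.site7) - set("ACGT"):
            raise ValueError(f"site7 must be DNA over ACGT, got {self.site7!r}")


@dataclass
class SeedSite:
    """A seed-match occurrence: ``utr_start`` is the 5' end of the 7-mer
    in UTR-relative coordinates."""

    gene_id: str
    utr_start: int
    family_id: str
    conserved: bool = False
    pct: float | None = None
    context_score: float | None = None


def seed_from_mirna(mature_seq: str) -> str:
    """Site 7-mer for a mature miRNA sequence: the DNA reverse complement
    of seed bases 2-8 (1-based)."""
    seq = mature_seq.upper().replace("U", "T")
    if len(seq) < 8:
        raise ValueError(f"mature sequence shorter than 8 nt: {mature_seq!r}")
    if set(seq[1:8]) - set("ACGT"):
        raise ValueError(f"non-nucleotide characters in seed of {mature_seq!r}")
    return reverse_complement(seq[1:8])


def scan_sites(utr: UTRModel, seeds: Iterable[MirnaSeed]) -> list[SeedSite]:
    """All exact occurrences of every seed's 7-mer in the UTR sequence.

    Overlapping occurrences and multiple families at one position are all
    reported; N never matches. Output sorted by (utr_start, family_id).
    """
    seq = utr.sequence
    out: list[SeedSite] = []
    for seed in seeds:
        start = seq.find(seed.site7)
        while start != -1:
            out.append(SeedSite(utr.gene_id, start, seed.family_id))
            start = seq.find(seed.site7, start + 1)
    out.sort(key=lambda s: (s.utr_start, s.family_id))
    return out


def scan_all(utrs: Iterable[UTRModel],
             seeds: Sequence[MirnaSeed]) -> list[SeedSite]:
    """:func:`scan_sites` over a collection of UTR models."""
    out: list[SeedSite] = []
    for utr in utrs:
        out.extend(scan_sites(utr, seeds))
    return out


def _validate_table(rows: Iterable[tuple[str, int, str]],
                    utrs_by_gene: Mapping[str, UTRModel],
                    seeds_by_family: Mapping[str, MirnaSeed],
                    what: str) -> float:
    """Check the 7-mer at each table position matches its family's site7.

    Returns the mismatch rate; raises :class:`FormatError` above
    :data:`MAX_TABLE_MISMATCH` (coordinate-system mismatch).
    """
    n = bad = 0
    for gene_id, utr_start, family_id in rows:
        utr = utrs_by_gene.get(gene_id)
        seed = seeds_by_family.get(family_id)
        if utr is None or seed is None:
            continue
        n += 1
        if utr.sequence[utr_start:utr_start + SITE_LEN] != seed.site7:
            bad += 1
    rate = bad / n if n else 0.0
    if rate > MAX_TABLE_MISMATCH:
        raise FormatError(
            f"{what}: {rate:.1%} of table 7-mers mismatch UTR sequences; "
            "the table's coordinate system does not match the UTR models")
    return rate


def label_conserved(sites: Sequence[SeedSite],
                    conserved_table: pd.DataFrame,
                    utrs: Sequence[UTRModel] | None = None,
                    seeds: Sequence[MirnaSeed] | None = None) -> float:
    """Set ``conserved`` on sites present in the table (in place).

    ``conserved_table`` needs columns gene_id, utr_start, family_id. With
    ``utrs`` and ``seeds`` given, table coordinates are validated against
    the sequences first. Returns the validation mismatch rate (0.0 when
    validation is skipped or the table is empty).
    """
    keys = set(zip(conserved_table["gene_id"],
                   conserved_table["utr_start"].astype(int),
                   conserved_table["family_id"]))
    rate = 0.0
    if utrs is not None and seeds is not None:
        rate = _validate_table(keys, {u.gene_id: u for u in utrs},
                               {s.family_id: s for s in seeds},
                               "conserved-site table")
    for s in sites:
        s.conserved = (s.gene_id, s.utr_start, s.family_id) in keys
    return rate


def attach_scores(sites: Sequence[SeedSite],
                  score_table: pd.DataFrame,
                  kind: str,
                  utrs: Sequence[UTRModel] | None = None,
                  seeds: Sequence[MirnaSeed] | None = None) -> float:
    """Attach P_CT (``kind='pct'``) or context++ (``kind='context'``)
    scores where the table lists the site; sites absent from the table
    keep ``None``. Duplicate keys with conflicting scores are an error.
    """
    if kind not in ("pct", "context"):
        raise ValueError("kind must be 'pct' or 'context'")
    scores: dict[tuple[str, int, str], float] = {}
    for gene_id, utr_start, family_id, score in zip(
            score_table["gene_id"], score_table["utr_start"].astype(int),
            score_table["family_id"], score_table["score"].astype(float)):
        key = (gene_id, utr_start, family_id)
        if key in scores and scores[key] != score:
            raise FormatError(f"conflicting {kind} scores for {key}")
        scores[key] = score
    rate = 0.0
    if utrs is not None and seeds is not None:
        rate = _validate_table(scores, {u.gene_id: u for u in utrs},
                               {s.family_id: s for s in seeds},
                               f"{kind}-score table")
    attr = "pct" if kind == "pct" else "context_score"
    for s in sites:
        val = scores.get((s.gene_id, s.utr_start, s.family_id))
        if val is not None:
            setattr(s, attr, val)
    return rate


def read_seed_table(path: str | os.PathLike) -> list[MirnaSeed]:
    """Read a seed TSV: family_id, site7, conserved_family (0/1)."""
    df = pd.read_csv(path, sep="\t", comment="#",
                     dtype={"family_id": str, "site7": str})
    return [MirnaSeed(r.family_id, r.site7, bool(int(r.conserved_family)))
            for r in df.itertuples()]


def write_seed_table(seeds: Iterable[MirnaSeed], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("family_id\tsite7\tconserved_family\n")
        for s in seeds:
            fh.write(f"{s.family_id}\t{s.site7}\t{int(s.conserved_family)}\n")


def read_site_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a (gene_id, utr_start, family_id[, score]) TSV."""
    return pd.read_csv(path, sep="\t", comment="#",
                       dtype={"gene_id": str, "family_id": str})


def write_sites_tsv(sites: Sequence[SeedSite], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tutr_start\tfamily_id\tconserved\tpct\tcontext_score\n")
        for s in sites:
            pct = "" if s.pct is None else f"{s.pct:g}"
            ctx = "" if s.context_score is None else f"{s.context_score:g}"
            fh.write(f"{s.gene_id}\t{s.utr_start}\t{s.family_id}\t"
                     f"{int(s.conserved)}\t{pct}\t{ctx}\n")
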