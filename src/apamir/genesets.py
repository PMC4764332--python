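"""Codon-usage vectors and codon-usage-based gene-set expansion.

A gene's codon usage is the relative frequency vector over the 61 sense
codons of its CDS. A seed gene set is expanded by admitting every gene
whose Pearson correlation with the seed set's centroid usage reaches a
threshold; genes qualifying for two competing sets go to the
higher-correlated one (exact ties are excluded).
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass
from itertools import product
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

STOP_CODONS = ("TAA", "TAG", "TGA")
SENSE_CODONS = tuple(
    "".join(c) for c in product("TCAG", repeat=3)
    if "".join(c) not in STOP_CODONS
)
_CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}


@dataclass
class CodonUsageVector:
    """Relative frequencies of the 61 sense codons in one CDS."""

    gene_id: str
    freqs: np.ndarray
    n_codons: int

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.shape != (61,):
            raise ValueError("freqs must have 61 entries")
        if self.n_codons < 1:
            raise ValueError("n_codons must be >= 1")
        if not math.isclose(self.freqs.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("codon frequencies must sum to 1")


@dataclass
class GeneSet:
    """A named gene set with provenance: 'seed', 'codon_expanded:<thr>',
    or 'external'."""

    name: str
    gene_ids: set[str]
    provenance: str = "seed"


def codon_usage(cds: str, gene_id: str = "") -> CodonUsageVector:
    """Codon-usage vector of a CDS.

    A single terminal stop codon is trimmed; an in-frame internal stop or
    a length not divisible by 3 is an error.
    """
    seq = cds.upper().replace("U", "T")
    if len(seq) % 3 != 0:
        raise ValueError(f"CDS length {len(seq)} not divisible by 3")
    codons = [seq[i:i + 3] for i in range(0, len(seq), 3)]
    if codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    if not codons:
        raise ValueError("CDS contains no sense codons")
    counts = np.zeros(61, dtype=float)
    for i, codon in enumerate(codons):
        if codon in STOP_CODONS:
            raise ValueError(f"internal stop codon {codon} at codon {i}")
        idx = _CODON_INDEX.get(codon)
        if idx is None:
            raise ValueError(f"non-ACGT codon {codon!r} at codon {i}")
        counts[idx] += 1
    return CodonUsageVector(gene_id, counts / counts.sum(), len(codons))


def codon_usage_from_fasta(path: str | os.PathLike) -> list[CodonUsageVector]:
    """Codon-usage vectors for every record of a CDS FASTA (record id =
    gene id)."""
    from pyfaidx import Fasta

    fa = Fasta(str(path))
    return [codon_usage(str(fa[name][:]), name) for name in fa.keys()]


def _centroid(vectors: Sequence[CodonUsageVector]) -> np.ndarray:
    return np.mean([v.freqs for v in vectors], axis=0)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc, yc = x - x.mean(), y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        return float("nan")
    return float(xc @ yc / denom)


def correlation_to_set(seed_set: GeneSet,
                       vectors: Mapping[str, CodonUsageVector]
                       ) -> dict[str, float]:
    """Pearson correlation of every gene's usage vector with the seed
    set's centroid usage."""
    seed_vecs = [vectors[g] for g in sorted(seed_set.gene_ids) if g in vectors]
    if len(seed_vecs) < 2:
        raise ValueError("seed set must have >= 2 genes with CDS vectors")
    centroid = _centroid(seed_vecs)
    return {g: _pearson(v.freqs, centroid) for g, v in vectors.items()}


def expand_set(seed_set: GeneSet,
               all_vectors: Iterable[CodonUsageVector],
               threshold: float) -> GeneSet:
    """Expand a seed set by codon-usage correlation to its centroid.

    A gene joins iff Pearson correlation >= threshold; seed genes are
    always retained.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    vecs = {v.gene_id: v for v in all_vectors}
    corr = correlation_to_set(seed_set, vecs)
    members = set(seed_set.gene_ids)
    members.update(g for g, c in corr.items()
                   if not math.isnan(c) and c >= threshold)
    return GeneSet(seed_set.name, members, f"codon_expanded:{threshold:g}")


def expand_competing(seed_sets: Sequence[GeneSet],
                     all_vectors: Iterable[CodonUsageVector],
                     threshold: float) -> list[GeneSet]:
    """Expand several seed sets jointly, resolving competition.

    A non-seed gene qualifying for more than one set is assigned to the
    set it correlates with most; exact correlation ties exclude the gene.
    Seed membership always wins for its own set.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    vecs = {v.gene_id: v for v in all_vectors}
    corrs = [correlation_to_set(s, vecs) for s in seed_sets]
    out = [GeneSet(s.name, set(s.gene_ids), f"codon_expanded:{threshold:g}")
           for s in seed_sets]
    seeded = set().union(*(s.gene_ids for s in seed_sets))
    for g in vecs:
        if g in seeded:
            continue
        cs = [c.get(g, float("nan")) for c in corrs]
        qual = [i for i, c in enumerate(cs)
                if not math.isnan(c) and c >= threshold]
        if not qual:
            continue
        best = max(qual, key=lambda i: cs[i])
        if sum(1 for i in qual if cs[i] == cs[best]) > 1:
            continue  # exact tie between competing sets
        out[best].gene_ids.add(g)
    return out


def load_external_sets(path: str | os.PathLike) -> list[GeneSet]:
    """Load gene sets from a two-column TSV (set name, gene id);
    duplicate rows are deduplicated."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype=str)
    if df.empty:
        raise ValueError(f"{path}: empty gene-set file")
    if df.shape[1] != 2:
        raise ValueError(f"{path}: expected 2 columns, got {df.shape[1]}")
    sets: dict[str, set[str]] = {}
    for name, gene in zip(df[0], df[1]):
        sets.setdefault(name, set()).add(gene)
    return [GeneSet(name, genes, "external")
            for name, genes in sets.items()]


def write_gene_sets(sets: Iterable[GeneSet], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for s in sets:
            for g in sorted(s.gene_ids):
                fh.write(f"{s.name}\t{g}\n")
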