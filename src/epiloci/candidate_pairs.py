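"""Prior-knowledge candidate SNP-pair generation.

Three strategies restrict the combinatorial space of pairwise interaction
tests: all pairs among a hit list of trait-associated SNPs, cross-gene pairs
from a list of interacting gene pairs, and all pairs among the SNPs mapped to
a gene set.  SNPs map to a gene when they fall within a flank (default 5 kb)
of the gene interval, irrespective of strand.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .geno_qc import VariantRecord

logger = logging.getLogger(__name__)

__all__ = [
    "GeneInterval",
    "PairSet",
    "all_pairs_count",
    "pairs_from_hits",
    "read_gene_intervals",
    "map_snps_to_genes",
    "pairs_from_gene_pairs",
    "pairs_from_gene_set",
]


@dataclass(frozen=True)
class GeneInterval:
    """Gene span, 1-based inclusive coordinates."""

    gene: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene}: start {self.start} > end {self.end}")


@dataclass
class PairSet:
    """De-duplicated unordered SNP-id pairs plus the Bonferroni denominator m.

    By default m equals the number of generated pairs before any per-cohort
    eligibility filtering, so the multiple-testing correction matches the size
    of the designed search, not the post-filter test count.
    """

    pairs: list[tuple[str, str]]
    provenance: str = "hits"
    n_raw: int | None = None  # pair instances before de-duplication

    def __post_init__(self) -> None:
        canon = [tuple(sorted(p)) for p in self.pairs]
        if any(a == b for a, b in canon):
            raise ValueError("self-pairs are not allowed")
        if len(set(canon)) != len(canon):
            raise ValueError("duplicate unordered pairs are not allowed")
        self.pairs = canon
        if self.n_raw is None:
            self.n_raw = len(canon)

    @property
    def m(self) -> int:
        return len(self.pairs)

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)


def all_pairs_count(n: int) -> int:
    """Number of unordered pairs among n items, n(n-1)/2."""
    if n < 0:
        raise ValueError("n must be non-negative")
    return n * (n - 1) // 2


def pairs_from_hits(snp_ids: Sequence[str]) -> PairSet:
    """All unordered pairs among a hit list of unique SNP ids."""
    ids = list(snp_ids)
    if len(set(ids)) != len(ids):
        dupes = sorted({s for s in ids if ids.count(s) > 1})
        raise ValueError(f"duplicate SNP ids in hit list: {dupes[:5]}")
    pairs = list(itertools.combinations(ids, 2))
    return PairSet(pairs=pairs, provenance="hits")


def read_gene_intervals(path: str | Path, fmt: str = "bed") -> list[GeneInterval]:
    """Read gene intervals from BED (0-based half-open) or a 1-based 4-column table.

    BED columns chrom/start/end/name are converted to 1-based inclusive; the
    table format is gene/chrom/start/end, already 1-based inclusive.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if fmt == "bed":
        return [
            GeneInterval(gene=r[3], chrom=str(r[0]), start=int(r[1]) + 1, end=int(r[2]))
            for r in df.itertuples(index=False)
        ]
    if fmt == "table":
        return [
            GeneInterval(gene=str(r[0]), chrom=str(r[1]), start=int(r[2]), end=int(r[3]))
            for r in df.itertuples(index=False)
        ]
    raise ValueError(f"unknown gene interval format {fmt!r}")


def map_snps_to_genes(
    variants: Iterable[VariantRecord],
    genes: Iterable[GeneInterval],
    flank: int = 5_000,
) -> dict[str, list[str]]:
    """Assign each SNP to every gene whose flanked interval contains it.

    A SNP maps to a gene iff start - flank <= pos <= end + flank on the same
    chromosome (both boundaries inclusive); one SNP may map to several genes.
    """
    variants = list(variants)
    mapping: dict[str, list[str]] = {}
    for gene in genes:
        lo, hi = gene.start - flank, gene.end + flank
        hits = [
            v.id for v in variants if v.chrom == gene.chrom and lo <= v.pos <= hi
        ]
        mapping[gene.gene] = hits
    return mapping


def _dedupe(pairs: Iterable[tuple[str, str]]) -> tuple[list[tuple[str, str]], int]:
    seen: set[tuple[str, str]] = set()
    out: list[tuple[str, str]] = []
    raw = 0
    for a, b in pairs:
        raw += 1
        if a == b:
            continue
        key = tuple(sorted((a, b)))
        if key not in seen:
            seen.add(key)
            out.append(key)
    return out, raw


def pairs_from_gene_pairs(
    gene_pairs: Sequence[tuple[str, str]],
    mapping: dict[str, list[str]],
) -> PairSet:
    """Cross-product SNP pairs for each interacting gene pair, de-duplicated.

    A gene pair with n1 and n2 mapped SNPs contributes n1*n2 pair instances;
    self-pairs (one SNP mapped to both genes) are dropped, and identical
    unordered pairs arising from different gene pairs are counted once.
    ``n_raw`` preserves the pre-de-duplication instance count.
    """
    instances: list[tuple[str, str]] = []
    for ga, gb in gene_pairs:
        if ga not in mapping or gb not in mapping:
            warnings.warn(f"gene pair ({ga}, {gb}) skipped: gene not in mapping")
            continue
        instances.extend(itertools.product(mapping[ga], mapping[gb]))
    pairs, raw = _dedupe(instances)
    return PairSet(pairs=pairs, provenance="ppi", n_raw=raw)


def pairs_from_gene_set(
    genes: Sequence[str],
    mapping: dict[str, list[str]],
) -> PairSet:
    """All unordered pairs among the union of SNPs mapped to any gene in the set."""
    union: list[str] = []
    seen: set[str] = set()
    for g in genes:
        for s in mapping.get(g, ()):
            if s not in seen:
                seen.add(s)
                union.append(s)
    if not union:
        raise ValueError("no SNPs mapped to any gene in the set")
    pairs = list(itertools.combinations(union, 2))
    return PairSet(pairs=pairs, provenance="pathway")
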