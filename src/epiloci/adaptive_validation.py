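"""Adaptive locus-based validation and fine mapping of SNP-pair interactions.

A discovered interaction between anchor SNPs A and B is validated in an
independent cohort by a sequential three-stage procedure that tests, in order:
(i) the anchor pair itself (1 test); (ii) each anchor against every SNP within
a window (default 200 kb) of the other anchor (n1 + n2 tests); (iii) every
pair between the two windows shrunk to 100 kb (n1 x n2 tests).  Each stage is
Bonferroni-corrected over its own test count and the procedure stops at the
first stage whose best corrected p-value clears alpha — replication is of the
locus pair, not of the original SNP pair.

Window membership for pair generation excludes the anchors themselves, so the
three stages partition cleanly: the anchor pair is tested once (stage i),
anchor-by-proxy pairs at stage ii, proxy-by-proxy pairs at stage iii.
Ineligible pairs (validation cell filter, pairwise LD) are excluded from both
testing and the stage's Bonferroni denominator.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from . import geno_qc as gq
from .epistasis_test import bonferroni
from .scan_engine import PairEvaluation, evaluate_pair

logger = logging.getLogger(__name__)

__all__ = [
    "LocusWindow",
    "StageResult",
    "ValidationOutcome",
    "window_snps",
    "run_adaptive",
    "FineMapResult",
    "fine_map",
    "CombinedEvidence",
    "combine_cohort_evidence",
]


@dataclass(frozen=True)
class LocusWindow:
    """SNPs strictly within ``half_width`` bp of an anchor position."""

    chrom: str
    center: int
    half_width: int
    snp_ids: tuple[str, ...]


def window_snps(
    variants, anchor: str, half_width: int
) -> LocusWindow:
    """SNPs with |pos - anchor_pos| < half_width on the anchor's chromosome.

    The boundary is strict, and hidden (simulated-causal) variants are never
    included.  The anchor itself qualifies (distance 0).
    """
    variants = list(variants)
    by_id = {v.id: v for v in variants}
    if anchor not in by_id:
        raise KeyError(f"anchor SNP {anchor!r} not in variant list")
    a = by_id[anchor]
    ids = tuple(
        v.id
        for v in variants
        if not v.hidden and v.chrom == a.chrom and abs(v.pos - a.pos) < half_width
    )
    return LocusWindow(chrom=a.chrom, center=a.pos, half_width=half_width, snp_ids=ids)


@dataclass
class StageResult:
    stage: str
    m: int  # Bonferroni denominator: eligible tests this stage
    n_ineligible: int
    results: pd.DataFrame  # per-pair snp1, snp2, p, p_c
    best_pair: tuple[str, str] | None
    best_p: float
    best_p_c: float


@dataclass
class ValidationOutcome:
    stage_reached: str  # "i", "ii", "iii", or "failed"
    tests_per_stage: tuple[int, ...]
    best_pair: tuple[str, str] | None
    best_p: float
    best_p_c: float
    stages: list[StageResult]
    reason: str | None = None

    def manifest(self) -> dict:
        """Machine-readable summary of the run for reproducibility."""
        return {
            "stage_reached": self.stage_reached,
            "tests_per_stage": list(self.tests_per_stage),
            "best_pair": list(self.best_pair) if self.best_pair else None,
            "best_p": self.best_p,
            "best_p_c": self.best_p_c,
            "stages": [
                {"stage": s.stage, "m": s.m, "n_ineligible": s.n_ineligible}
                for s in self.stages
            ],
            "reason": self.reason,
        }


def _run_stage(
    y, C, gm, pairs: list[tuple[str, str]], stage: str, min_cell: int, max_r2: float
) -> StageResult:
    evals: list[PairEvaluation] = [
        evaluate_pair(y, C, gm, a, b, min_cell=min_cell, max_r2=max_r2)
        for a, b in pairs
    ]
    tested = [e for e in evals if e.fit is not None]
    m = len(tested)
    rows = [
        {
            "snp1": e.snp1,
            "snp2": e.snp2,
            "p": e.fit.p,
            "p_c": bonferroni(e.fit.p, m) if m else 1.0,
        }
        for e in tested
    ]
    df = pd.DataFrame(rows, columns=["snp1", "snp2", "p", "p_c"])
    if rows:
        best = min(rows, key=lambda r: r["p"])
        best_pair = (best["snp1"], best["snp2"])
        best_p, best_p_c = best["p"], best["p_c"]
    else:
        best_pair, best_p, best_p_c = None, 1.0, 1.0
    return StageResult(
        stage=stage,
        m=m,
        n_ineligible=len(evals) - m,
        results=df,
        best_pair=best_pair,
        best_p=best_p,
        best_p_c=best_p_c,
    )


def run_adaptive(
    y: np.ndarray,
    C: np.ndarray | None,
    gm: gq.GenotypeMatrix,
    snpA: str,
    snpB: str,
    alpha: float = 0.05,
    w2: int = 200_000,
    w3: int = 100_000,
    min_cell: int = 10,
    max_r2: float = 0.1,
) -> ValidationOutcome:
    """Three-stage adaptive locus-based validation with sequential stopping."""
    variants = gm.visible().variants
    have_a = any(v.id == snpA for v in variants)
    have_b = any(v.id == snpB for v in variants)
    stages: list[StageResult] = []

    def proxies(window: LocusWindow, anchor: str) -> list[str]:
        return [s for s in window.snp_ids if s != anchor]

    # stage i: the anchor pair itself, a single uncorrected test
    if have_a and have_b:
        s1 = _run_stage(y, C, gm, [(snpA, snpB)], "i", min_cell, max_r2)
        stages.append(s1)
        if s1.best_p_c < alpha:
            return ValidationOutcome(
                "i", tuple(s.m for s in stages), s1.best_pair, s1.best_p, s1.best_p_c, stages
            )

    # stage ii: each anchor against the window around the other anchor
    pairs2: list[tuple[str, str]] = []
    if have_a and have_b:
        wA2 = window_snps(variants, snpA, w2)
        wB2 = window_snps(variants, snpB, w2)
        pairs2 = [(snpA, s) for s in proxies(wB2, snpB)] + [
            (snpB, s) for s in proxies(wA2, snpA)
        ]
    if pairs2:
        s2 = _run_stage(y, C, gm, pairs2, "ii", min_cell, max_r2)
        stages.append(s2)
        if s2.best_p_c < alpha:
            return ValidationOutcome(
                "ii", tuple(s.m for s in stages), s2.best_pair, s2.best_p, s2.best_p_c, stages
            )

    # stage iii: all proxy-by-proxy pairs within the shrunk windows
    pairs3: list[tuple[str, str]] = []
    if have_a and have_b:
        wA3 = window_snps(variants, snpA, w3)
        wB3 = window_snps(variants, snpB, w3)
        pairs3 = [
            (a, b)
            for a, b in itertools.product(proxies(wA3, snpA), proxies(wB3, snpB))
            if a != b
        ]
    if pairs3:
        s3 = _run_stage(y, C, gm, pairs3, "iii", min_cell, max_r2)
        stages.append(s3)
        if s3.best_p_c < alpha:
            return ValidationOutcome(
                "iii", tuple(s.m for s in stages), s3.best_pair, s3.best_p, s3.best_p_c, stages
            )

    if not stages or all(s.m == 0 for s in stages):
        return ValidationOutcome(
            "failed", tuple(s.m for s in stages), None, 1.0, 1.0, stages,
            reason="anchors absent or no eligible pairs in any stage",
        )
    best = min(stages, key=lambda s: s.best_p_c)
    return ValidationOutcome(
        "failed", tuple(s.m for s in stages), best.best_pair, best.best_p,
        best.best_p_c, stages, reason="no stage significant after correction",
    )


@dataclass
class FineMapResult:
    best_pair: tuple[str, str]
    best_p: float
    best_p_c: float
    m: int  # correction denominator including m_extra
    results: pd.DataFrame


def fine_map(
    y: np.ndarray,
    C: np.ndarray | None,
    gm: gq.GenotypeMatrix,
    snpA: str,
    snpB: str,
    w: int = 100_000,
    m_extra: int = 0,
    min_cell: int = 20,
    max_r2: float = 0.1,
) -> FineMapResult:
    """Exhaustive window-by-window testing around a discovered pair.

    All pairs between the two anchor windows (anchors included) are tested;
    the reported correction denominator adds ``m_extra`` (e.g. the discovery
    scan's test count) to the number of fine-mapping pairs tested.
    """
    variants = gm.visible().variants
    wA = window_snps(variants, snpA, w)
    wB = window_snps(variants, snpB, w)
    if not wA.snp_ids or not wB.snp_ids:
        empty = snpA if not wA.snp_ids else snpB
        raise ValueError(f"empty fine-mapping window around {empty}")
    pairs = [
        (a, b) for a, b in itertools.product(wA.snp_ids, wB.snp_ids) if a != b
    ]
    stage = _run_stage(y, C, gm, pairs, "finemap", min_cell, max_r2)
    if stage.best_pair is None:
        raise ValueError("no eligible pairs in fine-mapping windows")
    m = stage.m + m_extra
    df = stage.results.copy()
    df["p_c"] = [bonferroni(p, m) for p in df["p"]]
    return FineMapResult(
        best_pair=stage.best_pair,
        best_p=stage.best_p,
        best_p_c=bonferroni(stage.best_p, m),
        m=m,
        results=df,
    )


@dataclass(frozen=True)
class CombinedEvidence:
    p: float  # Fisher-combined raw p
    p_c: float  # Bonferroni over the product of per-cohort test counts
    statistic: float
    df: int


def combine_cohort_evidence(
    best_p: list[float], test_counts: list[int]
) -> CombinedEvidence:
    """Fisher combination of per-cohort best raw p-values with a conservative
    Bonferroni correction over the product of per-cohort test counts.

    This recipe is one documented, configurable choice among several defensible
    ways to pool locus-level evidence across cohorts.
    """
    if len(best_p) < 2:
        raise ValueError("need at least two cohorts to combine")
    if len(best_p) != len(test_counts):
        raise ValueError("one test count per cohort required")
    for p in best_p:
        if not (0.0 < p <= 1.0):
            raise ValueError(f"p-value out of (0,1]: {p}")
    stat = float(-2.0 * np.sum(np.log(best_p)))
    df = 2 * len(best_p)
    p_comb = float(chi2.sf(stat, df))
    m = int(np.prod([max(int(c), 1) for c in test_counts]))
    return CombinedEvidence(p=p_comb, p_c=min(1.0, p_comb * m), statistic=stat, df=df)
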