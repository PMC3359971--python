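"""Discovery-scan orchestration: eligibility filtering, pair fitting, reporting.

Every pair in a candidate set is either fitted and tested or recorded with an
ineligibility reason, so result rows plus ineligible rows always account for
the full candidate set.  Output ordering is deterministic (genomic order of
both SNPs), and QQ coordinates use the mid-rank expected quantiles
-log10((i - 0.5) / m).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import epistasis_test as et
from . import geno_qc as gq
from .candidate_pairs import PairSet

logger = logging.getLogger(__name__)

__all__ = [
    "ScanConfig",
    "QQData",
    "PairEvaluation",
    "evaluate_pair",
    "run_scan",
    "ScanResult",
    "qq_data",
]

RESULT_COLUMNS = [
    "trait", "snp1", "snp2", "chrom1", "pos1", "chrom2", "pos2", "n",
    "a1", "se_a1", "d1", "se_d1", "a2", "se_a2", "d2", "se_d2",
    "i_aa", "se_i_aa", "i_ad", "se_i_ad", "i_da", "se_i_da", "i_dd", "se_i_dd",
    "F", "p", "p_c", "r2_1", "r2_2", "min_cell", "pair_r2",
]


@dataclass
class ScanConfig:
    """Thresholds and bookkeeping for a discovery or validation scan."""

    trait: str = "trait"
    min_cell: int = 20
    max_r2: float = 0.1
    alpha: float = 0.05
    min_call_rate: float = 0.90
    min_maf: float = 0.01
    hwe_alpha: float = 1e-6
    max_missing: float = 0.10
    window_stage2: int = 200_000
    window_stage3: int = 100_000
    seed: int = 0
    out_dir: str = "."

    def __post_init__(self) -> None:
        if not (0.0 <= self.max_r2 <= 1.0):
            raise ValueError("max_r2 must be in [0,1]")
        if self.min_cell < 0:
            raise ValueError("min_cell must be non-negative")
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError("alpha must be in (0,1]")


@dataclass
class PairEvaluation:
    """Outcome of evaluating one candidate pair: a fit or a reason for skipping."""

    snp1: str
    snp2: str
    fit: et.InteractionFit | None
    reason: str | None
    min_cell: int
    pair_r2: float


def evaluate_pair(
    y: np.ndarray,
    C: np.ndarray | None,
    gm: gq.GenotypeMatrix,
    snp1: str,
    snp2: str,
    min_cell: int = 20,
    max_r2: float = 0.1,
) -> PairEvaluation:
    """Apply the per-pair eligibility rules, then fit and test if eligible."""
    try:
        g1 = gm.column(snp1)
        g2 = gm.column(snp2)
    except KeyError:
        return PairEvaluation(snp1, snp2, None, "variant_missing", 0, np.nan)
    ct = gq.cell_table(g1, g2)
    try:
        r2 = gq.ld_r2(g1, g2)
    except ValueError:
        return PairEvaluation(snp1, snp2, None, "r2_undefined", ct.min_count, np.nan)
    if not gq.pair_eligible(ct, r2, min_cell=min_cell, max_r2=max_r2):
        reason = "cell_count" if ct.min_count <= min_cell else "high_ld"
        return PairEvaluation(snp1, snp2, None, reason, ct.min_count, r2)
    try:
        fit = et.fit_pair(y, C, g1, g2)
    except (et.DegenerateDesignError, ValueError) as exc:
        logger.info("pair (%s, %s) skipped: %s", snp1, snp2, exc)
        return PairEvaluation(snp1, snp2, None, "degenerate_fit", ct.min_count, r2)
    return PairEvaluation(snp1, snp2, fit, None, ct.min_count, r2)


@dataclass
class ScanResult:
    results: pd.DataFrame
    ineligible: pd.DataFrame
    m: int
    config: ScanConfig


def run_scan(
    gm: gq.GenotypeMatrix,
    y: np.ndarray,
    C: np.ndarray | None,
    pair_set: PairSet,
    config: ScanConfig | None = None,
    m: int | None = None,
) -> ScanResult:
    """Test every eligible candidate pair; Bonferroni-correct over m.

    ``m`` defaults to the candidate set's pre-filter pair count.  Hidden
    (simulated-causal) genotype columns are never scanned.
    """
    config = config or ScanConfig()
    if len(pair_set) == 0:
        raise ValueError("empty candidate pair set")
    gm = gm.visible()
    m = m if m is not None else pair_set.m

    rows: list[dict] = []
    skipped: list[dict] = []
    for snp1, snp2 in pair_set:
        ev = evaluate_pair(
            y, C, gm, snp1, snp2, min_cell=config.min_cell, max_r2=config.max_r2
        )
        if ev.fit is None:
            skipped.append(
                {"snp1": snp1, "snp2": snp2, "reason": ev.reason,
                 "min_cell": ev.min_cell, "pair_r2": ev.pair_r2}
            )
            continue
        fit = ev.fit
        v1 = gm.variants[gm.variant_index(snp1)]
        v2 = gm.variants[gm.variant_index(snp2)]
        row = {
            "trait": config.trait, "snp1": snp1, "snp2": snp2,
            "chrom1": v1.chrom, "pos1": v1.pos, "chrom2": v2.chrom, "pos2": v2.pos,
            "n": fit.n_complete,
            "F": fit.F, "p": fit.p, "p_c": et.bonferroni(fit.p, m),
            "r2_1": fit.r2_model1, "r2_2": fit.r2_model2,
            "min_cell": ev.min_cell, "pair_r2": ev.pair_r2,
        }
        for name in ("a1", "d1", "a2", "d2", *et.COMPONENTS):
            row[name] = getattr(fit, name)
            row[f"se_{name}"] = fit.se[name]
        rows.append(row)

    if not rows:
        counts = pd.Series([s["reason"] for s in skipped]).value_counts().to_dict()
        raise ValueError(f"no eligible pairs in scan; skip reasons: {counts}")

    results = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    results = results.sort_values(
        ["chrom1", "pos1", "chrom2", "pos2"], kind="mergesort"
    ).reset_index(drop=True)
    ineligible = pd.DataFrame(
        skipped, columns=["snp1", "snp2", "reason", "min_cell", "pair_r2"]
    )
    return ScanResult(results=results, ineligible=ineligible, m=m, config=config)


@dataclass
class QQData:
    """Observed vs expected -log10 p-value quantiles for a QQ plot."""

    observed: np.ndarray
    expected: np.ndarray
    m: int


def qq_data(pvals) -> QQData:
    """QQ coordinates: sorted observed -log10 p against -log10((i-0.5)/m)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    observed = -np.log10(np.sort(p)[::-1])  # ascending -log10
    expected = -np.log10((np.arange(m, 0, -1) - 0.5) / m)
    return QQData(observed=observed, expected=expected, m=m)
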