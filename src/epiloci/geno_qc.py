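"""Genotype I/O, quality control, and per-pair eligibility statistics.

Genotype calls are stored as ``int8`` counts of the alternate (counted)
allele, with ``-1`` marking a missing call.  All operations treat missing
calls as absent observations; pairwise statistics are computed over the
jointly non-missing subset of individuals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from scipy.stats import chi2

logger = logging.getLogger(__name__)

MISSING = np.int8(-1)

__all__ = [
    "MISSING",
    "VariantRecord",
    "GenotypeMatrix",
    "GenotypePosterior",
    "CellTable",
    "read_genotypes",
    "read_vcf",
    "read_plink",
    "write_plink",
    "hard_call",
    "filter_individuals",
    "filter_variants",
    "variant_qc_table",
    "maf",
    "hwe_test",
    "ld_r2",
    "cell_table",
    "pair_eligible",
]


@dataclass(frozen=True)
class VariantRecord:
    """A biallelic variant with 1-based coordinates.

    ``hidden`` marks simulated causal columns that must never enter a scan;
    they are retained only so tests can compare estimates against the truth.
    """

    id: str
    chrom: str
    pos: int
    ref_allele: str = "A"
    alt_allele: str = "G"
    info_score: float | None = None
    hidden: bool = False

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"variant {self.id}: pos must be >= 1, got {self.pos}")


@dataclass
class GenotypeMatrix:
    """Individuals x variants hard-call matrix (alt-allele dosage 0/1/2, -1 missing)."""

    samples: list[str]
    variants: list[VariantRecord]
    calls: np.ndarray
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        bad = ~np.isin(self.calls, (-1, 0, 1, 2))
        if bad.any():
            raise ValueError("genotype calls must be in {0,1,2} or -1 (missing)")
        ids = [v.id for v in self.variants]
        if len(set(ids)) != len(ids):
            raise ValueError("variant ids must be unique within a dataset")
        self._index = {vid: j for j, vid in enumerate(ids)}

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def variant_index(self, variant_id: str) -> int:
        try:
            return self._index[variant_id]
        except KeyError:
            raise KeyError(f"variant {variant_id!r} not present") from None

    def column(self, variant_id: str) -> np.ndarray:
        return self.calls[:, self.variant_index(variant_id)]

    def subset(
        self,
        sample_idx: Sequence[int] | np.ndarray | None = None,
        variant_idx: Sequence[int] | np.ndarray | None = None,
    ) -> "GenotypeMatrix":
        si = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        vi = np.arange(self.n_variants) if variant_idx is None else np.asarray(variant_idx)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in si],
            variants=[self.variants[j] for j in vi],
            calls=self.calls[np.ix_(si, vi)],
        )

    def visible(self) -> "GenotypeMatrix":
        """Drop columns flagged hidden (simulated causal variants)."""
        keep = [j for j, v in enumerate(self.variants) if not v.hidden]
        return self.subset(variant_idx=keep)


@dataclass
class GenotypePosterior:
    """Per-sample, per-variant genotype posterior probability triples."""

    samples: list[str]
    variants: list[VariantRecord]
    probs: np.ndarray  # (n_samples, n_variants, 3)

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (len(self.samples), len(self.variants), 3):
            raise ValueError("probs must have shape (n_samples, n_variants, 3)")
        if (self.probs < -1e-9).any() or (self.probs > 1 + 1e-9).any():
            raise ValueError("posterior probabilities must lie in [0,1]")
        sums = self.probs.sum(axis=2)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("posterior triples must sum to 1")


@dataclass(frozen=True)
class CellTable:
    """3x3 joint genotype counts for a SNP pair (rows SNP1 0/1/2, cols SNP2 0/1/2)."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        if c.shape != (3, 3):
            raise ValueError("cell table must be 3x3")
        if (c < 0).any():
            raise ValueError("cell counts must be non-negative")
        object.__setattr__(self, "counts", c)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def min_count(self) -> int:
        return int(self.counts.min())


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_PLINK_MAGIC = b"\x6c\x1b\x01"  # bed magic + SNP-major flag


def read_genotypes(path: str | Path, format: str | None = None) -> GenotypeMatrix:
    """Read a genotype matrix from a VCF or a PLINK .bed/.bim/.fam triple.

    ``format`` may be ``"vcf"`` or ``"plink-bed"``; when omitted it is
    inferred from the file name.
    """
    path = Path(path)
    if format is None:
        name = path.name.lower()
        if name.endswith((".vcf", ".vcf.gz")):
            format = "vcf"
        elif name.endswith(".bed") or path.with_suffix(".bed").exists():
            format = "plink-bed"
        else:
            raise ValueError(f"cannot infer genotype format for {path}")
    if format == "vcf":
        return read_vcf(path)
    if format == "plink-bed":
        prefix = path.with_suffix("") if path.suffix == ".bed" else path
        return read_plink(prefix)
    raise ValueError(f"unknown genotype format {format!r}")


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read hard calls from a VCF (GT field); multi-allelic records are skipped."""
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path), gts012=True)
    except Exception as exc:  # pragma: no cover - cyvcf2 error text varies
        raise ValueError(f"cannot parse VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    variants: list[VariantRecord] = []
    columns: list[np.ndarray] = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            logger.warning(
                "skipping multi-allelic record %s:%d (%s)", rec.CHROM, rec.POS, rec.ID
            )
            continue
        gt = np.asarray(rec.gt_types, dtype=np.int8)  # 0/1/2, 3 = missing
        gt[gt == 3] = MISSING
        info = rec.INFO.get("INFO", None)
        variants.append(
            VariantRecord(
                id=rec.ID or f"{rec.CHROM}:{rec.POS}",
                chrom=str(rec.CHROM),
                pos=int(rec.POS),
                ref_allele=rec.REF,
                alt_allele=rec.ALT[0],
                info_score=float(info) if info is not None else None,
            )
        )
        columns.append(gt)
    calls = (
        np.column_stack(columns)
        if columns
        else np.zeros((len(samples), 0), dtype=np.int8)
    )
    return GenotypeMatrix(samples=samples, variants=variants, calls=calls)


def read_plink(prefix: str | Path) -> GenotypeMatrix:
    """Read a PLINK .bed/.bim/.fam triple (SNP-major .bed)."""
    prefix = Path(prefix)
    bed_path = prefix.with_suffix(".bed")
    bim_path = prefix.with_suffix(".bim")
    fam_path = prefix.with_suffix(".fam")
    for p in (bed_path, bim_path, fam_path):
        if not p.exists():
            raise FileNotFoundError(f"missing PLINK file {p}")

    fam = pd.read_csv(fam_path, sep=r"\s+", header=None, dtype=str)
    samples = list(fam.iloc[:, 1])
    bim = pd.read_csv(bim_path, sep=r"\s+", header=None, dtype=str)
    if bim.shape[1] < 6:
        raise ValueError(f"malformed .bim file {bim_path}")
    variants = [
        VariantRecord(
            id=row[1],
            chrom=str(row[0]),
            pos=int(row[3]),
            # A1 is the counted allele, matching calls = A1 dosage
            alt_allele=row[4],
            ref_allele=row[5],
        )
        for row in bim.itertuples(index=False)
    ]

    raw = bed_path.read_bytes()
    if raw[:3] != _PLINK_MAGIC:
        raise ValueError(f"{bed_path}: bad magic bytes (not SNP-major PLINK bed)")
    n, m = len(samples), len(variants)
    bytes_per_snp = (n + 3) // 4
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if body.size != bytes_per_snp * m:
        raise ValueError(
            f"{bed_path}: expected {bytes_per_snp * m} data bytes, found {body.size}"
        )
    body = body.reshape(m, bytes_per_snp)
    # unpack two-bit codes: 00 hom A1, 01 missing, 10 het, 11 hom A2
    shifts = np.arange(4, dtype=np.uint8) * 2
    codes = (body[:, :, None] >> shifts[None, None, :]) & 0b11
    codes = codes.reshape(m, -1)[:, :n]
    decode = np.array([2, MISSING, 1, 0], dtype=np.int8)  # A1 dosage
    calls = decode[codes].T.copy()
    return GenotypeMatrix(samples=samples, variants=variants, calls=calls)


def write_plink(gm: GenotypeMatrix, prefix: str | Path) -> None:
    """Write a GenotypeMatrix as a PLINK .bed/.bim/.fam triple (A1 = counted allele)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for s in gm.samples:
            fh.write(f"{s} {s} 0 0 0 -9\n")
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for v in gm.variants:
            fh.write(f"{v.chrom}\t{v.id}\t0\t{v.pos}\t{v.alt_allele}\t{v.ref_allele}\n")
    n = gm.n_samples
    encode = {0: 0b11, 1: 0b10, 2: 0b00, -1: 0b01}
    lut = np.zeros(4, dtype=np.uint8)
    for g, code in encode.items():
        lut[g % 4] = code  # -1 -> index 3
    codes = lut[gm.calls.T % 4]  # (m, n)
    pad = (-n) % 4
    if pad:
        codes = np.pad(codes, ((0, 0), (0, pad)), constant_values=0b01)
    shifts = np.arange(4, dtype=np.uint8) * 2
    packed = (codes.reshape(codes.shape[0], -1, 4) << shifts).sum(axis=2).astype(np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_PLINK_MAGIC)
        fh.write(packed.tobytes())


# ---------------------------------------------------------------------------
# Posterior hard-calling
# ---------------------------------------------------------------------------

def hard_call(
    post: GenotypePosterior, info_min: float = 0.6, prob_min: float = 0.8
) -> GenotypeMatrix:
    """Convert genotype posteriors to hard calls.

    Variants whose imputation info score is below ``info_min`` are dropped
    entirely; for the rest, the maximum-posterior genotype is called when that
    maximum is at least ``prob_min``, otherwise the call is missing.
    """
    keep = [
        j
        for j, v in enumerate(post.variants)
        if v.info_score is None or v.info_score >= info_min
    ]
    probs = post.probs[:, keep, :]
    calls = probs.argmax(axis=2).astype(np.int8)
    calls[probs.max(axis=2) < prob_min] = MISSING
    return GenotypeMatrix(
        samples=list(post.samples),
        variants=[post.variants[j] for j in keep],
        calls=calls,
    )


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def filter_individuals(gm: GenotypeMatrix, max_missing: float = 0.10) -> GenotypeMatrix:
    """Remove individuals with a missing-call fraction strictly above ``max_missing``."""
    if gm.n_variants == 0:
        return gm
    frac = (gm.calls == MISSING).mean(axis=1)
    keep = np.flatnonzero(frac <= max_missing)
    if keep.size == 0:
        raise ValueError("all individuals removed by missingness filter")
    n_removed = gm.n_samples - keep.size
    if n_removed:
        logger.info("filter_individuals: removed %d individuals", n_removed)
    return gm.subset(sample_idx=keep)


def _variant_failures(
    gm: GenotypeMatrix,
    min_call_rate: float,
    min_maf: float,
    hwe_alpha: float,
    hwe_method: str,
) -> list[list[str]]:
    reasons: list[list[str]] = []
    for j in range(gm.n_variants):
        g = gm.calls[:, j]
        obs = g[g != MISSING]
        why: list[str] = []
        call_rate = obs.size / g.size if g.size else 0.0
        if call_rate < min_call_rate:
            why.append(f"call_rate<{min_call_rate}")
        if obs.size:
            f = obs.mean() / 2.0
            if min(f, 1.0 - f) <= min_maf:
                why.append(f"maf<={min_maf}")
            n0, n1, n2 = [int((obs == k).sum()) for k in (0, 1, 2)]
            if hwe_test(n0, n1, n2, method=hwe_method) < hwe_alpha:
                why.append(f"hwe_p<{hwe_alpha}")
        reasons.append(why)
    return reasons


def filter_variants(
    gm: GenotypeMatrix,
    min_call_rate: float = 0.90,
    min_maf: float = 0.01,
    hwe_alpha: float = 1e-6,
    hwe_method: str = "exact",
) -> GenotypeMatrix:
    """Remove variants failing call-rate, MAF, or HWE rules.

    Boundary conventions: call rate strictly below ``min_call_rate`` fails;
    MAF equal to ``min_maf`` fails (the rule is <=); HWE p strictly below
    ``hwe_alpha`` fails.  Hidden (simulated-causal) columns are exempt.
    """
    reasons = _variant_failures(gm, min_call_rate, min_maf, hwe_alpha, hwe_method)
    keep = [
        j
        for j, why in enumerate(reasons)
        if not why or gm.variants[j].hidden
    ]
    return gm.subset(variant_idx=keep)


def variant_qc_table(
    gm: GenotypeMatrix,
    min_call_rate: float = 0.90,
    min_maf: float = 0.01,
    hwe_alpha: float = 1e-6,
    hwe_method: str = "exact",
) -> pd.DataFrame:
    """Tab-report of per-variant QC outcomes: id, kept flag, reasons for removal."""
    reasons = _variant_failures(gm, min_call_rate, min_maf, hwe_alpha, hwe_method)
    return pd.DataFrame(
        {
            "variant": [v.id for v in gm.variants],
            "kept": [not why or gm.variants[j].hidden for j, why in enumerate(reasons)],
            "reason": [";".join(why) for why in reasons],
        }
    )


# ---------------------------------------------------------------------------
# Per-variant and per-pair statistics
# ---------------------------------------------------------------------------

def maf(g: np.ndarray) -> float:
    """Minor allele frequency of a genotype vector (missing = -1 skipped)."""
    g = np.asarray(g)
    obs = g[g != MISSING]
    if obs.size == 0:
        raise ValueError("cannot compute MAF of an all-missing vector")
    f = float(obs.mean()) / 2.0
    return min(f, 1.0 - f)


def hwe_test(n0: int, n1: int, n2: int, method: str = "exact") -> float:
    """Hardy-Weinberg equilibrium p-value from genotype counts.

    ``method="exact"`` runs the conditional exact test on the heterozygote
    count given the allele counts, summing the probabilities of all
    configurations no more probable than the observed one (two-sided).
    ``method="chisq"`` is the 1-df goodness-of-fit chi-square.
    """
    for c in (n0, n1, n2):
        if c < 0:
            raise ValueError("genotype counts must be non-negative")
    n = n0 + n1 + n2
    if n < 1:
        raise ValueError("need at least one genotype")
    n_rare = min(2 * n0 + n1, 2 * n2 + n1)  # copies of the rarer allele
    if n_rare == 0:
        return 1.0

    if method == "chisq":
        p = (2 * n2 + n1) / (2 * n)
        exp = np.array([n * (1 - p) ** 2, 2 * n * p * (1 - p), n * p**2])
        obs = np.array([n0, n1, n2], dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            stat = np.nansum(np.where(exp > 0, (obs - exp) ** 2 / exp, 0.0))
        return float(chi2.sf(stat, df=1))
    if method != "exact":
        raise ValueError(f"unknown HWE method {method!r}")

    # heterozygote counts share the parity of the rare-allele count
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    hom_rare = (n_rare - hets) // 2
    hom_common = n - hets - hom_rare
    # log conditional probability up to a shared constant
    logp = (
        hets * np.log(2.0)
        - gammaln(hom_rare + 1)
        - gammaln(hets + 1)
        - gammaln(hom_common + 1)
    )
    logp -= logsumexp(logp)
    obs_logp = logp[np.searchsorted(hets, n1)]
    pval = float(np.exp(logsumexp(logp[logp <= obs_logp + 1e-12])))
    return min(pval, 1.0)


def _joint_mask(g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    if g1.shape != g2.shape:
        raise ValueError("genotype vectors must have equal length")
    return (g1 != MISSING) & (g2 != MISSING)


def ld_r2(g1: np.ndarray, g2: np.ndarray) -> float:
    """Composite (dosage-correlation) LD r-squared over jointly observed calls.

    Phase is unknown in hard-call data, so the squared Pearson correlation of
    genotype dosages is used as the standard surrogate for haplotype r^2.
    """
    mask = _joint_mask(g1, g2)
    if mask.sum() < 3:
        raise ValueError("need at least 3 jointly non-missing individuals")
    a = np.asarray(g1)[mask].astype(float)
    b = np.asarray(g2)[mask].astype(float)
    if a.std() == 0 or b.std() == 0:
        raise ValueError("undefined r2: monomorphic genotype vector")
    r = np.corrcoef(a, b)[0, 1]
    return float(min(r * r, 1.0))


def cell_table(g1: np.ndarray, g2: np.ndarray) -> CellTable:
    """3x3 joint genotype counts over jointly non-missing individuals."""
    mask = _joint_mask(g1, g2)
    a = np.asarray(g1)[mask].astype(np.int64)
    b = np.asarray(g2)[mask].astype(np.int64)
    counts = np.bincount(3 * a + b, minlength=9).reshape(3, 3)
    return CellTable(counts=counts)


def pair_eligible(
    ct: CellTable, r2: float, min_cell: int = 20, max_r2: float = 0.1
) -> bool:
    """Eligibility rule for a SNP pair: every cell strictly exceeds ``min_cell``
    and the pairwise dosage r^2 is strictly below ``max_r2``.

    ``min_cell`` is 20 for discovery scans and 10 for validation scans.
    """
    return ct.min_count > min_cell and r2 < max_r2
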