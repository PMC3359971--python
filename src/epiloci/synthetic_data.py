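"""Synthetic genotype/phenotype generation for two interacting loci.

Generates the data-generating process the analysis assumes: HWE genotypes at
two unlinked loci (random mating, two independent haplotype draws per locus),
tag SNPs coupled to unobserved causal variants at a specified haplotype r^2,
phenotypes built from covariate effects plus Cockerham-parameterized marginal
and interaction effects at the causal loci, optional polygenic (kinship)
variance, optional two-subpopulation allele-frequency divergence, and optional
sibling-block pedigrees.

The causal genotype columns are kept in the output matrix but flagged hidden,
so scans never see them while tests can compare estimates against the truth.
The expected additive-by-additive effect observed at tag SNPs equals the
causal effect times the product of the two tag-causal dosage correlations;
dominance-component attenuation involves squared correlations and is checked
empirically rather than in closed form.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geno_qc import GenotypeMatrix, VariantRecord

logger = logging.getLogger(__name__)

__all__ = [
    "TwoLocusSpec",
    "EffectSpec",
    "CohortSpec",
    "LOCUS_CHROMS",
    "LOCUS_CENTERS",
    "max_r2",
    "sim_locus_haplotypes",
    "haplotype_r2",
    "sim_genotypes",
    "sim_window_genotypes",
    "sim_phenotype",
    "sim_stratified_genotypes",
    "sibling_block_kinship",
    "expected_tag_attenuation",
]

# the discovered interaction in the motivating analysis spans chr5 and chr15;
# simulated loci inherit those labels so windowing code sees realistic input
LOCUS_CHROMS = ("5", "15")
LOCUS_CENTERS = (74_650_000, 58_700_000)


@dataclass(frozen=True)
class TwoLocusSpec:
    """Tag and causal allele frequencies plus target tag-causal LD per locus.

    The two loci are unlinked (inter-locus LD zero); within a locus the tag
    and causal variant sit on shared haplotypes with r^2 equal to the target.
    """

    q1: float = 0.5  # causal MAFs
    q2: float = 0.5
    p1: float = 0.5  # tag MAFs
    p2: float = 0.5
    r2_1: float = 1.0  # target tag-causal haplotype r^2
    r2_2: float = 1.0

    def __post_init__(self) -> None:
        for name in ("q1", "q2", "p1", "p2"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must be in (0,1), got {v}")
        for name in ("r2_1", "r2_2"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0,1], got {v}")


@dataclass(frozen=True)
class EffectSpec:
    """Genetic and nuisance effects at the causal loci, in trait units."""

    a1: float = 0.0
    d1: float = 0.0
    a2: float = 0.0
    d2: float = 0.0
    i_aa: float = 0.0
    i_ad: float = 0.0
    i_da: float = 0.0
    i_dd: float = 0.0
    intercept: float = 0.0
    beta_sex: float = 0.0
    beta_age: float = 0.0
    beta_bmi: float = 0.0
    sigma_e: float = 1.0
    sigma_g: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma_e <= 0:
            raise ValueError("residual sd must be positive")
        if self.sigma_g < 0:
            raise ValueError("polygenic sd must be non-negative")


@dataclass(frozen=True)
class CohortSpec:
    n: int = 1000
    loci: TwoLocusSpec = field(default_factory=TwoLocusSpec)
    effects: EffectSpec = field(default_factory=EffectSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("cohort size must be >= 1")


def max_r2(p: float, q: float) -> float:
    """Largest haplotype r^2 achievable between loci with allele freqs p and q."""
    d_max = min(p * (1 - q), (1 - p) * q)
    return d_max**2 / (p * (1 - p) * q * (1 - q))


def sim_locus_haplotypes(q: float, p: float, target_r2: float) -> np.ndarray:
    """Closed-form 2x2 haplotype frequency table for a tag-causal SNP pair.

    Rows index the tag allele (0/1), columns the causal allele; allele 1 is
    the counted allele with frequency p (tag) and q (causal).  D is taken
    positive: D = r * sqrt(p(1-p)q(1-q)) with r = sqrt(target_r2).
    """
    feasible = max_r2(p, q)
    if target_r2 > feasible + 1e-12:
        raise ValueError(
            f"target r2={target_r2} infeasible for p={p}, q={q}; r2max={feasible:.6f}"
        )
    d = np.sqrt(min(target_r2, feasible)) * np.sqrt(p * (1 - p) * q * (1 - q))
    freqs = np.array(
        [
            [(1 - p) * (1 - q) + d, (1 - p) * q - d],
            [p * (1 - q) - d, p * q + d],
        ]
    )
    freqs = np.clip(freqs, 0.0, None)
    freqs /= freqs.sum()
    realized = haplotype_r2(freqs)
    if abs(realized - target_r2) > 1e-9 and target_r2 <= feasible:
        raise RuntimeError(f"haplotype solve drifted: realized r2={realized}")
    return freqs


def haplotype_r2(freqs: np.ndarray) -> float:
    """r^2 implied by a 2x2 haplotype frequency table."""
    p = freqs[1].sum()
    q = freqs[:, 1].sum()
    d = freqs[1, 1] - p * q
    denom = p * (1 - p) * q * (1 - q)
    return float(d * d / denom) if denom > 0 else 0.0


def _draw_locus(
    rng: np.random.Generator, n: int, q: float, p: float, r2: float
) -> tuple[np.ndarray, np.ndarray]:
    """Two haplotype draws per individual from the tag-causal table; returns
    (tag genotype, causal genotype) dosage vectors."""
    freqs = sim_locus_haplotypes(q, p, r2)
    idx = rng.choice(4, size=(n, 2), p=freqs.ravel())
    tag = (idx // 2).sum(axis=1).astype(np.int8)
    causal = (idx % 2).sum(axis=1).astype(np.int8)
    return tag, causal


def sim_genotypes(cohort: CohortSpec) -> GenotypeMatrix:
    """Simulate one tag and one hidden causal variant at each of two unlinked loci."""
    rng = np.random.default_rng(cohort.seed)
    sp = cohort.loci
    t1, c1 = _draw_locus(rng, cohort.n, sp.q1, sp.p1, sp.r2_1)
    t2, c2 = _draw_locus(rng, cohort.n, sp.q2, sp.p2, sp.r2_2)
    variants = [
        VariantRecord("tag1", LOCUS_CHROMS[0], LOCUS_CENTERS[0]),
        VariantRecord("causal1", LOCUS_CHROMS[0], LOCUS_CENTERS[0] + 10_000, hidden=True),
        VariantRecord("tag2", LOCUS_CHROMS[1], LOCUS_CENTERS[1]),
        VariantRecord("causal2", LOCUS_CHROMS[1], LOCUS_CENTERS[1] + 10_000, hidden=True),
    ]
    calls = np.column_stack([t1, c1, t2, c2])
    samples = [f"ind{i:06d}" for i in range(cohort.n)]
    return GenotypeMatrix(samples=samples, variants=variants, calls=calls)


def sim_window_genotypes(
    n: int,
    tags1: list[tuple[float, float, int]],
    tags2: list[tuple[float, float, int]],
    causal_maf: tuple[float, float] = (0.5, 0.5),
    seed: int = 0,
) -> GenotypeMatrix:
    """Simulate multiple tags per locus around hidden causal variants.

    ``tags1``/``tags2`` list (maf, target_r2, position_offset_bp) per tag;
    offsets are relative to the locus center.  Each tag haplotype allele is
    drawn conditionally on the causal allele of the same haplotype, so tags
    are conditionally independent given the causal variant and realize their
    individual tag-causal r^2 targets.
    """
    rng = np.random.default_rng(seed)
    variants: list[VariantRecord] = []
    columns: list[np.ndarray] = []
    for locus, (q, tags) in enumerate(zip(causal_maf, (tags1, tags2)), start=1):
        chrom = LOCUS_CHROMS[locus - 1]
        center = LOCUS_CENTERS[locus - 1]
        causal_hap = rng.random((n, 2)) < q  # two haplotypes per individual
        variants.append(
            VariantRecord(f"causal{locus}", chrom, center, hidden=True)
        )
        columns.append(causal_hap.sum(axis=1).astype(np.int8))
        for t, (p, r2, offset) in enumerate(tags, start=1):
            freqs = sim_locus_haplotypes(q, p, r2)
            # P(tag allele = 1 | causal allele)
            p_given = freqs[1] / freqs.sum(axis=0)
            prob = np.where(causal_hap, p_given[1], p_given[0])
            tag_hap = rng.random((n, 2)) < prob
            pos = center + offset
            variants.append(VariantRecord(f"tag{locus}_{t}", chrom, pos))
            columns.append(tag_hap.sum(axis=1).astype(np.int8))
    samples = [f"ind{i:06d}" for i in range(n)]
    return GenotypeMatrix(
        samples=samples, variants=variants, calls=np.column_stack(columns)
    )


def _cockerham(g: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = g.astype(float) - 1.0
    z = np.where(g == 1, 0.5, -0.5)
    return x, z


def sim_phenotype(
    gm: GenotypeMatrix,
    effects: EffectSpec,
    K: np.ndarray | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Build a trait from the hidden causal columns plus covariates and noise.

    Covariates: sex ~ Bernoulli(0.5), age ~ Uniform(45, 65), BMI ~ N(27, 4^2).
    The genetic signal enters at the causal loci through the Cockerham terms
    with the specified effects; an optional polygenic term N(0, sigma_g^2 K)
    and iid N(0, sigma_e^2) noise complete the trait.
    """
    rng = np.random.default_rng(seed)
    hidden = [v.id for v in gm.variants if v.hidden]
    if len(hidden) < 2:
        raise ValueError("need two hidden causal columns to build the phenotype")
    x1, z1 = _cockerham(gm.column(hidden[0]))
    x2, z2 = _cockerham(gm.column(hidden[1]))
    n = gm.n_samples
    sex = rng.integers(0, 2, size=n).astype(float)
    age = rng.uniform(45, 65, size=n)
    bmi = rng.normal(27, 4, size=n)
    y = (
        effects.intercept
        + effects.beta_sex * sex
        + effects.beta_age * age
        + effects.beta_bmi * bmi
        + effects.a1 * x1
        + effects.d1 * z1
        + effects.a2 * x2
        + effects.d2 * z2
        + effects.i_aa * x1 * x2
        + effects.i_ad * x1 * z2
        + effects.i_da * z1 * x2
        + effects.i_dd * z1 * z2
    )
    if effects.sigma_g > 0:
        if K is None:
            raise ValueError("sigma_g > 0 requires a kinship matrix")
        L = np.linalg.cholesky(K + 1e-10 * np.eye(n))
        y = y + effects.sigma_g * (L @ rng.standard_normal(n))
    y = y + effects.sigma_e * rng.standard_normal(n)
    cov = pd.DataFrame(
        {"sample_id": gm.samples, "sex": sex, "age": age, "age2": age**2, "bmi": bmi}
    )
    return y, cov


def sim_stratified_genotypes(
    n_per_pop: int,
    n_snps: int,
    divergence: float = 0.2,
    seed: int = 0,
) -> GenotypeMatrix:
    """Two subpopulations with allele frequencies split +/- divergence/2.

    Background SNPs for principal-component tests; base frequencies are drawn
    Uniform(0.2, 0.8) and shifted in opposite directions per subpopulation.
    """
    rng = np.random.default_rng(seed)
    base = rng.uniform(0.2, 0.8, size=n_snps)
    f1 = np.clip(base - divergence / 2, 0.01, 0.99)
    f2 = np.clip(base + divergence / 2, 0.01, 0.99)
    g1 = rng.binomial(2, f1, size=(n_per_pop, n_snps))
    g2 = rng.binomial(2, f2, size=(n_per_pop, n_snps))
    calls = np.vstack([g1, g2]).astype(np.int8)
    variants = [
        VariantRecord(f"bg{j}", "1", 1_000_000 + 1_000 * j) for j in range(n_snps)
    ]
    samples = [f"pop1_{i}" for i in range(n_per_pop)] + [
        f"pop2_{i}" for i in range(n_per_pop)
    ]
    return GenotypeMatrix(samples=samples, variants=variants, calls=calls)


def sibling_block_kinship(n_blocks: int, block_size: int) -> np.ndarray:
    """Block-diagonal expected-relatedness matrix of full-sibling families."""
    block = np.full((block_size, block_size), 0.5)
    np.fill_diagonal(block, 1.0)
    K = np.zeros((n_blocks * block_size, n_blocks * block_size))
    for b in range(n_blocks):
        s = b * block_size
        K[s : s + block_size, s : s + block_size] = block
    return K


def expected_tag_attenuation(causal_effect: float, r1: float, r2: float) -> float:
    """Expected additive-by-additive effect observed at the tags.

    The observed A x A interaction coefficient equals the causal coefficient
    scaled by the product of the two tag-causal dosage correlations.
    """
    for r in (r1, r2):
        if not (-1.0 <= r <= 1.0):
            raise ValueError(f"correlation out of [-1,1]: {r}")
    return causal_effect * r1 * r2
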