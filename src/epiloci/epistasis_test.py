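"""Two-SNP interaction testing in a covariate-adjusted linear model.

Genotypes enter through the orthogonal Cockerham coding: an additive score
x in {-1, 0, +1} for genotypes 0/1/2 and a dominance score z equal to +0.5
for heterozygotes and -0.5 for homozygotes.  Two nested ordinary-least-squares
models are fitted per pair:

    model 1:  y ~ covariates + a1 x1 + d1 z1 + a2 x2 + d2 z2
    model 2:  model 1 + i_aa x1 x2 + i_ad x1 z2 + i_da z1 x2 + i_dd z1 z2

The overall interaction test is the 4-df F-test between the two models; the
four interaction components are additionally tested one at a time by t-tests
on the model-2 coefficients.  Any affine-equivalent genotype coding gives the
identical F-test; the component estimates are specific to this coding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import f as f_dist
from scipy.stats import t as t_dist

logger = logging.getLogger(__name__)

__all__ = [
    "COMPONENTS",
    "DegenerateDesignError",
    "CodedGenotype",
    "InteractionFit",
    "ComponentTest",
    "cockerham_code",
    "fit_pair",
    "interaction_f_test",
    "additive_only_test",
    "partition_components",
    "delta_r2",
    "bonferroni",
]

COMPONENTS = ("i_aa", "i_ad", "i_da", "i_dd")
_EFFECTS = ("a1", "d1", "a2", "d2") + COMPONENTS


class DegenerateDesignError(ValueError):
    """Raised when the pair design is rank deficient (e.g. an absent genotype class)."""


@dataclass(frozen=True)
class CodedGenotype:
    """Cockerham scores for one SNP; NaN marks missing calls."""

    x: np.ndarray
    z: np.ndarray


def cockerham_code(g: np.ndarray) -> CodedGenotype:
    """Code genotypes 0/1/2 as (x, z) = (g-1, +0.5 het / -0.5 hom); missing -> NaN."""
    g = np.asarray(g, dtype=float)
    miss = (g == -1) | np.isnan(g)
    valid = np.isin(g[~miss], (0.0, 1.0, 2.0))
    if not valid.all():
        raise ValueError("genotype values must be in {0,1,2} or missing")
    x = g - 1.0
    z = np.where(g == 1.0, 0.5, -0.5)
    x[miss] = np.nan
    z = np.where(miss, np.nan, z)
    return CodedGenotype(x=x, z=z)


@dataclass
class InteractionFit:
    """Coefficients, standard errors, and fit summaries for one SNP pair."""

    a1: float
    d1: float
    a2: float
    d2: float
    i_aa: float
    i_ad: float
    i_da: float
    i_dd: float
    se: dict[str, float]
    beta0: np.ndarray
    rss1: float
    rss2: float
    df2: int
    n_complete: int
    r2_model1: float
    r2_model2: float
    F: float = field(default=np.nan)
    p: float = field(default=np.nan)


def _complete_cases(y, C, g1, g2):
    y = np.asarray(y, dtype=float)
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    n = y.shape[0]
    if C is None:
        C = np.empty((n, 0))
    C = np.asarray(C, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    if not (g1.shape[0] == g2.shape[0] == C.shape[0] == n):
        raise ValueError("y, C, g1, g2 must have equal length")
    mask = (
        np.isfinite(y)
        & np.isfinite(C).all(axis=1)
        & np.isfinite(g1)
        & (g1 != -1)
        & np.isfinite(g2)
        & (g2 != -1)
    )
    return y[mask], C[mask], g1[mask], g2[mask]


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns by incremental rank
        bad = []
        r = 0
        for j in range(X.shape[1]):
            rj = np.linalg.matrix_rank(X[:, : j + 1])
            if rj == r:
                bad.append(names[j])
            r = rj
        raise DegenerateDesignError(f"design rank deficient; collinear columns: {bad}")


def _ols(X: np.ndarray, y: np.ndarray):
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    return beta, rss


def fit_pair(
    y: np.ndarray,
    C: np.ndarray | None,
    g1: np.ndarray,
    g2: np.ndarray,
) -> InteractionFit:
    """Fit the no-interaction and full two-locus models for one SNP pair.

    ``C`` holds extra covariates (no intercept column; one is added
    internally).  Complete-case analysis over y, C, and both genotype vectors.
    Raises :class:`DegenerateDesignError` when the design is rank deficient,
    e.g. when a genotype class is absent after complete-casing.
    """
    y, C, g1, g2 = _complete_cases(y, C, g1, g2)
    n = y.shape[0]
    c1 = cockerham_code(g1)
    c2 = cockerham_code(g2)
    base = np.column_stack([np.ones(n), C, c1.x, c1.z, c2.x, c2.z])
    inter = np.column_stack([c1.x * c2.x, c1.x * c2.z, c1.z * c2.x, c1.z * c2.z])
    X2 = np.column_stack([base, inter])
    p2 = X2.shape[1]
    if n < p2 + 1:
        raise ValueError(f"insufficient complete cases: n={n} for {p2} parameters")
    cov_names = [f"cov{j}" for j in range(C.shape[1])]
    names = ["intercept", *cov_names, "a1", "d1", "a2", "d2", *COMPONENTS]
    _check_rank(X2, names)

    beta1, rss1 = _ols(base, y)
    beta2, rss2 = _ols(X2, y)
    df2 = n - p2
    sigma2 = rss2 / df2
    xtx_inv = np.linalg.inv(X2.T @ X2)
    se_all = np.sqrt(sigma2 * np.diag(xtx_inv))

    tss = float(((y - y.mean()) ** 2).sum())
    if tss == 0:
        raise ValueError("trait vector is constant")
    n_cov = 1 + C.shape[1]
    effects = dict(zip(_EFFECTS, beta2[n_cov:]))
    se = dict(zip(_EFFECTS, se_all[n_cov:]))
    fit = InteractionFit(
        **effects,
        se=se,
        beta0=beta2[:n_cov],
        rss1=rss1,
        rss2=min(rss2, rss1),
        df2=df2,
        n_complete=n,
        r2_model1=1.0 - rss1 / tss,
        r2_model2=1.0 - min(rss2, rss1) / tss,
    )
    fit.F, fit.p = interaction_f_test(fit)
    return fit


def interaction_f_test(fit: InteractionFit) -> tuple[float, float]:
    """4-df F-test of model 2 against model 1: any interaction of any form."""
    if fit.df2 <= 0:
        raise ValueError("no residual degrees of freedom")
    if fit.rss2 <= 0:
        raise ValueError("saturated model: residual sum of squares is zero")
    num = max(fit.rss1 - fit.rss2, 0.0) / 4.0
    F = num / (fit.rss2 / fit.df2)
    p = float(f_dist.sf(F, 4, fit.df2))
    return float(F), max(p, np.finfo(float).tiny)


def additive_only_test(
    y: np.ndarray,
    C: np.ndarray | None,
    g1: np.ndarray,
    g2: np.ndarray,
) -> tuple[float, float]:
    """1-df F-test of the additive-by-additive term over an additive-only base.

    Mirrors the common pairwise-epistasis scan that models each SNP by its
    dosage alone and tests the single product term.
    """
    y, C, g1, g2 = _complete_cases(y, C, g1, g2)
    n = y.shape[0]
    x1 = g1 - 1.0
    x2 = g2 - 1.0
    base = np.column_stack([np.ones(n), C, x1, x2])
    full = np.column_stack([base, x1 * x2])
    if n < full.shape[1] + 1:
        raise ValueError("insufficient complete cases")
    _check_rank(full, ["intercept", *[f"cov{j}" for j in range(C.shape[1])], "x1", "x2", "x1x2"])
    _, rss_base = _ols(base, y)
    _, rss_full = _ols(full, y)
    df = n - full.shape[1]
    if rss_full <= 0:
        raise ValueError("saturated model")
    F = max(rss_base - rss_full, 0.0) / (rss_full / df)
    return float(F), float(f_dist.sf(F, 1, df))


@dataclass(frozen=True)
class ComponentTest:
    estimate: float
    se: float
    t: float
    p: float
    significant: bool


def partition_components(fit: InteractionFit, alpha: float = 0.01) -> dict[str, ComponentTest]:
    """t-tests of the four interaction components of the fitted model 2."""
    out = {}
    for name in COMPONENTS:
        est = getattr(fit, name)
        se = fit.se[name]
        t = est / se if se > 0 else 0.0
        p = float(2.0 * t_dist.sf(abs(t), fit.df2)) if se > 0 else 1.0
        out[name] = ComponentTest(estimate=est, se=se, t=t, p=p, significant=p < alpha)
    return out


def delta_r2(fit: InteractionFit) -> float:
    """Additional variance fraction explained by the interaction terms."""
    return max(fit.r2_model2 - fit.r2_model1, 0.0)


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-corrected p-value min(1, p*m)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value out of range: {p}")
    if m < 1:
        raise ValueError("number of tests must be >= 1")
    return min(1.0, p * m)
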