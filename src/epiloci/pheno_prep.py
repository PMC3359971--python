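"""Phenotype and covariate preparation.

Builds analysis-ready trait vectors: averages repeated visits, log-transforms
TG, excludes medicated individuals, assembles the covariate design (sex, age,
age^2, BMI, optional plate dummies, top principal components), and removes
familial covariance by mixed-model residualization against a kinship matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .geno_qc import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "average_trait",
    "transform_tg",
    "exclude_medicated",
    "prepare_phenotypes",
    "covariate_design",
    "compute_pcs",
    "kinship_from_pedigree",
    "KinshipFit",
    "fit_kinship_model",
    "kinship_residualize",
]

TRAITS = ("TC", "LDL-C", "TG", "HDL-C")


def average_trait(measurements) -> float:
    """Arithmetic mean of the non-missing per-visit values."""
    vals = np.asarray(measurements, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("all visit measurements are missing")
    return float(vals.mean())


def transform_tg(tg: float) -> float:
    """Natural log of a (positive) TG level."""
    if tg <= 0:
        raise ValueError(f"TG level must be positive, got {tg}")
    return float(np.log(tg))


def exclude_medicated(table: pd.DataFrame, med_flag: str = "lipid_med") -> pd.DataFrame:
    """Drop rows whose medication flag is truthy; a missing flag means not medicated."""
    flag = table[med_flag].notna() & table[med_flag].astype("boolean").fillna(False)
    n_removed = int(flag.sum())
    if n_removed:
        logger.info("exclude_medicated: removed %d individuals", n_removed)
    return table.loc[~flag].copy()


def prepare_phenotypes(
    visits: pd.DataFrame,
    trait: str,
    sample_col: str = "sample_id",
    med_flag: str = "lipid_med",
) -> pd.DataFrame:
    """Collapse a per-visit table into one row per individual.

    The visit table must carry ``sample_col``, the trait column, and may carry
    ``sex``, ``age``, ``bmi``, ``plate`` and a medication flag.  Trait, age and
    BMI are averaged over visits; age^2 is the square of the averaged age; TG
    is log-transformed after averaging.  Medicated individuals and individuals
    with no non-missing trait measurement are excluded.
    """
    if trait not in visits.columns:
        raise KeyError(f"trait column {trait!r} not in visit table")

    rows = []
    for sid, grp in visits.groupby(sample_col, sort=False):
        vals = grp[trait].to_numpy(dtype=float)
        if not np.isfinite(vals).any():
            logger.info("prepare_phenotypes: %s excluded (trait all missing)", sid)
            continue
        row: dict = {sample_col: sid, trait: average_trait(vals)}
        for cov in ("age", "bmi"):
            if cov in grp.columns:
                cvals = grp[cov].to_numpy(dtype=float)
                row[cov] = average_trait(cvals) if np.isfinite(cvals).any() else np.nan
        if "age" in row and np.isfinite(row["age"]):
            row["age2"] = row["age"] ** 2
        for cov in ("sex", "plate"):
            if cov in grp.columns:
                row[cov] = grp[cov].iloc[0]
        if med_flag in grp.columns:
            row[med_flag] = bool(
                grp[med_flag].astype("boolean").fillna(False).any()
            )
        rows.append(row)
    table = pd.DataFrame(rows)
    if med_flag in table.columns:
        table = exclude_medicated(table, med_flag).drop(columns=[med_flag])
    if trait == "TG":
        table[trait] = [transform_tg(v) for v in table[trait]]
    return table.reset_index(drop=True)


def covariate_design(
    table: pd.DataFrame,
    numeric: tuple[str, ...] = ("sex", "age", "age2", "bmi"),
    categorical: tuple[str, ...] = ("plate",),
    pcs: np.ndarray | None = None,
) -> np.ndarray:
    """Covariate matrix (no intercept): numeric columns, plate dummies, PCs.

    Model-fitting code adds the intercept itself, so the categorical dummies
    drop their first level to keep the design full-rank.
    """
    cols = [table[c].to_numpy(dtype=float) for c in numeric if c in table.columns]
    for c in categorical:
        if c in table.columns:
            dummies = pd.get_dummies(table[c], drop_first=True, dtype=float)
            cols.extend(dummies[c] for c in dummies.columns)
    parts = [np.column_stack(cols)] if cols else []
    if pcs is not None:
        parts.append(np.asarray(pcs, dtype=float))
    if not parts:
        return np.empty((len(table), 0))
    return np.column_stack(parts)


def compute_pcs(gm: GenotypeMatrix, k: int = 10) -> np.ndarray:
    """Top-k principal-component coordinates of the standardized genotype matrix.

    Missing calls are mean-imputed per variant; columns are centred and scaled
    by sqrt(2 p (1-p)); monomorphic columns are dropped.  Coordinates are the
    left singular vectors scaled by their singular values, with a deterministic
    sign convention.
    """
    if gm.n_samples <= k:
        raise ValueError(f"need more than k={k} individuals")
    G = gm.calls.astype(float)
    G[gm.calls == MISSING] = np.nan
    means = np.nanmean(G, axis=0)
    inds = np.where(np.isnan(G))
    G[inds] = np.take(means, inds[1])
    p = means / 2.0
    scale = np.sqrt(2.0 * p * (1.0 - p))
    poly = scale > 0
    if poly.sum() < k:
        raise ValueError(f"need at least k={k} polymorphic variants")
    Z = (G[:, poly] - means[poly]) / scale[poly]
    U, s, _ = np.linalg.svd(Z, full_matrices=False)
    coords = U[:, :k] * s[:k]
    # sign convention: largest-magnitude loading positive
    for j in range(coords.shape[1]):
        i = np.argmax(np.abs(coords[:, j]))
        if coords[i, j] < 0:
            coords[:, j] *= -1
    return coords


def kinship_from_pedigree(pedigree: pd.DataFrame) -> tuple[list[str], np.ndarray]:
    """Expected-relatedness (numerator-relationship) matrix from (id, father, mother).

    Unknown parents are coded "0", empty or NaN.  Rows may appear in any order;
    parents are sorted before offspring internally.  Returns (ids, K) with K
    following the pedigree's input id order.
    """
    ped = pedigree.copy()
    ped.columns = ["id", "father", "mother"][: len(ped.columns)]
    known = set(ped["id"])

    def norm(x):
        return None if (pd.isna(x) or str(x) == "0" or str(x) not in known) else str(x)

    parents = {str(r.id): (norm(r.father), norm(r.mother)) for r in ped.itertuples()}
    order: list[str] = []
    seen: set[str] = set()

    def visit(i: str) -> None:
        if i in seen:
            return
        seen.add(i)
        for par in parents[i]:
            if par is not None:
                visit(par)
        order.append(i)

    for i in parents:
        visit(i)
    idx = {i: j for j, i in enumerate(order)}
    n = len(order)
    A = np.zeros((n, n))
    for i in order:
        ii = idx[i]
        f, m = parents[i]
        A[ii, ii] = 1.0 + (0.5 * A[idx[f], idx[m]] if f and m else 0.0)
        for jname in order[: order.index(i)]:
            jj = idx[jname]
            val = 0.0
            if f:
                val += 0.5 * A[idx[f], jj]
            if m:
                val += 0.5 * A[idx[m], jj]
            A[ii, jj] = A[jj, ii] = val
    input_order = [str(i) for i in ped["id"]]
    perm = [idx[i] for i in input_order]
    return input_order, A[np.ix_(perm, perm)]


@dataclass
class KinshipFit:
    """Mixed-model fit y = X beta + g + e with g ~ (0, s2g K), e ~ (0, s2e I)."""

    residuals: np.ndarray
    beta: np.ndarray
    ratio: float  # s2g / s2e
    sigma2_e: float
    sigma2_g: float


def fit_kinship_model(
    y: np.ndarray, X: np.ndarray, K: np.ndarray, psd_tol: float = 1e-6
) -> KinshipFit:
    """REML fit of the single-variance-ratio mixed model via eigendecomposition.

    K is eigendecomposed once; the restricted likelihood is then a 1-D function
    of delta = s2g/s2e, optimized on the log scale.  Residuals subtract both the
    fixed effects and the BLUP of the genetic value.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    K = np.asarray(K, dtype=float)
    n, p = X.shape
    if y.shape != (n,) or K.shape != (n, n):
        raise ValueError("dimension mismatch among y, X, K")
    if not np.allclose(K, K.T, atol=1e-8):
        raise ValueError("kinship matrix must be symmetric")
    s, U = np.linalg.eigh(K)
    if s.min() < -psd_tol * max(s.max(), 1.0):
        raise ValueError(f"kinship matrix is not PSD (min eigenvalue {s.min():.3g})")
    s = np.clip(s, 0.0, None)
    yt = U.T @ y
    Xt = U.T @ X

    def neg_reml(delta: float) -> tuple[float, np.ndarray, float]:
        w = 1.0 / (delta * s + 1.0)
        sw = np.sqrt(w)
        Xw = Xt * sw[:, None]
        yw = yt * sw
        beta, _, rank, _ = np.linalg.lstsq(Xw, yw, rcond=None)
        if rank < p:
            raise np.linalg.LinAlgError("covariate design is rank deficient")
        resid = yw - Xw @ beta
        rss = float(resid @ resid)
        sigma2 = rss / (n - p)
        _, logdet_xx = np.linalg.slogdet(Xw.T @ Xw)
        crit = (n - p) * np.log(sigma2) - np.log(w).sum() + logdet_xx
        return 0.5 * crit, beta, sigma2

    f0, beta0, sig0 = neg_reml(0.0)
    opt = minimize_scalar(
        lambda t: neg_reml(np.exp(t))[0], bounds=(-10.0, 10.0), method="bounded"
    )
    if not opt.success:
        raise RuntimeError(f"REML optimization failed: {opt.message}")
    delta = float(np.exp(opt.x))
    f_opt, beta_opt, sig_opt = neg_reml(delta)
    if f0 <= f_opt + 1e-7:  # flat or no-genetic-variance likelihood: collapse to OLS
        delta, beta_opt, sig_opt = 0.0, beta0, sig0
    w = 1.0 / (delta * s + 1.0)
    rt = yt - Xt @ beta_opt
    residuals = U @ (w * rt)
    return KinshipFit(
        residuals=residuals,
        beta=beta_opt,
        ratio=delta,
        sigma2_e=sig_opt,
        sigma2_g=delta * sig_opt,
    )


def kinship_residualize(y: np.ndarray, X: np.ndarray, K: np.ndarray) -> np.ndarray:
    """Trait residuals after removing fixed effects and the kinship BLUP."""
    return fit_kinship_model(y, X, K).residuals
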