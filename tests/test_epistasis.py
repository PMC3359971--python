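"""Tests for the Cockerham-coded two-SNP interaction model.

The brute-force oracle here solves the normal equations directly with
explicit matrix inverses and evaluates F/t distributions independently of the
package's fitting path.
"""

import numpy as np
import pytest
import scipy.stats

from epiloci import synthetic_data as sd
from epiloci.epistasis_test import (
    COMPONENTS,
    DegenerateDesignError,
    additive_only_test,
    bonferroni,
    cockerham_code,
    delta_r2,
    fit_pair,
    interaction_f_test,
    partition_components,
)


# ---------------------------------------------------------------------------
# independent oracle: normal equations + distribution functions
# ---------------------------------------------------------------------------


def oracle_fit(y, C, g1, g2):
    """Normal-equations OLS of both nested models; returns coefficient dict,
    SEs, RSS pair, F and p, computed without the package's code path."""
    mask = (g1 >= 0) & (g2 >= 0) & np.isfinite(y)
    if C is not None:
        mask &= np.isfinite(C).all(axis=1)
    y = y[mask]
    g1 = g1[mask]
    g2 = g2[mask]
    n = y.size
    x1, z1 = g1 - 1.0, np.where(g1 == 1, 0.5, -0.5)
    x2, z2 = g2 - 1.0, np.where(g2 == 1, 0.5, -0.5)
    cov = C[mask] if C is not None else np.empty((n, 0))
    X1 = np.column_stack([np.ones(n), cov, x1, z1, x2, z2])
    X2 = np.column_stack([X1, x1 * x2, x1 * z2, z1 * x2, z1 * z2])
    b1 = np.linalg.solve(X1.T @ X1, X1.T @ y)
    b2 = np.linalg.solve(X2.T @ X2, X2.T @ y)
    rss1 = float(((y - X1 @ b1) ** 2).sum())
    rss2 = float(((y - X2 @ b2) ** 2).sum())
    df2 = n - X2.shape[1]
    F = ((rss1 - rss2) / 4.0) / (rss2 / df2)
    p = scipy.stats.f.sf(F, 4, df2)
    sigma2 = rss2 / df2
    se = np.sqrt(sigma2 * np.diag(np.linalg.inv(X2.T @ X2)))
    names = ["a1", "d1", "a2", "d2", "i_aa", "i_ad", "i_da", "i_dd"]
    k = 1 + cov.shape[1]
    return {
        "coefs": dict(zip(names, b2[k:])),
        "se": dict(zip(names, se[k:])),
        "rss1": rss1,
        "rss2": rss2,
        "F": F,
        "p": p,
        "df2": df2,
    }


def random_instance(rng, n=200, n_cov=3):
    g1 = rng.integers(0, 3, size=n).astype(np.int8)
    g2 = rng.integers(0, 3, size=n).astype(np.int8)
    C = rng.standard_normal((n, n_cov))
    y = rng.standard_normal(n) + 0.3 * g1 + 0.2 * g2 + C @ rng.standard_normal(n_cov)
    return y, C, g1, g2


# ---------------------------------------------------------------------------
# cockerham_code
# ---------------------------------------------------------------------------


def test_coding_definition():
    coded = cockerham_code(np.array([0, 1, 2]))
    np.testing.assert_array_equal(coded.x, [-1.0, 0.0, 1.0])
    np.testing.assert_array_equal(coded.z, [-0.5, 0.5, -0.5])


def test_coding_missing_propagates():
    coded = cockerham_code(np.array([0, -1, 2]))
    assert np.isnan(coded.x[1]) and np.isnan(coded.z[1])


def test_coding_rejects_bad_values():
    with pytest.raises(ValueError):
        cockerham_code(np.array([0, 3, 1]))


def test_coding_z_zero_mean_at_half_frequency():
    # E[z] under HWE genotype probabilities (0.25, 0.5, 0.25)
    probs = np.array([0.25, 0.5, 0.25])
    z = cockerham_code(np.array([0, 1, 2])).z
    assert probs @ z == pytest.approx(0.0)


# ---------------------------------------------------------------------------
# fit_pair
# ---------------------------------------------------------------------------


def test_fit_pair_null_construction(rng):
    """y built exactly as the no-interaction model: interaction terms vanish."""
    n = 500
    g1 = rng.integers(0, 3, size=n).astype(np.int8)
    g2 = rng.integers(0, 3, size=n).astype(np.int8)
    c1 = cockerham_code(g1)
    c2 = cockerham_code(g2)
    y = 2.0 + 1.5 * c1.x - 0.7 * c1.z + 0.9 * c2.x + 0.4 * c2.z
    fit = fit_pair(y, None, g1, g2)
    for name in COMPONENTS:
        assert getattr(fit, name) == pytest.approx(0.0, abs=1e-9)
    assert fit.rss1 == pytest.approx(0.0, abs=1e-14)
    assert fit.rss2 == pytest.approx(0.0, abs=1e-14)
    assert fit.a1 == pytest.approx(1.5)
    assert fit.d1 == pytest.approx(-0.7)


def test_fit_pair_recovers_injected_idd():
    spec = sd.CohortSpec(
        n=10_000, effects=sd.EffectSpec(i_dd=5.0, sigma_e=10.0), seed=77
    )
    gm = sd.sim_genotypes(spec)
    y, _ = sd.sim_phenotype(gm, spec.effects, seed=78)
    fit = fit_pair(y, None, gm.column("tag1"), gm.column("tag2"))
    assert abs(fit.i_dd - 5.0) < 2 * fit.se["i_dd"]


@pytest.mark.parametrize("seed", range(5))
def test_fit_pair_matches_oracle(seed):
    rng = np.random.default_rng(seed)
    y, C, g1, g2 = random_instance(rng)
    fit = fit_pair(y, C, g1, g2)
    ref = oracle_fit(y, C, g1, g2)
    for name, val in ref["coefs"].items():
        assert getattr(fit, name) == pytest.approx(val, rel=1e-10)
        assert fit.se[name] == pytest.approx(ref["se"][name], rel=1e-10)
    assert fit.rss1 == pytest.approx(ref["rss1"], rel=1e-10)
    assert fit.rss2 == pytest.approx(ref["rss2"], rel=1e-10)
    assert fit.F == pytest.approx(ref["F"], rel=1e-8)
    assert fit.p == pytest.approx(ref["p"], rel=1e-8)


def test_fit_pair_complete_case_missingness(rng):
    y, C, g1, g2 = random_instance(rng, n=300)
    g1_miss = g1.copy()
    g1_miss[:30] = -1
    fit = fit_pair(y, C, g1_miss, g2)
    sub = fit_pair(y[30:], C[30:], g1[30:], g2[30:])
    assert fit.n_complete == 270
    assert fit.F == pytest.approx(sub.F)


def test_fit_pair_degenerate_class_raises(rng):
    g1 = np.array([0, 2] * 100)  # no heterozygotes: z collinear with intercept
    g2 = rng.integers(0, 3, size=200).astype(np.int8)
    y = rng.standard_normal(200)
    with pytest.raises(DegenerateDesignError):
        fit_pair(y, None, g1, g2)


def test_fit_pair_insufficient_n(rng):
    with pytest.raises(ValueError):
        fit_pair(rng.standard_normal(8), None,
                 np.array([0, 1, 2, 0, 1, 2, 0, 1]), np.array([0, 1, 2, 1, 0, 2, 1, 0]))


def test_fit_pair_nested_model_invariants(rng):
    y, C, g1, g2 = random_instance(rng)
    fit = fit_pair(y, C, g1, g2)
    assert fit.rss2 <= fit.rss1
    assert fit.F >= 0
    assert 0 < fit.p <= 1
    assert fit.r2_model2 >= fit.r2_model1
    assert delta_r2(fit) == pytest.approx(fit.r2_model2 - fit.r2_model1)


def test_allele_relabel_invariance(rng):
    """Swapping allele labels at a SNP leaves F and p unchanged; additive and
    A x * coefficients flip sign, dominance-only terms are unchanged."""
    y, C, g1, g2 = random_instance(rng)
    fit = fit_pair(y, C, g1, g2)
    flip = fit_pair(y, C, (2 - g1).astype(np.int8), g2)
    assert flip.F == pytest.approx(fit.F, rel=1e-9)
    assert flip.p == pytest.approx(fit.p, rel=1e-9)
    assert flip.a1 == pytest.approx(-fit.a1)
    assert flip.d1 == pytest.approx(fit.d1)
    assert flip.i_aa == pytest.approx(-fit.i_aa)
    assert flip.i_ad == pytest.approx(-fit.i_ad)
    assert flip.i_da == pytest.approx(fit.i_da)
    assert flip.i_dd == pytest.approx(fit.i_dd)


def test_design_orthogonality_under_hwe():
    """At allele frequency 0.5 under HWE and linkage equilibrium the coded
    columns and their products are orthogonal in expectation."""
    rng = np.random.default_rng(99)
    n = 50_000
    g1 = rng.binomial(2, 0.5, size=n)
    g2 = rng.binomial(2, 0.5, size=n)
    c1 = cockerham_code(g1)
    c2 = cockerham_code(g2)
    cols = np.column_stack(
        [c1.x, c1.z, c2.x, c2.z, c1.x * c2.x, c1.x * c2.z, c1.z * c2.x, c1.z * c2.z]
    )
    cols -= cols.mean(axis=0)
    gram = cols.T @ cols / n
    off = gram - np.diag(np.diag(gram))
    assert np.abs(off).max() < 0.02


# ---------------------------------------------------------------------------
# interaction_f_test
# ---------------------------------------------------------------------------


def test_f_test_equal_rss():
    fit = _dummy_fit(rss1=100.0, rss2=100.0, df2=1000)
    F, p = interaction_f_test(fit)
    assert F == 0.0
    assert p == pytest.approx(1.0)


def test_f_test_arithmetic():
    fit = _dummy_fit(rss1=110.0, rss2=100.0, df2=1000)
    F, p = interaction_f_test(fit)
    assert F == pytest.approx(25.0)
    assert p == pytest.approx(scipy.stats.f.sf(25.0, 4, 1000), rel=1e-12)


def test_f_test_saturated_model_errors():
    with pytest.raises(ValueError, match="saturated"):
        interaction_f_test(_dummy_fit(rss1=1.0, rss2=0.0, df2=10))


def _dummy_fit(rss1, rss2, df2):
    from epiloci.epistasis_test import InteractionFit

    return InteractionFit(
        a1=0, d1=0, a2=0, d2=0, i_aa=0, i_ad=0, i_da=0, i_dd=0,
        se={k: 1.0 for k in ("a1", "d1", "a2", "d2", *COMPONENTS)},
        beta0=np.zeros(1), rss1=rss1, rss2=rss2, df2=df2, n_complete=df2 + 13,
        r2_model1=0.0, r2_model2=0.0,
    )


def test_f_test_type_one_error_small():
    """Modest-size null calibration; the full 10k-replicate check lives in
    the acceptance suite."""
    rng = np.random.default_rng(2024)
    reps, n = 2000, 500
    hits = 0
    for _ in range(reps):
        g1 = rng.binomial(2, 0.5, size=n).astype(np.int8)
        g2 = rng.binomial(2, 0.5, size=n).astype(np.int8)
        y = rng.standard_normal(n) + 0.5 * g1 - 0.3 * (g2 == 1)
        fit = fit_pair(y, None, g1, g2)
        if fit.p < 0.05:
            hits += 1
    assert 0.03 <= hits / reps <= 0.07


# ---------------------------------------------------------------------------
# additive-only (1-df) test
# ---------------------------------------------------------------------------


def test_additive_only_zero_noise_additive_trait(rng):
    n = 300
    g1 = rng.integers(0, 3, size=n).astype(np.int8)
    g2 = rng.integers(0, 3, size=n).astype(np.int8)
    y = 1.0 + 0.5 * g1 - 0.25 * g2
    # y exactly additive in the dosages: the product-term coefficient is zero
    x1, x2 = g1 - 1.0, g2 - 1.0
    X = np.column_stack([np.ones(n), x1, x2, x1 * x2])
    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    assert beta[3] == pytest.approx(0.0, abs=1e-10)
    y_noise = y + 1e-3 * rng.standard_normal(n)
    F, p = additive_only_test(y_noise, None, g1, g2)
    assert p > 0.001


def test_additive_only_beats_4df_on_pure_aa_signal():
    wins = 0
    reps = 200
    for seed in range(reps):
        rng = np.random.default_rng(seed)
        n = 400
        g1 = rng.binomial(2, 0.5, size=n).astype(np.int8)
        g2 = rng.binomial(2, 0.5, size=n).astype(np.int8)
        x1, x2 = g1 - 1.0, g2 - 1.0
        y = 0.35 * x1 * x2 + rng.standard_normal(n)
        _, p1 = additive_only_test(y, None, g1, g2)
        p4 = fit_pair(y, None, g1, g2).p
        if p1 < p4:
            wins += 1
    assert wins > reps / 2


def test_additive_only_type_one_error():
    rng = np.random.default_rng(7)
    reps, n = 2000, 400
    hits = 0
    for _ in range(reps):
        g1 = rng.binomial(2, 0.5, size=n).astype(np.int8)
        g2 = rng.binomial(2, 0.5, size=n).astype(np.int8)
        y = rng.standard_normal(n)
        _, p = additive_only_test(y, None, g1, g2)
        if p < 0.05:
            hits += 1
    assert 0.03 <= hits / reps <= 0.07


# ---------------------------------------------------------------------------
# component partition
# ---------------------------------------------------------------------------


def test_partition_zero_estimate():
    fit = _dummy_fit(rss1=2.0, rss2=1.0, df2=100)
    comp = partition_components(fit)
    for name in COMPONENTS:
        assert comp[name].t == 0.0
        assert comp[name].p == pytest.approx(1.0)
        assert not comp[name].significant


def test_partition_matches_t_distribution(rng):
    y, C, g1, g2 = random_instance(rng)
    fit = fit_pair(y, C, g1, g2)
    ref = oracle_fit(y, C, g1, g2)
    comp = partition_components(fit)
    for name in COMPONENTS:
        t_ref = ref["coefs"][name] / ref["se"][name]
        p_ref = 2 * scipy.stats.t.sf(abs(t_ref), ref["df2"])
        assert comp[name].t == pytest.approx(t_ref, rel=1e-8)
        assert comp[name].p == pytest.approx(p_ref, rel=1e-8)


def test_partition_flags_only_injected_component():
    flagged_only_idd = 0
    seeds = range(30)
    for seed in seeds:
        spec = sd.CohortSpec(
            n=10_000, effects=sd.EffectSpec(i_dd=5.0, sigma_e=10.0), seed=seed
        )
        gm = sd.sim_genotypes(spec)
        y, _ = sd.sim_phenotype(gm, spec.effects, seed=seed + 1000)
        fit = fit_pair(y, None, gm.column("tag1"), gm.column("tag2"))
        comp = partition_components(fit, alpha=0.01)
        if comp["i_dd"].significant and not any(
            comp[c].significant for c in ("i_aa", "i_ad", "i_da")
        ):
            flagged_only_idd += 1
    assert flagged_only_idd >= len(list(seeds)) * 0.8


# ---------------------------------------------------------------------------
# bonferroni
# ---------------------------------------------------------------------------


def test_bonferroni_cap_and_identity():
    assert bonferroni(0.001, 7750) == 1.0
    assert bonferroni(0.5, 1) == 0.5


def test_bonferroni_discovery_scale():
    assert bonferroni(1.032e-6, 7750) == pytest.approx(0.008, abs=5e-4)


def test_bonferroni_rejects_bad_input():
    with pytest.raises(ValueError):
        bonferroni(1.5, 10)
    with pytest.raises(ValueError):
        bonferroni(0.5, 0)
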