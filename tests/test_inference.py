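"""Crossover ANOVA, Tukey contrasts, Friedman, Pearson, mixed regression."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, special
from scipy.stats import studentized_range

from rumenkin import (cow_adjusted_regression, crossover_anova,
                      friedman_test, pearson, tukey_contrasts)

DIETS = ["A", "B", "C"]


def _crossover_table(y_fn, n_cows=6, rng=None):
    rows = []
    for i in range(n_cows):
        for p in range(3):
            d = DIETS[(i + p) % 3]
            rows.append(dict(cow_id=f"cow{i}", period=p + 1, diet=d,
                             y=y_fn(i, p, d)))
    return pd.DataFrame(rows)


def test_noiseless_additive_effects_recovered_exactly():
    """Diet effects (0, +2, +5) reappear as lsmean differences (2, 5, 3)."""
    eff = {"A": 0.0, "B": 2.0, "C": 5.0}
    tab = _crossover_table(lambda i, p, d: 10.0 + eff[d] + 0.5 * p + 0.3 * i)
    a = crossover_anova(tab, "y")
    np.testing.assert_allclose(a.lsmeans["B"] - a.lsmeans["A"], 2.0,
                               atol=1e-10)
    np.testing.assert_allclose(a.lsmeans["C"] - a.lsmeans["A"], 5.0,
                               atol=1e-10)
    np.testing.assert_allclose(a.lsmeans["C"] - a.lsmeans["B"], 3.0,
                               atol=1e-10)


def _projection_anova_oracle(tab):
    """Independent Type III oracle via explicit projection matrices."""
    from scipy.stats import f as f_dist

    def dummies(v):
        levels = sorted(set(v))
        return np.column_stack([(np.asarray(v) == lv).astype(float)
                                for lv in levels[1:]])

    y = tab["y"].to_numpy(float)
    ones = np.ones((len(tab), 1))
    Xd = dummies(tab["diet"])
    Xp = dummies(tab["period"])
    Xc = dummies(tab["cow_id"])

    def proj(X):
        Q, _ = np.linalg.qr(X)
        return Q @ Q.T

    P_full = proj(np.hstack([ones, Xd, Xp, Xc]))
    n = len(y)
    rank_full = int(round(np.trace(P_full)))
    rss_full = float(y @ (np.eye(n) - P_full) @ y)
    df_res = n - rank_full
    out = {}
    for name, drop, q in (("Diet", Xd, Xd.shape[1]),
                          ("Period", Xp, Xp.shape[1])):
        keep = [m for m in (ones, Xd, Xp, Xc) if m is not drop]
        P_red = proj(np.hstack(keep))
        ss = float(y @ (P_full - P_red) @ y)
        F = (ss / q) / (rss_full / df_res)
        out[name] = (F, float(f_dist.sf(F, q, df_res)))
    return out


def test_anova_matches_projection_oracle(rng):
    tab = _crossover_table(lambda i, p, d: rng.normal())
    a = crossover_anova(tab, "y")
    oracle = _projection_anova_oracle(tab)
    for effect in ("Diet", "Period"):
        row = a.table[a.table.effect == effect].iloc[0]
        F_o, p_o = oracle[effect]
        np.testing.assert_allclose(row["F"], F_o, rtol=1e-8)
        np.testing.assert_allclose(row["p"], p_o, rtol=1e-8)


def test_fixed_and_random_animal_give_same_f(rng):
    tab = _crossover_table(lambda i, p, d: rng.normal() + 0.8 * i)
    fr = crossover_anova(tab, "y", animal="random").table
    fx = crossover_anova(tab, "y", animal="fixed").table
    np.testing.assert_allclose(fr["F"], fx["F"], rtol=1e-10)


def test_duplicated_cow_period_rejected(rng):
    tab = _crossover_table(lambda i, p, d: rng.normal())
    dup = pd.concat([tab, tab.iloc[[0]]], ignore_index=True)
    with pytest.raises(ValueError, match="duplicated"):
        crossover_anova(dup, "y")


def test_tukey_null_contrast_and_monotonicity(rng):
    eff = {"A": 0.0, "B": 0.0, "C": 4.0}
    tab = _crossover_table(
        lambda i, p, d: eff[d] + rng.normal(scale=1.0) + 0.5 * i)
    cs = tukey_contrasts(crossover_anova(tab, "y")).table
    # adjusted never below raw
    assert (cs["p_adj"] >= cs["p_raw"] - 1e-12).all()
    null_row = cs[cs.contrast == "A - B"].iloc[0]
    assert null_row["p_adj"] > 0.4


def _studentized_range_sf_quadrature(q, k, df):
    """Numerical-integration oracle for the studentized range tail."""
    from scipy.stats import norm

    def inner(s):
        def f(z):
            return norm.pdf(z) * (norm.cdf(z) - norm.cdf(z - q * s)) ** (k - 1)
        val, _ = integrate.quad(f, -8, 8, limit=200)
        return k * val

    # density of S = sqrt(chi2_df / df)
    def s_density(s):
        return (2 * (df / 2.0) ** (df / 2.0) / special.gamma(df / 2.0)
                * s ** (df - 1) * np.exp(-df * s * s / 2.0))

    cdf, _ = integrate.quad(lambda s: s_density(s) * inner(s), 1e-8, 8,
                            limit=200)
    return 1.0 - cdf


def test_tukey_adjusted_p_matches_quadrature_oracle():
    for q, k, df in ((3.5, 3, 8), (2.0, 3, 8), (4.2, 3, 12)):
        ref = _studentized_range_sf_quadrature(q, k, df)
        np.testing.assert_allclose(studentized_range.sf(q, k, df), ref,
                                   atol=5e-6)


def test_friedman_degenerate_and_maximal_cases():
    # identical treatments in every block: no discrimination
    chi2, df, p = friedman_test(np.ones((4, 3)), exact=False)
    assert chi2 == 0.0 and df == 2 and p == 1.0
    # identical ordering in all 4 blocks: chi2 = 8 (closed form)
    M = np.tile([1.0, 2.0, 3.0], (4, 1))
    chi2, _, _ = friedman_test(M, exact=False)
    np.testing.assert_allclose(chi2, 8.0)


def test_friedman_asymptotic_consistent_with_full_enumeration(rng):
    """n=4, k=3: the chi-square approximation sits within the coarse
    exact permutation distribution's neighbouring atoms (all 1296
    within-block arrangements)."""
    M = rng.normal(size=(4, 3))
    chi2_a, _, p_asy = friedman_test(M, exact=False)
    chi2_e, _, p_exact = friedman_test(M, exact=True)
    assert chi2_a == chi2_e
    assert 0.0 <= p_exact <= 1.0
    # exact distribution atoms bracketing the observed statistic
    perms = list(itertools.permutations(range(3)))
    stats = []
    for combo in itertools.product(perms, repeat=4):
        R = np.array([[list(c).index(j) + 1.0 for j in range(3)]
                      for c in combo])
        stats.append(12.0 / 48.0 * float(R.sum(0) @ R.sum(0)) - 48.0)
    stats = np.asarray(stats)
    p_hi = float(np.mean(stats >= chi2_a - 1e-9))
    p_lo = float(np.mean(stats > chi2_a + 1e-9))
    assert p_exact == pytest.approx(p_hi)
    assert p_lo - 0.06 <= p_asy <= p_hi + 0.06


def test_friedman_exact_p_is_enumeration_fraction():
    M = np.array([[1., 2., 3.], [1., 2., 3.], [3., 2., 1.], [2., 1., 3.]])
    chi2, _, p = friedman_test(M, exact=True)
    # independent re-enumeration
    perms = list(itertools.permutations([1.0, 2.0, 3.0]))
    count = total = 0
    for combo in itertools.product(perms, repeat=4):
        R = np.array(combo)
        s = 12.0 / (4 * 3 * 4) * float(R.sum(0) @ R.sum(0)) - 3 * 4 * 4
        total += 1
        count += s >= chi2 - 1e-12
    np.testing.assert_allclose(p, count / total)


def test_friedman_rejects_missing_cells():
    M = np.array([[1.0, 2.0, np.nan], [1.0, 2.0, 3.0]])
    with pytest.raises(ValueError, match="missing"):
        friedman_test(M)


@settings(deadline=None, derandomize=True, max_examples=30)
@given(st.lists(st.lists(st.integers(0, 5), min_size=3, max_size=3),
                min_size=3, max_size=6))
def test_friedman_bound_and_monotone_invariance(rows):
    M = np.asarray(rows, dtype=float)
    chi2, _, _ = friedman_test(M, exact=False)
    n = M.shape[0]
    assert 0.0 <= chi2 <= 2.0 * n + 1e-12       # k = 3 bound
    # strictly increasing transform preserves ranks, hence the statistic
    chi2_t, _, _ = friedman_test(np.exp(M / 2.0), exact=False)
    np.testing.assert_allclose(chi2, chi2_t, atol=1e-9)


def test_pearson_perfect_line_and_df():
    x = np.arange(12, dtype=float)
    res = pearson(x, 2 * x + 1)
    np.testing.assert_allclose(res.r, 1.0)
    assert res.df == 10 and res.p == 0.0


@settings(deadline=None, derandomize=True, max_examples=25)
@given(st.integers(0, 10_000), st.floats(0.1, 5.0), st.floats(-3.0, 3.0))
def test_pearson_affine_invariance(seed, a, b):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=10)
    y = rng.normal(size=10)
    r0 = pearson(x, y).r
    r1 = pearson(a * x + b, y).r
    np.testing.assert_allclose(r0, r1, atol=1e-9)
    r2 = pearson(-a * x + b, y).r
    np.testing.assert_allclose(r0, -r2, atol=1e-9)


def test_pearson_p_matches_t_quadrature(rng):
    x = rng.normal(size=10)
    y = 0.5 * x + rng.normal(size=10)
    res = pearson(x, y)
    df = res.df
    tval = abs(res.r) * np.sqrt(df / (1 - res.r ** 2))

    def t_pdf(u):
        c = special.gamma((df + 1) / 2) / (np.sqrt(df * np.pi)
                                           * special.gamma(df / 2))
        return c * (1 + u * u / df) ** (-(df + 1) / 2)

    tail, _ = integrate.quad(t_pdf, tval, np.inf)
    np.testing.assert_allclose(res.p, 2 * tail, rtol=1e-6)


def test_pearson_degenerate_x_is_missing():
    with pytest.warns(UserWarning, match="zero variance"):
        res = pearson(np.ones(5), np.arange(5.0))
    assert np.isnan(res.r)


def _collapse_data(eps_scale=0.01):
    """Four cows, identical x grids, residuals summing to zero per cow:
    zero between-cow variance by construction."""
    x_one = np.array([-1.0, 0.0, 1.0])
    eps_one = eps_scale * np.array([1.0, -2.0, 1.0])
    x = np.tile(x_one, 4)
    cows = np.repeat([f"cow{i}" for i in range(4)], 3)
    y = 1.0 + 2.0 * x + np.tile(eps_one, 4)
    return x, y, cows


def test_regression_collapses_to_ols_without_cow_variance():
    x, y, cows = _collapse_data()
    res = cow_adjusted_regression(x, y, cows)
    X = np.column_stack([np.ones_like(x), x])
    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    np.testing.assert_allclose(res.slope, beta[1], atol=1e-8)
    assert res.sigma2_animal == 0.0


def test_marginal_r2_decomposition_and_ols_limit():
    x, y, cows = _collapse_data(eps_scale=1e-3)
    res = cow_adjusted_regression(x, y, cows)
    rebuilt = res.sigma2_fixed / (res.sigma2_fixed + res.sigma2_animal
                                  + res.sigma2_resid)
    np.testing.assert_allclose(res.r2_marginal, rebuilt, rtol=1e-12)
    X = np.column_stack([np.ones_like(x), x])
    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    rss = float(((y - X @ beta) ** 2).sum())
    tss = float(((y - y.mean()) ** 2).sum())
    # REML vs ML residual scaling differs by (n-2)/n, negligible here
    np.testing.assert_allclose(res.r2_marginal, 1 - rss / tss, atol=1e-4)
    assert 0.0 <= res.r2_marginal <= 1.0


def test_regression_slope_recovery_with_cow_effects(rng):
    u = rng.normal(0, 3.0, 5)
    cows = np.repeat(np.arange(5), 4)
    x = rng.normal(size=20)
    y = u[cows] + 1.7 * x + rng.normal(0, 0.3, 20)
    res = cow_adjusted_regression(x, y, cows)
    assert abs(res.slope - 1.7) < 3 * res.se
    assert res.sigma2_animal > 0.5


def test_regression_rejects_degenerate_input():
    with pytest.raises(ValueError, match="constant"):
        cow_adjusted_regression(np.ones(6), np.arange(6.0),
                                np.repeat([0, 1], 3))
    with pytest.raises(ValueError, match=">= 2 cows"):
        cow_adjusted_regression(np.arange(4.0), np.arange(4.0),
                                np.zeros(4))
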