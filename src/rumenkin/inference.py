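"""Statistical layer for the crossover trial.

Implements the trial's inference toolkit: the crossover ANOVA
``Y = mu + Diet + Period + Animal + error`` with Tukey-adjusted pairwise
contrasts, the Friedman rank test on complete animal-blocked matrices,
Pearson correlations reported with their df, and cow-adjusted mixed
regressions with Nakagawa-Schielzeth marginal R^2.

For the balanced crossover the mixed-model Wald F for Diet and Period
reduces exactly to the blocked least-squares F, so the F statistics are
computed by residual-sum-of-squares projection (exactly reproducible);
the REML fit supplies the animal variance component and the
least-squares-mean standard errors.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import (chi2 as chi2_dist, f as f_dist, rankdata,
                         studentized_range, t as t_dist)

from .lmm import fit_random_intercept

TREND_P, SIGNIF_P = 0.10, 0.05


@dataclass
class AnovaResult:
    """Crossover ANOVA for one response."""

    response: str
    lsmeans: dict                # diet -> least-squares mean
    se_lsmeans: dict             # diet -> SE of the lsmean
    table: pd.DataFrame          # effect, F, df1, df2, p
    sigma2_resid: float
    sigma2_animal: float
    mse: float                   # residual mean square of the blocked fit
    df_resid: int
    n_per_diet: int
    animal: str                  # "random" or "fixed"


@dataclass
class ContrastSet:
    table: pd.DataFrame          # contrast, estimate, se, p_raw, p_adj


@dataclass
class CorrelationResult:
    r: float
    df: int
    p: float
    n: int


@dataclass
class MixedRegressionResult:
    slope: float
    se: float
    intercept: float
    r2_marginal: float
    p: float
    n: int
    sigma2_fixed: float
    sigma2_animal: float
    sigma2_resid: float
    ranef: dict = field(default_factory=dict)


def _dummies(values, levels) -> np.ndarray:
    """Treatment-coded dummies (first level as reference)."""
    return np.column_stack([(values == lv).astype(float)
                            for lv in levels[1:]])


def _rss(X, y):
    beta, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    return float(((y - fitted) ** 2).sum()), rank


def crossover_anova(table: pd.DataFrame, response: str,
                    animal: str = "random") -> AnovaResult:
    """ANOVA ``response = mu + Diet + Period + Animal + error``.

    Fixed Diet and Period; Animal as a random intercept (default) or as
    a fixed block (``animal="fixed"``) — for the balanced design the F
    statistics coincide; only the reported variance components and
    lsmean SEs differ.
    """
    req = {"cow_id", "period", "diet", response}
    missing = req - set(table.columns)
    if missing:
        raise ValueError(f"table lacks columns {sorted(missing)}")
    if animal not in ("random", "fixed"):
        raise ValueError(f"unknown animal treatment {animal!r}")
    df = table[["cow_id", "period", "diet", response]].copy()
    if df.duplicated(["cow_id", "period"]).any():
        dup = df[df.duplicated(["cow_id", "period"])].iloc[0]
        raise ValueError(
            f"duplicated cow x period row: ({dup['cow_id']}, "
            f"{dup['period']})")
    df = df.sort_values(["cow_id", "period"], ignore_index=True)
    y = df[response].to_numpy(float)
    if not np.all(np.isfinite(y)):
        raise ValueError(f"non-finite values in response {response!r}")
    diets = sorted(df["diet"].unique())
    periods = sorted(df["period"].unique())
    cows = sorted(df["cow_id"].unique())
    if len(diets) < 2:
        raise ValueError("need >= 2 diets")

    n = len(df)
    ones = np.ones((n, 1))
    Xd = _dummies(df["diet"].to_numpy(), diets)
    Xp = _dummies(df["period"].to_numpy(), periods)
    Xc = _dummies(df["cow_id"].to_numpy(), cows)

    X_full = np.hstack([ones, Xd, Xp, Xc])
    rss_full, rank_full = _rss(X_full, y)
    df_resid = n - rank_full
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom")
    mse = rss_full / df_resid

    rows = []
    for name, drop, q in (("Diet", Xd, len(diets) - 1),
                          ("Period", Xp, len(periods) - 1)):
        keep = [m for m in (ones, Xd, Xp, Xc) if m is not drop]
        rss_red, _ = _rss(np.hstack(keep), y)
        F = ((rss_red - rss_full) / q) / mse
        rows.append(dict(effect=name, F=F, df1=q, df2=df_resid,
                         p=float(f_dist.sf(F, q, df_resid))))
    tab = pd.DataFrame(rows)

    # variance components and lsmean SEs from the REML random-intercept fit
    X_mixed = np.hstack([ones, Xd, Xp])
    names = (["mu"] + [("diet", d) for d in diets[1:]]
             + [("period", p) for p in periods[1:]])
    lmm = fit_random_intercept(X_mixed, y, df["cow_id"].to_numpy(),
                               names=names,
                               lam=None if animal == "random" else 0.0)
    lsmeans, se_lsmeans = {}, {}
    for d in diets:
        l = np.zeros(X_mixed.shape[1])
        l[0] = 1.0
        if d != diets[0]:
            l[1 + diets.index(d) - 1] = 1.0
        # average over periods
        for j in range(len(periods) - 1):
            l[len(diets) + j] = 1.0 / len(periods)
        lsmeans[d] = float(l @ lmm.beta)
        se_lsmeans[d] = float(np.sqrt(l @ lmm.cov_beta @ l))

    sigma2_animal = lmm.sigma2_u if animal == "random" else np.nan
    return AnovaResult(response, lsmeans, se_lsmeans, tab,
                       lmm.sigma2_e, sigma2_animal, mse, df_resid,
                       n // len(diets), animal)


def tukey_contrasts(anova: AnovaResult) -> ContrastSet:
    """All pairwise diet differences, Tukey-Kramer adjusted.

    Diet contrasts are within-animal in the crossover, so their SE uses
    the blocked residual mean square; family-wise adjustment via the
    studentized-range distribution.
    """
    diets = sorted(anova.lsmeans)
    k = len(diets)
    if k < 2:
        raise ValueError("need >= 2 lsmeans")
    rows = []
    for d1, d2 in itertools.combinations(diets, 2):
        diff = anova.lsmeans[d1] - anova.lsmeans[d2]
        se = float(np.sqrt(2.0 * anova.mse / anova.n_per_diet))
        if se == 0:
            p_raw = p_adj = (1.0 if diff == 0 else 0.0)
        else:
            tval = diff / se
            p_raw = 2.0 * float(t_dist.sf(abs(tval), anova.df_resid))
            p_adj = float(studentized_range.sf(
                abs(tval) * np.sqrt(2.0), k, anova.df_resid))
        rows.append(dict(contrast=f"{d1} - {d2}", estimate=diff, se=se,
                         p_raw=p_raw, p_adj=min(max(p_adj, p_raw), 1.0)))
    return ContrastSet(pd.DataFrame(rows))


def friedman_test(block_matrix, exact: bool | None = None
                  ) -> tuple[float, int, float]:
    """Friedman chi-square on a complete blocks x treatments matrix.

    Rows are blocks (animals), columns treatments (diets); ties receive
    midranks.  ``chi2 = 12/(n k (k+1)) sum R_j^2 - 3 n (k+1)`` with
    ``df = k - 1``.  With ``exact=True`` (default when ``n*k <= 20``)
    the p-value comes from full enumeration of all within-block rank
    permutations instead of the chi-square approximation.
    """
    M = np.asarray(block_matrix, dtype=float)
    if M.ndim != 2 or M.shape[0] < 2 or M.shape[1] < 2:
        raise ValueError("need a 2-D matrix with >= 2 blocks and >= 2 "
                         "treatments")
    if not np.all(np.isfinite(M)):
        raise ValueError("block matrix has missing cells; the Friedman "
                         "test needs complete blocks")
    n, k = M.shape
    ranks = np.vstack([rankdata(row) for row in M])

    def stat(R):
        col_sums = R.sum(axis=0)
        return (12.0 / (n * k * (k + 1))) * float(col_sums @ col_sums) \
            - 3.0 * n * (k + 1)

    chi2 = stat(ranks)
    dfree = k - 1
    if exact is None:
        exact = n * k <= 20
    if exact:
        perms = list(itertools.permutations(range(k)))
        if len(perms) ** n > 200_000:
            raise ValueError("exact enumeration too large; pass exact=False")
        count = total = 0
        for combo in itertools.product(perms, repeat=n):
            R = np.vstack([ranks[i, list(pi)] for i, pi in enumerate(combo)])
            total += 1
            if stat(R) >= chi2 - 1e-12:
                count += 1
        p = count / total
    else:
        p = float(chi2_dist.sf(chi2, dfree))
    return float(chi2), dfree, p


def pearson(x, y) -> CorrelationResult:
    """Product-moment correlation with ``df = n - 2`` and two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and the same length")
    n = len(x)
    if n < 3:
        raise ValueError("need n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("zero variance; correlation undefined")
        return CorrelationResult(np.nan, n - 2, np.nan, n)
    xc, yc = x - x.mean(), y - y.mean()
    r = float(xc @ yc / np.sqrt((xc @ xc) * (yc @ yc)))
    r = min(1.0, max(-1.0, r))
    dfree = n - 2
    if abs(r) == 1.0:
        p = 0.0
    else:
        tval = r * np.sqrt(dfree / (1.0 - r * r))
        p = 2.0 * float(t_dist.sf(abs(tval), dfree))
    return CorrelationResult(r, dfree, p, n)


def cow_adjusted_regression(x, y, cow_id) -> MixedRegressionResult:
    """``y ~ x`` with a random intercept per cow, by REML.

    Marginal R^2 is the fixed-effect share of the total variance,
    ``var(X beta) / (var(X beta) + sigma_u^2 + sigma_e^2)``
    (Nakagawa-Schielzeth), with the fixed-effect variance taken as the
    population variance of the fixed-part fitted values.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    cow_id = np.asarray(cow_id)
    if not (len(x) == len(y) == len(cow_id)):
        raise ValueError("x, y and cow_id must have equal length")
    uniq, counts = np.unique(cow_id, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need >= 2 cows")
    if counts.min() < 2:
        raise ValueError("need >= 2 observations per cow")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; slope is not identifiable")

    X = np.column_stack([np.ones_like(x), x])
    fit = fit_random_intercept(X, y, cow_id, names=["intercept", "slope"])
    slope = fit.coef("slope")
    se = fit.se("slope")
    fitted_fixed = X @ fit.beta
    var_f = float(np.var(fitted_fixed))          # ddof=0, population variance
    denom = var_f + fit.sigma2_u + fit.sigma2_e
    r2m = var_f / denom if denom > 0 else 1.0
    if se == 0:
        p = 0.0 if slope != 0 else 1.0
    else:
        tval = slope / se
        p = 2.0 * float(t_dist.sf(abs(tval), fit.df_resid))
    return MixedRegressionResult(
        slope=slope, se=se, intercept=fit.coef("intercept"),
        r2_marginal=min(1.0, max(0.0, r2m)), p=p, n=len(x),
        sigma2_fixed=var_f, sigma2_animal=fit.sigma2_u,
        sigma2_resid=fit.sigma2_e, ranef=dict(fit.ranef))
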