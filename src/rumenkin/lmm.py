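"""Linear mixed model with a single random intercept, by profiled REML.

The model is ``y = X beta + Z u + e`` with one grouping factor (the
animal), ``u ~ N(0, sigma_u^2 I)`` and ``e ~ N(0, sigma_e^2 I)``.  For
this structure the covariance is ``V = sigma_e^2 (I + lambda Z Z')`` with
``lambda = sigma_u^2 / sigma_e^2``, and everything — GLS coefficients,
REML criterion, BLUPs — has a closed form per group via the Woodbury
identity.  The only numerical step is a one-dimensional search over
``log lambda``, which keeps the fit deterministic and exact at the
boundaries that matter for noiseless synthetic data:

* perfect fit (all variances zero) short-circuits to exact OLS;
* ``lambda`` fixed at 0 reproduces pooled OLS to machine precision;
* ``lambda`` at its upper bound recovers the within-group (fixed-block)
  estimator, so zero-residual data with true group effects are fitted
  essentially exactly (shrinkage error ~1/(lambda n)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

_LOG_LAM_LO, _LOG_LAM_HI = np.log(1e-10), np.log(1e8)


@dataclass
class LMMFit:
    """Fitted random-intercept model."""

    beta: np.ndarray
    cov_beta: np.ndarray
    names: list
    sigma2_e: float
    sigma2_u: float
    ranef: dict                 # group label -> BLUP of the random intercept
    n_obs: int
    df_resid: int               # n_obs - n_fixed (residual approximation)
    lam: float
    reml_criterion: float

    def coef(self, name) -> float:
        return float(self.beta[self.names.index(name)])

    def se(self, name) -> float:
        i = self.names.index(name)
        return float(np.sqrt(self.cov_beta[i, i]))


def _group_indices(groups) -> dict:
    groups = np.asarray(groups)
    return {g: np.flatnonzero(groups == g) for g in np.unique(groups)}


def _profiled_quantities(lam, X, y, gidx):
    """GLS quantities at variance ratio ``lam`` (Woodbury per group).

    The generalized RSS is accumulated from residuals group by group,
    not as ``y'V^-1 y - beta'X'V^-1 y``, whose cancellation error of
    order ``eps * y'y`` would swamp near-perfect fits.
    """
    XtX = X.T @ X
    Xty = X.T @ y
    for idx in gidx.values():
        c = lam / (1.0 + lam * len(idx))
        sx = X[idx].sum(axis=0)
        sy = float(y[idx].sum())
        XtX = XtX - c * np.outer(sx, sx)
        Xty = Xty - c * sx * sy
    beta = np.linalg.solve(XtX, Xty)
    resid = y - X @ beta
    rss = 0.0
    for idx in gidx.values():
        c = lam / (1.0 + lam * len(idx))
        r = resid[idx]
        rss += float(r @ r) - c * float(r.sum()) ** 2
    return beta, XtX, max(rss, 0.0)


def _reml_criterion(lam, X, y, gidx, n, p):
    beta, XtViX, rss = _profiled_quantities(lam, X, y, gidx)
    sign, logdet = np.linalg.slogdet(XtViX)
    if sign <= 0:
        return np.inf
    log_v = sum(np.log1p(lam * len(idx)) for idx in gidx.values())
    return (n - p) * np.log(max(rss, 1e-300)) + log_v + logdet


def fit_random_intercept(X, y, groups, names=None, lam=None) -> LMMFit:
    """Fit ``y ~ X`` with a random intercept per level of ``groups``.

    Parameters
    ----------
    lam
        If given, the variance ratio sigma_u^2/sigma_e^2 is fixed at this
        value instead of being estimated (``lam=0`` gives pooled OLS).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or len(y) != X.shape[0]:
        raise ValueError("X must be 2-D with one row per element of y")
    n, p = X.shape
    if n <= p:
        raise ValueError(f"{n} observations cannot identify {p} fixed effects")
    if names is None:
        names = [f"x{j}" for j in range(p)]
    gidx = _group_indices(groups)

    # Perfect-fit guard: zero-residual data (all noise SDs zero in the
    # generator, leaving only float rounding) bypasses the search.  The
    # threshold is absolute — residual variance below 1e-28 — so that
    # genuinely tiny but real noise is still fitted, not short-circuited.
    beta0, XtX0, rss0 = _profiled_quantities(0.0, X, y, gidx)
    if lam is None and rss0 <= (n - p) * 1e-28:
        cov = np.zeros((p, p))
        return LMMFit(beta0, cov, list(names), 0.0, 0.0,
                      {g: 0.0 for g in gidx}, n, n - p, 0.0, -np.inf)

    if lam is None:
        # coarse deterministic grid, then a bounded local refinement
        grid = np.concatenate(([_LOG_LAM_LO],
                               np.linspace(np.log(1e-6), _LOG_LAM_HI, 57)))
        crits = [_reml_criterion(np.exp(ll), X, y, gidx, n, p) for ll in grid]
        k = int(np.argmin(crits))
        lo = grid[max(k - 1, 0)]
        hi = grid[min(k + 1, len(grid) - 1)]
        res = minimize_scalar(
            lambda ll: _reml_criterion(np.exp(ll), X, y, gidx, n, p),
            bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-10})
        lam_hat = float(np.exp(res.x))
        # compare against the lambda = 0 boundary (no animal variance)
        if _reml_criterion(0.0, X, y, gidx, n, p) <= res.fun:
            lam_hat = 0.0
    else:
        lam_hat = float(lam)

    beta, XtViX, rss = _profiled_quantities(lam_hat, X, y, gidx)
    sigma2_e = rss / (n - p)
    sigma2_u = lam_hat * sigma2_e
    cov_beta = sigma2_e * np.linalg.inv(XtViX)

    resid = y - X @ beta
    ranef = {}
    for g, idx in gidx.items():
        c = lam_hat / (1.0 + lam_hat * len(idx))
        ranef[g] = float(c * resid[idx].sum())

    crit = _reml_criterion(lam_hat, X, y, gidx, n, p)
    return LMMFit(beta, cov_beta, list(names), sigma2_e, sigma2_u,
                  ranef, n, n - p, lam_hat, crit)


def wald_f(fit: LMMFit, L: np.ndarray) -> tuple[float, int, int, float]:
    """Type III Wald F test of ``L beta = 0``.

    Returns ``(F, df_num, df_den, p)`` with denominator df by the
    residual approximation ``n_obs - n_fixed``.
    """
    from scipy.stats import f as f_dist

    L = np.atleast_2d(np.asarray(L, dtype=float))
    q = L.shape[0]
    Lb = L @ fit.beta
    M = L @ fit.cov_beta @ L.T
    if not np.any(M):
        # degenerate (zero-residual) fit: no contrast uncertainty at all
        F = np.inf if np.any(Lb) else 0.0
    else:
        F = float(Lb @ np.linalg.solve(M, Lb)) / q
    p = float(f_dist.sf(F, q, fit.df_resid))
    return F, q, fit.df_resid, p
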