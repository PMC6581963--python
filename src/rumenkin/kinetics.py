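"""Rumen pool volumes and passage rates from marker washout curves.

Single-pool marker dilution: a pulse dose D of an indigestible marker
mixes into a pool of volume V and washes out, so the concentration
follows ``C(t) = (D/V) exp(-k t)`` (liquid, Co-EDTA) or a log-quadratic
decay (solid, Yb-NDF, which mixes and clears more slowly).  Fitting
``log C`` against time with per-diet fixed curves and a random intercept
per animal gives

* pool volume  V = D / C0, with C0 the model's extrapolated zero-time
  concentration including the animal's random intercept,
* fractional passage rate Kp = the (maximal) descending slope (/h),
* absolute passage rate = V x Kp (l/h or kg DM/h).

Pre-dose (t = 0) samples are excluded from all fits; the first usable
point is 1 h.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import studentized_range, t as t_dist

from .lmm import LMMFit, fit_random_intercept, wald_f
from .inference import friedman_test
from .simulate import MarkerProfile

#: observation window (h) over which the quadratic slope is evaluated
DEFAULT_WINDOW = (1.0, 23.0)

PHASE_UNITS = {"liquid": ("l", "l/h"), "solid": ("kg DM", "kg DM/h")}


@dataclass
class DecayFit:
    """Mixed log-linear / log-quadratic washout fit for one phase."""

    phase: str
    model: str                   # "linear" or "quadratic"
    diets: list
    lmm: LMMFit
    n_obs: int

    def intercept(self, diet: str) -> float:
        return self.lmm.coef(("intercept", diet))

    def slope(self, diet: str) -> float:
        return self.lmm.coef(("time", diet))

    def quad(self, diet: str) -> float:
        if self.model != "quadratic":
            raise ValueError("no quadratic coefficient in a linear fit")
        return self.lmm.coef(("time2", diet))

    def cow_intercept(self, diet: str, cow_id: str) -> float:
        """Extrapolated zero-time log concentration for one animal."""
        return self.intercept(diet) + self.lmm.ranef.get(cow_id, 0.0)

    @property
    def sigma2_resid(self) -> float:
        return self.lmm.sigma2_e

    @property
    def sigma2_animal(self) -> float:
        return self.lmm.sigma2_u


@dataclass
class KineticsEstimate:
    """Per cow x diet pool size and passage rate for one digesta phase."""

    cow_id: str
    diet_label: str
    phase: str
    volume: float                # l (liquid) or kg DM (solid)
    frac_kp: float               # fraction/h
    abs_kp: float                # l/h or kg DM/h
    volume_units: str
    abs_kp_units: str
    c0: float                    # extrapolated zero-time concentration
    dose_g: float


def _profiles_long(profiles: list[MarkerProfile], phase: str) -> pd.DataFrame:
    rows = []
    for p in profiles:
        if p.phase != phase:
            raise ValueError(
                f"profile ({p.cow_id}, {p.diet_label}) has phase "
                f"{p.phase!r}; fit requested for {phase!r} — phases must "
                "not be mixed")
        p.validate()
        for i, (t, c) in enumerate(zip(p.times, p.concentrations)):
            if t <= 0:
                continue          # pre-dose background sample, never fitted
            if c <= 0:
                raise ValueError(
                    f"non-positive concentration at row {i} of profile "
                    f"({p.cow_id}, period {p.period}, {p.diet_label})")
            rows.append(dict(cow_id=p.cow_id, period=p.period,
                             diet=p.diet_label, time_h=t, log_conc=np.log(c)))
    df = pd.DataFrame(rows)
    # order-independence: fits see a canonical row ordering
    return df.sort_values(["cow_id", "period", "time_h"],
                          ignore_index=True)


def fit_decay(profiles: list[MarkerProfile], phase: str,
              model: str = "linear", lam: float | None = None) -> DecayFit:
    """REML fit of ``log C ~ diet + diet:time (+ diet:time^2) + (1|cow)``.

    Parameters
    ----------
    model
        "linear" for the liquid phase, "quadratic" for the solid phase
        (adds per-diet ``time^2`` terms).
    lam
        Optional fixed variance ratio passed to the mixed fitter
        (``lam=0`` collapses the fit to pooled OLS).
    """
    if model not in ("linear", "quadratic"):
        raise ValueError(f"unknown model {model!r}")
    df = _profiles_long(profiles, phase)
    if df.empty:
        raise ValueError(f"no usable {phase} observations")
    diets = sorted(df["diet"].unique())
    counts = df.groupby("diet")["time_h"].nunique()
    for d in diets:
        if counts.get(d, 0) < (3 if model == "quadratic" else 2):
            raise ValueError(
                f"diet {d!r} has too few distinct time points to fit")

    cols, names = [], []
    for d in diets:
        ind = (df["diet"] == d).to_numpy(float)
        cols.append(ind)
        names.append(("intercept", d))
    for d in diets:
        ind = (df["diet"] == d).to_numpy(float)
        cols.append(ind * df["time_h"].to_numpy())
        names.append(("time", d))
    if model == "quadratic":
        for d in diets:
            ind = (df["diet"] == d).to_numpy(float)
            cols.append(ind * df["time_h"].to_numpy() ** 2)
            names.append(("time2", d))
    X = np.column_stack(cols)
    y = df["log_conc"].to_numpy()
    lmm = fit_random_intercept(X, y, df["cow_id"].to_numpy(),
                               names=names, lam=lam)
    return DecayFit(phase, model, diets, lmm, len(df))


def fractional_kp(fit: DecayFit, diet: str,
                  window: tuple[float, float] = DEFAULT_WINDOW,
                  convention: str = "steepest") -> float:
    """Fractional passage rate (/h) for one diet.

    Linear model: ``-b``.  Quadratic model: the magnitude of the
    steepest descending tangent ``-(b + 2 c t)`` over the observation
    window (attained at the window end for ``c < 0``); with
    ``convention="initial"`` the tangent at the window start is used
    instead.
    """
    b = fit.slope(diet)
    if fit.model == "linear":
        kp = -b
    else:
        c = fit.quad(diet)
        lo, hi = window
        if not lo < hi:
            raise ValueError("window must be (lo, hi) with lo < hi")
        if convention == "steepest":
            kp = max(-(b + 2.0 * c * lo), -(b + 2.0 * c * hi))
        elif convention == "initial":
            kp = -(b + 2.0 * c * lo)
        else:
            raise ValueError(f"unknown convention {convention!r}")
    if kp <= 0:
        raise ValueError(
            f"fitted {fit.phase} curve for diet {diet!r} is not descending "
            "anywhere in the window — marker is not clearing")
    return float(kp)


def pool_volume(fit: DecayFit, diet: str, cow_id: str, dose_g: float,
                level: str = "cow") -> float:
    """Pool size as dose over extrapolated zero-time concentration.

    ``level="cow"`` (default) includes the animal's random intercept in
    C0; ``level="diet"`` uses the diet-level fixed intercept only.
    """
    if dose_g <= 0:
        raise ValueError("dose_g must be > 0")
    if level == "cow":
        a = fit.cow_intercept(diet, cow_id)
    elif level == "diet":
        a = fit.intercept(diet)
    else:
        raise ValueError(f"unknown level {level!r}")
    return float(dose_g / np.exp(a))


def summarize_kinetics(fit: DecayFit, profiles: list[MarkerProfile],
                       window: tuple[float, float] = DEFAULT_WINDOW,
                       level: str = "cow") -> list[KineticsEstimate]:
    """One estimate per cow x diet; ``abs_kp = volume * frac_kp`` exactly."""
    vol_units, abs_units = PHASE_UNITS[fit.phase]
    estimates = []
    for p in sorted(profiles, key=lambda p: (p.cow_id, p.period)):
        if p.phase != fit.phase:
            raise ValueError(
                f"profile phase {p.phase!r} does not match fit phase "
                f"{fit.phase!r}")
        vol = pool_volume(fit, p.diet_label, p.cow_id, p.dose_g, level=level)
        kp = fractional_kp(fit, p.diet_label, window=window)
        estimates.append(KineticsEstimate(
            cow_id=p.cow_id, diet_label=p.diet_label, phase=fit.phase,
            volume=vol, frac_kp=kp, abs_kp=vol * kp,
            volume_units=vol_units, abs_kp_units=abs_units,
            c0=p.dose_g / vol, dose_g=p.dose_g))
    return estimates


def estimates_to_frame(estimates: list[KineticsEstimate]) -> pd.DataFrame:
    return pd.DataFrame([dict(
        cow_id=e.cow_id, diet=e.diet_label, phase=e.phase,
        volume=e.volume, volume_units=e.volume_units,
        frac_kp_per_h=e.frac_kp, abs_kp=e.abs_kp,
        abs_kp_units=e.abs_kp_units) for e in estimates])


def test_kinetics_effects(fit: DecayFit,
                          estimates: list[KineticsEstimate]) -> pd.DataFrame:
    """Treatment tests on a fitted washout model.

    Type III Wald F for diet differences in intercepts and slopes (and
    curvatures for quadratic fits) with Tukey-adjusted pairwise
    contrasts via the studentized-range distribution, plus a Friedman
    chi-square on absolute Kp with animal as the block.
    """
    diets = fit.diets
    if len(diets) < 2:
        raise ValueError("need >= 2 diets to test treatment effects")
    terms = ["intercept", "time"] + (["time2"]
                                     if fit.model == "quadratic" else [])
    p_idx = {nm: i for i, nm in enumerate(fit.lmm.names)}
    rows = []
    k = len(diets)
    for term in terms:
        L = np.zeros((k - 1, len(fit.lmm.names)))
        for r, d in enumerate(diets[1:]):
            L[r, p_idx[(term, diets[0])]] = 1.0
            L[r, p_idx[(term, d)]] = -1.0
        F, df1, df2, p = wald_f(fit.lmm, L)
        rows.append(dict(effect=f"diet:{term}", test="wald_f",
                         statistic=F, df1=df1, df2=df2,
                         p_raw=p, p_adj=np.nan, contrast=""))
        for d1, d2 in itertools.combinations(diets, 2):
            l = np.zeros(len(fit.lmm.names))
            l[p_idx[(term, d1)]] = 1.0
            l[p_idx[(term, d2)]] = -1.0
            diff = float(l @ fit.lmm.beta)
            se = float(np.sqrt(l @ fit.lmm.cov_beta @ l))
            if se == 0.0:
                p_raw = p_adj = 1.0 if diff == 0.0 else 0.0
            else:
                tval = diff / se
                p_raw = 2.0 * float(t_dist.sf(abs(tval), fit.lmm.df_resid))
                p_adj = float(studentized_range.sf(
                    abs(tval) * np.sqrt(2.0), k, fit.lmm.df_resid))
            rows.append(dict(effect=f"diet:{term}", test="tukey",
                             statistic=diff, df1=1, df2=fit.lmm.df_resid,
                             p_raw=p_raw, p_adj=min(p_adj, 1.0),
                             contrast=f"{d1} - {d2}"))

    # absolute Kp: blocked rank test, animal = block, diet = treatment
    ek = pd.DataFrame([dict(cow=e.cow_id, diet=e.diet_label, y=e.abs_kp)
                       for e in estimates])
    mat = ek.pivot(index="cow", columns="diet", values="y")
    if mat.isna().any().any():
        raise ValueError("absolute-Kp block matrix has missing cow x diet "
                         "cells; Friedman test needs complete blocks")
    chi2, df, p = friedman_test(mat.to_numpy())
    rows.append(dict(effect="diet:abs_kp", test="friedman",
                     statistic=chi2, df1=df, df2=np.nan,
                     p_raw=p, p_adj=np.nan, contrast=""))
    return pd.DataFrame(rows)
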