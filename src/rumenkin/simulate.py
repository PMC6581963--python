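"""Synthetic 3x3 crossover trials with known ground truth.

Generates the complete data a marker-dilution balance trial produces:
a Latin-square design, pulse-dose marker washout curves for the
cannulated cows (Co-EDTA in the liquid phase, Yb-NDF in the solid
phase), daily mineral-balance records, and rumen chemistry — all from a
seeded RNG so every downstream estimator can be tested against the
generating values.

Streams are derived per component from the trial seed, and the realized
intake covariates are generated in their own stream, so the marker
curves and the balance records of one configuration always see the same
cow-by-period DM and NDF intakes even when the generator functions are
called independently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .config import (DIET_LABELS, MG_MOLAR_MASS, K_MOLAR_MASS, NA_MOLAR_MASS,
                     DietCalibration, TrialConfig, PLACEHOLDER_FIELDS,
                     calibration_to_jsonable, default_calibration)

#: hours post-dose at which rumen content is sampled
SAMPLING_HOURS = np.array([1.0, 2.0, 3.0, 5.0, 7.0, 10.0, 16.0, 23.0])

# fixed stream ids so each component's draws are independent of the others
_STREAM_DESIGN, _STREAM_INTAKE, _STREAM_PROFILE, _STREAM_BALANCE, \
    _STREAM_CHEM, _STREAM_COW = range(6)


def _rng(config: TrialConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((config.seed, stream)))


@dataclass
class TrialDesign:
    """Crossover assignment of cows to diet sequences over periods."""

    assignments: list            # (cow_id, period_index, diet_label)
    cannulated: dict             # cow_id -> bool
    bw_kg: dict                  # cow_id -> body weight

    @property
    def cow_ids(self) -> list:
        return sorted(self.cannulated)

    def diet_of(self, cow_id: str, period: int) -> str:
        for c, p, d in self.assignments:
            if c == cow_id and p == period:
                return d
        raise KeyError((cow_id, period))

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.assignments,
                            columns=["cow_id", "period", "diet"])


@dataclass
class MarkerProfile:
    """One pulse-dose washout curve (cow x period x digesta phase)."""

    cow_id: str
    period: int
    diet_label: str
    phase: str                   # "liquid" or "solid"
    times: np.ndarray            # h post-dose
    concentrations: np.ndarray   # g/l (liquid) or g/kg DM (solid)
    dose_g: float

    def validate(self) -> None:
        if self.phase not in ("liquid", "solid"):
            raise ValueError(f"unknown phase {self.phase!r}")
        t = np.asarray(self.times, dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        c = np.asarray(self.concentrations, dtype=float)
        if np.any(c[t > 0] <= 0):
            raise ValueError("concentrations must be > 0 for t > 0")
        if self.dose_g <= 0:
            raise ValueError("dose_g must be > 0")


def generate_design(config: TrialConfig) -> TrialDesign:
    """Stacked cyclic Latin squares with seed-randomized cow order.

    Body weights are Normal(697, 61) kg truncated at +/-3 SD; the first
    ``n_cannulated`` cows (after shuffling) carry ruminal cannulas.
    """
    config.validate()
    rng = _rng(config, _STREAM_DESIGN)
    k = config.n_diets
    cows = [f"cow{i + 1}" for i in range(config.n_cows)]
    order = list(rng.permutation(config.n_cows))

    assignments = []
    for slot, ci in enumerate(order):
        square = slot // k           # stacked 3x3 squares
        row = slot % k
        for period in range(1, config.n_periods + 1):
            # second square runs the cyclic sequence in reverse
            shift = (row + (period - 1)) if square % 2 == 0 \
                else (row - (period - 1))
            assignments.append(
                (cows[ci], period, DIET_LABELS[shift % k]))
    assignments.sort(key=lambda a: (int(a[0][3:]), a[1]))

    cannulated_set = {cows[ci] for ci in order[:config.n_cannulated]}
    bw = {}
    for ci in order:
        z = rng.normal()
        while abs(z) > 3.0:
            z = rng.normal()
        bw[cows[ci]] = config.bw_mean_kg + config.bw_sd_kg * z
    return TrialDesign(assignments,
                       {c: c in cannulated_set for c in cows},
                       bw)


def cow_effects(design: TrialDesign, config: TrialConfig) -> pd.DataFrame:
    """Per-animal random intercepts, one row per cow.

    ``a_liquid``/``a_solid`` act on the log marker-concentration scale
    (a positive value shifts the whole washout curve up, i.e. the cow's
    effective pool is smaller); ``rel_dmi``/``rel_bal`` are relative
    effects applied to intake and balance means.
    """
    rng = _rng(config, _STREAM_COW)
    rows = []
    for cow in design.cow_ids:
        rows.append(dict(
            cow_id=cow,
            a_liquid=rng.normal(0.0, config.cow_re_sd),
            a_solid=rng.normal(0.0, config.cow_re_sd),
            rel_dmi=rng.normal(0.0, config.cow_re_sd),
            rel_bal=rng.normal(0.0, config.cow_re_sd),
        ))
    return pd.DataFrame(rows).set_index("cow_id")


def generate_intakes(design: TrialDesign,
                     cal: Mapping[str, DietCalibration],
                     config: TrialConfig) -> pd.DataFrame:
    """Realized covariates per cow x period (shared by all components).

    DMI = diet mean x (1 + cow effect) + period noise; NDFi follows from
    the diet NDF concentration.  The liquid rumen volume responds
    linearly to realized NDFi, then scales by the cow's kinetic
    intercept effect (exp(-a_liquid)); the solid pool is the diet mean
    scaled the same way.
    """
    rng = _rng(config, _STREAM_INTAKE)
    eff = cow_effects(design, config)
    rows = []
    for cow, period, diet in design.assignments:
        c = cal[diet]
        base_dmi = c.dmi_mean * (1.0 + eff.loc[cow, "rel_dmi"])
        dmi = base_dmi + rng.normal(0.0, config.balance_cv * c.dmi_mean)
        for _ in range(config.max_resample):
            if dmi > 0:
                break
            dmi = base_dmi + rng.normal(0.0, config.balance_cv * c.dmi_mean)
        else:
            raise RuntimeError("could not draw a positive DMI")
        ndfi = dmi * c.ndf_diet / 1000.0
        vol_l = ((c.vol_liquid_intercept + c.vol_liquid_ndfi_slope * ndfi)
                 * np.exp(-eff.loc[cow, "a_liquid"]))
        vol_s = c.vol_solid_mean * np.exp(-eff.loc[cow, "a_solid"])
        water = c.water_intake_mean * (
            1.0 + rng.normal(0.0, config.balance_cv))
        milk = c.milk_yield_mean * (1.0 + eff.loc[cow, "rel_bal"]
                                    + rng.normal(0.0, config.balance_cv))
        urine = c.urine_volume_mean * (1.0 + rng.normal(0.0,
                                                        config.balance_cv))
        rows.append(dict(cow_id=cow, period=period, diet=diet,
                         bw_kg=design.bw_kg[cow], dmi_kg_d=dmi,
                         ndf_intake_kg_d=ndfi, vol_liquid_l=vol_l,
                         vol_solid_kg=vol_s, water_l_d=water,
                         milk_kg_d=milk, urine_l_d=urine))
    return pd.DataFrame(rows)


def generate_marker_profiles(design: TrialDesign,
                             cal: Mapping[str, DietCalibration],
                             config: TrialConfig,
                             intakes: pd.DataFrame | None = None
                             ) -> list[MarkerProfile]:
    """Pulse-dose washout curves for the cannulated cows.

    Liquid: ``log C(t) = log(D_Co / Vol_L) - kL t + a_cow + eps``.
    Solid:  ``log C(t) = log(D_Yb / Vol_S) + b t + c t^2 + a_cow + eps``
    with ``c <= 0``.  The grid is the sampling schedule plus a pre-dose
    record at t = 0 with concentration 0 (zero marker background).
    """
    config.validate()
    for c in cal.values():
        c.validate()
    if intakes is None:
        intakes = generate_intakes(design, cal, config)
    rng = _rng(config, _STREAM_PROFILE)
    profiles = []
    for row in intakes.itertuples():
        if not design.cannulated[row.cow_id]:
            continue
        c = cal[row.diet]
        if row.vol_liquid_l <= 0 or row.vol_solid_kg <= 0:
            raise ValueError("non-positive volume in calibration")
        for phase in ("liquid", "solid"):
            # the cow's random intercept is already inside the effective
            # volume (vol = base * exp(-a_cow)), so log(dose/vol) is the
            # NDFi-relation intercept plus a_cow, as generated
            if phase == "liquid":
                dose = config.dose_co_g
                log_c = (np.log(dose / row.vol_liquid_l)
                         - c.true_frac_kp_liquid * SAMPLING_HOURS)
            else:
                dose = config.dose_yb_g
                log_c = (np.log(dose / row.vol_solid_kg)
                         + c.quad_b_solid * SAMPLING_HOURS
                         + c.quad_coeff_solid * SAMPLING_HOURS ** 2)
            log_c = log_c + rng.normal(0.0, config.noise_log_conc_sd,
                                       size=log_c.shape)
            times = np.concatenate(([0.0], SAMPLING_HOURS))
            conc = np.concatenate(([0.0], np.exp(log_c)))
            prof = MarkerProfile(row.cow_id, row.period, row.diet, phase,
                                 times, conc, dose)
            prof.validate()
            profiles.append(prof)
    return profiles


_ELEMENTS = ("Mg", "K", "Na", "Ca", "P")


def generate_balance(design: TrialDesign,
                     cal: Mapping[str, DietCalibration],
                     config: TrialConfig,
                     intakes: pd.DataFrame | None = None
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Daily mineral-balance and rumen-chemistry records.

    Mg absorption is generated from the cow's liquid rumen volume
    (absorption = a + b Vol_L + cow effect + noise) and faecal Mg closes
    the balance exactly (faecal = intake - absorption).  K/Na/Ca/P
    absorption comes from diet-level absorbabilities; urinary and milk
    excretion are volume x concentration.  Negative draws are resampled
    up to ``config.max_resample`` times.

    Returns ``(balance, rumen)`` data frames; rumen chemistry exists for
    the cannulated cows only.
    """
    config.validate()
    if intakes is None:
        intakes = generate_intakes(design, cal, config)
    rng = _rng(config, _STREAM_BALANCE)
    eff = cow_effects(design, config)
    cv = config.balance_cv

    def noisy(mean, sd):
        for _ in range(config.max_resample):
            v = mean + rng.normal(0.0, sd) if sd > 0 else mean
            if v >= 0:
                return v
        raise RuntimeError("could not draw a non-negative value "
                           f"around mean {mean}")

    bal_rows = []
    for row in intakes.itertuples():
        c = cal[row.diet]
        rel_bal = eff.loc[row.cow_id, "rel_bal"]
        for element in _ELEMENTS:
            intake = row.dmi_kg_d * c.mineral_conc[element]
            if element == "Mg":
                mean_abs = (c.mg_abs_intercept
                            + c.mg_abs_vol_slope * row.vol_liquid_l
                            + rel_bal * abs(c.mg_abs_intercept))
                absorbed = noisy(mean_abs, cv * abs(mean_abs))
                urine = (row.urine_l_d
                         * noisy(c.urine_mg_conc_mean,
                                 cv * c.urine_mg_conc_mean)
                         * MG_MOLAR_MASS / 1000.0)
                milk = row.milk_kg_d * noisy(c.milk_mg_conc_mean,
                                             cv * c.milk_mg_conc_mean)
            else:
                frac = c.absorbability_pct[element] / 100.0
                absorbed = noisy(frac * intake, cv * frac * intake)
                if element in c.urine_conc_mmol_l:
                    molar = K_MOLAR_MASS if element == "K" else NA_MOLAR_MASS
                    urine = (row.urine_l_d
                             * noisy(c.urine_conc_mmol_l[element],
                                     cv * c.urine_conc_mmol_l[element])
                             * molar / 1000.0)
                else:
                    urine = noisy(c.urine_g_d[element],
                                  cv * c.urine_g_d[element])
                milk = row.milk_kg_d * noisy(c.milk_conc_g_kg[element],
                                             cv * c.milk_conc_g_kg[element])
            faecal = intake - absorbed
            for _ in range(config.max_resample):
                if faecal >= 0:
                    break
                absorbed = noisy(mean_abs if element == "Mg"
                                 else frac * intake,
                                 cv * abs(intake))
                faecal = intake - absorbed
            else:
                raise RuntimeError("faecal excretion stayed negative after "
                                   "bounded resampling")
            bal_rows.append(dict(
                cow_id=row.cow_id, period=row.period, diet=row.diet,
                bw_kg=row.bw_kg, dmi_kg_d=row.dmi_kg_d,
                ndf_intake_kg_d=row.ndf_intake_kg_d,
                water_l_d=row.water_l_d, element=element,
                intake_g_d=intake, faecal_g_d=faecal,
                urine_g_d=urine, milk_g_d=milk))

    chem_rows = []
    for row in intakes.itertuples():
        if not design.cannulated[row.cow_id]:
            continue
        c = cal[row.diet]
        chem_rows.append(dict(
            cow_id=row.cow_id, period=row.period, diet=row.diet,
            ph=noisy(c.rumen_ph_mean, 0.1 if cv > 0 else 0.0),
            liquid_mg_mmol_l=noisy(c.liquid_conc_mean["Mg"],
                                   cv * c.liquid_conc_mean["Mg"]),
            liquid_k_mmol_l=noisy(c.liquid_conc_mean["K"],
                                  cv * c.liquid_conc_mean["K"]),
            liquid_na_mmol_l=noisy(c.liquid_conc_mean["Na"],
                                   cv * c.liquid_conc_mean["Na"]),
            solid_mg_g_kg=noisy(c.solid_conc_mean["Mg"],
                                cv * c.solid_conc_mean["Mg"]),
            solid_k_g_kg=noisy(c.solid_conc_mean["K"],
                               cv * c.solid_conc_mean["K"]),
        ))
    return pd.DataFrame(bal_rows), pd.DataFrame(chem_rows)


@dataclass
class Trial:
    """A complete synthetic trial with its generating truth."""

    config: TrialConfig
    calibration: dict
    design: TrialDesign
    intakes: pd.DataFrame
    profiles: list
    balance: pd.DataFrame
    rumen: pd.DataFrame

    def truth(self) -> dict:
        per_record = []
        for row in self.intakes.itertuples():
            c = self.calibration[row.diet]
            mean_abs = (c.mg_abs_intercept
                        + c.mg_abs_vol_slope * row.vol_liquid_l)
            per_record.append(dict(
                cow_id=row.cow_id, period=row.period, diet=row.diet,
                dmi_kg_d=row.dmi_kg_d, ndf_intake_kg_d=row.ndf_intake_kg_d,
                vol_liquid_l=row.vol_liquid_l, vol_solid_kg=row.vol_solid_kg,
                frac_kp_liquid=c.true_frac_kp_liquid,
                frac_kp_solid=c.true_frac_kp_solid,
                mg_absorption_mean_g_d=mean_abs))
        return dict(
            config=asdict(self.config),
            calibration=calibration_to_jsonable(self.calibration),
            placeholder_fields=list(PLACEHOLDER_FIELDS),
            records=per_record,
        )


def generate_trial(config: TrialConfig | None = None,
                   cal: Mapping[str, DietCalibration] | None = None) -> Trial:
    """Generate a full trial: design, shared intakes, curves, balances."""
    config = config or TrialConfig()
    cal = dict(cal or default_calibration())
    design = generate_design(config)
    intakes = generate_intakes(design, cal, config)
    profiles = generate_marker_profiles(design, cal, config, intakes)
    balance, rumen = generate_balance(design, cal, config, intakes)
    return Trial(config, cal, design, intakes, profiles, balance, rumen)


def profiles_to_frame(profiles: list[MarkerProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        units = "g_per_l" if p.phase == "liquid" else "g_per_kg_dm"
        for t, conc in zip(p.times, p.concentrations):
            rows.append(dict(cow_id=p.cow_id, period=p.period,
                             diet=p.diet_label, phase=p.phase, time_h=t,
                             conc=conc, conc_units=units, dose_g=p.dose_g))
    return pd.DataFrame(rows)


def profiles_from_frame(df: pd.DataFrame) -> list[MarkerProfile]:
    profiles = []
    keys = ["cow_id", "period", "diet", "phase"]
    for (cow, period, diet, phase), g in df.groupby(keys, sort=True):
        g = g.sort_values("time_h")
        prof = MarkerProfile(cow, int(period), diet, phase,
                             g["time_h"].to_numpy(float),
                             g["conc"].to_numpy(float),
                             float(g["dose_g"].iloc[0]))
        prof.validate()
        profiles.append(prof)
    return profiles


def write_trial(trial: Trial, out_dir: str | Path) -> dict:
    """Write profiles.csv, balance.csv, rumen.csv and truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "profiles": out / "profiles.csv",
        "balance": out / "balance.csv",
        "rumen": out / "rumen.csv",
        "truth": out / "truth.json",
    }
    profiles_to_frame(trial.profiles).to_csv(paths["profiles"], index=False)
    trial.balance.to_csv(paths["balance"], index=False)
    trial.rumen.to_csv(paths["rumen"], index=False)
    paths["truth"].write_text(json.dumps(trial.truth(), indent=1))
    return {k: str(v) for k, v in paths.items()}
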