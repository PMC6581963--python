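"""Apparent mineral balance and rumen Mg partitioning.

Balance arithmetic on total-collection records (intake, faecal, urinary
and milk excretion, all g/day):

* apparent absorption = intake - faecal (endogenous faecal losses are
  not separated, so absorption can be negative);
* absorbability = 100 * absorption / intake (% of intake);
* retention = absorption - urine - milk;
* Mg per K absorbed = the cow x period ratio of the two absorptions;
* rumen Mg solubility = the liquid-phase share of the total rumen Mg
  pool, combining rumen chemistry with marker-dilution pool sizes.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .config import MG_MOLAR_MASS
from .kinetics import KineticsEstimate

REQUIRED_COLUMNS = ("cow_id", "period", "diet", "element",
                    "intake_g_d", "faecal_g_d", "urine_g_d", "milk_g_d")


def derive_balance(records: pd.DataFrame) -> pd.DataFrame:
    """Add absorption, absorbability, retention and flags to records.

    The identities hold exactly: ``absorption = intake - faecal`` and
    ``retention = absorption - urine - milk``.  Absorbability is
    missing (NaN, with a warning) when intake is zero.
    """
    missing = set(REQUIRED_COLUMNS) - set(records.columns)
    if missing:
        raise ValueError(f"balance records lack columns {sorted(missing)}")
    for col in ("intake_g_d", "faecal_g_d", "urine_g_d", "milk_g_d"):
        bad = records.index[records[col] < 0]
        if len(bad):
            raise ValueError(f"negative {col} at row {bad[0]}")
    out = records.copy()
    out["absorption_g_d"] = out["intake_g_d"] - out["faecal_g_d"]
    zero_intake = out["intake_g_d"] == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        out["absorbability_pct"] = np.where(
            zero_intake, np.nan,
            100.0 * out["absorption_g_d"] / out["intake_g_d"])
    if zero_intake.any():
        warnings.warn(f"{int(zero_intake.sum())} record(s) with zero "
                      "intake; absorbability undefined")
    out["retention_g_d"] = (out["absorption_g_d"] - out["urine_g_d"]
                            - out["milk_g_d"])
    out["negative_absorption"] = out["absorption_g_d"] < 0
    if out["negative_absorption"].any():
        warnings.warn(f"{int(out['negative_absorption'].sum())} record(s) "
                      "with negative apparent absorption")
    return out


def mg_per_k_absorbed(derived: pd.DataFrame) -> pd.DataFrame:
    """Grams Mg absorbed per gram K absorbed, per cow x period.

    Rows where K absorption is not positive get NaN with a warning.
    """
    need = derived[derived["element"].isin(["Mg", "K"])]
    wide = need.pivot_table(index=["cow_id", "period", "diet"],
                            columns="element", values="absorption_g_d")
    if "Mg" not in wide or "K" not in wide:
        raise ValueError("need both Mg and K records")
    bad = wide["K"] <= 0
    if bad.any():
        warnings.warn(f"{int(bad.sum())} record(s) with non-positive K "
                      "absorption; ratio undefined")
    ratio = np.where(bad, np.nan, wide["Mg"] / wide["K"])
    out = wide.reset_index()[["cow_id", "period", "diet"]]
    out["mg_per_k_absorbed_g_g"] = ratio
    return out


def mg_solubility(chem_row: pd.Series,
                  kin_liquid: KineticsEstimate,
                  kin_solid: KineticsEstimate) -> float:
    """Rumen Mg solubility (%) for one cow x diet.

    liquid pool (g) = liquid Mg (mmol/l) x 24.305 mg/mmol x Vol_L (l) / 1000;
    solid pool (g)  = solid Mg (g/kg DM) x Vol_S (kg DM);
    solubility      = 100 x liquid / (liquid + solid).
    """
    for kin, phase in ((kin_liquid, "liquid"), (kin_solid, "solid")):
        if kin.phase != phase:
            raise ValueError(f"expected a {phase} estimate, got {kin.phase}")
        if kin.cow_id != chem_row["cow_id"] or \
                kin.diet_label != chem_row["diet"]:
            raise ValueError("chemistry and kinetics rows refer to "
                             "different cow x diet")
        if kin.volume <= 0:
            raise ValueError("pool volume must be > 0")
    liquid_pool = (chem_row["liquid_mg_mmol_l"] * MG_MOLAR_MASS
                   * kin_liquid.volume / 1000.0)
    solid_pool = chem_row["solid_mg_g_kg"] * kin_solid.volume
    total = liquid_pool + solid_pool
    if total == 0:
        warnings.warn("both rumen Mg pools are zero; solubility undefined")
        return np.nan
    return float(100.0 * liquid_pool / total)


def solubility_table(rumen: pd.DataFrame,
                     estimates: list[KineticsEstimate]) -> pd.DataFrame:
    """Mg solubility per cow x diet from chemistry plus kinetics."""
    by_key = {}
    for e in estimates:
        by_key[(e.cow_id, e.diet_label, e.phase)] = e
    rows = []
    for _, r in rumen.iterrows():
        kl = by_key.get((r["cow_id"], r["diet"], "liquid"))
        ks = by_key.get((r["cow_id"], r["diet"], "solid"))
        if kl is None or ks is None:
            continue
        rows.append(dict(cow_id=r["cow_id"], period=r["period"],
                         diet=r["diet"],
                         mg_solubility_pct=mg_solubility(r, kl, ks)))
    return pd.DataFrame(rows)
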