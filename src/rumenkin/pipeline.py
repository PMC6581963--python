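"""Reproducible pipeline: simulate -> fit -> balance -> analyze -> report.

Each stage reads and writes plain CSV (comma-separated, UTF-8, '.'
decimal, header required) so stages are individually rerunnable and the
whole run is captured by a manifest of input/output digests.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import TrialConfig, default_calibration, load_config
from .simulate import generate_trial, profiles_from_frame, write_trial
from .kinetics import (estimates_to_frame, fit_decay, summarize_kinetics,
                       test_kinetics_effects)
from .balance import derive_balance, mg_per_k_absorbed, solubility_table
from .inference import (cow_adjusted_regression, crossover_anova, pearson,
                        tukey_contrasts)

log = logging.getLogger("rumenkin")


class ValidationError(ValueError):
    """Input fails schema or consistency checks (exit code 2 in the CLI)."""


@dataclass
class ValidationReport:
    errors: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


@dataclass
class RunManifest:
    seed: int
    config_digest: str
    input_digests: dict
    output_digests: dict
    version: str = __version__

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=1))


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


_SCHEMAS = {
    "profiles": ["cow_id", "period", "diet", "phase", "time_h", "conc",
                 "conc_units", "dose_g"],
    "balance": ["cow_id", "period", "diet", "bw_kg", "dmi_kg_d",
                "ndf_intake_kg_d", "water_l_d", "element", "intake_g_d",
                "faecal_g_d", "urine_g_d", "milk_g_d"],
    "rumen": ["cow_id", "period", "diet", "ph", "liquid_mg_mmol_l",
              "liquid_k_mmol_l", "liquid_na_mmol_l", "solid_mg_g_kg",
              "solid_k_g_kg"],
}


def validate_inputs(paths: dict) -> ValidationReport:
    """Schema, unit and design checks on the three trial CSVs.

    Fatal problems (missing columns, negative concentrations, bad units)
    land in ``errors``; recoverable design imbalance (a cow missing a
    period blocks the ANOVA but not the regressions) in ``warnings``.
    """
    rep = ValidationReport()
    frames = {}
    for kind, cols in _SCHEMAS.items():
        p = paths.get(kind)
        if p is None:
            continue
        p = Path(p)
        if not p.exists():
            rep.errors.append(f"{kind}: file {p} does not exist")
            continue
        df = pd.read_csv(p)
        missing = set(cols) - set(df.columns)
        if missing:
            rep.errors.append(
                f"{p.name}: missing required columns {sorted(missing)}")
            continue
        frames[kind] = df

    prof = frames.get("profiles")
    if prof is not None:
        bad_units = ~prof["conc_units"].isin(["g_per_l", "g_per_kg_dm"])
        if bad_units.any():
            rep.errors.append(
                f"profiles.csv: unknown conc_units at row "
                f"{int(prof.index[bad_units][0])}")
        neg = (prof["conc"] < 0) | ((prof["time_h"] > 0) &
                                    (prof["conc"] <= 0))
        if neg.any():
            rep.errors.append(
                f"profiles.csv: non-positive concentration at row "
                f"{int(prof.index[neg][0])}")
        if (prof["dose_g"] <= 0).any():
            rep.errors.append("profiles.csv: non-positive dose_g")

    bal = frames.get("balance")
    if bal is not None:
        for col in ("intake_g_d", "faecal_g_d", "urine_g_d", "milk_g_d"):
            neg = bal[col] < 0
            if neg.any():
                rep.errors.append(
                    f"balance.csv: negative {col} at row "
                    f"{int(bal.index[neg][0])}")
        if (bal["ndf_intake_kg_d"] > bal["dmi_kg_d"]).any():
            rep.errors.append("balance.csv: NDF intake exceeds DM intake")
        cells = bal.groupby(["cow_id", "period"]).size()
        per_cow = bal.groupby("cow_id")["period"].nunique()
        if per_cow.nunique() > 1:
            rep.warnings.append(
                "balance.csv: unequal period counts across cows — fatal "
                "for the crossover ANOVA, regressions still possible")
        del cells

    rum = frames.get("rumen")
    if rum is not None:
        bad_ph = ~rum["ph"].between(0, 14, inclusive="neither")
        if bad_ph.any():
            rep.errors.append(
                f"rumen.csv: pH outside (0, 14) at row "
                f"{int(rum.index[bad_ph][0])}")
        for col in _SCHEMAS["rumen"][4:]:
            if (rum[col] < 0).any():
                rep.errors.append(f"rumen.csv: negative {col}")
    return rep


def stage_simulate(config: TrialConfig, out_dir: Path) -> dict:
    trial = generate_trial(config, default_calibration())
    paths = write_trial(trial, out_dir)
    log.info("simulate: %d profiles, %d balance records, %d chemistry rows",
             len(trial.profiles), len(trial.balance), len(trial.rumen))
    return paths


def stage_fit_kinetics(out_dir: Path) -> dict:
    prof = pd.read_csv(out_dir / "profiles.csv")
    profiles = profiles_from_frame(prof)
    frames, tests = [], []
    for phase, model in (("liquid", "linear"), ("solid", "quadratic")):
        sub = [p for p in profiles if p.phase == phase]
        fit = fit_decay(sub, phase, model)
        est = summarize_kinetics(fit, sub)
        frames.append(estimates_to_frame(est))
        t = test_kinetics_effects(fit, est)
        t.insert(0, "phase", phase)
        tests.append(t)
    kin = pd.concat(frames, ignore_index=True)
    ktests = pd.concat(tests, ignore_index=True)
    kin.to_csv(out_dir / "kinetics.csv", index=False)
    ktests.to_csv(out_dir / "kinetics_tests.csv", index=False)
    log.info("fit-kinetics: %d estimates", len(kin))
    return {"kinetics": str(out_dir / "kinetics.csv"),
            "kinetics_tests": str(out_dir / "kinetics_tests.csv")}


def stage_balance(out_dir: Path) -> dict:
    bal = pd.read_csv(out_dir / "balance.csv")
    derived = derive_balance(bal)
    ratio = mg_per_k_absorbed(derived)
    derived = derived.merge(ratio, on=["cow_id", "period", "diet"],
                            how="left")
    derived.loc[derived["element"] != "Mg", "mg_per_k_absorbed_g_g"] = np.nan
    derived.to_csv(out_dir / "balance_derived.csv", index=False)
    log.info("balance: %d derived records", len(derived))
    return {"balance_derived": str(out_dir / "balance_derived.csv")}


_ANOVA_RESPONSES = ("absorption_g_d", "absorbability_pct", "retention_g_d",
                    "faecal_g_d", "urine_g_d", "milk_g_d")


def stage_analyze(out_dir: Path) -> dict:
    kin = pd.read_csv(out_dir / "kinetics.csv")
    derived = pd.read_csv(out_dir / "balance_derived.csv")
    rumen = pd.read_csv(out_dir / "rumen.csv")

    test_rows, regr_rows = [], []
    for element in ("Mg", "K"):
        sub = derived[derived["element"] == element]
        for resp in _ANOVA_RESPONSES:
            a = crossover_anova(sub, resp)
            for _, r in a.table.iterrows():
                test_rows.append(dict(
                    response=f"{element}:{resp}", effect=r["effect"],
                    test="wald_f", statistic=r["F"],
                    df1=r["df1"], df2=r["df2"], p_raw=r["p"], p_adj=np.nan,
                    contrast=""))
            for _, r in tukey_contrasts(a).table.iterrows():
                test_rows.append(dict(
                    response=f"{element}:{resp}", effect="Diet",
                    test="tukey", statistic=r["estimate"], df1=1,
                    df2=a.df_resid, p_raw=r["p_raw"], p_adj=r["p_adj"],
                    contrast=r["contrast"]))

    mg = derived[derived["element"] == "Mg"]
    liq = kin[kin["phase"] == "liquid"]
    merged = liq.merge(
        mg[["cow_id", "diet", "ndf_intake_kg_d", "absorption_g_d"]],
        on=["cow_id", "diet"])

    def add_regression(pair, x, y, cows):
        r = cow_adjusted_regression(x, y, cows)
        pr = pearson(x, y)
        regr_rows.append(dict(pair=pair, slope=r.slope, se=r.se,
                              intercept=r.intercept,
                              r2_marginal=r.r2_marginal, p_slope=r.p,
                              r=pr.r, df=pr.df, p_pearson=pr.p, n=r.n))

    add_regression("vol_liquid~ndfi", merged["ndf_intake_kg_d"],
                   merged["volume"], merged["cow_id"])
    add_regression("mg_absorption~vol_liquid", merged["volume"],
                   merged["absorption_g_d"], merged["cow_id"])
    add_regression("mg_absorption~ndfi", mg["ndf_intake_kg_d"],
                   mg["absorption_g_d"], mg["cow_id"])

    sol = solubility_table(
        rumen,
        _estimates_from_frame(kin))
    sol.to_csv(out_dir / "solubility.csv", index=False)

    pd.DataFrame(test_rows).to_csv(out_dir / "tests.csv", index=False)
    pd.DataFrame(regr_rows).to_csv(out_dir / "regressions.csv", index=False)
    log.info("analyze: %d tests, %d regressions", len(test_rows),
             len(regr_rows))
    return {"tests": str(out_dir / "tests.csv"),
            "regressions": str(out_dir / "regressions.csv"),
            "solubility": str(out_dir / "solubility.csv")}


def _estimates_from_frame(kin: pd.DataFrame):
    from .kinetics import KineticsEstimate, PHASE_UNITS
    out = []
    for _, r in kin.iterrows():
        vol_units, abs_units = PHASE_UNITS[r["phase"]]
        out.append(KineticsEstimate(
            cow_id=r["cow_id"], diet_label=r["diet"], phase=r["phase"],
            volume=r["volume"], frac_kp=r["frac_kp_per_h"],
            abs_kp=r["abs_kp"], volume_units=vol_units,
            abs_kp_units=abs_units, c0=np.nan, dose_g=np.nan))
    return out


def stage_report(out_dir: Path, plots: bool = True) -> dict:
    kin = pd.read_csv(out_dir / "kinetics.csv")
    derived = pd.read_csv(out_dir / "balance_derived.csv")
    regr = pd.read_csv(out_dir / "regressions.csv")
    sol = pd.read_csv(out_dir / "solubility.csv")

    lines = ["# Trial report", ""]
    lines.append("## Rumen passage kinetics (cannulated cows)")
    ksum = (kin.groupby(["phase", "diet"])
            .agg(volume=("volume", "mean"), frac_kp=("frac_kp_per_h", "mean"),
                 abs_kp=("abs_kp", "mean")).round(3))
    lines.append(ksum.to_markdown())
    lines.append("")
    lines.append("## Mineral balance (g/day; absorbability %)")
    bsum = (derived.groupby(["element", "diet"])
            [["intake_g_d", "faecal_g_d", "urine_g_d", "milk_g_d",
              "absorption_g_d", "absorbability_pct", "retention_g_d"]]
            .mean().round(2))
    lines.append(bsum.to_markdown())
    lines.append("")
    lines.append("## Rumen Mg solubility (%)")
    lines.append(sol.groupby("diet")["mg_solubility_pct"].mean().round(1)
                 .to_markdown())
    lines.append("")
    lines.append("## Regressions (cow-adjusted mixed models)")
    lines.append(regr.round(4).to_markdown(index=False))
    lines.append("")
    (out_dir / "report.md").write_text("\n".join(lines))

    outputs = {"report": str(out_dir / "report.md")}
    if plots:
        outputs.update(_regression_figures(out_dir, kin, derived, regr))
    return outputs


def _regression_figures(out_dir, kin, derived, regr) -> dict:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mg = derived[derived["element"] == "Mg"]
    liq = kin[kin["phase"] == "liquid"]
    merged = liq.merge(
        mg[["cow_id", "diet", "ndf_intake_kg_d", "absorption_g_d"]],
        on=["cow_id", "diet"])
    specs = {
        "vol_liquid~ndfi": (merged["ndf_intake_kg_d"], merged["volume"],
                            "NDF intake (kg/day)", "Vol_L (l)"),
        "mg_absorption~vol_liquid": (merged["volume"],
                                     merged["absorption_g_d"],
                                     "Vol_L (l)", "Mg absorption (g/day)"),
        "mg_absorption~ndfi": (mg["ndf_intake_kg_d"], mg["absorption_g_d"],
                               "NDF intake (kg/day)",
                               "Mg absorption (g/day)"),
    }
    out = {}
    for _, row in regr.iterrows():
        pair = row["pair"]
        if pair not in specs:
            continue
        x, y, xl, yl = specs[pair]
        fig, ax = plt.subplots(figsize=(4, 3))
        ax.scatter(x, y, s=18)
        xs = np.linspace(float(np.min(x)), float(np.max(x)), 50)
        ax.plot(xs, row["intercept"] + row["slope"] * xs, "k-")
        ax.set_xlabel(xl)
        ax.set_ylabel(yl)
        ax.set_title(f"slope={row['slope']:.3g} ± {row['se']:.2g}, "
                     f"R²m={row['r2_marginal']:.2f}", fontsize=9)
        fig.tight_layout()
        name = pair.replace("~", "_on_") + ".png"
        fig.savefig(out_dir / name, dpi=120)
        plt.close(fig)
        out[pair] = str(out_dir / name)
    return out


def run_pipeline(config_path: str | None, out_dir: str,
                 seed: int | None = None, plots: bool = True) -> RunManifest:
    """Execute simulate -> fit-kinetics -> balance -> analyze -> report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = load_config(config_path) if config_path else TrialConfig()
    if seed is not None:
        config.seed = seed
    config.validate()

    inputs = stage_simulate(config, out)
    rep = validate_inputs(inputs)
    for w in rep.warnings:
        log.warning(w)
    if not rep.ok:
        raise ValidationError("; ".join(rep.errors))
    outputs = {}
    outputs.update(stage_fit_kinetics(out))
    outputs.update(stage_balance(out))
    outputs.update(stage_analyze(out))
    outputs.update(stage_report(out, plots=plots))

    cfg_digest = hashlib.sha256(
        json.dumps(asdict(config), sort_keys=True).encode()).hexdigest()
    manifest = RunManifest(
        seed=config.seed, config_digest=cfg_digest,
        input_digests={k: _digest(Path(v)) for k, v in inputs.items()},
        output_digests={k: _digest(Path(v)) for k, v in outputs.items()
                        if Path(v).suffix != ".png"})
    manifest.write(out / "manifest.json")
    return manifest
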