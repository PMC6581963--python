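"""Replicate-trial recovery of the three headline regression slopes.

Each replicate generates a fresh default-calibration synthetic trial,
runs the full estimation pipeline (washout fit -> pool volumes ->
balance derivation) and fits the three cow-adjusted regressions:

* rumen liquid volume on daily NDF intake (cannulated cows),
* apparent Mg absorption on daily NDF intake (all cows),
* apparent Mg absorption on *estimated* liquid volume (cannulated cows).

Used by the acceptance machinery and by the replication analysis script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import TrialConfig, default_calibration
from .simulate import generate_trial
from .kinetics import estimates_to_frame, fit_decay, summarize_kinetics
from .balance import derive_balance
from .inference import cow_adjusted_regression

SLOPE_NAMES = ("vol_liquid_per_ndfi", "mg_abs_per_ndfi", "mg_abs_per_vol")


def trial_slopes(config: TrialConfig) -> dict:
    """Fit one synthetic trial end to end; return the three slopes."""
    trial = generate_trial(config, default_calibration())
    liquid = [p for p in trial.profiles if p.phase == "liquid"]
    fit = fit_decay(liquid, "liquid", "linear")
    kin = estimates_to_frame(summarize_kinetics(fit, liquid))

    derived = derive_balance(trial.balance)
    mg = derived[derived["element"] == "Mg"]
    merged = kin.merge(
        mg[["cow_id", "diet", "ndf_intake_kg_d", "absorption_g_d"]],
        on=["cow_id", "diet"])

    r_vol = cow_adjusted_regression(merged["ndf_intake_kg_d"],
                                    merged["volume"], merged["cow_id"])
    r_abs_ndfi = cow_adjusted_regression(mg["ndf_intake_kg_d"],
                                         mg["absorption_g_d"], mg["cow_id"])
    r_abs_vol = cow_adjusted_regression(merged["volume"],
                                        merged["absorption_g_d"],
                                        merged["cow_id"])
    return {
        "vol_liquid_per_ndfi": r_vol,
        "mg_abs_per_ndfi": r_abs_ndfi,
        "mg_abs_per_vol": r_abs_vol,
    }


def replicate_slopes(n_reps: int, seed: int) -> pd.DataFrame:
    """Slopes from ``n_reps`` independently seeded replicate trials."""
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, 2**31 - 1, size=n_reps)
    rows = []
    for i, s in enumerate(rep_seeds):
        res = trial_slopes(TrialConfig(seed=int(s)))
        rows.append({"replicate": i,
                     **{k: r.slope for k, r in res.items()}})
    return pd.DataFrame(rows)
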