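# rumenkin

Rumen marker-dilution kinetics, mineral balance and crossover inference
for magnesium absorption studies in lactating dairy cows.

Hypomagnesaemia (grass tetany) in dairy cows is driven by poor ruminal
Mg absorption, classically attributed to dietary potassium.  Fibre
intake is a further, less studied antagonist: low-NDF herbage shrinks
the rumen liquid pool, and with it the absorptive contact between
dissolved Mg²⁺ and the rumen wall.  `rumenkin` implements the complete
quantitative toolchain such a trial needs — and, because per-cow data
from such trials are rarely published, a calibrated synthetic-trial
generator so every estimator can be validated against known ground
truth.

## The models

**Marker dilution (single pool).**  A pulse dose *D* of an indigestible
marker (Co-EDTA for the liquid phase, Yb-labelled NDF for the solid
phase) mixes into a rumen pool of size *V* and washes out.  For the
liquid phase the concentration follows

    C(t) = (D / V) · e^(−k t)

so `log C` is linear in time; the solid marker follows a log-quadratic
decay with negative curvature.  Fitting `log C ~ diet + diet:time
(+ diet:time²)` with a random intercept per animal (REML) yields, per
cow × diet:

* pool volume `V = D / C₀` with `C₀` the extrapolated zero-time
  concentration including the animal's random intercept,
* fractional passage rate `Kp` (/h) — the washout slope, taken for the
  quadratic solid model as the steepest descending tangent over the
  1–23 h sampling window,
* absolute passage rate `V · Kp` (l/h or kg DM/h).

**Mineral balance.**  From total collection: apparent absorption =
intake − faecal; absorbability = 100·absorption/intake; retention =
absorption − urine − milk; rumen Mg solubility = liquid-phase share of
the total rumen Mg pool (liquid mmol/l × 24.305 × Vol_L vs solid g/kg
DM × Vol_S).

**Inference.**  Crossover ANOVA `Y = μ + Diet + Period + Animal + ε`
with Tukey-adjusted contrasts, Friedman χ² on animal-blocked matrices
(with exact permutation p for small designs), Pearson correlations with
df, and cow-adjusted mixed regressions `y ~ x + (1|cow)` reporting the
Nakagawa–Schielzeth marginal R².

## Worked example

```sh
python analysis/01_simulate_trial.py      # write results/{profiles,balance,rumen}.csv
python analysis/02_fit_kinetics.py        # fit washout models
python analysis/03_mineral_balance.py     # derive the balance
python analysis/04_treatment_effects.py   # ANOVA, contrasts, regressions
```

The last step prints (seed 0, default calibration):

```
Cow-adjusted mixed regressions:
                    pair   slope     se  r2_marginal      r  df  p_pearson
         vol_liquid~ndfi 12.1691 0.8242       0.7673 0.8949  10     0.0001
mg_absorption~vol_liquid  0.1078 0.0081       0.8825 0.9536  10     0.0000
      mg_absorption~ndfi  1.3608 0.0465       0.7756 0.8952  16     0.0000

Rumen Mg solubility by diet (%, liquid share of rumen Mg):
Fibre+      29.0
Fibre+CP    20.2
Fibre-      49.6
```

Reading: each kilogram of daily NDF intake adds ≈ 12 l of rumen liquid
volume; each litre of liquid volume carries ≈ 0.11 g/day of Mg
absorption, so a cow moved from a high- to a low-fibre silage (≈ 3 kg/d
less NDFi) loses ≈ 4 g/day of absorbed Mg.  On the low-fibre diet half
of the rumen Mg sits in solution (49.6%) versus 20–29% on the high-fibre
diets — more soluble, yet less absorbed, because the liquid pool is a
quarter smaller.  The same commands accept any trial data in the
documented CSV schemas; `rumenkin run-all --seed 0 --out results` runs
the five stages as one pipeline with a reproducibility manifest.

## Layout

```
src/rumenkin/     config, simulate, lmm, kinetics, balance, inference,
                  pipeline, recovery, cli
analysis/         numbered narrative drivers (01_simulate … 05_recovery)
tests/            pytest suite incl. end-to-end acceptance checks
docs/methods.md   model details, calibration rationale, limitations
```
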