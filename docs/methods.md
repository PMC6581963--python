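# Methods

## Scope and design

`rumenkin` reconstructs, as tested code, the analysis chain of a 3×3
crossover marker-dilution and mineral-balance trial in six lactating
dairy cows (four ruminally cannulated): estimation of rumen pool sizes
and passage rates from pulse-dose marker washout curves, apparent
mineral balance, and the statistical layer connecting NDF intake, rumen
liquid volume and Mg absorption.  Because individual-cow data from such
trials are not deposited, the package is organised around a
synthetic-trial generator whose defaults encode the trial's published
treatment effects; all validation is parameter recovery against that
known truth plus exact oracles for the statistical machinery.

## Marker kinetics

Single-pool dilution.  The liquid marker (Co-EDTA; elemental Co taken
as 14.5% of the 50 g dose, i.e. 7.25 g) follows
`log C(t) = log(D/V) − k t`; the solid marker (Yb-NDF; elemental Yb
taken as 3% of the 200 g dose — a typical labelling load, the trial
does not state it) follows `log C(t) = log(D/V) + b t + c t²` with
`c ≤ 0`, reflecting incomplete early mixing of labelled fibre.
Sampling is the trial's schedule: a pre-dose background sample at 0 h
(assumed marker-free and never fitted) and 1, 2, 3, 5, 7, 10, 16, 23 h.

The decay model is fitted by REML to all cannulated cows at once:
`log C ~ diet + diet:time (+ diet:time²) + (1 | animal)`.  Random
slopes are deliberately absent — with four animals they are not
reliably identifiable.  Derived quantities:

* **Volume** `V = D / exp(a_diet + u_animal)` — the animal's BLUP is
  included in the extrapolated zero-time concentration, so volumes are
  cow-specific (a diet-level variant is available).
* **Fractional Kp**: the negated slope (liquid), or for the quadratic
  solid model the *maximal* descending tangent `max −(b + 2 c t)` over
  the observed 1–23 h window, attained at 23 h when `c < 0`.  This is
  the terminal-slope convention for passage rates; the tangent at the
  window start is available via `convention="initial"`.
* **Absolute Kp** `= V × Kp`, an exact product identity by
  construction, in l/h (liquid) or kg DM/h (solid).

## The mixed-model core

All mixed fits use a purpose-built profiled-REML solver for the single
random-intercept model (`lmm.py`).  With `V = I + λ ZZ'`, every
quantity is closed-form per animal via the Woodbury identity, and the
fit reduces to a deterministic one-dimensional search over `log λ`
(coarse grid, then bounded refinement; the `λ = 0` boundary is always
compared explicitly).  This design makes the boundary cases exact
rather than approximately converged:

* perfectly noiseless data short-circuits to exact OLS (threshold:
  residual variance below 1e−28, absolute, so tiny real noise is still
  fitted);
* `λ` forced to 0 *is* pooled OLS to machine precision;
* zero-residual data with true animal effects drives `λ` to its upper
  bound (1e8), recovering the within-animal estimator with shrinkage
  error ~1/(λn);
* the generalized RSS is accumulated from residuals group by group —
  the textbook `y'V⁻¹y − β'X'V⁻¹y` form loses ~16 digits to
  cancellation on near-perfect fits.

Wald tests use the REML coefficient covariance with denominator df
`n_obs − n_fixed` (residual approximation).  The statsmodels MixedLM
implementation serves as an independent cross-check in the test suite,
never as the implementation.

## Crossover inference

The balance ANOVA is `Y = μ + Diet + Period + Animal + ε` with Animal
as a random intercept (a fixed-block variant is available; for the
balanced design the F statistics coincide).  F statistics for Diet and
Period are computed by Type III residual-sum-of-squares projection of
the blocked least-squares fit — for balanced crossovers this equals the
mixed-model Wald F exactly and is reproducible to machine precision —
while the REML fit supplies the animal variance component and lsmean
standard errors.  Pairwise diet contrasts use the Tukey–Kramer
studentized-range adjustment with the blocked residual mean square and
its df (8, for 6 cows × 3 periods); diet contrasts are within-animal,
so the animal variance cancels from their SE.

The Friedman statistic uses midranks and
`χ² = 12/(nk(k+1)) ΣR_j² − 3n(k+1)`, df `k−1`.  For small designs
(`n·k ≤ 20`, e.g. the 4-animal × 3-diet absolute-Kp test) the p-value
defaults to full enumeration of all `(k!)ⁿ` within-block rank
arrangements rather than the χ² approximation, which is visibly coarse
at n = 4.

Cow-adjusted regressions are `y ~ x + (1 | cow)` by REML.  Marginal R²
follows Nakagawa–Schielzeth:
`var(Xβ) / (var(Xβ) + σ²_animal + σ²_resid)` with the fixed-effect
variance taken as the population variance of the fixed-part fitted
values.  With REML residual variance in the denominator this equals the
OLS R² in the no-random-variance limit only up to the `n/(n−2)` scaling
of the residual variance — a negligible and documented discrepancy.
Two-sided tests throughout; significance at P ≤ 0.05, trends at
P < 0.10.

## Synthetic-trial generator

**Design.**  Two stacked cyclic 3×3 Latin squares (the second reversed)
with seed-randomized cow order guarantee balance: each cow gets each
diet once, each diet appears twice per period.  Body weight is
Normal(697, 61) kg truncated at ±3 SD; four of six cows are cannulated.

**Calibration.**  Diet-level means encode the published treatment
effects: silage NDF 341 vs 572 g/kg DM (diet-level 340/495/510 after
concentrate dilution); dietary Mg at the marginal 2.3 g/kg DM and K
near 27 g/kg DM; liquid volume responding as `Vol_L = 28 + 11.8 ×
NDFi` litres (≈24% smaller on the low-fibre diet, 16–21% of BW);
solid pool 7.0/11.0/11.5 kg DM (≈40% smaller on low fibre); fractional
Kp_L 0.115/0.105/0.104 /h (+10% numerically on low fibre); rumen pH
5.95/6.55/6.61; liquid Mg 3.6/1.2/1.45 mmol/l (tripled on low fibre);
urinary Mg 2.07/4.38/5.88 mmol/l.  Values the trial did not print
(DMI, milk yield, urine volume, water intake, solid-pool size, Kp
levels, concentrate NDF) are plausible dairy values consistent with the
published orderings and percentage contrasts; `truth.json` flags them
as placeholders.

**The Mg-absorption link.**  Absorption is generated as
`a + b · Vol_L + cow effect + noise`.  The published slopes are
mutually inconsistent as a deterministic chain: 0.10 g/d per l × 11.8
l/kg = 1.18, not the published 1.32 g/d per kg NDFi (each was estimated
on different subsets of noisy data).  The generator sets
`b = 1.32/11.8 = 0.1119` g/day per l — inside the published 0.10 ±
0.02 band — which makes all three published slopes simultaneous
estimands of the pipeline.  This is a calibration choice, fixed before
any validation was run.

**Noise structure.**  Log-concentration residuals SD 0.05 (assay plus
rumen-sampling heterogeneity); balance-scale CV 0.04 around diet means;
per-animal random intercepts SD 0.06 (log scale for kinetics — the
animal effect is folded into its effective volume, so the recorded
truth is what dilution can measure — and relative scale for balance
variables).  DM intake is diet mean × (1 + cow effect) + period noise;
NDFi, liquid volume and Mg absorption all respond to the *realized*
intake, so the covariates carried in `balance.csv` are the exact ones
the generative regressions used.  Faecal excretion closes every balance
exactly (faecal = intake − absorption); negative draws are resampled up
to 100 times, then rejected, avoiding silent truncation bias.  The
realized intake table is generated in its own seeded stream, so marker
curves and balance records always share identical covariates even when
generated by separate calls.

**What the generator does not emulate:** hourly intake patterns, marker
assay censoring near detection limits, period-by-diet carryover,
endogenous faecal Mg secretion, per-record variation in fractional Kp
(random washout slopes are off by default, so the water-intake–Kp_L
association enters only through diet-level co-calibration), and any
within-day kinetics of rumen chemistry (one chemistry record per
cow × period).  Passing recovery tests therefore demonstrate correctness
of the estimators under the stated model, not robustness to these
real-data features.

## Replicate recovery and problem sizes

The headline validation (`scripts/acceptance.py`,
`analysis/05_slope_recovery.py`) simulates 200 replicate trials at the
default calibration, fits each end to end and compares the mean fitted
slopes of Vol_L ~ NDFi (4 cows), Mg absorption ~ NDFi (6 cows) and
Mg absorption ~ estimated Vol_L (4 cows) against the calibrated
references.  The replicate SD is the Monte-Carlo estimate of a single
trial's slope SE — the same quantity the trial prints as ±SE.  Two
small, known biases remain by construction and are visible in the
recovered means: diet-level decay intercepts cannot capture
within-diet intake variation (≈4% attenuation of the Vol_L ~ NDFi
slope) and regression on the *estimated* volume carries its estimation
error (slight attenuation of the absorption ~ Vol_L slope).  Both are
well inside the Monte-Carlo spread.  The crossover ANOVA's type-I
error is checked over 1000 null simulations (expected 0.05, accepted
0.03–0.07).

## Numerical conventions

Profiles are sorted by (cow, period, time) before fitting, so results
are independent of input order.  Concentrations must be strictly
positive for t > 0; t = 0 rows are never fitted.  Units are carried
explicitly (`g_per_l` vs `g_per_kg_dm`; litres vs kg DM), and mixing
phases is rejected.  CSV dialect: comma-separated, UTF-8, '.' decimal,
header required.  Exit codes distinguish validation failures (2) from
runtime errors (1).  Atomic masses: Mg 24.305, K 39.098, Na 22.990
g/mol.
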