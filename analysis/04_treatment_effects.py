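"""Crossover ANOVA, Tukey contrasts and the headline regressions.

Runs the inference stage on results/: per-element crossover ANOVAs with
Tukey-adjusted diet contrasts, the three cow-adjusted regressions
(Vol_L ~ NDFi, Mg absorption ~ Vol_L, Mg absorption ~ NDFi) and the
rumen Mg solubility table.  Writes tests.csv, regressions.csv and
solubility.csv; prints the significant effects.
"""

import argparse
from pathlib import Path

import pandas as pd

from rumenkin.pipeline import stage_analyze


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    paths = stage_analyze(args.out)
    tests = pd.read_csv(paths["tests"])
    diet_f = tests[(tests.test == "wald_f") & (tests.effect == "Diet")]
    sig = diet_f[diet_f.p_raw <= 0.05]
    print("Diet effects significant at P <= 0.05 (crossover ANOVA):")
    print(sig[["response", "statistic", "df1", "df2", "p_raw"]]
          .round(4).to_string(index=False))

    regr = pd.read_csv(paths["regressions"])
    print("\nCow-adjusted mixed regressions:")
    print(regr[["pair", "slope", "se", "r2_marginal", "r", "df",
                "p_pearson"]].round(4).to_string(index=False))

    sol = pd.read_csv(paths["solubility"])
    print("\nRumen Mg solubility by diet (%, liquid share of rumen Mg):")
    print(sol.groupby("diet")["mg_solubility_pct"].mean().round(1))


if __name__ == "__main__":
    main()
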