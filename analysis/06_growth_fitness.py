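#!/usr/bin/env python
"""Fitness cost and phenotypic variance of carrying the suppressor.

Liquid phase: six-replicate microculture curves per strain and plasmid arm
(suppressor vs empty control), fit by max log-slope; the suppressor arm is
simulated with a 22.8% lower rate in a sensitive background and no effect
in a tolerant one.  Solid phase: colony-size grids across 11 stress
conditions normalised to rich medium, with planted strain-by-condition
effects; reports percent variation (flagged at >= 10%) and compares
phenotypic variance across strains per condition (F-test and
Brown-Forsythe).
"""

from pathlib import Path

import numpy as np
import pandas as pd

from yeastdmi.growth import (
    fit_growth_rate,
    growth_variation,
    suppressor_effect,
    variance_comparison,
)
from yeastdmi.io import write_table
from yeastdmi.simcross import simulate_colony_sizes, simulate_growth_curve

SEED = 20260928
OUT = Path(__file__).resolve().parent.parent / "results"

TIMES = np.arange(0, 48.01, 1 / 6)  # 10-min reads for 48 h
# per-strain control rate and suppressor-arm rate (per hour)
LIQUID = {
    "sensitive_1": (0.50, 0.50 * (1 - 0.228)),
    "sensitive_2": (0.45, 0.45 / 2.53),
    "tolerant_1": (0.40, 0.41),
}
CONDITIONS = [f"stress{i:02d}" for i in range(1, 12)]


def liquid_phase(rng) -> pd.DataFrame:
    rows = []
    for strain, (r_ctrl, r_sup) in LIQUID.items():
        rates = {}
        for plasmid, rate in (("Ctrl", r_ctrl), ("SUP", r_sup)):
            rates[plasmid] = [
                fit_growth_rate(
                    simulate_growth_curve(rate, 2.0, 1.2, 0.005, TIMES, rng)
                )
                for _ in range(6)
            ]
        comp = growth_variation(rates["SUP"], rates["Ctrl"], strain=strain,
                                condition="rich_medium")
        rows.append(vars(comp))
        print(f"  {strain}: {comp.percent_variation:+.1f}% growth-rate "
              f"variation (t-test p = {comp.p_t:.2g}, N = {comp.n})")
    return pd.DataFrame(rows)


def solid_phase(rng) -> pd.DataFrame:
    strains = [f"iso{i:02d}" for i in range(8)]
    effects = {}
    for i, strain in enumerate(strains):
        for j, cond in enumerate(CONDITIONS):
            # strain- and condition-specific effects, stronger variance in
            # half the conditions; tolerant strains gain fitness
            base = 0.15 if j % 2 else 0.02
            sign = 1 if (i + j) % 3 else -1
            effects[(strain, cond)] = sign * base * rng.uniform(0.5, 1.5)
    colonies = simulate_colony_sizes(strains, CONDITIONS, effects,
                                     noise_cv=0.05, seed=int(rng.integers(2**31)))
    comparisons = suppressor_effect(colonies)
    flagged = comparisons[comparisons.flagged]
    print(f"  {len(flagged)}/{len(comparisons)} strain x condition cases with "
          f">= 10% normalised-growth variation")

    # phenotypic variance across strains: per condition, compare the spread
    # of per-strain mean normalised ratios between the two plasmid arms
    ref = colonies[colonies.condition == "YPD"].set_index(
        ["strain", "plasmid", "replicate"]
    )["colony_size"]
    test = colonies[colonies.condition != "YPD"].copy()
    keys = list(zip(test.strain, test.plasmid, test.replicate))
    test["ratio"] = test.colony_size.to_numpy() / ref.loc[keys].to_numpy()
    strain_means = (test.groupby(["condition", "plasmid", "strain"])["ratio"]
                    .mean().reset_index())
    var_rows = []
    for cond, grp in strain_means.groupby("condition"):
        sup = grp[grp.plasmid == "SUP"].ratio.to_numpy()
        ctrl = grp[grp.plasmid == "Ctrl"].ratio.to_numpy()
        p_f, p_lev = variance_comparison(sup, ctrl)
        var_rows.append((cond, sup.var(ddof=1), ctrl.var(ddof=1), p_f, p_lev))
    var_df = pd.DataFrame(var_rows, columns=["condition", "var_sup",
                                             "var_ctrl", "p_F", "p_levene"])
    n_sig = int((var_df.p_F < 0.05).sum())
    print(f"  conditions with significantly different variance across "
          f"strains (F-test p < 0.05): {n_sig}/{len(var_df)}")
    return comparisons, var_df


def main():
    rng = np.random.default_rng(SEED)
    print("liquid microcultures (suppressor vs control, 6 replicates):")
    liquid = liquid_phase(rng)
    meta = {"seed": SEED, "script": "06_growth_fitness"}
    write_table(liquid, OUT / "growth_comparisons.tsv", meta=meta)

    print("solid-plate phenotyping across stress conditions:")
    comparisons, var_df = solid_phase(rng)
    write_table(comparisons, OUT / "suppressor_effect.tsv", meta=meta)
    write_table(var_df, OUT / "variance_by_condition.tsv", meta=meta)
    print(f"wrote growth_comparisons.tsv, suppressor_effect.tsv, "
          f"variance_by_condition.tsv to {OUT}")


if __name__ == "__main__":
    main()
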