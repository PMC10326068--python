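#!/usr/bin/env python
"""Decision-complex (BFC) lifetimes with and without twinfilin.

Simulates two cohorts of formin+CP-bound barbed ends released into flow at
t = 0 — a control and one with 20 nM twinfilin — then fits the survival
fraction, attaches bootstrap confidence intervals, and decomposes the total
dissociation rate into its CP-loss (to BF) and formin-loss (to BC) routes.
Writes results/decision_complex.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from bek import RateSet, fold_change
from bek.experiments import run_bfc_cohort

CONDITIONS = {
    # cohort sizes follow the two single-molecule datasets (110 control,
    # 57 complexes at 20 nM twinfilin)
    "control": {"conc_T": 0.0, "n": 110},
    "twinfilin_20nM": {"conc_T": 0.02, "n": 57},
}


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=20230706)
    parser.add_argument("--out", type=Path, default=Path("results/decision_complex.csv"))
    args = parser.parse_args()

    rows = []
    fits = {}
    for i, (name, cond) in enumerate(CONDITIONS.items()):
        rates = RateSet(conc_T=cond["conc_T"])
        res = run_bfc_cohort(rates, cond["n"], window=1500.0, seed=args.seed + i,
                             bootstrap_reps=1000)
        fits[name] = res
        d = res.decomposition
        rows.append({
            "condition": name,
            "n_filaments": cond["n"],
            "k_bfc_per_s": res.fit.rate,
            "ci65_low": res.fit.ci_low,
            "ci65_high": res.fit.ci_high,
            "mean_lifetime_s": 1.0 / res.fit.rate,
            "kprime_minus_C_per_s": d.kprime_minus_C,
            "kprime_minus_F_per_s": d.kprime_minus_F,
            "pct_to_BF": 100 * res.bf_route_fraction,
        })
        print(f"{name}: k_-BFC = {res.fit.rate:.3g} /s "
              f"(65% CI {res.fit.ci_low:.3g}-{res.fit.ci_high:.3g}), "
              f"mean lifetime {1/res.fit.rate:.0f} s, "
              f"{100*res.bf_route_fraction:.0f}% of complexes resolved to BF")

    fold = fold_change(fits["twinfilin_20nM"].fit.rate, fits["control"].fit.rate)
    print(f"20 nM twinfilin accelerates decision-complex dissociation "
          f"{fold:.1f}-fold and shifts resolution toward the elongating BF state.")

    args.out.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(args.out, index=False)
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
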