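#!/usr/bin/env python
"""Subgroup-level comparisons.

Applies each subgroup's exacerbation rate ratio to the shared placebo-arm
rate and reports the per-subgroup increments and ICER / dominance calls.
"""

from pathlib import Path

import pandas as pd

from asthma_cea.analyses import run_subgroups
from asthma_cea.parameters import load_parameters

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    params = load_parameters(OUT / "parameters.yaml")
    rows = []
    for sg, r in run_subgroups(params):
        rows.append({
            "subgroup": sg.name, "rr": sg.rr,
            "ci_low": sg.rr_ci[0], "ci_high": sg.rr_ci[1],
            "delta_cost": r.delta_cost, "delta_qaly": r.delta_qaly,
            "icer": r.icer, "classification": r.classification,
        })
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "subgroups.csv", index=False)

    print(df.to_string(index=False, float_format=lambda v: f"{v:,.3f}"))
    icers = df.loc[df.classification == "icer", "icer"]
    if len(icers):
        print(f"\nICER span across non-dominant subgroups: "
              f"${icers.min():,.2f} to ${icers.max():,.2f} per QALY")
    n_dom = (df.classification == "dominant").sum()
    print(f"dominant subgroups: {n_dom} of {len(df)}")


if __name__ == "__main__":
    main()
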