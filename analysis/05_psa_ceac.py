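#!/usr/bin/env python
"""Probabilistic sensitivity analysis and acceptability curve.

Draws all uncertain parameters from their assigned distributions (gamma for
costs and rates, beta for the utility, lognormal for the rate ratio), runs
the model per draw, and summarises the incremental cost/QALY cloud as a
cost-effectiveness acceptability curve.  The default 1,000 iterations keep
the driver quick; pass a first argument to change it (the published-scale
analysis would use 10,000).
"""

import sys
from pathlib import Path

import numpy as np

from asthma_cea.analyses import ceac, ceac_frame, default_wtp_grid, run_psa
from asthma_cea.parameters import load_parameters

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    n = int(sys.argv[1]) if len(sys.argv) > 1 else 1000
    seed = int(sys.argv[2]) if len(sys.argv) > 2 else 1
    params = load_parameters(OUT / "parameters.yaml")

    psa = run_psa(params, n=n, seed=seed)
    psa.to_frame().to_csv(OUT / "psa_scatter.csv", index=False)

    grid = default_wtp_grid()
    points = ceac(psa, grid)
    ceac_frame(points).to_csv(OUT / "ceac.csv", index=False)

    print(f"{n} Monte-Carlo iterations (seed {seed})")
    print(f"mean dC ${psa.delta_cost.mean():,.2f}, "
          f"mean dE {psa.delta_qaly.mean():.5f} QALYs")
    for wtp in (params.settings.wtp_lower, params.settings.wtp_upper):
        prob = float(np.mean(wtp * psa.delta_qaly - psa.delta_cost > 0))
        print(f"P(cost-effective) at WTP ${wtp:,.0f}: {prob:.1%}")
    above90 = [pt.wtp for pt in points if pt.prob_cost_effective >= 0.90]
    if above90:
        print(f"acceptability first reaches 90% at WTP ${min(above90):,.0f}")


if __name__ == "__main__":
    main()
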