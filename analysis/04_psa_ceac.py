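#!/usr/bin/env python
"""Probabilistic sensitivity analysis and acceptability curves.

Samples all model inputs jointly (beta utilities, gamma costs, Dirichlet
next-line shares, lognormal survival parameters; 10,000 draws) for the
Dutch and Danish scenarios, writes the incremental draws and the CEAC,
and prints the probability of cost-effectiveness at each country's
willingness-to-pay threshold.

Writes results/psa_<scenario>.csv and results/ceac_<scenario>.csv.
Pass --n to trade precision for speed (default 10,000).
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from tilcua.config import load_scenario, packaged_scenario_path
from tilcua.sensitivity import ceac, run_psa

HERE = Path(__file__).resolve().parent.parent
OUT = HERE / "results"

WTP_GRID = np.arange(0, 210_000, 10_000, dtype=float)


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--n", type=int, default=10_000)
    parser.add_argument("--seed", type=int, default=20240326)
    args = parser.parse_args()

    OUT.mkdir(exist_ok=True)
    for name in ("nl_base_case", "dk_scenario"):
        scenario, arms = load_scenario(packaged_scenario_path(name))
        res = run_psa(scenario, arms, n=args.n, seed=args.seed)
        res.draws.to_csv(OUT / f"psa_{name}.csv")
        curve = ceac(res, WTP_GRID)
        pd.DataFrame({"wtp": curve.wtp, "probability": curve.probability}) \
            .to_csv(OUT / f"ceac_{name}.csv", index=False)
        p_at_wtp = ceac(res, [scenario.wtp_threshold]).probability[0]
        se = np.sqrt(p_at_wtp * (1 - p_at_wtp) / args.n)
        print(f"{scenario.country_label}: base-case dCost="
              f"{res.base_delta_cost:,.0f} dQALY={res.base_delta_qaly:.3f}; "
              f"P(cost-effective at {scenario.wtp_threshold:,.0f}/QALY) = "
              f"{p_at_wtp:.3f} (MC se {se:.3f}, n={args.n})")
    print(
        "\nThe probability sits well below the published >=99% because, with"
        "\nmain-text inputs only, the base case is not cost-saving: draws are"
        "\njudged on the QALY gain against an extra cost, and survival-"
        "\nparameter uncertainty (10% CV) moves the QALY gain a lot."
    )


if __name__ == "__main__":
    main()
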