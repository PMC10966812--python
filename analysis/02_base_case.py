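#!/usr/bin/env python
"""Run the Dutch base case and the Danish scenario over all horizons.

Builds the cohort model from each shipped scenario file and reports
per-arm life years, QALYs and costs (discounted and undiscounted; 5-year,
10-year and lifetime horizons) with the incremental column and the
ICER/dominance line.

Writes results/base_case_<country>.csv (full precision) and a rounded
JSON rendering alongside.
"""

import json
from pathlib import Path

import pandas as pd

from tilcua.config import load_scenario, packaged_scenario_path
from tilcua.reporting import render_summary, summary_table

HERE = Path(__file__).resolve().parent.parent
OUT = HERE / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    pd.set_option("display.width", 220)
    for name in ("nl_base_case", "dk_scenario"):
        scenario, arms = load_scenario(packaged_scenario_path(name))
        table = summary_table(scenario, arms)
        table.to_csv(OUT / f"base_case_{name}.csv", index=False)
        rendered = render_summary(table)
        (OUT / f"base_case_{name}.json").write_text(
            json.dumps(rendered.to_dict(orient="records"), indent=2, default=str))
        print(f"\n=== {scenario.country_label} "
              f"(costs {scenario.discount_rate_costs:.1%}, "
              f"effects {scenario.discount_rate_effects:.1%}, "
              f"WTP {scenario.wtp_threshold:,.0f}/QALY) ===")
        cols = ["horizon_years", "discounted", "ly_incremental",
                "qaly_incremental", "cost_incremental", "icer", "classification"]
        print(rendered[cols].to_string(index=False))
    print(
        "\nWith the published main-text inputs the intervention gains QALYs at"
        "\nextra cost (NE quadrant, lifetime ICER around EUR 33,000/QALY, below"
        "\nboth country thresholds). The published tables additionally include"
        "\nsupplementary per-cycle disease-management costs, which is where the"
        "\npublished cost-saving (dominant) result comes from."
    )


if __name__ == "__main__":
    main()
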