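# tilcua — cost-utility model of TIL therapy vs ipilimumab in advanced melanoma

`tilcua` implements a trial-based cost-utility analysis of adoptive cell
therapy with tumor-infiltrating lymphocytes (TIL) against ipilimumab in
patients with unresectable stage IIIC–IV melanoma after first/second-line
treatment failure. It is written for health-economics modellers who want
the whole pipeline — parametric survival extrapolation, cohort model,
incremental cost-effectiveness reporting, and deterministic/probabilistic
sensitivity analysis — as tested, scriptable Python instead of a
spreadsheet.

## The model

Three mutually exclusive health states — progression-free (PFS),
progressive disease (PD), dead — on a 3-month cycle over a lifetime
horizon (cut off at age 100 or 99.9% cumulative mortality). State
occupancy is read directly off two parametric survival curves
(partitioned survival):

    PFS(t) = S_PFS(t),   dead(t) = 1 − S_OS(t),   PD(t) = S_OS(t) − S_PFS(t)

Both curves are log-logistic, S(t) = 1 / (1 + (t/α)^β), fitted to the
published modelled survival probabilities at months 3–12 by least squares
of logit S on log t (the transform is exactly linear, so α̂ and β̂ are
closed form). Each cycle accumulates:

* life years: alive occupancy × 0.25 y,
* QALYs: utility-weighted person-time (EQ-5D-based PFS utilities per
  visit, an expected next-line utility in PD, 0.665 for the cycle of
  death),
* costs: one-time treatment bundles, recurring follow-up and societal
  items, an expected next-line course cost at PD entry, and a death cost,

each discounted at country-specific annual rates (NL: 4% costs / 1.5%
effects; DK: 3.5% / 3.5%). Arms are compared by the incremental
cost-effectiveness ratio ICER = ΔCost/ΔQALY with dominance
classification, and by net monetary benefit NMB = WTP × ΔQALY − ΔCost.
One-way sensitivity analysis ranks parameters by NMB span; the
probabilistic analysis samples all inputs jointly (beta utilities, gamma
costs, Dirichlet next-line shares, lognormal survival parameters) and
summarises the draws as a cost-effectiveness acceptability curve.

Because patient-level trial data are available only on request, the
`tilcua.simulate` module generates synthetic individual-patient PFS/OS
times (inverse-CDF from the fitted laws, OS ≥ PFS by construction,
administrative censoring) and EQ-5D-style visit utilities, so the fitting
and engine stages are testable end to end.

## Worked example

```python
from tilcua import load_scenario, summary_table
from tilcua.config import packaged_scenario_path
from tilcua.reporting import render_summary

scenario, arms = load_scenario(packaged_scenario_path("nl_base_case"))
table = render_summary(summary_table(scenario, arms))
print(table[table["horizon_years"] == float("inf")]
      [["discounted", "qaly_incremental", "cost_incremental", "icer"]])
```

prints (lifetime horizon, Dutch base case):

```
 discounted  qaly_incremental  cost_incremental     icer
      False              1.35           38363.0  28497.0
       True              1.13           37057.0  32859.0
```

Read: over a lifetime, TIL therapy yields 1.13 discounted QALYs more than
ipilimumab at €37,057 extra cost — an ICER of €32,859 per QALY, well
below the Dutch €80,000 willingness-to-pay threshold. With the published
main-text inputs the model lands in the north-east quadrant
(cost-effective but not cost-saving); the published dominant result
additionally rests on supplementary per-cycle disease-management costs
that are not publicly available (see `docs/methods.md`).

The same pipeline is available from a shell:

```
cua run --scenario src/tilcua/data/nl_base_case.yaml --out out/
cua fit-survival points.csv --family loglogistic
cua dsa --scenario src/tilcua/data/nl_base_case.yaml
cua psa --scenario src/tilcua/data/nl_base_case.yaml --n 10000 --seed 1
cua simulate --scenario src/tilcua/data/nl_base_case.yaml --n-per-arm 100 --seed 1 --out out/
```

The numbered scripts under `analysis/` run the full study narrative
(survival fits → base case → tornado → PSA/CEAC → synthetic-data
validation) and write their tables under `results/`.

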