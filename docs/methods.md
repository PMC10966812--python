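# Methods

## Decision problem and model structure

The package evaluates second-line treatment of unresectable stage
IIIC–IV melanoma: adoptive TIL cell therapy versus ipilimumab. A cohort
moves through three mutually exclusive states — progression-free (PFS),
progressive disease (PD), dead — on a 3-month cycle (0.25 years) from
treatment start until the earlier of the cohort reaching age 100 or
99.9% cumulative mortality. All patients start progression-free.

Occupancy is constructed by partitioned survival rather than an explicit
transition matrix: at each cycle start t, PFS occupancy is S_PFS(t), the
dead state is 1 − S_OS(t), and PD is the difference. This construction is
uniquely determined by the two published curves, which is why it is the
default; no transition probabilities are published. If the fitted curves
cross (S_PFS > S_OS, possible under extrapolation), PD is clamped at zero
and PFS reduced to S_OS — the death state always follows the OS curve —
and the clamped mass is reported on the trace.

## Survival inputs and extrapolation

The published model inputs include modelled PFS and OS probabilities at
months 3, 6, 9 and 12 per arm. Fitting a two-parameter log-logistic,
S(t) = 1/(1 + (t/α)^β), to these points by least squares of
logit S on log t reproduces them almost exactly (SSE ≤ 1e-6 on the
probability scale), and a fit to months 3–9 alone extrapolates to the
printed month-12 PFS values exactly at 3 decimals (0.395 TIL, 0.072
ipilimumab) — the published rows are evaluations of log-logistic curves,
and those fitted parameters are what the shipped scenarios use:

| curve | α (months) | β |
|---|---|---|
| TIL PFS | 8.584 | 1.272 |
| TIL OS | 26.802 | 1.274 |
| ipilimumab PFS | 3.841 | 2.243 |
| ipilimumab OS | 20.496 | 1.395 |

Five families are implemented (exponential, Weibull, Gompertz,
log-normal, log-logistic). Point fits use exact linearisations where they
exist (logit, complementary log-log, probit), a through-origin regression
for the exponential, and numeric least squares for the Gompertz (started
at the interpolated median-crossing time with shape 1). Censored
individual-patient fits are maximum likelihood (via lifelines, except the
hand-written Gompertz likelihood) and populate log-likelihood, AIC
(−2ℓ + 2k), BIC (with log n) and the (α, β) covariance; model selection
ranks by AIC with BIC as tie-break, plus a fitted-vs-observed table for
visual inspection. Point fits carry an SSE instead and deliberately no
parameter covariance: a regression through four near-noiseless
model-generated points measures interpolation error, not sampling
uncertainty.

The log-logistic fits here have heavy tails (β ≈ 1.3 on OS), so lifetime
undiscounted life expectancy under the shipped curves (5.28 y TIL, 3.85 y
ipilimumab) exceeds the published 4.47/3.33 — the publication's own fits
were to patient-level data with unpublished parameters. Absolute lifetime
totals therefore depend on the extrapolation; incremental *signs* and the
within-trial-window values do not.

## Accounting conventions

Trace rows are cycle-start states; each row discounts at its start time,
(1 + r)^(−t), with separate annual rates for costs and effects; r = 0
reproduces undiscounted totals. No half-cycle correction is applied (the
source model does not state one); the cycle-start convention slightly
overstates person-time symmetrically in both arms. Events during the
3-month interval that starts at a row attach to that row: deaths there
receive the pre-death utility (0.665) and the death cost (€1,516), and
deaths are allocated to PFS/PD proportionally to cycle-start occupancy
(this allocation only affects the split of utility weights and the timing
of PD-entry costs, not occupancy itself).

QALYs per cycle: (continuing PFS mass × PFS utility at the cycle-start
month) + (continuing PD mass × expected next-line utility) + (dying mass
× 0.665), all × 0.25 y. PFS utilities are a step series at the visit
months (0–12); the month-12 value carries forward for later cycles, since
later visit values are not published. With all utilities ≤ 1, QALYs never
exceed life years.

Costs per cycle: one-time treatment items and first-cycle amounts fall at
t = 0; ">first cycle" recurring amounts scale with alive occupancy from
the second cycle on; annual amounts (copay) accrue at a quarter per
cycle. Follow-up (treatment-bundle) recurring items stop at 5 years,
when progression-free patients count as cured; societal items do not
stop. Next-line treatment costs enter as the mixture-expected course cost
(€46,867 TIL arm, €36,276 ipilimumab arm) applied **once at PD entry** —
the published values are per-patient course totals. Because the source's
footnote says some regimens run "per model cycle until progression or
death", a `pd_cost_mode: per_cycle` flag applies the expected cost each
PD cycle instead; it is off in the shipped scenarios (turning it on makes
the intervention's net monetary benefit negative and moves the model
further from the published result). A per-cycle ledger itemises
treatment, follow-up, next-line, death and societal costs; column sums
equal the reported totals exactly, and an independent naive per-cycle
loop in the test suite reproduces all accumulators to 1e-9.

Monetary values are floats (inputs have at most 2 decimals); rendering
rounds (QA)LYs to 2 decimals and euros to whole units, half-up, *after*
differencing, so incremental columns always equal differences of the
per-arm columns.

## Scenarios

`nl_base_case.yaml` carries the published Dutch inputs: the €117,940 TIL
treatment bundle (screening 3,822 + TIL isolation 2,043 + production
67,547 + admission/follow-up 44,528), the €77,823 ipilimumab bundle,
next-line mixtures with their proportions and utilities, societal costs
(first-cycle vs later-cycle amounts plus €385/year copay), 4%/1.5%
discounting and the €80,000/QALY threshold. Two inputs are not published
and are documented placeholders: the baseline cohort age (59, used only
by the age-100 cutoff, which never binds before the 99.9% mortality
cutoff matters) and the utility of the ipilimumab+pembrolizumab component
of the TIL arm's "other" next-line category (set to the mean of its
components' published utilities, giving 0.734 for the category).
`dk_scenario.yaml` is the Danish scenario: 3.5%/3.5% discounting,
€50,000/QALY threshold, 75.4-day friction period, and — because the
Danish unit costs live in unavailable supplementary material — the Dutch
cost values as explicit placeholders. The friction period is provenance
metadata only; productivity losses enter as already-computed euro
amounts.

## Sensitivity analysis

Ranges default to ±20% of base (clipped to each parameter's domain; a
95% CI can be given instead). The one-way analysis re-evaluates the model
at each bound and ranks by NMB span at the scenario threshold — NMB
because the raw ICER is unstable across the dominance boundary; both are
reported. Next-line proportions are excluded from one-way variation (a
simplex coordinate cannot move alone) and handled probabilistically.

The probabilistic analysis samples all parameters jointly, n = 10,000 by
default, with conventional HTA families: utilities ~ beta matched to mean
and range-implied variance ((high − low) treated as a 95% interval, so
sd = (high − low)/3.92; rescaled onto [−0.59, 1] if a range dips below
zero); costs ~ gamma with the same moment matching; each arm's next-line
proportions ~ Dirichlet with effective sample size 84 (the per-arm trial
size); survival α and β ~ independent mean-preserving lognormals whose
±20% range implies a ~10% CV (point fits provide no covariance to do
better). The CEAC reports, per willingness-to-pay value, the fraction of
draws with strictly positive NMB (ties count as not cost-effective; at
infinite WTP the curve tends to the fraction of draws with ΔQALY > 0).

## Synthetic patient-level data

`simulate_ipd` draws progression times by inverse CDF from the PFS law
and overall survival from the OS law conditioned on exceeding the
progression time (inverse CDF on S_OS(t)/S_OS(t_prog)). This guarantees
OS ≥ PFS for every patient exactly and keeps the marginal OS close to the
target law; it is exact at t ≤ t_prog and slightly light-tailed beyond,
an approximation the tests bound (KM vs curve within 0.02 at n = 5,000).
Administrative censoring truncates both endpoints at a common cut-off;
the real trial's accrual pattern is not reconstructible and is not
modelled. `simulate_eq5d` emits utility records at the 3-month visits
while progression-free only (measurement stops at progression, as per the
trial protocol), adds Gaussian noise clipped to the EQ-5D range
[−0.59, 1] (a beta error model would avoid the boundary mass; at the
default sd = 0.05 around ~0.87 the difference is negligible), and flags
completely-at-random missingness. No imputation is provided — synthetic
data are generated complete, so tests use complete or MCAR data. All
generators are pure functions of (parameters, seed). A recovery harness
closes the loop: simulate → refit → report relative bias (< 5% at
n = 2,000 per arm) and Wald CI coverage.

## What the shipped configuration can and cannot reproduce

Reproduced from the published inputs: the cost-bundle sums, the month-12
survival extrapolations, the incremental columns and dominance
classification recomputed from the published per-arm table values, and
the tornado's leading parameters (survival curves, PD utilities,
next-line costs). Not reproduced: the absolute lifetime totals and the
dominant (cost-saving) base case — the published €433,634 lifetime cost
of the ipilimumab arm implies substantial per-cycle disease-management
costs from supplementary material that is not publicly available. With
main-text inputs only, the lifetime discounted increment is
ΔQALY ≈ +1.13 at ΔCost ≈ +€37k (ICER ≈ €33k/QALY): cost-effective at
both country thresholds but in the north-east, not the dominant,
quadrant. Consequently the probabilistic probability of
cost-effectiveness is ≈ 86% at €80,000 (NL) and ≈ 64% at €50,000 (DK)
rather than the published ≥ 99%, driven almost entirely by the 10% CV on
the survival parameters. These probabilities are computed and reported as
is; closing the gap would require the unpublished cost schedules, not
different modelling choices.

## Problem sizes

Defaults used throughout the scripts and tests: 10,000 PSA draws
(acceptance and `analysis/04`), 2,000 patients per arm for parameter
recovery, 5,000 for distributional checks, 200 replicates × 200 patients
for CI coverage. The cohort trace has ~165 cycles (41 years) under the
shipped curves.

## Known limitations

* Two-arm comparisons only; no frontier analysis across >2 strategies.
* No adverse-event state, treatment waning, cure-point remodelling, or
  individual-level microsimulation.
* No EQ-5D tariff valuation (utilities enter as numbers) and no
  currency conversion.
* Survival parameter uncertainty is sampled independently per parameter;
  without a published fit covariance, the correlation that would
  constrain the curves near the data is unavailable, which likely
  overstates tail uncertainty.
* EVPI and correlated sampling beyond the Dirichlet groups are out of
  scope.
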