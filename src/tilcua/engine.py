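"""Cohort trace and accumulation of life years, QALYs and costs.

The engine runs a three-state (progression-free / progressive disease /
dead) cohort on a 3-month cycle grid. State occupancy at each cycle start
is read off the arm's PFS and OS curves (partitioned survival); the trace
stops at the earlier of the cohort reaching age 100 or 99.9% cumulative
mortality. Accumulators then integrate discounted person-time, utility-
weighted person-time and itemised costs over the trace.

Accounting conventions (documented here because the discrete grid forces
choices): occupancy rows are cycle-*start* states; a row's discount
factor is evaluated at its start time; deaths and PD entries during the
3-month interval that *starts* at a row attach to that row (so the
"cycle of death" carries the pre-death utility and the death cost).
No half-cycle correction is applied by default; a trapezoid variant can
be had by averaging adjacent rows but is not used in the shipped
scenarios.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .config import (
    ArmModel,
    Scenario,
    ValidationError,
    next_line_expected_cost,
    next_line_expected_utility,
)
from .survival import occupancy_from_curves

__all__ = [
    "CohortTrace",
    "CycleLedger",
    "build_trace",
    "accumulate_life_years",
    "accumulate_qalys",
    "accumulate_costs",
    "ArmOutcome",
    "evaluate_arm",
]

DEATH_CUTOFF = 0.999
MAX_HORIZON_YEARS = 200.0


@dataclass(frozen=True)
class CohortTrace:
    """Per-cycle state occupancy with incident flows.

    ``data`` has one row per cycle start: ``cycle_index``, ``time_years``,
    occupancy columns ``pfs``/``pd``/``dead``, and the backward-looking
    incident columns (``incident_deaths`` at row c is the mass dying in
    the interval ending at t_c). The forward-looking flows the
    accumulators need (events in the interval *starting* at each row,
    including the one interval beyond the cutoff) are kept alongside as
    ``fwd_deaths`` / ``fwd_pd`` / ``fwd_deaths_from_pfs``.
    """

    data: pd.DataFrame
    fwd_deaths: np.ndarray
    fwd_pd: np.ndarray
    fwd_deaths_from_pfs: np.ndarray
    cycle_length_years: float

    def __len__(self) -> int:
        return len(self.data)

    def truncate(self, horizon_years: float | None) -> "CohortTrace":
        """Restrict to cycles starting strictly before ``horizon_years``."""
        if horizon_years is None:
            return self
        keep = self.data["time_years"].to_numpy() < horizon_years
        n = int(keep.sum())
        return CohortTrace(
            self.data.iloc[:n].reset_index(drop=True),
            self.fwd_deaths[:n],
            self.fwd_pd[:n],
            self.fwd_deaths_from_pfs[:n],
            self.cycle_length_years,
        )


class CycleLedger(NamedTuple):
    """Itemised per-cycle audit trail; column sums equal the totals."""

    data: pd.DataFrame  # columns: treatment, follow_up, next_line, death, societal

    @property
    def total(self) -> float:
        return float(self.data[["treatment", "follow_up", "next_line", "death", "societal"]]
                     .to_numpy().sum())


def build_trace(arm: ArmModel, scenario: Scenario) -> CohortTrace:
    """Run the cohort over the lifetime horizon on the cycle grid.

    The trace ends at the first cycle where cumulative mortality reaches
    99.9% or the cohort reaches age 100; if neither happens within 200
    years the curves are considered mis-specified and an error is raised.
    """
    step_years = scenario.cycle_length_years
    step_months = step_years * 12.0
    age_cycles = int(np.floor((100.0 - scenario.baseline_age_years) / step_years + 1e-9))
    max_cycles = int(np.ceil(MAX_HORIZON_YEARS / step_years))

    # one row beyond the last kept cycle so the final interval closes
    n_grid = min(age_cycles, max_cycles) + 2
    grid_months = np.arange(n_grid) * step_months
    occ = occupancy_from_curves(arm.pfs_curve, arm.os_curve, grid_months)
    dead = occ["dead"].to_numpy()

    crossed = np.nonzero(dead >= DEATH_CUTOFF)[0]
    if crossed.size:
        last = int(min(crossed[0], age_cycles))
    elif age_cycles < max_cycles:
        last = age_cycles
    else:
        raise ValidationError(
            "neither the 99.9% mortality nor the age-100 cutoff is reached "
            "within 200 years; survival curves look mis-specified"
        )
    n = last + 1  # rows 0..last inclusive

    pfs = occ["pfs"].to_numpy()[: n + 1]
    pd_state = occ["pd"].to_numpy()[: n + 1]
    dead = dead[: n + 1]
    alive = pfs + pd_state

    deaths = np.diff(dead)                      # interval c -> c+1, length n
    with np.errstate(invalid="ignore", divide="ignore"):
        share_pfs = np.where(alive[:-1] > 0, pfs[:-1] / alive[:-1], 0.0)
    deaths_from_pfs = deaths * share_pfs
    pd_inflow = np.maximum(0.0, -np.diff(pfs) - deaths_from_pfs)

    data = pd.DataFrame({
        "cycle_index": np.arange(n),
        "time_years": np.arange(n) * step_years,
        "pfs": pfs[:n],
        "pd": pd_state[:n],
        "dead": dead[:n],
        "incident_deaths": np.concatenate([[0.0], deaths[: n - 1]]),
        "incident_pd": np.concatenate([[0.0], pd_inflow[: n - 1]]),
    })
    data.attrs["clamped"] = occ.attrs.get("clamped", 0.0)
    return CohortTrace(data, deaths, pd_inflow, deaths_from_pfs, step_years)


def _discount_factors(trace: CohortTrace, rate: float) -> np.ndarray:
    if rate < 0:
        raise ValidationError("discount rate must be >= 0")
    return (1.0 + rate) ** (-trace.data["time_years"].to_numpy())


def accumulate_life_years(trace: CohortTrace, rate: float = 0.0) -> float:
    """Discounted life years: alive occupancy x cycle length, summed."""
    alive = (trace.data["pfs"] + trace.data["pd"]).to_numpy()
    return float(np.sum(alive * trace.cycle_length_years * _discount_factors(trace, rate)))


def accumulate_qalys(
    trace: CohortTrace,
    arm: ArmModel,
    next_line_utility: float | None = None,
    rate: float = 0.0,
) -> float:
    """Discounted QALYs over the trace.

    Each cycle's person-time splits into: mass dying during the cycle
    (weighted by the pre-death utility), remaining progression-free mass
    (PFS utility series at the cycle-start month) and remaining PD mass
    (expected next-line utility). Deaths are allocated to the two alive
    states in proportion to cycle-start occupancy.
    """
    if next_line_utility is None:
        next_line_utility = next_line_expected_utility(arm.next_line_mix)
    months = trace.data["time_years"].to_numpy() * 12.0
    u_pfs = np.array([arm.pfs_utilities.at(m) for m in months])
    u_pre_death = arm.pfs_utilities.pre_death_utility

    pfs = trace.data["pfs"].to_numpy()
    pd_state = trace.data["pd"].to_numpy()
    d = trace.fwd_deaths
    d_pfs = trace.fwd_deaths_from_pfs
    cont_pfs = np.maximum(pfs - d_pfs, 0.0)
    cont_pd = np.maximum(pd_state - (d - d_pfs), 0.0)

    per_cycle = cont_pfs * u_pfs + cont_pd * next_line_utility + d * u_pre_death
    df = _discount_factors(trace, rate)
    return float(np.sum(per_cycle * trace.cycle_length_years * df))


def accumulate_costs(
    trace: CohortTrace,
    arm: ArmModel,
    scenario: Scenario,
) -> tuple[float, CycleLedger]:
    """Discounted costs over the trace, itemised per cycle.

    One-time and first-cycle amounts fall at model start; recurring
    per-cycle and annual amounts scale with alive occupancy at each cycle
    start (per-cycle items of a bundle with ``follow_up_stop_years`` stop
    at that time); next-line costs attach to PD inflow (once per entrant,
    or per PD cycle when the arm's ``pd_cost_mode`` is ``per_cycle``);
    death costs attach to deaths during each cycle. Everything discounts
    at the cycle-start time at the scenario's cost rate.
    """
    rate = scenario.discount_rate_costs
    df = _discount_factors(trace, rate)
    t = trace.data["time_years"].to_numpy()
    alive = (trace.data["pfs"] + trace.data["pd"]).to_numpy()
    n = len(trace)
    step = trace.cycle_length_years

    def recurring(bundle) -> tuple[np.ndarray, np.ndarray]:
        """(per-cycle series, annual series) for one bundle."""
        active = np.ones(n, bool)
        if bundle.follow_up_stop_years is not None:
            active = t < bundle.follow_up_stop_years
        per_cycle = np.zeros(n)
        per_cycle[1:] = bundle.per_cycle_amount * alive[1:] * df[1:]  # ">first cycle"
        per_cycle = np.where(active, per_cycle, 0.0)
        annual = bundle.annual_amount * step * alive * df
        annual = np.where(active, annual, 0.0)
        return per_cycle, annual

    tb, sb = arm.treatment_costs, arm.societal_costs

    treatment = np.zeros(n)
    if n:
        treatment[0] = (tb.one_time_total + tb.first_cycle_amount) * df[0]
    fu_cycle, fu_annual = recurring(tb)
    follow_up = fu_cycle + fu_annual

    societal = np.zeros(n)
    if n:
        societal[0] = (sb.one_time_total + sb.first_cycle_amount) * df[0]
    soc_cycle, soc_annual = recurring(sb)
    societal = societal + soc_cycle + soc_annual

    nl_cost = next_line_expected_cost(arm.next_line_mix) if arm.next_line_mix else 0.0
    if arm.pd_cost_mode == "per_cycle":
        next_line = nl_cost * trace.data["pd"].to_numpy() * df
    else:
        next_line = nl_cost * trace.fwd_pd * df

    death = (tb.death_cost + sb.death_cost) * trace.fwd_deaths * df

    ledger = CycleLedger(pd.DataFrame({
        "cycle_index": trace.data["cycle_index"],
        "time_years": trace.data["time_years"],
        "treatment": treatment,
        "follow_up": follow_up,
        "next_line": next_line,
        "death": death,
        "societal": societal,
    }))
    return ledger.total, ledger


@dataclass(frozen=True)
class ArmOutcome:
    """Engine results for one arm at one horizon/discounting setting."""

    arm_name: str
    horizon_years: float | None
    discounted: bool
    life_years: float
    qalys: float
    total_cost: float
    ledger: CycleLedger


def evaluate_arm(
    arm: ArmModel,
    scenario: Scenario,
    horizon_years: float | None = None,
    discounted: bool = True,
    trace: CohortTrace | None = None,
) -> ArmOutcome:
    """Build (or reuse) the trace and accumulate LY, QALYs and costs."""
    if trace is None:
        trace = build_trace(arm, scenario)
    trace = trace.truncate(horizon_years)
    if not discounted:
        from dataclasses import replace

        scenario = replace(scenario, discount_rate_costs=0.0, discount_rate_effects=0.0)
    rate_e = scenario.discount_rate_effects
    ly = accumulate_life_years(trace, rate_e)
    qaly = accumulate_qalys(trace, arm, rate=rate_e)
    cost, ledger = accumulate_costs(trace, arm, scenario)
    return ArmOutcome(arm.name, horizon_years, discounted, ly, qaly, cost, ledger)
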