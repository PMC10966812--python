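"""Cohort trace construction and the LY/QALY/cost accumulators.

The accumulators are checked against a deliberately naive scalar
re-implementation of the accounting rules (``_oracle_totals``) on
randomized small scenarios — same conventions, independent code path.
"""

import math

import numpy as np
import pandas as pd
import pytest

from tilcua.config import (
    ArmModel,
    CostBundle,
    NextLineOption,
    Scenario,
    UtilitySeries,
    next_line_expected_cost,
    next_line_expected_utility,
)
from tilcua.engine import (
    CohortTrace,
    accumulate_costs,
    accumulate_life_years,
    accumulate_qalys,
    build_trace,
    evaluate_arm,
)
from tilcua.survival import ParametricSurvival, survival_at

from conftest import make_random_model


def _simple_scenario(**kw) -> Scenario:
    base = dict(
        country_label="test", discount_rate_costs=0.0, discount_rate_effects=0.0,
        wtp_threshold=80_000.0, baseline_age_years=59.0,
    )
    base.update(kw)
    return Scenario(**base)


def _flat_utilities(u=1.0, pre_death=1.0):
    return UtilitySeries((0.0,), (u,), pre_death_utility=pre_death)


def _one_row_trace(occupancy=(1.0, 0.0, 0.0)):
    data = pd.DataFrame({
        "cycle_index": [0], "time_years": [0.0],
        "pfs": [occupancy[0]], "pd": [occupancy[1]], "dead": [occupancy[2]],
        "incident_deaths": [0.0], "incident_pd": [0.0],
    })
    return CohortTrace(data, np.zeros(1), np.zeros(1), np.zeros(1), 0.25)


def _oracle_totals(arm: ArmModel, scenario: Scenario):
    """Naive per-cycle loop over the accounting rules (test oracle)."""
    step = scenario.cycle_length_years
    months = step * 12

    def occ(c):
        s_os = survival_at(arm.os_curve, c * months)
        s_pfs = min(survival_at(arm.pfs_curve, c * months), s_os)
        return s_pfs, s_os - s_pfs, 1 - s_os

    # trace length: first cycle with dead >= 0.999, capped by age 100
    age_cap = math.floor((100 - scenario.baseline_age_years) / step + 1e-9)
    n = None
    for c in range(age_cap + 1):
        if occ(c)[2] >= 0.999:
            n = c + 1
            break
    if n is None:
        n = age_cap + 1

    nl_cost = next_line_expected_cost(arm.next_line_mix)
    nl_util = next_line_expected_utility(arm.next_line_mix)
    ly = qaly = cost = 0.0
    for c in range(n):
        t = c * step
        dfe = (1 + scenario.discount_rate_effects) ** (-t)
        dfc = (1 + scenario.discount_rate_costs) ** (-t)
        pfs, pd_, dead = occ(c)
        pfs1, pd1, dead1 = occ(c + 1)
        alive = pfs + pd_
        deaths = dead1 - dead
        d_pfs = deaths * (pfs / alive) if alive > 0 else 0.0
        pd_in = max(0.0, (pfs - pfs1) - d_pfs)
        ly += alive * step * dfe
        u_pfs = arm.pfs_utilities.at(t * 12)
        qaly += (
            max(pfs - d_pfs, 0.0) * u_pfs
            + max(pd_ - (deaths - d_pfs), 0.0) * nl_util
            + deaths * arm.pfs_utilities.pre_death_utility
        ) * step * dfe
        for bundle in (arm.treatment_costs, arm.societal_costs):
            if c == 0:
                cost += (bundle.one_time_total + bundle.first_cycle_amount) * dfc
            active = (bundle.follow_up_stop_years is None
                      or t < bundle.follow_up_stop_years)
            if active:
                if c >= 1:
                    cost += bundle.per_cycle_amount * alive * dfc
                cost += bundle.annual_amount * step * alive * dfc
            cost += bundle.death_cost * deaths * dfc
        if arm.pd_cost_mode == "per_cycle":
            cost += nl_cost * pd_ * dfc
        else:
            cost += nl_cost * pd_in * dfc
    return ly, qaly, cost


class TestBuildTrace:
    def test_immortal_cohort_truncates_at_age_100(self):
        scenario = _simple_scenario(baseline_age_years=99.0)
        arm_kw = dict(
            name="x", treatment_costs=CostBundle(), societal_costs=CostBundle(),
            pfs_utilities=_flat_utilities(),
            next_line_mix=(NextLineOption("n", 0.0, 1.0, 0.8),),
        )
        near_immortal = ParametricSurvival("exponential", 1e12)
        arm = ArmModel(pfs_curve=near_immortal, os_curve=near_immortal, **arm_kw)
        trace = build_trace(arm, scenario)
        assert len(trace) == 5  # cycle starts at ages 99.00 .. 100.00
        assert np.allclose(trace.data["dead"], 0.0, atol=1e-9)

    def test_mortality_cutoff_gives_k_plus_1_rows(self):
        # exponential OS, alpha = 3 months: dead(c) = 1 - exp(-c), so the
        # 99.9% crossing is the first cycle with c >= ln(1000) = 6.908 -> k=7
        scenario = _simple_scenario()
        curve = ParametricSurvival("exponential", 3.0)
        arm = ArmModel(
            name="x", pfs_curve=curve, os_curve=curve,
            treatment_costs=CostBundle(), societal_costs=CostBundle(),
            pfs_utilities=_flat_utilities(),
            next_line_mix=(NextLineOption("n", 0.0, 1.0, 0.8),),
        )
        trace = build_trace(arm, scenario)
        assert len(trace) == 8
        assert trace.data["dead"].iloc[-1] >= 0.999
        assert trace.data["dead"].iloc[-2] < 0.999

    def test_til_arm_cycle4_occupancy_matches_printed_month12(self, nl_scenario):
        scenario, arms = nl_scenario
        trace = build_trace(arms[0], scenario)
        row = trace.data.iloc[4]
        assert row["pfs"] == pytest.approx(0.395, abs=0.005)
        assert row["pd"] == pytest.approx(0.340, abs=0.005)
        assert row["dead"] == pytest.approx(0.265, abs=0.005)

    @pytest.mark.parametrize("seed", range(5))
    def test_trace_invariants(self, seed):
        scenario, arm = make_random_model(seed)
        trace = build_trace(arm, scenario)
        occ = trace.data[["pfs", "pd", "dead"]]
        assert np.allclose(occ.sum(axis=1), 1.0, atol=1e-9)
        assert (trace.data[["incident_deaths", "incident_pd"]] >= 0).all().all()
        # cumulative incident deaths reconstruct the dead column
        dead = trace.data["incident_deaths"].cumsum() + trace.data["dead"].iloc[0]
        assert np.allclose(dead, trace.data["dead"], atol=1e-12)


class TestAccumulators:
    def test_single_cycle_life_years(self):
        assert accumulate_life_years(_one_row_trace(), 0.0) == pytest.approx(0.25)

    def test_discounted_leq_undiscounted(self, nl_scenario):
        scenario, arms = nl_scenario
        trace = build_trace(arms[0], scenario)
        assert accumulate_life_years(trace, 0.04) <= accumulate_life_years(trace, 0.0)

    def test_four_alive_cycles_geometric_sum(self):
        data = pd.DataFrame({
            "cycle_index": range(4), "time_years": [0.0, 0.25, 0.5, 0.75],
            "pfs": 1.0, "pd": 0.0, "dead": 0.0,
            "incident_deaths": 0.0, "incident_pd": 0.0,
        })
        trace = CohortTrace(data, np.zeros(4), np.zeros(4), np.zeros(4), 0.25)
        expected = 0.25 * sum(1.04 ** (-0.25 * c) for c in range(4))
        assert accumulate_life_years(trace, 0.04) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.9854590755864889)

    def _arm(self, **overrides):
        kw = dict(
            name="x",
            pfs_curve=ParametricSurvival("exponential", 6.0),
            os_curve=ParametricSurvival("exponential", 12.0),
            treatment_costs=CostBundle(),
            societal_costs=CostBundle(),
            pfs_utilities=_flat_utilities(),
            next_line_mix=(NextLineOption("n", 0.0, 1.0, 1.0),),
        )
        kw.update(overrides)
        return ArmModel(**kw)

    def test_qalys_equal_life_years_at_unit_utility(self):
        scenario, _ = _simple_scenario(), None
        arm = self._arm()
        trace = build_trace(arm, scenario)
        assert accumulate_qalys(trace, arm, rate=0.0) == pytest.approx(
            accumulate_life_years(trace, 0.0), abs=1e-12)

    def test_single_cycle_qaly_with_til_baseline_utility(self):
        arm = self._arm(pfs_utilities=_flat_utilities(0.874, pre_death=0.665))
        assert accumulate_qalys(_one_row_trace(), arm, rate=0.0) == pytest.approx(0.2185)

    def test_incident_death_mass_weighted_by_pre_death_utility(self):
        arm = self._arm(pfs_utilities=UtilitySeries((0.0,), (0.8,), pre_death_utility=0.665))
        data = pd.DataFrame({
            "cycle_index": [0], "time_years": [0.0],
            "pfs": [1.0], "pd": [0.0], "dead": [0.0],
            "incident_deaths": [0.0], "incident_pd": [0.0],
        })
        trace = CohortTrace(data, np.array([0.1]), np.zeros(1), np.array([0.1]), 0.25)
        got = accumulate_qalys(trace, arm, rate=0.0)
        assert got == pytest.approx((0.9 * 0.8 + 0.1 * 0.665) * 0.25)

    def test_empty_bundles_cost_nothing(self):
        scenario = _simple_scenario()
        arm = self._arm()
        total, ledger = accumulate_costs(build_trace(arm, scenario), arm, scenario)
        assert total == 0.0

    def test_til_one_time_bundle_totals_printed_value(self, nl_scenario):
        scenario, arms = nl_scenario
        til = arms[0]
        assert til.treatment_costs.one_time_total == 117_940
        trace = build_trace(til, scenario)
        _, ledger = accumulate_costs(trace, til, scenario)
        assert ledger.data["treatment"].iloc[0] == pytest.approx(117_940)

    def test_death_cost_paid_once_per_cohort_member(self):
        scenario = _simple_scenario()
        arm = self._arm(treatment_costs=CostBundle(death_cost=1516.0))
        trace = build_trace(arm, scenario)
        total, ledger = accumulate_costs(trace, arm, scenario)
        total_deaths = trace.fwd_deaths.sum()
        assert total_deaths == pytest.approx(1.0, abs=2e-3)  # 99.9% cutoff
        assert total == pytest.approx(1516.0 * total_deaths)
        assert ledger.data["death"].sum() == pytest.approx(total)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(12))
    def test_accumulators_match_naive_loop(self, seed):
        scenario, arm = make_random_model(seed)
        ly_o, qaly_o, cost_o = _oracle_totals(arm, scenario)
        trace = build_trace(arm, scenario)
        ly = accumulate_life_years(trace, scenario.discount_rate_effects)
        qaly = accumulate_qalys(trace, arm, rate=scenario.discount_rate_effects)
        cost, _ = accumulate_costs(trace, arm, scenario)
        assert ly == pytest.approx(ly_o, abs=1e-9)
        assert qaly == pytest.approx(qaly_o, abs=1e-9)
        assert cost == pytest.approx(cost_o, abs=1e-6)


class TestProperties:
    @pytest.mark.parametrize("seed", range(6))
    def test_qaly_never_exceeds_life_years(self, seed):
        scenario, arm = make_random_model(seed)
        trace = build_trace(arm, scenario)
        assert accumulate_qalys(trace, arm, rate=0.0) <= accumulate_life_years(trace, 0.0) + 1e-12

    def test_zero_rates_reproduce_undiscounted_and_monotone(self, nl_scenario):
        scenario, arms = nl_scenario
        arm = arms[0]
        trace = build_trace(arm, scenario)
        undisc = accumulate_life_years(trace, 0.0)
        values = [accumulate_life_years(trace, r) for r in (0.0, 0.01, 0.03, 0.08)]
        assert values[0] == undisc
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_ledger_columns_sum_to_total_exactly(self, nl_scenario):
        scenario, arms = nl_scenario
        for arm in arms:
            trace = build_trace(arm, scenario)
            total, ledger = accumulate_costs(trace, arm, scenario)
            assert ledger.total == total

    def test_horizon_truncation_is_half_open(self, nl_scenario):
        scenario, arms = nl_scenario
        trace = build_trace(arms[0], scenario)
        t5 = trace.truncate(5.0)
        assert len(t5) == 20  # cycles at 0.00 .. 4.75 years
        assert t5.data["time_years"].max() < 5.0
        assert len(trace.truncate(0.0)) == 0

    def test_zero_horizon_outcome_is_all_zero(self, nl_scenario):
        scenario, arms = nl_scenario
        out = evaluate_arm(arms[0], scenario, horizon_years=0.0)
        assert (out.life_years, out.qalys, out.total_cost) == (0.0, 0.0, 0.0)
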