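"""Shared fixtures: the shipped scenarios and small randomized models."""

from __future__ import annotations

import numpy as np
import pytest

from tilcua.config import (
    ArmModel,
    CostBundle,
    NextLineOption,
    Scenario,
    UtilitySeries,
    load_scenario,
    packaged_scenario_path,
)
from tilcua.survival import ParametricSurvival


@pytest.fixture(scope="session")
def nl_scenario():
    return load_scenario(packaged_scenario_path("nl_base_case"))


@pytest.fixture(scope="session")
def dk_scenario():
    return load_scenario(packaged_scenario_path("dk_scenario"))


def make_random_model(seed: int) -> tuple[Scenario, ArmModel]:
    """A small, fast random scenario/arm pair for oracle comparisons.

    Curves are chosen with short survival so the 99.9% mortality cutoff
    arrives within a few dozen cycles.
    """
    rng = np.random.default_rng(seed)
    scenario = Scenario(
        country_label="synthetic",
        discount_rate_costs=float(rng.uniform(0, 0.08)),
        discount_rate_effects=float(rng.uniform(0, 0.05)),
        wtp_threshold=80_000.0,
        baseline_age_years=float(rng.uniform(40, 95)),
    )
    os_alpha = float(rng.uniform(4, 18))
    pfs_alpha = os_alpha * float(rng.uniform(0.3, 0.9))
    family = rng.choice(["weibull", "loglogistic", "exponential"])
    arm = ArmModel(
        name=f"random-{seed}",
        pfs_curve=ParametricSurvival(family, pfs_alpha, float(rng.uniform(1.1, 2.5))),
        os_curve=ParametricSurvival(family, os_alpha, float(rng.uniform(1.1, 2.5))),
        treatment_costs=CostBundle(
            one_time_items=(("upfront", float(rng.uniform(0, 50_000))),),
            first_cycle_amount=float(rng.uniform(0, 2_000)),
            per_cycle_amount=float(rng.uniform(0, 800)),
            annual_amount=float(rng.uniform(0, 500)),
            death_cost=float(rng.uniform(0, 3_000)),
            follow_up_stop_years=float(rng.uniform(1, 8)),
        ),
        societal_costs=CostBundle(
            first_cycle_amount=float(rng.uniform(0, 4_000)),
            per_cycle_amount=float(rng.uniform(0, 400)),
            annual_amount=float(rng.uniform(0, 400)),
        ),
        pfs_utilities=UtilitySeries(
            timepoints=(0.0, 3.0, 6.0, 9.0, 12.0),
            values=tuple(np.round(rng.uniform(0.6, 0.95, size=5), 3)),
            pre_death_utility=float(rng.uniform(0.4, 0.8)),
        ),
        next_line_mix=(
            NextLineOption("a", float(rng.uniform(0, 80_000)), 0.35, float(rng.uniform(0.5, 0.9))),
            NextLineOption("b", float(rng.uniform(0, 80_000)), 0.45, float(rng.uniform(0.5, 0.9))),
            NextLineOption("none", 0.0, 0.2, float(rng.uniform(0.5, 0.9))),
        ),
        pd_cost_mode="per_cycle" if rng.random() < 0.3 else "per_entry",
    )
    return scenario, arm
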