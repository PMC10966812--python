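"""Incremental cost-effectiveness results and summary tables.

The decision metric is the incremental cost-effectiveness ratio,
ICER = (C_intervention - C_comparator) / (Q_intervention - Q_comparator),
judged against a willingness-to-pay threshold. When the intervention is
both cheaper and more effective it *dominates* and no ratio is reported;
net monetary benefit, NMB = WTP x dQALY - dCost, is the dominance-safe
scalar used internally for ranking and acceptability curves.

All arithmetic is done at full precision; rounding ((QA)LYs to 2
decimals, euros to whole units, half-up) happens only when rendering,
and incremental columns are differenced before rounding.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .config import ArmModel, Scenario, ValidationError
from .engine import ArmOutcome, build_trace, evaluate_arm

__all__ = [
    "CEResult",
    "ICERResult",
    "icer",
    "nmb",
    "summary_table",
    "render_summary",
]


@dataclass(frozen=True)
class CEResult:
    """Per-arm totals at one horizon/discounting setting."""

    arm_name: str
    horizon_years: float | None  # None = lifetime
    discounted: bool
    life_years: float
    qalys: float
    total_cost: float

    @classmethod
    def from_outcome(cls, o: ArmOutcome) -> "CEResult":
        return cls(o.arm_name, o.horizon_years, o.discounted,
                   o.life_years, o.qalys, o.total_cost)


@dataclass(frozen=True)
class ICERResult:
    """Incremental comparison of intervention vs comparator."""

    delta_cost: float
    delta_qaly: float
    classification: str  # dominant | dominated | icer_ne_quadrant | icer_sw_quadrant
    icer_value: float | None
    nmb_at_wtp: float


def nmb(delta_cost: float, delta_qaly: float, wtp: float) -> float:
    """Net monetary benefit at a willingness-to-pay threshold."""
    if wtp < 0:
        raise ValidationError("willingness-to-pay must be >= 0")
    return wtp * delta_qaly - delta_cost


def icer(intervention: CEResult, comparator: CEResult, wtp: float) -> ICERResult:
    """Incremental result with dominance classification.

    Dominant: cheaper and more effective. Dominated: costlier and less
    effective. Otherwise the point lies in the NE (costlier, more
    effective) or SW (cheaper, less effective) quadrant and the ratio is
    reported. A zero QALY difference yields no ratio; the comparison is
    then classified by the cost sign alone (SW if cost-saving, NE
    otherwise).
    """
    if intervention.horizon_years != comparator.horizon_years:
        raise ValidationError("horizon mismatch between arms")
    if intervention.discounted != comparator.discounted:
        raise ValidationError("discounting mismatch between arms")
    dc = intervention.total_cost - comparator.total_cost
    dq = intervention.qalys - comparator.qalys
    if dq > 0 and dc < 0:
        cls, value = "dominant", None
    elif dq < 0 and dc > 0:
        cls, value = "dominated", None
    elif dq == 0:
        cls, value = ("icer_sw_quadrant" if dc < 0 else "icer_ne_quadrant"), None
    elif dq > 0:
        cls, value = "icer_ne_quadrant", dc / dq
    else:
        cls, value = "icer_sw_quadrant", dc / dq
    return ICERResult(dc, dq, cls, value, nmb(dc, dq, wtp))


def summary_table(
    scenario: Scenario,
    arms: list[ArmModel],
    horizons: tuple[float | None, ...] = (5.0, 10.0, None),
) -> pd.DataFrame:
    """Per-horizon, per-discounting summary with incremental columns.

    The first arm is the intervention, the second the comparator. Horizon
    truncation keeps cycles starting strictly before the horizon
    (half-open [0, horizon) on cycle-start times). Returns a tidy frame
    with one row per horizon x discounting, full-precision values.
    """
    if len(arms) != 2:
        raise ValidationError("summary table needs exactly two arms")
    traces = {a.name: build_trace(a, scenario) for a in arms}
    rows = []
    for horizon in horizons:
        for discounted in (False, True):
            res = [
                CEResult.from_outcome(
                    evaluate_arm(a, scenario, horizon, discounted, trace=traces[a.name])
                )
                for a in arms
            ]
            inc = icer(res[0], res[1], scenario.wtp_threshold)
            rows.append({
                "horizon_years": horizon if horizon is not None else float("inf"),
                "discounted": discounted,
                f"ly_{arms[0].name}": res[0].life_years,
                f"ly_{arms[1].name}": res[1].life_years,
                "ly_incremental": res[0].life_years - res[1].life_years,
                f"qaly_{arms[0].name}": res[0].qalys,
                f"qaly_{arms[1].name}": res[1].qalys,
                "qaly_incremental": inc.delta_qaly,
                f"cost_{arms[0].name}": res[0].total_cost,
                f"cost_{arms[1].name}": res[1].total_cost,
                "cost_incremental": inc.delta_cost,
                "classification": inc.classification,
                "icer": inc.icer_value,
                "nmb_at_wtp": inc.nmb_at_wtp,
            })
    return pd.DataFrame(rows)


def round_half_up(value: float, decimals: int = 0) -> float:
    """Decimal half-up rounding (0.5 always rounds away from zero)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def render_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Rounded view of :func:`summary_table` ((QA)LY 2 dp, euro whole)."""
    out = table.copy()
    for col in out.columns:
        if col.startswith(("ly_", "qaly_")):
            out[col] = out[col].map(lambda v: round_half_up(v, 2))
        elif col.startswith("cost_") or col in ("icer", "nmb_at_wtp"):
            out[col] = out[col].map(
                lambda v: None if v is None or pd.isna(v) else round_half_up(v, 0)
            )
    return out
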