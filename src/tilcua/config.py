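"""Parameter data model and scenario files for the cost-utility model.

A *scenario* bundles the country-level settings (discount rates on costs
and effects, willingness-to-pay threshold, baseline age, cycle length)
with two treatment arms. Each arm carries its survival curves (PFS and
OS), its cost schedules (a treatment/healthcare bundle and a societal
bundle), a progression-free utility series, and the mixture of next-line
treatments patients move to on progression. Scenario files are YAML (or
JSON — a YAML subset); survival curves are given either as explicit
``(family, alpha, beta)`` parameters or as a reference to a survival-
points CSV that is fitted on load.

Monetary amounts are euros; utilities are EQ-5D index values bounded
below by -0.59 (the worst health-state tariff) and above by 1 (perfect
health). Out-of-range inputs are rejected, never clamped.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import yaml

from .survival import ParametricSurvival, SurvivalPoints, fit_points

__all__ = [
    "UTILITY_FLOOR",
    "Scenario",
    "CostBundle",
    "NextLineOption",
    "UtilitySeries",
    "ArmModel",
    "SchemaError",
    "ValidationError",
    "load_scenario",
    "dump_scenario",
    "next_line_expected_cost",
    "next_line_expected_utility",
    "packaged_scenario_path",
]

#: Lower bound of the EQ-5D index value set (worst describable state).
UTILITY_FLOOR = -0.59

PROPORTION_TOL = 1e-9


class SchemaError(ValueError):
    """A scenario file is missing a required field or has a wrong type."""


class ValidationError(ValueError):
    """A value violates a model invariant (range, ordering, simplex)."""


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ValidationError(msg)


def _check_utility(u: float, what: str) -> None:
    _check(
        UTILITY_FLOOR <= u <= 1.0,
        f"{what} must lie in [{UTILITY_FLOOR}, 1], got {u}",
    )


@dataclass(frozen=True)
class Scenario:
    """Country-level settings of one cost-utility evaluation."""

    country_label: str
    discount_rate_costs: float   # fraction per year
    discount_rate_effects: float  # fraction per year
    wtp_threshold: float         # euro per QALY
    baseline_age_years: float
    cycle_length_years: float = 0.25
    friction_period_days: float | None = None  # provenance metadata only
    currency_label: str = "EUR"

    def __post_init__(self) -> None:
        for name in ("discount_rate_costs", "discount_rate_effects"):
            r = getattr(self, name)
            _check(0.0 <= r < 1.0, f"{name} must lie in [0, 1), got {r}")
        _check(self.wtp_threshold >= 0, f"wtp_threshold must be >= 0, got {self.wtp_threshold}")
        _check(self.cycle_length_years > 0, "cycle_length_years must be positive")
        _check(0 < self.baseline_age_years < 100, "baseline_age_years must lie in (0, 100)")


@dataclass(frozen=True)
class CostBundle:
    """One arm's cost schedule (either healthcare or societal items).

    ``one_time_items`` are incurred once at model start (e.g. screening,
    product manufacture); ``first_cycle_amount`` in the first 3-month
    cycle only; ``per_cycle_amount`` every later cycle while alive;
    ``annual_amount`` (e.g. copay) accrues at a quarter per cycle while
    alive; ``death_cost`` attaches to each incident death. When
    ``follow_up_stop_years`` is set, the recurring per-cycle items cease
    at that time (follow-up visits stop once patients count as cured).
    """

    one_time_items: tuple[tuple[str, float], ...] = ()
    first_cycle_amount: float = 0.0
    per_cycle_amount: float = 0.0
    annual_amount: float = 0.0
    death_cost: float = 0.0
    follow_up_stop_years: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "one_time_items",
            tuple((str(label), float(amount)) for label, amount in self.one_time_items),
        )
        for label, amount in self.one_time_items:
            _check(amount >= 0, f"one-time item {label!r} must be >= 0, got {amount}")
        for name in ("first_cycle_amount", "per_cycle_amount", "annual_amount", "death_cost"):
            _check(getattr(self, name) >= 0, f"{name} must be >= 0")
        if self.follow_up_stop_years is not None:
            _check(self.follow_up_stop_years > 0, "follow_up_stop_years must be positive")

    @property
    def one_time_total(self) -> float:
        return sum(amount for _, amount in self.one_time_items)


@dataclass(frozen=True)
class NextLineOption:
    """One component of the next-line treatment mixture in PD."""

    label: str
    course_cost: float       # euro per patient for the whole course
    proportion: float        # fraction of progressing patients
    utility: float | None = None  # per-cycle utility while on this option

    def __post_init__(self) -> None:
        _check(self.course_cost >= 0, f"course_cost of {self.label!r} must be >= 0")
        _check(0.0 <= self.proportion <= 1.0,
               f"proportion of {self.label!r} must lie in [0, 1], got {self.proportion}")
        if self.utility is not None:
            _check_utility(self.utility, f"utility of {self.label!r}")


@dataclass(frozen=True)
class UtilitySeries:
    """Progression-free utilities observed at scheduled visits.

    ``timepoints`` are months from baseline; lookups use the most recent
    value at or before the requested time (step function). With
    ``carry_forward`` the last value extends beyond the final visit.
    ``pre_death_utility`` is applied to the cycle in which death occurs
    (the "3 months prior to death" weight).
    """

    timepoints: tuple[float, ...]
    values: tuple[float, ...]
    pre_death_utility: float
    carry_forward: bool = True

    def __post_init__(self) -> None:
        _check(len(self.timepoints) == len(self.values) > 0,
               "timepoints and values must be equal-length and non-empty")
        _check(all(b > a for a, b in zip(self.timepoints, self.timepoints[1:])),
               "timepoints must be strictly increasing")
        for v in self.values:
            _check_utility(v, "utility value")
        _check_utility(self.pre_death_utility, "pre_death_utility")

    def at(self, month: float) -> float:
        """Utility applying at ``month`` (step lookup, optional carry-forward)."""
        if month < self.timepoints[0]:
            raise ValidationError(f"no utility defined before month {self.timepoints[0]}")
        if month > self.timepoints[-1] and not self.carry_forward:
            raise ValidationError(
                f"utility at month {month:g} unresolvable: series ends at "
                f"month {self.timepoints[-1]:g} and carry_forward is off"
            )
        idx = max(i for i, t in enumerate(self.timepoints) if t <= month)
        return self.values[idx]


@dataclass(frozen=True)
class ArmModel:
    """Everything the cohort engine needs about one treatment arm."""

    name: str
    pfs_curve: ParametricSurvival
    os_curve: ParametricSurvival
    treatment_costs: CostBundle
    societal_costs: CostBundle
    pfs_utilities: UtilitySeries
    next_line_mix: tuple[NextLineOption, ...]
    pd_cost_mode: str = "per_entry"  # or "per_cycle"

    def __post_init__(self) -> None:
        object.__setattr__(self, "next_line_mix", tuple(self.next_line_mix))
        if self.next_line_mix:
            total = sum(o.proportion for o in self.next_line_mix)
            _check(abs(total - 1.0) <= PROPORTION_TOL,
                   f"next-line proportions must sum to 1, got {total!r}")
        _check(self.pd_cost_mode in ("per_entry", "per_cycle"),
               f"pd_cost_mode must be per_entry or per_cycle, got {self.pd_cost_mode!r}")


# --- mixture expectations -------------------------------------------------

def next_line_expected_cost(mix: Sequence[NextLineOption]) -> float:
    """Expected next-line course cost per progressing patient (euro)."""
    if not mix:
        raise ValidationError("empty next-line mixture")
    return sum(o.proportion * o.course_cost for o in mix)


def next_line_expected_utility(mix: Sequence[NextLineOption]) -> float:
    """Expected per-cycle utility in PD under the next-line mixture."""
    if not mix:
        raise ValidationError("empty next-line mixture")
    for o in mix:
        if o.utility is None:
            raise ValidationError(f"next-line option {o.label!r} has no utility")
    return sum(o.proportion * o.utility for o in mix)


# --- scenario files -------------------------------------------------------

_SCENARIO_REQUIRED = (
    "country_label", "discount_rate_costs", "discount_rate_effects",
    "wtp_threshold", "baseline_age_years",
)


def _require(mapping: dict, key: str, where: str):
    if key not in mapping:
        raise SchemaError(f"missing required field {key!r} in {where}")
    return mapping[key]


def _parse_curve(spec: dict, where: str, base_dir: Path) -> ParametricSurvival:
    if not isinstance(spec, dict):
        raise SchemaError(f"{where} must be a mapping")
    if "points_csv" in spec:
        path = Path(spec["points_csv"])
        if not path.is_absolute():
            path = base_dir / path
        import pandas as pd

        df = pd.read_csv(path)
        for key in ("arm", "endpoint"):
            if key in spec:
                if key not in df.columns:
                    raise SchemaError(f"{where}: points CSV has no {key!r} column to filter on")
                df = df[df[key] == spec[key]]
        if df.empty:
            raise SchemaError(f"{where}: no survival points after filtering")
        df = df.sort_values("time_months")
        points = SurvivalPoints(tuple(df["time_months"]), tuple(df["survival_probability"]))
        return fit_points(points, spec.get("family", "loglogistic"))
    family = _require(spec, "family", where)
    alpha = float(_require(spec, "alpha", where))
    beta = float(spec.get("beta", 1.0))
    return ParametricSurvival(family, alpha, beta, fitted_from="specified")


def _parse_bundle(raw: dict, where: str) -> CostBundle:
    if not isinstance(raw, dict):
        raise SchemaError(f"{where} must be a mapping")
    items = raw.get("one_time_items", [])
    parsed = []
    for entry in items:
        if isinstance(entry, dict):
            parsed.append((_require(entry, "label", where), float(_require(entry, "amount", where))))
        else:
            label, amount = entry
            parsed.append((str(label), float(amount)))
    stop = raw.get("follow_up_stop_years")
    return CostBundle(
        one_time_items=tuple(parsed),
        first_cycle_amount=float(raw.get("first_cycle_amount", 0.0)),
        per_cycle_amount=float(raw.get("per_cycle_amount", 0.0)),
        annual_amount=float(raw.get("annual_amount", 0.0)),
        death_cost=float(raw.get("death_cost", 0.0)),
        follow_up_stop_years=None if stop is None else float(stop),
    )


def _parse_arm(raw: dict, base_dir: Path) -> ArmModel:
    name = _require(raw, "name", "arm")
    where = f"arm {name!r}"
    util_raw = _require(raw, "pfs_utilities", where)
    series = UtilitySeries(
        timepoints=tuple(float(t) for t in _require(util_raw, "timepoints", where)),
        values=tuple(float(v) for v in _require(util_raw, "values", where)),
        pre_death_utility=float(_require(util_raw, "pre_death_utility", where)),
        carry_forward=bool(util_raw.get("carry_forward", True)),
    )
    mix = []
    for opt in _require(raw, "next_line_mix", where):
        mix.append(NextLineOption(
            label=_require(opt, "label", f"{where} next_line_mix"),
            course_cost=float(_require(opt, "course_cost", f"{where} next_line_mix")),
            proportion=float(_require(opt, "proportion", f"{where} next_line_mix")),
            utility=None if opt.get("utility") is None else float(opt["utility"]),
        ))
    return ArmModel(
        name=name,
        pfs_curve=_parse_curve(_require(raw, "pfs_curve", where), f"{where} pfs_curve", base_dir),
        os_curve=_parse_curve(_require(raw, "os_curve", where), f"{where} os_curve", base_dir),
        treatment_costs=_parse_bundle(_require(raw, "treatment_costs", where), f"{where} treatment_costs"),
        societal_costs=_parse_bundle(_require(raw, "societal_costs", where), f"{where} societal_costs"),
        pfs_utilities=series,
        next_line_mix=tuple(mix),
        pd_cost_mode=raw.get("pd_cost_mode", "per_entry"),
    )


def load_scenario(path) -> tuple[Scenario, list[ArmModel]]:
    """Load and validate a scenario file, returning the scenario and arms."""
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"scenario file {path} does not exist")
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "scenario" not in raw:
        raise SchemaError("scenario file must contain a top-level 'scenario' block")
    sraw = raw["scenario"]
    for key in _SCENARIO_REQUIRED:
        _require(sraw, key, "scenario")
    scenario = Scenario(
        country_label=sraw["country_label"],
        discount_rate_costs=float(sraw["discount_rate_costs"]),
        discount_rate_effects=float(sraw["discount_rate_effects"]),
        wtp_threshold=float(sraw["wtp_threshold"]),
        baseline_age_years=float(sraw["baseline_age_years"]),
        cycle_length_years=float(sraw.get("cycle_length_years", 0.25)),
        friction_period_days=(None if sraw.get("friction_period_days") is None
                              else float(sraw["friction_period_days"])),
        currency_label=sraw.get("currency_label", "EUR"),
    )
    arms_raw = _require(raw, "arms", "scenario file")
    if not isinstance(arms_raw, list) or not arms_raw:
        raise SchemaError("'arms' must be a non-empty list")
    arms = [_parse_arm(a, path.parent) for a in arms_raw]
    return scenario, arms


def dump_scenario(path, scenario: Scenario, arms: Sequence[ArmModel]) -> None:
    """Write a scenario back to YAML (curves as explicit parameters)."""

    def curve_dict(c: ParametricSurvival) -> dict:
        return {"family": c.family, "alpha": c.scale_alpha, "beta": c.shape_beta}

    def bundle_dict(b: CostBundle) -> dict:
        out = {
            "one_time_items": [[label, amount] for label, amount in b.one_time_items],
            "first_cycle_amount": b.first_cycle_amount,
            "per_cycle_amount": b.per_cycle_amount,
            "annual_amount": b.annual_amount,
            "death_cost": b.death_cost,
        }
        if b.follow_up_stop_years is not None:
            out["follow_up_stop_years"] = b.follow_up_stop_years
        return out

    doc = {
        "scenario": {
            "country_label": scenario.country_label,
            "discount_rate_costs": scenario.discount_rate_costs,
            "discount_rate_effects": scenario.discount_rate_effects,
            "wtp_threshold": scenario.wtp_threshold,
            "baseline_age_years": scenario.baseline_age_years,
            "cycle_length_years": scenario.cycle_length_years,
            "friction_period_days": scenario.friction_period_days,
            "currency_label": scenario.currency_label,
        },
        "arms": [
            {
                "name": a.name,
                "pfs_curve": curve_dict(a.pfs_curve),
                "os_curve": curve_dict(a.os_curve),
                "treatment_costs": bundle_dict(a.treatment_costs),
                "societal_costs": bundle_dict(a.societal_costs),
                "pfs_utilities": {
                    "timepoints": list(a.pfs_utilities.timepoints),
                    "values": list(a.pfs_utilities.values),
                    "pre_death_utility": a.pfs_utilities.pre_death_utility,
                    "carry_forward": a.pfs_utilities.carry_forward,
                },
                "next_line_mix": [
                    {"label": o.label, "course_cost": o.course_cost,
                     "proportion": o.proportion, "utility": o.utility}
                    for o in a.next_line_mix
                ],
                "pd_cost_mode": a.pd_cost_mode,
            }
            for a in arms
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def packaged_scenario_path(name: str) -> Path:
    """Path of a scenario file shipped with the package.

    Known names: ``nl_base_case``, ``dk_scenario``.
    """
    from importlib import resources

    base = resources.files("tilcua") / "data" / f"{name}.yaml"
    with resources.as_file(base) as p:
        return Path(p)
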