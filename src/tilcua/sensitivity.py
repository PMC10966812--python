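"""Deterministic and probabilistic sensitivity analysis.

The deterministic (one-way) analysis re-runs the model with each
parameter alternately at its low and high value — parameter-specific
best/worst cases — and ranks parameters by the span of net monetary
benefit they induce (NMB is stable across the dominance boundary, where
the raw ICER is not; both are reported). The probabilistic analysis
samples all parameters jointly from conventional health-technology-
assessment distributions — beta for utilities, gamma for costs,
Dirichlet for next-line treatment shares, lognormal for survival
parameters — and summarises the draws as a cost-effectiveness
acceptability curve: the fraction of draws with positive NMB at each
willingness-to-pay value.

Ranges default to ±20% of the base value (clipped to the parameter's
domain) unless a 95% CI is supplied; (high - low) is treated as an
approximate 95% interval when matching distribution variances, i.e.
sd = (high - low) / (2 x 1.96).
"""

from __future__ import annotations

import copy
import re
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .config import ArmModel, Scenario, UTILITY_FLOOR, ValidationError
from .engine import evaluate_arm
from .reporting import CEResult, icer

__all__ = [
    "ParamSpec",
    "PSAResult",
    "CEACCurve",
    "default_param_specs",
    "sample_parameters",
    "run_dsa",
    "run_psa",
    "ceac",
]

_Z95 = 1.959963984540054
#: Dirichlet effective sample size for next-line shares: per-arm trial size.
DIRICHLET_ESS = 84.0


@dataclass(frozen=True)
class ParamSpec:
    """One perturbable parameter.

    ``path`` addresses a field in the (scenario, arms) structure, e.g.
    ``arms[0].pfs_curve.scale_alpha`` or
    ``arms[1].next_line_mix[2].course_cost``. ``group`` ties
    dirichlet-group members (one simplex) together.
    """

    path: str
    base: float
    low: float
    high: float
    distribution: str  # beta | gamma | dirichlet-group | lognormal | fixed
    group: str | None = None

    def __post_init__(self) -> None:
        if not (self.low <= self.base <= self.high):
            raise ValidationError(
                f"{self.path}: need low <= base <= high, got "
                f"({self.low}, {self.base}, {self.high})"
            )
        if self.distribution not in ("beta", "gamma", "dirichlet-group", "lognormal", "fixed"):
            raise ValidationError(f"{self.path}: unknown distribution {self.distribution!r}")


@dataclass(frozen=True)
class PSAResult:
    """Sampled incremental pairs from the probabilistic analysis."""

    draws: pd.DataFrame  # columns: delta_cost, delta_qaly
    base_delta_cost: float
    base_delta_qaly: float
    n: int
    seed: int


@dataclass(frozen=True)
class CEACCurve:
    """Probability cost-effective as a function of willingness-to-pay."""

    wtp: np.ndarray
    probability: np.ndarray

    def at(self, wtp_value: float) -> float:
        idx = int(np.argmin(np.abs(self.wtp - wtp_value)))
        if not np.isclose(self.wtp[idx], wtp_value):
            raise ValidationError(f"wtp {wtp_value} not on the curve grid")
        return float(self.probability[idx])


# --- parameter paths ------------------------------------------------------

_TOKEN = re.compile(r"\.?(\w+)|\[(\d+)\]")


def _walk(root, path: str):
    """Yield (parent, accessor) pairs down a dotted/indexed path."""
    pos = 0
    obj = root
    steps = []
    while pos < len(path):
        m = _TOKEN.match(path, pos)
        if m is None:
            raise ValidationError(f"unresolvable parameter path {path!r} (at {path[pos:]!r})")
        pos = m.end()
        if m.group(1) is not None:
            steps.append(("attr", m.group(1)))
        else:
            steps.append(("index", int(m.group(2))))
    for kind, key in steps:
        try:
            nxt = getattr(obj, key) if kind == "attr" else obj[key]
        except (AttributeError, IndexError, KeyError, TypeError) as exc:
            raise ValidationError(f"unresolvable parameter path {path!r}: {exc}") from None
        yield obj, (kind, key)
        obj = nxt


def get_param(root, path: str) -> float:
    *_, (parent, (kind, key)) = _walk(root, path)
    return getattr(parent, key) if kind == "attr" else parent[key]


def set_param(root, path: str, value: float) -> None:
    """Set a (possibly frozen-dataclass) field addressed by ``path``.

    Frozen dataclasses along the way are mutated via object.__setattr__;
    callers pass a deep copy of the base structure, never the original.
    """
    *_, (parent, (kind, key)) = _walk(root, path)
    if kind == "attr":
        object.__setattr__(parent, key, value)
    else:
        if isinstance(parent, tuple):
            raise ValidationError(f"cannot assign into tuple at {path!r}")
        parent[key] = value


class _Workspace:
    """Deep-copied (scenario, arms) the setters can mutate per evaluation."""

    def __init__(self, scenario: Scenario, arms: Sequence[ArmModel]):
        self.scenario = scenario
        self.arms = list(arms)

    def perturbed(self, assignments: dict[str, float]) -> "_Workspace":
        clone = copy.deepcopy(self)
        # thaw tuples that hold perturbable leaves
        for arm in clone.arms:
            object.__setattr__(arm, "next_line_mix", list(arm.next_line_mix))
            us = arm.pfs_utilities
            object.__setattr__(us, "values", list(us.values))
            for bundle in (arm.treatment_costs, arm.societal_costs):
                object.__setattr__(
                    bundle, "one_time_items",
                    [[label, amount] for label, amount in bundle.one_time_items],
                )
        for path, value in assignments.items():
            set_param(clone, path, value)
        return clone


def _evaluate_deltas(ws: _Workspace, horizon=None, discounted=True) -> tuple[float, float]:
    res = [
        CEResult.from_outcome(evaluate_arm(a, ws.scenario, horizon, discounted))
        for a in ws.arms
    ]
    return (res[0].total_cost - res[1].total_cost, res[0].qalys - res[1].qalys)


# --- default specs --------------------------------------------------------

def default_param_specs(scenario: Scenario, arms: Sequence[ArmModel]) -> list[ParamSpec]:
    """The shipped parameter list: every substantive input, ±20% ranges.

    Utilities get beta distributions (high clipped to 1), monetary
    amounts gamma, next-line proportions one Dirichlet group per arm,
    survival scale/shape lognormal (the ±20% range maps to a ~10% CV;
    point fits carry no usable covariance, so no correlation is
    imposed). Zero-cost entries stay fixed.
    """
    specs: list[ParamSpec] = []

    def pm20(base: float, lo_floor=None, hi_cap=None) -> tuple[float, float]:
        lo, hi = 0.8 * base, 1.2 * base
        if base < 0:
            lo, hi = hi, lo
        if lo_floor is not None:
            lo = max(lo, lo_floor)
        if hi_cap is not None:
            hi = min(hi, hi_cap)
        return lo, hi

    def money(path: str, base: float) -> None:
        if base > 0:
            specs.append(ParamSpec(path, base, *pm20(base), "gamma"))

    def utility(path: str, base: float) -> None:
        lo, hi = pm20(base, lo_floor=UTILITY_FLOOR, hi_cap=1.0)
        specs.append(ParamSpec(path, base, lo, hi, "beta"))

    for i, arm in enumerate(arms):
        prefix = f"arms[{i}]"
        for curve in ("pfs_curve", "os_curve"):
            c = getattr(arm, curve)
            specs.append(ParamSpec(f"{prefix}.{curve}.scale_alpha", c.scale_alpha,
                                   *pm20(c.scale_alpha), "lognormal"))
            specs.append(ParamSpec(f"{prefix}.{curve}.shape_beta", c.shape_beta,
                                   *pm20(c.shape_beta), "lognormal"))
        for j, v in enumerate(arm.pfs_utilities.values):
            utility(f"{prefix}.pfs_utilities.values[{j}]", v)
        utility(f"{prefix}.pfs_utilities.pre_death_utility",
                arm.pfs_utilities.pre_death_utility)
        for bundle in ("treatment_costs", "societal_costs"):
            b = getattr(arm, bundle)
            for j, (_, amount) in enumerate(b.one_time_items):
                money(f"{prefix}.{bundle}.one_time_items[{j}][1]", amount)
            for fname in ("first_cycle_amount", "per_cycle_amount",
                          "annual_amount", "death_cost"):
                money(f"{prefix}.{bundle}.{fname}", getattr(b, fname))
        for j, opt in enumerate(arm.next_line_mix):
            money(f"{prefix}.next_line_mix[{j}].course_cost", opt.course_cost)
            if opt.utility is not None:
                utility(f"{prefix}.next_line_mix[{j}].utility", opt.utility)
            specs.append(ParamSpec(
                f"{prefix}.next_line_mix[{j}].proportion", opt.proportion,
                *pm20(opt.proportion, hi_cap=1.0), "dirichlet-group",
                group=f"{prefix}.next_line_mix",
            ))
    return specs


# --- deterministic (tornado) ----------------------------------------------

def run_dsa(
    scenario: Scenario,
    arms: Sequence[ArmModel],
    specs: Sequence[ParamSpec] | None = None,
) -> pd.DataFrame:
    """One-way sensitivity analysis, sorted by descending NMB span.

    Dirichlet-group (proportion) specs are skipped: a single simplex
    coordinate cannot move while the others stay fixed; proportion
    uncertainty is exercised jointly in the PSA instead.
    """
    ws = _Workspace(scenario, list(arms))
    if specs is None:
        specs = default_param_specs(scenario, arms)
    wtp = scenario.wtp_threshold
    rows = []
    for spec in specs:
        if spec.distribution == "dirichlet-group":
            continue
        get_param(ws, spec.path)  # raises a named error if unresolvable
        results = {}
        for side, value in (("low", spec.low), ("high", spec.high)):
            dc, dq = _evaluate_deltas(ws.perturbed({spec.path: value}))
            inc = icer(
                CEResult("i", None, True, float("nan"), dq, dc),
                CEResult("c", None, True, float("nan"), 0.0, 0.0),
                wtp,
            )
            results[side] = (inc.icer_value, inc.nmb_at_wtp)
        rows.append({
            "parameter": spec.path,
            "low": spec.low,
            "high": spec.high,
            "icer_low": results["low"][0],
            "icer_high": results["high"][0],
            "nmb_low": results["low"][1],
            "nmb_high": results["high"][1],
            "span": abs(results["high"][1] - results["low"][1]),
        })
    out = pd.DataFrame(rows).sort_values("span", ascending=False, kind="stable")
    return out.reset_index(drop=True)


# --- probabilistic ---------------------------------------------------------

def _beta_from_range(base: float, low: float, high: float, rng):
    sd = (high - low) / (2 * _Z95)
    if sd == 0 or not 0.0 < base < 1.0:
        return lambda n: np.full(n, base)
    m, v = base, sd**2
    v = min(v, m * (1 - m) * 0.999)  # keep a valid beta
    common = m * (1 - m) / v - 1
    a, b = m * common, (1 - m) * common
    return lambda n: rng.beta(a, b, size=n)


def _gamma_from_range(base: float, low: float, high: float, rng):
    sd = (high - low) / (2 * _Z95)
    if sd == 0 or base == 0:
        return lambda n: np.full(n, base)
    shape = (base / sd) ** 2
    scale = sd**2 / base
    return lambda n: rng.gamma(shape, scale, size=n)


def _lognormal_from_range(base: float, low: float, high: float, rng):
    cv = (high - low) / (2 * _Z95) / base if base > 0 else 0.0
    if cv == 0:
        return lambda n: np.full(n, base)
    sigma = np.sqrt(np.log1p(cv**2))
    mu = np.log(base) - sigma**2 / 2  # mean-preserving
    return lambda n: rng.lognormal(mu, sigma, size=n)


def run_psa(
    scenario: Scenario,
    arms: Sequence[ArmModel],
    specs: Sequence[ParamSpec] | None = None,
    n: int = 10_000,
    seed: int = 0,
) -> PSAResult:
    """Joint Monte-Carlo over all parameters; returns incremental draws.

    Utilities draw from betas matched to mean and range-implied variance
    (rescaled onto [floor, 1] when the range dips below 0); costs from
    gammas; each arm's next-line proportions from one Dirichlet with
    effective sample size 84 (the per-arm trial size); survival
    parameters from mean-preserving lognormals with a 10% CV. ``fixed``
    parameters stay at base. Same seed, same draws.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    ws = _Workspace(scenario, list(arms))
    if specs is None:
        specs = default_param_specs(scenario, arms)
    samples = sample_parameters(specs, n, seed)

    base_dc, base_dq = _evaluate_deltas(ws)
    dcs = np.empty(n)
    dqs = np.empty(n)
    for i in range(n):
        assignment = {path: float(vals[i]) for path, vals in samples.items()}
        dcs[i], dqs[i] = _evaluate_deltas(ws.perturbed(assignment))
    draws_df = pd.DataFrame({"delta_cost": dcs, "delta_qaly": dqs})
    draws_df.index.name = "draw"
    return PSAResult(draws_df, base_dc, base_dq, n, seed)


def sample_parameters(
    specs: Sequence[ParamSpec], n: int, seed: int
) -> dict[str, np.ndarray]:
    """Draw the joint parameter sample matrix used by :func:`run_psa`."""
    rng = np.random.default_rng(seed)
    samples: dict[str, np.ndarray] = {}
    groups: dict[str, list[ParamSpec]] = {}
    for spec in specs:
        if spec.distribution == "dirichlet-group":
            groups.setdefault(spec.group or spec.path, []).append(spec)
            continue
        if spec.distribution == "fixed":
            samples[spec.path] = np.full(n, spec.base)
        elif spec.distribution == "beta":
            if spec.low < 0:  # rescale onto [floor, 1]
                span = 1.0 - UTILITY_FLOOR
                draw = _beta_from_range(
                    (spec.base - UTILITY_FLOOR) / span,
                    (spec.low - UTILITY_FLOOR) / span,
                    (spec.high - UTILITY_FLOOR) / span, rng)
                samples[spec.path] = UTILITY_FLOOR + span * draw(n)
            else:
                samples[spec.path] = _beta_from_range(spec.base, spec.low, spec.high, rng)(n)
        elif spec.distribution == "gamma":
            samples[spec.path] = _gamma_from_range(spec.base, spec.low, spec.high, rng)(n)
        elif spec.distribution == "lognormal":
            samples[spec.path] = _lognormal_from_range(spec.base, spec.low, spec.high, rng)(n)
    for gname, members in groups.items():
        bases = np.array([m.base for m in members])
        if np.any(bases <= 0):
            keep = bases > 0
            alpha = DIRICHLET_ESS * bases[keep]
            draws = np.zeros((n, len(members)))
            draws[:, keep] = rng.dirichlet(alpha, size=n) * bases[keep].sum()
            draws[:, ~keep] = bases[~keep]
        else:
            draws = rng.dirichlet(DIRICHLET_ESS * bases, size=n)
        for j, m in enumerate(members):
            samples[m.path] = draws[:, j]
    return samples


def ceac(psa: PSAResult, wtp_grid: Sequence[float]) -> CEACCurve:
    """Cost-effectiveness acceptability curve from PSA draws.

    At each willingness-to-pay value, the probability is the fraction of
    draws with strictly positive net monetary benefit (ties count as not
    cost-effective).
    """
    if psa.draws.empty:
        raise ValidationError("no PSA draws")
    wtp = np.asarray(list(wtp_grid), float)
    dc = psa.draws["delta_cost"].to_numpy()
    dq = psa.draws["delta_qaly"].to_numpy()
    prob = np.array([(w * dq - dc > 0).mean() for w in wtp])
    return CEACCurve(wtp, prob)
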