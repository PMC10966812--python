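"""Parametric survival laws for extrapolating trial PFS and OS curves.

The cohort model reads state occupancy directly off a pair of survival
curves (partitioned survival): progression-free occupancy is S_PFS(t),
the dead state is 1 - S_OS(t), and progressive disease is the gap between
the two. Curves are fitted either to published summary points (e.g. the
modelled survival probabilities a paper prints at a few months) or to
right-censored individual-patient data, and extrapolated over a lifetime
horizon. Five conventional families are supported; the log-logistic,
S(t) = 1 / (1 + (t / alpha)^beta), is the default in the shipped configs
because logit S(t) is exactly linear in log t, which makes the point fit
a closed-form regression.

Time is measured in months throughout this module; the cohort engine
converts to years at its boundary (one cycle = 3 months = 0.25 years).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "FAMILIES",
    "ParametricSurvival",
    "FitDiagnostics",
    "SurvivalPoints",
    "survival_at",
    "inverse_survival",
    "fit_points",
    "fit_ipd",
    "compare_fits",
    "FitComparison",
    "occupancy_from_curves",
]

FAMILIES = ("exponential", "weibull", "gompertz", "lognormal", "loglogistic")


class SurvivalError(ValueError):
    """Invalid survival input (domain violation or unusable data)."""


@dataclass(frozen=True)
class FitDiagnostics:
    """Goodness-of-fit record attached to a fitted curve.

    ``log_likelihood``, ``aic`` and ``bic`` are populated for censored
    maximum-likelihood fits (AIC = -2 loglik + 2k, BIC with log n);
    ``sse`` (on the probability scale) for summary-point fits.
    ``parameter_covariance`` is the 2x2 covariance of (alpha, beta) from
    the MLE information matrix; point fits leave it ``None`` because a
    regression through near-noiseless model-generated points carries no
    meaningful sampling uncertainty.
    """

    log_likelihood: float | None = None
    aic: float | None = None
    bic: float | None = None
    sse: float | None = None
    parameter_covariance: np.ndarray | None = None


@dataclass(frozen=True)
class ParametricSurvival:
    """A fitted (or specified) parametric survival law.

    ``scale_alpha`` is in months and ``shape_beta`` dimensionless; the
    exponential ignores the shape. ``fitted_from`` records provenance:
    ``"points"`` (summary-point regression), ``"ipd"`` (censored MLE) or
    ``"specified"`` (parameters given directly).
    """

    family: str
    scale_alpha: float
    shape_beta: float = 1.0
    fitted_from: str = "specified"
    diagnostics: FitDiagnostics | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise SurvivalError(f"unknown survival family {self.family!r}")
        if not self.scale_alpha > 0:
            raise SurvivalError(f"scale_alpha must be > 0, got {self.scale_alpha}")
        if self.family != "exponential" and not self.shape_beta > 0:
            raise SurvivalError(f"shape_beta must be > 0, got {self.shape_beta}")
        if self.fitted_from not in ("points", "ipd", "specified"):
            raise SurvivalError(f"unknown provenance {self.fitted_from!r}")

    def survival(self, t):
        return survival_at(self, t)


@dataclass(frozen=True)
class SurvivalPoints:
    """Summary survival points (time in months, survival probability)."""

    time_months: tuple[float, ...]
    survival_probability: tuple[float, ...]

    def __post_init__(self) -> None:
        t = np.asarray(self.time_months, float)
        s = np.asarray(self.survival_probability, float)
        if t.size != s.size:
            raise SurvivalError("time and survival columns differ in length")
        if t.size and not np.all(t > 0):
            raise SurvivalError("survival points require time > 0")
        if np.any(np.diff(t) <= 0):
            raise SurvivalError("times must be strictly increasing")
        if np.any(np.diff(s) > 0):
            raise SurvivalError("survival must be non-increasing")
        if np.any((s <= 0) | (s >= 1)):
            raise SurvivalError(
                "survival values must lie strictly inside (0, 1); "
                "0 and 1 make the fitting transforms undefined"
            )

    @classmethod
    def from_csv(cls, path) -> "SurvivalPoints":
        df = pd.read_csv(path)
        missing = {"time_months", "survival_probability"} - set(df.columns)
        if missing:
            raise SurvivalError(f"points CSV missing columns {sorted(missing)}")
        return cls(tuple(df["time_months"]), tuple(df["survival_probability"]))

    def __len__(self) -> int:
        return len(self.time_months)


# --- survival functions -------------------------------------------------

def _sf(family: str, t: np.ndarray, a: float, b: float) -> np.ndarray:
    with np.errstate(over="ignore", divide="ignore"):
        if family == "exponential":
            return np.exp(-t / a)
        if family == "weibull":
            return np.exp(-((t / a) ** b))
        if family == "gompertz":
            # hazard (b/a) exp(t/a): shape b > 0 guarantees S -> 0
            return np.exp(-b * np.expm1(t / a))
        if family == "lognormal":
            out = np.ones_like(t, dtype=float)
            pos = t > 0
            out[pos] = stats.norm.sf(b * np.log(t[pos] / a))
            return out
        if family == "loglogistic":
            return 1.0 / (1.0 + (t / a) ** b)
    raise SurvivalError(f"unknown survival family {family!r}")


def survival_at(model: ParametricSurvival, t):
    """Evaluate S(t) at ``t`` months (scalar or array). Requires t >= 0."""
    arr = np.asarray(t, dtype=float)
    if np.any(arr < 0):
        raise SurvivalError("survival is undefined at negative times")
    out = _sf(model.family, np.atleast_1d(arr), model.scale_alpha, model.shape_beta)
    out = np.clip(out, 0.0, 1.0)
    return float(out[0]) if arr.ndim == 0 else out


def inverse_survival(model: ParametricSurvival, s):
    """Time t (months) at which S(t) = s; the quantile used by simulators."""
    arr = np.atleast_1d(np.asarray(s, dtype=float))
    if np.any((arr <= 0) | (arr > 1)):
        raise SurvivalError("inverse survival needs s in (0, 1]")
    a, b = model.scale_alpha, model.shape_beta
    fam = model.family
    with np.errstate(divide="ignore"):
        if fam == "exponential":
            out = -a * np.log(arr)
        elif fam == "weibull":
            out = a * (-np.log(arr)) ** (1.0 / b)
        elif fam == "gompertz":
            out = a * np.log1p(-np.log(arr) / b)
        elif fam == "lognormal":
            out = a * np.exp(stats.norm.isf(arr) / b)
        else:  # loglogistic
            out = a * ((1.0 - arr) / arr) ** (1.0 / b)
    out = np.maximum(out, 0.0)
    return float(out[0]) if np.asarray(s).ndim == 0 else out


# --- fitting from summary points ----------------------------------------

def _linearized_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """OLS of y on x returning (alpha, beta) for y = -beta (x - log alpha)."""
    slope, intercept = (float(v) for v in np.polyfit(x, y, 1))
    beta = -slope
    if beta <= 0:
        raise SurvivalError("fitted shape is non-positive; survival not decreasing")
    return math.exp(intercept / beta), beta


def fit_points(points: SurvivalPoints, family: str = "loglogistic") -> ParametricSurvival:
    """Fit a survival law to summary points.

    Log-logistic, Weibull and log-normal use exact linearisations
    (logit S, log(-log S) and probit(1 - S) on log t respectively), so the
    two parameters come from a closed-form least-squares line. The
    exponential is a one-parameter regression through the origin and the
    Gompertz falls back to numeric least squares on the probability scale
    (starting values: alpha at the interpolated median crossing, beta 1).
    ``diagnostics.sse`` is the residual sum of squares on probabilities.
    """
    if family not in FAMILIES:
        raise SurvivalError(f"unknown survival family {family!r}")
    t = np.asarray(points.time_months, float)
    s = np.asarray(points.survival_probability, float)
    n_needed = 1 if family == "exponential" else 2
    if len(points) < n_needed:
        raise SurvivalError(f"{family} fit needs at least {n_needed} points")

    logt = np.log(t)
    if family == "loglogistic":
        a, b = _linearized_fit(logt, np.log(s / (1 - s)))
    elif family == "weibull":
        a, b = _linearized_fit(logt, -np.log(-np.log(s)))
    elif family == "lognormal":
        a, b = _linearized_fit(logt, -stats.norm.ppf(1 - s))
    elif family == "exponential":
        # -log S = t / alpha: least squares through the origin
        y = -np.log(s)
        a, b = float(np.dot(t, t) / np.dot(t, y)), 1.0
    else:  # gompertz: no exact linearisation
        median_t = float(np.interp(0.5, s[::-1], t[::-1])) if s.min() < 0.5 < s.max() else float(t[-1])
        res = optimize.least_squares(
            lambda p: _sf("gompertz", t, math.exp(p[0]), math.exp(p[1])) - s,
            x0=[math.log(median_t), 0.0],
        )
        a, b = math.exp(res.x[0]), math.exp(res.x[1])

    model = ParametricSurvival(family, a, b, fitted_from="points")
    sse = float(np.sum((survival_at(model, t) - s) ** 2))
    return replace(model, diagnostics=FitDiagnostics(sse=sse))


# --- fitting from individual-patient data --------------------------------

_LIFELINES_MAP = {
    "exponential": ("ExponentialFitter", ("lambda_",)),
    "weibull": ("WeibullFitter", ("lambda_", "rho_")),
    "lognormal": ("LogNormalFitter", ("mu_", "sigma_")),
    "loglogistic": ("LogLogisticFitter", ("alpha_", "beta_")),
}


def _gompertz_mle(time: np.ndarray, event: np.ndarray):
    """Censored Gompertz MLE in log-parameter space (no lifelines fitter)."""

    def negll(p):
        a, b = np.exp(p)
        # log h(t) = log(b/a) + t/a ; H(t) = b (exp(t/a) - 1)
        ll = np.sum(event * (np.log(b / a) + time / a)) - np.sum(b * np.expm1(time / a))
        return -ll

    start = np.log([max(float(np.mean(time)), 1e-6), 0.5])
    res = optimize.minimize(negll, start, method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
    loga, logb = res.x
    # observed information on the log scale by central differences
    h = 1e-5
    H = np.zeros((2, 2))
    for i in range(2):
        for j in range(2):
            pij = res.x.copy()
            pts = []
            for si, sj in ((h, h), (h, -h), (-h, h), (-h, -h)):
                p = res.x.copy()
                p[i] += si
                p[j] += sj
                pts.append(negll(p))
            H[i, j] = (pts[0] - pts[1] - pts[2] + pts[3]) / (4 * h * h)
    try:
        cov_log = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov_log = np.full((2, 2), np.nan)
    a, b = math.exp(loga), math.exp(logb)
    jac = np.diag([a, b])  # d(param)/d(log param)
    return a, b, -res.fun, jac @ cov_log @ jac.T


def fit_ipd(data: pd.DataFrame, family: str = "loglogistic") -> ParametricSurvival:
    """Maximum-likelihood fit to right-censored event times.

    ``data`` needs columns ``time_months`` (> 0) and ``event`` (1 event,
    0 censored) — the IPD CSV dialect. The four families lifelines covers
    are delegated to its fitters; the Gompertz likelihood is maximised
    directly. Diagnostics carry the log-likelihood, AIC, BIC and the
    (alpha, beta) covariance.
    """
    if family not in FAMILIES:
        raise SurvivalError(f"unknown survival family {family!r}")
    missing = {"time_months", "event"} - set(data.columns)
    if missing:
        raise SurvivalError(f"IPD table missing columns {sorted(missing)}")
    time = np.asarray(data["time_months"], float)
    event = np.asarray(data["event"], float)
    if np.any(time <= 0):
        raise SurvivalError("event times must be positive")
    if not np.any(event == 1):
        raise SurvivalError("all observations censored; nothing to fit")

    n = len(time)
    if family == "gompertz":
        a, b, ll, cov = _gompertz_mle(time, event)
        k = 2
    else:
        import lifelines

        cls, names = _LIFELINES_MAP[family]
        fitter = getattr(lifelines, cls)().fit(time, event)
        raw = [float(getattr(fitter, name)) for name in names]
        V = fitter.variance_matrix_.to_numpy()
        if family == "exponential":
            a, b, k = raw[0], 1.0, 1
            cov = np.array([[V[0, 0], 0.0], [0.0, 0.0]])
        elif family == "lognormal":
            mu, sigma = raw
            a, b, k = math.exp(mu), 1.0 / sigma, 2
            jac = np.array([[math.exp(mu), 0.0], [0.0, -1.0 / sigma**2]])
            cov = jac @ V @ jac.T
        else:  # weibull (lambda, rho) and loglogistic (alpha, beta) map directly
            a, b, k = raw[0], raw[1], 2
            cov = V
        ll = float(fitter.log_likelihood_)

    diag = FitDiagnostics(
        log_likelihood=ll,
        aic=-2.0 * ll + 2.0 * k,
        bic=-2.0 * ll + k * math.log(n),
        parameter_covariance=cov,
    )
    return ParametricSurvival(family, a, b, fitted_from="ipd", diagnostics=diag)


# --- model comparison ----------------------------------------------------

class FitComparison(NamedTuple):
    ranked: list[ParametricSurvival]
    table: pd.DataFrame


def compare_fits(
    models: Sequence[ParametricSurvival],
    eval_times: Iterable[float] | None = None,
    observed: SurvivalPoints | None = None,
) -> FitComparison:
    """Rank fitted models for selection (ascending AIC, BIC tie-break).

    All models must share provenance and carry diagnostics; summary-point
    fits (no likelihood) rank by SSE instead. The returned table lists one
    row per model with its criteria and, when ``eval_times`` (or observed
    points) are given, fitted survival alongside the observations — the
    "visual inspection" companion to the information criteria.
    """
    models = list(models)
    if not models:
        raise SurvivalError("no models to compare")
    provenances = {m.fitted_from for m in models}
    if len(provenances) > 1:
        raise SurvivalError(f"mixed fit provenance {sorted(provenances)}; refit on identical data")
    if any(m.diagnostics is None for m in models):
        raise SurvivalError("all models need populated diagnostics")

    by_points = provenances == {"points"}

    def key(m: ParametricSurvival):
        d = m.diagnostics
        return (d.sse,) if by_points else (d.aic, d.bic)

    ranked = sorted(models, key=key)  # sorted() is stable: ties keep input order

    if eval_times is None and observed is not None:
        eval_times = observed.time_months
    rows = []
    for m in ranked:
        d = m.diagnostics
        row = {
            "family": m.family,
            "alpha": m.scale_alpha,
            "beta": m.shape_beta,
            "aic": d.aic,
            "bic": d.bic,
            "sse": d.sse,
        }
        if eval_times is not None:
            for t in eval_times:
                row[f"S({t:g}m)"] = survival_at(m, t)
        rows.append(row)
    table = pd.DataFrame(rows)
    if observed is not None:
        obs_row = {"family": "observed"}
        for t, s in zip(observed.time_months, observed.survival_probability):
            obs_row[f"S({t:g}m)"] = s
        table = pd.concat([table, pd.DataFrame([obs_row])], ignore_index=True)
    return FitComparison(ranked, table)


# --- partitioned-survival occupancy --------------------------------------

def occupancy_from_curves(
    pfs: ParametricSurvival,
    os: ParametricSurvival,
    grid_months: np.ndarray,
) -> pd.DataFrame:
    """Three-state occupancy (pfs, pd, dead) on a cycle grid.

    Partitioned-survival construction: PFS occupancy is S_PFS(t), the dead
    state 1 - S_OS(t), progressive disease the gap S_OS - S_PFS. If the
    fitted curves cross (S_PFS > S_OS), the deficit is resolved in favour
    of OS — PFS is reduced to S_OS so PD stays at 0 and rows still sum to
    one exactly; the clamped mass is reported in ``df.attrs["clamped"]``.
    """
    grid = np.asarray(grid_months, float)
    if grid.size == 0 or grid[0] != 0:
        raise SurvivalError("cycle grid must start at 0")
    steps = np.diff(grid)
    if grid.size > 1 and not np.allclose(steps, steps[0]):
        raise SurvivalError("cycle grid must have a constant step")
    s_pfs = survival_at(pfs, grid)
    s_os = survival_at(os, grid)
    clamped = float(np.sum(np.maximum(s_pfs - s_os, 0.0)))
    s_pfs = np.minimum(s_pfs, s_os)
    df = pd.DataFrame(
        {"pfs": s_pfs, "pd": s_os - s_pfs, "dead": 1.0 - s_os},
        index=pd.Index(grid, name="time_months"),
    )
    df.attrs["clamped"] = clamped
    return df
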