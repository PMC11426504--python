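"""Stochastic ten-year harvest projections under landings scenarios.

Five standard scenarios contrast harvest policies: constant catch at the
MSY, at the average total latent productivity (TLP), at the historical
average landings (AL), and at 75% and 50% of AL.  MSY- and TLP-level
catches carry a 25% implementation CV; AL uses the historical CV and the
scaled scenarios scale the CV proportionally.  Each replicate draws one
(K, p, r) parameter set from unbounded normals centred on the estimates
with SD equal to the standard errors (infeasible draws rejected and
redrawn), draws annual catches from a normal truncated one standard
deviation to each side of the expectation (and at zero), and iterates the
Pella-Tomlinson recursion.  Realized catch in a year cannot exceed the
available biomass; biomass reaching zero is absorbing (a collapse).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

__all__ = [
    "Scenario",
    "build_scenarios",
    "project_stochastic",
    "project_scenarios",
    "ProjectionResult",
    "summarize_bands",
]

_REDRAW_CAP = 1000


@dataclass(frozen=True)
class Scenario:
    """A constant-expectation landings policy with implementation error."""
    label: str
    mean_catch: float  # tonnes per year
    cv: float

    def __post_init__(self):
        if self.mean_catch < 0:
            raise ValueError("scenario catch must be non-negative")
        if self.cv < 0:
            raise ValueError("scenario CV must be non-negative")


def build_scenarios(msy_tonnes: float, tlp_tonnes: float,
                    historical_landings) -> list[Scenario]:
    """The five standard scenarios from reference points and history.

    MSY and TLP scenarios carry a 25% CV (wide implementation error); the
    average-landings scenario uses the historical mean and CV; the 75% and
    50% scenarios scale both the mean and the CV proportionally.
    """
    if msy_tonnes is None or tlp_tonnes is None:
        raise ValueError("reference points required to build scenarios")
    hist = np.asarray(historical_landings, dtype=float)
    if hist.size < 1:
        raise ValueError("historical landings series required")
    mean = float(np.mean(hist))
    cv = float(np.std(hist, ddof=1) / mean) if hist.size > 1 and mean > 0 else 0.0
    return [
        Scenario("MSY", float(msy_tonnes), 0.25),
        Scenario("TLP", float(tlp_tonnes), 0.25),
        Scenario("AL", mean, cv),
        Scenario("0.75AL", 0.75 * mean, 0.75 * cv),
        Scenario("0.50AL", 0.50 * mean, 0.50 * cv),
    ]


@dataclass
class ProjectionResult:
    """Replicate trajectories and their summary for one scenario."""
    scenario: Scenario
    years: np.ndarray
    biomass: np.ndarray          # (n_reps, n_years + 1); column 0 = start
    realized_catch: np.ndarray   # (n_reps, n_years)
    collapsed_at: np.ndarray     # year index of first collapse, -1 if none

    @property
    def n_reps(self) -> int:
        return self.biomass.shape[0]

    def summary(self) -> pd.DataFrame:
        return summarize_bands(self)

    def collapse_probability(self) -> float:
        return float(np.mean(self.collapsed_at >= 0))

    def plot(self, ax=None):
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        s = self.summary()
        ax.fill_between(s["year"], s["lo"], s["hi"], alpha=0.3,
                        color="steelblue", label="mean +/- 2 SE")
        ax.plot(s["year"], s["mean"], color="steelblue")
        ax.set_title(self.scenario.label)
        ax.set_xlabel("year")
        ax.set_ylabel("biomass (tonnes)")
        return ax


def _draw_params(rng, est: dict, se: dict):
    """One feasible (K, p, r) draw from unbounded normals (reject/redraw)."""
    for _ in range(_REDRAW_CAP):
        K = rng.normal(est["K"], se["K"])
        p = rng.normal(est["p"], se["p"])
        r = rng.normal(est["r"], se["r"])
        if K > 0 and p > 1.0 and r > 0:
            return K, p, r
    raise RuntimeError(
        f"no feasible (K, p, r) draw in {_REDRAW_CAP} tries; SEs too wide")


def _catch_draws(u: np.ndarray, mean: float, cv: float) -> np.ndarray:
    """Inverse-CDF truncated-normal catches from common uniforms.

    Truncation at one SD each side of the expectation and at zero.
    """
    if mean == 0 or cv == 0:
        return np.full_like(u, mean)
    sd = cv * mean
    lo = max(0.0, mean - sd)
    hi = mean + sd
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.ppf(u, a, b, loc=mean, scale=sd)


def project_stochastic(fit, scenario: Scenario, years: int = 10,
                       n_reps: int = 1000, seed=None,
                       b_init: float | None = None,
                       period: int = 2) -> ProjectionResult:
    """Stochastic projection of a fitted production model.

    ``fit`` is a :class:`~fluctstock.production.PellaTomlinsonResults`
    (post-switch regime parameters and SEs are used by default) or a dict
    with keys ``est`` = {K, p, r}, ``se`` = {K, p, r}, ``b_init`` and
    ``first_year``.  Starting biomass defaults to the fitted trajectory's
    final year.  A fixed seed makes the result bit-reproducible.
    """
    est, se, start_b, first_year = _unpack_fit(fit, period)
    if b_init is not None:
        start_b = float(b_init)
    rng = np.random.default_rng(seed)
    n_years = int(years)
    biomass = np.empty((n_reps, n_years + 1))
    realized = np.empty((n_reps, n_years))
    collapsed_at = np.full(n_reps, -1, dtype=int)
    for rep in range(n_reps):
        K, p, r = _draw_params(rng, est, se)
        u = rng.random(n_years)
        catches = _catch_draws(u, scenario.mean_catch, scenario.cv)
        B = start_b
        biomass[rep, 0] = B
        for y in range(n_years):
            if B <= 0.0:
                realized[rep, y] = 0.0
                biomass[rep, y + 1] = 0.0
                continue
            growth = r * B * (1.0 - (B / K) ** (p - 1.0))
            avail = max(B + growth, 0.0)
            c = min(catches[y], avail)  # catch cannot exceed what is there
            realized[rep, y] = c
            B = avail - c
            if B <= 0.0:
                B = 0.0
                if collapsed_at[rep] < 0:
                    collapsed_at[rep] = y
            biomass[rep, y + 1] = B
    yrs = first_year + np.arange(n_years + 1)
    return ProjectionResult(scenario=scenario, years=yrs, biomass=biomass,
                            realized_catch=realized, collapsed_at=collapsed_at)


def project_scenarios(fit, scenarios, years: int = 10, n_reps: int = 1000,
                      seed=None, b_init=None, period: int = 2) -> dict:
    """Project several scenarios with common random numbers.

    Every scenario re-uses the same seed, hence the same parameter draws
    and catch-quantile stream, which makes collapse probabilities directly
    comparable across catch levels.
    """
    return {sc.label: project_stochastic(fit, sc, years=years, n_reps=n_reps,
                                         seed=seed, b_init=b_init,
                                         period=period)
            for sc in scenarios}


def _unpack_fit(fit, period: int):
    if isinstance(fit, dict):
        return (fit["est"], fit["se"], float(fit["b_init"]),
                int(fit.get("first_year", 0)))
    full = fit.full_params
    bse = fit.bse
    est = {"K": full[f"K{period}"], "p": full[f"p{period}"],
           "r": full[f"r{period}"]}
    se = {}
    for base in ("K", "p", "r"):
        if base in fit.regime.change:
            se[base] = float(bse[f"{base}{period}"])
        else:
            se[base] = float(bse[base])
    start_b = float(fit.fittedvalues.iloc[-1])
    first_year = int(fit.fittedvalues.index[-1])
    return est, se, start_b, first_year


def summarize_bands(result: ProjectionResult) -> pd.DataFrame:
    """Per-year mean, mean +/- 2 SE bands and collapse probability.

    SE is the replicate standard deviation divided by sqrt(n_reps); the
    lower band is floored at zero for reporting.
    """
    if result.n_reps < 2:
        raise ValueError("need at least two replicates to summarize")
    mean = result.biomass.mean(axis=0)
    se = result.biomass.std(axis=0, ddof=1) / np.sqrt(result.n_reps)
    # collapse probability by year: replicate has collapsed at or before y
    n_years = result.biomass.shape[1] - 1
    pcol = np.zeros(n_years + 1)
    for y in range(1, n_years + 1):
        pcol[y] = np.mean((result.collapsed_at >= 0) &
                          (result.collapsed_at <= y - 1))
    return pd.DataFrame({
        "year": result.years,
        "mean": mean,
        "lo": np.maximum(mean - 2.0 * se, 0.0),
        "hi": mean + 2.0 * se,
        "p_collapse": pcol,
    })
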