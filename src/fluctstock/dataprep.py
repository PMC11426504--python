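"""Trip-level records to weekly season tables; mean-weight completion.

Trip records (sailing date, catch weight, effort in effective fishing
days) are aggregated to the weekly time step of each annual fishing
season, with each trip attributed wholly to its week of sailing.  The
mean individual weight per week, needed to convert catch weight into
catch numbers, is completed by smoothing all available biological samples
against week-of-season (pooled across years) and replacing every week's
value -- observed or missing -- with a draw from a truncated normal
centred on the smoothed prediction, truncated at two prediction standard
errors.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, datetime

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.interpolate import BSpline
from scipy.stats import truncnorm

__all__ = [
    "SeasonCalendar",
    "aggregate_trips",
    "AggregationResult",
    "MeanWeightSmoother",
    "impute_mean_weights",
    "catch_numbers",
]

MEAN_WEIGHT_FLOOR_KG = 1e-3  # lower truncation floor when mean - 2 SE < 0


@dataclass(frozen=True)
class SeasonCalendar:
    """Annual season window; default August through December."""
    start_month: int = 8
    start_day: int = 1
    end_month: int = 12
    end_day: int = 31

    def season_of(self, d: date):
        """Season year of a sailing date, or None when outside the window."""
        start = date(d.year, self.start_month, self.start_day)
        end = date(d.year, self.end_month, self.end_day)
        return d.year if start <= d <= end else None

    def week_of(self, d: date) -> int:
        """Week index within the season, t = 1 at the opening week."""
        start = date(d.year, self.start_month, self.start_day)
        return (d - start).days // 7 + 1


@dataclass
class AggregationResult:
    tables: dict  # season year -> weekly DataFrame
    n_rejected: int

    def combined(self) -> pd.DataFrame:
        return pd.concat(self.tables.values(), ignore_index=True)


def aggregate_trips(trips: pd.DataFrame,
                    calendar: SeasonCalendar = SeasonCalendar()) -> AggregationResult:
    """Aggregate trip records to one weekly table per season.

    ``trips`` needs columns ``date`` (sailing date), ``catch_weight_kg``
    and ``effort_days``; an optional ``species_label`` is carried through.
    Each trip's whole catch and effort is assigned to the week of sailing
    (multi-week trips incur a tolerated time-attribution error rather than
    being pro-rated).  Weeks without trips appear with zero effort and
    catch.  Trips outside every season window are rejected and counted.
    """
    if trips.empty:
        return AggregationResult(tables={}, n_rejected=0)
    t = trips.copy()
    if np.any(t["effort_days"].to_numpy() < 0) or \
            np.any(t["catch_weight_kg"].to_numpy() < 0):
        raise ValueError("effort and catch must be non-negative")
    dates = [_as_date(d) for d in t["date"]]
    seasons = [calendar.season_of(d) for d in dates]
    weeks = [calendar.week_of(d) if s is not None else -1
             for d, s in zip(dates, seasons)]
    t["season"] = seasons
    t["week"] = weeks
    rejected = int(sum(s is None for s in seasons))
    t = t[t["season"].notna()]
    label = (t["species_label"].iloc[0]
             if "species_label" in t.columns and len(t) else "unknown")

    tables = {}
    for season, grp in t.groupby("season"):
        agg = grp.groupby("week").agg(
            effort_days=("effort_days", "sum"),
            catch_weight_kg=("catch_weight_kg", "sum"),
        )
        full = agg.reindex(range(1, int(agg.index.max()) + 1), fill_value=0.0)
        out = full.reset_index().rename(columns={"index": "week"})
        out.insert(0, "season", int(season))
        out.insert(0, "species_label", label)
        tables[int(season)] = out
    return AggregationResult(tables=tables, n_rejected=rejected)


def _as_date(d) -> date:
    if isinstance(d, datetime):
        return d.date()
    if isinstance(d, date):
        return d
    return pd.Timestamp(d).date()


# ---------------------------------------------------------------------------
# mean-weight smoothing
# ---------------------------------------------------------------------------

class MeanWeightSmoother:
    """Cubic-spline smoother of mean individual weight against week.

    A penalized-equivalent regression spline: ordinary least squares on a
    cubic B-spline basis, with the basis dimension chosen by generalized
    cross-validation.  ``predict`` returns the expected mean weight and
    the prediction standard error for a typical season (residual scale
    plus mean uncertainty); requesting weeks outside the sampled range is
    an error rather than a silent extrapolation.
    """

    def __init__(self, df_grid=range(4, 13)):
        self.df_grid = list(df_grid)
        self._fit = None

    def fit(self, weeks, weights_kg) -> "MeanWeightSmoother":
        weeks = np.asarray(weeks, dtype=float)
        weights_kg = np.asarray(weights_kg, dtype=float)
        if len(weeks) < 10:
            raise ValueError("need at least 10 mean-weight samples")
        if np.any(weights_kg <= 0):
            raise ValueError("individual weights must be positive")
        self.week_range = (float(weeks.min()), float(weeks.max()))
        n = len(weeks)
        best = None
        for df in self.df_grid:
            if df + 1 >= n or df < 4:
                continue
            X = self._basis(weeks, df)
            res = sm.OLS(weights_kg, X).fit()
            tr_h = X.shape[1]  # trace of the hat matrix for OLS on the basis
            denom = (1.0 - tr_h / n) ** 2
            gcv = (res.ssr / n) / denom if denom > 0 else np.inf
            if best is None or gcv < best[0]:
                best = (gcv, df, res)
        if best is None:
            raise ValueError("no admissible basis dimension for this sample size")
        self.gcv_, self.df_, self._res = best
        self.n_samples = n
        self._fit = True
        return self

    def _knots(self, df: int) -> np.ndarray:
        lo, hi = self.week_range
        k = 3
        n_inner = df - k - 1
        inner = np.linspace(lo, hi, n_inner + 2)[1:-1] if n_inner > 0 else []
        return np.r_[[lo] * (k + 1), inner, [hi] * (k + 1)]

    def _basis(self, weeks, df: int) -> np.ndarray:
        t = self._knots(df)
        x = np.clip(weeks, *self.week_range)
        return BSpline.design_matrix(x, t, 3).toarray()

    def predict(self, weeks):
        """(expected mean weight, prediction SE) at the given weeks."""
        if not self._fit:
            raise ValueError("smoother not fitted")
        weeks = np.asarray(weeks, dtype=float)
        lo, hi = self.week_range
        if np.any(weeks < lo) or np.any(weeks > hi):
            raise ValueError(
                f"weeks outside the sampled range [{lo:g}, {hi:g}]; "
                "no silent extrapolation")
        X = self._basis(weeks, self.df_)
        pred = self._res.get_prediction(X)
        mean = pred.predicted_mean
        se = pred.se_obs  # prediction SE of a new observation
        if np.any(mean <= 0):
            raise ValueError("smoother predicts non-positive mean weight")
        return mean, se


def impute_mean_weights(smoother: MeanWeightSmoother, season_weeks: dict,
                        seed, replace_observed: bool = True,
                        observed: dict | None = None) -> dict:
    """Randomized-predicted mean weight for every week of every season.

    For each week, draw from a normal with mean = smoothed expectation and
    sd = prediction SE, truncated to a band of two standard deviations
    (lower bound clipped to a small positive floor when it would cross
    zero).  By default both missing and raw observed values are replaced;
    with ``replace_observed=False``, weeks present in ``observed`` keep
    their raw value.

    ``season_weeks`` maps season -> iterable of week indices; returns
    season -> array of imputed mean weights (kg).
    """
    rng = np.random.default_rng(seed)
    out = {}
    for season, weeks in season_weeks.items():
        weeks = np.asarray(list(weeks))
        mean, se = smoother.predict(weeks)
        draws = np.empty(len(weeks))
        for i, (mu, sd) in enumerate(zip(mean, se)):
            if sd <= 0:
                draws[i] = mu
                continue
            lo = max(mu - 2.0 * sd, MEAN_WEIGHT_FLOOR_KG)
            hi = mu + 2.0 * sd
            a, b = (lo - mu) / sd, (hi - mu) / sd
            draws[i] = truncnorm.rvs(a, b, loc=mu, scale=sd, random_state=rng)
        if not replace_observed and observed and season in observed:
            obs = observed[season]
            for i, w in enumerate(weeks):
                if w in obs and np.isfinite(obs[w]) and obs[w] > 0:
                    draws[i] = obs[w]
        out[season] = draws
    return out


def catch_numbers(catch_weight_kg, mean_weight_kg):
    """Convert catch weight to catch in numbers (weight / mean weight)."""
    w = np.asarray(mean_weight_kg, dtype=float)
    if np.any(w <= 0):
        raise ValueError("mean weights must be positive")
    return np.asarray(catch_weight_kg, dtype=float) / w
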