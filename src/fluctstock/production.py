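"""Regime-switching Pella-Tomlinson surplus production models.

Annual biomass dynamics are modelled with the discrete Pella-Tomlinson
recursion

    B_y = B_{y-1} + r_i B_{y-1} (1 - (B_{y-1}/K_i)^{p_i - 1}) - C_{y-1}

where ``K`` is the carrying capacity (tonnes), ``r`` the intrinsic growth
rate (1/yr), ``p > 1`` the shape of the production curve and ``C_y`` the
annual landings, treated as observed without error.  The parameters may
switch between two regimes at a known transition year, giving eight model
variants (change in any subset of {K, p, r}).

The model is fitted to a series of externally estimated annual biomasses
and their standard errors by maximising a self-weighting marginal normal
likelihood: years with precise biomass estimates dominate the fit, years
with vague estimates are automatically down-weighted.

Reference points:

    MSY   = r K (p - 1) p^(-p/(p-1))
    B_MSY = K p^(1/(1-p))
    TLP_y = gamma MSY (B_y/K)(1 - (B_y/K)^(p-1)) + C_y,
            gamma = p^(p/(p-1)) / (p - 1)

The total latent productivity (TLP) generalises the surplus-production
concept to stocks whose biomass fluctuates: it varies with the yearly
biomass, and its multi-year average is a sustainable harvest rate even
when a stable MSY equilibrium does not exist (the unfished map is
unstable whenever r (p - 1) > 2).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "msy",
    "bmsy",
    "gamma_coefficient",
    "tlp",
    "stability_classification",
    "RegimeSpec",
    "pt_step",
    "pt_trajectory",
    "marginal_neg_loglik",
    "PellaTomlinson",
    "PellaTomlinsonResults",
    "fit_all_variants",
    "select_pt_variant",
    "VariantSelectionError",
    "delta_method_se",
]

_COLLAPSE_PENALTY = 1e10


# ---------------------------------------------------------------------------
# closed-form reference points
# ---------------------------------------------------------------------------

def msy(K: float, p: float, r: float) -> float:
    """Maximum sustainable yield r*K*(p-1)*p**(-p/(p-1)) (tonnes)."""
    _check_kpr(K, p, r)
    return r * K * (p - 1.0) * p ** (-p / (p - 1.0))


def bmsy(K: float, p: float) -> float:
    """Biomass producing the MSY, K*p**(1/(1-p)) (tonnes)."""
    _check_kpr(K, p, 1.0)
    return K * p ** (1.0 / (1.0 - p))


def gamma_coefficient(p: float) -> float:
    """Scaling gamma = p^(p/(p-1)) / (p-1) linking MSY and TLP.

    Satisfies the identity gamma * MSY = r * K for every p > 1.
    """
    if p <= 1.0:
        raise ValueError(f"p must exceed 1, got {p}")
    return p ** (p / (p - 1.0)) / (p - 1.0)


def tlp(B, C, K: float, p: float, r: float):
    """Total latent productivity at biomass ``B`` with catch ``C``.

    TLP_y = gamma*MSY*(B/K)*(1-(B/K)^(p-1)) + C.  Vectorised over B, C.
    """
    _check_kpr(K, p, r)
    B = np.asarray(B, dtype=float)
    C = np.asarray(C, dtype=float)
    ratio = B / K
    return gamma_coefficient(p) * msy(K, p, r) * ratio * (1.0 - ratio ** (p - 1.0)) + C


def _check_kpr(K, p, r):
    if K <= 0:
        raise ValueError(f"K must be positive, got {K}")
    if p <= 1.0:
        raise ValueError(f"p must exceed 1, got {p}")
    if r <= 0:
        raise ValueError(f"r must be positive, got {r}")


@dataclass(frozen=True)
class StabilityClass:
    label: str  # "stable" or "oscillatory/unstable"
    boundary: bool = False

    @property
    def stable(self) -> bool:
        return self.label == "stable"


def stability_classification(r: float, p: float, tol: float = 0.0) -> StabilityClass:
    """Classify the unfished equilibrium of the Pella-Tomlinson map.

    The derivative of the unfished map at B = K is 1 - r(p-1); the
    equilibrium is locally unstable (sustained oscillation or chaos) iff
    r(p-1) > 2.  The exact boundary is classified stable with a flag.
    """
    if p <= 1.0 or r <= 0:
        raise ValueError("require p > 1 and r > 0")
    crit = r * (p - 1.0)
    if abs(crit - 2.0) <= tol or crit == 2.0:
        return StabilityClass("stable", boundary=True)
    if crit > 2.0:
        return StabilityClass("oscillatory/unstable")
    return StabilityClass("stable")


# ---------------------------------------------------------------------------
# trajectory and likelihood
# ---------------------------------------------------------------------------

_ALL_CHANGE_SETS = [frozenset(s) for n in range(4)
                    for s in itertools.combinations(("K", "p", "r"), n)]


@dataclass(frozen=True)
class RegimeSpec:
    """Which parameters switch value at the transition year.

    ``change`` is a subset of {"K", "p", "r"}; empty set is the null
    (time-invariant) model.  Eight possible change sets in total.
    """
    switch_year: int
    change: frozenset = frozenset()

    def __post_init__(self):
        object.__setattr__(self, "change", frozenset(self.change))
        if not self.change <= {"K", "p", "r"}:
            raise ValueError(f"change set must be a subset of {{K,p,r}}: {self.change}")

    @property
    def label(self) -> str:
        return "+".join(sorted(self.change)) if self.change else "none"

    def n_params(self) -> int:
        return 3 + len(self.change)


def pt_step(B: float, C: float, K: float, p: float, r: float) -> float:
    """One year of the Pella-Tomlinson recursion."""
    return B + r * B * (1.0 - (B / K) ** (p - 1.0)) - C


def pt_trajectory(params: dict, regime: RegimeSpec, catches, years,
                  b_init: float | None = None):
    """Predicted biomass series under the two-regime recursion.

    Parameters
    ----------
    params : dict with keys K1, K2, p1, p2, r1, r2 (tied values equal).
    catches : annual landings C_y aligned with ``years``; C for the last
        year is unused.
    years : increasing array of calendar years.
    b_init : biomass the year before the series; defaults to K1.

    Returns
    -------
    (B, collapse_index) : predicted biomass per year and the index of the
    first non-positive biomass (None if the trajectory stays positive).
    The series is truncated at zero from the collapse year onwards.
    """
    years = np.asarray(years)
    catches = np.asarray(catches, dtype=float)
    n = len(years)
    if len(catches) != n:
        raise ValueError("catches must align with years")
    B = np.zeros(n)
    prev = params["K1"] if b_init is None else float(b_init)
    collapse = None
    for i, y in enumerate(years):
        if y >= regime.switch_year:
            K, p, r = params["K2"], params["p2"], params["r2"]
        else:
            K, p, r = params["K1"], params["p1"], params["r1"]
        c_prev = 0.0 if i == 0 else catches[i - 1]
        cur = pt_step(prev, c_prev, K, p, r)
        if not np.isfinite(cur) or cur <= 0.0:
            collapse = i
            B[i:] = 0.0
            return B, collapse
        B[i] = cur
        prev = cur
    return B, collapse


def _soft_trajectory(params: dict, regime: RegimeSpec, catches, years,
                     floor: float = 1.0):
    """Trajectory with a positivity floor and the violation magnitudes.

    Where the recursion would drive biomass to ``floor`` or below, the
    trajectory continues from the floor and the shortfall is recorded.
    Keeps the likelihood surface continuous near the collapse boundary
    (a hard penalty cliff makes numerical gradients meaningless there).
    """
    years = np.asarray(years)
    catches = np.asarray(catches, dtype=float)
    n = len(years)
    B = np.zeros(n)
    viol = np.zeros(n)
    prev = params["K1"]
    for i, y in enumerate(years):
        if y >= regime.switch_year:
            K, p, r = params["K2"], params["p2"], params["r2"]
        else:
            K, p, r = params["K1"], params["p1"], params["r1"]
        c_prev = 0.0 if i == 0 else catches[i - 1]
        cur = pt_step(prev, c_prev, K, p, r)
        if not np.isfinite(cur):
            viol[i:] = np.max(np.abs(B[:i])) if i else params["K1"]
            B[i:] = floor
            return B, viol
        if cur <= floor:
            viol[i] = floor - cur
            cur = floor
        B[i] = cur
        prev = cur
    return B, viol


def _nll_and_grad_free(x: np.ndarray, free_names, regime: RegimeSpec,
                       years, bhat, se, catches, floor: float = 1.0):
    """Objective and its exact gradient w.r.t. the free natural parameters.

    Forward-propagates dB_y/dtheta through the recursion (chain rule), so
    stationarity can be verified even where the trajectory's sensitivity
    to parameters is enormous (oscillatory regime) and finite differences
    are useless.
    """
    nfree = len(x)
    idx = {}
    i = 0
    for base in _BASE_ORDER:
        if base in regime.change:
            idx[f"{base}1"], idx[f"{base}2"] = i, i + 1
            i += 2
        else:
            idx[f"{base}1"] = idx[f"{base}2"] = i
            i += 1
    full = {nm: x[j] for nm, j in idx.items()}

    B = full["K1"]
    dB = np.zeros(nfree)
    dB[idx["K1"]] = 1.0
    nll = 0.5 * np.sum(np.log(2.0 * np.pi * se ** 2))
    grad = np.zeros(nfree)
    with np.errstate(over="ignore", invalid="ignore"):
        for i, y in enumerate(years):
            period = "2" if y >= regime.switch_year else "1"
            K, p, r = full["K" + period], full["p" + period], full["r" + period]
            kK, kp, kr = idx["K" + period], idx["p" + period], idx["r" + period]
            c_prev = 0.0 if i == 0 else catches[i - 1]
            u = (B / K) ** (p - 1.0)
            raw = B + r * B * (1.0 - u) - c_prev
            if not np.isfinite(raw) or not np.isfinite(u):
                return 1e12, np.zeros(nfree)
            draw = (1.0 + r * (1.0 - u) - r * (p - 1.0) * u) * dB
            draw[kK] += r * B * (p - 1.0) * u / K
            draw[kp] += -r * B * u * np.log(B / K)
            draw[kr] += B * (1.0 - u)
            if raw <= floor:
                viol = floor - raw
                nll += (viol / se[i]) ** 2
                grad += 2.0 * viol / se[i] ** 2 * (-draw)
                B = floor
                dB = np.zeros(nfree)
            else:
                B = raw
                dB = draw
            resid = bhat[i] - B
            nll += 0.5 * resid ** 2 / se[i] ** 2
            grad += -resid / se[i] ** 2 * dB
    return float(nll), grad


def marginal_neg_loglik(params: dict, observations: pd.DataFrame,
                        regime: RegimeSpec) -> float:
    """Negative self-weighting marginal log-likelihood.

    0.5 * sum_y [log(2 pi s_y^2) + (Bhat_y - B_y)^2 / s_y^2] with B_y from
    the production recursion.  Standard errors s_y act as per-year
    weights, automatically down-weighting imprecise biomass estimates.
    A trajectory that would collapse inside the observation window is
    floored at a token biomass and each year's shortfall enters as an
    additional squared term on the same weighted scale -- a large but
    smooth penalty, so optimizers and finite-difference gradients remain
    informative near the collapse boundary.
    """
    years = observations["year"].to_numpy()
    bhat = observations["biomass"].to_numpy(dtype=float)
    se = observations["biomass_se"].to_numpy(dtype=float)
    if np.any(se <= 0):
        raise ValueError("biomass standard errors must be strictly positive")
    catches = observations["landings"].to_numpy(dtype=float)
    B, viol = _soft_trajectory(params, regime, catches, years)
    nll = 0.5 * np.sum(np.log(2.0 * np.pi * se ** 2) + (bhat - B) ** 2 / se ** 2)
    if np.any(viol > 0):
        nll += np.sum((viol / se) ** 2)
    return float(nll)


# ---------------------------------------------------------------------------
# parameter packing
# ---------------------------------------------------------------------------

_BASE_ORDER = ("K", "p", "r")


def _free_names(regime: RegimeSpec):
    names = []
    for base in _BASE_ORDER:
        if base in regime.change:
            names.extend([f"{base}1", f"{base}2"])
        else:
            names.append(base)
    return names


def _expand(free: dict, regime: RegimeSpec) -> dict:
    full = {}
    for base in _BASE_ORDER:
        if base in regime.change:
            full[f"{base}1"] = free[f"{base}1"]
            full[f"{base}2"] = free[f"{base}2"]
        else:
            full[f"{base}1"] = full[f"{base}2"] = free[base]
    return full


def _to_transformed(x: np.ndarray, names) -> np.ndarray:
    z = np.empty_like(x)
    for i, nm in enumerate(names):
        z[i] = np.log(x[i] - 1.0) if nm.startswith("p") else np.log(x[i])
    return z


def _from_transformed(z: np.ndarray, names) -> np.ndarray:
    x = np.empty_like(z)
    for i, nm in enumerate(names):
        x[i] = 1.0 + np.exp(z[i]) if nm.startswith("p") else np.exp(z[i])
    return x


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

class PellaTomlinson:
    """Regime-switching Pella-Tomlinson model for annual biomass estimates.

    Parameters
    ----------
    observations : DataFrame with columns ``year``, ``biomass`` (tonnes),
        ``biomass_se`` (tonnes) and ``landings`` (tonnes).  Biomass rows are
        the stage-1 start-of-season estimates; landings are exact.
    regime : RegimeSpec giving the switch year and the changing parameters.
    """

    def __init__(self, observations: pd.DataFrame, regime: RegimeSpec):
        required = {"year", "biomass", "biomass_se", "landings"}
        missing = required - set(observations.columns)
        if missing:
            raise ValueError(f"observations missing columns: {sorted(missing)}")
        if len(observations) < 8:
            raise ValueError("need at least 8 annual observations")
        obs = observations.sort_values("year").reset_index(drop=True)
        if np.any(obs["biomass"].to_numpy() <= 0):
            raise ValueError("biomass estimates must be positive")
        if np.any(obs["biomass_se"].to_numpy() <= 0):
            raise ValueError("biomass SEs must be positive")
        if np.any(obs["landings"].to_numpy() < 0):
            raise ValueError("landings must be non-negative")
        self.observations = obs
        self.regime = regime
        self.free_names = _free_names(regime)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, switch_year: int,
                       change=()) -> "PellaTomlinson":
        return cls(df, RegimeSpec(switch_year, frozenset(change)))

    # -- objective ---------------------------------------------------------

    def _nll_free(self, x: np.ndarray) -> float:
        if np.any(~np.isfinite(x)) or np.any(x <= 0):
            return _COLLAPSE_PENALTY
        free = dict(zip(self.free_names, x))
        for nm, v in free.items():
            if nm.startswith("p") and v <= 1.0:
                return _COLLAPSE_PENALTY
        return marginal_neg_loglik(_expand(free, self.regime),
                                   self.observations, self.regime)

    def _nll_transformed(self, z: np.ndarray) -> float:
        return self._nll_free(_from_transformed(z, self.free_names))

    def _nll_grad_transformed(self, z: np.ndarray):
        """Objective and exact gradient on the transformed scale."""
        x = _from_transformed(z, self.free_names)
        if np.any(~np.isfinite(x)):
            return 1e12, np.zeros_like(z)
        obs = self.observations
        nll, g = _nll_and_grad_free(
            x, self.free_names, self.regime,
            obs["year"].to_numpy(), obs["biomass"].to_numpy(dtype=float),
            obs["biomass_se"].to_numpy(dtype=float),
            obs["landings"].to_numpy(dtype=float))
        # chain rule: dx/dz is x for log-scaled, (p-1) for shape params
        dxdz = np.array([x[i] - 1.0 if nm.startswith("p") else x[i]
                         for i, nm in enumerate(self.free_names)])
        return nll, g * dxdz

    def _default_start(self) -> dict:
        b = self.observations["biomass"].to_numpy()
        start = {}
        for nm in self.free_names:
            if nm.startswith("K"):
                start[nm] = float(np.max(b))
            elif nm.startswith("p"):
                start[nm] = 2.0
            else:
                start[nm] = 1.0
        return start

    # -- fitting -----------------------------------------------------------

    def fit(self, start: dict | None = None, r_cap: float = 10.0,
            p_cap: float = 5.0, maxiter: int = 4000, restarts: int = 6,
            restart_seed: int = 0) -> "PellaTomlinsonResults":
        """Maximum likelihood fit: bounded quasi-Newton phase inside wide
        boxes, then free simplex polish.  Estimates sitting on a bound are
        flagged as anomalous rather than accepted.
        """
        if start is None:
            start = self._default_start()
        for nm in self.free_names:
            if nm not in start:
                raise ValueError(f"start value missing for {nm}")
            if nm.startswith("p") and start[nm] <= 1.0:
                raise ValueError(f"start for {nm} must exceed 1")
            if not nm.startswith("p") and start[nm] <= 0:
                raise ValueError(f"start for {nm} must be positive")
        x0 = np.array([float(start[nm]) for nm in self.free_names])
        z0 = _to_transformed(x0, self.free_names)

        # bounded phase: boxes at the plausibility caps (the free polish
        # afterwards may leave them, which is flagged, not silently kept)
        bounds = []
        for nm in self.free_names:
            if nm.startswith("K"):
                bounds.append((np.log(1e1), np.log(1e8)))
            elif nm.startswith("p"):
                bounds.append((np.log(1e-3), np.log(p_cap - 1.0)))
            else:
                bounds.append((np.log(1e-4), np.log(r_cap)))
        # The likelihood surface is rugged when the map is in its
        # oscillatory regime (trajectories are sensitive to parameters), so
        # a simplex multistart precedes the bounded quasi-Newton phase.
        rng = np.random.default_rng(restart_seed)
        starts = [z0] + [z0 + rng.normal(0.0, 0.08, len(z0))
                         for _ in range(restarts)]
        # coarse (r, p) grid pre-screen at the starting K: cycling
        # trajectories alias badly, so basin-finding needs global probes
        k_start = [float(start[nm]) for nm in self.free_names
                   if nm.startswith("K")]
        probes = []
        for r_try in (0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5):
            for p_try in (1.3, 1.6, 2.0, 2.5, 3.0):
                xg = []
                ki = 0
                for nm in self.free_names:
                    if nm.startswith("K"):
                        xg.append(k_start[min(ki, len(k_start) - 1)])
                        ki += 1
                    elif nm.startswith("p"):
                        xg.append(p_try)
                    else:
                        xg.append(r_try)
                zg = _to_transformed(np.array(xg), self.free_names)
                probes.append((self._nll_transformed(zg), zg))
        probes.sort(key=lambda t: t[0])
        starts.extend(zg for _, zg in probes[:3])
        best_z, best_f = z0, self._nll_transformed(z0)
        with np.errstate(all="ignore"):
            for zs in starts:
                nm = optimize.minimize(self._nll_transformed, zs,
                                       method="Nelder-Mead",
                                       options={"maxiter": 2000,
                                                "adaptive": True})
                if nm.fun < best_f:
                    best_z, best_f = nm.x, nm.fun
            z_clamped = np.clip(best_z, [lo for lo, _ in bounds],
                                [hi for _, hi in bounds])
            res1 = optimize.minimize(self._nll_grad_transformed, z_clamped,
                                     jac=True, method="L-BFGS-B",
                                     bounds=bounds,
                                     options={"maxiter": maxiter})
            z_bounded = res1.x
            f_bounded = res1.fun
            # free phase: exact-gradient quasi-Newton polish interleaved
            # with a simplex pass (the quasi-Newton runs verify true
            # stationarity, which finite differences cannot on this
            # steeply curved surface)
            res2 = optimize.minimize(self._nll_grad_transformed, z_bounded,
                                     jac=True, method="BFGS",
                                     options={"maxiter": maxiter,
                                              "gtol": 1e-10})
            res3 = optimize.minimize(self._nll_transformed, res2.x,
                                     method="Nelder-Mead",
                                     options={"maxiter": maxiter, "xatol": 1e-10,
                                              "fatol": 1e-10, "adaptive": True})
            res4 = optimize.minimize(self._nll_grad_transformed, res3.x,
                                     jac=True, method="BFGS",
                                     options={"maxiter": maxiter,
                                              "gtol": 1e-10})
        nll, zhat = min([(res2.fun, res2.x), (res3.fun, res3.x),
                         (res4.fun, res4.x)], key=lambda t: t[0])

        # the (r, p) ridge is flat: when the free polish merely slides
        # toward implausible values without a material likelihood gain,
        # keep the bounded-phase (interior) representative of the ridge
        def _implausible(z):
            x = _from_transformed(z, self.free_names)
            for nm, v in zip(self.free_names, x):
                if nm.startswith("r") and v > r_cap:
                    return True
                if nm.startswith("p") and v > p_cap:
                    return True
            return False

        if (_implausible(zhat) and not _implausible(z_bounded)
                and f_bounded - nll < 1.0):
            zhat, nll = z_bounded, f_bounded
        xhat = _from_transformed(zhat, self.free_names)

        on_bound = any(
            abs(zi - lo) < 1e-6 or abs(zi - hi) < 1e-6
            for zi, (lo, hi) in zip(zhat, bounds)
        )

        _, grad = self._nll_grad_transformed(zhat)
        max_abs_grad = float(np.max(np.abs(grad)))

        from .depletion import _robust_covariance
        cov = _robust_covariance(self._nll_free, self._nll_transformed,
                                 xhat, zhat)

        converged = bool(np.isfinite(nll) and nll < _COLLAPSE_PENALTY
                         and (res2.success or res3.success or res4.success
                              or res1.success or max_abs_grad < 1.0))
        return PellaTomlinsonResults(self, xhat, nll, cov, max_abs_grad,
                                     converged, on_bound, r_cap, p_cap)


class PellaTomlinsonResults:
    """Estimates, uncertainty and derived reference points of a PT fit."""

    def __init__(self, model, xhat, nll, cov, max_abs_grad, converged,
                 on_bound, r_cap, p_cap):
        self.model = model
        self.regime = model.regime
        self.free_names = model.free_names
        self._xhat = np.asarray(xhat, dtype=float)
        self.nll = float(nll)
        self.llf = -self.nll
        self.cov = cov
        self.max_abs_grad = max_abs_grad
        self.converged = converged
        self.on_bound = on_bound
        self.r_cap = r_cap
        self.p_cap = p_cap
        self.params = pd.Series(self._xhat, index=self.free_names)
        self.full_params = _expand(dict(self.params), self.regime)
        self.nparams = len(self.free_names)
        self.aic = 2.0 * self.nparams - 2.0 * self.llf
        obs = model.observations
        traj, collapse = pt_trajectory(self.full_params, self.regime,
                                       obs["landings"].to_numpy(),
                                       obs["year"].to_numpy())
        self.fittedvalues = pd.Series(traj, index=obs["year"], name="biomass")
        self.collapse_index = collapse

    # -- uncertainty -------------------------------------------------------

    @property
    def bse(self) -> pd.Series:
        if self.cov is None:
            return pd.Series(np.nan, index=self.free_names)
        return pd.Series(np.sqrt(np.diag(self.cov)), index=self.free_names)

    @property
    def cv_percent(self) -> pd.Series:
        return 100.0 * self.bse / self.params.abs()

    @property
    def corr_matrix(self) -> pd.DataFrame:
        if self.cov is None:
            raise ValueError("covariance unavailable (fit did not converge)")
        sd = np.sqrt(np.diag(self.cov))
        corr = self.cov / np.outer(sd, sd)
        np.fill_diagonal(corr, 1.0)
        return pd.DataFrame(corr, index=self.free_names, columns=self.free_names)

    def mean_abs_correlation(self) -> float:
        c = self.corr_matrix.to_numpy()
        off = c[~np.eye(len(c), dtype=bool)]
        return float(np.mean(np.abs(off))) if off.size else 0.0

    # -- anomaly screening -------------------------------------------------

    @property
    def anomalies(self) -> list[str]:
        flags = []
        for nm, v in self.params.items():
            if nm.startswith("r") and v > self.r_cap:
                flags.append(f"implausible {nm}={v:.3g} (> {self.r_cap}/yr)")
            if nm.startswith("p") and v > self.p_cap:
                flags.append(f"implausible {nm}={v:.3g} (> {self.p_cap})")
        if self.collapse_index is not None:
            year = int(self.model.observations["year"].iloc[self.collapse_index])
            flags.append(f"predicted stock collapse in {year}")
        if self.on_bound:
            flags.append("estimate on an optimization bound")
        return flags

    # -- derived quantities ------------------------------------------------

    def _kpr(self, period: int):
        full = self.full_params
        return full[f"K{period}"], full[f"p{period}"], full[f"r{period}"]

    def msy(self, period: int) -> float:
        return msy(*self._kpr(period))

    def bmsy(self, period: int) -> float:
        K, p, _ = self._kpr(period)
        return bmsy(K, p)

    def stability(self, period: int) -> StabilityClass:
        _, p, r = self._kpr(period)
        return stability_classification(r, p)

    def _derived_fun(self, kind: str, period: int):
        """Closure: derived quantity as a function of the free parameters."""
        obs = self.model.observations

        def fun(x):
            full = _expand(dict(zip(self.free_names, x)), self.regime)
            K, p, r = (full[f"K{period}"], full[f"p{period}"], full[f"r{period}"])
            if kind == "msy":
                return msy(K, p, r)
            if kind == "bmsy":
                return bmsy(K, p)
            if kind == "avg_tlp":
                B, collapse = pt_trajectory(full, self.regime,
                                            obs["landings"].to_numpy(),
                                            obs["year"].to_numpy())
                mask = self._period_mask(period)
                t = tlp(B[mask], obs["landings"].to_numpy()[mask], K, p, r)
                return float(np.mean(t))
            raise ValueError(kind)

        return fun

    def _period_mask(self, period: int) -> np.ndarray:
        years = self.model.observations["year"].to_numpy()
        return (years < self.regime.switch_year) if period == 1 \
            else (years >= self.regime.switch_year)

    def delta_se(self, kind: str, period: int) -> float:
        """Delta-method SE of a derived quantity ('msy', 'bmsy', 'avg_tlp')."""
        if self.cov is None:
            raise ValueError("covariance unavailable (fit did not converge)")
        return delta_method_se(self._derived_fun(kind, period),
                               self._xhat, self.cov)

    def tlp_series(self) -> pd.DataFrame:
        """Per-year total latent productivity along the fitted trajectory."""
        obs = self.model.observations
        years = obs["year"].to_numpy()
        out = np.empty(len(years))
        for period in (1, 2):
            mask = self._period_mask(period)
            if mask.any():
                K, p, r = self._kpr(period)
                out[mask] = tlp(self.fittedvalues.to_numpy()[mask],
                                obs["landings"].to_numpy()[mask], K, p, r)
        return pd.DataFrame({"year": years, "tlp": out})

    def average_tlp(self, period: int) -> float:
        return float(self._derived_fun("avg_tlp", period)(self._xhat))

    def reference_points(self) -> pd.DataFrame:
        """Reference-point table: MSY, B_MSY, average TLP and average
        landings per period, with delta-method SEs and CVs."""
        obs = self.model.observations
        rows = []
        for period in (1, 2):
            mask = self._period_mask(period)
            if not mask.any():
                continue
            land = obs["landings"].to_numpy()[mask]
            for kind, label in (("msy", "MSY"), ("bmsy", "B_MSY"),
                                ("avg_tlp", "avg_TLP")):
                val = self._derived_fun(kind, period)(self._xhat)
                se = self.delta_se(kind, period) if self.cov is not None else np.nan
                rows.append({"quantity": label, "period": period,
                             "estimate": val, "se": se,
                             "cv_percent": 100.0 * se / abs(val)})
            lbar = float(np.mean(land))
            lse = float(np.std(land, ddof=1) / np.sqrt(mask.sum())) if mask.sum() > 1 else 0.0
            rows.append({"quantity": "avg_landings", "period": period,
                         "estimate": lbar, "se": lse,
                         "cv_percent": (100.0 * np.std(land, ddof=1) / lbar
                                        if mask.sum() > 1 and lbar > 0 else 0.0)})
        return pd.DataFrame(rows)

    def trajectory_se(self) -> pd.Series:
        """Delta-method SEs of the fitted annual biomass trajectory."""
        if self.cov is None:
            raise ValueError("covariance unavailable")
        obs = self.model.observations
        years = obs["year"].to_numpy()
        ses = np.empty(len(years))
        for i in range(len(years)):
            def fun(x, i=i):
                full = _expand(dict(zip(self.free_names, x)), self.regime)
                B, _ = pt_trajectory(full, self.regime,
                                     obs["landings"].to_numpy(), years)
                return B[i]
            ses[i] = delta_method_se(fun, self._xhat, self.cov)
        return pd.Series(ses, index=years, name="biomass_se")

    # -- presentation ------------------------------------------------------

    def summary(self) -> str:
        lines = [
            "Pella-Tomlinson surplus production fit",
            f"  change set: {self.regime.label} (switch year {self.regime.switch_year})",
            f"  n obs: {len(self.model.observations)}   n params: {self.nparams}",
            f"  logLik: {self.llf:.3f}   AIC: {self.aic:.1f}   "
            f"max|grad|: {self.max_abs_grad:.3g}",
            f"  converged: {self.converged}   anomalies: {self.anomalies or 'none'}",
            "",
            f"  {'param':>6} {'estimate':>14} {'SE':>12} {'CV%':>8}",
        ]
        bse = self.bse
        for nm in self.free_names:
            cv = 100.0 * bse[nm] / abs(self.params[nm]) if np.isfinite(bse[nm]) else np.nan
            lines.append(f"  {nm:>6} {self.params[nm]:>14,.4f} "
                         f"{bse[nm]:>12,.4f} {cv:>8.1f}")
        for period in (1, 2):
            _, p, r = self._kpr(period)
            st = self.stability(period)
            lines.append(f"  period {period}: r(p-1) = {r * (p - 1):.3f} -> {st.label}")
        return "\n".join(lines)

    def plot_fit(self, ax=None):
        """Observed biomass (with 2 SE bars) and fitted trajectory."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        obs = self.model.observations
        ax.errorbar(obs["year"], obs["biomass"], yerr=2 * obs["biomass_se"],
                    fmt="o", label="stage-1 estimates", color="seagreen")
        ax.plot(self.fittedvalues.index, self.fittedvalues.values, "k-",
                label="fitted trajectory")
        ax.axvline(self.regime.switch_year, ls=":", color="grey")
        ax.set_xlabel("year")
        ax.set_ylabel("biomass (tonnes)")
        ax.legend()
        return ax

    def project(self, scenario, years: int = 10, n_reps: int = 1000,
                seed=None, b_init=None):
        """Stochastic harvest projection under a landings scenario."""
        from .projection import project_stochastic
        return project_stochastic(self, scenario, years=years, n_reps=n_reps,
                                  seed=seed, b_init=b_init)


# ---------------------------------------------------------------------------
# variant scan and selection
# ---------------------------------------------------------------------------

def fit_all_variants(observations: pd.DataFrame, switch_year: int,
                     start: dict | None = None, r_cap: float = 10.0,
                     p_cap: float = 5.0) -> list[PellaTomlinsonResults]:
    """Fit all eight regime variants (change sets over {K, p, r})."""
    fits = []
    for change in _ALL_CHANGE_SETS:
        model = PellaTomlinson(observations, RegimeSpec(switch_year, change))
        st = None
        if start is not None:
            st = {}
            for nm in model.free_names:
                base = nm.rstrip("12")
                st[nm] = start.get(nm, start.get(base))
        fits.append(model.fit(start=st, r_cap=r_cap, p_cap=p_cap))
    return fits


class VariantSelectionError(RuntimeError):
    """Every candidate fit failed a selection filter."""

    def __init__(self, reasons: dict):
        self.reasons = reasons
        msg = "; ".join(f"{k}: {v}" for k, v in reasons.items())
        super().__init__(f"all variants rejected -- {msg}")


def select_pt_variant(fits, grad_threshold: float = 1.0) -> PellaTomlinsonResults:
    """Select the best production-model variant.

    Sequential filters: drop non-converged fits and fits with
    max|gradient| above ``grad_threshold``; drop anomaly-flagged fits
    (implausible r or p, collapse inside the window, bound-crash); among
    survivors pick minimum AIC (all variants share one likelihood form),
    ties broken by correlation clustering then parsimony.
    """
    reasons = {}
    survivors = []
    for f in fits:
        label = f.regime.label
        if not f.converged:
            reasons[label] = "did not converge"
        elif f.max_abs_grad > grad_threshold:
            reasons[label] = f"max|grad|={f.max_abs_grad:.3g} > {grad_threshold}"
        elif f.anomalies:
            reasons[label] = "; ".join(f.anomalies)
        elif f.cov is None:
            reasons[label] = "covariance unavailable"
        else:
            survivors.append(f)
    if not survivors:
        raise VariantSelectionError(reasons)
    return min(survivors, key=lambda f: (round(f.aic, 6),
                                         f.mean_abs_correlation(),
                                         f.nparams))


# ---------------------------------------------------------------------------
# delta method
# ---------------------------------------------------------------------------

def delta_method_se(fun, params: np.ndarray, cov: np.ndarray,
                    rel_step: float = 1e-5) -> float:
    """First-order (delta-method) SE of ``fun(params)``.

    Central-difference gradient with a relative step, propagated through
    the estimate covariance.
    """
    params = np.asarray(params, dtype=float)
    if cov is None:
        raise ValueError("covariance matrix required")
    g = np.empty(len(params))
    for i in range(len(params)):
        h = rel_step * max(abs(params[i]), 1e-8)
        up = params.copy(); up[i] += h
        dn = params.copy(); dn[i] -= h
        g[i] = (fun(up) - fun(dn)) / (2.0 * h)
    var = float(g @ cov @ g)
    return float(np.sqrt(max(var, 0.0)))
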