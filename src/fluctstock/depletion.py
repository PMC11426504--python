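"""Intra-annual generalized depletion models for weekly catch and effort.

Within a fishing season the expected catch in numbers at week ``t`` is

    C_t = k E_t^alpha m ( N0 e^{-M t}
          - m sum_{i=1}^{t-1} C_i e^{-M (t-i-1)}
          + sum_j I_j(t) R_j e^{-M (t - tau_j)} )^beta,    m = e^{-M/2}

where ``N0`` is abundance at the season start (t = 0), ``M`` the weekly
natural mortality, ``k`` a generalized catchability scaling, ``alpha`` and
``beta`` effort- and abundance-response exponents, and each pulse
``(R_j, tau_j)`` an episodic in-season addition to vulnerable abundance
(recruitment or fleet area expansion).  The bracketed quantity is the
latent weekly abundance ``N_t``; the half-week survival factor ``m``
places all catch instantaneously at mid-week.

The estimator treats the observed weekly catch as a noisy realization of
the true catch, so by default the depletion sum runs on the model's own
predicted catches (a pure observation-error model); conditioning on the
observed catches instead is available as an option.  Four observation
likelihoods are supported: concentrated ("profile") normal and lognormal,
and exact normal and lognormal with a jointly estimated dispersion.
Positivity of all parameters is enforced by optimizing on the log scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit
from scipy import optimize
from statsmodels.tools.numdiff import approx_fprime, approx_hess

from .production import delta_method_se

__all__ = [
    "PulseSpec",
    "IAGDParams",
    "depletion_kernel",
    "predict_catch",
    "latent_abundance",
    "neg_log_likelihood",
    "DepletionModel",
    "DepletionResults",
    "enumerate_pulse_hypotheses",
    "variant_scan",
    "select_variant",
    "SelectionError",
    "solve_baranov_f",
    "exploitation_rate",
    "WEEKS_PER_YEAR",
]

WEEKS_PER_YEAR = 53  # annualization convention: annual M = 53 * weekly M

LIKELIHOOD_FORMS = ("profile-normal", "profile-lognormal", "normal", "lognormal")
OPTIMIZERS = ("cg", "spg", "neldermead")

_WORST = 1e10


@dataclass(frozen=True)
class PulseSpec:
    """Timing of in-season abundance input pulses (week indices)."""
    timings: tuple = ()
    max_u: int = 5

    def __post_init__(self):
        t = tuple(int(x) for x in self.timings)
        object.__setattr__(self, "timings", t)
        if len(t) > self.max_u:
            raise ValueError(f"at most {self.max_u} pulses allowed, got {len(t)}")
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError(f"pulse timings must be strictly increasing: {t}")
        if t and t[0] < 1:
            raise ValueError("pulse weeks start at 1")

    @property
    def u(self) -> int:
        return len(self.timings)

    def validate_for(self, n_weeks: int):
        if self.timings and self.timings[-1] > n_weeks:
            raise ValueError(
                f"pulse week {self.timings[-1]} outside season of {n_weeks} weeks")


@dataclass(frozen=True)
class IAGDParams:
    """Parameter set of the depletion model (all strictly positive)."""
    k: float
    M: float
    N0: float
    R: tuple = ()
    alpha: float = 1.0
    beta: float = 1.0

    def __post_init__(self):
        object.__setattr__(self, "R", tuple(float(x) for x in self.R))
        for nm in ("k", "M", "N0", "alpha", "beta"):
            if getattr(self, nm) <= 0:
                raise ValueError(f"{nm} must be positive, got {getattr(self, nm)}")
        if any(r <= 0 for r in self.R):
            raise ValueError("pulse abundances must be positive")

    def to_array(self) -> np.ndarray:
        return np.array([self.k, self.M, self.N0, *self.R, self.alpha, self.beta])

    @classmethod
    def from_array(cls, x, u: int) -> "IAGDParams":
        x = np.asarray(x, dtype=float)
        return cls(k=x[0], M=x[1], N0=x[2], R=tuple(x[3:3 + u]),
                   alpha=x[3 + u], beta=x[4 + u])

    @staticmethod
    def names(u: int) -> list:
        return ["k", "M", "N0", *[f"R{j + 1}" for j in range(u)], "alpha", "beta"]


# ---------------------------------------------------------------------------
# catch-prediction kernel
# ---------------------------------------------------------------------------

def depletion_kernel(k, M, N0, R, alpha, beta, effort, timings, catches=None):
    """Evaluate the weekly catch equation over a season.

    With ``catches`` given, the depletion sum conditions on those observed
    catches (likelihood evaluation); with ``catches=None`` the model's own
    predictions are fed back recursively (simulation).

    Returns
    -------
    (chat, N, feasible) : predicted catch, latent abundance per week, and
    False if the abundance bracket went non-positive at any week.
    """
    effort = np.ascontiguousarray(effort, dtype=np.float64)
    R_arr = np.asarray(R, dtype=np.float64)
    tau_arr = np.asarray(timings, dtype=np.float64)
    if catches is None:
        cond = np.empty(0)
        use_cond = False
    else:
        cond = np.ascontiguousarray(catches, dtype=np.float64)
        use_cond = True
    with np.errstate(over="ignore", invalid="ignore"):
        chat, N, feasible = _kernel_loop(float(k), float(M), float(N0), R_arr,
                                         float(alpha), float(beta), effort,
                                         tau_arr, cond, use_cond)
    return chat, N, bool(feasible)


@njit(cache=True)
def _kernel_loop(k, M, N0, R, alpha, beta, effort, timings, cond, use_cond):
    T = effort.shape[0]
    m = np.exp(-M / 2.0)
    decay = np.exp(-M)
    chat = np.zeros(T)
    N = np.zeros(T)
    feasible = True
    D = 0.0  # running discounted sum of prior catches
    for t in range(1, T + 1):
        pulse = 0.0
        for j in range(R.shape[0]):
            if t >= timings[j]:
                pulse += R[j] * np.exp(-M * (t - timings[j]))
        Nt = N0 * np.exp(-M * t) - m * D + pulse
        if np.isfinite(Nt):
            N[t - 1] = Nt
        else:
            N[t - 1] = 0.0
        if not np.isfinite(Nt) or Nt <= 0.0:
            feasible = False
            Nt = 0.0
        if effort[t - 1] > 0.0 and Nt > 0.0:
            c = k * effort[t - 1] ** alpha * m * Nt ** beta
            if not np.isfinite(c):
                feasible = False
                c = 0.0
            chat[t - 1] = c
        if use_cond:
            D = decay * D + cond[t - 1]
        else:
            D = decay * D + chat[t - 1]
    return chat, N, feasible


def predict_catch(params: IAGDParams, effort, pulse: PulseSpec,
                  observed_catch=None):
    """Predicted weekly catch series (numbers) for a parameter set."""
    pulse.validate_for(len(effort))
    if len(params.R) != pulse.u:
        raise ValueError("number of pulse abundances must match pulse timings")
    chat, _, feasible = depletion_kernel(
        params.k, params.M, params.N0, params.R, params.alpha, params.beta,
        effort, pulse.timings, catches=observed_catch)
    return chat, feasible


def latent_abundance(params: IAGDParams, effort, pulse: PulseSpec,
                     observed_catch):
    """Latent weekly abundance N_t, conditioning on observed catches."""
    pulse.validate_for(len(effort))
    _, N, _ = depletion_kernel(
        params.k, params.M, params.N0, params.R, params.alpha, params.beta,
        effort, pulse.timings, catches=observed_catch)
    return N


# ---------------------------------------------------------------------------
# likelihoods
# ---------------------------------------------------------------------------

def _residual_mask(effort, obs, form):
    mask = np.asarray(effort) > 0
    if form.endswith("lognormal"):
        mask &= np.asarray(obs) > 0
    return mask


def neg_log_likelihood(params: IAGDParams, effort, obs_catch,
                       pulse: PulseSpec, form: str,
                       sigma: float | None = None,
                       conditioning: str = "predicted") -> float:
    """Negative log-likelihood of one season under a likelihood form.

    Profile forms concentrate the dispersion analytically; exact forms
    require ``sigma``.  Infeasible parameter sets (negative abundance
    bracket) return a large finite worst value, keeping simplex searches
    stable.
    """
    if form not in LIKELIHOOD_FORMS:
        raise ValueError(f"unknown likelihood form {form!r}")
    obs_catch = np.asarray(obs_catch, dtype=float)
    cond = obs_catch if conditioning == "observed" else None
    chat, feasible = predict_catch(params, effort, pulse,
                                   observed_catch=cond)
    if not feasible:
        return _WORST
    mask = _residual_mask(effort, obs_catch, form)
    n = int(mask.sum())
    if n == 0:
        return _WORST
    if form.endswith("lognormal"):
        if np.any(chat[mask] <= 0):
            return _WORST
        resid = np.log(obs_catch[mask]) - np.log(chat[mask])
        jacobian = float(np.sum(np.log(obs_catch[mask])))
    else:
        resid = obs_catch[mask] - chat[mask]
        jacobian = 0.0
    ssr = float(resid @ resid)
    if form.startswith("profile"):
        sig2 = (ssr + 1e-12) / n  # epsilon floor guards the perfect fit
        return 0.5 * n * (np.log(2.0 * np.pi * sig2) + 1.0) + jacobian
    if sigma is None or sigma <= 0:
        raise ValueError("exact likelihoods require a positive dispersion")
    return (0.5 * n * np.log(2.0 * np.pi * sigma ** 2)
            + ssr / (2.0 * sigma ** 2) + jacobian)


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

class DepletionModel:
    """Generalized depletion model for one season's weekly table.

    Parameters
    ----------
    catch : observed weekly catch in numbers.
    effort : observed weekly effort (effective fishing days).
    pulse : PulseSpec with the hypothesised pulse timings.
    likelihood : one of ``profile-normal``, ``profile-lognormal``,
        ``normal``, ``lognormal``.
    conditioning : ``"predicted"`` (default) runs the depletion sum on the
        model's own predicted catches, the coherent choice under pure
        observation error in the catch series; ``"observed"`` conditions
        on the observed catches instead (classical conditional depletion),
        which is fragile when the season nearly exhausts the stock.
    """

    def __init__(self, catch, effort, pulse: PulseSpec = PulseSpec(),
                 likelihood: str = "profile-normal",
                 conditioning: str = "predicted"):
        if conditioning not in ("predicted", "observed"):
            raise ValueError("conditioning must be 'predicted' or 'observed'")
        self.conditioning = conditioning
        self.catch = np.asarray(catch, dtype=float)
        self.effort = np.asarray(effort, dtype=float)
        if len(self.catch) != len(self.effort):
            raise ValueError("catch and effort must have equal length")
        if np.any(self.catch < 0) or np.any(self.effort < 0):
            raise ValueError("catch and effort must be non-negative")
        if likelihood not in LIKELIHOOD_FORMS:
            raise ValueError(f"unknown likelihood form {likelihood!r}")
        pulse.validate_for(len(self.effort))
        self.pulse = pulse
        self.likelihood = likelihood
        self.n_weeks = len(self.effort)

    @classmethod
    def from_table(cls, table: pd.DataFrame, pulse: PulseSpec = PulseSpec(),
                   likelihood: str = "profile-normal") -> "DepletionModel":
        """Build from a weekly season table with ``catch_weight_kg`` and
        ``mean_weight_kg`` columns (catch numbers = weight / mean weight)."""
        t = table.sort_values("week")
        numbers = t["catch_weight_kg"].to_numpy() / t["mean_weight_kg"].to_numpy()
        return cls(numbers, t["effort_days"].to_numpy(), pulse, likelihood)

    @property
    def exact(self) -> bool:
        return not self.likelihood.startswith("profile")

    def _param_count(self) -> int:
        return 5 + self.pulse.u + (1 if self.exact else 0)

    def _nll_log(self, z: np.ndarray) -> float:
        with np.errstate(all="ignore"):
            x = np.exp(z)
            if np.any(~np.isfinite(x)):
                return _WORST
            u = self.pulse.u
            try:
                params = IAGDParams.from_array(x[:5 + u], u)
            except ValueError:
                return _WORST
            sigma = x[5 + u] if self.exact else None
            return neg_log_likelihood(params, self.effort, self.catch,
                                      self.pulse, self.likelihood, sigma=sigma,
                                      conditioning=self.conditioning)

    def _nll_natural(self, x: np.ndarray) -> float:
        if np.any(x <= 0):
            return _WORST
        return self._nll_log(np.log(x))

    def _ls_residuals(self, z_core: np.ndarray, conditioning: str) -> np.ndarray:
        """Residual vector (natural or log scale per the likelihood form)
        for the trust-region least-squares refinement stage."""
        u = self.pulse.u
        x = np.exp(z_core)
        cond = self.catch if conditioning == "observed" else None
        chat, _, _ = depletion_kernel(x[0], x[1], x[2], tuple(x[3:3 + u]),
                                      x[3 + u], x[4 + u], self.effort,
                                      self.pulse.timings, catches=cond)
        mask = _residual_mask(self.effort, self.catch, self.likelihood)
        if self.likelihood.endswith("lognormal"):
            return np.log(self.catch[mask]) - np.log(np.maximum(chat[mask], 1e-300))
        return chat[mask] - self.catch[mask]

    def _ls_refine(self, z_core: np.ndarray, maxiter: int) -> np.ndarray:
        """Refine the non-dispersion parameters by trust-region least
        squares.  For the profile likelihoods the concentrated objective is
        a monotone transform of the residual sum of squares, so this solves
        the same problem; for the exact likelihoods it refines the location
        parameters at the conditional dispersion optimum sigma^2 = SSR/n.

        The first pass always conditions the depletion sum on the observed
        catches: that surface is anchored to the data and stays finite for
        wild exploratory parameter values.  When the model itself uses the
        predicted-catch recursion, a second pass refines under that
        recursion from the first pass's solution, which by then lies in a
        stable region.
        """
        z = z_core
        stages = ["observed"]
        if self.conditioning == "predicted":
            stages.append("predicted")
        for cond in stages:
            try:
                with np.errstate(all="ignore"):
                    ls = optimize.least_squares(
                        lambda zz: self._ls_residuals(zz, cond), z,
                        method="trf", x_scale="jac",
                        max_nfev=200 * len(z))
                z = ls.x
            except Exception:
                pass
        return z

    def default_start(self) -> IAGDParams:
        """Heuristic starting values from the season's own totals."""
        total = float(np.sum(self.catch))
        if total <= 0:
            raise ValueError("season has no catch; nothing to fit")
        N0 = 2.0 * total
        M = 0.05
        m = np.exp(-M / 2.0)
        Emean = float(np.mean(self.effort[self.effort > 0]))
        k = float(np.mean(self.catch[self.effort > 0])) / (Emean * m * (N0 / 2.0))
        R = tuple(0.3 * N0 for _ in range(self.pulse.u))
        return IAGDParams(k=k, M=M, N0=N0, R=R, alpha=1.0, beta=1.0)

    def fit(self, start: IAGDParams | None = None, method: str = "cg",
            start_sigma: float | None = None, maxiter: int = 3000,
            polish: bool = True) -> "DepletionResults":
        """Maximise the likelihood from strictly positive starting values.

        ``method`` is one of ``cg`` (conjugate gradients), ``spg``
        (bounded quasi-Newton) or ``neldermead`` (simplex).  A simplex
        polish pass follows gradient-based methods.  All parameters are
        optimized on the log scale, which enforces positivity without
        imposing box constraints.
        """
        if method not in OPTIMIZERS:
            raise ValueError(f"unknown optimizer {method!r}; pick from {OPTIMIZERS}")
        if start is None:
            start = self.default_start()
        if len(start.R) != self.pulse.u:
            raise ValueError("start values must carry one R per pulse")
        x0 = start.to_array()
        if self.exact:
            if start_sigma is None:
                # crude residual scale at the start values
                chat, _ = predict_catch(start, self.effort, self.pulse,
                                        observed_catch=self.catch)
                mask = _residual_mask(self.effort, self.catch, self.likelihood)
                if self.likelihood.endswith("lognormal"):
                    resid = np.log(np.maximum(self.catch[mask], 1e-12)) - \
                        np.log(np.maximum(chat[mask], 1e-12))
                else:
                    resid = self.catch[mask] - chat[mask]
                start_sigma = float(np.std(resid)) or 1.0
            x0 = np.append(x0, start_sigma)
        z0 = np.log(x0)

        # least-squares refinement of the location parameters, then the
        # requested optimizer on the actual likelihood
        u = self.pulse.u
        z_core = self._ls_refine(z0[:5 + u], maxiter)
        if self.exact:
            resid = self._ls_residuals(z_core, self.conditioning)
            sigma = float(np.sqrt(np.mean(resid ** 2)))
            z_ref = np.append(z_core, np.log(max(sigma, 1e-12)))
        else:
            z_ref = z_core
        if self._nll_log(z_ref) < self._nll_log(z0):
            z0 = z_ref

        scipy_method = {"cg": "CG", "spg": "L-BFGS-B",
                        "neldermead": "Nelder-Mead"}[method]
        opts = {"maxiter": maxiter}
        if scipy_method == "Nelder-Mead":
            opts.update({"maxfev": 6000, "xatol": 1e-9, "fatol": 1e-10,
                         "adaptive": True})
        with np.errstate(all="ignore"):
            res = optimize.minimize(self._nll_log, z0, method=scipy_method,
                                    options=opts)
        best_z, best_f, success = res.x, res.fun, bool(res.success)
        if polish:
            for _ in range(2):
                pol = optimize.minimize(
                    self._nll_log, best_z, method="Nelder-Mead",
                    options={"maxiter": maxiter, "maxfev": 4000,
                             "xatol": 1e-9, "fatol": 1e-10, "adaptive": True})
                if pol.fun < best_f - 1e-12:
                    best_z, best_f = pol.x, pol.fun
                    success = success or bool(pol.success)
                else:
                    best_z, best_f = (pol.x, pol.fun) if pol.fun < best_f else (best_z, best_f)
                    break
        grad = approx_fprime(best_z, self._nll_log, centered=True)
        max_abs_grad = float(np.max(np.abs(grad)))
        # optimizer success flags are unreliable on ridge-shaped surfaces;
        # call a fit converged when it terminated on a finite, feasible
        # objective either normally or at a small gradient
        converged = bool(np.isfinite(best_f) and best_f < _WORST / 2
                         and (success or max_abs_grad < 1.0))
        xhat = np.exp(best_z)

        cov = _robust_covariance(self._nll_natural, self._nll_log, xhat, best_z)
        return DepletionResults(self, xhat, best_f, cov, max_abs_grad,
                                converged, method)




def _robust_covariance(nll_natural, nll_log, xhat, zhat):
    """Inverse-Hessian covariance with a log-scale fallback.

    The natural-scale Hessian can be singular on nearly flat ridges; the
    log-scale Hessian is often better conditioned and transforms back via
    the chain rule (dx = x dz at the optimum).
    """
    with np.errstate(all="ignore"):
        try:
            cov = np.linalg.inv(approx_hess(xhat, nll_natural))
            if np.all(np.isfinite(cov)) and np.all(np.diag(cov) > 0):
                return cov
        except np.linalg.LinAlgError:
            pass
        try:
            cov_z = np.linalg.inv(approx_hess(zhat, nll_log))
            J = np.diag(xhat)
            cov = J @ cov_z @ J
            if np.all(np.isfinite(cov)) and np.all(np.diag(cov) > 0):
                return cov
        except np.linalg.LinAlgError:
            pass
    return None


class DepletionResults:
    """Estimates and derived in-season quantities for one fitted variant."""

    def __init__(self, model: DepletionModel, xhat, nll, cov, max_abs_grad,
                 converged, method):
        self.model = model
        self.pulse = model.pulse
        self.likelihood = model.likelihood
        self.method = method
        self._xhat = np.asarray(xhat, dtype=float)
        self.nll = float(nll)
        self.llf = -self.nll
        self.cov = cov
        self.max_abs_grad = max_abs_grad
        self.converged = converged
        u = self.pulse.u
        self.param_names = IAGDParams.names(u) + (["sigma"] if model.exact else [])
        self.params = pd.Series(self._xhat, index=self.param_names)
        self.iagd_params = IAGDParams.from_array(self._xhat[:5 + u], u)
        self.nparams = len(self.param_names)
        self.aic = 2.0 * self.nparams - 2.0 * self.llf
        cond = model.catch if model.conditioning == "observed" else None
        chat, _ = predict_catch(self.iagd_params, model.effort, self.pulse,
                                observed_catch=cond)
        self.fittedvalues = chat
        self.resid = model.catch - chat

    # -- uncertainty -------------------------------------------------------

    @property
    def bse(self) -> pd.Series:
        if self.cov is None:
            return pd.Series(np.nan, index=self.param_names)
        return pd.Series(np.sqrt(np.diag(self.cov)), index=self.param_names)

    @property
    def cv_percent(self) -> pd.Series:
        return 100.0 * self.bse / self.params.abs()

    @property
    def corr_matrix(self) -> pd.DataFrame:
        if self.cov is None:
            raise ValueError("covariance unavailable")
        sd = np.sqrt(np.diag(self.cov))
        corr = self.cov / np.outer(sd, sd)
        np.fill_diagonal(corr, 1.0)
        return pd.DataFrame(corr, index=self.param_names,
                            columns=self.param_names)

    def mean_abs_correlation(self) -> float:
        c = self.corr_matrix.to_numpy()
        off = c[~np.eye(len(c), dtype=bool)]
        return float(np.mean(np.abs(off))) if off.size else 0.0

    def key_param_cv_count(self, threshold: float = 50.0) -> int:
        """How many biomass-relevant parameters (M, N0, R_j) have CV below
        ``threshold`` percent."""
        keys = ["M", "N0"] + [f"R{j + 1}" for j in range(self.pulse.u)]
        cvs = self.cv_percent
        return int(sum(1 for nm in keys if np.isfinite(cvs[nm])
                       and cvs[nm] < threshold))

    # -- derived in-season series -----------------------------------------

    def weekly_abundance(self) -> np.ndarray:
        """Latent abundance N_t (the bracket of the catch equation),
        conditioning the depletion sum on observed catches."""
        return latent_abundance(self.iagd_params, self.model.effort,
                                self.pulse, self.model.catch)

    def fishing_mortality(self) -> np.ndarray:
        """Weekly F_t from Baranov's catch equation; NaN where the observed
        catch is not attainable from the latent abundance (misfit flag)."""
        N = self.weekly_abundance()
        M = self.iagd_params.M
        F = np.empty(self.model.n_weeks)
        for i, (c, n) in enumerate(zip(self.model.catch, N)):
            try:
                F[i] = solve_baranov_f(c, n, M)
            except ValueError:
                F[i] = np.nan
        return F

    def exploitation_rate(self) -> np.ndarray:
        """Weekly exploitation rate, percent of total mortality fished."""
        return exploitation_rate(self.fishing_mortality(), self.iagd_params.M)

    def annualized_m(self) -> float:
        return WEEKS_PER_YEAR * self.iagd_params.M

    def total_initial_biomass(self, w0_kg: float):
        """Start-of-season total biomass (tonnes) with delta-method SE.

        N0_total = N0 + sum_j R_j e^{M tau_j} back-discounts each pulse to
        the season start; biomass = N0_total * w0 (w0 in kg, result in
        tonnes).
        """
        if self.cov is None:
            raise ValueError("covariance unavailable (fit did not converge)")
        if w0_kg <= 0:
            raise ValueError("start-of-season mean weight must be positive")
        timings = self.pulse.timings

        def fun(x):
            M = x[1]
            N0 = x[2]
            R = x[3:3 + self.pulse.u]
            n0_total = N0 + sum(r * np.exp(M * tau) for r, tau in zip(R, timings))
            return n0_total * w0_kg / 1000.0

        value = fun(self._xhat)
        se = delta_method_se(fun, self._xhat, self.cov)
        return value, se

    def derived_series(self) -> pd.DataFrame:
        """Weekly table of latent abundance, F and exploitation rate."""
        N = self.weekly_abundance()
        F = self.fishing_mortality()
        return pd.DataFrame({
            "week": np.arange(1, self.model.n_weeks + 1),
            "abundance": N,
            "fishing_mortality": F,
            "exploitation_pct": exploitation_rate(F, self.iagd_params.M),
        })

    # -- presentation ------------------------------------------------------

    def summary(self) -> str:
        lines = [
            "Generalized depletion fit",
            f"  likelihood: {self.likelihood}   optimizer: {self.method}",
            f"  pulses: u={self.pulse.u} at weeks {self.pulse.timings or '()'}",
            f"  logLik: {self.llf:.3f}   AIC: {self.aic:.1f}   "
            f"max|grad|: {self.max_abs_grad:.3g}   converged: {self.converged}",
            f"  annualized M: {self.annualized_m():.2f}/yr",
            "",
            f"  {'param':>6} {'estimate':>14} {'SE':>12} {'CV%':>8}",
        ]
        bse = self.bse
        for nm in self.param_names:
            cv = 100.0 * bse[nm] / abs(self.params[nm]) if np.isfinite(bse[nm]) else np.nan
            lines.append(f"  {nm:>6} {self.params[nm]:>14.6g} "
                         f"{bse[nm]:>12.4g} {cv:>8.1f}")
        return "\n".join(lines)

    def plot_fit(self, ax=None):
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        weeks = np.arange(1, self.model.n_weeks + 1)
        ax.plot(weeks, self.model.catch, "o", label="observed")
        ax.plot(weeks, self.fittedvalues, "-", label="predicted")
        for tau in self.pulse.timings:
            ax.axvline(tau, ls=":", color="grey")
        ax.set_xlabel("week")
        ax.set_ylabel("catch (numbers)")
        ax.legend()
        return ax


# ---------------------------------------------------------------------------
# pulse enumeration and variant selection
# ---------------------------------------------------------------------------

def enumerate_pulse_hypotheses(catch, effort, form: str = "profile-normal",
                               max_u: int = 5, method: str = "cg",
                               z_threshold: float = 2.0,
                               tie_band: float = 0.5, **fit_kwargs):
    """Forward search over pulse hypotheses from pure-depletion residuals.

    Starting from the pure depletion fit (u = 0), each step looks for
    standing-out positive residuals (standardized residual above
    ``z_threshold``), proposes a new pulse at the week of the largest one
    (plus near-tied alternatives within ``tie_band`` standard deviations),
    refits, and keeps the best-AIC extension.  Stops when no standout
    remains, no extension improves the AIC, or ``max_u`` is reached.

    Returns
    -------
    (specs, fits) : every PulseSpec visited and the corresponding fitted
    DepletionResults, in visit order.  The pure-depletion spec is always
    first.
    """
    specs = [PulseSpec()]
    base = DepletionModel(catch, effort, PulseSpec(), form).fit(method=method,
                                                               **fit_kwargs)
    fits = [base]
    current = base
    while current.pulse.u < max_u:
        resid = current.resid
        scale = float(np.std(resid, ddof=1)) if len(resid) > 1 else 0.0
        if scale <= 0:
            break
        z = resid / scale
        taken = set(current.pulse.timings)
        ranked = [(w + 1, z[w]) for w in np.argsort(z)[::-1]
                  if (w + 1) not in taken and z[w] > 0]
        if not ranked:
            break
        zmax = ranked[0][1]
        standouts = [w for w, zz in ranked
                     if zz > z_threshold and zz >= zmax - tie_band]
        # even without a standout the two largest positive residuals are
        # probed: flexible effort/abundance exponents smear pulse
        # signatures, and an ill-determined fit is informative through
        # the manner in which it fails
        cand_weeks = sorted(set(standouts) | {w for w, _ in ranked[:2]})
        trial_fits = []
        for w in cand_weeks:
            spec = PulseSpec(tuple(sorted(current.pulse.timings + (w,))))
            specs.append(spec)
            fit = DepletionModel(catch, effort, spec, form).fit(method=method,
                                                                **fit_kwargs)
            fits.append(fit)
            trial_fits.append(fit)
        # continue the forward search from the best extension while
        # standouts remain; final arbitration happens in select_variant
        current = min(trial_fits, key=lambda f: f.aic)
    return specs, fits


def variant_scan(catch, effort, forms=("profile-normal",),
                 optimizers=("cg",), max_u: int = 5, **fit_kwargs):
    """Full variant scan: pulse enumeration crossed with likelihood forms
    and optimizers.  Returns the list of all fitted variants."""
    fits = []
    for form in forms:
        specs, form_fits = enumerate_pulse_hypotheses(
            catch, effort, form=form, max_u=max_u, method=optimizers[0],
            **fit_kwargs)
        fits.extend(form_fits)
        for method in optimizers[1:]:
            for spec in specs:
                fits.append(DepletionModel(catch, effort, spec, form)
                            .fit(method=method, **fit_kwargs))
    return fits


class SelectionError(RuntimeError):
    """Raised when every candidate variant fails a selection filter."""

    def __init__(self, reasons):
        self.reasons = reasons
        super().__init__("all variants rejected -- " +
                         "; ".join(f"[{k}] {v}" for k, v in reasons))


def select_variant(fits, grad_threshold: float = 1.0,
                   cv_threshold: float = 50.0) -> DepletionResults:
    """Select the best depletion variant by sequential criteria.

    (1) numerical: drop fits with max|gradient| above ``grad_threshold``
    (and non-converged fits); (2) statistical: keep the fits whose count
    of biomass-relevant parameters (M, N0, R_j) with CV below
    ``cv_threshold`` percent is maximal; (3) information: within each
    likelihood form pick minimum AIC; across forms the winner is the fit
    with correlations most clustered around zero (lowest mean absolute
    off-diagonal correlation), ties broken by parsimony.
    """
    reasons = []
    stage1 = []
    for i, f in enumerate(fits):
        tag = f"{f.likelihood}/u={f.pulse.u}@{f.pulse.timings}/{f.method}"
        if not f.converged:
            reasons.append((tag, "did not converge"))
        elif f.max_abs_grad > grad_threshold:
            reasons.append((tag, f"max|grad|={f.max_abs_grad:.3g} > {grad_threshold}"))
        elif f.cov is None:
            reasons.append((tag, "covariance unavailable"))
        else:
            stage1.append(f)
    if not stage1:
        raise SelectionError(reasons)
    counts = [f.key_param_cv_count(cv_threshold) for f in stage1]
    best_count = max(counts)
    stage2 = [f for f, c in zip(stage1, counts) if c == best_count]
    per_form = {}
    for f in stage2:
        cur = per_form.get(f.likelihood)
        if cur is None or (f.aic, f.nparams, f.mean_abs_correlation()) < \
                (cur.aic, cur.nparams, cur.mean_abs_correlation()):
            per_form[f.likelihood] = f
    return min(per_form.values(),
               key=lambda f: (f.mean_abs_correlation(), f.nparams, f.aic))


# ---------------------------------------------------------------------------
# Baranov catch equation
# ---------------------------------------------------------------------------

def solve_baranov_f(C: float, N: float, M: float) -> float:
    """Fishing mortality solving C = F/(F+M) * N * (1 - e^{-(F+M)}).

    The catch is strictly increasing in F on (0, inf) with supremum N, so
    a unique root exists for 0 <= C < N.  C = 0 returns F = 0.
    """
    if M <= 0:
        raise ValueError("M must be positive")
    if C < 0:
        raise ValueError("catch must be non-negative")
    if C == 0:
        return 0.0
    if N <= 0 or C >= N:
        raise ValueError(f"catch {C} not attainable from abundance {N}")

    def f(F):
        Z = F + M
        return F / Z * N * (1.0 - np.exp(-Z)) - C

    hi = 1.0
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e6:
            raise ValueError("no finite F solves the catch equation")
    return float(optimize.brentq(f, 0.0, hi, xtol=1e-12, rtol=1e-14))


def exploitation_rate(F, M: float):
    """Exploitation rate 100*F/(F+M), the fished percent of total
    mortality; the 40% line is a common management reference."""
    if M <= 0:
        raise ValueError("M must be positive")
    F = np.asarray(F, dtype=float)
    return 100.0 * F / (F + M)
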