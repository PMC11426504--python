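"""Depletion model: catch kernel against an independent transcription,
likelihood identities, Baranov inversion, derived quantities, pulse
enumeration and variant selection."""

import numpy as np
import pytest

from fluctstock.depletion import (
    WEEKS_PER_YEAR,
    DepletionModel,
    DepletionResults,
    IAGDParams,
    PulseSpec,
    SelectionError,
    depletion_kernel,
    enumerate_pulse_hypotheses,
    exploitation_rate,
    neg_log_likelihood,
    predict_catch,
    select_variant,
    solve_baranov_f,
)
from fluctstock.operating_model import (
    ObservationError,
    OperatingModelConfig,
    SeasonDynamics,
    depletion_experiment_config,
    simulate_season,
)


def catch_equation_transcription(k, M, N0, R, alpha, beta, E, taus):
    """Literal, non-recursive transcription of the weekly catch equation,
    evaluated term by term with the predicted catches re-derived from
    scratch at every week (independent oracle for the kernel)."""
    m = np.exp(-M / 2.0)
    T = len(E)
    C = []
    for t in range(1, T + 1):
        depletion = sum(C[i - 1] * np.exp(-M * (t - i - 1))
                        for i in range(1, t))
        pulses = sum(R[j] * np.exp(-M * (t - taus[j]))
                     for j in range(len(taus)) if t >= taus[j])
        bracket = N0 * np.exp(-M * t) - m * depletion + pulses
        C.append(k * E[t - 1] ** alpha * m * bracket ** beta)
    return np.array(C)


class TestCatchKernel:
    def test_matches_independent_transcription(self, rng):
        for _ in range(20):
            T = 5
            E = rng.uniform(50, 200, T)
            k = rng.uniform(1e-5, 1e-3)
            M = rng.uniform(0.01, 0.2)
            N0 = rng.uniform(1e5, 1e7)
            taus = (3,)
            R = (rng.uniform(1e4, 1e6),)
            alpha = rng.uniform(0.7, 1.2)
            beta = rng.uniform(0.7, 1.1)
            oracle = catch_equation_transcription(k, M, N0, R, alpha, beta,
                                                  E, taus)
            chat, _, feasible = depletion_kernel(k, M, N0, R, alpha, beta,
                                                 E, taus)
            assert feasible
            assert np.allclose(chat, oracle, rtol=1e-12)

    def test_vanishing_mortality_limit(self):
        # alpha=beta=1, M->0, no pulses: C_t = k E_t (N0 - sum of priors)
        params = IAGDParams(k=1e-4, M=1e-10, N0=1e6)
        E = np.full(6, 150.0)
        chat, feasible = predict_catch(params, E, PulseSpec())
        assert feasible
        cum, expected = 0.0, []
        for t in range(6):
            c = 1e-4 * 150.0 * (1e6 - cum)
            expected.append(c)
            cum += c
        assert np.allclose(chat, expected, rtol=1e-6)

    def test_zero_effort_weeks_produce_zero_catch(self):
        params = IAGDParams(k=1e-4, M=0.05, N0=1e6)
        E = np.array([100.0, 0.0, 100.0, 0.0])
        chat, _ = predict_catch(params, E, PulseSpec())
        assert chat[1] == 0.0 and chat[3] == 0.0 and chat[0] > 0.0

    def test_latent_abundance_decays_without_fishing(self):
        _, N, _ = depletion_kernel(1e-4, 0.1, 1e6, (), 1.0, 1.0,
                                   np.zeros(8), ())
        t = np.arange(1, 9)
        assert np.allclose(N, 1e6 * np.exp(-0.1 * t), rtol=1e-12)

    def test_infeasible_bracket_flagged(self):
        # absurd catchability exhausts the stock -> infeasible
        _, _, feasible = depletion_kernel(1.0, 0.05, 1e4, (), 1.0, 1.0,
                                          np.full(10, 100.0), ())
        assert not feasible


class TestPulseSpec:
    def test_ordering_enforced(self):
        with pytest.raises(ValueError):
            PulseSpec((5, 5))
        with pytest.raises(ValueError):
            PulseSpec((8, 3))

    def test_cap_enforced(self):
        with pytest.raises(ValueError):
            PulseSpec((1, 2, 3), max_u=2)

    def test_week_range_checked_at_use(self):
        with pytest.raises(ValueError):
            PulseSpec((25,)).validate_for(20)

    def test_invalid_start_values_rejected(self):
        with pytest.raises(ValueError):
            IAGDParams(k=1e-4, M=0.05, N0=-5.0)


@pytest.fixture(scope="module")
def season():
    cfg = OperatingModelConfig(rng_seed=21)
    table, truth = simulate_season(80_000.0, cfg, seed=77)
    numbers = (table["catch_weight_kg"] / table["mean_weight_kg"]).to_numpy()
    effort = table["effort_days"].to_numpy()
    params = IAGDParams(k=truth["k"], M=truth["M"], N0=truth["N0"],
                        R=truth["pulse_abundances"],
                        alpha=truth["alpha"], beta=truth["beta"])
    return numbers, effort, params, PulseSpec(truth["pulse_timings"])


class TestLikelihoods:
    def test_exact_normal_at_profile_sigma_equals_profile(self, season):
        numbers, effort, params, pulse = season
        chat, _ = predict_catch(params, effort, pulse)
        resid = numbers - chat
        sigma_hat = float(np.sqrt(np.mean(resid ** 2)))
        exact = neg_log_likelihood(params, effort, numbers, pulse, "normal",
                                   sigma=sigma_hat)
        profile = neg_log_likelihood(params, effort, numbers, pulse,
                                     "profile-normal")
        assert exact == pytest.approx(profile, abs=1e-6)

    def test_exact_lognormal_at_profile_sigma_equals_profile(self, season):
        numbers, effort, params, pulse = season
        chat, _ = predict_catch(params, effort, pulse)
        resid = np.log(numbers) - np.log(chat)
        sigma_hat = float(np.sqrt(np.mean(resid ** 2)))
        exact = neg_log_likelihood(params, effort, numbers, pulse, "lognormal",
                                   sigma=sigma_hat)
        profile = neg_log_likelihood(params, effort, numbers, pulse,
                                     "profile-lognormal")
        assert exact == pytest.approx(profile, abs=1e-6)

    def test_lognormal_scale_equivariance(self, season):
        # doubling observations and the abundance scale (beta = 1) shifts
        # the lognormal objective only by the Jacobian term n log 2
        numbers, effort, _, _ = season
        params = IAGDParams(k=1e-4, M=0.05, N0=4.0 * numbers.sum(),
                            alpha=1.0, beta=1.0)
        doubled = IAGDParams(k=1e-4, M=0.05, N0=8.0 * numbers.sum(),
                             alpha=1.0, beta=1.0)
        n = int(np.sum((effort > 0) & (numbers > 0)))
        nll1 = neg_log_likelihood(params, effort, numbers, PulseSpec(),
                                  "profile-lognormal")
        nll2 = neg_log_likelihood(doubled, effort, 2.0 * numbers, PulseSpec(),
                                  "profile-lognormal")
        assert nll2 - nll1 == pytest.approx(n * np.log(2.0), abs=1e-8)

    def test_infeasible_returns_worst_value(self, season):
        numbers, effort, _, _ = season
        absurd = IAGDParams(k=10.0, M=0.05, N0=numbers.sum())
        assert neg_log_likelihood(absurd, effort, numbers, PulseSpec(),
                                  "profile-normal",
                                  conditioning="observed") >= 1e9

    def test_unknown_form_rejected(self, season):
        numbers, effort, params, pulse = season
        with pytest.raises(ValueError):
            neg_log_likelihood(params, effort, numbers, pulse, "cauchy")


class TestBaranov:
    def test_zero_catch_zero_f(self):
        assert solve_baranov_f(0.0, 1e6, 0.05) == 0.0

    def test_small_m_limit(self):
        # M -> 0: C = N (1 - e^-F), so F = -log(1 - C/N)
        C, N = 3e5, 1e6
        F = solve_baranov_f(C, N, 1e-9)
        assert F == pytest.approx(-np.log(1.0 - C / N), rel=1e-6)

    def test_round_trip(self):
        F, M, N = 0.3, 0.05, 1e6
        Z = F + M
        C = F / Z * N * (1.0 - np.exp(-Z))
        assert solve_baranov_f(C, N, M) == pytest.approx(F, abs=1e-8)

    def test_unattainable_catch_rejected(self):
        with pytest.raises(ValueError):
            solve_baranov_f(1e6, 1e6, 0.05)

    @pytest.mark.parametrize("F,M,expected", [
        (0.0, 0.05, 0.0),
        (0.05, 0.05, 50.0),
        (2.0 / 30, 0.1, 40.0),
    ])
    def test_exploitation_rate(self, F, M, expected):
        assert exploitation_rate(F, M) == pytest.approx(expected)


class TestFitting:
    def test_noise_free_recovery(self, noise_free_season):
        table, truth = noise_free_season
        numbers = (table["catch_weight_kg"] / table["mean_weight_kg"]).to_numpy()
        spec = PulseSpec(truth["pulse_timings"])
        true_params = IAGDParams(k=truth["k"], M=truth["M"], N0=truth["N0"],
                                 R=truth["pulse_abundances"],
                                 alpha=truth["alpha"], beta=truth["beta"])
        start = IAGDParams.from_array(true_params.to_array() * 1.5, spec.u)
        model = DepletionModel(numbers, table["effort_days"].to_numpy(),
                               spec, "profile-normal")
        res = model.fit(start=start, method="cg")
        rel = np.abs(res.iagd_params.to_array() / true_params.to_array() - 1.0)
        assert np.max(rel) < 1e-3

    def test_annualized_mortality_convention(self, noise_free_season):
        table, truth = noise_free_season
        numbers = (table["catch_weight_kg"] / table["mean_weight_kg"]).to_numpy()
        model = DepletionModel(numbers, table["effort_days"].to_numpy())
        res = model.fit()
        assert res.annualized_m() == pytest.approx(
            WEEKS_PER_YEAR * res.params["M"])

    def test_mismatched_start_rejected(self, noise_free_season):
        table, _ = noise_free_season
        numbers = (table["catch_weight_kg"] / table["mean_weight_kg"]).to_numpy()
        model = DepletionModel(numbers, table["effort_days"].to_numpy(),
                               PulseSpec((5,)))
        with pytest.raises(ValueError):
            model.fit(start=IAGDParams(k=1e-4, M=0.05, N0=1e6))  # no R

    def test_unknown_optimizer_rejected(self, noise_free_season):
        table, _ = noise_free_season
        numbers = (table["catch_weight_kg"] / table["mean_weight_kg"]).to_numpy()
        with pytest.raises(ValueError):
            DepletionModel(numbers, table["effort_days"].to_numpy()).fit(
                method="bfgs")


class TestDerivedQuantities:
    def _manual_results(self, u=0, cov=None):
        rng = np.random.default_rng(0)
        T = 10
        effort = np.full(T, 100.0)
        timings = (4,) if u else ()
        params = IAGDParams(k=1e-4, M=0.05, N0=1e6,
                            R=(2e5,) * u, alpha=1.0, beta=1.0)
        chat, _ = predict_catch(params, effort, PulseSpec(timings))
        catch = chat * rng.lognormal(0, 0.05, T)
        model = DepletionModel(catch, effort, PulseSpec(timings))
        x = params.to_array()
        if cov is None:
            cov = np.diag((0.05 * x) ** 2)
        return DepletionResults(model, x, 10.0, cov, 0.01, True, "cg")

    def test_b0_total_linear_case(self):
        res = self._manual_results(u=0)
        w0 = 0.5
        b0, se = res.total_initial_biomass(w0)
        assert b0 == pytest.approx(1e6 * w0 / 1000.0)
        assert se == pytest.approx(0.05 * 1e6 * w0 / 1000.0, rel=1e-4)

    def test_b0_total_back_discounts_pulses(self):
        res = self._manual_results(u=1)
        b0, _ = res.total_initial_biomass(1.0)
        expected = (1e6 + 2e5 * np.exp(0.05 * 4)) * 1.0 / 1000.0
        assert b0 == pytest.approx(expected, rel=1e-6)

    def test_b0_total_tiny_m_leaves_pulses_undiscounted(self):
        rng = np.random.default_rng(0)
        effort = np.full(10, 100.0)
        params = IAGDParams(k=1e-4, M=1e-12, N0=1e6, R=(2e5,))
        chat, _ = predict_catch(params, effort, PulseSpec((4,)))
        model = DepletionModel(chat, effort, PulseSpec((4,)))
        x = params.to_array()
        res = DepletionResults(model, x, 0.0, np.eye(len(x)), 0.0, True, "cg")
        b0, _ = res.total_initial_biomass(1.0)
        assert b0 == pytest.approx((1e6 + 2e5) / 1000.0, rel=1e-9)

    def test_delta_se_matches_monte_carlo(self, rng):
        x = IAGDParams(k=1e-4, M=0.05, N0=1e6, R=(2e5,)).to_array()
        sd = 0.05 * x
        cov = np.diag(sd ** 2)
        res = self._manual_results(u=1, cov=None)
        res_cov = np.diag((0.05 * res._xhat) ** 2)
        res.cov = res_cov
        w0 = 0.8
        _, se = res.total_initial_biomass(w0)
        draws = rng.multivariate_normal(res._xhat, res_cov, size=100_000)
        mc = (draws[:, 2] + draws[:, 3] * np.exp(draws[:, 1] * 4)) * w0 / 1000.0
        assert se == pytest.approx(mc.std(), rel=0.05)

    def test_missing_covariance_is_an_error(self):
        res = self._manual_results(u=0)
        res.cov = None
        with pytest.raises(ValueError):
            res.total_initial_biomass(0.5)

    def test_fishing_mortality_and_exploitation(self, noise_free_season):
        table, truth = noise_free_season
        numbers = (table["catch_weight_kg"] / table["mean_weight_kg"]).to_numpy()
        spec = PulseSpec(truth["pulse_timings"])
        params = IAGDParams(k=truth["k"], M=truth["M"], N0=truth["N0"],
                            R=truth["pulse_abundances"],
                            alpha=truth["alpha"], beta=truth["beta"])
        model = DepletionModel(numbers, table["effort_days"].to_numpy(), spec)
        x = params.to_array()
        res = DepletionResults(model, x, 0.0, np.eye(len(x)), 0.0, True, "cg")
        derived = res.derived_series()
        assert (derived["abundance"] > 0).all()
        assert (derived["fishing_mortality"].dropna() >= 0).all()
        e = derived["exploitation_pct"].dropna()
        assert ((e >= 0) & (e < 100)).all()


class TestEnumerationAndSelection:
    def test_recovers_single_pulse_timing(self):
        cfg = OperatingModelConfig(
            rng_seed=0, weeks_min=20, weeks_max=20,
            season=SeasonDynamics(k=3e-4, M_weekly=0.08,
                                  pulse_week_fracs=(0.5,), pulse_fracs=(0.3,)),
            obs_error=ObservationError(catch_cv=0.02, mean_weight_cv=0.0))
        table, truth = simulate_season(80_000.0, cfg, seed=6)
        numbers = (table["catch_weight_kg"] / table["mean_weight_kg"]).to_numpy()
        specs, fits = enumerate_pulse_hypotheses(
            numbers, table["effort_days"].to_numpy(), max_u=2)
        tau_true = truth["pulse_timings"][0]
        assert any(s.u >= 1 and min(abs(t - tau_true) for t in s.timings) <= 1
                   for s in specs)

    def test_max_u_zero_keeps_pure_depletion_only(self, noise_free_season):
        table, _ = noise_free_season
        numbers = (table["catch_weight_kg"] / table["mean_weight_kg"]).to_numpy()
        specs, fits = enumerate_pulse_hypotheses(
            numbers, table["effort_days"].to_numpy(), max_u=0)
        assert specs == [PulseSpec()]
        assert len(fits) == 1

    def test_selection_filters_and_tie_breaks(self):
        class Stub:
            def __init__(self, grad=0.1, cv_count=3, aic=100.0, nparams=5,
                         corr=0.2, form="profile-normal", converged=True):
                self.max_abs_grad = grad
                self._cv = cv_count
                self.aic = aic
                self.nparams = nparams
                self._corr = corr
                self.likelihood = form
                self.converged = converged
                self.cov = np.eye(2)
                self.pulse = PulseSpec()
                self.method = "cg"

            def key_param_cv_count(self, threshold=50.0):
                return self._cv

            def mean_abs_correlation(self):
                return self._corr

        ok = Stub(aic=100.0, nparams=5)
        big_grad = Stub(grad=1.5, aic=50.0)
        assert select_variant([ok, big_grad]) is ok

        # identical AIC: fewer parameters wins within a form
        lean = Stub(aic=100.0, nparams=5)
        heavy = Stub(aic=100.0, nparams=6)
        assert select_variant([heavy, lean]) is lean

        with pytest.raises(SelectionError):
            select_variant([Stub(converged=False), Stub(grad=7.0)])

    def test_selected_variant_never_exceeds_gradient_threshold(self):
        cfg = depletion_experiment_config(seed=1)
        table, _ = simulate_season(80_000.0, cfg, seed=31)
        numbers = (table["catch_weight_kg"] / table["mean_weight_kg"]).to_numpy()
        _, fits = enumerate_pulse_hypotheses(
            numbers, table["effort_days"].to_numpy(),
            form="profile-lognormal", max_u=1)
        best = select_variant(fits)
        assert best.max_abs_grad <= 1.0
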