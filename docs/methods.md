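# Methods

`fluctstock` implements a two-stage, hierarchical assessment of stocks
whose biomass fluctuates — short-lived, high-growth-rate species such as
octopus, squid and small pelagic fish — together with a ground-truthed
operating model for testing it. This note records the models, the
defaults and why they were chosen, the numerical choices, and what the
synthetic experiments do and do not demonstrate.

## Stage 1 — in-season generalized depletion

Within one fishing season of `T` weeks the expected catch in numbers is

    C_t = k E_t^α m (N0 e^{-Mt} − m Σ_{i<t} C_i e^{-M(t-i-1)}
          + Σ_j 1{t ≥ τ_j} R_j e^{-M(t-τ_j)})^β,   m = e^{-M/2}

- `N0` — vulnerable abundance at the season start (t = 0), numbers.
- `M` — weekly natural mortality (1/week); reported annualized as 53·M.
- `k` — generalized catchability scaling; `α` (effort response) and `β`
  (abundance response) modulate gear saturation and hyperstability
  (`β < 1`: catch rates fall slower than abundance).
- `(R_j, τ_j)` — episodic abundance inputs (recruitment to the fished
  sizes, or fleet area expansion) at week `τ_j`.
- `m` places the week's catch instantaneously at mid-week.

The bracket is the latent weekly abundance `N_t`. Derived quantities:
weekly fishing mortality by inverting Baranov's catch equation
(Brent root-finding; `C = F/(F+M)·N·(1−e^{-(F+M)})`), the exploitation
rate `100·F/(F+M)` (reported against the 40% reference line), and
start-of-season total biomass
`B0 = (N0 + Σ_j R_j e^{M τ_j})·w̄0 / 1000` tonnes, pulses back-discounted
to the season start, with a delta-method standard error.

**Observation model.** The observed catch is treated as a noisy
(lognormal or normal) realization of the true catch. Coherently with
that, the depletion sum inside the likelihood runs on the model's own
predicted catches (`conditioning="predicted"`, the default). The
classical alternative — conditioning the depletion sum on the observed
catches — is available (`conditioning="observed"`) but is fragile
precisely in the informative regime: when a season removes most of the
stock, observation noise makes the observed removals overshoot the
remaining abundance, so the latent bracket turns negative at the true
parameter values in a large fraction of replicates.

**Likelihoods.** Four forms: concentrated ("profile") normal and
lognormal, in which the dispersion is profiled out analytically, and
exact normal and lognormal with the dispersion estimated jointly. The
published description of the two approximated likelihoods delegates
their exact algebra to a cited table; the package implements the
standard concentrated forms, which share their argmin with the exact
forms at the conditional dispersion optimum (`σ̂² = SSR/n`) — the joint
AIC differs only through the extra counted parameter.

**Optimization.** All parameters are estimated on the log scale
(positivity without box constraints). A trust-region least-squares
refinement stage runs first — valid because the concentrated objectives
are monotone transforms of the residual sum of squares — followed by the
requested optimizer (`cg` conjugate gradients, `spg` bounded
quasi-Newton, `neldermead` simplex) and a simplex polish. When the model
conditions on predicted catches, the least-squares stage first uses the
observed-catch recursion (anchored to the data, finite everywhere) and
then re-refines under the predicted recursion. Infeasible brackets
return a large finite objective (1e10) so simplex searches stay stable.
Standard errors come from the inverse observed Hessian at the optimum
(finite differences), with a log-scale fallback when the natural-scale
Hessian is singular.

**Pulse enumeration.** Following the forward protocol: fit pure
depletion; propose a pulse at each standing-out positive residual
(standardized residual > 2, near-ties within 0.5 SD spawning alternative
timings); refit; keep extending while the AIC improves and `u` is below
the cap (5). A poorly determined pure fit with no standout is still
probed once at its largest positive residual week — ill-determined pure
fits are informative through the manner in which they fail.

**Variant selection.** Sequential filters: (1) numerical — drop fits
with max|gradient| above 1 (gradient measured on the log/optimization
scale) or without a usable covariance; (2) statistical — keep the fits
with the most biomass-relevant parameters (`M`, `N0`, `R_j`) estimated
with CV below 50%; (3) information — minimum AIC within a likelihood
form; across forms the fit with off-diagonal correlations most clustered
around zero wins, ties broken by parsimony.

## Stage 2 — regime-switching Pella-Tomlinson production

Annual dynamics: `B_y = B_{y-1} + r_i B_{y-1}(1 − (B_{y-1}/K_i)^{p_i−1})
− C_{y-1}`, with biomass the year before the series fixed at `K1` and an
optional parameter switch (any subset of {K, p, r}, eight variants) at a
known transition year. Landings are treated as exact. The fit maximizes
the self-weighting marginal likelihood

    −½ Σ_y [log(2π s_y²) + (B̂_y − B_y)² / s_y²]

where `B̂_y, s_y` are the stage-1 biomass estimates and SEs: imprecise
years weigh themselves down.

**Optimization.** Transformed scale (log K, log(p−1), log r). The
gradient of the marginal likelihood is computed analytically by
forward-propagating the trajectory sensitivities dB_y/dθ through the
recursion (verified against finite differences to 1e-10). This matters:
in the oscillatory regime the trajectory's parameter sensitivity is
enormous, finite-difference gradients read 1e6 and beyond even at true
optima, and a max-gradient retention rule is only implementable with
exact derivatives. Where the recursion would drive predicted biomass
non-positive, the trajectory is floored at a token 1 t and each year's
shortfall enters the objective as a squared term on the weighted
residual scale — a large but smooth penalty, so gradients stay
informative near the collapse boundary (the hard-collapse trajectory
still drives the anomaly flag).

Fitting runs: a coarse global pre-screen over an (r, p) grid at the
starting K; a simplex multistart (default 6 jittered starts); a bounded
exact-gradient quasi-Newton phase inside boxes set at the plausibility
caps (r ≤ 10/yr — the upper end of empirically observed growth rates —
and p ≤ 5, both configurable); then free quasi-Newton polish passes
interleaved with a simplex pass. The likelihood is flat along the ridge
where only `r/(p−1)` matters (the effective growth rate), so a free
polish can drift to absurd (p→1, r→∞) points of equal likelihood; when
that happens without a material likelihood gain (< 1 log-unit) the
bounded-phase interior representative is kept. Estimates still beyond
the caps, predicted collapse inside the observation window, or estimates
crashed against a bound are anomaly flags; variant selection drops
flagged fits and non-converged fits, then takes minimum AIC (one shared
likelihood form), ties by correlation clustering then parsimony.

**Reference points.**
`MSY = rK(p−1)p^{−p/(p−1)}`, `B_MSY = K p^{1/(1−p)}`, and the total
latent productivity `TLP_y = γ·MSY·(B_y/K)(1−(B_y/K)^{p−1}) + C_y` with
`γ = p^{p/(p−1)}/(p−1)` (identity: `γ·MSY = r·K`). The TLP's multi-year
average per regime period is the sustainable harvest rate for
fluctuating stocks; delta-method SEs propagate the full fit covariance
through the trajectory. The stability diagnostic classifies the unfished
equilibrium by the map derivative at K: unstable iff `r(p−1) > 2`
(boundary classified stable with a flag).

A property worth knowing: beyond `r(p−1) ≈ 2.57` the unfished discrete
map is not merely cyclic — overshoots above K can drive the next step
negative. Unfished trajectories at the case-study offshore-stock
estimates (r(p−1) ≈ 3.2) crash from generic starting points; only the
exact fixed point at K persists. The operating model treats such crashes
as errors rather than clipping them.

## Projections

Ten-year stochastic projections under five landings scenarios: constant
expectation at MSY, at the average TLP (both with 25% implementation
CV), at the historical average landings with the historical CV, and at
75%/50% of that average with proportionally scaled CVs. Per replicate,
one `(K, p, r)` is drawn from unbounded normals centred at the estimates
with SD equal to the SEs (infeasible draws rejected, capped at 1,000
tries); annual catches are drawn from a normal truncated one SD each
side of the expectation and at zero; realized catch cannot exceed the
biomass present; biomass at or below zero is absorbing and recorded as a
collapse. Bands are mean ± 2·(replicate SD/√n_reps), lower band floored
at zero. Scenario comparisons reuse one seed (common random numbers).

A substantive finding reproduced by the test suite: collapse risk is
*not* always monotone in the catch level. At the offshore stock's
estimates, lightly fished replicates climb to carrying capacity, where
the map overshoots and self-crashes, so the TLP scenario has *lower*
collapse risk than scenarios at half the historical landings. At the
inshore stock's estimates monotonicity holds.

## Data preparation

Trip records are aggregated to the weekly step of each August–December
season, each trip attributed wholly to its sailing week (multi-week
trips incur a tolerated time-attribution error rather than being
pro-rated); weeks without trips appear with zero effort and catch. Mean
individual weight against week-of-season (pooled across years) is
smoothed with a cubic B-spline regression whose basis dimension is
chosen by generalized cross-validation; every week of every season —
observed or missing — is then replaced by a draw from a normal centred
on the smoothed prediction with the prediction SE as scale, truncated at
two SDs (lower bound floored at 1 g when the band crosses zero; a flag
preserves raw observed values instead). Catch in numbers is catch weight
divided by the week's mean weight. Weeks per year: 53, matching the
annualization convention.

## Operating model (synthetic data)

The generator emulates the fishery that motivates the package: 22
seasons of 19–23 weeks, annual biomass from the two-regime recursion
started at `K1` with a production-shape change at the 12th season (the
published inshore-stock estimates are the defaults), and within each
season the depletion equation run forward without noise for the truth,
then multiplicative lognormal observation error (catch CV 5% --
weekly totals aggregate hundreds of trips, so their relative error is
small -- and mean-weight CV 5%). Effort is a unimodal in-season shape (optionally
with a multi-week closure window, as storm shutdowns impose in the
emulated region) times lognormal variation (CV 30%) around 3,000
effective days/week. The season's start biomass is split into `N0` and
pulse abundances so that back-discounting reproduces the biomass
exactly; two pulses at ~25% and ~55% of the season each carry 20% of the
start abundance (in-season additions of the order the emulated fishery
reports, and large enough for residual-based enumeration to find). The season's true landed weight feeds back into the
annual recursion. A master seed spawns one substream per season and is
recorded in the truth bundle; infeasible configurations raise instead of
clipping.

Default in-season catchability (k = 3e-4, M = 0.08/week) places the
fishery in the informative regime the motivating assessment reports —
roughly half the vulnerable stock removed per season and weekly
exploitation near the 40% reference — because a weakly depleted season
leaves `N0` and `M` on a likelihood ridge where no estimator determines
them usefully.

**Recovery-study conditions.** Single-season parameter-recovery
experiments use `depletion_experiment_config()`: a pulse-free 23-week
season with front-loaded effort (effort peak at ~25% of the season,
effort CV 0.15) and k = 6e-4, M = 0.1/week (annualized ≈ 5.3/yr, the
upper range observed in short-lived octopus), removing ≈ 70% of the
stock. A Fisher-information analysis guided this design: near-exhaustion
early in the season pins `N0` against the cumulative catch, and the
remaining decline identifies `M`. Free pulse sizes absorb `M` almost
completely, which is why the recovery design is pulse-free; with pulses,
`M` is reported honestly with CVs that often exceed 50%, as the
selection protocol expects. Even in this design, the finite-sample
median error of `M` under 10% catch noise sits near the 10% mark — the
`β–M` coupling is an information limit of the model at ~20 observations
per season, not an optimizer artifact (fits reaching lower
negative log-likelihood than the truth confirm this).

Stage-2 recovery studies use constant annual catches at the published
period-average landings (7,319 t pre-switch, 19,206 t post-switch) — the
catch series itself is not published — and normal biomass observation
noise with SD = 3% of the true biomass, reported as the known
observation SE (exactly the observation model the marginal likelihood
assumes). Richer (randomly varying) catch series were *not* used: in the
oscillatory regime they excite trajectory divergence and degrade
estimation, which is itself a property worth knowing.

## What the synthetic experiments do and do not show

They show: the estimation pipeline recovers its own generating process
(correct likelihoods, correct derivatives, correct uncertainty
propagation at first order); the selection filters discard
ridge-degenerate variants; the MSY/TLP projection contrast follows from
the fitted dynamics. They do not show: robustness to structural
misspecification (process error in the in-season dynamics, time-varying
catchability within a season, species misclassification, effort
measurement error), because the generator does not produce those
features. Mean-weight noise cancels exactly in the synthetic
weight-to-numbers conversion, so the imputation machinery is exercised
by its own tests, not by the recovery studies.

## Numerical conventions

- Week index starts at t = 1 on the first fishing week; `N0` is at t = 0.
- Positivity via log (and log(p−1)) re-parameterization; no boxes except
  the stage-2 bounded phase.
- Delta-method gradients: central differences, relative step 1e-5.
- Profile likelihoods guard a perfect fit with an absolute epsilon floor
  (1e-12) inside the log.
- Collapsing stage-2 trajectories are floored at 1 t with smooth
  squared shortfall penalties rather than a hard cliff or NaN.
- AIC = 2·n_par − 2·logLik, dispersion counted where jointly estimated.
- Tie-breaks in selection are deterministic (AIC rounded at 1e-6, then
  parsimony, then correlation clustering).

## Known limitations

- `M` and `N0` are only as identifiable as the season design allows;
  weakly depleted seasons produce large, honestly reported CVs.
- The `r/(p−1)` ridge means `r` and `p` separately are poorly determined
  unless removals excite the dynamics at different biomass levels; the
  bounded phase keeps fits interior but cannot add information.
- Stage-2 SEs are curvature-based; in the oscillatory regime the
  sampling distribution is heavier-tailed than Gaussian, so nominal 2-SE
  coverage runs a few points below 95%.
- The pipeline assumes one species per dataset and a single fleet.
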