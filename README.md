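# fluctstock

Two-stage stock assessment for **fluctuating stocks** — populations
(octopus, squid, small pelagic fish, other short-lived species) whose
high intrinsic growth rate `r` puts their discrete-time dynamics into
sustained oscillation, where a classical MSY equilibrium does not exist.

The package is aimed at stock-assessment scientists working with
data-intermediate fisheries: weekly totals of fishing effort, catch
weight and mean individual weight, over many annual seasons.

## What it computes

**Stage 1 — intra-annual generalized depletion.** For each season, the
weekly catch equation

    C_t = k E_t^α m (N0 e^{-Mt} − m Σ_{i<t} C_i e^{-M(t-i-1)}
          + Σ_j 1{t ≥ τ_j} R_j e^{-M(t-τ_j)})^β,   m = e^{-M/2}

is fitted by maximum likelihood (profile/exact, normal/lognormal forms),
with in-season abundance pulses `(R_j, τ_j)` found by a forward residual
search and the best variant chosen by gradient, correlation, CV and AIC
criteria. Derived outputs: weekly abundance, Baranov fishing mortality,
exploitation rate, and start-of-season total biomass with a delta-method
SE.

**Stage 2 — regime-switching Pella-Tomlinson.** The annual biomass
estimates (with their SEs) are fitted by a self-weighting marginal
likelihood to

    B_y = B_{y-1} + r_i B_{y-1} (1 − (B_{y-1}/K_i)^{p_i−1}) − C_{y-1}

with an optional parameter switch at a known year (eight variants).
Reference points: `MSY = rK(p−1)p^{−p/(p−1)}`, `B_MSY = K p^{1/(1−p)}`,
and the **total latent productivity**
`TLP_y = γ·MSY·(B_y/K)(1−(B_y/K)^{p−1}) + C_y`, whose multi-year average
is the sustainable harvest rate when the stock fluctuates
(`r(p−1) > 2` ⇒ the unfished equilibrium is unstable).

**Projections.** Ten-year stochastic projections under five landings
scenarios (MSY, average TLP, historical average landings, 75% and 50%
of it) with parameter and implementation uncertainty, reporting
mean ± 2 SE bands and collapse probabilities.

A ground-truthed synthetic operating model (`fluctstock.operating_model`)
generates multi-season weekly datasets from this exact generative
process, so every stage is testable without any proprietary data.

## Worked example

```python
import numpy as np
from fluctstock import msy, bmsy, tlp

# published post-expansion estimates of the offshore Yucatan octopus
K, p, r = 82_354.0, 1.9108, 3.5084
print(f"MSY   = {msy(K, p, r):,.0f} t")
print(f"B_MSY = {bmsy(K, p):,.0f} t")
print(f"TLP at B=60,000 t, C=11,216 t: {tlp(60_000, 11_216, K, p, r):,.0f} t")
```

prints

```
MSY   = 67,646 t
B_MSY = 40,451 t
TLP at B=60,000 t, C=11,216 t: 63,961 t
```

MSY and B_MSY are the classical reference points computed from the
fitted production curve; the TLP line evaluates that year's total latent
productivity (latent surplus production at the current biomass plus the
observed catch). Projecting this stock forward shows why the MSY is the
wrong harvest rate for a fluctuating stock:

```python
from fluctstock import Scenario, project_stochastic

fit = {"est": {"K": K, "p": p, "r": r},
       "se": {"K": 0.0, "p": 0.0, "r": 0.0},
       "b_init": K, "first_year": 2021}
msy_run = project_stochastic(fit, Scenario("MSY", 67_646.0, 0.0),
                             n_reps=2, seed=0)
tlp_run = project_stochastic(fit, Scenario("TLP", 24_963.0, 0.0),
                             n_reps=2, seed=0)
print("collapse year under MSY:", msy_run.years[msy_run.collapsed_at[0] + 1])
print("biomass in 2031 under TLP:",
      round(float(tlp_run.biomass[0, -1])), "t")
```

```
collapse year under MSY: 2023
biomass in 2031 under TLP: 88917 t
```

Constant harvest at the MSY drives the stock to zero in two years;
harvest at the average TLP keeps it cycling and positive through the
decade.

End-to-end on synthetic data (simulate → per-season depletion fits →
annual series → production variants → reference points → projections):

```bash
fluctstock run --seed 3 --out my_run     # or: simulate / prep / fit-iagd / fit-pt / refpoints / project
```

which writes per-stage CSV/JSON artifacts and a `manifest.json` tracing
every number to its stage output.

## Documentation

`docs/methods.md` describes the models, estimation details, the
operating-model design and its rationale, numerical conventions and
known limitations.
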