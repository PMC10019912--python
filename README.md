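# cbctrends

Century-scale population dynamics of over-wintering birds from
Christmas-Bird-Count-style survey data: Bayesian abundance estimation
under imperfect detection, trend-derivative non-stationarity analysis,
and k-medoids clustering of population trajectories.

Winter count surveys are one of the few data sources long enough to ask
how bird populations changed over a full century — but the raw counts
confound abundance with observation effort, effort itself often went
unrecorded before 1967, and some circle-years were never surveyed.
`cbctrends` is for quantitative ecologists who want to work with such
data end to end:

1. **Effort imputation** — per circle, party hours over years are fit by
   a scaled gamma-density curve, `hours ≈ A·g(year − y₀; k, θ)`; pre-1967
   gaps are filled from the curve and post-1967 gaps by loess-style local
   regression, each with 2-SE prediction intervals that feed forward as
   detection-covariate measurement error.
2. **Single-visit Dail–Madsen model** — an open-population N-mixture
   model estimated by MCMC:

       N[i,1] ~ Poisson(Λ_i)                        log Λ = Z·β_λ
       S[i,t] | N[i,t−1] ~ Binomial(N[i,t−1], ω)    logit ω = Z·β_ω
       R[i,t] | N[i,t−1] ~ Poisson(γ·N[i,t−1])      log γ = Z·β_γ
       N[i,t] = S[i,t] + R[i,t]
       X[i,t] | N[i,t] ~ Binomial(N[i,t], p)        logit p = α₀ + a_e·effort + a_m·temp

   with standardized covariates (elevation, preferred-habitat area,
   developed area, human density), sign-constrained detection slopes
   (a_e > 0, a_m < 0), latent effort where imputed, and Gelman–Rubin
   convergence diagnostics.
3. **Trends** — posterior mean abundances, trimmed to the species'
   detection range, are smoothed by a penalized cubic-spline GAM
   (thin-plate fallback); first derivatives over 3-year windows classify
   trajectories as temporally non-stationary (sustained rise *and* fall
   of ≥ 5 years), ≥ 15-year decliners, or ≥ 8-year increasers.
4. **Clustering** — standardized trends are partitioned around k = 4
   medoids (exact PAM; CLARA-style subsampling for large
   circle-by-species matrices), and per-circle cluster composition is
   tested against uniformity with a chi-square dominance test.

Real survey data of this kind are available only by request, so the
package ships a first-class synthetic-data module that generates panels
with the same statistical structure (gamma-shaped effort with archival
missingness, near-stationary demography, detection driven by effort and
temperature, four planted trend archetypes); every stage is tested
against it, several directly against exact enumeration oracles.

## Worked example

```python
import numpy as np
import cbctrends as cb
from cbctrends import clustering, effort, trends
from cbctrends.dmm import (MCMCConfig, gelman_rubin, sample_posterior,
                           summarize_abundance)

# 1. simulate a small 40-year study and apply the study filters
cfg = cb.synthetic.SimulationConfig(n_circles=8, year_start=1979, year_end=2018,
                                    missing_prob_pre1967=0.0,
                                    missing_prob_post1967=0.04, seed=42)
study = cb.synthetic.simulate(cfg)
panel, report = cb.synthetic.apply_study_filters(study.panel)

# 2. impute missing effort (adds interval_width + source columns)
imputed = effort.impute_effort_panel(study.effort_table)
print(f"imputed {(imputed['source'] != 'observed').sum()} of {len(imputed)} "
      "circle-year effort values")

# 3. fit the Dail-Madsen model (short demonstration chains)
draws = sample_posterior(panel, config=MCMCConfig(n_iter=4000, burn_in=2000,
                                                  chains=2), seed=1)
print(f"max Gelman-Rubin over coefficients: {gelman_rubin(draws).max():.3f}")
est = summarize_abundance(draws)
print("regional mean abundance, first/last 3 years:")
print(est.yearly_mean.iloc[[0, 1, 2, -3, -2, -1]].round(1).to_string())

# 4. smooth the regional series and classify its runs
detections = panel.years[np.nansum(panel.counts > 0, axis=0) > 0]
curve = trends.fit_trend(trends.mean_abundance_series(est, detections))
flags = trends.classify_trend(curve)
print(f"basis: {curve.basis}; derivative steps: {len(curve.derivative)}")
print(f"nonstationary={flags.nonstationary} decline15={flags.decline15} "
      f"increase8={flags.increase8}")
print(flags.runs.to_string(index=False))

# 5. cluster planted archetype trends
import itertools
m, labels = cb.synthetic.generate_trend_archetypes(50, 100, 0.1, seed=0)
std, kept = clustering.standardize_trends(m)
res = clustering.pam(std, k=4, seed=0)
agree = max(np.mean(np.array([p[l] for l in labels[kept]]) == res.assignments)
            for p in itertools.permutations(range(4)))
print(f"k-medoids cost {res.total_cost:.1f}; label agreement {agree:.3f}")
```

Output:

```
imputed 9 of 320 circle-year effort values
max Gelman-Rubin over coefficients: 1.364
regional mean abundance, first/last 3 years:
year
1979    12.7
1980    13.1
1981    13.2
2016    16.8
2017    16.6
2018    16.7
basis: cubic-spline; derivative steps: 13
nonstationary=True decline15=False increase8=True
 direction  start_year  length_years
increasing        1979            18
decreasing        1997             3
increasing        2000             6
decreasing        2006            12
k-medoids cost 742.7; label agreement 1.000
```

Reading it: nine unrecorded effort values were reconstructed before
fitting; the demonstration-length chains (4,000 iterations) have not yet
converged (Gelman–Rubin 1.36 — the desk preset of 20,000 iterations
reaches ≤ 1.1); the smoothed regional trajectory rose for 18 years, fell,
recovered and fell again — a temporally non-stationary history with a
sustained (≥ 8-year) increase but no 15-year decline; and exact k-medoids
recovers all four planted trend archetypes at 10% noise.

The same pipeline is scriptable from a shell:

```bash
cbctrends simulate --out sim/ --seed 1
cbctrends impute-effort --in sim/effort.csv --out sim/effort_imputed.csv
cbctrends fit-dmm --panel sim/ --out fit/ --mcmc-preset desk --seed 1
cbctrends trend --estimates fit/abundance.csv --out trends/
cbctrends cluster --trends trends/fitted.csv --k 4 --out clusters/
cbctrends summarize --assignments clusters/assignments.csv --out summary/
```

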