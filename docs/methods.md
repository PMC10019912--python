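# Methods

`cbctrends` implements a century-scale population-dynamics pipeline for
winter bird-count data: effort imputation, Bayesian open-population
abundance estimation under imperfect detection, GAM-based trend and
derivative extraction, run-length non-stationarity classification, and
k-medoids clustering of population trajectories. This note records the
models, the default parameter choices and why, the numerical decisions,
and what the synthetic test bed does and does not establish.

## The observation problem

Winter count surveys record, once per year per survey circle, the number
of individuals of a species seen during a day of fieldwork. Counts
confound true abundance with detection: more party hours (observer-hours)
find more birds, colder days hide them. The record is also ragged — in
the early decades effort often went unrecorded, and some circle-years were
never surveyed at all. The pipeline therefore (1) reconstructs missing
effort with quantified uncertainty, (2) estimates true abundance jointly
with detection, and only then (3) measures trends.

## Effort imputation (`cbctrends.effort`)

Party hours per circle grew over the century along a hump-shaped path
that is well approximated by a scaled gamma probability density in the
survey year. Each circle is fit independently by nonlinear least squares:

    hours(year) ≈ A · g(year − y₀; k, θ),   g = gamma pdf.

The fit is multimodal in (k, θ, y₀), so the optimizer runs from a default
initialization (onset at the circle's first sampled year) plus three
perturbed restarts, keeping the lowest-SSE solution; A, k, θ are
optimized on the log scale to stay positive. Pre-1967 gaps are filled
from this curve. Post-1967 gaps (the modern record is ~96% complete) are
filled by loess-style local regression — tricube weights over a span of
0.75 of the data, locally *quadratic* (degree 2, matching standard loess
and needed to avoid curvature bias; a locally linear fit leaves ~2% bias
on the curved effort path even without noise). Extrapolation outside the
observed span is refused and deferred to the gamma curve.

Every imputed value carries a 2-standard-error prediction interval;
`interval_width` stores the full width (4·SE for the gamma curve,
equivalent-kernel SE for the smoother) and is exactly 0 for observed
entries. Observed values are never altered. The positivity floor for
effort is 0.1 party hours, because the detection link requires positive
effort.

## The single-visit Dail–Madsen model (`cbctrends.dmm`)

For circles i and years t:

    N[i,1] ~ Poisson(Λ_i),                log Λ = Z·β_λ
    S[i,t] | N[i,t−1] ~ Binomial(N[i,t−1], ω_it),   logit ω = Z·β_ω
    R[i,t] | N[i,t−1] ~ Poisson(γ_it · N[i,t−1]),   log γ = Z·β_γ
    N[i,t] = S[i,t] + R[i,t]
    X[i,t] | N[i,t] ~ Binomial(N[i,t], p_it),
    logit p = α₀ + a_e·effort + a_m·temp,   a_e > 0, a_m < 0.

Z holds an intercept plus elevation, preferred-habitat area, developed
area and human population density, all standardized to mean 0, sd 1.
Log links for Λ and γ and logit links for ω and p are the canonical
choices for this model family. Rates are clipped after link inversion
(ω to [1e−9, 1−1e−9]; γ, Λ to [1e−9, ∞)) so extreme covariate draws
cannot produce degenerate samplers. Years without a survey contribute no
observation term but the latent dynamics still propagate. Detection is
shared across circles (one global α); the species are fit independently.

Priors are Normal(0, 10²) on all coefficients, with a_e and a_m restricted
to half-lines by proposal rejection (equivalently, truncated normals).
Where effort was imputed, the standardized effort covariate is itself a
latent variable with a normal measurement model centered at the imputed
value; the sd maps from the stored interval width by a configurable rule
{width, width/2, width/4}, default width/4 (the 2-SE half-width
back-transformed to one SE).

### Sampler

The posterior is explored by Metropolis-within-Gibbs over coefficients,
latent integer abundances, and latent effort. The single-visit design
makes this posterior ridge-heavy — survival trades against recruitment
through the latent survivor/recruit split, the detection intercept trades
against total abundance, and collinear trending covariates correlate the
slope blocks — so the sampler layers several move families, each of which
was validated against exact enumeration posteriors on tiny instances
(total-variation distance < 0.015 at 50k draws):

* component-wise random-walk sweeps with burn-in-adapted scales (target
  acceptance 0.44, frozen afterwards so retained draws come from a fixed
  kernel);
* adaptive-covariance block proposals (Haario-style, covariance learned
  during burn-in then frozen) for the initial-abundance block, the
  detection block, and a *joint* 10-dimensional survival+recruitment
  block — the ω/γ slope pairs of one covariate are correlated near −1 and
  must move together;
* integer random-walk moves on the latent states: initial abundance,
  recruit-driven abundance changes on an odd/even year checkerboard
  (so simultaneous proposals never share a likelihood term),
  survivor/recruit swaps at fixed N, and whole-trajectory shifts, all
  with symmetric two-scale step sizes (small steps plus occasional large
  ones for high-abundance sites);
* an exact Gibbs re-draw of the survivor/recruit split: conditional on
  N[t−1], N[t] and the rates, the survivor count has a log-concave
  discrete density sampled exactly by inverse CDF on a windowed grid;
* survivor-*marginalized* moves: the demographic block proposal and a
  coordinated (α₀, trajectory-shift) ridge move are accepted using
  P(N | θ) = Σ_s Bin(s; N_prev, ω)·Pois(N_t − s; γ N_prev), i.e. with the
  split summed out, and the split is re-drawn from its exact conditional
  on acceptance. The acceptance ratio provably does not involve the
  current split, which removes the stiffest ridges entirely. The
  marginal sums run in numba kernels; windows are centered on the exact
  per-cell mode (binary search on the monotone weight ratio) and grown
  adaptively until edge weights fall 30 log-units below the mode, making
  truncation error ~1e−11 (verified against full-support summation over
  500 random transitions).

The coordinated ridge move proposes α₀ + u together with per-site
trajectory shifts of opposite sign whose magnitudes are Poisson with mean
|u|·k_i (k_i a fixed per-site count scale); the magnitude law depends
only on |u|, so the proposal is symmetric and ordinary Metropolis
acceptance applies.

Initialization: N[i,t] = max observed count of the circle + 1,
coefficients at zero (sign-projected for a_e, a_m); chains beyond the
first jitter their starting coefficients by N(0, 0.5²) for over-dispersed
starts. Presets: `desk` (3 chains × 20,000 iterations, 10,000 burn-in —
all defaults and benchmarks below) and `production` (100,000/80,000), with
latent states thinned 20× for storage.

### Coefficients are scale-relative

Coefficients are defined relative to the z-scores of the panel being
fit. Filtering circles (e.g. dropping ones where the species became too
rare) re-centers and re-scales the covariates, and because the filter
selects on abundance the shift is systematic, not noise — on recovery
benchmarks the implied initial-abundance intercept moves by ~0.05–0.1.
`rescale_params` re-expresses a coefficient vector under a different
standardization (slopes scale by sd ratios; intercepts absorb the mean
shifts), which is how simulation truths are compared against fits on
filtered panels.

### Exact oracle

`marginal_loglik_bruteforce` computes the observed-data likelihood
exactly on tiny instances by a forward recursion over truncated abundance
(the transition kernel is the explicit survivor sum above), and
`grid_posterior` turns it into a normalized posterior over a grid for one
coefficient. These are the independent reference implementations for the
sampler-validation tests; they share only the link functions with the
sampler. One caution baked into the tests: a grid comparison is only
meaningful when the data actually identify the profiled coefficient. For
a recruitment (or survival) intercept this requires counts that *rise
from zero* — otherwise survival alone explains the data, the likelihood
plateaus as the rate → 0, and the true posterior carries a prior-wide
tail that no finite grid covers.

### Convergence and summaries

The Gelman–Rubin statistic uses the classic between/within variance form,
floored at 1.0 (the raw statistic is exactly √((n−1)/n) < 1 for identical
chains, and values below 1 carry no information); values ≤ 1.1 are taken
as adequate convergence. Abundance summaries report the posterior mean,
central 95% interval (empirical 2.5%/97.5% quantiles of pooled draws) and
effective sample size per circle-year, plus the region-wide yearly series
as the arithmetic mean of per-circle posterior means.

## Trends and non-stationarity (`cbctrends.trends`)

Region-wide series are trimmed to the species' detection range (no
extrapolation beyond the years it was ever recorded) and smoothed with a
GAM: a penalized cubic B-spline of abundance on year, basis dimension
clip(n/4, 4, 10), penalty weight chosen by GCV with a deterministic
optimizer (the default stochastic basin-hopping search made refits
non-reproducible at the 1e−6 level). If the cubic fit fails — e.g. a
zero-residual series trips the perfect-separation guard — the fallback is
the GCV cubic smoothing spline, the 1-D thin-plate equivalent, and the
basis used is recorded.

Rates of change are first differences of the fitted curve over
consecutive non-overlapping 3-year windows anchored at the trimmed start
(positive = increasing abundance). Finite differences were chosen over
analytic spline derivatives as the more assumption-free reading of a
"per-3-year-interval" derivative; on a fitted line of slope b every step
equals 3b to 1e−6. Maximal same-sign runs of these steps (a run of r
steps spans 3r years; steps exactly zero within 1e−12 break runs and
count toward neither direction) classify a trajectory:

* non-stationary — an increasing and a decreasing run of ≥ 5 years each;
* sustained decline — a decreasing run of ≥ 15 years;
* sustained increase — an increasing run of ≥ 8 years.

## Clustering (`cbctrends.clustering`)

Trend curves are standardized row-wise to mean 0, sd 1 (shape, not level
or amplitude, drives the grouping; constant rows are excluded with a log
entry). Curves of unequal year span are linearly time-rescaled to a
common 100-point grid first. Dissimilarity is Euclidean.

`pam` is the classic BUILD + SWAP partitioning around k = 4 medoids.
SWAP is a single-exchange local search; on small unstructured instances
it can stall in a local optimum (the R reference implementation stalls on
the same instances), so `pam` restarts SWAP from seven seeded random
medoid sets besides the BUILD start and keeps the cheapest solution —
each descent is still textbook PAM with non-increasing cost. `clara`
handles large matrices by running PAM on random subsamples (without
replacement within a subsample, default size 1000) and scoring every
candidate medoid set on the *full* matrix; the default of 5 subsamples is
the classical CLARA choice, with the production-scale 1000×1000
configuration available for very large circle-by-species matrices.
Assignment to medoids is nearest-medoid with ties broken toward the
lowest index.

## Spatial summaries (`cbctrends.spatial`)

Per circle, the species present are tallied by cluster label (optionally
within one habitat guild). A chi-square goodness-of-fit test against
equal proportions (df = 3; configurable non-uniform null) flags circles
whose composition departs from uniform; a dominant label (argmax count)
is reported only when p < 0.05, so maps never color a circle on noise.
Circles with fewer than 8 species are left untested — below that the
expected cell count drops under 2 and the chi-square approximation is
unreliable. No multiple-testing correction is applied across circles:
the test is used descriptively to decide which circles get a color, and
the choice is recorded in the output metadata.

## Synthetic data (`cbctrends.synthetic`)

The generator emulates the statistical structure the analysis assumes:
gamma-shaped effort growth (default peak ~60 party hours around 2010)
with ~50% pre-1967 and 4% post-1967 missingness, circle-level minimum
temperature gradients, static elevation, land-cover areas stepping every
5 years, decadal human-density steps with last-value-carried-forward,
Dail–Madsen latent dynamics, and binomial thinning through the
detection model. Counts are missing wherever the effort record is
missing. Everything is deterministic given the configuration seed.

Default demography is deliberately near-stationary: ω ≈ 0.85,
γ ≈ 0.15, demographic covariate slopes ≤ 0.03 in magnitude. Effects on
survival and recruitment compound over 100 transitions — slopes of 0.1–0.3
(unremarkable for a single-year model) drive sites to 10⁵ birds or
extinction within the century — whereas initial-abundance effects do not
compound, so the λ block keeps strong slopes (up to 0.4). Typical counts
are tens per circle with realistic local extinctions (which the study
filters then remove: circles sampled fewer than 30 times or with fewer
than 10 detections are dropped, thresholds exclusive).

Two named parameter sets support the benchmark studies, both chosen by
identifiability reasoning at their study scales: `convergence_dmm_params`
(abundance scale Λ ≈ 30 on a 20-circle × 40-year panel — binomial
information about survival and detection grows with N, making all
coefficients estimable while counts stay in the low hundreds) and
`recovery_dmm_params` (50 circles × 30 years; demographic slopes
|0.1–0.12|, about twice their posterior sd at that scale, so sign
recovery is a meaningful check rather than a coin flip).

The four planted trend archetypes mirror the common century-scale
patterns: steady decline (fastest early), steady increase,
increase-then-decline (peak near mid-century), and flat-then-increase
(rise beginning around the 1970s mark of the series).

### What the synthetic bed does not show

The generator draws covariates independently across circles, uses a
single global detection model, and contains no spatial autocorrelation,
observer heterogeneity, zero-inflation beyond the model's own dynamics,
or species interactions. Passing tests therefore demonstrate that the
estimation machinery is *correct under its own assumptions* and
well-calibrated at the stated scales — not that those assumptions hold
for any particular field data set.

## Benchmark problem sizes

Desk-scale studies were sized to run comfortably on one CPU: the
convergence benchmark fits 20 circles × 40 years (3 chains, desk preset,
~5 minutes); the recovery study fits three replicate 50 × 30 panels with
2 chains each (the Gelman–Rubin diagnostic needs only ≥ 2; ~4 minutes per
fit); the sampler-vs-enumeration comparison uses a 2-site × 3-year
instance with counts ≤ 5 and 50,000 draws; clustering recovery uses
5,000 planted trends. The production preset (100k iterations) and the
1000×1000 CLARA configuration remain available for full-scale runs.

## Known limitations

* Credible-interval coverage at desk scale is good but not nominal
  (pooled ~85–95% across recovery replicates, with the initial-abundance
  intercept the most biased coefficient); coverage is characterized
  empirically by the tests rather than asserted to be exact.
* Detection is identified only through covariate variation (effort,
  temperature); panels with near-constant effort leave p and N weakly
  separated, and the posterior honestly widens.
* GAM penalty selection is per-series GCV; no uncertainty from the
  abundance posterior is propagated into the trend fits (point estimates
  are smoothed, as in the analysis the pipeline reproduces).
* The latent-effort measurement error is exercised where imputed effort
  coincides with recorded counts; under the generator's default
  missingness rule (counts missing wherever effort is missing) that
  situation must be constructed explicitly, as the unit tests do.
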