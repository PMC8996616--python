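# Methods

## The model

`memstep` fits a discrete-time, two-state hidden Markov movement model to
GPS relocation tracks on a regular fix interval (4 h by default).  The
*stationary* state represents resting: step lengths are half-normal with
the mean fixed at 0.03 km (one raster cell; scale 0.03·√(π/2)), headings
uniform.  The *non-stationary* state represents travel: its step density
is a step-selection function

    f_ns(x_t | x_{t-1}, φ_{t-1}, Z_{t-1}) = k(x_t) W(x_t) / ∫_Ω k W dx,

where the resource-independent kernel `k` is a correlated random walk —
exponential step lengths with mean ρ_ns·Δt and wrapped-Cauchy turning
angles with concentration κ ∈ [0,1) — expressed as a planar density (the
polar Jacobian 1/length is applied in `k` and in the stationary
emission, nowhere else).  State persistence is governed by λ = P(stay
stationary) and γ = P(stay non-stationary); the chain is initialized at
its stationary distribution and restarts there after each collar gap.
The occupancy summary reported by `stationary_fraction` is
λ/(λ+γ) — the conventional form — rather than the chain's stationary
distribution; both are available.

Four nested weighting functions encode the behavioural hypotheses:

- **null**: W ≡ 1, so f_ns = k;
- **resource-only**: W_R = exp(Σ_p β_p r_p(x)) over P = 6 covariates;
- **memory-only**: W_M = (1−β_d) + β_d·A(x), where the *attraction*
  A(x) ∈ [0,1] is a Gaussian-weighted average over time lags τ of
  exp(−‖x − z_{t−τ}‖ / 10^α); weights ∝ φ(τ | μ, σ) with μ, σ in days,
  truncated at |τ−μ| > 5σ and renormalized over the lags with a defined
  remembered location z_{t−τ};
- **resource-memory**: W_RM = W_R(x) · [(1−β_d) + β_d Σ_τ w_τ
  g(z_{t−τ}) exp(−‖x−z_{t−τ}‖/10^α)], where the logistic gate
  g(z) = expit(logit(β_0) + β·r(z)) downweights remembered locations
  with poor resources; g = β_0 exactly at zero covariates.

The memory-only model carries β_0 fixed at expit(1) ≈ 0.7311 as a
reported constant (it is not estimated and does not enter W_M).

The cognitive map Z_t records every fix (including training data) both
as per-cell visit-time lists and as a time-indexed path; the memory sum
needs z_{t−τ}, which exact lag indexing on the fix grid provides.  Lags
falling in collar gaps (denning) are undefined and the Gaussian lag
weights renormalize over the defined ones; a step with no defined lag in
the truncation window falls back to W = 1.

The normalizing integral is approximated by Monte Carlo: A "available"
endpoints per observed step (A = 50 when fitting) are drawn from `k`
itself, so the candidate mean of W estimates ∫ k W.  Candidates are
derived by inverse-CDF from a fixed array of uniform variates, which
makes the approximate likelihood a smooth function of (ρ_ns, κ) and lets
all four models share identical candidate randomness — BIC differences
are then never Monte-Carlo artifacts.  Candidate endpoints that fall off
the landscape take the nearest cell's covariates (synthetic landscapes
are built with generous margins).

Headings: displacements shorter than 0.09 km (3× the stationary mean)
are resting jitter whose direction is noise, so the inbound heading
φ_{t-1} carries the direction of the last longer step; gaps reset it,
and a step with no defined heading gets a uniform angular factor.  The
simulator applies the same rule, so simulated and fitted processes
match.

## Seasonal resource windows

Each resource layer may carry an inclusive day-of-year availability
window: berries Aug 1–Nov 30 (doy 213–334), riparian habitat May 10–
Oct 16 (130–289), ground squirrels Sep 11–Nov 30 (254–334), sweetvetch
Apr 1–Jun 15 (91–166); the anthropogenic distance layers are temporally
constant.  With `seasonal=True` the covariates are set to 0 outside
their window (never rescaled); leap days map to day 366 so the windows
are year-invariant.  The same mask applies to remembered-location
covariates inside the resource-memory gate, evaluated at the current
step's date.

## Parameters, units, transforms

| name | units | default / bounds | role |
|------|-------|------------------|------|
| ρ_ns | km/h | >0 (log scale) | mean travel speed |
| κ | – | [0,1) (logit) | directional persistence |
| β_1..β_6 | – or 1/km | free | resource selection |
| β_0 | – | (0,1) (logit) | revisitation probability gate |
| β_d | – | (0,1) (logit) | strength of memory-informed movement |
| μ | days | [3, 400] (scaled logit) | revisitation lag |
| σ | days | [3, 45] (shifted log) | lag spread |
| α | log10 km | identity, [−4, 3] | perceptual decay scale |
| λ, γ | – | (0,1) (logit) | state persistence |

μ's upper bound admits circannual (≈365 d) schedules; σ's lower bound of
3 days prevents degenerate single-lag spikes and its upper bound keeps
the truncation window (10σ wide) within the data span.  Free-parameter
counts per model: null 4, resource-only 10, memory-only 8,
resource-memory 15; BIC = k·ln(n) − 2·logL with n the number of
post-training emission steps.

## Training data

The first 365 days of each track are training: their fixes seed the
cognitive map but their steps contribute no likelihood terms.  Tracks
whose data do not extend past the training window are flagged excluded
(the operational form of the requirement of at least one post-training
year).  Fix timestamps are snapped to the nominal interval grid when
within ±10% of it; larger deviations split the track into bursts, with
no interpolation.

## Fitting

Likelihoods are maximized by L-BFGS-B on the transformed scale with
forward-difference gradients (step 1e-4).  Initialization is staged:

1. moment-based starts (speed from the mean of non-resting steps,
   κ from the mean resultant turning length, λ/γ from short-step run
   statistics), then a null-model fit of (ρ_ns, κ, λ, γ);
2. for memory-bearing models, candidate revisitation lags are ranked by
   actual likelihood over the prominent dips of the lag-distance scan
   plus a coarse geometric grid (and 365 d when the track spans it);
   the cognition block (β_0, β_d, μ, σ, α) is optimized from the best
   starts with movement parameters held at their null estimates;
3. a joint quasi-Newton polish of all active parameters.

During stage 2 the memory sum samples the lag grid daily and
renormalizes the Gaussian weights (σ ≥ 3 d makes this accurate to
≪0.1 nats); the polish and every reported likelihood use the exact
fix-interval lag grid.  The evaluator caches the candidate endpoints,
the lag bookkeeping and the (step × candidate × lag) decay tensor keyed
on the parameters that actually change them, which is what makes the
finite-difference loop affordable; the decay tensor is stored in float32
(its rounding is orders of magnitude below the finite-difference step,
and the schedule-parameter perturbations reuse the identical tensor, so
the error cancels where it matters).  A second, loop-based
implementation of the memory weighting exists both as the documented
reference (`movement_core`) and as the constant-memory fallback for very
wide lag windows; tests pin all implementations together.

Confidence intervals default to Wald (numeric Hessian on the transformed
scale, endpoints back-transformed); profile-likelihood intervals
(deviance threshold χ²₁(0.95)/2 = 1.9207 nats, bisection outward on the
transformed scale with nuisance re-optimization) are available through
`results.conf_int(method="profile")` and reduce to Wald exactly for
quadratic objectives.  An endpoint that never crosses the threshold
inside the bounds is reported at the bound (one-sided).  Significance
conventions: κ and each β_p against 0; β_d and β_0 against 0.5; λ, γ
against 0.5; α against log10(ρ̂_ns), the scale at which the decay over
one mean step equals e^{-1}.  No multiple-testing correction is applied;
intervals are per-parameter.

Model selection fits all four models on shared candidate sets, ranks by
BIC, flags runners within 2 of the best, and breaks exact ties toward
the model with fewer parameters.  Non-converged fits stay in the table,
flagged.

## Synthetic data

The landscape generator builds raster stacks with the statistical
structure the analysis assumes: spatially autocorrelated Gaussian fields
(white noise convolved with an isotropic kernel, standardized to mean 0
/ sd 1 so selection coefficients are comparable), Euclidean
distance-to-feature layers (riparian water, settlements, cabins), an
interaction field (product of two smooth fields, emulating a
slope × shrub covariate), and constants.  Coordinates are planar km,
row-major grids, origin at the lower-left corner, half-open cells.  The
default stack uses 0.5 km cells on a 60–120 km extent — coarser than a
30 m field raster, but the model's spatial scales (step ~1.6 km,
perception ~1–10 km) sit well above the cell size either way.

The simulator alternates HMM states, draws resting steps from the
half-normal, and selects travel steps by importance resampling:
n = 100 candidates from `k`, one chosen with probability ∝ W.  As the
candidate count grows this converges to exact sampling from f_ns (a test
tracks the total-variation distance).  Multi-year studies place 4-h
fixes in an Apr 1–Nov 30 active season with denning gaps between years,
re-drawing the behavioural state and resetting the heading each spring;
the first year is flagged training, and single-year animals are emitted
with the excluded flag.

Default generating parameters sit at the medians of the reported bear
fits (ρ_ns = 0.4 km/h, κ = 0.3, λ = 0.4, γ = 0.76) with a 10-km
perceptual scale (α = 1), β_d = 0.95 and a μ = 100 d, σ = 5 d schedule.
Desk-scale regime simulations (300–600 steps) run at one fix per time
unit with the unit set to a day, so the 100-unit revisitation cycle is
μ = 100 d and the sharpest schedule the fitted family admits (σ = 3 d,
the optimization floor) is exactly representable — at 4-h fixes a
100-fix cycle would force a generating σ below the floor, putting the
truth outside the estimable family.  The regimes use near-deterministic
memory (β_d = 0.999), a perceptual scale (~3 km) matching the daily step
scale (ρ_ns = 0.15 km/h), and rare resting (λ = 0.05, γ = 0.98):
continuous-movement tracks whose revisitation loops make the four
regimes separable on short tracks.  The separability is driven by
within-step weighting contrasts — the normalization of f_ns cancels
anything slower than the candidate spread — which is why the demo
regimes want a perceptual scale near the step length while the
multi-year default wants one near the range scale.

What the generator does *not* emulate: real topography and vegetation
classes, collar measurement error, irregular fix success, resource
depletion, conspecifics.  Passing recovery and identification tests
therefore demonstrate internal consistency of estimator and simulator
under the stated regimes, not field validity on real collars.

## Known limitations

- **Long-lag schedule identifiability.**  Under the convex-mixture
  memory weighting, the floor (1−β_d) makes the weighting flat once the
  animal is beyond a few perceptual scales from every remembered
  location, and the step-selection normalization only uses *within-step*
  contrasts between candidates ~1 step length apart.  With β_d = 0.95
  and a σ = 5 d schedule, simulated memory-only tracks hold a drifting
  home range rather than tight loops, the σ-smoothed lag target varies
  slowly with μ, and the likelihood surface over μ is shallow (a few
  nats across tens of days).  Recovery of a 100-day lag to ±10 days is
  then unreliable: competing modes (e.g., year-over-year range
  similarity near 200–400 d) can genuinely exceed the generating lag's
  likelihood.  Sharp schedules with β_d near 1 — the desk-scale regime —
  are identified easily.  This is a property of the model family at
  these parameters, not of the optimizer: refitting from the true values
  confirms the spurious modes score higher.
- The Monte-Carlo normalizer is shared across models but still a noisy
  estimate; with heavy-tailed W (strong coefficients on raw-km distance
  covariates) its error shrinks slowly in A.
- Viterbi ties break toward the stationary state (documented, arbitrary).
- No CRS handling: all coordinates must already be planar km.
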