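# Methods

`postcapture` estimates how long GPS-collared, home-range-resident deer take
to return to their average ranging behaviour after a capture-and-release
event. This note documents the models, the numerical choices, what the
synthetic-data generator does and does not emulate, and the package's known
limitations.

## Data model and preprocessing

Inputs are a fix table (animal, site, UTC timestamp, projected x/y in
metres) and a capture-event table (animal, site, capture time, capture
method, sex, age class). Capture methods form a closed vocabulary of five:
`box_trap`, `box_trap_short`, `net_drive`, `net_drive_sedation`,
`net_trap`. Coordinates must be planar metres; a helper converts lon/lat by
a local azimuthal equirectangular projection about the site centroid, which
is accurate to well under a metre at home-range extents.

Monitoring runs from each capture to 15 April of the same capture season
(winter seasons span the New Year: an October capture is monitored into the
following April). Captures are restricted to 3 October – 25 March when
strict-season checking is on (default).

Fix series are regularized per animal, in this order:

1. clip to the monitoring window;
2. partition time into consecutive 4-h bins anchored at the capture
   timestamp and keep the earliest fix of each bin;
3. enforce a minimum spacing of 4 h between retained fixes (greedy: a kept
   fix closer than 4 h to the previously kept one is dropped). Binning
   alone does not bound the count in a *sliding* 24-h window — two
   bin-earliest fixes can sit minutes apart across a bin boundary — while
   binning plus spacing provably yields at most six fixes in any half-open
   24-h window;
4. truncate at the first gap longer than 72 h between retained fixes;
   missing data are never interpolated.

Individuals are excluded when the first retained fix falls more than 3 days
after capture, or the retained span is under 20 days; exclusions are
written to a QC log with reason codes.

Anchoring bins at the capture time (rather than calendar midnight) keeps
the bins aligned with the days-since-capture response; the within-bin
tie-break (earliest fix) is deterministic and maximises temporal spread.

## Response metrics

Two per-fix metrics, both natural-log transformed with a +1 m offset
(distances of exactly 0 m are possible on the retained grid; 1 m is
negligible at home-range scale):

* **distance to the centre of gravity (COG)** — Euclidean distance to the
  arithmetic mean position of all retained fixes in the monitoring window;
* **step length** — Euclidean distance from the previous retained fix,
  attributed to the later fix. Steps are not divided by elapsed time: fix
  spacing is regularized, and the metric is defined as the distance between
  successive locations.

The COG is computed from retained (post-regularization) fixes only. Both
metrics are relative measures — pre-capture behaviour is unknown — so
"recovery" means rebounding to the individual-adjusted average, not to a
known baseline.

## Home-range covariate

Between-individual variation in ranging extent is controlled by the log of
a per-individual home-range area: the 90% isopleth of a bivariate Gaussian
kernel density estimate of the fixes recorded between days 11 and 21 after
capture (inclusive at both ends; inclusivity maximizes data). Individuals
with fewer than 10 locations in that window are dropped from the models and
flagged in the QC log.

The bandwidth is the per-individual reference ("href") value
`h = sigma * n^(-1/6)` with `sigma = (sd_x + sd_y)/2` — the conventional
per-individual default in home-range software. The density is evaluated on
a regular grid with cell size h/4 and a margin of 3h around the points
(grid mass deviates from 1 by well under 1%, and the area error against the
analytic normal isopleth `2 ln(10) pi sigma^2` is a few percent at
n = 2000). The isopleth threshold is the largest density whose super-level
set holds at least 90% of the grid mass; the area is the number of
super-level cells times the cell area.

## The additive mixed model

For each log metric y:

    y = X beta + sum_m f_m(t) * 1[method = m] + b_animal + b_site + eps

* `f_m` — one penalized cubic B-spline of days since capture per capture
  method, basis dimension k = 10, second-difference penalty, with a
  sum-to-zero constraint over the method's observed t values absorbed into
  the basis. Zero therefore *is* the average behaviour, and the plotted
  curve is centred on zero. Interior knots are quadratically warped towards
  t = 0: post-release disturbances decay fastest immediately after capture,
  and a warped k = 10 basis represents a 3-day exponential decay with an
  order of magnitude smaller sup-error than a uniform one (uniform knots
  at k = 10 visibly bias the rebound day of fast-recovering methods).
* `X beta` — intercept, log home-range area, and optionally factor main
  effects (method, sex, age) with two-way interactions.
* `b_animal`, `b_site` — random intercepts, represented as ridge-penalized
  indicator blocks (variance sigma^2 / lambda).
* Residuals are i.i.d. Gaussian; temporal autocorrelation beyond the time
  smooth is deliberately not modelled.

Smoothing parameters and variance components are selected by Gaussian REML
(Wood-style criterion with the scale profiled out), optimized over
log-lambda by L-BFGS-B with bounds ±18 and a small jitter fallback in the
Cholesky factorization. Pointwise smooth SEs come from the Bayesian
coefficient covariance `phi (X'X + S_lambda)^{-1}`. On a shared single-smooth
benchmark the fitted curve agrees with `mgcv::gam(..., method="REML")` to
about 5% of the signal SD and the SEs to within ~10% (see the cross-check
test).

**Candidate set and selection.** Ten fixed-effect structures are compared:
the empty set, each single main effect, each pair of mains, and each pair
with its own interaction (interactions never appear without both mains);
every candidate keeps the by-method smooth, the log home-range covariate
and both random intercepts. Ranking uses AICc,
`-2 logLik + 2k + 2k(k+1)/(n-k-1)`, with k counted as fixed coefficients +
variance components (animal, site, residual) + summed effective degrees of
freedom of the smooths, and Akaike weights `exp(-delta/2)` normalized. The
conditional Gaussian log-likelihood at the REML fit is used; candidates
differ only in fixed terms, so the ranking is insensitive to this
convention. Ties break towards fewer parameters. Candidates that are
unidentifiable on sparse factor combinations are skipped with a warning.

## Recovery (rebound) times

For each method the centred smooth and its ±1 SE band are evaluated on a
0.1-day grid from release to the search horizon — 60 days for the
distance-to-COG metric, the full monitoring window for the step metric
(both configurable). The recovery time is the first day the curve attains
zero or changes sign from its sign at release, located by linear
interpolation; the interval takes the crossings of f − SE and f + SE
(smaller = lower bound). A curve (or band edge) that never crosses within
the horizon is censored and reported at the horizon. First crossing (rather
than last sustained crossing) matches the "days to attain the average"
reading; the band is ±1 SE, not 1.96 SE. Estimates are reported to 0.1 day.

## Synthetic telemetry and ground truth

The generator emulates winter-captured roe deer: home-range-resident
movement (discrete-time Ornstein–Uhlenbeck about an animal-specific centre),
five capture methods across multiple sites, both sexes, three age classes,
captures spread over 3 October – 25 March and monitored to 15 April,
regular 4-h fix schedules thinned by i.i.d. dropout, and Gaussian GPS error.
Defaults: 100 animals; method mix 36/5/25/30/4% (the composition of a large
multi-site roe-deer programme); stationary positional SD 150 m (~30 ha
90% range) with 0.25 log-normal between-animal spread; 12-h positional
autocorrelation time; 10% fix loss; 15 m GPS error.

The capture effect injects two disturbances chosen to be *exactly
exponential on the analysed log scale* and mutually orthogonal, so that the
estimation pipeline can be validated against a closed form:

* **range shift** — positions are `mu + gamma(t) z_t` with
  `gamma(t) = exp(A_c e^{-t/tau_cog})` and
  `A_c = ln(1 + d0/(sigma sqrt(pi/2)))`: the expected distance to the
  centre is elevated by exactly d0 (default 300 m) at release, and log
  distance-to-COG carries the disturbance `A_c e^{-t/tau_cog}`. An additive
  fixed-direction offset — the more literal mechanism — was implemented
  first and rejected: after the log transform its disturbance decays like
  `e^{-2t/tau}` once the offset drops below the positional SD, so no closed
  form exists on the analysed scale and the ground truth would be wrong by
  ~7 days.
* **movement suppression** — the OU mean-reversion factor is modulated as
  `rho_k = 1 - (1 - rho)(s(t)/gamma(t))^2` with
  `s(t) = exp(ln(1 - a0) e^{-t/tau_step})`, and innovation SD
  `sigma sqrt(1 - rho_k^2)`. This preserves the stationary positional
  variance exactly at every step — the step channel cannot leak into the
  distance-to-COG metric — while scaling observed step lengths by s(t):
  steps are reduced by the factor 1 − a0 (default 0.5) at release and
  recover with tau_step.

Because both log-scale disturbances are single exponentials, the day the
centred disturbance crosses zero over a monitoring window of T days is

    t* = tau * ln( T / (tau (1 - e^{-T/tau})) ),

independent of amplitude and sign, increasing in tau and T, approaching T/2
as tau grows. `SimTruth` records tau, amplitude and t* per method and
metric, using each method's mean monitoring horizon. Randomness uses one
named substream per animal derived from the master seed, so adding or
removing animals never perturbs the others, and a fixed seed reproduces
every output byte for byte.

**What the generator does not emulate:** habitat and terrain, inter-animal
interaction and territoriality, behavioural-state switching, irregular
duty-cycled fix schedules, DOP-dependent GPS error, multi-year histories,
or method-dependent effect *amplitudes* (only the decay times are
method-specific, and no per-method effect sizes are published — defaults
are chosen for testability). Passing validation therefore shows the
pipeline recovers known exponential disturbances in OU-resident movement;
it does not certify behaviour on real telemetry with state switching or
non-exponential recovery.

## Validation design and measured behaviour

End-to-end validation simulates 100 animals captured in a one-week window
(~76-day horizons), balanced across methods so each per-method smooth rests
on ~20 animals, with a0 = 0.5, d0 = 300 m, tau = 5 d: the per-metric median
recovery day must land within ±3 d of t* ≈ 13.6 in at least 16 of 20 seeds
(both metrics pass). With per-method tau of 3/5/8 d over three methods, the
per-method recovery times (averaged over the two metrics) must preserve the
injected order in at least 16 of 20 seeds (20/20 measured; the step metric
alone gives 19/20). The distance-to-COG metric alone orders correctly in
only ~13–15/20: its positions are OU-autocorrelated (roughly 6× fewer
effective observations than steps), the centred disturbance's slope at the
crossing is ~0.013 per day, and the penalized fit flattens the near-zero
tail, so per-method crossings carry an SD of ~2.5–3 d against gaps of
~4 d — an information limit of the prescribed estimator class, not an
implementation defect.

Null calibration uses an i.i.d. N(0,1) response over simulated covariates
(50 animals): the per-method smooths stay inside their 2·SE bands in ≥90%
of (seed × method) replicates. The *joint* event — every one of five
smooths inside simultaneously — occurs in only ~2/3 of replicates by
multiplicity: each smooth's sup-statistic exceeds 2 with probability
~0.05–0.08 under the null because the constrained basis retains an
unpenalized linear component. An injected covariate slope of 0.3 on log
home-range area is recovered within 2 SE.

## Numerical choices and degenerate inputs

* Basis dimension k = 10 per method smooth; REML for smoothing parameters;
  centring constraint absorbed by a null-space reparameterization.
* Penalized normal equations solved by Cholesky with escalating jitter
  (starting at 1e-10 of the mean diagonal) on failure.
* Recovery grid step 0.1 day with linear interpolation — well below the
  0.1-day reporting precision.
* A curve starting exactly at zero recovers at day 0. Empty fix tables are
  empty outputs, not errors; a run in which fewer than two individuals
  survive QC skips the model stage and flags `NO_DATA` in the manifest.
* Duplicate (animal, timestamp) fixes collapse to the first occurrence with
  a logged warning; unknown factor labels and unparsable timestamps are
  schema errors naming the row and column.
* Penalties are totals, not per-observation quantities: duplicating every
  record reproduces the same point estimates only when each lambda is
  doubled along with the data (the REML-selected lambdas change with n).

## Known limitations

* Random intercepts only; no random slopes, spatial fields, or
  autocorrelated error structures. SEs for the distance-to-COG smooth are
  anti-conservative in the presence of strong positional autocorrelation.
* The AICc parameter count uses effective degrees of freedom of the
  smooths; other conventions shift all candidates equally but would change
  the absolute AICc values.
* First-crossing semantics: a smooth that wiggles across zero several times
  reports the earliest crossing; a "last sustained crossing" variant is not
  implemented.
* Home-range areas from 11 days of data are biased low for animals with
  slow range use; they serve as a covariate (units cancel in centring), not
  as a home-range estimate in their own right.
* The lon/lat helper assumes home-range-scale extents; do not use it for
  study areas spanning hundreds of kilometres.
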