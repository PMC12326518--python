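# Methods

`aasarray` analyzes how detections of fish aggregation-associated
sounds (AAS) vary across a linear hydrophone array at a spawning
site. This note documents the model, the synthetic-data generator
that stands in for raw acoustic data, the numerical choices, and what
the package's tests do and do not establish.

## The call-rate model

The analysis unit is the hour cell: station *j* in study hour *i*,
with detection count V, effort τ ∈ (0, 1] (the fraction of the
hour's minutes retained after interference exclusion) and three
categorical covariates. The model is a hierarchical Poisson
regression with an exposure offset:

```
V[j,i] ~ Poisson(mu[j,i])
log mu[j,i] = log tau[j,i] + T[t(i)] + D[d(i)] + FP[j,i] + h[j,i]

(h[1,i], ..., h[J,i]) ~ MVNormal(0, diag(sigma_h) R diag(sigma_h))

T_k, D_k, FP_k ~ Normal(0, 1)
sigma_h[j]     ~ Exponential(1)
R              ~ LKJ(1)
```

* **T** — 24 hour-of-day effects capturing the diel (crepuscular)
  calling cycle.
* **D** — 7 day effects indexed by days after first spawn (DAFS),
  spanning −4..+2.
* **FP** — 3 fish-proximity effects: the aggregation's bulk not
  observed within 100 m (0), within 100 m (1), within 20 m (2).
* **h** — an hour-level station random effect whose cross-station
  correlation matrix **R** is the quantity of spatial interest:
  after the covariates are accounted for, R[j,k] measures whether
  stations j and k rise and fall together.

Index coding is deliberate: every category keeps its own effect with
a standard-normal prior and no reference level or sum-to-zero
constraint. The absolute levels of T, D and FP are therefore only
weakly identified (an additive constant can shift between factors,
restrained only by the priors), which is why recovery tests and
reported summaries work with within-factor contrasts (e.g.
T[19] − T[7], FP[2] − FP[0]) and full linear predictors. The
covariance is the quadratic form diag(σ)·R·diag(σ); each station SD
gets its own Exponential(1) prior.

Hours in which a station recorded no observable minutes are simply
absent cells; that hour's h-vector stays J-dimensional and the
missing station's Poisson term is omitted (the multivariate normal
marginalizes cleanly). By default the design is restricted to hours
observed by every station, matching a complete-case analysis window.

## Fitting

The sampler is an in-package Hamiltonian Monte Carlo implementation
with analytic gradients:

* **Non-centered random effects.** h = diag(σ) L z with z standard
  normal and L the Cholesky factor of R. This leaves the posterior
  unchanged and removes the funnel between σ and h.
* **Correlation transform.** R is parameterized by canonical partial
  correlations w = tanh(y) mapped row-wise to L; the LKJ(1) prior
  plus tanh Jacobian collapse to Σ b·log(1−w²) with known Beta
  shapes b — the standard construction in gradient-based PPLs.
  Gradients flow through the row-wise Cholesky construction by a
  hand-written reverse pass, verified against finite differences.
* **Adaptation.** Dual averaging targets acceptance 0.8; a diagonal
  inverse mass matrix is re-estimated in doubling windows over the
  middle of warmup. Defaults: 3 chains, 1000 iterations per chain,
  half discarded as warmup.
* **Trajectories.** Leapfrog length ≈ `traj_length / step_size`
  (default 14 units, capped at 512 steps), jittered uniformly over
  the upper half of the range. The long default is needed because
  the factor-level trade-off directions are wide (prior-scale) and
  highly correlated; shorter trajectories leave split R-hat for some
  hour effects above 1.05 at the default problem size. The
  Metropolis correction always uses the exact joint density, so
  sampler tuning affects efficiency only, never the target.
* **Diagnostics.** Split R-hat and bulk ESS via ArviZ; the
  convergence table flags a fit when any R-hat ≥ 1.05. Divergent
  transitions after warmup are surfaced with a warning.

Sampler correctness is tested three ways: the vectorized joint
density equals a naive term-by-term oracle to 1e−8 relative; the
potential's gradient matches finite differences; and with an empty
design the sampler reproduces the exact priors (standard-normal
effects, Exponential(1) SDs, uniform correlation for J = 2).

## The synthetic-data generator

The generator defines the study conditions and every pipeline input:

* **Geometry.** Six stations 150 m apart along a fixed bearing from
  an origin on a shelf edge; great-circle placement and distances on
  a sphere of radius 6,378,137 m.
* **Window.** 158 continuous hours starting at 10:00 local time;
  DAFS 0 begins at study hour 86 (midnight of the first spawning
  night), so the window spans DAFS −4..+2 exactly.
* **Effect templates.** T has crepuscular peaks at 06:00–08:00 and
  18:00–20:00 with the evening peak (4.3 at 19:00, log scale) above
  the morning one (3.6 at 07:00) and minima at 02:00 and 13:00; D
  rises from −1.0 on the first day to a peak 0.8 at DAFS 0, staying
  high on spawning days; FP is (0, 0.55, 1.1), i.e. fish within
  20 m roughly triple the detection rate — magnitudes chosen to
  match the qualitative patterns the monitored system shows.
* **Station correlation.** R[j,k] = exp(−d[j,k]/decay) with decay
  350 m by default (positive correlations decaying over a few
  hundred meters); any user matrix can be substituted and is
  projected to the nearest valid correlation matrix. The
  exponential kernel is always positive — the generator does not
  produce the negative long-range correlations a real site can show.
* **Fish-mass trajectory.** A 1-D along-array reflected Gaussian
  random walk (step SD 40 m/h) with an optional persistent shift
  episode (default +400 m at the first spawning hour, emulating an
  aggregation forming away from its traditional location). Proximity
  categories are pure distance thresholds at 20 m and 100 m.
* **Interference.** Every 5th minute is in the inspection subsample;
  each sampled minute is flagged independently with probability
  0.044, and flags exclude the ±2 min window around them — so the
  expected excluded share equals the configured fraction (edge
  clipping makes it very slightly lower).
* **Detection streams.** Each hour's V events are scattered
  uniformly over the 2-s bins of the hour's observed minutes, at
  most one per bin. The synthetic classifier detects each true event
  with probability 0.735 and adds false alarms in empty bins at an
  expected 0.03 per observed minute.
* **Randomness.** One root seed; every stage draws from an
  independently keyed substream, so adding a stage never perturbs
  the others, and all outputs are bit-reproducible.

What the generator does **not** emulate: acoustic propagation,
per-fish agents, call-type structure, diel structure in interference
(real vessel noise clusters around dive operations), hardware
failures mid-study, and classifier error that depends on
signal-to-noise. Passing recovery tests therefore show that the
estimator is correct when the model is true and well-specified; they
do not validate the model against real acoustic data.

## Preprocessing conventions

* 2-s bins are anchored at even seconds within each minute; several
  calls in one bin collapse to the earliest.
* Exclusion windows are closed intervals [m−2, m+2] minutes, clipped
  to each station's record; two flags five minutes apart produce one
  contiguous 10-minute exclusion.
* Effort uses a fixed 60-minute denominator; hours with zero
  observed minutes are dropped, never emitted with τ = 0.
* MaxN video counts map to abundance categories 0/1/2–10/11–100/>100;
  composite proximity takes the most informative source (within 20 m
  dominates within 100 m dominates not observed).

## Classifier evaluation conventions

Agreement between a "true" and a "predicted" detection stream is
scored per 2-s bin for presences, while a true negative is a whole
evaluation minute empty in both streams (scoring empty bins would
inflate accuracy, because calls are rare). Evaluation minutes are
200 uniform draws per station, extended until the sample holds at
least 100 true detections. Kappa is Cohen's chance-corrected
agreement with marginal-product expected agreement. The bundled
published evaluation table has one station whose printed total n
disagrees with its four cells by 5; the module carries the printed n
(which the published accuracy and kappa values use as denominator)
and flags the inconsistency rather than silently recomputing.
Published kappas for three rows differ from the standard formula by
up to 0.013; the package does not guess the original computation and
matches kappa exactly only where the standard formula reproduces it.

## Spatial analysis

Pairwise great-circle distances use the haversine formula with the
6,378,137 m radius (configurable). Each pair's posterior correlation
is summarized by the median and quartiles of the R[j,k] draws; the
decay fit is ordinary least squares of the pair medians on distance,
with the zero crossing −intercept/slope and a standard 95%
confidence band. A draw-wise variant refits the line to every
posterior draw of R for uncertainty propagation. With J = 5
stations there are exactly 10 pairs — few points, so the regression
is descriptive, not inferential.

## Problem sizes and defaults

The default test and example runs use reduced problems (e.g. 5
stations × 72 h, or 3-station 30-h pipeline smoke runs) chosen so
that the whole suite completes in minutes on one core while leaving
every estimator in its asymptotically informative regime; the
flagship recovery experiment runs the full 5 × 158 configuration
with 3 chains × 1000 iterations. The acceptance script
(`scripts/acceptance.py`) re-runs that full-scale experiment from
scratch.

## Known limitations

* Absolute factor levels are weakly identified by construction;
  only contrasts should be interpreted.
* The HMC implementation uses a diagonal metric; strongly correlated
  posteriors are handled by long trajectories rather than a dense
  metric, which costs gradient evaluations.
* The exponential correlation kernel cannot represent negative
  correlations, so the generator cannot reproduce an inverted
  far-station pattern; fits to real data are not so constrained.
* The minute/event tables live in memory as pandas frames; the
  design comfortably covers a single-site deployment (~10⁵ minutes),
  not archives of many sites.
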