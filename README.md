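# aasarray

Spatiotemporal analysis of fish **aggregation-associated sound (AAS)
detections** across a hydrophone array at a spawning site.

Passive acoustic monitoring of fish spawning aggregations (FSAs)
usually relies on one hydrophone — but call detection ranges are
short (a few hundred meters) and the aggregation moves, so where a
hydrophone sits can change not only how many calls it logs but even
the apparent temporal pattern of the season. `aasarray` is a tested,
reusable pipeline for quantifying that variability with a linear
array of hydrophones: it preprocesses classifier detections into
effort-normalized hourly counts, evaluates the call classifier with
confusion matrices, fits a hierarchical Bayesian model of call
rates, and measures how inter-station agreement decays with
distance. A first-class synthetic-data generator reproduces the
whole study design with a known truth, so every estimator ships with
parameter-recovery evidence.

## The model

For station *j* in study hour *i*, with detection count V and effort
τ (the fraction of the hour's minutes kept after vessel-noise
exclusion):

```
V[j,i] ~ Poisson(mu[j,i])
log mu[j,i] = log tau[j,i] + T[t(i)] + D[d(i)] + FP[j,i] + h[j,i]
h[.,i]  ~ MVNormal(0, diag(sigma_h) R diag(sigma_h))

T_k, D_k, FP_k ~ Normal(0,1);  sigma_h[j] ~ Exponential(1);  R ~ LKJ(1)
```

with 24 hour-of-day effects **T**, 7 days-after-first-spawn effects
**D**, 3 fish-proximity effects **FP** (bulk of fish within 20 m /
100 m / farther), and an hour-level station random effect **h**
whose correlation matrix **R** carries the spatial signal. The
model is fit by an in-package Hamiltonian Monte Carlo sampler
(analytic gradients, non-centered random effects, tanh/Cholesky
LKJ transform), 3 chains × 1000 iterations by default, with ArviZ
R-hat/ESS diagnostics. Pairwise posterior correlations are then
regressed on great-circle distance; the line's zero crossing is the
separation at which two hydrophones stop agreeing.

## Worked example

```python
import numpy as np
from aasarray import (SimulationConfig, simulate_all, encode_design,
                      fit, convergence, correlation_pairs,
                      corr_distance_regression, haversine_matrix,
                      make_geometry)

cfg = SimulationConfig(n_stations=5, n_hours=72, first_spawn_hour=38, seed=1)
sim = simulate_all(cfg)                     # geometry, minutes, events, hour cells
post = fit(encode_design(sim["hourcells"]), chains=3, iterations=1000, seed=1)
print(convergence(post).attrs["max_rhat"])

fp = post.stacked("FP"); c = fp[:, 2] - fp[:, 0]
print(np.median(c), np.percentile(c, [5, 95]))
```

prints (seed 1):

```
1.008218788319606
1.0533807726705917 [0.90392718 1.19523877]
```

— the chains mix (max split R-hat 1.008), and the proximity
contrast "fish within 20 m vs not observed" has posterior median
1.05 on the log scale with 90% interval (0.90, 1.20), covering
the generating truth 1.1: fish sitting on top of a hydrophone
roughly triple its detection rate. Running
`python examples/spatial_decay.py` continues to the spatial step and
prints each station pair's posterior correlation with distance and
the fitted decay line.

More narrative scripts live in `examples/`: one per capability
(generator, preprocessing conventions, classifier evaluation, model
fit, spatial decay). A thin CLI drives the same pipeline from a
shell:

```bash
aasarray all --seed 1 --out run/      # simulate -> preprocess -> evaluate
                                      # -> fit -> spatial -> report
```

writing headered CSVs plus a `manifest.json` with a checksum of
every artifact; identical config and seed reproduce byte-identical
tables.

## Classifier evaluation

`aasarray.confusion` scores paired true/predicted 2-s-bin detection
streams (a true negative is a whole empty minute, since calls are
rare) and pools stations. The published per-station evaluation
counts of the FADAR grouper-call classifier ship with the package;
`examples/evaluate_classifier.py` recomputes the full metric table —
pooled accuracy 76.0% and true-positive rate 53.2% across all five
stations, improving to 85.6% and 73.5% after dropping the two
stations with hardware floor noise.

## Layout

```
src/aasarray/
  config.py      simulation configuration, seeded substreams
  geometry.py    array placement, haversine distances
  simulate.py    synthetic-data generator (the study conditions)
  preprocess.py  2-s binning, interference exclusion, effort, hour cells
  confusion.py   confusion matrices, Cohen's kappa, pooling
  lkj.py         correlation-matrix transform and LKJ prior
  hmc.py         Hamiltonian Monte Carlo with warmup adaptation
  model.py       the call-rate model: design, joint density, fit,
                 diagnostics, effect summaries
  spatial.py     pair correlations, correlation-distance regression
  reporting.py   heat-map matrices, box-plot summary tables
  pipeline.py    stage orchestration and run manifests
  cli.py         command-line interface
docs/methods.md  model, generator and numerical documentation
```
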