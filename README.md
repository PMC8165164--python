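# aviforage

Pose-trajectory analysis of arena foraging under mirror and stranger
exposure.

Birds that fail the classic mark test of mirror self-recognition may
still treat their mirror image differently from a real conspecific. One
way to measure this is a foraging assay: a pigeon walks from the
entrance of a small compartment (50 × 60 cm) to a feeder placed against
a separation panel that is either an opaque wall, a mirror, or a
transparent barrier with an unfamiliar pigeon behind it. How quickly the
bird approaches, how much it moves, how strongly it orients toward the
feeder (and hence the partner/reflection), and how often it shows
displacement behaviors such as preening all differ between conditions.

`aviforage` turns keypoint-tracker output (the common three-header-row
CSV dialect with `x, y, likelihood` triplets per bodypart) into those
statistics:

* **kinematics** — per-session preprocessing (2-s trim, likelihood
  filtering with gap interpolation, LOESS smoothing) and the derived
  statistics: latency to the first feeding episode, log activity rate
  outside feeding, and the body-orientation index
  cos θ between the body→head and body→feeder vectors
  (1 = facing the feeder, 0 = perpendicular, −1 = facing away);
* **condition model** — a Bayesian state-space comparison of the binned
  orientation time courses of two conditions,

  ```
  y_ref[t] = μ[t]        + ε[t]          μ[t] ~ N(μ[t−1], σ_μ²)
  y_alt[t] = μ[t] + δ[t] + ε'[t]         δ[t] ~ N(δ[t−1], σ_δ²)
  ```

  with half-normal priors on all scales, fitted by a blocked Gibbs
  sampler (banded-precision joint state draws, slice-sampled scales,
  ancillarity–sufficiency interweaving). It reports the posterior of the
  time-averaged difference Δ̄ with a 95% credible interval, and the
  *difference periods*: bins whose pointwise 95% CI for δ excludes 0;
* **behavior stats** — ethogram summaries, Cohen's κ for inter-rater
  reliability, two-way repeated-measures ANOVA with partial η² and Tukey
  post-hocs, and mixed-model likelihood-ratio tests for latency and
  activity;
* **simulate** — a synthetic arena-foraging generator with known ground
  truth (true latency, clean paths, feeding mask), so the entire chain
  is testable without any video data.

## Worked example

Compare orientation dynamics between a reference and an alternative
condition with a known injected difference of 0.32:

```python
import numpy as np
from aviforage import ConditionDifferenceModel

rng = np.random.default_rng(0)
t = np.arange(600) + 0.5                       # 1-s bins over a 10-min session
shared = 0.30 + 0.15 * np.sin(t / 60.0)        # slowly drifting shared trend
wall = shared + rng.normal(0, 0.08, 600)
stranger = shared + 0.32 + rng.normal(0, 0.08, 600)

model = ConditionDifferenceModel(wall, stranger, bin_time=t,
                                 reference="Wall", alternative="Stranger")
result = model.fit(draws=1000, warmup=1000, chains=4, seed=1)
print(result.summary())
```

prints

```
Condition-difference state-space model
  comparison : Stranger - Wall
  bins       : 600 (width 1 s)
  chains x draws : 4 x 1000
  Delta-bar  : 0.318 (18.57 deg)
  95% CI     : (0.310, 0.327)  [excludes 0]
  difference periods : 600 bins
  R-hat      : sigma_mu=1.013, sigma_delta=1.003, sigma_obs=1.000, delta_bar=0.999
  converged  : True
```

Δ̄ is the posterior mean of the time-averaged orientation difference
(the Stranger condition is 0.318 more feeder-directed on the cosine
scale, ≈ 18.6° via the arcsine conversion); the CI excludes 0, all 600
bins are flagged as difference periods because the injected difference
is constant, and split-R̂ ≤ 1.05 on all monitored scalars indicates the
chains mixed.

The full pipeline runs from a session manifest (or a simulated fixture
set) via the CLI:

```sh
avi-forage all --config config.yml --out out/ --seed 1
```

which writes `session_stats.csv` (latency, log activity, mean
orientation per bird × condition × session), `posterior_summary.csv`
(one row per condition comparison: Δ̄, CI, degrees, number of difference
bins), per-bin difference CSVs, ethogram summaries and test tables, plus
ribbon and activity plots. A typical simulated `posterior_summary.csv`
looks like:

```
     comparison  delta_mean   ci_low  ci_high  degrees  n_difference_bins
    Wall-Mirror    0.158596 0.123860 0.193867  9.12542                 91
  Wall-Stranger    0.307575 0.276785 0.339067 17.91320                104
Mirror-Stranger    0.147745 0.124994 0.171083  8.49628                 98
```

matching the generator's configured orientation biases
(Wall 0.30 < Mirror 0.46 < Stranger 0.62).

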