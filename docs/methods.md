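# Methods

This note documents the models, the synthetic-data generator, the
numerical choices, and the limitations of `aviforage`.

## The measurement chain

A session is a keypoint trajectory (head and body-center, with per-frame
tracker likelihoods) of one bird in a 50 × 60 cm compartment with a
feeder in the corner opposite the entrance, recorded for 10 minutes
under one of three separation-panel conditions (Wall, Mirror, Stranger).

Preprocessing, in order:

1. **Trim** — the first 2 s of every session are discarded (the
   companion bird enters slightly before the focal bird; trimming
   equalizes the conditions). Frame numbers are preserved so all times
   stay absolute.
2. **Likelihood filter** — frames whose tracker confidence for a
   required bodypart falls below 0.6 are set to missing; missing runs up
   to 0.5 s are linearly interpolated, longer runs stay missing and
   propagate as missing through every downstream statistic. The
   threshold and gap are conventional for this tracker dialect and are
   exercised directly by the simulated dropouts (clean frames carry
   likelihood 0.99, dropouts uniform(0, 0.5)).
3. **LOESS smoothing** — locally weighted linear regression with
   tricube weights per coordinate (`statsmodels` lowess, no robustness
   iterations). The window is specified in *seconds* (default 0.3 s) and
   converted to a span per session. A span expressed as a fixed fraction
   of the session would mean a 30-s window on a 10-min recording, which
   averages the 5-cm head–body geometry away entirely and inflates the
   orientation index; a fixed-duration window keeps the smoothing
   strength independent of session length and frame rate. The lowess
   `delta` shortcut is capped at one fifth of the window so the linear
   interpolation between anchors never smooths beyond the window itself.
   Degree-1 local fits reproduce constants and straight lines exactly.

Derived statistics:

* **Body-orientation index** — cos θ between (head − body) and
  (feeder − body), computed per frame in arena coordinates. It is
  invariant under translation, rotation and uniform scaling, and lies in
  [−1, 1] by construction; degenerate frames (zero-length vectors,
  missing coordinates) yield missing values rather than errors. The
  feeder center is the target point in all conditions: feeder and
  barrier are adjacent, so one convention serves all three.
* **Angle conversion** — reported index differences are also expressed
  in degrees as arcsin(x)·180/π. The arcsine (not arccosine) form is
  used because it is sign-preserving and maps 0 → 0°, 1 → 90°, which is
  the natural reading of a *difference* of orientation indices
  (0.32 → 18.66°).
* **Feeding episodes** — head within the feeder-zone radius (default
  8 cm, a head-proximity criterion scaled to the 10.8-cm feed bowl),
  debounced by removing episodes shorter than 0.3 s so single-frame zone
  crossings do not count.
* **Latency to feed** — time from session start to the first frame of
  the first debounced feeding episode. The original assay scored the
  first *peck*, which cannot be derived from two-point tracking; the
  first feeder-zone entry of the head is the proxy, and its fidelity is
  validated against simulator ground truth (recovered within one frame
  plus the debounce window on clean data). Sessions with no feeding
  episode are right-censored at the session length and flagged; censored
  sessions are excluded from the latency mixed model with their count
  reported.
* **Activity rate** — mean body-center speed (|Δposition| · fps, cm/s)
  over frame pairs in which neither frame is feeding, then
  log-transformed. The mean speed is floored at 10⁻³ cm/s before the
  log; the floor is far below tracker noise and only prevents −∞ for a
  perfectly stationary bird.

## The condition-comparison model

Orientation series are averaged within 1-s bins per session, then across
sessions and birds per condition, giving two series on a shared grid.
The comparison model is a Gaussian state-space model with two coupled
first-order random walks:

    y_ref[t] = μ[t]        + ε[t]       ε  ~ N(0, σ_obs²)
    y_alt[t] = μ[t] + δ[t] + ε'[t]      ε' ~ N(0, σ_obs²)
    μ[t] ~ N(μ[t−1], σ_μ²)              δ[t] ~ N(δ[t−1], σ_δ²)

μ carries the dynamics the conditions share (approach, settling at the
feeder); δ is the time-varying condition difference. Half-normal(0.5)
priors sit on the three scales — weakly informative on the cosine scale,
where every observable lies in [−1, 1]. The initial states carry flat
priors: the observations anchor both chains, and a flat start makes the
δ posterior exactly invariant to adding a constant to both series.

This form is a reconstruction: it is the minimal model that yields the
three quantities of interest — a shared trend, a scalar condition
difference, and the periods during which the difference occurred — not a
replication of any particular published implementation.

**Inference.** Blocked Gibbs sampling. Given the scales, the joint state
(μ₁, δ₁, …, μ_T, δ_T) is Gaussian with a banded precision matrix
(bandwidth 2 after interleaving); one draw costs a single banded
Cholesky factorization (O(T)). Given the states, each log-scale is
updated by stepping-out slice sampling, followed by an
ancillarity–sufficiency interweaving step that re-draws σ_μ and σ_δ in
the non-centered parameterization (state = start + σ · cumulated
standardized increments), where the conditional for σ is Gaussian. The
interweaving is essential: when the true walk variance is near zero the
centered sampler alone gets trapped in the funnel (observed split-R̂ ≈ 2
on σ_δ without it, ≤ 1.02 with it). Missing bins contribute no
observation term and are bridged by the state equations.

Defaults: 1-s bins, 4 chains × 1,000 draws after 1,000 warmup,
over-dispersed chain initialization, seeds derived from one user seed
via `SeedSequence`. Convergence is monitored with split-R̂ on σ_μ, σ_δ,
σ_obs and Δ̄ (threshold 1.05); a non-converged fit is returned flagged
and warned about, never silently. A full 600-bin fit takes a few seconds
on one CPU.

**Summaries.** Δ̄ is the posterior of the time-average of δ (one scalar
per draw), reported as mean and central 95% interval; difference periods
are bins whose pointwise 95% interval for δ[t] excludes zero. The three
condition contrasts are fitted pairwise (Wall–Mirror, Wall–Stranger,
Mirror–Stranger) rather than in one three-condition model, matching the
three reported comparisons. Swapping reference and alternative negates
the δ posterior distributionally; because a generic sampler consumes its
random stream in non-negated coordinates, the negation is exact only in
distribution, and the test suite checks it within Monte-Carlo tolerance.

**Calibration.** Under a null difference the 95% interval for Δ̄ covers
zero in ≥ 44/50 simulated replicates (checked at 120 bins with reduced
draws); with a constant injected δ = 0.32 the full-scale fit recovers it
within the CI half-width.

## Ethogram and repeated-measures statistics

* **Summaries** — per behavior × condition: total, mean (= total / 48
  bird × session observations in the full design), SEM across those
  observations.
* **Cohen's κ** — (p_o − p_e)/(1 − p_e) via scikit-learn; undefined
  (NaN, warned) when both raters are constant on the same label.
* **Two-way RM-ANOVA** — condition × day, both within-subject, via
  pingouin; partial η² = SS_effect/(SS_effect + SS_error) is recovered
  from each term's F ratio. The condition post-hoc is a Tukey test on
  subject × condition means with the condition × subject interaction as
  error term (df = (k−1)(n−1) = 14 in the full design). The expected df
  structure — condition (2, 14), day (5, 35), interaction (10, 70) — is
  asserted in the tests.
* **Mixed-model LRTs** — latency and log activity are modelled with a
  bird random intercept, fitted by maximum likelihood (not REML, which
  would invalidate fixed-effect LRTs). Condition and session are tested
  against the additive model, the interaction against the full model,
  each by a χ² likelihood-ratio test. A likelihood-based pseudo effect
  size, 1 − exp(−χ²/n), is reported alongside; it lies in [0, 1] and is
  invariant to outcome rescaling. Pairwise condition contrasts use the
  fixed-effect covariance with studentized-range (Tukey) adjustment over
  the three pairs. Singular random-effect fits fall back to OLS for all
  nested fits, flagged in the result. Type-I error of the condition LRT
  is calibrated to [0.01, 0.10] at nominal 0.05 over 200 null
  replicates.
* **Behavior groups** — "body-oriented" (displacement behaviors):
  shaking, preening, head scratching, wing flapping/opening;
  "surrounding-oriented": barrier pecking, attack.

## The synthetic generator

The generator emulates the study design — 8 birds × 3 conditions × 6
sessions of 600 s — with two deliberately decoupled processes per
session:

* **Locomotion** (body-center): entrance dwell whose duration is set so
  that total latency matches a Gamma draw (shape 9) around the
  configured per-condition × session mean; a curved approach at the
  session's walking speed (Gamma around the per-condition mean, OU
  heading noise); then feeding bouts (exponential durations, mean 12 s)
  at a fixed spot just off the feeder center, alternating with
  reflecting-random-walk excursions and straight returns.
* **Body axis** (heading that places the head 5 cm from the
  body-center): during the post-approach segment it is the bearing to
  the feeder plus a stationary OU offset (relaxation 0.5 s⁻¹) whose
  standard deviation s satisfies E[cos offset] = exp(−s²/2) = the
  configured orientation bias. The time-mean orientation index of the
  clean path is therefore known analytically, which is what makes exact
  recovery tests possible. Real birds do not decouple gaze from gait
  like this; the decoupling exists to make the target statistics
  controllable, not to be ethologically faithful.

Ground truth recorded per session: clean body/head paths, heading, the
feeding mask (head-in-zone of the clean path, by construction), the true
latency (first frame of that mask), and the index of the first
post-approach frame. Tracker degradation is applied last: iid Gaussian
jitter (default 0.3 cm) on every coordinate and per-frame dropouts
(default 2%) whose coordinates are replaced by uniform arena positions
and whose likelihood falls below 0.5. Files are written in pixels
(10 px/cm) in the three-header-row pose CSV dialect, so the reader's
calibration path is exercised.

Default study conditions, chosen once as field-realistic where the
design itself does not fix them: frame rate 30 fps; walking speeds
Wall 9, Mirror 8, Stranger 11 cm/s (a visible conspecific evokes
competitive foraging; the mirror dampens it); orientation biases
Wall 0.30 < Mirror 0.46 < Stranger 0.62 (separations of 0.16 and 0.32
on the cosine scale); latency means declining over the six sessions with
a marked Mirror elevation in session 1; behavior count means set to the
published per-session means with negative-binomial overdispersion 2
(variance/mean). Ethogram counts come with a second rater whose 5-s
interval judgments are flipped with probability 0.05, making the
expected inter-rater κ controllable (0 disagreement ⇒ κ = 1).

What the generator does **not** emulate — and hence what passing tests
do not show about real data: pecking and head-bobbing kinematics,
interaction between the focal bird and the companion's actual movements,
non-Gaussian tracker error (identity swaps, systematic occlusion near
the feeder wall), within-session fatigue, and any coupling between
orientation and locomotion. Recovery results on synthetic data bound the
pipeline's correctness, not the assay's biological validity.

## Problem sizes and runtime

All simulations are sized for a single CPU: the default test suite runs
in about two minutes, with the statistical calibration tests using
reduced designs (2 chains × 300–500 draws at 120–240 bins for the
replicate studies; the single full-scale recovery fit uses 600 bins and
4 × 1,000 draws). The full default fixture set (144 sessions × 18,000
frames) generates and writes in ~15 s.

## Known limitations

* The latency proxy (zone entry) systematically precedes the first peck
  by a fraction of a second; comparisons between conditions are
  unaffected, absolute latencies are slightly low.
* The dual-random-walk model assumes a common observation variance for
  both conditions and Gaussian bin noise; heavy-tailed bin means (few
  contributing sessions) are not specially handled.
* κ is computed on whatever label vectors are supplied; the package does
  not prescribe the unit of analysis (per video, per interval, per
  event), which materially affects the value.
* Wing flapping/opening published means are inconsistent with the
  published totals divided by 48; the generator uses totals/48 and the
  summary tables report what the data contain, without reconciling the
  discrepancy.
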