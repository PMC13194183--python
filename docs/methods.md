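# Methods

## Task geometry and conventions

Workspace coordinates are millimetres with the resting position at the
origin, +y straight ahead, +x rightward. Bearings are degrees clockwise
from +y; a positive deviation rotates the cursor clockwise, so for the
right target (bearing +25°) a positive deviation is *converging* (it
pushes the cursor toward the target side and compensation is toward the
midline) and a negative one *diverging*. The mirror rule holds for the
left target: `classify_mode(left, α) == classify_mode(right, −α)`.

The range of motion is sin(max tilt) × pelvis height (default 8.5°,
1.0 m → 147.8 mm); targets sit at 80% of it (118.2 mm). The deviation
onset defaults to 25 mm from the resting position. The task description
and the quantification section of the source protocol disagree on this
radius (250 vs 25 mm); 250 mm would lie *beyond* the target distance, so
the rotation would never engage — geometrically impossible — hence the
25 mm default, exposed as `TaskGeometry.deviation_onset_mm`.

Sub-blocks are 88 trials: 24 control plus 16 per |α| ∈ {7.5°, 15°,
22.5°, 30°}, balanced 4/4/4/4 over sign × target side within each
magnitude (control 12/12 over targets), shuffled by a seeded generator.
The sign × target balance within magnitude is stricter than the source
protocol states ("evenly distributed across targets"); full balance makes
the marginal mode contrasts exactly orthogonal. The randomization is an
unconstrained shuffle (no consecutive-repeat constraint; none is
documented for the original task).

## Synthetic observers

P(yes | d) = λ_low + (1 − λ_low − λ_high) · (1 − Φ((d − μ_eff)/σ)), with
d = |α|, μ_eff = μ + mode_shift on converging trials. The cumulative
Gaussian (descending in d) follows from the field's convention of
reporting sensitivity as 1/σ; the asymmetric lapse reproduces the ~90%
ceiling on veridical trials (λ_low = 0 by default). The mode effect is an
additive threshold shift (default +3°) rather than a σ change — the
simplest mechanism producing more self-attribution when the rotation
"helps" the reach; it is configurable (`mode_shift_deg`).

Population structure: each parameter is truncated normal across
participants. Sampling uses a Gaussian copula — correlated standard
normals pushed through the truncated-normal quantile function — so
marginals are exactly truncated normal (making the calibration's analytic
expectations exact one-dimensional integrals) while one shared latent
factor per parameter family induces the between-effector correlation of
thresholds and slopes (underlying-normal correlation `latent_strength`,
default 0.75). Defaults per (effector, task): threshold means/SDs
26.81 ± 12.33, 22.86 ± 8.07, 22.01 ± 9.21, 20.57 ± 6.77 (hand/full-body ×
single/dual), slopes 0.077 ± 0.035, 0.070 ± 0.025, 0.081 ± 0.040,
0.078 ± 0.027, with bounds μ ∈ [2, 60]°, slope ∈ [0.02, 0.25] (σ = 1/slope).
λ_high is solved per effector at calibration-construction time so the
analytic control-trial yes rate E[(1 − λ_high)·Φ(μ·slope)], pooled over
tasks, equals the published self-attribution rates (0.913 hand, 0.899
full body); with the default population spread this gives λ_high ≈ 0.003
(hand) and 0.011 (full body).

## Synthetic agents

Reaches follow a minimum-jerk arc-length profile aimed at the target,
time-scaled so the target radius is crossed exactly at
`movement_duration` (the profile then decelerates into a 15% overshoot
and holds still, so completion detection can operate). Beyond the
deviation onset (plus `correction_lag`, default 0) the heading rotates by
−gain·α plus a per-trial angular noise draw ε ~ N(0, motor_noise_sd):
the agent cancels the fraction `gain` of the imposed cursor rotation.
This construction makes the measured MP equal gain·|α| exactly for
noiseless agents — the package's cross-module oracle. A consequence worth
knowing: because the first 25 mm are travelled before feedback deviates,
a gain-1 agent's *cursor* endpoint misses the target bearing by
asin(r₀·sin α / R) (≈ 6° at α = 30°); exact cursor-on-target behavior and
MP = |α| measured from the onset point are geometrically incompatible,
and the package pins the latter.

Blind reaches are endpoint draws: target + isotropic Gaussian noise
(optionally a radial bias, default 0). Per-trial error is then Rayleigh
with mean σ·√(π/2), so the default noise SDs are solved from the
published mean errors (26 mm hand → σ = 20.7 mm; 18 mm full body →
σ = 14.4 mm; between-participant SDs 9 and 6 mm scaled the same way).
Under this model the within-participant error SD is ≈ 0.66·σ (13.6 and
9.4 mm), somewhat above the published 11 and 9 mm — a single isotropic
noise scale cannot match the mean and SD independently; the mean is the
calibrated quantity. Motor angular noise defaults come from the folded
normal mean E|ε| = sd·√(2/π) applied to the published visually-guided
errors (2.5° hand, 4.0° full body). Movement durations (1.0 / 1.5 s) and
response-time means (1.1 / 1.4 s) express the reported hand-faster
ordering; no absolute values are published for them.

Randomness: one root `SeedSequence`; child streams in documented order
(cohort sampling, then one stream per participant covering all trials);
sub-block shuffles use per-participant child seeds plus the condition
index.

## Trajectory processing

Smoothing is a centered 5-sample moving average with shrinking windows at
the edges (no padding). Per-trial metrics run on the smoothed stream at
native sampling; arc-length-uniform resampling (default 100 points) is
reserved for averaging trajectories across trials, since it destroys the
dwell information the completion rule needs. Onset is the first sample
whose radial velocity (first differences × rate, no extra smoothing)
exceeds 2% of the trajectory's maximum — about 3 samples into a
minimum-jerk profile at 30 Hz. Completion requires < 0.5 mm displacement
over a 0.5 s window after ≥ 50 mm of cumulative path. The endpoint is the
linear interpolation at the first target-radius crossing, projected onto
the circle (removing the chord residual, so endpoints lie on the target
circle to near machine precision). Reaching time runs from onset to end
of trial, where end of trial defaults to the stillness criterion and can
be switched to the radius crossing (`AnalysisOptions.end_rule`); with the
stillness rule a 0.5 s dwell is part of every reaching time by
construction. A trial is a *restart* if its radial distance, after
exceeding 30% of the target radius, falls below 10% before completion
(thresholds configurable); restarts are excluded upstream.

MP sign convention: positive opposes the imposed rotation, so full
compensation reads +|α| and Fig-style MP curves increase with |α|.
Control trials return the signed endpoint bearing error (positive =
clockwise of the target) as the MP baseline.

## Psychometric fitting

Bernoulli MLE of P(yes | d) over (μ, σ, λ_high), λ_low fixed at 0 and
λ_high bounded by 0.15 (fitted by default because the ~0.9 veridical
ceiling otherwise forces σ upward). Trials pool modes within participant
× effector × task and include the d = 0 level by default (configurable).
Optimization is L-BFGS-B restarted from a 5 × 5 grid of (μ, σ) starts
(log-likelihood tolerance 1e-8, ties toward the smallest σ); the fitted
optimum is checked in tests against an exhaustive 21 × 21 × 16
(μ, σ, λ) grid. Box bounds default to μ ∈ [0.5, 60]°, σ ∈ [2, 60]°: a σ
below the 7.5° level spacing is not resolvable by this design. SE(μ̂)
comes from the central-difference observed information.

Flags instead of silent numbers: *degenerate* (identical yes rate at
every level — no threshold information, e.g. all-yes observers),
*boundary* (optimum on the μ or σ box edge — typically observers whose
true threshold lies beyond the largest tested deviation of 30°, where
the likelihood favors a step at the last level). Group summaries (the
threshold/slope table with t-based 95% CIs, and the between-effector
correlations) exclude degenerate and boundary fits and report the
per-cell n. Participant exclusion follows the yes-rate rule: dropped only
when the rate is below 0.5 at *every* level including control (strictly —
exactly 0.5 keeps the participant).

Reported sensitivity is slope = 1/σ (the convention of the field's
summary tables); the derivative at the PSE,
(1 − λ_low − λ_high)/(σ√(2π)), is exposed as `slope_at_pse_`.

## Robust and Bayesian statistics

Skipped Pearson correlation: robust center from the minimum covariance
determinant (75% support); each point is tested on the projection of the
sample onto the line through the center and that point, flagged by the
MAD-median rule at √χ²₀.₉₉₉(2) ≈ 3.72 robust-z units; Pearson's r, its
t = r√(n−2)/√(1−r²), and a percentile bootstrap CI (default 1000
resamples of the retained pairs) follow. The gross-outlier cutoff keeps
the expected false-flag count on clean Gaussian samples below ~0.1% of
points, so on clean data the skipped estimate coincides with plain
Pearson; the more aggressive 95% cutoff and the union-over-all-directions
rule are available (`cutoff=`, `union_directions=`). Between-effector
correlations are computed on task-averaged thresholds (and slopes) per
participant.

JZS paired Bayes factor: Cauchy prior (scale √2/2, configurable) on the
standardized effect of the differences, computed through the
inverse-gamma mixture representation as a one-dimensional log-space
quadrature — numerically stable for arbitrary n and t, and cross-checked
in tests against an independent Monte-Carlo integration and a reference
implementation. p-values are two-sided throughout; Bonferroni correction
multiplies by the family size and caps at 1.

## Problem sizes and known limitations

- The default study is 20 participants × 4 sub-blocks × 88 trials (7040
  action-monitoring trials) plus 2 × 60 blind reaches per participant;
  the parameter-recovery experiment uses 200 observers with one 88-trial
  sub-block each.
- With 5 deviation levels and 88 trials, threshold estimates carry a
  sampling SE of roughly 1–3° depending on σ; thresholds beyond the
  largest tested deviation (30°) are extrapolations and often end as
  boundary fits. Slope (1/σ) estimates are noisier still, so
  between-effector slope correlations are strongly attenuated at this
  trial count even when the generating correlation is high; threshold
  correlations survive with moderate attenuation.
- The Cramér–Rao bound for this design caps the achievable fitted-vs-true
  threshold correlation near 0.93 for cohorts spanning σ ∈ [5, 20] —
  a property of the design, not the optimizer; the recovery tests verify
  the MLE attains the grid-search optimum on every fit.
- The generator emulates the statistical structure the analysis assumes
  (balanced design, stationary observers, isotropic blind noise,
  independent trials). It does not emulate learning or fatigue across
  trials, trajectory curvature beyond a single post-onset heading change,
  vestibular physiology, or the vocal dual task itself (only its
  calibrated effects on thresholds and durations). Passing tests
  therefore validate the pipeline's correctness and calibration, not
  claims about real participants.
- Blind-reach variability (precision) is a derived quantity of the noise
  model, ≈ 25% above the published SDs (see above).
- The stillness end-of-trial rule embeds its 0.5 s dwell window in every
  reaching time; use `end_rule="radius"` for dwell-free durations.
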