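# Methods

## Problem setting

A smartphone carried loose in a pocket observes the wearer's movement
through its accelerometer, gyroscope, and magnetometer, and its own carry
state through the light sensor, proximity sensor, and telephony state. The
pipeline answers two questions: *is the phone in a pocket right now?* and,
when it is, *which of five activities — static, walking, running, walking
upstairs, walking downstairs — is the wearer performing?*

## In-pocket rule

A context sample is in-pocket iff

* light `< lux_threshold` (default 100 lux, strict inequality: a reading of
  exactly 100 lux is out-of-pocket — 100 lux is roughly cloudy-sky
  luminance, and a covered sensor reads well below it),
* proximity is `near` (the pocket fabric sits against the sensor), and
* the phone is idle (an active call overrides: a handset at the ear in the
  dark also reads dark + near).

Between context samples the state is held piecewise-constant from the last
sample; `segment_in_pocket` therefore emits maximal half-open intervals
whose endpoints are context timestamps. No hysteresis or debouncing is
applied — the rule is deliberately memoryless, and flicker suppression is
out of scope. The rule is monotone in lux by construction.

## Signal conditioning

* **Resampling.** Device clocks jitter, so every trace is linearly
  interpolated onto a uniform grid (default 25 Hz) spanning the trace; no
  extrapolation. Multi-sensor alignment uses the intersection of the
  traces' time spans.
* **Gravity split.** Gravity is the output of a 2nd-order Butterworth
  low-pass at 0.25 Hz applied per axis forward and backward
  (`sosfiltfilt`), so the split is zero-phase and windows stay aligned with
  their labels; linear acceleration is defined as the residual, making
  GA + LA = A exact to round-off. The filter's edge transient decays within
  roughly 1/cutoff = 4 s, which the 5 s edge trim absorbs.
* **Edge trim.** The first and last 5 s of a recording (traces, context,
  and annotations alike) are dropped: the wearer needs a moment to pocket
  the phone and to retrieve it.
* **Five channels.** la3a = ‖LA‖ and gyr3a = ‖ω‖ are rotation-invariant
  magnitudes (any orthonormal R applied to all axes leaves them unchanged,
  because per-axis linear filtering commutes with the fixed rotation); the
  magnetometer's three axes are passed through raw. The magnetometer
  channels are *not* orientation-invariant — they are retained for parity
  with the conventional five-channel layout, and the tests assert both
  directions (magnitude features invariant, magnetometer features not).

## Windows and features

Windows are 1.6 s long (40 samples at 25 Hz) with 50 % overlap → 0.8 s
stride; a signal of N samples yields floor((N − n)/stride) + 1 windows
before label filtering. A window takes the label of the annotation that
contains it entirely; windows straddling an annotation boundary are dropped
rather than majority-labelled, since transitions between activities are
genuinely ambiguous.

Per channel and window, six statistics (30 features total, signal-major
order, names like `la3a_mean` … `mag_z_iqr`; the gyroscope magnitude is
exported under its conventional field label `gyr3z`):

* mean, median;
* standard deviation with the n−1 denominator (consistent with the
  bias-correction factors below);
* skewness `n/((n−1)(n−2)) · Σ((xᵢ−x̄)/s)³`;
* excess kurtosis `[n(n+1)ΣD⁴ − 3(ΣD²)²(n−1)] / [(n−1)(n−2)(n−3)s⁴]`,
  algebraically identical to the spreadsheet KURT estimator (asserted in
  tests against an independent implementation);
* inter-quartile range with linearly interpolated percentiles (the "type 7"
  rule — the common default; the choice is pinned and tested rather than
  left to ambiguity).

**Degenerate windows.** A perfectly constant window has s = 0; skewness and
kurtosis are defined as 0 there instead of NaN so that static activity
remains classifiable.

## Classifiers and evaluation

* **Decision tree.** scikit-learn's entropy-criterion tree supplies the
  split search with `min_samples_leaf = 30`; on top of it sits a
  C4.5-style error-based pruning pass: each internal node is collapsed when
  the pessimistic error of the node-as-leaf (upper confidence bound of the
  binomial error at one-sided confidence `confidence_factor`, default 0.25,
  via the normal approximation) does not exceed the summed pessimistic
  errors of its children. `pruned=False` skips the pass; both
  configurations run. Note the 30-object minimum leaf means datasets with
  under 60 training instances cannot split at all — intended behaviour, not
  a bug.
* **Naive Bayes.** Hand-written Gaussian naive Bayes: the class-conditional
  density is the product of univariate normal densities, one per feature
  (maximum-likelihood variance floored at 1e-9 to keep densities proper).
  scikit-learn's GaussianNB serves as an independent cross-check in the
  tests, never as the implementation.
* **SMO SVM.** scikit-learn's `SVC` (libsvm's SMO solver), linear kernel,
  C = 1, one-vs-one. Class probabilities are pairwise vote shares
  (votes / number of pairs), which sum to 1 by construction; Platt scaling
  is deliberately not used, so the SVM's RMSE is coarse by design.
* **Cross-validation.** Stratified shuffled k-fold (default k = 10, fixed
  seed). When a class has fewer members than k — e.g. the leave-one-out
  limit — stratification is impossible and a plain shuffled k-fold is used.
  Every instance is tested exactly once; the report aggregates all test
  predictions.
* **Metrics.** Confusion matrix (rows actual, columns predicted, fixed
  class order static/walking/running/upstairs/downstairs), accuracy
  = 100·trace/total, per-class precision/recall, and
  RMSE = √(mean over instances × classes of (p − onehot)²) ∈ [0, 1].
  Fit time is logged but excluded from `metrics.json` so that repeated runs
  with the same seed are byte-identical.

## Synthetic generator

The generator emulates exactly the structure the pipeline relies on:

* gravity of 9.81 m/s² along the canonical device vertical;
* a gait component that is a planar rotating vector
  `LA(t) = r(t)(cos θ d₁ + sin θ d₂)`, θ = 2π·step_hz·t. Its per-axis
  signals are nearly DC-free, so the 0.25 Hz gravity split passes it
  through intact and la3a tracks r(t) directly — the fundamental of la3a is
  the step frequency itself, not its double, as it would be for a rectified
  1-D oscillation;
* `r(t) = amp(1 + 0.35 cos θ + 2.2·asym·burst(θ))·env(t)` with `burst` a
  brief once-per-cycle pulse: positive asymmetry adds heel-strike-like
  spikes (upstairs), negative adds dips (downstairs); |asym| ≤ 0.25 keeps
  r > 0. `env` is per-stride amplitude jitter (~8 %);
* gyroscope: periodic angular velocity at the same step frequency; the
  default per-class angular-velocity scales order the moving classes with
  wide gaps (stair gait swings the leg more slowly than level walking;
  running fastest), which keeps classes separable in `gyr3z` statistics
  whatever the pocket's amplitude scaling;
* magnetometer: a constant ~49 µT ambient field in the world frame —
  orientation-dependent on purpose;
* placements: six pockets; coat pockets scale amplitudes by 0.8 (the trunk
  moves less than the legs), so coat recordings show smaller mean la3a than
  trouser recordings of the same activity — a generator contract the tests
  assert; orientations: the four vertical carry orientations (head up/down
  × face in/out) or a uniformly random rotation;
* context: 1 Hz light/proximity/call streams whose ground-truth pocket
  state is known by construction (dim in-pocket daylight, 0.25 lux
  full-moon darkness with a call in the middle third, or 10 000 lux
  overcast out-of-pocket).

Default profiles (step_hz / la_amp in m/s²): static 0 / 0.05, walking
1.8 / 2.0, running 2.8 / 6.0, upstairs 1.5 / 2.5, downstairs 1.6 / 3.0;
accelerometer noise 0.3 m/s² (0.02 when static). These are stated defaults,
tunable per call; they were chosen to make the five classes separable while
walking and the stair classes still overlap in the low-order la3a features,
and they carry no claim of physiological fidelity.

**What passing tests do and do not show.** The generator produces stationary
periodic gait with modest jitter, a single noise scale, perfectly known
labels, and no inter-subject variability, soft-tissue artefacts, pocket
slip, or transition dynamics. Cross-validated accuracies near 100 % on it
demonstrate that the pipeline's plumbing — gating, invariant channels,
windowing, features, CV bookkeeping — is correct, *not* that comparable
accuracy would be reached on real recordings, where reported figures for
this class of pipeline are substantially lower (roughly 75–90 % depending
on classifier). The tree-vs-naive-Bayes ranking on synthetic data is
reported by the acceptance suite but deliberately not asserted.

## Numerical choices and degenerate inputs

* Timestamps are seconds as doubles; file round-trips use `%.17g` so all
  numeric fields survive write→read to better than 1e-9 relative.
* Resampling grid size uses `floor((t_end − t_start)·rate + 1e-9) + 1` to
  avoid dropping the final sample to float fuzz.
* Window/annotation containment uses a 1e-9 tolerance at interval
  endpoints.
* Readers count malformed rows (wrong arity, unparseable numbers) in a
  parse report instead of dropping them silently; an unknown sensor tag or
  non-monotone timestamps abort with the offending line identified.
* `rmse` validates that probability rows sum to 1 within 1e-6; fold models
  that never saw a class leave zero columns, which are renormalized
  defensively before scoring.
* Problem sizes in the test and acceptance suites (250-row default dataset,
  100 rotations, 1000 oracle windows, 12–40 s recordings) were chosen as
  the smallest sizes at which the checked properties are stable and
  meaningful.

## Known limitations

* Only pocket carry positions are modelled; hand, bag, and mounted carry
  are out of scope, as is any hysteresis in the pocket rule.
* The magnetometer channels are orientation-dependent; a deployment that
  rotates devices freely should expect their 18 features to carry little
  transferable signal (the orientation-invariance tests quantify exactly
  this).
* The C4.5-style pruning uses the normal-approximation confidence bound,
  not WEKA's exact implementation; parity with WEKA's J48 trees is not a
  goal — the pinned contract is entropy splits, the 30-object leaf minimum,
  and a confidence-factor-driven pruning pass.
* The tree's `numFolds`-style reduced-error pruning is not implemented
  (irrelevant when error-based pruning is active).
* Real-time/on-device operation is out of scope; the pipeline is offline
  batch only.
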