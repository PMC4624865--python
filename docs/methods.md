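# Methods

## Model

The decoder is a linear-Gaussian state-space model in which the usual
roles of state and measurement are arranged to match the physiology:
muscle activity *causes* pen movement, so EMG enters through an inverse
measurement map rather than the textbook observation equation.

**State.** `s_t` stacks pen position, velocity and acceleration in x and
y over the `K` most recent samples (6K entries). Velocities and
accelerations are first and second *backward* finite differences of the
tablet coordinates, in tablet-units per sample; any centered scheme would
leak future samples and break causality. The per-sample scaling is
deliberate — the fitted matrices absorb the sampling rate, so the filter
never needs to know it.

**Dynamics.** `s_t = A s_{t−1} + v_t`, `v_t ~ N(0, Q)` — a first-order
multivariate autoregression capturing the smoothness and rhythm of
handwriting. Note position dynamics are near unit-root (position is
integrated velocity), so `A` is not assumed stable; the filter never
iterates it in open loop for long.

**Measurement.** `s_t = H z_t + w_t`, `w_t ~ N(0, R)`, where `z_t`
concatenates the `L` most recent 8-channel envelope samples
(newest-first). The noise `w_t` lives on the state side, so `R` is a
6K×6K state-space covariance and the Kalman gain
`K_t = P_{t|t−1}(P_{t|t−1} + R)⁻¹` is a square state-dimension matrix;
no measurement-side projection appears anywhere in the update. `Σ₂ = R`
is treated as stationary even though `z_t` varies.

**Fusion.** Each update multiplies the two Gaussian beliefs. The
implementation uses the gain form (`Σ = Σ₁ − KΣ₁`,
`μ = μ₁ + K(μ₂ − μ₁)`) rather than the information form
(`(Σ₁⁻¹+Σ₂⁻¹)⁻¹`): one linear solve instead of three inversions, and it
tolerates one singular input. Tests verify the two forms agree to 1e-8
across dimensions 1–12.

## Preprocessing

Per channel: absolute value → 2nd-order Butterworth low-pass at
`fc = 2 Hz` → clip at 0 → element-wise square root. Filtering is a
single causal forward pass from zero initial state; zero-phase filtering
would use future samples. The clip exists because a Butterworth response
to nonnegative input can transiently undershoot zero, which would break
the square root; at 2 Hz the distortion is negligible. The square root
stabilises the variance of the envelope (EMG amplitude noise scales with
activation). Envelopes are decimated to the pen rate by plain striding —
legitimate because the signal is already band-limited at 2 Hz.

Defaults: raw EMG at `fs_raw = 1000 Hz`, envelopes and pen at
`fs_env = 100 Hz`. These are package choices for desk-scale realism, not
constants of the method; both are configurable.

## Estimation

`A` and `H` are pooled ordinary least squares over training trials;
transition pairs never straddle trial boundaries (trials are independent
writings). `Q` and `R` are the ML residual covariances, symmetrised as
`(C+Cᵀ)/2` plus a relative jitter `1e-9·mean(diag)·I` so the filter is
guaranteed positive semi-definite inputs. A ridge penalty is available on
both regressions (default 0, i.e. plain OLS) for strongly collinear
lagged envelopes. Rank-deficient regressors raise an explicit
fit-degenerate error naming the deficiency rather than silently
producing a pseudoinverse fit.

Decoding starts every trial from `s₀ = 0` — trials are translated so the
pen starts at the origin — with `P₀ = Q`: one step of process
uncertainty is the natural prior scale (the start state itself is known
exactly, but `P₀ = 0` would make the first gains degenerate; this choice
is configurable and washes out within a few samples).

## Evaluation protocol

Within each (subject, symbol) group, trials are split 50/50 at random
(ceil(n/2) to training when odd); fits are per subject. Two designs:
*within-group* pools all symbols into one model per subject;
*per-symbol* fits ten models per subject and tests each on its own
symbol. Scores are computed per trial per coordinate, aggregated per
symbol within subject, and summarised across subjects with Student-t 95%
confidence intervals on the subject means (dispersions are reported
three ways — sd, sem, CI half-width — since conventions differ). Burn-in
samples are included in the score.

**The two metrics.** The explained-energy ratio
`Σ(ŝᵢ − s̄)²/Σ(sᵢ − s̄)²` (with `s̄` the actual trace's mean) is the
package's default table metric. It is *not* a squared correlation and is
not bounded by 1: any noise in the prediction adds to the numerator, so
a noisy decoder can score arbitrarily "well". For this reason every
decoder *comparison* (`run_comparison`, the Wilcoxon test, the grid
search as configured in the acceptance script) defaults to the squared
Pearson correlation, under which "higher is better" actually holds; the
energy ratio is kept as the default table metric for descriptive
continuity, with the discrepancy surfaced here rather than silently
resolved. The two agree exactly for predictions that are recentred,
unit-slope affine copies of the truth.

**Model order.** `grid_search_order` evaluates each (K, L) cell by
`g = mean(R²)/sd(R²)` over trials — accuracy weighted by stability. The
grid runs on the training half with an internal sub-split (outer seed +
1), leaving the outer test half untouched; whether to nest the selection
this way was an open choice, and nesting was preferred to keep the final
test trials unseen. Zero spread is reported as `+inf` and excluded from
the argmax (an all-degenerate grid falls back to highest mean).

**Comparison.** KF and WF are compared on identical preprocessed inputs:
shared envelope cache, shared split, same fitted model. The one-sided
Wilcoxon matched-pair test drops zero differences, uses the exact null
for n < 25 pairs and the normal approximation with continuity correction
otherwise (if exact enumeration is impossible because of tied absolute
differences, the normal approximation is used).

## The simulator

The generator produces the study conditions the protocol defaults to: 6
subjects × 10 digits × 50 trials, SNR 10, 2 s trials.

* **Pen traces**: cubic splines through fixed per-digit control points
  (single continuous stroke, chord-length parametrised), with per-trial
  scale jitter ±10%, rotation ±5°, and a smooth monotone time warp;
  translated to start at (0, 0).
* **Muscles**: 8 channels with cosine-like preferred directions in
  velocity space plus a weak acceleration coupling, rectified-linear,
  with a resting baseline — redundant coverage of 4 kinematic drives, so
  the EMG→kinematics inverse is well-posed only statistically. Each
  subject multiplicatively perturbs the tuning (±30% scale).
* **Raw EMG**: `e_c(t) = a_c(t)·η(t) + σ_b·ν(t)` with unit-variance
  white `η, ν`. This amplitude-modulated-noise model is the minimal one
  for which rectification + low-pass provably recovers (a smooth
  function of) the activation: the envelope tends to
  `sqrt(2/π)·sqrt(a² + σ_b²)`, approximately affine in the kinematic
  drives after the square-root transform. `σ_b` is set from the
  configured activation-to-baseline power ratio (`snr`); a trial with
  identically zero activation falls back to a unit reference power so
  the noise floor stays defined.

What the simulator does **not** emulate: motor-unit action potentials or
any biophysical muscle dynamics, electrode crosstalk, drift and motion
artifacts, pen lifts and pressure, inter-trial fatigue, or truly
nonlinear EMG–kinematics relationships beyond the rectification. Passing
tests therefore demonstrate that the pipeline is correct and that the
decoder exploits dynamics when the modelling assumptions approximately
hold — not that these accuracy levels transfer to laboratory recordings,
where scores are typically much lower and far more subject-dependent.
In particular the simulator's strokes are highly repeatable, which
inflates absolute scores relative to natural handwriting; the
*directional* findings (Kalman > Wiener; per-symbol ≥ pooled) are the
transferable content.

## Numerical choices

* Covariances symmetrised after every update; all inverses are linear
  solves; degenerate solves raise an error carrying the failing time
  index.
* Boundary handling is deterministic: derivative slots of the first two
  samples are zero, missing lag blocks (state and observation) repeat
  the earliest available sample.
* CSV containers are written with `%.17g` and read with round-trip float
  parsing, so text round-trips are bit-exact; manifests carry SHA-256
  checksums per file.
* All randomness flows through `numpy.random.default_rng` seeded from
  the configuration; a dataset is a pure function of its config.

## Problem sizes

The test suite exercises the full default scenario (3,000 trials) once
for the directional claims and contraction checks, and small scenarios
(tens to hundreds of trials) everywhere else; parameter-recovery checks
use 20,000-sample simulations. The acceptance script runs the full
default scenario plus a 2-subject × 20-trial grid search, completing in
about a minute on one core.

## Known limitations

* The inverse-form filter treats `R` as stationary and ignores any
  cross-covariance between process and measurement residuals; a
  cross-covariance-aware variant is out of scope.
* No smoothing (RTS) pass and no online re-estimation of `Q`/`R`.
* The energy metric's inflation under prediction noise means its
  absolute values should not be compared across decoders of different
  noise levels; use the squared correlation for that.
* With `K > 1` the lagged state blocks make `Q` nearly singular in the
  copied coordinates; the jitter keeps the filter well-posed, but large
  `K` mostly adds computation, not information.
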