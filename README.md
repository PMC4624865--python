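# emg2pen

Causal decoding of 2-D handwriting trajectories from multichannel surface
EMG, for researchers in myoelectric interfaces and neuroprosthetics.

Surface EMG recorded from hand and forearm muscles carries enough
information to reconstruct what a pen is writing — but a purely static
regression from EMG to pen position is noisy. `emg2pen` improves on the
static (Wiener-filter) decoder by fusing two information sources with a
Kalman filter:

1. **Pen dynamics.** The state
   `s_t = [x, y, ẋ, ẏ, ẍ, ÿ, …]` (position, velocity, acceleration over
   `K` lags, 6K entries) evolves as a multivariate autoregression
   `s_t = A s_{t−1} + v_t`, `v_t ~ N(0, Q)`.
2. **Muscle activity.** Because muscles *cause* the pen movement, the
   measurement model is used in inverse form: lagged EMG envelopes
   `z_t = [e_t; …; e_{t−L+1}]` (8 channels × `L` lags) map directly into
   state space, `s_t = H z_t + w_t`, `w_t ~ N(0, R)`.

At each step the filter multiplies the two Gaussian beliefs: with gain
`K_t = P_{t|t−1}(P_{t|t−1} + R)⁻¹`,

```
ŝ_t|t = ŝ_t|t−1 + K_t (H z_t − ŝ_t|t−1),     P_t|t = P_t|t−1 − K_t P_t|t−1.
```

Everything is strictly causal — the estimate at time `t` uses EMG samples
up to `t` only — so the decoder is suitable for real-time use. `A, Q, H,
R` are estimated by ordinary least squares on training trials. The causal
Wiener baseline `ŝ_t = H z_t` (measurement model alone) is included so
the benefit of the dynamics prior can be isolated. A synthetic
handwriting/EMG simulator makes the whole pipeline testable without
laboratory recordings.

## Worked example

```bash
python examples/04_kalman_vs_wiener.py
```

```
mean squared correlation, Kalman filter : 0.959
mean squared correlation, Wiener filter : 0.536
one-sided Wilcoxon (KF > WF)            : p = 1.98e-18
per-symbol (between-group) Kalman mean  : 0.979
p << 0.05: the dynamics prior significantly improves reconstruction
```

Two synthetic subjects write each digit ten times; both decoders share
the same fitted `H`, the same train/test split and byte-identical
envelopes, so the gap (0.959 vs 0.536 mean squared correlation between
decoded and actual coordinates, Wilcoxon p ≈ 2e-18) measures exactly what
the autoregressive pen-dynamics prior contributes. Fitting one model per
digit ("between-group" design, 0.979) beats the pooled model
("within-group", 0.959) because each digit's dynamics are more
predictable in isolation.

The other `examples/` scripts walk the individual capabilities: envelope
extraction (`01`), dataset simulation (`02`), fitting and single-trial
decoding (`03`), and model-order selection by the accuracy/stability
ratio `g = mean(R²)/sd(R²)` (`05`).

A thin CLI wraps the same library calls:

```bash
emg2pen simulate --seed 7 --out data/
emg2pen evaluate --data data/ --design within-group --k 1 --l 2
emg2pen gridsearch --data data/ --k-range 1,2 --l-range 1,2,3
```

## Evaluation metric

Per-trial reconstruction accuracy is reported with two metrics, per
coordinate: the explained-energy ratio
`R² = Σ(ŝᵢ − s̄)² / Σ(sᵢ − s̄)²` (with `s̄` the mean of the actual
trace — note this ratio can exceed 1 and credits prediction noise as
energy), and the squared Pearson correlation (`metric="pearson"`).
Decoder comparisons default to the squared correlation, which is the
metric under which "higher is better" holds for noisy decoders; see
`docs/methods.md` for the full discussion.
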