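"""Generate a small synthetic handwriting/EMG dataset.

Two synthetic subjects write each digit 0-9 six times; every trial carries
8 channels of activation-modulated EMG at 1 kHz and a 100 Hz pen trace.
The printout shows the dataset size and, for one trial, the trace extent
and EMG power — the raw material every other example starts from.
"""

import numpy as np

from emg2pen import SimulationConfig, generate_dataset

cfg = SimulationConfig(n_subjects=2, n_trials_per_symbol=6, seed=7)
trials = generate_dataset(cfg)

print(f"trials generated : {len(trials)} "
      f"({cfg.n_subjects} subjects x {len(cfg.symbols)} digits x {cfg.n_trials_per_symbol})")
trial = trials[0]
print(f"one trial        : id={trial.trial_id} symbol={trial.symbol}")
print(f"  pen samples    : {trial.pen.shape[1]} at {trial.fs_env:.0f} Hz, "
      f"extent x={np.ptp(trial.pen[0]):.2f} y={np.ptp(trial.pen[1]):.2f} units")
print(f"  raw EMG        : {trial.emg.shape[0]} channels x {trial.emg.shape[1]} "
      f"samples at {trial.fs_raw:.0f} Hz, rms={trial.emg.std():.3f}")
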