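"""Extract a variance-stabilised envelope from raw EMG.

Builds a 50 Hz carrier whose amplitude steps up mid-signal (a crude
"muscle burst"), rectifies and causally low-passes it at 2 Hz, and prints
the steady-state envelope before and after the burst. The envelope should
sit near sqrt(amplitude * 2/pi): the mean of a rectified sine is 2/pi of
its amplitude, and the square-root transform stabilises the variance.
"""

import numpy as np

from emg2pen import RawEMG, extract_envelope

fs = 1000.0
t = np.arange(0, 20.0, 1 / fs)
amplitude = np.where(t < 10.0, 1.0, 4.0)
emg = amplitude * np.sin(2 * np.pi * 50 * t)

env = extract_envelope(RawEMG(emg[None, :], fs=fs), fc=2.0, order=2, sqrt=True)

quiet = env.samples[0, 8000:10000].mean()
burst = env.samples[0, 18000:].mean()
print(f"envelope during quiet phase : {quiet:.4f} (expect ~{np.sqrt(2 / np.pi):.4f})")
print(f"envelope during burst phase : {burst:.4f} (expect ~{np.sqrt(4 * 2 / np.pi):.4f})")
print("ratio burst/quiet           :", round(burst / quiet, 3), "(expect ~2: sqrt of 4x)")
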