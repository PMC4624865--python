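"""EMG envelope extraction.

Raw surface EMG is an amplitude-modulated broadband signal; the decoder
consumes its *envelope*: per channel, the absolute value is taken
(full-wave rectification), low-pass filtered with a causal Butterworth
filter (default 2nd order, cut-off 2 Hz) and, optionally, square-root
transformed to stabilise the variance.

All filtering is strictly causal (single forward pass, zero initial filter
state): the envelope at sample t depends only on raw samples up to t. This
is what makes the downstream decoder usable in real time.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .errors import InvalidInputError, InvalidParameterError

__all__ = [
    "RawEMG",
    "EnvelopeSignal",
    "extract_envelope",
    "decimate_envelope",
    "attach_envelopes",
]

DEFAULT_N_CHANNELS = 8


@dataclass(frozen=True)
class RawEMG:
    """Multichannel raw EMG: ``samples`` is (n_channels, n_samples)."""

    samples: np.ndarray
    fs: float
    channel_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 2:
            raise InvalidInputError(
                f"raw EMG must be 2-D (channels, samples); got ndim={samples.ndim}"
            )
        if self.fs <= 0:
            raise InvalidParameterError(f"sampling rate must be positive; got {self.fs}")
        object.__setattr__(self, "samples", samples)
        if not self.channel_names:
            names = tuple(f"emg{i + 1}" for i in range(samples.shape[0]))
            object.__setattr__(self, "channel_names", names)
        elif len(self.channel_names) != samples.shape[0]:
            raise InvalidInputError(
                f"{len(self.channel_names)} channel names for {samples.shape[0]} channels"
            )

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]


@dataclass(frozen=True)
class EnvelopeSignal:
    """Nonnegative per-channel envelope; same layout and rate as its source."""

    samples: np.ndarray
    fs: float
    fc: float
    sqrt_applied: bool

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]


def extract_envelope(
    raw: RawEMG, fc: float = 2.0, order: int = 2, sqrt: bool = True
) -> EnvelopeSignal:
    """Rectify, causally low-pass, clip and (optionally) square-root each channel.

    Parameters
    ----------
    raw
        Multichannel raw EMG.
    fc
        Butterworth cut-off frequency in Hz; must lie below Nyquist.
    order
        Butterworth filter order (>= 1).
    sqrt
        Apply the element-wise square-root transform after clipping.

    Notes
    -----
    The low-pass is applied as a single forward pass with zero initial
    state, so the output is causal. Because a Butterworth filter can
    transiently undershoot below zero even for nonnegative input, the
    filtered signal is clipped at 0 before the square root.
    """
    if raw.n_samples == 0:
        raise InvalidInputError("empty EMG signal")
    if order < 1:
        raise InvalidParameterError(f"filter order must be >= 1; got {order}")
    if fc <= 0 or fc >= raw.fs / 2:
        raise InvalidParameterError(
            f"cut-off fc={fc} Hz must satisfy 0 < fc < Nyquist ({raw.fs / 2} Hz)"
        )
    if raw.n_samples <= 3 * order:
        raise InvalidInputError(
            f"signal length {raw.n_samples} too short for order-{order} filter"
        )
    b, a = signal.butter(order, fc, btype="low", fs=raw.fs)
    rectified = np.abs(raw.samples)
    env = signal.lfilter(b, a, rectified, axis=-1)
    np.clip(env, 0.0, None, out=env)
    if sqrt:
        np.sqrt(env, out=env)
    return EnvelopeSignal(samples=env, fs=raw.fs, fc=fc, sqrt_applied=sqrt)


def decimate_envelope(env: EnvelopeSignal, fs_out: float) -> EnvelopeSignal:
    """Downsample an envelope by integer striding.

    The envelope is already band-limited far below any practical ``fs_out``
    (fc defaults to 2 Hz), so plain striding introduces no aliasing.
    """
    ratio = env.fs / fs_out
    if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
        raise InvalidParameterError(
            f"fs_out={fs_out} must divide the envelope rate {env.fs} evenly"
        )
    step = int(round(ratio))
    return EnvelopeSignal(
        samples=env.samples[:, ::step], fs=fs_out, fc=env.fc, sqrt_applied=env.sqrt_applied
    )


def attach_envelopes(trials, fc: float = 2.0, order: int = 2, sqrt: bool = True, *,
                     drop_raw: bool = False):
    """Precompute and cache envelopes (at fs_env) on a list of trial records.

    Returns new records with ``envelope`` filled; with ``drop_raw`` the raw
    EMG array is replaced by an empty array to free memory. Used to
    guarantee that alternative decoders are scored on byte-identical
    preprocessed inputs.
    """
    out = []
    for trial in trials:
        if trial.envelope is not None:
            env_s = trial.envelope
        else:
            env = extract_envelope(
                RawEMG(trial.emg, trial.fs_raw), fc=fc, order=order, sqrt=sqrt
            )
            env_s = decimate_envelope(env, trial.fs_env).samples
        rep = {"envelope": env_s}
        if drop_raw:
            rep["emg"] = np.empty((trial.emg.shape[0], 0))
        out.append(dataclasses.replace(trial, **rep))
    return out
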