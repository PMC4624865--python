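"""Lagged state and observation vectors.

The decoder's state vector stacks pen position, velocity and acceleration
(x and y) over K time lags: s_t = [x_t, y_t, x'_t, y'_t, x''_t, y''_t, ...,
back K time moments], giving 6K entries. The observation vector stacks the
L most recent envelope samples newest-first: z_t = [e_t; e_{t-1}; ...;
e_{t-L+1}], giving (n_channels * L) entries.

Derivatives use *backward* finite differences so the features remain
causal, and are expressed per sample (not per second); the fitted matrices
absorb the rate. The first two samples' derivative slots are zero-padded;
missing lag blocks at the start of a trial repeat the earliest available
sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError, InvalidParameterError
from .preprocess import EnvelopeSignal

__all__ = [
    "PenTrace",
    "StateSequence",
    "ObservationSequence",
    "build_state_sequence",
    "build_observation_sequence",
]


@dataclass(frozen=True)
class PenTrace:
    """A 2-D pen trajectory in tablet units, sampled at ``fs`` Hz."""

    x: np.ndarray
    y: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if x.shape != y.shape or x.ndim != 1:
            raise InvalidInputError(
                f"x and y must be equal-length 1-D arrays; got {x.shape} and {y.shape}"
            )
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise InvalidInputError("pen trace contains non-finite values")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    def __len__(self) -> int:
        return self.x.shape[0]


@dataclass(frozen=True)
class StateSequence:
    """Per-sample 6K state vectors; ``states`` is (n_samples, 6K)."""

    states: np.ndarray
    K: int

    def __post_init__(self) -> None:
        states = np.asarray(self.states, dtype=float)
        if states.ndim != 2 or states.shape[1] != 6 * self.K:
            raise InvalidInputError(
                f"state array must be (n, {6 * self.K}) for K={self.K}; got {states.shape}"
            )
        object.__setattr__(self, "states", states)

    def __len__(self) -> int:
        return self.states.shape[0]

    @property
    def coords(self) -> np.ndarray:
        """The (n, 2) pen coordinates, i.e. the newest lag block's x, y."""
        return self.states[:, :2]


@dataclass(frozen=True)
class ObservationSequence:
    """Per-sample lagged envelope vectors; ``observations`` is (n, C*L)."""

    observations: np.ndarray
    L: int

    def __post_init__(self) -> None:
        obs = np.asarray(self.observations, dtype=float)
        if obs.ndim != 2 or obs.shape[1] % self.L != 0:
            raise InvalidInputError(
                f"observation width {obs.shape[1]} is not a multiple of L={self.L}"
            )
        object.__setattr__(self, "observations", obs)

    def __len__(self) -> int:
        return self.observations.shape[0]

    @property
    def n_channels(self) -> int:
        return self.observations.shape[1] // self.L


def build_state_sequence(trace: PenTrace, K: int) -> StateSequence:
    """Stack position, backward-difference velocity and acceleration over K lags.

    For sample t, lag block k (k = 0..K-1) holds the sextet
    [x, y, x', y', x'', y''] at time t-k; blocks referring to times before
    the first sample repeat the earliest sextet.
    """
    if K < 1:
        raise InvalidParameterError(f"state lag order K must be >= 1; got {K}")
    n = len(trace)
    if n < K + 2:
        raise InvalidInputError(f"trace length {n} too short for K={K} (need >= {K + 2})")
    coords = np.column_stack([trace.x, trace.y])
    vel = np.zeros_like(coords)
    vel[1:] = coords[1:] - coords[:-1]
    acc = np.zeros_like(coords)
    acc[2:] = coords[2:] - 2 * coords[1:-1] + coords[:-2]
    # startup convention: derivative slots of the first two samples are zero
    vel[:2] = 0.0
    acc[:2] = 0.0
    sextet = np.column_stack([coords, vel, acc])
    if K == 1:
        states = sextet
    else:
        idx = np.arange(n)
        blocks = [sextet[np.maximum(idx - k, 0)] for k in range(K)]
        states = np.concatenate(blocks, axis=1)
    return StateSequence(states=states, K=K)


def build_observation_sequence(
    env: EnvelopeSignal | np.ndarray, L: int
) -> ObservationSequence:
    """Concatenate the L most recent envelope samples, newest first.

    For t < L-1 the missing older blocks repeat the earliest available
    sample.
    """
    if L < 1:
        raise InvalidParameterError(f"measurement lag order L must be >= 1; got {L}")
    samples = env.samples if isinstance(env, EnvelopeSignal) else np.asarray(env, float)
    if samples.ndim != 2 or samples.shape[1] == 0:
        raise InvalidInputError("envelope must be a non-empty (channels, samples) array")
    per_sample = samples.T  # (n, C)
    n = per_sample.shape[0]
    idx = np.arange(n)
    blocks = [per_sample[np.maximum(idx - l, 0)] for l in range(L)]
    return ObservationSequence(observations=np.concatenate(blocks, axis=1), L=L)
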