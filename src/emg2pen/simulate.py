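"""Synthetic handwriting trials with forward-modelled surface EMG.

The generator emulates the statistical structure the decoder assumes:
repeatable digit-like pen strokes whose muscle activations relate
approximately linearly to pen kinematics, realised as amplitude-modulated
broadband noise on eight channels.

Pen traces
    A fixed per-digit template (cubic spline through hard-coded control
    points, one continuous stroke) is sampled at the envelope rate over
    the trial duration; each trial gets random affine jitter (scale,
    rotation, smooth monotone time-warp) and is translated so the first
    sample is (0, 0).

Muscles
    Each of the 8 channels has a rectified-linear directional tuning to
    the four kinematic drives (vx, vy, ax, ay): activation
    a_c(t) = max(0, w_c . kin(t) + baseline_c). Eight channels covering
    four drives embody motor redundancy. Each synthetic subject perturbs
    the tuning matrix multiplicatively.

Raw EMG
    e_c(t) = a_c(t) * eta(t) + sigma_b * nu(t) with eta, nu independent
    unit-variance white noise at the raw rate; sigma_b is set from the
    configured SNR (ratio of activation-driven to baseline EMG power).
    Rectification + low-pass then provably recovers (a smooth function
    of) the activation envelope.

Everything is a pure function of the configuration, including its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.interpolate import CubicSpline

from ._templates import DIGIT_CONTROL_POINTS, template_points
from .errors import InvalidParameterError
from .features import PenTrace
from .io import TrialRecord, write_trials
from .preprocess import RawEMG

__all__ = [
    "SimulationConfig",
    "MuscleModel",
    "default_muscle_model",
    "generate_pen_trial",
    "generate_emg",
    "generate_dataset",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic dataset.

    Defaults emulate the recording setup the decoder targets: 6 subjects,
    ~50 repetitions of each digit 0-9, 8 EMG channels, raw EMG at
    1000 Hz with pen/envelope streams at 100 Hz, 2 s per trial, and an
    activation-to-baseline EMG power ratio (snr) of 10.
    """

    n_subjects: int = 6
    n_trials_per_symbol: int = 50
    symbols: tuple[int, ...] = tuple(range(10))
    fs_raw: float = 1000.0
    fs_env: float = 100.0
    trial_duration: float = 2.0
    snr: float = 10.0
    scale_jitter: float = 0.10
    rotation_jitter_deg: float = 5.0
    time_jitter: float = 0.08
    subject_variability: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_trials_per_symbol < 1:
            raise InvalidParameterError("subject and trial counts must be positive")
        if not self.symbols:
            raise InvalidParameterError("symbols must be nonempty")
        for s in self.symbols:
            if s not in DIGIT_CONTROL_POINTS:
                raise InvalidParameterError(f"unknown symbol {s!r}")
        if self.fs_raw <= 0 or self.fs_env <= 0 or self.trial_duration <= 0:
            raise InvalidParameterError("rates and duration must be positive")
        if self.snr <= 0:
            raise InvalidParameterError("snr must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["symbols"] = list(self.symbols)
        return d


@dataclass(frozen=True)
class MuscleModel:
    """Rectified-linear mapping from kinematic drives to channel activations.

    ``W`` is (n_channels, 4) over drives (vx, vy, ax, ay) in units/s and
    units/s^2; ``baseline`` holds resting activation levels. Channel
    activation is max(0, W @ kin + baseline), hence always nonnegative.
    """

    W: np.ndarray
    baseline: np.ndarray

    def __post_init__(self) -> None:
        W = np.atleast_2d(np.asarray(self.W, float))
        baseline = np.atleast_1d(np.asarray(self.baseline, float))
        if W.shape[1] != 4 or baseline.shape[0] != W.shape[0]:
            raise InvalidParameterError(
                f"W must be (channels, 4) with matching baseline; got {W.shape}"
            )
        object.__setattr__(self, "W", W)
        object.__setattr__(self, "baseline", baseline)

    @property
    def n_channels(self) -> int:
        return self.W.shape[0]

    def activation(self, kin: np.ndarray) -> np.ndarray:
        """(n, 4) kinematics -> (n_channels, n) nonnegative activations."""
        drive = kin @ self.W.T + self.baseline
        return np.maximum(drive, 0.0).T


# velocity and acceleration tuning gains: chosen so that template-scale
# strokes (units ~1-2, 2 s) yield activations of order one
_VEL_GAIN = 0.8
_ACC_GAIN = 0.015
_BASELINE = 0.3


def default_muscle_model(
    rng: np.random.Generator | None = None,
    n_channels: int = 8,
    perturbation: float = 0.0,
) -> MuscleModel:
    """Eight channels with cosine-like preferred directions in velocity space.

    With ``rng`` and ``perturbation`` > 0 the tuning matrix and baselines
    are multiplicatively perturbed, producing one synthetic subject.
    """
    theta = 2 * np.pi * np.arange(n_channels) / n_channels
    W = np.column_stack(
        [
            _VEL_GAIN * np.cos(theta),
            _VEL_GAIN * np.sin(theta),
            _ACC_GAIN * np.cos(theta + np.pi / 4),
            _ACC_GAIN * np.sin(theta + np.pi / 4),
        ]
    )
    baseline = np.full(n_channels, _BASELINE)
    if rng is not None and perturbation > 0:
        W = W * (1.0 + perturbation * rng.standard_normal(W.shape))
        baseline = np.maximum(
            baseline * (1.0 + perturbation * rng.standard_normal(n_channels)), 0.0
        )
    return MuscleModel(W=W, baseline=baseline)


def generate_pen_trial(
    symbol: int, cfg: SimulationConfig, rng: np.random.Generator
) -> PenTrace:
    """One jittered digit stroke at the envelope rate, starting at (0, 0)."""
    if symbol not in cfg.symbols:
        raise InvalidParameterError(f"symbol {symbol!r} not in cfg.symbols")
    pts = template_points(symbol)
    # chord-length parametrisation of the template spline
    chord = np.sqrt(np.sum(np.diff(pts, axis=0) ** 2, axis=1))
    u_pts = np.concatenate([[0.0], np.cumsum(chord)])
    u_pts /= u_pts[-1]
    # strictly increasing knots (duplicate control points get a tiny nudge)
    u_pts = np.maximum.accumulate(u_pts + 1e-9 * np.arange(len(u_pts)))
    spline = CubicSpline(u_pts, pts, axis=0)

    n = int(round(cfg.fs_env * cfg.trial_duration))
    tau = np.linspace(0.0, 1.0, n)
    # smooth monotone time-warp, endpoints fixed
    a1, a2 = cfg.time_jitter * rng.uniform(-1.0, 1.0, size=2)
    tau_w = tau + (a1 * np.sin(np.pi * tau) + 0.5 * a2 * np.sin(2 * np.pi * tau)) / np.pi
    tau_w = np.clip(tau_w, 0.0, 1.0)
    xy = spline(tau_w)

    scale = 1.0 + cfg.scale_jitter * rng.uniform(-1.0, 1.0)
    angle = np.deg2rad(cfg.rotation_jitter_deg) * rng.uniform(-1.0, 1.0)
    c, s = np.cos(angle), np.sin(angle)
    xy = scale * xy @ np.array([[c, s], [-s, c]])
    xy = xy - xy[0]
    return PenTrace(x=xy[:, 0], y=xy[:, 1], fs=cfg.fs_env)


def _kinematic_drives(trace: PenTrace) -> np.ndarray:
    """Backward-difference (vx, vy, ax, ay) in units/s and units/s^2."""
    coords = np.column_stack([trace.x, trace.y])
    vel = np.zeros_like(coords)
    vel[1:] = (coords[1:] - coords[:-1]) * trace.fs
    acc = np.zeros_like(coords)
    acc[2:] = (coords[2:] - 2 * coords[1:-1] + coords[:-2]) * trace.fs**2
    return np.column_stack([vel, acc])


def generate_emg(
    trace: PenTrace,
    muscles: MuscleModel,
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> RawEMG:
    """Activation-modulated white noise plus a baseline noise floor.

    The baseline std sigma_b is set so that the ratio of activation-driven
    to baseline power equals cfg.snr; if the trial carries no activation
    at all, a unit reference power defines the floor instead.
    """
    ratio = cfg.fs_raw / trace.fs
    if abs(ratio - round(ratio)) > 1e-9:
        raise InvalidParameterError(
            f"fs_raw={cfg.fs_raw} must be an integer multiple of the trace rate {trace.fs}"
        )
    ratio = int(round(ratio))
    act = muscles.activation(_kinematic_drives(trace))  # (C, n_env)
    act_up = np.repeat(act, ratio, axis=1)  # (C, n_raw)
    p_act = float(np.mean(act_up**2))
    sigma_b = np.sqrt((p_act if p_act > 0 else 1.0) / cfg.snr)
    eta = rng.standard_normal(act_up.shape)
    nu = rng.standard_normal(act_up.shape)
    raw = act_up * eta + sigma_b * nu
    return RawEMG(samples=raw, fs=cfg.fs_raw)


def generate_dataset(
    cfg: SimulationConfig, path=None
) -> list[TrialRecord]:
    """Generate the full multi-subject dataset described by ``cfg``.

    One muscle model is drawn per subject (fixed within subject); trials
    are generated symbol by symbol. With ``path`` given, the trial
    container and a manifest recording the configuration and seed are
    written there.
    """
    rng = np.random.default_rng(cfg.seed)
    records = []
    for si in range(cfg.n_subjects):
        subject_id = f"S{si + 1}"
        muscles = default_muscle_model(
            rng=rng, perturbation=cfg.subject_variability
        )
        for symbol in cfg.symbols:
            for ti in range(cfg.n_trials_per_symbol):
                trace = generate_pen_trial(symbol, cfg, rng)
                raw = generate_emg(trace, muscles, cfg, rng)
                records.append(
                    TrialRecord(
                        trial_id=f"{subject_id}_d{symbol}_t{ti:03d}",
                        subject_id=subject_id,
                        symbol=symbol,
                        emg=raw.samples,
                        pen=np.vstack([trace.x, trace.y]),
                        fs_raw=cfg.fs_raw,
                        fs_env=cfg.fs_env,
                    )
                )
    if path is not None:
        write_trials(records, path, config=cfg.to_dict(), seed=cfg.seed)
    return records
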