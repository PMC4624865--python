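"""System identification: OLS estimation of the decoder's four matrices.

The state evolves as a first-order multivariate autoregression,
s_t = A s_{t-1} + v_t with process noise covariance Q, and the inverse
measurement model maps lagged EMG envelopes directly into state space,
s_t = H z_t + w_t with noise covariance R. Both A and H are estimated by
ordinary least squares on training trials; Q and R are the empirical
covariances of the corresponding residuals (maximum-likelihood
normalisation, symmetrised, with a tiny diagonal jitter so the filter
always sees positive semi-definite matrices).

Transition pairs (s_{t-1}, s_t) never straddle a trial boundary: trials
are independent writings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import FitDegenerateError, InvalidInputError, MissingDataError
from .features import (
    ObservationSequence,
    PenTrace,
    StateSequence,
    build_observation_sequence,
    build_state_sequence,
)
from .preprocess import RawEMG, decimate_envelope, extract_envelope

__all__ = [
    "KFModel",
    "fit_state_transition",
    "fit_measurement_map",
    "fit_model",
    "prepare_trial",
]

JITTER_SCALE = 1e-9


@dataclass(frozen=True)
class KFModel:
    """Fitted decoder: transition (A, Q), measurement (H, R), orders, settings."""

    A: np.ndarray  # (6K, 6K)
    Q: np.ndarray  # (6K, 6K)
    H: np.ndarray  # (6K, C*L)
    R: np.ndarray  # (6K, 6K)
    K: int
    L: int
    fc: float = 2.0
    filter_order: int = 2
    sqrt: bool = True
    design: str = "within-group"
    n_channels: int = 8

    @property
    def state_dim(self) -> int:
        return 6 * self.K

    @property
    def obs_dim(self) -> int:
        return self.n_channels * self.L

    def to_dict(self) -> dict:
        return {
            "A": self.A.tolist(),
            "Q": self.Q.tolist(),
            "H": self.H.tolist(),
            "R": self.R.tolist(),
            "K": self.K,
            "L": self.L,
            "fc": self.fc,
            "filter_order": self.filter_order,
            "sqrt": self.sqrt,
            "design": self.design,
            "n_channels": self.n_channels,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "KFModel":
        return cls(
            A=np.asarray(d["A"], float),
            Q=np.asarray(d["Q"], float),
            H=np.asarray(d["H"], float),
            R=np.asarray(d["R"], float),
            K=int(d["K"]),
            L=int(d["L"]),
            fc=float(d["fc"]),
            filter_order=int(d["filter_order"]),
            sqrt=bool(d["sqrt"]),
            design=str(d["design"]),
            n_channels=int(d["n_channels"]),
        )


def _residual_cov(resid: np.ndarray) -> np.ndarray:
    """ML covariance of residuals, symmetrised, plus relative diagonal jitter."""
    n = resid.shape[0]
    cov = resid.T @ resid / n
    cov = 0.5 * (cov + cov.T)
    cov += JITTER_SCALE * float(np.mean(np.diag(cov))) * np.eye(cov.shape[0])
    return cov


def _pooled_ols(X: np.ndarray, Y: np.ndarray, what: str, ridge: float = 0.0):
    n, p = X.shape
    if n <= p:
        raise FitDegenerateError(
            f"{what}: {n} samples cannot determine {p} regressor dimensions"
        )
    if ridge > 0:
        G = X.T @ X + ridge * np.eye(p)
        coef = np.linalg.solve(G, X.T @ Y)
        rank = p
    else:
        coef, _, rank, _ = np.linalg.lstsq(X, Y, rcond=None)
    if rank < p:
        raise FitDegenerateError(
            f"{what}: regressor matrix is rank deficient (rank {rank} < {p})"
        )
    resid = Y - X @ coef
    return coef.T, _residual_cov(resid)


def fit_state_transition(states: list[StateSequence], ridge: float = 0.0):
    """OLS fit of A in s_t = A s_{t-1} + v_t; Q from the residuals.

    Pairs are formed within each sequence only.
    """
    if not states:
        raise InvalidInputError("no state sequences supplied")
    X = np.concatenate([s.states[:-1] for s in states], axis=0)
    Y = np.concatenate([s.states[1:] for s in states], axis=0)
    return _pooled_ols(X, Y, "state transition fit", ridge=ridge)


def fit_measurement_map(
    states: list[StateSequence], obs: list[ObservationSequence], ridge: float = 0.0
):
    """OLS fit of H in s_t = H z_t + w_t; R from the residuals."""
    if not states or len(states) != len(obs):
        raise InvalidInputError(
            f"{len(states)} state sequences vs {len(obs)} observation sequences"
        )
    for i, (s, z) in enumerate(zip(states, obs)):
        if len(s) != len(z):
            raise InvalidInputError(
                f"sequence {i}: {len(s)} states vs {len(z)} observations"
            )
    X = np.concatenate([z.observations for z in obs], axis=0)
    Y = np.concatenate([s.states for s in states], axis=0)
    return _pooled_ols(X, Y, "measurement map fit", ridge=ridge)


def prepare_trial(
    trial,
    K: int,
    L: int,
    fc: float = 2.0,
    filter_order: int = 2,
    sqrt: bool = True,
    center: bool = True,
):
    """Turn one trial record into aligned (StateSequence, ObservationSequence).

    Uses the trial's cached envelope when present, otherwise extracts one
    from the raw EMG and decimates it to the pen rate. The pen trace is
    shifted so its first sample is (0, 0), matching the decoder's zero
    start state.
    """
    if trial.envelope is not None:
        env_samples = trial.envelope
    else:
        env = extract_envelope(
            RawEMG(trial.emg, trial.fs_raw), fc=fc, order=filter_order, sqrt=sqrt
        )
        env_samples = decimate_envelope(env, trial.fs_env).samples
    if env_samples.shape[1] != trial.pen.shape[1]:
        raise InvalidInputError(
            f"trial {trial.trial_id}: envelope length {env_samples.shape[1]} "
            f"!= pen length {trial.pen.shape[1]}"
        )
    x, y = trial.pen
    if center:
        x = x - x[0]
        y = y - y[0]
    states = build_state_sequence(PenTrace(x, y, trial.fs_env), K)
    obs = build_observation_sequence(env_samples, L)
    return states, obs


def _fit_group(prepared, K, L, fc, filter_order, sqrt, design, n_channels, ridge):
    states = [s for s, _ in prepared]
    obs = [z for _, z in prepared]
    A, Q = fit_state_transition(states, ridge=ridge)
    H, R = fit_measurement_map(states, obs, ridge=ridge)
    return KFModel(
        A=A, Q=Q, H=H, R=R, K=K, L=L, fc=fc, filter_order=filter_order,
        sqrt=sqrt, design=design, n_channels=n_channels,
    )


def fit_model(
    trials,
    K: int = 1,
    L: int = 2,
    design: str = "within-group",
    fc: float = 2.0,
    filter_order: int = 2,
    sqrt: bool = True,
    symbols=None,
    ridge: float = 0.0,
):
    """Fit decoder parameters on training trials.

    ``design="within-group"`` pools all symbols into a single model;
    ``design="per-symbol"`` fits one model per symbol and returns a dict
    mapping symbol -> KFModel. ``symbols`` fixes the expected symbol set
    for the per-symbol design (default: the symbols present in ``trials``);
    an expected symbol with fewer than 2 trials raises MissingDataError.
    """
    trials = list(trials)
    if design not in ("within-group", "per-symbol"):
        raise InvalidInputError(f"unknown design {design!r}")
    if not trials:
        raise MissingDataError("no training trials")
    n_channels = (
        trials[0].envelope.shape[0]
        if trials[0].envelope is not None
        else trials[0].emg.shape[0]
    )

    def prep(ts):
        return [
            prepare_trial(t, K=K, L=L, fc=fc, filter_order=filter_order, sqrt=sqrt)
            for t in ts
        ]

    if design == "within-group":
        if len(trials) < 2:
            raise MissingDataError("within-group design needs at least 2 trials")
        return _fit_group(
            prep(trials), K, L, fc, filter_order, sqrt, design, n_channels, ridge
        )

    by_symbol: dict[int, list] = {}
    for t in trials:
        by_symbol.setdefault(int(t.symbol), []).append(t)
    expected = sorted(by_symbol) if symbols is None else sorted(int(s) for s in symbols)
    models = {}
    for sym in expected:
        group = by_symbol.get(sym, [])
        if len(group) < 2:
            raise MissingDataError(
                f"symbol {sym}: {len(group)} training trials (need >= 2)"
            )
        models[sym] = _fit_group(
            prep(group), K, L, fc, filter_order, sqrt, design, n_channels, ridge
        )
    return models
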