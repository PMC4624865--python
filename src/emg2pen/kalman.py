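"""Gaussian-fusion Kalman filter core and the causal Wiener baseline.

The filter fuses two Gaussian beliefs about the state at each step: the
endogenous prediction from the autoregressive pen-dynamics model, and the
exogenous estimate H z_t obtained by mapping lagged EMG envelopes into
state space (the "inverse" measurement form: the noise lives on the state
side, so the gain K_t = P(P + R)^{-1} is a square state-dimension matrix
and no measurement-side projection appears in the update).

All covariance updates are symmetrised and every inverse is replaced by a
linear solve; this keeps the recursion stable over thousands of steps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError, NumericalDegeneracyError
from .features import ObservationSequence
from .fit import KFModel

__all__ = [
    "GaussianBelief",
    "FilterTrace",
    "fuse_gaussians",
    "kalman_gain",
    "kf_predict",
    "kf_update",
    "kf_decode",
    "wiener_decode",
]

_SYM_TOL = 1e-10


def _sym(M: np.ndarray) -> np.ndarray:
    return 0.5 * (M + M.T)


@dataclass(frozen=True)
class GaussianBelief:
    """A Gaussian state belief N(mean, cov)."""

    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self) -> None:
        mean = np.atleast_1d(np.asarray(self.mean, dtype=float))
        cov = np.atleast_2d(np.asarray(self.cov, dtype=float))
        if cov.shape != (mean.shape[0], mean.shape[0]):
            raise InvalidInputError(
                f"covariance shape {cov.shape} does not match mean dim {mean.shape[0]}"
            )
        scale = max(1.0, float(np.max(np.abs(cov))))
        if np.max(np.abs(cov - cov.T)) > _SYM_TOL * scale:
            raise InvalidInputError("covariance is not symmetric")
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "cov", _sym(cov))

    @property
    def dim(self) -> int:
        return self.mean.shape[0]


@dataclass(frozen=True)
class FilterTrace:
    """Per-sample filter output; the first two mean entries are decoded (x, y)."""

    means: np.ndarray  # (n, d)
    covs: np.ndarray | None = None  # (n, d, d) posterior covariances
    gains: np.ndarray | None = None  # (n, d, d)
    prior_covs: np.ndarray | None = None  # (n, d, d)
    innovations: np.ndarray | None = None  # (n, d) Hz_t - prior mean

    @property
    def xy(self) -> np.ndarray:
        """Decoded pen coordinates, shape (n, 2)."""
        return self.means[:, :2]


def kalman_gain(P_prior: np.ndarray, R: np.ndarray) -> np.ndarray:
    """K_t = P(P + R)^{-1}, computed via a linear solve (no explicit inverse)."""
    P_prior = np.atleast_2d(np.asarray(P_prior, float))
    R = np.atleast_2d(np.asarray(R, float))
    if P_prior.shape != R.shape:
        raise InvalidInputError(
            f"P {P_prior.shape} and R {R.shape} dimensions differ"
        )
    S = P_prior + R
    try:
        # solve S^T X^T = P^T  =>  X = P S^{-1}
        gain = np.linalg.solve(S.T, P_prior.T).T
    except np.linalg.LinAlgError as exc:
        raise NumericalDegeneracyError(f"singular P + R in gain computation: {exc}")
    return gain


def fuse_gaussians(b1: GaussianBelief, b2: GaussianBelief) -> GaussianBelief:
    """Product of two Gaussian densities, in the gain form.

    Equivalent to the information form
    cov = (S1^{-1} + S2^{-1})^{-1}, mean = cov (S1^{-1} m1 + S2^{-1} m2),
    but computed as K = S1 (S1 + S2)^{-1}, cov = S1 - K S1,
    mean = m1 + K (m2 - m1), which needs a single solve and tolerates one
    singular input.
    """
    if b1.dim != b2.dim:
        raise InvalidInputError(f"dimension mismatch: {b1.dim} vs {b2.dim}")
    gain = kalman_gain(b1.cov, b2.cov)
    cov = _sym(b1.cov - gain @ b1.cov)
    mean = b1.mean + gain @ (b2.mean - b1.mean)
    return GaussianBelief(mean=mean, cov=cov)


def kf_predict(belief: GaussianBelief, A: np.ndarray, Q: np.ndarray) -> GaussianBelief:
    """Endogenous step: mean -> A mean, cov -> A cov A^T + Q."""
    A = np.atleast_2d(np.asarray(A, float))
    Q = np.atleast_2d(np.asarray(Q, float))
    return GaussianBelief(
        mean=A @ belief.mean, cov=_sym(A @ belief.cov @ A.T + Q)
    )


def kf_update(
    prior: GaussianBelief, z_t: np.ndarray, H: np.ndarray, R: np.ndarray
) -> GaussianBelief:
    """Fuse the prior with the measurement-derived belief (H z_t, R)."""
    H = np.atleast_2d(np.asarray(H, float))
    s_z = H @ np.atleast_1d(np.asarray(z_t, float))
    gain = kalman_gain(prior.cov, np.atleast_2d(np.asarray(R, float)))
    mean = prior.mean + gain @ (s_z - prior.mean)
    cov = _sym(prior.cov - gain @ prior.cov)
    return GaussianBelief(mean=mean, cov=cov)


def kf_decode(
    model: KFModel,
    obs: ObservationSequence,
    s0: np.ndarray | None = None,
    P0: np.ndarray | None = None,
    store_cov: bool = False,
    store_gain: bool = False,
    store_innovation: bool = False,
) -> FilterTrace:
    """Run the full predict / gain / update recursion over a trial.

    Starts from s0 = 0 (the trial's pen start) and P0 = Q unless given.
    Strictly causal: the output at sample t depends only on obs[0..t].
    """
    d = model.state_dim
    Z = obs.observations
    if Z.shape[1] != model.obs_dim:
        raise InvalidInputError(
            f"observation width {Z.shape[1]} != model obs dim {model.obs_dim}"
        )
    mean = np.zeros(d) if s0 is None else np.asarray(s0, float).copy()
    P = model.Q.copy() if P0 is None else np.atleast_2d(np.asarray(P0, float)).copy()
    A, Q, H, R = model.A, model.Q, model.H, model.R
    n = Z.shape[0]
    means = np.empty((n, d))
    covs = np.empty((n, d, d)) if store_cov else None
    gains = np.empty((n, d, d)) if store_gain else None
    prior_covs = np.empty((n, d, d)) if store_gain else None
    innovations = np.empty((n, d)) if store_innovation else None
    for t in range(n):
        try:
            mean = A @ mean
            P_prior = _sym(A @ P @ A.T + Q)
            S = P_prior + R
            gain = np.linalg.solve(S.T, P_prior.T).T
            s_z = H @ Z[t]
            innov = s_z - mean
            mean = mean + gain @ innov
            P = _sym(P_prior - gain @ P_prior)
        except np.linalg.LinAlgError as exc:
            raise NumericalDegeneracyError(
                f"filter degenerated at time index {t}: {exc}"
            )
        means[t] = mean
        if store_cov:
            covs[t] = P
        if store_gain:
            gains[t] = gain
            prior_covs[t] = P_prior
        if store_innovation:
            innovations[t] = innov
    return FilterTrace(
        means=means, covs=covs, gains=gains, prior_covs=prior_covs,
        innovations=innovations,
    )


def wiener_decode(model: KFModel, obs: ObservationSequence) -> FilterTrace:
    """Causal Wiener baseline: per-sample static regression s_t = H z_t.

    The measurement model alone — no dynamics, no covariance propagation.
    """
    Z = obs.observations
    if Z.shape[1] != model.obs_dim:
        raise InvalidInputError(
            f"observation width {Z.shape[1]} != model obs dim {model.obs_dim}"
        )
    return FilterTrace(means=Z @ model.H.T)
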