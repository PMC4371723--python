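"""Unscented Kalman filter/smoother for the combinatorial transcription model.

A deterministic Gaussian approximation used as the cheap screening
evaluator during structure search: sigma points of the current belief are
pushed through the full nonlinear transition (2p+1 scaled-unscented points),
while the observation update is exact because the observation model is the
identity plus diagonal Gaussian noise.  Replicated observations at one time
point are absorbed as sequential conditionally-exact scalar-vector updates,
which also yields the exact Gaussian prediction-error decomposition of the
log-likelihood.

No randomness anywhere: identical inputs give identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import CompiledModel, CTMParameters, NetworkStructure, ObservationSet

__all__ = ["GaussianBelief", "UKFConfig", "UKFRun", "UKFSmoothResult",
           "sigma_points", "ukf_filter", "ukf_smooth"]

_EIG_FLOOR = 1e-10


@dataclass
class GaussianBelief:
    mean: np.ndarray
    cov: np.ndarray


@dataclass
class UKFConfig:
    """Scaled unscented-transform spread parameters.

    lambda = alpha^2 (p + kappa) - p; kappa defaults to 3 - p so that
    p + kappa = 3, the classical fourth-moment-matching choice for
    Gaussian priors.
    """

    alpha: float = 0.9
    beta: float = 2.0
    kappa: float | None = None  # default 3 - p

    def weights(self, p: int) -> tuple[float, np.ndarray, np.ndarray]:
        kappa = self.kappa if self.kappa is not None else 3.0 - p
        lam = self.alpha ** 2 * (p + kappa) - p
        if p + lam <= 0:
            raise ValueError("sigma-point spread p + lambda must be positive")
        wm = np.full(2 * p + 1, 1.0 / (2.0 * (p + lam)))
        wc = wm.copy()
        wm[0] = lam / (p + lam)
        wc[0] = wm[0] + (1.0 - self.alpha ** 2 + self.beta)
        return lam, wm, wc


@dataclass
class UKFRun:
    predicted: list[GaussianBelief]   # per time t=1..T (prior belief at t)
    filtered: list[GaussianBelief]    # per time t=1..T (posterior at t)
    cross: list[np.ndarray | None]    # Cov(x_t, x_{t+1} | Y_t), index t-1
    loglik: float


@dataclass
class UKFSmoothResult:
    means: list[np.ndarray]           # E[x_t | Y_T]
    covs: list[np.ndarray]            # Var[x_t | Y_T]
    lag_one: list[np.ndarray]         # Cov(x_t, x_{t+1} | Y_T), index t-1


def _psd(V: np.ndarray) -> np.ndarray:
    V = 0.5 * (V + V.T)
    w, U = np.linalg.eigh(V)
    return (U * np.maximum(w, _EIG_FLOOR)) @ U.T


def _sqrt_psd(V: np.ndarray) -> np.ndarray:
    V = 0.5 * (V + V.T)
    w, U = np.linalg.eigh(V)
    return (U * np.sqrt(np.maximum(w, _EIG_FLOOR))) @ U.T


def sigma_points(mean: np.ndarray, cov: np.ndarray,
                 config: UKFConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """2p+1 scaled sigma points and their mean/cov weights."""
    p = mean.shape[0]
    lam, wm, wc = config.weights(p)
    S = _sqrt_psd((p + lam) * cov)
    pts = np.empty((2 * p + 1, p))
    pts[0] = mean
    pts[1:p + 1] = mean + S.T
    pts[p + 1:] = mean - S.T
    return pts, wm, wc


def ukf_filter(obs: ObservationSet, params: CTMParameters,
               structure: NetworkStructure,
               config: UKFConfig | None = None) -> UKFRun:
    """Unscented filter with exact identity-observation updates.

    The prior at t=1 is N(mu0, diag(sigma0)).  At each observed time every
    replicate is processed as one exact linear-Gaussian update, and its
    one-step prediction-error density accumulates into the log-likelihood.
    Unobserved times contribute prediction only.
    """
    config = config or UKFConfig()
    p, T = structure.p, obs.T
    model = CompiledModel(params, structure)
    observed = set(obs.observed_times)
    Q = np.diag(params.q_diag)
    r = params.r_diag

    mean = params.mu0.copy()
    cov = np.diag(params.sigma0_diag).astype(float)
    predicted: list[GaussianBelief] = []
    filtered: list[GaussianBelief] = []
    cross: list[np.ndarray | None] = []
    loglik = 0.0

    for t in range(1, T + 1):
        predicted.append(GaussianBelief(mean.copy(), cov.copy()))
        if t in observed:
            for y in obs.y[t - 1]:
                S = cov + np.diag(r)
                resid = y - mean
                Sinv = np.linalg.inv(S)
                sign, logdet = np.linalg.slogdet(S)
                loglik += -0.5 * (p * np.log(2.0 * np.pi) + logdet
                                  + resid @ Sinv @ resid)
                K = cov @ Sinv
                mean = mean + K @ resid
                cov = _psd(cov - K @ cov)
        filtered.append(GaussianBelief(mean.copy(), cov.copy()))
        if t < T:
            pts, wm, wc = sigma_points(mean, cov, config)
            prop = model.mean(pts, obs.d_at(t))
            new_mean = wm @ prop
            dp = prop - new_mean
            dx = pts - mean
            new_cov = _psd((dp * wc[:, None]).T @ dp + Q)
            C = (dx * wc[:, None]).T @ dp  # Cov(x_t, x_{t+1} | Y_t)
            cross.append(C)
            mean, cov = new_mean, new_cov
    cross.append(None)
    return UKFRun(predicted=predicted, filtered=filtered, cross=cross,
                  loglik=float(loglik))


def ukf_smooth(run: UKFRun, params: CTMParameters,
               structure: NetworkStructure) -> UKFSmoothResult:
    """Unscented Rauch-Tung-Striebel backward recursion.

    Uses the stored filtered beliefs and propagation cross-covariances:
    J_t = Cov(x_t, x_{t+1}|Y_t) V_{t+1|t}^{-1}, the standard smoother
    gain; also returns the lag-one smoothed covariances
    Cov(x_t, x_{t+1}|Y_T) = J_t V_{t+1|T} needed by the EM statistics.
    """
    T = len(run.filtered)
    p = structure.p
    means: list[np.ndarray] = [None] * T  # type: ignore[list-item]
    covs: list[np.ndarray] = [None] * T  # type: ignore[list-item]
    lag_one: list[np.ndarray] = [None] * (T - 1)  # type: ignore[list-item]
    means[T - 1] = run.filtered[T - 1].mean.copy()
    covs[T - 1] = run.filtered[T - 1].cov.copy()
    for t in range(T - 1, 0, -1):  # state time t, 0-based index t-1
        fb = run.filtered[t - 1]
        pred_next = run.predicted[t]
        C = run.cross[t - 1]
        ridge = 1e-12 * (np.trace(pred_next.cov) / p + 1.0)
        J = C @ np.linalg.inv(pred_next.cov + ridge * np.eye(p))
        means[t - 1] = fb.mean + J @ (means[t] - pred_next.mean)
        covs[t - 1] = _psd(fb.cov + J @ (covs[t] - pred_next.cov) @ J.T)
        lag_one[t - 1] = J @ covs[t]
    return UKFSmoothResult(means=means, covs=covs, lag_one=lag_one)
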