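"""Independent closed-form oracles for the test suite.

A textbook Kalman filter / Rauch-Tung-Striebel smoother for the linear
special case of the model (no pair terms), written directly from the
standard recursions and deliberately independent of the package's filter
implementations.  Replicated observations are processed as sequential
exact updates, matching the Gaussian likelihood factorization.
"""

from __future__ import annotations

import numpy as np


def kalman_filter(obs, A_full, u, Q, R, mu0, Sigma0, G=None):
    """Exact filter for x_t+1 = A x_t + G d_t + u + v, y = x + w.

    ``obs`` is a grnrestore ObservationSet used only as a data container.
    Returns (pred_means, pred_covs, filt_means, filt_covs, loglik).
    """
    p = len(mu0)
    T = obs.T
    observed = set(obs.observed_times)
    mean, cov = np.asarray(mu0, float).copy(), np.asarray(Sigma0, float).copy()
    pred_m, pred_P, filt_m, filt_P = [], [], [], []
    loglik = 0.0
    for t in range(1, T + 1):
        pred_m.append(mean.copy())
        pred_P.append(cov.copy())
        if t in observed:
            for y in obs.y[t - 1]:
                S = cov + R
                Sinv = np.linalg.inv(S)
                resid = y - mean
                sign, logdet = np.linalg.slogdet(S)
                loglik += -0.5 * (p * np.log(2 * np.pi) + logdet
                                  + resid @ Sinv @ resid)
                K = cov @ Sinv
                mean = mean + K @ resid
                cov = cov - K @ cov
                cov = 0.5 * (cov + cov.T)
        filt_m.append(mean.copy())
        filt_P.append(cov.copy())
        if t < T:
            d_t = obs.d_at(t)
            drive = G @ d_t if (G is not None and d_t is not None) else 0.0
            mean = A_full @ mean + u + drive
            cov = A_full @ cov @ A_full.T + Q
            cov = 0.5 * (cov + cov.T)
    return pred_m, pred_P, filt_m, filt_P, float(loglik)


def rts_smoother(pred_m, pred_P, filt_m, filt_P, A_full):
    """Standard RTS backward pass; returns smoothed means and covariances."""
    T = len(filt_m)
    sm = [None] * T
    sP = [None] * T
    sm[-1], sP[-1] = filt_m[-1].copy(), filt_P[-1].copy()
    for t in range(T - 2, -1, -1):
        Pp = pred_P[t + 1]
        J = filt_P[t] @ A_full.T @ np.linalg.inv(Pp)
        sm[t] = filt_m[t] + J @ (sm[t + 1] - pred_m[t + 1])
        sP[t] = filt_P[t] + J @ (sP[t + 1] - Pp) @ J.T
        sP[t] = 0.5 * (sP[t] + sP[t].T)
    return sm, sP


def full_linear_matrix(params):
    """Eq.-3-style linear matrix: off-diagonals a_ij, diagonal 1 + a_ii."""
    A = params.a.copy()
    p = A.shape[0]
    A[np.arange(p), np.arange(p)] = 1.0 + np.diag(params.a)
    return A


def kalman_for(params, obs):
    """Convenience wrapper running the oracle on a linear parameter set."""
    A = full_linear_matrix(params)
    G = params.g if params.g.size else None
    return kalman_filter(obs, A, params.u, np.diag(params.q_diag),
                         np.diag(params.r_diag), params.mu0,
                         np.diag(params.sigma0_diag), G=G)
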