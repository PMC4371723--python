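"""EM parameter estimation for a fixed network structure, plus BIC.

The complete-data log-likelihood of the state-space model is quadratic in
the regression parameters (a_i, b_i, g_i, u_i) of every gene, so the
M-step reduces to per-gene normal equations over the augmented regressor

    phi_{t-1} = (x_{t-1}; x_j x_k for active pairs; d_{t-1}; 1)

restricted to each gene's active sets.  The E-step supplies the smoothed
expectations E[x_t phi_{t-1}'] and E[phi_{t-1} phi_{t-1}'] from one of two
engines:

* ``ukf`` — deterministic Gaussian smoothing; expectations of products of
  up to four jointly Gaussian coordinates are evaluated in closed form
  (Isserlis' theorem with non-zero means).
* ``hmenpf`` — higher-moment ensemble smoothing; expectations are sample
  averages over smoothed particles, so the third/fourth moments retained
  by the filter enter the statistics directly.

Noise variances stay diagonal; sigma0 is held fixed (the estimated
parameter set is {A, B, G, u, Q, R, mu0}).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import hmenpf, ukf
from .model import CTMParameters, NetworkStructure, ObservationSet

__all__ = ["RegressorBasis", "SufficientStats", "EMTrace",
           "e_step", "m_step", "fit_em", "bic", "default_init"]


class RegressorBasis:
    """Global augmented-regressor layout shared by all genes.

    Columns: the p states, the union of all active pairs (canonical j<k,
    sorted), the M inputs, and the intercept.  Per-gene fits restrict to
    the gene's own active columns; the state column of the gene itself is
    always active (its coefficient is 1 + a_ii).
    """

    def __init__(self, structure: NetworkStructure):
        self.p = structure.p
        self.M = structure.M
        self.pairs = sorted({pair for i in range(structure.p)
                             for pair in structure.pair_sets[i]})
        self.pair_col = {pair: structure.p + k for k, pair in enumerate(self.pairs)}
        self.drug_col0 = structure.p + len(self.pairs)
        self.const_col = self.drug_col0 + structure.M
        self.ncols = self.const_col + 1
        # stochastic coordinate tuple per column (indices into x_{t-1})
        self.coords: list[tuple[int, ...]] = (
            [(j,) for j in range(structure.p)]
            + [tuple(pair) for pair in self.pairs]
            + [() for _ in range(structure.M)]
            + [()]
        )

    def active_columns(self, structure: NetworkStructure, i: int) -> list[int]:
        cols = [i] + sorted(structure.linear_sets[i])
        cols += [self.pair_col[pair] for pair in sorted(structure.pair_sets[i])]
        cols += [self.drug_col0 + m for m in sorted(structure.drug_sets[i])]
        cols.append(self.const_col)
        return cols

    def phi_matrix(self, X: np.ndarray, d: np.ndarray | None) -> np.ndarray:
        """Evaluate all regressor columns for a batch of states X (N, p)."""
        N = X.shape[0]
        phi = np.empty((N, self.ncols))
        phi[:, :self.p] = X
        for pair, col in self.pair_col.items():
            phi[:, col] = X[:, pair[0]] * X[:, pair[1]]
        if self.M:
            phi[:, self.drug_col0:self.drug_col0 + self.M] = (
                d if d is not None else 0.0)
        phi[:, self.const_col] = 1.0
        return phi

    def det_coef(self, d: np.ndarray | None) -> np.ndarray:
        """Deterministic multiplier per column at one transition."""
        c = np.ones(self.ncols)
        if self.M:
            c[self.drug_col0:self.drug_col0 + self.M] = (
                d if d is not None else 0.0)
        return c


@dataclass
class SufficientStats:
    """Smoothed-expectation sums accumulated across series and transitions."""

    basis: RegressorBasis
    s_xphi: np.ndarray       # (p, ncols): sum_t E[x_t phi_{t-1}']
    s_phiphi: np.ndarray     # (ncols, ncols): sum_t E[phi phi']
    s_xx_diag: np.ndarray    # (p,): sum_t E[x_{i,t}^2]
    obs_resid: np.ndarray    # (p,): sum over obs reps of E[(y - x)^2]
    n_trans: int = 0
    n_obs_reps: int = 0      # replicate-observations (same for every gene)
    x1_mean: np.ndarray | None = None  # sum over series of E[x_1 | Y_T]
    n_series: int = 0

    @classmethod
    def empty(cls, basis: RegressorBasis, p: int) -> "SufficientStats":
        return cls(basis=basis,
                   s_xphi=np.zeros((p, basis.ncols)),
                   s_phiphi=np.zeros((basis.ncols, basis.ncols)),
                   s_xx_diag=np.zeros(p),
                   obs_resid=np.zeros(p),
                   x1_mean=np.zeros(p))


@dataclass
class EMTrace:
    logliks: list[float] = field(default_factory=list)
    converged: bool = False
    iterations: int = 0


# ---------------------------------------------------------------------------
# Gaussian product moments (Isserlis with non-zero means), vectorized over
# transitions and over batches of index tuples of equal length.
# ---------------------------------------------------------------------------

def _gaussian_product_moment(mw: np.ndarray, Sw: np.ndarray,
                             idx: np.ndarray) -> np.ndarray:
    """E[prod_k w_{idx[:, k]}] for jointly Gaussian w per transition.

    mw: (n_t, D) means; Sw: (n_t, D, D) covariances; idx: (K, L) index
    tuples with L in 0..4.  Returns (n_t, K).
    """
    n_t = mw.shape[0]
    K, L = idx.shape if idx.ndim == 2 else (idx.shape[0], 1)
    if L == 0:
        return np.ones((n_t, K))
    m = mw[:, idx]  # (n_t, K, L)
    if L == 1:
        return m[..., 0]

    def S(u: int, v: int) -> np.ndarray:
        return Sw[:, idx[:, u], idx[:, v]]

    if L == 2:
        return S(0, 1) + m[..., 0] * m[..., 1]
    if L == 3:
        return (m[..., 0] * m[..., 1] * m[..., 2]
                + m[..., 0] * S(1, 2) + m[..., 1] * S(0, 2)
                + m[..., 2] * S(0, 1))
    if L == 4:
        mm = m
        return (
            mm[..., 0] * mm[..., 1] * mm[..., 2] * mm[..., 3]
            + S(0, 1) * mm[..., 2] * mm[..., 3]
            + S(0, 2) * mm[..., 1] * mm[..., 3]
            + S(0, 3) * mm[..., 1] * mm[..., 2]
            + S(1, 2) * mm[..., 0] * mm[..., 3]
            + S(1, 3) * mm[..., 0] * mm[..., 2]
            + S(2, 3) * mm[..., 0] * mm[..., 1]
            + S(0, 1) * S(2, 3) + S(0, 2) * S(1, 3) + S(0, 3) * S(1, 2)
        )
    raise ValueError(f"unsupported moment order {L}")


def _accumulate_gaussian(stats: SufficientStats, mw: np.ndarray,
                         Sw: np.ndarray, coef: np.ndarray, p: int) -> None:
    """Add Gaussian-engine expectations for one series' transitions.

    mw/Sw describe the joint smoothed density of (x_{t-1}, x_t) per
    transition (dimension 2p); coef holds the deterministic column values.
    """
    basis = stats.basis
    coords = basis.coords
    ncols = basis.ncols
    # --- E[phi phi'] upper triangle, grouped by tuple length
    groups: dict[int, list[tuple[int, int, tuple[int, ...]]]] = {}
    for a in range(ncols):
        for b in range(a, ncols):
            tup = coords[a] + coords[b]
            groups.setdefault(len(tup), []).append((a, b, tup))
    phiphi = np.zeros((mw.shape[0], ncols, ncols))
    for L, entries in groups.items():
        idx = np.array([e[2] for e in entries], dtype=int).reshape(len(entries), L)
        vals = _gaussian_product_moment(mw, Sw, idx)
        aa = np.array([e[0] for e in entries])
        bb = np.array([e[1] for e in entries])
        vals = vals * coef[:, aa] * coef[:, bb]
        phiphi[:, aa, bb] = vals
        phiphi[:, bb, aa] = vals
    stats.s_phiphi += phiphi.sum(axis=0)
    # --- E[x_t phi'] (x_t lives at joint index p + i)
    xgroups: dict[int, list[tuple[int, int, tuple[int, ...]]]] = {}
    for i in range(p):
        for a in range(ncols):
            tup = (p + i,) + coords[a]
            xgroups.setdefault(len(tup), []).append((i, a, tup))
    xphi = np.zeros((mw.shape[0], p, ncols))
    for L, entries in xgroups.items():
        idx = np.array([e[2] for e in entries], dtype=int).reshape(len(entries), L)
        vals = _gaussian_product_moment(mw, Sw, idx)
        ii = np.array([e[0] for e in entries])
        aa = np.array([e[1] for e in entries])
        xphi[:, ii, aa] = vals * coef[:, aa]
    stats.s_xphi += xphi.sum(axis=0)
    # --- E[x_{i,t}^2]
    diag_idx = np.arange(p, 2 * p)
    stats.s_xx_diag += (Sw[:, diag_idx, diag_idx] + mw[:, diag_idx] ** 2).sum(axis=0)
    stats.n_trans += mw.shape[0]


def e_step(obs, params: CTMParameters, structure: NetworkStructure,
           engine: str = "ukf", N: int = 500,
           rng: np.random.Generator | int | None = None,
           basis: RegressorBasis | None = None,
           ) -> tuple[SufficientStats, float]:
    """Smoothed sufficient statistics and the loglik of the given params.

    ``obs`` is one :class:`ObservationSet` or a list (independent series;
    statistics and logliks add across series).
    """
    obs_list = obs if isinstance(obs, (list, tuple)) else [obs]
    basis = basis or RegressorBasis(structure)
    p = structure.p
    stats = SufficientStats.empty(basis, p)
    loglik = 0.0
    if engine == "hmenpf" and not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    for series in obs_list:
        if engine == "ukf":
            run = ukf.ukf_filter(series, params, structure)
            sm = ukf.ukf_smooth(run, params, structure)
            loglik += run.loglik
            _accumulate_ukf(stats, series, sm, p)
        elif engine == "hmenpf":
            run = hmenpf.filter_series(series, params, structure, N, rng)
            smoothed = hmenpf.smooth(run, params, structure)
            loglik += run.loglik
            _accumulate_ensemble(stats, series, smoothed, p)
        else:
            raise ValueError(f"unknown engine {engine!r}")
        stats.n_series += 1
    return stats, float(loglik)


def _accumulate_ukf(stats: SufficientStats, series: ObservationSet,
                    sm: ukf.UKFSmoothResult, p: int) -> None:
    T = len(sm.means)
    n_t = T - 1
    mw = np.empty((n_t, 2 * p))
    Sw = np.empty((n_t, 2 * p, 2 * p))
    coef = np.empty((n_t, stats.basis.ncols))
    for k, t in enumerate(range(2, T + 1)):
        mw[k, :p] = sm.means[t - 2]
        mw[k, p:] = sm.means[t - 1]
        Sw[k, :p, :p] = sm.covs[t - 2]
        Sw[k, p:, p:] = sm.covs[t - 1]
        L = sm.lag_one[t - 2]
        Sw[k, :p, p:] = L
        Sw[k, p:, :p] = L.T
        coef[k] = stats.basis.det_coef(series.d_at(t - 1))
    _accumulate_gaussian(stats, mw, Sw, coef, p)
    for t in series.observed_times:
        m, V = sm.means[t - 1], sm.covs[t - 1]
        for y in series.y[t - 1]:
            stats.obs_resid += (y - m) ** 2 + np.diag(V)
            stats.n_obs_reps += 1
    stats.x1_mean += sm.means[0]


def _accumulate_ensemble(stats: SufficientStats, series: ObservationSet,
                         smoothed: list[hmenpf.Ensemble], p: int) -> None:
    basis = stats.basis
    T = len(smoothed)
    for t in range(2, T + 1):
        phi = basis.phi_matrix(smoothed[t - 2].particles, series.d_at(t - 1))
        X = smoothed[t - 1].particles
        N = X.shape[0]
        stats.s_phiphi += phi.T @ phi / N
        stats.s_xphi += X.T @ phi / N
        stats.s_xx_diag += np.mean(X ** 2, axis=0)
        stats.n_trans += 1
    for t in series.observed_times:
        X = smoothed[t - 1].particles
        for y in series.y[t - 1]:
            stats.obs_resid += np.mean((y - X) ** 2, axis=0)
            stats.n_obs_reps += 1
    stats.x1_mean += smoothed[0].particles.mean(axis=0)


def m_step(stats: SufficientStats, structure: NetworkStructure,
           current: CTMParameters,
           var_floor: float = 1e-8) -> CTMParameters:
    """Maximize the expected complete-data log-likelihood.

    Per gene the regression coefficients solve the normal equations on the
    active columns (ridge-regularized on numerical failure); q and r are
    mean squared smoothed residuals; mu0 is the smoothed initial mean
    averaged over series; sigma0 is held fixed; inactive entries stay
    exactly zero.
    """
    p = structure.p
    basis = stats.basis
    new = current.copy()
    new.a = np.zeros_like(current.a)
    new.b = {}
    new.g = np.zeros_like(current.g)
    for i in range(p):
        cols = basis.active_columns(structure, i)
        A = stats.s_phiphi[np.ix_(cols, cols)]
        rhs = stats.s_xphi[i, cols]
        try:
            c = np.linalg.solve(A, rhs)
            if not np.all(np.isfinite(c)):
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            lam = 1e-6 * np.trace(A) / len(cols) + 1e-12
            c = np.linalg.solve(A + lam * np.eye(len(cols)), rhs)
        resid = (stats.s_xx_diag[i] - 2.0 * c @ rhs + c @ A @ c)
        new.q_diag[i] = max(resid / stats.n_trans, var_floor)
        for col, val in zip(cols, c):
            if col == i:
                new.a[i, i] = val - 1.0
            elif col < p:
                new.a[i, col] = val
            elif col < basis.drug_col0:
                new.b[(i, basis.pairs[col - p])] = float(val)
            elif col < basis.const_col:
                new.g[i, col - basis.drug_col0] = val
            else:
                new.u[i] = val
    new.r_diag = np.maximum(stats.obs_resid / stats.n_obs_reps, var_floor)
    new.mu0 = stats.x1_mean / max(stats.n_series, 1)
    return new


def default_init(obs, structure: NetworkStructure,
                 q: float | None = None, r: float | None = None,
                 ) -> CTMParameters:
    """Damped-diagonal starting point for EM.

    a_ii = -0.5, active off-diagonals 0, u = per-gene mean level times the
    implied damping (so the stationary level matches the data mean), noise
    variances from sample-variance heuristics unless given.
    """
    obs_list = obs if isinstance(obs, (list, tuple)) else [obs]
    p = structure.p
    ys = np.concatenate([series.y[t - 1]
                         for series in obs_list for t in series.observed_times])
    mean_level = ys.mean(axis=0)
    var_level = ys.var(axis=0)
    params = CTMParameters.zeros(structure)
    params.a[np.arange(p), np.arange(p)] = -0.5
    params.u = 0.5 * mean_level
    params.q_diag = np.maximum(0.25 * var_level, 1e-4)
    params.r_diag = np.maximum(0.25 * var_level, 1e-4)
    if q is not None:
        params.q_diag = np.full(p, q)
    if r is not None:
        params.r_diag = np.full(p, r)
    params.mu0 = obs_list[0].y[obs_list[0].observed_times[0] - 1].mean(axis=0)
    params.sigma0_diag = np.ones(p)
    return params


def fit_em(obs, structure: NetworkStructure,
           init: CTMParameters | None = None,
           engine: str = "ukf", N: int = 500,
           max_iter: int = 50, tol: float = 1e-3,
           rng: np.random.Generator | int | None = None,
           ) -> tuple[CTMParameters, EMTrace]:
    """Alternate E- and M-steps until the loglik change drops below tol.

    Returns the iterate whose E-step log-likelihood was best (for the
    ensemble engine the trace is monotone only up to Monte-Carlo noise).
    """
    obs_list = obs if isinstance(obs, (list, tuple)) else [obs]
    params = (init or default_init(obs_list, structure)).copy()
    basis = RegressorBasis(structure)
    if engine == "hmenpf":
        seed_seq = (rng if isinstance(rng, np.random.SeedSequence)
                    else np.random.SeedSequence(
                        rng if isinstance(rng, int) else 0))
        child_seeds = seed_seq.spawn(max_iter)
    trace = EMTrace()
    best_ll = -np.inf
    best_params = params.copy()
    prev_ll = None
    for it in range(max_iter):
        it_rng = (np.random.default_rng(child_seeds[it])
                  if engine == "hmenpf" else None)
        stats, ll = e_step(obs_list, params, structure, engine=engine, N=N,
                           rng=it_rng, basis=basis)
        if not np.isfinite(ll):
            raise RuntimeError(
                f"non-finite log-likelihood at EM iteration {it}; trace: "
                f"{trace.logliks}")
        trace.logliks.append(ll)
        if ll > best_ll:
            best_ll, best_params = ll, params.copy()
        if prev_ll is not None and abs(ll - prev_ll) < tol:
            trace.converged = True
            break
        prev_ll = ll
        params = m_step(stats, structure, params)
        trace.iterations = it + 1  # completed E+M cycles
    return best_params, trace


def bic(loglik: float, structure: NetworkStructure, n_obs_values: int) -> float:
    """Bayesian information criterion -2 loglik + k log(n).

    k counts the free coefficients of the structure (diagonal a, active
    linear/pair/drug entries, intercepts, diagonal noise variances and the
    initial mean), so comparisons between structures differ only through
    the active-set sizes.
    """
    k = structure.n_structural_params()
    return -2.0 * loglik + k * np.log(n_obs_values)
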