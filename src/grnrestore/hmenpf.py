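"""Higher-moment ensemble particle filter (HMEnPF) and smoother.

The filter represents each conditional state density by an ensemble of N
particles.  At every observed time three sub-steps run:

1. *Particle-filter step* — importance weights from the Gaussian
   observation density (product over replicates), systematic resampling
   back to exactly N particles, and a moment summary (mean, covariance,
   and elementwise third/fourth standardized central moments of the
   whitened resampled ensemble).
2. *Ensemble-Kalman-filter step* — a stochastic EnKF update of the
   predicted particles with a sample Kalman gain, plus its own summary.
3. *Merging step* — the EnKF ensemble is whitened, mapped back to
   (approximately) standard normal by the inverse four-moment transform
   at the EnKF targets, re-targeted at the particle-filter skewness and
   kurtosis, and re-colored with the particle-filter mean and covariance.
   The merged ensemble therefore carries the particle filter's first four
   elementwise moments while preserving the EnKF ensemble's particle
   pairing, which the smoother and EM statistics rely on.

The particle count is never reduced, and particle pairing is preserved
through every sub-step, so particle n at time t descends from particle n
at time t-1; the smoother exploits this to form cross-time covariances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .model import CompiledModel, CTMParameters, NetworkStructure, ObservationSet
from .moments import s_inv, s_transform

__all__ = [
    "Ensemble",
    "MomentSummary",
    "FilterRun",
    "predict",
    "pf_update",
    "enkf_update",
    "merge",
    "filter_series",
    "smooth",
    "dump_moment_summaries",
    "DegenerateWeightsError",
]

_EIG_FLOOR = 1e-10


class DegenerateWeightsError(RuntimeError):
    """All particle weights underflowed even in the log domain."""


@dataclass
class Ensemble:
    """N particles of the p-dimensional hidden state at one time index."""

    particles: np.ndarray  # (N, p)
    time_index: int
    conditioning: str  # "predicted" | "filtered" | "smoothed"

    @property
    def N(self) -> int:
        return self.particles.shape[0]

    def mean(self) -> np.ndarray:
        return self.particles.mean(axis=0)

    def cov(self) -> np.ndarray:
        return np.cov(self.particles, rowvar=False, ddof=0).reshape(
            self.particles.shape[1], self.particles.shape[1])


@dataclass
class MomentSummary:
    """First four elementwise moments of an ensemble.

    ``m3`` and ``m4`` are moments of the whitened coordinates
    z = V^{-1/2} (x - mu), i.e. skewness and kurtosis after joint
    standardization.
    """

    mean: np.ndarray
    cov: np.ndarray
    m3: np.ndarray
    m4: np.ndarray


@dataclass
class FilterRun:
    """Stored output of one filtering pass over a single series."""

    ensembles: list[Ensemble]  # state ensemble per time t=1..T (post-update)
    predicted: list[Ensemble | None]  # predicted ensemble per time (None at t=1)
    pf_summaries: dict[int, MomentSummary]
    enkf_summaries: dict[int, MomentSummary]
    loglik: float
    rng_seed: int | None = None
    per_time_loglik: dict[int, float] = field(default_factory=dict)


def _sym_sqrt(V: np.ndarray, inverse: bool = False) -> np.ndarray:
    """Symmetric (eigendecomposition) matrix square root with eigen floor."""
    V = 0.5 * (V + V.T)
    w, U = np.linalg.eigh(V)
    w = np.maximum(w, _EIG_FLOOR)
    pw = 1.0 / np.sqrt(w) if inverse else np.sqrt(w)
    return (U * pw) @ U.T


def summarize(particles: np.ndarray) -> MomentSummary:
    """Mean, covariance and whitened elementwise third/fourth moments."""
    mu = particles.mean(axis=0)
    centered = particles - mu
    V = centered.T @ centered / particles.shape[0]
    z = centered @ _sym_sqrt(V, inverse=True)
    return MomentSummary(mean=mu, cov=V,
                         m3=np.mean(z ** 3, axis=0),
                         m4=np.mean(z ** 4, axis=0))


def predict(ensemble: Ensemble, params: CTMParameters,
            structure: NetworkStructure, d_t: np.ndarray | None,
            rng: np.random.Generator,
            model: CompiledModel | None = None) -> Ensemble:
    """Propagate every particle through the transition plus system noise."""
    model = model or CompiledModel(params, structure)
    prop = model.mean(ensemble.particles, d_t)
    prop = prop + np.sqrt(params.q_diag) * rng.standard_normal(prop.shape)
    if not np.all(np.isfinite(prop)) or np.any(np.abs(prop) > 1e12):
        raise RuntimeError("unstable model: particle propagation diverged")
    return Ensemble(particles=prop, time_index=ensemble.time_index + 1,
                    conditioning="predicted")


def _log_obs_density(particles: np.ndarray, y_reps: np.ndarray,
                     r_diag: np.ndarray) -> np.ndarray:
    """Log p(all replicates | particle) under N(x, diag(r)), per particle."""
    logw = np.zeros(particles.shape[0])
    const = -0.5 * np.sum(np.log(2.0 * np.pi * r_diag))
    for y in y_reps:
        resid = y - particles
        logw += const - 0.5 * np.sum(resid ** 2 / r_diag, axis=1)
    return logw


def _systematic_resample(logw: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    lw = logw - np.max(logw)
    w = np.exp(lw)
    tot = w.sum()
    if not np.isfinite(tot) or tot <= 0.0:
        raise DegenerateWeightsError("particle weights degenerate after normalization")
    w /= tot
    N = len(w)
    positions = (rng.random() + np.arange(N)) / N
    return np.searchsorted(np.cumsum(w), positions)


def pf_update(ensemble: Ensemble, y_reps: np.ndarray, r_diag: np.ndarray,
              rng: np.random.Generator) -> tuple[Ensemble, MomentSummary]:
    """Particle-filter sub-step: weight, systematically resample, summarize."""
    logw = _log_obs_density(ensemble.particles, np.atleast_2d(y_reps), r_diag)
    idx = _systematic_resample(logw, rng)
    resampled = ensemble.particles[idx]
    return (
        Ensemble(particles=resampled, time_index=ensemble.time_index,
                 conditioning="filtered"),
        summarize(resampled),
    )


def enkf_update(ensemble: Ensemble, y_reps: np.ndarray, r_diag: np.ndarray,
                rng: np.random.Generator) -> tuple[Ensemble, MomentSummary]:
    """Stochastic EnKF sub-step.

    Replicated observations enter as their mean with the observation
    variance scaled by 1/J; the gain uses the predicted-ensemble sample
    covariance and the sample covariance of freshly drawn observation-noise
    particles, so the update is exactly consistent with the ensemble
    approximation.
    """
    y_reps = np.atleast_2d(y_reps)
    J = y_reps.shape[0]
    y_bar = y_reps.mean(axis=0)
    r_eff = np.asarray(r_diag, dtype=float) / J
    N, p = ensemble.particles.shape
    w = np.sqrt(r_eff) * rng.standard_normal((N, p))
    V = np.cov(ensemble.particles, rowvar=False, ddof=0).reshape(p, p)
    R_t = np.cov(w, rowvar=False, ddof=0).reshape(p, p)
    A = V + R_t
    try:
        K = V @ np.linalg.inv(A)
    except np.linalg.LinAlgError:
        ridge = 1e-8 * np.trace(A) / p + 1e-12
        K = V @ np.linalg.inv(A + ridge * np.eye(p))
    updated = ensemble.particles + (y_bar - ensemble.particles + w) @ K.T
    return (
        Ensemble(particles=updated, time_index=ensemble.time_index,
                 conditioning="filtered"),
        summarize(updated),
    )


def merge(pf_summary: MomentSummary, enkf_ensemble: Ensemble,
          enkf_summary: MomentSummary) -> Ensemble:
    """Merging sub-step: EnKF particle structure, particle-filter moments.

    Whitens the EnKF ensemble, removes its skewness/kurtosis through the
    inverse four-moment transform, re-targets the particle-filter m3/m4,
    then re-standardizes exactly and colors with the particle-filter mean
    and covariance, so the output's first two moments equal the
    particle-filter summary to numerical precision and its third/fourth
    whitened moments approach the particle-filter targets.  Particle
    ordering is inherited from the EnKF ensemble.
    """
    X = enkf_ensemble.particles
    z_tilde = (X - enkf_summary.mean) @ _sym_sqrt(enkf_summary.cov, inverse=True)
    z = s_inv(z_tilde, enkf_summary.m3, enkf_summary.m4)
    x_std = s_transform(z, pf_summary.m3, pf_summary.m4)
    # exact re-standardization keeps the first two moments at the PF summary
    mu = x_std.mean(axis=0)
    Vs = np.cov(x_std, rowvar=False, ddof=0).reshape(X.shape[1], X.shape[1])
    white = (x_std - mu) @ _sym_sqrt(Vs, inverse=True)
    out = white @ _sym_sqrt(pf_summary.cov) + pf_summary.mean
    return Ensemble(particles=out, time_index=enkf_ensemble.time_index,
                    conditioning="filtered")


def filter_series(obs: ObservationSet, params: CTMParameters,
                  structure: NetworkStructure, N: int,
                  rng_seed: int | np.random.Generator) -> FilterRun:
    """Run the full HMEnPF over one series.

    Alternates prediction with the three-sub-step filtering update at
    observed times (prediction only elsewhere).  The log-likelihood
    accumulates log of the ensemble-averaged observation density of the
    predicted particles at each observed time; at t=1 the "predicted"
    ensemble is the initial-state draw from N(mu0, diag(sigma0)).
    """
    if N < 2:
        raise ValueError("ensemble size N must be at least 2")
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    model = CompiledModel(params, structure)
    p, T = structure.p, obs.T
    observed = set(obs.observed_times)

    init = params.mu0 + np.sqrt(params.sigma0_diag) * rng.standard_normal((N, p))
    current = Ensemble(particles=init, time_index=1, conditioning="predicted")

    ensembles: list[Ensemble] = []
    predicted: list[Ensemble | None] = []
    pf_summaries: dict[int, MomentSummary] = {}
    enkf_summaries: dict[int, MomentSummary] = {}
    per_time_ll: dict[int, float] = {}
    loglik = 0.0

    for t in range(1, T + 1):
        if t > 1:
            current = predict(ensembles[-1], params, structure,
                              obs.d_at(t - 1), rng, model=model)
            predicted.append(current)
        else:
            predicted.append(None)
        if t in observed:
            y_reps = obs.y[t - 1]
            logw = _log_obs_density(current.particles, y_reps, params.r_diag)
            ll_t = float(logsumexp(logw) - np.log(N))
            loglik += ll_t
            per_time_ll[t] = ll_t
            pf_ens, pf_sum = pf_update(current, y_reps, params.r_diag, rng)
            enkf_ens, enkf_sum = enkf_update(current, y_reps, params.r_diag, rng)
            current = merge(pf_sum, enkf_ens, enkf_sum)
            pf_summaries[t] = pf_sum
            enkf_summaries[t] = enkf_sum
        ensembles.append(current)

    return FilterRun(ensembles=ensembles, predicted=predicted,
                     pf_summaries=pf_summaries, enkf_summaries=enkf_summaries,
                     loglik=loglik, per_time_loglik=per_time_ll)


def smooth(run: FilterRun, params: CTMParameters,
           structure: NetworkStructure) -> list[Ensemble]:
    """Fixed-interval ensemble smoother over a completed filter run.

    Backward pass of the ensemble Rauch-Tung-Striebel form: particle n at
    time t is shifted by J_t (x_{t+1|T}^(n) - x_{t+1|t}^(n)) with
    J_t = Cov(x_{t|t}, x_{t+1|t}) V_{t+1|t}^{-1}, computable because
    particle pairing survives every filtering sub-step.  At t = T the
    smoothed ensemble is the filtered one; on linear models the smoothed
    moments converge to the exact RTS smoother as N grows.
    """
    T = len(run.ensembles)
    p = structure.p
    smoothed: list[Ensemble] = [None] * T  # type: ignore[list-item]
    last = run.ensembles[-1]
    smoothed[T - 1] = Ensemble(particles=last.particles.copy(),
                               time_index=T, conditioning="smoothed")
    for t in range(T - 1, 0, -1):  # smoothed index t-1 (state time t)
        filt = run.ensembles[t - 1].particles
        pred_next = run.predicted[t].particles  # x_{t+1|t}, paired with filt
        mu_f = filt.mean(axis=0)
        mu_p = pred_next.mean(axis=0)
        C = (filt - mu_f).T @ (pred_next - mu_p) / filt.shape[0]
        Vp = np.cov(pred_next, rowvar=False, ddof=0).reshape(p, p)
        ridge = 1e-10 * (np.trace(Vp) / p + 1.0)
        J = C @ np.linalg.inv(Vp + ridge * np.eye(p))
        shift = (smoothed[t].particles - pred_next) @ J.T
        smoothed[t - 1] = Ensemble(particles=filt + shift, time_index=t,
                                   conditioning="smoothed")
    return smoothed


def dump_moment_summaries(run: FilterRun, path) -> None:
    """Write per-time particle-filter and EnKF moment summaries as TSV.

    Debugging aid: one row per observed time and gene with the mean,
    variance, whitened skewness and kurtosis from both sub-step
    summaries.
    """
    lines = ["time\tgene\tstep\tmean\tvar\tm3\tm4"]
    for t in sorted(run.pf_summaries):
        for label, summary in (("pf", run.pf_summaries[t]),
                               ("enkf", run.enkf_summaries[t])):
            for i in range(summary.mean.shape[0]):
                lines.append(
                    f"{t}\t{i + 1}\t{label}\t{summary.mean[i]:.6g}\t"
                    f"{summary.cov[i, i]:.6g}\t{summary.m3[i]:.6g}\t"
                    f"{summary.m4[i]:.6g}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
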