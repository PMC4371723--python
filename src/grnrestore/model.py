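"""Combinatorial transcription model: structures, parameters, simulation.

The model describes p genes whose abundances evolve by a first-order
difference equation with linear regulatory effects, pairwise (synergistic)
product effects between regulators, optional exogenous inputs such as a drug
concentration, and additive Gaussian system noise.  Observations are the
latent abundances plus Gaussian measurement noise.

Per gene i the noise-free one-step map is

    x_i' = (1 + a_ii) x_i + sum_{j in A_i} a_ij x_j
           + sum_{(j,k) in B_i} b_i,(j,k) x_j x_k
           + sum_{m in G_i} g_im d_m + u_i

where A_i, B_i, G_i are the active regulator / pair / input sets, the
self-coefficient a_ii is always free (it parameterizes degradation and is
never part of the searched edge set), and each unordered pair (j<k)
contributes once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np

__all__ = [
    "StructureError",
    "UnstableModelError",
    "NetworkStructure",
    "CTMParameters",
    "ObservationSet",
    "TrajectorySet",
    "CompiledModel",
    "transition_mean",
    "simulate",
    "sample_parameters",
    "make_benchmark",
    "undirected_to_directed",
]

#: hard guard against runaway trajectories during simulation
OVERFLOW_GUARD = 1.0e6


class StructureError(ValueError):
    """A network structure or parameter set violates a model invariant."""


class UnstableModelError(RuntimeError):
    """A simulated trajectory exceeded the overflow guard."""


@dataclass
class NetworkStructure:
    """Active regulator sets per gene.

    Gene indices are 0-based internally.  ``linear_sets[i]`` holds the
    regulators j with a linear coefficient a_ij (excluding i itself);
    ``pair_sets[i]`` holds canonical unordered pairs (j, k) with j < k, both
    members of ``linear_sets[i]``; ``drug_sets[i]`` holds exogenous input
    indices.  ``tf_mask[j]`` is False when gene j may not act as a regulator
    of any gene; ``locked_edges`` are directed (regulator, target) edges the
    structure search may never remove.
    """

    p: int
    M: int = 0
    linear_sets: list[set[int]] = field(default_factory=list)
    pair_sets: list[set[tuple[int, int]]] = field(default_factory=list)
    drug_sets: list[set[int]] = field(default_factory=list)
    tf_mask: np.ndarray | None = None
    locked_edges: set[tuple[int, int]] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.p <= 0:
            raise StructureError("gene count p must be positive")
        if self.M < 0:
            raise StructureError("input count M must be non-negative")
        if not self.linear_sets:
            self.linear_sets = [set() for _ in range(self.p)]
        if not self.pair_sets:
            self.pair_sets = [set() for _ in range(self.p)]
        if not self.drug_sets:
            self.drug_sets = [set() for _ in range(self.p)]
        if self.tf_mask is None:
            self.tf_mask = np.ones(self.p, dtype=bool)
        else:
            self.tf_mask = np.asarray(self.tf_mask, dtype=bool)
        self.validate()

    def validate(self) -> None:
        p = self.p
        if not (len(self.linear_sets) == len(self.pair_sets) == len(self.drug_sets) == p):
            raise StructureError("per-gene set lists must all have length p")
        for i in range(p):
            for j in self.linear_sets[i]:
                if not (0 <= j < p):
                    raise StructureError(f"regulator index {j} out of range")
                if j == i:
                    raise StructureError("self-regulation is the a_ii term, not an edge")
                if not self.tf_mask[j]:
                    raise StructureError(f"gene {j} is masked as non-regulator")
            for pair in self.pair_sets[i]:
                j, k = pair
                if j == k:
                    raise StructureError("self pair (j, j) is not allowed")
                if j > k:
                    raise StructureError("pairs must be canonical j < k")
                if j not in self.linear_sets[i] or k not in self.linear_sets[i]:
                    raise StructureError(
                        f"pair {pair} of gene {i} references inactive linear regulator"
                    )
            for m in self.drug_sets[i]:
                if not (0 <= m < self.M):
                    raise StructureError(f"input index {m} out of range")
        edges = self.edges()
        for e in self.locked_edges:
            if e not in edges:
                raise StructureError(f"locked edge {e} is not a declared edge")

    def edges(self) -> set[tuple[int, int]]:
        """Directed (regulator, target) edges implied by the linear sets."""
        return {(j, i) for i in range(self.p) for j in self.linear_sets[i]}

    def n_edges(self) -> int:
        return sum(len(s) for s in self.linear_sets)

    def n_structural_params(self) -> int:
        """Count of free coefficients attached to this structure.

        Diagonal a_ii, active linear/pair/drug coefficients, intercept u,
        system and observation noise variances, and the initial mean.
        """
        return (
            self.p
            + sum(len(s) for s in self.linear_sets)
            + sum(len(s) for s in self.pair_sets)
            + sum(len(s) for s in self.drug_sets)
            + self.p  # u
            + 2 * self.p  # q, r
            + self.p  # mu0
        )

    def copy(self) -> "NetworkStructure":
        return NetworkStructure(
            p=self.p,
            M=self.M,
            linear_sets=[set(s) for s in self.linear_sets],
            pair_sets=[set(s) for s in self.pair_sets],
            drug_sets=[set(s) for s in self.drug_sets],
            tf_mask=self.tf_mask.copy(),
            locked_edges=set(self.locked_edges),
        )


@dataclass
class CTMParameters:
    """Numerical parameters of the model for a given structure.

    ``a`` is the p x p linear-effect matrix whose diagonal holds the
    self-coefficients (entering the dynamics as 1 + a_ii); ``b`` maps
    (target, (j, k)) to the pair coefficient; ``g`` is p x M; ``u`` the
    intercept.  Noise covariances are diagonal, stored as vectors.
    """

    a: np.ndarray
    b: dict[tuple[int, tuple[int, int]], float]
    g: np.ndarray
    u: np.ndarray
    q_diag: np.ndarray
    r_diag: np.ndarray
    mu0: np.ndarray
    sigma0_diag: np.ndarray

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        self.u = np.asarray(self.u, dtype=float)
        self.q_diag = np.asarray(self.q_diag, dtype=float)
        self.r_diag = np.asarray(self.r_diag, dtype=float)
        self.mu0 = np.asarray(self.mu0, dtype=float)
        self.sigma0_diag = np.asarray(self.sigma0_diag, dtype=float)

    @property
    def p(self) -> int:
        return self.a.shape[0]

    def validate(self, structure: NetworkStructure) -> None:
        p = structure.p
        if self.a.shape != (p, p):
            raise StructureError("a must be p x p")
        if self.g.shape != (p, max(structure.M, 1)) and self.g.size != p * structure.M:
            if structure.M == 0 and self.g.size != 0:
                raise StructureError("g must be empty when M = 0")
        for i in range(p):
            for j in range(p):
                if i != j and self.a[i, j] != 0.0 and j not in structure.linear_sets[i]:
                    raise StructureError(f"a[{i},{j}] nonzero outside active set")
        for (i, pair), val in self.b.items():
            if val != 0.0 and pair not in structure.pair_sets[i]:
                raise StructureError(f"b[{i},{pair}] nonzero outside active pairs")
        # zero variances are permitted only as a degenerate noise-free
        # simulation mode; filtering requires strictly positive r
        for name, vec in (("q_diag", self.q_diag), ("r_diag", self.r_diag),
                          ("sigma0_diag", self.sigma0_diag)):
            if np.any(np.asarray(vec) < 0):
                raise StructureError(f"{name} must be non-negative")

    @classmethod
    def zeros(cls, structure: NetworkStructure,
              q: float = 0.01, r: float = 0.3,
              sigma0: float = 1.0) -> "CTMParameters":
        p, M = structure.p, structure.M
        return cls(
            a=np.zeros((p, p)),
            b={},
            g=np.zeros((p, M)),
            u=np.zeros(p),
            q_diag=np.full(p, q),
            r_diag=np.full(p, r),
            mu0=np.zeros(p),
            sigma0_diag=np.full(p, sigma0),
        )

    def copy(self) -> "CTMParameters":
        return CTMParameters(
            a=self.a.copy(), b=dict(self.b), g=self.g.copy(), u=self.u.copy(),
            q_diag=self.q_diag.copy(), r_diag=self.r_diag.copy(),
            mu0=self.mu0.copy(), sigma0_diag=self.sigma0_diag.copy(),
        )


@dataclass
class ObservationSet:
    """One time-course of noisy observations.

    ``y[t-1]`` is an (n_reps, p) array for observed time t (1-based) or None
    at unobserved times; ``observed_times`` lists the observed subset of
    {1..T}; ``d`` is an optional (T, M) matrix of exogenous input values.
    """

    y: list[np.ndarray | None]
    observed_times: list[int]
    d: np.ndarray | None = None
    series_id: str = "series"

    def __post_init__(self) -> None:
        T = len(self.y)
        for t in self.observed_times:
            if not (1 <= t <= T):
                raise StructureError(f"observed time {t} outside 1..{T}")
            if self.y[t - 1] is None or len(self.y[t - 1]) < 1:
                raise StructureError(f"observed time {t} has no replicate")
        for t, arr in enumerate(self.y, start=1):
            if arr is not None:
                self.y[t - 1] = np.atleast_2d(np.asarray(arr, dtype=float))
        if self.d is not None:
            self.d = np.atleast_2d(np.asarray(self.d, dtype=float))

    @property
    def T(self) -> int:
        return len(self.y)

    @property
    def p(self) -> int:
        return self.y[self.observed_times[0] - 1].shape[1]

    def n_obs_values(self) -> int:
        """Total scalar measurements (replicates x genes over observed times)."""
        return sum(self.y[t - 1].shape[0] * self.y[t - 1].shape[1]
                   for t in self.observed_times)

    def d_at(self, t: int) -> np.ndarray | None:
        """Input vector associated with time t (1-based), None when absent."""
        if self.d is None:
            return None
        return self.d[t - 1]

    @classmethod
    def from_matrix(cls, y: np.ndarray, d: np.ndarray | None = None,
                    series_id: str = "series") -> "ObservationSet":
        """Build a fully observed single-replicate set from a (T, p) matrix."""
        y = np.asarray(y, dtype=float)
        return cls(y=[y[t][None, :] for t in range(y.shape[0])],
                   observed_times=list(range(1, y.shape[0] + 1)),
                   d=d, series_id=series_id)


@dataclass
class TrajectorySet:
    """Latent trajectories, one (T, p) matrix per simulated series."""

    x: list[np.ndarray]
    rng_seed: int


class CompiledModel:
    """Dense/array form of (structure, params) for vectorized propagation."""

    def __init__(self, params: CTMParameters, structure: NetworkStructure):
        p, M = structure.p, structure.M
        self.p, self.M = p, M
        self.a_full = params.a * _linear_mask(structure)
        self.a_full[np.arange(p), np.arange(p)] = 1.0 + np.diag(params.a)
        pairs = sorted({(i, pair) for i in range(p) for pair in structure.pair_sets[i]})
        self.pair_j = np.array([jk[0] for _, jk in pairs], dtype=int)
        self.pair_k = np.array([jk[1] for _, jk in pairs], dtype=int)
        # map each pair term onto its target gene with its coefficient
        self.pair_map = np.zeros((p, len(pairs)))
        for col, (i, jk) in enumerate(pairs):
            self.pair_map[i, col] = params.b.get((i, jk), 0.0)
        self.g = params.g.reshape(p, M) if M else np.zeros((p, 0))
        self.u = params.u

    def mean(self, x: np.ndarray, d: np.ndarray | None = None) -> np.ndarray:
        """Noise-free one-step map; x is (p,) or (N, p)."""
        x = np.asarray(x, dtype=float)
        single = x.ndim == 1
        X = np.atleast_2d(x)
        if X.shape[1] != self.p:
            raise StructureError(f"state dimension {X.shape[1]} != p={self.p}")
        out = X @ self.a_full.T + self.u
        if self.pair_j.size:
            out += (X[:, self.pair_j] * X[:, self.pair_k]) @ self.pair_map.T
        if self.M:
            if d is None:
                raise StructureError("model has inputs but no d vector given")
            out += self.g @ np.asarray(d, dtype=float)
        return out[0] if single else out


def _linear_mask(structure: NetworkStructure) -> np.ndarray:
    mask = np.zeros((structure.p, structure.p))
    for i in range(structure.p):
        for j in structure.linear_sets[i]:
            mask[i, j] = 1.0
    return mask


def transition_mean(params: CTMParameters, structure: NetworkStructure,
                    x: np.ndarray, d: np.ndarray | None = None) -> np.ndarray:
    """Noise-free one-step transition mean for a single state vector."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise StructureError("state vector must be finite")
    if (d is None) != (structure.M == 0):
        raise StructureError("d must be given iff the structure has inputs")
    return CompiledModel(params, structure).mean(x, d)


def simulate(structure: NetworkStructure, params: CTMParameters,
             T: int, n_series: int, rng_seed: int,
             n_reps: int = 1,
             observed_times: list[int] | None = None,
             d: np.ndarray | None = None,
             ) -> tuple[TrajectorySet, list[ObservationSet]]:
    """Simulate latent trajectories and noisy observations.

    States run over t = 1..T with x_1 ~ N(mu0, diag(sigma0)); each later
    state is the transition mean of its predecessor plus system noise
    N(0, diag(q)); observations add N(0, diag(r)) independently per
    replicate.  Raises :class:`UnstableModelError` when any state exceeds
    the overflow guard instead of silently propagating non-finite values.
    """
    if T < 2:
        raise StructureError("T must be at least 2")
    params.validate(structure)
    model = CompiledModel(params, structure)
    rng = np.random.default_rng(rng_seed)
    obs_times = observed_times or list(range(1, T + 1))
    q_sd = np.sqrt(params.q_diag)
    r_sd = np.sqrt(params.r_diag)
    xs: list[np.ndarray] = []
    obs: list[ObservationSet] = []
    for s in range(n_series):
        x = np.empty((T, structure.p))
        x[0] = params.mu0 + np.sqrt(params.sigma0_diag) * rng.standard_normal(structure.p)
        for t in range(1, T):
            d_t = d[t - 1] if d is not None else None
            x[t] = model.mean(x[t - 1], d_t) + q_sd * rng.standard_normal(structure.p)
            if np.any(np.abs(x[t]) > OVERFLOW_GUARD) or not np.all(np.isfinite(x[t])):
                raise UnstableModelError(
                    f"trajectory diverged at series {s}, step {t + 1}"
                )
        y: list[np.ndarray | None] = [None] * T
        for t in obs_times:
            y[t - 1] = x[t - 1] + r_sd * rng.standard_normal((n_reps, structure.p))
        xs.append(x)
        obs.append(ObservationSet(y=y, observed_times=list(obs_times), d=d,
                                  series_id=f"series{s + 1}"))
    return TrajectorySet(x=xs, rng_seed=rng_seed), obs


def sample_parameters(structure: NetworkStructure, rng_seed: int,
                      stability_check: bool = True,
                      q_var: float = 0.01, r_var: float = 0.3,
                      mu0: np.ndarray | None = None,
                      sigma0: float = 1.0,
                      bound: float = 50.0,
                      stability_T: int = 30,
                      max_resamples: int = 500) -> CTMParameters:
    """Draw benchmark parameters with all active coefficients uniform in [-1, 1].

    The uniform draw applies to the entries of the full linear-effect
    matrix of the state-space form, including its diagonal — so the
    self-multiplier 1 + a_ii is uniform in [-1, 1] (i.e. a_ii in [-2, 0],
    a damped self-effect), and every active off-diagonal, pair, input and
    intercept coefficient is uniform in [-1, 1].

    With ``stability_check`` the draw is rejected (and redrawn) until a
    noise-free ``stability_T``-step trajectory from mu0 stays within
    ``bound`` in absolute value, screening out divergent dynamics.
    """
    rng = np.random.default_rng(rng_seed)
    p, M = structure.p, structure.M
    mu0 = np.zeros(p) if mu0 is None else np.asarray(mu0, dtype=float)
    for _ in range(max_resamples):
        a = np.zeros((p, p))
        a[np.arange(p), np.arange(p)] = rng.uniform(-1, 1, size=p) - 1.0
        for i in range(p):
            for j in structure.linear_sets[i]:
                a[i, j] = rng.uniform(-1, 1)
        b = {(i, pair): float(rng.uniform(-1, 1))
             for i in range(p) for pair in sorted(structure.pair_sets[i])}
        g = np.zeros((p, M))
        for i in range(p):
            for m in structure.drug_sets[i]:
                g[i, m] = rng.uniform(-1, 1)
        u = rng.uniform(-1, 1, size=p)
        params = CTMParameters(a=a, b=b, g=g, u=u,
                               q_diag=np.full(p, q_var),
                               r_diag=np.full(p, r_var),
                               mu0=mu0.copy(),
                               sigma0_diag=np.full(p, sigma0))
        if not stability_check:
            return params
        model = CompiledModel(params, structure)
        x = mu0.copy()
        d0 = np.zeros(M) if M else None
        stable = True
        for _ in range(stability_T):
            x = model.mean(x, d0)
            if np.any(np.abs(x) > bound) or not np.all(np.isfinite(x)):
                stable = False
                break
        if stable:
            return params
    raise UnstableModelError(
        f"no stable parameter draw within {max_resamples} resamples "
        f"(bound {bound}, horizon {stability_T}); sparsify the structure "
        "or relax the bound"
    )


def add_random_pairs(structure: NetworkStructure, fraction: float = 0.2,
                     rng_seed: int = 0) -> NetworkStructure:
    """Activate combinatorial terms on a random fraction of eligible pairs.

    Eligible pairs are unordered combinations (j < k) of a gene's active
    linear regulators.  Synthetic benchmark truths activate 20% of them by
    default so the generative model exercises the quadratic terms.
    """
    rng = np.random.default_rng(rng_seed)
    out = structure.copy()
    eligible = [(i, (j, k))
                for i in range(out.p)
                for j in sorted(out.linear_sets[i])
                for k in sorted(out.linear_sets[i]) if j < k]
    n_pick = int(round(fraction * len(eligible)))
    if n_pick:
        idx = rng.choice(len(eligible), size=n_pick, replace=False)
        for sel in sorted(idx):
            i, pair = eligible[sel]
            out.pair_sets[i].add(pair)
    out.validate()
    return out


#: shipped benchmark fixtures: {name: (filename, expected_edges)}
_BENCHMARKS = {
    "wnt5a": ("wnt5a_synthetic.tsv", 30),
    "yeast_cell_cycle": ("yeast_cell_cycle_synthetic.tsv", 26),
}


def make_benchmark(name: str, rng_seed: int | None = None,
                   path: str | None = None) -> NetworkStructure:
    """Load a 10-gene benchmark topology.

    ``wnt5a`` has 30 directed edges and ``yeast_cell_cycle`` has 26,
    matching the published network sizes.  The shipped fixture files are
    synthetic placeholder topologies with those exact sizes; pass ``path``
    to substitute a curated edge-list file with the same format.  The
    ``rng_seed`` argument is accepted for interface stability and unused by
    the file-backed fixtures.
    """
    if name not in _BENCHMARKS:
        raise ValueError(f"unknown benchmark {name!r}; options: {sorted(_BENCHMARKS)}")
    fname, n_edges = _BENCHMARKS[name]
    from .io import read_network  # local import to avoid a cycle

    if path is None:
        ref = resources.files("grnrestore.data").joinpath(fname)
        with resources.as_file(ref) as fp:
            structure = read_network(fp, p=10)
    else:
        structure = read_network(path, p=10)
    if structure.n_edges() != n_edges:
        raise StructureError(
            f"benchmark {name} expected {n_edges} edges, file has {structure.n_edges()}"
        )
    return structure


def undirected_to_directed(undirected_edges, truth: NetworkStructure,
                           rng_seed: int) -> set[tuple[int, int]]:
    """Orient undirected edges against a directed truth.

    An undirected edge matching a true edge in either orientation keeps the
    true orientation (both, if both directions are true); a spurious edge
    gets a uniformly random orientation.
    """
    rng = np.random.default_rng(rng_seed)
    true_edges = truth.edges()
    out: set[tuple[int, int]] = set()
    for e in sorted({tuple(sorted(e)) for e in undirected_edges}):
        j, k = e
        fwd, rev = (j, k) in true_edges, (k, j) in true_edges
        if fwd:
            out.add((j, k))
        if rev:
            out.add((k, j))
        if not (fwd or rev):
            out.add((j, k) if rng.random() < 0.5 else (k, j))
    return out
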