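"""Greedy BIC-driven network restoration with two-phase candidate scoring.

Starting from an original network, the search repeatedly proposes
single-element moves (add / delete / replace a linear edge, pair term or
input edge on one gene's row), pre-screens them with cheap residual
heuristics, shortlists the top r1 per row for evaluation by UKF-based EM,
shortlists the top r2 overall for evaluation by the higher-moment ensemble
filter's EM, and accepts the best move if and only if it strictly lowers
the ensemble-engine BIC.  The search terminates when no candidate
improves, which is guaranteed in finitely many steps because the accepted
BIC sequence decreases strictly over a finite move space.

All ensemble evaluations in one search share a common seed so that
candidate comparisons are paired (common random numbers), making the
accepted BIC sequence deterministic given the search seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from . import em, ukf
from .model import CTMParameters, NetworkStructure, ObservationSet

__all__ = ["CandidateMove", "SearchConfig", "SearchState", "RestoreResult",
           "enumerate_moves", "apply_move", "prescreen", "restore"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CandidateMove:
    """One structural edit on one gene's row.

    ``element`` is the regulator index (linear), canonical (j, k) pair, or
    input index; for replace moves ``removed`` holds the element that
    leaves and ``element`` the one that enters (same kind, same row).
    """

    target: int
    action: str       # add | delete | replace
    kind: str         # linear | pair | drug
    element: object
    removed: object = None

    def sort_key(self) -> tuple:
        return (self.target, self.action, self.kind,
                str(self.element), str(self.removed))


@dataclass
class SearchConfig:
    """Search settings: shortlist sizes, caps, and evaluator budgets.

    ``r1`` candidates per row go to the UKF phase and ``r2`` overall to
    the ensemble phase ({5, 5} with uncapped add/delete by default);
    ``N`` is the ensemble size.  ``fast()`` gives a scaled-down profile
    for small problems.
    """

    r1: int = 5
    r2: int = 5
    add_max: float = math.inf
    del_max: float = math.inf
    N: int = 500
    score_N: int = 1000          # ensemble for the BIC-scoring pass; larger
    # than N because the likelihood estimator's bias and variance, not the
    # EM fit, limit the fidelity of candidate comparisons
    ukf_em_iters: int = 50       # full fits of the current model
    ukf_screen_iters: int = 10   # capped screening fits
    hmenpf_em_iters: int = 25
    em_tol: float = 1e-3
    max_accepted_moves: int = 200

    def __post_init__(self) -> None:
        if not (self.r1 >= self.r2 >= 1):
            raise ValueError("need r1 >= r2 >= 1")

    @classmethod
    def fast(cls) -> "SearchConfig":
        return cls(r1=3, r2=3, N=200, ukf_screen_iters=5,
                   hmenpf_em_iters=15)


@dataclass
class SearchState:
    structure: NetworkStructure
    params: CTMParameters
    bic: float
    original: NetworkStructure
    history: list[dict] = field(default_factory=list)


@dataclass
class RestoreResult:
    structure: NetworkStructure
    params: CTMParameters
    bic: float
    original_bic: float
    history: list[dict]
    n_outer_iterations: int


def _net_changes(structure: NetworkStructure, original: NetworkStructure,
                 i: int) -> tuple[int, int]:
    added = len(structure.linear_sets[i] - original.linear_sets[i])
    deleted = len(original.linear_sets[i] - structure.linear_sets[i])
    return added, deleted


def enumerate_moves(structure: NetworkStructure, original: NetworkStructure,
                    config: SearchConfig) -> list[CandidateMove]:
    """All legal single-element adds, deletes and replaces per row.

    Adds respect the TF mask and (for pairs) the active-regulator subset
    rule; deletes skip locked edges; the add_max/del_max caps count net
    linear-edge changes relative to the original structure.  A replace is
    one delete plus one add of the same element kind on the same row and
    is exempt from the caps (it leaves the net counts unchanged).
    """
    moves: list[CandidateMove] = []
    p, M = structure.p, structure.M
    for i in range(p):
        act = structure.linear_sets[i]
        added, deleted = _net_changes(structure, original, i)
        add_ok = added < config.add_max
        del_ok = deleted < config.del_max
        lin_adds = [j for j in range(p)
                    if j != i and j not in act and structure.tf_mask[j]]
        lin_dels = [j for j in sorted(act)
                    if (j, i) not in structure.locked_edges]
        pair_adds = [(j, k) for j in sorted(act) for k in sorted(act)
                     if j < k and (j, k) not in structure.pair_sets[i]]
        pair_dels = sorted(structure.pair_sets[i])
        drug_adds = [m for m in range(M) if m not in structure.drug_sets[i]]
        drug_dels = sorted(structure.drug_sets[i])
        if add_ok:
            moves += [CandidateMove(i, "add", "linear", j) for j in lin_adds]
        moves += [CandidateMove(i, "add", "pair", pr) for pr in pair_adds]
        if add_ok:
            moves += [CandidateMove(i, "add", "drug", m) for m in drug_adds]
        if del_ok:
            moves += [CandidateMove(i, "delete", "linear", j) for j in lin_dels]
        moves += [CandidateMove(i, "delete", "pair", pr) for pr in pair_dels]
        if del_ok:
            moves += [CandidateMove(i, "delete", "drug", m) for m in drug_dels]
        moves += [CandidateMove(i, "replace", "linear", j, removed=j0)
                  for j0 in lin_dels for j in lin_adds]
        moves += [CandidateMove(i, "replace", "pair", pr, removed=pr0)
                  for pr0 in pair_dels for pr in pair_adds]
        moves += [CandidateMove(i, "replace", "drug", m, removed=m0)
                  for m0 in drug_dels for m in drug_adds]
    return moves


def apply_move(structure: NetworkStructure,
               move: CandidateMove) -> NetworkStructure:
    """Return a new structure with the move applied.

    Deleting a linear edge cascades deletion of any pair terms that
    depended on the removed regulator, preserving the pair-subset
    invariant.
    """
    out = structure.copy()
    i = move.target

    def _delete(kind: str, element) -> None:
        if kind == "linear":
            if (element, i) in out.locked_edges:
                raise ValueError(f"move would remove locked edge {(element, i)}")
            out.linear_sets[i].discard(element)
            out.pair_sets[i] = {pr for pr in out.pair_sets[i]
                                if element not in pr}
        elif kind == "pair":
            out.pair_sets[i].discard(tuple(element))
        else:
            out.drug_sets[i].discard(element)

    def _add(kind: str, element) -> None:
        if kind == "linear":
            out.linear_sets[i].add(element)
        elif kind == "pair":
            out.pair_sets[i].add(tuple(element))
        else:
            out.drug_sets[i].add(element)

    if move.action in ("delete", "replace"):
        _delete(move.kind, move.removed if move.action == "replace"
                else move.element)
    if move.action in ("add", "replace"):
        _add(move.kind, move.element)
    out.validate()
    return out


def _adapt_params(params: CTMParameters, old: NetworkStructure,
                  new: NetworkStructure,
                  resid_data=None) -> CTMParameters:
    """Carry fitted coefficients over to a modified structure.

    Entries that left the active sets are zeroed.  New entries start at
    their one-step residual-regression estimate when smoothed residual
    data is supplied (EM then starts near the refit optimum, which keeps
    capped-iteration candidate scoring comparable across candidates), and
    at 0 otherwise.
    """
    out = params.copy()
    for i in range(new.p):
        for j in range(new.p):
            if i != j and j not in new.linear_sets[i]:
                out.a[i, j] = 0.0
    out.b = {key: v for key, v in out.b.items()
             if key[1] in new.pair_sets[key[0]]}
    for i in range(new.p):
        for m in range(new.M):
            if m not in new.drug_sets[i]:
                out.g[i, m] = 0.0

    def _ols(i: int, reg: np.ndarray) -> float:
        if resid_data is None:
            return 0.0
        _, resid, _ = resid_data
        var = np.var(reg)
        if var <= 0:
            return 0.0
        r = resid[:, i]
        return float(np.mean((reg - reg.mean()) * (r - r.mean())) / var)

    if resid_data is not None:
        X_prev, _, D = resid_data
        for i in range(new.p):
            for j in new.linear_sets[i] - old.linear_sets[i]:
                out.a[i, j] = _ols(i, X_prev[:, j])
            for pr in new.pair_sets[i] - old.pair_sets[i]:
                out.b[(i, pr)] = _ols(i, X_prev[:, pr[0]] * X_prev[:, pr[1]])
            for m in new.drug_sets[i] - old.drug_sets[i]:
                out.g[i, m] = _ols(i, D[:, m])
    return out


def _smoothed_residual_data(obs_list: list[ObservationSet],
                            params: CTMParameters,
                            structure: NetworkStructure):
    """Pooled smoothed states, inputs and one-step residuals per gene."""
    from .model import CompiledModel

    model = CompiledModel(params, structure)
    states_prev, resids, drugs = [], [], []
    for series in obs_list:
        run = ukf.ukf_filter(series, params, structure)
        sm = ukf.ukf_smooth(run, params, structure)
        X = np.array(sm.means)  # (T, p)
        for t in range(2, X.shape[0] + 1):
            d_t = series.d_at(t - 1)
            pred = model.mean(X[t - 2], d_t)
            states_prev.append(X[t - 2])
            resids.append(X[t - 1] - pred)
            drugs.append(d_t if d_t is not None else np.zeros(structure.M))
    return (np.array(states_prev), np.array(resids), np.array(drugs))


def _abs_corr(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = np.std(x), np.std(y)
    if sx <= 0 or sy <= 0:
        return 0.0
    return float(abs(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy)))


def prescreen(structure: NetworkStructure, params: CTMParameters,
              obs_list: list[ObservationSet],
              moves: list[CandidateMove],
              resid_data=None) -> np.ndarray:
    """Cheap promise score per move (higher = more promising).

    Add candidates score the absolute correlation between the current
    model's one-step smoothed residual for the target gene and the
    candidate regressor; delete candidates score one minus the removed
    term's share of the row's total regulatory contribution; replaces
    average the two.  Deterministic given the smoothed states.
    """
    X_prev, resid, D = (resid_data if resid_data is not None
                        else _smoothed_residual_data(obs_list, params,
                                                     structure))

    def regressor(i: int, kind: str, element) -> np.ndarray:
        if kind == "linear":
            return X_prev[:, element]
        if kind == "pair":
            j, k = element
            return X_prev[:, j] * X_prev[:, k]
        return D[:, element]

    def coefficient(i: int, kind: str, element) -> float:
        if kind == "linear":
            return float(params.a[i, element])
        if kind == "pair":
            return float(params.b.get((i, tuple(element)), 0.0))
        return float(params.g[i, element])

    def add_score(i: int, kind: str, element) -> float:
        return _abs_corr(resid[:, i], regressor(i, kind, element))

    def delete_score(i: int, kind: str, element) -> float:
        contrib = abs(coefficient(i, kind, element)) * np.std(
            regressor(i, kind, element))
        total = contrib
        for j in structure.linear_sets[i]:
            total += abs(params.a[i, j]) * np.std(X_prev[:, j])
        for pr in structure.pair_sets[i]:
            total += abs(params.b.get((i, pr), 0.0)) * np.std(
                X_prev[:, pr[0]] * X_prev[:, pr[1]])
        for m in structure.drug_sets[i]:
            total += abs(params.g[i, m]) * np.std(D[:, m])
        if total <= 0:
            return 1.0
        return 1.0 - contrib / total

    scores = np.empty(len(moves))
    for idx, mv in enumerate(moves):
        if mv.action == "add":
            scores[idx] = add_score(mv.target, mv.kind, mv.element)
        elif mv.action == "delete":
            scores[idx] = delete_score(mv.target, mv.kind, mv.element)
        else:
            scores[idx] = 0.5 * (add_score(mv.target, mv.kind, mv.element)
                                 + delete_score(mv.target, mv.kind, mv.removed))
    return scores


def _fit_bic_ukf(obs_list, structure, init, n_obs, max_iter, tol):
    params, trace = em.fit_em(obs_list, structure, init=init, engine="ukf",
                              max_iter=max_iter, tol=tol)
    return params, em.bic(max(trace.logliks), structure, n_obs)


def _fit_bic_hmenpf(obs_list, structure, init, n_obs, config, eval_seed):
    # a fresh SeedSequence per fit from the same entropy pairs every
    # candidate evaluation on common random numbers
    from . import hmenpf

    params, _ = em.fit_em(obs_list, structure, init=init,
                          engine="hmenpf", N=config.N,
                          max_iter=config.hmenpf_em_iters,
                          tol=config.em_tol,
                          rng=np.random.SeedSequence(eval_seed))
    # score with a dedicated likelihood pass on common random numbers:
    # comparisons across candidates are then paired and free of the upward
    # bias of taking the max over noisy EM-iterate logliks
    rng = np.random.default_rng(np.random.SeedSequence(entropy=eval_seed,
                                                       spawn_key=(999,)))
    loglik = sum(hmenpf.filter_series(series, params, structure,
                                      max(config.score_N, config.N),
                                      rng).loglik
                 for series in obs_list)
    return params, em.bic(loglik, structure, n_obs)


def restore(obs, original: NetworkStructure,
            config: SearchConfig | None = None,
            rng_seed: int = 0) -> RestoreResult:
    """Greedy two-phase restoration of an original network.

    Fits the original structure (UKF-EM warm start, then ensemble-EM),
    then loops enumerate -> prescreen -> UKF shortlist -> ensemble
    shortlist, accepting the best strictly-BIC-improving move until none
    remains.  A candidate whose fit fails is skipped with a warning.
    """
    config = config or SearchConfig()
    obs_list = obs if isinstance(obs, (list, tuple)) else [obs]
    n_obs = sum(series.n_obs_values() for series in obs_list)
    eval_seed = int(rng_seed)

    ukf_params, _ = em.fit_em(obs_list, original, engine="ukf",
                              max_iter=config.ukf_em_iters, tol=config.em_tol)
    params, bic_current = _fit_bic_hmenpf(obs_list, original, ukf_params,
                                          n_obs, config, eval_seed)
    original_bic = bic_current
    state = SearchState(structure=original.copy(), params=params,
                        bic=bic_current, original=original)

    for outer in range(config.max_accepted_moves):
        moves = enumerate_moves(state.structure, original, config)
        if not moves:
            break
        resid_data = _smoothed_residual_data(obs_list, state.params,
                                             state.structure)
        scores = prescreen(state.structure, state.params, obs_list, moves,
                           resid_data=resid_data)
        # top r1 per row and per action kind: add/delete/replace scores live
        # on different scales, so ranking them jointly would let deletes
        # (scores near 1) crowd every add out of the shortlist
        shortlist: list[CandidateMove] = []
        by_group: dict[tuple[int, str], list[tuple[float, CandidateMove]]] = {}
        for mv, sc in zip(moves, scores):
            by_group.setdefault((mv.target, mv.action), []).append((sc, mv))
        for group_moves in by_group.values():
            group_moves.sort(key=lambda t: (-t[0],) + t[1].sort_key())
            shortlist += [mv for _, mv in group_moves[:config.r1]]
        # UKF phase
        ukf_scored: list[tuple[float, CandidateMove, NetworkStructure,
                               CTMParameters]] = []
        for mv in shortlist:
            try:
                cand = apply_move(state.structure, mv)
                init = _adapt_params(state.params, state.structure, cand,
                                     resid_data=resid_data)
                cand_params, cand_bic = _fit_bic_ukf(
                    obs_list, cand, init, n_obs,
                    config.ukf_screen_iters, config.em_tol)
                ukf_scored.append((cand_bic, mv, cand, cand_params))
            except Exception as exc:  # noqa: BLE001 - candidate-level isolation
                logger.warning("skipping candidate %s: %s", mv, exc)
        if not ukf_scored:
            break
        ukf_scored.sort(key=lambda t: (t[0], t[2].n_structural_params())
                        + t[1].sort_key())
        # ensemble phase on the r2 best
        best = None
        for cand_bic_ukf, mv, cand, cand_params in ukf_scored[:config.r2]:
            try:
                fitted, cand_bic = _fit_bic_hmenpf(obs_list, cand, cand_params,
                                                   n_obs, config, eval_seed)
            except Exception as exc:  # noqa: BLE001
                logger.warning("skipping candidate %s in ensemble phase: %s",
                               mv, exc)
                continue
            key = (cand_bic, cand.n_structural_params()) + mv.sort_key()
            if best is None or key < best[0]:
                best = (key, mv, cand, fitted, cand_bic)
        if best is None or best[4] >= state.bic - 1e-9:
            break
        _, mv, cand, fitted, cand_bic = best
        state.history.append({
            "iteration": outer, "move": mv, "bic_before": state.bic,
            "bic_after": cand_bic,
        })
        logger.info("accepted %s: BIC %.3f -> %.3f", mv, state.bic, cand_bic)
        state.structure, state.params, state.bic = cand, fitted, cand_bic
    else:
        logger.warning("search stopped at max_accepted_moves")

    return RestoreResult(structure=state.structure, params=state.params,
                         bic=state.bic, original_bic=original_bic,
                         history=state.history,
                         n_outer_iterations=len(state.history))
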