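"""Variable selection: stepwise/backward logistic tracks scored by AIC/BIC
and repeated-CV c-index, fast forward selection for linear-kernel LS-SVMs
(R1U), and a greedy budgeted coordinator for the six one-versus-one tasks.

The R1U procedure adds, at each step, the variable with the best
leave-one-out c-index while re-tuning the regularization parameter over a
grid.  Adding a variable to a linear kernel is a rank-one update
K <- K + x_v x_v', so the LS-SVM system inverse is updated by the
Sherman-Morrison identity and the LOO outputs fall out of the inverse's
diagonal -- no refit, yet exactly equal to refitting from scratch.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2
from sklearn.model_selection import StratifiedKFold

from .data import Dataset
from .linear import LogisticModel, MultinomialModel, aic as _aic, bic as _bic
from .metrics import c_index


class SelectionError(ValueError):
    pass


@dataclass
class CandidateSet:
    names: list[str]
    provenance: str = "manual"

    def __post_init__(self):
        if len(set(self.names)) != len(self.names):
            raise SelectionError("duplicate variable names in candidate set")


@dataclass
class CriteriaReport:
    candidate: CandidateSet
    aic: float
    bic: float
    cv_c_per_event: dict
    runs: int
    folds: int
    seeds: list[int]

    def to_dict(self) -> dict:
        return {
            "names": self.candidate.names,
            "provenance": self.candidate.provenance,
            "aic": self.aic,
            "bic": self.bic,
            "cv_c_per_event": self.cv_c_per_event,
            "runs": self.runs,
            "folds": self.folds,
            "seeds": self.seeds,
        }


@dataclass
class SelectionStep:
    variable: str
    c_index: float
    gamma: float


@dataclass
class SelectionTrace:
    steps: list[SelectionStep] = field(default_factory=list)

    @property
    def variables(self) -> list[str]:
        return [s.variable for s in self.steps]

    def to_json(self) -> str:
        return json.dumps([
            {"variable": s.variable, "c_index": s.c_index, "gamma": s.gamma}
            for s in self.steps
        ])

    @classmethod
    def from_json(cls, text: str) -> "SelectionTrace":
        return cls([SelectionStep(d["variable"], d["c_index"], d["gamma"])
                    for d in json.loads(text)])


# ---------------------------------------------------------------------------
# Likelihood-ratio stepwise tracks
# ---------------------------------------------------------------------------

def _lr_pvalue(X, y, base: list[str], full: list[str]) -> float:
    ll0 = LogisticModel(X[base] if base else X[[]], y).fit().llf
    ll1 = LogisticModel(X[full], y).fit().llf
    stat = max(0.0, 2.0 * (ll1 - ll0))
    return float(chi2.sf(stat, df=len(full) - len(base)))


def stepwise_select(X: pd.DataFrame, y, p_enter: float = 0.05,
                    p_remove: float = 0.05, candidates=None,
                    max_iter: int = 100) -> CandidateSet:
    """Classic forward stepwise selection with removal, on LR-test p-values."""
    candidates = list(candidates if candidates is not None else X.columns)
    selected: list[str] = []
    for _ in range(max_iter):
        changed = False
        # entry step
        best_p, best_v = None, None
        for v in candidates:
            if v in selected:
                continue
            p = _lr_pvalue(X, y, selected, selected + [v])
            if best_p is None or p < best_p:
                best_p, best_v = p, v
        if best_v is not None and best_p < p_enter:
            selected.append(best_v)
            changed = True
        # removal step (never the variable just added)
        worst_p, worst_v = None, None
        for v in selected[:-1] if changed else selected:
            rest = [u for u in selected if u != v]
            p = _lr_pvalue(X, y, rest, selected)
            if worst_p is None or p > worst_p:
                worst_p, worst_v = p, v
        if worst_v is not None and worst_p > p_remove:
            selected.remove(worst_v)
            changed = True
        if not changed:
            break
    return CandidateSet(selected, "stepwise")


def backward_select(X: pd.DataFrame, y, p_remove: float = 0.05,
                    candidates=None) -> CandidateSet:
    """Backward elimination: start full, drop the weakest until all p <= p_remove."""
    selected = list(candidates if candidates is not None else X.columns)
    while selected:
        worst_p, worst_v = None, None
        for v in selected:
            rest = [u for u in selected if u != v]
            p = _lr_pvalue(X, y, rest, selected)
            if worst_p is None or p > worst_p:
                worst_p, worst_v = p, v
        if worst_p is not None and worst_p > p_remove:
            selected.remove(worst_v)
        else:
            break
    return CandidateSet(selected, "backward")


# ---------------------------------------------------------------------------
# Candidate evaluation: AIC/BIC + repeated stratified CV c-index per event
# ---------------------------------------------------------------------------

def evaluate_candidate(candidate: CandidateSet, ds: Dataset, runs: int = 20,
                       folds: int = 5, seeds=None) -> CriteriaReport:
    """Score a candidate set: information criteria from the full-data
    multinomial fit plus per-event mean CV c-index from out-of-fold
    predictions over ``runs`` independent stratified ``folds``-fold splits.
    """
    unknown = [v for v in candidate.names if v not in ds.schema]
    if unknown:
        raise SelectionError(f"candidate references unknown column(s) {unknown}")
    if seeds is None:
        seeds = list(range(1, runs + 1))
    if len(seeds) != runs:
        raise SelectionError("need one seed per run")
    X = ds.X(candidate.names) if candidate.names else ds.df[[]]
    y = ds.outcome.to_numpy()
    classes = [c for c in ds.class_counts().index if (y == c).sum() > 0]
    res = MultinomialModel(X, y).fit()
    acc = {c: [] for c in classes}
    for seed in seeds:
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        oof = pd.DataFrame(np.nan, index=range(len(y)), columns=classes)
        for tr, va in skf.split(np.zeros(len(y)), y):
            fit = MultinomialModel(X.iloc[tr], y[tr]).fit()
            oof.iloc[va] = fit.predict(X.iloc[va])[classes].to_numpy()
        for c in classes:
            acc[c].append(c_index(oof[c].to_numpy(), (y == c).astype(int)).estimate)
    cv_c = {c: float(np.mean(v)) for c, v in acc.items()}
    return CriteriaReport(candidate, _aic(res), _bic(res), cv_c, runs, folds, list(seeds))


# ---------------------------------------------------------------------------
# R1U: fast forward selection for linear-kernel LS-SVMs
# ---------------------------------------------------------------------------

def rank_one_inverse_update(A_inv: np.ndarray, u: np.ndarray, c: float = 1.0) -> np.ndarray:
    """(A + c uu')^{-1} from A^{-1} by the Sherman-Morrison identity."""
    A_inv = np.asarray(A_inv, dtype=float)
    u = np.asarray(u, dtype=float)
    if c == 0.0:
        return A_inv.copy()
    Au = A_inv @ u
    denom = 1.0 + c * float(u @ Au)
    if abs(denom) < 1e-12:
        raise SelectionError("Sherman-Morrison denominator numerically zero")
    return A_inv - (c / denom) * np.outer(Au, u @ A_inv)


def _standardize_columns(X: pd.DataFrame) -> np.ndarray:
    mat = X.to_numpy(dtype=float)
    mean = mat.mean(axis=0)
    sd = mat.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (mat - mean) / sd


def _loo_c_from_inverse(Minv: np.ndarray, y: np.ndarray) -> float:
    rhs = np.concatenate([[0.0], y])
    sol = Minv @ rhs
    alpha = sol[1:]
    d = np.diag(Minv)[1:]
    if np.any(np.abs(d) < 1e-14):
        return -np.inf
    loo = y - alpha / d
    return c_index(loo, (y > 0).astype(int)).estimate


def r1u_forward(X: pd.DataFrame, y, max_vars: int, gamma_grid=None) -> SelectionTrace:
    """Forward selection for linear-kernel LS-SVMs via rank-one updates.

    At every step each remaining variable's rank-one kernel update is pushed
    through Sherman-Morrison updates of the per-gamma system inverses; the
    LOO latent outputs come from the inverse's diagonal and the (variable,
    gamma) pair with the highest LOO c-index is appended.  Ties prefer
    earlier column order for variables and smaller gamma (more regularized).
    """
    y = np.asarray(y, dtype=float)
    if not set(np.unique(y)) <= {-1.0, 1.0}:
        raise SelectionError("labels must be in {-1, +1}")
    if y.min() == y.max():
        raise SelectionError("both classes must be present")
    cols = list(X.columns)
    if max_vars > len(cols):
        raise SelectionError(f"max_vars={max_vars} exceeds {len(cols)} variables")
    if gamma_grid is None:
        gamma_grid = list(np.logspace(-3, 3, 13))
    Xs = _standardize_columns(X)
    n = len(y)
    # base system for the empty kernel: M = [[0, 1'], [1, I/gamma]]
    inverses = {}
    for g in gamma_grid:
        M = np.zeros((n + 1, n + 1))
        M[0, 1:] = 1.0
        M[1:, 0] = 1.0
        M[1:, 1:] = np.eye(n) / g
        inverses[g] = np.linalg.inv(M)
    trace = SelectionTrace()
    remaining = list(range(len(cols)))
    for _ in range(max_vars):
        best = None  # (c, var_pos, gamma, updated inverses cache entry)
        for pos in remaining:
            u = np.concatenate([[0.0], Xs[:, pos]])
            for g in gamma_grid:
                Minv_new = rank_one_inverse_update(inverses[g], u, 1.0)
                cval = _loo_c_from_inverse(Minv_new, y)
                if best is None or cval > best[0]:
                    best = (cval, pos, g)
                elif cval == best[0]:
                    # earlier column, then smaller gamma (more regularized)
                    if pos < best[1] or (pos == best[1] and g < best[2]):
                        best = (cval, pos, g)
        cval, pos, g = best
        u = np.concatenate([[0.0], Xs[:, pos]])
        for gg in gamma_grid:
            inverses[gg] = rank_one_inverse_update(inverses[gg], u, 1.0)
        remaining.remove(pos)
        trace.steps.append(SelectionStep(cols[pos], float(cval), float(g)))
    return trace


def naive_forward_lssvm(X: pd.DataFrame, y, max_vars: int,
                        gamma_grid=None) -> SelectionTrace:
    """Reference forward selection with full refits and explicit LOO solves.

    Semantically identical to :func:`r1u_forward` but rebuilds and inverts
    every candidate system from scratch; kept as the slow cross-check.
    """
    y = np.asarray(y, dtype=float)
    cols = list(X.columns)
    if gamma_grid is None:
        gamma_grid = list(np.logspace(-3, 3, 13))
    Xs = _standardize_columns(X)
    n = len(y)
    trace = SelectionTrace()
    selected: list[int] = []
    remaining = list(range(len(cols)))
    for _ in range(max_vars):
        best = None
        for pos in remaining:
            sub = Xs[:, selected + [pos]]
            K = sub @ sub.T
            for g in gamma_grid:
                M = np.zeros((n + 1, n + 1))
                M[0, 1:] = 1.0
                M[1:, 0] = 1.0
                M[1:, 1:] = K + np.eye(n) / g
                Minv = np.linalg.inv(M)
                cval = _loo_c_from_inverse(Minv, y)
                if best is None or cval > best[0]:
                    best = (cval, pos, g)
                elif cval == best[0]:
                    if pos < best[1] or (pos == best[1] and g < best[2]):
                        best = (cval, pos, g)
        cval, pos, g = best
        selected.append(pos)
        remaining.remove(pos)
        trace.steps.append(SelectionStep(cols[pos], float(cval), float(g)))
    return trace


# ---------------------------------------------------------------------------
# Budgeted coordination of the six one-versus-one selections
# ---------------------------------------------------------------------------

def _pair_cv_c(X: pd.DataFrame, y01: np.ndarray, names: list[str], runs: int,
               folds: int, seed: int, cache: dict) -> float:
    key = tuple(names)
    if key in cache:
        return cache[key]
    if not names:
        cache[key] = 0.5
        return 0.5
    vals = []
    for r in range(runs):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + r)
        oof = np.full(len(y01), np.nan)
        for tr, va in skf.split(np.zeros(len(y01)), y01):
            fit = LogisticModel(X.iloc[tr][names], y01[tr]).fit()
            oof[va] = fit.predict(X.iloc[va][names])
        vals.append(c_index(oof, y01).estimate)
    cache[key] = float(np.mean(vals))
    return cache[key]


def coordinate_1v1_selection(ds: Dataset, pools: dict, budget: int,
                             min_per_pair: int = 3, max_per_pair: int = 5,
                             runs: int = 5, folds: int = 5,
                             seed: int = 1) -> dict:
    """Greedy budgeted selection across the six one-versus-one problems.

    Repeatedly grants the single (pair, variable) addition with the largest
    mean-CV c-index gain, subject to: at most ``budget`` distinct variables
    in the union, at most ``max_per_pair`` per pair.  Stops when every pair
    holds at least ``min_per_pair`` variables and the union has reached the
    budget (or no admissible addition remains).  A formalization of an
    intertwined selection whose exact recipe is a judgement call; see
    docs/methods.md.
    """
    if budget < min_per_pair:
        raise SelectionError("budget smaller than the per-pair minimum")
    from .coupling import decompose_1v1

    subsets = decompose_1v1(ds)
    pairs = list(subsets)
    sets: dict = {p: [] for p in pairs}
    caches: dict = {p: {} for p in pairs}
    data = {}
    for p in pairs:
        sub = subsets[p]
        data[p] = (sub.df, (sub.outcome == p[0]).to_numpy().astype(int))
    while True:
        union = set().union(*sets.values())
        done = all(len(sets[p]) >= min_per_pair for p in pairs) and len(union) >= budget
        if done:
            break
        best = None
        for p in pairs:
            if len(sets[p]) >= max_per_pair:
                continue
            Xp, yp = data[p]
            base = _pair_cv_c(Xp, yp, sets[p], runs, folds, seed, caches[p])
            for v in pools.get(p, ds.predictors):
                if v in sets[p]:
                    continue
                if v not in union and len(union) >= budget:
                    continue
                gain = _pair_cv_c(Xp, yp, sets[p] + [v], runs, folds, seed,
                                  caches[p]) - base
                cand = (gain, p, v)
                if best is None or gain > best[0]:
                    best = cand
        if best is None:
            break
        gain, p, v = best
        need = (len(sets[p]) < min_per_pair) or (len(set().union(*sets.values())) < budget and v not in union)
        if gain <= 0 and not need:
            # only accept non-improving additions while constraints unmet
            break
        sets[p].append(v)
    return {p: CandidateSet(list(s), "coordinated-1v1") for p, s in sets.items()}
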