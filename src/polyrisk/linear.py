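"""Maximum-likelihood dichotomous and multinomial logistic regression.

Both models are fitted by Newton's method on the (multinomial) binomial
log-likelihood with step-halving, no shrinkage or penalty.  They follow the
statsmodels convention: a model object built from data whose :meth:`fit`
returns a results object carrying estimates, standard errors and fit
metadata.  Non-convergence and quasi-complete separation are flagged on the
results object rather than raised, because one-versus-one fits on rare
outcome classes legitimately separate now and then and the capped fit is
still usable for ranking cases.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

MAXITER = 100
SCORE_TOL = 1e-8
SEPARATION_COEF = 15.0


class FitError(RuntimeError):
    pass


def _design(X: pd.DataFrame | np.ndarray, names=None):
    if isinstance(X, pd.DataFrame):
        if names is not None:
            missing = [c for c in names if c not in X.columns]
            if missing:
                raise KeyError(f"missing predictor column(s) {missing}")
            X = X[list(names)]
        names = list(X.columns)
        mat = X.to_numpy(dtype=float)
    else:
        mat = np.asarray(X, dtype=float)
        if mat.ndim == 1:
            mat = mat[:, None]
        if names is None:
            names = [f"x{i}" for i in range(mat.shape[1])]
    return np.column_stack([np.ones(len(mat)), mat]), ["const"] + list(names)


@dataclass
class _FitMeta:
    llf: float
    nobs: int
    iterations: int
    converged: bool
    separated: bool


class LogisticModel:
    """Dichotomous logistic regression, ML via Newton-Raphson.

    Parameters
    ----------
    X : DataFrame or array
        Predictor table (an intercept is always added).
    y : array-like
        Binary labels; either {0,1} or two arbitrary labels with
        ``positive`` designating the modelled event.
    """

    def __init__(self, X, y, positive=None):
        self.exog, self.names = _design(X)
        y = np.asarray(y)
        labels = np.unique(y)
        if len(labels) != 2 and not (len(labels) == 1 and labels[0] in (0, 1)):
            if set(labels) <= {0, 1}:
                pass
            else:
                raise FitError(f"need exactly two labels, got {labels}")
        if positive is None:
            if not set(labels) <= {0, 1}:
                raise FitError("non-numeric labels require `positive`")
            self.labels = (0, 1)
            self.endog = y.astype(float)
        else:
            negs = [l for l in labels if l != positive]
            if positive not in labels or len(negs) != 1:
                raise FitError(f"positive label {positive!r} not one of two labels {labels}")
            self.labels = (negs[0], positive)
            self.endog = (y == positive).astype(float)
        if self.endog.min() == self.endog.max():
            raise FitError("both outcome labels must be present")

    def loglike(self, beta):
        eta = self.exog @ beta
        # numerically stable: -log(1+exp(-eta)) for y=1 etc.
        return float(-np.sum(np.logaddexp(0.0, eta)) + self.endog @ eta)

    def fit(self, maxiter: int = MAXITER, tol: float = SCORE_TOL) -> "LogisticResults":
        X, y = self.exog, self.endog
        beta = np.zeros(X.shape[1])
        ll = self.loglike(beta)
        converged = False
        it = 0
        for it in range(1, maxiter + 1):
            mu = expit(X @ beta)
            score = X.T @ (y - mu)
            if np.max(np.abs(score)) < tol:
                converged = True
                break
            w = np.clip(mu * (1.0 - mu), 1e-12, None)
            H = (X * w[:, None]).T @ X
            try:
                step = np.linalg.solve(H, score)
            except np.linalg.LinAlgError:
                # near-separation drives weights to 0 and H to singularity;
                # keep the capped fit usable (flagged below) via a tiny ridge
                ridge = 1e-8 * (np.trace(H) / len(H) + 1.0)
                try:
                    step = np.linalg.solve(H + ridge * np.eye(len(H)), score)
                except np.linalg.LinAlgError as exc:
                    raise FitError(f"singular information matrix: {exc}") from exc
            # step-halving to guarantee likelihood ascent
            for _ in range(30):
                cand = beta + step
                ll_new = self.loglike(cand)
                if ll_new >= ll - 1e-12:
                    break
                step *= 0.5
            beta, ll = cand, ll_new
        # diverging coefficients signal (quasi-)separation even when the
        # score happens to fall below tolerance: the ML estimate is at
        # infinity and the capped fit only ranks cases
        separated = bool(np.max(np.abs(beta)) > SEPARATION_COEF)
        converged = converged and not separated
        mu = expit(X @ beta)
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        H = (X * w[:, None]).T @ X
        try:
            cov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            cov = np.full((X.shape[1],) * 2, np.nan)
        meta = _FitMeta(self.loglike(beta), len(y), it, converged, separated)
        return LogisticResults(self, beta, cov, meta)


class LogisticResults:
    """Fitted dichotomous logistic regression."""

    def __init__(self, model: LogisticModel, beta, cov, meta: _FitMeta):
        self.model = model
        self.params = pd.Series(beta, index=model.names)
        self.cov_params = pd.DataFrame(cov, index=model.names, columns=model.names)
        self.bse = pd.Series(np.sqrt(np.diag(cov)), index=model.names)
        self.llf = meta.llf
        self.nobs = meta.nobs
        self.iterations = meta.iterations
        self.converged = meta.converged
        self.separated = meta.separated
        self.labels = model.labels

    @property
    def df_model(self) -> int:
        return len(self.params)

    @property
    def aic(self) -> float:
        return aic(self)

    @property
    def bic(self) -> float:
        return bic(self)

    def linear_predictor(self, X) -> np.ndarray:
        mat, _ = _design(X, names=self.params.index[1:])
        return mat @ self.params.to_numpy()

    def predict(self, X) -> np.ndarray:
        """Probability of the positive event for each case."""
        return expit(self.linear_predictor(X))

    def summary(self) -> str:
        lines = [
            "Dichotomous logistic regression (ML, no shrinkage)",
            f"positive event: {self.labels[1]!r} vs {self.labels[0]!r}   "
            f"n = {self.nobs}   log-likelihood = {self.llf:.4f}",
            f"converged = {self.converged}  separated = {self.separated}  "
            f"AIC = {self.aic:.2f}  BIC = {self.bic:.2f}",
            f"{'':<22}{'coef':>10}{'se':>10}",
        ]
        for name in self.params.index:
            lines.append(f"{name:<22}{self.params[name]:>10.4f}{self.bse[name]:>10.4f}")
        return "\n".join(lines)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "kind": "logistic",
            "names": list(self.params.index),
            "params": [float(v) for v in self.params],
            "labels": list(self.labels),
            "llf": self.llf,
            "nobs": int(self.nobs),
            "converged": bool(self.converged),
            "separated": bool(self.separated),
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "LoadedLogistic":
        return LoadedLogistic(doc)


class LoadedLogistic:
    """Prediction-only logistic model re-loaded from a serialized document."""

    def __init__(self, doc: dict):
        self.params = pd.Series(doc["params"], index=doc["names"])
        self.labels = tuple(doc["labels"])
        self.llf = doc["llf"]
        self.nobs = doc["nobs"]
        self.converged = doc["converged"]
        self.separated = doc.get("separated", False)

    def predict(self, X) -> np.ndarray:
        mat, _ = _design(X, names=self.params.index[1:])
        return expit(mat @ self.params.to_numpy())

    def to_dict(self) -> dict:
        return {
            "kind": "logistic",
            "names": list(self.params.index),
            "params": [float(v) for v in self.params],
            "labels": list(self.labels),
            "llf": self.llf,
            "nobs": int(self.nobs),
            "converged": bool(self.converged),
            "separated": bool(self.separated),
        }


class MultinomialModel:
    """Multinomial (polytomous) logistic regression with a reference class.

    One coefficient vector per non-reference class; fitted by full Newton on
    the multinomial log-likelihood with step-halving.
    """

    def __init__(self, X, y, reference=None):
        self.exog, self.names = _design(X)
        y = np.asarray(y)
        self.classes = list(pd.unique(pd.Series(y)))
        # canonical ordering: keep first-appearance order unless all labels
        # are outcome labels, then use canonical outcome order
        from .data import OUTCOMES
        if set(self.classes) <= set(OUTCOMES):
            self.classes = [c for c in OUTCOMES if c in self.classes]
        if reference is None:
            reference = self.classes[0]
        if reference not in self.classes:
            raise FitError(f"reference {reference!r} not among classes {self.classes}")
        self.reference = reference
        self.nonref = [c for c in self.classes if c != reference]
        self.Y = np.column_stack([(y == c).astype(float) for c in self.nonref])
        if min((y == c).sum() for c in self.classes) == 0:
            raise FitError("every class must have at least one case")

    def _probs(self, B: np.ndarray) -> np.ndarray:
        """Per-case probabilities, columns ordered [reference, *nonref]."""
        eta = self.exog @ B.T  # n x (K-1)
        full = np.column_stack([np.zeros(len(eta)), eta])
        full -= full.max(axis=1, keepdims=True)
        e = np.exp(full)
        return e / e.sum(axis=1, keepdims=True)

    def loglike(self, B) -> float:
        P = self._probs(B)
        ref_mask = self.Y.sum(axis=1) == 0
        ll = np.sum(np.log(np.clip(P[ref_mask, 0], 1e-300, None)))
        for j in range(len(self.nonref)):
            mask = self.Y[:, j] == 1
            ll += np.sum(np.log(np.clip(P[mask, j + 1], 1e-300, None)))
        return float(ll)

    def fit(self, maxiter: int = MAXITER, tol: float = SCORE_TOL) -> "MultinomialResults":
        X = self.exog
        n, p = X.shape
        Km1 = len(self.nonref)
        B = np.zeros((Km1, p))
        ll = self.loglike(B)
        converged = False
        it = 0
        for it in range(1, maxiter + 1):
            P = self._probs(B)[:, 1:]  # n x (K-1)
            score = np.concatenate([X.T @ (self.Y[:, j] - P[:, j]) for j in range(Km1)])
            if np.max(np.abs(score)) < tol:
                converged = True
                break
            H = np.zeros((Km1 * p, Km1 * p))
            for j in range(Km1):
                for k in range(j, Km1):
                    w = P[:, j] * ((j == k) - P[:, k])
                    blk = (X * w[:, None]).T @ X
                    H[j * p:(j + 1) * p, k * p:(k + 1) * p] = blk
                    if k != j:
                        H[k * p:(k + 1) * p, j * p:(j + 1) * p] = blk
            try:
                step = np.linalg.solve(H + 1e-12 * np.eye(Km1 * p), score)
            except np.linalg.LinAlgError:
                ridge = 1e-8 * (np.trace(H) / len(H) + 1.0)
                try:
                    step = np.linalg.solve(H + ridge * np.eye(Km1 * p), score)
                except np.linalg.LinAlgError as exc:
                    raise FitError(f"singular information matrix: {exc}") from exc
            step = step.reshape(Km1, p)
            for _ in range(30):
                cand = B + step
                ll_new = self.loglike(cand)
                if ll_new >= ll - 1e-12:
                    break
                step *= 0.5
            B, ll = cand, ll_new
        separated = bool(np.max(np.abs(B)) > SEPARATION_COEF)
        converged = converged and not separated
        meta = _FitMeta(self.loglike(B), n, it, converged, separated)
        return MultinomialResults(self, B, meta)


class MultinomialResults:
    def __init__(self, model: MultinomialModel, B, meta: _FitMeta):
        self.model = model
        self.params = pd.DataFrame(B, index=model.nonref, columns=model.names)
        self.classes = list(model.classes)
        self.reference = model.reference
        self.llf = meta.llf
        self.nobs = meta.nobs
        self.iterations = meta.iterations
        self.converged = meta.converged
        self.separated = meta.separated

    @property
    def df_model(self) -> int:
        return int(self.params.size)

    @property
    def aic(self) -> float:
        return aic(self)

    @property
    def bic(self) -> float:
        return bic(self)

    def predict(self, X) -> pd.DataFrame:
        """Per-case class probabilities (columns in canonical class order)."""
        mat, _ = _design(X, names=self.params.columns[1:])
        eta = mat @ self.params.to_numpy().T
        full = np.column_stack([np.zeros(len(eta)), eta])
        full -= full.max(axis=1, keepdims=True)
        e = np.exp(full)
        P = e / e.sum(axis=1, keepdims=True)
        cols = [self.reference] + list(self.params.index)
        frame = pd.DataFrame(P, columns=cols)
        return frame[self.classes]

    def summary(self) -> str:
        lines = [
            "Multinomial logistic regression (ML, no shrinkage)",
            f"reference class: {self.reference!r}   n = {self.nobs}   "
            f"log-likelihood = {self.llf:.4f}",
            f"converged = {self.converged}  AIC = {self.aic:.2f}  BIC = {self.bic:.2f}",
        ]
        for cls in self.params.index:
            lines.append(f"-- {cls} vs {self.reference} --")
            for name in self.params.columns:
                lines.append(f"{name:<22}{self.params.loc[cls, name]:>10.4f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "kind": "multinomial",
            "names": list(self.params.columns),
            "classes": self.classes,
            "reference": self.reference,
            "params": {c: [float(v) for v in self.params.loc[c]] for c in self.params.index},
            "llf": self.llf,
            "nobs": int(self.nobs),
            "converged": bool(self.converged),
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "LoadedMultinomial":
        return LoadedMultinomial(doc)


class LoadedMultinomial:
    def __init__(self, doc: dict):
        self.classes = list(doc["classes"])
        self.reference = doc["reference"]
        nonref = [c for c in self.classes if c != self.reference]
        self.params = pd.DataFrame(
            [doc["params"][c] for c in nonref], index=nonref, columns=doc["names"]
        )
        self.llf = doc["llf"]
        self.nobs = doc["nobs"]
        self.converged = doc["converged"]

    predict = MultinomialResults.predict


# ---------------------------------------------------------------------------
# Information criteria and functional wrappers
# ---------------------------------------------------------------------------

def aic(results) -> float:
    """Akaike information criterion, -2*llf + 2p."""
    return -2.0 * results.llf + 2.0 * results.df_model


def bic(results) -> float:
    """Bayesian information criterion, -2*llf + p*ln(n)."""
    return -2.0 * results.llf + results.df_model * np.log(results.nobs)


def fit_logistic(X, y, positive=None) -> LogisticResults:
    return LogisticModel(X, y, positive=positive).fit()


def fit_multinomial(X, y, reference=None) -> MultinomialResults:
    return MultinomialModel(X, y, reference=reference).fit()


def save_model(results, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(results.to_dict(), fh)


def load_model(path):
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    if doc["kind"] == "logistic":
        return LoadedLogistic(doc)
    if doc["kind"] == "multinomial":
        return LoadedMultinomial(doc)
    raise ValueError(f"unknown model kind {doc['kind']!r}")
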