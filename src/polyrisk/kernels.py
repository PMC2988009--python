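"""Kernel-based classifiers: LS-SVM with Bayesian probabilistic output,
kernel logistic regression (KLR) and its multinomial extension (MKLR).

An LS-SVM replaces the SVM's inequality constraints with equality
constraints on squared residuals, so fitting reduces to one symmetric linear
(KKT) system; gamma is its regularization parameter.  Probabilities come
from Gaussian class-conditional modelling of the latent output combined with
prior class prevalences via Bayes' rule (a documented approximation to a
full Bayesian evidence treatment).  KLR/MKLR minimise a kernel-penalized
(multinomial) negative log-likelihood by iteratively re-weighted least
squares in which every step solves a system with LS-SVM structure.

Predictors are standardized internally (training mean/SD); Gaussian kernels
are scale-sensitive and the transformation is stored on the model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.model_selection import StratifiedKFold

JITTER_REL = 1e-10


class KernelError(ValueError):
    pass


@dataclass(frozen=True)
class KernelSpec:
    """Kernel family: ``linear`` (x'z) or ``gaussian`` (exp(-||x-z||^2/sigma^2))."""

    kind: str = "linear"
    sigma: float | None = None

    def __post_init__(self):
        if self.kind not in ("linear", "gaussian"):
            raise KernelError(f"unknown kernel kind {self.kind!r}")
        if self.kind == "gaussian":
            if self.sigma is None or not np.isfinite(self.sigma) or self.sigma <= 0:
                raise KernelError("gaussian kernel requires finite sigma > 0")


def kernel_matrix(X, Z, spec: KernelSpec) -> np.ndarray:
    """K[i, j] = k(X[i], Z[j]) under the given kernel."""
    X = np.asarray(X, dtype=float)
    Z = np.asarray(Z, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if Z.ndim == 1:
        Z = Z[:, None]
    if X.shape[1] != Z.shape[1]:
        raise KernelError(f"dimension mismatch: {X.shape[1]} vs {Z.shape[1]} columns")
    if spec.kind == "linear":
        return X @ Z.T
    d2 = (
        np.sum(X**2, axis=1)[:, None]
        + np.sum(Z**2, axis=1)[None, :]
        - 2.0 * X @ Z.T
    )
    return np.exp(-np.clip(d2, 0.0, None) / spec.sigma**2)


def median_heuristic_sigma(X) -> float:
    """Median pairwise Euclidean distance, the standard Gaussian-bandwidth anchor."""
    X = np.asarray(X, dtype=float)
    n = len(X)
    if n > 500:  # subsample for the heuristic only
        idx = np.random.default_rng(0).choice(n, 500, replace=False)
        X = X[idx]
    d2 = (
        np.sum(X**2, axis=1)[:, None]
        + np.sum(X**2, axis=1)[None, :]
        - 2.0 * X @ X.T
    )
    d = np.sqrt(np.clip(d2[np.triu_indices(len(X), 1)], 0.0, None))
    med = float(np.median(d))
    return med if med > 0 else 1.0


class _Standardizer:
    def __init__(self, X):
        X = _as_matrix(X)
        self.mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        self.scale = np.where(sd > 0, sd, 1.0)

    def __call__(self, X) -> np.ndarray:
        return (_as_matrix(X) - self.mean) / self.scale


def _as_matrix(X) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    return X[:, None] if X.ndim == 1 else X


def _columns(X):
    return list(X.columns) if isinstance(X, pd.DataFrame) else None


# ---------------------------------------------------------------------------
# LS-SVM
# ---------------------------------------------------------------------------

class LSSVM:
    """Least squares support vector machine classifier.

    Parameters
    ----------
    X, y : training data; ``y`` in {-1, +1} (or two labels with ``positive``).
    gamma : regularization parameter (> 0); larger = less regularized.
    kernel : :class:`KernelSpec`.
    """

    def __init__(self, X, y, gamma: float, kernel: KernelSpec | None = None,
                 positive=None, standardize: bool = True):
        if gamma <= 0:
            raise KernelError("gamma must be > 0")
        self.columns = _columns(X)
        y = np.asarray(y)
        labels = np.unique(y)
        if set(labels) <= {-1, 1} and positive is None:
            self.labels = (-1, 1)
            yy = y.astype(float)
        else:
            if positive is None or len(labels) != 2:
                raise KernelError("need two labels and `positive` for non +/-1 labels")
            neg = [l for l in labels if l != positive][0]
            self.labels = (neg, positive)
            yy = np.where(y == positive, 1.0, -1.0)
        if yy.min() == yy.max():
            raise KernelError("both classes must be present")
        self.standardizer = _Standardizer(X) if standardize else None
        self.Xtr = self.standardizer(X) if standardize else _as_matrix(X)
        self.y = yy
        self.gamma = float(gamma)
        self.kernel = kernel or KernelSpec("linear")

    def _system(self) -> np.ndarray:
        n = len(self.y)
        K = kernel_matrix(self.Xtr, self.Xtr, self.kernel)
        K = K + (JITTER_REL * np.trace(K) / n) * np.eye(n)
        M = np.zeros((n + 1, n + 1))
        M[0, 1:] = 1.0
        M[1:, 0] = 1.0
        M[1:, 1:] = K + np.eye(n) / self.gamma
        return M

    def fit(self) -> "LSSVMResults":
        n = len(self.y)
        M = self._system()
        rhs = np.concatenate([[0.0], self.y])
        try:
            Minv = np.linalg.inv(M)
        except np.linalg.LinAlgError:
            M[1:, 1:] += 1e-8 * np.eye(n)
            try:
                Minv = np.linalg.inv(M)
            except np.linalg.LinAlgError as exc:
                raise KernelError(f"singular KKT system: {exc}") from exc
        sol = Minv @ rhs
        return LSSVMResults(self, sol[0], sol[1:], M, Minv)


class LSSVMResults:
    """Fitted LS-SVM: dual coefficients, bias, fast LOO, Bayesian posterior.

    Internally the dual is parameterized so the latent output is
    f(x) = sum_i alpha_i K(x_i, x) + b with alpha_i = y_i * alpha^KKT_i;
    the KKT conditions translate to sum_i alpha_i = 0.
    """

    def __init__(self, model: LSSVM, b: float, alpha: np.ndarray, M, Minv):
        self.model = model
        self.b = float(b)
        self.alpha = alpha
        self._M = M
        self._Minv = Minv
        self.gamma = model.gamma
        self.kernel = model.kernel
        self.labels = model.labels
        f = self.latent(raw=True)
        self.latent_train = f
        pos = model.y > 0
        self.latent_stats = {
            "pos": (float(f[pos].mean()), float(f[pos].std(ddof=1)) if pos.sum() > 1 else 0.0),
            "neg": (float(f[~pos].mean()), float(f[~pos].std(ddof=1)) if (~pos).sum() > 1 else 0.0),
        }
        self.priors = (float((~pos).mean()), float(pos.mean()))

    # -- defining properties ----------------------------------------------
    def kkt_residual(self) -> float:
        rhs = np.concatenate([[0.0], self.model.y])
        sol = np.concatenate([[self.b], self.alpha * self.model.y])
        # residual of the y-encoded system equals (after sign conjugation)
        # the residual of the Omega-form KKT system
        r = self._M @ np.concatenate([[self.b], self.alpha]) - rhs
        return float(np.max(np.abs(r)) / max(1.0, np.max(np.abs(sol))))

    @property
    def sum_alpha_y(self) -> float:
        """KKT constraint sum_i alpha^KKT_i y_i (= sum alpha_i here)."""
        return float(np.sum(self.alpha))

    def latent(self, X=None, raw: bool = False) -> np.ndarray:
        """Latent output f(x); ``raw`` skips standardization (internal use)."""
        if X is None:
            Xs = self.model.Xtr
        elif raw:
            Xs = _as_matrix(X)
        else:
            Xs = self._prepare(X)
        K = kernel_matrix(Xs, self.model.Xtr, self.kernel)
        return K @ self.alpha + self.b

    def _prepare(self, X):
        if self.model.columns is not None and isinstance(X, pd.DataFrame):
            missing = [c for c in self.model.columns if c not in X.columns]
            if missing:
                raise KeyError(f"missing predictor column(s) {missing}")
            X = X[self.model.columns]
        return self.model.standardizer(X) if self.model.standardizer else _as_matrix(X)

    def decision(self, X):
        return self.latent(self._prepare(X), raw=True)

    def loo_latent(self) -> np.ndarray:
        """Leave-one-out latent outputs from the full system's inverse.

        Uses the hat-matrix identity e_{i,-i} = e_i / (1 - h_ii) in its dual
        form (LOO residual = alpha_i / [M^{-1}]_ii), avoiding n refits but
        agreeing with them exactly.
        """
        d = np.diag(self._Minv)[1:]
        if np.any(np.abs(d) < 1e-12):
            raise KernelError("leverage numerically 1: LOO undefined for some case")
        return self.model.y - self.alpha / d

    def posterior(self, X=None, priors=None) -> np.ndarray:
        """P(positive event | x) via Gaussian class-conditional latent densities.

        ``priors`` is (P(negative), P(positive)); defaults to training
        prevalences, mirroring the use of the outcome distribution of the
        development data as prior event probabilities.
        """
        if priors is None:
            priors = self.priors
        p_neg, p_pos = float(priors[0]), float(priors[1])
        if not (0 < p_pos < 1 and abs(p_neg + p_pos - 1.0) < 1e-8):
            raise KernelError("priors must be two probabilities summing to 1")
        f = self.latent_train if X is None else self.latent(self._prepare(X), raw=True)
        m_pos, s_pos = self.latent_stats["pos"]
        m_neg, s_neg = self.latent_stats["neg"]
        if s_pos <= 1e-12 or s_neg <= 1e-12:
            import warnings

            warnings.warn("degenerate latent spread; returning hard 0/1 posterior")
            return np.where(f >= (m_pos + m_neg) / 2.0, 1.0, 0.0)
        # log-density difference for numerical stability
        log_num = np.log(p_pos) - np.log(s_pos) - 0.5 * ((f - m_pos) / s_pos) ** 2
        log_den = np.log(p_neg) - np.log(s_neg) - 0.5 * ((f - m_neg) / s_neg) ** 2
        return expit(log_num - log_den)

    def predict(self, X) -> np.ndarray:
        """Probability of the positive event (Bayesian posterior, training priors)."""
        return self.posterior(X)

    def summary(self) -> str:
        m = self.model
        return "\n".join([
            "LS-SVM classifier (KKT linear system)",
            f"kernel = {self.kernel.kind}"
            + (f" (sigma={self.kernel.sigma:.4g})" if self.kernel.kind == "gaussian" else "")
            + f"   gamma = {self.gamma:.4g}   n = {len(m.y)}",
            f"positive event: {self.labels[1]!r}   priors = ({self.priors[0]:.3f}, {self.priors[1]:.3f})",
            f"KKT residual = {self.kkt_residual():.2e}   sum(alpha*y) = {self.sum_alpha_y:.2e}",
            f"latent (neg) mean/sd = {self.latent_stats['neg'][0]:.3f}/{self.latent_stats['neg'][1]:.3f}"
            f"   latent (pos) mean/sd = {self.latent_stats['pos'][0]:.3f}/{self.latent_stats['pos'][1]:.3f}",
        ])

    def to_dict(self) -> dict:
        m = self.model
        return {
            "kind": "lssvm",
            "columns": m.columns,
            "Xtr": m.Xtr.tolist(),
            "mean": m.standardizer.mean.tolist() if m.standardizer else None,
            "scale": m.standardizer.scale.tolist() if m.standardizer else None,
            "alpha": self.alpha.tolist(),
            "b": self.b,
            "gamma": self.gamma,
            "kernel": {"kind": self.kernel.kind, "sigma": self.kernel.sigma},
            "labels": list(self.labels),
            "latent_stats": self.latent_stats,
            "priors": list(self.priors),
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "LoadedLSSVM":
        return LoadedLSSVM(doc)


class LoadedLSSVM:
    """Prediction-only LS-SVM re-loaded from a serialized document."""

    def __init__(self, doc: dict):
        self.columns = doc["columns"]
        self.Xtr = np.asarray(doc["Xtr"], dtype=float)
        self.mean = None if doc["mean"] is None else np.asarray(doc["mean"])
        self.scale = None if doc["scale"] is None else np.asarray(doc["scale"])
        self.alpha = np.asarray(doc["alpha"], dtype=float)
        self.b = float(doc["b"])
        self.gamma = doc["gamma"]
        self.kernel = KernelSpec(doc["kernel"]["kind"], doc["kernel"]["sigma"])
        self.labels = tuple(doc["labels"])
        self.latent_stats = {k: tuple(v) for k, v in doc["latent_stats"].items()}
        self.priors = tuple(doc["priors"])

    def predict(self, X) -> np.ndarray:
        if self.columns is not None and isinstance(X, pd.DataFrame):
            X = X[self.columns]
        Xs = _as_matrix(X)
        if self.mean is not None:
            Xs = (Xs - self.mean) / self.scale
        f = kernel_matrix(Xs, self.Xtr, self.kernel) @ self.alpha + self.b
        m_pos, s_pos = self.latent_stats["pos"]
        m_neg, s_neg = self.latent_stats["neg"]
        p_neg, p_pos = self.priors
        if s_pos <= 1e-12 or s_neg <= 1e-12:
            return np.where(f >= (m_pos + m_neg) / 2.0, 1.0, 0.0)
        log_num = np.log(p_pos) - np.log(s_pos) - 0.5 * ((f - m_pos) / s_pos) ** 2
        log_den = np.log(p_neg) - np.log(s_neg) - 0.5 * ((f - m_neg) / s_neg) ** 2
        return expit(log_num - log_den)

    def to_dict(self) -> dict:
        return {
            "kind": "lssvm",
            "columns": self.columns,
            "Xtr": self.Xtr.tolist(),
            "mean": None if self.mean is None else self.mean.tolist(),
            "scale": None if self.scale is None else self.scale.tolist(),
            "alpha": self.alpha.tolist(),
            "b": self.b,
            "gamma": self.gamma,
            "kernel": {"kind": self.kernel.kind, "sigma": self.kernel.sigma},
            "labels": list(self.labels),
            "latent_stats": {k: list(v) for k, v in self.latent_stats.items()},
            "priors": list(self.priors),
        }


# ---------------------------------------------------------------------------
# Kernel logistic regression (binary and multinomial)
# ---------------------------------------------------------------------------

def _klr_step(K: np.ndarray, z: np.ndarray, w: np.ndarray, lam: float):
    """One weighted penalized least-squares solve with LS-SVM structure."""
    n = len(z)
    M = np.zeros((n + 1, n + 1))
    M[0, 1:] = 1.0
    M[1:, 0] = 1.0
    M[1:, 1:] = K + lam * np.diag(1.0 / w)
    rhs = np.concatenate([[0.0], z])
    sol = np.linalg.solve(M, rhs)
    return sol[0], sol[1:]


class KLR:
    """Dichotomous kernel logistic regression via penalized IRLS.

    Minimizes the binomial negative log-likelihood plus (lam/2) a' K a over
    the kernel expansion f(x) = sum_i a_i K(x_i, x) + b; each IRLS step
    solves a weighted system with the structure of an LS-SVM.
    """

    def __init__(self, X, y, lam: float, kernel: KernelSpec | None = None,
                 positive=None, standardize: bool = True):
        if lam <= 0:
            raise KernelError("lam must be > 0")
        self.columns = _columns(X)
        y = np.asarray(y)
        labels = np.unique(y)
        if set(labels) <= {0, 1} and positive is None:
            self.labels = (0, 1)
            self.y01 = y.astype(float)
        elif set(labels) <= {-1, 1} and positive is None:
            self.labels = (-1, 1)
            self.y01 = (y > 0).astype(float)
        else:
            if positive is None or len(labels) != 2:
                raise KernelError("need two labels and `positive`")
            neg = [l for l in labels if l != positive][0]
            self.labels = (neg, positive)
            self.y01 = (y == positive).astype(float)
        if self.y01.min() == self.y01.max():
            raise KernelError("both classes must be present")
        self.standardizer = _Standardizer(X) if standardize else None
        self.Xtr = self.standardizer(X) if standardize else _as_matrix(X)
        self.lam = float(lam)
        self.kernel = kernel or KernelSpec("linear")

    def _objective(self, K, a, b) -> float:
        f = K @ a + b
        nll = float(np.sum(np.logaddexp(0.0, f)) - self.y01 @ f)
        return nll + 0.5 * self.lam * float(a @ K @ a)

    def fit(self, maxiter: int = 100, tol: float = 1e-8) -> "KLRResults":
        n = len(self.y01)
        K = kernel_matrix(self.Xtr, self.Xtr, self.kernel)
        K = K + (JITTER_REL * np.trace(K) / n) * np.eye(n)
        a = np.zeros(n)
        b = 0.0
        obj = self._objective(K, a, b)
        converged = False
        it = 0
        for it in range(1, maxiter + 1):
            f = K @ a + b
            p = expit(f)
            w = np.clip(p * (1.0 - p), 1e-10, None)
            z = f + (self.y01 - p) / w
            b_new, a_new = _klr_step(K, z, w, self.lam)
            # step-halving on the penalized objective
            t = 1.0
            for _ in range(30):
                a_try = a + t * (a_new - a)
                b_try = b + t * (b_new - b)
                obj_try = self._objective(K, a_try, b_try)
                if obj_try <= obj + 1e-12:
                    break
                t *= 0.5
            delta = obj - obj_try
            a, b, obj = a_try, b_try, obj_try
            if abs(delta) < tol:
                converged = True
                break
        return KLRResults(self, a, b, K, obj, it, converged)


class KLRResults:
    def __init__(self, model: KLR, a, b, K, objective, iterations, converged):
        self.model = model
        self.alpha = a
        self.b = float(b)
        self._K = K
        self.objective = float(objective)
        self.iterations = iterations
        self.converged = converged
        self.lam = model.lam
        self.kernel = model.kernel
        self.labels = model.labels

    def _prepare(self, X):
        if self.model.columns is not None and isinstance(X, pd.DataFrame):
            X = X[self.model.columns]
        return self.model.standardizer(X) if self.model.standardizer else _as_matrix(X)

    def predict(self, X=None) -> np.ndarray:
        """Probability of the positive event."""
        if X is None:
            f = self._K @ self.alpha + self.b
        else:
            Xs = self._prepare(X)
            f = kernel_matrix(Xs, self.model.Xtr, self.kernel) @ self.alpha + self.b
        return expit(f)

    def summary(self) -> str:
        return "\n".join([
            "Kernel logistic regression (penalized IRLS)",
            f"kernel = {self.kernel.kind}   lambda = {self.lam:.4g}   "
            f"n = {len(self.alpha)}",
            f"converged = {self.converged} after {self.iterations} iterations; "
            f"penalized objective = {self.objective:.6f}",
        ])

    def to_dict(self) -> dict:
        m = self.model
        return {
            "kind": "klr",
            "columns": m.columns,
            "Xtr": m.Xtr.tolist(),
            "mean": m.standardizer.mean.tolist() if m.standardizer else None,
            "scale": m.standardizer.scale.tolist() if m.standardizer else None,
            "alpha": self.alpha.tolist(),
            "b": self.b,
            "lam": self.lam,
            "kernel": {"kind": self.kernel.kind, "sigma": self.kernel.sigma},
            "labels": [_json_label(l) for l in self.labels],
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "LoadedKLR":
        return LoadedKLR(doc)


def _json_label(l):
    return int(l) if isinstance(l, (np.integer,)) else l


class LoadedKLR:
    def __init__(self, doc: dict):
        self.columns = doc["columns"]
        self.Xtr = np.asarray(doc["Xtr"], dtype=float)
        self.mean = None if doc["mean"] is None else np.asarray(doc["mean"])
        self.scale = None if doc["scale"] is None else np.asarray(doc["scale"])
        self.alpha = np.asarray(doc["alpha"], dtype=float)
        self.b = float(doc["b"])
        self.lam = doc["lam"]
        self.kernel = KernelSpec(doc["kernel"]["kind"], doc["kernel"]["sigma"])
        self.labels = tuple(doc["labels"])

    def predict(self, X) -> np.ndarray:
        if self.columns is not None and isinstance(X, pd.DataFrame):
            X = X[self.columns]
        Xs = _as_matrix(X)
        if self.mean is not None:
            Xs = (Xs - self.mean) / self.scale
        return expit(kernel_matrix(Xs, self.Xtr, self.kernel) @ self.alpha + self.b)


class MKLR:
    """Multinomial kernel logistic regression (reference-class softmax).

    Penalized multinomial negative log-likelihood, penalty
    (lam/2) * sum_c a_c' K a_c over non-reference classes, minimized by
    cycling IRLS where each class update solves an LS-SVM-structured system
    with diagonal working weights; global step-halving guarantees descent.
    """

    def __init__(self, X, y, lam: float, kernel: KernelSpec | None = None,
                 reference=None, standardize: bool = True):
        if lam <= 0:
            raise KernelError("lam must be > 0")
        self.columns = _columns(X)
        y = np.asarray(y)
        self.classes = list(pd.unique(pd.Series(y)))
        from .data import OUTCOMES
        if set(self.classes) <= set(OUTCOMES):
            self.classes = [c for c in OUTCOMES if c in self.classes]
        if reference is None:
            reference = self.classes[0]
        self.reference = reference
        self.nonref = [c for c in self.classes if c != reference]
        if min((y == c).sum() for c in self.classes) == 0:
            raise KernelError("every class needs at least one case")
        self.Y = np.column_stack([(y == c).astype(float) for c in self.nonref])
        self.standardizer = _Standardizer(X) if standardize else None
        self.Xtr = self.standardizer(X) if standardize else _as_matrix(X)
        self.lam = float(lam)
        self.kernel = kernel or KernelSpec("linear")

    def _probs(self, F: np.ndarray) -> np.ndarray:
        full = np.column_stack([np.zeros(len(F)), F])
        full -= full.max(axis=1, keepdims=True)
        e = np.exp(full)
        return e / e.sum(axis=1, keepdims=True)

    def _objective(self, K, A, b) -> float:
        F = K @ A + b[None, :]
        P = self._probs(F)
        ref_mask = self.Y.sum(axis=1) == 0
        nll = -float(np.sum(np.log(np.clip(P[ref_mask, 0], 1e-300, None))))
        for j in range(len(self.nonref)):
            mask = self.Y[:, j] == 1
            nll -= float(np.sum(np.log(np.clip(P[mask, j + 1], 1e-300, None))))
        pen = 0.5 * self.lam * float(np.sum(A * (K @ A)))
        return nll + pen

    def fit(self, maxiter: int = 200, tol: float = 1e-8) -> "MKLRResults":
        n, J = self.Y.shape
        K = kernel_matrix(self.Xtr, self.Xtr, self.kernel)
        K = K + (JITTER_REL * np.trace(K) / n) * np.eye(n)
        A = np.zeros((n, J))
        b = np.zeros(J)
        obj = self._objective(K, A, b)
        converged = False
        it = 0
        for it in range(1, maxiter + 1):
            A_new = A.copy()
            b_new = b.copy()
            F = K @ A + b[None, :]
            P = self._probs(F)[:, 1:]
            for j in range(J):
                w = np.clip(P[:, j] * (1.0 - P[:, j]), 1e-10, None)
                z = F[:, j] + (self.Y[:, j] - P[:, j]) / w
                bj, aj = _klr_step(K, z, w, self.lam)
                A_new[:, j] = aj
                b_new[j] = bj
            t = 1.0
            for _ in range(30):
                A_try = A + t * (A_new - A)
                b_try = b + t * (b_new - b)
                obj_try = self._objective(K, A_try, b_try)
                if obj_try <= obj + 1e-12:
                    break
                t *= 0.5
            delta = obj - obj_try
            A, b, obj = A_try, b_try, obj_try
            if abs(delta) < tol:
                converged = True
                break
        return MKLRResults(self, A, b, K, obj, it, converged)


class MKLRResults:
    def __init__(self, model: MKLR, A, b, K, objective, iterations, converged):
        self.model = model
        self.A = A
        self.b = b
        self._K = K
        self.objective = float(objective)
        self.iterations = iterations
        self.converged = converged
        self.lam = model.lam
        self.kernel = model.kernel
        self.classes = list(model.classes)
        self.reference = model.reference

    def predict(self, X=None) -> pd.DataFrame:
        """Per-case class probabilities (columns in canonical class order)."""
        if X is None:
            F = self._K @ self.A + self.b[None, :]
        else:
            if self.model.columns is not None and isinstance(X, pd.DataFrame):
                X = X[self.model.columns]
            Xs = self.model.standardizer(X) if self.model.standardizer else _as_matrix(X)
            F = kernel_matrix(Xs, self.model.Xtr, self.kernel) @ self.A + self.b[None, :]
        P = self.model._probs(F)
        cols = [self.reference] + list(self.model.nonref)
        return pd.DataFrame(P, columns=cols)[self.classes]

    def to_dict(self) -> dict:
        m = self.model
        return {
            "kind": "mklr",
            "columns": m.columns,
            "Xtr": m.Xtr.tolist(),
            "mean": m.standardizer.mean.tolist() if m.standardizer else None,
            "scale": m.standardizer.scale.tolist() if m.standardizer else None,
            "A": self.A.tolist(),
            "b": self.b.tolist(),
            "lam": self.lam,
            "kernel": {"kind": self.kernel.kind, "sigma": self.kernel.sigma},
            "classes": [_json_label(c) for c in self.classes],
            "reference": _json_label(self.reference),
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "LoadedMKLR":
        return LoadedMKLR(doc)

    def summary(self) -> str:
        return "\n".join([
            "Multinomial kernel logistic regression (penalized IRLS)",
            f"classes = {self.classes} (reference {self.reference!r})",
            f"kernel = {self.kernel.kind}   lambda = {self.lam:.4g}   n = {self.A.shape[0]}",
            f"converged = {self.converged} after {self.iterations} iterations; "
            f"penalized objective = {self.objective:.6f}",
        ])


class LoadedMKLR:
    def __init__(self, doc: dict):
        self.columns = doc["columns"]
        self.Xtr = np.asarray(doc["Xtr"], dtype=float)
        self.mean = None if doc["mean"] is None else np.asarray(doc["mean"])
        self.scale = None if doc["scale"] is None else np.asarray(doc["scale"])
        self.A = np.asarray(doc["A"], dtype=float)
        self.b = np.asarray(doc["b"], dtype=float)
        self.lam = doc["lam"]
        self.kernel = KernelSpec(doc["kernel"]["kind"], doc["kernel"]["sigma"])
        self.classes = list(doc["classes"])
        self.reference = doc["reference"]
        self.nonref = [c for c in self.classes if c != self.reference]

    def predict(self, X) -> pd.DataFrame:
        if self.columns is not None and isinstance(X, pd.DataFrame):
            X = X[self.columns]
        Xs = _as_matrix(X)
        if self.mean is not None:
            Xs = (Xs - self.mean) / self.scale
        F = kernel_matrix(Xs, self.Xtr, self.kernel) @ self.A + self.b[None, :]
        full = np.column_stack([np.zeros(len(F)), F])
        full -= full.max(axis=1, keepdims=True)
        e = np.exp(full)
        P = e / e.sum(axis=1, keepdims=True)
        return pd.DataFrame(P, columns=[self.reference] + self.nonref)[self.classes]


# ---------------------------------------------------------------------------
# Hyperparameter tuning
# ---------------------------------------------------------------------------

def tune_cv(fit_predict, grid, X, y, folds: int = 5, seed: int = 0, metric=None):
    """Pick the grid point maximizing mean stratified-CV metric.

    Parameters
    ----------
    fit_predict : callable(params, X_train, y_train, X_val) -> scores
        Returns validation scores (higher = more positive) for one fold.
    grid : sequence of parameter dicts (keys among gamma/lam/sigma or others).
    metric : callable(scores, y_val) -> float; default is the c-index.

    Ties go to the most-regularized point: largest ``lam`` (or smallest
    ``gamma``), then largest ``sigma``.
    """
    if len(grid) == 0:
        raise KernelError("empty hyperparameter grid")
    if metric is None:
        from .metrics import c_index

        metric = lambda s, yv: c_index(s, yv).estimate
    y = np.asarray(y)
    Xm = X if isinstance(X, pd.DataFrame) else _as_matrix(X)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    results = []
    for params in grid:
        vals = []
        for tr, va in skf.split(np.zeros(len(y)), y):
            Xtr = Xm.iloc[tr] if isinstance(Xm, pd.DataFrame) else Xm[tr]
            Xva = Xm.iloc[va] if isinstance(Xm, pd.DataFrame) else Xm[va]
            scores = fit_predict(params, Xtr, y[tr], Xva)
            vals.append(metric(np.asarray(scores), y[va]))
        results.append((float(np.mean(vals)), params))

    def reg_key(params):
        return (
            -params.get("lam", 0.0),
            params.get("gamma", np.inf),
            -(params.get("sigma") or 0.0),
        )

    best_score = max(r[0] for r in results)
    tied = [p for s, p in results if s >= best_score - 1e-12]
    tied.sort(key=reg_key)
    return tied[0], dict(results_table=results, best_score=best_score)


def default_gamma_grid(n_points: int = 13) -> list[float]:
    return list(np.logspace(-3, 3, n_points))


def default_lambda_grid(n_points: int = 13) -> list[float]:
    return list(np.logspace(-3, 3, n_points))


def default_sigma_grid(X, n_points: int = 7) -> list[float]:
    med = median_heuristic_sigma(_as_matrix(X))
    return list(med * np.logspace(-1, 1, n_points))
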