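"""One-versus-one decomposition, pairwise coupling, and the nested tree.

Pairwise coupling reconstructs a full event-probability vector pi from the
six one-versus-one conditional estimates pihat_ij = P(event i | case, event
in {i, j}) by solving the linear system

    pi_i = sum_{j != i} pihat_ij (pi_i + pi_j) / (k - 1),   for all i,

subject to sum_i pi_i = 1 and pi_i >= 0.  When the pairwise estimates are
mutually consistent (pihat_ij = pi_i / (pi_i + pi_j) for some simplex pi)
the system recovers that pi exactly; otherwise a nonnegativity-constrained
least-squares solution on the simplex is returned.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy.optimize import lsq_linear

from .data import OUTCOMES, Dataset


class CouplingError(ValueError):
    pass


def pair_list(k: int = 4) -> list[tuple[int, int]]:
    """Unordered event pairs in canonical order (0,1),(0,2),...,(k-2,k-1)."""
    return list(combinations(range(k), 2))


def validate_pairwise(P: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    P = np.asarray(P, dtype=float)
    k = P.shape[0]
    if P.shape != (k, k):
        raise CouplingError("pairwise matrix must be square")
    if np.any((P < -tol) | (P > 1 + tol)):
        raise CouplingError("pairwise probabilities outside [0,1]")
    off = ~np.eye(k, dtype=bool)
    if np.max(np.abs((P + P.T)[off] - 1.0)) > tol:
        raise CouplingError("pihat_ij + pihat_ji must equal 1")
    return P


def couple(P: np.ndarray) -> np.ndarray:
    """Couple a k x k pairwise probability matrix into a simplex vector.

    ``P[i, j]`` is pihat_ij for i != j; the diagonal is ignored.
    """
    P = validate_pairwise(P)
    k = P.shape[0]
    # Row i of the homogeneous system: (k-1) pi_i - sum_{j!=i} pihat_ij (pi_i + pi_j) = 0
    A = np.zeros((k + 1, k))
    for i in range(k):
        A[i, i] = (k - 1) - sum(P[i, j] for j in range(k) if j != i)
        for j in range(k):
            if j != i:
                A[i, j] = -P[i, j]
    A[k, :] = 1.0
    b = np.zeros(k + 1)
    b[k] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    if np.any(pi < 0) or abs(pi.sum() - 1.0) > 1e-8:
        # constrained solve: weight the normalization row heavily, bound to
        # [0, 1], then renormalize exactly onto the simplex
        W = A.copy()
        bw = b.copy()
        W[k, :] *= 1e6
        bw[k] *= 1e6
        res = lsq_linear(W, bw, bounds=(0.0, 1.0))
        pi = res.x
        s = pi.sum()
        pi = pi / s if s > 0 else np.full(k, 1.0 / k)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def pairwise_from_simplex(pi: np.ndarray) -> np.ndarray:
    """Consistent pairwise matrix pihat_ij = pi_i/(pi_i+pi_j) for a simplex pi."""
    pi = np.asarray(pi, dtype=float)
    k = len(pi)
    P = np.full((k, k), 0.5)
    for i, j in pair_list(k):
        denom = pi[i] + pi[j]
        pij = 0.5 if denom == 0 else pi[i] / denom
        P[i, j] = pij
        P[j, i] = 1.0 - pij
    return P


def decompose_1v1(ds: Dataset, classes=OUTCOMES) -> dict[tuple[str, str], Dataset]:
    """Six pairwise training subsets, one per unordered pair of events."""
    counts = ds.class_counts()
    for c in classes:
        if counts.get(c, 0) == 0:
            raise CouplingError(f"class {c!r} has no cases")
    subsets = {}
    for i, j in pair_list(len(classes)):
        pair = (classes[i], classes[j])
        subsets[pair] = ds.subset_classes(pair)
    return subsets


class OneVsOneEnsemble:
    """Six fitted dichotomous models, one per event pair, plus coupling.

    ``models`` maps (event_i, event_j) -> fitted model whose ``predict``
    returns P(event_i | case, event in pair).  Each pair model is applied to
    every case, including cases from outside its pair.
    """

    def __init__(self, models: dict, classes=OUTCOMES, prevalences=None):
        self.classes = list(classes)
        expected = {(self.classes[i], self.classes[j]) for i, j in pair_list(len(self.classes))}
        if set(models) != expected:
            raise CouplingError(f"need exactly the pairs {sorted(expected)}")
        self.models = models
        self.prevalences = prevalences

    def pairwise_matrix(self, X) -> np.ndarray:
        """Per-case stack of pairwise matrices, shape (n, k, k)."""
        k = len(self.classes)
        n = len(X)
        P = np.full((n, k, k), 0.5)
        for i, j in pair_list(k):
            pij = np.asarray(self.models[(self.classes[i], self.classes[j])].predict(X))
            P[:, i, j] = pij
            P[:, j, i] = 1.0 - pij
        return P

    def predict(self, X) -> pd.DataFrame:
        """Coupled polytomous probabilities, one simplex row per case."""
        P = self.pairwise_matrix(X)
        out = np.vstack([couple(P[i]) for i in range(len(P))])
        return pd.DataFrame(out, columns=self.classes)

    def to_dict(self) -> dict:
        return {
            "kind": "one_vs_one",
            "classes": self.classes,
            "coupling": "pairwise-linear-system",
            "models": {
                f"{a}|{b}": m.to_dict() for (a, b), m in self.models.items()
            },
        }

    @classmethod
    def from_dict(cls, doc: dict, loader) -> "OneVsOneEnsemble":
        models = {
            tuple(key.split("|")): loader(sub) for key, sub in doc["models"].items()
        }
        return cls(models, classes=doc["classes"])


class NestedTreeModel:
    """Sequential dichotomies: benign|malignant, then borderline|invasive
    among malignant, then primary|metastatic among invasive.

    With stage probabilities p1, p2, p3 the polytomous probabilities are
    P(benign) = p1, P(borderline) = (1-p1) p2,
    P(primary) = (1-p1)(1-p2) p3, P(metastatic) = (1-p1)(1-p2)(1-p3),
    which sum to one identically.
    """

    STAGES = ("benign_vs_malignant", "borderline_vs_invasive", "primary_vs_metastatic")

    def __init__(self, stage_models: dict, classes=OUTCOMES):
        missing = [s for s in self.STAGES if s not in stage_models]
        if missing:
            raise CouplingError(f"missing stage model(s) {missing}")
        self.models = stage_models
        self.classes = list(classes)

    def predict(self, X) -> pd.DataFrame:
        p1 = np.asarray(self.models["benign_vs_malignant"].predict(X))
        p2 = np.asarray(self.models["borderline_vs_invasive"].predict(X))
        p3 = np.asarray(self.models["primary_vs_metastatic"].predict(X))
        probs = np.column_stack([
            p1,
            (1 - p1) * p2,
            (1 - p1) * (1 - p2) * p3,
            (1 - p1) * (1 - p2) * (1 - p3),
        ])
        return pd.DataFrame(probs, columns=self.classes)

    def to_dict(self) -> dict:
        return {
            "kind": "nested_tree",
            "classes": self.classes,
            "models": {s: m.to_dict() for s, m in self.models.items()},
        }

    @classmethod
    def from_dict(cls, doc: dict, loader) -> "NestedTreeModel":
        return cls({s: loader(sub) for s, sub in doc["models"].items()},
                   classes=doc["classes"])


def predict_nested_tree(p1, p2, p3) -> np.ndarray:
    """Polytomous probabilities from the three stage probabilities."""
    p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p1, p2, p3))
    return np.column_stack([
        p1, (1 - p1) * p2, (1 - p1) * (1 - p2) * p3, (1 - p1) * (1 - p2) * (1 - p3)
    ])
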