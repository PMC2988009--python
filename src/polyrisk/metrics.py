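"""Discrimination and calibration metrics for polytomous risk models.

The dichotomous c-index is the Mann-Whitney estimate of P(score_pos >
score_neg) (ties credit 1/2), i.e. the area under the ROC curve.  Its
polytomous extension considers quadruples holding one case of each event:
for every quadruple, count the events whose own-event predicted probability
is strictly largest for the case of that event (0..4), average over all
N1*N2*N3*N4 quadruples, and divide by 4.  The value 0.25 corresponds to
random discrimination and 1 to perfect separation.  The quadruple average
factorizes over events, so the index is computed in O(n log n) per event
rather than by brute-force enumeration; the enumeration is retained as a
testing oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from statsmodels.nonparametric.smoothers_lowess import lowess

from .data import OUTCOMES


class MetricError(ValueError):
    pass


@dataclass
class CIndexResult:
    estimate: float
    n_pos: int
    n_neg: int
    ties: int
    ci: tuple[float, float] | None = None
    ci_level: float | None = None

    def __float__(self):
        return self.estimate


@dataclass
class PolyCIndexResult:
    estimate: float
    counts: dict
    mode: str
    per_event: dict | None = None
    ci: tuple[float, float] | None = None
    ci_level: float | None = None

    def __float__(self):
        return self.estimate


def c_index(scores, labels, positive=None) -> CIndexResult:
    """Dichotomous c-index (area under the ROC curve), ties credited 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if positive is None:
        if set(uniq) <= {0, 1}:
            positive = 1
        elif set(uniq) <= {-1, 1}:
            positive = 1
        elif len(uniq) == 2:
            positive = uniq[1]
        else:
            raise MetricError(f"cannot infer positive label from {uniq}")
    pos = labels == positive
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise MetricError("both classes must be present")
    r = rankdata(scores)  # midranks: ties get credit 1/2 automatically
    auc = (r[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    # tie count across pos/neg pairs (diagnostic)
    ties = 0
    vals, counts = np.unique(scores, return_counts=True)
    for v, c in zip(vals, counts):
        if c > 1:
            ties += int((pos & (scores == v)).sum() * ((~pos) & (scores == v)).sum())
    return CIndexResult(float(auc), n_pos, n_neg, ties)


def _as_prob_frame(probs, classes) -> pd.DataFrame:
    if isinstance(probs, pd.DataFrame):
        missing = [c for c in classes if c not in probs.columns]
        if missing:
            raise MetricError(f"probability columns missing {missing}")
        return probs[list(classes)]
    arr = np.asarray(probs, dtype=float)
    if arr.shape[1] != len(classes):
        raise MetricError("probability matrix has wrong number of columns")
    return pd.DataFrame(arr, columns=list(classes))


def polytomous_c_index(probs, labels, classes=OUTCOMES) -> PolyCIndexResult:
    """Polytomous c-index by the factorized algorithm.

    For each event e, the quadruple indicator for e factorizes into a
    product over the other events f of the fraction of f-cases whose
    predicted probability for e is strictly smaller than that of the e-case;
    tied values earn no credit.
    """
    classes = list(classes)
    frame = _as_prob_frame(probs, classes)
    labels = np.asarray(labels)
    counts = {c: int((labels == c).sum()) for c in classes}
    if min(counts.values()) == 0:
        missing = [c for c in classes if counts[c] == 0]
        raise MetricError(f"event class(es) {missing} absent")
    per_event = {}
    for e in classes:
        s = frame[e].to_numpy()
        own = s[labels == e]
        frac_prod = np.ones(len(own))
        for f in classes:
            if f == e:
                continue
            other = np.sort(s[labels == f])
            # strictly smaller count via searchsorted on the sorted scores
            smaller = np.searchsorted(other, own, side="left")
            frac_prod *= smaller / len(other)
        per_event[e] = float(frac_prod.mean())
    est = float(np.mean([per_event[e] for e in classes]))
    return PolyCIndexResult(est, counts, "exact-factorized", per_event)


def polytomous_c_index_brute(probs, labels, classes=OUTCOMES) -> PolyCIndexResult:
    """Brute-force quadruple enumeration (testing oracle; O(N1*N2*N3*N4))."""
    classes = list(classes)
    frame = _as_prob_frame(probs, classes)
    labels = np.asarray(labels)
    idx = {c: np.flatnonzero(labels == c) for c in classes}
    counts = {c: len(idx[c]) for c in classes}
    if min(counts.values()) == 0:
        raise MetricError("every event class must be present")
    S = frame.to_numpy().tolist()  # plain lists: the loop below is hot
    k = len(classes)
    total = 0
    n_quad = 0
    for quad in product(*(idx[c] for c in classes)):
        n_quad += 1
        for e_pos in range(k):
            own = S[quad[e_pos]][e_pos]
            if all(S[quad[o]][e_pos] < own for o in range(k) if o != e_pos):
                total += 1
    est = total / (k * n_quad)
    return PolyCIndexResult(float(est), counts, "brute-force")


def pairwise_c_indexes(probs, labels, classes=OUTCOMES, ensemble=None,
                       X=None) -> dict[tuple[str, str], CIndexResult]:
    """Dichotomous c-index for every pair of events (six values for k=4).

    For a one-versus-one ``ensemble`` (with ``X`` supplied) the score for
    pair (i, j) is the pair model's own output; otherwise the renormalized
    polytomous ratio pi_i / (pi_i + pi_j) is used.
    """
    classes = list(classes)
    labels = np.asarray(labels)
    from .coupling import pair_list

    out = {}
    if ensemble is not None:
        if X is None:
            raise MetricError("ensemble scoring needs the predictor table X")
        Pmat = ensemble.pairwise_matrix(X)
    else:
        frame = _as_prob_frame(probs, classes)
    for i, j in pair_list(len(classes)):
        ci, cj = classes[i], classes[j]
        mask = (labels == ci) | (labels == cj)
        if (labels == ci).sum() == 0 or (labels == cj).sum() == 0:
            raise MetricError(f"pair ({ci}, {cj}): one class absent")
        y = (labels[mask] == ci).astype(int)
        if ensemble is not None:
            score = Pmat[mask, i, j]
        else:
            pi = frame[ci].to_numpy()[mask]
            pj = frame[cj].to_numpy()[mask]
            denom = pi + pj
            score = np.where(denom > 0, pi / np.where(denom > 0, denom, 1.0), 0.5)
        out[(ci, cj)] = c_index(score, y, positive=1)
    return out


def benign_vs_malignant_c(probs, labels, classes=OUTCOMES) -> CIndexResult:
    """c-index of 1 - P(benign) against the benign/malignant dichotomy."""
    classes = list(classes)
    frame = _as_prob_frame(probs, classes)
    labels = np.asarray(labels)
    y = (labels != classes[0]).astype(int)  # malignant = positive
    if y.min() == y.max():
        raise MetricError("need both benign and malignant cases")
    return c_index(1.0 - frame[classes[0]].to_numpy(), y, positive=1)


@dataclass
class CalibrationCurve:
    grid: np.ndarray
    observed: np.ndarray
    span: float
    event: str | None
    n: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"predicted": self.grid, "observed": self.observed})

    def plot(self, path=None, ax=None):
        """Calibration graph against the identity line (perfect calibration)."""
        import matplotlib

        if path is not None:
            matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4, 4))
        ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=1)
        ax.plot(self.grid, self.observed, c="C0")
        ax.set_xlabel("predicted probability")
        ax.set_ylabel("observed proportion")
        if self.event:
            ax.set_title(f"{self.event} (n={self.n})")
        ax.set_xlim(0, 1)
        ax.set_ylim(0, 1)
        if path is not None:
            ax.figure.savefig(path, dpi=120, bbox_inches="tight")
            plt.close(ax.figure)
        return ax


def calibration_curve(p, y, span: float = 0.75, event=None,
                      gridsize: int = 100) -> CalibrationCurve:
    """Loess (locally weighted linear) calibration curve of outcome on risk.

    Smooths the event indicator against the predicted probability on a
    ``gridsize``-point grid spanning the observed predictions, clipped to
    [0, 1].
    """
    p = np.asarray(p, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(p) < 10:
        raise MetricError("need at least 10 cases for a calibration curve")
    if p.max() - p.min() <= 0:
        raise MetricError("constant predicted probabilities: no curve")
    grid = np.linspace(p.min(), p.max(), gridsize)
    smoothed = lowess(y, p, frac=span, it=0, xvals=grid)
    return CalibrationCurve(grid, np.clip(smoothed, 0.0, 1.0), span, event, len(p))


# ---------------------------------------------------------------------------
# Bootstrap confidence intervals
# ---------------------------------------------------------------------------

def _stratified_resample(rng, labels, strata) -> np.ndarray:
    idx = []
    for s in strata:
        pool = np.flatnonzero(labels == s)
        idx.append(rng.choice(pool, size=len(pool), replace=True))
    return np.concatenate(idx)


def bootstrap_ci(metric, labels, B: int = 1000, level: float = 0.95,
                 seed: int = 0, strata=None):
    """Percentile bootstrap CI of ``metric(indices)``, resampling cases
    stratified by event class.

    ``metric`` receives an integer index array into the original cases and
    returns a scalar.  Resamples that lose an event class are redrawn (cap
    10*B attempts).
    """
    if B < 100:
        raise MetricError("B must be at least 100")
    labels = np.asarray(labels)
    if strata is None:
        strata = list(pd.unique(pd.Series(labels)))
    rng = np.random.default_rng(seed)
    stats_ = []
    attempts = 0
    while len(stats_) < B:
        attempts += 1
        if attempts > 10 * B:
            raise MetricError("too many degenerate bootstrap resamples")
        idx = _stratified_resample(rng, labels, strata)
        try:
            stats_.append(float(metric(idx)))
        except MetricError:
            continue
    lo, hi = np.quantile(stats_, [(1 - level) / 2, 1 - (1 - level) / 2])
    return float(lo), float(hi)


def bootstrap_diff_ci(metric_a, metric_b, labels, B: int = 1000,
                      level: float = 0.95, seed: int = 0, strata=None):
    """Percentile CI of metric_a - metric_b using shared paired resamples."""
    if B < 100:
        raise MetricError("B must be at least 100")
    labels = np.asarray(labels)
    if strata is None:
        strata = list(pd.unique(pd.Series(labels)))
    rng = np.random.default_rng(seed)
    diffs = []
    attempts = 0
    while len(diffs) < B:
        attempts += 1
        if attempts > 10 * B:
            raise MetricError("too many degenerate bootstrap resamples")
        idx = _stratified_resample(rng, labels, strata)
        try:
            diffs.append(float(metric_a(idx)) - float(metric_b(idx)))
        except MetricError:
            continue
    lo, hi = np.quantile(diffs, [(1 - level) / 2, 1 - (1 - level) / 2])
    return float(lo), float(hi)
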