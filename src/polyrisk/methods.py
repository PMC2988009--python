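"""The named polytomous methods under one fit/predict/validate contract.

Eight assembled methods:

====================  ==========================  =========================
name                  decomposition               base family / selection
====================  ==========================  =========================
MLR                   all-at-once                 multinomial LR, LR track
LR-PC                 1-vs-1 + pairwise coupling  logistic, LR track
LR-PC2                1-vs-1 + pairwise coupling  logistic, R1U-track lists
MKLR                  all-at-once                 multinomial KLR
KLR-PC                1-vs-1 + pairwise coupling  kernel LR
LSSVM-PC              1-vs-1 + pairwise coupling  Bayesian LS-SVM
stepLR-PC             1-vs-1 + pairwise coupling  logistic, stepwise p=0.05
nested-LR             nested tree of dichotomies  logistic
====================  ==========================  =========================

The packaged default variable lists transcribe the study's published
per-model selections, so that a fixed-list fit on synthetic data mirrors the
published model structure; the automatic selection tracks (lr-criteria,
r1u, stepwise) can be requested instead.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import metrics
from .coupling import NestedTreeModel, OneVsOneEnsemble, decompose_1v1, pair_list
from .data import OUTCOMES, Dataset
from .kernels import (
    KLR,
    KLRResults,
    KernelSpec,
    LSSVM,
    LSSVMResults,
    LoadedKLR,
    LoadedLSSVM,
    LoadedMKLR,
    MKLR,
    MKLRResults,
    default_gamma_grid,
    default_lambda_grid,
    default_sigma_grid,
    tune_cv,
)
from .linear import (
    LogisticModel,
    LogisticResults,
    LoadedLogistic,
    LoadedMultinomial,
    MultinomialModel,
    MultinomialResults,
)
from .selection import (
    CandidateSet,
    backward_select,
    evaluate_candidate,
    r1u_forward,
    stepwise_select,
)

PAIRS = [(OUTCOMES[i], OUTCOMES[j]) for i, j in pair_list(4)]

# Published per-model variable lists (LR-selection track and R1U track).
MLR_VARIABLES = [
    "ascites", "solid_diameter", "age", "solid_tumor", "irregular_walls",
    "personal_history", "bilateral", "lesion_diameter", "papillary_flow",
]
LR_PC_VARIABLES = {
    ("benign", "borderline"): ["lesion_diameter", "papillary_flow", "unilocular"],
    ("benign", "primary_invasive"): ["ascites", "solid_diameter", "age",
                                     "irregular_walls", "papillary_flow"],
    ("benign", "metastatic"): ["ascites", "solid_diameter", "age",
                               "solid_tumor", "irregular_walls"],
    ("borderline", "primary_invasive"): ["ascites", "solid_diameter", "bilateral"],
    ("borderline", "metastatic"): ["ascites", "solid_diameter", "solid_tumor"],
    ("primary_invasive", "metastatic"): ["ascites", "personal_history", "solid_tumor"],
}
R1U_VARIABLES = {
    ("benign", "borderline"): ["age", "personal_history", "lesion_diameter",
                               "papillary_flow", "papillation_count"],
    ("benign", "primary_invasive"): ["ascites", "solid_diameter", "age",
                                     "irregular_walls", "acoustic_shadows"],
    ("benign", "metastatic"): ["ascites", "solid_diameter", "solid_tumor",
                               "irregular_walls"],
    ("borderline", "primary_invasive"): ["ascites", "solid_diameter", "age",
                                         "irregular_walls", "bilateral"],
    ("borderline", "metastatic"): ["ascites", "solid_diameter", "solid_tumor"],
    ("primary_invasive", "metastatic"): ["ascites", "solid_tumor", "personal_history"],
}
MKLR_VARIABLES = sorted({v for vs in R1U_VARIABLES.values() for v in vs})
NESTED_VARIABLES = {
    "benign_vs_malignant": MLR_VARIABLES,
    "borderline_vs_invasive": ["ascites", "solid_diameter", "bilateral", "solid_tumor"],
    "primary_vs_metastatic": ["ascites", "personal_history", "solid_tumor"],
}

METHOD_NAMES = ("MLR", "LR-PC", "LR-PC2", "MKLR", "KLR-PC", "LSSVM-PC",
                "stepLR-PC", "nested-LR")


@dataclass
class MethodSpec:
    """Recipe for one polytomous method."""

    name: str
    family: str  # logistic | multinomial | lssvm | klr | mklr
    decomposition: str  # all_at_once | one_vs_one | nested
    selection: str = "fixed"  # fixed | lr-criteria | r1u | stepwise
    variables: object = None  # list (all_at_once) or dict keyed by pair/stage
    kernel: str = "linear"
    sigma: float | None = None
    gamma_grid: list = field(default_factory=list)
    lambda_grid: list = field(default_factory=list)
    tune_folds: int = 5
    max_vars: int = 5

    def __post_init__(self):
        if self.family in ("multinomial", "mklr") and self.decomposition != "all_at_once":
            raise ValueError(f"{self.family} requires all_at_once decomposition")
        if self.decomposition == "all_at_once" and self.family in ("logistic", "klr", "lssvm"):
            raise ValueError("all_at_once needs a true polytomous family")


def default_method_specs() -> dict[str, MethodSpec]:
    """The eight packaged method recipes with published variable lists."""
    return {
        "MLR": MethodSpec("MLR", "multinomial", "all_at_once",
                          variables=list(MLR_VARIABLES)),
        "LR-PC": MethodSpec("LR-PC", "logistic", "one_vs_one",
                            variables={p: list(v) for p, v in LR_PC_VARIABLES.items()}),
        "LR-PC2": MethodSpec("LR-PC2", "logistic", "one_vs_one",
                             variables={p: list(v) for p, v in R1U_VARIABLES.items()}),
        "MKLR": MethodSpec("MKLR", "mklr", "all_at_once",
                           variables=list(MKLR_VARIABLES)),
        "KLR-PC": MethodSpec("KLR-PC", "klr", "one_vs_one",
                             variables={p: list(v) for p, v in R1U_VARIABLES.items()}),
        "LSSVM-PC": MethodSpec("LSSVM-PC", "lssvm", "one_vs_one",
                               variables={p: list(v) for p, v in R1U_VARIABLES.items()}),
        "stepLR-PC": MethodSpec("stepLR-PC", "logistic", "one_vs_one",
                                selection="stepwise"),
        "nested-LR": MethodSpec("nested-LR", "logistic", "nested",
                                variables={s: list(v) for s, v in NESTED_VARIABLES.items()}),
    }


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _fit_pair_model(family, X, y_pair, positive, spec: MethodSpec, seed: int):
    """Fit one dichotomous component with its hyperparameter tuning."""
    if family == "logistic":
        return LogisticModel(X, y_pair, positive=positive).fit()
    y01 = (np.asarray(y_pair) == positive).astype(int)
    kernel = (KernelSpec("linear") if spec.kernel == "linear"
              else KernelSpec("gaussian", spec.sigma or default_sigma_grid(X, 1)[0]))
    if family == "lssvm":
        grid = [{"gamma": g} for g in (spec.gamma_grid or default_gamma_grid(7))]

        def fp(params, Xtr, ytr, Xva):
            fit = LSSVM(Xtr, 2.0 * ytr - 1.0, params["gamma"], kernel).fit()
            return fit.posterior(Xva)

        best, _ = tune_cv(fp, grid, X, y01, folds=spec.tune_folds, seed=seed)
        fit = LSSVM(X, y_pair, best["gamma"], kernel, positive=positive).fit()
        return fit
    if family == "klr":
        grid = [{"lam": l} for l in (spec.lambda_grid or default_lambda_grid(7))]

        def fp(params, Xtr, ytr, Xva):
            fit = KLR(Xtr, ytr, params["lam"], kernel).fit()
            return fit.predict(Xva)

        best, _ = tune_cv(fp, grid, X, y01, folds=spec.tune_folds, seed=seed)
        return KLR(X, y_pair, best["lam"], kernel, positive=positive).fit()
    raise ValueError(f"unknown dichotomous family {family!r}")


def _select_pair_variables(spec: MethodSpec, subsets, seed: int) -> dict:
    """Resolve the per-pair variable lists for a one-versus-one method."""
    if spec.selection == "fixed":
        if not isinstance(spec.variables, dict):
            raise ValueError("fixed 1-vs-1 selection needs a per-pair dict")
        return {p: list(v) for p, v in spec.variables.items()}
    out = {}
    for pair, sub in subsets.items():
        X = sub.X()
        y01 = (sub.outcome == pair[0]).to_numpy().astype(int)
        if spec.selection == "stepwise":
            out[pair] = stepwise_select(X, y01).names
        elif spec.selection == "r1u":
            trace = r1u_forward(X, 2.0 * y01 - 1.0, min(spec.max_vars, X.shape[1]),
                                spec.gamma_grid or None)
            # best prefix by LOO c-index, shorter on ties
            cs = [s.c_index for s in trace.steps]
            k = int(np.argmax(cs)) + 1
            out[pair] = trace.variables[:k]
        elif spec.selection == "lr-criteria":
            cands = [stepwise_select(X, y01), backward_select(X, y01)]
            # prefer the candidate with the better CV c-index on the pair
            from .selection import _pair_cv_c

            cache: dict = {}
            scored = [(_pair_cv_c(X, y01, c.names, 5, spec.tune_folds, seed, cache),
                       -len(c.names), c.names) for c in cands]
            scored.sort(reverse=True)
            out[pair] = list(scored[0][2])
        else:
            raise ValueError(f"unknown selection track {spec.selection!r}")
        if not out[pair]:  # guard: empty selection, keep the single best LR var
            out[pair] = [X.columns[0]]
    return out


class PolytomousMethod:
    """Model object for one named method; ``fit`` returns the fitted results."""

    def __init__(self, spec: MethodSpec, train: Dataset):
        counts = train.class_counts()
        if (counts == 0).any():
            raise ValueError(f"training data missing class(es) "
                             f"{list(counts.index[counts == 0])}")
        self.spec = spec
        self.train = train

    def fit(self, seed: int = 1) -> "PolytomousResults":
        spec, train = self.spec, self.train
        meta = {
            "seed": int(seed),
            "n_per_class": {k: int(v) for k, v in train.class_counts().items()},
        }
        if spec.decomposition == "all_at_once":
            if spec.selection == "fixed":
                variables = list(spec.variables)
            elif spec.selection == "lr-criteria":
                variables = _lr_criteria_all_at_once(train, seed)
            else:
                raise ValueError(f"selection {spec.selection!r} unsupported for "
                                 "all-at-once methods")
            X, y = train.X(variables), train.outcome.to_numpy()
            if spec.family == "multinomial":
                component = MultinomialModel(X, y).fit()
            else:  # mklr
                kernel = (KernelSpec("linear") if spec.kernel == "linear"
                          else KernelSpec("gaussian", spec.sigma))
                grid = spec.lambda_grid or default_lambda_grid(7)

                def fp(params, Xtr, ytr, Xva):
                    # looser IRLS tolerance inside tuning only: c-index
                    # ranking is insensitive to the last digits of the fit
                    fit = MKLR(Xtr, ytr, params["lam"], kernel).fit(
                        maxiter=40, tol=1e-6)
                    return fit.predict(Xva)

                def poly_metric(scores, yva):
                    return metrics.polytomous_c_index(
                        pd.DataFrame(scores, columns=fp_classes), yva,
                        classes=fp_classes).estimate

                fp_classes = [c for c in OUTCOMES]
                best, _ = tune_cv(fp, [{"lam": l} for l in grid], X, y,
                                  folds=spec.tune_folds, seed=seed,
                                  metric=poly_metric)
                component = MKLR(X, y, best["lam"], kernel).fit()
            return PolytomousResults(spec, component, {"all": variables}, meta)

        if spec.decomposition == "one_vs_one":
            subsets = decompose_1v1(train)
            variables = _select_pair_variables(spec, subsets, seed)
            models = {}
            for pair, sub in subsets.items():
                X = sub.X(variables[pair])
                models[pair] = _fit_pair_model(spec.family, X,
                                               sub.outcome.to_numpy(), pair[0],
                                               spec, seed)
            component = OneVsOneEnsemble(models)
            return PolytomousResults(spec, component, variables, meta)

        if spec.decomposition == "nested":
            stages = spec.variables or {}
            df = train.df
            y = train.outcome
            stage_models = {}
            # stage 1: benign vs malignant on everyone
            v1 = list(stages.get("benign_vs_malignant", train.predictors))
            y1 = np.where(y == "benign", "benign", "malignant")
            stage_models["benign_vs_malignant"] = LogisticModel(
                train.X(v1), y1, positive="benign").fit()
            # stage 2: borderline vs invasive among malignant
            mask2 = (y != "benign").to_numpy()
            v2 = list(stages.get("borderline_vs_invasive", train.predictors))
            y2 = np.where(y[mask2] == "borderline", "borderline", "invasive")
            stage_models["borderline_vs_invasive"] = LogisticModel(
                df.loc[mask2, v2], y2, positive="borderline").fit()
            # stage 3: primary vs metastatic among invasive
            mask3 = y.isin(["primary_invasive", "metastatic"]).to_numpy()
            v3 = list(stages.get("primary_vs_metastatic", train.predictors))
            stage_models["primary_vs_metastatic"] = LogisticModel(
                df.loc[mask3, v3], y[mask3].to_numpy(),
                positive="primary_invasive").fit()
            component = NestedTreeModel(stage_models)
            variables = {"benign_vs_malignant": v1, "borderline_vs_invasive": v2,
                         "primary_vs_metastatic": v3}
            return PolytomousResults(spec, component, variables, meta)

        raise ValueError(f"unknown decomposition {spec.decomposition!r}")


def _lr_criteria_all_at_once(train: Dataset, seed: int) -> list[str]:
    """LR-track selection for the all-at-once model: union candidates from
    per-pair stepwise/backward runs, scored by AIC/BIC plus CV c-index."""
    subsets = decompose_1v1(train)
    union_fwd, union_bwd = [], []
    for pair, sub in subsets.items():
        y01 = (sub.outcome == pair[0]).to_numpy().astype(int)
        for v in stepwise_select(sub.X(), y01).names:
            if v not in union_fwd:
                union_fwd.append(v)
        for v in backward_select(sub.X(), y01).names:
            if v not in union_bwd:
                union_bwd.append(v)
    cands = [CandidateSet(union_fwd, "stepwise"), CandidateSet(union_bwd, "backward")]
    reports = [evaluate_candidate(c, train, runs=3, folds=5,
                                  seeds=list(range(seed, seed + 3))) for c in cands]
    scored = sorted(
        zip(reports, cands),
        key=lambda rc: (-float(np.mean(list(rc[0].cv_c_per_event.values()))), rc[0].aic),
    )
    best = scored[0][1].names
    return best if best else list(train.predictors)[:1]


@dataclass
class ValidationReport:
    method: str
    n: int
    n_predictors: int
    poly_c: float
    poly_ci: tuple | None
    per_event_c: dict
    pairwise_c: dict
    benign_vs_malignant_c: float
    calibration: dict

    def table3_row(self) -> dict:
        row = {
            "model": self.method,
            "n_predictors": self.n_predictors,
            "n": self.n,
            "polytomous_c_index": round(self.poly_c, 4),
        }
        if self.poly_ci is not None:
            row["ci_low"], row["ci_high"] = (round(v, 4) for v in self.poly_ci)
        return row

    def table4_row(self) -> dict:
        row = {"model": self.method}
        for (a, b), res in self.pairwise_c.items():
            row[f"{a}_vs_{b}"] = round(res.estimate, 4)
        row["benign_vs_malignant"] = round(self.benign_vs_malignant_c, 4)
        return row


class PolytomousResults:
    """Fitted polytomous method: prediction, validation, serialization."""

    def __init__(self, spec: MethodSpec, component, variables: dict, meta: dict):
        self.spec = spec
        self.component = component
        self.variables = variables
        self.meta = meta

    @property
    def name(self) -> str:
        return self.spec.name

    @property
    def n_predictors(self) -> int:
        distinct = set()
        for v in self.variables.values():
            distinct.update(v)
        return len(distinct)

    def predict(self, X) -> pd.DataFrame:
        """Polytomous probabilities, one simplex row per case."""
        if isinstance(X, Dataset):
            X = X.df
        if isinstance(self.component, (MultinomialResults, LoadedMultinomial)):
            return self.component.predict(X[self.variables["all"]])
        if isinstance(self.component, (MKLRResults, LoadedMKLR)):
            return self.component.predict(X[self.variables["all"]])
        return self.component.predict(X)

    def validate(self, ds: Dataset, bootstrap: int = 0, level: float = 0.95,
                 seed: int = 0, calibration: bool = True) -> ValidationReport:
        """Discrimination + calibration report on an evaluation dataset."""
        probs = self.predict(ds)
        y = ds.outcome.to_numpy()
        poly = metrics.polytomous_c_index(probs, y)
        ci = None
        if bootstrap:
            P = probs.to_numpy()

            def stat(idx):
                return metrics.polytomous_c_index(
                    pd.DataFrame(P[idx], columns=list(OUTCOMES)), y[idx]).estimate

            ci = metrics.bootstrap_ci(stat, y, B=bootstrap, level=level, seed=seed)
        if isinstance(self.component, OneVsOneEnsemble):
            pw = metrics.pairwise_c_indexes(None, y, ensemble=self.component, X=ds.df)
        else:
            pw = metrics.pairwise_c_indexes(probs, y)
        bvm = metrics.benign_vs_malignant_c(probs, y)
        calib = {}
        if calibration:
            for e in OUTCOMES:
                p_e = probs[e].to_numpy()
                if p_e.max() - p_e.min() > 0 and len(p_e) >= 10:
                    calib[e] = metrics.calibration_curve(
                        p_e, (y == e).astype(float), event=e)
        return ValidationReport(self.name, len(ds), self.n_predictors,
                                poly.estimate, ci, poly.per_event, pw,
                                bvm.estimate, calib)

    def summary(self) -> str:
        lines = [
            f"Polytomous method {self.name}",
            f"family = {self.spec.family}   decomposition = {self.spec.decomposition}"
            f"   selection = {self.spec.selection}",
            f"distinct predictors = {self.n_predictors}   "
            f"n per class = {self.meta.get('n_per_class')}",
        ]
        for key, vs in self.variables.items():
            tag = " vs ".join(key) if isinstance(key, tuple) else key
            lines.append(f"  {tag}: {', '.join(vs)}")
        return "\n".join(lines)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        spec = asdict(self.spec)
        if isinstance(self.spec.variables, dict):
            spec["variables"] = {
                "|".join(k) if isinstance(k, tuple) else k: list(v)
                for k, v in self.spec.variables.items()
            }
        variables = {
            "|".join(k) if isinstance(k, tuple) else k: list(v)
            for k, v in self.variables.items()
        }
        if isinstance(self.component, (OneVsOneEnsemble, NestedTreeModel)):
            comp = self.component.to_dict()
        else:
            comp = self.component.to_dict()
        return {"spec": spec, "variables": variables, "meta": self.meta,
                "component": comp}

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "PolytomousResults":
        with open(path, encoding="utf-8") as fh:
            doc = json.load(fh)
        spec_doc = dict(doc["spec"])
        if isinstance(spec_doc.get("variables"), dict):
            spec_doc["variables"] = {
                tuple(k.split("|")) if "|" in k else k: v
                for k, v in spec_doc["variables"].items()
            }
        spec = MethodSpec(**spec_doc)
        variables = {
            tuple(k.split("|")) if "|" in k else k: v
            for k, v in doc["variables"].items()
        }
        comp = _load_component(doc["component"])
        return cls(spec, comp, variables, doc["meta"])


def _load_component(doc: dict):
    kind = doc["kind"]
    if kind == "one_vs_one":
        return OneVsOneEnsemble.from_dict(doc, _load_component)
    if kind == "nested_tree":
        return NestedTreeModel.from_dict(doc, _load_component)
    if kind == "logistic":
        return LoadedLogistic(doc)
    if kind == "multinomial":
        return LoadedMultinomial(doc)
    if kind == "lssvm":
        return LoadedLSSVM(doc)
    if kind == "klr":
        return LoadedKLR(doc)
    if kind == "mklr":
        return LoadedMKLR(doc)
    raise ValueError(f"unknown component kind {kind!r}")


def develop(spec: MethodSpec, train: Dataset, seed: int = 1) -> PolytomousResults:
    """Run the method recipe's selection track and fit all components."""
    return PolytomousMethod(spec, train).fit(seed)
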