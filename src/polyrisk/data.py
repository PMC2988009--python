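"""Case-level data model, CSV I/O, stratified splitting and synthetic generation.

The central container is :class:`Dataset`, a thin validated wrapper around a
:class:`pandas.DataFrame` with a typed predictor schema and a four-level
outcome (``benign``, ``borderline``, ``primary_invasive``, ``metastatic``).
A :class:`ClassProfile` describes class prevalences and class-conditional
predictor distributions; :func:`generate_synthetic` draws a dataset from it.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, stats

OUTCOMES = ("benign", "borderline", "primary_invasive", "metastatic")
OUTCOME_COL = "outcome"
CENTER_COL = "center"
KINDS = ("continuous", "ordinal", "binary")


class DataError(ValueError):
    """Raised for schema or value violations in case-level data."""


def _validate_column(values: pd.Series, name: str, kind: str) -> None:
    if kind not in KINDS:
        raise DataError(f"unknown predictor kind {kind!r} for column {name!r}")
    arr = pd.to_numeric(values, errors="coerce")
    bad = arr.index[arr.isna()]
    if len(bad):
        raise DataError(
            f"column {name!r}: unparseable value {values.loc[bad[0]]!r} at row {bad[0]}"
        )
    a = arr.to_numpy(dtype=float)
    if not np.all(np.isfinite(a)):
        row = int(np.flatnonzero(~np.isfinite(a))[0])
        raise DataError(f"column {name!r}: non-finite value at row {row}")
    if kind == "binary" and not np.all(np.isin(a, (0.0, 1.0))):
        row = int(np.flatnonzero(~np.isin(a, (0.0, 1.0)))[0])
        raise DataError(f"column {name!r}: binary value not in {{0,1}} at row {row}")
    if kind == "ordinal" and (np.any(a < 0) or np.any(a != np.round(a))):
        row = int(np.flatnonzero((a < 0) | (a != np.round(a)))[0])
        raise DataError(f"column {name!r}: ordinal value not a nonnegative integer at row {row}")


@dataclass
class Dataset:
    """Validated table of cases with typed predictors and a 4-level outcome.

    Parameters
    ----------
    df : pandas.DataFrame
        One row per case.  Must contain every schema column plus an
        ``outcome`` column with labels from :data:`OUTCOMES`; an optional
        ``center`` column carries the recruiting-center label.
    schema : dict
        Mapping predictor name -> kind (``continuous`` | ``ordinal`` |
        ``binary``).
    """

    df: pd.DataFrame
    schema: dict[str, str]

    def __post_init__(self) -> None:
        if OUTCOME_COL not in self.df.columns:
            raise DataError(f"missing outcome column {OUTCOME_COL!r}")
        bad = ~self.df[OUTCOME_COL].isin(OUTCOMES)
        if bad.any():
            row = self.df.index[bad][0]
            raise DataError(
                f"unknown outcome label {self.df.loc[row, OUTCOME_COL]!r} at row {row}"
            )
        for name, kind in self.schema.items():
            if name not in self.df.columns:
                raise DataError(f"schema column {name!r} missing from data")
            _validate_column(self.df[name], name, kind)
        self.df = self.df.reset_index(drop=True)

    # -- basic accessors ---------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    @property
    def predictors(self) -> list[str]:
        return list(self.schema)

    @property
    def outcome(self) -> pd.Series:
        return self.df[OUTCOME_COL]

    def X(self, columns: list[str] | None = None) -> pd.DataFrame:
        return self.df[list(columns) if columns is not None else self.predictors]

    def class_counts(self) -> pd.Series:
        """Per-class case counts N1..N4 in canonical outcome order."""
        vc = self.df[OUTCOME_COL].value_counts()
        return pd.Series([int(vc.get(c, 0)) for c in OUTCOMES], index=list(OUTCOMES))

    def filter_rows(self, predicate) -> "Dataset":
        """Subset cases; ``predicate`` maps the underlying frame to a boolean mask.

        String predicates are evaluated with :meth:`pandas.DataFrame.eval`
        (e.g. ``"ascites == 0"``).
        """
        if isinstance(predicate, str):
            try:
                mask = self.df.eval(predicate)
            except Exception as exc:  # unknown column, syntax
                raise DataError(f"bad row predicate {predicate!r}: {exc}") from exc
        else:
            mask = predicate(self.df)
        mask = np.asarray(mask, dtype=bool)
        return Dataset(self.df.loc[mask].reset_index(drop=True), dict(self.schema))

    def subset_classes(self, classes) -> "Dataset":
        mask = self.df[OUTCOME_COL].isin(list(classes)).to_numpy()
        return Dataset(self.df.loc[mask].reset_index(drop=True), dict(self.schema))


def read_csv(path, schema: dict[str, str]) -> Dataset:
    """Read a case-level CSV (comma, UTF-8, header row) against a schema."""
    df = pd.read_csv(path, encoding="utf-8")
    missing = [c for c in list(schema) + [OUTCOME_COL] if c not in df.columns]
    if missing:
        raise DataError(f"missing column(s) {missing} in {path}")
    return Dataset(df, dict(schema))


def write_csv(ds: Dataset, path) -> None:
    """Write a dataset as UTF-8 CSV with a header row, one record per case."""
    ds.df.to_csv(path, index=False, encoding="utf-8")


@dataclass
class SplitResult:
    train: Dataset
    test: Dataset
    fraction: float
    strata: list[str]
    seed: int


def stratified_split(ds: Dataset, fraction: float, strata=None, seed: int = 0) -> SplitResult:
    """Split cases into training/test sets, stratified on the given columns.

    Within each stratum ``round-half-up(fraction * n)`` cases go to training;
    which cases is randomized under ``seed``.  Default strata are outcome
    plus the center label when present.
    """
    if not 0.0 < fraction < 1.0:
        raise DataError(f"fraction must be in (0,1), got {fraction}")
    if strata is None:
        strata = [OUTCOME_COL] + ([CENTER_COL] if CENTER_COL in ds.df.columns else [])
    strata = list(strata)
    for col in strata:
        if col not in ds.df.columns:
            raise DataError(f"stratum column {col!r} absent")
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    for _, grp in ds.df.groupby(strata, sort=True):
        n = len(grp)
        n_train = int(np.floor(fraction * n + 0.5))  # round half up
        order = rng.permutation(n)
        train_idx.extend(grp.index[order[:n_train]])
    mask = np.zeros(len(ds.df), dtype=bool)
    mask[train_idx] = True
    train = Dataset(ds.df.loc[mask].reset_index(drop=True), dict(ds.schema))
    test = Dataset(ds.df.loc[~mask].reset_index(drop=True), dict(ds.schema))
    return SplitResult(train, test, fraction, strata, seed)


# ---------------------------------------------------------------------------
# Class profiles and the synthetic generator
# ---------------------------------------------------------------------------

@dataclass
class ClassProfile:
    """Class prevalences plus per-class generative targets per predictor.

    ``variables[name]`` is ``{"kind": ..., "params": {class: {...}}}`` where
    the per-class parameter block holds ``median`` (+ optional ``log_sd``,
    ``zero_mass``, ``nonzero_median``) for continuous variables, ``mean`` for
    ordinals and ``prop`` for binaries.
    """

    prevalences: dict[str, float]
    variables: dict[str, dict]
    defaults: dict = field(default_factory=lambda: {"log_sd": 0.5, "ordinal_max": 4})

    def __post_init__(self) -> None:
        prev = np.array([self.prevalences[c] for c in OUTCOMES], dtype=float)
        if np.any(prev < 0) or abs(prev.sum() - 1.0) > 1e-9:
            raise DataError("prevalences must be nonnegative and sum to 1")
        for name, spec in self.variables.items():
            kind = spec.get("kind")
            if kind not in KINDS:
                raise DataError(f"variable {name!r}: unknown kind {kind!r}")
            for cls in OUTCOMES:
                p = spec["params"][cls]
                if kind == "binary" and not 0.0 <= p["prop"] <= 1.0:
                    raise DataError(f"variable {name!r}/{cls}: proportion outside [0,1]")
                if kind == "continuous" and p["median"] < 0:
                    raise DataError(f"variable {name!r}/{cls}: negative median")

    @property
    def schema(self) -> dict[str, str]:
        return {name: spec["kind"] for name, spec in self.variables.items()}

    @classmethod
    def from_yaml(cls, path) -> "ClassProfile":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        return cls(doc["prevalences"], doc["variables"], doc.get("defaults", {}))

    def to_yaml(self, path) -> None:
        doc = {
            "prevalences": self.prevalences,
            "defaults": self.defaults,
            "variables": self.variables,
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


def default_profile() -> ClassProfile:
    """The packaged profile transcribing the study cohort's descriptives."""
    ref = importlib.resources.files("polyrisk.profiles") / "default_profile.yaml"
    with importlib.resources.as_file(ref) as path:
        return ClassProfile.from_yaml(path)


def largest_remainder_counts(prevalences: np.ndarray, n: int) -> np.ndarray:
    """Integer class counts by exact proportional (largest-remainder) allocation."""
    quota = np.asarray(prevalences, dtype=float) * n
    counts = np.floor(quota).astype(int)
    short = n - counts.sum()
    # ties broken by class order (stable argsort on negated remainder)
    order = np.argsort(-(quota - counts), kind="stable")
    counts[order[:short]] += 1
    return counts


def _truncated_poisson_pmf(lam: float, kmax: int) -> np.ndarray:
    k = np.arange(kmax + 1)
    pmf = stats.poisson.pmf(k, lam)
    return pmf / pmf.sum()


def truncated_poisson_lambda(mean: float, kmax: int) -> float:
    """Rate of a Poisson conditioned on {0..kmax} with the given mean."""
    if not 0.0 <= mean < kmax:
        raise DataError(f"ordinal mean {mean} outside [0, {kmax})")
    if mean == 0.0:
        return 0.0

    def f(lam):
        pmf = _truncated_poisson_pmf(lam, kmax)
        return pmf @ np.arange(kmax + 1) - mean

    return optimize.brentq(f, 1e-12, 50.0 + 10 * kmax)


def _draw_variable(spec: dict, cls: str, n: int, rng: np.random.Generator,
                   defaults: dict) -> np.ndarray:
    kind = spec["kind"]
    p = spec["params"][cls]
    if kind == "binary":
        return (rng.random(n) < p["prop"]).astype(int)
    if kind == "ordinal":
        kmax = int(defaults.get("ordinal_max", 4))
        lam = truncated_poisson_lambda(float(p["mean"]), kmax)
        pmf = _truncated_poisson_pmf(lam, kmax)
        return rng.choice(kmax + 1, size=n, p=pmf)
    # continuous: log-normal with exact theoretical median, optional point
    # mass at zero (structural zeros) for variables whose target median is 0
    log_sd = float(p.get("log_sd", defaults.get("log_sd", 0.5)))
    median = float(p["median"])
    zero_mass = float(p.get("zero_mass", 0.0))
    if median == 0.0 and zero_mass == 0.0:
        return np.zeros(n)
    base_median = median if median > 0 else float(p.get("nonzero_median", 1.0))
    x = base_median * np.exp(log_sd * rng.standard_normal(n))
    if zero_mass > 0:
        x[rng.random(n) < zero_mass] = 0.0
    return x


def generate_class(profile: ClassProfile, cls: str, n: int, seed: int) -> pd.DataFrame:
    """Draw ``n`` cases of a single outcome class (without the outcome column)."""
    if cls not in OUTCOMES:
        raise DataError(f"unknown class {cls!r}")
    rng = np.random.default_rng(seed)
    cols = {
        name: _draw_variable(spec, cls, n, rng, profile.defaults)
        for name, spec in profile.variables.items()
    }
    return pd.DataFrame(cols)


def generate_synthetic(profile: ClassProfile, n: int, seed: int,
                       multinomial_counts: bool = False) -> Dataset:
    """Generate a synthetic dataset emulating the profile's class structure.

    Class counts follow exact largest-remainder allocation of the prevalence
    vector (or a multinomial draw when ``multinomial_counts``); predictors
    are drawn independently within class from the profile's families.
    """
    if n < len(OUTCOMES):
        raise DataError(f"n={n} smaller than the number of classes")
    prev = np.array([profile.prevalences[c] for c in OUTCOMES])
    rng = np.random.default_rng(seed)
    if multinomial_counts:
        counts = rng.multinomial(n, prev)
    else:
        counts = largest_remainder_counts(prev, n)
    frames = []
    for cls, cnt in zip(OUTCOMES, counts):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        frame = generate_class(profile, cls, int(cnt), sub_seed)
        frame[OUTCOME_COL] = cls
        frames.append(frame)
    df = pd.concat(frames, ignore_index=True)
    # shuffle rows so class blocks are not contiguous
    df = df.iloc[rng.permutation(len(df))].reset_index(drop=True)
    return Dataset(df, profile.schema)
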