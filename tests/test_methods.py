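"""The assembled named methods: develop, predict, validate, serialize."""

import numpy as np
import pandas as pd
import pytest

import polyrisk as pr
from polyrisk.data import OUTCOMES
from polyrisk.methods import (
    MKLR_VARIABLES,
    MethodSpec,
    PolytomousMethod,
    PolytomousResults,
    default_method_specs,
)


class TestSpecs:
    def test_eight_methods_packaged(self):
        specs = default_method_specs()
        assert set(specs) == {"MLR", "LR-PC", "LR-PC2", "MKLR", "KLR-PC",
                              "LSSVM-PC", "stepLR-PC", "nested-LR"}
        assert len(MKLR_VARIABLES) == 11

    def test_incompatible_decomposition_rejected(self):
        with pytest.raises(ValueError):
            MethodSpec("bad", "multinomial", "one_vs_one")
        with pytest.raises(ValueError):
            MethodSpec("bad", "logistic", "all_at_once")


class TestDevelopPredict:
    def test_fixed_list_respected_and_six_components(self, split):
        res = pr.develop(default_method_specs()["LR-PC"], split.train, seed=1)
        assert len(res.component.models) == 6
        assert res.n_predictors == 10
        res_mlr = pr.develop(default_method_specs()["MLR"], split.train, seed=1)
        assert res_mlr.variables["all"] == default_method_specs()["MLR"].variables

    def test_simplex_rows(self, split):
        res = pr.develop(default_method_specs()["nested-LR"], split.train, seed=1)
        probs = res.predict(split.test).to_numpy()
        assert np.all(probs >= 0)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-10)

    def test_lr_pc_equals_manual_coupling(self, split):
        from polyrisk.coupling import couple

        res = pr.develop(default_method_specs()["LR-PC"], split.train, seed=1)
        X = split.test.df.head(5)
        P = res.component.pairwise_matrix(X)
        manual = np.vstack([couple(P[i]) for i in range(len(P))])
        assert np.allclose(res.predict(X).to_numpy(), manual, atol=1e-12)

    def test_mlr_prediction_delegates_to_multinomial(self, split):
        spec = default_method_specs()["MLR"]
        res = pr.develop(spec, split.train, seed=1)
        direct = pr.fit_multinomial(split.train.X(spec.variables),
                                    split.train.outcome.to_numpy())
        assert np.allclose(res.predict(split.test).to_numpy(),
                           direct.predict(split.test.X(spec.variables)).to_numpy(),
                           atol=1e-10)

    def test_develop_seed_reproducible(self, split, tmp_path):
        a = pr.develop(default_method_specs()["LR-PC2"], split.train, seed=5)
        b = pr.develop(default_method_specs()["LR-PC2"], split.train, seed=5)
        pa, pb = tmp_path / "a.json", tmp_path / "b.json"
        a.save(pa)
        b.save(pb)
        assert pa.read_text() == pb.read_text()

    def test_serialize_load_predict_bit_stable(self, split, tmp_path):
        res = pr.develop(default_method_specs()["nested-LR"], split.train, seed=1)
        path = tmp_path / "m.json"
        res.save(path)
        loaded = PolytomousResults.load(path)
        assert np.array_equal(res.predict(split.test).to_numpy(),
                              loaded.predict(split.test).to_numpy())

    def test_missing_class_rejected(self, small_ds):
        two = small_ds.subset_classes(["benign", "borderline"])
        with pytest.raises(ValueError, match="missing class"):
            PolytomousMethod(default_method_specs()["MLR"], two)

    def test_r1u_track_runs(self, split):
        spec = MethodSpec("LR-PC2", "logistic", "one_vs_one", selection="r1u",
                          max_vars=3, gamma_grid=[0.1, 1.0, 10.0])
        res = pr.develop(spec, split.train, seed=1)
        assert all(1 <= len(v) <= 3 for v in res.variables.values())
        probs = res.predict(split.test).to_numpy()
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-10)


class TestValidate:
    def test_perfect_classifier_fixture_scores_one(self, split):
        class Oracle:
            def predict(self, X):
                onehot = np.eye(4)[[list(OUTCOMES).index(c) for c in X["outcome"]]]
                return pd.DataFrame(onehot, columns=list(OUTCOMES))

        res = PolytomousResults(default_method_specs()["MLR"], None, {"all": []},
                                {})
        res.predict = lambda ds: Oracle().predict(ds.df if hasattr(ds, "df") else ds)
        rep = res.validate(split.test, calibration=False)
        assert rep.poly_c == 1.0
        assert all(r.estimate == 1.0 for r in rep.pairwise_c.values())

    def test_prevalence_only_classifier_is_chance(self, split):
        prev = split.train.class_counts() / len(split.train)

        res = PolytomousResults(default_method_specs()["MLR"], None, {"all": []}, {})
        res.predict = lambda ds: pd.DataFrame(
            np.tile(prev.to_numpy(), (len(ds), 1)), columns=list(OUTCOMES))
        rep = res.validate(split.test, calibration=False)
        assert rep.poly_c == 0.0  # constant rows: every comparison ties
        assert all(r.estimate == 0.5 for r in rep.pairwise_c.values())

    def test_report_rows_and_bootstrap_ci(self, split):
        res = pr.develop(default_method_specs()["LR-PC"], split.train, seed=1)
        rep = res.validate(split.test, bootstrap=120, seed=2)
        row3 = rep.table3_row()
        assert row3["model"] == "LR-PC" and "ci_low" in row3
        assert row3["ci_low"] <= row3["polytomous_c_index"] <= row3["ci_high"]
        row4 = rep.table4_row()
        assert len([k for k in row4 if "_vs_" in k]) == 7  # 6 pairs + ben-vs-mal


class TestQualitativeClaims:
    def test_true_model_near_best_on_mlr_data(self, rng):
        # simulate from a known multinomial model; MLR cannot lose badly to
        # the 1-vs-1 decomposition of the same family on its own data
        n = 3000
        X = pd.DataFrame(rng.normal(size=(n, 3)), columns=["a", "b", "c"])
        B = np.array([[0.0, 1.2, -0.5, 0.0],
                      [-1.0, -0.8, 1.0, 0.6],
                      [-1.5, 0.5, 0.8, -1.0]])
        eta = np.column_stack([np.zeros(n),
                               X.to_numpy() @ B[:, 1:].reshape(3, 3).T + B[:, 0]])
        P = np.exp(eta - eta.max(axis=1, keepdims=True))
        P /= P.sum(axis=1, keepdims=True)
        draws = (P.cumsum(axis=1) < rng.random((n, 1))).sum(axis=1)
        labels = np.array(list(OUTCOMES))[draws]
        df = X.copy()
        df["outcome"] = labels
        ds = pr.Dataset(df, {c: "continuous" for c in ["a", "b", "c"]})
        split = pr.stratified_split(ds, 0.71, seed=1)
        mlr = PolytomousMethod(
            MethodSpec("MLR", "multinomial", "all_at_once",
                       variables=["a", "b", "c"]), split.train).fit(1)
        lrpc = PolytomousMethod(
            MethodSpec("LR-PC", "logistic", "one_vs_one",
                       variables={p: ["a", "b", "c"] for p in mlr_pairs()}),
            split.train).fit(1)
        c_mlr = mlr.validate(split.test, calibration=False).poly_c
        c_lrpc = lrpc.validate(split.test, calibration=False).poly_c
        assert c_mlr >= c_lrpc - 0.03

    def test_pair_specific_signal_favors_1v1(self, rng):
        # one variable only separates borderline from metastatic; under a
        # shared 2-variable budget the pairwise models can exploit it while
        # the all-at-once model must spread its coefficients
        n = 4000
        base = rng.normal(size=n)
        pairvar = rng.normal(size=n)
        labels = rng.choice(list(OUTCOMES), size=n, p=[0.4, 0.2, 0.2, 0.2])
        base = base + np.select(
            [labels == c for c in OUTCOMES], [0.0, 0.6, 1.2, 1.8])
        pairvar = pairvar + np.where(labels == "borderline", 2.0, 0.0) \
            - np.where(labels == "metastatic", 2.0, 0.0)
        df = pd.DataFrame({"base": base, "pairvar": pairvar, "outcome": labels})
        ds = pr.Dataset(df, {"base": "continuous", "pairvar": "continuous"})
        split = pr.stratified_split(ds, 0.71, seed=2)
        mlr = PolytomousMethod(
            MethodSpec("MLR", "multinomial", "all_at_once",
                       variables=["base", "pairvar"]), split.train).fit(1)
        lrpc = PolytomousMethod(
            MethodSpec("LR-PC", "logistic", "one_vs_one",
                       variables={p: ["base", "pairvar"] for p in mlr_pairs()}),
            split.train).fit(1)
        c_mlr = mlr.validate(split.test, calibration=False).poly_c
        c_lrpc = lrpc.validate(split.test, calibration=False).poly_c
        assert c_lrpc >= c_mlr - 0.01


def mlr_pairs():
    from polyrisk.coupling import pair_list

    return [(OUTCOMES[i], OUTCOMES[j]) for i, j in pair_list(4)]
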