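"""Dichotomous and polytomous c-index, calibration curves, bootstrap CIs."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import balanced_labels, random_probs
from polyrisk.data import OUTCOMES
from polyrisk.metrics import (
    MetricError,
    benign_vs_malignant_c,
    bootstrap_ci,
    bootstrap_diff_ci,
    c_index,
    calibration_curve,
    pairwise_c_indexes,
    polytomous_c_index,
    polytomous_c_index_brute,
)


class TestCIndex:
    @pytest.mark.parametrize("scores,labels,expected", [
        ([1, 2, 3, 10, 11], [0, 0, 0, 1, 1], 1.0),        # perfect separation
        ([5, 5, 5, 5], [0, 1, 0, 1], 0.5),                # all tied
        ([3, 1, 2], [1, 0, 1], 1.0),                      # pairs (3,1),(2,1)
        ([1, 2, 3], [1, 0, 1], 0.5),                      # pairs (1,2)=0,(3,2)=1
    ])
    def test_exhaustive_pair_examples(self, scores, labels, expected):
        assert c_index(scores, labels).estimate == pytest.approx(expected)

    def test_single_class_rejected(self):
        with pytest.raises(MetricError):
            c_index([1, 2], [1, 1])

    def test_matches_exhaustive_enumeration(self, rng):
        scores = rng.normal(size=40)
        labels = (rng.random(40) < 0.4).astype(int)
        pairs = [(s1, s0) for s1, l1 in zip(scores, labels) if l1
                 for s0, l0 in zip(scores, labels) if not l0]
        brute = np.mean([1.0 if a > b else 0.5 if a == b else 0.0 for a, b in pairs])
        assert c_index(scores, labels).estimate == pytest.approx(brute, abs=1e-12)


class TestPolytomousCIndex:
    def test_perfect_classifier_scores_one(self):
        labels = balanced_labels(3)
        P = pd.DataFrame(np.eye(4)[np.repeat(np.arange(4), 3)], columns=list(OUTCOMES))
        assert polytomous_c_index(P, labels).estimate == 1.0

    def test_all_uniform_ties_score_zero(self):
        labels = balanced_labels(1)
        P = pd.DataFrame(np.full((4, 4), 0.25), columns=list(OUTCOMES))
        assert polytomous_c_index(P, labels).estimate == 0.0

    def test_two_cases_per_event_matches_16_quadruples(self, rng):
        labels = balanced_labels(2)
        P = random_probs(rng, 8)
        fac = polytomous_c_index(P, labels)
        brute = polytomous_c_index_brute(P, labels)
        assert fac.estimate == pytest.approx(brute.estimate, abs=1e-12)
        assert fac.counts == {c: 2 for c in OUTCOMES}

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_factorized_equals_brute_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(1, 7, size=4)
        labels = np.repeat(list(OUTCOMES), counts)
        P = random_probs(rng, len(labels))
        a = polytomous_c_index(P, labels).estimate
        b = polytomous_c_index_brute(P, labels).estimate
        assert a == pytest.approx(b, abs=1e-12)

    def test_missing_event_rejected(self, rng):
        labels = np.repeat(list(OUTCOMES[:3]), 3)
        with pytest.raises(MetricError):
            polytomous_c_index(random_probs(rng, 9), labels)

    def test_random_classifier_near_quarter(self, rng):
        labels = balanced_labels(100)
        vals = [polytomous_c_index(random_probs(rng, 400), labels).estimate
                for _ in range(10)]
        assert np.mean(vals) == pytest.approx(0.25, abs=0.02)


class TestPairwiseCIndexes:
    def test_perfect_classifier_all_one(self):
        labels = balanced_labels(3)
        P = pd.DataFrame(np.eye(4)[np.repeat(np.arange(4), 3)], columns=list(OUTCOMES))
        out = pairwise_c_indexes(P, labels)
        assert len(out) == 6
        assert all(r.estimate == 1.0 for r in out.values())

    def test_uniform_probs_all_half(self):
        labels = balanced_labels(2)
        P = pd.DataFrame(np.full((8, 4), 0.25), columns=list(OUTCOMES))
        out = pairwise_c_indexes(P, labels)
        assert all(r.estimate == 0.5 for r in out.values())

    def test_matches_restricted_c_index(self, rng):
        labels = balanced_labels(5)
        P = random_probs(rng, 20)
        out = pairwise_c_indexes(P, labels)
        for (a, b), res in out.items():
            mask = (labels == a) | (labels == b)
            pi, pj = P[a].to_numpy()[mask], P[b].to_numpy()[mask]
            manual = c_index(pi / (pi + pj), (labels[mask] == a).astype(int))
            assert res.estimate == pytest.approx(manual.estimate, abs=1e-12)

    def test_label_permutation_equivariance(self, rng):
        labels = balanced_labels(4)
        P = random_probs(rng, 16)
        out = pairwise_c_indexes(P, labels)
        perm = [2, 0, 3, 1]
        re_classes = [OUTCOMES[i] for i in perm]
        out2 = pairwise_c_indexes(P[re_classes], labels, classes=re_classes)
        for (a, b), res in out2.items():
            # reversing a pair swaps both the score and the positive label,
            # so the estimate is unchanged in either orientation
            key = (a, b) if (a, b) in out else (b, a)
            assert res.estimate == pytest.approx(out[key].estimate, abs=1e-12)

    def test_benign_vs_malignant(self):
        labels = np.array(["benign", "benign", "borderline", "metastatic"])
        P = pd.DataFrame([[1, 0, 0, 0], [1, 0, 0, 0], [0, 1, 0, 0], [0, 0, 0, 1.0]],
                         columns=list(OUTCOMES))
        assert benign_vs_malignant_c(P, labels).estimate == 1.0
        Pc = pd.DataFrame(np.full((4, 4), 0.25), columns=list(OUTCOMES))
        assert benign_vs_malignant_c(Pc, labels).estimate == 0.5


class TestCalibration:
    def test_perfectly_calibrated_near_identity(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(0.02, 0.98, size=10_000)
        y = (rng.random(10_000) < p).astype(float)
        curve = calibration_curve(p, y)
        assert np.max(np.abs(curve.observed - curve.grid)) <= 0.05

    def test_all_events_curve_is_one(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(0, 1, size=200)
        curve = calibration_curve(p, np.ones(200))
        assert np.allclose(curve.observed, 1.0)

    def test_constant_predictions_rejected(self):
        with pytest.raises(MetricError):
            calibration_curve(np.full(50, 0.3), np.zeros(50))

    def test_step_outcome_tracks_threshold(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(0, 1, size=5000)
        y = (p > 0.5).astype(float)
        curve = calibration_curve(p, y, span=0.3)
        # far from the step the smooth must be near 0 / near 1
        assert np.all(curve.observed[curve.grid < 0.2] < 0.1)
        assert np.all(curve.observed[curve.grid > 0.8] > 0.9)


class TestBootstrap:
    def test_constant_metric_zero_width(self):
        labels = balanced_labels(5)
        lo, hi = bootstrap_ci(lambda idx: 0.42, labels, B=100, seed=0)
        assert lo == hi == 0.42

    def test_interval_contains_point_estimate(self, rng):
        for _ in range(10):
            labels = balanced_labels(8)
            P = random_probs(rng, 32).to_numpy()

            def stat(idx):
                return polytomous_c_index(
                    pd.DataFrame(P[idx], columns=list(OUTCOMES)), labels[idx]).estimate

            point = stat(np.arange(32))
            lo, hi = bootstrap_ci(stat, labels, B=150, seed=3)
            assert lo - 1e-9 <= point <= hi + 1e-9

    def test_paired_difference_of_identical_models_is_zero(self, rng):
        labels = balanced_labels(6)
        P = random_probs(rng, 24).to_numpy()

        def stat(idx):
            return polytomous_c_index(
                pd.DataFrame(P[idx], columns=list(OUTCOMES)), labels[idx]).estimate

        lo, hi = bootstrap_diff_ci(stat, stat, labels, B=100, seed=1)
        assert lo == hi == 0.0

    def test_coverage_for_normal_mean(self):
        rng = np.random.default_rng(11)
        n, B, sims = 40, 200, 150
        labels = np.zeros(n, dtype=int)  # single stratum: plain resampling
        hits = 0
        for s in range(sims):
            x = rng.normal(size=n)
            lo, hi = bootstrap_ci(lambda idx: x[idx].mean(), labels, B=B, seed=s)
            hits += lo <= 0.0 <= hi
        assert 0.88 <= hits / sims <= 0.99
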