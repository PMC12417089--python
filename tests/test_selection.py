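"""CV harness, incremental feature selection, MI estimators, IMI."""

import numpy as np
import pytest
from sklearn.metrics import mutual_info_score

from nfembed.features import FeatureBlock, FeatureGroupSet
from nfembed.selection import (
    continuous_mutual_information,
    cv_score,
    discrete_mutual_information,
    ifs_search,
    imi_search,
)
from nfembed.stacking import LearnerSpec

CHEAP = LearnerSpec("logistic_regression", {"max_iter": 500})
TREE = LearnerSpec("decision_tree")


def make_group_set(arrays: dict[str, np.ndarray]) -> FeatureGroupSet:
    n = len(next(iter(arrays.values())))
    ids = tuple(f"s{i}" for i in range(n))
    blocks = {}
    for name, a in arrays.items():
        a = np.asarray(a, dtype=float)
        if a.ndim == 1:
            a = a[:, None]
        blocks[name] = FeatureBlock(
            name, ids, a, tuple(f"{name}_{j}" for j in range(a.shape[1]))
        )
    return FeatureGroupSet(blocks)


class TestCvScore:
    def test_perfectly_informative_feature_scores_one(self, rng):
        y = rng.integers(0, 2, 100)
        gs = make_group_set({"leak": y.astype(float)})
        assert cv_score(gs, ("leak",), y, TREE) == 1.0

    def test_noise_feature_scores_near_chance(self):
        scores = []
        for seed in range(3):
            r = np.random.default_rng(seed)
            y = np.repeat([0, 1], 100)
            gs = make_group_set({"noise": r.normal(size=(200, 5))})
            ev = LearnerSpec("logistic_regression", {"max_iter": 500}, seed=seed)
            scores.append(cv_score(gs, ("noise",), y, ev))
        assert abs(np.mean(scores) - 0.5) < 0.15

    def test_deterministic_under_fixed_seed(self, rng):
        y = rng.integers(0, 2, 60)
        gs = make_group_set({"x": rng.normal(size=(60, 3))})
        assert cv_score(gs, ("x",), y, TREE) == cv_score(gs, ("x",), y, TREE)

    def test_regression_metric_is_r2(self, rng):
        x = rng.normal(size=200)
        gs = make_group_set({"x": x})
        score = cv_score(gs, ("x",), 3 * x + 1, LearnerSpec("ridge"))
        assert score > 0.99


class TestIfs:
    def _planted(self, seed, n=120, noise_groups=3):
        r = np.random.default_rng(seed)
        y = r.integers(0, 2, n)
        arrays = {"signal": y.astype(float) + 0.01 * r.normal(size=n)}
        for i in range(noise_groups):
            arrays[f"noise{i}"] = r.normal(size=(n, 4))
        return make_group_set(arrays), y

    def test_planted_group_selected_first_across_seeds(self):
        hits = 0
        for seed in range(20):
            gs, y = self._planted(seed)
            trace = ifs_search(gs, y, LearnerSpec("decision_tree", seed=seed))
            if trace.retained[0] == ("signal",) and "signal" in trace.selection:
                hits += 1
        assert hits >= 18  # >= 90% of 20 seeds

    def test_additive_half_signals_both_selected(self):
        hits = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            f1, f2 = r.normal(size=(2, 200))
            y = (f1 + f2 > 0).astype(int)
            gs = make_group_set(
                {"half_a": f1, "half_b": f2, "noise": r.normal(size=(200, 3))}
            )
            ev = LearnerSpec("logistic_regression", {"max_iter": 500}, seed=seed)
            trace = ifs_search(gs, y, ev)
            if {"half_a", "half_b"} <= set(trace.selection):
                hits += 1
        assert hits >= 18

    def test_trace_structure(self, rng):
        gs, y = self._planted(0, noise_groups=4)  # 5 groups
        trace = ifs_search(gs, y, TREE)
        # exhaustion over G groups evaluates G + (G-1) + ... + 1 sets
        assert trace.n_evaluated == 5 + 4 + 3 + 2 + 1
        for prev, cur in zip(trace.retained, trace.retained[1:]):
            assert cur[:-1] == prev
        assert trace.score == max(s for _, s in trace.all_evaluations())

    def test_single_group_rejected(self, rng):
        gs = make_group_set({"only": rng.normal(size=(30, 2))})
        with pytest.raises(ValueError):
            ifs_search(gs, rng.integers(0, 2, 30), TREE)


class TestDiscreteMi:
    def test_identical_balanced_vectors_give_ln2(self):
        v = np.array([0, 1] * 50)
        assert discrete_mutual_information(v, v) == pytest.approx(np.log(2))

    def test_constant_prediction_gives_zero(self, rng):
        truth = rng.integers(0, 2, 100)
        assert discrete_mutual_information(np.zeros(100), truth) == 0.0

    def test_independent_vectors_near_zero(self):
        r = np.random.default_rng(0)
        a, b = r.integers(0, 2, (2, 10_000))
        assert discrete_mutual_information(a, b) <= 0.01

    def test_symmetry_and_entropy_bound(self, rng):
        a = rng.integers(0, 3, 200)
        b = rng.integers(0, 2, 200)
        mi_ab = discrete_mutual_information(a, b)
        assert mi_ab == pytest.approx(discrete_mutual_information(b, a))

        def entropy(v):
            _, counts = np.unique(v, return_counts=True)
            p = counts / counts.sum()
            return -np.sum(p * np.log(p))

        assert mi_ab <= min(entropy(a), entropy(b)) + 1e-12

    def test_matches_plug_in_reference(self, rng):
        a = rng.integers(0, 4, 300)
        b = rng.integers(0, 3, 300)
        assert discrete_mutual_information(a, b) == pytest.approx(
            mutual_info_score(a, b)
        )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            discrete_mutual_information([0, 1], [0, 1, 0])


class TestContinuousMi:
    def test_self_information_is_large(self):
        x = np.random.default_rng(1).normal(size=500)
        assert continuous_mutual_information(x, x) > 2.0

    def test_independent_vectors_near_zero(self):
        r = np.random.default_rng(2)
        assert continuous_mutual_information(r.normal(size=500), r.normal(size=500)) <= 0.05

    def test_never_negative(self):
        r = np.random.default_rng(3)
        for _ in range(5):
            mi = continuous_mutual_information(r.normal(size=30), r.normal(size=30))
            assert mi >= 0.0

    def test_multivariate_predictions_accepted(self):
        r = np.random.default_rng(4)
        y = r.normal(size=300)
        preds = np.column_stack([y + 0.1 * r.normal(size=300), r.normal(size=300)])
        assert continuous_mutual_information(preds, y) > 1.0

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            continuous_mutual_information([1.0, 2.0], [1.0, 2.0], k=3)


class TestImi:
    def _xor_data(self, seed, n=240):
        r = np.random.default_rng(seed)
        X = r.integers(0, 2, (n, 2)).astype(float)
        y = (X[:, 0] != X[:, 1]).astype(int)
        return X, y

    def test_memorizing_candidate_selected_alone(self):
        X, y = self._xor_data(0)
        candidates = [
            LearnerSpec("logistic_regression", {"max_iter": 200}),  # linear: blind to XOR
            LearnerSpec("decision_tree"),
        ]
        trace = imi_search(candidates, X[:150], y[:150], X[150:], y[150:], "classification")
        assert trace.selection == ("decision_tree",)
        assert trace.score == pytest.approx(np.log(2), abs=0.05)

    def test_all_constant_candidates_fall_back_to_first_singleton(self, rng):
        # zero features force every learner to a constant prediction
        X = np.zeros((60, 1))
        y = np.repeat([0, 1], 30)
        candidates = [
            LearnerSpec("logistic_regression"),
            LearnerSpec("decision_tree"),
        ]
        trace = imi_search(candidates, X[:40], y[:40], X[40:], y[40:], "classification")
        assert trace.score == 0.0
        assert trace.selection == ("logistic_regression",)

    def test_regression_planted_learner_first(self):
        r = np.random.default_rng(5)
        X = r.normal(size=(300, 3))
        y = np.sin(3 * X[:, 0]) + X[:, 1] ** 2  # nonlinear: linear models fail
        candidates = [
            LearnerSpec("ridge"),
            LearnerSpec("random_forest_regressor", {"n_estimators": 50}),
        ]
        trace = imi_search(candidates, X[:200], y[:200], X[200:], y[200:], "regression")
        assert trace.retained[0] == ("random_forest_regressor",)

    def test_trace_extends_by_one_learner_per_round(self):
        X, y = self._xor_data(1)
        candidates = [LearnerSpec("decision_tree"), LearnerSpec("knn"),
                      LearnerSpec("logistic_regression", {"max_iter": 200})]
        trace = imi_search(candidates, X[:150], y[:150], X[150:], y[150:], "classification")
        assert trace.n_evaluated == 3 + 2 + 1
        for prev, cur in zip(trace.retained, trace.retained[1:]):
            assert cur[:-1] == prev

    def test_failing_candidate_skipped_with_warning(self, caplog, rng):
        X = rng.normal(size=(40, 2))
        y = rng.integers(0, 2, 40)
        bad = LearnerSpec("knn", {"n_neighbors": 1000})  # more neighbors than samples
        with caplog.at_level("WARNING", logger="nfembed"):
            trace = imi_search(
                [bad, LearnerSpec("decision_tree")], X[:25], y[:25], X[25:], y[25:],
                "classification",
            )
        assert trace.selection == ("decision_tree",) or "decision_tree" in trace.selection
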