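"""Binary relevance, classifier chains, ranked ordering, grid search,
persistence."""

import numpy as np
import pytest

from pathpred import (
    BinaryLearnerSpec,
    BinaryRelevance,
    ClassifierChain,
    RankingConfig,
    grid_search_cv,
    load_model,
    rank_chain_order,
    save_model,
)
from pathpred.exceptions import ConfigError, ConsistencyError, ValidationError
from pathpred.metrics import prf1
from pathpred.multilabel import (
    predict_binary_relevance,
    predict_classifier_chain,
    train_binary_relevance,
    train_classifier_chain,
)

from conftest import lookup_spec, small_xgb

MAJORITY = BinaryLearnerSpec.make("majority")
COL0 = BinaryLearnerSpec.make("col0_threshold")
LASTC = BinaryLearnerSpec.make("last_coordinate")
ZERO = BinaryLearnerSpec.make("zero")


def separable_problem(n=80, t=4, seed=0):
    """Labels j = sign of feature j, plus distractor features."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, t + 3))
    Y = np.where(X[:, :t] > 0, 1, -1).astype(np.int8)
    return X, Y


class TestBinaryRelevance:
    def test_single_label_degenerate(self):
        X, Y = separable_problem(t=1)
        br = BinaryRelevance(learner=MAJORITY).fit(X, Y)
        assert br.n_labels_ == 1
        assert br.predict(X).shape == (X.shape[0], 1)

    def test_majority_learner_predicts_column_majority(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 4))
        Y = np.where(rng.random((30, 5)) < [0.8, 0.2, 0.9, 0.1, 0.5], 1, -1)
        br = BinaryRelevance(learner=MAJORITY).fit(X, Y)
        pred = br.predict(X)
        for j in range(5):
            maj = 1 if np.mean(Y[:, j]) > 0 else -1
            assert (pred[:, j] == maj).all()

    def test_predictions_match_direct_scorer_loop(self):
        X, Y = separable_problem(seed=2)
        br = BinaryRelevance(learner=small_xgb()).fit(X, Y)
        Xq, _ = separable_problem(n=25, seed=3)
        pred = br.predict(Xq)
        for i in range(Xq.shape[0]):
            for j, scorer in enumerate(br.scorers_):
                s = scorer.scores(Xq[i : i + 1])[0]
                assert pred[i, j] == (1 if s > 0 else -1)

    def test_score_exactly_zero_predicts_absent(self):
        X, Y = separable_problem()
        br = BinaryRelevance(learner=ZERO).fit(X, Y)
        assert (br.predict(X) == -1).all()
        assert all(not s for s in br.predict_label_sets(X))

    def test_label_column_permutation_permutes_scorers(self):
        X, Y = separable_problem(seed=4)
        perm = np.array([2, 0, 3, 1])
        a = BinaryRelevance(learner=small_xgb(), random_state=7).fit(X, Y)
        b = BinaryRelevance(learner=small_xgb(), random_state=7).fit(X, Y[:, perm])
        assert np.array_equal(b.predict(X), a.predict(X)[:, perm])

    def test_independence_of_label_columns(self):
        X, Y = separable_problem(seed=5)
        full = BinaryRelevance(learner=small_xgb(), random_state=0).fit(X, Y)
        dropped = BinaryRelevance(learner=small_xgb(), random_state=0).fit(X, Y[:, :-1])
        assert np.array_equal(
            full.decision_function(X)[:, :-1], dropped.decision_function(X)
        )

    def test_invalid_labels_rejected(self):
        X = np.zeros((4, 2))
        with pytest.raises(ValidationError, match="outside"):
            BinaryRelevance(learner=MAJORITY).fit(X, np.array([[0, 1]] * 4))

    def test_query_layout_mismatch(self):
        X, Y = separable_problem()
        br = BinaryRelevance(learner=MAJORITY).fit(X, Y)
        with pytest.raises(ConsistencyError):
            br.predict(X[:, :-1])

    def test_functional_wrappers(self):
        X, Y = separable_problem(t=2)
        model = train_binary_relevance(X, Y, learner=MAJORITY)
        pred, sets = predict_binary_relevance(model, X, label_ids=["P1", "P2"])
        assert pred.shape == Y.shape
        assert all(s <= {"P1", "P2"} for s in map(set, sets))


class TestClassifierChain:
    def test_first_position_equals_br_scorer(self):
        X, Y = separable_problem(seed=6)
        order = np.array([2, 0, 1, 3])
        cc = ClassifierChain(learner=small_xgb(), order=order, random_state=3).fit(X, Y)
        br = BinaryRelevance(learner=small_xgb(), random_state=3).fit(X, Y)
        # position 1 is trained on unaugmented features: same scorer as BR's
        assert np.array_equal(cc.scorers_[0].scores(X), br.scorers_[2].scores(X))

    def test_hand_traced_copy_chain(self):
        # t=2, identity order, scorer returns the last input coordinate:
        # position 2 sees [x, eta_1] so label 2's prediction copies label 1's
        rng = np.random.default_rng(7)
        X = rng.normal(size=(40, 3))
        y1 = np.where(X[:, -1] > 0, 1, -1)
        Y = np.column_stack([y1, y1]).astype(np.int8)
        cc = ClassifierChain(learner=LASTC, order=[0, 1]).fit(X, Y)
        pred = cc.predict(X)
        assert np.array_equal(pred[:, 1], pred[:, 0])
        # and position-2 training targets are the augmented coordinate itself
        aug = np.hstack([X, Y[:, :1].astype(float)])
        s = cc.scorers_[1].scores(aug)
        assert np.array_equal(np.where(s > 0, 1, -1), Y[:, 1])

    def test_augmentation_blind_learner_equals_br(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(60, 5))
        Y = np.where(rng.random((60, 6)) < 0.3, 1, -1).astype(np.int8)
        br = BinaryRelevance(learner=COL0).fit(X, Y)
        for order in (np.arange(6), np.array([5, 3, 1, 0, 2, 4])):
            cc = ClassifierChain(learner=COL0, order=order).fit(X, Y)
            assert np.array_equal(cc.predict(X), br.predict(X))

    def test_order_independence_for_blind_scorers(self):
        X, Y = separable_problem(t=4, seed=9)
        p1 = ClassifierChain(learner=COL0, order=[0, 1, 2, 3]).fit(X, Y).predict(X)
        p2 = ClassifierChain(learner=COL0, order=[3, 1, 0, 2]).fit(X, Y).predict(X)
        assert np.array_equal(p1, p2)

    def test_constant_positive_scorers_predict_all_labels(self):
        X, _ = separable_problem(t=3)
        cc = ClassifierChain(learner=MAJORITY, order=[2, 1, 0]).fit(
            X, np.ones((X.shape[0], 3), dtype=np.int8)
        )
        sets = cc.predict_label_sets(X, label_ids=["a", "b", "c"])
        assert all(set(s) == {"a", "b", "c"} for s in sets)

    def test_non_bijection_order_rejected(self):
        X, Y = separable_problem(t=3)
        with pytest.raises(ValidationError):
            ClassifierChain(learner=MAJORITY, order=[0, 0, 2]).fit(X, Y)

    def test_random_order_is_seeded_permutation(self):
        X, Y = separable_problem(t=4)
        a = ClassifierChain(learner=MAJORITY, order="random", random_state=5).fit(X, Y)
        b = ClassifierChain(learner=MAJORITY, order="random", random_state=5).fit(X, Y)
        assert np.array_equal(a.order_, b.order_)
        assert np.array_equal(np.sort(a.order_), np.arange(4))

    def test_functional_wrappers(self):
        X, Y = separable_problem(t=2)
        model = train_classifier_chain(X, Y, learner=COL0, order=[1, 0])
        pred, sets = predict_classifier_chain(model, X)
        assert pred.shape == Y.shape


class TestRankChainOrder:
    def test_descending_sort_of_constructed_scores(self):
        # scorers reproduce predetermined predictions: label 1 perfect,
        # label 2 middling, label 0 poor -> order (1, 2, 0)
        rng = np.random.default_rng(10)
        n, t = 50, 3
        Y = np.where(rng.random((n, t)) < 0.5, 1, -1).astype(np.int8)
        P = Y.copy()
        flip0 = rng.choice(n, size=40, replace=False)
        P[flip0, 0] *= -1
        flip2 = rng.choice(n, size=12, replace=False)
        P[flip2, 2] *= -1
        X = np.arange(n, dtype=float)[:, None]  # row-id feature
        spec = lookup_spec("rank3", P.astype(float))
        order = rank_chain_order(X, Y, spec, RankingConfig(valid_fraction=0.3, seed=1))
        assert list(order) == [1, 2, 0]

    def test_full_tie_gives_identity_order(self):
        X, Y = separable_problem(t=5, seed=11)
        Ysame = np.repeat(Y[:, :1], 5, axis=1)  # all labels identical
        order = rank_chain_order(X, Ysame, COL0, RankingConfig(seed=2))
        assert list(order) == [0, 1, 2, 3, 4]

    def test_matches_independent_recomputation(self):
        from sklearn.metrics import f1_score

        X, Y = separable_problem(n=120, t=6, seed=12)
        cfg = RankingConfig(valid_fraction=0.25, seed=3)
        order = rank_chain_order(X, Y, small_xgb(), cfg)
        # oracle: same split, own BR, sklearn per-label F1, reference sort
        n_valid = int(round(cfg.valid_fraction * X.shape[0]))
        perm = np.random.default_rng(cfg.seed).permutation(X.shape[0])
        vi, ti = perm[:n_valid], perm[n_valid:]
        br = BinaryRelevance(learner=small_xgb(), random_state=cfg.seed).fit(X[ti], Y[ti])
        f1 = f1_score((Y[vi] == 1).astype(int), (br.predict(X[vi]) == 1).astype(int),
                      average=None, zero_division=0)
        expected = sorted(range(6), key=lambda j: (-f1[j], j))
        assert list(order) == expected

    def test_f1_along_order_non_increasing(self):
        X, Y = separable_problem(n=100, t=5, seed=13)
        cfg = RankingConfig(valid_fraction=0.3, seed=4)
        order = rank_chain_order(X, Y, small_xgb(), cfg)
        assert np.array_equal(np.sort(order), np.arange(5))
        n_valid = int(round(cfg.valid_fraction * X.shape[0]))
        perm = np.random.default_rng(cfg.seed).permutation(X.shape[0])
        vi, ti = perm[:n_valid], perm[n_valid:]
        br = BinaryRelevance(learner=small_xgb(), random_state=cfg.seed).fit(X[ti], Y[ti])
        _, _, f1 = prf1(Y[vi], br.predict(X[vi]), granularity="per_label", empty_both=0.0)
        assert np.all(np.diff(f1[order]) <= 1e-12)

    def test_degenerate_split_rejected(self):
        X, Y = separable_problem(n=4, t=2)
        with pytest.raises(ConfigError):
            rank_chain_order(X, Y, MAJORITY, RankingConfig(valid_fraction=0.01, seed=0))
        with pytest.raises(ConfigError):
            RankingConfig(valid_fraction=1.5)


class TestGridSearch:
    def test_single_setting_returns_it_with_fold_scores(self):
        X, Y = separable_problem(n=40, t=2)
        best, report = grid_search_cv(X, Y, [MAJORITY], k=4, seed=0)
        assert best == MAJORITY
        assert len(report["results"][0]["fold_scores"]) == 4

    def test_dominance(self):
        X, Y = separable_problem(n=40, t=2)
        best, _ = grid_search_cv(X, Y, [ZERO, COL0], k=3, seed=0)
        assert best == COL0  # constant-absent learner scores 0 everywhere

    def test_fold_scores_match_manual_loop(self):
        from sklearn.model_selection import KFold

        X, Y = separable_problem(n=36, t=3, seed=14)
        grid = [small_xgb(2, 5), small_xgb(3, 5)]
        k, seed = 3, 6
        _, report = grid_search_cv(X, Y, grid, k=k, seed=seed)
        for spec, res in zip(grid, report["results"]):
            manual = []
            for ti, vi in KFold(n_splits=k, shuffle=True, random_state=seed).split(X):
                br = BinaryRelevance(learner=spec, random_state=seed).fit(X[ti], Y[ti])
                _, _, f1 = prf1(Y[vi], br.predict(X[vi]), granularity="sample_average")
                manual.append(f1)
            assert res["fold_scores"] == pytest.approx(manual)
            assert res["mean"] == pytest.approx(np.mean(manual))

    def test_config_errors(self):
        X, Y = separable_problem(n=10, t=2)
        with pytest.raises(ConfigError):
            grid_search_cv(X, Y, [MAJORITY], k=1)
        with pytest.raises(ConfigError):
            grid_search_cv(X, Y, [MAJORITY], k=11)
        with pytest.raises(ConfigError):
            grid_search_cv(X, Y, [], k=2)


class TestPersistence:
    def test_br_round_trip(self, tmp_path):
        X, Y = separable_problem(seed=15)
        br = BinaryRelevance(learner=small_xgb()).fit(X, Y)
        save_model(br, tmp_path / "m", fingerprint="fp1", label_ids=["a", "b", "c", "d"])
        back = load_model(tmp_path / "m", expect_fingerprint="fp1")
        Xq, _ = separable_problem(n=30, seed=16)
        assert np.array_equal(back.predict(Xq), br.predict(Xq))
        assert np.array_equal(back.decision_function(Xq), br.decision_function(Xq))

    def test_chain_round_trip_preserves_order(self, tmp_path):
        X, Y = separable_problem(seed=17)
        cc = ClassifierChain(learner=small_xgb(), order=[3, 1, 2, 0]).fit(X, Y)
        save_model(cc, tmp_path / "m")
        back = load_model(tmp_path / "m")
        assert np.array_equal(back.order_, cc.order_)
        Xq, _ = separable_problem(n=20, seed=18)
        assert np.array_equal(back.predict(Xq), cc.predict(Xq))

    def test_fingerprint_mismatch_rejected(self, tmp_path):
        X, Y = separable_problem()
        br = BinaryRelevance(learner=small_xgb()).fit(X, Y)
        save_model(br, tmp_path / "m", fingerprint="fp1")
        with pytest.raises(ConsistencyError, match="fingerprint"):
            load_model(tmp_path / "m", expect_fingerprint="other")

    def test_unfitted_model_rejected(self, tmp_path):
        with pytest.raises(ValidationError):
            save_model(BinaryRelevance(), tmp_path / "m")

    def test_toy_scorer_not_serializable(self, tmp_path):
        X, Y = separable_problem()
        br = BinaryRelevance(learner=MAJORITY).fit(X, Y)
        with pytest.raises(ValidationError, match="serialization"):
            save_model(br, tmp_path / "m")

    def test_sklearn_params_round_trip(self):
        cc = ClassifierChain(valid_fraction=0.3, random_state=9)
        params = cc.get_params()
        assert params["valid_fraction"] == 0.3
        cc2 = ClassifierChain(**params)
        assert cc2.random_state == 9
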