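"""Reference classifiers (naive Bayes, 1-NN) and library adapters."""

import numpy as np
import pytest

from screenratio.classifiers import (
    ClassifierSpec,
    fit,
    knn1_predict,
    nb_posterior,
    predict,
)


class TestSpec:
    def test_defaults_mirror_conventions(self):
        svm = ClassifierSpec("svm-poly")
        assert svm.params["complexity"] == 1.0
        assert svm.params["epsilon"] == 1.0e-12
        assert svm.params["degree"] == 2
        rf = ClassifierSpec("rf")
        assert rf.params["n_trees"] == 10
        assert rf.params["max_depth"] is None
        assert rf.params["seed"] == 1

    def test_unknown_algorithm_and_params_rejected(self):
        with pytest.raises(ValueError):
            ClassifierSpec("svm-rbf")
        with pytest.raises(ValueError):
            ClassifierSpec("nb", {"trees": 5})

    def test_overrides_merge_with_defaults(self):
        spec = ClassifierSpec("rf", {"n_trees": 25})
        assert spec.params["n_trees"] == 25
        assert spec.params["seed"] == 1


def two_class(n=40, d=16, seed=0):
    rng = np.random.default_rng(seed)
    tpos = (rng.random(d) < 0.7).astype(np.uint8)
    tneg = (rng.random(d) < 0.2).astype(np.uint8)
    Xp = tpos ^ (rng.random((n // 2, d)) < 0.1).astype(np.uint8)
    Xn = tneg ^ (rng.random((n // 2, d)) < 0.1).astype(np.uint8)
    X = np.vstack([Xp, Xn])
    y = np.r_[np.ones(n // 2, dtype=np.uint8), np.zeros(n // 2, dtype=np.uint8)]
    return X, y


class TestFitContract:
    def test_metadata_records_class_counts(self):
        X = np.array([[1, 1], [1, 0], [0, 1], [0, 0]], dtype=np.uint8)
        y = np.array([1, 1, 0, 0], dtype=np.uint8)
        state = fit(ClassifierSpec("nb"), X, y, fingerprint_kind="keyed-166")
        assert (state.n_pos, state.n_neg) == (2, 2)
        assert state.n_features == 2
        assert state.fingerprint_kind == "keyed-166"

    def test_single_class_and_empty_rejected(self):
        X = np.ones((3, 4), dtype=np.uint8)
        with pytest.raises(ValueError):
            fit(ClassifierSpec("nb"), X, np.ones(3, dtype=np.uint8))
        with pytest.raises(ValueError):
            fit(ClassifierSpec("nb"), np.empty((0, 4), dtype=np.uint8), np.empty(0))

    @pytest.mark.parametrize("alg", ["nb", "knn1", "svm-poly", "tree-c45", "rf"])
    def test_all_algorithms_fit_predict_deterministically(self, alg):
        X, y = two_class(seed=1)
        Xt, yt = two_class(seed=2)
        s1 = fit(ClassifierSpec(alg), X, y, seed=3)
        s2 = fit(ClassifierSpec(alg), X, y, seed=3)
        p1, p2 = predict(s1, Xt), predict(s2, Xt)
        assert np.array_equal(p1, p2)
        assert set(np.unique(p1)) <= {0, 1}
        # separable data: better than chance
        assert (p1 == yt).mean() > 0.7

    def test_predict_shape_contracts(self):
        X, y = two_class()
        state = fit(ClassifierSpec("knn1"), X, y)
        assert predict(state, np.empty((0, 16), dtype=np.uint8)).shape == (0,)
        with pytest.raises(ValueError):
            predict(state, np.ones((2, 17), dtype=np.uint8))

    def test_rf_tree_count_readable_from_state(self):
        X, y = two_class()
        state = fit(ClassifierSpec("rf"), X, y)
        assert state.model.n_estimators == 10
        assert len(state.model.estimators_) == 10


class TestNaiveBayes:
    def test_posterior_hand_computed_single_example_per_class(self):
        # theta with Laplace smoothing: pos [2/3,2/3,1/3,1/3], neg mirrored;
        # for x equal to the positive example the likelihoods are (2/3)^4 vs
        # (1/3)^4, so p_active = 16/17
        X = np.array([[1, 1, 0, 0], [0, 0, 1, 1]], dtype=np.uint8)
        y = np.array([1, 0], dtype=np.uint8)
        state = fit(ClassifierSpec("nb"), X, y)
        p_act, p_inact = nb_posterior(state, np.array([1, 1, 0, 0]))
        assert p_act == pytest.approx(16 / 17)
        assert p_act + p_inact == pytest.approx(1.0)

    def test_uninformative_bits_return_prior(self):
        # both classes have smoothed per-bit rate exactly 0.5, so the
        # posterior equals the class prior (0.9 inactive)
        Xp = np.array([[0, 1], [1, 0]], dtype=np.uint8)
        Xn = np.array([[0, 1], [1, 0]] * 9, dtype=np.uint8)
        X = np.vstack([Xp, Xn])
        y = np.r_[np.ones(2, dtype=np.uint8), np.zeros(18, dtype=np.uint8)]
        state = fit(ClassifierSpec("nb"), X, y)
        for x in ([0, 0], [1, 1], [1, 0]):
            p_act, p_inact = nb_posterior(state, np.array(x))
            assert p_inact == pytest.approx(0.9)

    def test_posterior_tie_breaks_negative(self):
        X = np.array([[1, 0], [0, 1]], dtype=np.uint8)
        y = np.array([1, 0], dtype=np.uint8)
        state = fit(ClassifierSpec("nb"), X, y)
        # x = [1,1] is symmetric between the classes: posterior exactly 0.5
        p_act, _ = nb_posterior(state, np.array([1, 1]))
        assert p_act == pytest.approx(0.5)
        assert predict(state, np.array([[1, 1]], dtype=np.uint8))[0] == 0

    def test_posterior_normalization_random_inputs(self, rng):
        X, y = two_class(seed=5)
        state = fit(ClassifierSpec("nb"), X, y)
        for _ in range(20):
            x = (rng.random(16) < 0.5).astype(np.uint8)
            p_act, p_inact = nb_posterior(state, x)
            assert p_act + p_inact == pytest.approx(1.0)
            assert 0 <= p_act <= 1

    def test_non_binary_input_rejected(self):
        X, y = two_class()
        state = fit(ClassifierSpec("nb"), X, y)
        with pytest.raises(ValueError):
            nb_posterior(state, np.full(16, 2))

    def test_prior_log_odds_monotone_in_ratio(self):
        rng = np.random.default_rng(0)
        logodds = []
        for n_neg in (5, 10, 50, 200):
            X = (rng.random((10 + n_neg, 8)) < 0.3).astype(np.uint8)
            y = np.r_[np.ones(10, dtype=np.uint8), np.zeros(n_neg, dtype=np.uint8)]
            state = fit(ClassifierSpec("nb"), X, y)
            logodds.append(state.model.log_prior[1] - state.model.log_prior[0])
        assert all(a > b for a, b in zip(logodds, logodds[1:]))

    def test_single_template_rule_matches_hamming(self, rng):
        # duplicated templates per class make the smoothed bit rates
        # symmetric (1/4 vs 3/4), so NB must pick the Hamming-closer template
        tp = (rng.random(24) < 0.5).astype(np.uint8)
        tn = (rng.random(24) < 0.5).astype(np.uint8)
        X = np.vstack([tp, tp, tn, tn])
        y = np.array([1, 1, 0, 0], dtype=np.uint8)
        state = fit(ClassifierSpec("nb"), X, y)
        for _ in range(50):
            x = (rng.random(24) < 0.5).astype(np.uint8)
            dp, dn = np.sum(x != tp), np.sum(x != tn)
            if dp == dn:
                continue
            expected = 1 if dp < dn else 0
            assert predict(state, x[None, :])[0] == expected


class TestOneNN:
    def test_identical_training_row_returns_its_label(self):
        X, y = two_class()
        state = fit(ClassifierSpec("knn1"), X, y)
        assert predict(state, X[3][None, :])[0] == y[3]
        assert knn1_predict(X, y, X[25]) == y[25]

    def test_tie_broken_by_lowest_row_index(self):
        X = np.array([[0, 0, 0, 0], [1, 1, 0, 0]], dtype=np.uint8)
        y = np.array([0, 1], dtype=np.uint8)
        # x is at Hamming distance 1 from both rows
        assert knn1_predict(X, y, np.array([1, 0, 0, 0])) == 0
        assert knn1_predict(X[::-1], y[::-1], np.array([1, 0, 0, 0])) == 1

    def test_brute_force_oracle_agreement(self, rng):
        X = (rng.random((60, 12)) < 0.4).astype(np.uint8)
        y = (rng.random(60) < 0.5).astype(np.uint8)
        if y.sum() in (0, 60):
            y[0] ^= 1
        state = fit(ClassifierSpec("knn1"), X, y)
        Xt = (rng.random((100, 12)) < 0.4).astype(np.uint8)
        got = predict(state, Xt)
        for i in range(100):
            dists = [int(np.sum((X[j].astype(int) - Xt[i].astype(int)) ** 2))
                     for j in range(60)]
            expected = y[int(np.argmin(dists))]
            assert got[i] == expected

    def test_euclidean_and_hamming_orderings_coincide(self, rng):
        for _ in range(10):
            X = (rng.random((20, 10)) < 0.5).astype(np.uint8)
            x = (rng.random(10) < 0.5).astype(np.uint8)
            eu = np.array([np.sum((r.astype(float) - x) ** 2) for r in X])
            ham = np.array([np.sum(r != x) for r in X])
            assert np.array_equal(np.argsort(eu, kind="stable"),
                                  np.argsort(ham, kind="stable"))
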