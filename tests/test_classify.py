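"""Logistic core against brute-force oracles; scaled-probability semantics."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sccmsi import classify as cl
from sccmsi.msi_io import BACKGROUND, NONTUMOR, TUMOR, UNCLASSIFIED
from sccmsi.preprocess import FeatureMatrix


class TestNormalize:
    def test_single_nonzero_entry_becomes_unit_vector(self):
        out, zero = cl.normalize(np.array([[0.0, 9.0, 0.0]]))
        np.testing.assert_allclose(out, [[0.0, 1.0, 0.0]])
        assert not zero[0]

    def test_all_zero_row_left_zero_and_flagged(self):
        out, zero = cl.normalize(np.array([[0.0, 0.0], [1.0, 1.0]]))
        np.testing.assert_array_equal(out[0], [0.0, 0.0])
        assert zero.tolist() == [True, False]

    def test_matches_hand_rolled_oracle_with_unit_row_norms(self):
        rng = np.random.default_rng(3)
        v = rng.gamma(2.0, 50.0, size=(20, 7))
        out, _ = cl.normalize(v)
        norms = np.linalg.norm(out, axis=1)
        np.testing.assert_allclose(norms, 1.0, atol=1e-12)
        logged = np.log10(v + 1.0)
        np.testing.assert_allclose(out, logged / np.linalg.norm(logged, axis=1, keepdims=True), rtol=1e-12)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            cl.normalize(np.array([[-1.0]]))

    def test_feature_matrix_round_trip(self):
        fm = FeatureMatrix(coords=np.array([[0, 0]]), mzs=np.array([500.0]), values=np.array([[3.0]]))
        out = cl.normalize(fm)
        assert isinstance(out, FeatureMatrix)
        assert out.zero_rows is not None and not out.zero_rows[0]


def grid_search_loss_minimum(x, y, l2_lambda, lo=-10, hi=10, coarse=81, refine=4):
    """Independent oracle: nested grid minimization of the penalized loss
    over (intercept, weights) for problems with at most 2 features."""
    p = x.shape[1]
    centers = np.zeros(p + 1)
    width = hi - lo
    best = None
    for _ in range(refine):
        axes = [np.linspace(c - width / 2, c + width / 2, coarse) for c in centers]
        best = None
        for point in itertools.product(*axes):
            point = np.asarray(point)
            loss = cl.penalized_loss(x, y, point[:p], point[p], l2_lambda)
            if best is None or loss < best[0]:
                best = (loss, point)
        centers = best[1]
        width = width / (coarse - 1) * 4
    return best[1]


class TestTrainLogistic:
    def test_symmetric_data_yields_zero_intercept(self):
        x = np.array([[1.0], [-1.0]])
        y = np.array([1.0, 0.0])
        model = cl.train_logistic(x, y, l2_lambda=0.1)
        assert abs(model.intercept) < 1e-6

    def test_separable_two_feature_problem_reaches_perfect_training_accuracy(self):
        rng = np.random.default_rng(0)
        x = np.vstack([rng.normal([2, 2], 0.3, (20, 2)), rng.normal([-2, -2], 0.3, (20, 2))])
        y = np.concatenate([np.ones(20), np.zeros(20)])
        model = cl.train_logistic(x, y, l2_lambda=0.01)
        assert ((model.predict_proba(x) > 0.5) == y.astype(bool)).all()

    @pytest.mark.parametrize("l2_lambda", [0.01, 0.5])
    def test_one_feature_fit_matches_grid_search_oracle(self, l2_lambda):
        x = np.array([[-2.0], [-1.0], [0.0], [1.0], [2.0]])
        y = np.array([0.0, 0.0, 1.0, 1.0, 1.0])
        model = cl.train_logistic(x, y, l2_lambda=l2_lambda)
        oracle = grid_search_loss_minimum(x, y, l2_lambda)
        assert abs(model.weights[0] - oracle[0]) < 1e-3
        assert abs(model.intercept - oracle[1]) < 1e-3

    def test_two_feature_fit_matches_grid_search_oracle(self):
        x = np.array([[0.2, 1.1], [-0.5, 0.3], [1.4, -0.2], [-1.0, -0.8], [0.7, 0.9], [-0.1, -1.3]])
        y = np.array([1.0, 0.0, 1.0, 0.0, 1.0, 0.0])
        model = cl.train_logistic(x, y, l2_lambda=0.1)
        oracle = grid_search_loss_minimum(x, y, 0.1, coarse=41, refine=6)
        np.testing.assert_allclose(model.weights, oracle[:2], atol=1e-3)
        assert abs(model.intercept - oracle[2]) < 1e-3

    def test_gradient_vanishes_at_the_optimum(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(50, 3))
        y = (x @ [1.0, -2.0, 0.5] + rng.normal(0, 0.5, 50) > 0).astype(float)
        model = cl.train_logistic(x, y, l2_lambda=0.05)
        p = model.predict_proba(x)
        grad_w = x.T @ (p - y) + 0.05 * model.weights
        grad_b = np.sum(p - y)
        assert max(np.max(np.abs(grad_w)), abs(grad_b)) < 1e-6

    def test_weight_norm_shrinks_monotonically_with_penalty(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(60, 4))
        y = (x[:, 0] - x[:, 1] > 0).astype(float)
        norms = [
            np.linalg.norm(cl.train_logistic(x, y, l2_lambda=lam).weights)
            for lam in (0.01, 0.1, 1.0, 10.0)
        ]
        assert all(a > b for a, b in zip(norms, norms[1:]))

    def test_single_class_rejected(self):
        with pytest.raises(cl.TrainingError):
            cl.train_logistic(np.ones((5, 1)), np.ones(5))

    def test_agrees_with_reference_solver(self):
        # independent cross-check: scikit-learn minimizes the same objective
        from sklearn.linear_model import LogisticRegression

        rng = np.random.default_rng(4)
        x = rng.normal(size=(80, 3))
        y = (x @ [1.0, 1.0, -1.0] + rng.normal(0, 1, 80) > 0).astype(float)
        lam = 0.5
        ours = cl.train_logistic(x, y, l2_lambda=lam)
        ref = LogisticRegression(C=1.0 / lam, tol=1e-10, max_iter=5000)
        ref.fit(x, y)
        np.testing.assert_allclose(ours.weights, ref.coef_[0], atol=1e-4)
        assert abs(ours.intercept - ref.intercept_[0]) < 1e-4


class TestScaledProbabilities:
    def test_already_normalized_scores_pass_through(self):
        scaled = cl.fuse_scores(0.9, 0.05, 0.05)
        np.testing.assert_allclose(scaled, [0.9, 0.05, 0.05])
        assert cl.decide(scaled) == TUMOR

    def test_no_majority_score_is_unclassified(self):
        scaled = cl.fuse_scores(0.4, 0.4, 0.2)
        np.testing.assert_allclose(scaled, [0.4, 0.4, 0.2])
        assert cl.decide(scaled) == UNCLASSIFIED

    def test_degenerate_zero_scores_fall_back_to_uniform_unclassified(self):
        scaled = cl.fuse_scores(0.0, 0.0, 0.0)
        np.testing.assert_allclose(scaled, 1.0 / 3.0)
        assert cl.decide(scaled) == UNCLASSIFIED

    @settings(max_examples=300, deadline=None)
    @given(
        st.tuples(
            st.floats(0, 100, allow_nan=False),
            st.floats(0, 100, allow_nan=False),
            st.floats(0, 100, allow_nan=False),
        )
    )
    def test_fusion_semantics_for_arbitrary_scores(self, scores):
        scaled = np.asarray(cl.fuse_scores(*scores))
        assert np.isclose(scaled.sum(), 1.0)
        assert (scaled >= 0).all()
        assert int(np.sum(scaled > 0.5)) <= 1
        decision = cl.decide(scaled)
        if scaled.max() > 0.5:
            assert decision in (TUMOR, NONTUMOR, BACKGROUND)
        else:
            assert decision == UNCLASSIFIED


@pytest.fixture(scope="module")
def toy_ovr():
    rng = np.random.default_rng(5)
    n = 60
    x = np.vstack(
        [
            rng.gamma(2.0, 100.0, (n, 4)) * [10, 1, 1, 1],  # tumor: ion 0 high
            rng.gamma(2.0, 100.0, (n, 4)) * [1, 10, 1, 1],  # non-tumor: ion 1 high
            rng.gamma(2.0, 1.0, (n, 4)) * (rng.random((n, 4)) < 0.3),  # background: sparse noise
        ]
    )
    y = np.concatenate([np.full(n, TUMOR), np.full(n, NONTUMOR), np.full(n, BACKGROUND)])
    return x, y


class TestOvr:
    def test_three_problems_with_equal_weight_lengths(self, toy_ovr):
        x, y = toy_ovr
        clf = cl.train_ovr(x, y, feature_mzs=np.array([400.0, 500.0, 600.0, 700.0]))
        assert set(clf.problems) == {cl.PROBLEM_TUMOR, cl.PROBLEM_TISSUE, cl.PROBLEM_NONTUMOR}
        assert all(len(m.weights) == 4 for m in clf.problems.values())

    def test_missing_background_class_rejected(self, toy_ovr):
        x, y = toy_ovr
        keep = y != BACKGROUND
        with pytest.raises(cl.TrainingError, match="Background"):
            cl.train_ovr(x[keep], y[keep])

    def test_training_pixels_are_recovered(self, toy_ovr):
        x, y = toy_ovr
        clf = cl.train_ovr(x, y)
        xn, _ = cl.normalize(x)
        pred = cl.decide(cl.scaled_probabilities(clf, xn))
        assert (pred == y).mean() > 0.95

    def test_classifier_json_round_trip(self, toy_ovr, tmp_path):
        x, y = toy_ovr
        clf = cl.train_ovr(x, y)
        back = cl.OvrClassifier.from_json(clf.to_json(tmp_path / "clf.json"))
        for name in clf.problems:
            np.testing.assert_allclose(back.problems[name].weights, clf.problems[name].weights)
            assert back.problems[name].positive_classes == clf.problems[name].positive_classes


class TestPredictImage:
    def test_every_pixel_is_classified_or_unclassified(self, toy_ovr):
        x, y = toy_ovr
        clf = cl.train_ovr(x, y)
        coords = np.array([(i % 18, i // 18) for i in range(len(x))])
        fm = FeatureMatrix(coords=coords, mzs=np.array([400.0, 500.0, 600.0, 700.0]), values=x)
        pred = cl.predict_image(clf, fm, (10, 18))
        assert pred.class_image.shape == (10, 18)
        seen = set(np.unique(pred.class_image))
        assert seen <= {TUMOR, NONTUMOR, BACKGROUND, UNCLASSIFIED}
        sums = pred.scaled_probabilities[coords[:, 1], coords[:, 0]].sum(axis=-1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)

    def test_majority_scaled_probability_maps_to_its_class(self):
        scaled = np.array([[[0.51, 0.29, 0.20], [0.2, 0.51, 0.29]]])
        decided = cl.decide(scaled)
        assert decided[0, 0] == TUMOR and decided[0, 1] == NONTUMOR


class TestRankCoefficients:
    def test_full_ranking_returns_all_features(self, toy_ovr):
        x, y = toy_ovr
        clf = cl.train_ovr(x, y, feature_mzs=np.array([400.0, 500.0, 600.0, 700.0]))
        table = cl.rank_coefficients(clf, top_n=4)
        assert len(table) == 4
        assert set(table.columns) == {"mz", "coefficient", "direction"}

    def test_tumor_marker_gets_negative_coefficient(self, toy_ovr):
        # reporting convention: negative coefficient = upregulated in tumor
        x, y = toy_ovr
        clf = cl.train_ovr(x, y, feature_mzs=np.array([400.0, 500.0, 600.0, 700.0]))
        table = cl.rank_coefficients(clf, top_n=4).set_index("mz")
        assert table.loc[400.0, "direction"] == "tumor-up"
        assert table.loc[400.0, "coefficient"] < 0

    def test_all_zero_weights_yield_empty_ranking_with_warning(self):
        zero = cl.LogisticModel(weights=np.zeros(3), intercept=0.0, positive_classes=(TUMOR,))
        clf = cl.OvrClassifier(
            feature_mzs=np.array([1.0, 2.0, 3.0]),
            problems={cl.PROBLEM_TUMOR: zero, cl.PROBLEM_TISSUE: zero, cl.PROBLEM_NONTUMOR: zero},
        )
        with pytest.warns(UserWarning):
            table = cl.rank_coefficients(clf)
        assert table.empty
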