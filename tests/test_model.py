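"""Iterative logistic training, iteration selection, PHRED scaling,
coefficient reporting."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from varprox.model import (
    DegenerateLabelsError,
    IterativeLogisticRegression,
    ModelSnapshot,
    PhredReference,
    TrainerConfig,
    load_model,
    phred_scale,
    save_model,
    score,
    select_iteration,
    top_coefficients,
    train_iterative,
)
from varprox.features import ManifestMismatchError


def two_clouds(n=200, sep=6.0, seed=0):
    rng = np.random.default_rng(seed)
    X0 = rng.normal(0.0, 1.0, (n // 2, 2))
    X1 = rng.normal(sep, 1.0, (n // 2, 2))
    X = np.vstack([X0, X1])
    y = np.repeat([0, 1], n // 2)
    return X, y


class TestTrainIterative:
    def test_separable_clouds_reach_perfect_training_auroc(self):
        from varprox.metrics import auroc

        X, y = two_clouds()
        trace = train_iterative(X, y, config=TrainerConfig(max_iterations=20))
        s = expit(X @ trace.iteration(20).coef + trace.iteration(20).intercept)
        assert auroc(s, y) == 1.0

    def test_zero_features_give_class_balance_intercept(self):
        X = np.zeros((60, 3))
        y = np.array([0] * 20 + [1] * 40)
        trace = train_iterative(X, y, config=TrainerConfig(max_iterations=20))
        for snap in trace:
            assert np.allclose(snap.coef, 0.0)
        assert trace.iteration(20).intercept == pytest.approx(logit(2 / 3), abs=1e-4)

    def test_trace_length_matches_config(self):
        X, y = two_clouds(n=80)
        trace = train_iterative(X, y, config=TrainerConfig(max_iterations=20))
        assert len(trace) == 20
        assert [s.iteration for s in trace] == list(range(1, 21))

    def test_objective_non_increasing(self):
        X, y = two_clouds(n=300, sep=1.0, seed=3)
        trace = train_iterative(X, y, config=TrainerConfig(max_iterations=30))
        objectives = [s.objective for s in trace]
        assert all(b <= a + 1e-6 for a, b in zip(objectives, objectives[1:]))

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateLabelsError):
            train_iterative(np.zeros((5, 2)), np.ones(5))

    def test_integer_weights_equal_duplication(self):
        """Weight w on a record equals duplicating that record w times."""
        rng = np.random.default_rng(7)
        X = rng.normal(size=(40, 3))
        y = (rng.random(40) < 0.5).astype(int)
        y[:2] = [0, 1]
        w = np.ones(40)
        w[:10] = 3.0
        X_dup = np.vstack([X, X[:10], X[:10]])
        y_dup = np.concatenate([y, y[:10], y[:10]])
        t1 = train_iterative(X, y, weights=w, config=TrainerConfig(max_iterations=40))
        t2 = train_iterative(X_dup, y_dup, config=TrainerConfig(max_iterations=40))
        assert t1.iteration(40).objective == pytest.approx(
            t2.iteration(40).objective, abs=1e-8)
        assert np.allclose(t1.iteration(40).coef, t2.iteration(40).coef, atol=1e-5)

    def test_converged_coefficients_match_reference_solver(self):
        """The converged trace agrees with an independent lbfgs logistic fit."""
        from sklearn.linear_model import LogisticRegression

        rng = np.random.default_rng(11)
        X = rng.normal(size=(500, 4))
        y = (expit(X @ np.array([1.0, -0.5, 0.25, 0.0])) > rng.random(500)).astype(int)
        trace = train_iterative(X, y, config=TrainerConfig(max_iterations=200))
        ref = LogisticRegression(C=1.0, solver="lbfgs",
                                 max_iter=2000, tol=1e-10).fit(X, y)
        assert np.allclose(trace.iteration(200).coef, ref.coef_[0], atol=1e-3)
        assert trace.iteration(200).intercept == pytest.approx(
            ref.intercept_[0], abs=1e-3)


class TestSelectIteration:
    def _trace_with_scores(self):
        # three snapshots whose validation ranking quality differs by design:
        # coef [1,0] ranks by the informative feature, [0,1] by noise
        names = ("a", "b")
        snaps = [
            ModelSnapshot(np.array([0.2, 1.0]), 0.0, 1, names),
            ModelSnapshot(np.array([1.0, 0.0]), 0.0, 2, names),
            ModelSnapshot(np.array([-1.0, 0.5]), 0.0, 3, names),
        ]
        from varprox.model import ModelTrace

        return ModelTrace(snapshots=snaps)

    def test_argmax_of_mean_auroc_auprc(self):
        trace = self._trace_with_scores()
        rng = np.random.default_rng(0)
        y = np.repeat([0, 1], 50)
        X = np.column_stack([y + rng.normal(0, 0.3, 100), rng.normal(0, 1, 100)])
        snap, table = select_iteration(trace, [(X, y)])
        assert snap.iteration == 2
        assert list(table["iteration"]) == [1, 2, 3]
        assert table["mean_score"].idxmax() == 1

    def test_tie_goes_to_smallest_iteration(self):
        from varprox.model import ModelTrace

        names = ("a",)
        snaps = [ModelSnapshot(np.array([1.0]), 0.0, k, names) for k in (1, 2, 3)]
        trace = ModelTrace(snapshots=snaps)
        X = np.array([[0.0], [1.0], [2.0], [3.0]])
        y = np.array([0, 0, 1, 1])
        snap, _ = select_iteration(trace, [(X, y)])
        assert snap.iteration == 1

    def test_empty_validation_falls_back_to_default(self):
        trace = self._trace_with_scores()
        with pytest.warns(UserWarning, match="default iteration"):
            snap, table = select_iteration(trace, [], default_iteration=3)
        assert snap.iteration == 3 and table.empty


class TestScore:
    def test_zero_model_scores_half(self):
        snap = ModelSnapshot(np.zeros(2), 0.0, 1, ("a", "b"))
        assert np.allclose(score(snap, np.ones((3, 2))), 0.5)

    def test_large_intercept_saturates_to_one(self):
        snap = ModelSnapshot(np.zeros(1), 40.0, 1, ("a",))
        assert score(snap, np.zeros((2, 1))) == pytest.approx(1.0)

    def test_monotone_in_linear_predictor(self):
        snap = ModelSnapshot(np.array([2.0]), 0.0, 1, ("a",))
        s = score(snap, np.array([[0.1], [0.5], [0.9]]))
        assert np.all(np.diff(s) > 0)

    def test_manifest_mismatch_lists_columns(self):
        snap = ModelSnapshot(np.zeros(2), 0.0, 1, ("a", "b"))
        frame = pd.DataFrame({"a": [1.0], "c": [2.0]})
        with pytest.raises(ManifestMismatchError, match="missing=\\['b'\\]"):
            score(snap, frame)


class TestPhredScale:
    def test_top_percent_anchor_is_twenty(self):
        ref = PhredReference.from_scores(np.linspace(0, 1, 1000))
        q = np.sort(ref.scores_desc)[::-1][9]  # rank 10 of 1000 -> fraction 0.01
        assert phred_scale([q], ref)[0] == pytest.approx(20.0)

    def test_bottom_rank_is_zero(self):
        ref = PhredReference.from_scores(np.linspace(0, 1, 100))
        assert phred_scale([0.0], ref)[0] == pytest.approx(0.0)

    def test_median_rank_value(self):
        ref = PhredReference.from_scores(np.arange(1000, dtype=float))
        q = ref.scores_desc[499]  # rank 500 -> fraction 0.5
        assert phred_scale([q], ref)[0] == pytest.approx(3.0103, abs=1e-4)

    def test_rank_order_preserved(self):
        rng = np.random.default_rng(4)
        ref = PhredReference.from_scores(rng.random(500))
        queries = rng.random(200)
        phred = phred_scale(queries, ref)
        order = np.argsort(queries)
        assert np.all(np.diff(phred[order]) >= 0)

    def test_maximum_attained_by_top_reference_score(self):
        ref = PhredReference.from_scores(np.arange(100, dtype=float))
        top = phred_scale([99.0], ref)[0]
        assert top == pytest.approx(20.0)  # -10*log10(1/100)
        assert phred_scale([1e9], ref)[0] == pytest.approx(top)


class TestTopCoefficients:
    def test_absolute_ordering(self):
        snap = ModelSnapshot(np.array([2.0, -3.0, 1.0]), 0.0, 1, ("a", "b", "c"))
        report = top_coefficients(snap, k=2)
        assert report.table["feature"].tolist() == ["b", "a"]
        assert report.table["coefficient"].tolist() == [-3.0, 2.0]

    def test_all_zero_is_deterministic_manifest_order(self):
        snap = ModelSnapshot(np.zeros(4), 0.0, 1, ("a", "b", "c", "d"))
        report = top_coefficients(snap, k=3)
        assert report.table["feature"].tolist() == ["a", "b", "c"]

    def test_k_larger_than_columns_returns_all(self):
        snap = ModelSnapshot(np.array([1.0, 2.0]), 0.0, 1, ("a", "b"))
        assert len(top_coefficients(snap, k=30).table) == 2

    def test_group_totals(self):
        snap = ModelSnapshot(np.array([1.0, -2.0, 0.5]), 0.0, 1, ("a", "b", "c"))
        groups = {"a": "conservation_constraint", "b": "variant_density",
                  "c": "variant_density"}
        report = top_coefficients(snap, k=3, groups=groups)
        assert report.group_totals["variant_density"] == pytest.approx(2.5)


class TestEstimatorFacade:
    def test_fit_sets_sklearn_attributes(self):
        X, y = two_clouds()
        model = IterativeLogisticRegression(max_iterations=20).fit(X, y)
        assert model.coef_.shape == (1, 2)
        assert model.selected_iteration_ == 13
        assert model.n_features_in_ == 2
        assert (model.predict(X) == y).mean() > 0.95

    def test_get_set_params_roundtrip(self):
        model = IterativeLogisticRegression(C=2.0, max_iterations=5,
                                            default_iteration=3)
        params = model.get_params()
        clone = IterativeLogisticRegression().set_params(**params)
        assert clone.get_params() == params

    def test_balanced_class_weight_equalizes_mass(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(90, 2))
        y = np.array([0] * 60 + [1] * 30)
        X[y == 1] += 2.0
        model = IterativeLogisticRegression(max_iterations=30,
                                            class_weight="balanced").fit(X, y)
        # with equalized class mass the intercept is near the boundary midpoint
        unw = IterativeLogisticRegression(max_iterations=30).fit(X, y)
        assert model.intercept_[0] > unw.intercept_[0]

    def test_save_load_roundtrip(self, tmp_path):
        X, y = two_clouds()
        model = IterativeLogisticRegression(max_iterations=15,
                                            default_iteration=10).fit(X, y)
        path = tmp_path / "model.json"
        save_model(path, model.snapshot_)
        snap, norm = load_model(path)
        assert norm is None
        assert np.allclose(snap.coef, model.snapshot_.coef)
        assert snap.iteration == 10
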