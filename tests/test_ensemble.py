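"""Splitting, normalization, the model registry, metrics and the ensemble."""

import numpy as np
import pytest
from scipy.stats import rankdata

from watchtox.ensemble import (
    VIEW_ORDER,
    EnsembleModel,
    ModelSpec,
    apply_normalizer,
    average_baseline,
    build_estimator,
    evaluate,
    fit_base,
    fit_normalizer,
    make_split,
    model_registry,
    run_watch,
)
from watchtox.types import FeatureMatrix, Label, View


def _split_input(n_w, n_n):
    return {
        Label.WITHDRAWN: [f"w{i}" for i in range(n_w)],
        Label.NOT_WITHDRAWN: [f"n{i}" for i in range(n_n)],
    }


class TestMakeSplit:
    def test_even_pool_80_10_10(self):
        s = make_split(_split_input(50, 50), seed=0)
        assert (len(s.train_ids), len(s.test1_ids), len(s.test2_ids)) == (80, 10, 10)
        for seg in (s.train_ids, s.test1_ids, s.test2_ids):
            w = sum(d.startswith("w") for d in seg)
            assert w == len(seg) // 2  # class-balanced

    def test_imbalanced_pool_undersamples_majority(self):
        s = make_split(_split_input(120, 1511), seed=1)
        assert (len(s.train_ids), len(s.test1_ids), len(s.test2_ids)) == (192, 24, 24)

    def test_deterministic_and_disjoint(self):
        a = make_split(_split_input(40, 60), seed=9)
        b = make_split(_split_input(40, 60), seed=9)
        assert a == b
        assert not (set(a.train_ids) & set(a.test1_ids) & set(a.test2_ids))

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            make_split(_split_input(5, 50), seed=0)


class TestNormalizer:
    def _train(self):
        return FeatureMatrix(["a", "b", "c"], ["x"], [[2.0], [4.0], [6.0]], View.CHEM)

    def test_midpoint_maps_to_half(self):
        stats = fit_normalizer(self._train())
        out = apply_normalizer(stats, self._train())
        assert out.values[:, 0].tolist() == [0.0, 0.5, 1.0]

    def test_held_out_values_extrapolate_unclipped(self):
        stats = fit_normalizer(self._train())
        test = FeatureMatrix(["t"], ["x"], [[8.0]], View.CHEM)
        assert apply_normalizer(stats, test).values[0, 0] == pytest.approx(1.5)

    def test_constant_train_column_maps_to_zero(self):
        train = FeatureMatrix(["a", "b"], ["x"], [[3.0], [3.0]], View.CHEM)
        stats = fit_normalizer(train)
        test = FeatureMatrix(["t"], ["x"], [[99.0]], View.CHEM)
        assert apply_normalizer(stats, test).values[0, 0] == 0.0

    def test_column_mismatch_rejected(self):
        stats = fit_normalizer(self._train())
        other = FeatureMatrix(["a"], ["y"], [[1.0]], View.CHEM)
        with pytest.raises(ValueError):
            apply_normalizer(stats, other)


class TestRegistry:
    def test_published_hyperparameters(self):
        assert model_registry(View.FINGERPRINT).hyperparameters["n_estimators"] == 188
        assert model_registry(View.FINGERPRINT).family == "random_forest"
        assert model_registry(View.TARGET).hyperparameters["rbf_gamma"] == 0.05
        meta = model_registry("meta").hyperparameters
        assert meta == {"n_neighbors": 57, "weights": "distance"}
        mlp = model_registry(View.TARGET_FEATURE).hyperparameters
        assert mlp["hidden_layer_sizes"] == (150,) and mlp["solver"] == "sgd"

    def test_unknown_view_rejected(self):
        with pytest.raises(KeyError):
            model_registry("nonsense")

    def test_overrides_are_validated_and_applied(self):
        spec = model_registry(View.FINGERPRINT, {"fingerprint": {"n_estimators": 10}})
        assert spec.hyperparameters["n_estimators"] == 10
        with pytest.raises(KeyError):
            model_registry(View.FINGERPRINT, {"fingerprint": {"bogus": 1}})

    @pytest.mark.parametrize("view", list(VIEW_ORDER) + ["meta"])
    def test_every_family_instantiates(self, view):
        assert build_estimator(model_registry(view), seed=0) is not None


class TestFitBase:
    def _separable(self, n=60):
        rng = np.random.default_rng(0)
        y = np.array([1] * (n // 2) + [0] * (n // 2))
        x = np.column_stack([y + rng.normal(0, 0.01, n), rng.random(n)])
        m = FeatureMatrix([f"d{i}" for i in range(n)], ["s", "r"], x, View.CHEM)
        return m, y

    def test_separable_fixture_fit_perfectly(self):
        m, y = self._separable()
        model = fit_base(m, y, model_registry(View.FINGERPRINT), seed=0)
        assert (model.predict(m.values) == y).all()

    def test_probabilities_sum_to_one(self):
        m, y = self._separable()
        model = fit_base(m, y, model_registry(View.TARGET), seed=0)
        assert model.predict_proba(m.values).sum(axis=1) == pytest.approx(np.ones(len(y)))

    def test_refit_same_seed_identical(self):
        m, y = self._separable()
        spec = model_registry(View.CHEM)
        p1 = fit_base(m, y, spec, seed=3).predict_proba(m.values)
        p2 = fit_base(m, y, spec, seed=3).predict_proba(m.values)
        assert np.array_equal(p1, p2)

    def test_single_class_rejected(self):
        m, y = self._separable()
        with pytest.raises(ValueError):
            fit_base(m, np.ones_like(y), model_registry(View.CHEM))


def oracle_metrics(y_true, probs):
    """Independent confusion-matrix / rank-statistic implementation."""
    y_pred = (np.asarray(probs) >= 0.5).astype(int)
    y_true = np.asarray(y_true)
    tp = int(((y_pred == 1) & (y_true == 1)).sum())
    tn = int(((y_pred == 0) & (y_true == 0)).sum())
    fp = int(((y_pred == 1) & (y_true == 0)).sum())
    fn = int(((y_pred == 0) & (y_true == 1)).sum())
    n = tp + tn + fp + fn
    acc = (tp + tn) / n
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom else 0.0
    ranks = rankdata(probs)
    n_pos, n_neg = int(y_true.sum()), int((1 - y_true).sum())
    auroc = (ranks[y_true == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    return acc, f1, prec, rec, mcc, auroc


class TestEvaluate:
    def test_perfect_predictions(self):
        r = evaluate([1, 1, 0, 0], [0.9, 0.8, 0.1, 0.2])
        assert (r.accuracy, r.mcc, r.auroc) == (1.0, 1.0, 1.0)

    def test_mcc_closed_form_case(self):
        # TP=45, TN=47, FP=3, FN=5 -> 2100 / sqrt(6,240,000)
        y = [1] * 50 + [0] * 50
        p = [0.9] * 45 + [0.1] * 5 + [0.9] * 3 + [0.1] * 47
        r = evaluate(y, p)
        assert r.mcc == pytest.approx(2100 / np.sqrt(6_240_000), abs=1e-12)

    def test_degenerate_all_positive_gives_mcc_zero(self):
        r = evaluate([1, 1, 0, 0], [0.9, 0.9, 0.9, 0.9])
        assert r.mcc == 0.0

    def test_tie_at_threshold_goes_positive(self):
        r = evaluate([1], [0.5])
        assert r.recall == 1.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            evaluate([], [])

    def test_agrees_with_oracle_on_random_vectors(self):
        rng = np.random.default_rng(12345)
        for _ in range(100):
            n = rng.integers(10, 60)
            y = rng.integers(0, 2, n)
            if len(np.unique(y)) < 2:
                y[0], y[1] = 0, 1
            p = rng.random(n)
            r = evaluate(y, p)
            acc, f1, prec, rec, mcc, auroc = oracle_metrics(y, p)
            assert r.accuracy == pytest.approx(acc, abs=1e-12)
            assert r.f1 == pytest.approx(f1, abs=1e-12)
            assert r.precision == pytest.approx(prec, abs=1e-12)
            assert r.recall == pytest.approx(rec, abs=1e-12)
            assert r.mcc == pytest.approx(mcc, abs=1e-12)
            assert r.auroc == pytest.approx(auroc, abs=1e-12)


@pytest.fixture(scope="module")
def run(small_bundle):
    b = small_bundle
    return run_watch(b.drugs, b.activities, b.profiles, seed=0)


class TestEndToEnd:

    def test_meta_input_width_is_four(self, run, small_bundle):
        b = small_bundle
        views = run.model.view_builder.transform(
            [r for r in b.drugs if r.label is not Label.INVESTIGATIONAL], b.activities
        )
        base = run.model.base_probabilities(views, run.model.split.test2_ids)
        assert base.shape[1] == 4
        assert ((base >= 0) & (base <= 1)).all()

    def test_missing_view_feature_defaults_to_half(self, run, small_bundle):
        views = {}  # no views available at all
        base = run.model.base_probabilities(views, ["w0"])
        assert base.tolist() == [[0.5, 0.5, 0.5, 0.5]]

    def test_baseline_is_mean_of_base_probabilities(self, run, small_bundle):
        b = small_bundle
        labeled = [r for r in b.drugs if r.label is not Label.INVESTIGATIONAL]
        views = run.model.view_builder.transform(labeled, b.activities)
        ids = run.model.split.test2_ids
        base = run.model.base_probabilities(views, ids)
        avg = average_baseline(run.model, views, ids)
        assert avg == pytest.approx(base.mean(axis=1))

    def test_no_leakage_into_normalization(self, run, small_bundle):
        """Train min/max must equal statistics of the train segment alone."""
        b = small_bundle
        labeled = [r for r in b.drugs if r.label is not Label.INVESTIGATIONAL]
        views = run.model.view_builder.transform(labeled, b.activities)
        split = run.model.split
        assert not (set(split.train_ids) & set(split.test1_ids))
        assert not (set(split.train_ids) & set(split.test2_ids))
        for view in VIEW_ORDER:
            train = views[view].subset_rows(split.train_ids)
            stats = run.model.norm_stats[view]
            assert np.array_equal(stats.mins, train.values.min(axis=0))
            assert np.array_equal(stats.maxs, train.values.max(axis=0))

    def test_rerun_is_reproducible(self, run, small_bundle):
        b = small_bundle
        again = run_watch(b.drugs, b.activities, b.profiles, seed=0)
        assert again.ensemble_test2 == run.ensemble_test2
        assert again.model.split == run.model.split

    def test_signal_condition_beats_chance_clearly(self, run):
        assert run.ensemble_test2.accuracy >= 0.8

    def test_averaging_tie_rule(self):
        model = EnsembleModel({}, None, {}, None)
        probs = np.array([[0.2, 0.4, 0.6, 0.8]])
        assert probs.mean() == 0.5  # mean 0.5 -> positive by the >= rule
        assert (probs.mean(axis=1) >= 0.5).all()
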