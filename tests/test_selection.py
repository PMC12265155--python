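"""Balanced resampling, the three selectors, consensus scoring, contrasts."""

import math

import numpy as np
import pytest

import watchtox.selection as sel
from watchtox.selection import (
    balanced_resample,
    class_contrast,
    consensus_score,
    select_rfecv,
    select_univariate,
    select_variance,
)
from watchtox.types import DrugRecord, FeatureMatrix, Label, View


def _records(n_withdrawn, n_not, features=None):
    out = []
    for i in range(n_withdrawn):
        out.append(DrugRecord(f"w{i}", Label.WITHDRAWN, chem_features=dict(features or {})))
    for i in range(n_not):
        out.append(DrugRecord(f"n{i}", Label.NOT_WITHDRAWN, chem_features=dict(features or {})))
    return out


def _matrix(ids, data, names=None):
    data = np.asarray(data, dtype=float)
    names = names or [f"f{j}" for j in range(data.shape[1])]
    return FeatureMatrix(ids, names, data, View.CHEM)


class TestBalancedResample:
    def test_even_classes(self):
        sub = balanced_resample(_records(50, 50), 0.8, seed=0)
        labels = [r.label for r in sub]
        assert len(sub) == 80
        assert labels.count(Label.WITHDRAWN) == labels.count(Label.NOT_WITHDRAWN) == 40

    def test_minority_limits_imbalanced_corpus(self):
        sub = balanced_resample(_records(120, 1511), 0.8, seed=3)
        labels = [r.label for r in sub]
        assert len(sub) == 192
        assert labels.count(Label.WITHDRAWN) == 96

    def test_deterministic_per_seed(self):
        records = _records(30, 70)
        a = balanced_resample(records, 0.8, seed=5)
        b = balanced_resample(records, 0.8, seed=5)
        assert [r.drug_id for r in a] == [r.drug_id for r in b]

    def test_tiny_class_rejected(self):
        with pytest.raises(ValueError):
            balanced_resample(_records(1, 50), 0.8, seed=0)


class TestVariance:
    def test_constant_excluded_varying_kept(self):
        m = _matrix(["a", "b", "c"], [[1, 0], [1, 1], [1, 0]])
        assert select_variance(m) == {"f1"}

    def test_defined_on_the_subsample(self):
        m = _matrix(["a", "b", "c", "d"], [[0.0], [0.0], [1.0], [1.0]])
        assert select_variance(m.subset_rows(["a", "b"])) == set()
        assert select_variance(m) == {"f0"}


class TestUnivariate:
    def test_quarter_of_eight_is_two(self):
        rng = np.random.default_rng(0)
        m = _matrix(list("abcdefgh"), rng.random((8, 8)))
        y = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        assert len(select_univariate(m, y)) == 2

    def test_separator_beats_uninformative_feature(self):
        y = np.array([1, 1, 0, 0])
        m = _matrix(
            ["a", "b", "c", "d"],
            [[1, 0.5], [1, 0.5], [0, 0.5], [0, 0.5]],
            names=["separator", "flat"],
        )
        assert select_univariate(m, y, fraction=0.5) == {"separator"}

    def test_statistic_matches_class_count_definition(self):
        # chi2 over a 0/1 column: observed class sums vs expectations from
        # class priors (the scorer uses the feature-count row only)
        x = np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0])
        y = np.array([1, 1, 1, 0, 0, 0])
        from sklearn.feature_selection import chi2

        stat = chi2(x.reshape(-1, 1), y)[0][0]
        observed = np.array([0.0, 3.0])  # class 0 sum, class 1 sum
        expected = x.sum() * np.array([0.5, 0.5])
        assert stat == pytest.approx(((observed - expected) ** 2 / expected).sum())

    def test_negative_values_rejected_with_guidance(self):
        m = _matrix(["a", "b"], [[-1.0], [1.0]])
        with pytest.raises(ValueError, match="normalize"):
            select_univariate(m, np.array([0, 1]))


class TestRfecv:
    def test_planted_feature_recovered_across_seeds(self):
        rng = np.random.default_rng(42)
        n = 160
        y = np.array([1] * (n // 2) + [0] * (n // 2))
        signal = y + rng.normal(0, 0.3, n)
        noise = rng.random((n, 15))
        m = _matrix([f"d{i}" for i in range(n)], np.column_stack([signal, noise]),
                    names=["signal"] + [f"noise{j}" for j in range(15)])
        hits = sum("signal" in select_rfecv(m, y, seed=s, n_trees=50) for s in range(10))
        assert hits >= 9

    def test_duplicate_of_signal_feature_keeps_at_least_one_copy(self):
        rng = np.random.default_rng(1)
        n = 100
        y = np.array([1] * 50 + [0] * 50)
        signal = y + rng.normal(0, 0.3, n)
        m = _matrix([f"d{i}" for i in range(n)],
                    np.column_stack([signal, signal, rng.random(n)]),
                    names=["sig_a", "sig_b", "noise"])
        kept = select_rfecv(m, y, seed=0, n_trees=50)
        assert kept & {"sig_a", "sig_b"}

    def test_constant_labels_rejected(self):
        m = _matrix(["a", "b"], [[0.0], [1.0]])
        with pytest.raises(ValueError):
            select_rfecv(m, np.array([1, 1]))


class TestConsensus:
    def test_combined_is_mean_of_methods(self, monkeypatch):
        records = _records(10, 10)
        ids = [r.drug_id for r in records]
        m = _matrix(ids, np.random.default_rng(0).random((20, 2)), names=["x", "y"])

        # constructed trace: rfecv 10/10, univariate 5/10, variance 10/10 for x
        state = {"seed": 0}

        def fake_rfecv(matrix, labels, seed, n_trees=100):
            return {"x", "y"}

        def fake_univariate(matrix, labels, fraction=0.25):
            state["seed"] += 1
            return {"x"} if state["seed"] % 2 else {"y"}

        monkeypatch.setattr(sel, "select_rfecv", fake_rfecv)
        monkeypatch.setattr(sel, "select_univariate", fake_univariate)
        scores = {s.feature_name: s for s in consensus_score(records, m)}
        assert scores["x"].per_method == {"rfecv": 10.0, "variance": 10.0, "univariate": 5.0}
        assert scores["x"].combined == pytest.approx((10 + 10 + 5) / 3)

    def test_constant_feature_scores_zero_variance(self):
        records = _records(12, 12)
        ids = [r.drug_id for r in records]
        values = np.column_stack([
            np.ones(24),
            np.random.default_rng(2).random(24),
        ])
        m = _matrix(ids, values, names=["const", "vary"])
        scores = {s.feature_name: s for s in consensus_score(records, m, seeds=range(3))}
        assert scores["const"].per_method["variance"] == 0.0

    def test_scores_bounded_and_reproducible(self, small_bundle):
        w = [r for r in small_bundle.drugs if r.label is Label.WITHDRAWN][:30]
        nw = [r for r in small_bundle.drugs if r.label is Label.NOT_WITHDRAWN][:30]
        records = w + nw
        ids = [r.drug_id for r in records]
        m = _matrix(ids, np.random.default_rng(3).random((60, 6)))
        a = consensus_score(records, m, seeds=range(2))
        b = consensus_score(records, m, seeds=range(2))
        assert [(s.feature_name, s.combined) for s in a] == [
            (s.feature_name, s.combined) for s in b
        ]
        assert all(0 <= s.combined <= 10 for s in a)


class TestClassContrast:
    def _with_feature(self, w_values, n_values, name="x"):
        records = []
        for i, v in enumerate(w_values):
            records.append(DrugRecord(f"w{i}", Label.WITHDRAWN, chem_features={name: v}))
        for i, v in enumerate(n_values):
            records.append(DrugRecord(f"n{i}", Label.NOT_WITHDRAWN, chem_features={name: v}))
        return records

    def test_equal_means_give_zero(self):
        r = self._with_feature([1.0, 2.0, 3.0], [2.0, 2.0, 2.0])
        assert class_contrast(r, "x").log2_ratio == pytest.approx(0.0)

    def test_flag_frequency_ratio(self):
        r = self._with_feature([1.0] * 4 + [0.0] * 6, [1.0] * 1 + [0.0] * 9)
        c = class_contrast(r, "x")
        assert c.log2_ratio == pytest.approx(2.0)  # log2(0.4 / 0.1)

    def test_halved_mean_gives_minus_one(self):
        r = self._with_feature([1.0, 1.0], [2.0, 2.0])
        assert class_contrast(r, "x").log2_ratio == pytest.approx(-1.0)

    def test_zero_denominator_is_undefined_not_inf(self):
        r = self._with_feature([1.0, 1.0], [0.0, 0.0])
        assert math.isnan(class_contrast(r, "x").log2_ratio)

    def test_planted_shift_is_significant(self, small_bundle):
        labeled = [r for r in small_bundle.drugs if r.label is not Label.INVESTIGATIONAL]
        c = class_contrast(labeled, "alogp")
        assert c.significant and c.log2_ratio > 0
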