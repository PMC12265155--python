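"""The WATCH stacked ensemble for drug withdrawal prediction.

Pipeline per seed:

1. Undersample the majority class to parity and split the balanced pool
   into 80/10/10 train / test1 / test2 segments, class-balanced within
   each segment.
2. Min-max normalize every view with train-segment statistics only
   (constant train columns map to 0; held-out values are not clipped).
3. Fit one base classifier per view with the fixed hyperparameter
   registry: a random forest on fingerprints, stacked extra trees +
   decision tree on chemical descriptors, an RBF-sampler + gradient
   boosting pipeline on protein targets, and a multilayer perceptron on
   IC50-weighted protein structural features.
4. Train a K-nearest-neighbour meta-classifier (57 neighbours, distance
   weights) on the four base withdrawal probabilities over train + test1;
   evaluate on the untouched test2 segment, alongside an unweighted
   probability-averaging baseline.

Ten repetitions with seeds 0-9 give the summary statistics and the model
set used for candidate screening.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn import metrics as skm
from sklearn.ensemble import (
    ExtraTreesClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
    StackingClassifier,
)
from sklearn.exceptions import ConvergenceWarning
from sklearn.kernel_approximation import RBFSampler
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.tree import DecisionTreeClassifier

from .types import DrugRecord, FeatureMatrix, Label, ProteinStructureProfile, TargetActivity, View
from .views import ViewBuilder

__all__ = [
    "VIEW_ORDER",
    "DataSplit",
    "NormalizationStats",
    "ModelSpec",
    "MetricsReport",
    "EnsembleModel",
    "WatchRunResult",
    "make_split",
    "fit_normalizer",
    "apply_normalizer",
    "model_registry",
    "build_estimator",
    "fit_base",
    "fit_meta",
    "average_baseline",
    "evaluate",
    "run_watch",
    "run_watch_repeated",
]

#: Fixed order of the views in the meta feature vector.
VIEW_ORDER: tuple[View, ...] = (View.FINGERPRINT, View.CHEM, View.TARGET, View.TARGET_FEATURE)

#: Base probability used for a drug absent from a view: an uninformative prior.
MISSING_VIEW_PROBABILITY = 0.5


@dataclass(frozen=True)
class DataSplit:
    """Balanced 80/10/10 partition of the drug pool."""

    train_ids: list[str]
    test1_ids: list[str]
    test2_ids: list[str]
    seed: int

    def __post_init__(self) -> None:
        segments = [set(self.train_ids), set(self.test1_ids), set(self.test2_ids)]
        total = sum(len(s) for s in segments)
        if len(set().union(*segments)) != total:
            raise ValueError("split segments overlap")


def make_split(
    ids_by_class: Mapping[Label, Sequence[str]],
    seed: int = 0,
    test_fraction: float = 0.1,
) -> DataSplit:
    """Undersample the majority class to the minority count, then split each
    class 80/10/10 into train/test1/test2. Deterministic per seed."""
    withdrawn = list(ids_by_class[Label.WITHDRAWN])
    not_withdrawn = list(ids_by_class[Label.NOT_WITHDRAWN])
    m = min(len(withdrawn), len(not_withdrawn))
    if m < 10:
        raise ValueError(f"need >= 10 drugs per class, have {m}")
    n_test = int(round(test_fraction * m))
    rng = np.random.default_rng(seed)
    train: list[str] = []
    test1: list[str] = []
    test2: list[str] = []
    for group in (withdrawn, not_withdrawn):
        picked = rng.permutation(len(group))[:m]
        ids = [group[i] for i in picked]
        test1.extend(ids[:n_test])
        test2.extend(ids[n_test: 2 * n_test])
        train.extend(ids[2 * n_test:])
    return DataSplit(train, test1, test2, seed)


@dataclass(frozen=True)
class NormalizationStats:
    """Per-feature train-segment minima and maxima."""

    col_names: list[str]
    mins: np.ndarray
    maxs: np.ndarray


def fit_normalizer(matrix: FeatureMatrix) -> NormalizationStats:
    """Min-max statistics of a train-restricted matrix."""
    return NormalizationStats(
        list(matrix.col_names),
        matrix.values.min(axis=0).copy(),
        matrix.values.max(axis=0).copy(),
    )


def apply_normalizer(stats: NormalizationStats, matrix: FeatureMatrix) -> FeatureMatrix:
    """(value - min) / (max - min) with train statistics.

    Constant train columns map to 0 everywhere; out-of-range held-out
    values extrapolate beyond [0, 1] rather than being clipped.
    """
    if list(matrix.col_names) != stats.col_names:
        raise ValueError("normalization statistics do not match matrix columns")
    span = stats.maxs - stats.mins
    safe = np.where(span > 0, span, 1.0)
    values = (matrix.values - stats.mins) / safe
    values[:, span == 0] = 0.0
    return FeatureMatrix(matrix.row_ids, matrix.col_names, values, matrix.view, normalized=True)


@dataclass(frozen=True)
class ModelSpec:
    """A base- or meta-classifier family with its full hyperparameter set."""

    view: str
    family: str
    hyperparameters: dict


_REGISTRY: dict[str, ModelSpec] = {
    View.FINGERPRINT.value: ModelSpec(
        View.FINGERPRINT.value,
        "random_forest",
        {
            "criterion": "entropy",
            "max_depth": 64,
            "max_features": "log2",
            "min_samples_leaf": 2,
            "min_samples_split": 5,
            "n_estimators": 188,
        },
    ),
    View.CHEM.value: ModelSpec(
        View.CHEM.value,
        "extratrees_stacked_decision_tree",
        {
            "et_bootstrap": True,
            "et_criterion": "gini",
            "et_max_features": 0.65,
            "et_min_samples_leaf": 7,
            "et_n_estimators": 100,
            "dt_criterion": "gini",
            "dt_max_depth": 5,
            "dt_min_samples_leaf": 18,
            "dt_min_samples_split": 3,
            # stacked tree also sees the raw feature vector by default
            "passthrough": True,
            "cv": 5,
        },
    ),
    View.TARGET.value: ModelSpec(
        View.TARGET.value,
        "rbf_approx_plus_gradient_boosting",
        {
            "rbf_gamma": 0.05,
            "learning_rate": 0.1,
            "max_depth": 9,
            "max_features": 0.65,
            "min_samples_leaf": 14,
            "min_samples_split": 15,
            "n_estimators": 100,
            "subsample": 0.5,
        },
    ),
    View.TARGET_FEATURE.value: ModelSpec(
        View.TARGET_FEATURE.value,
        "mlp",
        {
            "activation": "identity",
            "hidden_layer_sizes": (150,),
            "solver": "sgd",
            "max_iter": 500,
        },
    ),
    "meta": ModelSpec("meta", "knn_meta", {"n_neighbors": 57, "weights": "distance"}),
}


def model_registry(view: View | str, overrides: Mapping[str, Mapping] | None = None) -> ModelSpec:
    """The fixed final-model specification for a view (or ``"meta"``).

    ``overrides`` maps view name -> hyperparameter updates, allowing the
    registry to be edited from a config file without touching code.
    """
    key = view.value if isinstance(view, View) else str(view)
    if key not in _REGISTRY:
        raise KeyError(f"unknown view {key!r}; known: {sorted(_REGISTRY)}")
    spec = _REGISTRY[key]
    if overrides and key in overrides:
        hp = dict(spec.hyperparameters)
        unknown = set(overrides[key]) - set(hp)
        if unknown:
            raise KeyError(f"unknown hyperparameters for {key}: {sorted(unknown)}")
        hp.update(overrides[key])
        spec = ModelSpec(spec.view, spec.family, hp)
    return spec


def build_estimator(spec: ModelSpec, seed: int = 0):
    """Instantiate the scikit-learn estimator described by a ModelSpec."""
    hp = spec.hyperparameters
    if spec.family == "random_forest":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **hp)
    if spec.family == "mlp":
        return MLPClassifier(random_state=seed, **hp)
    if spec.family == "rbf_approx_plus_gradient_boosting":
        return Pipeline(
            [
                ("rbf", RBFSampler(gamma=hp["rbf_gamma"], random_state=seed)),
                (
                    "gb",
                    GradientBoostingClassifier(
                        random_state=seed,
                        **{k: v for k, v in hp.items() if k != "rbf_gamma"},
                    ),
                ),
            ]
        )
    if spec.family == "extratrees_stacked_decision_tree":
        et = ExtraTreesClassifier(
            bootstrap=hp["et_bootstrap"],
            criterion=hp["et_criterion"],
            max_features=hp["et_max_features"],
            min_samples_leaf=hp["et_min_samples_leaf"],
            n_estimators=hp["et_n_estimators"],
            random_state=seed,
            n_jobs=1,
        )
        dt = DecisionTreeClassifier(
            criterion=hp["dt_criterion"],
            max_depth=hp["dt_max_depth"],
            min_samples_leaf=hp["dt_min_samples_leaf"],
            min_samples_split=hp["dt_min_samples_split"],
            random_state=seed,
        )
        return StackingClassifier(
            estimators=[("extra_trees", et)],
            final_estimator=dt,
            passthrough=hp["passthrough"],
            cv=hp["cv"],
            stack_method="predict_proba",
            n_jobs=1,
        )
    if spec.family == "knn_meta":
        return KNeighborsClassifier(n_neighbors=hp["n_neighbors"], weights=hp["weights"])
    raise ValueError(f"unknown model family {spec.family!r}")


def fit_base(matrix: FeatureMatrix, labels: np.ndarray, spec: ModelSpec, seed: int = 0):
    """Fit one view-specific base classifier on a normalized train matrix."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("base classifier needs both classes in the training labels")
    model = build_estimator(spec, seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(matrix.values, labels)
    return model


def positive_probability(model, values: np.ndarray) -> np.ndarray:
    """P(withdrawn) from a fitted binary classifier."""
    proba = model.predict_proba(values)
    idx = int(np.where(model.classes_ == 1)[0][0])
    return proba[:, idx]


@dataclass(frozen=True)
class MetricsReport:
    accuracy: float
    f1: float
    precision: float
    recall: float
    mcc: float
    auroc: float


def evaluate(y_true: np.ndarray, probabilities: np.ndarray) -> MetricsReport:
    """Standard binary metrics at the 0.5 decision threshold (ties positive).

    MCC is 0 when a confusion-matrix marginal is empty; AUROC is the
    tie-averaged rank statistic, nan when the truth is single-class.
    """
    y_true = np.asarray(y_true, dtype=int)
    probabilities = np.asarray(probabilities, dtype=float)
    if y_true.size == 0:
        raise ValueError("cannot evaluate an empty prediction set")
    y_pred = (probabilities >= 0.5).astype(int)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mcc = float(skm.matthews_corrcoef(y_true, y_pred))
        auroc = (
            float(skm.roc_auc_score(y_true, probabilities))
            if len(np.unique(y_true)) == 2
            else float("nan")
        )
        return MetricsReport(
            accuracy=float(skm.accuracy_score(y_true, y_pred)),
            f1=float(skm.f1_score(y_true, y_pred, zero_division=0)),
            precision=float(skm.precision_score(y_true, y_pred, zero_division=0)),
            recall=float(skm.recall_score(y_true, y_pred, zero_division=0)),
            mcc=mcc,
            auroc=auroc,
        )


@dataclass
class EnsembleModel:
    """A fully fitted WATCH ensemble: per-view normalizers and base models,
    the KNN meta-classifier, the view layout, and the split it came from."""

    base_models: dict[View, object]
    meta_model: object
    norm_stats: dict[View, NormalizationStats]
    split: DataSplit
    view_builder: ViewBuilder | None = None
    seed: int = 0

    def base_probabilities(self, views: Mapping[View, FeatureMatrix], drug_ids: Sequence[str]) -> np.ndarray:
        """(n_drugs, 4) matrix of base withdrawal probabilities, in
        VIEW_ORDER; drugs absent from a view get the uninformative 0.5."""
        out = np.full((len(drug_ids), len(VIEW_ORDER)), MISSING_VIEW_PROBABILITY)
        for j, view in enumerate(VIEW_ORDER):
            matrix = views.get(view)
            if matrix is None:
                continue
            present = [d for d in drug_ids if d in matrix._row_index]
            if not present:
                continue
            normalized = apply_normalizer(self.norm_stats[view], matrix.subset_rows(present))
            probs = positive_probability(self.base_models[view], normalized.values)
            pos = {d: i for i, d in enumerate(drug_ids)}
            for d, p in zip(present, probs):
                out[pos[d], j] = p
        return out

    def predict_proba_views(self, views: Mapping[View, FeatureMatrix], drug_ids: Sequence[str]) -> np.ndarray:
        """Meta-classifier withdrawal probability per drug."""
        meta_features = self.base_probabilities(views, drug_ids)
        return positive_probability(self.meta_model, meta_features)

    def predict_proba(
        self, records: Sequence[DrugRecord], activities: Sequence[TargetActivity]
    ) -> np.ndarray:
        """Withdrawal probability for raw records, projected through the
        training-corpus view layout."""
        if self.view_builder is None:
            raise RuntimeError("this EnsembleModel was fitted without a ViewBuilder")
        views = self.view_builder.transform(records, activities)
        return self.predict_proba_views(views, [r.drug_id for r in records])


def fit_meta(
    base_models: dict[View, object],
    norm_stats: dict[View, NormalizationStats],
    views: Mapping[View, FeatureMatrix],
    labels_by_id: Mapping[str, int],
    split: DataSplit,
    spec: ModelSpec | None = None,
    seed: int = 0,
) -> EnsembleModel:
    """Train the KNN meta-classifier on pooled base predictions.

    Base models must have been fitted on the train segment only; the meta
    training pool is train + test1, leaving test2 untouched for final
    evaluation. ``n_neighbors`` is clamped to the pool size for tiny
    corpora.
    """
    if spec is None:
        spec = model_registry("meta")
    model = EnsembleModel(base_models, None, dict(norm_stats), split, seed=seed)
    meta_ids = list(split.train_ids) + list(split.test1_ids)
    meta_x = model.base_probabilities(views, meta_ids)
    meta_y = np.array([labels_by_id[d] for d in meta_ids])
    hp = dict(spec.hyperparameters)
    hp["n_neighbors"] = min(hp["n_neighbors"], len(meta_ids))
    meta = build_estimator(ModelSpec(spec.view, spec.family, hp), seed)
    meta.fit(meta_x, meta_y)
    model.meta_model = meta
    return model


def average_baseline(
    model: EnsembleModel, views: Mapping[View, FeatureMatrix], drug_ids: Sequence[str]
) -> np.ndarray:
    """Unweighted mean of the four base probabilities (label at >= 0.5)."""
    return model.base_probabilities(views, drug_ids).mean(axis=1)


@dataclass
class WatchRunResult:
    """Everything one seeded end-to-end run produces."""

    model: EnsembleModel
    ensemble_test2: MetricsReport
    baseline_test2: MetricsReport
    per_view_test1: dict[View, MetricsReport]
    per_view_test2: dict[View, MetricsReport]
    seed: int


def run_watch(
    records: Sequence[DrugRecord],
    activities: Sequence[TargetActivity],
    profiles: Sequence[ProteinStructureProfile],
    seed: int = 0,
    registry_overrides: Mapping[str, Mapping] | None = None,
    builder: ViewBuilder | None = None,
) -> WatchRunResult:
    """One seeded end-to-end run: split, normalize, fit bases, fit meta,
    evaluate ensemble and averaging baseline on test2."""
    trainable = [r for r in records if r.label is not Label.INVESTIGATIONAL]
    labels_by_id = {r.drug_id: 1 if r.label is Label.WITHDRAWN else 0 for r in trainable}
    ids_by_class = {
        Label.WITHDRAWN: [r.drug_id for r in trainable if r.label is Label.WITHDRAWN],
        Label.NOT_WITHDRAWN: [r.drug_id for r in trainable if r.label is Label.NOT_WITHDRAWN],
    }
    split = make_split(ids_by_class, seed)

    by_id = {r.drug_id: r for r in trainable}
    train_records = [by_id[d] for d in split.train_ids]
    pool_ids = split.train_ids + split.test1_ids + split.test2_ids
    pool_records = [by_id[d] for d in pool_ids]

    vb = builder if builder is not None else ViewBuilder()
    vb.fit(train_records, activities, profiles)
    views = vb.transform(pool_records, activities)

    norm_stats: dict[View, NormalizationStats] = {}
    base_models: dict[View, object] = {}
    y_train = np.array([labels_by_id[d] for d in split.train_ids])
    for view in VIEW_ORDER:
        train_matrix = views[view].subset_rows(split.train_ids)
        stats = fit_normalizer(train_matrix)
        norm_stats[view] = stats
        spec = model_registry(view, registry_overrides)
        base_models[view] = fit_base(apply_normalizer(stats, train_matrix), y_train, spec, seed)

    model = fit_meta(
        base_models, norm_stats, views, labels_by_id, split,
        model_registry("meta", registry_overrides), seed,
    )
    model.view_builder = vb

    y1 = np.array([labels_by_id[d] for d in split.test1_ids])
    y2 = np.array([labels_by_id[d] for d in split.test2_ids])
    base1 = model.base_probabilities(views, split.test1_ids)
    base2 = model.base_probabilities(views, split.test2_ids)
    per_view_test1 = {v: evaluate(y1, base1[:, j]) for j, v in enumerate(VIEW_ORDER)}
    per_view_test2 = {v: evaluate(y2, base2[:, j]) for j, v in enumerate(VIEW_ORDER)}
    ensemble_test2 = evaluate(y2, model.predict_proba_views(views, split.test2_ids))
    baseline_test2 = evaluate(y2, base2.mean(axis=1))
    return WatchRunResult(model, ensemble_test2, baseline_test2, per_view_test1, per_view_test2, seed)


def run_watch_repeated(
    records: Sequence[DrugRecord],
    activities: Sequence[TargetActivity],
    profiles: Sequence[ProteinStructureProfile],
    seeds: Sequence[int] = tuple(range(10)),
    registry_overrides: Mapping[str, Mapping] | None = None,
) -> tuple[list[WatchRunResult], dict[str, float]]:
    """Repeat :func:`run_watch` over ``seeds`` (the protocol uses 0-9) and
    summarize mean +/- sd of the headline metrics."""
    results = [
        run_watch(records, activities, profiles, seed, registry_overrides)
        for seed in seeds
    ]
    ens_acc = np.array([r.ensemble_test2.accuracy for r in results])
    ens_mcc = np.array([r.ensemble_test2.mcc for r in results])
    base_acc = np.array([r.baseline_test2.accuracy for r in results])
    view_acc = {
        v: np.array([r.per_view_test1[v].accuracy for r in results]) for v in VIEW_ORDER
    }
    summary = {
        "ensemble_accuracy_mean": float(ens_acc.mean()),
        "ensemble_accuracy_sd": float(ens_acc.std(ddof=1)) if len(results) > 1 else 0.0,
        "ensemble_mcc_mean": float(ens_mcc.mean()),
        "baseline_accuracy_mean": float(base_acc.mean()),
        "best_view_accuracy_mean": float(max(a.mean() for a in view_acc.values())),
    }
    for v, a in view_acc.items():
        summary[f"{v.value}_accuracy_mean"] = float(a.mean())
    return results, summary
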