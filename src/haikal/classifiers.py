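"""The three classifier families and the class-probability augmentation.

Three families are supported, all through scikit-learn: a single-layer
perceptron (a logistic unit trained by stochastic gradient updates), a
small dense feed-forward network, and a 100-tree random forest.  The
class-probability augmentation appends, as the last three features of a
table, the probability-of-correct assigned by the three classifiers
trained on the core balanced set; these probabilities already live in
[0, 1] and are not re-normalized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import SGDClassifier
from sklearn.neural_network import MLPClassifier

from .core_data import FeatureTable

__all__ = [
    "CLASSIFIER_KINDS",
    "ClassifierSpec",
    "TrainedModel",
    "train_classifier",
    "predict_proba",
    "augment_with_class_probs",
]

CLASSIFIER_KINDS = ("perceptron", "dense-net", "random-forest")


@dataclass
class ClassifierSpec:
    """Classifier family plus hyperparameters.

    Defaults: the forest has 100 trees; the dense net has three processing
    layers (64, 32, 16 units) regularized by an L2 penalty and early
    stopping on a 10% validation split; the perceptron is a single
    logistic unit with stochastic updates.  ``params`` overrides the
    underlying estimator's keyword arguments.
    """

    kind: str
    seed: int = 0
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in CLASSIFIER_KINDS:
            raise ValueError(
                f"unknown classifier kind {self.kind!r}; "
                f"expected one of {CLASSIFIER_KINDS}"
            )


def _make_estimator(spec: ClassifierSpec):
    if spec.kind == "perceptron":
        kw = dict(
            loss="log_loss",
            penalty=None,
            max_iter=1000,
            tol=1e-4,
            random_state=spec.seed,
        )
    elif spec.kind == "dense-net":
        kw = dict(
            hidden_layer_sizes=(64, 32, 16),
            alpha=1e-3,
            learning_rate_init=0.01,
            early_stopping=True,
            validation_fraction=0.1,
            n_iter_no_change=25,
            max_iter=500,
            random_state=spec.seed,
        )
    else:  # random-forest
        kw = dict(n_estimators=100, random_state=spec.seed, n_jobs=1)
    kw.update(spec.params)
    if spec.kind == "perceptron":
        return SGDClassifier(**kw)
    if spec.kind == "dense-net":
        return MLPClassifier(**kw)
    return RandomForestClassifier(**kw)


@dataclass
class TrainedModel:
    """A fitted classifier bound to its training feature schema."""

    spec: ClassifierSpec
    estimator: object
    feature_names: list[str]
    provenance: str = "core"  # core vs augmented training data


def train_classifier(
    spec: ClassifierSpec, table: FeatureTable, labels=None, provenance: str = "core"
) -> TrainedModel:
    """Fit one classifier on a labeled feature table.

    Deterministic for the forest and perceptron given the spec's seed; the
    dense net is seeded too but small run-to-run differences from its
    internal validation split are tolerated downstream.
    """
    y = table.labels if labels is None else labels
    if y is None:
        raise ValueError("labels required for training")
    y = np.asarray(y, dtype=bool)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    est = _make_estimator(spec)
    est.fit(table.X.to_numpy(dtype=float), y)
    return TrainedModel(spec, est, list(table.feature_names), provenance)


def predict_proba(model: TrainedModel, table: FeatureTable) -> np.ndarray:
    """Probability of being correct for every decoy in the table.

    The table must carry exactly the model's training features (any column
    order); columns are aligned to the training schema before prediction.
    """
    missing = [f for f in model.feature_names if f not in table.feature_names]
    extra = [f for f in table.feature_names if f not in model.feature_names]
    if missing or extra:
        raise ValueError(
            f"feature schema mismatch: missing {missing}, unexpected {extra}"
        )
    X = table.X[model.feature_names].to_numpy(dtype=float)
    proba = model.estimator.predict_proba(X)
    pos = list(model.estimator.classes_).index(True)
    return proba[:, pos]


def augment_with_class_probs(
    table: FeatureTable, core_models: list[TrainedModel]
) -> FeatureTable:
    """Append the three core classifiers' class probabilities as features.

    Exactly three models (one per family) are required; the new columns
    are named ``class_prob_<kind>`` and left unnormalized since they
    already range between 0 and 1.  The original feature columns are
    untouched.
    """
    if len(core_models) != 3:
        raise ValueError(f"expected exactly 3 core models, got {len(core_models)}")
    df = table.df.copy()
    for model in core_models:
        df[f"class_prob_{model.spec.kind}"] = predict_proba(model, table)
    return FeatureTable(df)
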