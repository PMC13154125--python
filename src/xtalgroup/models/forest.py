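"""Ensemble-of-trees space-group classifier on descriptor feature tables.

A thin layer over scikit-learn's random forest that exposes per-class
probabilities as tree-vote shares (the fraction of trees predicting each
class), the top-N class ranking with frequency-then-number tie-breaking, and
a seeded random-search tuning hook.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import ParameterSampler, train_test_split

from ..descriptors import FeatureTable

DEFAULT_HYPERPARAMS = {"n_estimators": 500, "max_depth": None}


@dataclass
class ClassProbabilities:
    class_labels: list[int]
    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if (self.probs < 0).any() or abs(self.probs.sum() - 1.0) > 1e-6:
            raise ValueError("probabilities must be nonnegative and sum to 1")


@dataclass
class ForestModel:
    classifier: RandomForestClassifier
    class_labels: list[int]
    feature_names: list[int]
    training_frequency: dict[int, int]

    def vote_shares(self, x: np.ndarray) -> np.ndarray:
        """Per-class probability = fraction of trees voting for the class."""
        x = np.asarray(x, dtype=float)
        n_classes = len(self.classifier.classes_)
        votes = np.zeros((len(x), n_classes))
        rows = np.arange(len(x))
        for tree in self.classifier.estimators_:
            idx = np.argmax(tree.predict_proba(x), axis=1)
            np.add.at(votes, (rows, idx), 1.0)
        return votes / len(self.classifier.estimators_)

    def predict_proba(self, x: np.ndarray) -> list[ClassProbabilities]:
        shares = self.vote_shares(x)
        labels = [int(c) for c in self.classifier.classes_]
        return [ClassProbabilities(labels, row) for row in shares]

    def save(self, path: str | Path) -> None:
        joblib.dump(self, path)

    @classmethod
    def load(cls, path: str | Path) -> "ForestModel":
        return joblib.load(path)


def train_forest(
    table: FeatureTable,
    labels: dict[str, int] | list[int],
    hyperparams: dict | None = None,
    seed: int = 0,
    tuning_space: dict | None = None,
    tuning_budget: int = 0,
) -> ForestModel:
    """Fit the tree ensemble; optionally run a seeded random hyperparameter search.

    ``tuning_space`` maps hyperparameter name to a list of candidate values;
    ``tuning_budget`` is the number of sampled configurations, each scored on
    an internal 80/20 holdout of the training rows.
    """
    if isinstance(labels, dict):
        y = np.array([labels[rid] for rid in table.row_ids])
    else:
        y = np.asarray(labels)
    if len(y) != len(table.frame):
        raise ValueError("labels not aligned with feature rows")
    if len(set(y.tolist())) < 2:
        raise ValueError("need at least 2 classes to train")
    x = table.values
    params = dict(DEFAULT_HYPERPARAMS)
    if hyperparams:
        params.update(hyperparams)
    if tuning_space and tuning_budget > 0:
        xt, xv, yt, yv = train_test_split(x, y, test_size=0.2, random_state=seed, stratify=None)
        best_score, best = -np.inf, None
        for cand in ParameterSampler(tuning_space, n_iter=tuning_budget, random_state=seed):
            trial = dict(params)
            trial.update(cand)
            clf = RandomForestClassifier(random_state=seed, n_jobs=1, **trial)
            clf.fit(xt, yt)
            score = clf.score(xv, yv)
            if score > best_score:
                best_score, best = score, trial
        params = best
    clf = RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    clf.fit(x, y)
    return ForestModel(
        classifier=clf,
        class_labels=[int(c) for c in clf.classes_],
        feature_names=list(table.column_names),
        training_frequency=dict(Counter(int(v) for v in y)),
    )


def top_n_classes(
    probs: ClassProbabilities, n: int, training_frequency: dict[int, int] | None = None
) -> list[int]:
    """Classes of the n largest probabilities.

    Ties are broken by higher training frequency, then lower space-group
    number, so rankings are deterministic.
    """
    k = len(probs.class_labels)
    if not 1 <= n <= k:
        raise ValueError(f"n={n} out of range 1..{k}")
    freq = training_frequency or {}
    order = sorted(
        range(k),
        key=lambda i: (
            -probs.probs[i],
            -freq.get(probs.class_labels[i], 0),
            probs.class_labels[i],
        ),
    )
    return [probs.class_labels[i] for i in order[:n]]
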