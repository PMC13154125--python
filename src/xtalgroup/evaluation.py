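"""Top-N evaluation with frequency/random baselines and 1/N-scaled precision-recall.

Because crystal-structure prediction is run over a set of candidate space
groups rather than a single one, classifiers are scored by top-N accuracy
(N = 1, 3, 5, 10 by default) against two baselines: the *frequency reference*
(always predict the N most frequent space groups; its accuracy is the
proportion of the test set covered by them) and, for balanced datasets, the
*random reference* 100 * N / M with M classes.

Per-class precision and recall for top-N lists follow a 1/N-scaled tally:
each example contributes tp = 1 to its true class if that class is listed
(else fn = 1), and every other listed class collects fp = 1/N — including the
co-listed classes of a correct prediction. Never-predicted classes have
undefined precision, reported as missing rather than zero.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.model_selection import KFold

from .descriptors import FeatureTable
from .models.forest import ForestModel, top_n_classes, train_forest

DEFAULT_N_SET = (1, 3, 5, 10)


@dataclass
class ClassScores:
    tp: float
    fp: float
    fn: float
    recall: float | None
    precision: float | None


@dataclass
class EvalReport:
    n_test: int
    per_n: dict[int, dict]  # n -> {top_n_accuracy, reference_accuracy, delta, per_class}

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "n_test": self.n_test,
            "per_n": {
                str(n): {
                    **{k: v for k, v in d.items() if k != "per_class"},
                    "per_class": {
                        str(c): vars(s) for c, s in d["per_class"].items()
                    },
                }
                for n, d in self.per_n.items()
            },
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text: str) -> "EvalReport":
        payload = json.loads(text)
        per_n = {}
        for n, d in payload["per_n"].items():
            per_class = {
                int(c): ClassScores(**s) for c, s in d["per_class"].items()
            }
            entry = {k: v for k, v in d.items() if k != "per_class"}
            entry["per_class"] = per_class
            per_n[int(n)] = entry
        return cls(n_test=payload["n_test"], per_n=per_n)


def top_n_accuracy(truths: Sequence[int], predictions: Sequence[Sequence[int]]) -> float:
    """Percent of examples whose true label appears in their top-N list."""
    if len(truths) != len(predictions):
        raise ValueError("truths and predictions differ in length")
    if not truths:
        raise ValueError("empty test set")
    hits = sum(1 for t, p in zip(truths, predictions) if t in p)
    return 100.0 * hits / len(truths)


def reference_accuracy_frequency(
    test_truths: Sequence[int], frequency_order: Sequence[int], n: int
) -> float:
    """Percent of test truths covered by the n most frequent space groups."""
    missing = set(test_truths) - set(frequency_order)
    if missing:
        raise ValueError(f"frequency order does not cover labels {sorted(missing)}")
    top = set(list(frequency_order)[:n])
    return 100.0 * sum(1 for t in test_truths if t in top) / len(test_truths)


def reference_accuracy_balanced(m_classes: int, n: int) -> float:
    """Random-guess reference for a balanced M-class set: 100 * n / M percent."""
    if not 1 <= n <= m_classes:
        raise ValueError(f"n={n} out of range 1..{m_classes}")
    return 100.0 * n / m_classes


def frequency_order(labels: Sequence[int]) -> list[int]:
    """Space groups by descending frequency; ties to the lower group number."""
    counts = Counter(labels)
    return sorted(counts, key=lambda sg: (-counts[sg], sg))


def scaled_precision_recall(
    truths: Sequence[int], predictions: Sequence[Sequence[int]]
) -> dict[int, ClassScores]:
    """Per-class (tp, fp, fn, recall, precision) under the 1/N-scaled fp rule."""
    if len(truths) != len(predictions):
        raise ValueError("truths and predictions differ in length")
    tp: Counter = Counter()
    fp: Counter = Counter()
    fn: Counter = Counter()
    classes = set(truths)
    for t, preds in zip(truths, predictions):
        n = len(preds)
        classes.update(preds)
        if t in preds:
            tp[t] += 1.0
            for h in preds:
                if h != t:
                    fp[h] += 1.0 / n
        else:
            fn[t] += 1.0
            for h in preds:
                fp[h] += 1.0 / n
    out: dict[int, ClassScores] = {}
    for c in sorted(classes):
        t_, f_, m_ = tp[c], fp[c], fn[c]
        recall = t_ / (t_ + m_) if t_ + m_ > 0 else None
        precision = t_ / (t_ + f_) if t_ + f_ > 0 else None
        out[c] = ClassScores(tp=t_, fp=f_, fn=m_, recall=recall, precision=precision)
    return out


def forest_top_n_lists(
    model: ForestModel, x: np.ndarray, n: int
) -> list[list[int]]:
    return [
        top_n_classes(p, n, model.training_frequency) for p in model.predict_proba(x)
    ]


def evaluate(
    model: ForestModel,
    table: FeatureTable,
    labels: dict[str, int] | Sequence[int],
    n_set: Sequence[int] = DEFAULT_N_SET,
    reference: tuple[str, object] | None = None,
) -> EvalReport:
    """Assemble top-N accuracies, reference accuracies, deltas and class scores.

    ``reference`` is ("frequency", order_list) or ("balanced", m_classes);
    default is the frequency reference with the order taken from the model's
    training labels.
    """
    if isinstance(labels, dict):
        truths = [labels[rid] for rid in table.row_ids]
    else:
        truths = list(labels)
    if not truths:
        raise ValueError("empty test set")
    if reference is None:
        order = sorted(
            model.training_frequency,
            key=lambda sg: (-model.training_frequency[sg], sg),
        )
        reference = ("frequency", order)
    kind, arg = reference
    x = table.values
    per_n: dict[int, dict] = {}
    n_classes = len(model.class_labels)
    for n in n_set:
        n_eff = min(n, n_classes)
        preds = forest_top_n_lists(model, x, n_eff)
        acc = top_n_accuracy(truths, preds)
        if kind == "frequency":
            ref = reference_accuracy_frequency(truths, list(arg), n_eff)
        elif kind == "balanced":
            ref = reference_accuracy_balanced(int(arg), n_eff)
        else:
            raise ValueError(f"unknown reference kind {kind!r}")
        per_n[n] = {
            "top_n_accuracy": acc,
            "reference_accuracy": ref,
            "delta": acc - ref,
            "per_class": scaled_precision_recall(truths, preds),
        }
    return EvalReport(n_test=len(truths), per_n=per_n)


def cross_validate(
    table: FeatureTable,
    labels: dict[str, int] | Sequence[int],
    k: int = 10,
    seed: int = 0,
    hyperparams: dict | None = None,
    n_set: Sequence[int] = DEFAULT_N_SET,
) -> dict:
    """k-fold cross-validation of the forest track.

    Returns per-fold top-N accuracies and deltas against the frequency
    reference (order fitted on each training fold), with mean and standard
    deviation over folds.
    """
    if isinstance(labels, dict):
        y = np.array([labels[rid] for rid in table.row_ids])
    else:
        y = np.asarray(list(labels))
    if k < 2 or len(y) < k:
        raise ValueError("need k >= 2 and at least k records")
    folds: dict[int, list[dict]] = {n: [] for n in n_set}
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    x_frame = table.frame
    for train_idx, test_idx in kf.split(x_frame):
        sub = FeatureTable(
            frame=x_frame.iloc[train_idx],
            column_class=table.column_class,
            geometry_source=table.geometry_source,
        )
        model = train_forest(sub, list(y[train_idx]), hyperparams=hyperparams, seed=seed)
        order = frequency_order(y[train_idx])
        # classes unseen in training stay in the reference order at the end
        order += [c for c in sorted(set(y)) if c not in order]
        truths = list(y[test_idx])
        xt = x_frame.iloc[test_idx].to_numpy(dtype=float)
        for n in n_set:
            n_eff = min(n, len(model.class_labels))
            preds = forest_top_n_lists(model, xt, n_eff)
            acc = top_n_accuracy(truths, preds)
            ref = reference_accuracy_frequency(truths, order, n_eff)
            folds[n].append({"accuracy": acc, "reference": ref, "delta": acc - ref})
    out = {}
    for n in n_set:
        accs = np.array([f["accuracy"] for f in folds[n]])
        deltas = np.array([f["delta"] for f in folds[n]])
        out[n] = {
            "folds": folds[n],
            "mean_accuracy": float(accs.mean()),
            "std_accuracy": float(accs.std(ddof=1)),
            "mean_delta": float(deltas.mean()),
            "std_delta": float(deltas.std(ddof=1)),
        }
    return out


def permutation_importance(
    model: ForestModel,
    table: FeatureTable,
    labels: dict[str, int] | Sequence[int],
    n_repeats: int = 10,
    seed: int = 0,
    columns: Sequence[str] | None = None,
) -> dict[str, dict]:
    """Mean top-1 accuracy drop when each feature column is shuffled.

    ``columns`` restricts the computation to a subset of features.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    if isinstance(labels, dict):
        truths = [labels[rid] for rid in table.row_ids]
    else:
        truths = list(labels)
    rng = np.random.default_rng(seed)
    x = table.values.copy()
    baseline = top_n_accuracy(truths, forest_top_n_lists(model, x, 1))
    out: dict[str, dict] = {}
    targets = list(columns) if columns is not None else table.column_names
    for name in targets:
        j = table.column_names.index(name)
        drops = []
        for _ in range(n_repeats):
            xp = x.copy()
            xp[:, j] = rng.permutation(xp[:, j])
            acc = top_n_accuracy(truths, forest_top_n_lists(model, xp, 1))
            drops.append(baseline - acc)
        drops = np.array(drops)
        out[name] = {
            "importance": float(drops.mean()),
            "std": float(drops.std(ddof=1)) if n_repeats > 1 else 0.0,
            "baseline": baseline,
        }
    return out
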