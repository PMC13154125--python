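"""Model tracks: forest vote shares and ranking, graph-network contracts."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy.stats import special_ortho_group

from xtalgroup.descriptors import FeatureTable
from xtalgroup.models import (
    ClassProbabilities,
    build_gnn,
    gnn_spec,
    top_n_classes,
    train_forest,
    train_gnn,
)
from xtalgroup.models.gnn import GNNSpec
from xtalgroup.molgraph import build_graph


def _table(x, prefix="f"):
    frame = pd.DataFrame(x, columns=[f"{prefix}{j}" for j in range(x.shape[1])])
    frame.index = [f"r{i}" for i in range(len(frame))]
    return FeatureTable(frame=frame, column_class={c: "general" for c in frame.columns})


@pytest.fixture(scope="module")
def labeled_graphs(small_dataset):
    records = small_dataset[:120]
    labels = sorted({r.space_group for r in records})
    idx = {l: i for i, l in enumerate(labels)}
    graphs = [
        build_graph(r, include_coordinates=True, label_index=idx[r.space_group])
        for r in records
    ]
    return graphs, labels


class TestForest:
    def test_separable_data_fits_perfectly(self):
        rng = np.random.default_rng(0)
        x = np.vstack([rng.normal(-3, 0.3, (50, 4)), rng.normal(3, 0.3, (50, 4))])
        y = [14] * 50 + [2] * 50
        model = train_forest(_table(x), y, hyperparams={"n_estimators": 50}, seed=0)
        preds = [
            top_n_classes(p, 1, model.training_frequency)[0]
            for p in model.predict_proba(x)
        ]
        assert preds == y

    def test_vote_shares_equal_per_tree_tally(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(60, 5))
        y = list(rng.choice([2, 14, 19], size=60))
        model = train_forest(_table(x), y, hyperparams={"n_estimators": 20}, seed=1)
        shares = model.vote_shares(x[:10])
        clf = model.classifier
        manual = np.zeros_like(shares)
        for tree in clf.estimators_:
            votes = clf.classes_[np.argmax(tree.predict_proba(x[:10]), axis=1)]
            for row, c in enumerate(votes):
                manual[row, list(clf.classes_).index(c)] += 1
        assert np.allclose(shares, manual / 20)
        assert np.allclose(shares.sum(axis=1), 1.0)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(80, 6))
        y = list(rng.choice([1, 14], size=80))
        a = train_forest(_table(x), y, hyperparams={"n_estimators": 30}, seed=5)
        b = train_forest(_table(x), y, hyperparams={"n_estimators": 30}, seed=5)
        assert np.array_equal(a.vote_shares(x), b.vote_shares(x))

    def test_single_class_rejected(self):
        x = np.random.default_rng(0).normal(size=(10, 3))
        with pytest.raises(ValueError):
            train_forest(_table(x), [14] * 10)

    def test_shuffled_labels_near_chance(self):
        """Permutation null: held-out top-1 within 3 SE of 1/K for balanced labels."""
        rng = np.random.default_rng(3)
        n, k = 1000, 10
        x = rng.normal(size=(n, 8))
        y = list(rng.permutation(np.repeat(np.arange(1, k + 1), n // k)))
        model = train_forest(
            _table(x[:800]), y[:800], hyperparams={"n_estimators": 100}, seed=0
        )
        preds = [
            top_n_classes(p, 1, model.training_frequency)[0]
            for p in model.predict_proba(x[800:])
        ]
        acc = np.mean([p == t for p, t in zip(preds, y[800:])])
        se = np.sqrt(0.1 * 0.9 / 200)
        assert abs(acc - 0.1) < 3 * se

    def test_tuning_hook_runs(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(60, 4))
        y = list(rng.choice([2, 14], size=60))
        model = train_forest(
            _table(x),
            y,
            seed=0,
            tuning_space={"n_estimators": [10, 20], "max_depth": [2, None]},
            tuning_budget=3,
        )
        assert model.classifier.n_estimators in (10, 20)


class TestTopN:
    def test_ordering(self):
        probs = ClassProbabilities([2, 14, 19], [0.3, 0.6, 0.1])
        assert top_n_classes(probs, 2) == [14, 2]

    def test_all_classes(self):
        probs = ClassProbabilities([2, 14, 19], [0.3, 0.6, 0.1])
        assert set(top_n_classes(probs, 3)) == {2, 14, 19}

    def test_tie_broken_by_training_frequency(self):
        probs = ClassProbabilities([2, 19], [0.5, 0.5])
        assert top_n_classes(probs, 1, {2: 100, 19: 5}) == [2]
        assert top_n_classes(probs, 1, {2: 5, 19: 100}) == [19]

    def test_tie_without_frequency_prefers_lower_number(self):
        probs = ClassProbabilities([19, 2], [0.5, 0.5])
        assert top_n_classes(probs, 1) == [2]

    def test_out_of_range(self):
        probs = ClassProbabilities([2, 14], [0.5, 0.5])
        with pytest.raises(ValueError):
            top_n_classes(probs, 0)
        with pytest.raises(ValueError):
            top_n_classes(probs, 3)


class TestGNN:
    def test_spec_layer_invariants(self):
        with pytest.raises(ValueError):
            GNNSpec("no_coords", n_message_layers=4, n_edge_layers=1, n_dense_layers=2)
        with pytest.raises(ValueError):
            GNNSpec("augmented", n_message_layers=3, n_edge_layers=1, n_dense_layers=2)
        spec = gnn_spec("augmented")
        assert (spec.n_message_layers, spec.n_edge_layers, spec.n_dense_layers) == (4, 2, 3)

    def test_forward_returns_probability_vectors(self, labeled_graphs):
        graphs, labels = labeled_graphs
        for variant in ("no_coords", "coords", "equivariant"):
            m = build_gnn(gnn_spec(variant, hidden_width=12, seed=0), n_classes=len(labels))
            p = m.predict_proba(graphs[:6])
            assert p.shape == (6, len(labels))
            assert (p >= 0).all() and np.allclose(p.sum(axis=1), 1.0)

    def test_equivariant_invariance_to_rigid_motion(self, labeled_graphs):
        graphs, labels = labeled_graphs
        m = build_gnn(gnn_spec("equivariant", hidden_width=12, seed=1), n_classes=len(labels))
        base = m.predict_proba(graphs[:8])
        rng = np.random.default_rng(0)
        for _ in range(10):
            rot = special_ortho_group.rvs(3, random_state=rng)
            shift = rng.normal(size=3)
            moved = [
                dataclasses.replace(g, coordinates=g.coordinates @ rot.T + shift)
                for g in graphs[:8]
            ]
            assert np.abs(m.predict_proba(moved) - base).max() < 1e-5

    def test_no_coords_ignores_coordinates_exactly(self, labeled_graphs):
        graphs, labels = labeled_graphs
        m = build_gnn(gnn_spec("no_coords", hidden_width=12, seed=2), n_classes=len(labels))
        stripped = [dataclasses.replace(g, coordinates=None) for g in graphs[:6]]
        assert np.array_equal(m.predict_proba(graphs[:6]), m.predict_proba(stripped))

    def test_best_checkpoint_contract(self, labeled_graphs):
        graphs, labels = labeled_graphs
        spec = gnn_spec(
            "no_coords", hidden_width=12, seed=0, batch_size=16, learning_rate=3e-3
        )
        m = build_gnn(spec, n_classes=len(labels))
        m, log = train_gnn(m, graphs[:60], graphs[60:90], spec, epochs=8)
        from xtalgroup.models.gnn import collate
        from xtalgroup.models._autodiff import cross_entropy

        batch = collate(graphs[60:90])
        lab = np.array([g.label for g in graphs[60:90]])
        final_val = float(cross_entropy(m.forward(batch), lab).data)
        assert final_val <= min(l["val_loss"] for l in log) + 1e-9

    def test_augmented_variant_quadruples_batch(self, labeled_graphs, monkeypatch):
        graphs, labels = labeled_graphs
        import xtalgroup.models.gnn as gnn_mod

        sizes = []
        orig = gnn_mod.collate

        def spy(gs):
            sizes.append(len(gs))
            return orig(gs)

        monkeypatch.setattr(gnn_mod, "collate", spy)
        spec = gnn_spec("augmented", hidden_width=8, seed=0, batch_size=16)
        m = build_gnn(spec, n_classes=len(labels))
        train_gnn(m, graphs[:16], graphs[16:24], spec, epochs=1)
        assert 64 in sizes

    def test_training_reduces_loss_and_overfits_small_set(self, small_dataset):
        """Capacity check: a small unique-molecule set is driven below CE 0.05."""
        seen, uniq = set(), []
        for r in small_dataset:
            if r.smiles not in seen:
                seen.add(r.smiles)
                uniq.append(r)
        records = uniq[:32]
        labels = sorted({r.space_group for r in records})
        idx = {l: i for i, l in enumerate(labels)}
        graphs = [build_graph(r, True, label_index=idx[r.space_group]) for r in records]
        spec = gnn_spec(
            "coords", hidden_width=32, batch_size=8, seed=0, learning_rate=5e-3
        )
        m = build_gnn(spec, n_classes=len(labels))
        m, log = train_gnn(m, graphs, graphs, spec, epochs=200)
        assert log[-1]["train_loss"] < 0.05

    def test_save_load_round_trip(self, labeled_graphs, tmp_path):
        graphs, labels = labeled_graphs
        m = build_gnn(gnn_spec("coords", hidden_width=8, seed=3), n_classes=len(labels))
        m.save(tmp_path / "model")
        from xtalgroup.models.gnn import GraphNetModel

        again = GraphNetModel.load(tmp_path / "model")
        assert np.array_equal(m.predict_proba(graphs[:4]), again.predict_proba(graphs[:4]))
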