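"""Graph-network classifiers for space-group prediction.

Two architectures, four variants:

* ``no_coords`` / ``coords`` — edge-conditioned convolution (NNConv style):
  each message-passing layer feeds the edge attributes through an edge network
  producing a per-edge weight matrix that transforms the neighbor embedding;
  messages are mean-aggregated. 3 message-passing layers (1 edge layer),
  global mean pool, 2 dense layers. The ``coords`` variant appends raw
  Cartesian coordinates to the node features (not rotation invariant).
* ``augmented`` — same convolution but trained with rotation-augmented
  batches (each batch quadrupled), with a larger network: 4 message-passing
  layers (2 edge layers), 3 dense layers.
* ``equivariant`` — E(n)-style layers whose messages use only node embeddings
  and squared pairwise distances; coordinate updates stay internal and the
  readout uses node embeddings only, so class probabilities are exactly
  invariant to rigid motions of the input conformer.

Training uses Adam, ReLU activations, softmax cross-entropy, optional
per-graph feature normalization between message layers, global-norm gradient
clipping, and retains the parameters with the best validation loss.
"""

from __future__ import annotations

import copy
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ..molgraph import EDGE_DIM, NODE_DIM, MolecularGraph, augment_batch
from ._autodiff import Adam, Parameter, Tensor, concat, cross_entropy, glorot, softmax

logger = logging.getLogger(__name__)

VARIANTS = ("no_coords", "coords", "augmented", "equivariant")


@dataclass
class GNNSpec:
    variant: str
    n_message_layers: int
    n_edge_layers: int
    n_dense_layers: int
    hidden_width: int = 64
    normalization: bool = True
    grad_clip: float = 1.0
    learning_rate: float = 1e-3
    batch_size: int = 16
    max_epochs: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        expected = {
            "no_coords": (3, 1, 2),
            "coords": (3, 1, 2),
            "augmented": (4, 2, 3),
            "equivariant": (3, 0, 2),
        }[self.variant]
        got = (self.n_message_layers, self.n_edge_layers, self.n_dense_layers)
        if got != expected:
            raise ValueError(
                f"layer counts {got} inconsistent with variant {self.variant!r}; "
                f"expected (MP, EL, NN) = {expected}"
            )
        if self.grad_clip <= 0:
            raise ValueError("grad_clip must be positive")


def gnn_spec(variant: str, **overrides) -> GNNSpec:
    """Spec with the layer counts fixed per variant."""
    counts = {
        "no_coords": (3, 1, 2),
        "coords": (3, 1, 2),
        "augmented": (4, 2, 3),
        "equivariant": (3, 0, 2),
    }
    if variant not in counts:
        raise ValueError(f"unknown variant {variant!r}")
    mp, el, nn = counts[variant]
    return GNNSpec(
        variant=variant, n_message_layers=mp, n_edge_layers=el, n_dense_layers=nn, **overrides
    )


@dataclass
class Batch:
    node_x: np.ndarray
    edge_index: np.ndarray
    edge_attrs: np.ndarray
    coords: np.ndarray | None
    graph_ids: np.ndarray
    labels: np.ndarray
    n_graphs: int


def collate(graphs: list[MolecularGraph]) -> Batch:
    xs, eidx, eattr, coords, gids, labels = [], [], [], [], [], []
    offset = 0
    has_coords = all(g.coordinates is not None for g in graphs)
    for gid, g in enumerate(graphs):
        xs.append(g.node_attrs)
        eidx.append(g.edge_index + offset)
        eattr.append(g.edge_attrs)
        if has_coords:
            coords.append(g.coordinates)
        gids.append(np.full(g.n_nodes, gid))
        labels.append(g.label)
        offset += g.n_nodes
    return Batch(
        node_x=np.vstack(xs),
        edge_index=np.hstack(eidx),
        edge_attrs=np.vstack(eattr),
        coords=np.vstack(coords) if has_coords else None,
        graph_ids=np.concatenate(gids),
        labels=np.array(labels, dtype=int),
        n_graphs=len(graphs),
    )


class _MLP:
    def __init__(self, rng, dims: list[int], prefix: str, params: dict):
        self.layers = []
        for i, (a, b) in enumerate(zip(dims[:-1], dims[1:])):
            w = Parameter(glorot(rng, a, b))
            bias = Parameter(np.zeros(b))
            params[f"{prefix}_w{i}"] = w
            params[f"{prefix}_b{i}"] = bias
            self.layers.append((w, bias))

    def __call__(self, x: Tensor, final_relu: bool = False) -> Tensor:
        for i, (w, b) in enumerate(self.layers):
            x = x.matmul(w) + b
            if i < len(self.layers) - 1 or final_relu:
                x = x.relu()
        return x


def _graph_norm(
    h: Tensor, graph_ids: np.ndarray, n_graphs: int, gamma: Parameter, beta: Parameter
) -> Tensor:
    """Per-graph feature standardization with a learnable affine.

    Applied between message-passing layers only — normalizing after the last
    layer would zero the per-graph mean and collapse the mean-pool readout.
    """
    mu = h.segment_mean(graph_ids, n_graphs).gather_rows(graph_ids)
    centered = h - mu
    var = (centered * centered).segment_mean(graph_ids, n_graphs).gather_rows(graph_ids)
    return centered * (var + 1e-5).pow(-0.5) * gamma + beta


class GraphNetModel:
    """Trainable graph classifier (NNConv-style or equivariant variant)."""

    def __init__(self, spec: GNNSpec, node_dim: int = NODE_DIM, edge_dim: int = EDGE_DIM,
                 n_classes: int = 2, class_labels: list[int] | None = None):
        if n_classes < 2:
            raise ValueError("need at least 2 classes")
        self.spec = spec
        self.node_dim = node_dim
        self.edge_dim = edge_dim
        self.n_classes = n_classes
        self.class_labels = class_labels or list(range(n_classes))
        if len(self.class_labels) != n_classes:
            raise ValueError("class_labels length must equal n_classes")
        self.params: dict[str, Parameter] = {}
        rng = np.random.default_rng(spec.seed)
        h = spec.hidden_width
        in_dim = node_dim + (3 if spec.variant in ("coords", "augmented") else 0)
        self.embed = _MLP(rng, [in_dim, h], "embed", self.params)
        self.mp: list = []
        if spec.variant == "equivariant":
            for l in range(spec.n_message_layers):
                phi_e = _MLP(rng, [2 * h + 1, h, h], f"mp{l}_e", self.params)
                phi_x = _MLP(rng, [h, 1], f"mp{l}_x", self.params)
                phi_h = _MLP(rng, [2 * h, h, h], f"mp{l}_h", self.params)
                self.mp.append((phi_e, phi_x, phi_h))
        else:
            edge_dims = [edge_dim] + [h] * (spec.n_edge_layers - 1) + [h * h]
            for l in range(spec.n_message_layers):
                edge_nn = _MLP(rng, edge_dims, f"mp{l}_edge", self.params)
                root = Parameter(glorot(rng, h, h))
                bias = Parameter(np.zeros(h))
                self.params[f"mp{l}_root"] = root
                self.params[f"mp{l}_bias"] = bias
                self.mp.append((edge_nn, root, bias))
        self.norms: list[tuple[Parameter, Parameter]] = []
        if spec.normalization:
            for l in range(spec.n_message_layers - 1):
                gamma = Parameter(np.ones(h))
                beta = Parameter(np.zeros(h))
                self.params[f"norm{l}_gamma"] = gamma
                self.params[f"norm{l}_beta"] = beta
                self.norms.append((gamma, beta))
        dense_dims = [h] * spec.n_dense_layers + [n_classes]
        self.dense = _MLP(rng, dense_dims, "dense", self.params)

    # -- forward ------------------------------------------------------------

    def forward(self, batch: Batch) -> Tensor:
        spec = self.spec
        n_nodes = batch.node_x.shape[0]
        src, dst = batch.edge_index
        if spec.variant in ("coords", "augmented"):
            if batch.coords is None:
                raise ValueError(f"variant {spec.variant!r} requires coordinates")
            x_in = np.hstack([batch.node_x, batch.coords])
        else:
            x_in = batch.node_x
        h = self.embed(Tensor(x_in), final_relu=True)
        if spec.variant == "equivariant":
            if batch.coords is None:
                raise ValueError("equivariant variant requires coordinates")
            x = Tensor(batch.coords)
            for l, (phi_e, phi_x, phi_h) in enumerate(self.mp):
                diff = x.gather_rows(dst) - x.gather_rows(src)
                d2 = (diff * diff).sum(axis=1, keepdims=True)
                m = phi_e(concat([h.gather_rows(src), h.gather_rows(dst), d2]))
                w = phi_x(m)
                x = x + (diff * w).segment_mean(dst, n_nodes)
                agg = m.segment_mean(dst, n_nodes)
                h = h + phi_h(concat([h, agg]))
                if spec.normalization and l < len(self.mp) - 1:
                    gamma, beta = self.norms[l]
                    h = _graph_norm(h, batch.graph_ids, batch.n_graphs, gamma, beta)
        else:
            hw = spec.hidden_width
            eattr = Tensor(batch.edge_attrs)
            for l, (edge_nn, root, bias) in enumerate(self.mp):
                w_e = edge_nn(eattr).reshape(-1, hw, hw)
                h_src = h.gather_rows(src).reshape(-1, 1, hw)
                msg = h_src.bmm(w_e).reshape(-1, hw)
                agg = msg.segment_mean(dst, n_nodes)
                h = (h.matmul(root) + agg + bias).relu()
                if spec.normalization and l < len(self.mp) - 1:
                    gamma, beta = self.norms[l]
                    h = _graph_norm(h, batch.graph_ids, batch.n_graphs, gamma, beta)
        pooled = h.segment_mean(batch.graph_ids, batch.n_graphs)
        return self.dense(pooled)

    def predict_proba(self, graphs: list[MolecularGraph]) -> np.ndarray:
        batch = collate(graphs)
        return softmax(self.forward(batch).data)

    # -- persistence --------------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, p in self.params.items():
            p.data = state[k].copy()

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.state_dict())
        meta = {
            "spec": self.spec.__dict__,
            "node_dim": self.node_dim,
            "edge_dim": self.edge_dim,
            "n_classes": self.n_classes,
            "class_labels": self.class_labels,
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "GraphNetModel":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        model = cls(
            GNNSpec(**meta["spec"]),
            node_dim=meta["node_dim"],
            edge_dim=meta["edge_dim"],
            n_classes=meta["n_classes"],
            class_labels=meta["class_labels"],
        )
        with np.load(path.with_suffix(".npz")) as state:
            model.load_state_dict({k: state[k] for k in state.files})
        return model


def build_gnn(
    spec: GNNSpec, node_dim: int = NODE_DIM, edge_dim: int = EDGE_DIM,
    n_classes: int = 2, class_labels: list[int] | None = None,
) -> GraphNetModel:
    return GraphNetModel(spec, node_dim, edge_dim, n_classes, class_labels)


def train_gnn(
    model: GraphNetModel,
    train_graphs: list[MolecularGraph],
    val_graphs: list[MolecularGraph],
    spec: GNNSpec | None = None,
    epochs: int | None = None,
) -> tuple[GraphNetModel, list[dict]]:
    """Minimize softmax cross-entropy with Adam; keep the best-validation weights.

    For the ``augmented`` variant each training batch is quadrupled by
    rotation augmentation before the optimizer step; validation is never
    augmented. Returns the model (restored to the best-validation checkpoint)
    and a per-epoch log of train/validation loss.
    """
    spec = spec or model.spec
    if not train_graphs or not val_graphs:
        raise ValueError("train and validation sets must be non-empty")
    n_epochs = epochs if epochs is not None else spec.max_epochs
    rng = np.random.default_rng(spec.seed)
    opt = Adam(
        list(model.params.values()), lr=spec.learning_rate, grad_clip=spec.grad_clip
    )
    label_to_index = {lab: i for i, lab in enumerate(model.class_labels)}

    def loss_of(graphs: list[MolecularGraph]) -> float:
        batch = collate(graphs)
        labels = np.array([label_to_index[g.label] for g in graphs])
        logits = model.forward(batch)
        return float(cross_entropy(logits, labels).data)

    best_state = model.state_dict()
    best_val = loss_of(val_graphs)
    log: list[dict] = []
    order = np.arange(len(train_graphs))
    for epoch in range(n_epochs):
        rng.shuffle(order)
        epoch_losses = []
        for start in range(0, len(order), spec.batch_size):
            chunk = [train_graphs[i] for i in order[start : start + spec.batch_size]]
            if spec.variant == "augmented":
                chunk = augment_batch(chunk, seed=int(rng.integers(2**31)))
            batch = collate(chunk)
            labels = np.array([label_to_index[g.label] for g in chunk])
            logits = model.forward(batch)
            loss = cross_entropy(logits, labels)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"divergent loss at epoch {epoch}: {float(loss.data)}; "
                    f"log so far: {log[-3:]}"
                )
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data))
        val_loss = loss_of(val_graphs)
        log.append(
            {"epoch": epoch, "train_loss": float(np.mean(epoch_losses)), "val_loss": val_loss}
        )
        if val_loss < best_val:
            best_val = val_loss
            best_state = model.state_dict()
    model.load_state_dict(best_state)
    return model, log
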