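"""Graph-level classifiers over per-sample subgraphs.

A :class:`GraphNetClassifier` stacks GCN / GAT / GATv2 layers, pools
node embeddings into a graph embedding, and applies a linear two-class
head.  It follows the sklearn estimator contract (``fit``,
``predict_proba``, ``predict``, ``get_params``/``set_params``, fitted
attributes with trailing underscores) so it composes with sklearn model
selection utilities.

Empty subgraphs — samples that fell into no cluster — receive a
prior-based default probability and are flagged rather than failing.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from ..graph import SampleSubgraph
from .autograd import Adam, Tensor, concatenate
from .layers import GATLayer, GATv2Layer, GCNLayer, Linear, graph_readout

__all__ = ["GraphNet", "GraphNetClassifier", "train_classifier", "predict",
           "save_checkpoint", "load_checkpoint"]

MODELS = ("gcn", "gat", "gatv2")


class GraphNet:
    """A stack of graph layers plus readout and a linear softmax head."""

    def __init__(self, model: str, in_dim: int, hidden_dim: int,
                 n_layers: int, n_heads: int, pooling: str,
                 rng: np.random.Generator, edge_bias: bool = False):
        if model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}")
        self.model = model
        self.pooling = pooling
        self.layers: list = []
        dim = in_dim
        for layer_i in range(n_layers):
            last = layer_i == n_layers - 1
            if model == "gcn":
                self.layers.append(GCNLayer(dim, hidden_dim, rng))
                dim = hidden_dim
            else:
                cls = GATLayer if model == "gat" else GATv2Layer
                # concatenate heads in hidden layers, average in the last
                concat = not last
                self.layers.append(cls(dim, hidden_dim, rng, n_heads=n_heads,
                                       concat=concat, edge_bias=edge_bias))
                dim = hidden_dim * (n_heads if concat else 1)
        self.head = Linear(dim, 2, rng)
        self.out_dim = dim

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for layer in self.layers:
            params.extend(layer.parameters())
        params.extend(self.head.parameters())
        return params

    def forward(self, sub: SampleSubgraph, weighted: bool = True) -> Tensor:
        """Logits (1, 2) for one subgraph; empty graphs embed as zeros."""
        if sub.n_nodes == 0:
            emb = Tensor(np.zeros((1, self.out_dim)))
            return self.head(emb)
        h = Tensor(sub.node_features)
        a = sub.adjacency(weighted=weighted)
        for layer in self.layers:
            h = layer(h, a)
        emb = graph_readout(h, self.pooling).reshape(1, -1)
        return self.head(emb)


def _cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    onehot = np.zeros(logits.shape)
    onehot[np.arange(len(labels)), labels] = 1.0
    logp = logits.log_softmax(axis=1)
    return -(logp * onehot).sum() * (1.0 / len(labels))


class GraphNetClassifier:
    """Two-class graph-level classifier with seeded, deterministic training.

    Parameters
    ----------
    model : {"gcn", "gat", "gatv2"}
    hidden_dim, n_layers, n_heads : architecture knobs.
    lr, epochs : Adam learning rate and fixed epoch budget (no early
        stopping by default, which keeps runs bit-reproducible).
    pooling : {"mean", "sum", "max"} graph readout.
    weighted_adjacency : feed normalized shared-sample counts as GCN edge
        weights (attention models take them as a logit bias when
        ``edge_bias`` is set).
    patience : optional early stopping on training loss; ``None`` (the
        default) trains for the full epoch budget.
    """

    _param_names = ("model", "hidden_dim", "n_layers", "n_heads", "lr",
                    "epochs", "pooling", "weighted_adjacency", "edge_bias",
                    "patience", "random_state")

    def __init__(self, model: str = "gcn", hidden_dim: int = 64,
                 n_layers: int = 2, n_heads: int = 4, lr: float = 0.01,
                 epochs: int = 50, pooling: str = "mean",
                 weighted_adjacency: bool = True, edge_bias: bool = False,
                 patience: int | None = None, random_state: int = 0):
        self.model = model
        self.hidden_dim = hidden_dim
        self.n_layers = n_layers
        self.n_heads = n_heads
        self.lr = lr
        self.epochs = epochs
        self.pooling = pooling
        self.weighted_adjacency = weighted_adjacency
        self.edge_bias = edge_bias
        self.patience = patience
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in self._param_names}

    def set_params(self, **params) -> "GraphNetClassifier":
        for k, v in params.items():
            if k not in self._param_names:
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    # -- fitting ---------------------------------------------------------------

    def fit(self, subgraphs: list[SampleSubgraph],
            labels: list[str] | None = None) -> "GraphNetClassifier":
        if labels is None:
            labels = [s.label for s in subgraphs]
        if any(lbl is None for lbl in labels):
            raise ValueError("every training subgraph needs a label")
        self.classes_ = sorted(set(labels))
        if len(self.classes_) != 2:
            raise ValueError("exactly two classes required for training")
        y = np.array([self.classes_.index(lbl) for lbl in labels])
        self.class_prior_ = np.bincount(y, minlength=2) / len(y)

        in_dim = subgraphs[0].node_features.shape[1]
        self.feature_names_ = list(subgraphs[0].feature_names)
        rng = np.random.default_rng(self.random_state)
        self.net_ = GraphNet(self.model, in_dim, self.hidden_dim,
                             self.n_layers, self.n_heads, self.pooling, rng,
                             edge_bias=self.edge_bias)
        opt = Adam(self.net_.parameters(), lr=self.lr)
        self.history_ = []
        best = np.inf
        since_best = 0
        for _ in range(self.epochs):
            opt.zero_grad()
            logits = concatenate(
                [self.net_.forward(s, weighted=self.weighted_adjacency)
                 for s in subgraphs], axis=0)
            loss = _cross_entropy(logits, y)
            loss.backward()
            opt.step()
            value = float(loss.data)
            self.history_.append(value)
            if self.patience is not None:
                if value < best - 1e-6:
                    best, since_best = value, 0
                else:
                    since_best += 1
                    if since_best >= self.patience:
                        break
        return self

    # -- inference -------------------------------------------------------------

    def predict_proba(self, subgraphs: list[SampleSubgraph]) -> np.ndarray:
        if not hasattr(self, "net_"):
            raise ValueError("classifier is not fitted")
        for s in subgraphs:
            if s.n_nodes and s.node_features.shape[1] != len(self.feature_names_):
                raise ValueError(
                    f"feature dimension mismatch for sample {s.sample_id!r}")
        probs = np.empty((len(subgraphs), 2))
        self.default_flags_ = np.zeros(len(subgraphs), dtype=bool)
        for i, s in enumerate(subgraphs):
            if s.is_empty or s.n_nodes == 0:
                probs[i] = self.class_prior_
                self.default_flags_[i] = True
                continue
            logits = self.net_.forward(s, weighted=self.weighted_adjacency)
            probs[i] = logits.softmax(axis=1).data[0]
        return probs

    def predict(self, subgraphs: list[SampleSubgraph]) -> list[str]:
        probs = self.predict_proba(subgraphs)
        return [self.classes_[int(i)] for i in probs.argmax(axis=1)]

    def score(self, subgraphs: list[SampleSubgraph],
              labels: list[str] | None = None) -> float:
        if labels is None:
            labels = [s.label for s in subgraphs]
        pred = self.predict(subgraphs)
        return float(np.mean([p == t for p, t in zip(pred, labels)]))


def train_classifier(train: list[SampleSubgraph],
                     **config) -> GraphNetClassifier:
    """Functional wrapper: fit a :class:`GraphNetClassifier` on subgraphs."""
    return GraphNetClassifier(**config).fit(train)


def predict(model: GraphNetClassifier,
            subgraphs: list[SampleSubgraph]) -> np.ndarray:
    """Per-sample class probabilities (rows sum to 1)."""
    return model.predict_proba(subgraphs)


# -- checkpoints ---------------------------------------------------------------


def save_checkpoint(clf: GraphNetClassifier, path: str | Path,
                    extra: dict | None = None) -> None:
    """JSON checkpoint: config, classes, and all weights."""
    payload = {
        "config": clf.get_params(),
        "classes": clf.classes_,
        "class_prior": clf.class_prior_.tolist(),
        "feature_names": clf.feature_names_,
        "weights": [p.data.tolist() for p in clf.net_.parameters()],
        "extra": extra or {},
    }
    Path(path).write_text(json.dumps(payload))


def load_checkpoint(path: str | Path) -> GraphNetClassifier:
    payload = json.loads(Path(path).read_text())
    clf = GraphNetClassifier(**payload["config"])
    clf.classes_ = payload["classes"]
    clf.class_prior_ = np.array(payload["class_prior"])
    clf.feature_names_ = payload["feature_names"]
    rng = np.random.default_rng(clf.random_state)
    clf.net_ = GraphNet(clf.model, len(clf.feature_names_), clf.hidden_dim,
                        clf.n_layers, clf.n_heads, clf.pooling, rng,
                        edge_bias=clf.edge_bias)
    for p, w in zip(clf.net_.parameters(), payload["weights"]):
        p.data = np.asarray(w, dtype=float)
    return clf
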