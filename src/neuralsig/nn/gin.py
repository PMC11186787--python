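"""Graph isomorphism network regressor for neural-score prediction.

Three GIN convolution layers process a batch of spot subgraphs. Each
layer combines a node's own features with the rectified sum of its
neighbors' features (self-loops included),

    combine_v = (1 + eps) * x_v + sum_{u in N(v)} ReLU(x_u),

passes the result through a two-layer MLP, batch normalization, a
LeakyReLU with negative slope 0.2 and dropout 0.5. The final node
embeddings are merged into a latent space by a Xavier-initialized affine
map, global mean pooling produces one vector per subgraph, and an MLP
head  h(x) = W2 . Dropout(BatchNorm(ReLU(W1 x + b1))) + b2  emits the
scalar score. Training minimizes mean absolute error with Adam over
mini-batches of 32 subgraphs.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import scipy.sparse
import warnings

from .autodiff import Adam, Tensor, absolute, dropout, leaky_relu, relu, spmm

__all__ = [
    "Linear",
    "BatchNorm",
    "GINLayer",
    "GNNModel",
    "TrainConfig",
    "GraphExample",
    "subgraph_example",
    "batch_examples",
    "train",
    "predict",
    "evaluate",
]


class Linear:
    """Affine map with uniform (default) or Xavier-uniform initialization."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 init: str = "uniform"):
        if init == "xavier":
            limit = np.sqrt(6.0 / (in_dim + out_dim))
        elif init == "uniform":
            limit = 1.0 / np.sqrt(in_dim)
        else:
            raise ValueError(f"unknown init {init!r}")
        self.weight = Tensor(
            rng.uniform(-limit, limit, size=(in_dim, out_dim)), requires_grad=True
        )
        self.bias = Tensor(rng.uniform(-limit, limit, size=out_dim),
                           requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias

    def parameters(self) -> list[Tensor]:
        return [self.weight, self.bias]


class BatchNorm:
    """Per-feature batch normalization with running statistics for eval."""

    def __init__(self, dim: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        if training:
            mu = x.mean(axis=0)
            var = ((x - mu) ** 2.0).mean(axis=0)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mu.data
            )
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var.data
            )
            inv = (var + self.eps) ** -0.5
            return (x - mu) * inv * self.gamma + self.beta
        inv = 1.0 / np.sqrt(self.running_var + self.eps)
        return (x - Tensor(self.running_mean)) * Tensor(inv) * self.gamma + self.beta

    def parameters(self) -> list[Tensor]:
        return [self.gamma, self.beta]


class GINLayer:
    """One GIN convolution: epsilon-weighted combine, MLP, norm, activation."""

    def __init__(
        self,
        in_dim: int,
        out_dim: int,
        rng: np.random.Generator,
        leaky_slope: float = 0.2,
        dropout_rate: float = 0.5,
    ):
        self.epsilon = Tensor(0.0, requires_grad=True)
        self.lin1 = Linear(in_dim, out_dim, rng)
        self.lin2 = Linear(out_dim, out_dim, rng)
        self.norm = BatchNorm(out_dim)
        self.leaky_slope = leaky_slope
        self.dropout_rate = dropout_rate

    def __call__(
        self,
        x: Tensor,
        adjacency: scipy.sparse.spmatrix,
        training: bool,
        rng: np.random.Generator,
    ) -> Tensor:
        combined = x * (self.epsilon + 1.0) + spmm(adjacency, relu(x))
        h = self.lin2(relu(self.lin1(combined)))
        h = self.norm(h, training)
        h = leaky_relu(h, self.leaky_slope)
        return dropout(h, self.dropout_rate, rng, training)

    def parameters(self) -> list[Tensor]:
        return (
            [self.epsilon]
            + self.lin1.parameters()
            + self.lin2.parameters()
            + self.norm.parameters()
        )


class GNNModel:
    """Three GIN layers, Xavier merge, mean pooling, one regression head."""

    def __init__(
        self,
        in_dim: int,
        hidden_dim: int = 64,
        latent_dim: int = 32,
        n_layers: int = 3,
        seed: int = 0,
        dropout_rate: float = 0.5,
    ):
        rng = np.random.default_rng(seed)
        dims = [in_dim] + [hidden_dim] * n_layers
        self.convs = [
            GINLayer(dims[i], dims[i + 1], rng, dropout_rate=dropout_rate)
            for i in range(n_layers)
        ]
        self.merge = Linear(hidden_dim, latent_dim, rng, init="xavier")
        self.head_lin1 = Linear(latent_dim, latent_dim, rng)
        self.head_norm = BatchNorm(latent_dim)
        self.head_lin2 = Linear(latent_dim, 1, rng)
        self.dropout_rate = dropout_rate

    def forward(
        self,
        features: np.ndarray | Tensor,
        adjacency: scipy.sparse.spmatrix,
        pool: scipy.sparse.spmatrix,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> Tensor:
        """Predict one score per graph in the (possibly batched) input.

        ``adjacency`` must already contain self-loops; ``pool`` is the
        graphs x nodes mean-pooling matrix.
        """
        if not isinstance(features, Tensor):
            features = Tensor(features)
        if features.data.size == 0:
            raise ValueError("empty subgraph: no node features")
        if training and rng is None:
            raise ValueError("training-mode forward needs an rng for dropout")
        rng = rng or np.random.default_rng(0)
        h = features
        for conv in self.convs:
            h = conv(h, adjacency, training, rng)
        z = self.merge(h)
        pooled = spmm(pool, z)
        a = self.head_norm(relu(self.head_lin1(pooled)), training)
        a = dropout(a, self.dropout_rate, rng, training)
        return self.head_lin2(a)

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for conv in self.convs:
            params += conv.parameters()
        params += self.merge.parameters()
        params += self.head_lin1.parameters()
        params += self.head_norm.parameters()
        params += self.head_lin2.parameters()
        return params


@dataclasses.dataclass
class GraphExample:
    """A subgraph ready for the model: features, self-looped adjacency, target."""

    features: np.ndarray  # node x gene
    adjacency: scipy.sparse.csr_matrix  # includes self-loops
    target: float | None = None

    @property
    def n_nodes(self) -> int:
        return self.features.shape[0]


def subgraph_example(subgraph, spatial_graph, target: float | None = None
                     ) -> GraphExample:
    """Build a GraphExample from a Subgraph and its parent SpatialGraph.

    Self-loop edges are added to the adjacency here, before any forward
    pass. Node order follows the subgraph's sorted node ids.
    """
    import networkx as nx

    if subgraph.feature_matrix is None:
        raise ValueError("subgraph has no feature matrix")
    nodes = subgraph.node_ids
    sub = spatial_graph.graph.subgraph(nodes)
    adj = nx.to_scipy_sparse_array(sub, nodelist=nodes, format="csr")
    adj = (adj + scipy.sparse.eye(len(nodes), format="csr")).tocsr()
    if target is None:
        target = subgraph.target_score
    return GraphExample(
        features=np.asarray(subgraph.feature_matrix, dtype=float),
        adjacency=adj,
        target=target,
    )


def batch_examples(examples: list[GraphExample]):
    """Stack examples block-diagonally: features, adjacency, pooling, targets."""
    if not examples:
        raise ValueError("empty batch")
    features = np.vstack([ex.features for ex in examples])
    adjacency = scipy.sparse.block_diag(
        [ex.adjacency for ex in examples], format="csr"
    )
    sizes = [ex.n_nodes for ex in examples]
    rows = np.repeat(np.arange(len(examples)), sizes)
    cols = np.arange(sum(sizes))
    vals = np.concatenate([np.full(n, 1.0 / n) for n in sizes])
    pool = scipy.sparse.csr_matrix(
        (vals, (rows, cols)), shape=(len(examples), sum(sizes))
    )
    targets = np.array(
        [np.nan if ex.target is None else ex.target for ex in examples]
    )
    return features, adjacency, pool, targets


@dataclasses.dataclass
class TrainConfig:
    epochs: int = 30
    batch_size: int = 32
    learning_rate: float = 1e-3
    lr_decay: float = 1.0  # per-epoch multiplicative decay of the learning rate
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.epochs < 0:
            raise ValueError("epochs must be non-negative")
        if not 0.0 < self.lr_decay <= 1.0:
            raise ValueError("lr_decay must lie in (0, 1]")


def train(
    model: GNNModel, examples: list[GraphExample], config: TrainConfig
) -> list[float]:
    """Mini-batch MAE training with Adam; returns per-epoch mean loss."""
    if not examples:
        raise ValueError("need at least one training subgraph")
    rng = np.random.default_rng(config.seed)
    optimizer = Adam(model.parameters(), lr=config.learning_rate)
    history: list[float] = []
    for epoch in range(config.epochs):
        optimizer.lr = config.learning_rate * config.lr_decay**epoch
        order = rng.permutation(len(examples))
        losses: list[float] = []
        for start in range(0, len(examples), config.batch_size):
            batch = [examples[i] for i in order[start : start + config.batch_size]]
            features, adjacency, pool, targets = batch_examples(batch)
            optimizer.zero_grad()
            preds = model.forward(features, adjacency, pool, training=True, rng=rng)
            loss = absolute(preds - Tensor(targets[:, None])).mean()
            loss.backward()
            optimizer.step()
            losses.append(float(loss.data))
        history.append(float(np.mean(losses)))
    return history


def predict(
    model: GNNModel, examples: list[GraphExample], batch_size: int = 256
) -> np.ndarray:
    """Deterministic eval-mode predictions, one score per example."""
    preds = []
    for start in range(0, len(examples), batch_size):
        batch = examples[start : start + batch_size]
        features, adjacency, pool, _ = batch_examples(batch)
        out = model.forward(features, adjacency, pool, training=False)
        preds.append(out.data.ravel())
    return np.concatenate(preds)


def score_report(predictions: np.ndarray, truth: np.ndarray,
                 cutoff: float = 0.41) -> dict:
    """R^2 of predictions vs truth, and F1 after binarizing both at the cutoff.

    The positive class is high-neural (score >= cutoff). With constant
    truth, R^2 is undefined and reported as None with a warning.
    """
    from sklearn.metrics import f1_score, r2_score

    predictions = np.asarray(predictions, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if np.allclose(truth, truth[0]):
        warnings.warn("constant truth scores: R^2 is undefined", stacklevel=2)
        r2 = None
    else:
        r2 = float(r2_score(truth, predictions))
    f1 = float(
        f1_score(
            truth >= cutoff, predictions >= cutoff, pos_label=True, zero_division=0
        )
    )
    return {"r2": r2, "f1": f1, "predictions": predictions, "truth": truth}


def evaluate(
    model: GNNModel,
    examples: list[GraphExample],
    cutoff: float = 0.41,
) -> dict:
    """Evaluate a model on scored subgraphs; see :func:`score_report`."""
    truth = np.array([ex.target for ex in examples], dtype=float)
    if np.isnan(truth).any():
        raise ValueError("evaluation requires a truth score on every example")
    preds = predict(model, examples)
    return score_report(preds, truth, cutoff)
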