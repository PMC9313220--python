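"""Protein graph construction and the sampled graph convolutional network.

The network treats graph convolution as an integral of the embedding
function over a probability measure P on the vertex set: layer l maps

    h_tilde^{l+1}(v) = integral of A_hat(v, u) h^l(u) W^l dP(u),
    h^{l+1}(v)       = sigma(h_tilde^{l+1}(v)),

and estimates each layer with t_l i.i.d. vertex samples drawn from P
(Monte-Carlo, importance-weighted so the estimator is unbiased for the
full-batch product A_hat H W under any sampling distribution).  Training
minimises cross-entropy over labelled training nodes plus an L2 weight
penalty, with the sampled estimator in every layer; the hidden-layer
activations of the fitted model are the protein features handed to the
downstream classifier.

Default hyperparameters: learning rate 0.1, one hidden layer of 256
neurons, 200 training iterations, L2 regularisation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.neighbors import NearestNeighbors

ActivationPair = Tuple[Callable[[np.ndarray], np.ndarray], Callable[[np.ndarray], np.ndarray]]

_ACTIVATIONS: dict = {
    "relu": (lambda z: np.maximum(z, 0.0), lambda z: (z > 0.0).astype(float)),
    "identity": (lambda z: z, lambda z: np.ones_like(z)),
    "tanh": (np.tanh, lambda z: 1.0 - np.tanh(z) ** 2),
}


@dataclass
class ProteinGraph:
    """A protein similarity graph: node features, normalised adjacency, vertex measure.

    ``adjacency_hat`` is the symmetric self-looped normalisation
    D^{-1/2} (A + I) D^{-1/2}; ``sampling_dist`` is the probability vector
    P over vertices used by the Monte-Carlo layer estimator.
    """

    features: np.ndarray
    adjacency_hat: np.ndarray
    sampling_dist: np.ndarray
    labels: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.adjacency_hat = np.asarray(self.adjacency_hat, dtype=float)
        self.sampling_dist = np.asarray(self.sampling_dist, dtype=float)
        n = self.features.shape[0]
        if self.adjacency_hat.shape != (n, n):
            raise ValueError(
                f"adjacency is {self.adjacency_hat.shape}, expected ({n}, {n})"
            )
        if not np.allclose(self.adjacency_hat, self.adjacency_hat.T, atol=1e-10):
            raise ValueError("normalised adjacency must be symmetric")
        if np.any(np.diag(self.adjacency_hat) <= 0):
            raise ValueError("every node needs a positive self-loop weight")
        if self.sampling_dist.shape != (n,):
            raise ValueError("sampling distribution length must equal node count")
        if abs(self.sampling_dist.sum() - 1.0) > 1e-9 or np.any(self.sampling_dist <= 0):
            raise ValueError("sampling distribution must be positive and sum to 1")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (n,):
                raise ValueError("labels length must equal node count")

    @property
    def n_nodes(self) -> int:
        return self.features.shape[0]


@dataclass
class TrainConfig:
    """Training configuration for the sampled graph network.

    Defaults: learning rate 0.1, 256 hidden neurons, 200 iterations, L2
    coefficient 5e-4, per-layer sample size min(256, n).  ``optimizer`` is
    ``"adam"`` (default) or ``"gd"`` for plain gradient descent.
    """

    learning_rate: float = 0.1
    hidden_dim: int = 256
    epochs: int = 200
    l2: float = 5e-4
    sample_size: int = 256
    optimizer: str = "adam"
    activation: str = "relu"
    n_classes: int = 2
    seed: int = 0


@dataclass
class GCNModel:
    """Fitted per-layer weights plus the recorded training-loss trajectory."""

    weights: List[np.ndarray]
    activation: str = "relu"
    train_config: Optional[TrainConfig] = None
    loss_trajectory: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if len(self.weights) < 1:
            raise ValueError("model needs at least one layer")
        for a, b in zip(self.weights, self.weights[1:]):
            if a.shape[1] != b.shape[0]:
                raise ValueError(
                    f"consecutive weight shapes do not chain: {a.shape} -> {b.shape}"
                )

    @property
    def n_layers(self) -> int:
        return len(self.weights)


def build_knn_graph(
    features: np.ndarray,
    k: int = 10,
    *,
    sampling: str = "importance",
    labels: Optional[np.ndarray] = None,
) -> ProteinGraph:
    """Cosine-similarity k-nearest-neighbour graph over protein feature rows.

    Each node is linked to its k nearest neighbours (self excluded), the
    edge set is symmetrised by union, self-loops added, and the adjacency
    normalised as A_hat = D^{-1/2}(A + I)D^{-1/2}.  The vertex sampling
    distribution defaults to the variance-reducing importance weights
    q(u) proportional to the squared column norm of A_hat (``sampling="uniform"``
    for the uniform measure).
    """
    X = np.asarray(features, dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least two nodes to build a graph")
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the node count {n}")
    norms = np.linalg.norm(X, axis=1)
    if np.any(norms == 0):
        bad = int(np.flatnonzero(norms == 0)[0])
        raise ValueError(f"node {bad} has a zero-norm feature row; cosine undefined")

    nn = NearestNeighbors(n_neighbors=k + 1, metric="cosine").fit(X)
    _, idx = nn.kneighbors(X)
    A = np.zeros((n, n))
    for i in range(n):
        neigh = [j for j in idx[i] if j != i][:k]
        A[i, neigh] = 1.0
    A = np.maximum(A, A.T)  # symmetrise by union
    np.fill_diagonal(A, 0.0)
    A_loop = A + np.eye(n)
    deg = A_loop.sum(axis=1)
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    A_hat = A_loop * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]

    if sampling == "importance":
        q = np.linalg.norm(A_hat, axis=0) ** 2
        q = q / q.sum()
    elif sampling == "uniform":
        q = np.full(n, 1.0 / n)
    else:
        raise ValueError(f"unknown sampling distribution {sampling!r}")
    return ProteinGraph(features=X, adjacency_hat=A_hat, sampling_dist=q, labels=labels)


def _activation(name: str) -> ActivationPair:
    try:
        return _ACTIVATIONS[name]
    except KeyError:
        raise ValueError(f"unknown activation {name!r}") from None


def gcn_layer_full(
    H: np.ndarray,
    graph: ProteinGraph,
    W: np.ndarray,
    activate: bool = True,
    activation: str = "relu",
) -> np.ndarray:
    """Exact full-batch layer propagation sigma(A_hat H W)."""
    H = np.asarray(H, dtype=float)
    W = np.asarray(W, dtype=float)
    if H.shape[0] != graph.n_nodes or H.shape[1] != W.shape[0]:
        raise ValueError(
            f"shape mismatch: H is {H.shape}, A_hat is {graph.adjacency_hat.shape}, "
            f"W is {W.shape}"
        )
    Z = graph.adjacency_hat @ H @ W
    if activate:
        Z = _activation(activation)[0](Z)
    return Z


def gcn_layer_sampled(
    H: np.ndarray,
    graph: ProteinGraph,
    W: np.ndarray,
    t: int,
    rng: np.random.Generator,
    *,
    activate: bool = True,
    activation: str = "relu",
    exhaustive: bool = False,
) -> np.ndarray:
    """Monte-Carlo layer propagation with t vertex samples from P.

    Draws u_1..u_t i.i.d. from the graph's sampling distribution q and
    estimates the pre-activation at every node v as

        (1/t) * sum_j A_hat(v, u_j) h(u_j) W / q(u_j),

    whose expectation equals the full-batch pre-activation (A_hat H W)_v
    for any positive q; the activation is applied after estimation.  With
    ``exhaustive=True`` (requires t = n) the sample average is replaced by
    the exact expectation, recovering the full-batch layer deterministically.
    """
    H = np.asarray(H, dtype=float)
    W = np.asarray(W, dtype=float)
    n = graph.n_nodes
    if t < 1:
        raise ValueError(f"sample count t={t} must be >= 1")
    if H.shape[0] != n or H.shape[1] != W.shape[0]:
        raise ValueError(f"shape mismatch: H is {H.shape}, W is {W.shape}")
    if exhaustive:
        if t != n:
            raise ValueError("exhaustive mode requires t equal to the node count")
        Z = graph.adjacency_hat @ H @ W
    else:
        q = graph.sampling_dist
        u = rng.choice(n, size=t, replace=True, p=q)
        # scale sampled columns by 1/(t q(u)) for unbiasedness
        A_cols = graph.adjacency_hat[:, u] / (t * q[u])[None, :]
        Z = A_cols @ (H[u] @ W)
    if activate:
        Z = _activation(activation)[0](Z)
    return Z


def _forward_full(model: GCNModel, graph: ProteinGraph) -> List[np.ndarray]:
    """Full-batch forward pass; returns activations per layer (last = logits)."""
    act = _activation(model.activation)[0]
    H = graph.features
    outs = []
    for l, W in enumerate(model.weights):
        Z = graph.adjacency_hat @ H @ W
        H = act(Z) if l < model.n_layers - 1 else Z
        outs.append(H)
    return outs


def _softmax(Z: np.ndarray) -> np.ndarray:
    Z = Z - Z.max(axis=1, keepdims=True)
    E = np.exp(Z)
    return E / E.sum(axis=1, keepdims=True)


def _cross_entropy(logits: np.ndarray, y: np.ndarray) -> float:
    shifted = logits - logits.max(axis=1, keepdims=True)
    logsumexp = np.log(np.exp(shifted).sum(axis=1))
    return float(np.mean(logsumexp - shifted[np.arange(len(y)), y]))


def fastgcn_loss(
    model: GCNModel, graph: ProteinGraph, node_subset: Sequence[int]
) -> float:
    """Mean cross-entropy of the softmax outputs over ``node_subset`` plus the
    L2 weight penalty lambda * sum ||W^l||^2 (full-batch propagation)."""
    subset = np.asarray(node_subset, dtype=int)
    if subset.size == 0:
        raise ValueError("node subset is empty")
    if graph.labels is None:
        raise ValueError("graph has no labels")
    logits = _forward_full(model, graph)[-1]
    ce = _cross_entropy(logits[subset], graph.labels[subset])
    l2 = model.train_config.l2 if model.train_config is not None else 5e-4
    penalty = l2 * sum(float(np.sum(W**2)) for W in model.weights)
    return ce + penalty


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def train_fastgcn(
    graph: ProteinGraph,
    config: TrainConfig = TrainConfig(),
    train_nodes: Optional[Sequence[int]] = None,
) -> GCNModel:
    """Fit the sampled graph network on the training nodes' labels.

    Every epoch performs one gradient step on the cross-entropy +
    L2-penalty objective, with the output batch fixed to the training
    nodes and each lower layer estimated from ``config.sample_size``
    importance-weighted vertex samples.  Test-fold labels are never
    touched: only ``train_nodes`` (default: all nodes) enter the loss.
    Fully reproducible from ``config.seed``; the recorded per-epoch batch
    losses are returned on the model as ``loss_trajectory``.
    """
    if graph.labels is None:
        raise ValueError("graph has no labels to train on")
    if train_nodes is None:
        train_nodes = np.arange(graph.n_nodes)
    batch = np.asarray(train_nodes, dtype=int)
    if batch.size == 0:
        raise ValueError("no labelled training nodes")
    y = graph.labels[batch]
    if y.min() < 0 or y.max() >= config.n_classes:
        raise ValueError("labels outside [0, n_classes)")

    n = graph.n_nodes
    d = graph.features.shape[1]
    dims = [d, config.hidden_dim, config.n_classes]
    rng = np.random.default_rng(config.seed)
    weights = [_glorot(rng, dims[l], dims[l + 1]) for l in range(len(dims) - 1)]
    act, act_grad = _activation(config.activation)
    t = min(config.sample_size, n)
    q = graph.sampling_dist
    A_hat = graph.adjacency_hat
    X0 = graph.features
    Y_onehot = np.eye(config.n_classes)[y]

    # Adam state
    use_adam = config.optimizer == "adam"
    if not use_adam and config.optimizer != "gd":
        raise ValueError(f"unknown optimizer {config.optimizer!r}")
    m_state = [np.zeros_like(W) for W in weights]
    v_state = [np.zeros_like(W) for W in weights]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    l2 = config.l2
    losses = np.empty(config.epochs)

    n_layers = len(weights)
    for epoch in range(config.epochs):
        # layer-wise vertex samples; the output layer uses the full train batch
        samples = [rng.choice(n, size=t, replace=True, p=q) for _ in range(n_layers)]
        # forward: layer l reads its inputs at samples[l] and writes outputs
        # at samples[l+1] (the final layer writes at the train batch), with
        # each adjacency slice importance-scaled by 1/(t q(u)).
        As: List[np.ndarray] = [
            A_hat[
                np.ix_(batch if l == n_layers - 1 else samples[l + 1], samples[l])
            ]
            / (t * q[samples[l]])[None, :]
            for l in range(n_layers)
        ]
        Xs: List[np.ndarray] = []  # input activations per layer
        Zs: List[np.ndarray] = []  # pre-activations
        H_prev = X0[samples[0]]
        for l in range(n_layers):
            Xs.append(H_prev)
            Z = As[l] @ (H_prev @ weights[l])
            Zs.append(Z)
            if l < n_layers - 1:
                H_prev = act(Z)
        logits = Zs[-1]
        P = _softmax(logits)
        ce = _cross_entropy(logits, y)
        penalty = l2 * sum(float(np.sum(W**2)) for W in weights)
        losses[epoch] = ce + penalty

        # backward
        grads: List[Optional[np.ndarray]] = [None] * n_layers
        dZ = (P - Y_onehot) / batch.size
        for l in range(n_layers - 1, -1, -1):
            AX = As[l] @ Xs[l]
            grads[l] = AX.T @ dZ + 2.0 * l2 * weights[l]
            if l > 0:
                dH = (As[l].T @ dZ) @ weights[l].T
                dZ = dH * act_grad(Zs[l - 1])

        # update
        for l in range(n_layers):
            g = grads[l]
            if use_adam:
                m_state[l] = beta1 * m_state[l] + (1 - beta1) * g
                v_state[l] = beta2 * v_state[l] + (1 - beta2) * g**2
                m_hat = m_state[l] / (1 - beta1 ** (epoch + 1))
                v_hat = v_state[l] / (1 - beta2 ** (epoch + 1))
                weights[l] -= config.learning_rate * m_hat / (np.sqrt(v_hat) + eps)
            else:
                weights[l] -= config.learning_rate * g

    return GCNModel(
        weights=weights,
        activation=config.activation,
        train_config=replace(config),
        loss_trajectory=losses,
    )


def extract_embeddings(model: GCNModel, graph: ProteinGraph) -> np.ndarray:
    """Hidden-layer protein features from a deterministic full-batch pass.

    Returns the post-activation output of the last hidden layer (n x 256
    with the default width); these are the features the downstream
    classifier consumes.
    """
    if graph.features.shape[1] != model.weights[0].shape[0]:
        raise ValueError(
            f"graph features have dim {graph.features.shape[1]} but the model "
            f"expects {model.weights[0].shape[0]}"
        )
    if model.n_layers == 1:
        return _forward_full(model, graph)[-1]
    return _forward_full(model, graph)[-2]


def predict_proba(model: GCNModel, graph: ProteinGraph) -> np.ndarray:
    """Softmax class probabilities from a full-batch forward pass."""
    return _softmax(_forward_full(model, graph)[-1])
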