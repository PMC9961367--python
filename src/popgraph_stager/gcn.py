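"""Two-layer graph convolutional network with the renormalized propagation
rule, trained transductively on a population graph.

The propagation operator is S = D̂^{-1/2} (A + I) D̂^{-1/2}, where D̂ is the
degree matrix of A + I; the self-loop keeps every node's own features in the
message and bounds the spectral radius by 1.  The forward pass is

    H1 = ReLU(S X W0 + b0),        P = softmax(S H1 W1 + b1)

with dropout on both layer inputs during training.  The whole graph —
including unlabelled test nodes — participates in every forward pass;
cross-entropy is accumulated over training nodes only (transductive,
semi-supervised).  Training uses Adam, early stopping on validation accuracy
and restores the best-validation weights.  Gradients are computed in closed
form (the model is two layers), so there is no framework dependency.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import PopulationGraph


@dataclass
class GCNConfig:
    hidden_units: int = 32
    dropout: float = 0.5
    learning_rate: float = 1e-3
    max_epochs: int = 500
    patience: int = 20
    n_classes: int = 2
    standardize_features: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.n_classes not in (2, 3):
            raise ValueError("n_classes must be 2 or 3")


@dataclass
class PropagationOperator:
    """S = D̂^{-1/2} Â D̂^{-1/2}; symmetric, spectral radius ≤ 1."""

    S: np.ndarray


@dataclass
class GCNModel:
    W0: np.ndarray
    b0: np.ndarray
    W1: np.ndarray
    b1: np.ndarray
    config: GCNConfig

    def save(self, path: str | Path) -> None:
        np.savez(path, W0=self.W0, b0=self.b0, W1=self.W1, b1=self.b1,
                 config=json.dumps(asdict(self.config)))

    @classmethod
    def load(cls, path: str | Path) -> "GCNModel":
        with np.load(path, allow_pickle=False) as z:
            config = GCNConfig(**json.loads(str(z["config"])))
            return cls(W0=z["W0"], b0=z["b0"], W1=z["W1"], b1=z["b1"],
                       config=config)


def normalize_adjacency(A: np.ndarray) -> PropagationOperator:
    """Renormalized symmetric propagation operator from a raw adjacency."""
    A = np.asarray(A, float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(A, A.T):
        raise ValueError("adjacency must be symmetric")
    if np.any(A < 0):
        raise ValueError("adjacency must be nonnegative")
    A_hat = A + np.eye(A.shape[0])
    d = A_hat.sum(axis=1)  # > 0 thanks to the self-loop
    inv_sqrt = 1.0 / np.sqrt(d)
    S = A_hat * inv_sqrt[:, None] * inv_sqrt[None, :]
    return PropagationOperator(S=S)


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def init_model(n_features: int, config: GCNConfig,
               rng: np.random.Generator | None = None) -> GCNModel:
    rng = rng or np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    return GCNModel(
        W0=_glorot(rng, n_features, config.hidden_units),
        b0=np.zeros(config.hidden_units),
        W1=_glorot(rng, config.hidden_units, config.n_classes),
        b1=np.zeros(config.n_classes),
        config=config,
    )


def _softmax(Z: np.ndarray) -> np.ndarray:
    Z = Z - Z.max(axis=1, keepdims=True)
    E = np.exp(Z)
    return E / E.sum(axis=1, keepdims=True)


def forward(
    model: GCNModel,
    operator: PropagationOperator | np.ndarray,
    X: np.ndarray,
    training: bool = False,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Per-node class probabilities; each row sums to 1."""
    probs, _ = _forward_cached(model, operator, X, training, rng)
    return probs


def _forward_cached(model, operator, X, training, rng):
    S = operator.S if isinstance(operator, PropagationOperator) else operator
    X = np.asarray(X, float)
    p = model.config.dropout
    if training and p > 0:
        if rng is None:
            raise ValueError("training-mode forward needs an rng for dropout")
        mask_x = (rng.random(X.shape) >= p) / (1.0 - p)
        Xd = X * mask_x
    else:
        mask_x = None
        Xd = X
    SX = S @ Xd
    Z1 = SX @ model.W0 + model.b0
    H1 = np.maximum(Z1, 0.0)
    if training and p > 0:
        mask_h = (rng.random(H1.shape) >= p) / (1.0 - p)
        H1d = H1 * mask_h
    else:
        mask_h = None
        H1d = H1
    SH = S @ H1d
    Z2 = SH @ model.W1 + model.b1
    if not np.all(np.isfinite(Z2)):
        raise FloatingPointError("non-finite activations in GCN forward pass")
    probs = _softmax(Z2)
    cache = dict(S=S, SX=SX, Z1=Z1, SH=SH, mask_h=mask_h)
    return probs, cache


def node_features(graph: PopulationGraph, config: GCNConfig) -> np.ndarray:
    """Node feature matrix as seen by the GCN.

    When ``standardize_features`` is set (default), columns are z-scored
    over *all* nodes — a transductive, label-free transform analogous to the
    feature normalization of the reference GCN implementations.  Raw
    post-ReLU embeddings share a large all-positive common component that
    otherwise dwarfs the class-discriminative directions after graph
    smoothing.
    """
    if not config.standardize_features:
        return graph.X
    sd = graph.X.std(axis=0)
    return (graph.X - graph.X.mean(axis=0)) / np.where(sd == 0, 1.0, sd)


def predict(model: GCNModel, graph: PopulationGraph) -> tuple[np.ndarray, np.ndarray]:
    """Hard labels (argmax; ties -> lower class index) and probabilities."""
    op = normalize_adjacency(graph.A)
    probs = forward(model, op, node_features(graph, model.config),
                    training=False)
    return probs.argmax(axis=1), probs


class _Adam:
    def __init__(self, shapes, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        out = []
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            out.append(p - self.lr * mhat / (np.sqrt(vhat) + self.eps))
        return out


def train_transductive(
    graph: PopulationGraph,
    labels: np.ndarray,
    config: GCNConfig,
) -> tuple[GCNModel, pd.DataFrame]:
    """Full-batch transductive training on the population graph.

    ``labels`` is an int vector aligned with ``graph.ids``; only entries
    under the train mask enter the loss, validation accuracy drives early
    stopping, and test nodes are never touched.  Deterministic given
    ``config.seed``.
    """
    masks = graph.masks
    train_mask = masks["train"]
    val_mask = masks["val"]
    if not train_mask.any():
        raise ValueError("empty training mask")
    labels = np.asarray(labels, int)
    present = set(labels[train_mask].tolist())
    missing = [c for c in range(config.n_classes) if c not in present]
    if missing:
        raise ValueError(f"classes absent from training mask: {missing}")

    ss = np.random.SeedSequence([int(config.seed), 11])
    rng_init, rng_drop = (np.random.default_rng(c) for c in ss.spawn(2))
    model = init_model(graph.X.shape[1], config, rng_init)
    op = normalize_adjacency(graph.A)
    X = node_features(graph, config)
    n_train = int(train_mask.sum())
    Y = np.zeros((len(labels), config.n_classes))
    Y[np.arange(len(labels)), labels] = 1.0

    params = [model.W0, model.b0, model.W1, model.b1]
    opt = _Adam([p.shape for p in params], lr=config.learning_rate)
    best = dict(val_acc=-np.inf, epoch=-1,
                params=[p.copy() for p in params])
    epochs_since_best = 0
    history = []

    for epoch in range(config.max_epochs):
        probs, cache = _forward_cached(model, op, X, training=True, rng=rng_drop)
        # cross-entropy over training nodes only
        eps = 1e-12
        train_loss = -float(np.mean(
            np.log(probs[train_mask, labels[train_mask]] + eps)))
        dZ2 = (probs - Y) * train_mask[:, None] / n_train
        gW1 = cache["SH"].T @ dZ2
        gb1 = dZ2.sum(axis=0)
        dH1d = cache["S"] @ (dZ2 @ model.W1.T)  # S is symmetric
        if cache["mask_h"] is not None:
            dH1d = dH1d * cache["mask_h"]
        dZ1 = dH1d * (cache["Z1"] > 0)
        gW0 = cache["SX"].T @ dZ1
        gb0 = dZ1.sum(axis=0)
        params = opt.step(params, [gW0, gb0, gW1, gb1])
        model.W0, model.b0, model.W1, model.b1 = params

        eval_probs = forward(model, op, X, training=False)
        pred = eval_probs.argmax(axis=1)
        val_acc = float(np.mean(pred[val_mask] == labels[val_mask])) \
            if val_mask.any() else float("nan")
        train_acc = float(np.mean(pred[train_mask] == labels[train_mask]))
        history.append(dict(epoch=epoch, train_loss=train_loss,
                            train_acc=train_acc, val_acc=val_acc))

        if val_mask.any() and val_acc > best["val_acc"]:
            best = dict(val_acc=val_acc, epoch=epoch,
                        params=[p.copy() for p in params])
            epochs_since_best = 0
        else:
            epochs_since_best += 1
            if val_mask.any() and epochs_since_best >= max(1, config.patience):
                break

    if val_mask.any():
        model.W0, model.b0, model.W1, model.b1 = best["params"]
    return model, pd.DataFrame(history)
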