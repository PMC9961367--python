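"""3-D DenseNet feature extractor for gray-matter density volumes.

The network is a small densely connected 3-D CNN: an initial 3x3x3
convolution, then ``n_blocks`` dense blocks separated by transition layers.
Each dense-block unit is pre-activation (BN -> ReLU -> 1x1x1 bottleneck
conv -> BN -> ReLU -> 3x3x3 conv producing ``growth_rate`` channels) and
concatenates its output onto the running channel stack, so a block adds
``units_per_block * growth_rate`` channels.  A transition layer compresses
channels by ``compression`` (floor) with a 1x1x1 convolution and halves each
spatial dimension with 2x2x2 average pooling.  The last block's output is
flattened into two fully connected layers (default 512 then 256 units); the
post-ReLU activations of the first FC layer are the anatomical embedding
used as population-graph node features.

Training minimises class-weighted cross-entropy (weights inversely
proportional to training-class frequency) with Adam, early-stopping on
validation loss and restoring the best-validation weights.  Harder tasks can
be warm-started from a previously trained model (transfer initialization).

Everything is sized by configuration so tests train on 8^3 phantoms in
seconds while the default configuration reproduces the full architecture
(64^3 input, three blocks, growth 12, bottleneck 48, compression 0.5,
512/256 FC head).
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import FeatureMatrix, VolumeSet
from .nn import autograd as ag


@dataclass
class DenseNetConfig:
    input_shape: tuple[int, int, int] = (64, 64, 64)
    n_blocks: int = 3
    units_per_block: int = 3
    growth_rate: int = 12
    bottleneck_channels: int = 48
    compression: float = 0.5
    init_channels: int = 24
    initial_batchnorm: bool = False
    initial_pool: bool = False
    fc_sizes: tuple[int, int] = (512, 256)
    learning_rate: float = 1e-4
    batch_size: int = 64
    max_epochs: int = 200
    patience: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.compression <= 1:
            raise ValueError("compression must be in (0, 1]")
        if self.growth_rate < 1:
            raise ValueError("growth_rate must be >= 1")
        if len(self.fc_sizes) != 2:
            raise ValueError("fc_sizes must be a pair")

    @property
    def embedding_dim(self) -> int:
        return self.fc_sizes[0]


@dataclass
class ModelSpec:
    """Layer-by-layer shape table of the architecture (no weights)."""

    config: DenseNetConfig
    n_classes: int
    layers: list[dict] = field(default_factory=list)

    @property
    def n_params(self) -> int:
        return sum(l["n_params"] for l in self.layers)

    @property
    def embedding_dim(self) -> int:
        return self.config.embedding_dim

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.layers)


def build_extractor(config: DenseNetConfig, n_classes: int = 2) -> ModelSpec:
    """Resolve the architecture into an explicit shape table.

    Raises if the pooling schedule does not divide the input shape (each
    transition halves every spatial dimension).
    """
    layers: list[dict] = []
    spatial = tuple(config.input_shape)
    c = config.init_channels

    def put(name, channels, spatial, n_params):
        layers.append(dict(name=name, channels=channels,
                           spatial=tuple(spatial), n_params=int(n_params)))

    put("init_conv3", c, spatial, 27 * 1 * c + c)
    if config.initial_batchnorm:
        put("init_bn", c, spatial, 2 * c)
    if config.initial_pool:
        spatial = _halve(spatial, "initial pool")
        put("init_pool", c, spatial, 0)
    for b in range(config.n_blocks):
        for u in range(config.units_per_block):
            bc = config.bottleneck_channels
            g = config.growth_rate
            n = 2 * c + (c * bc + bc) + 2 * bc + (27 * bc * g + g)
            c = c + g
            put(f"block{b}.unit{u}", c, spatial, n)
        if b < config.n_blocks - 1:
            out_c = int(np.floor(c * config.compression))
            n = 2 * c + (c * out_c + out_c)
            spatial = _halve(spatial, f"transition {b}")
            put(f"transition{b}", out_c, spatial, n)
            c = out_c
    put("final_bn", c, spatial, 2 * c)
    flat = c * int(np.prod(spatial))
    put("flatten", flat, (1, 1, 1), 0)
    f1, f2 = config.fc_sizes
    put("fc1", f1, (1, 1, 1), flat * f1 + f1)
    put("fc2", f2, (1, 1, 1), f1 * f2 + f2)
    put("logits", n_classes, (1, 1, 1), f2 * n_classes + n_classes)
    return ModelSpec(config=config, n_classes=n_classes, layers=layers)


def _halve(spatial, where):
    if any(s % 2 or s < 2 for s in spatial):
        raise ValueError(
            f"input shape too small for the pooling schedule at {where}: "
            f"{spatial}")
    return tuple(s // 2 for s in spatial)


class DenseNet3D:
    """Instantiated network: parameters, batch-norm state, forward pass."""

    def __init__(self, config: DenseNetConfig, n_classes: int = 2,
                 rng: np.random.Generator | None = None):
        self.config = config
        self.n_classes = n_classes
        self.spec = build_extractor(config, n_classes)  # validates shapes
        rng = rng or np.random.default_rng(
            np.random.SeedSequence([config.seed, 21]))
        self.params: dict[str, ag.Tensor] = {}
        self.bns: dict[str, ag.BatchNorm] = {}

        def conv_param(name, c_in, c_out, k):
            fan_in = c_in * k ** 3
            w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                           size=(c_out, c_in, k, k, k))
            self.params[name + ".w"] = ag.parameter(w)
            self.params[name + ".b"] = ag.parameter(np.zeros(c_out))

        def fc_param(name, n_in, n_out):
            limit = np.sqrt(6.0 / (n_in + n_out))
            self.params[name + ".w"] = ag.parameter(
                rng.uniform(-limit, limit, size=(n_in, n_out)))
            self.params[name + ".b"] = ag.parameter(np.zeros(n_out))

        c = config.init_channels
        conv_param("init", 1, c, 3)
        if config.initial_batchnorm:
            self.bns["init"] = ag.BatchNorm(c)
        for b in range(config.n_blocks):
            for u in range(config.units_per_block):
                pre = f"block{b}.unit{u}"
                self.bns[pre + ".bn1"] = ag.BatchNorm(c)
                conv_param(pre + ".conv1", c, config.bottleneck_channels, 1)
                self.bns[pre + ".bn2"] = ag.BatchNorm(config.bottleneck_channels)
                conv_param(pre + ".conv3", config.bottleneck_channels,
                           config.growth_rate, 3)
                c += config.growth_rate
            if b < config.n_blocks - 1:
                out_c = int(np.floor(c * config.compression))
                self.bns[f"transition{b}.bn"] = ag.BatchNorm(c)
                conv_param(f"transition{b}.conv", c, out_c, 1)
                c = out_c
        self.bns["final"] = ag.BatchNorm(c)
        flat = next(l for l in self.spec.layers if l["name"] == "flatten")
        fc_param("fc1", flat["channels"], config.fc_sizes[0])
        fc_param("fc2", config.fc_sizes[0], config.fc_sizes[1])
        fc_param("logits", config.fc_sizes[1], n_classes)

    # -- parameter plumbing -------------------------------------------------
    def parameters(self) -> list[ag.Tensor]:
        out = list(self.params.values())
        for bn in self.bns.values():
            out.extend(bn.parameters())
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {k: t.data.copy() for k, t in self.params.items()}
        for name, bn in self.bns.items():
            state[f"bn::{name}.gamma"] = bn.gamma.data.copy()
            state[f"bn::{name}.beta"] = bn.beta.data.copy()
            state[f"bn::{name}.running_mean"] = bn.running_mean.copy()
            state[f"bn::{name}.running_var"] = bn.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, t in self.params.items():
            t.data = np.array(state[k])
        for name, bn in self.bns.items():
            bn.gamma.data = np.array(state[f"bn::{name}.gamma"])
            bn.beta.data = np.array(state[f"bn::{name}.beta"])
            bn.running_mean = np.array(state[f"bn::{name}.running_mean"])
            bn.running_var = np.array(state[f"bn::{name}.running_var"])

    # -- forward ------------------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False
                ) -> tuple[ag.Tensor, ag.Tensor]:
        """Return (logits, post-ReLU first-FC embedding) for a batch.

        ``x`` is (N, D, H, W) or (N, 1, D, H, W).
        """
        x = np.asarray(x, np.float64)
        if x.ndim == 4:
            x = x[:, None]
        cfg = self.config
        h = ag.conv3d(ag.Tensor(x), self.params["init.w"],
                      self.params["init.b"], padding=1)
        if cfg.initial_batchnorm:
            h = self.bns["init"](h, training)
        if cfg.initial_pool:
            h = ag.avgpool3d(h)
        for b in range(cfg.n_blocks):
            for u in range(cfg.units_per_block):
                pre = f"block{b}.unit{u}"
                t = ag.relu(self.bns[pre + ".bn1"](h, training))
                t = ag.conv3d(t, self.params[pre + ".conv1.w"],
                              self.params[pre + ".conv1.b"], padding=0)
                t = ag.relu(self.bns[pre + ".bn2"](t, training))
                t = ag.conv3d(t, self.params[pre + ".conv3.w"],
                              self.params[pre + ".conv3.b"], padding=1)
                h = ag.concat_channels([h, t])
            if b < cfg.n_blocks - 1:
                t = ag.relu(self.bns[f"transition{b}.bn"](h, training))
                t = ag.conv3d(t, self.params[f"transition{b}.conv.w"],
                              self.params[f"transition{b}.conv.b"], padding=0)
                h = ag.avgpool3d(t)
        h = ag.relu(self.bns["final"](h, training))
        n = h.data.shape[0]
        h = ag.reshape(h, (n, -1))
        z1 = ag.add_bias(ag.matmul(h, self.params["fc1.w"]),
                         self.params["fc1.b"])
        feat = ag.relu(z1)
        z2 = ag.relu(ag.add_bias(ag.matmul(feat, self.params["fc2.w"]),
                                 self.params["fc2.b"]))
        logits = ag.add_bias(ag.matmul(z2, self.params["logits.w"]),
                             self.params["logits.b"])
        return logits, feat

    def save(self, path: str | Path) -> None:
        state = self.state_dict()
        state["__config__"] = np.frombuffer(
            json.dumps({"config": asdict(self.config),
                        "n_classes": self.n_classes}).encode(), dtype=np.uint8)
        np.savez(path, **{k.replace("::", "--"): v for k, v in state.items()})

    @classmethod
    def load(cls, path: str | Path) -> "DenseNet3D":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(bytes(z["__config__"]).decode())
            cfg = meta["config"]
            cfg["input_shape"] = tuple(cfg["input_shape"])
            cfg["fc_sizes"] = tuple(cfg["fc_sizes"])
            model = cls(DenseNetConfig(**cfg), n_classes=meta["n_classes"])
            state = {k.replace("--", "::"): z[k] for k in z.files
                     if k != "__config__"}
            model.load_state_dict(state)
        return model


def class_weights(train_labels: np.ndarray, n_classes: int) -> np.ndarray:
    """Weights inversely proportional to training-class frequency (mean 1)."""
    counts = np.bincount(np.asarray(train_labels, int), minlength=n_classes)
    if np.any(counts == 0):
        missing = [int(c) for c in np.flatnonzero(counts == 0)]
        raise ValueError(f"classes absent from the training split: {missing}")
    w = len(train_labels) / (n_classes * counts.astype(float))
    return w


def train_extractor(
    volumes: VolumeSet,
    labels: np.ndarray,
    split: dict[str, str],
    config: DenseNetConfig,
    init: DenseNet3D | dict[str, np.ndarray] | None = None,
) -> tuple[DenseNet3D, pd.DataFrame]:
    """Train the CNN on the train split; early-stop on validation loss.

    ``labels`` is an int vector aligned with ``volumes.ids``; ``init`` warm
    starts from previously trained weights (transfer protocol for the harder
    tasks).  Returns the best-validation model and the epoch history
    (train_loss, val_loss, val_acc).
    """
    labels = np.asarray(labels, int)
    n_classes = int(labels.max()) + 1
    ss = np.random.SeedSequence([config.seed, 22])
    rng_init, rng_batch = (np.random.default_rng(c) for c in ss.spawn(2))
    model = DenseNet3D(config, n_classes=n_classes, rng=rng_init)
    if init is not None:
        model.load_state_dict(init.state_dict()
                              if isinstance(init, DenseNet3D) else init)
    split_arr = np.array([split[sid] for sid in volumes.ids])
    train_idx = np.flatnonzero(split_arr == "train")
    val_idx = np.flatnonzero(split_arr == "val")
    weights = class_weights(labels[train_idx], n_classes)

    params = model.parameters()
    opt = _Adam([p.data.shape for p in params], lr=config.learning_rate)
    best = dict(val_loss=np.inf, state=model.state_dict(), epoch=-1)
    since_best = 0
    history = []

    def eval_split(idx):
        losses, correct = [], 0
        for start in range(0, len(idx), config.batch_size):
            batch = idx[start:start + config.batch_size]
            logits, _ = model.forward(volumes.data[batch], training=False)
            loss = ag.weighted_cross_entropy(logits, labels[batch], weights)
            losses.append(loss.data * len(batch))
            correct += int((logits.data.argmax(1) == labels[batch]).sum())
        return float(np.sum(losses) / len(idx)), correct / len(idx)

    for epoch in range(config.max_epochs):
        order = rng_batch.permutation(train_idx)
        epoch_loss = 0.0
        for start in range(0, len(order), config.batch_size):
            batch = order[start:start + config.batch_size]
            logits, _ = model.forward(volumes.data[batch], training=True)
            loss = ag.weighted_cross_entropy(logits, labels[batch], weights)
            loss.backward()
            grads = [p.grad for p in params]
            new = opt.step([p.data for p in params], grads)
            for p, d in zip(params, new):
                p.data = d
            epoch_loss += loss.data * len(batch)
        epoch_loss /= len(order)
        if len(val_idx):
            val_loss, val_acc = eval_split(val_idx)
        else:
            val_loss, val_acc = float("nan"), float("nan")
        history.append(dict(epoch=epoch, train_loss=epoch_loss,
                            val_loss=val_loss, val_acc=val_acc))
        if len(val_idx) and val_loss < best["val_loss"]:
            best = dict(val_loss=val_loss, state=model.state_dict(),
                        epoch=epoch)
            since_best = 0
        elif len(val_idx):
            since_best += 1
            if since_best >= max(1, config.patience):
                break
    if len(val_idx):
        model.load_state_dict(best["state"])
    return model, pd.DataFrame(history)


def extract_features(model: DenseNet3D, volumes: VolumeSet,
                     batch_size: int = 32) -> FeatureMatrix:
    """Post-ReLU first-FC-layer activations per subject (inference mode)."""
    rows = []
    for start in range(0, len(volumes.ids), batch_size):
        _, feat = model.forward(volumes.data[start:start + batch_size],
                                training=False)
        rows.append(feat.data)
    return FeatureMatrix(ids=list(volumes.ids), values=np.vstack(rows))


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
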