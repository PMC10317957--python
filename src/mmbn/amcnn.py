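"""Multi-branch attention-mechanism CNN (AM-CNN) for MMBN classification.

The model mirrors the multilayer network structure: one branch per
frequency-band layer, each receiving that layer's N x N adjacency matrix as
a single-channel image. Per branch (K = 16 kernels throughout):

* L1, L2: two 3x3 same-padding convolutions with ReLU (N x N x K maps);
* L3-L6, the squeeze-and-excitation attention path: global average pooling
  to a K-vector, a bottleneck dense pair (K/r units with ReLU, then K units
  with sigmoid, reduction ratio r = 2), and channel-wise multiplication of
  the resulting gates with the L2 maps, followed by ReLU;
* L7: batch normalization.

The fusion block concatenates the L1, L2 and L7 maps of all branches along
the channel axis (depth 3*K per branch, 384 for eight branches), applies a
3x3 convolution with 32 kernels and a 1x1 convolution with 10 kernels (both
ReLU), flattens (5290 features at N = 23) and classifies with a 2-way
softmax dense layer.

Branches share the structure but not the parameters. The attention path can
be removed (``attention=False``) for the ablation comparison model; only
L3-L6 disappear — batch normalization then acts on the L2 maps directly.

Training follows the usual fully-supervised protocol: Adam on softmax
cross-entropy, a stratified validation split, and restoration of the
parameter snapshot with minimum validation loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import nn
from .network import MultilayerNetwork

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "AMCNN",
    "build_model",
    "attention_gates",
    "train",
    "predict",
    "networks_to_array",
]


@dataclass
class ModelConfig:
    """Architecture hyperparameters (defaults reproduce the reference model)."""

    n_channels: int = 23
    n_branches: int = 8
    conv_kernels: int = 16
    kernel_size: int = 3
    reduction_ratio: int = 2
    fusion_kernels: tuple = (32, 10)
    n_classes: int = 2
    attention: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.conv_kernels % self.reduction_ratio:
            raise ValueError("conv_kernels must be divisible by reduction_ratio")
        if self.kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd")
        if min(self.n_channels, self.n_branches, self.n_classes) < 1:
            raise ValueError("sizes must be positive")


@dataclass
class TrainConfig:
    """Optimization protocol.

    Reference protocol: Adam, cross-entropy, 200 epochs, batch 64, learning
    rate 0.001, 10% validation split. The desk-scale default is 30 epochs
    with early-stopping patience 10; the best-validation-loss snapshot is
    restored either way. ``patience=None`` disables early stopping.
    """

    epochs: int = 30
    batch_size: int = 64
    learning_rate: float = 1e-3
    validation_fraction: float = 0.1
    patience: int | None = 10
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 0 or self.batch_size < 1 or self.learning_rate <= 0:
            raise ValueError("invalid training configuration")
        if not 0 < self.validation_fraction < 1:
            raise ValueError("validation_fraction must be in (0, 1)")


class _Branch:
    """One attention feature-extraction branch (layers L1-L7)."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        K, ks = cfg.conv_kernels, cfg.kernel_size
        self.attention = cfg.attention
        self.conv1 = nn.Conv2D(1, K, ks, rng)
        self.relu1 = nn.ReLU()
        self.conv2 = nn.Conv2D(K, K, ks, rng)
        self.relu2 = nn.ReLU()
        if self.attention:
            self.gap = nn.GlobalAvgPool()
            self.fc1 = nn.Dense(K, K // cfg.reduction_ratio, rng)
            self.relu3 = nn.ReLU()
            self.fc2 = nn.Dense(K // cfg.reduction_ratio, K, rng)
            self.sigmoid = nn.Sigmoid()
            self.gate = nn.ChannelGate()
            self.relu4 = nn.ReLU()
        self.bn = nn.BatchNorm(K)

    @property
    def layers(self):
        out = [self.conv1, self.relu1, self.conv2, self.relu2]
        if self.attention:
            out += [self.gap, self.fc1, self.relu3, self.fc2, self.sigmoid, self.gate, self.relu4]
        return out + [self.bn]

    @property
    def params(self):
        return [p for layer in self.layers for p in layer.params]

    def forward(self, x: np.ndarray, train: bool):
        """Returns (s1, s2, s7): the L1, L2 and L7 maps fed to the fusion block."""
        s1 = self.relu1.forward(self.conv1.forward(x))
        s2 = self.relu2.forward(self.conv2.forward(s1))
        if self.attention:
            gates = self.sigmoid.forward(self.fc2.forward(self.relu3.forward(self.fc1.forward(self.gap.forward(s2)))))
            s6 = self.relu4.forward(self.gate.forward(s2, gates))
        else:
            s6 = s2
        s7 = self.bn.forward(s6, train=train)
        return s1, s2, s7

    def backward(self, g1: np.ndarray, g2: np.ndarray, g7: np.ndarray) -> np.ndarray:
        g6 = self.bn.backward(g7)
        if self.attention:
            gmaps, ggates = self.gate.backward(self.relu4.backward(g6))
            g2 = g2 + gmaps
            ggap = self.fc1.backward(self.relu3.backward(self.fc2.backward(self.sigmoid.backward(ggates))))
            g2 = g2 + self.gap.backward(ggap)
        else:
            g2 = g2 + g6
        g1 = g1 + self.conv2.backward(self.relu2.backward(g2))
        return self.conv1.backward(self.relu1.backward(g1))


class AMCNN:
    """The full multi-branch model. Input shape (batch, N, N, n_branches)."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.branches = [_Branch(config, rng) for _ in range(config.n_branches)]
        K = config.conv_kernels
        depth = 3 * K * config.n_branches
        f1, f2 = config.fusion_kernels
        self.fuse_conv1 = nn.Conv2D(depth, f1, config.kernel_size, rng)
        self.fuse_relu1 = nn.ReLU()
        self.fuse_conv2 = nn.Conv2D(f1, f2, 1, rng)
        self.fuse_relu2 = nn.ReLU()
        self.classifier = nn.Dense(config.n_channels**2 * f2, config.n_classes, rng)
        self.loss = nn.SoftmaxCrossEntropy()
        self._fitted = False

        # Architecture contract, asserted at build time
        self.concat_depth = depth
        self.flatten_length = config.n_channels**2 * f2
        shapes = self.layer_output_shapes()
        N = config.n_channels
        assert shapes["L8"] == (N, N, depth)
        assert shapes["L11"] == (self.flatten_length,)

    def layer_output_shapes(self) -> dict:
        """Per-layer output sizes (without the batch axis)."""
        cfg = self.config
        N, K = cfg.n_channels, cfg.conv_kernels
        f1, f2 = cfg.fusion_kernels
        shapes = {
            "L1": (N, N, K),
            "L2": (N, N, K),
            "L6": (N, N, K),
            "L7": (N, N, K),
            "L8": (N, N, 3 * K * cfg.n_branches),
            "L9": (N, N, f1),
            "L10": (N, N, f2),
            "L11": (N * N * f2,),
            "L12": (cfg.n_classes,),
        }
        if cfg.attention:
            shapes["L3"] = (K,)
            shapes["L4"] = (K // cfg.reduction_ratio,)
            shapes["L5"] = (K,)
        return shapes

    @property
    def params(self):
        out = [p for br in self.branches for p in br.params]
        for layer in (self.fuse_conv1, self.fuse_conv2, self.classifier):
            out.extend(layer.params)
        return out

    def get_weights(self) -> list:
        return [p.value.copy() for p in self.params]

    def set_weights(self, weights: list):
        for p, w in zip(self.params, weights):
            p.value[...] = w

    def _check_input(self, x: np.ndarray):
        cfg = self.config
        if x.ndim != 4 or x.shape[1:] != (cfg.n_channels, cfg.n_channels, cfg.n_branches):
            raise ValueError(
                f"expected input (batch, {cfg.n_channels}, {cfg.n_channels}, {cfg.n_branches}), got {x.shape}"
            )

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Logits for a batch of stacked-layer inputs."""
        x = np.asarray(x, dtype=nn.DTYPE)
        self._check_input(x)
        feats = []
        for b, br in enumerate(self.branches):
            feats.extend(br.forward(x[..., b : b + 1], train=train))
        cat = np.concatenate(feats, axis=-1)
        h = self.fuse_relu1.forward(self.fuse_conv1.forward(cat))
        h = self.fuse_relu2.forward(self.fuse_conv2.forward(h))
        flat = h.reshape(h.shape[0], -1)
        return self.classifier.forward(flat)

    def backward(self, glogits: np.ndarray):
        cfg = self.config
        N, f2 = cfg.n_channels, cfg.fusion_kernels[1]
        g = self.classifier.backward(glogits).reshape(-1, N, N, f2)
        g = self.fuse_conv2.backward(self.fuse_relu2.backward(g))
        gcat = self.fuse_conv1.backward(self.fuse_relu1.backward(g))
        K = cfg.conv_kernels
        for b, br in enumerate(self.branches):
            off = 3 * K * b
            br.backward(
                gcat[..., off : off + K],
                gcat[..., off + K : off + 2 * K],
                gcat[..., off + 2 * K : off + 3 * K],
            )

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Class probabilities (softmax of the logits), inference mode."""
        return nn.SoftmaxCrossEntropy.probs(self.forward(x, train=False))


def build_model(config: ModelConfig | None = None, **kwargs) -> AMCNN:
    """Construct an AM-CNN; keyword arguments override config fields."""
    cfg = config or ModelConfig()
    if kwargs:
        cfg = replace(cfg, **kwargs)
    return AMCNN(cfg)


def attention_gates(feature_maps: np.ndarray, W1: np.ndarray, W2: np.ndarray, b1=0.0, b2=0.0) -> np.ndarray:
    """Squeeze-and-excitation gates of one map stack (H, W, K) -> (K,) in (0, 1).

    gates = sigmoid(W2 @ relu(W1 @ gap(maps) + b1) + b2); the bottleneck
    matrices have shapes (K/r, K) and (K, K/r).
    """
    s3 = np.asarray(feature_maps, dtype=float).mean(axis=(0, 1))
    hidden = np.maximum(W1 @ s3 + b1, 0.0)
    return 1.0 / (1.0 + np.exp(-(W2 @ hidden + b2)))


def networks_to_array(networks: list) -> tuple[np.ndarray, np.ndarray]:
    """Stack MMBNs into model input (n, N, N, n_layers) plus a label vector."""
    X = np.stack([net.as_array().transpose(1, 2, 0) for net in networks]).astype(nn.DTYPE)
    y = np.array([net.label if net.label is not None else -1 for net in networks], dtype=int)
    return X, y


def _as_xy(dataset) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(dataset, tuple):
        X, y = dataset
        return np.asarray(X, dtype=nn.DTYPE), np.asarray(y, dtype=int)
    if dataset and isinstance(dataset[0], MultilayerNetwork):
        return networks_to_array(dataset)
    nets, labels = zip(*dataset)
    X, _ = networks_to_array(list(nets))
    return X, np.asarray(labels, dtype=int)


def train(model: AMCNN, dataset, config: TrainConfig | None = None) -> list:
    """Fit the model; returns the per-epoch history.

    The dataset is ``(X, y)`` arrays, a list of labelled
    :class:`MultilayerNetwork`, or a list of ``(network, label)`` pairs. A
    stratified ``validation_fraction`` of it is held out; after the epoch
    loop the parameters with minimum validation loss are restored. History
    rows carry epoch, loss, val_loss and val_accuracy.
    """
    from sklearn.model_selection import train_test_split

    cfg = config or TrainConfig()
    X, y = _as_xy(dataset)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    if cfg.epochs == 0:
        return []
    # at least one validation sample per class, even on tiny datasets
    n_val = max(2, int(round(cfg.validation_fraction * len(y))))
    Xtr, Xval, ytr, yval = train_test_split(
        X, y, test_size=n_val, stratify=y, random_state=cfg.seed % 2**31
    )
    rng = np.random.default_rng(cfg.seed)
    opt = nn.Adam(model.params, lr=cfg.learning_rate)
    history = []
    best_loss, best_weights, since_best = np.inf, None, 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(Xtr))
        epoch_loss, nb = 0.0, 0
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            logits = model.forward(Xtr[idx], train=True)
            epoch_loss += model.loss.forward(logits, ytr[idx])
            nb += 1
            opt.zero_grad()
            model.backward(model.loss.backward())
            opt.step()
        val_logits = model.forward(Xval, train=False)
        val_loss = nn.SoftmaxCrossEntropy().forward(val_logits, yval)
        val_acc = float((val_logits.argmax(axis=1) == yval).mean())
        history.append(
            {"epoch": epoch, "loss": epoch_loss / max(nb, 1), "val_loss": val_loss, "val_accuracy": val_acc}
        )
        if val_loss < best_loss:
            best_loss, best_weights, since_best = val_loss, model.get_weights(), 0
        else:
            since_best += 1
            if cfg.patience is not None and since_best >= cfg.patience:
                break
    if best_weights is not None:
        model.set_weights(best_weights)
    model._fitted = True
    return history


def predict(model: AMCNN, mmbn) -> np.ndarray:
    """Class probabilities for one MMBN (or input array); shape (2,)."""
    if isinstance(mmbn, MultilayerNetwork):
        x = mmbn.as_array().transpose(1, 2, 0)[None, ...]
    else:
        x = np.asarray(mmbn, dtype=nn.DTYPE)
        if x.ndim == 3:
            x = x[None, ...]
    p = model.predict_proba(x)
    return p[0] if p.shape[0] == 1 else p
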