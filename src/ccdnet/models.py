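"""Compression-quality classifier architectures and training.

Four small 1D-CNNs operating on max-aligned pulse vectors:

``lenet5_1d``
    LeNet-5 adapted to one dimension: input length 70, two conv blocks
    (32 and 64 channels, kernel 5), hidden dense widths 128 and 64,
    flatten length 64 x 17 = 1088, 158,274 trainable scalars.
``cpcnn4`` / ``cpcnn5``
    The compression-pulse CNNs: input length 72, three (kernels 7,5,3)
    or four (kernels 11,7,5,3) conv blocks with channels 32/64/128(/196),
    batch normalization after each activation, dropout after the last conv
    block and the first dense layer.
``alexnet_1d``
    A best-effort 1D AlexNet-style variant (optional extra).

Every conv is same-padded with stride 1, followed by ReLU and a length-2
floor max pool; the head is softmax over two classes (1 = correct depth).
Trainable-parameter counts are available both in closed form and by
materializing the network, and the two always agree.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import nn

__all__ = [
    "ConvBlock",
    "ArchitectureSpec",
    "ModelState",
    "TrainConfig",
    "TrainingError",
    "ARCHITECTURES",
    "build_architecture",
    "count_parameters",
    "materialize",
    "forward",
    "feature_maps",
    "cross_entropy",
    "train",
]


class TrainingError(RuntimeError):
    """Raised when optimization diverges (non-finite loss)."""


@dataclass(frozen=True)
class ConvBlock:
    out_channels: int
    kernel_length: int
    batch_norm: bool = False

    def __post_init__(self) -> None:
        if self.kernel_length % 2 == 0 or self.kernel_length < 1:
            raise ValueError("kernel_length must be odd")
        if self.out_channels < 1:
            raise ValueError("out_channels must be >= 1")


@dataclass(frozen=True)
class ArchitectureSpec:
    """Declarative description of a 1D-CNN classifier."""

    name: str
    input_length: int
    conv_blocks: tuple[ConvBlock, ...]
    fc_widths: tuple[int, ...]
    n_classes: int = 2
    dropout_after_last_conv: float = 0.0
    dropout_after_first_fc: float = 0.5

    def __post_init__(self) -> None:
        if self.n_classes != 2:
            raise ValueError("binary classifier: n_classes must be 2")
        L = self.input_length
        for blk in self.conv_blocks:
            L //= 2  # same-padded conv keeps length; pool floor-halves
            if L < 1:
                raise ValueError("pooled length collapses below 1 sample")

    @property
    def pooled_length(self) -> int:
        L = self.input_length
        for _ in self.conv_blocks:
            L //= 2
        return L

    @property
    def flatten_length(self) -> int:
        return self.conv_blocks[-1].out_channels * self.pooled_length


def _cpcnn_blocks(kernels: Sequence[int], channels: Sequence[int]) -> tuple[ConvBlock, ...]:
    return tuple(ConvBlock(c, k, batch_norm=True) for c, k in zip(channels, kernels))


ARCHITECTURES: dict[str, ArchitectureSpec] = {
    "lenet5_1d": ArchitectureSpec(
        name="lenet5_1d",
        input_length=70,
        conv_blocks=(ConvBlock(32, 5), ConvBlock(64, 5)),
        fc_widths=(128, 64),
        dropout_after_last_conv=0.0,
        dropout_after_first_fc=0.5,
    ),
    "cpcnn4": ArchitectureSpec(
        name="cpcnn4",
        input_length=72,
        conv_blocks=_cpcnn_blocks((7, 5, 3), (32, 64, 128)),
        fc_widths=(128, 64),
        dropout_after_last_conv=0.5,
        dropout_after_first_fc=0.5,
    ),
    "cpcnn5": ArchitectureSpec(
        name="cpcnn5",
        input_length=72,
        conv_blocks=_cpcnn_blocks((11, 7, 5, 3), (32, 64, 128, 196)),
        fc_widths=(128, 64),
        dropout_after_last_conv=0.5,
        dropout_after_first_fc=0.5,
    ),
    "alexnet_1d": ArchitectureSpec(
        name="alexnet_1d",
        input_length=72,
        conv_blocks=_cpcnn_blocks((11, 5, 3, 3), (32, 64, 128, 256)),
        fc_widths=(1024, 128),
        dropout_after_last_conv=0.5,
        dropout_after_first_fc=0.5,
    ),
}


def build_architecture(name: str) -> ArchitectureSpec:
    """Return the fixed spec of a named architecture."""
    try:
        return ARCHITECTURES[name]
    except KeyError:
        raise ValueError(
            f"unknown architecture {name!r}; choose from {sorted(ARCHITECTURES)}"
        ) from None


def count_parameters(spec: ArchitectureSpec, include_batch_norm: bool = True) -> int:
    """Closed-form trainable-scalar count.

    Each conv block adds ``out * (in * k + 1)``; each dense layer adds
    ``out * (in + 1)``; batch normalization adds ``2 * channels`` per
    flagged block when ``include_batch_norm``.
    """
    total = 0
    in_ch = 1
    for blk in spec.conv_blocks:
        total += blk.out_channels * (in_ch * blk.kernel_length + 1)
        if include_batch_norm and blk.batch_norm:
            total += 2 * blk.out_channels
        in_ch = blk.out_channels
    width = spec.flatten_length
    for w in list(spec.fc_widths) + [spec.n_classes]:
        total += w * (width + 1)
        width = w
    return total


class ModelState:
    """A materialized network: spec plus all trainable parameters.

    Holds the layer stack (``net``), the architecture spec and the dropout
    random stream.  ``training`` toggles batch-norm statistics and dropout.
    """

    def __init__(self, spec: ArchitectureSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        layers: list[nn.Layer] = []
        in_ch = 1
        for i, blk in enumerate(spec.conv_blocks):
            layers.append(nn.Conv1d(in_ch, blk.out_channels, blk.kernel_length, rng))
            layers.append(nn.ReLU())
            if blk.batch_norm:
                layers.append(nn.BatchNorm1d(blk.out_channels))
            layers.append(nn.MaxPool1d())
            if i == len(spec.conv_blocks) - 1 and spec.dropout_after_last_conv > 0:
                layers.append(nn.Dropout(spec.dropout_after_last_conv, rng))
            in_ch = blk.out_channels
        self._n_conv_layers = len(layers)
        layers.append(nn.Flatten())
        width = spec.flatten_length
        for i, w in enumerate(spec.fc_widths):
            layers.append(nn.Dense(width, w, rng))
            layers.append(nn.ReLU())
            if i == 0 and spec.dropout_after_first_fc > 0:
                layers.append(nn.Dropout(spec.dropout_after_first_fc, rng))
            width = w
        layers.append(nn.Dense(width, spec.n_classes, rng))
        self.net = nn.Sequential(layers)

    @property
    def training(self) -> bool:
        return self.net.training

    def train_mode(self, flag: bool = True) -> None:
        self.net.train_mode(flag)

    def n_parameters(self) -> int:
        return self.net.n_parameters()

    def logits(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.spec.input_length:
            raise ValueError(
                f"batch width {X.shape[1]} != input_length {self.spec.input_length}"
            )
        return self.net.forward(X[:, None, :])

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {}
        for i, name, arr in self.net.parameters():
            out[f"{i}.{name}"] = arr
        for i, layer in enumerate(self.net.layers):
            if isinstance(layer, nn.BatchNorm1d):
                out[f"{i}.running_mean"] = layer.running_mean
                out[f"{i}.running_var"] = layer.running_var
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, name, arr in self.net.parameters():
            arr[...] = state[f"{i}.{name}"]
        for i, layer in enumerate(self.net.layers):
            if isinstance(layer, nn.BatchNorm1d):
                layer.running_mean = np.asarray(state[f"{i}.running_mean"], dtype=float)
                layer.running_var = np.asarray(state[f"{i}.running_var"], dtype=float)


def forward(model: ModelState, batch: np.ndarray) -> np.ndarray:
    """Per-class posterior probabilities, one row per pulse (sums to 1)."""
    return nn.softmax(model.logits(batch))


def feature_maps(model: ModelState, batch: np.ndarray) -> np.ndarray:
    """Pre-flatten feature maps (batch, channels, pooled length), eval mode."""
    was_training = model.training
    model.train_mode(False)
    X = np.asarray(batch, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    out = model.net.forward(X[:, None, :], upto=model._n_conv_layers)
    model.train_mode(was_training)
    return out


def cross_entropy(probabilities: np.ndarray, labels: np.ndarray, eps: float = 1e-12) -> float:
    """Mean binary cross-entropy.

    ``probabilities`` may be the (n, 2) softmax output or the class-1
    probability vector; ``labels`` are 0/1.  Probabilities are clamped to
    ``[eps, 1-eps]`` so a confidently wrong prediction yields a large finite
    loss instead of an infinity.
    """
    p = np.asarray(probabilities, dtype=float)
    if p.ndim == 2:
        p = p[:, 1]
    y = np.asarray(labels)
    if p.shape != y.shape:
        raise ValueError("probabilities and labels must have matching lengths")
    p = np.clip(p, eps, 1.0 - eps)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


@dataclass(frozen=True)
class TrainConfig:
    """Mini-batch training settings (batch size 40 by default)."""

    batch_size: int = 40
    iterations: int = 300
    learning_rate: float = 1e-3
    seed: int = 0
    optimizer: str = "adam"
    eval_every: int = 25

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.iterations < 1:
            raise ValueError("batch_size and iterations must be >= 1")
        if self.optimizer != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")


def _as_xy(dataset) -> tuple[np.ndarray, np.ndarray]:
    if hasattr(dataset, "X") and hasattr(dataset, "y"):
        return np.asarray(dataset.X, dtype=float), np.asarray(dataset.y, dtype=int)
    X, y = dataset
    return np.asarray(X, dtype=float), np.asarray(y, dtype=int)


def train(
    spec: ArchitectureSpec,
    train_set,
    val_set=None,
    cfg: TrainConfig | None = None,
) -> tuple[ModelState, dict]:
    """Minimize cross-entropy by seeded mini-batch Adam.

    ``train_set``/``val_set`` are (X, y) pairs or objects with ``X``/``y``
    attributes.  Batches cycle through a reshuffled permutation each epoch.
    Returns the trained model and a history dict with per-iteration loss and
    periodic train/validation accuracy.

    Raises
    ------
    TrainingError
        If the loss becomes non-finite.
    """
    from .metrics import accuracy, confusion  # local import avoids a cycle

    cfg = cfg or TrainConfig()
    X, y = _as_xy(train_set)
    if len(X) == 0:
        raise ValueError("empty training set")
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")

    model = ModelState(spec, seed=cfg.seed)
    optimizer = nn.Adam(model.net, lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed + 0x5EED)
    order = rng.permutation(len(X))
    cursor = 0
    history: dict = {"loss": [], "iteration": [], "val_acc": [], "train_acc": [],
                     "eval_iteration": []}

    def _acc(data) -> float:
        Xe, ye = _as_xy(data)
        model.train_mode(False)
        pred = forward(model, Xe).argmax(axis=1)
        return accuracy(confusion(pred, ye))

    for it in range(cfg.iterations):
        if cursor + cfg.batch_size > len(order):
            order = rng.permutation(len(X))
            cursor = 0
        idx = order[cursor : cursor + cfg.batch_size]
        cursor += cfg.batch_size
        xb, yb = X[idx], y[idx]

        model.train_mode(True)
        logits = model.logits(xb)
        probs = nn.softmax(logits)
        loss = cross_entropy(probs, yb)
        if not np.isfinite(loss):
            raise TrainingError(
                f"loss became non-finite at iteration {it} "
                f"(lr={cfg.learning_rate}, batch={cfg.batch_size})"
            )
        onehot = np.eye(spec.n_classes)[yb]
        model.net.backward((probs - onehot) / len(yb))
        optimizer.step()

        history["loss"].append(loss)
        history["iteration"].append(it)
        if (it + 1) % cfg.eval_every == 0 or it == cfg.iterations - 1:
            history["eval_iteration"].append(it)
            history["train_acc"].append(_acc((X, y)))
            history["val_acc"].append(_acc(val_set) if val_set is not None else np.nan)

    model.train_mode(False)
    return model, history
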