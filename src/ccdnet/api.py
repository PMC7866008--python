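"""Model/Results interface over the compression-quality classifiers.

Follows the familiar two-object pattern of statistical modelling packages:
construct a :class:`CompressionQualityCNN` from data, call :meth:`fit` to
obtain a :class:`CNNFitResults` carrying the trained parameters, training
history and evaluation methods (:meth:`~CNNFitResults.evaluate`,
:meth:`~CNNFitResults.summary`, :meth:`~CNNFitResults.plot_roc`).

Example
-------
>>> from ccdnet import SimulatorConfig, make_dataset, CompressionQualityCNN
>>> data = make_dataset(200, 0.5, SimulatorConfig.separable(seed=7))
>>> model = CompressionQualityCNN(data, arch="cpcnn4")
>>> res = model.fit(iterations=300, seed=0)
>>> print(res.summary())            # doctest: +SKIP
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np

from .metrics import ROCCurve, accuracy, confusion, f_score, roc_auc
from .models import (
    ArchitectureSpec,
    ModelState,
    TrainConfig,
    build_architecture,
    count_parameters,
    cross_entropy,
    forward,
    train,
)
from .pipeline import PulseDataset

__all__ = ["CompressionQualityCNN", "CNNFitResults"]


class CompressionQualityCNN:
    """A 1D-CNN compression-depth quality classifier bound to training data.

    Parameters
    ----------
    data : PulseDataset or (X, y)
        Normalized pulses (n x L) with 0/1 labels; L must match the chosen
        architecture's input length.
    arch : str or ArchitectureSpec
        One of ``lenet5_1d``, ``cpcnn4``, ``cpcnn5``, ``alexnet_1d`` or an
        explicit spec.
    val_data : optional
        Held-out pulses evaluated periodically during fitting.
    """

    def __init__(self, data, arch="cpcnn4", val_data=None):
        self.spec: ArchitectureSpec = (
            arch if isinstance(arch, ArchitectureSpec) else build_architecture(arch)
        )
        X, y = self._coerce(data)
        if X.shape[1] != self.spec.input_length:
            raise ValueError(
                f"pulse length {X.shape[1]} != {self.spec.name} input length "
                f"{self.spec.input_length}"
            )
        self.data = (X, y)
        self.val_data = self._coerce(val_data) if val_data is not None else None

    @staticmethod
    def _coerce(data) -> tuple[np.ndarray, np.ndarray]:
        if hasattr(data, "X") and hasattr(data, "y"):
            return np.asarray(data.X, dtype=float), np.asarray(data.y, dtype=int)
        X, y = data
        return np.asarray(X, dtype=float), np.asarray(y, dtype=int)

    def fit(
        self,
        iterations: int = 300,
        batch_size: int = 40,
        learning_rate: float = 1e-3,
        seed: int = 0,
    ) -> "CNNFitResults":
        """Train by seeded mini-batch Adam on the bound data."""
        cfg = TrainConfig(
            batch_size=batch_size,
            iterations=iterations,
            learning_rate=learning_rate,
            seed=seed,
        )
        state, history = train(self.spec, self.data, self.val_data, cfg)
        return CNNFitResults(self, state, history, cfg)


class CNNFitResults:
    """Trained classifier: parameters, history and evaluation surface."""

    def __init__(self, model: CompressionQualityCNN, state: ModelState,
                 history: dict, train_config: TrainConfig):
        self.model = model
        self.state = state
        self.history = history
        self.train_config = train_config

    # -- prediction -------------------------------------------------------
    def predict_proba(self, X) -> np.ndarray:
        """Class-1 ("correct depth") posterior probability per pulse."""
        return forward(self.state, np.asarray(X, dtype=float))[:, 1]

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X) >= 0.5).astype(int)

    # -- evaluation -------------------------------------------------------
    def evaluate(self, data) -> dict:
        """ACC, F-score, AUC, cross-entropy and confusion counts."""
        X, y = CompressionQualityCNN._coerce(data)
        scores = self.predict_proba(X)
        c = confusion((scores >= 0.5).astype(int), y)
        return {
            "accuracy": accuracy(c),
            "f_score": f_score(c),
            "auc": roc_auc(scores, y).auc,
            "cross_entropy": cross_entropy(scores, y),
            "confusion": dataclasses.asdict(c),
            "n": len(y),
        }

    def roc(self, data) -> ROCCurve:
        X, y = CompressionQualityCNN._coerce(data)
        return roc_auc(self.predict_proba(X), y)

    # -- reporting --------------------------------------------------------
    def summary(self, eval_data=None) -> str:
        """Plain-text summary table of the fit (and optional evaluation)."""
        spec = self.model.spec
        lines = [
            "Compression-depth quality classifier",
            "=" * 52,
            f"{'Architecture:':<28}{spec.name}",
            f"{'Input length:':<28}{spec.input_length}",
            f"{'Conv blocks:':<28}"
            + ", ".join(f"{b.out_channels}@k{b.kernel_length}" for b in spec.conv_blocks),
            f"{'Flatten length:':<28}{spec.flatten_length}",
            f"{'Trainable parameters:':<28}{self.state.n_parameters():,}"
            f" (closed form {count_parameters(spec):,})",
            f"{'Iterations x batch:':<28}{self.train_config.iterations}"
            f" x {self.train_config.batch_size}",
            f"{'Final training loss:':<28}{self.history['loss'][-1]:.4f}",
            f"{'Final training ACC:':<28}{self.history['train_acc'][-1]:.4f}",
        ]
        if self.history["val_acc"] and np.isfinite(self.history["val_acc"][-1]):
            lines.append(f"{'Final validation ACC:':<28}{self.history['val_acc'][-1]:.4f}")
        if eval_data is not None:
            m = self.evaluate(eval_data)
            lines += [
                "-" * 52,
                f"{'Test ACC:':<28}{m['accuracy']:.4f}",
                f"{'Test F-score:':<28}{m['f_score']:.4f}",
                f"{'Test AUC:':<28}{m['auc']:.4f}",
            ]
        return "\n".join(lines)

    def plot_roc(self, data, ax=None):
        """ROC curve with the random-guess diagonal, on a matplotlib axis."""
        import matplotlib.pyplot as plt

        roc = self.roc(data)
        if ax is None:
            _, ax = plt.subplots(figsize=(4.5, 4.5))
        ax.plot(roc.fpr, roc.tpr, label=f"{self.model.spec.name} (AUC={roc.auc:.3f})")
        ax.plot([0, 1], [0, 1], "k:", label="random guess (AUC=0.5)")
        ax.set_xlabel("False positive rate")
        ax.set_ylabel("True positive rate")
        ax.legend(loc="lower right")
        return ax
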