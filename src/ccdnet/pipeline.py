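"""End-to-end pipeline: simulate -> filter -> segment -> train -> evaluate.

The default configuration mirrors the study conditions the package targets:
937 labelled compression pulses, half of them (471) correct-depth, split
680/120/137 into training/testing/validation (stratified by label), a batch
size of 40 and 300 training iterations of the cpcnn4 classifier.  A single
global seed fans out deterministically to the simulator, the split and the
training run.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .filters import FilterConfig
from .metrics import accuracy, confusion, f_score, integrate_depth, roc_auc
from .models import TrainConfig, build_architecture, count_parameters, forward, train
from .segment import SegmentationConfig
from .simulate import SimulatorConfig, make_dataset

__all__ = ["PulseDataset", "PipelineConfig", "stratified_split", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PulseDataset:
    """Normalized pulses with labels, true depths and source segments."""

    X: np.ndarray
    y: np.ndarray
    depth_mm: np.ndarray
    segments: Optional[list] = None
    sampling_interval: float = 0.005

    def __len__(self) -> int:
        return len(self.y)

    def subset(self, idx: np.ndarray) -> "PulseDataset":
        return PulseDataset(
            X=self.X[idx],
            y=self.y[idx],
            depth_mm=self.depth_mm[idx],
            segments=[self.segments[i] for i in idx] if self.segments else None,
            sampling_interval=self.sampling_interval,
        )


@dataclass(frozen=True)
class PipelineConfig:
    """Full configuration of one reproducible pipeline run."""

    simulator: SimulatorConfig = field(default_factory=SimulatorConfig)
    filters: FilterConfig = field(default_factory=FilterConfig)
    segmentation: SegmentationConfig = field(
        default_factory=lambda: SegmentationConfig(effective_points=72)
    )
    architecture: str = "cpcnn4"
    training: TrainConfig = field(default_factory=TrainConfig)
    n_pulses: int = 937
    correct_fraction: float = 471 / 937
    n_train: int = 680
    n_test: int = 120
    seed: int = 0

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        """Build from a plain mapping (e.g. parsed YAML), nested sections
        ``simulator``/``filters``/``segmentation``/``training`` included."""
        raw = dict(raw)
        for key, ctor in (
            ("simulator", SimulatorConfig),
            ("filters", FilterConfig),
            ("segmentation", SegmentationConfig),
            ("training", TrainConfig),
        ):
            if key in raw and isinstance(raw[key], dict):
                section = {
                    k: tuple(v) if isinstance(v, list) else v
                    for k, v in raw[key].items()
                }
                if key == "simulator" and "depth_ranges" in section:
                    section["depth_ranges"] = tuple(
                        tuple(r) for r in section["depth_ranges"]
                    )
                raw[key] = ctor(**section)
        return cls(**raw)

    def __post_init__(self) -> None:
        if self.n_train + self.n_test >= self.n_pulses:
            raise ValueError("split counts must leave a validation remainder")
        spec = build_architecture(self.architecture)
        if spec.input_length != self.segmentation.effective_points:
            raise ValueError(
                f"normalized length {self.segmentation.effective_points} "
                f"!= model input length {spec.input_length}"
            )


def stratified_split(
    dataset: PulseDataset, n_train: int, n_test: int, seed: int
) -> tuple[PulseDataset, PulseDataset, PulseDataset]:
    """Seeded train/test/validation split, stratified by label.

    Per-class allocations are proportional (largest remainder), keeping each
    split's class fractions within one item of the dataset's.
    """
    n = len(dataset)
    if n_train + n_test >= n:
        raise ValueError("n_train + n_test must be < dataset size")
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    val_idx: list[int] = []
    for label in (0, 1):
        members = np.nonzero(dataset.y == label)[0]
        rng.shuffle(members)
        frac = len(members) / n
        k_train = int(round(n_train * frac))
        k_test = int(round(n_test * frac))
        train_idx.extend(members[:k_train])
        test_idx.extend(members[k_train : k_train + k_test])
        val_idx.extend(members[k_train + k_test :])
    parts = (
        np.sort(np.asarray(train_idx, dtype=int)),
        np.sort(np.asarray(test_idx, dtype=int)),
        np.sort(np.asarray(val_idx, dtype=int)),
    )
    return tuple(dataset.subset(a) for a in parts)  # type: ignore[return-value]


def _integration_metrics(split: PulseDataset) -> Optional[dict]:
    if not split.segments:
        return None
    pred = np.array(
        [
            integrate_depth(seg, split.sampling_interval)[1]
            for seg in split.segments
        ]
    )
    c = confusion(pred, split.y)
    return {
        "accuracy": accuracy(c),
        "f_score": f_score(c),
        "confusion": dataclasses.asdict(c),
    }


def run_pipeline(cfg: PipelineConfig | None = None) -> dict:
    """Run the full pipeline and return a structured report.

    Stages: simulate + filter + segment (via ``make_dataset``), stratified
    split, train the configured architecture, evaluate ACC / F-score / AUC /
    confusion counts on the test split, and score the double-integration
    depth baseline on the same test segments.
    """
    cfg = cfg or PipelineConfig()
    t0 = time.time()
    sim = replace(cfg.simulator, seed=cfg.seed)
    stage = "simulate+segment"
    try:
        data = make_dataset(
            cfg.n_pulses, cfg.correct_fraction, sim, cfg.filters, cfg.segmentation
        )
        logger.info("[%s] %d pulses of length %d", stage, len(data), data.X.shape[1])

        stage = "split"
        train_set, test_set, val_set = stratified_split(
            data, cfg.n_train, cfg.n_test, seed=cfg.seed + 1
        )
        logger.info(
            "[split] train/test/val = %d/%d/%d",
            len(train_set), len(test_set), len(val_set),
        )

        stage = "train"
        spec = build_architecture(cfg.architecture)
        tcfg = replace(cfg.training, seed=cfg.seed + 2)
        model, history = train(spec, train_set, val_set, tcfg)

        stage = "evaluate"
        probs = forward(model, test_set.X)[:, 1]
        pred = (probs >= 0.5).astype(int)
        c = confusion(pred, test_set.y)
        roc = roc_auc(probs, test_set.y)
    except Exception as err:
        raise RuntimeError(f"pipeline failed in stage '{stage}': {err}") from err

    report = {
        "config": {
            "architecture": cfg.architecture,
            "n_pulses": cfg.n_pulses,
            "correct_fraction": cfg.correct_fraction,
            "split": [len(train_set), len(test_set), len(val_set)],
            "seed": cfg.seed,
            "batch_size": cfg.training.batch_size,
            "iterations": cfg.training.iterations,
            "simulator": dataclasses.asdict(sim),
        },
        "model": {
            "name": spec.name,
            "n_parameters": model.n_parameters(),
            "n_parameters_closed_form": count_parameters(spec),
            "final_loss": history["loss"][-1],
        },
        "metrics": {
            "accuracy": accuracy(c),
            "f_score": f_score(c),
            "auc": roc.auc,
            "confusion": dataclasses.asdict(c),
        },
        "integration_baseline": _integration_metrics(test_set),
        "history": {
            "eval_iteration": history["eval_iteration"],
            "train_acc": history["train_acc"],
            "val_acc": history["val_acc"],
        },
        "elapsed_s": time.time() - t0,
    }
    return report
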