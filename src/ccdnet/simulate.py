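"""Synthetic chest-compression accelerometry.

Real CPR recordings of labelled compressions are rarely shareable, so this
module generates accelerometer traces with the statistical structure the rest
of the pipeline assumes: a quiescent gravity baseline, reciprocating
compression pulses at 100-120 per minute, pulse amplitude tied to compression
depth, white measurement noise, optional low-frequency drift, and sparse
"hammering" spike anomalies.

The pulse template is a raised-cosine (Hann) deflection of the acceleration
away from the static gravity reading.  Its amplitude is linear in compression
depth; the default slope is calibrated so that double integration of a
detected noise-free pulse recovers the depth in millimetres (see
:func:`ccdnet.metrics.integrate_depth`).  A compression is labelled *correct*
(class 1) when its depth lies in [50 mm, 60 mm], boundaries inclusive;
anything shallower or deeper is class 0.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

__all__ = [
    "SimulatorConfig",
    "PulseAnnotation",
    "AccelTrace",
    "GenerationError",
    "simulate_trace",
    "depth_to_label",
    "pulse_template",
    "trace_template",
    "make_dataset",
]

#: depth band (mm) counted as a correct compression, boundaries inclusive
CORRECT_DEPTH_MM = (50.0, 60.0)

#: acceleration amplitude per mm of depth (m/s^2 per mm).  Calibrated so that
#: the peak of the twice-integrated default pulse (duration ~0.46 s, cut at
#: the alpha/2 detection boundary) equals the depth on the mm scale.
DEFAULT_AMPLITUDE_PER_MM = 0.0297


class GenerationError(RuntimeError):
    """Raised when a requested dataset cannot be produced."""


def depth_to_label(depth_mm: float) -> int:
    """Binary quality label for a compression depth.

    1 = correct depth (50-60 mm inclusive), 0 = insufficient (<50 mm) or
    excessive (>60 mm).
    """
    if not np.isfinite(depth_mm) or depth_mm <= 0:
        raise ValueError(f"depth_mm must be positive and finite, got {depth_mm!r}")
    lo, hi = CORRECT_DEPTH_MM
    return int(lo <= depth_mm <= hi)


@dataclass(frozen=True)
class PulseAnnotation:
    """Ground truth for one simulated compression (pre-noise).

    Indices are 0-based into the parent trace; ``[start_index, end_index)``
    is half-open.
    """

    start_index: int
    end_index: int
    peak_index: int
    depth_mm: float
    label: int

    def __post_init__(self) -> None:
        if not (self.start_index < self.peak_index < self.end_index):
            raise ValueError(
                "require start_index < peak_index < end_index, got "
                f"({self.start_index}, {self.peak_index}, {self.end_index})"
            )
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")


@dataclass
class AccelTrace:
    """Uniformly sampled acceleration series.

    Parameters
    ----------
    samples : array of float
        Acceleration values (m/s^2).
    sampling_interval : float
        Time between samples in seconds.
    annotations : list of PulseAnnotation, optional
        Ground-truth compressions, sorted and non-overlapping.
    """

    samples: np.ndarray
    sampling_interval: float
    annotations: Optional[list[PulseAnnotation]] = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a non-empty 1D array")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be positive")
        if self.annotations:
            prev_end = -1
            for a in self.annotations:
                if a.start_index < prev_end:
                    raise ValueError("annotations must be sorted and non-overlapping")
                prev_end = a.end_index
            if self.annotations[-1].end_index > len(self.samples):
                raise ValueError("annotation extends past end of trace")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def duration(self) -> float:
        return len(self.samples) * self.sampling_interval

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) * self.sampling_interval


@dataclass(frozen=True)
class SimulatorConfig:
    """Study conditions for the synthetic compression generator.

    ``depth_ranges``/``depth_weights`` describe a mixture of uniform depth
    components covering insufficient (<50 mm), correct ([50, 60] mm) and
    excessive (>60 mm) compressions.  ``gravity_baseline`` is the quiescent
    accelerometer reading (projection of gravity on the sensing axis).
    """

    sampling_interval: float = 0.005
    rate_per_minute: tuple[float, float] = (100.0, 120.0)
    depth_ranges: tuple[tuple[float, float], ...] = (
        (40.0, 49.5),
        (50.0, 60.0),
        (60.5, 72.0),
    )
    depth_weights: tuple[float, ...] = (0.25, 0.5, 0.25)
    gravity_baseline: float = 3.0
    amplitude_per_mm: float = DEFAULT_AMPLITUDE_PER_MM
    noise_sd: float = 0.08
    drift_sd: float = 0.0
    spike_rate: float = 3.0
    spike_magnitude: tuple[float, float] = (3.0, 8.0)
    pulse_duration: tuple[float, float] = (0.44, 0.48)
    inter_pulse_gap: tuple[float, float] = (0.04, 0.08)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be positive")
        lo, hi = self.rate_per_minute
        if not (0 < lo <= hi < 300):
            raise ValueError("rate_per_minute bounds must satisfy 0 < lo <= hi < 300")
        if len(self.depth_ranges) != len(self.depth_weights):
            raise ValueError("depth_ranges and depth_weights lengths differ")
        for dlo, dhi in self.depth_ranges:
            if not (0 < dlo <= dhi):
                raise ValueError("depth ranges must be positive and ordered")
        if any(w < 0 for w in self.depth_weights) or sum(self.depth_weights) <= 0:
            raise ValueError("depth_weights must be non-negative with positive sum")
        if self.noise_sd < 0 or self.drift_sd < 0:
            raise ValueError("noise/drift standard deviations must be >= 0")
        if self.spike_rate < 0:
            raise ValueError("spike_rate must be >= 0")
        glo, ghi = self.inter_pulse_gap
        if not (0 <= glo <= ghi):
            raise ValueError("inter_pulse_gap bounds must satisfy 0 <= lo <= hi")
        plo, phi = self.pulse_duration
        if not (0 < plo <= phi):
            raise ValueError("pulse_duration bounds must satisfy 0 < lo <= hi")

    def amplitude_for_depth(self, depth_mm: float) -> float:
        """Peak acceleration deflection (m/s^2) of a pulse of this depth."""
        return self.amplitude_per_mm * depth_mm

    def with_correct_fraction(self, fraction: float) -> "SimulatorConfig":
        """Mixture reweighted so the correct class has probability `fraction`."""
        if not 0.0 <= fraction <= 1.0:
            raise ValueError("fraction must lie in [0, 1]")
        rest = (1.0 - fraction) / 2.0
        return replace(self, depth_weights=(rest, fraction, rest))

    @classmethod
    def separable(cls, **kwargs) -> "SimulatorConfig":
        """Conditions with a depth margin around the 50/60 mm boundaries.

        With no depths near the class boundary the amplitude bands of the two
        classes are disjoint, which makes the classification problem
        (noise aside) linearly separable -- useful for learning sanity checks.
        """
        kwargs.setdefault(
            "depth_ranges", ((40.0, 47.0), (52.0, 58.0), (63.0, 70.0))
        )
        return cls(**kwargs)


def pulse_template(
    depth_mm: float, n_samples: int, amplitude_per_mm: float = DEFAULT_AMPLITUDE_PER_MM
) -> np.ndarray:
    """Noise-free acceleration deflection of one compression.

    A Hann (raised-cosine) bump over ``n_samples`` points: zero at both ends,
    peaked at the midpoint.  ``n_samples`` should be even so the peak falls
    exactly on a sample.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    amp = amplitude_per_mm * depth_mm
    t = np.arange(n_samples)
    return amp * 0.5 * (1.0 - np.cos(2.0 * np.pi * t / n_samples))


def trace_template(trace: AccelTrace, config: SimulatorConfig) -> np.ndarray:
    """Reconstruct the noise-free signal of an annotated trace.

    Gravity baseline plus the pulse template of every annotation; exact for
    traces produced by :func:`simulate_trace`.
    """
    out = np.full(len(trace), config.gravity_baseline)
    for a in trace.annotations or []:
        n = a.end_index - a.start_index
        out[a.start_index : a.end_index] += pulse_template(
            a.depth_mm, n, config.amplitude_per_mm
        )
    return out


def _draw_depth(rng: np.random.Generator, config: SimulatorConfig) -> float:
    w = np.asarray(config.depth_weights, dtype=float)
    comp = rng.choice(len(w), p=w / w.sum())
    lo, hi = config.depth_ranges[comp]
    return float(rng.uniform(lo, hi))


def simulate_trace(config: SimulatorConfig, duration: float) -> AccelTrace:
    """Generate one annotated accelerometer trace.

    Compression cycles are laid down sequentially: a raised-cosine pulse of
    duration drawn from ``config.pulse_duration`` followed by a quiescent
    gap that pads the cycle out to 60/rate seconds (rate drawn per cycle
    from ``config.rate_per_minute``), but never shorter than
    ``config.inter_pulse_gap``.  Pulse durations are rounded to an even
    number of samples so the peak lands exactly on the sampling grid.  White noise,
    drift (integrated white noise) and single-sample spike anomalies are
    superimposed after the ground-truth annotations are recorded.

    Parameters
    ----------
    config : SimulatorConfig
    duration : float
        Trace length in seconds; must cover at least one compression period.

    Returns
    -------
    AccelTrace with per-pulse :class:`PulseAnnotation` ground truth.
    """
    dt = config.sampling_interval
    min_period = 60.0 / config.rate_per_minute[1]
    if duration <= 0 or duration < min_period:
        raise ValueError(
            f"duration must cover at least one compression period "
            f"({min_period:.3f} s), got {duration!r}"
        )
    n = int(round(duration / dt))
    rng = np.random.default_rng(config.seed)
    samples = np.full(n, config.gravity_baseline)
    annotations: list[PulseAnnotation] = []

    pos = int(round(rng.uniform(*config.inter_pulse_gap) / dt))  # lead-in gap
    while True:
        rate = rng.uniform(*config.rate_per_minute)
        period_s = 60.0 / rate
        pulse_s = rng.uniform(*config.pulse_duration)
        gap_s = max(period_s - pulse_s, rng.uniform(*config.inter_pulse_gap))
        pulse_n = 2 * int(round(pulse_s / (2 * dt)))
        gap_n = max(int(round(gap_s / dt)), 1)
        depth = _draw_depth(rng, config)
        end = pos + pulse_n
        if end > n:
            break
        samples[pos:end] += pulse_template(depth, pulse_n, config.amplitude_per_mm)
        annotations.append(
            PulseAnnotation(
                start_index=pos,
                end_index=end,
                peak_index=pos + pulse_n // 2,
                depth_mm=depth,
                label=depth_to_label(depth),
            )
        )
        pos = end + gap_n

    if config.noise_sd > 0:
        samples = samples + rng.normal(0.0, config.noise_sd, size=n)
    if config.drift_sd > 0:
        samples = samples + np.cumsum(rng.normal(0.0, config.drift_sd, size=n))
    if config.spike_rate > 0:
        n_spikes = rng.poisson(config.spike_rate * duration / 60.0)
        if n_spikes > 0:
            idx = rng.integers(0, n, size=n_spikes)
            mag = rng.uniform(*config.spike_magnitude, size=n_spikes)
            sign = rng.choice([-1.0, 1.0], size=n_spikes)
            samples[idx] += sign * mag

    return AccelTrace(samples, dt, annotations)


def make_dataset(
    n: int,
    correct_fraction: float,
    config: SimulatorConfig,
    filter_config=None,
    segmentation_config=None,
    pulse_length: Optional[int] = None,
    max_attempts: int = 200,
):
    """Generate ``n`` normalized pulses via the full processing path.

    Traces are simulated in chunks, filtered, segmented, matched against the
    ground-truth annotations for labels/depths and normalized; pulses are
    accumulated per class until ``round(correct_fraction * n)`` correct and
    the remaining abnormal pulses are collected.  ``pulse_length`` overrides
    the segmentation config's normalized length (e.g. 72 for the CPCNN
    classifiers).

    Returns
    -------
    PulseDataset (see :mod:`ccdnet.pipeline`) with arrays ``X`` (n x L),
    ``y``, ``depth_mm`` and the source :class:`PulseSegment` objects.

    Raises
    ------
    GenerationError
        If the class quotas cannot be filled within ``max_attempts`` chunks.
    """
    # imported here to avoid a cycle (segmentation imports AccelTrace)
    from .filters import FilterConfig, filter_trace
    from .pipeline import PulseDataset
    from .segment import (
        SegmentationConfig,
        align_and_pad,
        detect_pulses,
        match_segments,
    )

    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= correct_fraction <= 1.0:
        raise ValueError("correct_fraction must lie in [0, 1]")
    fcfg = filter_config or FilterConfig()
    scfg = segmentation_config or SegmentationConfig()
    if pulse_length is not None:
        scfg = replace(scfg, effective_points=pulse_length)
    base = config.with_correct_fraction(correct_fraction)

    n_correct = int(round(correct_fraction * n))
    n_abnormal = n - n_correct
    got: dict[int, list] = {0: [], 1: []}  # label -> [(values, depth, segment)]
    chunk_duration = 30.0

    for attempt in range(max_attempts):
        if len(got[1]) >= n_correct and len(got[0]) >= n_abnormal:
            break
        cfg = replace(base, seed=(base.seed + 1_000_003 * attempt) % (2**31))
        trace = simulate_trace(cfg, chunk_duration)
        filtered = filter_trace(trace, fcfg)
        segments = detect_pulses(trace, filtered, scfg)
        for seg, ann in match_segments(segments, trace.annotations):
            if ann is None:
                continue
            pulse = align_and_pad(seg, scfg.effective_points)
            got[ann.label].append((pulse.values, ann.depth_mm, seg))
    else:
        raise GenerationError(
            f"could not reach {n_correct}/{n_abnormal} correct/abnormal pulses "
            f"in {max_attempts} chunks (have {len(got[1])}/{len(got[0])})"
        )

    rows, labels, depths, segs = [], [], [], []
    for label, quota in ((1, n_correct), (0, n_abnormal)):
        for values, depth, seg in got[label][:quota]:
            rows.append(values)
            labels.append(label)
            depths.append(depth)
            segs.append(seg)
    return PulseDataset(
        X=np.asarray(rows, dtype=float),
        y=np.asarray(labels, dtype=int),
        depth_mm=np.asarray(depths, dtype=float),
        segments=segs,
        sampling_interval=config.sampling_interval,
    )
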