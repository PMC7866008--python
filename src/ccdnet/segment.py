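"""Compression-pulse recognition and normalization.

Detection follows a dual-sliding-window threshold procedure: a window over
the raw samples (window A) and one over the filtered samples (window B).  A
candidate pulse opens when the filtered signal's deviation from the static
gravity value exceeds a threshold of alpha% of that gravity value; the cut
starts at the last near-baseline sample before the crossing (taken from
window B, falling back to window A when B is flat) and ends where the signal
returns near baseline.  Candidates are kept only if they pass three
restrictions: duration within bounds, sufficient peak amplitude, and
unimodality (exactly one dominant extreme after filtering).

Each kept pulse is normalized for the classifier by max-value alignment:
baseline-subtracted samples are placed in a fixed-length zero vector with the
largest sample at 75% of the window (75% of the points to its left, 25% to
its right), tails truncated, the rest zero-filled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .filters import FilterConfig, filter_trace
from .simulate import AccelTrace, PulseAnnotation

__all__ = [
    "SegmentationConfig",
    "PulseSegment",
    "NormalizedPulse",
    "estimate_static_gravity",
    "detect_pulses",
    "align_and_pad",
    "segment_trace",
    "match_segments",
]


@dataclass(frozen=True)
class SegmentationConfig:
    """Settings for pulse detection and normalization.

    ``alpha_percent`` is the detection threshold expressed as a percentage
    change from the static gravity value (empirically useful range about
    21-32).  ``effective_points`` is the fixed normalized pulse length L fed
    to a classifier (70 for the LeNet5 reproduction, 72 for the CPCNN
    variants).  ``min_amplitude`` defaults to the alpha threshold itself when
    left as ``None``.
    """

    alpha_percent: float = 25.0
    min_duration_s: float = 0.25
    max_duration_s: float = 0.60
    min_amplitude: Optional[float] = None
    effective_points: int = 70
    window_len: int = 128

    def __post_init__(self) -> None:
        if not 0 < self.alpha_percent < 100:
            raise ValueError("alpha_percent must lie in (0, 100)")
        if not 0 < self.min_duration_s < self.max_duration_s:
            raise ValueError("require 0 < min_duration_s < max_duration_s")
        if self.effective_points < 2:
            raise ValueError("effective_points must be >= 2")
        if self.window_len < 2:
            raise ValueError("window_len must be >= 2")


@dataclass
class PulseSegment:
    """One compression's cut waveform.

    ``samples`` are the (filtered) values over ``[start_index, end_index)``
    of the source trace; ``peak_index`` locates the extreme deviation.
    ``baseline`` records the static gravity estimate used during detection.
    """

    samples: np.ndarray
    start_index: int
    end_index: int
    peak_index: int
    baseline: Optional[float] = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.end_index - self.start_index < 2:
            raise ValueError("segment must span at least 2 samples")
        if len(self.samples) != self.end_index - self.start_index:
            raise ValueError("samples length must equal end_index - start_index")
        if not self.start_index <= self.peak_index < self.end_index:
            raise ValueError("peak_index must lie in [start_index, end_index)")

    def __len__(self) -> int:
        return len(self.samples)


@dataclass
class NormalizedPulse:
    """Fixed-length, max-aligned, zero-padded pulse vector."""

    values: np.ndarray
    label: Optional[int] = None
    depth_mm: Optional[float] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be 1D")


def estimate_static_gravity(trace: AccelTrace) -> float:
    """Robust estimate of the quiescent (static gravity) level.

    Compression traces can spend most of their time inside pulses, so a plain
    median is biased.  Instead the sample histogram's modal bin anchors the
    quiescent cluster and the estimate is the median of all samples within a
    few noise standard deviations of that mode; the noise scale comes from
    the median absolute successive difference, which is insensitive to the
    slow pulse component.
    """
    x = trace.samples
    if len(x) < max(2, int(round(1.0 / trace.sampling_interval))):
        raise ValueError("need at least 1 s of data to estimate static gravity")
    if np.ptp(x) == 0:
        return float(x[0])
    # noise sd from successive differences: var(diff) = 2 sigma^2 for white noise
    noise_sd = np.median(np.abs(np.diff(x))) / (np.sqrt(2.0) * 0.6745)
    counts, edges = np.histogram(x, bins=200)
    k = int(np.argmax(counts))
    mode = 0.5 * (edges[k] + edges[k + 1])
    half_width = max(3.0 * noise_sd, edges[1] - edges[0])
    quiescent = x[np.abs(x - mode) <= half_width]
    return float(np.median(quiescent))


def _three_restrictions(
    dev: np.ndarray, start: int, end: int, dt: float, cfg: SegmentationConfig, thr: float
) -> bool:
    """Step-4 checks: duration bounds, peak amplitude, unimodality."""
    duration = (end - start) * dt
    if not cfg.min_duration_s <= duration <= cfg.max_duration_s:
        return False
    seg = dev[start:end]
    peak = seg.max()
    min_amp = cfg.min_amplitude if cfg.min_amplitude is not None else thr
    if peak < min_amp:
        return False
    # unimodal: exactly one dominant extreme, i.e. a single connected region
    # above half of the peak deviation (a noise dimple on one hump does not
    # split it; a merged double pulse or a large spike remnant does)
    above = seg >= 0.5 * peak
    n_runs = int(above[0]) + int(np.sum(above[1:] & ~above[:-1]))
    return n_runs == 1


def detect_pulses(
    raw: AccelTrace, filtered: AccelTrace, cfg: SegmentationConfig | None = None
) -> list[PulseSegment]:
    """Dual-sliding-window threshold detection of compression pulses.

    Parameters
    ----------
    raw, filtered : AccelTrace
        The original trace (window A) and its filter-chain output
        (window B); must have equal length.
    cfg : SegmentationConfig

    Returns
    -------
    list of PulseSegment, disjoint and in temporal order, carrying the
    filtered samples and the estimated static gravity as ``baseline``.
    """
    cfg = cfg or SegmentationConfig()
    if len(raw) != len(filtered):
        raise ValueError("raw and filtered traces must have equal length")
    dt = filtered.sampling_interval
    g = estimate_static_gravity(filtered)
    thr = abs(g) * cfg.alpha_percent / 100.0
    near = 0.5 * thr  # "near baseline" = within alpha/2 percent of gravity

    dev_b = np.abs(filtered.samples - g)
    dev_a = np.abs(raw.samples - g)
    n = len(dev_b)
    segments: list[PulseSegment] = []
    last_end = 0
    i = last_end
    while i < n:
        if dev_b[i] <= thr:
            i += 1
            continue
        # candidate opened at i: cut start = last near-baseline sample in
        # window B before the crossing; fall back to window A when B is flat
        # (no near-baseline sample) inside the window.
        w0 = max(last_end, i - cfg.window_len)
        start = None
        for dev in (dev_b, dev_a):
            below = np.nonzero(dev[w0:i] <= near)[0]
            if below.size:
                start = w0 + int(below[-1])
                break
        if start is None:
            start = w0
        # pulse end: first return to near-baseline after the crossing
        j = i
        while j < n and dev_b[j] > near:
            j += 1
        end = min(j + 1, n)  # include the returning sample
        if end - start >= 2 and _three_restrictions(dev_b, start, end, dt, cfg, thr):
            peak = start + int(np.argmax(dev_b[start:end]))
            segments.append(
                PulseSegment(
                    samples=filtered.samples[start:end].copy(),
                    start_index=start,
                    end_index=end,
                    peak_index=peak,
                    baseline=g,
                )
            )
            last_end = end
        i = max(end, i + 1)
    return segments


def align_and_pad(seg: PulseSegment, L: int) -> NormalizedPulse:
    """Normalize a segment by max-value alignment with zero filling.

    The baseline is subtracted (so the zero fill is meaningful), then the
    sample of maximum absolute deviation (first occurrence on ties) is placed
    at index ``floor(0.75 * L)``; remaining samples are copied around it,
    positions outside the segment are zero and samples falling outside
    ``[0, L)`` are truncated.
    """
    if L < 2:
        raise ValueError("L must be >= 2")
    if seg.baseline is not None:
        base = seg.baseline
    else:
        edge = max(1, min(3, len(seg) // 2))
        base = float(np.median(np.r_[seg.samples[:edge], seg.samples[-edge:]]))
    values = seg.samples - base
    k = int(np.argmax(np.abs(values)))  # first occurrence on ties
    anchor = int(np.floor(0.75 * L))
    out = np.zeros(L)
    lo = max(0, anchor - k)
    hi = min(L, anchor + (len(values) - k))
    out[lo:hi] = values[k - (anchor - lo) : k + (hi - anchor)]
    return NormalizedPulse(out)


def segment_trace(
    raw: AccelTrace,
    fcfg: FilterConfig | None = None,
    scfg: SegmentationConfig | None = None,
) -> list[NormalizedPulse]:
    """Filter, detect and normalize every compression pulse in a trace."""
    scfg = scfg or SegmentationConfig()
    filtered = filter_trace(raw, fcfg)
    return [
        align_and_pad(seg, scfg.effective_points)
        for seg in detect_pulses(raw, filtered, scfg)
    ]


def match_segments(
    segments: list[PulseSegment],
    annotations: Optional[list[PulseAnnotation]],
    min_overlap: float = 0.5,
) -> list[tuple[PulseSegment, Optional[PulseAnnotation]]]:
    """Pair detected segments with ground-truth annotations.

    A segment is matched to the annotation with which it shares the largest
    overlap, provided that overlap covers at least ``min_overlap`` of the
    annotation; unmatched segments pair with ``None``.  Each annotation is
    used at most once.
    """
    annotations = annotations or []
    used: set[int] = set()
    out: list[tuple[PulseSegment, Optional[PulseAnnotation]]] = []
    for seg in segments:
        best, best_ov = None, 0.0
        for idx, ann in enumerate(annotations):
            if idx in used:
                continue
            ov = min(seg.end_index, ann.end_index) - max(seg.start_index, ann.start_index)
            frac = ov / (ann.end_index - ann.start_index)
            if frac > best_ov:
                best, best_ov = idx, frac
        if best is not None and best_ov >= min_overlap:
            used.add(best)
            out.append((seg, annotations[best]))
        else:
            out.append((seg, None))
    return out
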