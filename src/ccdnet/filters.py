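"""Noise-reduction filters for compression accelerometry.

Two filters are applied, in order: a low-pass amplitude-controlled filter
(clip large excursions from a running-median baseline, then a first-order
low-pass recursion) that removes white noise and single-sample "hammering"
spikes, followed by a 1D sliding-window median filter for residual burrs.
Both preserve trace length and sampling interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage, signal

from .simulate import AccelTrace

__all__ = [
    "FilterConfig",
    "lowpass_amplitude_filter",
    "median_filter",
    "filter_trace",
]


@dataclass(frozen=True)
class FilterConfig:
    """Settings for the filter chain.

    Parameters
    ----------
    lowpass_cutoff_hz : float
        -3 dB cutoff of the single-pole low-pass recursion.  Compression
        energy at 100-120/min lies below ~10 Hz including harmonics, so the
        default 15 Hz keeps pulse shape while attenuating broadband noise.
    amplitude_clamp : float or None
        Maximum allowed deviation from the running-median baseline; larger
        excursions are clipped to the clamp boundary.  ``None`` (default)
        resolves per trace to 3x the robust (MAD-based) spread of the
        deviations.
    median_window : int
        Odd sliding-window length for the median filter; default 5 samples
        (25 ms at the 5 ms sampling interval), small enough to keep peaks.
    baseline_window : int
        Odd window (samples) of the running median used as the clipping
        baseline.
    """

    lowpass_cutoff_hz: float = 15.0
    amplitude_clamp: Optional[float] = None
    median_window: int = 5
    baseline_window: int = 51

    def __post_init__(self) -> None:
        if self.lowpass_cutoff_hz <= 0:
            raise ValueError("lowpass_cutoff_hz must be positive")
        if self.amplitude_clamp is not None and self.amplitude_clamp <= 0:
            raise ValueError("amplitude_clamp must be positive")
        for name in ("median_window", "baseline_window"):
            w = getattr(self, name)
            if w < 3 or w % 2 == 0:
                raise ValueError(f"{name} must be odd and >= 3, got {w}")


def _resolve_clamp(deviation: np.ndarray, clamp: Optional[float]) -> float:
    if clamp is not None:
        return clamp
    mad = np.median(np.abs(deviation - np.median(deviation)))
    robust_sd = 1.4826 * mad
    # floor avoids a zero clamp on noise-free signals
    return max(3.0 * robust_sd, 1e-12)


def lowpass_amplitude_filter(trace: AccelTrace, cfg: FilterConfig) -> AccelTrace:
    """Clip excursions from a running baseline, then low-pass smooth.

    The clipping step computes a running median (replicate-padded) as local
    baseline and limits each sample's deviation from it to the clamp value.
    The smoothing step is the causal first-order recursion
    ``y[i] = y[i-1] + beta * (x[i] - y[i-1])`` with
    ``beta = 1 - exp(-2*pi*fc*dt)``, initialised at the first sample so a
    constant signal passes through unchanged (unit DC gain).
    """
    x = trace.samples
    nyquist = 0.5 / trace.sampling_interval
    if cfg.lowpass_cutoff_hz >= nyquist:
        raise ValueError(
            f"cutoff {cfg.lowpass_cutoff_hz} Hz must be below Nyquist {nyquist} Hz"
        )
    if len(x) <= cfg.baseline_window:
        raise ValueError("trace shorter than the filter warm-up (baseline window)")

    baseline = ndimage.median_filter(x, size=cfg.baseline_window, mode="nearest")
    deviation = x - baseline
    clamp = _resolve_clamp(deviation, cfg.amplitude_clamp)
    clipped = baseline + np.clip(deviation, -clamp, clamp)

    beta = 1.0 - np.exp(-2.0 * np.pi * cfg.lowpass_cutoff_hz * trace.sampling_interval)
    zi = signal.lfiltic([beta], [1.0, beta - 1.0], y=[clipped[0]], x=[clipped[0]])
    smoothed, _ = signal.lfilter([beta], [1.0, beta - 1.0], clipped, zi=zi)
    return AccelTrace(smoothed, trace.sampling_interval, trace.annotations)


def median_filter(trace: AccelTrace, window: int) -> AccelTrace:
    """Sliding-window median with replicate (nearest-edge) padding."""
    if window % 2 == 0 or window < 1:
        raise ValueError(f"window must be odd, got {window}")
    if window > len(trace):
        raise ValueError("window longer than trace")
    out = ndimage.median_filter(trace.samples, size=window, mode="nearest")
    return AccelTrace(out, trace.sampling_interval, trace.annotations)


def filter_trace(trace: AccelTrace, cfg: FilterConfig | None = None) -> AccelTrace:
    """Full chain: amplitude-controlled low-pass, then median filter."""
    cfg = cfg or FilterConfig()
    return median_filter(lowpass_amplitude_filter(trace, cfg), cfg.median_window)
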