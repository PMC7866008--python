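# Methods

This note documents the models, the synthetic-data generator and the
numerical choices behind `ccdnet`, and what the test suite does and does
not establish.

## Problem and model

Each chest compression produces one acceleration pulse.  The task is binary
classification of a pulse into *correct depth* (50–60 mm, boundaries
inclusive, class 1) vs *abnormal* (class 0).  A classifier
`Y = F(X | Θ)` maps a fixed-length normalized pulse `X` to posterior class
probabilities through stacked 1D convolution blocks (same padding, stride
1, odd kernels), each followed by ReLU, optional batch normalization, and
length-2 max pooling with floor division, then two hidden dense layers and
a softmax output.  Training minimizes the mean binary cross-entropy
`−(1/N) Σ [ŷ log y + (1−ŷ) log(1−y)]` by mini-batch Adam.

Fixed architectures (hidden dense widths 128/64 throughout):

| name | input | conv channels · kernels | flatten | parameters |
|---|---|---|---|---|
| `lenet5_1d` | 70 | 32·k5, 64·k5 | 64×17 = 1088 | 158,274 |
| `cpcnn4` | 72 | 32·k7, 64·k5, 128·k3 | 128×9 = 1152 | 191,234 (+448 batch-norm) |
| `cpcnn5` | 72 | 32·k11, 64·k7, 128·k5, 196·k3 | 196×4 = 784 | 240,198 (+840) |
| `alexnet_1d` | 72 | 32·k11, 64·k5, 128·k3, 256·k3 | 256×4 = 1024 | ~1.32×10⁶ |

Same padding with floor pooling is the combination that yields the flatten
lengths 1088 (input 70) and 1152 (input 72) above; parameter counts follow
in closed form (conv: `out·(in·k+1)`; dense: `out·(in+1)`; batch-norm:
`2·channels`) and are verified against the materialized networks.
`cpcnn5`'s flatten length of 784 follows necessarily from 196 channels and
four pooling stages; no integer pooled length is compatible with a flatten
of 896, so its parameter total (~2.40×10⁵) is what the architecture
implies, not an external constant.  `alexnet_1d` is a best-effort variant
kept for breadth.

Batch normalization and pooling are applied *after* the activation;
dropout (default 0.5) after the last conv block and the first dense layer
for the CPCNN variants, after the first dense layer only for `lenet5_1d`
(which also omits batch-norm).  The optimizer is Adam with learning rate
1e-3 — an unexceptional default for networks of this size; it is exposed in
`TrainConfig` along with batch size (default 40) and iteration count
(default 300 mini-batch steps).  The network engine (convolution via
im2col + BLAS, explicit backward passes) lives in `ccdnet.nn`; a
finite-difference gradient check in the test suite validates it end to end.

## Synthetic generator

The generator emulates manikin CPR accelerometry under the study
conditions the pipeline assumes.  Defaults, with rationale:

- **Sampling interval** 5 ms.
- **Rate** uniform per cycle in 100–120 compressions/min; the cycle is a
  pulse of duration U(0.44, 0.48) s followed by a quiescent gap filling the
  rest of the 60/rate-second cycle (never below U(0.04, 0.08) s).  Keeping
  the pulse duration roughly constant and letting the gap absorb rate
  variation mirrors how a person compresses faster by pausing less.
- **Pulse template**: a raised-cosine (Hann) deflection of the
  acceleration from the baseline — smooth, unimodal, zero at both ends.
  Real pulse shape is not analytically known; this is the simplest template
  with the right qualitative features, and it admits a closed-form double
  integral (`x(T) = A·T²/4`) used as a test oracle.
- **Amplitude map**: linear in depth, `A = 0.0297 (m/s²)/mm`.  The slope is
  the generator's depth calibration: it was set once so that trapezoidal
  double integration of a detected noise-free default pulse returns the
  true depth in mm (measured ratio 1.008 ± 0.083 over 30 traces), making
  the classifier and the integration baseline operate on a common scale.
- **Gravity baseline** 3.0 m/s² — the quiescent projection of gravity on a
  tilted sensing axis.  Together with the amplitude map this places the
  default α = 25% detection threshold (0.75 m/s²) well below the weakest
  default pulse (A(40 mm) ≈ 1.19 m/s²).
- **Depth mixture**: uniform components on (40, 49.5), (50, 60),
  (60.5, 72) mm with weights ¼/½/¼, covering insufficient, correct and
  excessive compressions; `make_dataset` reweights the mixture to hit a
  requested class fraction exactly.  `SimulatorConfig.separable()` keeps a
  ±2–3 mm margin around the class boundaries, which (noise aside) makes
  the two amplitude bands disjoint — the benchmark used for learning
  sanity checks.
- **Noise**: white Gaussian, sd 0.08 m/s² (pulse-amplitude SNR ≈ 15–27);
  single-sample spikes ("hammering" anomalies) at 3/min with magnitude
  U(3, 8) m/s² and random sign; optional integrated-white-noise drift
  (`drift_sd`, default 0) for experiments on integration error.

Ground truth (pulse boundaries, peak, depth, label) is recorded *before*
noise is added, so segmentation recall is well defined.  All randomness
flows from one seed through one `numpy.random.Generator`.

What the generator does **not** emulate: mattress compliance and sloped
surfaces, multi-axis coupling, leaning (incomplete release), sensor
quantization, and any waveform asymmetry between downstroke and release.
Tests passing on this data show the pipeline's mechanics are correct under
its stated assumptions — not that the trained classifiers transfer to real
manikin or patient recordings.

## Filtering

Order: low-pass amplitude-controlled filter, then median filter.

- The amplitude-controlled step computes a 51-sample (255 ms) running
  median as local baseline and clips deviations beyond a clamp (default:
  3× the MAD-based robust spread of the deviations, per trace).  This
  removes spike anomalies without touching pulse peaks, because the running
  median tracks the pulse itself.
- The low-pass is the causal single-pole recursion
  `y[i] = y[i−1] + β(x[i] − y[i−1])`, `β = 1 − exp(−2π f_c Δt)`, cutoff
  default 15 Hz (compression energy sits below ~10 Hz at 100–120/min).
  Initialization at the first sample gives exact unit DC gain.
- Median window default 5 samples (25 ms), replicate padding — small
  enough to preserve peaks ("small losses").

No default here is forced by theory; all are exposed in `FilterConfig`.

## Segmentation

The detector maintains the raw trace (window A) and the filtered trace
(window B).  The static gravity value g is estimated robustly: the sample
histogram's modal bin anchors the quiescent cluster and the median of
samples within 3 noise-sd of the mode (noise sd from the median absolute
successive difference) is used — a plain median would be biased at the
~85% duty cycle of real compression traces.

A candidate opens when `|filtered − g|` exceeds `α/100 · |g|` (α default
25).  The cut start is the last sample within α/2 of baseline before the
crossing, searched in window B and falling back to window A when B has no
such sample inside the window; the cut end is the first return to within
α/2 of baseline.  Three restrictions then apply: duration within
[0.25, 0.60] s (one compression takes 500–600 ms at 100–120/min, minus the
gap), peak deviation at least the α threshold, and unimodality.
Unimodality is implemented as "exactly one connected region above half the
peak deviation": a noise dimple on one hump does not split it, while a
merged double pulse or large spike remnant does.  (A prominence-based peak
count was tried first and rejected — twin sub-peaks created by a noise
dimple at a rounded top each receive full prominence.)

Because the threshold is a percentage *of the estimated gravity value*,
detection is only approximately invariant under a DC offset of the whole
trace (the offset changes g and hence the threshold); the property test
asserts stability (same pulses, boundaries within a few samples) for
moderate offsets rather than bit-identity.

Max-value alignment places the sample of largest absolute deviation
(first occurrence on ties — deterministic and order-stable) at index
⌊0.75·L⌋, copies the rest of the baseline-subtracted segment around it,
zero-fills uncovered positions and truncates overhang.  L is 70 for
`lenet5_1d` and 72 for the CPCNN variants; both are configuration values
(`effective_points`).

## Evaluation and the integration baseline

Class 1 (correct compression) is positive.  ACC and F-score follow the
standard definitions with the convention F = 0 when TP = 0.  The ROC sweep
runs over descending unique scores; AUC is the trapezoidal integral and
equals the tie-corrected normalized Mann–Whitney U statistic (both checked
against oracles, including `scikit-learn`, in the tests).

`integrate_depth` removes the segment's recorded baseline (or an explicit
one; an unannotated segment defaults to baseline 0 so closed-form inputs
integrate as given), applies the trapezoidal rule twice from rest, and
takes the peak displacement magnitude in mm.  On default simulated data it
recovers depth with ≈ 8% relative spread — duration variation and noise
enter quadratically — which caps its classification accuracy near 0.75–0.85
while the trained cpcnn4 typically reaches 0.85–0.99 on the same splits.

## Problem sizes and reproducibility

The standard conditions are 937 pulses, 471 of them correct, split
680/120/137 (train/test/validation, stratified by label), batch size 40,
300 training iterations.  Unit tests use smaller datasets (200–400 pulses,
30–150 iterations) chosen to exercise the same code paths; the acceptance
script runs the full standard conditions.  Every stochastic component —
simulator, splits, weight initialization, batch order, dropout — draws
from explicit seeds, and a single pipeline seed fans out deterministically
to the stages, so repeated runs are bit-identical.

## Known limitations

- The synthetic pulse template is symmetric and noise is stationary; real
  compression waveforms are asymmetric with non-stationary interference.
- Boundary depths (near 50 and 60 mm) are intrinsically ambiguous under
  the linear amplitude map; test accuracy on the default mixture
  fluctuates by several points across seeds for this reason.
- The detector is a batch algorithm over complete traces; no streaming or
  embedded-latency claims are made.
- `alexnet_1d` is provided for completeness and not tuned.
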