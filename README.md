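# ccdnet — chest-compression-depth quality from accelerometry

During CPR training, each chest compression should reach a depth of roughly
5–6 cm; shallower or deeper compressions are clinically inadequate.  The
traditional way to check this with a wearable accelerometer is to integrate
the acceleration twice and read off the displacement, which is notoriously
sensitive to sensor drift and baseline error.  `ccdnet` implements the
alternative: treat each compression's acceleration waveform as a pattern and
*classify* it as correct-depth vs abnormal with a small 1D convolutional
network, skipping the error-prone displacement calculation entirely.

The package provides the full pipeline for anyone studying
compression-quality feedback algorithms:

1. **Synthetic data** (`ccdnet.simulate`) — labelled compression
   accelerometry: raised-cosine pulses at 100–120 compressions/min on a
   static gravity baseline, amplitude linear in true depth, with white
   noise, optional drift, and "hammering" spike anomalies.
2. **Filtering** (`ccdnet.filters`) — low-pass amplitude-controlled
   filtering (clip excursions from a running-median baseline, then a
   single-pole low-pass) followed by sliding-window median filtering.
3. **Segmentation** (`ccdnet.segment`) — dual-sliding-window threshold
   detection: a pulse candidate opens when the filtered signal deviates
   from the static gravity value g by more than α% of g (default α = 25),
   is cut at near-baseline boundary points, and must pass three
   restrictions (duration, amplitude, unimodality).  Each pulse is
   normalized to a fixed length L by **max-value alignment**: the largest
   sample is pinned at ⌊0.75·L⌋ with zero fill on both sides.
4. **Models** (`ccdnet.models`, `ccdnet.nn`) — 1D CNNs
   `Y = F(X | Θ)` built from declarative specs: `lenet5_1d` (input 70,
   convs 32·k5 / 64·k5, flatten 1088, 158,274 parameters), `cpcnn4`
   (input 72, convs 32·k7 / 64·k5 / 128·k3, flatten 1152, 191,234
   parameters without batch-norm) and the deeper `cpcnn5` and
   `alexnet_1d`.  Convolutions are same-padded with stride 1, each block
   ends in ReLU (+ batch-norm) and length-2 max pooling; training minimizes
   binary cross-entropy with seeded mini-batch Adam (batch size 40).  The
   forward/backward passes are implemented in NumPy inside the package.
5. **Evaluation** (`ccdnet.metrics`) — confusion counts with class 1
   ("correct compression") positive, ACC = (TP+TN)/(TP+TN+FP+FN),
   F-score = 2PR/(P+R), ROC/AUC by threshold sweep, and the
   double-integration depth baseline.

## Worked example

```python
from ccdnet import (SimulatorConfig, make_dataset, stratified_split,
                    CompressionQualityCNN)

data = make_dataset(937, 471 / 937, SimulatorConfig(seed=1), pulse_length=72)
train, test, val = stratified_split(data, 680, 120, seed=2)   # 471 correct
res = CompressionQualityCNN(train, arch="cpcnn4", val_data=val).fit(
    iterations=300, batch_size=40, seed=0)
print(res.summary(eval_data=test))
```

prints:

```
Compression-depth quality classifier
====================================================
Architecture:               cpcnn4
Input length:               72
Conv blocks:                32@k7, 64@k5, 128@k3
Flatten length:             1152
Trainable parameters:       191,682 (closed form 191,682)
Iterations x batch:         300 x 40
Final training loss:        0.1233
Final training ACC:         0.9412
Final validation ACC:       0.9708
----------------------------------------------------
Test ACC:                   0.9250
Test F-score:               0.9231
Test AUC:                   0.9906
```

Test accuracy around 0.90–0.99 (seed-dependent) with AUC near 1 is
expected: the remaining errors sit at depths near the 50/60 mm class
boundaries, where the waveforms of the two classes are nearly identical.
The double-integration baseline on the same test segments scores roughly
0.75–0.85 because pulse-duration variation and noise enter the depth
estimate quadratically — exactly the weakness the classifier avoids.
(The parameter count shown includes batch-norm scales/shifts; without
batch-norm cpcnn4 has 191,234 trainable scalars.)

The same pipeline is scriptable from the shell:

```bash
ccdnet simulate --duration 60 --seed 1 --out trace.csv
ccdnet filter   --in trace.csv --out filtered.csv
ccdnet segment  --in trace.csv --length 72 --out pulses.csv
ccdnet run      --arch cpcnn4 --iterations 300 --seed 1 --report report.json
ccdnet count-params cpcnn4
```

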