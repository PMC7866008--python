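"""File formats: delimited traces, annotation sidecars, datasets, checkpoints.

Traces travel as two-column delimited text (time in seconds, acceleration),
with an optional header line that is auto-detected and skipped.  Annotations
use a five-column sidecar (start, end, peak, depth_mm, label; 0-based,
half-open).  Normalized-pulse datasets are stored in a single HDF5 file
(N x L matrix plus labels and depths); model checkpoints in a NumPy ``.npz``
archive with the architecture spec embedded as JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional

import h5py
import numpy as np

from .models import ArchitectureSpec, ConvBlock, ModelState
from .simulate import AccelTrace, PulseAnnotation

__all__ = [
    "ParseError",
    "read_trace",
    "write_trace",
    "read_annotations",
    "write_annotations",
    "save_dataset",
    "load_dataset",
    "save_checkpoint",
    "load_checkpoint",
]


class ParseError(ValueError):
    """Malformed delimited input; carries the offending line number."""


def _split(line: str) -> list[str]:
    line = line.strip()
    for sep in (",", "\t", ";"):
        if sep in line:
            return [f.strip() for f in line.split(sep)]
    return line.split()


def read_trace(path, annotations: Optional[str | Path] = "auto") -> AccelTrace:
    """Read a two-column (time_s, accel) delimited text trace.

    A non-numeric first row is treated as a header and skipped.  The
    sampling interval is taken from the first two time stamps.  When
    ``annotations`` is ``"auto"`` a sidecar named ``<path>.ann`` is loaded
    if present.
    """
    path = Path(path)
    times: list[float] = []
    values: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = _split(line)
            if len(fields) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns, got {len(fields)}")
            try:
                t, v = float(fields[0]), float(fields[1])
            except ValueError:
                if lineno == 1:  # header row
                    continue
                raise ParseError(f"{path}:{lineno}: non-numeric value") from None
            times.append(t)
            values.append(v)
    if len(values) < 1:
        raise ParseError(f"{path}: no data rows")
    dt = times[1] - times[0] if len(times) > 1 else 1.0
    if dt <= 0:
        raise ParseError(f"{path}: non-increasing time stamps")
    ann = None
    if annotations == "auto":
        side = path.with_suffix(path.suffix + ".ann")
        ann = read_annotations(side) if side.exists() else None
    elif annotations is not None:
        ann = read_annotations(annotations)
    return AccelTrace(np.asarray(values), dt, ann)


def write_trace(trace: AccelTrace, path, write_annotations_sidecar: bool = True) -> None:
    """Write a trace as delimited text, full float precision, plus sidecar."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("time_s,accel\n")
        for i, v in enumerate(trace.samples):
            fh.write(f"{i * trace.sampling_interval:.6f},{float(v)!r}\n")
    if write_annotations_sidecar and trace.annotations:
        write_annotations(trace.annotations, path.with_suffix(path.suffix + ".ann"))


def read_annotations(path) -> list[PulseAnnotation]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("start"):
                continue
            f = _split(line)
            if len(f) != 5:
                raise ParseError(f"{path}:{lineno}: expected 5 columns")
            out.append(
                PulseAnnotation(int(f[0]), int(f[1]), int(f[2]), float(f[3]), int(f[4]))
            )
    return out


def write_annotations(annotations: list[PulseAnnotation], path) -> None:
    with open(path, "w") as fh:
        fh.write("start,end,peak,depth_mm,label\n")
        for a in annotations:
            fh.write(
                f"{a.start_index},{a.end_index},{a.peak_index},{float(a.depth_mm)!r},{a.label}\n"
            )


def save_dataset(dataset, path) -> None:
    """Store a pulse dataset (X, y, depth_mm) in one HDF5 file."""
    with h5py.File(path, "w") as h5:
        h5.create_dataset("X", data=np.asarray(dataset.X, dtype=float))
        h5.create_dataset("y", data=np.asarray(dataset.y, dtype=np.int8))
        h5.create_dataset("depth_mm", data=np.asarray(dataset.depth_mm, dtype=float))
        h5.attrs["sampling_interval"] = float(dataset.sampling_interval)


def load_dataset(path):
    from .pipeline import PulseDataset

    with h5py.File(path, "r") as h5:
        return PulseDataset(
            X=h5["X"][...],
            y=h5["y"][...].astype(int),
            depth_mm=h5["depth_mm"][...],
            segments=None,
            sampling_interval=float(h5.attrs["sampling_interval"]),
        )


def save_checkpoint(model: ModelState, path) -> None:
    spec_json = json.dumps(dataclasses.asdict(model.spec))
    np.savez(path, __spec__=np.bytes_(spec_json), **model.state_dict())


def load_checkpoint(path) -> ModelState:
    with np.load(path) as data:
        raw = json.loads(data["__spec__"].item().decode())
        raw["conv_blocks"] = tuple(ConvBlock(**blk) for blk in raw["conv_blocks"])
        raw["fc_widths"] = tuple(raw["fc_widths"])
        spec = ArchitectureSpec(**raw)
        model = ModelState(spec)
        model.load_state_dict({k: data[k] for k in data.files if k != "__spec__"})
    return model
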