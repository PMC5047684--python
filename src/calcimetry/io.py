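"""File I/O: line-scan TIFFs with JSON sidecars, trace CSVs, truth JSON.

Line-scan images travel as single-channel 32-bit float TIFF, axis order
(space, time), beside a ``<name>.json`` sidecar carrying pixel_size_um,
line_rate_hz, seed and, for simulated data, the planted ground truth.
Traces are two-column CSV with header ``time_s,value`` (fluorescence) or
``time_s,voltage_uv`` (field potentials).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile

from .sparks import LineScanImage
from .leakload import FluorescenceTrace, PhaseSegmentation
from .fieldpotential import FPTrace

__all__ = [
    "write_linescan", "read_linescan",
    "write_trace", "read_fluorescence_trace", "read_fp_trace",
    "write_json", "read_json",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, sort_keys=True, indent=2,
                                     default=_np_default))


def _np_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())


def write_linescan(path, img: LineScanImage, truth: Optional[dict] = None,
                   seed: Optional[int] = None) -> None:
    """Write a line-scan TIFF and its calibration/truth sidecar."""
    path = Path(path)
    tifffile.imwrite(path, img.values.astype(np.float32))
    meta = {"pixel_size_um": img.pixel_size_um,
            "line_rate_hz": img.line_rate_hz,
            "axes": "space,time"}
    if seed is not None:
        meta["seed"] = seed
    if truth is not None:
        meta["truth"] = truth
    write_json(_sidecar(path), meta)


def read_linescan(path, pixel_size_um: Optional[float] = None,
                  line_rate_hz: Optional[float] = None
                  ) -> tuple[LineScanImage, dict]:
    """Read a line-scan TIFF; calibrations from the sidecar unless given."""
    path = Path(path)
    values = tifffile.imread(path)
    meta: dict = {}
    if _sidecar(path).exists():
        meta = read_json(_sidecar(path))
    px = pixel_size_um if pixel_size_um is not None else meta.get("pixel_size_um")
    lr = line_rate_hz if line_rate_hz is not None else meta.get("line_rate_hz")
    if px is None or lr is None:
        raise ValueError("pixel size / line rate not in sidecar; pass them "
                         "explicitly")
    return LineScanImage(values=values, pixel_size_um=float(px),
                         line_rate_hz=float(lr)), meta


def write_trace(path, time_s, value, value_column: str = "value") -> None:
    pd.DataFrame({"time_s": np.asarray(time_s),
                  value_column: np.asarray(value)}).to_csv(path, index=False)


def read_fluorescence_trace(path) -> FluorescenceTrace:
    df = pd.read_csv(path)
    col = "value" if "value" in df.columns else df.columns[1]
    return FluorescenceTrace(time_s=df["time_s"].to_numpy(),
                             value=df[col].to_numpy())


def read_fp_trace(path, sampling_hz: Optional[float] = None) -> FPTrace:
    df = pd.read_csv(path)
    col = "voltage_uv" if "voltage_uv" in df.columns else df.columns[1]
    t = df["time_s"].to_numpy()
    if sampling_hz is None:
        sampling_hz = 1.0 / float(np.median(np.diff(t)))
    return FPTrace(time_s=t, voltage=df[col].to_numpy(),
                   sampling_hz=sampling_hz)
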