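"""File interchange: multi-page TIFF + JSON sidecars, CSV pressure traces.

Volumes and image sequences travel as multi-page TIFF with a JSON sidecar
carrying the physical metadata (voxel size, frame rate, angles, timestamps,
i0); pressure traces as two-column CSV whose header rows carry the sampling
rate and chamber configuration; metric tables and reports as tidy CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .gating import ProjectionSet
from .wbp import ChamberConfig, PressureTrace
from .xlf import RadiographSequence


def _sidecar(path) -> Path:
    p = Path(path)
    return p.with_suffix(p.suffix + ".json")


def write_volume(path, voxels: np.ndarray, voxel_size: float, **meta) -> None:
    tifffile.imwrite(path, np.asarray(voxels, dtype=np.float32), photometric="minisblack")
    _sidecar(path).write_text(json.dumps({"voxel_size_mm": voxel_size, **meta}))


def read_volume(path) -> tuple[np.ndarray, dict]:
    meta = json.loads(_sidecar(path).read_text())
    return tifffile.imread(path).astype(float), meta


def write_radiographs(path, seq: RadiographSequence) -> None:
    tifffile.imwrite(path, seq.frames.astype(np.float32), photometric="minisblack")
    _sidecar(path).write_text(json.dumps({
        "frame_rate_hz": seq.frame_rate,
        "timestamps_s": seq.timestamps.tolist(),
    }))


def read_radiographs(path) -> RadiographSequence:
    meta = json.loads(_sidecar(path).read_text())
    return RadiographSequence(frames=tifffile.imread(path).astype(float),
                              frame_rate=meta["frame_rate_hz"],
                              timestamps=np.asarray(meta["timestamps_s"]))


def write_projections(path, projset: ProjectionSet) -> None:
    tifffile.imwrite(path, projset.frames.astype(np.float32), photometric="minisblack")
    _sidecar(path).write_text(json.dumps({
        "angles_deg": projset.angles.tolist(),
        "timestamps_s": projset.timestamps.tolist(),
        "pixel_mm": projset.pixel,
        "i0": projset.i0,
    }))


def read_projections(path) -> ProjectionSet:
    meta = json.loads(_sidecar(path).read_text())
    return ProjectionSet(frames=tifffile.imread(path).astype(float),
                         angles=np.asarray(meta["angles_deg"]),
                         timestamps=np.asarray(meta["timestamps_s"]),
                         pixel=meta["pixel_mm"], i0=meta["i0"])


def write_pressure_trace(path, trace: PressureTrace) -> None:
    """Two-column CSV (time_s, pressure) with '#'-prefixed metadata header."""
    ch = trace.chamber
    header = "\n".join([
        f"# sampling_rate_hz={trace.sampling_rate}",
        f"# calibration_ml_per_unit={ch.calibration}",
        f"# recording_volume_ml={ch.recording_volume_ml}",
        f"# reference_volume_ml={ch.reference_volume_ml}",
        f"# temperature_c={ch.temperature_c}",
        f"# humidity_pct={ch.humidity_pct}",
        "time_s,pressure",
    ])
    body = "\n".join(f"{t:.6f},{p:.8g}" for t, p in zip(trace.t, trace.p))
    Path(path).write_text(header + "\n" + body + "\n")


def read_pressure_trace(path) -> PressureTrace:
    meta = {}
    lines = Path(path).read_text().splitlines()
    n_header = 0
    for line in lines:
        if not line.startswith("#"):
            break
        n_header += 1
        key, val = line[1:].split("=", 1)
        meta[key.strip()] = float(val)
    df = pd.read_csv(path, skiprows=n_header)
    chamber = ChamberConfig(
        recording_volume_ml=meta.get("recording_volume_ml", 220.0),
        reference_volume_ml=meta.get("reference_volume_ml", 50.0),
        calibration=meta.get("calibration_ml_per_unit", 1.0),
        temperature_c=meta.get("temperature_c", 22.0),
        humidity_pct=meta.get("humidity_pct", 45.0),
    )
    return PressureTrace(t=df.time_s.to_numpy(), p=df.pressure.to_numpy(),
                         sampling_rate=meta["sampling_rate_hz"],
                         chamber=chamber)
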