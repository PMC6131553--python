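"""Readers and writers for the portable on-disk formats.

Velocity-field stacks go to an ``.npz`` array container with a JSON
sidecar carrying the physical metadata (grid spacing in µm, frame
interval in min); tracks, angle samples, inheritance counts and nuclear
series are plain CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .flow import VelocityField
from .tracks import DirectionSample, TrackSet

__all__ = [
    "write_flow_stack",
    "read_flow_stack",
    "write_tracks_csv",
    "read_tracks_csv",
    "write_angles_csv",
    "read_angles_csv",
    "write_inheritance_csv",
    "read_inheritance_csv",
    "write_speed_tiff",
]


def write_flow_stack(path, fields: list[VelocityField]) -> Path:
    """Write a stack of velocity fields to ``path``.npz + ``path``.json."""
    path = Path(path).with_suffix("")
    arrays = {}
    for k, f in enumerate(fields):
        arrays[f"u{k}"] = f.u
        arrays[f"v{k}"] = f.v
        arrays[f"mask{k}"] = f.mask
    np.savez_compressed(path.with_suffix(".npz"), **arrays)
    meta = {
        "n_frames": len(fields),
        "window_spacing_um": fields[0].window_spacing,
        "frame_interval_min": fields[0].frame_interval,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))
    return path.with_suffix(".npz")


def read_flow_stack(path) -> list[VelocityField]:
    path = Path(path).with_suffix("")
    meta = json.loads(path.with_suffix(".json").read_text())
    with np.load(path.with_suffix(".npz")) as data:
        return [
            VelocityField(
                u=data[f"u{k}"],
                v=data[f"v{k}"],
                mask=data[f"mask{k}"],
                window_spacing=meta["window_spacing_um"],
                frame_interval=meta["frame_interval_min"],
            )
            for k in range(meta["n_frames"])
        ]


def write_tracks_csv(path, tracks: TrackSet) -> Path:
    path = Path(path)
    tracks.data.to_csv(path, index=False)
    return path


def read_tracks_csv(path, frame_interval: float | None = None) -> TrackSet:
    """Load a track table; the frame interval is inferred from the t_min
    column unless given explicitly."""
    df = pd.read_csv(path)
    if frame_interval is None:
        one = df[df["track_id"] == df["track_id"].iloc[0]].sort_values("frame")
        dt = np.diff(one["t_min"].to_numpy())
        frame_interval = float(dt[0]) if len(dt) else 1.0
    return TrackSet(data=df, frame_interval=frame_interval)


def write_angles_csv(path, sample: DirectionSample) -> Path:
    path = Path(path)
    pd.DataFrame({"angle_deg": sample.angles_deg}).to_csv(path, index=False)
    return path


def read_angles_csv(path, axial: bool = False) -> DirectionSample:
    df = pd.read_csv(path)
    return DirectionSample(angles_deg=df["angle_deg"].to_numpy(), axial=axial)


def write_inheritance_csv(path, counts: pd.DataFrame) -> Path:
    path = Path(path)
    counts[["division_id", "count1", "count2"]].to_csv(path, index=False)
    return path


def read_inheritance_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_sim_summary(path, summary) -> Path:
    """Write a simulation summary as CSV (t, mean_speed, iop) plus a JSON
    manifest of all model parameters and the seed."""
    from dataclasses import asdict

    path = Path(path).with_suffix("")
    pd.DataFrame(
        {"t": summary.times, "mean_speed": summary.mean_speed, "iop": summary.iop}
    ).to_csv(path.with_suffix(".csv"), index=False)
    manifest = {
        "params": asdict(summary.params),
        "seed": summary.seed,
        "steady_speed": summary.steady_speed,
        "steady_iop": summary.steady_iop,
    }
    path.with_suffix(".json").write_text(json.dumps(manifest, indent=1))
    return path.with_suffix(".csv")


def write_speed_tiff(path, fields: list[VelocityField]) -> Path:
    """Optional multi-page TIFF export of the speed maps."""
    import tifffile

    path = Path(path)
    stack = np.stack([f.magnitude.astype(np.float32) for f in fields])
    tifffile.imwrite(path, stack)
    return path
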