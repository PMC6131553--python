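"""Track-level motility and polarity statistics.

Works on tracking-output tables (one row per nucleus per frame), angle
samples of cell-division or nucleus-to-Golgi directions, and nuclear /
membrane coordinate series around mitosis entry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TrackSet",
    "DirectionSample",
    "OrderStats",
    "fixed_lag_msd",
    "mpi_series",
    "track_motility_summary",
    "direction_order_stats",
    "rose_histogram",
    "relative_nuclear_position",
]

TRACK_COLUMNS = ["track_id", "frame", "t_min", "x_um", "y_um"]


@dataclass
class TrackSet:
    """Tracking output: per-cell time-ordered coordinates.

    ``data`` holds columns track_id, frame, t_min, x_um, y_um; frames
    within a track must be strictly increasing with no gaps (gap closing
    with max frame gap 0 upstream).
    """

    data: pd.DataFrame
    frame_interval: float  # min

    def __post_init__(self):
        missing = [c for c in TRACK_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"track table lacks columns {missing}")
        if not np.all(np.isfinite(self.data[["x_um", "y_um"]].to_numpy())):
            raise ValueError("track coordinates must be finite")
        for tid, grp in self.data.groupby("track_id"):
            frames = grp["frame"].to_numpy()
            if len(frames) > 1 and not np.all(np.diff(frames) == 1):
                raise ValueError(f"track {tid}: frames not contiguous")

    def __len__(self) -> int:
        return self.data["track_id"].nunique()


@dataclass
class DirectionSample:
    """Angles (degrees) of directed events such as cell divisions.

    ``axial=True`` treats theta and theta+180 deg as the same orientation.
    """

    angles_deg: np.ndarray
    axial: bool = False

    def __post_init__(self):
        self.angles_deg = np.mod(np.asarray(self.angles_deg, dtype=float), 360.0)
        if self.angles_deg.size < 1:
            raise ValueError("need at least one angle")


@dataclass
class OrderStats:
    """Resultant of unit vectors: component means, magnitude, mean angle."""

    mean_x: float
    mean_y: float
    magnitude: float
    mean_angle_deg: float  # NaN when the magnitude vanishes


def fixed_lag_msd(tracks: TrackSet, lag: float, min_spots: int = 19) -> pd.DataFrame:
    """Mean square displacement at a fixed time lag, per time point.

    For each time t, averages |r(t+lag) - r(t)|^2 over tracks that span
    both times; tracks shorter than ``min_spots`` frames are discarded,
    and a track ending within ``lag`` of t does not contribute at t.
    ``lag`` is in minutes and must be a whole number of frames.

    Returns a frame-indexed table with columns t_min, msd_um2 (NaN where
    no track is eligible) and n_tracks.
    """
    lag_frames = lag / tracks.frame_interval
    if abs(lag_frames - round(lag_frames)) > 1e-6:
        raise ValueError("lag must be a whole multiple of the frame interval")
    lag_frames = int(round(lag_frames))
    if lag_frames < 1:
        raise ValueError("lag must be positive")

    df = tracks.data
    fmin, fmax = int(df["frame"].min()), int(df["frame"].max())
    frames = np.arange(fmin, fmax - lag_frames + 1)
    total = np.zeros(len(frames))
    count = np.zeros(len(frames), dtype=int)
    for _, grp in df.groupby("track_id"):
        if len(grp) < min_spots:
            continue
        g = grp.sort_values("frame")
        f = g["frame"].to_numpy()
        xy = g[["x_um", "y_um"]].to_numpy()
        if len(f) <= lag_frames:
            continue
        sq = ((xy[lag_frames:] - xy[:-lag_frames]) ** 2).sum(axis=1)
        idx = f[:-lag_frames] - fmin
        total[idx] += sq
        count[idx] += 1
    with np.errstate(invalid="ignore"):
        msd = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return pd.DataFrame(
        {
            "frame": frames,
            "t_min": frames * tracks.frame_interval,
            "msd_um2": msd,
            "n_tracks": count,
        }
    )


def mpi_series(track_xy: np.ndarray, window: int = 10) -> np.ndarray:
    """Migration persistency index over a running window.

    ``track_xy`` is the (T, 2) coordinate series of one track.  Each
    window of ``window`` successive frames contributes the magnitude of
    the mean of its displacement unit vectors (an MPI of 1 means
    straight-line motion, ~0 random turning).  Zero-length displacements
    have no direction and are skipped; windows with fewer than 2 usable
    displacements yield NaN.
    """
    track_xy = np.asarray(track_xy, dtype=float)
    if track_xy.ndim != 2 or track_xy.shape[1] != 2:
        raise ValueError("track must be a (T, 2) coordinate array")
    if len(track_xy) < window:
        raise ValueError("track shorter than the window")
    steps = np.diff(track_xy, axis=0)
    norms = np.hypot(steps[:, 0], steps[:, 1])
    ok = norms > 0.0
    units = np.zeros_like(steps)
    units[ok] = steps[ok] / norms[ok, None]

    per_win = window - 1  # displacements per window of `window` frames
    out = np.full(len(track_xy) - window + 1, np.nan)
    for s in range(len(out)):
        sel = ok[s : s + per_win]
        if sel.sum() < 2:
            continue
        mean = units[s : s + per_win][sel].mean(axis=0)
        out[s] = np.hypot(mean[0], mean[1])
    return out


def track_motility_summary(tracks: TrackSet) -> pd.DataFrame:
    """Per-track mean velocity (µm/h, total path / elapsed time) and
    Euclidean (straight-line start-to-end) distance (µm).

    Single-point tracks carry no motion information and are excluded.
    """
    rows = []
    for tid, grp in tracks.data.groupby("track_id"):
        g = grp.sort_values("frame")
        if len(g) < 2:
            continue
        xy = g[["x_um", "y_um"]].to_numpy()
        t = g["t_min"].to_numpy()
        steps = np.diff(xy, axis=0)
        path = np.hypot(steps[:, 0], steps[:, 1]).sum()
        elapsed_h = (t[-1] - t[0]) / 60.0
        rows.append(
            {
                "track_id": tid,
                "mean_velocity_um_h": path / elapsed_h,
                "euclidean_um": float(np.hypot(*(xy[-1] - xy[0]))),
            }
        )
    return pd.DataFrame(rows, columns=["track_id", "mean_velocity_um_h", "euclidean_um"])


def direction_order_stats(sample: DirectionSample) -> OrderStats:
    """Resultant-vector statistics of directed angles.

    Each angle theta_n becomes a unit vector (cos theta, sin theta); the
    component means <x>, <y> give the magnitude sqrt(<x>^2+<y>^2) (1 =
    perfectly common direction, 0 = none) and the mean angle through the
    quadrant-correct two-argument arctangent.  In axial mode angles are
    doubled before averaging and the mean angle halved after, so theta
    and theta+180 deg are equivalent.
    """
    theta = np.radians(sample.angles_deg)
    if sample.axial:
        theta = 2.0 * theta
    mx = float(np.cos(theta).mean())
    my = float(np.sin(theta).mean())
    mag = float(np.hypot(mx, my))
    if mag < 1e-12:
        ang = float("nan")
    else:
        ang = np.degrees(np.arctan2(my, mx))
        if sample.axial:
            ang /= 2.0
        ang = float(np.mod(ang, 360.0 if not sample.axial else 180.0))
    return OrderStats(mean_x=mx, mean_y=my, magnitude=mag, mean_angle_deg=ang)


def rose_histogram(sample: DirectionSample, n_bins: int) -> tuple[np.ndarray, np.ndarray]:
    """Unity-based (min-max) normalized angular histogram.

    Returns (bin_edges_deg, heights) with heights rescaled so the least
    occupied bin is 0 and the fullest is 1; if every bin is equally
    occupied the heights are all 0 by convention.
    """
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    edges = np.linspace(0.0, 360.0, n_bins + 1)
    counts, _ = np.histogram(sample.angles_deg, bins=edges)
    span = counts.max() - counts.min()
    if span == 0:
        return edges, np.zeros(n_bins)
    heights = (counts - counts.min()) / span
    return edges, heights


def relative_nuclear_position(
    series: pd.DataFrame, frame_interval: float = 2.0, tol: float = 1e-9
) -> pd.DataFrame:
    """Relative nuclear position p = |c - x| / |y - x| per frame.

    ``series`` has columns frame, cx, cy (nucleus centre), xx, xy (the
    membrane point nearest the nucleus) and yx, yy (the opposite membrane
    point).  p is 0 with the nucleus at the near membrane, 0.5 at the cell
    midpoint and 1 at the far membrane.  Time is reported relative to the
    last frame (mitosis entry at t = 0, earlier frames negative, matching
    the reversed-traversal convention of the measurement).  Frames with
    coincident membrane points are marked invalid (NaN).
    """
    needed = ["frame", "cx", "cy", "xx", "xy", "yx", "yy"]
    missing = [c for c in needed if c not in series.columns]
    if missing:
        raise ValueError(f"nuclear series lacks columns {missing}")
    s = series.sort_values("frame")
    c = s[["cx", "cy"]].to_numpy()
    x = s[["xx", "xy"]].to_numpy()
    y = s[["yx", "yy"]].to_numpy()
    span = np.hypot(*(y - x).T)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(span > tol, np.hypot(*(c - x).T) / span, np.nan)
    frames = s["frame"].to_numpy()
    return pd.DataFrame(
        {
            "frame": frames,
            "t_min": (frames - frames[-1]) * frame_interval,
            "p": p,
        }
    )
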