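"""Synthetic inputs with controlled statistical structure.

Generates every input class the analysis consumes — gridded velocity
fields, Vicsek particle flows, cell tracks, division-angle samples,
organelle-inheritance counts and pre-mitotic nuclear series — so each
downstream statistic can be exercised with known ground truth.  Every
generator is a pure function of its spec, including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .flow import VelocityField
from .tracks import DirectionSample, TrackSet

__all__ = [
    "FlowSpec",
    "TrackSpec",
    "PartitionSpec",
    "gen_gridded_flow",
    "gen_vicsek_particles",
    "gen_tracks",
    "gen_division_angles",
    "gen_inheritance_counts",
    "gen_premitotic_track",
]

TRACK_KINDS = ("ballistic", "persistent", "brownian", "alternating", "stationary")


@dataclass(frozen=True)
class FlowSpec:
    """Recipe for a smoothly varying synthetic velocity-field stack.

    A white Gaussian angle field around ``base_angle`` is smoothed over
    ``correlation_scale`` grid windows (on the Cartesian components of
    the unit headings, avoiding angle wrap-around artefacts) and carries
    a deterministic magnitude ``speed_mean``.
    """

    grid_shape: tuple = (64, 64)       # rows x cols, PIV windows
    base_angle: float = 0.0            # degrees
    angular_noise_sd: float = 30.0     # degrees
    correlation_scale: float = 2.0     # windows
    speed_mean: float = 20.0           # µm/h
    n_frames: int = 1
    window_spacing: float = 90.0       # µm between adjacent windows
    frame_interval: float = 12.0       # min
    seed: int = 0

    def __post_init__(self):
        r, c = self.grid_shape
        if r < 1 or c < 1:
            raise ValueError("grid_shape must be positive")
        if self.angular_noise_sd < 0:
            raise ValueError("angular_noise_sd must be non-negative")
        if self.correlation_scale < 0:
            raise ValueError("correlation_scale must be non-negative")
        if self.n_frames < 1:
            raise ValueError("n_frames must be at least 1")


@dataclass(frozen=True)
class TrackSpec:
    """Recipe for synthetic cell tracks of a given motion class."""

    kind: str = "persistent"
    n_tracks: int = 20
    n_frames: int = 40
    frame_interval: float = 8.0   # min
    speed: float = 20.0           # µm/h
    persistence: float = 0.5      # 0 = diffusive turning, 1 = straight
    field_size: float = 1000.0    # µm, extent of random start positions
    seed: int = 0

    def __post_init__(self):
        if self.kind not in TRACK_KINDS:
            raise ValueError(f"unknown track kind {self.kind!r}; one of {TRACK_KINDS}")
        if self.n_frames < 2:
            raise ValueError("tracks need at least 2 frames")
        if not 0.0 <= self.persistence <= 1.0:
            raise ValueError("persistence must lie in [0, 1]")


@dataclass(frozen=True)
class PartitionSpec:
    """Recipe for daughter-pair organelle counts.

    ``body_count_law`` is an explicit probability table over per-division
    body totals (default uniform over 1..6 — a placeholder, since the
    empirical count distribution is not published); each body goes to
    daughter 1 independently with probability ``p_sym``.
    """

    n_divisions: int = 100
    body_count_law: tuple = tuple((n, 1.0 / 6.0) for n in range(1, 7))
    p_sym: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_divisions < 1:
            raise ValueError("need at least one division")
        law = dict(self.body_count_law)
        if not law:
            raise ValueError("body_count_law must be non-empty")
        probs = np.array(list(law.values()))
        if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("body_count_law probabilities must be >=0 and sum to 1")
        if not 0.0 < self.p_sym < 1.0:
            raise ValueError("p_sym must lie strictly between 0 and 1")


def gen_gridded_flow(spec: FlowSpec) -> list[VelocityField]:
    """Velocity-field stack with tunable spatial order.

    Per frame: headings are drawn as base_angle + N(0, angular_noise_sd)
    per window, converted to unit vectors, smoothed with an isotropic
    Gaussian of width ``correlation_scale`` (periodic boundaries),
    re-normalised and scaled to the deterministic magnitude
    ``speed_mean``.  The mask is all-valid.
    """
    rng = np.random.default_rng(spec.seed)
    fields = []
    for _ in range(spec.n_frames):
        ang = np.radians(
            spec.base_angle
            + rng.normal(0.0, spec.angular_noise_sd, size=spec.grid_shape)
        )
        u, v = np.cos(ang), np.sin(ang)
        if spec.correlation_scale > 0:
            u = gaussian_filter(u, spec.correlation_scale, mode="wrap")
            v = gaussian_filter(v, spec.correlation_scale, mode="wrap")
        norm = np.hypot(u, v)
        # fully cancelling headings have no direction; keep the base angle
        tiny = norm < 1e-12
        if np.any(tiny):
            u[tiny], v[tiny] = np.cos(np.radians(spec.base_angle)), np.sin(
                np.radians(spec.base_angle)
            )
            norm[tiny] = 1.0
        fields.append(
            VelocityField(
                u=spec.speed_mean * u / norm,
                v=spec.speed_mean * v / norm,
                window_spacing=spec.window_spacing,
                frame_interval=spec.frame_interval,
            )
        )
    return fields


def gen_vicsek_particles(
    n: int,
    box: float,
    speed: float,
    radius: float,
    noise_width: float,
    n_steps: int,
    seed: int = 0,
    grid_shape: tuple = (16, 16),
) -> list[VelocityField]:
    """Classic point-Vicsek flock, rasterised to a velocity grid.

    Each step every particle adopts the circular mean heading of all
    particles within ``radius`` (itself included), plus uniform angular
    noise in [-noise_width/2, +noise_width/2] degrees, then moves
    ``speed`` along its heading (periodic box).  Per frame the particle
    velocities are averaged into ``grid_shape`` bins; empty bins are
    masked.  An order-tunable flow source: zero noise with global
    coupling flocks completely, radius 0 decouples every particle.
    """
    if n < 1:
        raise ValueError("need at least one particle")
    if box <= 0:
        raise ValueError("box must be positive")
    if radius < 0:
        raise ValueError("radius must be non-negative")
    rng = np.random.default_rng(seed)
    pos = rng.uniform(0.0, box, size=(n, 2))
    theta = rng.uniform(-np.pi, np.pi, size=n)
    half_noise = np.radians(noise_width) / 2.0

    frames = []
    for _ in range(n_steps):
        # neighbour average of headings (vectorial circular mean)
        delta = pos[None, :, :] - pos[:, None, :]
        delta -= box * np.round(delta / box)
        within = (delta**2).sum(axis=2) <= radius**2  # includes self
        cs = within @ np.cos(theta)
        sn = within @ np.sin(theta)
        theta = np.arctan2(sn, cs)
        if half_noise > 0:
            theta = theta + rng.uniform(-half_noise, half_noise, size=n)
        vel = speed * np.stack([np.cos(theta), np.sin(theta)], axis=1)
        pos = np.mod(pos + vel, box)

        rows, cols = grid_shape
        iy = np.minimum((pos[:, 1] / box * rows).astype(int), rows - 1)
        ix = np.minimum((pos[:, 0] / box * cols).astype(int), cols - 1)
        flat = iy * cols + ix
        cnt = np.bincount(flat, minlength=rows * cols)
        u = np.bincount(flat, weights=vel[:, 0], minlength=rows * cols)
        v = np.bincount(flat, weights=vel[:, 1], minlength=rows * cols)
        occupied = cnt > 0
        u = np.where(occupied, u / np.maximum(cnt, 1), 0.0).reshape(rows, cols)
        v = np.where(occupied, v / np.maximum(cnt, 1), 0.0).reshape(rows, cols)
        frames.append(
            VelocityField(u=u, v=v, mask=occupied.reshape(rows, cols),
                          window_spacing=box / cols)
        )
    return frames


def _headings(spec: TrackSpec, rng: np.random.Generator) -> np.ndarray:
    """Per-step heading angles (radians) for one track of spec.kind."""
    n_steps = spec.n_frames - 1
    start = rng.uniform(-np.pi, np.pi)
    if spec.kind == "ballistic":
        return np.full(n_steps, start)
    if spec.kind == "brownian":
        return rng.uniform(-np.pi, np.pi, size=n_steps)
    if spec.kind == "alternating":
        return start + np.pi * (np.arange(n_steps) % 2)
    if spec.kind == "persistent":
        # wrapped-normal turning, SD = (1 - persistence) * 180 degrees
        sd = np.radians((1.0 - spec.persistence) * 180.0)
        return start + np.cumsum(
            np.concatenate([[0.0], rng.normal(0.0, sd, size=n_steps - 1)])
        )
    return np.full(n_steps, 0.0)  # stationary: unused


def gen_tracks(spec: TrackSpec) -> TrackSet:
    """Synthetic tracks: straight, persistent, diffusive, back-and-forth
    or stationary motion, one independent random substream per track."""
    step_len = spec.speed * spec.frame_interval / 60.0  # µm per frame
    streams = np.random.SeedSequence(spec.seed).spawn(spec.n_tracks)
    frames = np.arange(spec.n_frames)
    parts = []
    for tid, stream in enumerate(streams):
        rng = np.random.default_rng(stream)
        origin = rng.uniform(0.0, spec.field_size, size=2)
        if spec.kind == "stationary":
            xy = np.tile(origin, (spec.n_frames, 1))
        else:
            ang = _headings(spec, rng)
            steps = step_len * np.stack([np.cos(ang), np.sin(ang)], axis=1)
            xy = origin + np.concatenate([[(0.0, 0.0)], np.cumsum(steps, axis=0)])
        parts.append(
            pd.DataFrame(
                {
                    "track_id": tid,
                    "frame": frames,
                    "t_min": frames * spec.frame_interval,
                    "x_um": xy[:, 0],
                    "y_um": xy[:, 1],
                }
            )
        )
    return TrackSet(
        data=pd.concat(parts, ignore_index=True), frame_interval=spec.frame_interval
    )


def gen_division_angles(
    n: int, mean_angle: float = 0.0, concentration: float = 1.0, seed: int = 0
) -> DirectionSample:
    """Division/polarity angles from a von Mises law around ``mean_angle``
    (degrees); concentration 0 gives the uniform circle."""
    if n < 1:
        raise ValueError("need at least one angle")
    if concentration < 0:
        raise ValueError("concentration must be non-negative")
    rng = np.random.default_rng(seed)
    theta = rng.vonmises(np.radians(mean_angle), concentration, size=n)
    return DirectionSample(angles_deg=np.degrees(theta))


def gen_inheritance_counts(spec: PartitionSpec) -> pd.DataFrame:
    """Daughter-pair body counts under the binomial partition model.

    For each division the total is drawn from ``body_count_law`` and each
    body lands in daughter 1 with probability ``p_sym``; the table has
    columns division_id, count1, count2 and count1+count2 equals the
    drawn total by construction.
    """
    rng = np.random.default_rng(spec.seed)
    law = dict(spec.body_count_law)
    totals = rng.choice(
        np.array(list(law.keys()), dtype=int),
        p=np.array(list(law.values())),
        size=spec.n_divisions,
    )
    count1 = rng.binomial(totals, spec.p_sym)
    return pd.DataFrame(
        {
            "division_id": np.arange(spec.n_divisions),
            "count1": count1,
            "count2": totals - count1,
        }
    )


def gen_premitotic_track(
    n_frames: int = 61,
    frame_interval: float = 2.0,
    drift_onset: float = 30.0,
    seed: int = 0,
    cell_span: float = 30.0,
    jitter_sd: float = 0.3,
    final_position: float = 0.2,
) -> pd.DataFrame:
    """Nucleus / membrane coordinate series around mitosis entry.

    The nucleus centre c sits at the cell midpoint with Gaussian jitter,
    then drifts linearly towards the near membrane point x during the
    final ``drift_onset`` minutes (the pre-mitotic nuclear migration),
    reaching relative position ``final_position`` at the last frame.
    x = (0, 0) and y = (cell_span, 0) are fixed.  Columns: frame, cx, cy,
    xx, xy, yx, yy.
    """
    if drift_onset >= n_frames * frame_interval:
        raise ValueError("drift_onset must be shorter than the series")
    rng = np.random.default_rng(seed)
    frames = np.arange(n_frames)
    t_before_end = (frames[-1] - frames) * frame_interval
    rel = np.where(
        t_before_end >= drift_onset,
        0.5,
        final_position + (0.5 - final_position) * t_before_end / max(drift_onset, 1e-12),
    )
    cx = rel * cell_span + rng.normal(0.0, jitter_sd, size=n_frames)
    cy = rng.normal(0.0, jitter_sd, size=n_frames)
    return pd.DataFrame(
        {
            "frame": frames,
            "cx": cx,
            "cy": cy,
            "xx": 0.0,
            "xy": 0.0,
            "yx": cell_span,
            "yy": 0.0,
        }
    )
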