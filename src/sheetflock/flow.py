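"""Velocity-field (PIV output) statistics for collective migration.

Operates on gridded two-component velocity rasters with a validity mask,
as produced by block-matching PIV of epithelial sheet movies: speed maps
with median filtering, the instantaneous order parameter, and the
angle-versus-distance correlation curve whose 5-sigma cutoff defines the
velocity correlation length C_vv.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "VelocityField",
    "CorrelationCurve",
    "SpeedMap",
    "temporal_median",
    "speed_field",
    "iop_frame",
    "angle_correlation_curve",
    "correlation_length",
    "correlation_length_series",
    "allpairs_correlation_oracle",
]


@dataclass
class VelocityField:
    """One frame of gridded flow: U/V component rasters plus validity mask.

    ``window_spacing`` is the physical distance (µm) between adjacent
    grid positions; ``frame_interval`` the time between frames (min).
    Masked entries (mask == False) are excluded from every statistic.
    """

    u: np.ndarray
    v: np.ndarray
    mask: np.ndarray = None
    window_spacing: float = 1.0
    frame_interval: float = 1.0

    def __post_init__(self):
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.mask is None:
            self.mask = np.ones(self.u.shape, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if not (self.u.shape == self.v.shape == self.mask.shape):
            raise ValueError("U, V and mask must have congruent shapes")
        if self.u.ndim != 2:
            raise ValueError("velocity rasters must be 2-D")

    @property
    def magnitude(self) -> np.ndarray:
        return np.hypot(self.u, self.v)


@dataclass
class CorrelationCurve:
    """Mean inter-vector angle versus grid separation for one frame."""

    r_windows: np.ndarray      # integer grid distances
    r_um: np.ndarray           # the same distances in µm
    theta_mean_deg: np.ndarray
    theta_sem_deg: np.ndarray  # NaN where fewer than 2 samples
    n_samples: np.ndarray

    def as_frame(self):
        """The curve as a pandas table (one row per distance)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "r_windows": self.r_windows,
                "r_um": self.r_um,
                "theta_mean_deg": self.theta_mean_deg,
                "theta_sem_deg": self.theta_sem_deg,
                "n": self.n_samples,
            }
        )


@dataclass
class SpeedMap:
    """Speed raster M = sqrt(U^2+V^2), its 5x5 median-filtered version and
    the frame mean over unmasked entries (NaN if fully masked)."""

    speed: np.ndarray
    filtered: np.ndarray
    frame_mean: float


def temporal_median(frames: np.ndarray, bin: int = 3) -> np.ndarray:
    """Running temporal median: output frame k is the pixelwise median of
    input frames k .. k+bin-1; output length is len(frames) - bin + 1."""
    frames = np.asarray(frames)
    if bin < 1:
        raise ValueError("bin must be at least 1")
    if len(frames) < bin:
        raise ValueError(f"need at least {bin} frames")
    windows = np.lib.stride_tricks.sliding_window_view(frames, bin, axis=0)
    return np.median(windows, axis=-1)


def _masked_median_filter(values: np.ndarray, mask: np.ndarray, size: int = 5) -> np.ndarray:
    """size x size spatial median ignoring masked entries; a pixel whose
    whole window is masked stays NaN."""
    half = size // 2
    padded = np.full((values.shape[0] + 2 * half, values.shape[1] + 2 * half), np.nan)
    padded[half:-half or None, half:-half or None] = np.where(mask, values, np.nan)
    win = np.lib.stride_tricks.sliding_window_view(padded, (size, size))
    with np.errstate(all="ignore"):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmedian(win, axis=(-2, -1))


def speed_field(field: VelocityField, median_size: int = 5) -> SpeedMap:
    """Speed raster, its spatially median-filtered version and frame mean.

    The median filter ignores masked entries; the frame mean is taken
    over the unmasked entries of the filtered raster.
    """
    m = field.magnitude
    filtered = _masked_median_filter(m, field.mask, median_size)
    eligible = field.mask & np.isfinite(filtered)
    mean = float(filtered[eligible].mean()) if np.any(eligible) else float("nan")
    return SpeedMap(speed=m, filtered=filtered, frame_mean=mean)


def iop_frame(field: VelocityField, eps: float = 0.0) -> float:
    """Instantaneous order parameter: magnitude of the mean unit-velocity
    vector over unmasked vectors of nonzero magnitude; NaN if none."""
    mag = field.magnitude
    ok = field.mask & (mag > eps)
    if not np.any(ok):
        return float("nan")
    ux = (field.u[ok] / mag[ok]).mean()
    uy = (field.v[ok] / mag[ok]).mean()
    return float(np.hypot(ux, uy))


def _pair_angles_deg(u0, v0, u1, v1):
    """Angles (degrees) between vector pairs; both must be nonzero."""
    dot = u0 * u1 + v0 * v1
    norm = np.hypot(u0, v0) * np.hypot(u1, v1)
    return np.degrees(np.arccos(np.clip(dot / norm, -1.0, 1.0)))


def _curve_from_samples(samples: dict, spacing: float) -> CorrelationCurve:
    rs = np.array(sorted(samples), dtype=int)
    means = np.empty(len(rs))
    sems = np.empty(len(rs))
    ns = np.empty(len(rs), dtype=int)
    for k, r in enumerate(rs):
        vals = np.asarray(samples[r])
        ns[k] = len(vals)
        means[k] = vals.mean()
        sems[k] = vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else np.nan
    return CorrelationCurve(
        r_windows=rs,
        r_um=rs * spacing,
        theta_mean_deg=means,
        theta_sem_deg=sems,
        n_samples=ns,
    )


def angle_correlation_curve(field: VelocityField) -> CorrelationCurve:
    """Diagonal-seeded angle-distance curve.

    Every vector on the main (top-left to bottom-right) diagonal is a seed
    v0; from each seed the four cardinal directions are walked one grid
    position at a time, recording the angle between v0 and the vector at
    every integer distance.  Masked positions, positions outside the grid
    and zero vectors are skipped.
    """
    rows, cols = field.u.shape
    mag = field.magnitude
    eligible = field.mask & (mag > 0.0)
    if eligible.sum() < 2:
        raise ValueError("need at least 2 unmasked, nonzero vectors")

    samples: dict[int, list] = {}
    ndiag = min(rows, cols)
    for i in range(ndiag):
        if not eligible[i, i]:
            continue
        u0, v0 = field.u[i, i], field.v[i, i]
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            r = 1
            while True:
                rr, cc = i + dr * r, i + dc * r
                if rr < 0 or rr >= rows or cc < 0 or cc >= cols:
                    break
                if eligible[rr, cc]:
                    ang = _pair_angles_deg(u0, v0, field.u[rr, cc], field.v[rr, cc])
                    samples.setdefault(r, []).append(float(ang))
                r += 1
    if not samples:
        raise ValueError("no angle samples could be collected")
    return _curve_from_samples(samples, field.window_spacing)


def correlation_length(
    source: VelocityField | CorrelationCurve,
    n_sigma: float = 5.0,
    contiguous: bool = False,
) -> float:
    """Velocity correlation length C_vv in µm.

    The largest grid distance r whose mean angle passes
    ``mean + n_sigma * SEM < 90°`` (distances with fewer than 2 samples
    cannot pass); 0 if none does.  With ``contiguous=True`` the criterion
    must additionally hold at every smaller distance (first-failure
    variant, for sensitivity analysis).
    """
    curve = source if isinstance(source, CorrelationCurve) else angle_correlation_curve(source)
    with np.errstate(invalid="ignore"):
        passing = (curve.theta_mean_deg + n_sigma * curve.theta_sem_deg < 90.0) & (
            curve.n_samples >= 2
        )
    if not np.any(passing):
        return 0.0
    if contiguous:
        k = np.argmin(passing) - 1 if not passing.all() else len(passing) - 1
        if k < 0:
            return 0.0
        return float(curve.r_um[k])
    return float(curve.r_um[np.flatnonzero(passing)[-1]])


def correlation_length_series(
    fields, n_sigma: float = 5.0, contiguous: bool = False
) -> np.ndarray:
    """C_vv (µm) for each frame of a velocity-field stack."""
    return np.array([correlation_length(f, n_sigma, contiguous) for f in fields])


def allpairs_correlation_oracle(field: VelocityField) -> CorrelationCurve:
    """Exhaustive all-pairs reference estimator (small grids).

    Averages the inter-vector angle over every unmasked nonzero vector
    pair at each axis-aligned integer separation; serves as an
    independent check of the diagonal-seeded walk.
    """
    rows, cols = field.u.shape
    if rows > 32 or cols > 32:
        raise ValueError("oracle is restricted to grids of at most 32 x 32")
    mag = field.magnitude
    eligible = field.mask & (mag > 0.0)
    samples: dict[int, list] = {}
    for r in range(1, max(rows, cols)):
        vals = []
        if r < cols:  # horizontal pairs
            ok = eligible[:, :-r] & eligible[:, r:]
            vals.append(
                _pair_angles_deg(
                    field.u[:, :-r][ok], field.v[:, :-r][ok],
                    field.u[:, r:][ok], field.v[:, r:][ok],
                )
            )
        if r < rows:  # vertical pairs
            ok = eligible[:-r, :] & eligible[r:, :]
            vals.append(
                _pair_angles_deg(
                    field.u[:-r, :][ok], field.v[:-r, :][ok],
                    field.u[r:, :][ok], field.v[r:, :][ok],
                )
            )
        if vals:
            flat = np.concatenate([np.atleast_1d(x) for x in vals])
            if len(flat):
                samples[r] = list(flat)
    if not samples:
        raise ValueError("no angle samples could be collected")
    return _curve_from_samples(samples, field.window_spacing)
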