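"""Hybrid Self-Propelled-Voronoi / Vicsek dynamics of a confluent sheet.

Every cell centre r_i moves under the Voronoi tissue force and a
self-propulsion of speed v0 along its polarization n_i = (cos θ_i, sin θ_i):

    r_i(t+Δt) = r_i(t) + [μ F_i(t) + v0 n_i(t+Δt)] Δt

while the polarization angle relaxes, Vicsek-style, towards the mean
velocity direction φ_j of all neighbours within a radius R_V:

    θ_i(t+Δt) = θ_i(t) + (Δt/τ_V) <φ_j − θ_i>_{0<|r_j−r_i|≤R_V} + η_i(t)

η_i is Gaussian rotational noise; here it is discretised as a Brownian
increment of variance 2 D_r Δt per step, which makes the angular dynamics
independent of the step size.  Angle differences are wrapped to (−π, π]
before averaging.  φ_j comes from the displacement over the completed
previous step, so at t = 0 (and for R_V = 0) the alignment term is absent.

All lengths are in units of r0 = sqrt(A0) and times in units of
τ0 = 1/(μ K_A A0); the box side is L = sqrt(N A0) (confluent density 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from numba import njit

from .voronoi import sheet_forces

__all__ = [
    "ModelParams",
    "SheetState",
    "SimSummary",
    "init_state",
    "alignment_update",
    "step",
    "simulate",
    "avg_speed",
    "iop_sim",
    "rv_sweep",
]

#: speed threshold below which a velocity has no defined direction
IOP_SPEED_EPS = 1e-9


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the hybrid model (defaults: the reference active set)."""

    n: int = 1000
    k_area: float = 1.0      # area stiffness K_A, energy / length^4
    k_perim: float = 1.0     # perimeter stiffness K_p, energy / length^2
    a0: float = 1.0          # preferred area
    shape_index: float = 4.0  # p0 / sqrt(A0)
    mu: float = 1.0          # mobility
    v0: float = 0.5          # self-propulsion speed
    tau_v: float = 1.0       # alignment persistence time
    r_v: float = 0.0         # Vicsek radius
    d_r: float = 1.5         # rotational noise strength
    dt: float = 0.001        # time step

    def __post_init__(self):
        if self.n < 3:
            raise ValueError("need at least 3 cells")
        for name in ("k_area", "k_perim", "a0", "tau_v", "dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        # mu = 0 is the Vicsek point-particle limit
        for name in ("mu", "v0", "r_v", "d_r"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def p0(self) -> float:
        return self.shape_index * np.sqrt(self.a0)

    @property
    def r0(self) -> float:
        """Length unit sqrt(A0)."""
        return float(np.sqrt(self.a0))

    @property
    def tau0(self) -> float:
        """Time unit 1/(mu K_A A0); infinite in the mu = 0 limit."""
        if self.mu == 0.0:
            return float("inf")
        return 1.0 / (self.mu * self.k_area * self.a0)

    @property
    def box(self) -> float:
        """Periodic box side L = sqrt(N A0)."""
        return float(np.sqrt(self.n * self.a0))


@dataclass
class SheetState:
    """Simulator state: unwrapped positions, the positions one step back
    (defining neighbour velocity angles), polarization angles, time."""

    positions: np.ndarray        # (N, 2), unwrapped
    angles: np.ndarray           # (N,)
    box: float
    time: float = 0.0
    prev_positions: np.ndarray | None = None

    @property
    def wrapped(self) -> np.ndarray:
        return np.mod(self.positions, self.box)


@dataclass
class SimSummary:
    """Observable time series and steady-state means of one run."""

    times: np.ndarray            # in tau0
    mean_speed: np.ndarray       # in r0/tau0
    iop: np.ndarray              # dimensionless, NaN where undefined
    steady_speed: float
    steady_iop: float
    params: ModelParams
    seed: int


def init_state(params: ModelParams, rng: np.random.Generator) -> SheetState:
    """Random initial condition; a 1e-9 r0 jitter guards against
    accidentally degenerate (cocircular) point sets."""
    box = params.box
    pos = rng.uniform(0.0, box, size=(params.n, 2))
    pos += rng.normal(scale=1e-9 * params.r0, size=pos.shape)
    ang = rng.uniform(-np.pi, np.pi, size=params.n)
    return SheetState(positions=pos, angles=ang, box=box)


def alignment_update(
    state: SheetState, params: ModelParams, noise: np.ndarray
) -> np.ndarray:
    """New polarization angles θ(t+Δt).

    The alignment term averages the wrapped differences φ_j − θ_i over
    neighbours within R_V (minimum-image centre distance, self excluded);
    neighbours that did not move (φ undefined) are skipped, and an empty
    neighbourhood contributes nothing.
    """
    theta = state.angles
    if params.r_v <= 0.0 or state.prev_positions is None:
        return theta + noise

    disp = state.positions - state.prev_positions
    align = _alignment_terms(state.wrapped, state.box, params.r_v, disp, theta)
    return theta + (params.dt / params.tau_v) * align + noise


@njit(cache=True)
def _alignment_terms(pos, box, r_v, disp, theta):
    """Per-cell mean wrapped angle difference <phi_j - theta_i> over
    neighbours within r_v (minimum image, self excluded, immobile
    neighbours skipped); zero where the neighbourhood is empty."""
    n = len(pos)
    px = np.empty(n)
    py = np.empty(n)
    phi = np.empty(n)
    tw = np.empty(n)  # theta reduced to (-pi, pi]
    moved = np.empty(n, dtype=np.bool_)
    for j in range(n):
        px[j] = pos[j, 0]
        py[j] = pos[j, 1]
        dx, dy = disp[j, 0], disp[j, 1]
        moved[j] = dx != 0.0 or dy != 0.0
        phi[j] = np.arctan2(dy, dx)
        tw[j] = np.arctan2(np.sin(theta[j]), np.cos(theta[j]))
    total = np.zeros(n)
    count = np.zeros(n, dtype=np.int64)
    rv2 = r_v * r_v
    half = 0.5 * box
    two_pi = 2.0 * np.pi
    for i in range(n):
        xi, yi = px[i], py[i]
        for j in range(i + 1, n):
            dx = px[j] - xi
            if dx > half:
                dx -= box
            elif dx < -half:
                dx += box
            if dx > r_v or dx < -r_v:
                continue
            dy = py[j] - yi
            if dy > half:
                dy -= box
            elif dy < -half:
                dy += box
            d2 = dx * dx + dy * dy
            if d2 > rv2 or d2 <= 0.0:
                continue
            if moved[j]:
                d = phi[j] - tw[i]
                if d > np.pi:
                    d -= two_pi
                elif d <= -np.pi:
                    d += two_pi
                total[i] += d
                count[i] += 1
            if moved[i]:
                d = phi[i] - tw[j]
                if d > np.pi:
                    d -= two_pi
                elif d <= -np.pi:
                    d += two_pi
                total[j] += d
                count[j] += 1
    align = np.zeros(n)
    for i in range(n):
        if count[i] > 0:
            align[i] = total[i] / count[i]
    return align


def step(state: SheetState, params: ModelParams, rng: np.random.Generator) -> SheetState:
    """Advance one time step: angles first, then positions with the new
    polarization, as in the discrete equation of motion."""
    noise = rng.normal(0.0, np.sqrt(2.0 * params.d_r * params.dt), size=params.n)
    new_theta = alignment_update(state, params, noise)

    if params.mu != 0.0:
        forces = sheet_forces(
            state.positions, state.box,
            params.k_area, params.k_perim, params.a0, params.p0,
        )
        drift = params.mu * forces
    else:
        drift = 0.0
    heading = np.stack([np.cos(new_theta), np.sin(new_theta)], axis=1)
    new_pos = state.positions + (drift + params.v0 * heading) * params.dt
    if not np.all(np.isfinite(new_pos)):
        raise FloatingPointError(
            f"non-finite positions at t={state.time + params.dt:.4f}"
        )
    return SheetState(
        positions=new_pos,
        angles=new_theta,
        box=state.box,
        time=state.time + params.dt,
        prev_positions=state.positions,
    )


def avg_speed(
    snapshots: np.ndarray, snapshot_dt: float, lag_steps: int = 1
) -> np.ndarray:
    """Mean cell speed series from unwrapped position snapshots.

    ``snapshots`` has shape (T, N, 2); the speed at snapshot t is the mean
    over cells of |r(t+lag) - r(t)| / (lag * snapshot_dt).
    """
    snapshots = np.asarray(snapshots)
    if lag_steps < 1 or lag_steps >= len(snapshots):
        raise ValueError("lag must be at least one and shorter than the trajectory")
    disp = snapshots[lag_steps:] - snapshots[:-lag_steps]
    speeds = np.hypot(disp[..., 0], disp[..., 1]) / (lag_steps * snapshot_dt)
    return speeds.mean(axis=1)


def iop_sim(
    snapshots: np.ndarray, lag_steps: int = 1, eps: float = IOP_SPEED_EPS
) -> np.ndarray:
    """Instantaneous order parameter series from position snapshots.

    IOP(t) is the magnitude of the mean unit-velocity vector over cells
    whose lagged displacement exceeds ``eps``; NaN if no cell moved.
    """
    snapshots = np.asarray(snapshots)
    disp = snapshots[lag_steps:] - snapshots[:-lag_steps]
    mag = np.hypot(disp[..., 0], disp[..., 1])
    out = np.full(len(disp), np.nan)
    for t in range(len(disp)):
        ok = mag[t] > eps
        if not np.any(ok):
            continue
        unit = disp[t][ok] / mag[t][ok, None]
        out[t] = np.hypot(*unit.mean(axis=0))
    return out


def simulate(
    params: ModelParams,
    n_equil: int = 10_000,
    n_prod: int = 20_000,
    seed: int | np.random.SeedSequence = 0,
    stride: int = 100,
) -> SimSummary:
    """Full protocol: random start, passive equilibration (v0 = R_V = 0),
    then active production; observables on a fixed stride.

    Speeds use the standard 100-step lagged displacement (one stride);
    steady-state means are taken over the final half of production.
    """
    if n_equil < 0 or n_prod < 0:
        raise ValueError("step counts must be non-negative")
    if params.mu == 0.0:
        raise ValueError("mu = 0 leaves the time unit tau0 undefined")
    rng = np.random.default_rng(seed)
    seed_int = seed if isinstance(seed, (int, np.integer)) else -1
    state = init_state(params, rng)

    passive = replace(params, v0=0.0, r_v=0.0)
    for _ in range(n_equil):
        state = step(state, passive, rng)

    snaps = [state.positions.copy()]
    for k in range(1, n_prod + 1):
        state = step(state, params, rng)
        if k % stride == 0:
            snaps.append(state.positions.copy())
    snaps = np.array(snaps)

    snapshot_dt = stride * params.dt
    unit = params.r0 / params.tau0
    speeds = avg_speed(snaps, snapshot_dt) / unit
    iops = iop_sim(snaps)
    times = snapshot_dt * np.arange(len(speeds)) / params.tau0

    half = len(speeds) // 2
    return SimSummary(
        times=times,
        mean_speed=speeds,
        iop=iops,
        steady_speed=float(speeds[half:].mean()),
        steady_iop=float(np.nanmean(iops[half:])),
        params=params,
        seed=int(seed_int),
    )


def rv_sweep(
    params: ModelParams,
    rv_values,
    n_runs: int = 3,
    seed: int = 0,
    n_equil: int = 10_000,
    n_prod: int = 20_000,
) -> pd.DataFrame:
    """Independent seeded runs for each Vicsek radius.

    Returns one row per (R_V, run) with the steady-state mean speed and
    IOP; aggregate with ``df.groupby("rv")`` as needed.
    """
    rv_values = list(rv_values)
    if not rv_values:
        raise ValueError("rv_values must be non-empty")
    streams = np.random.SeedSequence(seed).spawn(len(rv_values) * n_runs)
    rows = []
    k = 0
    for rv in rv_values:
        for run in range(n_runs):
            summary = simulate(
                replace(params, r_v=rv), n_equil, n_prod, seed=streams[k]
            )
            rows.append(
                {
                    "rv": rv,
                    "run": run,
                    "steady_speed": summary.steady_speed,
                    "steady_iop": summary.steady_iop,
                }
            )
            k += 1
    return pd.DataFrame(rows)
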