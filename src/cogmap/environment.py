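"""Synthetic arenas and exploratory trajectories.

An :class:`Environment` is a planar rectangular arena with rectangular or
circular holes removed.  Holes are the only topological features, so the
reference Betti numbers of the accessible region are known by construction:
``b0 = 1`` (one connected piece) and ``b1 = number of holes``.

Exploration is simulated as a momentum-smoothed random walk: the scalar
speed follows an Ornstein-Uhlenbeck process around a target mean while the
heading diffuses, which produces non-preferential coverage of the arena at
rodent-like speeds without favouring any subregion.  The walker reflects off
the outer walls and off hole boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage


class EnvironmentError_(ValueError):
    """Raised for invalid arena specifications."""


@dataclass(frozen=True)
class RectHole:
    """Axis-aligned rectangular hole; center and full side lengths in cm."""

    cx: float
    cy: float
    width: float
    height: float

    def contains(self, x, y, pad: float = 0.0):
        return (np.abs(np.asarray(x) - self.cx) < self.width / 2 + pad) & (
            np.abs(np.asarray(y) - self.cy) < self.height / 2 + pad
        )

    @property
    def bounds(self):  # (xmin, xmax, ymin, ymax)
        return (
            self.cx - self.width / 2,
            self.cx + self.width / 2,
            self.cy - self.height / 2,
            self.cy + self.height / 2,
        )


@dataclass(frozen=True)
class DiscHole:
    """Circular hole; center and radius in cm."""

    cx: float
    cy: float
    radius: float

    def contains(self, x, y, pad: float = 0.0):
        dx = np.asarray(x) - self.cx
        dy = np.asarray(y) - self.cy
        return dx * dx + dy * dy < (self.radius + pad) ** 2

    @property
    def bounds(self):
        return (
            self.cx - self.radius,
            self.cx + self.radius,
            self.cy - self.radius,
            self.cy + self.radius,
        )


Hole = RectHole | DiscHole


@dataclass(frozen=True)
class Environment:
    """Planar arena (cm) minus a set of pairwise-disjoint holes."""

    width: float
    height: float
    holes: tuple[Hole, ...] = ()

    @property
    def reference_betti(self) -> tuple[int, int]:
        """(b0, b1) of the accessible region: one component, one loop per hole."""
        return (1, len(self.holes))

    def in_hole(self, x, y):
        """Boolean mask of points strictly inside any hole."""
        x = np.asarray(x, dtype=float)
        mask = np.zeros(np.shape(x), dtype=bool)
        for h in self.holes:
            mask |= h.contains(x, y)
        return mask

    def accessible(self, x, y):
        """Points inside the arena and outside every hole."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        inside = (x >= 0) & (x <= self.width) & (y >= 0) & (y <= self.height)
        return inside & ~self.in_hole(x, y)


def _holes_disjoint(a: Hole, b: Hole) -> bool:
    ax0, ax1, ay0, ay1 = a.bounds
    bx0, bx1, by0, by1 = b.bounds
    if isinstance(a, RectHole) and isinstance(b, RectHole):
        return ax1 <= bx0 or bx1 <= ax0 or ay1 <= by0 or by1 <= ay0
    if isinstance(a, DiscHole) and isinstance(b, DiscHole):
        d2 = (a.cx - b.cx) ** 2 + (a.cy - b.cy) ** 2
        return d2 >= (a.radius + b.radius) ** 2
    disc, rect = (a, b) if isinstance(a, DiscHole) else (b, a)
    rx0, rx1, ry0, ry1 = rect.bounds
    nx = min(max(disc.cx, rx0), rx1)
    ny = min(max(disc.cy, ry0), ry1)
    return (disc.cx - nx) ** 2 + (disc.cy - ny) ** 2 >= disc.radius**2


def make_environment(
    width: float, height: float, holes: list[Hole] | tuple[Hole, ...] = ()
) -> Environment:
    """Validate and build an :class:`Environment`.

    Raises :class:`EnvironmentError_` if dimensions are non-positive, a hole
    sticks out of the arena, holes overlap, or the holes disconnect the
    accessible region (checked on a 1-cm occupancy grid).
    """
    if width <= 0 or height <= 0:
        raise EnvironmentError_("arena dimensions must be positive")
    holes = tuple(holes)
    for h in holes:
        x0, x1, y0, y1 = h.bounds
        if x0 <= 0 or y0 <= 0 or x1 >= width or y1 >= height:
            raise EnvironmentError_(f"hole {h} not strictly inside the arena")
        if isinstance(h, RectHole) and (h.width <= 0 or h.height <= 0):
            raise EnvironmentError_("rectangular hole with non-positive side")
        if isinstance(h, DiscHole) and h.radius <= 0:
            raise EnvironmentError_("disc hole with non-positive radius")
    for i in range(len(holes)):
        for j in range(i + 1, len(holes)):
            if not _holes_disjoint(holes[i], holes[j]):
                raise EnvironmentError_(f"holes {holes[i]} and {holes[j]} overlap")
    env = Environment(width, height, holes)
    if holes and not _accessible_connected(env):
        raise EnvironmentError_("hole layout disconnects the accessible region")
    return env


def _accessible_connected(env: Environment, resolution: float = 1.0) -> bool:
    nx = max(int(round(env.width / resolution)), 2)
    ny = max(int(round(env.height / resolution)), 2)
    xs = (np.arange(nx) + 0.5) * env.width / nx
    ys = (np.arange(ny) + 0.5) * env.height / ny
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    free = env.accessible(gx, gy)
    _, ncomp = ndimage.label(free)
    return ncomp == 1


@dataclass
class Trajectory:
    """Uniformly sampled path; times in s, positions in cm."""

    dt: float
    times: np.ndarray
    positions: np.ndarray  # shape (n, 2)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if len(self.times) != len(self.positions):
            raise ValueError("times and positions length mismatch")

    @property
    def duration(self) -> float:
        return len(self.times) * self.dt

    @property
    def speeds(self) -> np.ndarray:
        """Instantaneous speed (cm/s) from forward differences."""
        if len(self.positions) < 2:
            return np.zeros(len(self.positions))
        d = np.linalg.norm(np.diff(self.positions, axis=0), axis=1) / self.dt
        return np.concatenate([d, d[-1:]])

    @property
    def velocities(self) -> np.ndarray:
        """Forward-difference velocity vectors (cm/s), last one repeated."""
        if len(self.positions) < 2:
            return np.zeros_like(self.positions)
        v = np.diff(self.positions, axis=0) / self.dt
        return np.vstack([v, v[-1:]])


def simulate_trajectory(
    env: Environment,
    duration: float,
    mean_speed: float = 20.0,
    speed_sd: float = 8.0,
    dt: float = 0.01,
    seed: int | None = None,
    start: tuple[float, float] | None = None,
    speed_relax_s: float = 1.0,
    heading_diffusion: float = 0.6,
) -> Trajectory:
    """Simulate non-preferential exploration.

    Parameters
    ----------
    duration : session length (s); ``0`` yields a single start point.
    mean_speed, speed_sd : stationary mean and SD of the OU speed (cm/s).
    dt : time step (s).
    heading_diffusion : heading diffusion coefficient (rad / sqrt(s)).
    """
    if duration < 0:
        raise ValueError("duration must be non-negative")
    if mean_speed <= 0 or speed_sd <= 0:
        raise ValueError("speed parameters must be positive")
    rng = np.random.default_rng(seed)
    if start is None:
        while True:
            p = rng.uniform([0, 0], [env.width, env.height])
            if env.accessible(p[0], p[1]):
                break
    else:
        p = np.asarray(start, dtype=float)
        if not env.accessible(p[0], p[1]):
            raise ValueError("start position outside the accessible region")
    n = int(round(duration / dt))
    times = np.arange(n + 1) * dt
    pos = np.empty((n + 1, 2))
    pos[0] = p
    if n == 0:
        return Trajectory(dt, times, pos)

    # exact OU discretization for the speed, reflected at zero
    rho = np.exp(-dt / speed_relax_s)
    sq = speed_sd * np.sqrt(1 - rho * rho)
    xi_s = rng.standard_normal(n)
    xi_h = rng.standard_normal(n) * heading_diffusion * np.sqrt(dt)
    speed = mean_speed
    heading = rng.uniform(0, 2 * np.pi)
    for k in range(n):
        speed = abs(mean_speed + (speed - mean_speed) * rho + sq * xi_s[k])
        heading += xi_h[k]
        step = speed * dt
        cand = pos[k] + step * np.array([np.cos(heading), np.sin(heading)])
        if env.accessible(cand[0], cand[1]):
            pos[k + 1] = cand
            continue
        # reflect: try mirroring each component of the step, else reverse
        placed = False
        for trial, ang in (
            ((pos[k][0] - step * np.cos(heading), cand[1]), np.pi - heading),
            ((cand[0], pos[k][1] - step * np.sin(heading)), -heading),
            ((pos[k][0] - step * np.cos(heading), pos[k][1] - step * np.sin(heading)), heading + np.pi),
        ):
            if env.accessible(trial[0], trial[1]):
                pos[k + 1] = trial
                heading = ang
                placed = True
                break
        if not placed:
            pos[k + 1] = pos[k]
            heading = rng.uniform(0, 2 * np.pi)
    return Trajectory(dt, times, pos)


def occupancy_map(
    traj: Trajectory, env: Environment, bins: int | tuple[int, int] = 10
) -> np.ndarray:
    """Dwell time (s) per spatial bin; half-open bins covering the arena.

    Entries sum to the trajectory duration; bins fully inside holes are zero
    because no samples fall there.
    """
    if isinstance(bins, int):
        bins = (bins, bins)
    h, _, _ = np.histogram2d(
        traj.positions[:, 0],
        traj.positions[:, 1],
        bins=bins,
        range=[[0, env.width], [0, env.height]],
    )
    return h * traj.dt


def write_trajectory(traj: Trajectory, path) -> None:
    """Write a t,x,y delimited text file (s, cm, cm) with a header."""
    pd.DataFrame(
        {"t": traj.times, "x": traj.positions[:, 0], "y": traj.positions[:, 1]}
    ).to_csv(path, index=False, float_format="%.6f")


def read_trajectory(path) -> Trajectory:
    df = pd.read_csv(path)
    t = df["t"].to_numpy()
    dt = float(t[1] - t[0]) if len(t) > 1 else 0.01
    return Trajectory(dt, t, df[["x", "y"]].to_numpy())
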