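"""Place-field maps and rhythmically modulated Poisson spiking.

Each place cell ``i`` fires as an inhomogeneous Poisson process whose rate is
a Gaussian bump of the animal's position,

    rate_i(x, t) = f_i * G_i(x) * Theta_i(t) * exp(-A_gamma(t) / tau_i),

with ``f_i`` the peak rate, ``G_i`` a unit-peak Gaussian, ``Theta_i`` a
theta-precession factor and the last term a Boltzmann coupling of spikes to
gamma-wave troughs (``tau_i = inf`` disables it).

Field sizes and peak rates across the ensemble are drawn from log-normal
distributions parameterized by their mode (``s`` in cm, ``f`` in Hz) and
standard deviations ``sigma_s = b*s`` and ``sigma_f = a*f``; an ensemble is
therefore indexed by the triplet ``(s, f, N)`` plus the spread coefficients.

The field size ``s_i`` is the diameter at which the Gaussian falls to
``0.2 * f_i``, i.e. the Gaussian SD is ``s_i / (2*sqrt(2*ln 5))``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import i0

from .environment import Environment, Trajectory

# G(d) = exp(-d^2 / (2 sig^2)) with G(s/2) = 0.2  =>  sig = s / (2 sqrt(2 ln 5))
_SIZE_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(5.0)))


def lognormal_from_mode_sd(mode: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with the given mode and standard deviation.

    mode = exp(mu - sigma^2), SD = exp(mu + sigma^2/2) sqrt(exp(sigma^2) - 1);
    the ratio SD/mode fixes sigma, solved numerically.
    """
    if mode <= 0:
        raise ValueError("mode must be positive")
    if sd < 0:
        raise ValueError("sd must be non-negative")
    if sd == 0:
        return np.log(mode), 0.0
    r = sd / mode

    def f(s2):
        return np.exp(1.5 * s2) * np.sqrt(np.expm1(s2)) - r

    s2 = brentq(f, 1e-12, 20.0)
    return np.log(mode) + s2, np.sqrt(s2)


@dataclass
class PlaceFieldMap:
    """Gaussian place fields of an ensemble of N cells."""

    centers: np.ndarray  # (N, 2) cm
    sizes: np.ndarray  # (N,) cm, 0.2-peak diameter
    rates: np.ndarray  # (N,) Hz, peak rate
    s: float
    f: float
    a: float
    b: float

    def __post_init__(self):
        self.centers = np.asarray(self.centers, dtype=float)
        self.sizes = np.asarray(self.sizes, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        if np.any(self.sizes <= 0) or np.any(self.rates <= 0):
            raise ValueError("field sizes and peak rates must be positive")

    @property
    def n_cells(self) -> int:
        return len(self.centers)

    @property
    def sigmas(self) -> np.ndarray:
        """Gaussian SDs (cm) corresponding to the 0.2-peak diameters."""
        return self.sizes * _SIZE_TO_SIGMA


def sample_place_field_map(
    env: Environment,
    s: float,
    f: float,
    n_cells: int,
    a: float = 0.3,
    b: float = 0.3,
    seed: int | None = None,
) -> PlaceFieldMap:
    """Sample an (s, f, N) ensemble: centers uniform over the arena rectangle
    (fields may overhang holes), sizes/rates log-normal with modes s, f and
    SDs b*s, a*f.  ``a = b = 0`` degenerates to identical fields."""
    if s <= 0 or f <= 0:
        raise ValueError("s and f must be positive")
    if n_cells < 1:
        raise ValueError("need at least one cell")
    if a < 0 or b < 0:
        raise ValueError("spread coefficients must be non-negative")
    rng = np.random.default_rng(seed)
    centers = rng.uniform([0, 0], [env.width, env.height], size=(n_cells, 2))
    mu_s, sig_s = lognormal_from_mode_sd(s, b * s)
    mu_f, sig_f = lognormal_from_mode_sd(f, a * f)
    sizes = rng.lognormal(mu_s, sig_s, n_cells) if sig_s else np.full(n_cells, s)
    rates = rng.lognormal(mu_f, sig_f, n_cells) if sig_f else np.full(n_cells, f)
    return PlaceFieldMap(centers, sizes, rates, s, f, a, b)


@dataclass
class ModulationConfig:
    """Theta/gamma modulation of the Poisson rate.

    theta_depth in [0, 1] scales the raised-cosine precession factor
    (0 = no modulation); precession maps field entry->exit onto preferred
    phase 2*pi -> 0.  gamma amplitude is A(t) = (1 + cos(2 pi f_gamma t))/2,
    normalized to [0, 1]; tau is the effective spiking temperature in the
    same units (tau = inf disables gamma coupling; tau ~ mean(A) = 0.5 is
    the physiological default when enabled).
    """

    theta_on: bool = False
    gamma_on: bool = False
    theta_freq: float = 8.0
    theta_depth: float = 0.8
    gamma_freq: float = 60.0
    tau: float = 0.5
    rate_preserving: bool = True

    def __post_init__(self):
        if self.theta_freq <= 0 or self.gamma_freq <= 0:
            raise ValueError("rhythm frequencies must be positive")
        if not 0 <= self.theta_depth <= 1:
            raise ValueError("theta_depth must lie in [0, 1]")
        if self.tau <= 0:
            raise ValueError("tau must be positive (inf allowed)")

    @property
    def theta_period(self) -> float:
        return 1.0 / self.theta_freq

    def gamma_norm(self) -> float:
        """Cycle-average of the Boltzmann factor, exp(-1/2tau) I0(1/2tau).

        With ``rate_preserving`` the factor is divided by this partition
        term, so gamma coupling redistributes spikes toward the wave troughs
        without changing a cell's mean rate (a timing, not a gain, effect);
        otherwise the raw factor thins the train.
        """
        if not self.rate_preserving or not np.isfinite(self.tau):
            return 1.0
        x = 1.0 / (2.0 * self.tau)
        return float(np.exp(-x) * i0(x))

    def theta_norm(self) -> float:
        """Phase-average of the precession factor (1 - depth/2)."""
        if not self.rate_preserving:
            return 1.0
        return 1.0 - self.theta_depth / 2.0


def gamma_amplitude(t, freq: float = 60.0):
    """Normalized gamma-wave amplitude in [0, 1]; troughs at A = 0."""
    return 0.5 * (1.0 + np.cos(2 * np.pi * freq * np.asarray(t)))


@dataclass
class SpikeTrains:
    """Per-cell sorted spike times (s) over a session."""

    trains: list[np.ndarray]
    duration: float

    def __post_init__(self):
        self.trains = [np.asarray(tr, dtype=float) for tr in self.trains]
        for tr in self.trains:
            if len(tr) and (tr[0] < 0 or tr[-1] > self.duration + 1e-9):
                raise ValueError("spike outside the session")
            if np.any(np.diff(tr) < 0):
                raise ValueError("spike times must be sorted")

    @property
    def n_cells(self) -> int:
        return len(self.trains)

    @property
    def n_spikes(self) -> int:
        return sum(len(tr) for tr in self.trains)


def _theta_factor(mod, t, u):
    """Raised-cosine precession factor given time and field fraction u in [0,1]."""
    pref = 2 * np.pi * (1.0 - u)
    phase = 2 * np.pi * mod.theta_freq * t
    return 1.0 - mod.theta_depth + mod.theta_depth * 0.5 * (1 + np.cos(phase - pref))


def _field_fraction(rel, vel, size):
    """Fraction of the field traversed, from the projection of the offset onto
    the instantaneous movement direction (entry -0.5 -> exit +0.5)."""
    speed = np.linalg.norm(vel, axis=-1)
    speed = np.where(speed > 1e-9, speed, 1.0)
    proj = (rel * vel).sum(axis=-1) / speed
    return np.clip(proj / np.maximum(size, 1e-9) + 0.5, 0.0, 1.0)


def instantaneous_rate(
    pf: PlaceFieldMap,
    cell: int,
    position,
    t,
    mod: ModulationConfig | None = None,
    velocity=None,
) -> np.ndarray | float:
    """Modulated Poisson rate (Hz) of one cell.

    Bounded by the peak rate times the peak modulation factor (exactly the
    peak rate when modulation is off or non-rate-preserving).

    ``velocity`` (cm/s) is needed only for the precession factor; when absent
    the cell's preferred phase is taken at the field midpoint.
    """
    pos = np.atleast_2d(np.asarray(position, dtype=float))
    tt = np.atleast_1d(np.asarray(t, dtype=float))
    rel = pos - pf.centers[cell]
    d2 = (rel**2).sum(axis=-1)
    sig = pf.sigmas[cell]
    rate = pf.rates[cell] * np.exp(-d2 / (2 * sig * sig))
    if mod is not None and mod.theta_on:
        if velocity is None:
            u = np.full(len(tt), 0.5)
        else:
            u = _field_fraction(rel, np.atleast_2d(np.asarray(velocity, float)), pf.sizes[cell])
        rate = rate * (_theta_factor(mod, tt, u) / mod.theta_norm())
    if mod is not None and mod.gamma_on and np.isfinite(mod.tau):
        rate = rate * (
            np.exp(-gamma_amplitude(tt, mod.gamma_freq) / mod.tau) / mod.gamma_norm()
        )
    return rate if np.ndim(position) > 1 or np.ndim(t) else float(rate[0])


def generate_spike_trains(
    pf: PlaceFieldMap,
    traj: Trajectory,
    mod: ModulationConfig | None = None,
    seed: int | None = None,
    cutoff_sigmas: float = 3.5,
    time_oversample: int = 1,
) -> SpikeTrains:
    """Bernoulli thinning of the modulated rate along the trajectory.

    One draw per time step and cell (at most one spike per cell per step);
    only steps within ``cutoff_sigmas`` Gaussian widths of a field center
    are evaluated.  Seeded and reproducible.

    ``time_oversample`` subdivides each trajectory step (positions linearly
    interpolated) so that spike times can resolve rhythms faster than the
    trajectory sampling — needed for gamma-synchronized spiking, where the
    ~60 Hz cycle is shorter than the usual 10 ms behavioural step.
    """
    rng = np.random.default_rng(seed)
    pos = traj.positions
    tt = traj.times
    vel = traj.velocities
    dt = traj.dt
    if time_oversample > 1:
        k = int(time_oversample)
        n = len(tt)
        tt = np.arange((n - 1) * k + 1) * (dt / k) + traj.times[0]
        frac = np.linspace(0, 1, k, endpoint=False)
        base = pos[:-1, None, :] + (pos[1:] - pos[:-1])[:, None, :] * frac[None, :, None]
        pos = np.concatenate([base.reshape(-1, 2), pos[-1:]], axis=0)
        vel = np.repeat(vel[:-1], k, axis=0)
        vel = np.concatenate([vel, vel[-1:]], axis=0)
        dt = dt / k
    trains: list[np.ndarray] = []
    for i in range(pf.n_cells):
        rel = pos - pf.centers[i]
        sig = pf.sigmas[i]
        d2 = (rel**2).sum(axis=1)
        idx = np.nonzero(d2 < (cutoff_sigmas * sig) ** 2)[0]
        if len(idx) == 0:
            trains.append(np.empty(0))
            continue
        rate = pf.rates[i] * np.exp(-d2[idx] / (2 * sig * sig))
        if mod is not None and mod.theta_on:
            u = _field_fraction(rel[idx], vel[idx], pf.sizes[i])
            rate = rate * (_theta_factor(mod, tt[idx], u) / mod.theta_norm())
        if mod is not None and mod.gamma_on and np.isfinite(mod.tau):
            rate = rate * (
                np.exp(-gamma_amplitude(tt[idx], mod.gamma_freq) / mod.tau)
                / mod.gamma_norm()
            )
        p = np.minimum(rate * dt, 1.0)
        fired = rng.random(len(idx)) < p
        trains.append(tt[idx[fired]])
    return SpikeTrains(trains, duration=max(traj.duration, tt[-1] if len(tt) else 0.0))


def write_spike_raster(spikes: SpikeTrains, path) -> None:
    """Delimited text raster: cell_id, spike_time_s; sorted by time."""
    cells = np.concatenate(
        [np.full(len(tr), i, dtype=int) for i, tr in enumerate(spikes.trains)]
        or [np.empty(0, dtype=int)]
    )
    times = np.concatenate([tr for tr in spikes.trains] or [np.empty(0)])
    order = np.argsort(times, kind="stable")
    pd.DataFrame({"cell_id": cells[order], "spike_time_s": times[order]}).to_csv(
        path, index=False, float_format="%.6f"
    )


def read_spike_raster(path, n_cells: int | None = None, duration: float | None = None) -> SpikeTrains:
    df = pd.read_csv(path)
    cid = df["cell_id"].to_numpy(dtype=int)
    ts = df["spike_time_s"].to_numpy(dtype=float)
    n = n_cells if n_cells is not None else (cid.max() + 1 if len(cid) else 0)
    trains = [np.sort(ts[cid == i]) for i in range(n)]
    dur = duration if duration is not None else (ts.max() if len(ts) else 0.0)
    return SpikeTrains(trains, duration=dur)
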