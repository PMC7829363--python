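"""Flickering (transient) coactivity graphs and their topological dynamics.

A link of the coactivity graph appears when its two cells first become
coactive and thereafter may *decay*; vertices, once active, never decay
(place cells remain stable in a learned environment).  Decay modes:

``exponential``
    At each (re)birth a link draws a patience ``T ~ Exponential(tau)`` and
    dies once the time since its *last* activation exceeds ``T``; every
    reactivation resets the activation clock.  Reactivation therefore
    extends lifetimes: links reactivated at a characteristic interval
    ``dt`` acquire effective lifetimes well above ``tau``, and the long
    draws form a pool of session-long survivors (the stable core).
``quenched``
    Deterministic patience: the link dies exactly ``tau`` after its last
    activation.  No lifetime spread, hence no survivor pool.
``windowed``
    Finite-latency rule: the link is present at ``t`` iff it was activated
    within the look-back window ``[t - latency, t]``.
``random-control``
    Birth times are re-drawn as a Poisson process matching each link's
    empirical activation rate; deaths follow the exponential rule.

``tau = inf`` reproduces the perennial, monotonically growing graph in
every decaying mode.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import networkx as nx
from scipy import stats

from . import homology

Link = tuple[int, int]


@dataclass
class FlickerConfig:
    """Decay mode and its timescales (seconds)."""

    mode: str = "exponential"  # exponential | quenched | windowed | random-control
    tau: float = 90.0  # proper decay constant (inf allowed)
    latency: float = 300.0  # look-back window for 'windowed' mode
    latency_step: float | None = None  # evaluation step, default 0.05 * latency
    time_step: float = 5.0  # Betti evaluation grid
    seed: int | None = None

    def __post_init__(self):
        if self.mode not in ("exponential", "quenched", "windowed", "random-control"):
            raise ValueError(f"unknown flicker mode {self.mode!r}")
        if self.tau <= 0:
            raise ValueError("tau must be positive (inf allowed)")
        if self.latency <= 0:
            raise ValueError("latency must be positive")
        step = self.latency_step if self.latency_step is not None else 0.05 * self.latency
        if step < 0.01 * self.latency - 1e-12:
            raise ValueError("latency step must be at least 1% of the latency")
        self.latency_step = step


def link_activations(graph: nx.Graph) -> dict[Link, list[float]]:
    """Per-link sorted activation times from a coactivity graph."""
    return {
        (min(u, v), max(u, v)): list(d["times"]) for u, v, d in graph.edges(data=True)
    }


def _decay_intervals(acts, tau, duration, rng, quenched):
    """Birth/death intervals of one link under patience decay."""
    intervals = []
    i = 0
    n = len(acts)
    while i < n:
        birth = acts[i]
        patience = tau if quenched else rng.exponential(tau)
        last = birth
        j = i + 1
        while j < n and acts[j] <= last + patience:
            last = acts[j]
            j += 1
        death = last + patience
        if death >= duration or not np.isfinite(death):
            intervals.append((birth, duration))
            break
        intervals.append((birth, death))
        i = j
    return intervals


def _window_intervals(acts, latency, duration):
    """Merged union of [a, a + latency] over activations."""
    intervals = []
    for a in acts:
        d = min(a + latency, duration)
        if intervals and a <= intervals[-1][1]:
            intervals[-1] = (intervals[-1][0], max(intervals[-1][1], d))
        else:
            intervals.append((a, d))
    return intervals


@dataclass
class FlickerTimeline:
    """Active-link intervals of a transient coactivity graph."""

    duration: float
    activations: dict[Link, list[float]]
    intervals: dict[Link, list[tuple[float, float]]]
    cfg: FlickerConfig
    vertex_first: dict[int, float]

    def active_links(self, t: float) -> list[Link]:
        out = []
        for link, ivs in self.intervals.items():
            for b, d in ivs:
                if b <= t < d or (d >= self.duration and b <= t <= self.duration):
                    out.append(link)
                    break
        return out

    def vertices_at(self, t: float) -> list[int]:
        return [v for v, f in self.vertex_first.items() if f <= t]

    def grid(self) -> np.ndarray:
        step = (
            self.cfg.latency_step if self.cfg.mode == "windowed" else self.cfg.time_step
        )
        return np.arange(step, self.duration + step / 2, step)

    def event_log(self) -> list[tuple[float, int, int, str]]:
        """(t, u, v, 'birth'|'death') rows, sorted by time; replaying them
        reconstructs every active set exactly."""
        rows = []
        for (u, v), ivs in self.intervals.items():
            for b, d in ivs:
                rows.append((b, u, v, "birth"))
                if d < self.duration:
                    rows.append((d, u, v, "death"))
        rows.sort()
        return rows

    def write_event_log(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("t,link_u,link_v,event\n")
            for t, u, v, kind in self.event_log():
                fh.write(f"{t:.6f},{u},{v},{kind}\n")


def evolve_flicker_timeline(
    activations: dict[Link, list[float]],
    cfg: FlickerConfig,
    duration: float,
    vertex_first: dict[int, float] | None = None,
) -> FlickerTimeline:
    """Evolve per-link birth/death intervals under the configured decay mode."""
    rng = np.random.default_rng(cfg.seed)
    activations = {k: sorted(v) for k, v in activations.items() if v}
    if vertex_first is None:
        vertex_first = {}
        for (u, v), ts in activations.items():
            for c in (u, v):
                vertex_first[c] = min(vertex_first.get(c, np.inf), ts[0])
    intervals: dict[Link, list[tuple[float, float]]] = {}
    for link, acts in sorted(activations.items()):
        if cfg.mode == "windowed":
            intervals[link] = _window_intervals(acts, cfg.latency, duration)
        elif cfg.mode == "random-control":
            rate = len(acts) / duration
            n = rng.poisson(rate * duration)
            births = np.sort(rng.uniform(0, duration, n)).tolist() or acts[:1]
            if np.isinf(cfg.tau):
                intervals[link] = [(births[0], duration)]
            else:
                intervals[link] = _decay_intervals(births, cfg.tau, duration, rng, False)
        elif np.isinf(cfg.tau):
            intervals[link] = [(acts[0], duration)]
        else:
            intervals[link] = _decay_intervals(
                acts, cfg.tau, duration, rng, cfg.mode == "quenched"
            )
    return FlickerTimeline(duration, activations, intervals, cfg, vertex_first)


def clique_complex(
    vertices, edges, max_dim: int = 2
) -> dict[tuple[int, ...], float]:
    """Flag (clique) complex of a graph up to simplex dimension ``max_dim``,
    by common-neighbor enumeration (cliques of 2-4 vertices)."""
    simplices: dict[tuple[int, ...], float] = {(v,): 0.0 for v in vertices}
    nbr: dict[int, set[int]] = {}
    edge_list = []
    for u, v in edges:
        u, v = (u, v) if u < v else (v, u)
        nbr.setdefault(u, set()).add(v)
        nbr.setdefault(v, set()).add(u)
        simplices[(u, v)] = 0.0
        edge_list.append((u, v))
    triangles = []
    if max_dim >= 2:
        for u, v in edge_list:
            for w in nbr[u] & nbr[v]:
                if w > v:
                    simplices[(u, v, w)] = 0.0
                    triangles.append((u, v, w))
    if max_dim >= 3:
        for u, v, w in triangles:
            for z in nbr[u] & nbr[v] & nbr[w]:
                if z > w:
                    simplices[(u, v, w, z)] = 0.0
    return simplices


def clique_complex_at(
    tl: FlickerTimeline, t: float, max_dim: int = 2
) -> dict[tuple[int, ...], float]:
    """Dimension-capped clique complex of the active link set at time t."""
    return clique_complex(tl.vertices_at(t), tl.active_links(t), max_dim)


def betti_time_series(
    tl: FlickerTimeline, d_max: int = 1, times: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Betti numbers b_0..b_{d_max} of the per-step clique complexes.

    Each per-step complex is the flag complex of the active link set capped
    at simplex dimension ``d_max + 1`` (enough to resolve b_{d_max})."""
    ts = tl.grid() if times is None else np.asarray(times, dtype=float)
    betti = np.array(
        [
            homology.betti_numbers(clique_complex_at(tl, t, d_max + 1), d_max)
            for t in ts
        ],
        dtype=int,
    )
    return ts, betti


def write_betti_series(path, times, betti) -> None:
    with open(path, "w") as fh:
        fh.write("t," + ",".join(f"b{k}" for k in range(betti.shape[1])) + "\n")
        for t, row in zip(times, betti):
            fh.write(f"{t:.6f}," + ",".join(map(str, row)) + "\n")


@dataclass
class LifetimeStats:
    """Lifetime statistics of links (order 2) and triangles (order 3)."""

    lifetimes: dict[int, np.ndarray]  # completed (non-survivor) lifetimes
    tau_e: dict[int, float]  # fitted exponential means
    survivor_fraction: float  # links alive through session end
    mean_reactivation_interval: float  # burst-collapsed mean interval


def _merge_bursts(acts: list[float], merge_window: float) -> list[float]:
    out = []
    for a in acts:
        if not out or a - out[-1] > merge_window:
            out.append(a)
    return out


def _triangle_lifetimes(tl: FlickerTimeline, max_triangles: int = 2000):
    links = set(tl.intervals)
    nbrs: dict[int, set[int]] = {}
    for u, v in links:
        nbrs.setdefault(u, set()).add(v)
        nbrs.setdefault(v, set()).add(u)
    tris = []
    for u, v in sorted(links):
        for w in sorted(nbrs.get(u, set()) & nbrs.get(v, set())):
            if w > v:
                tris.append((u, v, w))
                if len(tris) >= max_triangles:
                    break
        if len(tris) >= max_triangles:
            break
    lifetimes, survivors = [], 0
    for u, v, w in tris:
        ivs = [tl.intervals[e] for e in ((u, v), (u, w), (v, w))]
        # sweep the intersection of three interval unions
        bounds = sorted({b for iv in ivs for b, d in iv} | {d for iv in ivs for b, d in iv})
        active = None
        for i in range(len(bounds) - 1):
            mid = (bounds[i] + bounds[i + 1]) / 2
            alive = all(any(b <= mid < d for b, d in iv) for iv in ivs)
            if alive and active is None:
                active = bounds[i]
            elif not alive and active is not None:
                lifetimes.append(bounds[i] - active)
                active = None
        if active is not None:
            survivors += 1
    return np.asarray(lifetimes), survivors


def lifetime_statistics(
    tl: FlickerTimeline, burst_merge_s: float = 1.0, with_triangles: bool = True
) -> LifetimeStats:
    """Empirical lifetime distributions and fitted effective lifetimes.

    Lifetimes are spans between a birth and the next death of the same
    link/triangle; session-end survivors are excluded from the exponential
    fit and counted separately.  The reactivation interval is measured on
    burst-collapsed activation sequences (activations closer than
    ``burst_merge_s`` count as one visit to the overlap region).
    """
    link_lt, survivors = [], 0
    gaps = []
    for link, ivs in tl.intervals.items():
        for b, d in ivs:
            if d >= tl.duration:
                survivors += 1
            else:
                link_lt.append(d - b)
        merged = _merge_bursts(tl.activations.get(link, []), burst_merge_s)
        gaps.extend(np.diff(merged))
    lifetimes = {2: np.asarray(link_lt)}
    tau_e = {}
    if len(link_lt):
        # MLE of the exponential mean, via scipy's fit with the origin pinned
        tau_e[2] = float(stats.expon.fit(lifetimes[2], floc=0)[1])
    if with_triangles:
        tri_lt, _ = _triangle_lifetimes(tl)
        lifetimes[3] = tri_lt
        if len(tri_lt):
            tau_e[3] = float(stats.expon.fit(tri_lt, floc=0)[1])
    n_stretch = survivors + len(link_lt)
    return LifetimeStats(
        lifetimes=lifetimes,
        tau_e=tau_e,
        survivor_fraction=survivors / n_stretch if n_stretch else 0.0,
        mean_reactivation_interval=float(np.mean(gaps)) if gaps else np.nan,
    )


@dataclass
class StabilitySummary:
    """Topological fluctuation of a Betti time series after map formation."""

    times: np.ndarray
    betti: np.ndarray
    reference: tuple[int, ...]
    formation_time: float
    fluctuation_fraction: float


def stability_summary(
    times: np.ndarray,
    betti: np.ndarray,
    reference: tuple[int, ...],
    formation_time: float,
) -> StabilitySummary:
    """Share of post-formation steps whose (b0, b1) deviate from the
    environment's signature; zero iff the series is constant-correct."""
    times = np.asarray(times, dtype=float)
    betti = np.asarray(betti, dtype=int)
    ref = np.asarray(reference[:2], dtype=int)
    mask = times >= formation_time
    if not mask.any():
        raise ValueError("formation_time beyond the series")
    bad = np.any(betti[mask][:, :2] != ref, axis=1)
    return StabilitySummary(times, betti, tuple(reference), formation_time, float(bad.mean()))


def find_stabilization_threshold(
    values: np.ndarray, fractions: np.ndarray
) -> float | None:
    """Smallest parameter value (tau or latency) with zero fluctuation."""
    values = np.asarray(values, dtype=float)
    fractions = np.asarray(fractions, dtype=float)
    order = np.argsort(values)
    for v, f in zip(values[order], fractions[order]):
        if f == 0:
            return float(v)
    return None


def inject_replays(
    activations: dict[Link, list[float]],
    rate_per_min: float,
    duration: float,
    seed: int | None = None,
) -> dict[Link, list[float]]:
    """Add endogenous reactivation (replay) events at Poisson times, each
    reusing a uniformly sampled link that was already active earlier.
    Rate 0 returns the input unchanged."""
    if rate_per_min < 0:
        raise ValueError("replay rate must be non-negative")
    if rate_per_min == 0:
        return {k: list(v) for k, v in activations.items()}
    rng = np.random.default_rng(seed)
    out = {k: list(v) for k, v in activations.items()}
    links = sorted(out)
    firsts = np.array([out[l][0] for l in links])
    n = rng.poisson(rate_per_min * duration / 60.0)
    for t in np.sort(rng.uniform(0, duration, n)):
        eligible = np.nonzero(firsts < t)[0]
        if len(eligible) == 0:
            continue
        link = links[rng.choice(eligible)]
        out[link].append(float(t))
    for l in out:
        out[l].sort()
    return out
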