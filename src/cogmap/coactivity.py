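"""From spike trains to coactivity events, graphs and filtered complexes.

Two place cells are *coactive* when both fire inside one coactivity window
of width ``w`` (~200 ms physiologically).  Coactivity events feed either

* a **simplex-detection** complex, where a k-simplex appears the first time
  all k+1 cells co-fire inside a single window, or
* a **clique-accumulation** complex, where a clique of the pairwise
  coactivity graph appears once every constituent link has been active
  within a look-back integration window (``integration_window = inf``
  reduces to plain first-appearance accumulation).

Both yield a filtered simplicial complex: simplexes carry first-appearance
times, the filtration is closed under faces and monotone along inclusions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from bisect import bisect_left, bisect_right

import numpy as np
import networkx as nx
from scipy.stats import truncnorm

from .place_cells import PlaceFieldMap, SpikeTrains


@dataclass
class CoactivityConfig:
    """Detection and complex-assembly parameters (times in seconds)."""

    window: float = 0.2  # coactivity window w
    placement: str = "binned"  # "binned" | "sliding"
    step: float | None = None  # sliding step, default w/4
    jitter: float = 0.0  # fractional window-width jitter, in [0, 1)
    shift: bool = False  # random global offset in [0, w)
    k_max: int = 2  # highest coactivity order detected
    integration_window: float = np.inf  # look-back for clique accumulation
    d_max: int = 3  # dimension cap of constructed complexes

    def __post_init__(self):
        if self.window <= 0:
            raise ValueError("window width must be positive")
        if not 0 <= self.jitter < 1:
            raise ValueError("jitter fraction must lie in [0, 1)")
        if self.integration_window < self.window:
            raise ValueError("integration window must be at least one coactivity window")
        if self.d_max < 1:
            raise ValueError("d_max must be at least 1")
        if self.k_max < 2:
            raise ValueError("k_max must be at least 2")
        if self.placement not in ("binned", "sliding"):
            raise ValueError("placement must be 'binned' or 'sliding'")


@dataclass(frozen=True)
class CoactivityEvent:
    cells: tuple[int, ...]  # sorted, distinct, >= 2 ids
    t: float  # window center (s)


def detect_coactivity_events(
    spikes: SpikeTrains, cfg: CoactivityConfig, seed: int | None = None
) -> list[CoactivityEvent]:
    """Scan windows over the session and emit one event per co-firing cell
    subset of size 2..k_max per window.  Jitter perturbs individual window
    widths (uniform in [w(1-j), w(1+j)]); the optional global shift offsets
    the whole partition.  Both are seeded."""
    rng = np.random.default_rng(seed)
    T = spikes.duration
    w = cfg.window
    offset = rng.uniform(0, w) if cfg.shift else 0.0
    if cfg.placement == "binned":
        if cfg.jitter > 0:
            widths = []
            total = T - offset + w
            # draw enough jittered widths to tile the session
            n_guess = int(total / (w * (1 - cfg.jitter))) + 2
            widths = rng.uniform(w * (1 - cfg.jitter), w * (1 + cfg.jitter), n_guess)
            edges = offset + np.concatenate([[0.0], np.cumsum(widths)])
        else:
            edges = offset + np.arange(0.0, T + w, w)
        starts, ends = edges[:-1], edges[1:]
    else:
        step = cfg.step if cfg.step is not None else w / 4
        starts = np.arange(-w + step + offset, T, step)
        ends = starts + w
        if cfg.jitter > 0:
            half = rng.uniform(w * (1 - cfg.jitter), w * (1 + cfg.jitter), len(starts)) / 2
            mid = (starts + ends) / 2
            starts, ends = mid - half, mid + half

    cells = np.concatenate(
        [np.full(len(tr), i, dtype=int) for i, tr in enumerate(spikes.trains)]
        or [np.empty(0, dtype=int)]
    )
    times = np.concatenate([tr for tr in spikes.trains] or [np.empty(0)])
    order = np.argsort(times, kind="stable")
    cells, times = cells[order], times[order]

    events: list[CoactivityEvent] = []
    for s0, s1 in zip(starts, ends):
        lo, hi = np.searchsorted(times, [s0, s1])
        if hi - lo < 2:
            continue
        active = np.unique(cells[lo:hi])
        if len(active) < 2:
            continue
        center = float((s0 + s1) / 2)
        for k in range(2, min(cfg.k_max, len(active)) + 1):
            for combo in itertools.combinations(active.tolist(), k):
                events.append(CoactivityEvent(tuple(combo), center))
    events.sort(key=lambda e: (e.t, e.cells))
    return events


def build_coactivity_graph(
    events: list[CoactivityEvent], duration: float | None = None
) -> nx.Graph:
    """Pairwise coactivity graph.  Vertices carry ``first`` activity times;
    links carry the full activation time list, ``count``, ``first`` and a
    ``rate`` in events/min (when the session length is known)."""
    g = nx.Graph()
    for ev in events:
        if len(ev.cells) != 2:
            continue
        u, v = ev.cells
        for c in (u, v):
            if c not in g:
                g.add_node(c, first=ev.t)
        if g.has_edge(u, v):
            g[u][v]["times"].append(ev.t)
        else:
            g.add_edge(u, v, times=[ev.t])
    for u, v, d in g.edges(data=True):
        d["times"] = sorted(d["times"])
        d["count"] = len(d["times"])
        d["first"] = d["times"][0]
        if duration:
            d["rate"] = d["count"] / (duration / 60.0)
    g.graph["duration"] = duration
    return g


@dataclass
class FilteredComplex:
    """Simplexes with first-appearance (filtration) times.

    Invariants: closed under faces; ``t(face) <= t(coface)``.
    """

    times: dict[tuple[int, ...], float]
    d_max: int = 3

    def __len__(self):
        return len(self.times)

    def simplices(self) -> list[tuple[int, ...]]:
        """Filtration order: time, then dimension, then lexicographic."""
        return sorted(self.times, key=lambda s: (self.times[s], len(s), s))

    def validate(self) -> None:
        for s, t in self.times.items():
            if len(s) < 2:
                continue
            for face in itertools.combinations(s, len(s) - 1):
                if face not in self.times:
                    raise ValueError(f"complex not closed under faces: {face} missing")
                if self.times[face] > t + 1e-12:
                    raise ValueError(f"filtration not monotone at {s}")

    def close_under_faces(self) -> None:
        """Add missing faces, propagating the earliest coface time down.
        One sweep in decreasing dimension reaches the fixpoint; a second
        sweep verifies it (guards against pathological inputs)."""
        changed = True
        while changed:
            changed = False
            for s in sorted(self.times, key=len, reverse=True):
                if len(s) < 2:
                    continue
                t = self.times[s]
                for face in itertools.combinations(s, len(s) - 1):
                    if face not in self.times or self.times[face] > t:
                        self.times[face] = t
                        changed = True

    def subcomplex_at(self, t: float) -> "FilteredComplex":
        return FilteredComplex(
            {s: ts for s, ts in self.times.items() if ts <= t}, self.d_max
        )

    def counts(self) -> dict[int, int]:
        """N_d: number of d-simplexes."""
        out: dict[int, int] = {}
        for s in self.times:
            out[len(s) - 1] = out.get(len(s) - 1, 0) + 1
        return out

    def eta(self, n_cells: int) -> dict[int, float]:
        """Complex saturation ratios eta_d = N_d / C(n_cells, d+1)."""
        from math import comb

        return {
            d: n / comb(n_cells, d + 1)
            for d, n in self.counts().items()
            if d + 1 <= n_cells
        }

    def write(self, path) -> None:
        """One simplex per line: ``t_sigma v0 v1 ... vk``."""
        with open(path, "w") as fh:
            for s in self.simplices():
                fh.write(f"{self.times[s]:.6f} " + " ".join(map(str, s)) + "\n")

    @classmethod
    def read(cls, path, d_max: int = 3) -> "FilteredComplex":
        times: dict[tuple[int, ...], float] = {}
        with open(path) as fh:
            for line in fh:
                parts = line.split()
                if not parts:
                    continue
                t = float(parts[0])
                s = tuple(sorted(int(v) for v in parts[1:]))
                times[s] = min(t, times.get(s, np.inf))
        return cls(times, d_max)


def _clique_accumulation_time(edge_times: list[list[float]], lookback: float) -> float | None:
    """Earliest t by which every link has an activation in [t - lookback, t]."""
    if np.isinf(lookback):
        return max(ts[0] for ts in edge_times)
    candidates = sorted(set(itertools.chain.from_iterable(edge_times)))
    for t in candidates:
        ok = True
        for ts in edge_times:
            i = bisect_right(ts, t)
            if i == 0 or ts[i - 1] < t - lookback:
                ok = False
                break
        if ok:
            return t
    return None


def build_filtered_complex(
    source,
    mode: str = "clique-accumulation",
    cfg: CoactivityConfig | None = None,
) -> FilteredComplex:
    """Assemble a filtered coactivity complex.

    ``mode='simplex-detection'`` takes a list of events (orders up to the
    detection order) and stamps each simplex with its first event time.
    ``mode='clique-accumulation'`` takes a pairwise coactivity graph and
    stamps each clique with its accumulation time under the configured
    integration window.
    """
    cfg = cfg or CoactivityConfig()
    times: dict[tuple[int, ...], float] = {}
    if mode == "simplex-detection":
        for ev in source:
            if len(ev.cells) - 1 > cfg.d_max:
                continue
            if ev.cells not in times:
                times[ev.cells] = ev.t
            for c in ev.cells:
                if (c,) not in times:
                    times[(c,)] = ev.t
        fc = FilteredComplex(times, cfg.d_max)
        fc.close_under_faces()
        return fc
    if mode == "clique-accumulation":
        g: nx.Graph = source
        for v, data in g.nodes(data=True):
            times[(v,)] = data.get("first", 0.0)
        nbr: dict[int, set[int]] = {v: set(g[v]) for v in g}
        lookback = cfg.integration_window
        plain = np.isinf(lookback)

        def stamp(s):
            if plain:
                times[s] = max(g[u][v]["first"] for u, v in itertools.combinations(s, 2))
                return True
            t = _clique_accumulation_time(
                [g[u][v]["times"] for u, v in itertools.combinations(s, 2)], lookback
            )
            if t is None:
                return False
            times[s] = t
            return True

        cliques = [tuple(sorted(e)) for e in g.edges]
        for u, v in cliques:
            stamp((u, v))
        for dim in range(2, cfg.d_max + 1):
            nxt = []
            for s in cliques:
                if s not in times:
                    continue
                common = nbr[s[0]]
                for v in s[1:]:
                    common = common & nbr[v]
                for w in common:
                    if w > s[-1]:
                        cand = s + (w,)
                        if stamp(cand):
                            nxt.append(cand)
            cliques = nxt
        fc = FilteredComplex(times, cfg.d_max)
        fc.close_under_faces()  # guards vertices appearing after their edges
        return fc
    raise ValueError(f"unknown mode {mode!r}")


def select_assembly_subgraph(
    g: nx.Graph, xi: float | None = None, n0: int | None = None
) -> nx.Graph:
    """Cell-assembly selection on the coactivity graph.

    ``xi``: keep links whose activation rate (events/min) exceeds xi.
    ``n0``: for every cell keep its n0 most frequently coactive neighbors
    (union over cells) — a preferential rule that yields heavier-tailed
    degree distributions.  The vertex set is preserved either way.
    """
    if (xi is None) == (n0 is None):
        raise ValueError("specify exactly one of xi, n0")
    out = nx.Graph()
    out.add_nodes_from(g.nodes(data=True))
    out.graph.update(g.graph)
    if xi is not None:
        if xi < 0:
            raise ValueError("xi must be non-negative")
        for u, v, d in g.edges(data=True):
            if d.get("rate", d["count"]) > xi:
                out.add_edge(u, v, **d)
        return out
    if n0 < 1:
        raise ValueError("n0 must be at least 1")
    for u in g.nodes:
        nbrs = sorted(
            g[u].items(), key=lambda kv: (-kv[1]["count"], kv[0])
        )[:n0]
        for v, d in nbrs:
            out.add_edge(u, v, **d)
    return out


@dataclass
class SynapseModel:
    """Stochastic synaptic transmission and readout response.

    Per (assembly, link) transmission probabilities are drawn once from a
    truncated Gaussian on [0, 1] with mode ``p_star`` and spread ``dp``;
    per-assembly readout response probabilities likewise from
    (``q_star``, ``dq``).  Zero spreads give deterministic probabilities.
    """

    p_star: float = 1.0
    dp: float = 0.0
    q_star: float = 1.0
    dq: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        for p in (self.p_star, self.q_star):
            if not 0 <= p <= 1:
                raise ValueError("probability modes must lie in [0, 1]")
        if self.dp < 0 or self.dq < 0:
            raise ValueError("spreads must be non-negative")

    def _draw(self, rng, mode, spread, size):
        if spread == 0:
            return np.full(size, float(mode))
        a, b = (0 - mode) / spread, (1 - mode) / spread
        return truncnorm.rvs(a, b, loc=mode, scale=spread, size=size, random_state=rng)


def apply_synaptic_filter(
    events: list[CoactivityEvent],
    model: SynapseModel,
    assemblies: list[tuple[int, ...]] | None = None,
) -> list[CoactivityEvent]:
    """Pass pairwise coactivity events through the cell-assembly readout.

    Each event must be transmitted across its link (probability p drawn per
    (assembly, link)) and elicit the assembly's readout response (probability
    q per assembly).  A pair belonging to several assemblies survives if any
    of them ignites.  With assemblies omitted, every link is treated as its
    own minimal assembly.  ``p*=q*=1`` with zero spreads is the identity.
    """
    rng = np.random.default_rng(model.seed)
    pairs = sorted({ev.cells for ev in events if len(ev.cells) == 2})
    if assemblies is None:
        # minimal assemblies: one link, one readout each — vectorized path
        p = model._draw(rng, model.p_star, model.dp, len(pairs))
        q = model._draw(rng, model.q_star, model.dq, len(pairs))
        index = {pair: i for i, pair in enumerate(pairs)}
        pair_events = [ev for ev in events if len(ev.cells) == 2]
        idx = np.array([index[ev.cells] for ev in pair_events], dtype=int)
        keep = (rng.random(len(idx)) < p[idx]) & (rng.random(len(idx)) < q[idx])
        return [ev for ev, k in zip(pair_events, keep) if k]
    pair_to_assemblies: dict[tuple[int, int], list[int]] = {}
    link_keys = []
    for ai, asm in enumerate(assemblies):
        for link in itertools.combinations(sorted(asm), 2):
            pair_to_assemblies.setdefault(link, []).append(len(link_keys))
            link_keys.append((ai, link))
    p = model._draw(rng, model.p_star, model.dp, len(link_keys))
    q = model._draw(rng, model.q_star, model.dq, len(assemblies))
    asm_of_link = np.array([ai for ai, _ in link_keys], dtype=int) if link_keys else np.empty(0, int)

    kept: list[CoactivityEvent] = []
    for ev in events:
        if len(ev.cells) != 2:
            continue
        ids = pair_to_assemblies.get(ev.cells)
        if not ids:
            continue
        for li in ids:
            if rng.random() < p[li] and rng.random() < q[asm_of_link[li]]:
                kept.append(ev)
                break
    return kept


def nerve_complex(
    pf: PlaceFieldMap,
    env,
    resolution: float = 2.0,
    d_max: int = 3,
    radius_factor: float = 0.5,
) -> FilteredComplex:
    """Nerve of the place-field cover of the accessible region.

    Each field is taken as the disc of radius ``radius_factor * s_i`` around
    its center; a simplex joins every set of fields (up to ``d_max + 1``)
    whose common overlap meets the accessible region, detected on a dense
    sampling grid.  All filtration times are zero.
    """
    xs = np.arange(resolution / 2, env.width, resolution)
    ys = np.arange(resolution / 2, env.height, resolution)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    pts = pts[env.accessible(pts[:, 0], pts[:, 1])]
    radii = radius_factor * pf.sizes
    times: dict[tuple[int, ...], float] = {}
    d2 = ((pts[:, None, :] - pf.centers[None, :, :]) ** 2).sum(axis=2)
    covered = d2 <= (radii[None, :] ** 2)
    for row in covered:
        active = np.nonzero(row)[0]
        for k in range(1, min(d_max + 2, len(active) + 1)):
            for combo in itertools.combinations(active.tolist(), k):
                times.setdefault(tuple(combo), 0.0)
    return FilteredComplex(times, d_max)
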