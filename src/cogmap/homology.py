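"""Simplicial homology over Z2, persistence, and learning-time extraction.

Betti numbers are computed from boundary-matrix ranks over GF(2)
(b_k = dim ker d_k - dim im d_{k+1}); persistence uses the standard
column-reduction of the boundary matrix in filtration order.  Coefficients
are Z2 throughout, the convention of this literature, which makes the
computation orientation-free.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import inf

import numpy as np

from .coactivity import FilteredComplex
from .environment import Trajectory
from .place_cells import PlaceFieldMap


def _as_simplex_set(source) -> dict[tuple[int, ...], float]:
    if isinstance(source, FilteredComplex):
        return dict(source.times)
    if isinstance(source, dict):
        return {tuple(sorted(s)): t for s, t in source.items()}
    return {tuple(sorted(s)): 0.0 for s in source}


def _check_face_closed(simplices: set[tuple[int, ...]]) -> None:
    for s in simplices:
        if len(s) < 2:
            continue
        for face in itertools.combinations(s, len(s) - 1):
            if face not in simplices:
                raise ValueError(f"complex not closed under faces: missing {face}")


def _gf2_rank(columns: list[set[int]]) -> int:
    """Rank of a sparse GF(2) matrix given as a list of column supports."""
    pivots: dict[int, set[int]] = {}
    rank = 0
    for col in columns:
        col = set(col)
        while col:
            low = max(col)
            if low in pivots:
                col ^= pivots[low]
            else:
                pivots[low] = col
                rank += 1
                break
    return rank


def boundary_columns(
    simplices_k: list[tuple[int, ...]], index_km1: dict[tuple[int, ...], int]
) -> list[set[int]]:
    """Boundary of each k-simplex as the set of its facet indices (Z2)."""
    cols = []
    for s in simplices_k:
        cols.append({index_km1[f] for f in itertools.combinations(s, len(s) - 1)})
    return cols


def betti_numbers(source, d_max: int = 2) -> tuple[int, ...]:
    """Z2 Betti numbers (b_0, ..., b_{d_max}) by Gaussian elimination.

    ``source`` may be a :class:`FilteredComplex`, a dict of simplex -> time,
    or any iterable of vertex tuples; it must be closed under faces.
    """
    times = _as_simplex_set(source)
    simplices = set(times)
    _check_face_closed(simplices)
    by_dim: dict[int, list[tuple[int, ...]]] = {}
    for s in simplices:
        by_dim.setdefault(len(s) - 1, []).append(s)
    ranks: dict[int, int] = {}
    for k in range(1, min(max(by_dim, default=0), d_max + 1) + 1):
        if k not in by_dim:
            ranks[k] = 0
            continue
        index = {s: i for i, s in enumerate(sorted(by_dim.get(k - 1, [])))}
        ranks[k] = _gf2_rank(boundary_columns(sorted(by_dim[k]), index))
    betti = []
    for k in range(d_max + 1):
        nk = len(by_dim.get(k, []))
        betti.append(nk - ranks.get(k, 0) - ranks.get(k + 1, 0))
    return tuple(betti)


@dataclass(frozen=True)
class PersistenceInterval:
    dim: int
    birth: float
    death: float  # inf for immortal classes


@dataclass
class Barcode:
    """Multiset of birth-death intervals of Z2 homology classes."""

    intervals: list[PersistenceInterval]

    def betti_at(self, t: float, d_max: int = 2) -> tuple[int, ...]:
        b = [0] * (d_max + 1)
        for iv in self.intervals:
            if iv.dim <= d_max and iv.birth <= t < iv.death:
                b[iv.dim] += 1
        return tuple(b)

    def in_dim(self, dim: int) -> list[PersistenceInterval]:
        return [iv for iv in self.intervals if iv.dim == dim]

    def event_times(self) -> list[float]:
        ts = {iv.birth for iv in self.intervals}
        ts |= {iv.death for iv in self.intervals if np.isfinite(iv.death)}
        return sorted(ts)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("dim,birth,death\n")
            for iv in self.intervals:
                death = "inf" if np.isinf(iv.death) else f"{iv.death:.6f}"
                fh.write(f"{iv.dim},{iv.birth:.6f},{death}\n")

    @classmethod
    def read(cls, path) -> "Barcode":
        intervals = []
        with open(path) as fh:
            next(fh)
            for line in fh:
                d, b, dth = line.strip().split(",")
                intervals.append(
                    PersistenceInterval(int(d), float(b), float(dth))
                )
        return cls(intervals)


def persistence_barcode(fc: FilteredComplex, d_max: int = 2) -> Barcode:
    """Persistent Z2 homology of the first-appearance filtration.

    Standard boundary-matrix column reduction in filtration order (ties
    broken by dimension, then lexicographically).  Zero-length intervals are
    discarded.  Simplexes of dimension above ``d_max + 1`` are ignored; they
    cannot affect classes of dimension <= d_max.
    """
    times = fc.times
    order = [s for s in fc.simplices() if len(s) - 1 <= d_max + 1]
    for s in order:
        if len(s) >= 2:
            for f in itertools.combinations(s, len(s) - 1):
                if times[f] > times[s] + 1e-12:
                    raise ValueError(f"non-monotone filtration at {s}")
    index = {s: i for i, s in enumerate(order)}
    pivot: dict[int, set[int]] = {}
    pivot_owner: dict[int, int] = {}
    creators: set[int] = set()
    intervals: list[PersistenceInterval] = []
    for i, s in enumerate(order):
        if len(s) == 1:
            creators.add(i)
            continue
        col = {index[f] for f in itertools.combinations(s, len(s) - 1)}
        while col:
            low = max(col)
            if low in pivot:
                col ^= pivot[low]
            else:
                break
        if col:
            low = max(col)
            pivot[low] = col
            pivot_owner[low] = i
            creators.discard(low)
            birth, death = times[order[low]], times[s]
            if death > birth:
                intervals.append(PersistenceInterval(len(order[low]) - 1, birth, death))
        else:
            creators.add(i)
    for i in creators:
        dim = len(order[i]) - 1
        if dim <= d_max:
            intervals.append(PersistenceInterval(dim, times[order[i]], inf))
    intervals.sort(key=lambda iv: (iv.dim, iv.birth, iv.death))
    return Barcode(intervals)


@dataclass
class LearningResult:
    """Outcome of topological learning against a reference Betti signature."""

    t_min: float | None
    success: bool
    times: np.ndarray  # Betti timeline sample points (simplex arrival times)
    betti: np.ndarray  # shape (len(times), d_checked)


def learning_time(
    source: FilteredComplex | Barcode,
    reference: tuple[int, ...],
    horizon: float | None = None,
    d_check: int = 2,
) -> LearningResult:
    """Minimal time after which (b0, b1) match the reference and stay matched.

    The Betti timeline is evaluated at every simplex-arrival time (the only
    moments it can change).  ``reference`` gives the environment's signature;
    only its first ``d_check`` entries gate success (planar environments are
    judged on b0 and b1).  ``success=False`` if the match is never attained
    or the final complex is wrong.
    """
    bc = source if isinstance(source, Barcode) else persistence_barcode(source, d_max=d_check)
    ref = tuple(reference[:d_check])
    ts = bc.event_times()
    if horizon is not None:
        ts = [t for t in ts if t <= horizon] + [horizon]
    if not ts:
        return LearningResult(None, False, np.empty(0), np.empty((0, d_check)))
    betti = np.array([bc.betti_at(t, d_max=d_check - 1) for t in ts], dtype=int)
    ok = np.all(betti == np.array(ref, dtype=int), axis=1)
    if not ok[-1]:
        return LearningResult(None, False, np.asarray(ts), betti)
    # longest correct suffix
    idx = len(ok) - 1
    while idx > 0 and ok[idx - 1]:
        idx -= 1
    return LearningResult(float(ts[idx]), True, np.asarray(ts), betti)


@dataclass
class SimplicialPath:
    """Chain of maximal coactivity simplexes traced along a trajectory."""

    simplices: list[tuple[int, ...]]
    entry_times: list[float]
    closed: bool
    contiguity: float  # fraction of consecutive pairs sharing a vertex


def simplicial_path(
    traj: Trajectory, pf: PlaceFieldMap, radius_factor: float = 0.5
) -> SimplicialPath:
    """Sequence of distinct maximal simplexes (sets of fields containing the
    animal) entered along the trajectory.  Fields are the discs of radius
    ``radius_factor * s_i``.  Empty if the path never meets a field."""
    pos = traj.positions
    d2 = ((pos[:, None, :] - pf.centers[None, :, :]) ** 2).sum(axis=2)
    inside = d2 <= (radius_factor * pf.sizes[None, :]) ** 2
    sims: list[tuple[int, ...]] = []
    entry: list[float] = []
    for k in range(len(pos)):
        active = tuple(np.nonzero(inside[k])[0].tolist())
        if not active:
            continue
        if sims and sims[-1] == active:
            continue
        sims.append(active)
        entry.append(float(traj.times[k]))
    if not sims:
        return SimplicialPath([], [], False, 0.0)
    shared = [
        bool(set(a) & set(b)) for a, b in zip(sims[:-1], sims[1:])
    ]
    contiguity = float(np.mean(shared)) if shared else 1.0
    return SimplicialPath(sims, entry, closed=sims[0] == sims[-1], contiguity=contiguity)


def alexandrov_neighborhood(source, simplex) -> set[tuple[int, ...]]:
    """All cofaces of ``simplex`` (itself included): its neighborhood basis in
    the finite Alexandrov topology on the complex's simplexes."""
    simplices = set(_as_simplex_set(source))
    s = tuple(sorted(simplex))
    if s not in simplices:
        raise KeyError(f"simplex {s} not in complex")
    ss = set(s)
    return {c for c in simplices if ss.issubset(c)}


def euler_characteristic(source) -> int:
    times = _as_simplex_set(source)
    return sum((-1) ** (len(s) - 1) for s in times)
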