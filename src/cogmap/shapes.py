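"""Reference triangulations with known Betti signatures.

Used as exact analytic fixtures for the homology engine: a minimal 7-vertex
torus, the octahedron boundary (a triangulated 2-sphere), a square annulus,
and boundaries of simplexes (spheres of any dimension).
"""

from __future__ import annotations

import itertools


def close_under_faces(maximal) -> dict[tuple[int, ...], float]:
    """All faces of the given maximal simplexes, filtration time zero."""
    out: dict[tuple[int, ...], float] = {}
    for s in maximal:
        s = tuple(sorted(s))
        for k in range(1, len(s) + 1):
            for face in itertools.combinations(s, k):
                out[face] = 0.0
    return out


def torus_minimal() -> dict[tuple[int, ...], float]:
    """Csaszar's 7-vertex triangulation of the 2-torus: 21 edges, 14
    triangles, Euler characteristic 0, Betti (1, 2, 1)."""
    tris = [tuple(sorted(((i) % 7, (i + 1) % 7, (i + 3) % 7))) for i in range(7)]
    tris += [tuple(sorted(((i) % 7, (i + 2) % 7, (i + 3) % 7))) for i in range(7)]
    return close_under_faces(tris)


def octahedron() -> dict[tuple[int, ...], float]:
    """Boundary of the octahedron: 6 vertices, 12 edges, 8 triangles;
    a triangulated 2-sphere, Betti (1, 0, 1)."""
    tris = [(i, j, k) for i in (0, 1) for j in (2, 3) for k in (4, 5)]
    return close_under_faces(tris)


def annulus() -> dict[tuple[int, ...], float]:
    """Square annulus: outer corners 0-3, inner corners 4-7, eight triangles
    around the removed center; Betti (1, 1)."""
    tris = []
    for i in range(4):
        a, b = i, (i + 1) % 4
        tris.append((a, b, 4 + i))
        tris.append((b, 4 + i, 4 + (i + 1) % 4))
    return close_under_faces(tris)


def simplex_boundary(d: int) -> dict[tuple[int, ...], float]:
    """Boundary of the (d+1)-simplex: a triangulated d-sphere."""
    verts = tuple(range(d + 2))
    return close_under_faces(itertools.combinations(verts, d + 1))


def solid_simplex(d: int) -> dict[tuple[int, ...], float]:
    """The full d-simplex with all faces; contractible."""
    return close_under_faces([tuple(range(d + 1))])
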