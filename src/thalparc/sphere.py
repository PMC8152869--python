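"""Icosphere tessellation of the unit sphere with solid-angle quadrature weights.

The tessellation is used both to evaluate fiber orientation distributions
(FODs) as spherical functions and to integrate them over lobes.  A subdivided
icosahedron gives near-uniform coverage; because the icosahedron's vertex set
is antipodally symmetric and midpoint subdivision preserves that symmetry,
every direction appears together with its antipode, which is what the
even-order (antipodally symmetric) FOD model requires.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

_PHI = (1.0 + np.sqrt(5.0)) / 2.0


def _icosahedron() -> tuple[np.ndarray, np.ndarray]:
    v = np.array(
        [
            [-1, _PHI, 0], [1, _PHI, 0], [-1, -_PHI, 0], [1, -_PHI, 0],
            [0, -1, _PHI], [0, 1, _PHI], [0, -1, -_PHI], [0, 1, -_PHI],
            [_PHI, 0, -1], [_PHI, 0, 1], [-_PHI, 0, -1], [-_PHI, 0, 1],
        ],
        dtype=float,
    )
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    f = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ],
        dtype=int,
    )
    return v, f


def _subdivide(verts: np.ndarray, faces: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split each triangle into four, projecting midpoints onto the sphere."""
    verts = list(map(tuple, verts))
    index = {v: i for i, v in enumerate(verts)}
    cache: dict[tuple[int, int], int] = {}

    def midpoint(i: int, j: int) -> int:
        key = (min(i, j), max(i, j))
        if key in cache:
            return cache[key]
        m = np.asarray(verts[i]) + np.asarray(verts[j])
        m /= np.linalg.norm(m)
        m = tuple(m)
        if m not in index:
            index[m] = len(verts)
            verts.append(m)
        cache[key] = index[m]
        return cache[key]

    new_faces = []
    for a, b, c in faces:
        ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
        new_faces += [[a, ab, ca], [ab, b, bc], [ca, bc, c], [ab, bc, ca]]
    return np.asarray(verts, dtype=float), np.asarray(new_faces, dtype=int)


def _triangle_solid_angles(verts: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Spherical-triangle solid angles (Van Oosterom & Strackee)."""
    a = verts[faces[:, 0]]
    b = verts[faces[:, 1]]
    c = verts[faces[:, 2]]
    num = np.abs(np.einsum("ij,ij->i", a, np.cross(b, c)))
    den = (
        1.0
        + np.einsum("ij,ij->i", a, b)
        + np.einsum("ij,ij->i", b, c)
        + np.einsum("ij,ij->i", c, a)
    )
    return 2.0 * np.arctan2(num, den)


@dataclass(frozen=True)
class SphereMesh:
    """Unit-sphere sample set with quadrature weights and adjacency.

    Attributes
    ----------
    vertices : (n, 3) unit direction vectors, antipodally symmetric as a set.
    weights : (n,) per-vertex solid angles (a third of each adjacent triangle);
        they sum to 4*pi.
    neighbors : (n, max_degree) vertex adjacency, padded with the vertex's own
        index, used for mesh-local maxima detection.
    """

    vertices: np.ndarray
    weights: np.ndarray
    neighbors: np.ndarray

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    def integrate(self, values: np.ndarray) -> np.ndarray:
        """Quadrature integral over the full sphere (last axis = vertices)."""
        return np.asarray(values) @ self.weights


@lru_cache(maxsize=8)
def icosphere(subdivisions: int = 4) -> SphereMesh:
    """Build the subdivided icosahedron mesh.

    ``subdivisions=4`` gives 2562 directions (1281 per half-sphere), dense
    enough that every lobe of an lmax=6 FOD contains well over 5 samples.
    """
    verts, faces = _icosahedron()
    for _ in range(subdivisions):
        verts, faces = _subdivide(verts, faces)
    areas = _triangle_solid_angles(verts, faces)

    weights = np.zeros(len(verts))
    for corner in range(3):
        np.add.at(weights, faces[:, corner], areas / 3.0)

    degree = np.zeros(len(verts), dtype=int)
    pairs = set()
    for a, b, c in faces:
        pairs.update({(a, b), (b, a), (b, c), (c, b), (c, a), (a, c)})
    for i, _ in pairs:
        degree[i] += 1
    neighbors = np.repeat(np.arange(len(verts))[:, None], degree.max(), axis=1)
    fill = np.zeros(len(verts), dtype=int)
    for i, j in sorted(pairs):
        neighbors[i, fill[i]] = j
        fill[i] += 1
    return SphereMesh(vertices=verts, weights=weights, neighbors=neighbors)
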