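"""Deterministic direction sets on the sphere.

Two generators: subdivided-icosahedron hemispheres (the coarse/fine axis
grids of the multi-resolution discrete search; 321 and 1,281 axes at
subdivision levels 3 and 4) and a spherical Fibonacci spiral (the
simulated 90-direction acquisition table).
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

__all__ = ["icosphere_hemisphere", "fibonacci_directions"]


def _icosahedron() -> tuple[np.ndarray, np.ndarray]:
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array(
        [
            [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
            [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
            [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
        ],
        dtype=float,
    )
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    faces = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ]
    )
    return verts, faces


def _subdivide(verts: np.ndarray, faces: np.ndarray):
    verts = list(verts)
    midpoint: dict[tuple[int, int], int] = {}

    def mid(i: int, j: int) -> int:
        key = (i, j) if i < j else (j, i)
        if key not in midpoint:
            v = verts[i] + verts[j]
            verts.append(v / np.linalg.norm(v))
            midpoint[key] = len(verts) - 1
        return midpoint[key]

    new_faces = []
    for a, b, c in faces:
        ab, bc, ca = mid(a, b), mid(b, c), mid(c, a)
        new_faces += [[a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca]]
    return np.array(verts), np.array(new_faces)


@lru_cache(maxsize=8)
def icosphere_hemisphere(subdivisions: int) -> np.ndarray:
    """Unit axes covering one hemisphere of a subdivided icosahedron.

    One representative of each antipodal vertex pair is kept, so the set
    samples the space of *axes* (orientations without sign).  Levels 3
    and 4 give 321 and 1,281 axes.
    """
    verts, faces = _icosahedron()
    for _ in range(subdivisions):
        verts, faces = _subdivide(verts, faces)
    # keep z>0 hemisphere; resolve the z=0 ring by x then y sign
    keep = (verts[:, 2] > 1e-9) | (
        (np.abs(verts[:, 2]) <= 1e-9)
        & ((verts[:, 0] > 1e-9) | ((np.abs(verts[:, 0]) <= 1e-9) & (verts[:, 1] > 0)))
    )
    return verts[keep]


def fibonacci_directions(n: int) -> np.ndarray:
    """``n`` unit vectors on a spherical Fibonacci spiral (deterministic)."""
    i = np.arange(n, dtype=float) + 0.5
    golden = (1.0 + np.sqrt(5.0)) / 2.0
    theta = np.arccos(1.0 - 2.0 * i / n)
    phi = 2.0 * np.pi * i / golden
    return np.stack(
        [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)],
        axis=1,
    )
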