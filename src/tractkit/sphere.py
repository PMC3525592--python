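"""Deterministic sphere samplings for ODF evaluation and maxima extraction.

Uses a geodesic subdivision of the icosahedron: each face is split into
``freq``^2 triangles and the vertices projected to the unit sphere, giving
``10*freq^2 + 2`` near-uniform samples.  The icosahedron is antipodally
symmetric, and the subdivision preserves that symmetry, so every sample's
antipode is also a sample — the property ODFs (which are even functions)
require.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_PHI = (1.0 + np.sqrt(5.0)) / 2.0

_ICO_VERTS = np.array(
    [
        (-1, _PHI, 0), (1, _PHI, 0), (-1, -_PHI, 0), (1, -_PHI, 0),
        (0, -1, _PHI), (0, 1, _PHI), (0, -1, -_PHI), (0, 1, -_PHI),
        (_PHI, 0, -1), (_PHI, 0, 1), (-_PHI, 0, -1), (-_PHI, 0, 1),
    ],
    dtype=float,
)

_ICO_FACES = [
    (0, 11, 5), (0, 5, 1), (0, 1, 7), (0, 7, 10), (0, 10, 11),
    (1, 5, 9), (5, 11, 4), (11, 10, 2), (10, 7, 6), (7, 1, 8),
    (3, 9, 4), (3, 4, 2), (3, 2, 6), (3, 6, 8), (3, 8, 9),
    (4, 9, 5), (2, 4, 11), (6, 2, 10), (8, 6, 7), (9, 8, 1),
]


@dataclass(frozen=True)
class Sphere:
    """Unit-vector sample set with an angular neighbour graph.

    ``neighbours[i]`` lists the indices within ``cap_angle_deg`` of sample
    ``i`` (excluding ``i`` itself); ``antipode[i]`` is the index of ``-v_i``.
    """

    vertices: np.ndarray
    neighbours: tuple
    antipode: np.ndarray
    cap_angle_deg: float

    @property
    def n(self) -> int:
        return len(self.vertices)


def icosphere_vertices(freq: int = 6) -> np.ndarray:
    """Vertices of the frequency-``freq`` geodesic icosahedron (10*freq^2+2)."""
    if freq < 1:
        raise ValueError("freq must be >= 1")
    verts = _ICO_VERTS / np.linalg.norm(_ICO_VERTS, axis=1, keepdims=True)
    points = []
    for (a, b, c) in _ICO_FACES:
        va, vb, vc = verts[a], verts[b], verts[c]
        for i in range(freq + 1):
            for j in range(freq + 1 - i):
                k = freq - i - j
                p = (i * va + j * vb + k * vc) / freq
                points.append(p / np.linalg.norm(p))
    points = np.asarray(points)
    # dedupe shared edge/vertex samples
    key = np.round(points, 9)
    _, idx = np.unique(key, axis=0, return_index=True)
    points = points[np.sort(idx)]
    return points


def make_sphere(freq: int = 6, cap_angle_deg: float | None = None) -> Sphere:
    """Build the default ODF sampling sphere (freq 6 -> 362 samples).

    ``cap_angle_deg`` defaults to 1.6x the median nearest-neighbour angle,
    which connects each sample to its ~6 surrounding samples.
    """
    verts = icosphere_vertices(freq)
    n = len(verts)
    dots = np.clip(verts @ verts.T, -1.0, 1.0)
    ang = np.degrees(np.arccos(dots))
    np.fill_diagonal(ang, np.inf)
    if cap_angle_deg is None:
        cap_angle_deg = 1.6 * float(np.median(ang.min(axis=1)))
    neighbours = tuple(
        tuple(np.flatnonzero(ang[i] <= cap_angle_deg)) for i in range(n)
    )
    anti = np.empty(n, dtype=int)
    for i in range(n):
        d = np.linalg.norm(verts + verts[i], axis=1)
        anti[i] = int(np.argmin(d))
        if d[anti[i]] > 1e-6:
            raise ValueError("sampling is not antipodally symmetric")
    return Sphere(verts, neighbours, anti, float(cap_angle_deg))
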