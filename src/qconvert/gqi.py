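"""Generalized q-sampling (GQI) reconstruction.

GQI expresses the spin distribution function (SDF) Ψ — the density of
diffusing spins per orientation — as a linear transform of the measured
diffusion signals w:

    Ψ = A · w,      A[j, i] = sinc( σ · sqrt(6 · D · b_i) · ⟨b̂_i, û_j⟩ )

where b_i (s/mm^2) and b̂_i come from the acquisition b-table, û_j are
the ODF sampling directions, σ is a dimensionless length ratio that sets
the diffusion-displacement detection radius, and D (mm^2/s) is the free
water diffusivity.  ``sinc`` here is the *unnormalized* sin(x)/x with
sinc(0) = 1 — not numpy's sin(pi x)/(pi x).

The SDF is stored on one hemisphere: sinc is even, so Ψ is antipodally
symmetric by construction, and consumers needing full-sphere values
mirror it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .schemes import BTable

__all__ = [
    "DEFAULT_SIGMA",
    "DEFAULT_DIFFUSIVITY",
    "DEFAULT_SUBDIVISION",
    "ODFSampling",
    "GQIBasis",
    "make_odf_directions",
    "build_gqi_matrix",
    "compute_sdf",
]

#: Default length ratio σ (dimensionless).
DEFAULT_SIGMA = 1.25
#: Default free-water diffusivity D, mm^2/s, body temperature.
DEFAULT_DIFFUSIVITY = 2.5e-3
#: Default icosphere subdivision: 10*8^2+2 = 642 vertices, 321 hemisphere
#: directions, over-determining the conversion to 252/256-direction shells.
DEFAULT_SUBDIVISION = 8


@dataclass(frozen=True)
class ODFSampling:
    """Hemisphere ODF sampling directions with mesh adjacency.

    ``directions`` holds one unit vector per antipodal vertex pair of a
    subdivided icosahedron; ``adjacency[j]`` lists the hemisphere indices
    of the mesh neighbours of û_j (neighbours of the antipode included,
    so peak finding sees the full-sphere neighbourhood).
    """

    directions: np.ndarray
    adjacency: tuple

    @property
    def n_dirs(self) -> int:
        return int(self.directions.shape[0])


@dataclass(frozen=True)
class GQIBasis:
    """The GQI matrix A for one b-table and ODF sampling."""

    matrix: np.ndarray  # (n_odf_dirs, n_volumes)
    sigma: float
    diffusivity: float
    btable: BTable
    odf: ODFSampling


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


def _subdivide(verts: np.ndarray, faces: np.ndarray, k: int):
    """k-fold edge subdivision of a triangle mesh, vertices on the sphere.

    Each face is split into k^2 triangles; duplicated vertices along
    shared edges are merged by coordinate rounding.  For the icosahedron
    this yields the classic 10k^2 + 2 vertex count.
    """
    vert_map: dict[tuple, int] = {}
    new_verts: list[np.ndarray] = []
    new_faces: list[tuple[int, int, int]] = []

    def add_vertex(p: np.ndarray) -> int:
        p = p / np.linalg.norm(p)
        key = tuple(np.round(p, 9))
        idx = vert_map.get(key)
        if idx is None:
            idx = len(new_verts)
            vert_map[key] = idx
            new_verts.append(p)
        return idx

    for a, b, c in faces:
        va, vb, vc = verts[a], verts[b], verts[c]
        # barycentric lattice rows: row i has i+1 points
        grid = [
            [
                add_vertex(va * (k - i) + vb * (i - j) + vc * j)
                for j in range(i + 1)
            ]
            for i in range(k + 1)
        ]
        for i in range(k):
            for j in range(i + 1):
                new_faces.append((grid[i][j], grid[i + 1][j], grid[i + 1][j + 1]))
                if j < i:
                    new_faces.append((grid[i][j], grid[i + 1][j + 1], grid[i][j + 1]))
    return np.asarray(new_verts), np.asarray(new_faces)


def make_odf_directions(subdivision: int = DEFAULT_SUBDIVISION) -> ODFSampling:
    """Hemisphere ODF sampling from a ``subdivision``-fold subdivided icosahedron.

    The full sphere has ``10*subdivision**2 + 2`` vertices; the
    icosahedron is centrally symmetric, so vertices pair up antipodally
    and the hemisphere keeps ``5*subdivision**2 + 1`` of them (canonical
    representative: z > 0, else z = 0 and y > 0, else z = y = 0 and
    x > 0).
    """
    if subdivision < 1:
        raise ValueError("subdivision must be >= 1")
    verts, faces = _icosahedron()
    if subdivision > 1:
        verts, faces = _subdivide(verts, faces, subdivision)

    # canonical hemisphere representative per antipodal pair
    canonical = (verts[:, 2] > 1e-9) | (
        (np.abs(verts[:, 2]) <= 1e-9)
        & ((verts[:, 1] > 1e-9) | ((np.abs(verts[:, 1]) <= 1e-9) & (verts[:, 0] > 0)))
    )
    hemi_idx = np.flatnonzero(canonical)
    hemi = verts[hemi_idx]
    # map every full-sphere vertex to its hemisphere index
    key_of = {tuple(np.round(v, 6)): i for i, v in enumerate(hemi)}
    full_to_hemi = np.empty(len(verts), dtype=int)
    for i, v in enumerate(verts):
        k = tuple(np.round(v, 6))
        if k in key_of:
            full_to_hemi[i] = key_of[k]
        else:
            full_to_hemi[i] = key_of[tuple(np.round(-v, 6))]

    adjacency = [set() for _ in range(len(hemi))]
    for a, b, c in faces:
        for u, v in ((a, b), (b, c), (c, a)):
            hu, hv = full_to_hemi[u], full_to_hemi[v]
            if hu != hv:
                adjacency[hu].add(hv)
                adjacency[hv].add(hu)
    adjacency = tuple(tuple(sorted(s)) for s in adjacency)
    return ODFSampling(hemi, adjacency)


def sinc(x: np.ndarray) -> np.ndarray:
    """Unnormalized sinc: sin(x)/x with sinc(0) = 1."""
    return np.sinc(np.asarray(x) / np.pi)


def build_gqi_matrix(
    btable: BTable,
    odf: ODFSampling,
    sigma: float = DEFAULT_SIGMA,
    diffusivity: float = DEFAULT_DIFFUSIVITY,
) -> GQIBasis:
    """GQI matrix A with A[j, i] = sinc(σ sqrt(6 D b_i) ⟨b̂_i, û_j⟩)."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if diffusivity <= 0:
        raise ValueError("diffusivity must be positive")
    length = sigma * np.sqrt(6.0 * diffusivity * btable.bvalues)  # (n_vols,)
    cosines = odf.directions @ btable.directions.T  # (n_odf, n_vols)
    matrix = sinc(length[None, :] * cosines)
    return GQIBasis(matrix, float(sigma), float(diffusivity), btable, odf)


def compute_sdf(basis: GQIBasis, signals: np.ndarray) -> np.ndarray:
    """Spin distribution functions Ψ = A·w for each voxel.

    ``signals`` has volumes on the last axis; the result replaces that
    axis by the ODF directions.  Linear in the signals.
    """
    signals = np.asarray(signals, dtype=float)
    if signals.shape[-1] != basis.matrix.shape[1]:
        raise ValueError(
            f"signals have {signals.shape[-1]} volumes, basis expects "
            f"{basis.matrix.shape[1]}"
        )
    return signals @ basis.matrix.T
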