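"""Diffusion acquisition schemes (b-tables): I/O, generation, gradient-deviation handling.

A *b-table* pairs every volume of a 4D diffusion acquisition with a
diffusion weighting ``b`` (s/mm^2) and a unit gradient direction
(b-vector, image coordinate frame).  Three families of schemes are
modelled:

* single-shell HARDI — one nonzero b-value, many directions;
* multi-shell — several shells, each with its own b-value and direction set;
* DSI — a Cartesian q-space grid, giving a range of b-values up to ``b_max``.

Directions for shell schemes are generated quasi-uniformly on the
hemisphere (antipodally equivalent) by spherical-Fibonacci initialisation
followed by a fixed number of electrostatic-repulsion iterations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from pathlib import Path

import numpy as np

__all__ = [
    "B0_THRESHOLD",
    "BTable",
    "GradientDeviationField",
    "load_btable",
    "save_btable",
    "make_single_shell_scheme",
    "make_multishell_scheme",
    "make_dsi_scheme",
    "apply_gradient_deviation",
]

#: b-values below this (s/mm^2) are treated as b=0; scanner tables often
#: carry small nonzero values on their "b0" volumes.
B0_THRESHOLD = 50.0


class BTableError(ValueError):
    """Malformed or inconsistent b-table."""


@dataclass(frozen=True)
class BTable:
    """Per-volume diffusion weighting: b-values and unit gradient directions.

    Parameters
    ----------
    bvalues : (N,) array
        Diffusion weighting per volume, s/mm^2, non-negative.
    directions : (N, 3) array
        Unit gradient directions in the image frame.  Volumes with
        b < `B0_THRESHOLD` may carry the zero vector.
    """

    bvalues: np.ndarray
    directions: np.ndarray

    def __post_init__(self) -> None:
        bvals = np.atleast_1d(np.asarray(self.bvalues, dtype=float))
        dirs = np.asarray(self.directions, dtype=float).reshape(-1, 3)
        if bvals.shape[0] != dirs.shape[0]:
            raise BTableError(
                f"{bvals.shape[0]} b-values but {dirs.shape[0]} directions"
            )
        if np.any(bvals < 0):
            raise BTableError("negative b-value")
        norms = np.linalg.norm(dirs, axis=1)
        dwi = bvals >= B0_THRESHOLD
        if np.any(np.abs(norms[dwi] - 1.0) > 1e-6):
            raise BTableError("non-unit direction on a diffusion-weighted volume")
        object.__setattr__(self, "bvalues", bvals)
        object.__setattr__(self, "directions", dirs)

    @property
    def n_volumes(self) -> int:
        return int(self.bvalues.shape[0])

    @property
    def b0_mask(self) -> np.ndarray:
        """Boolean mask of b=0 volumes (b below `B0_THRESHOLD`)."""
        return self.bvalues < B0_THRESHOLD

    @property
    def dwi_mask(self) -> np.ndarray:
        return ~self.b0_mask

    def subset(self, index: np.ndarray) -> "BTable":
        return BTable(self.bvalues[index], self.directions[index])

    def __eq__(self, other: object) -> bool:  # value equality, used in caching
        if not isinstance(other, BTable):
            return NotImplemented
        return (
            self.bvalues.shape == other.bvalues.shape
            and np.array_equal(self.bvalues, other.bvalues)
            and np.array_equal(self.directions, other.directions)
        )


@dataclass(frozen=True)
class GradientDeviationField:
    """Per-voxel 3x3 gradient-deviation matrices G.

    ``matrices`` has shape ``grid_shape + (3, 3)``; the identity matrix
    means no deviation.  Component order on disk (9-component NIfTI) is
    row-major (Gxx, Gxy, Gxz, Gyx, ...), the HCP convention.
    """

    matrices: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrices, dtype=float)
        if m.shape[-2:] != (3, 3):
            raise ValueError(f"expected trailing (3, 3) shape, got {m.shape}")
        if not np.all(np.isfinite(m)):
            raise ValueError("non-finite gradient-deviation entries")
        object.__setattr__(self, "matrices", m)

    @property
    def grid_shape(self) -> tuple:
        return self.matrices.shape[:-2]

    @classmethod
    def from_flat(cls, flat: np.ndarray) -> "GradientDeviationField":
        """Build from a ``grid + (9,)`` row-major component array."""
        flat = np.asarray(flat, dtype=float)
        return cls(flat.reshape(flat.shape[:-1] + (3, 3)))


def _parse_numeric_rows(path) -> list[list[float]]:
    rows = []
    text = Path(path).read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        try:
            rows.append([float(tok) for tok in line.replace(",", " ").split()])
        except ValueError as exc:
            raise BTableError(f"non-numeric token in {path}: {exc}") from exc
    return rows


def _normalize_table(bvals: np.ndarray, dirs: np.ndarray) -> BTable:
    bvals = np.asarray(bvals, dtype=float)
    dirs = np.asarray(dirs, dtype=float).reshape(-1, 3).copy()
    norms = np.linalg.norm(dirs, axis=1)
    nz = norms > 0
    dirs[nz] /= norms[nz, None]
    dirs[bvals < B0_THRESHOLD] = 0.0
    if np.any((bvals >= B0_THRESHOLD) & ~nz):
        raise BTableError("zero direction on a diffusion-weighted volume")
    return BTable(bvals, dirs)


def load_btable(bval_path, bvec_path=None) -> BTable:
    """Load a b-table from FSL bval/bvec files or a 4-column text file.

    With two arguments, reads the FSL dialect: ``bval_path`` holds one
    whitespace-separated row of b-values and ``bvec_path`` three rows
    (x, y, z) of N columns each.  With a single argument, reads the
    4-column dialect, one ``b x y z`` row per volume.  Directions are
    renormalized to unit length; vectors paired with b=0 are forced to
    the zero vector.
    """
    if bvec_path is None:
        rows = _parse_numeric_rows(bval_path)
        if not rows:
            return BTable(np.zeros(0), np.zeros((0, 3)))
        if any(len(r) != 4 for r in rows):
            raise BTableError(f"{bval_path}: expected 4 columns (b x y z) per row")
        arr = np.asarray(rows, dtype=float)
        return _normalize_table(arr[:, 0], arr[:, 1:4])

    bval_rows = _parse_numeric_rows(bval_path)
    bvec_rows = _parse_numeric_rows(bvec_path)
    bvals = np.asarray([v for row in bval_rows for v in row], dtype=float)
    if len(bvec_rows) not in (0, 3):
        raise BTableError(f"{bvec_path}: expected 3 rows, got {len(bvec_rows)}")
    if not bvec_rows:
        dirs = np.zeros((0, 3))
    else:
        if len({len(r) for r in bvec_rows}) > 1:
            raise BTableError(f"{bvec_path}: ragged rows")
        dirs = np.asarray(bvec_rows, dtype=float).T
    if bvals.shape[0] != dirs.shape[0]:
        raise BTableError(
            f"{bvals.shape[0]} b-values but {dirs.shape[0]} b-vectors"
        )
    return _normalize_table(bvals, dirs)


def save_btable(btable: BTable, bval_path, bvec_path) -> None:
    """Write FSL bval/bvec files (column i corresponds to 4D volume i)."""
    with open(bval_path, "w") as fh:
        fh.write(" ".join(f"{b:.6f}" for b in btable.bvalues) + "\n")
    with open(bvec_path, "w") as fh:
        for axis in range(3):
            fh.write(" ".join(f"{d:.8f}" for d in btable.directions[:, axis]) + "\n")


def _fibonacci_hemisphere(n: int) -> np.ndarray:
    """Spherical-Fibonacci points on the upper hemisphere."""
    i = np.arange(n) + 0.5
    z = i / n  # (0, 1): upper hemisphere
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _repel_hemisphere(points: np.ndarray, n_iter: int = 120, step: float = 5e-3) -> np.ndarray:
    """Electrostatic-repulsion refinement with antipodal symmetry.

    Each point interacts with every other point and with every antipode,
    so minimising energy spreads directions uniformly on the projective
    sphere.  Fixed iteration count keeps the result deterministic.
    """
    p = points.copy()
    n = len(p)
    for _ in range(n_iter):
        diff_p = p[:, None, :] - p[None, :, :]
        diff_m = p[:, None, :] + p[None, :, :]
        d2_p = np.sum(diff_p**2, axis=-1)
        d2_m = np.sum(diff_m**2, axis=-1)
        np.fill_diagonal(d2_p, np.inf)
        d2_m[d2_m < 1e-12] = np.inf
        force = (diff_p / d2_p[..., None] ** 1.5).sum(axis=1)
        force += (diff_m / d2_m[..., None] ** 1.5).sum(axis=1)
        # project force onto the tangent plane and take a bounded step
        force -= (np.sum(force * p, axis=1))[:, None] * p
        norm = np.linalg.norm(force, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        p = p + step * force / norm * min(1.0, 4.0 / np.sqrt(n))
        p /= np.linalg.norm(p, axis=1, keepdims=True)
        # fold back to the canonical hemisphere
        flip = (p[:, 2] < 0) | ((p[:, 2] == 0) & (p[:, 1] < 0))
        p[flip] *= -1
    return p


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def generate_hemisphere_directions(n: int, seed: int = 0) -> np.ndarray:
    """n quasi-uniform unit vectors, one per antipodal pair; deterministic."""
    rng = np.random.default_rng(seed)
    pts = _fibonacci_hemisphere(n) @ _random_rotation(rng).T
    flip = pts[:, 2] < 0
    pts[flip] *= -1
    return _repel_hemisphere(pts)


def make_single_shell_scheme(n_dirs: int, b: float, n_b0: int = 1, seed: int = 0) -> BTable:
    """Single-shell (HARDI) scheme: ``n_b0`` b=0 volumes then ``n_dirs`` at ``b``."""
    if n_dirs < 6:
        raise ValueError("a shell needs at least 6 directions")
    dirs = generate_hemisphere_directions(n_dirs, seed=seed)
    bvals = np.concatenate([np.zeros(n_b0), np.full(n_dirs, float(b))])
    directions = np.vstack([np.zeros((n_b0, 3)), dirs])
    return BTable(bvals, directions)


def make_multishell_scheme(shells, n_b0: int = 1, seed: int = 0) -> BTable:
    """Multi-shell scheme from ``[(n_dirs, b), ...]``; per-shell direction sets."""
    shells = list(shells)
    if not shells:
        raise ValueError("empty shell list")
    bvals = [np.zeros(n_b0)]
    dirs = [np.zeros((n_b0, 3))]
    for k, (n_dirs, b) in enumerate(shells):
        if n_dirs < 6:
            raise ValueError("each shell needs at least 6 directions")
        bvals.append(np.full(n_dirs, float(b)))
        dirs.append(generate_hemisphere_directions(n_dirs, seed=seed + k))
    return BTable(np.concatenate(bvals), np.vstack(dirs))


def make_dsi_scheme(radius: float, b_max: float, half_sphere: bool = True) -> BTable:
    """DSI Cartesian q-space grid scheme.

    The grid consists of one b=0 volume plus every nonzero integer lattice
    point q with squared norm at most ``n_max = round(radius**2)`` (q-space
    shells carry integer squared norms, so the cutoff shell is the integer
    nearest ``radius**2``).  Each point maps to ``b = b_max * |q|^2 / n_max``
    and direction ``q/|q|``.  With ``half_sphere`` only one representative
    per antipodal pair is kept (z > 0, or z = 0 and y > 0, or
    z = y = 0 and x > 0).
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    if b_max <= 0:
        raise ValueError("b_max must be positive")
    n_max = int(round(radius * radius))
    extent = int(np.floor(np.sqrt(n_max)))
    points = []
    for q in product(range(-extent, extent + 1), repeat=3):
        n2 = q[0] * q[0] + q[1] * q[1] + q[2] * q[2]
        if n2 == 0 or n2 > n_max:
            continue
        if half_sphere:
            keep = q[2] > 0 or (q[2] == 0 and (q[1] > 0 or (q[1] == 0 and q[0] > 0)))
            if not keep:
                continue
        points.append((q, n2))
    points.sort(key=lambda item: (item[1], item[0]))
    bvals = [0.0]
    dirs = [np.zeros(3)]
    for q, n2 in points:
        bvals.append(b_max * n2 / n_max)
        dirs.append(np.asarray(q, dtype=float) / np.sqrt(n2))
    return BTable(np.asarray(bvals), np.vstack(dirs))


def apply_gradient_deviation(btable: BTable, G: np.ndarray) -> BTable:
    """Effective b-table under a gradient-deviation matrix G.

    For each diffusion-weighted volume the effective weighting is
    ``|G b̂|^2 b`` along direction ``G b̂ / |G b̂|``; b=0 volumes are
    unchanged.
    """
    G = np.asarray(G, dtype=float)
    if G.shape != (3, 3) or not np.all(np.isfinite(G)):
        raise ValueError("G must be a finite 3x3 matrix")
    bvals = btable.bvalues.copy()
    dirs = btable.directions.copy()
    dwi = btable.dwi_mask
    g_eff = dirs[dwi] @ G.T
    norms = np.linalg.norm(g_eff, axis=1)
    if np.any(norms < 1e-12):
        raise ValueError("gradient deviation maps a direction to the zero vector")
    bvals[dwi] = bvals[dwi] * norms**2
    dirs[dwi] = g_eff / norms[:, None]
    return BTable(bvals, dirs)
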