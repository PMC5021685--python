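"""Synthetic diffusion datasets: multi-tensor phantoms, brain-like voxels, Rician noise.

The physical crossing-fiber phantom that motivates the geometry here is
emulated with a multi-tensor Gaussian signal model: each voxel holds one
or more compartments, each a Gaussian diffusion tensor with a volume
fraction, and the noise-free signal is

    S(b, ĝ) = S0 · Σ_k f_k · exp(−b ĝᵀ D_k ĝ).

The default phantom contains one straight fiber bundle, a pair of
bundles crossing at 90°, and an isotropic free-water region, with
analysis ROIs of 29 voxels (straight) and 20 voxels (crossing).
Magnitude-MRI noise is Rician: S' = sqrt((S+n1)² + n2²) with n1, n2
independent N(0, σ²), σ = S0_ref / SNR.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .schemes import BTable

__all__ = [
    "STICK_EIGENVALUES",
    "FREE_WATER_DIFFUSIVITY",
    "Compartment",
    "PhantomSpec",
    "PhantomData",
    "simulate_signal",
    "build_phantom",
    "add_rician_noise",
    "make_brain_like_volume",
]

#: Stick-like fiber tensor eigenvalues, mm^2/s.
STICK_EIGENVALUES = (1.7e-3, 0.2e-3, 0.2e-3)
#: Isotropic free-water diffusivity, mm^2/s.
FREE_WATER_DIFFUSIVITY = 2.5e-3


@dataclass(frozen=True)
class Compartment:
    """One diffusion compartment: volume fraction, tensor eigenvalues, axis.

    ``direction=None`` marks an isotropic compartment (eigenvalues are
    then averaged into a single diffusivity).
    """

    volume_fraction: float
    eigenvalues: tuple
    direction: tuple | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.volume_fraction <= 1):
            raise ValueError("volume fraction must be in [0, 1]")
        if any(ev < 0 for ev in self.eigenvalues):
            raise ValueError("negative tensor eigenvalue")
        if self.direction is not None:
            d = np.asarray(self.direction, dtype=float)
            n = np.linalg.norm(d)
            if n == 0:
                raise ValueError("zero principal direction")
            object.__setattr__(self, "direction", tuple(d / n))

    def tensor(self) -> np.ndarray:
        ev = np.asarray(self.eigenvalues, dtype=float)
        if self.direction is None:
            return np.eye(3) * ev.mean()
        e1 = np.asarray(self.direction)
        # any orthonormal completion; the tensor is axially symmetric in
        # the default (λ2 = λ3) case, and the completion is deterministic
        helper = np.array([1.0, 0.0, 0.0])
        if abs(e1 @ helper) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        e2 = np.cross(e1, helper)
        e2 /= np.linalg.norm(e2)
        e3 = np.cross(e1, e2)
        R = np.column_stack([e1, e2, e3])
        return R @ np.diag(ev) @ R.T


def simulate_signal(compartments, btable: BTable, S0: float = 100.0) -> np.ndarray:
    """Noise-free multi-tensor signal, one value per b-table volume."""
    comps = list(compartments)
    total = sum(c.volume_fraction for c in comps)
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"volume fractions sum to {total}, not 1")
    b = btable.bvalues
    g = btable.directions
    signal = np.zeros(btable.n_volumes)
    for c in comps:
        D = c.tensor()
        adc = np.einsum("ij,jk,ik->i", g, D, g)
        signal += c.volume_fraction * np.exp(-b * adc)
    return S0 * signal


@dataclass
class PhantomSpec:
    """Geometry and tissue parameters of the synthetic crossing phantom.

    The grid is a single 32 x 16 x 1 slab: a straight bundle along x, a
    pair of bundles crossing at ``crossing_angle`` centred in a crossing
    block, an isotropic free-water block, and empty background.  The
    analysis ROIs are fixed by construction to 29 voxels (straight) and
    20 voxels (crossing).
    """

    grid_shape: tuple = (32, 16, 1)
    stick_eigenvalues: tuple = STICK_EIGENVALUES
    free_water_diffusivity: float = FREE_WATER_DIFFUSIVITY
    crossing_angle: float = 90.0
    S0: float = 100.0


@dataclass
class PhantomData:
    """Noise-free phantom signals with ROI masks and ground truth."""

    signals: np.ndarray  # grid + (n_volumes,)
    labels: np.ndarray  # 0 bg, 1 straight, 2 crossing, 3 free water
    rois: dict  # name -> bool mask
    truth_directions: np.ndarray  # grid + (2, 3); NaN where absent
    mask: np.ndarray  # labels > 0
    btable: BTable
    spec: PhantomSpec


def _phantom_labels(spec: PhantomSpec):
    nx, ny, nz = spec.grid_shape
    if nx < 32 or ny < 16 or nz < 1:
        raise ValueError("phantom grid must be at least 32 x 16 x 1")
    labels = np.zeros(spec.grid_shape, dtype=int)
    z = nz // 2
    # straight bundle: three rows along x
    labels[1:31, 2:5, z] = 1
    # crossing block: 6 x 6 region where the two oblique bundles overlap
    labels[13:19, 8:14, z] = 2
    # free-water block
    labels[2:7, 8:13, z] = 3
    rois = {
        "straight": np.zeros(spec.grid_shape, dtype=bool),
        "crossing": np.zeros(spec.grid_shape, dtype=bool),
        "free_water": labels == 3,
    }
    # 29-voxel straight ROI: the central row of the straight bundle
    rois["straight"][2:31, 3, z] = True
    # 20-voxel crossing ROI: a 5 x 4 block at the crossing centre
    rois["crossing"][13:18, 9:13, z] = True
    assert rois["straight"].sum() == 29 and rois["crossing"].sum() == 20
    if np.any(rois["straight"] & (labels != 1)) or np.any(rois["crossing"] & (labels != 2)):
        raise ValueError("ROI leaks outside its region")
    return labels, rois


def build_phantom(
    spec: PhantomSpec | None = None, btable: BTable | None = None, seed: int = 0
) -> PhantomData:
    """Noise-free phantom dataset on ``btable`` with ROI masks and truth.

    Ground-truth principal directions are stored per voxel (two slots,
    NaN-padded) so scoring never needs the compartment internals.
    """
    if spec is None:
        spec = PhantomSpec()
    if btable is None:
        raise ValueError("a b-table is required")
    labels, rois = _phantom_labels(spec)
    half = np.deg2rad(spec.crossing_angle) / 2.0
    x_axis = (1.0, 0.0, 0.0)
    cross_a = (np.cos(half), np.sin(half), 0.0)
    cross_b = (np.cos(half), -np.sin(half), 0.0)
    stick = spec.stick_eigenvalues
    fw = Compartment(1.0, (spec.free_water_diffusivity,) * 3, None)
    profiles = {
        1: [Compartment(1.0, stick, x_axis)],
        2: [Compartment(0.5, stick, cross_a), Compartment(0.5, stick, cross_b)],
        3: [fw],
    }
    signals = np.zeros(spec.grid_shape + (btable.n_volumes,))
    truth = np.full(spec.grid_shape + (2, 3), np.nan)
    for label, comps in profiles.items():
        sig = simulate_signal(comps, btable, spec.S0)
        where = labels == label
        signals[where] = sig
        if label == 1:
            truth[where, 0] = x_axis
        elif label == 2:
            truth[where, 0] = cross_a
            truth[where, 1] = cross_b
    return PhantomData(signals, labels, rois, truth, labels > 0, btable, spec)


def add_rician_noise(
    signals: np.ndarray, snr, S0_ref: float, seed: int = 0
) -> np.ndarray:
    """Rician-corrupted magnitude signals at σ = S0_ref / snr; seeded.

    ``snr`` may be a scalar or an array broadcastable over the voxel
    grid (signal shape without the trailing volume axis) for
    voxel-dependent noise levels.
    """
    signals = np.asarray(signals, dtype=float)
    snr = np.asarray(snr, dtype=float)
    if np.any(snr <= 0):
        raise ValueError("snr must be positive")
    sigma = S0_ref / snr
    if sigma.ndim:
        sigma = np.broadcast_to(sigma, signals.shape[:-1])[..., None]
    rng = np.random.default_rng(seed)
    n1 = rng.normal(0.0, sigma, signals.shape)
    n2 = rng.normal(0.0, sigma, signals.shape)
    return np.sqrt((signals + n1) ** 2 + n2**2)


def _random_unit_vectors(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def make_brain_like_volume(
    n_voxels: int,
    btable: BTable,
    fw_fraction_range: tuple = (0.0, 0.2),
    seed: int = 0,
    S0: float = 100.0,
    two_fiber_fraction: float = 0.5,
    crossing_angle_range: tuple = (45.0, 90.0),
) -> tuple[np.ndarray, dict]:
    """Synthetic population of white-matter-like voxels.

    Each voxel holds one or two stick-like fiber compartments with
    uniformly random orientations plus an isotropic free-water fraction
    drawn from ``fw_fraction_range``.  Two-fiber voxels cross at an
    angle drawn from ``crossing_angle_range`` (degrees).  Returns the
    noise-free signals, shape ``(n_voxels, n_volumes)``, and a ground
    truth dict with per-voxel fiber directions (2-slot, NaN-padded),
    fiber counts and free-water fractions.
    """
    if n_voxels < 1:
        raise ValueError("n_voxels must be >= 1")
    lo, hi = fw_fraction_range
    if not (0 <= lo <= hi < 1):
        raise ValueError("free-water fraction range must satisfy 0 <= lo <= hi < 1")
    rng = np.random.default_rng(seed)
    first = _random_unit_vectors(rng, n_voxels)
    two = rng.random(n_voxels) < two_fiber_fraction if n_voxels > 1 else np.zeros(1, bool)
    angles = np.deg2rad(rng.uniform(*crossing_angle_range, n_voxels))
    fw = rng.uniform(lo, hi, n_voxels)
    signals = np.empty((n_voxels, btable.n_volumes))
    truth_dirs = np.full((n_voxels, 2, 3), np.nan)
    fw_comp_ev = (FREE_WATER_DIFFUSIVITY,) * 3
    for v in range(n_voxels):
        e1 = first[v]
        comps = []
        fiber_frac = 1.0 - fw[v]
        if two[v]:
            # second fiber: rotate e1 by the crossing angle about a
            # random perpendicular axis
            perp = np.cross(e1, _random_unit_vectors(rng, 1)[0])
            while np.linalg.norm(perp) < 1e-6:
                perp = np.cross(e1, _random_unit_vectors(rng, 1)[0])
            perp /= np.linalg.norm(perp)
            e2 = np.cos(angles[v]) * e1 + np.sin(angles[v]) * perp
            comps.append(Compartment(fiber_frac / 2, STICK_EIGENVALUES, tuple(e1)))
            comps.append(Compartment(fiber_frac / 2, STICK_EIGENVALUES, tuple(e2)))
            truth_dirs[v, 0] = e1
            truth_dirs[v, 1] = e2
        else:
            comps.append(Compartment(fiber_frac, STICK_EIGENVALUES, tuple(e1)))
            truth_dirs[v, 0] = e1
        if fw[v] > 0:
            comps.append(Compartment(fw[v], fw_comp_ev, None))
        signals[v] = simulate_signal(comps, btable, S0)
    truth = {
        "directions": truth_dirs,
        "n_fibers": np.where(two, 2, 1),
        "free_water_fraction": fw,
        "S0": S0,
    }
    return signals, truth
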