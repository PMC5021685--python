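"""Evaluation metrics: DTI fit, FA/MD, GFA, SNR, ODF peaks, angular error, regression.

These are the quantities used to judge a scheme conversion against
directly acquired (or directly simulated) HARDI: per-voxel tensor
measures from a log-linear DTI fit, the generalized fractional
anisotropy of the spin distribution function, peak fiber orientations
extracted on the ODF mesh, the angular error between matched primary
peaks, and ordinary least-squares regression/correlation summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats

from .gqi import ODFSampling
from .schemes import BTable

__all__ = [
    "TensorFit",
    "PeakSet",
    "RegressionSummary",
    "fit_dti",
    "fa",
    "md",
    "gfa",
    "estimate_snr",
    "extract_peaks",
    "angular_error",
    "correlate",
    "roi_average_signals",
]


@dataclass(frozen=True)
class TensorFit:
    """Per-voxel diffusion tensors with sorted eigendecomposition.

    ``tensors``: (..., 3, 3) symmetric, mm^2/s.  ``eigenvalues``:
    (..., 3) sorted descending.  ``eigenvectors``: (..., 3, 3) with
    column k the eigenvector of eigenvalue k.  ``valid`` flags voxels
    whose signals admitted the log-linear fit.
    """

    tensors: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    S0: np.ndarray
    valid: np.ndarray


@dataclass
class PeakSet:
    """Per-voxel ODF peak orientations, descending amplitude.

    ``directions[v]`` is an (n_peaks, 3) array of unit vectors (possibly
    empty); ``amplitudes[v]`` the matching ODF values.
    """

    directions: list
    amplitudes: list

    @property
    def n_voxels(self) -> int:
        return len(self.directions)

    def primary(self) -> np.ndarray:
        """(n_voxels, 3) primary peaks, NaN rows where no peak was found."""
        out = np.full((self.n_voxels, 3), np.nan)
        for v, d in enumerate(self.directions):
            if len(d):
                out[v] = d[0]
        return out


@dataclass(frozen=True)
class RegressionSummary:
    """OLS fit of y on x with the Pearson correlation."""

    slope: float
    intercept: float
    pearson_r: float
    n_points: int


def _dti_design(btable: BTable) -> np.ndarray:
    b = btable.bvalues
    g = btable.directions
    return np.column_stack(
        [
            np.ones_like(b),
            -b * g[:, 0] ** 2,
            -b * g[:, 1] ** 2,
            -b * g[:, 2] ** 2,
            -2 * b * g[:, 0] * g[:, 1],
            -2 * b * g[:, 0] * g[:, 2],
            -2 * b * g[:, 1] * g[:, 2],
        ]
    )


def fit_dti(signals: np.ndarray, btable: BTable) -> TensorFit:
    """Log-linear least-squares tensor fit: ln S = ln S0 − b ĝᵀ D ĝ.

    Voxels with any non-positive signal are flagged invalid (zero
    tensor) rather than fatal.  Requires at least six non-collinear
    diffusion directions and one b=0 volume.
    """
    signals = np.asarray(signals, dtype=float)
    if signals.shape[-1] != btable.n_volumes:
        raise ValueError("signal/b-table volume mismatch")
    if np.count_nonzero(btable.b0_mask) < 1:
        raise ValueError("DTI fit needs at least one b=0 volume")
    X = _dti_design(btable)
    if np.linalg.matrix_rank(X) < 7:
        raise ValueError(
            "DTI fit needs >= 6 non-collinear diffusion directions plus b0"
        )
    grid = signals.shape[:-1]
    flat = signals.reshape(-1, btable.n_volumes)
    valid = np.all(flat > 0, axis=1)
    coeffs = np.zeros((flat.shape[0], 7))
    if valid.any():
        logs = np.log(flat[valid])
        coeffs[valid] = np.linalg.lstsq(X, logs.T, rcond=None)[0].T
    D = np.zeros((flat.shape[0], 3, 3))
    D[:, 0, 0] = coeffs[:, 1]
    D[:, 1, 1] = coeffs[:, 2]
    D[:, 2, 2] = coeffs[:, 3]
    D[:, 0, 1] = D[:, 1, 0] = coeffs[:, 4]
    D[:, 0, 2] = D[:, 2, 0] = coeffs[:, 5]
    D[:, 1, 2] = D[:, 2, 1] = coeffs[:, 6]
    evals, evecs = np.linalg.eigh(D)  # ascending
    evals = evals[:, ::-1]
    evecs = evecs[:, :, ::-1]
    S0 = np.where(valid, np.exp(coeffs[:, 0]), 0.0)
    return TensorFit(
        D.reshape(grid + (3, 3)),
        evals.reshape(grid + (3,)),
        evecs.reshape(grid + (3, 3)),
        S0.reshape(grid),
        valid.reshape(grid),
    )


def fa(fit: TensorFit) -> np.ndarray:
    """Fractional anisotropy, clipped to [0, 1]; 0 for zero tensors."""
    ev = fit.eigenvalues
    mean = ev.mean(axis=-1, keepdims=True)
    num = np.sum((ev - mean) ** 2, axis=-1)
    den = np.sum(ev**2, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.sqrt(1.5 * num / den)
    out = np.where(den > 0, out, 0.0)
    return np.clip(out, 0.0, 1.0)


def md(fit: TensorFit, mode: str = "trace") -> np.ndarray:
    """Mean diffusivity (mm^2/s).

    ``"trace"``: (λ1+λ2+λ3)/3.  ``"axial_radial_mean"``: the mean of the
    axial diffusivity λ1 and the radial diffusivity (λ2+λ3)/2.
    """
    ev = fit.eigenvalues
    if mode == "trace":
        return ev.mean(axis=-1)
    if mode == "axial_radial_mean":
        return (ev[..., 0] + (ev[..., 1] + ev[..., 2]) / 2.0) / 2.0
    raise ValueError(f"unknown MD mode {mode!r}")


def gfa(psi: np.ndarray) -> np.ndarray:
    """Generalized fractional anisotropy of an ODF/SDF sample vector.

    GFA = sqrt( n Σ(Ψj − Ψ̄)² / ((n−1) ΣΨj²) ), in [0, 1]; defined as 0
    for the all-zero vector.
    """
    psi = np.asarray(psi, dtype=float)
    n = psi.shape[-1]
    if n < 2:
        raise ValueError("GFA needs at least 2 ODF directions")
    mean = psi.mean(axis=-1, keepdims=True)
    num = n * np.sum((psi - mean) ** 2, axis=-1)
    den = (n - 1) * np.sum(psi**2, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.sqrt(num / den)
    out = np.where(den > 0, out, 0.0)
    return np.clip(out, 0.0, 1.0)


RAYLEIGH_MEAN = np.sqrt(np.pi / 2.0)


def estimate_snr(
    signals: np.ndarray,
    btable: BTable,
    noise_sigma: float | np.ndarray | None = None,
    background_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Per-voxel SNR: mean b0 signal over the noise standard deviation.

    σ is the supplied ground-truth value when given (simulations; scalar
    or per-voxel array); otherwise it is estimated from the background as
    mean(|background|)/sqrt(π/2), the Rician (Rayleigh) background mean.
    """
    signals = np.asarray(signals, dtype=float)
    b0 = btable.b0_mask
    if not b0.any():
        raise ValueError("SNR estimation needs at least one b=0 volume")
    if noise_sigma is None:
        if background_mask is None:
            raise ValueError("need noise_sigma or a background mask")
        bg = signals[np.asarray(background_mask, dtype=bool)]
        noise_sigma = float(np.mean(np.abs(bg)) / RAYLEIGH_MEAN)
    noise_sigma = np.asarray(noise_sigma, dtype=float)
    if np.any(noise_sigma <= 0):
        raise ValueError("noise sigma must be positive")
    return signals[..., b0].mean(axis=-1) / noise_sigma


def extract_peaks(
    psi: np.ndarray,
    odf: ODFSampling,
    max_peaks: int = 3,
    min_separation: float = 25.0,
    amplitude_fraction: float = 0.3,
) -> PeakSet:
    """Local ODF maxima over the mesh adjacency, greedily separated.

    A direction is a candidate peak when its value is >= all of its mesh
    neighbours (antipodal neighbourhood included via the hemisphere
    adjacency).  Peak amplitude is measured *above the voxel's ODF
    floor* (its minimum value, the isotropic baseline — the spin
    distribution function rides on a large isotropic component);
    candidates below ``amplitude_fraction`` of the largest
    baseline-subtracted amplitude are discarded, and the survivors are
    taken in descending amplitude subject to a pairwise separation of
    at least ``min_separation`` degrees (axial angle), up to
    ``max_peaks``.  Constant Ψ yields no peaks.
    """
    if not (0 < amplitude_fraction <= 1):
        raise ValueError("amplitude_fraction must be in (0, 1]")
    psi = np.asarray(psi, dtype=float)
    flat = psi.reshape(-1, odf.n_dirs)
    if flat.shape[1] != odf.n_dirs:
        raise ValueError("psi/ODF direction-count mismatch")
    # neighbour matrix padded with own index
    max_deg = max(len(a) for a in odf.adjacency)
    nbr = np.empty((odf.n_dirs, max_deg), dtype=int)
    for j, adj in enumerate(odf.adjacency):
        nbr[j, : len(adj)] = adj
        nbr[j, len(adj):] = j
    neighbour_max = flat[:, nbr].max(axis=2)
    is_candidate = flat >= neighbour_max
    cos_sep = np.cos(np.deg2rad(min_separation))
    dirs_out: list[np.ndarray] = []
    amps_out: list[np.ndarray] = []
    for v in range(flat.shape[0]):
        vals = flat[v]
        floor = vals.min()
        span = vals.max() - floor
        # a constant (or near-constant) profile carries no orientation
        if span <= 1e-12 * max(1.0, abs(vals.max())):
            dirs_out.append(np.zeros((0, 3)))
            amps_out.append(np.zeros(0))
            continue
        cand = np.flatnonzero(
            is_candidate[v] & (vals - floor >= amplitude_fraction * span)
        )
        order = cand[np.argsort(vals[cand])[::-1]]
        chosen: list[int] = []
        for j in order:
            if len(chosen) >= max_peaks:
                break
            u = odf.directions[j]
            if all(
                abs(u @ odf.directions[c]) < cos_sep for c in chosen
            ):
                chosen.append(j)
        dirs_out.append(odf.directions[chosen].copy())
        amps_out.append(vals[chosen].copy())
    return PeakSet(dirs_out, amps_out)


def angular_error(a: PeakSet, b: PeakSet, mode: str = "primary") -> dict:
    """Angular error in degrees between matched primary peaks.

    Per voxel the error is arccos(|⟨p_a, p_b⟩|) between the
    largest-amplitude peaks — antipodally invariant and symmetric in the
    arguments.  Voxels where either set is empty are excluded and
    counted.  Returns a dict with the per-voxel errors, the mean,
    quartiles, and exclusion count.
    """
    if mode != "primary":
        raise ValueError("only mode='primary' is supported")
    if a.n_voxels != b.n_voxels:
        raise ValueError("peak sets cover different voxel counts")
    pa = a.primary()
    pb = b.primary()
    ok = ~(np.isnan(pa[:, 0]) | np.isnan(pb[:, 0]))
    dots = np.abs(np.sum(pa[ok] * pb[ok], axis=1))
    errors = np.degrees(np.arccos(np.clip(dots, -1.0, 1.0)))
    if errors.size:
        q1, q2, q3 = np.percentile(errors, [25, 50, 75])
        mean = float(errors.mean())
    else:
        q1 = q2 = q3 = mean = float("nan")
    return {
        "per_voxel": errors,
        "voxel_index": np.flatnonzero(ok),
        "mean": mean,
        "median": float(q2),
        "q1": float(q1),
        "q3": float(q3),
        "n_compared": int(errors.size),
        "n_excluded": int(np.count_nonzero(~ok)),
    }


def correlate(x: np.ndarray, y: np.ndarray) -> RegressionSummary:
    """OLS regression of y on x with the Pearson correlation coefficient."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need two equal-length samples of size >= 2")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; the regression slope is undefined")
    res = scipy.stats.linregress(x, y)
    return RegressionSummary(
        float(res.slope), float(res.intercept), float(res.rvalue), int(x.size)
    )


def roi_average_signals(signals: np.ndarray, roi_mask: np.ndarray) -> np.ndarray:
    """Mean signal over the ROI voxels, one value per diffusion volume."""
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if not roi_mask.any():
        raise ValueError("empty ROI")
    return np.asarray(signals, dtype=float)[roi_mask].mean(axis=0)
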