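"""End-to-end evaluation of a scheme conversion against reference HARDI data.

Builds the comparison report used throughout the package: regressions
between converted and reference signals (ROI-averaged and voxelwise),
between their scalar maps (GFA from the spin distribution function, FA
and MD from the tensor fit), and SNR-stratified angular errors between
primary ODF peaks.
"""

from __future__ import annotations

import json

import numpy as np

from . import metrics
from .gqi import (
    DEFAULT_DIFFUSIVITY,
    DEFAULT_SIGMA,
    DEFAULT_SUBDIVISION,
    build_gqi_matrix,
    compute_sdf,
    make_odf_directions,
)
from .schemes import BTable

__all__ = ["evaluate_conversion", "report_to_text"]


def _regression_dict(x: np.ndarray, y: np.ndarray) -> dict:
    r = metrics.correlate(x, y)
    return {
        "slope": r.slope,
        "intercept": r.intercept,
        "pearson_r": r.pearson_r,
        "n_points": r.n_points,
    }


def evaluate_conversion(
    converted: np.ndarray,
    original: np.ndarray,
    btable: BTable,
    mask: np.ndarray,
    rois: dict | None = None,
    truth_directions: np.ndarray | None = None,
    snr_strata: tuple = (5.0,),
    noise_sigma: float | None = None,
    background_mask: np.ndarray | None = None,
    include_b0: bool = False,
    sigma: float = DEFAULT_SIGMA,
    diffusivity: float = DEFAULT_DIFFUSIVITY,
    odf_subdivision: int = DEFAULT_SUBDIVISION,
    metadata: dict | None = None,
) -> dict:
    """Compare converted and original HARDI datasets on one b-table.

    ``snr_strata`` lists stratum edges; with the default ``(5,)`` the
    angular error is reported for SNR < 5 and SNR >= 5 separately.  The
    error is measured between primary SDF peaks of the two datasets, or
    against ``truth_directions`` (grid + (2, 3), first slot primary)
    when provided.  b=0 volumes are excluded from signal regressions
    unless ``include_b0``.
    """
    converted = np.asarray(converted, dtype=float)
    original = np.asarray(original, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if converted.shape != original.shape:
        raise ValueError("converted/original grids differ")
    if converted.shape[-1] != btable.n_volumes:
        raise ValueError("signal/b-table volume mismatch")
    if mask.shape != converted.shape[:-1]:
        raise ValueError("mask grid does not match the signals")

    vol_sel = np.ones(btable.n_volumes, bool) if include_b0 else btable.dwi_mask
    report: dict = {"metadata": metadata or {}}

    # ---- signal regressions -------------------------------------------------
    signals: dict = {}
    signals["voxelwise"] = _regression_dict(
        original[mask][:, vol_sel].ravel(), converted[mask][:, vol_sel].ravel()
    )
    if rois:
        per_roi = {}
        for name, roi in rois.items():
            x = metrics.roi_average_signals(original, roi)[vol_sel]
            y = metrics.roi_average_signals(converted, roi)[vol_sel]
            per_roi[name] = _regression_dict(x, y)
        signals["roi_averaged"] = per_roi
    report["signals"] = signals

    # ---- scalar maps --------------------------------------------------------
    odf = make_odf_directions(odf_subdivision)
    basis = build_gqi_matrix(btable, odf, sigma, diffusivity)
    psi_conv = compute_sdf(basis, converted[mask])
    psi_orig = compute_sdf(basis, original[mask])
    scalar_maps = {
        "gfa": _regression_dict(metrics.gfa(psi_orig), metrics.gfa(psi_conv))
    }
    try:
        fit_orig = metrics.fit_dti(original[mask], btable)
        fit_conv = metrics.fit_dti(converted[mask], btable)
        ok = fit_orig.valid & fit_conv.valid
        if np.count_nonzero(ok) >= 2:
            scalar_maps["fa"] = _regression_dict(
                metrics.fa(fit_orig)[ok], metrics.fa(fit_conv)[ok]
            )
            scalar_maps["md"] = _regression_dict(
                metrics.md(fit_orig)[ok], metrics.md(fit_conv)[ok]
            )
    except ValueError:
        pass  # degenerate designs (too few directions) skip the DTI block
    report["scalar_maps"] = scalar_maps

    # ---- angular error, SNR-stratified -------------------------------------
    peaks_conv = metrics.extract_peaks(psi_conv, odf)
    if truth_directions is not None:
        primary = np.asarray(truth_directions)[mask][:, 0, :]
        ref_dirs = [
            p[None, :] if np.isfinite(p).all() else np.zeros((0, 3))
            for p in primary
        ]
        peaks_ref = metrics.PeakSet(ref_dirs, [np.ones(len(d)) for d in ref_dirs])
    else:
        peaks_ref = metrics.extract_peaks(psi_orig, odf)

    try:
        snr = metrics.estimate_snr(original, btable, noise_sigma, background_mask)[mask]
    except ValueError:
        snr = None
    angular: dict = {"overall": _angular_summary(peaks_conv, peaks_ref)}
    if snr is not None:
        edges = [-np.inf, *sorted(snr_strata), np.inf]
        for lo, hi in zip(edges[:-1], edges[1:]):
            sel = (snr >= lo) & (snr < hi)
            label = f"snr_{_edge(lo)}_to_{_edge(hi)}"
            if np.count_nonzero(sel) == 0:
                angular[label] = {"n_compared": 0}
                continue
            angular[label] = _angular_summary(
                _subset_peaks(peaks_conv, sel), _subset_peaks(peaks_ref, sel)
            )
    report["angular_error"] = angular
    return report


def _edge(v: float) -> str:
    if np.isinf(v):
        return "inf" if v > 0 else "0"
    return f"{v:g}"


def _subset_peaks(peaks: "metrics.PeakSet", sel: np.ndarray) -> "metrics.PeakSet":
    idx = np.flatnonzero(sel)
    return metrics.PeakSet(
        [peaks.directions[i] for i in idx], [peaks.amplitudes[i] for i in idx]
    )


def _angular_summary(a, b) -> dict:
    res = metrics.angular_error(a, b)
    return {k: res[k] for k in ("mean", "median", "q1", "q3", "n_compared", "n_excluded")}


def report_to_text(report: dict) -> str:
    """Human-readable aligned-text rendering of an evaluation report."""
    lines = ["Scheme conversion evaluation", "=" * 28]

    def reg_line(name: str, d: dict) -> str:
        return (
            f"  {name:<18} slope {d['slope']:+.4f}  intercept {d['intercept']:+.4f}"
            f"  r {d['pearson_r']:.4f}  (n={d['n_points']})"
        )

    lines.append("Signals:")
    lines.append(reg_line("voxelwise", report["signals"]["voxelwise"]))
    for name, d in report["signals"].get("roi_averaged", {}).items():
        lines.append(reg_line(f"ROI {name}", d))
    if report.get("scalar_maps"):
        lines.append("Scalar maps:")
        for name, d in report["scalar_maps"].items():
            lines.append(reg_line(name.upper(), d))
    lines.append("Angular error (degrees, primary peaks):")
    for name, d in report.get("angular_error", {}).items():
        if d.get("n_compared", 0):
            lines.append(
                f"  {name:<18} mean {d['mean']:6.2f}  median {d['median']:6.2f}"
                f"  IQR [{d['q1']:.2f}, {d['q3']:.2f}]"
                f"  n={d['n_compared']} (excluded {d['n_excluded']})"
            )
        else:
            lines.append(f"  {name:<18} (no voxels)")
    return "\n".join(lines)


def save_report(report: dict, json_path, text_path=None) -> None:
    with open(json_path, "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    if text_path is not None:
        with open(text_path, "w") as fh:
            fh.write(report_to_text(report) + "\n")
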