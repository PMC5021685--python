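from itertools import combinations
from types import SimpleNamespace

import numpy as np
import pytest

from qconvert.convert import (
    SchemeConversion,
    equalize_scale,
    nnls_refine,
    select_lambda,
    tikhonov_solve,
)
from qconvert.gqi import build_gqi_matrix, compute_sdf, make_odf_directions
from qconvert.metrics import correlate, extract_peaks
from qconvert.phantom import STICK_EIGENVALUES, Compartment, simulate_signal


def basis_of(matrix):
    """Minimal stand-in carrying just the matrix, for solver-level tests."""
    return SimpleNamespace(matrix=np.asarray(matrix, dtype=float))


def ridge_oracle(A, psi, lam):
    """Independent dense normal-equation solve."""
    n = A.shape[1]
    return np.linalg.solve(A.T @ A + lam * np.eye(n), A.T @ psi)


class TestTikhonov:
    def test_zero_psi_gives_zero(self, rng):
        A = rng.normal(size=(8, 4))
        out = tikhonov_solve(basis_of(A), np.zeros(8), 0.1)
        assert np.allclose(out, 0.0)

    def test_small_instance_against_normal_equations(self, rng):
        A = rng.normal(size=(5, 3))
        psi = rng.normal(size=5)
        out = tikhonov_solve(basis_of(A), psi, 0.3)
        assert np.max(np.abs(out - ridge_oracle(A, psi, 0.3))) < 1e-10

    @pytest.mark.parametrize("shape", [(10, 6), (30, 20), (50, 50)])
    def test_oracle_equivalence_up_to_50x50(self, rng, shape):
        A = rng.normal(size=shape)
        psi = rng.normal(size=(4, shape[0]))
        for lam in (1e-3, 0.05, 1.0):
            out = tikhonov_solve(basis_of(A), psi, lam)
            expected = ridge_oracle(A, psi.T, lam).T
            assert np.max(np.abs(out - expected)) < 1e-8

    def test_least_squares_identity_at_tiny_lambda(self, rng):
        A = rng.normal(size=(12, 5))
        w = rng.uniform(1, 2, 5)
        out = tikhonov_solve(basis_of(A), A @ w, 1e-8)
        assert np.linalg.norm(out - w) / np.linalg.norm(w) < 1e-4

    def test_solution_norm_nonincreasing_in_lambda(self, rng):
        A = rng.normal(size=(20, 10))
        psi = rng.normal(size=20)
        norms = [
            np.linalg.norm(tikhonov_solve(basis_of(A), psi, lam))
            for lam in np.logspace(-4, 2, 13)
        ]
        assert np.all(np.diff(norms) <= 1e-12)

    def test_rank_deficient_at_zero_lambda(self):
        A = np.ones((4, 2))  # identical columns
        with pytest.raises(np.linalg.LinAlgError):
            tikhonov_solve(basis_of(A), np.ones(4), 0.0)


class TestSelectLambda:
    def test_all_positive_returns_grid_minimum(self, rng):
        A = np.eye(4)
        psi = rng.uniform(1, 2, size=(3, 4))
        lam, exhausted = select_lambda(psi, basis_of(A), (0.01, 0.1, 1.0), 0.99)
        assert lam == 0.01 and not exhausted

    def test_tiny_threshold_returns_grid_minimum(self, rng):
        A = rng.normal(size=(6, 4))
        psi = rng.normal(size=(3, 6))
        lam, _ = select_lambda(psi, basis_of(A), (0.01, 0.1), 1e-9)
        assert lam == 0.01

    def test_exhausted_grid_warns_and_returns_maximum(self):
        A = np.eye(2)
        psi = -np.ones((1, 2))  # solution always negative
        with pytest.warns(RuntimeWarning):
            lam, exhausted = select_lambda(psi, basis_of(A), (0.01, 0.1), 0.99)
        assert lam == 0.1 and exhausted

    def test_empty_grid_is_error(self):
        with pytest.raises(ValueError):
            select_lambda(np.ones((1, 2)), basis_of(np.eye(2)), (), 0.99)


class TestNNLS:
    def test_recovers_exactly_representable_nonnegative(self, rng):
        A = rng.normal(size=(10, 4))
        w = rng.uniform(0.5, 2, 4)
        out = nnls_refine(basis_of(A), A @ w)
        assert np.linalg.norm(A @ out - A @ w) < 1e-8

    def test_all_negative_target_gives_zero(self, rng):
        A = np.abs(rng.normal(size=(8, 3)))
        out = nnls_refine(basis_of(A), -(A @ np.ones(3)))
        assert np.allclose(out, 0.0)

    def test_matches_active_set_enumeration(self, rng):
        A = rng.normal(size=(10, 6))
        psi = rng.normal(size=10)
        out = nnls_refine(basis_of(A), psi)
        res_nnls = np.linalg.norm(A @ out - psi) ** 2
        # brute force: solve the unconstrained LS on every support and keep
        # the best feasible candidate
        best = np.linalg.norm(psi) ** 2  # empty support
        for k in range(1, 7):
            for support in combinations(range(6), k):
                sub = A[:, support]
                w_s = np.linalg.lstsq(sub, psi, rcond=None)[0]
                if np.all(w_s >= -1e-12):
                    best = min(best, np.linalg.norm(sub @ w_s - psi) ** 2)
        assert abs(res_nnls - best) < 1e-8
        assert np.all(out >= 0)


class TestEqualizeScale:
    def test_ratio_of_means(self):
        scaled, factor = equalize_scale(np.full(4, 5.0), np.full(4, 10.0))
        assert factor == 2.0
        assert np.allclose(scaled, 10.0)

    def test_identity(self, rng):
        x = rng.uniform(1, 2, 10)
        _, factor = equalize_scale(x, x)
        assert np.isclose(factor, 1.0)

    def test_mask_restricts_the_means(self, rng):
        conv = rng.uniform(1, 2, (5, 3))
        ref = rng.uniform(2, 4, (5, 3))
        mask = np.array([True, True, False, False, False])
        _, f1 = equalize_scale(conv, ref, mask)
        conv2 = conv.copy()
        conv2[~mask] = 999.0
        _, f2 = equalize_scale(conv2, ref, mask)
        assert np.isclose(f1, f2)

    def test_zero_mean_is_error(self):
        with pytest.raises(ValueError):
            equalize_scale(np.zeros(3), np.ones(3))


class TestSchemeConversion:
    def test_identity_conversion(self, hardi64):
        # diffusion signals are band-limited in the sinc basis, so the
        # tiny-lambda ridge reproduces them; per-voxel norm-relative error
        from qconvert.phantom import make_brain_like_volume

        w, _ = make_brain_like_volume(10, hardi64, (0.0, 0.2), seed=3)
        res = SchemeConversion(w, hardi64, hardi64).fit(1e-8)
        rel = np.linalg.norm(res.signals - w, axis=1) / np.linalg.norm(w, axis=1)
        assert rel.max() < 1e-4

    def test_linearity_in_input(self, hardi64, multishell, rng):
        w = rng.uniform(10, 100, (3, multishell.n_volumes))
        r1 = SchemeConversion(w, multishell, hardi64).fit(0.05)
        r2 = SchemeConversion(2 * w, multishell, hardi64).fit(0.05)
        assert np.allclose(r2.signals, 2 * r1.signals, rtol=1e-10)

    def test_roundtrip_idempotent_at_small_lambda(self, hardi64):
        from qconvert.phantom import make_brain_like_volume

        w, _ = make_brain_like_volume(4, hardi64, (0.0, 0.2), seed=5)
        once = SchemeConversion(w, hardi64, hardi64).fit(1e-11).signals
        twice = SchemeConversion(once, hardi64, hardi64).fit(1e-11).signals
        assert np.max(np.abs(twice - once)) < 1e-6 * np.max(np.abs(once))

    def test_moderate_tensor_conversion_accuracy(self, hardi64, multishell):
        comp = [Compartment(1.0, (1.0e-3, 0.5e-3, 0.5e-3), (0.2, 0.5, 0.84))]
        src = simulate_signal(comp, multishell, 100.0)[None, :]
        truth = simulate_signal(comp, hardi64, 100.0)
        res = SchemeConversion(src, multishell, hardi64).fit(0.05)
        dwi = hardi64.dwi_mask
        scaled, _ = equalize_scale(res.signals[0][dwi], truth[dwi])
        rel = np.abs(scaled - truth[dwi]) / truth[dwi]
        assert np.median(rel) < 0.10
        assert correlate(truth[dwi], scaled).pearson_r > 0.97

    def test_stick_tensor_conversion_correlates(self, hardi64, multishell):
        comp = [Compartment(1.0, STICK_EIGENVALUES, (0.2, 0.5, 0.84))]
        src = simulate_signal(comp, multishell, 100.0)[None, :]
        truth = simulate_signal(comp, hardi64, 100.0)
        res = SchemeConversion(src, multishell, hardi64).fit(0.05)
        dwi = hardi64.dwi_mask
        assert correlate(truth[dwi], res.signals[0][dwi]).pearson_r > 0.97

    def test_crossing_peaks_preserved(self, odf8, hardi256, multishell):
        # noise-free 90-degree crossing: peaks of the converted SDF match
        # peaks of the directly simulated target SDF within one mesh edge
        comps = [
            Compartment(0.5, STICK_EIGENVALUES, (1.0, 0.0, 0.0)),
            Compartment(0.5, STICK_EIGENVALUES, (0.0, 1.0, 0.0)),
        ]
        src = simulate_signal(comps, multishell, 100.0)[None, :]
        direct = simulate_signal(comps, hardi256, 100.0)[None, :]
        res = SchemeConversion(src, multishell, hardi256).fit(0.05)
        basis = build_gqi_matrix(hardi256, odf8)
        pk_conv = extract_peaks(compute_sdf(basis, res.signals), odf8)
        pk_direct = extract_peaks(compute_sdf(basis, direct), odf8)
        assert len(pk_conv.directions[0]) == len(pk_direct.directions[0]) == 2
        for p in pk_conv.directions[0]:
            best = max(abs(p @ q) for q in pk_direct.directions[0])
            assert np.degrees(np.arccos(min(1.0, best))) <= 10.0

    def test_extrapolation_warns(self, rng):
        from qconvert.schemes import make_single_shell_scheme

        low = make_single_shell_scheme(8, 1000.0, seed=1)
        high = make_single_shell_scheme(8, 4000.0, seed=2)
        w = rng.uniform(10, 100, (1, low.n_volumes))
        with pytest.warns(RuntimeWarning):
            SchemeConversion(w, low, high)

    def test_empty_mask_is_error(self, hardi64, rng):
        w = rng.uniform(10, 100, (2, hardi64.n_volumes))
        with pytest.raises(ValueError):
            SchemeConversion(w, hardi64, hardi64, mask=np.zeros(2, bool))

    def test_masked_voxels_returned_as_zero(self, hardi64, rng):
        w = rng.uniform(10, 100, (3, hardi64.n_volumes))
        mask = np.array([True, False, True])
        res = SchemeConversion(w, hardi64, hardi64, mask=mask).fit(0.05)
        assert np.allclose(res.signals[1], 0.0)

    def test_summary_mentions_key_diagnostics(self, hardi64, rng):
        w = rng.uniform(10, 100, (2, hardi64.n_volumes))
        res = SchemeConversion(w, hardi64, hardi64).fit(0.05)
        text = res.summary()
        assert "Lambda used" in text and "Positivity fraction" in text


class TestGradDevConversion:
    def test_identity_field_matches_global_basis(self, hardi64, multishell, rng):
        from qconvert.schemes import GradientDeviationField

        w = rng.uniform(10, 100, (2, multishell.n_volumes))
        gd = GradientDeviationField(np.broadcast_to(np.eye(3), (2, 3, 3)).copy())
        plain = SchemeConversion(w, multishell, hardi64).fit(0.05)
        with_gd = SchemeConversion(w, multishell, hardi64, grad_dev=gd).fit(0.05)
        assert np.allclose(plain.signals, with_gd.signals)

    def test_scaled_field_changes_effective_weighting(self, hardi64, multishell, rng):
        from qconvert.schemes import GradientDeviationField

        w = rng.uniform(10, 100, (1, multishell.n_volumes))
        gd = GradientDeviationField((1.2 * np.eye(3))[None])
        plain = SchemeConversion(w, multishell, hardi64).fit(0.05)
        with_gd = SchemeConversion(w, multishell, hardi64, grad_dev=gd).fit(0.05)
        assert not np.allclose(plain.signals, with_gd.signals)
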