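"""Affine camera estimation and ridge shape fitting against brute-force oracles."""

import numpy as np
import pytest

from palsyflow.errors import DegenerateGeometryError, ValidationError
from palsyflow.fitting import (
    AffineCamera,
    FitConfig,
    estimate_affine_camera,
    fit_face,
    fit_shape,
    fitting_energy,
    project,
    reprojection_rmse,
)
from palsyflow.landmark_io import Landmarks2D, synthesize_landmarks
from palsyflow.morphable_model import ShapeCoefficients, instantiate_shape


def random_affine_camera(rng, scale=100.0):
    linear = rng.normal(0, scale / 3, size=(2, 3))
    return AffineCamera.from_linear(linear, rng.normal(256, 50, size=2))


def reproj_rmse(camera, p3, p2):
    return float(np.sqrt(np.mean(np.sum((project(camera, p3) - p2) ** 2, axis=1))))


class TestProject:
    def test_identity_orthographic_drops_z(self, rng):
        cam = AffineCamera.from_linear(np.array([[1.0, 0, 0], [0, 1.0, 0]]), np.zeros(2))
        v = rng.normal(size=(50, 3))
        np.testing.assert_array_equal(project(cam, v), v[:, :2])

    def test_translation_equivariance(self, rng):
        cam = random_affine_camera(rng)
        shifted = AffineCamera.from_linear(cam.linear, cam.translation + (3.5, -2.0))
        v = rng.normal(size=(20, 3))
        np.testing.assert_allclose(
            project(shifted, v), project(cam, v) + (3.5, -2.0), atol=1e-12
        )

    def test_matches_per_point_matrix_multiplication(self, rng):
        """Brute-force oracle: homogeneous multiply point by point."""
        cam = random_affine_camera(rng)
        v = rng.normal(size=(1000, 3))
        oracle = np.array([(cam.C @ np.append(p, 1.0))[:2] for p in v])
        assert np.abs(project(cam, v) - oracle).max() < 1e-12

    def test_camera_last_row_enforced(self):
        bad = np.eye(3, 4)
        bad[2] = (0, 0, 1, 0)
        with pytest.raises(ValidationError, match="last row"):
            AffineCamera(bad)


class TestEstimateAffineCamera:
    def test_exact_orthographic_projection(self, rng):
        p3 = rng.normal(size=(68, 3))
        p2 = p3[:, :2].copy()
        cam = estimate_affine_camera(p2, p3)
        assert reproj_rmse(cam, p3, p2) < 1e-9

    def test_recovers_random_affine_camera(self, rng):
        true = random_affine_camera(rng)
        p3 = rng.normal(size=(68, 3))
        p2 = project(true, p3)
        cam = estimate_affine_camera(p2, p3)
        assert reproj_rmse(cam, p3, p2) < 1e-8

    def test_coplanar_points_rejected(self, rng):
        p3 = rng.normal(size=(68, 3))
        p3[:, 2] = 4.2
        with pytest.raises(DegenerateGeometryError):
            estimate_affine_camera(p3[:, :2], p3)

    def test_count_mismatch_rejected(self, rng):
        with pytest.raises(ValidationError, match="mismatch"):
            estimate_affine_camera(rng.normal(size=(10, 2)), rng.normal(size=(11, 3)))

    def test_invariant_under_2d_similarity(self, rng):
        """Reprojections agree to 1e-9 after rotating/scaling the 2D points."""
        p3 = rng.normal(size=(68, 3))
        p2 = project(random_affine_camera(rng), p3)
        theta = 0.7
        R = 2.5 * np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        p2_t = p2 @ R.T + (40.0, -7.0)
        cam = estimate_affine_camera(p2, p3)
        cam_t = estimate_affine_camera(p2_t, p3)
        back = (project(cam_t, p3) - (40.0, -7.0)) @ np.linalg.inv(R).T
        assert np.abs(back - project(cam, p3)).max() < 1e-9


class TestFitShape:
    def test_mean_shape_landmarks_give_zero_coefficients(self, model, rng):
        cam = random_affine_camera(rng)
        lms = Landmarks2D(project(cam, model.mean_shape[model.landmark_corr]))
        coeffs = fit_shape(model, cam, lms, FitConfig(sigma_2d=1.0))
        assert np.array_equal(coeffs.alpha, np.zeros(model.n_components))

    def test_recovery_matches_normal_equations_oracle(self, model, rng):
        """Independent oracle: assemble A by projecting each scaled basis
        column through the camera and solve the ridge system with numpy."""
        cam = random_affine_camera(rng)
        alpha_true = rng.normal(size=model.n_components)
        lms = synthesize_landmarks(model, ShapeCoefficients(alpha_true), cam, 0.0)
        sigma = 1e-3
        coeffs = fit_shape(model, cam, lms, FitConfig(sigma_2d=sigma))
        assert np.abs(coeffs.alpha - alpha_true).max() < 1e-3

        corr = model.landmark_corr
        mean_proj = project(cam, model.mean_shape[corr])
        cols = []
        for j in range(model.n_components):
            mode = model.basis[:, j].reshape(-1, 3) * model.stddevs[j]
            cols.append((project(cam, model.mean_shape + mode)[corr] - mean_proj).ravel())
        A = np.stack(cols, axis=1)
        b = (lms.points - mean_proj).ravel()
        oracle = np.linalg.solve(
            A.T @ A + 2 * sigma**2 * np.eye(model.n_components), A.T @ b
        )
        np.testing.assert_allclose(coeffs.alpha, oracle, atol=1e-8)

    def test_huge_sigma_drives_coefficients_to_zero(self, model, rng):
        cam = random_affine_camera(rng)
        lms = synthesize_landmarks(model, ShapeCoefficients(rng.normal(size=10)), cam, 0.0)
        coeffs = fit_shape(model, cam, lms, FitConfig(sigma_2d=1e6))
        assert np.linalg.norm(coeffs.alpha) < 1e-6

    def test_gradient_of_energy_vanishes_at_solution(self, model, rng):
        """Finite-difference gradient check of E at the returned alpha."""
        cam = random_affine_camera(rng)
        lms = synthesize_landmarks(model, ShapeCoefficients(rng.normal(size=10)), cam, 1.0, seed=4)
        sigma = 3.0
        coeffs = fit_shape(model, cam, lms, FitConfig(sigma_2d=sigma))
        eps = 1e-6
        grad = np.empty(model.n_components)
        for j in range(model.n_components):
            up = coeffs.alpha.copy()
            dn = coeffs.alpha.copy()
            up[j] += eps
            dn[j] -= eps
            grad[j] = (
                fitting_energy(model, cam, lms, ShapeCoefficients(up), sigma)
                - fitting_energy(model, cam, lms, ShapeCoefficients(dn), sigma)
            ) / (2 * eps)
        assert np.linalg.norm(grad) < 1e-4

    def test_noise_degrades_recovery_smoothly(self, model, rng):
        cam = random_affine_camera(rng)
        alpha_true = rng.normal(size=model.n_components)
        clean = synthesize_landmarks(model, ShapeCoefficients(alpha_true), cam, 0.0)
        rms0 = np.sqrt(
            np.mean((fit_shape(model, cam, clean, FitConfig(sigma_2d=1e-3)).alpha - alpha_true) ** 2)
        )
        rmss = []
        for seed in range(5):
            noisy = synthesize_landmarks(model, ShapeCoefficients(alpha_true), cam, 1.0, seed=seed)
            fitted = fit_shape(model, cam, noisy, FitConfig(sigma_2d=1e-3))
            rmss.append(np.sqrt(np.mean((fitted.alpha - alpha_true) ** 2)))
        assert rms0 < np.mean(rmss)  # noise hurts
        assert np.mean(rmss) < 1.0  # but degradation stays modest


class TestFitFace:
    def test_end_to_end_noiseless_recovery(self, small_cohort):
        from palsyflow.simulator import true_landmarks

        cohort = small_cohort
        for record in cohort.records[:4]:
            lms = true_landmarks(cohort.model, record, cohort.config, noise_sd=0.0)
            cam, coeffs = fit_face(cohort.model, lms, FitConfig(sigma_2d=1e-3, iterations=3))
            assert reprojection_rmse(cohort.model, cam, lms, coeffs) < 1e-6
            assert np.abs(coeffs.alpha - record.shape_coeffs.alpha).max() < 1e-3

    def test_single_iteration_equals_manual_composition(self, model, rng):
        lms = synthesize_landmarks(
            model, ShapeCoefficients(rng.normal(size=10)), random_affine_camera(rng), 1.0, seed=1
        )
        config = FitConfig(sigma_2d=3.0, iterations=1)
        cam, coeffs = fit_face(model, lms, config)
        cam_manual = estimate_affine_camera(lms.points, model.mean_shape[model.landmark_corr])
        coeffs_manual = fit_shape(model, cam_manual, lms, config)
        np.testing.assert_array_equal(cam.C, cam_manual.C)
        np.testing.assert_array_equal(coeffs.alpha, coeffs_manual.alpha)

    def test_energy_nonincreasing_across_alternations(self, model):
        """Alternating camera/shape steps never increase the fit energy."""
        sigma = 3.0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            cam_true = random_affine_camera(rng)
            lms = synthesize_landmarks(
                model, ShapeCoefficients(rng.normal(size=10)), cam_true, 2.0, seed=rng
            )
            energies = []
            for iterations in range(1, 5):
                cam, coeffs = fit_face(model, lms, FitConfig(sigma_2d=sigma, iterations=iterations))
                energies.append(fitting_energy(model, cam, lms, coeffs, sigma))
            diffs = np.diff(energies)
            assert np.all(diffs <= 1e-9), f"seed {seed}: {energies}"
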