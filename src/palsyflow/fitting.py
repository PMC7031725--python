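"""Affine camera estimation and PCA shape-coefficient fitting.

The camera is an affine 3x4 projection matrix ``C`` (last row fixed at
``(0, 0, 0, 1)``) estimated from 2D-3D landmark correspondences with the
normalized least-squares "gold standard" procedure: both point sets are
translated to zero centroid and isotropically scaled (RMS norm sqrt(2) in 2D,
sqrt(3) in 3D) before solving, then the solution is denormalized back to
pixel units.

Shape fitting minimizes the landmark reprojection energy with a standardized
ridge prior on the coefficients::

    E(alpha) = sum_i ||y_i(alpha) - x_i||^2 / (2 sigma_2d^2) + ||alpha||^2

where ``y_i`` is the camera projection of the i-th correspondence vertex of
the instantiated shape.  Because the model is linear in ``alpha`` the unique
minimizer is the ridge solution of a 136 x M linear system:
``(A^T A + 2 sigma_2d^2 I) alpha = A^T b``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .errors import DegenerateGeometryError, ValidationError
from .landmark_io import Landmarks2D
from .morphable_model import MorphableModel, ShapeCoefficients, instantiate_shape

logger = logging.getLogger(__name__)

_LAST_ROW = np.array([0.0, 0.0, 0.0, 1.0])


@dataclass
class AffineCamera:
    """Affine projection: homogeneous 3D point -> homogeneous 2D point."""

    C: np.ndarray  # (3, 4)

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, dtype=float)
        if self.C.shape != (3, 4):
            raise ValidationError(f"camera matrix must be 3x4, got {self.C.shape}")
        if not np.all(np.isfinite(self.C)):
            raise ValidationError("camera matrix must be finite")
        if not np.array_equal(self.C[2], _LAST_ROW):
            raise ValidationError("affine camera last row must be exactly (0, 0, 0, 1)")

    @classmethod
    def from_linear(cls, linear: np.ndarray, translation: np.ndarray) -> "AffineCamera":
        C = np.zeros((3, 4))
        C[:2, :3] = linear
        C[:2, 3] = translation
        C[2] = _LAST_ROW
        return cls(C)

    @property
    def linear(self) -> np.ndarray:
        return self.C[:2, :3]

    @property
    def translation(self) -> np.ndarray:
        return self.C[:2, 3]


@dataclass
class FitConfig:
    """Landmark-fitting configuration.

    sigma_2d
        Assumed landmark noise scale in pixels; enters the energy as the
        ridge weight ``2 sigma_2d^2``.  Default 3 px (typical detector noise).
    iterations
        Camera/shape alternations.  1 reproduces the sequential procedure
        (camera from mean-shape correspondences, then one shape solve);
        larger values re-estimate the camera against the fitted mesh.
    n_components
        Number of leading PCA modes to solve for (default: all).
    """

    sigma_2d: float = 3.0
    iterations: int = 1
    n_components: int | None = None

    def __post_init__(self) -> None:
        if self.sigma_2d <= 0:
            raise ValidationError("sigma_2d must be positive")
        if self.iterations < 1:
            raise ValidationError("iterations must be >= 1")


def project(camera: AffineCamera, vertices: np.ndarray) -> np.ndarray:
    """Project 3D points to pixel coordinates: ``p = dehomog(C (v, 1))``.

    With an affine camera the third homogeneous coordinate is identically 1,
    so this reduces to ``v @ linear.T + translation``.
    """
    v = np.asarray(vertices, dtype=float)
    single = v.ndim == 1
    v = np.atleast_2d(v)
    if v.shape[1] != 3:
        raise ValidationError("vertices must be (N, 3)")
    p = v @ camera.linear.T + camera.translation
    return p[0] if single else p


def _normalization_2d(pts: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    c = pts.mean(axis=0)
    rms = np.sqrt(np.mean(np.sum((pts - c) ** 2, axis=1)))
    f = np.sqrt(2.0) / rms if rms > 0 else 1.0
    return (pts - c) * f, c, f


def _normalization_3d(pts: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    c = pts.mean(axis=0)
    rms = np.sqrt(np.mean(np.sum((pts - c) ** 2, axis=1)))
    f = np.sqrt(3.0) / rms if rms > 0 else 1.0
    return (pts - c) * f, c, f


def estimate_affine_camera(points2d, points3d) -> AffineCamera:
    """Normalized least-squares (gold standard) affine camera estimate.

    Minimizes ``sum_i ||C X_i - x_i||^2`` over affine ``C``.  Requires at
    least 4 correspondences and a non-coplanar 3D configuration.
    """
    p2 = np.asarray(getattr(points2d, "points", points2d), dtype=float)
    p3 = np.asarray(points3d, dtype=float)
    if p2.ndim != 2 or p2.shape[1] != 2 or p3.ndim != 2 or p3.shape[1] != 3:
        raise ValidationError("expected (n, 2) image points and (n, 3) model points")
    if p2.shape[0] != p3.shape[0]:
        raise ValidationError(
            f"correspondence count mismatch: {p2.shape[0]} 2D vs {p3.shape[0]} 3D"
        )
    n = p2.shape[0]
    if n < 4:
        raise ValidationError(f"need at least 4 correspondences, got {n}")
    centered = p3 - p3.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[0] == 0 or s[2] <= 1e-9 * s[0]:
        raise DegenerateGeometryError(
            "3D points are (near-)coplanar; affine camera is not determined"
        )
    x2n, c2, f2 = _normalization_2d(p2)
    x3n, c3, f3 = _normalization_3d(p3)
    design = np.hstack([x3n, np.ones((n, 1))])  # (n, 4)
    sol, *_ = np.linalg.lstsq(design, x2n, rcond=None)  # (4, 2)
    Cn = np.vstack([sol.T, _LAST_ROW])  # normalized-coordinates camera
    # denormalize: C = T2^-1 @ Cn @ T3, all affine so the last row survives
    T2inv = np.array([[1 / f2, 0, c2[0]], [0, 1 / f2, c2[1]], [0, 0, 1]])
    T3 = np.eye(4)
    T3[:3, :3] *= f3
    T3[:3, 3] = -f3 * c3
    C = T2inv @ Cn @ T3
    C[2] = _LAST_ROW  # exact by construction; enforce bitwise
    return AffineCamera(C)


def _design_matrix(model: MorphableModel, camera: AffineCamera, m: int) -> np.ndarray:
    basis = model.basis.reshape(model.n_vertices, 3, -1)[model.landmark_corr, :, :m]
    scaled = basis * model.stddevs[:m]
    # per landmark: (2, 3) camera linear part applied to the (3, m) mode block
    return np.einsum("kj,njm->nkm", camera.linear, scaled).reshape(2 * len(model.landmark_corr), m)


def fit_shape(
    model: MorphableModel,
    camera: AffineCamera,
    landmarks: Landmarks2D,
    config: FitConfig | None = None,
) -> ShapeCoefficients:
    """Closed-form ridge solution of the landmark-fitting energy."""
    config = config or FitConfig()
    m = model.n_components if config.n_components is None else config.n_components
    if m > model.n_components:
        raise ValidationError(
            f"requested {m} components but the model has {model.n_components}"
        )
    A = _design_matrix(model, camera, m)
    mean_proj = project(camera, model.mean_shape[model.landmark_corr])
    b = (landmarks.points - mean_proj).ravel()
    lam = 2.0 * config.sigma_2d**2
    G = A.T @ A + lam * np.eye(m)
    logger.debug("fit_shape: normal-equations condition number %.3e", np.linalg.cond(G))
    alpha = scipy.linalg.solve(G, A.T @ b, assume_a="pos")
    return ShapeCoefficients(alpha)


def fitting_energy(
    model: MorphableModel,
    camera: AffineCamera,
    landmarks: Landmarks2D,
    coeffs: ShapeCoefficients,
    sigma_2d: float,
) -> float:
    """Evaluate the fitted energy E (data term + ridge prior) at ``coeffs``."""
    mesh = instantiate_shape(model, coeffs)
    proj = project(camera, mesh.vertices[model.landmark_corr])
    resid = float(np.sum((proj - landmarks.points) ** 2))
    return resid / (2.0 * sigma_2d**2) + float(np.sum(coeffs.alpha**2))


def reprojection_rmse(
    model: MorphableModel,
    camera: AffineCamera,
    landmarks: Landmarks2D,
    coeffs: ShapeCoefficients,
) -> float:
    mesh = instantiate_shape(model, coeffs)
    proj = project(camera, mesh.vertices[model.landmark_corr])
    return float(np.sqrt(np.mean(np.sum((proj - landmarks.points) ** 2, axis=1))))


def fit_face(
    model: MorphableModel,
    landmarks: Landmarks2D,
    config: FitConfig | None = None,
) -> tuple[AffineCamera, ShapeCoefficients]:
    """Camera estimation followed by shape fitting, optionally alternated.

    Iteration 1 estimates the camera against the mean-shape correspondences
    and solves once for the coefficients.  Further iterations re-estimate the
    camera against the current fitted mesh and re-solve; each step minimizes
    the energy in one block, so E is non-increasing across alternations.
    """
    config = config or FitConfig()
    pts3 = model.mean_shape[model.landmark_corr]
    camera = None
    coeffs = ShapeCoefficients.zeros(model.n_components)
    for _ in range(config.iterations):
        camera = estimate_affine_camera(landmarks.points, pts3)
        coeffs = fit_shape(model, camera, landmarks, config)
        pts3 = instantiate_shape(model, coeffs).vertices[model.landmark_corr]
    return camera, coeffs
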