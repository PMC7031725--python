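"""Synthetic LSCI cohort simulator with ground truth for every stage.

The clinical dataset behind this kind of study (paired color / blood-flow
frames of Bell's palsy patients with clinician House-Brackmann grades) is
not publicly deposited, so this module generates a statistically analogous
cohort end to end:

* a synthetic PCA morphable face model (parametric face-like surface,
  smooth random deformation modes, region atlas and 68-landmark
  correspondences placed from parametric surface coordinates);
* per-patient shape coefficients, pose (affine camera), affected side and
  HB grade following the study composition (8 healthy, 17/16/13/16/10 at
  grades II-VI, 100 frames each);
* grade-dependent regional perfusion: the affected side's flux is the
  healthy side's times ``m(grade) = 1 - delta * (grade - 1)``, so the
  expected healthy/affected ratio P_r = 1/m increases with severity;
  multiplicative lognormal noise acts at the subject, region-side, frame
  and frame-region levels;
* optional whole-frame motion artifacts (global flux elevation plus slight
  blur) and a robust-z quality-control filter over the frame-mean series;
* a speckle-physics forward model mapping a flow map to speckle intensity,
  local contrast K (sd/mean) and the conventional 1/K^2 flow estimate.

Everything is a pure function of the configuration: per-patient seeds are
derived from the master seed by stable hashing of the patient index, so
adding a patient never perturbs the others.

Frames are rendered lazily (``render_blood_frame``) from the per-frame
regional flux table stored on each record; materializing 8,000 full-size
float rasters at once is neither needed nor affordable in memory.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter, uniform_filter

from .errors import ValidationError
from .fitting import AffineCamera, project
from .landmark_io import Landmarks2D, synthesize_landmarks
from .morphable_model import (
    N_LANDMARKS,
    REGION_CODES,
    SIDES,
    MorphableModel,
    ShapeCoefficients,
)
from .rasterize import rasterize_values
from .segmentation import RegionMaskSet, project_region_masks

logger = logging.getLogger(__name__)

DEFAULT_GRADE_COUNTS = (8, 17, 16, 13, 16, 10)  # HB I..VI


@dataclass
class SimulationConfig:
    """Cohort-generation parameters.

    The defaults reproduce the study conditions: 80 participants split
    8/17/16/13/16/10 over HB grades I-VI, 100 frames each, 512x512 frames,
    and a perfusion asymmetry that grows linearly with grade (``delta`` per
    grade step).  Noise scales are lognormal sigmas.
    """

    grade_counts: tuple = DEFAULT_GRADE_COUNTS
    frames_per_patient: int = 100
    image_size: tuple = (512, 512)  # (H, W)
    delta: float = 0.09
    subject_scale_sd: float = 0.2
    region_jitter_sd: float = 0.05
    frame_noise_sd: float = 0.1
    frame_region_noise_sd: float = 0.03
    artifact_fraction: float = 0.0
    artifact_amplitude_range: tuple = (1.8, 2.5)
    seed: int = 0
    model_vertices: int = 1500
    model_components: int = 10
    base_flux: tuple = (1.2, 1.5, 1.3, 1.1, 1.0, 1.05, 0.95)  # regions B..MB
    skin_flux: float = 0.85
    ambient_flux: float = 0.12
    render_smooth_sigma: float = 1.5
    pixel_noise_sd: float = 0.02

    def __post_init__(self) -> None:
        if len(self.grade_counts) != 6 or any(c < 0 for c in self.grade_counts):
            raise ValidationError("grade_counts must be 6 nonnegative integers (HB I-VI)")
        if self.frames_per_patient < 1:
            raise ValidationError("frames_per_patient must be >= 1")
        if min(self.image_size) <= 0:
            raise ValidationError("image_size must be positive")
        if not 0 < 1 - 5 * self.delta:
            raise ValidationError(
                "delta too large: the grade-VI multiplier 1 - 5*delta must stay positive"
            )
        if not 0 <= self.artifact_fraction <= 1:
            raise ValidationError("artifact_fraction must lie in [0, 1]")
        lo, hi = self.artifact_amplitude_range
        if lo <= 1 or hi < lo:
            raise ValidationError("artifact amplitudes must exceed 1")
        if len(self.base_flux) != 7 or any(b <= 0 for b in self.base_flux):
            raise ValidationError("base_flux must be 7 positive values")

    @property
    def n_patients(self) -> int:
        return int(sum(self.grade_counts))

    @property
    def grades(self) -> list:
        out = []
        for grade, count in enumerate(self.grade_counts, start=1):
            out.extend([grade] * count)
        return out


def perfusion_multiplier(grade: int, delta: float) -> float:
    """Affected-side flux multiplier ``m = 1 - delta*(grade-1)``; P_r = 1/m."""
    if not 1 <= int(grade) <= 6:
        raise ValidationError(f"HB grade must lie in 1-6, got {grade}")
    m = 1.0 - delta * (int(grade) - 1)
    if m <= 0:
        raise ValidationError(f"nonpositive perfusion multiplier for grade {grade}, delta {delta}")
    return m


@dataclass
class PatientRecord:
    """One simulated participant with ground truth for every stage."""

    patient_id: str
    hb_grade: int
    ill_side: str  # 'L' or 'R'; right for grade I by convention
    shape_coeffs: ShapeCoefficients
    camera: AffineCamera
    frame_flux: np.ndarray  # (F, 7, 2) regional flux, sides ordered (L, R)
    frame_skin_flux: np.ndarray  # (F, 2) non-region facial skin flux per side
    artifact_flags: np.ndarray  # (F,) bool
    artifact_amplitudes: np.ndarray  # (F,)
    seed: int
    features: object = None  # FeatureVector, filled by the extraction stage

    @property
    def n_frames(self) -> int:
        return int(self.frame_flux.shape[0])

    @property
    def frame_mean_series(self) -> np.ndarray:
        """Per-frame mean regional flux; the QC screening statistic."""
        return self.frame_flux.mean(axis=(1, 2))


@dataclass
class Cohort:
    config: SimulationConfig
    model: MorphableModel
    records: list

    @property
    def n_frames(self) -> int:
        return int(sum(r.n_frames for r in self.records))


# ---------------------------------------------------------------------------
# Synthetic morphable model
# ---------------------------------------------------------------------------

# region boxes in parametric (u, v) coordinates, right side (u > 0); the left
# side mirrors u.  v grows downward: forehead ~ -1.3, chin ~ +1.2.
_REGION_BOXES = {
    1: (0.28, 0.62, -0.88, -0.74),  # eyebrow: small region above the brow
    2: (0.28, 0.62, -0.48, -0.30),  # eye circumference: within the socket
    3: (0.10, 0.28, 0.00, 0.20),  # nose wing: both sides of the nose
    4: (0.40, 0.75, 0.00, 0.40),  # cheek
    5: (0.06, 0.30, 0.30, 0.40),  # mouth upper
    6: (0.34, 0.50, 0.48, 0.64),  # mouth corner
    7: (0.06, 0.30, 0.74, 0.88),  # mouth below
}


def _landmark_targets() -> np.ndarray:
    """68 iBUG-ordered landmark positions in parametric (u, v) coordinates."""
    pts = np.zeros((N_LANDMARKS, 2))
    # 0-16 jaw line, left ear over the chin to the right ear
    phi = np.linspace(0.0, np.pi, 17)
    pts[0:17, 0] = -np.cos(phi) * 0.95
    pts[0:17, 1] = 0.2 + np.sin(phi)
    # 17-26 eyebrows
    pts[17:22, 0] = np.linspace(-0.62, -0.28, 5)
    pts[22:27, 0] = np.linspace(0.28, 0.62, 5)
    arc = -0.68 - 0.05 * np.sin(np.linspace(0, np.pi, 5))
    pts[17:22, 1] = arc
    pts[22:27, 1] = arc
    # 27-30 nose bridge, 31-35 nose base
    pts[27:31, 0] = 0.0
    pts[27:31, 1] = np.linspace(-0.45, 0.0, 4)
    pts[31:36, 0] = np.linspace(-0.18, 0.18, 5)
    pts[31:36, 1] = 0.12
    # 36-47 eyes (hexagons)
    hexagon = np.array(
        [(-1.0, 0.0), (-0.5, -1.0), (0.5, -1.0), (1.0, 0.0), (0.5, 1.0), (-0.5, 1.0)]
    )
    pts[36:42] = np.array([-0.45, -0.39]) + hexagon * np.array([0.15, 0.07])
    pts[42:48] = np.array([0.45, -0.39]) + hexagon * np.array([0.15, 0.07])
    # 48-59 outer lips, 60-67 inner lips
    ang = np.linspace(np.pi, -np.pi, 13)[:12]
    pts[48:60, 0] = 0.30 * np.cos(ang)
    pts[48:60, 1] = 0.55 - 0.12 * np.sin(ang)
    ang = np.linspace(np.pi, -np.pi, 9)[:8]
    pts[60:68, 0] = 0.18 * np.cos(ang)
    pts[60:68, 1] = 0.55 - 0.05 * np.sin(ang)
    return pts


def _face_surface(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Map parametric coordinates to a face-like 3D surface (z toward camera)."""
    taper = 0.8 + 0.2 * np.sqrt(np.clip(1.0 - (v / 1.35) ** 2, 0.0, None))
    x = u * taper
    y = v
    dome = 0.65 * np.sqrt(np.clip(1.0 - 0.9 * (u**2 + (v / 1.35) ** 2), 0.0, None))
    nose = 0.25 * np.exp(-((u / 0.16) ** 2 + ((v - 0.02) / 0.28) ** 2))
    mouth = 0.05 * np.exp(-((u / 0.35) ** 2 + ((v - 0.55) / 0.20) ** 2))
    brow = 0.06 * np.exp(-(((v + 0.68) / 0.16) ** 2)) * np.exp(
        -(((np.abs(u) - 0.45) / 0.35) ** 2)
    )
    return np.stack([x, y, dome + nose + mouth + brow], axis=-1)


def build_synthetic_model(
    n_vertices: int = 1500, n_components: int = 10, seed=0
) -> MorphableModel:
    """Deterministic synthetic PCA face model with atlas and landmarks.

    The mean surface is a parametric grid over (u, v) with nose/mouth/brow
    displacement fields; the basis consists of seeded random smooth
    deformation modes (low-order polynomial/harmonic fields per coordinate)
    orthonormalized by QR.
    """
    if n_vertices < 300:
        raise ValidationError(
            f"n_vertices={n_vertices} is too few to host 14 disjoint regions (need >= 300)"
        )
    if n_components < 1:
        raise ValidationError("n_components must be >= 1")
    rng = np.random.default_rng(seed)
    nv = int(round(np.sqrt(n_vertices * 1.3)))
    nu = int(np.ceil(n_vertices / nv))
    us = np.linspace(-1.0, 1.0, nu)
    vs = np.linspace(-1.3, 1.2, nv)
    uu, vv = np.meshgrid(us, vs)
    u = uu.ravel()
    v = vv.ravel()
    mean_shape = _face_surface(u, v)
    n = mean_shape.shape[0]

    # grid triangulation
    tris = []
    for r in range(nv - 1):
        for c in range(nu - 1):
            a = r * nu + c
            tris.append((a, a + 1, a + nu))
            tris.append((a + 1, a + nu + 1, a + nu))
    triangles = np.asarray(tris, dtype=np.int64)

    # region atlas from parametric boxes (half-open, assigned once)
    assigned = np.zeros(n, dtype=bool)
    atlas = {}
    for code in REGION_CODES:
        ulo, uhi, vlo, vhi = _REGION_BOXES[code]
        for side in SIDES:
            uu_side = -u if side == "L" else u
            inside = (
                (uu_side >= ulo)
                & (uu_side < uhi)
                & (v >= vlo)
                & (v < vhi)
                & ~assigned
            )
            idx = np.nonzero(inside)[0]
            if idx.size == 0:
                raise ValidationError(
                    f"region ({code}, {side}) received no vertices; "
                    f"increase n_vertices (got {n_vertices})"
                )
            assigned[idx] = True
            atlas[(code, side)] = idx

    # landmark correspondences: greedy nearest unused vertex in (u, v)
    targets = _landmark_targets()
    params = np.stack([u, v], axis=1)
    used = np.zeros(n, dtype=bool)
    corr = np.empty(N_LANDMARKS, dtype=np.int64)
    for i, t in enumerate(targets):
        d2 = np.sum((params - t) ** 2, axis=1)
        d2[used] = np.inf
        j = int(np.argmin(d2))
        corr[i] = j
        used[j] = True

    # smooth random deformation modes, orthonormalized
    feats = np.stack(
        [
            u,
            v,
            u**2,
            u * v,
            v**2,
            u**3,
            u**2 * v,
            u * v**2,
            v**3,
            np.sin(np.pi * u),
            np.sin(np.pi * v / 1.3),
            np.cos(np.pi * u) * np.cos(np.pi * v / 1.3),
            np.sin(2 * np.pi * u),
            np.sin(2 * np.pi * v / 1.3),
        ],
        axis=1,
    )
    max_modes = 3 * feats.shape[1]
    if n_components > max_modes:
        raise ValidationError(f"n_components={n_components} exceeds {max_modes} smooth modes")
    cols = []
    for _ in range(n_components):
        w = rng.normal(size=(feats.shape[1], 3))
        cols.append((feats @ w).ravel())
    B = np.stack(cols, axis=1)
    # remove the affine gauge: displacement fields of the form A x + t are
    # absorbable by the affine camera.  The camera is estimated from the 68
    # landmark correspondences, so each mode's landmark restriction is made
    # least-squares orthogonal to the affine fields of the mean shape there.
    affine = np.zeros((3 * n, 12))
    k = 0
    for c in range(3):
        for j in range(3):
            affine[c::3, k] = mean_shape[:, j]
            k += 1
        affine[c::3, k] = 1.0
        k += 1
    lm_rows = (3 * corr[:, None] + np.arange(3)).ravel()
    coeffs_aff, *_ = np.linalg.lstsq(affine[lm_rows], B[lm_rows], rcond=None)
    B = B - affine @ coeffs_aff
    q, _ = np.linalg.qr(B)
    # deterministic sign convention: largest-magnitude entry positive
    for j in range(q.shape[1]):
        i = int(np.argmax(np.abs(q[:, j])))
        if q[i, j] < 0:
            q[:, j] = -q[:, j]
    # one sigma of the leading mode displaces the surface by ~5% of the face
    # half-width (per-vertex RMS = sigma/sqrt(N)), a realistic inter-face scale
    stddevs = 0.05 * np.sqrt(n) * 0.9 ** np.arange(n_components)

    return MorphableModel(
        mean_shape=mean_shape,
        basis=q,
        stddevs=stddevs,
        triangles=triangles,
        landmark_corr=corr,
        region_atlas=atlas,
    )


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------


def _patient_seed(master_seed: int, index: int) -> int:
    """Stable per-patient seed: hashing (master, index) via SeedSequence."""
    return int(np.random.SeedSequence([int(master_seed), int(index)]).generate_state(1)[0])


def _sample_camera(rng: np.random.Generator, image_size: tuple) -> AffineCamera:
    h, w = image_size
    s = rng.uniform(0.28, 0.33) * min(h, w)
    theta = rng.normal(0.0, np.deg2rad(2.0))
    tilt = rng.normal(0.0, 0.02 * s, size=2)
    linear = np.array(
        [
            [s * np.cos(theta), -s * np.sin(theta), tilt[0]],
            [s * np.sin(theta), s * np.cos(theta), tilt[1]],
        ]
    )
    center = np.array([w / 2.0, h / 2.0]) + rng.normal(0.0, 0.01 * min(h, w), size=2)
    return AffineCamera.from_linear(linear, center)


def camera_for_size(
    camera: AffineCamera, from_size: tuple, to_size: tuple
) -> AffineCamera:
    """Rescale a camera calibrated for one raster size to another."""
    fy = to_size[0] / from_size[0]
    fx = to_size[1] / from_size[1]
    C = camera.C.copy()
    C[0, :] *= fx
    C[1, :] *= fy
    C[2] = (0.0, 0.0, 0.0, 1.0)
    return AffineCamera(C)


def _simulate_flux(
    rng: np.random.Generator, config: SimulationConfig, grade: int, ill_side: str
):
    """Per-frame regional and skin flux for one patient (sides ordered L, R)."""
    f = config.frames_per_patient
    base = np.asarray(config.base_flux, dtype=float)[:, None]  # (7, 1)
    subject = rng.lognormal(0.0, config.subject_scale_sd)
    jitter = rng.lognormal(0.0, config.region_jitter_sd, size=(7, 2))
    frame = rng.lognormal(0.0, config.frame_noise_sd, size=f)
    eps = rng.lognormal(0.0, config.frame_region_noise_sd, size=(f, 7, 2))
    flux = base * subject * jitter * frame[:, None, None] * eps
    skin = config.skin_flux * subject * frame[:, None] * np.ones((f, 2))
    m = perfusion_multiplier(grade, config.delta)
    ill_col = SIDES.index(ill_side)
    flux[:, :, ill_col] *= m
    skin[:, ill_col] *= m
    flags = rng.random(f) < config.artifact_fraction
    amplitudes = np.ones(f)
    amplitudes[flags] = rng.uniform(*config.artifact_amplitude_range, size=int(flags.sum()))
    flux *= amplitudes[:, None, None]
    skin *= amplitudes[:, None]
    return flux, skin, flags, amplitudes


def simulate_cohort(config: SimulationConfig, model: MorphableModel | None = None) -> Cohort:
    """Generate the full cohort; a pure function of the configuration."""
    if model is None:
        model_seed = np.random.SeedSequence([int(config.seed), 0xFACE])
        model = build_synthetic_model(
            config.model_vertices, config.model_components, seed=model_seed
        )
    records = []
    for idx, grade in enumerate(config.grades):
        seed = _patient_seed(config.seed, idx)
        rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), int(idx)]))
        alpha = rng.normal(0.0, 1.0, size=model.n_components)
        ill_side = "R" if grade == 1 else ("L", "R")[rng.integers(2)]
        camera = _sample_camera(rng, config.image_size)
        flux, skin, flags, amplitudes = _simulate_flux(rng, config, grade, ill_side)
        records.append(
            PatientRecord(
                patient_id=f"P{idx:03d}",
                hb_grade=grade,
                ill_side=ill_side,
                shape_coeffs=ShapeCoefficients(alpha),
                camera=camera,
                frame_flux=flux,
                frame_skin_flux=skin,
                artifact_flags=flags,
                artifact_amplitudes=amplitudes,
                seed=seed,
            )
        )
    return Cohort(config=config, model=model, records=records)


def sample_patient_means(
    config: SimulationConfig,
    grade: int,
    n: int,
    rng: np.random.Generator,
    ill_side: str = "R",
    chunk: int = 1000,
) -> np.ndarray:
    """Monte-Carlo draws of per-patient mean regional flux, shape (n, 7, 2).

    Each draw averages ``frames_per_patient`` frames of the generative flux
    model (no rendering); used for statistical checks of the perfusion model
    at large n.
    """
    ill_col = SIDES.index(ill_side)
    m = perfusion_multiplier(grade, config.delta)
    base = np.asarray(config.base_flux, dtype=float)[None, :, None]
    f = config.frames_per_patient
    out = np.empty((n, 7, 2))
    for start in range(0, n, chunk):
        size = min(chunk, n - start)
        subject = rng.lognormal(0.0, config.subject_scale_sd, size=(size, 1, 1))
        jitter = rng.lognormal(0.0, config.region_jitter_sd, size=(size, 7, 2))
        frame = rng.lognormal(0.0, config.frame_noise_sd, size=(size, f)).mean(axis=1)
        eps = rng.lognormal(
            0.0, config.frame_region_noise_sd, size=(size, f, 7, 2)
        ).mean(axis=1)
        flux = base * subject * jitter * frame[:, None, None] * eps
        flux[:, :, ill_col] *= m
        out[start : start + size] = flux
    return out


def patient_region_means(record: PatientRecord, qc_z_threshold: float = 3.0):
    """QC-screened per-patient mean regional flux as a (7, 2) array.

    Frames whose mean-flux robust z exceeds the threshold are dropped before
    averaging (they correspond to motion artifacts).
    """
    _, flagged = qc_filter(record.frame_mean_series, qc_z_threshold)
    keep = np.ones(record.n_frames, dtype=bool)
    keep[flagged] = False
    if not keep.any():
        raise ValidationError(f"QC rejected every frame of {record.patient_id}")
    return record.frame_flux[keep].mean(axis=0)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def _vertex_flux(model: MorphableModel, record: PatientRecord, frame_idx: int) -> np.ndarray:
    values = np.empty(model.n_vertices)
    left = model.mean_shape[:, 0] < 0
    values[left] = record.frame_skin_flux[frame_idx, 0]
    values[~left] = record.frame_skin_flux[frame_idx, 1]
    for region_i, region in enumerate(REGION_CODES):
        for side_i, side in enumerate(SIDES):
            values[model.region_atlas[(region, side)]] = record.frame_flux[
                frame_idx, region_i, side_i
            ]
    return values


def render_blood_frame(
    model: MorphableModel,
    record: PatientRecord,
    frame_idx: int,
    config: SimulationConfig,
    image_size: tuple | None = None,
) -> np.ndarray:
    """Render one blood-flow raster (positive float) for a frame index.

    Per-vertex flux is interpolated barycentrically over the projected
    triangles on a low positive ambient background, Gaussian-smoothed, and
    modulated by seeded multiplicative pixel noise.  Artifact frames get the
    extra slight blur of a moving head (their flux is already elevated in
    the record's flux table).
    """
    size = tuple(image_size or config.image_size)
    camera = camera_for_size(record.camera, config.image_size, size)
    mesh_vertices = _instantiated_vertices(model, record)
    proj = project(camera, mesh_vertices)
    values = _vertex_flux(model, record, frame_idx)
    img = rasterize_values(proj, model.triangles, values, size, background=config.ambient_flux)
    if config.render_smooth_sigma > 0:
        img = gaussian_filter(img, config.render_smooth_sigma)
    rng = np.random.default_rng(np.random.SeedSequence([record.seed, 7, int(frame_idx)]))
    if config.pixel_noise_sd > 0:
        img = img * rng.lognormal(0.0, config.pixel_noise_sd, size=img.shape)
    if record.artifact_flags[frame_idx]:
        img = gaussian_filter(img, 1.0)
    return np.maximum(img, 1e-9)


def render_color_frame(
    model: MorphableModel,
    record: PatientRecord,
    config: SimulationConfig,
    image_size: tuple | None = None,
) -> np.ndarray:
    """Flat-shaded front-lit color render (uint8 RGB) for landmarking/QC."""
    size = tuple(image_size or config.image_size)
    camera = camera_for_size(record.camera, config.image_size, size)
    vertices = _instantiated_vertices(model, record)
    proj = project(camera, vertices)
    normals = _vertex_normals(vertices, model.triangles)
    shade = np.clip(normals[:, 2], 0.0, 1.0)
    img = rasterize_values(proj, model.triangles, shade, size, background=0.0)
    skin = np.array([205, 170, 150], dtype=float)
    rgb = (img[..., None] * skin + (img[..., None] == 0) * 20.0).clip(0, 255)
    return rgb.astype(np.uint8)


def _instantiated_vertices(model: MorphableModel, record: PatientRecord) -> np.ndarray:
    from .morphable_model import instantiate_shape

    return instantiate_shape(model, record.shape_coeffs).vertices


def _vertex_normals(vertices: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    v0, v1, v2 = (vertices[triangles[:, i]] for i in range(3))
    fn = np.cross(v1 - v0, v2 - v0)
    normals = np.zeros_like(vertices)
    for i in range(3):
        np.add.at(normals, triangles[:, i], fn)
    norm = np.linalg.norm(normals, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    normals /= norm
    # orient toward the camera (+z)
    flip = normals[:, 2] < 0
    normals[flip] *= -1
    return normals


def true_label_image(
    model: MorphableModel,
    record: PatientRecord,
    config: SimulationConfig,
    image_size: tuple | None = None,
) -> RegionMaskSet:
    """Ground-truth region label image rendered from the generating pose."""
    size = tuple(image_size or config.image_size)
    camera = camera_for_size(record.camera, config.image_size, size)
    return project_region_masks(model, record.shape_coeffs, camera, size)


def true_landmarks(
    model: MorphableModel,
    record: PatientRecord,
    config: SimulationConfig,
    image_size: tuple | None = None,
    noise_sd: float = 0.0,
    seed=None,
) -> Landmarks2D:
    """Ground-truth (optionally noise-perturbed) landmarks for a record."""
    size = tuple(image_size or config.image_size)
    camera = camera_for_size(record.camera, config.image_size, size)
    if seed is None:
        seed = np.random.default_rng(np.random.SeedSequence([record.seed, 11]))
    return synthesize_landmarks(
        model, record.shape_coeffs, camera, noise_sd=noise_sd, seed=seed
    )


# ---------------------------------------------------------------------------
# Motion artifacts and quality control
# ---------------------------------------------------------------------------


def inject_motion_artifact(
    frame: np.ndarray, amplitude: float, blur_sigma: float = 0.8
) -> np.ndarray:
    """Simulate head motion: whole-frame flux elevation plus slight blur.

    The multiplicative elevation is applied first (the frame mean scales by
    exactly ``amplitude`` before blurring); set ``blur_sigma=0`` to skip the
    blur.
    """
    if amplitude <= 1:
        raise ValidationError(f"artifact amplitude must exceed 1, got {amplitude}")
    out = np.asarray(frame, dtype=float) * amplitude
    if blur_sigma > 0:
        out = gaussian_filter(out, blur_sigma)
    return out


def robust_z(series: np.ndarray) -> np.ndarray:
    """Median/MAD z-scores; zeros (with a warning) when the MAD vanishes."""
    series = np.asarray(series, dtype=float)
    med = np.median(series)
    mad = np.median(np.abs(series - med))
    if mad == 0:
        logger.warning("robust_z: zero dispersion (MAD = 0); no frame can be flagged")
        return np.zeros_like(series)
    return (series - med) / (1.4826 * mad)


def qc_filter(frames, z_threshold: float = 3.0):
    """Screen frames whose mean flux is abnormally elevated.

    ``frames`` is either a sequence of 2-D rasters or a 1-D series of frame
    means.  Head motion raises the whole-frame flux, so frames with robust
    z-score above ``z_threshold`` (one-sided) are flagged and removed.
    Returns ``(kept, flagged_indices)`` with ``kept`` matching the input
    form.
    """
    frames = list(frames) if not isinstance(frames, np.ndarray) else frames
    n = len(frames)
    if n < 5:
        raise ValidationError(f"QC needs at least 5 frames (got {n}); statistic unstable")
    if isinstance(frames, np.ndarray) and frames.ndim == 1:
        means = frames.astype(float)
        as_series = True
    else:
        means = np.array([float(np.mean(f)) for f in frames])
        as_series = False
    z = robust_z(means)
    flagged = np.nonzero(z > z_threshold)[0]
    keep = np.setdiff1d(np.arange(n), flagged)
    kept = means[keep] if as_series else [frames[i] for i in keep]
    return kept, flagged


# ---------------------------------------------------------------------------
# Speckle physics forward model
# ---------------------------------------------------------------------------


def speckle_forward(
    flow_map: np.ndarray,
    window: int = 7,
    exposure_scale: float = 1.0,
    seed=None,
    n_realizations: int = 10,
    mean_intensity: float = 1.0,
):
    """Synthesize speckle and recover flow from spatial contrast.

    Flow blurs the speckle interference pattern, lowering the local contrast
    ``K = sd / mean``; the model takes ``K_true = (1 + s * flow)^(-1/2)`` so
    the conventional estimate ``1/K^2`` is affine in flow.  Intensity is
    gamma-distributed with the prescribed local contrast; ``K`` is measured
    over a sliding ``window`` and averaged over ``n_realizations``
    independent speckle frames (temporal averaging, as LSCI devices do).

    Returns ``(intensity, K, flow_estimate)``; the intensity frame is the
    first realization.
    """
    flow = np.asarray(flow_map, dtype=float)
    if flow.ndim != 2 or flow.size == 0:
        raise ValidationError("flow_map must be a nonempty 2-D array")
    if np.any(~np.isfinite(flow)) or flow.min() <= 0:
        raise ValidationError("flow_map values must be positive and finite")
    if window < 3 or window % 2 == 0:
        raise ValidationError("window must be an odd integer >= 3")
    if exposure_scale <= 0:
        raise ValidationError("exposure_scale must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    k2_true = 1.0 / (1.0 + exposure_scale * flow)
    shape_param = 1.0 / k2_true  # gamma shape: sd/mean = K_true
    k2_acc = np.zeros_like(flow)
    first = None
    masked = 0
    for _ in range(n_realizations):
        intensity = rng.gamma(shape_param, mean_intensity * k2_true)
        if first is None:
            first = intensity
        mu = uniform_filter(intensity, window)
        var = uniform_filter(intensity**2, window) - mu**2
        good = mu > 0
        masked += int((~good).sum())
        k2 = np.zeros_like(mu)
        k2[good] = np.clip(var[good], 0.0, None) / mu[good] ** 2
        k2_acc += k2
    if masked:
        logger.warning("speckle_forward: %d windows with zero local mean were masked", masked)
    k2_mean = k2_acc / n_realizations
    K = np.sqrt(k2_mean)
    flow_est = np.full_like(flow, np.nan)
    pos = k2_mean > 0
    flow_est[pos] = (1.0 / k2_mean[pos] - 1.0) / exposure_scale
    return first, K, flow_est
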