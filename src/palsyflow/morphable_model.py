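"""PCA statistical face-shape model, region atlas, and shape instantiation.

A morphable model represents face shape as a mean mesh plus a linear
combination of principal deformation modes: ``S = mean + sum_i alpha_i *
sigma_i * v_i``.  Coefficients ``alpha`` are standardized (unit-normal prior),
the basis columns ``v_i`` are unit vectors, and the per-mode standard
deviations ``sigma_i`` are stored separately.

The model also carries the segmentation conventions used downstream:

* ``landmark_corr`` — for each of the 68 facial landmarks (iBUG ordering),
  the index of the corresponding model vertex;
* ``region_atlas`` — for each of the 7 premarked facial regions and each face
  side, the set of vertex indices belonging to that region.

Region codes (shared across the package):

====  ==================  ======
code  region              abbrev
====  ==================  ======
1     eyebrow             B
2     eye circumference   E
3     nose wing           N
4     cheek               C
5     mouth upper         MU
6     mouth corner        MC
7     mouth below         MB
====  ==================  ======
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import FormatError, ValidationError

N_LANDMARKS = 68

REGION_NAMES = {
    1: "eyebrow",
    2: "eye_circumference",
    3: "nose_wing",
    4: "cheek",
    5: "mouth_upper",
    6: "mouth_corner",
    7: "mouth_below",
}
REGION_ABBREV = {1: "B", 2: "E", 3: "N", 4: "C", 5: "MU", 6: "MC", 7: "MB"}
REGION_CODES = tuple(REGION_NAMES)
SIDES = ("L", "R")


@dataclass
class ShapeCoefficients:
    """Standardized PCA shape coefficients (dimensionless)."""

    alpha: np.ndarray

    def __post_init__(self) -> None:
        self.alpha = np.atleast_1d(np.asarray(self.alpha, dtype=float))
        if self.alpha.ndim != 1:
            raise ValidationError("shape coefficients must be a 1-D vector")
        if not np.all(np.isfinite(self.alpha)):
            raise ValidationError("shape coefficients must be finite")

    @classmethod
    def zeros(cls, m: int) -> "ShapeCoefficients":
        return cls(np.zeros(m))

    def __len__(self) -> int:
        return self.alpha.size


@dataclass
class FaceMesh:
    """A concrete triangulated face surface instantiated from the model."""

    vertices: np.ndarray  # (N, 3)
    triangles: np.ndarray  # (T, 3) int


@dataclass
class MorphableModel:
    mean_shape: np.ndarray  # (N, 3)
    basis: np.ndarray  # (3N, M), unit-norm columns
    stddevs: np.ndarray  # (M,), positive
    triangles: np.ndarray  # (T, 3) int
    landmark_corr: np.ndarray  # (68,) int
    region_atlas: dict = field(default_factory=dict)  # (code, side) -> int array

    def __post_init__(self) -> None:
        self.mean_shape = np.asarray(self.mean_shape, dtype=float)
        self.basis = np.asarray(self.basis, dtype=float)
        self.stddevs = np.asarray(self.stddevs, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        self.landmark_corr = np.asarray(self.landmark_corr, dtype=np.int64)
        self.region_atlas = {
            key: np.asarray(idx, dtype=np.int64) for key, idx in self.region_atlas.items()
        }
        self.validate()

    @property
    def n_vertices(self) -> int:
        return self.mean_shape.shape[0]

    @property
    def n_components(self) -> int:
        return self.basis.shape[1]

    def validate(self) -> None:
        n = self.n_vertices
        if self.mean_shape.ndim != 2 or self.mean_shape.shape[1] != 3:
            raise FormatError("mean_shape: expected an (N, 3) array")
        if self.basis.ndim != 2 or self.basis.shape[0] != 3 * n:
            raise FormatError(
                f"basis: expected {3 * n} rows (3 x {n} vertices), found {self.basis.shape[0]}"
            )
        if self.stddevs.shape != (self.basis.shape[1],):
            raise FormatError(
                f"stddevs: expected {self.basis.shape[1]} values (one per basis column), "
                f"found {self.stddevs.size}"
            )
        if np.any(self.stddevs <= 0):
            raise FormatError("stddevs: all values must be strictly positive")
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise FormatError("triangles: expected a (T, 3) array")
        if self.triangles.size and (
            self.triangles.min() < 0 or self.triangles.max() >= n
        ):
            raise FormatError("triangles: vertex index out of range")
        if self.landmark_corr.shape != (N_LANDMARKS,):
            raise FormatError(
                f"landmark_corr: expected {N_LANDMARKS} indices, found {self.landmark_corr.size}"
            )
        if self.landmark_corr.min() < 0 or self.landmark_corr.max() >= n:
            raise FormatError("landmark_corr: vertex index out of range")
        seen: set[int] = set()
        for code in REGION_CODES:
            for side in SIDES:
                if (code, side) not in self.region_atlas:
                    raise FormatError(f"region_atlas: missing region ({code}, {side})")
                idx = self.region_atlas[(code, side)]
                if idx.size == 0:
                    raise FormatError(f"region_atlas: region ({code}, {side}) is empty")
                if idx.min() < 0 or idx.max() >= n:
                    raise FormatError(
                        f"region_atlas: region ({code}, {side}) has vertex index out of range"
                    )
                overlap = seen.intersection(idx.tolist())
                if overlap:
                    raise FormatError(
                        f"region_atlas: region ({code}, {side}) overlaps another region "
                        f"(e.g. vertex {min(overlap)})"
                    )
                seen.update(idx.tolist())


def instantiate_shape(model: MorphableModel, coeffs: ShapeCoefficients) -> FaceMesh:
    """Instantiate a face surface: ``mean + sum_i alpha_i * sigma_i * v_i``.

    Coefficients may be shorter than the model dimensionality; missing modes
    are treated as zero.  A zero coefficient vector returns the mean shape
    exactly (no floating-point drift).
    """
    alpha = np.atleast_1d(np.asarray(coeffs.alpha, dtype=float))
    m = model.n_components
    if alpha.size > m:
        raise ValidationError(
            f"{alpha.size} coefficients exceed the model dimensionality M={m}"
        )
    if alpha.size == 0 or not alpha.any():
        return FaceMesh(model.mean_shape.copy(), model.triangles)
    disp = model.basis[:, : alpha.size] @ (alpha * model.stddevs[: alpha.size])
    return FaceMesh(model.mean_shape + disp.reshape(-1, 3), model.triangles)


def region_vertices(model: MorphableModel, region_code: int, side: str) -> np.ndarray:
    """Vertex indices of one premarked region on one face side."""
    if region_code not in REGION_NAMES:
        raise ValidationError(
            f"unknown region code {region_code!r}; valid codes are 1-7"
        )
    side = str(side).upper()
    if side not in SIDES:
        raise ValidationError(f"unknown side {side!r}; expected 'L' or 'R'")
    return model.region_atlas[(region_code, side)]


# ---------------------------------------------------------------------------
# Serialization: directory container with a JSON manifest, flat little-endian
# float64/int64 arrays, and a courtesy PLY export of the mean mesh.
# ---------------------------------------------------------------------------

_MANIFEST = "manifest.json"
_ARRAYS = {
    "mean_shape": ("<f8", "mean_shape.f64"),
    "basis": ("<f8", "basis.f64"),
    "stddevs": ("<f8", "stddevs.f64"),
    "triangles": ("<i8", "triangles.i64"),
}


def save_model(model: MorphableModel, path: str | Path) -> None:
    """Write the model container (manifest + flat binary arrays + mesh.ply)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {
        "format": "palsyflow-morphable-model",
        "version": 1,
        "n_vertices": model.n_vertices,
        "n_components": model.n_components,
        "n_triangles": int(model.triangles.shape[0]),
        "landmark_corr": model.landmark_corr.tolist(),
        "region_atlas": {
            f"{code}{side}": model.region_atlas[(code, side)].tolist()
            for code in REGION_CODES
            for side in SIDES
        },
    }
    (path / _MANIFEST).write_text(json.dumps(manifest, indent=1))
    for name, (dtype, fname) in _ARRAYS.items():
        arr = getattr(model, name)
        (path / fname).write_bytes(np.ascontiguousarray(arr, dtype=dtype).tobytes())
    _export_ply(model, path / "mesh.ply")


def _export_ply(model: MorphableModel, path: Path) -> None:
    # visualization convenience only; never read back
    try:
        import trimesh

        trimesh.Trimesh(
            vertices=model.mean_shape, faces=model.triangles, process=False
        ).export(path)
    except Exception:  # pragma: no cover - cosmetic output
        pass


def load_model(path: str | Path) -> MorphableModel:
    """Load a model container written by :func:`save_model`.

    Raises :class:`FormatError` naming the offending field when the manifest
    and the binary payloads disagree.
    """
    path = Path(path)
    mpath = path / _MANIFEST
    if not mpath.exists():
        raise FormatError(f"manifest: {mpath} not found")
    try:
        manifest = json.loads(mpath.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"manifest: invalid JSON ({exc})") from exc
    for key in ("n_vertices", "n_components", "n_triangles", "landmark_corr", "region_atlas"):
        if key not in manifest:
            raise FormatError(f"manifest: missing field {key!r}")
    n = int(manifest["n_vertices"])
    m = int(manifest["n_components"])
    t = int(manifest["n_triangles"])
    shapes = {
        "mean_shape": (n, 3),
        "basis": (3 * n, m),
        "stddevs": (m,),
        "triangles": (t, 3),
    }
    arrays = {}
    for name, (dtype, fname) in _ARRAYS.items():
        fpath = path / fname
        if not fpath.exists():
            raise FormatError(f"{name}: payload {fname} not found")
        raw = fpath.read_bytes()
        expect = int(np.prod(shapes[name])) * 8
        if len(raw) != expect:
            raise FormatError(
                f"{name}: expected {expect} bytes for shape {shapes[name]}, "
                f"found {len(raw)} (truncated or inconsistent with manifest)"
            )
        arrays[name] = np.frombuffer(raw, dtype=dtype).reshape(shapes[name]).copy()
    atlas = {}
    for code in REGION_CODES:
        for side in SIDES:
            key = f"{code}{side}"
            if key not in manifest["region_atlas"]:
                raise FormatError(f"region_atlas: missing region {key!r}")
            atlas[(code, side)] = np.asarray(manifest["region_atlas"][key], dtype=np.int64)
    return MorphableModel(
        mean_shape=arrays["mean_shape"],
        basis=arrays["basis"],
        stddevs=arrays["stddevs"],
        triangles=arrays["triangles"],
        landmark_corr=np.asarray(manifest["landmark_corr"], dtype=np.int64),
        region_atlas=atlas,
    )
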