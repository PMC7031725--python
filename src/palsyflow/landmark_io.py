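"""Read, write, validate and synthesize 68-point 2D facial landmarks.

Pixel coordinates are 0-based, x rightward, y downward, in iBUG 68-point
ordering.  Two text dialects are supported: a pts-like format (one ``x y``
pair per line, optional ``version``/``n_points``/brace header lines) and CSV
with an ``x,y`` header.

Real-image landmark detection is delegated to any external detector that can
produce such a file; :func:`synthesize_landmarks` generates landmarks from a
posed model instance for simulation and testing.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ValidationError
from .morphable_model import N_LANDMARKS, MorphableModel, ShapeCoefficients, instantiate_shape


@dataclass
class Landmarks2D:
    points: np.ndarray  # (68, 2) float, pixel coordinates

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.shape != (N_LANDMARKS, 2):
            found = self.points.shape[0] if self.points.ndim == 2 else self.points.shape
            raise ValidationError(f"expected {N_LANDMARKS} landmark points, found {found}")
        if not np.all(np.isfinite(self.points)):
            raise ValidationError("landmark coordinates must be finite")


_HEADER_PREFIXES = ("version", "n_points", "{", "}")


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in ("txt", "csv"):
            raise ValidationError(f"unknown landmark format {fmt!r}; expected 'txt' or 'csv'")
        return fmt
    return "csv" if path.suffix.lower() == ".csv" else "txt"


def load_landmarks(path: str | Path, fmt: str | None = None) -> Landmarks2D:
    path = Path(path)
    fmt = _infer_format(path, fmt)
    rows: list[list[float]] = []
    if fmt == "csv":
        with path.open(newline="") as fh:
            reader = csv.reader(fh)
            for i, row in enumerate(reader):
                if not row:
                    continue
                if i == 0 and not _is_number(row[0]):
                    continue  # header
                rows.append([float(row[0]), float(row[1])])
    else:
        for line in path.read_text().splitlines():
            line = line.strip()
            if not line or any(line.lower().startswith(p) for p in _HEADER_PREFIXES):
                continue
            parts = line.replace(",", " ").split()
            rows.append([float(parts[0]), float(parts[1])])
    if len(rows) != N_LANDMARKS:
        raise ValidationError(
            f"expected {N_LANDMARKS} landmark points, found {len(rows)} in {path}"
        )
    return Landmarks2D(np.asarray(rows, dtype=float))


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def save_landmarks(lms: Landmarks2D, path: str | Path, fmt: str | None = None) -> None:
    """Write landmarks at 6-decimal precision."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "csv":
        lines = ["x,y"] + [f"{x:.6f},{y:.6f}" for x, y in lms.points]
    else:
        lines = [f"{x:.6f} {y:.6f}" for x, y in lms.points]
    path.write_text("\n".join(lines) + "\n")


def synthesize_landmarks(
    model: MorphableModel,
    coeffs: ShapeCoefficients,
    camera,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator | None = None,
) -> Landmarks2D:
    """Project the model's landmark-correspondence vertices through a camera.

    Adds isotropic Gaussian pixel noise of standard deviation ``noise_sd``
    (a stand-in for detector error); reproducible for a fixed seed.
    """
    from .fitting import project

    if noise_sd < 0:
        raise ValidationError("noise_sd must be nonnegative")
    mesh = instantiate_shape(model, coeffs)
    pts = project(camera, mesh.vertices[model.landmark_corr])
    if noise_sd > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        pts = pts + rng.normal(0.0, noise_sd, size=pts.shape)
    return Landmarks2D(pts)
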