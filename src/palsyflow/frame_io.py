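"""Raster and tabular I/O for frames, masks, landmarks and features.

Blood-flow frames are single-channel 32-bit float TIFFs (lossless for the
device's positive relative perfusion values); color frames are 8-bit PNG;
region label images are 8-bit PNG with codes 0-14; features and reports are
CSV/JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .errors import FormatError, ValidationError
from .perfusion_features import FEATURE_NAMES, FeatureVector
from .segmentation import N_REGION_CODES, RegionMaskSet


def write_flow_frame(frame: np.ndarray, path: str | Path) -> None:
    """Write a blood-flow raster as single-channel float32 TIFF."""
    frame = np.asarray(frame)
    if frame.ndim != 2:
        raise FormatError(f"blood-flow frame must be single-channel 2-D, got shape {frame.shape}")
    _validate_positive(frame)
    tifffile.imwrite(str(path), frame.astype(np.float32))


def read_flow_frame(path: str | Path) -> np.ndarray:
    """Read a blood-flow TIFF; validates single channel and positivity."""
    arr = tifffile.imread(str(path))
    if arr.ndim != 2:
        raise FormatError(
            f"expected a single-channel blood-flow TIFF, got shape {arr.shape} from {path}"
        )
    arr = arr.astype(np.float64)
    _validate_positive(arr)
    return arr


def _validate_positive(arr: np.ndarray) -> None:
    bad = int(np.sum(~np.isfinite(arr)) + np.sum(arr[np.isfinite(arr)] <= 0))
    if bad:
        raise ValidationError(
            f"blood-flow values must be positive finite; {bad} offending pixel(s)"
        )


def write_label_image(masks: RegionMaskSet, path: str | Path) -> None:
    iio.imwrite(str(path), masks.label_image.astype(np.uint8))


def read_label_image(path: str | Path) -> RegionMaskSet:
    arr = np.asarray(iio.imread(str(path)))
    if arr.ndim == 3:
        raise FormatError(f"label image must be single-channel, got shape {arr.shape}")
    if arr.max() > N_REGION_CODES:
        raise FormatError(f"label image contains codes above {N_REGION_CODES}")
    return RegionMaskSet(arr.astype(np.uint8))


def write_color_frame(rgb: np.ndarray, path: str | Path) -> None:
    iio.imwrite(str(path), np.asarray(rgb, dtype=np.uint8))


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------

FEATURE_COLUMNS = ["patient_id", "ill_side", "hb_grade", *FEATURE_NAMES, "volume_min"]


def features_to_frame(records) -> pd.DataFrame:
    """Tabulate per-patient features (records must carry .features)."""
    rows = []
    for r in records:
        if r.features is None:
            raise ValidationError(f"patient {r.patient_id} has no extracted features")
        row = {
            "patient_id": r.patient_id,
            "ill_side": r.ill_side,
            "hb_grade": int(r.hb_grade),
        }
        row.update(dict(zip(FEATURE_NAMES, r.features.values)))
        row["volume_min"] = r.features.volume_min
        rows.append(row)
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)


def load_features_csv(path: str | Path):
    """Read a features CSV -> (ids, ill_sides, grades, FeatureVector list)."""
    df = pd.read_csv(path)
    missing = [c for c in FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"features CSV missing columns: {missing}")
    feats = [
        FeatureVector(values=row[list(FEATURE_NAMES)].to_numpy(dtype=float),
                      volume_min=float(row["volume_min"]))
        for _, row in df.iterrows()
    ]
    return (
        df["patient_id"].astype(str).tolist(),
        df["ill_side"].astype(str).tolist(),
        df["hb_grade"].astype(int).tolist(),
        feats,
    )


def write_json(payload: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
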