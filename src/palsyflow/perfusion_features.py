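"""Regional perfusion features for House-Brackmann grading.

From a registered blood-flow raster and a region label image this module
computes per-region mean flow, orders the 14 means by affected/healthy side,
and rescales them by the minimum regional mean (the device reports perfusion
only in relative units, so features must be scale-free):

    features = [A_B, A_E, A_N, A_C, A_MU, A_MC, A_MB,
                H_B, H_E, H_N, H_C, H_MU, H_MC, H_MB] / Volume_min

where ``A_*`` are the affected-side regional means in region order
(B, E, N, C, MU, MC, MB), ``H_*`` the healthy-side ones, and ``Volume_min``
the minimum over all 14 raw means.  After normalization the minimum entry is
exactly 1 and every entry is >= 1.

The regional asymmetry statistic is ``P_r = P_h / P_a`` — healthy-side over
affected-side mean flow; 1 indicates symmetric perfusion and larger values
indicate greater paralysis-associated asymmetry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .morphable_model import REGION_ABBREV, REGION_CODES, SIDES
from .segmentation import RegionMaskSet, mask_code

FEATURE_NAMES = tuple(
    f"{half}_{REGION_ABBREV[code]}" for half in ("A", "H") for code in REGION_CODES
)


@dataclass
class RegionMeans:
    """Mean blood flow per (region, side); missing regions are None."""

    means: dict  # (region_code, side) -> float | None

    def __post_init__(self) -> None:
        for region in REGION_CODES:
            for side in SIDES:
                if (region, side) not in self.means:
                    raise ValidationError(f"missing entry for region ({region}, {side})")
                v = self.means[(region, side)]
                if v is not None and (not np.isfinite(v) or v <= 0):
                    raise ValidationError(
                        f"region ({region}, {side}) mean must be finite and positive, got {v}"
                    )

    def missing(self) -> list[tuple[int, str]]:
        return [k for k, v in sorted(self.means.items(), key=str) if v is None]

    def __getitem__(self, key: tuple[int, str]) -> float | None:
        return self.means[key]

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "RegionMeans":
        """Build from a (7, 2) array ordered (region 1..7) x (L, R)."""
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (7, 2):
            raise ValidationError(f"expected a (7, 2) array, got {arr.shape}")
        return cls(
            {
                (region, side): float(arr[i, j])
                for i, region in enumerate(REGION_CODES)
                for j, side in enumerate(SIDES)
            }
        )


@dataclass
class FeatureVector:
    """Ordered 14-element relative regional flow vector plus its divisor."""

    values: np.ndarray  # (14,) dimensionless, min exactly 1
    volume_min: float  # retained for audit; raw means = values * volume_min

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (14,):
            raise ValidationError(f"feature vector must have 14 entries, got {self.values.shape}")
        if self.volume_min <= 0:
            raise ValidationError("volume_min must be positive")


def regional_mean_flow(blood: np.ndarray, masks: RegionMaskSet) -> RegionMeans:
    """Arithmetic mean of blood-flow pixels under each region code."""
    blood = np.asarray(blood, dtype=float)
    if blood.shape != masks.shape:
        raise ValidationError(
            f"blood frame shape {blood.shape} does not match masks {masks.shape}"
        )
    if blood.size and (not np.all(np.isfinite(blood)) or blood.min() <= 0):
        raise ValidationError("blood-flow values must be positive and finite")
    labels = masks.label_image.ravel()
    sums = np.bincount(labels, weights=blood.ravel(), minlength=15)
    counts = np.bincount(labels, minlength=15)
    means = {}
    n_empty = 0
    for region in REGION_CODES:
        for side in SIDES:
            code = mask_code(region, side)
            if counts[code] == 0:
                means[(region, side)] = None
                n_empty += 1
            else:
                means[(region, side)] = float(sums[code] / counts[code])
    if n_empty == 14:
        raise ValidationError("all 14 region masks are empty; segmentation failed")
    return RegionMeans(means)


def order_and_normalize(means: RegionMeans, ill_side: str) -> FeatureVector:
    """Affected-first ordering followed by minimum normalization.

    The affected half ``A_*`` is taken from ``ill_side``, the healthy half
    ``H_*`` from the contralateral side, both in region order
    B, E, N, C, MU, MC, MB; every value is divided by the minimum of the 14
    raw means (``Volume_min``), making the features scale invariant.
    """
    ill_side = str(ill_side).upper()
    if ill_side not in SIDES:
        raise ValidationError(f"ill_side must be 'L' or 'R', got {ill_side!r}")
    missing = means.missing()
    if missing:
        raise ValidationError(
            "cannot normalize with missing region means: "
            + ", ".join(f"({r}, {s})" for r, s in missing)
        )
    healthy_side = "R" if ill_side == "L" else "L"
    raw = np.array(
        [means[(region, ill_side)] for region in REGION_CODES]
        + [means[(region, healthy_side)] for region in REGION_CODES],
        dtype=float,
    )
    volume_min = float(raw.min())
    return FeatureVector(values=raw / volume_min, volume_min=volume_min)


def denormalize(features: FeatureVector) -> np.ndarray:
    """Recover the raw 14 regional means (A half then H half)."""
    return features.values * features.volume_min


def asymmetry_ratio(means: RegionMeans, region_code: int, ill_side: str) -> float:
    """Healthy-to-affected perfusion ratio ``P_r = P_h / P_a`` for a region."""
    ill_side = str(ill_side).upper()
    if ill_side not in SIDES:
        raise ValidationError(f"ill_side must be 'L' or 'R', got {ill_side!r}")
    if region_code not in REGION_CODES:
        raise ValidationError(f"unknown region code {region_code!r}")
    healthy_side = "R" if ill_side == "L" else "L"
    p_a = means[(region_code, ill_side)]
    p_h = means[(region_code, healthy_side)]
    if p_a is None or p_h is None:
        raise ValidationError(f"region {region_code} mean missing on one side")
    if p_a <= 0:
        raise ValidationError("affected-side mean must be positive")
    return float(p_h / p_a)
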