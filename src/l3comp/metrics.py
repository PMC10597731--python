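"""Per-slice body-composition measures: surface area and radiodensity.

Six measures per slice: surface area (cm^2) and mean radiodensity (HU)
for skeletal muscle (SM), visceral adipose tissue (VAT) and subcutaneous
adipose tissue (SAT).  Area is pixel count times the physical pixel
area (row spacing x column spacing, mm^2 -> cm^2); radiodensity is the
arithmetic mean HU over the tissue's pixels of the unmodified image.

An empty tissue has area 0 and an *undefined* radiodensity, represented
as NaN — never 0, since 0 HU is water and would bias any average.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dicom_io import CTSlice
from .errors import AlignmentError, MetadataError
from .segmentation import TISSUES, LabelMask

#: Column order of the tidy per-slice measures table.
MEASURE_COLUMNS = [
    "patient_id",
    "slice_index",
    "is_mid",
    "tissue",
    "area_cm2",
    "radiodensity_hu",
]


@dataclass
class CompositionMeasure:
    """Areas (cm^2) and radiodensities (HU) of one slice, keyed by tissue."""

    patient_id: str
    slice_index: int
    is_mid: bool
    area_cm2: dict[str, float] = field(default_factory=dict)
    radiodensity_hu: dict[str, float] = field(default_factory=dict)


def tissue_area(mask: np.ndarray, pixel_spacing_mm: tuple[float, float]) -> float:
    """Mask area in cm^2: ``count * row_spacing * col_spacing / 100``."""
    rs, cs = pixel_spacing_mm
    if rs <= 0 or cs <= 0:
        raise MetadataError(f"pixel spacing must be positive, got {pixel_spacing_mm}")
    return int(np.asarray(mask, dtype=bool).sum()) * rs * cs / 100.0


def tissue_radiodensity(hu_image: np.ndarray, mask: np.ndarray) -> float:
    """Mean HU over the mask; NaN (undefined) for an empty mask."""
    hu = np.asarray(hu_image)
    m = np.asarray(mask, dtype=bool)
    if hu.shape != m.shape:
        raise AlignmentError(f"image {hu.shape} vs mask {m.shape}")
    if not m.any():
        return math.nan
    return float(hu[m].mean())


def measure_slice(ct_slice: CTSlice, mask: LabelMask) -> CompositionMeasure:
    """Apply area and radiodensity to all three tissues of one slice."""
    if mask.shape != ct_slice.hu_image.shape:
        raise AlignmentError(
            f"mask {mask.shape} does not match image {ct_slice.hu_image.shape}"
        )
    out = CompositionMeasure(
        patient_id=ct_slice.patient_id,
        slice_index=ct_slice.slice_index,
        is_mid=ct_slice.is_mid,
    )
    for t in TISSUES:
        m = mask.mask(t)
        out.area_cm2[t] = tissue_area(m, ct_slice.pixel_spacing_mm)
        out.radiodensity_hu[t] = tissue_radiodensity(ct_slice.hu_image, m)
    return out


def measures_to_frame(measures: list[CompositionMeasure]) -> pd.DataFrame:
    """Tidy long-format table: one row per (slice, tissue)."""
    rows = [
        {
            "patient_id": m.patient_id,
            "slice_index": m.slice_index,
            "is_mid": m.is_mid,
            "tissue": t,
            "area_cm2": m.area_cm2[t],
            "radiodensity_hu": m.radiodensity_hu[t],
        }
        for m in measures
        for t in TISSUES
    ]
    return pd.DataFrame(rows, columns=MEASURE_COLUMNS)
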