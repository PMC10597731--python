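"""Reading axial L3 CT slices from DICOM and study-level quality control.

A *study* here is the ordered stack of axial slices spanning the third
lumbar vertebra (L3) for one patient, with exactly one slice designated
as the mid-L3 slice.  The mid-L3 designation is always an input (it is a
human judgement in the grading protocol this pipeline mirrors); nothing
in this module tries to infer it.

Raw stored pixel values are converted to Hounsfield units (HU) with the
standard CT rescale ``HU = pixel * RescaleSlope + RescaleIntercept``
using each file's own tags.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pydicom

from .errors import (
    AlignmentError,
    DesignationError,
    GeometryError,
    InsufficientDataError,
    InvalidInputError,
    MetadataError,
    OrderingError,
)

#: Expected in-plane matrix size of an axial abdominal CT slice.
IMAGE_SIZE = 512

#: Physical plausibility clamp applied after HU conversion.
HU_MIN, HU_MAX = -1100.0, 3100.0

#: Default QC thresholds; the grading protocol's exclusion criteria are
#: qualitative, so automation needs explicit numbers (tunable in RunConfig).
DEFAULT_NOISE_SD_HU = 25.0
DEFAULT_ARTEFACT_BOUND_HU = 3000.0

_REQUIRED_TAGS = (
    "RescaleSlope",
    "RescaleIntercept",
    "PixelSpacing",
    "SliceThickness",
    "ImagePositionPatient",
    "Rows",
    "Columns",
)


@dataclass
class CTSlice:
    """One axial CT slice in Hounsfield units plus its geometry metadata.

    ``pixel_spacing_mm`` follows the DICOM attribute order: (row spacing,
    column spacing).  ``slice_index`` / ``is_mid`` are assigned when the
    slice is placed into a :class:`PatientStudy`.
    """

    patient_id: str
    hu_image: np.ndarray
    pixel_spacing_mm: tuple[float, float]
    slice_thickness_mm: float
    z_position_mm: float
    slice_index: int = 0
    is_mid: bool = False
    source_path: str | None = None

    def validate(self) -> None:
        if self.hu_image.shape != (IMAGE_SIZE, IMAGE_SIZE):
            raise GeometryError(
                f"expected {IMAGE_SIZE}x{IMAGE_SIZE} image, got {self.hu_image.shape}"
            )
        if min(self.pixel_spacing_mm) <= 0:
            raise MetadataError(f"non-positive pixel spacing {self.pixel_spacing_mm}")
        if not (0 < self.slice_thickness_mm <= 20):
            raise MetadataError(
                f"slice thickness {self.slice_thickness_mm} mm outside (0, 20]"
            )
        lo, hi = float(self.hu_image.min()), float(self.hu_image.max())
        if lo < HU_MIN or hi > HU_MAX:
            raise InvalidInputError(f"HU values [{lo}, {hi}] outside [{HU_MIN}, {HU_MAX}]")


@dataclass
class PatientStudy:
    """Ordered L3 slice stack for one patient with the mid-L3 designation."""

    patient_id: str
    sex: str  # "female" | "male"
    age_years: float
    slices: list[CTSlice]
    mid_index: int

    def validate(self) -> None:
        if self.sex not in ("female", "male"):
            raise InvalidInputError(f"sex must be 'female' or 'male', got {self.sex!r}")
        if self.age_years < 0:
            raise InvalidInputError("age_years must be non-negative")
        if len(self.slices) < 2:
            raise InsufficientDataError(
                "a study needs >= 2 slices (mid plus at least one non-mid)"
            )
        z = [s.z_position_mm for s in self.slices]
        if any(b <= a for a, b in zip(z, z[1:])):
            raise OrderingError(f"z positions not strictly increasing: {z}")
        mids = [i for i, s in enumerate(self.slices) if s.is_mid]
        if mids != [self.mid_index]:
            raise DesignationError(
                f"exactly one slice must be mid (mid_index={self.mid_index}, flags at {mids})"
            )

    @property
    def mid_slice(self) -> CTSlice:
        return self.slices[self.mid_index]


@dataclass
class QCReport:
    """Automated quality-control outcome for one study.

    ``flags`` mirror the exclusion criteria of the source protocol:
    subcutaneous fat or muscle cut off by the field of view, excessive
    image noise, or a major artefact.  An empty flag set means the study
    passes inclusion.
    """

    patient_id: str
    flags: set[str] = field(default_factory=set)
    per_slice: dict[int, set[str]] = field(default_factory=dict)

    @property
    def passed(self) -> bool:
        return not self.flags


def to_hounsfield(
    raw_pixels: np.ndarray, slope: float, intercept: float
) -> np.ndarray:
    """Convert stored pixel values to Hounsfield units: ``raw * slope + intercept``."""
    raw = np.asarray(raw_pixels)
    if raw.ndim != 2 or raw.size == 0:
        raise InvalidInputError(f"raw pixel grid must be non-empty 2-D, got shape {raw.shape}")
    if slope == 0:
        raise MetadataError("RescaleSlope must be non-zero")
    return raw.astype(np.float64) * float(slope) + float(intercept)


def read_slice(path: str | Path) -> CTSlice:
    """Read one DICOM file into a :class:`CTSlice` (already in HU).

    The file must carry RescaleSlope, RescaleIntercept, PixelSpacing,
    SliceThickness and ImagePositionPatient, and be a 512 x 512 single
    frame; anything else raises :class:`MetadataError` /
    :class:`GeometryError` naming the offending tag.
    """
    path = Path(path)
    ds = pydicom.dcmread(path)
    for tag in _REQUIRED_TAGS:
        if getattr(ds, tag, None) is None:
            raise MetadataError(f"{path.name}: missing required DICOM tag {tag}")
    if int(ds.Rows) != IMAGE_SIZE or int(ds.Columns) != IMAGE_SIZE:
        raise GeometryError(
            f"{path.name}: expected Rows=Columns={IMAGE_SIZE}, got {ds.Rows}x{ds.Columns}"
        )
    hu = to_hounsfield(ds.pixel_array, float(ds.RescaleSlope), float(ds.RescaleIntercept))
    np.clip(hu, HU_MIN, HU_MAX, out=hu)
    spacing = (float(ds.PixelSpacing[0]), float(ds.PixelSpacing[1]))
    sl = CTSlice(
        patient_id=str(getattr(ds, "PatientID", "") or "unknown"),
        hu_image=hu,
        pixel_spacing_mm=spacing,
        slice_thickness_mm=float(ds.SliceThickness),
        z_position_mm=float(ds.ImagePositionPatient[2]),
        source_path=str(path),
    )
    sl.validate()
    return sl


def load_study(
    paths: Sequence[str | Path],
    mid_designation: str | Path,
    sex: str,
    age_years: float,
    patient_id: str | None = None,
) -> PatientStudy:
    """Assemble a :class:`PatientStudy` from per-slice DICOM files.

    ``mid_designation`` identifies the human-designated mid-L3 slice by
    file path (full path or basename).  Slices are sorted by ascending z
    (ImagePositionPatient[2]); duplicate z positions are an error because
    the stack order would be ambiguous.
    """
    if len(paths) < 2:
        raise InsufficientDataError(f"need >= 2 slices, got {len(paths)}")
    slices = [read_slice(p) for p in paths]
    z = [s.z_position_mm for s in slices]
    if len(set(z)) != len(z):
        raise OrderingError("duplicate z positions in study")
    slices.sort(key=lambda s: s.z_position_mm)

    mid_name = Path(mid_designation).name
    matches = [
        i
        for i, s in enumerate(slices)
        if s.source_path is not None
        and (s.source_path == str(mid_designation) or Path(s.source_path).name == mid_name)
    ]
    if len(matches) != 1:
        raise DesignationError(
            f"mid designation {mid_designation!r} matched {len(matches)} slices"
        )
    mid_index = matches[0]
    pid = patient_id or slices[0].patient_id
    out = []
    for i, s in enumerate(slices):
        out.append(
            dataclasses.replace(s, patient_id=pid, slice_index=i, is_mid=(i == mid_index))
        )
    study = PatientStudy(
        patient_id=pid, sex=sex, age_years=age_years, slices=out, mid_index=mid_index
    )
    study.validate()
    return study


def estimate_noise_sd(hu_image: np.ndarray, interior: np.ndarray) -> float:
    """Robust HU noise estimate inside the body.

    Uses horizontally adjacent pixel differences restricted to the eroded
    body interior; for white noise ``median(|d|) = sqrt(2) * sigma *
    Phi^-1(3/4)``, so the estimator is insensitive to anatomy except at
    tissue boundaries, which are a small minority of pairs.
    """
    pair = interior[:, 1:] & interior[:, :-1]
    if not pair.any():
        return 0.0
    d = hu_image[:, 1:][pair] - hu_image[:, :-1][pair]
    return float(np.median(np.abs(d)) / (np.sqrt(2.0) * 0.6744897501960817))


def qc_study(
    study: PatientStudy,
    masks: Sequence["np.ndarray | object"],
    noise_sd_hu: float = DEFAULT_NOISE_SD_HU,
    artefact_bound_hu: float = DEFAULT_ARTEFACT_BOUND_HU,
) -> QCReport:
    """Run the automated exclusion checks on a segmented study.

    ``masks`` are the per-slice label masks (aligned with ``study.slices``).
    Flags:

    * ``sat_cutoff`` — subcutaneous fat touches the image border
      (fat extends outside the field of view);
    * ``muscle_cutoff`` — muscle touches the image border;
    * ``low_quality`` — robust HU noise estimate above ``noise_sd_hu``;
    * ``major_artefact`` — any ``|HU| > artefact_bound_hu`` inside the body.
    """
    from .segmentation import LabelMask, body_mask

    if len(masks) != len(study.slices):
        raise AlignmentError(
            f"{len(masks)} masks for {len(study.slices)} slices"
        )
    report = QCReport(patient_id=study.patient_id)
    for sl, m in zip(study.slices, masks):
        labels = m.labels if isinstance(m, LabelMask) else np.asarray(m)
        if labels.shape != sl.hu_image.shape:
            raise AlignmentError(
                f"slice {sl.slice_index}: mask shape {labels.shape} != image {sl.hu_image.shape}"
            )
        flags: set[str] = set()
        border = np.zeros_like(labels, dtype=bool)
        border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
        if (labels[border] == LabelMask.SAT).any():
            flags.add("sat_cutoff")
        if (labels[border] == LabelMask.SM).any():
            flags.add("muscle_cutoff")
        body = body_mask(sl.hu_image)
        from scipy import ndimage

        interior = ndimage.binary_erosion(body, iterations=3)
        if estimate_noise_sd(sl.hu_image, interior) > noise_sd_hu:
            flags.add("low_quality")
        if (np.abs(sl.hu_image[body]) > artefact_bound_hu).any():
            flags.add("major_artefact")
        report.per_slice[sl.slice_index] = flags
        report.flags |= flags
    return report
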