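"""Parametric axial abdominal CT phantoms with analytic ground truth.

The phantom is a stack of nested elliptical compartments mimicking an
axial abdominal cross-section at L3: an outer subcutaneous-fat ring, an
abdominal muscle wall, and a visceral cavity containing a central
visceral-fat region plus gas-containing bowel.  The geometry is
deliberately simple rather than anatomical: every tissue area has a
closed form (pi * (a_outer*b_outer - a_inner*b_inner) * pixel area), so
the full pipeline can be validated against exact oracles.

Slice-to-slice variation emulates how composition changes across the L3
span: each geometric component follows a mild monotone ramp along z
(zero at the designated mid slice) plus per-slice random jitter, and
each tissue's mean HU receives a small per-slice offset.  Sex effects
are multiplicative on ring thicknesses, visceral fat fraction and the
modulation amplitudes, reproducing the qualitative cohort structure
(females: larger subcutaneous fat, smaller muscle and visceral fat).

Everything is a pure function of the parameters including the seed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian

from .dicom_io import CTSlice, PatientStudy, IMAGE_SIZE
from .errors import ParameterError
from .metrics import MEASURE_COLUMNS
from .segmentation import TISSUES, LabelMask

_CT_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.2"
_UID_ROOT = "1.2.826.0.1.3680043.8.498."

#: Stored-value clamp of the 12-bit CT dialect used for written files.
STORED_HU_MIN, STORED_HU_MAX = -1024, 3071


@dataclass(frozen=True)
class ModulationProfile:
    """Per-component slice-to-slice geometry modulation.

    ``*_ramp`` is the total fractional change per unit of normalised
    slice offset (slice i sits at ``u = (i - mid) / (n - 1)``), i.e. a
    monotone drift along z that is zero at the mid slice; ``*_jitter_sd``
    is the SD of an additional independent fractional perturbation per
    slice.  Defaults are tuned so the resulting average percent
    differences are of the same order as published multi-slice L3
    variability (muscle ~3.5%, subcutaneous fat ~5.5%, visceral fat
    ~6.5% for areas; ~1-3% for radiodensities).
    """

    body_ramp: float = 0.04
    body_jitter_sd: float = 0.006
    sat_ramp: float = 0.16
    sat_jitter_sd: float = 0.025
    muscle_ramp: float = 0.10
    muscle_jitter_sd: float = 0.018
    vat_ramp: float = 0.20
    vat_jitter_sd: float = 0.03


@dataclass(frozen=True)
class SexEffects:
    """Multiplicative sex effects on geometry and modulation amplitude."""

    body: float = 1.0
    sat_thickness: float = 1.0
    muscle_thickness: float = 1.0
    vat_fraction: float = 1.0
    sat_modulation: float = 1.0
    muscle_modulation: float = 1.0
    vat_modulation: float = 1.0

    def validate(self) -> None:
        for name in (
            "body",
            "sat_thickness",
            "muscle_thickness",
            "vat_fraction",
            "sat_modulation",
            "muscle_modulation",
            "vat_modulation",
        ):
            if getattr(self, name) <= 0:
                raise ParameterError(f"sex effect {name} must be positive")


#: Defaults reproduce the qualitative cohort orderings: females carry
#: more subcutaneous fat, less muscle and visceral fat, and show larger
#: visceral-fat slice-to-slice variation, males larger subcutaneous.
DEFAULT_SEX_EFFECTS: dict[str, SexEffects] = {
    "female": SexEffects(
        body=0.95,
        sat_thickness=1.35,
        muscle_thickness=0.85,
        vat_fraction=0.75,
        vat_modulation=1.3,
    ),
    "male": SexEffects(sat_modulation=1.5),
}


@dataclass
class PhantomParams:
    """Generative description of one synthetic L3 study.

    HU means sit strictly inside the tissue threshold ranges (muscle
    40, visceral fat -90, subcutaneous fat -105).  The non-fat cavity
    content is modelled as gas-containing bowel (-300 HU), which lies
    outside every tissue range; see the methods note for why organ-like
    soft tissue (~20-60 HU) cannot be used as a default in a
    threshold-segmented phantom.
    """

    patient_id: str = "PHANTOM"
    sex: str = "female"
    age_years: float = 61.0
    seed: int = 0
    n_slices: int = 10
    body_a_px: float = 170.0
    body_b_px: float = 125.0
    sat_thickness_px: float = 16.0
    muscle_thickness_px: float = 13.0
    vat_fraction: float = 0.35
    hu_mean: dict[str, float] = field(
        default_factory=lambda: {"sm": 40.0, "vat": -90.0, "sat": -105.0, "cavity": -300.0, "air": -1000.0}
    )
    hu_sd: dict[str, float] = field(
        default_factory=lambda: {"sm": 10.0, "vat": 15.0, "sat": 15.0, "cavity": 15.0, "air": 5.0}
    )
    radiodensity_jitter_hu: dict[str, float] = field(
        default_factory=lambda: {"sm": 1.4, "vat": 1.45, "sat": 1.1}
    )
    modulation: ModulationProfile = field(default_factory=ModulationProfile)
    pixel_spacing_mm: tuple[float, float] = (0.8, 0.8)
    slice_thickness_mm: float = 5.0
    z0_mm: float = 0.0
    center_rc: tuple[float, float] = (255.5, 255.5)
    margin_px: float = 16.0
    allow_border_contact: bool = False

    def with_noise(self, sd: float) -> "PhantomParams":
        """Copy with every tissue's pixel-noise SD set to ``sd``."""
        return replace(self, hu_sd={k: float(sd) for k in self.hu_sd})

    def noiseless(self) -> "PhantomParams":
        """Copy with zero pixel noise and zero per-slice HU jitter."""
        return replace(
            self,
            hu_sd={k: 0.0 for k in self.hu_sd},
            radiodensity_jitter_hu={k: 0.0 for k in self.radiodensity_jitter_hu},
        )

    def validate(self) -> None:
        if self.n_slices < 2:
            raise ParameterError("n_slices must be >= 2")
        if self.sex not in ("female", "male"):
            raise ParameterError(f"sex must be 'female' or 'male', got {self.sex!r}")
        for name in ("body_a_px", "body_b_px", "sat_thickness_px", "muscle_thickness_px"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if not 0.0 <= self.vat_fraction <= 1.0:
            raise ParameterError("vat_fraction must lie in [0, 1]")
        inner = min(
            self.body_a_px - self.sat_thickness_px - self.muscle_thickness_px,
            self.body_b_px - self.sat_thickness_px - self.muscle_thickness_px,
        )
        if inner <= 2:
            raise ParameterError("rings not nested: cavity would be degenerate")
        from .segmentation import ALBERTA

        for t in TISSUES:
            lo, hi = ALBERTA.bounds(t)
            if not lo < self.hu_mean[t] < hi:
                raise ParameterError(
                    f"{t} HU mean {self.hu_mean[t]} outside its threshold range ({lo}, {hi})"
                )
        if not self.allow_border_contact:
            r0, c0 = self.center_rc
            # 10% headroom over the base radii covers ramp + jitter excursions
            if (
                c0 - 1.1 * self.body_a_px < self.margin_px
                or c0 + 1.1 * self.body_a_px > IMAGE_SIZE - 1 - self.margin_px
                or r0 - 1.1 * self.body_b_px < self.margin_px
                or r0 + 1.1 * self.body_b_px > IMAGE_SIZE - 1 - self.margin_px
            ):
                raise ParameterError("body does not fit inside the frame with the margin")


@dataclass
class SliceGeometry:
    """Resolved geometry and generating HU means of one phantom slice."""

    body_ab: tuple[float, float]
    sat_inner_ab: tuple[float, float]  # outer muscle boundary
    muscle_inner_ab: tuple[float, float]  # cavity boundary
    vat_ab: tuple[float, float]
    vat_fraction: float
    hu_means: dict[str, float]  # per-tissue generating mean incl. slice offset


@dataclass
class GroundTruth:
    """Analytic truth for one phantom study."""

    label_masks: list[LabelMask]
    areas_cm2: list[dict[str, float]]  # analytic ellipse-ring areas
    hu_means: list[dict[str, float]]  # generating per-slice tissue means
    geometry: list[SliceGeometry]

    def measures_frame(self, params: PhantomParams) -> pd.DataFrame:
        """Truth measures in the tidy per-slice format of the metrics module."""
        mid = params.n_slices // 2
        rows = [
            {
                "patient_id": params.patient_id,
                "slice_index": i,
                "is_mid": i == mid,
                "tissue": t,
                "area_cm2": self.areas_cm2[i][t],
                "radiodensity_hu": self.hu_means[i][t],
            }
            for i in range(params.n_slices)
            for t in TISSUES
        ]
        df = pd.DataFrame(rows, columns=MEASURE_COLUMNS)
        df["sex"] = params.sex
        return df


def _plan_slices(params: PhantomParams, rng: np.random.Generator) -> list[SliceGeometry]:
    """Resolve per-slice geometry; consumes a fixed number of rng draws
    so the truth-only and fully rendered paths stay in lockstep."""
    n = params.n_slices
    mid = n // 2
    mod = params.modulation
    geo_jit = rng.standard_normal((n, 4))
    hu_jit = rng.standard_normal((n, 3))
    plan = []
    for i in range(n):
        u = (i - mid) / max(n - 1, 1)
        fb = 1.0 + mod.body_ramp * u + mod.body_jitter_sd * geo_jit[i, 0]
        fs = 1.0 + mod.sat_ramp * u + mod.sat_jitter_sd * geo_jit[i, 1]
        fm = 1.0 + mod.muscle_ramp * u + mod.muscle_jitter_sd * geo_jit[i, 2]
        fv = 1.0 + mod.vat_ramp * u + mod.vat_jitter_sd * geo_jit[i, 3]
        a, b = params.body_a_px * fb, params.body_b_px * fb
        t_s = max(params.sat_thickness_px * fs, 1.0)
        t_m = max(params.muscle_thickness_px * fm, 1.0)
        frac = float(np.clip(params.vat_fraction * fv, 0.0, 0.95))
        si = (a - t_s, b - t_s)
        mi = (a - t_s - t_m, b - t_s - t_m)
        if mi[0] <= 2 or mi[1] <= 2:
            raise ParameterError(f"slice {i}: rings not nested after modulation")
        s = float(np.sqrt(frac))
        means = {
            t: params.hu_mean[t] + params.radiodensity_jitter_hu[t] * hu_jit[i, k]
            for k, t in enumerate(TISSUES)
        }
        plan.append(
            SliceGeometry(
                body_ab=(a, b),
                sat_inner_ab=si,
                muscle_inner_ab=mi,
                vat_ab=(mi[0] * s, mi[1] * s),
                vat_fraction=frac,
                hu_means=means,
            )
        )
    return plan


def _analytic_areas(geo: SliceGeometry, pixel_spacing_mm: tuple[float, float]) -> dict[str, float]:
    pxa = pixel_spacing_mm[0] * pixel_spacing_mm[1] / 100.0
    (a, b), (sa, sb), (ma, mb) = geo.body_ab, geo.sat_inner_ab, geo.muscle_inner_ab
    return {
        "sm": float(np.pi * (sa * sb - ma * mb) * pxa),
        "vat": float(np.pi * ma * mb * geo.vat_fraction * pxa),
        "sat": float(np.pi * (a * b - sa * sb) * pxa),
    }


def _ellipse_mask(
    shape: tuple[int, int], center_rc: tuple[float, float], ab: tuple[float, float]
) -> np.ndarray:
    """Pixel-centre rasterisation of ((x/a)^2 + (y/b)^2) <= 1; the a
    semi-axis runs along columns, b along rows."""
    r0, c0 = center_rc
    rr = (np.arange(shape[0]) - r0)[:, None]
    cc = (np.arange(shape[1]) - c0)[None, :]
    a, b = ab
    return (cc / a) ** 2 + (rr / b) ** 2 <= 1.0


def _render_slice(
    params: PhantomParams, geo: SliceGeometry, rng: np.random.Generator
) -> tuple[np.ndarray, LabelMask]:
    shape = (IMAGE_SIZE, IMAGE_SIZE)
    body = _ellipse_mask(shape, params.center_rc, geo.body_ab)
    sat_in = _ellipse_mask(shape, params.center_rc, geo.sat_inner_ab)
    musc_in = _ellipse_mask(shape, params.center_rc, geo.muscle_inner_ab)
    vat = (
        _ellipse_mask(shape, params.center_rc, geo.vat_ab)
        if geo.vat_ab[0] > 0 and geo.vat_ab[1] > 0
        else np.zeros(shape, dtype=bool)
    )
    sat = body & ~sat_in
    sm = sat_in & ~musc_in
    cavity_bg = musc_in & ~vat

    mean = np.full(shape, params.hu_mean["air"])
    sd = np.full(shape, params.hu_sd["air"])
    for region, tissue in ((sat, "sat"), (sm, "sm"), (vat, "vat")):
        mean[region] = geo.hu_means[tissue]
        sd[region] = params.hu_sd[tissue]
    mean[cavity_bg] = params.hu_mean["cavity"]
    sd[cavity_bg] = params.hu_sd["cavity"]

    hu = mean + sd * rng.standard_normal(shape)
    hu = np.clip(np.rint(hu), STORED_HU_MIN, STORED_HU_MAX)
    return hu.astype(np.float64), LabelMask.from_masks(sm, vat, sat)


def generate_phantom_study(params: PhantomParams) -> tuple[PatientStudy, GroundTruth]:
    """Render one phantom study: DICOM-ready slices plus analytic truth.

    Deterministic in ``params.seed``; the mid slice is the central index
    (``n_slices // 2``) where the modulation ramp is zero.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    plan = _plan_slices(params, rng)
    mid = params.n_slices // 2
    slices, masks, areas, means = [], [], [], []
    for i, geo in enumerate(plan):
        hu, mask = _render_slice(params, geo, rng)
        slices.append(
            CTSlice(
                patient_id=params.patient_id,
                hu_image=hu,
                pixel_spacing_mm=params.pixel_spacing_mm,
                slice_thickness_mm=params.slice_thickness_mm,
                z_position_mm=params.z0_mm + i * params.slice_thickness_mm,
                slice_index=i,
                is_mid=(i == mid),
            )
        )
        masks.append(mask)
        areas.append(_analytic_areas(geo, params.pixel_spacing_mm))
        means.append(dict(geo.hu_means))
    study = PatientStudy(
        patient_id=params.patient_id,
        sex=params.sex,
        age_years=params.age_years,
        slices=slices,
        mid_index=mid,
    )
    study.validate()
    return study, GroundTruth(label_masks=masks, areas_cm2=areas, hu_means=means, geometry=plan)


def truth_measures(params: PhantomParams) -> pd.DataFrame:
    """Analytic truth measures without rasterising any pixels.

    Identical geometry draws to :func:`generate_phantom_study` with the
    same seed; used for fast statistical simulation on the truth.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    plan = _plan_slices(params, rng)
    gt = GroundTruth(
        label_masks=[],
        areas_cm2=[_analytic_areas(g, params.pixel_spacing_mm) for g in plan],
        hu_means=[dict(g.hu_means) for g in plan],
        geometry=plan,
    )
    return gt.measures_frame(params)


# --- cohort generation -------------------------------------------------

_SLICE_COUNTS = np.array([8, 9, 10, 11, 12])
_SLICE_PROBS = np.array([1, 2, 3, 2, 1]) / 9.0  # discrete triangular, median 10, IQR 9-11


def sample_cohort_params(
    n_female: int,
    n_male: int,
    seed: int,
    sex_effects: dict[str, SexEffects] | None = None,
    base: PhantomParams | None = None,
) -> list[PhantomParams]:
    """Draw per-patient phantom parameters for a two-sex cohort.

    Patient-level anatomy (body radii, ring thicknesses, visceral fat
    fraction, age, slice count) is sampled around the ``base`` values,
    then scaled by the sex-effect multipliers; per-patient seeds derive
    reproducibly from the master seed.
    """
    if n_female < 1 or n_male < 1:
        raise ParameterError("need at least one patient per sex")
    effects = sex_effects if sex_effects is not None else DEFAULT_SEX_EFFECTS
    for e in effects.values():
        e.validate()
    base = base if base is not None else PhantomParams()
    rng = np.random.default_rng(seed)
    out = []
    for sex, count, prefix in (("female", n_female, "F"), ("male", n_male, "M")):
        eff = effects[sex]
        for i in range(count):
            pseed = int(rng.integers(2**31))
            n_slices = int(rng.choice(_SLICE_COUNTS, p=_SLICE_PROBS))
            body_scale = eff.body * float(np.clip(rng.normal(1.0, 0.05), 0.85, 1.15))
            mod = base.modulation
            out.append(
                replace(
                    base,
                    patient_id=f"{prefix}{i:03d}",
                    sex=sex,
                    age_years=float(np.clip(rng.normal(61.0, 12.0), 18.0, 95.0)),
                    seed=pseed,
                    n_slices=n_slices,
                    body_a_px=base.body_a_px * body_scale,
                    body_b_px=base.body_b_px * body_scale,
                    sat_thickness_px=float(
                        np.clip(rng.normal(base.sat_thickness_px, 2.5), 6.0, 40.0)
                    )
                    * eff.sat_thickness,
                    muscle_thickness_px=float(
                        np.clip(rng.normal(base.muscle_thickness_px, 1.5), 6.0, 25.0)
                    )
                    * eff.muscle_thickness,
                    vat_fraction=float(
                        np.clip(rng.normal(base.vat_fraction, 0.06) * eff.vat_fraction, 0.05, 0.8)
                    ),
                    modulation=replace(
                        mod,
                        sat_ramp=mod.sat_ramp * eff.sat_modulation,
                        sat_jitter_sd=mod.sat_jitter_sd * eff.sat_modulation,
                        muscle_ramp=mod.muscle_ramp * eff.muscle_modulation,
                        muscle_jitter_sd=mod.muscle_jitter_sd * eff.muscle_modulation,
                        vat_ramp=mod.vat_ramp * eff.vat_modulation,
                        vat_jitter_sd=mod.vat_jitter_sd * eff.vat_modulation,
                    ),
                )
            )
    return out


def generate_cohort(
    n_female: int,
    n_male: int,
    sex_effects: dict[str, SexEffects] | None = None,
    seed: int = 0,
    base: PhantomParams | None = None,
) -> list[tuple[PatientStudy, GroundTruth]]:
    """Render a full two-sex cohort of phantom studies (deterministic in seed)."""
    params = sample_cohort_params(n_female, n_male, seed, sex_effects, base)
    return [generate_phantom_study(p) for p in params]


def cohort_truth_measures(
    n_female: int,
    n_male: int,
    sex_effects: dict[str, SexEffects] | None = None,
    seed: int = 0,
    base: PhantomParams | None = None,
) -> pd.DataFrame:
    """Analytic truth measures for a whole cohort (no pixel rendering)."""
    params = sample_cohort_params(n_female, n_male, seed, sex_effects, base)
    return pd.concat([truth_measures(p) for p in params], ignore_index=True)


# --- DICOM writing -----------------------------------------------------


def _derived_uid(*parts: object) -> str:
    digest = hashlib.sha1("/".join(str(p) for p in parts).encode()).hexdigest()
    return _UID_ROOT + str(int(digest[:28], 16))[:30]


def write_dicom_series(study: PatientStudy, directory: str | Path) -> list[Path]:
    """Write one DICOM file per slice (int16 storage, slope 1, intercept
    -1024, explicit-VR little endian) and return the paths in z order.

    Output is byte-reproducible: UIDs derive from the patient id and
    slice index, and no date/time tags are written.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    study_uid = _derived_uid(study.patient_id, "study")
    series_uid = _derived_uid(study.patient_id, "series")
    for sl in study.slices:
        ds = Dataset()
        ds.SOPClassUID = _CT_SOP_CLASS
        ds.SOPInstanceUID = _derived_uid(study.patient_id, "sop", sl.slice_index)
        ds.StudyInstanceUID = study_uid
        ds.SeriesInstanceUID = series_uid
        ds.Modality = "CT"
        ds.PatientID = study.patient_id
        ds.PatientSex = "F" if study.sex == "female" else "M"
        ds.Rows = ds.Columns = IMAGE_SIZE
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1
        ds.RescaleSlope = 1
        ds.RescaleIntercept = -1024
        ds.PixelSpacing = [f"{sl.pixel_spacing_mm[0]:g}", f"{sl.pixel_spacing_mm[1]:g}"]
        ds.SliceThickness = f"{sl.slice_thickness_mm:g}"
        ds.ImagePositionPatient = ["0", "0", f"{sl.z_position_mm:g}"]
        ds.ImageOrientationPatient = ["1", "0", "0", "0", "1", "0"]
        ds.InstanceNumber = sl.slice_index + 1
        stored = np.clip(np.rint(sl.hu_image), STORED_HU_MIN, STORED_HU_MAX) + 1024
        ds.PixelData = stored.astype("<i2").tobytes()

        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = _CT_SOP_CLASS
        meta.MediaStorageSOPInstanceUID = ds.SOPInstanceUID
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        meta.ImplementationClassUID = _UID_ROOT + "1"
        ds.file_meta = meta

        path = directory / f"{study.patient_id}_{sl.slice_index:03d}.dcm"
        ds.save_as(path, enforce_file_format=True)
        paths.append(path)
    return paths


def manifest_rows(study: PatientStudy, paths: Sequence[Path]) -> pd.DataFrame:
    """Manifest rows (one per slice) for :func:`l3comp.pipeline.run_pipeline`."""
    return pd.DataFrame(
        [
            {
                "patient_id": study.patient_id,
                "sex": study.sex,
                "age_years": study.age_years,
                "path": str(p),
                "z_position_mm": sl.z_position_mm,
                "is_mid": sl.is_mid,
            }
            for sl, p in zip(study.slices, paths)
        ]
    )


def write_cohort(
    cohort: Sequence[tuple[PatientStudy, GroundTruth]],
    directory: str | Path,
    write_truth: bool = True,
) -> Path:
    """Write a cohort as DICOM series + ``manifest.csv`` (+ truth CSV).

    Returns the manifest path.  Truth masks are not persisted here (they
    can be regenerated exactly from the parameters); the analytic truth
    measures go to ``truth_measures.csv``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifests, truth_frames = [], []
    for study, gt in cohort:
        paths = write_dicom_series(study, directory / study.patient_id)
        manifests.append(manifest_rows(study, paths))
        if write_truth and gt.areas_cm2:
            rows = [
                {
                    "patient_id": study.patient_id,
                    "slice_index": i,
                    "tissue": t,
                    "area_cm2": gt.areas_cm2[i][t],
                    "radiodensity_hu": gt.hu_means[i][t],
                }
                for i in range(len(gt.areas_cm2))
                for t in TISSUES
            ]
            truth_frames.append(pd.DataFrame(rows))
    manifest_path = directory / "manifest.csv"
    pd.concat(manifests, ignore_index=True).to_csv(manifest_path, index=False)
    if truth_frames:
        pd.concat(truth_frames, ignore_index=True).to_csv(
            directory / "truth_measures.csv", index=False
        )
    return manifest_path
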