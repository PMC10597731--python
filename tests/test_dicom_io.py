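"""DICOM reading, HU conversion, study assembly and QC flagging."""

import numpy as np
import pydicom
import pytest

from l3comp.dicom_io import estimate_noise_sd, load_study, qc_study, read_slice, to_hounsfield
from l3comp.errors import (
    DesignationError,
    GeometryError,
    InsufficientDataError,
    InvalidInputError,
    MetadataError,
    OrderingError,
)
from l3comp.phantom import PhantomParams, generate_phantom_study, write_dicom_series


@pytest.mark.parametrize(
    "raw,slope,intercept,expected",
    [(0, 1, -1024, -1024.0), (1024, 1, -1024, 0.0), (500, 2, -1000, 0.0)],
)
def test_hu_conversion_formula(raw, slope, intercept, expected):
    out = to_hounsfield(np.full((2, 2), raw), slope, intercept)
    assert out.shape == (2, 2)
    assert np.all(out == expected)


def test_hu_conversion_is_affine_and_invertible():
    rng = np.random.default_rng(3)
    raw = rng.integers(0, 4096, size=(64, 64))
    slope, intercept = 2.0, -1000.0
    hu = to_hounsfield(raw, slope, intercept)
    np.testing.assert_allclose(hu, raw * slope + intercept)
    recovered = (hu - intercept) / slope
    assert np.array_equal(np.rint(recovered).astype(raw.dtype), raw)


def test_hu_conversion_error_paths():
    with pytest.raises(MetadataError):
        to_hounsfield(np.zeros((4, 4)), slope=0, intercept=0)
    with pytest.raises(InvalidInputError):
        to_hounsfield(np.zeros((0, 4)), slope=1, intercept=0)


@pytest.fixture(scope="module")
def written_study(tmp_path_factory):
    params = PhantomParams(patient_id="RT01", seed=21, pixel_spacing_mm=(0.7, 0.7)).noiseless()
    study, gt = generate_phantom_study(params)
    paths = write_dicom_series(study, tmp_path_factory.mktemp("dcm"))
    return study, gt, paths


def test_read_slice_roundtrip_is_exact(written_study):
    study, _, paths = written_study
    for sl, path in zip(study.slices, paths):
        back = read_slice(path)
        assert np.array_equal(back.hu_image, sl.hu_image)
        assert back.pixel_spacing_mm == (0.7, 0.7)
        assert back.slice_thickness_mm == sl.slice_thickness_mm
        assert back.z_position_mm == sl.z_position_mm


def test_read_slice_missing_tag_and_bad_geometry(written_study, tmp_path):
    _, _, paths = written_study
    ds = pydicom.dcmread(paths[0])
    del ds.PixelSpacing
    bad = tmp_path / "missing_spacing.dcm"
    ds.save_as(bad, enforce_file_format=True)
    with pytest.raises(MetadataError, match="PixelSpacing"):
        read_slice(bad)

    ds = pydicom.dcmread(paths[0])
    ds.Rows = 256
    ds.PixelData = ds.pixel_array[:256].tobytes()
    bad = tmp_path / "rows256.dcm"
    ds.save_as(bad, enforce_file_format=True)
    with pytest.raises(GeometryError):
        read_slice(bad)


def test_load_study_orders_by_z_and_sets_mid(written_study):
    study, _, paths = written_study
    mid_path = paths[study.mid_index]
    # shuffle input order: ordering must come from z, not the argument list
    shuffled = [paths[i] for i in (3, 0, 7, 1, 9, 5, 2, 8, 4, 6)]
    loaded = load_study(shuffled, mid_designation=mid_path, sex="female", age_years=60)
    assert [s.z_position_mm for s in loaded.slices] == [s.z_position_mm for s in study.slices]
    assert loaded.mid_index == study.mid_index
    assert loaded.slices[loaded.mid_index].is_mid


def test_load_study_error_paths(written_study, tmp_path):
    _, _, paths = written_study
    with pytest.raises(InsufficientDataError):
        load_study(paths[:1], mid_designation=paths[0], sex="female", age_years=60)
    with pytest.raises(OrderingError):
        load_study([paths[0], paths[0]], mid_designation=paths[0], sex="female", age_years=60)
    with pytest.raises(DesignationError):
        load_study(paths, mid_designation="no_such_file.dcm", sex="female", age_years=60)


def test_qc_centred_phantom_is_clean(noiseless):
    _, study, gt = noiseless
    report = qc_study(study, gt.label_masks)
    assert report.flags == set()
    assert report.passed


def test_qc_flags_sat_cutoff_when_body_crosses_border():
    params = PhantomParams(
        patient_id="EDGE", seed=5, center_rc=(255.5, 420.0), allow_border_contact=True
    ).noiseless()
    study, gt = generate_phantom_study(params)
    report = qc_study(study, gt.label_masks)
    assert "sat_cutoff" in report.flags


def test_qc_flags_muscle_cutoff_from_mask(noiseless):
    _, study, gt = noiseless
    labels = gt.label_masks[0].labels.copy()
    labels[0, 200:220] = 1  # muscle touching the top border
    masks = list(gt.label_masks)
    from l3comp.segmentation import LabelMask

    masks[0] = LabelMask(labels)
    report = qc_study(study, masks)
    assert "muscle_cutoff" in report.flags
    assert report.per_slice[0] == {"muscle_cutoff"}


def test_qc_flags_major_artefact(noiseless):
    import dataclasses

    _, study, gt = noiseless
    hu = study.slices[0].hu_image.copy()
    hu[250:256, 250:256] = 3071.0  # metal-like insert, clipped to the stored maximum
    slices = list(study.slices)
    slices[0] = dataclasses.replace(slices[0], hu_image=hu)
    tampered = dataclasses.replace(study, slices=slices)
    report = qc_study(tampered, gt.label_masks, artefact_bound_hu=3000.0)
    assert "major_artefact" in report.flags


def test_qc_flags_low_quality_on_heavy_noise():
    params = PhantomParams(patient_id="NOISY", seed=6).with_noise(40.0)
    study, gt = generate_phantom_study(params)
    report = qc_study(study, gt.label_masks, noise_sd_hu=25.0)
    assert "low_quality" in report.flags


def test_noise_estimator_tracks_true_sd():
    rng = np.random.default_rng(7)
    img = 40.0 + 10.0 * rng.standard_normal((512, 512))
    interior = np.zeros((512, 512), dtype=bool)
    interior[100:400, 100:400] = True
    est = estimate_noise_sd(img, interior)
    assert abs(est - 10.0) < 0.5


def test_qc_mask_alignment_error(noiseless):
    from l3comp.errors import AlignmentError

    _, study, gt = noiseless
    with pytest.raises(AlignmentError):
        qc_study(study, gt.label_masks[:-1])
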