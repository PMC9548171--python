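from __future__ import annotations

import numpy as np
import pytest

from adipovol import PipelineConfig, generate_phantom, mouse_spec


def make_tiny_mouse_spec(seed: int = 0, **overrides):
    """A small, fast mouse-regime phantom for unit tests."""
    defaults = dict(
        width=96,
        height=96,
        n_slices=2,
        body_a=36.0,
        body_b=30.0,
        sat_thickness=6.0,
        n_vat_blobs=2,
        blob_radius_range=(3.0, 4.0),
        kidneys=((-10.0, 0.0, 5.0, 8.0), (10.0, 0.0, 5.0, 8.0)),
        background_noise_sd=0.0,
    )
    defaults.update(overrides)
    return mouse_spec(seed=seed, **defaults)


@pytest.fixture
def tiny_phantom():
    scan, truth = generate_phantom(make_tiny_mouse_spec(seed=5))
    return scan, truth


@pytest.fixture
def tiny_config():
    return PipelineConfig.for_species("mouse", seed=5)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def write_dicom_series(directory, stack_data, geometry, *, reverse_order=False):
    """Write a minimal single-frame DICOM series for round-trip tests."""
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    series_uid = generate_uid()
    n = stack_data.shape[0]
    order = range(n - 1, -1, -1) if reverse_order else range(n)
    for file_idx, s in enumerate(order):
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = pydicom.uid.MRImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
        ds.SOPClassUID = meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.SeriesInstanceUID = series_uid
        ds.Modality = "MR"
        ds.InstanceNumber = s + 1
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.ImagePositionPatient = [0.0, 0.0, float(s) * geometry.dz_mm]
        ds.PixelSpacing = [geometry.dy_mm, geometry.dx_mm]
        ds.SliceThickness = geometry.dz_mm
        ds.Rows, ds.Columns = stack_data.shape[1:]
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.PixelData = stack_data[s].astype(np.uint16).tobytes()
        ds.save_as(directory / f"img_{file_idx:03d}.dcm", enforce_file_format=True)
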