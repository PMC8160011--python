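"""Shared fixtures: RNG, phantom datasets, synthetic DICOM series."""

from __future__ import annotations

import numpy as np
import pydicom
import pytest
from pydicom.dataset import FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from nodulepipe.phantom import PhantomConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_phantom_cfg():
    """Desk-scale phantom: 48px slices, small nodules."""
    return PhantomConfig(image_size=48, n_slices=4, nodule_radius_px=(2, 5),
                         nodules_per_case=(1, 3))


@pytest.fixture(scope="session")
def phantom_cases(small_phantom_cfg):
    cases, manifest = generate_dataset(small_phantom_cfg, n_cases=8, master_seed=42)
    return cases, manifest


def make_ct_file(path, stored: np.ndarray, *, series_uid: str, instance: int,
                 z_pos: float, slope: float = 1.0, intercept: float = -1024.0,
                 pixel_spacing=(0.7, 0.7), slice_thickness: float = 5.0,
                 with_rescale: bool = True) -> None:
    """Write a minimal single-frame CT DICOM file for fixtures."""
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.CTImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = pydicom.uid.CTImageStorage
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "CT"
    ds.PatientID = "fixture"
    ds.SeriesInstanceUID = series_uid
    ds.InstanceNumber = instance
    ds.ImagePositionPatient = [0.0, 0.0, z_pos]
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    ds.PixelSpacing = list(pixel_spacing)
    ds.SliceThickness = slice_thickness
    if with_rescale:
        ds.RescaleSlope = slope
        ds.RescaleIntercept = intercept
    ds.Rows, ds.Columns = stored.shape
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.PixelData = stored.astype(np.uint16).tobytes()
    ds.save_as(str(path), enforce_file_format=True)


@pytest.fixture
def dicom_series_factory(tmp_path):
    """Factory writing an n-slice series of given stored-value slices."""

    def build(slices, *, slope=1.0, intercept=-1024.0, shuffle_names=False,
              series_uid=None, **kwargs):
        series_uid = series_uid or generate_uid()
        d = tmp_path / "series"
        d.mkdir(exist_ok=True)
        order = list(range(len(slices)))
        names = [f"img{i:03d}.dcm" for i in order]
        if shuffle_names:
            names = list(reversed(names))
        for i, (name, sl) in enumerate(zip(names, slices)):
            make_ct_file(d / name, np.asarray(sl), series_uid=series_uid,
                         instance=i + 1, z_pos=float(i) * 5.0,
                         slope=slope, intercept=intercept, **kwargs)
        return d

    return build
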