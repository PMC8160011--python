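"""Reading, writing and resampling of CT volumes.

CT scanners store attenuation as raw integers plus a per-file linear
rescale (slope, intercept) that maps them to Hounsfield units (HU), the
calibrated scale with water at 0 HU and air at -1000 HU.  This module
turns a DICOM series or a NIfTI file into a :class:`CTVolume` of HU
values, writes volumes back to NIfTI, and resamples individual slices
to the working resolution.

Conventions
-----------
Voxel indices are 0-based ``(slice, row, col)``.  Images and masks that
belong together always share one grid.  On disk, HU volumes are stored
as signed 16-bit integers, masks as 8-bit, normalized images as 32-bit
float.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pydicom
from skimage.transform import resize as _sk_resize

__all__ = [
    "CTVolume",
    "SliceImage",
    "read_dicom_series",
    "read_nifti",
    "write_nifti",
    "resize_slice",
]

#: plausible HU range after rescale; values outside indicate a rescale bug
HU_MIN, HU_MAX = -1024.0, 3000.0


@dataclass
class CTVolume:
    """A HU-valued voxel grid with spacing metadata.

    Parameters
    ----------
    voxels : ndarray, shape (slices, rows, cols)
        Hounsfield-unit values, finite.
    spacing : tuple of float
        (slice-thickness, row, col) in millimetres, all positive.
    orientation : str
        Axis-order tag relative to patient axes; passed through, never
        validated against anatomy.
    case_id : str
        Opaque identifier of the originating case.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    orientation: str = "SRC"
    case_id: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or self.voxels.shape[0] < 1:
            raise ValueError(
                f"voxels must be 3D (slices, rows, cols), got shape {self.voxels.shape}"
            )
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("voxels contain non-finite HU values")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def slice_shape(self) -> tuple[int, int]:
        return self.voxels.shape[1:]

    def slice(self, index: int) -> "SliceImage":
        """Extract one slice as a HU-valued :class:`SliceImage`."""
        return SliceImage(
            pixels=self.voxels[index],
            unit_normalized=False,
            case_id=self.case_id,
            slice_index=index,
        )


@dataclass
class SliceImage:
    """A single 2D slice, either HU-valued or unit-normalized.

    ``unit_normalized`` records the value domain: False means HU, True
    means the pixels lie in [0, 1] after windowing.
    """

    pixels: np.ndarray
    unit_normalized: bool = False
    case_id: str = ""
    slice_index: int = 0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(f"slice pixels must be 2D, got shape {self.pixels.shape}")
        if self.unit_normalized and (
            self.pixels.min() < -1e-9 or self.pixels.max() > 1 + 1e-9
        ):
            raise ValueError("unit-normalized slice has values outside [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def _series_sort_key(ds: pydicom.Dataset) -> float:
    """Spatial position along the slice axis; falls back to instance number."""
    try:
        ipp = np.asarray(ds.ImagePositionPatient, dtype=float)
        iop = np.asarray(ds.ImageOrientationPatient, dtype=float)
        normal = np.cross(iop[:3], iop[3:])
        return float(np.dot(ipp, normal))
    except (AttributeError, TypeError, ValueError):
        return float(getattr(ds, "InstanceNumber", 0))


def read_dicom_series(directory: str | Path) -> CTVolume:
    """Read a single-frame CT DICOM series into a HU-valued volume.

    Slices are ordered by spatial position along the slice axis (falling
    back to instance number when position metadata is absent) and stored
    values are mapped to HU via each file's rescale slope and intercept.

    Raises
    ------
    ValueError
        If the directory holds more than one series, a file lacks
        rescale metadata, or slice shapes differ.
    """
    directory = Path(directory)
    paths = sorted(p for p in directory.iterdir() if p.is_file())
    datasets = []
    for p in paths:
        try:
            datasets.append(pydicom.dcmread(str(p)))
        except pydicom.errors.InvalidDicomError:
            continue
    if not datasets:
        raise ValueError(f"no DICOM files found in {directory}")

    series_ids = {str(getattr(ds, "SeriesInstanceUID", "")) for ds in datasets}
    if len(series_ids) > 1:
        raise ValueError(
            "directory mixes multiple DICOM series: " + ", ".join(sorted(series_ids))
        )

    datasets.sort(key=_series_sort_key)

    slices = []
    for ds in datasets:
        if "RescaleSlope" not in ds or "RescaleIntercept" not in ds:
            raise ValueError(
                f"missing rescale metadata (slope/intercept) in series {series_ids.pop()}"
            )
        hu = ds.pixel_array.astype(np.float64) * float(ds.RescaleSlope) + float(
            ds.RescaleIntercept
        )
        slices.append(hu)

    shapes = {s.shape for s in slices}
    if len(shapes) > 1:
        raise ValueError(f"inconsistent slice shapes in series: {sorted(shapes)}")
    voxels = np.stack(slices)

    ds0 = datasets[0]
    row_mm, col_mm = (float(v) for v in getattr(ds0, "PixelSpacing", [1.0, 1.0]))
    slice_mm = float(getattr(ds0, "SliceThickness", 1.0))
    if len(datasets) > 1:
        positions = np.array([_series_sort_key(ds) for ds in datasets])
        gaps = np.diff(positions)
        if gaps.size and np.all(gaps > 0):
            if np.ptp(gaps) > 0.01 * np.median(gaps):
                warnings.warn(
                    "non-uniform inter-slice gap; using median gap as slice spacing",
                    stacklevel=2,
                )
            slice_mm = float(np.median(gaps))

    return CTVolume(
        voxels=voxels,
        spacing=(slice_mm, row_mm, col_mm),
        case_id=str(getattr(ds0, "PatientID", directory.name)),
    )


# on-disk dtypes by content kind
_NIFTI_DTYPES = {"hu": np.int16, "mask": np.uint8, "float": np.float32}


def write_nifti(volume: CTVolume, path: str | Path, kind: str = "hu") -> Path:
    """Write a volume to NIfTI-1 with spacing encoded in the affine.

    ``kind`` selects the on-disk dtype: ``hu`` (int16), ``mask``
    (uint8) or ``float`` (float32).  The affine maps voxel index
    (col, row, slice order on disk) to millimetres.
    """
    if kind not in _NIFTI_DTYPES:
        raise ValueError(f"unknown kind {kind!r}; expected one of {sorted(_NIFTI_DTYPES)}")
    path = Path(path)
    slice_mm, row_mm, col_mm = volume.spacing
    affine = np.diag([col_mm, row_mm, slice_mm, 1.0])
    # store (cols, rows, slices) so NIfTI's fastest-varying axis is in-plane
    data = np.transpose(volume.voxels, (2, 1, 0)).astype(_NIFTI_DTYPES[kind])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms((col_mm, row_mm, slice_mm))
    nib.save(img, str(path))
    return path


def read_nifti(path: str | Path) -> CTVolume:
    """Read a NIfTI volume written by :func:`write_nifti` (or compatible)."""
    path = Path(path)
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
    except Exception as exc:  # nibabel raises several error types
        raise ValueError(f"not a readable NIfTI file: {path}") from exc
    if data.ndim == 2:
        data = data[..., np.newaxis]
    if data.ndim != 3:
        raise ValueError(f"expected a 3D NIfTI volume, got {data.ndim}D in {path}")
    zooms = img.header.get_zooms()[:3]
    voxels = np.transpose(data, (2, 1, 0)).astype(np.float64)
    return CTVolume(
        voxels=voxels,
        spacing=(float(zooms[2]), float(zooms[1]), float(zooms[0])),
        case_id=path.stem.replace(".nii", ""),
    )


def resize_slice(img: SliceImage, target: tuple[int, int]) -> SliceImage:
    """Resample a slice to ``target`` (rows, cols) by bilinear interpolation.

    Anti-aliasing is applied when downsizing.  Linear interpolation never
    expands the value range beyond the input min/max.  Masks must go
    through :func:`nodulepipe.labeling.resize_mask` instead.
    """
    rows, cols = target
    if rows < 2 or cols < 2:
        raise ValueError(f"target dims must be >= 2, got {target}")
    src = img.pixels
    anti_alias = rows < src.shape[0] or cols < src.shape[1]
    out = _sk_resize(
        src, (rows, cols), order=1, anti_aliasing=anti_alias,
        preserve_range=True, mode="reflect",
    )
    # guard against interpolation overshoot at boundaries
    out = np.clip(out, src.min(), src.max())
    return SliceImage(
        pixels=out,
        unit_normalized=img.unit_normalized,
        case_id=img.case_id,
        slice_index=img.slice_index,
    )
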