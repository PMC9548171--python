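"""Image containers and I/O for fat–water abdominal MRI.

The pipeline works on stacks of axial slices. Two acquisition schemes are
supported:

* base + fat-suppressed ("water") images, where the fat-only image is the
  voxelwise difference base − water (rodent T1 RARE + CHESS protocols);
* 2-point Dixon in-phase / out-of-phase magnitude images, combined with the
  standard sum/difference formulas into water and fat images (human scans).

Stacks are plain ``(n_slices, height, width)`` float arrays carried together
with their voxel geometry, which is all the volumetry step needs.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import pydicom
from pydicom.errors import InvalidDicomError

__all__ = [
    "VoxelGeometry",
    "MOUSE_GEOMETRY",
    "HUMAN_GEOMETRY",
    "ImageStack",
    "SubjectScan",
    "read_dicom_series",
    "derive_fat_image",
    "dixon_combine",
    "select_kidney_window",
    "write_depot_map",
    "read_depot_map",
]

MODALITIES = ("base", "water", "fat", "in_phase", "out_phase", "label")


@dataclass(frozen=True)
class VoxelGeometry:
    """In-plane voxel spacing and slice thickness, all in millimetres."""

    dx_mm: float
    dy_mm: float
    dz_mm: float

    def __post_init__(self) -> None:
        if not (self.dx_mm > 0 and self.dy_mm > 0 and self.dz_mm > 0):
            raise ValueError("voxel dimensions must be strictly positive")

    @property
    def voxel_volume_mm3(self) -> float:
        return self.dx_mm * self.dy_mm * self.dz_mm


#: 7 T small-animal protocol: 0.156 x 0.156 mm in plane, 1 mm slices.
MOUSE_GEOMETRY = VoxelGeometry(0.156, 0.156, 1.0)
#: 1.5 T clinical 2-point Dixon protocol: 1.234 x 1.234 mm, 2.5 mm slices.
HUMAN_GEOMETRY = VoxelGeometry(1.234, 1.234, 2.5)


@dataclass
class ImageStack:
    """An ordered stack of axial slices with shared geometry.

    ``data`` has shape ``(n_slices, height, width)`` and is non-negative
    (magnitude MR signal). ``source_indices`` preserves the original slice
    indices after windowing operations.
    """

    data: np.ndarray
    geometry: VoxelGeometry
    modality: str
    source_indices: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("stack data must be (n_slices, height, width)")
        if self.data.size and self.data.min() < 0:
            raise ValueError("signal intensities must be non-negative")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.source_indices is None:
            self.source_indices = np.arange(self.data.shape[0])
        else:
            self.source_indices = np.asarray(self.source_indices, dtype=int)
            if self.source_indices.shape != (self.data.shape[0],):
                raise ValueError("source_indices must have one entry per slice")

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]

    @property
    def height(self) -> int:
        return self.data.shape[1]

    @property
    def width(self) -> int:
        return self.data.shape[2]


def _check_same_shape(a: ImageStack, b: ImageStack) -> None:
    if a.data.shape != b.data.shape or a.geometry != b.geometry:
        raise ValueError("shape mismatch")


@dataclass
class SubjectScan:
    """The stacks needed to segment one subject.

    ``anatomy_reference`` is the stack used for body-mask / contour
    extraction: the unsuppressed base stack for mice, the in-phase stack for
    humans.
    """

    subject_id: str
    species: str
    fat: ImageStack
    anatomy_reference: ImageStack
    water: ImageStack | None = None
    out_phase: ImageStack | None = None

    def __post_init__(self) -> None:
        if self.species not in ("mouse", "human"):
            raise ValueError("species must be 'mouse' or 'human'")
        _check_same_shape(self.fat, self.anatomy_reference)


# ---------------------------------------------------------------------------
# DICOM reading
# ---------------------------------------------------------------------------

def _slice_sort_key(ds) -> tuple[float, int]:
    instance = int(getattr(ds, "InstanceNumber", 0) or 0)
    iop = getattr(ds, "ImageOrientationPatient", None)
    ipp = getattr(ds, "ImagePositionPatient", None)
    if iop is not None and ipp is not None:
        row = np.asarray(iop[:3], dtype=float)
        col = np.asarray(iop[3:], dtype=float)
        normal = np.cross(row, col)
        return (float(np.dot(np.asarray(ipp, dtype=float), normal)), instance)
    return (0.0, instance)


def read_dicom_series(
    directory: str | os.PathLike,
    modality: str,
    geometry: VoxelGeometry | None = None,
) -> ImageStack:
    """Read a single-frame DICOM series into an ordered :class:`ImageStack`.

    Slices are ordered by the projection of the image position onto the slice
    normal, tie-broken by instance number. Stored values are mapped through
    rescale slope/intercept when present; negative rescaled values are clipped
    to zero (magnitude images).

    Parameters
    ----------
    geometry:
        Fallback geometry when the series lacks pixel-spacing or
        slice-thickness attributes; without it a missing attribute raises
        ``ValueError("missing geometry")``.
    """
    directory = Path(directory)
    datasets = []
    for path in sorted(directory.iterdir()):
        if not path.is_file():
            continue
        try:
            datasets.append(pydicom.dcmread(path))
        except (InvalidDicomError, IsADirectoryError):
            continue
    if not datasets:
        raise ValueError("no images")

    datasets.sort(key=_slice_sort_key)
    shapes = {ds.pixel_array.shape for ds in datasets}
    if len(shapes) != 1:
        raise ValueError("inconsistent series")

    slices = []
    for ds in datasets:
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0) or 1.0)
        intercept = float(getattr(ds, "RescaleIntercept", 0.0) or 0.0)
        slices.append(np.maximum(arr * slope + intercept, 0.0))

    first = datasets[0]
    spacing = getattr(first, "PixelSpacing", None)
    thickness = getattr(first, "SliceThickness", None)
    if spacing is None or thickness is None:
        if geometry is None:
            raise ValueError("missing geometry")
    else:
        # DICOM PixelSpacing is (row spacing, column spacing) = (dy, dx)
        geometry = VoxelGeometry(float(spacing[1]), float(spacing[0]), float(thickness))

    return ImageStack(np.stack(slices), geometry, modality)


# ---------------------------------------------------------------------------
# Fat-image derivation
# ---------------------------------------------------------------------------

def derive_fat_image(base: ImageStack, water: ImageStack) -> ImageStack:
    """Fat-only image from a base stack and its fat-suppressed counterpart.

    ``fat = max(base − water, 0)`` voxelwise; magnitude signal cannot go
    negative, so subtraction overshoot is clamped.
    """
    _check_same_shape(base, water)
    fat = np.maximum(base.data - water.data, 0.0)
    return ImageStack(fat, base.geometry, "fat", base.source_indices.copy())


def dixon_combine(in_phase: ImageStack, out_phase: ImageStack) -> tuple[ImageStack, ImageStack]:
    """Standard magnitude 2-point Dixon water/fat separation.

    water = (IP + OP) / 2, fat = max((IP − OP) / 2, 0).
    """
    _check_same_shape(in_phase, out_phase)
    water = (in_phase.data + out_phase.data) / 2.0
    fat = np.maximum((in_phase.data - out_phase.data) / 2.0, 0.0)
    idx = in_phase.source_indices.copy()
    return (
        ImageStack(water, in_phase.geometry, "water", idx),
        ImageStack(fat, in_phase.geometry, "fat", idx.copy()),
    )


def select_kidney_window(stack: ImageStack, midpoint_index: int, n: int = 10) -> ImageStack:
    """Select the ``n`` slices around the kidney midpoint.

    Uses the half-open window ``[midpoint − n/2, midpoint + n/2)``: the
    midpoint's own slice counts on the upper side, giving n/2 slices on each
    side. Original slice indices are kept in ``source_indices``.
    """
    if n <= 0 or n % 2 != 0:
        raise ValueError("n must be a positive even count")
    lo = midpoint_index - n // 2
    hi = midpoint_index + n // 2
    if lo < 0 or hi > stack.n_slices:
        raise ValueError("window out of range")
    return ImageStack(
        stack.data[lo:hi].copy(),
        stack.geometry,
        stack.modality,
        stack.source_indices[lo:hi].copy(),
    )


# ---------------------------------------------------------------------------
# Label-map I/O
# ---------------------------------------------------------------------------

def _check_labels(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    if not np.isin(labels, (0, 1, 2)).all():
        raise ValueError("labels must be in {0, 1, 2}")
    return labels.astype(np.uint8)


def write_depot_map(
    labels: np.ndarray,
    path: str | os.PathLike,
    format: str = "nifti",
    geometry: VoxelGeometry | None = None,
) -> None:
    """Write a depot label stack (0 background, 1 SAT, 2 VAT) losslessly.

    ``nifti`` writes a single uint8 NIfTI-1 volume with the voxel geometry in
    the affine; ``png_series`` writes one 8-bit greyscale PNG per slice into
    the directory ``path`` (created if needed).
    """
    labels = _check_labels(labels)
    if format == "nifti":
        g = geometry or VoxelGeometry(1.0, 1.0, 1.0)
        affine = np.diag([g.dx_mm, g.dy_mm, g.dz_mm, 1.0])
        # store as (x, y, z) = (col, row, slice)
        img = nib.Nifti1Image(labels.transpose(2, 1, 0), affine)
        nib.save(img, str(path))
    elif format == "png_series":
        out = Path(path)
        out.mkdir(parents=True, exist_ok=True)
        for i in range(labels.shape[0]):
            iio.imwrite(out / f"slice_{i:04d}.png", labels[i])
    else:
        raise ValueError(f"unknown format {format!r}")


def read_depot_map(path: str | os.PathLike, format: str = "nifti") -> np.ndarray:
    """Read a label stack written by :func:`write_depot_map`."""
    if format == "nifti":
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
        return _check_labels(np.asarray(data).transpose(2, 1, 0))
    if format == "png_series":
        files = sorted(Path(path).glob("slice_*.png"), key=lambda p: int(re.findall(r"\d+", p.stem)[0]))
        if not files:
            raise ValueError("no images")
        return _check_labels(np.stack([iio.imread(f) for f in files]))
    raise ValueError(f"unknown format {format!r}")
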