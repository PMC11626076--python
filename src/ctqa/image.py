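"""HU-calibrated CT images and file loaders.

A :class:`CTImage` is a 2D array of Hounsfield Units plus the physical pixel
spacing in millimetres.  All downstream measurements (line profiles, ROI
statistics) operate on this type, so every loader is responsible for
delivering HU-calibrated pixels.

Supported inputs: NIfTI (via nibabel), plain-text arrays, ``.npy`` arrays,
and — when :mod:`pydicom` is installed — single-frame DICOM files with
rescale slope/intercept applied.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = ["CTImage", "load_nifti", "load_array", "load_dicom"]


@dataclass
class CTImage:
    """A 2D CT slice in Hounsfield Units with physical pixel spacing.

    Parameters
    ----------
    pixels:
        2D array of HU values, indexed ``pixels[row, col]`` i.e. ``[y, x]``.
    spacing_x, spacing_y:
        Pixel spacing in mm along the x (column) and y (row) axes.
    metadata:
        Free-form acquisition tags (kVp, mA, slice thickness, window...).
    """

    pixels: np.ndarray
    spacing_x: float = 1.0
    spacing_y: float = 1.0
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError(
                f"pixels must be a non-empty 2D array, got shape {self.pixels.shape}"
            )
        for name in ("spacing_x", "spacing_y"):
            value = float(getattr(self, name))
            if not np.isfinite(value) or value <= 0:
                raise ValueError(f"{name} must be strictly positive and finite, got {value}")
            setattr(self, name, value)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # (rows, cols)

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    def contains(self, x: int, y: int) -> bool:
        """Whether integer pixel coordinate (x, y) lies inside the image."""
        return 0 <= x < self.width and 0 <= y < self.height

    def hu(self, x: int, y: int) -> float:
        """HU value at integer pixel coordinate (x = column, y = row)."""
        return float(self.pixels[y, x])


def load_array(path: str | os.PathLike, spacing: tuple[float, float] = (1.0, 1.0)) -> CTImage:
    """Load a 2D HU array from a ``.npy`` or whitespace-delimited text file."""
    path = os.fspath(path)
    if path.endswith(".npy"):
        pixels = np.load(path)
    else:
        pixels = np.loadtxt(path)
    return CTImage(pixels=pixels, spacing_x=spacing[0], spacing_y=spacing[1])


def load_nifti(path: str | os.PathLike) -> list[CTImage]:
    """Load a NIfTI volume as a list of axial :class:`CTImage` slices.

    The NIfTI data array is interpreted as (x, y[, z]); zooms supply the
    pixel spacing in mm.  Scaling (scl_slope/scl_inter) is applied by
    nibabel's ``get_fdata`` so voxels come out in HU for HU-calibrated files.
    """
    import nibabel as nib

    img = nib.load(os.fspath(path))
    data = np.asanyarray(img.get_fdata())
    zooms = img.header.get_zooms()
    sx, sy = float(zooms[0]), float(zooms[1])
    if data.ndim == 2:
        data = data[:, :, np.newaxis]
    if data.ndim != 3:
        raise ValueError(f"expected a 2D or 3D NIfTI volume, got {data.ndim}D")
    slices = []
    for k in range(data.shape[2]):
        # transpose (x, y) -> (row=y, col=x)
        slices.append(CTImage(pixels=data[:, :, k].T, spacing_x=sx, spacing_y=sy))
    return slices


def load_dicom(path: str | os.PathLike) -> CTImage:
    """Load a single-frame DICOM file, applying rescale slope/intercept.

    Requires the optional :mod:`pydicom` dependency.
    """
    try:
        import pydicom
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise ImportError(
            "DICOM support requires the optional 'pydicom' package "
            "(pip install ctqa[dicom]); NIfTI and array inputs work without it"
        ) from exc
    ds = pydicom.dcmread(os.fspath(path))
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    pixels = ds.pixel_array.astype(np.float64) * slope + intercept
    spacing = getattr(ds, "PixelSpacing", [1.0, 1.0])
    # DICOM PixelSpacing is (row spacing, column spacing)
    return CTImage(
        pixels=pixels,
        spacing_x=float(spacing[1]),
        spacing_y=float(spacing[0]),
        metadata={
            "kvp": getattr(ds, "KVP", None),
            "ma": getattr(ds, "XRayTubeCurrent", None),
            "slice_thickness": getattr(ds, "SliceThickness", None),
        },
    )
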