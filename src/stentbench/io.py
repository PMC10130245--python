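"""Volume I/O: NIfTI read/write and DICOM-series reading.

Volumes are exchanged as :class:`~stentbench.phantom.ImageVolume`.  NIfTI
stores voxels in (x, y, z) order with spacing on the affine diagonal; the
in-memory convention is (z, y, x), so axes are transposed on the way in and
out.  DICOM series are read slice-by-slice, sorted by z position, with the
rescale slope/intercept applied to obtain HU.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import InvalidParameterError
from .phantom import ImageVolume


def save_nifti(volume: ImageVolume, path: str | Path) -> None:
    """Write an ImageVolume as NIfTI with spacing and origin in the header."""
    dx, dy, dz = volume.spacing_mm
    affine = np.diag([dx, dy, dz, 1.0]).astype(float)
    affine[:3, 3] = volume.origin_mm
    data = np.ascontiguousarray(volume.voxels.transpose(2, 1, 0))
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms((dx, dy, dz))
    nib.save(img, str(path))


def load_nifti(path: str | Path) -> ImageVolume:
    """Read a NIfTI volume; spacing comes from the affine/zooms."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(np.float32)
    if data.ndim != 3:
        raise InvalidParameterError(f"expected a 3-D NIfTI volume, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return ImageVolume(
        data.transpose(2, 1, 0).copy(),
        spacing_mm=tuple(float(z) for z in zooms),
        origin_mm=origin,
    )


def load_dicom_series(directory: str | Path) -> ImageVolume:
    """Read a single-frame DICOM series from a directory into HU.

    Slices are sorted by ImagePositionPatient z (falling back to
    InstanceNumber); in-plane spacing comes from PixelSpacing and the axial
    spacing from consecutive slice positions (or SliceThickness for a
    single slice).
    """
    import pydicom

    directory = Path(directory)
    files = sorted(p for p in directory.iterdir() if p.suffix.lower() in (".dcm", ".ima"))
    if not files:
        files = sorted(p for p in directory.iterdir() if p.is_file())
    if not files:
        raise InvalidParameterError(f"no DICOM files found in {directory}")
    datasets = [pydicom.dcmread(str(p)) for p in files]

    def _zpos(ds) -> float:
        if getattr(ds, "ImagePositionPatient", None) is not None:
            return float(ds.ImagePositionPatient[2])
        return float(getattr(ds, "InstanceNumber", 0))

    datasets.sort(key=_zpos)
    ref = datasets[0]
    dy, dx = (float(v) for v in ref.PixelSpacing)
    if len(datasets) > 1:
        dz = abs(_zpos(datasets[1]) - _zpos(datasets[0]))
    else:
        dz = float(getattr(ref, "SliceThickness", 1.0))
    if dz <= 0:
        raise InvalidParameterError("non-positive slice spacing in DICOM series")
    slices = []
    for ds in datasets:
        arr = ds.pixel_array.astype(np.float32)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        slices.append(arr * slope + intercept)
    vox = np.stack(slices, axis=0)
    if getattr(ref, "ImagePositionPatient", None) is not None:
        origin = (
            float(ref.ImagePositionPatient[0]),
            float(ref.ImagePositionPatient[1]),
            _zpos(ref),
        )
    else:
        origin = (0.0, 0.0, 0.0)
    return ImageVolume(vox, spacing_mm=(dx, dy, dz), origin_mm=origin)


def load_volume(path: str | Path) -> ImageVolume:
    """Dispatch on path type: NIfTI file or DICOM-series directory."""
    path = Path(path)
    if path.is_dir():
        return load_dicom_series(path)
    return load_nifti(path)
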