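"""File readers/writers: NIfTI, DICOM, 16-bit PNG/TIFF, CSV traces.

NIfTI is the working volume format (pixel spacing travels in the
header, so degradation/up-sampling bookkeeping is externally visible);
DICOM is read-only for single frames; PNG/TIFF exports are for visual
inspection.
"""

from __future__ import annotations

import numpy as np

from .image import GrayImage
from .tracking_sim import MotionTrace

__all__ = [
    "save_nifti",
    "load_nifti_slices",
    "load_dicom",
    "save_png16",
    "save_trace_csv",
    "load_trace_csv",
]


def save_nifti(images: list[GrayImage] | GrayImage, path) -> None:
    """Write slices as a (n, H, W) NIfTI volume with spacing in the header."""
    import nibabel as nib

    if isinstance(images, GrayImage):
        images = [images]
    spacing = images[0].spacing
    for im in images:
        if im.shape != images[0].shape or im.spacing != spacing:
            raise ValueError("all slices must share shape and spacing")
    vol = np.stack([im.pixels for im in images], axis=0)
    affine = np.diag([1.0, spacing[0], spacing[1], 1.0])
    nii = nib.Nifti1Image(vol.astype(np.float32), affine)
    nii.header.set_zooms((1.0, spacing[0], spacing[1]))
    nib.save(nii, str(path))


def load_nifti_slices(path, axis: int = 0) -> list[GrayImage]:
    """Read a NIfTI volume and extract 2-D slices along ``axis``."""
    import nibabel as nib

    try:
        nii = nib.load(str(path))
        vol = np.asarray(nii.get_fdata(), dtype=np.float64)
    except (nib.filebasedimages.ImageFileError, OSError) as exc:
        raise ValueError(f"cannot read NIfTI file {path!r}: {exc}") from exc
    if vol.ndim == 2:
        vol = vol[None]
        axis = 0
    if vol.ndim != 3:
        raise ValueError(f"expected a 2-D or 3-D NIfTI, got ndim={vol.ndim}")
    zooms = nii.header.get_zooms()[:3]
    in_plane = tuple(z for i, z in enumerate(zooms) if i != axis)
    vol = np.moveaxis(vol, axis, 0)
    return [GrayImage(np.abs(sl), in_plane) for sl in vol]


def load_dicom(path) -> GrayImage:
    """Read a single-frame DICOM image (PixelSpacing honoured if present)."""
    import pydicom

    ds = pydicom.dcmread(str(path))
    px = np.abs(np.asarray(ds.pixel_array, dtype=np.float64))
    if px.ndim != 2:
        raise ValueError("only single-frame DICOM supported")
    spacing = (1.0, 1.0)
    if getattr(ds, "PixelSpacing", None) is not None:
        spacing = (float(ds.PixelSpacing[0]), float(ds.PixelSpacing[1]))
    return GrayImage(px, spacing)


def save_png16(img: GrayImage, path) -> None:
    """Export intensities (clipped to [0, 65535]) as 16-bit PNG/TIFF."""
    import imageio.v3 as iio

    px = np.clip(np.round(img.pixels), 0, 65535).astype(np.uint16)
    iio.imwrite(str(path), px)


def save_trace_csv(trace: MotionTrace, path) -> None:
    np.savetxt(str(path), np.column_stack([trace.t, trace.x]),
               delimiter=",", header="t_s,x_mm", comments="")


def load_trace_csv(path) -> MotionTrace:
    data = np.loadtxt(str(path), delimiter=",", skiprows=1)
    return MotionTrace(data[:, 0], data[:, 1])
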