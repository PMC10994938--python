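"""Frequency-domain degradation and intensity pre-processing.

Low-resolution MRI acquisitions measure only the centre of k-space, so a
realistic low/high-resolution training pair is built by Fourier
transforming a high-resolution image, cropping the central block of the
spectrum and inverse transforming.  This module implements that
degradation plus the intensity normalisation steps applied before image
quality metrics (percentile clipping, min-max scaling, clamping).

Conventions
-----------
* Orthonormal ("ortho") FFTs, so Parseval's identity holds without extra
  factors.
* After the centre shift the DC coefficient sits at 0-based index
  ``(H//2, W//2)``, for both even and odd sizes.
* The cropped spectrum is rescaled by ``sqrt(Mh*Mw/(Nh*Nw))`` so a
  constant image keeps its value through down-sampling; low- and
  high-resolution images therefore share one intensity scale.
* Outputs are magnitude images (MR magnitude data are nonnegative).
"""

from __future__ import annotations

import warnings

import numpy as np

from .image import GrayImage

__all__ = [
    "Spectrum2D",
    "fft_centered",
    "ifft_centered",
    "kspace_downsample",
    "zero_pad_to",
    "clip_to_percentile",
    "minmax_scale",
    "clamp_max",
]


class Spectrum2D:
    """Centred complex k-space grid paired with its image-domain size."""

    __slots__ = ("coeffs", "source_shape", "spacing")

    def __init__(self, coeffs: np.ndarray, source_shape: tuple[int, int],
                 spacing: tuple[float, float] = (1.0, 1.0)):
        coeffs = np.asarray(coeffs, dtype=np.complex128)
        if coeffs.ndim != 2:
            raise ValueError("spectrum must be 2-D")
        if coeffs.shape != tuple(source_shape):
            raise ValueError("coeffs shape must equal source_shape")
        self.coeffs = coeffs
        self.source_shape = tuple(source_shape)
        self.spacing = (float(spacing[0]), float(spacing[1]))

    @property
    def dc_index(self) -> tuple[int, int]:
        h, w = self.source_shape
        return (h // 2, w // 2)


def fft_centered(img: GrayImage) -> Spectrum2D:
    """Orthonormal, centre-shifted 2-D Fourier transform of an image."""
    px = img.pixels
    if px.ndim != 2:
        raise ValueError("fft_centered expects a 2-D image")
    coeffs = np.fft.fftshift(np.fft.fft2(px, norm="ortho"))
    return Spectrum2D(coeffs, px.shape, img.spacing)


def ifft_centered(spec: Spectrum2D, magnitude: bool = False) -> GrayImage:
    """Inverse of :func:`fft_centered`.

    With ``magnitude=True`` the absolute value is returned, which is the
    convention for MR magnitude images; otherwise the real part is kept
    (the imaginary part of a spectrum from a real image is numerically
    zero after the round trip).
    """
    field = np.fft.ifft2(np.fft.ifftshift(spec.coeffs), norm="ortho")
    px = np.abs(field) if magnitude else field.real
    return GrayImage(px, spec.spacing)


def _center_crop_slices(n: int, m: int) -> slice:
    """Slice retaining the centred block of size m in an axis of size n."""
    c = n // 2
    return slice(c - m // 2, c + (m + 1) // 2)


def kspace_downsample(img: GrayImage, factor: int) -> GrayImage:
    """Synthesize a low-resolution image by truncating k-space.

    The centre of the spectrum — the low spatial frequencies — is cropped
    to ``(H/factor, W/factor)``, rescaled to preserve the intensity
    scale, and inverse transformed.  The pixel spacing grows by
    ``factor`` so the field of view is preserved.
    """
    if int(factor) != factor or factor < 1:
        raise ValueError(f"factor must be a positive integer, got {factor}")
    factor = int(factor)
    h, w = img.shape
    if h % factor or w % factor:
        raise ValueError(
            f"image shape {img.shape} not divisible by factor {factor}")
    mh, mw = h // factor, w // factor
    spec = fft_centered(img)
    block = spec.coeffs[_center_crop_slices(h, mh), _center_crop_slices(w, mw)]
    block = block * np.sqrt((mh * mw) / (h * w))
    out_spec = Spectrum2D(block, (mh, mw),
                          (img.spacing[0] * factor, img.spacing[1] * factor))
    return ifft_centered(out_spec, magnitude=True)


def zero_pad_to(img: GrayImage, target: tuple[int, int]) -> GrayImage:
    """Pad an image with zeros to ``target`` shape, content centred.

    For odd margins the extra row/column goes to the bottom/right, i.e.
    the content is anchored toward the top-left.  Intensity sum is
    preserved exactly.
    """
    th, tw = int(target[0]), int(target[1])
    h, w = img.shape
    if th < h or tw < w:
        raise ValueError(f"target {target} smaller than source {img.shape}")
    out = np.zeros((th, tw), dtype=np.float64)
    r0, c0 = (th - h) // 2, (tw - w) // 2
    out[r0:r0 + h, c0:c0 + w] = img.pixels
    return GrayImage(out, img.spacing)


def clip_to_percentile(img: GrayImage, q: float = 99.9) -> GrayImage:
    """Set voxels above the q-th percentile to that percentile value.

    Removes extreme bright spots (e.g. vessels or artefacts) before
    min-max normalisation, reassigning at most ``(100-q)%`` of voxels.
    The percentile uses the linear-interpolation rule on the sorted
    flattened image.
    """
    if not (0 < q <= 100):
        raise ValueError(f"percentile q must lie in (0, 100], got {q}")
    if img.pixels.size == 0:
        raise ValueError("empty image")
    cap = float(np.percentile(img.pixels, q))
    return img.with_pixels(np.minimum(img.pixels, cap))


def minmax_scale(img: GrayImage, lo: float = 0.0, hi: float = 4096.0) -> GrayImage:
    """Affine map sending the image minimum to ``lo`` and maximum to ``hi``."""
    px = img.pixels
    mn, mx = float(px.min()), float(px.max())
    if mx <= mn:
        warnings.warn("minmax_scale: constant image, returning all-lo",
                      RuntimeWarning, stacklevel=2)
        return img.with_pixels(np.full_like(px, lo))
    return img.with_pixels(lo + (px - mn) * ((hi - lo) / (mx - mn)))


def clamp_max(img: GrayImage, cap: float = 4096.0) -> GrayImage:
    """Clamp intensities to ``cap`` (idempotent)."""
    if cap <= 0:
        raise ValueError("cap must be positive")
    return img.with_pixels(np.minimum(img.pixels, cap))
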