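"""Greyscale gradient operators and binary boundary extraction.

The thresholding methods in this package all rest on two primitives: a
per-pixel gradient-magnitude raster of the input image, and the one-pixel
inner boundary of a binary phase.  Both are defined with a 3x3 square
structuring element ``A``:

* the Beucher (morphological) gradient, ``(I (+) A) - (I (-) A)``, i.e.
  greyscale dilation minus erosion — the local max-minus-min contrast;
* the internal morphological gradient of a mask ``B``,
  ``B AND NOT (B (-) A)`` — the set of foreground pixels with at least one
  background pixel (or the image frame) in their 3x3 neighbourhood.

Border conventions (stated once, used everywhere): greyscale morphology and
the Sobel filter use replicate padding; *binary* erosion treats
outside-the-image as background, so regions touching the frame acquire
boundary pixels along the frame and every phase boundary is a closed curve
suitable for hole filling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .exceptions import ParameterError

__all__ = [
    "GreyImage",
    "GradientImage",
    "BinaryMask",
    "BoundaryMask",
    "SQUARE_3X3",
    "gaussian_preprocess",
    "compute_gradient",
    "phase_boundary",
]

#: 3x3 square structuring element A used by all morphological operators.
SQUARE_3X3 = np.ones((3, 3), dtype=bool)

# Array aliases for readability of signatures.  A GradientImage is a float64
# raster of non-negative magnitudes; Binary/BoundaryMask are boolean rasters.
GradientImage = np.ndarray
BinaryMask = np.ndarray
BoundaryMask = np.ndarray

_DTYPES = {8: np.uint8, 16: np.uint16}


@dataclass(frozen=True)
class GreyImage:
    """A single-channel intensity raster with an explicit bit depth.

    Parameters
    ----------
    pixels : ndarray
        2-D array of dtype uint8 or uint16.
    bit_depth : int
        8 or 16; must match the dtype of ``pixels``.
    """

    pixels: np.ndarray
    bit_depth: int = field(default=8)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ParameterError(f"expected a 2-D raster, got ndim={px.ndim}")
        if self.bit_depth not in _DTYPES:
            raise ParameterError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if px.dtype != _DTYPES[self.bit_depth]:
            raise ParameterError(
                f"dtype {px.dtype} does not match bit_depth {self.bit_depth}"
            )
        object.__setattr__(self, "pixels", px)

    @classmethod
    def from_array(cls, array: np.ndarray, bit_depth: int | None = None) -> "GreyImage":
        """Build a GreyImage from any integer array, validating its range."""
        arr = np.asarray(array)
        if arr.ndim != 2:
            raise ParameterError(f"expected a 2-D raster, got ndim={arr.ndim}")
        if not np.issubdtype(arr.dtype, np.integer):
            raise ParameterError(f"expected integer pixel values, got {arr.dtype}")
        if bit_depth is None:
            bit_depth = 8 if arr.max(initial=0) <= 255 and arr.dtype.itemsize == 1 else (
                8 if arr.dtype == np.uint8 else 16
            )
        lo, hi = 0, 2**bit_depth - 1
        if arr.min(initial=0) < lo or arr.max(initial=0) > hi:
            raise ParameterError(f"pixel values outside [{lo}, {hi}] for {bit_depth}-bit")
        return cls(arr.astype(_DTYPES[bit_depth]), bit_depth)

    # -- geometry ---------------------------------------------------------
    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    # -- levels -----------------------------------------------------------
    @property
    def max_representable(self) -> int:
        return 2**self.bit_depth - 1

    @property
    def level_min(self) -> int:
        """Smallest grey level present in the image."""
        return int(self.pixels.min())

    @property
    def level_max(self) -> int:
        """Largest grey level present in the image."""
        return int(self.pixels.max())

    def invert(self) -> "GreyImage":
        """Photometric inversion over the full representable range."""
        return GreyImage(
            (self.max_representable - self.pixels.astype(np.int64)).astype(
                _DTYPES[self.bit_depth]
            ),
            self.bit_depth,
        )


def _require_min_size(image: GreyImage) -> None:
    if image.height < 3 or image.width < 3:
        raise ParameterError(
            f"gradient computation needs at least 3x3 pixels, got {image.shape}"
        )


def gaussian_preprocess(image: GreyImage, radius: float) -> GreyImage:
    """Smooth an image with a Gaussian of the given radius (taken as sigma).

    ``radius=0`` returns the input unchanged.  The result is rounded and
    clipped back to the image's bit-depth range.
    """
    if radius < 0:
        raise ParameterError(f"Gaussian radius must be >= 0, got {radius}")
    if radius == 0:
        return image
    smoothed = ndimage.gaussian_filter(
        image.pixels.astype(np.float64), sigma=radius, mode="nearest"
    )
    clipped = np.clip(np.rint(smoothed), 0, image.max_representable)
    return GreyImage(clipped.astype(_DTYPES[image.bit_depth]), image.bit_depth)


def compute_gradient(image: GreyImage, method: str = "beucher") -> GradientImage:
    """Gradient-magnitude raster of an image.

    ``beucher``: greyscale dilation minus erosion with the 3x3 square
    (exact integer arithmetic, returned as float64).
    ``sobel``: Euclidean magnitude of the two 3x3 Sobel responses, kept at
    full float precision (no quantisation to the bit-depth range).
    """
    _require_min_size(image)
    px = image.pixels
    if method == "beucher":
        dil = ndimage.grey_dilation(px, size=(3, 3), mode="nearest")
        ero = ndimage.grey_erosion(px, size=(3, 3), mode="nearest")
        return dil.astype(np.float64) - ero.astype(np.float64)
    if method == "sobel":
        f = px.astype(np.float64)
        gy = ndimage.sobel(f, axis=0, mode="nearest")
        gx = ndimage.sobel(f, axis=1, mode="nearest")
        return np.hypot(gx, gy)
    raise ParameterError(f"unknown gradient method {method!r}; use 'beucher' or 'sobel'")


# Laplacian kernels with 4- and 8-connected support.
_LAPLACIAN = {
    4: np.array([[0, -1, 0], [-1, 4, -1], [0, -1, 0]], dtype=np.int64),
    8: np.array([[-1, -1, -1], [-1, 8, -1], [-1, -1, -1]], dtype=np.int64),
}


def phase_boundary(
    mask: BinaryMask, method: str = "internal_gradient", connectivity: int = 4
) -> BoundaryMask:
    """One-pixel boundary of a binary phase; always a subset of the mask.

    ``internal_gradient`` is the mask minus its erosion by the 3x3 square,
    with outside-the-image treated as background (frame-touching regions get
    frame-edge boundary pixels).  ``laplacian`` marks foreground pixels with
    a nonzero response of the 4- or 8-connectivity Laplacian kernel.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2 or mask.size == 0:
        raise ParameterError("mask must be a non-empty 2-D boolean raster")
    if method == "internal_gradient":
        eroded = ndimage.binary_erosion(mask, structure=SQUARE_3X3, border_value=0)
        return mask & ~eroded
    if method == "laplacian":
        if connectivity not in _LAPLACIAN:
            raise ParameterError(f"Laplacian connectivity must be 4 or 8, got {connectivity}")
        resp = ndimage.convolve(
            mask.astype(np.int64), _LAPLACIAN[connectivity], mode="constant", cval=0
        )
        return (resp != 0) & mask
    raise ParameterError(
        f"unknown boundary method {method!r}; use 'internal_gradient' or 'laplacian'"
    )
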