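"""Image, mask and configuration readers/writers.

Greyscale input is accepted as single-channel 8- or 16-bit TIFF or PNG.
Binary masks are written as 8-bit images (foreground 255); label images as
16-bit TIFF/PNG.  All formats are lossless.

Coordinate convention, stated once: rasters are row-major with the origin
at the top-left; CSV output reports (x, y) = (column, row), 0-based.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .exceptions import ImageFormatError, ParameterError
from .gradient_ops import GreyImage

__all__ = ["read_grey_image", "write_grey_image", "write_mask", "read_mask", "RunConfig"]

_TIFF = {".tif", ".tiff"}
_PNG = {".png"}


def _read_raw(path: Path) -> np.ndarray:
    if path.suffix.lower() in _TIFF:
        return tifffile.imread(path)
    if path.suffix.lower() in _PNG:
        return iio.imread(path)
    raise ImageFormatError(
        f"unsupported extension {path.suffix!r}; use .tif/.tiff or .png"
    )


def read_grey_image(path) -> GreyImage:
    """Read a single-channel 8/16-bit TIFF or PNG as a :class:`GreyImage`."""
    path = Path(path)
    if not path.exists():
        raise ImageFormatError(f"no such file: {path}")
    arr = _read_raw(path)
    if arr.ndim != 2:
        raise ImageFormatError(
            f"{path.name} has shape {arr.shape}; convert multi-channel images "
            "to single-channel greyscale first"
        )
    if arr.dtype == np.uint8:
        return GreyImage(arr, 8)
    if arr.dtype == np.uint16:
        return GreyImage(arr, 16)
    raise ImageFormatError(
        f"{path.name} has dtype {arr.dtype}; only uint8/uint16 are supported "
        "(rescale floating-point data explicitly)"
    )


def _write_raw(arr: np.ndarray, path: Path) -> None:
    if path.suffix.lower() in _TIFF:
        tifffile.imwrite(path, arr)
    elif path.suffix.lower() in _PNG:
        iio.imwrite(path, arr)
    else:
        raise ImageFormatError(
            f"unsupported extension {path.suffix!r}; use .tif/.tiff or .png"
        )


def write_grey_image(image: GreyImage, path) -> None:
    """Write a GreyImage losslessly (dtype preserved)."""
    _write_raw(image.pixels, Path(path))


def write_mask(mask: np.ndarray, path) -> None:
    """Write a binary mask (as 0/255 uint8) or a label image (uint16)."""
    path = Path(path)
    mask = np.asarray(mask)
    if mask.dtype == bool:
        _write_raw(mask.astype(np.uint8) * 255, path)
        return
    if not np.issubdtype(mask.dtype, np.integer):
        raise ImageFormatError(f"mask dtype {mask.dtype} is neither bool nor integer")
    if mask.min(initial=0) < 0 or mask.max(initial=0) > 65535:
        raise ImageFormatError("label images must fit in uint16 (0..65535 labels)")
    _write_raw(mask.astype(np.uint16), path)


def read_mask(path, as_labels: bool = False) -> np.ndarray:
    """Read a mask file: boolean (>0) by default, or raw integer labels."""
    arr = _read_raw(Path(path))
    if arr.ndim != 2:
        raise ImageFormatError(f"mask {path} is not single-channel")
    return arr.astype(np.int64) if as_labels else arr > 0


@dataclasses.dataclass
class RunConfig:
    """All CLI-exposed parameters with their defaults.

    Serialises to a plain-text ``key = value`` file and back without loss.
    """

    polarity: str = "dark_objects"
    gradient: str = "beucher"
    statistic: str = "average"
    mode: str = "cumulative"
    min_circularity: float = 0.5
    min_area: float = 250
    max_area: float = 3000
    gauss_radius: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.polarity not in ("dark_objects", "bright_objects"):
            raise ParameterError(f"bad polarity {self.polarity!r}")
        if self.gradient not in ("beucher", "sobel"):
            raise ParameterError(f"bad gradient {self.gradient!r}")
        if self.statistic not in ("total", "average"):
            raise ParameterError(f"bad statistic {self.statistic!r}")
        if self.mode not in ("stack", "cumulative"):
            raise ParameterError(f"bad mode {self.mode!r}")
        if not 0 <= self.min_circularity <= 1:
            raise ParameterError("min_circularity outside [0, 1]")
        if self.gauss_radius < 0:
            raise ParameterError("gauss_radius must be >= 0")

    def to_file(self, path) -> None:
        lines = []
        for f in dataclasses.fields(self):
            value = getattr(self, f.name)
            if isinstance(value, float) and math.isinf(value):
                value = "inf"
            lines.append(f"{f.name} = {value}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        kwargs = {}
        types = {f.name: f.type for f in dataclasses.fields(cls)}
        casts = {"str": str, "float": float, "int": int}
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ParameterError(f"bad config line: {line!r}")
            key, _, raw = line.partition("=")
            key = key.strip()
            if key not in types:
                raise ParameterError(f"unknown config key {key!r}")
            kwargs[key] = casts[types[key]](raw.strip())
        return cls(**kwargs)
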