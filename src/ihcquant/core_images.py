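"""Image data model, file I/O, region-of-interest handling and scale bookkeeping.

Images are plain numpy arrays throughout the package:

* RGB raster: ``uint8`` array of shape ``(height, width, 3)``.
* Grayscale / component / mask images: ``uint8`` array of shape
  ``(height, width)``; binary masks use the values {0, 255}.

Coordinates are 0-based.  Pixel ``(x, y)`` occupies the half-open square
``[x, x+1) x [y, y+1)`` and its center is ``(x + 0.5, y + 0.5)``; a pixel
belongs to a region of interest when its center lies inside the polygon.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import imageio.v3 as iio
import shapely

from .errors import ImageFormatError, ValidationError

#: File extensions accepted by :func:`read_image`.  JPEG2000 (``.jp2``) is
#: optional: it is attempted through imageio and reported (not fatal) when the
#: installed backends cannot decode it.
SUPPORTED_EXTENSIONS = {
    ".png", ".jpg", ".jpeg", ".tif", ".tiff", ".bmp", ".jp2", ".j2k",
}


def _to_uint8_rgb(arr: np.ndarray, path: Path) -> np.ndarray:
    """Coerce a decoded array to 8-bit RGB.

    Grayscale sources are replicated across channels; alpha channels are
    dropped; 16-bit sources are rescaled to 8-bit by max-value normalization.
    """
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    elif arr.ndim == 3 and arr.shape[2] == 1:
        arr = np.repeat(arr, 3, axis=2)
    elif arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ImageFormatError(f"unsupported image layout {arr.shape} in {path}")
    if arr.dtype == np.uint8:
        return arr
    arr = arr.astype(np.float64)
    maxval = arr.max()
    if maxval <= 0:
        return np.zeros(arr.shape, dtype=np.uint8)
    return np.clip(np.round(arr / maxval * 255.0), 0, 255).astype(np.uint8)


def read_image(path: str | Path) -> np.ndarray:
    """Read an image file as an 8-bit RGB array of shape (H, W, 3).

    Supported formats: JPEG, TIFF, BMP, PNG and (backend permitting) JPEG2000.

    Raises
    ------
    ImageFormatError
        If the file does not exist, has an unsupported extension, or cannot
        be decoded (e.g. a truncated JPEG).
    """
    path = Path(path)
    if not path.exists():
        raise ImageFormatError(f"no such image file: {path}")
    if path.suffix.lower() not in SUPPORTED_EXTENSIONS:
        raise ImageFormatError(
            f"unsupported image format {path.suffix!r} for {path}"
        )
    try:
        arr = np.asarray(iio.imread(path))
    except Exception as exc:  # decoding errors vary by backend
        raise ImageFormatError(f"cannot decode image {path}: {exc}") from exc
    return _to_uint8_rgb(arr, path)


def write_image(path: str | Path, image: np.ndarray, *, jpeg_quality: int = 90) -> None:
    """Write an 8-bit image (RGB or grayscale) to ``path``.

    The format is chosen from the file extension.  ``jpeg_quality`` applies
    only when writing JPEG.
    """
    path = Path(path)
    image = np.asarray(image, dtype=np.uint8)
    if path.suffix.lower() in {".jpg", ".jpeg"}:
        iio.imwrite(path, image, quality=jpeg_quality)
    else:
        iio.imwrite(path, image)


@dataclass(frozen=True)
class ImageScale:
    """Spatial sampling of the image in pixels per micrometer.

    ``estimated`` marks scales derived from the scale-finder regression
    rather than from microscope optics.
    """

    pixels_per_um: float
    estimated: bool = False

    def __post_init__(self) -> None:
        if not self.pixels_per_um > 0:
            raise ValidationError("pixels_per_um must be positive")

    def area_px_to_um2(self, area_px: float) -> float:
        return area_px / self.pixels_per_um**2

    def um_to_px(self, length_um: float) -> float:
        return length_um * self.pixels_per_um


@dataclass(frozen=True)
class RegionOfInterest:
    """A simple (non-self-intersecting) polygon in pixel coordinates.

    Vertices are ``(x, y)`` pairs; the polygon is closed implicitly.
    """

    vertices: tuple[tuple[float, float], ...]
    _polygon: shapely.Polygon = field(init=False, repr=False, compare=False)

    def __init__(self, vertices) -> None:
        verts = tuple((float(x), float(y)) for x, y in vertices)
        if len(verts) < 3:
            raise ValidationError("a region of interest needs at least 3 vertices")
        poly = shapely.Polygon(verts)
        if not poly.is_valid or poly.area == 0:
            raise ValidationError("region-of-interest polygon is degenerate or self-intersecting")
        object.__setattr__(self, "vertices", verts)
        object.__setattr__(self, "_polygon", poly)

    @property
    def polygon(self) -> shapely.Polygon:
        return self._polygon

    @classmethod
    def from_file(cls, path: str | Path) -> "RegionOfInterest":
        """Load a polygon from a JSON file containing a list of [x, y] pairs."""
        with open(path) as fh:
            data = json.load(fh)
        return cls(data)

    @classmethod
    def rectangle(cls, x0: float, y0: float, x1: float, y1: float) -> "RegionOfInterest":
        return cls([(x0, y0), (x1, y0), (x1, y1), (x0, y1)])


def mask_from_roi(roi: RegionOfInterest, width: int, height: int) -> np.ndarray:
    """Rasterize a region of interest to a binary 0/255 mask of (height, width).

    A pixel is set when its center ``(x + 0.5, y + 0.5)`` lies strictly
    inside the polygon.
    """
    xs, ys = np.meshgrid(
        np.arange(width, dtype=np.float64) + 0.5,
        np.arange(height, dtype=np.float64) + 0.5,
    )
    inside = shapely.contains_xy(roi.polygon, xs.ravel(), ys.ravel())
    return np.where(inside.reshape(height, width), 255, 0).astype(np.uint8)


def validate_rgb(image: np.ndarray) -> np.ndarray:
    """Check that ``image`` is a uint8 (H, W, 3) raster and return it."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3 or image.dtype != np.uint8:
        raise ValidationError(
            f"expected uint8 RGB array of shape (H, W, 3), got {image.dtype} {image.shape}"
        )
    if image.shape[0] < 1 or image.shape[1] < 1:
        raise ValidationError("image must be at least 1x1")
    return image
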