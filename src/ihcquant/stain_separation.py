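"""Color deconvolution of H-DAB stained brightfield images.

Stain amounts add linearly in optical-density (OD) space (Beer-Lambert):
``OD_c = -log10(I_c / 255)`` per channel.  Each stain has a characteristic
unit-length OD absorption vector; a pixel's OD triplet is the concentration-
weighted sum of the stain vectors.  Inverting that 3x3 linear system recovers
per-stain concentration images, which are re-exported on the familiar 8-bit
transmittance scale (255 = no stain, darker = more stain).

The default hematoxylin and DAB vectors are the widely used values from the
reference color-deconvolution implementation; the third (residual) vector is
the normalized cross product of the two and its channel is discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_images import validate_rgb
from .errors import ValidationError

_MAX_CONDITION = 1e6


@dataclass(frozen=True)
class StainVector:
    """Unit-length optical-density absorption vector of one stain."""

    od_red: float
    od_green: float
    od_blue: float

    def __post_init__(self) -> None:
        v = self.as_array()
        if np.all(v == 0):
            raise ValidationError("stain vector cannot be all zero")
        if abs(np.linalg.norm(v) - 1.0) > 1e-6:
            raise ValidationError("stain vector must have unit Euclidean norm")

    def as_array(self) -> np.ndarray:
        return np.array([self.od_red, self.od_green, self.od_blue], dtype=np.float64)

    @classmethod
    def normalized(cls, od_red: float, od_green: float, od_blue: float) -> "StainVector":
        v = np.array([od_red, od_green, od_blue], dtype=np.float64)
        norm = np.linalg.norm(v)
        if norm == 0:
            raise ValidationError("stain vector cannot be all zero")
        v = v / norm
        return cls(*v)


@dataclass(frozen=True)
class StainMatrix:
    """Stain basis: hematoxylin, DAB and a residual third vector.

    The residual defaults to the normalized cross product of the two stain
    vectors, completing the basis for pixels whose color is not exactly a
    mix of the two stains.
    """

    hematoxylin: StainVector
    dab: StainVector
    residual: StainVector = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.residual is None:
            cross = np.cross(self.hematoxylin.as_array(), self.dab.as_array())
            norm = np.linalg.norm(cross)
            if norm < 1e-12:
                raise ValidationError("hematoxylin and DAB vectors are collinear")
            object.__setattr__(self, "residual", StainVector(*(cross / norm)))
        if np.linalg.cond(self.as_matrix()) >= _MAX_CONDITION:
            raise ValidationError("stain matrix is singular or ill-conditioned")

    def as_matrix(self) -> np.ndarray:
        """Rows are the stain vectors (hematoxylin, DAB, residual)."""
        return np.stack(
            [self.hematoxylin.as_array(), self.dab.as_array(), self.residual.as_array()]
        )


def default_hdab_matrix() -> StainMatrix:
    """The standard H-DAB stain basis (user-overridable via configuration)."""
    return StainMatrix(
        hematoxylin=StainVector.normalized(0.650, 0.704, 0.286),
        dab=StainVector.normalized(0.269, 0.568, 0.778),
    )


@dataclass(frozen=True)
class ComponentImage:
    """Single-stain 8-bit transmittance image (255 = no stain)."""

    gray: np.ndarray
    stain_name: str

    def __post_init__(self) -> None:
        if self.gray.dtype != np.uint8 or self.gray.ndim != 2:
            raise ValidationError("component image must be a 2-D uint8 array")


def rgb_to_od(intensity: np.ndarray | float) -> np.ndarray | float:
    """Convert 8-bit intensity to optical density: ``-log10(max(I, 1) / 255)``.

    Intensities are floored at 1 so saturated-dark pixels keep a finite OD.
    """
    i = np.maximum(np.asarray(intensity, dtype=np.float64), 1.0)
    return -np.log10(i / 255.0)


def od_to_intensity(od: np.ndarray | float) -> np.ndarray:
    """Map optical density back to the 8-bit transmittance scale."""
    out = np.round(255.0 * np.power(10.0, -np.asarray(od, dtype=np.float64)))
    return np.clip(out, 0, 255).astype(np.uint8)


def separate_concentrations(image: np.ndarray, stains: StainMatrix | None = None) -> np.ndarray:
    """Recover per-pixel stain concentrations (OD units) as an (H, W, 3) array.

    The channels are (hematoxylin, DAB, residual).  Negative concentrations
    are clamped to 0: a pixel cannot contain a negative amount of stain.
    """
    image = validate_rgb(image)
    if stains is None:
        stains = default_hdab_matrix()
    od = rgb_to_od(image)  # (H, W, 3)
    inverse = np.linalg.inv(stains.as_matrix())
    conc = od @ inverse
    return np.maximum(conc, 0.0)


def separate_stains(
    image: np.ndarray, stains: StainMatrix | None = None
) -> tuple[ComponentImage, ComponentImage]:
    """Deconvolve an RGB image into hematoxylin and DAB component images.

    Returns ``(hematoxylin, dab)`` 8-bit transmittance images; the residual
    channel is discarded.
    """
    conc = separate_concentrations(image, stains)
    h = ComponentImage(od_to_intensity(conc[:, :, 0]), "hematoxylin")
    dab = ComponentImage(od_to_intensity(conc[:, :, 1]), "dab")
    return h, dab
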