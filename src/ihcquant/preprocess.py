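"""Illumination and color correction.

Two alternatives are offered, mirroring typical brightfield practice:

* flat-field ("blankfield") correction, dividing the image by a photograph of
  empty slide background taken with the same optics and exposure, rescaled so
  that blank background maps to white (255); and
* rolling-ball background subtraction as a fallback when no blankfield image
  is available, run per channel in light-background mode.

The blankfield route is preferred: downstream optical-density conversion
assumes incident intensity I0 = 255, which the division guarantees.
"""

from __future__ import annotations

import numpy as np
from skimage import restoration

from .core_images import validate_rgb
from .errors import ValidationError


def correct_blankfield(image: np.ndarray, blankfield: np.ndarray) -> np.ndarray:
    """Flat-field correct ``image`` with a same-session blankfield image.

    Per channel c and pixel p::

        out(p, c) = clamp(round(in(p, c) / blank(p, c) * 255), 0, 255)

    Blankfield pixels equal to 0 are floored to 1 so dead pixels cannot blow
    up the division.  An image identical to its blankfield maps to uniform
    white (255).

    Raises
    ------
    ValidationError
        If the two images do not share dimensions.
    """
    image = validate_rgb(image)
    blankfield = validate_rgb(blankfield)
    if image.shape != blankfield.shape:
        raise ValidationError(
            f"blankfield shape {blankfield.shape} does not match image shape {image.shape}"
        )
    blank = np.maximum(blankfield.astype(np.float64), 1.0)
    out = np.round(image.astype(np.float64) / blank * 255.0)
    return np.clip(out, 0, 255).astype(np.uint8)


def subtract_background_rolling_ball(image: np.ndarray, radius_px: float = 50.0) -> np.ndarray:
    """Remove slowly varying background with the rolling-ball algorithm.

    Brightfield images have a light background, so each channel is inverted,
    the background surface is estimated by rolling a ball of the given radius
    under the inverted intensity surface, subtracted, and the result is
    re-inverted.  A uniform image (pure background) maps to uniform 255.

    ``radius_px`` should exceed the radius of the largest foreground object;
    smaller radii absorb objects into the background estimate.
    """
    image = validate_rgb(image)
    if radius_px < 1:
        raise ValidationError("rolling-ball radius must be >= 1 px")
    out = np.empty_like(image)
    for c in range(3):
        inverted = (255 - image[:, :, c]).astype(np.float64)
        background = restoration.rolling_ball(inverted, radius=radius_px)
        residual = np.clip(inverted - background, 0, 255)
        out[:, :, c] = (255 - np.round(residual)).astype(np.uint8)
    return out
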