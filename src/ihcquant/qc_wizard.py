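"""Camera quality-control checks and image-scale estimation.

Two acquisition-time checks guard the analysis:

* brightness: the mean gray intensity of the blankfield image should fall in
  [200, 250] (0 = black); dimmer means underexposure, brighter risks channel
  clipping; and
* contrast: after an IsoData split of the gray image into hematoxylin-stained
  foreground and background, the foreground mean should be 50-80% of the
  background mean.  Ratios in (80, 85] are labeled borderline; above 85 the
  contrast is too low for reliable nuclear segmentation, below 50 too high.

"Mean gray intensity" uses the unweighted channel mean (R + G + B) / 3.

The scale finder estimates pixels-per-micrometer from the measured mean
diameter (in pixels) of hematoxylin-stained nuclei, via a first-degree
polynomial fitted over known microscope setups.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .core_images import ImageScale, validate_rgb
from .errors import ValidationError
from .segmentation import isodata_threshold

BRIGHTNESS_MIN = 200.0
BRIGHTNESS_MAX = 250.0
CONTRAST_OPTIMAL_LOW = 50.0
CONTRAST_OPTIMAL_HIGH = 80.0
CONTRAST_BORDERLINE_HIGH = 85.0


def _mean_gray(image: np.ndarray) -> np.ndarray:
    """Unweighted luminance (R + G + B) / 3 as float."""
    image = validate_rgb(image)
    return image.astype(np.float64).mean(axis=2)


def check_brightness(blankfield: np.ndarray) -> tuple[float, str]:
    """Classify blankfield exposure from its mean gray intensity.

    Returns ``(mean, status)`` with status one of ``underexposed``,
    ``optimal`` (mean in [200, 250]) or ``overexposed``.
    """
    mean = float(_mean_gray(blankfield).mean())
    if mean < BRIGHTNESS_MIN:
        status = "underexposed"
    elif mean > BRIGHTNESS_MAX:
        status = "overexposed"
    else:
        status = "optimal"
    return mean, status


def check_contrast(cell_image: np.ndarray) -> tuple[float, str]:
    """Foreground/background contrast analysis of a hematoxylin-stained field.

    The gray image is split with an IsoData threshold; pixels at or below the
    threshold are the stained foreground.  Returns ``(ratio_pct, status)``
    where ``ratio_pct = 100 * mean(foreground) / mean(background)`` and the
    status is ``optimal`` (50-80), ``borderline`` (80-85], ``too_low``
    (> 85) or ``too_high`` (< 50).
    """
    gray_f = _mean_gray(cell_image)
    gray = np.clip(np.round(gray_f), 0, 255).astype(np.uint8)
    hist = np.bincount(gray.ravel(), minlength=256)
    t = isodata_threshold(hist)  # degenerate single-class images raise here
    foreground = gray_f[gray <= t]
    background = gray_f[gray > t]
    if foreground.size == 0 or background.size == 0:
        raise ValidationError("contrast check needs both stained and background pixels")
    ratio = 100.0 * float(foreground.mean()) / float(background.mean())
    if ratio < CONTRAST_OPTIMAL_LOW:
        status = "too_high"
    elif ratio <= CONTRAST_OPTIMAL_HIGH:
        status = "optimal"
    elif ratio <= CONTRAST_BORDERLINE_HIGH:
        status = "borderline"
    else:
        status = "too_low"
    return ratio, status


@dataclass
class WizardReport:
    """Combined camera-adjustment report."""

    blankfield_mean: float
    brightness_status: str
    contrast_ratio_pct: float | None = None
    contrast_status: str | None = None


def camera_wizard(
    blankfield: np.ndarray, cell_image: np.ndarray | None = None
) -> WizardReport:
    """Run the brightness check and, when a cell image is given, the contrast check."""
    mean, b_status = check_brightness(blankfield)
    report = WizardReport(blankfield_mean=mean, brightness_status=b_status)
    if cell_image is not None:
        ratio, c_status = check_contrast(cell_image)
        report.contrast_ratio_pct = ratio
        report.contrast_status = c_status
    return report


@dataclass(frozen=True)
class ScaleModel:
    """Line mapping mean nucleus diameter (px) to image scale (px/um).

    ``diameter_range`` documents the diameters the model was fitted over;
    estimates outside it carry a warning flag.
    """

    slope: float
    intercept: float
    diameter_range: tuple[float, float] = (5.0, 40.0)

    def predict(self, diameter_px: float) -> float:
        return self.slope * diameter_px + self.intercept


def fit_scale_model(diameters_px, scales_px_per_um) -> ScaleModel:
    """Least-squares first-degree polynomial of scale on nucleus diameter."""
    d = np.asarray(diameters_px, dtype=np.float64)
    s = np.asarray(scales_px_per_um, dtype=np.float64)
    if d.shape != s.shape or d.ndim != 1 or d.size < 2 or np.unique(d).size < 2:
        raise ValidationError("scale model needs >= 2 distinct diameter measurements")
    slope, intercept = np.polyfit(d, s, 1)
    model = ScaleModel(
        slope=float(slope),
        intercept=float(intercept),
        diameter_range=(float(d.min()), float(d.max())),
    )
    lo, hi = model.diameter_range
    if model.predict(lo) <= 0 or model.predict(hi) <= 0:
        raise ValidationError("fitted scale model predicts non-positive scales in range")
    return model


def default_scale_model() -> ScaleModel:
    """Scale model fitted to the bundled synthetic diameter/scale table.

    The table pairs the mean segmented nucleus diameter of synthetic scenes
    with the scale they were rendered at; users with real measurements
    should refit with :func:`fit_scale_model`.
    """
    table = resources.files("ihcquant").joinpath("data/scale_table.csv")
    diameters, scales = [], []
    with table.open() as fh:
        for row in csv.DictReader(fh):
            diameters.append(float(row["mean_nucleus_diameter_px"]))
            scales.append(float(row["pixels_per_um"]))
    return fit_scale_model(diameters, scales)


def estimate_scale(
    mean_nucleus_diameter_px: float, model: ScaleModel | None = None
) -> tuple[ImageScale, list[str]]:
    """Estimate pixels-per-micrometer from a measured mean nucleus diameter.

    Returns the scale (flagged as an estimate) plus any warnings, e.g. a
    diameter outside the model's documented range.
    """
    if mean_nucleus_diameter_px <= 0:
        raise ValidationError("nucleus diameter must be positive")
    if model is None:
        model = default_scale_model()
    warnings_list = []
    lo, hi = model.diameter_range
    if not lo <= mean_nucleus_diameter_px <= hi:
        warnings_list.append(
            f"diameter {mean_nucleus_diameter_px:.1f} px outside fitted range [{lo:.1f}, {hi:.1f}]"
        )
    value = model.predict(mean_nucleus_diameter_px)
    if value <= 0:
        raise ValidationError("scale model predicts a non-positive scale for this diameter")
    return ImageScale(pixels_per_um=value, estimated=True), warnings_list
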