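"""End-to-end analysis: corrected image -> stain components -> nucleus masks
-> labeling index -> rendered result.

This is the library surface the command line wraps.  One call to
:func:`analyze_image` executes the whole chain: read/accept an RGB field,
blankfield correction (or rolling-ball background subtraction when no
blankfield is available), H-DAB color deconvolution, per-component mean
filtering, IsoData thresholding with optional per-component adjustments,
median smoothing, watershed splitting, size filtering (both components) and
roundness filtering (hematoxylin only), the area-ratio labeling index, the
optional cubic calibration, and the result card rendering.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace

import numpy as np

from . import reporting
from .core_images import ImageScale, validate_rgb
from .preprocess import correct_blankfield, subtract_background_rolling_ball
from .quantification import (
    CalibrationPolynomial,
    LabelingIndexResult,
    SampleResult,
    aggregate_images,
    apply_calibration,
    labeling_index,
)
from .segmentation import segment_component
from .stain_separation import StainMatrix, default_hdab_matrix, separate_stains

#: Reference scale (px/um) at which the pixel-unit defaults below are stated;
#: radii scale linearly with pixels_per_um.  4.55 px/um is the recommended
#: acquisition setup: a 4.40 um camera pixel behind a 20x objective and 1x
#: phototube (0.22 um per pixel in the specimen plane).
REFERENCE_PIXELS_PER_UM = 4.55


@dataclass(frozen=True)
class AnalysisConfig:
    """All tunable parameters of one analysis run.

    Pixel-unit parameters (filter radii, rolling-ball radius) are stated at
    the 4.55 px/um reference scale and rescaled to the actual image scale,
    so behavior is invariant across microscope setups.
    """

    scale: ImageScale = field(default_factory=lambda: ImageScale(REFERENCE_PIXELS_PER_UM))
    h_adjust: int = 0
    dab_adjust: int = 0
    mean_radius_px: int = 2
    median_radius_px: int = 2
    min_area_um2: float = 10.0
    min_circularity: float = 0.35
    min_nucleus_diameter_um: float = 4.0
    rolling_ball_radius_px: float = 50.0
    stains: StainMatrix = field(default_factory=default_hdab_matrix)
    calibration: CalibrationPolynomial | None = None
    render_mode: str = "fill"

    def scaled(self) -> "AnalysisConfig":
        """Rescale pixel-unit parameters from the reference scale to ``scale``."""
        factor = self.scale.pixels_per_um / REFERENCE_PIXELS_PER_UM
        return replace(
            self,
            mean_radius_px=max(1, int(round(self.mean_radius_px * factor))),
            median_radius_px=max(1, int(round(self.median_radius_px * factor))),
            rolling_ball_radius_px=max(1.0, self.rolling_ball_radius_px * factor),
        )


@dataclass
class AnalysisRecord:
    """Machine-readable outcome of one image analysis."""

    image_id: str
    date: str
    result: LabelingIndexResult
    dab_labels: np.ndarray
    h_labels: np.ndarray
    corrected_image: np.ndarray
    pseudo_colored: np.ndarray
    card: np.ndarray
    warnings: list[str]

    def csv_row(self) -> dict:
        r = self.result
        return {
            "image_id": self.image_id,
            "date": self.date,
            "dab_area_px": r.dab_area_px,
            "h_area_px": r.h_area_px,
            "raw_index_pct": "" if r.undefined else f"{r.raw_index:.4f}",
            "corrected_index_pct": "" if r.undefined else f"{r.corrected_index:.4f}",
            "n_warnings": len(self.warnings),
        }


def analyze_image(
    image: np.ndarray,
    config: AnalysisConfig,
    *,
    blankfield: np.ndarray | None = None,
    roi_mask: np.ndarray | None = None,
    image_id: str = "image",
    date: str | None = None,
) -> AnalysisRecord:
    """Run the full analysis chain on one RGB field."""
    image = validate_rgb(image)
    cfg = config.scaled()
    warnings_list: list[str] = []
    if date is None:
        date = _dt.date.today().isoformat()

    if blankfield is not None:
        corrected = correct_blankfield(image, blankfield)
    else:
        warnings_list.append("no blankfield image; rolling-ball background subtraction used")
        corrected = subtract_background_rolling_ball(image, cfg.rolling_ball_radius_px)

    h_comp, dab_comp = separate_stains(corrected, cfg.stains)
    common = dict(
        mean_radius_px=cfg.mean_radius_px,
        median_radius_px=cfg.median_radius_px,
        min_area_um2=cfg.min_area_um2,
        min_nucleus_diameter_um=cfg.min_nucleus_diameter_um,
    )
    h_labels = segment_component(
        h_comp, cfg.scale, threshold_offset=cfg.h_adjust,
        min_circularity=cfg.min_circularity, **common,
    )
    dab_labels = segment_component(
        dab_comp, cfg.scale, threshold_offset=cfg.dab_adjust,
        min_circularity=None, **common,
    )
    dab_mask = np.where(dab_labels > 0, 255, 0).astype(np.uint8)
    h_mask = np.where(h_labels > 0, 255, 0).astype(np.uint8)
    result = labeling_index(dab_mask, h_mask, roi_mask=roi_mask, image_id=image_id)
    if result.undefined:
        warnings_list.extend(result.warnings)
    elif cfg.calibration is not None:
        result.corrected_index = apply_calibration(result.raw_index, cfg.calibration)

    pseudo = reporting.render_pseudocolor(
        dab_labels, h_labels, mode=cfg.render_mode, original=corrected
    )
    card = reporting.render_result_card(
        original=image,
        pseudo_colored=pseudo,
        labeling_index_pct=result.corrected_index,
        id_string=image_id,
        analysis_date=date,
    )
    return AnalysisRecord(
        image_id=image_id,
        date=date,
        result=result,
        dab_labels=dab_labels,
        h_labels=h_labels,
        corrected_image=corrected,
        pseudo_colored=pseudo,
        card=card,
        warnings=warnings_list,
    )


#: At least this many fields per specimen are needed for a stable mean index.
RECOMMENDED_IMAGES_PER_SAMPLE = 3


def analyze_sample(
    images,
    config: AnalysisConfig,
    *,
    blankfield: np.ndarray | None = None,
    image_ids=None,
    date: str | None = None,
) -> tuple[SampleResult, list[AnalysisRecord], np.ndarray]:
    """Analyze every field of one specimen and average the indexes.

    Returns the aggregated result, the per-image records, and a montage of
    all result cards with the sample mean in its header.  A warning is
    attached when fewer than three images are provided.
    """
    images = list(images)
    if image_ids is None:
        image_ids = [f"image_{i + 1}" for i in range(len(images))]
    records = [
        analyze_image(
            img, config, blankfield=blankfield, image_id=iid, date=date
        )
        for img, iid in zip(images, image_ids)
    ]
    sample = aggregate_images([r.result for r in records])
    if len(images) < RECOMMENDED_IMAGES_PER_SAMPLE:
        for rec in records:
            rec.warnings.append(
                f"only {len(images)} image(s) provided; averaging at least "
                f"{RECOMMENDED_IMAGES_PER_SAMPLE} is recommended"
            )
    montage = reporting.render_montage(
        [r.card for r in records], mean_index_pct=sample.mean_index
    )
    return sample, records, montage
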