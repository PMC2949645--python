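"""Nuclear segmentation of a stain component image.

The chain is: mean filter -> IsoData threshold (+ per-component adjustment)
-> median smoothing -> watershed splitting of touching nuclei -> size filter
-> (hematoxylin only) roundness filter.  Component images encode stain as
darkness, so the stained class is "value <= threshold".
"""

from __future__ import annotations

from dataclasses import dataclass
import math

import numpy as np
from scipy import ndimage as ndi
from skimage import measure, morphology, segmentation as sk_segmentation

from .core_images import ImageScale
from .errors import DegenerateHistogramError, ValidationError
from .stain_separation import ComponentImage

#: 8-connectivity structure for particle labeling.
_STRUCTURE_8 = np.ones((3, 3), dtype=bool)


def mean_filter(gray: np.ndarray, radius_px: int) -> np.ndarray:
    """Smooth with the rounded mean of a disk neighborhood.

    Edges are handled by nearest-border replication.  A uniform image is
    unchanged.
    """
    if radius_px < 1:
        raise ValidationError("mean filter radius must be >= 1")
    gray = np.asarray(gray, dtype=np.uint8)
    footprint = morphology.disk(radius_px).astype(np.float64)
    kernel = footprint / footprint.sum()
    out = ndi.convolve(gray.astype(np.float64), kernel, mode="nearest")
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


def isodata_threshold(histogram: np.ndarray) -> int:
    """IsoData (iterative intermeans) threshold of a 256-bin histogram.

    Starting from the mid-range of the occupied bins, iterate

        t <- round((mean of values <= t + mean of values > t) / 2)

    until the threshold is stable, and return the fixed point.  Values at or
    below the threshold form the "stained" (dark) class of a component image.

    Raises
    ------
    DegenerateHistogramError
        If fewer than two bins are occupied, in which case no two-class
        split exists.
    """
    hist = np.asarray(histogram, dtype=np.float64)
    if hist.shape != (256,):
        raise ValidationError("histogram must have exactly 256 bins")
    nonzero = np.nonzero(hist)[0]
    if nonzero.size < 2:
        raise DegenerateHistogramError("histogram has all mass in a single bin")
    values = np.arange(256, dtype=np.float64)
    lo, hi = int(nonzero[0]), int(nonzero[-1])
    t = int(round((lo + hi) / 2.0))
    seen = set()
    while t not in seen:
        seen.add(t)
        below = hist[: t + 1]
        above = hist[t + 1 :]
        mean_below = (values[: t + 1] * below).sum() / below.sum() if below.sum() else float(t)
        mean_above = (
            (values[t + 1 :] * above).sum() / above.sum() if above.sum() else float(t)
        )
        t = int(round((mean_below + mean_above) / 2.0))
    return t


#: A component whose stained class is brighter than this fraction of the
#: unstained class carries no separable stain (same 85% breakpoint at which
#: the camera wizard declares contrast too low) and yields an empty mask.
BLANK_CONTRAST_RATIO = 0.85


def binarize_component(component: ComponentImage, offset: int = 0) -> np.ndarray:
    """Threshold a component image into a 0/255 stained mask.

    The IsoData threshold of the component histogram is shifted by the
    per-component ``offset`` (clamped to [0, 255]); pixels at or below the
    shifted threshold are stained.  A blank component — exactly uniform 255,
    or one whose IsoData "stained" class is merely the bright tail of the
    background noise (stained-class mean above 85% of the unstained-class
    mean) — yields an empty mask rather than an error: an unstained field is
    a legitimate input, not a failure.
    """
    if abs(offset) > 50:
        raise ValidationError("threshold adjustment must be within [-50, 50]")
    gray = component.gray
    if gray.min() == gray.max():
        if gray.flat[0] == 255:
            return np.zeros(gray.shape, dtype=np.uint8)
        raise DegenerateHistogramError("component image is uniformly non-white")
    hist = np.bincount(gray.ravel(), minlength=256)
    t = int(np.clip(isodata_threshold(hist) + offset, 0, 255))
    stained = gray <= t
    if stained.any() and not stained.all():
        stained_mean = float(gray[stained].mean())
        background_mean = float(gray[~stained].mean())
        if stained_mean > BLANK_CONTRAST_RATIO * background_mean:
            return np.zeros(gray.shape, dtype=np.uint8)
    return np.where(stained, 255, 0).astype(np.uint8)


def median_filter(mask: np.ndarray, radius_px: int) -> np.ndarray:
    """Majority vote over a disk neighborhood; smooths a binary mask."""
    if radius_px < 1:
        raise ValidationError("median filter radius must be >= 1")
    mask = np.asarray(mask, dtype=np.uint8)
    footprint = morphology.disk(radius_px)
    out = ndi.median_filter(mask, footprint=footprint, mode="nearest")
    return np.where(out > 0, 255, 0).astype(np.uint8)


def watershed_split(mask: np.ndarray, seed_merge_distance_px: float = 2.0) -> np.ndarray:
    """Split touching particles along ridges of the negated distance map.

    Seeds are the connected regional maxima of the Euclidean distance
    transform (a flat ridge, e.g. along an elongated particle, is one seed,
    not many); maxima closer than ``seed_merge_distance_px`` are merged to
    prevent oversegmentation of single convex nuclei.  One-pixel watershed
    lines separate touching particles; the returned label map uses
    consecutive positive integers with 8-connected particles.
    """
    binary = np.asarray(mask) > 0
    if not binary.any():
        return np.zeros(binary.shape, dtype=np.int32)
    distance = ndi.distance_transform_edt(binary)
    tolerance = max(1, int(round(seed_merge_distance_px)))
    # smooth the distance map so boundary roughness does not spawn seeds,
    # then drop maxima whose prominence is below half the merge tolerance
    # (ridge undulation along one particle, not a second nucleus)
    distance = ndi.gaussian_filter(distance, sigma=max(1.0, tolerance / 2.0))
    peak_mask = morphology.h_maxima(distance, max(1.0, tolerance / 2.0)) > 0
    peak_mask &= binary
    # every connected component keeps at least one seed
    comp_labels, n_comps = ndi.label(binary, structure=_STRUCTURE_8)
    seeded = np.unique(comp_labels[peak_mask])
    for comp in range(1, n_comps + 1):
        if comp not in seeded:
            comp_distance = np.where(comp_labels == comp, distance, -1.0)
            peak_mask[np.unravel_index(np.argmax(comp_distance), binary.shape)] = True
    # merge maxima closer than the tolerance into one seed; seeds never merge
    # across distinct connected components of the mask
    merged = ndi.binary_dilation(
        peak_mask, structure=morphology.disk(math.ceil(tolerance / 2))
    )
    seed_labels, n_seeds = ndi.label(merged, structure=_STRUCTURE_8)
    keys = np.where(
        peak_mask, seed_labels.astype(np.int64) * (n_comps + 1) + comp_labels, 0
    )
    markers = np.searchsorted(np.unique(keys), keys)
    labels = sk_segmentation.watershed(
        -distance, markers=markers, mask=binary, watershed_line=True, connectivity=1
    )
    return relabel_consecutive(labels)


def relabel_consecutive(labels: np.ndarray) -> np.ndarray:
    """Compact labels to consecutive positive integers (0 stays background)."""
    labels = np.asarray(labels)
    present = np.unique(labels)
    present = present[present > 0]
    lut = np.zeros(int(labels.max()) + 1 if labels.size else 1, dtype=np.int32)
    lut[present] = np.arange(1, present.size + 1, dtype=np.int32)
    return lut[labels]


@dataclass(frozen=True)
class Particle:
    """Shape measurements of one labeled particle.

    ``circularity`` is ``4*pi*area / perimeter**2`` with a Crofton perimeter
    estimate, capped at 1 (pixel-grid perimeters otherwise push small disks
    above the disk bound).
    """

    label: int
    area_px: int
    area_um2: float
    perimeter_px: float
    circularity: float


def measure_particles(labels: np.ndarray, scale: ImageScale) -> list[Particle]:
    """Measure area, Crofton perimeter and circularity of every particle."""
    particles = []
    for region in measure.regionprops(np.asarray(labels, dtype=np.int32)):
        area = int(region.area)
        perimeter = float(region.perimeter_crofton)
        if perimeter > 0:
            circ = min(1.0, 4.0 * np.pi * area / perimeter**2)
        else:
            circ = 1.0
        particles.append(
            Particle(
                label=int(region.label),
                area_px=area,
                area_um2=scale.area_px_to_um2(area),
                perimeter_px=perimeter,
                circularity=circ,
            )
        )
    return particles


def _drop_labels(labels: np.ndarray, drop: set[int]) -> np.ndarray:
    if not drop:
        return relabel_consecutive(labels)
    out = np.asarray(labels).copy()
    out[np.isin(out, list(drop))] = 0
    return relabel_consecutive(out)


def filter_small_particles(
    labels: np.ndarray, min_area_um2: float, scale: ImageScale
) -> np.ndarray:
    """Remove particles smaller than ``min_area_um2``; labels recompacted."""
    drop = {
        p.label for p in measure_particles(labels, scale) if p.area_um2 < min_area_um2
    }
    return _drop_labels(labels, drop)


def filter_nonround_particles(labels: np.ndarray, min_circularity: float) -> np.ndarray:
    """Remove elongated particles (circularity below ``min_circularity``).

    Used on the hematoxylin component only, to discard thin fibroblastic
    cells that are not carcinoma nuclei.
    """
    if not 0 <= min_circularity <= 1:
        raise ValidationError("min_circularity must be in [0, 1]")
    scale = ImageScale(1.0)  # circularity is scale-free
    drop = {
        p.label
        for p in measure_particles(labels, scale)
        if p.circularity < min_circularity
    }
    return _drop_labels(labels, drop)


def segment_component(
    component: ComponentImage,
    scale: ImageScale,
    *,
    threshold_offset: int = 0,
    mean_radius_px: int = 2,
    median_radius_px: int = 2,
    min_area_um2: float = 10.0,
    min_circularity: float | None = None,
    min_nucleus_diameter_um: float = 4.0,
) -> np.ndarray:
    """Full segmentation of one component image into a nucleus label map.

    ``min_circularity`` is applied only when given (the hematoxylin chain
    passes it; the DAB chain does not).
    """
    smoothed = mean_filter(component.gray, mean_radius_px)
    mask = binarize_component(
        ComponentImage(smoothed, component.stain_name), threshold_offset
    )
    mask = median_filter(mask, median_radius_px)
    merge_px = 0.5 * scale.um_to_px(min_nucleus_diameter_um)
    labels = watershed_split(mask, seed_merge_distance_px=merge_px)
    labels = filter_small_particles(labels, min_area_um2, scale)
    if min_circularity is not None:
        labels = filter_nonround_particles(labels, min_circularity)
    return labels
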