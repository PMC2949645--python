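"""Deterministic synthetic two-stain brightfield scenes with known truth.

The generator emulates a hematoxylin-counterstained, DAB-immunostained
section photographed in brightfield: elliptical nuclei carry per-pixel stain
concentrations (peak optical density at the center, quadratic falloff to the
rim), stain amounts mix additively in OD space through the standard H-DAB
stain vectors, and the scene is rendered over a near-white illumination
field with optional radial vignetting and Gaussian sensor noise.  A matching
blankfield image (the illumination field alone, with its own noise) is
returned alongside, as acquired from empty slide background in a real
session.

Ground truth carries the exact nucleus masks, so the true labeling index is
the area ratio over the generator's own masks.  Thin hematoxylin-stained
bars emulate fibroblastic cells that the roundness filter should discard;
they are excluded from the true nuclear area.  Everything is a deterministic
function of the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage as ndi

from .errors import GenerationError, ValidationError
from .stain_separation import StainMatrix, default_hdab_matrix

#: Staining-condition variants: multiplicative factors on the peak optical
#: densities, plus a cytoplasmic halo of the affected stain for the "strong"
#: conditions (over-concentrated reagents deposit in the cytoplasm).
STAINING_VARIANTS = {
    "antibody_weak": {"dab_factor": 0.25},
    "antibody_strong": {"dab_factor": 4.0, "halo_stain": "dab", "halo_od": 0.45},
    "hematoxylin_weak": {"h_factor": 0.15},
    "hematoxylin_strong": {"h_factor": 3.0, "halo_stain": "h", "halo_od": 0.45},
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic scene.

    ``dab_fraction`` is the target fraction of total nucleus *area* that is
    DAB-positive; whole nuclei are assigned to the positive class until the
    running area is as close as possible to the target, so the realized
    ground-truth index can differ from the target by up to about half a
    nucleus area.
    """

    width: int = 256
    height: int = 256
    pixels_per_um: float = 2.2
    n_nuclei: int = 30
    dab_fraction: float = 0.3
    nucleus_diameter_um: tuple[float, float] = (7.0, 10.0)
    h_od: float = 0.7
    dab_od: float = 1.0
    n_fibroblasts: int = 3
    vignette_strength: float = 0.0
    noise_sd: float = 0.0
    background_intensity: float = 245.0
    overlap_pairs: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.dab_fraction <= 1:
            raise ValidationError("dab_fraction must be in [0, 1]")
        if not 0 <= self.vignette_strength < 1:
            raise ValidationError("vignette_strength must be in [0, 1)")
        if self.noise_sd < 0 or self.pixels_per_um <= 0:
            raise ValidationError("noise_sd must be >= 0 and pixels_per_um > 0")
        lo, hi = self.nucleus_diameter_um
        if not 0 < lo <= hi:
            raise ValidationError("nucleus diameter range must be positive and ordered")


@dataclass(frozen=True)
class NucleusRecord:
    center: tuple[float, float]
    semi_axes_px: tuple[float, float]
    angle_rad: float
    area_px: int
    dab_positive: bool


@dataclass
class GroundTruth:
    """Exact masks and areas underlying a generated scene."""

    dab_mask: np.ndarray
    h_mask: np.ndarray
    fibroblast_mask: np.ndarray
    nuclei: list[NucleusRecord]
    seed: int
    variant: str | None = None

    @property
    def true_dab_area_px(self) -> int:
        return int((self.dab_mask > 0).sum())

    @property
    def true_h_area_px(self) -> int:
        return int((self.h_mask > 0).sum())

    @property
    def true_index(self) -> float:
        total = self.true_dab_area_px + self.true_h_area_px
        return float("nan") if total == 0 else 100.0 * self.true_dab_area_px / total


def _ellipse_mask_and_rho2(
    shape: tuple[int, int],
    center: tuple[float, float],
    axes: tuple[float, float],
    angle: float,
) -> tuple[np.ndarray, np.ndarray, tuple[slice, slice]]:
    """Boolean ellipse mask and squared normalized radius over a bounding window."""
    cy, cx = center
    a, b = axes
    r = math.ceil(max(a, b)) + 1
    y0, y1 = max(0, int(cy) - r), min(shape[0], int(cy) + r + 1)
    x0, x1 = max(0, int(cx) - r), min(shape[1], int(cx) + r + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dy = (yy + 0.5) - cy
    dx = (xx + 0.5) - cx
    u = dx * math.cos(angle) + dy * math.sin(angle)
    v = -dx * math.sin(angle) + dy * math.cos(angle)
    rho2 = (u / a) ** 2 + (v / b) ** 2
    return rho2 <= 1.0, rho2, (slice(y0, y1), slice(x0, x1))


def _place_nuclei(spec: SyntheticSpec, rng: np.random.Generator):
    """Rejection-sample non-overlapping ellipse nuclei (plus optional pairs)."""
    shape = (spec.height, spec.width)
    occupied = np.zeros(shape, dtype=bool)
    placements = []  # (center, axes, angle, window, inside, rho2)
    scale = spec.pixels_per_um
    lo_um, hi_um = spec.nucleus_diameter_um
    max_attempts = 400 * max(1, spec.n_nuclei + 2 * spec.overlap_pairs)
    attempts = 0

    def sample_geometry():
        diameter_px = rng.uniform(lo_um, hi_um) * scale
        axis_ratio = rng.uniform(1.0, 1.5)
        a = diameter_px / 2.0 * math.sqrt(axis_ratio)
        b = diameter_px / 2.0 / math.sqrt(axis_ratio)
        return a, b, rng.uniform(0, math.pi)

    def try_place(center=None, allow_overlap_with=None):
        nonlocal attempts
        while attempts < max_attempts:
            attempts += 1
            a, b, angle = sample_geometry()
            margin = max(a, b) + 1
            if center is None:
                cy = rng.uniform(margin, spec.height - margin)
                cx = rng.uniform(margin, spec.width - margin)
            else:
                cy, cx = center
                if not (margin <= cy <= spec.height - margin and margin <= cx <= spec.width - margin):
                    center = None
                    continue
            inside, rho2, window = _ellipse_mask_and_rho2(shape, (cy, cx), (a, b), angle)
            clash = occupied[window] & inside
            if allow_overlap_with is not None:
                clash = clash & ~allow_overlap_with[window]
            if clash.any():
                center = None
                continue
            occupied[window] |= inside
            placements.append(((cy, cx), (a, b), angle, window, inside, rho2))
            return True
        return False

    for _ in range(spec.n_nuclei):
        if not try_place():
            raise GenerationError(
                f"cannot pack {spec.n_nuclei} nuclei into a {spec.width}x{spec.height} field"
            )
    for _ in range(spec.overlap_pairs):
        if not try_place():
            raise GenerationError("cannot place overlap pair")
        first_mask = np.zeros(shape, dtype=bool)
        (cy, cx), (a, b), _, window, inside, _ = placements[-1]
        first_mask[window] |= inside
        offset = 0.8 * (a + b)
        theta = rng.uniform(0, 2 * math.pi)
        partner = (cy + offset * math.sin(theta), cx + offset * math.cos(theta))
        if not try_place(center=partner, allow_overlap_with=first_mask):
            raise GenerationError("cannot place overlap pair")
    return placements


def _select_positives(placements, dab_fraction: float, rng: np.random.Generator):
    """Greedily assign whole nuclei to the DAB-positive class to hit the target area fraction."""
    areas = np.array([int(p[4].sum()) for p in placements], dtype=np.int64)
    total = int(areas.sum())
    target = dab_fraction * total
    order = rng.permutation(len(placements))
    positive = np.zeros(len(placements), dtype=bool)
    cum = 0
    for idx in order:
        if cum < target:
            positive[idx] = True
            cum += areas[idx]
    # refine with single toggles and pair swaps until the realized positive
    # area is as close to the target as whole-nucleus assignment allows
    improved = True
    while improved:
        improved = False
        gap = cum - target
        best_delta, best_move = 0.0, None
        for i in np.nonzero(positive)[0]:
            for delta, move in ((-areas[i], ("toggle", i)),):
                if abs(gap + delta) < abs(gap + best_delta) - 1e-9:
                    best_delta, best_move = delta, move
        for j in np.nonzero(~positive)[0]:
            if abs(gap + areas[j]) < abs(gap + best_delta) - 1e-9:
                best_delta, best_move = areas[j], ("toggle", j)
        for i in np.nonzero(positive)[0]:
            for j in np.nonzero(~positive)[0]:
                delta = areas[j] - areas[i]
                if abs(gap + delta) < abs(gap + best_delta) - 1e-9:
                    best_delta, best_move = delta, ("swap", i, j)
        if best_move is not None:
            if best_move[0] == "toggle":
                i = best_move[1]
                positive[i] = ~positive[i]
            else:
                _, i, j = best_move
                positive[i], positive[j] = False, True
            cum += int(best_delta)
            improved = True
    return positive


def _vignette_field(spec: SyntheticSpec) -> np.ndarray:
    """Radial illumination falloff: 1 at center, 1 - strength at the corners."""
    yy, xx = np.mgrid[0 : spec.height, 0 : spec.width]
    cy, cx = (spec.height - 1) / 2.0, (spec.width - 1) / 2.0
    r2 = (yy - cy) ** 2 + (xx - cx) ** 2
    r2max = cy**2 + cx**2
    return 1.0 - spec.vignette_strength * (r2 / max(r2max, 1.0))


def _render(
    spec: SyntheticSpec,
    h_map: np.ndarray,
    d_map: np.ndarray,
    rng: np.random.Generator,
    stains: StainMatrix,
) -> tuple[np.ndarray, np.ndarray]:
    matrix = stains.as_matrix()
    od = h_map[:, :, None] * matrix[0] + d_map[:, :, None] * matrix[1]
    transmittance = np.power(10.0, -od)
    illumination = spec.background_intensity * _vignette_field(spec)
    image = illumination[:, :, None] * transmittance
    blank = np.repeat(illumination[:, :, None], 3, axis=2)
    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, image.shape)
        blank = blank + rng.normal(0.0, spec.noise_sd, blank.shape)
    image = np.clip(np.round(image), 0, 255).astype(np.uint8)
    blank = np.clip(np.round(blank), 0, 255).astype(np.uint8)
    return image, blank


def generate_scene(
    spec: SyntheticSpec,
    *,
    stains: StainMatrix | None = None,
    _h_factor: float = 1.0,
    _dab_factor: float = 1.0,
    _halo_stain: str | None = None,
    _halo_od: float = 0.0,
) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Generate one scene: RGB image, matching blankfield, and ground truth.

    Fully determined by ``spec.seed``: the same spec yields bit-identical
    images.
    """
    if stains is None:
        stains = default_hdab_matrix()
    rng = np.random.default_rng(spec.seed)
    shape = (spec.height, spec.width)
    placements = _place_nuclei(spec, rng)
    positive = _select_positives(placements, spec.dab_fraction, rng)

    h_map = np.zeros(shape, dtype=np.float64)
    d_map = np.zeros(shape, dtype=np.float64)
    dab_mask = np.zeros(shape, dtype=bool)
    h_mask = np.zeros(shape, dtype=bool)
    records = []
    h_od = spec.h_od * _h_factor
    dab_od = spec.dab_od * _dab_factor
    for i, ((cy, cx), axes, angle, window, inside, rho2) in enumerate(placements):
        profile = np.where(inside, 1.0 - 0.5 * np.minimum(rho2, 1.0), 0.0)
        if positive[i]:
            d_map[window] += dab_od * profile
            h_map[window] += 0.3 * h_od * profile  # counterstain under the DAB
            dab_mask[window] |= inside
        else:
            h_map[window] += h_od * profile
            h_mask[window] |= inside
        records.append(
            NucleusRecord(
                center=(cy, cx),
                semi_axes_px=axes,
                angle_rad=angle,
                area_px=int(inside.sum()),
                dab_positive=bool(positive[i]),
            )
        )

    fibro_mask = np.zeros(shape, dtype=bool)
    for _ in range(spec.n_fibroblasts):
        fibro_mask |= _stamp_fibroblast(spec, rng, dab_mask | h_mask | fibro_mask)
    h_map[fibro_mask] += 0.6 * h_od

    if _halo_stain is not None and _halo_od > 0:
        nuclei = dab_mask | h_mask
        halo_px = max(1, int(round(2.0 * spec.pixels_per_um)))
        halo = ndi.binary_dilation(nuclei, iterations=halo_px) & ~nuclei
        if _halo_stain == "dab":
            d_map[halo] += _halo_od
        else:
            h_map[halo] += _halo_od

    image, blank = _render(spec, h_map, d_map, rng, stains)
    truth = GroundTruth(
        dab_mask=np.where(dab_mask, 255, 0).astype(np.uint8),
        h_mask=np.where(h_mask, 255, 0).astype(np.uint8),
        fibroblast_mask=np.where(fibro_mask, 255, 0).astype(np.uint8),
        nuclei=records,
        seed=spec.seed,
    )
    return image, blank, truth


def _stamp_fibroblast(
    spec: SyntheticSpec, rng: np.random.Generator, occupied: np.ndarray
) -> np.ndarray:
    """One thin hematoxylin-stained bar (aspect ratio >= 6), avoiding nuclei.

    Dimensions emulate spindle-shaped fibroblastic cells: ~1.8 um wide and
    30-45 um long, so the bar stays far below the roundness cutoff even
    after the smoothing filters fatten it by a pixel or two.  Bars keep a
    stromal clearance of a few micrometers from the nuclei, as free-lying
    stromal cells do; without it the smoothing filters would fuse bar and
    nucleus into one compound particle.
    """
    shape = (spec.height, spec.width)
    width_px = max(2.0, 1.8 * spec.pixels_per_um)
    margin_px = 4.0 * spec.pixels_per_um
    length_px = rng.uniform(30.0, 45.0) * spec.pixels_per_um
    length_px = min(length_px, 0.45 * min(spec.width, spec.height))
    length_px = max(length_px, 6.0 * width_px)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    for _ in range(200):
        cy = rng.uniform(length_px / 2, spec.height - length_px / 2)
        cx = rng.uniform(length_px / 2, spec.width - length_px / 2)
        angle = rng.uniform(0, math.pi)
        dy = (yy + 0.5) - cy
        dx = (xx + 0.5) - cx
        u = dx * math.cos(angle) + dy * math.sin(angle)
        v = -dx * math.sin(angle) + dy * math.cos(angle)
        bar = (np.abs(u) <= length_px / 2) & (np.abs(v) <= width_px / 2)
        cleared = (np.abs(u) <= length_px / 2 + margin_px) & (
            np.abs(v) <= width_px / 2 + margin_px
        )
        if not (cleared & occupied).any():
            return bar
    return np.zeros(shape, dtype=bool)


def generate_staining_variants(
    spec: SyntheticSpec, variant: str, *, stains: StainMatrix | None = None
) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Generate a scene under a degraded staining condition.

    ``antibody_weak`` / ``antibody_strong`` emulate over-dilute and
    over-concentrated primary antibody (scaled DAB optical density; the
    strong condition adds a cytoplasmic DAB halo); ``hematoxylin_weak`` /
    ``hematoxylin_strong`` do the same for the counterstain.
    """
    if variant not in STAINING_VARIANTS:
        raise ValidationError(
            f"unknown variant {variant!r}; choose from {sorted(STAINING_VARIANTS)}"
        )
    params = STAINING_VARIANTS[variant]
    image, blank, truth = generate_scene(
        spec,
        stains=stains,
        _h_factor=params.get("h_factor", 1.0),
        _dab_factor=params.get("dab_factor", 1.0),
        _halo_stain=params.get("halo_stain"),
        _halo_od=params.get("halo_od", 0.0),
    )
    truth.variant = variant
    return image, blank, truth


def sweep_specs(
    fractions, seeds, **overrides
) -> list[SyntheticSpec]:
    """Convenience grid of specs over DAB fractions x seeds (same geometry family)."""
    base = SyntheticSpec(**overrides) if overrides else SyntheticSpec()
    return [
        replace(base, dab_fraction=float(p), seed=int(s))
        for p in fractions
        for s in seeds
    ]
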