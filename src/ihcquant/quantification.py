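"""Labeling index computation, cubic calibration and per-sample averaging.

The labeling index is the percentage of DAB-stained nuclear area out of the
total nuclear area.  Pixels present in both final masks are assigned to DAB
(the brown reaction product optically dominates the blue counterstain), so

    raw_index = 100 * A_DAB / (A_DAB + A_H_only)

An optional cubic polynomial, fitted against visually counted labeling
indexes, corrects the raw area ratio onto the visual-count scale; corrected
values are clamped to [0, 100].  Sample-level results average the per-image
corrected indexes with equal weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import AggregationError, CalibrationError, ValidationError


@dataclass
class LabelingIndexResult:
    """Areas and index for one analyzed image.

    When no nuclear area was found at all, ``undefined`` is set and the
    indexes are NaN ("no nuclear area"), never a division by zero.
    """

    dab_area_px: int
    h_area_px: int
    raw_index: float
    corrected_index: float
    undefined: bool = False
    image_id: str = ""
    warnings: tuple[str, ...] = ()

    @property
    def total_area_px(self) -> int:
        return self.dab_area_px + self.h_area_px


def labeling_index(
    dab_mask: np.ndarray,
    h_mask: np.ndarray,
    roi_mask: np.ndarray | None = None,
    image_id: str = "",
) -> LabelingIndexResult:
    """Compute the labeling index from the two final particle masks.

    ``roi_mask`` (0/255) restricts the measurement; the whole image is used
    when absent.  Overlap pixels count as DAB only.
    """
    dab = np.asarray(dab_mask) > 0
    h = np.asarray(h_mask) > 0
    if dab.shape != h.shape:
        raise ValidationError("DAB and hematoxylin masks must share dimensions")
    if roi_mask is not None:
        roi = np.asarray(roi_mask) > 0
        if roi.shape != dab.shape:
            raise ValidationError("ROI mask must share the image dimensions")
        dab = dab & roi
        h = h & roi
    dab_area = int(dab.sum())
    h_only_area = int((h & ~dab).sum())
    total = dab_area + h_only_area
    if total == 0:
        return LabelingIndexResult(
            dab_area_px=0,
            h_area_px=0,
            raw_index=float("nan"),
            corrected_index=float("nan"),
            undefined=True,
            image_id=image_id,
            warnings=("no nuclear area",),
        )
    raw = 100.0 * dab_area / total
    return LabelingIndexResult(
        dab_area_px=dab_area,
        h_area_px=h_only_area,
        raw_index=raw,
        corrected_index=raw,
        image_id=image_id,
    )


@dataclass(frozen=True)
class CalibrationPolynomial:
    """Cubic correction mapping the raw area-ratio index to visual counts.

    ``corrected(x) = clamp(c0 + c1*x + c2*x^2 + c3*x^3, 0, 100)``.
    Fit diagnostics (R^2, residuals, coefficient standard errors) travel with
    the fitted polynomial; they are ``None`` for hand-specified coefficients.
    """

    c0: float
    c1: float
    c2: float
    c3: float
    r_squared: float | None = None
    residuals: tuple[float, ...] | None = field(default=None, repr=False)
    std_errors: tuple[float, ...] | None = None

    def coefficients(self) -> tuple[float, float, float, float]:
        return (self.c0, self.c1, self.c2, self.c3)

    def __call__(self, x: float | np.ndarray) -> float | np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        y = self.c0 + self.c1 * x + self.c2 * x**2 + self.c3 * x**3
        out = np.clip(y, 0.0, 100.0)
        return float(out) if out.ndim == 0 else out

    def is_monotone(self, lo: float = 0.0, hi: float = 100.0, n: int = 1001) -> bool:
        grid = np.linspace(lo, hi, n)
        raw = self.c0 + self.c1 * grid + self.c2 * grid**2 + self.c3 * grid**3
        return bool(np.all(np.diff(raw) >= -1e-9))

    @classmethod
    def identity(cls) -> "CalibrationPolynomial":
        return cls(0.0, 1.0, 0.0, 0.0)

    @classmethod
    def from_file(cls, path) -> "CalibrationPolynomial":
        """Read four whitespace/comma-separated coefficients, constant first."""
        text = open(path).read().replace(",", " ")
        coeffs = [float(tok) for tok in text.split()]
        if len(coeffs) != 4:
            raise CalibrationError(
                f"calibration file must hold exactly 4 coefficients, got {len(coeffs)}"
            )
        return cls(*coeffs)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(" ".join(f"{c!r}" for c in self.coefficients()) + "\n")


def fit_calibration(
    raw_indexes, visual_indexes
) -> CalibrationPolynomial:
    """Ordinary least-squares cubic of visual index on raw index.

    Requires at least 4 paired points in [0, 100].  Emits a warning when the
    fitted cubic is not monotone over [0, 100] (a symptom of sparse or noisy
    calibration data).
    """
    raw = np.asarray(raw_indexes, dtype=np.float64)
    visual = np.asarray(visual_indexes, dtype=np.float64)
    if raw.shape != visual.shape or raw.ndim != 1:
        raise CalibrationError("raw and visual index lists must be equal-length 1-D")
    if raw.size < 4:
        raise CalibrationError("calibration needs at least 4 paired points")
    if np.any((raw < 0) | (raw > 100)) or np.any((visual < 0) | (visual > 100)):
        raise CalibrationError("labeling indexes must lie in [0, 100]")
    design = np.vander(raw, 4, increasing=True)
    if np.linalg.matrix_rank(design) < 4:
        raise CalibrationError("rank-deficient calibration design (too few distinct raw values)")
    coeffs, _, _, _ = np.linalg.lstsq(design, visual, rcond=None)
    fitted = design @ coeffs
    residuals = visual - fitted
    ss_res = float(np.sum(residuals**2))
    ss_tot = float(np.sum((visual - visual.mean()) ** 2))
    r_squared = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    dof = raw.size - 4
    if dof > 0:
        sigma2 = ss_res / dof
        cov = sigma2 * np.linalg.inv(design.T @ design)
        std_errors = tuple(float(s) for s in np.sqrt(np.diag(cov)))
    else:
        std_errors = (0.0, 0.0, 0.0, 0.0)
    poly = CalibrationPolynomial(
        *(float(c) for c in coeffs),
        r_squared=r_squared,
        residuals=tuple(float(r) for r in residuals),
        std_errors=std_errors,
    )
    if not poly.is_monotone():
        warnings.warn(
            "fitted calibration polynomial is not monotone on [0, 100]",
            stacklevel=2,
        )
    return poly


def apply_calibration(raw: float, poly: CalibrationPolynomial) -> float:
    """Evaluate the correction polynomial, clamped to [0, 100]."""
    if not 0 <= raw <= 100:
        raise ValidationError("raw index must be in [0, 100]")
    return float(poly(raw))


@dataclass
class SampleResult:
    """Averaged result over the images of one specimen.

    ``running_mean[k]`` is the mean of the first ``k + 1`` corrected indexes,
    i.e. the accuracy-versus-image-count curve used to justify averaging at
    least three fields per sample.
    """

    results: list[LabelingIndexResult]
    mean_index: float
    n_images: int
    running_mean: tuple[float, ...]
    n_excluded: int = 0


def aggregate_images(results) -> SampleResult:
    """Unweighted mean of per-image corrected indexes.

    Undefined (no-nuclear-area) results are excluded and counted; if every
    result is undefined there is nothing to average.
    """
    results = list(results)
    defined = [r for r in results if not r.undefined]
    if not defined:
        raise AggregationError("all per-image results are undefined (no nuclear area)")
    values = np.array([r.corrected_index for r in defined], dtype=np.float64)
    running = np.cumsum(values) / np.arange(1, values.size + 1)
    return SampleResult(
        results=results,
        mean_index=float(values.mean()),
        n_images=len(defined),
        running_mean=tuple(float(v) for v in running),
        n_excluded=len(results) - len(defined),
    )
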