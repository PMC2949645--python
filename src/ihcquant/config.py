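"""YAML configuration loading for the command line.

A config file mirrors :class:`ihcquant.pipeline.AnalysisConfig`; CLI flags
override file values.  Schema (all keys optional)::

    scale:
      pixels_per_um: 4.55
    thresholds:
      h_adjust: 0          # [-50, 50]
      dab_adjust: 0
    filters:
      mean_radius_px: 2    # at the 1.1 px/um reference scale
      median_radius_px: 2
      min_area_um2: 10.0
      min_circularity: 0.35
      min_nucleus_diameter_um: 4.0
    rolling_ball_radius_px: 50.0
    stains:
      hematoxylin: [0.650, 0.704, 0.286]   # OD triplets, auto-normalized
      dab: [0.269, 0.568, 0.778]
    calibration: path/to/coefficients.txt  # 4 numbers, constant term first
    render_mode: fill                      # fill | outline
"""

from __future__ import annotations

from dataclasses import replace
from pathlib import Path

import yaml

from .core_images import ImageScale
from .errors import ValidationError
from .pipeline import AnalysisConfig
from .quantification import CalibrationPolynomial
from .stain_separation import StainMatrix, StainVector


def load_config(path: str | Path | None) -> AnalysisConfig:
    """Build an :class:`AnalysisConfig` from a YAML file (defaults if None)."""
    config = AnalysisConfig()
    if path is None:
        return config
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValidationError(f"config file {path} must contain a mapping")
    if "scale" in data:
        config = replace(
            config, scale=ImageScale(float(data["scale"]["pixels_per_um"]))
        )
    thresholds = data.get("thresholds", {})
    filters = data.get("filters", {})
    updates = {}
    for key in ("h_adjust", "dab_adjust"):
        if key in thresholds:
            updates[key] = int(thresholds[key])
    for key in (
        "mean_radius_px",
        "median_radius_px",
        "min_area_um2",
        "min_circularity",
        "min_nucleus_diameter_um",
    ):
        if key in filters:
            updates[key] = type(getattr(config, key))(filters[key])
    if "rolling_ball_radius_px" in data:
        updates["rolling_ball_radius_px"] = float(data["rolling_ball_radius_px"])
    if "render_mode" in data:
        updates["render_mode"] = str(data["render_mode"])
    if "stains" in data:
        stains = data["stains"]
        updates["stains"] = StainMatrix(
            hematoxylin=StainVector.normalized(*stains["hematoxylin"]),
            dab=StainVector.normalized(*stains["dab"]),
        )
    if data.get("calibration"):
        calib_path = Path(data["calibration"])
        if not calib_path.is_absolute():
            calib_path = Path(path).parent / calib_path
        updates["calibration"] = CalibrationPolynomial.from_file(calib_path)
    return replace(config, **updates)
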