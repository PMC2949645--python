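"""Regenerate the bundled scale-finder table.

For a range of known image scales, a synthetic hematoxylin-stained scene is
generated, the hematoxylin component is segmented with the standard chain,
and the mean equivalent-circle diameter of the segmented nuclei is recorded.
The resulting (diameter_px, pixels_per_um) table backs the default scale
model; users refit with their own measurements.

Run from the repository root:  python scripts/make_scale_table.py
"""

import csv
from pathlib import Path

import numpy as np

from ihcquant import (
    ImageScale,
    SyntheticSpec,
    correct_blankfield,
    generate_scene,
    measure_particles,
    segment_component,
    separate_stains,
)

OUT = Path(__file__).resolve().parents[1] / "src" / "ihcquant" / "data" / "scale_table.csv"

SCALES = [0.6, 0.9, 1.1, 1.5, 2.0, 2.75, 3.5, 4.55]


def mean_diameter_px(scale: float, seed: int) -> float:
    side = max(192, int(round(160 * scale)))
    spec = SyntheticSpec(
        width=side,
        height=side,
        pixels_per_um=scale,
        n_nuclei=25,
        dab_fraction=0.0,
        n_fibroblasts=0,
        noise_sd=2.0,
        seed=seed,
    )
    image, blank, _ = generate_scene(spec)
    corrected = correct_blankfield(image, blank)
    h_comp, _ = separate_stains(corrected)
    labels = segment_component(h_comp, ImageScale(scale), min_circularity=0.35)
    particles = measure_particles(labels, ImageScale(scale))
    diameters = [2.0 * np.sqrt(p.area_px / np.pi) for p in particles]
    return float(np.mean(diameters))


def main() -> None:
    OUT.parent.mkdir(parents=True, exist_ok=True)
    with open(OUT, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["mean_nucleus_diameter_px", "pixels_per_um"])
        for scale in SCALES:
            for seed in (11, 12):
                d = mean_diameter_px(scale, seed)
                writer.writerow([f"{d:.3f}", scale])
                print(f"scale {scale:5.2f} px/um  seed {seed}: mean diameter {d:6.2f} px")
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
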