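# ihcquant

Quantitative scoring of nuclear immunostains (estrogen receptor,
progesterone receptor, Ki-67) in brightfield microscope images of
DAB-stained, hematoxylin-counterstained tissue sections.

The package computes the **labeling index** — the percentage of
DAB-stained nuclear area out of the total nuclear area,

```
LI = 100 · A_DAB / (A_DAB + A_H)
```

where `A_DAB` is the segmented area of diaminobenzidine-positive nuclei and
`A_H` the area of hematoxylin-only (negative) nuclei.  It is written for
pathology labs and image-analysis researchers who want a scriptable,
headless implementation of this widely used area-ratio score, with the
supporting machinery a real deployment needs: flat-field correction, camera
QC, scale adaptation, calibration against visual counts, and rendered
result images for review.

## The analysis chain

1. **Illumination correction** — divide by a *blankfield* image (an empty
   slide field captured with the same optics and exposure), rescaling blank
   background to white; without a blankfield, rolling-ball background
   subtraction is used instead.
2. **Color deconvolution** — per pixel, the RGB optical densities
   `OD_c = −log10(I_c / 255)` are expressed in the H-DAB stain basis
   (Beer–Lambert mixing); inverting the 3×3 stain matrix yields hematoxylin
   and DAB concentration images, re-exported as 8-bit component images
   (255 = unstained).
3. **Segmentation** (per component) — mean filter, adaptive IsoData
   threshold (the fixed point of `t ← round((μ_≤t + μ_>t)/2)`) with
   optional per-component offsets, median smoothing, watershed splitting of
   touching nuclei on the distance transform, removal of particles below
   10 µm², and (hematoxylin only) removal of elongated particles with
   circularity `4πA/P² < 0.35` (fibroblastic cells).
4. **Index & calibration** — overlap pixels count as DAB; an optional cubic
   polynomial, fitted to visually counted labeling indexes, maps the raw
   area ratio onto the visual-count scale (clamped to [0, 100]).
5. **Reporting** — pseudo-colored segmentation (brown/blue/white or red
   outlines), a result card (id, date, index, original + pseudo-color side
   by side), and multi-image montages with the sample mean; at least three
   fields per specimen are recommended for a stable mean.

A Camera Adjustment Wizard checks acquisition quality (blankfield mean gray
in [200, 250]; stained-cell foreground 50–80 % of background gray), and a
Scale Finder estimates pixels-per-µm from the mean nucleus diameter via a
fitted first-degree polynomial.

A deterministic synthetic-scene generator (`ihcquant.synthetic_fixtures`)
renders two-stain fields with exact ground-truth masks; it backs the test
suite and the reproduction script.

## Worked example

Generate a synthetic field with a known 35 % labeling index and analyze it:

```
$ ihcquant simulate --seed 11 --dab-fraction 0.35 --out scene
wrote scene to scene (true labeling index 35.0%)

$ ihcquant analyze scene/scene.png --blankfield scene/blankfield.png \
      --scale 2.2 --date 2026-09-19 --out results
scene.png: labeling index 35.0%

$ cat results/results.csv
image_id,date,dab_area_px,h_area_px,raw_index_pct,corrected_index_pct,n_warnings
scene,2026-09-19,2807,5212,35.0044,35.0044,0
```

The analysis found 2 807 px of DAB-positive and 5 212 px of
hematoxylin-only nuclear area, i.e. a labeling index of
100·2807/(2807+5212) = 35.0 % — matching the generator's ground truth.
`results/scene_card.png` holds the rendered result card.  Camera QC on the
same session:

```
$ ihcquant wizard --blankfield scene/blankfield.png --cells scene/scene.png
blankfield mean gray: 245.0 (optimal; optimal range 200-250)
contrast ratio: 48.3% (too_high; optimal range 50-80%)

$ ihcquant scale-finder --diameter 18.5
estimated scale: 2.267 px/um (rough estimate)
```

Library use mirrors the CLI:

```python
from ihcquant import AnalysisConfig, ImageScale, analyze_image, read_image

config = AnalysisConfig(scale=ImageScale(2.2))
record = analyze_image(read_image("field.png"), config,
                       blankfield=read_image("blank.png"))
print(record.result.raw_index)
```

Other subcommands: `sample` (multi-image averaging + montage), `calibrate`
(cubic fit from a raw/visual CSV), `simulate` (synthetic scenes).

## Limitations

- Single camera fields only; no whole-slide (pyramidal) formats.
- Area-ratio scoring only: no intensity-weighted scores (histoscore,
  Allred) and no per-cell counting — DAB optical density is not assumed
  proportional to antigen abundance.
- Membrane stains (e.g. HER-2) are out of scope.

See `docs/methods.md` for the model, parameter defaults, and numerical
choices.
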