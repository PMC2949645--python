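# Methods

## Imaging model and stain separation

A brightfield field of an immunostained section is modeled with
Beer–Lambert absorption: for channel `c` with white level `I0 = 255`,

```
I_c = I0 · 10^(−(h·V_H,c + d·V_DAB,c))
```

where `h` and `d` are the per-pixel hematoxylin and DAB amounts (in optical
density, OD) and `V_H`, `V_DAB` are unit-length stain absorption vectors.
Deconvolution inverts the 3×3 matrix of `V_H`, `V_DAB` and a residual third
vector (their normalized cross product) applied to the pixel's OD triplet
`OD_c = −log10(max(I_c, 1)/255)`.  Negative concentrations are clamped to
zero, and components are re-exported on the 8-bit transmittance scale
(`round(255·10^(−conc))`).

Defaults are the standard H-DAB vectors, hematoxylin `(0.650, 0.704,
0.286)` and DAB `(0.269, 0.568, 0.778)`, overridable through configuration
because real stain spectra vary between labs; the cubic calibration step is
designed to absorb residual spectral mismatch.

Numerical accuracy: with 8-bit input the round trip (synthesize → quantize
→ deconvolve) is accurate to ≤ 0.02 OD as long as the *total* stain OD per
pixel stays below ≈ 1.25 (minimum transmittance ≈ 6 %, ≥ 14 intensity
counts).  Beyond that, quantization of near-black pixels dominates: at
total OD 2 a half-intensity step is already ≈ 0.1 OD.  All defaults in this
package keep pixels inside the accurate regime.

## Illumination correction

Flat-field correction divides by the blankfield image pixel-wise and
rescales to white, `out = clamp(round(in/blank · 255), 0, 255)`, flooring
blankfield pixels at 1.  The normalization target is white (255), not the
blankfield mean, because downstream OD conversion assumes `I0 = 255`.
Without a blankfield, rolling-ball background subtraction runs per channel
in light-background mode (invert, estimate the background surface by
rolling a ball under it, subtract, re-invert).  The default ball radius is
50 px at the reference scale and scales with pixels-per-µm; radii smaller
than the largest nuclei absorb foreground into the background estimate, so
the blankfield path is always preferred when available.

## Scale convention

Pixel-unit parameters (mean/median filter radii of 2 px, rolling-ball
radius of 50 px) are stated at a reference scale of **4.55 px/µm** — the
recommended acquisition setup of a 4.40 µm camera pixel behind a 20×
objective with a 1× phototube (0.22 µm per specimen pixel) — and are
rescaled linearly to the actual image scale, with a floor of 1 px.  This
keeps the physical footprint of every filter constant across microscope
setups.  Micrometer-unit parameters (particle area cutoff, minimum nucleus
diameter) are converted per image with the supplied scale.

## Segmentation

Per component: disk mean filter (radius 2 px at reference scale,
replicate-padded) → IsoData threshold → optional per-component offset in
[−50, 50] → "stained = value ≤ threshold" (components encode stain as
darkness) → disk median filter (majority vote) → watershed → size filter →
(hematoxylin only) roundness filter.

**IsoData.**  The threshold is the fixed point of
`t ← round((mean of values ≤ t + mean of values > t)/2)`, iterated from the
mid-range of the occupied bins.  Both class means are non-decreasing in
`t`, so the iteration is monotone and always terminates at a fixed point;
the test suite checks agreement with an exhaustive fixed-point search.

**Blank-component guard.**  An unstained field is a legitimate input (a
completely negative tumor has an empty DAB component).  With sensor noise
such a component is never exactly white, and IsoData — which assumes two
classes — would happily split the noise.  The guard reuses the camera
wizard's own contrast-failure rule: if the stained class mean exceeds 85 %
of the unstained class mean, the component carries no separable stain and
yields an empty mask.

**Watershed.**  Euclidean distance transform of the mask; the distance map
is Gaussian-smoothed (σ = half the seed-merge tolerance) and seeds are its
h-maxima with prominence ≥ half the tolerance — undulations along the ridge
of a single (possibly elongated) particle are shallower than that, while
the saddle between two touching ~8 µm nuclei is deeper, so bars stay whole
and nucleus doublets split.  Seeds closer than the tolerance (half the
minimum nucleus diameter, default 4 µm) merge; every connected component
keeps at least one seed; seeds never merge across components.  Flooding
uses 4-connectivity with one-pixel watershed lines; particles are
8-connected.

**Particle filters.**  Area below 10 µm² (a 4 µm nucleus has ≈ 12.6 µm²) is
noise/debris; hematoxylin particles with circularity `4πA/P² < 0.35`
(Crofton perimeter, capped at 1) are discarded as fibroblastic cells.  With
the Crofton estimator an exact rectangle needs aspect ≳ 9 to fall below
0.35; real spindle cells (aspect 15+) are far below it.  The two filters
commute; the roundness filter runs only on the hematoxylin component, since
elongated DAB-positive objects are not a described failure mode.

## Labeling index, calibration, averaging

Pixels in both final masks count as DAB only (the brown polymer optically
masks the counterstain; this also keeps the denominator free of double
counting):

```
raw = 100 · A_DAB / (A_DAB + A_H-only)
```

restricted to the ROI when one is supplied (pixel centers `(x+0.5, y+0.5)`
strictly inside the polygon).  Zero total nuclear area yields an explicit
"no nuclear area" result, never a division by zero.

Calibration is an unconstrained ordinary-least-squares cubic of visual
index on raw index, requiring ≥ 4 points in [0, 100]; R², residuals and
coefficient standard errors accompany the fit, and a non-monotone fit on
[0, 100] triggers a warning rather than an error (sparse calibration data
can legitimately wiggle).  The correction is applied per image, before
averaging, and clamped to [0, 100].  Sample results are the unweighted mean
of per-image corrected indexes; undefined images are excluded and counted,
and the running mean versus image count is reported — with the default
scene statistics it stabilizes by about three images, which is why the CLI
warns below three.

## Camera QC and scale estimation

"Mean gray intensity" is the unweighted channel mean `(R+G+B)/3`.
Brightness: blankfield mean in [200, 250] is optimal, below is
underexposed, above overexposed.  Contrast: after an IsoData split of the
gray image, `ratio = 100·mean(foreground)/mean(background)`; 50–80 % is
optimal, < 50 % too high, > 85 % too low (segmentation becomes unreliable),
and the undocumented gap (80, 85] is labeled *borderline* with a warning
rather than a failure.

The scale finder is a first-degree polynomial from mean nucleus diameter
(px) to pixels-per-µm, fitted by least squares.  The bundled default model
is fitted to a table generated by the synthetic module (segmented mean
nucleus diameter at eight known scales, 0.6–4.55 px/µm); labs should refit
with their own measurements (`fit_scale_model`).  Estimates are flagged,
and diameters outside the fitted range carry a warning.

## Synthetic scenes

`SyntheticSpec` defaults describe one 256×256 px field at 2.2 px/µm (a
mid-range binned camera setup; ≈ 116 µm square): 30 elliptical nuclei of
7–10 µm diameter (axis ratio ≤ 1.5) packed without overlap, three
fibroblast bars (1.8 µm × 30–45 µm) kept ≥ 4 µm clear of nuclei, background
intensity 245, optional radial vignette (strength = relative corner
falloff) applied identically to scene and returned blankfield, and
independent Gaussian sensor noise added to both.  Nuclei carry peak ODs of
0.7 (hematoxylin) and 1.0 (DAB) at the center with quadratic falloff to
half the peak at the rim; DAB-positive nuclei retain 30 % of the normal
counterstain underneath the chromogen.  Whole nuclei are assigned to the
positive class by greedy selection with toggle/swap refinement, so the
realized ground-truth index matches the requested fraction to a fraction of
a percentage point.  Everything derives from one seed; regeneration is
bit-identical.

Degraded-staining variants scale the peak ODs (antibody ×0.25 / ×4 with a
cytoplasmic DAB halo; hematoxylin ×0.15 / ×3 with a blue halo) to emulate
over-dilute and over-concentrated reagents.  In this idealized imaging
model the weak-counterstain failure is abrupt rather than gradual — at
×0.15 the hematoxylin component falls under the blank-component guard and
segmentation collapses entirely, whereas real weak staining degrades
patchily; the variant is therefore suited to directional assertions, not to
quantifying partial degradation.

What the generator does **not** model: chromatin texture, nuclear
pleomorphism beyond ellipses, overlapping nuclei in depth, stain spectral
variation between labs, JPEG blocking from the camera, tissue folds, or
out-of-focus fields.  Passing the synthetic recovery tests therefore shows
the pipeline is correct under its own imaging model, not that it matches
visual counting on real slides — on real material the cubic calibration
against a lab's own visual counts remains essential, which is the method's
own position.

## Problem sizes and determinism

The test suite and the reproduction script use 256×256 px scenes, a 0–100 %
positive-fraction sweep in steps of 10 % with three seeds per fraction,
1 000 random histograms for the IsoData cross-check, and a 101×101
concentration grid for the deconvolution round trip; the full suite runs in
well under a minute on one core.  All randomness flows through explicit
seeds (`numpy.random.default_rng`); analysis dates are injectable so CSV
outputs are byte-reproducible.

## Known limitations

- Heavily saturated staining (total OD ≳ 1.25 per pixel) leaves the
  accurate deconvolution regime; the wizard's exposure rules exist to keep
  acquisitions away from it.
- Elongated-particle removal operates on post-watershed particles; rarely,
  a thin cell fused with a nucleus can survive as one compound particle.
- The cubic calibration is unconstrained; with sparse or noisy training
  data it can be non-monotone on [0, 100] (a warning is emitted).
- JPEG2000 reading depends on the installed imageio backends; absence is
  reported as a format error for that file only.
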