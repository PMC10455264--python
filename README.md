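# splenovol

Automated spleen volumetry from axial MRI-like series.

Accurate spleen volume is a key endpoint in conditions that cause
splenomegaly (e.g. Gaucher disease), where it anchors the baseline
assessment and the monitoring of treatment response. Clinical practice
often estimates the volume from three linear measurements on the axial
images — the craniocaudal length *L*, the largest axial long-axis
diameter *D*, and the largest in-plane extent *T* perpendicular to *D* —
through the formula

```
V (cm³) = 30 + 0.58 · L · D · T        (L, D, T in cm)
```

which presumes a roughly ellipsoidal organ and degrades badly on the
deformed, enlarged spleens where volumetry matters most. The alternative
is segmentation-based volumetry: predict a per-slice spleen mask,
compute each slice's area (foreground pixel count × pixel-size
conversion factor, mm²), and integrate the areas over the physical slice
positions with the trapezoid rule,

```
V = Σᵢ (Aᵢ + Aᵢ₊₁)/2 · (zᵢ₊₁ − zᵢ)  → cm³.
```

`splenovol` implements that pipeline end to end and the formula method
beside it, so the two can be compared against ground truth:

* **phantom** — synthetic abdominal scans whose spleen is a deformed
  ellipsoid with *analytically known* volume; cohort sampling over
  ~300–2500 cm³; emulation of outlined/plain manual-labeling image pairs;
  corruption of predictions with holes and spurious components; DICOM
  series + TIFF mask I/O.
* **preprocess** — body-restricted standardization (background excluded)
  with min–max normalization to [0, 1], bottom-right 256×256 cropping,
  ±5° rotation augmentation of the training set (tripling it).
* **model** — a 2D U-Net (encoder with three 2×2 down-samplings, decoder
  with skip connections) implemented in pure NumPy (im2col convolutions,
  hand-derived backprop, Adam, combined Dice + cross-entropy loss), with
  subject-level leave-one-out cross-validation and 5-fold CV learning-rate
  tuning.
* **postprocess** — per-slice repair (hole filling → connected components
  → largest-component retention) and full-scan confinement: detect the
  slice interval containing the spleen on the per-slice area profile
  (first-zero walk, or low-value thresholding + two-cluster boundaries)
  and nullify everything outside it.
* **volumetry** — trapezoidal volume integration, automated L/D/T
  measurement from a mask, the radiologist formula, Dice coefficient
  `2|GT∩MP| / (|GT|+|MP|)`, relative volume error.
* **evaluate** — the cohort experiment: per-subject GT/formula/MP/MP-FS
  volumes, relative errors and Dice, with mean ± SD ± range summaries and
  1.5×IQR box-plot statistics, written as CSV tables, a figure and a run
  manifest.

## Worked example

```python
from splenovol import (PhantomSpec, generate_phantom, integrate_volume,
                       measure_ldt, formula_volume)
from splenovol.postprocess import area_profile

spec = PhantomSpec(semi_axes=(60, 40, 30), in_plane_spacing=(1.0, 1.0),
                   slice_spacing=3.0, grid_shape=(40, 300, 300),
                   body_radius=110.0)
scan, gt_mask, analytic = generate_phantom(spec)
vol = integrate_volume(area_profile(gt_mask, scan))
ldt = measure_ldt(gt_mask, scan.pixel_spacing, scan.slice_spacing)
print(f"analytic {analytic:.1f} cm^3, integrated {vol:.1f} cm^3")
print(f"L={ldt.L:.1f} D={ldt.D:.1f} T={ldt.T:.1f} cm "
      f"-> formula {formula_volume(ldt):.1f} cm^3")
```

prints

```
analytic 301.6 cm^3, integrated 301.8 cm^3
L=5.7 D=11.9 T=8.0 cm -> formula 343.8 cm^3
```

— integration recovers the closed-form ellipsoid volume (4/3·π·6·4·3 =
301.6 cm³) to 0.1 %, while the formula overestimates this (perfectly
ellipsoidal!) spleen by ~14 %; on deformed cohorts the gap widens.

The full comparison — leave-one-out U-Net segmentation vs the formula on
a deformed-phantom cohort — runs from the command line:

```
splenovol evaluate --n 6 --seed 0 --out results/
```

and writes `table1_dice.csv`, `table2_errors.csv`, `fig4_boxstats.csv`,
`fig4_boxplot.png` and `manifest.json`.

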