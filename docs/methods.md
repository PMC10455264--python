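# Methods

## The estimation problem

Spleen volume from an axial scan can be obtained two ways. The
segmentation route sums, per slice, the spleen-labelled pixels times the
pixel-size conversion factor (PixelSpacing row × col, mm²) to get an
area profile A(z), and integrates it over the physical slice positions z
with the trapezoid rule; the result is exact for the piecewise-linear
interpolant of the true cross-sectional area and converges quadratically
in the slice spacing away from the organ's poles. The formula route
reduces the organ to three linear measurements (L, D, T, in cm) and
evaluates 30 + 0.58·L·D·T; its implicit ellipsoid assumption makes it a
biased estimator on deformed organs. The package implements both so
their errors can be measured against a common ground truth.

## Phantoms with known volume

Real cohorts come with no analytic truth, so validation uses synthetic
phantoms: an elliptic-cylinder "body" of tissue-level intensity on an
air background, with an embedded spleen whose surface is a radially
perturbed ellipsoid,

    r(Ω) = r_ellipsoid(Ω) · (1 + A·f(Ω)),

where f is a fixed low-order combination of real spherical harmonics
(degrees 2–3), normalized to max |f| = 1, and A ∈ [0, 0.3] is the
deformation amplitude. The reference volume is (4/3)πabc exactly when
A = 0 and otherwise (abc/3)∮(1 + A·f)³ dΩ by dense angular quadrature
(512×1024 nodes; the integrand is smooth, so quadrature error is far
below voxelization error). Voxelization assigns a voxel to the spleen
when its centre lies inside the surface; at 1×1 mm in-plane and 3 mm
slices the voxel-sum volume agrees with the reference within 2% for
semi-axes ≥ 30 mm.

Intensities are three-level piecewise-constant (air 0, body 450, spleen
900, arbitrary scanner-like units) plus additive Gaussian noise with
σ = 0.03 × spleen level, clipped and quantized to uint16. This is
deliberately simpler than MR physics (no bias fields, no Rician floor,
no texture): it suffices for contrast-driven segmentation, and passing
tests on phantoms therefore demonstrate the *pipeline's* correctness —
geometry, integration, repair, confinement, cross-validation hygiene —
not clinical segmentation accuracy on real MRI.

Default sampling mirrors an abdominal protocol: 3 mm slice spacing,
sub-mm (0.9 mm) in-plane spacing, cohort volumes log-spaced over
~300–2500 cm³ (small spleens < 350 cm³ up to pronounced splenomegaly)
with bounded anisotropy and per-subject deformation amplitudes of
0.08–0.18. Spleens are auto-placed toward the image bottom-right (the
patient-left position in axial display) with strict containment checks:
spleen inside body, body inside grid, one spleen-free slice margin at
both scan ends.

The labeling emulation draws the mask's 1-pixel inner contour on the
slice in a reserved marker color (purple; grayscale content can never
equal it), and recovers the mask from the image pair by pixel
difference plus interior flood fill. The binding contract is the round
trip — extract(render(mask)) = mask for single-region masks — not visual
fidelity of the overlay; an open contour is detected (a fill with no
interior) and rejected.

`corrupt_prediction` manufactures the two failure modes the repair
chain addresses: interior holes (eroded so that filling restores the
segment exactly) and small spurious components, each strictly smaller
than its slice's spleen segment so that largest-component retention is
well posed; spurious components may also appear in spleen-free slices,
which is precisely what full-scan confinement must remove.

## Pre-processing

Body extraction uses an Otsu threshold on the whole volume (shift
invariant, parameter free), keeps the largest 3-D connected component
and fills per-slice holes. Standardization (mean subtraction, SD
division) uses body voxels only, removing body-size and background
effects; the subsequent min–max rescale to [0, 1] uses the whole volume
by default so background maps consistently near 0 (body-only extrema
are available as a config option; the choice only changes an affine
map). Cropping takes the bottom-right window (default 256×256; must
divide by 2^depth) with no padding — undersized slices fail loudly
rather than silently changing the field of view. Augmentation rotates
image (bilinear) and mask (nearest-neighbour, so masks stay binary) by
±5° about the image centre, tripling the training set; it is applied to
training slices only.

## Segmentation model

The segmenter is a 2D U-Net: an encoder that halves resolution
`depth` times (default 3) with 2×2 max pooling while doubling channels
from `base_channels` (default 8), a mirrored decoder using nearest ×2
upsampling followed by a channel-reducing 3×3 convolution, skip
connections concatenating each encoder stage into its matching decoder
stage, and a 1×1 output convolution producing per-pixel spleen logits.
An alternative encoder option ("resnet34-style") uses residual
double-convolution blocks, honoring the four-stage residual-encoder
variant of the architecture; the two options are alternatives, not
reconciled.

The network is implemented directly in NumPy: convolutions as im2col
matrix products in float32, backprop derived by hand (the gradient of a
same-padded stride-1 correlation is a correlation with the flipped,
channel-transposed kernel), verified against finite differences in the
test suite. Training uses Adam and a combined Dice + binary
cross-entropy loss (the standard choice for heavily class-imbalanced
organ masks; loss, optimizer, epochs and the 0.5 binarization threshold
are configuration with these defaults). Spleen-free slices are kept in
training by default, since full-scan prediction requires the model to
have seen empty anatomy. All randomness (initialization, batch
shuffling, fold assignment) flows from explicit seeds; runs are
bit-reproducible on a given machine.

Cross-validation is strictly subject-level: leave-one-out over the
cohort for evaluation (each subject predicted by a model that never saw
any of its slices or their augmented copies), and k-fold (default 5)
over training subjects for learning-rate selection by mean validation
Dice, with divergent candidates (non-finite loss) scoring zero.

## Post-processing and confinement

Per-slice repair: fill holes (background regions not connected to the
slice border), label connected components (8-connectivity in-plane,
configurable), keep the largest by pixel area. Ties are broken toward
the component appearing first in raster order — deterministic and
labeling-order independent. The chain is idempotent, never increases
the per-slice component count, and cannot lower Dice on the corruption
suite.

Full-scan confinement operates on the area profile. The first-zero walk
from the argmax is exact on clean unimodal profiles but truncates at
spurious interior zeros. The default cluster strategy thresholds the
profile at 5% of its maximum (no canonical value exists; 0.05 is logged
and configurable), takes the candidate indices with 0 < A ≤ threshold,
splits them at the argmax into a left and right cluster (exact 2-means
for well-separated 1-D tails), and uses the candidate nearest the
argmax on each side as the boundary; slices outside the boundary
interval are nullified. Sides without candidates fall back to the
first-zero walk; with no candidates at all the region is the positive
support. On noise-free unimodal profiles at 3 mm spacing both
strategies coincide with the positive support to within one slice
(the sub-5% zone of an ellipsoid profile is narrower than one slice for
semi-axes up to ~110 mm).

## Volumetry details

mm³ → cm³ conversion happens once, at the integration boundary. L uses
the inclusive first-to-last nonempty slice-index span × slice spacing;
an `include_endpoint_thickness` flag adds one spacing for the
convention that counts both endpoint slices' thickness. D is the exact
maximal pairwise distance between foreground pixel centres (computed on
the convex hull; the diameter is attained there), searched over all
slices; T is the perpendicular extent of the *same* slice's foreground
projected orthogonally to the D chord — measuring D and T on the same
image matches radiological practice (the alternative, T from any slice,
is configurable in principle but not default). The Dice implementation
returns 1 when both masks are empty (agreement on absence; the ratio is
0/0 there). Degenerate inputs fail explicitly: empty masks, zero GT
volumes, single-slice profiles, non-monotonic slice positions.

## Evaluation design

Per subject the harness reports: GT volume (integration of the GT
mask), formula volume (L/D/T measured from the GT mask — mirroring the
clinical workflow, where the radiologist measures on images independent
of any model), MP volume (LOOCV prediction, post-processed, restricted
to the GT spleen-bearing slice range, as in curated test sets), MP-FS
volume (full-scan prediction with confinement nullification), relative
errors of the last three against GT, and Dice(GT, MP). Cohort summaries
use the sample (n−1) standard deviation and report min–max ranges;
box-plot statistics use Q1/median/Q3 with whiskers at the most extreme
data inside 1.5×IQR fences and explicit outlier lists. Subject-subset
summaries support sensitivity analyses such as excluding the
smallest-volume subjects.

## Problem sizes

The cohort experiment (`desk_scale_experiment`) runs at a deliberately
reduced resolution chosen as this package's standard validation scale:
6–8 phantoms, 4 mm in-plane grids (~80×80 pixels), 3 mm slices, crop
size chosen automatically as the smallest multiple of 2^depth covering
every spleen, and a depth-3, 8-channel U-Net trained 4 epochs per
leave-one-out fold. At this scale the full experiment trains ~6 models
in roughly ten minutes on one CPU. The phantom geometry, spacing along
the scan axis, cohort volume range and deformation amplitudes are
unchanged from the defaults; only the in-plane sampling density and
network size are reduced, which raises voxelization noise slightly but
leaves the formula-vs-model comparison intact.

## Known limitations

* The intensity model is far simpler than MR; results quantify pipeline
  correctness, not clinical accuracy.
* The 2D model treats slices independently; no 3-D context or 3-D
  connected-component filtering (the repair chain is per-slice by
  design).
* Confinement assumes a single dominant lobe in the area profile; a
  genuinely bimodal profile (e.g. accessory spleen of comparable size)
  would confuse the boundary clustering.
* The NumPy trainer is single-threaded-BLAS fast for small networks but
  not intended for clinical-resolution training.
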