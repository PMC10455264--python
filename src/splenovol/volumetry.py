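"""Volume estimation and overlap metrics.

Two volume estimators are implemented side by side:

* **Integration** — the per-slice segmented areas (mm², from the pixel
  count times the pixel-size conversion factor) are integrated along the
  scan axis with the trapezoid rule over the physical slice positions,
  yielding cm³.  Applied to ground-truth masks this is the reference
  volume; applied to model predictions it is the automated estimate.

* **Radiologist formula** — V(cm³) = 30 + 0.58·L·D·T from three linear
  measurements (cm): the craniocaudal span L, the largest axial long-axis
  diameter D, and the largest in-plane extent T perpendicular to the D
  chord.  The formula assumes a roughly ellipsoidal organ and degrades on
  deformed (splenomegalic) spleens; :func:`measure_ldt` automates the
  three measurements from a binary mask so the formula can be evaluated
  against the same ground truth.

Segmentation overlap is scored with the Dice coefficient
2|GT∩MP| / (|GT|+|MP|).
"""

from __future__ import annotations

import numpy as np

from .core import AreaProfile, AxialMeasurements, EmptyPredictionError, MaskVolume

__all__ = [
    "integrate_volume",
    "measure_ldt",
    "formula_volume",
    "dice",
    "relative_error",
]

FORMULA_INTERCEPT_CM3 = 30.0
FORMULA_SLOPE = 0.58


def integrate_volume(profile: AreaProfile) -> float:
    """Trapezoidal integration of an area profile, in cm³.

    V = Σ_i (A_i + A_{i+1})/2 × (z_{i+1} − z_i), mm³ → cm³.  The profile
    should include the zero-area slices bracketing the organ so the
    tapering ends integrate naturally.  A single-slice profile is
    rejected (the trapezoid rule is undefined); callers may fall back to
    area × slice spacing.
    """
    if len(profile) < 2:
        raise ValueError("trapezoid integration needs at least 2 slices")
    z = profile.slice_positions
    if not (np.all(np.diff(z) > 0) or np.all(np.diff(z) < 0)):
        raise ValueError("slice_positions must be strictly monotonic")
    mm3 = float(abs(np.trapezoid(profile.areas, z)))
    return mm3 / 1000.0


def _max_diameter_chord(points: np.ndarray) -> tuple[float, np.ndarray]:
    """Maximal pairwise distance among 2-D points and its direction.

    Exact: brute force over convex-hull vertices (the diameter of a point
    set is attained on its hull); plain brute force for tiny sets.
    """
    if points.shape[0] == 1:
        return 0.0, np.array([1.0, 0.0])
    pts = points
    if points.shape[0] > 10:
        try:
            from scipy.spatial import ConvexHull

            pts = points[ConvexHull(points).vertices]
        except Exception:  # degenerate (collinear) sets
            pts = points
    diff = pts[:, None, :] - pts[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    i, j = np.unravel_index(np.argmax(d2), d2.shape)
    direction = pts[i] - pts[j]
    norm = np.linalg.norm(direction)
    if norm == 0:
        return 0.0, np.array([1.0, 0.0])
    return float(norm), direction / norm


def measure_ldt(
    mask: MaskVolume,
    pixel_spacing: tuple[float, float],
    slice_spacing: float,
    include_endpoint_thickness: bool = False,
) -> AxialMeasurements:
    """Automate the radiologist's L, D, T measurements from a mask (cm).

    L is the inclusive slice-index span of nonempty slices times the
    slice spacing (``include_endpoint_thickness`` adds one spacing to
    count both endpoint slices' thickness — the craniocaudal definition is
    ambiguous, so both conventions are exposed).  D is the maximal
    pairwise distance between foreground pixel centres over all slices,
    in physical units; T is the extent of that same slice's foreground
    projected perpendicular to the D chord, matching how radiologists
    measure both on one image.
    """
    fg_slices = mask.foreground_slices()
    if fg_slices.size == 0:
        raise EmptyPredictionError("empty mask: no measurements possible")
    span = float(fg_slices[-1] - fg_slices[0])
    if include_endpoint_thickness:
        span += 1.0
    length_cm = span * slice_spacing / 10.0

    rs, cs = pixel_spacing
    best_d, best_slice, best_dir = 0.0, int(fg_slices[0]), np.array([1.0, 0.0])
    for i in fg_slices:
        ys, xs = np.nonzero(mask.voxels[i])
        pts = np.column_stack([ys * rs, xs * cs])
        d, direction = _max_diameter_chord(pts)
        if d > best_d:
            best_d, best_slice, best_dir = d, int(i), direction
    perp = np.array([-best_dir[1], best_dir[0]])
    ys, xs = np.nonzero(mask.voxels[best_slice])
    proj = np.column_stack([ys * rs, xs * cs]) @ perp
    t_mm = float(proj.max() - proj.min()) if proj.size > 1 else 0.0
    return AxialMeasurements(
        L=length_cm,
        D=best_d / 10.0,
        T=min(t_mm, best_d) / 10.0,
        d_slice_index=best_slice,
    )


def formula_volume(m: AxialMeasurements) -> float:
    """Radiologist spleen-volume formula: 30 + 0.58 × L × D × T (cm³)."""
    return FORMULA_INTERCEPT_CM3 + FORMULA_SLOPE * m.L * m.D * m.T


def dice(gt: MaskVolume, mp: MaskVolume) -> float:
    """Dice coefficient 2|GT∩MP| / (|GT| + |MP|) over the whole volume.

    Returns 1.0 when both masks are empty (perfect agreement on absence;
    the ratio itself is 0/0 there).
    """
    if gt.shape != mp.shape:
        raise ValueError(f"shape mismatch: {gt.shape} vs {mp.shape}")
    a = gt.voxels.astype(bool)
    b = mp.voxels.astype(bool)
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


def relative_error(estimate: float, gt: float) -> float:
    """Unsigned relative volume error in percent: 100·|estimate − gt|/gt."""
    if gt <= 0:
        raise ValueError("ground-truth volume must be > 0")
    return 100.0 * abs(estimate - gt) / gt
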