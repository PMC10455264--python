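"""Prediction clean-up and full-scan confinement.

Raw per-slice predictions fail in two characteristic ways: interior holes
in an otherwise correct segment, and small spurious components away from
the spleen.  The per-slice repair chain is: fill holes → connected
components → keep the largest component (the spleen is by far the largest
plausible segment in its slice).

On a full scan, slices before and after the spleen should predict nothing,
but a model can hallucinate artifacts there.  Confinement works on the
per-slice area profile A(z): either walk from the profile maximum outward
to the first zero on each side, or threshold the profile at a small
fraction of its maximum and cluster the low-area indices into a left and a
right boundary; everything outside the confined slice interval is
nullified.  The cluster strategy is the default — the first-zero walk is
brittle when a spurious interior zero occurs inside the true spleen run.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.measure import label as _sk_label

from .core import AreaProfile, ConfinedRegion, EmptyPredictionError, MaskVolume, ScanVolume

__all__ = [
    "fill_holes",
    "connected_components",
    "keep_largest_component",
    "postprocess_volume",
    "area_profile",
    "confine_first_zero",
    "confine_cluster",
    "nullify_outside",
]

DEFAULT_LOW_THRESHOLD_FRACTION = 0.05


def fill_holes(mask_slice: np.ndarray) -> np.ndarray:
    """Fill background regions not connected to the slice border.

    Foreground never shrinks; idempotent.
    """
    return ndimage.binary_fill_holes(mask_slice.astype(bool)).astype(np.uint8)


def connected_components(mask_slice: np.ndarray, connectivity: int = 2) -> tuple[np.ndarray, dict[int, int]]:
    """Label maximal connected foreground regions and report pixel sizes.

    ``connectivity`` is in scikit-image convention: 2 means 8-connected
    in-plane (the default for organ masks), 1 means 4-connected.
    """
    labels = _sk_label(mask_slice.astype(bool), connectivity=connectivity)
    counts = np.bincount(labels.ravel())
    sizes = {int(lab): int(counts[lab]) for lab in range(1, counts.size)}
    return labels, sizes


def keep_largest_component(mask_slice: np.ndarray, connectivity: int = 2) -> np.ndarray:
    """Retain only the largest component (in pixel area) of a slice.

    Size ties are broken toward the component whose first pixel in raster
    (row, col) order comes earliest, which is deterministic and
    independent of labeling order.
    """
    labels, sizes = connected_components(mask_slice, connectivity=connectivity)
    if not sizes:
        return np.zeros_like(mask_slice, dtype=np.uint8)
    max_size = max(sizes.values())
    tied = [lab for lab, s in sizes.items() if s == max_size]
    if len(tied) == 1:
        keep = tied[0]
    else:
        flat = labels.ravel()
        keep = min(tied, key=lambda lab: int(np.argmax(flat == lab)))
    return (labels == keep).astype(np.uint8)


def postprocess_volume(mp: MaskVolume, connectivity: int = 2) -> MaskVolume:
    """Per-slice repair chain: fill holes, label components, keep largest.

    Applied independently to every slice, in that order; idempotent, never
    increases the per-slice component count, and leaves already-clean
    predictions untouched.
    """
    out = np.empty_like(mp.voxels)
    for i in range(mp.n_slices):
        out[i] = keep_largest_component(fill_holes(mp.voxels[i]), connectivity=connectivity)
    return MaskVolume(out, role="MP_pp")


def area_profile(mask: MaskVolume, scan_or_spacing: ScanVolume | tuple[float, float],
                 slice_positions: np.ndarray | None = None) -> AreaProfile:
    """Per-slice segmented area in mm² along the scan axis.

    area[i] = foreground pixel count of slice i × (row spacing × col
    spacing), the pixel-size conversion factor.
    """
    if isinstance(scan_or_spacing, ScanVolume):
        pix_area = scan_or_spacing.pixel_area_mm2
        positions = scan_or_spacing.slice_positions
    else:
        rs, cs = scan_or_spacing
        if rs <= 0 or cs <= 0:
            raise ValueError("pixel spacing must be > 0")
        pix_area = rs * cs
        if slice_positions is None:
            raise ValueError("slice_positions required when passing raw spacing")
        positions = np.asarray(slice_positions, dtype=float)
    counts = mask.voxels.sum(axis=(1, 2)).astype(float)
    return AreaProfile(areas=counts * pix_area, slice_positions=positions)


def confine_first_zero(profile: AreaProfile) -> ConfinedRegion:
    """Walk from the profile maximum outward to the first zero on each side.

    The confined region is the open interval between the two first-zero
    slices (clipped to the scan).  Fails on an all-zero profile.  Known
    failure mode: a spurious zero inside the true spleen run truncates the
    region.
    """
    areas = profile.areas
    if not np.any(areas > 0):
        raise EmptyPredictionError("all-zero area profile: nothing to confine")
    peak = int(np.argmax(areas))
    left = peak
    while left - 1 >= 0 and areas[left - 1] > 0:
        left -= 1
    right = peak
    while right + 1 < areas.size and areas[right + 1] > 0:
        right += 1
    return ConfinedRegion(left_index=left, right_index=right)


def confine_cluster(
    profile: AreaProfile,
    low_threshold_fraction: float = DEFAULT_LOW_THRESHOLD_FRACTION,
) -> ConfinedRegion:
    """Low-value thresholding + two-cluster boundary detection.

    Candidate indices are slices with 0 < area ≤ fraction × max(area).
    Splitting the candidates at the profile argmax partitions them into a
    left and a right cluster (2-means on well-separated 1-D tails); the
    boundary on each side is the candidate nearest the argmax.  All slices
    outside [left, right] are to be nullified.  If one side has no
    candidates, that side falls back to the first-zero walk; if both are
    empty, the region is the full support of positive areas.
    """
    if not 0 < low_threshold_fraction < 1:
        raise ValueError("low_threshold_fraction must be in (0, 1)")
    areas = profile.areas
    if not np.any(areas > 0):
        raise EmptyPredictionError("all-zero area profile: nothing to confine")
    peak = int(np.argmax(areas))
    thresh = low_threshold_fraction * areas[peak]
    candidates = np.flatnonzero((areas > 0) & (areas <= thresh))
    left_cands = candidates[candidates < peak]
    right_cands = candidates[candidates > peak]

    if left_cands.size == 0 and right_cands.size == 0:
        support = np.flatnonzero(areas > 0)
        return ConfinedRegion(int(support[0]), int(support[-1]))

    fz = confine_first_zero(profile)
    left = int(left_cands.max()) if left_cands.size else fz.left_index
    right = int(right_cands.min()) if right_cands.size else fz.right_index
    return ConfinedRegion(left_index=left, right_index=right)


def nullify_outside(mask: MaskVolume, region: ConfinedRegion) -> MaskVolume:
    """Zero every slice outside the confined region; inside slices untouched."""
    if region.right_index >= mask.n_slices:
        raise ValueError("region exceeds scan range")
    out = mask.voxels.copy()
    out[: region.left_index] = 0
    out[region.right_index + 1:] = 0
    return MaskVolume(out, role=mask.role)
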