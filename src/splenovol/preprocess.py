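"""Scan pre-processing: body-restricted intensity normalization, cropping,
and rotation augmentation.

The normalization statistics (mean, std) are computed over the body only,
with the air background excluded, so that patient/body size does not bias
the intensity scale; the standardized volume is then min–max rescaled to
[0, 1] globally.  Slices are cropped to a fixed window anchored at the
bottom-right corner — in axial radiological display the spleen (patient
left) sits on the image right — and the training set is augmented with
small in-plane rotations (±5°), tripling its slice count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label

from .core import DegenerateScanError, MaskVolume, ScanVolume

__all__ = [
    "PreprocConfig",
    "estimate_body_mask",
    "standardize_normalize",
    "crop_bottom_right",
    "crop_volume_bottom_right",
    "augment_rotations",
    "preprocess_scan",
]


@dataclass(frozen=True)
class PreprocConfig:
    """Pre-processing parameters.

    ``crop_size`` is the side of the square window cut from the
    bottom-right of every slice; ``rotation_degrees`` are the augmentation
    angles applied to training slices (the originals are always kept, so
    the default [-5, +5] triples the training set); ``minmax_domain``
    selects whether the final [0, 1] rescale uses global or body-only
    extrema.
    """

    crop_size: int = 256
    rotation_degrees: tuple[float, ...] = (-5.0, 5.0)
    body_mask_method: str = "otsu"
    minmax_domain: str = "global"

    def __post_init__(self) -> None:
        if self.crop_size < 1:
            raise ValueError("crop_size must be >= 1")
        if any(d == 0 for d in self.rotation_degrees):
            raise ValueError("rotation_degrees must not include 0 (original always kept)")
        if self.minmax_domain not in ("global", "body"):
            raise ValueError("minmax_domain must be 'global' or 'body'")

    def to_dict(self) -> dict:
        return {
            "crop_size": self.crop_size,
            "rotation_degrees": list(self.rotation_degrees),
            "body_mask_method": self.body_mask_method,
            "minmax_domain": self.minmax_domain,
        }


def estimate_body_mask(scan: ScanVolume) -> MaskVolume:
    """Segment the body (air background excluded) from a whole scan.

    A bimodal threshold (Otsu) on the volume separates air from tissue;
    the largest 3-D connected component is kept and its internal holes are
    filled slice-wise.  The threshold adapts to the data, so the mask is
    invariant to adding a constant to all voxels.
    """
    vol = np.asarray(scan.voxels, dtype=float)
    if vol.max() == vol.min():
        raise DegenerateScanError("constant scan: no separable body")
    t = threshold_otsu(vol)
    fg = vol > t
    if not fg.any():
        raise DegenerateScanError("thresholding produced an empty body mask")
    labels = label(fg, connectivity=1)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    body = labels == sizes.argmax()
    filled = np.empty_like(body)
    for i in range(body.shape[0]):
        filled[i] = ndimage.binary_fill_holes(body[i])
    return MaskVolume(filled.astype(np.uint8), role="body")


def standardize_normalize(scan: ScanVolume, body: MaskVolume, minmax_domain: str = "global") -> ScanVolume:
    """Standardize over body voxels, then min–max rescale to [0, 1].

    The mean and standard deviation are computed over body voxels only.
    The rescale domain is the whole volume by default so background maps
    consistently near 0; both transforms are monotone, so intensity order
    is preserved.
    """
    if body.shape != scan.shape:
        raise ValueError("body mask shape must equal scan shape")
    vol = np.asarray(scan.voxels, dtype=np.float64)
    inside = body.voxels.astype(bool)
    if inside.sum() < 2:
        raise DegenerateScanError("body mask too small for statistics")
    mu = vol[inside].mean()
    sigma = vol[inside].std()
    if sigma == 0:
        raise DegenerateScanError("zero intensity variance inside body")
    z = (vol - mu) / sigma
    domain = z[inside] if minmax_domain == "body" else z
    lo, hi = float(domain.min()), float(domain.max())
    if hi == lo:
        raise DegenerateScanError("degenerate min-max domain")
    out = np.clip((z - lo) / (hi - lo), 0.0, 1.0).astype(np.float32)
    return ScanVolume(
        voxels=out,
        pixel_spacing=scan.pixel_spacing,
        slice_spacing=scan.slice_spacing,
        slice_positions=scan.slice_positions.copy(),
    )


def crop_bottom_right(slice_2d: np.ndarray, size: int) -> np.ndarray:
    """Return the size×size window anchored at the maximal row/col corner.

    No padding: a slice smaller than the window is an error, so the field
    of view is never silently changed.
    """
    rows, cols = slice_2d.shape[:2]
    if rows < size or cols < size:
        raise ValueError(f"slice {rows}x{cols} smaller than crop size {size}")
    return slice_2d[rows - size:, cols - size:]


def crop_volume_bottom_right(voxels: np.ndarray, size: int) -> np.ndarray:
    """Apply the bottom-right crop identically to every slice of a volume."""
    return np.stack([crop_bottom_right(voxels[i], size) for i in range(voxels.shape[0])])


def augment_rotations(
    pairs: list[tuple[np.ndarray, np.ndarray]],
    degrees: tuple[float, ...] = (-5.0, 5.0),
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Augment (image, mask) slice pairs with in-plane rotations.

    Output is the originals plus one rotated copy per angle per slice
    (with the default ±5° this triples the slice count).  Images are
    resampled bilinearly, masks with nearest neighbor so they stay
    binary; rotation is about the image centre and revealed corners are
    filled with 0, the background value after normalization.
    """
    if not degrees:
        raise ValueError("degrees must be nonempty")
    out = list(pairs)
    for img, msk in pairs:
        for deg in degrees:
            rot_img = ndimage.rotate(img, deg, reshape=False, order=1, mode="constant", cval=0.0)
            rot_msk = ndimage.rotate(
                msk.astype(np.uint8), deg, reshape=False, order=0, mode="constant", cval=0
            )
            out.append((rot_img.astype(np.float32), (rot_msk > 0).astype(np.uint8)))
    return out


def preprocess_scan(
    scan: ScanVolume,
    config: PreprocConfig,
    mask: MaskVolume | None = None,
) -> tuple[ScanVolume, MaskVolume | None]:
    """Full per-scan pipeline: body mask → standardize/normalize → crop.

    The same crop is applied to the scan and (if given) the aligned mask,
    keeping them index-aligned at every stage.  Augmentation is *not*
    applied here — it belongs to the training set only.
    """
    body = estimate_body_mask(scan)
    norm = standardize_normalize(scan, body, minmax_domain=config.minmax_domain)
    cropped = crop_volume_bottom_right(norm.voxels, config.crop_size)
    out_scan = ScanVolume(
        voxels=cropped,
        pixel_spacing=scan.pixel_spacing,
        slice_spacing=scan.slice_spacing,
        slice_positions=scan.slice_positions.copy(),
    )
    out_mask = None
    if mask is not None:
        if mask.shape != scan.shape:
            raise ValueError("mask shape must equal scan shape")
        out_mask = MaskVolume(crop_volume_bottom_right(mask.voxels, config.crop_size), role=mask.role)
    return out_scan, out_mask
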