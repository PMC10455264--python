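"""Synthetic abdominal phantoms with analytically known spleen volumes.

A phantom is a stack of axial slices containing a bright elliptic-cylinder
"body" on a dark background, with an embedded spleen modelled as an
ellipsoid whose radius is perturbed by a low-order spherical-harmonic bump
(splenomegalic spleens deviate from pure ellipsoids, which is exactly what
breaks the linear-measurement volume formula).  The ground-truth mask is
the voxelization of that deformed ellipsoid and the reference volume is
known in closed form (undeformed) or by angular quadrature (deformed), so
every downstream volumetry estimate can be checked against truth.

The module also emulates the manual labeling workflow (an outlined/plain
image pair from which the filled mask is recovered), manufactures the
failure modes that post-processing must repair (interior holes, small
spurious components), and round-trips scans through a DICOM series plus
TIFF mask stacks.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.special import sph_harm_y

from .core import GeometryError, MaskVolume, MetadataError, ScanVolume

__all__ = [
    "PhantomSpec",
    "OutlinedSlicePair",
    "generate_phantom",
    "render_outlined_pair",
    "extract_mask_from_pair",
    "corrupt_prediction",
    "write_series",
    "read_series",
    "sample_cohort",
]

# Piecewise-constant intensity levels in raw scanner-like integer units.
BACKGROUND_LEVEL = 0.0
BODY_LEVEL = 450.0
SPLEEN_LEVEL = 900.0

# Reserved marker color for manual outlines (purple, per radiology overlay
# convention); grayscale image pixels always have r == g == b, so the marker
# can never collide with image content.
OUTLINE_COLOR = (160, 32, 240)

# Low-order real spherical harmonics used for the radial bump: (l, m) pairs.
_HARMONICS = ((2, 0), (2, 1), (2, 2), (3, 1), (3, 3))


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, intensity and sampling parameters of one phantom.

    Distances are mm.  ``semi_axes`` are the (x, y, z) semi-axes of the
    base spleen ellipsoid with z along the scan axis; ``deform_amplitude``
    scales a smooth radial perturbation with max |bump| = 1, so the local
    radius varies within (1 ± amplitude)× the ellipsoid radius.
    ``center`` is the spleen centre as (z, y, x) in physical mm; ``None``
    auto-places the spleen slightly toward the image bottom-right, where
    the spleen sits in axial radiological display.
    """

    semi_axes: tuple[float, float, float] = (60.0, 40.0, 30.0)
    deform_amplitude: float = 0.0
    center: tuple[float, float, float] | None = None
    body_radius: float = 120.0
    noise_sigma: float = 0.03
    in_plane_spacing: tuple[float, float] = (0.9, 0.9)
    slice_spacing: float = 3.0
    grid_shape: tuple[int, int, int] = (36, 320, 320)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.semi_axes):
            raise ValueError("semi_axes must be > 0")
        if not 0.0 <= self.deform_amplitude <= 0.3:
            raise ValueError("deform_amplitude must be in [0, 0.3]")
        if any(s <= 0 for s in self.in_plane_spacing) or self.slice_spacing <= 0:
            raise ValueError("spacings must be > 0")
        if self.body_radius <= 0:
            raise ValueError("body_radius must be > 0")

    # -- physical layout helpers ------------------------------------------
    @property
    def field_extent(self) -> tuple[float, float, float]:
        """Physical (z, y, x) extent of the voxel grid in mm."""
        nz, ny, nx = self.grid_shape
        return (
            nz * self.slice_spacing,
            ny * self.in_plane_spacing[0],
            nx * self.in_plane_spacing[1],
        )

    @property
    def body_center(self) -> tuple[float, float]:
        ez, ey, ex = self.field_extent
        return (ey / 2.0, ex / 2.0)

    def resolved_center(self) -> tuple[float, float, float]:
        if self.center is not None:
            return self.center
        ez, ey, ex = self.field_extent
        # Offset toward bottom-right, bounded so large spleens stay in body.
        a, b, c = self.semi_axes
        bound = (1.0 + self.deform_amplitude) * max(a, b)
        slack = self.body_radius - bound
        if slack <= 0:
            raise GeometryError(
                f"spleen (in-plane bound {bound:.1f} mm) cannot fit inside "
                f"body of radius {self.body_radius:.1f} mm"
            )
        off = min(0.35 * slack, 25.0)
        return (ez / 2.0, ey / 2.0 + off, ex / 2.0 + off)

    def validate_geometry(self) -> None:
        """Spleen strictly inside body, body strictly inside grid."""
        ez, ey, ex = self.field_extent
        by, bx = self.body_center
        if not (self.body_radius < by and self.body_radius < ey - by
                and self.body_radius < bx and self.body_radius < ex - bx):
            raise GeometryError("body does not fit strictly inside the grid")
        cz, cy, cx = self.resolved_center()
        a, b, c = self.semi_axes
        amp = 1.0 + self.deform_amplitude
        in_plane_bound = amp * max(a, b)
        dist = float(np.hypot(cy - by, cx - bx))
        if dist + in_plane_bound >= self.body_radius:
            raise GeometryError(
                f"spleen not strictly inside body: offset {dist:.1f} + "
                f"extent {in_plane_bound:.1f} >= body radius {self.body_radius:.1f}"
            )
        # At least one guaranteed-empty slice at each end of the scan, so
        # full-scan confinement has a spleen-free margin to work with.
        z_bound = amp * c
        if cz - z_bound <= self.slice_spacing or cz + z_bound >= ez - 2 * self.slice_spacing:
            raise GeometryError("spleen does not fit axially inside the scan with end margins")


@dataclass
class OutlinedSlicePair:
    """A plain slice and the same slice with the spleen contour drawn on it.

    Both are (rows, cols, 3) uint8 RGB; they differ exactly on the drawn
    1-pixel contour, which uses the reserved marker color.
    """

    plain: np.ndarray
    outlined: np.ndarray

    def __post_init__(self) -> None:
        if self.plain.shape != self.outlined.shape:
            raise ValueError("plain and outlined images must have identical shape")


# ---------------------------------------------------------------------------
# deformation field


def _harmonic_coeffs(seed: int) -> np.ndarray:
    rng = np.random.default_rng(np.uint32(seed) ^ np.uint32(0x5EED))
    return rng.normal(size=len(_HARMONICS))


def _real_sph_harm(l: int, m: int, theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Real-valued spherical harmonic (theta = polar angle, phi = azimuth)."""
    y = sph_harm_y(l, abs(m), theta, phi)
    if m > 0:
        return np.sqrt(2.0) * (-1.0) ** m * y.real
    if m < 0:
        return np.sqrt(2.0) * (-1.0) ** m * y.imag
    return y.real


def _bump(theta: np.ndarray, phi: np.ndarray, coeffs: np.ndarray) -> np.ndarray:
    out = np.zeros(np.broadcast(theta, phi).shape)
    for (l, m), c in zip(_HARMONICS, coeffs):
        out += c * _real_sph_harm(l, m, theta, phi)
    return out


def _bump_normalization(coeffs: np.ndarray) -> float:
    """max |bump| over the sphere, by dense angular sampling."""
    theta = np.linspace(0.0, np.pi, 181)
    phi = np.linspace(0.0, 2 * np.pi, 361)
    tt, pp = np.meshgrid(theta, phi, indexing="ij")
    return float(np.abs(_bump(tt, pp, coeffs)).max())


def deformed_radius(theta: np.ndarray, phi: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    """Normalized radius 1 + amplitude*bump(direction), max |bump| = 1."""
    if spec.deform_amplitude == 0.0:
        return np.ones(np.broadcast(theta, phi).shape)
    coeffs = _harmonic_coeffs(spec.seed)
    f = _bump(theta, phi, coeffs) / _bump_normalization(coeffs)
    return 1.0 + spec.deform_amplitude * f


def analytic_spleen_volume(spec: PhantomSpec, n_theta: int = 512, n_phi: int = 1024) -> float:
    """Reference spleen volume in cm³.

    Closed form (4/3)πabc for the undeformed ellipsoid.  For a radial
    perturbation r(Ω) = 1 + A·f(Ω) of the unit sphere mapped through the
    ellipsoid scaling, V = (abc/3)∮ r(Ω)³ dΩ, evaluated by dense angular
    quadrature (midpoint in θ with sinθ weight, periodic in φ).
    """
    a, b, c = spec.semi_axes
    if spec.deform_amplitude == 0.0:
        return 4.0 / 3.0 * np.pi * a * b * c / 1000.0
    theta = (np.arange(n_theta) + 0.5) * np.pi / n_theta
    phi = np.arange(n_phi) * 2 * np.pi / n_phi
    tt, pp = np.meshgrid(theta, phi, indexing="ij")
    r = deformed_radius(tt, pp, spec)
    integrand = (r ** 3) * np.sin(tt)
    omega = integrand.sum() * (np.pi / n_theta) * (2 * np.pi / n_phi)
    return float(a * b * c / 3.0 * omega / 1000.0)


# ---------------------------------------------------------------------------
# generation


def _voxelize_spleen(spec: PhantomSpec) -> np.ndarray:
    nz, ny, nx = spec.grid_shape
    cz, cy, cx = spec.resolved_center()
    a, b, c = spec.semi_axes
    z = (np.arange(nz) + 0.5) * spec.slice_spacing - cz
    y = (np.arange(ny) + 0.5) * spec.in_plane_spacing[0] - cy
    x = (np.arange(nx) + 0.5) * spec.in_plane_spacing[1] - cx
    zz, yy, xx = np.meshgrid(z, y, x, indexing="ij", sparse=True)
    ux, uy, uz = xx / a, yy / b, zz / c
    rho = np.sqrt(ux ** 2 + uy ** 2 + uz ** 2)
    if spec.deform_amplitude == 0.0:
        return (rho <= 1.0).astype(np.uint8)
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.arccos(np.clip(np.broadcast_to(uz, rho.shape) / np.where(rho > 0, rho, 1.0), -1, 1))
        phi = np.arctan2(np.broadcast_to(uy, rho.shape), np.broadcast_to(ux, rho.shape))
    limit = deformed_radius(theta, phi, spec)
    return (rho <= limit).astype(np.uint8)


def _body_mask(spec: PhantomSpec) -> np.ndarray:
    nz, ny, nx = spec.grid_shape
    by, bx = spec.body_center
    y = (np.arange(ny) + 0.5) * spec.in_plane_spacing[0] - by
    x = (np.arange(nx) + 0.5) * spec.in_plane_spacing[1] - bx
    yy, xx = np.meshgrid(y, x, indexing="ij")
    disk = (yy ** 2 + xx ** 2) <= spec.body_radius ** 2
    return np.broadcast_to(disk, (nz, ny, nx)).astype(np.uint8)


def generate_phantom(spec: PhantomSpec) -> tuple[ScanVolume, MaskVolume, float]:
    """Generate (scan, ground-truth mask, reference volume in cm³).

    The scan assigns distinct mean intensities to background, body tissue
    and spleen, adds Gaussian noise (sigma = ``noise_sigma`` × spleen
    level) and quantizes to nonnegative uint16, mimicking integer scanner
    units.  Deterministic for a fixed ``spec.seed``.
    """
    spec.validate_geometry()
    spleen = _voxelize_spleen(spec)
    body = _body_mask(spec)
    if np.any(spleen & ~body):
        raise GeometryError("voxelized spleen leaks outside the body")

    levels = np.full(spec.grid_shape, BACKGROUND_LEVEL, dtype=np.float64)
    levels[body == 1] = BODY_LEVEL
    levels[spleen == 1] = SPLEEN_LEVEL
    rng = np.random.default_rng(spec.seed)
    noisy = levels + rng.normal(scale=spec.noise_sigma * SPLEEN_LEVEL, size=spec.grid_shape)
    voxels = np.clip(np.rint(noisy), 0, 65535).astype(np.uint16)

    scan = ScanVolume(
        voxels=voxels,
        pixel_spacing=spec.in_plane_spacing,
        slice_spacing=spec.slice_spacing,
        slice_positions=(np.arange(spec.grid_shape[0]) + 0.5) * spec.slice_spacing,
    )
    mask = MaskVolume(spleen, role="GT")
    return scan, mask, analytic_spleen_volume(spec)


def sample_cohort(
    n: int,
    seed: int = 0,
    volume_range_cm3: tuple[float, float] = (300.0, 2500.0),
    deform_range: tuple[float, float] = (0.08, 0.18),
    in_plane_spacing: tuple[float, float] = (0.9, 0.9),
    slice_spacing: float = 3.0,
    grid_inplane: int | None = None,
) -> list[PhantomSpec]:
    """Sample a cohort of phantom specs spanning the target volume range.

    Target volumes are log-spaced over ``volume_range_cm3`` (the observed
    ground-truth spread in a splenomegaly cohort, small spleens < 350 cm³
    up to ~2500 cm³) with mild per-subject jitter; semi-axes are drawn
    around the sphere-equivalent radius with bounded anisotropy so every
    spleen fits a common grid.  The grid is sized automatically from the
    largest spleen unless ``grid_inplane`` is given.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    lo, hi = volume_range_cm3
    targets = np.exp(np.linspace(np.log(lo), np.log(hi), n))
    targets = targets * rng.uniform(0.92, 1.08, size=n)

    specs = []
    max_bound = 0.0
    draws = []
    for i, v in enumerate(targets):
        r = (3.0 * v * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
        f = rng.uniform(0.78, 1.28, size=3)
        f /= f.prod() ** (1.0 / 3.0)
        a, b, c = (r * f).tolist()
        amp = float(rng.uniform(*deform_range))
        draws.append(((a, b, c), amp, int(rng.integers(0, 2 ** 31 - 1))))
        max_bound = max(max_bound, (1 + amp) * max(a, b), (1 + amp) * c)

    body_radius = max_bound + 22.0
    if grid_inplane is None:
        grid_inplane = int(np.ceil(2 * (body_radius + 8.0) / in_plane_spacing[0]))
    nz_needed = int(np.ceil((2 * max_bound + 8 * slice_spacing) / slice_spacing))
    for (axes, amp, sd) in draws:
        specs.append(
            PhantomSpec(
                semi_axes=axes,
                deform_amplitude=amp,
                body_radius=body_radius,
                in_plane_spacing=in_plane_spacing,
                slice_spacing=slice_spacing,
                grid_shape=(nz_needed, grid_inplane, grid_inplane),
                seed=sd,
            )
        )
    return specs


# ---------------------------------------------------------------------------
# outlined-pair labeling emulation


def _to_rgb(slice_2d: np.ndarray) -> np.ndarray:
    img = np.asarray(slice_2d, dtype=float)
    vmax = img.max() if img.max() > 0 else 1.0
    gray = np.clip(np.rint(img / vmax * 255.0), 0, 255).astype(np.uint8)
    return np.stack([gray] * 3, axis=-1)


def _inner_contour(mask_2d: np.ndarray) -> np.ndarray:
    m = mask_2d.astype(bool)
    return m & ~ndimage.binary_erosion(m, structure=np.ones((3, 3)), border_value=0)


def render_outlined_pair(slice_2d: np.ndarray, mask_slice: np.ndarray) -> OutlinedSlicePair:
    """Draw the 1-pixel spleen contour on a slice in the reserved marker color.

    Emulates the manual labeling step that produces, per slice, one image
    without and one with the drawn boundary.  An empty mask yields
    ``outlined == plain``.
    """
    if slice_2d.shape != mask_slice.shape:
        raise ValueError("slice and mask shapes must match")
    plain = _to_rgb(slice_2d)
    outlined = plain.copy()
    contour = _inner_contour(mask_slice)
    outlined[contour] = OUTLINE_COLOR
    return OutlinedSlicePair(plain=plain, outlined=outlined)


def extract_mask_from_pair(pair: OutlinedSlicePair) -> np.ndarray:
    """Recover the filled binary mask from an outlined/plain image pair.

    The drawn boundary is located by pixel-wise difference and its
    interior flood-filled, reproducing boundary-plus-interior labeling.
    A boundary with no interior (an open curve, through which a fill
    would leak to the border) raises :class:`LabelingError`.
    """
    from .core import LabelingError

    boundary = np.any(pair.plain != pair.outlined, axis=-1)
    if not boundary.any():
        return np.zeros(boundary.shape, dtype=np.uint8)
    filled = ndimage.binary_fill_holes(boundary)
    if filled.sum() == boundary.sum():
        raise LabelingError("outline is not a closed curve; interior fill leaks")
    return filled.astype(np.uint8)


# ---------------------------------------------------------------------------
# prediction corruption


def corrupt_prediction(
    mask: MaskVolume,
    hole_rate: float = 0.3,
    artifact_rate: float = 0.3,
    seed: int = 0,
    artifact_in_empty: bool = True,
) -> MaskVolume:
    """Corrupt a mask the way raw model predictions fail.

    With probability ``hole_rate`` per spleen-bearing slice, punch 1–3
    small interior holes (strictly inside the segment so hole filling can
    restore it exactly).  With probability ``artifact_rate`` per slice,
    add a small spurious component, strictly smaller in pixel area than
    that slice's spleen segment (so largest-component retention is
    well-posed); in spleen-free slices a small artifact is placed
    unconditionally of size, which is what full-scan confinement must
    remove.  Deterministic per ``seed``.
    """
    if not (0 <= hole_rate <= 1 and 0 <= artifact_rate <= 1):
        raise ValueError("rates must be in [0, 1]")
    rng = np.random.default_rng(seed)
    out = mask.voxels.copy()
    n_slices, rows, cols = out.shape
    for i in range(n_slices):
        sl = out[i]
        fg = int(sl.sum())
        if fg > 0 and rng.random() < hole_rate:
            interior = ndimage.binary_erosion(sl.astype(bool), iterations=3)
            ys, xs = np.nonzero(interior)
            if ys.size:
                for _ in range(rng.integers(1, 4)):
                    j = rng.integers(0, ys.size)
                    r = int(rng.integers(1, 3))
                    yy, xx = np.ogrid[:rows, :cols]
                    hole = (yy - ys[j]) ** 2 + (xx - xs[j]) ** 2 <= r ** 2
                    sl[hole & interior] = 0
        if rng.random() < artifact_rate and (fg > 0 or artifact_in_empty):
            cap = max(2, min(fg - 1, 40)) if fg > 0 else 20
            size = int(rng.integers(2, cap + 1)) if cap >= 2 else 0
            if size > 0:
                _place_artifact(sl, size, rng)
    return MaskVolume(out, role="MP_raw")


def _place_artifact(sl: np.ndarray, size: int, rng: np.random.Generator) -> None:
    """Grow a small connected blob of ``size`` pixels away from existing foreground."""
    rows, cols = sl.shape
    excl = ndimage.binary_dilation(sl.astype(bool), iterations=3)
    free = np.nonzero(~excl)
    if free[0].size == 0:
        return
    j = rng.integers(0, free[0].size)
    y0, x0 = int(free[0][j]), int(free[1][j])
    blob = {(y0, x0)}
    frontier = [(y0, x0)]
    while len(blob) < size and frontier:
        y, x = frontier[rng.integers(0, len(frontier))]
        nbrs = [(y + dy, x + dx) for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1))]
        nbrs = [
            (yy, xx)
            for yy, xx in nbrs
            if 0 <= yy < rows and 0 <= xx < cols and (yy, xx) not in blob and not excl[yy, xx]
        ]
        if not nbrs:
            frontier.remove((y, x))
            continue
        pick = nbrs[rng.integers(0, len(nbrs))]
        blob.add(pick)
        frontier.append(pick)
    for y, x in blob:
        sl[y, x] = 1


# ---------------------------------------------------------------------------
# DICOM / TIFF series I/O


def write_series(scan: ScanVolume, mask: MaskVolume | None, directory: str | os.PathLike) -> None:
    """Write a scan as a one-file-per-slice DICOM series plus TIFF mask stack.

    DICOM slices carry PixelSpacing, SliceThickness and ImagePositionPatient
    so that :func:`read_series` can restore ordering and spacing losslessly.
    """
    import pydicom
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    os.makedirs(directory, exist_ok=True)
    if mask is not None and mask.shape != scan.shape:
        raise ValueError("mask shape must equal scan shape")
    series_uid = generate_uid(entropy_srcs=["splenovol-series"])
    voxels = scan.voxels.astype(np.uint16)
    for i in range(scan.n_slices):
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = pydicom.uid.MRImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid(entropy_srcs=[f"splenovol-{i}"])
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = Dataset()
        ds.file_meta = meta
        ds.SOPClassUID = meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.SeriesInstanceUID = series_uid
        ds.Modality = "MR"
        ds.InstanceNumber = i + 1
        ds.Rows, ds.Columns = voxels.shape[1:]
        ds.PixelSpacing = [str(scan.pixel_spacing[0]), str(scan.pixel_spacing[1])]
        ds.SliceThickness = str(scan.slice_spacing)
        ds.ImagePositionPatient = ["0", "0", str(float(scan.slice_positions[i]))]
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.PixelData = voxels[i].tobytes()
        ds.save_as(os.path.join(directory, f"slice_{i:04d}.dcm"), enforce_file_format=True)
    if mask is not None:
        import tifffile

        tifffile.imwrite(os.path.join(directory, "mask.tif"), mask.voxels.astype(np.uint8))


def read_series(directory: str | os.PathLike) -> tuple[ScanVolume, MaskVolume | None]:
    """Read a DICOM series (re-sorted by slice position) and optional mask stack.

    Raises :class:`MetadataError` on missing PixelSpacing/position tags or
    inconsistent spacing across the series — never silently defaults.
    """
    import pydicom

    files = sorted(
        os.path.join(directory, f) for f in os.listdir(directory) if f.lower().endswith(".dcm")
    )
    if not files:
        raise MetadataError(f"no DICOM files found in {directory}")
    slices = []
    for f in files:
        ds = pydicom.dcmread(f)
        if "PixelSpacing" not in ds:
            raise MetadataError(f"{os.path.basename(f)}: missing PixelSpacing tag")
        if "ImagePositionPatient" not in ds:
            raise MetadataError(f"{os.path.basename(f)}: missing ImagePositionPatient tag")
        if "SliceThickness" not in ds:
            raise MetadataError(f"{os.path.basename(f)}: missing SliceThickness tag")
        slices.append(ds)
    spacings = {(float(ds.PixelSpacing[0]), float(ds.PixelSpacing[1])) for ds in slices}
    thicknesses = {float(ds.SliceThickness) for ds in slices}
    if len(spacings) != 1 or len(thicknesses) != 1:
        raise MetadataError("inconsistent PixelSpacing/SliceThickness across series")
    slices.sort(key=lambda ds: float(ds.ImagePositionPatient[2]))
    voxels = np.stack([ds.pixel_array for ds in slices])
    positions = np.array([float(ds.ImagePositionPatient[2]) for ds in slices])
    scan = ScanVolume(
        voxels=voxels,
        pixel_spacing=spacings.pop(),
        slice_spacing=thicknesses.pop(),
        slice_positions=positions,
    )
    mask_path = os.path.join(directory, "mask.tif")
    mask = None
    if os.path.exists(mask_path):
        import tifffile

        mask = MaskVolume(tifffile.imread(mask_path), role="GT")
    return scan, mask
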