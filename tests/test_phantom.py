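"""Phantom generation, labeling emulation, corruption and series I/O."""

import os

import numpy as np
import pytest

from splenovol.core import GeometryError, LabelingError, MetadataError
from splenovol.phantom import (
    OutlinedSlicePair,
    PhantomSpec,
    analytic_spleen_volume,
    corrupt_prediction,
    extract_mask_from_pair,
    generate_phantom,
    read_series,
    render_outlined_pair,
    sample_cohort,
    write_series,
)
from splenovol.postprocess import fill_holes
from splenovol.volumetry import dice


class TestGeneratePhantom:
    def test_undeformed_volume_is_closed_form(self, ellipsoid_phantom):
        _, _, vol = ellipsoid_phantom
        assert vol == pytest.approx(4.0 / 3.0 * np.pi * 6 * 4 * 3, rel=1e-12)
        assert vol == pytest.approx(301.59, abs=0.01)

    def test_voxel_volume_within_2pct_at_default_resolution(self, ellipsoid_phantom, ellipsoid_spec):
        scan, mask, vol = ellipsoid_phantom
        voxel_vol = mask.voxels.sum() * scan.pixel_area_mm2 * scan.slice_spacing / 1000.0
        assert abs(voxel_vol - vol) / vol < 0.02

    def test_voxelization_converges_when_spacing_halved(self):
        def voxel_volume(spacing_scale):
            spec = PhantomSpec(
                semi_axes=(60.0, 40.0, 30.0),
                in_plane_spacing=(2.0 * spacing_scale, 2.0 * spacing_scale),
                slice_spacing=4.0 * spacing_scale,
                grid_shape=(int(30 / spacing_scale), int(150 / spacing_scale), int(150 / spacing_scale)),
                body_radius=110.0,
            )
            _, mask, vol = generate_phantom(spec)
            vv = mask.voxels.sum() * spec.in_plane_spacing[0] ** 2 * spec.slice_spacing / 1000.0
            return abs(vv - vol)

        assert voxel_volume(0.5) < voxel_volume(1.0)

    def test_deformed_volume_differs_and_voxelization_tracks_quadrature(self, coarse_spec, coarse_phantom):
        scan, mask, vol = coarse_phantom
        undeformed = 4.0 / 3.0 * np.pi * np.prod(coarse_spec.semi_axes) / 1000.0
        assert vol != pytest.approx(undeformed, rel=1e-6)
        voxel_vol = mask.voxels.sum() * scan.pixel_area_mm2 * scan.slice_spacing / 1000.0
        assert voxel_vol == pytest.approx(vol, rel=0.02)

    def test_deterministic_for_fixed_seed(self, coarse_spec):
        scan1, mask1, v1 = generate_phantom(coarse_spec)
        scan2, mask2, v2 = generate_phantom(coarse_spec)
        assert np.array_equal(scan1.voxels, scan2.voxels)
        assert np.array_equal(mask1.voxels, mask2.voxels)
        assert v1 == v2

    def test_spleen_outside_body_rejected(self):
        spec = PhantomSpec(
            semi_axes=(80.0, 80.0, 30.0),
            body_radius=70.0,
            in_plane_spacing=(2.0, 2.0),
            grid_shape=(30, 120, 120),
        )
        with pytest.raises(GeometryError):
            generate_phantom(spec)

    def test_distinct_intensity_levels(self, coarse_phantom):
        scan, mask, _ = coarse_phantom
        spleen_mean = scan.voxels[mask.voxels == 1].mean()
        corner = scan.voxels[:, :8, :8].mean()  # air background
        assert spleen_mean > 700
        assert corner < 100

    def test_cohort_spans_volume_range(self):
        specs = sample_cohort(8, seed=1, in_plane_spacing=(4.0, 4.0))
        vols = [analytic_spleen_volume(s) for s in specs]
        assert min(vols) < 350
        assert max(vols) > 2000
        assert all(s.deform_amplitude > 0 for s in specs)
        for s in specs:
            s.validate_geometry()


class TestOutlinedPair:
    def test_empty_mask_outlined_equals_plain(self, rng):
        img = rng.integers(0, 500, size=(20, 20))
        pair = render_outlined_pair(img, np.zeros((20, 20), dtype=np.uint8))
        assert np.array_equal(pair.plain, pair.outlined)
        assert extract_mask_from_pair(pair).sum() == 0

    def test_square_contour_pixel_count_matches_brute_force(self, rng):
        # brute-force oracle: boundary pixels of a filled square are those
        # with at least one 8-neighbour outside the mask
        mask = np.zeros((20, 20), dtype=np.uint8)
        mask[5:15, 5:15] = 1
        expected = 0
        for y in range(20):
            for x in range(20):
                if not mask[y, x]:
                    continue
                nbrs = [
                    mask[yy, xx]
                    for yy in range(max(0, y - 1), min(20, y + 2))
                    for xx in range(max(0, x - 1), min(20, x + 2))
                ]
                if len(nbrs) < 9 or not all(nbrs):
                    expected += 1
        assert expected == 36  # perimeter of a 10x10 square
        img = rng.integers(0, 500, size=(20, 20))
        pair = render_outlined_pair(img, mask)
        assert int(np.any(pair.plain != pair.outlined, axis=-1).sum()) == expected

    def test_round_trip_recovers_filled_masks(self, rng):
        yy, xx = np.mgrid[:30, :30]
        disk = ((yy - 14) ** 2 + (xx - 16) ** 2 <= 64).astype(np.uint8)
        img = rng.integers(0, 900, size=(30, 30))
        pair = render_outlined_pair(img, disk)
        assert np.array_equal(extract_mask_from_pair(pair), disk)

    def test_annulus_outline_is_filled_to_disk(self, rng):
        # an annulus-shaped drawn boundary encloses a full disk interior
        yy, xx = np.mgrid[:30, :30]
        disk = ((yy - 15) ** 2 + (xx - 15) ** 2 <= 81).astype(np.uint8)
        img = rng.integers(0, 900, size=(30, 30))
        pair = render_outlined_pair(img, disk)
        recovered = extract_mask_from_pair(pair)
        assert np.array_equal(recovered, disk)
        assert recovered.sum() > np.any(pair.plain != pair.outlined, axis=-1).sum()

    def test_open_boundary_raises_labeling_error(self, rng):
        img = rng.integers(0, 900, size=(20, 20))
        plain = np.stack([np.clip(img // 4, 0, 255).astype(np.uint8)] * 3, axis=-1)
        outlined = plain.copy()
        outlined[10, 3:17] = (160, 32, 240)  # an open stroke, not a loop
        with pytest.raises(LabelingError):
            extract_mask_from_pair(OutlinedSlicePair(plain=plain, outlined=outlined))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            render_outlined_pair(np.zeros((10, 10)), np.zeros((9, 10), dtype=np.uint8))


class TestCorruptPrediction:
    def test_zero_rates_identity(self, coarse_phantom):
        _, mask, _ = coarse_phantom
        out = corrupt_prediction(mask, hole_rate=0.0, artifact_rate=0.0, seed=7)
        assert np.array_equal(out.voxels, mask.voxels)

    def test_deterministic_per_seed(self, coarse_phantom):
        _, mask, _ = coarse_phantom
        a = corrupt_prediction(mask, 0.5, 0.5, seed=11)
        b = corrupt_prediction(mask, 0.5, 0.5, seed=11)
        assert np.array_equal(a.voxels, b.voxels)

    def test_holes_only_corruption_repaired_exactly_by_fill(self, coarse_phantom):
        _, mask, _ = coarse_phantom
        holey = corrupt_prediction(mask, hole_rate=1.0, artifact_rate=0.0, seed=5)
        assert holey.voxels.sum() < mask.voxels.sum()
        repaired = np.stack([fill_holes(holey.voxels[i]) for i in range(holey.n_slices)])
        assert np.array_equal(repaired, mask.voxels)

    def test_artifacts_strictly_smaller_than_spleen_segment(self, coarse_phantom):
        from skimage.measure import label

        _, mask, _ = coarse_phantom
        out = corrupt_prediction(mask, hole_rate=0.0, artifact_rate=1.0, seed=9)
        for i in mask.foreground_slices():
            labels = label(out.voxels[i], connectivity=2)
            sizes = sorted(np.bincount(labels.ravel())[1:], reverse=True)
            spleen_size = int(mask.voxels[i].sum())
            assert sizes[0] == spleen_size  # spleen segment untouched
            assert all(s < spleen_size for s in sizes[1:])

    def test_corruption_lowers_dice(self, coarse_phantom):
        _, mask, _ = coarse_phantom
        out = corrupt_prediction(mask, 0.5, 0.5, seed=2)
        assert dice(mask, out) < 1.0


class TestSeriesIO:
    def test_round_trip_bit_identical(self, coarse_phantom, tmp_path):
        scan, mask, _ = coarse_phantom
        write_series(scan, mask, tmp_path / "series")
        scan2, mask2 = read_series(tmp_path / "series")
        assert np.array_equal(scan.voxels, scan2.voxels)
        assert np.array_equal(mask.voxels, mask2.voxels)
        assert scan2.pixel_spacing == scan.pixel_spacing
        assert scan2.slice_spacing == scan.slice_spacing
        assert np.allclose(scan2.slice_positions, scan.slice_positions)

    def test_shuffled_file_names_resorted_by_position(self, coarse_phantom, tmp_path):
        scan, mask, _ = coarse_phantom
        d = tmp_path / "series"
        write_series(scan, mask, d)
        files = sorted(f for f in os.listdir(d) if f.endswith(".dcm"))
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(files))
        for f, p in zip(files, perm):
            os.rename(d / f, d / f"x_{p:04d}.dcm")
        scan2, _ = read_series(d)
        assert np.array_equal(scan.voxels, scan2.voxels)

    def test_missing_pixel_spacing_is_explicit_error(self, coarse_phantom, tmp_path):
        import pydicom

        scan, _, _ = coarse_phantom
        d = tmp_path / "series"
        write_series(scan, None, d)
        f = d / "slice_0003.dcm"
        ds = pydicom.dcmread(f)
        del ds.PixelSpacing
        ds.save_as(f, enforce_file_format=True)
        with pytest.raises(MetadataError, match="PixelSpacing"):
            read_series(d)

    def test_empty_directory_rejected(self, tmp_path):
        with pytest.raises(MetadataError):
            read_series(tmp_path)
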