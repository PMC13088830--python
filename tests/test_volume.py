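import numpy as np
import pytest

from canalseg.volume import (
    BinaryMask,
    CropBox,
    Volume3D,
    binarize,
    crop_to_box,
    read_volume,
    resample_volume,
    tooth_crop_box,
    write_volume,
)

from conftest import make_mask, make_volume


class TestNiftiRoundTrip:
    def test_integer_volume_identity(self, tmp_path):
        vol = make_volume(np.full((4, 4, 4), 5, np.int16), voxel=0.2)
        write_volume(vol, tmp_path / "v.nii.gz")
        back = read_volume(tmp_path / "v.nii.gz")
        np.testing.assert_array_equal(back.data, vol.data)
        np.testing.assert_allclose(back.voxel_size, vol.voxel_size, atol=1e-6)
        np.testing.assert_allclose(back.origin, vol.origin, atol=1e-6)

    def test_mask_preserves_binary_values(self, tmp_path, cube_mask):
        write_volume(cube_mask, tmp_path / "m.nii.gz")
        back = read_volume(tmp_path / "m.nii.gz", as_mask=True)
        np.testing.assert_array_equal(back.data, cube_mask.data)

    def test_origin_survives_round_trip(self, tmp_path):
        vol = make_volume(np.zeros((3, 4, 5), np.float32), voxel=0.5,
                          origin=(1.0, 2.0, 3.0))
        write_volume(vol, tmp_path / "o.nii.gz")
        back = read_volume(tmp_path / "o.nii.gz")
        np.testing.assert_allclose(back.origin, (1.0, 2.0, 3.0), atol=1e-6)
        assert back.shape == (3, 4, 5)

    def test_phantom_uct_voxel_size(self, tmp_path, sr_phantom):
        _, uct, _, _ = sr_phantom
        write_volume(uct, tmp_path / "uct.nii.gz")
        back = read_volume(tmp_path / "uct.nii.gz")
        np.testing.assert_allclose(back.voxel_size, 0.03, atol=1e-7)

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_volume(tmp_path / "absent.nii.gz")

    def test_non_3d_image_raises(self, tmp_path):
        import nibabel as nib

        img = nib.Nifti1Image(np.zeros((4, 4)), np.eye(4))
        nib.save(img, str(tmp_path / "flat.nii.gz"))
        with pytest.raises(ValueError, match="dimension"):
            read_volume(tmp_path / "flat.nii.gz")


class TestResample:
    def test_constant_volume_is_exact(self):
        vol = make_volume(np.full((8, 8, 8), 7.0), voxel=0.2)
        for mode in ("linear", "nearest"):
            out = resample_volume(vol, 0.13, mode)
            np.testing.assert_allclose(out.data, 7.0, atol=1e-5)

    def test_extent_law_64_to_128(self):
        vol = make_volume(np.zeros((64, 64, 64), np.float32), voxel=0.2)
        out = resample_volume(vol, 0.1, "linear")
        assert out.shape == (128, 128, 128)

    def test_world_extent_conserved(self):
        rng = np.random.default_rng(0)
        vol = make_volume(rng.random((17, 23, 9)).astype(np.float32), voxel=0.11)
        for target in (0.03, 0.07, 0.25):
            out = resample_volume(vol, target)
            in_extent = np.asarray(vol.shape) * vol.voxel_size
            out_extent = np.asarray(out.shape) * out.voxel_size
            assert np.all(np.abs(out_extent - in_extent) <= target + 1e-9)

    def test_identity_at_source_size(self):
        rng = np.random.default_rng(1)
        vol = make_volume(rng.random((6, 6, 6)).astype(np.float32), voxel=0.2)
        out = resample_volume(vol, 0.2, "linear")
        np.testing.assert_allclose(out.data, vol.data, atol=1e-6)

    def test_nearest_keeps_mask_binary(self, cube_mask):
        out = resample_volume(cube_mask, 0.4, "nearest")
        assert isinstance(out, BinaryMask)
        assert set(np.unique(out.data)) <= {0, 1}

    def test_allones_mask_linear_binarize_interior(self):
        ones = make_mask(np.ones((6, 6, 6), np.uint8), voxel=1.0)
        out = binarize(resample_volume(ones, 0.7, "linear"), 0.5)
        # interior of the covered region stays foreground
        assert out.data[1:-2, 1:-2, 1:-2].all()

    def test_nonpositive_target_raises(self, cube_mask):
        with pytest.raises(ValueError):
            resample_volume(cube_mask, 0.0)


class TestCrop:
    def test_full_extent_box_is_identity(self, cube_mask):
        box = CropBox((0, 0, 0), cube_mask.shape)
        out = crop_to_box(cube_mask, box)
        np.testing.assert_array_equal(out.data, cube_mask.data)
        np.testing.assert_allclose(out.origin, cube_mask.origin)

    def test_corner_crop_selects_lowest_voxels(self):
        data = np.arange(64).reshape(4, 4, 4).astype(np.float32)
        vol = make_volume(data, voxel=1.0)
        out = crop_to_box(vol, CropBox((0, 0, 0), (2, 2, 2)))
        np.testing.assert_array_equal(out.data, data[:2, :2, :2])

    def test_origin_shift(self):
        vol = make_volume(np.zeros((5, 5, 5), np.float32), voxel=0.5, origin=(1, 1, 1))
        out = crop_to_box(vol, CropBox((1, 2, 3), (4, 4, 4)))
        np.testing.assert_allclose(out.origin, (1.5, 2.0, 2.5))

    def test_empty_interval_rejected(self):
        with pytest.raises(ValueError):
            CropBox((1, 0, 0), (1, 4, 4))

    def test_out_of_range_rejected(self, cube_mask):
        with pytest.raises(ValueError):
            crop_to_box(cube_mask, CropBox((0, 0, 0), (10, 9, 9)))

    def test_crop_idempotent(self, cube_mask):
        box = CropBox((2, 2, 2), (8, 8, 8))
        once = crop_to_box(cube_mask, box)
        full = CropBox((0, 0, 0), once.shape)
        twice = crop_to_box(once, full)
        np.testing.assert_array_equal(once.data, twice.data)


class TestToothCropBox:
    def test_single_voxel_centered_window(self):
        data = np.zeros((32, 100, 100), np.uint8)
        data[16, 50, 50] = 1
        mask = make_mask(data)
        box = tooth_crop_box(mask, axial_size=64, z_margin=4)
        assert box.widths[1:] == (64, 64)
        assert box.lo[1] <= 50 < box.hi[1] and box.lo[2] <= 50 < box.hi[2]
        assert box.widths[0] == 1 + 2 * 4

    def test_z_clamped_at_grid_edge(self):
        data = np.zeros((10, 20, 20), np.uint8)
        data[0, 10, 10] = 1
        box = tooth_crop_box(make_mask(data), axial_size=16, z_margin=5)
        assert box.lo[0] == 0

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError, match="empty"):
            tooth_crop_box(make_mask(np.zeros((4, 4, 4), np.uint8)), 4)

    def test_window_smaller_than_mask_raises(self):
        data = np.zeros((4, 20, 20), np.uint8)
        data[1, 2:18, 2:18] = 1
        with pytest.raises(ValueError, match="axial_size"):
            tooth_crop_box(make_mask(data), axial_size=8)


class TestBinarize:
    def test_threshold_with_tie_to_foreground(self):
        vol = make_volume(np.full((3, 3, 3), 0.5, np.float32))
        assert binarize(vol, 0.5).count == 27

    def test_count_matches_bruteforce(self):
        rng = np.random.default_rng(2)
        data = rng.random((8, 8, 8)).astype(np.float32)
        vol = make_volume(data)
        mask = binarize(vol, 0.4)
        expect = sum(
            1
            for k in range(8) for j in range(8) for i in range(8)
            if data[k, j, i] >= 0.4
        )
        assert mask.count == expect


class TestInvariants:
    def test_voxel_size_must_be_positive(self):
        with pytest.raises(ValueError):
            Volume3D(np.zeros((2, 2, 2)), voxel_size=-1.0)

    def test_nonfinite_data_rejected(self):
        data = np.zeros((2, 2, 2))
        data[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            Volume3D(data, 1.0)

    def test_mask_values_restricted(self):
        with pytest.raises(ValueError):
            BinaryMask(np.full((2, 2, 2), 3.0), 1.0)

    def test_world_coordinate_convention(self):
        vol = make_volume(np.zeros((4, 4, 4), np.float32), voxel=0.25,
                          origin=(1.0, 0.0, -1.0))
        np.testing.assert_allclose(
            vol.index_to_world([(2, 1, 3)])[0], (1.5, 0.25, -0.25)
        )
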