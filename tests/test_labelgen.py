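import numpy as np
import pytest

from canalseg.evaluate import overlap_metrics
from canalseg.geometry import RigidTransform
from canalseg.labelgen import (
    RigidICP,
    extract_surface_points,
    groundtruth_fidelity,
    icp_register,
    threshold_uct,
    transfer_labels,
)
from canalseg.phantom import PhantomSpec, generate_tooth
from canalseg.volume import BinaryMask, Volume3D

from conftest import make_mask, make_volume


class TestThresholdUct:
    def test_tooth_mask_matches_analytic_solid(self, sr_phantom):
        _, uct, tooth_gt, _ = sr_phantom
        tooth_m, _ = threshold_uct(uct, "global", value=550)
        assert overlap_metrics(tooth_gt, tooth_m).dsc >= 0.99

    def test_canal_recovered_as_interior_cavity(self, sr_phantom):
        _, uct, _, canal_gt = sr_phantom
        _, canal_m = threshold_uct(uct, "global", value=550)
        assert overlap_metrics(canal_gt, canal_m).dsc >= 0.95

    def test_otsu_equivalent_on_phantom(self, sr_phantom):
        _, uct, tooth_gt, _ = sr_phantom
        tooth_m, _ = threshold_uct(uct, "otsu")
        assert overlap_metrics(tooth_gt, tooth_m).dsc >= 0.99

    def test_uniform_background_raises(self):
        vol = make_volume(np.full((8, 8, 8), 5.0, np.float32))
        with pytest.raises(ValueError):
            threshold_uct(vol, "global", value=100.0)


class TestExtractSurfacePoints:
    def test_cube_surface_count(self, cube_mask):
        pts = extract_surface_points(cube_mask)
        assert len(pts) == 26  # all but the center voxel

    def test_single_voxel_center(self):
        data = np.zeros((5, 5, 5), np.uint8)
        data[2, 2, 2] = 1
        pts = extract_surface_points(make_mask(data, voxel=0.5, origin=(1, 1, 1)))
        np.testing.assert_allclose(pts[0], (2.0, 2.0, 2.0))

    def test_subsampling_reproducible(self, sr_phantom):
        _, _, tooth_gt, _ = sr_phantom
        a = extract_surface_points(tooth_gt, max_points=10, seed=4)
        b = extract_surface_points(tooth_gt, max_points=10, seed=4)
        assert len(a) == 10
        np.testing.assert_array_equal(a, b)

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            extract_surface_points(make_mask(np.zeros((3, 3, 3), np.uint8)))


class TestIcpRegister:
    def test_self_alignment_is_identity(self, curved_phantom):
        _, _, tooth_gt, _ = curved_phantom
        pts = extract_surface_points(tooth_gt, 500, seed=0)
        T, rms = icp_register(pts, pts)
        assert np.abs(T.rotation - np.eye(3)).max() < 1e-6
        assert np.linalg.norm(T.translation) < 1e-6
        assert rms < 1e-6

    def test_known_transform_recovery(self, curved_phantom):
        _, _, tooth_gt, _ = curved_phantom
        pts = extract_surface_points(tooth_gt, 600, seed=1)
        pose = RigidTransform.from_axis_angle((0, 0, 1), 5.0, (0.3, -0.2, 0.1))
        T, rms = icp_register(pts, pose.apply(pts))
        err = T.compose(pose.inverse())
        assert err.angle_deg < 0.5
        assert np.linalg.norm(err.translation) < 0.02
        assert rms < 0.01

    def test_residual_log_non_increasing(self, curved_phantom):
        _, _, tooth_gt, _ = curved_phantom
        pts = extract_surface_points(tooth_gt, 600, seed=2)
        pose = RigidTransform.from_axis_angle((1, 1, 0), 12.0, (1.0, -0.5, 0.8))
        est = RigidICP().fit(pts, pose.apply(pts))
        assert np.all(np.diff(est.residuals_) <= 1e-9)

    def test_two_point_cloud_rejected(self):
        with pytest.raises(ValueError):
            icp_register(np.zeros((2, 3)), np.ones((4, 3)))

    def test_collinear_cloud_rejected(self):
        line = np.stack([np.arange(10.0)] * 3, axis=1)  # points on a line
        target = np.random.default_rng(0).normal(size=(10, 3))
        with pytest.raises(ValueError, match="degenerate"):
            icp_register(line, target)

    def test_sklearn_estimator_protocol(self):
        est = RigidICP(max_iter=50, trim_fraction=0.2)
        assert est.get_params()["max_iter"] == 50
        est.set_params(max_iter=10)
        assert est.max_iter == 10


class TestTransferLabels:
    def test_identity_same_grid_is_identity(self, sr_phantom):
        _, _, tooth_gt, _ = sr_phantom
        out = transfer_labels(tooth_gt, RigidTransform.identity(), tooth_gt)
        np.testing.assert_array_equal(out.data, tooth_gt.data)

    def test_volume_conserved_at_80um(self, sr_phantom):
        _, _, tooth_gt, _ = sr_phantom
        grid = _empty_grid(tooth_gt, 0.08)
        out = transfer_labels(tooth_gt, RigidTransform.identity(), grid)
        assert out.volume_mm3 == pytest.approx(tooth_gt.volume_mm3, rel=0.05)

    def test_thin_filament_may_vanish_at_200um(self):
        # a 1-voxel-wide 30 um filament has no support on a 200 um grid
        data = np.zeros((60, 40, 40), np.uint8)
        data[10:50, 21, 21] = 1
        fil = make_mask(data, voxel=0.03)
        grid = _empty_grid(fil, 0.2)
        out = transfer_labels(fil, RigidTransform.identity(), grid)
        assert out.count == 0

    def test_disjoint_grids_give_empty_mask(self, cube_mask):
        far = Volume3D(np.zeros((4, 4, 4), np.float32), 1.0, origin=(100, 100, 100))
        out = transfer_labels(cube_mask, RigidTransform.identity(), far)
        assert out.count == 0


def _empty_grid(like: BinaryMask, voxel: float) -> Volume3D:
    n = np.maximum(
        np.ceil(np.asarray(like.shape) * like.voxel_size / voxel).astype(int), 1
    )
    return Volume3D(np.zeros(tuple(n), np.float32), voxel, like.origin.copy())


class TestGroundtruthFidelity:
    def test_native_size_is_exact(self, sr_phantom):
        _, _, _, canal_gt = sr_phantom
        fid = groundtruth_fidelity(canal_gt, [0.03])
        assert fid[0.03] == pytest.approx(1.0)

    def test_canal_dsc_non_increasing_with_voxel_size(self, sr_phantom):
        _, _, _, canal_gt = sr_phantom
        fid = groundtruth_fidelity(canal_gt, [0.04, 0.08, 0.2])
        vals = [fid[v] for v in (0.04, 0.08, 0.2)]
        assert vals[0] >= vals[1] >= vals[2]

    def test_bulk_object_survives_coarsening(self):
        # a 4 mm cube is much larger than every tested voxel size
        n, pad = 133, 6  # 3.99 mm edge
        data = np.zeros((n + 2 * pad,) * 3, np.uint8)
        data[pad:pad + n, pad:pad + n, pad:pad + n] = 1
        cube = make_mask(data, voxel=0.03)
        fid = groundtruth_fidelity(cube, [0.04, 0.08, 0.2])
        assert all(v >= 0.95 for v in fid.values())
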