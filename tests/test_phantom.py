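import numpy as np
import pytest

from canalseg.evaluate import overlap_metrics
from canalseg.geometry import RigidTransform
from canalseg.labelgen import transfer_labels
from canalseg.phantom import (
    PhantomSpec,
    contrast_separation,
    degrade_labels,
    generate_cohort,
    generate_tooth,
    simulate_cbct,
)
from canalseg.postprocess import connected_components
from canalseg.volume import BinaryMask

from conftest import make_mask


class TestSpecValidation:
    def test_sr_must_be_single_rooted(self):
        with pytest.raises(ValueError):
            PhantomSpec(tooth_class="SR", n_roots=2).validate()

    def test_canal_taper_required(self):
        with pytest.raises(ValueError):
            PhantomSpec(canal_radius_coronal=0.1, canal_radius_apical=0.2).validate()

    def test_intensity_ordering_required(self):
        with pytest.raises(ValueError):
            PhantomSpec(enamel_intensity=500, dentin_intensity=1000).validate()

    def test_isthmus_molar_only(self):
        with pytest.raises(ValueError):
            PhantomSpec(tooth_class="SR", isthmus=True).validate()


class TestGenerateTooth:
    def test_canal_contained_in_tooth(self, sr_phantom):
        _, _, tooth_gt, canal_gt = sr_phantom
        assert not (canal_gt.as_bool() & ~tooth_gt.as_bool()).any()

    def test_straight_sr_canal_single_component(self, sr_phantom):
        _, _, _, canal_gt = sr_phantom
        assert connected_components(canal_gt, 26).n_components == 1

    def test_intensity_ordering_in_rendering(self, sr_phantom):
        spec, uct, tooth_gt, canal_gt = sr_phantom
        tooth = tooth_gt.as_bool()
        canal = canal_gt.as_bool()
        dentin_like = tooth & ~canal
        mean_tissue = uct.data[dentin_like].mean()   # dentin + enamel
        mean_canal = uct.data[canal].mean()
        assert mean_tissue > mean_canal
        # enamel cap is brighter than the overall tissue mean
        assert uct.data[dentin_like].max() > spec.dentin_intensity * 1.5

    def test_deterministic_per_seed(self):
        spec = PhantomSpec(seed=9)
        a = generate_tooth(spec)
        b = generate_tooth(spec)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.data, y.data)

    def test_molar_has_multiple_canals(self):
        spec = PhantomSpec(tooth_class="M", n_roots=2, crown_radius=1.45, seed=4)
        _, tooth_gt, canal_gt = generate_tooth(spec)
        # two root canals merge only through the pulp chamber; below the
        # chamber the mid-root slice shows two separate cross-sections
        k = int(0.4 * spec.root_length / 0.03)
        from scipy import ndimage

        _, n = ndimage.label(canal_gt.data[k])
        assert n == 2


class TestSimulateCbct:
    def test_degenerate_degradation_is_pure_resample(self, sr_phantom):
        _, uct, tooth_gt, _ = sr_phantom
        cbct = simulate_cbct(uct, 0.12, psf_sigma=0.0, noise_sd=0.0, seed=0)
        interior = transfer_labels(tooth_gt, RigidTransform.identity(), cbct)
        # means over the tooth interior are preserved by interpolation
        assert np.isclose(
            cbct.data[interior.as_bool()].mean(),
            uct.data[tooth_gt.as_bool()].mean(),
            rtol=0.05,
        )

    def test_blur_preserves_interior_mean(self, sr_phantom):
        """A 0.1 mm PSF redistributes intensity but keeps the interior mean."""
        _, uct, tooth_gt, _ = sr_phantom
        cbct = simulate_cbct(uct, 0.08, psf_sigma=0.1, noise_sd=0.0, seed=0)
        from scipy import ndimage

        # interior = tooth (canal space included) clear of the outer surface
        core = ndimage.binary_erosion(tooth_gt.as_bool(), iterations=6)
        core_mask = BinaryMask(core.astype(np.uint8), tooth_gt.voxel_size,
                               tooth_gt.origin)
        t = transfer_labels(core_mask, RigidTransform.identity(), cbct)
        assert np.isclose(cbct.data[t.as_bool()].mean(),
                          uct.data[core].mean(), rtol=0.01)

    def test_seeded_reproducibility(self, sr_phantom):
        _, uct, _, _ = sr_phantom
        a = simulate_cbct(uct, 0.2, seed=5)
        b = simulate_cbct(uct, 0.2, seed=5)
        c = simulate_cbct(uct, 0.2, seed=6)
        np.testing.assert_array_equal(a.data, b.data)
        assert not np.array_equal(a.data, c.data)
        # different seeds differ only in the additive noise
        na = simulate_cbct(uct, 0.2, noise_sd=0.0, seed=5)
        nc = simulate_cbct(uct, 0.2, noise_sd=0.0, seed=6)
        np.testing.assert_array_equal(na.data, nc.data)

    def test_target_not_coarser_than_source_rejected(self, sr_phantom):
        _, uct, _, _ = sr_phantom
        with pytest.raises(ValueError):
            simulate_cbct(uct, 0.01)

    def test_contrast_loss_at_coarse_voxels(self, sr_phantom):
        """Canal-dentin separation shrinks from the 80 um to the 200 um scan."""
        _, uct, tooth_gt, canal_gt = sr_phantom
        seps = {}
        for voxel in (0.08, 0.2):
            cbct = simulate_cbct(uct, voxel, seed=2)
            canal_t = transfer_labels(canal_gt, RigidTransform.identity(), cbct)
            tooth_t = transfer_labels(tooth_gt, RigidTransform.identity(), cbct)
            dentin_t = BinaryMask(
                (tooth_t.as_bool() & ~canal_t.as_bool()).astype(np.uint8),
                cbct.voxel_size, cbct.origin,
            )
            seps[voxel] = contrast_separation(cbct, canal_t, dentin_t)
        assert seps[0.2] < seps[0.08]


class TestDegradeLabels:
    def test_identity_when_no_degradation(self, cube_mask):
        out = degrade_labels(cube_mask, 0, 0.0)
        np.testing.assert_array_equal(out.data, cube_mask.data)

    def test_single_dilation_matches_bruteforce_count(self, cube_mask):
        out = degrade_labels(cube_mask, 1, 0.0)
        # brute-force face-dilation of a 3^3 cube: 27 + 6 faces * 9
        assert out.count == 27 + 6 * 9

    def test_superset_gives_full_recall_lower_precision(self, cube_mask):
        out = degrade_labels(cube_mask, 1, 0.0)
        r = overlap_metrics(cube_mask, out)
        assert r.sen == 1.0
        precision = r.n_intersection / r.n_seg
        assert precision < 1.0

    def test_count_monotone_in_dilation(self, cube_mask):
        counts = [degrade_labels(cube_mask, d, 0.0).count for d in range(4)]
        assert all(b >= a for a, b in zip(counts, counts[1:]))

    def test_jitter_preserves_eroded_core(self, sr_phantom):
        _, _, tooth_gt, _ = sr_phantom
        from scipy import ndimage

        out = degrade_labels(tooth_gt, 1, boundary_jitter_sd=1.0, seed=3)
        core = ndimage.binary_erosion(tooth_gt.as_bool())
        assert not (core & ~out.as_bool()).any()


class TestGenerateCohort:
    def test_deterministic(self):
        a = generate_cohort(2, 1, voxel=0.2, seed=1)
        b = generate_cohort(2, 1, voxel=0.2, seed=1)
        for pa, pb in zip(a, b):
            np.testing.assert_array_equal(pa.uct.data, pb.uct.data)
            np.testing.assert_array_equal(pa.cbct.data, pb.cbct.data)

    def test_pair_invariants(self):
        pairs = generate_cohort(2, 1, voxel=0.2, seed=2)
        assert len(pairs) == 3
        for p in pairs:
            assert not (p.canal_gt.as_bool() & ~p.tooth_gt.as_bool()).any()
            assert p.tooth_gt.same_grid(p.canal_gt)
            assert p.cbct.voxel_size[0] == pytest.approx(0.2)
            assert p.pose.is_orthonormal(tol=1e-6)
            assert p.pose.angle_deg <= 10.0 + 1e-6

    def test_empty_cohort(self):
        assert generate_cohort(0, 0, seed=0) == []
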