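"""Phantom cohort generator: geometry, bias fields, determinism."""

import numpy as np
import pytest
from scipy import ndimage

from fetquant import (
    BiasFieldModel,
    PhantomError,
    PhantomSpec,
    TumorFocus,
    apply_bias,
    generate_cohort,
    generate_phantom,
    make_bias_field,
    make_followup,
)
from fetquant.phantom import (
    DEFAULT_METHOD_PROFILES,
    MethodProfile,
    Nodule,
    sample_scale_errors,
)


class TestGeneratePhantom:
    def test_truth_mask_matches_analytic_sphere(self, small_spec, small_scene):
        focus = small_scene.spec.tumor_foci[0]
        vox_ml = small_scene.truth_activity.voxel_volume_ml
        measured_ml = small_scene.tumor_truth_mask.sum() * vox_ml
        analytic_ml = 4.0 / 3.0 * np.pi * focus.radius_mm**3 / 1000.0
        shell_ml = 4.0 * np.pi * focus.radius_mm**2 * max(small_spec.spacing) / 1000.0
        assert abs(measured_ml - analytic_ml) < shell_ml
        # and voxel-exactly: the truth mask is the set of voxel centres
        # strictly inside the focus radius
        idx = np.indices(small_spec.grid_shape)
        c = focus.center_vox
        r_mm = np.sqrt(
            sum(((idx[i] - c[i]) * small_spec.spacing[i]) ** 2 for i in range(3))
        )
        assert np.array_equal(small_scene.tumor_truth_mask, r_mm < focus.radius_mm)

    def test_truth_background_is_uniform_outside_foci(self, small_scene):
        scene = small_scene
        focus = scene.spec.tumor_foci[0]
        idx = np.indices(scene.truth_activity.shape)
        c = focus.center_vox
        r_mm = np.sqrt(
            sum(((idx[i] - c[i]) * scene.truth_activity.spacing[i]) ** 2 for i in range(3))
        )
        outside_focus = scene.brain_mask & (r_mm > focus.radius_mm + focus.penumbra_mm)
        assert np.allclose(
            scene.truth_activity.values[outside_focus], scene.spec.background_uptake
        )

    def test_no_foci_is_rejected(self):
        with pytest.raises(PhantomError, match="focus"):
            generate_phantom(PhantomSpec(grid_shape=(32, 32, 32), tumor_foci=()))

    def test_subthreshold_contrast_is_rejected(self):
        spec = PhantomSpec(
            grid_shape=(32, 32, 32),
            spacing=(4.0, 4.0, 4.0),
            tumor_foci=(TumorFocus((20, 16, 16), 10.0, 1.5),),
        )
        with pytest.raises(PhantomError, match="1.6"):
            generate_phantom(spec)

    def test_deterministic_for_fixed_spec(self, small_spec):
        a = generate_phantom(small_spec)
        b = generate_phantom(small_spec)
        assert np.array_equal(a.truth_activity.values, b.truth_activity.values)
        for name in ("brain_mask", "tumor_truth_mask", "background_roi_mask",
                     "exclusion_mask", "skull_mask"):
            assert np.array_equal(getattr(a, name), getattr(b, name))

    def test_mask_algebra_invariants_on_random_specs(self):
        rng = np.random.default_rng(11)
        shape, spacing = (40, 40, 40), (3.0, 3.0, 3.0)
        for _ in range(100):
            side = 1 if rng.random() < 0.5 else -1
            center = (
                int(20 + side * rng.integers(4, 9)),
                int(rng.integers(14, 26)),
                int(rng.integers(16, 24)),
            )
            spec = PhantomSpec(
                grid_shape=shape,
                spacing=spacing,
                tumor_foci=(
                    TumorFocus(center, float(rng.uniform(8, 14)),
                               float(rng.uniform(2.0, 4.5))),
                ),
                noise_sd=0.0,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            scene = generate_phantom(spec)
            assert not (scene.background_roi_mask & scene.tumor_truth_mask).any()
            assert (scene.background_roi_mask & ~scene.brain_mask).sum() == 0
            assert not (scene.exclusion_mask & scene.brain_mask).any()
            assert scene.tumor_truth_mask.sum() > 0
            assert scene.background_roi_mask.sum() > 0

    def test_roi_respects_distance_and_hemisphere(self, small_scene):
        focus = small_scene.spec.tumor_foci[0]
        spacing = small_scene.truth_activity.spacing
        roi_idx = np.argwhere(small_scene.background_roi_mask)
        c = np.asarray(focus.center_vox) * np.asarray(spacing)
        dists = np.linalg.norm(roi_idx * np.asarray(spacing) - c, axis=1)
        assert (dists >= focus.radius_mm + small_scene.spec.roi_min_distance_mm).all()
        # contralateral: all ROI voxels on the other side of the midline
        mid = (small_scene.truth_activity.shape[0] - 1) / 2
        assert ((roi_idx[:, 0] - mid) * np.sign(focus.center_vox[0] - mid) < 0).all()


class TestMakeBiasField:
    def test_identity_model_gives_unit_field(self, small_scene):
        field = make_bias_field(BiasFieldModel(), small_scene.brain_mask,
                                small_scene.truth_activity.spacing)
        assert np.allclose(field.values, 1.0, atol=1e-12)

    def test_linear_gradient_endpoints(self, small_scene):
        model = BiasFieldModel(gradient_surface=-0.15, gradient_center=-0.05)
        field = make_bias_field(model, small_scene.brain_mask,
                                small_scene.truth_activity.spacing)
        depth = ndimage.distance_transform_edt(
            small_scene.brain_mask, sampling=small_scene.truth_activity.spacing
        )
        inside = small_scene.brain_mask
        edge_val = field.values[inside][np.argmin(depth[inside])]
        deep_val = field.values[inside][np.argmax(depth[inside])]
        assert edge_val == pytest.approx(0.85, abs=1e-6)
        assert deep_val == pytest.approx(0.95, abs=1e-6)

    def test_nodule_closed_form_at_center(self, small_scene):
        center = small_scene.spec.tumor_foci[0].center_vox
        model = BiasFieldModel(
            gradient_surface=-0.10, gradient_center=-0.02,
            nodules=(Nodule(center, fwhm_mm=20.0, amplitude=0.10),),
        )
        field = make_bias_field(model, small_scene.brain_mask,
                                small_scene.truth_activity.spacing)
        no_nodule = make_bias_field(
            BiasFieldModel(gradient_surface=-0.10, gradient_center=-0.02),
            small_scene.brain_mask, small_scene.truth_activity.spacing,
        )
        expected = 1.10 * no_nodule.values[center]
        assert field.values[center] == pytest.approx(expected, rel=1e-12)

    def test_field_is_global_scale_outside_brain(self, small_scene):
        model = BiasFieldModel(global_scale=0.9, gradient_surface=-0.1)
        field = make_bias_field(model, small_scene.brain_mask,
                                small_scene.truth_activity.spacing)
        assert np.allclose(field.values[~small_scene.brain_mask], 0.9)

    def test_nonpositive_field_aborts(self, small_scene):
        model = BiasFieldModel(gradient_surface=-1.5)
        with pytest.raises(PhantomError, match="positive"):
            make_bias_field(model, small_scene.brain_mask,
                            small_scene.truth_activity.spacing)


class TestApplyBias:
    def test_identity_field_no_noise_is_identity(self, small_scene):
        truth = small_scene.truth_activity
        ones = truth.copy_with(np.ones(truth.shape))
        out = apply_bias(truth, ones, noise_sd=0.0)
        assert np.array_equal(out.values, truth.values)

    def test_uniform_field_scales_exactly(self, small_scene):
        truth = small_scene.truth_activity
        field = truth.copy_with(np.full(truth.shape, 0.851))
        out = apply_bias(truth, field, noise_sd=0.0)
        assert np.array_equal(out.values, truth.values * 0.851)

    def test_noise_sd_is_calibrated(self):
        from fetquant import VolumeImage

        truth = VolumeImage(np.ones((50, 50, 50)))  # 125k voxels
        field = truth.copy_with(np.ones(truth.shape))
        out = apply_bias(truth, field, noise_sd=0.05, seed=12345)
        rel = out.values / truth.values - 1.0
        assert 0.048 < rel.std() < 0.052

    def test_seed_reproducibility(self, small_scene):
        truth = small_scene.truth_activity
        field = truth.copy_with(np.ones(truth.shape))
        a = apply_bias(truth, field, noise_sd=0.05, seed=3)
        b = apply_bias(truth, field, noise_sd=0.05, seed=3)
        c = apply_bias(truth, field, noise_sd=0.05, seed=4)
        assert np.array_equal(a.values, b.values)
        assert not np.array_equal(a.values, c.values)


class TestMakeFollowup:
    def test_zero_change_reproduces_ground_truth(self, small_scene):
        fu = make_followup(small_scene, 0.0, 0.0)
        assert np.array_equal(fu.tumor_truth_mask, small_scene.tumor_truth_mask)
        assert np.array_equal(fu.truth_activity.values,
                              small_scene.truth_activity.values)

    def test_twenty_percent_growth_voxelizes_within_band(self):
        spec = PhantomSpec(
            grid_shape=(80, 80, 80), spacing=(1.5, 1.5, 1.5),
            tumor_foci=(TumorFocus((49, 44, 40), 15.0, 3.0),), noise_sd=0.0,
        )
        scene = generate_phantom(spec)
        fu = make_followup(scene, 20.0, 0.0)
        ratio = fu.tumor_truth_mask.sum() / scene.tumor_truth_mask.sum()
        assert 1.18 <= ratio <= 1.22

    def test_tbr_change_scales_truth_contrast(self, small_scene):
        fu = make_followup(small_scene, 0.0, 10.0)
        focus = small_scene.spec.tumor_foci[0]
        peak_before = small_scene.truth_activity.values[focus.center_vox]
        peak_after = fu.truth_activity.values[focus.center_vox]
        # centre value is B * (1 + (c - 1) * (1 + core_peaking))
        g0 = 1.0 + focus.core_peaking
        expected = (1 + (3.0 * 1.1 - 1) * g0) / (1 + (3.0 - 1) * g0)
        assert peak_after / peak_before == pytest.approx(expected, rel=1e-6)

    def test_shrinkage_below_1ml_floor_is_rejected(self, small_scene):
        with pytest.raises(PhantomError, match="1 mL"):
            make_followup(small_scene, -99.0, 0.0)


class TestGenerateCohort:
    def test_identity_profile_recovers_truth_up_to_noise(self):
        identity = MethodProfile(scale_err_mean=0.0, scale_err_sd=0.0,
                                 scale_err_max=0.01)
        records = generate_cohort(
            1, {"IDENT": identity}, seed=5,
            grid_shape=(40, 40, 40), spacing=(3.0, 3.0, 3.0), noise_sd=0.0,
        )
        (rec,) = records
        assert np.array_equal(
            rec.scene.biased_images["IDENT"].values,
            rec.scene.truth_activity.values,
        )
        assert np.array_equal(
            rec.scene.biased_images["CTAC"].values,
            rec.scene.truth_activity.values,
        )

    def test_truncated_normal_injection_recovers_profile_mean(self, rng):
        profile = DEFAULT_METHOD_PROFILES["RESOLUTE"]
        errors = sample_scale_errors(profile, 50, rng)
        assert abs(errors).max() <= profile.scale_err_max
        assert errors.mean() * 100 == pytest.approx(-1.9, abs=0.6)

    def test_followup_count_is_round_of_fraction(self):
        records = generate_cohort(
            6, {"R": DEFAULT_METHOD_PROFILES["RESOLUTE"]},
            followup_fraction=1 / 3, seed=2,
            grid_shape=(40, 40, 40), spacing=(3.0, 3.0, 3.0), noise_sd=0.0,
        )
        n_followups = sum(1 for r in records if r.timepoint == "followup")
        assert n_followups == 2
        assert len(records) == 8

    def test_cohort_reproducible_from_seed(self):
        kwargs = dict(
            method_profiles={"R": DEFAULT_METHOD_PROFILES["RESOLUTE"]},
            followup_fraction=0.5, seed=9,
            grid_shape=(40, 40, 40), spacing=(3.0, 3.0, 3.0), noise_sd=0.02,
        )
        a = generate_cohort(2, **kwargs)
        b = generate_cohort(2, **kwargs)
        assert len(a) == len(b)
        for ra, rb in zip(a, b):
            assert ra.injected == rb.injected
            assert np.array_equal(
                ra.scene.biased_images["R"].values,
                rb.scene.biased_images["R"].values,
            )

    def test_injected_global_scale_recovered_as_tmean_error(self):
        """On a noiseless scene with pure global bias the measured T_MEAN
        relative error equals the injected scale error."""
        from fetquant import background_mean, delineate_btv

        # a radius that is not a multiple of the spacing, so no voxel centre
        # sits exactly on the isocontour (where strict thresholding would be
        # sensitive to last-ulp rounding under rescaling)
        spec = PhantomSpec(grid_shape=(48, 48, 48), spacing=(3.0, 3.0, 3.0),
                           tumor_foci=(TumorFocus((31, 27, 25), 12.7, 3.0),),
                           noise_sd=0.0)
        scene = generate_phantom(spec)
        model = BiasFieldModel(global_scale=0.93)
        field = make_bias_field(model, scene.brain_mask, spec.spacing)
        biased = apply_bias(scene.truth_activity, field, 0.0)

        def tmean(img):
            b = background_mean(img, scene.background_roi_mask)
            return delineate_btv(img, b, scene.exclusion_mask,
                                 scene.tumor_truth_mask).t_mean

        rel_err_pct = 100 * (tmean(biased) - tmean(scene.truth_activity)) / tmean(
            scene.truth_activity
        )
        assert rel_err_pct == pytest.approx(-7.0, abs=0.5)
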