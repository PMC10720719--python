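"""Normalization and registration: masks, bias, modal scaling, rigid/warp,
MDT, propagation, smoothing."""

import numpy as np
import pytest

from mntrace.image import BrainMask, VolumeImage
from mntrace.phantom import GroupPlan, PhantomSpec, make_phantom_atlas, simulate_subject
from mntrace.preprocess import (
    FWHM_TO_SIGMA,
    RigidConfig,
    WarpConfig,
    build_mdt,
    compute_brain_mask,
    correct_bias,
    erode_mask,
    estimate_bias_field,
    estimate_warp,
    histogram_mode,
    modal_scale,
    ncc,
    propagate_to_timepoints,
    register_rigid,
    smooth_gaussian,
)
from mntrace.transforms import ComposedTransform, RigidTransform, resample

from conftest import clean_spec


def _dice(a, b) -> float:
    return 2.0 * (a & b).sum() / (a.sum() + b.sum())


def _ellipsoid_image(value=100.0, shape=(40, 40, 32), semi=(1.4, 1.4, 1.1)):
    aff = np.eye(4)
    aff[:3, :3] = np.diag([0.1, 0.1, 0.1])
    aff[:3, 3] = -(np.asarray(shape) - 1) / 2 * 0.1
    img = VolumeImage(np.zeros(shape, dtype=np.float32), aff)
    w = img.world_grid()
    mask = (np.einsum("...d,...d->...", w / np.asarray(semi), w / np.asarray(semi)) <= 1.0)
    vox = np.zeros(shape, dtype=np.float32)
    vox[mask] = value
    return VolumeImage(vox, aff), mask


class TestBrainMask:
    def test_noiseless_phantom_mask_matches_support(self, clean_atlas):
        sessions, _ = simulate_subject(clean_spec(), "ACA", 0, atlas=clean_atlas)
        mask = compute_brain_mask(sessions[0].image)
        support = clean_atlas.meta["brain_support"]
        # the template is PSF band-limited, so the thresholded edge can move
        # by a fraction of a voxel; interior agreement must be essentially exact
        assert _dice(mask.data, support) > 0.99

    def test_single_connected_component(self, clean_atlas):
        sessions, _ = simulate_subject(clean_spec(), "ACA", 0, atlas=clean_atlas)
        from scipy import ndimage

        mask = compute_brain_mask(sessions[0].image)
        _, n = ndimage.label(mask.data, structure=ndimage.generate_binary_structure(3, 1))
        assert n == 1

    def test_default_noise_dice_against_truth_support(self, default_atlas):
        spec = PhantomSpec(seed=7)
        sessions, truth = simulate_subject(spec, "ACA", 0, atlas=default_atlas)
        pre = sessions[0].image
        mask = compute_brain_mask(pre)
        # truth support in the subject frame: pull the atlas support through
        # the planted transform with nearest-neighbour interpolation
        supp = resample(
            VolumeImage(default_atlas.meta["brain_support"].astype(np.float32), default_atlas.gray.affine),
            truth.transform,
            pre,
            interp="nearest",
        ).voxels.astype(bool)
        assert _dice(mask.data, supp) >= 0.98

    def test_constant_image_rejected(self):
        img = VolumeImage(np.ones((10, 10, 10), dtype=np.float32))
        with pytest.raises(ValueError, match="Otsu"):
            compute_brain_mask(img)


class TestBiasCorrection:
    def test_planted_polynomial_bias_removed(self):
        img, m = _ellipsoid_image()
        w = img.world_grid()
        planted = np.exp(0.1 * w[..., 0] + 0.08 * w[..., 1] * w[..., 2] - 0.05 * w[..., 2] ** 2)
        biased = img.like(img.voxels * planted.astype(np.float32))
        mask = BrainMask(m, img.affine)
        out = correct_bias(biased, mask, order=3)
        residual = out.voxels[m] / img.voxels[m]
        residual /= residual.mean()
        assert np.abs(residual - 1).max() <= 1e-3

    def test_bias_free_image_unchanged(self):
        img, m = _ellipsoid_image()
        out = correct_bias(img, BrainMask(m, img.affine))
        np.testing.assert_allclose(out.voxels[m], img.voxels[m], rtol=1e-6)

    def test_in_mask_mean_preserved(self):
        img, m = _ellipsoid_image()
        w = img.world_grid()
        biased = img.like(img.voxels * np.exp(0.15 * w[..., 0]).astype(np.float32))
        out = correct_bias(biased, BrainMask(m, img.affine))
        assert out.voxels[m].mean() == pytest.approx(biased.voxels[m].mean() / np.exp(0.15 * w[..., 0])[m].mean(), rel=2e-3)
        # geometric-mean normalization keeps the intensity scale
        assert out.voxels[m].mean() == pytest.approx(100.0, rel=1e-2)

    def test_nonpositive_intensities_rejected(self):
        img, m = _ellipsoid_image()
        vox = img.voxels.copy()
        vox[tuple(np.argwhere(m)[0])] = -1.0
        with pytest.raises(ValueError, match="positive"):
            correct_bias(img.like(vox), BrainMask(m, img.affine))

    def test_field_estimated_on_pre_transfers_to_post(self):
        """The pre-estimated field removes the same subject bias from a
        post-injection image exactly (the phantom bias is session-constant)."""
        img, m = _ellipsoid_image()
        w = img.world_grid()
        field = np.exp(0.12 * w[..., 0] - 0.07 * w[..., 1])
        pre = img.like(img.voxels * field.astype(np.float32))
        post = img.like(img.voxels * 1.1 * field.astype(np.float32))
        est = estimate_bias_field(pre, BrainMask(m, img.affine))
        from mntrace.preprocess import apply_bias_field

        out = apply_bias_field(post, est)
        ratio = out.voxels[m] / img.voxels[m]
        assert np.abs(ratio / ratio.mean() - 1).max() <= 1e-3


class TestHistogramModeAndScaling:
    def test_constant_image_mode_is_value(self):
        img, m = _ellipsoid_image(value=7.0)
        assert histogram_mode(img, BrainMask(m, img.affine)) == pytest.approx(7.0)

    def test_bimodal_mixture_mode_near_taller_component(self):
        rng = np.random.default_rng(1)
        vals = np.concatenate(
            [rng.normal(100.0, 3.0, 40000), rng.normal(60.0, 3.0, 15000)]
        )
        img = VolumeImage(vals.reshape(50, 50, 22).astype(np.float32))
        m = BrainMask(np.ones(img.shape, dtype=bool), img.affine)
        mode = histogram_mode(img, m)
        lo, hi = np.percentile(vals, [1, 99])
        bin_width = (hi - lo) / 256
        assert abs(mode - 100.0) <= max(bin_width, 1.0)

    def test_scale_equivariance(self, clean_atlas):
        img = clean_atlas.gray
        m = BrainMask(clean_atlas.meta["brain_support"], img.affine)
        mode = histogram_mode(img, m)
        mode_scaled = histogram_mode(img.like(img.voxels * 3.0), m)
        vals = img.voxels[m.data]
        lo, hi = np.percentile(vals, [1, 99])
        assert abs(mode_scaled - 3.0 * mode) <= 3.0 * (hi - lo) / 256

    def test_too_few_voxels_rejected(self):
        img = VolumeImage(np.random.default_rng(0).normal(size=(6, 6, 6)).astype(np.float32))
        m = BrainMask(np.ones(img.shape, dtype=bool), img.affine)
        with pytest.raises(ValueError, match="n_bins"):
            histogram_mode(img, m)

    def test_modal_scale_factor_and_identity(self):
        img, m = _ellipsoid_image(value=50.0)
        mask = BrainMask(m, img.affine)
        out, factor = modal_scale(img, mask, 100.0)
        assert factor == pytest.approx(2.0)
        np.testing.assert_allclose(out.voxels, img.voxels * 2.0)
        _, f2 = modal_scale(out, mask, 100.0)
        assert f2 == pytest.approx(1.0, abs=1e-6)

    def test_modal_scale_roundtrip_on_phantom(self, default_atlas):
        sessions, _ = simulate_subject(PhantomSpec(seed=3), "ACA", 0, atlas=default_atlas)
        img = sessions[0].image
        mask = erode_mask(compute_brain_mask(img), 0.25)
        out, _ = modal_scale(correct_bias(img, mask), mask, 100.0)
        vals = out.voxels[mask.data]
        lo, hi = np.percentile(vals, [1, 99])
        assert abs(histogram_mode(out, mask) - 100.0) <= (hi - lo) / 256

    def test_nonpositive_mode_rejected(self):
        img, m = _ellipsoid_image(value=-5.0)
        with pytest.raises(ValueError):
            modal_scale(img, BrainMask(m, img.affine), 100.0)


class TestRigid:
    def test_self_registration_is_identity(self, clean_atlas):
        img = clean_atlas.gray
        t = register_rigid(img, img, fixed_mask=clean_atlas.meta["brain_support"])
        assert np.abs(t.translation_mm).max() < 0.02
        assert np.abs(t.rotation_deg).max() < 0.05

    def test_planted_offset_recovered(self, clean_atlas):
        spec = clean_spec(rigid_jitter_mm=0.3, rigid_jitter_deg=3.0)
        sessions, truth = simulate_subject(spec, "ACA", 0, atlas=clean_atlas)
        moving = sessions[0].image
        t = register_rigid(moving, clean_atlas.gray, fixed_mask=clean_atlas.meta["brain_support"])
        # composition with the planted transform must be the identity
        R_comp = truth.rigid.rotation_matrix() @ t.rotation_matrix()
        angle = np.degrees(np.arccos(np.clip((np.trace(R_comp) - 1) / 2, -1, 1)))
        assert angle <= 0.2
        pts = clean_atlas.gray.world_grid()[clean_atlas.meta["brain_support"]][::500]
        res = truth.rigid.map_points(t.map_points(pts)) - pts
        assert np.linalg.norm(res, axis=1).mean() <= 0.05

    def test_alignment_never_decreases_ncc(self, default_atlas):
        spec = PhantomSpec(seed=11)
        sessions, _ = simulate_subject(spec, "ILPL", 1, atlas=default_atlas)
        moving = sessions[0].image
        fixed = default_atlas.gray
        support = default_atlas.meta["brain_support"]
        t = register_rigid(moving, fixed, fixed_mask=support)
        before = ncc(moving.voxels, fixed.voxels, support)
        after = ncc(resample(moving, t, fixed).voxels, fixed.voxels, support)
        assert after >= before

    def test_solution_outside_bounds_rejected(self, clean_atlas):
        img = clean_atlas.gray
        shifted = resample(img, RigidTransform([0, 0, 0], [3.5, 0, 0]), img)
        with pytest.raises(RuntimeError, match="bounds"):
            register_rigid(
                shifted,
                img,
                fixed_mask=clean_atlas.meta["brain_support"],
                config=RigidConfig(bound_mm=2.0),
            )


class TestResample:
    def test_identity_same_grid_exact(self, clean_atlas):
        img = clean_atlas.gray
        out = resample(img, None, img)
        np.testing.assert_array_equal(out.voxels, img.voxels)

    def test_nearest_never_invents_labels(self, default_atlas):
        lbl = default_atlas.label_image()
        t = RigidTransform([2.0, -1.0, 0.5], [0.15, -0.1, 0.2], center=lbl.center_world())
        out = resample(lbl, t, lbl, interp="nearest")
        assert set(np.unique(out.voxels)) <= set(np.unique(lbl.voxels))

    def test_integer_voxel_shift_matches_roll(self, clean_atlas):
        img = clean_atlas.gray
        t = RigidTransform([0, 0, 0], [0.1, 0.0, 0.0])  # exactly one voxel in +x
        out = resample(img, t, img)
        np.testing.assert_allclose(out.voxels[:-1], img.voxels[1:], atol=1e-3)

    def test_unknown_interp_rejected(self, clean_atlas):
        with pytest.raises(ValueError, match="interp"):
            resample(clean_atlas.gray, None, None, interp="sinc")


class TestWarp:
    def test_identical_images_near_zero_field(self, clean_atlas):
        img = clean_atlas.gray
        w = estimate_warp(img, img, mask=clean_atlas.meta["brain_support"])
        assert w.max_displacement() < 0.02

    def test_planted_deformation_recovered(self, clean_atlas):
        spec = clean_spec(warp_jitter_mm=0.3)
        atlas = clean_atlas
        sessions, truth = simulate_subject(spec, "ACA", 0, atlas=atlas)
        w = estimate_warp(sessions[0].image, atlas.gray, mask=atlas.meta["brain_support"])
        errs = []
        for name in ("ACA", "DS", "RTN", "SNr", "BLA", "LC", "AHN", "MBO", "PAG"):
            pts = atlas.gray.world_grid()[np.isin(atlas.labels, atlas.ids_for(name))]
            c = pts.mean(axis=0, keepdims=True)
            errs.append(np.linalg.norm(truth.transform.map_points(w.map_points(c)) - c))
        assert np.mean(errs) <= 0.1

    def test_bending_energy_monotone_in_reg_weight(self, clean_atlas):
        from mntrace.preprocess import _bending_energy_and_grad

        spec = clean_spec(warp_jitter_mm=0.25)
        sessions, _ = simulate_subject(spec, "ACA", 1, atlas=clean_atlas)
        img = sessions[0].image
        support = clean_atlas.meta["brain_support"]
        energies = []
        for rw in (0.01, 0.1):
            w = estimate_warp(
                img, clean_atlas.gray, mask=support, config=WarpConfig(reg_weight=rw)
            )
            e, _ = _bending_energy_and_grad(w.control_points, w.control_spacing_mm)
            energies.append(e)
        assert energies[1] <= energies[0]


class TestMDT:
    def test_identical_inputs_fixed_point(self, clean_atlas):
        img = clean_atlas.gray
        res = build_mdt([img, img, img], seed=0, with_warp=False)
        rng_range = float(np.ptp(img.voxels))
        assert np.abs(res.mdt.voxels - img.voxels).max() <= 1e-3 * rng_range

    def test_seed_changes_reference_but_not_mdt(self, default_atlas):
        spec = PhantomSpec(n_subjects_per_group=3, seed=4)
        pres = []
        for g in ("ACA", "ILPL"):
            for i in range(3):
                sessions, _ = simulate_subject(spec, g, i, atlas=default_atlas)
                img = sessions[0].image
                mask = erode_mask(compute_brain_mask(img), 0.25)
                pres.append(modal_scale(correct_bias(img, mask), mask, 100.0)[0])
        r1 = build_mdt(pres, seed=0, with_warp=False)
        r2 = build_mdt(pres, seed=3, with_warp=False)
        assert r1.reference_index != r2.reference_index
        # the two MDTs inherit their reference subject's pose; align them
        # rigidly before comparing anatomy
        m = compute_brain_mask(r1.mdt).data
        t = register_rigid(r2.mdt, r1.mdt, fixed_mask=m)
        assert ncc(r1.mdt.voxels, resample(r2.mdt, t, r1.mdt).voxels, m) >= 0.99

    def test_too_few_inputs_rejected(self, clean_atlas):
        with pytest.raises(ValueError):
            build_mdt([clean_atlas.gray], seed=0)


class TestPropagation:
    def test_pre_image_through_own_chain_matches(self, default_atlas):
        spec = PhantomSpec(seed=5)
        sessions, _ = simulate_subject(spec, "ACA", 0, atlas=default_atlas)
        pre = sessions[0].image
        t = register_rigid(pre, default_atlas.gray, fixed_mask=default_atlas.meta["brain_support"])
        out_direct = resample(pre, t, default_atlas.gray)
        out_prop = propagate_to_timepoints(t, [pre], default_atlas.gray)[0]
        np.testing.assert_array_equal(out_direct.voxels, out_prop.voxels)

    def test_transform_invariant_to_post_injection_content(self, default_atlas):
        """Replacing the 24 h voxels changes nothing about the applied map."""
        spec = PhantomSpec(seed=5)
        sessions, _ = simulate_subject(spec, "ACA", 0, atlas=default_atlas)
        imgs = {s.timepoint: s.image for s in sessions}
        t = register_rigid(imgs["pre"], default_atlas.gray, fixed_mask=default_atlas.meta["brain_support"])
        doctored = imgs["24h"].like(imgs["24h"].voxels * 2.0 + 5.0)
        a = propagate_to_timepoints(t, [imgs["24h"]], default_atlas.gray)[0]
        b = propagate_to_timepoints(t, [doctored], default_atlas.gray)[0]
        # exclude cells whose interpolation stencil touches the out-of-field
        # constant, where the affine relation cannot hold
        from scipy import ndimage

        inside = ndimage.binary_erosion(
            resample(imgs["24h"], t, default_atlas.gray).voxels != 0, iterations=2
        )
        np.testing.assert_allclose(
            b.voxels[inside], a.voxels[inside] * 2.0 + 5.0, rtol=1e-4, atol=1e-3
        )

    def test_grid_mismatch_rejected(self, default_atlas):
        img = default_atlas.gray
        other = VolumeImage(img.voxels[:-2], img.affine)
        with pytest.raises(ValueError, match="grid"):
            propagate_to_timepoints(RigidTransform.identity(), [img, other], img)

    def test_in_mask_mean_changes_little_under_resampling(self, default_atlas):
        spec = PhantomSpec(seed=5)
        sessions, _ = simulate_subject(spec, "ACA", 0, atlas=default_atlas)
        pre = sessions[0].image
        support = default_atlas.meta["brain_support"]
        t = register_rigid(pre, default_atlas.gray, fixed_mask=support)
        moved = resample(pre, t, default_atlas.gray)
        # compare the mean of the same content: the subject-frame mask mapped
        # through the same transform selects matching voxels
        submask = compute_brain_mask(pre)
        mapped = resample(submask.as_image(), t, default_atlas.gray, interp="nearest")
        sel = mapped.voxels.astype(bool)
        before = pre.voxels[submask.data].mean()
        after = moved.voxels[sel].mean()
        assert abs(after - before) / before < 0.01


class TestSmoothing:
    def test_sigma_from_fwhm_closed_form(self):
        assert (0.3 / 0.1) * FWHM_TO_SIGMA == pytest.approx(1.27398, abs=1e-4)

    def test_zero_fwhm_is_identity(self, clean_atlas):
        img = clean_atlas.gray
        out = smooth_gaussian(img, 0.0)
        np.testing.assert_array_equal(out.voxels, img.voxels)

    def test_negative_fwhm_rejected(self, clean_atlas):
        with pytest.raises(ValueError):
            smooth_gaussian(clean_atlas.gray, -0.1)

    def test_mask_renormalization_preserves_constant(self):
        img, m = _ellipsoid_image(value=80.0)
        out = smooth_gaussian(img, 0.3, mask=BrainMask(m, img.affine))
        np.testing.assert_allclose(out.voxels[m], 80.0, rtol=1e-10)
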