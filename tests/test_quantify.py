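"""Atlas alignment, fractional volumes, dynamics, injection sites, ROIs."""

import numpy as np
import pandas as pd
import pytest

from mntrace.image import BrainMask, VolumeImage
from mntrace.phantom import GroupPlan, PhantomSpec, make_phantom_atlas, simulate_subject
from mntrace.preprocess import compute_brain_mask, correct_bias, erode_mask, modal_scale
from mntrace.quantify import (
    ROISpec,
    align_atlas,
    classify_dynamics,
    cohort_site_summary,
    extract_roi_timecourse,
    fractional_accumulation,
    locate_injection_site,
    register_affine,
    roi_group_stats,
    segment_voxel_counts,
    site_to_stereotaxic,
    InjectionSite,
)
from mntrace.statmap import ThresholdedMap, paired_tmap, bh_fdr_threshold
from mntrace.transforms import AffineTransform, resample

from conftest import clean_spec, rng


def _thresholded_from(binary, atlas, contrast="test"):
    return ThresholdedMap(
        binary=binary,
        q=0.05,
        correction="BH-FDR",
        critical_t=0.0 if binary.any() else float("inf"),
        n_suprathreshold=int(binary.sum()),
        contrast=contrast,
    )


class TestAlignAtlas:
    def test_atlas_already_in_study_space(self, clean_atlas):
        out = align_atlas(clean_atlas, clean_atlas.gray, mdt_mask=clean_atlas.meta["brain_support"])
        M = np.array(out.meta["mdt_to_atlas_affine"])
        assert np.abs(M[:3, :3] - np.eye(3)).max() < 0.01
        assert np.abs(M[:3, 3]).max() < 0.05
        same = (out.labels == clean_atlas.labels).mean()
        assert same > 0.995
        assert set(np.unique(out.labels)) - {0} <= set(out.lut)
        np.testing.assert_allclose(out.bregma_world, clean_atlas.bregma_world, atol=0.05)

    def test_planted_affine_recovered(self, clean_atlas):
        true = np.eye(4)
        true[:3, :3] = np.diag([1.03, 0.98, 1.01])
        true[0, 1] = 0.02
        true[:3, 3] = [0.2, -0.15, 0.1]
        planted = AffineTransform(true)
        # "study" image: atlas gray seen through the planted affine
        mdt = resample(clean_atlas.gray, planted, clean_atlas.gray, interp="cubic")
        mask = compute_brain_mask(mdt).data
        pull = register_affine(clean_atlas.gray, mdt, fixed_mask=mask)
        pts = clean_atlas.gray.world_grid()[clean_atlas.meta["brain_support"]][::400]
        err = np.linalg.norm(pull.map_points(pts) - planted.map_points(pts), axis=1)
        assert err.mean() <= 0.05
        scales_est = np.linalg.norm(pull.matrix[:3, :3], axis=0)
        scales_true = np.linalg.norm(true[:3, :3], axis=0)
        assert np.abs(scales_est / scales_true - 1).max() <= 0.01


class TestSegmentCounts:
    def test_partition_property(self, default_atlas):
        counts = segment_voxel_counts(default_atlas.labels)
        assert sum(counts.values()) == int((default_atlas.labels != 0).sum())

    def test_synthetic_two_label_volume(self):
        lbl = np.zeros((5, 5, 5), dtype=np.int16)
        lbl.flat[:10] = 1
        lbl.flat[10:30] = 2
        assert segment_voxel_counts(lbl) == {1: 10, 2: 20}


class TestFractionalAccumulation:
    def test_hand_fraction(self, default_atlas):
        labels = default_atlas.labels
        seg = np.isin(labels, default_atlas.ids_for("DS"))
        flat = np.zeros(labels.size, dtype=bool)
        flat[np.flatnonzero(seg.ravel())[: int(seg.sum()) // 4]] = True
        binary = flat.reshape(labels.shape)
        rows = fractional_accumulation(_thresholded_from(binary, default_atlas), default_atlas)
        row = next(r for r in rows if r.abbrev == "DS")
        assert row.enhanced_voxels == int(seg.sum()) // 4
        assert row.total_voxels == int(seg.sum())
        assert row.fraction == pytest.approx((int(seg.sum()) // 4) / seg.sum())

    def test_empty_map_all_zero(self, default_atlas):
        rows = fractional_accumulation(
            _thresholded_from(np.zeros(default_atlas.labels.shape, dtype=bool), default_atlas),
            default_atlas,
        )
        assert all(r.fraction == 0 for r in rows)
        assert all(0 <= r.fraction <= 1 for r in rows)

    def test_partition_against_voxel_loop_oracle(self, default_atlas):
        r = rng(2)
        binary = r.uniform(size=default_atlas.labels.shape) < 0.1
        rows = fractional_accumulation(
            _thresholded_from(binary, default_atlas), default_atlas, include_tracts=True
        )
        total_enhanced = sum(row.enhanced_voxels for row in rows)
        # independent voxel loop over the labeled region
        want = int(sum(1 for v, l in zip(binary.ravel(), default_atlas.labels.ravel()) if v and l))
        assert total_enhanced == want

    def test_tracts_excluded_by_default(self, default_atlas):
        rows = fractional_accumulation(
            _thresholded_from(np.zeros(default_atlas.labels.shape, dtype=bool), default_atlas),
            default_atlas,
        )
        tract_bases = {e.lateral_base for e in default_atlas.lut.values() if e.is_tract}
        assert not tract_bases & {r.abbrev for r in rows}


class TestDynamics:
    def test_rule_cases(self):
        rows = classify_dynamics(
            {"A": 0.30, "B": 0.20, "C": 0.10, "D": 0.01},
            {"A": 0.10, "B": 0.20, "C": 0.40, "D": 0.02},
            {"A": 0.0, "B": 0.0, "C": 0.0, "D": 0.0},
        )
        cats = {r.segment: r.category for r in rows}
        assert cats == {"A": "greater_at_6h", "B": "similar", "C": "greater_at_24h"}

    def test_accumulating_overrides_similar(self):
        rows = classify_dynamics({"X": 0.2}, {"X": 0.22}, {"X": 0.10})
        assert rows[0].category == "accumulating_6_24"

    def test_invalid_delta(self):
        with pytest.raises(ValueError):
            classify_dynamics({}, {}, {}, delta=0.0)


class TestInjectionSite:
    def test_noise_free_core_within_one_voxel(self, clean_atlas):
        sessions, truth = simulate_subject(clean_spec(), "ACA", 0, atlas=clean_atlas)
        imgs = {s.timepoint: s.image for s in sessions}
        mask = compute_brain_mask(imgs["pre"])
        site = locate_injection_site(imgs["30min"], mask)
        err = np.linalg.norm(site.centroid_world - truth.injection_centroid_world)
        assert err <= 0.1

    def test_default_noise_within_two_voxels(self, default_atlas):
        spec = PhantomSpec(seed=17)
        errs = []
        for g in ("ACA", "ILPL"):
            for i in range(5):
                sessions, truth = simulate_subject(spec, g, i, atlas=default_atlas)
                imgs = {s.timepoint: s.image for s in sessions}
                mask = erode_mask(compute_brain_mask(imgs["pre"]), 0.25)
                img = modal_scale(correct_bias(imgs["30min"], mask), mask, 100.0)[0]
                idx = np.argwhere(mask.data)
                anterior = np.zeros_like(mask.data)
                anterior[:, int(np.ceil(idx[:, 1].mean())):, :] = True
                anterior &= mask.data
                site = locate_injection_site(img, mask, search_region=anterior)
                errs.append(np.linalg.norm(site.centroid_world - truth.injection_centroid_world))
        assert max(errs) <= 0.2

    def test_pre_injection_image_raises(self, clean_atlas):
        sessions, _ = simulate_subject(clean_spec(), "ACA", 0, atlas=clean_atlas)
        imgs = {s.timepoint: s.image for s in sessions}
        mask = compute_brain_mask(imgs["pre"])
        with pytest.raises(ValueError, match="no injection core"):
            locate_injection_site(imgs["pre"], mask)


class TestStereotaxic:
    def test_midline_bregma_surface_origin(self, clean_atlas):
        mask = BrainMask(clean_atlas.meta["brain_support"], clean_atlas.gray.affine)
        bregma = clean_atlas.bregma_world
        # a point on the midline at bregma's AP position, at the surface
        idx = clean_atlas.gray.world_to_index(bregma)
        i, j = int(round(idx[0])), int(round(idx[1]))
        k_top = int(np.max(np.nonzero(mask.data[i, j, :])[0]))
        surface = clean_atlas.gray.index_to_world(np.array([i, j, k_top]))
        ml, ap, dv = site_to_stereotaxic(surface * [1, 0, 1] + [0, bregma[1], 0], clean_atlas, mask)
        assert ml == pytest.approx(surface[0], abs=1e-9)
        assert ap == pytest.approx(0.0, abs=1e-9)
        assert dv == pytest.approx(0.0, abs=1e-9)

    def test_planted_plan_recovered(self, clean_atlas):
        spec = clean_spec()
        plan = spec.group_defs["ACA"].injection
        plan.site_jitter_mm = 0.0  # compare against the exact plan
        sessions, truth = simulate_subject(spec, "ACA", 0, atlas=clean_atlas)
        imgs = {s.timepoint: s.image for s in sessions}
        mask = compute_brain_mask(imgs["pre"])
        site = locate_injection_site(imgs["30min"], mask)
        ml, ap, dv = site_to_stereotaxic(site.centroid_world, clean_atlas, mask)
        assert ml == pytest.approx(plan.ml_mm, abs=0.15)
        assert ap == pytest.approx(plan.ap_mm, abs=0.15)
        assert dv == pytest.approx(plan.dv_mm, abs=0.15)

    def test_column_outside_mask_rejected(self, clean_atlas):
        mask = BrainMask(clean_atlas.meta["brain_support"], clean_atlas.gray.affine)
        with pytest.raises(ValueError, match="outside"):
            site_to_stereotaxic(np.array([3.8, 3.0, 0.0]), clean_atlas, mask)


class TestCohortSummary:
    def _sites(self, coords):
        return [
            InjectionSite(subject_id=str(i), centroid_world=np.zeros(3), ml_mm=c[0], ap_mm=c[1], dv_mm=c[2])
            for i, c in enumerate(coords)
        ]

    def test_two_point_hand_case(self):
        s = cohort_site_summary(self._sites([(0, 0, 0), (1, 0, 0)]))
        assert s["ml_mean"] == pytest.approx(0.5)
        assert s["max_distance_from_centroid"] == pytest.approx(0.5)

    def test_identical_sites(self):
        s = cohort_site_summary(self._sites([(1, 2, -1)] * 4))
        assert s["ml_sd"] == 0 and s["max_distance_from_centroid"] == 0

    def test_sampling_distribution_of_sd(self):
        r = rng(8)
        coords = r.normal([0.5, 1.0, -0.8], 0.15, size=(12, 3))
        s = cohort_site_summary(self._sites(coords))
        for axis in ("ml_sd", "ap_sd", "dv_sd"):
            assert 0.08 <= s[axis] <= 0.25

    def test_single_site_rejected(self):
        with pytest.raises(ValueError):
            cohort_site_summary(self._sites([(0, 0, 0)]))


class TestROI:
    def _sessions(self, values, shape=(9, 9, 9)):
        aff = np.eye(4)
        return {
            tp: VolumeImage(np.full(shape, v, dtype=np.float32), aff)
            for tp, v in values.items()
        }

    def test_constant_image_ratios(self):
        sess = self._sessions({"30min": 100.0, "6h": 110.0, "24h": 120.0})
        tc = extract_roi_timecourse(sess, ROISpec("x", "left", (4, 4, 4)))
        assert tc.ratio_6h == pytest.approx(1.10)
        assert tc.ratio_24h == pytest.approx(1.20)

    def test_identical_timepoints_unity(self):
        sess = self._sessions({"30min": 50.0, "6h": 50.0, "24h": 50.0})
        tc = extract_roi_timecourse(sess, ROISpec("x", "left", (4, 4, 4)))
        assert tc.ratio_6h == 1.0 and tc.ratio_24h == 1.0

    def test_cube_exits_grid_rejected(self):
        sess = self._sessions({"30min": 1.0})
        with pytest.raises(ValueError, match="grid"):
            extract_roi_timecourse(sess, ROISpec("x", "left", (0, 4, 4)))

    def test_cube_exits_mask_rejected(self):
        sess = self._sessions({"30min": 1.0})
        m = np.zeros((9, 9, 9), dtype=bool)
        m[3:6, 3:6, 3:6] = True
        with pytest.raises(ValueError, match="mask"):
            extract_roi_timecourse(sess, ROISpec("x", "left", (4, 4, 6)), mask=m)

    def test_planted_enhancement_recovered_in_ratio(self, clean_atlas):
        spec = clean_spec(noise_sigma=0.04)
        spec.group_defs = {"A": GroupPlan(schedule=[("DS", "24h", 0.10)]), "B": GroupPlan()}
        idx = np.argwhere(np.isin(clean_atlas.labels, clean_atlas.ids_for("DS-R")))
        center = tuple(int(round(v)) for v in idx.mean(axis=0))
        ratios = []
        for i in range(10):
            sessions, _ = simulate_subject(spec, "A", i, atlas=clean_atlas)
            sess = {s.timepoint: s.image for s in sessions}
            tc = extract_roi_timecourse(sess, ROISpec("DS", "right", center))
            ratios.append(tc.ratio_24h)
        assert np.mean(ratios) == pytest.approx(1.10, abs=0.03)


class TestROIGroupStats:
    def _toy_timecourses(self, shift=0.0, n=4, seed=0):
        r = rng(seed)
        tcs = []
        for g, gshift in (("A", shift), ("B", 0.0)):
            for i in range(n):
                base = 100.0
                m30 = base * (1 + r.normal(0, 0.01))
                m6 = base * (1.02 + r.normal(0, 0.01))
                m24 = base * (1.05 + gshift + r.normal(0, 0.01))
                from mntrace.quantify import ROITimecourse

                tcs.append(
                    ROITimecourse(
                        roi=ROISpec("seg", "left", (0, 0, 0)),
                        subject_id=f"{g}{i}",
                        group=g,
                        means={"30min": m30, "6h": m6, "24h": m24},
                    )
                )
        return tcs

    def test_identical_groups_null(self):
        df = roi_group_stats(self._toy_timecourses(shift=0.0, n=6))
        between = df[df["family"].str.startswith("between")]
        assert (between["p_adj"] > 0.2).all()
        assert np.abs(between["estimate"]).max() < 0.02

    def test_paired_branch_matches_hand_computation(self):
        from mntrace.quantify import ROITimecourse

        vals = {"A0": (100.0, 102.0, 110.0), "A1": (100.0, 104.0, 109.0), "A2": (100.0, 101.0, 111.0)}
        tcs = [
            ROITimecourse(ROISpec("seg", "left", (0, 0, 0)), sid, "A",
                          {"30min": v[0], "6h": v[1], "24h": v[2]})
            for sid, v in vals.items()
        ]
        tcs += [
            ROITimecourse(ROISpec("seg", "left", (0, 0, 0)), f"B{i}", "B",
                          {"30min": 100.0, "6h": 101.0 + i, "24h": 102.0 + i})
            for i in range(3)
        ]
        df = roi_group_stats(tcs)
        row = df[(df["family"] == "within:A:24h_vs_6h")].iloc[0]
        d = [np.log(v[2] / v[0]) - np.log(v[1] / v[0]) for v in vals.values()]
        d = np.array(d)
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(3))
        assert row["t"] == pytest.approx(t_hand, abs=1e-10)
        assert row["estimate"] == pytest.approx(d.mean(), abs=1e-12)

    def test_unbalanced_structure_rejected(self):
        tcs = self._toy_timecourses(n=4)
        kept = [t for t in tcs if t.group == "A"] + [t for t in tcs if t.group == "B"][:2]
        with pytest.raises(ValueError, match="< 3"):
            roi_group_stats(kept)
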