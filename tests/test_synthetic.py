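"""Phantom cohort generator: determinism, geometry and outcome model."""

import numpy as np
import pytest
from dataclasses import replace

from vimtarget.grids import BinaryMask
from vimtarget.metrics import center_of_mass
from vimtarget.stats import pearson
from vimtarget.synthetic import (
    NUCLEUS_CODES,
    AblationSpec,
    OutcomeModel,
    PhantomSpec,
    draw_ablation_centers,
    generate_cohort,
    generate_outcomes,
    generate_phantom,
    plant_ablation,
    true_overlap_fractions,
)


@pytest.fixture(scope="module")
def phantom():
    spec = PhantomSpec()
    pre, nuclei, landmarks = generate_phantom(spec, rng_seed=0)
    return spec, pre, nuclei, landmarks


class TestGeneratePhantom:
    def test_deterministic_for_fixed_seed(self, phantom):
        spec, pre, nuclei, _ = phantom
        pre2, nuclei2, _ = generate_phantom(spec, rng_seed=0)
        np.testing.assert_array_equal(pre.values, pre2.values)
        np.testing.assert_array_equal(nuclei.labels, nuclei2.labels)

    def test_thalamus_brighter_than_white_matter(self, phantom):
        _, pre, nuclei, _ = phantom
        inside = nuclei.labels > 0
        assert pre.values[inside].mean() > pre.values[~inside].mean()

    def test_vlp_count_matches_analytic_ellipsoid(self, phantom):
        # independent oracle: voxel-center-in-ellipsoid test by direct loop
        spec, _, nuclei, _ = phantom
        center, axes = spec.nuclei["VLp"]
        grid = nuclei.grid
        count = 0
        for hemi in (1, -1):
            c = np.array([hemi * center[0], center[1], center[2]])
            for i in range(grid.dims[0]):
                for j in range(grid.dims[1]):
                    for k in range(grid.dims[2]):
                        w = grid.index_to_world(np.array([i, j, k]))
                        if np.sum(((w - c) / np.array(axes)) ** 2) <= 1.0:
                            count += 1
        assert int((nuclei.labels == NUCLEUS_CODES["VLp"]).sum()) == count

    def test_right_treated_landmarks_mirror(self):
        spec = PhantomSpec()
        _, _, lm_l = generate_phantom(spec, rng_seed=0, treated_side="left")
        _, _, lm_r = generate_phantom(spec, rng_seed=0, treated_side="right")
        assert lm_r.third_ventricle_wall_x == -lm_l.third_ventricle_wall_x
        assert lm_r.treated_side == "right"


class TestPlantAblation:
    def test_zero_levels_leave_image_unchanged(self, phantom):
        spec, pre, nuclei, _ = phantom
        thal = BinaryMask(nuclei.grid, nuclei.labels > 0)
        ab = AblationSpec(
            center=spec.efficacious_center,
            penumbra_boost=0.0,
            core_boost=0.0,
            hypointense_offset=0.0,
            texture_sd=0.0,
        )
        post, _, _ = plant_ablation(pre, ab, thal, rng_seed=0)
        np.testing.assert_array_equal(post.values, pre.values)

    def test_core_volume_matches_sphere_voxelization(self, phantom):
        spec, pre, nuclei, _ = phantom
        thal = BinaryMask(nuclei.grid, nuclei.labels > 0)
        ab = AblationSpec(center=spec.efficacious_center)
        _, core, _ = plant_ablation(pre, ab, thal, rng_seed=0)
        # oracle: count voxel centers within core_radius of the center
        idx = np.argwhere(np.ones(nuclei.grid.dims, dtype=bool))
        world = nuclei.grid.index_to_world(idx)
        d = np.linalg.norm(world - np.array(ab.center), axis=1)
        assert core.count == int((d <= ab.core_radius).sum())

    def test_zone_structure(self, phantom):
        spec, pre, nuclei, _ = phantom
        grid = nuclei.grid
        thal = BinaryMask(grid, nuclei.labels > 0)
        ab = AblationSpec(center=spec.efficacious_center, hypointense_radius=1.0)
        post, core, whole = plant_ablation(pre, ab, thal, rng_seed=0)

        # post equals pre outside the penumbra
        np.testing.assert_array_equal(post.values[~whole.data], pre.values[~whole.data])
        # hypointense centre darker than the core ring around it
        idx = np.argwhere(core.data)
        d = np.linalg.norm(grid.index_to_world(idx) - np.array(ab.center), axis=1)
        hypo = d <= ab.hypointense_radius
        assert hypo.any() and (~hypo).any()
        vals = post.values[idx[:, 0], idx[:, 1], idx[:, 2]]
        assert vals[hypo].mean() < vals[~hypo].mean()

    def test_core_satisfies_threshold_rule_by_construction(self, phantom):
        # recoverability: non-hypointense core voxels exceed scaled 1.25
        spec, pre, nuclei, _ = phantom
        grid = nuclei.grid
        thal = BinaryMask(grid, nuclei.labels > 0)
        ab = AblationSpec(center=spec.efficacious_center)
        post, core, whole = plant_ablation(pre, ab, thal, rng_seed=0)
        normal = thal.data & ~whole.data
        med = np.percentile(post.values[normal], 50)
        p99 = np.percentile(post.values[normal], 99)
        idx = np.argwhere(core.data)
        d = np.linalg.norm(grid.index_to_world(idx) - np.array(ab.center), axis=1)
        ring = idx[d > ab.hypointense_radius]
        scaled = (post.values[ring[:, 0], ring[:, 1], ring[:, 2]] - med) / (p99 - med)
        assert (scaled > 1.25).all()


class TestGenerateOutcomes:
    def test_deterministic_improvement_without_noise(self):
        model = OutcomeModel(improvement_intercept=12.0, improvement_slope=0.0, noise_sd=0.0)
        pairs = generate_outcomes([0.3] * 20, model, rng_seed=1)
        for base, month in pairs:
            assert month == int(np.clip(base - 12, 0, 32))

    def test_overlap_effect_is_beta(self):
        model = OutcomeModel(baseline_sd=0.0, noise_sd=0.0)
        (b1, m1), = generate_outcomes([1.0], model, rng_seed=2)
        (b0, m0), = generate_outcomes([0.0], model, rng_seed=2)
        assert b1 == b0 == 20
        assert (b1 - m1) - (b0 - m0) == round(model.improvement_slope)

    def test_default_cohort_correlation_is_negative(self):
        rng = np.random.default_rng(0)
        phantom = PhantomSpec()
        centers = draw_ablation_centers(14, phantom, 1.5, rng)
        ov = true_overlap_fractions(centers, phantom)
        pairs = generate_outcomes(ov, OutcomeModel(), rng_seed=0)
        months = [m for _, m in pairs]
        assert pearson(ov, months).r < 0

    def test_invalid_overlap_rejected(self):
        with pytest.raises(ValueError):
            generate_outcomes([1.5], OutcomeModel(), rng_seed=0)


class TestGenerateCohort:
    def test_cohort_size_and_ids(self, seed0_cohort):
        assert len(seed0_cohort) == 14
        assert [r.patient_id for r in seed0_cohort][:3] == ["A", "B", "C"]

    def test_three_right_treated_with_right_hemisphere_ablation(self, seed0_cohort):
        right = [r for r in seed0_cohort if r.treated_side == "right"]
        assert [r.patient_id for r in right] == ["B", "D", "L"]
        for r in right:
            assert center_of_mass(r.true_core)[0] > 0
        for r in seed0_cohort:
            if r.treated_side == "left":
                assert center_of_mass(r.true_core)[0] < 0

    def test_overlap_fractions_spread(self, seed0_cohort):
        ov = [r.true_overlap for r in seed0_cohort]
        assert min(ov) < 0.5 < max(ov)

    def test_zero_jitter_zero_noise_gives_identical_improvements(self):
        # modest effect so no patient's score hits the 0-point floor
        model = OutcomeModel(
            improvement_intercept=4.0, improvement_slope=5.0, noise_sd=0.0
        )
        records = generate_cohort(
            n_patients=4,
            phantom=PhantomSpec(dims=(64, 64, 64)),
            ablation_jitter=0.0,
            model=model,
            right_treated_ids=[],
            rng_seed=1,
        )
        overlaps = {r.true_overlap for r in records}
        improvements = {r.crst_baseline - r.crst_1month for r in records}
        assert len(overlaps) == 1
        assert len(improvements) == 1

    def test_determinism(self):
        a = generate_cohort(n_patients=3, phantom=PhantomSpec(dims=(64, 64, 64)), rng_seed=7)
        b = generate_cohort(n_patients=3, phantom=PhantomSpec(dims=(64, 64, 64)), rng_seed=7)
        for ra, rb in zip(a, b):
            np.testing.assert_array_equal(ra.post_volume.values, rb.post_volume.values)
            assert ra.crst_1month == rb.crst_1month
            np.testing.assert_array_equal(ra.to_template, rb.to_template)

    def test_invalid_right_ids_rejected(self):
        with pytest.raises(ValueError):
            generate_cohort(n_patients=3, right_treated_ids=[5], rng_seed=0)


class TestParameterRecovery:
    def test_regression_recovers_slope_within_two_se(self):
        # n=100 synthetic patients via the geometric fast path
        phantom = PhantomSpec()
        model = OutcomeModel()
        rng = np.random.default_rng(11)
        centers = draw_ablation_centers(100, phantom, 1.5, rng)
        ov = true_overlap_fractions(centers, phantom)
        pairs = generate_outcomes(ov, model, rng_seed=11)
        improvement = np.array([b - m for b, m in pairs], dtype=float)
        X = np.column_stack([np.ones_like(ov), ov])
        coef, res, *_ = np.linalg.lstsq(X, improvement, rcond=None)
        resid = improvement - X @ coef
        s2 = (resid**2).sum() / (len(ov) - 2)
        cov = s2 * np.linalg.inv(X.T @ X)
        se_beta = np.sqrt(cov[1, 1])
        assert abs(coef[1] - model.improvement_slope) < 2 * se_beta
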