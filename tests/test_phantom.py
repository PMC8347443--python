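from __future__ import annotations

import numpy as np
import pytest

from nanori import phantom
from nanori.phantom import (
    CalibrationError,
    PlacementError,
    PhantomConfig,
    RIDistributionConstraints,
    RIDistributionParams,
    calibrate_cytoplasm_ri,
    generate_cohort,
    generate_scene,
    render_stacks,
)

from conftest import small_phantom_config

PAPER_CONSTRAINTS = RIDistributionConstraints(
    mode_ri=1.3725,
    support_lo=1.365,
    support_hi=1.395,
    frac_in_band=0.995,
    band_lo=1.365,
    band_hi=1.39,
    frac_below_mode=0.34,
)


class TestCalibration:
    def test_symmetric_constraints_give_zero_shape(self):
        c = RIDistributionConstraints(
            mode_ri=1.38,
            support_lo=1.37,
            support_hi=1.39,
            frac_in_band=1.0,
            band_lo=1.37,
            band_hi=1.39,
            frac_below_mode=0.5,
        )
        params = calibrate_cytoplasm_ri(c, tol=0.002)
        # symmetry forces (numerically) zero skew
        assert abs(params.shape) < 0.2
        assert abs(params.mode() - 1.38) < 0.002

    def test_control_constraints_integrate_to_targets(self):
        params = calibrate_cytoplasm_ri(PAPER_CONSTRAINTS, tol=0.002)
        assert abs(params.mass_in(1.365, 1.39) - 0.995) < 0.002
        assert abs(float(params.cdf(params.mode())) - 0.34) < 0.002
        assert abs(params.mode() - 1.3725) < 0.002

    def test_band_equal_support_is_total_mass(self):
        c = RIDistributionConstraints(
            mode_ri=1.372,
            support_lo=1.365,
            support_hi=1.395,
            frac_in_band=1.0,
            band_lo=1.365,
            band_hi=1.395,
            frac_below_mode=0.4,
        )
        params = calibrate_cytoplasm_ri(c, tol=0.002)
        assert params.mass_in(1.365, 1.395) == pytest.approx(1.0, abs=1e-9)

    def test_unsatisfiable_constraints_raise(self):
        c = RIDistributionConstraints(
            mode_ri=1.3651,
            support_lo=1.365,
            support_hi=1.395,
            frac_in_band=0.01,  # almost no mass near the mode: impossible
            band_lo=1.365,
            band_hi=1.3925,
            frac_below_mode=0.49,
        )
        with pytest.raises(CalibrationError):
            calibrate_cytoplasm_ri(c, tol=1e-4)

    def test_default_params_match_documented_calibration(self):
        # defaults were produced by calibrate_cytoplasm_ri with the
        # below-mode target compensated to 0.357 for the nuclear mixture
        compensated = RIDistributionConstraints(
            mode_ri=1.3725,
            support_lo=1.365,
            support_hi=1.395,
            frac_in_band=0.995,
            band_lo=1.365,
            band_hi=1.39,
            frac_below_mode=0.357,
        )
        params = calibrate_cytoplasm_ri(compensated, tol=0.002)
        d = phantom.DEFAULT_CYTOPLASM_RI
        assert params.location == pytest.approx(d.location, abs=5e-4)
        assert params.scale == pytest.approx(d.scale, abs=5e-4)
        assert params.shape == pytest.approx(d.shape, abs=0.3)


class TestDistribution:
    def test_sampling_respects_truncation_exactly(self, rng):
        params = phantom.DEFAULT_CYTOPLASM_RI
        x = params.sample(1_000_000, rng)
        assert x.min() >= params.support_lo
        assert x.max() <= params.support_hi

    def test_large_sample_recovers_calibrated_fractions(self, rng):
        params = phantom.DEFAULT_CYTOPLASM_RI
        x = params.sample(1_000_000, rng)
        frac_band = np.mean((x >= 1.365) & (x <= 1.39))
        frac_below = np.mean(x < params.mode())
        assert frac_band == pytest.approx(0.995, abs=0.005)
        assert frac_below == pytest.approx(0.357, abs=0.01)

    def test_cdf_ppf_inverse(self, rng):
        params = phantom.DEFAULT_NUCLEUS_RI
        q = rng.random(1000)
        assert np.allclose(params.cdf(params.ppf(q)), q, atol=1e-6)


class TestScene:
    def test_zero_dose_has_no_particles_and_flat_fluor(self, small_config):
        scene = generate_scene(small_config, 0.0, seed=3)
        assert scene.np_mask.sum() == 0
        inside = scene.true_fluor[scene.cell_mask]
        assert np.all(inside == np.float32(small_config.fluor_background_mean))
        assert np.all(scene.true_fluor[~scene.cell_mask] == 0)

    def test_np_fraction_hits_target_within_one_punctum(self, small_config):
        scene = generate_scene(small_config, 0.5, seed=42)
        n_cyto = int(scene.cytoplasm_mask.sum())
        target = small_config.np_voxel_fraction_per_dose[0.5] * n_cyto
        got = int(scene.np_mask.sum())
        # brute-force voxel counting against the declared tolerance:
        # overshoot bounded by the largest possible punctum
        rmax_nm = small_config.puncta_radius_range_vox[1] * 200.0
        vox_nm3 = np.prod(small_config.voxel_size_nm)
        max_punctum = 4 / 3 * np.pi * rmax_nm**3 / vox_nm3 * 1.5
        assert got >= target
        assert got - target < max_punctum

    @pytest.mark.parametrize("dose", [0.25, 0.5])
    def test_no_particles_in_nucleus(self, small_config, dose):
        scene = generate_scene(small_config, dose, seed=11)
        assert not (scene.np_mask & scene.nucleus_mask).any()
        assert not (scene.np_mask & ~scene.cell_mask).any()

    def test_np_ri_in_band(self, small_config):
        scene = generate_scene(small_config, 0.5, seed=5)
        vals = scene.true_ri[scene.np_mask]
        assert vals.min() >= small_config.np_band[0]
        assert vals.max() <= small_config.np_band[1]

    def test_scene_determinism(self, small_config):
        a = generate_scene(small_config, 0.5, seed=9)
        b = generate_scene(small_config, 0.5, seed=9)
        assert np.array_equal(a.true_ri, b.true_ri)
        assert np.array_equal(a.np_mask, b.np_mask)
        assert np.array_equal(a.true_fluor, b.true_fluor)

    def test_unknown_dose_rejected(self, small_config):
        with pytest.raises(KeyError):
            generate_scene(small_config, 0.123, seed=0)

    def test_unreachable_fraction_raises_placement_error(self):
        cfg = small_phantom_config(
            np_voxel_fraction_per_dose={0.0: 0.0, 0.5: 0.9},
            perinuclear_shell_nm=300.0,
        )
        with pytest.raises(PlacementError):
            generate_scene(cfg, 0.5, seed=0)

    def test_expected_np_count_monotone_in_dose(self, small_config):
        counts = [
            int(generate_scene(small_config, d, seed=21).np_mask.sum())
            for d in (0.0, 0.25, 0.5)
        ]
        assert counts[0] < counts[1] < counts[2]


class TestRender:
    def test_zero_noise_identity(self):
        cfg = small_phantom_config(noise_sd_ri=0.0, fluor_background_sd=0.0)
        scene = generate_scene(cfg, 0.25, seed=7)
        ri, fl = render_stacks(scene, cfg)
        assert np.array_equal(ri.voxels, scene.true_ri)
        assert np.array_equal(fl.voxels, scene.true_fluor)

    def test_medium_is_flat_at_zero_noise(self):
        cfg = small_phantom_config(noise_sd_ri=0.0)
        scene = generate_scene(cfg, 0.0, seed=7)
        ri, _ = render_stacks(scene, cfg)
        assert np.all(ri.voxels[~scene.cell_mask] == np.float32(cfg.medium_ri))

    def test_render_determinism(self, small_config):
        scene = generate_scene(small_config, 0.5, seed=13)
        a = render_stacks(scene, small_config)
        b = render_stacks(scene, small_config)
        assert np.array_equal(a[0].voxels, b[0].voxels)
        assert np.array_equal(a[1].voxels, b[1].voxels)

    def test_shape_mismatch_rejected(self, small_config):
        scene = generate_scene(small_config, 0.0, seed=1)
        other = small_phantom_config(grid_shape=(20, 40, 40))
        with pytest.raises(ValueError):
            render_stacks(scene, other)


class TestCohort:
    def test_singleton_matches_generate_scene_with_derived_seed(self, small_config):
        [(scene, ri, fl)] = generate_cohort(small_config, 1, 0.25, seed=50)
        cfg0 = phantom.cell_config(small_config, 50)
        direct = generate_scene(cfg0, 0.25, 50)
        assert np.array_equal(scene.true_ri, direct.true_ri)
        ri2, _ = render_stacks(direct, cfg0)
        assert np.array_equal(ri.voxels, ri2.voxels)

    def test_dose_separation_by_construction(self, small_config):
        zero = generate_cohort(small_config, 5, 0.0, seed=1)
        dosed = generate_cohort(small_config, 5, 0.5, seed=1)
        assert all(s.np_mask.sum() == 0 for s, _, _ in zero)
        assert all(s.np_mask.sum() > 0 for s, _, _ in dosed)

    def test_cohort_checksum_reproducible(self, small_config):
        def checksum(cohort):
            return [float(ri.voxels.sum()) for _, ri, _ in cohort]

        a = checksum(generate_cohort(small_config, 4, 0.5, seed=77))
        b = checksum(generate_cohort(small_config, 4, 0.5, seed=77))
        assert a == b

    def test_geometry_jitter_varies_cells(self, small_config):
        cohort = generate_cohort(small_config, 4, 0.0, seed=5)
        sizes = {int(s.cell_mask.sum()) for s, _, _ in cohort}
        assert len(sizes) > 1

    def test_invalid_n_cells(self, small_config):
        with pytest.raises(ValueError):
            list(phantom.iter_cohort(small_config, 0, 0.0, 1))


class TestConfig:
    def test_np_fraction_must_be_monotone(self):
        with pytest.raises(ValueError):
            small_phantom_config(np_voxel_fraction_per_dose={0.0: 0.0, 0.25: 0.02, 0.5: 0.01})

    def test_dose_zero_fraction_must_be_zero(self):
        with pytest.raises(ValueError):
            small_phantom_config(np_voxel_fraction_per_dose={0.0: 0.01, 0.5: 0.02})

    def test_roundtrip_dict(self, small_config):
        d = small_config.to_dict()
        back = PhantomConfig.from_dict(d)
        assert back == small_config

    def test_constraint_invariants(self):
        with pytest.raises(ValueError):
            RIDistributionConstraints(1.40, 1.365, 1.395, 0.99, 1.365, 1.39, 0.34)
        with pytest.raises(ValueError):
            RIDistributionParams(1.37, -1.0, 0.0, 1.365, 1.395)
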