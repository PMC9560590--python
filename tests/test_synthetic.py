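import numpy as np
import pytest

from dbsaudit.leads import load_lead_library
from dbsaudit.metrics import boundary_distance, centroid_offset
from dbsaudit.synthetic import (
    ATLAS_LABELS,
    AtlasSizingError,
    AtlasSpec,
    CohortConfig,
    ConfigurationError,
    Stratum,
    atlas_mask,
    atlas_region_labels,
    brain_mask_volume,
    carve_air_cavity,
    generate_atlas,
    generate_cohort,
    generate_electrodes,
    generate_outcomes,
    generate_postop_state,
    generate_subject,
)

LIB = load_lead_library()


def zero_noise_config(**kw):
    dm = {k: Stratum((0.0, 0.0, 0.0), (0.0, 0.0, 0.0))
          for k in [("left", "GPi"), ("right", "GPi"),
                    ("left", "STN"), ("right", "STN")]}
    defaults = dict(n_subjects=2, displacement_model=dm,
                    right_x_variance_multiplier=1.0,
                    pneumocephalus_volume_range_ml=(0.0, 0.0),
                    scrf_translation_scale_mm=0.0, scrf_rotation_scale_deg=0.0)
    defaults.update(kw)
    return CohortConfig(**defaults)


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        dict(n_subjects=0),
        dict(gpi_fraction=1.5),
        dict(right_x_variance_multiplier=0.5),
        dict(pneumocephalus_volume_range_ml=(5.0, 1.0)),
        dict(scrf_translation_scale_mm=-1.0),
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            CohortConfig(**kwargs)

    def test_negative_stratum_sd_rejected(self):
        with pytest.raises(ConfigurationError):
            Stratum((0, 0, 0), (-1, 0, 0))


class TestAtlas:
    def test_motor_voxels_belong_to_main_region(self, default_atlas):
        for nucleus in ("GPi", "STN"):
            for hemi in ("left", "right"):
                motor = atlas_mask(default_atlas, nucleus, hemi, "motor")
                main = atlas_mask(default_atlas, nucleus, hemi, "main")
                assert motor.any()
                assert np.all(main[motor])          # strict subset
                assert main.sum() > motor.sum()

    def test_nucleus_volumes_near_configured(self, default_atlas):
        spec = AtlasSpec()
        vv = default_atlas.voxel_volume
        for nucleus, target in (("GPi", spec.gpi_volume_mm3),
                                ("STN", spec.stn_volume_mm3)):
            for hemi in ("left", "right"):
                vol = atlas_mask(default_atlas, nucleus, hemi, "main").sum() * vv
                assert abs(vol / target - 1) < 0.2

    def test_voxelised_ellipsoid_volume_near_analytic(self):
        from dbsaudit.volumes import ellipsoid_mask
        from conftest import make_label_volume

        vol = make_label_volume((21, 21, 21))
        n = ellipsoid_mask(vol, (0, 0, 0), (5, 4, 3)).sum()
        analytic = 4 / 3 * np.pi * 60
        assert abs(n / analytic - 1) < 0.2

    def test_brain_mask_contains_all_nuclei(self, default_atlas):
        brain = brain_mask_volume(default_atlas)
        assert np.all(brain.data[default_atlas.data > 0] == 1)

    def test_deterministic(self, default_atlas):
        again = generate_atlas()
        assert np.array_equal(again.data, default_atlas.data)
        assert np.allclose(again.affine, default_atlas.affine)

    def test_too_small_grid_raises_sizing_error(self):
        with pytest.raises(AtlasSizingError):
            generate_atlas(AtlasSpec(grid_shape=(40, 40, 40)))


class TestElectrodes:
    def test_zero_displacement_gives_zero_boundary_distance(self, default_atlas):
        cfg = zero_noise_config()
        for target in ("GPi", "STN"):
            electrodes, truth = generate_electrodes(
                default_atlas, cfg, 0, target, LIB["3389"])
            for hemi, e in electrodes.items():
                labels = atlas_region_labels(target, hemi, "motor")
                assert boundary_distance(e, default_atlas, labels) == 0.0
                assert np.allclose(truth[hemi], 0)

    def test_injected_offset_recovered_exactly(self, default_atlas):
        dm = {k: Stratum((0.0, 0.0, 0.0), (0.0, 0.0, 0.0))
              for k in [("left", "STN"), ("right", "STN"),
                        ("left", "GPi"), ("right", "GPi")]}
        dm[("left", "STN")] = Stratum((1.0, 0.0, 0.0), (0.0, 0.0, 0.0))
        cfg = zero_noise_config(displacement_model=dm)
        electrodes, _ = generate_electrodes(default_atlas, cfg, 0, "STN",
                                            LIB["3389"])
        labels = atlas_region_labels("STN", "left", "motor")
        off, norm = centroid_offset(electrodes["left"], default_atlas, labels)
        assert np.allclose(off, [1.0, 0.0, 0.0], atol=1e-9)
        assert norm == pytest.approx(1.0, abs=1e-9)

    def test_right_x_variance_multiplier(self, default_atlas):
        """Monte-Carlo check: with multiplier 2 the right-side lateral
        displacement variance is ~4x the left's at n = 500 per side."""
        dm = {k: Stratum((0.0, 0.0, 0.0), (1.0, 1.0, 1.0))
              for k in [("left", "STN"), ("right", "STN"),
                        ("left", "GPi"), ("right", "GPi")]}
        cfg = CohortConfig(n_subjects=500, displacement_model=dm,
                           right_x_variance_multiplier=2.0, seed=3)
        left_x, right_x = [], []
        for k in range(500):
            _, truth = generate_electrodes(default_atlas, cfg, k, "STN",
                                           LIB["3389"])
            left_x.append(truth["left"][0])
            right_x.append(truth["right"][0])
        ratio = np.var(right_x) / np.var(left_x)
        assert 2.8 < ratio < 5.7   # ~99% interval for a variance ratio, n=500

    def test_missing_stratum_is_configuration_error(self, default_atlas):
        cfg = zero_noise_config()
        dm = dict(cfg.displacement_model)
        del dm[("right", "STN")]
        cfg2 = zero_noise_config(displacement_model=dm)
        with pytest.raises(ConfigurationError, match="stratum"):
            generate_electrodes(default_atlas, cfg2, 0, "STN", LIB["3389"])


class TestPostopState:
    def test_zero_cavity_leaves_mask_unchanged(self, default_atlas):
        brain = brain_mask_volume(default_atlas)
        cfg = zero_noise_config()
        carved, scrf, truth = generate_postop_state(0, brain, cfg)
        assert np.array_equal(carved.data, brain.data)
        assert truth["pneumocephalus_ml"] == 0.0

    def test_zero_scrf_scales_give_identity(self, default_atlas):
        brain = brain_mask_volume(default_atlas)
        cfg = zero_noise_config()
        _, scrf, _ = generate_postop_state(0, brain, cfg)
        for hemi in ("left", "right"):
            assert np.array_equal(scrf[hemi], np.eye(4))

    def test_five_ml_removes_about_5000_voxels(self, default_atlas):
        brain = brain_mask_volume(default_atlas)
        rng = np.random.default_rng(0)
        carved, truth_ml = carve_air_cavity(brain, 5.0, rng)
        removed = int(brain.data.sum() - carved.data.sum())
        assert abs(removed - 5000) < 250
        assert truth_ml == pytest.approx(removed / 1000.0)

    def test_cavity_is_frontal(self, default_atlas):
        brain = brain_mask_volume(default_atlas)
        rng = np.random.default_rng(1)
        carved, _ = carve_air_cavity(brain, 8.0, rng)
        removed = np.argwhere((brain.data == 1) & (carved.data == 0))
        y = brain.voxel_to_world(removed)[:, 1]
        all_y = brain.voxel_to_world(np.argwhere(brain.data == 1))[:, 1]
        third = all_y.min() + 2 * (all_y.max() - all_y.min()) / 3
        assert y.min() >= third - 1e-9

    def test_oversized_cavity_rejected(self, default_atlas):
        brain = brain_mask_volume(default_atlas)
        with pytest.raises(ValueError, match="exceeds"):
            carve_air_cavity(brain, 1e6, np.random.default_rng(0))


class TestOutcomes:
    def test_zero_dispersion_reproduces_exact_effect(self):
        cfg = zero_noise_config()
        effects = dict(cfg.outcome_effects)
        for k, v in effects.items():
            effects[k] = type(v)(v.mean_pct, 0.0)
        cfg = zero_noise_config(outcome_effects=effects)
        pre, post, pct = generate_outcomes(cfg, 0, "STN")
        assert post["UPDRS3"] == pytest.approx(pre["UPDRS3"] * (1 - 0.459))
        assert pct["UPDRS3"] == -45.9

    def test_null_effect_means_post_equals_pre(self):
        cfg = zero_noise_config()
        effects = {k: type(v)(0.0, 0.0) for k, v in cfg.outcome_effects.items()}
        cfg = zero_noise_config(outcome_effects=effects)
        pre, post, _ = generate_outcomes(cfg, 0, "GPi")
        assert pre == post

    def test_ledd_reduction_larger_for_stn(self):
        cfg = CohortConfig(n_subjects=200, seed=5)
        stn = [generate_outcomes(cfg, k, "STN") for k in range(100)]
        gpi = [generate_outcomes(cfg, k, "GPi") for k in range(100, 200)]

        def mean_pct(rows):
            return np.mean([
                100 * (post["LEDD"] - pre["LEDD"]) / pre["LEDD"]
                for pre, post, _ in rows
            ])

        assert mean_pct(stn) < mean_pct(gpi)

    def test_scores_floored_at_zero(self):
        cfg = zero_noise_config()
        effects = {k: type(v)(-150.0, 0.0) for k, v in cfg.outcome_effects.items()}
        cfg = zero_noise_config(outcome_effects=effects)
        _, post, _ = generate_outcomes(cfg, 0, "STN")
        assert all(v == 0.0 for v in post.values())

    def test_missing_effect_rejected(self):
        cfg = zero_noise_config()
        effects = dict(cfg.outcome_effects)
        del effects["LEDD_STN"]
        cfg = zero_noise_config(outcome_effects=effects)
        with pytest.raises(ConfigurationError, match="LEDD_STN"):
            generate_outcomes(cfg, 0, "STN")


class TestCohortDeterminism:
    def test_same_seed_bit_identical(self):
        a = generate_cohort(CohortConfig(n_subjects=3, seed=11))
        b = generate_cohort(CohortConfig(n_subjects=3, seed=11))
        assert np.array_equal(a.atlas.data, b.atlas.data)
        for sa, sb in zip(a.subjects, b.subjects):
            assert sa.target == sb.target and sa.lead_model == sb.lead_model
            for h in ("left", "right"):
                assert np.array_equal(sa.electrodes[h].tip, sb.electrodes[h].tip)
                assert np.array_equal(sa.scrf[h], sb.scrf[h])
            assert sa.scores_pre == sb.scores_pre
            assert sa.pneumocephalus_truth_ml == sb.pneumocephalus_truth_ml

    def test_subject_k_invariant_to_cohort_size(self, default_atlas):
        lib = load_lead_library()
        brain = brain_mask_volume(default_atlas)
        small = CohortConfig(n_subjects=2, seed=4)
        large = CohortConfig(n_subjects=5, seed=4)
        sa = generate_subject(small, 1, default_atlas, brain, lib)
        sb = generate_subject(large, 1, default_atlas, brain, lib)
        assert sa.target == sb.target
        assert np.array_equal(sa.electrodes["left"].tip, sb.electrodes["left"].tip)
        assert sa.scores_pre == sb.scores_pre

    def test_nifti_round_trip_lossless(self, default_atlas, tmp_path):
        from dbsaudit.io import read_nifti, write_nifti

        p = tmp_path / "atlas.nii.gz"
        write_nifti(default_atlas, p)
        back = read_nifti(p)
        assert np.array_equal(back.data, default_atlas.data)
        assert np.allclose(back.affine, default_atlas.affine, atol=1e-6)
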