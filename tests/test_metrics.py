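import numpy as np
import pytest

from dbsaudit.leads import ElectrodeModel, LeadSpec
from dbsaudit.metrics import (
    apply_scrf,
    boundary_distance,
    centroid_offset,
    flag_outliers,
    rigid_affine,
    summarise_accuracy,
    target_plot_table,
    validate_affine,
)
from dbsaudit.volumes import LabelVolume, ellipsoid_mask

from conftest import (
    make_label_volume,
    random_electrode,
    random_ellipsoid_volume,
    random_rigid,
    sphere_volume,
    surface_voxel_centers,
)

POINT_SPEC = LeadSpec("point", 1, 1.0, 1.0, 0.0)


def point_electrode(at):
    """Single-contact electrode whose only contact sits exactly at ``at``."""
    return ElectrodeModel(tip=at, direction=(0, 0, 1), spec=POINT_SPEC)


class TestBoundaryDistance:
    def test_contact_inside_region_clamps_to_zero(self):
        vol = sphere_volume(4.0)
        assert boundary_distance(point_electrode((0, 0, 0)), vol, 1) == 0.0

    def test_sphere_analytic(self):
        vol = sphere_volume(4.0)
        d = boundary_distance(point_electrode((0, 0, 6)), vol, 1)
        assert d == pytest.approx(2.0, abs=1e-9)

    def test_signed_depth_for_inside_contact(self):
        vol = sphere_volume(5.0)
        d = boundary_distance(point_electrode((0, 0, 0)), vol, 1, signed=True)
        assert d < -3.0

    def test_empty_region_error_names_label(self):
        vol = make_label_volume()
        with pytest.raises(ValueError, match="region"):
            boundary_distance(point_electrode((0, 0, 0)), vol, "region")

    def test_matches_brute_force_surface_oracle(self):
        """Random voxelised ellipsoids vs exhaustive min over contacts x
        surface-voxel centres, within one voxel diagonal."""
        from dbsaudit.leads import contact_centers

        rng = np.random.default_rng(42)
        tol = np.sqrt(3.0)  # one voxel diagonal at 1 mm voxels
        for _ in range(40):
            vol = random_ellipsoid_volume(rng)
            e = random_electrode(rng, tip_range=13.0)
            got = boundary_distance(e, vol, 1)
            centers = contact_centers(e)
            surf = surface_voxel_centers(vol)
            brute = np.linalg.norm(
                centers[:, None, :] - surf[None, :, :], axis=-1).min()
            inside = vol.mask(1)[tuple(np.clip(
                np.round(vol.world_to_voxel(centers)).astype(int),
                0, np.array(vol.data.shape) - 1).T)]
            if inside.any():
                brute = 0.0
            assert abs(got - brute) <= tol

    def test_bounded_by_centroid_offset_outside(self):
        """When the electrode is outside the region, the boundary is nearer
        than the centre of gravity."""
        rng = np.random.default_rng(3)
        for _ in range(20):
            vol = random_ellipsoid_volume(rng)
            e = random_electrode(rng, tip_range=13.0)
            bd = boundary_distance(e, vol, 1)
            if bd > 0:
                _, norm = centroid_offset(e, vol, 1)
                assert bd <= norm + 1e-9


class TestCentroidOffset:
    def test_contact_at_centroid_gives_zero(self):
        vol = sphere_volume(4.0)
        c = vol.centroid_world(1)
        off, norm = centroid_offset(point_electrode(c), vol, 1)
        assert np.allclose(off, 0, atol=1e-9) and norm == pytest.approx(0, abs=1e-9)

    def test_norm_is_euclidean(self):
        vol = sphere_volume(4.0)
        c = vol.centroid_world(1)
        off, norm = centroid_offset(point_electrode(c + [1, 2, 2]), vol, 1)
        assert np.allclose(off, [1, 2, 2], atol=1e-9)
        assert norm == pytest.approx(3.0, abs=1e-9)

    def test_symmetric_ellipsoid_centroid_near_analytic_center(self):
        vol = make_label_volume((41, 41, 41))
        vol.data[ellipsoid_mask(vol, (1.0, -2.0, 3.0), (7, 5, 4))] = 1
        assert np.all(np.abs(vol.centroid_world(1) - [1.0, -2.0, 3.0]) <= 0.5)


class TestApplyScrf:
    def test_identity_leaves_electrode_unchanged(self, simple_spec):
        e = random_electrode(np.random.default_rng(0), simple_spec)
        out = apply_scrf(e, np.eye(4))
        assert np.allclose(out.tip, e.tip) and np.allclose(out.direction, e.direction)

    def test_pure_translation_shifts_centroid_offset_exactly(self, simple_spec):
        vol = sphere_volume(5.0, shape=(61, 61, 61))
        e = ElectrodeModel(tip=(1, 1, -2), direction=(0, 0, 1), spec=simple_spec)
        t = np.array([1.5, -2.0, 0.5])
        off0, _ = centroid_offset(e, vol, 1)
        off1, _ = centroid_offset(apply_scrf(e, rigid_affine(t)), vol, 1)
        assert np.allclose(off1 - off0, t, atol=1e-9)

    def test_composition_matches_matrix_product(self, simple_spec):
        rng = np.random.default_rng(11)
        for _ in range(20):
            e = random_electrode(rng, simple_spec)
            A, B = random_rigid(rng), random_rigid(rng)
            once = apply_scrf(e, A @ B)
            twice = apply_scrf(apply_scrf(e, B), A)
            assert np.allclose(once.tip, twice.tip, atol=1e-9)
            assert np.allclose(once.direction, twice.direction, atol=1e-9)

    def test_singular_matrix_rejected(self, simple_spec):
        e = random_electrode(np.random.default_rng(0), simple_spec)
        bad = np.eye(4)
        bad[0, 0] = 0.0
        with pytest.raises(ValueError, match="singular"):
            apply_scrf(e, bad)

    def test_affine_validation(self):
        with pytest.raises(ValueError, match="last row"):
            validate_affine(np.ones((4, 4)))


class TestRigidMotionInvariance:
    def test_boundary_distance_invariant_under_joint_rigid_motion(self):
        """Moving electrode and region together leaves the distance unchanged
        to within one voxel diagonal (the region is re-voxelised)."""
        rng = np.random.default_rng(7)
        tol = np.sqrt(3.0)
        for _ in range(10):
            center = rng.uniform(-3, 3, 3)
            semi = rng.uniform(3, 6, 3)
            vol = make_label_volume((36, 36, 36))
            vol.data[ellipsoid_mask(vol, center, semi)] = 1
            e = random_electrode(rng, tip_range=12.0)
            d0 = boundary_distance(e, vol, 1)

            M = random_rigid(rng, translation_scale=2.0)
            moved = make_label_volume((46, 46, 46))
            # transform the ellipsoid analytically: rigid image of an
            # ellipsoid with rotated axes; voxelise in the moved frame by
            # pulling voxel centres back through the inverse
            inv = np.linalg.inv(M)
            ijk = np.indices(moved.data.shape).reshape(3, -1).T
            xyz = moved.voxel_to_world(ijk)
            back = xyz @ inv[:3, :3].T + inv[:3, 3]
            inside = (((back - center) / semi) ** 2).sum(axis=1) <= 1.0
            moved.data[tuple(ijk[inside].T)] = 1
            d1 = boundary_distance(apply_scrf(e, M), moved, 1)
            assert abs(d1 - d0) <= tol


class TestOutliers:
    def test_all_equal_has_no_outliers(self):
        assert not flag_outliers([2.0] * 8).any()

    def test_single_extreme_value_flagged(self):
        flags = flag_outliers([0, 0, 0, 0, 0, 0, 0, 10])
        assert flags.tolist() == [False] * 7 + [True]

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            flag_outliers([1.0, 2.0, 3.0])

    def test_matches_literal_quartile_recomputation(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            x = rng.exponential(1.0, rng.integers(4, 60))
            q1, q3 = np.percentile(x, [25, 75])
            expected = x > q3 + 1.5 * (q3 - q1)
            assert (flag_outliers(x) == expected).all()


def _fake_results():
    import pandas as pd

    rng = np.random.default_rng(2)
    rows = []
    for i in range(12):
        for nucleus in ("GPi", "STN"):
            rows.append(dict(
                subject=f"s{i}", hemisphere="left" if i % 2 else "right",
                nucleus=nucleus, reference="main",
                boundary_distance=float(rng.exponential(0.5)),
                dx=float(rng.normal()), dy=float(rng.normal()),
                dz=float(rng.normal()), centroid_norm=1.0,
                scrf_applied=True, outlier=False,
            ))
    return pd.DataFrame(rows)


class TestSummaries:
    def test_zero_distances_all_within_threshold(self):
        df = _fake_results()
        df["boundary_distance"] = 0.0
        out = summarise_accuracy(df, ["nucleus"])
        assert (out["mean"] == 0).all()
        assert (out["within_threshold"] == out["n"]).all()

    def test_group_means_match_hand_computation(self):
        df = _fake_results()
        out = summarise_accuracy(df, ["nucleus"]).set_index("nucleus")
        for nucleus, grp in df.groupby("nucleus"):
            assert out.loc[nucleus, "mean"] == pytest.approx(
                grp["boundary_distance"].mean())
            assert out.loc[nucleus, "sd"] == pytest.approx(
                grp["boundary_distance"].std(ddof=1))

    def test_two_sd_columns_by_construction(self):
        out = summarise_accuracy(_fake_results(), ["nucleus"])
        assert np.allclose(out["mean_plus_2sd"], out["mean"] + 2 * out["sd"])
        assert np.allclose(out["mean_minus_2sd"], out["mean"] - 2 * out["sd"])

    def test_unknown_grouping_key_rejected(self):
        with pytest.raises(KeyError, match="flavour"):
            summarise_accuracy(_fake_results(), ["flavour"])

    def test_target_plot_table_scrf_states(self):
        df = _fake_results()
        df2 = df.copy()
        df2["scrf_applied"] = False
        both = target_plot_table(__import__("pandas").concat([df, df2]))
        assert set(both["scrf_state"]) == {"SCRF", "nSCRF"}
        # identity SCRF: both variants carry identical coordinates
        a = both[both["scrf_state"] == "SCRF"][["dx", "dy", "dz"]].to_numpy()
        b = both[both["scrf_state"] == "nSCRF"][["dx", "dy", "dz"]].to_numpy()
        assert np.allclose(np.sort(a, axis=0), np.sort(b, axis=0))
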