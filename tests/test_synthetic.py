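"""Phantom and feature-table generator behaviour."""

import numpy as np
import pytest

from vmi_radstab.stability import ccc
from vmi_radstab.synthetic import (
    DOSES_MGY,
    ENERGIES_KEV,
    AcquisitionCondition,
    FeatureTableSpec,
    ObjectSpec,
    PhantomSpec,
    default_phantom_spec,
    energy_transform,
    generate_feature_table,
    generate_phantom_volume,
    noise_sigma,
    simulate_repeat,
)


class TestEnergyTransform:
    def test_no_iodine_is_energy_independent(self):
        for e in ENERGIES_KEV:
            assert energy_transform(0.0, 0.0, e) == 0.0
            assert energy_transform(-179.0, 0.0, e) == -179.0

    def test_reference_anchor_at_75kev(self):
        assert energy_transform(45.0, 1.0, 75) == 145.0

    def test_strictly_decreasing_in_energy_with_iodine(self):
        vals = [energy_transform(0.0, 0.5, e) for e in ENERGIES_KEV]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_unsupported_energy_names_allowed_set(self):
        with pytest.raises(ValueError, match=r"40.*50.*75.*120.*190"):
            energy_transform(0.0, 0.0, 60)


class TestNoiseSigma:
    def test_square_root_dose_law_exact(self):
        for scanner in ("DSDE", "SFDE"):
            for e in ENERGIES_KEV:
                lo = noise_sigma(AcquisitionCondition(e, 5, scanner))
                hi = noise_sigma(AcquisitionCondition(e, 15, scanner))
                assert abs(lo / hi - np.sqrt(3.0)) < 1e-12

    def test_split_filter_noisier_than_dual_source(self):
        for e in ENERGIES_KEV:
            for d in DOSES_MGY:
                assert noise_sigma(
                    AcquisitionCondition(e, d, "SFDE")
                ) > noise_sigma(AcquisitionCondition(e, d, "DSDE"))

    def test_minimal_at_75_kev(self):
        sigmas = {e: noise_sigma(AcquisitionCondition(e, 15, "DSDE")) for e in ENERGIES_KEV}
        assert min(sigmas, key=sigmas.get) == 75


class TestPhantomVolume:
    def test_noise_and_texture_free_objects_are_constant(self):
        objs = (ObjectSpec("o", "A", (16.0, 16.0, 16.0), (6.0, 5.0, 4.0), 50.0, 0.3),)
        spec = PhantomSpec(grid_shape=(32, 32, 32), objects=objs, seed=0)
        cond = AcquisitionCondition(120, 15, "DSDE")
        vol, masks = generate_phantom_volume(spec, cond, noise_scale=0.0)
        inside = vol.values[masks["o"].values]
        expected = energy_transform(50.0, 0.3, 120)
        assert np.all(inside == expected)
        assert np.all(vol.values[~masks["o"].values] == -1000.0)

    def test_masks_are_exact_ellipsoid_membership(self):
        objs = (ObjectSpec("o", "A", (16.0, 16.0, 16.0), (6.0, 5.0, 4.0), 50.0),)
        spec = PhantomSpec(grid_shape=(32, 32, 32), objects=objs, seed=0)
        _, masks = generate_phantom_volume(spec, AcquisitionCondition(75, 15, "DSDE"))
        idx = np.indices((32, 32, 32)).reshape(3, -1).T
        centers = (idx + 0.5) * 1.0
        rel = (centers - np.array([16.0, 16.0, 16.0])) / np.array([6.0, 5.0, 4.0])
        inside = ((rel**2).sum(axis=1) <= 1.0).reshape(32, 32, 32)
        assert np.array_equal(masks["o"].values, inside)

    def test_bit_reproducible(self, phantom_spec):
        cond = AcquisitionCondition(40, 5, "SFDE", 1)
        v1, m1 = generate_phantom_volume(phantom_spec, cond)
        v2, m2 = generate_phantom_volume(phantom_spec, cond)
        assert np.array_equal(v1.values, v2.values)
        for k in m1:
            assert np.array_equal(m1[k].values, m2[k].values)

    def test_repeats_differ_only_in_pose_and_noise(self, phantom_spec):
        c0 = AcquisitionCondition(75, 15, "DSDE", 0)
        c1 = AcquisitionCondition(75, 15, "DSDE", 1)
        v0, m0 = generate_phantom_volume(phantom_spec, c0)
        v1, m1 = generate_phantom_volume(phantom_spec, c1)
        assert set(m0) == set(m1)
        assert not np.array_equal(v0.values, v1.values)

    def test_overlapping_objects_rejected(self):
        objs = (
            ObjectSpec("a", "A", (16.0, 16.0, 16.0), (6.0, 6.0, 6.0), 0.0),
            ObjectSpec("b", "B", (20.0, 16.0, 16.0), (6.0, 6.0, 6.0), 0.0),
        )
        spec = PhantomSpec(grid_shape=(32, 32, 32), objects=objs, seed=0)
        with pytest.raises(ValueError, match="overlap"):
            generate_phantom_volume(spec, AcquisitionCondition(75, 15, "DSDE"))

    def test_object_outside_grid_rejected(self):
        objs = (ObjectSpec("a", "A", (3.0, 16.0, 16.0), (6.0, 6.0, 6.0), 0.0),)
        spec = PhantomSpec(grid_shape=(32, 32, 32), objects=objs, seed=0)
        with pytest.raises(ValueError, match="outside the grid"):
            generate_phantom_volume(spec, AcquisitionCondition(75, 15, "DSDE"))

    def test_mean_hu_matches_analytic_within_clt_bound(self):
        # texture off: in-mask mean of pure noise around the class mean
        objs = (ObjectSpec("o", "A", (16.0, 16.0, 16.0), (7.0, 6.0, 5.0), -30.0),)
        spec = PhantomSpec(grid_shape=(32, 32, 32), objects=objs, seed=4)
        cond = AcquisitionCondition(75, 15, "DSDE")
        vol, masks = generate_phantom_volume(spec, cond)
        x = vol.values[masks["o"].values]
        sigma = noise_sigma(cond)
        assert abs(x.mean() - (-30.0)) < 3.0 * sigma / np.sqrt(x.size)


class TestSimulateRepeat:
    def test_requires_repeat_id_one(self, phantom_spec):
        with pytest.raises(ValueError, match="repeat_id"):
            simulate_repeat(phantom_spec, AcquisitionCondition(75, 15, "DSDE", 0))

    def test_volumes_agree_within_voxelization_tolerance(self, fine_phantom_spec):
        c0 = AcquisitionCondition(75, 15, "DSDE", 0)
        c1 = AcquisitionCondition(75, 15, "DSDE", 1)
        _, m0 = generate_phantom_volume(fine_phantom_spec, c0)
        _, m1 = simulate_repeat(fine_phantom_spec, c1)
        for k in m0:
            v0, v1 = m0[k].n_voxels, m1[k].n_voxels
            assert abs(v0 - v1) / v0 < 0.02

    def test_mean_hu_agrees_between_repeats_within_noise(self, fine_phantom_spec):
        cond0 = AcquisitionCondition(75, 15, "DSDE", 0)
        cond1 = AcquisitionCondition(75, 15, "DSDE", 1)
        vol0, m0 = generate_phantom_volume(fine_phantom_spec, cond0)
        vol1, m1 = simulate_repeat(fine_phantom_spec, cond1)
        sigma = noise_sigma(cond0)
        for k in m0:
            a = vol0.values[m0[k].values]
            b = vol1.values[m1[k].values]
            se = sigma * np.sqrt(1.0 / a.size + 1.0 / b.size)
            # 5 standard errors: voxelization adds a little beyond pure noise
            assert abs(a.mean() - b.mean()) < 5.0 * se


class TestFeatureTable:
    def test_perfect_target_ccc_gives_identical_repeats(self):
        spec = FeatureTableSpec(n_objects=20, n_features=10, target_ccc=1.0, seed=0)
        test, retest, _ = generate_feature_table(spec)
        assert np.array_equal(test.to_numpy(), retest.to_numpy())

    def test_invalid_target_ccc_rejected(self):
        with pytest.raises(ValueError, match="target_ccc"):
            FeatureTableSpec(target_ccc=0.0)
        with pytest.raises(ValueError, match="target_ccc"):
            FeatureTableSpec(target_ccc=1.2)

    def test_objects_divisible_by_classes(self):
        with pytest.raises(ValueError, match="divisible"):
            FeatureTableSpec(n_objects=10, n_classes=4)

    @pytest.mark.parametrize("n,tol", [(50, 0.12), (200, 0.06), (1000, 0.02)])
    def test_empirical_ccc_converges_to_target(self, n, tol):
        """Mean estimated CCC approaches the target as n_objects grows."""
        spec = FeatureTableSpec(
            n_objects=n, n_classes=2, n_features=40, target_ccc=0.8, seed=7
        )
        test, retest, _ = generate_feature_table(spec)
        est = np.mean(
            [ccc(test[c].to_numpy(), retest[c].to_numpy()) for c in test.columns]
        )
        assert abs(est - 0.8) < tol
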