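"""Kabsch superposition, centre of mass and transform decomposition."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from helicore.structure import AtomSet
from helicore.superpose import (RigidTransform, center_of_mass,
                                decompose_transform, kabsch_fit,
                                pair_common_atoms, rotation_from_axis_angle)
from helicore.synthetic import gen_rigid_pair, random_rigid_transform


def _atomset(keys, coords):
    coords = np.asarray(coords, dtype=float)
    return AtomSet("T", "A", keys, coords, np.ones(len(coords)))


class TestPairCommonAtoms:
    def test_identical_sets_pair_fully(self, rng):
        keys = [(i, "", "CA") for i in range(1, 11)]
        a = _atomset(keys, rng.normal(size=(10, 3)))
        b = _atomset(keys, rng.normal(size=(10, 3)))
        ca, cb, common, _ = pair_common_atoms(a, b)
        assert len(common) == 10

    def test_missing_residues_reduce_pairs(self, rng):
        keys_b = [(i, "", "CA") for i in range(1, 11)]
        keys_a = [k for k in keys_b if k[0] not in (5, 7)]
        a = _atomset(keys_a, rng.normal(size=(8, 3)))
        b = _atomset(keys_b, rng.normal(size=(10, 3)))
        _, _, common, _ = pair_common_atoms(a, b)
        assert len(common) == 8
        assert [k[0] for k in common] == [1, 2, 3, 4, 6, 8, 9, 10]

    def test_random_deletions_match_set_oracle(self, rng):
        for trial in range(10):
            all_keys = [(i, "", "CA") for i in range(1, 31)]
            ka = [k for k in all_keys if rng.random() > 0.3]
            kb = [k for k in all_keys if rng.random() > 0.3]
            if len(set(ka) & set(kb)) < 3:
                continue
            a = _atomset(ka, rng.normal(size=(len(ka), 3)))
            b = _atomset(kb, rng.normal(size=(len(kb), 3)))
            _, _, common, _ = pair_common_atoms(a, b)
            assert set(common) == set(ka) & set(kb)

    def test_alignment_mode_maps_residue_numbers(self, rng):
        ka = [(i, "", "CA") for i in range(1, 6)]
        kb = [(i + 100, "", "CA") for i in range(1, 6)]
        a = _atomset(ka, rng.normal(size=(5, 3)))
        b = _atomset(kb, rng.normal(size=(5, 3)))
        with pytest.raises(ValueError):
            pair_common_atoms(a, b)          # no overlap by raw number
        equiv = {i: i + 100 for i in range(1, 6)}
        _, _, common, _ = pair_common_atoms(a, b, "by-alignment", equiv)
        assert len(common) == 5

    def test_too_few_pairs_is_an_error(self, rng):
        a = _atomset([(1, "", "CA"), (2, "", "CA")], rng.normal(size=(2, 3)))
        with pytest.raises(ValueError, match=">= 3"):
            pair_common_atoms(a, a)


class TestKabschFit:
    def test_identity_on_identical_sets(self, rng):
        pts = rng.normal(size=(20, 3)) * 5
        fit = kabsch_fit(pts, pts)
        assert fit.rmsd == pytest.approx(0.0, abs=1e-12)
        dec = decompose_transform(fit.transform, np.zeros(3))
        assert dec.angle_deg == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize("angle,axis,trans", [
        (19.0, (0, 0, 1), (1, 2, 3)),
        (5.0, (1, 1, 0), (0, 0, 1.8)),
        (90.0, (1, 0, 0), (-4, 2, 0)),
        (179.0, (0, 1, 0), (0, 0, 0)),
    ])
    def test_recovers_generator_transform(self, angle, axis, trans):
        fx = gen_rigid_pair(40, angle, axis, trans, seed=7)
        fit = kabsch_fit(fx.set_a.coords, fx.set_b.coords)
        np.testing.assert_allclose(fit.transform.rotation,
                                   fx.truth.rotation, atol=1e-9)
        np.testing.assert_allclose(fit.transform.translation,
                                   fx.truth.translation, atol=1e-8)
        dec = decompose_transform(fit.transform, np.zeros(3))
        assert dec.angle_deg == pytest.approx(angle, abs=1e-6)

    def test_noisy_rmsd_equals_recomputed_residual_rms(self):
        fx = gen_rigid_pair(60, 25.0, (0, 1, 1), (2, -1, 0),
                            noise_sigma=0.2, seed=9)
        fit = kabsch_fit(fx.set_a.coords, fx.set_b.coords)
        moved = fx.set_a.coords @ fit.transform.rotation.T \
            + fit.transform.translation
        rms = np.sqrt(np.mean(np.sum((moved - fx.set_b.coords) ** 2, axis=1)))
        assert fit.rmsd == pytest.approx(rms, abs=1e-9)

    def test_agrees_with_scipy_align_vectors(self, rng):
        """Independent oracle: scipy's Wahba solver on centred clouds."""
        a = rng.normal(size=(30, 3)) * 8
        truth = random_rigid_transform(3)
        b = truth.apply(a) + rng.normal(scale=0.1, size=(30, 3))
        fit = kabsch_fit(a, b)
        rot, _ = Rotation.align_vectors(b - b.mean(axis=0),
                                        a - a.mean(axis=0))
        np.testing.assert_allclose(fit.transform.rotation,
                                   rot.as_matrix(), atol=1e-6)

    def test_fit_never_worse_than_untransformed(self, rng):
        a = rng.normal(size=(25, 3)) * 6
        b = rng.normal(size=(25, 3)) * 6
        fit = kabsch_fit(a, b)
        raw = np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1)))
        assert fit.rmsd <= raw + 1e-12

    def test_collinear_input_raises_not_reflects(self):
        t = np.linspace(0, 10, 12)
        line = np.stack([t, 2 * t, -t], axis=1)
        with pytest.raises(ValueError, match="degenerate|collinear"):
            kabsch_fit(line, line[::-1])

    def test_weighted_fit_matches_mass_replication(self, rng):
        """Integer weights equal plain Kabsch on a replicated point list."""
        a = rng.normal(size=(12, 3)) * 5
        truth = random_rigid_transform(5)
        b = truth.apply(a) + rng.normal(scale=0.3, size=a.shape)
        w = rng.integers(1, 4, size=12).astype(float)
        fit_w = kabsch_fit(a, b, weights=w)
        rep = np.repeat(np.arange(12), w.astype(int))
        fit_r = kabsch_fit(a[rep], b[rep])
        np.testing.assert_allclose(fit_w.transform.rotation,
                                   fit_r.transform.rotation, atol=1e-9)
        assert fit_w.rmsd == pytest.approx(fit_r.rmsd, abs=1e-9)

    def test_rigid_motion_invariance_of_rmsd_and_angle(self, rng):
        """Applying one global rigid motion to both members leaves rmsd,
        angle and point displacement unchanged."""
        fx = gen_rigid_pair(30, 33.0, (1, 2, 2), (1, 0, -2),
                            noise_sigma=0.15, seed=13)
        ref_fit = kabsch_fit(fx.set_a.coords, fx.set_b.coords)
        ref_dec = decompose_transform(ref_fit.transform,
                                      fx.set_a.coords.mean(axis=0))
        for seed in range(5):
            g = random_rigid_transform(seed)
            fit = kabsch_fit(g.apply(fx.set_a.coords),
                             g.apply(fx.set_b.coords))
            dec = decompose_transform(fit.transform,
                                      g.apply(fx.set_a.coords.mean(axis=0)))
            assert fit.rmsd == pytest.approx(ref_fit.rmsd, abs=1e-9)
            assert dec.angle_deg == pytest.approx(ref_dec.angle_deg,
                                                  abs=1e-7)
            assert dec.point_displacement == pytest.approx(
                ref_dec.point_displacement, abs=1e-7)


class TestCenterOfMass:
    def test_single_and_symmetric_pairs(self):
        one = _atomset([(1, "", "CA")], [[1.0, 2.0, 3.0]])
        np.testing.assert_allclose(center_of_mass(one), [1, 2, 3])
        two = _atomset([(1, "", "CA"), (2, "", "CA")],
                       [[0, 0, 0], [2, 0, 0]])
        np.testing.assert_allclose(center_of_mass(two), [1, 0, 0])

    def test_mass_weighting_matches_brute_force_loop(self, rng):
        coords = rng.normal(size=(50, 3)) * 4
        masses = rng.uniform(1.0, 32.0, size=50)
        s = AtomSet("T", "A", [(i, "", "X") for i in range(50)],
                    coords, masses)
        num = np.zeros(3)
        for m, x in zip(masses, coords):
            num += m * x
        np.testing.assert_allclose(center_of_mass(s, "atomic-mass"),
                                   num / masses.sum(), atol=1e-12)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            center_of_mass(np.empty((0, 3)))


class TestDecompose:
    def test_identity_transform(self):
        dec = decompose_transform(RigidTransform.identity(),
                                  np.array([5.0, 5.0, 5.0]))
        assert dec.angle_deg == pytest.approx(0.0)
        assert dec.point_displacement == pytest.approx(0.0)

    def test_rotation_about_axis_through_reference_point(self):
        p = np.array([3.0, -2.0, 7.0])
        R = rotation_from_axis_angle(np.array([0, 0, 1.0]), 19.0)
        t = p - R @ p                  # axis passes through p
        dec = decompose_transform(RigidTransform(R, t), p)
        assert dec.angle_deg == pytest.approx(19.0, abs=1e-9)
        assert dec.point_displacement == pytest.approx(0.0, abs=1e-9)

    def test_decompose_recompose_roundtrip(self, rng):
        for _ in range(30):
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            angle = float(rng.uniform(0.1, 179.9))
            R = rotation_from_axis_angle(axis, angle)
            dec = decompose_transform(RigidTransform(R, np.zeros(3)),
                                      np.zeros(3))
            R2 = rotation_from_axis_angle(dec.axis, dec.angle_deg)
            np.testing.assert_allclose(R2, R, atol=1e-6)

    def test_angle_always_in_0_180(self, rng):
        for seed in range(20):
            g = random_rigid_transform(seed)
            dec = decompose_transform(g, rng.normal(size=3))
            assert 0.0 <= dec.angle_deg <= 180.0
            assert np.linalg.norm(dec.axis) == pytest.approx(1.0)


def test_improper_rotation_rejected():
    refl = np.diag([1.0, 1.0, -1.0])
    with pytest.raises(ValueError, match="improper"):
        RigidTransform(refl, np.zeros(3))
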