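"""Rigid alignment by SVD and the iterative 2D-3D correction."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from poselift import (
    EuclideanTransform,
    Heatmap,
    WeightVector,
    alignment_residual,
    decode,
    iterative_correction,
    kabsch,
    lift_keypoints,
    mpjpe,
    normalize_points,
    sample_scene,
)


def _random_instance(g, k=None, scale_noise=0.0):
    k = k or int(g.integers(3, 11))
    P = g.normal(size=(k, 3))
    R = Rotation.random(random_state=int(g.integers(2**31))).as_matrix()
    t = g.normal(size=3)
    Q = P @ R.T + t + scale_noise * g.normal(size=(k, 3))
    w = g.uniform(0.2, 5.0, size=k)
    return P, Q, w, R, t


class TestKabsch:
    def test_identity_alignment(self):
        P = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0]])
        T = kabsch(P, P)
        np.testing.assert_allclose(T.rotation, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(T.translation, 0, atol=1e-12)

    def test_quarter_turn_recovered(self, rng):
        P = rng.normal(size=(6, 3))
        Rz = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        Q = P @ Rz.T
        T = kabsch(P, Q)
        np.testing.assert_allclose(T.apply(P), Q, atol=1e-9)

    def test_translation_maps_centroids(self, rng):
        P, Q, w, _, _ = _random_instance(rng, scale_noise=0.1)
        T = kabsch(P, Q, w)
        wn = w / w.sum()
        np.testing.assert_allclose(T.apply(P).T @ wn, Q.T @ wn, atol=1e-9)

    def test_uniform_weights_equal_unweighted(self, rng):
        P, Q, _, _, _ = _random_instance(rng, scale_noise=0.3)
        a = kabsch(P, Q)
        b = kabsch(P, Q, np.full(len(P), 3.7))
        np.testing.assert_array_equal(a.rotation, b.rotation)
        np.testing.assert_allclose(a.translation, b.translation, atol=1e-12)

    def test_rotation_sampling_oracle(self, rng):
        # the closed form must beat a dense random sweep over SO(3)
        samples = Rotation.random(20000, random_state=99).as_matrix()
        for _ in range(25):
            P, Q, w, _, _ = _random_instance(rng, scale_noise=0.2)
            T = kabsch(P, Q, w)
            best = min(
                alignment_residual(
                    P, Q, w, _with_optimal_translation(P, Q, w, R)
                )
                for R in samples[:: max(1, len(samples) // 2000)]
            )
            assert alignment_residual(P, Q, w, T) <= best + 1e-9

    def test_reflection_corrected_to_proper_rotation(self, rng):
        P = rng.normal(size=(8, 3))
        Q = P.copy()
        Q[:, 0] *= -1  # mirrored target: unconstrained optimum is a reflection
        T = kabsch(P, Q)
        assert np.linalg.det(T.rotation) == pytest.approx(1.0, abs=1e-9)
        assert np.abs(T.rotation.T @ T.rotation - np.eye(3)).max() < 1e-9

    def test_degenerate_and_bad_weights_rejected(self, rng):
        line = np.outer(np.arange(5.0), [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            kabsch(line, line + 1.0)
        P, Q, w, _, _ = _random_instance(rng)
        w[0] = 0.0
        with pytest.raises(ValueError):
            kabsch(P, Q, w)


def _with_optimal_translation(P, Q, w, R):
    wn = w / w.sum()
    return EuclideanTransform(rotation=R, translation=wn @ Q - R @ (wn @ P))


class TestResidualAndLift:
    def test_perfect_alignment_zero(self, rng):
        P, Q, w, _, _ = _random_instance(rng)
        assert alignment_residual(P, Q, w, kabsch(P, Q, w)) < 1e-18

    def test_linear_in_weights(self, rng):
        P, Q, w, _, _ = _random_instance(rng, scale_noise=0.4)
        T = kabsch(P, Q, w)
        r1 = alignment_residual(P, Q, w, T)
        r2 = alignment_residual(P, Q, 2 * w, T)
        assert r2 == pytest.approx(2 * r1, rel=1e-12)

    def test_matches_loop_oracle(self, rng):
        P, Q, w, _, _ = _random_instance(rng, scale_noise=0.4)
        T = kabsch(P, Q, w)
        brute = 0.0
        for i in range(len(P)):
            d = T.rotation @ P[i] + T.translation - Q[i]
            brute += 0.5 * w[i] * d @ d
        assert alignment_residual(P, Q, w, T) == pytest.approx(brute, rel=1e-12)

    def test_lift_round_trip(self, rng):
        pts = rng.normal(size=(7, 2))
        z = rng.normal(size=7)
        lifted = lift_keypoints(pts, z)
        np.testing.assert_array_equal(lifted[:, :2], pts)
        np.testing.assert_array_equal(lifted[:, 2], z)
        assert lift_keypoints(pts, np.zeros(7))[:, 2].max() == 0.0

    def test_lifted_truth_is_rigid_transform_of_template(self):
        scene = sample_scene(seed=9)
        depths = scene.scale * scene.truth3d.points[:, 2]
        lifted = lift_keypoints(scene.truth2d, depths)
        template = normalize_points(scene.truth3d.points).points * scene.scale
        T = kabsch(template, lifted)
        assert alignment_residual(template, lifted, None, T) < 1e-15


class TestIterativeCorrection:
    def test_noise_free_self_consistency(self):
        scene = sample_scene(seed=21)
        res = iterative_correction(scene.truth2d, scene.truth3d)
        assert np.abs(res.corrected2d - scene.truth2d).max() < 1e-6
        assert res.residuals[-1] < 1e-10
        assert res.iterations == 3 and len(res.residuals) == 3

    def test_depth_recovery_up_to_mirror(self):
        scene = sample_scene(seed=22)
        res = iterative_correction(scene.truth2d, scene.truth3d)
        true_z = scene.scale * scene.truth3d.points[:, 2]
        rmse = min(
            np.sqrt(np.mean((res.depths - true_z) ** 2)),
            np.sqrt(np.mean((res.depths + true_z) ** 2)),
        )
        assert rmse < 1e-6

    def test_fixed_point_when_lift_matches_template(self):
        # feed the template's own projection: the lift at the recovered
        # depths equals the template, so nothing may move
        scene = sample_scene(seed=23)
        q = scene.truth3d
        res = iterative_correction(q.points[:, :2].copy(), q, n_iter=3)
        np.testing.assert_allclose(res.corrected2d, q.points[:, :2], atol=1e-9)
        sign = np.sign(res.depths @ q.points[:, 2])
        np.testing.assert_allclose(sign * res.depths, q.points[:, 2], atol=1e-9)
        np.testing.assert_allclose(
            res.transform.rotation @ res.transform.rotation.T, np.eye(3), atol=1e-9
        )

    def test_residuals_non_increasing_noise_free(self):
        for seed in range(10):
            scene = sample_scene(seed=seed)
            res = iterative_correction(scene.truth2d, scene.truth3d)
            diffs = np.diff(res.residuals)
            assert np.all(diffs <= 1e-9)

    def test_weighting_beats_uniform_on_corrupted_joints(self, rng):
        # two joints blown up by noise, their uncertainty inflated tenfold:
        # the weighted fit must track the clean joints more closely
        wins = 0
        n_trials = 60
        for trial in range(n_trials):
            scene = sample_scene(seed=1000 + trial)
            g = np.random.default_rng(trial)
            noisy = scene.truth2d + g.normal(0, 0.2, size=scene.truth2d.shape)
            bad = g.choice(len(noisy), 2, replace=False)
            noisy[bad] += g.normal(0, 3.0, size=(2, 2))
            c = np.full(len(noisy), 0.5)
            c[bad] *= 10
            w = WeightVector.from_uncertainties(c)
            err_w = mpjpe(
                iterative_correction(noisy, scene.truth3d, weights=w).corrected2d,
                scene.truth2d,
            )
            err_u = mpjpe(
                iterative_correction(noisy, scene.truth3d).corrected2d,
                scene.truth2d,
            )
            wins += err_w < err_u
        assert wins > n_trials // 2

    def test_uncertainties_flow_from_estimates(self):
        scene = sample_scene(seed=31, noise_sigma=0.05, occlusion_rate=0.3)
        est = decode(scene.heatmaps)
        res = iterative_correction(est, scene.truth3d)
        assert np.all(np.isfinite(res.corrected2d))

    def test_validation_errors(self):
        scene = sample_scene(seed=1)
        with pytest.raises(ValueError):
            iterative_correction(scene.truth2d, scene.truth3d, n_iter=0)
        from poselift import Skeleton3D

        raw = Skeleton3D(points=scene.truth3d.points * 2.0, normalized=False)
        with pytest.raises(ValueError):
            iterative_correction(scene.truth2d, raw)
        with pytest.raises(ValueError):
            iterative_correction(np.ones((17, 2)), scene.truth3d)
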