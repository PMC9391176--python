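import numpy as np
import pytest

from ringsift.errors import (LowParallaxError, ParameterError,
                             RansacFailureError)
from ringsift.robust import RansacConfig
from ringsift.sfm import (CameraIntrinsics, decompose_essential, eight_point,
                          essential_from_f,
                          fundamental_8pt_ransac, pnp_dlt, pnp_ransac,
                          projection_matrix, reconstruct_from_tracks,
                          reproject, sampson_distance, triangulate,
                          triangulate_points, two_view_geometry)
from ringsift.synthetic import make_rig

RIG_CEILING = 2.0 * 4096 / 512  # paper's 2 px threshold scaled to the rig camera


def rotation_error_deg(R_est, R_true):
    c = (np.trace(R_est @ R_true.T) - 1) / 2
    return np.degrees(np.arccos(np.clip(c, -1, 1)))


def translation_error_deg(t_est, t_true):
    tn = t_true / np.linalg.norm(t_true)
    return np.degrees(np.arccos(np.clip(abs(t_est @ tn), -1, 1)))


def sampson_oracle(F, xy_ref, xy_tgt):
    """Straight-loop Sampson distance (independent of the vectorized path)."""
    out = []
    for (x1, y1), (x2, y2) in zip(xy_ref, xy_tgt):
        p1 = np.array([x1, y1, 1.0])
        p2 = np.array([x2, y2, 1.0])
        Fp1 = F @ p1
        Ftp2 = F.T @ p2
        num = p2 @ F @ p1
        den = Fp1[0] ** 2 + Fp1[1] ** 2 + Ftp2[0] ** 2 + Ftp2[1] ** 2
        out.append(abs(num) / np.sqrt(den))
    return np.array(out)


def triangulate_oracle(P1, P2, m, m2):
    """Independent DLT via the eigenvector of A^T A (different algebra path)."""
    A = np.stack([m[0] * P1[2] - P1[0], m[1] * P1[2] - P1[1],
                  m2[0] * P2[2] - P2[0], m2[1] * P2[2] - P2[1]])
    w, v = np.linalg.eigh(A.T @ A)
    X = v[:, 0]
    return X[:3] / X[3]


class TestCameraIntrinsics:
    def test_valid_k_accepted(self):
        K = CameraIntrinsics(np.array([[700, 0, 256], [0, 700, 256], [0, 0, 1.0]]))
        assert K.K[0, 0] == 700

    @pytest.mark.parametrize("bad", [
        np.eye(4),
        np.array([[-1, 0, 0], [0, 1, 0], [0, 0, 1.0]]),
        np.array([[1, 0, 0], [0.5, 1, 0], [0, 0, 1.0]]),
    ])
    def test_invalid_k_rejected(self, bad):
        with pytest.raises(ParameterError):
            CameraIntrinsics(bad)

    def test_from_file_json_and_whitespace(self, tmp_path):
        import json
        K = [[700.0, 0, 256], [0, 700, 256], [0, 0, 1]]
        pj = tmp_path / "k.json"
        pj.write_text(json.dumps({"K": K}))
        pw = tmp_path / "k.txt"
        pw.write_text("700 0 256  0 700 256  0 0 1")
        assert np.allclose(CameraIntrinsics.from_file(pj).K,
                           CameraIntrinsics.from_file(pw).K)

    def test_approximate_fallback(self):
        K = CameraIntrinsics.approximate(640, 480)
        assert K.K[0, 0] == pytest.approx(1.2 * 640)
        assert K.K[0, 2] == 320


class TestEightPoint:
    def test_exact_rig_satisfies_epipolar_constraint(self):
        rig = make_rig(n_points=50, n_cameras=2, noise_sigma=0.0, seed=3)
        F = eight_point(rig.observations[0], rig.observations[1])
        # normalized residual |x'^T F x| with unit-normalized homogeneous points
        for p1, p2 in zip(rig.observations[0], rig.observations[1]):
            h1 = np.append(p1, 1.0)
            h2 = np.append(p2, 1.0)
            r = abs(h2 @ F @ h1) / (np.linalg.norm(h1) * np.linalg.norm(h2))
            assert r < 1e-8

    def test_f_matches_ground_truth_up_to_scale(self):
        rig = make_rig(n_points=40, n_cameras=2, noise_sigma=0.0, seed=4)
        F = eight_point(rig.observations[0][:8], rig.observations[1][:8])
        F_true = rig.fundamental(0, 1)
        F = F / np.linalg.norm(F)
        if np.sign(F.ravel()[np.argmax(np.abs(F))]) != np.sign(
                F_true.ravel()[np.argmax(np.abs(F_true))]):
            F = -F
        assert np.allclose(F, F_true, atol=1e-6)

    def test_rank_two_enforced(self):
        rig = make_rig(n_points=30, n_cameras=2, noise_sigma=0.5, seed=5)
        F = eight_point(rig.observations[0], rig.observations[1])
        assert np.linalg.svd(F, compute_uv=False)[2] < 1e-12

    def test_too_few_points_rejected(self):
        with pytest.raises(ParameterError):
            eight_point(np.zeros((7, 2)), np.zeros((7, 2)))


class TestFundamentalRansac:
    def test_noisy_rig_median_sampson_below_2px(self):
        rig = make_rig(n_points=100, n_cameras=2, noise_sigma=1.0, seed=6)
        F, mask = fundamental_8pt_ransac(rig.observations[0], rig.observations[1],
                                         RansacConfig(seed=6), 2.0)
        d = sampson_distance(F, rig.observations[0], rig.observations[1])
        assert np.median(d) < 2.0
        # vectorized Sampson agrees with the straight-loop oracle
        o = sampson_oracle(F, rig.observations[0][:30], rig.observations[1][:30])
        assert np.allclose(d[:30], o, atol=1e-10)

    def test_too_few_correspondences(self):
        with pytest.raises(RansacFailureError) as e:
            fundamental_8pt_ransac(np.zeros((8, 2)), np.zeros((8, 2)))
        assert e.value.reason == "too few matches"


class TestEssential:
    def test_identity_k_reduces_to_projected_f(self):
        rig = make_rig(n_points=30, n_cameras=2, noise_sigma=0.0, seed=7)
        F = rig.fundamental(0, 1)
        K_id = CameraIntrinsics(np.eye(3))
        E = essential_from_f(F, K_id, K_id)
        U, S, Vt = np.linalg.svd(F)
        F_proj = U @ np.diag([(S[0] + S[1]) / 2] * 2 + [0.0]) @ Vt
        assert np.allclose(E, F_proj, atol=1e-12)

    def test_matches_tx_r_up_to_scale(self):
        rig = make_rig(n_points=30, n_cameras=2, noise_sigma=0.0, seed=8)
        K = rig.cameras[0][0]
        E = essential_from_f(rig.fundamental(0, 1), K, K)
        E_true = rig.essential(0, 1)  # [t]x R built by hand
        E = E / np.linalg.norm(E)
        E_true = E_true / np.linalg.norm(E_true)
        if np.sign(E.ravel()[np.argmax(np.abs(E))]) != np.sign(
                E_true.ravel()[np.argmax(np.abs(E_true))]):
            E = -E
        assert np.allclose(E, E_true, atol=1e-6)

    def test_smallest_singular_value_exactly_zero(self):
        rig = make_rig(n_points=30, n_cameras=2, noise_sigma=1.0, seed=9)
        K = rig.cameras[0][0]
        F = eight_point(rig.observations[0], rig.observations[1])
        E = essential_from_f(F, K, K)
        S = np.linalg.svd(E, compute_uv=False)
        assert S[2] <= 1e-12 * S[0]  # zero to machine precision
        assert S[0] == pytest.approx(S[1])

    def test_singular_k_rejected(self):
        with pytest.raises(ParameterError):
            CameraIntrinsics(np.diag([1.0, 0.0, 1.0]))


class TestDecomposeEssential:
    def test_canonical_stereo_rig(self):
        # R = I, t = (1, 0, 0): scene points in front of both cameras
        K = CameraIntrinsics(np.array([[500, 0, 250], [0, 500, 250], [0, 0, 1.0]]))
        rng = np.random.default_rng(0)
        X = rng.uniform(-1, 1, (40, 3)) + [0, 0, 6.0]
        R_true = np.eye(3)
        t_true = np.array([1.0, 0, 0])
        P1 = projection_matrix(K, np.eye(3), np.zeros(3))
        P2 = projection_matrix(K, R_true, t_true)
        x1 = reproject(P1, X)
        x2 = reproject(P2, X)
        tx = np.array([[0, 0, 0], [0, 0, -1.0], [0, 1.0, 0]])  # [t]x for (1,0,0)
        E = tx @ R_true
        R, t = decompose_essential(E, x1, x2, K, K)
        assert np.allclose(R, R_true, atol=1e-6)
        assert np.allclose(t, t_true, atol=1e-6)

    def test_ten_degree_rotation_recovered(self):
        rig = make_rig(n_points=60, n_cameras=2, noise_sigma=0.0, seed=10,
                       separation_deg=10.0)
        K = rig.cameras[0][0]
        R_true, t_true = rig.relative_pose(0, 1)
        E = rig.essential(0, 1)
        R, t = decompose_essential(E, rig.observations[0], rig.observations[1], K, K)
        assert rotation_error_deg(R, R_true) < 0.01
        assert translation_error_deg(t, t_true) < 0.01
        # the relative rotation of a 10-degree arc is 10 degrees
        ang = np.degrees(np.arccos(np.clip((np.trace(R_true) - 1) / 2, -1, 1)))
        assert ang == pytest.approx(10.0, abs=1e-6)

    def test_four_candidate_structure(self):
        """The SVD decomposition enumerates exactly 4 pose candidates:
        {U W V^T, U W^T V^T} x {+-u3}; the returned one must be among them."""
        rig = make_rig(n_points=40, n_cameras=2, noise_sigma=0.0, seed=11)
        K = rig.cameras[0][0]
        E = rig.essential(0, 1)
        U, _, Vt = np.linalg.svd(E)
        if np.linalg.det(U) < 0:
            U = -U
        if np.linalg.det(Vt) < 0:
            Vt = -Vt
        W = np.array([[0, -1, 0], [1, 0, 0], [0, 0, 1.0]])
        candidates = [(R, s * U[:, 2]) for R in (U @ W @ Vt, U @ W.T @ Vt)
                      for s in (1, -1)]
        assert len(candidates) == 4
        R, t = decompose_essential(E, rig.observations[0], rig.observations[1], K, K)
        hit = any(np.allclose(R, Rc, atol=1e-9)
                  and np.allclose(t, tc / np.linalg.norm(tc), atol=1e-9)
                  for Rc, tc in candidates)
        assert hit


class TestTriangulate:
    def test_noise_free_round_trip(self):
        K = CameraIntrinsics(np.array([[500, 0, 250], [0, 500, 250], [0, 0, 1.0]]))
        P1 = projection_matrix(K, np.eye(3), np.zeros(3))
        R2 = np.eye(3)
        P2 = projection_matrix(K, R2, np.array([1.0, 0, 0]))
        M = np.array([0.0, 0.0, 5.0])
        m = reproject(P1, M)[0]
        m2 = reproject(P2, M)[0]
        X = triangulate(P1, P2, m, m2)
        assert np.allclose(X, M, atol=1e-9)

    def test_zero_baseline_rejected(self):
        K = CameraIntrinsics(np.eye(3))
        P = projection_matrix(K, np.eye(3), np.zeros(3))
        with pytest.raises(LowParallaxError):
            triangulate(P, P, np.array([0.0, 0]), np.array([0.0, 0]))

    def test_agrees_with_independent_oracle_under_noise(self):
        rig = make_rig(n_points=30, n_cameras=2, noise_sigma=1.0, seed=12)
        K, R1, t1 = rig.cameras[0]
        _, R2, t2 = rig.cameras[1]
        P1 = projection_matrix(K, R1, t1)
        P2 = projection_matrix(K, R2, t2)
        X = triangulate_points(P1, P2, rig.observations[0], rig.observations[1])
        for i in range(30):
            Xo = triangulate_oracle(P1, P2, rig.observations[0][i],
                                    rig.observations[1][i])
            assert np.allclose(X[i], Xo, atol=1e-6 * max(1, np.abs(Xo).max()))

    def test_noisy_median_error_within_oracle_bound(self):
        """Median 3-D error at 1 px noise stays within the bound measured by
        the independent straight-loop DLT on the same seed."""
        rig = make_rig(n_points=100, n_cameras=2, noise_sigma=1.0, seed=13)
        K, R1, t1 = rig.cameras[0]
        _, R2, t2 = rig.cameras[1]
        P1 = projection_matrix(K, R1, t1)
        P2 = projection_matrix(K, R2, t2)
        X = triangulate_points(P1, P2, rig.observations[0], rig.observations[1])
        err = np.linalg.norm(X - rig.points3d, axis=1)
        oracle_err = np.array([
            np.linalg.norm(triangulate_oracle(
                P1, P2, rig.observations[0][i], rig.observations[1][i])
                - rig.points3d[i])
            for i in range(100)])
        assert np.median(err) <= np.median(oracle_err) * (1 + 1e-9)


class TestPnP:
    def test_exact_resection(self):
        rig = make_rig(n_points=50, n_cameras=2, noise_sigma=0.0, seed=14)
        K, R, t = rig.cameras[1]
        R_est, t_est = pnp_dlt(rig.points3d, rig.exact_observations[1], K)
        assert rotation_error_deg(R_est, R) < 1e-6
        assert np.allclose(t_est, t, atol=1e-6)

    def test_ransac_survives_outliers(self):
        rig = make_rig(n_points=60, n_cameras=2, noise_sigma=0.0, seed=15)
        K, R, t = rig.cameras[1]
        xy = rig.exact_observations[1].copy()
        xy[:6] += 300.0  # gross outliers
        R_est, t_est, mask = pnp_ransac(rig.points3d, xy, K,
                                        RansacConfig(seed=15), 2.0)
        assert mask.sum() == 54
        assert rotation_error_deg(R_est, R) < 1e-4


class TestTwoViewPipeline:
    def test_pose_recovery_on_noisy_rig(self):
        rig = make_rig(n_points=150, n_cameras=2, noise_sigma=1.0, seed=16)
        K = rig.cameras[0][0]
        geom, mask = two_view_geometry(rig.observations[0], rig.observations[1],
                                       K, K, RansacConfig(seed=16), 2.0)
        R_true, t_true = rig.relative_pose(0, 1)
        assert rotation_error_deg(geom.R, R_true) <= 0.5
        assert translation_error_deg(geom.T_vec, t_true) <= 1.0
        assert mask.sum() >= 100

    def test_scale_freedom_of_reconstruction(self):
        """Scaling T and all 3-D points by a common factor leaves every
        reprojection unchanged."""
        rig = make_rig(n_points=40, n_cameras=2, noise_sigma=0.0, seed=17)
        K = rig.cameras[0][0]
        geom, mask = two_view_geometry(rig.observations[0], rig.observations[1],
                                       K, K, RansacConfig(seed=17), 2.0)
        X = triangulate_points(geom.P1, geom.P2, rig.observations[0],
                               rig.observations[1])
        s = 3.7
        P2s = projection_matrix(K, geom.R, s * geom.T_vec)
        assert np.allclose(reproject(geom.P2, X), reproject(P2s, s * X), atol=1e-6)

    def test_three_view_track_reconstruction(self):
        rig = make_rig(n_points=120, n_cameras=3, noise_sigma=1.0, seed=18)
        K = rig.cameras[0][0]
        rec = reconstruct_from_tracks(rig.observations, K, RansacConfig(seed=18),
                                      reproj_ceiling=RIG_CEILING)
        assert len(rec.cloud) >= 0.9 * 120
        assert len(rec.poses) == 3
        assert all(len(t) >= 2 for t in rec.cloud.tracks)
        assert np.all(np.isfinite(rec.cloud.points))

    def test_zero_baseline_rejected(self):
        rig = make_rig(n_points=50, n_cameras=2, noise_sigma=0.0, seed=19)
        obs = [rig.observations[0], rig.observations[0].copy()]
        with pytest.raises(LowParallaxError):
            reconstruct_from_tracks(obs, rig.cameras[0][0], RansacConfig(seed=19))


class TestImageReconstruction:
    def test_two_plane_scene_full_pipeline(self, plane_scene):
        from ringsift.config import PipelineConfig
        from ringsift.sfm import reconstruct

        rec = reconstruct(plane_scene.images, plane_scene.K, PipelineConfig(seed=0))
        assert rec.report["points"] >= 100
        assert rec.report["mean_reprojection_error"] < 1.0
        # recovered pose of the second camera matches the rendered rig
        R0, t0 = plane_scene.cameras[0]
        R1, t1 = plane_scene.cameras[1]
        R_true = R1 @ R0.T
        t_true = t1 - R_true @ t0
        R_est = np.array(rec.poses[1]["R"])
        assert rotation_error_deg(R_est, R_true) < 1.0

    def test_identical_images_flag_low_parallax(self, plane_scene):
        from ringsift.config import PipelineConfig
        from ringsift.sfm import reconstruct

        with pytest.raises(LowParallaxError):
            reconstruct([plane_scene.images[0], plane_scene.images[0]],
                        plane_scene.K, PipelineConfig(seed=0))

    def test_wrong_image_count_rejected(self, plane_scene):
        from ringsift.sfm import reconstruct

        with pytest.raises(ParameterError):
            reconstruct([plane_scene.images[0]], plane_scene.K)


class TestPlyRoundTrip:
    def test_points_and_colors_survive(self, tmp_path):
        from ringsift.ply import read_ply, write_ply

        rng = np.random.default_rng(1)
        pts = rng.uniform(-5, 5, (77, 3)).astype(np.float32)
        cols = rng.integers(0, 256, (77, 3), dtype=np.uint8)
        p = tmp_path / "cloud.ply"
        write_ply(p, pts, cols)
        pts2, cols2 = read_ply(p)
        assert np.array_equal(pts2.astype(np.float32), pts)
        assert np.array_equal(cols2, cols)

    def test_write_is_deterministic(self, tmp_path):
        from ringsift.ply import write_ply

        pts = np.arange(30, dtype=np.float32).reshape(10, 3)
        a, b = tmp_path / "a.ply", tmp_path / "b.ply"
        write_ply(a, pts)
        write_ply(b, pts)
        assert a.read_bytes() == b.read_bytes()
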