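"""Point coupling, rigid Procrustes fit, ICP, and displacement reports."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skimage.transform import EuclideanTransform

from fidqa import registration
from fidqa.errors import InvalidParameterError, UnderdeterminedError
from fidqa.registration import PointCloud2D, RigidTransform2D


def rigid(points, theta, t):
    c, s = np.cos(theta), np.sin(theta)
    return points @ np.array([[c, -s], [s, c]]).T + np.asarray(t)


def random_cloud(rng, n=3, min_sep=10.0, extent=40.0):
    while True:
        pts = rng.uniform(-extent, extent, (n, 2))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        if np.min(d[~np.eye(n, dtype=bool)]) >= min_sep:
            return pts


class TestCouplePoints:
    def test_identity_for_identical_clouds(self):
        pts = np.array([[0.0, 0.0], [25.0, 0.0], [10.0, 20.0]])
        corr = registration.couple_points(PointCloud2D(pts), PointCloud2D(pts))
        assert corr == [(0, 0), (1, 1), (2, 2)]

    def test_reversed_listing_recovered(self):
        pts = np.array([[0.0, 0.0], [25.0, 0.0], [10.0, 20.0]])
        corr = registration.couple_points(PointCloud2D(pts[::-1]), PointCloud2D(pts))
        assert corr == [(2, 0), (1, 1), (0, 2)]

    def test_correct_coupling_under_perturbation(self):
        # markers >= 20 mm apart survive <= 5 mm perturbations: exhaustive
        # search after centroid alignment always recovers the truth
        rng = np.random.default_rng(99)
        for _ in range(300):
            fixed = random_cloud(rng, min_sep=20.0)
            perm = rng.permutation(3)
            moving = fixed[perm] + rng.uniform(-5, 5, (3, 2)) * rng.uniform(0, 1)
            moving = moving + rng.uniform(-40, 40, 2)  # arbitrary frame offset
            corr = registration.couple_points(PointCloud2D(moving), PointCloud2D(fixed))
            # moving row i was built from fixed row perm[i]
            assert all(perm[c[0]] == c[1] for c in corr)

    def test_unequal_counts_rejected(self):
        with pytest.raises(InvalidParameterError):
            registration.couple_points(
                PointCloud2D([[0, 0], [10, 0]]),
                PointCloud2D([[0, 0], [10, 0], [0, 10]]),
            )


class TestFitRigid2D:
    def test_identity_for_identical_clouds(self):
        pts = PointCloud2D([[0.0, 0.0], [25.0, 0.0], [10.0, 20.0]])
        tr = registration.fit_rigid_2d(pts, pts)
        assert tr.theta == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(tr.t, 0.0, atol=1e-12)

    def test_known_transform_recovered(self):
        pts = np.array([[0.0, 0.0], [25.0, 0.0], [10.0, 20.0]])
        theta, t = np.radians(5.0), np.array([3.0, -2.0])
        tr = registration.fit_rigid_2d(PointCloud2D(pts), PointCloud2D(rigid(pts, theta, t)))
        assert tr.theta == pytest.approx(theta, abs=1e-12)
        np.testing.assert_allclose(tr.apply(pts), rigid(pts, theta, t), atol=1e-9)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        theta=st.floats(-np.pi, np.pi),
        tx=st.floats(-50, 50),
        ty=st.floats(-50, 50),
    )
    def test_transform_recovery_property(self, seed, theta, tx, ty):
        pts = random_cloud(np.random.default_rng(seed))
        moved = rigid(pts, theta, (tx, ty))
        tr = registration.fit_rigid_2d(PointCloud2D(pts), PointCloud2D(moved))
        assert np.max(np.abs(tr.apply(pts) - moved)) < 1e-9

    def test_reflection_refused(self):
        pts = np.array([[0.0, 0.0], [25.0, 0.0], [10.0, 20.0]])
        mirrored = pts * np.array([-1.0, 1.0])
        tr = registration.fit_rigid_2d(PointCloud2D(pts), PointCloud2D(mirrored))
        assert np.linalg.det(tr.rotation) == pytest.approx(1.0)
        residual = np.linalg.norm(tr.apply(pts) - mirrored, axis=1)
        assert residual.max() > 1.0

    def test_matches_skimage_euclidean_estimate(self):
        # independent oracle: scikit-image's Euclidean (rigid) estimator
        rng = np.random.default_rng(5)
        for _ in range(20):
            src = random_cloud(rng, n=4)
            dst = rigid(src, rng.uniform(-3, 3), rng.uniform(-20, 20, 2))
            dst += rng.normal(0, 0.5, dst.shape)  # noisy, so the LS fit matters
            ours = registration.fit_rigid_2d(PointCloud2D(src), PointCloud2D(dst))
            if hasattr(EuclideanTransform, "from_estimate"):
                ski = EuclideanTransform.from_estimate(src, dst)
            else:  # older scikit-image
                ski = EuclideanTransform()
                assert ski.estimate(src, dst)
            np.testing.assert_allclose(ours.rotation, ski.params[:2, :2], atol=1e-9)
            np.testing.assert_allclose(ours.t, ski.params[:2, 2], atol=1e-9)

    def test_coincident_points_rejected(self):
        with pytest.raises(InvalidParameterError):
            PointCloud2D([[1.0, 1.0], [1.0, 1.0]])
        with pytest.raises(UnderdeterminedError):
            registration.fit_rigid_2d(
                PointCloud2D([[1.0, 1.0]]), PointCloud2D([[2.0, 2.0]])
            )


class TestIcp:
    def test_noiseless_round_trip(self):
        pts = np.array([[0.0, 0.0], [25.0, 0.0], [10.0, 20.0]])
        moved = rigid(pts, np.radians(4), (3.0, -2.0))
        res = registration.icp_register(PointCloud2D(moved), PointCloud2D(pts))
        assert res.rms_mm < 1e-6

    def test_fixed_correspondences_equal_closed_form(self):
        rng = np.random.default_rng(8)
        moving = PointCloud2D(random_cloud(rng))
        fixed = PointCloud2D(random_cloud(rng))
        corr = [(0, 0), (1, 1), (2, 2)]
        icp = registration.icp_register(moving, fixed, correspondences=corr)
        direct = registration.fit_rigid_2d(moving, fixed, corr)
        assert icp.transform.theta == pytest.approx(direct.theta, abs=1e-12)
        np.testing.assert_allclose(icp.transform.t, direct.t, atol=1e-12)

    def test_objective_monotone_nonincreasing(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            fixed = PointCloud2D(random_cloud(rng))
            moving = PointCloud2D(
                rigid(fixed.points, rng.uniform(-0.3, 0.3), rng.uniform(-10, 10, 2))
                + rng.normal(0, 1.0, (3, 2))
            )
            res = registration.icp_register(moving, fixed)
            assert np.all(np.diff(res.objective_history) <= 1e-12)


class TestTransforms:
    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(theta=st.floats(-np.pi, np.pi), tx=st.floats(-100, 100), ty=st.floats(-100, 100))
    def test_isometry_preserves_pairwise_distances(self, theta, tx, ty):
        pts = np.array([[0.0, 0.0], [25.0, 0.0], [10.0, 20.0], [-14.0, 7.0]])
        tr = RigidTransform2D(theta=theta, t=np.array([tx, ty]))
        moved = tr.apply(pts)
        d0 = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        d1 = np.linalg.norm(moved[:, None] - moved[None, :], axis=-1)
        assert np.max(np.abs(d0 - d1)) < 1e-9

    def test_inverse_composes_to_identity(self):
        tr = RigidTransform2D(theta=0.3, t=np.array([5.0, -7.0]))
        pts = np.array([[1.0, 2.0], [30.0, -4.0]])
        np.testing.assert_allclose(tr.inverse().apply(tr.apply(pts)), pts, atol=1e-12)


class TestDisplacements:
    def _report(self, fixed, moved):
        corr = [(i, i) for i in range(len(fixed))]
        return registration.compute_displacements(
            PointCloud2D(fixed), PointCloud2D(moved), corr
        )

    def test_identical_clouds_zero(self):
        pts = np.array([[0.0, 0.0], [25.0, 0.0], [10.0, 20.0]])
        report = self._report(pts, pts.copy() + 1e-15)
        assert np.allclose(report.dtotal, 0.0)

    def test_pythagorean_pair(self):
        report = self._report(
            np.array([[3.0, 4.0], [25.0, 0.0]]), np.array([[0.0, 0.0], [25.0, 0.0]])
        )
        assert report.dtotal[0] == pytest.approx(5.0)
        assert report.dx[0] == pytest.approx(3.0) and report.dy[0] == pytest.approx(4.0)

    def test_inferior_superior_outlier_magnitude(self):
        # a purely inferior-superior 6.3 mm discrepancy shows up entirely in
        # dY and dTotal
        report = self._report(
            np.array([[0.0, 6.3], [25.0, 0.0]]), np.array([[0.0, 0.0], [25.0, 0.0]])
        )
        assert report.dx[0] == 0.0
        assert report.dy[0] == pytest.approx(6.3)
        assert report.dtotal[0] == pytest.approx(6.3)

    def test_common_mode_displacement_is_invisible(self):
        # every marker shifted by the same vector is indistinguishable from
        # organ motion: the registration absorbs it completely
        pts = np.array([[0.0, 0.0], [25.0, 0.0], [10.0, 20.0]])
        moved = pts + np.array([4.0, -3.0])
        tr = registration.fit_rigid_2d(PointCloud2D(moved), PointCloud2D(pts))
        registered = PointCloud2D(tr.apply(moved))
        report = registration.compute_displacements(
            PointCloud2D(pts), registered, [(i, i) for i in range(3)]
        )
        assert np.max(report.dtotal) < 1e-9

    def test_single_marker_migration_underestimated(self):
        # one migrating marker drags the least-squares fit with it, so the
        # reported displacement is strictly below the true migration
        rng = np.random.default_rng(31)
        for _ in range(20):
            pts = random_cloud(rng, min_sep=18.0)
            d = rng.uniform(4.0, 10.0)
            direction = rng.normal(size=2)
            direction /= np.linalg.norm(direction)
            moved = pts.copy()
            moved[0] += d * direction
            tr = registration.fit_rigid_2d(PointCloud2D(moved), PointCloud2D(pts))
            report = registration.compute_displacements(
                PointCloud2D(pts),
                PointCloud2D(tr.apply(moved)),
                [(i, i) for i in range(3)],
            )
            assert 0.0 < report.dtotal[0] < d
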