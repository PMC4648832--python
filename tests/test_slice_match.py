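import numpy as np
import pytest

from histofuse import (
    InsufficientLandmarksError,
    LineFiducial,
    PointFiducial,
    RigidTransform2D,
    RmsCurve,
    find_corresponding_plane,
    fit_negative_gaussian,
    in_plane_fiducials_at_z,
    rms_curve,
)
from histofuse.slice_match import GaussianFit


def diverging_spines(angle_deg=30.0, n=4, length=30.0):
    """Spines fanning out from a common apex at the origin plane, at the
    given polar angle from the cutting axis (mutually non-parallel)."""
    polar = np.radians(angle_deg / 2)
    out = []
    for i in range(n):
        phi = 2 * np.pi * i / n + 0.3
        d = [np.sin(polar) * np.cos(phi), np.sin(polar) * np.sin(phi), np.cos(polar)]
        out.append(LineFiducial(f"S{i+1}", [0.0, 0.0, 0.0], d, length))
    return out


def parallel_spines(n=4, length=30.0):
    xy = [(0.0, 0.0), (10.0, 0.0), (0.0, 10.0), (8.0, 7.0)]
    return [
        LineFiducial(f"S{i+1}", [*xy[i % 4], 0.0], [0, 0, 1.0], length)
        for i in range(n)
    ]


def exact_gaussian_curve(a=2.0, b=1.8, c=3.0, mu=10.0, z=None, noise=None):
    if z is None:
        z = np.arange(0.0, 21.0)
    r = a - b * np.exp(-((z - mu) ** 2) / c**2)
    if noise is not None:
        r = np.clip(r + noise, 0, None)
    return RmsCurve(z, r, np.full(z.shape, 4, dtype=int))


class TestInPlaneFiducials:
    def test_vertical_spines_project_to_their_origins(self):
        fids = [
            LineFiducial("a", [0, 0, 0], [0, 0, 1], 25.0),
            LineFiducial("b", [10, 0, 0], [0, 0, 1], 25.0),
        ]
        pts = in_plane_fiducials_at_z(fids, 12.0)
        np.testing.assert_allclose(pts["a"], [0, 0])
        np.testing.assert_allclose(pts["b"], [10, 0])

    def test_cone_pattern_grows_linearly_from_apex(self):
        fids = diverging_spines(30.0, n=2)
        d1 = np.linalg.norm(np.subtract(*in_plane_fiducials_at_z(fids, 10.0).values()))
        d2 = np.linalg.norm(np.subtract(*in_plane_fiducials_at_z(fids, 20.0).values()))
        assert d2 == pytest.approx(2 * d1, rel=1e-9)

    def test_beyond_extent_is_empty(self):
        assert in_plane_fiducials_at_z(parallel_spines(), 45.0) == {}

    def test_point_fiducial_window(self):
        lm = PointFiducial("L", [1.0, 2.0, 10.0], z_tolerance=0.5)
        assert "L" in in_plane_fiducials_at_z([lm], 10.4)
        assert in_plane_fiducials_at_z([lm], 11.0) == {}


class TestRmsCurve:
    def test_zero_at_true_plane_and_unique_minimum(self):
        fids = diverging_spines(30.0)
        pose = RigidTransform2D(0.8, [5.0, -3.0])
        hist = {l: pose.apply(p) for l, p in in_plane_fiducials_at_z(fids, 12.0).items()}
        curve = rms_curve(hist, fids, np.arange(1.0, 26.0))
        i = int(np.argmin(curve.rms_values))
        assert curve.z_values[i] == 12.0
        assert curve.rms_values[i] < 1e-9
        others = np.delete(curve.rms_values, i)
        assert others.min() > 1e-3  # unique global minimum

    def test_parallel_spines_give_constant_curve(self):
        fids = parallel_spines()
        pose = RigidTransform2D(-0.4, [2.0, 7.0])
        hist = {l: pose.apply(p) for l, p in in_plane_fiducials_at_z(fids, 12.0).items()}
        curve = rms_curve(hist, fids, np.arange(1.0, 26.0))
        assert np.ptp(curve.rms_values) < 1e-9

    def test_single_plane_curve(self):
        fids = diverging_spines(30.0)
        hist = in_plane_fiducials_at_z(fids, 9.0)
        curve = rms_curve(hist, fids, np.array([9.0]))
        assert len(curve) == 1
        assert curve.rms_values[0] < 1e-9

    def test_no_shared_labels_raises(self):
        fids = diverging_spines(30.0)
        hist = {"X1": np.zeros(2), "X2": np.ones(2), "X3": np.full(2, 2.0)}
        with pytest.raises(InsufficientLandmarksError):
            rms_curve(hist, fids, np.arange(1.0, 26.0))

    def test_landmark_narrows_into_label_set_near_its_plane(self):
        # a point fiducial participates only near its own z
        fids = diverging_spines(30.0) + [PointFiducial("L1", [3.0, 1.0, 12.0])]
        hist = dict(in_plane_fiducials_at_z(fids, 12.0))
        curve = rms_curve(hist, fids, np.arange(1.0, 26.0))
        at = dict(zip(curve.z_values, curve.n_points_used))
        assert at[12.0] == 5 and at[20.0] == 4


class TestNegativeGaussianFit:
    def test_exact_model_samples_recovered(self):
        fit = fit_negative_gaussian(exact_gaussian_curve())
        assert fit.converged
        assert np.allclose([fit.a, fit.b, fit.c, fit.mu], [2.0, 1.8, 3.0, 10.0], atol=1e-6)

    def test_noisy_center_recovery_monte_carlo(self):
        rng = np.random.default_rng(11)
        hits = 0
        n_rep = 500
        for _ in range(n_rep):
            noise = rng.normal(0, 0.05, size=21)
            fit = fit_negative_gaussian(exact_gaussian_curve(noise=noise))
            hits += abs(fit.mu - 10.0) <= 0.3
        assert hits / n_rep >= 0.95

    def test_constant_curve_flagged_not_raised(self):
        z = np.arange(0.0, 10.0)
        fit = fit_negative_gaussian(RmsCurve(z, np.full(10, 2.0), np.full(10, 4)))
        assert not fit.converged or fit.b <= 1e-5

    def test_too_few_points_rejected(self):
        z = np.arange(3.0)
        with pytest.raises(InsufficientLandmarksError):
            fit_negative_gaussian(RmsCurve(z, np.ones(3), np.full(3, 4)))


class TestFindCorrespondingPlane:
    def test_noiseless_dip_found_at_subgrid_center(self):
        match = find_corresponding_plane(exact_gaussian_curve(mu=10.3))
        assert match.method == "gaussian"
        assert match.z_star == pytest.approx(10.3, abs=1e-4)
        assert match.rms_star >= 0

    def test_grid_point_minimum_of_convex_curve(self):
        z = np.arange(0.0, 9.0)
        r = (z - 4.0) ** 2 + 0.5
        match = find_corresponding_plane(RmsCurve(z, r, np.full(9, 4)))
        assert abs(match.z_star - 4.0) <= 0.5

    def test_flat_curve_falls_back_to_smallest_z(self):
        z = np.arange(0.0, 10.0)
        curve = RmsCurve(z, np.full(10, 1.5), np.full(10, 4))
        with pytest.warns(UserWarning):
            match = find_corresponding_plane(curve)
        assert match.method == "discrete_argmin"
        assert match.z_star == 0.0

    def test_gaussian_and_argmin_agree_on_deep_dips(self):
        # deep single-minimum curves: the two estimators agree within one
        # grid spacing (dip depth far above the noise level)
        rng = np.random.default_rng(5)
        for _ in range(50):
            mu = rng.uniform(5, 15)
            noise = rng.normal(0, 0.05, size=21)
            curve = exact_gaussian_curve(b=1.8, mu=mu, noise=noise)
            match = find_corresponding_plane(curve)
            argmin_z = curve.z_values[np.argmin(curve.rms_values)]
            assert match.method == "gaussian"
            assert abs(match.z_star - argmin_z) <= 1.0


class TestRmsCurveValidation:
    @pytest.mark.parametrize(
        "z, r",
        [
            ([1.0, 1.0, 2.0], [0.1, 0.2, 0.3]),  # non-increasing z
            ([1.0, 2.0, 3.0], [0.1, -0.2, 0.3]),  # negative rms
            ([], []),  # empty
        ],
    )
    def test_invalid_curves_rejected(self, z, r):
        with pytest.raises(ValueError):
            RmsCurve(np.array(z), np.array(r), np.full(len(z), 4, dtype=int))
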