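import warnings

import numpy as np
import pytest

from histofuse import (
    PhantomSpec,
    compose,
    cut_slice,
    find_corresponding_plane,
    fit_rigid_3d,
    invert,
    make_phantom,
    observe_landmarks,
    rms_curve,
    sample_slice_thicknesses,
)
from histofuse.phantom import (
    SLICE_THICKNESS_MEAN_MM,
    SLICE_THICKNESS_SD_MM,
)


def full_grid(spec):
    return np.arange(0.0, spec.specimen_extent[2] + 1e-9, spec.ct_plane_spacing)


class TestMakePhantom:
    def test_same_seed_is_bitwise_identical(self):
        a = make_phantom(PhantomSpec(seed=42))
        b = make_phantom(PhantomSpec(seed=42))
        for sa, sb in zip(a.spines, b.spines):
            assert sa.label == sb.label and sa.length == sb.length
            np.testing.assert_array_equal(sa.origin, sb.origin)
            np.testing.assert_array_equal(sa.direction, sb.direction)
        for l in a.landmarks_exvivo:
            np.testing.assert_array_equal(
                a.landmarks_exvivo[l], b.landmarks_exvivo[l]
            )
        np.testing.assert_array_equal(
            a.gt_invivo_to_exvivo.matrix, b.gt_invivo_to_exvivo.matrix
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_pairwise_angles_near_target(self, seed):
        ph = make_phantom(PhantomSpec(seed=seed, target_pairwise_angle=30.0))
        assert len(ph.pairwise_angles_deg) == 6  # C(4,2)
        assert np.all(ph.pairwise_angles_deg >= 20.0)
        assert np.all(ph.pairwise_angles_deg <= 40.0)

    def test_two_spines_have_one_angle(self):
        ph = make_phantom(PhantomSpec(seed=1, n_spines=2))
        assert len(ph.pairwise_angles_deg) == 1

    def test_spines_inside_specimen(self):
        ph = make_phantom(PhantomSpec(seed=9))
        hi = np.array(ph.spec.specimen_extent)
        for s in ph.spines:
            for p in (s.origin, s.end):
                assert np.all(p >= 0) and np.all(p <= hi)

    def test_spine_lengths_in_range(self):
        ph = make_phantom(PhantomSpec(seed=2))
        lo, hi = ph.spec.spine_length_range
        assert all(lo <= s.length <= hi for s in ph.spines)


class TestObserveLandmarks:
    def test_noise_free_round_trip_recovers_ground_truth(self):
        ph = make_phantom(PhantomSpec(seed=7))
        c = observe_landmarks(ph, noise_sd=0.0)
        fit = fit_rigid_3d(c)
        residual = compose(fit.transform, invert(ph.gt_invivo_to_exvivo))
        assert np.abs(residual.matrix - np.eye(4)).max() < 1e-8

    def test_labels_preserved(self):
        ph = make_phantom(PhantomSpec(seed=7))
        c = observe_landmarks(ph, noise_sd=1.0)
        assert c.labels == list(ph.landmarks_exvivo)


class TestCutSlice:
    def test_exact_chain_recovers_plane_and_pose(self):
        spec = PhantomSpec(seed=13, slice_tilt_max=0.0)
        ph = make_phantom(spec)
        lo, hi = ph.common_z_interval()
        z = (lo + hi) / 2
        sl = cut_slice(ph, z)
        curve = rms_curve(sl.hist_points, ph.spines, full_grid(spec))
        match = find_corresponding_plane(curve)
        assert abs(match.z_star - z) <= spec.ct_plane_spacing / 2
        # the in-plane fit at the true plane must invert the mounting pose
        from histofuse import Correspondences2D, fit_rigid_2d, in_plane_fiducials_at_z

        plane_pts = in_plane_fiducials_at_z(ph.spines, z)
        labels = list(sl.hist_points)
        fit = fit_rigid_2d(
            Correspondences2D(
                labels,
                np.array([sl.hist_points[l] for l in labels]),
                np.array([plane_pts[l] for l in labels]),
            )
        )
        assert fit.rms < 1e-6
        assert abs(fit.transform.theta - sl.gt_inplane.inverse().theta) < 1e-6

    def test_out_of_extent_plane_warns_with_few_points(self):
        ph = make_phantom(PhantomSpec(seed=13))
        with pytest.warns(UserWarning):
            sl = cut_slice(ph, 45.0)  # above every spine tip
        assert sl.warning and len(sl.hist_points) < 3

    def test_outside_specimen_rejected(self):
        ph = make_phantom(PhantomSpec(seed=13))
        with pytest.raises(ValueError):
            cut_slice(ph, 60.0)

    def test_tilt_bounded(self):
        spec = PhantomSpec(seed=3, slice_tilt_max=2.0)
        ph = make_phantom(spec)
        lo, hi = ph.common_z_interval()
        for z in np.linspace(lo, hi, 5):
            assert 0.0 <= cut_slice(ph, float(z)).tilt_deg <= 2.0


class TestDegeneracy:
    def test_parallel_spines_lose_axial_information(self):
        # z-recovery error with a parallel bundle approaches the search-range
        # scale; with ~30 deg mutual angles it stays at the grid scale
        def mean_abs_err(angle, n=30):
            errs = []
            for s in range(n):
                spec = PhantomSpec(
                    seed=500 + s,
                    target_pairwise_angle=angle,
                    inplane_noise_sd=0.1,
                    slice_tilt_max=2.0,
                )
                ph = make_phantom(spec)
                lo, hi = ph.common_z_interval()
                z = lo + 0.5 * (hi - lo)
                sl = cut_slice(ph, z)
                curve = rms_curve(sl.hist_points, ph.spines, full_grid(spec))
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    errs.append(abs(find_corresponding_plane(curve).z_star - z))
            return np.mean(errs)

        assert mean_abs_err(0.0) > 5 * mean_abs_err(30.0)


class TestSliceThicknesses:
    def test_statistics_and_support(self):
        x = sample_slice_thicknesses(10_000, seed=0)
        assert np.all(x > 0)
        assert 5.0 < x.mean() < 5.7
        assert abs(x.std() - SLICE_THICKNESS_SD_MM) < 0.5
        assert abs(SLICE_THICKNESS_MEAN_MM - 5.28) < 1e-12

    def test_deterministic_given_seed(self):
        np.testing.assert_array_equal(
            sample_slice_thicknesses(100, seed=5), sample_slice_thicknesses(100, seed=5)
        )

    def test_n_must_be_positive(self):
        with pytest.raises(ValueError):
            sample_slice_thicknesses(0)


class TestSpecValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_spines": 1},
            {"n_landmarks": 3},
            {"landmark_noise_sd": -0.1},
            {"ct_plane_spacing": 0.0},
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            PhantomSpec(**kwargs)
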