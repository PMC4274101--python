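"""Uptake quantification: corrections, surface detection, projection,
averaging — each against an independent oracle where one exists."""

import numpy as np
import pytest

from cuffmap import synthetic as syn
from cuffmap import uptake as up
from cuffmap.types import DepthMap, UptakeProfile


class TestFlatField:
    def test_constant_calibration_is_identity(self, rng):
        chan = rng.uniform(1, 10, size=(4, 5, 6))
        out = up.correct_flat_field(chan, np.full((5, 6), 3.0))
        np.testing.assert_allclose(out, chan)

    def test_ramp_input_flattens_to_ramp_mean(self, rng):
        """Correcting the calibration ramp itself must give a constant equal
        to the ramp mean (elementwise-division oracle)."""
        ramp = np.linspace(1, 2, 30).reshape(5, 6) * np.ones((5, 1))
        chan = np.broadcast_to(ramp, (3, 5, 6))
        out = up.correct_flat_field(chan, ramp)
        np.testing.assert_allclose(out, ramp.mean())

    def test_idempotent_after_correction(self, rng):
        chan = rng.uniform(1, 10, size=(2, 5, 6))
        calib = rng.uniform(0.5, 1.5, size=(5, 6))
        once = up.correct_flat_field(chan, calib)
        again = up.correct_flat_field(once, np.full((5, 6), 2.0))
        np.testing.assert_allclose(once, again)

    def test_zero_calibration_pixel_rejected(self):
        calib = np.ones((4, 4))
        calib[1, 2] = 0.0
        with pytest.raises(up.CalibrationError):
            up.correct_flat_field(np.ones((2, 4, 4)), calib)


class TestZAttenuation:
    def test_identity_curve_unchanged(self, rng):
        chan = rng.uniform(0, 5, size=(6, 3, 3))
        np.testing.assert_array_equal(
            up.correct_z_attenuation(chan, np.ones(6)), chan)

    def test_inverts_known_decay(self):
        curve = np.exp(-0.05 * np.arange(8))
        truth = np.full((8, 4, 4), 7.0)
        degraded = truth * curve[:, None, None]
        out = up.correct_z_attenuation(degraded, curve)
        np.testing.assert_allclose(out, truth, rtol=1e-9)

    def test_short_or_zero_curve_rejected(self):
        with pytest.raises(up.CalibrationError):
            up.correct_z_attenuation(np.ones((8, 2, 2)), np.ones(5))
        bad = np.ones(8)
        bad[3] = 0.0
        with pytest.raises(up.CalibrationError):
            up.correct_z_attenuation(np.ones((8, 2, 2)), bad)


class TestSurfaceDetection:
    def test_step_surface_found_exactly(self):
        auto = np.zeros((10, 4, 5))
        auto[5:] = 100.0
        dm = up.detect_luminal_surface(auto, z_spacing=2.0, smooth=False)
        assert not dm.missing.any()
        np.testing.assert_allclose(dm.depth, (5 + 0.5) * 2.0)

    def test_tilted_plane_recovered(self, curved_clean_config):
        """Generator's curved surface recovered within one voxel at >= 99%
        of columns."""
        stack, truth = syn.gen_enface_stack(curved_clean_config, 5)
        dm = up.detect_luminal_surface(stack.autofluorescence,
                                       z_spacing=stack.z_spacing)
        err = np.abs(dm.depth - truth.true_surface_depth)
        ok = (err <= stack.z_spacing + 1e-9) & ~dm.missing
        assert ok.mean() >= 0.99

    def test_all_zero_channel_all_missing(self):
        dm = up.detect_luminal_surface(np.zeros((5, 3, 3)))
        assert dm.missing.all()

    def test_negative_fixed_threshold_rejected(self):
        with pytest.raises(ValueError):
            up.detect_luminal_surface(np.ones((5, 3, 3)), threshold=-1.0)


class TestDepthWindowedMax:
    def test_single_bright_voxel_in_window(self):
        chan = np.zeros((20, 3, 3))
        chan[5, 1, 1] = 42.0  # voxel centre at 11 µm depth
        dm = DepthMap(np.full((3, 3), 1.0), np.zeros((3, 3), bool))
        out = up.depth_windowed_max(chan, dm, (0, 25), z_spacing=2.0)
        assert out[1, 1] == 42.0

    def test_voxel_beyond_window_excluded(self):
        """A bright voxel 30 µm below the surface must not leak into the
        0-25 µm window."""
        chan = np.ones((25, 3, 3))
        dm = DepthMap(np.full((3, 3), 1.0), np.zeros((3, 3), bool))
        deep = int((1.0 + 30.0) / 2.0)  # ~31 µm depth
        chan[deep, 1, 1] = 99.0
        out = up.depth_windowed_max(chan, dm, (0, 25), z_spacing=2.0)
        assert out[1, 1] == 1.0

    def test_matches_brute_force_on_random_stacks(self, rng):
        """Exact agreement with a per-voxel loop oracle."""
        for _ in range(5):
            nz, ny, nx = 12, 4, 6
            chan = rng.uniform(0, 10, size=(nz, ny, nx))
            depth = rng.uniform(0, 8, size=(ny, nx))
            missing = rng.random((ny, nx)) < 0.2
            dm = DepthMap(np.where(missing, np.nan, depth), missing)
            zsp = 1.5
            out = up.depth_windowed_max(chan, dm, (0, 10), z_spacing=zsp)
            for j in range(ny):
                for i in range(nx):
                    if missing[j, i]:
                        assert np.isnan(out[j, i])
                        continue
                    best = -np.inf
                    for k in range(nz):
                        rel = (k + 0.5) * zsp - depth[j, i]
                        if 0 <= rel <= 10:
                            best = max(best, chan[k, j, i])
                    if best == -np.inf:
                        assert np.isnan(out[j, i])
                    else:
                        assert out[j, i] == best

    def test_empty_window_rejected(self):
        dm = DepthMap(np.zeros((2, 2)), np.zeros((2, 2), bool))
        with pytest.raises(ValueError):
            up.depth_windowed_max(np.ones((5, 2, 2)), dm, (5, 5))


class TestCircumferentialAverage:
    def test_constant_map(self):
        prof = up.circumferential_average(np.full((8, 5), 3.0))
        np.testing.assert_allclose(prof.intensity, 3.0)
        assert (prof.n_pixels == 8).all()

    def test_missing_excluded_from_mean(self):
        col = np.array([[1.0], [2.0], [3.0], [np.nan]])
        prof = up.circumferential_average(col, min_fraction=0.0)
        assert prof.intensity[0] == pytest.approx(2.0)
        assert prof.n_pixels[0] == 3

    def test_sparse_station_marked_missing(self):
        col = np.full((8, 1), np.nan)
        col[0, 0] = 5.0  # 12.5% of circumference < default 25%
        prof = up.circumferential_average(col)
        assert prof.n_pixels[0] == 0
        assert np.isnan(prof.intensity[0])

    def test_max_projection_dominates_median(self, noisy_config):
        stack, truth = syn.gen_enface_stack(noisy_config, 8)
        dm = up.detect_luminal_surface(stack.autofluorescence,
                                       z_spacing=stack.z_spacing)
        mx = up.depth_windowed_max(stack.tracer, dm, z_spacing=stack.z_spacing)
        # median over the same window per column
        z = stack.z_coords
        rel = z[:, None, None] - np.nan_to_num(dm.depth)[None]
        sel = (rel >= 0) & (rel <= 25) & ~dm.missing[None]
        med = np.nanmedian(np.where(sel, stack.tracer, np.nan), axis=0)
        good = np.isfinite(mx) & np.isfinite(med)
        assert np.all(mx[good] >= med[good])


class TestSegmentAveraging:
    def _profile(self, x, y):
        return UptakeProfile(x=np.asarray(x, float), intensity=np.asarray(y, float),
                             n_pixels=np.ones(len(x), int))

    def test_identical_segments(self):
        p = self._profile([0, 1, 2], [5, 6, 7])
        out = up.average_segments(p, p)
        np.testing.assert_allclose(out.intensity, p.intensity)

    def test_p_and_3p_average_to_2p(self):
        x = np.arange(5.0)
        p = self._profile(x, x + 1)
        q = self._profile(x, 3 * (x + 1))
        out = up.average_segments(p, q)
        np.testing.assert_allclose(out.intensity, 2 * (x + 1))

    def test_offset_grids_use_overlap(self):
        """Linear-interpolation oracle on shifted grids."""
        p = self._profile(np.arange(0, 10.0), np.arange(0, 10.0))
        q = self._profile(np.arange(2.5, 12.5), 2 * np.arange(2.5, 12.5))
        out = up.average_segments(p, q)
        assert out.x.min() >= 2.5 and out.x.max() <= 9.0
        np.testing.assert_allclose(out.intensity, 1.5 * out.x, rtol=1e-12)

    def test_disjoint_ranges_rejected(self):
        p = self._profile([0, 1], [1, 1])
        q = self._profile([5, 6], [1, 1])
        with pytest.raises(ValueError, match="overlap"):
            up.average_segments(p, q)


class TestGroupMeanSem:
    def _profile(self, y):
        x = np.arange(len(y), dtype=float)
        return UptakeProfile(x=x, intensity=np.asarray(y, float),
                             n_pixels=np.ones(len(y), int))

    def test_identical_profiles_zero_sem(self):
        p = self._profile([4, 5, 6])
        mean, sem, n = up.group_mean_sem([p, p, p])
        np.testing.assert_allclose(sem, 0.0)
        assert n == 3

    def test_two_profiles_sem_one(self):
        """Profiles {1, 3}: SD = sqrt(2), SEM = sqrt(2)/sqrt(2) = 1."""
        mean, sem, _ = up.group_mean_sem(
            [self._profile([1, 1]), self._profile([3, 3])])
        np.testing.assert_allclose(mean.intensity, 2.0)
        np.testing.assert_allclose(sem, 1.0)

    def test_single_profile_sem_missing(self):
        mean, sem, n = up.group_mean_sem([self._profile([1, 2, 3])])
        assert n == 1
        assert np.isnan(sem).all()
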