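"""Phantom generators: ground-truth bookkeeping, projections, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lungkit.phantom import (BreathingLungPhantom, PhantomSpec,
                             breathing_waveform, ellipsoid_occupancy,
                             make_breathing_volume_series,
                             make_gated_projection_set, make_porous_cube,
                             make_propagated_projection, make_wbp_trace,
                             project_radiographs, true_phase_labels)
from lungkit.xlf import RadiographSequence


class TestWaveform:
    def test_bounds_and_extremes(self):
        t = np.linspace(0.0, 10.0, 5000)
        w = breathing_waveform(t, 0.7, 3.0)
        assert w.min() >= 0.0 and w.max() <= 1.0
        assert w.max() == pytest.approx(1.0)
        assert w.min() == pytest.approx(0.0, abs=1e-3)

    def test_periodicity(self):
        t = np.linspace(0.0, 1.0 / 0.7, 200, endpoint=False)
        w0 = breathing_waveform(t, 0.7, 3.0)
        w1 = breathing_waveform(t + 3.0 / 0.7, 0.7, 3.0)
        np.testing.assert_allclose(w0, w1, atol=1e-12)

    def test_expiration_is_mono_exponential(self):
        # log of (w - asymptote) must be linear on the expiratory limb
        f, k, fi = 0.7, 3.0, 0.3
        T = 1.0 / f
        t_hold = fi * T
        tau = np.linspace(t_hold + 0.01, T - 0.01, 50)
        w = breathing_waveform(tau, f, k, inspiration_fraction=fi)
        w_end = np.exp(-k * (T - t_hold))
        asymptote = -w_end / (1.0 - w_end)
        slope = np.polyfit(tau, np.log(w - asymptote), 1)[0]
        assert slope == pytest.approx(-k, rel=1e-9)


class TestGroundTruth:
    def test_generator_echoes_parameters(self):
        spec = PhantomSpec(expiration_decay_rate=3.0, severity=0.0)
        series = make_breathing_volume_series(spec, 40, 14.0)
        gt = series.ground_truth
        assert gt.decay_rate == pytest.approx(3.0)
        assert gt.tidal_volume == pytest.approx(spec.tidal_air_volume)
        assert gt.air_volume_insp - gt.air_volume_exp == pytest.approx(gt.tidal_volume)

    @pytest.mark.parametrize("metric", ["decay_rate", "air_volume_insp",
                                        "tidal_volume", "air_ratio"])
    def test_severity_monotone(self, metric):
        values = []
        for s in (0.0, 0.25, 0.5, 0.75, 1.0):
            gt = BreathingLungPhantom(PhantomSpec(severity=s)).ground_truth()
            values.append(getattr(gt, metric))
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_severity_lowers_inspiratory_volume(self):
        gt0 = BreathingLungPhantom(PhantomSpec(severity=0.0)).ground_truth()
        gt1 = BreathingLungPhantom(PhantomSpec(severity=1.0)).ground_truth()
        assert gt1.air_volume_insp < gt0.air_volume_insp

    def test_voxelised_air_volume_matches_analytic(self):
        ph = BreathingLungPhantom(PhantomSpec(), supersample=2)
        vox = ph.air_occupancy(1.0).sum() * ph.spec.voxel_size**3
        analytic = ph.ground_truth().air_volume_insp * 1000.0
        assert vox == pytest.approx(analytic, rel=0.01)

    def test_determinism(self):
        a = make_breathing_volume_series(PhantomSpec(seed=3), 21, 14.0)
        b = make_breathing_volume_series(PhantomSpec(seed=3), 21, 14.0)
        np.testing.assert_array_equal(a.volumes, b.volumes)

    def test_aliasing_frame_rate_rejected(self):
        with pytest.raises(ValueError, match="alias"):
            make_breathing_volume_series(PhantomSpec(), 40, 1.0)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            PhantomSpec(severity=1.5)
        with pytest.raises(ValueError):
            PhantomSpec(breathing_frequency=-1.0)
        with pytest.raises(ValueError):
            PhantomSpec(expiration_decay_rate=0.0)


class TestProjection:
    def test_zero_attenuation_gives_flat_i0(self):
        from lungkit.phantom import beer_lambert_project

        img = beer_lambert_project(np.zeros((8, 8, 8)), 0.5, axis=1, i0=123.0)
        np.testing.assert_allclose(img, 123.0)

    def test_single_voxel_beer_lambert(self):
        from lungkit.phantom import beer_lambert_project

        vol = np.zeros((5, 5, 5))
        vol[2, 2, 2] = np.log(2.0) / 0.5  # mu * dx = ln 2
        img = beer_lambert_project(vol, 0.5, axis=1, i0=1.0)
        assert img[2, 2] == pytest.approx(0.5)
        assert img[0, 0] == pytest.approx(1.0)

    def test_log_additivity(self, rng):
        from lungkit.phantom import beer_lambert_project

        v1 = rng.uniform(0.0, 0.05, (6, 6, 6))
        v2 = rng.uniform(0.0, 0.05, (6, 6, 6))
        i0 = 2.0
        p1 = beer_lambert_project(v1, 0.3, i0=i0)
        p2 = beer_lambert_project(v2, 0.3, i0=i0)
        p12 = beer_lambert_project(v1 + v2, 0.3, i0=i0)
        np.testing.assert_allclose(p12, p1 * p2 / i0, rtol=1e-12)

    def test_matches_brute_force_ray_sums(self):
        spec = PhantomSpec.with_grid(24)
        series = make_breathing_volume_series(spec, 21, 14.0)
        seq = project_radiographs(series, axis=1, i0=1.0)
        vol = series.volumes[0]
        # independent oracle: explicit per-ray loop
        nz, ny, nx = vol.shape
        expected = np.empty((nz, nx))
        for iz in range(nz):
            for ix in range(nx):
                s = 0.0
                for iy in range(ny):
                    s += vol[iz, iy, ix] * spec.voxel_size
                expected[iz, ix] = np.exp(-s)
        np.testing.assert_allclose(seq.frames[0], expected, rtol=1e-10)

    def test_poisson_noise_reproducible_and_applied(self):
        spec = PhantomSpec.with_grid(24)
        series = make_breathing_volume_series(spec, 21, 14.0)
        a = project_radiographs(series, noise_model=1000.0, seed=5)
        b = project_radiographs(series, noise_model=1000.0, seed=5)
        clean = project_radiographs(series, i0=1000.0)
        np.testing.assert_array_equal(a.frames, b.frames)
        assert not np.array_equal(a.frames, clean.frames)

    def test_nonpositive_i0_rejected(self):
        from lungkit.phantom import beer_lambert_project

        with pytest.raises(ValueError):
            beer_lambert_project(np.zeros((4, 4, 4)), 0.5, i0=0.0)


class TestGatedProjections:
    def test_frozen_phantom_is_static(self):
        spec = PhantomSpec.with_grid(32, tidal_air_volume=0.0)
        projset, truth = make_gated_projection_set(spec, n_angles=40,
                                                   rotation_time=30.0)
        assert set(truth.labels) == {"static"}
        # all projections at the same angle-independent state: the sinogram
        # of slice z is consistent with a single volume (first/last agree at
        # matched angles 0 and 180 via parallel-beam symmetry)
        assert np.ptp(truth.amplitudes) == 0.0

    def test_label_alternation_period(self):
        spec = PhantomSpec.with_grid(24)
        projset, truth = make_gated_projection_set(spec, n_angles=200,
                                                   rotation_time=30.0)
        # inspiration labels recur once per breath: ~0.7 Hz * 30 s breaths
        insp = truth.labels == "inspiration"
        blocks = np.diff(np.flatnonzero(np.diff(insp.astype(int)) == 1))
        expected_frames = 200 / 30.0 / 0.7  # frames per breathing period
        assert np.median(blocks) == pytest.approx(expected_frames, rel=0.25)

    def test_too_few_angles_rejected(self):
        with pytest.raises(ValueError):
            make_gated_projection_set(PhantomSpec.with_grid(16), n_angles=1)

    def test_short_rotation_rejected(self):
        with pytest.raises(ValueError, match="10 breathing cycles"):
            make_gated_projection_set(PhantomSpec.with_grid(16), n_angles=40,
                                      rotation_time=5.0)


class TestWBPTrace:
    def test_positive_half_cycle_integral_is_tidal_volume(self):
        trace, tv = make_wbp_trace(0.2, frequency=2.0, duration=5.0,
                                   flow_calibration=3.0)
        # analytic: integral of A sin over half cycle = A/(pi f)
        dt = 1.0 / trace.sampling_rate
        half = trace.p[: int(0.25 / dt)]  # first half cycle at 2 Hz
        integral = np.trapezoid(half, dx=dt)
        assert integral == pytest.approx(0.2 * 3.0, rel=1e-4)

    def test_seeds_change_noise_not_flow(self):
        t1, _ = make_wbp_trace(0.2, 2.0, 5.0, noise_amp=0.1, seed=1)
        t2, _ = make_wbp_trace(0.2, 2.0, 5.0, noise_amp=0.1, seed=2)
        clean, _ = make_wbp_trace(0.2, 2.0, 5.0)
        assert not np.array_equal(t1.p, t2.p)
        np.testing.assert_allclose(t1.p - (t1.p - clean.p), clean.p, atol=1e-12)

    def test_out_of_band_frequency_warns(self):
        with pytest.warns(UserWarning, match="passband"):
            make_wbp_trace(0.2, frequency=0.3, duration=15.0)

    def test_too_short_duration_rejected(self):
        with pytest.raises(ValueError):
            make_wbp_trace(0.2, frequency=2.0, duration=1.0)


class TestPorousCube:
    def test_single_sphere_analytic_air_ratio(self):
        vol, gt = make_porous_cube(1.75, 1.75 / 64, [0.25],
                                   [[0.875, 0.875, 0.875]])
        assert gt.air_ratio == pytest.approx(
            (4.0 / 3.0) * np.pi * 0.25**3 / 1.75**3)
        assert gt.air_ratio == pytest.approx(0.0122, abs=2e-4)

    def test_no_spheres(self):
        vol, gt = make_porous_cube(1.0, 1.0 / 32, [], [])
        assert gt.air_ratio == 0.0
        assert gt.interface_area == 0.0
        np.testing.assert_allclose(vol, 1.0)

    def test_voxelised_air_count_converges(self):
        r, side = 0.4, 1.75
        vol, gt = make_porous_cube(side, side / 256, [r],
                                   [[0.875, 0.875, 0.875]])
        occ_air = 1.0 - vol
        rel_err = occ_air.sum() * (side / 256) ** 3 / (
            (4.0 / 3.0) * np.pi * r**3) - 1.0
        assert abs(rel_err) < 0.01

    def test_overlapping_spheres_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            make_porous_cube(2.0, 0.05, [0.5, 0.5], [[0.7, 1.0, 1.0],
                                                     [1.3, 1.0, 1.0]])

    def test_sphere_outside_cube_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            make_porous_cube(1.0, 0.05, [0.4], [[0.1, 0.5, 0.5]])


class TestPropagation:
    def test_zero_distance_is_pure_absorption(self):
        t = np.zeros((32, 32))
        t[10:20, 10:20] = 0.05
        lam = 1.23984193e-6 / 23.6
        mu = 4.0 * np.pi * 1e-9 / lam
        out = make_propagated_projection(t, 23.6, 0.0, 0.002, 1e-7, 1e-9)
        np.testing.assert_allclose(out, np.exp(-mu * t), rtol=1e-12)

    def test_flat_thickness_gives_flat_intensity(self):
        t = np.full((64, 64), 0.03)
        out = make_propagated_projection(t, 23.6, 150.0, 0.002, 1e-7, 1e-9)
        assert np.ptp(out) < 1e-10

    def test_negative_thickness_rejected(self):
        with pytest.raises(ValueError):
            make_propagated_projection(np.full((8, 8), -1.0), 23.6, 150.0,
                                       0.002, 1e-7, 1e-9)

    def test_band_limit_guard(self):
        t = np.zeros((32, 32))
        with pytest.raises(ValueError, match="band limit"):
            make_propagated_projection(t, 23.6, 1e9, 0.002, 1e-7, 1e-9)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.floats(0.5, 5.0), st.floats(0.5, 8.0),
       st.floats(0.0, 30.0))
def test_waveform_stays_in_unit_interval(freq, k, t0):
    t = t0 + np.linspace(0.0, 2.0 / freq, 97)
    w = breathing_waveform(t, freq, k)
    assert np.all(w >= -1e-12) and np.all(w <= 1.0 + 1e-12)


def test_true_phase_labels_partition():
    w = breathing_waveform(np.linspace(0, 30, 500), 0.7, 3.0)
    lab = true_phase_labels(w)
    assert set(lab) == {"inspiration", "expiration", "discarded"}
    assert np.all(w[lab == "inspiration"].min() >= w[lab == "expiration"].max())
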