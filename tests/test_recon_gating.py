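"""FBP reconstruction, respiratory gating, segmentation and volumetry."""

import numpy as np
import pytest
from skimage.transform import iradon

from lungkit import gating
from lungkit.recon import angular_weights, fbp_slice
from lungkit.phantom import PhantomSpec, BreathingLungPhantom


def disk_sinogram(n=256, spacing=0.1, radius=8.0, density=0.04, angles=None):
    if angles is None:
        angles = np.linspace(0.0, 360.0, 360, endpoint=False)
    det = (np.arange(n) - n // 2) * spacing
    p = 2.0 * density * np.sqrt(np.maximum(radius**2 - det**2, 0.0))
    return np.tile(p[:, None], (1, len(angles))), angles


def disk_masks(n=256, spacing=0.1, radius=8.0):
    c0 = n // 2
    yy, xx = np.mgrid[0:n, 0:n]
    r = np.hypot((xx - c0) * spacing, (c0 - yy) * spacing)
    inside = r < radius - 3 * spacing
    outside = (r > radius + 3 * spacing) & (r < 2.2 * radius)
    return inside, outside


class TestFBP:
    def test_uniform_disk_density(self):
        sino, angles = disk_sinogram()
        rec = fbp_slice(sino, angles, 0.1)
        inside, outside = disk_masks()
        assert rec[inside].mean() == pytest.approx(0.04, rel=0.03)
        assert abs(rec[outside].mean()) < 0.02 * 0.04

    def test_random_subset_preserves_contrast(self, rng):
        sino, angles = disk_sinogram()
        sub = np.sort(rng.choice(len(angles), size=int(0.4 * len(angles)),
                                 replace=False))
        rec = fbp_slice(sino[:, sub], angles[sub], 0.1)
        inside, outside = disk_masks()
        contrast = rec[inside].mean() / max(np.abs(rec[outside]).mean(), 1e-12)
        assert contrast > 5.0

    def test_zero_sinogram(self):
        sino, angles = disk_sinogram()
        rec = fbp_slice(np.zeros_like(sino), angles, 0.1)
        np.testing.assert_allclose(rec, 0.0)

    def test_linearity(self, rng):
        sino, angles = disk_sinogram(n=64, radius=2.0)
        noise = rng.uniform(0, 0.01, sino.shape)
        a = fbp_slice(sino, angles, 0.1)
        b = fbp_slice(noise, angles, 0.1)
        ab = fbp_slice(sino + noise, angles, 0.1)
        np.testing.assert_allclose(ab, a + b, atol=1e-10)

    def test_matches_skimage_iradon_uniform_angles(self):
        """Independent oracle: uniform half-turn FBP against skimage."""
        n, spacing = 128, 0.1
        sino, _ = disk_sinogram(n=n, spacing=spacing, radius=4.0)
        angles = np.linspace(0.0, 180.0, 180, endpoint=False)
        sino = sino[:, :180]
        mine = fbp_slice(sino, angles, spacing)
        ref = iradon(sino / spacing, theta=angles, filter_name="ramp",
                     circle=True)
        inside, _ = disk_masks(n=n, spacing=spacing, radius=4.0)
        np.testing.assert_allclose(mine[inside], ref[inside], atol=2e-3 * 0.04)

    def test_angular_weights_sum_to_half_turn(self):
        angles = np.sort(np.random.default_rng(0).uniform(0, 360, 50))
        assert angular_weights(angles).sum() == pytest.approx(np.pi)


class TestBreathingSignal:
    def test_static_phantom_flat_corrected(self):
        from lungkit.phantom import make_gated_projection_set

        ptp = {}
        for tidal in (0.0, 0.15):
            spec = PhantomSpec.with_grid(24, tidal_air_volume=tidal)
            row = 12 + int(round(spec.geometry.lung_center_z
                                 / spec.voxel_size))
            projset, _ = make_gated_projection_set(spec, n_angles=60,
                                                   rotation_time=30.0)
            sig = gating.breathing_signal_from_projections(projset, row,
                                                           frequency=0.7)
            ptp[tidal] = np.ptp(sig.corrected)
        # a frozen phantom leaves only a small residual of the slow angular
        # anatomy variation, far below the breathing modulation
        assert ptp[0.0] < 0.1 * ptp[0.15]

    def test_tracks_true_amplitude(self, gated_set, small_spec):
        projset, truth = gated_set
        row = 24 + int(round(small_spec.geometry.lung_center_z
                             / small_spec.voxel_size))
        sig = gating.as_inspiration_positive(
            gating.breathing_signal_from_projections(projset, row,
                                                     frequency=0.7))
        r = np.corrcoef(sig.corrected, truth.amplitudes)[0, 1]
        assert r > 0.95

    def test_drift_removed(self, gated_set, small_spec):
        projset, truth = gated_set
        row = 24
        sig0 = gating.breathing_signal_from_projections(projset, row,
                                                        frequency=0.7)
        # impose an intensity drift on the frames: raw gains a linear trend
        drifted = gating.ProjectionSet(
            frames=projset.frames * np.exp(
                -np.linspace(0, 0.05, len(projset.frames)))[:, None, None],
            angles=projset.angles, timestamps=projset.timestamps,
            pixel=projset.pixel, i0=projset.i0)
        sig1 = gating.breathing_signal_from_projections(drifted, row,
                                                        frequency=0.7)
        np.testing.assert_allclose(sig1.corrected, sig0.corrected, atol=5e-4)

    def test_invalid_row_rejected(self, gated_set):
        projset, _ = gated_set
        with pytest.raises(ValueError):
            gating.breathing_signal_from_projections(projset, 1000)


class TestAssignPhases:
    def test_sinusoid_order_statistics(self):
        t = np.linspace(0.0, 100.0, 5000, endpoint=False)
        sig = gating.BreathingSignal(t=t, raw=np.sin(t), corrected=np.sin(t))
        asn = gating.assign_phases(sig, 80.0, 20.0)
        n = len(t)
        assert len(asn.indices("inspiration")) == pytest.approx(0.2 * n, abs=2)
        assert len(asn.indices("expiration")) == pytest.approx(0.2 * n, abs=2)
        hi = np.percentile(np.sin(t), 80)
        np.testing.assert_array_equal(asn.indices("inspiration"),
                                      np.flatnonzero(np.sin(t) >= hi))

    def test_equal_quantiles_retain_everything(self):
        t = np.linspace(0.0, 10.0, 500)
        sig = gating.BreathingSignal(t=t, raw=np.sin(t), corrected=np.sin(t))
        asn = gating.assign_phases(sig, 50.0, 50.0)
        assert len(asn.indices("discarded")) == 0

    def test_zero_variance_rejected(self):
        sig = gating.BreathingSignal(t=np.arange(10.0), raw=np.ones(10),
                                     corrected=np.ones(10))
        with pytest.raises(ValueError):
            gating.assign_phases(sig)

    def test_phantom_agreement_with_truth(self, gated_set, small_spec):
        projset, truth = gated_set
        row = 24 + int(round(small_spec.geometry.lung_center_z
                             / small_spec.voxel_size))
        sig = gating.as_inspiration_positive(
            gating.breathing_signal_from_projections(projset, row,
                                                     frequency=0.7))
        asn = gating.assign_phases(sig, 80.0, 20.0)
        from lungkit.cohort import phase_agreement

        assert phase_agreement(asn.labels, truth.labels) >= 0.90


class TestVolumePostprocessing:
    def test_background_subtraction_of_identical_slices(self):
        vol = gating.ReconVolume(np.tile(np.random.rand(8, 8), (5, 1, 1)), 0.5)
        out = gating.subtract_background_slice(vol, 2)
        np.testing.assert_allclose(out.voxels, 0.0)

    def test_background_subtraction_restores_offset(self, rng):
        base = rng.uniform(0, 1, (6, 8, 8))
        offset = rng.uniform(0, 1, (8, 8))
        vol = gating.ReconVolume(base + offset, 0.5)
        ref = gating.ReconVolume(base, 0.5)
        out = gating.subtract_background_slice(vol, 3)
        expected = gating.subtract_background_slice(ref, 3)
        np.testing.assert_allclose(out.voxels, expected.voxels, atol=1e-12)

    def test_smooth_identity_and_constant(self):
        vol = gating.ReconVolume(np.random.rand(8, 8, 8), 0.5)
        assert gating.smooth_3d(vol, 0.0) is vol
        const = gating.ReconVolume(np.full((8, 8, 8), 2.0), 0.5)
        np.testing.assert_allclose(gating.smooth_3d(const, 1.5).voxels, 2.0,
                                   rtol=1e-10)

    def test_smoothing_variance_reduction_matches_kernel_theory(self, rng):
        sigma = 1.5
        noise = rng.normal(0.0, 1.0, (48, 48, 48))
        out = gating.smooth_3d(gating.ReconVolume(noise, 0.5), sigma)
        # closed form: white-noise variance shrinks by the kernel's sum of
        # squares, (1 / (2 sqrt(pi) sigma))^3 for a sampled Gaussian per axis
        expected = (1.0 / (2.0 * np.sqrt(np.pi) * sigma)) ** 3
        inner = out.voxels[8:-8, 8:-8, 8:-8]
        assert inner.var() == pytest.approx(expected, rel=0.10)


class TestSegmentation:
    def make_air_box(self):
        vol = np.full((40, 40, 40), 1.0)
        vol[10:30, 10:30, 10:30] = 0.0
        return gating.ReconVolume(vol, 0.05)

    def test_air_box_exact_voxel_count(self):
        vol = self.make_air_box()
        mask = gating.segment_lung(vol, (20, 20, 20), threshold_policy=0.5,
                                   r_close=0)
        assert mask.voxels.sum() == 8000

    def test_lung_volume_in_ml(self):
        vol = self.make_air_box()
        mask = gating.segment_lung(vol, (20, 20, 20), threshold_policy=0.5,
                                   r_close=0)
        assert gating.lung_volume(mask) == pytest.approx(8000 * 0.05**3 / 1000.0)
        assert gating.lung_volume(mask) == pytest.approx(0.001)

    def test_empty_mask_zero_volume(self):
        mask = gating.LungMask(np.zeros((4, 4, 4), dtype=bool), 0.05)
        assert gating.lung_volume(mask) == 0.0

    def test_closing_bridges_vessel(self):
        vol = self.make_air_box()
        vol.voxels[10:30, 19, 19] = 1.0  # 1-voxel vessel-like tube through it
        mask = gating.segment_lung(vol, (20, 20, 25), threshold_policy=0.5,
                                   r_close=2)
        assert mask.voxels[10:30, 10:30, 10:30].sum() >= 0.99 * 8000

    def test_disconnected_box_not_segmented(self):
        vol = np.full((40, 40, 40), 1.0)
        vol[5:15, 5:15, 5:15] = 0.0
        vol[25:35, 25:35, 25:35] = 0.0
        rv = gating.ReconVolume(vol, 0.05)
        mask = gating.segment_lung(rv, (10, 10, 10), threshold_policy=0.5,
                                   r_close=0)
        assert mask.voxels[5:15, 5:15, 5:15].all()
        assert not mask.voxels[25:35, 25:35, 25:35].any()

    def test_seed_above_threshold_rejected(self):
        vol = self.make_air_box()
        with pytest.raises(ValueError, match="seed"):
            gating.segment_lung(vol, (2, 2, 2), threshold_policy=0.5)

    def test_multi_seed_union(self):
        vol = np.full((40, 40, 40), 1.0)
        vol[5:15, 5:15, 5:15] = 0.0
        vol[25:35, 25:35, 25:35] = 0.0
        rv = gating.ReconVolume(vol, 0.05)
        mask = gating.segment_lung(rv, [(10, 10, 10), (30, 30, 30)],
                                   threshold_policy=0.5, r_close=0)
        assert mask.voxels.sum() == 2000


class TestGatingNecessity:
    def test_ungated_reconstruction_blurs_volumetry(self, gated_set,
                                                    small_spec):
        """Reconstructing from all projections mixes breathing states and
        degrades the inspiratory volume estimate versus gated recon."""
        projset, truth = gated_set
        spec = small_spec
        phantom = BreathingLungPhantom(spec)
        row = 24 + int(round(spec.geometry.lung_center_z / spec.voxel_size))
        sig = gating.as_inspiration_positive(
            gating.breathing_signal_from_projections(projset, row,
                                                     frequency=0.7))
        gated = gating.assign_phases(sig, 85.0, 10.0)
        all_in = gating.PhaseAssignment(
            labels=np.asarray(["inspiration"] * len(projset.frames),
                              dtype=object))
        v_true = truth.ground_truth.air_volume_insp
        errs = {}
        for name, asn in (("gated", gated), ("ungated", all_in)):
            vol = gating.reconstruct_phase(projset, asn, "inspiration")
            vol = gating.smooth_3d(vol, 1.0)
            mask = gating.segment_lung(vol, phantom.seed_voxels(), "midpoint",
                                       thoracic_mask=phantom.thoracic_mask())
            errs[name] = abs(gating.lung_volume(mask) - v_true)
        assert errs["ungated"] > errs["gated"]
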