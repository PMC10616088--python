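"""Synthetic breathing-lung phantom with analytically known ground truth.

The phantom emulates a mouse thorax in a gated-microCT / XLF / WBP study:
two ellipsoidal lung fields inside a soft-tissue cylinder with rib-like
high-attenuation rings.  Breathing is geometric - an inner air-compartment
ellipsoid pair is rescaled each time point so that its *analytic* volume
equals the instantaneous air volume

    A(t) = V_exp + TV * w(t)

where ``w`` is a cyclic waveform at the breathing frequency (default 0.7 Hz):
a linear inspiratory rise, a short end-inspiratory pause, then exponential
passive expiration ``exp(-k t)`` whose rate constant ``k`` is the
ground-truth decay rate.  A scalar ``severity`` in [0, 1] jointly lowers the
decay rate, the tidal and resting air volumes, and raises the parenchymal
density - the qualitative fingerprint of bleomycin fibrosis.

All generators export the exact analytic ground truth (volumes, decay rate,
air ratio, interface areas) so every downstream stage is testable without
animal data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from skimage.transform import radon

from .gating import ProjectionSet, STATIC, INSPIRATION, EXPIRATION, DISCARDED
from .wbp import ChamberConfig, PressureTrace
from .xlf import RadiographSequence, TransmissionCurve

# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class SeverityCoupling:
    """How the fibrosis-severity scalar maps onto physiology.

    Each entry is the fractional reduction (or increase, for density) at
    severity 1.  Values are design constants chosen to mirror the qualitative
    fibrotic contrasts: slower expiration, smaller breaths, denser lung.
    """

    decay_rate: float = 0.6
    tidal_volume: float = 0.6
    resting_volume: float = 0.35
    tissue_density: float = 0.2


@dataclass(frozen=True)
class LungGeometry:
    """Parametric thorax: cylinder + two lung ellipsoids + rib rings (mm)."""

    thorax_radius: float = 8.2
    thorax_half_height: float = 8.8
    lung_offset_x: float = 3.9
    lung_center_z: float = -0.5
    lung_semiaxes: tuple = (6.5, 3.2, 3.5)  # (z, y, x)
    rib_z_positions: tuple = (-6.0, -3.0, 0.0, 3.0, 6.0)
    rib_shell: tuple = (6.8, 7.6)  # radial band, mm
    rib_half_thickness: float = 0.25
    mu_tissue: float = 0.04  # 1/mm
    mu_bone: float = 0.10
    mu_air: float = 0.0

    def lung_centers(self):
        return [(self.lung_center_z, 0.0, -self.lung_offset_x),
                (self.lung_center_z, 0.0, +self.lung_offset_x)]

    def lung_pair_volume(self) -> float:
        az, ay, ax = self.lung_semiaxes
        return 2.0 * 4.0 / 3.0 * np.pi * az * ay * ax


@dataclass
class PhantomSpec:
    """Full description of one synthetic animal at one imaging session."""

    grid_shape: tuple = (64, 64, 64)  # (nz, ny, nx) voxels
    voxel_size: float = 0.325  # mm
    geometry: LungGeometry = field(default_factory=LungGeometry)
    breathing_frequency: float = 0.7  # Hz
    inspiration_fraction: float = 0.3  # fraction of the cycle spent inflating
    rise_fraction: float = 2.0 / 3.0  # rise part of inspiration; rest = pause
    expiration_decay_rate: float = 3.0  # 1/s, ground-truth k at severity 0
    severity: float = 0.0
    tidal_air_volume: float = 0.15  # ml at severity 0
    resting_air_volume: float = 0.32  # ml at severity 0 (end-expiration)
    volume_scale: float = 1.0  # animal-size factor on all air volumes
    coupling: SeverityCoupling = field(default_factory=SeverityCoupling)
    noise_model: float | str = "none"  # photon count for Poisson, or "none"
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.severity <= 1.0:
            raise ValueError("severity must lie in [0, 1]")
        if self.breathing_frequency <= 0:
            raise ValueError("breathing_frequency must be positive")
        if self.expiration_decay_rate <= 0:
            raise ValueError("expiration_decay_rate must be positive")
        if any(n <= 0 for n in self.grid_shape):
            raise ValueError("grid_shape must be positive")
        if not 0.0 < self.inspiration_fraction < 1.0:
            raise ValueError("inspiration_fraction must lie in (0, 1)")
        if self.tidal_air_volume < 0 or self.resting_air_volume <= 0:
            raise ValueError("air volumes must be positive")

    @classmethod
    def with_grid(cls, n: int, fov_mm: float = 20.8, **kwargs) -> "PhantomSpec":
        """Spec with an n^3 grid spanning a fixed 20.8 mm field of view."""
        return cls(grid_shape=(n, n, n), voxel_size=fov_mm / n, **kwargs)

    # severity-coupled effective parameters -------------------------------
    @property
    def decay_rate_eff(self) -> float:
        return self.expiration_decay_rate * (1.0 - self.coupling.decay_rate * self.severity)

    @property
    def tidal_volume_eff(self) -> float:
        """ml"""
        return (self.tidal_air_volume * self.volume_scale
                * (1.0 - self.coupling.tidal_volume * self.severity))

    @property
    def resting_volume_eff(self) -> float:
        """ml"""
        return (self.resting_air_volume * self.volume_scale
                * (1.0 - self.coupling.resting_volume * self.severity))

    @property
    def mu_parenchyma(self) -> float:
        g = self.geometry
        return g.mu_tissue * (1.0 + self.coupling.tissue_density * self.severity)


@dataclass
class GroundTruth:
    """Analytic truth exported with every generated dataset."""

    air_volume_insp: float  # ml
    air_volume_exp: float  # ml
    tidal_volume: float  # ml
    decay_rate: float  # 1/s
    air_ratio: float
    interface_area: float  # mm^2
    tissue_volume: float  # mm^3

    def __post_init__(self):
        if self.air_volume_insp < self.air_volume_exp:
            raise ValueError("inspiratory air volume must be >= expiratory")
        if abs(self.tidal_volume - (self.air_volume_insp - self.air_volume_exp)) > 1e-9:
            raise ValueError("tidal_volume must equal V_insp - V_exp")
        if not 0.0 <= self.air_ratio <= 1.0:
            raise ValueError("air_ratio must lie in [0, 1]")


# ---------------------------------------------------------------------------
# waveform


def breathing_waveform(
    t,
    frequency: float,
    decay_rate: float,
    inspiration_fraction: float = 0.3,
    rise_fraction: float = 2.0 / 3.0,
):
    """Normalised breathing amplitude w(t) in [0, 1].

    Linear rise over ``inspiration_fraction * rise_fraction`` of the period,
    an end-inspiratory pause at 1 for the rest of the inspiration fraction,
    then exponential relaxation with rate constant ``decay_rate``.  The
    relaxation is normalised so the expiratory baseline w = 0 is reached
    exactly at end-cycle: ``w = (exp(-k tau) - w_end) / (1 - w_end)``.  This
    keeps the limb exactly mono-exponential with rate k (toward a slightly
    shifted asymptote) while making end-expiration an attained state - so
    the generator's tidal volume is exactly the inspiratory minus the
    end-expiratory air volume, and the waveform is continuous across cycles.
    """
    t = np.asarray(t, dtype=float)
    T = 1.0 / frequency
    tau = np.mod(t, T)
    t_rise = inspiration_fraction * rise_fraction * T
    t_hold = inspiration_fraction * T
    w_end = np.exp(-decay_rate * (T - t_hold))
    rising = tau < t_rise
    holding = (tau >= t_rise) & (tau < t_hold)
    w = np.empty_like(tau)
    w[rising] = tau[rising] / max(t_rise, 1e-12)
    w[holding] = 1.0
    exhaling = ~(rising | holding)
    w[exhaling] = (np.exp(-decay_rate * (tau[exhaling] - t_hold)) - w_end) \
        / (1.0 - w_end)
    return w


def true_phase_labels(w, insp_q: float = 80.0, exp_q: float = 20.0):
    """Reference phase labels from the true amplitude (same percentile rule)."""
    w = np.asarray(w, dtype=float)
    if np.ptp(w) == 0:
        return np.asarray([STATIC] * len(w), dtype=object)
    hi, lo = np.percentile(w, insp_q), np.percentile(w, exp_q)
    lab = np.full(len(w), DISCARDED, dtype=object)
    lab[w >= hi] = INSPIRATION
    lab[w <= lo] = EXPIRATION
    return lab


# ---------------------------------------------------------------------------
# voxelisation helpers


def _axis_coords(n: int, voxel: float) -> np.ndarray:
    # centre at n//2 to match the skimage radon rotation centre
    return (np.arange(n) - n // 2) * voxel


def _supersample_offsets(ss: int, voxel: float) -> np.ndarray:
    return ((np.arange(ss) + 0.5) / ss - 0.5) * voxel


def ellipsoid_occupancy(
    grid_shape, voxel: float, center, semiaxes, ss: int = 2
) -> np.ndarray:
    """Fractional voxel occupancy of an ellipsoid, ss^3-supersampled.

    center and semiaxes in mm, ordered (z, y, x).
    """
    nz, ny, nx = grid_shape
    z, y, x = (_axis_coords(n, voxel) for n in (nz, ny, nx))
    cz, cy, cx = center
    az, ay, ax = semiaxes
    margin = voxel
    izs = np.flatnonzero(np.abs(z - cz) <= az + margin)
    iys = np.flatnonzero(np.abs(y - cy) <= ay + margin)
    ixs = np.flatnonzero(np.abs(x - cx) <= ax + margin)
    occ = np.zeros(grid_shape)
    if len(izs) == 0 or len(iys) == 0 or len(ixs) == 0:
        return occ
    offs = _supersample_offsets(ss, voxel)
    box = np.zeros((len(izs), len(iys), len(ixs)))
    for oz in offs:
        qz = ((z[izs] + oz - cz) / az) ** 2
        for oy in offs:
            qy = ((y[iys] + oy - cy) / ay) ** 2
            for ox in offs:
                qx = ((x[ixs] + ox - cx) / ax) ** 2
                box += (qz[:, None, None] + qy[None, :, None]
                        + qx[None, None, :]) <= 1.0
    occ[np.ix_(izs, iys, ixs)] = box / ss**3
    return occ


def _cylinder_occupancy(grid_shape, voxel, radius, half_height, ss=2):
    nz, ny, nx = grid_shape
    z, y, x = (_axis_coords(n, voxel) for n in (nz, ny, nx))
    offs = _supersample_offsets(ss, voxel)
    occ = np.zeros(grid_shape)
    for oz in offs:
        inz = np.abs(z + oz) <= half_height
        for oy in offs:
            for ox in offs:
                r2 = (y[:, None] + oy) ** 2 + (x[None, :] + ox) ** 2
                occ += inz[:, None, None] * (r2 <= radius**2)[None, :, :]
    return occ / ss**3


def ellipsoid_surface_area(semiaxes) -> float:
    """Thomsen's approximation (p = 1.6075, error < 1.1%)."""
    a, b, c = semiaxes
    p = 1.6075
    return 4.0 * np.pi * (((a * b) ** p + (a * c) ** p + (b * c) ** p) / 3.0) ** (1 / p)


# ---------------------------------------------------------------------------
# the breathing phantom


class BreathingLungPhantom:
    """Voxelises a :class:`PhantomSpec` at arbitrary breathing amplitudes.

    The attenuation map is affine in the air-compartment occupancy, so the
    static anatomy (thorax, rib rings, parenchymal envelope) is computed once
    and only the two air ellipsoids are re-voxelised per breathing state.
    """

    def __init__(self, spec: PhantomSpec, supersample: int = 2):
        self.spec = spec
        self.ss = supersample
        g = spec.geometry
        n_xy = min(spec.grid_shape[1:])
        if g.thorax_radius > (n_xy // 2 - 1) * spec.voxel_size:
            raise ValueError("thorax does not fit the reconstruction circle")
        scale = spec.volume_scale ** (1.0 / 3.0)
        self.semiaxes_eff = tuple(a * scale for a in g.lung_semiaxes)
        self.v_pair = g.lung_pair_volume() * spec.volume_scale  # mm^3
        v_insp = (spec.resting_volume_eff + spec.tidal_volume_eff) * 1000.0
        if v_insp > self.v_pair:
            raise ValueError("inspiratory air volume exceeds the lung envelope")
        occ_thorax = _cylinder_occupancy(
            spec.grid_shape, spec.voxel_size, g.thorax_radius,
            g.thorax_half_height, ss=supersample)
        occ_lung = np.zeros(spec.grid_shape)
        for c in g.lung_centers():
            occ_lung += ellipsoid_occupancy(
                spec.grid_shape, spec.voxel_size, c, self.semiaxes_eff,
                ss=supersample)
        occ_lung = np.minimum(occ_lung, occ_thorax)
        occ_rib = self._rib_occupancy()
        self.mu_base = (
            g.mu_tissue * (occ_thorax - occ_lung)
            + spec.mu_parenchyma * occ_lung
            + (g.mu_bone - g.mu_tissue) * occ_rib
        )
        self.occ_lung = occ_lung

    def _rib_occupancy(self):
        g, spec = self.spec.geometry, self.spec
        nz, ny, nx = spec.grid_shape
        z, y, x = (_axis_coords(n, spec.voxel_size) for n in (nz, ny, nx))
        r = np.hypot(y[:, None], x[None, :])
        shell = (r >= g.rib_shell[0]) & (r <= g.rib_shell[1])
        occ = np.zeros(spec.grid_shape)
        for zi in g.rib_z_positions:
            inz = np.abs(z - zi) <= g.rib_half_thickness
            occ[inz] = np.maximum(occ[inz], shell.astype(float))
        return occ

    # breathing state -----------------------------------------------------
    def air_volume_mm3(self, w: float) -> float:
        spec = self.spec
        return (spec.resting_volume_eff + spec.tidal_volume_eff * float(w)) * 1000.0

    def air_occupancy(self, w: float) -> np.ndarray:
        c = (self.air_volume_mm3(w) / self.v_pair) ** (1.0 / 3.0)
        axes = tuple(a * c for a in self.semiaxes_eff)
        occ = np.zeros(self.spec.grid_shape)
        for ctr in self.spec.geometry.lung_centers():
            occ += ellipsoid_occupancy(self.spec.grid_shape,
                                       self.spec.voxel_size, ctr, axes,
                                       ss=self.ss)
        return np.minimum(occ, 1.0)

    def volume_at(self, w: float) -> np.ndarray:
        """Attenuation volume (1/mm) at breathing amplitude w."""
        return self.mu_base - self.spec.mu_parenchyma * self.air_occupancy(w)

    def ground_truth(self) -> GroundTruth:
        spec = self.spec
        v_exp = spec.resting_volume_eff
        v_insp = v_exp + spec.tidal_volume_eff
        c = (v_insp * 1000.0 / self.v_pair) ** (1.0 / 3.0)
        area = 2.0 * ellipsoid_surface_area(tuple(a * c for a in self.semiaxes_eff))
        return GroundTruth(
            air_volume_insp=v_insp,
            air_volume_exp=v_exp,
            tidal_volume=v_insp - v_exp,
            decay_rate=spec.decay_rate_eff,
            air_ratio=v_insp * 1000.0 / self.v_pair,
            interface_area=area,
            tissue_volume=self.v_pair - v_insp * 1000.0,
        )

    # pipeline helpers -----------------------------------------------------
    def seed_voxels(self):
        """One voxel index (z, y, x) inside each air compartment."""
        spec = self.spec
        nz, ny, nx = spec.grid_shape
        vox = spec.voxel_size
        out = []
        for cz, cy, cx in spec.geometry.lung_centers():
            out.append((int(round(cz / vox)) + nz // 2,
                        int(round(cy / vox)) + ny // 2,
                        int(round(cx / vox)) + nx // 2))
        return out

    def thoracic_mask(self) -> np.ndarray:
        """Conservative lung-bounding mask: the lung envelopes dilated by 1 voxel."""
        from scipy import ndimage

        return ndimage.binary_dilation(self.occ_lung > 0.0, iterations=1)

    def lung_roi_radiograph(self):
        """(z0, x0, z1, x1) box over one lung field in an axis-1 radiograph."""
        spec = self.spec
        nz, _, nx = spec.grid_shape
        vox = spec.voxel_size
        az, _, ax = self.semiaxes_eff
        cz, _, cx = spec.geometry.lung_centers()[1]
        z0 = max(0, int((cz - 0.7 * az) / vox) + nz // 2)
        z1 = min(nz, int((cz + 0.7 * az) / vox) + nz // 2)
        x0 = max(0, int((cx - 0.7 * ax) / vox) + nx // 2)
        x1 = min(nx, int((cx + 0.7 * ax) / vox) + nx // 2)
        return (z0, x0, z1, x1)


# ---------------------------------------------------------------------------
# generators


@dataclass
class VolumeSeries:
    """Time series of attenuation volumes plus the exported ground truth."""

    volumes: np.ndarray  # (n_frames, nz, ny, nx)
    timestamps: np.ndarray
    frame_rate: float
    voxel_size: float
    ground_truth: GroundTruth
    amplitudes: np.ndarray  # true w(t) per frame


def make_breathing_volume_series(
    spec: PhantomSpec, n_frames: int, frame_rate: float,
    supersample: int = 2,
) -> VolumeSeries:
    """Render the phantom at ``n_frames`` consecutive time points."""
    f = spec.breathing_frequency
    if frame_rate <= 2.0 * f:
        raise ValueError(
            f"frame_rate {frame_rate} Hz aliases breathing at {f} Hz "
            "(need frame_rate > 2 * breathing_frequency)")
    if n_frames / frame_rate < 1.0 / f:
        raise ValueError("series must span at least one full breathing cycle")
    phantom = BreathingLungPhantom(spec, supersample=supersample)
    t = np.arange(n_frames) / frame_rate
    w = breathing_waveform(t, f, spec.decay_rate_eff,
                           spec.inspiration_fraction, spec.rise_fraction)
    vols = np.stack([phantom.volume_at(wi) for wi in w])
    return VolumeSeries(volumes=vols, timestamps=t, frame_rate=frame_rate,
                        voxel_size=spec.voxel_size,
                        ground_truth=phantom.ground_truth(), amplitudes=w)


def beer_lambert_project(volume: np.ndarray, voxel_size: float,
                         axis: int = 1, i0: float = 1.0) -> np.ndarray:
    """Transmission image I = I0 exp(-sum mu dx) along one volume axis."""
    if i0 <= 0:
        raise ValueError("i0 must be positive")
    path = volume.sum(axis=axis) * voxel_size
    return i0 * np.exp(-path)


def project_radiographs(
    series: VolumeSeries,
    axis: int = 1,
    i0: float = 1.0e4,
    noise_model: float | str = "none",
    seed: int = 0,
) -> RadiographSequence:
    """Beer-Lambert radiographs of a volume series, optional Poisson noise.

    With a numeric ``noise_model`` the incident intensity is that photon
    count and detected intensities are Poisson draws.
    """
    if noise_model != "none":
        i0 = float(noise_model)
    frames = np.stack([
        beer_lambert_project(v, series.voxel_size, axis=axis, i0=i0)
        for v in series.volumes
    ])
    if noise_model != "none":
        rng = np.random.default_rng(seed)
        frames = rng.poisson(frames).astype(float)
        frames = np.maximum(frames, 0.5)  # keep -log finite
    return RadiographSequence(frames=frames, frame_rate=series.frame_rate,
                              timestamps=series.timestamps)


@dataclass
class GatingTruth:
    """Per-projection truth for validating retrospective gating."""

    amplitudes: np.ndarray
    labels: np.ndarray
    ground_truth: GroundTruth


def make_gated_projection_set(
    spec: PhantomSpec,
    n_angles: int = 400,
    rotation_time: float = 270.0,
    i0: float = 1.0e4,
    state_bins: int | None = 32,
    supersample: int = 2,
) -> tuple[ProjectionSet, GatingTruth]:
    """Rotational projections of the breathing phantom across many breaths.

    Angles are evenly spaced over 360 degrees; each projection is rendered at
    the breathing state of its timestamp.  Breathing amplitudes are quantised
    to ``state_bins`` levels so that projections sharing a state can be
    batched through the slice-wise radon transform (worst-case volume error
    tidal/(2*state_bins)); ``state_bins=None`` renders every projection at
    its exact state.
    """
    if n_angles < 2:
        raise ValueError("need at least two projection angles")
    f = spec.breathing_frequency
    if rotation_time < 10.0 / f:
        raise ValueError("rotation must span at least 10 breathing cycles")
    phantom = BreathingLungPhantom(spec, supersample=supersample)
    angles = 360.0 * np.arange(n_angles) / n_angles
    times = rotation_time * np.arange(n_angles) / n_angles
    static = spec.tidal_volume_eff == 0.0
    if static:
        w = np.zeros(n_angles)
    else:
        w = breathing_waveform(times, f, spec.decay_rate_eff,
                               spec.inspiration_fraction, spec.rise_fraction)
    if state_bins is not None and not static:
        levels = np.linspace(w.min(), w.max(), state_bins)
        w_render = levels[np.argmin(np.abs(w[:, None] - levels[None, :]), axis=1)]
    else:
        w_render = w
    nz = spec.grid_shape[0]
    n_det = spec.grid_shape[1]
    frames = np.empty((n_angles, nz, n_det))
    for level in np.unique(w_render):
        idx = np.flatnonzero(w_render == level)
        vol = phantom.volume_at(level)
        theta = angles[idx]
        for iz in range(nz):
            sino = radon(vol[iz], theta=theta, circle=True)  # (n_det, k)
            frames[idx, iz, :] = (i0 * np.exp(-sino.T * spec.voxel_size))
    if spec.noise_model != "none":
        rng = np.random.default_rng(spec.seed)
        scale = float(spec.noise_model) / i0
        frames = rng.poisson(frames * scale).astype(float) / scale
        frames = np.maximum(frames, 0.5 / scale)
    projset = ProjectionSet(frames=frames, angles=angles, timestamps=times,
                            pixel=spec.voxel_size, i0=i0)
    labels = true_phase_labels(w) if not static else np.asarray(
        [STATIC] * n_angles, dtype=object)
    return projset, GatingTruth(amplitudes=w, labels=labels,
                                ground_truth=phantom.ground_truth())


# ---------------------------------------------------------------------------
# 1-D signal generators


def make_transmission_curve(
    decay_rate: float,
    frequency: float = 0.7,
    duration: float = 10.0,
    sampling_rate: float = 14.0,
    baseline: float = 100.0,
    peak: float = 160.0,
    inspiration_fraction: float = 0.25,
    rise_fraction: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> TransmissionCurve:
    """Synthetic lung-ROI transmission curve with known decay rate.

    ``T(t) = baseline + (peak - baseline) * w(t)`` plus optional white noise.
    The default rise_fraction of 1 gives a pure linear-rise / exponential-
    decay cycle (no end-inspiratory pause), the cleanest oracle for the
    decay-rate estimator.
    """
    t = np.arange(int(round(duration * sampling_rate))) / sampling_rate
    w = breathing_waveform(t, frequency, decay_rate,
                           inspiration_fraction, rise_fraction)
    T = baseline + (peak - baseline) * w
    if noise_sd > 0:
        T = T + np.random.default_rng(seed).normal(0.0, noise_sd, len(T))
    return TransmissionCurve(t=t, T=T)


def _highpass_noise(n: int, fs: float, cutoff: float, amp: float,
                    rng: np.random.Generator) -> np.ndarray:
    from scipy.signal import butter, sosfiltfilt

    x = rng.normal(0.0, 1.0, n)
    sos = butter(4, cutoff, btype="highpass", fs=fs, output="sos")
    y = sosfiltfilt(sos, x)
    s = y.std()
    return amp * y / s if s > 0 else y


def make_wbp_trace(
    tidal_volume: float,
    frequency: float = 0.7,
    duration: float = 30.0,
    sampling_rate: float = 1000.0,
    flow_calibration: float = 1.0,  # signal units per (ml/s)
    drift_amp: float = 0.0,
    noise_amp: float = 0.0,
    seed: int = 0,
) -> tuple[PressureTrace, float]:
    """Flow-proportional chamber-pressure trace with drift and sensor noise.

    The flow component is ``A sin(2 pi f t)`` with ``A = TV * pi * f *
    flow_calibration`` so that the positive half-cycle integrates exactly to
    ``TV * flow_calibration``.  Drift is a sum of sub-0.1 Hz sinusoids of
    amplitude ``drift_amp``; noise is >30 Hz high-passed white noise with
    standard deviation ``noise_amp``.  Returns the trace (whose chamber
    calibration converts integral units back to ml) and the true TV.
    """
    if duration < 3.0 / frequency:
        raise ValueError("duration must cover at least 3 breathing cycles")
    if not 0.5 < frequency < 20.0:
        warnings.warn("breathing frequency outside the 0.5-20 Hz passband; "
                      "the filtered signal will be attenuated by design")
    rng = np.random.default_rng(seed)
    n = int(round(duration * sampling_rate))
    t = np.arange(n) / sampling_rate
    amp = tidal_volume * np.pi * frequency * flow_calibration
    p = amp * np.sin(2.0 * np.pi * frequency * t)
    if drift_amp > 0:
        p = p + drift_amp * np.sin(2.0 * np.pi * 0.05 * t + rng.uniform(0, 2 * np.pi))
        p = p + 0.5 * drift_amp * np.sin(2.0 * np.pi * 0.02 * t + rng.uniform(0, 2 * np.pi))
    if noise_amp > 0:
        p = p + _highpass_noise(n, sampling_rate, 35.0, noise_amp, rng)
    chamber = ChamberConfig(calibration=1.0 / flow_calibration)
    return (PressureTrace(t=t, p=p, sampling_rate=sampling_rate, chamber=chamber),
            tidal_volume)


# ---------------------------------------------------------------------------
# porous (alveolar) cubes for morphometry


def make_porous_cube(
    side_mm: float,
    voxel_mm: float,
    sphere_radii,
    sphere_centers,
    air_value: float = 0.0,
    tissue_value: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    supersample: int = 2,
) -> tuple[np.ndarray, GroundTruth]:
    """Air spheres in a tissue cube with fully analytic morphometry truth.

    Spheres must lie inside the cube and be pairwise non-overlapping, so that
    air ratio, interface area and tissue volume have closed forms.
    Intensities: air low, tissue high, with supersampled partial volume at
    the interfaces.  Returns (intensity volume, GroundTruth).
    """
    radii = np.asarray(sphere_radii, dtype=float)
    centers = np.asarray(sphere_centers, dtype=float).reshape(-1, 3)
    if len(radii) != len(centers):
        raise ValueError("one radius per center required")
    for r, c in zip(radii, centers):
        if np.any(c - r < 0) or np.any(c + r > side_mm):
            raise ValueError("sphere extends outside the cube")
    for i in range(len(radii)):
        for j in range(i + 1, len(radii)):
            if np.linalg.norm(centers[i] - centers[j]) < radii[i] + radii[j]:
                raise ValueError(f"spheres {i} and {j} overlap")
    n = int(round(side_mm / voxel_mm))
    occ = np.zeros((n, n, n))
    for r, c in zip(radii, centers):
        # cube coordinates run [0, side]; occupancy helper is centre-based
        occ += ellipsoid_occupancy(
            (n, n, n), voxel_mm,
            tuple(ci - (n // 2 + 0.5) * voxel_mm for ci in c),
            (r, r, r), ss=supersample)
    occ = np.minimum(occ, 1.0)
    vol = tissue_value - (tissue_value - air_value) * occ
    if noise_sd > 0:
        vol = vol + np.random.default_rng(seed).normal(0.0, noise_sd, vol.shape)
    v_air = float(np.sum(4.0 / 3.0 * np.pi * radii**3))
    v_cube = side_mm**3
    gt = GroundTruth(
        air_volume_insp=v_air / 1000.0, air_volume_exp=v_air / 1000.0,
        tidal_volume=0.0, decay_rate=0.0,
        air_ratio=v_air / v_cube,
        interface_area=float(np.sum(4.0 * np.pi * radii**2)),
        tissue_volume=v_cube - v_air,
    )
    return vol, gt


def pack_spheres(
    side_mm: float,
    radii,
    min_gap: float = 0.01,
    seed: int = 0,
    max_attempts: int = 50000,
) -> np.ndarray:
    """Sequential rejection packing of non-overlapping spheres in a cube."""
    rng = np.random.default_rng(seed)
    radii = np.asarray(radii, dtype=float)
    # place the largest spheres first: late large placements are what jam
    order = np.argsort(radii)[::-1]
    centers = np.empty((len(radii), 3))
    placed_r: list[float] = []
    placed_c: list[np.ndarray] = []
    for i in order:
        r = radii[i]
        for _ in range(max_attempts):
            c = rng.uniform(r + min_gap, side_mm - r - min_gap, size=3)
            if all(np.linalg.norm(c - cj) >= r + rj + min_gap
                   for cj, rj in zip(placed_c, placed_r)):
                centers[i] = c
                placed_c.append(c)
                placed_r.append(r)
                break
        else:
            raise ValueError(
                f"could not place sphere {i} (r={r:.3f}) of {len(radii)}")
    return centers


def make_alveolar_cube(
    severity: float,
    side_mm: float = 1.75,
    voxel_mm: float | None = None,
    grid_n: int = 96,
    seed: int = 0,
    base_count: int = 60,
    base_radius: float = 0.15,
    noise_sd: float = 0.02,
) -> tuple[np.ndarray, GroundTruth]:
    """Severity-driven porous cube: fibrosis removes and shrinks air spaces.

    Sphere count scales as (1 - 0.55 s) and mean radius as (1 - 0.35 s), so
    both the air ratio and the interface area per tissue volume fall
    monotonically with severity - the morphometric fingerprint of fibrotic
    consolidation (absolute values are not calibrated to real lungs).
    """
    if voxel_mm is None:
        voxel_mm = side_mm / grid_n
    rng = np.random.default_rng(seed)
    n_spheres = max(3, int(round(base_count * (1.0 - 0.55 * severity))))
    mean_r = base_radius * (1.0 - 0.35 * severity)
    radii = np.clip(mean_r * np.exp(rng.normal(0.0, 0.15, n_spheres)),
                    0.04, 0.3 * side_mm)
    centers = pack_spheres(side_mm, radii, seed=seed + 1)
    return make_porous_cube(side_mm, voxel_mm, radii, centers,
                            noise_sd=noise_sd, seed=seed + 2)


# ---------------------------------------------------------------------------
# Fresnel forward model for phase retrieval


def make_propagated_projection(
    thickness_mm: np.ndarray,
    energy_kev: float,
    distance_mm: float,
    pixel_mm: float,
    delta: float,
    beta: float,
) -> np.ndarray:
    """Fresnel free-space propagation of a homogeneous object's exit wave.

    The object transmission is ``exp(-mu t / 2 - i 2 pi delta t / lambda)``
    with ``mu = 4 pi beta / lambda``; propagation multiplies its spectrum by
    the paraxial transfer function ``exp(-i pi lambda z |f|^2)``.  Returns
    the propagated intensity (flat field = 1).  At distance 0 this reduces to
    pure absorption ``exp(-mu t)``.
    """
    from .srct import wavelength_mm

    t = np.asarray(thickness_mm, dtype=float)
    if np.any(t < 0):
        raise ValueError("thickness map must be non-negative")
    if distance_mm < 0:
        raise ValueError("distance must be >= 0")
    lam = wavelength_mm(energy_kev)
    n_min = min(t.shape)
    if distance_mm > n_min * pixel_mm**2 / lam:
        raise ValueError("propagator band limit violated: reduce distance or "
                         "refine sampling")
    mu = 4.0 * np.pi * beta / lam
    field = np.exp(-mu * t / 2.0 - 1j * 2.0 * np.pi * delta * t / lam)
    if distance_mm == 0:
        return np.abs(field) ** 2
    fy = np.fft.fftfreq(t.shape[0], d=pixel_mm)
    fx = np.fft.fftfreq(t.shape[1], d=pixel_mm)
    f2 = fy[:, None] ** 2 + fx[None, :] ** 2
    H = np.exp(-1j * np.pi * lam * distance_mm * f2)
    out = np.fft.ifft2(np.fft.fft2(field) * H)
    return np.abs(out) ** 2
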