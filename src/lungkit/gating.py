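"""Retrospective respiratory gating, phase-resolved reconstruction, volumetry.

A rotational microCT scan of a freely breathing animal spans many breaths.
The breathing motion is recovered *from the projections themselves*: the mean
attenuation along one detector row near the diaphragm oscillates with the
breath, and after subtracting a moving-average baseline (which removes the
slow angular variation of the anatomy across the gantry rotation) the
residual is a usable respiratory surrogate.  Projections whose surrogate
amplitude falls in the top/bottom percentile bands are pooled into
end-inspiration / end-expiration subsets and reconstructed separately with
angle-spacing-weighted filtered backprojection.  The air-filled lung is then
segmented by region growing and its volume is the voxel count times the voxel
volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from scipy.signal import periodogram
from skimage.morphology import ball

from .recon import fbp_volume

INSPIRATION = "inspiration"
EXPIRATION = "expiration"
DISCARDED = "discarded"
STATIC = "static"


@dataclass
class ProjectionSet:
    """Rotational projections with per-frame angle and timestamp.

    frames: (n_proj, n_rows, n_det) transmission images (detector counts);
    angles: degrees in [0, 360); timestamps: seconds; pixel: detector pixel
    size in mm (isotropic); i0: unattenuated intensity used for -log
    normalisation.
    """

    frames: np.ndarray
    angles: np.ndarray
    timestamps: np.ndarray
    pixel: float
    i0: float = 1.0

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        self.angles = np.asarray(self.angles, dtype=float)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (n_proj, n_rows, n_det)")
        if not (len(self.frames) == len(self.angles) == len(self.timestamps)):
            raise ValueError("frames, angles and timestamps must have equal length")
        if np.any(self.angles < 0) or np.any(self.angles >= 360):
            raise ValueError("angles must lie in [0, 360)")
        if self.pixel <= 0:
            raise ValueError("pixel size must be positive")


@dataclass
class BreathingSignal:
    """Respiratory surrogate: raw attenuation trace and baseline-corrected residual."""

    t: np.ndarray
    raw: np.ndarray
    corrected: np.ndarray


@dataclass
class PhaseAssignment:
    """Per-projection phase label: inspiration / expiration / discarded."""

    labels: np.ndarray  # array of str

    def indices(self, phase: str) -> np.ndarray:
        return np.flatnonzero(self.labels == phase)


@dataclass
class ReconVolume:
    """Reconstructed attenuation volume (1/mm) with isotropic voxel size (mm)."""

    voxels: np.ndarray
    voxel_size: float
    phase: str = ""

    def __post_init__(self):
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")


@dataclass
class LungMask:
    """Binary air-compartment mask sharing the geometry of its volume."""

    voxels: np.ndarray
    voxel_size: float

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=bool)
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")


def breathing_signal_from_projections(
    projset: ProjectionSet,
    line_row: int,
    window_periods: float = 3.0,
    frequency: float | None = None,
) -> BreathingSignal:
    """Extract the respiratory surrogate from one detector row.

    raw[i] is the mean of -log(frame_i / i0) along ``line_row``; the
    correction subtracts a moving average whose window spans
    ``window_periods`` breathing periods.  When ``frequency`` is None the
    dominant frequency of the raw trace (above the rotation frequency) is
    estimated from its periodogram.
    """
    n_rows = projset.frames.shape[1]
    if not 0 <= line_row < n_rows:
        raise ValueError(f"line_row {line_row} outside detector rows [0, {n_rows})")
    if np.any(projset.frames[:, line_row, :] <= 0) or projset.i0 <= 0:
        raise ValueError("non-positive intensities cannot be log-normalised")
    raw = -np.log(projset.frames[:, line_row, :] / projset.i0).mean(axis=1)
    t = projset.timestamps
    dt = float(np.median(np.diff(t))) if len(t) > 1 else 1.0
    if frequency is None:
        frequency = _dominant_frequency(raw, 1.0 / dt, t[-1] - t[0])
    win = max(3, int(round(window_periods / (frequency * dt))) | 1)  # odd
    baseline = _moving_average(raw, win)
    return BreathingSignal(t=t, raw=raw, corrected=raw - baseline)


def _moving_average(x: np.ndarray, win: int) -> np.ndarray:
    pad = win // 2
    xp = np.pad(x, pad, mode="reflect")
    kern = np.ones(win) / win
    return np.convolve(xp, kern, mode="valid")


def _dominant_frequency(x: np.ndarray, fs: float, span: float) -> float:
    # ignore trends slower than ~3 cycles over the whole record
    f, p = periodogram(x - x.mean(), fs=fs)
    f_lo = 3.0 / max(span, 1e-9)
    band = f > f_lo
    if not band.any() or p[band].max() <= 0:
        return max(f_lo, fs / 10.0)
    return float(f[band][np.argmax(p[band])])


def as_inspiration_positive(signal: BreathingSignal) -> BreathingSignal:
    """Flip the surrogate so larger values mean more air in the beam path.

    The raw surrogate is an *attenuation*, which falls during inspiration;
    percentile gating expects an inspiration-positive signal.
    """
    return replace(signal, corrected=-signal.corrected)


def assign_phases(
    signal: BreathingSignal,
    insp_q: float = 80.0,
    exp_q: float = 20.0,
) -> PhaseAssignment:
    """Amplitude gating: label each sample by percentile of the corrected signal.

    corrected >= percentile(insp_q) -> inspiration;
    corrected <= percentile(exp_q) -> expiration; the rest are discarded.
    """
    if exp_q > insp_q:
        raise ValueError("exp_q must not exceed insp_q")
    c = signal.corrected
    if np.ptp(c) == 0:
        raise ValueError("degenerate (zero-variance) breathing signal")
    hi = np.percentile(c, insp_q)
    lo = np.percentile(c, exp_q)
    labels = np.full(len(c), DISCARDED, dtype=object)
    labels[c >= hi] = INSPIRATION
    labels[c <= lo] = EXPIRATION
    return PhaseAssignment(labels=np.asarray(labels))


def reconstruct_phase(
    projset: ProjectionSet,
    assignment: PhaseAssignment,
    phase: str,
    min_angles: int = 20,
) -> ReconVolume:
    """Filtered backprojection of the projections retained for one phase.

    Each axial slice (detector row) is reconstructed independently over the
    retained, generally irregular, angle subset with angular-spacing weights.
    """
    idx = assignment.indices(phase)
    if len(idx) < min_angles:
        raise ValueError(
            f"only {len(idx)} projections retained for phase {phase!r}, "
            f"need >= {min_angles}"
        )
    frames = projset.frames[idx]
    line_integrals = -np.log(frames / projset.i0)
    # (n_proj, n_rows, n_det) -> (n_rows, n_det, n_proj)
    sinograms = np.moveaxis(line_integrals, 0, -1)
    vol = fbp_volume(sinograms, projset.angles[idx], projset.pixel)
    return ReconVolume(voxels=vol, voxel_size=projset.pixel, phase=phase)


def subtract_background_slice(volume: ReconVolume, ref_slice: int) -> ReconVolume:
    """Subtract one reference axial slice from every slice (uniform background)."""
    if not 0 <= ref_slice < volume.voxels.shape[0]:
        raise ValueError("ref_slice index out of range")
    out = volume.voxels - volume.voxels[ref_slice]
    return ReconVolume(voxels=out, voxel_size=volume.voxel_size, phase=volume.phase)


def smooth_3d(volume: ReconVolume, sigma: float) -> ReconVolume:
    """3-D Gaussian smoothing (reflective borders); sigma in voxels, 0 = identity."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return volume
    out = ndimage.gaussian_filter(volume.voxels, sigma=sigma, mode="reflect")
    return ReconVolume(voxels=out, voxel_size=volume.voxel_size, phase=volume.phase)


def _midpoint_threshold(values: np.ndarray, bins: int = 128,
                        smooth_bins: float = 2.0,
                        min_separation: float = 0.2) -> float:
    """Midpoint between the two dominant modes of the intensity histogram.

    The histogram is lightly smoothed; the second mode must lie at least
    ``min_separation`` of the intensity range away from the first and be
    separated from it by a genuine dip, otherwise the histogram is declared
    unimodal and the caller should supply a fixed threshold.
    """
    hist, edges = np.histogram(values, bins=bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    h = ndimage.gaussian_filter1d(hist.astype(float), smooth_bins)
    i1 = int(np.argmax(h))
    sep = max(3, int(min_separation * bins))
    cand = np.flatnonzero(np.abs(np.arange(bins) - i1) >= sep)
    if len(cand) == 0:
        raise ValueError("histogram is not bimodal; supply a fixed threshold")
    i2 = int(cand[np.argmax(h[cand])])
    lo, hi = sorted((i1, i2))
    dip = h[lo:hi + 1].min()
    if dip > 0.9 * min(h[i1], h[i2]):
        raise ValueError("histogram is not bimodal; supply a fixed threshold")
    return float(0.5 * (centers[i1] + centers[i2]))


def segment_lung(
    volume: ReconVolume,
    seed_voxel,
    threshold_policy="midpoint",
    r_close: int = 2,
    thoracic_mask: np.ndarray | None = None,
) -> LungMask:
    """Region-grow the air compartment from seed voxel(s), then close gaps.

    seed_voxel: one (z, y, x) triple or a list of them (one per lung field;
    the grown regions are unioned).  threshold_policy: "midpoint" (midpoint
    between the air and tissue modes of the histogram, restricted to
    ``thoracic_mask`` when given) or a fixed numeric threshold.  Voxels with
    intensity <= threshold that are 26-connected to a seed are kept, then a
    morphological closing with a ball of radius ``r_close`` voxels fills
    vessel-sized gaps.  Voxels outside ``thoracic_mask`` are excluded.
    """
    vox = volume.voxels
    seeds = np.atleast_2d(np.asarray(seed_voxel, dtype=int))
    if isinstance(threshold_policy, str):
        if threshold_policy != "midpoint":
            raise ValueError(f"unknown threshold policy {threshold_policy!r}")
        vals = vox[thoracic_mask] if thoracic_mask is not None else vox.ravel()
        threshold = _midpoint_threshold(vals)
    else:
        threshold = float(threshold_policy)
    air = vox <= threshold
    if thoracic_mask is not None:
        air &= thoracic_mask
    structure = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity
    labels, _ = ndimage.label(air, structure=structure)
    mask = np.zeros_like(air)
    for z, y, x in seeds:
        if not air[z, y, x]:
            raise ValueError(f"seed {(z, y, x)} is above the threshold {threshold:.4g}")
        mask |= labels == labels[z, y, x]
    if r_close > 0:
        mask = ndimage.binary_closing(mask, structure=ball(r_close))
        if thoracic_mask is not None:
            mask &= thoracic_mask
    if not mask.any():
        raise ValueError("empty segmentation")
    return LungMask(voxels=mask, voxel_size=volume.voxel_size)


def lung_volume(mask: LungMask) -> float:
    """Segmented air volume in ml (voxel count x voxel volume; 1 ml = 1000 mm^3)."""
    return float(mask.voxels.sum()) * mask.voxel_size**3 / 1000.0
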