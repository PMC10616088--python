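"""X-ray based lung function (XLF) metrics from planar radiograph time series.

A radiograph sequence of a freely breathing animal is reduced to a 1-D
transmission curve over a lung region of interest.  Peak transmission marks
end-inspiration; during expiration the transmission relaxes toward a baseline
roughly exponentially, and the rate constant of that relaxation (the *decay
rate*, 1/s) tracks the elastic recoil of the lung.  Fibrotic stiffening slows
passive expiration and lowers the decay rate, lowers the inspiratory peak and
raises the expiratory baseline; these are the quantities computed here,
together with the per-cycle area under the curve (AUC).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import find_peaks


@dataclass
class RadiographSequence:
    """Time-ordered planar transmission images at a fixed frame rate.

    frames: array (n_frames, ny, nx), detector intensity (transmission) units.
    frame_rate: Hz. timestamps: seconds, one per frame.
    """

    frames: np.ndarray
    frame_rate: float
    timestamps: np.ndarray = field(default=None)

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (n_frames, ny, nx)")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.timestamps is None:
            self.timestamps = np.arange(len(self.frames)) / self.frame_rate
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if len(self.timestamps) != len(self.frames):
            raise ValueError("one timestamp per frame required")


@dataclass
class TransmissionCurve:
    """Mean transmission in a lung ROI versus time."""

    t: np.ndarray
    T: np.ndarray

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.T = np.asarray(self.T, dtype=float)
        if self.t.shape != self.T.shape:
            raise ValueError("t and T must have equal length")
        if len(self.t) > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("t must be strictly increasing")


@dataclass
class BreathCycle:
    """One breath delimited by an inspiratory peak and the next cycle start."""

    peak_index: int
    end_index: int
    baseline_level: float
    peak_level: float

    def __post_init__(self):
        if self.peak_index >= self.end_index:
            raise ValueError("peak_index must precede end_index")
        if self.peak_level < self.baseline_level:
            raise ValueError("peak_level must be >= baseline_level")


@dataclass
class XLFMetrics:
    """Per-animal XLF summary: means +/- SD over valid breath cycles."""

    decay_rate: float
    decay_rate_sd: float
    peak_transmission: float
    peak_transmission_sd: float
    expiratory_baseline: float
    expiratory_baseline_sd: float
    auc: float
    auc_sd: float
    n_cycles: int
    n_invalid: int = 0


def extract_transmission_curve(seq: RadiographSequence, roi) -> TransmissionCurve:
    """Mean pixel value of each frame inside a rectangular ROI.

    roi: (y0, x0, y1, x1), 0-based, half-open.
    """
    y0, x0, y1, x1 = roi
    ny, nx = seq.frames.shape[1:]
    if not (0 <= y0 < y1 <= ny and 0 <= x0 < x1 <= nx):
        raise ValueError(f"ROI {roi} outside frame bounds {(ny, nx)} or empty")
    T = seq.frames[:, y0:y1, x0:x1].mean(axis=(1, 2))
    return TransmissionCurve(t=seq.timestamps, T=T)


def detect_cycles(
    curve: TransmissionCurve,
    f_min: float = 0.4,
    f_max: float = 1.5,
    baseline_percentile: float = 10.0,
    guard_samples: int = 1,
) -> list[BreathCycle]:
    """Find breath cycles as prominent transmission peaks in a frequency band.

    Peaks must be separated by at least 1/f_max; a cycle runs from one peak to
    the sample before the next peak (minus a small guard).  The expiratory
    baseline of a cycle is a low percentile (default 10th) of the transmission
    within the final third of the cycle.  Returns [] with a warning when the
    curve has no peaks in band.
    """
    T, t = curve.T, curve.t
    if len(t) < 3:
        return []
    dt = float(np.median(np.diff(t)))
    span = t[-1] - t[0]
    if span < 2.0 / f_min:
        raise ValueError(f"curve spans {span:.2f}s < 2/f_min = {2 / f_min:.2f}s")
    amp = np.ptp(T)
    if amp == 0:
        warnings.warn("flat transmission curve: no breath cycles detected")
        return []
    min_dist = max(1, int(round(1.0 / (f_max * dt))))
    peaks, _ = find_peaks(T, distance=min_dist, prominence=0.25 * amp)
    if len(peaks) == 0:
        warnings.warn("no transmission peaks found in band")
        return []
    # close the last cycle at the end of the record
    bounds = list(peaks[1:]) + [len(T)]
    cycles = []
    for p, nxt in zip(peaks, bounds):
        end = nxt - guard_samples
        if end - p < 3:
            continue
        seg = T[p:end]
        tail = seg[2 * len(seg) // 3:]
        base = float(np.percentile(tail, baseline_percentile)) if len(tail) else float(seg.min())
        cycles.append(
            BreathCycle(peak_index=int(p), end_index=int(end),
                        baseline_level=min(base, float(T[p])),
                        peak_level=float(T[p]))
        )
    return cycles


def _expo(t, B, A, k):
    return B + A * np.exp(-k * t)


def fit_decay_rate(
    curve: TransmissionCurve,
    cycle: BreathCycle,
    baseline_tolerance: float = 0.05,
    plateau_tolerance: float = 0.01,
    refine: bool = True,
) -> float:
    """Expiratory decay rate (1/s) of one breath cycle.

    Fits ``T(t) = B + (P - B) exp(-k (t - t_peak))`` on the expiration limb.
    The fit window starts at the inspiratory peak (skipping any end-inspiratory
    plateau, defined as samples within ``plateau_tolerance`` of the peak
    amplitude) and ends where the transmission first falls within
    ``baseline_tolerance`` (fraction of the peak-baseline amplitude) of the
    cycle baseline.  The initial estimate comes from log-linear regression on
    the baseline-subtracted signal; by default it is refined by nonlinear
    least squares with the baseline free, which makes the noiseless case exact
    and removes the bias of the percentile baseline estimate.

    Raises ValueError for windows that are too short or not decreasing overall
    (the caller should treat that cycle as invalid and exclude it).
    """
    T, t = curve.T, curve.t
    P, B = cycle.peak_level, cycle.baseline_level
    amp = P - B
    if amp <= 0:
        raise ValueError("degenerate cycle: zero amplitude")
    i0 = cycle.peak_index
    # skip an end-inspiratory plateau, if any
    while i0 + 1 < cycle.end_index and T[i0 + 1] >= P - plateau_tolerance * amp:
        i0 += 1
    # window ends when T first comes within baseline_tolerance of the baseline
    i1 = cycle.end_index
    for i in range(i0 + 1, cycle.end_index):
        if T[i] <= B + baseline_tolerance * amp:
            i1 = i + 1
            break
    tw = t[i0:i1] - t[i0]
    Tw = T[i0:i1]
    if len(tw) < 4:
        raise ValueError("expiration window has fewer than 4 samples")
    if Tw[-1] >= Tw[0]:
        raise ValueError("expiration window is not decreasing")
    # log-linear initialization on baseline-subtracted samples
    pos = Tw - B > 1e-3 * amp
    if pos.sum() < 3:
        raise ValueError("too few samples above baseline")
    slope, intercept = np.polyfit(tw[pos], np.log(Tw[pos] - B), 1)
    k0 = -slope
    if k0 <= 0:
        raise ValueError("non-decaying expiration")
    if not refine:
        return float(k0)
    try:
        popt, _ = curve_fit(
            _expo, tw, Tw, p0=[B, np.exp(intercept), k0],
            maxfev=10000,
        )
    except RuntimeError as err:  # pragma: no cover - pathological windows
        raise ValueError(f"decay fit failed: {err}") from err
    k = float(popt[2])
    if k <= 0:
        raise ValueError("refined decay rate non-positive")
    return k


def compute_auc(curve: TransmissionCurve, cycle: BreathCycle,
                baseline_relative: bool = False) -> float:
    """Trapezoidal area under the transmission curve over one cycle.

    By default the absolute area above zero (the "total AUC" convention);
    with ``baseline_relative=True`` the cycle baseline is subtracted first.
    """
    sl = slice(cycle.peak_index, cycle.end_index)
    T = curve.T[sl] - (cycle.baseline_level if baseline_relative else 0.0)
    return float(np.trapezoid(T, curve.t[sl]))


def summarize_xlf(curve: TransmissionCurve, cycles: list[BreathCycle],
                  **fit_kwargs) -> XLFMetrics:
    """Fit every cycle and reduce to per-animal means +/- SD.

    Cycles whose expiration limb cannot be fit (non-monotone, too short) are
    excluded, never imputed; their count is reported in ``n_invalid``.
    """
    ks, peaks, bases, aucs = [], [], [], []
    n_invalid = 0
    for cyc in cycles:
        try:
            k = fit_decay_rate(curve, cyc, **fit_kwargs)
        except ValueError:
            n_invalid += 1
            continue
        ks.append(k)
        peaks.append(cyc.peak_level)
        bases.append(cyc.baseline_level)
        aucs.append(compute_auc(curve, cyc))
    if not ks:
        raise ValueError("no valid breath cycles")
    arr = lambda v: (float(np.mean(v)), float(np.std(v)))
    km, ks_ = arr(ks)
    pm, ps = arr(peaks)
    bm, bs = arr(bases)
    am, asd = arr(aucs)
    return XLFMetrics(
        decay_rate=km, decay_rate_sd=ks_,
        peak_transmission=pm, peak_transmission_sd=ps,
        expiratory_baseline=bm, expiratory_baseline_sd=bs,
        auc=am, auc_sd=asd,
        n_cycles=len(ks), n_invalid=n_invalid,
    )
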