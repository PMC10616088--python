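"""Whole-body plethysmography (WBP) signal processing.

The chamber pressure difference is proportional to airflow.  After zero-phase
band-pass filtering (0.5-20 Hz by default, removing bias flow / drift below
and sensor noise above the breathing band) the signal is integrated with a
*reset each cycle* rule: the running integral restarts whenever the flow
signal crosses zero going positive, and the tidal volume of a cycle is the
calibration factor times the maximum of the running integral within that
cycle (the inspiratory excursion).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.signal import butter, sosfiltfilt


@dataclass
class ChamberConfig:
    """Plethysmograph geometry and recording conditions.

    calibration: ml of volume per integrated signal unit (signal x s).
    Temperature / humidity are recorded but no correction is applied.
    """

    recording_volume_ml: float = 220.0
    reference_volume_ml: float = 50.0
    calibration: float = 1.0
    temperature_c: float = 22.0
    humidity_pct: float = 45.0


@dataclass
class PressureTrace:
    """Uniformly sampled differential-pressure recording."""

    t: np.ndarray
    p: np.ndarray
    sampling_rate: float
    chamber: ChamberConfig = field(default_factory=ChamberConfig)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        if self.t.shape != self.p.shape:
            raise ValueError("t and p must have equal length")
        if self.sampling_rate < 100.0:
            raise ValueError("sampling_rate must be >= 100 Hz")
        dt = np.diff(self.t)
        if len(dt) and not np.allclose(dt, 1.0 / self.sampling_rate, rtol=1e-6):
            raise ValueError("t must be uniform at sampling_rate")


@dataclass
class TidalVolumeSeries:
    """Per-cycle tidal volumes (ml if calibrated), cycle starts, mean rate."""

    tv: np.ndarray
    tv_raw: np.ndarray  # integral units, before calibration
    cycle_starts: np.ndarray  # s
    breathing_rate: float  # Hz

    def __post_init__(self):
        if np.any(self.tv < 0):
            raise ValueError("tidal volumes must be non-negative")
        if len(self.cycle_starts) > 1 and not np.all(np.diff(self.cycle_starts) > 0):
            raise ValueError("cycle starts must be increasing")


def bandpass(
    trace: PressureTrace,
    f_lo: float = 0.5,
    f_hi: float = 20.0,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass of the pressure signal.

    Forward-backward filtering doubles the effective order and cancels the
    phase delay, so in-band components keep their timing; DC and >40 Hz
    content is attenuated by well over 20 dB.
    """
    nyq = trace.sampling_rate / 2.0
    if not 0 < f_lo < f_hi < nyq:
        raise ValueError(f"band ({f_lo}, {f_hi}) Hz outside (0, {nyq}) Hz")
    sos = butter(order, [f_lo, f_hi], btype="bandpass", fs=trace.sampling_rate,
                 output="sos")
    # the low corner has a ~1/f_lo impulse response; pad accordingly so the
    # first and last breaths are not distorted by edge transients
    padlen = min(len(trace.p) - 1, int(3.0 * trace.sampling_rate / f_lo))
    return sosfiltfilt(sos, trace.p, padlen=padlen)


def _positive_crossings(x: np.ndarray, hyst: float) -> np.ndarray:
    """Indices where x crosses from below -hyst to above +hyst (state machine)."""
    state = np.zeros(len(x), dtype=np.int8)  # +1 above, -1 below, 0 inside band
    state[x > hyst] = 1
    state[x < -hyst] = -1
    # forward-fill the last decided state so band chatter is ignored
    idx = np.arange(len(x))
    decided = state != 0
    if not decided.any():
        return np.array([], dtype=int)
    last = np.maximum.accumulate(np.where(decided, idx, -1))
    filled = np.where(last >= 0, state[np.maximum(last, 0)], 0)
    ups = np.flatnonzero((filled[1:] == 1) & (filled[:-1] == -1)) + 1
    return ups


def integrate_reset_cycles(
    trace: PressureTrace,
    signal: np.ndarray | None = None,
    hysteresis_sd: float = 0.02,
) -> TidalVolumeSeries:
    """Cycle-reset integration of the (band-passed) flow-proportional signal.

    Cycles are delimited by positive-going zero crossings, detected with a
    hysteresis band of ``hysteresis_sd`` signal standard deviations to
    suppress chatter.  Within each cycle the signal is integrated with the
    trapezoidal rule; the tidal volume is the calibration factor times the
    cycle maximum of the running integral.
    """
    x = bandpass(trace) if signal is None else np.asarray(signal, dtype=float)
    h = hysteresis_sd * float(np.std(x))
    ups = _positive_crossings(x, h)
    if len(ups) < 2:
        raise ValueError("fewer than two positive-going zero crossings")
    tv_raw, starts = [], []
    for a, b in zip(ups[:-1], ups[1:]):
        run = cumulative_trapezoid(x[a:b], trace.t[a:b], initial=0.0)
        tv_raw.append(max(run.max(), 0.0))
        starts.append(trace.t[a])
    tv_raw = np.asarray(tv_raw)
    starts = np.asarray(starts)
    rate = (len(ups) - 1) / (trace.t[ups[-1]] - trace.t[ups[0]])
    cal = trace.chamber.calibration
    return TidalVolumeSeries(tv=cal * tv_raw, tv_raw=tv_raw,
                             cycle_starts=starts, breathing_rate=float(rate))


@dataclass
class WBPSummary:
    tv_mean: float
    tv_sd: float
    tv_raw_mean: float
    breathing_rate: float
    n_cycles: int
    n_outliers: int


def summarize_wbp(series: TidalVolumeSeries, min_cycles: int = 5) -> WBPSummary:
    """Robust per-recording summary: cycles outside median +/- 3 MAD excluded."""
    tv = series.tv
    if len(tv) < min_cycles:
        raise ValueError(f"only {len(tv)} cycles, need >= {min_cycles}")
    med = np.median(tv)
    mad = np.median(np.abs(tv - med))
    keep = np.abs(tv - med) <= 3.0 * max(mad, 1e-12 * max(med, 1.0)) if mad > 0 \
        else np.ones(len(tv), dtype=bool)
    kept = tv[keep]
    return WBPSummary(
        tv_mean=float(kept.mean()),
        tv_sd=float(kept.std()),
        tv_raw_mean=float(series.tv_raw[keep].mean()),
        breathing_rate=series.breathing_rate,
        n_cycles=int(keep.sum()),
        n_outliers=int((~keep).sum()),
    )


def calibration_from_injection(
    trace: PressureTrace, injected_volume_ml: float
) -> float:
    """Calibration factor from a known-volume injection recording.

    The injection appears as one flow excursion; the factor maps its
    integrated signal to the known volume.  The trace is only
    baseline-corrected (median subtraction), not band-passed: a controlled
    injection is a one-shot transient that the breathing band-pass would
    distort.
    """
    x = trace.p - np.median(trace.p)
    run = cumulative_trapezoid(np.abs(x), trace.t, initial=0.0)
    total = run[-1] / 2.0  # in-and-out counted twice
    if total <= 0:
        raise ValueError("no signal excursion in calibration trace")
    return injected_volume_ml / total
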