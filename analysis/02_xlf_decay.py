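"""X-ray lung function on single phantoms across fibrosis severities.

Renders radiograph sequences of one synthetic animal per severity level,
extracts the lung-ROI transmission curve, detects breath cycles and fits the
expiratory decay rate.  Shows that the fitted rate, the inspiratory peak and
the AUC all fall monotonically with severity while the expiratory
transmission baseline falls (equivalently: the attenuation baseline rises).

Writes results/xlf_severity.csv.
"""

from pathlib import Path

import pandas as pd

from lungkit import xlf
from lungkit.cohort import StudyScale, xlf_session
from lungkit.phantom import PhantomSpec

OUT = Path(__file__).resolve().parents[1] / "results"


def main():
    OUT.mkdir(exist_ok=True)
    scale = StudyScale()
    rows = []
    for sev in (0.0, 0.25, 0.5, 0.75, 1.0):
        spec = PhantomSpec.with_grid(48, severity=sev, seed=11)
        m = xlf_session(spec, scale)
        rows.append({
            "severity": sev,
            "true_decay_rate": spec.decay_rate_eff,
            "fitted_decay_rate": m.decay_rate,
            "decay_rate_sd": m.decay_rate_sd,
            "peak_transmission": m.peak_transmission,
            "expiratory_baseline": m.expiratory_baseline,
            "auc": m.auc,
            "n_cycles": m.n_cycles,
        })
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "xlf_severity.csv", index=False)
    print(df.round(3).to_string(index=False))
    print("\nFitted decay rate tracks the ground-truth rate monotonically; "
          "the absolute offset\nreflects the nonlinear mapping from air "
          "volume to transmission, which compresses\nthe effective rate "
          "(directional claims only).")


if __name__ == "__main__":
    main()
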