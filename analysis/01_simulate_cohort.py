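"""Simulate the full synthetic study and write its tidy metric table.

Three arms (healthy, bleo.+vehicle, bleo.+nintedanib), five animals each,
measured on days 0/7/14/21.  Every cell runs the complete measurement
pipelines: planar radiographs -> XLF metrics, gated rotational projections ->
phase-resolved lung volumes, pressure trace -> WBP tidal volume, and porous
cubes -> ex-vivo morphometry on day 21.

Writes results/cohort_metrics.csv and prints the group x day means of the
headline metrics.
"""

import time
from pathlib import Path

from lungkit.cohort import group_day_mean, simulate_study

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 1


def main():
    OUT.mkdir(exist_ok=True)
    t0 = time.time()
    table = simulate_study(seed=SEED)
    table.to_csv(OUT / "cohort_metrics.csv", index=False)
    print(f"simulated 3 x 5 x 4 study in {time.time() - t0:.0f} s "
          f"({len(table)} metric rows) -> results/cohort_metrics.csv\n")
    for metric in ("decay_rate", "v_insp", "tv_wbp", "air_ratio", "sa_v"):
        print(f"== group x day mean: {metric}")
        print(group_day_mean(table, metric).round(4), "\n")
    print("Findings to look for: decay rate, V_insp and TV_WBP all drop at "
          "day 7 in both bleomycin arms;\nonly the nintedanib arm recovers "
          "at day 14; day-21 cubes lose air ratio and SA:V with severity.")


if __name__ == "__main__":
    main()
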