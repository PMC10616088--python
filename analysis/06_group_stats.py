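"""Group statistics and correlation report over the simulated study.

Reads results/cohort_metrics.csv (produced by 01_simulate_cohort.py), runs
pairwise Welch comparisons with Holm-Sidak adjustment per (metric, day)
panel, Spearman correlations between the in-vivo volumetric readouts, and
writes the report tables plus a correlation heatmap figure.

Writes results/comparisons.csv, results/correlations.csv,
results/group_summary.csv and results/correlation_heatmap.png.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from lungkit import stats

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results"


def main():
    table = pd.read_csv(OUT / "cohort_metrics.csv")
    rep = stats.cohort_report(
        table[~table.metric.str.endswith("_true")],
        correlation_pairs=[("v_insp", "tv_wbp"), ("v_insp", "air_ratio"),
                           ("tv_wbp", "air_ratio"), ("v_insp", "sa_v")])
    rep["summary"].to_csv(OUT / "group_summary.csv", index=False)
    rep["comparisons"].to_csv(OUT / "comparisons.csv", index=False)
    rep["correlations"].to_csv(OUT / "correlations.csv", index=False)

    sig = rep["comparisons"].query("significant")
    print(f"{len(rep['comparisons'])} comparisons, {len(sig)} significant "
          "after Holm-Sidak; headline cells:")
    cols = ["metric", "day", "group_a", "group_b", "t", "p_adjusted"]
    headline = sig[sig.metric.isin(["decay_rate", "v_insp", "tv_wbp"])]
    print(headline[cols].round(4).to_string(index=False), "\n")
    print(rep["correlations"].round(3).to_string(index=False))

    corr = rep["correlations"]
    piv = corr.pivot_table(index="group", columns=["metric_x", "metric_y"],
                           values="value")
    fig, ax = plt.subplots(figsize=(7, 3))
    im = ax.imshow(piv.to_numpy(), vmin=0, vmax=1, cmap="viridis")
    ax.set_yticks(range(len(piv.index)), piv.index)
    ax.set_xticks(range(piv.shape[1]),
                  [f"{a}\nvs {b}" for a, b in piv.columns], fontsize=8)
    for i in range(piv.shape[0]):
        for j in range(piv.shape[1]):
            ax.text(j, i, f"{piv.to_numpy()[i, j]:.2f}", ha="center",
                    va="center", color="w", fontsize=8)
    ax.set_title("Spearman r between volumetric readouts")
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(OUT / "correlation_heatmap.png", dpi=150)
    print("\nwrote results/correlation_heatmap.png")


if __name__ == "__main__":
    main()
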