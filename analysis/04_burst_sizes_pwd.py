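"""Burst sizes from pairwise-distance distributions on all four substrates.

Simulates low-force cohorts, removes slip events on the RNA-tracking
substrates, computes per-trace PWDs (41-point moving average, 0.05 nm
grid), grades them by spectral periodicity, selectively averages the top
30%, and reads the burst size off the mean peak spacing.  The recovered
sizes should track the helical pitches: dsDNA > hybrids > dsRNA.
Writes results/burst_sizes.tsv and one PWD figure per substrate.
"""

from pathlib import Path

import matplotlib.pyplot as plt
import pandas as pd

from dwellburst.pipeline import PUBLISHED_VALUES, recover_burst_size
from dwellburst.plots import plot_pwd

OUT = Path("results")
FIG = Path("results/figures")
N_TRACES = 12
DURATION_S = 30.0
SEED0 = 100


def main():
    FIG.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, name in enumerate(("dsDNA", "DTS_hybrid", "RTS_hybrid", "dsRNA")):
        seeds = range(SEED0 + i * N_TRACES, SEED0 + (i + 1) * N_TRACES)
        res = recover_burst_size(name, seeds=seeds, duration_s=DURATION_S)
        rows.append({"substrate": name,
                     "recovered_burst_nm": round(res.burst_size, 3),
                     "se_nm": round(res.burst_size_se, 3),
                     "published_burst_nm": PUBLISHED_VALUES[name]["burst_nm"],
                     "n_traces": N_TRACES})
        ax = plot_pwd(res)
        ax.figure.savefig(FIG / f"pwd_{name}.png", dpi=150,
                          bbox_inches="tight")
        plt.close(ax.figure)
        print(f"{name:11s}  burst {res.burst_size:.2f} +- "
              f"{res.burst_size_se:.2f} nm "
              f"(published {PUBLISHED_VALUES[name]['burst_nm']})")
    table = pd.DataFrame(rows)
    table.to_csv(OUT / "burst_sizes.tsv", sep="\t", index=False)
    order = table.sort_values("recovered_burst_nm", ascending=False)
    print("ordering:", " > ".join(order["substrate"]))


if __name__ == "__main__":
    main()
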