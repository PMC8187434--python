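"""Simulate a small packaging cohort on all four substrates.

Writes rendered traces, noiseless contour trajectories, and ground-truth
event logs under results/sim/, plus one example trace figure per substrate.
The low-force semi-passive conditions (7-12 pN band, 0.25 mM ATP, 2.5 kHz)
match the velocity / burst-size experiments; downstream scripts re-simulate
their own condition-specific cohorts.
"""

from pathlib import Path

import matplotlib.pyplot as plt

from dwellburst import WlcParams, contour_trajectory, get_substrate, \
    packaged_length, read_trace
from dwellburst.pipeline import cmd_simulate
from dwellburst.plots import plot_trace

OUT = Path("results/sim")
FIG = Path("results/figures")
CONFIG = {"n_traces": 3, "duration_s": 30.0}
SEED = 1


def main():
    FIG.mkdir(parents=True, exist_ok=True)
    paths = cmd_simulate(CONFIG, OUT, seed=SEED)
    print(f"wrote {len(paths)} traces to {OUT}")
    for name in ("dsDNA", "DTS_hybrid", "RTS_hybrid", "dsRNA"):
        trace = read_trace(OUT / f"{name}_000.trace.tsv")
        sub = get_substrate(name)
        wlc = WlcParams(sub.persistence_length, sub.stretch_modulus, 1.0)
        packaged = packaged_length(contour_trajectory(trace, wlc))
        ax = plot_trace(trace, packaged)
        ax.figure.savefig(FIG / f"trace_{name}.png", dpi=150,
                          bbox_inches="tight")
        plt.close(ax.figure)
        print(f"  {name}: packaged {packaged[-1]:.0f} nm in "
              f"{trace.duration:.0f} s")


if __name__ == "__main__":
    main()
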