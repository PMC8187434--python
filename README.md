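# dwellburst

Simulation and analysis of dwell–burst packaging trajectories for the
bacteriophage ϕ29 DNA-packaging motor on double-helical substrates.

The ϕ29 packaging ATPase is a homopentameric ring motor that internalizes
its genome against tens of piconewtons of load. Its mechanochemical cycle
segregates an ATP-loading **dwell** (no translocation; subunits exchange
ADP for ATP sequentially, making dwell durations gamma-distributed) from a
translocation **burst** of four power strokes. On B-form dsDNA the four
strokes are each 0.85 nm, totalling one helical turn (10 bp, ≈3.4 nm).
Challenged with A-form substrates of shorter pitch (DNA/RNA hybrids,
dsRNA), the motor keeps three strokes invariant and shortens the fourth so
the burst matches the new period — the *helical inchworm* mechanism, in
which the ring opens into a lock-washer during loading and closes back to
planar stroke by stroke. When the strand being tracked 5′→3′ is RNA, the
motor sporadically loses grip and reverse-translocates in slips of exactly
one burst.

This package is for single-molecule biophysicists who want a ground-truthed
test bed for that analysis chain. It provides:

- a stochastic generator of packaging trajectories from the dwell–burst
  state machine, with packaging-competent/incompetent (PC/PI) slipping
  kinetics and optical-trap measurement rendering
  (Ornstein–Uhlenbeck bead noise, semi-passive or force-feedback modes);
- extensible worm-like chain (XWLC) elasticity,
  `x = L0 [1 − ½√(kT/FP) + F/S]`, for contour-length conversion and
  pulling-curve fitting;
- pause-free velocity estimation (Savitzky–Golay differentiation +
  constrained two-Gaussian mixture);
- burst-size estimation from pairwise-distance distributions (PWD) with
  spectral periodicity grading and top-30% selective averaging;
- change-point stepfinding (Kalafut–Visscher Schwarz-criterion and a
  ladder-HMM Viterbi variant), gamma dwell fits, and differential step-size
  distributions;
- slip-event detection and the event anatomy statistics (start dwell,
  slipping dwells, end dwell, total length, mid-time, slipping velocity).

## Worked example

Simulate a small dsRNA cohort (slipping enabled) and run the full analysis
chain:

```python
from dwellburst.pipeline import simulate_cohort, analyze_cohort

traces, trajs, truths = simulate_cohort(
    "dsRNA", {"substrates": ["dsRNA"], "n_traces": 6, "duration_s": 30.0},
    seed=42)
report = analyze_cohort(traces)
print(report["burst_size_nm"], report["pause_free_velocity_nm_s"],
      report["slip_event_frequency_per_s"])
```

prints (seed 42):

```
burst_size_nm                 2.70
pause_free_velocity_nm_s      31.3
negative_tail_fraction        0.012
dwell_mean_ms                 94.9
slip_event_frequency_per_s    0.078
```

The PWD peak spacing recovers the dsRNA burst (2.70 nm, matching its
shorter A-form pitch), the pause-free velocity lands near the ~31 nm/s
dsRNA packaging speed, the negative velocity tail and the nonzero slip
frequency reflect reverse translocation on an RNA tracking strand, and the
dwell mean is the ATP-loading dwell as seen by the stepfinder.

The numbered scripts under `analysis/` run the complete study on synthetic
cohorts — trace simulation, pulling-curve fits, velocity distributions,
PWD burst sizes, high-force step sizes with the dsDNA-vs-DTS differential,
and slip-event statistics under saturating vs limiting ATP — writing
tables, JSON reports and figures under `results/`.

There is also a small CLI:

```
dwellburst simulate --out results/sim --seed 1
dwellburst analyze results/sim/*.trace.tsv
dwellburst table1 --seeds 1 2 3
dwellburst pulling-fit curve.tsv
```

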