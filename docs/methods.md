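# Methods

## The mechanochemical model

Each packaging cycle alternates a dwell and a burst.

**Dwell.** ATP loading is modelled as `dwell_shape` (default 5, one per
subunit exchange event) sequential exponential steps, so dwell durations
are gamma(shape, mean/shape) distributed with mean `dwell_mean`. Per-
substrate dwell means are the measured values at 0.25 mM ATP (dsDNA 86 ms,
DTS hybrid 105 ms, RTS hybrid 85 ms, dsRNA 83 ms). Exchange rates scale
with the Michaelis saturation f = [ATP]/([ATP]+Km), Km = 0.030 mM,
relative to the 0.25 mM reference (≈8×Km), so limiting ATP stretches the
dwell and widens the window in which the motor is not ATP-saturated.

**Burst.** `steps_per_burst` (4) power strokes, each an instantaneous jump
after an exponential wait at `burst_step_rate`. Three strokes have the
inherent size 0.85 nm; the fourth is the burst remainder
`burst_size − 3×0.85`: 0.85 nm on dsDNA (burst 3.40 = 4×0.85), 0.54 nm on
the DTS hybrid (burst 3.09), 0.47 nm on the RTS hybrid (burst 3.02),
0.15 nm on dsRNA (burst 2.70). `burst_size` is carried on the
`SubstrateSpec` alongside the crystallographic pitch; the two track each
other closely but are not identical, and both the burst total and the slip
quantum use `burst_size` (the slips observed on RNA-tracking substrates
coincide with the burst, not the pitch). `burst_step_rate` defaults to
580 s⁻¹, chosen once so the dsDNA cycle (86 ms dwell + ~6.9 ms burst)
yields a mean pause-free velocity near the measured 36.6 nm/s; stroke
durations themselves are unresolved experimentally.

**Slipping (PC/PI kinetics).** On RNA tracking strands only, while ATP
loading is incomplete, a constant hazard `pi_entry_rate` (0.10 s⁻¹)
carries the motor from the packaging-competent state into a
packaging-incompetent gripping state; nucleotide exchange freezes at its
current occupancy. After an exponential PI-gripping phase
(`grip_to_slip_rate`, 5 s⁻¹ — the start dwell), the motor slips backward
in quanta of exactly one burst at `slip_dwell_rate` (8 s⁻¹), in kinetic
competition with grip recovery (`recovery_rate`: 8 s⁻¹ on the RTS hybrid,
4 s⁻¹ on dsRNA, encoding the roughly twofold longer events on dsRNA).
Slips per event are therefore geometric with mean
1 + slip_dwell_rate/recovery_rate and independent of [ATP]. The end dwell
exits at `end_to_pc_rate` (5 s⁻¹) scaled by the same ATP saturation
factor, so limiting ATP lengthens the end dwell, and loading then resumes
where it halted. These rates are not reported as numbers in the source
measurements; they were fixed once at values that place event frequency
(~0.05 s⁻¹), slipping dwells (~80 ms) and slips per event (2–3) in the
observed regime.

**Measurement rendering.** Extension is the XWLC image of the unpackaged
contour plus (i) an Ornstein–Uhlenbeck bead fluctuation with equilibrium
variance kT/κ (trap stiffness κ = 0.55 pN/nm, drag 9.4×10⁻⁶ pN·s/nm for a
1 µm bead; the corner frequency lies above the 2.5 kHz Nyquist, so samples
are nearly white), (ii) white detector noise (0.5 nm default), and (iii)
optional linear drift. Force-feedback mode holds force constant;
semi-passive mode ramps force with packaging at half the trap stiffness
and re-centres to the low band edge (7→12 pN) — a modulo model of the
recentring sweeps. Setting the drag to zero disables the OU term, used for
the step-resolution studies where an effective plateau noise is specified
directly.

**High-force regime.** Against 30–35 pN the motor slows; the preset
(`highforce_config`) uses dwell_mean 0.25 s and burst_step_rate 15 s⁻¹ in
force-feedback at 32 pN with 0.2 nm plateau noise. This is what makes
individual power strokes resolvable, as in the step-size experiments.

## Elasticity

The high-force XWLC interpolation `x = L0[1 − ½√(kT/FP) + F/S]` is used
throughout (kT = 4.114 pN·nm at 25 °C, configurable). It is linear in L0,
so the per-sample extension→contour inversion is exact; it is valid above
a few pN and all analyses here operate at ≥7 pN. Pulling-curve fits are
unweighted least squares in extension with forces treated as exact
(bounded trust-region, P∈[1,500] nm, S∈[50,5000] pN); L0 is seeded from
the top of the curve. A force span under a factor of two sets a
`narrow_range` diagnostic. Note the dsDNA and dsRNA parameter sets make
the force–extension curves cross near 7 pN: dsRNA is the shorter polymer
at low force (smaller P) but the more extensible one at high force
(smaller S). Full Marko–Siggia solutions, twist–stretch coupling and the
<1 pN regime are out of scope.

## Analysis chain

**Packaged length.** All analyses use p(t) = L0(0) − L0(t), making
packaging velocity and forward steps positive.

**Velocity.** Savitzky–Golay differentiation, order 1, width 301 at
2.5 kHz (≈8.3 Hz bandwidth: smooths the ~11 Hz dwell–burst cycle but keeps
slip onsets). Edge samples (half a window) are excluded from histograms.
Histograms use 0.7 nm/s bins; the density is fit with
w₀N(0,σ₀²)+w₁N(µ,σ₁²), area-parameterized, the zero mean pinned. The fit
is flagged degenerate when the packaging component vanishes (<1% weight),
has non-positive mean, or its mean is buried inside the pause peak
(µ < 2σ₀). The negative tail fraction is the observed mass below −3σ₀.

**Pairwise-distance distributions.** Traces are smoothed with a 41-point
moving average (~61 Hz), cut into 5 s windows to limit drift, positions
binned at 0.05 nm, and the all-pairs distance histogram computed as the
autocorrelation of the binned occupancy (exactly the pair count per binned
distance, at O(n log n)). Distributions are kept to 15 nm and unit area.
Per-trace distributions are graded by the fraction of spectral power
within ±10% of the cohort-average distribution's dominant spatial
frequency (scale-invariant); the top 30% are averaged, peaks with ≥10%
prominence are found, and the burst size is the mean of the first three
inter-peak gaps with its SE. On slipping substrates, detected slip events
(padded by 0.2 s) are excised before the PWD.

**Stepfinding.** The Kalafut–Visscher fit adds change points greedily at
the globally best SSE-reducing placement, accepting while the Schwarz
criterion `sensitivity·m·ln n + n·ln(SSE/n)` decreases; ties break to the
earlier index, plateaus have a minimum length (2 samples; 10 ms for
low-force slip analysis, suppressing noise-spike plateaus), and the SSE
floor scales with the data so float cancellation cannot read as structure
on noiseless series. The default sensitivity is 2.0: at 1.0 the criterion
over-segments long noisy series (the best-split statistic behaves like the
supremum of a squared Brownian bridge and exceeds ln n with appreciable
probability — measured 19% false-positive runs on flat σ=0.3 noise at 10⁴
samples, vs 0% at 2.0 with essentially unchanged staircase recovery).
Low-force data are block-averaged to 500 Hz first; at low force the burst
is unresolved and the fitter reports one ~burst-sized step per cycle,
which is the regime the PWD and dwell statistics use.

The HMM stepfinder decodes a ladder of Gaussian-emission levels by
Viterbi. The ladder quantum is half the expected step so substrates mixing
full and fractional steps stay representable; transitions are banded (±4
quanta; stay probability 0.99), which keeps the decode linear in ladder
size, and the ladder offset minimizes the squared distance of the samples
to the ladder. When no spacing hint is given, the spacing is chosen by
Viterbi likelihood over a grid (19 values in 0.3–1.2 nm). Plateau means
are re-estimated from the data after segmentation — recovered step sizes
are not quantized to the ladder — and plateaus shorter than the minimum
are merged into the nearer-mean neighbour.

Dwell durations are fit by maximum-likelihood gamma (location 0) with a KS
goodness-of-fit p-value. Step-size distributions use 0.05 nm bins;
differential distributions resample both densities onto the common grid,
renormalize, subtract, and fit up to two Gaussians to the excess of one
substrate over the other. On the DTS hybrid the excess shows the shortened
fourth step (~0.54 nm) and a second lobe one inherent step higher
(~1.39 nm) from fourth steps merged with a neighbouring stroke by the
stepfinder — reproducing the known merging artifact mechanism.

**Slip events.** Maximal runs of consecutive backward steps form events.
Backward steps under half the expected burst are stepfinder noise and do
not open events; steps near k≥2 bursts are split into k recorded slips
(their separating dwell was below resolution; such merged pairs report a
zero intervening slipping dwell, and the mid-time identity below applies to
resolved events). Start dwell = plateau before the first slip; slipping
dwells = plateaus between slips; end dwell = plateau after the last slip;
mid-time = time from first to last slip change point, so
total length = slipping velocity × mid-time holds exactly for events with
≥2 resolved slips. Events touching trace edges are flagged and excluded
from dwell statistics. Whether the mid-time should include parts of the
start/end dwells is not experimentally defined; this definition is the one
that makes the identity exact.

## What the generator does and does not emulate

It reproduces the dwell–burst alternation with per-substrate burst sizes
and gamma dwells, burst-quantized slipping confined to RNA tracking
strands with ATP-dependent frequency and end dwells, trap noise with the
equipartition variance, and both trap operation modes. It does not model:
capsid-filling effects on velocity (velocity is stationary), force
dependence of rates within a mode (the high-force regime is a discrete
preset), substrate rotation, dual-trap cross-correlation (one effective
bead coordinate), instrument drift beyond a linear term, or partial/
compound slips. Passing tests therefore demonstrate that the analysis
chain recovers the generator's ground truth under realistic noise — not
that real data are free of these unmodelled effects.

## Problem sizes

The test suite runs cohorts of 3–12 traces of 10–40 s; the reproduction
script (`scripts/acceptance.py`) uses 30-trace low-force cohorts at 40 s
(spacing estimates are insensitive to trace length beyond ~20 s),
10-trace high-force cohorts at 15 s, and 100 pulling curves of 200 points.
All randomness flows from one top-level seed through
`numpy.random.SeedSequence` expansion.

## Known limitations

- The burst/pitch distinction means the dsRNA slip quantum (2.70 nm) sits
  ~10% below the dsRNA pitch; analyses compare slips to the burst.
- The DTS fourth step is 0.54 nm by the self-consistent burst arithmetic,
  while stepfinding-based estimates in the literature of this motor report
  ~0.45–0.51 nm; the recovered minor mode here lands at 0.50–0.55 nm.
- At low force individual power strokes are unresolvable by construction
  (~2 ms apart); per-stroke statistics require the high-force preset.
- The two-Gaussian velocity mixture slightly overestimates the pause-free
  mean (a few percent) because the packaging peak is skewed by cycles
  containing long dwells.
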