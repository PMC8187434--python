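"""Stochastic dwell-burst packaging simulator with slipping kinetics.

The generator implements the helical-inchworm mechanochemical cycle: each
cycle is an ATP-loading *dwell* — ``dwell_shape`` sequential exponential
nucleotide-exchange events, so dwell durations are gamma distributed —
followed by a translocation *burst* of ``steps_per_burst`` power strokes.
Three strokes have the fixed inherent size (0.85 nm); the last stroke is the
burst remainder, which shrinks on the shorter-pitch A-form substrates.

On RNA-tracking substrates the motor can leave the packaging-competent (PC)
state while ATP loading is incomplete, entering a packaging-incompetent (PI)
state: a PI-gripping phase (the *start dwell*), then PI-slipping, emitting
backward slips of exactly one burst separated by short *slipping dwells*
until grip is recovered, then an *end dwell* whose exit rate scales with ATP
saturation, after which nucleotide exchange resumes where it halted.

Measurement rendering adds Ornstein-Uhlenbeck bead fluctuation (trap
stiffness / drag corner frequency) plus white detector noise, sampled on the
acquisition grid, under either constant-force (force_feedback) or banded
(semi_passive) trap operation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from .elasticity import KT_ROOM, WlcParams, xwlc_extension
from .trace_model import ContourTrajectory, SubstrateSpec, Trace

__all__ = [
    "MotorParams",
    "SlipParams",
    "NoiseParams",
    "GroundTruth",
    "simulate_packaging",
    "render_trace",
    "simulate_pulling",
    "default_motor_params",
    "default_slip_params",
]

#: acquisition rate of the instrument (Hz)
SAMPLE_RATE = 2500.0


@dataclass(frozen=True)
class MotorParams:
    """Kinetic parameters of the packaging cycle.

    ``burst_size`` is the total translocation per burst; the fourth-step
    size is ``burst_size - (steps_per_burst - 1) * inherent_step`` and must
    be non-negative.  ``dwell_mean`` is the mean loading dwell at the
    reference saturating ATP (0.25 mM); exchange rates scale with the
    Michaelis saturation [ATP]/([ATP]+Km) relative to that reference.
    """

    burst_size: float              # nm per cycle
    dwell_mean: float              # s at reference ATP
    inherent_step: float = 0.85    # nm per power stroke
    steps_per_burst: int = 4
    dwell_shape: int = 5           # sequential exchange events per dwell
    burst_step_rate: float = 580.0  # 1/s per power stroke
    atp_mM: float = 0.25
    Km_mM: float = 0.030
    atp_ref_mM: float = 0.25

    def __post_init__(self):
        if self.fourth_step < 0:
            raise ValueError(
                f"burst_size {self.burst_size} nm cannot accommodate "
                f"{self.steps_per_burst - 1} inherent steps of {self.inherent_step} nm")
        if self.dwell_shape < 1:
            raise ValueError("dwell_shape must be >= 1")
        if min(self.dwell_mean, self.burst_step_rate, self.atp_mM, self.Km_mM) <= 0:
            raise ValueError("dwell_mean, burst_step_rate, atp_mM, Km_mM must be > 0")

    @property
    def fourth_step(self) -> float:
        return self.burst_size - (self.steps_per_burst - 1) * self.inherent_step

    @property
    def step_sizes(self) -> tuple:
        return tuple([self.inherent_step] * (self.steps_per_burst - 1)
                     + [self.fourth_step])

    @property
    def atp_saturation(self) -> float:
        """Michaelis saturation relative to the reference ATP."""
        sat = self.atp_mM / (self.atp_mM + self.Km_mM)
        sat_ref = self.atp_ref_mM / (self.atp_ref_mM + self.Km_mM)
        return sat / sat_ref


@dataclass(frozen=True)
class SlipParams:
    """PC/PI state rates governing burst-sized slipping.

    ``pi_entry_rate`` is the PC->PI hazard, active only while the dwell's
    ATP loading is incomplete and only on RNA tracking strands (it must be 0
    on DNA tracking strands).  Mean slips per event is
    1 + slip_dwell_rate / recovery_rate (the first slip defines the event).
    """

    pi_entry_rate: float = 0.0      # 1/s, PC -> PI-gripping
    grip_to_slip_rate: float = 5.0  # 1/s, PI-gripping -> PI-slipping
    slip_dwell_rate: float = 8.0    # 1/s, per backward slip
    recovery_rate: float = 8.0      # 1/s, PI-slipping -> end dwell
    end_to_pc_rate: float = 5.0     # 1/s at reference ATP saturation

    def __post_init__(self):
        if min(self.pi_entry_rate, self.grip_to_slip_rate, self.slip_dwell_rate,
               self.recovery_rate, self.end_to_pc_rate) < 0:
            raise ValueError("slip rates must be >= 0")

    @property
    def mean_slips_per_event(self) -> float:
        if self.recovery_rate == 0:
            return float("inf")
        return 1.0 + self.slip_dwell_rate / self.recovery_rate


@dataclass(frozen=True)
class NoiseParams:
    """Measurement-noise model of the dual-trap instrument.

    Bead fluctuation is an Ornstein-Uhlenbeck process with equilibrium
    variance kT/trap_stiffness and corner time drag/stiffness; setting
    ``drag_coefficient`` to 0 disables it.  ``measurement_sigma`` is white
    detector noise; ``drift_rate`` a deterministic linear drift.
    """

    trap_stiffness: float = 0.55       # pN/nm
    drag_coefficient: float = 9.4e-6   # pN s/nm (1 um bead in water)
    measurement_sigma: float = 0.5     # nm
    drift_rate: float = 0.0            # nm/s
    kT: float = KT_ROOM

    def __post_init__(self):
        if min(self.trap_stiffness, self.drag_coefficient,
               self.measurement_sigma, self.kT) < 0:
            raise ValueError("noise parameters must be >= 0")


@dataclass
class GroundTruth:
    """Event log of a simulated run; validation scaffold for the analyses.

    Event kinds: dwell_start, power_stroke, slip, pi_entry, pi_exit.
    Signed ``sizes`` (nm) cumulate to the noiseless packaged-length path.
    """

    times: np.ndarray
    kinds: list
    sizes: np.ndarray
    dwell_durations: np.ndarray = field(default_factory=lambda: np.empty(0))
    slip_counts: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    burst_steps: list = field(default_factory=list)

    @property
    def n_slip_events(self) -> int:
        return int(self.slip_counts.size)

    @property
    def total_packaged(self) -> float:
        return float(self.sizes.sum())

    def packaged_at(self, t: np.ndarray) -> np.ndarray:
        """Noiseless packaged length sampled at times ``t``."""
        cum = np.cumsum(self.sizes)
        idx = np.searchsorted(self.times, t, side="right")
        out = np.zeros_like(np.asarray(t, dtype=float))
        nz = idx > 0
        out[nz] = cum[idx[nz] - 1]
        return out


def default_motor_params(substrate: SubstrateSpec, atp_mM: float = 0.25,
                         **overrides) -> MotorParams:
    kw = dict(burst_size=substrate.burst_size, dwell_mean=substrate.dwell_mean,
              atp_mM=atp_mM)
    kw.update(overrides)
    return MotorParams(**kw)


def default_slip_params(substrate: SubstrateSpec, **overrides) -> SlipParams:
    """Slipping defaults: active only on RNA tracking strands; grip recovery
    is slower on dsRNA than on the RTS hybrid (events last about twice as
    long on dsRNA)."""
    if substrate.tracking_strand == "DNA":
        kw = dict(pi_entry_rate=0.0)
    elif substrate.name == "dsRNA":
        kw = dict(pi_entry_rate=0.10, recovery_rate=4.0)
    else:
        kw = dict(pi_entry_rate=0.10, recovery_rate=8.0)
    kw.update(overrides)
    return SlipParams(**kw)


def simulate_packaging(substrate: SubstrateSpec, motor: MotorParams,
                       slips: SlipParams, duration: float, seed: int,
                       sample_rate: float = SAMPLE_RATE,
                       tether_margin: float = 340.0):
    """Simulate one packaging run; returns (noiseless ContourTrajectory, GroundTruth).

    The contour trajectory is sampled on the acquisition grid; its initial
    unpackaged contour is the total packaged length plus ``tether_margin``
    so contour stays positive throughout.  Bit-reproducible for fixed seed.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if substrate.tracking_strand == "DNA" and slips.pi_entry_rate > 0:
        raise ValueError("pi_entry_rate must be 0 on DNA tracking strands")
    rng = np.random.default_rng(seed)

    sat = motor.atp_saturation
    exchange_rate = motor.dwell_shape / motor.dwell_mean * sat
    end_rate = slips.end_to_pc_rate * sat
    step_sizes = motor.step_sizes
    slip_size = motor.burst_size
    can_slip = substrate.tracking_strand == "RNA" and slips.pi_entry_rate > 0

    times: list = []
    kinds: list = []
    sizes: list = []
    dwell_durations: list = []
    slip_counts: list = []
    burst_steps: list = []

    t = 0.0
    while t < duration:
        # ---- dwell: sequential exchange events with optional PI interruption
        times.append(t); kinds.append("dwell_start"); sizes.append(0.0)
        loaded = 0
        dwell_time = 0.0
        while loaded < motor.dwell_shape:
            if can_slip:
                total = exchange_rate + slips.pi_entry_rate
                wait = rng.exponential(1.0 / total)
                pi_fired = rng.random() < slips.pi_entry_rate / total
            else:
                wait = rng.exponential(1.0 / exchange_rate)
                pi_fired = False
            t += wait
            dwell_time += wait
            if not pi_fired:
                loaded += 1
                continue
            # PC -> PI: nucleotide exchange freezes at `loaded`
            times.append(t); kinds.append("pi_entry"); sizes.append(0.0)
            t += rng.exponential(1.0 / slips.grip_to_slip_rate)
            n_slips = 0
            while True:
                comp = slips.slip_dwell_rate + slips.recovery_rate
                if comp == 0:
                    break
                t += rng.exponential(1.0 / comp)
                if rng.random() < slips.slip_dwell_rate / comp:
                    times.append(t); kinds.append("slip"); sizes.append(-slip_size)
                    n_slips += 1
                else:
                    break
            if end_rate > 0:
                t += rng.exponential(1.0 / end_rate)
            times.append(t); kinds.append("pi_exit"); sizes.append(0.0)
            slip_counts.append(n_slips)
            # loading resumes where it halted
        dwell_durations.append(dwell_time)
        # ---- burst: sequential power strokes
        this_burst = []
        for size in step_sizes:
            t += rng.exponential(1.0 / motor.burst_step_rate)
            times.append(t); kinds.append("power_stroke"); sizes.append(size)
            this_burst.append(size)
        burst_steps.append(this_burst)

    times_arr = np.asarray(times)
    sizes_arr = np.asarray(sizes)
    keep = times_arr <= duration
    gt = GroundTruth(times_arr[keep],
                     [k for k, m in zip(kinds, keep) if m],
                     sizes_arr[keep],
                     np.asarray(dwell_durations),
                     np.asarray(slip_counts, dtype=int),
                     burst_steps)

    n = int(round(duration * sample_rate))
    grid = np.arange(n) / sample_rate
    packaged = gt.packaged_at(grid)
    l0_init = float(packaged.max()) + tether_margin
    contour = l0_init - packaged
    meta = {"substrate_name": substrate.name, "atp_mM": motor.atp_mM,
            "seed": seed, "noiseless": True}
    traj = ContourTrajectory(grid, contour, np.full(n, np.nan), sample_rate, meta)
    return traj, gt


# ---------------------------------------------------------------------------
# measurement rendering

def _ou_noise(n: int, dt: float, noise: NoiseParams, rng) -> np.ndarray:
    """Sampled Ornstein-Uhlenbeck bead fluctuation (equilibrium start)."""
    if noise.trap_stiffness == 0 or noise.drag_coefficient == 0:
        return np.zeros(n)
    tau = noise.drag_coefficient / noise.trap_stiffness
    sigma_eq = np.sqrt(noise.kT / noise.trap_stiffness)
    a = np.exp(-dt / tau)
    w = rng.standard_normal(n) * sigma_eq * np.sqrt(1.0 - a * a)
    w[0] = rng.standard_normal() * sigma_eq
    return lfilter([1.0], [1.0, -a], w)


def render_trace(traj: ContourTrajectory, substrate: SubstrateSpec,
                 noise: NoiseParams, force_mode: str, force_setpoint,
                 seed: int) -> Trace:
    """Render a noiseless contour trajectory into a measured Trace.

    ``force_mode`` is 'force_feedback' (constant force = ``force_setpoint``)
    or 'semi_passive' (``force_setpoint`` is a (low, high) pN band; force
    ramps with packaging at half the trap stiffness and re-centres to the
    low edge when it reaches the high edge).
    """
    rng = np.random.default_rng(seed)
    n = traj.time.size
    dt = 1.0 / traj.sample_rate
    packaged = traj.contour[0] - traj.contour

    if force_mode == "force_feedback":
        f0 = float(force_setpoint)
        if f0 < 1.0:
            raise ValueError("force below 1 pN is outside XWLC validity")
        force = np.full(n, f0)
    elif force_mode == "semi_passive":
        f_lo, f_hi = (float(force_setpoint[0]), float(force_setpoint[1]))
        if f_lo < 1.0 or f_hi <= f_lo:
            raise ValueError("semi_passive band must satisfy 1 <= low < high")
        kappa_eff = 0.5 * noise.trap_stiffness if noise.trap_stiffness > 0 else 0.25
        force = f_lo + np.mod(kappa_eff * packaged, f_hi - f_lo)
    else:
        raise ValueError(f"unknown force_mode {force_mode!r}")

    params = WlcParams(substrate.persistence_length, substrate.stretch_modulus,
                       1.0, noise.kT)
    # extension is linear in L0: evaluate the bracket once per sample
    extension = traj.contour * (xwlc_extension(force, params))
    extension = extension + _ou_noise(n, dt, noise, rng)
    if noise.measurement_sigma > 0:
        extension = extension + rng.standard_normal(n) * noise.measurement_sigma
    if noise.drift_rate != 0:
        extension = extension + noise.drift_rate * traj.time

    meta = dict(traj.meta)
    meta.update({"force_mode": force_mode, "noiseless": False,
                 "trap_stiffness_pN_per_nm": noise.trap_stiffness,
                 "render_seed": seed})
    return Trace(traj.time, extension, force, traj.sample_rate, meta)


def simulate_pulling(substrate: SubstrateSpec, L0: float, noise_sigma: float,
                     n_points: int, seed: int,
                     force_range: tuple = (5.0, 40.0)) -> tuple:
    """Synthetic force-extension pulling curve: (force pN, extension nm).

    XWLC evaluated on an even force grid over ``force_range`` with additive
    Gaussian extension noise.
    """
    if n_points <= 0:
        raise ValueError("n_points must be positive")
    if L0 <= 0 or noise_sigma < 0:
        raise ValueError("L0 must be > 0 and noise_sigma >= 0")
    rng = np.random.default_rng(seed)
    force = np.linspace(force_range[0], force_range[1], n_points)
    params = WlcParams(substrate.persistence_length, substrate.stretch_modulus, L0)
    extension = xwlc_extension(force, params)
    if noise_sigma > 0:
        extension = extension + rng.standard_normal(n_points) * noise_sigma
    return force, extension
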