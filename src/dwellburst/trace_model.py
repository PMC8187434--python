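"""Core data types and plain-text I/O for optical-tweezers packaging traces.

Units are fixed package-wide: nanometres, seconds, piconewtons, hertz.
Packaging shortens the tether, so raw extension and unpackaged contour
length decrease over time; analysis modules work on the *packaged length*
p(t) = L0(0) - L0(t), which makes packaging velocity and forward steps
positive.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "Trace",
    "ContourTrajectory",
    "SubstrateSpec",
    "TraceFormatError",
    "TraceValidationError",
    "read_trace",
    "write_trace",
    "default_substrates",
    "get_substrate",
    "packaged_length",
]

#: relative tolerance on time-grid uniformity (1 part in 1e6)
GRID_RTOL = 1e-6

FORCE_MODES = ("semi_passive", "force_feedback")


class TraceFormatError(ValueError):
    """Raised when a trace file cannot be parsed."""


class TraceValidationError(ValueError):
    """Raised when arrays violate a trace invariant."""


def _check_grid(time: np.ndarray, sample_rate: float) -> None:
    if time.size < 2:
        return
    dt = np.diff(time)
    expected = 1.0 / sample_rate
    bad = np.nonzero(np.abs(dt - expected) > GRID_RTOL * max(expected, abs(time[-1])))[0]
    if bad.size:
        raise TraceValidationError(
            f"non-uniform time grid: first offending interval at index {int(bad[0])} "
            f"(dt={dt[bad[0]]:.6g} s, expected {expected:.6g} s)"
        )


@dataclass
class Trace:
    """Raw sampled optical-trap record: tether extension and force vs time."""

    time: np.ndarray        # s, uniform grid
    extension: np.ndarray   # nm, bead-to-bead end-to-end distance
    force: np.ndarray       # pN
    sample_rate: float      # Hz
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.extension = np.asarray(self.extension, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        self.validate()

    def validate(self) -> None:
        n = self.time.size
        if n == 0:
            raise TraceValidationError("empty trace")
        if self.extension.size != n or self.force.size != n:
            raise TraceValidationError("time/extension/force lengths differ")
        if self.sample_rate <= 0:
            raise TraceValidationError("sample_rate must be positive")
        if np.any(np.diff(self.time) <= 0):
            raise TraceValidationError("time must be strictly increasing")
        _check_grid(self.time, self.sample_rate)
        if np.any(self.force < 0):
            raise TraceValidationError("force must be >= 0")
        if np.any(self.extension <= 0):
            raise TraceValidationError("extension must be > 0")
        mode = self.meta.get("force_mode")
        if mode is not None and mode not in FORCE_MODES:
            raise TraceValidationError(f"unknown force_mode {mode!r}")

    @property
    def duration(self) -> float:
        return self.time[-1] - self.time[0] + 1.0 / self.sample_rate


@dataclass
class ContourTrajectory:
    """Unpackaged tether contour length L0(t); decreases as DNA is packaged."""

    time: np.ndarray
    contour: np.ndarray     # nm of not-yet-packaged tether contour
    force: np.ndarray
    sample_rate: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.contour = np.asarray(self.contour, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        self.validate()

    def validate(self) -> None:
        n = self.time.size
        if n == 0:
            raise TraceValidationError("empty trajectory")
        if self.contour.size != n or self.force.size != n:
            raise TraceValidationError("time/contour/force lengths differ")
        if self.sample_rate <= 0:
            raise TraceValidationError("sample_rate must be positive")
        if np.any(np.diff(self.time) <= 0):
            raise TraceValidationError("time must be strictly increasing")
        _check_grid(self.time, self.sample_rate)
        if np.any(self.contour <= 0):
            raise TraceValidationError("contour must be > 0")


def packaged_length(traj: ContourTrajectory) -> np.ndarray:
    """Packaged length p(t) = L0(0) - L0(t), positive-forward convention."""
    return traj.contour[0] - traj.contour


@dataclass(frozen=True)
class SubstrateSpec:
    """Helical and elastic parameters of one of the four duplex substrates.

    ``pitch`` is the crystallographic helical pitch (nm/turn); ``burst_size``
    is the measured translocation burst (nm), which closely tracks but does
    not exactly equal the pitch.  The motor's slip quantum on RNA-tracking
    substrates equals ``burst_size``.
    """

    name: str
    periodicity: float        # bp/turn
    pitch: float              # nm/turn
    burst_size: float         # nm per dwell-burst cycle
    tracking_strand: str      # "DNA" or "RNA"
    persistence_length: float  # nm
    stretch_modulus: float     # pN
    dwell_mean: float          # s, mean ATP-loading dwell at 0.25 mM ATP

    def __post_init__(self):
        if self.pitch <= 0 or self.periodicity <= 0:
            raise ValueError("pitch and periodicity must be positive")
        if self.tracking_strand not in ("DNA", "RNA"):
            raise ValueError("tracking_strand must be 'DNA' or 'RNA'")

    @property
    def rise(self) -> float:
        """Axial rise per base pair (nm/bp)."""
        return self.pitch / self.periodicity


def default_substrates() -> list[SubstrateSpec]:
    """The four duplexes: B-form dsDNA, the two DNA/RNA hybrids, A-form dsRNA.

    Hybrids share the DNA/RNA-hybrid elastic parameters.  Dwell means are the
    per-substrate measured values at saturating (0.25 mM) ATP.
    """
    return [
        SubstrateSpec("dsDNA", 10.4, 3.52, 3.40, "DNA", 50.0, 900.0, 0.086),
        SubstrateSpec("DTS_hybrid", 10.8, 3.11, 3.09, "DNA", 35.0, 700.0, 0.105),
        SubstrateSpec("RTS_hybrid", 10.8, 3.11, 3.02, "RNA", 35.0, 700.0, 0.085),
        SubstrateSpec("dsRNA", 11.0, 3.02, 2.70, "RNA", 40.0, 500.0, 0.083),
    ]


def get_substrate(name: str) -> SubstrateSpec:
    for s in default_substrates():
        if s.name == name:
            return s
    raise KeyError(f"unknown substrate {name!r}; expected one of "
                   f"{[s.name for s in default_substrates()]}")


# ---------------------------------------------------------------------------
# TSV I/O: '#'-prefixed key=value metadata lines, then a header naming the
# columns time_s, extension_nm, force_pN.

_COLUMNS = ("time_s", "extension_nm", "force_pN")
_META_CASTS = {
    "sample_rate": float,
    "atp_mM": float,
    "trap_stiffness_pN_per_nm": float,
    "seed": int,
}


def _parse_meta_value(key: str, raw: str):
    cast = _META_CASTS.get(key)
    if cast is not None:
        return cast(raw)
    return raw


def read_trace(path) -> Trace:
    """Read a TSV trace file into a validated :class:`Trace`.

    Metadata absent from the file defaults to: sample_rate inferred from the
    median time step; other keys simply missing from ``meta``.
    """
    path = Path(path)
    meta: dict = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            body = line[1:].strip()
            if "=" in body:
                key, _, raw = body.partition("=")
                meta[key.strip()] = _parse_meta_value(key.strip(), raw.strip())
            pos = fh.tell()
            line = fh.readline()
        header = line.strip().split("\t")
        if tuple(header[:3]) != _COLUMNS:
            raise TraceFormatError(
                f"{path}: malformed header {header!r}; expected columns {_COLUMNS}"
            )
        data = np.loadtxt(fh, delimiter="\t", ndmin=2)
    if data.size == 0:
        raise TraceValidationError(f"{path}: no data rows")
    time, extension, force = data[:, 0], data[:, 1], data[:, 2]
    sample_rate = meta.pop("sample_rate", None)
    if sample_rate is None:
        if time.size < 2:
            raise TraceValidationError(f"{path}: cannot infer sample_rate from one row")
        sample_rate = 1.0 / float(np.median(np.diff(time)))
    return Trace(time, extension, force, float(sample_rate), meta)


def write_trace(trace: Trace, path) -> None:
    """Write a Trace as TSV, losslessly round-trippable via :func:`read_trace`."""
    trace.validate()
    path = Path(path)
    buf = io.StringIO()
    buf.write(f"# sample_rate = {trace.sample_rate!r}\n")
    for key, value in trace.meta.items():
        buf.write(f"# {key} = {value}\n")
    buf.write("\t".join(_COLUMNS) + "\n")
    np.savetxt(
        buf,
        np.column_stack([trace.time, trace.extension, trace.force]),
        delimiter="\t",
        fmt="%.9f",
    )
    path.write_text(buf.getvalue())


def contour_trajectory_like(trace: Trace, contour: np.ndarray) -> ContourTrajectory:
    """Build a ContourTrajectory sharing a Trace's grid and metadata."""
    return ContourTrajectory(trace.time, contour, trace.force,
                             trace.sample_rate, dict(trace.meta))
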