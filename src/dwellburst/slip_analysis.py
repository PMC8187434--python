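"""Reverse-translocation (burst-sized slipping) event detection and stats.

Events are maximal runs of consecutive backward steps in a step fit.  Each
event is sectioned into a *start dwell* (the plateau before the first
backward step), *slipping dwells* (plateaus between backward steps), and an
*end dwell* (the plateau after the last backward step).  The *mid-time* is
the time from the first to the last backward change point, so for events
with >= 2 slips the identity total_length = slipping_velocity * mid_time
holds exactly.

Slips are burst-quantized, so a backward step whose magnitude is close to
k >= 2 bursts is interpreted as k slips whose separating dwell fell below
the stepfinder's resolution; it is split into k equal recorded slips with a
zero intervening slipping dwell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .stepfinding import StepFit

__all__ = ["SlipEvent", "SlipCohortStats", "detect_slip_events", "cohort_stats"]

#: backward steps smaller than this fraction of the expected burst are
#: treated as stepfinder noise and do not open events
NOISE_FLOOR_FRAC = 0.5


@dataclass
class SlipEvent:
    start_dwell: float            # s (NaN when the event touches the edge)
    slip_sizes: np.ndarray        # nm magnitudes, one per slip
    slipping_dwells: np.ndarray   # s, between consecutive slips
    end_dwell: float              # s
    mid_time: float               # s, first to last slip change point
    step_indices: np.ndarray      # indices into the StepFit's step list
    at_edge: bool = False         # missing start or end dwell
    off_size: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=bool))

    @property
    def n_slips(self) -> int:
        return int(self.slip_sizes.size)

    @property
    def total_length(self) -> float:
        return float(self.slip_sizes.sum())

    @property
    def slipping_velocity(self) -> float:
        """nm/s over the slipping section; NaN for single-slip events."""
        if self.n_slips < 2 or self.mid_time == 0:
            return float("nan")
        return self.total_length / self.mid_time


@dataclass
class SlipCohortStats:
    event_frequency: float        # events per second of packaging
    n_events: int
    summaries: dict               # field -> {median, mean, sem, n}
    raw: dict                     # field -> ndarray


def _split_quanta(size: float, expected_burst: float, tolerance: float) -> int:
    """Number of burst quanta a backward step represents (>= 1)."""
    k = int(round(size / expected_burst))
    if k >= 2 and abs(size - k * expected_burst) <= tolerance * expected_burst * k:
        return k
    return 1


def detect_slip_events(fit: StepFit, expected_burst: float,
                       tolerance: float = 0.3) -> list:
    """Find reverse-translocation events in a step fit.

    Backward steps below ``NOISE_FLOOR_FRAC * expected_burst`` in magnitude
    are ignored (stepfinder noise).  Recorded slips outside
    ``(1 +/- tolerance) * expected_burst`` are retained but flagged in
    ``off_size``.  Events touching the trace edges are flagged ``at_edge``
    (their missing dwells are reported as NaN).  An empty list (no backward
    steps) is a valid result, not an error.
    """
    if expected_burst <= 0:
        raise ValueError("expected_burst must be positive")
    steps = fit.step_sizes
    if steps.size == 0:
        return []
    backward = steps < -NOISE_FLOOR_FRAC * expected_burst
    cp_times = fit.change_point_times()
    dwells = fit.dwell_durations

    events = []
    i = 0
    while i < steps.size:
        if not backward[i]:
            i += 1
            continue
        j = i
        while j + 1 < steps.size and backward[j + 1]:
            j += 1
        sizes, slipping, indices = [], [], []
        for idx in range(i, j + 1):
            k = _split_quanta(-steps[idx], expected_burst, tolerance)
            sizes.extend([-steps[idx] / k] * k)
            indices.extend([idx] * k)
            # unresolved sub-slips get zero separating dwell
            slipping.extend([0.0] * (k - 1))
            if idx < j:
                slipping.append(dwells[idx + 1])
        sizes = np.asarray(sizes)
        at_edge = (i == 0) or (j == steps.size - 1)
        start = dwells[i] if i > 0 else float("nan")
        end = dwells[j + 1] if j < steps.size - 1 else float("nan")
        mid = float(cp_times[j] - cp_times[i])
        lo, hi = (1 - tolerance) * expected_burst, (1 + tolerance) * expected_burst
        off = (sizes < lo) | (sizes > hi)
        events.append(SlipEvent(float(start), sizes, np.asarray(slipping),
                                float(end), mid, np.asarray(indices, dtype=int),
                                at_edge, off))
        i = j + 1
    return events


def cohort_stats(events: list, packaging_time: float) -> SlipCohortStats:
    """Per-cohort summary of slip events.

    Frequency is events per second of packaging.  Edge events are excluded
    from start/end-dwell statistics but retained everywhere else.
    """
    if packaging_time <= 0:
        raise ValueError("packaging_time must be positive")
    freq = len(events) / packaging_time
    interior = [e for e in events if not e.at_edge]
    raw = {
        "start_dwell": np.array([e.start_dwell for e in interior]),
        "end_dwell": np.array([e.end_dwell for e in interior]),
        "slipping_dwell": (np.concatenate([e.slipping_dwells for e in events])
                           if events else np.empty(0)),
        "total_length": np.array([e.total_length for e in events]),
        "mid_time": np.array([e.mid_time for e in events]),
        "slipping_velocity": np.array([e.slipping_velocity for e in events
                                       if e.n_slips >= 2]),
        "n_slips": np.array([e.n_slips for e in events], dtype=float),
        "slip_size": (np.concatenate([e.slip_sizes for e in events])
                      if events else np.empty(0)),
    }
    summaries = {}
    for key, arr in raw.items():
        arr = arr[np.isfinite(arr)] if arr.size else arr
        if arr.size == 0:
            summaries[key] = {"median": float("nan"), "mean": float("nan"),
                              "sem": float("nan"), "n": 0}
        else:
            sem = float(np.std(arr, ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else 0.0
            summaries[key] = {"median": float(np.median(arr)),
                              "mean": float(np.mean(arr)),
                              "sem": sem, "n": int(arr.size)}
    return SlipCohortStats(freq, len(events), summaries, raw)
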