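"""Extensible worm-like chain (XWLC) elasticity: force-extension model,
contour-length conversion, and pulling-curve fitting.

The high-force interpolation formula is used throughout,

    x(F) = L0 * [1 - (1/2) * sqrt(kT / (F * P)) + F / S],

with persistence length P (nm), stretch modulus S (pN), contour length L0
(nm) and thermal energy kT (pN nm, default 4.114 at 25 degC).  It is valid
in the >= 5 pN window where all analysis here takes place, and is linear in
L0, so the extension -> contour inversion is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import least_squares

from .trace_model import ContourTrajectory, Trace, contour_trajectory_like

__all__ = [
    "KT_ROOM",
    "WlcParams",
    "xwlc_extension",
    "contour_from_extension",
    "contour_trajectory",
    "fit_pulling_curve",
    "PullingFit",
]

#: kT at 25 degC in pN nm
KT_ROOM = 4.114

#: B-form DNA rise used to seed contour-length guesses (nm/bp)
B_DNA_RISE = 0.34


@dataclass(frozen=True)
class WlcParams:
    persistence_length: float   # P, nm
    stretch_modulus: float      # S, pN
    contour_length: float       # L0, nm
    kT: float = KT_ROOM         # pN nm

    def __post_init__(self):
        if min(self.persistence_length, self.stretch_modulus,
               self.contour_length, self.kT) <= 0:
            raise ValueError("all WLC parameters must be strictly positive")
        if self.persistence_length < 1.0:
            raise ValueError("persistence length below 1 nm is unphysical here")
        if self.stretch_modulus < 50.0:
            raise ValueError("stretch modulus below 50 pN is unphysical here")


def _bracket(force, P, S, kT):
    """The dimensionless factor x/L0 = 1 - 0.5*sqrt(kT/(F P)) + F/S."""
    force = np.asarray(force, dtype=float)
    return 1.0 - 0.5 * np.sqrt(kT / (force * P)) + force / S


def xwlc_extension(force, params: WlcParams):
    """End-to-end extension (nm) at tension ``force`` (pN).

    Strictly increasing in force; requires force > 0.
    """
    force = np.asarray(force, dtype=float)
    if np.any(force <= 0):
        raise ValueError("xwlc_extension requires force > 0")
    out = params.contour_length * _bracket(force, params.persistence_length,
                                           params.stretch_modulus, params.kT)
    return out if out.ndim else float(out)


def contour_from_extension(extension, force, params: WlcParams):
    """Invert the XWLC for contour length: L0 = x / (x/L0 factor).

    Exact inverse of :func:`xwlc_extension` in L0 (which enters linearly).
    ``params.contour_length`` is ignored.
    """
    force = np.asarray(force, dtype=float)
    extension = np.asarray(extension, dtype=float)
    if np.any(force <= 0):
        raise ValueError("contour_from_extension requires force > 0")
    b = _bracket(force, params.persistence_length, params.stretch_modulus, params.kT)
    if np.any(b <= 0):
        raise ValueError("XWLC bracket term non-positive: force too low for the "
                         "high-force interpolation regime")
    out = extension / b
    return out if out.ndim else float(out)


def contour_trajectory(trace: Trace, params: WlcParams) -> ContourTrajectory:
    """Convert a raw Trace sample-wise to unpackaged contour length."""
    contour = contour_from_extension(trace.extension, trace.force, params)
    return contour_trajectory_like(trace, contour)


@dataclass
class PullingFit:
    params: WlcParams
    residual_rms: float         # nm
    n_points: int
    force_range: tuple          # (min, max) pN
    narrow_range: bool          # True if max/min force < 2 (warning flag)
    converged: bool


def fit_pulling_curve(force, extension, kT: float = KT_ROOM,
                      p0: WlcParams | None = None) -> PullingFit:
    """Least-squares XWLC fit of a pulling curve for (P, S, L0).

    Unweighted least squares in extension; forces are treated as exact
    (force noise is far below extension noise in dual-trap data).  Requires
    at least 20 points; a force span below a factor of 2 sets the
    ``narrow_range`` diagnostic flag.
    """
    force = np.asarray(force, dtype=float)
    extension = np.asarray(extension, dtype=float)
    if force.size != extension.size:
        raise ValueError("force and extension must have equal length")
    if force.size < 20:
        raise ValueError("need >= 20 points to fit a pulling curve")
    if np.any(force <= 0):
        raise ValueError("pulling-curve forces must be positive")
    fmin, fmax = float(force.min()), float(force.max())
    narrow = fmax / fmin < 2.0

    if p0 is None:
        # seed L0 from the top of the curve assuming near-inextensible WLC
        l0_guess = float(extension[np.argmax(force)]) / 0.97
        p0 = WlcParams(50.0, 900.0, l0_guess, kT)

    def resid(theta):
        P, S, L0 = theta
        return L0 * _bracket(force, P, S, kT) - extension

    sol = least_squares(
        resid,
        x0=[p0.persistence_length, p0.stretch_modulus, p0.contour_length],
        bounds=([1.0, 50.0, 1.0], [500.0, 5000.0, 1e6]),
        method="trf",
    )
    if not sol.success:
        raise RuntimeError(f"pulling-curve fit did not converge: {sol.message}; "
                           f"last iterate {sol.x}")
    P, S, L0 = sol.x
    rms = float(np.sqrt(np.mean(sol.fun ** 2)))
    return PullingFit(WlcParams(P, S, L0, kT), rms, force.size,
                      (fmin, fmax), narrow, True)
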