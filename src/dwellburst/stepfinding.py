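"""Change-point stepfinding, dwell/step statistics, and step-size
distributions.

Two stepfinders share the :class:`StepFit` contract:

* :func:`kv_stepfind` — greedy change-point placement accepting a new step
  only if it lowers the Schwarz information criterion
  ``SIC = sensitivity * m * ln(n) + n * ln(SSE / n)`` (m = parameter count);
  deterministic, no level assumptions.
* :func:`hmm_stepfind` — Viterbi decoding through a ladder of equally
  spaced Gaussian-emission levels with banded transitions; plateau levels
  are re-estimated from the data after segmentation so recovered step sizes
  are not quantized to the ladder.

Dwell durations are summarized by maximum-likelihood gamma fits (the number
of rate-limiting nucleotide-exchange events sets the shape), and step-size
distributions from two substrates can be aligned and differenced to expose
substrate-specific step populations.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import curve_fit

__all__ = [
    "StepFit", "GammaFit", "DifferentialStepDist",
    "decimate_mean", "kv_stepfind", "hmm_stepfind",
    "extract_step_distribution", "differential_distribution",
    "bimodal_modes", "fit_gamma_dwells",
]

#: minimum plateau length (samples); steps closer than this are merged
MIN_PLATEAU = 2
_SSE_FLOOR = 1e-12


@dataclass
class StepFit:
    """Piecewise-constant fit of a packaged-length series."""

    change_point_indices: np.ndarray   # sample index of first sample of each new plateau
    plateau_means: np.ndarray          # nm, len = change points + 1
    dwell_durations: np.ndarray        # s, per plateau
    step_sizes: np.ndarray             # signed nm, positive = packaging
    method: str                        # "KV" or "HMM"
    sensitivity: float
    sample_rate: float
    no_steps: bool = False

    @property
    def n_steps(self) -> int:
        return int(self.step_sizes.size)

    def change_point_times(self) -> np.ndarray:
        return self.change_point_indices / self.sample_rate


@dataclass
class GammaFit:
    shape: float
    scale: float          # s
    mean: float           # s, = shape * scale
    log_likelihood: float
    ks_pvalue: float


@dataclass
class DifferentialStepDist:
    grid: np.ndarray          # nm, common bin grid
    density_A: np.ndarray
    density_B: np.ndarray
    difference: np.ndarray    # density_A - density_B
    lobe_means: np.ndarray    # up to two Gaussians fit to the B-excess
    lobe_sigmas: np.ndarray
    lobe_amplitudes: np.ndarray


def decimate_mean(y: np.ndarray, factor: int) -> np.ndarray:
    """Block-average decimation (anti-aliasing for white noise)."""
    y = np.asarray(y, dtype=float)
    if factor <= 1:
        return y
    n = (y.size // factor) * factor
    return y[:n].reshape(-1, factor).mean(axis=1)


# ---------------------------------------------------------------------------
# Kalafut-Visscher greedy SIC stepfinder

def _sse(cum, cum2, s, e):
    m = (cum[e] - cum[s]) / (e - s)
    return (cum2[e] - cum2[s]) - (e - s) * m * m


def _best_split(cum, cum2, s, e, min_plateau=MIN_PLATEAU):
    """Best single change point inside [s, e); earliest index wins ties.

    Returns (gain, k) with gain = SSE(s,e) - SSE(s,k) - SSE(k,e), or
    (None, None) if the segment is too short to split with min_plateau.
    """
    if e - s < 2 * min_plateau:
        return None, None
    ks = np.arange(s + min_plateau, e - min_plateau + 1)
    left_n = ks - s
    right_n = e - ks
    left_sum = cum[ks] - cum[s]
    right_sum = cum[e] - cum[ks]
    left_sse = (cum2[ks] - cum2[s]) - left_sum ** 2 / left_n
    right_sse = (cum2[e] - cum2[ks]) - right_sum ** 2 / right_n
    cost = left_sse + right_sse
    j = int(np.argmin(cost))
    gain = _sse(cum, cum2, s, e) - cost[j]
    return float(gain), int(ks[j])


def kv_stepfind(series: np.ndarray, sensitivity: float = 2.0,
                sample_rate: float = 1.0,
                min_plateau: int = MIN_PLATEAU) -> StepFit:
    """Greedy Kalafut-Visscher change-point fit.

    Steps are added one at a time at the globally best placement, accepted
    while they lower ``sensitivity * m * ln(n) + n * ln(SSE/n)``; larger
    sensitivity inflates the penalty and yields fewer steps.  Deterministic:
    ties break to the earlier index.  ``min_plateau`` (samples) is the
    shortest plateau the fit may produce; raising it above the default of 2
    suppresses short spike plateaus on noisy data.

    The default sensitivity of 2.0 holds the false-positive rate on flat
    Gaussian series of 10^4 samples below 5% while recovering sub-nanometre
    staircases essentially always; at 1.0 the plain Schwarz criterion
    over-segments long noisy series (the best-split statistic grows like
    the supremum of a squared Brownian bridge, which exceeds ln(n) with
    appreciable probability).
    """
    y = np.asarray(series, dtype=float)
    n = y.size
    if n < 10:
        raise ValueError("need >= 10 samples for stepfinding")
    if sensitivity <= 0:
        raise ValueError("sensitivity must be positive")
    cum = np.concatenate([[0.0], np.cumsum(y)])
    cum2 = np.concatenate([[0.0], np.cumsum(y * y)])
    log_n = np.log(n)
    penalty = sensitivity * log_n
    # floor scales with the data so float cancellation in the cumulative-sum
    # SSE cannot masquerade as structure on noiseless series
    sse_floor = max(_SSE_FLOOR, 1e-12 * cum2[-1])

    def sic_term(sse):
        return n * np.log(max(sse, sse_floor) / n)

    segments = {(0, n): _sse(cum, cum2, 0, n)}
    heap = []
    gain, k = _best_split(cum, cum2, 0, n, min_plateau)
    if gain is not None:
        heapq.heappush(heap, (-gain, 0, n, k))
    total_sse = segments[(0, n)]
    change_points = []

    while heap:
        neg_gain, s, e, k = heapq.heappop(heap)
        if (s, e) not in segments:
            continue
        new_sse = total_sse + neg_gain  # gain = -neg_gain subtracted
        if sic_term(new_sse) + penalty >= sic_term(total_sse):
            break
        seg_sse = segments.pop((s, e))
        left_sse = _sse(cum, cum2, s, k)
        right_sse = _sse(cum, cum2, k, e)
        segments[(s, k)] = left_sse
        segments[(k, e)] = right_sse
        total_sse = total_sse - seg_sse + left_sse + right_sse
        change_points.append(k)
        for a, b in ((s, k), (k, e)):
            g, kk = _best_split(cum, cum2, a, b, min_plateau)
            if g is not None:
                heapq.heappush(heap, (-g, a, b, kk))

    change_points = np.asarray(sorted(change_points), dtype=int)
    return _build_fit(y, change_points, "KV", sensitivity, sample_rate)


def _build_fit(y, change_points, method, sensitivity, sample_rate):
    bounds = np.concatenate([[0], change_points, [y.size]])
    means = np.array([y[a:b].mean() for a, b in zip(bounds[:-1], bounds[1:])])
    dwells = np.diff(bounds) / sample_rate
    steps = np.diff(means)
    return StepFit(change_points, means, dwells, steps, method,
                   sensitivity, sample_rate, no_steps=change_points.size == 0)


# ---------------------------------------------------------------------------
# HMM (ladder Viterbi) stepfinder

def _banded_viterbi(y, levels, sigma, p_stay, band):
    """Viterbi path through `levels` with transitions limited to +/-band."""
    n_states = levels.size
    shifts = np.arange(-band, band + 1)
    log_move = np.log((1.0 - p_stay) / (2 * band))
    log_stay = np.log(p_stay)
    trans = np.where(shifts == 0, log_stay, log_move)

    inv2s2 = 1.0 / (2.0 * sigma * sigma)
    score = -((y[0] - levels) ** 2) * inv2s2
    back = np.empty((y.size, n_states), dtype=np.int16)
    back[0] = 0
    cand = np.full((shifts.size, n_states), -np.inf)
    for t in range(1, y.size):
        for si, sh in enumerate(shifts):
            if sh == 0:
                cand[si] = score + trans[si]
            elif sh > 0:
                cand[si, sh:] = score[:-sh] + trans[si]
                cand[si, :sh] = -np.inf
            else:
                cand[si, :sh] = score[-sh:] + trans[si]
                cand[si, sh:] = -np.inf
        best = np.argmax(cand, axis=0)
        score = cand[best, np.arange(n_states)] - (y[t] - levels) ** 2 * inv2s2
        back[t] = shifts[best]
    path = np.empty(y.size, dtype=int)
    path[-1] = int(np.argmax(score))
    for t in range(y.size - 1, 0, -1):
        path[t - 1] = path[t] - back[t, path[t]]
    return path, float(score.max())


def _ladder_offset(y, spacing):
    """Offset minimizing squared distance of samples to the ladder."""
    grid = np.linspace(0.0, spacing, 21, endpoint=False)
    res = np.mod(y[None, :] - grid[:, None] + spacing / 2, spacing) - spacing / 2
    return float(grid[np.argmin((res ** 2).sum(axis=1))])


def hmm_stepfind(series: np.ndarray, level_spacing_hint: float | None = None,
                 n_levels: int | None = None, sample_rate: float = 1.0,
                 sigma: float | None = None, p_stay: float = 0.99,
                 band: int = 4,
                 spacing_grid=(0.3, 1.2, 19)) -> StepFit:
    """Hidden-Markov staircase fit.

    The emission means form an equally spaced ladder spanning the data; the
    ladder quantum is half the expected step so that substrates mixing full
    and fractional steps remain representable.  When no spacing hint is
    given, the hint is chosen by Viterbi likelihood over a grid (default 19
    spacings in [0.3, 1.2] nm).  After decoding, plateau means are
    re-estimated from the data between change points, and plateaus shorter
    than the minimum length are merged into their nearer neighbour.
    """
    y = np.asarray(series, dtype=float)
    if y.size < 10:
        raise ValueError("need >= 10 samples for stepfinding")
    if np.var(y) == 0:
        return _build_fit(y, np.asarray([], dtype=int), "HMM", 1.0, sample_rate)
    if sigma is None:
        sigma = float(np.std(np.diff(y)) / np.sqrt(2))
        sigma = max(sigma, 1e-6)

    def decode(spacing):
        quantum = spacing / 2.0
        offset = _ladder_offset(y, quantum)
        lo = np.floor((y.min() - offset) / quantum) - 1
        hi = np.ceil((y.max() - offset) / quantum) + 1
        levels = offset + np.arange(lo, hi + 1) * quantum
        if n_levels is not None and levels.size > max(n_levels, 3):
            pass  # ladder must span the data; n_levels is advisory
        return _banded_viterbi(y, levels, sigma, p_stay, band)

    if level_spacing_hint is None:
        lo, hi, num = spacing_grid
        best_ll, best_path = -np.inf, None
        for spacing in np.linspace(lo, hi, int(num)):
            path, ll = decode(spacing)
            if ll > best_ll:
                best_ll, best_path = ll, path
        path = best_path
    else:
        if level_spacing_hint <= 0:
            raise ValueError("level_spacing_hint must be positive")
        path, _ = decode(level_spacing_hint)

    cps = np.nonzero(np.diff(path))[0] + 1
    cps = _merge_short_plateaus(y, cps)
    return _build_fit(y, cps, "HMM", 1.0, sample_rate)


def _merge_short_plateaus(y, cps):
    """Drop change points bounding plateaus shorter than MIN_PLATEAU."""
    cps = list(cps)
    changed = True
    while changed and cps:
        changed = False
        bounds = [0] + cps + [y.size]
        lengths = np.diff(bounds)
        short = np.nonzero(lengths < MIN_PLATEAU)[0]
        if short.size:
            i = int(short[0])
            # remove the change point that merges the short plateau with the
            # neighbour of closer mean
            left_cp = i - 1   # index into cps bounding plateau i on the left
            right_cp = i      # on the right
            if left_cp < 0:
                cps.pop(right_cp)
            elif right_cp >= len(cps):
                cps.pop(left_cp)
            else:
                seg = y[bounds[i]:bounds[i + 1]].mean()
                left_mean = y[bounds[i - 1]:bounds[i]].mean()
                right_mean = y[bounds[i + 1]:bounds[i + 2]].mean()
                if abs(seg - left_mean) <= abs(seg - right_mean):
                    cps.pop(left_cp)
                else:
                    cps.pop(right_cp)
            changed = True
    return np.asarray(cps, dtype=int)


# ---------------------------------------------------------------------------
# step-size distributions

def extract_step_distribution(fits, forward_only: bool = False,
                              bin_width: float = 0.05):
    """Pooled step-size density over a list of StepFits.

    Returns (bin_centers, density); bins are centered on multiples of
    ``bin_width``.
    """
    if not fits:
        raise ValueError("need at least one StepFit")
    steps = np.concatenate([f.step_sizes for f in fits if f.step_sizes.size])
    if forward_only:
        steps = steps[steps > 0]
    if steps.size == 0:
        raise ValueError("no steps to histogram")
    lo = np.floor(steps.min() / bin_width) - 0.5
    hi = np.ceil(steps.max() / bin_width) + 0.5
    edges = np.arange(lo, hi + 1) * bin_width
    density, edges = np.histogram(steps, bins=edges, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, density


def bimodal_modes(centers: np.ndarray, density: np.ndarray,
                  min_separation: float = 0.2):
    """Major and minor modes of a bimodal step-size density.

    The major mode is the global maximum; the minor mode is the highest
    density at least ``min_separation`` (nm) away from the major mode.
    Returns (major, minor); minor is NaN if nothing qualifies.
    """
    centers = np.asarray(centers, dtype=float)
    density = np.asarray(density, dtype=float)
    major = float(centers[np.argmax(density)])
    away = np.abs(centers - major) >= min_separation
    if not np.any(away) or density[away].max() <= 0:
        return major, float("nan")
    minor = float(centers[away][np.argmax(density[away])])
    return major, minor


def _two_gauss(x, a1, m1, s1, a2, m2, s2):
    return (a1 * np.exp(-0.5 * ((x - m1) / s1) ** 2)
            + a2 * np.exp(-0.5 * ((x - m2) / s2) ** 2))


def differential_distribution(grid_A, density_A, grid_B, density_B) -> DifferentialStepDist:
    """Align two step-size densities on a common grid and difference them.

    Both densities are resampled by linear interpolation onto the
    overlapping grid and renormalized to unit area; ``difference`` is
    density_A - density_B.  Up to two Gaussians are fit to the B-excess
    (the positive part of density_B - density_A), exposing step populations
    present in B but not in A.
    """
    grid_A = np.asarray(grid_A, dtype=float)
    grid_B = np.asarray(grid_B, dtype=float)
    lo = max(grid_A.min(), grid_B.min())
    hi = min(grid_A.max(), grid_B.max())
    if hi <= lo:
        raise ValueError("step-size distributions have disjoint supports")
    step = min(np.diff(grid_A).min(), np.diff(grid_B).min())
    grid = np.arange(lo, hi + step / 2, step)
    dA = np.interp(grid, grid_A, density_A)
    dB = np.interp(grid, grid_B, density_B)
    for d in (dA, dB):
        area = np.trapezoid(d, grid)
        if area > 0:
            d /= area
    diff = dA - dB
    excess = np.clip(dB - dA, 0.0, None)

    lobe_means = np.empty(0)
    lobe_sigmas = np.empty(0)
    lobe_amps = np.empty(0)
    if excess.max() > 0:
        peak = grid[np.argmax(excess)]
        p0 = [excess.max(), peak, 0.1, excess.max() / 3, peak + 0.85, 0.1]
        try:
            popt, _ = curve_fit(
                _two_gauss, grid, excess, p0=p0,
                bounds=([0, grid[0], 0.01, 0, grid[0], 0.01],
                        [np.inf, grid[-1], 2.0, np.inf, grid[-1], 2.0]),
                maxfev=20000)
            a1, m1, s1, a2, m2, s2 = popt
            order = np.argsort([m1, m2])
            lobe_means = np.array([m1, m2])[order]
            lobe_sigmas = np.array([s1, s2])[order]
            lobe_amps = np.array([a1, a2])[order]
        except RuntimeError:
            pass
    return DifferentialStepDist(grid, dA, dB, diff, lobe_means,
                                lobe_sigmas, lobe_amps)


# ---------------------------------------------------------------------------
# gamma dwell fits

def fit_gamma_dwells(dwells) -> GammaFit:
    """Maximum-likelihood gamma fit of dwell durations (location fixed at 0).

    The fitted shape estimates the number of rate-limiting sequential
    events per dwell.  Reports a Kolmogorov-Smirnov goodness-of-fit p-value.
    """
    dwells = np.asarray(dwells, dtype=float)
    if dwells.size < 30:
        raise ValueError("need >= 30 dwells for a gamma fit")
    if np.any(dwells <= 0):
        raise ValueError("all dwells must be positive")
    if np.std(dwells) == 0:
        raise ValueError("constant dwells: gamma shape diverges")
    shape, loc, scale = stats.gamma.fit(dwells, floc=0)
    ll = float(np.sum(stats.gamma.logpdf(dwells, shape, loc=0, scale=scale)))
    ks = stats.kstest(dwells, "gamma", args=(shape, 0, scale))
    return GammaFit(float(shape), float(scale), float(shape * scale),
                    ll, float(ks.pvalue))
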