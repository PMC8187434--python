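"""End-to-end orchestration: simulate cohorts, run the analysis chain,
and build per-substrate summary tables.

All randomness flows from one top-level seed, expanded deterministically
per trace with ``numpy.random.SeedSequence(seed).spawn`` (each child's
first 31-bit state word is the per-trace seed); the resolved configuration
and its hash accompany every output so runs can be reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .elasticity import WlcParams, contour_trajectory
from .periodicity import grade_periodicity, selective_average, windowed_pwd
from .simulate import (NoiseParams, default_motor_params, default_slip_params,
                       render_trace, simulate_packaging)
from .slip_analysis import cohort_stats, detect_slip_events
from .stepfinding import decimate_mean, extract_step_distribution, \
    fit_gamma_dwells, kv_stepfind
from .trace_model import (Trace, default_substrates, get_substrate,
                          packaged_length, read_trace, write_trace)
from .velocity import fit_velocity_mixture, sg_velocity, velocity_histogram

__all__ = ["DEFAULT_CONFIG", "PUBLISHED_VALUES", "resolve_config", "expand_seeds",
           "cmd_simulate", "cmd_analyze", "cmd_table1", "analyze_cohort",
           "simulate_cohort", "slip_free_packaged", "highforce_config",
           "recover_burst_size", "recover_step_distribution",
           "recover_wlc_params"]

DEFAULT_CONFIG = {
    "substrates": ["dsDNA", "DTS_hybrid", "RTS_hybrid", "dsRNA"],
    "n_traces": 3,
    "duration_s": 20.0,
    "atp_mM": 0.25,
    "force_mode": "semi_passive",
    "force_band": [7.0, 12.0],
    "force_setpoint": 10.0,
    "motor": {},        # MotorParams overrides
    "slips": {},        # SlipParams overrides
    "noise": {},        # NoiseParams overrides
    "analysis": {
        "decimate_to_hz": 500.0,
        "kv_sensitivity": 2.0,
        "kv_min_plateau_s": 0.01,
        "sg_width": 301,
        "pwd_window_s": 5.0,
        "top_fraction": 0.30,
        "slip_tolerance": 0.3,
    },
}

#: published per-substrate measurements (mean +/- SEM where applicable);
#: used only for side-by-side comparison tables
PUBLISHED_VALUES = {
    "dsDNA": {"burst_nm": 3.39, "dwell_ms": 86.0, "velocity_nm_s": 36.6},
    "DTS_hybrid": {"burst_nm": 3.09, "dwell_ms": 105.0, "velocity_nm_s": 29.4},
    "RTS_hybrid": {"burst_nm": 3.02, "dwell_ms": 85.0, "velocity_nm_s": 33.9},
    "dsRNA": {"burst_nm": 2.70, "dwell_ms": 83.0, "velocity_nm_s": 30.6},
}


class ConfigError(ValueError):
    pass


def highforce_config(**overrides) -> dict:
    """Configuration preset for step-resolving high-force experiments.

    Against 30-35 pN of opposing load the motor slows (longer dwells,
    slower power strokes), which is what makes individual steps resolvable;
    traces are taken in force-feedback mode and the effective plateau noise
    is 0.2 nm.
    """
    cfg = {
        "force_mode": "force_feedback",
        "force_setpoint": 32.0,
        "motor": {"dwell_mean": 0.25, "burst_step_rate": 15.0},
        "noise": {"drag_coefficient": 0.0, "measurement_sigma": 0.2},
    }
    cfg.update(overrides)
    return cfg


def resolve_config(config: dict | None) -> dict:
    """Merge a user config over the defaults; unknown keys are an error."""
    config = config or {}
    bad = set(config) - set(DEFAULT_CONFIG)
    if bad:
        raise ConfigError(f"unknown config keys: {sorted(bad)}")
    merged = {**DEFAULT_CONFIG, **config}
    merged["analysis"] = {**DEFAULT_CONFIG["analysis"],
                          **(config.get("analysis") or {})}
    bad = set(merged["analysis"]) - set(DEFAULT_CONFIG["analysis"])
    if bad:
        raise ConfigError(f"unknown analysis config keys: {sorted(bad)}")
    return merged


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        yaml.safe_dump(config, sort_keys=True).encode()).hexdigest()[:16]


def expand_seeds(seed: int, n: int) -> list:
    """Deterministic per-trace seeds below 2**31 from one top-level seed."""
    children = np.random.SeedSequence(seed).spawn(n)
    return [int(c.generate_state(1)[0] % (2 ** 31)) for c in children]


# ---------------------------------------------------------------------------

def simulate_cohort(substrate_name: str, config: dict, seed: int):
    """Simulate ``n_traces`` rendered traces plus ground truths for one
    substrate.  Returns (traces, trajectories, ground_truths)."""
    config = resolve_config(config)
    substrate = get_substrate(substrate_name)
    motor = default_motor_params(substrate, atp_mM=config["atp_mM"],
                                 **config["motor"])
    slips = default_slip_params(substrate, **config["slips"])
    noise = NoiseParams(**config["noise"])
    if config["force_mode"] == "semi_passive":
        setpoint = tuple(config["force_band"])
    else:
        setpoint = config["force_setpoint"]
    traces, trajs, gts = [], [], []
    for s in expand_seeds(seed, config["n_traces"]):
        traj, gt = simulate_packaging(substrate, motor, slips,
                                      config["duration_s"], seed=s)
        trace = render_trace(traj, substrate, noise, config["force_mode"],
                             setpoint, seed=s + 1)
        traces.append(trace)
        trajs.append(traj)
        gts.append(gt)
    return traces, trajs, gts


def cmd_simulate(config: dict | None, out_dir, seed: int) -> list:
    """Simulate all configured substrates and write traces, noiseless
    trajectories, ground-truth event logs, and the resolved config."""
    config = resolve_config(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name in config["substrates"]:
        traces, trajs, gts = simulate_cohort(name, config, seed)
        for i, (trace, traj, gt) in enumerate(zip(traces, trajs, gts)):
            stem = f"{name}_{i:03d}"
            tpath = out_dir / f"{stem}.trace.tsv"
            write_trace(trace, tpath)
            written.append(tpath)
            noiseless = Trace(traj.time, traj.contour,
                              np.zeros_like(traj.time) + 1.0,
                              traj.sample_rate, dict(traj.meta))
            write_trace(noiseless, out_dir / f"{stem}.contour.tsv")
            with open(out_dir / f"{stem}.events.jsonl", "w") as fh:
                for t, k, sz in zip(gt.times, gt.kinds, gt.sizes):
                    fh.write(json.dumps({"time_s": round(float(t), 9),
                                         "kind": k,
                                         "size_nm": round(float(sz), 9)}) + "\n")
    resolved = dict(config)
    resolved["seed"] = seed
    resolved["config_hash"] = config_hash(config)
    (out_dir / "config.resolved.yaml").write_text(yaml.safe_dump(resolved))
    return written


# ---------------------------------------------------------------------------

def slip_free_packaged(packaged: np.ndarray, fit, events, pad_s: float,
                       decimation: int, sample_rate: float):
    """Split a packaged-length series into segments free of slip events.

    ``fit`` is the step fit of the decimated series; detected event spans
    (padded by ``pad_s``) are cut out and the remaining segments returned.
    """
    if not events:
        return [packaged]
    cp = fit.change_point_indices
    cuts = []
    pad = int(pad_s * sample_rate)
    for ev in events:
        first, last = ev.step_indices[0], ev.step_indices[-1]
        a = max(0, cp[first] * decimation - pad)
        b = min(packaged.size, (cp[last] + 1) * decimation + pad)
        cuts.append((int(a), int(b)))
    segments = []
    pos = 0
    for a, b in sorted(cuts):
        if a > pos:
            segments.append(packaged[pos:a])
        pos = max(pos, b)
    if pos < packaged.size:
        segments.append(packaged[pos:])
    return [s for s in segments if s.size]


def _detect_backward(fit, expected_burst, tolerance):
    from .slip_analysis import detect_slip_events
    return detect_slip_events(fit, expected_burst, tolerance)


def analyze_cohort(traces: list, config: dict | None = None) -> dict:
    """Run the full analysis chain on one substrate's traces.

    Stages: XWLC contour conversion -> pause-free velocity mixture -> PWD
    burst size (slip-free segments, selective averaging) -> KV stepfinding
    (dwells, step sizes, gamma fit) -> slip-event statistics.
    """
    if not traces:
        raise ValueError("need at least one trace")
    config = resolve_config(config)
    acfg = config["analysis"]
    name = traces[0].meta.get("substrate_name")
    substrate = get_substrate(name)
    wlc = WlcParams(substrate.persistence_length, substrate.stretch_modulus, 1.0)

    velocities, pwds, fits, all_events = [], [], [], []
    all_dwells, packaging_time = [], 0.0
    for trace in traces:
        traj = contour_trajectory(trace, wlc)
        packaged = packaged_length(traj)
        fs = trace.sample_rate
        # velocity
        v = sg_velocity(packaged, fs, width=acfg["sg_width"])
        centers, density = velocity_histogram(v, edge_trim=acfg["sg_width"] // 2)
        vfit = fit_velocity_mixture(centers, density)
        velocities.append(vfit)
        # stepfinding on decimated data
        factor = max(1, int(round(fs / acfg["decimate_to_hz"])))
        dec = decimate_mean(packaged, factor)
        dec_fs = fs / factor
        fit = kv_stepfind(dec, sensitivity=acfg["kv_sensitivity"],
                          sample_rate=dec_fs,
                          min_plateau=max(2, int(round(
                              acfg["kv_min_plateau_s"] * dec_fs))))
        fits.append(fit)
        all_dwells.extend(fit.dwell_durations[fit.dwell_durations > 0])
        # slips
        events = _detect_backward(fit, substrate.burst_size,
                                  acfg["slip_tolerance"])
        all_events.extend(events)
        packaging_time += trace.duration
        # PWD on slip-free segments
        segs = slip_free_packaged(packaged, fit, events, pad_s=0.2,
                                  decimation=factor, sample_rate=fs)
        seg_pwds = []
        for seg in segs:
            try:
                seg_pwds.append(windowed_pwd(seg, fs,
                                             window_s=acfg["pwd_window_s"]))
            except ValueError:
                continue
        if seg_pwds:
            pwds.append(np.mean(seg_pwds, axis=0))

    report = {"substrate": name, "n_traces": len(traces)}
    # velocity summary
    means = np.array([v.packaging_mean for v in velocities if not v.degenerate])
    if means.size:
        report["pause_free_velocity_nm_s"] = float(means.mean())
        report["pause_free_velocity_se"] = (
            float(means.std(ddof=1) / np.sqrt(means.size)) if means.size > 1 else 0.0)
        report["negative_tail_fraction"] = float(
            np.mean([v.negative_tail_fraction for v in velocities]))
    # burst size from PWD
    if len(pwds) >= 3:
        pwds_arr = np.asarray(pwds)
        scores = grade_periodicity(pwds_arr)
        res = selective_average(pwds_arr, scores,
                                top_fraction=acfg["top_fraction"])
        report["burst_size_nm"] = res.burst_size
        report["burst_size_se"] = res.burst_size_se
    elif pwds:
        res = selective_average(np.asarray(pwds), np.ones(len(pwds)),
                                top_fraction=1.0)
        report["burst_size_nm"] = res.burst_size
        report["burst_size_se"] = res.burst_size_se
    # dwells and steps
    if len(all_dwells) >= 30:
        gfit = fit_gamma_dwells(all_dwells)
        report["dwell_mean_ms"] = gfit.mean * 1e3
        report["gamma_shape"] = gfit.shape
    centers, density = extract_step_distribution(fits, forward_only=True)
    report["modal_step_nm"] = float(centers[np.argmax(density)])
    # slips
    stats = cohort_stats(all_events, packaging_time)
    report["slip_event_frequency_per_s"] = stats.event_frequency
    report["slip_stats"] = stats.summaries
    return report


def cmd_analyze(trace_paths, config: dict | None = None) -> dict:
    """Read traces, group by substrate, and emit the full AnalysisReport."""
    config = resolve_config(config)
    traces = [read_trace(p) for p in trace_paths]
    if not traces:
        raise ValueError("need at least one readable trace")
    by_substrate: dict = {}
    for t in traces:
        name = t.meta.get("substrate_name")
        if name is None:
            raise ValueError("trace missing substrate_name metadata")
        by_substrate.setdefault(name, []).append(t)
    report = {
        "per_substrate": {name: analyze_cohort(group, config)
                          for name, group in by_substrate.items()},
        "provenance": {
            "config_hash": config_hash(config),
            "seeds": sorted({t.meta.get("seed") for t in traces
                             if t.meta.get("seed") is not None}),
            "package_version": __version__,
        },
    }
    return report


# ---------------------------------------------------------------------------
# parameter-recovery experiments (simulate with the study conditions, then
# run the corresponding analysis end to end)

def _simulate_with_seeds(substrate_name: str, config: dict, seeds):
    config = resolve_config(config)
    substrate = get_substrate(substrate_name)
    motor = default_motor_params(substrate, atp_mM=config["atp_mM"],
                                 **config["motor"])
    slips = default_slip_params(substrate, **config["slips"])
    noise = NoiseParams(**config["noise"])
    setpoint = (tuple(config["force_band"])
                if config["force_mode"] == "semi_passive"
                else config["force_setpoint"])
    out = []
    for s in seeds:
        traj, gt = simulate_packaging(substrate, motor, slips,
                                      config["duration_s"], seed=s)
        trace = render_trace(traj, substrate, noise, config["force_mode"],
                             setpoint, seed=s + 500_000)
        out.append((trace, traj, gt))
    return out


def recover_burst_size(substrate_name: str, seeds, duration_s: float = 40.0,
                       config: dict | None = None):
    """Burst size from a simulated low-force cohort: simulate, convert to
    packaged length, exclude slip events, compute per-trace PWDs, grade and
    selectively average, and measure the peak spacing.

    Returns the :class:`~dwellburst.periodicity.PwdResult`.
    """
    config = resolve_config(dict(config or {}, duration_s=duration_s))
    acfg = config["analysis"]
    substrate = get_substrate(substrate_name)
    wlc = WlcParams(substrate.persistence_length, substrate.stretch_modulus, 1.0)
    pwds = []
    for trace, _, _ in _simulate_with_seeds(substrate_name, config, seeds):
        packaged = packaged_length(contour_trajectory(trace, wlc))
        factor = max(1, int(round(trace.sample_rate / acfg["decimate_to_hz"])))
        dec_fs = trace.sample_rate / factor
        fit = kv_stepfind(decimate_mean(packaged, factor),
                          sensitivity=acfg["kv_sensitivity"],
                          sample_rate=dec_fs,
                          min_plateau=max(2, int(round(
                              acfg["kv_min_plateau_s"] * dec_fs))))
        events = _detect_backward(fit, substrate.burst_size,
                                  acfg["slip_tolerance"])
        segs = slip_free_packaged(packaged, fit, events, pad_s=0.2,
                                  decimation=factor,
                                  sample_rate=trace.sample_rate)
        seg_pwds = []
        for seg in segs:
            try:
                seg_pwds.append(windowed_pwd(seg, trace.sample_rate,
                                             window_s=acfg["pwd_window_s"]))
            except ValueError:
                continue
        if seg_pwds:
            pwds.append(np.mean(seg_pwds, axis=0))
    pwds = np.asarray(pwds)
    scores = (grade_periodicity(pwds) if len(pwds) >= 3
              else np.ones(len(pwds)))
    return selective_average(pwds, scores, top_fraction=acfg["top_fraction"])


def recover_step_distribution(substrate_name: str, seeds,
                              duration_s: float = 12.0, method: str = "KV",
                              config: dict | None = None):
    """Step-size density from a simulated high-force cohort.

    Simulates step-resolving force-feedback traces (see
    :func:`highforce_config`), fits each with the requested stepfinder, and
    pools the forward step sizes.  Returns (bin_centers, density, fits).
    """
    config = highforce_config(**dict(config or {}, duration_s=duration_s))
    substrate = get_substrate(substrate_name)
    wlc = WlcParams(substrate.persistence_length, substrate.stretch_modulus, 1.0)
    fits = []
    for trace, _, _ in _simulate_with_seeds(substrate_name, config, seeds):
        packaged = packaged_length(contour_trajectory(trace, wlc))
        if method == "KV":
            fit = kv_stepfind(packaged, sample_rate=trace.sample_rate)
        else:
            from .stepfinding import hmm_stepfind
            fit = hmm_stepfind(decimate_mean(packaged, 5),
                               level_spacing_hint=0.85, sample_rate=500.0)
        fits.append(fit)
    centers, density = extract_step_distribution(fits, forward_only=True)
    return centers, density, fits


def recover_wlc_params(substrate_name: str, n_curves: int = 100,
                       noise_sigma: float = 2.0, n_points: int = 200,
                       seed: int = 0):
    """Mean (P, S) recovered by XWLC fits of noisy synthetic pulling curves
    over a 4 kb duplex."""
    from .elasticity import fit_pulling_curve
    from .simulate import simulate_pulling

    substrate = get_substrate(substrate_name)
    L0 = 4000 * substrate.rise
    Ps, Ss = [], []
    for s in expand_seeds(seed, n_curves):
        f, x = simulate_pulling(substrate, L0, noise_sigma, n_points, seed=s)
        fit = fit_pulling_curve(f, x)
        Ps.append(fit.params.persistence_length)
        Ss.append(fit.params.stretch_modulus)
    return float(np.mean(Ps)), float(np.mean(Ss))


def cmd_table1(config: dict | None, seeds) -> "pandas.DataFrame":
    """Side-by-side table of simulated-recovered vs published per-substrate
    values, averaged over ``seeds``."""
    import pandas as pd

    config = resolve_config(config)
    rows = []
    for name in config["substrates"]:
        recovered = {"burst_size_nm": [], "pause_free_velocity_nm_s": [],
                     "dwell_mean_ms": []}
        for seed in seeds:
            traces, _, _ = simulate_cohort(name, config, seed)
            rep = analyze_cohort(traces, config)
            for key in recovered:
                if key in rep:
                    recovered[key].append(rep[key])
        sub = get_substrate(name)
        published = PUBLISHED_VALUES[name]
        rows.append({
            "substrate": name,
            "periodicity_bp_turn": sub.periodicity,
            "pitch_nm_turn": sub.pitch,
            "published_burst_nm": published["burst_nm"],
            "recovered_burst_nm": float(np.mean(recovered["burst_size_nm"]))
                if recovered["burst_size_nm"] else float("nan"),
            "published_velocity_nm_s": published["velocity_nm_s"],
            "recovered_velocity_nm_s":
                float(np.mean(recovered["pause_free_velocity_nm_s"]))
                if recovered["pause_free_velocity_nm_s"] else float("nan"),
            "published_dwell_ms": published["dwell_ms"],
            "recovered_dwell_ms": float(np.mean(recovered["dwell_mean_ms"]))
                if recovered["dwell_mean_ms"] else float("nan"),
        })
    return pd.DataFrame(rows)
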