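import numpy as np
import pytest

import dwellburst as db
from dwellburst.pipeline import highforce_config, simulate_cohort


@pytest.fixture(scope="session")
def dsdna_lowforce():
    """Three low-force semi-passive dsDNA traces with ground truth."""
    cfg = {"n_traces": 3, "duration_s": 30.0, "substrates": ["dsDNA"]}
    return simulate_cohort("dsDNA", cfg, seed=7)


@pytest.fixture(scope="session")
def dsrna_lowforce():
    """Five low-force force-feedback dsRNA traces (slipping enabled)."""
    cfg = {"n_traces": 5, "duration_s": 30.0, "substrates": ["dsRNA"],
           "force_mode": "force_feedback", "force_setpoint": 10.0}
    return simulate_cohort("dsRNA", cfg, seed=11)


@pytest.fixture(scope="session")
def dsdna_highforce():
    """Four step-resolving high-force dsDNA traces."""
    cfg = highforce_config(n_traces=4, duration_s=12.0, substrates=["dsDNA"])
    return simulate_cohort("dsDNA", cfg, seed=21)


@pytest.fixture(scope="session")
def dts_highforce():
    """Four step-resolving high-force DTS-hybrid traces."""
    cfg = highforce_config(n_traces=4, duration_s=12.0,
                           substrates=["DTS_hybrid"])
    return simulate_cohort("DTS_hybrid", cfg, seed=22)


def packaged_from_trace(trace, substrate_name):
    sub = db.get_substrate(substrate_name)
    wlc = db.WlcParams(sub.persistence_length, sub.stretch_modulus, 1.0)
    return db.packaged_length(db.contour_trajectory(trace, wlc))


def staircase(levels, samples_per_plateau, noise_sigma=0.0, rng=None):
    """Piecewise-constant series from a list of plateau levels."""
    y = np.repeat(np.asarray(levels, dtype=float), samples_per_plateau)
    if noise_sigma:
        y = y + rng.standard_normal(y.size) * noise_sigma
    return y
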