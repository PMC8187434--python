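import numpy as np
import pytest
from scipy import stats

import dwellburst as db
from dwellburst.simulate import (MotorParams, NoiseParams, SlipParams,
                                 _ou_noise, default_motor_params,
                                 default_slip_params, simulate_packaging,
                                 simulate_pulling, render_trace)
from dwellburst.trace_model import get_substrate


DSDNA = get_substrate("dsDNA")
DSRNA = get_substrate("dsRNA")
NO_SLIP = SlipParams()


class TestMotorParams:
    def test_dsdna_burst_is_four_inherent_steps(self):
        m = default_motor_params(DSDNA)
        assert m.step_sizes == pytest.approx((0.85, 0.85, 0.85, 0.85), abs=1e-12)
        assert sum(m.step_sizes) == pytest.approx(3.40, abs=1e-12)

    def test_dsrna_fourth_step(self):
        m = default_motor_params(DSRNA)
        assert m.step_sizes[:3] == (0.85, 0.85, 0.85)
        assert m.step_sizes[3] == pytest.approx(0.15, abs=1e-12)

    def test_negative_fourth_step_rejected(self):
        with pytest.raises(ValueError):
            MotorParams(burst_size=2.4, dwell_mean=0.086)

    def test_slip_rate_on_dna_tracking_rejected(self):
        with pytest.raises(ValueError):
            simulate_packaging(DSDNA, default_motor_params(DSDNA),
                               SlipParams(pi_entry_rate=0.5), 1.0, seed=0)


class TestPackagingKinetics:
    def test_conservation_and_path(self):
        traj, gt = simulate_packaging(DSRNA, default_motor_params(DSRNA),
                                      default_slip_params(DSRNA), 30.0, seed=5)
        forward = gt.sizes[gt.sizes > 0].sum()
        slipped = -gt.sizes[gt.sizes < 0].sum()
        assert gt.total_packaged == pytest.approx(forward - slipped, abs=1e-12)
        packaged = traj.contour[0] - traj.contour
        np.testing.assert_allclose(packaged, gt.packaged_at(traj.time), atol=1e-12)

    def test_no_slips_without_pi_entry(self):
        dwells = []
        for seed in (1, 2):
            traj, gt = simulate_packaging(DSDNA, default_motor_params(DSDNA),
                                          NO_SLIP, 60.0, seed=seed)
            assert all(k not in ("slip", "pi_entry", "pi_exit")
                       for k in gt.kinds)
            dwells.append(gt.dwell_durations)
        dwells = np.concatenate(dwells)
        assert dwells.size >= 500
        se = dwells.std(ddof=1) / np.sqrt(dwells.size)
        assert abs(dwells.mean() - 0.086) < 3 * se

    def test_dwells_are_gamma(self):
        # pool ~1e4 dwells; shape/scale per the five-exchange loading clock
        dwells = []
        for seed in range(10):
            _, gt = simulate_packaging(DSDNA, default_motor_params(DSDNA),
                                       NO_SLIP, 95.0, seed=seed)
            dwells.append(gt.dwell_durations)
        dwells = np.concatenate(dwells)
        assert dwells.size >= 10_000
        ks = stats.kstest(dwells, "gamma", args=(5, 0, 0.086 / 5))
        assert ks.pvalue > 0.01

    def test_slip_quantization(self):
        _, gt = simulate_packaging(DSRNA, default_motor_params(DSRNA),
                                   default_slip_params(DSRNA), 120.0, seed=9)
        slips = -gt.sizes[gt.sizes < 0]
        assert slips.size > 0
        np.testing.assert_allclose(slips, DSRNA.burst_size, atol=1e-12)

    def test_seed_reproducibility(self):
        a = simulate_packaging(DSRNA, default_motor_params(DSRNA),
                               default_slip_params(DSRNA), 10.0, seed=42)
        b = simulate_packaging(DSRNA, default_motor_params(DSRNA),
                               default_slip_params(DSRNA), 10.0, seed=42)
        np.testing.assert_array_equal(a[0].contour, b[0].contour)
        np.testing.assert_array_equal(a[1].sizes, b[1].sizes)

    def test_atp_dependence(self):
        """Limiting ATP raises slip-event frequency and lengthens end dwells
        but leaves slips-per-event unchanged."""
        sp = default_slip_params(DSRNA)
        out = {}
        for atp in (0.25, 0.025):
            motor = default_motor_params(DSRNA, atp_mM=atp)
            events, ends, time = [], [], 0.0
            for seed in range(6):
                _, gt = simulate_packaging(DSRNA, motor, sp, 120.0,
                                           seed=seed + int(atp * 1000))
                events.append(gt.slip_counts[gt.slip_counts > 0])
                time += 120.0
                # end dwell = pi_exit minus last slip of each event
                last_slip = None
                for t, k in zip(gt.times, gt.kinds):
                    if k == "slip":
                        last_slip = t
                    elif k == "pi_exit" and last_slip is not None:
                        ends.append(t - last_slip)
                        last_slip = None
            counts = np.concatenate(events)
            out[atp] = (counts.size / time, np.mean(ends), counts.mean())
        freq_hi, end_hi, n_hi = out[0.25]
        freq_lo, end_lo, n_lo = out[0.025]
        assert freq_lo > freq_hi
        assert end_lo > end_hi
        assert abs(n_lo - n_hi) < 1.0  # slips per event ~ ATP independent


class TestRendering:
    def test_noiseless_feedback_is_exact_xwlc(self):
        traj, _ = simulate_packaging(DSDNA, default_motor_params(DSDNA),
                                     NO_SLIP, 2.0, seed=0)
        noise = NoiseParams(drag_coefficient=0.0, measurement_sigma=0.0)
        tr = render_trace(traj, DSDNA, noise, "force_feedback", 10.0, seed=1)
        params = db.WlcParams(50.0, 900.0, 1.0)
        expected = traj.contour * db.xwlc_extension(10.0, params)
        np.testing.assert_allclose(tr.extension, expected, rtol=1e-12)

    def test_ou_equipartition(self):
        noise = NoiseParams(trap_stiffness=0.55, drag_coefficient=9.4e-6)
        x = _ou_noise(10 ** 6, 1 / 2500.0, noise, np.random.default_rng(0))
        assert np.var(x) == pytest.approx(4.114 / 0.55, rel=0.05)

    def test_semi_passive_band_respected(self):
        traj, _ = simulate_packaging(DSDNA, default_motor_params(DSDNA),
                                     NO_SLIP, 10.0, seed=3)
        tr = render_trace(traj, DSDNA, NoiseParams(), "semi_passive",
                          (7.0, 12.0), seed=4)
        assert tr.force.min() >= 7.0
        assert tr.force.max() <= 12.0

    def test_low_force_rejected(self):
        traj, _ = simulate_packaging(DSDNA, default_motor_params(DSDNA),
                                     NO_SLIP, 1.0, seed=0)
        with pytest.raises(ValueError):
            render_trace(traj, DSDNA, NoiseParams(), "force_feedback", 0.5, 1)


class TestPulling:
    def test_noiseless_curve_matches_closed_form(self):
        f, x = simulate_pulling(DSDNA, 1000.0, 0.0, 50, seed=0)
        params = db.WlcParams(50.0, 900.0, 1000.0)
        np.testing.assert_allclose(x, db.xwlc_extension(f, params), rtol=1e-12)

    def test_dsrna_shorter_than_dsdna_at_low_force(self):
        # below ~7 pN the shorter persistence length dominates; above, the
        # smaller stretch modulus makes dsRNA the more extensible polymer
        f1, x1 = simulate_pulling(DSDNA, 1000.0, 0.0, 20, seed=0,
                                  force_range=(5.0, 6.5))
        f2, x2 = simulate_pulling(DSRNA, 1000.0, 0.0, 20, seed=0,
                                  force_range=(5.0, 6.5))
        assert np.all(x2 < x1)

    def test_zero_points_rejected(self):
        with pytest.raises(ValueError):
            simulate_pulling(DSDNA, 1000.0, 1.0, 0, seed=0)
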