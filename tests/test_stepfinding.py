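import itertools

import numpy as np
import pytest
from scipy import stats

from dwellburst.stepfinding import (bimodal_modes, decimate_mean,
                                    differential_distribution,
                                    extract_step_distribution,
                                    fit_gamma_dwells, hmm_stepfind,
                                    kv_stepfind)
from tests.conftest import packaged_from_trace, staircase


def exhaustive_best_sse(y, n_changepoints, min_plateau=2):
    """Brute-force minimum SSE over all change-point placements."""
    n = y.size
    cum = np.concatenate([[0.0], np.cumsum(y)])
    cum2 = np.concatenate([[0.0], np.cumsum(y * y)])

    def sse(s, e):
        m = (cum[e] - cum[s]) / (e - s)
        return (cum2[e] - cum2[s]) - (e - s) * m * m

    best = np.inf
    positions = range(min_plateau, n - min_plateau + 1)
    for cps in itertools.combinations(positions, n_changepoints):
        bounds = (0,) + cps + (n,)
        if any(b - a < min_plateau for a, b in zip(bounds[:-1], bounds[1:])):
            continue
        total = sum(sse(a, b) for a, b in zip(bounds[:-1], bounds[1:]))
        best = min(best, total)
    return best


class TestKV:
    def test_noiseless_staircase_exact(self):
        y = staircase([0.0, 0.85, 1.70, 2.55], 250)
        fit = kv_stepfind(y, sample_rate=2500.0)
        np.testing.assert_array_equal(fit.change_point_indices,
                                      [250, 500, 750])
        np.testing.assert_allclose(fit.step_sizes, 0.85, atol=1e-12)

    def test_noisy_staircase_recovery(self):
        errs, found = [], 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            y = staircase([0.0, 0.85, 1.70, 2.55], 250, 0.25, rng)
            fit = kv_stepfind(y, sample_rate=2500.0)
            if fit.n_steps == 3:
                found += 1
                errs.extend(np.abs(fit.step_sizes - 0.85))
        assert found >= 95
        assert np.mean(errs) < 0.05

    def test_false_positive_rate_on_flat_noise(self):
        clean = 0
        for seed in range(100):
            y = np.random.default_rng(seed).normal(0, 0.3, 10_000)
            if kv_stepfind(y).n_steps == 0:
                clean += 1
        assert clean >= 95

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_enumeration(self, seed):
        """Greedy KV attains the globally optimal SSE at its model size on
        small stepped fixtures."""
        rng = np.random.default_rng(seed)
        y = staircase([0.0, 1.0, 2.3], 40, 0.2, rng)  # 120 samples, 2 steps
        fit = kv_stepfind(y)
        assert fit.n_steps == 2
        resid = np.concatenate([
            y[a:b] - y[a:b].mean()
            for a, b in zip([0, *fit.change_point_indices],
                            [*fit.change_point_indices, y.size])])
        kv_sse = np.sum(resid ** 2)
        assert kv_sse == pytest.approx(exhaustive_best_sse(y, 2), abs=1e-9)

    def test_sensitivity_monotone(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            levels = np.cumsum(rng.uniform(0.5, 1.2, 6))
            y = staircase(levels, 60, 0.3, rng)
            counts = [kv_stepfind(y, sensitivity=s).n_steps
                      for s in (0.5, 1.0, 2.0, 4.0)]
            assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_bookkeeping_identities(self):
        rng = np.random.default_rng(5)
        y = staircase([0, 1, 2, 3.5], 100, 0.2, rng)
        fit = kv_stepfind(y, sample_rate=500.0)
        assert fit.dwell_durations.sum() == pytest.approx(y.size / 500.0)
        assert fit.step_sizes.sum() == pytest.approx(
            fit.plateau_means[-1] - fit.plateau_means[0])

    def test_too_short_series(self):
        with pytest.raises(ValueError):
            kv_stepfind(np.zeros(5))


class TestHMM:
    def test_agrees_with_kv_on_clean_staircase(self):
        y = staircase([0.0, 0.85, 1.70, 2.55], 100)
        kv = kv_stepfind(y)
        hmm = hmm_stepfind(y, level_spacing_hint=0.85)
        np.testing.assert_array_equal(hmm.change_point_indices,
                                      kv.change_point_indices)
        np.testing.assert_allclose(hmm.step_sizes, kv.step_sizes, atol=1e-9)

    def test_hint_robustness(self):
        y = staircase([0.0, 0.85, 1.70, 2.55], 100)
        a = hmm_stepfind(y, level_spacing_hint=0.85)
        b = hmm_stepfind(y, level_spacing_hint=0.80)
        np.testing.assert_array_equal(a.change_point_indices,
                                      b.change_point_indices)

    def test_spacing_grid_search(self):
        rng = np.random.default_rng(3)
        y = staircase([0.0, 0.85, 1.70, 2.55, 3.40], 80, 0.1, rng)
        fit = hmm_stepfind(y)
        assert fit.n_steps == 4
        np.testing.assert_allclose(fit.step_sizes, 0.85, atol=0.1)

    def test_dts_burst_pattern_bimodal(self, dts_highforce):
        """High-force DTS bursts of three 0.85 nm strokes plus the pitch
        remainder give a bimodal step histogram whose minor mode sits near
        the shortened fourth step."""
        traces, _, _ = dts_highforce
        fits = []
        for tr in traces:
            p = packaged_from_trace(tr, "DTS_hybrid")
            fits.append(hmm_stepfind(decimate_mean(p, 5),
                                     level_spacing_hint=0.85,
                                     sample_rate=500.0))
        c, d = extract_step_distribution(fits, forward_only=True)
        major, minor = bimodal_modes(c, d)
        assert major == pytest.approx(0.85, abs=0.05)
        assert minor == pytest.approx(0.45, abs=0.1 + 1e-9)

    def test_flat_series_no_steps(self):
        fit = hmm_stepfind(np.zeros(100), level_spacing_hint=0.85)
        assert fit.no_steps


class TestStepDistributions:
    def test_mass_ratio(self):
        from dwellburst.stepfinding import StepFit
        fit = StepFit(np.array([10, 20, 30, 40]),
                      np.array([0.0, 0.85, 1.70, 2.55, 3.0]),
                      np.ones(5), np.array([0.85, 0.85, 0.85, 0.45]),
                      "KV", 1.0, 1.0)
        c, d = extract_step_distribution([fit])
        occupied = d[d > 0]
        assert occupied.size == 2
        assert occupied.max() / occupied.min() == pytest.approx(3.0)

    def test_forward_only_drops_negatives(self):
        from dwellburst.stepfinding import StepFit
        fit = StepFit(np.array([10, 20]), np.array([0.0, 0.85, 0.0]),
                      np.ones(3), np.array([0.85, -0.85]), "KV", 1.0, 1.0)
        c, d = extract_step_distribution([fit], forward_only=True)
        assert np.all(c[d > 0] > 0)

    def test_simulated_dsdna_mode(self, dsdna_highforce):
        traces, _, _ = dsdna_highforce
        fits = [kv_stepfind(packaged_from_trace(t, "dsDNA"),
                            sample_rate=t.sample_rate) for t in traces]
        c, d = extract_step_distribution(fits, forward_only=True)
        assert c[np.argmax(d)] == pytest.approx(0.85, abs=0.05)


class TestDifferential:
    def test_identical_distributions_zero(self):
        grid = np.arange(0, 2, 0.05)
        dens = np.exp(-0.5 * ((grid - 0.85) / 0.1) ** 2)
        res = differential_distribution(grid, dens, grid, dens)
        np.testing.assert_allclose(res.difference, 0.0, atol=1e-12)

    def test_alignment_shift_invariance(self):
        grid = np.arange(0, 2, 0.05)
        dens_a = np.exp(-0.5 * ((grid - 0.85) / 0.15) ** 2)
        dens_b = np.exp(-0.5 * ((grid - 0.50) / 0.15) ** 2)
        res1 = differential_distribution(grid, dens_a, grid, dens_b)
        shifted = grid + 0.025
        res2 = differential_distribution(grid, dens_a, shifted, dens_b)
        common = (res1.grid >= res2.grid.min()) & (res1.grid <= res2.grid.max())
        interp = np.interp(res1.grid[common], res2.grid, res2.difference)
        # linear resampling of a sigma=3-bin Gaussian flattens its peak by
        # ~10%; allow that much relative to the ~2.5 peak amplitude
        np.testing.assert_allclose(res1.difference[common], interp, atol=0.3)

    def test_disjoint_supports_rejected(self):
        with pytest.raises(ValueError):
            differential_distribution(np.array([0.0, 0.1]), np.array([1.0, 1.0]),
                                      np.array([5.0, 5.1]), np.array([1.0, 1.0]))

    def test_dts_excess_lobes_separated_by_inherent_step(self, dsdna_highforce,
                                                         dts_highforce):
        """The DTS-minus-dsDNA differential shows the shortened fourth step
        and its merge with one inherent step, ~0.85 nm apart."""
        def dist(cohort, name):
            fits = [hmm_stepfind(decimate_mean(packaged_from_trace(t, name), 5),
                                 level_spacing_hint=0.85, sample_rate=500.0)
                    for t in cohort[0]]
            return extract_step_distribution(fits, forward_only=True)

        cA, dA = dist(dsdna_highforce, "dsDNA")
        cB, dB = dist(dts_highforce, "DTS_hybrid")
        res = differential_distribution(cA, dA, cB, dB)
        assert res.lobe_means.size == 2
        sep = res.lobe_means[1] - res.lobe_means[0]
        assert sep == pytest.approx(0.85, abs=0.25)


class TestGammaDwells:
    def test_mle_recovery(self):
        rng = np.random.default_rng(0)
        draws = rng.gamma(5.0, 0.0172, 10_000)
        fit = fit_gamma_dwells(draws)
        assert fit.shape == pytest.approx(5.0, abs=0.15)
        assert fit.mean == pytest.approx(0.086, abs=0.002)
        assert fit.ks_pvalue > 0.01

    def test_exponential_is_shape_one(self):
        rng = np.random.default_rng(1)
        fit = fit_gamma_dwells(rng.exponential(0.1, 5000))
        assert fit.shape == pytest.approx(1.0, abs=0.1)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            fit_gamma_dwells(np.full(100, 0.1))
        with pytest.raises(ValueError):
            fit_gamma_dwells(np.concatenate([np.ones(50), [-1.0]]))
        with pytest.raises(ValueError):
            fit_gamma_dwells(np.ones(10))

    def test_simulated_dwell_shape(self, dsdna_lowforce):
        """Low-force KV dwells pool to a gamma with mean near the generator
        dwell; burst samples make the apparent dwell slightly shorter."""
        traces, _, gts = dsdna_lowforce
        dwells = np.concatenate([gt.dwell_durations for gt in gts])
        fit = fit_gamma_dwells(dwells)
        assert fit.mean == pytest.approx(0.086, rel=0.1)
        assert fit.shape == pytest.approx(5.0, rel=0.35)
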