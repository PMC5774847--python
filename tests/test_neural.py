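"""Random walk, Poisson spiking, circular Bayes filter and width calibration."""

import math

import numpy as np
import pytest
from scipy.special import comb

from gridcode.neural import (
    CircularPosterior,
    SpikeRaster,
    TuningParams,
    WalkParams,
    bayes_filter,
    estimate_module_delta,
    fit_von_mises,
    kappa_from_resultant,
    mean_rate,
    sample_spikes,
    simulate_walk,
    tuning_rate,
)


class TestWalk:
    def test_starts_at_origin_and_is_reproducible(self):
        p = WalkParams(steps=100, seed=5)
        x1, x2 = simulate_walk(p), simulate_walk(p)
        assert x1[0] == 0.0
        np.testing.assert_array_equal(x1, x2)
        assert not np.array_equal(x1, simulate_walk(WalkParams(steps=100, seed=6)))

    def test_rms_displacement_matches_closed_form(self):
        # sqrt(D * t): 5 cm after 0.5 s at D = 0.005 m^2/s
        sq = [simulate_walk(WalkParams(steps=500, seed=s))[-1] ** 2
              for s in range(400)]
        assert math.sqrt(np.mean(sq)) == pytest.approx(0.05, rel=0.1)

    def test_variance_linear_in_time(self):
        xs = np.stack([simulate_walk(WalkParams(steps=400, seed=s)) for s in range(300)])
        t = np.arange(401) * 0.001
        var = xs.var(axis=0)
        slope = np.polyfit(t, var, 1)[0]
        assert slope == pytest.approx(0.005, rel=0.2)

    def test_tiny_diffusion_is_nearly_constant(self):
        x = simulate_walk(WalkParams(D=1e-12, steps=1000, seed=0))
        assert np.max(np.abs(x)) < 1e-3

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            WalkParams(D=0.0)
        with pytest.raises(ValueError):
            WalkParams(steps=0)


class TestTuning:
    def test_peak_and_baseline(self):
        p = TuningParams()
        # cell 0 prefers x where sin(pi x / lam) = +-1
        x_peak = p.lam / 2
        assert tuning_rate(x_peak, p, 0) == pytest.approx(15.1)
        # at the trough (sine term zero) only the baseline remains
        assert tuning_rate(x_peak + p.lam / 2, p, 0) == pytest.approx(0.1, abs=1e-6)
        # a quarter of the rate period away the sin^22 factor is ~0.7^22
        assert tuning_rate(x_peak + p.lam / 4, p, 0) == pytest.approx(
            15 * 0.5**11 + 0.1, rel=1e-6)

    def test_periodicity(self):
        p = TuningParams()
        xs = np.random.default_rng(0).uniform(0, 10, 100)
        np.testing.assert_allclose(tuning_rate(xs, p, 3),
                                   tuning_rate(xs + p.lam, p, 3), rtol=1e-10)

    def test_odd_exponent_rejected(self):
        with pytest.raises(ValueError):
            TuningParams(n_pow=21)

    def test_mean_rate_matches_binomial_closed_form(self):
        # spatial mean of sin^n is C(n, n/2)/2^n for even n
        p = TuningParams()
        expected = p.r_max * comb(22, 11) / 2**22 + p.r0
        assert mean_rate(p) == pytest.approx(expected, rel=1e-6)


class TestSpikes:
    def test_empirical_mean_count(self):
        p = TuningParams(N=5)
        walk = WalkParams(steps=40_000, seed=2)
        raster = sample_spikes(simulate_walk(walk), p, seed=3)
        got = raster.counts.mean()
        assert got == pytest.approx(0.001 * mean_rate(p), rel=0.1)

    def test_zero_baseline_silent_far_from_field(self):
        p = TuningParams(r0=0.0, N=1)
        x = np.full(5000, p.lam / 4 + p.lam / 2)  # trough of cell 0
        raster = sample_spikes(x, p, seed=0)
        assert raster.counts.sum() == 0

    def test_seeded_reproducibility(self):
        p = TuningParams(N=3)
        x = simulate_walk(WalkParams(steps=500, seed=9))
        r1 = sample_spikes(x, p, seed=4)
        r2 = sample_spikes(x, p, seed=4)
        np.testing.assert_array_equal(r1.counts, r2.counts)

    def test_table_roundtrip(self):
        p = TuningParams(N=4)
        x = simulate_walk(WalkParams(steps=300, seed=1))
        raster = sample_spikes(x, p, seed=1)
        back = SpikeRaster.from_table(raster.to_table(), 300, 4, 0.001)
        np.testing.assert_array_equal(back.counts, raster.counts)


class TestFilter:
    def test_flat_prior_stays_flat_without_information(self):
        # r_max = 0 makes every rate constant in x: the likelihood carries
        # no spatial information and the uniform posterior is a fixed point
        p = TuningParams(r_max=0.0, r0=1.0, n_pow=2, N=3)
        walk = WalkParams(steps=50, seed=0)
        raster = sample_spikes(simulate_walk(walk), p, seed=0)
        for post in bayes_filter(raster, walk, p, B=64):
            np.testing.assert_allclose(post.probs, 1 / 64, atol=1e-12)

    def test_single_spike_peaks_at_preferred_phase(self):
        p = TuningParams(N=1)
        walk = WalkParams(D=1e-12, steps=1, seed=0)
        counts = np.array([[1]], dtype=np.int16)
        post = list(bayes_filter(SpikeRaster(counts, 0.001), walk, p, B=256))[-1]
        x_hat = np.argmax(post.probs) / 256 * p.lam
        # cell 0 peaks at lam/2 (and by symmetry of sin^22 also at 0)
        assert min(abs(x_hat - p.lam / 2), abs(x_hat), abs(x_hat - p.lam)) < p.lam / 16

    def test_normalisation_preserved(self):
        p = TuningParams(N=8)
        walk = WalkParams(steps=200, seed=3)
        raster = sample_spikes(simulate_walk(walk), p, seed=4)
        for post in bayes_filter(raster, walk, p):
            assert abs(post.probs.sum() - 1.0) < 1e-9

    def test_posterior_tracks_true_phase(self):
        p = TuningParams(N=50)
        walk = WalkParams(steps=12_000, seed=12)
        traj = simulate_walk(walk)
        raster = sample_spikes(traj, p, seed=13)
        hits = total = 0
        for t, post in enumerate(bayes_filter(raster, walk, p)):
            if t < 1000:
                continue
            fit = fit_von_mises(post)
            delta_t = 1.0 / (2 * math.pi * math.sqrt(max(fit.kappa, 1e-12)))
            d = abs(fit.mu - traj[t + 1] % p.lam)
            d = min(d, p.lam - d) / p.lam
            hits += d < 3 * delta_t
            total += 1
        assert hits / total >= 0.99

    def test_equivariance_under_phase_shift(self):
        # shifting all preferred phases and the trajectory by the same
        # offset shifts the posterior mean by that offset (mod lam)
        p = TuningParams(N=20)
        shift = 0.1
        shifted = TuningParams(N=20, phases=tuple(
            (ph + math.pi * shift / p.lam) % (2 * math.pi) for ph in p.phases))
        walk = WalkParams(steps=2000, seed=21)
        traj = simulate_walk(walk)
        r1 = sample_spikes(traj, p, seed=22)
        r2 = sample_spikes(traj + shift, shifted, seed=22)
        np.testing.assert_array_equal(r1.counts, r2.counts)
        last1 = None
        for last1 in bayes_filter(r1, walk, p):
            pass
        last2 = None
        for last2 in bayes_filter(r2, walk, shifted):
            pass
        m1, m2 = fit_von_mises(last1).mu, fit_von_mises(last2).mu
        d = (m2 - m1 - shift) % p.lam
        assert min(d, p.lam - d) < p.lam / 32


class TestVonMises:
    def test_round_trip_recovery(self):
        B, kappa, lam = 256, 5.0, 0.25
        theta = 2 * math.pi * np.arange(B) / B
        dens = np.exp(kappa * np.cos(theta - 1.0))
        post = CircularPosterior(dens / dens.sum(), lam)
        fit = fit_von_mises(post)
        assert fit.kappa == pytest.approx(kappa, rel=0.02)
        assert fit.mu == pytest.approx(1.0 / (2 * math.pi) * lam, rel=0.02)

    def test_flat_posterior_flagged(self):
        post = CircularPosterior(np.full(128, 1 / 128), 0.25)
        fit = fit_von_mises(post)
        assert fit.kappa == pytest.approx(0.0, abs=1e-9)
        assert fit.flag == "flat"

    def test_point_mass_flagged_degenerate(self):
        probs = np.zeros(128)
        probs[17] = 1.0
        fit = fit_von_mises(CircularPosterior(probs, 0.25))
        assert fit.flag == "degenerate"

    def test_resultant_inversion_consistency(self):
        from scipy.special import i0e, i1e
        for kappa in (0.5, 3.0, 50.0, 2000.0):
            R = i1e(kappa) / i0e(kappa)
            assert kappa_from_resultant(R) == pytest.approx(kappa, rel=5e-3)


class TestModuleDelta:
    def test_delta_decreases_with_cell_count(self):
        deltas = {}
        for N in (8, 32):
            vals = [estimate_module_delta(TuningParams(N=N),
                                          WalkParams(steps=15_000, seed=s),
                                          burn_in=500).delta
                    for s in range(3)]
            deltas[N] = np.mean(vals)
        assert deltas[32] < deltas[8]

    def test_delta_increases_with_diffusion(self):
        lo = estimate_module_delta(TuningParams(N=20),
                                   WalkParams(D=0.001, steps=15_000, seed=1),
                                   burn_in=500).delta
        hi = estimate_module_delta(TuningParams(N=20),
                                   WalkParams(D=0.01, steps=15_000, seed=1),
                                   burn_in=500).delta
        assert hi > lo

    def test_requires_enough_steps(self):
        with pytest.raises(ValueError):
            estimate_module_delta(TuningParams(), WalkParams(steps=5000), burn_in=100)
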