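"""Pooled Bayesian machinery: likelihood, sampler, diagnostics, bands."""

import numpy as np
import pytest
from scipy import stats as sps
from scipy.optimize import minimize

from steatopk.bayes import (
    BayesianPKModel,
    CredibilityBand,
    PosteriorEnsemble,
    PriorSpec,
    bands_overlap_at,
    effective_sample_size,
    geweke_burnin,
    log_likelihood,
    log_posterior,
    posterior_predictive_band,
    sample_posterior,
)
from steatopk.fitting import ConcentrationSeries, fit_replicate
from steatopk.model import PKParams, evaluate_curve
from steatopk.synthetic import DEFAULT_TIME_GRID

GRID = np.asarray(DEFAULT_TIME_GRID)


def series_at(params, times, sigma=0.0, seed=0, n_reps=1, clamp=True):
    """Replicates of model + Gaussian noise (clamped at zero)."""
    rng = np.random.default_rng(seed)
    out = []
    for j in range(n_reps):
        c = evaluate_curve(times, params)
        if sigma:
            c = c + rng.normal(0, sigma, times.shape)
            if clamp:
                c = np.maximum(c, 0.0)
            c[times == 0] = 0.0
        out.append(ConcentrationSeries(f"a{j}", "control", "caffeine", times, c))
    return out


class TestLogLikelihood:
    def test_single_exact_point(self):
        p = PKParams(A=2.0, B=3.0)
        s = ConcentrationSeries("a", "control", "x", [1.0, 2.0, 3.0],
                                evaluate_curve(np.array([1.0, 2.0, 3.0]), p))
        one = ConcentrationSeries("a", "control", "x", [1.0],
                                  [evaluate_curve(1.0, p)])
        assert log_likelihood(p, 1.0, [one]) == pytest.approx(
            -0.5 * np.log(2 * np.pi), abs=1e-12)
        # three zero-residual points: additive
        assert log_likelihood(p, 1.0, [s]) == pytest.approx(
            -1.5 * np.log(2 * np.pi), abs=1e-12)

    def test_matches_normal_density_oracle(self):
        p = PKParams(A=1.5, B=4.0)
        reps = series_at(p, GRID, sigma=2.0, seed=3, n_reps=3)
        sigma = 1.7
        expected = sum(
            sps.norm.logpdf(s.concentrations, evaluate_curve(s.times, p), sigma).sum()
            for s in reps)
        assert log_likelihood(p, sigma, reps) == pytest.approx(expected, rel=1e-12)

    def test_nonpositive_sigma_rejected(self):
        p = PKParams(A=1.0, B=1.0)
        reps = series_at(p, GRID)
        with pytest.raises(ValueError):
            log_likelihood(p, 0.0, reps)


class TestLogPosterior:
    def test_outside_prior_box_is_minus_inf(self):
        reps = series_at(PKParams(A=2.0, B=5.0), GRID)
        assert log_posterior(PKParams(A=101.0, B=5.0), 1.0, reps) == -np.inf
        assert log_posterior(PKParams(A=2.0, B=5.0), 1001.0, reps) == -np.inf

    def test_inside_box_equals_likelihood(self):
        p = PKParams(A=2.0, B=5.0)
        reps = series_at(p, GRID, sigma=1.0, seed=1)
        assert log_posterior(p, 2.0, reps) == pytest.approx(
            log_likelihood(p, 2.0, reps))

    def test_mode_coincides_with_least_squares_on_noiseless_data(self):
        truth = PKParams(A=1.8, B=6.2)
        reps = series_at(truth, GRID)
        ls = fit_replicate(reps[0]).params

        def neg(theta):
            a, b, s = theta
            if a <= 0 or s <= 0:
                return np.inf
            return -log_posterior(PKParams(A=a, B=b), s, reps)

        res = minimize(neg, [1.0, 5.0, 0.5], method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-10, "maxiter": 5000})
        assert res.x[0] == pytest.approx(ls.A, abs=1e-4)
        assert res.x[1] == pytest.approx(ls.B, abs=1e-4)


class TestGewekeBurnin:
    def test_stationary_chain_returns_floor(self):
        chain = np.random.default_rng(2).standard_normal(10_000)
        assert geweke_burnin(chain) == 100

    def test_detects_injected_level_shift(self):
        # every shifted sample must fall inside the cut
        rng = np.random.default_rng(1)
        chain = rng.standard_normal(10_000)
        chain[:5_000] += 5.0
        assert geweke_burnin(chain) >= 5_000

    def test_short_chain_rejected(self):
        with pytest.raises(ValueError):
            geweke_burnin(np.zeros(150), min_cut=100)


class TestEffectiveSampleSize:
    def test_iid_chain_is_near_n(self):
        chain = np.random.default_rng(2).standard_normal(10_000)
        assert 8_000 <= effective_sample_size(chain) <= 12_000

    def test_ar1_matches_closed_form(self):
        phi = 0.9
        rng = np.random.default_rng(3)
        n = 50_000
        x = np.empty(n)
        x[0] = rng.standard_normal()
        for i in range(1, n):
            x[i] = phi * x[i - 1] + rng.standard_normal()
        expected = n * (1 - phi) / (1 + phi)
        assert effective_sample_size(x) == pytest.approx(expected, rel=0.3)

    def test_never_exceeds_n(self):
        chain = np.random.default_rng(4).standard_normal(500)
        assert effective_sample_size(chain) <= 500

    def test_agrees_with_arviz_on_autocorrelated_chain(self):
        az = pytest.importorskip("arviz")
        phi = 0.7
        rng = np.random.default_rng(5)
        x = np.empty(20_000)
        x[0] = 0.0
        for i in range(1, x.size):
            x[i] = phi * x[i - 1] + rng.standard_normal()
        ours = effective_sample_size(x)
        theirs = float(az.ess(x[None, :]))
        assert ours == pytest.approx(theirs, rel=0.25)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            effective_sample_size(np.arange(50, dtype=float))
        with pytest.raises(ValueError):
            effective_sample_size(np.full(200, 3.14))


class TestSamplePosterior:
    def test_recovers_truth_within_three_posterior_sd(self):
        truth = PKParams(A=2.0, B=6.0)
        reps = series_at(truth, GRID, sigma=0.1, seed=6, n_reps=20)
        ens = sample_posterior(reps, n_samples=20_000, seed=7)
        mean, sd = ens.samples.mean(axis=0), ens.samples.std(axis=0)
        assert abs(mean[0] - truth.A) < 3 * sd[0]
        assert abs(mean[1] - truth.B) < 3 * sd[1]

    def test_samples_stay_inside_prior_box(self):
        truth = PKParams(A=2.0, B=6.0)
        reps = series_at(truth, GRID, sigma=1.0, seed=8, n_reps=4)
        prior = PriorSpec()
        ens = sample_posterior(reps, prior=prior, n_samples=5_000, seed=9)
        assert np.all(ens.samples >= prior.lower)
        assert np.all(ens.samples <= prior.upper)
        assert ens.burn_in_index >= 100

    def test_bit_reproducible(self):
        truth = PKParams(A=1.5, B=5.0)
        reps = series_at(truth, GRID, sigma=1.0, seed=10, n_reps=3)
        e1 = sample_posterior(reps, n_samples=2_000, seed=11)
        e2 = sample_posterior(reps, n_samples=2_000, seed=11)
        np.testing.assert_array_equal(e1.samples, e2.samples)

    def test_cold_chain_acceptance_in_healthy_range(self):
        truth = PKParams(A=2.0, B=6.0)
        reps = series_at(truth, GRID, sigma=1.0, seed=12, n_reps=6)
        ens = sample_posterior(reps, n_samples=10_000, seed=13)
        assert 0.1 < ens.acceptance_rate < 0.6

    def test_degenerate_data_rejected(self):
        s = ConcentrationSeries("a", "control", "x", GRID, np.zeros(GRID.size))
        with pytest.raises(ValueError, match="degenerate|3 positive"):
            sample_posterior([s], n_samples=1_000)

    def test_posterior_mean_approaches_least_squares_as_noise_vanishes(self):
        truth = PKParams(A=2.0, B=6.0)
        reps = series_at(truth, GRID, sigma=1e-3, seed=14, n_reps=5, clamp=False)
        ls = fit_replicate(reps[0]).params
        ens = sample_posterior(reps, n_samples=20_000, seed=15)
        mean = ens.samples.mean(axis=0)
        assert mean[0] == pytest.approx(ls.A, abs=1e-3)
        assert mean[1] == pytest.approx(ls.B, abs=1e-3)


class TestPosteriorPredictiveBand:
    @staticmethod
    def _ensemble(rows):
        return PosteriorEnsemble(samples=np.asarray(rows, dtype=float),
                                 n_chains=4, n_samples_requested=len(rows),
                                 burn_in_index=100,
                                 ess=np.full(3, float(len(rows))), seed=0)

    def test_degenerate_ensemble_collapses_to_curve(self):
        rows = [[2.0, 5.0, 1.0]] * 50
        grid = np.linspace(0, 6, 13)
        band = posterior_predictive_band(self._ensemble(rows), grid)
        curve = evaluate_curve(grid, PKParams(A=2.0, B=5.0))
        np.testing.assert_allclose(band.lower, curve, atol=1e-12)
        np.testing.assert_allclose(band.upper, curve, atol=1e-12)
        np.testing.assert_allclose(band.center, curve, atol=1e-12)

    def test_band_pinned_to_zero_at_origin(self):
        rows = np.random.default_rng(16).uniform(1, 3, (100, 3))
        band = posterior_predictive_band(self._ensemble(rows), [0.0, 1.0])
        assert band.lower[0] == band.upper[0] == 0.0

    def test_band_widens_with_data_noise(self):
        truth = PKParams(A=2.0, B=6.0)
        grid = np.linspace(0.25, 6, 24)
        widths = []
        for sigma in (0.1, 1.0, 5.0):
            reps = series_at(truth, GRID, sigma=sigma, seed=17, n_reps=6)
            ens = sample_posterior(reps, n_samples=5_000, seed=18)
            band = posterior_predictive_band(ens, grid)
            widths.append(np.mean(band.upper - band.lower))
        assert widths[0] < widths[1] < widths[2]

    def test_empty_ensemble_rejected(self):
        ens = PosteriorEnsemble(samples=np.empty((0, 3)), n_chains=4,
                                n_samples_requested=0, burn_in_index=100,
                                ess=np.ones(3), seed=0)
        with pytest.raises(ValueError):
            posterior_predictive_band(ens, [0, 1])


class TestBandsOverlap:
    @staticmethod
    def _band(lo, hi):
        g = np.array([0.0, 1.0])
        return CredibilityBand(time_grid=g, lower=np.full(2, lo),
                               upper=np.full(2, hi),
                               center=np.full(2, (lo + hi) / 2), level=0.95)

    def test_identical_bands_overlap(self):
        b = self._band(1, 2)
        assert bands_overlap_at(b, b, 1.0)

    def test_disjoint_bands_do_not(self):
        assert not bands_overlap_at(self._band(1, 2), self._band(3, 4), 1.0)

    def test_touching_bands_overlap(self):
        # closed-interval convention: shared endpoint counts as overlap
        assert bands_overlap_at(self._band(1, 2), self._band(2, 3), 1.0)

    def test_time_off_grid_rejected(self):
        with pytest.raises(ValueError):
            bands_overlap_at(self._band(1, 2), self._band(1, 2), 0.5)


class TestBayesianPKModelEstimator:
    def test_fit_predict_roundtrip(self):
        truth = PKParams(A=2.0, B=6.0)
        reps = series_at(truth, GRID, sigma=1.0, seed=19, n_reps=6)
        t = np.concatenate([s.times for s in reps])
        c = np.concatenate([s.concentrations for s in reps])
        est = BayesianPKModel(n_samples=5_000, random_state=20).fit(t, c)
        assert est.A_ == pytest.approx(truth.A, abs=0.2)
        pred = est.predict(GRID)
        assert pred[0] == 0.0
        assert np.argmax(pred) in (2, 3)  # peak near 1/A = 0.5 h
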