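"""Trimodal model evaluation and bound-constrained fitting."""

import numpy as np
import pytest
from scipy import integrate, stats

from ntra import (
    HUHistogram,
    NTRAParameters,
    N_FREE_PARAMETERS,
    TissueDomains,
    component_density,
    fit_ntra,
    initialize_from_domains,
    smooth_histogram,
    build_histogram,
    trimodal_density,
)
from ntra.model import refit


def random_component(rng):
    return (
        rng.uniform(0.1, 2.0),       # N
        rng.uniform(-80, 80),        # mu
        rng.uniform(5, 30),          # sigma
        rng.uniform(-5, 5),          # alpha
    )


class TestComponentDensity:
    def test_gaussian_peak(self):
        assert component_density(0.0, 1.0, 0.0, 1.0, 0.0) == pytest.approx(
            1.0 / np.sqrt(2 * np.pi)
        )

    def test_alpha_zero_is_gaussian(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(-100, 100, 20)
        got = component_density(x, 2.0, 10.0, 15.0, 0.0)
        np.testing.assert_allclose(got, 2.0 * stats.norm.pdf(x, 10.0, 15.0), rtol=1e-12)

    @pytest.mark.parametrize("seed", range(8))
    def test_mass_equals_amplitude(self, seed):
        """Quadrature of a component over the real line returns N."""
        N, mu, sigma, alpha = random_component(np.random.default_rng(seed))
        val, _ = integrate.quad(
            lambda x: component_density(x, N, mu, sigma, alpha),
            -np.inf, np.inf,
        )
        assert val == pytest.approx(N, abs=1e-6)

    def test_nonnegative_and_sigma_rejection(self):
        x = np.linspace(-300, 300, 1001)
        assert np.all(component_density(x, 1.0, 0.0, 10.0, 3.0) >= 0)
        with pytest.raises(ValueError):
            component_density(0.0, 1.0, 0.0, -1.0, 0.0)


class TestTrimodalDensity:
    def test_null_model(self, known_params):
        p = NTRAParameters(
            N=np.zeros(3), mu=known_params.mu, sigma=known_params.sigma,
            alpha=known_params.alpha,
        )
        x = np.linspace(-200, 200, 64)
        assert np.all(trimodal_density(x, p) == 0)

    def test_additivity(self, known_params):
        x = np.linspace(-200, 200, 64)
        solo = NTRAParameters(
            N=np.array([0.0, known_params.N[1], 0.0]),
            mu=known_params.mu, sigma=known_params.sigma, alpha=known_params.alpha,
        )
        np.testing.assert_allclose(
            trimodal_density(x, solo),
            component_density(x, known_params.N[1], known_params.mu[1],
                              known_params.sigma[1], 0.0),
            rtol=1e-12,
        )

    def test_total_mass(self, known_params):
        val, _ = integrate.quad(
            lambda x: float(trimodal_density(x, known_params)), -np.inf, np.inf,
            limit=200,
        )
        assert val == pytest.approx(known_params.N.sum(), abs=1e-6)


class TestParameterContainer:
    def test_eleven_free_parameters(self, known_params):
        vec = known_params.to_vector()
        assert vec.size == N_FREE_PARAMETERS == 11
        back = NTRAParameters.from_vector(vec)
        np.testing.assert_allclose(back.alpha[1], 0.0)
        np.testing.assert_allclose(back.to_vector(), vec)

    def test_centre_skew_pinned(self):
        with pytest.raises(ValueError, match="zero"):
            NTRAParameters(
                N=np.ones(3), mu=np.array([-50.0, 0.0, 50.0]),
                sigma=np.ones(3), alpha=np.array([0.0, 1.0, 0.0]),
            )

    def test_location_ordering_enforced(self):
        with pytest.raises(ValueError, match="ordered"):
            NTRAParameters(
                N=np.ones(3), mu=np.array([0.0, -50.0, 50.0]),
                sigma=np.ones(3), alpha=np.zeros(3),
            )

    def test_domains_must_ascend(self):
        with pytest.raises(ValueError):
            TissueDomains(fat=(-200, 50), connective=(-9, 40), muscle=(41, 200))


def _exact_histogram(params, n_bins=128):
    """Histogram whose density IS the model curve (no sampling noise)."""
    edges = np.linspace(-200, 200, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    density = trimodal_density(centers, params)
    return HUHistogram(
        bin_edges=edges, counts=density, total_pixels=0, density=density,
    )


class TestInitialization:
    def test_separated_peaks_located(self):
        p = NTRAParameters(
            N=np.array([0.3, 0.2, 0.5]), mu=np.array([-100.0, 15.0, 60.0]),
            sigma=np.array([8.0, 5.0, 6.0]), alpha=np.zeros(3),
        )
        init = initialize_from_domains(_exact_histogram(p))
        assert np.all(np.abs(init.mu - p.mu) < 2.0)

    def test_uniform_density_gives_midpoints(self):
        edges = np.linspace(-200, 200, 129)
        centers = 0.5 * (edges[:-1] + edges[1:])
        h = HUHistogram(
            bin_edges=edges, counts=np.ones(128), total_pixels=128,
            density=np.full(128, 1 / 400),
        )
        init = initialize_from_domains(h)
        doms = TissueDomains()
        mids = [0.5 * (lo + hi) for lo, hi in doms.intervals]
        assert np.all(np.abs(init.mu - mids) < 2.0)

    def test_empty_domain_floored(self):
        # all mass in fat+connective; muscle domain empty
        p = NTRAParameters(
            N=np.array([0.6, 0.4, 0.0]), mu=np.array([-100.0, 10.0, 60.0]),
            sigma=np.array([8.0, 5.0, 6.0]), alpha=np.zeros(3),
        )
        init = initialize_from_domains(_exact_histogram(p))
        assert init.N[2] == pytest.approx(1e-6)
        assert init.mu[2] == pytest.approx(0.5 * (41 + 200))


class TestFit:
    def test_self_consistency_zero_noise(self, known_params):
        """An exactly model-generated curve is recovered to 1e-3 relative."""
        h = _exact_histogram(known_params)
        res = fit_ntra(h, seed=0)
        assert res.r_squared >= 1 - 1e-8
        truth = known_params.to_vector()
        np.testing.assert_allclose(res.params.to_vector(), truth, rtol=1e-3, atol=5e-3)

    def test_sampled_recovery(self, trimodal_hist, known_params):
        res = fit_ntra(trimodal_hist, seed=0)
        assert res.converged
        assert np.all(np.abs(res.params.mu - known_params.mu) <= 2.0)
        np.testing.assert_allclose(res.params.N, known_params.N, rtol=0.05)

    def test_zero_density_rejected(self):
        edges = np.linspace(-200, 200, 129)
        h = HUHistogram(
            bin_edges=edges, counts=np.zeros(128), total_pixels=0,
            density=np.zeros(128),
        )
        with pytest.raises(ValueError, match="zero"):
            fit_ntra(h)

    def test_idempotence(self, trimodal_hist):
        first = fit_ntra(trimodal_hist, seed=0)
        second = refit(trimodal_hist, first)
        assert abs(second.sse - first.sse) <= 1e-12 * max(first.sse, 1e-300) + 1e-18

    def test_monotone_restart_improvement(self, trimodal_hist):
        sses = [
            fit_ntra(trimodal_hist, seed=5, n_restarts=k).sse for k in (1, 2, 4)
        ]
        assert sses[1] <= sses[0] + 1e-15
        assert sses[2] <= sses[1] + 1e-15

    def test_invalid_bounds_rejected(self, trimodal_hist):
        lo = np.zeros(11)
        hi = np.zeros(11)  # lower == upper
        with pytest.raises(ValueError, match="bounds"):
            fit_ntra(trimodal_hist, bounds=(lo, hi))

    def test_fit_counts_option(self, trimodal_pixels, known_params):
        h = build_histogram(trimodal_pixels)
        res = fit_ntra(h, use_counts=True, seed=0)
        assert np.all(np.abs(res.params.mu - known_params.mu) <= 2.0)


class TestSkewMeanLaw:
    def test_component_mean_formula(self):
        """Sampled mean matches mu - sigma*delta*sqrt(2/pi) (erfc convention)."""
        from ntra.cohort import sample_component

        mu, sigma, alpha = 20.0, 15.0, 2.0
        x = sample_component(1_000_000, mu, sigma, alpha, seed=3)
        expected = mu - sigma * (alpha / np.sqrt(1 + alpha**2)) * np.sqrt(2 / np.pi)
        assert x.mean() == pytest.approx(expected, abs=5 * sigma / 1000)
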