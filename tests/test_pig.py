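"""Poisson-inverse-Gaussian engine: pmf correctness, kernels, sampling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from spatialsort.pig import (
    PIGParams,
    TruncationError,
    pig_logpmf,
    pig_logpmf_table,
    pig_loglik,
    pig_pmf,
    pig_sample,
    symmetric_kernel,
    wave_mixture,
)

# Frozen values from independent numerical quadrature of the Poisson pmf
# against the inverse-Gaussian mixing density (mean xi, IG shape xi*omega),
# computed with scipy.integrate.quad to ~1e-9 absolute accuracy.
QUADRATURE_ORACLE = [
    (0, 1.0, 1.0, 0.48092170020252584),
    (0, 3.0, 0.5, 0.2717763923503983),
    (3, 3.0, 0.5, 0.09359703322664305),
    (5, 2.0, 4.0, 0.04366805286149014),
]


class TestPmf:
    @pytest.mark.parametrize("k,xi,omega,expected", QUADRATURE_ORACLE)
    def test_matches_quadrature_oracle(self, k, xi, omega, expected):
        assert pig_pmf(k, PIGParams(xi, omega)) == pytest.approx(expected, abs=1e-8)

    @pytest.mark.parametrize(
        "xi,omega", [(0.1, 0.05), (0.1, 50.0), (3.0, 0.5), (20.0, 0.05), (20.0, 50.0)]
    )
    def test_normalizes_over_support(self, xi, omega):
        # support long enough for the heavy-tailed corners of the grid
        var = xi * (1 + xi / omega)
        kmax = int(max(2000, xi + 400 * np.sqrt(var)))
        total = np.exp(pig_logpmf_table(kmax, xi, omega)).sum()
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_poisson_limit(self):
        params = PIGParams(3.0, 1e6)
        ks = np.arange(0, 60)
        diff = np.abs(pig_pmf(ks, params) - stats.poisson.pmf(ks, 3.0))
        assert diff.max() < 1e-6

    def test_agrees_with_direct_bessel_evaluation(self):
        import math

        from scipy.special import kv

        xi, omega = 3.0, 0.5
        L = xi * omega
        z = np.sqrt(omega**2 + 2 * L)
        direct = np.array(
            [
                np.sqrt(L / (2 * np.pi)) * np.exp(omega) * 2
                * (L / z) ** (k - 0.5) * kv(k - 0.5, z) / math.factorial(k)
                for k in range(30)
            ]
        )
        ours = pig_pmf(np.arange(30), PIGParams(xi, omega))
        assert np.abs(ours / direct - 1).max() < 1e-8

    def test_stable_at_large_k_small_omega(self):
        table = pig_logpmf_table(500, 50.0, 0.01)
        assert np.all(np.isfinite(table))

    @pytest.mark.parametrize("bad", [-1, 1.5, [2, -3]])
    def test_rejects_invalid_counts(self, bad):
        with pytest.raises(ValueError):
            pig_logpmf(bad, PIGParams(1, 1))

    @pytest.mark.parametrize("xi,omega", [(0, 1), (-1, 1), (1, 0), (1, -2), (np.nan, 1)])
    def test_rejects_invalid_params(self, xi, omega):
        with pytest.raises(ValueError):
            PIGParams(xi, omega)

    @given(
        xi=st.floats(0.1, 20.0),
        omega=st.floats(0.05, 50.0),
    )
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_pmf_is_probability_mass(self, xi, omega):
        var = xi * (1 + xi / omega)
        kmax = int(max(1000, xi + 300 * np.sqrt(var)))
        table = np.exp(pig_logpmf_table(min(kmax, 60_000), xi, omega))
        assert np.all(table >= 0)
        assert table.sum() <= 1 + 1e-9


class TestSampling:
    def test_moments_match(self):
        params = PIGParams(2.0, 4.0)
        x = pig_sample(10**6, params, 7)
        se = np.sqrt(params.variance / x.size)
        assert abs(x.mean() - 2.0) < 3 * se
        assert x.var() == pytest.approx(3.0, rel=0.02)  # xi(1 + xi/omega)

    def test_empty_draw(self):
        assert pig_sample(0, PIGParams(1, 1), 0).size == 0

    def test_reproducible(self):
        a = pig_sample(100, PIGParams(1.5, 0.8), 42)
        b = pig_sample(100, PIGParams(1.5, 0.8), 42)
        assert np.array_equal(a, b)

    def test_goodness_of_fit(self):
        params = PIGParams(1.5, 0.8)
        x = pig_sample(100_000, params, 11)
        kmax = 15
        obs = np.bincount(np.minimum(x, kmax), minlength=kmax + 1)
        pm = pig_pmf(np.arange(kmax), params)
        expected = np.append(pm, 1 - pm.sum()) * x.size
        chi2 = ((obs - expected) ** 2 / expected).sum()
        # df = kmax; alpha = 0.001
        assert chi2 < stats.chi2.ppf(0.999, kmax)


class TestSymmetricKernel:
    def test_symmetry_and_normalization(self):
        K = symmetric_kernel(PIGParams(3.0, 0.5))
        assert np.allclose(K.probs, K.probs[::-1])
        assert K.probs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_zero_class_counted_once(self):
        params = PIGParams(2.0, 1.0)
        K = symmetric_kernel(params)
        assert K.prob(0) == pytest.approx(pig_pmf(0, params), rel=1e-8)
        assert K.prob(3) == pytest.approx(pig_pmf(3, params) / 2, rel=1e-8)
        # direct enumeration: mass off zero equals 1 - PIG(0)
        off_zero = K.probs.sum() - K.prob(0)
        assert off_zero == pytest.approx(1 - pig_pmf(0, params), abs=1e-8)

    def test_truncation_error_raised(self):
        with pytest.raises(TruncationError):
            symmetric_kernel(PIGParams(5.0, 0.5), support_radius=3)

    def test_mean_is_zero(self):
        K = symmetric_kernel(PIGParams(1.5, 0.7))
        assert K.mean == pytest.approx(0.0, abs=1e-12)


class TestWaveMixture:
    def test_single_source_equals_kernel(self):
        params = PIGParams(1.5, 0.7)
        K = symmetric_kernel(params)
        M = wave_mixture(params, 1)
        assert np.allclose(M.probs, K.probs)

    def test_mean_is_source_centroid(self):
        # moment oracle: mean(M) = mean(K) + (N-1)/2, and mean(K) = 0
        M = wave_mixture(PIGParams(1.5, 0.7), 5)
        assert M.mean == pytest.approx(2.0, abs=1e-10)

    def test_normalizes(self):
        M = wave_mixture(PIGParams(2.0, 0.3), 5)
        assert M.probs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_rejects_no_sources(self):
        with pytest.raises(ValueError):
            wave_mixture(PIGParams(1, 1), 0)


class TestLoglik:
    def test_single_point(self):
        assert pig_loglik([0], PIGParams(1, 1)) == pytest.approx(
            float(pig_logpmf(0, PIGParams(1, 1)))
        )

    def test_permutation_invariant(self, rng):
        data = pig_sample(50, PIGParams(2, 1), rng)
        p = PIGParams(1.7, 0.9)
        assert pig_loglik(data, p) == pytest.approx(pig_loglik(data[::-1], p))

    def test_grid_maximum_near_truth(self):
        truth = PIGParams(2.0, 1.0)
        data = pig_sample(10_000, truth, 5)
        xis = np.linspace(1.6, 2.4, 33)
        omegas = np.linspace(0.6, 1.4, 33)
        ll = np.array(
            [[pig_loglik(data, PIGParams(x, o)) for o in omegas] for x in xis]
        )
        i, j = np.unravel_index(np.argmax(ll), ll.shape)
        assert abs(xis[i] - 2.0) / 2.0 < 0.05
        assert abs(omegas[j] - 1.0) < 0.05 * 1.0 + 0.05

    def test_empty_data_rejected(self):
        with pytest.raises(ValueError):
            pig_loglik([], PIGParams(1, 1))
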