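"""Dispersal-kernel inference: spec lattice, discrete KS, wave fits."""

import numpy as np
import pandas as pd
import pytest

from spatialsort.inference import SamplerConfig
from spatialsort.kernels import (
    KernelSpec,
    candidate_kernel_specs,
    compare_pre_post,
    discrete_ks_test,
    fit_kernel_model,
    fit_pig_ml,
    fit_wave_kernels,
)
from spatialsort.pig import PIGParams, pig_sample, wave_mixture

from conftest import simulate_kernel_obs


class TestCandidateSpecs:
    def test_lattice_contents(self):
        specs = candidate_kernel_specs()
        assert KernelSpec((), False) in specs                       # null
        assert KernelSpec(("TRT", "CGG", "TRTxCGG"), True) in specs  # full
        assert len(specs) == len(set(specs))
        # interaction never appears without both main effects
        for s in specs:
            if "TRTxCGG" in s.terms:
                assert {"TRT", "CGG"} <= set(s.terms)


class TestDiscreteKS:
    def test_identical_samples(self):
        a = [0, 1, 1, 2, 3]
        res = discrete_ks_test(a, a, n_boot=500, rng=0)
        assert res.d == 0
        assert res.p_value > 0.9

    def test_hand_enumeration_oracle(self):
        # F_a on {0,1,2}: 1/3, 1, 1 ; F_b: 0, 1/2, 1
        res = discrete_ks_test([0, 1, 1], [1, 2], n_boot=100, rng=0)
        assert res.d_plus == pytest.approx(1 / 2)
        assert res.d_minus == pytest.approx(0.0)
        assert res.d == pytest.approx(1 / 2)

    def test_matches_bruteforce_ecdf_on_random_pairs(self, rng):
        for _ in range(100):
            a = rng.integers(0, 8, size=rng.integers(2, 40))
            b = rng.integers(0, 8, size=rng.integers(2, 40))
            res = discrete_ks_test(a, b, n_boot=10, rng=1)
            support = np.arange(min(a.min(), b.min()), max(a.max(), b.max()) + 1)
            fa = np.array([(a <= x).mean() for x in support])
            fb = np.array([(b <= x).mean() for x in support])
            assert res.d_plus == pytest.approx(max((fa - fb).max(), 0.0))
            assert res.d_minus == pytest.approx(max((fb - fa).max(), 0.0))

    def test_shifting_a_up_lowers_its_ecdf_excess(self, rng):
        a = rng.integers(0, 6, size=60)
        b = rng.integers(0, 6, size=60)
        base = discrete_ks_test(a, b, n_boot=10, rng=2)
        shifted = discrete_ks_test(a + 1, b, n_boot=10, rng=2)
        assert shifted.d_plus <= base.d_plus + 1e-12

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            discrete_ks_test([], [1, 2], n_boot=10, rng=0)

    def test_detects_true_shift(self, rng):
        a = pig_sample(400, PIGParams(1.0, 0.8), rng)
        b = pig_sample(400, PIGParams(2.0, 0.8), rng)
        res = discrete_ks_test(a, b, n_boot=2000, rng=3)
        assert res.p_value < 0.01
        assert res.d_plus > res.d_minus  # a is stochastically smaller


class TestWaveFits:
    def test_recovers_mixture_parameters(self):
        truth = PIGParams(1.5, 0.7)
        M = wave_mixture(truth, 5)
        rng = np.random.default_rng(0)
        draws = rng.choice(M.support, p=M.probs, size=2000)
        counts = pd.DataFrame(
            {"patch": np.arange(draws.min(), draws.max() + 1)}
        )
        counts["females"] = [(draws == p).sum() for p in counts["patch"]]
        counts["males"] = 0
        fit = fit_wave_kernels(counts, "female", "sorted")
        assert float(fit.draws["xi"].iloc[0]) == pytest.approx(1.5, rel=0.10)
        assert float(fit.draws["omega"].iloc[0]) == pytest.approx(0.7, rel=0.10)

    def test_single_source_reduces_to_magnitude_fit(self):
        truth = PIGParams(1.2, 0.9)
        rng = np.random.default_rng(1)
        mags = pig_sample(3000, truth, rng)
        signs = np.where(mags == 0, 1, rng.integers(0, 2, mags.size) * 2 - 1)
        positions = mags * signs
        counts = pd.DataFrame({"patch": np.arange(positions.min(), positions.max() + 1)})
        counts["males"] = [(positions == p).sum() for p in counts["patch"]]
        counts["females"] = 0
        wave = fit_wave_kernels(counts, "male", "sorted", n_sources=1)
        direct = fit_pig_ml(mags)
        assert float(wave.draws["xi"].iloc[0]) == pytest.approx(
            float(direct.draws["xi"].iloc[0]), rel=0.02
        )

    def test_likelihood_peaks_at_truth_for_large_n(self):
        from spatialsort.kernels import _wave_negloglik

        truth = PIGParams(1.5, 0.7)
        M = wave_mixture(truth, 5)
        n = (M.probs * 100_000).round()
        pos = M.support
        at_truth = _wave_negloglik(np.log([1.5, 0.7]), pos, n, 5)
        at_perturbed = _wave_negloglik(np.log([3.0, 0.7]), pos, n, 5)
        assert at_truth < at_perturbed

    def test_ml_consistency_large_sample(self):
        truth = PIGParams(2.0, 1.0)
        data = pig_sample(100_000, truth, 9)
        fit = fit_pig_ml(data)
        assert float(fit.draws["xi"].iloc[0]) == pytest.approx(2.0, rel=0.02)
        assert float(fit.draws["omega"].iloc[0]) == pytest.approx(1.0, rel=0.05)


class TestPrePost:
    def _pre(self, xi=1.5):
        return {
            ("sorted", "female"): fit_from_value(xi),
            ("shuffled", "female"): fit_from_value(xi),
        }

    def test_identical_fits_zero_shift(self):
        pre = self._pre()
        post = {("r1", "sorted", "female"): fit_from_value(1.5)}
        table = compare_pre_post(pre, post)
        assert table["shift"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_table_covers_all_replicate_sex_pairs(self):
        pre = self._pre()
        post = {
            (f"r{i}", trt, "female"): fit_from_value(1.5 + 0.1 * i)
            for i in range(3)
            for trt in ("sorted", "shuffled")
        }
        table = compare_pre_post(pre, post)
        assert len(table) == len(post)

    def test_unmatched_labels_rejected(self):
        post = {("r1", "sorted", "male"): fit_from_value(1.0)}
        with pytest.raises(ValueError):
            compare_pre_post(self._pre(), post)


def fit_from_value(xi, omega=1.0, se_log=0.05):
    from spatialsort.inference import FitResult

    return FitResult(
        draws=pd.DataFrame({"xi": [xi], "omega": [omega]}),
        pointwise_loglik=None,
        diagnostics={"se_log": np.array([se_log, se_log]), "converged": True},
        criterion=np.nan,
        criterion_name="aic",
    )


class TestHierarchicalKernelModel:
    def test_posterior_centres_on_truth_single_replicate(self):
        obs = simulate_kernel_obs(
            alpha_trt=0.0, seed=4, n_rep=1, n_per=2000, sd_eps=1e-3, sd_gam=1e-3
        )
        obs = obs[obs.treatment == "sorted"]
        fit = fit_kernel_model(
            obs,
            KernelSpec((), False),
            "female",
            SamplerConfig(n_steps=1000, seed=0, ess_min=100, max_pointwise_draws=100),
        )
        # with a single replicate only the cell-level parameters
        # (intercept + replicate effect) are identified
        rep = obs["replicate"].iloc[0]
        log_xi = fit.draws["alpha_1"] + fit.draws[f"eps_raw_{rep}"] * np.exp(
            fit.draws["log_sd_eps_0"]
        )
        log_om = fit.draws["beta_1"] + fit.draws[f"gam_raw_{rep}"] * np.exp(
            fit.draws["log_sd_gam_0"]
        )
        assert np.exp(np.median(log_xi)) == pytest.approx(1.8, rel=0.05)
        assert np.exp(np.median(log_om)) == pytest.approx(1.0, rel=0.15)

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError):
            fit_kernel_model(
                pd.DataFrame({"distance": [1, 2]}), KernelSpec((), False), "female"
            )
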