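"""Signal models, simulator and the analytic (Lyapunov) oracles."""

import numpy as np
import pytest

from eipr import (
    DataError,
    EiprError,
    UnstableModelError,
    VarModelSpec,
    simulate_var,
    stationary_autocovariance,
    synth_ecog,
    true_eipr,
    true_partial_powers,
    winterhalder_model,
)

from conftest import CAUSAL_PAIRS, NONCAUSAL_PAIRS, random_stable_sparse_spec


class TestBenchmarkModel:
    @pytest.mark.parametrize(
        "lag,target,source,value",
        [
            (1, 0, 0, 0.8), (4, 0, 1, 0.65),
            (1, 1, 1, 0.6), (5, 1, 3, 0.6),
            (3, 2, 2, 0.5), (1, 2, 0, -0.6), (4, 2, 1, 0.4),
            (1, 3, 3, 1.2), (2, 3, 3, -0.7),
        ],
    )
    def test_coefficients(self, benchmark, lag, target, source, value):
        assert benchmark.coeffs[lag - 1, target, source] == pytest.approx(value)

    def test_all_other_coefficients_zero(self, benchmark):
        assert np.count_nonzero(benchmark.coeffs) == 9
        assert np.array_equal(benchmark.noise_cov, np.eye(4))
        assert benchmark.order == 5 and benchmark.n_channels == 4

    def test_stable(self, benchmark):
        rho = benchmark.spectral_radius()
        assert rho < 1.0
        assert rho == pytest.approx(0.83666, abs=1e-4)


class TestVarModelSpec:
    def test_rejects_asymmetric_noise_cov(self):
        with pytest.raises(DataError, match="symmetric"):
            VarModelSpec(
                coeffs=np.zeros((1, 2, 2)),
                noise_cov=np.array([[1.0, 0.5], [0.0, 1.0]]),
            )

    def test_rejects_indefinite_noise_cov(self):
        with pytest.raises(DataError, match="positive definite"):
            VarModelSpec(
                coeffs=np.zeros((1, 2, 2)),
                noise_cov=np.array([[1.0, 2.0], [2.0, 1.0]]),
            )

    def test_rejects_nonsquare_coeffs(self):
        with pytest.raises(DataError):
            VarModelSpec(coeffs=np.zeros((1, 2, 3)), noise_cov=np.eye(2))


class TestSimulateVar:
    def test_benchmark_shape(self, benchmark):
        rec = simulate_var(benchmark, 12800, seed=0)
        assert rec.data.shape == (4, 12800)
        assert rec.sampling_rate == 128.0

    def test_deterministic_given_seed(self, benchmark):
        a = simulate_var(benchmark, 500, seed=7)
        b = simulate_var(benchmark, 500, seed=7)
        c = simulate_var(benchmark, 500, seed=8)
        assert np.array_equal(a.data, b.data)
        assert not np.array_equal(a.data, c.data)

    def test_zero_coefficients_give_white_noise(self):
        spec = VarModelSpec(coeffs=np.zeros((2, 3, 3)), noise_cov=np.eye(3))
        rec = simulate_var(spec, 20000, seed=2)
        x = rec.data - rec.data.mean(axis=1, keepdims=True)
        lag1 = np.array(
            [x[k, 1:] @ x[k, :-1] / (x[k] @ x[k]) for k in range(3)]
        )
        assert np.abs(lag1).max() < 0.03

    def test_ar1_stationary_variance(self, ar1_spec):
        rec = simulate_var(ar1_spec, 200000, seed=0)
        assert rec.data.var() == pytest.approx(1 / (1 - 0.64), rel=0.02)

    def test_unstable_spec_rejected_with_radius(self):
        spec = VarModelSpec(coeffs=np.array([[[1.2]]]), noise_cov=np.array([[1.0]]))
        with pytest.raises(UnstableModelError) as err:
            simulate_var(spec, 100, seed=0)
        assert err.value.spectral_radius == pytest.approx(1.2)

    def test_custom_noise_sampler(self, ar1_spec):
        def uniform_noise(rng, n, k):
            return rng.uniform(-np.sqrt(3), np.sqrt(3), size=(n, k))

        rec = simulate_var(ar1_spec, 50000, seed=0, noise_sampler=uniform_noise)
        assert rec.data.var() == pytest.approx(1 / (1 - 0.64), rel=0.05)


class TestStationaryAutocovariance:
    def test_ar1_closed_form(self, ar1_spec):
        acov = stationary_autocovariance(ar1_spec, max_lag=3)
        g0 = 1.0 / (1 - 0.64)
        assert acov.gamma(0)[0, 0] == pytest.approx(g0, abs=1e-10)
        assert acov.gamma(1)[0, 0] == pytest.approx(0.8 * g0, abs=1e-10)
        assert acov.gamma(2)[0, 0] == pytest.approx(0.64 * g0, abs=1e-10)
        assert acov.gamma(-1)[0, 0] == pytest.approx(0.8 * g0, abs=1e-10)

    def test_white_noise_gammas(self):
        sigma = np.array([[2.0, 0.3], [0.3, 1.0]])
        spec = VarModelSpec(coeffs=np.zeros((1, 2, 2)), noise_cov=sigma)
        acov = stationary_autocovariance(spec, max_lag=2)
        assert np.allclose(acov.gamma(0), sigma, atol=1e-12)
        assert np.allclose(acov.gamma(1), 0, atol=1e-12)
        assert np.allclose(acov.gamma(2), 0, atol=1e-12)

    def test_matches_long_simulation(self, benchmark):
        """Sample autocovariance of a 1e6-sample run converges to the oracle."""
        rec = simulate_var(benchmark, 1_000_000, seed=0)
        x = rec.data - rec.data.mean(axis=1, keepdims=True)
        acov = stationary_autocovariance(benchmark, max_lag=5)
        n = x.shape[1]
        for s in range(6):
            sample = x[:, s:] @ x[:, : n - s].T / (n - s)
            scale = np.abs(acov.gamma(0)).max()
            assert np.abs(sample - acov.gamma(s)).max() / scale < 0.05

    def test_unstable_rejected(self):
        spec = VarModelSpec(coeffs=np.array([[[1.0]]]), noise_cov=np.array([[1.0]]))
        with pytest.raises(UnstableModelError, match="1"):
            stationary_autocovariance(spec, max_lag=1)


class TestTrueEipr:
    def test_benchmark_structure(self, benchmark):
        eta = true_eipr(benchmark)
        assert np.array_equal(np.diag(eta), np.ones(4))
        for k, l in CAUSAL_PAIRS:
            assert eta[k, l] > 0
        for k, l in NONCAUSAL_PAIRS:
            assert eta[k, l] == 0.0

    def test_matches_monte_carlo(self, benchmark):
        """Analytic EIPR sits within 3 SE of the mean over 20 estimates."""
        from eipr import eipr_matrix

        eta = true_eipr(benchmark)
        draws = np.array(
            [
                eipr_matrix(
                    simulate_var(benchmark, 12800, seed=s).data, 5,
                    use_selection=False,
                ).values
                for s in range(20)
            ]
        )
        mean = draws.mean(axis=0)
        se = draws.std(axis=0, ddof=1) / np.sqrt(20)
        for k, l in CAUSAL_PAIRS:
            assert abs(mean[k, l] - eta[k, l]) < 3 * se[k, l]

    def test_scale_invariance(self, benchmark):
        """Rescaling channels (with adjusted coefficients) leaves EIPR fixed."""
        rng = np.random.default_rng(0)
        c = rng.uniform(0.25, 4.0, size=4)
        D, Dinv = np.diag(c), np.diag(1 / c)
        scaled = VarModelSpec(
            coeffs=np.array([D @ A @ Dinv for A in benchmark.coeffs]),
            noise_cov=D @ benchmark.noise_cov @ D,
        )
        assert np.allclose(true_eipr(scaled), true_eipr(benchmark), atol=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_zero_iff_granger_noncausal(self, seed):
        """Off-diagonal population EIPR is 0 exactly when A_{k,l}[.] == 0."""
        spec = random_stable_sparse_spec(np.random.default_rng(seed))
        eta = true_eipr(spec)
        K = spec.n_channels
        for k in range(K):
            for l in range(K):
                if k == l:
                    continue
                if np.all(spec.coeffs[:, k, l] == 0):
                    assert eta[k, l] == 0.0
                else:
                    assert eta[k, l] > 0

    def test_zero_intrinsic_power_rejected(self):
        # channel 0 has no intrinsic dynamics at all -> V{mu_00} = 0
        A = np.zeros((1, 2, 2))
        A[0, 0, 1] = 0.5
        A[0, 1, 1] = 0.3
        spec = VarModelSpec(coeffs=A, noise_cov=np.eye(2))
        with pytest.raises(EiprError, match="intrinsic"):
            true_eipr(spec)

    def test_partial_powers_definition(self, benchmark):
        """V{mu_{2,4}} has a single lag-5 coefficient: V = 0.36 * r_4[0]."""
        acov = stationary_autocovariance(benchmark, max_lag=5)
        V = true_partial_powers(benchmark)
        assert V[1, 3] == pytest.approx(0.36 * acov.autocorr(3, 0), rel=1e-12)


class TestSynthEcog:
    def test_deterministic(self):
        a = synth_ecog(4, 0, 1000, 2000, seed=5)
        b = synth_ecog(4, 0, 1000, 2000, seed=5)
        assert np.array_equal(a.data, b.data)

    def test_shape_and_labels(self):
        rec = synth_ecog(5, 2, 500, 1500, seed=1)
        assert rec.data.shape == (5, 1500)
        assert rec.channel_labels == [f"E{k}" for k in range(5)]

    def test_coupling_appears_after_onset(self):
        """Estimated EIPR into the driven channels rises after onset."""
        from eipr import eipr_matrix

        rec = synth_ecog(4, 0, 4096, 8192, seed=2, neighbors=[1, 2])
        pre = eipr_matrix(rec.data[:, :4096], 7, use_selection=False).values
        post = eipr_matrix(rec.data[:, 4096:], 7, use_selection=False).values
        assert post[1, 0] > pre[1, 0]
        assert post[2, 0] > pre[2, 0]

    def test_unstable_parameters_rejected(self):
        with pytest.raises(UnstableModelError):
            synth_ecog(4, 0, 100, 1000, seed=0, focus_modulus=1.01)
        with pytest.raises(UnstableModelError):
            synth_ecog(3, 0, 100, 1000, seed=0, background_modulus=1.5)

    def test_invalid_onset_rejected(self):
        with pytest.raises(DataError):
            synth_ecog(4, 0, 2000, 1000, seed=0)
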