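"""Surrogate nulls and significance thresholds."""

import logging

import numpy as np
import pytest

from eipr import (
    SignificanceConfig,
    SurrogateDistribution,
    eipr_matrix,
    loom_bootstrap_eiprs,
    make_surrogates,
    significance_thresholds,
    significant_coupling,
    simulate_var,
    surrogate_eiprs,
    synth_ecog,
)

from conftest import CAUSAL_PAIRS, NONCAUSAL_PAIRS


def _distribution_with(mean, sd, n=100):
    """N draws for one pair with exact sample mean and sd (ddof=1)."""
    rng = np.random.default_rng(0)
    a = rng.standard_normal(n)
    z = (a - a.mean()) / a.std(ddof=1)
    vals = np.full((n, 2, 2), np.nan)
    vals[:, 0, 1] = mean + sd * z
    return SurrogateDistribution(values=vals)


class TestThresholdRules:
    def test_mean_ci_matches_worked_example(self):
        """mean 0.01, sd 0.02, N=100, alpha=0.01 -> 0.01 + 2.3646*0.02/10."""
        cfg = SignificanceConfig(threshold_rule="mean_ci")
        dist = _distribution_with(0.01, 0.02)
        thr = significance_thresholds(
            np.zeros((2, 64)), 2, cfg, sets=((1,), ()), distribution=dist
        )
        assert thr[0, 1] == pytest.approx(0.014729, abs=1e-5)
        assert np.isnan(thr[1, 0]) and np.isnan(thr[0, 0])

    def test_t_quantile_value(self):
        assert SignificanceConfig().t_quantile == pytest.approx(2.3646, abs=1e-4)

    @pytest.mark.parametrize("rule", ["log_prediction", "prediction", "mean_ci"])
    def test_monotone_in_mean_and_sd(self, rule):
        cfg = SignificanceConfig(threshold_rule=rule)
        window, sets = np.zeros((2, 64)), ((1,), ())

        def thr(mean, sd):
            return significance_thresholds(
                window, 2, cfg, sets=sets,
                distribution=_distribution_with(mean, sd),
            )[0, 1]

        # positive-valued null samples (required by the log-scale rule)
        assert thr(0.2, 0.02) > thr(0.1, 0.02)
        assert thr(0.1, 0.03) > thr(0.1, 0.02)

    def test_zero_spread_degenerates_to_mean(self, caplog):
        cfg = SignificanceConfig()
        vals = np.full((100, 2, 2), np.nan)
        vals[:, 0, 1] = 0.42
        with caplog.at_level(logging.WARNING, logger="eipr"):
            thr = significance_thresholds(
                np.zeros((2, 64)), 2, cfg, sets=((1,), ()),
                distribution=SurrogateDistribution(values=vals),
            )
        assert thr[0, 1] == pytest.approx(0.42)
        assert "zero surrogate variance" in caplog.text

    def test_invalid_config_rejected(self):
        with pytest.raises(Exception):
            SignificanceConfig(n_surrogates=1)
        with pytest.raises(Exception):
            SignificanceConfig(alpha=0.7)
        with pytest.raises(Exception):
            SignificanceConfig(method="fft_magic")


class TestWindowSurrogates:
    def test_deterministic(self, benchmark_recording):
        cfg = SignificanceConfig(n_surrogates=5, method="circular_shift", seed=3)
        a = make_surrogates(benchmark_recording.data, cfg)
        b = make_surrogates(benchmark_recording.data, cfg)
        for sa, sb in zip(a, b):
            assert np.array_equal(sa, sb)

    def test_circular_shift_preserves_circular_autocorrelation(self):
        x = np.random.default_rng(2).standard_normal((3, 256))
        cfg = SignificanceConfig(n_surrogates=4, method="circular_shift", seed=1)
        for surr in make_surrogates(x, cfg):
            for k in range(3):
                for s in range(1, 6):
                    orig = x[k] @ np.roll(x[k], s)
                    got = surr[k] @ np.roll(surr[k], s)
                    assert got == pytest.approx(orig, rel=1e-12)

    def test_block_permute_preserves_marginal_samples(self):
        x = np.random.default_rng(4).standard_normal((2, 256))
        cfg = SignificanceConfig(n_surrogates=3, method="block_permute", seed=1)
        for surr in make_surrogates(x, cfg):
            for k in range(2):
                assert np.array_equal(np.sort(surr[k]), np.sort(x[k]))

    def test_cross_channel_alignment_destroyed(self, benchmark_recording):
        """Mean cross-correlation at the imposed lags shrinks toward zero."""
        x = benchmark_recording.data
        x = x - x.mean(axis=1, keepdims=True)
        cfg = SignificanceConfig(n_surrogates=20, method="circular_shift", seed=9)
        # x3 <- x1 at lag 1 is the strongest imposed dependency
        def lag1_corr(w):
            a, b = w[2, 1:], w[0, :-1]
            return (a - a.mean()) @ (b - b.mean()) / (
                len(a) * a.std() * b.std()
            )

        assert abs(lag1_corr(x)) > 0.3
        rho = np.mean([abs(lag1_corr(s)) for s in make_surrogates(x, cfg)])
        assert rho < 0.05

    def test_surrogate_eiprs_shape_and_determinism(self, benchmark_recording):
        cfg = SignificanceConfig(
            n_surrogates=8, method="circular_shift", seed=11
        )
        d1 = surrogate_eiprs(benchmark_recording.data, 5, cfg, use_selection=False)
        d2 = surrogate_eiprs(benchmark_recording.data, 5, cfg, use_selection=False)
        assert d1.values.shape == (8, 4, 4)
        assert np.array_equal(d1.values, d2.values)
        # surrogate EIPR of a decoupled window is far below the real coupling
        cm = eipr_matrix(benchmark_recording.data, 5, use_selection=False)
        assert d1.mean[2, 0] < 0.01 < cm.values[2, 0]


class TestLoomBootstrap:
    def test_deterministic(self, benchmark_recording):
        cfg = SignificanceConfig(n_surrogates=20, seed=5)
        a = loom_bootstrap_eiprs(benchmark_recording.data, 5, cfg)
        b = loom_bootstrap_eiprs(benchmark_recording.data, 5, cfg)
        assert np.array_equal(
            a.values[np.isfinite(a.values)], b.values[np.isfinite(b.values)]
        )

    def test_null_values_positive_and_small(self, benchmark_recording):
        cfg = SignificanceConfig(n_surrogates=30, seed=5)
        dist = loom_bootstrap_eiprs(benchmark_recording.data, 5, cfg)
        finite = dist.values[np.isfinite(dist.values)]
        assert np.all(finite > 0)
        assert np.median(finite) < 0.01

    def test_respects_extrinsic_sets(self, benchmark_recording):
        cfg = SignificanceConfig(n_surrogates=10, seed=2)
        sets = ((1,), (3,), (0, 1), ())
        dist = loom_bootstrap_eiprs(benchmark_recording.data, 5, cfg, sets=sets)
        assert np.isfinite(dist.values[:, 0, 1]).all()
        assert np.isnan(dist.values[:, 0, 2]).all()   # unselected pair
        assert np.isnan(dist.values[:, 3, :]).all()   # empty set -> no pairs


class TestSignificantCoupling:
    def test_benchmark_mask_matches_imposed_structure(self, benchmark_recording):
        cfg = SignificanceConfig(seed=7)
        cm = significant_coupling(
            benchmark_recording.data, 5, cfg, use_selection=False
        )
        for k, l in CAUSAL_PAIRS:
            assert cm.significant[k, l]
            assert cm.values[k, l] > cm.thresholds[k, l]
        for k, l in NONCAUSAL_PAIRS:
            assert not cm.significant[k, l]
        assert not cm.significant.diagonal().any()

    def test_null_rate_on_white_noise(self):
        """Independent channels: flagged pairs stay near the nominal level."""
        flags, tests = 0, 0
        for rep in range(8):
            x = np.random.default_rng(200 + rep).standard_normal((5, 1024))
            cm = significant_coupling(
                x, 3, SignificanceConfig(seed=900 + rep), use_selection=False
            )
            flags += int(cm.significant.sum())
            tests += 20
        assert flags / tests <= 0.06

    def test_uncoupled_fixture_not_significant(self):
        """gain=0: no coupling injected, so post-onset windows stay quiet."""
        quiet = 0
        for seed in range(8):
            rec = synth_ecog(4, 0, 1024, 2048, seed=seed, gain=0.0)
            cm = significant_coupling(
                rec.data[:, 1024:], 7, SignificanceConfig(seed=50 + seed)
            )
            quiet += int(cm.significant.sum()) == 0
        assert quiet >= 6

    def test_selection_mode_thresholds_only_for_selected(self, benchmark_recording):
        cfg = SignificanceConfig(seed=3)
        cm = significant_coupling(benchmark_recording.data, 5, cfg)
        for k, l in CAUSAL_PAIRS:
            assert np.isfinite(cm.thresholds[k, l])
        assert np.isnan(cm.thresholds[3, 0])  # L4 is empty
        assert not cm.significant[3].any()
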