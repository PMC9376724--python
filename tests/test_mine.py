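"""DV-bound training, bias-correction fit, jackknife and replicate handling.

Structural and self-consistency checks run with a budget network; the full
quantitative calibration against closed-form Gaussian MI lives in the
acceptance suite.
"""

from dataclasses import replace

import numpy as np
import pytest

from phenoinfo import (
    MineConfig,
    TrainingCurve,
    estimate_mi,
    fit_bias_curve,
    jackknife_correct,
    train_dv_bound,
)
from phenoinfo.mine import _bias_model


def make_curve(i_true, a, b, c, n=2000, noise=0.0, seed=0):
    t = np.arange(1, n + 1, dtype=float)
    y = _bias_model(t, i_true, a, b, c)
    if noise:
        y = y + np.random.default_rng(seed).normal(0, noise, size=n)
    return TrainingCurve(iterations=t, observed_bound=y)


class TestMineConfig:
    def test_published_defaults(self):
        cfg = MineConfig()
        assert cfg.hidden_units == 600
        assert cfg.learning_rate == pytest.approx(3e-4)
        assert cfg.n_replicates == 3

    def test_invalid_rejected(self):
        with pytest.raises(ValueError):
            MineConfig(hidden_units=0)
        with pytest.raises(ValueError):
            MineConfig(ema_decay=1.5)


class TestBiasFit:
    # model-generated curves carry no warmup artifact, so the cleanup cut
    # that real training curves need is disabled here
    def test_parameter_recovery_within_5pct(self):
        true = dict(i_true=2.0, a=0.9, b=0.01, c=1e-5)
        fit = fit_bias_curve(make_curve(**true, noise=0.01), warmup_fraction=0.0)
        assert fit.converged
        for name, val in true.items():
            assert getattr(fit, name) == pytest.approx(val, rel=0.05)

    def test_pure_saturating_exponential_limit(self):
        fit = fit_bias_curve(make_curve(1.5, 1.0, 0.005, 0.0, noise=0.005), warmup_fraction=0.0)
        assert fit.i_true == pytest.approx(1.5, rel=0.02)
        assert abs(fit.c) < 1e-5

    def test_flat_curve_degenerate(self):
        fit = fit_bias_curve(make_curve(0.8, 0.0, 0.01, 0.0, noise=1e-4), warmup_fraction=0.0)
        assert fit.i_true == pytest.approx(0.8, abs=0.02)
        assert abs(fit.c) < 1e-5

    def test_short_curve_rejected(self):
        fit = fit_bias_curve(make_curve(1.0, 0.9, 0.01, 0.0, n=20))
        assert not fit.converged

    def test_noisy_minibatch_level_noise_still_converges(self):
        # per-iteration spread ~0.15 bits, far above the misfit threshold,
        # must not fail the fit: the diagnostic uses block-averaged residuals
        fit = fit_bias_curve(make_curve(1.0, 0.9, 0.01, 1e-5, noise=0.15))
        assert fit.converged
        assert fit.i_true == pytest.approx(1.0, rel=0.05)


class TestTraining:
    def test_determinism_same_seed(self, fast_config):
        rng = np.random.default_rng(0)
        x, y = rng.standard_normal((500, 1)), rng.standard_normal((500, 1))
        c1 = train_dv_bound(x, y, fast_config)
        c2 = train_dv_bound(x, y, fast_config)
        np.testing.assert_array_equal(c1.observed_bound, c2.observed_bound)

    def test_independence_fluctuates_near_zero(self, fast_config):
        rng = np.random.default_rng(1)
        x, y = rng.standard_normal((2000, 1)), rng.standard_normal((2000, 1))
        fit = fit_bias_curve(train_dv_bound(x, y, fast_config))
        assert abs(fit.i_true) < 0.1

    def test_exact_copy_beats_noisy_copy(self, fast_config):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((3000, 1))
        cfg = replace(fast_config, n_iterations=2500)
        exact = fit_bias_curve(train_dv_bound(x, x, cfg)).i_true
        noisy = fit_bias_curve(
            train_dv_bound(x, x + 0.5 * rng.standard_normal((3000, 1)), cfg)
        ).i_true
        assert exact > noisy

    def test_mismatched_rows_rejected(self, fast_config):
        with pytest.raises(ValueError, match="same number of rows"):
            train_dv_bound(np.zeros((10, 1)), np.zeros((12, 1)), fast_config)

    def test_numba_and_numpy_backends_agree(self):
        """Both inner-loop implementations consume the same pregenerated
        random stream and must produce numerically matching bound curves."""
        rng = np.random.default_rng(11)
        z = rng.multivariate_normal([0, 0], [[1, 0.6], [0.6, 1]], size=1000)
        cfg = MineConfig(
            hidden_units=32, n_iterations=300, batch_size=64,
            n_replicates=1, n_jackknife=0, seed=2,
        )
        c_nb = train_dv_bound(z[:, :1], z[:, 1:], replace(cfg, backend="numba"))
        c_np = train_dv_bound(z[:, :1], z[:, 1:], replace(cfg, backend="numpy"))
        np.testing.assert_allclose(
            c_nb.observed_bound, c_np.observed_bound, atol=5e-4
        )


class TestJackknife:
    def test_no_bias_case_small_correction(self, fast_config):
        rng = np.random.default_rng(3)
        x, y = rng.standard_normal((4000, 1)), rng.standard_normal((4000, 1))
        cfg = replace(fast_config, n_jackknife=2)
        rec = jackknife_correct(x, y, cfg)
        assert rec["corrected"] is not None
        assert abs(rec["corrected"] - rec["uncorrected"]) < 0.1

    def test_metadata_records_scheme(self, fast_config):
        rng = np.random.default_rng(4)
        x, y = rng.standard_normal((500, 1)), rng.standard_normal((500, 1))
        rec = jackknife_correct(x, y, replace(fast_config, n_jackknife=2))
        assert "half-sample" in rec["scheme"]
        assert len(rec["half_fits"]) == 2

    def test_independence_no_spurious_information(self, fast_config):
        """Under independence the correction must not manufacture signal:
        corrected values stay near zero and near the uncorrected plateau.
        (The training-curve fit already removes the overfitting drift, so
        there is little residual 1/n bias left for the jackknife to shrink.)"""
        cfg = replace(fast_config, n_jackknife=2, n_iterations=2000)
        corr, deltas = [], []
        for s in range(4):
            rng = np.random.default_rng(100 + s)
            x, y = rng.standard_normal((600, 1)), rng.standard_normal((600, 1))
            rec = jackknife_correct(x, y, replace(cfg, seed=s))
            if rec["corrected"] is not None:
                corr.append(abs(rec["corrected"]))
                deltas.append(abs(rec["corrected"] - rec["uncorrected"]))
        assert len(corr) >= 2  # screening may drop some replicates
        assert np.mean(corr) < 0.1
        assert np.mean(deltas) < 0.1

    def test_gaussian_correction_is_modest_and_bounded(self, fast_config):
        """The 1/n extrapolation must neither blow up the estimate nor move
        it outside estimator tolerance of the closed-form value; at this
        budget the correction itself is small compared to the signal."""
        true_mi = -0.5 * np.log2(1 - 0.81)  # rho = 0.9
        cfg = replace(fast_config, n_jackknife=2, n_iterations=4000, n_replicates=1)
        resid_c, shifts = [], []
        for s in range(3):
            rng = np.random.default_rng(300 + s)
            z = rng.multivariate_normal([0, 0], [[1, 0.9], [0.9, 1]], size=4000)
            rec = jackknife_correct(z[:, :1], z[:, 1:], replace(cfg, seed=s))
            if rec["corrected"] is None:
                continue
            resid_c.append(abs(rec["corrected"] - true_mi))
            shifts.append(abs(rec["corrected"] - rec["uncorrected"]))
        assert len(resid_c) >= 2  # screening may drop a replicate
        assert np.mean(shifts) < 0.25
        assert np.mean(resid_c) <= 0.3


class TestEstimateMI:
    def test_independence_near_zero(self, fast_config):
        rng = np.random.default_rng(5)
        x, y = rng.standard_normal((2000, 1)), rng.standard_normal((2000, 1))
        est = estimate_mi(x, y, replace(fast_config, n_replicates=3))
        assert est.ok
        assert abs(est.value) < 0.1

    def test_determinism(self, fast_config):
        rng = np.random.default_rng(6)
        x, y = rng.standard_normal((1000, 1)), rng.standard_normal((1000, 1))
        a = estimate_mi(x, y, fast_config)
        b = estimate_mi(x, y, fast_config)
        assert a.value == b.value
        assert a.replicate_values == b.replicate_values

    def test_symmetry_within_spread(self, fast_config):
        rng = np.random.default_rng(7)
        z = rng.multivariate_normal([0, 0], [[1, 0.8], [0.8, 1]], size=3000)
        cfg = replace(fast_config, n_replicates=3)
        xy = estimate_mi(z[:, :1], z[:, 1:], cfg)
        yx = estimate_mi(z[:, 1:], z[:, :1], cfg)
        tol = 3 * max(xy.spread, yx.spread, 0.05)
        assert abs(xy.value - yx.value) < tol

    def test_noise_column_does_not_add_information(self, fast_config):
        rng = np.random.default_rng(8)
        z = rng.multivariate_normal([0, 0], [[1, 0.7], [0.7, 1]], size=3000)
        x, y = z[:, :1], z[:, 1:]
        base = estimate_mi(x, y, fast_config)
        padded = estimate_mi(np.hstack([x, rng.standard_normal((3000, 1))]), y, fast_config)
        tol = 3 * max(base.spread, padded.spread, 0.05)
        assert padded.value <= base.value + tol

    def test_monotone_on_gaussian_ladder(self, deep_config):
        rng = np.random.default_rng(9)
        ests = []
        for rho in (0.0, 0.45, 0.8, 0.95):
            z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=3000)
            ests.append(estimate_mi(z[:, :1], z[:, 1:], deep_config).value)
        # allow at most one inversion at the noise floor
        inversions = int(np.sum(np.diff(ests) < -0.05))
        assert inversions <= 1
        assert ests[-1] > ests[0]

    def test_all_replicates_failed_is_explicit(self):
        cfg = MineConfig(
            hidden_units=8, n_iterations=60, batch_size=32,
            n_replicates=2, n_jackknife=0, seed=0,
        )  # too few iterations for the fit to even run (<50 usable points ok, but force fail below)
        rng = np.random.default_rng(10)
        x, y = rng.standard_normal((100, 1)), rng.standard_normal((100, 1))
        cfg = replace(cfg, n_iterations=40)  # below the 50-point floor of the fit
        est = estimate_mi(x, y, cfg)
        assert not est.ok
        assert est.value is None
        assert est.n_converged == 0
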