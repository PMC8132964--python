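import numpy as np
import pytest
from scipy.stats import binom, norm

import fetaldelta as fd
from fetaldelta.detector import _se_kernel, min_qualifying_count

from conftest import stationary_gp_series


class TestConfig:
    @pytest.mark.parametrize("kwargs", [
        dict(alpha=0.0), dict(alpha=1.5), dict(interval_size=1),
        dict(training_size=15, interval_size=10),
    ])
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            fd.DeltaPointConfig(**kwargs)

    def test_qualifying_count_from_exact_binomial(self):
        # P(K>=2 | B(10, .05)) = 0.0861 >= 0.05; P(K>=3) = 0.0115 < 0.05
        assert binom.sf(1, 10, 0.05) == pytest.approx(0.0861, abs=1e-4)
        assert binom.sf(2, 10, 0.05) == pytest.approx(0.0115, abs=1e-4)
        assert min_qualifying_count(10, 0.05, 0.05) == 3


class TestFit:
    def test_constant_training_series_uses_variance_floor(self):
        centers = 150.0 + 150.0 * np.arange(80)
        s = fd.RMSSDSeries(centers, np.full(80, 3.0), "beat_exact",
                           np.ones(80, bool))
        model = fd.fit_gp_baseline(s)
        assert model.noise_variance >= 1e-6
        assert model.training_mean == pytest.approx(3.0)

    def test_insufficient_windows_rejected(self):
        centers = 150.0 + 150.0 * np.arange(30)
        s = fd.RMSSDSeries(centers, np.full(30, 3.0), "beat_exact",
                           np.ones(30, bool))
        with pytest.raises(ValueError, match="retained windows"):
            fd.fit_gp_baseline(s)

    def test_white_noise_training_attributed_to_noise(self):
        """On uncorrelated training data the fitted noise variance captures
        most of the total variance (median over 20 seeds)."""
        fracs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            y = 3.0 + 0.3 * rng.normal(size=80)
            centers = 150.0 + 150.0 * np.arange(80)
            s = fd.RMSSDSeries(centers, y, "beat_exact", np.ones(80, bool))
            m = fd.fit_gp_baseline(s)
            fracs.append(m.noise_variance
                         / (m.noise_variance + m.kernel_variance))
        assert np.median(fracs) >= 0.8

    def test_lengthscale_recovery_within_factor_two(self):
        """Training data drawn from a known SE GP (l = 5): the fitted
        lengthscale recovers the truth within a factor of 2 (median)."""
        recovered = []
        for seed in range(20):
            s = stationary_gp_series(seed, n_windows=80, sf2=0.25, ell=5.0,
                                     sn2=0.01)
            m = fd.fit_gp_baseline(s)
            recovered.append(m.length_scale)
        med = np.median(recovered)
        assert 2.5 <= med <= 10.0

    def test_matches_sklearn_gp_posterior(self):
        """Posterior mean/SD with fixed hyperparameters agree with
        scikit-learn's GP regression (independent implementation)."""
        from sklearn.gaussian_process import GaussianProcessRegressor
        from sklearn.gaussian_process.kernels import RBF, ConstantKernel

        rng = np.random.default_rng(5)
        x = np.arange(40.0)
        y = 3.0 + 0.4 * np.sin(x / 4.0) + 0.05 * rng.normal(size=40)
        sf2, ell, sn2 = 0.2, 4.0, 0.01
        K = _se_kernel(x, x, sf2, ell) + sn2 * np.eye(40)
        from scipy.linalg import cho_factor, cho_solve
        cf = cho_factor(K, lower=True)
        xq = np.array([41.0, 45.0])
        ks = _se_kernel(x, xq, sf2, ell)
        mean_mine = ks.T @ cho_solve(cf, y - y.mean()) + y.mean()
        var_mine = sf2 - np.einsum("ij,ij->j", ks, cho_solve(cf, ks)) + sn2

        # sklearn: noise passed via alpha (jitter on the training diagonal),
        # so its predictive std excludes observation noise
        gpr = GaussianProcessRegressor(
            kernel=ConstantKernel(sf2, "fixed") * RBF(ell, "fixed"),
            optimizer=None, normalize_y=False, alpha=sn2)
        gpr.fit(x[:, None], y - y.mean())
        mu, sd = gpr.predict(xq[:, None], return_std=True)
        assert np.allclose(mean_mine, mu + y.mean(), atol=1e-8)
        assert np.allclose(var_mine, sd ** 2 + sn2, atol=1e-8)


class TestOnlinePredict:
    def test_tail_probability_identity(self):
        """p equals 2(1 - Phi(|obs - mean| / SD)) for every reported window,
        so an observation at mean + 1.959964 SD has p = 0.05 and an
        observation at the mean has p = 1."""
        s = stationary_gp_series(0)
        model = fd.fit_gp_baseline(s)
        preds = fd.online_predict(model, s)
        z = (preds.observed - preds.mean) / preds.sd
        assert np.allclose(preds.p, 2 * norm.sf(np.abs(z)), atol=1e-12)
        assert 2 * norm.sf(1.959964) == pytest.approx(0.05, abs=1e-6)

    def test_requires_windows_beyond_training(self):
        s = stationary_gp_series(1, n_windows=60)
        model = fd.fit_gp_baseline(s)
        with pytest.raises(ValueError, match="beyond the training span"):
            fd.online_predict(model, s)

    def test_flag_rate_calibrated_on_in_model_series(self):
        """Stationary series drawn from a GP, model fit on the training span:
        the per-window flag rate is close to alpha (50 seeds)."""
        rates = []
        for seed in range(50):
            s = stationary_gp_series(seed + 200)
            model = fd.fit_gp_baseline(s)
            preds = fd.online_predict(model, s)
            rates.append(np.mean(preds.p < 0.05))
        assert 0.03 <= np.mean(rates) <= 0.07

    def test_outlier_window_is_most_significant(self):
        """A +5 SD outlier is flagged and carries the smallest p within its
        +/-2-window neighborhood in at least 95% of seeds."""
        hits = 0
        n_seeds = 50
        for seed in range(n_seeds):
            s = stationary_gp_series(seed + 400)
            y = s.rmssd_ms.copy()
            y[90] += 5 * np.sqrt(0.09 + 0.02)
            s2 = fd.RMSSDSeries(s.window_centers, y, "beat_exact",
                                s.retained_mask)
            model = fd.fit_gp_baseline(s2)
            preds = fd.online_predict(model, s2)
            d = dict(zip(preds.window_index, preds.p))
            neighborhood = [d[k] for k in range(88, 93) if k in d and k != 90]
            if d[90] < 0.05 and d[90] < min(neighborhood):
                hits += 1
        assert hits / n_seeds >= 0.95


class TestFlagAndDeclare:
    def test_no_suspects_when_all_p_large(self):
        preds = fd.OnlinePredictions(
            np.arange(60, 80), 150.0 * np.arange(60, 80), np.ones(20),
            np.ones(20), np.ones(20), np.full(20, 0.5), np.zeros(20))
        assert fd.flag_suspects(preds) == []
        res = fd.declare_delta_point([], preds)
        assert not res.declared

    def test_alpha_one_flags_everything(self):
        preds = fd.OnlinePredictions(
            np.arange(60, 80), 150.0 * np.arange(60, 80), np.ones(20),
            np.ones(20), np.ones(20), np.full(20, 0.5), np.zeros(20))
        cfg = fd.DeltaPointConfig(alpha=0.999999, interval_alpha=0.05)
        assert len(fd.flag_suspects(preds, cfg)) == 20

    def test_declaration_picks_min_p_in_first_qualifying_interval(self):
        wi = np.arange(60, 90)
        p = np.full(30, 0.5)
        # 3 suspects in the second block of 10; the middle one most significant
        p[12], p[14], p[17] = 0.02, 0.001, 0.03
        preds = fd.OnlinePredictions(wi, 150.0 * wi, np.ones(30), np.ones(30),
                                     np.ones(30), p, np.ones(30))
        res = fd.declare_delta_point(fd.flag_suspects(preds), preds)
        assert res.declared
        assert res.interval_index == 1
        assert res.window_index == 74
        assert res.suspects_in_interval == 3

    def test_two_suspects_not_enough(self):
        wi = np.arange(60, 90)
        p = np.full(30, 0.5)
        p[3], p[5] = 0.001, 0.001
        preds = fd.OnlinePredictions(wi, 150.0 * wi, np.ones(30), np.ones(30),
                                     np.ones(30), p, np.ones(30))
        assert not fd.declare_delta_point(fd.flag_suspects(preds), preds).declared


class TestRunDetector:
    def test_deterministic(self, default_series):
        r1 = fd.run_detector(default_series)
        r2 = fd.run_detector(default_series)
        assert r1 == r2

    def test_sources_detected_independently(self, default_record):
        from fetaldelta.pipeline import analyze_record
        beats, _ = default_record
        analysis = analyze_record("r", beats)
        assert set(analysis.results) == {"beat_exact", "resampled_4hz"}
        # both are genuine per-source results, not shared state
        assert analysis.series["beat_exact"] is not analysis.series["resampled_4hz"]

    def test_causality_truncation_invariance(self, default_series):
        """Dropping all windows after the declared interval leaves the
        declaration unchanged."""
        res = fd.run_detector(default_series)
        assert res.declared
        cfg = fd.DeltaPointConfig()
        # keep everything up to the end of the declared interval
        idx_all = np.round((default_series.window_centers
                            - default_series.window_centers[0]) / 150.0).astype(int)
        retained_idx = idx_all[default_series.retained_mask]
        n_keep = cfg.training_size + (res.interval_index + 1) * cfg.interval_size
        cut_idx = retained_idx[n_keep - 1]
        keep = idx_all <= cut_idx
        trunc = fd.RMSSDSeries(default_series.window_centers[keep],
                               default_series.rmssd_ms[keep],
                               default_series.source,
                               default_series.retained_mask[keep])
        res2 = fd.run_detector(trunc)
        assert res2.declared
        assert res2.time == res.time
        assert res2.predictive_p == res.predictive_p

    def test_masked_window_values_never_used(self, default_record):
        beats, _ = default_record
        q = fd.assess_quality(beats)
        s = fd.rmssd_series(beats, q)
        poisoned = np.where(np.isnan(s.rmssd_ms), 1e6, s.rmssd_ms)
        s2 = fd.RMSSDSeries(s.window_centers, poisoned, s.source,
                            s.retained_mask)
        assert fd.run_detector(s2) == fd.run_detector(s)

    def test_stationary_record_rarely_declares(self):
        """False-alarm control: baseline-only records with no decompensation
        stay undeclared in at least 90% of 20 seeds."""
        declared = 0
        for seed in range(20):
            subj = fd.SubjectParams(rng_seed=seed)
            beats = fd.simulate_baseline(19800.0, subj)
            s = fd.rmssd_series(beats, fd.assess_quality(beats))
            declared += fd.run_detector(s).declared
        assert declared <= 2

    def test_detection_delay_monotone_in_growth(self):
        """Raising the post-onset RMSSD growth never increases the median
        detection delay (paired seeds, 3-point grid)."""
        medians = []
        for growth in (3.0, 6.0, 12.0):
            delays = []
            for seed in range(12):
                subj = fd.SubjectParams(decomp_time=10800.0,
                                        rmssd_growth=growth,
                                        rng_seed=700 + seed)
                beats = fd.simulate_beats(fd.make_protocol(), subj)
                s = fd.rmssd_series(beats, fd.assess_quality(beats))
                res = fd.run_detector(s)
                delays.append((res.time - 10800.0) / 60.0
                              if res.declared else 90.0)
            medians.append(np.median(delays))
        # ties allowed: sub-window differences are numerical noise
        tol = 0.05  # minutes, far below the 2.5-min window grid
        assert medians[1] <= medians[0] + tol
        assert medians[2] <= medians[1] + tol
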