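"""Trace preprocessing and the nonlinear/linear fitting chain."""

import numpy as np
import pytest

from sodmimic import (
    DecayTrace,
    DriftModel,
    FitError,
    TraceFitResult,
    TraceGeneratorConfig,
    default_window,
    fit_activity_series,
    fit_background,
    fit_degradation,
    fit_superoxide_trace,
    make_activity_dataset,
    preprocess,
    simulate_degradation_trace,
    simulate_superoxide_trace,
    summarize_half_lives,
)
from sodmimic.workflows import analyze_activity_campaign


def _noiseless_trace(b=0.0, **kw):
    cfg = TraceGeneratorConfig(b=b, noise_sigma=0.0, duration=1.0, **kw)
    return cfg, simulate_superoxide_trace(cfg)


class TestPreprocess:
    def test_single_trace_identity(self):
        _, tr = _noiseless_trace()
        out = preprocess([tr], discard_initial=0.0)
        np.testing.assert_array_equal(out.time, tr.time)
        np.testing.assert_array_equal(out.absorbance, tr.absorbance)

    def test_identical_replicates_average_to_same(self):
        _, tr = _noiseless_trace()
        out = preprocess([tr, tr, tr], discard_initial=0.0)
        np.testing.assert_allclose(out.absorbance, tr.absorbance, rtol=1e-15)

    def test_discard_and_window(self):
        _, tr = _noiseless_trace()
        out = preprocess([tr], window=(0.005, 0.5))
        assert out.time[0] >= 0.005
        assert out.time[-1] <= 0.5

    def test_blank_subtraction(self):
        _, tr = _noiseless_trace()
        blank = DecayTrace(time=tr.time, absorbance=np.full_like(tr.time, 0.01))
        out = preprocess([tr], blank=blank, discard_initial=0.0)
        np.testing.assert_allclose(out.absorbance, tr.absorbance - 0.01, rtol=1e-12)

    def test_replicate_noise_shrinks_sqrt_n(self):
        """Pointwise noise SD of a 10-replicate average shrinks ~ sqrt(10)."""
        cfg0, clean = _noiseless_trace()
        reps = [
            simulate_superoxide_trace(
                TraceGeneratorConfig(noise_sigma=0.002, duration=1.0, seed=s)
            )
            for s in range(10)
        ]
        avg = preprocess(reps, discard_initial=0.0)
        resid_sd = np.std(avg.absorbance - clean.absorbance)
        expected = 0.002 / np.sqrt(10)
        assert expected * 0.8 < resid_sd < expected * 1.2

    def test_mismatched_metadata_rejected(self):
        _, tr1 = _noiseless_trace(b=0.0)
        _, tr2 = _noiseless_trace(b=10e-6)
        with pytest.raises(ValueError, match="concentrations"):
            preprocess([tr1, tr2])

    def test_too_few_points_after_window(self):
        _, tr = _noiseless_trace()
        with pytest.raises(ValueError, match="points"):
            preprocess([tr], window=(0.005, 0.015))


class TestSuperoxideFits:
    def test_background_noiseless_recovery(self):
        cfg, tr = _noiseless_trace(k2=2e4, k1=3.0, C=0.0)
        bg = fit_background(preprocess([tr], window=(0.005, 0.5)))
        assert bg.k2 == pytest.approx(2e4, rel=1e-3)
        assert bg.k1 == pytest.approx(3.0, rel=1e-3)

    def test_background_requires_uncatalyzed(self):
        _, tr = _noiseless_trace(b=20e-6)
        with pytest.raises(ValueError, match="b = 0"):
            fit_background(tr)

    def test_background_k2_in_plausible_range(self):
        """With truth k2 inside 1e4-4e4 the estimate lands inside its CI."""
        for k2_true, seed in [(1.2e4, 0), (2.5e4, 1), (3.8e4, 2)]:
            tr = simulate_superoxide_trace(
                TraceGeneratorConfig(k2=k2_true, noise_sigma=0.002, duration=1.0, seed=seed)
            )
            bg = fit_background(preprocess([tr], window=(0.005, 0.5)), seed=seed)
            assert abs(bg.k2 - k2_true) < 3 * bg.k2_stderr

    def test_catalyzed_noiseless_recovery(self):
        cfg, tr = _noiseless_trace(b=30e-6)
        fit = fit_superoxide_trace(
            preprocess([tr], window=(0.005, 0.5)), k2=cfg.k2
        )
        assert fit.k_obs == pytest.approx(cfg.k_obs, rel=1e-3)
        assert fit.a0 == pytest.approx(cfg.a0, rel=1e-3)

    def test_catalyzed_noisy_within_two_se(self):
        cfg = TraceGeneratorConfig(b=30e-6, noise_sigma=0.002, duration=1.0, seed=9)
        tr = simulate_superoxide_trace(cfg)
        fit = fit_superoxide_trace(preprocess([tr], window=(0.005, 0.5)), k2=cfg.k2)
        assert abs(fit.k_obs - 65.0) <= 2 * fit.stderr["k_obs"]

    def test_window_robustness_without_drift(self):
        """Shrinking the window does not move k_obs beyond combined SEs."""
        cfg = TraceGeneratorConfig(b=30e-6, noise_sigma=0.002, duration=1.0, seed=4)
        tr = simulate_superoxide_trace(cfg)
        f_long = fit_superoxide_trace(tr, k2=cfg.k2, window=(0.005, 0.5))
        f_short = fit_superoxide_trace(tr, k2=cfg.k2, window=(0.005, 0.35))
        combined = np.hypot(f_long.stderr["k_obs"], f_short.stderr["k_obs"])
        assert abs(f_long.k_obs - f_short.k_obs) <= 2 * combined

    def test_drift_bias_shrinks_with_window(self):
        """With a degradation-like baseline, the short window is less biased."""
        long_b, short_b = [], []
        for s in range(10):
            cfg = TraceGeneratorConfig(
                b=30e-6, noise_sigma=0.002, duration=1.0,
                drift=DriftModel(kind="first-order", amplitude=0.05), seed=300 + s,
            )
            tr = simulate_superoxide_trace(cfg)
            long_b.append(fit_superoxide_trace(tr, k2=cfg.k2, window=(0.005, 0.5)).k_obs - cfg.k_obs)
            short_b.append(fit_superoxide_trace(tr, k2=cfg.k2, window=(0.005, 0.35)).k_obs - cfg.k_obs)
        assert abs(np.mean(short_b)) < abs(np.mean(long_b))

    def test_resampling_invariance(self):
        """A denser grid changes the point estimate by < 0.1%."""
        fits = []
        for rate in (1000.0, 4000.0):
            cfg, tr = _noiseless_trace(b=20e-6, sampling_rate=rate)
            fits.append(fit_superoxide_trace(tr, k2=cfg.k2, window=(0.005, 0.5)).k_obs)
        assert fits[0] == pytest.approx(fits[1], rel=1e-3)

    def test_flat_trace_raises(self):
        t = np.linspace(0, 1, 200)
        tr = DecayTrace(time=t, absorbance=np.full_like(t, 0.2))
        with pytest.raises(FitError, match="flat|decay"):
            fit_superoxide_trace(tr, k2=2e4)

    def test_k2_required_when_fixed(self):
        _, tr = _noiseless_trace(b=20e-6)
        with pytest.raises(FitError, match="k2"):
            fit_superoxide_trace(tr)

    def test_default_window_rule(self):
        assert default_window(20e-6) == (0.005, 0.5)
        assert default_window(40e-6) == (0.005, 0.35)


class TestActivitySeries:
    def test_exact_line(self):
        b = np.array([10, 20, 30, 40, 50]) * 1e-6
        res = fit_activity_series([(bi, 5.0 + 2e6 * bi) for bi in b])
        assert res.k_cat == pytest.approx(2e6, rel=1e-9)
        assert res.k1 == pytest.approx(5.0, rel=1e-9)
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            fit_activity_series([(10e-6, 25.0)])
        with pytest.raises(ValueError, match="identical"):
            fit_activity_series([(10e-6, 25.0), (10e-6, 26.0)])

    def test_weighted_equals_unweighted_for_equal_ses(self):
        b = np.array([10, 20, 30, 40, 50]) * 1e-6
        k_obs = 5.0 + 2e6 * b + np.array([0.3, -0.2, 0.1, -0.4, 0.2])
        plain = fit_activity_series(list(zip(b, k_obs)))
        def _res(ko):
            return TraceFitResult(
                a0=1e-4, k2=2e4, k_obs=ko, C=0.0,
                stderr={"k_obs": 0.5}, rss=0.0, window=(0.005, 0.5),
                n_points=100, converged=True,
            )
        weighted = fit_activity_series([(bi, _res(ko)) for bi, ko in zip(b, k_obs)])
        assert weighted.k_cat == pytest.approx(plain.k_cat, rel=1e-10)
        assert weighted.k1 == pytest.approx(plain.k1, rel=1e-10)

    def test_full_campaign_recovery(self):
        """Five concentrations x five replicates recover k_cat within 10%."""
        camp = make_activity_dataset(seed=11)
        act, _ = analyze_activity_campaign(camp, seed=1)
        assert act.k_cat == pytest.approx(2e6, rel=0.10)
        assert act.r_squared > 0.99


class TestDegradation:
    def test_noiseless_half_life(self):
        tr = simulate_degradation_trace(
            A0=0.8, A_inf=0.05, k=np.log(2) / 16, sigma=0.0, duration=120, sampling_rate=2.0
        )
        res = fit_degradation(tr)
        assert res.t_half == pytest.approx(16.0, rel=1e-3)

    def test_concentration_independence(self):
        """Same rate at three nominal concentrations gives the same half-life."""
        t_halves = []
        for b in (0.316e-3, 0.158e-3, 0.04e-3):
            tr = simulate_degradation_trace(
                A0=0.8 * b / 0.316e-3 + 0.1, A_inf=0.02, k=np.log(2) / 16,
                sigma=0.0, duration=120, sampling_rate=2.0, b=b,
            )
            t_halves.append(fit_degradation(tr).t_half)
        assert max(t_halves) - min(t_halves) < 1e-3

    def test_noisy_coverage(self):
        """Truth within 2 SE in >= 90% of seeded noisy repeats."""
        k_true = np.log(2) / 16
        hits = 0
        for s in range(40):
            tr = simulate_degradation_trace(
                A0=0.8, A_inf=0.05, k=k_true, sigma=0.005,
                duration=120, sampling_rate=2.0, seed=s,
            )
            r = fit_degradation(tr)
            hits += abs(r.k - k_true) <= 2 * r.k_stderr
        assert hits / 40 >= 0.9

    def test_increasing_signal_flagged(self):
        t = np.linspace(0, 100, 300)
        tr = DecayTrace(time=t, absorbance=0.1 + 0.5 * (1 - np.exp(-t / 20)), wavelength=460)
        with pytest.warns(UserWarning, match="increases"):
            res = fit_degradation(tr)
        assert "increasing-signal" in res.flags

    def test_short_trace_warns(self):
        tr = simulate_degradation_trace(
            A0=0.8, A_inf=0.05, k=np.log(2) / 160, sigma=0.0, duration=60, sampling_rate=2.0
        )
        with pytest.warns(UserWarning, match="half-lives"):
            fit_degradation(tr)

    def test_flat_trace_rejected(self):
        t = np.linspace(0, 100, 200)
        with pytest.raises(FitError):
            fit_degradation(DecayTrace(time=t, absorbance=np.full_like(t, 0.3)))


class TestSummary:
    def test_table_of_five_half_lives(self):
        """The five per-condition half-lives summarize to 16 +/- 3 s."""
        mean, sd = summarize_half_lives([14, 13, 17, 15, 21])
        assert mean == pytest.approx(16.0, abs=1e-12)
        assert sd == pytest.approx(3.1623, abs=1e-3)
        assert round(mean) == 16 and round(sd) == 3

    def test_repeated_value(self):
        mean, sd = summarize_half_lives([12.5] * 4)
        assert (mean, sd) == (12.5, 0.0)

    def test_mean_within_bounds(self):
        vals = [3.0, 9.0, 4.5, 7.25]
        mean, _ = summarize_half_lives(vals)
        assert min(vals) <= mean <= max(vals)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_half_lives([])


class TestIdentifiability:
    def test_round_trip_bias_and_coverage(self):
        """Repeated seeded campaigns: small k_cat bias, 2-SE coverage >= 90%."""
        est, hit = [], 0
        n_rep = 200
        for s in range(n_rep):
            camp = make_activity_dataset(seed=5000 + s)
            act, _ = analyze_activity_campaign(camp, seed=s)
            est.append(act.k_cat)
            hit += abs(act.k_cat - 2e6) <= 2 * act.k_cat_stderr
        bias = abs(np.mean(est) - 2e6) / 2e6
        assert bias < 0.02
        assert hit / n_rep >= 0.9
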