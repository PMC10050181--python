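"""Periodogram, slope fitting, classification, bands, linearity, ACF."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flownoise import (
    ColorConfig,
    ColoredNoiseSpec,
    FitBand,
    QCError,
    StreamflowSimSpec,
    autocorrelation,
    classify_color,
    compare_detrending_methods,
    estimate_gage_colors,
    fit_noise_color,
    gen_ar1,
    gen_colored_noise,
    gen_streamflow_like,
    linearity_check,
    local_slopes,
    periodogram,
)
from flownoise.spectral import GLOBAL_BAND, Periodogram


def make_pgram(T, power_fn):
    """Build a Periodogram with a prescribed deterministic spectrum."""
    k = np.arange(1, T // 2 + 1)
    f = k / T
    P = power_fn(f)
    return Periodogram(T, k, f, P, float(2 * P.sum()))


class TestPeriodogram:
    def test_constant_series_has_zero_power(self):
        pg = periodogram(np.zeros(64))
        assert np.allclose(pg.power, 0.0)

    def test_cosine_concentrates_at_its_frequency(self):
        T, k0 = 256, 17
        t = np.arange(T)
        x = np.cos(2 * np.pi * k0 * t / T)
        pg = periodogram(x - x.mean())
        peak = pg.power[pg.freq_index == k0][0]
        others = pg.power[pg.freq_index != k0]
        assert peak > 0
        assert np.max(others) < 1e-10 * peak

    def test_parseval(self):
        rng = np.random.default_rng(21)
        for _ in range(10):
            x = rng.normal(size=rng.integers(16, 500))
            x -= x.mean()
            pg = periodogram(x)
            ss = np.sum(x**2)
            assert abs(pg.total_power_two_sided - ss) < 1e-8 * ss

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            periodogram(np.ones(8))

    def test_nonfinite_rejected(self):
        x = np.zeros(64)
        x[5] = np.nan
        with pytest.raises(ValueError):
            periodogram(x)


class TestFitNoiseColor:
    @pytest.mark.parametrize("a", [0.5, 1.0, 2.0])
    def test_exact_power_law(self, a):
        pg = make_pgram(4096, lambda f: f ** (-a))
        est = fit_noise_color(pg)
        assert abs(est.a - a) < 1e-10
        assert abs(est.r_squared - 1.0) < 1e-12

    def test_white_noise_ensemble(self):
        colors = []
        for seed in range(100):
            x = np.random.default_rng(seed).normal(size=4096)
            colors.append(fit_noise_color(periodogram(x - x.mean())))
        mean_a = np.mean([c.a for c in colors])
        white = sum(c.category == "white" for c in colors)
        assert abs(mean_a) < 0.05
        assert white >= 95

    def test_colored_noise_recovery(self):
        est = [
            fit_noise_color(periodogram(gen_colored_noise(ColoredNoiseSpec(2.0, 16384, seed=s)))).a
            for s in range(20)
        ]
        assert 1.9 <= np.mean(est) <= 2.1

    def test_degenerate_when_too_few_bins(self):
        pg = make_pgram(64, lambda f: np.where(f < 0.1, 1.0, 0.0))
        est = fit_noise_color(pg, FitBand(2.0, 5.0, "hf"))
        assert est.degenerate
        assert math.isnan(est.a)
        assert "zero_power_bins_dropped" in est.flags

    @given(st.floats(min_value=-3, max_value=3), st.sampled_from([1e-3, 1.0, 1e3]))
    @settings(max_examples=40, deadline=None)
    def test_scale_invariance(self, log_c_extra, c):
        # multiplying the series by c > 0 shifts only the intercept
        x = gen_colored_noise(ColoredNoiseSpec(1.2, 1024, seed=5))
        scale = c * 10.0**log_c_extra
        base = fit_noise_color(periodogram(x))
        scaled = fit_noise_color(periodogram(scale * x))
        assert abs(scaled.a - base.a) < 1e-10
        assert abs(scaled.b - base.b - 2 * math.log10(scale)) < 1e-8

    def test_time_reversal_invariance(self):
        x = gen_colored_noise(ColoredNoiseSpec(1.7, 2048, seed=8))
        fwd = periodogram(x)
        rev = periodogram(x[::-1])
        assert np.allclose(fwd.power, rev.power)
        assert fit_noise_color(fwd).a == pytest.approx(fit_noise_color(rev).a, abs=1e-12)


class TestClassification:
    @pytest.mark.parametrize("a,expected", [
        (1.0, "pink"),
        (2.6, "black"),
        (-0.5, "white"),
        (0.5, "white"),
        (0.51, "pink"),
        (-0.51, "blue"),
        (1.5, "pink"),
        (1.51, "red"),
        (2.5, "red"),
        (-1.5, "blue"),
        (-2.2, "blue"),
        (0.0, "white"),
    ])
    def test_category_map(self, a, expected):
        assert classify_color(a) == expected

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            classify_color(math.nan)

    def test_below_blue_range_flagged(self):
        # a spectrum rising steeply with frequency: slope beyond the blue range
        pg = make_pgram(1024, lambda f: f**2.0)
        est = fit_noise_color(pg)
        assert est.category == "blue"
        assert "below_blue_range" in est.flags


class TestLocalSlopes:
    def test_submonthly_bin_count_arithmetic(self):
        T = 18250
        pg = make_pgram(T, lambda f: f**-1.0)
        est = local_slopes(pg)["submonthly"]
        expected = math.floor(T / 7) - math.ceil(T / 30) + 1
        assert est.n_freqs == expected

    def test_broken_power_law_separation(self):
        # slope 2 for periods < 30 d, slope 0.5 for >= 30 d
        T = 8192
        knee = 1 / 30

        def spectrum(f):
            hi = f >= knee
            P = np.empty_like(f)
            P[hi] = f[hi] ** -2.0
            P[~hi] = knee**-2.0 * (f[~hi] / knee) ** -0.5
            return P

        pg = make_pgram(T, spectrum)
        fits = local_slopes(pg, [FitBand(2, 30, "short"), FitBand(30, math.inf, "long")])
        assert fits["short"].a == pytest.approx(2.0, abs=1e-10)
        assert fits["long"].a == pytest.approx(0.5, abs=1e-10)

    def test_degenerate_band_does_not_disturb_others(self):
        pg = make_pgram(64, lambda f: f**-1.0)
        fits = local_slopes(pg, [FitBand(2, 4, "ok"), FitBand(40, 60, "empty")])
        assert fits["empty"].degenerate
        assert not fits["ok"].degenerate

    def test_global_and_submonthly_correlated(self):
        # on single-regime synthetic noise the global and sub-monthly colors
        # track each other across gages
        from scipy.stats import pearsonr

        rng = np.random.default_rng(0)
        g, sub = [], []
        for seed in range(60):
            a = rng.uniform(0.5, 2.0)
            x = gen_colored_noise(ColoredNoiseSpec(a, 7300, seed=seed))
            pg = periodogram(x)
            fits = local_slopes(pg)
            g.append(fits["global"].a)
            sub.append(fits["submonthly"].a)
        assert pearsonr(g, sub).statistic >= 0.8


class TestLinearityCheck:
    def test_exact_power_law_is_linear(self):
        pg = make_pgram(2048, lambda f: f**-1.5)
        diag = linearity_check(pg)
        assert diag.verdict == "linear"
        assert abs(diag.quadratic_coef) < 1e-10

    def test_curved_spectrum_is_nonlinear(self):
        # log10 P = -2 (log10 f)^2: curvature 2 across any band
        pg = make_pgram(2048, lambda f: 10 ** (-(np.log10(f) ** 2)))
        rng = np.random.default_rng(1)
        pg.power *= np.exp(rng.normal(0, 0.01, pg.power.size))  # break exact fit
        diag = linearity_check(pg)
        assert diag.verdict == "nonlinear"
        assert abs(diag.slope_change) > 0.5

    def test_white_noise_type_one_error(self):
        linear = 0
        for seed in range(50):
            x = np.random.default_rng(seed).normal(size=4096)
            if linearity_check(periodogram(x - x.mean())).verdict == "linear":
                linear += 1
        assert linear >= 47

    def test_too_few_bins_rejected(self):
        pg = make_pgram(64, lambda f: f**-1.0)
        with pytest.raises(ValueError):
            linearity_check(pg, FitBand(2.0, 2.5, "tiny"))


class TestAutocorrelation:
    def test_lag_zero_is_one(self):
        x = np.random.default_rng(2).normal(size=100)
        acf = autocorrelation(x, 10)
        assert acf[0] == 1.0
        assert len(acf) == 11

    def test_white_noise_lag1(self):
        x = np.random.default_rng(3).normal(size=4096)
        assert abs(autocorrelation(x, 1)[1]) < 3 / math.sqrt(4096)

    def test_ar1_matches_closed_form(self):
        x = gen_ar1(0.8, 32768, seed=6)
        assert abs(autocorrelation(x, 1)[1] - 0.8) < 0.02

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            autocorrelation(np.ones(50), 5)


class TestEstimateGageColors:
    CFG = ColorConfig(min_annual_years=30)

    def test_qc_failure_raises(self, make_series):
        short = gen_streamflow_like(StreamflowSimSpec(n_years=5, seed=0))
        with pytest.raises(QCError):
            estimate_gage_colors(short, self.CFG)

    def test_full_record_produces_all_estimates(self):
        series = gen_streamflow_like(
            StreamflowSimSpec(start_date="1970-01-01", n_years=40, noise_exponent=1.0, seed=3)
        )
        rec = estimate_gage_colors(series, self.CFG)
        assert rec.daily_global.category is not None
        assert set(rec.daily_bands) == {"global", "submonthly", "seasonal",
                                        "intra_annual", "supra_annual"}
        for metric in ("mean", "min", "max"):
            assert getattr(rec, f"annual_{metric}") is not None

    def test_short_record_has_no_annual_estimates(self):
        series = gen_streamflow_like(StreamflowSimSpec(n_years=20, seed=4))
        rec = estimate_gage_colors(series, self.CFG)
        assert rec.annual_mean is None

    def test_color_recovery_through_pipeline(self):
        recovered = []
        for seed in range(20):
            series = gen_streamflow_like(
                StreamflowSimSpec(n_years=20, noise_exponent=1.5, seed=seed)
            )
            recovered.append(estimate_gage_colors(series, self.CFG).daily_global.a)
        assert 1.35 <= np.mean(recovered) <= 1.65


class TestCompareDetrending:
    @staticmethod
    def _noise_gages(n, trend=0.0, seed0=0):
        import pandas as pd

        from flownoise import FlowSeries

        # whole calendar years so the leap-day drop leaves exactly 365
        # samples per year (the regime the pipeline operates in)
        dates = pd.date_range("1981-01-01", "1995-12-31", freq="D")
        T = len(dates)
        rng = np.random.default_rng(seed0)
        out = []
        for i in range(n):
            a = rng.uniform(0.5, 2.0)
            x = gen_colored_noise(ColoredNoiseSpec(a, T, seed=seed0 + 1000 + i))
            out.append(FlowSeries(f"g{i}", dates, x + trend * np.arange(T) + 100.0))
        return out

    def test_trend_free_gages_agree_across_methods(self):
        # linear detrending of trend-free noise is near-neutral; STL
        # additionally flattens reddened spectra slightly (its trend
        # component absorbs supra-annual stochastic power), so its offset
        # is larger but bounded. Colors track tightly across methods.
        sens = compare_detrending_methods(self._noise_gages(30))
        off_diag = sens.pairwise_r.values[~np.eye(3, dtype=bool)]
        assert np.all(off_diag >= 0.99)
        assert abs(sens.mean_diff_vs_raw["linear"]) <= 0.05
        assert -0.15 < sens.mean_diff_vs_raw["stl"] < 0.0

    def test_constant_color_vector_reported_degenerate(self):
        import pandas as pd

        from flownoise import FlowSeries

        T = 2 * 365
        dates = pd.date_range("2001-01-01", periods=T, freq="D")
        x = gen_colored_noise(ColoredNoiseSpec(1.0, T, seed=1))
        same = [FlowSeries(f"g{i}", dates, x + 10.0) for i in range(3)]
        sens = compare_detrending_methods(same)
        assert sens.degenerate_pairs  # identical gages: zero-variance columns
        assert np.isnan(sens.pairwise_r.loc["raw", "linear"])

    def test_strong_trend_reddens_raw_fit(self):
        trended = self._noise_gages(30, trend=0.05, seed0=50)
        sens = compare_detrending_methods(trended)
        assert (sens.colors["raw"] - sens.colors["linear"]).mean() > 0

    def test_too_few_series_rejected(self):
        with pytest.raises(ValueError):
            compare_detrending_methods(self._noise_gages(2))
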