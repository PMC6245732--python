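"""Delay estimation, chi-squared fitting, and model comparison."""

import numpy as np
import pytest
from scipy import stats

from alleledyn.mixture_quantify import FractionSeries
from alleledyn.model_fit import (
    DelayVector,
    compare_models,
    delayed_model_series,
    estimate_delays,
    fit_model,
    read_fraction_table_ci,
)
from alleledyn.state_models import (
    RateParams,
    closed_form_cis_only,
    naive_init,
    population_fractions,
)


def make_series(f, df, times=None, n=200):
    f = np.asarray(f, dtype=float)
    times = np.arange(2.5, 2.5 + 5.0 * len(f), 5.0) if times is None else times
    return FractionSeries(times, f, np.broadcast_to(df, f.shape).copy(),
                         np.full(len(f), n))


class TestEstimateDelays:
    def test_step_series_delay(self):
        f = np.zeros((10, 4))
        f[:, 0] = 1.0
        f[4:, 1] = 0.2  # monoY significant from the bin centered at 22.5 h
        f[4:, 0] = 0.8
        series = make_series(f, 0.01)
        tau = estimate_delays(series)
        assert tau.tau[1] == pytest.approx(22.5)

    def test_single_bin_blip_is_ignored(self):
        f = np.zeros((10, 4))
        f[:, 0] = 1.0
        f[2, 1] = 0.2  # isolated blip fails the persistence requirement
        f[6:, 1] = 0.2
        series = make_series(f, 0.01)
        tau = estimate_delays(series)
        assert tau.tau[1] == pytest.approx(32.5)

    def test_never_detected_is_flagged_at_last_bin(self):
        f = np.zeros((6, 4))
        f[:, 0] = 1.0
        series = make_series(f, 0.05)
        tau = estimate_delays(series)
        assert tau.tau[1] == series.bin_centers[-1]
        assert set(tau.flagged) == {"monoY", "monoR", "bi"}

    def test_movie_delay_reflects_maturation_lag(self, movie_delays):
        # mono-class delays should land near the generator's ~16 h effective
        # detection lag (within one 5 h bin-width band on each side)
        for i in (1, 2):
            assert 10.0 <= movie_delays.tau[i] <= 35.0

    def test_delay_vector_validation(self):
        with pytest.raises(ValueError):
            DelayVector(np.array([1.0, 0, 0, 0]))


class TestDelayedSeries:
    def test_zero_delay_is_identity(self):
        t = np.linspace(0, 100, 21)
        rates = RateParams(kC=0.005)
        pred = delayed_model_series(
            "cis_only", rates, naive_init("cis_only"), DelayVector.zero(), t
        )
        assert np.allclose(pred, closed_form_cis_only(0.005, t), atol=1e-10)

    def test_shifts_each_class_by_its_delay(self):
        tau = DelayVector(np.array([0.0, 0.0, 0.0, 20.0]))
        rates = RateParams(kC=0.005)
        pred = delayed_model_series(
            "cis_only", rates, naive_init("cis_only"), tau, np.array([60.0])
        )
        assert pred[0, 3] == pytest.approx(closed_form_cis_only(0.005, 40.0)[3], abs=1e-10)

    def test_rows_sum_to_one(self):
        tau = DelayVector(np.array([0.0, 10.0, 15.0, 30.0]))
        pred = delayed_model_series(
            "parallel", RateParams(kC=0.004, kT=0.02), naive_init("parallel"),
            tau, np.linspace(0, 100, 11),
        )
        assert np.allclose(pred.sum(axis=1), 1.0, atol=1e-12)


class TestFitModel:
    def test_noiseless_cis_only_recovery(self):
        t = np.arange(2.5, 105, 5.0)
        f = closed_form_cis_only(0.005, t)
        series = make_series(f, 0.01, times=t)
        fit = fit_model("cis_only", series, DelayVector.zero(), seed=0)
        assert fit.rates.kC == pytest.approx(0.005, abs=1e-4)
        assert fit.chi2_red < 1e-6

    def test_parallel_fits_cis_only_data_by_nesting(self):
        t = np.arange(2.5, 105, 5.0)
        f = closed_form_cis_only(0.005, t)
        series = make_series(f, 0.01, times=t)
        fit = fit_model("parallel", series, DelayVector.zero(), seed=0)
        assert fit.chi2_red < 1e-3

    def test_parallel_sse_never_above_cis_only(self, quantified_movie):
        _, _, _, _, series = quantified_movie
        tau = DelayVector.zero()
        f_cis = fit_model("cis_only", series, tau, seed=3)
        f_par = fit_model("parallel", series, tau, seed=3)
        assert f_par.sse <= f_cis.sse * (1 + 1e-6)

    def test_binomial_noise_recovery(self, rng):
        """kC and kT recovered within 25% (median) from counting noise."""
        t = np.arange(2.5, 105, 5.0)
        truth = RateParams(kC=0.004, kT=0.012)
        f_true = population_fractions("parallel", truth, naive_init("parallel"), t).fractions
        n = 200
        rel_kc = []
        for rep in range(9):
            rep_rng = np.random.default_rng(100 + rep)
            counts = np.vstack([rep_rng.multinomial(n, p) for p in f_true])
            f_obs = counts / n
            df = np.sqrt(np.clip(f_obs * (1 - f_obs), 1e-4, None) / n)
            series = make_series(f_obs, 0.0, times=t)
            series.df_obs = df
            fit = fit_model("parallel", series, DelayVector.zero(), seed=rep,
                            n_restarts=8)
            rel_kc.append(abs(fit.rates.kC - truth.kC) / truth.kC)
        assert np.median(rel_kc) < 0.25

    def test_chi2_decomposition(self, quantified_movie, movie_delays):
        """chi2_red * dof equals the recomputed sum of squared residuals."""
        _, _, _, _, series = quantified_movie
        fit = fit_model("parallel", series, movie_delays, seed=1, n_restarts=6)
        pred = delayed_model_series(
            fit.model_kind, fit.rates, fit.init, fit.delays, series.bin_centers
        )
        sse = 0.0
        n_pts = 0
        for i in (1, 2, 3):
            for j, t in enumerate(series.bin_centers):
                if series.df_obs[j, i] > 0 and t >= fit.delays.tau[i]:
                    sse += ((pred[j, i] - series.f_obs[j, i]) / series.df_obs[j, i]) ** 2
                    n_pts += 1
        assert n_pts == fit.n_points
        assert fit.chi2_red * fit.dof == pytest.approx(sse, rel=1e-9)

    def test_dof_guard(self):
        f = np.tile([0.7, 0.1, 0.1, 0.1], (2, 1))
        series = make_series(f, 0.01)
        with pytest.raises(ValueError):
            fit_model("parallel", series, DelayVector.zero())


class TestCompareModels:
    def test_identical_fits_give_unit_f(self, quantified_movie, movie_delays):
        _, _, _, _, series = quantified_movie
        fit = fit_model("cis_only", series, movie_delays, seed=0, n_restarts=4)
        cmp_ = compare_models(fit, fit)
        assert cmp_.F_value == pytest.approx(1.0)

    def test_f_value_and_p_from_distribution(self):
        from alleledyn.model_fit import FitResult
        from alleledyn.state_models import ModelKind

        def dummy(chi2_red, dof, kind):
            return FitResult(
                model_kind=kind, rates=RateParams(kC=0.01), init=naive_init(kind),
                delays=DelayVector.zero(), chi2_red=chi2_red, dof=dof,
                n_points=dof + 1, n_free=1, sse=chi2_red * dof,
                param_names=("kC",), param_values=np.array([0.01]),
                param_cov=None, seed=0,
            )

        a = dummy(2.0, 20, ModelKind.CIS_ONLY)
        b = dummy(1.0, 18, ModelKind.PARALLEL)
        cmp_ = compare_models(a, b)
        assert cmp_.F_value == pytest.approx(2.0)
        assert cmp_.p_value == pytest.approx(float(stats.f.sf(2.0, 20, 18)))
        # paper-scale ratio: chi2 ratio of 12.2 yields F = 12.2 by definition
        cmp2 = compare_models(dummy(12.2, 9, ModelKind.CIS_ONLY), dummy(1.0, 7, ModelKind.PARALLEL))
        assert cmp2.F_value == pytest.approx(12.2)

    def test_perfect_reference_fit_reports_infinite_f(self):
        t = np.arange(2.5, 105, 5.0)
        f = closed_form_cis_only(0.005, t)
        series = make_series(f, 0.01, times=t)
        good = fit_model("cis_only", series, DelayVector.zero(), seed=0)
        bad = fit_model("sequential", series, DelayVector.zero(), seed=0, n_restarts=4)
        cmp_ = compare_models(good, bad)
        if cmp_.better.value == "cis_only" and good.chi2_red == 0.0:
            assert np.isinf(cmp_.F_value)


class TestCITableReader:
    def test_reads_fraction_ci_layout(self, tmp_path):
        import pandas as pd

        df = pd.DataFrame(
            {
                "time_h": [10.0, 20.0],
                "f_none": [0.9, 0.8],
                "f_monoY": [0.05, 0.1],
                "f_monoR": [0.05, 0.08],
                "f_bi": [0.0, 0.02],
                "ci_none": [0.0392, 0.0392],
                "ci_monoY": [0.0196, 0.0196],
                "ci_monoR": [0.0196, 0.0196],
                "ci_bi": [0.0098, 0.0098],
            }
        )
        path = tmp_path / "frac.csv"
        df.to_csv(path, index=False)
        series = read_fraction_table_ci(path)
        assert series.df_obs[0, 0] == pytest.approx(0.02)
        assert series.df_obs[0, 1] == pytest.approx(0.01)
        assert series.f_obs[1, 3] == pytest.approx(0.02)
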