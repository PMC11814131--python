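import numpy as np
import pandas as pd
import pytest

from mhwbloom import (
    InjectedEvent,
    ScenarioConfig,
    build_climatology,
    generate_chla,
    generate_chla_field,
    generate_sst,
    generate_sst_field,
)
from mhwbloom.synthetic import _bloom_curve, _seasonal_sst

from _oracles import lag1_autocorr


def warm_event(start="2005-01-10", duration=15, amplitude=2.0, **kw):
    return InjectedEvent("warm", start, duration, amplitude, **kw)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "field,value",
        [
            ("n_years", 0),
            ("ar1_coef", 1.0),
            ("ar1_coef", -0.1),
            ("noise_sd", -1.0),
            ("missing_fraction", 1.0),
            ("chla_base", 0.0),
            ("outlier_rate", -0.01),
        ],
    )
    def test_invalid_fields_error_by_name(self, field, value):
        with pytest.raises(ValueError, match=field):
            ScenarioConfig(**{field: value})

    def test_event_outside_axis_is_rejected(self):
        cfg = ScenarioConfig(n_years=2, start_year=2000,
                             injected_events=(warm_event("2005-01-10"),))
        with pytest.raises(ValueError, match="outside"):
            generate_sst(cfg)

    def test_inconsistent_chla_response_is_rejected(self):
        with pytest.raises(ValueError, match="chla_response_amp"):
            InjectedEvent("warm", "2005-01-10", 10, 2.0,
                          chla_response_sign=-1, chla_response_amp=2.0)


class TestSST:
    def test_zero_noise_null_scenario_is_the_pure_seasonal_cycle(self):
        cfg = ScenarioConfig(n_years=3, start_year=2000, noise_sd=0.0)
        sst, _ = generate_sst(cfg)
        assert np.allclose(sst.to_numpy(), _seasonal_sst(cfg, cfg.dates))

    def test_same_seed_is_bit_identical(self):
        cfg = ScenarioConfig(n_years=3, seed=99)
        a, truth_a = generate_sst(cfg)
        b, truth_b = generate_sst(cfg)
        assert (a.to_numpy() == b.to_numpy()).all()
        assert generate_chla(cfg, truth_a).equals(generate_chla(cfg, truth_b))

    def test_series_length_covers_whole_calendar_years(self):
        cfg = ScenarioConfig(n_years=3, start_year=1999)  # includes leap 2000
        sst, _ = generate_sst(cfg)
        assert len(sst) == 365 + 366 + 365
        assert sst.index[0] == pd.Timestamp("1999-01-01")
        assert sst.index[-1] == pd.Timestamp("2001-12-31")

    def test_injected_events_shift_values_by_exactly_their_amplitude(self):
        base_cfg = ScenarioConfig(n_years=4, start_year=2004, seed=5)
        ev_cfg = ScenarioConfig(
            n_years=4, start_year=2004, seed=5,
            injected_events=(
                warm_event("2005-02-01", 12, 1.5),
                InjectedEvent("cold", "2006-12-20", 20, 2.0),
            ),
        )
        base, _ = generate_sst(base_cfg)
        shifted, truth = generate_sst(ev_cfg)
        diff = shifted - base
        warm_days = diff.loc["2005-02-01":"2005-02-12"]
        cold_days = diff.loc["2006-12-20":"2007-01-08"]
        assert np.allclose(warm_days, 1.5)
        assert np.allclose(cold_days, -2.0)
        assert (diff.abs() > 1e-12).sum() == 12 + 20
        # truth records the realized spans exactly as requested
        assert truth.events[0].start_date == pd.Timestamp("2005-02-01")
        assert truth.events[0].end_date == pd.Timestamp("2005-02-12")

    def test_residual_autocorrelation_matches_the_ar1_coefficient(self):
        cfg = ScenarioConfig(n_years=10, start_year=2000, ar1_coef=0.7, seed=11)
        sst, _ = generate_sst(cfg)
        residuals = sst.to_numpy() - _seasonal_sst(cfg, cfg.dates)
        assert lag1_autocorr(residuals) == pytest.approx(0.7, abs=0.05)

    def test_warming_trend_recovers_in_annual_means(self):
        cfg = ScenarioConfig(n_years=30, start_year=1989, noise_sd=0.0,
                             warming_trend=0.5)
        sst, _ = generate_sst(cfg)
        annual = sst.groupby(sst.index.year).mean()
        fit = np.polyfit(annual.index, annual.to_numpy(), 1)
        assert fit[0] * 10 == pytest.approx(0.5, abs=0.02)


class TestChla:
    def test_noise_free_series_is_the_smooth_bloom_curve(self):
        cfg = ScenarioConfig(n_years=2, start_year=2000, chla_noise_cv=0.0,
                             missing_fraction=0.0, outlier_rate=0.0)
        _, truth = generate_sst(cfg)
        chla = generate_chla(cfg, truth)
        assert np.allclose(chla.to_numpy(), _bloom_curve(cfg, cfg.dates))
        assert (chla > 0).all()

    def test_event_span_mean_is_scaled_by_the_response_factor(self):
        common = dict(n_years=4, start_year=2004, chla_noise_cv=0.0,
                      missing_fraction=0.0, outlier_rate=0.0,
                      coupling_lag_days=0, seed=3)
        quiet = ScenarioConfig(**common)
        _, quiet_truth = generate_sst(quiet)
        ref = generate_chla(quiet, quiet_truth)
        cfg = ScenarioConfig(
            injected_events=(warm_event("2005-01-10", 15, 2.0,
                                        chla_response_amp=0.5),),
            **common,
        )
        _, truth = generate_sst(cfg)
        chla = generate_chla(cfg, truth)
        span = slice("2005-01-10", "2005-01-24")
        assert chla.loc[span].mean() == pytest.approx(0.5 * ref.loc[span].mean())
        outside = chla.drop(chla.loc[span].index)
        assert np.allclose(outside, ref.drop(ref.loc[span].index))

    def test_response_is_shifted_by_the_coupling_lag(self):
        common = dict(n_years=3, start_year=2004, chla_noise_cv=0.0,
                      missing_fraction=0.0, outlier_rate=0.0, seed=3)
        cfg = ScenarioConfig(coupling_lag_days=5,
                             injected_events=(warm_event("2005-01-10", 10, 2.0),),
                             **common)
        quiet = ScenarioConfig(coupling_lag_days=5, **common)
        _, truth = generate_sst(cfg)
        _, quiet_truth = generate_sst(quiet)
        ratio = generate_chla(cfg, truth) / generate_chla(quiet, quiet_truth)
        assert np.allclose(ratio.loc["2005-01-15":"2005-01-24"], 0.5)
        assert np.allclose(ratio.loc["2005-01-10":"2005-01-14"], 1.0)

    def test_missing_fraction_is_realized(self):
        cfg = ScenarioConfig(n_years=10, start_year=2000, missing_fraction=0.2,
                             seed=8)
        _, truth = generate_sst(cfg)
        chla = generate_chla(cfg, truth)
        frac = chla.isna().mean()
        assert frac == pytest.approx(0.20, abs=0.02)

    def test_outliers_exceed_the_qc_cap(self):
        cfg = ScenarioConfig(n_years=10, start_year=2000, outlier_rate=0.01,
                             missing_fraction=0.0, seed=8)
        _, truth = generate_sst(cfg)
        chla = generate_chla(cfg, truth)
        spikes = chla[chla > 10.0]
        assert len(spikes) > 0
        assert (spikes <= 20.0).all()

    def test_oversized_lag_errors(self):
        cfg = ScenarioConfig(n_years=1, start_year=2000, coupling_lag_days=400)
        _, truth = generate_sst(cfg)
        with pytest.raises(ValueError, match="coupling_lag_days"):
            generate_chla(cfg, truth)


class TestNullCalibration:
    def test_exceedance_above_p90_threshold_is_ten_percent(self, null_scenario,
                                                           null_climatology):
        _, sst, _ = null_scenario
        above = sst.to_numpy() > null_climatology.threshold(90.0, sst.index)
        assert 100.0 * above.mean() == pytest.approx(10.0, abs=1.5)


class TestGriddedFields:
    def test_sst_field_pixels_scatter_around_the_series(self):
        cfg = ScenarioConfig(n_years=1, start_year=2000, seed=2)
        sst, _ = generate_sst(cfg)
        field, _ = generate_sst_field(cfg, [20.0, 21.0], [38.0, 39.0],
                                      pixel_noise_sd=0.05)
        assert field.dims == ("time", "lat", "lon")
        pixel_mean = field.mean(dim=("lat", "lon")).to_numpy()
        assert np.corrcoef(pixel_mean, sst.to_numpy())[0, 1] > 0.99

    def test_chla_field_has_dropout_days(self):
        cfg = ScenarioConfig(n_years=2, start_year=2000, seed=2)
        _, truth = generate_sst(cfg)
        field = generate_chla_field(cfg, truth, np.arange(20, 22, 0.5),
                                    np.arange(38, 40, 0.5),
                                    dropout_day_fraction=0.1)
        coverage = field.notnull().mean(dim=("lat", "lon")).to_numpy()
        assert (coverage < 0.3).sum() > 10

    def test_field_generation_is_deterministic(self):
        cfg = ScenarioConfig(n_years=1, start_year=2000, seed=4)
        a, _ = generate_sst_field(cfg, [20.0], [38.0])
        b, _ = generate_sst_field(cfg, [20.0], [38.0])
        assert (a.to_numpy() == b.to_numpy()).all()
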