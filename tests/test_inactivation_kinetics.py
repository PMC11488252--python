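import math

import numpy as np
import pytest

from thermoclot.errors import DomainError, InsufficientDataError, ValidationError
from thermoclot.inactivation_kinetics import (ThermalSeries,
                                              check_half_life_d_value,
                                              d_value, d_value_from_half_life,
                                              fit_first_order_decay, half_life,
                                              half_life_from_d_value,
                                              series_from_frame,
                                              summarize_inactivation)
from thermoclot.synthetic_data import SimulationConfig, generate_thermal_series


def exact_series(kd, times=(0.0, 15.0, 30.0, 45.0, 60.0), **kw):
    return ThermalSeries(
        level=kw.pop("level", 50.0),
        times_min=times,
        residual_activity=tuple(100.0 * math.exp(-kd * t) for t in times),
        **kw)


class TestFitFirstOrderDecay:
    def test_noiseless_exponential_recovers_kd_exactly(self):
        fit = fit_first_order_decay(exact_series(0.01))
        assert fit.kd == pytest.approx(0.01, rel=1e-10)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)
        assert fit.decaying

    def test_two_point_fit_matches_closed_form(self):
        series = ThermalSeries(level=50.0, times_min=(0.0, 60.0),
                               residual_activity=(100.0, 50.0))
        with pytest.warns(UserWarning, match="only 2 points"):
            fit = fit_first_order_decay(series)
        assert fit.kd == pytest.approx(math.log(2) / 60, rel=1e-12)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.half_life_min == pytest.approx(60.0, rel=1e-12)

    def test_noisy_synthetic_series_recovers_kd_within_15_percent(self):
        # sampling spans ~two half-lives; a shorter window leaves the slope
        # ill-conditioned relative to sigma = 0.05 noise
        config = SimulationConfig(
            temperatures_C=(55.0,),
            times_min=(0.0, 60.0, 120.0, 180.0, 240.0, 300.0),
            kd_by_temperature={55.0: 0.005},
            noise_model="multiplicative_lognormal", noise_sd=0.05, seed=42)
        (series,) = generate_thermal_series(config)
        fit = fit_first_order_decay(series)
        assert fit.kd == pytest.approx(0.005, rel=0.15)

    def test_nonpositive_activities_are_excluded_not_fatal(self, caplog):
        series = ThermalSeries(level=50.0, times_min=(0.0, 30.0, 60.0, 90.0),
                               residual_activity=(100.0, 50.0, 25.0, 0.0))
        with caplog.at_level("WARNING"):
            fit = fit_first_order_decay(series)
        assert fit.n_points == 3
        assert "non-positive" in caplog.text
        assert fit.kd == pytest.approx(math.log(2) / 30, rel=1e-10)

    def test_fewer_than_two_usable_points_is_an_error(self):
        series = ThermalSeries(level=50.0, times_min=(0.0, 30.0),
                               residual_activity=(100.0, 0.0))
        with pytest.raises(InsufficientDataError):
            fit_first_order_decay(series)

    def test_rising_activity_flagged_as_non_decaying(self):
        series = ThermalSeries(level=30.0, times_min=(0.0, 30.0, 60.0),
                               residual_activity=(100.0, 110.0, 120.0))
        fit = fit_first_order_decay(series)
        assert not fit.decaying
        assert math.isnan(fit.half_life_min)
        assert math.isnan(fit.d_value_min)

    def test_activity_scale_only_moves_the_intercept(self):
        base = exact_series(0.004)
        scaled = ThermalSeries(
            level=base.level, times_min=base.times_min,
            residual_activity=tuple(3.7 * a for a in base.residual_activity))
        f1, f2 = fit_first_order_decay(base), fit_first_order_decay(scaled)
        assert f2.kd == pytest.approx(f1.kd, rel=1e-12)
        assert f2.intercept == pytest.approx(f1.intercept + math.log(3.7))

    def test_times_must_strictly_increase(self):
        with pytest.raises(ValidationError):
            ThermalSeries(level=50.0, times_min=(0.0, 30.0, 30.0),
                          residual_activity=(100.0, 50.0, 40.0))


class TestDerivedTimes:
    def test_unit_cases(self):
        assert half_life(math.log(2)) == pytest.approx(1.0)
        assert d_value(math.log(10)) == pytest.approx(1.0)

    @pytest.mark.parametrize("kd, expected_half_life", [
        (math.log(10) / 718, 216),   # reported immobilized D at 50 degC
        (0.0052116, 133),
    ])
    def test_half_life_values(self, kd, expected_half_life):
        assert round(half_life(kd)) == expected_half_life

    def test_half_life_full_precision_case(self):
        assert half_life(0.0052116) == pytest.approx(133.0, abs=0.05)

    @pytest.mark.parametrize("kd, expected_d", [
        (math.log(2) / 182, 605),    # reported free t1/2 at 55 degC
        (math.log(2) / 192, 638),    # reported immobilized t1/2 at 55 degC
    ])
    def test_d_values(self, kd, expected_d):
        assert round(d_value(kd)) == expected_d

    @pytest.mark.parametrize("func", [half_life, d_value,
                                      d_value_from_half_life,
                                      half_life_from_d_value])
    def test_nonpositive_arguments_rejected(self, func):
        with pytest.raises(DomainError):
            func(0.0)
        with pytest.raises(DomainError):
            func(-1.0)

    def test_interconversion_round_trip(self):
        assert half_life_from_d_value(d_value_from_half_life(123.4)) == (
            pytest.approx(123.4, rel=1e-14))


class TestPairConsistency:
    def test_rounded_but_consistent_pair_passes(self):
        report = check_half_life_d_value(182, 605)
        assert report.consistent
        assert abs(report.deviation_min) < 1

    def test_inconsistent_pair_is_detected(self):
        # 238 min implies D = 790.7 min; the reported 793 is 2.4 min off
        report = check_half_life_d_value(238, 793)
        assert not report.consistent
        assert report.deviation_min == pytest.approx(2.38, abs=0.01)


class TestSummarizeInactivation:
    def test_noiseless_batch_reports_expected_half_lives(self):
        kds = (0.002, 0.003, 0.005)
        series = [exact_series(kd, level=level, form="free")
                  for kd, level in zip(kds, (50.0, 55.0, 60.0))]
        table = summarize_inactivation(series)
        assert list(table["half_life_min"].round(1)) == [346.6, 231.0, 138.6]
        assert (table["r_squared"] > 1 - 1e-12).all()

    def test_rows_ordered_by_form_then_level(self):
        series = [exact_series(0.01, level=60.0, form="immobilized"),
                  exact_series(0.01, level=50.0, form="free"),
                  exact_series(0.01, level=50.0, form="immobilized")]
        table = summarize_inactivation(series)
        assert list(zip(table["form"], table["level"])) == [
            ("free", 50.0), ("immobilized", 50.0), ("immobilized", 60.0)]

    def test_empty_input_yields_empty_table_with_warning(self):
        with pytest.warns(UserWarning, match="no series"):
            table = summarize_inactivation([])
        assert table.empty
        assert "kd_per_min" in table.columns

    def test_fit_errors_identify_the_series(self):
        bad = ThermalSeries(level=55.0, times_min=(0.0, 30.0),
                            residual_activity=(100.0, 0.0), form="immobilized")
        with pytest.raises(InsufficientDataError, match="level=55.0"):
            summarize_inactivation([bad])


def test_series_from_frame_groups_and_orders():
    import pandas as pd
    frame = pd.DataFrame({
        "form": ["free", "free", "free", "immobilized", "immobilized"],
        "temperature_C": [50, 50, 50, 50, 50],
        "time_min": [30, 0, 60, 0, 60],
        "residual_pct": [74.1, 100.0, 54.9, 100.0, 80.0],
    })
    series = series_from_frame(frame)
    assert [s.form for s in series] == ["free", "immobilized"]
    assert series[0].times_min == (0.0, 30.0, 60.0)
    assert series[0].residual_activity == (100.0, 74.1, 54.9)
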